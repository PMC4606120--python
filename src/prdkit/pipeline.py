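"""End-to-end orchestration: scan, annotate, enrich, census, report.

The reporting layer makes every printed percentage a pure function of its
integer numerator and denominator plus an explicit decimals setting, with
half-away-from-zero rounding — so report-level numbers are exactly
recomputable from the counts the pipeline also emits.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import annotation as ann_mod
from . import enrichment as enr_mod
from . import prd_scorer as scorer_mod
from . import sequence_io as seq_mod
from . import synthetic_data as syn_mod

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_STAGE = 3

#: decimals used for each summary percentage (explicit, never inferred)
PCT_DECIMALS = {
    "pct_prd": 1,
    "pct_annotated": 2,
    "pct_with_domain": 0,
    "pct_multidomain": 0,
    "pct_prd_pathogen": 1,
    "pct_prd_share_pathogen": 0,
    "per_organism": 1,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def report_fraction(numerator: int, denominator: int, decimals: int) -> float:
    """``100 * numerator / denominator`` rounded half-away-from-zero.

    This is the single rounding rule behind every reported percentage.
    """
    if denominator == 0:
        raise ValueError("denominator must be non-zero")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-loadable).

    Either ``fasta`` + ``annotations`` point at real inputs, or
    ``simulate`` is true and seeded synthetic inputs are generated with
    ``sim_proteome`` / ``sim_annotation`` parameter overrides.
    """

    fasta: Optional[str] = None
    metadata: Optional[str] = None
    annotations: Optional[str] = None
    cluster_map: Optional[str] = None
    prion_model: Optional[str] = None
    background_model: Optional[str] = None

    window_length: int = 60
    step: int = 1
    cutoff_bits: float = 50.0
    merge_gap: int = 0

    namespace: str = "GO"
    background_universe: str = "all"
    log2_min: float = 0.5
    fdr: float = 0.1
    census_min_count: int = 5

    pathogen_organisms: list[str] = field(default_factory=list)

    simulate: bool = False
    sim_proteome: dict = field(default_factory=dict)
    sim_annotation: dict = field(default_factory=dict)

    out_dir: str = "prdkit_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def scoring_params(self) -> scorer_mod.ScoringParams:
        return scorer_mod.ScoringParams(
            window_length=self.window_length,
            step=self.step,
            cutoff_bits=self.cutoff_bits,
            merge_gap=self.merge_gap,
        )

    def validate(self) -> None:
        if not self.simulate:
            for key in ("fasta", "annotations"):
                value = getattr(self, key)
                if value is None:
                    raise ValueError(
                        f"config requires {key!r} unless simulate is true"
                    )
                if not Path(value).exists():
                    raise ValueError(f"{key} path does not exist: {value}")
        for key in ("metadata", "cluster_map", "prion_model",
                    "background_model"):
            value = getattr(self, key)
            if value is not None and not Path(value).exists():
                raise ValueError(f"{key} path does not exist: {value}")
        if not (0 < self.fdr <= 1):
            raise ValueError("fdr must lie in (0, 1]")
        if self.log2_min < 0:
            raise ValueError("log2_min must be >= 0")


@dataclass
class SummaryReport:
    """Headline counts and percentages of one run.

    Every percentage equals ``report_fraction(numerator, denominator,
    PCT_DECIMALS[...])`` of the counts carried alongside it.
    """

    n_proteomes: int
    n_proteins: int
    n_prd: int
    pct_prd: float
    n_annotated: int
    pct_annotated: float
    n_with_domain: int
    pct_with_domain: float
    n_multidomain: int
    pct_multidomain: float
    per_organism: list[dict]
    n_prd_pathogen: int
    n_proteins_pathogen: int
    pct_prd_pathogen: Optional[float]
    pct_prd_share_pathogen: Optional[float]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def per_organism_breakdown(
    calls: scorer_mod.PrDCallSet,
    proteome_sizes: Optional[dict[str, int]] = None,
    decimals: int = 1,
) -> pd.DataFrame:
    """Per-organism PrD counts and shares.

    ``pct_of_all_prd`` is each organism's share of all calls;
    ``pct_of_organism_proteome`` (needs ``proteome_sizes``) is the PrD
    percentage within that organism's proteome.
    """
    counts = calls.per_organism_counts()
    total = sum(counts.values())
    rows = []
    for organism in sorted(counts, key=lambda o: (-counts[o], o)):
        n = counts[organism]
        row = {
            "organism": organism,
            "n_prd": n,
            "pct_of_all_prd": report_fraction(n, total, decimals),
        }
        if proteome_sizes and organism in proteome_sizes:
            row["pct_of_organism_proteome"] = report_fraction(
                n, proteome_sizes[organism], decimals
            )
        else:
            row["pct_of_organism_proteome"] = float("nan")
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["organism", "n_prd", "pct_of_all_prd",
                 "pct_of_organism_proteome"],
    )


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        prot_kwargs = dict(config.sim_proteome)
        prot_kwargs.setdefault("seed", config.seed)
        proteome_params = syn_mod.SyntheticProteomeParams(**prot_kwargs)
        proteome, truth = syn_mod.generate_proteome(proteome_params)
        ann_kwargs = dict(config.sim_annotation)
        ann_kwargs.setdefault("seed", config.seed)
        ann_params = syn_mod.SyntheticAnnotationParams(**ann_kwargs)
        annotations, truth = syn_mod.generate_annotations(
            proteome, truth, ann_params
        )
        return proteome, annotations, truth
    proteome = seq_mod.read_fasta(config.fasta)
    if config.metadata:
        seq_mod.apply_metadata(proteome, seq_mod.read_metadata(config.metadata))
    annotations = ann_mod.load_annotations(config.annotations)
    return proteome, annotations, None


def run_pipeline(config: PipelineConfig) -> SummaryReport:
    """Run scan -> annotate -> enrich -> census -> report; write all outputs.

    Outputs under ``config.out_dir``: calls.tsv, enrichment_go.tsv,
    enrichment_pfam.tsv, enrichment_comparison.tsv (when a pathogen subset
    exists), census.tsv, clusters.tsv, summary.json, summary.tsv, truth.tsv
    (simulated runs) and the effective config echo.  Deterministic given
    config (and seed for simulated inputs).
    """
    try:
        config.validate()
    except ValueError as exc:
        raise StageError("validate", str(exc)) from exc
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "effective_config.yaml")

    stage = "load"
    try:
        proteome, annotations, truth = _load_inputs(config)
        logger.info("load: %d proteins, %d organisms, %d annotation rows",
                    proteome.n_proteins, proteome.n_proteomes,
                    len(annotations))

        stage = "scan"
        prion = (scorer_mod.CompositionModel.from_tsv(config.prion_model)
                 if config.prion_model else scorer_mod.default_prion_model())
        background = (
            scorer_mod.CompositionModel.from_tsv(config.background_model)
            if config.background_model
            else scorer_mod.default_background_model()
        )
        calls = scorer_mod.scan_proteome(proteome, prion, background,
                                         config.scoring_params())
        scorer_mod.write_calls(calls, out_dir / "calls.tsv")
        if truth is not None:
            truth.to_tsv(out_dir / "truth.tsv")
        logger.info("scan: %d/%d proteins called PrD-positive",
                    calls.n_calls, calls.n_scanned)

        stage = "enrich"
        pathogens = set(config.pathogen_organisms)
        try:
            enrich_go = enr_mod.run_enrichment(
                calls, annotations, namespace="GO",
                background=config.background_universe,
                log2_min=config.log2_min, fdr=config.fdr,
            )
        except enr_mod.EmptyUniverseError:
            logger.warning("enrich: no GO-annotated PrD protein; GO "
                           "enrichment skipped")
            enrich_go = pd.DataFrame(columns=enr_mod.RESULT_COLUMNS)
        enrich_go.to_csv(out_dir / "enrichment_go.tsv", sep="\t", index=False)
        try:
            enrich_pfam = enr_mod.run_enrichment(
                calls, annotations, namespace="Pfam",
                background=config.background_universe,
                log2_min=config.log2_min, fdr=config.fdr,
            )
        except enr_mod.EmptyUniverseError:
            logger.warning("enrich: no Pfam-annotated PrD protein; Pfam "
                           "enrichment skipped")
            enrich_pfam = pd.DataFrame(columns=enr_mod.RESULT_COLUMNS)
        enrich_pfam.to_csv(out_dir / "enrichment_pfam.tsv", sep="\t",
                           index=False)
        logger.info("enrich: %d GO terms (%d significant), %d Pfam terms "
                    "(%d significant)",
                    len(enrich_go), int(enrich_go["significant"].sum())
                    if len(enrich_go) else 0,
                    len(enrich_pfam), int(enrich_pfam["significant"].sum())
                    if len(enrich_pfam) else 0)

        stage = "pathogen-subset"
        pathogen_calls = [
            c for c in calls
            if c.is_pathogen or c.organism in pathogens
        ]
        n_prd_pathogen = len(pathogen_calls)
        if pathogen_calls:
            subset = scorer_mod.PrDCallSet(
                calls=pathogen_calls, n_scanned=calls.n_scanned
            )
            try:
                enrich_sub = enr_mod.run_enrichment(
                    subset, annotations, namespace="GO",
                    background=config.background_universe,
                    log2_min=config.log2_min, fdr=config.fdr,
                )
                joined, _, _ = enr_mod.compare_subsets(enrich_sub, enrich_go)
                joined.to_csv(out_dir / "enrichment_comparison.tsv",
                              sep="\t", index=False)
            except enr_mod.EmptyUniverseError:
                logger.warning("pathogen subset has no annotated PrD "
                               "protein; comparison skipped")
        else:
            logger.warning("no pathogen-flagged PrD calls; subset "
                           "comparison skipped")

        stage = "census"
        census = ann_mod.pfam_census(calls, annotations,
                                     min_count=config.census_min_count)
        cluster_map = (
            ann_mod.FunctionalClusterMap.from_yaml(config.cluster_map)
            if config.cluster_map
            else ann_mod.FunctionalClusterMap()
        )
        census["cluster"] = [cluster_map.cluster_of(p)
                             for p in census["pfam_id"]]
        census.to_csv(out_dir / "census.tsv", sep="\t", index=False)
        clusters = ann_mod.cluster_rollup(census[["pfam_id", "count"]],
                                          cluster_map)
        clusters.to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
        logger.info("census: %d domain families above the >%d filter",
                    len(census), config.census_min_count)

        stage = "report"
        n_annotated = sum(
            1 for c in calls
            if (a := annotations.get(c.accession)) is not None
            and a.is_go_annotated
        )
        if calls.n_calls:
            md = ann_mod.multidomain_stats(calls, annotations)
            n_with, pct_with = md.n_with_domain, md.pct_with_domain
            n_multi, pct_multi = (md.n_multidomain,
                                  md.pct_multidomain_of_with_domain)
            pct_annotated = report_fraction(
                n_annotated, calls.n_calls, PCT_DECIMALS["pct_annotated"]
            )
        else:
            n_with = n_multi = 0
            pct_with = pct_multi = 0.0
            pct_annotated = 0.0

        sizes: dict[str, int] = {}
        n_proteins_pathogen = 0
        for rec in proteome:
            sizes[rec.organism] = sizes.get(rec.organism, 0) + 1
            if rec.is_pathogen or rec.organism in pathogens:
                n_proteins_pathogen += 1
        breakdown = per_organism_breakdown(
            calls, sizes, PCT_DECIMALS["per_organism"]
        ) if calls.n_calls else pd.DataFrame(
            columns=["organism", "n_prd", "pct_of_all_prd",
                     "pct_of_organism_proteome"]
        )
        breakdown.to_csv(out_dir / "per_organism.tsv", sep="\t", index=False)

        report = SummaryReport(
            n_proteomes=proteome.n_proteomes,
            n_proteins=proteome.n_proteins,
            n_prd=calls.n_calls,
            pct_prd=report_fraction(calls.n_calls, proteome.n_proteins,
                                    PCT_DECIMALS["pct_prd"]),
            n_annotated=n_annotated,
            pct_annotated=pct_annotated,
            n_with_domain=n_with,
            pct_with_domain=pct_with,
            n_multidomain=n_multi,
            pct_multidomain=pct_multi,
            per_organism=breakdown.to_dict("records"),
            n_prd_pathogen=n_prd_pathogen,
            n_proteins_pathogen=n_proteins_pathogen,
            pct_prd_pathogen=(
                report_fraction(n_prd_pathogen, n_proteins_pathogen,
                                PCT_DECIMALS["pct_prd_pathogen"])
                if n_proteins_pathogen else None
            ),
            pct_prd_share_pathogen=(
                report_fraction(n_prd_pathogen, calls.n_calls,
                                PCT_DECIMALS["pct_prd_share_pathogen"])
                if calls.n_calls else None
            ),
        )
        with (out_dir / "summary.json").open("w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
            fh.write("\n")
        summary_rows = [
            (k, v) for k, v in report.to_dict().items() if k != "per_organism"
        ]
        pd.DataFrame(summary_rows, columns=["field", "value"]).to_csv(
            out_dir / "summary.tsv", sep="\t", index=False
        )
        logger.info("report: %d PrD calls (%s%%) in %d proteins",
                    report.n_prd, report.pct_prd, report.n_proteins)
        return report
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
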