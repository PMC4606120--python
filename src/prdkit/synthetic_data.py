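"""Seeded synthetic proteomes and annotation tables with planted ground truth.

The generator emulates, at desk scale, the two inputs of the analysis:

* bacterial proteomes in which a small fraction of proteins (default 0.3%)
  carry an N/Q/S/G-biased low-complexity segment planted into an otherwise
  background-composition sequence, and
* annotation tables in which chosen GO terms are over-represented among the
  PrD-carrying proteins by a controlled fold, on top of an independent
  per-term baseline, with only a fraction of PrD proteins (default 11%)
  GO-annotated at all.

Planted segments *replace* background residues rather than being inserted,
so protein lengths follow the configured distribution exactly.  Every draw
comes from a per-protein substream seeded as ``[seed, stage, index]``, so
outputs are pure functions of (params, seed) and do not depend on
iteration order.

The ground truth (planted intervals, true term folds) is carried in a
:class:`SyntheticTruth` and suffices to score any downstream call set as
TP/FP/FN.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .annotation import AnnotationTable, ProteinAnnotation
from .prd_scorer import (
    CompositionModel,
    PrDCallSet,
    default_background_model,
    default_prion_model,
)
from .sequence_io import STANDARD_AMINO_ACIDS, ProteinRecord, ProteomeSet

logger = logging.getLogger(__name__)

_RESIDUES = np.array(list(STANDARD_AMINO_ACIDS))

# substream tags so proteome and annotation draws never collide
_STAGE_PROTEOME = 0
_STAGE_ANNOTATION = 1


@dataclass
class SyntheticProteomeParams:
    """Parameters of the proteome generator.

    Defaults mirror the study conditions: 0.3% of proteins carry a planted
    PrD of 60-150 residues drawn from the N 30% / Q 21% / S 11% / G 11%
    composition; the rest is background composition throughout.
    """

    n_proteins: int = 10_000
    length_min: int = 200
    length_max: int = 600
    background: Optional[CompositionModel] = None
    prd_fraction: float = 0.003
    prd_length_min: int = 60
    prd_length_max: int = 150
    prion: Optional[CompositionModel] = None
    organism: str = "synthetic"
    is_pathogen: bool = False
    accession_prefix: str = "SYN"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.prd_fraction <= 1.0):
            raise ValueError("prd_fraction must lie in [0, 1]")
        if self.length_min < 1 or self.length_max < self.length_min:
            raise ValueError("invalid protein length range")
        if (self.prd_length_min < 1
                or self.prd_length_max < self.prd_length_min):
            raise ValueError("invalid PrD length range")
        if self.prd_length_max > self.length_min:
            raise ValueError(
                "prd_length_max exceeds length_min: a planted PrD could be "
                "longer than its protein"
            )
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")


@dataclass
class SyntheticAnnotationParams:
    """Parameters of the annotation generator.

    ``planted_terms`` lists (term_id, fold): among annotated PrD-truth
    proteins the term's assignment probability is ``fold * baseline``
    (capped at 1 with a logged warning); everywhere else it is ``baseline``.
    """

    n_terms: int = 50
    baseline: float = 0.02
    planted_terms: Sequence[tuple[str, float]] = ()
    annotated_fraction: float = 0.11
    pfam_catalog_size: int = 30
    #: probability of a protein having 0, 1, 2, ... Pfam domain instances
    architecture_dist: Sequence[float] = (0.30, 0.40, 0.20, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.baseline <= 1.0):
            raise ValueError("baseline must lie in [0, 1]")
        if not (0.0 <= self.annotated_fraction <= 1.0):
            raise ValueError("annotated_fraction must lie in [0, 1]")
        for term, fold in self.planted_terms:
            if fold < 1.0:
                raise ValueError(
                    f"planted fold for {term!r} must be >= 1 (got {fold})"
                )
        if abs(sum(self.architecture_dist) - 1.0) > 1e-9:
            raise ValueError("architecture_dist must sum to 1")

    @property
    def term_catalog(self) -> list[str]:
        catalog = [f"GO:{i + 1:07d}" for i in range(self.n_terms)]
        for term, _ in self.planted_terms:
            if term not in catalog:
                catalog.append(term)
        return catalog

    @property
    def pfam_catalog(self) -> list[str]:
        return [f"PFSYN{i + 1:04d}" for i in range(self.pfam_catalog_size)]


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic dataset.

    ``prd_intervals`` maps accession -> (start, end), 1-based inclusive,
    for proteins that received a planted segment; ``term_folds`` records
    every catalogued term's true fold (1.0 unless planted).
    """

    accessions: list[str] = field(default_factory=list)
    prd_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    term_folds: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    @property
    def n_planted(self) -> int:
        return len(self.prd_intervals)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["kind", "id", "value_1", "value_2"])
            for acc in self.accessions:
                if acc in self.prd_intervals:
                    s, e = self.prd_intervals[acc]
                    writer.writerow(["prd", acc, s, e])
                else:
                    writer.writerow(["prd", acc, "none", "none"])
            for term, fold in sorted(self.term_folds.items()):
                writer.writerow(["term", term, fold, ""])

    @classmethod
    def from_tsv(cls, path: str | Path, seed: int = 0) -> "SyntheticTruth":
        truth = cls(seed=seed)
        with Path(path).open() as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                if row["kind"] == "prd":
                    truth.accessions.append(row["id"])
                    if row["value_1"] != "none":
                        truth.prd_intervals[row["id"]] = (
                            int(row["value_1"]), int(row["value_2"])
                        )
                elif row["kind"] == "term":
                    truth.term_folds[row["id"]] = float(row["value_1"])
        return truth


def _model_probs(model: CompositionModel) -> np.ndarray:
    return np.array([model.probs[a] for a in STANDARD_AMINO_ACIDS])


def sample_region(
    rng: np.random.Generator, length: int, probs: np.ndarray
) -> str:
    idx = rng.choice(len(_RESIDUES), size=length, p=probs)
    return "".join(_RESIDUES[idx])


def generate_proteome(
    params: SyntheticProteomeParams,
) -> tuple[ProteomeSet, SyntheticTruth]:
    """Generate a seeded synthetic proteome with planted PrD segments."""
    background = (params.background if params.background is not None
                  else default_background_model())
    prion = (params.prion if params.prion is not None
             else default_prion_model())
    bg_probs = _model_probs(background)
    prd_probs = _model_probs(prion)

    width = max(5, len(str(params.n_proteins)))
    proteome = ProteomeSet()
    truth = SyntheticTruth(seed=params.seed)

    for i in range(params.n_proteins):
        rng = np.random.default_rng([params.seed, _STAGE_PROTEOME, i])
        length = int(rng.integers(params.length_min, params.length_max + 1))
        seq = sample_region(rng, length, bg_probs)
        accession = f"{params.accession_prefix}{i:0{width}d}"
        if rng.random() < params.prd_fraction:
            prd_len = int(rng.integers(params.prd_length_min,
                                       params.prd_length_max + 1))
            start0 = int(rng.integers(0, length - prd_len + 1))
            planted = sample_region(rng, prd_len, prd_probs)
            seq = seq[:start0] + planted + seq[start0 + prd_len:]
            truth.prd_intervals[accession] = (start0 + 1, start0 + prd_len)
        proteome.add(
            ProteinRecord(
                accession=accession,
                sequence=seq,
                organism=params.organism,
                is_pathogen=params.is_pathogen,
            )
        )
        truth.accessions.append(accession)
    return proteome, truth


def _sample_architecture(
    rng: np.random.Generator,
    protein_length: int,
    catalog: list[str],
    arch_probs: np.ndarray,
) -> list[tuple[str, int, int]]:
    n_domains = int(rng.choice(len(arch_probs), p=arch_probs))
    if n_domains == 0:
        return []
    # lay domains in equal blocks so instances never overlap
    block = protein_length // n_domains
    domains: list[tuple[str, int, int]] = []
    for k in range(n_domains):
        pfam_id = catalog[int(rng.integers(0, len(catalog)))]
        lo = k * block + 1
        hi = (k + 1) * block
        span = max(10, min(hi - lo, int(rng.integers(30, 120))))
        start = lo + int(rng.integers(0, max(1, hi - lo - span + 1)))
        domains.append((pfam_id, start, min(start + span - 1, hi)))
    return domains


def generate_annotations(
    proteome: ProteomeSet,
    truth: SyntheticTruth,
    params: SyntheticAnnotationParams,
) -> tuple[AnnotationTable, SyntheticTruth]:
    """Generate a synthetic annotation table with planted enriched terms.

    Baseline terms are assigned independently per protein and term; planted
    terms get probability ``fold * baseline`` on annotated PrD-truth
    proteins.  Only a fraction of PrD-truth proteins (default 11%) receives
    GO annotation at all; non-PrD proteins are always annotation-eligible.
    Updates and returns the truth with the per-term true folds.
    """
    catalog = params.term_catalog
    planted = dict(params.planted_terms)
    for term, fold in planted.items():
        if fold * params.baseline > 1.0:
            logger.warning(
                "planted fold %g x baseline %g for %s exceeds 1; capped",
                fold, params.baseline, term,
            )
    base_p = np.full(len(catalog), params.baseline)
    planted_p = base_p.copy()
    for j, term in enumerate(catalog):
        if term in planted:
            planted_p[j] = min(1.0, planted[term] * params.baseline)

    arch_probs = np.asarray(params.architecture_dist, dtype=float)
    pfam_catalog = params.pfam_catalog

    table = AnnotationTable()
    for i, record in enumerate(proteome):
        rng = np.random.default_rng([params.seed, _STAGE_ANNOTATION, i])
        is_prd = record.accession in truth.prd_intervals
        go_eligible = (rng.random() < params.annotated_fraction) if is_prd else True
        p_vec = planted_p if is_prd else base_p
        if go_eligible:
            hits = rng.random(len(catalog)) < p_vec
            go_terms = {catalog[j] for j in np.nonzero(hits)[0]}
        else:
            rng.random(len(catalog))  # keep the stream aligned
            go_terms = set()
        pfam = _sample_architecture(rng, len(record), pfam_catalog, arch_probs)
        table.merge(
            ProteinAnnotation(
                accession=record.accession,
                go_terms=go_terms,
                pfam_domains=pfam,
                organism=record.organism,
                is_pathogen=record.is_pathogen,
            )
        )
    truth.term_folds = {t: planted.get(t, 1.0) for t in catalog}
    return table, truth


@dataclass
class RecoveryStats:
    """How well a call set recovers the planted truth."""

    n_truth: int
    n_calls: int
    tp: int
    fp: int
    fn: int
    sensitivity: float
    precision: float
    mean_overlap_fraction: float
    false_positive_rate_per_protein: float


def score_calls_against_truth(
    calls: PrDCallSet, truth: SyntheticTruth
) -> RecoveryStats:
    """Score calls against planted intervals.

    A call is a true positive when it overlaps its protein's planted
    interval by at least 50% of the planted length; calls on unplanted
    proteins (or with insufficient overlap) are false positives, and
    planted proteins without a qualifying call are false negatives.
    """
    known = set(truth.accessions)
    tp = fp = 0
    overlaps: list[float] = []
    recovered: set[str] = set()
    for call in calls:
        if call.accession not in known:
            raise ValueError(
                f"call accession {call.accession!r} not in the truth's proteome"
            )
        interval = truth.prd_intervals.get(call.accession)
        if interval is None:
            fp += 1
            continue
        t_start, t_end = interval
        t_len = t_end - t_start + 1
        overlap = max(0, min(call.end, t_end) - max(call.start, t_start) + 1)
        overlaps.append(overlap / t_len)
        if overlap >= 0.5 * t_len:
            tp += 1
            recovered.add(call.accession)
        else:
            fp += 1
    fn = truth.n_planted - len(recovered)
    n_calls = len(calls)
    if n_calls == 0:
        warnings.warn("no calls to score; precision reported as 0",
                      stacklevel=2)
        precision = 0.0
    else:
        precision = tp / n_calls
    sensitivity = tp / truth.n_planted if truth.n_planted else 0.0
    n_unplanted = len(known) - truth.n_planted
    fp_rate = fp / n_unplanted if n_unplanted else 0.0
    return RecoveryStats(
        n_truth=truth.n_planted,
        n_calls=n_calls,
        tp=tp,
        fp=fp,
        fn=fn,
        sensitivity=sensitivity,
        precision=precision,
        mean_overlap_fraction=(float(np.mean(overlaps)) if overlaps else 0.0),
        false_positive_rate_per_protein=fp_rate,
    )
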