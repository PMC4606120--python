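"""GO/Pfam annotation tables, the domain census, and functional clustering.

Annotations arrive as a TSV with one row per protein (header: ``accession``,
``go_terms``, ``pfam``, ``organism``, ``is_pathogen``); GO terms are
semicolon-separated IDs and Pfam domains semicolon-separated
``pfam_id:start-end`` triples with 1-based inclusive coordinates.  A protein
with no GO terms is "unannotated" for GO purposes but still participates in
the domain census.

The census applies a strictly-greater-than occurrence filter (a domain seen
exactly ``min_count`` times is dropped), and counts domain *instances*: a
domain appearing twice in one protein counts twice.  "Multi-domain"
likewise means at least two domain instances, not two distinct families.
"""

from __future__ import annotations

import csv
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .prd_scorer import PrDCallSet

logger = logging.getLogger(__name__)

UNCLUSTERED = "unclustered"

Domain = tuple[str, int, int]  # (pfam_id, start, end), 1-based inclusive


class AnnotationFormatError(ValueError):
    """Raised for malformed annotation input."""


@dataclass
class ProteinAnnotation:
    accession: str
    go_terms: set[str] = field(default_factory=set)
    pfam_domains: list[Domain] = field(default_factory=list)
    organism: str = ""
    is_pathogen: bool = False

    @property
    def is_go_annotated(self) -> bool:
        return bool(self.go_terms)


@dataclass
class DomainArchitecture:
    """Ordered Pfam domains of one protein, sorted by start coordinate."""

    accession: str
    domains: list[Domain]
    has_overlaps: bool = False

    def __post_init__(self) -> None:
        self.domains = sorted(self.domains, key=lambda d: (d[1], d[2]))
        self.has_overlaps = any(
            self.domains[i][2] >= self.domains[i + 1][1]
            for i in range(len(self.domains) - 1)
        )

    @property
    def domain_ids(self) -> tuple[str, ...]:
        return tuple(d[0] for d in self.domains)

    @property
    def n_domains(self) -> int:
        return len(self.domains)


class AnnotationTable:
    """Per-accession GO terms, Pfam domains and organism metadata."""

    def __init__(self, annotations: Iterable[ProteinAnnotation] = ()) -> None:
        self._by_accession: dict[str, ProteinAnnotation] = {}
        for ann in annotations:
            self.merge(ann)

    def merge(self, ann: ProteinAnnotation) -> None:
        """Add an annotation; duplicate accessions merge by union."""
        existing = self._by_accession.get(ann.accession)
        if existing is None:
            self._by_accession[ann.accession] = ann
            return
        existing.go_terms |= ann.go_terms
        for dom in ann.pfam_domains:
            if dom not in existing.pfam_domains:
                existing.pfam_domains.append(dom)
        existing.organism = existing.organism or ann.organism
        existing.is_pathogen = existing.is_pathogen or ann.is_pathogen

    def get(self, accession: str) -> ProteinAnnotation | None:
        return self._by_accession.get(accession)

    def architecture(self, accession: str) -> DomainArchitecture:
        ann = self._by_accession.get(accession)
        domains = list(ann.pfam_domains) if ann is not None else []
        return DomainArchitecture(accession=accession, domains=domains)

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    def __iter__(self):
        return iter(self._by_accession.values())

    def __len__(self) -> int:
        return len(self._by_accession)

    @property
    def accessions(self) -> set[str]:
        return set(self._by_accession)


def _parse_pfam_field(text: str, line_no: int) -> list[Domain]:
    domains: list[Domain] = []
    for token in filter(None, (t.strip() for t in text.split(";"))):
        try:
            pfam_id, coords = token.rsplit(":", 1)
            start_s, end_s = coords.split("-")
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise AnnotationFormatError(
                f"line {line_no}: malformed pfam token {token!r} "
                "(expected pfam_id:start-end)"
            ) from exc
        if start < 1 or end < start:
            raise AnnotationFormatError(
                f"line {line_no}: bad domain coordinates {token!r}"
            )
        domains.append((pfam_id, start, end))
    return domains


REQUIRED_COLUMNS = ("accession", "go_terms", "pfam", "organism", "is_pathogen")


def load_annotations(path: str | Path) -> AnnotationTable:
    """Load an annotation TSV; malformed rows are reported with line numbers."""
    path = Path(path)
    table = AnnotationTable()
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(REQUIRED_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise AnnotationFormatError(
                f"{path}: missing required columns {sorted(missing)}"
            )
        for line_no, row in enumerate(reader, start=2):
            accession = (row["accession"] or "").strip()
            if not accession:
                raise AnnotationFormatError(f"line {line_no}: empty accession")
            go_terms = {
                t.strip()
                for t in (row["go_terms"] or "").split(";")
                if t.strip()
            }
            pfam = _parse_pfam_field(row["pfam"] or "", line_no)
            is_pathogen = (row["is_pathogen"] or "").strip() in {"1", "true",
                                                                 "True", "yes"}
            table.merge(
                ProteinAnnotation(
                    accession=accession,
                    go_terms=go_terms,
                    pfam_domains=pfam,
                    organism=(row["organism"] or "").strip(),
                    is_pathogen=is_pathogen,
                )
            )
    return table


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(REQUIRED_COLUMNS)
        for ann in table:
            pfam = ";".join(f"{p}:{s}-{e}" for p, s, e in ann.pfam_domains)
            writer.writerow(
                [ann.accession, ";".join(sorted(ann.go_terms)), pfam,
                 ann.organism, int(ann.is_pathogen)]
            )


def pfam_census(
    calls: PrDCallSet,
    annotations: AnnotationTable,
    min_count: int = 5,
) -> pd.DataFrame:
    """Count Pfam domain instances across PrD-containing proteins.

    A domain occurring twice in one protein counts twice.  Only domains with
    count strictly greater than ``min_count`` are kept; rows are sorted by
    descending count, then by ID for determinism.
    """
    counter: Counter[str] = Counter()
    for call in calls:
        ann = annotations.get(call.accession)
        if ann is None:
            continue
        counter.update(d[0] for d in ann.pfam_domains)
    rows = [(pfam_id, n) for pfam_id, n in counter.items() if n > min_count]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["pfam_id", "count"])


@dataclass
class MultidomainSummary:
    n_prd: int
    n_with_domain: int
    pct_with_domain: float
    n_multidomain: int
    pct_multidomain_of_with_domain: float


def multidomain_stats(
    calls: PrDCallSet, annotations: AnnotationTable
) -> MultidomainSummary:
    """Count PrD proteins with >= 1 Pfam domain and with >= 2 domain instances.

    Percentages are plain ratios x 100 (report-level rounding is applied by
    the reporting layer, not here).
    """
    from .pipeline import report_fraction

    if len(calls) == 0:
        raise ValueError("empty call set")
    n_with = 0
    n_multi = 0
    for call in calls:
        ann = annotations.get(call.accession)
        n_dom = len(ann.pfam_domains) if ann is not None else 0
        if n_dom >= 1:
            n_with += 1
        if n_dom >= 2:
            n_multi += 1
    if n_with == 0:
        warnings.warn(
            "no PrD protein has any Pfam domain; multi-domain percentage "
            "reported as 0",
            stacklevel=2,
        )
        pct_multi = 0.0
    else:
        pct_multi = report_fraction(n_multi, n_with, 0)
    return MultidomainSummary(
        n_prd=len(calls),
        n_with_domain=n_with,
        pct_with_domain=report_fraction(n_with, len(calls), 0),
        n_multidomain=n_multi,
        pct_multidomain_of_with_domain=pct_multi,
    )


def domain_combinations(
    calls: PrDCallSet,
    annotations: AnnotationTable,
    min_count: int = 2,
) -> pd.DataFrame:
    """Count full ordered domain-ID architectures among PrD proteins.

    Each multi-domain protein contributes its complete ordered tuple of
    domain IDs; single-domain and domainless proteins contribute nothing.
    Combinations occurring at least ``min_count`` times are reported.
    """
    counter: Counter[tuple[str, ...]] = Counter()
    for call in calls:
        arch = annotations.architecture(call.accession)
        if arch.n_domains >= 2:
            counter[arch.domain_ids] += 1
    rows = [(combo, n) for combo, n in counter.items() if n >= min_count]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["combination", "count"])


class FunctionalClusterMap:
    """Mapping from GO/Pfam IDs to named functional cluster labels.

    The grouping of terms and domains into clusters (nucleotide binding,
    cell wall dynamics, invasion and virulence, ...) is curated data, not an
    algorithm; it is supplied as an editable YAML file of
    ``id: cluster label`` pairs.  IDs absent from the map fall into the
    ``unclustered`` bucket.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None) -> None:
        self.mapping: dict[str, str] = dict(mapping or {})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FunctionalClusterMap":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise AnnotationFormatError(
                f"{path}: cluster map must be a mapping of id -> cluster"
            )
        return cls({str(k): str(v) for k, v in data.items()})

    def cluster_of(self, term_id: str) -> str:
        return self.mapping.get(term_id, UNCLUSTERED)


def cluster_rollup(
    counts: Mapping[str, float] | pd.DataFrame,
    cluster_map: FunctionalClusterMap,
    id_column: str = "pfam_id",
    value_column: str = "count",
) -> pd.DataFrame:
    """Aggregate per-ID counts into per-cluster totals.

    Accepts either a mapping ``id -> count`` or a DataFrame with an ID column
    and a value column (census or enrichment output).  Cluster totals
    conserve the input total; unmapped IDs are summed under ``unclustered``.
    """
    if isinstance(counts, pd.DataFrame):
        items = zip(counts[id_column], counts[value_column])
    else:
        items = counts.items()
    totals: dict[str, float] = {}
    for term_id, value in items:
        label = cluster_map.cluster_of(str(term_id))
        totals[label] = totals.get(label, 0) + value
    rows = sorted(totals.items(), key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["cluster", value_column])
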