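"""Sliding-window compositional scoring of prion-like domains (PrDs).

The scorer is a position-independent log-likelihood-ratio model: each
residue ``a`` in a window contributes ``log2(P_prion(a) / P_background(a))``
bits, and the window score is the sum of the contributions.  Windows of a
fixed length (default 60 residues) slide along the protein; a protein is
called PrD-positive when its best window reaches the call threshold
(default 50 bits).  Q/N/S/G-rich low-complexity stretches are the regions
this model is built to detect: the default prion composition puts 73% of
its mass on N, Q, S and G, so only strongly biased windows can accumulate
50 bits over 60 residues.

Ambiguity codes (B, Z, X, U, O) contribute 0 bits and are excluded from
composition summaries: they carry no information, so they incur no penalty.

Coordinates are 1-based inclusive throughout, the protein-annotation
convention.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .sequence_io import (
    AMBIGUITY_CODES,
    STANDARD_AMINO_ACIDS,
    ProteinRecord,
    ProteomeSet,
)

DEFAULT_PSEUDOCOUNT = 1e-4

#: scores are rounded to this many decimals before cutoff comparison, so the
#: ">= cutoff" rule is well defined against float noise
SCORE_DECIMALS = 6


class CompositionModel:
    """A per-residue probability model over the 20 standard amino acids.

    A pseudocount is added to every residue weight before normalisation, so
    all probabilities are strictly positive and log-ratios stay finite even
    for residues absent from the input weights.
    """

    def __init__(
        self,
        weights: Mapping[str, float],
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> None:
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        unknown = set(weights) - set(STANDARD_AMINO_ACIDS)
        if unknown:
            raise ValueError(f"non-standard residues in model: {sorted(unknown)}")
        if any(w < 0 for w in weights.values()):
            raise ValueError("negative residue weight")
        raw = {a: float(weights.get(a, 0.0)) + pseudocount
               for a in STANDARD_AMINO_ACIDS}
        total = sum(raw.values())
        self.probs: dict[str, float] = {a: w / total for a, w in raw.items()}
        self.pseudocount = pseudocount

    def __getitem__(self, residue: str) -> float:
        return self.probs[residue]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompositionModel):
            return NotImplemented
        return self.probs == other.probs

    def as_series(self) -> pd.Series:
        return pd.Series(self.probs, name="probability")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT) -> "CompositionModel":
        """Load a model from a TSV with columns ``residue``, ``probability``."""
        df = pd.read_csv(path, sep="\t")
        if not {"residue", "probability"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns residue, probability")
        return cls(dict(zip(df["residue"], df["probability"])), pseudocount)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["residue", "probability"])
            for a in STANDARD_AMINO_ACIDS:
                writer.writerow([a, f"{self.probs[a]:.10g}"])


def _load_packaged_model(name: str) -> CompositionModel:
    ref = resources.files("prdkit").joinpath("data", name)
    with resources.as_file(ref) as path:
        return CompositionModel.from_tsv(path)


def default_prion_model() -> CompositionModel:
    """The default PrD composition: N 30%, Q 21%, S 11%, G 11%, the
    remaining 27% spread uniformly over the other 16 residues."""
    return _load_packaged_model("prion_composition.tsv")


def default_background_model() -> CompositionModel:
    """Average bacterial residue composition (editable packaged fixture)."""
    return _load_packaged_model("background_bacterial.tsv")


@dataclass
class ScoringParams:
    """Window-scan parameters.

    window_length : residues per scored window (default 60)
    step : offset between consecutive windows (default 1)
    cutoff_bits : call threshold on the best-window score (default 50)
    merge_gap : maximum gap, in residues, across which qualifying windows
        are merged into one called region (default 0: only overlapping or
        adjacent windows merge)
    strict_greater : require score > cutoff instead of >= (default False;
        comparison happens after rounding to 6 decimals)
    """

    window_length: int = 60
    step: int = 1
    cutoff_bits: float = 50.0
    merge_gap: int = 0
    strict_greater: bool = False

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if not math.isfinite(self.cutoff_bits):
            raise ValueError("cutoff_bits must be finite")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


@dataclass
class PrDCall:
    """A called prion-like region (1-based inclusive coordinates)."""

    accession: str
    start: int
    end: int
    score_bits: float
    region_sequence: str
    organism: str = ""
    is_pathogen: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PrDCallSet:
    """All calls from one proteome scan (at most one call per protein)."""

    calls: list[PrDCall]
    n_scanned: int
    #: secondary qualifying regions per accession, (start, end, score_bits);
    #: diagnostics only, never counted
    secondary_regions: dict[str, list[tuple[int, int, float]]] = field(
        default_factory=dict
    )

    @property
    def n_calls(self) -> int:
        return len(self.calls)

    @property
    def fraction_positive(self) -> float:
        return len(self.calls) / self.n_scanned if self.n_scanned else 0.0

    @property
    def accessions(self) -> set[str]:
        return {c.accession for c in self.calls}

    def per_organism_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for call in self.calls:
            counts[call.organism] = counts.get(call.organism, 0) + 1
        return counts

    def __iter__(self):
        return iter(self.calls)

    def __len__(self) -> int:
        return len(self.calls)


def _log_ratio_table(
    prion: CompositionModel, background: CompositionModel
) -> dict[str, float]:
    table = {
        a: math.log2(prion.probs[a] / background.probs[a])
        for a in STANDARD_AMINO_ACIDS
    }
    for a in AMBIGUITY_CODES:
        table[a] = 0.0
    return table


def window_score(
    window: str, prion: CompositionModel, background: CompositionModel
) -> float:
    """Score one window in bits: sum of per-residue log2 likelihood ratios.

    Ambiguity codes contribute 0 bits.  Raises ValueError on an empty window.
    """
    if not window:
        raise ValueError("empty window")
    table = _log_ratio_table(prion, background)
    try:
        return sum(table[a] for a in window.upper())
    except KeyError as exc:
        raise ValueError(f"illegal residue {exc.args[0]!r} in window") from exc


def _residue_scores(
    sequence: str, table: dict[str, float]
) -> np.ndarray:
    return np.fromiter((table[a] for a in sequence), dtype=float,
                       count=len(sequence))


def _merge_runs(
    starts: np.ndarray, window: int, merge_gap: int
) -> list[tuple[int, int]]:
    """Merge qualifying window start offsets (0-based) into region spans.

    Two windows merge when their spans overlap, touch, or are separated by
    at most ``merge_gap`` residues.
    """
    regions: list[tuple[int, int]] = []
    cur_start = int(starts[0])
    cur_end = cur_start + window - 1
    for s in starts[1:]:
        s = int(s)
        if s <= cur_end + 1 + merge_gap:
            cur_end = s + window - 1
        else:
            regions.append((cur_start, cur_end))
            cur_start, cur_end = s, s + window - 1
    regions.append((cur_start, cur_end))
    return regions


def scan_protein(
    protein: ProteinRecord,
    prion: CompositionModel,
    background: CompositionModel,
    params: ScoringParams | None = None,
    _table: dict[str, float] | None = None,
) -> tuple[Optional[PrDCall], list[tuple[int, int, float]]]:
    """Scan one protein; return (call or None, secondary qualifying regions).

    All windows of ``params.window_length`` at offsets of ``params.step``
    are scored.  A protein shorter than the window is scanned as a single
    window of its own length.  If the best window reaches the cutoff, the
    call spans the merged run of qualifying windows that contains the best
    one; its score is the best-window score.  Other qualifying runs are
    returned as secondary regions (diagnostics).
    """
    if params is None:
        params = ScoringParams()
    table = _table if _table is not None else _log_ratio_table(prion, background)
    seq = protein.sequence
    n = len(seq)
    w = min(params.window_length, n)

    scores = _residue_scores(seq, table)
    csum = np.concatenate(([0.0], np.cumsum(scores)))
    starts = np.arange(0, n - w + 1, params.step)
    window_sums = np.round(csum[starts + w] - csum[starts], SCORE_DECIMALS)

    if params.strict_greater:
        qualifying = window_sums > params.cutoff_bits
    else:
        qualifying = window_sums >= params.cutoff_bits
    if not qualifying.any():
        return None, []

    best_idx = int(np.argmax(window_sums))
    best_score = float(window_sums[best_idx])
    q_starts = starts[qualifying]
    regions = _merge_runs(q_starts, w, params.merge_gap)

    best_start = int(starts[best_idx])
    primary = None
    secondary: list[tuple[int, int, float]] = []
    for r0, r1 in regions:
        r1 = min(r1, n - 1)
        in_region = (q_starts >= r0) & (q_starts + w - 1 <= r1 + params.merge_gap)
        region_best = float(
            np.max(window_sums[qualifying][in_region])
        ) if in_region.any() else best_score
        if r0 <= best_start <= r1:
            primary = PrDCall(
                accession=protein.accession,
                start=r0 + 1,
                end=r1 + 1,
                score_bits=best_score,
                region_sequence=seq[r0 : r1 + 1],
                organism=protein.organism,
                is_pathogen=protein.is_pathogen,
            )
        else:
            secondary.append((r0 + 1, r1 + 1, region_best))
    assert primary is not None
    return primary, secondary


def scan_proteome(
    proteome: ProteomeSet,
    prion: CompositionModel | None = None,
    background: CompositionModel | None = None,
    params: ScoringParams | None = None,
) -> PrDCallSet:
    """Scan every protein in a proteome; deterministic for fixed inputs."""
    if len(proteome) == 0:
        raise ValueError("empty proteome")
    prion = prion if prion is not None else default_prion_model()
    background = background if background is not None else default_background_model()
    params = params if params is not None else ScoringParams()
    table = _log_ratio_table(prion, background)

    calls: list[PrDCall] = []
    secondary: dict[str, list[tuple[int, int, float]]] = {}
    for record in proteome:
        call, extra = scan_protein(record, prion, background, params,
                                   _table=table)
        if call is not None:
            calls.append(call)
        if extra:
            secondary[record.accession] = extra
    return PrDCallSet(calls=calls, n_scanned=len(proteome),
                      secondary_regions=secondary)


def composition_summary(calls: PrDCallSet | Iterable[PrDCall]) -> pd.Series:
    """Pooled residue frequencies over all called region sequences.

    Returns a Series indexed by the 20 standard amino acids, summing to 1.
    Ambiguity codes are excluded from both numerator and denominator.
    """
    call_list = list(calls)
    if not call_list:
        raise ValueError("empty call set")
    counts = dict.fromkeys(STANDARD_AMINO_ACIDS, 0)
    for call in call_list:
        for a in call.region_sequence:
            if a in counts:
                counts[a] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("regions contain no standard residues")
    return pd.Series({a: counts[a] / total for a in STANDARD_AMINO_ACIDS},
                     name="frequency")


def prd_localization(call: PrDCall, architecture) -> str:
    """Position of a called region relative to a protein's Pfam domains.

    Returns one of ``undomained``, ``overlapping``, ``N-terminal``,
    ``C-terminal``, ``inter-domain``.  A call overlapping any domain by
    more than 10% of the call length is ``overlapping``.
    """
    if architecture.accession != call.accession:
        raise ValueError(
            f"architecture is for {architecture.accession!r}, "
            f"call is for {call.accession!r}"
        )
    domains = architecture.domains
    if not domains:
        return "undomained"
    call_len = call.length
    for _, d_start, d_end in domains:
        overlap = min(call.end, d_end) - max(call.start, d_start) + 1
        if overlap > 0.10 * call_len:
            return "overlapping"
    first_start = min(d[1] for d in domains)
    last_end = max(d[2] for d in domains)
    # incursions within the tolerated 10% do not change the positional class
    tol = 0.10 * call_len
    if call.end < first_start + tol:
        return "N-terminal"
    if call.start > last_end - tol:
        return "C-terminal"
    return "inter-domain"


def write_calls(calls: PrDCallSet, path: str | Path) -> None:
    """Write calls as TSV: accession, organism, start, end, score_bits,
    region_sequence."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["accession", "organism", "start", "end", "score_bits",
             "region_sequence"]
        )
        for c in calls:
            writer.writerow(
                [c.accession, c.organism, c.start, c.end,
                 f"{c.score_bits:.6f}", c.region_sequence]
            )


def read_calls(path: str | Path, n_scanned: int | None = None) -> PrDCallSet:
    """Read a calls TSV written by :func:`write_calls`."""
    df = pd.read_csv(path, sep="\t", dtype={"organism": str},
                     keep_default_na=False)
    calls = [
        PrDCall(
            accession=str(row.accession),
            organism=str(row.organism),
            start=int(row.start),
            end=int(row.end),
            score_bits=float(row.score_bits),
            region_sequence=str(row.region_sequence),
        )
        for row in df.itertuples()
    ]
    return PrDCallSet(calls=calls,
                      n_scanned=n_scanned if n_scanned is not None else len(calls))
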