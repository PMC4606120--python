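"""Term enrichment among PrD-containing proteins.

For every annotation term (GO ID or Pfam ID) a 2x2-style contingency is
assembled:

* ``n_l`` — proteins carrying the term among the annotated PrD proteins,
* ``p_l`` — annotated proteins in the PrD list,
* ``n_b`` — proteins carrying the term in the background,
* ``p_b`` — proteins in the background.

The enrichment factor is the ratio of proportions

    EF = (n_l / p_l) / (n_b / p_b) = (n_l * p_b) / (n_b * p_l)

i.e. how much more frequent the term is in the PrD list than in the
background.  Significance is a one-sided hypergeometric
(over-representation) test with Benjamini-Hochberg FDR adjustment; a term
is flagged significant when log2(EF) > 0.5 and q < 0.1 (both strict).

Universe conventions: ``p_l`` counts only annotated PrD proteins (a PrD
protein with no terms in the namespace is outside the list universe); the
background defaults to every protein in the annotation table, with an
``annotated-only`` switch that restricts it to proteins annotated in the
namespace.  Terms never seen in the background (``n_b = 0``) are skipped
with a warning rather than aborting the run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotation import AnnotationTable
from .prd_scorer import PrDCallSet

logger = logging.getLogger(__name__)

DEFAULT_LOG2_MIN = 0.5
DEFAULT_FDR = 0.1

Namespace = Literal["GO", "Pfam"]
Background = Literal["all", "annotated"]

RESULT_COLUMNS = [
    "term_id", "n_l", "p_l", "n_b", "p_b",
    "EF", "log2_EF", "p_value", "q_value", "significant",
]


class UndefinedEnrichmentError(ValueError):
    """EF is undefined: the term does not occur in the background."""


class EmptyUniverseError(ValueError):
    """No annotated PrD protein: the list universe is empty."""


@dataclass(frozen=True)
class TermContingency:
    """The four counts behind one term's enrichment factor."""

    term_id: str
    n_l: int
    p_l: int
    n_b: int
    p_b: int

    def __post_init__(self) -> None:
        if self.p_l <= 0:
            raise ValueError("p_l must be positive")
        if self.p_l > self.p_b:
            raise ValueError("p_l cannot exceed p_b")
        if not (0 <= self.n_b <= self.p_b):
            raise ValueError("n_b must lie in [0, p_b]")
        if not (0 <= self.n_l <= min(self.p_l, self.n_b) or self.n_b == 0
                and self.n_l == 0):
            raise ValueError("n_l must lie in [0, min(p_l, n_b)]")


def enrichment_factor(c: TermContingency) -> float:
    """EF = (n_l * p_b) / (n_b * p_l), exactly.

    Raises :class:`UndefinedEnrichmentError` when ``n_b == 0``.
    """
    if c.n_b == 0:
        raise UndefinedEnrichmentError(
            f"term {c.term_id!r} absent from the background (n_b = 0)"
        )
    return (c.n_l * c.p_b) / (c.n_b * c.p_l)


def term_pvalue(c: TermContingency) -> float:
    """One-sided over-representation probability P[X >= n_l].

    X ~ Hypergeometric(population p_b, successes n_b, draws p_l): the
    chance of seeing at least ``n_l`` term-carrying proteins in a random
    list of ``p_l`` proteins.
    """
    return float(hypergeom.sf(c.n_l - 1, c.p_b, c.n_b, c.p_l))


def benjamini_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _namespace_terms(ann, namespace: Namespace) -> set[str]:
    if namespace == "GO":
        return set(ann.go_terms)
    return {d[0] for d in ann.pfam_domains}


def build_contingencies(
    calls: PrDCallSet,
    annotations: AnnotationTable,
    namespace: Namespace = "GO",
    background: Background = "all",
) -> tuple[list[TermContingency], dict[str, int]]:
    """Assemble one contingency per term seen in the annotated PrD list.

    Returns the contingencies plus the universe sizes actually used
    (``{"p_l": ..., "p_b": ...}``).  Terms with ``n_b = 0`` cannot occur
    here by construction (every list protein is also a background protein).
    """
    if namespace not in ("GO", "Pfam"):
        raise ValueError(f"unknown namespace {namespace!r}")

    call_accessions = calls.accessions
    list_term_sets: dict[str, set[str]] = {}
    for acc in call_accessions:
        ann = annotations.get(acc)
        if ann is None:
            continue
        terms = _namespace_terms(ann, namespace)
        if terms:
            list_term_sets[acc] = terms
    p_l = len(list_term_sets)
    if p_l == 0:
        raise EmptyUniverseError(
            f"no PrD protein carries any {namespace} annotation"
        )

    if background == "all":
        bg_anns = list(annotations)
    elif background == "annotated":
        bg_anns = [a for a in annotations if _namespace_terms(a, namespace)]
    else:
        raise ValueError(f"unknown background mode {background!r}")
    p_b = len(bg_anns)

    n_b: dict[str, int] = {}
    for ann in bg_anns:
        for term in _namespace_terms(ann, namespace):
            n_b[term] = n_b.get(term, 0) + 1

    n_l: dict[str, int] = {}
    for terms in list_term_sets.values():
        for term in terms:
            n_l[term] = n_l.get(term, 0) + 1

    contingencies = []
    for term in sorted(n_l):
        if n_b.get(term, 0) == 0:
            logger.warning(
                "term %s absent from background; skipped (n_b = 0)", term
            )
            continue
        contingencies.append(
            TermContingency(term_id=term, n_l=n_l[term], p_l=p_l,
                            n_b=n_b[term], p_b=p_b)
        )
    return contingencies, {"p_l": p_l, "p_b": p_b}


def results_table(
    contingencies: Iterable[TermContingency],
    log2_min: float = DEFAULT_LOG2_MIN,
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """EF, p, BH q and significance flags for a set of contingencies.

    ``significant`` is True iff log2(EF) > ``log2_min`` and q < ``fdr``
    (both strict).
    """
    rows = []
    for c in contingencies:
        ef = enrichment_factor(c)
        rows.append(
            {
                "term_id": c.term_id,
                "n_l": c.n_l, "p_l": c.p_l, "n_b": c.n_b, "p_b": c.p_b,
                "EF": ef,
                "log2_EF": math.log2(ef) if ef > 0 else -math.inf,
                "p_value": term_pvalue(c),
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-2])
    if df.empty:
        df["q_value"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    df["q_value"] = benjamini_adjust(df["p_value"].to_numpy())
    df["significant"] = (df["log2_EF"] > log2_min) & (df["q_value"] < fdr)
    return df


def run_enrichment(
    calls: PrDCallSet,
    annotations: AnnotationTable,
    namespace: Namespace = "GO",
    background: Background = "all",
    log2_min: float = DEFAULT_LOG2_MIN,
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Full enrichment run: contingencies, EF, p, q, significance flags.

    Deterministic; rows are sorted by term_id.  Raises
    :class:`EmptyUniverseError` when no PrD protein is annotated in the
    namespace.
    """
    contingencies, _ = build_contingencies(calls, annotations, namespace,
                                           background)
    return results_table(contingencies, log2_min=log2_min, fdr=fdr)


def compare_subsets(
    results_subset: pd.DataFrame, results_full: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pair a subset's enrichment results with the full set's.

    Returns (joined, subset_only, full_only): the join carries EF in both
    runs and the log2 ratio of the subset EF over the full EF.  Both runs
    must share the same background size ``p_b``.
    """
    for df in (results_subset, results_full):
        missing = set(RESULT_COLUMNS[:-2]) - set(df.columns)
        if missing:
            raise ValueError(f"results missing columns {sorted(missing)}")
    if (not results_subset.empty and not results_full.empty
            and results_subset["p_b"].iat[0] != results_full["p_b"].iat[0]):
        raise ValueError(
            "subset and full results were computed over different backgrounds"
        )
    joined = results_subset.merge(
        results_full[["term_id", "EF"]],
        on="term_id",
        suffixes=("_subset", ""),
    ).rename(columns={"EF": "EF_full", "EF_subset": "EF_subset"})
    joined = joined[["term_id", "EF_subset", "EF_full"]].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        joined["log2_ratio"] = np.log2(
            joined["EF_subset"].to_numpy() / joined["EF_full"].to_numpy()
        )
    shared = set(joined["term_id"])
    subset_only = results_subset[~results_subset["term_id"].isin(shared)]
    full_only = results_full[~results_full["term_id"].isin(shared)]
    return joined, subset_only.reset_index(drop=True), full_only.reset_index(drop=True)
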