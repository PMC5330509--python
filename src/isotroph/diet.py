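"""Prey trophic coding, weighted trophic rank, and diet-space distances.

A species' trophic position is summarized from stomach contents as a
weighted trophic rank (WTR): the sum over prey categories of the proportion
of the category in the diet times the category's trophic rank,

    WTR = sum_i p_i * T_i,

with ranks on a 1..5 scale (1 producer, 2 primary grazer, 3 omnivorous
consumer, 4 predator of omnivores, 5 predator of vertebrates; higher taxa
spanning two adjacent ranks take the midpoint).  Diet-space distances are
Euclidean distances between species' proportion vectors, optionally
restricted to a category subset (e.g. termites only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import DietTable, DistanceMatrix, TrophicCoding, canonical_name
from .errors import AnalysisError, CodingError

__all__ = [
    "assign_trophic_rank",
    "WeightedTrophicRank",
    "weighted_trophic_rank",
    "wtr_table",
    "diet_distance",
    "ConcordanceResult",
    "rank_concordance",
]


def assign_trophic_rank(category: str, coding: TrophicCoding) -> float:
    """Rank of one prey category under the coding; unknown categories raise."""
    rank = coding.rank_of(category)
    if rank is None:
        raise CodingError(f"prey category {category!r} has no trophic rank in the coding")
    return rank


@dataclass(frozen=True)
class WeightedTrophicRank:
    species: str
    wtr: float
    n_prey_types: int
    normalized: bool


def weighted_trophic_rank(
    proportions: dict[str, float] | "np.ndarray",
    coding: TrophicCoding,
    *,
    categories: list[str] | None = None,
    normalize: bool = True,
    species: str = "",
) -> WeightedTrophicRank:
    """Sum of proportion x rank over the prey categories a species eats.

    ``proportions`` is either a category->proportion mapping or a vector
    paired with ``categories``.  With ``normalize`` set (the default),
    proportions are rescaled to sum to one first — published percent-volume
    rows rarely sum exactly to 1 — and the flag records which convention
    produced the value.  Categories with zero proportion do not need a rank.
    """
    if isinstance(proportions, dict):
        cats = list(proportions)
        p = np.array([proportions[c] for c in cats], dtype=float)
    else:
        if categories is None:
            raise CodingError("categories required when proportions is a vector")
        cats = list(categories)
        p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise AnalysisError("proportions must be non-negative")
    total = p.sum()
    if total <= 0:
        raise AnalysisError(f"empty stomach: all proportions zero for {species or 'species'}")
    eaten = p > 0
    ranks = np.array([assign_trophic_rank(c, coding) for c, e in zip(cats, eaten) if e])
    weights = p[eaten] / total if normalize else p[eaten]
    return WeightedTrophicRank(
        species=species,
        wtr=float(weights @ ranks),
        n_prey_types=int(eaten.sum()),
        normalized=bool(normalize),
    )


def wtr_table(
    table: DietTable, coding: TrophicCoding, *, normalize: bool = True, min_n: int = 1
) -> list[WeightedTrophicRank]:
    """WTR for every species in a diet table meeting the sample-size floor."""
    out = []
    for i, sp in enumerate(table.species):
        if table.n_individuals[i] < min_n:
            continue
        out.append(
            weighted_trophic_rank(
                table.proportions[i],
                coding,
                categories=list(table.categories),
                normalize=normalize,
                species=sp,
            )
        )
    return out


def diet_distance(
    table: DietTable,
    categories: list[str] | None = None,
    *,
    min_n: int = 1,
) -> DistanceMatrix:
    """Euclidean distance between species' diet-proportion vectors.

    ``categories`` restricts the diet space to a subset (the termite-only
    analysis passes ``["Isoptera"]``).  Species with fewer than ``min_n``
    sampled stomachs are excluded.
    """
    keep = np.flatnonzero(table.n_individuals >= min_n)
    if len(keep) < 2:
        raise AnalysisError("need at least two species above the sample-size floor")
    if categories is not None:
        canon = {canonical_name(c): j for j, c in enumerate(table.categories)}
        cols = [canon[canonical_name(c)] for c in categories if canonical_name(c) in canon]
        if not cols:
            raise AnalysisError("category subset shares nothing with the diet table")
    else:
        cols = list(range(len(table.categories)))
    pts = table.proportions[np.ix_(keep, cols)]
    return DistanceMatrix.from_points([table.species[i] for i in keep], pts)


@dataclass(frozen=True)
class ConcordanceResult:
    r: float
    p: float
    n: int
    method: str


def rank_concordance(
    mean_d15N: "np.ndarray",
    wtr: "np.ndarray",
    method: str = "pearson",
) -> ConcordanceResult:
    """Concordance of the d15N ordering with the stomach-content trophic rank.

    Product-moment correlation with a two-sided t-based p by default;
    ``method="spearman"`` gives the rank-based alternative.  Inputs must be
    aligned per-species vectors.
    """
    x = np.asarray(mean_d15N, dtype=float)
    y = np.asarray(wtr, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AnalysisError("aligned 1-d vectors required")
    if len(x) < 3:
        raise AnalysisError("need at least 3 species")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("correlation undefined: zero variance in an input vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise AnalysisError(f"unknown method {method!r}")
    return ConcordanceResult(r=float(r), p=float(p), n=len(x), method=method)
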