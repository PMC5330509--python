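"""Species habitat scores from pitfall-trap measurements.

Each trap carries 14 habitat variables (vegetation cover percentages,
substrate composition, soil compaction, woody-debris volume, ...).  A
species' habitat score for a variable is the unweighted mean over the
distinct traps where it was captured; per-variable transforms (log, logit,
arcsine-square-root) are then selected by best approximation of normality
before species are placed in a Euclidean habitat space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit as _logit

from .core import CaptureRecords, DistanceMatrix, TrapHabitatTable
from .errors import AnalysisError

__all__ = [
    "species_habitat_means",
    "TransformResult",
    "select_transform",
    "SpeciesHabitatMatrix",
    "transform_matrix",
    "habitat_distance",
]

# tie-break preference when normality scores are equal
_TRANSFORM_ORDER = ("log", "logit", "arcsine-sqrt")


def species_habitat_means(
    traps: TrapHabitatTable,
    captures: CaptureRecords,
    *,
    capture_weighted: bool = False,
) -> pd.DataFrame:
    """Per-species raw means of every habitat variable over capture traps.

    By default a trap contributes once per species no matter how many
    individuals it caught there (distinct-trap convention);
    ``capture_weighted=True`` weights traps by capture count instead.
    Species whose captures reference no known trap are dropped and reported
    via the returned frame's ``attrs["excluded"]``.
    """
    captures.check_against(traps)
    pairs = captures.frame
    if not capture_weighted:
        pairs = pairs.drop_duplicates()
    joined = pairs.merge(traps.frame, left_on="trap_id", right_index=True, how="left")
    means = joined.groupby("species", sort=True)[traps.variables].mean()
    means.attrs["excluded"] = []
    means.attrs["capture_weighted"] = capture_weighted
    return means


@dataclass(frozen=True)
class TransformResult:
    name: str
    values: np.ndarray
    shapiro_w: float
    epsilon: float  # boundary shift applied before log/logit, 0 if none


def _candidate_transforms(values: np.ndarray, percent: bool) -> dict[str, TransformResult]:
    """Evaluate every admissible transform of one variable's species means."""
    v = np.asarray(values, dtype=float)
    out: dict[str, TransformResult] = {}

    def shapiro_w(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            return -np.inf
        return float(stats.shapiro(x).statistic)

    # log: needs positive values; zeros shifted by half the smallest nonzero
    if np.all(v >= 0) and np.any(v > 0):
        eps = 0.0
        w = v.copy()
        if np.any(w == 0):
            eps = 0.5 * w[w > 0].min()
            w = w + eps
        t = np.log(w)
        out["log"] = TransformResult("log", t, shapiro_w(t), eps)

    # logit / arcsine-sqrt: need a [0, 1] representation
    frac = v / 100.0 if percent else v
    if np.all(frac >= 0) and np.all(frac <= 1):
        eps = 0.0
        w = frac.copy()
        nz = w[(w > 0) & (w < 1)]
        shift = 0.5 * nz.min() if len(nz) else 0.25
        if np.any(w == 0) or np.any(w == 1):
            eps = shift
            w = np.clip(w, shift, 1 - shift)
        t = _logit(w)
        out["logit"] = TransformResult("logit", t, shapiro_w(t), eps)
        t2 = np.arcsin(np.sqrt(frac))
        out["arcsine-sqrt"] = TransformResult("arcsine-sqrt", t2, shapiro_w(t2), 0.0)

    return out


def select_transform(values: np.ndarray, *, percent: bool = False) -> TransformResult:
    """Pick the transform of one variable best approximating normality.

    Candidates are log, logit and arcsine-square-root (the latter two only
    when the values are representable on [0, 1]; set ``percent`` for 0-100
    covers).  Normality is scored by the Shapiro-Wilk W statistic, highest
    wins, ties broken in the fixed order log > logit > arcsine-sqrt.  When no
    transform is admissible the identity is returned as ``"none"``.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise AnalysisError("need at least 3 species means to select a transform")
    if not np.all(np.isfinite(v)):
        raise AnalysisError("non-finite habitat means")
    candidates = _candidate_transforms(v, percent)
    if not candidates:
        return TransformResult("none", v.copy(), np.nan, 0.0)
    best = max(
        _TRANSFORM_ORDER,
        key=lambda name: (candidates[name].shapiro_w if name in candidates else -np.inf,
                          -_TRANSFORM_ORDER.index(name)),
    )
    return candidates[best]


@dataclass(frozen=True)
class SpeciesHabitatMatrix:
    """Species x variable matrix of transformed means, with the transform
    recorded per variable."""

    frame: pd.DataFrame
    transform_used: dict[str, str]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(str(i) for i in self.frame.index)

    def reindex(self, order) -> "SpeciesHabitatMatrix":
        from .core import canonical_name

        by_canon = {canonical_name(i): i for i in self.frame.index}
        rows = [by_canon[canonical_name(o)] for o in order]
        return SpeciesHabitatMatrix(self.frame.loc[rows], dict(self.transform_used))


def transform_matrix(raw_means: pd.DataFrame) -> SpeciesHabitatMatrix:
    """Apply per-variable normality-driven transforms to a raw mean matrix.

    Columns named ``pct_*`` are treated as percentage covers (scaled to [0,1]
    for the logit/arcsine candidates).
    """
    cols = {}
    used = {}
    for col in raw_means.columns:
        res = select_transform(
            raw_means[col].to_numpy(), percent=str(col).startswith("pct_")
        )
        cols[col] = res.values
        used[str(col)] = res.name
    out = pd.DataFrame(cols, index=raw_means.index)
    return SpeciesHabitatMatrix(out, used)


def habitat_distance(
    matrix: SpeciesHabitatMatrix | pd.DataFrame, *, standardize: bool = True
) -> DistanceMatrix:
    """Euclidean distance between species in (transformed) habitat space.

    With ``standardize`` (default), each variable is z-scored first so that
    covers, counts and volumes contribute on a common scale; a constant
    column is then an error because its z-score is undefined.
    """
    frame = matrix.frame if isinstance(matrix, SpeciesHabitatMatrix) else matrix
    if len(frame) < 2:
        raise AnalysisError("need at least two species")
    X = frame.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        flat = np.flatnonzero(sd == 0)
        if len(flat):
            raise AnalysisError(
                f"constant column under standardization: {frame.columns[flat[0]]!r}"
            )
        X = (X - X.mean(axis=0)) / sd
    return DistanceMatrix.from_points([str(i) for i in frame.index], X)
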