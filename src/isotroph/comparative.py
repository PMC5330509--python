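"""Distance-matrix association tests and phylogenetic signal.

Implemented from first principles:

* Mantel test — product-moment correlation between the strictly-lower
  triangles of two species distance matrices, with a permutation null built
  by jointly permuting rows and columns of the second matrix.  The reported
  p includes the identity permutation, so p >= 1/(n_perm + 1).
* Partial / phylogenetically permuted Mantel — the partial correlation
  r_12.3 controlling a third matrix, with an optional phylogenetically
  restricted permutation null in which swapping two species becomes less
  likely the further apart they sit on the tree.
* Pagel's lambda — maximum-likelihood multiplier on the off-diagonal of the
  Brownian-motion covariance C; mean and rate are profiled out by
  generalized least squares and lambda is optimized on [0, 1] by a dense
  grid followed by bounded local refinement, with a likelihood-ratio test
  against lambda = 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core import DistanceMatrix, Phylogeny, canonical_name
from .errors import AlignmentError, AnalysisError, ValidationError

__all__ = [
    "PhyloCovariance",
    "phylo_covariance",
    "lambda_transform",
    "LambdaResult",
    "pagel_lambda",
    "MantelResult",
    "mantel",
    "mantel_exact",
    "phylo_mantel",
    "restricted_permutation",
]

LAMBDA_EFFECTIVELY_ZERO = 1e-3


# ---------------------------------------------------------------------------
# phylogenetic covariance


@dataclass(frozen=True)
class PhyloCovariance:
    """Species-ordered matrix of shared branch lengths under Brownian motion.

    ``matrix[i, j]`` is the path length from the root to the most recent
    common ancestor of tips i and j; the diagonal holds tip depths.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if np.any(np.abs(m - m.T) > 1e-10):
            raise ValidationError("phylogenetic covariance must be symmetric")


def phylo_covariance(tree: Phylogeny, order=None) -> PhyloCovariance:
    labels, C = tree.covariance_matrix(order)
    return PhyloCovariance(tuple(labels), C)


def lambda_transform(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Multiply off-diagonal covariances by lambda, keeping tip variances."""
    if not (0.0 <= lam <= 1.0):
        raise AnalysisError(f"lambda must be in [0, 1], got {lam}")
    M = C.matrix * lam
    np.fill_diagonal(M, np.diag(C.matrix))
    return PhyloCovariance(C.labels, M)


# ---------------------------------------------------------------------------
# Pagel's lambda


@dataclass(frozen=True)
class LambdaResult:
    lambda_hat: float
    sigma2_hat: float
    root_state: float
    logL_hat: float
    logL_lambda0: float
    lrt_p: float
    n: int
    effectively_zero: bool

    @property
    def lrt_statistic(self) -> float:
        return 2.0 * (self.logL_hat - self.logL_lambda0)


def _gls_profile_loglik(y: np.ndarray, V: np.ndarray):
    """ML log-likelihood of y ~ N(mu 1, sigma2 V) with mu, sigma2 profiled."""
    n = len(y)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as e:
        cond = np.linalg.cond(V)
        raise AnalysisError(f"singular lambda-transformed covariance (cond={cond:.3g})") from e
    one = np.ones(n)
    Li_y = np.linalg.solve(L, y)
    Li_1 = np.linalg.solve(L, one)
    mu = (Li_1 @ Li_y) / (Li_1 @ Li_1)
    resid = Li_y - mu * Li_1
    sigma2 = (resid @ resid) / n
    if sigma2 <= 0:
        raise AnalysisError("zero trait variance: likelihood degenerate")
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    logL = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)
    return logL, mu, sigma2


def pagel_lambda(
    tree: Phylogeny,
    trait: dict | "np.ndarray",
    *,
    labels=None,
    grid_size: int = 1001,
    boundary_mixture: bool = False,
) -> LambdaResult:
    """Maximum-likelihood phylogenetic signal for one continuous trait.

    The trait is modelled as multivariate normal with mean ``mu * 1`` and
    covariance ``sigma2 * C(lambda)`` where C(lambda) scales the shared
    branch lengths by lambda off the diagonal.  mu and sigma2 have closed
    GLS profiles; lambda is maximized on [0, 1] by a dense grid (default
    1001 points) then bounded scalar refinement.  The likelihood-ratio test
    against lambda = 0 uses chi-squared with 1 df (the common convention for
    this boundary test); ``boundary_mixture`` switches to the conservative
    50:50 point-mass/chi-squared mixture.

    Estimates below 1e-3 are flagged ``effectively_zero``.
    """
    if isinstance(trait, dict):
        canon = {canonical_name(k): float(v) for k, v in trait.items()}
        order = [l for l in tree.tip_labels if canonical_name(l) in canon]
        y = np.array([canon[canonical_name(l)] for l in order])
    else:
        if labels is None:
            raise AlignmentError("labels required when trait is a plain vector")
        canon = {canonical_name(k): float(v) for k, v in zip(labels, trait)}
        order = [l for l in tree.tip_labels if canonical_name(l) in canon]
        y = np.array([canon[canonical_name(l)] for l in order])
    if len(order) < 4:
        raise AnalysisError("need at least 4 species shared by tree and trait vector")
    if np.ptp(y) == 0:
        raise AnalysisError("zero trait variance")
    sub = tree if len(order) == tree.n_tips else tree.reindex(order)
    C = phylo_covariance(sub, order).matrix

    diag = np.diag(C).copy()
    # tiny ridge keeps C(lambda) factorizable when near-zero terminal branches
    # make tips nearly collinear; identical at every lambda, so it cancels in
    # likelihood comparisons
    ridge = 1e-9 * float(diag.mean())
    n = len(y)
    one = np.ones(n)

    if np.allclose(diag, diag[0], rtol=1e-8, atol=1e-12):
        # ultrametric fast path: V(lam) = lam*C + (1-lam)*T*I shares C's
        # eigenvectors, so one eigendecomposition serves every lambda
        T = float(diag[0])
        eigval, Q = np.linalg.eigh(C)
        yt = Q.T @ y
        ot = Q.T @ one

        def profile(lam: float):
            w = lam * eigval + (1.0 - lam) * T + ridge
            w = np.maximum(w, 1e-12 * T)
            mu = float((ot * yt / w).sum() / (ot * ot / w).sum())
            sigma2 = float(((yt - mu * ot) ** 2 / w).sum()) / n
            if sigma2 <= 0:
                raise AnalysisError("zero trait variance: likelihood degenerate")
            logL = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + np.log(w).sum() + n)
            return float(logL), mu, sigma2

    else:

        def profile(lam: float):
            V = C * lam
            np.fill_diagonal(V, diag + ridge)
            return _gls_profile_loglik(y, V)

    def nll(lam: float) -> float:
        return -profile(lam)[0]

    grid = np.linspace(0.0, 1.0, grid_size)
    grid_vals = np.array([nll(l) for l in grid])
    k = int(np.argmin(grid_vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid_size - 1)]
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    lam_hat, best_nll = (float(res.x), float(res.fun))
    if grid_vals[k] < best_nll:  # refinement should never lose; guard anyway
        lam_hat, best_nll = float(grid[k]), float(grid_vals[k])

    logL_hat, mu_hat, sigma2_hat = profile(lam_hat)
    logL0, _, _ = profile(0.0)
    stat = max(0.0, 2.0 * (logL_hat - logL0))
    if boundary_mixture:
        p = 1.0 if stat == 0 else 0.5 * stats.chi2.sf(stat, df=1)
    else:
        p = float(stats.chi2.sf(stat, df=1))
    return LambdaResult(
        lambda_hat=lam_hat,
        sigma2_hat=float(sigma2_hat),
        root_state=float(mu_hat),
        logL_hat=float(logL_hat),
        logL_lambda0=float(logL0),
        lrt_p=float(p),
        n=len(y),
        effectively_zero=lam_hat < LAMBDA_EFFECTIVELY_ZERO,
    )


# ---------------------------------------------------------------------------
# Mantel machinery


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str
    seed: int | None
    n: int
    partial_controls: str | None = None
    permutation_scheme: str = "free"


def _check_aligned(*mats: DistanceMatrix) -> int:
    first = mats[0]
    for m in mats[1:]:
        if tuple(map(canonical_name, m.labels)) != tuple(map(canonical_name, first.labels)):
            raise AlignmentError("distance matrices must share labels and ordering")
    if first.n < 4:
        raise AnalysisError("need at least 4 species for a Mantel test")
    return first.n


def _tri_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise AnalysisError("zero variance in a distance-matrix triangle")
    return float((xc @ yc) / denom)


def _partial_r(r12: float, r13: float, r23: float) -> float:
    if abs(r13) >= 1.0 or abs(r23) >= 1.0:
        raise AnalysisError("degenerate partial correlation: a control correlation is +-1")
    return (r12 - r13 * r23) / math.sqrt((1 - r13**2) * (1 - r23**2))


def _tail_p(obs: float, null: np.ndarray, tail: str) -> float:
    # observed statistic stands in for the identity permutation
    n_perm = len(null)
    if tail == "upper":
        count = int(np.sum(null >= obs))
    elif tail == "lower":
        count = int(np.sum(null <= obs))
    elif tail == "two-sided":
        count = int(np.sum(np.abs(null) >= abs(obs)))
    else:
        raise AnalysisError(f"unknown tail {tail!r}")
    return (1 + count) / (n_perm + 1)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    *,
    n_perm: int = 999,
    tail: str = "upper",
    seed: int | None = 0,
) -> MantelResult:
    """Permutation Mantel test between two species distance matrices.

    r is the product-moment correlation over the strictly-lower triangles;
    the null permutes rows and columns of ``d2`` jointly with a seeded
    generator.  Default tail is upper (positive association)."""
    n = _check_aligned(d1, d2)
    il, jl = np.tril_indices(n, k=-1)
    x = d1.values[il, jl]
    obs = _tri_r(x, d2.values[il, jl])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    B = d2.values
    for k in range(n_perm):
        p = rng.permutation(n)
        null[k] = _tri_r(x, B[np.ix_(p, p)][il, jl])
    return MantelResult(
        r=obs, p=_tail_p(obs, null, tail), n_perm=n_perm, tail=tail, seed=seed, n=n
    )


def mantel_exact(d1: DistanceMatrix, d2: DistanceMatrix, *, tail: str = "upper") -> MantelResult:
    """Exact Mantel p by full enumeration of every relabeling (n <= 7)."""
    n = _check_aligned(d1, d2)
    if n > 7:
        raise AnalysisError("full enumeration only supported for n <= 7")
    il, jl = np.tril_indices(n, k=-1)
    x = d1.values[il, jl]
    obs = _tri_r(x, d2.values[il, jl])
    rs = []
    for p in itertools.permutations(range(n)):
        p = np.array(p)
        rs.append(_tri_r(x, d2.values[np.ix_(p, p)][il, jl]))
    rs = np.array(rs)
    if tail == "upper":
        p_val = float(np.mean(rs >= obs - 1e-12))
    elif tail == "lower":
        p_val = float(np.mean(rs <= obs + 1e-12))
    else:
        p_val = float(np.mean(np.abs(rs) >= abs(obs) - 1e-12))
    return MantelResult(
        r=obs, p=p_val, n_perm=math.factorial(n), tail=tail, seed=None, n=n,
        permutation_scheme="exact",
    )


def restricted_permutation(
    patristic: np.ndarray,
    rng: np.random.Generator,
    *,
    delta: float | None = None,
    n_swaps: int | None = None,
) -> np.ndarray:
    """One phylogenetically restricted permutation of ``range(n)``.

    Built by sequential pair swaps: the first index is uniform, its partner j
    is drawn with probability proportional to ``1 / (d_patristic(i, j) +
    delta)``, so closely related species trade places more readily than
    distant ones.  ``delta`` defaults to 0.1 x the mean off-diagonal
    patristic distance; ``n_swaps`` defaults to n.
    """
    n = patristic.shape[0]
    if delta is None:
        il, jl = np.tril_indices(n, k=-1)
        delta = 0.1 * float(patristic[il, jl].mean())
    if n_swaps is None:
        n_swaps = n
    w = 1.0 / (patristic + delta)
    np.fill_diagonal(w, 0.0)
    cum = np.cumsum(w, axis=1)
    cum /= cum[:, -1:]
    perm = np.arange(n)
    firsts = rng.integers(n, size=n_swaps)
    u = rng.random(n_swaps)
    for i, ui in zip(firsts, u):
        j = int(np.searchsorted(cum[i], ui, side="right"))
        perm[i], perm[j] = perm[j], perm[i]
    return perm


def phylo_mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    tree: Phylogeny | None = None,
    d3: DistanceMatrix | None = None,
    *,
    n_perm: int = 999,
    tail: str = "upper",
    seed: int | None = 0,
    delta: float | None = None,
    n_swaps: int | None = None,
) -> MantelResult:
    """Partial and/or phylogenetically permuted Mantel test.

    With ``d3`` the statistic is the partial correlation r_12.3 over lower
    triangles (the "three-way" comparison: the third matrix is controlled
    linearly).  With a ``tree`` the permutation null is phylogenetically
    restricted (see :func:`restricted_permutation`); without one it falls
    back to free permutations.  A common usage passes the tree's patristic
    distance matrix itself as ``d3`` while also permuting phylogenetically.
    """
    mats = [d1, d2] + ([d3] if d3 is not None else [])
    n = _check_aligned(*mats)
    il, jl = np.tril_indices(n, k=-1)
    x = d1.values[il, jl]
    z = d3.values[il, jl] if d3 is not None else None

    def statistic(Bv: np.ndarray) -> float:
        y = Bv[il, jl]
        r12 = _tri_r(x, y)
        if z is None:
            return r12
        return _partial_r(r12, _tri_r(x, z), _tri_r(y, z))

    obs = statistic(d2.values)
    rng = np.random.default_rng(seed)
    if tree is not None:
        pat = tree.patristic_matrix(list(d1.labels)).values
        draw = lambda: restricted_permutation(pat, rng, delta=delta, n_swaps=n_swaps)
        scheme = "phylogenetically-restricted"
    else:
        draw = lambda: rng.permutation(n)
        scheme = "free"
    null = np.empty(n_perm)
    B = d2.values
    for k in range(n_perm):
        p = draw()
        null[k] = statistic(B[np.ix_(p, p)])
    return MantelResult(
        r=obs,
        p=_tail_p(obs, null, tail),
        n_perm=n_perm,
        tail=tail,
        seed=seed,
        n=n,
        partial_controls=None if d3 is None else "d3",
        permutation_scheme=scheme,
    )
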