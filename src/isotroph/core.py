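"""Core domain types for community stable-isotope analysis.

The pipeline moves between a small set of labelled structures: per-individual
isotope measurements, species-by-prey diet tables with a trophic coding,
per-trap habitat measurements with capture records, an ultrametric species
phylogeny, and symmetric species distance matrices.  Species labels originate
from heterogeneous sources (field tables, museum records, Newick tip labels)
and are matched case-insensitively with spaces and underscores treated as
equivalent; every structure that carries labels supports ``reindex`` so that
:func:`align_labels` can put a collection of structures on one shared species
ordering before distances and comparative tests are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError

__all__ = [
    "canonical_name",
    "IsotopeMeasurement",
    "RatioPair",
    "DietTable",
    "TrophicCoding",
    "TrapHabitatTable",
    "CaptureRecords",
    "Phylogeny",
    "DistanceMatrix",
    "AlignmentResult",
    "align_labels",
    "validate_measurements",
]

#: ranks a trophic coding may assign: integers 1..5 and their midpoints
ALLOWED_RANKS = frozenset(x / 2 for x in range(2, 11))


def canonical_name(name: str) -> str:
    """Canonical form of a species/trap label for cross-source matching.

    Trims whitespace, casefolds, and collapses internal whitespace to single
    underscores, so ``"Ctenotus dux "`` and ``"ctenotus_dux"`` compare equal
    (Newick files conventionally use underscores where tables use spaces).
    """
    return "_".join(str(name).strip().casefold().split())


@dataclass(frozen=True)
class IsotopeMeasurement:
    """One specimen's carbon and nitrogen isotope deltas, in per mil."""

    specimen_id: str
    species: str
    site: str
    d13C: float
    d15N: float

    def __post_init__(self) -> None:
        if not str(self.species).strip():
            raise ValidationError("species label must be non-empty")
        if not str(self.site).strip():
            raise ValidationError("site label must be non-empty")
        for name in ("d13C", "d15N"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(
                    f"{name} must be finite for specimen {self.specimen_id!r}, got {v!r}"
                )


def validate_measurements(measurements: Sequence[IsotopeMeasurement]) -> None:
    """Check dataset-level invariants: specimen ids unique within the dataset."""
    seen: dict[str, int] = {}
    for i, m in enumerate(measurements):
        if m.specimen_id in seen:
            raise ValidationError(
                f"duplicate specimen_id {m.specimen_id!r} at records "
                f"{seen[m.specimen_id]} and {i}"
            )
        seen[m.specimen_id] = i


@dataclass(frozen=True)
class RatioPair:
    """Heavy/light isotope ratios for a sample and its working standard."""

    r_sample: float
    r_standard: float

    def __post_init__(self) -> None:
        if not (self.r_sample > 0 and self.r_standard > 0):
            raise ValidationError(
                f"isotope ratios must be strictly positive, got "
                f"({self.r_sample!r}, {self.r_standard!r})"
            )


@dataclass(frozen=True)
class DietTable:
    """Species-by-prey-category matrix of mean proportional stomach volume.

    ``proportions`` is on the [0, 1] scale (a row need not sum exactly to 1;
    published per-category means rarely do).  ``n_individuals`` records how
    many stomachs each species mean is based on, which downstream operations
    use to apply the minimum-sample-size filter.
    """

    species: tuple[str, ...]
    categories: tuple[str, ...]
    proportions: np.ndarray
    n_individuals: np.ndarray

    ROW_SUM_TOL = 1e-6

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(str(s) for s in self.species))
        object.__setattr__(self, "categories", tuple(str(c) for c in self.categories))
        p = np.asarray(self.proportions, dtype=float)
        n = np.asarray(self.n_individuals, dtype=int)
        object.__setattr__(self, "proportions", p)
        object.__setattr__(self, "n_individuals", n)
        if p.shape != (len(self.species), len(self.categories)):
            raise ValidationError(
                f"proportions shape {p.shape} does not match "
                f"{len(self.species)} species x {len(self.categories)} categories"
            )
        if n.shape != (len(self.species),):
            raise ValidationError("n_individuals must have one entry per species")
        if not np.all(np.isfinite(p)):
            raise ValidationError("diet proportions must be finite")
        if np.any(p < 0) or np.any(p > 1):
            raise ValidationError("diet proportions must lie in [0, 1]")
        sums = p.sum(axis=1)
        if np.any(sums <= 0) or np.any(sums > 1 + self.ROW_SUM_TOL):
            bad = [self.species[i] for i in np.flatnonzero((sums <= 0) | (sums > 1 + self.ROW_SUM_TOL))]
            raise ValidationError(f"diet row sums must be in (0, 1]: offending species {bad}")
        if np.any(n < 1):
            raise ValidationError("n_individuals must be >= 1")
        if len(set(map(canonical_name, self.species))) != len(self.species):
            raise ValidationError("duplicate species in diet table")

    @property
    def labels(self) -> tuple[str, ...]:
        return self.species

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.proportions, index=list(self.species), columns=list(self.categories))
        df.insert(0, "n", self.n_individuals)
        df.index.name = "species"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DietTable":
        if "n" in df.columns:
            n = df["n"].to_numpy()
            df = df.drop(columns="n")
        else:
            n = np.ones(len(df), dtype=int)
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy(dtype=float), n)

    def reindex(self, order: Sequence[str]) -> "DietTable":
        idx = _match_indices(self.species, order, what="diet table")
        return DietTable(
            tuple(self.species[i] for i in idx),
            self.categories,
            self.proportions[idx],
            self.n_individuals[idx],
        )


@dataclass(frozen=True)
class TrophicCoding:
    """Mapping from prey category to trophic rank on the 1..5 scale.

    Ranks are integers 1-5 or midpoints (2.5, 3.5, ...) for higher taxa that
    span two adjacent ranks.  Category names are matched case-insensitively.
    """

    category_rank: Mapping[str, float]

    def __post_init__(self) -> None:
        canon: dict[str, float] = {}
        for cat, rank in dict(self.category_rank).items():
            r = float(rank)
            if r not in ALLOWED_RANKS:
                raise ValidationError(
                    f"rank for {cat!r} must be in {{1, 1.5, ..., 5}}, got {rank!r}"
                )
            canon[canonical_name(cat)] = r
        object.__setattr__(self, "category_rank", dict(self.category_rank))
        object.__setattr__(self, "_canon", canon)

    def rank_of(self, category: str) -> float | None:
        return self._canon.get(canonical_name(category))

    def covers(self, categories: Iterable[str]) -> list[str]:
        """Categories from the iterable that have no rank (empty when fully covered)."""
        return [c for c in categories if self.rank_of(c) is None]


class TrapHabitatTable:
    """Per-trap habitat measurements: one row per pitfall trap, 14 variables.

    Columns whose name starts with ``pct_`` are percentage covers and must lie
    in [0, 100]; other variables (counts, volumes, compaction scores) are only
    required to be finite.
    """

    N_VARIABLES = 14

    def __init__(self, frame: pd.DataFrame):
        if frame.index.name != "trap_id":
            if "trap_id" in frame.columns:
                frame = frame.set_index("trap_id")
            else:
                raise ValidationError("habitat table needs a trap_id column or index")
        frame = frame.astype(float)
        if frame.shape[1] != self.N_VARIABLES:
            raise ValidationError(
                f"habitat table must have exactly {self.N_VARIABLES} variables, "
                f"got {frame.shape[1]}"
            )
        if frame.index.duplicated().any():
            raise ValidationError("duplicate trap_id in habitat table")
        if not np.all(np.isfinite(frame.to_numpy())):
            raise ValidationError("habitat measurements must be finite")
        for col in frame.columns:
            if str(col).startswith("pct_"):
                v = frame[col]
                if (v < 0).any() or (v > 100).any():
                    raise ValidationError(f"percentage variable {col} outside [0, 100]")
        self.frame = frame

    @property
    def trap_ids(self) -> list[str]:
        return [str(t) for t in self.frame.index]

    @property
    def variables(self) -> list[str]:
        return [str(c) for c in self.frame.columns]

    def __len__(self) -> int:
        return len(self.frame)


class CaptureRecords:
    """(species, trap_id) pairs; every trap must exist in the habitat table."""

    def __init__(self, frame: pd.DataFrame):
        missing = {"species", "trap_id"} - set(frame.columns)
        if missing:
            raise ValidationError(f"capture records missing columns: {sorted(missing)}")
        self.frame = frame[["species", "trap_id"]].astype(str).reset_index(drop=True)

    def check_against(self, traps: TrapHabitatTable) -> None:
        known = set(traps.trap_ids)
        unknown = sorted(set(self.frame["trap_id"]) - known)
        if unknown:
            raise ValidationError(f"captures reference unknown traps: {unknown[:5]}")

    @property
    def species(self) -> list[str]:
        return sorted(set(self.frame["species"]))

    def __len__(self) -> int:
        return len(self.frame)


class Phylogeny:
    """A labelled, rooted tree with branch lengths in time units.

    Thin wrapper over a :class:`dendropy.Tree` that enforces the invariants the
    comparative machinery relies on: unique tip labels, non-negative branch
    lengths, and (reported, not enforced) ultrametricity.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not str(leaf.taxon.label).strip():
                raise ValidationError("every tip must carry a label")
            labels.append(str(leaf.taxon.label))
        if len(set(map(canonical_name, labels))) != len(labels):
            raise ValidationError("tip labels must be unique")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValidationError("every non-root branch must have a length")
            if edge.length < 0:
                raise ValidationError(f"negative branch length {edge.length}")
        self._labels = labels
        self._depths = self._compute_depths()

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    def _compute_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}
        self.tree.calc_node_root_distances(return_leaf_distances_only=False)
        for leaf in self.tree.leaf_node_iter():
            depths[str(leaf.taxon.label)] = float(leaf.root_distance)
        return depths

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(self._labels)

    @property
    def labels(self) -> tuple[str, ...]:
        return self.tip_labels

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    @property
    def depth(self) -> float:
        return max(self._depths.values())

    def tip_depths(self) -> dict[str, float]:
        return dict(self._depths)

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = list(self._depths.values())
        return (max(d) - min(d)) <= rel_tol * max(max(d), 1e-300)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def _full_covariance(self) -> np.ndarray:
        """Shared-path-length matrix over all tips in ``self._labels`` order."""
        index = {l: i for i, l in enumerate(self._labels)}
        n = len(self._labels)
        C = np.zeros((n, n))
        tips_below: dict[int, list[int]] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                tips_below[id(node)] = [index[str(node.taxon.label)]]
                continue
            child_sets = [tips_below.pop(id(c)) for c in node.child_nodes()]
            depth = float(node.root_distance)
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    C[np.ix_(child_sets[a], child_sets[b])] = depth
                    C[np.ix_(child_sets[b], child_sets[a])] = depth
            tips_below[id(node)] = [i for s in child_sets for i in s]
        np.fill_diagonal(C, [self._depths[l] for l in self._labels])
        return C

    def patristic_matrix(self, order: Sequence[str] | None = None) -> "DistanceMatrix":
        """Pairwise path-length (patristic) distances between tips."""
        labels, C = self.covariance_matrix(order)
        depths = np.array([self._depths[l] for l in labels])
        d = depths[:, None] + depths[None, :] - 2.0 * C
        np.fill_diagonal(d, 0.0)
        d[d < 0] = 0.0  # guard rounding on near-duplicate tips
        return DistanceMatrix(tuple(labels), d)

    def covariance_matrix(self, order: Sequence[str] | None = None):
        """Shared-path-length matrix C (species x species), diag = tip depths.

        C[i, j] is the branch length shared from the root down to the most
        recent common ancestor of tips i and j -- the trait covariance
        structure implied by Brownian evolution along the tree.
        """
        order = list(order) if order is not None else list(self._labels)
        idx = _match_indices(self._labels, order, what="phylogeny")
        labels = tuple(self._labels[i] for i in idx)
        C = self._full_covariance()[np.ix_(idx, idx)]
        return labels, C

    def reindex(self, order: Sequence[str]) -> "Phylogeny":
        """Prune the tree to the given tips (canonical-name matched)."""
        keep = {canonical_name(o) for o in order}
        own = [l for l in self._labels if canonical_name(l) in keep]
        if not own:
            raise AlignmentError("no tree tips match the requested labels")
        sub = self.tree.extract_tree_with_taxa_labels(
            own, suppress_unifurcations=True
        )
        return Phylogeny(sub)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny({self.n_tips} tips, depth={self.depth:.4g})"


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with a fixed label order."""

    labels: tuple[str, ...]
    values: np.ndarray

    SYM_TOL = 1e-12

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValidationError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.all(np.isfinite(v)):
            raise ValidationError("distances must be finite")
        if np.any(np.abs(v - v.T) > self.SYM_TOL):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal must be exactly zero")
        if np.any(v < 0):
            raise ValidationError("distances must be non-negative")
        if len(set(map(canonical_name, self.labels))) != n:
            raise ValidationError("duplicate labels in distance matrix")

    @classmethod
    def from_points(cls, labels: Sequence[str], points: np.ndarray) -> "DistanceMatrix":
        """Euclidean distances between row vectors of ``points``."""
        from scipy.spatial.distance import pdist, squareform

        points = np.atleast_2d(np.asarray(points, dtype=float))
        if points.shape[0] != len(labels):
            raise ValidationError("one point row per label required")
        d = squareform(pdist(points)) if len(labels) > 1 else np.zeros((1, 1))
        return cls(tuple(labels), d)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries as a flat vector."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def reindex(self, order: Sequence[str]) -> "DistanceMatrix":
        idx = _match_indices(self.labels, order, what="distance matrix")
        return DistanceMatrix(
            tuple(self.labels[i] for i in idx), self.values[np.ix_(idx, idx)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


def _match_indices(own: Sequence[str], order: Sequence[str], *, what: str) -> list[int]:
    by_canon = {canonical_name(l): i for i, l in enumerate(own)}
    idx = []
    for o in order:
        c = canonical_name(o)
        if c not in by_canon:
            raise AlignmentError(f"label {o!r} not present in {what}")
        idx.append(by_canon[c])
    return idx


@dataclass
class AlignmentResult:
    """Shared ordering plus the per-object labels it dropped."""

    order: list[str]
    objects: tuple
    dropped: list[list[str]] = field(default_factory=list)


def _labels_of(obj) -> Sequence[str]:
    if hasattr(obj, "labels"):
        return obj.labels
    if isinstance(obj, (list, tuple)) and all(isinstance(x, str) for x in obj):
        return obj
    if isinstance(obj, pd.Series):
        return [str(i) for i in obj.index]
    if isinstance(obj, pd.DataFrame):
        return [str(i) for i in obj.index]
    raise AlignmentError(f"object of type {type(obj).__name__} carries no labels")


def _reindex_obj(obj, order: list[str]):
    if hasattr(obj, "reindex") and not isinstance(obj, (pd.Series, pd.DataFrame)):
        return obj.reindex(order)
    if isinstance(obj, (pd.Series, pd.DataFrame)):
        by_canon = {canonical_name(i): i for i in obj.index}
        return obj.loc[[by_canon[canonical_name(o)] for o in order]]
    if isinstance(obj, (list, tuple)):
        return list(order)
    return obj


def align_labels(*objects) -> AlignmentResult:
    """Put labelled structures on one shared, canonically sorted species order.

    The shared order is the intersection of all label sets (canonical-name
    matched), sorted by canonical name and spelled as in the first object.
    Every object that supports ``reindex`` is returned reindexed; labels each
    object loses are reported in ``dropped``.
    """
    if len(objects) < 2:
        raise AlignmentError("need at least two labelled structures to align")
    label_sets = [list(_labels_of(o)) for o in objects]
    canon_sets = [set(map(canonical_name, ls)) for ls in label_sets]
    shared = set.intersection(*canon_sets)
    if not shared:
        raise AlignmentError("label sets have an empty intersection")
    spelling = {canonical_name(l): l for l in reversed(label_sets[0])}
    order = [spelling[c] for c in sorted(shared)]
    dropped = [
        sorted(l for l in ls if canonical_name(l) not in shared) for ls in label_sets
    ]
    reindexed = tuple(_reindex_obj(o, order) for o in objects)
    return AlignmentResult(order=order, objects=reindexed, dropped=dropped)
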