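"""Core data types for multi-arrangement dissimilarity data.

The central objects are the representational dissimilarity matrix (RDM) —
a symmetric item-by-item matrix of non-negative dissimilarities with a zero
diagonal — and the Arrangement, one trial's 2D placement of an item subset
inside a circular arena. A single trial only constrains the pairs it
contains, so RDMs carry a boolean ``defined`` mask distinguishing measured
from missing entries; a "full" RDM has every entry defined.

All dissimilarities are unitless: within a trial the subject zooms the
subset to fill the arena, so only distance *ratios* carry information.
Normalisation to unit root-mean-square (RMS) over the defined pairs fixes
the scale gauge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ItemSet",
    "RDM",
    "Arrangement",
    "DegenerateRDMError",
    "num_pairs",
    "rdm_from_points",
    "distances_from_arrangement",
    "normalize_rdm",
    "disparity",
]


class DegenerateRDMError(ValueError):
    """Raised when an operation requires non-zero dissimilarity signal."""


class ItemSet:
    """An ordered collection of unique, non-empty item identifiers."""

    __slots__ = ("items", "_index")

    def __init__(self, items):
        items = tuple(str(i) for i in items)
        if len(items) < 2:
            raise ValueError("an ItemSet needs at least 2 items")
        if any(not i for i in items):
            raise ValueError("item identifiers must be non-empty")
        if len(set(items)) != len(items):
            raise ValueError("item identifiers must be unique")
        self.items = items
        self._index = {item: k for k, item in enumerate(items)}

    @property
    def n(self) -> int:
        return len(self.items)

    def index(self, item: str) -> int:
        try:
            return self._index[item]
        except KeyError:
            raise KeyError(f"unknown item {item!r}") from None

    def __len__(self):
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __contains__(self, item):
        return item in self._index

    def __getitem__(self, k):
        return self.items[k]

    def __eq__(self, other):
        return isinstance(other, ItemSet) and self.items == other.items

    def __hash__(self):
        return hash(self.items)

    def __repr__(self):
        return f"ItemSet({list(self.items)!r})"


def num_pairs(n) -> int:
    """Number of unordered item pairs, (n**2 - n) / 2.

    This is the trial count a pairwise-judgment experiment needs for ``n``
    items, and the number of independent entries of a full RDM.
    """
    if isinstance(n, bool) or not isinstance(n, (int, np.integer)):
        raise TypeError(f"n must be an integer, got {n!r}")
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    return (int(n) * int(n) - int(n)) // 2


@dataclass
class RDM:
    """Symmetric dissimilarity matrix with an optional defined-entry mask.

    Parameters
    ----------
    items : ItemSet
        The items the rows/columns refer to, in order.
    values : (n, n) ndarray of float
        Non-negative dissimilarities, symmetric with zero diagonal.
        Undefined entries may hold any value (conventionally 0 or NaN in
        serialized form); consult ``defined``.
    defined : (n, n) ndarray of bool, optional
        Which entries carry information. Defaults to all True (full RDM).
        Symmetric; the diagonal is always defined (trivially zero).
    """

    items: ItemSet
    values: np.ndarray
    defined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not isinstance(self.items, ItemSet):
            self.items = ItemSet(self.items)
        n = self.items.n
        v = np.asarray(self.values, dtype=float)
        if v.shape != (n, n):
            raise ValueError(f"values must be {n}x{n}, got {v.shape}")
        if self.defined is None:
            d = np.ones((n, n), dtype=bool)
        else:
            d = np.asarray(self.defined, dtype=bool)
            if d.shape != (n, n):
                raise ValueError(f"defined mask must be {n}x{n}, got {d.shape}")
        if not np.array_equal(d, d.T):
            raise ValueError("defined mask must be symmetric")
        np.fill_diagonal(d, True)
        both = d & d.T
        if not np.allclose(v[both], v.T[both], rtol=0.0, atol=1e-9):
            raise ValueError("values must be symmetric on defined entries")
        with np.errstate(invalid="ignore"):
            if np.any(v[d] < -1e-12) or np.any(~np.isfinite(v[d])):
                raise ValueError("defined dissimilarities must be finite and >= 0")
        v = np.where(d, 0.5 * (v + v.T), 0.0)
        v[v < 0] = 0.0
        np.fill_diagonal(v, 0.0)
        self.values = v
        self.defined = d

    # -- basic views ---------------------------------------------------
    @property
    def n(self) -> int:
        return self.items.n

    @property
    def is_full(self) -> bool:
        return bool(self.defined.all())

    def triu_indices(self):
        return np.triu_indices(self.n, k=1)

    def upper_values(self) -> np.ndarray:
        """Upper-triangle dissimilarities (each pair once), row-major order."""
        iu = self.triu_indices()
        return self.values[iu]

    def upper_defined(self) -> np.ndarray:
        iu = self.triu_indices()
        return self.defined[iu]

    def defined_pairs(self):
        """Yield (item_i, item_j, value) for each defined upper-triangle pair."""
        iu, ju = self.triu_indices()
        for i, j in zip(iu, ju):
            if self.defined[i, j]:
                yield self.items[i], self.items[j], float(self.values[i, j])

    # -- construction helpers ------------------------------------------
    def copy(self) -> "RDM":
        return RDM(self.items, self.values.copy(), self.defined.copy())

    def with_values(self, values: np.ndarray) -> "RDM":
        return RDM(self.items, values, self.defined.copy())

    def restrict(self, subset) -> "RDM":
        """Sub-RDM over ``subset`` (order preserved as given)."""
        idx = np.array([self.items.index(i) for i in subset])
        return RDM(
            ItemSet(subset),
            self.values[np.ix_(idx, idx)],
            self.defined[np.ix_(idx, idx)],
        )

    def get(self, item_i: str, item_j: str) -> float:
        i, j = self.items.index(item_i), self.items.index(item_j)
        if not self.defined[i, j]:
            raise KeyError(f"pair ({item_i}, {item_j}) is undefined")
        return float(self.values[i, j])


@dataclass
class Arrangement:
    """One trial: a subset of items placed at 2D coordinates in the arena.

    Coordinates are in arena units with the origin at the arena centre;
    the arena is the disc of diameter ``arena_diameter``. Placements
    outside the arena are tolerated with a warning — real trial logs may
    contain edge placements.
    """

    trial_index: int
    items: tuple
    coords: np.ndarray
    arena_diameter: float = 1.0

    def __post_init__(self):
        self.trial_index = int(self.trial_index)
        if self.trial_index < 1:
            raise ValueError("trial_index must be >= 1")
        self.items = tuple(str(i) for i in self.items)
        if len(self.items) < 2:
            raise ValueError("an arrangement needs at least 2 items")
        if len(set(self.items)) != len(self.items):
            raise ValueError("subset items must be unique")
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (len(self.items), 2):
            raise ValueError(
                f"coords must be ({len(self.items)}, 2), got {c.shape}"
            )
        if not np.all(np.isfinite(c)):
            raise ValueError("coordinates must be finite")
        self.coords = c
        self.arena_diameter = float(self.arena_diameter)
        if self.arena_diameter <= 0:
            raise ValueError("arena_diameter must be positive")
    def out_of_arena(self) -> int:
        """Number of icons placed outside the circular arena.

        Checked when a trial log is read: an out-of-arena placement is
        reported as a warning, not rejected — real logs contain edge
        placements, and only relative distances matter.
        """
        radii = np.linalg.norm(self.coords, axis=1)
        return int(np.sum(radii > self.arena_diameter / 2 * (1 + 1e-9)))

    @property
    def k(self) -> int:
        return len(self.items)

    def distances(self) -> np.ndarray:
        """Condensed vector of pairwise screen distances (pdist order)."""
        return pdist(self.coords)

    def distance_matrix(self) -> np.ndarray:
        return squareform(self.distances())


def rdm_from_points(items, points) -> RDM:
    """Full RDM of pairwise Euclidean distances among ``points``.

    ``points`` is (m, d); ``items`` the m identifiers. Coincident points
    are allowed and give a distance of zero.
    """
    itemset = items if isinstance(items, ItemSet) else ItemSet(items)
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] != itemset.n:
        raise ValueError(
            f"points must be ({itemset.n}, d), got {pts.shape}"
        )
    return RDM(itemset, squareform(pdist(pts)))


def distances_from_arrangement(arr: Arrangement, items) -> RDM:
    """Partial RDM over the full item set from one arrangement.

    Pairs within the arrangement's subset get their 2D screen distance;
    every other entry is undefined.
    """
    itemset = items if isinstance(items, ItemSet) else ItemSet(items)
    idx = [itemset.index(i) for i in arr.items]  # raises on unknown item
    n = itemset.n
    values = np.zeros((n, n))
    defined = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(defined, True)
    dmat = arr.distance_matrix()
    for a, ia in enumerate(idx):
        for b, ib in enumerate(idx):
            values[ia, ib] = dmat[a, b]
            defined[ia, ib] = True
    return RDM(itemset, values, defined)


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def normalize_rdm(rdm: RDM, mask: np.ndarray | None = None) -> RDM:
    """Rescale so the RMS over defined off-diagonal entries equals 1.

    ``mask`` optionally restricts the RMS computation to a sub-mask of the
    defined entries (used when two partial RDMs are compared over their
    common pairs). The RMS is taken over the upper triangle, each pair
    counted once.
    """
    iu = rdm.triu_indices()
    use = rdm.defined[iu]
    if mask is not None:
        use = use & np.asarray(mask, dtype=bool)[iu]
    if not np.any(use):
        raise ValueError("no defined off-diagonal entries to normalize over")
    rms = _rms(rdm.upper_values()[use])
    if rms == 0.0:
        raise DegenerateRDMError("all defined dissimilarities are zero")
    return rdm.with_values(rdm.values / rms)


def disparity(a: RDM, b: RDM) -> float:
    """RMS difference between two RDMs after normalizing both.

    Both matrices are normalized to unit RMS over the pairs defined in
    *both*, then the RMS of the entrywise differences over those pairs is
    returned. Zero iff the two agree up to a positive scale factor on the
    common defined set.
    """
    if a.items != b.items:
        raise ValueError("RDMs must share the same ItemSet")
    common = a.defined & b.defined
    iu = a.triu_indices()
    use = common[iu]
    if not np.any(use):
        raise ValueError("no pair is defined in both RDMs")
    an = normalize_rdm(a, mask=common)
    bn = normalize_rdm(b, mask=common)
    return _rms(an.upper_values()[use] - bn.upper_values()[use])
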