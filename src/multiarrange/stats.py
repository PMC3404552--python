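"""RDM comparison statistics and parsers for companion judgment methods.

Two RDMs measured for the same items (different sessions, methods, or
subjects) are compared by the Spearman rank correlation of their upper
triangles. Because the n*(n-1)/2 entries of an RDM are not independent
observations, significance is assessed with a condition-label
randomization test: the items of one RDM are relabelled (rows and columns
permuted jointly) to build the null distribution of the correlation.

Also included: parsers turning the raw records of two simpler judgment
tasks — pairwise 1D distance placements, and ranking of all pair icons
along a vertical dissimilarity axis — into RDMs for cross-method
validation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats as sps

from .core import RDM, ItemSet, num_pairs

__all__ = [
    "RandomizationResult",
    "spearman_rdm",
    "randomization_test",
    "rdm_from_pairwise_1d",
    "rdm_from_pair_ranking",
]


@dataclass
class RandomizationResult:
    """Observed RDM correlation with its randomization-test p-value."""

    observed_r: float
    p_value: float
    n_permutations: int
    seed: int | None
    exhaustive: bool = False


def spearman_rdm(a: RDM, b: RDM) -> float:
    """Spearman correlation of the two RDMs' upper-triangle vectors.

    Average ranks for ties. Raises on a constant vector, for which the
    correlation is undefined.
    """
    if a.items != b.items:
        raise ValueError("RDMs must share the same ItemSet")
    if not (a.is_full and b.is_full):
        raise ValueError("both RDMs must be fully defined")
    x, y = a.upper_values(), b.upper_values()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant RDM")
    r = sps.spearmanr(x, y).statistic
    return float(r)


def _spearman_vec(x_rank: np.ndarray, y: np.ndarray) -> float:
    """Pearson of pre-ranked x against rankdata(y)."""
    yr = sps.rankdata(y)
    xc = x_rank - x_rank.mean()
    yc = yr - yr.mean()
    return float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))


def randomization_test(
    a: RDM,
    b: RDM,
    n_permutations: int = 1000,
    seed: int = 0,
    exhaustive: bool | None = None,
) -> RandomizationResult:
    """Condition-label randomization test of a positive RDM correlation.

    Item labels of ``b`` are permuted (rows and columns jointly) and the
    Spearman correlation with ``a`` recomputed under each relabelling.
    The one-sided p-value counts permutations with correlation at least
    the observed one. By default all n! relabellings are enumerated when
    there are no more of them than ``n_permutations`` (the identity is
    included in the null set and p = count / n!); otherwise
    ``n_permutations`` relabellings are sampled with the given seed and
    p = (1 + count) / (1 + n_permutations), which can never be zero.
    """
    if a.items != b.items:
        raise ValueError("RDMs must share the same ItemSet")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    n = a.n
    observed = spearman_rdm(a, b)
    if exhaustive is None:
        exhaustive = math.factorial(n) <= n_permutations

    iu = np.triu_indices(n, k=1)
    a_rank = sps.rankdata(a.upper_values())
    bv = b.values
    tol = 1e-12

    if exhaustive:
        count = 0
        total = 0
        for perm in permutations(range(n)):
            p = np.array(perm)
            r = _spearman_vec(a_rank, bv[np.ix_(p, p)][iu])
            if r >= observed - tol:
                count += 1
            total += 1
        return RandomizationResult(
            observed_r=observed,
            p_value=count / total,
            n_permutations=total,
            seed=None,
            exhaustive=True,
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        p = rng.permutation(n)
        r = _spearman_vec(a_rank, bv[np.ix_(p, p)][iu])
        if r >= observed - tol:
            count += 1
    return RandomizationResult(
        observed_r=observed,
        p_value=(1 + count) / (1 + n_permutations),
        n_permutations=n_permutations,
        seed=seed,
        exhaustive=False,
    )


def _rdm_from_pair_records(records, value_name: str) -> RDM:
    records = list(records)
    items = sorted({it for i, j, _ in records for it in (i, j)})
    itemset = ItemSet(items)
    n = itemset.n
    values = np.zeros((n, n))
    seen: dict[tuple, int] = {}
    duplicated = []
    for i, j, v in records:
        if i == j:
            raise ValueError(f"self-pair record for item {i!r}")
        key = tuple(sorted((str(i), str(j))))
        if key in seen:
            duplicated.append(key)
        seen[key] = seen.get(key, 0) + 1
        ii, jj = itemset.index(str(i)), itemset.index(str(j))
        values[ii, jj] = values[jj, ii] = float(v)
    expected = num_pairs(n)
    missing = [
        (itemset[i], itemset[j])
        for i in range(n)
        for j in range(i + 1, n)
        if tuple(sorted((itemset[i], itemset[j]))) not in seen
    ]
    if duplicated or missing:
        raise ValueError(
            f"bad {value_name} records: "
            f"{len(seen)} distinct pairs, expected {expected}; "
            f"duplicated={sorted(set(duplicated))}, missing={missing}"
        )
    return RDM(itemset, values)


def rdm_from_pairwise_1d(records) -> RDM:
    """RDM from pairwise 1D placements: (item_i, item_j, horizontal distance).

    Each unordered pair must appear exactly once; the recorded horizontal
    distance is taken directly as the pair's dissimilarity.
    """
    return _rdm_from_pair_records(records, "pairwise-1D")


def rdm_from_pair_ranking(records) -> RDM:
    """RDM from a 1D ranking of pair icons: (item_i, item_j, vertical position).

    Positions increase downwards from the top of the scale, with the most
    similar pairs at the top (position 0), so the raw position is itself a
    dissimilarity. A constant arrangement is degenerate (it carries no
    ordering information) and triggers a warning.
    """
    rdm = _rdm_from_pair_records(records, "pair-ranking")
    if np.ptp(rdm.upper_values()) == 0:
        warnings.warn(
            "all pair icons share one position: the ranking is degenerate",
            stacklevel=2,
        )
    return rdm
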