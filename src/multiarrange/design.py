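"""Adaptive "lift-the-weakest" design of the next trial's item subset.

The designer keeps a per-pair record of how much measurement evidence the
trials so far provide. Placement error is assumed roughly constant on
screen, so the dissimilarity signal-to-noise of a pair grows with its
on-screen distance: a trial contributes evidence w = (d / arena_diameter)^2
for each pair it contains. The next subset is seeded with the weakest pair
and grown greedily to maximize expected evidence-utility gain per unit
trial cost, under the zooming assumption that the subset will be rescaled
to fill the arena. The session terminates once every pair's cumulative
evidence reaches the threshold.

Because tight clusters of similar items yield the weakest evidence on a
full-set trial (they sit close together on screen), the greedy naturally
proposes within-cluster subsets, letting the subject spread a cluster over
the whole arena.
"""

from __future__ import annotations

import configparser
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import RDM, Arrangement, ItemSet

__all__ = [
    "EvidenceMatrix",
    "DesignParams",
    "trial_evidence",
    "trial_evidence_values",
    "update_evidence",
    "utility",
    "design_next_subset",
]


@dataclass
class EvidenceMatrix:
    """Cumulative per-pair evidence weights (symmetric, zero diagonal)."""

    items: ItemSet
    weights: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if not isinstance(self.items, ItemSet):
            self.items = ItemSet(self.items)
        n = self.items.n
        if self.weights is None:
            self.weights = np.zeros((n, n))
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (n, n):
            raise ValueError(f"weights must be {n}x{n}, got {w.shape}")
        if not np.allclose(w, w.T, rtol=0.0, atol=1e-12):
            raise ValueError("evidence weights must be symmetric")
        if np.any(w < 0):
            raise ValueError("evidence weights must be >= 0")
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n(self) -> int:
        return self.items.n

    def copy(self) -> "EvidenceMatrix":
        return EvidenceMatrix(self.items, self.weights.copy())

    def min_pair(self):
        """Weakest pair (item_i, item_j); ties broken lexicographically."""
        best = None
        best_w = np.inf
        for i in range(self.n):
            for j in range(i + 1, self.n):
                a, b = sorted((self.items[i], self.items[j]))
                key = (self.weights[i, j], a, b)
                if best is None or key < (best_w,) + best:
                    best = (a, b)
                    best_w = self.weights[i, j]
        return best


@dataclass(frozen=True)
class DesignParams:
    """Tunables of the adaptive designer.

    evidence_threshold : cumulative evidence at which a pair counts as
        sufficiently measured (session ends when all pairs reach it).
    utility_exponent : steepness of the saturating utility of evidence;
        large values concentrate utility gain on the weakest pairs.
    min_subset / max_subset : bounds on the subset size (max_subset=None
        means the full item set).
    cost_per_item, cost_offset : linear model of the time cost of a trial
        with k items, cost = cost_offset + cost_per_item * k.
    """

    evidence_threshold: float = 0.5
    utility_exponent: float = 10.0
    min_subset: int = 3
    max_subset: int | None = None
    cost_per_item: float = 1.0
    cost_offset: float = 1.0

    def __post_init__(self):
        if self.evidence_threshold <= 0:
            raise ValueError("evidence_threshold must be > 0")
        if self.utility_exponent < 1:
            raise ValueError("utility_exponent must be >= 1")
        if self.min_subset < 3:
            raise ValueError("min_subset must be >= 3")
        if self.max_subset is not None and self.max_subset < self.min_subset:
            raise ValueError("min_subset must be <= max_subset")
        if self.cost_per_item <= 0 or self.cost_offset < 0:
            raise ValueError("invalid cost model constants")

    @classmethod
    def from_file(cls, path) -> "DesignParams":
        """Load parameters from a flat JSON object or an INI [design] section."""
        text = Path(path).read_text()
        try:
            raw = json.loads(text)
        except json.JSONDecodeError:
            cp = configparser.ConfigParser()
            cp.read_string(text)
            section = "design" if cp.has_section("design") else cp.default_section
            raw = dict(cp[section])
        kwargs = {}
        for f in (
            "evidence_threshold",
            "utility_exponent",
            "cost_per_item",
            "cost_offset",
        ):
            if f in raw:
                kwargs[f] = float(raw[f])
        for f in ("min_subset", "max_subset"):
            if f in raw and raw[f] is not None:
                kwargs[f] = int(raw[f])
        return cls(**kwargs)


def trial_evidence_values(arr: Arrangement) -> np.ndarray:
    """Evidence weights for the arrangement's pairs, in pair order.

    w = (screen distance / arena diameter)^2 — in [0, 1] for in-arena
    placements, zero for coincident icons.
    """
    return (arr.distances() / arr.arena_diameter) ** 2


def trial_evidence(arr: Arrangement) -> dict:
    """Evidence weights keyed by (item_i, item_j) for pairs in the trial."""
    vals = trial_evidence_values(arr)
    out = {}
    k = 0
    for a in range(arr.k):
        for b in range(a + 1, arr.k):
            out[(arr.items[a], arr.items[b])] = float(vals[k])
            k += 1
    return out


def update_evidence(ev: EvidenceMatrix, arr: Arrangement) -> EvidenceMatrix:
    """Return a new EvidenceMatrix with the trial's evidence added."""
    for it in arr.items:
        if it not in ev.items:
            raise ValueError(f"arrangement item {it!r} not in the item set")
    w = ev.weights.copy()
    for (a, b), gain in trial_evidence(arr).items():
        i, j = ev.items.index(a), ev.items.index(b)
        w[i, j] += gain
        w[j, i] += gain
    return EvidenceMatrix(ev.items, w)


def utility(w, params: DesignParams):
    """Saturating utility of cumulative evidence, in [0, 1].

    u(w) = (min(w, T) / T)^(1/e) with threshold T and exponent e: concave,
    rising steeply from zero and flat above the threshold, so marginal
    utility is concentrated on the pairs with the least evidence.
    Vectorized over ``w``.
    """
    w = np.asarray(w, dtype=float)
    u = (np.minimum(w, params.evidence_threshold) / params.evidence_threshold) ** (
        1.0 / params.utility_exponent
    )
    return float(u) if u.ndim == 0 else u


def _subset_score(idx, est_v, ev_w, params):
    """(benefit, cost) of presenting subset ``idx`` (list of item indices)."""
    sub = np.asarray(idx)
    d = est_v[np.ix_(sub, sub)][np.triu_indices(len(sub), k=1)]
    w = ev_w[np.ix_(sub, sub)][np.triu_indices(len(sub), k=1)]
    dmax = d.max()
    gain = (d / dmax) ** 2 if dmax > 0 else np.zeros_like(d)
    benefit = float(np.sum(utility(w + gain, params) - utility(w, params)))
    cost = params.cost_offset + params.cost_per_item * len(sub)
    return benefit, cost


def design_next_subset(
    est: RDM | None,
    ev: EvidenceMatrix,
    params: DesignParams,
    trial_index: int,
) -> list | None:
    """Choose the next trial's item subset, or None to terminate.

    Trial 1 always presents the full item set. Afterwards, if every
    pair's cumulative evidence has reached the threshold the session is
    over (returns None). Otherwise the subset is seeded with the weakest
    pair and grown greedily: each step adds the item giving the largest
    utility-gain-per-cost ratio, where the expected evidence gain of pair
    (i, j) in subset S is (est(i,j) / max_{(a,b) in S} est(a,b))^2 — the
    subset is assumed rescaled ("zoomed") to fill the arena. Growth stops
    when the best addition no longer improves the ratio or the subset
    reaches ``max_subset``; at least ``min_subset`` items are returned.
    """
    items = ev.items
    n = items.n
    if trial_index == 1:
        return list(items)
    iu = np.triu_indices(n, k=1)
    if np.all(ev.weights[iu] >= params.evidence_threshold):
        return None
    if est is None or not est.is_full:
        raise ValueError(
            "design after trial 1 needs a fully defined RDM estimate"
        )
    if est.items != items:
        raise ValueError("estimate and evidence must share the same ItemSet")

    max_subset = n if params.max_subset is None else min(params.max_subset, n)
    a, b = ev.min_pair()
    subset = [items.index(a), items.index(b)]
    est_v = est.values
    ev_w = ev.weights

    while len(subset) < max_subset:
        benefit, cost = _subset_score(subset, est_v, ev_w, params)
        current_ratio = benefit / cost
        best = None
        for cand in range(n):
            if cand in subset:
                continue
            cb, cc = _subset_score(subset + [cand], est_v, ev_w, params)
            key = (-(cb / cc), items[cand])  # ratio desc, then lexicographic
            if best is None or key < best[0]:
                best = (key, cand, cb / cc)
        _, cand, ratio = best
        if len(subset) >= params.min_subset and ratio <= current_ratio:
            break
        subset.append(cand)
    return [items[i] for i in sorted(subset)]
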