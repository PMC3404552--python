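"""Simulated subject: arrangements generated from a ground-truth RDM.

A simulated subject "arranges" a subset by embedding the ground-truth
sub-RDM in 2D with metric-stress MDS, rescaling the configuration so the
largest inter-icon distance spans 95% of the arena diameter (the subject
is instructed to zoom in and use the whole arena), and optionally
jittering every icon with isotropic 2D Gaussian placement noise.

Together with the adaptive designer this closes the loop: entire sessions
can be simulated without a human, which is how parameter-recovery tests
and the worked four-item toy example are produced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .core import RDM, Arrangement, ItemSet, rdm_from_points
from .design import DesignParams, EvidenceMatrix, design_next_subset, update_evidence
from .estimation import mds_embed, weighted_average_estimate

__all__ = [
    "SubjectModel",
    "make_toy_tetrahedron",
    "random_ground_truth",
    "simulate_arrangement",
    "simulate_session",
]

ZOOM_FILL = 0.95  # fraction of the arena diameter spanned by the widest pair


@dataclass
class SubjectModel:
    """Ground-truth RDM plus placement-noise level and seed."""

    truth: RDM
    noise_sd: float = 0.0
    seed: int = 0
    arena_diameter: float = 1.0

    def __post_init__(self):
        if not self.truth.is_full:
            raise ValueError("ground truth must be a full RDM")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.arena_diameter <= 0:
            raise ValueError("arena_diameter must be positive")


def make_toy_tetrahedron() -> RDM:
    """Four items, all six pairwise dissimilarities equal to 1.

    The configuration is a regular unit-edge tetrahedron: it lives in 3D,
    so no single 2D arrangement can represent it exactly — the minimal
    interesting case for estimation from multiple arrangements.
    """
    items = ItemSet(["A", "B", "C", "D"])
    values = np.ones((4, 4)) - np.eye(4)
    return RDM(items, values)


def random_ground_truth(n: int, dims: int, seed: int) -> RDM:
    """Euclidean RDM of ``n`` points uniform in the unit ``dims``-cube."""
    if n < 3:
        raise ValueError("need at least 3 items")
    if dims < 1:
        raise ValueError("dims must be >= 1")
    rng = np.random.default_rng(seed)
    pts = rng.uniform(size=(n, dims))
    width = max(2, len(str(n)))
    items = [f"item{k + 1:0{width}d}" for k in range(n)]
    return rdm_from_points(items, pts)


def simulate_arrangement(
    model: SubjectModel, subset, trial_index: int
) -> Arrangement:
    """One simulated trial: 2D MDS of the true sub-RDM, zoomed, jittered.

    The noise stream is derived deterministically from (model.seed,
    trial_index), so a fixed pair gives a bit-identical arrangement while
    different trials are independent.
    """
    subset = list(subset)
    if len(subset) < 2:
        raise ValueError("subset must contain at least 2 items")
    sub = model.truth.restrict(subset)
    coords = mds_embed(sub, dims=2)
    dmax = float(pdist(coords).max()) if len(subset) > 1 else 0.0
    if dmax > 0:
        coords = coords * (ZOOM_FILL * model.arena_diameter / dmax)
    if model.noise_sd > 0:
        rng = np.random.default_rng([int(model.seed), int(trial_index)])
        coords = coords + rng.normal(
            scale=model.noise_sd, size=coords.shape
        )
    return Arrangement(
        trial_index=trial_index,
        items=subset,
        coords=coords,
        arena_diameter=model.arena_diameter,
    )


def simulate_session(
    model: SubjectModel,
    params: DesignParams | None = None,
    max_trials: int = 100,
) -> list:
    """Closed-loop session: adaptive designer driving the simulated subject.

    Trial 1 presents the full item set; after each trial the evidence
    record and the designer's running estimate (scaled-to-match weighted
    average) are refreshed and the designer proposes the next subset.
    Stops at the evidence threshold or after ``max_trials`` trials.
    Returns the trial log (list of Arrangements).
    """
    if max_trials < 1:
        raise ValueError("max_trials must be >= 1")
    params = params or DesignParams()
    items = model.truth.items
    ev = EvidenceMatrix(items)
    trials: list[Arrangement] = []
    est = None
    for t in range(1, max_trials + 1):
        subset = design_next_subset(est, ev, params, t)
        if subset is None:
            break
        arr = simulate_arrangement(model, subset, t)
        trials.append(arr)
        ev = update_evidence(ev, arr)
        est = weighted_average_estimate(trials, items).estimate
    return trials
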