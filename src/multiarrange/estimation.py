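"""Estimating the full RDM from multiple partial 2D arrangements.

Two estimators are provided.

``weighted_average_estimate`` — the scaled-to-match weighted average: each
trial's distance matrix is rescaled onto the current estimate (the subject
zooms each subset to fill the arena, so each trial has its own unknown
scale), entries are averaged with per-pair evidence weights, and the
rescale/average cycle is iterated to a fixed point.

``inverse_mds_estimate`` — iterative inverse MDS: starting from the
aligned average, the current RDM estimate is used to *predict* each
trial's arrangement by metric-stress MDS of the relevant sub-RDM, and the
estimate is adjusted to drive down the residuals between predicted and
actual inter-item distances. Comparing in distance space (rather than
coordinate space) makes the residuals invariant to rotation, reflection
and translation of the arrangements, so no Procrustes alignment is
needed.

The scale of an RDM is unidentifiable from zoomed arrangements, so both
estimators return estimates normalized to unit RMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import pdist
from sklearn.manifold import smacof

from .core import (
    RDM,
    Arrangement,
    DegenerateRDMError,
    ItemSet,
    normalize_rdm,
    disparity,
)

__all__ = [
    "EstimationResult",
    "mds_embed",
    "align_scale",
    "weighted_average_estimate",
    "inverse_mds_estimate",
    "prediction_error",
]


@dataclass
class EstimationResult:
    """Outcome of an RDM estimation run.

    ``estimate`` is normalized to unit RMS over its defined entries.
    ``prediction_error_trace`` holds, per iteration, the RMS residual
    between predicted and actual arrangement distances of the best
    estimate found so far (hence non-increasing); for the weighted-average
    estimator it holds the per-iteration maximum entry change instead.
    ``disparity_trace`` is populated when a ground-truth RDM is supplied.
    """

    estimate: RDM
    prediction_error_trace: list = field(default_factory=list)
    disparity_trace: list | None = None
    converged: bool = False
    iterations: int = 0


# ---------------------------------------------------------------------
# Forward MDS (metric stress)
# ---------------------------------------------------------------------

def _classical_scaling(d: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson classical scaling: deterministic initial configuration."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:dims]
    lam = np.clip(w[order], 0.0, None)
    x = v[:, order] * np.sqrt(lam)
    if x.shape[1] < dims:
        x = np.hstack([x, np.zeros((n, dims - x.shape[1]))])
    return x


def _stress_and_grad(x_flat: np.ndarray, d: np.ndarray, n: int, dims: int):
    x = x_flat.reshape(n, dims)
    diff = x[:, None, :] - x[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    resid = dist - d
    np.fill_diagonal(resid, 0.0)
    stress = 0.5 * float(np.sum(resid**2)) / 2.0  # each pair once
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = np.where(dist > 0, resid / dist, 0.0)
    grad = np.einsum("ij,ijk->ik", coef, diff)
    return stress, grad.ravel()


def mds_embed(
    rdm: RDM,
    dims: int = 2,
    seed: int = 0,
    n_restarts: int = 0,
    max_iter: int = 50,
) -> np.ndarray:
    """Embed a fully defined RDM by metric-stress MDS.

    SMACOF majorization initialized from classical scaling — deterministic
    for a given input — followed by a quasi-Newton polish of the raw
    metric stress sum_{i<j} (d_ij - ||x_i - x_j||)^2, which drives the
    configuration to high precision. ``n_restarts`` adds seeded random
    restarts for hard instances, keeping the minimum-stress solution
    (ties resolved in favour of the earliest).

    Returns (n, dims) coordinates centered on the origin.
    """
    if not rdm.is_full:
        raise ValueError("mds_embed requires a fully defined RDM")
    n = rdm.n
    if n < 2:
        raise ValueError("need at least 2 items to embed")
    if dims < 1:
        raise ValueError("dims must be >= 1")
    d = rdm.values

    inits = [_classical_scaling(d, dims)]
    if n_restarts:
        rng = np.random.default_rng(seed)
        scale = max(float(d.max()), 1e-12)
        for _ in range(int(n_restarts)):
            inits.append(rng.normal(scale=scale, size=(n, dims)))

    best_x, best_stress = None, np.inf
    for x0 in inits:
        x, _ = smacof(
            d,
            metric=True,
            n_components=dims,
            init=x0,
            n_init=1,
            max_iter=max_iter,
            eps=1e-12,
            normalized_stress=False,
        )
        res = minimize(
            _stress_and_grad,
            x.ravel(),
            args=(d, n, dims),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-17, "gtol": 1e-12},
        )
        if res.fun < best_stress - 1e-15:
            best_stress = res.fun
            best_x = res.x.reshape(n, dims)
    best_x = best_x - best_x.mean(axis=0)
    return best_x


# ---------------------------------------------------------------------
# Scaled-to-match weighted averaging
# ---------------------------------------------------------------------

def align_scale(partial, reference, weights=None) -> float:
    """Weighted least-squares scale factor mapping ``partial`` onto ``reference``.

    Accepts either two RDMs (compared over pairs defined in both) or two
    flat arrays of matched pair values. Returns the c minimizing
    sum w (c*p - r)^2, i.e. c = sum(w p r) / sum(w p^2).
    """
    if isinstance(partial, RDM) and isinstance(reference, RDM):
        if partial.items != reference.items:
            raise ValueError("RDMs must share the same ItemSet")
        common = partial.upper_defined() & reference.upper_defined()
        if not np.any(common):
            raise ValueError("no common defined pairs")
        p = partial.upper_values()[common]
        r = reference.upper_values()[common]
        w = np.ones_like(p) if weights is None else np.asarray(weights, float)[common]
    else:
        p = np.asarray(partial, dtype=float)
        r = np.asarray(reference, dtype=float)
        w = np.ones_like(p) if weights is None else np.asarray(weights, float)
    denom = float(np.sum(w * p * p))
    if denom == 0.0:
        raise DegenerateRDMError("cannot scale an all-zero partial matrix")
    return float(np.sum(w * p * r) / denom)


def _trial_pair_table(trials, itemset: ItemSet):
    """Per-trial (pair-row-indices, distances, weights) in condensed indexing.

    Weights are the *relative* evidence weights (d / d_max)^2 within each
    trial: proportional to the trial evidence for a zoom-filled
    arrangement, but independent of the trial's overall scale, which
    keeps the estimators invariant to rescaling any single trial's
    coordinates.
    """
    from .design import trial_evidence_values

    n = itemset.n
    # map (i, j), i<j -> condensed row
    row = {}
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            row[(i, j)] = k
            k += 1
    tables = []
    for arr in trials:
        idx = [itemset.index(it) for it in arr.items]
        dists = arr.distances()
        weights = trial_evidence_values(arr)
        wmax = weights.max() if len(weights) else 0.0
        if wmax > 0:
            weights = weights / wmax
        rows = []
        m = len(idx)
        pos = 0
        for a in range(m):
            for b in range(a + 1, m):
                i, j = idx[a], idx[b]
                rows.append(row[(i, j)] if i < j else row[(j, i)])
                pos += 1
        tables.append((np.array(rows, dtype=int), dists, weights))
    return tables, k


def _unit_rms(x: np.ndarray) -> np.ndarray:
    rms = np.sqrt(np.mean(x * x))
    if rms == 0:
        raise DegenerateRDMError("all distances zero")
    return x / rms


def weighted_average_estimate(
    trials,
    items=None,
    ev_weights=None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> EstimationResult:
    """Scaled-to-match weighted average of the trials' distance matrices.

    The estimate is initialized as the unweighted average of the per-trial
    distance matrices, each first normalized to unit RMS over its own
    pairs (the aligned average). It is then refined by alternating
    (a) a per-trial least-squares rescale onto the current estimate and
    (b) an evidence-weighted per-pair average of the rescaled distances,
    renormalized to unit RMS, until the largest entry change falls below
    ``tol``.

    Per-pair weights default to the trial evidence weights (squared
    relative screen distance); ``ev_weights`` may supply one weight array
    per trial in the trial's own pair order. Pairs never presented
    together remain undefined in the returned estimate.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials supplied")
    if items is None:
        seen = []
        for arr in trials:
            for it in arr.items:
                if it not in seen:
                    seen.append(it)
        items = seen
    itemset = items if isinstance(items, ItemSet) else ItemSet(items)
    tables, n_pairs = _trial_pair_table(trials, itemset)
    if ev_weights is not None:
        tables = [
            (rows, dists, np.asarray(w, dtype=float))
            for (rows, dists, _), w in zip(tables, ev_weights)
        ]

    covered = np.zeros(n_pairs, dtype=bool)
    init_sum = np.zeros(n_pairs)
    init_cnt = np.zeros(n_pairs)
    for rows, dists, _ in tables:
        # A single-pair trial has no internal ratio information: its one
        # distance is taken at face value (normalizing it would erase the
        # judgment and break the reduction to pairwise judgments).
        nd = _unit_rms(dists) if len(dists) > 1 else dists
        covered[rows] = True
        init_sum[rows] += nd
        init_cnt[rows] += 1
    est = np.zeros(n_pairs)
    est[covered] = init_sum[covered] / init_cnt[covered]
    est[covered] = _unit_rms(est[covered])

    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        num = np.zeros(n_pairs)
        den = np.zeros(n_pairs)
        cnt_num = np.zeros(n_pairs)
        cnt = np.zeros(n_pairs)
        for rows, dists, w in tables:
            c = align_scale(dists, est[rows], w) if len(dists) > 1 else 1.0
            num[rows] += w * c * dists
            den[rows] += w
            cnt_num[rows] += c * dists
            cnt[rows] += 1
        new = est.copy()
        pos = covered & (den > 0)
        new[pos] = num[pos] / den[pos]
        zero_w = covered & (den == 0)  # coincident-only pairs: unweighted mean
        new[zero_w] = cnt_num[zero_w] / cnt[zero_w]
        new[covered] = _unit_rms(new[covered])
        change = float(np.max(np.abs(new - est))) if n_pairs else 0.0
        est = new
        trace.append(change)
        if change < tol:
            converged = True
            break

    n = itemset.n
    values = np.zeros((n, n))
    defined = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(defined, True)
    iu = np.triu_indices(n, k=1)
    values[iu] = est
    defined[iu] = covered
    values = values + values.T
    defined = defined | defined.T
    rdm = RDM(itemset, values, defined)
    return EstimationResult(
        estimate=rdm,
        prediction_error_trace=trace,
        converged=converged,
        iterations=it,
    )


# ---------------------------------------------------------------------
# Iterative inverse MDS
# ---------------------------------------------------------------------

def _trial_residuals(est: RDM, tables, trials, dims=2):
    """Residuals c_t * d_actual - d_predicted per trial, via MDS prediction."""
    out = []
    for (rows, dists, w), arr in zip(tables, trials):
        sub = est.restrict(arr.items)
        coords = mds_embed(sub, dims=dims)
        d_pred = pdist(coords)
        # Single-pair trials get no free scale (see weighted_average_estimate).
        denom = float(np.sum(w * dists * dists))
        if len(dists) > 1 and denom > 0:
            c = float(np.sum(w * dists * d_pred) / denom)
        else:
            c = 1.0
        out.append((rows, c * dists - d_pred, w))
    return out


def prediction_error(est: RDM, trials, items=None) -> float:
    """RMS residual between MDS-predicted and (rescaled) actual distances."""
    trials = list(trials)
    itemset = est.items if items is None else (
        items if isinstance(items, ItemSet) else ItemSet(items)
    )
    tables, _ = _trial_pair_table(trials, itemset)
    resid = np.concatenate(
        [r for _, r, _ in _trial_residuals(est, tables, trials)]
    )
    return float(np.sqrt(np.mean(resid * resid)))


def inverse_mds_estimate(
    trials,
    items=None,
    init: RDM | None = None,
    eta: float = 0.3,
    tol: float = 1e-10,
    max_iter: int = 500,
    truth: RDM | None = None,
    abs_tol: float = 1e-12,
) -> EstimationResult:
    """Iteratively adjust the RDM estimate to fit the arrangements.

    Each iteration predicts every trial's arrangement by 2D metric-stress
    MDS of the current estimate restricted to the trial's subset, rescales
    the actual distances onto the prediction by least squares, and nudges
    each estimated dissimilarity by ``eta`` times the evidence-weighted
    mean residual, clamping at zero and renormalizing to unit RMS. The
    best estimate seen (lowest RMS residual) is retained; iteration stops
    when the best error improves by less than ``tol``, drops below
    ``abs_tol``, or ``max_iter`` is reached.

    ``init`` defaults to the scaled-to-match weighted average of the same
    trials and must be fully defined. When ``truth`` is given, the
    disparity of the current estimate to it is recorded per iteration.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    trials = list(trials)
    if not trials:
        raise ValueError("no trials supplied")
    if init is None:
        init = weighted_average_estimate(trials, items).estimate
    if not init.is_full:
        missing = [
            (init.items[i], init.items[j])
            for i, j in zip(*init.triu_indices())
            if not init.defined[i, j]
        ]
        raise ValueError(
            f"initial estimate has undefined entries: {missing}"
        )
    itemset = init.items if items is None else (
        items if isinstance(items, ItemSet) else ItemSet(items)
    )
    if itemset != init.items:
        raise ValueError("init ItemSet does not match items")
    tables, n_pairs = _trial_pair_table(trials, itemset)
    iu = np.triu_indices(itemset.n, k=1)

    est = normalize_rdm(init)
    best_est = est.copy()
    best_err = np.inf
    trace: list[float] = []
    disp_trace: list[float] | None = [] if truth is not None else None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resids = _trial_residuals(est, tables, trials)
        all_r = np.concatenate([r for _, r, _ in resids])
        err = float(np.sqrt(np.mean(all_r * all_r)))
        if err < best_err:
            best_err = err
            best_est = est.copy()
        trace.append(best_err)
        if disp_trace is not None:
            disp_trace.append(disparity(est, truth))
        if best_err <= abs_tol:
            converged = True
            break
        if it >= 2 and trace[-2] - trace[-1] < tol:
            converged = True
            break
        # damped additive update of the covered pairs
        num = np.zeros(n_pairs)
        den = np.zeros(n_pairs)
        cnt_num = np.zeros(n_pairs)
        cnt = np.zeros(n_pairs)
        for rows, r, w in resids:
            num[rows] += w * r
            den[rows] += w
            cnt_num[rows] += r
            cnt[rows] += 1
        upper = est.values[iu].copy()
        pos = den > 0
        upper[pos] += eta * num[pos] / den[pos]
        zero_w = (den == 0) & (cnt > 0)
        upper[zero_w] += eta * cnt_num[zero_w] / cnt[zero_w]
        upper = np.clip(upper, 0.0, None)
        values = np.zeros_like(est.values)
        values[iu] = upper
        values = values + values.T
        est = normalize_rdm(est.with_values(values))

    return EstimationResult(
        estimate=normalize_rdm(best_est),
        prediction_error_trace=trace,
        disparity_trace=disp_trace,
        converged=converged,
        iterations=it,
    )
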