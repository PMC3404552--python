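# Methods

## The measurement model

A subject's perceived dissimilarities among `n` items are modelled as a
representational dissimilarity matrix (RDM): symmetric, non-negative,
zero diagonal. In a multi-arrangement session the subject arranges item
subsets in a 2D circular arena; within a trial, on-screen distance
ratios are taken to reflect dissimilarity ratios, but the absolute scale
of each trial is meaningless because the subject zooms every subset to
fill the arena. Consequently:

- each trial `t` with subset `S_t` yields a *partial* distance matrix
  `d_t(i,j)`, `i,j ∈ S_t`, known only up to a trial-specific factor;
- the overall scale of the RDM is unidentifiable, so every estimate is
  reported normalized to unit root-mean-square (RMS) over its defined
  upper-triangle entries.

Placement error is modelled (in the simulator, and implicitly in the
evidence bookkeeping) as independent isotropic 2D Gaussian jitter of
each icon. Under that model the signal-to-noise ratio of a pair's
measured distance grows with its screen distance, which motivates both
the evidence weights and the adaptive design below.

## Evidence and the lift-the-weakest designer

Each trial contributes, for every pair it contains,

    w(i,j) = (d_screen(i,j) / arena_diameter)²,

accumulated across trials in an evidence matrix. Evidence is converted
to a saturating utility

    u(w) = (min(w, T) / T)^(1/e),

with threshold `T` (default 0.5) and exponent `e` (default 10). With
`e = 10` the utility rises very steeply from zero and is flat above `T`:
nearly all attainable utility lies with the weakest pairs, which is what
gives the designer its lift-the-weakest character.

The next subset is chosen greedily:

1. trial 1 presents all items (it yields a complete, if 2D-limited,
   initial estimate);
2. if all pairs have evidence ≥ `T`, the session terminates;
3. otherwise the subset `S` is seeded with the minimum-evidence pair
   (ties broken lexicographically, so the designer is deterministic
   without a seed) and repeatedly extended by the item that maximizes
   expected-utility-gain per cost, where the expected evidence gain of
   pair `(i,j) ∈ S` is `(est(i,j) / max_{(a,b)∈S} est(a,b))²` — the
   zooming assumption: the widest pair of the presented subset will span
   the arena — and `cost(S) = cost_offset + cost_per_item·|S|`. Growth
   stops when the best single-item addition no longer improves the
   benefit/cost ratio, subject to `min_subset ≤ |S| ≤ max_subset`
   (defaults 3 and `n`).

The expected-gain model deliberately ignores MDS distortion of the
upcoming arrangement; simulating the expected arrangement inside the
designer is out of scope here.

Parameters, with units and defaults:

| parameter | default | meaning |
|---|---|---|
| `evidence_threshold` | 0.5 | cumulative squared relative distance at which a pair counts as measured |
| `utility_exponent` | 10 | steepness of the saturating utility |
| `min_subset` / `max_subset` | 3 / n | subset-size bounds (a 2-item trial degenerates to a pairwise judgment and is wasteful) |
| `cost_per_item`, `cost_offset` | 1.0, 1.0 | linear trial-time model, arbitrary common units |

## Estimators

**Scaled-to-match weighted average.** Initialization: the unweighted
mean of the per-trial distance matrices, each normalized to unit RMS
over its own pairs, missing entries ignored (the "aligned average").
Refinement alternates, until the largest entry change is < 1e-8 (at most
100 iterations):

1. per-trial scale `c_t = Σ w·d_t·r / Σ w·d_t²` (weighted least squares
   of the trial's distances `d_t` onto the current estimate `r`);
2. per-pair update `est(i,j) = Σ_t w_t c_t d_t(i,j) / Σ_t w_t` over the
   trials containing the pair;
3. renormalization to unit RMS.

**Iterative inverse MDS.** Starting from the aligned average (or any
fully defined initial RDM), each iteration:

1. predicts every trial's arrangement by 2D metric-stress MDS of the
   current estimate restricted to the trial's subset;
2. rescales the trial's actual distances onto the predicted ones by
   least squares (the residuals are computed in *distance* space, which
   is invariant to rotation, reflection and translation, so no
   Procrustes alignment is needed);
3. updates each entry by a damped additive step,
   `est ← max(0, est + η · Σ_t w_t r_t / Σ_t w_t)` with step size
   `η = 0.3`, clamping at zero and renormalizing to unit RMS;
4. records the RMS of all residuals and keeps the best estimate seen.

The raw per-iteration error may fluctuate (the procedure is a local
heuristic with no convergence guarantee), so the reported trace is the
best-so-far error, which is non-increasing by construction. Iteration
stops when that trace improves by less than `tol` (default 1e-10),
falls below 1e-12, or `max_iter` (default 500) is reached.

**Per-pair weights.** Both estimators weight a pair's contribution from
trial `t` by the *relative* evidence `(d_t(i,j)/max d_t)²`. For
zoom-filled arrangements this equals the raw evidence weight up to one
constant shared by all trials; using the relative form in the estimators
makes them exactly invariant to rescaling any single trial's
coordinates, which is the correct behaviour when only distance ratios
are informative.

**Single-pair trials.** A trial containing exactly one pair carries no
internal ratio information: a free per-trial scale would fit its one
distance perfectly and erase the judgment. Such trials are therefore
taken at face value (`c_t = 1`, no per-trial normalization), which is
precisely how classical pairwise judgments record distances on a common
axis. This is what makes the method reduce to pairwise dissimilarity
judgments when every arrangement contains two items. A mixed log of
zoomed multi-item trials and raw single-pair trials assumes the
single-pair distances share one scale; if they do not, their
contributions are biased — a known limitation.

## Forward MDS

`mds_embed` minimizes raw metric stress `Σ_{i<j} (d_ij − ‖x_i − x_j‖)²`
by SMACOF majorization (scikit-learn) initialized from Torgerson
classical scaling, followed by an L-BFGS polish of the same objective to
bring the configuration to near machine precision — the inverse-MDS
fixed point tests require predicted distances accurate to ~1e-8. The
default is fully deterministic (no random restarts); classical-scaling
initialization can occasionally settle in a local stress minimum
slightly above the global one, and an `n_restarts` option with seeded
random initializations is available for hard instances (minimum stress
wins, first found on ties). The SMACOF stage runs at most 50 iterations;
the quasi-Newton polish reaches the same stationary stress as longer
majorization runs at a fraction of the cost.

## The simulated subject

`simulate_arrangement` embeds the ground-truth sub-RDM in 2D by
`mds_embed`, rescales so the maximum inter-icon distance is 0.95 of the
arena diameter (zoom-to-fill; the 5% margin keeps the widest pair just
inside the rim — note the *vertices* of wide configurations such as an
equilateral triangle can still protrude slightly beyond the circular
boundary, which mirrors real edge placements and is reported as a
warning when logs are read back), and adds optional isotropic Gaussian
jitter. The noise stream is derived from `(session seed, trial index)`,
so sessions are reproducible while trials stay independent.

What the simulator does *not* emulate: icon-overlap avoidance,
attention to local relationships, context-dependent dimension
re-weighting, non-Gaussian placement error, or any drift in the
subject's criterion. Passing closed-loop tests therefore demonstrates
that the estimation machinery recovers metric structure from zoomed 2D
projections of it — not that human arrangements satisfy these
assumptions.

## Comparison statistics

RDMs are compared by the Spearman correlation of their upper triangles
(average ranks on ties; undefined, and an error, for a constant RDM).
Significance uses the condition-label randomization test: item labels of
one RDM are permuted — rows and columns jointly — and the correlation
recomputed. The test is one-sided (a positive correspondence is the
hypothesis of interest). With sampling, `p = (1 + #{r_perm ≥ r_obs}) /
(1 + n_permutations)`, so p can never be zero; when `n!` does not exceed
the requested permutation count all relabelings are enumerated and
`p = #{r_perm ≥ r_obs}/n!` exactly (the identity is part of the null
set). No histogram equalization is applied before correlation: Spearman
is rank-based, so monotone equalization would not change it.

## Problem sizes used in the test suite

The closed-loop recovery study runs 20 simulated sessions with 8–12
items and 3-dimensional ground truths, noise-free, with the default
designer settings and inverse MDS capped at 100 iterations — enough for
the estimate to stabilize to ~3 decimal places of Spearman correlation
on these sizes. The randomization-calibration study uses 1000 null runs
of 12-item RDMs with 199 sampled permutations each. The four-item toy
problem runs with the library defaults.

## Known limitations

- Inverse MDS is a local method; with few trials the solution set
  consistent with the arrangements can be large, and the algorithm
  returns one point estimate biased toward its initialization.
- Only symmetric, context-independent dissimilarities are representable;
  intransitive or asymmetric judgment patterns are averaged over.
- Non-metric (rank-only) inverse MDS and explicit placement-error models
  are not implemented.
- The evidence model assumes constant on-screen placement error; if
  subjects place familiar clusters more precisely, evidence is
  miscalibrated.
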