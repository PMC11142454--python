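# Methods

This note documents the models implemented in `tnulls`, the conventions and
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Temporal graphs

A temporal graph is a stack of `T` undirected, simple binary adjacency
matrices over nodes `0..N−1`. Time and node indices are 0-based internally
(`t ∈ [0, T)`); the contact-list file format optionally reads and writes
1-based times, since published contact lists use both conventions. Graphs
are simple at every step: windowed Pearson matrices are symmetric and the
self-correlation diagonal is never an edge, so duplicate contacts collapse
silently on construction. The dense `(T, N, N)` uint8 tensor is the single
internal representation — at the scales this package targets (hundreds of
nodes, tens of snapshots) it is faster and simpler than sparse storage, and
semantic equality is what the API promises, not a representation.

## Measures

**Clustering.** `C(t)` is the transitivity of snapshot `t`: ordered closed
triplets `trace(A³)` over ordered triplets `Σ_i k_i(k_i−1)`. The mean of the
*local* clustering coefficients is also provided but is a different
statistic on degree-heterogeneous graphs (they coincide on regular graphs);
the transitivity form is the authoritative definition here, and the package
treats the equivalence only as an identity to test where it holds, not to
assume. Zero-denominator conventions: `C(t) = 0` when no node has degree
≥ 2, local clustering is 0 when `k_i < 2`, and a temporal-correlation
summand is 0 when the node is isolated at either of the two steps. These are
the conventional limits and make the small worked examples (star:
`TC = 1, C = 0`; alternating triplet: `TC = 0, C = 0.5`; hubs: 0, 1/3, 1)
exactly reproducible.

**Fastest temporal paths.** Travel starts at time 0; traversal at step `t`
uses the edges of snapshot `t`; at most one edge per step; waiting at a node
is free. `l_ij` is then the number of elapsed snapshots until `j` is first
reached, computed by vectorized layer expansion of reachable sets (verified
in tests against an exhaustive dynamic program over `(node, time)` states).
This is the unique reading under which identical snapshots recover classical
hop-count distances. Temporal reachability is time-directed, so `l_ij ≠ l_ji`
in general and `L` averages over ordered pairs. An unreachable pair scores
the maximum distance `T` by default; a `drop` mode excludes such pairs
instead, for users who prefer connectivity-conditional path lengths.

**Small-worldness.** `S = C/L` and `S_SB = TC/L`, both deliberately
unnormalized (no random-graph baseline in the ratio — the null models serve
that role). `S` is reported as 0 whenever `C = 0`.

## Null models

**RTPT (permuted times).** Default mode shuffles the timestamp multiset
uniformly across individual contacts. A uniform shuffle can propose the same
`(u, v, t)` twice; to keep the conservation guarantees exact (contact count,
per-pair multiplicity, timestamp multiset — and hence the average degree),
colliding timestamps are swapped with uniformly chosen partners until the
contact set is duplicate-free. A `snapshots` mode applies a single
permutation to the snapshot order instead, which conserves everything
trivially but only reorders whole time slices; both interpretations appear
in the literature, so both are shipped, with contact-level shuffling the
default because it is the one that actually destroys temporal structure.

**RTE (randomized edges).** One independent uniform permutation `σ_t` per
time step; contacts are stored with `u < v` and the second endpoint is
rewired, `(u, v, t) → (u, σ_t(v), t)`. Self-loops are dropped and duplicates
merged, so per-step edge counts never increase.

**RTS / RTT.** Positions i.i.d. uniform on `[0,1]²`; edge iff distance
`< r` — strict inequality throughout the package, a measure-zero choice for
continuous positions. Torus distance folds each axis to
`min(|Δ|, 1−|Δ|)`. Movement: direction uniform on `[0, 2π)`, length uniform
on `(0, v)`; the square reflects overshoots off the boundary (billiard
reflection, `x → 2−x` above 1 and `x → −x` below 0, applied periodically for
arbitrarily large steps), the torus wraps. Both updates preserve the uniform
positional marginal (tested by KS after 500 steps from a point mass).

**RTH.** Angular coordinate uniform; radial coordinate drawn by inverse-CDF
sampling from `ρ(r) = α sinh(αr) / (cosh(αR) − 1)` on `[0, R]`. Hyperbolic
distance in curvature `−ζ²`:
`d = (1/ζ)·acosh(cosh ζr_u cosh ζr_v − sinh ζr_u sinh ζr_v cos Δθ)` with the
angular difference `Δθ = π − |π − |θ_u − θ_v||` (the only symmetric,
2π-periodic form with range `[0, π]`); acosh arguments within a few ulp of 1
are clamped to distance 0. Edge iff `d < R`. Movement: the angle gains
`Uniform(0, v)` modulo 2π (a symmetric variant is available behind a flag;
rotation does not change the graph distribution either way); the radius is
updated in CDF space — `u = F(r)` is uniform on `[0, 1]`, a `Uniform(−v, v)`
increment is added and reflected back into `[0, 1]`, then `r = F⁻¹(u)`. The
CDF-space walk is the reading of "reflect in [0, 1] to keep the distribution
uniform" under which the stationarity guarantee is provable: reflected
random walks preserve the uniform law on the unit interval, so the radial
marginal is exactly `ρ(r)` at every step (tested by chi-square on
equiprobable bins after 500 steps with 10⁴ nodes).

**Curvature redundancy.** Rescaling `ζ → cζ`, `α → cα` maps
`RH(ζ, α, R)` onto `RH(1, α/ζ, ζR)`: only the ratio `α/ζ` matters once the
disk radius is stated in the `ζ = 1` metric (`R → R/c`). The default is
therefore `ζ = 1`, and the invariance is verified in the tests with the
radius rescaled accordingly — with `R` held fixed instead, doubling `(ζ, α)`
produces a very different (much sparser) ensemble.

**Randomness.** Every stochastic operation takes an explicit integer seed or
an already-spawned generator. A generator run consumes one stream in a fixed
order: initial positions first, then one movement draw per step, so runs are
bit-reproducible per seed.

## Signal-to-network pipeline

Stages, in order: OLS confound regression (intercept always included;
rank-deficient designs are rejected naming the collinear columns), zero-phase
band-pass, optional voxel-to-region label averaging, rectangular sliding
windows, windowed Pearson correlation, thresholding.

Defaults mirror resting-state practice: sampling interval TR = 0.72 s, band
0.01–0.08 Hz, windows of 60 s with 30 s overlap. Seconds convert to samples
by floor (windows never exceed the stated duration): at 1,200 samples this
gives 83-sample windows stepping by 41, i.e. 28 windows. The filter is an
order-4 Butterworth applied forward–backward (`sosfiltfilt`); the normative
contract is the response, not the family: pass-band attenuation < 3 dB,
attenuation > 20 dB at half the low cutoff and twice the high cutoff, zero
phase. Thresholding keeps `r > τ` strictly, for τ on the grid 0.20–0.90 in
steps of 0.05 plus 0.92–0.98 in steps of 0.02 (19 graphs); only positive
thresholds are used, since negative correlations have no agreed
interpretation as edges. Zero-variance regions inside a window get their
correlations set to 0 with a logged warning (the unit self-correlation is
kept so the tensor invariant holds).

## Synthetic BOLD generator

`simulate_bold` draws white Gaussian noise per region, band-passes it with
the same filter contract as the pipeline (so the pipeline's spectral
assumptions are exercised), standardizes, and mixes through the Cholesky
factor of a target correlation matrix with three levels: within-hemisphere
blocks at `ρ_within` (default 0.5), homotopic pairs `(i, i + N/2)` at
`ρ_homotopic` (default 0.35), and zero elsewhere. The defaults mirror the
qualitative structure of hemisphere-ordered resting-state correlation
matrices — strong intra-hemispheric blocks, a visible homotopic sub-diagonal
— at the standard dimensions (302 regions, 1,200 samples). Targets must
leave the matrix positive definite (roughly `ρ_within + ρ_homotopic < 1`).

What it does *not* emulate: hemodynamic response dynamics, spatial voxel
structure, scanner drift or motion artifacts, non-stationarity of the
correlation structure, and subject-to-subject variability. Passing tests
therefore demonstrate that the pipeline and measures behave correctly on
signals with the right second-order and spectral structure, not that the
package reproduces any particular empirical dataset.

## Degree calibration and curve fitting

Small-worldness curves are `(average degree, statistic)` knot sequences with
linear interpolation and no extrapolation. Curve discrepancy is summarized
by the exact area between the two piecewise-linear curves (segment-wise
integration, splitting segments at sign changes) and by four norms of the
pointwise difference on an equispaced grid, by default 16,861 points on
[0, 170]: minimum, maximum, mean absolute, and the mean Euclidean distance
`‖d‖₂ / n`. The last is a scaled (not RMS) norm — the convention inferred
from the reported magnitudes in this literature, where the mean Euclidean
value is orders of magnitude below the mean absolute value; an RMS variant
(`‖d‖₂ / √n`) is available as an option.

**Calibration.** Because every movement rule is stationary, the expected
average degree is independent of the speed `v` and monotone in the
connection radius (increasing in `r`, decreasing in `R`). The radius for a
target degree is found by bisection on a Monte-Carlo estimate of the
expected degree (12 replicate generations of 6 snapshots each, relative
tolerance 0.5%, at most 40 bisections). The estimate uses common random
numbers — the same replicate seeds at every radius, from a fixed calibration
stream — which makes the estimated degree a deterministic monotone function
of the radius and makes calibrated radii identical across all sweeps that
share a model, node count and radial spread; calibrations are memoized on
exactly that key. Without this, calibration noise (realized degrees off by
several percent) dominates the differences between the curves being
compared.

**Sweeps and fits.** `sweep_curve` generates `replicates` graphs per
calibrated degree and records the median statistic (plus quartiles, as the
spread band). `fit_parameters` grid-searches the free parameters, scoring
each candidate by the area between its sweep curve and the empirical curve;
ties break by smaller mean absolute difference, then lexicographic parameter
order. All candidates share the same replicate seeds, so candidate-to-
candidate differences are systematic rather than sampling noise. The
parameter-recovery test extends this pairing to the reference curve itself
(the candidate sweeps reuse the reference sweep's seed): a deliberate
paired-simulation design, because the S-statistic is nearly flat in `v` once
the CDF-space radial walk mixes fast (empirically, for `v ≳ 0.4` the
S-curves at `N = 100` differ by ~0.003 while an unpaired 10-replicate median
curve has seed-to-seed noise of the same size — `v` is simply not
identifiable from `S` at desk scale under independent noise, though it is
strongly identifiable from `S_SB`, which depends on neighbourhood
persistence). `SmallWorldnessFit` wraps this in a model/results interface:
construct with the empirical curve, call `fit(parameter_grid)`, read the
returned `FitResult.summary()`.

**Problem sizes.** The package's own test and demonstration scale is
`N ≈ 100–302` nodes, `T ≈ 28` snapshots, tens of replicates — chosen as the
scale at which a single analyst explores these models interactively; the
sweep and fit machinery accepts arbitrary sizes.

## Known limitations

- Measures operate on binary undirected graphs only; weighted or directed
  temporal measures are out of scope (thresholding happens upstream).
- Dense snapshot tensors bound the practical size to a few thousand nodes.
- The fitting module's grid search reports no uncertainty on fitted
  parameters; the replicate quartile bands on sweep curves are the only
  spread information carried through.
- Atlas handling of real imaging volumes (NIfTI/CIFTI parcellation) is not
  included; the pipeline starts from region-level series or voxel matrices
  with precomputed integer labels.
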