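# Methods

This note records the models implemented, the estimator and parameter
choices that were genuinely open, and what the synthetic studies do and do
not demonstrate.

## Candidate processes

**Fractional Brownian motion.** Gaussian, self-similar, covariance
R(s,t) = (σ²/2)(s^{2H} + t^{2H} − |t−s|^{2H}), H ∈ (0,1). Simulated
*exactly*: the fractional-Gaussian-noise autocovariance is embedded in a
circulant matrix (Davies–Harte) and sampled by FFT; if the embedding
spectrum were ever negative the generator falls back to the
Durbin–Levinson (Hosking) recursion, which is exact at O(n²). Exactness
here anchors every downstream recovery study — the FBM generator is the
oracle the other components are checked against. Default σ = 1, dt = 1
(arbitrary units; only exponents matter downstream).

**α-stable variates.** Chambers–Mallows–Stuck transform in the S1
parameterization: a uniform angle and an exponential variate map to a
standard stable draw; α = 2 reduces to N(0, 2·scale²), α = 1/skew = 0 to
Cauchy. Tests check the Gaussian limit, Cauchy quantiles against scipy's
closed form, and the tail index by survival regression on 10⁶ draws.

**Fractional Lévy α-stable motion.** Moving-average discretization:
increments are the convolution of i.i.d. stable innovations with the
kernel c_j = (j+1)^d − j^d, d = H − 1/α. Two numerical choices:

* *Truncation.* The kernel is cut at 4× the simulated grid length.
* *Normalization.* Innovation scale is chosen so that the end point X(T)
  is **exactly** stable with scale σ·T^H (the weight of each innovation in
  X(T) is a window sum of the kernel, so the aggregate scale is available
  in closed form). At α = 2 the end-point law therefore coincides exactly
  with the FBM generator's, which is what the two-sample KS consistency
  check exercises.
* *Oversampling.* The Riemann scheme is run on a grid 4× finer than the
  output grid and micro-increments are aggregated per output step. Without
  this the small-lag increments are too weakly correlated and the fitted
  sample-MSD slope at H = 0.7 lands ≈ 0.07 below 2H; with 4× oversampling
  the residual deficit is ≈ 0.02–0.03 (measured against the exact FBM
  generator under the identical fitting protocol). The refinement is a
  documented accuracy/cost trade-off (`oversample` parameter).

**Continuous-time random walk.** Waiting times are Pareto:
ψ(t) = β τ0^β t^{−(1+β)} for t ≥ τ0, so the survival tail is
(t/τ0)^{−β} and, for β ∈ (0,1), the mean wait is infinite. (Two
conventions exist for the exponent symbol in this family — PDF exponent
1+β vs survival exponent β; this package fixes β as the survival/tail
exponent, which is also the ensemble subdiffusion exponent.) Jumps are
i.i.d. stable (Gaussian by default); the walk is rendered on a uniform
grid by last observation carried forward — piecewise constancy is the
physical picture of trapping, so no interpolation is ever applied. True
jump times are kept in the path metadata. Defaults τ0 = 1 = grid step: one
natural trapping time per observation frame.

## Observables

Radius of gyration is the root-mean-square distance of (atom-uniform,
unweighted) selected atoms from their center; mass weighting is available
but off by default. Two MSD estimators are implemented and every report
row names the one used: *fixed-origin* (displacement from frame 0,
averaged over atoms — the convention for trajectory curves) and
*time-averaged* (sliding origin — the convention that matches the
sample-MSD statistic). Coordinates are Cartesian with no periodic-boundary
handling; minimum-image artifacts in wrapped trajectories are the caller's
responsibility (documented limitation).

## Sample-MSD test

M_N(τ) is evaluated exactly with denominator N − τ + 1. The fit is OLS of
ln M on ln τ over the first 20 lags (10 for short scalar observable
series) — the statistic's derivation assumes τ ≪ N, so only the smallest
lags carry the signal. The decision rule is a normal-theory confidence
interval on the slope (default 95%): CI ∋ 1 ⇒ CTRW not rejected, otherwise
the slope is read through τ^{2d+1} giving d̂ = (α−1)/2 and
Ĥ = d̂ + 1/α_stable. Fits with R² < 0.9 are inconclusive (the floor is a
package choice; "log-linear" is otherwise unquantified). The regression SE
understates trajectory-to-trajectory spread, so simulation studies report
across-seed dispersion as well. Zero curve values cannot enter the log
fit: leading ones are skipped and counted, interior ones are an error
naming the lag.

## p-variation test

The series is truncated *from the end* to the largest dyadic length
2^m + 1 (padding would fabricate increments); level n uses increments of
span 2^{m−n}, so n = 0 is the coarsest view and n = m the finest. Verdict
heuristics (the diagnostic literature gives no numeric rule, so these are
package constructions, exposed as configuration):

* *step-dominated* (CTRW-like): fraction of exactly-flat path increments
  at the finest level > 0.5;
* *FBM/FLSM-like*: the p = 1/Ĥ profile is level-stable
  (|Spearman ρ| ≤ 0.8 across levels) while p = 2 trends (|ρ| > 0.8);
* otherwise inconclusive.

The trend statistic uses only levels with ≥ 8 increments (n ≥ 3): coarser
levels are one-to-four draws and carry no rank information. Because
V_p^n(T) values are strongly correlated across levels, the rank
correlation is a noisy statistic — on H = 0.35 FBM paths of length 2^12
the heuristic alone returns the FBM verdict in roughly three quarters of
seeds and inconclusive otherwise. This is why the *combined* classifier
(pipeline) orders the rules: step-dominance decides CTRW first (trapping
is visible directly and almost never occurs for FBM), then the slope CI,
then the p-variation trend as a tie-break. At H exactly 0.5 both profiles
are level-stable and the heuristic is inconclusive by construction; the
slope rule handles that boundary.

## Synthetic studies and their scope

The bead-chain generator builds either straight parallel chains (spacing
`chain_spacing`, an inter-molecular network) or self-avoiding random-walk
coils (fixed bond length, 0.9×bond overlap floor, backtracking on dead
ends — an intra-molecular network) and advances every bead coordinate
independently under a chosen mechanism. It reproduces the *statistical*
situation — known ground-truth mechanism per bead, chain labels, both
initial geometries — not polymer physics: there are no bonds during the
dynamics, no excluded volume after frame 0, no solvent, no chemistry.
Passing recovery tests therefore validates the inference chain, not any
claim about real biopolymer networks.

Study sizes (package defaults, chosen to make Monte-Carlo error small
relative to the tolerances they are compared against): FBM recovery — 50
paths of N = 4096 per H; CTRW — 100 paths for the single-trajectory
median, 500 for the ensemble MSD (single-path statistics need no large
ensemble; the ensemble mean does); discrimination — 100 + 100 paths of
length 2^12; FLSM/FBM consistency — 500 end points for the KS test, 50
paths for the slope.

**Known finite-time effect.** The CTRW ensemble exponent converges to β
slowly: the renewal function's subleading correction decays as t^{β−1},
so for β = 0.9 the measurable local slope at T = 4096 (τ0 = 1) is ≈ 0.83,
not 0.9 — a property of the process, not the estimator. The ensemble fit
window is the upper decade t ∈ [T/16, T] (15 log-spaced points), the best
bias/variance compromise measured across independent replications;
expect the β = 0.9 estimate to sit near the lower edge of a ±0.1 band.

## Determinism

Every generator consumes a single integer seed through
`numpy.random.default_rng`/`SeedSequence` with no global state; composite
operations spawn child seeds. Reports echo the fully resolved
configuration (including realized per-case seeds), and re-running from
the echo byte-reproduces all tables.
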