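# Methods

## Scheme design

**Electrostatic repulsion (EEM).** Direction sets are optimized under the
bipolar electrostatic model: each unit direction u and its antipode −u act
as point charges, and the energy Σ_{i<j} (1/‖uᵢ−uⱼ‖ + 1/‖uᵢ+uⱼ‖) is
minimized. For a multi-shell scheme the objective is the sum of per-shell
energies plus a coupling term — the energy of the union of all shells —
weighted 0.5, balancing per-shell uniformity against whole-scheme
uniformity. Optimization is L-BFGS on unnormalized direction vectors
(analytic gradient, normalization inside the objective) from seeded random
starts; 20 restarts are kept by default and the lowest-energy solution
wins. The optimizer routinely recovers the icosahedral-axes optimum for 6
directions (covering radius ≥ 60°) and beats the best of 100 random
configurations at 60 directions.

**Interruption-robust ordering.** Volumes are ordered greedily: at each
step the shell whose prefix count most lags its full-scheme proportion
(32:60) is chosen — ties to the lower shell — and within that shell the
direction that adds the least weighted bipolar energy to the prefix is
appended, ties to the lowest original index. The 8 b = 0 volumes are
interleaved evenly with one at the very start. Every prefix therefore
keeps per-shell counts within ±1 of proportionality; truncating the
ordered scheme is the Opt_EEM subsampling strategy.

**Spherical-codes subsampling (Opt_SC).** Subsets maximize
0.5 × (mean per-shell covering radius) + 0.5 × (union covering radius),
where the covering radius of a set is its minimum pairwise line-angle
min arccos|uᵢ·uⱼ|. The search is greedy removal (each removal the one that
maximizes the objective) followed by first-improvement kept↔dropped
exchanges within each shell until a local optimum; ties keep the lowest
original acquisition index, making the procedure deterministic. On a
choose-8-of-16 instance the result matches or beats the best of 1000
random subsets and is verified against exhaustive enumeration. Subset
levels are built sequentially — each level from the previous one — so the
chain full → 95% → … → 50% is nested, mirroring an acquisition stopped at
successively earlier points. The referenced mixed-integer formulation
would guarantee global optima; greedy + exchange was chosen because it is
deterministic, dependency-free, and oracle-checkable at small sizes.

**Random truncation (Random_TRUNC).** The entire scheme — b = 0 volumes
included — is shuffled once with a seeded RNG and truncated to the same
total volume count as the corresponding optimized subset. Per-shell
balance and the number of surviving b = 0 volumes are left to chance
(about 4 of 8 at 50% truncation). This models stopping an acquisition
whose ordering was never optimized and is the reference the optimized
strategies are compared against. One shuffle serves all truncation
levels, so random subsets are nested too.

**Subset sizes.** Retained per-shell counts are round-half-up of
fraction × count; a shell below 6 directions is refused. For (32, 60)
directions and fractions 0.95…0.5 this yields (30, 57), (29, 54),
(26, 48), (22, 42), (19, 36), (16, 30).

## Signal model

The substrate is the 60°-crossing two-fiber voxel described in the README.
By default signals are generated from the DKI representation itself:
D(n) = nᵀD̄n and K(n) from the mixture formula, inserted into
ln S = ln S₀ − b·D(n) + (b²/6)·D(n)²·K(n). Because D(n)²·K(n) is exactly a
quartic form in n, these signals lie exactly in the 22-parameter DKI model
space, and noise-free fits recover the ground truth to machine precision —
which is what makes the very-high-SNR convergence check meaningful. A
`model="mixture"` option generates the raw multi-exponential signal
Σ fₖ exp(−b·nᵀDₖn) instead; at b = 2000 s/mm² its un-truncated higher
cumulants bias a DKI fit (MK −13% on the full scheme), which is a property
of the representation, not of the estimator, and is deliberately excluded
from the truncation study.

**Noise.** Rician: S ← √((S+ε₁)² + ε₂²), ε ~ N(0, σ²), σ = S₀/SNR with
SNR defined on b = 0 (S₀ = 1). Each simulation instance draws one pair of
quadrature noise fields for the full 100-volume scheme; every subset
extracts its volumes from that same realization (as truncating a real scan
would), making subset-versus-full comparisons paired, and the same fields
are scaled to produce all SNR levels.

**Orientations.** Substrate orientations are uniform random rotations
(uniform quaternions), both fibers rotated together so the crossing angle
is preserved. The study default is 100 orientations × 100 noise draws
(10,000 instances); all seeds derive deterministically from one master
seed keyed by purpose, orientation and noise index, so results are
bit-reproducible and independent of execution order.

## Estimation

**Design.** Per volume, ln S is linear in 22 coefficients: ln S₀, the 6
diffusion-tensor components (multiplicities 1/2), and 15 kurtosis-block
coefficients with multiplicities (1, 4, 6, 12). The kurtosis block stores
MD²·W directly so the regression stays linear; W is recovered at
metric-derivation time by dividing by the fitted MD².

**Weighted least squares.** Signals are floored at 10⁻¹⁰·S₀, logged, and
fit by OLS; predicted-signal-squared weights from that pass feed one WLS
re-solve (the standard correction for log-transformed magnitude noise).

**Positivity-constrained fit.** The simulation pipeline's default fit
minimizes the same WLS objective subject to K_app(n) ≥ 0 — equivalently a
non-negative quartic form in the kurtosis block, a linear constraint — on
every acquired diffusion direction plus a 60-point quasi-uniform sphere
(our reading of restricting *all* directional kurtosis; pass
`n_sphere=0` for acquired-directions-only). The QP is convex and is
solved exactly: Cholesky whitening reduces it to a least-distance problem,
whose dual is a non-negative least-squares problem solved by
Lawson–Hanson NNLS. Fits where no constraint binds equal the WLS solution
identically; fits with active constraints are flagged. No upper kurtosis
bound and no D_app ≥ 0 constraint are imposed. Batched fitting vectorizes
the OLS/WLS passes across instances and only routes constraint violators
through the QP.

## Scalar metrics

FA, MD, AD, RD come from the eigenvalues of the fitted tensor
(λ₁ ≥ λ₂ ≥ λ₃; AD = λ₁, RD = (λ₂+λ₃)/2, FA = √(3/2)·‖λ−λ̄‖/‖λ‖). MK is
the mean of K_app over a 10,000-point Fibonacci sphere (numerical
averaging instead of the closed-form elliptic integrals: simpler, and
directly checkable against brute-force oracles; 10,242 vs 40,962 points
differ by < 0.1%). AK evaluates K_app along the principal eigenvector; RK
averages it over 36 evenly spaced directions in the perpendicular plane
(the in-plane profile has low harmonic content, so 36 points are
effectively exact). Apparent diffusivities are floored at 10⁻⁶ mm²/s when
evaluating K_app so that pathological noisy fits stay finite; kurtosis
medians are reported unclipped so noise-floor biases remain visible.

## Evaluation pipeline and error definition

For every cell (method × fraction × SNR) the seven parameter medians and
interquartile ranges are aggregated over all instances, and the relative
error is the difference of paired medians,
100·|median_subset − median_full| / median_full, with the signed variant
retained in the export. Difference-of-medians was chosen (over medians of
per-instance errors) because the subsets physically share the full
dataset's noise, and because per-instance absolute errors conflate
variance with bias. Cells with more than 1% failed fits are flagged but
the run continues; a zero full-data median flags the cell and yields NaN
errors. Exports are tidy CSVs (medians, IQRs, relative errors) with
6-significant-digit formatting so re-reading and re-writing is
byte-identical, plus a JSON manifest of the configuration and seeds.

**Problem sizes.** The headline SNR-20 comparison runs at the full
100 × 100 replication. The all-methods × all-fractions × SNR 10–50
factorial is run at 20 × 20 replication (400 instances per cell), which
keeps a full sweep to a few minutes on one core; at that replication the
Monte-Carlo scatter of a cell's relative error is roughly ±1–1.5
percentage points, which is also the tolerance used when comparing against
published values.

## Histogram summaries

Any scalar value collection (simulation estimates, or masked NIfTI maps
via `values_from_nifti`) is summarized by a 1000-bin equal-width histogram
over [min, max], normalized to unit integral: the summary reports the
median, the height and center of the tallest bin (ties to the lowest bin),
and the peak width p95 − p5 (linear-interpolated percentiles). The
percentile-based width is independent of binning; the peak location is
only meaningful for unimodal data — near-tied bins make it jump, which is
why its equivariance is only guaranteed up to one bin width.

## What the synthetic data does and does not show

The generator emulates a single representative white-matter voxel with
fixed compartments, no exchange, no dispersion, no free water, and perfect
gradient directions; passing tests therefore demonstrate properties of
the estimator and of the sampling schemes, not of full in-vivo pipelines
(registration, denoising, skeletonization are out of scope). Two
limitations found in this study are worth noting. First, the relative
error of the *random* strategy depends strongly on the single shuffle
realization (across shuffles, MD errors at SNR 20/50% span roughly 2–4%),
so single-realization comparisons against it inherit that spread. Second,
AK is the least robust parameter in relative terms: its reference value in
a 60°-crossing voxel is small (≈ 0.12) because the principal axis sits at
the directional-kurtosis minimum between the fibers, and orientation
noise in the fitted axis plus positivity clipping inflate subset medians —
relative AK errors reach ~35% where RK stays below ~25%. Radial and mean
kurtosis remain the practically relevant stability indicators.
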