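# Methods

This note records the models behind `gfadwi`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the
numerical conventions a user relying on the outputs should know.

## Signal model and phantoms

Each phantom voxel contains one or more Gaussian diffusion compartments
and follows the multi-tensor forward model

    S(g, b) = S0 * sum_k f_k * exp(-b * g^T D_k g),    sum_k f_k = 1,

with D_k built from eigenvalues (λ1 ≥ λ2 ≥ λ3, mm²/s) and a principal
direction.  Single fibers default to (1.7, 0.2, 0.2)·10⁻³ mm²/s —
canonical healthy white-matter diffusivities.  Crossing-fiber voxels are
two equal-fraction perpendicular copies of that tensor.  Background
voxels follow the free-water limit: full signal at b0 and complete
attenuation under diffusion weighting.

The emulated acquisition is a clinical 21-axis, b = 1000 s/mm² protocol
with one b0 volume (an unweighted reference is mathematically required
to compute ADCs; one is the minimal and therefore default count).
Directions are laid out on a deterministic golden-angle (Fibonacci)
spiral so runs are reproducible without a stored table; at exactly six
axes the spiral happens to be degenerate for a tensor fit (the 6×6
design matrix is numerically rank 5), so the minimal scheme uses the
classical icosahedral six-direction set instead.  Voxels default to
0.9 × 0.9 × 5 mm, recorded in the NIfTI affine (RAS+, 0-based indices).

Noise is Rician — magnitude of a complex Gaussian,
sqrt((s+n₁)² + n₂²) — the standard model for magnitude MR images.  σ is
configurable; SNR 30 on b0 is a realistic clinical default.  σ = 0
bypasses the noise path bit-for-bit.

## ADC profiles, GFA, FA

Per-axis ADCs are Ψ(u_i) = −ln(S_i/S̄0)/b_i with S̄0 the mean over all
b0 volumes.  GFA is the sample standard deviation (n−1 denominator)
of the profile over its root mean square; written out,

    GFA = sqrt( n_s · Σ(Ψ_i − <Ψ>)² / ((n_s − 1) · ΣΨ_i²) ).

The formula's two count symbols are the same n_s (only one count
exists); this reading makes the closed form literally std/rms.  For
nonnegative profiles the value is provably in [0, 1]: 0 iff the profile
is constant, 1 iff exactly one entry is nonzero.  The implementation
rescales each profile by its maximum entry before squaring — the ratio
is scale-invariant, and this keeps the computation finite for profiles
near the floating-point underflow limit.

Magnitude noise can push S_i above S̄0, giving a negative raw ADC.  By
default such values are clamped to 0 (diffusion coefficients are
physical, and clamping keeps GFA within [0, 1]); `clamp=False` disables
this for comparisons against external implementations.  The clamp is
never applied inside the tensor fit, which needs the raw log-signal.

The tensor fit is ordinary log-linear least squares for the six unique
tensor elements; weighted and iterative fits are out of scope.  FA and
MD use the standard eigenvalue closed forms.  Voxels where a metric is
undefined (no b0 signal, nonpositive DW signal, all-zero profile) are
carried in an explicit validity mask, never as zeros — zero is a
meaningful anisotropy value.

## Smoothing and ROI reduction

Metric maps (never raw DWI) are smoothed with a separable Gaussian of
FWHM 6 mm by default, σ_axis = FWHM/(2√(2 ln 2)) scaled per-axis by the
voxel size so thick slices get proportionally fewer voxels of kernel.
Edges replicate the nearest voxel and invalid voxels are excluded by
normalized convolution; together these make constant maps exact fixed
points.  ROI means are arithmetic means over valid voxels of an integer
label volume; an ROI with no valid voxels is an error naming the ROI,
not a silent NaN.  Whether smoothing precedes ROI averaging is a config
toggle (`smooth_before_roi`, default on, matching the usual map-then-
average order); on noiseless constant blocks the two orders agree.

Spatial normalization and atlas-mask construction are intentionally
absent: synthetic volumes are generated directly in a shared space with
label volumes standing in for atlas masks, because registration is an
external-tool preprocessing step, not part of the analysis being
modelled.

## Clinical scores

WMFT task times are capped at 120 s ("not completed" ⇒ 120 s).  The
per-task rate is 60/time per minute, with "within 120 seconds" read
inclusively: exactly 120 s earns 0.5/min, anything slower earns 0.
The lpt summary is ln(mean capped time) — the literal reading of the
published procedure; the alternative mean-of-logs is available behind
`per_task_log=True` for sensitivity analyses.  FMA is an opaque 0–66
integer.  Consequences tested as invariants: slowing any task never
raises the mean rate and never lowers lpt, and lpt ≤ ln 120 always.

## Cohort simulator

The simulator draws a 36-subject single-arm cohort (the published
group's size) with per-ROI pre/post GFA and FA means/SDs taken from the
published group table, FMA 45.4 ± 12.3 → 50.9 ± 12.0 and lpt
2.8 ± 1.2 → 2.4 ± 1.3.  Pre and post values of each measure share a
within-subject test-retest correlation of 0.7 — a typical published
reliability for both DTI metrics and clinical motor scores; this one
value is the only free parameter not pinned by the emulated study.

The change in lesioned-BA4 GFA and the change in lpt are coupled by a
Gaussian copula with Pearson r = 2 sin(π ρ*/6) on the latent change
normals, so the planted Spearman correlation equals ρ* (−0.363 by
default) in expectation, exactly monotone at ρ* = ±1.  Two deliberate
approximations follow from this construction:

* the lpt change is innovated directly (post = pre + Δ), so the
  post-lpt marginal SD is slightly above its configured value;
* all 15 WMFT task times are set equal to exp(lpt) (the simplest table
  consistent with the lpt transform), so the derived mean performance
  rate is 60·e^(−lpt) rather than an independently specified quantity —
  the published rate summary is not reproduced, only its direction of
  change.

GFA/FA draws are clipped to [0, 1] and FMA to integer 0–66; lpt is
clipped at ln 120 (so back-generated times respect the cap).  At the
default parameters the clips are far in the tails and the finite-sample
Spearman expectation at n = 36 dominates the small (≈0.02) gap between
the mean recovered correlation and ρ*.

What the simulator does **not** emulate: registration error, partial
volume and atlas-mask misplacement, correlated noise between ROIs,
skewed or heteroscedastic score distributions, dropout, or any
treatment mechanism.  Passing tests therefore demonstrate that the
analysis chain recovers effects of the published size and direction
under idealized Gaussian conditions — not that it would do so on real
patient data.

## Statistics

Wilcoxon signed-rank: differences post − pre, zeros discarded
(the classical rule, not Pratt's), midranks on |d|, W = min(W⁺, W⁻).
For effective n ≤ 20 without ties the two-sided p is exact — the null
distribution of W⁺ is built by dynamic programming over rank subsets,
equivalent to enumerating all 2ⁿ sign patterns, and p = 2·P(W ≤ w),
capped at 1.  Otherwise a normal approximation with tie correction
(Σ(t³−t)/48 subtracted from the variance) and a 0.5 continuity
correction is used, matching the values mainstream statistics packages
print.  All-zero differences return the degenerate p = 1, flagged.

Spearman's rho is the Pearson correlation of midranks with the
t-distribution p-value on n−2 degrees of freedom; R² = ρ² is reported
alongside ρ because clinical reports print either.  All tests are
two-sided; no multiplicity correction is applied by default, mirroring
standard single-study reporting (a Holm adjustment can be applied
downstream to the report's p columns).

## Determinism and problem sizes

Every stochastic component takes an explicit seed (`numpy.random.
default_rng`); pipeline runs with the same config produce byte-identical
reports.  Test and demo problem sizes — 16×16×4 phantoms, 36-subject
cohorts, 200–500 Monte-Carlo replicates, 10⁵ random profiles for the
GFA bound — were chosen as the smallest sizes at which the planted
effects and analytic properties are unambiguous.

## Known limitations

* GFA from 21 axes is a low-angular-resolution estimate; the package
  models the estimator, not high-angular-resolution acquisition.
* The tensor fit is unweighted OLS; at very low SNR its eigenvalue bias
  is larger than weighted alternatives would give.
* The ROI pipeline assumes data already share a space; no registration.
* The cohort simulator's Gaussian marginals understate the skew real
  WMFT times show.
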