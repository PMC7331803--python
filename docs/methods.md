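# Methods

`stepdown` re-implements, as a tested pipeline on synthetic data, the
analysis of a stepping-down study in older adults: does a postural threat
(walking at elevation) shift the step height at which people abandon the
easy heel landing for the safer, more effortful toe landing?

## The behavioural model

Each participant in each threat condition carries a latent critical
switching height `h_crit` and steepness `b`; the probability of a heel
landing at step height `h` is logistic,

    P(heel | h) = 1 / (1 + exp(b (h − h_crit))),

so `h_crit` is the 50% point and larger `b` means more consistent strategy
selection.  The curve family is not uniquely determined by the source
description (logistic vs cumulative normal); the logistic is used because
its midpoint identity `P(h_crit) = 1/2` is exact in floating point, which
the test suite exploits.  Slope consistency is retained internally but is
not an outcome: with switching heights near the lower end of the grid, few
trials inform the lower limb of the curve and the slope estimate is
unreliable, which is why the original analysis dropped it.

### Adaptive protocol

Heights come from the fixed grid 0.025–0.150 m (0.025 m steps), six trials
per block, starting at 0.050 m.  The published description defers the
adaptation rule to earlier work, so this package fixes one explicitly
(documented stand-in): after each block, all-heel moves to the smallest
unvisited height above (hunting the toe anchor), all-toe to the largest
unvisited height below, and a mixed block moves toward whichever 6/6
anchor is missing, upward when both are.  The run stops when both anchors
exist, the grid is exhausted in the needed direction, or six heights have
been visited — at most 36 trials.  For monotone (step-function) responders
this provably terminates with both anchors or a grid boundary.

### Psychometric fit

Per participant × condition, a Bernoulli maximum-likelihood logistic fit
with a deterministic optimizer: a vectorized coarse lattice over
`(h_crit, b)` (0.0025 m × log-spaced slopes up to 2000 /m) seeds L-BFGS-B
polishes from the best cell and from near-competitive per-slope profile
optima (quasi-separated data push the slope to the boundary, where the
optimum in `h_crit` is sharper than the lattice).  A weak ridge on the
slope (λ = 1e−6) stabilizes near-separated fits; the brute-force oracle
tests run with λ = 0.  Degenerate cases follow the published convention:
all-toe → `h_crit = 0.015 m`, all-heel → `0.165 m`; an interior estimate
escaping [0.015, 0.165] m is clamped to keep that codomain; complete
separation caps the slope at 2000 /m and places `h_crit` at the midpoint
of the bracketing heights (the definitional 50% point).

## Bayesian inference

All tests are Jeffreys–Zellner–Siow defaults: a zero-centred Cauchy prior
on the standardized effect δ (paired Cohen's δ; `t = δ√n`), Jeffreys prior
on the variance.  The marginal likelihood under H1 is a one-dimensional
integral of the noncentral-t density against the Cauchy prior, evaluated
by Gauss–Legendre quadrature on each half line after `δ = ±γ tan θ` (240
nodes per half line; agreement with adaptive quadrature below 1e−8
relative, asserted against independent oracles including
`pingouin.bayesfactor_ttest`).  One-sided factors double the matching
half-line numerator, so `(BF⁺ + BF⁻)/2 = BF_two` holds by construction and
is additionally checked against a Monte-Carlo prior-predictive oracle.
Noncentralities more than 40 sampling SDs from the observed t contribute
nothing and are skipped, which also avoids instability in the backend's
noncentral-t series.  Posterior summaries of δ come from a 6001-point
trapezoid CDF on a likelihood-confined grid, verified against an MCMC
oracle.

**Prior scale.**  The pre-registered one-sided tests use Cauchy scale
γ = 1.0.  The published phrasing ("interquartile range of r = 1") is
ambiguous, but the printed triple for the switching-height contrast —
posterior-median δ = −0.59, 95% CI [−1.03, −0.19], BF10 = 13.7 — is
mutually consistent only at scale 1.0 with δ read as the posterior median
(implying a data t ≈ −3.06).  The reconstruction therefore inverts the
posterior-median map (`t_from_delta_median`) before reporting the Bayes
factor or credible bound.  Exploratory two-sided step-length tests also
use γ = 1.0; robustness scans over {0.5, 0.707, 1.0} accompany every
headline factor.  The group-interaction contrast uses γ = 0.5 (the
default fixed-effect scale of Bayesian repeated-measures ANOVA), and the
regression uses the JZS regression default 0.354.

**Sequential design.**  First evaluation at n = 20, one participant per
step, stopping at BF10 ≥ 10, BF10 ≤ 0.1, or n = 50.  Under a null stream
most runs exit on the H0 boundary or the ceiling; the H1 stop rate of the
optional-stopping design is a few percent (estimated by simulation in the
tests, not asserted against any published value — optional stopping
inflates it above the fixed-n rate).

**Power.**  Exact from the noncentral t: δ = 0.4, n = 50, one-sided
α = 0.05 gives 0.874 ≥ 0.85, cross-checked by 200,000 simulated t-tests.

**Signed-rank test.**  The rank-based Bayes factor uses latent-normal data
augmentation: standard-normal latents constrained to the observed signed
ranking are Gibbs-sampled (truncated normals bounded by rank neighbours),
with δ drawn between sweeps by grid inverse-CDF under its Cauchy prior;
BF10 follows from the Savage–Dickey ratio at δ = 0 (Gaussian KDE), with a
per-chain Monte-Carlo SE of log BF.  Defaults: 5 chains × 10,000
iterations, 1,000 burn-in.  Zero differences are discarded as in the
classical test.  Concordance with the parametric path on normal data is a
test invariant (|Δ log BF| < 1).

**Group interaction.**  With one within factor (threat) and one between
factor (fear group), the threat × group interaction is exactly a
between-group comparison of within-participant difference scores; it is
implemented as a two-sample JZS test (pooled t, effective
n = n₁n₂/(n₁+n₂)).  This is a documented simplification of multi-model
Bayesian RM-ANOVA: the numerical factor differs from model-averaged
output, so no published ANOVA value is treated as reproducible.

**Regression.**  `BF10 = E_g[(1+g)^{(n−1−p)/2} (1+g(1−R²))^{−(n−1)/2}]`
with `g ~ InverseGamma(1/2, n·0.354²/2)`, by adaptive quadrature, checked
against a dense-grid oracle under the compactifying substitution
`u = g/(1+g)`.  Coefficients are reported with the posterior shrinkage
factor `E[g/(1+g) | data]`.

## Kinematics

Right-handed axes: x travel, z up, y mediolateral; metres; 100 samples/s.
Seven four-marker clusters (feet, calves, thighs, pelvis).

* **Pose**: per-frame orthogonal Procrustes (proper rotation, det +1) with
  the standard sign correction for planar subsets; a genuinely 3-D cluster
  demanding a reflection raises.  Frames with < 3 visible markers are
  invalid and gap-filled.
* **Gap filling**: orientations by slerp between bounding frames
  (verified against the fractional-power oracle `R₁(R₁ᵀR₂)^s` to 1e−9
  rad), origins linearly; `max_gap` 20 samples (0.2 s), longer or boundary
  gaps invalidate the trial.  A single missing marker inside a solvable
  cluster is spline-interpolated in cluster-local coordinates and mapped
  back through the rigid pose.
* **Joint angles**: intrinsic Y–X–Z decomposition of the relative rotation
  (flexion axis first), sagittal angle sign-flipped so negative means
  plantar flexion (ankle) or flexion (knee); `joint_rotation` is the
  inverse map, so synthesis and analysis share one convention and the
  noiseless round trip is exact.  Angular velocity is the mediolateral
  component of the relative angular-velocity vector (central differences).
  |second angle| > 80° flags gimbal proximity.
* **Events**: foot contacts are forward-velocity downcrossings of 0.2 m/s
  refined to the local vertical minimum within ±0.1 s; the landing is the
  first contact at the lower level (minimum contact height), bracketed by
  the preceding and following heel strikes.  Thresholds are configurable;
  they were chosen for robustness on the synthetic trials and are not a
  reimplementation of the original (citation-only) detector, whose manual
  verification step is out of scope.
* **Normalization**: 101 nodes, [hs_pre, landing] → 0–50 and
  [landing, hs_next] → 50–100, landing pinned at node 50.
* **Spatiotemporal**: step length is the forward foot separation at the
  landing (double-support) sample; walking speed the mean first derivative
  of pelvis position along the travel path over the analysed cycle.

## Trajectory SPM

At each of the 101 nodes a paired JZS test (two-sided, γ = 0.707) across
participants; clusters are maximal runs of nodes with BF10 ≥ 10, the same
strong-evidence criterion as the sequential design.  This is a documented
methodological stand-in for the (unpublished) adapted Bayesian-SPM code:
no random-field or cluster-level multiplicity correction is applied, and
the family-wise false-positive behaviour under the null is characterized
empirically — on 200 simulated null cohorts (n = 13 pairs, smooth
participant-level curve variability) the large majority of replicates
show zero clusters.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes:
latent switching heights bivariate-normal across conditions (defaults
0.043 ± 0.018 m low threat, −0.010 m threat shift, within-participant
correlation 0.8, truncated to (0.005, 0.20) m — the truncation shifts the
realized mean up by ≈ 0.0025 m, a property the tests account for),
log-normal slopes (150 ± 50 /m), alternating condition order (the realized
14/10 split is an option), tonic EDA 16.8 ± 10.0 μS with +1.8 μS threat
shift plus session-level variability (SD 1.5 μS), drift and noise;
fear ratings on the 1–10 half-point scale with exactly 7/24 responders
whose first-block rating rises under threat; imposed speed 1.1 m/s with a
−0.04 m/s threat shift (between-subject SD 0.12, within 0.08 m/s).  The
within-participant correlation 0.8 follows from the printed paired effect
(≈ −0.6) against the between-subject SDs.  Condition duration is not
published; the EDA duration is a parameter (default 60 s in studies).

Marker trials author foot trajectories with quintic-smoothstep swings so
contacts are exact vertical minima with zero landing velocity, a pelvis at
exactly the imposed speed, and leading-leg orientations composed from
latent spline angle templates whose landing shape is strategy-dependent
(dorsiflexed heel landing vs plantar-flexed toe landing — qualitative
shapes only, no claim of matching published curves).  `trajectory_noise_sd`
is an angular jitter (degrees) converted to marker-position noise through
a nominal 0.05 m cluster lever arm.  Step length is modelled through
strategy (0.58 m heel, 0.52 m toe): the generator makes no attempt to
reproduce the published all-trials step-length direction, which depends on
height-sampling details the source does not specify.

Consequently, passing tests show that the *pipeline* is correct (exact
round trips, oracle agreement, calibrated operating characteristics on
data that satisfy the model), not that real marker, EDA, or behavioural
data satisfy the model: real clusters deform, real EDA has phasic
structure, real strategy selection may lapse at extreme heights, and real
event detection required visual verification.

## Problem sizes and numerical choices

Simulation-based checks use: 500 participants for parameter recovery
(median |ĥ_crit − truth| < 0.0125 m, half the grid spacing), 100 replicate
null studies for the Bayes-factor null behaviour (BF10 < 1 in ≥ 80%), 200
null cohorts for the SPM family-wise behaviour, and 400 null streams for
the sequential design — sizes chosen to make each estimate's Monte-Carlo
error small relative to its acceptance margin.  Tolerances: quadrature
1e−8 relative; slerp and rotation round trips 1e−9; noiseless angle
round trip < 0.1° RMS; posterior quantiles vs MCMC ± 0.02.  Ties in
absolute differences are ordered stably by the sort; all RNG streams
derive from a single seed through fixed named offsets, so every report is
bit-reproducible from its config and seed.

## Known limitations

Clamped fits enter the paired contrast at their clamp values, as in the
source analysis, which compresses true effects for floor-level
participants.  The SPM stand-in and the two-sample interaction are
documented deviations, not re-implementations, of the cited procedures.
The signed-rank sampler assumes continuous data (ties broken by stable
ordering).  The OSF deposit of the original study is not downloaded or
parsed; the file readers define the expected delimited-text layout
instead.
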