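# Methods

## Paradigm generator

The probability schedule is drawn per seed from a parameterized family:
the first half of the 1800-trial sequence alternates stable blocks
(≥ 100 trials at tone-1 probability 0.85 or 0.15, up to 150 extra trials
of random slack) with volatile blocks built from reversal segments drawn
uniformly on the integers [25, 60]; two 50-trial neutral phases at
p = 0.5 are inserted at random segment boundaries (never first), and the
second half is the probability-flipped mirror (p → 1 − p), giving four
neutral phases and exact tone-role balance overall. Volatile segment
lengths are always untruncated uniform draws — leftover block budget is
absorbed by stable blocks — so the realized segment-length distribution
is exactly uniform. Layouts whose closing probability equals the flipped
opening probability are redrawn, so no constant-p run straddles the
mirror boundary and phase labels are exactly half-symmetric. One integer
seed feeds independent substreams for the layout and the tone draws.

The published experiment used a single fixed realization of (a layout
like) this family; its printed trial counts (119 deviants, 106 standards
under INIT) are one draw. Across seeds the generator yields ≈ 115
deviants and ≈ 95 standards on average, and the tests assert band
membership (95–140 / 80–125), not equality.

Distractor targets occupy distinct tones, open left for exactly half the
events, and follow tone offset by 50–250 ms, which keeps them strictly
inside the inter-stimulus gap.

## Synthetic cohorts

Every evoked response is a sum of Gaussian-in-time components with fixed
signed scalp topographies: N1/P2 on every tone; on INIT-deviants a
mismatch component (−2 µV, 172 ms, σ = 28 ms, fronto-central with
temporo-parietal reversal) multiplied by a stability gain (default 1.3 on
stable-phase trials) plus optional P3a/P3b-like components. Topographies
are zero-sum ("dipolar") mixtures of 2D Gaussian lobes on the projected
montage. Group effects scale, delay, and topographically displace the
mismatch component and add per-condition offsets at its (shifted)
topography and latency.

Three granularities share this template code path:

* **continuous recordings** (500 Hz, 63 scalp channels + infraorbital
  EOG): spatially correlated 1/f + white noise (9 + 4 µV RMS,
  120 mm correlation length) and Poisson blink transients
  (15/min, 120 µV, frontal-dominant). The blink scalp field is
  orthogonalized against the evoked topographies: blink and signal
  subspaces are genuinely distinct in real data (ocular vs cortical
  generators), and the low spatial rank of a smooth 2D simulation would
  otherwise create artificial collinearity that no blink-removal method
  could escape;
* **per-trial epochs** at the analysis rate;
* **condition-average ERPs**, the scaled path used by all cohort-level
  simulation studies: per subject, a multiplicative gain
  (SD 0.10) plus smooth condition-level residual noise (1.07 µV per
  channel/time point, 25 ms temporal smoothing) standing in for the
  average over that condition's trials.

**Calibration.** The condition-level noise is set so that the
between-subject SD of a condition-cell image at the mismatch peak voxel
is ≈ 1 µV; the mismatch amplitude then reproduces the published main
effect's peak t (observed ≈ 15 vs printed 16.6 at N = 71). The
biperiden-like effect combines the printed +13 ms latency shift, a
(25, −20) mm topographic displacement, and per-condition offsets
(+0.40 µV standards, −0.44 µV deviants) chosen so that at the empirically
selected interaction peak of a full-size cohort the mismatch × drug peak
t is ≈ 4.5 (printed: 4.45) and the per-condition effect sizes average
Cohen's d ≈ 0.9 (printed range 0.83–1.13). The deviant-side d runs above
the standard-side d because the latency/topography shift loads on
deviants only.

What the generator does **not** emulate: real source geometry and volume
conduction (topographies are 2D Gaussian mixtures), non-stationary or
muscle/line noise, trial-to-trial latency jitter, subject-specific
montage digitization, and any true coupling between plasma concentration
and ERP effect size (the covariate is exercised in the design but carries
no signal by default). Passing tests therefore demonstrate correctness
and calibration of the *analysis chain*, not properties of any real
recording.

## Preprocessing

Main variant: average reference (scalp channels only), 0.1 Hz high-pass,
decimation to 250 Hz, 30 Hz low-pass; control variant: linked-mastoid
reference, 1 Hz high-pass, 100 ms pre-stimulus baseline. Filters are
4th-order zero-phase Butterworth applied reference → high-pass →
anti-aliased decimation → low-pass; this ordering is a package choice and
is recorded here rather than asserted as the original study's.

Blinks are detected on vEOG = Fp1 − EOG at 5 robust SDs
(1.4826 × MAD), merged within a 0.5 s refractory window; a warning fires
when more than 10% of samples exceed threshold (pathological setting).
Blink epochs (1 s) whose peak-to-peak range exceeds 5× the median are
excluded as large transients; the leading left singular vector of the
stacked blink topographies defines the rank-1 noise subspace and
P = I − uuᵀ is applied to the stimulus-locked epochs. Epochs span
−100…+400 ms; any scalp channel exceeding 75 µV rejects the trial
(after projection); vEOG is exempt from the criterion. Per-channel
rejection above 20% triggers a data-quality warning.

## Scalp-time images and group statistics

2D channel positions come from an azimuthal-equidistant projection of the
standard 10-05 3D positions (85 mm equatorial radius). Interpolation is
linear on the Delaunay triangulation of the channel positions with
nearest-neighbour fill inside the hull margin; voxels outside the convex
hull are masked. The published geometry (4.2 × 5.4 mm × 4 ms over
100–400 ms, 16 mm FWHM spatial-only smoothing, mask-aware so constants
are preserved) is the default; simulation studies use a coarser
16 × 16 × 38 grid (8 ms bins). Exact voxel coordinates of the original
software are not recoverable; geometric consistency, not coordinate
equality, is promised.

First-level "GLMs" reduce to condition cell means because the trial-wise
regressors are indicators; contrasts are formed directly from the four
cell means. The group model combines group indicators with plasma
covariate columns mean-centered within each active-drug group. Two error
models are implemented:

* **pooled** (default): per-group variance *factors* pooled across
  voxels (a moment-based analogue of SPM-style global non-sphericity),
  one whitening for all voxels, residual df = n − p. Chosen because the
  random-field correction assumes a t field of homogeneous df: with
  fully voxel-wise Welch variances the Satterthwaite df is low and noisy
  (median ≈ 13 at 24 subjects), the EC densities over-predict the tail,
  and the empirical family-wise error drops to ≈ 0.025;
* **welch**: voxel-wise per-group variances with Welch–Satterthwaite df,
  kept as the closed-form-equivalent mode (it reduces exactly to Welch's
  t on two-group designs) and for heteroscedasticity-robust checks.

Smoothness is estimated from the variance-normalized residual images'
forward differences (λ̂ per axis rescaled for the 1/n normalization;
FWHM = √(4 ln 2 / λ̂)); resel counts use the standard
point/edge/face/cube decomposition of the mask. Peak-level corrected
p-values use the Worsley t-field EC densities with
p = 1 − exp(−Σ R_d ρ_d(t)), floored at the uncorrected tail probability;
below each density's mode the density is clamped at its mode, which makes
the corrected p provably monotone in t without changing it in the
thresholding regime. Cluster tables use 18-connected components, peak
|t| with deterministic tie-breaks (earliest time, then smallest x, y),
and z-equivalents computed in log space (underflowing tails print Inf).

The permutation alternative permutes group labels, recomputes the Welch
t map per permutation, and ranks observed t values in the max-T null
distribution (identity permutation included, so min p = 1/(B+1)).

Functional masks are the union of significant positive and negative
average-effect voxels; drug contrasts are orthogonal to the average
contrasts used to build them. `run_study` reports the whole-volume
correction always and adds an `@svc` entry when only the small-volume
route is significant — the two-route reporting spends additional alpha,
which the null-cohort study quantifies for the whole-volume route alone.

## Simulation studies (problem sizes)

The standing validation studies run on the reduced grid with the
condition-ERP cohort path: family-wise error on 200 null cohorts of
3 × 8 subjects (300 permutations; empirical FWER ≈ 0.035 for both GRF
and max-T, voxel agreement > 0.999), and effect recovery on 15 cohorts at
the published group sizes (detection of the mismatch × drug battery in
100% of cohorts; cohort-mean ROI latency difference ≈ 8–9 ms against the
injected 13 ms). The ROI latency difference is biased low because the
plain window-minimum latency estimator is noise-susceptible — the same
caveat the peak-based ROI literature itself raises — so the recovery
check evaluates the mean over cohorts against a ±8 ms band.

## ROI and behavior

The ROI difference wave is deviant − standard and the MMN peak its
minimum in 150–250 ms at Fz/FCz/Cz (earliest-sample tie-break; boundary
minima flagged). This sign convention reproduces negative peak
amplitudes (≈ −1.8 to −2 µV); the alternative "standard − deviant"
wording would mirror the wave and is not used. Peak amplitude and latency
enter separate 3 × 3 drug × sensor ANOVAs, fixed-effects additive with
subjects as replicates (no repeated-measures correction — matching the
published analysis; with strong within-subject correlation across sensors
this inflates the group F, which the tests account for by using
independent replicates in the null case). Behavioral tests: one-way ANOVA
on mean RTs, Kruskal–Wallis on hit rates, pairwise post-hocs on
significant omnibus tests, and flagging of hit rates below 75%.

## Ideal observer

The 3-level binary hierarchical Gaussian filter runs in ideal-observer
mode with fixed a-priori parameters: κ = 1, ω₂ = −3, θ = 0.05, priors
μ₂ = 0, σ₂ = 1, μ₃ = 1, σ₃ = 1. θ (the volatility level's evolution
variance) is set large enough that the volatility belief tracks the
paradigm's phase structure within a session — with very slow level-3
learning (θ ~ e⁻⁶) the belief integrates over the whole session and the
stable/volatile contrast washes out. Updates are strictly filtering (no
look-ahead); non-positive posterior precisions raise an error naming the
trial. Note that the level-2 posterior variance is *not* globally
monotone under a constant sequence: it shrinks while outcomes are
informative and then relaxes toward a volatility-set equilibrium as the
predicted probability saturates — a property of the model, not a bug.
Regressors are |low-level pwPE| and signed high-level pwPE, z-scored,
with their collinearity reported (≈ 0.9 on this paradigm — the two
quantities share the surprise signal; analyses using both should
orthogonalize or report shared variance).

## Known limitations

* The scalp model is 2D and low-rank; topographic effects are coarser
  than real volume conduction.
* The cohort-level fast path simulates condition averages directly;
  trial-count asymmetries between conditions enter only through the
  calibrated noise level, not explicitly.
* GRF correction remains mildly conservative (FWER ≈ 0.035 at nominal
  0.05) — inherited from lattice discreteness and estimated smoothness.
* The 2REP standard-subsampling rule is uniform within repetition
  strata; the original selection rule is unspecified.
* EDF export is not provided; BrainVision covers continuous-data
  interchange.
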