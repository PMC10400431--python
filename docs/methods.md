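# Methods

## Behavior model and state extraction

The simulator represents the floating-ball task in a 2-D virtual plane
(arc-length coordinates on the ball, radius 1.2192 m). Speed follows an
Ornstein–Uhlenbeck process whose set point alternates between rest
(0.005 m/s) and movement (0.07 m/s) bouts with exponential durations (means
2 s and 4 s); heading is a wrapped-normal random walk whose increments are
von Mises with concentration `heading_persistence` (default 50) and a mean
drift toward the goal equal to `goal_bias × turn_gain ×` (bearing error),
plus a soft centering term outside a 1.5-m arena radius. The goal is a disk
whose radius is the arc subtended by a 30° solid-angle cap (half-angle 15°).
Sensor noise of 0.002 m/s is added to the translational channels.
Ground-truth frame states are the rest/movement threshold rules applied to
the noiseless speed, so state-classification accuracy against ground truth
is meaningful (measured 0.97–0.98 on 200-s sessions).

Frame classification: rest if speed < 0.02 m/s and |accel| < 0.2 m/s²;
movement if speed > 0.03 m/s and not rest; an uncategorized bout becomes
movement if either flank is movement, and rest if both flanks are rest —
for a rest-flanked bout of ≥ 1 s this is a design choice (its speed never
crossed the movement threshold); session-edge bouts follow their single
flank. The acceleration threshold applies to the magnitude. Movement
direction is atan2(forward, rightward) in degrees [0, 360), defined on
movement frames only. Goal-directedness of a frame means the MD falls
within the angular window subtending the goal cap from the current position
(180° when inside the goal). Goal proximity is the mean great-circle
angular distance to the goal center; cumulative turning integrates signed
MD increments over movement frames (CCW positive).

Rewards: a reward is delivered whenever the animal is on the goal and ≥ 3 s
have passed since the last reward, so a continuous stay yields
refractory-spaced rewards and a re-entry within 3 s yields none. Latency is
measured from the session start to the first reward and between consecutive
rewards thereafter.

## Fluorescence model and ΔF/F

Simulated neurons emit Bernoulli events per frame at rate
`base_rate · exp(κ cos(MD − PD))/I0(κ)` during movement (so the
direction-averaged rate equals `base_rate`), scaled by `rest_rate_scale`
(0.1) at rest and by `offpd_suppression` beyond 90° from the PD. Events are
convolved with a unit-peak AR(2) kernel; raw fluorescence adds a 100-unit
baseline, a slow sinusoidal drift, a shared low-pass background entering
the ROI at the true neuropil weight (0.7), and white noise. The indicator
kinetics default to 0.06 s rise / 0.3 s decay at the 100 Hz simulation
rate: this keeps the printed 120-frame baseline span about four times the
transient decay, the same span:decay ratio a slow indicator has at
conventional two-photon frame rates. The `snr` of a trace is the transient
peak (1.0 ΔF/F) over `noise_sd`.

Baseline estimation follows the printed recipe exactly: PreF0 =
LOESS(F, 120 frames) (locally linear, tricube weights, via statsmodels);
PreΔF = F − PreF0; noise = s.d. of (PreΔF − LOESS(PreΔF)) — the residual
s.d., the only dimensionally coherent reading of the printed noise step;
offset = mean of PreΔF values with |PreΔF| ≤ 2 × noise; F0 = PreF0 +
offset, floored at a small positive epsilon. ΔF/F = (F − F0)/F0 − 0.7 ×
(background ΔF/F), where the background trace is processed identically.
Neuropil masks are 0.3–10 µm annuli excluding all neuronal ROIs; an annulus
pixel is excluded when its difference from the ROI trace shows a sustained
transient (≥ 3 consecutive frames above 3 robust s.d. of the difference);
the 3-consecutive-frame requirement keeps isolated noise excursions from
emptying the annulus on long traces. The exclusion is a single pass.

## Event inference

Binary events come from the FOOPSI objective — minimize ½‖conv(h, s) + b −
y‖² + λ Σs with s ≥ 0 — solved exactly by coordinate descent over event
amplitudes (numba-jitted; the scalar baseline b is an extra least-squares
coordinate, so the objective is monotone). The AR(2) kernel is estimated
per neuron by least-squares Yule–Walker over autocovariance lags ≥ 2 (the
noise-inflated lag-0 term never enters) on a 1-s high-passed trace (slow
event-rate autocorrelation from behavioral bouts otherwise biases the
kernel slow), with sanity bounds on the implied time constants; when the
full AR(2) is unidentifiable, the robustly estimable decay root (log-linear
fit of autocovariance lags 2–10) is combined with the assumed rise, and
failing that the default kernel (0.1 s rise, 1 s decay) is used. λ is one
matched-filter noise unit (sn · ‖h‖); detection is decided afterwards by a
cluster-total significance threshold (4 σ of the amplitude estimator, then
a relative cut at 0.25 × the median cluster total), with deconvolved mass
merged within 120 ms. When the AR recursion on event-free frames shows the
trace is essentially noiseless (robust quiet-row regression with intercept,
residual < 0.5 × the estimated noise), the kernel is refined on those rows
and events are recovered by exact AR-whitening inversion — this makes the
noiseless simulator round trip exact (Jaccard 1.0).

Measured operating range through the full ΔF/F pipeline, with one-to-one
matching at ±100 ms: F1 ≈ 1.0 noiseless, ≈ 0.65 at snr 10, ≈ 0.5 at snr 5
(at 1 event/s during movement). Two physical effects cap noisy performance:
the 120-frame LOESS baseline partially absorbs and reshapes transients
(peak attenuation ≈ 40%, shortened effective decay), and events inside
bursts shorter than the kernel decay are not frame-separable at these noise
levels (the lasso places their mass coherently). Passing tests therefore
demonstrate event detection well above chance and exact noiseless
inversion, not frame-perfect recovery in noise.

## Direction tuning

Likelihoods P(active | MD_i) use 72 five-degree bins over movement frames
only, smoothed with a Savitzky–Golay filter (window 11 bins, order 3,
circular padding — unstated in the source of the procedure; chosen to
smooth without flattening a κ = 2 lobe) and clipped back to [0, 1].
The circular-shift bootstrap shifts the event train by 100 uniform offsets;
z = (actual − shuffle mean)/shuffle s.d. per bin. The active-cell test
compares max |z| against the shuffle max-|z| distribution (family-wise over
bins) at two-sided p < 0.05; shuffle maxima use leave-one-out mean/s.d. so
each shuffle is scored the same way the actual curve is — without this the
false-positive rate was ~9% instead of the nominal 5% (measured 5–6% over
1,000 nulls with it). The two-lobe von Mises fit uses nonlinear least
squares with 8 θ0 starts, κ ∈ (0, 20], a1, a2 ≥ 0; fit_p is an F-test
against the constant model; the PD is the fitted curve's argmax with ties
resolved to the smaller angle. DSI evaluates the min-max-normalized fitted
curve at PD and PD + 180°; selective means fit_p < 0.05 and DSI ≥ 0.4; the
tuned-cell gate is a one-way ANOVA of per-frame activity across MD bins.
Population precision is 1/variance of summed activity per MD bin (infinite
flagged, < 5 frames missing); the percent-active-by-PD-distance curve is
normalized by its distance-0 bin.

## Decoding

The posterior is the product over active neurons of
P(active_k | MD) P(MD) / P(active_k) — the prior inside every factor, as
the source formula prints it (prior_mode="single" applies it once, as a
documented alternative) — computed in log space and renormalized.
Likelihood values are floored at 1e-4 so a sampled zero down-weights a bin
rather than vetoing it. Frames with no active neuron are undecoded; frames
whose product vanishes everywhere fall back to the prior and are flagged.
MAP ties resolve to the smaller angle. Decode error is the circular
difference wrapped to (−180°, 180°]. The population vector sums unit
vectors at the active tuned neurons' PDs; frames with zero resultant are
skipped and counted; "decoded"/"anti-decoded" fractions use ±22.5° sectors
around 0°/180°, a stated interpretation of the sector width.

## Correlations

CI_ij interprets ⟨E_i⟩ as the per-frame event probability n_i/N, which
makes N⟨E_i⟩⟨E_j⟩ the independence-expected coincidence count and keeps CI
of order ±1 (identical trains give 1 − n/N; disjoint trains give
−√(p_i p_j); both verified to 1e-12). Pairs are positive/negative when a
95% frame-resampling bootstrap interval (1,000 reps, multinomial frame
weights) excludes 0. CI is computed on all frames by default with the
state filter available to the caller. Pearson correlations by state
require ≥ 100 frames per state; the high-correlation fraction uses
r > 0.6.

## Synapse quantification

Per-plane binarization: threshold = local mean over the role's neighborhood
(19 px AIS / 15 px ChC) × (1 − sensitivity) (0.08 / 0), intersected with a
global robust noise floor (median + 2 MAD-s.d.) — without the floor the
background percolates into one giant component that can swallow a fiber.
Candidate filters: area ≥ 10 px, mean intensity ≥ plane median + 1 s.d.;
registered objects must be narrower than 3 µm (AIS) / 4 µm (ChC) orthogonal
to their principal axis. Cross-plane linking requires ≥ 1 px mask overlap
between consecutive planes; AISs ≤ 10 µm are discarded. Any co-localized
ChC area makes a contact. Geometry: the lengthwise axis is the principal
axis of the projected mask; AIS and ChC max-intensity profiles are taken in
a 1.5-µm corridor with the ROI extended 5 µm past the AIS ends; lengths are
read at half of each profile's maximum; A is the projected ChC-on-AIS mask
area. Gephyrin puncta: per-plane local maxima above median + 6 robust s.d.,
fixed-σ (1.5 px) Gaussian fits with free position/amplitude; elongated
blobs whose single-kernel residual exceeds 3× the plane noise are refit as
two-kernel mixtures (resolves pairs below the classical limit); duplicates
within 2 px on adjacent planes keep the brighter fit; modified z-scores use
the median and s.d. of all detected puncta in the tile, as printed (not
MAD). POST sums signed z-scores (unclipped; exact cancellation is flagged
NaN). Subgroup boundaries are strict inequalities.

The stack generator renders straight AIS fibers (~1 µm ridge, 3 z-planes)
on a non-overlapping grid, bouton strings covering a known fraction of each
chosen AIS with per-cartridge bouton size (so Pre-SSE spans a range),
gephyrin puncta ≥ 1 µm apart and ≥ 1 µm clear of cartridge boundaries
(ground-truth membership stays unambiguous at the rendering resolution),
and ~400 dimmer background puncta off-AIS — these anchor the tile z-score
statistics the way neuropil synapses do in real tissue; without them Z_AIS
is centered at zero and POST degenerates into a ratio of cancelling sums.
Noise is Poisson shot noise on signal-plus-background (background =
peak/snr) plus Gaussian read noise. Ground-truth PRE/POST are computed from
the noiseless half-max masks with the same formulas the pipeline applies.
Measured recovery at 30 AISs, snr 10: detection sensitivity 1.0, Pearson r
≈ 0.95–0.98 for both Pre- and Post-SSE across seeds.

The bootstrap comparison draws, per repetition, one mouse per condition and
n = 3,000 values with replacement from each, differences their normalized
histograms, and summarizes 10 repetitions by per-bin mean ± s.d.; subgroup
proportion changes are computed the same way; mice with < 30 values are
excluded with a warning.

## What the generators do and do not emulate

They reproduce the statistical structure the analyses rely on — bout-like
kinematics, goal-biased heading, von Mises event tuning, AR(2) calcium
dynamics with neuropil contamination and drift, fiber/cartridge/puncta
geometry with realistic SNR — but not: texture cues on the maze, air puffs,
brain motion, non-Gaussian optics, curved or branching AISs, anisotropic
PSFs, or session-to-session remapping. Passing tests demonstrate the
algorithms' correctness and calibration on data whose generative process
matches the model assumptions; real recordings violate those assumptions in
ways the tests do not probe.

## Problem sizes

Tests and the analysis scripts use desk-scale sizes chosen for coverage:
200–800-s sessions at 100 Hz, populations of 8–50 neurons, 20,000 movement
frames for PD recovery, 1,000 nulls for bootstrap calibration, 1,000
Bernoulli pairs at N = 10,000 for the correlation null, one 10 × 1100 ×
1100 tile with 30 AISs for the synapse pipeline, and 10 × 3,000-draw
repetitions for the SSE comparison.

## Known limitations

- Frame-exact event recovery in noise is capped by baseline absorption and
  burst coherence (see Event inference); downstream tuning and decoding are
  robust to ±100 ms event jitter, but users fitting faster behavioral
  covariates should not rely on single-frame event timing.
- The quiet-row kernel refinement assumes a stationary kernel per neuron.
- The synapse pipeline assumes straight, non-crossing fibers; crossing or
  branching AISs would merge into single objects and fail the width filter.
- Reported POST values are unclipped sums of signed z-scores and can exceed
  [0, 1] when a tile's z-score distribution is unusual; the degenerate
  cancellation case is flagged rather than silently clipped.
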