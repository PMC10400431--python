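# chcmotif

Analysis library for studying how chandelier-cell (ChC) axo-axonic
inhibition shapes premotor direction coding during goal-directed navigation.
A head-fixed mouse runs on a floating spherical maze toward a hidden goal
while layer-2/3 premotor neurons are imaged with a calcium indicator; in
fixed tissue, ChC cartridges and gephyrin puncta on pyramidal-cell axon
initial segments (AISs) quantify the structural strength of axo-axonic
synapses. The package implements every computational stage of that paradigm,
with synthetic generators (known ground truth) standing in for raw
recordings.

## What it computes

**Behavior** — 100 Hz ball-sensor kinematics are LOWESS-smoothed (500 ms),
frames are classified rest/movement (rest: speed < 0.02 m/s and |accel| <
0.2; movement: speed > 0.03 m/s; uncategorized bouts resolved by their
flanks), the movement direction is MD = atan2(v_fb, v_rl), rewards follow a
3-s refractory rule at the 30°-cap goal, and session metrics (success,
latency, accuracy, quadrant occupancy, turning) are derived.

**Calcium** — ΔF/F with a neuropil annulus (0.3–10 µm) subtracted at weight
0.7 and a LOESS baseline F0 (120-frame span plus a noise-calibrated
offset); binary events by sparse nonnegative deconvolution under an AR(2)
kernel (exact coordinate-descent solution of the L1-penalized objective,
with an exact whitening inversion in the noiseless limit).

**Direction tuning** — the likelihood P(active | MD_i) over 72 five-degree
bins, z-scored against a 100-fold circular-shift bootstrap, fitted with

    R(θ) = a0 + a1 e^{κ cos(θ−θ0)} + a2 e^{κ cos(θ−θ0+180°)}

whose argmax is the preferred direction (PD); the selectivity index is
DSI = (R_pref − R_oppo)/(R_pref + R_oppo) on the min-max-normalized curve.

**Decoding** — the Bayesian posterior over MD bins from the active neurons'
likelihood factors (MAP readout, chance-normalized posterior curves) and a
population-vector readout from the active tuned neurons' PDs.

**Correlations** — the coincident-event statistic
CI_ij = (E_i·E_j − N⟨E_i⟩⟨E_j⟩)/(N√(⟨E_i⟩⟨E_j⟩)) with a frame-resampling
bootstrap sign classification, Pearson correlations split by behavioral
state, and CI as a function of pairwise PD difference.

**Synapse quantification** — per-plane adaptive-threshold segmentation of
the AnkG and ChC channels, 3-D registration (AISs > 10 µm kept), contact
classification by any co-localized area, half-max profile lengths along the
fiber axis, Gaussian-fitted gephyrin puncta with modified z-scores, and the
structural synaptic efficacies

    Pre-SSE  = (A_ChC−AIS / L_AIS) × (L_ChC−AIS / L_ChC)
    Post-SSE = Z_ChC−AIS / Z_AIS

with high/mid/low subgrouping (>1.5 / <0.5 for Pre; >0.6 / <0.1 for Post)
and a robust random-sampling bootstrap (10 × n = 3,000 draws) for condition
comparisons.

## Worked example

```
$ python analysis/03_direction_tuning.py
24/24 active cells, 24 selective; median |PD error| 1.5 deg; median precision 1.0

$ python analysis/04_decode_direction.py
MAP decode: median |error| 15.9 deg over 22281 frames; posterior mass at the
true direction 4.3x chance; PoV decoded fraction 0.66

$ python analysis/06_synapse_quantification.py
detected 30 AISs (sensitivity 1.00); Pre-SSE r=0.97, Post-SSE r=0.98 vs ground truth
```

The first simulates a sharply tuned population (κ = 4) on a 400-s session:
every neuron passes the bootstrap active-cell test and the fitted PDs land
within a couple of degrees of the generative ones. The second decodes the
movement direction from that population frame by frame: the posterior
concentrates 4.3× above the 1/72 chance level at the true direction. The
third renders a synthetic three-channel tile with 30 AISs, runs the full
detection pipeline, and recovers both structural-efficacy parameters with
r ≈ 0.97 against the generative geometry.

The numbered scripts under `analysis/` run the whole study in order
(behavior → events → tuning → decoding → correlations → synapse
quantification → group comparison) and write their tables to `results/`.

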