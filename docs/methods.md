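# Methods

## Network model

Each region i of a parcellation (162 regions in the full-scale
configuration; 10 in the desk-scale study patients) carries a
phenomenological Epileptor with state (x1, y1, x2, y2, z, g):

```
ẋ1 = y1 − f1(x1, x2) − z + Iext1
ẏ1 = c − d·x1² − y1
ẋ2 = −y2 + x2 − x2³ + Iext2 + 0.002·g − 0.3·(z − 3.5)
ẏ2 = (−y2 + f2(x2)) / τ
ż  = r·( 4(x1 − x0) − z + f3(z) − K·Σ_j C_ij (x1_j − x1_i) )
ġ  = −0.01·(g − 0.1·x1)

f1 = a·x1³ − b·x1²                     for x1 < 0
   = −(m − x2 + 0.6(z−4)²)·x1          for x1 ≥ 0
f2 = 0                                  for x2 < −0.25
   = a2·(x2 + 0.25)                     otherwise
f3 = −0.1·z⁷ for z < 0, else 0
```

Defaults: r = 0.00035 /ms, τ = 10 ms, Iext1 = 3.1, Iext2 = 0.45, a = 1,
a2 = 6, b = 3, c = 1, d = 5, m = 0. Time is in milliseconds; state
variables are dimensionless model units.

**Coupling sign.** The permittivity coupling K·Σ C_ij (x1_j − x1_i) is
*subtracted* in ż: input from seizing neighbours (elevated x1) lowers z
and recruits a region, while quiescent neighbours raise z and act as
seizure inhibitors. With the opposite sign a near-critical
epileptogenic region surrounded by healthy tissue would be
*destabilized* by its neighbours and seizures could never propagate,
contradicting both the intended phenomenology and the canonical
permittivity-coupling formulation. `coupling_term` returns the raw sum
K·Σ C_ij (x1_j − x1_i); the integrator applies the sign.

**Excitability regimes.** For an isolated default-parameter node the
down-state equilibrium undergoes a fold when the fast-subsystem
Jacobian determinant vanishes at x1 = −4/3, which places the
interictal/seizure boundary at x0 ≈ −2.062; `seizure_onset_boundary`
finds it by bisection on noise-free 200-s simulations. The up-state
equilibrium is born where the quiescent equilibrium branch crosses
x1 = 0, i.e. at x0 = −(c + Iext1)/4 = −1.025; `up_state_boundary`
bisects on the sign of the stationary x1 computed from the implemented
vector field. Note that the newly born up-state equilibrium is at
first linearly unstable (it stabilizes only near x0 ≈ −0.94), so
forward simulation from generic initial conditions keeps producing
seizure-like bursts slightly beyond −1.025; the reported boundary is
the equilibrium-existence one.

**Regime classification** uses x1: peak-to-peak below 0.5 model units
over the last 20 s marks a fixed point (down vs up decided by the tail
value), anything that still visits x1 < −0.5 while oscillating is a
seizure-like event. x2-based measures cannot be used because with the
default parameters the intermediate population's equilibrium is
unstable at rest (Jacobian trace ≈ 0.81 > 0) and oscillates
autonomously with amplitude ≈ 2 — this steady background rhythm is
also why the simulated SEEG has ongoing baseline activity.

## Integration

Explicit Euler, Euler–Maruyama when any noise amplitude is nonzero,
with additive Gaussian increments σ·√dt·N(0,1) per state variable.
The default step is **dt = 0.05 ms**: the fast subsystem relaxes at up
to ≈ 13/ms at the down state, so explicit Euler needs dt ≲ 0.15 ms for
stability (0.05 leaves a comfortable margin; halving dt moves the
regime boundary by < 0.005). Each run starts from
(0, 0, 0, 0, 3, 0[, 0]) and discards a noise-free burn-in (10 s; 30 s
for interictal runs, whose z equilibrium near 5.8 is further from the
initial value). Noise starts after burn-in and is seeded; the
stimulation variant draws the same noise sequence as the base model
(six core variables, never m), so with Istim ≡ 0 and m(0) = 0 it
retraces the 6D trajectory exactly.

**State floor on z.** In the stimulated regime the Heaviside term
shifts z's attractor four units down; z then leaves its operating range
(≈ [2.9, 4.2]) and the seizure relaxation oscillation grows without
bound in amplitude and stiffness, which no fixed explicit step
survives. `NetworkModelSpec.z_floor` (default 1.0, disable with None)
clips z from below — the same device whole-brain simulators expose as
state-variable boundaries. Spontaneous and interictal trajectories
stay above z ≈ 2.8 and never touch the floor. Stimulated runs use
dt = 0.02 ms, since deep-ictal excursions (x1 down to ≈ −3.3) are
stiffer than anything the spontaneous regime produces.

Recorded output keeps every 20th step (50th for stimulated runs),
giving 1000 Hz sampled series; the SEEG source proxy is x2 − x1.

## EZ hypothesis and parameter maps

The per-region normalized epileptogenicity ev ∈ [0, 1] is the ground
truth of every run. Affine maps translate it per condition:

| condition   | map                            | range            |
|-------------|--------------------------------|------------------|
| spontaneous | x0 = −2.2 + ev                 | [−2.2, −1.2]     |
| stimulated  | x0 = −2.2 + 0.13·ev            | [−2.2, −2.07]    |
|             | m_thresh = 10 − 9.5·ev         | [10, 0.5]        |
| interictal  | x0 = −3 + 0.2·ev, Iext1 = 6    | [−3, −2.8]       |

The stimulated map keeps every region sub-critical (even ev = 1 gives
x0 = −2.07 < −2.062) so seizures arise only through stimulation;
epileptogenic regions get the lower seizure thresholds. Under
Iext1 = 6 the fold moves to x0 ≈ −2.787, so the interictal map places
epileptogenic regions just below the seizure threshold where noise
produces frequent spikes.

**Interictal noise** acts on x1 and y1 (amplitude 0.1). On the resting
branch f1 has no x2 dependence, so noise on the intermediate
population cannot reach the fast one and would produce spike rates
almost independent of ev; forcing the fast population makes the
escape rate across the nearby fold — and hence the spike rate —
strongly ev-dependent (tens of spikes per two minutes at ev = 1 versus
a handful of detector-level events elsewhere).

## Stimulation

The stimulus is a symmetric biphasic pulse train (positive phase then
equal negative phase, each one pulse width long) at the clinical
frequency/amplitude/pulse-width/duration; its sum is exactly zero
(charge balance). Spatially, both contacts are point charges and
|E(r)| of the resulting dipole is evaluated at every mesh vertex,
averaged per region with vertex-area weights (mirroring the gain
aggregation), and max-normalized to per-region weights in [0, 1];
Istim(i, t) = weight_i · waveform(t).

The absolute field scale entering the model is a free scalar, as the
phenomenological model has no physical units. `calibrate_stim_scale`
fixes it the way a modeler does against an empirical stimulated
seizure: find (doubling + bisection) the minimal gain at which the
reference-amplitude stimulus induces a post-stimulus seizure, then add
20% headroom. With the gain fixed, weaker amplitudes (0.5, 1 mA
against a 2 mA reference) fail to induce and stronger ones (3, 4 mA)
succeed — the clinical pattern. The induced-seizure indicator is a
post-stimulus x1 excursion (peak-to-peak > 2 model units in any
region).

**Location sweeps** hold every parameter fixed and move the pair, so
the field there is normalized by the *reference* pair's maximum rather
than per pair; otherwise a pair far from all sources would be silently
re-normalized to full strength. Contact pairs are grouped by midpoint
distance from the reference pair midpoint (≤1, 1–2, 2–3, >3 cm).

## Forward model and output

Gain: g[j,k] = Σ_{i ∈ region j} a_i / d_ik², with a_i the one-third
rule vertex area; no normalization and no dipole orientation, so SEEG
amplitudes are arbitrary units (written ×100, a microvolt-like range).
Bipolar channels subtract adjacent same-shaft contacts; the raw pulse
waveform is added to the two stimulating contacts so the stimulation
artifact is visible in the output. Cohorts are written as BIDS-iEEG
style trees: BrainVision triplets (text header/markers + float32
multiplexed binary) with model-derived seizure onset/offset markers,
channels/electrodes TSVs, a TVB-style connectome zip of whitespace
text tables, the gain TSV, the hypothesis TSV, and per-run JSON
sidecars carrying everything needed to re-simulate bit-identically
(x0, thresholds, K, dt, noise, seed, stimulus, field weights).

## Evaluation

Envelope: order-2 zero-phase Butterworth high-pass at 10 Hz,
rectification, order-2 zero-phase low-pass smoothing at 1 Hz. (A much
slower smoother would erase the few-second post-stimulus seizures this
model produces.) Seizure channels are flagged by *envelope contrast*:
peak > 2.5× the channel's own 10% envelope quantile. The per-channel
floor is needed because inverse-square gains spread channel amplitudes
over orders of magnitude, so no single absolute level separates
seizing from quiet channels; the contrast threshold itself is one
number shared by all channels of both recordings, chosen between the
contrast observed in seizure-free simulated recordings (≤ ~1.9) and in
seizure recordings (≥ ~2.9). An absolute-threshold variant
(`flag_and_mark`, default baseline mean + 3 SD) remains available for
data without that gain spread. For stimulated comparisons the floors
are estimated on the full trace (including the pre-stimulus baseline)
and flags, onsets and masks are taken in the post-stimulus window
only.

Masks are channel × time binaries filled between the first and last
level crossings of flagged channels; masks of unequal duration are
nearest-neighbour resampled to 512 common bins (identity on an
already-common grid). Metrics: 2D Pearson correlation over all mask
entries; binary overlap |E ∩ S| / |E| (the identical-sample fraction
is available as `binary_agreement`); SO channels are flagged channels
whose onset falls in the first 10% (configurable 5–15%) of the global
seizure span, the rest are SP, each compared by Jaccard (two empty
sets agree, J = 1). In a comparison, a simulated recording with no
seizure channel reports correlation/overlap/Jaccards of 0 with a
`degenerate` flag rather than an error, so sweeps containing
non-inducing stimulations remain well defined — the low-level
`mask_correlation` still refuses zero-variance masks.

Spikes: band-pass 1–70 Hz (zero-phase, order 4), robust noise scale
σ̂ = median(|x|)/0.6745, peaks of |x| above 4σ̂, peaks within 250 ms
merged; for empirical recordings an additional 25 µV amplitude floor
applies. Channels whose in-band content is pure float residue
(σ̂ ≤ 1e−12 × signal scale) are treated as spike-free. Per-channel
counts normalize to the IIS fraction S_i/ΣS and two recordings are
compared by the Pearson correlation of their IIS vectors.

Permutation test: statistic = difference of group means; one-sided p =
fraction of permutations with statistic ≥ observed (ties count as
extreme, so identical groups give p = 1); 200 000 shuffles by default,
exact enumeration of all C(n, n_a) splits when the pooled sample has
≤ 10 observations.

## Synthetic anatomy

The generator emulates the *interfaces* of imaging-derived data, not
their content: region centers are drawn in a 60-mm-radius ball with
minimum separation, each region's surface is a small closed
convex-hull sphere (~4 mm radius) — sufficient because the forward
model consumes only vertex positions, areas and region membership;
connectome weights are heavy-tailed log-normal magnitudes sparsified
to a target density, symmetrized, zero-diagonal, max-normalized;
shafts are straight lines of 10–18 point contacts at 1.5 or 5 mm
spacing aimed at random region centers (the 2 mm physical contact
length is metadata). Synthetic EZ hypotheses place EZ regions
(ev ∈ [0.9, 1]) near the first shaft's deep contact — clinical
implantations sample the suspected EZ — with PZ regions at
ev ∈ [0.05, 0.13] and HZ at 0.

What passing tests on this scaffold do **not** show: realistic
cortical folding and dipole orientation effects, realistic connectome
topology (modules, hubs, distance-dependence), empirical SEEG noise,
artifacts and background spectra, or inter-patient anatomical
variability. Results transfer to real data only at the level of the
algorithms (model dynamics, forward projection, detection and metric
definitions), not of effect sizes.

## Study configurations and problem sizes

The in-silico experiments run on desk-scale patients chosen to keep a
full study in minutes on one core while preserving the qualitative
regimes: 10 regions, 4 shafts, 30 vertices/region, K = 1 with the
max-normalized connectome; spontaneous runs 60 s, stimulated runs 30 s
(50 Hz, 1 ms pulses, 4 s trains, onset at 5 s), interictal runs
120 s. The personalized-vs-randomized study uses 5 patients, one noisy
pseudo-empirical run each (noise 0.01 on x2, y2), one matched
re-simulation, and 3 randomized-hypothesis draws per patient (15
controls). Location sweeps use 3 pairs per distance group.

## Known limitations

* Post-stimulus seizures self-terminate within a few seconds because z
  recovers quickly once the Heaviside releases; long reverberating
  stimulated seizures would require richer connectomes with many
  near-critical regions.
* The background rhythm generated by the intermediate population is an
  intrinsic property of the printed parameter set; it stands in for
  real SEEG background but has a fixed narrowband spectrum.
* The z floor slightly alters deep-ictal trajectories of strongly
  stimulated runs (it exists precisely because that regime is outside
  the model's calibrated range).
* Afterdischarges, dipole orientation, field inhomogeneity and neural
  field (continuum) effects are out of scope.
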