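# Methods

This note documents the models behind `aquaflux`, the defaults that
matter, and the numerical and design choices made where the measurement
procedures left them open.

## The osmotic volume model

A single astrocyte is treated as a well-mixed compartment of water volume
V (µm³) containing a conserved amount N_in = C0_in·V0 of impermeant
osmolytes (mOsM·µm³). Water crosses the membrane through two parallel
osmotic pathways — an aquaporin conductance `g_aqp` that can be fractionally
blocked, and a residual leak `g_leak` — plus a constant water source
`J_met` that lumps cotransporter-coupled and metabolic water accumulation:

    dV/dt = [g_aqp·(1 − block(t)) + g_leak] · (N_in/V − C_out(t)) + J_met

Units: conductances in µm³·s⁻¹·mOsM⁻¹, osmolarities in mOsM, time in s.

Consequences used throughout the tests:

* With J_met = 0, the equilibrium is the van't Hoff volume
  V_eq = N_in/C_out (a 300→100 mOsM step triples the volume).
* With J_met > 0 at steady state, the source is balanced by a tonic
  osmotic efflux: the cell sits slightly hyposmotic to the bath.  Blocking
  the aquaporin then forces dV/dt = J_met·(1 − g_leak/g_total) > 0 — the
  cell swells, which is the model-level statement of "blocking AQP4 causes
  water accumulation".  This is a derived property, not an assumption, and
  is verified on a parameter grid.
* With full block and a source, V* = N_in/(C_out − J_met/g_leak).

The source form (`J_met` as a water flux) was chosen over the alternative
of an active solute influx raising C_in; both produce a tonic efflux, but
the water-source form needs one parameter and keeps N_in conserved, which
makes every equilibrium closed-form testable.

Integration is fixed-step classical Runge-Kutta (RK4). `dt` must be at
most one tenth of the linearised relaxation time V0/(g_total·C_max);
coarser steps are rejected rather than silently inaccurate. Trajectories
reaching non-positive volume abort with an error (the parameter regime is
rejected, never clipped). Accuracy is checked against `scipy`'s LSODA at
rtol 1e-10 (< 0.1% everywhere, including across protocol discontinuities).

Defaults: V0 = 4000 µm³, C0_in = 300 mOsM, g_aqp = 2.0, g_leak = 0.5
µm³·s⁻¹·mOsM⁻¹ (aquaporin ≈ 4× the residual pathway), J_met = 0 unless a
tonic-efflux scenario is requested. Bath osmolarity defaults: 300 mOsM
baseline, 100 mOsM hypotonic and 400 mOsM hypertonic challenges.

## Dye-dilution (FIT) rendering and quantification

The renderer draws each cell as a fixed disc (default 50 µm diameter) and
sets the in-cell intensity to `F0_scale·V0/V(t)·exp(−t/bleach_tau)` plus a
flat background offset and white Gaussian noise. The footprint geometry
deliberately does not change with volume: in a fixed field of view the
collected fluorescence tracks dye concentration, so the volume signal is
carried entirely by intensity. True dF/F₀ is V0/V − 1.

The quantification chain mirrors the wet-lab procedure:

1. **Background**: mean over the k = 4 darkest 15×15 µm² tiles in the
   one-tile-deep border band (by temporal mean), evaluated per frame.
   Explicit background regions may be supplied instead and are validated
   against cell ROIs for overlap.
2. **ROI trace**: mean over a 50 µm disc, background-subtracted, floored
   at zero.
3. **Onset**: first run of `m_consec = 5` consecutive samples deviating
   from the pre-stimulus baseline by ≥ `k_sigma = 3` baseline SDs in the
   stated direction, never earlier than the stimulus. These defaults give
   < 1 false onset per 10³ baseline frames under Gaussian noise. A
   zero-SD baseline falls back to an absolute epsilon of
   1e−9·max(1, |baseline mean|) per sigma.
4. **F₀**: mean of the 10 samples immediately preceding the onset sample.
   The apparent circularity (F₀ needs the onset, dF/F₀ needs F₀) is
   resolved by detecting the onset on the background-corrected raw trace
   first.
5. **Response metrics**: peak = directional extremum within a search
   window after the onset (earliest sample wins ties); amplitude is
   |dF/F₀| at the peak; times are referenced to the stimulus. Direction
   convention: hypertonic challenge (shrinking) ⇒ "up", hypotonic
   (swelling) ⇒ "down".
6. **Slopes**: ordinary least squares per window; windows default to the
   full pre/post segments minus 10 s guard bands around the event. Both
   the slope and the net ΔF per phase are reported; the slope is primary.
   An optional exponential bleach detrend exists but is off by default
   (slice traces are analysed raw).

With 2% photon noise and no bleaching, the chain recovers response
amplitudes within 5% relative error and onsets within 2 frames across a
50-scenario grid (this is an acceptance guarantee, not merely typical).

## Ca²⁺ signal strength

Signal strength = trapezoidal integral of dF/F₀ over an analysis window,
divided by the window length in minutes (units dF/F₀·s·min⁻¹);
F₀ = mean of the 20 smallest samples of the trace. The integral is
signed — "temporal integral" is taken literally — with a `rectify` option
(off by default). The statistic is linear in dF/F₀ and additive over
disjoint windows (duration-weighted), both property-tested.

The synthetic generator places double-exponential transients
(τ_rise = 1 s, τ_decay = 4 s, unit-peak normalised, exponentially
distributed amplitudes with mean 0.5 dF/F₀) at Poisson times, 2 events/min
before and 6 events/min after the switch, on a unit baseline with 1% white
noise. The expected strength is rate × mean transient area, so tripling
the rate should triple the statistic; the measured median ratio over 200
traces lies in [2.5, 3.5]. It sits slightly below 3 because the lowest-20
baseline estimate is biased a little low under noise, adding an equal
positive offset to both windows — visible in the generator's analytic
expectation and accepted as part of the statistic's definition.

The active-region detector (per-pixel lowest-20 F₀, 1.4826·MAD robust
noise, ≥ 3 consecutive suprathreshold frames, 8-connected components
above a minimum area) is a deliberately simplified stand-in for dedicated
spatiotemporal screening methods and is labelled as such; it is adequate
for well-separated synthetic sources, and touching sources merge by
construction.

## Photometry detrending

The photobleaching tendency is a least-squares line fitted on
pre-injection data only and extrapolated across the recording. Residual
metrics: level change = mean post-window residual divided by the trend
value at the injection; oscillation range = 5th-to-95th percentile span of
the window's mean-removed residuals (robust to isolated spikes; SD and
peak-to-peak variants selectable).

Two variance sources matter and are documented because they bound what a
passing test shows:

* **Trend-extrapolation drift.** The slope error of a line fitted on
  autocorrelated noise scales with the oscillation SD and correlation
  time; extrapolated over the post segment it inflates the post-window
  range. With the generator's 20 s correlation time the effect is
  negligible for hour-long sessions (30 min pre-injection fit) but
  substantial for 10-minute fits — hence the recovery tests simulate
  hour-long sessions, the realistic length for this assay.
* **Injection transient.** The drug-uptake level ramp (≈ 1 min time
  constant) is a moving level inside the post window that mean removal
  cannot absorb. `detrended_metrics(..., settle_s=300)` starts the post
  window 5 min after the injection so the plateau, not the ramp, is
  measured; the default remains `settle_s = 0` (the plain contract).

The generator's oscillation is an Ornstein–Uhlenbeck process (exact
discretisation) whose stationary SD switches at the injection, plus white
measurement noise; the injection drop ramps in mono-exponentially.

## Intrinsic optical signal and CSD

dT/T₀ uses a per-pixel baseline mean over the pre-stimulation frames
(≥ 5 required); pixels with near-zero baseline are masked. Kymographs
sample dT/T₀ along a line at ~1 px spacing, averaging `width_px = 5`
perpendicular pixels by bilinear interpolation.

The synthetic wave is radial from an origin at speed `speed_um_s`, with
two causal unit-peak double-exponential components delayed by
distance/speed: a fast front (τ = 1/5 s, peak 0.08 dT/T₀) and a slower,
prolonged swelling component (τ = 30/90 s, peak 0.06 dT/T₀). These
defaults were chosen so the superposition is genuinely biphasic (a trough
separates the peaks), as in the recordings this emulates.

Peak metrics: onset via the baseline-band detector (direction up);
peak 1 = first local maximum after onset; peak 2 = largest local maximum
at least `min_separation_s = 20 s` later; peak prominence must exceed the
baseline noise band (3σ) to ignore ripple. Amplitudes are referenced to
the pre-stimulation baseline, with the trough-referenced second-peak
amplitude also reported. Swelling kinetics: speed = maximum forward
difference on the rising limb from the inter-peak trough to peak 2;
duration = contiguous time above half the peak-2 amplitude; recovery =
time from peak 2 to first re-entry into baseline ± 10% of the peak-2
amplitude (absent if never re-entered — note that for an ideal triangular
pulse of half-width w this rule gives 0.9·w analytically).

Wave speed: onsets are detected independently per kymograph row, onset
time is regressed on distance, and speed = 1/slope with a direction sign.
At least 5 onsets are required; a slope below the resolvable epsilon
(half a frame interval across the position span) returns "no propagating
wave" — the correct answer for a global, non-travelling transient. Median
absolute relative error is ≤ 10% across 20–100 µm/s and noise SDs up to
10% of the front amplitude. Speed estimation assumes the line of interest
is radial (passes through the wave origin); an oblique line mixes
distance-to-origin into the position coordinate and biases the estimate
upward.

## Diffusion-weighted MRI

The voxel model is mono-exponential: S(b) = S₀·exp(−b·ADC), fitted by an
unweighted least-squares line through ln S versus b over all b-values
(default 0/250/1800 s/mm²). ADC = −slope, S₀ = exp(intercept). Voxels
with any non-positive signal are flagged failed, excluded from region
means, and counted. No iterative reweighting and no Rician noise-floor
correction are applied: at the SNR regime simulated (50 at b = 0) the
residual median bias is ≈ 0.5% (the b = 1800 signal retains SNR ≈ 8), and
the bound |median bias| ≤ 5% holds with a wide margin; at substantially
lower SNR a floor correction would be needed — a documented limitation.

Region read-outs are map-then-average: ADC is fitted per voxel and then
averaged within each labelled ROI. ΔADC_i = (ADC_i/baseline − 1)×100 %,
with the baseline the mean ADC of the first two scans (acquired before the
injection). A `baseline="scan2"` compatibility option divides by the
second scan alone. ΔADC is invariant to any rescaling of the time course,
and the two baseline scans average to zero by construction.

Phantom QC: a single-region series' maximum |ΔADC| from its basal mean
must stay within 2% for a stable scanner; the simulated 14-scan,
500-voxel, SNR-50 phantom sits near 0.5–0.7%, so the bound is met with
real headroom rather than by luck.

The generator applies Rician noise as the modulus of the complex signal
with i.i.d. Gaussian perturbations of SD S₀/SNR in both quadratures;
direction averaging is considered pre-applied (one signal per b-value),
and motion is out of scope (synthetic series are motion-free; a rigid
registration hook is not provided).

Group summaries over a post-injection window default to the scans falling
30–50 min after the injection (scans 8–12 of the 14-scan, 5-min protocol
with injection after scan 2). Repeated-measures ANOVA across the full
time course is out of scope; per-time-point two-sample tests with Holm
adjustment are the provided substitute.

## Statistics

All tests are two-sided. The t test is the classic pooled-variance
two-sample statistic (Welch optional) or the paired t; the degenerate
all-equal case returns t = 0, p = 1 by convention. Mann-Whitney U is
reported as the U of the first sample (mid-ranks for ties); the p value is
exact when n₁+n₂ ≤ 12 with no ties and otherwise a tie-corrected,
continuity-corrected normal approximation. Exactness is verified against
full enumeration of all group assignments for every n₁, n₂ ≤ 6.
Bonferroni-Holm is the step-down adjustment
adj_(k) = max_{j≤k} min(1, (m−j+1)·p_(j)), implemented directly and
cross-checked against `statsmodels`. Calibration is verified by
simulation: type-I error 0.05 ± 0.01 for the t test and familywise error
≤ nominal for Holm under the complete null (m = 10), both at 10⁴
replicates.

A caveat carried from the study design: figure-level comparisons may
treat either ROIs/astrocytes or animals as the statistical unit; the
`group_compare` table works on whatever unit the caller supplies and both
groupings can be reported, but no nesting/mixed-effects structure is
modelled.

## What the synthetic data do and do not show

The generators reproduce the quantities the pipeline measures (dye
dilution ∝ 1/V, Poisson event statistics, bleaching trends, a radial
biphasic wave, mono-exponential diffusion decay with Rician noise) but not
everything real data contain: no motion or slice drift, no spatially
structured background or autofluorescence, no cell-to-cell parameter
heterogeneity beyond what a scenario sets, no perivascular/IVIM
contribution at b = 250, and footprint geometry that is fixed by
construction. Passing parameter-recovery tests therefore demonstrates the
correctness of the estimators under the stated noise models, not
robustness to every artefact of live-tissue imaging.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to keep the full
suite fast while leaving the statistics meaningful: 64×64–48×100 px
stacks at 1 Hz, 50-scenario FIT grids, 200 Ca²⁺ traces, 15-condition CSD
grids, 10⁴-voxel Monte-Carlo ADC batches and 10⁴-replicate test
calibrations. Every simulation consumes an explicit seed and identical
seeds give byte-identical outputs.
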