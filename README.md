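# aquaflux

Quantification of astrocyte transmembrane water flux and volume dynamics
from optical and MR imaging, for slice/in-vivo physiologists studying
aquaporin-4 (AQP4) water transport.

Astrocytes loaded with a fixed amount of a fluorescent dye (e.g.
sulforhodamine B) report their water content through dye dilution: in a
fixed field of view, fluorescence scales as 1/volume, so swelling dims the
cell and shrinking brightens it (fluorescence-intensity-translated, "FIT",
imaging). This package implements the full measurement chain around that
principle, together with the companion read-outs used to characterise tonic
AQP4-mediated water efflux:

- **fit_imaging** — raw TIFF stacks → background-corrected dF/F₀ traces
  (background from peripheral cell-free 15×15 µm² subregions; 50 µm ROIs;
  F₀ = mean of the 10 samples before the detected change), onset delay,
  time-to-peak and amplitude of osmotically evoked responses, and pre/post
  drug slopes.
- **calcium** — the Ca²⁺ signal-strength statistic: temporal integral of
  dF/F₀ normalised per minute (F₀ = mean of the lowest 20 samples), plus a
  simplified active-region detector.
- **photometry** — fiber-photometry detrending against the photobleaching
  line; injection-locked level change and oscillation range.
- **ios_csd** — intrinsic-optical-signal analysis of cortical spreading
  depression: dT/T₀ conversion, kymographs, biphasic peak metrics,
  swelling kinetics and wave-speed estimation.
- **dwi_adc** — voxelwise apparent diffusion coefficient from
  multi-b-value DWI (log-linear fit of ln S(b) = ln S₀ − b·ADC over
  b = 0/250/1800 s/mm²), region ADC time courses,
  ΔADC_i = (ADC_i/ADC_baseline − 1)×100 % with the first two scans as the
  basal period, and phantom stability QC.
- **stats** — two-sample/paired t tests, Mann-Whitney U (exact for small
  tie-free samples) and Bonferroni-Holm adjustment.
- **synth** — forward models with known ground truth for every modality:
  a single-compartment osmotic volume ODE
  (dV/dt = g·(N_in/V − C_out) + J_met), the dye-dilution stack renderer,
  Poisson-event Ca²⁺ traces, bleaching photometry traces, a propagating
  biphasic CSD wave, and Rician-noise DWI series. Every analysis stage is
  validated by parameter recovery against these generators.

## Worked example

Recover evoked-response kinetics from a rendered dye-dilution stack
(`examples/fit_imaging_recovery.py`):

```sh
$ python examples/fit_imaging_recovery.py
onset delay: 1 s after challenge (truth: 0 s)
time to peak: 40 s
amplitude |dF/F0|: 0.3347 (truth 0.3333, error 0.4%)
```

A hypertonic 300→400 mOsM challenge shrinks the cell toward the van't Hoff
volume N_in/C_out = 0.75·V₀, concentrating the dye; the predicted
fluorescence peak is 1/0.75 − 1 = +0.333 dF/F₀ and the pipeline reads it
back within half a percent from a stack with 1% photon noise. The other
scripts in `examples/` exercise each capability the same way, e.g.:

```sh
$ python examples/dwi_phantom_qc.py
phantom: max |dADC| over 14 scans = 0.53%  (quality bound: 2%)
cortex   : mean dADC after the step = +0.16% (truth +0.00%)
striatum : mean dADC after the step = +6.48% (truth +6.00%)
```

A command-line interface chains the stages into reproducible, manifest-led
runs:

```sh
aquaflux simulate --scenario phantom --seed 7 --out runs/phantom
aquaflux dwi-adc --config cfg.yml --seed 7 --out runs/adc
```

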