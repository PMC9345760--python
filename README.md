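# rdretina

Stage-dependent analysis of retinal ganglion cell (RGC) spike trains in the
degenerating retina, built around the *rd10* mouse model of retinitis
pigmentosa.

As photoreceptors die, the surviving retinal network changes what RGCs —
the retina's output neurons, and the cells a retinal prosthesis must drive
— do with light and with electrical stimulation. This package implements
the standard multi-electrode-array analyses used to track those changes
across degeneration stages (postnatal days P45, P70, P140, P238 vs wild
type), together with a calibrated synthetic spike-train generator so every
analysis can be exercised and validated end-to-end without recorded data.
It is aimed at retinal electrophysiologists and prosthesis researchers
working with sorted spike timestamps.

## What it computes

**Light-response typing.** Spikes are aligned to a full-field flash
protocol (ON 4 s / OFF 4 s, 50 cycles). A cell is classified by comparing
its mean firing rate in the 100 ms after light onset and after light offset
with twice its baseline rate *b* (the cycle-wide mean excluding the two
criterion windows):

    ON     : r_onset  > 2b  only
    OFF    : r_offset > 2b  only
    ON/OFF : both           unresponsive : neither

**Electrically evoked, network-mediated responses.** Spikes are aligned to
biphasic current pulses (500 µs/phase; 1–50 µA ladder, 50 pulses at 1 Hz
per amplitude). Spikes within 10 ms of a pulse are discarded (stimulus
artifact / direct activation), isolating the response relayed through the
surviving bipolar–amacrine network. Per cell the pipeline computes:

* the *electrically responsive* (ER) flag — mean evoked count in the
  (10, 510] ms window strictly exceeds the count expected from the
  spontaneous rate (estimated over the 25 s before stimulation);
* the burst-peak group — local maxima of the 3-bin-smoothed 20 ms-bin
  PSTH above a 2 SD Poisson band: one peak (**single**, the wild-type
  pattern) vs several peaks within 500 ms (**multiple**, the oscillatory
  signature of degeneration);
* the **dominant frequency** of multiple-peak cells — argmax over 2–15 Hz
  of the power spectral density (zero-padded FFT) of the mean-removed
  50 µA PSTH; this tracks the slowing retinal oscillation (≈8.7 Hz at P45
  down to ≈4.4 Hz at P238);
* amplitude–response curves — evoked/spontaneous spike-count ratios in the
  100 ms and 500 ms windows per ladder amplitude.

**Optomotor visual acuity.** Per animal, successful head-tracking trials
define a contrast–resolution frontier; a saturating exponential
r(C) = a·(1 − e^(−kC/100)) is least-squares fitted and acuity is r(100)
in cycles/degree. Blind animals enter group means as 0.

**Statistics.** Student's t (paired/unpaired), one-way ANOVA with Tukey
HSD, and per-stage report assembly.

**Synthetic generator.** Each cell is an inhomogeneous Poisson process
(thinning sampler) whose rate profile encodes its labels: alpha-function
flash transients, Gaussian single-peak bursts with sigmoidal amplitude
gain, damped half-rectified-cosine oscillatory bursts, and mild
stimulus-locked suppression for undriven cells. Stage presets carry the
published population parameters (light-responsive fractions 73/22/10.4/
2.6/0 %, ER fraction ≈40 %, multiple:single ratios 0.70–8.98, oscillation
frequencies 8.7–4.4 Hz, acuities 0.53/0.31/0.04 cyc/°). See
`docs/methods.md` for the model and its calibration.

## Worked example

Simulate one P45 multiple-peak ER cell and characterize it:

```python
import numpy as np
from rdretina import (stage_preset, draw_truth, generate_population,
                      analyze_electrical_train)

preset = stage_preset("RD_P45", n_cells=1, seed=42)
truth = draw_truth(preset, np.random.default_rng(0), force_peak_group="multiple")
ds = generate_population(preset, protocol="electrical", truth=truth)
r = analyze_electrical_train(ds.electrical_trains[0], ds.electrical_events)
print(r.peak_group, [round(t, 3) for t in r.peak_times_s])
print(round(r.dominant_freq_hz, 2), "Hz;",
      round(r.spontaneous_rate_hz, 2), "Hz spontaneous;",
      "100-ms ratio @50uA:", round(r.response_curve_100[50.0], 2))
```

prints

```
multiple [0.04, 0.16, 0.26, 0.36]
9.18 Hz; 9.12 Hz spontaneous; 100-ms ratio @50uA: 2.92
```

— the cell oscillates: four burst peaks ~115 ms apart within 500 ms of the
pulse, a dominant frequency near the P45 population value of 8.7 Hz (this
cell drew a slightly fast oscillation), and a 50 µA response about 2.9×
its spontaneous rate in the first 100 ms.

The same pipeline is scriptable from the shell:

```bash
rdretina simulate --stage RD_P45 --n-cells 300 --protocol both --seed 7 --out sim/
rdretina classify-light --spikes sim/light_spikes.csv --events sim/light_events.csv --out light.csv
rdretina analyze-electrical --spikes sim/electrical_spikes.csv --events sim/electrical_events.csv --out elec.csv
rdretina run-all --stage RD_P45 --n-cells 30 --seed 7 --out out/
```

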