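# Methods

This note documents the models, estimators and conventions behind
`rdretina`: what the analysis pipeline assumes, how the synthetic
degenerating-retina generator is built and calibrated, and which design
choices were genuinely open.

## Analysis pipeline

### Timebase and binning

All times are seconds (float64) from recording start. Histogram bins are
half-open `[a, b)`: a spike exactly on an interior edge belongs to the bin
to its right, and a spike exactly at a trial window's right edge belongs to
the next trial. This matters for 1 Hz pulse trains, whose ±500 ms windows
abut exactly — no spike is ever counted twice. Bin membership is resolved
by `searchsorted` against the materialized edge array, so binned counting
and interval counting compare spikes against identical floats (a tie at a
criterion threshold must not flip on `4.1 - 4.0 != 0.1` artifacts; window
rates divide by nominal window length for the same reason).

### Light-response typing

The flash cycle (ON 4 s / OFF 4 s, 50 cycles) has no long dark stretch, so
the spontaneous reference is defined as the cycle-wide mean rate excluding
the two 100 ms criterion windows — 7.8 s of every cycle, which keeps the
baseline stable even for low-rate cells. The criterion compares *rates*
(count / 0.1 s / n_trials vs 2x baseline in Hz), a deliberate resolution of
the ambiguity between comparing counts and comparing rates: it makes the
two sides dimensionally commensurable and independent of trial count.
Exceedance is strict (`>`): a cell exactly at twice baseline is not
responsive. Zero-spike cells are retained and classified unresponsive
(population denominators count all recorded cells). Criterion windows are
`(0, 100 ms]` after the onset/offset transition.

### Electrically evoked responses

* **Artifact exclusion.** Relative times in `(0, 10 ms]` are removed.
  Everything downstream is network-mediated by construction; direct
  (sub-10 ms) responses are out of scope.
* **Spontaneous rate.** Count in the 25 s before the first pulse / 25 s.
  If less than 25 s is available the full pre-stimulus span is used and the
  record is flagged (`short_window`).
* **ER criterion.** Mean spikes per trial in `(10, 510] ms` at the maximal
  amplitude (50 µA) strictly greater than `spontaneous_rate x 0.5 s`.
  The maximal-amplitude choice is a documented decision: it is the
  amplitude at which a responsive cell is most separable from baseline.
* **Peak detection.** The 20 ms-bin PSTH over `(10, 510] ms` is smoothed
  with a 3-bin moving average; peaks are local maxima above
  `spont + 2*sqrt(spont/(bin_width * n_trials))` (a 2 SD Poisson band
  around the baseline rate) separated by >= 2 bins. This is the smallest
  detector whose failure modes are analyzable; all three constants are
  exposed as arguments. 0/1/>=2 peaks map to none/single/multiple.
* **Dominant frequency.** PSTH of the 50 pulses at 50 µA over the full 1 s
  inter-pulse interval (50 bins on the artifact-excluded raster), mean
  removed, zero-padded to 4096 samples; PSD = squared FFT magnitude;
  estimate = argmax over 2–15 Hz. The 1 s window is an interpretation
  choice: a 0.5 s window has a 2 Hz native grid from which sub-hertz group
  means cannot arise, whereas the 1 s window plus zero-padding yields a
  ~0.012 Hz interpolated grid. The band excludes DC leakage (< 2 Hz) and
  comfortably brackets the 4–9 Hz degenerate-retina oscillation. The
  estimator carries an intrinsic few-hundredths-of-Hz uncertainty from
  interference with the conjugate spectral kernel of a finite-length
  oscillation, and a damping-dependent bias up to ~0.2 Hz for the most
  heavily damped profiles — both negligible against the 0.5 Hz scale of
  the stage differences, but visible in noiseless tests.
* **Response curves.** `ratio(I) = mean spikes/trial in
  (10 ms, 10 ms + W] / (spont * W)` for W = 100 and 500 ms. Zero
  spontaneous rate yields a missing ratio, never infinity.

### Optomotor acuity

Per animal and contrast, the frontier is the highest spatial resolution
with a successful trial (0 cyc/° when no trial succeeds at that contrast).
The contrast–resolution curve is modelled as a saturating exponential
`r(C) = a(1 - exp(-kC/100))` — the "exponential regression" convention for
optomotor data — and visual acuity is r(100). Fitting is a coarse grid
search (a over [0, 0.7] in 0.01 steps, k log-spaced over [0.1, 20])
polished by a bounded trust-region pass: deterministic for fixed data,
robust to non-monotone frontiers, and exact for the all-zero frontier.
Animals without a fittable frontier (or with no responses) enter group
means as acuity 0 — blind animals count.

### Statistics

Student's t (pooled variance by default, Welch and paired options) and
one-way ANOVA with Tukey-HSD pairwise p-values, computed via scipy.stats.
Degenerate all-equal inputs use the t = 0, p = 1 convention rather than
NaN. Duncan's multiple-range test is deliberately omitted: it adds no
decision the Tukey p-values do not already support.

## Synthetic generator

### Model

Every cell is an inhomogeneous Poisson process sampled by thinning
(candidates at the profile's stated maximum, kept with probability
rate/max). There is no refractoriness and no inter-cell correlation; at
the firing rates involved (≈4–20 Hz baseline) refractory effects are
irrelevant to every criterion the pipeline applies. Baseline rates are
log-normal across cells (median 10 Hz for rd10 — degeneration-driven
hyperactivity — vs 4 Hz wild type; sigma = 0.25 log units).

Label-dependent rate profiles:

* **Flash transients** (ON/OFF/ON-OFF cells): alpha function
  `(t/tau)e^(1-t/tau)` with tau = 25 ms and peak 40 Hz, after onset,
  offset, or both. >90% of the added mass falls inside the 100 ms
  criterion window (closed form: `1-(1+x)e^(-x)` at x = 4).
* **Single-peak pulse response**: Gaussian burst, center 40 ms, sd 15 ms,
  peak 25 Hz (rd10) / 80 Hz (WT), scaled by the amplitude gain
  `g(I) = sigmoid((I - 25 µA)/8 µA)` normalized to 1 at 50 µA.
* **Multiple-peak pulse response**: damped half-rectified cosine,
  first crest at 40 ms, per-cell frequency `f ~ N(f_stage, 0.7 Hz)`,
  envelope `exp(-t/tau_stage)`, crest amplitude 55 Hz. Only the first
  crest follows the amplitude gain at P45–P140 (later crests are
  amplitude-insensitive, reproducing flat 500 ms response curves); at
  P238 the gain scales every crest, so both the 100 ms and 500 ms windows
  rise with amplitude.
* **Suppression.** ER cells' baseline is scaled by 0.9 over (0.1, 0.5] s
  post-pulse (post-burst inhibition); cells that electrical stimulation
  fails to drive are scaled by 0.75 over (0, 0.5] s. These terms are the
  one deliberate departure from a purely additive model, for two reasons.
  First, identifiability: with a purely additive model an undriven cell
  passes "fires more than spontaneous" half the time, since the test then
  compares two unbiased noisy estimates of the same rate, and no ~40% ER
  fraction could ever be recovered to binomial precision. Second, realism
  of the curve shapes: a rising 100 ms ratio next to a 500 ms ratio
  pinned at ~1.0 arithmetically requires below-baseline firing somewhere
  in 100–500 ms. Stimulus-locked suppression of undriven/post-burst
  retina is the standard account of both.

### Stage presets

| stage | light ON/OFF/ON-OFF/unresp (%) | multi-peak fraction | f_osc (Hz) | tau (s) |
|---|---|---|---|---|
| WT_P70 | 18 / 17 / 38 / 27 | 0 | – | – |
| RD_P45 | 18.15 / 3.29 / 0.43 / 78.13 | 0.70/1.70 | 8.7 | 0.25 |
| RD_P70 | 8.8 / 0.8 / 0.8 / 89.6 | 1.78/2.78 | 6.8 | 0.30 |
| RD_P140 | 2.2 / 0.2 / 0.2 / 97.4 | 1.80/2.80 | 4.6 | 0.45 |
| RD_P238 | 0 / 0 / 0 / 100 | 8.98/9.98 | 4.4 | 0.24 |

ER fraction is 0.40 at every stage. Multi-peak fractions are r/(1+r) from
the published multiple:single count ratios. The P70/P140 subtype splits
are a generator convention (only the responsive totals 10.4% and 2.6% are
published); they are ON-dominant because the ON pathway outlives the OFF
pathway in this model of degeneration. The decay constants tau are
calibrated on the noiseless canonical profile (baseline at the population
median) so that at least three crests clear the peak-detection threshold
within 500 ms at P45–P140 and exactly two at P238 — the published
late-stage phenotype. The 0.7 Hz cell-level frequency jitter matches the
dispersion implied by published per-stage standard errors and is what
makes the P140-vs-P238 difference (0.2 Hz) statistically indistinguishable
at n = 30 cells while each stage mean still recovers to ±0.5 Hz.

Free constants (burst amplitudes, gain threshold/slope, baseline medians,
suppression depths) were fixed once by power analysis against the recovery
bands the package tests (2-binomial-SD label recovery, strict 100 ms curve
increase over 10–50 µA with the 500 ms curve within 1.0 ± 0.15, reliable
crest-2 detection across the baseline-rate spread) — they are generator
conventions, not empirical claims.

### Optomotor presets

Latent frontier `a(1 - e^(-kC/100))/(1 - e^(-k))` + Gaussian scatter,
truncated to the instrument range [0, 0.7] cyc/°; the normalization makes
the noiseless frontier at 100% contrast equal the preset acuity exactly.
Group acuities: WT 0.53 (scatter sd 0.03), P45 0.31 (sd 0.08, the
high-variability stage), P164 0.04 (sd 0.05), late-stage 0.0 (sd 0, no
successful trial at any contrast). Trials sweep a 0.01 cyc/° resolution
grid at contrasts 25/50/75/100%; success iff resolution <= frontier.

### What the generator does not emulate

No biophysics (no AII-amacrine/bipolar coupling model), no electrode
geometry or distance effects, no local field potentials, no direct
(sub-10 ms) responses, no refractoriness, no inter-cell correlation, no
drift or non-stationarity, and no spike-sorting errors. Passing recovery
tests therefore show that the pipeline's estimators invert this generative
family at realistic rates and trial counts — not that they are robust to
sorting artifacts or correlated oscillatory populations in recorded data.

## Recovery experiments and problem sizes

The end-to-end checks (`rdretina.recovery`, exercised by the test suite
and `scripts/acceptance.py`) use stratified cohorts: class labels are
allocated in exact preset proportions (largest-remainder rounding) and
only within-cell randomness is stochastic. A recovery experiment should
measure pipeline fidelity, not the binomial noise of a label draw; the
i.i.d. label path keeps its own convergence test. Cohort sizes: 30
multiple-peak cells per stage for dominant-frequency means, 2000 ER cells
for peak-group mixtures, 10000 cells for light/ER fraction recovery,
100/60 cells for mean response curves, 6 animals per optomotor group —
sizes at which the binomial/normal bands quoted above have useful power
while a full run stays within a few minutes on one CPU. Populations are
generated and analyzed in 1000-cell chunks with seeds spawned
deterministically from the experiment seed, so memory stays flat and
results are reproducible.

## Known limitations

* The dominant-frequency estimator inherits a small damping-dependent bias
  (up to ~+0.2 Hz at heavy damping) from taking the argmax of the PSD of a
  short, decaying, rectified oscillation.
* The ER criterion's margin for single-peak rd10 cells is intrinsically
  thin: the criterion window coincides with the 500 ms response-curve
  window, so a burst large enough to be detected with near certainty would
  push the 500 ms ratio visibly above 1. With the chosen burst mass
  (~0.9 spikes/trial) roughly one in ten single-peak ER cells fails the
  criterion; population ER fractions recover to ~38–40%.
* Multiple-peak cells drawn with very slow oscillations (< ~3 Hz, ~2% of
  cells at P238) can place their second crest too late/weak to detect,
  slightly deflating the recovered late-stage multiple:single ratio.
* `read_spike_table` loads whole files into memory; recordings are a few
  hundred seconds at tens of Hz, so this is far from a constraint.
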