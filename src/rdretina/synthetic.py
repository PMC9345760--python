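"""Synthetic degenerating-retina data generator.

Generates spike-train populations and optomotor sessions with the
statistical structure the analysis pipeline assumes, under per-stage presets
calibrated to published population parameters of the rd10 mouse model
(light-responsive fractions, electrically responsive fraction, single- vs
multiple-peak mixture, oscillation frequency of the network-mediated
response, and behavioral visual acuity).

Model
-----
Each cell fires as an inhomogeneous Poisson process (thinning sampler) whose
rate is a stage- and label-dependent profile on top of a log-normal
population of baseline rates:

* light ON/OFF/ON-OFF cells add an alpha-function transient (time constant
  25 ms, >90% of its mass inside 100 ms) after light onset, offset, or both;
* electrically responsive (ER) single-peak cells add a Gaussian burst
  (center 40 ms, sd 15 ms) after each pulse, scaled by a sigmoidal
  amplitude gain, followed by a mild post-burst baseline suppression;
* ER multiple-peak cells add a damped half-rectified cosine train (first
  crest at 40 ms, stage-dependent frequency and decay);
* non-ER cells show a mild stimulus-locked suppression, the generative
  counterpart of "electrical stimulation fails to drive the cell".

The suppression terms are deliberate departures from a purely additive
model: without them a flat cell passes the "fires more than spontaneous"
test half the time (two unbiased estimates of the same rate), and the
published flat 500-ms response curves next to rising 100-ms curves
themselves imply below-baseline firing at 100-500 ms post-pulse.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .spike_data import (
    AMPLITUDE_LADDER_UA,
    SpikeTrain,
    StimulusEvents,
    electrical_protocol,
    light_protocol,
)

__all__ = [
    "STAGES",
    "StagePreset",
    "OptomotorPreset",
    "SyntheticDataset",
    "stage_preset",
    "optomotor_preset",
    "sample_inhomogeneous_poisson",
    "light_rate_profile",
    "electrical_rate_profile",
    "amplitude_gain",
    "draw_truth",
    "generate_population",
    "generate_optomotor_session",
]

STAGES = ("WT_P70", "RD_P45", "RD_P70", "RD_P140", "RD_P238")

LIGHT_TYPES = ("ON", "OFF", "ONOFF", "unresponsive")

#: Alpha-function time constant of the flash-evoked transient (s).
LIGHT_TAU_S = 0.025

#: First-crest / burst-center latency of the pulse-evoked response (s).
BURST_CENTER_S = 0.040

#: Gaussian width of the single-peak burst (s).
BURST_SD_S = 0.015


class PresetError(ValueError):
    """Raised when a preset violates its invariants."""


@dataclass
class StagePreset:
    """Generative parameters of one degeneration stage.

    Attributes
    ----------
    light_fractions : tuple
        ``(p_ON, p_OFF, p_ONOFF, p_unresponsive)``, summing to 1.
    er_fraction : float
        Probability a cell responds to electrical stimulation (~0.40 at
        every stage).
    multi_peak_fraction : float
        Probability an ER cell belongs to the multiple-peak group; derived
        from the published multiple:single count ratios r as r/(1+r).
    f_osc_hz : float
        Population oscillation frequency of multiple-peak responses; each
        cell gets ``f_osc_hz + N(0, f_osc_jitter_hz)``. The cell-level
        dispersion (0.7 Hz) matches the magnitude implied by published
        per-stage standard errors, and makes the P140-P238 saturation
        (a 0.2 Hz population difference) statistically indistinguishable
        at realistic sample sizes, as observed.
    osc_decay_tau_s : float
        Exponential damping constant of the crest train, calibrated so that
        at least three crests clear the peak-detection threshold within
        500 ms at P45-P140 and exactly two at P238.
    spont_rate_median_hz, spont_rate_log_sd : float
        Log-normal baseline-rate population (median in Hz, sd of the log).
        rd10 baselines exceed WT (degeneration-driven hyperactivity).
    gain_threshold_uA, gain_slope_uA : float
        Sigmoidal amplitude gain ``sigmoid((I - threshold)/slope)``,
        normalized to 1 at 50 uA; subthreshold amplitudes (1-5 uA) leave
        the profile essentially at baseline.
    single_peak_rate_hz : float
        Peak added rate of the single-peak burst at 50 uA.
    osc_peak_rate_hz : float
        First-crest added rate of the multiple-peak response at 50 uA.
    scale_all_crests : bool
        P238 only: the amplitude gain scales every crest (both windows of
        the response curve then rise with amplitude); at earlier stages
        later crests are amplitude-insensitive, reproducing flat 500-ms
        curves.
    er_suppression, non_er_suppression : float
        Multiplicative baseline factors, ER cells over (0.1, 0.5] s and
        non-ER cells over (0, 0.5] s post-pulse.
    """

    stage: str
    n_cells: int = 100
    light_fractions: tuple[float, float, float, float] = (0.18, 0.17, 0.38, 0.27)
    er_fraction: float = 0.40
    multi_peak_fraction: float = 0.0
    f_osc_hz: float = 6.0
    f_osc_jitter_hz: float = 0.7
    osc_decay_tau_s: float = 0.3
    spont_rate_median_hz: float = 10.0
    spont_rate_log_sd: float = 0.25
    gain_threshold_uA: float = 25.0
    gain_slope_uA: float = 8.0
    single_peak_rate_hz: float = 25.0
    osc_peak_rate_hz: float = 55.0
    light_peak_rate_hz: float = 40.0
    scale_all_crests: bool = False
    er_suppression: float = 0.9
    non_er_suppression: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise PresetError(f"unknown stage {self.stage!r}")
        fr = np.asarray(self.light_fractions, dtype=float)
        if fr.size != 4 or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise PresetError("light_fractions must be 4 non-negative values summing to 1")
        for name in ("er_fraction", "multi_peak_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PresetError(f"{name} must be in [0, 1]")
        if self.f_osc_hz <= 0 or self.osc_decay_tau_s <= 0:
            raise PresetError("f_osc_hz and osc_decay_tau_s must be > 0")
        if self.n_cells < 1:
            raise PresetError("n_cells must be >= 1")

    def replace(self, **kw) -> "StagePreset":
        return dataclasses.replace(self, **kw)


# Published population parameters per stage. Light fractions:
# WT 18/17/38/27%; P45 18.15/3.29/0.43%; P70 and P140 totals 10.4% and 2.6%
# with ON-dominant splits (the ON response outlives the OFF response);
# P238 has no light-responsive cells. Multiple:single count ratios
# 0.70, 1.78, 1.80, 8.98 give the multiple-peak mixture r/(1+r); the
# oscillation slows from 8.7 to 4.4 Hz across stages.
_STAGE_TABLE: dict[str, dict] = {
    "WT_P70": dict(
        light_fractions=(0.18, 0.17, 0.38, 0.27),
        multi_peak_fraction=0.0,
        f_osc_hz=6.0,            # unused: WT has no multiple-peak cells
        osc_decay_tau_s=0.3,
        spont_rate_median_hz=4.0,
        single_peak_rate_hz=80.0,
    ),
    "RD_P45": dict(
        light_fractions=(0.1815, 0.0329, 0.0043, 0.7813),
        multi_peak_fraction=0.70 / 1.70,
        f_osc_hz=8.7,
        osc_decay_tau_s=0.25,
    ),
    "RD_P70": dict(
        light_fractions=(0.088, 0.008, 0.008, 0.896),
        multi_peak_fraction=1.78 / 2.78,
        f_osc_hz=6.8,
        osc_decay_tau_s=0.30,
    ),
    "RD_P140": dict(
        light_fractions=(0.022, 0.002, 0.002, 0.974),
        multi_peak_fraction=1.80 / 2.80,
        f_osc_hz=4.6,
        osc_decay_tau_s=0.45,
    ),
    "RD_P238": dict(
        light_fractions=(0.0, 0.0, 0.0, 1.0),
        multi_peak_fraction=8.98 / 9.98,
        f_osc_hz=4.4,
        osc_decay_tau_s=0.24,
        scale_all_crests=True,
    ),
}


def stage_preset(stage: str, n_cells: int = 100, seed: int = 0, **overrides) -> StagePreset:
    """Build the calibrated preset of one degeneration stage."""
    if stage not in _STAGE_TABLE:
        raise PresetError(f"unknown stage {stage!r}; choose from {STAGES}")
    kw = dict(_STAGE_TABLE[stage])
    kw.update(overrides)
    return StagePreset(stage=stage, n_cells=n_cells, seed=seed, **kw)


@dataclass
class OptomotorPreset:
    """Generative parameters of an optomotor session group.

    The contrast-resolution frontier of each animal follows a saturating
    exponential normalized so that the frontier at 100% contrast equals
    ``true_acuity_cpd`` exactly, plus Gaussian trial scatter truncated to
    the instrument's 0-0.7 cyc/deg range.
    """

    true_acuity_cpd: float
    shape_k: float = 1.5
    frontier_noise_sd_cpd: float = 0.03
    contrast_levels: tuple[float, ...] = (25.0, 50.0, 75.0, 100.0)
    n_animals: int = 6
    resolution_step_cpd: float = 0.01
    max_resolution_cpd: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_acuity_cpd <= 0.7:
            raise PresetError("true_acuity_cpd must lie in [0, 0.7]")
        if any(not 0.0 < c <= 100.0 for c in self.contrast_levels):
            raise PresetError("contrast levels must lie in (0, 100]")


# Group acuities (cyc/deg): WT 0.53, rd10 P45 0.31, rd10 P164 0.04; animals
# past ~P170 show no optomotor response at any contrast.
_OPTO_TABLE = {
    "WT": dict(true_acuity_cpd=0.53, frontier_noise_sd_cpd=0.03),
    "RD_P45": dict(true_acuity_cpd=0.31, frontier_noise_sd_cpd=0.08),
    "RD_P164": dict(true_acuity_cpd=0.04, frontier_noise_sd_cpd=0.05),
    "RD_LATE": dict(true_acuity_cpd=0.0, frontier_noise_sd_cpd=0.0),
}


def optomotor_preset(group: str, n_animals: int = 6, seed: int = 0, **overrides) -> OptomotorPreset:
    if group not in _OPTO_TABLE:
        raise PresetError(f"unknown optomotor group {group!r}; choose from {list(_OPTO_TABLE)}")
    kw = dict(_OPTO_TABLE[group])
    kw.update(overrides)
    return OptomotorPreset(n_animals=n_animals, seed=seed, **kw)


@dataclass
class SyntheticDataset:
    """Generated population with ground truth.

    ``truth`` has one row per cell: cell_id, light_type, er, peak_group,
    f_osc_hz (NaN for cells outside the multiple-peak group).
    """

    truth: pd.DataFrame
    light_trains: list[SpikeTrain] = field(default_factory=list)
    electrical_trains: list[SpikeTrain] = field(default_factory=list)
    light_events: StimulusEvents | None = None
    electrical_events: StimulusEvents | None = None


# ---------------------------------------------------------------------------
# Rate profiles
# ---------------------------------------------------------------------------

def _alpha(t: np.ndarray, tau: float) -> np.ndarray:
    """Unit-peak alpha function (t/tau) e^(1 - t/tau), zero for t < 0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / tau
    out[pos] = x * np.exp(1.0 - x)
    return out


def light_rate_profile(cell_type: str, t_in_cycle: np.ndarray | float,
                       base_hz: float, preset: StagePreset) -> np.ndarray:
    """Firing rate (Hz) of one cell at phase ``t_in_cycle`` of the 8 s flash cycle.

    ON cells add an alpha-function transient after light onset (t = 0), OFF
    cells after light offset (t = 4 s), ON/OFF cells after both; unresponsive
    cells sit at baseline throughout.
    """
    if cell_type not in LIGHT_TYPES:
        raise PresetError(f"unknown light type {cell_type!r}")
    t = np.atleast_1d(np.asarray(t_in_cycle, dtype=float))
    rate = np.full_like(t, float(base_hz))
    a = preset.light_peak_rate_hz
    if cell_type in ("ON", "ONOFF"):
        rate += a * _alpha(t, LIGHT_TAU_S)
    if cell_type in ("OFF", "ONOFF"):
        rate += a * _alpha(t - 4.0, LIGHT_TAU_S)
    return rate if np.ndim(t_in_cycle) else float(rate[0])


def amplitude_gain(amplitude_uA: np.ndarray | float, preset: StagePreset) -> np.ndarray:
    """Sigmoidal pulse-amplitude gain, normalized to 1 at 50 uA."""
    i = np.asarray(amplitude_uA, dtype=float)
    s = 1.0 / (1.0 + np.exp(-(i - preset.gain_threshold_uA) / preset.gain_slope_uA))
    s50 = 1.0 / (1.0 + np.exp(-(50.0 - preset.gain_threshold_uA) / preset.gain_slope_uA))
    return s / s50


def electrical_rate_profile(group: str, t_after_pulse: np.ndarray | float,
                            amplitude_uA: float, preset: StagePreset,
                            base_hz: float, f_osc_hz: float | None = None,
                            ) -> np.ndarray:
    """Firing rate (Hz) at ``t_after_pulse`` seconds after one pulse.

    ``group`` is the cell's response class: ``single`` (Gaussian burst at
    40 ms), ``multiple`` (damped half-rectified cosine, first crest at
    40 ms), or ``none`` (non-ER: suppressed baseline). The evoked terms add
    nothing below 10 ms beyond the Gaussian's small left tail, which the
    artifact-exclusion step removes anyway; direct (sub-10 ms) responses are
    deliberately not modelled.
    """
    if amplitude_uA not in AMPLITUDE_LADDER_UA:
        raise PresetError(f"amplitude {amplitude_uA} uA not in the ladder")
    if group not in ("single", "multiple", "none"):
        raise PresetError(f"unknown response group {group!r}")
    t = np.atleast_1d(np.asarray(t_after_pulse, dtype=float))
    gain = float(amplitude_gain(amplitude_uA, preset))

    if group == "none":
        rate = base_hz * np.where((t > 0) & (t <= 0.5), preset.non_er_suppression, 1.0)
    else:
        rate = base_hz * np.where(
            (t > 0.1) & (t <= 0.5), preset.er_suppression, 1.0
        )
        if group == "single":
            rate = rate + preset.single_peak_rate_hz * gain * np.exp(
                -0.5 * ((t - BURST_CENTER_S) / BURST_SD_S) ** 2
            )
        else:
            f = preset.f_osc_hz if f_osc_hz is None else float(f_osc_hz)
            osc = np.cos(2.0 * np.pi * f * (t - BURST_CENTER_S))
            env = np.where((t >= 0) & (osc > 0), osc, 0.0) * np.exp(
                -np.maximum(t, 0.0) / preset.osc_decay_tau_s
            )
            # first lobe (the crest at 40 ms) is always amplitude-scaled;
            # later crests follow the gain only when scale_all_crests is set
            first_lobe = t <= BURST_CENTER_S + 1.0 / (4.0 * f)
            crest_gain = np.where(
                first_lobe | preset.scale_all_crests, gain, 1.0
            )
            rate = rate + preset.osc_peak_rate_hz * crest_gain * env
    return rate if np.ndim(t_after_pulse) else float(rate[0])


# ---------------------------------------------------------------------------
# Poisson sampling
# ---------------------------------------------------------------------------

def sample_inhomogeneous_poisson(rate_fn: Callable[[np.ndarray], np.ndarray],
                                 duration_s: float, rate_max_hz: float,
                                 rng: np.random.Generator | int,
                                 ) -> np.ndarray:
    """Draw spike times from an inhomogeneous Poisson process by thinning.

    ``rate_fn`` maps an array of times (s) to rates (Hz); it must be
    non-negative and bounded by ``rate_max_hz``. Candidates are drawn as a
    homogeneous process at ``rate_max_hz`` and kept with probability
    ``rate(t)/rate_max_hz``. Reproducible for a given generator/seed.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if rate_max_hz < 0:
        raise PresetError("rate_max_hz must be >= 0")
    if rate_max_hz == 0:
        return np.empty(0)
    n = rng.poisson(rate_max_hz * duration_s)
    t = np.sort(rng.uniform(0.0, duration_s, size=n))
    r = np.asarray(rate_fn(t), dtype=float)
    if np.any(r < -1e-12):
        raise PresetError("rate function returned a negative rate")
    if np.any(r > rate_max_hz * (1 + 1e-9)):
        raise PresetError("rate function exceeds its stated bound")
    keep = rng.uniform(0.0, 1.0, size=n) < r / rate_max_hz
    return t[keep]


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------

def draw_truth(preset: StagePreset, rng: np.random.Generator,
               force_er: bool | None = None,
               force_peak_group: str | None = None) -> pd.DataFrame:
    """Draw per-cell ground-truth labels from the preset's mixture fractions.

    ``force_er`` / ``force_peak_group`` condition the population on a class
    (e.g. an all-ER cohort, or an all-multiple-peak cohort) while every
    other label is still drawn from the preset.
    """
    n = preset.n_cells
    light = rng.choice(LIGHT_TYPES, size=n, p=np.asarray(preset.light_fractions))
    er = rng.uniform(size=n) < preset.er_fraction
    multi = rng.uniform(size=n) < preset.multi_peak_fraction
    if force_er is not None:
        er = np.full(n, bool(force_er))
    if force_peak_group is not None:
        if force_peak_group not in ("single", "multiple", "none"):
            raise PresetError(f"unknown peak group {force_peak_group!r}")
        multi = np.full(n, force_peak_group == "multiple")
        er = np.full(n, force_peak_group != "none")
    peak_group = np.where(er, np.where(multi, "multiple", "single"), "none")
    f_osc = np.where(
        peak_group == "multiple",
        preset.f_osc_hz + preset.f_osc_jitter_hz * rng.standard_normal(n),
        np.nan,
    )
    spont = preset.spont_rate_median_hz * np.exp(
        preset.spont_rate_log_sd * rng.standard_normal(n)
    )
    return pd.DataFrame(
        {
            "cell_id": [f"{preset.stage}_c{i:05d}" for i in range(n)],
            "light_type": light,
            "er": er,
            "peak_group": peak_group,
            "f_osc_hz": f_osc,
            "spont_rate_hz": spont,
        }
    )


def _light_rate_fn(row, preset: StagePreset):
    base = row.spont_rate_hz

    def fn(t: np.ndarray) -> np.ndarray:
        return light_rate_profile(row.light_type, np.mod(t, 8.0), base, preset)

    return fn, base + preset.light_peak_rate_hz


def _electrical_rate_fn(row, preset: StagePreset, events: StimulusEvents):
    base = row.spont_rate_hz
    group = row.peak_group
    f_osc = None if np.isnan(row.f_osc_hz) else row.f_osc_hz
    onsets = events.onsets
    amps = events.amplitudes_uA
    ladder = sorted(set(amps))

    def fn(t: np.ndarray) -> np.ndarray:
        # map each time to its preceding pulse (if any, within 1 s)
        idx = np.searchsorted(onsets, t, side="right") - 1
        idx = np.clip(idx, 0, len(onsets) - 1)
        dt = t - onsets[idx]
        rate = np.full(t.shape, float(base))
        active = (dt >= 0) & (dt < 1.0)
        for amp in ladder:
            sel = active & (amps[idx] == amp)
            if np.any(sel):
                rate[sel] = electrical_rate_profile(
                    group, dt[sel], amp, preset, base, f_osc
                )
        return rate

    peak = {"none": 0.0, "single": preset.single_peak_rate_hz,
            "multiple": preset.osc_peak_rate_hz}[group]
    return fn, base + peak


def generate_population(preset: StagePreset,
                        protocol: Literal["light", "electrical", "both"] = "both",
                        truth: pd.DataFrame | None = None) -> SyntheticDataset:
    """Generate a labelled population under the flash and/or pulse protocol.

    Labels are drawn from the preset's fractions unless an explicit
    ``truth`` table is supplied (used to condition on a class, e.g. an
    all-ER or all-multiple-peak population). Identical preset + seed gives
    a byte-identical dataset.
    """
    if protocol not in ("light", "electrical", "both"):
        raise PresetError(f"unknown protocol {protocol!r}")
    root = np.random.SeedSequence(preset.seed)
    label_ss, light_ss, elec_ss = root.spawn(3)
    if truth is None:
        truth = draw_truth(preset, np.random.default_rng(label_ss))
    else:
        truth = truth.reset_index(drop=True)
        if truth["cell_id"].duplicated().any():
            raise PresetError("truth table must cover every cell_id exactly once")

    ds = SyntheticDataset(truth=truth)
    if protocol in ("light", "both"):
        events = light_protocol()
        duration = float(events.onsets[-1] + 8.0)
        rngs = [np.random.default_rng(s) for s in light_ss.spawn(len(truth))]
        trains = []
        for row, rng in zip(truth.itertuples(index=False), rngs):
            fn, rmax = _light_rate_fn(row, preset)
            times = sample_inhomogeneous_poisson(fn, duration, rmax, rng)
            trains.append(SpikeTrain(row.cell_id, times, duration))
        ds.light_trains, ds.light_events = trains, events
    if protocol in ("electrical", "both"):
        events = electrical_protocol()
        duration = float(events.onsets[-1] + 1.0)
        rngs = [np.random.default_rng(s) for s in elec_ss.spawn(len(truth))]
        trains = []
        for row, rng in zip(truth.itertuples(index=False), rngs):
            fn, rmax = _electrical_rate_fn(row, preset, events)
            times = sample_inhomogeneous_poisson(fn, duration, rmax, rng)
            trains.append(SpikeTrain(row.cell_id, times, duration))
        ds.electrical_trains, ds.electrical_events = trains, events
    return ds


# ---------------------------------------------------------------------------
# Optomotor sessions
# ---------------------------------------------------------------------------

def generate_optomotor_session(preset: OptomotorPreset) -> pd.DataFrame:
    """Generate optomotor trials for ``n_animals`` animals.

    For each animal and contrast C the latent frontier is
    ``a (1 - exp(-k C/100)) / (1 - exp(-k)) + noise`` truncated to
    [0, 0.7] cyc/deg, so the noiseless frontier at 100% contrast equals the
    preset's true acuity exactly. Trials sweep the spatial-resolution grid;
    a trial succeeds iff its resolution does not exceed the frontier, so
    successes and failures bracket the frontier. An animal with a zero
    frontier everywhere produces no successful trial at any contrast.
    """
    rng = np.random.default_rng(preset.seed)
    grid = np.arange(
        preset.resolution_step_cpd,
        preset.max_resolution_cpd + 1e-9,
        preset.resolution_step_cpd,
    )
    a, k = preset.true_acuity_cpd, preset.shape_k
    rows = []
    for animal in range(preset.n_animals):
        for c in preset.contrast_levels:
            shape = (1.0 - np.exp(-k * c / 100.0)) / (1.0 - np.exp(-k))
            frontier = a * shape + preset.frontier_noise_sd_cpd * rng.standard_normal()
            frontier = float(np.clip(frontier, 0.0, preset.max_resolution_cpd))
            for res in grid:
                rows.append(
                    {
                        "animal_id": f"m{animal:02d}",
                        "contrast_pct": float(c),
                        "spatial_resolution_cpd": float(res),
                        "success": bool(res <= frontier),
                    }
                )
    return pd.DataFrame(rows)
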