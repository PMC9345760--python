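"""Parameter-recovery experiments: generate a stage population, run the
full analysis pipeline on it, and measure the recovered quantity.

These are the package's end-to-end self-checks — each function simulates a
population under a calibrated stage preset, pushes every cell through the
same entry points a user would call on recorded data, and returns the
population-level estimate (mean dominant frequency, peak-group count ratio,
light-responsive fraction, electrically responsive fraction, mean
amplitude-response curves, group mean acuity).

Design note: recovery cohorts are *stratified* — class labels are allocated
in exact preset proportions (largest-remainder rounding) and only the
within-cell randomness (baseline rate, oscillation frequency, spiking) is
drawn stochastically. Conditioning the cohort composition this way makes a
recovery experiment measure what it is meant to measure, the fidelity of
the analysis pipeline, instead of mixing in the binomial noise of a label
draw. The unconditioned i.i.d. label path of
:func:`rdretina.synthetic.draw_truth` is exercised by its own tests.

Large populations are generated and analyzed in chunks of cells so that
memory stays flat; chunk seeds are spawned deterministically from the
experiment seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
import pandas as pd

from .electrical_response import analyze_electrical_train
from .light_response import classify_light_train
from .optomotor import session_acuities
from .spike_data import AMPLITUDE_LADDER_UA
from .synthetic import (
    LIGHT_TYPES,
    SyntheticDataset,
    draw_truth,
    generate_optomotor_session,
    generate_population,
    optomotor_preset,
    stage_preset,
)

__all__ = [
    "stratified_labels",
    "dominant_frequency_sample",
    "peak_group_ratio",
    "light_responsive_fraction",
    "er_fraction",
    "mean_response_curves",
    "optomotor_mean_acuity",
]

_CHUNK = 1000


def stratified_labels(values: list, fractions: np.ndarray, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Label vector with exact class counts (largest-remainder), shuffled."""
    fractions = np.asarray(fractions, dtype=float)
    ideal = fractions * n
    counts = np.floor(ideal).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(ideal - counts))
        counts[order[:short]] += 1
    out = np.repeat(np.asarray(values, dtype=object), counts)
    rng.shuffle(out)
    return out


def _chunked_populations(stage: str, n_cells: int, seed: int, protocol: str,
                         light_labels: np.ndarray | None = None,
                         er_labels: np.ndarray | None = None,
                         peak_labels: np.ndarray | None = None,
                         ) -> Iterator[SyntheticDataset]:
    """Yield the population in chunks, overriding labels where given."""
    n_chunks = int(np.ceil(n_cells / _CHUNK))
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n_chunks)
    ]
    start = 0
    for i, chunk_seed in enumerate(seeds):
        n = min(_CHUNK, n_cells - start)
        preset = stage_preset(stage, n_cells=n, seed=chunk_seed)
        rng = np.random.default_rng(np.random.SeedSequence(chunk_seed).spawn(3)[0])
        truth = draw_truth(preset, rng)
        truth["cell_id"] = [f"{stage}_s{seed}_c{start + j:06d}" for j in range(n)]
        sl = slice(start, start + n)
        if light_labels is not None:
            truth["light_type"] = light_labels[sl]
        if er_labels is not None:
            truth["er"] = er_labels[sl]
        if peak_labels is not None:
            labels = np.asarray(peak_labels[sl], dtype=object)
            truth["peak_group"] = labels
            truth["er"] = labels != "none"
            # redraw the per-cell oscillation frequency for the final groups
            truth["f_osc_hz"] = np.where(
                labels == "multiple",
                preset.f_osc_hz
                + preset.f_osc_jitter_hz * rng.standard_normal(n),
                np.nan,
            )
        yield generate_population(preset, protocol=protocol, truth=truth)
        start += n


def dominant_frequency_sample(stage: str, n_cells: int = 30,
                              seed: int = 1) -> np.ndarray:
    """Pipeline dominant-frequency estimates over a multiple-peak ER cohort.

    Simulates ``n_cells`` multiple-peak ER cells (50 pulses at 50 uA within
    the full amplitude-ladder protocol), applies artifact exclusion, PSTH
    peak grouping and the FFT dominant-frequency estimator, and returns the
    per-cell estimates of the cells the pipeline itself classified as
    multiple-peak.
    """
    peak = np.full(n_cells, "multiple", dtype=object)
    out = []
    for ds in _chunked_populations(stage, n_cells, seed, "electrical",
                                   peak_labels=peak):
        for train in ds.electrical_trains:
            r = analyze_electrical_train(train, ds.electrical_events,
                                         compute_curves=False)
            if r.dominant_freq_hz is not None:
                out.append(r.dominant_freq_hz)
    return np.asarray(out)


def peak_group_ratio(stage: str, n_cells: int = 2000,
                     seed: int = 3) -> tuple[float, int, int]:
    """Multiple:single count ratio recovered from a simulated ER population.

    The cohort carries the stage's multiple-peak mixture in exact
    proportions; the ratio is computed from the peak-group classifier's
    calls at 50 uA. Returns ``(ratio, n_multiple, n_single)``.
    """
    preset = stage_preset(stage)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    peak = stratified_labels(
        ["multiple", "single"],
        [preset.multi_peak_fraction, 1.0 - preset.multi_peak_fraction],
        n_cells, rng,
    )
    n_single = n_multi = 0
    for ds in _chunked_populations(stage, n_cells, seed, "electrical",
                                   peak_labels=peak):
        for train in ds.electrical_trains:
            r = analyze_electrical_train(train, ds.electrical_events,
                                         compute_curves=False)
            if r.peak_group == "single":
                n_single += 1
            elif r.peak_group == "multiple":
                n_multi += 1
    ratio = n_multi / n_single if n_single else float("inf")
    return ratio, n_multi, n_single


def light_responsive_fraction(stage: str, n_cells: int = 10000,
                              seed: int = 5) -> float:
    """Fraction of simulated cells classified light-responsive (not
    unresponsive) by the 100 ms / 2x-baseline criterion."""
    preset = stage_preset(stage)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    light = stratified_labels(list(LIGHT_TYPES), preset.light_fractions,
                              n_cells, rng)
    responsive = total = 0
    for ds in _chunked_populations(stage, n_cells, seed, "light",
                                   light_labels=light):
        for train in ds.light_trains:
            c = classify_light_train(train, ds.light_events)
            responsive += c.light_type != "unresponsive"
            total += 1
    return responsive / total


def er_fraction(stage: str, n_cells: int = 10000, seed: int = 11) -> float:
    """Fraction of simulated cells passing the ER criterion at 50 uA.

    The cohort is electrically responsive in the exact preset proportion
    (~40%), with the ER cells' single/multiple split at the stage mixture.
    """
    preset = stage_preset(stage)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    mpf = preset.multi_peak_fraction
    e = preset.er_fraction
    peak = stratified_labels(
        ["multiple", "single", "none"],
        [e * mpf, e * (1.0 - mpf), 1.0 - e],
        n_cells, rng,
    )
    er = total = 0
    for ds in _chunked_populations(stage, n_cells, seed, "electrical",
                                   peak_labels=peak):
        for train in ds.electrical_trains:
            r = analyze_electrical_train(train, ds.electrical_events,
                                         compute_curves=False)
            er += r.is_er
            total += 1
    return er / total


def mean_response_curves(stage: str, peak_group: str, n_cells: int = 100,
                         seed: int = 13) -> tuple[dict, dict]:
    """Population-mean amplitude-response curves of one response class.

    Returns ``(curve_100, curve_500)``: mean relative spike ratio per ladder
    amplitude over ``n_cells`` cells of the given peak group, for the 100 ms
    and 500 ms windows.
    """
    peak = np.full(n_cells, peak_group, dtype=object)
    sums100 = {a: 0.0 for a in AMPLITUDE_LADDER_UA}
    sums500 = {a: 0.0 for a in AMPLITUDE_LADDER_UA}
    n = 0
    for ds in _chunked_populations(stage, n_cells, seed, "electrical",
                                   peak_labels=peak):
        for train in ds.electrical_trains:
            r = analyze_electrical_train(train, ds.electrical_events)
            if any(v is None for v in r.response_curve_100.values()):
                continue
            for a in AMPLITUDE_LADDER_UA:
                sums100[a] += r.response_curve_100[a]
                sums500[a] += r.response_curve_500[a]
            n += 1
    return (
        {a: sums100[a] / n for a in AMPLITUDE_LADDER_UA},
        {a: sums500[a] / n for a in AMPLITUDE_LADDER_UA},
    )


def optomotor_mean_acuity(group: str, n_animals: int = 6,
                          seed: int = 7) -> float:
    """Group mean visual acuity from simulated optomotor sessions.

    Generates sessions, extracts per-animal frontiers, fits the saturating
    exponential and averages the fitted acuity at 100% contrast; animals
    without a valid fit count as acuity 0.
    """
    preset = optomotor_preset(group, n_animals=n_animals, seed=seed)
    trials = generate_optomotor_session(preset)
    acuities = session_acuities(trials)
    return float(np.mean([v if v is not None else 0.0
                          for v in acuities.values()]))
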