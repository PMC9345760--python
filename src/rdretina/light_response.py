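"""ON/OFF/ON-OFF classification of flash responses and population summaries.

A cell is typed by comparing its mean firing rate in the 100 ms after light
onset (and after light offset at t = 4 s) against twice its baseline rate:
exceeding the threshold after onset only makes it ON, after offset only OFF,
after both ON/OFF, after neither unresponsive.

The baseline is the cycle-wide mean rate excluding the two 100 ms criterion
windows — the flash protocol has no long dark stretch, so the remaining
7.8 s of each cycle is the natural spontaneous reference. The criterion is a
strict inequality ("exceeds"): a rate exactly at twice baseline does not
qualify. Criterion windows are half-open ``(0, 100 ms]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .spike_data import SpikeTrain, StimulusEvents, TrialRaster, align_to_events

__all__ = [
    "CRITERION_WINDOW_S",
    "LightClassification",
    "light_baseline_rate",
    "classify_light",
    "classify_light_train",
    "summarize_light_population",
]

#: Length of the post-onset / post-offset criterion window (s).
CRITERION_WINDOW_S = 0.1


@dataclass
class LightClassification:
    """Per-cell light-response record; rates in Hz."""

    cell_id: str
    light_type: str
    onset_rate_hz: float
    offset_rate_hz: float
    baseline_rate_hz: float


def _window_rate(raster: TrialRaster, lo: float, width: float) -> float:
    """Mean rate (Hz) in the half-open interval (lo, lo + width] across trials.

    The nominal width is used for the division so that e.g. the offset
    window at (4.0, 4.1] has exactly the same length as the onset window —
    ``4.1 - 4.0`` in floating point does not, and the criterion's strict
    tie-break is sensitive to that.
    """
    if raster.n_trials == 0:
        return 0.0
    return raster.count_in(lo, lo + width) / (width * raster.n_trials)


def light_baseline_rate(raster: TrialRaster, on_duration_s: float = 4.0,
                        cycle_s: float = 8.0) -> float:
    """Cycle-wide mean rate excluding the two 100 ms criterion windows.

    The raster must cover the full flash cycle (window ``(0, cycle_s)``
    relative to light onset). Uses all 7.8 s of non-criterion time per
    cycle, which keeps the estimate stable even at low firing rates.
    """
    if raster.n_trials == 0:
        return 0.0
    w = CRITERION_WINDOW_S
    total = raster.count_in(0.0, cycle_s)
    in_windows = raster.count_in(0.0, w) + raster.count_in(on_duration_s, on_duration_s + w)
    span = cycle_s - 2.0 * w
    return (total - in_windows) / (span * raster.n_trials)


def classify_light(raster: TrialRaster, baseline_hz: float,
                   cell_id: str | None = None,
                   on_duration_s: float = 4.0) -> LightClassification:
    """Apply the 100 ms / 2x-baseline criterion to a full-cycle raster.

    A zero-spike cell is unresponsive with baseline 0 (0 > 0 is false), and
    is retained rather than dropped so population denominators count every
    recorded cell.
    """
    w = CRITERION_WINDOW_S
    onset = _window_rate(raster, 0.0, w)
    offset = _window_rate(raster, on_duration_s, w)
    on_crit = onset > 2.0 * baseline_hz
    off_crit = offset > 2.0 * baseline_hz
    if on_crit and off_crit:
        light_type = "ONOFF"
    elif on_crit:
        light_type = "ON"
    elif off_crit:
        light_type = "OFF"
    else:
        light_type = "unresponsive"
    return LightClassification(
        cell_id=cell_id if cell_id is not None else raster.cell_id,
        light_type=light_type,
        onset_rate_hz=onset,
        offset_rate_hz=offset,
        baseline_rate_hz=baseline_hz,
    )


def classify_light_train(train: SpikeTrain, events: StimulusEvents) -> LightClassification:
    """Align one cell to the flash schedule and classify it."""
    cycle = (events.on_duration_s or 4.0) + (events.off_duration_s or 4.0)
    raster = align_to_events(train, events, window=(0.0, cycle))
    baseline = light_baseline_rate(raster, on_duration_s=events.on_duration_s or 4.0,
                                   cycle_s=cycle)
    return classify_light(raster, baseline, on_duration_s=events.on_duration_s or 4.0)


def summarize_light_population(classifications: Sequence[LightClassification],
                               ) -> dict[str, float]:
    """Population fractions of ON/OFF/ON-OFF/unresponsive cells.

    Returns a dict with the four type fractions (summing to 1 exactly) plus
    ``responsive`` = 1 - unresponsive.
    """
    if not classifications:
        raise ValueError("cannot summarize an empty classification list")
    n = len(classifications)
    counts = {t: 0 for t in ("ON", "OFF", "ONOFF", "unresponsive")}
    for c in classifications:
        counts[c.light_type] += 1
    fractions = {t: counts[t] / n for t in counts}
    fractions["responsive"] = 1.0 - fractions["unresponsive"]
    return fractions
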