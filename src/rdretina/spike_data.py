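"""Spike-train data model, file I/O, trial alignment and PSTH construction.

This module is the substrate of the whole pipeline: every analysis stage
consumes :class:`SpikeTrain` objects aligned to a :class:`StimulusEvents`
schedule, binned into a :class:`Psth`.

Conventions
-----------
* Time is in seconds (float) from recording start, everywhere.
* Histogram bins are half-open ``[a, b)``; a spike exactly at a window's
  right edge belongs to the next trial, never to the current bin, so the
  abutting +-500 ms windows of a 1 Hz pulse train never double-count.
* File columns carry explicit unit suffixes (``time_s``, ``amplitude_uA``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AMPLITUDE_LADDER_UA",
    "SpikeTrain",
    "StimulusEvents",
    "TrialRaster",
    "Psth",
    "SpontaneousRate",
    "CellResult",
    "light_protocol",
    "electrical_protocol",
    "read_spike_table",
    "write_spike_table",
    "read_event_table",
    "write_event_table",
    "align_to_events",
    "compute_psth",
    "spontaneous_rate_electrical",
    "write_results_table",
    "read_results_table",
]

#: Pulse-amplitude ladder of the electrical protocol (uA per phase).
AMPLITUDE_LADDER_UA = (1.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0)

#: Pulse width of the biphasic stimulus, microseconds per phase.
PULSE_WIDTH_US_PER_PHASE = 500.0

#: Length of the pre-stimulation window used for spontaneous-rate estimation.
SPONTANEOUS_WINDOW_S = 25.0


class SpikeDataError(ValueError):
    """Raised on malformed spike/event tables or invalid container state."""


@dataclass
class SpikeTrain:
    """Spike timestamps of one cell over one recording.

    Parameters
    ----------
    cell_id : str
        Unit identifier (one sorted unit from the array).
    times : ndarray of float
        Spike times in seconds from recording start, non-decreasing,
        all within ``[0, duration]``.
    duration : float
        Recording length in seconds, strictly positive.
    """

    cell_id: str
    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.duration <= 0:
            raise SpikeDataError(
                f"cell {self.cell_id!r}: duration must be > 0, got {self.duration}"
            )
        if self.times.ndim != 1:
            raise SpikeDataError(f"cell {self.cell_id!r}: times must be 1-D")
        if self.times.size:
            if np.any(np.diff(self.times) < 0):
                raise SpikeDataError(f"cell {self.cell_id!r}: times must be sorted")
            if self.times[0] < 0 or self.times[-1] > self.duration:
                raise SpikeDataError(
                    f"cell {self.cell_id!r}: times outside [0, {self.duration}]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass
class StimulusEvents:
    """Flash or pulse schedule that defines trial alignment.

    For the electrical protocol, ``amplitudes_uA`` holds the pulse amplitude
    of every onset (constant within each 50-pulse block); for the light
    protocol it is ``None`` and the flash timing is carried by
    ``on_duration_s`` / ``off_duration_s``.
    """

    kind: str  # "light_flash" | "electrical_pulse"
    onsets: np.ndarray
    amplitudes_uA: np.ndarray | None = None
    pulse_width_us_per_phase: float | None = None
    on_duration_s: float | None = None
    off_duration_s: float | None = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.kind not in ("light_flash", "electrical_pulse"):
            raise SpikeDataError(f"unknown stimulus kind {self.kind!r}")
        if self.onsets.size == 0:
            raise SpikeDataError("stimulus must have at least one onset")
        if np.any(np.diff(self.onsets) <= 0):
            raise SpikeDataError("onsets must be strictly increasing")
        if self.kind == "electrical_pulse":
            if self.amplitudes_uA is None:
                raise SpikeDataError("electrical stimulus requires amplitudes_uA")
            self.amplitudes_uA = np.asarray(self.amplitudes_uA, dtype=float)
            if self.amplitudes_uA.shape != self.onsets.shape:
                raise SpikeDataError("amplitudes_uA must match onsets in length")
            bad = set(np.unique(self.amplitudes_uA)) - set(AMPLITUDE_LADDER_UA)
            if bad:
                raise SpikeDataError(f"amplitudes outside the ladder: {sorted(bad)}")

    @property
    def n_events(self) -> int:
        return int(self.onsets.size)

    def onsets_at(self, amplitude_uA: float) -> np.ndarray:
        """Onsets of the pulse block at one amplitude (electrical only)."""
        if self.kind != "electrical_pulse":
            raise SpikeDataError("onsets_at() only applies to electrical stimuli")
        if amplitude_uA not in AMPLITUDE_LADDER_UA:
            raise SpikeDataError(f"amplitude {amplitude_uA} uA not in the ladder")
        return self.onsets[self.amplitudes_uA == amplitude_uA]


def light_protocol(n_cycles: int = 50, on_duration_s: float = 4.0,
                   off_duration_s: float = 4.0, start_s: float = 0.0) -> StimulusEvents:
    """Full-field flash schedule: ON 4 s / OFF 4 s, 50 cycles by default.

    Onsets mark the light-ON transitions; the light-OFF transition of cycle
    *i* is ``onsets[i] + on_duration_s``.
    """
    period = on_duration_s + off_duration_s
    onsets = start_s + period * np.arange(n_cycles)
    return StimulusEvents(
        kind="light_flash",
        onsets=onsets,
        on_duration_s=on_duration_s,
        off_duration_s=off_duration_s,
    )


def electrical_protocol(first_onset_s: float = SPONTANEOUS_WINDOW_S,
                        n_pulses_per_block: int = 50,
                        inter_pulse_s: float = 1.0,
                        inter_block_gap_s: float = 5.0,
                        amplitudes_uA: Sequence[float] = AMPLITUDE_LADDER_UA,
                        ) -> StimulusEvents:
    """Biphasic pulse schedule: 50 pulses at 1 Hz per amplitude block.

    Blocks run through the amplitude ladder in ascending order, separated by
    ``inter_block_gap_s`` of silence, preceded by ``first_onset_s`` of
    pre-stimulation silence for the spontaneous-rate estimate.
    """
    onsets, amps = [], []
    t = float(first_onset_s)
    for amp in amplitudes_uA:
        block = t + inter_pulse_s * np.arange(n_pulses_per_block)
        onsets.append(block)
        amps.append(np.full(n_pulses_per_block, amp))
        t = block[-1] + inter_pulse_s + inter_block_gap_s
    return StimulusEvents(
        kind="electrical_pulse",
        onsets=np.concatenate(onsets),
        amplitudes_uA=np.concatenate(amps),
        pulse_width_us_per_phase=PULSE_WIDTH_US_PER_PHASE,
    )


@dataclass
class TrialRaster:
    """Trial-aligned relative spike times for one cell.

    ``window = (t_pre, t_post)`` means each trial covers relative times
    ``[-t_pre, t_post)`` around its event onset.
    """

    cell_id: str
    window: tuple[float, float]
    trials: list[np.ndarray]

    def __post_init__(self) -> None:
        t_pre, t_post = self.window
        if t_pre < 0 or t_post <= 0:
            raise SpikeDataError("window must satisfy t_pre >= 0 and t_post > 0")
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.trials))

    def count_in(self, lo: float, hi: float) -> int:
        """Total spikes with relative time in the half-open interval (lo, hi]."""
        return int(sum(int(np.count_nonzero((t > lo) & (t <= hi))) for t in self.trials))


@dataclass
class Psth:
    """Peri-stimulus time histogram with uniform bins.

    ``counts`` are total spikes per bin summed over trials (the conservation
    reference); ``rate_per_bin`` is the per-trial mean count and ``rate_hz``
    the per-trial mean rate.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_trials: int
    bin_width_s: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def rate_per_bin(self) -> np.ndarray:
        """Mean spikes per trial per bin (counts mode of the ordinate)."""
        return self.counts / max(self.n_trials, 1)

    @property
    def rate_hz(self) -> np.ndarray:
        return self.rate_per_bin / self.bin_width_s


@dataclass
class SpontaneousRate:
    """Baseline firing estimated from the pre-stimulation window."""

    cell_id: str
    rate_hz: float
    window_s: float
    short_window: bool = False

    def __post_init__(self) -> None:
        if self.rate_hz < 0 or self.window_s <= 0:
            raise SpikeDataError("invalid spontaneous-rate record")


@dataclass
class CellResult:
    """Per-cell classification record assembled across analysis stages.

    A missing dominant frequency (cell not in the multiple-peak group) is
    ``None`` and is serialized as an empty field, never as 0.
    """

    cell_id: str
    light_type: str | None = None          # ON | OFF | ONOFF | unresponsive
    is_er: bool | None = None
    peak_group: str | None = None          # single | multiple | none
    dominant_freq_hz: float | None = None
    spontaneous_rate_hz: float | None = None
    onset_rate_hz: float | None = None
    offset_rate_hz: float | None = None
    baseline_rate_hz: float | None = None


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_spike_table(path: str | os.PathLike) -> list[SpikeTrain]:
    """Read a delimited spike table into one :class:`SpikeTrain` per cell.

    The file has header columns ``cell_id,time_s`` and may start with a
    comment line ``# duration_s=<float>``. Without the header comment the
    recording length defaults to the last spike time rounded up to the next
    whole second.

    Raises
    ------
    SpikeDataError
        Naming the offending line for malformed rows, and flagging negative
        spike times.
    """
    sep = _sep_for(path)
    duration = None
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "duration_s=" in first:
                duration = float(first.split("duration_s=")[1].strip())
            body = fh.read()
            header_offset = 1
        else:
            body = first + fh.read()
            header_offset = 0

    lines = body.splitlines()
    if not lines:
        raise SpikeDataError(f"{path}: empty file")
    header = [c.strip() for c in lines[0].split(sep)]
    if "cell_id" not in header or "time_s" not in header:
        raise SpikeDataError(f"{path}: header must contain cell_id and time_s")
    i_cell, i_time = header.index("cell_id"), header.index("time_s")

    cells: dict[str, list[float]] = {}
    for lineno, line in enumerate(lines[1:], start=header_offset + 2):
        if not line.strip():
            continue
        parts = line.split(sep)
        try:
            cell = parts[i_cell].strip()
            t = float(parts[i_time])
        except (IndexError, ValueError) as exc:
            raise SpikeDataError(f"{path}: parse error at line {lineno}: {line!r}") from exc
        if t < 0:
            raise SpikeDataError(f"{path}: negative spike time at line {lineno}")
        cells.setdefault(cell, []).append(t)

    if duration is None:
        tmax = max((max(ts) for ts in cells.values() if ts), default=0.0)
        duration = float(np.ceil(tmax)) or 1.0
    return [
        SpikeTrain(cell_id=cid, times=np.sort(ts), duration=duration)
        for cid, ts in cells.items()
    ]


def write_spike_table(trains: Iterable[SpikeTrain], path: str | os.PathLike) -> None:
    """Write spike trains as a ``cell_id,time_s`` table with a duration header."""
    trains = list(trains)
    sep = _sep_for(path)
    duration = max((t.duration for t in trains), default=1.0)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# duration_s={duration}\n")
        fh.write(sep.join(["cell_id", "time_s"]) + "\n")
        for tr in trains:
            for t in tr.times:
                fh.write(f"{tr.cell_id}{sep}{t:.6f}\n")


def read_event_table(path: str | os.PathLike) -> StimulusEvents:
    """Read a stimulus-event table (columns ``time_s,kind,amplitude_uA``)."""
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    for col in ("time_s", "kind"):
        if col not in df.columns:
            raise SpikeDataError(f"{path}: missing column {col}")
    kinds = df["kind"].unique()
    if len(kinds) != 1:
        raise SpikeDataError(f"{path}: mixed stimulus kinds {list(kinds)}")
    kind = str(kinds[0])
    if kind == "electrical_pulse":
        return StimulusEvents(
            kind=kind,
            onsets=df["time_s"].to_numpy(),
            amplitudes_uA=df["amplitude_uA"].to_numpy(),
            pulse_width_us_per_phase=PULSE_WIDTH_US_PER_PHASE,
        )
    return StimulusEvents(
        kind=kind,
        onsets=df["time_s"].to_numpy(),
        on_duration_s=4.0,
        off_duration_s=4.0,
    )


def write_event_table(events: StimulusEvents, path: str | os.PathLike) -> None:
    amp = (
        events.amplitudes_uA
        if events.amplitudes_uA is not None
        else np.full(events.n_events, np.nan)
    )
    df = pd.DataFrame(
        {"time_s": events.onsets, "kind": events.kind, "amplitude_uA": amp}
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


#: Stable column order of the per-cell results table.
RESULT_COLUMNS = [
    "cell_id",
    "light_type",
    "is_er",
    "peak_group",
    "dominant_freq_hz",
    "spontaneous_rate_hz",
    "onset_rate_hz",
    "offset_rate_hz",
    "baseline_rate_hz",
]


def write_results_table(results: Iterable[CellResult], path: str | os.PathLike) -> None:
    """Write per-cell results as CSV with a stable column order.

    ``None`` fields are written as empty cells (missing), never coerced to 0,
    and the table round-trips through :func:`read_results_table`.
    """
    rows = [{c: getattr(r, c if c != "is_er" else "is_er") for c in RESULT_COLUMNS}
            for r in results]
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, index=False)


def read_results_table(path: str | os.PathLike) -> list[CellResult]:
    df = pd.read_csv(path, dtype={"cell_id": str})
    out = []
    for _, row in df.iterrows():
        kw = {}
        for col in RESULT_COLUMNS:
            val = row[col] if col in row else None
            if pd.isna(val):
                val = None
            elif col == "is_er":
                val = bool(val)
            elif col.endswith("_hz"):
                val = float(val)
            kw[col] = val
        out.append(CellResult(**kw))
    return out


# ---------------------------------------------------------------------------
# Trial alignment and PSTH
# ---------------------------------------------------------------------------

def align_to_events(train: SpikeTrain, onsets: np.ndarray | StimulusEvents,
                    window: tuple[float, float]) -> TrialRaster:
    """Cut spike times into per-event trials of relative times.

    Trial *i* contains ``t - onset_i`` for every spike with
    ``onset_i - t_pre <= t < onset_i + t_post``; trials keep the event order.
    A spike can land in two trials only if consecutive windows overlap.
    """
    if isinstance(onsets, StimulusEvents):
        onsets = onsets.onsets
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        raise SpikeDataError("cannot align to an empty event list")
    t_pre, t_post = window
    if t_pre < 0 or t_post <= 0:
        raise SpikeDataError("window must satisfy t_pre >= 0 and t_post > 0")
    lo = np.searchsorted(train.times, onsets - t_pre, side="left")
    hi = np.searchsorted(train.times, onsets + t_post, side="left")
    trials = [train.times[a:b] - onset for a, b, onset in zip(lo, hi, onsets)]
    return TrialRaster(cell_id=train.cell_id, window=window, trials=trials)


def compute_psth(raster: TrialRaster, bin_width_s: float,
                 t_start: float | None = None,
                 t_stop: float | None = None) -> Psth:
    """Bin a raster into a PSTH with half-open ``[a, b)`` bins.

    ``bin_width_s`` must divide the binned span to within 1e-9 s (no partial
    bins). ``t_start``/``t_stop`` default to the raster window; pass them to
    bin a sub-range, e.g. the (10, 510] ms post-pulse span at 20 ms bins.
    """
    if bin_width_s <= 0:
        raise SpikeDataError("bin width must be > 0")
    t_pre, t_post = raster.window
    a = -t_pre if t_start is None else float(t_start)
    b = t_post if t_stop is None else float(t_stop)
    span = b - a
    n_bins_f = span / bin_width_s
    n_bins = int(round(n_bins_f))
    if n_bins < 1 or abs(n_bins_f - n_bins) > 1e-9 * max(1.0, n_bins):
        raise SpikeDataError(
            f"bin width {bin_width_s} does not divide window span {span}"
        )
    edges = a + bin_width_s * np.arange(n_bins + 1)
    counts = np.zeros(n_bins, dtype=float)
    for trial in raster.trials:
        if trial.size == 0:
            continue
        # classify against the materialized edges (not floor division) so a
        # spike compares with exactly the same floats as edge-based counting
        idx = np.searchsorted(edges, trial, side="right") - 1
        ok = (idx >= 0) & (idx < n_bins)
        np.add.at(counts, idx[ok], 1.0)
    return Psth(bin_edges=edges, counts=counts, n_trials=raster.n_trials,
                bin_width_s=bin_width_s)


def spontaneous_rate_electrical(train: SpikeTrain, first_onset_s: float,
                                window_s: float = SPONTANEOUS_WINDOW_S,
                                ) -> SpontaneousRate:
    """Baseline rate from the 25 s immediately preceding the first pulse.

    If fewer than 25 s precede the first stimulus the full available
    pre-stimulus span is used instead and the record is flagged
    ``short_window`` (the estimate is then noisier but not biased). Spikes
    at or after ``first_onset_s`` never enter the estimate.
    """
    if first_onset_s <= 0:
        raise SpikeDataError("first stimulus onset must be > 0 s")
    span = min(window_s, first_onset_s)
    lo, hi = first_onset_s - span, first_onset_s
    n = int(np.count_nonzero((train.times >= lo) & (train.times < hi)))
    return SpontaneousRate(
        cell_id=train.cell_id,
        rate_hz=n / span,
        window_s=span,
        short_window=span < window_s,
    )
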