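"""Shared fixtures and helpers for the rdretina test suite."""

from __future__ import annotations

import numpy as np
import pytest

from rdretina import Psth, SpikeTrain, TrialRaster


def make_raster(trials, window=(0.5, 0.5), cell_id="c0") -> TrialRaster:
    return TrialRaster(cell_id=cell_id, window=window,
                       trials=[np.asarray(t, dtype=float) for t in trials])


def noiseless_psth(profile_fn, t0: float, t1: float, bin_s: float = 0.02,
                   n_trials: int = 50, n_sub: int = 200) -> Psth:
    """Expected-value PSTH of a rate profile (per-bin integrals, no noise)."""
    edges = np.arange(t0, t1 + 1e-12, bin_s)
    counts = []
    for a, b in zip(edges[:-1], edges[1:]):
        tt = np.linspace(a, b, n_sub)
        counts.append(np.trapezoid(profile_fn(tt), tt) * n_trials)
    return Psth(bin_edges=edges, counts=np.asarray(counts),
                n_trials=n_trials, bin_width_s=bin_s)


@pytest.fixture
def simple_train() -> SpikeTrain:
    return SpikeTrain("c1", np.array([0.95, 1.03, 1.42]), duration=2.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
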