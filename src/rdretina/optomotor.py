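"""Visual-acuity estimation from optomotor trials.

The optomotor task measures, per contrast level, the highest spatial
resolution (cycles/degree) of a rotating grating that still drives reflexive
head tracking. Per animal the successful trials define a contrast-resolution
frontier; a saturating exponential

    r(C) = a * (1 - exp(-k * C / 100))

is least-squares fitted to the frontier points and visual acuity is the
fitted curve at 100% contrast. Animals with no successful trial at any
contrast are assigned acuity 0 and enter group averages as zeros (blind
animals count, they are not dropped).

Frontier points need not be monotone in contrast (degenerating animals show
highly variable frontiers); the fit handles non-monotone and all-zero inputs
without failure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "AcuityFit",
    "AcuityFitError",
    "extract_frontier",
    "fit_acuity",
    "session_acuities",
    "group_acuity",
]


class AcuityFitError(ValueError):
    """Raised when the frontier has too few points for a valid fit."""


@dataclass
class AcuityFit:
    """Saturating-exponential contrast-resolution fit.

    ``acuity_cpd`` is the fitted curve evaluated at 100% contrast,
    ``a * (1 - exp(-k))``.
    """

    a: float
    k: float
    acuity_cpd: float
    rss: float
    n_points: int


def extract_frontier(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-contrast frontier points of one animal.

    For every tested contrast, the highest ``spatial_resolution_cpd`` among
    successful trials; a contrast with no success contributes a 0-cpd point.
    Expects columns ``contrast_pct, spatial_resolution_cpd, success``.
    """
    if len(trials) == 0:
        raise ValueError("cannot extract a frontier from zero trials")
    rows = []
    for contrast, sub in trials.groupby("contrast_pct"):
        ok = sub.loc[sub["success"].astype(bool), "spatial_resolution_cpd"]
        rows.append(
            {"contrast_pct": float(contrast),
             "frontier_cpd": float(ok.max()) if len(ok) else 0.0}
        )
    return pd.DataFrame(rows).sort_values("contrast_pct", ignore_index=True)


def _model(params: np.ndarray, contrast: np.ndarray) -> np.ndarray:
    a, k = params
    return a * (1.0 - np.exp(-k * contrast / 100.0))


def fit_acuity(frontier: pd.DataFrame,
               a_grid: np.ndarray | None = None,
               k_grid: np.ndarray | None = None) -> AcuityFit:
    """Least-squares saturating-exponential fit of frontier points.

    Needs at least 3 points spanning at least 2 distinct contrasts. The
    optimum is located by a coarse grid search over ``a in [0, 0.7]`` and
    ``k in [0.1, 20]`` and polished with a bounded trust-region pass, which
    makes the result deterministic for fixed data.

    Raises
    ------
    AcuityFitError
        For <3 points or a single distinct contrast; callers report the
        acuity as missing in that case.
    """
    contrast = frontier["contrast_pct"].to_numpy(dtype=float)
    r = frontier["frontier_cpd"].to_numpy(dtype=float)
    if len(r) < 3 or len(np.unique(contrast)) < 2:
        raise AcuityFitError(
            f"need >=3 points over >=2 contrasts, got {len(r)} points "
            f"over {len(np.unique(contrast))} contrasts"
        )
    if np.allclose(r, 0.0):
        return AcuityFit(a=0.0, k=1.0, acuity_cpd=0.0, rss=0.0, n_points=len(r))

    if a_grid is None:
        a_grid = np.linspace(0.0, 0.7, 71)
    if k_grid is None:
        k_grid = np.geomspace(0.1, 20.0, 60)
    # coarse grid: vectorized RSS over the (a, k) lattice
    shape = 1.0 - np.exp(-np.outer(k_grid, contrast) / 100.0)  # (k, C)
    rss = (
        (a_grid[:, None, None] * shape[None, :, :] - r[None, None, :]) ** 2
    ).sum(axis=2)
    ia, ik = np.unravel_index(np.argmin(rss), rss.shape)
    x0 = np.array([a_grid[ia], max(k_grid[ik], 0.1)])

    sol = least_squares(
        lambda p: _model(p, contrast) - r,
        x0=x0,
        bounds=([0.0, 0.05], [1.4, 40.0]),
        method="trf",
    )
    a, k = sol.x
    return AcuityFit(
        a=float(a),
        k=float(k),
        acuity_cpd=float(_model(sol.x, np.array([100.0]))[0]),
        rss=float(np.sum(sol.fun**2)),
        n_points=len(r),
    )


def session_acuities(trials: pd.DataFrame) -> dict[str, float | None]:
    """Per-animal acuity from a trial table (column ``animal_id`` required).

    Animals whose frontier cannot be fitted get ``None`` (missing).
    """
    out: dict[str, float | None] = {}
    for animal, sub in trials.groupby("animal_id"):
        frontier = extract_frontier(sub)
        try:
            out[str(animal)] = fit_acuity(frontier).acuity_cpd
        except AcuityFitError:
            out[str(animal)] = None
    return out


def group_acuity(acuities: dict[str, float | None],
                 groups: dict[str, str]) -> pd.DataFrame:
    """Group mean +- SD of per-animal acuities.

    Missing acuities (no optomotor response) are counted as 0 so that blind
    animals enter the average. Sample SD (ddof=1); a single-animal group has
    SD NaN. Raises on an empty group.
    """
    rows = []
    for label in sorted(set(groups.values())):
        vals = [
            acuities[a] if acuities[a] is not None else 0.0
            for a in acuities
            if groups.get(a) == label
        ]
        if not vals:
            raise ValueError(f"group {label!r} has no animals")
        arr = np.asarray(vals, dtype=float)
        rows.append(
            {
                "group": label,
                "n": len(arr),
                "mean_acuity_cpd": float(arr.mean()),
                "sd_acuity_cpd": float(arr.std(ddof=1)) if len(arr) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
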