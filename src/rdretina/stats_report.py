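"""Group-comparison statistics and per-stage report assembly.

Two tests cover the pipeline's comparisons: Student's t-test (paired or
two-sample; pooled variance by default, Welch optional) for pairs of stages,
and one-way ANOVA with Tukey's HSD post-hoc (studentized-range adjusted
pairwise p-values) for three or more groups. Computation is delegated to
scipy.stats; the degenerate all-equal case is mapped to the (t=0, p=1)
convention instead of NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "two_sample_t", "anova_tukey", "build_stage_report"]


@dataclass
class GroupComparison:
    """Result of one group comparison.

    ``pairwise`` (adjusted p per pair) is present only for ANOVA + Tukey.
    """

    test: str                      # "t_test" | "anova_tukey"
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def two_sample_t(sample_a: Sequence[float], sample_b: Sequence[float],
                 paired: bool = False, equal_var: bool = True) -> GroupComparison:
    """Student's t-test, two-sided.

    Pooled-variance by default (``equal_var=False`` gives Welch). Paired
    mode requires equal lengths. Identical degenerate samples (zero variance
    on both sides, equal means) return t = 0, p = 1 by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal sample sizes")
        res = sps.ttest_rel(a, b)
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t) or np.isnan(p):
        # zero variance everywhere: no evidence against equal means
        if np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:  # pragma: no cover - means differ with zero variance
            t, p = np.inf, 0.0
    return GroupComparison(test="t_test", statistic=t, p_value=min(p, 1.0))


def anova_tukey(groups: dict[str, Sequence[float]]) -> GroupComparison:
    """One-way ANOVA with Tukey's HSD pairwise post-hoc.

    Needs >= 3 groups with n >= 2 each. The pairwise table has columns
    ``group_a, group_b, p_adj`` with p-values adjusted via the studentized
    range distribution.
    """
    if len(groups) < 3:
        raise ValueError("ANOVA + Tukey requires at least 3 groups")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(a.size < 2 for a in arrays):
        small = [k for k, a in zip(labels, arrays) if a.size < 2]
        raise ValueError(f"groups with n < 2: {small}")
    f_res = sps.f_oneway(*arrays)
    f, p = float(f_res.statistic), float(f_res.pvalue)
    if np.isnan(f):
        f, p = 0.0, 1.0
    tukey = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "p_adj": float(tukey.pvalue[i, j]),
                }
            )
    return GroupComparison(
        test="anova_tukey", statistic=f, p_value=min(p, 1.0),
        pairwise=pd.DataFrame(rows),
    )


def build_stage_report(light_summaries: dict[str, dict[str, float]] | None = None,
                       electrical_results: dict[str, list] | None = None,
                       acuity_means: dict[str, float] | None = None,
                       ) -> pd.DataFrame:
    """Assemble the per-stage summary table.

    Inputs are per-stage dicts: ``light_summaries`` maps stage to the output
    of ``summarize_light_population``; ``electrical_results`` maps stage to
    a list of ``ElectricalResult``; ``acuity_means`` maps stage to a group
    mean acuity. Sections that are absent simply contribute no columns.
    Assembly is pure: identical inputs give an identical table.
    """
    stages: list[str] = sorted(
        set(light_summaries or []) | set(electrical_results or [])
        | set(acuity_means or [])
    )
    rows = []
    for stage in stages:
        row: dict[str, object] = {"stage": stage}
        if light_summaries and stage in light_summaries:
            s = light_summaries[stage]
            row.update(
                frac_on=s["ON"], frac_off=s["OFF"], frac_onoff=s["ONOFF"],
                frac_unresponsive=s["unresponsive"], frac_responsive=s["responsive"],
            )
        if electrical_results and stage in electrical_results:
            res = electrical_results[stage]
            if res:
                n = len(res)
                n_single = sum(r.peak_group == "single" for r in res)
                n_multi = sum(r.peak_group == "multiple" for r in res)
                doms = [r.dominant_freq_hz for r in res
                        if r.dominant_freq_hz is not None]
                row.update(
                    er_fraction=sum(r.is_er for r in res) / n,
                    multi_single_ratio=(n_multi / n_single if n_single else np.nan),
                    mean_dominant_freq_hz=(float(np.mean(doms)) if doms else np.nan),
                )
        if acuity_means and stage in acuity_means:
            row["mean_acuity_cpd"] = acuity_means[stage]
        rows.append(row)
    return pd.DataFrame(rows)
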