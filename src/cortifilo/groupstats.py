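"""Group-level statistics: ROUT outlier exclusion, one-way ANOVA with
Tukey or Dunnett post-hoc comparisons, Student's t-test, per-experiment
means, and the summary-table report.

The analysis convention throughout: statistical tests run on the full
cell-level datasets; per-experiment (replicate) means are computed only
for display, to show experiment-to-experiment variability ("superplot"
style).  Definite outliers at Q = 0.1 % by the ROUT method are excluded
for the cortex:cytoplasm ratio before summarising.

ROUT here is the constant-model reduction of the published
robust-regression-plus-FDR procedure, which is the applicable special
case for a univariate metric: robust location = median, robust scale =
the RSDR (68.27th percentile of absolute residuals with an n/(n−1)
small-sample correction), per-point two-sided t p-values at n−1 degrees
of freedom, and a Benjamini–Hochberg step-up at rate Q to call outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "RoutConfig",
    "GroupedValues",
    "ComparisonTable",
    "rout_filter",
    "one_way_anova",
    "students_t",
    "experiment_means",
    "build_summary_table",
    "star_code",
]

#: Significance cutpoints for the star convention.
STAR_CUTPOINTS = (0.05, 0.01, 0.001, 0.0001)


def star_code(p: float, cutpoints=STAR_CUTPOINTS) -> str:
    """'ns', '*', '**', '***' or '****' at the conventional cutpoints."""
    stars = sum(p < c for c in cutpoints)
    return "*" * stars if stars else "ns"


class RoutConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    q: float = 0.001  # maximum desired FDR for outlier calls (0.1 %)

    @field_validator("q")
    @classmethod
    def _q_range(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("Q must lie in (0, 1)")
        return v


@dataclass
class GroupedValues:
    """Per-cell values with group and experiment labels and outlier flags."""

    values: np.ndarray
    group: np.ndarray
    experiment: np.ndarray
    metric: str = ""
    outlier: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.group = np.asarray(self.group)
        self.experiment = np.asarray(self.experiment)
        if not (self.values.size == self.group.size == self.experiment.size):
            raise ValueError("values, group and experiment must be aligned")
        if self.outlier is None:
            self.outlier = np.zeros(self.values.size, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": self.values,
                "group": self.group,
                "experiment": self.experiment,
                "outlier": self.outlier,
            }
        )


@dataclass
class ComparisonTable:
    test: str
    statistic: float
    df: tuple
    p_value: float
    pairwise: pd.DataFrame | None = None  # group1, group2, diff, p_raw, p_adj, stars


def rout_filter(
    values, config: RoutConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Flag definite outliers of a univariate sample at FDR Q.

    Returns ``(retained_values, outlier_flags)``.  Samples smaller than 10
    are returned unfiltered with a warning; an all-identical sample flags
    nothing.
    """
    config = config or RoutConfig()
    values = np.asarray(values, dtype=float)
    n = values.size
    flags = np.zeros(n, dtype=bool)
    if n < 10:
        warnings.warn("fewer than 10 values: ROUT filtering skipped", stacklevel=2)
        return values, flags
    med = np.median(values)
    absres = np.abs(values - med)
    rsdr = np.percentile(absres, 68.27) * n / (n - 1)
    if rsdr == 0:
        return values, flags
    t = absres / rsdr
    p = 2.0 * sps.t.sf(t, df=n - 1)
    # Benjamini-Hochberg step-up at rate Q
    order = np.argsort(p)
    below = np.nonzero(p[order] <= (np.arange(n) + 1) / n * config.q)[0]
    if below.size:
        k = below.max()
        flags[order[: k + 1]] = True
    return values[~flags], flags


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, dict):
        return {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    return {f"g{i}": np.asarray(v, dtype=float) for i, v in enumerate(groups)}


def one_way_anova(
    groups,
    posthoc: str = "tukey",
    control: str | None = None,
    cutpoints=STAR_CUTPOINTS,
) -> ComparisonTable:
    """Classical one-way ANOVA with Tukey HSD or Dunnett comparisons.

    ``groups`` is a mapping of group name → values (or a sequence of value
    arrays).  ``posthoc='dunnett'`` compares every group against the named
    ``control`` only.
    """
    gd = _as_groups(groups)
    if len(gd) < 2:
        raise ValueError("need at least 2 groups")
    if any(v.size < 2 for v in gd.values()):
        raise ValueError("every group needs at least 2 values")
    if all(np.var(v) == 0 for v in gd.values()):
        raise ValueError("zero within-group variance in all groups: F undefined")

    names = list(gd)
    arrays = [gd[k] for k in names]
    f_stat, p = sps.f_oneway(*arrays)
    n_total = sum(a.size for a in arrays)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_within

    rows = []
    if posthoc == "tukey":
        import itertools

        flat = np.concatenate(arrays)
        labels = np.concatenate([[k] * gd[k].size for k in names])
        res = pairwise_tukeyhsd(flat, labels)
        pairs = list(itertools.combinations(res.groupsunique, 2))
        for (g1, g2), diff, p_adj in zip(pairs, res.meandiffs, res.pvalues):
            a, b = gd[str(g1)], gd[str(g2)]
            se = np.sqrt(mse * (1 / a.size + 1 / b.size))
            t_raw = (b.mean() - a.mean()) / se
            p_raw = 2 * sps.t.sf(abs(t_raw), df_within)
            rows.append(
                {
                    "group1": str(g1),
                    "group2": str(g2),
                    "diff": float(diff),
                    "p_raw": float(p_raw),
                    "p_adj": float(p_adj),
                    "stars": star_code(float(p_adj), cutpoints),
                }
            )
    elif posthoc == "dunnett":
        if control is None or control not in gd:
            raise ValueError("dunnett post hoc requires a control group name")
        treat_names = [k for k in names if k != control]
        res = sps.dunnett(*[gd[k] for k in treat_names], control=gd[control])
        for name, stat, p_adj in zip(treat_names, res.statistic, res.pvalue):
            a, b = gd[control], gd[name]
            se = np.sqrt(mse * (1 / a.size + 1 / b.size))
            t_raw = (b.mean() - a.mean()) / se
            p_raw = 2 * sps.t.sf(abs(t_raw), df_within)
            rows.append(
                {
                    "group1": control,
                    "group2": name,
                    "diff": float(b.mean() - a.mean()),
                    "p_raw": float(p_raw),
                    "p_adj": float(min(1.0, p_adj)),
                    "stars": star_code(float(p_adj), cutpoints),
                }
            )
    elif posthoc is not None and posthoc != "none":
        raise ValueError(f"unknown posthoc {posthoc!r}")

    return ComparisonTable(
        test="one-way ANOVA",
        statistic=float(f_stat),
        df=(df_between, df_within),
        p_value=float(p),
        pairwise=pd.DataFrame(rows) if rows else None,
    )


def students_t(group_a, group_b, equal_var: bool = True) -> ComparisonTable:
    """Two-sided Student's t-test (pooled variance by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if equal_var and np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return ComparisonTable("Student's t", 0.0, (a.size + b.size - 2,), 1.0)
        raise ValueError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    df = a.size + b.size - 2 if equal_var else None
    return ComparisonTable(
        test="Student's t" if equal_var else "Welch's t",
        statistic=float(t),
        df=(df,),
        p_value=float(p),
    )


def experiment_means(grouped: GroupedValues) -> pd.DataFrame:
    """Mean per (group, experiment) for superplot-style display.

    Also reports the pooled cell-level group mean and the unweighted grand
    mean of experiment means — these differ under unequal per-experiment n,
    and tests always run on the pooled cell-level values.
    """
    df = grouped.to_frame()
    df = df[~df["outlier"]]
    per_exp = (
        df.groupby(["group", "experiment"], sort=True)["value"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "experiment_mean", "count": "n_cells"})
    )
    pooled = df.groupby("group")["value"].mean().rename("pooled_mean")
    grand = (
        per_exp.groupby("group")["experiment_mean"].mean().rename("mean_of_experiment_means")
    )
    per_exp = per_exp.merge(pooled, on="group").merge(grand, on="group")
    return per_exp


def build_summary_table(
    metrics: pd.DataFrame,
    group_col: str = "group",
    experiment_col: str = "experiment_id",
    count_col: str = "filopodia_count",
    ratio_col: str = "cortex_cyto_ratio",
    rout: RoutConfig | None = None,
) -> pd.DataFrame:
    """Per-condition summary in the published table shape.

    For every condition: percent of cells with ≥1 filopodium, mean ± SEM
    of the count among those cells, mean ± SEM of the cortex:cytoplasm
    ratio after ROUT filtering (applied to the ratio only), the number of
    experiments N and of cells n.  Conditions with zero cells are omitted
    with a warning.
    """
    rout = rout or RoutConfig()
    rows = []
    for group, sub in metrics.groupby(group_col, sort=True):
        if len(sub) == 0:
            warnings.warn(f"condition {group!r} has zero cells: omitted", stacklevel=2)
            continue
        counts = sub[count_col].to_numpy(dtype=float)
        counts = counts[np.isfinite(counts)].astype(int)
        fsum = None
        if counts.size:
            from .filopodia import summarize_filopodia

            fsum = summarize_filopodia(counts)
        ratios = sub[ratio_col].to_numpy(dtype=float)
        ratios = ratios[np.isfinite(ratios)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kept, _ = rout_filter(ratios, rout)
        ratio_mean = float(kept.mean()) if kept.size else np.nan
        ratio_sem = (
            float(kept.std(ddof=1) / np.sqrt(kept.size)) if kept.size > 1 else 0.0
        )
        rows.append(
            {
                "group": group,
                "percent_with_filopodia": fsum.percent_with_filopodia if fsum else np.nan,
                "filopodia_mean_positive": fsum.mean_count_positive if fsum else np.nan,
                "filopodia_sem_positive": fsum.sem_count_positive if fsum else np.nan,
                "cortex_cyto_ratio_mean": ratio_mean,
                "cortex_cyto_ratio_sem": ratio_sem,
                "n_ratio_outliers": int(ratios.size - kept.size),
                "N_experiments": int(sub[experiment_col].nunique()),
                "n_cells": int(len(sub)),
            }
        )
    return pd.DataFrame(rows)
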