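"""Group comparison: one-way ANOVA, Tukey HSD and percent differences.

Works either from raw per-sample data or — the case needed when only a
published summary table is available — from per-group summary statistics
(mean, SD, n).  The summary-statistics path is algebraically identical
to the raw-data ANOVA: the between- and within-group sums of squares are
fully determined by the group means, SDs and sizes, so both routes agree
to machine precision on moment-matched data.

Tukey's honestly-significant-difference post hoc uses the studentized
range distribution with the pooled within-group mean square; for
unbalanced designs the harmonic mean of the pair's group sizes is used
(Tukey–Kramer).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupSummary:
    """Per-group summary statistics of one variable."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0")


@dataclass
class StatsResult:
    F: float
    df: tuple[int, int]  # (between, within)
    p: float
    posthoc: dict[tuple[str, str], float] = field(default_factory=dict)
    percent_diffs: dict[tuple[str, str], float] = field(default_factory=dict)
    zero_variance_flag: bool = False


def summarize_groups(data: dict[str, np.ndarray]) -> list[GroupSummary]:
    """Raw samples per group -> summary statistics (SD with ddof=1)."""
    return [
        GroupSummary(label=k, mean=float(np.mean(v)), sd=float(np.std(v, ddof=1)), n=len(v))
        for k, v in data.items()
    ]


def _mean_squares(groups: list[GroupSummary]) -> tuple[float, float, int, int]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    k = len(groups)
    ns = np.array([g.n for g in groups], dtype=np.float64)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    n_total = ns.sum()
    grand = float((ns * means).sum() / n_total)
    df_b = k - 1
    df_w = int(n_total) - k
    ms_between = float((ns * (means - grand) ** 2).sum()) / df_b
    ms_within = float(((ns - 1) * sds**2).sum()) / df_w
    return ms_between, ms_within, df_b, df_w


def anova_from_summary(groups: list[GroupSummary]) -> StatsResult:
    """One-way ANOVA from per-group (mean, SD, n).

    ``F = MS_between / MS_within`` with ``MS_between = sum n_i (mean_i -
    grand)^2 / (k-1)`` and ``MS_within = sum (n_i - 1) sd_i^2 /
    (N - k)``; p from the F distribution.  Zero within-group variance
    with unequal means is reported as p = 0 with a flag (the F statistic
    is infinite).
    """
    ms_b, ms_w, df_b, df_w = _mean_squares(groups)
    if ms_w == 0:
        if ms_b == 0:
            return StatsResult(F=0.0, df=(df_b, df_w), p=1.0)
        return StatsResult(F=math.inf, df=(df_b, df_w), p=0.0, zero_variance_flag=True)
    F = ms_b / ms_w
    p = float(sps.f.sf(F, df_b, df_w))
    return StatsResult(F=float(F), df=(df_b, df_w), p=p)


def anova_from_raw(data: dict[str, np.ndarray]) -> StatsResult:
    """One-way ANOVA from raw per-group samples (via the summary path —
    the two are algebraically identical)."""
    return anova_from_summary(summarize_groups(data))


def tukey_from_summary(groups: list[GroupSummary]) -> dict[tuple[str, str], float]:
    """Tukey HSD adjusted p per group pair, from summary statistics.

    ``q = |mean_i - mean_j| / sqrt(MS_within / n_h)`` with ``n_h`` the
    harmonic mean of the pair's sizes (equal n in a balanced design);
    p from the studentized range distribution with k groups and the
    within-group degrees of freedom.
    """
    ms_b, ms_w, df_b, df_w = _mean_squares(groups)
    k = len(groups)
    out: dict[tuple[str, str], float] = {}
    for g1, g2 in itertools.combinations(groups, 2):
        pair = (g1.label, g2.label)
        if ms_w == 0:
            out[pair] = 1.0 if g1.mean == g2.mean else 0.0
            continue
        n_h = 2.0 / (1.0 / g1.n + 1.0 / g2.n)
        q = abs(g1.mean - g2.mean) / math.sqrt(ms_w / n_h)
        out[pair] = float(sps.studentized_range.sf(q, k, df_w))
    return out


def signed_rank_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired raw data (statistic, p).

    The non-parametric branch for paired comparisons (e.g. cis vs trans
    within animals); it requires raw data and cannot run from summaries.
    """
    res = sps.wilcoxon(a, b)
    return float(res.statistic), float(res.pvalue)


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of printed tables)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percent_difference(test: float, reference: float, decimals: int = 0) -> float:
    """``100 * (test/reference - 1)``, rounded half away from zero."""
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return round_half_away(100.0 * (test / reference - 1.0), decimals)


def build_comparison_table(
    samples: pd.DataFrame,
    group_col: str = "group",
    variable_col: str = "variable",
    value_col: str = "value",
    percent_decimals: int = 1,
) -> pd.DataFrame:
    """Per-variable group summaries, ANOVA, Tukey and percent differences.

    ``samples`` is long-format raw data (one row per sample x variable).
    Missing values are kept as flagged rows, never silently dropped.
    Returns one row per variable with group mean/sd/n columns, the ANOVA
    F and p, Tukey adjusted p per pair and all pairwise percent
    differences of the group means.
    """
    group_labels = sorted(samples[group_col].unique())
    if len(group_labels) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for variable, sub in samples.groupby(variable_col):
        row: dict[str, object] = {"variable": variable}
        data = {}
        incomplete = False
        for g in group_labels:
            vals = sub.loc[sub[group_col] == g, value_col]
            missing = int(vals.isna().sum())
            vals = vals.dropna().to_numpy(dtype=float)
            if missing:
                incomplete = True
            row[f"{g}_mean"] = float(np.mean(vals)) if vals.size else np.nan
            row[f"{g}_sd"] = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
            row[f"{g}_n"] = int(vals.size)
            if vals.size >= 2:
                data[g] = vals
        row["incomplete"] = incomplete
        if len(data) >= 2:
            summaries = summarize_groups(data)
            res = anova_from_summary(summaries)
            row["anova_F"] = res.F
            row["anova_p"] = res.p
            row["zero_variance_flag"] = res.zero_variance_flag
            for pair, p in tukey_from_summary(summaries).items():
                row[f"tukey_{pair[0]}_vs_{pair[1]}_p"] = p
        for g1, g2 in itertools.combinations(group_labels, 2):
            m1, m2 = row.get(f"{g1}_mean"), row.get(f"{g2}_mean")
            if m1 is not None and m2 is not None and np.isfinite([m1, m2]).all() and m1 != 0:
                # convention: later group relative to earlier (test vs reference)
                row[f"pct_{g2}_vs_{g1}"] = percent_difference(m2, m1, percent_decimals)  # type: ignore[arg-type]
        rows.append(row)
    return pd.DataFrame(rows)
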