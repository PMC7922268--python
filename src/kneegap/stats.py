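"""Cohort statistics and report tables.

Group summaries ("mean +/- SD (range)"), Welch two-sample t-test, one-way
ANOVA with Tukey HSD post hoc and a compact-letter display, Pearson
chi-squared for categorical ratios, balance-rate tables and 1-mm-binned
imbalance histograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GroupSummary",
    "summarize",
    "welch_t",
    "anova_posthoc",
    "chi_squared",
    "balance_rate_table",
    "imbalance_histogram",
    "ALPHA",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float  # sample SD (n-1); NaN for n = 1
    min: float
    max: float

    def format(self, fmt: str = "{:.1f}") -> str:
        sd = "NA" if np.isnan(self.sd) else fmt.format(self.sd)
        return (
            f"{fmt.format(self.mean)} ± {sd} "
            f"({fmt.format(self.min)}, {fmt.format(self.max)})"
        )


def summarize(values: Sequence[float]) -> GroupSummary:
    """Arithmetic mean, sample SD and range of a metric selection."""
    a = np.asarray(values, dtype=float)
    if a.size == 0:
        raise ValueError("summarize: empty selection")
    sd = float(np.std(a, ddof=1)) if a.size > 1 else float("nan")
    return GroupSummary(
        n=int(a.size), mean=float(np.mean(a)), sd=sd, min=float(np.min(a)), max=float(np.max(a))
    )


def welch_t(a: Sequence[float], b: Sequence[float]) -> dict:
    """Welch unequal-variance two-sample t-test (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires n >= 2 per group")
    res = sps.ttest_ind(a, b, equal_var=False)
    va, vb = np.var(a, ddof=1) / a.size, np.var(b, ddof=1) / b.size
    if va + vb == 0:
        df = float(a.size + b.size - 2)
        return {"t": 0.0, "df": df, "p": 1.0}
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return {"t": float(res.statistic), "df": float(df), "p": float(res.pvalue)}


def _compact_letters(names: list, nonsig: set) -> dict:
    """Compact-letter display via the insert-and-absorb algorithm: groups
    sharing a letter are not significantly different."""
    sets: list[set] = [set(names)]
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            if (gi, gj) in nonsig or (gj, gi) in nonsig:
                continue
            new_sets = []
            for s in sets:
                if gi in s and gj in s:
                    new_sets.extend([s - {gi}, s - {gj}])
                else:
                    new_sets.append(s)
            # absorb subsets
            sets = [
                s
                for s in new_sets
                if s and not any(s < t for t in new_sets if s is not t)
            ]
            # dedupe
            uniq = []
            for s in sets:
                if s not in uniq:
                    uniq.append(s)
            sets = uniq
    letters = {g: "" for g in names}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", sets):
        for g in s:
            letters[g] += letter
    return letters


def anova_posthoc(groups: dict, paired_by_knee: bool = False, alpha: float = ALPHA) -> dict:
    """One-way ANOVA over >= 3 groups with Tukey HSD post hoc comparisons.

    Returns the F statistic, its p-value, the Tukey pairwise table and a
    compact-letter display (groups sharing a letter do not differ at
    ``alpha``). ``paired_by_knee=True`` switches the omnibus test to a
    repeated-measures ANOVA (groups must then be aligned, equal-length
    per-knee sequences); Tukey comparisons remain unpaired.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 3:
        raise ValueError("anova_posthoc requires >= 3 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("anova_posthoc requires >= 2 values per group")
    if paired_by_knee:
        if len({a.size for a in arrays}) != 1:
            raise ValueError("paired ANOVA requires equal group sizes")
        data = np.column_stack(arrays)
        n, k = data.shape
        grand = data.mean()
        ss_treat = n * ((data.mean(axis=0) - grand) ** 2).sum()
        ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
        ss_tot = ((data - grand) ** 2).sum()
        ss_err = ss_tot - ss_treat - ss_subj
        df_t, df_e = k - 1, (k - 1) * (n - 1)
        F = (ss_treat / df_t) / (ss_err / df_e)
        p = float(sps.f.sf(F, df_t, df_e))
    else:
        F, p = sps.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([np.full(a.size, g) for g, a in zip(names, arrays)])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    frame = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    nonsig = {
        (row["group1"], row["group2"]) for _, row in frame.iterrows() if not row["reject"]
    }
    return {
        "F": float(F),
        "p": float(p),
        "tukey": frame,
        "letters": _compact_letters(names, nonsig),
    }


def chi_squared(counts) -> dict:
    """Pearson chi-squared test (no continuity correction) on an r x k table."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("chi_squared expects a 2D contingency table")
    expected = sps.contingency.expected_freq(table)
    if np.any(expected <= 0):
        raise ValueError("chi_squared: zero expected count")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return {"chi2": float(chi2), "df": int(df), "p": float(p)}


def balance_rate_table(results: pd.DataFrame, thresholds=(1.0, 2.0, 3.0)) -> pd.DataFrame:
    """Percentage of knees per method x group whose medial and lateral |FEI|
    are simultaneously within each threshold."""
    if results.empty:
        raise ValueError("balance_rate_table: empty results")
    rows = []
    for (method, group), sub in results.groupby(["method", "group"], sort=False):
        row = {"method": method, "group": group, "n": len(sub)}
        for t in thresholds:
            ok = (sub["fei_med"].abs() <= t) & (sub["fei_lat"].abs() <= t)
            row[f"balanced_le_{t:g}mm_pct"] = 100.0 * ok.mean()
        rows.append(row)
    return pd.DataFrame(rows)


def imbalance_histogram(values: Sequence[float], bin_width: float = 1.0) -> pd.DataFrame:
    """Histogram over half-open bins [k*w, (k+1)*w); proportions sum to 1."""
    a = np.asarray(values, dtype=float)
    if a.size == 0:
        raise ValueError("imbalance_histogram: empty input")
    k = np.floor(a / bin_width).astype(int)
    lo, hi = k.min(), k.max()
    edges = np.arange(lo, hi + 2) * bin_width
    counts = np.bincount(k - lo, minlength=hi - lo + 1)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "proportion": counts / a.size,
        }
    )
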