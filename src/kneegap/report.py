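"""Report generation: cohort tables, figures and a stats JSON."""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .anatomy import METHODS
from .stats import (
    anova_posthoc,
    balance_rate_table,
    imbalance_histogram,
    summarize,
    welch_t,
)

__all__ = ["write_report"]


def _summary_row(values) -> dict:
    s = summarize(values)
    return {"n": s.n, "mean": s.mean, "sd": s.sd, "min": s.min, "max": s.max}


def _extension_table(per_knee: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for group, sub in per_knee.groupby("group", sort=False):
        for metric in ("mli_ext", "ext_med", "ext_lat"):
            rows.append({"group": group, "metric": metric, **_summary_row(sub[metric])})
    return pd.DataFrame(rows)


def _flexion_table(results: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (method, group), sub in results.groupby(["method", "group"], sort=False):
        for metric in ("mli_flex", "flex_med", "flex_lat"):
            rows.append(
                {"method": method, "group": group, "metric": metric, **_summary_row(sub[metric])}
            )
    return pd.DataFrame(rows)


def _fe_table(results: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (method, group), sub in results.groupby(["method", "group"], sort=False):
        for comp, ext_c, flex_c, fei_c in (
            ("medial", "ext_med", "flex_med", "fei_med"),
            ("lateral", "ext_lat", "flex_lat", "fei_lat"),
        ):
            row = {"method": method, "group": group, "compartment": comp}
            for label, col in (("extension", ext_c), ("flexion", flex_c), ("delta", fei_c)):
                s = summarize(sub[col])
                row.update({f"{label}_mean": s.mean, f"{label}_sd": s.sd})
            rows.append(row)
    return pd.DataFrame(rows)


def _group_tests(results: pd.DataFrame) -> dict:
    """Varus-vs-valgus Welch tests and across-method ANOVA, where group sizes allow."""
    out: dict = {}
    per_knee = results.drop_duplicates("knee_id")
    groups = {g: sub["mli_ext"].to_numpy() for g, sub in per_knee.groupby("group")}
    if {"varus", "valgus"} <= set(groups) and all(len(v) >= 2 for v in groups.values()):
        out["mli_ext_varus_vs_valgus"] = welch_t(groups["varus"], groups["valgus"])
    for metric in ("mli_flex", "fei_med", "fei_lat"):
        for group, sub in results.groupby("group", sort=False):
            by_method = {
                m: s[metric].to_numpy() for m, s in sub.groupby("method", sort=False)
            }
            if len(by_method) >= 3 and all(len(v) >= 2 for v in by_method.values()):
                res = anova_posthoc(by_method)
                out[f"{metric}_anova_{group}"] = {
                    "F": res["F"],
                    "p": res["p"],
                    "letters": res["letters"],
                }
    return out


def _histogram_figure(path, series: dict, title: str, xlabel: str) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, values in series.items():
        h = imbalance_histogram(values)
        centers = (h["bin_left"] + h["bin_right"]) / 2
        ax.bar(centers, 100 * h["proportion"], width=0.9, alpha=0.55, label=label)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("patients (%)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def write_report(results: pd.DataFrame, out_dir, metadata: dict | None = None) -> dict:
    """Write all report artifacts for a results table; returns written paths."""
    if results.empty:
        raise ValueError("write_report: empty results table")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_knee = results.drop_duplicates("knee_id")

    paths = {}
    tables = {
        "extension_mli.csv": _extension_table(per_knee),
        "flexion_mli.csv": _flexion_table(results),
        "flexion_extension_imbalance.csv": _fe_table(results),
        "balance_rates.csv": balance_rate_table(results),
    }
    for name, table in tables.items():
        table.to_csv(out / name, index=False)
        paths[name] = str(out / name)

    series_ext = {
        g: sub["mli_ext"].to_numpy() for g, sub in per_knee.groupby("group", sort=False)
    }
    _histogram_figure(
        out / "mli_extension_hist.png", series_ext, "MLI in extension", "MLI (mm)"
    )
    paths["mli_extension_hist.png"] = str(out / "mli_extension_hist.png")
    for method in [m for m in METHODS if m in set(results["method"])]:
        sub = results[results["method"] == method]
        _histogram_figure(
            out / f"mli_flexion_{method}_hist.png",
            {g: s["mli_flex"].to_numpy() for g, s in sub.groupby("group", sort=False)},
            f"MLI in flexion ({method})",
            "MLI (mm)",
        )
        for comp in ("fei_med", "fei_lat"):
            _histogram_figure(
                out / f"{comp}_{method}_hist.png",
                {g: s[comp].to_numpy() for g, s in sub.groupby("group", sort=False)},
                f"{comp.replace('_', ' ').upper()} ({method})",
                "FEI (mm)",
            )

    stats_doc = {"tests": _group_tests(results), "metadata": metadata or {}}
    with open(out / "stats.json", "w") as fh:
        json.dump(stats_doc, fh, indent=1, default=float)
    paths["stats.json"] = str(out / "stats.json")
    return paths
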