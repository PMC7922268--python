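"""Published reference cohort gap means shipped with the package.

These are printed group-mean gap distances (631 varus / 107 valgus knees)
from a reference MRI cohort. They serve as worked-example inputs: the
imbalance operations applied to the printed medial/lateral and
extension/flexion means must reproduce the printed imbalance cells wherever
the printed components reconcile (the ``reconciles`` column marks rows whose
printed imbalance differs from the component difference by printed rounding;
those rows are excluded from exact checks).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .gaps import GapSet, fei, mli

__all__ = [
    "GROUP_N",
    "load_ml_means",
    "load_fe_means",
    "worked_examples_ml",
    "worked_examples_fe",
    "acceptance_values",
]

GROUP_N = {"varus": 631, "valgus": 107}


def _load(name: str) -> pd.DataFrame:
    with resources.files("kneegap.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_ml_means() -> pd.DataFrame:
    """Printed medial/lateral gap means per pose (extension rows are
    method-independent, tagged method='all')."""
    return _load("reference_gap_means_ml.csv")


def load_fe_means() -> pd.DataFrame:
    """Printed extension/flexion gap means per method, group and compartment."""
    return _load("reference_gap_means_fe.csv")


def _ml_gapset(row) -> GapSet:
    if row["pose"] == "extension":
        return GapSet(ext_med=row["medial"], ext_lat=row["lateral"], flex_med=0.0, flex_lat=0.0)
    return GapSet(ext_med=0.0, ext_lat=0.0, flex_med=row["medial"], flex_lat=row["lateral"])


def worked_examples_ml() -> pd.DataFrame:
    """MLI computed from the printed gap means, next to the printed imbalance."""
    df = load_ml_means().copy()
    df["computed_imbalance"] = [
        mli(_ml_gapset(row), row["pose"]) for _, row in df.iterrows()
    ]
    return df


def worked_examples_fe() -> pd.DataFrame:
    """FEI computed from the printed gap means, next to the printed delta."""
    df = load_fe_means().copy()
    computed = []
    for _, row in df.iterrows():
        if row["compartment"] == "medial":
            g = GapSet(ext_med=row["extension"], ext_lat=0.0, flex_med=row["flexion"], flex_lat=0.0)
        else:
            g = GapSet(ext_med=0.0, ext_lat=row["extension"], flex_med=0.0, flex_lat=row["flexion"])
        computed.append(fei(g, row["compartment"]))
    df["computed_delta"] = computed
    return df


def acceptance_values() -> dict:
    """The eight reconcilable worked-example imbalances, computed at call time
    from the shipped printed means via the package's MLI/FEI operations."""
    ml = worked_examples_ml().set_index(["pose", "method", "group"])
    fe = worked_examples_fe().set_index(["method", "group", "compartment"])

    def _ml(pose, method, group):
        row = ml.loc[(pose, method, group)]
        return {"value": round(float(row["computed_imbalance"]), 10), "n": GROUP_N[group]}

    def _fe(method, group, compartment):
        row = fe.loc[(method, group, compartment)]
        return {"value": round(float(row["computed_delta"]), 10), "n": GROUP_N[group]}

    return {
        "t1": _ml("extension", "all", "varus"),
        "t2": _ml("flexion", "TEA", "varus"),
        "t3": _ml("flexion", "PCA", "valgus"),
        "t4": _ml("flexion", "WSL", "varus"),
        "t5": _ml("flexion", "FEA", "valgus"),
        "t6": _fe("TEA", "varus", "medial"),
        "t7": _fe("TEA", "valgus", "lateral"),
        "t8": _fe("FEA", "valgus", "lateral"),
    }
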