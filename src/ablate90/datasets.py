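"""Bundled reference cohort.

A published retrospective cohort of 15 liver tumors (14 patients; one
patient had two independently treated foci) that received ⁹⁰Y
radioembolization followed by simulated adjuvant RF ablation.  The table
records, per tumor: disease, microsphere device, infused activity, the
number and duration of ablation sites, and pre-/post-ablation tumor volume,
together with the percent volume change as printed in the source report.
It anchors the bookkeeping conventions of the analysis (site-count totals,
volume differences, and the post-denominator percent volume change).
"""

from __future__ import annotations

import math
from importlib import resources

import pandas as pd

from .pipeline import pct_volume_change

__all__ = [
    "load_reference_cohort",
    "round_half_up",
    "recomputed_pct_volume_change",
    "summarize_reference_cohort",
]


def load_reference_cohort() -> pd.DataFrame:
    """Per-tumor rows of the bundled reference cohort."""
    with resources.files("ablate90.data").joinpath("reference_cohort.csv").open() as fh:
        return pd.read_csv(fh)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (the tabulation convention;
    numpy/python banker's rounding would flip exact .x5 ties)."""
    scale = 10 ** decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def recomputed_pct_volume_change(df: pd.DataFrame | None = None) -> pd.Series:
    """Percent volume change recomputed from the pre/post volumes with the
    post-ablation denominator, rounded half-up to one decimal."""
    if df is None:
        df = load_reference_cohort()
    return pd.Series(
        [round_half_up(pct_volume_change(pre, post))
         for pre, post in zip(df["pre_volume_cm3"], df["post_volume_cm3"])],
        index=df.index, name="pct_volume_change",
    )


def summarize_reference_cohort(df: pd.DataFrame | None = None) -> dict[str, float]:
    """Cohort bookkeeping: total ablation simulations (sum of per-tumor site
    counts) and the mean per-tumor pre−post volume difference in cm³."""
    if df is None:
        df = load_reference_cohort()
    return {
        "n_tumors": int(len(df)),
        "n_patients": int(df["patient"].nunique()),
        "total_simulations": int(df["n_sites"].sum()),
        "mean_volume_difference_cm3": float(
            (df["pre_volume_cm3"] - df["post_volume_cm3"]).mean()),
    }
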