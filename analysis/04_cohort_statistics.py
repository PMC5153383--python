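"""Statistical analysis of the adjuvant-ablation cohort table.

Reads results/adjuvant_cohort_table.csv (produced by 03_adjuvant_ablation)
and runs the cohort battery: Lilliefors-corrected KS normality screens,
paired t tests on pre- vs post-ablation metrics, Spearman correlations of
the metric changes against pre-ablation tumor volume, and, where |ρ| > 0.5,
linear regression against the constant model.  Also recomputes the bundled
reference cohort's bookkeeping as a cross-check of conventions.

Writes results/cohort_statistics.csv.
"""

import json
from pathlib import Path

import pandas as pd

from ablate90 import datasets, stats

RESULTS = Path(__file__).resolve().parents[1] / "results"
METRICS = ("d_avg", "d50", "d70", "d90", "v100")


def main() -> None:
    table_path = RESULTS / "adjuvant_cohort_table.csv"
    if not table_path.exists():
        raise SystemExit("run analysis/03_adjuvant_ablation.py first")
    df = pd.read_csv(table_path)
    rows = []

    for metric in METRICS:
        pre = df[f"pre_{metric}"].to_numpy()
        post = df[f"post_{metric}"].to_numpy()
        delta = df[f"delta_{metric}"].to_numpy()
        ks = stats.ks_normality(delta)
        t = stats.paired_t(post, pre)
        rows.append({"test": f"ks_normality_delta_{metric}",
                     "statistic": ks.statistic, "p_value": ks.p_value,
                     "n": ks.n, "significant": ks.significant})
        rows.append({"test": f"paired_t_{metric}_post_vs_pre",
                     "statistic": t.statistic, "p_value": t.p_value,
                     "n": t.n, "significant": t.significant})
        sp = stats.spearman(df["pre_volume_cm3"], delta)
        rows.append({"test": f"spearman_delta_{metric}_vs_volume",
                     "statistic": sp.statistic, "p_value": sp.p_value,
                     "n": sp.n, "significant": sp.significant})
        if stats.correlation_gate(sp.statistic):
            reg = stats.regress_vs_constant(df["pre_volume_cm3"], delta)
            rows.append({"test": f"regression_delta_{metric}_vs_volume",
                         "statistic": reg.slope, "p_value": reg.p_value,
                         "n": reg.n, "significant": reg.significant})
            print(f"Δ{metric} vs volume: ρ = {sp.statistic:+.2f} -> fit slope "
                  f"{reg.slope:+.4f}/cm³, R² = {reg.r_squared:.2f}, "
                  f"P = {reg.p_value:.3g}")

    sites = df["n_sites"].to_numpy()
    dv = (df["pre_volume_cm3"] - df["post_volume_cm3"]).to_numpy()
    if sites.max() > sites.min():  # undefined when every case used one site
        sp = stats.spearman(sites, dv)
        rows.append({"test": "spearman_sites_vs_volume_change",
                     "statistic": sp.statistic, "p_value": sp.p_value,
                     "n": sp.n, "significant": sp.significant})

    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "cohort_statistics.csv", index=False)
    print(out.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

    ref = datasets.summarize_reference_cohort()
    print("\nreference cohort bookkeeping:", json.dumps(ref))
    print(f"wrote {RESULTS / 'cohort_statistics.csv'}")


if __name__ == "__main__":
    main()
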