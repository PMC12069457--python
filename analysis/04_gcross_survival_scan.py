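"""Spatial interactions and survival: KM per stage, then a Cox scan of
pairwise G-cross features at 40 µm with patient-level clustering.

Writes results/km_summary.csv and results/survival_scan_40um.csv.
"""

import itertools

import pandas as pd

import timescape as ts
from timescape.spatial import gcross_feature_table

from common import RESULTS, classified_cohort

cells, clinical = classified_cohort()
RESULTS.mkdir(exist_ok=True)

# Kaplan-Meier per stage + log-rank between stages
rows = []
for stage, clin in clinical.groupby("stage"):
    est = ts.km_estimate(clin["time_months"], clin["event"])
    rows.append(
        {
            "stage": stage,
            "n": est.n,
            "events": est.n_events,
            "median_os_months": round(est.median, 1),
            "median_ci_low": round(est.median_ci[0], 1),
            "median_ci_high": round(est.median_ci[1], 1),
            "surv_5y": round(est.survival_at[60.0], 3),
            "surv_10y": round(est.survival_at[120.0], 3),
        }
    )
km = pd.DataFrame(rows)
stat, p = ts.logrank_test(
    clinical["time_months"], clinical["event"], clinical["stage"]
)
km.to_csv(RESULTS / "km_summary.csv", index=False)
print(km.to_string(index=False))
print(f"log-rank III vs IV: chi2={stat:.2f}, p={p:.2g}\n")

# pairwise G-cross(40) scan within each stage arm
types = ["B", "T", "Th", "CTL", "NK", "TAM", "M2", "Tumor"]
pairs = [(i, j) for i, j in itertools.product(types, types) if i != j]
scans = []
for stage, clin in clinical.groupby("stage"):
    sub = cells[cells["patient_id"].isin(clin["patient_id"])]
    feats = gcross_feature_table(sub, pairs, radii_report=(40.0,))
    cols = [c for c in feats.columns if c.endswith("_40")]
    scan = ts.spatial_survival_scan(feats, clin, feature_cols=cols,
                                    family=f"stage_{stage}_40um")
    scans.append(scan)
out = pd.concat(scans, ignore_index=True)
out.to_csv(RESULTS / "survival_scan_40um.csv", index=False)
sig = out[(out.skip_reason == "") & (out.p < 0.05)]
print(f"{len(sig)} of {len(out)} pairwise interactions reach p<0.05:")
print(sig[["family", "feature", "log_HR", "robust_se", "p", "tier"]].to_string(index=False))
print("\n(The demo hazard is independent of spatial features, so significant "
      "pairs here are the expected false-positive background.)")
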