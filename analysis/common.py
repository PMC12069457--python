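"""Shared cohort for the analysis drivers.

Generates (once, cached under scratch/) a demo-scale two-arm synthetic
cohort shaped like the study: a "Stage III" arm of 40 patients × 2 cores and
a "Stage IV" arm of 60 patients across five metastatic-site strata. Sizes
are scaled down from the full cohorts so every driver runs in seconds; the
full-shape generator (157 × 2 and 248/393) is available via
``timescape.generate_study``.
"""

from pathlib import Path

import pandas as pd

import timescape as ts

SEED = 20250925
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "analysis_cohort"
RESULTS = Path(__file__).resolve().parent.parent / "results"


def load_cohort():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    cells_p = SCRATCH / "cells.csv"
    clin_p = SCRATCH / "clinical.csv"
    if cells_p.exists() and clin_p.exists():
        return pd.read_csv(cells_p), pd.read_csv(clin_p)
    c3, k3, _ = ts.generate_cohort(ts.stage_iii_config(seed=SEED, n_patients=40))
    c4, k4, _ = ts.generate_cohort(
        ts.stage_iv_config(seed=SEED + 1, n_patients=60, cores_per_patient=1)
    )
    cells = pd.concat([c3, c4], ignore_index=True)
    clinical = pd.concat([k3, k4], ignore_index=True)
    from timescape import io as tio

    tio.write_cells(cells, cells_p)
    tio.write_clinical(clinical, clin_p)
    return pd.read_csv(cells_p), pd.read_csv(clin_p)


def classified_cohort():
    cells, clinical = load_cohort()
    return ts.classify_cells(cells), clinical


def stage_of_samples(cells: pd.DataFrame, clinical: pd.DataFrame) -> pd.Series:
    stages = clinical.set_index("patient_id")["stage"]
    return cells.groupby("sample_id")["patient_id"].first().map(stages)
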