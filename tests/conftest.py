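import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# ---------------------------------------------------------------------------
# Independent O(n²) G-cross oracle (plain loops over the definition).


def gcross_bruteforce(xy_i, xy_j, radii, window, correction="raw", same_type=False):
    """Literal nearest-neighbor-CDF computation used as the test oracle."""
    xy_i = np.asarray(xy_i, float)
    xy_j = np.asarray(xy_j, float)
    nn = np.empty(len(xy_i))
    for a, p in enumerate(xy_i):
        best = np.inf
        for b, q in enumerate(xy_j):
            if same_type and a == b:
                continue
            d = np.hypot(p[0] - q[0], p[1] - q[1])
            if d < best:
                best = d
        nn[a] = best
    out = np.empty(len(radii))
    for k, r in enumerate(radii):
        if correction == "raw":
            refs = list(range(len(xy_i)))
        else:
            refs = [
                a for a, p in enumerate(xy_i)
                if min(p[0], p[1], window.width - p[0], window.height - p[1]) >= r
            ]
        out[k] = np.mean([nn[a] <= r for a in refs]) if refs else np.nan
    return out


def bh_bruteforce(p):
    """Step-up BH by the definition: q_(i) = min_{k>=i} p_(k) m / k, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            min(p[order[k]] * m / (k + 1) for k in range(i, m)), 1.0
        )
    q = np.empty(m)
    q[order] = q_sorted
    return q


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-arm classified cohort reused across tests (seeded)."""
    import timescape as ts

    cells3, clin3, _ = ts.generate_cohort(ts.stage_iii_config(seed=101, n_patients=4))
    cells4, clin4, _ = ts.generate_cohort(ts.stage_iv_config(seed=202, n_patients=4))
    cells = pd.concat([cells3, cells4], ignore_index=True)
    clinical = pd.concat([clin3, clin4], ignore_index=True)
    classified = ts.classify_cells(cells)
    return classified, clinical


@pytest.fixture()
def hand_cells():
    """Tiny hand-built single-sample cell table with known marker positivity."""
    # thresholds default to 3.0; intensity 10 = positive, 1 = negative
    rows = [
        # x, y, CD3, CD4, CD8, CD20, CD68, CD163, NKp46, SOX10, CD74, CD44, MIF
        (10, 10, 10, 1, 10, 1, 1, 1, 1, 1, 10, 10, 10),   # CTL, anchor for CD74/CD44/MIF combos
        (20, 10, 10, 10, 1, 1, 1, 1, 1, 1, 1, 1, 1),      # Th
        (90, 90, 1, 1, 1, 10, 1, 1, 1, 1, 10, 1, 1),      # B, CD74 only
        (50, 50, 1, 1, 1, 1, 10, 10, 1, 1, 1, 1, 1),      # M2
        (55, 50, 1, 1, 1, 1, 1, 1, 1, 10, 1, 10, 10),     # Tumor, MIF+CD44
        (70, 70, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1),        # other
    ]
    cols = ["x_um", "y_um", "CD3", "CD4", "CD8", "CD20", "CD68", "CD163",
            "NKp46", "SOX10", "CD74", "CD44", "MIF"]
    df = pd.DataFrame(rows, columns=cols)
    for m in ("iNOS", "mPGES1", "NT"):
        df[m] = 1.0
    df.insert(0, "patient_id", "P1")
    df.insert(0, "sample_id", "S1")
    return df
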