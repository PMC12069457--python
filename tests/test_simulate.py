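"""Synthetic-cohort generator: distributional laws, determinism, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import timescape as ts
from timescape.simulate import (
    AttractionRule,
    MarkerModel,
    SimulationConfig,
    SurvivalLink,
    assign_anchor_positivity,
    generate_cohort,
    generate_study,
    simulate_attraction,
    simulate_marker_intensities,
    simulate_poisson_multitype,
    simulate_survival,
    stage_iii_config,
    stage_iv_config,
)
from timescape.spatial import Window, gcross_arrays, gcross_theoretical
from timescape.phenotyping import classify_cells


class TestPoissonPattern:
    def test_zero_density_empty_table(self):
        out = simulate_poisson_multitype({"A": 0.0, "B": 0.0}, Window(), seed=1)
        assert len(out) == 0

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            simulate_poisson_multitype({"A": -1e-4}, Window(), seed=1)

    def test_same_seed_byte_identical(self):
        a = simulate_poisson_multitype({"A": 2e-4, "B": 1e-4}, Window(), seed=9)
        b = simulate_poisson_multitype({"A": 2e-4, "B": 1e-4}, Window(), seed=9)
        assert a.to_csv() == b.to_csv()

    def test_poisson_mean_and_gof(self):
        counts = np.array(
            [
                len(simulate_poisson_multitype({"A": 0.002}, Window(), seed=s))
                for s in range(200)
            ]
        )
        # mean within 3 standard errors of 2000
        se = np.sqrt(2000 / 200)
        assert abs(counts.mean() - 2000) < 3 * se
        # chi-square GOF against Poisson(2000), binned to expected >= 5
        edges = stats.poisson(2000).ppf(np.linspace(0.001, 0.999, 12))
        obs, _ = np.histogram(counts, np.concatenate([[0], edges, [np.inf]]))
        probs = np.diff(
            stats.poisson(2000).cdf(np.concatenate([[-1], edges, [np.inf]]))
        )
        keep = probs * 200 >= 5
        chi2 = ((obs[keep] - 200 * probs[keep]) ** 2 / (200 * probs[keep])).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01


class TestAttraction:
    def test_zero_mean_offspring(self):
        out = simulate_attraction("P", "O", 1e-4, 0.0, 5.0, Window(), seed=2)
        assert (out["true_type"] == "O").sum() == 0

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            simulate_attraction("P", "O", 1e-4, 1.0, 0.0, Window(), seed=2)

    def test_offspring_inside_window(self):
        out = simulate_attraction("P", "O", 5e-4, 3.0, 30.0, Window(200, 200), seed=3)
        assert out["x_um"].between(0, 200).all()
        assert out["y_um"].between(0, 200).all()

    def test_clustered_pair_lifts_gcross_above_poisson(self):
        w = Window()
        lifts = []
        for s in range(20):
            out = simulate_attraction("P", "O", 5e-4, 5.0, 5.0, w, seed=100 + s)
            xy_p = out.loc[out.true_type == "P", ["x_um", "y_um"]].to_numpy(float)
            xy_o = out.loc[out.true_type == "O", ["x_um", "y_um"]].to_numpy(float)
            g = gcross_arrays(xy_p, xy_o, np.array([20.0]), w, "raw")[0]
            baseline = gcross_theoretical(len(xy_o) / w.area, 20.0)
            lifts.append(g - baseline)
        assert np.mean(lifts) > 0.02

    def test_independent_types_within_null_envelope(self):
        # 500-replicate pointwise 99% envelope of the Poisson closed form
        w = Window()
        radii = np.array([20.0, 40.0, 60.0, 80.0])
        sims, sims_border = [], []
        for s in range(500):
            pat = simulate_poisson_multitype({"i": 5e-4, "j": 5e-4}, w, seed=3000 + s)
            xi = pat.loc[pat.true_type == "i", ["x_um", "y_um"]].to_numpy(float)
            xj = pat.loc[pat.true_type == "j", ["x_um", "y_um"]].to_numpy(float)
            sims.append(gcross_arrays(xi, xj, radii, w, "raw"))
            sims_border.append(gcross_arrays(xi, xj, radii, w, "border"))
        sims = np.array(sims)
        lo, hi = np.quantile(sims, 0.005, axis=0), np.quantile(sims, 0.995, axis=0)
        held_out = sims[0]
        assert np.all(held_out >= lo - 1e-12) and np.all(held_out <= hi + 1e-12)
        # the (unbiased) border-corrected replicate mean tracks the closed form
        theo = gcross_theoretical(5e-4, radii)
        assert np.all(np.abs(np.array(sims_border).mean(axis=0) - theo) < 0.01)


class TestMarkers:
    def _cells(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "x_um": rng.uniform(0, 100, n),
                "y_um": rng.uniform(0, 100, n),
                "true_type": rng.choice(["CTL", "Tumor", "B", "other"], n),
            }
        )

    def test_zero_noise_exact_medians(self):
        cells = self._cells()
        out = simulate_marker_intensities(cells, MarkerModel(sigma=0.0), seed=1)
        ctl = out[out.true_type == "CTL"]
        assert (ctl["CD3"] == 10.0).all() and (ctl["CD8"] == 10.0).all()
        assert (ctl["CD20"] == 1.0).all()

    def test_unknown_type_rejected(self):
        cells = self._cells()
        cells.loc[0, "true_type"] = "Martian"
        with pytest.raises(KeyError):
            simulate_marker_intensities(cells, MarkerModel(), seed=1)

    def test_recovery_high_at_default_separation(self):
        cfg = stage_iii_config(seed=5, n_patients=2)
        cells, _, _ = generate_cohort(cfg)
        out = classify_cells(cells)
        assert (out["phenotype"] == out["true_type"]).mean() >= 0.99

    def test_recovery_degrades_monotonically_with_noise(self):
        rates = []
        for sigma in (0.25, 0.8, 1.6):
            cfg = stage_iii_config(
                seed=6, n_patients=2, marker_model=MarkerModel(sigma=sigma)
            )
            cells, _, _ = generate_cohort(cfg)
            out = classify_cells(cells)
            rates.append((out["phenotype"] == out["true_type"]).mean())
        assert rates[0] > rates[1] > rates[2]

    def test_anchor_rates_respected(self):
        cells = self._cells(n=5000, seed=2)
        flags = assign_anchor_positivity(cells, {"CD74_MIF": 0.1}, seed=3)
        rate = flags["anchor_CD74_MIF"].mean()
        assert abs(rate - 0.1) < 3 * np.sqrt(0.1 * 0.9 / 5000)


class TestSurvival:
    def _features(self, n, rng=None, binary=False):
        x = (
            (np.arange(n) % 2).astype(float)
            if binary
            else (rng.uniform(0, 1, n) if rng is not None else np.zeros(n))
        )
        return pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(n)],
             "patient_id": [f"p{i}" for i in range(n)], "f": x}
        )

    def test_invalid_baseline_rejected(self):
        with pytest.raises(ValueError):
            SurvivalLink(baseline_hazard=0.0)

    def test_no_censoring_all_events(self):
        feats = self._features(100)
        link = SurvivalLink(baseline_hazard=0.05, censoring_rate=0.0)
        clin = simulate_survival(feats, link, seed=4)
        assert (clin["event"] == 1).all()

    def test_null_model_km_median_matches_closed_form(self):
        feats = self._features(2000)
        link = SurvivalLink(baseline_hazard=0.05, censoring_rate=0.0)
        clin = simulate_survival(feats, link, seed=5)
        est = ts.km_estimate(clin["time_months"], clin["event"])
        # exponential median ln2/0.05 = 13.86; MC error ~ 13.86/sqrt(2000)*1.25
        assert abs(est.median - np.log(2) / 0.05) < 1.2

    def test_binary_feature_log_hr_recovered(self):
        feats = self._features(1000, binary=True)
        link = SurvivalLink(
            baseline_hazard=0.05, coefficients={"f": np.log(2)}, censoring_rate=0.0
        )
        clin = simulate_survival(feats, link, seed=6)
        merged = feats.merge(clin, on="patient_id")
        fit = ts.fit_cox_univariate(
            merged["f"], merged["time_months"], merged["event"], merged["patient_id"]
        )
        assert abs(fit.coef - np.log(2)) < 3 * fit.se_robust

    def test_recovery_rate_across_replicates(self):
        # configured log-HR recovered within 3 robust SE in >= 95% of runs
        hits = 0
        for s in range(40):
            rng = np.random.default_rng(s)
            feats = self._features(300, rng=rng)
            link = SurvivalLink(
                baseline_hazard=0.05, coefficients={"f": 1.0}, censoring_rate=0.01
            )
            clin = simulate_survival(feats, link, seed=1000 + s)
            merged = feats.merge(clin, on="patient_id")
            fit = ts.fit_cox_univariate(
                merged["f"], merged["time_months"], merged["event"], merged["patient_id"]
            )
            hits += abs(fit.coef - 1.0) <= 3 * fit.se_robust
        assert hits / 40 >= 0.95


class TestCohort:
    def test_study_shape_core_counts(self):
        cfg = stage_iii_config(seed=1, n_patients=157, cores_per_patient=2)
        assert cfg.n_patients * cfg.cores_per_patient == 314
        cells, clinical, _ = generate_cohort(
            stage_iii_config(seed=1, n_patients=5)
        )
        assert cells["sample_id"].nunique() == 10
        assert len(clinical) == 5

    def test_determinism_under_fixed_seed(self):
        a = generate_cohort(stage_iii_config(seed=33, n_patients=2))[0]
        b = generate_cohort(stage_iii_config(seed=33, n_patients=2))[0]
        assert a.to_csv() == b.to_csv()

    def test_study_sizes_match_cohort_description(self):
        cells, clinical, _ = generate_study(seed=0)
        by_stage = cells.groupby(
            cells["sample_id"].str.startswith("III")
        )["sample_id"].nunique()
        assert by_stage[True] == 314
        assert by_stage[False] == 393
        assert (clinical["stage"] == "IV").sum() == 248
        assert set(clinical.loc[clinical.stage == "IV", "site"]) == {
            "GI", "Skin", "LymphNode", "Lung", "Other"
        }

    def test_stage_effect_recovered_by_beta_regression(self):
        # configured CTL density ratio IV:III of 2 -> positive, significant
        # stage coefficient in >= 95% of replicates
        dens = {t: d * 0.6 for t, d in ts.simulate.DEFAULT_DENSITIES.items()}
        dens_iv = dict(dens)
        dens_iv["CTL"] = dens["CTL"] * 2.0
        hits = 0
        n_rep = 50
        for s in range(n_rep):
            common = dict(
                n_patients=30, cores_per_patient=2, density_sigma=0.4,
                simulate_markers=False,
            )
            c3, _, _ = generate_cohort(
                stage_iii_config(seed=5000 + s, type_densities=dens, **common)
            )
            c4, _, _ = generate_cohort(
                stage_iv_config(seed=6000 + s, type_densities=dens_iv,
                                site_probs=None, anchor_rates={}, **common)
            )
            cells = pd.concat([c3, c4], ignore_index=True)
            prop = (
                cells.assign(is_ctl=cells["true_type"] == "CTL")
                .groupby("sample_id")["is_ctl"].mean()
            )
            groups = pd.Series(
                np.where(prop.index.str.startswith("III"), "III", "IV"),
                index=prop.index,
            )
            res = ts.compare_cohorts(prop.to_frame("CTL"), groups)
            row = res.iloc[0]
            hits += (row["beta"] > 0) and (row["q"] < 0.05)
        assert hits / n_rep >= 0.95
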