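"""Abundance estimation: L2R, probe weights, medians, plate scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoabund.abundance import (
    abundance_table,
    compute_l2r,
    compute_ml2rauto,
    compute_ml2rmt,
    fit_probe_weights,
    standardize_by_plate,
)
from tests.conftest import make_intensity


class TestComputeL2R:
    @pytest.mark.parametrize(
        "obs,ref,expected",
        [(500.0, 500.0, 0.0), (1000.0, 500.0, 1.0), (300.0, 400.0, np.log2(0.75))],
    )
    def test_values(self, obs, ref, expected):
        assert compute_l2r(obs, ref) == pytest.approx(expected, abs=1e-6)

    @given(
        x=st.floats(1e-3, 1e6), y=st.floats(1e-3, 1e6), k=st.floats(1e-3, 1e3)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, x, y, k):
        assert compute_l2r(k * x, k * y) == pytest.approx(compute_l2r(x, y), abs=1e-8)

    def test_rejects_nonpositive_naming_probe(self):
        with pytest.raises(ValueError, match="MT_0"):
            compute_l2r(
                np.array([100.0, -1.0]), np.array([100.0, 100.0]),
                probe_id=["MT_9", "MT_0"], sample_id=["S1", "S2"],
            )


class TestFitProbeWeights:
    def test_perfect_predictor_recovers_unit_weight(self):
        rng = np.random.default_rng(0)
        cov = rng.normal(0, 1, 200)
        intensity = make_intensity(cov[:, None], "MT")
        coverage = pd.DataFrame(
            {"sample_id": [f"S{i}" for i in range(200)], "normalized_mt_coverage": cov}
        )
        fit = fit_probe_weights(intensity, coverage)
        assert fit.table.selected.all()
        assert fit.table.weight.iloc[0] == pytest.approx(1.0, abs=1e-8)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)

    def test_pure_noise_probe_rarely_selected(self):
        """Null probe held at alpha: selected in well under 10% of refits."""
        rng = np.random.default_rng(1)
        n, hits, reps = 400, 0, 100
        for _ in range(reps):
            signal = rng.normal(0, 1, n)
            l2r = np.column_stack([signal + rng.normal(0, 0.5, n), rng.normal(0, 1, n)])
            coverage = pd.DataFrame(
                {
                    "sample_id": [f"S{i}" for i in range(n)],
                    "normalized_mt_coverage": signal + rng.normal(0, 0.3, n),
                }
            )
            fit = fit_probe_weights(make_intensity(l2r, "MT"), coverage)
            hits += bool(fit.table.selected.iloc[1])
        assert hits <= 10

    def test_rank_deficient_design_names_probes(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 50)
        l2r = np.column_stack([x, x, rng.normal(0, 1, 50)])
        coverage = pd.DataFrame(
            {"sample_id": [f"S{i}" for i in range(50)], "normalized_mt_coverage": x}
        )
        with pytest.raises(ValueError, match="MT_0.*MT_1|collinear"):
            fit_probe_weights(make_intensity(l2r, "MT"), coverage)

    def test_more_probes_than_samples_rejected(self):
        rng = np.random.default_rng(3)
        l2r = rng.normal(0, 1, (5, 8))
        coverage = pd.DataFrame(
            {"sample_id": [f"S{i}" for i in range(5)], "normalized_mt_coverage": rng.normal(0, 1, 5)}
        )
        with pytest.raises(ValueError, match="more samples than probes"):
            fit_probe_weights(make_intensity(l2r, "MT"), coverage)


class TestMedians:
    def _weights(self, probe_ids, weights):
        return pd.DataFrame(
            {"probe_id": probe_ids, "weight": weights, "p_value": 0.0, "selected": True}
        )

    def test_plain_median(self):
        intensity = make_intensity(np.array([[0.1, 0.2, 0.3]]), "MT")
        w = self._weights(["MT_0", "MT_1", "MT_2"], [1.0, 1.0, 1.0])
        out = compute_ml2rmt(intensity, w)
        assert out.ml2rmt_raw.iloc[0] == pytest.approx(0.2)

    def test_even_count_mean_of_middle_two(self):
        intensity = make_intensity(np.array([[0.1, 0.3]]), "MT")
        w = self._weights(["MT_0", "MT_1"], [2.0, 1.0])
        out = compute_ml2rmt(intensity, w)
        assert out.ml2rmt_raw.iloc[0] == pytest.approx(0.25)  # median of {0.2, 0.3}

    def test_singleton_selection(self):
        intensity = make_intensity(np.array([[0.4, 0.9, -0.2]]), "MT")
        w = pd.DataFrame(
            {
                "probe_id": ["MT_0", "MT_1", "MT_2"],
                "weight": [0.0, 3.0, 0.0],
                "p_value": [0.9, 0.001, 0.9],
                "selected": [False, True, False],
            }
        )
        out = compute_ml2rmt(intensity, w)
        assert out.ml2rmt_raw.iloc[0] == pytest.approx(3.0 * 0.9)

    def test_unweighted_all_is_plain_median(self):
        intensity = make_intensity(np.array([[1.0, 2.0, 10.0]]), "MT")
        out = compute_ml2rmt(intensity, method="unweighted_all")
        assert out.ml2rmt_raw.iloc[0] == pytest.approx(2.0)

    def test_unweighted_subset(self):
        intensity = make_intensity(np.array([[1.0, 2.0, 10.0]]), "MT")
        out = compute_ml2rmt(intensity, method="unweighted_subset", subset=["MT_0", "MT_2"])
        assert out.ml2rmt_raw.iloc[0] == pytest.approx(5.5)

    def test_all_probes_missing_flagged(self):
        intensity = make_intensity(np.array([[np.nan, np.nan], [0.1, 0.2]]), "MT")
        out = compute_ml2rmt(intensity, method="unweighted_all")
        row = out.set_index("sample_id")
        assert np.isnan(row.loc["S0", "ml2rmt_raw"]) and row.loc["S0", "all_probes_missing"]
        assert row.loc["S1", "ml2rmt_raw"] == pytest.approx(0.15)


class TestMl2rauto:
    def test_zero_and_unit_l2r(self):
        intensity = make_intensity(np.array([[0.0, 0.0], [1.0, 1.0]]), "autosomal")
        out = compute_ml2rauto(intensity).set_index("sample_id")
        assert out.loc["S0", "ml2rauto_raw"] == pytest.approx(0.0)
        assert out.loc["S1", "ml2rauto_raw"] == pytest.approx(1.0)

    def test_call_rate_correlation_sign_matches_confounding(self):
        from mitoabund.synthio import SimulationConfig, simulate_cohort

        c = simulate_cohort(
            SimulationConfig(seed=6, n_samples=3000, n_mt_probes=2, n_variants=2,
                             missingness_confounding=1.0)
        )
        auto = compute_ml2rauto(c.intensity).set_index("sample_id")
        merged = auto.join(c.truth.set_index("sample_id").call_rate)
        assert merged.ml2rauto_raw.corr(merged.call_rate, method="spearman") > 0


class TestStandardizeByPlate:
    def test_three_sample_plate(self):
        out = standardize_by_plate(np.array([1.0, 2.0, 3.0]), ["A", "A", "A"])
        np.testing.assert_allclose(out.to_numpy(), [-1.0, 0.0, 1.0])

    def test_constant_plate_set_missing(self):
        out = standardize_by_plate(np.array([5.0, 5.0, 5.0]), ["A", "A", "A"])
        assert out.isna().all()

    def test_singleton_plate_set_missing(self):
        out = standardize_by_plate(np.array([1.0, 2.0, 3.0]), ["A", "A", "B"])
        assert np.isnan(out.iloc[2])
        np.testing.assert_allclose(out.iloc[:2].to_numpy(), [-1.0, 1.0] / np.sqrt(2), atol=1e-12)

    def test_idempotence(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 3, 500)
        plates = np.repeat([f"P{i}" for i in range(5)], 100)
        once = standardize_by_plate(x, plates)
        twice = standardize_by_plate(once, plates)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-9)

    def test_within_plate_moments(self):
        rng = np.random.default_rng(9)
        x = rng.normal(2, 5, 960)
        plates = np.repeat([f"P{i}" for i in range(10)], 96)
        out = pd.Series(standardize_by_plate(x, plates).to_numpy())
        for _, grp in out.groupby(pd.Series(plates)):
            assert abs(grp.mean()) < 1e-9
            assert abs(grp.std(ddof=1) - 1.0) < 1e-9


def test_weighted_pipeline_rectifies_adversarial_probes(small_cohort):
    """Weights flip anti-correlated probes, so the weighted estimate
    correlates with truth at least as well as the raw median here."""
    fit = fit_probe_weights(small_cohort.intensity, small_cohort.coverage)
    table = abundance_table(
        small_cohort.intensity, fit,
        small_cohort.phenotypes[["sample_id", "plate_id"]],
    ).set_index("sample_id")
    lcn = small_cohort.truth.set_index("sample_id").true_log_copy_number
    rho = table.ml2rmt_raw.corr(lcn, method="spearman")
    assert rho > 0.5
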