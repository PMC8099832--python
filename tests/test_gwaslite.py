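"""Variant scan: HWE exact test, filters, inflation factor, clumping."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from mitoabund.gwaslite import (
    CHI2_1_MEDIAN,
    VariantFilters,
    clump_signals,
    filter_variants,
    genomic_inflation,
    gwas_scan,
    hwe_test,
    variant_metrics,
)


def hwe_exact_oracle(n_aa, n_ab, n_bb):
    """Independent exact HWE p by direct rational enumeration."""
    n = n_aa + n_ab + n_bb
    na, nb = 2 * n_aa + n_ab, 2 * n_bb + n_ab
    if na == 0 or nb == 0:
        return 1.0
    rare = min(na, nb)

    def prob(het):
        hr = (rare - het) // 2
        hc = n - het - hr
        return Fraction(
            math.factorial(n) * 2**het * math.factorial(na) * math.factorial(nb),
            math.factorial(hr) * math.factorial(het) * math.factorial(hc) * math.factorial(2 * n),
        )

    table = {het: prob(het) for het in range(rare % 2, rare + 1, 2)}
    obs = table[n_ab]
    return float(sum(p for p in table.values() if p <= obs))


class TestHwe:
    def test_perfect_hwe_proportions(self):
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_no_heterozygotes_extreme(self):
        assert hwe_test(50, 0, 50) < 1e-5

    def test_monomorphic_returns_one(self):
        assert hwe_test(100, 0, 0) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(-1, 5, 5)
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)

    def test_matches_exact_enumeration_small_tables(self):
        """All genotype tables with total <= 25 agree with the rational oracle."""
        for n in range(1, 26):
            for n_aa in range(n + 1):
                for n_ab in range(n - n_aa + 1):
                    n_bb = n - n_aa - n_ab
                    got = hwe_test(n_aa, n_ab, n_bb)
                    want = hwe_exact_oracle(n_aa, n_ab, n_bb)
                    assert got == pytest.approx(want, rel=1e-8), (n_aa, n_ab, n_bb)

    def test_allele_label_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c = rng.integers(0, 40, 3)
            if a + b + c == 0:
                continue
            assert hwe_test(a, b, c) == pytest.approx(hwe_test(c, b, a), rel=1e-12)


class TestFilters:
    def _row(self, **kw):
        base = {"variant_id": "v", "maf": 0.1, "missingness": 0.0,
                "imputation_r2": 0.9, "hwe_p": 0.5}
        base.update(kw)
        return pd.DataFrame([base])

    def test_low_maf_excluded(self):
        kept, report = filter_variants(self._row(maf=0.04))
        assert kept.empty and report["maf"] == 1

    def test_high_missingness_excluded(self):
        kept, report = filter_variants(self._row(missingness=0.03))
        assert kept.empty and report["missingness"] == 1

    def test_clean_variant_retained(self):
        kept, report = filter_variants(self._row())
        assert len(kept) == 1 and report["retained"] == 1

    def test_hwe_and_imputation(self):
        assert filter_variants(self._row(hwe_p=1e-6))[0].empty
        assert filter_variants(self._row(imputation_r2=0.5))[0].empty
        assert len(filter_variants(self._row(hwe_p=1e-5))[0]) == 1  # boundary retained

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(50)],
                "maf": rng.uniform(0, 0.5, 50),
                "missingness": rng.uniform(0, 0.05, 50),
                "imputation_r2": rng.uniform(0.3, 1.0, 50),
                "hwe_p": rng.uniform(0, 1, 50),
            }
        )
        once, _ = filter_variants(df)
        twice, _ = filter_variants(once)
        pd.testing.assert_frame_equal(once, twice)
        shuffled, _ = filter_variants(df.sample(frac=1.0, random_state=2))
        assert set(shuffled.variant_id) == set(once.variant_id)


class TestInflation:
    def test_definitional_unity(self):
        assert genomic_inflation([CHI2_1_MEDIAN] * 5) == pytest.approx(1.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        chi2 = rng.chisquare(1, 1000)
        assert genomic_inflation(1.2 * chi2) == pytest.approx(
            1.2 * genomic_inflation(chi2), rel=1e-12
        )

    def test_null_scan_lambda_near_one(self, truth_only_config):
        from mitoabund.synthio import simulate_cohort

        c = simulate_cohort(truth_only_config(11, 2000, n_variants=5000))
        outcome = c.truth.set_index("sample_id").true_log_copy_number
        summary = gwas_scan(c.dosages, outcome)
        assert 0.95 <= summary.lambda_gc <= 1.05


class TestScan:
    def test_causal_variant_ranked_first(self, truth_only_config):
        from mitoabund.synthio import simulate_cohort

        hits = 0
        for seed in range(10):
            c = simulate_cohort(
                truth_only_config(seed, 4000, n_variants=50,
                                  causal_variant_effects=((10, 0.15),))
            )
            outcome = c.truth.set_index("sample_id").true_log_copy_number
            summary = gwas_scan(c.dosages, outcome)
            hits += summary.table.sort_values("p").variant_id.iloc[0] == "rs000010"
        assert hits >= 9

    def test_matches_statsmodels_single_variant(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 500
        g = rng.binomial(2, 0.3, n).astype(float)
        z = rng.normal(0, 1, n)
        y = 0.2 * g + 0.5 * z + rng.normal(0, 1, n)
        idx = pd.Index([f"S{i}" for i in range(n)], name="sample_id")
        summary = gwas_scan(
            pd.DataFrame({"v1": g}, index=idx),
            pd.Series(y, index=idx),
            covariates=pd.DataFrame({"z": z}, index=idx),
        )
        X = sm.add_constant(np.column_stack([g, z]))
        ref = sm.OLS(y, X).fit()
        row = summary.table.iloc[0]
        assert row.slope == pytest.approx(ref.params[1], rel=1e-9)
        assert row.se == pytest.approx(ref.bse[1], rel=1e-9)
        assert row.p == pytest.approx(ref.pvalues[1], rel=1e-6)

    def test_constant_dosage_skipped(self):
        idx = pd.Index(["S0", "S1", "S2", "S3"], name="sample_id")
        summary = gwas_scan(
            pd.DataFrame({"v1": [1.0, 1.0, 1.0, 1.0], "v2": [0, 1, 2, 1.0]}, index=idx),
            pd.Series([0.1, 0.2, 0.3, 0.4], index=idx),
        )
        assert np.isnan(summary.table.set_index("variant_id").loc["v1", "p"])

    def test_variant_metrics_from_dosages(self):
        idx = pd.Index([f"S{i}" for i in range(4)], name="sample_id")
        dos = pd.DataFrame({"v1": [0.0, 1.0, 2.0, np.nan]}, index=idx)
        m = variant_metrics(dos).iloc[0]
        assert m.missingness == pytest.approx(0.25)
        assert m.maf == pytest.approx(0.5)


def _clump_oracle(summary, dosages, p_threshold, r2_threshold, window):
    """Naive loop re-statement of the greedy clumping rule."""
    sig = summary[summary.p < p_threshold].sort_values(["p", "variant_id"]).copy()
    loci = []
    while len(sig):
        lead = sig.iloc[0]
        members = sig[(sig.chrom == lead.chrom) & (abs(sig.pos - lead.pos) <= window)]
        indep = [lead.variant_id]
        for vid in members.variant_id:
            if vid == lead.variant_id:
                continue
            a, b = dosages[lead.variant_id], dosages[vid]
            r2 = np.corrcoef(a, b)[0, 1] ** 2
            if r2 < r2_threshold:
                indep.append(vid)
        loci.append((lead.variant_id, sorted(indep)))
        sig = sig[~sig.variant_id.isin(members.variant_id)]
    return loci


class TestClump:
    def _summary(self, pvals, pos=None, chrom="1"):
        k = len(pvals)
        return pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(k)],
                "chrom": chrom,
                "pos": pos if pos is not None else np.arange(k) * 1000 + 1,
                "p": pvals,
            }
        )

    def _dosages(self, mat):
        return pd.DataFrame(
            np.asarray(mat, dtype=float),
            index=pd.Index([f"S{i}" for i in range(len(mat))], name="sample_id"),
            columns=[f"v{i}" for i in range(np.asarray(mat).shape[1])],
        )

    def test_single_significant_variant(self):
        rng = np.random.default_rng(4)
        loci = clump_signals(
            self._summary([1e-9, 0.5]), self._dosages(rng.binomial(2, 0.3, (50, 2)))
        )
        assert len(loci) == 1
        assert loci[0]["independent_signals"] == ["v0"]

    def test_correlated_pair_one_signal(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.5, 200).astype(float)
        g2 = g.copy()
        flip = rng.random(200) < 0.02  # r2 ~ 0.9+
        g2[flip] = rng.binomial(2, 0.5, flip.sum())
        loci = clump_signals(self._summary([1e-10, 1e-9]), self._dosages(np.column_stack([g, g2])))
        assert len(loci) == 1
        assert loci[0]["independent_signals"] == ["v0"]

    def test_uncorrelated_pair_two_signals(self):
        rng = np.random.default_rng(6)
        g = rng.binomial(2, 0.5, (500, 2)).astype(float)
        loci = clump_signals(self._summary([1e-10, 1e-9]), self._dosages(g))
        assert len(loci) == 1
        assert sorted(loci[0]["independent_signals"]) == ["v0", "v1"]

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(7)
        for rep in range(20):
            k = rng.integers(2, 11)
            n = 120
            base = rng.binomial(2, 0.4, (n, k)).astype(float)
            # induce correlation blocks
            for j in range(1, k):
                if rng.random() < 0.5:
                    base[:, j] = np.where(rng.random(n) < 0.9, base[:, j - 1], base[:, j])
            pvals = 10.0 ** rng.uniform(-12, -4, k)
            pos = np.sort(rng.integers(1, 3_000_000, k))
            summary = self._summary(pvals, pos=pos)
            dosages = self._dosages(base)
            got = clump_signals(summary, dosages, p_threshold=5e-8, r2_threshold=0.1,
                                window_bp=1_000_000)
            want = _clump_oracle(summary, dosages, 5e-8, 0.1, 1_000_000)
            assert [(l["lead_variant"], sorted(l["independent_signals"])) for l in got] == want
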