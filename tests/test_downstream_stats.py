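import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from axialmrg import downstream_stats as ds


def _plate(gene_ct: dict, hk_ct: dict):
    """Build a plate from {sample: ct} dicts for one target gene and shared
    housekeeping Ct per sample (all three housekeeping genes identical)."""
    rows = []
    for sample, ct in gene_ct.items():
        for rep in (1, 2):
            rows.append({"gene": "tgt", "sample": sample, "replicate": rep,
                         "ct": ct})
    for sample, ct in hk_ct.items():
        for hk in ("hk_1", "hk_2", "hk_3"):
            for rep in (1, 2):
                rows.append({"gene": hk, "sample": sample, "replicate": rep,
                             "ct": ct})
    cond = {
        s: ("control" if s.startswith("ctrl") else "treatment")
        for s in gene_ct
    }
    return ds.QPCRPlate(
        table=pd.DataFrame(rows), housekeeping=("hk_1", "hk_2", "hk_3"),
        sample_condition=cond,
    )


class TestDdct:
    def test_treatment_equal_to_control_mean_gives_zero(self):
        plate = _plate(
            {"ctrl1": 21.0, "trt1": 21.0}, {"ctrl1": 22.0, "trt1": 22.0}
        )
        out = ds.ddct(plate).set_index("sample")
        assert out.loc["trt1", "log2fc"] == pytest.approx(0.0)

    def test_sign_convention_hand_arithmetic(self):
        # treatment: Ct 20, hk 22 -> dCt = -2; control dCt = -1
        # ddCt = -1 -> log2fc = +1 (one fewer cycle = twice the product)
        plate = _plate(
            {"ctrl1": 21.0, "trt1": 20.0}, {"ctrl1": 22.0, "trt1": 22.0}
        )
        out = ds.ddct(plate).set_index("sample")
        assert out.loc["trt1", "dct"] == pytest.approx(-2.0)
        assert out.loc["trt1", "ddct"] == pytest.approx(-1.0)
        assert out.loc["trt1", "log2fc"] == pytest.approx(1.0)

    def test_sample_offset_cancels(self):
        # adding a constant to every Ct of a sample leaves dCt unchanged
        p1 = _plate({"ctrl1": 21.0, "trt1": 20.0},
                    {"ctrl1": 22.0, "trt1": 22.0})
        p2 = _plate({"ctrl1": 21.0, "trt1": 23.5},
                    {"ctrl1": 22.0, "trt1": 25.5})
        o1 = ds.ddct(p1).set_index("sample")
        o2 = ds.ddct(p2).set_index("sample")
        assert o1.loc["trt1", "log2fc"] == pytest.approx(
            o2.loc["trt1", "log2fc"]
        )

    def test_missing_housekeeping_errors(self):
        plate = _plate({"ctrl1": 21.0}, {"ctrl1": 22.0})
        plate.table = plate.table[plate.table["gene"] != "hk_2"]
        with pytest.raises(ValueError, match="housekeeping"):
            ds.ddct(plate)


class TestNormalizeMeasurements:
    def _dt(self):
        return ds.DomainTable(table=pd.DataFrame({
            "animal": ["a1", "a2"],
            "condition": ["control", "rnai"],
            "total_length_um": [1000.0, 2000.0],
            "domain_length_um": [200.0, 400.0],
        }))

    def test_domain_over_total(self):
        table, summary = ds.normalize_measurements(
            self._dt(), "domain_over_total"
        )
        assert np.allclose(table["normalized"], [0.2, 0.2])
        assert summary.loc["control", "mean"] == pytest.approx(0.2)

    def test_count_over_reference(self):
        dt = ds.DomainTable(table=pd.DataFrame({
            "animal": ["a1"], "condition": ["control"],
            "cell_count": [30], "reference_length_um": [600.0],
        }))
        table, _ = ds.normalize_measurements(dt, "count_over_reference")
        assert table["normalized"].iloc[0] == pytest.approx(0.05)

    def test_scale_invariance(self):
        dt = self._dt()
        dt.table[["total_length_um", "domain_length_um"]] *= 2
        table, _ = ds.normalize_measurements(dt, "domain_over_total")
        assert np.allclose(table["normalized"], [0.2, 0.2])

    def test_zero_length_rejected(self):
        dt = self._dt()
        dt.table.loc[0, "total_length_um"] = 0.0
        with pytest.raises(ValueError, match="a1"):
            ds.normalize_measurements(dt, "domain_over_total")


def _fisher_oracle(table):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = stats.hypergeom.pmf(x, n, r1, c1)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


class TestFisherExact:
    def test_balanced_table_p_one(self):
        assert ds.fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_diagonal_table_one_third(self):
        assert ds.fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(
            1 / 3, abs=1e-9
        )

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(150):
            t = rng.integers(0, 16, size=(2, 2))  # margins <= 30
            assert ds.fisher_exact_2x2(t) == pytest.approx(
                _fisher_oracle(t), rel=1e-7, abs=1e-12
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ds.fisher_exact_2x2([[1, -2], [3, 4]])


class TestOneWayAnova:
    def test_identical_groups(self):
        f, p = ds.one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_groups_f_is_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=8), rng.normal(0.5, 1, size=6)
        f, p = ds.one_way_anova([a, b])
        t = stats.ttest_ind(a, b).statistic
        assert f == pytest.approx(t**2, rel=1e-10)

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            groups = [rng.normal(size=6) for _ in range(3)]
            _, p = ds.one_way_anova(groups)
            rejections += p < 0.05
        sd = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) <= 3 * sd

    def test_zero_variance_unequal_means(self):
        f, p = ds.one_way_anova([[1.0, 1.0], [2.0, 2.0]])
        assert p == 0.0 and np.isinf(f)


class TestDunnett:
    def test_two_group_degeneracy_matches_t_test(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=10), rng.normal(0.8, 1, size=10)
        out = ds.dunnett_many_to_one([a, b], control_index=0,
                                     n_mc=200_000, seed=0)
        t_p = stats.ttest_ind(b, a).pvalue
        assert out["p_adjusted"].iloc[0] == pytest.approx(t_p, abs=0.01)

    def test_identical_groups_p_near_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        out = ds.dunnett_many_to_one([g, list(g), list(g)], seed=0,
                                     n_mc=20_000)
        assert (out["p_adjusted"] > 0.99).all()

    def test_adjusted_at_least_unadjusted(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1, 8) for m in (0.0, 0.4, 0.9, 1.5)]
        out = ds.dunnett_many_to_one(groups, seed=1, n_mc=50_000)
        assert (out["p_adjusted"] >= out["p_unadjusted"] - 1e-12).all()

    def test_matches_scipy_dunnett(self):
        rng = np.random.default_rng(5)
        control = rng.normal(size=9)
        t1 = rng.normal(0.8, 1, size=9)
        t2 = rng.normal(-0.3, 1, size=9)
        ours = ds.dunnett_many_to_one([control, t1, t2], control_index=0,
                                      n_mc=200_000, seed=2)
        ref = stats.dunnett(t1, t2, control=control)
        np.testing.assert_allclose(
            ours["p_adjusted"], ref.pvalue, atol=0.015
        )


class TestPower:
    def test_two_proportion_closed_form(self):
        spec = ds.PowerSpec("two_proportions", 0.2)
        # 2 * (1.95996 + 0.84162)^2 / 0.04 = 392.4
        assert ds.power_two_proportions(spec) == pytest.approx(392.4)

    def test_anova_large_effect_hits_lower_bound(self):
        spec = ds.PowerSpec("one_way_anova", 10.0, k=3)
        assert ds.power_anova(spec) == pytest.approx(2.0)

    def test_monotone_in_effect_size_and_power(self):
        n1 = ds.power_two_proportions(ds.PowerSpec("two_proportions", 0.3))
        n2 = ds.power_two_proportions(ds.PowerSpec("two_proportions", 0.6))
        assert n2 < n1
        lo = ds.power_anova(ds.PowerSpec("one_way_anova", 0.5, power=0.6, k=3))
        hi = ds.power_anova(ds.PowerSpec("one_way_anova", 0.5, power=0.95, k=3))
        assert hi > lo

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ds.PowerSpec("two_proportions", 0.0)
        with pytest.raises(ValueError):
            ds.PowerSpec("one_way_anova", 0.5, alpha=1.5)
        with pytest.raises(ValueError):
            ds.PowerSpec("one_way_anova", 0.5, k=1)
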