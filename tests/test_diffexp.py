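import numpy as np
import pandas as pd
import pytest
from scipy import stats

from axialmrg import diffexp
from axialmrg.counts_io import CountMatrix
from axialmrg.qc_normalize import to_log_cpm
from axialmrg.synthetic_data import SimConfig, simulate_axis_counts
from conftest import make_expression


class TestContrast:
    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            diffexp.Contrast.of("bad", {1, 2}, {2, 3})

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            diffexp.Contrast.of("bad", set(), {1})

    def test_default_contrasts_match_axial_design(self):
        byname = {c.name: c for c in diffexp.DEFAULT_CONTRASTS}
        assert byname["anterior_vs_posterior"].group_a == {1, 2, 3}
        assert byname["anterior_vs_posterior"].group_b == {8, 9, 10}
        assert byname["head_vs_postpharyngeal"].group_a == {1}
        assert byname["prepharyngeal_vs_tail"].group_b == {10}


def _manual_model(cells, totals, theta0=50.0, theta1=0.0, phi=0.2):
    """ErrorModel with hand-set parameters (theta0=50 => no dropout)."""
    params = pd.DataFrame({
        "theta0": theta0, "theta1": theta1, "total_counts": totals,
    }, index=pd.Index(cells, name="cell_id"))
    return diffexp.ErrorModel(params=params, lambda0=0.1, phi=phi)


def _count_matrix(counts_a, counts_b):
    """Genes x (group A cells + group B cells) CountMatrix, regions 1 and 2."""
    a = np.asarray(counts_a)
    b = np.asarray(counts_b)
    cells = [f"a{i}" for i in range(a.shape[1])] + [
        f"b{i}" for i in range(b.shape[1])
    ]
    counts = pd.DataFrame(
        np.hstack([a, b]),
        index=[f"g{i}" for i in range(a.shape[0])],
        columns=cells,
    )
    meta = pd.DataFrame(
        {"region": [1] * a.shape[1] + [2] * b.shape[1]}, index=cells
    )
    return CountMatrix(counts, meta)


CON = diffexp.Contrast.of("ab", {1}, {2})


class TestFitErrorModels:
    def test_no_dropout_cell_gets_small_p_drop(self):
        # every gene detected in every cell, across a wide expression range
        # => the fitted dropout curve is negligible everywhere
        rng = np.random.default_rng(0)
        means = np.geomspace(0.5, 2000, 300)
        counts = rng.poisson(means[:, None], size=(300, 8)) + 1
        cm = _count_matrix(counts[:, :4], counts[:, 4:])
        em = to_log_cpm(cm)
        models = diffexp.fit_error_models(cm, em, list(cm.cell_ids))
        e = np.array([1.0, 10.0, 100.0])
        for cell in cm.cell_ids:
            assert (models.p_drop(cell, e) <= 0.05).all()

    def test_parameter_recovery(self):
        # strong-dropout regime: p_drop(e) = sigmoid(2 - 1.5 log(e+1)),
        # i.e. theta0 = -2, theta1 = 1.5 in the fitted parameterization
        cfg = SimConfig(
            seed=4, n_genes=1500, cells_per_region=6,
            cell_class_proportions={
                "muscle": 1.0, "neoblast": 0.0, "epidermal": 0.0, "other": 0.0
            },
            mrg_profiles=(), dropout_midpoint=2.0, dropout_slope=1.5,
            nb_dispersion=0.3,
        )
        cm, _ = simulate_axis_counts(cfg)
        em = to_log_cpm(cm)
        models = diffexp.fit_error_models(cm, em, list(cm.cell_ids))
        med = models.params[["theta0", "theta1"]].median()
        assert abs(med["theta0"] - (-2.0)) / 2.0 < 0.25
        assert abs(med["theta1"] - 1.5) / 1.5 < 0.25

    def test_too_few_cells_rejected(self, tiny_cm):
        em = to_log_cpm(tiny_cm)
        with pytest.raises(ValueError, match="5 cells"):
            diffexp.fit_error_models(tiny_cm, em, list(tiny_cm.cell_ids))


class TestDeDropout:
    def test_identical_groups_null(self):
        col = np.array([[5], [40], [0], [200]])
        cm = _count_matrix(
            np.tile(col, (1, 4)), np.tile(col, (1, 4))
        )
        models = _manual_model(list(cm.cell_ids), 1e6)
        res = diffexp.de_dropout(cm, models, CON)
        assert np.allclose(res.table["log2fc"], 0.0)
        assert np.allclose(res.table["z"], 0.0, atol=1e-9)

    def test_tenfold_ratio_recovered(self):
        rng = np.random.default_rng(1)
        base = rng.integers(20, 200, size=(30, 1))
        a = np.tile(base, (1, 5))
        b = 10 * a
        cm = _count_matrix(a, b)
        models = _manual_model(list(cm.cell_ids), 1e6, phi=0.05)
        res = diffexp.de_dropout(cm, models, CON)
        # fold change is A minus B: magnitude log2(10)
        assert np.allclose(
            np.abs(res.table["log2fc"]), np.log2(10), atol=0.2
        )
        assert (res.table["log2fc"] < 0).all()
        assert (res.table["z"] < 0).all()

    def test_undetected_gene_flagged(self):
        a = np.array([[0, 0, 0], [10, 12, 9]])
        b = np.array([[0, 0, 0], [11, 10, 13]])
        cm = _count_matrix(a, b)
        models = _manual_model(list(cm.cell_ids), 1e6)
        res = diffexp.de_dropout(cm, models, CON)
        assert bool(res.table.loc["g0", "undetected"])
        assert res.table.loc["g0", "p"] == 1.0
        assert res.table.loc["g0", "z"] == 0.0


class TestDeBimod:
    def test_identical_groups(self):
        vals = np.tile([[3.0, 4.0, 5.0]], (2, 1))
        em = make_expression(
            np.hstack([vals, vals]), regions=[1, 1, 1, 2, 2, 2]
        )
        res = diffexp.de_bimod(em, CON)
        assert np.allclose(res.table["lrt"], 0.0, atol=1e-9)
        assert np.allclose(res.table["p"], 1.0)

    def test_detection_only_difference_closed_form(self):
        # 0/10 detected vs 10/10, equal positive means: binomial part only.
        # alt ll = 0; null ll = 20 ln(1/2) => LRT = 2 * 20 * ln 2 = 27.726
        a = np.zeros((1, 10))
        b = np.full((1, 10), 6.0)
        em = make_expression(np.hstack([a, b]), regions=[1] * 10 + [2] * 10)
        res = diffexp.de_bimod(em, CON)
        assert res.table.loc["g0", "lrt"] == pytest.approx(
            2 * 20 * np.log(2), abs=1e-9
        )
        assert res.table.loc["g0", "p"] < 0.001

    def test_single_cell_groups_no_crash(self):
        em = make_expression([[3.0, 4.0]], regions=[1, 2])
        res = diffexp.de_bimod(em, CON)
        assert np.isfinite(res.table["p"]).all()


class TestDeTtest:
    def test_identical_groups(self):
        em = make_expression(
            [[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], regions=[1, 1, 1, 2, 2, 2]
        )
        res = diffexp.de_ttest(em, CON)
        assert res.table.loc["g0", "t"] == pytest.approx(0.0)
        assert res.table.loc["g0", "p"] == pytest.approx(1.0)

    def test_closed_form_example(self):
        # {1,2,3} vs {2,3,4}: pooled t = -1.2247, df = 4, p ~ 0.2879
        em = make_expression(
            [[1.0, 2.0, 3.0, 2.0, 3.0, 4.0]], regions=[1, 1, 1, 2, 2, 2]
        )
        res = diffexp.de_ttest(em, CON)
        assert res.table.loc["g0", "t"] == pytest.approx(-1.224745, abs=1e-5)
        expect_p = 2 * stats.t.sf(1.224745, df=4)
        assert res.table.loc["g0", "p"] == pytest.approx(expect_p, abs=1e-5)
        assert res.table.loc["g0", "p"] == pytest.approx(0.288, abs=2e-3)

    def test_single_cell_group_rejected(self):
        em = make_expression([[1.0, 2.0, 3.0]], regions=[1, 2, 2])
        with pytest.raises(ValueError, match="two cells"):
            diffexp.de_ttest(em, CON)

    def test_null_p_values_uniform(self):
        # equal-variance t on iid normal data: p ~ Uniform(0, 1)
        rng = np.random.default_rng(0)
        em = make_expression(
            rng.normal(5.0, 1.0, size=(1000, 20)),
            regions=[1] * 10 + [2] * 10,
        )
        res = diffexp.de_ttest(em, CON)
        ks = stats.kstest(res.table["p"], "uniform")
        assert ks.pvalue > 0.01


def _fake_results(z_by_contrast):
    out = {}
    for name, zs in z_by_contrast.items():
        z = np.asarray(zs, dtype=float)
        p = 2 * stats.norm.sf(np.abs(z))
        table = pd.DataFrame(
            {"log2fc": z, "z": z, "p": p},
            index=[f"g{i}" for i in range(len(z))],
        )
        diffexp._attach_corrected(table)
        out[name] = diffexp.DEResult(table=table, method="dropout",
                                     contrast=name)
    return out


class TestCallSignificant:
    def test_any_contrast_rule_and_strictness(self):
        res = _fake_results({
            "c1": [2.59, 2.58, -3.0, 1.0],
            "c2": [0.0, 0.0, 0.0, 0.0],
            "c3": [0.0, 0.0, 0.0, 0.0],
        })
        out = diffexp.call_significant(res)
        assert bool(out.loc["g0", "flagged"])  # 2.59 > 2.58 in one contrast
        assert not bool(out.loc["g1", "flagged"])  # exactly 2.58: strict
        assert bool(out.loc["g2", "flagged"])  # absolute value
        assert not bool(out.loc["g3", "flagged"])


class TestBenchmarkRankings:
    def test_best_p_is_rank_one_and_ties_deterministic(self):
        res = {"m": _fake_results({"c": [5.0, 3.0, 3.0, 0.5]})}
        table = diffexp.benchmark_rankings(res, ["g0", "g1", "g2", "missing"])
        by_gene = table.set_index("gene")
        assert by_gene.loc["g0", "rank"] == 1
        # g1 and g2 tie on p and |z|; gene ID breaks the tie
        assert by_gene.loc["g1", "rank"] == 2
        assert by_gene.loc["g2", "rank"] == 3
        assert by_gene.loc["missing", "rank"] is None or np.isnan(
            by_gene.loc["missing", "rank"]
        )
        assert bool(by_gene.loc["g0", "significant"])
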