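"""GDP prior density, EM-MAP fit, BIC selection, prediction, model report."""

import math

import numpy as np
import pytest
from scipy import integrate

from gdprisk.datatypes import DosageDataset
from gdprisk.errors import DesignError, UsageError
from gdprisk.gdp import (
    GdpHyper,
    bic_select,
    build_joint_design,
    em_map_fit,
    fit_polygenic,
    gdp_log_density,
    model_report,
    predict_risk,
)
from gdprisk.scan import fit_logistic


class TestGdpDensity:
    def test_symmetric(self):
        h = GdpHyper(1.3, 0.7)
        for b in (0.0, 0.2, 1.5, 7.0):
            assert gdp_log_density(b, h) == pytest.approx(gdp_log_density(-b, h))

    @pytest.mark.parametrize("alpha,eta", [(1.0, 1.0), (0.5, 2.0), (3.0, 0.3)])
    def test_integrates_to_one(self, alpha, eta):
        h = GdpHyper(alpha, eta)
        val, _ = integrate.quad(lambda b: math.exp(gdp_log_density(b, h)), -np.inf, np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_mode_at_zero(self):
        h = GdpHyper(2.0, 1.5)
        f0 = gdp_log_density(0.0, h)
        assert all(gdp_log_density(b, h) <= f0 for b in np.linspace(-5, 5, 101))

    def test_invalid_hyper_rejected(self):
        with pytest.raises(UsageError):
            GdpHyper(0.0, 1.0)


def logistic_data(n, p, beta, seed, binary_frac=0.0):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
    prob = 1 / (1 + np.exp(-(X @ beta)))
    y = (rng.random(n) < prob).astype(float)
    return y, X


class TestEmMapFit:
    def test_vanishing_penalty_approaches_ml_fit(self):
        beta = np.array([0.3, 0.8, -0.5])
        y, X = logistic_data(300, 2, beta, seed=1)
        pen = np.array([False, True, True])
        m = em_map_fit(y, X, pen, GdpHyper(1.0, 1e6), standardize=False)
        ml, _, _, ok = fit_logistic(y, X)
        assert ok
        np.testing.assert_allclose(
            np.concatenate([[m.intercept], m.coef]), ml, atol=1e-3
        )

    def test_strong_penalty_zeroes_everything(self):
        beta = np.array([0.3, 0.8, -0.5])
        y, X = logistic_data(300, 2, beta, seed=2)
        pen = np.array([False, True, True])
        m = em_map_fit(y, X, pen, GdpHyper(1.0, 1e-6), standardize=False)
        assert np.all(m.coef == 0.0)
        assert m.df == 1

    def test_single_mstep_orthonormal_soft_threshold(self):
        # one EM iteration from zero on an orthonormal design equals the
        # soft-thresholded majorized least-squares solution, computed here
        # independently:  b_j = S(4 x_j'(y - 1/2), 4 w) with w = (a+1)/eta
        rng = np.random.default_rng(3)
        n, p = 64, 4
        raw = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
        Q, _ = np.linalg.qr(raw)  # col 0 proportional to the intercept
        X = np.column_stack([np.ones(n), Q[:, 1:]])  # unit-norm SNP cols, all orthogonal
        y = (rng.random(n) < 0.5).astype(float)
        hyper = GdpHyper(1.0, 0.5)
        pen = np.array([False] + [True] * p)
        m = em_map_fit(y, X, pen, hyper, max_iter=1, standardize=False,
                       curvature="bound", inner_max=1)
        # orthonormal columns make the coordinate updates independent:
        # b_j = S(x_j'(y - 1/2), w_j) / (1/4), the soft-thresholded
        # majorized least-squares solution for working response 4(y - 1/2)
        w = (hyper.alpha + 1) / hyper.eta  # E-step weight at beta = 0
        expected = []
        for j in range(p + 1):
            z = X[:, j] @ (y - 0.5)
            wj = 0.0 if j == 0 else w
            L = (X[:, j] ** 2).sum() / 4.0
            expected.append(math.copysign(max(abs(z) - wj, 0.0), z) / L)
        got = np.concatenate([[m.intercept], m.coef])
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_two_predictor_matches_brute_force_map(self):
        # grid-refined direct maximization of loglik + GDP log prior
        rng = np.random.default_rng(4)
        n = 150
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        prob = 1 / (1 + np.exp(-(0.2 + 0.9 * X[:, 1] - 0.1 * X[:, 2])))
        y = (rng.random(n) < prob).astype(float)
        hyper = GdpHyper(1.0, 0.3)
        pen = np.array([False, True, True])
        m = em_map_fit(y, X, pen, hyper, standardize=False)

        def objective(b0, b1, b2):
            lin = b0 + b1 * X[:, 1] + b2 * X[:, 2]
            ll = float(y @ lin - np.logaddexp(0, lin).sum())
            return ll + gdp_log_density(b1, hyper) + gdp_log_density(b2, hyper)

        center = np.array([m.intercept, m.coef[0], m.coef[1]])
        width = 1.0
        best = None
        for _ in range(8):  # coarse-to-fine refinement
            grid = [np.linspace(c - width, c + width, 11) for c in center]
            vals = [
                (objective(a, b, c), (a, b, c))
                for a in grid[0] for b in grid[1] for c in grid[2]
            ]
            best = max(vals)[1]
            center = np.array(best)
            width /= 4
        np.testing.assert_allclose(
            [m.intercept, m.coef[0], m.coef[1]], best, atol=1e-3
        )

    def test_bound_and_irls_curvature_agree(self):
        beta = np.array([-0.2, 0.7, 0.0, -0.6])
        y, X = logistic_data(250, 3, beta, seed=5)
        pen = np.array([False, True, True, True])
        m1 = em_map_fit(y, X, pen, GdpHyper(1.0, 0.5))
        m2 = em_map_fit(y, X, pen, GdpHyper(1.0, 0.5), curvature="bound", max_iter=20000)
        np.testing.assert_allclose(m1.coef, m2.coef, atol=2e-3)

    def test_constant_outcome_rejected(self):
        y = np.ones(50)
        X = np.column_stack([np.ones(50), np.random.default_rng(0).standard_normal(50)])
        with pytest.raises(DesignError):
            em_map_fit(y, X, np.array([False, True]), GdpHyper(1.0, 1.0))

    def test_bic_identity(self):
        beta = np.array([0.1, 0.6, -0.4])
        y, X = logistic_data(200, 2, beta, seed=6)
        pen = np.array([False, True, True])
        m = em_map_fit(y, X, pen, GdpHyper(1.0, 0.5))
        assert m.bic == pytest.approx(-2 * m.loglik + m.df * math.log(200), abs=1e-9)
        assert m.df == 1 + int(np.count_nonzero(m.coef))


class TestBicSelect:
    def test_singleton_grid_returns_that_fit(self):
        beta = np.array([0.1, 0.6, -0.4])
        y, X = logistic_data(200, 2, beta, seed=7)
        pen = np.array([False, True, True])
        best, path = bic_select(y, X, pen, grid=[GdpHyper(2.0, 0.7)])
        assert best.hyper == GdpHyper(2.0, 0.7)
        assert len(path) == 1

    def test_sparsity_path_monotone_in_eta(self):
        # stronger rate penalty (smaller eta) never increases df, plateaus allowed
        rng = np.random.default_rng(8)
        n, p = 200, 8
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
        beta = np.concatenate([[0.1], rng.normal(0, 0.6, p)])
        yprob = 1 / (1 + np.exp(-(X @ beta)))
        y = (rng.random(n) < yprob).astype(float)
        pen = np.array([False] + [True] * p)
        grid = [GdpHyper(0.5, e) for e in (0.01, 0.03, 0.1, 0.3, 1.0, 3.0)]
        _, path = bic_select(y, X, pen, grid=grid)
        dfs = [r["df"] for r in sorted(path, key=lambda r: r["eta"])]
        assert all(a <= b for a, b in zip(dfs, dfs[1:]))

    def test_null_sparsity_at_bic_consistent_scale(self):
        # with m
        # candidates small enough that 2 ln m < ln n, the empty model
        # is the BIC optimum for most null datasets
        n, p = 400, 10
        all_zero = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
            y = (rng.random(n) < 0.5).astype(float)
            pen = np.array([False] + [True] * p)
            best, _ = bic_select(y, X, pen)
            all_zero += int(np.all(best.coef == 0.0))
        assert all_zero >= 14  # ~0.8 expected from the order statistics of z^2

    def test_empty_grid_rejected(self):
        with pytest.raises(UsageError):
            bic_select(np.array([0.0, 1.0]), np.ones((2, 1)), np.array([False]), grid=[])


class TestPredictAndReport:
    def test_null_model_predicts_half(self, tiny_dataset):
        X, pen, names = build_joint_design(tiny_dataset, np.array([], dtype=int))
        y = tiny_dataset.status_vector()
        m = em_map_fit(y, X, pen, GdpHyper(1.0, 1e-6))
        m.intercept = 0.0
        probs = predict_risk(m, tiny_dataset)
        np.testing.assert_allclose(probs, 0.5)

    def test_intercept_only_logistic_value(self, tiny_dataset):
        X, pen, names = build_joint_design(tiny_dataset, np.array([], dtype=int))
        m = em_map_fit(tiny_dataset.status_vector(), X, pen, GdpHyper(1.0, 1e-6))
        m.intercept = 0.90
        m.coef[:] = 0.0
        probs = predict_risk(m, tiny_dataset)
        np.testing.assert_allclose(probs, 1 / (1 + math.exp(-0.90)))
        assert probs[0] == pytest.approx(0.711, abs=5e-4)

    def test_risk_monotone_in_positive_coefficient_dosage(self, small_cohort):
        _, dataset, truth = small_cohort
        model, _ = fit_polygenic(dataset, np.arange(dataset.n_variants))
        vidx = dataset.variant_index()
        pos_snps = [nm for nm, c in zip(model.names, model.coef) if c > 0 and nm in vidx]
        if not pos_snps:
            pytest.skip("no positive SNP coefficient in this fit")
        name = pos_snps[0]
        j = vidx[name]
        base = predict_risk(model, dataset)
        dos = dataset.dosages.copy()
        dos[:, j] = np.minimum(dos[:, j] + 1.0, 2.0)
        bumped = DosageDataset(samples=dataset.samples, variants=dataset.variants,
                               dosages=dos)
        up = predict_risk(model, bumped)
        moved = dos[:, j] != dataset.dosages[:, j]
        assert np.all(up[moved] > base[moved])

    def test_report_counts_and_maf_consistency(self, small_cohort):
        from gdprisk.qc import minor_allele_frequency

        _, dataset, _ = small_cohort
        model, _ = fit_polygenic(dataset, np.arange(dataset.n_variants))
        rows = model_report(model, dataset)
        vidx = dataset.variant_index()
        n_nonzero_snps = sum(
            1 for nm, c in zip(model.names, model.coef) if c != 0.0 and nm in vidx
        )
        snp_rows = [r for r in rows if r["vid"]]
        assert len(snp_rows) == n_nonzero_snps
        assert rows[0]["term"] == "Intercept"
        cov_rows = [r for r in rows if r["term"] in ("sex", "age", "bmi", "smoking")]
        assert len(cov_rows) == 4  # covariates reported even when zero
        for r in snp_rows:
            j = vidx[r["vid"]]
            assert r["maf"] == pytest.approx(
                minor_allele_frequency(dataset.dosages[:, j])
            )

    def test_gene_annotation_from_intervals(self, small_cohort):
        _, dataset, _ = small_cohort
        model, _ = fit_polygenic(dataset, np.arange(dataset.n_variants))
        rows = model_report(model, dataset,
                            gene_intervals=[("1", 0, 10**9, "GENE1")])
        snp_rows = [r for r in rows if r["vid"]]
        assert all(r["gene"] == "GENE1" for r in snp_rows)
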