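import numpy as np
import pytest
import scipy.stats

from sctemporal.io import CellMetadata, ExpressionMatrix, TimepointDataset, ValidationError
from sctemporal.simulate import nb_glm_counts
from sctemporal.tdeg import (
    call_tdegs,
    find_tdegs,
    fit_gene,
    fit_genes,
    nb_log_pmf,
    prefilter_genes,
)


def balanced_design(n=900, n_timepoints=3):
    time = np.arange(n) % n_timepoints
    strata = (np.arange(n) // n_timepoints) % 2
    return time, strata


class TestNbLogPmf:
    def test_zero_count_closed_form(self):
        mu, omega = 3.0, 2.0
        expected = omega * (np.log(omega) - np.log(omega + mu))
        assert nb_log_pmf(0, mu, omega) == pytest.approx(expected, abs=1e-12)

    def test_geometric_special_case(self):
        # omega=1 reduces to a geometric law: p(y) = (w/(w+mu)) (mu/(w+mu))^y
        assert np.exp(nb_log_pmf(1, 2.0, 1.0)) == pytest.approx(2 / 9, abs=1e-12)
        assert np.exp(nb_log_pmf(0, 2.0, 1.0)) == pytest.approx(1 / 3, abs=1e-12)

    def test_poisson_limit(self):
        y = np.arange(11)
        nb = nb_log_pmf(y, 3.0, 1e8)
        pois = scipy.stats.poisson.logpmf(y, 3.0)
        np.testing.assert_allclose(nb, pois, atol=1e-4)

    @pytest.mark.parametrize("mu", [0.3, 1.0, 5.0, 25.0])
    @pytest.mark.parametrize("omega", [0.5, 2.0, 10.0])
    def test_normalizes_to_one(self, mu, omega):
        # support chosen so the truncated tail mass is < 1e-10
        y = np.arange(0, 3000)
        total = np.exp(nb_log_pmf(y, mu, omega)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            nb_log_pmf(-1, 1.0, 1.0)
        with pytest.raises(ValidationError):
            nb_log_pmf(1.5, 1.0, 1.0)


class TestFitGene:
    def test_parameter_recovery_on_simulated_gene(self):
        """Averaged over 50 replicates, the interaction MLE is near truth."""
        rng = np.random.default_rng(0)
        time, strata = balanced_design()
        b3_hat, omega_hat = [], []
        for _ in range(50):
            y = nb_glm_counts(time, strata, (1.0, 0.5, -0.3, 0.8), 2.0, rng)
            fit = fit_gene(y, time, strata)
            assert fit.converged
            b3_hat.append(fit.coefficients[3])
            omega_hat.append(fit.omega)
        assert abs(np.mean(b3_hat) - 0.8) < 0.15
        assert abs(np.mean(omega_hat) - 2.0) / 2.0 < 0.25

    def test_constant_gene_has_null_slopes(self):
        time, strata = balanced_design(n=120)
        y = np.full(120, 5)
        fit = fit_gene(y, time, strata)
        assert np.all(np.abs(fit.coefficients[1:]) < 1e-6)

    def test_poisson_limit_matches_poisson_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        time, strata = balanced_design(n=600)
        mu = np.exp(1.0 + 0.4 * time - 0.2 * strata + 0.3 * time * strata)
        y = rng.poisson(mu)
        fit = fit_gene(y, time, strata)
        X = np.column_stack([np.ones_like(time), time, strata, time * strata])
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-3)

    def test_matches_statsmodels_joint_nb_mle(self):
        """Independent full-likelihood fit agrees on coefficients and dispersion."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        time, strata = balanced_design()
        y = nb_glm_counts(time, strata, (1.0, 0.5, -0.3, 0.8), 2.0, rng)
        fit = fit_gene(y, time, strata)
        X = np.column_stack([np.ones_like(time), time, strata, time * strata])
        ref = sm.NegativeBinomial(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients, ref.params[:4], atol=1e-3)
        assert fit.omega == pytest.approx(1.0 / ref.params[4], rel=1e-3)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-4)

    def test_interaction_p_invariant_to_stratum_relabeling(self):
        rng = np.random.default_rng(5)
        time, strata = balanced_design(n=300)
        y = nb_glm_counts(time, strata, (0.8, 0.3, 0.2, 0.4), 3.0, rng)
        fit_a = fit_gene(y, time, strata, tol=1e-12)
        fit_b = fit_gene(y, time, 1 - strata, tol=1e-12)
        assert fit_b.coefficients[3] == pytest.approx(-fit_a.coefficients[3], abs=1e-7)
        assert fit_b.p_values[3] == pytest.approx(fit_a.p_values[3], abs=1e-10)

    def test_all_zero_gene_rejected(self):
        time, strata = balanced_design(n=60)
        with pytest.raises(ValidationError):
            fit_gene(np.zeros(60), time, strata)

    def test_batched_all_zero_gene_is_unconverged_with_missing_p(self):
        time, strata = balanced_design(n=60)
        rng = np.random.default_rng(0)
        counts = np.vstack([rng.poisson(2.0, 60), np.zeros(60, dtype=int)])
        fits = fit_genes(counts, time, strata)
        assert fits[0].converged
        assert not fits[1].converged and np.isnan(fits[1].p_interaction)


class TestCallTdegs:
    def test_bonferroni_arithmetic(self):
        time, strata = balanced_design(n=60)
        rng = np.random.default_rng(2)
        counts = rng.poisson(3.0, size=(3, 60))
        fits = fit_genes(counts, time, strata)
        for f, p in zip(fits, (0.001, 0.04, 0.5)):
            f.p_values = np.array([0.5, 0.5, 0.5, p])
        table = call_tdegs(fits, alpha=0.05)
        adj = list(table.frame["p_interaction_bonf"])
        assert adj == pytest.approx([0.003, 0.12, 1.0])
        assert table.frame["is_tdeg"].sum() == 1

    def test_single_gene_keeps_raw_p(self):
        time, strata = balanced_design(n=60)
        counts = np.random.default_rng(3).poisson(3.0, size=(1, 60))
        fits = fit_genes(counts, time, strata)
        table = call_tdegs(fits)
        assert table.frame["p_interaction_bonf"][0] == pytest.approx(
            table.frame["p_interaction_raw"][0]
        )

    def test_no_converged_fits_rejected(self):
        time, strata = balanced_design(n=60)
        fits = fit_genes(np.zeros((2, 60)), time, strata)
        with pytest.raises(ValidationError):
            call_tdegs(fits)


class TestPrefilter:
    def test_threshold_rule(self):
        values = np.zeros((2, 20), dtype=int)
        values[0, :3] = 1  # expressed in 3 cells
        values[1, :15] = 2
        m = ExpressionMatrix(values, ["lowly", "widely"], [f"c{i}" for i in range(20)])
        assert prefilter_genes(m, 10) == ["widely"]
        assert prefilter_genes(m, 0) == ["lowly", "widely"]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(8)
        values = rng.poisson(0.3, size=(50, 40))
        m = ExpressionMatrix(
            values, [f"g{i}" for i in range(50)], [f"c{i}" for i in range(40)]
        )
        kept = prefilter_genes(m, 5)
        expected = [
            f"g{i}" for i in range(50) if sum(1 for v in values[i] if v > 0) >= 5
        ]
        assert kept == expected


def test_find_tdegs_end_to_end_table_shape():
    rng = np.random.default_rng(4)
    n = 240
    time = np.arange(n) % 3
    strata = ["A" if s == 0 else "B" for s in (np.arange(n) // 3) % 2]
    values = rng.poisson(2.0, size=(30, n))
    values[0] = nb_glm_counts(time, [0 if s == "A" else 1 for s in strata],
                              (0.7, 0.6, 0.0, -1.2), 2.0, rng)
    ds = TimepointDataset(
        ExpressionMatrix(values, [f"g{i}" for i in range(30)], [f"c{i}" for i in range(n)]),
        CellMetadata([f"c{i}" for i in range(n)], timepoint=list(time), strata=strata),
    )
    table = find_tdegs(ds, min_cells_expressed=5)
    assert set(table.frame.columns) >= {
        "gene_id", "beta_interaction", "omega", "p_interaction_raw",
        "p_interaction_bonf", "is_tdeg", "converged",
    }
    assert "g0" in table.called  # the spiked interaction gene is recovered
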