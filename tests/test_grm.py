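"""Graded response model estimation, scoring, reliability, and fit."""

import numpy as np
import pandas as pd
import pytest

from sensefactor.grm import (
    QuadratureSpec,
    bifactor_loglik_bruteforce,
    eap_scores,
    fit_bifactor_grm,
    fit_unidimensional_grm,
    limited_information_fit,
    loadings_to_slopes,
    marginal_reliability,
    standardize_loadings,
)
from sensefactor.polychoric import polychoric_matrix
from sensefactor.synthetic import SyntheticSpec, generate
from tests.conftest import make_uni_table

FAST = dict(tol=1e-4, max_cycles=150)


class TestStandardization:
    def test_zero_slope_zero_loading(self):
        assert standardize_loadings(0.0, 0.0) == (0.0, 0.0)

    def test_unit_probit_slope_closed_form(self):
        lam, _ = standardize_loadings(1.702)  # a* = 1
        assert abs(lam - 1 / np.sqrt(2)) < 1e-12

    def test_roundtrip_through_slopes(self):
        lam = (0.513, 0.699)
        a_g, a_s = loadings_to_slopes(*lam)
        back = standardize_loadings(a_g, a_s)
        np.testing.assert_allclose(back, lam, atol=1e-12)

    def test_degenerate_communality_rejected(self):
        with pytest.raises(ValueError):
            loadings_to_slopes(0.8, 0.7)


class TestUnidimensional:
    def test_loading_recovery(self, uni6_dataset, uni6_solution):
        true = uni6_dataset.truth["lambda_g"]
        est = np.array([it.lambda_general for it in uni6_solution.items])
        assert uni6_solution.converged
        assert np.all(np.abs(est - true) < 0.05)

    def test_loglik_monotone(self, uni6_solution):
        path = np.array(uni6_solution.loglik_path)
        assert np.all(np.diff(path) >= -1e-6)

    def test_null_item_estimated_near_zero(self):
        table = make_uni_table(5, 0.66)
        table.loc[4, "lambda_g"] = 0.0
        ds = generate(SyntheticSpec(loading_table=table, n_studies=1,
                                    study_sizes=[1500], study_mean_sd=0.0,
                                    seed=13))
        sol = fit_unidimensional_grm(ds.matrix, **FAST)
        lams = [it.lambda_general for it in sol.items]
        assert abs(lams[4]) < 0.08
        assert np.all(np.abs(np.array(lams[:4]) - 0.66) < 0.06)

    def test_determinism(self, uni6_dataset):
        a = fit_unidimensional_grm(uni6_dataset.matrix, **FAST)
        b = fit_unidimensional_grm(uni6_dataset.matrix, **FAST)
        for x, y in zip(a.items, b.items):
            assert x.a_general == y.a_general
            assert np.array_equal(x.intercepts, y.intercepts)

    def test_solution_serialization(self, uni6_solution, tmp_path):
        path = tmp_path / "sol.json"
        uni6_solution.save(path)
        import json

        payload = json.loads(path.read_text())
        assert len(payload["items"]) == 6
        assert payload["model"] == "unidimensional"


@pytest.fixture(scope="module")
def toy_fit():
    toy = pd.DataFrame({
        "item": ["A", "B", "C", "D"],
        "specific_factor": ["G1", "G1", "", ""],
        "lambda_g": [0.5, 0.5, 0.6, 0.6],
        "lambda_s": [0.5, 0.5, np.nan, np.nan],
    })
    ds = generate(SyntheticSpec(loading_table=toy, n_studies=1,
                                study_sizes=[400], study_mean_sd=0.0,
                                seed=21))
    sol = fit_bifactor_grm(ds.matrix, {"A": "G1", "B": "G1"},
                           max_cycles=40, tol=1e-4)
    return ds, sol


class TestBifactor:
    def test_dimension_reduction_equals_bruteforce(self, toy_fit):
        ds, sol = toy_fit
        brute = bifactor_loglik_bruteforce(sol, ds.matrix)
        assert abs(sol.log_likelihood - brute) / abs(brute) < 1e-6

    def test_single_item_specific_factor_rejected(self, toy_fit):
        ds, _ = toy_fit
        with pytest.raises(ValueError, match="single-item"):
            fit_bifactor_grm(ds.matrix, {"A": "G1"})

    def test_zero_specific_slopes_match_unidimensional(self):
        """With no true specific variance the bifactor fit collapses to the
        unidimensional solution: general loadings agree and the implied
        specific-factor covariances (the identified quantities) vanish."""
        table = pd.DataFrame({
            "item": [f"I{i}" for i in range(5)],
            "specific_factor": ["S", "S", "S", "", ""],
            "lambda_g": [0.6] * 5,
            "lambda_s": [0.0, 0.0, 0.0, np.nan, np.nan],
        })
        ds = generate(SyntheticSpec(loading_table=table, n_studies=1,
                                    study_sizes=[1500], study_mean_sd=0.0,
                                    seed=33))
        bif = fit_bifactor_grm(ds.matrix, {"I0": "S", "I1": "S", "I2": "S"},
                               tol=1e-4, max_cycles=100)
        uni = fit_unidimensional_grm(ds.matrix, **FAST)
        lg_b = np.array([it.lambda_general for it in bif.items])
        ls_b = np.array([it.lambda_specific for it in bif.items])
        lg_u = np.array([it.lambda_general for it in uni.items])
        assert np.all(np.abs(lg_b - lg_u) < 0.05)
        # specific-factor contributions to item covariances (the identified
        # quantities) are ~0 within ~3 MC standard errors of a residual
        # polychoric correlation at this n
        for i in range(3):
            for j in range(i + 1, 3):
                assert abs(ls_b[i] * ls_b[j]) < 0.09

    def test_item_order_invariance(self, toy_fit):
        ds, sol = toy_fit
        perm = ["C", "A", "D", "B"]
        sol2 = fit_bifactor_grm(ds.matrix, {"A": "G1", "B": "G1"},
                                item_ids=perm, max_cycles=40, tol=1e-4)
        by_id = {it.item_id: it for it in sol2.items}
        for it in sol.items:
            other = by_id[it.item_id]
            assert abs(it.a_general - other.a_general) < 1e-6
            assert abs(it.a_specific - other.a_specific) < 1e-6


class TestEap:
    def test_all_missing_person_gets_prior(self, uni6_solution, uni6_dataset):
        matrix = uni6_dataset.matrix.select_persons(
            np.arange(uni6_dataset.matrix.n_persons) < 5)
        matrix.codes[0, :] = 0  # wipe person 0
        scores = eap_scores(uni6_solution, matrix)
        assert scores.theta[0] == 0.0
        assert scores.sd[0] == 1.0
        assert scores.all_missing[0]

    def test_monotone_in_response_category(self, uni6_solution, uni6_dataset):
        matrix = uni6_dataset.matrix.select_persons(
            np.arange(uni6_dataset.matrix.n_persons) < 2)
        matrix.codes[0, :] = 3
        matrix.codes[1, :] = 3
        matrix.codes[1, 0] = 4  # one response one category higher
        scores = eap_scores(uni6_solution, matrix)
        assert scores.theta[1] > scores.theta[0]

    def test_score_correlation_attains_reliability_bound(
            self, uni6_solution, uni6_dataset):
        scores = eap_scores(uni6_solution, uni6_dataset.matrix)
        rho = marginal_reliability(scores)
        r = np.corrcoef(scores.theta, uni6_dataset.truth["theta_g"])[0, 1]
        assert r >= np.sqrt(rho) - 0.05

    def test_zero_slope_scale_zero_reliability(self):
        """Items with zero slopes carry no information: the EAP posterior is
        the prior for every person, so marginal reliability is exactly 0."""
        from sensefactor.grm import GrmItemParams, GrmSolution

        table = make_uni_table(4, 0.0)
        ds = generate(SyntheticSpec(loading_table=table, n_studies=1,
                                    study_sizes=[400], study_mean_sd=0.0,
                                    seed=3))
        sol = GrmSolution(
            items=[GrmItemParams(item_id=f"I{i + 1}", a_general=0.0,
                                 a_specific=0.0,
                                 intercepts=np.array([2.0, 1.0, -1.0, -2.0]))
                   for i in range(4)],
            n_persons=400, log_likelihood=0.0, converged=True, n_cycles=0)
        rho = marginal_reliability(eap_scores(sol, ds.matrix))
        assert abs(rho) < 1e-6

    def test_high_slopes_high_reliability(self):
        lam = 4 / np.sqrt(1 + 16)  # a* = 4
        table = make_uni_table(10, float(lam))
        ds = generate(SyntheticSpec(loading_table=table, n_studies=1,
                                    study_sizes=[500], study_mean_sd=0.0,
                                    seed=8))
        sol = fit_unidimensional_grm(ds.matrix, tol=1e-3, max_cycles=60)
        rho = marginal_reliability(eap_scores(sol, ds.matrix))
        assert rho > 0.9


class TestLimitedInformationFit:
    def test_exact_model_zero_srmr(self, uni6_solution, uni6_dataset):
        poly = polychoric_matrix(uni6_dataset.matrix)
        lam = np.array([it.lambda_general for it in uni6_solution.items])
        implied = np.outer(lam, lam)
        np.fill_diagonal(implied, 1.0)
        poly.corr = implied  # replace the sample matrix by the implied one
        fit = limited_information_fit(uni6_solution, poly)
        assert fit.srmr < 1e-10
        assert fit.rmsea == 0.0

    def test_true_model_within_retention_region(self, uni6_solution,
                                                uni6_dataset):
        poly = polychoric_matrix(uni6_dataset.matrix)
        fit = limited_information_fit(uni6_solution, poly)
        assert fit.srmr < 0.05
        assert fit.defined

    def test_misspecified_model_fits_worse(self):
        # two independent 3-item factors forced into one dimension
        table = pd.DataFrame({
            "item": [f"I{i}" for i in range(6)],
            "specific_factor": ["A"] * 3 + ["B"] * 3,
            "lambda_g": [0.0] * 6,
            "lambda_s": [0.75] * 6,
        })
        ds = generate(SyntheticSpec(loading_table=table, n_studies=1,
                                    study_sizes=[1500], study_mean_sd=0.0,
                                    seed=17))
        sol = fit_unidimensional_grm(ds.matrix, **FAST)
        poly = polychoric_matrix(ds.matrix)
        fit_bad = limited_information_fit(sol, poly)
        assert fit_bad.srmr > 0.1

    def test_just_identified_indices_undefined(self, uni6_dataset):
        sol3 = fit_unidimensional_grm(uni6_dataset.matrix,
                                      item_ids=["I1", "I2", "I3"], **FAST)
        poly = polychoric_matrix(uni6_dataset.matrix, ["I1", "I2", "I3"])
        fit = limited_information_fit(sol3, poly)
        assert not fit.defined
        assert fit.rmsea is None and fit.tli is None
        assert fit.srmr >= 0.0
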