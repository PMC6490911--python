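import numpy as np
import pandas as pd
import pytest

from lznpk import (CovariateCandidate, FitSettings, OneCompartmentNLME,
                   PopulationModel, empirical_bayes, fit,
                   likelihood_ratio_test, marginal_objective,
                   stepwise_covariate_search)
from lznpk.estimate import _Objective, prepare_design
from lznpk.io import make_pk_dataset
from lznpk.pkmodel import _conc_arrays
from lznpk.simulate import generate_concentrations
from oracles import ofv_agq_reference

FAST = FitSettings(compute_rse=False, truncated_residuals=False)


def reorder_subjects(ds, order):
    blocks = [g for _, g in ds.df.groupby("ID", sort=False)]
    df = pd.concat([blocks[i] for i in order]).reset_index(drop=True)
    return make_pk_dataset(df)


class TestMarginalObjective:
    def test_degenerate_random_effects_equal_weighted_ls(self, small_cohort,
                                                         final_model):
        """With omega = 0 the objective is the plain fixed-effects -2LL."""
        ds, _ = small_cohort
        m0 = final_model.with_updates(omega2_cl=0.0, omega2_v=0.0)
        ofv = marginal_objective(m0, ds)
        d = prepare_design(ds)
        fw = d.weight / 70.0
        cl = 4.73 * fw ** 0.75
        v = 54.8 * fw
        ka = 0.77 + cl / v
        f = np.real(_conc_arrays(d.t, d.dose, d.tau, d.ss, cl[d.subj],
                                 v[d.subj], ka[d.subj]))
        var = m0.sigma2_prop * f * f + m0.sigma2_add
        direct = float(np.sum(np.log(2 * np.pi * var) + (d.y - f) ** 2 / var))
        assert ofv == pytest.approx(direct, abs=1e-8)

    def test_matches_adaptive_quadrature_oracle(self, final_model, rich_design):
        """Laplace objective tracks 17-node adaptive Gauss-Hermite."""
        ds, _ = rich_design(4, seed=5, model=final_model)
        laplace = marginal_objective(final_model, ds, method="laplace")
        oracle = ofv_agq_reference(final_model, ds, n_nodes=17)
        assert abs(laplace - oracle) < 0.5
        # the package's own AGQ evaluator agrees tightly with the oracle
        agq = marginal_objective(final_model, ds, method="agq", n_nodes=17)
        assert agq == pytest.approx(oracle, abs=1e-4)

    def test_subject_order_invariance(self, small_cohort, final_model):
        ds, _ = small_cohort
        base = marginal_objective(final_model, ds)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.n_subjects)
        shuffled = reorder_subjects(ds, perm)
        assert marginal_objective(final_model, shuffled) == pytest.approx(
            base, abs=1e-10)

    def test_deterministic(self, small_cohort, final_model):
        ds, _ = small_cohort
        assert marginal_objective(final_model, ds) == marginal_objective(
            final_model, ds)


class TestFit:
    def test_noiseless_self_consistency(self, final_model, rich_design):
        """Near-zero noise at a rich design recovers thetas to 3 figures."""
        gen = final_model.with_updates(omega2_cl=1e-12, omega2_v=1e-12)
        ds, _ = rich_design(40, seed=9, model=gen, sigma_scale=1e-4)
        init = final_model.with_updates(theta_ka=0.6, theta_cl=4.0,
                                        theta_v=45.0, omega2_cl=0.01,
                                        omega2_v=0.01, sigma2_prop=1e-4,
                                        sigma2_add=1e-4)
        res = fit(ds, init=init, settings=FAST)
        assert res.estimates["theta_cl"] == pytest.approx(4.73, rel=5e-4)
        assert res.estimates["theta_v"] == pytest.approx(54.8, rel=5e-4)
        assert res.estimates["theta_ka"] == pytest.approx(0.77, rel=5e-3)

    def test_duplicating_subjects_doubles_ofv(self, final_model, rich_design):
        """A duplicated cohort gives the same estimates and twice the OFV."""
        ds, _ = rich_design(10, seed=21, model=final_model)
        res1 = fit(ds, init=final_model, settings=FAST)
        dup = ds.df.copy()
        dup2 = dup.copy()
        dup2["ID"] = dup2["ID"] + "_b"
        doubled = make_pk_dataset(pd.concat([dup, dup2]).reset_index(drop=True))
        res2 = fit(doubled, init=final_model, settings=FAST)
        assert res2.estimates["theta_cl"] == pytest.approx(
            res1.estimates["theta_cl"], rel=1e-3)
        ofv1_at_2 = marginal_objective(res2.model, ds, method="foce")
        assert res2.ofv == pytest.approx(2 * ofv1_at_2, rel=1e-6)

    def test_estimator_follows_sklearn_conventions(self, small_cohort,
                                                   final_model):
        est = OneCompartmentNLME(init=final_model, settings=FAST)
        params = est.get_params()
        assert "init" in params and "settings" in params
        est.set_params(settings=FAST)
        ds, _ = small_cohort
        est.fit(ds)
        assert hasattr(est, "model_") and hasattr(est, "ofv_")
        assert len(est.ebes_) == ds.n_subjects
        pred = est.predict(ds)
        assert pred.shape == (len(ds.observations()),)
        assert np.all(np.isfinite(pred))

    def test_requires_two_subjects(self, final_model, rich_design):
        ds, _ = rich_design(1, seed=2, model=final_model)
        with pytest.raises(ValueError, match="2 subjects"):
            fit(ds, init=final_model, settings=FAST)


class TestLikelihoodRatio:
    @pytest.mark.parametrize("delta,df,expected", [
        (3.841, 1, 0.050), (6.635, 1, 0.010), (0.0, 1, 1.0), (5.991, 2, 0.050)])
    def test_chi_square_tail(self, delta, df, expected):
        assert likelihood_ratio_test(100.0 + delta, 100.0, df) == pytest.approx(
            expected, abs=5e-4)

    def test_small_negative_delta_clamps_to_one(self):
        with pytest.warns(RuntimeWarning):
            p = likelihood_ratio_test(99.9999, 100.0, 1, tol=1e-6)
        assert p == 1.0

    def test_df_below_one_rejected(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(100.0, 99.0, 0)


class TestEmpiricalBayes:
    def test_prior_mode_with_no_observations(self, final_model):
        df = pd.DataFrame({"ID": ["Z"], "TIME": [0.0], "EVID": [1],
                           "AMT": [100.0], "DV": [0.0], "WT": [20.0],
                           "SS": [1], "II": [24.0]})
        ds = make_pk_dataset(df)
        assert empirical_bayes(final_model, ds) == (0.0, 0.0)

    def test_recovers_true_etas_with_rich_low_noise_data(self, final_model,
                                                         rich_design):
        gen = final_model.with_updates(omega2_cl=1e-12, omega2_v=1e-12)
        rng_eta = (0.3, -0.2)
        import pandas as pd
        times = np.arange(0.0, 24.0, 1.5)
        rows = [dict(ID="E1", OCC=1, TIME=0.0, EVID=1, AMT=200.0, DV=np.nan,
                     SS=1, II=24.0, WT=20.0)]
        rows += [dict(ID="E1", OCC=1, TIME=t, EVID=0, AMT=0.0, DV=np.nan,
                      SS=0, II=0.0, WT=20.0) for t in times]
        skel = pd.DataFrame(rows)
        from lznpk.pkmodel import individual_parameters, Regimen, concentration
        ind = individual_parameters(final_model, *rng_eta, 20.0)
        reg = Regimen(200.0, 24.0, "steady_state")
        skel.loc[skel.EVID == 0, "DV"] = concentration(ind, reg, times)
        tiny = final_model.with_updates(sigma2_prop=1e-8, sigma2_add=1e-8)
        ds = make_pk_dataset(skel)
        eta = empirical_bayes(tiny, ds)
        assert eta[0] == pytest.approx(0.3, abs=0.02)
        assert eta[1] == pytest.approx(-0.2, abs=0.02)

    def test_mode_matches_grid_search(self, final_model, rich_design):
        """The Newton mode agrees with an exhaustive 2-D grid (step 1e-3)."""
        ds, _ = rich_design(1, seed=13, model=final_model)
        eta = empirical_bayes(final_model, ds)
        d = prepare_design(ds)
        obj = _Objective(d, final_model)
        tv = obj._typicals(final_model)
        w2 = obj._omegas(final_model)
        g1 = np.arange(eta[0] - 0.25, eta[0] + 0.25, 1e-3)
        g2 = np.arange(eta[1] - 0.25, eta[1] + 0.25, 1e-3)
        A, B = np.meshgrid(g1, g2, indexing="ij")
        best, arg = np.inf, None
        for j in range(A.shape[1]):
            etas = np.stack([A[:, j], B[:, j]], axis=1)
            qs = np.array([np.real(obj._q(e[None, :], final_model, tv, w2))[0]
                           for e in etas])
            k = int(np.argmin(qs))
            if qs[k] < best:
                best, arg = qs[k], (A[k, j], B[k, j])
        assert eta[0] == pytest.approx(arg[0], abs=2e-3)
        assert eta[1] == pytest.approx(arg[1], abs=2e-3)

    def test_shrinkage_grows_as_observations_shrink(self, final_model):
        """EBEs shrink toward zero as per-subject information drops."""
        from lznpk.pkmodel import individual_parameters, Regimen, concentration
        ind = individual_parameters(final_model, 0.5, 0.4, 20.0)
        reg = Regimen(200.0, 24.0, "steady_state")
        sizes = (12, 4, 1)
        norms = []
        for n_obs in sizes:
            times = np.linspace(1.0, 23.0, n_obs)
            rows = [dict(ID="S", OCC=1, TIME=0.0, EVID=1, AMT=200.0,
                         DV=np.nan, SS=1, II=24.0, WT=20.0)]
            rows += [dict(ID="S", OCC=1, TIME=t, EVID=0, AMT=0.0,
                          DV=float(concentration(ind, reg, t)), SS=0, II=0.0,
                          WT=20.0) for t in times]
            ds = make_pk_dataset(pd.DataFrame(rows))
            eta = empirical_bayes(final_model, ds)
            norms.append(np.hypot(*eta))
        assert norms[0] > norms[1] > norms[2]


class TestStepwiseCovariateSearch:
    def _cohort_with_age_effect(self, final_model, beta, n=40, seed=3):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            age = float(rng.uniform(1.0, 15.0))
            w = 4.0 + 2.2 * age + 0.07 * age ** 2
            base = dict(ID=f"C{i:03d}", OCC=1, WT=round(w, 2), AGE=round(age, 2),
                        SEX="M", ETHN="black", HIV=0, FORM="suspension",
                        ROUTE="oral", COHORT="MDRPK2")
            rows.append(dict(base, TIME=0.0, EVID=1, AMT=10.0 * w, DV=np.nan,
                             SS=1, II=24.0))
            for t in (0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 18.0):
                rows.append(dict(base, TIME=t, EVID=0, AMT=0.0, DV=np.nan,
                                 SS=0, II=0.0))
        skel = pd.DataFrame(rows)
        gen = final_model.with_updates(
            omega2_cl=0.02, omega2_v=0.02,
            covariate_effects=(
                __import__("lznpk").CovariateEffect("cl", "AGE", "exponential",
                                                    beta=beta, center=8.0),))
        ds, truth = generate_concentrations(skel, gen, seed=seed)
        return ds

    def test_strong_age_effect_is_selected_forward(self, final_model):
        """A real age-on-CL signal beyond allometry enters the model."""
        ds = self._cohort_with_age_effect(final_model, beta=0.08)
        base = fit(ds, init=final_model.with_updates(omega2_cl=0.02,
                                                     omega2_v=0.02),
                   settings=FAST)
        cands = [CovariateCandidate("CL", "AGE", "exponential"),
                 CovariateCandidate("V", "HIV", "categorical-shift")]
        out = stepwise_covariate_search(ds, base, cands, forward_alpha=0.05,
                                        backward_alpha=0.01, settings=FAST)
        selected = {(c.parameter, c.covariate) for c in out.selected}
        assert ("CL", "AGE") in selected
        assert {"step", "phase", "candidate", "dofv", "p",
                "decision"} <= set(out.trail.columns)

    def test_forward_threshold_rejects_small_improvement(self):
        """An OFV drop of 3.0 on 1 df is not significant at alpha 0.05."""
        assert likelihood_ratio_test(103.0, 100.0, 1) > 0.05
        assert likelihood_ratio_test(104.0, 100.0, 1) < 0.05

    def test_null_covariate_not_selected(self, final_model):
        """With no simulated effect the search returns an empty selection."""
        ds = self._cohort_with_age_effect(final_model, beta=0.0, seed=8)
        base = fit(ds, init=final_model.with_updates(omega2_cl=0.02,
                                                     omega2_v=0.02),
                   settings=FAST)
        cands = [CovariateCandidate("V", "HIV", "categorical-shift")]
        out = stepwise_covariate_search(ds, base, cands, settings=FAST)
        assert out.selected == []
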