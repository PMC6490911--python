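import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lznpk import (CohortDesign, PopulationModel, ToxicityModel,
                   generate_cohort, generate_concentrations,
                   generate_pk_dataset, generate_safety, make_pk_dataset)


class TestGenerateCohort:
    def test_same_seed_identical(self):
        a = generate_cohort(CohortDesign(), seed=5)
        b = generate_cohort(CohortDesign(), seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_study_structure(self):
        """48 children: ages within range, ~31/48 single dose, both designs."""
        df = generate_cohort(CohortDesign(), seed=7)
        sub = df.groupby("ID").first()
        assert len(sub) == 48
        assert sub["AGE"].between(0.6, 15.3).all()
        doses = df[df.EVID == 1]
        single = doses[doses.SS == 0]["ID"].nunique()
        assert single == 31
        assert set(sub["COHORT"]) == {"MDRPK1", "MDRPK2"}
        # twice-daily steady state below 10 y, once daily above
        ss = doses[doses.SS == 1].join(sub[["AGE"]], on="ID", rsuffix="_s")
        assert (ss.loc[ss.AGE < 10, "II"] == 12.0).all()
        assert (ss.loc[ss.AGE >= 10, "II"] == 24.0).all()
        # ~10 mg/kg per administered dose
        mgkg = doses["AMT"] / doses["WT"]
        assert mgkg.between(8.0, 12.0).mean() > 0.9

    def test_all_single_dose_design_has_no_ss_flags(self):
        df = generate_cohort(CohortDesign(single_dose_fraction=1.0,
                                          mdrpk1_fraction=0.0), seed=3)
        assert (df["SS"] == 0).all()

    def test_weights_span_expected_range(self):
        df = generate_cohort(CohortDesign(n_subjects=400), seed=11)
        w = df.groupby("ID").first()["WT"]
        assert w.min() >= 4.5 and w.max() <= 60.0
        assert w.min() < 8.0 and w.max() > 40.0

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign(n_subjects=0)
        with pytest.raises(ValueError):
            CohortDesign(single_dose_fraction=1.5)


class TestGenerateConcentrations:
    def test_noiseless_observations_equal_closed_form(self, final_model):
        skel = generate_cohort(CohortDesign(n_subjects=5), seed=2)
        gen = final_model.with_updates(omega2_cl=0.0, omega2_v=0.0,
                                       sigma2_prop=0.0, sigma2_add=0.0)
        ds, truth = generate_concentrations(skel, gen, seed=2)
        from lznpk.estimate import prepare_design
        from lznpk.pkmodel import _conc_arrays
        d = prepare_design(ds)
        fw = d.weight / 70.0
        cl = 4.73 * fw ** 0.75
        v = 54.8 * fw
        ka = 0.77 + cl / v
        f = np.real(_conc_arrays(d.t, d.dose, d.tau, d.ss, cl[d.subj],
                                 v[d.subj], ka[d.subj]))
        np.testing.assert_allclose(d.y, f, atol=1e-6)

    def test_proportional_error_cv_at_high_concentrations(self, final_model):
        """Residual CV approaches 25% where predictions are large."""
        rng = np.random.default_rng(0)
        rows = []
        for i in range(2000):
            base = dict(ID=f"H{i}", OCC=1, WT=70.0, AGE=10.0)
            rows.append(dict(base, TIME=0.0, EVID=1, AMT=4000.0, DV=np.nan,
                             SS=1, II=24.0))
            rows.append(dict(base, TIME=2.0, EVID=0, AMT=0.0, DV=np.nan,
                             SS=0, II=0.0))
        gen = final_model.with_updates(omega2_cl=0.0, omega2_v=0.0)
        ds, _ = generate_concentrations(pd.DataFrame(rows), gen, seed=4)
        d = ds.observations()
        f = d["DV"].mean()
        cv = d["DV"].std() / f
        assert cv == pytest.approx(0.25, abs=0.02)

    def test_no_negative_concentrations_and_truth_recorded(self, final_model):
        ds, truth = generate_pk_dataset(CohortDesign(n_subjects=30),
                                        final_model, seed=6)
        assert (ds.observations()["DV"] >= 0).all()
        assert {"ID", "eta_cl", "eta_v", "cl", "v", "ka"} <= set(truth.columns)
        assert len(truth) == 30

    def test_fraction_below_lloq_matches_large_sample_reference(self,
                                                                final_model):
        """The share of sub-LLOQ draws agrees with a big independent run."""
        design = CohortDesign(n_subjects=300)
        ds, _ = generate_pk_dataset(design, final_model, seed=13)
        frac = float((ds.observations()["DV"] < 0.1).mean())
        big, _ = generate_pk_dataset(CohortDesign(n_subjects=3000),
                                     final_model, seed=99)
        ref = float((big.observations()["DV"] < 0.1).mean())
        assert frac == pytest.approx(ref, abs=0.02)

    def test_generated_datasets_pass_validation(self, final_model):
        ds, _ = generate_pk_dataset(CohortDesign(n_subjects=20), final_model,
                                    seed=8)
        make_pk_dataset(ds.df)  # revalidates without error


class TestSeedIsolation:
    def test_streams_are_independent(self, final_model):
        """Changing the toxicity stream leaves PK data untouched."""
        skel1 = generate_cohort(CohortDesign(n_subjects=10), seed=21)
        ds1, truth1 = generate_concentrations(skel1, final_model, seed=21)
        ds2, truth2 = generate_concentrations(skel1, final_model, seed=21)
        pd.testing.assert_frame_equal(ds1.df, ds2.df)
        subjects = truth1.assign(auc24ss=100.0)[["ID", "auc24ss"]]
        generate_safety(subjects, ToxicityModel(), seed=21)
        ds3, _ = generate_concentrations(skel1, final_model, seed=21)
        pd.testing.assert_frame_equal(ds1.df, ds3.df)


class TestGenerateSafety:
    def test_zero_hazard_zero_events(self):
        subjects = pd.DataFrame({"ID": ["A", "B"], "auc24ss": [100.0, 200.0]})
        tox = ToxicityModel(baseline_hazard=0.0, log_hazard_slope=0.0)
        rec = generate_safety(subjects, tox, seed=1)
        assert (rec["event_type"] == "").all()

    def test_onset_never_exceeds_followup(self):
        subjects = pd.DataFrame({"ID": [f"S{i}" for i in range(200)],
                                 "auc24ss": np.linspace(40, 300, 200)})
        rec = generate_safety(subjects, ToxicityModel(), seed=2)
        ev = rec[rec.event_type != ""]
        assert (ev["onset_day"] <= ev["followup_days"]).all()
        assert (ev["onset_day"] >= 0).all()

    def test_positive_slope_links_auc_and_events(self):
        """Kendall tau between AUC and event occurrence is positive."""
        tox = ToxicityModel()
        rng = np.random.default_rng(3)
        positive = 0
        n_rep = 60
        for rep in range(n_rep):
            aucs = rng.uniform(40.0, 260.0, 40)
            subjects = pd.DataFrame({"ID": [f"T{i}" for i in range(40)],
                                     "auc24ss": aucs})
            rec = generate_safety(subjects, tox, seed=5000 + rep)
            ev = (rec["event_type"] != "").astype(int)
            tau = stats.kendalltau(rec["auc24ss"], ev).statistic
            if tau > 0:
                positive += 1
        assert positive >= int(0.95 * n_rep)
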