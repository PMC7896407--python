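import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from petsubtype.outcomes import (EligibilityError, NonConvergenceError, adni_diff,
                                 atn_classify, cox_ph, fdr_bh,
                                 group_test_categorical, group_test_continuous,
                                 hv_ctv_ratio, kaplan_meier, lmm_trajectories,
                                 progression_event, progression_table)


class TestCompositeArithmetic:
    def test_typical_subtype_printed_means(self):
        # the memory-minus-executive difference for the typical subtype
        assert adni_diff(-0.90, -1.11) == pytest.approx(0.21)

    def test_equal_scores_give_zero(self):
        assert adni_diff(-1.2, -1.2) == 0.0

    def test_cortical_subtype_printed_means(self):
        # printed cell is 0.41; per-subject averaging before rounding explains 0.01
        assert adni_diff(-1.31, -1.73) == pytest.approx(0.42)

    def test_hv_ctv_worked_example(self):
        assert hv_ctv_ratio(4.05, 75.84) == pytest.approx(53.4, abs=0.05)

    def test_hv_ctv_scale_invariance_and_identity(self):
        assert hv_ctv_ratio(2.0, 2.0) == pytest.approx(1000.0)
        assert hv_ctv_ratio(8.1, 151.68) == pytest.approx(hv_ctv_ratio(4.05, 75.84))

    def test_nonpositive_ctv_rejected(self):
        with pytest.raises(ValueError):
            hv_ctv_ratio(4.0, 0.0)


class TestATN:
    def test_pet_threshold_inclusive(self):
        assert atn_classify(av45_suvr=1.11).A == "+"
        assert atn_classify(av45_suvr=1.1099).A == "-"

    def test_csf_abeta_fallback_strict(self):
        assert atn_classify(csf_abeta=880.0).A == "-"
        assert atn_classify(csf_abeta=879.9).A == "+"

    def test_tau_thresholds_strict(self):
        p = atn_classify(av45_suvr=1.2, csf_ptau=19.2, csf_ttau=242.0)
        assert (p.T, p.N) == ("-", "-")
        p = atn_classify(av45_suvr=1.2, csf_ptau=19.3, csf_ttau=242.1)
        assert (p.T, p.N) == ("+", "+")

    def test_pet_takes_precedence_over_csf(self):
        assert atn_classify(av45_suvr=1.05, csf_abeta=500.0).A == "-"

    def test_missing_inputs(self):
        p = atn_classify(av45_suvr=1.2)
        assert p.T == "unknown" and p.N == "unknown"
        with pytest.raises(ValueError):
            atn_classify()


class TestFdrBH:
    def test_worked_example(self):
        adj = fdr_bh([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(adj, [0.02, 0.02, 0.04, 0.04])

    def test_single_p_unchanged_and_equal_ps_fixed_point(self):
        assert fdr_bh([0.37])[0] == pytest.approx(0.37)
        assert np.allclose(fdr_bh([0.2, 0.2, 0.2]), 0.2)

    def test_monotone_and_never_below_raw(self, rng):
        p = rng.uniform(size=25)
        adj = fdr_bh(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.1, 1.2])


class TestGroupTests:
    def test_two_group_f_equals_squared_t(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(1, 1, 25)
        res = group_test_continuous(np.concatenate([a, b]),
                                    ["a"] * 20 + ["b"] * 25)
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        assert res.global_stat == pytest.approx(t ** 2, rel=1e-10)

    def test_null_p_uniform(self, rng):
        ps = []
        for _ in range(400):
            y = rng.normal(size=30)
            g = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
            ps.append(group_test_continuous(y, g).global_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_shift_detected_with_post_hocs(self, rng):
        y = np.concatenate([rng.normal(0, 1, 50), rng.normal(1, 1, 50),
                            rng.normal(0, 1, 50)])
        g = ["a"] * 50 + ["b"] * 50 + ["c"] * 50
        res = group_test_continuous(y, g)
        assert res.global_p < 0.05
        pw = res.pairwise.set_index(["g1", "g2"])
        assert pw.loc[("a", "b"), "p_fdr"] < 0.05
        assert pw.loc[("a", "c"), "p_fdr"] > pw.loc[("a", "b"), "p_fdr"]

    def test_ancova_covariate_absorbs_variance(self, rng):
        age = rng.normal(70, 5, 60)
        y = 0.1 * age + rng.normal(0, 0.5, 60)
        g = ["a", "b", "c"] * 20
        res = group_test_continuous(y, g, covariates=pd.DataFrame({"age": age}))
        assert res.global_p > 0.001  # group carries no signal beyond age

    def test_chi_square_hand_example(self):
        res = group_test_categorical(np.array([[30, 10], [10, 30]]))
        assert res.global_stat == pytest.approx(20.0)

    def test_chi_square_identical_columns(self):
        res = group_test_categorical(np.array([[10, 10], [10, 10]]))
        assert res.global_stat == 0.0 and res.global_p == 1.0

    def test_chi_square_pairwise_fdr(self):
        table = np.array([[40, 38, 5], [10, 12, 45]])
        res = group_test_categorical(pd.DataFrame(table, columns=["a", "b", "c"]))
        assert res.global_p < 0.05
        pw = res.pairwise.set_index(["g1", "g2"])
        assert pw.loc[("a", "c"), "p_fdr"] < 0.05
        assert pw.loc[("a", "b"), "p_fdr"] > 0.05

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError):
            group_test_categorical(np.array([[5, 0], [5, 0]]).T * 0)


class TestProgressionEvent:
    def visits(self, months, cdrs):
        return pd.DataFrame({"month": months, "cdr": cdrs})

    def test_event_at_first_cdr_one(self):
        assert progression_event(self.visits([0, 12, 24], [0.5, 0.5, 1.0])) == (24.0, True)

    def test_censored_at_last_visit(self):
        assert progression_event(self.visits([0, 12], [0.5, 0.5])) == (12.0, False)

    def test_cdr_two_counts_as_event(self):
        assert progression_event(self.visits([0, 6], [0.5, 2.0])) == (6.0, True)

    def test_non_mci_baseline_rejected(self):
        with pytest.raises(EligibilityError):
            progression_event(self.visits([0, 6], [0.0, 0.5]))


class TestKaplanMeier:
    def test_hand_worked_product_limit(self):
        rec = pd.DataFrame({"time": [1.0, 2.0, 3.0],
                            "event": [True, False, True]})
        sf = kaplan_meier(rec)["all"].set_index("time")["survival"]
        assert sf.loc[1.0] == pytest.approx(2.0 / 3.0)
        assert sf.loc[3.0] == pytest.approx(0.0)

    def test_no_events_flat_at_one(self):
        rec = pd.DataFrame({"time": [5.0, 8.0], "event": [False, False]})
        sf = kaplan_meier(rec)["all"]
        assert (sf["survival"] == 1.0).all()

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = np.sort(rng.exponential(10, size=40))
        rec = pd.DataFrame({"time": times, "event": True})
        sf = kaplan_meier(rec)["all"].set_index("time")["survival"]
        for k, t in enumerate(times, start=1):
            assert sf.loc[t] == pytest.approx((40 - k) / 40)


class TestCox:
    def test_four_subject_partial_likelihood_oracle(self):
        # x=1 events at t=1,3; x=0 events at t=2,4
        rec = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0],
                            "event": [True] * 4,
                            "subtype": ["b", "a", "b", "a"]})

        def neg_log_pl(beta):
            e = np.exp(beta)
            return -(np.log(e / (2 * e + 2)) + np.log(1 / (e + 2))
                     + np.log(e / (e + 1)))

        oracle = minimize_scalar(neg_log_pl, bounds=(-5, 5), method="bounded",
                                 options={"xatol": 1e-12}).x
        res = cox_ph(rec, reference="a", covariates=())
        assert res.summary.loc[0, "coef"] == pytest.approx(oracle, abs=1e-6)

    def test_null_groups_hr_near_one(self, rng):
        inside = 0
        for s in range(40):
            r = np.random.default_rng(s)
            n = 500
            t = r.exponential(20, n)
            c = r.uniform(5, 40, n)
            rec = pd.DataFrame({"time": np.minimum(t, c), "event": t <= c,
                                "subtype": r.choice(["a", "b"], n)})
            hr = cox_ph(rec, reference="a", covariates=()).hazard_ratio("subtype[b]")
            inside += 0.8 < hr < 1.25
        assert inside >= 38  # >= 95% of seeds

    def test_hr_invariant_to_covariate_rescaling(self, rng):
        n = 300
        t = rng.exponential(20, n)
        rec = pd.DataFrame({"time": t, "event": True,
                            "subtype": rng.choice(["a", "b"], n),
                            "age": rng.normal(70, 6, n),
                            "gender": rng.choice(["M", "F"], n),
                            "education": rng.normal(16, 2, n)})
        r1 = cox_ph(rec, reference="a")
        rec2 = rec.assign(age=(rec.age - 70) / 6)
        r2 = cox_ph(rec2, reference="a")
        assert r1.hazard_ratio("subtype[b]") == pytest.approx(
            r2.hazard_ratio("subtype[b]"), rel=1e-6)

    def test_group_without_events_raises(self):
        rec = pd.DataFrame({"time": [1, 2, 3, 4.0], "event": [True, True, False, False],
                            "subtype": ["a", "a", "b", "b"]})
        with pytest.raises(NonConvergenceError):
            cox_ph(rec, reference="a", covariates=())


class TestMixedModels:
    def _cohort_visits(self, slopes, n_per=40, noise=0.0, u0=0.0, u1=0.0, seed=0):
        from petsubtype.simulate import CohortConfig, generate_longitudinal

        rng = np.random.default_rng(seed)
        rows = []
        for st, slope in slopes.items():
            for i in range(n_per):
                rows.append(dict(subject_id=f"{st}_{i}", group="MCI",
                                 true_subtype=st, MEM=rng.normal(0, 0.2),
                                 EF=0.0, VS=0.0, Lan=0.0,
                                 age=rng.normal(72, 5),
                                 gender=rng.choice(["M", "F"]),
                                 education=rng.normal(16, 2)))
        cohort = pd.DataFrame(rows)
        decline = {st: dict(MEM=sl, EF=0.0, VS=0.0, Lan=0.0)
                   for st, sl in slopes.items()}
        cfg = CohortConfig(seed=seed, decline_slopes=decline,
                           hazard_ratios={st: 1.0 for st in slopes},
                           visit_noise_sd=noise, random_intercept_sd=u0,
                           random_slope_sd=u1, min_followup_months=36)
        visits, _ = generate_longitudinal(cohort, cfg)
        return cohort.rename(columns={"true_subtype": "subtype"}), visits

    def test_zero_noise_recovers_slopes_exactly(self):
        cohort, visits = self._cohort_visits(
            {"no_hypometabolism": -0.002, "typical": -0.015}, n_per=12)
        res = lmm_trajectories(visits, cohort, "MEM", covariates=())
        fe = res.fixed_effects.set_index("term")
        # exact up to the REML optimizer's tolerance in this degenerate limit
        assert fe.loc["month", "estimate"] == pytest.approx(-0.002, abs=1e-5)
        inter = res.interaction("typical")
        assert inter["estimate"] == pytest.approx(-0.013, abs=1e-5)

    def test_balanced_equivalence_with_per_subject_ols(self):
        cohort, visits = self._cohort_visits(
            {"no_hypometabolism": -0.004, "typical": -0.014},
            n_per=25, noise=0.15, u0=0.3, u1=0.004, seed=4)
        # complete balanced grid: force common last visit
        counts = visits.groupby("subject_id")["month"].max()
        common = counts.min()
        bal = visits[visits["month"] <= common]
        slopes = bal.groupby("subject_id").apply(
            lambda d: np.polyfit(d["month"], d["MEM"], 1)[0], include_groups=False)
        merged = cohort.set_index("subject_id").join(slopes.rename("slope"))
        diff = (merged.loc[merged.subtype == "typical", "slope"].mean()
                - merged.loc[merged.subtype == "no_hypometabolism", "slope"].mean())
        res = lmm_trajectories(bal, cohort, "MEM", covariates=())
        assert res.interaction("typical")["estimate"] == pytest.approx(diff, abs=1e-6)

    def test_planted_slope_difference_recovered(self):
        hits, est_ok = 0, []
        for seed in range(8):
            cohort, visits = self._cohort_visits(
                {"no_hypometabolism": -0.002, "typical": -0.012},
                n_per=150, noise=0.25, u0=0.4, u1=0.005, seed=100 + seed)
            res = lmm_trajectories(visits, cohort, "MEM")
            inter = res.interaction("typical")
            est_ok.append(inter["estimate"])
            hits += inter["p"] < 0.05
        assert hits >= 7  # rejection rate >= 0.9 at planted difference 0.01/month
        assert np.mean(est_ok) == pytest.approx(-0.010, rel=0.2)


def test_progression_table_joins_subtypes():
    visits = pd.DataFrame({
        "subject_id": ["s1"] * 3 + ["s2"] * 2,
        "month": [0, 6, 12, 0, 6],
        "cdr": [0.5, 0.5, 1.0, 0.5, 0.5],
    })
    cohort = pd.DataFrame({"subject_id": ["s1", "s2"], "subtype": ["typical", "no_hypometabolism"],
                           "age": [70, 72], "gender": ["F", "M"], "education": [16, 14]})
    rec = progression_table(visits, cohort)
    assert rec.set_index("subject_id").loc["s1", "event"]
    assert rec.set_index("subject_id").loc["s2", "time"] == 6.0
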