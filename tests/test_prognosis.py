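"""Median splits, KM curves, log-rank test, Cox fits and risk models."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from cerna_prognost import (
    fit_cox,
    km_curve,
    logrank_test,
    median_split,
    simulate_cohort,
    triplet_risk_analysis,
)
from cerna_prognost.errors import (
    CollinearityError,
    DegenerateSplitError,
    ValidationError,
)
from cerna_prognost.prognosis import SurvivalSplit, km_by_group, standardize
from cerna_prognost.simulate import simulate_survival

from conftest import make_clinical


def km_oracle(times, events):
    """Brute-force product-limit: iterate the risk table literally."""
    out = {}
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n = sum(1 for x in times if x >= t)
        d = sum(1 for x, e in zip(times, events) if x == t and e == 1)
        s *= 1 - d / n
        out[t] = s
    return out


class TestMedianSplit:
    def test_even_split(self):
        split = median_split(pd.Series([1, 2, 3, 4], index=list("abcd")))
        assert split.split_value == 2.5
        assert set(split.high) == {"c", "d"}
        assert set(split.low) == {"a", "b"}

    def test_ties_go_low(self):
        split = median_split(pd.Series([1, 2, 2, 3], index=list("abcd")))
        assert split.split_value == 2
        assert set(split.high) == {"d"}
        assert set(split.low) == {"a", "b", "c"}

    def test_constant_rejected(self):
        with pytest.raises(DegenerateSplitError):
            median_split(pd.Series([5, 5, 5, 5]))

    def test_balanced_without_ties(self):
        rng = np.random.default_rng(0)
        x = pd.Series(rng.normal(size=101))
        split = median_split(x)
        assert abs(len(split.high) - len(split.low)) <= 1


class TestLogRank:
    def test_mirrored_groups_give_zero(self):
        times = [5, 10, 15, 20] * 2
        events = [1, 1, 0, 1] * 2
        ids = [f"P{i}" for i in range(8)]
        clin = make_clinical(times, events, ids)
        group = pd.Series(["high"] * 4 + ["low"] * 4, index=ids)
        res = logrank_test(SurvivalSplit(group=group, split_value=0.0), clin)
        assert res.chi_square == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_risk_table(self):
        # group A dies at 1,2,3; group B at 4,5,6: O_A=3, E_A=1.15, V=0.6775
        ids = [f"P{i}" for i in range(6)]
        clin = make_clinical([1, 2, 3, 4, 5, 6], [1] * 6, ids)
        group = pd.Series(["high"] * 3 + ["low"] * 3, index=ids)
        res = logrank_test(SurvivalSplit(group=group, split_value=0.0), clin)
        expected = (3 - 1.15) ** 2 / 0.6775
        assert res.chi_square == pytest.approx(expected, rel=1e-12)
        assert res.observed["high"] == 3
        assert res.expected["high"] == pytest.approx(1.15)
        assert res.p == pytest.approx(float(chi2.sf(expected, 1)))
        assert sum(res.observed.values()) == pytest.approx(
            sum(res.expected.values())
        )

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(9)
        n = 60
        times = rng.exponential(100, n)
        events = rng.integers(0, 2, n)
        events[0] = 1  # ensure at least one event
        ids = [f"P{i}" for i in range(n)]
        clin = make_clinical(times, events, ids)
        group = pd.Series(np.where(rng.random(n) < 0.5, "high", "low"), index=ids)
        res = logrank_test(SurvivalSplit(group=group, split_value=0.0), clin)
        ref = ll_logrank(
            times[group.values == "high"], times[group.values == "low"],
            events[group.values == "high"], events[group.values == "low"],
        )
        assert res.chi_square == pytest.approx(ref.test_statistic, rel=1e-8)
        assert res.p == pytest.approx(ref.p_value, rel=1e-8)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(13)
        n = 40
        ids = [f"P{i}" for i in range(n)]
        clin = make_clinical(rng.exponential(50, n), rng.integers(0, 2, n), ids)
        g = np.where(rng.random(n) < 0.5, "high", "low")
        a = logrank_test(SurvivalSplit(pd.Series(g, index=ids), 0.0), clin)
        swapped = np.where(g == "high", "low", "high")
        b = logrank_test(SurvivalSplit(pd.Series(swapped, index=ids), 0.0), clin)
        assert a.chi_square == pytest.approx(b.chi_square)


class TestKM:
    def test_all_censored_is_flat_one(self):
        curve = km_curve(np.array([5.0, 10.0, 15.0]), np.array([0, 0, 0]))
        assert (curve["survival"] == 1.0).all()

    def test_two_patient_closed_form(self):
        curve = km_curve(np.array([1.0, 2.0]), np.array([1, 1]))
        assert list(curve["survival"]) == [1.0, 0.5, 0.0]

    def test_matches_brute_force_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            n = rng.integers(2, 21)
            times = np.round(rng.exponential(10, n), 1) + 0.1  # ties, all > 0
            events = rng.integers(0, 2, n)
            curve = km_curve(times, events).set_index("time")["survival"]
            for t, s in km_oracle(times, events).items():
                assert curve.loc[t] == pytest.approx(s)

    def test_non_increasing(self):
        rng = np.random.default_rng(32)
        times = rng.exponential(10, 50)
        curve = km_curve(times, np.ones(50, dtype=int))
        assert (np.diff(curve["survival"]) <= 1e-12).all()


class TestCox:
    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(42)
        x = rng.normal(size=(200, 3))
        clin = simulate_survival(x, np.array([0.5, -0.3, 0.2]), seed=5)
        feats = pd.DataFrame(x, index=clin.sample_ids, columns=list("abc"))
        feats = standardize(feats)
        beta, converged = fit_cox(feats, clin)
        assert converged
        df = feats.copy()
        df["T"] = clin.df["time_days"].to_numpy()
        df["E"] = clin.df["event"].to_numpy()
        ref = CoxPHFitter().fit(df, "T", "E").params_.to_numpy()
        assert np.abs(beta - ref).max() < 1e-4

    def test_recovers_true_beta(self):
        est = []
        for s in range(10):
            rng = np.random.default_rng(s)
            x = rng.normal(size=(500, 1))
            clin = simulate_survival(x, np.array([0.8]), seed=1000 + s)
            feats = standardize(
                pd.DataFrame({"f": x[:, 0]}, index=clin.sample_ids)
            )
            beta, _ = fit_cox(feats, clin)
            est.append(beta[0])
        # per-seed SE is ~0.06 at n=500: allow ~3 SE, and require the mean
        # of the ten estimates to sit tightly on the truth
        assert all(0.6 <= b <= 1.0 for b in est)
        assert abs(np.mean(est) - 0.8) < 0.06

    def test_null_beta_near_zero(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            x = rng.normal(size=(500, 1))
            clin = simulate_survival(np.zeros((500, 1)), np.array([0.0]),
                                     seed=2000 + s)
            feats = standardize(
                pd.DataFrame({"f": x[:, 0]}, index=clin.sample_ids)
            )
            beta, _ = fit_cox(feats, clin)
            hits += abs(beta[0]) < 0.2
        assert hits >= 9

    def test_duplicated_feature_rejected(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(100, 1))
        clin = simulate_survival(x, np.array([0.5]), seed=3)
        feats = pd.DataFrame(
            {"a": x[:, 0], "b": x[:, 0]}, index=clin.sample_ids
        )
        with pytest.raises(CollinearityError):
            fit_cox(standardize(feats.assign(b=feats["b"] * 1.0)), clin)

    def test_too_few_events_rejected(self):
        clin = make_clinical([10.0] * 12, [1] + [0] * 11)
        feats = pd.DataFrame(
            {"f": np.arange(12.0)}, index=clin.sample_ids
        )
        with pytest.raises(ValidationError):
            fit_cox(standardize(feats), clin)


class TestTripletRisk:
    def test_risk_score_is_linear_predictor(self, cohort_logcpm):
        from cerna_prognost import CeRNATriplet

        logcpm, _db, clin, truth = cohort_logcpm
        l, m, g = truth.planted_triplets[0]
        rm = triplet_risk_analysis(
            CeRNATriplet(l, m, g), logcpm["lncRNA"], logcpm["miRNA"],
            logcpm["mRNA"], clin,
        )
        # risk score = sum_i beta_i * x_i on the standardized features
        patients = rm.risk_scores.index
        feats = pd.DataFrame({
            l: logcpm["lncRNA"].values.loc[l, patients],
            m: logcpm["miRNA"].values.loc[m, patients],
            g: logcpm["mRNA"].values.loc[g, patients],
        })
        feats = standardize(feats)
        expected = feats.to_numpy() @ rm.betas
        assert np.allclose(rm.risk_scores.to_numpy(), expected)
        # a patient sitting exactly at the feature means scores 0
        assert abs(rm.risk_scores.mean()) < 1.0
        assert rm.median_rs == pytest.approx(
            float(rm.risk_scores.median())
        )

    def test_survival_driving_triplet_is_significant(self, cohort_logcpm):
        from cerna_prognost import CeRNATriplet

        logcpm, _db, clin, truth = cohort_logcpm
        l, m, g = truth.planted_triplets[truth.designated_triplet]
        rm = triplet_risk_analysis(
            CeRNATriplet(l, m, g), logcpm["lncRNA"], logcpm["miRNA"],
            logcpm["mRNA"], clin,
        )
        assert rm.logrank_p < 0.05
        groups = rm.split.group
        assert set(groups.unique()) == {"high", "low"}

    def test_too_few_patients_rejected(self, cohort_logcpm):
        from cerna_prognost import CeRNATriplet

        logcpm, _db, clin, truth = cohort_logcpm
        l, m, g = truth.planted_triplets[0]
        small = clin.subset(clin.sample_ids[:10])
        with pytest.raises(ValidationError):
            triplet_risk_analysis(
                CeRNATriplet(l, m, g), logcpm["lncRNA"], logcpm["miRNA"],
                logcpm["mRNA"], small,
            )
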