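import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pubmeth.dmp import (
    DMPError,
    DeltaMatrix,
    ModerationPrior,
    bh_fdr,
    classify_dmps,
    estimate_prior,
    interaction_test,
    moderated_paired_test,
    paired_delta,
    summarize_dmps,
)


def _delta_frame(arr, probes=None):
    arr = np.asarray(arr, dtype=float)
    probes = probes or [f"p{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"i{k}" for k in range(arr.shape[0])], columns=probes)


class TestPairedDelta:
    def test_identical_timepoints_give_zeros(self, small_cohort):
        inds = small_cohort.sheet["individual_id"].unique()
        post_like = pd.DataFrame(
            small_cohort.pre.loc[[f"{i}_pre" for i in inds]].to_numpy(),
            index=[f"{i}_post" for i in inds],
            columns=small_cohort.pre.columns,
        )
        d = paired_delta(small_cohort.pre, post_like, small_cohort.sheet)
        assert np.allclose(d.values.to_numpy(), 0.0)

    def test_planted_effect_recovered_in_column_mean(self, small_cohort):
        t = small_cohort.truth
        d = paired_delta(small_cohort.pre, small_cohort.post, small_cohort.sheet)
        d_f = d.subset("F")
        fem = t[t["effect_class"] == "female_specific"]
        probe = fem.index[0]
        col = d_f.values[probe]
        se = col.std(ddof=1) / np.sqrt(len(col))
        assert abs(col.mean() - fem.loc[probe, "true_delta"]) <= 3 * se + 1e-3

    def test_sample_order_invariance(self, small_cohort):
        d1 = paired_delta(small_cohort.pre, small_cohort.post, small_cohort.sheet)
        shuffled_pre = small_cohort.pre.sample(frac=1, random_state=0)
        shuffled_post = small_cohort.post.sample(frac=1, random_state=1)
        d2 = paired_delta(shuffled_pre, shuffled_post, small_cohort.sheet)
        pd.testing.assert_frame_equal(d1.values, d2.values)

    def test_unpaired_individual_named_in_error(self, small_cohort):
        pre = small_cohort.pre.drop(index="F000_pre")
        with pytest.raises(DMPError, match="F000"):
            paired_delta(pre, small_cohort.post, small_cohort.sheet)

    def test_values_within_bounds(self, small_cohort):
        d = paired_delta(small_cohort.pre, small_cohort.post, small_cohort.sheet)
        v = d.values.to_numpy()
        assert v.min() >= -1.0 and v.max() <= 1.0


class TestEstimatePrior:
    def test_parameter_recovery(self, rng):
        d0_true, s0_true, d = 4.0, 0.01, 10
        n = 10_000
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, n)
        s2 = sigma2 * rng.chisquare(d, n) / d
        prior = estimate_prior(s2, d)
        assert 3.0 <= prior.d0 <= 5.0
        assert 0.008 <= prior.s0_sq <= 0.012

    def test_identical_variances_give_infinite_d0(self):
        prior = estimate_prior(np.full(500, 0.02), d=10)
        assert math.isinf(prior.d0)
        # scale carries the log-chi-square bias correction exp(log(d/2) - digamma(d/2))
        assert prior.s0_sq == pytest.approx(0.02, rel=0.15)

    def test_scale_equivariance(self, rng):
        s2 = rng.chisquare(5, 2000) * 0.01
        p1 = estimate_prior(s2, d=8)
        p2 = estimate_prior(2 * s2, d=8)
        assert p2.d0 == pytest.approx(p1.d0, rel=1e-9)
        assert p2.s0_sq == pytest.approx(2 * p1.s0_sq, rel=1e-9)

    def test_all_zero_variances_raise(self):
        with pytest.raises(DMPError):
            estimate_prior(np.zeros(100), d=5)


class TestModeratedPairedTest:
    def test_d0_zero_reduces_to_classical_t(self, rng):
        x = _delta_frame(rng.normal(0, 0.03, size=(12, 50)))
        res = moderated_paired_test(x, prior=ModerationPrior(d0=0.0, s0_sq=1.0))
        ref = stats.ttest_1samp(x.to_numpy(), 0.0, axis=0)
        assert np.abs(res["p_value"].to_numpy() - ref.pvalue).max() < 1e-12
        assert np.abs(res["t"].to_numpy() - ref.statistic).max() < 1e-12

    def test_d0_infinite_shares_common_variance(self, rng):
        x = _delta_frame(rng.normal(0, 0.03, size=(10, 30)))
        prior = ModerationPrior(d0=math.inf, s0_sq=0.0009)
        res = moderated_paired_test(x, prior=prior)
        assert (res["s2_moderated"] == 0.0009).all()

    def test_type_one_error_calibrated(self, rng):
        # small version of the null calibration run (full one in acceptance)
        hits, total = 0, 0
        for _ in range(50):
            x = _delta_frame(rng.normal(0, 0.03, size=(30, 1000)))
            res = moderated_paired_test(x)
            hits += int((res["p_value"] < 0.05).sum())
            total += len(res)
        assert 0.035 <= hits / total <= 0.065

    def test_power_on_planted_effect(self, rng):
        x = rng.normal(0, 0.03, size=(30, 2000))
        x[:, :100] += 0.05
        res = moderated_paired_test(_delta_frame(x))
        power = res["sig_fdr05"].to_numpy()[:100].mean()
        assert power > 0.9

    def test_effect_estimate_bias_small(self, rng):
        errs = []
        for _ in range(20):
            x = rng.normal(0.05, 0.03, size=(30, 200))
            res = moderated_paired_test(_delta_frame(x))
            errs.append(res["mean_delta"].mean() - 0.05)
        assert abs(np.mean(errs)) < 0.002

    def test_too_few_individuals_raise(self, rng):
        with pytest.raises(DMPError):
            moderated_paired_test(_delta_frame(rng.normal(size=(2, 5))))


class TestInteractionTest:
    def test_null_p_uniform(self, rng):
        f = _delta_frame(rng.normal(0, 0.03, size=(30, 3000)))
        m = _delta_frame(rng.normal(0, 0.03, size=(25, 3000)))
        res = interaction_test(f, m)
        ks = stats.kstest(res["p_value"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_female_only_effect_detected(self, rng):
        f = rng.normal(0, 0.03, size=(30, 2000))
        f[:, :80] += 0.05
        m = rng.normal(0, 0.03, size=(25, 2000))
        res = interaction_test(_delta_frame(f), _delta_frame(m))
        assert res["q_value"].to_numpy()[:80].max() < 0.5
        assert np.median(res["q_value"].to_numpy()[:80]) < 0.05

    def test_sex_swap_flips_sign_keeps_p(self, rng):
        f = _delta_frame(rng.normal(0, 0.03, size=(10, 100)))
        m = _delta_frame(rng.normal(0.02, 0.03, size=(12, 100)))
        res = interaction_test(f, m)
        swapped = interaction_test(m, f)
        assert np.allclose(res["t"].to_numpy(), -swapped["t"].to_numpy())
        assert np.allclose(res["p_value"].to_numpy(), swapped["p_value"].to_numpy())


class TestBhFdr:
    def test_hand_computed_example(self):
        # p = {0.01, 0.02, 0.03, 0.04}, m = 4:
        # q_(i) = min over j>=i of p_(j) * 4 / j = 0.04 for every rank
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        q = bh_fdr(np.ones(5))
        assert (q == 1.0).all()

    def test_matches_statsmodels(self, rng):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.random(500)
        q = bh_fdr(p)
        ref = statsmodels.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, ref)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=40))
    @settings(max_examples=100)
    def test_monotone_in_sorted_p(self, plist):
        p = np.sort(np.array(plist))
        q = bh_fdr(p)
        assert (np.diff(q) >= -1e-12).all()

    def test_flags_nested(self, rng):
        x = _delta_frame(rng.normal(0.02, 0.03, size=(20, 300)))
        res = moderated_paired_test(x)
        assert res.loc[res["sig_fdr05"], "sig_fdr10"].all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(DMPError):
            bh_fdr(np.array([0.5, 1.2]))


class TestClassifyDmps:
    @staticmethod
    def _result(probes, sig):
        sigarr = np.isin(probes, sig)
        return pd.DataFrame(
            {"sig_fdr05": sigarr, "sig_fdr10": sigarr},
            index=pd.Index(probes, name="probe_id"),
        )

    def test_female_only_probe_is_female_specific(self):
        probes = ["a", "b", "c"]
        sets = classify_dmps(
            self._result(probes, ["a"]),
            self._result(probes, []),
            self._result(probes, []),
        )
        assert sets["female_specific"] == ["a"]
        assert sets["male_specific"] == [] and sets["shared"] == []

    def test_empty_everything(self):
        probes = ["a", "b"]
        empty = self._result(probes, [])
        sets = classify_dmps(empty, empty, empty)
        assert all(v == [] for v in sets.values())

    def test_recovery_on_synthetic_truth(self, small_cohort):
        d = paired_delta(small_cohort.pre, small_cohort.post, small_cohort.sheet)
        d_f, d_m = d.subset("F"), d.subset("M")
        res_f = moderated_paired_test(d_f, group="female")
        res_m = moderated_paired_test(d_m, group="male")
        res_c = moderated_paired_test(d, group="combined")
        sets = classify_dmps(res_f, res_m, res_c)
        truth = small_cohort.truth
        big = truth[(truth["true_delta"].abs() >= 0.06) & (truth["effect_class"] != "null")]
        hits = 0
        for probe, row in big.iterrows():
            cls = row["effect_class"]
            if cls == "shared":
                ok = probe in sets["shared"]
            elif cls == "female_specific":
                ok = probe in sets["female_specific"] or probe in sets["overlap_female_male"]
            else:
                ok = probe in sets["male_specific"] or probe in sets["overlap_female_male"]
            hits += int(ok)
        assert hits / len(big) >= 0.9


class TestSummarizeDmps:
    def test_printed_hyper_fraction(self):
        # 155 of 347 probes with positive mean difference -> 44.7%
        n_hyper, n_hypo = 155, 192
        arr = np.concatenate([np.full(n_hyper, 0.03), np.full(n_hypo, -0.03)])
        delta = _delta_frame(np.tile(arr, (5, 1)))
        summary = summarize_dmps(list(delta.columns), delta)
        assert summary["n"] == 347
        assert summary["pct_hyper"] == 44.7
        assert summary["pct_hypo"] == 55.3

    def test_all_positive(self, rng):
        delta = _delta_frame(np.abs(rng.normal(0.05, 0.01, size=(4, 20))))
        summary = summarize_dmps(list(delta.columns), delta)
        assert summary["pct_hyper"] == 100.0

    def test_empty_set(self, rng):
        assert summarize_dmps([], _delta_frame(rng.normal(size=(3, 4))))["n"] == 0

    def test_median_matches_truth(self, small_cohort):
        truth = small_cohort.truth
        fem = truth[truth["effect_class"] == "female_specific"]
        d = paired_delta(small_cohort.pre, small_cohort.post, small_cohort.sheet)
        summary = summarize_dmps(list(fem.index), d.subset("F"))
        assert summary["median_abs_delta"] == pytest.approx(
            fem["true_delta"].abs().median(), abs=0.01
        )

    def test_region_fractions_present(self, small_cohort):
        truth = small_cohort.truth
        fem = list(truth.index[truth["effect_class"] == "female_specific"])
        d = paired_delta(small_cohort.pre, small_cohort.post, small_cohort.sheet)
        summary = summarize_dmps(fem, d.subset("F"), small_cohort.annotation)
        fracs = summary["region_fractions"]
        assert set(fracs) == {"TSS200", "TSS1500", "Body", "Intergenic"}
        assert abs(sum(fracs.values()) - 100.0) < 1.0
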