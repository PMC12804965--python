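"""Counting, per-image d', i1n normalization, lapse, pooled performance."""

from statistics import NormalDist

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import facebench as fb
from facebench.metrics import ImageCounts, clip_rate
from .conftest import make_random_trials

Z = NormalDist().inv_cdf  # stdlib quantile function as the independent oracle


def _trials(rows):
    return pd.DataFrame(
        [
            {
                "subject_id": "s", "pool_id": "p", "image_id": img,
                "true_category": t, "response_category": r, "session": "x",
            }
            for img, t, r in rows
        ]
    )


def _counts(per_image, per_category, n):
    pi = pd.DataFrame(per_image).set_index("image_id")
    pc = pd.DataFrame(per_category).set_index("category")
    return ImageCounts(pi, pc, n)


class TestTabulateCounts:
    def test_direct_counts(self):
        tr = _trials([("i", "A", "A")] * 3 + [("i", "A", "B")])
        c = fb.tabulate_counts(tr)
        assert c.per_image.loc["i", "n_presented"] == 4
        assert c.per_image.loc["i", "n_correct"] == 3

    def test_single_category_table_false_alarm_denominators(self):
        # all images are category A: FA denominator for B is every trial,
        # for A it is zero
        tr = _trials([("i1", "A", "A"), ("i2", "A", "B"), ("i3", "A", "A")])
        c = fb.tabulate_counts(tr)
        assert c.per_category.loc["B", "n_other"] == 3
        assert c.per_category.loc["B", "n_fa"] == 1
        assert c.per_category.loc["A", "n_other"] == 0

    def test_matches_brute_force_recount(self):
        tr = make_random_trials(10_000, 40, seed=5)
        c = fb.tabulate_counts(tr)
        # independent single-pass tally
        pres, corr, fa, other = {}, {}, {"A": 0, "B": 0}, {"A": 0, "B": 0}
        for row in tr.itertuples():
            pres[row.image_id] = pres.get(row.image_id, 0) + 1
            if row.true_category == row.response_category:
                corr[row.image_id] = corr.get(row.image_id, 0) + 1
            for cat in ("A", "B"):
                if row.true_category != cat:
                    other[cat] += 1
                    if row.response_category == cat:
                        fa[cat] += 1
        for img in pres:
            assert c.per_image.loc[img, "n_presented"] == pres[img]
            assert c.per_image.loc[img, "n_correct"] == corr.get(img, 0)
        for cat in ("A", "B"):
            assert c.per_category.loc[cat, "n_other"] == other[cat]
            assert c.per_category.loc[cat, "n_fa"] == fa[cat]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fb.tabulate_counts(_trials([]).reindex(columns=[
                "subject_id", "pool_id", "image_id",
                "true_category", "response_category", "session"]))

    def test_third_category_label_rejected_with_row(self):
        tr = _trials([("i", "A", "A"), ("i", "A", "Q"), ("j", "B", "B")])
        with pytest.raises(ValueError, match="row index 1"):
            fb.tabulate_counts(tr)


class TestDprimePerImage:
    def test_symmetric_rates_give_zero(self):
        c = _counts(
            [{"image_id": "i", "category": "A", "n_presented": 10, "n_correct": 5}],
            [{"category": "A", "n_other": 10, "n_fa": 5},
             {"category": "B", "n_other": 10, "n_fa": 5}],
            20,
        )
        i1 = fb.dprime_per_image(c)
        assert i1.dprime.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_unit_z_rates_give_dprime_two(self):
        # HR = 0.841345, FA = 0.158655: both quantiles are +/-1
        c = _counts(
            [{"image_id": "i", "category": "A",
              "n_presented": 1_000_000, "n_correct": 841_345}],
            [{"category": "A", "n_other": 1_000_000, "n_fa": 158_655},
             {"category": "B", "n_other": 1_000_000, "n_fa": 158_655}],
            2_000_000,
        )
        assert fb.dprime_per_image(c).dprime.iloc[0] == pytest.approx(2.000, abs=1e-3)

    def test_perfect_hit_rate_clipped_to_half_count(self):
        c = _counts(
            [{"image_id": "i", "category": "A", "n_presented": 20, "n_correct": 20}],
            [{"category": "A", "n_other": 40, "n_fa": 20},
             {"category": "B", "n_other": 20, "n_fa": 10}],
            60,
        )
        # z(1 - 1/40) = z(0.975), FA = 0.5 contributes 0
        assert fb.dprime_per_image(c).dprime.iloc[0] == pytest.approx(
            Z(0.975), abs=1e-9
        )

    def test_zero_false_alarm_denominator_flagged_not_dropped(self):
        tr = _trials([("i1", "A", "A"), ("i2", "A", "B")])
        i1 = fb.dprime_per_image(fb.tabulate_counts(tr))
        assert len(i1) == 2
        assert (~i1.scorable).all() and i1.dprime.isna().all()

    def test_agrees_with_quantile_oracle_on_random_tables(self):
        for seed in range(10):
            tr = make_random_trials(2000, 12, seed=seed)
            c = fb.tabulate_counts(tr)
            i1 = fb.dprime_per_image(c).set_index("image_id")
            fa = {}
            for cat in ("A", "B"):
                n_o = c.per_category.loc[cat, "n_other"]
                r = c.per_category.loc[cat, "n_fa"] / n_o
                r = 1 / (2 * n_o) if r == 0 else (1 - 1 / (2 * n_o) if r == 1 else r)
                fa[cat] = r
            for img, row in c.per_image.iterrows():
                hr = row.n_correct / row.n_presented
                n = row.n_presented
                hr = 1 / (2 * n) if hr == 0 else (1 - 1 / (2 * n) if hr == 1 else hr)
                expect = Z(hr) - Z(fa[row.category])
                assert i1.loc[img, "dprime"] == pytest.approx(expect, abs=1e-9)

    def test_clipping_only_at_exact_extremes(self):
        k = np.array([1, 5, 0, 10])
        n = np.array([10, 10, 10, 10])
        out = clip_rate(k, n)
        np.testing.assert_allclose(out, [0.1, 0.5, 0.05, 0.95])


class TestNormalizeI1:
    def test_constant_vector_normalizes_to_zero(self):
        tr = make_random_trials(400, 8, seed=1)
        i1 = fb.dprime_per_image(fb.tabulate_counts(tr))
        i1["dprime"] = 1.7
        out = fb.normalize_i1(i1)
        assert np.allclose(out.i1n, 0.0)

    def test_two_point_means(self):
        i1 = pd.DataFrame(
            {
                "image_id": list("wxyz"),
                "category": ["A", "A", "B", "B"],
                "dprime": [1.0, 3.0, 0.0, 2.0],
                "scorable": True,
            }
        )
        out = fb.normalize_i1(i1)
        assert list(out.i1n) == [-1.0, 1.0, -1.0, 1.0]

    def test_per_category_means_vanish(self):
        tr = make_random_trials(5000, 30, seed=2)
        out = fb.i1_from_trials(tr)
        assert out.groupby("category")["i1n"].mean().abs().max() < 1e-12

    @given(st.floats(-3, 3), st.integers(0, 2**31 - 1))
    def test_invariant_to_per_category_constant_shift(self, shift, seed):
        tr = make_random_trials(1500, 10, seed=seed % 1000)
        i1 = fb.dprime_per_image(fb.tabulate_counts(tr))
        base = fb.normalize_i1(i1)
        shifted = i1.copy()
        shifted.loc[shifted.category == "A", "dprime"] += shift
        assert np.allclose(fb.normalize_i1(shifted).i1n, base.i1n, atol=1e-12)

    def test_category_without_scorable_images_rejected(self):
        i1 = pd.DataFrame(
            {
                "image_id": ["w", "x"],
                "category": ["A", "B"],
                "dprime": [1.0, np.nan],
                "scorable": [True, False],
            }
        )
        with pytest.raises(ValueError, match="B"):
            fb.normalize_i1(i1)


class TestLapse:
    def test_perfect_observer_has_zero_lapse(self, stim_small):
        obs = fb.ObserverModel("p", pd.Series(1.0, index=stim_small.image_ids))
        tr = fb.simulate_trials(obs, stim_small, trials_per_image=30, seed=0)
        est = fb.estimate_lapse(tr, n_partitions=10, seed=1)
        assert est.lapse == 0.0

    def test_recovers_always_wrong_lapse(self, stim_small):
        ids = stim_small.image_ids
        p = np.concatenate([np.ones(8), np.linspace(0.62, 0.9038, len(ids) - 8)])
        obs = fb.ObserverModel(
            "aw", pd.Series(p, index=ids), lapse=0.02, lapse_guess_correct=0.0
        )
        tr = fb.simulate_trials(obs, stim_small, n_trials=20_000, seed=3)
        est = fb.estimate_lapse(tr, n_partitions=25, seed=4)
        assert est.lapse == pytest.approx(0.02, abs=0.01)

    def test_chance_observer_estimate_nonnegative(self, stim_small):
        obs = fb.ObserverModel("c", pd.Series(0.5, index=stim_small.image_ids))
        tr = fb.simulate_trials(obs, stim_small, trials_per_image=40, seed=5)
        est = fb.estimate_lapse(tr, n_partitions=10, seed=6)
        assert est.lapse >= 0.0  # selection makes it upward-biased, never negative

    def test_requires_repeated_presentations(self):
        tr = _trials([("i1", "A", "A"), ("i2", "B", "B")])
        with pytest.raises(ValueError):
            fb.estimate_lapse(tr, n_partitions=2, seed=0)


class TestLapseCorrection:
    @pytest.mark.parametrize("model", ["always_wrong", "guess"])
    def test_zero_lapse_is_identity(self, model):
        assert fb.lapse_corrected_accuracy(0.7317, 0.0, model) == pytest.approx(0.7317)

    def test_ceiling_case(self):
        assert fb.lapse_corrected_accuracy(0.98, 0.02, "always_wrong") == pytest.approx(1.0)

    def test_guess_model_inverts_its_generative_mixture(self):
        # observed = (1-lam)p + lam/2 with measured floor lam/2
        p, lam = 0.8, 0.04
        obs = (1 - lam) * p + lam / 2
        assert fb.lapse_corrected_accuracy(obs, lam / 2, "guess") == pytest.approx(p)

    @given(st.floats(0, 1), st.floats(0, 0.4))
    def test_result_always_a_proportion(self, p_obs, lam):
        out = fb.lapse_corrected_accuracy(p_obs, lam, "always_wrong")
        assert 0.0 <= out <= 1.0

    def test_degenerate_lapse_rejected(self):
        with pytest.raises(ValueError):
            fb.lapse_corrected_accuracy(0.5, 1.0, "always_wrong")
        with pytest.raises(ValueError):
            fb.lapse_corrected_accuracy(0.5, 0.5, "guess")

    def test_round_trip_with_generator(self, stim_small):
        obs = fb.ObserverModel(
            "g", pd.Series(0.8, index=stim_small.image_ids),
            lapse=0.02, lapse_guess_correct=0.0,
        )
        tr = fb.simulate_trials(obs, stim_small, n_trials=50_000, seed=7)
        p_obs = (tr.true_category == tr.response_category).mean()
        assert fb.lapse_corrected_accuracy(p_obs, 0.02, "always_wrong") == pytest.approx(
            0.80, abs=0.01
        )


class TestPooledPerformance:
    def test_all_correct_table(self):
        tr = _trials([("i", "A", "A")] * 50)
        out = fb.pooled_performance(tr, n_boot=100, seed=0)
        assert out.accuracy == 1.0 and out.boot_sd == 0.0

    def test_bootstrap_sd_matches_binomial_se(self, stim_small):
        obs = fb.ObserverModel("b", pd.Series(0.78, index=stim_small.image_ids))
        tr = fb.simulate_trials(obs, stim_small, n_trials=10_000, seed=8)
        out = fb.pooled_performance(tr, n_boot=1000, seed=9)
        se = np.sqrt(out.accuracy_raw * (1 - out.accuracy_raw) / 10_000)
        assert abs(out.boot_sd - se) < 0.3 * se

    def test_pooling_is_trial_weighted(self):
        rows = [("i", "A", "A")] * 70 + [("i", "A", "B")] * 30
        t1 = _trials(rows).assign(subject_id="s1")
        rows = [("i", "A", "A")] * 90 + [("i", "A", "B")] * 10
        t2 = _trials(rows).assign(subject_id="s2")
        out = fb.pooled_performance(pd.concat([t1, t2]), n_boot=10, seed=0)
        assert out.accuracy == pytest.approx(0.8)

    def test_invalid_n_boot_rejected(self):
        with pytest.raises(ValueError):
            fb.pooled_performance(_trials([("i", "A", "A")]), n_boot=0)


class TestEstimatorConsistency:
    def test_dprime_recovers_latent_vector(self, stim_small):
        # narrow-spread observer, 500 trials/image: the shared-FA estimator
        # tracks the latent d' to within 0.15 mean absolute error
        obs = fb.make_observer(stim_small, mean_dprime=1.5, sd_dprime=0.2, seed=10)
        tr = fb.simulate_trials(obs, stim_small, trials_per_image=500, seed=11)
        i1 = fb.dprime_per_image(fb.tabulate_counts(tr)).set_index("image_id")
        err = (i1.dprime - obs.latent_dprime.loc[i1.index]).abs().mean()
        assert err < 0.15
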