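"""Decoding machinery: windowing, feature layout, cross-validation,
empirical chance, RT matching, second-level inference, group scores."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import errmon as em
from errmon.decoding import DecodingResult, PART_CONTRASTS, stratified_fold_ids
from conftest import make_epochs


FAST = em.DecodingConfig(n_folds=5, n_repetitions=2, n_permutation_runs=5,
                         analysis_window_ms=(0.0, 100.0))


class TestWindows:
    def test_standard_epoch_yields_110_windows(self):
        times = -900.0 + 2.0 * np.arange(551)
        cfg = em.DecodingConfig()
        wins = em.make_windows(times, cfg)
        assert len(wins) == 110
        # half-open sample convention, consecutive and disjoint
        assert wins[0] == (0, 5)
        assert all(b[0] == a[1] for a, b in zip(wins, wins[1:]))
        assert wins[-1] == (545, 550)  # one trailing sample dropped

    def test_toy_axis_ten_windows(self):
        times = 2.0 * np.arange(50)
        cfg = em.DecodingConfig(analysis_window_ms=(0.0, 98.0))
        assert len(em.make_windows(times, cfg)) == 10

    def test_uncovered_analysis_window_rejected(self):
        times = 2.0 * np.arange(50)
        with pytest.raises(ValueError, match="not covered"):
            em.make_windows(times, em.DecodingConfig())


class TestFeatureVectors:
    def test_63_channels_give_315_features(self, rng):
        channels = list(em.synthetic.montage.SCALP_63)
        ep = make_epochs(rng.normal(size=(4, 63, 10)), channels=channels)
        X = em.build_feature_vectors(ep, (0, 5))
        assert X.shape == (4, 315)

    def test_channel_major_layout_by_hand(self):
        data = np.arange(2 * 2 * 6).reshape(2, 2, 6).astype(float)
        ep = make_epochs(data, channels=["FCz", "Cz"])
        X = em.build_feature_vectors(ep, (1, 6))
        np.testing.assert_array_equal(X[0], [1, 2, 3, 4, 5, 7, 8, 9, 10, 11])

    def test_aux_channels_excluded(self, rng):
        ep = make_epochs(rng.normal(size=(3, 4, 8)),
                         channels=["FCz", "Cz", "M1", "vEOG"])
        X = em.build_feature_vectors(ep, (0, 5))
        assert X.shape == (3, 10)

    def test_zero_epoch_zero_vector(self):
        ep = make_epochs(np.zeros((2, 3, 8)), channels=["FCz", "Cz", "Pz"])
        assert not em.build_feature_vectors(ep, (0, 5)).any()


class TestCrossValidation:
    def test_fold_partition_property(self, rng):
        for n, k in [(20, 10), (23, 5), (12, 3)]:
            ids = stratified_fold_ids(rng, n, k)
            assert ids.shape == (2 * n,)
            # every trial in exactly one fold; folds balanced per class
            for cls in (slice(0, n), slice(n, 2 * n)):
                counts = np.bincount(ids[cls], minlength=k)
                assert counts.sum() == n
                assert counts.max() - counts.min() <= 1

    def test_separable_clusters_decoded(self, rng):
        X = rng.normal(size=(60, 30))
        y = np.repeat([0, 1], 30)
        X[y == 1, :8] += 5.0
        assert em.decode_window(X, y, FAST) >= 0.99

    def test_identical_vectors_at_chance(self, rng):
        X = np.tile(rng.normal(size=(1, 20)), (40, 1))
        y = np.repeat([0, 1], 20)
        assert em.decode_window(X, y, FAST) == pytest.approx(0.5, abs=1e-12)

    def test_structureless_noise_near_half(self, rng):
        accs = [em.decode_window(rng.normal(size=(60, 20)),
                                 np.repeat([0, 1], 30),
                                 dataclasses.replace(FAST, seed=s))
                for s in range(8)]
        assert abs(np.mean(accs) - 0.5) < 0.05

    def test_label_swap_invariance(self, rng):
        """Swapping the two class labels leaves accuracy unchanged up to
        cross-validation resampling noise (checked on seed averages)."""
        X = rng.normal(size=(40, 15))
        y = np.repeat([0, 1], 20)
        X[y == 1, :3] += 1.0
        a = np.mean([em.decode_window(X, y, dataclasses.replace(FAST, seed=s))
                     for s in range(10)])
        b = np.mean([em.decode_window(X, 1 - y, dataclasses.replace(FAST, seed=s))
                     for s in range(10)])
        assert a == pytest.approx(b, abs=0.03)

    def test_too_few_trials_raises(self, rng):
        X = rng.normal(size=(7, 5))
        y = np.array([0, 0, 0, 1, 1, 1, 1])
        with pytest.raises(ValueError, match="folds"):
            em.decode_window(X, y, em.DecodingConfig(n_folds=5))


class TestEmpiricalChance:
    def test_balanced_labels_near_half(self, rng):
        X = rng.normal(size=(60, 20))
        X[:30, :5] += 3.0   # structure unrelated to labels after shuffling
        y = np.repeat([0, 1], 30)
        assert em.empirical_chance(X, y, FAST) == pytest.approx(0.5, abs=0.06)

    def test_separable_data_still_chance(self, rng):
        X = rng.normal(size=(60, 20))
        y = np.repeat([0, 1], 30)
        X[y == 1] += 4.0
        assert em.empirical_chance(X, y, FAST) == pytest.approx(0.5, abs=0.08)

    def test_run_count_consistency(self, rng):
        X = rng.normal(size=(50, 12))
        y = np.repeat([0, 1], 25)
        few = em.empirical_chance(X, y, dataclasses.replace(FAST, n_permutation_runs=2))
        many = em.empirical_chance(X, y, dataclasses.replace(FAST, n_permutation_runs=30))
        assert few == pytest.approx(many, abs=0.12)


class TestFirstLevel:
    def test_effect_confined_to_post_response_windows(self):
        """With only a post-response component injected, above-chance
        decoding of error vs correct appears only at post-response
        windows (zero background noise makes this sharp)."""
        lay = em.ExperimentLayout(
            blocks=[em.BlockSpec("no_self_eval", 60)],
            scalp_channels=em.synthetic._spread_subset(6),
            epoch_span_ms=(-200.0, 300.0))
        truth = em.GroundTruth.null(
            seed=2, noise_sd=1.0, error_rate=0.5,
            ne_amp_by_celltype={"error": -8.0, "correct": -1.0})
        ep, tab = em.generate_experiment(truth, lay)
        cfg = em.DecodingConfig(analysis_window_ms=(-200.0, 290.0), n_folds=5,
                                n_repetitions=1, n_permutation_runs=2, seed=0)
        r = em.first_level(ep, tab, em.Contrast("accuracy", "error", "correct"), cfg)
        pre = r.window_start_ms < -10
        post = (r.window_start_ms >= 10) & (r.window_start_ms <= 130)
        assert np.all(np.abs(r.accuracy[pre] - r.chance[pre]) < 0.25)
        assert np.mean(r.accuracy[post] - r.chance[post]) > 0.3

    def test_small_class_skipped_with_warning(self):
        lay = em.ExperimentLayout(
            blocks=[em.BlockSpec("no_self_eval", 30)],
            scalp_channels=["FCz", "Cz", "Pz"], epoch_span_ms=(0.0, 100.0))
        truth = em.GroundTruth.null(seed=0, error_rate=0.02)
        ep, tab = em.generate_experiment(truth, lay)
        cfg = em.DecodingConfig(analysis_window_ms=(0.0, 90.0), n_folds=10)
        with pytest.warns(UserWarning, match="skipped"):
            assert em.first_level(ep, tab,
                                  em.Contrast("accuracy", "error", "correct"),
                                  cfg) is None


class TestRtMatch:
    def test_identical_distributions_fully_retained(self):
        rts = np.r_[np.linspace(500, 900, 40), np.linspace(500, 900, 40)]
        tab = pd.DataFrame({"rt": rts})
        a = np.r_[np.ones(40, bool), np.zeros(40, bool)]
        ma, mb = em.rt_match(tab, a, ~a)
        assert ma.sum() == mb.sum() == 40

    def test_disjoint_ranges_empty(self):
        tab = pd.DataFrame({"rt": np.r_[np.full(10, 300.0), np.full(10, 900.0)]})
        a = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        ma, mb = em.rt_match(tab, a, ~a)
        assert ma.sum() == 0 and mb.sum() == 0

    def test_planted_shift_removed(self, rng):
        base = rng.normal(700, 80, size=500)
        tab = pd.DataFrame({"rt": np.r_[base, base + 30.0]})
        a = np.r_[np.ones(500, bool), np.zeros(500, bool)]
        ma, mb = em.rt_match(tab, a, ~a, seed=1)
        diff = tab["rt"][mb].mean() - tab["rt"][ma].mean()
        assert ma.sum() > 400
        assert abs(diff) < 5.0


class TestSecondLevel:
    def _result(self, pid, acc, cha):
        w = 10.0 * np.arange(len(acc)) - 900.0
        return DecodingResult(pid, "c", w, np.asarray(acc, float),
                              np.asarray(cha, float), (20, 20))

    def test_accuracy_equal_chance_empty_mask(self, rng):
        res = [self._result(f"P{i}", 0.5 + rng.normal(0, 1e-3, 50),
                            0.5 + rng.normal(0, 1e-3, 50)) for i in range(10)]
        sec = em.second_level(res)
        assert not sec["significant"].any()

    def test_constructed_band_exactly_recovered(self, rng):
        res = []
        for i in range(12):
            acc = np.full(50, 0.5) + rng.normal(0, 1e-4, 50)
            cha = np.full(50, 0.5) + rng.normal(0, 1e-4, 50)
            acc[30:40] += 0.10
            res.append(self._result(f"P{i}", acc, cha))
        sec = em.second_level(res)
        assert set(np.flatnonzero(sec["significant"])) == set(range(30, 40))

    def test_single_extreme_participant_stays_null(self, rng):
        res = [self._result(f"P{i}", 0.5 + rng.normal(0, 0.02, 40),
                            0.5 + rng.normal(0, 0.02, 40)) for i in range(9)]
        res.append(self._result("P9", np.full(40, 0.95), np.full(40, 0.5)))
        sec = em.second_level(res)
        assert not sec["significant"].any()

    def test_needs_two_participants(self):
        with pytest.raises(ValueError):
            em.second_level([self._result("P0", np.full(5, 0.6), np.full(5, 0.5))])


class TestGroupScores:
    def _results(self, score_by_group, pid="P01"):
        out = {}
        for (a, b) in PART_CONTRASTS:
            g = f"{a}v{b}"
            acc = 0.5 + score_by_group.get(g, 0.0) / 100.0 + np.zeros(20)
            out[g] = DecodingResult(pid, g, 10.0 * np.arange(20), acc,
                                    np.full(20, 0.5), (30, 30))
        return out

    def test_equal_accuracy_gives_zero(self):
        scores = em.decoding_group_scores({"P01": self._results({})})
        assert np.allclose(scores["score"], 0.0)

    def test_ten_point_offset(self):
        scores = em.decoding_group_scores(
            {"P01": self._results({"1.1v2.2": 10.0})})
        got = scores.set_index("group")["score"]
        assert got["1.1v2.2"] == pytest.approx(10.0)
        assert got["1.1v1.2"] == pytest.approx(0.0)

    def test_missing_contrast_drops_participant(self):
        res = {"P01": self._results({}), "P02": self._results({})}
        del res["P02"]["1.1v2.2"]
        with pytest.warns(UserWarning, match="dropped"):
            scores = em.decoding_group_scores(res)
        assert set(scores["participant"]) == {"P01"}
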