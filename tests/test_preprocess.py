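"""Preprocessing stage contracts: re-reference, baseline, ocular
correction, artifact rejection, and the no-filtering guarantee."""

import numpy as np
import pandas as pd
import pytest

import errmon as em
from conftest import make_epochs


def epochs_with_aux(data_scalp, mastoids=0.0, eog=0.0, times=None):
    """Two scalp channels + M1/M2 + hEOG/vEOG."""
    n_tr, _, n_s = np.shape(data_scalp)
    full = np.zeros((n_tr, 6, n_s))
    full[:, :2] = data_scalp
    full[:, 2:4] = mastoids
    full[:, 4:6] = eog
    return make_epochs(full, times=times,
                       channels=["FCz", "Cz", "M1", "M2", "hEOG", "vEOG"])


class TestRereference:
    def test_zero_mastoids_no_change(self):
        ep = epochs_with_aux(np.full((2, 2, 10), 7.0))
        out = em.rereference_linked_mastoids(ep)
        np.testing.assert_array_equal(out.data[:, :2], ep.data[:, :2])
        assert out.reference == "linked_mastoid"

    def test_constant_mastoids_subtract_mean(self):
        ep = epochs_with_aux(np.full((1, 2, 4), 10.0))
        ep.data[:, 2] = 3.0
        ep.data[:, 3] = 5.0
        out = em.rereference_linked_mastoids(ep)
        np.testing.assert_allclose(out.data[:, :2], 6.0)  # 10 - (3+5)/2
        # EOG untouched
        np.testing.assert_array_equal(out.data[:, 4:], ep.data[:, 4:])

    def test_second_application_is_noop(self):
        ep = epochs_with_aux(np.full((1, 2, 4), 10.0), mastoids=2.0)
        out = em.rereference_linked_mastoids(ep)
        with pytest.warns(UserWarning, match="no-op"):
            again = em.rereference_linked_mastoids(out)
        np.testing.assert_array_equal(again.data, out.data)

    def test_missing_mastoid_rejected(self):
        ep = make_epochs(np.zeros((1, 2, 4)), channels=["FCz", "Cz"])
        with pytest.raises(ValueError, match="mastoid"):
            em.rereference_linked_mastoids(ep)


class TestBaseline:
    def test_constant_epoch_becomes_zero(self):
        ep = make_epochs(np.full((3, 2, 50), 7.0), times=-20 + 2.0 * np.arange(50))
        out = em.baseline_correct(ep, (-20.0, 0.0))
        np.testing.assert_allclose(out.data, 0.0)
        assert out.baseline_interval == (-20.0, 0.0)

    def test_step_epoch(self):
        times = -100 + 2.0 * np.arange(100)
        data = np.where(times >= 0, 5.0, 2.0)[None, None, :] * np.ones((1, 2, 1))
        ep = make_epochs(data, times=times)
        out = em.baseline_correct(ep, (-100.0, -2.0))
        assert out.data[0, 0, times >= 0].mean() == pytest.approx(3.0)

    def test_stimulus_locked_per_trial_windows(self):
        """Two trials with different stimulus onsets: each trial's own
        pre-stimulus mean is subtracted (hand-computed)."""
        times = -200 + 2.0 * np.arange(151)  # -200..100
        data = np.zeros((2, 1, 151))
        data[0, 0] = np.where(times <= -100, 4.0, 1.0)   # stim at -100
        data[1, 0] = np.where(times <= -60, -3.0, 2.0)   # stim at -60
        ep = make_epochs(data, times=times, channels=["FCz"], trial_ids=["a", "b"])
        tab = pd.DataFrame({
            "trial_id": ["a", "b"],
            "stimulus_onset_ms": [-100.0, -60.0],
        })
        out = em.baseline_correct(ep, (-40.0, 0.0), lock="stimulus", table=tab)
        assert out.data[0, 0, -1] == pytest.approx(1.0 - 4.0)
        assert out.data[1, 0, -1] == pytest.approx(2.0 - (-3.0))

    def test_out_of_epoch_baseline_drops_trial(self):
        times = -100 + 2.0 * np.arange(101)
        ep = make_epochs(np.ones((2, 1, 101)), times=times, channels=["FCz"],
                         trial_ids=["a", "b"])
        tab = pd.DataFrame({"trial_id": ["a", "b"],
                            "stimulus_onset_ms": [-50.0, -300.0]})
        out = em.baseline_correct(ep, (-40.0, 0.0), lock="stimulus", table=tab)
        assert list(out.trial_ids) == ["a"]

    def test_rerun_is_noop(self):
        ep = make_epochs(np.ones((1, 1, 30)), times=-20 + 2.0 * np.arange(30))
        out = em.baseline_correct(ep, (-20.0, 0.0))
        with pytest.warns(UserWarning, match="no-op"):
            again = em.baseline_correct(out, (-20.0, 0.0))
        np.testing.assert_array_equal(again.data, out.data)


class TestOcularCorrection:
    def test_zero_eog_zero_coefficients(self):
        ep = epochs_with_aux(np.random.default_rng(0).normal(size=(4, 2, 60)))
        with pytest.warns(UserWarning, match="zero-variance"):
            out, coeffs = em.ocular_correct(ep)
        assert all(b == 0.0 for b in coeffs["vEOG"].values())
        np.testing.assert_allclose(out.data, ep.data, atol=1e-10)

    def test_known_propagation_recovered(self, rng):
        n_tr, n_s = 30, 200
        blink = np.zeros((n_tr, n_s))
        for i in range(n_tr):
            c = rng.integers(40, n_s - 40)
            blink[i, c - 30:c + 30] = 120.0 * np.hanning(60)
        noise = rng.normal(0, 2.0, size=(n_tr, 2, n_s))
        data = np.zeros((n_tr, 6, n_s))
        data[:, :2] = noise
        data[:, 0] += 0.2 * blink          # FCz picks up 20% of the blink
        data[:, 5] = blink + rng.normal(0, 0.5, size=(n_tr, n_s))
        data[:, 4] = rng.normal(0, 0.5, size=(n_tr, n_s))
        ep = make_epochs(data, channels=["FCz", "Cz", "M1", "M2", "hEOG", "vEOG"])
        out, coeffs = em.ocular_correct(ep)
        assert coeffs["vEOG"]["FCz"] == pytest.approx(0.2, abs=0.01)
        assert abs(coeffs["vEOG"]["Cz"]) < 0.01
        r = np.corrcoef(out.data[:, 0].ravel(), data[:, 5].ravel())[0, 1]
        assert abs(r) < 0.05

    def test_orthogonal_eeg_untouched(self, rng):
        """EEG exactly orthogonal to the EOG residuals stays unchanged."""
        n_tr, n_s = 10, 64
        t = np.arange(n_s)
        eog = np.sin(2 * np.pi * t / 16)[None, :] * rng.normal(size=(n_tr, 1))
        eeg = np.cos(2 * np.pi * t / 16)[None, :] * rng.normal(size=(n_tr, 1))
        data = np.zeros((n_tr, 6, n_s))
        data[:, 0] = eeg
        data[:, 5] = eog   # hEOG left flat so only the orthogonal vEOG enters
        ep = make_epochs(data, channels=["FCz", "Cz", "M1", "M2", "hEOG", "vEOG"])
        with pytest.warns(UserWarning, match="zero-variance"):
            out, coeffs = em.ocular_correct(ep)
        assert abs(coeffs["vEOG"]["FCz"]) < 1e-6
        np.testing.assert_allclose(out.data[:, 0], ep.data[:, 0], atol=1e-6)


class TestArtifactRejection:
    def test_boundary_at_threshold(self):
        data = np.zeros((2, 1, 10))
        data[0, 0, 3] = 101.0
        data[1, 0, 3] = 99.0
        ep = make_epochs(data, channels=["FCz"], trial_ids=["hot", "ok"])
        out, rejected = em.reject_artifacts(ep, 100.0)
        assert list(rejected) == ["hot"]
        assert list(out.trial_ids) == ["ok"]

    def test_infinite_threshold_keeps_all(self):
        ep = make_epochs(np.random.default_rng(0).normal(size=(5, 1, 10)) * 1e3,
                         channels=["FCz"])
        out, rejected = em.reject_artifacts(ep, np.inf)
        assert len(rejected) == 0 and out.n_trials == 5

    def test_planted_excursion_count(self, rng):
        data = rng.normal(0, 10.0, size=(100, 3, 50))
        np.clip(data, -95, 95, out=data)
        bad = rng.choice(100, 13, replace=False)
        data[bad, 1, 7] = 150.0
        ep = make_epochs(data, channels=["FCz", "Cz", "Pz"])
        out, rejected = em.reject_artifacts(ep, 100.0)
        assert len(rejected) == 13
        assert out.n_trials == 87

    def test_eog_not_consulted(self):
        data = np.zeros((1, 6, 10))
        data[0, 5, 0] = 500.0   # huge blink on vEOG only
        ep = make_epochs(data, channels=["FCz", "Cz", "M1", "M2", "hEOG", "vEOG"])
        out, rejected = em.reject_artifacts(ep, 100.0)
        assert len(rejected) == 0

    def test_all_rejected_raises(self):
        ep = make_epochs(np.full((3, 1, 5), 200.0), channels=["FCz"])
        with pytest.raises(ValueError, match=r"±100"):
            em.reject_artifacts(ep, 100.0)


class TestNoFiltering:
    def test_white_spectrum_preserved(self, rng):
        """With artifacts disabled the chain applies no spectral filter:
        every non-DC Fourier coefficient of a white-noise epoch survives
        re-reference + baseline + ocular correction unchanged."""
        n_s = 128
        data = np.zeros((6, 6, n_s))
        data[:, :2] = rng.normal(size=(6, 2, n_s))
        ep = make_epochs(data, times=-100 + 2.0 * np.arange(n_s),
                         channels=["FCz", "Cz", "M1", "M2", "hEOG", "vEOG"])
        out = em.rereference_linked_mastoids(ep)
        out = em.baseline_correct(out, (-100.0, 0.0))
        with pytest.warns(UserWarning, match="zero-variance"):
            out, _ = em.ocular_correct(out)
        out, _ = em.reject_artifacts(out, 100.0)
        before = np.fft.rfft(ep.data[:, :2], axis=-1)[..., 1:]
        after = np.fft.rfft(out.data[:, :2], axis=-1)[..., 1:]
        np.testing.assert_allclose(after, before, atol=1e-9)


def test_config_validation():
    with pytest.raises(ValueError):
        em.PreprocConfig(reject_uv=-5.0)
    with pytest.raises(ValueError):
        em.PreprocConfig(erp_window_ms=(100.0, -100.0))
    with pytest.raises(ValueError):
        em.PreprocConfig(csd_m=1)
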