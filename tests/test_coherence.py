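"""Wavelet transform, cross-brain coherence and the bin decision rule."""

import numpy as np
import pytest

from dyadflow import coherence as coh
from dyadflow import synthdyad as sd


DT = 0.1
PERIODS = coh.default_periods()


class TestCwt:
    def test_zero_input_zero_coefficients(self):
        c, kept = coh.cwt(np.zeros(1800), PERIODS, DT)
        np.testing.assert_allclose(np.abs(c), 0.0, atol=1e-12)

    def test_sinusoid_peaks_at_matching_period(self):
        t = np.arange(1800) * DT
        x = np.sin(2 * np.pi * t / 12.8)
        c, kept = coh.cwt(x, PERIODS, DT)
        mid = np.abs(c[:, 400:1400]).mean(axis=1)
        best = kept[np.argmax(mid)]
        target = kept[np.argmin(np.abs(kept - 12.8))]
        assert best == pytest.approx(target)

    def test_linearity_in_amplitude(self, rng):
        x = rng.normal(size=1800)
        c1, _ = coh.cwt(x, PERIODS, DT)
        c3, _ = coh.cwt(3 * x, PERIODS, DT)
        np.testing.assert_allclose(c3, 3 * c1, atol=1e-10)

    def test_too_long_periods_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropping"):
            _, kept = coh.cwt(np.random.default_rng(0).normal(size=600),
                              PERIODS, DT)
        assert kept.max() <= 600 * DT / 3


class TestRoiSignal:
    def _session(self, schedule, geometry):
        truth = sd.HemoGroundTruth(noise_sd=0.1, seed=1)
        return sd.generate_hemodynamics(schedule, truth, geometry)

    def test_single_channel_roi_identity(self, schedule, small_geometry):
        sess = self._session(schedule, small_geometry)
        x = coh.roi_signal(sess, "A", "STG")
        np.testing.assert_array_equal(
            x, sess.subjects["A"].hbr[small_geometry.roi_indices("STG")[0]]
        )

    def test_mean_of_identical_channels(self, schedule, small_geometry):
        sess = self._session(schedule, small_geometry)
        idx = small_geometry.roi_indices("AG")
        sess.subjects["A"].hbr[idx[1]] = sess.subjects["A"].hbr[idx[0]]
        x = coh.roi_signal(sess, "A", "AG")
        np.testing.assert_allclose(x, sess.subjects["A"].hbr[idx[0]])

    def test_opposite_channels_cancel(self, schedule, small_geometry):
        sess = self._session(schedule, small_geometry)
        idx = small_geometry.roi_indices("AG")
        sess.subjects["A"].hbr[idx[1]] = -sess.subjects["A"].hbr[idx[0]]
        np.testing.assert_allclose(coh.roi_signal(sess, "A", "AG"), 0.0, atol=1e-12)

    def test_all_dead_roi_rejected(self, schedule, small_geometry):
        sess = self._session(schedule, small_geometry)
        dead = np.zeros(small_geometry.n_channels, bool)
        dead[small_geometry.roi_indices("AG")] = True
        with pytest.raises(ValueError, match="live"):
            coh.roi_signal(sess, "A", "AG", dead_mask=dead)


class TestCrossBrainCoherence:
    def test_identical_signals_give_unit_coherence(self, rng):
        x = rng.normal(size=1800)
        c, kept = coh.cross_brain_coherence(x, x.copy(), PERIODS, DT)
        np.testing.assert_allclose(c, 1.0, atol=1e-8)

    def test_values_bounded(self, rng):
        a, b = rng.normal(size=(2, 1800))
        c, _ = coh.cross_brain_coherence(a, b, PERIODS, DT)
        valid = c[np.isfinite(c)]
        assert np.all(valid >= -1 - 1e-12) and np.all(valid <= 1 + 1e-12)

    def test_subject_order_symmetric(self, rng):
        a, b = rng.normal(size=(2, 1800))
        c1, _ = coh.cross_brain_coherence(a, b, PERIODS, DT)
        c2, _ = coh.cross_brain_coherence(b, a, PERIODS, DT)
        np.testing.assert_allclose(c1, c2, atol=1e-12)

    def test_constant_series_undefined(self):
        c, kept = coh.cross_brain_coherence(
            np.zeros(1800), np.zeros(1800), PERIODS, DT
        )
        assert np.isnan(c).all()

    def test_independent_noise_null_centered(self, rng):
        few = np.array([5.0, 12.8, 25.0])
        vals = []
        for _ in range(100):
            a, b = rng.normal(size=(2, 1200))
            c, _ = coh.cross_brain_coherence(a, b, few, DT)
            vals.append(c)
        mean = np.nanmean(np.array(vals), axis=0)
        assert np.all(np.abs(mean) < 0.1)

    def test_shared_am_oscillation_raises_band_coherence(self, rng):
        t = np.arange(1800) * DT
        env = 1 + 0.6 * np.sin(2 * np.pi * t / 60.0)
        shared = env * np.sin(2 * np.pi * t / 12.8)
        a = shared + 0.4 * rng.normal(size=1800)
        b = shared + 0.4 * rng.normal(size=1800)
        c, kept = coh.cross_brain_coherence(a, b, PERIODS, DT)
        band = np.nanmean(c[(kept >= 10) & (kept < 16)])
        far = np.nanmean(c[kept > 20])
        assert band > far


class TestResolvableBound:
    def test_three_cycles_of_experimental_period(self):
        assert coh.resolvable_period_bound() == 30.0


def _toy_spectra(rng, n_dyads, band_mean, condition, ids=None):
    out = []
    for i in range(n_dyads):
        vals = band_mean + 0.1 * rng.normal(size=PERIODS.size)
        out.append(
            coh.CoherenceSpectrum(
                ids[i] if ids else f"d{i}", condition, ("AG", "SMG"), PERIODS, vals
            )
        )
    return out


class TestCompareConditions:
    def test_identical_sets_not_significant(self, rng):
        a = _toy_spectra(rng, 8, 0.3, "agree")
        b = [coh.CoherenceSpectrum(s.dyad_id, "disagree", s.roi_pair, s.periods,
                                   s.coherence.copy()) for s in a]
        res = coh.compare_conditions(a, b)
        assert not res.decision
        np.testing.assert_allclose(res.t, 0.0, atol=1e-10)

    def test_clear_difference_detected(self, rng):
        a = _toy_spectra(rng, 12, 0.6, "agree")
        b = _toy_spectra(rng, 12, 0.1, "disagree")
        res = coh.compare_conditions(a, b)
        assert res.decision
        assert (res.mean_diff > 0).all()

    def test_consecutive_rule(self):
        assert coh._consecutive_rule(np.array([True, True, False]))
        assert coh._consecutive_rule(np.array([False, True, True]))
        assert not coh._consecutive_rule(np.array([True, False, True]))

    def test_too_few_dyads_rejected(self, rng):
        a = _toy_spectra(rng, 1, 0.3, "agree")
        b = _toy_spectra(rng, 5, 0.3, "disagree")
        with pytest.raises(ValueError, match="dyads"):
            coh.compare_conditions(a, b)


class TestShuffledControl:
    def test_zero_coupling_true_and_shuffled_negative(self):
        sessions = sd.simulate_cohort(n_dyads=6, seed=5, couplings=())
        cohort = coh.CohortCoherence(sessions, rois=["AG", "SMG"])
        sp = cohort.condition_spectra(("AG", "SMG"))
        assert not coh.compare_conditions(sp["agree"], sp["disagree"]).decision
        ctrl = coh.shuffled_control(cohort, [("AG", "SMG")], seed=1)
        assert not ctrl[("AG", "SMG")].decision

    def test_single_dyad_rejected(self):
        sessions = sd.simulate_cohort(n_dyads=1, seed=5, couplings=())
        with pytest.raises(ValueError, match="derangement"):
            coh.shuffled_control(sessions, [("AG", "SMG")], seed=0,
                                 rois=["AG", "SMG"])
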