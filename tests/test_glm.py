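"""HRF, design construction, OLS fitting and FDR correction."""

import numpy as np
import pytest

from dyadflow import glm
from dyadflow import synthdyad as sd


class TestHrf:
    def test_zero_at_onset(self):
        assert glm.hrf(0.0) == pytest.approx(0.0, abs=1e-12)

    def test_peak_between_five_and_seven_seconds(self):
        t = np.arange(0, 30, 0.01)
        h = glm.hrf(t)
        assert 5.0 <= t[np.argmax(h)] <= 7.0
        assert h.max() == pytest.approx(1.0, abs=1e-6)

    def test_late_tail_near_zero(self):
        assert abs(glm.hrf(30.0)) < 0.01

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            glm.HrfParams(peak_dispersion=-1.0)


class TestAseRegressor:
    def test_silent_session_gives_zero(self):
        reg = glm.ase_regressor(np.zeros(1800), 1800, 0.1)
        np.testing.assert_allclose(reg, 0.0)

    def test_linearity(self, rng):
        e = rng.random(1800)
        one = glm.ase_regressor(e, 1800, 0.1)
        np.testing.assert_allclose(glm.ase_regressor(2 * e, 1800, 0.1), 2 * one,
                                   atol=1e-12)

    def test_speech_only_during_one_speaker_matches_boxcar(self, schedule):
        # constant-amplitude speech in subject A's turns: the regressor must be
        # proportional to A's talk-boxcar convolved with the HRF
        n = 1800
        energy = schedule.speaker_boxcar("A", n, 0.1)  # 10 Hz grid == 0.1 s
        reg = glm.ase_regressor(energy, n, 0.1)
        design = glm.make_design(schedule, "A", n, 0.1)
        talk = design.column("talk")
        r = np.corrcoef(reg, talk)[0, 1]
        assert r > 0.999

    def test_grid_mismatch_reports_offset(self, schedule):
        with pytest.raises(ValueError, match="offset"):
            glm.ase_regressor(np.ones(1500), 1800, 0.1)


class TestFitGlm:
    def test_noise_free_recovery_is_exact(self, schedule):
        design = glm.make_design(schedule, "A", 1800, 0.1)
        beta = np.array([2.0, -1.0, 0.0])
        y = design.matrix @ np.append(beta[:2], [beta[2]])  # talk, listen, const
        fit = glm.fit_glm(y, design)
        np.testing.assert_allclose(fit.betas[0], [2.0, -1.0, 0.0], atol=1e-9)
        assert fit.contrast[0] == pytest.approx(3.0, abs=1e-9)

    def test_equal_betas_zero_contrast(self, schedule, rng):
        design = glm.make_design(schedule, "A", 1800, 0.1)
        y = design.matrix @ np.array([1.5, 1.5, 0.2])
        fit = glm.fit_glm(y, design)
        assert fit.contrast[0] == pytest.approx(0.0, abs=1e-9)
        # with noise the contrast stays statistically indistinguishable from 0
        noisy = y + rng.normal(0, 0.2, size=(50, 1800))
        nfit = glm.fit_glm(noisy, design)
        assert abs(nfit.t.mean()) < 3 / np.sqrt(50)
        assert nfit.contrast.mean() == pytest.approx(0.0, abs=0.01)

    def test_residuals_orthogonal_to_design(self, schedule, rng):
        design = glm.make_design(schedule, "A", 1800, 0.1)
        y = rng.normal(size=(5, 1800))
        fit = glm.fit_glm(y, design, keep_residuals=True)
        dots = fit.residuals @ design.matrix
        scale = np.abs(y).max() * np.abs(design.matrix).max() * 1800
        assert np.abs(dots).max() < 1e-8 * scale

    def test_rank_deficiency_names_columns(self, schedule):
        design = glm.make_design(schedule, "A", 1800, 0.1)
        design.matrix[:, 1] = design.matrix[:, 0]
        with pytest.raises(ValueError, match="collinear"):
            glm.fit_glm(np.zeros(1800), design)

    def test_monte_carlo_beta_recovery(self, schedule, rng):
        design = glm.make_design(schedule, "A", 1800, 0.1)
        truth = np.array([1.0, 0.4, 0.0])
        y = design.matrix @ truth + rng.normal(0, 0.5, size=(200, 1800))
        fit = glm.fit_glm(y, design)
        for j in range(3):
            est = fit.betas[:, j]
            sem = est.std(ddof=1) / np.sqrt(len(est))
            assert abs(est.mean() - truth[j]) < 2 * sem + 1e-9


def _bh_oracle(p, q):
    """Exhaustive step-up: largest k with p_(k) <= qk/m, reject below."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p)
    thresh = 0.0
    for k in range(m, 0, -1):
        if p[order[k - 1]] <= q * k / m:
            thresh = p[order[k - 1]]
            break
    return p <= thresh if thresh > 0 else np.zeros(m, bool)


class TestFdr:
    def test_all_ones_rejects_none(self):
        assert not glm.fdr_bh(np.ones(6)).any()

    def test_stepup_example_all_rejected(self):
        mask = glm.fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert mask.all()

    def test_single_test_reduces_to_raw_threshold(self):
        assert glm.fdr_bh(np.array([0.04]), q=0.05).all()
        assert not glm.fdr_bh(np.array([0.06]), q=0.05).any()

    def test_empty_vector(self):
        assert glm.fdr_bh(np.array([])).size == 0

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(300):
            m = rng.integers(1, 13)
            p = rng.random(m)
            q = rng.choice([0.01, 0.05, 0.1])
            np.testing.assert_array_equal(glm.fdr_bh(p, q), _bh_oracle(p, q))


class TestConditionContrast:
    def test_identical_conditions_give_zero_t(self, rng):
        c = rng.normal(size=(10, 8))
        res = glm.condition_contrast(c, c.copy())
        np.testing.assert_allclose(res.t, 0.0, atol=1e-12)
        assert not res.fdr_significant.any()

    def test_label_flip_negates_t(self, rng):
        a = rng.normal(size=(10, 8))
        b = rng.normal(size=(10, 8))
        res1 = glm.condition_contrast(a, b)
        res2 = glm.condition_contrast(b, a)
        np.testing.assert_allclose(res1.t, -res2.t, atol=1e-12)

    def test_unmatched_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="unmatched"):
            glm.condition_contrast(rng.normal(size=(5, 8)), rng.normal(size=(5, 7)))

    def test_recovers_condition_effect(self, schedule, rng):
        # first-level contrasts simulated larger under disagreement at
        # half of the channels: group t positive there
        n_subj, n_ch = 16, 10
        effect = np.zeros(n_ch)
        effect[:5] = 0.8
        agree = rng.normal(0, 0.3, size=(n_subj, n_ch))
        disagree = effect + rng.normal(0, 0.3, size=(n_subj, n_ch))
        res = glm.condition_contrast(disagree, agree)
        assert (res.t[:5] > 2).all()
        assert res.fdr_significant[:5].all()


class TestEndToEndRecovery:
    def test_generator_glm_chain_recovers_betas(self, schedule, small_geometry):
        truth = sd.HemoGroundTruth(beta_talk=1.2, beta_listen=0.3, global_gain=0.0,
                                   noise_sd=0.0, seed=21)
        sess = sd.generate_hemodynamics(schedule, truth, small_geometry)
        design = glm.make_design(schedule, "A", sess.n_samples, 0.1)
        fit = glm.fit_glm(sess.subjects["A"].hbo, design)
        np.testing.assert_allclose(fit.betas[:, 0], 1.2, atol=1e-8)
        np.testing.assert_allclose(fit.betas[:, 1], 0.3, atol=1e-8)
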