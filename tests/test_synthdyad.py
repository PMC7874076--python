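"""Generator tests: schedules, hemodynamics, speech and pseudo-dyads."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadflow import synthdyad as sd
from dyadflow.preprocess import default_geometry


class TestTurnSchedule:
    @pytest.mark.parametrize(
        "run,turn,first,n_turns,speakers",
        [
            (180, 15, "A", 12, None),  # protocol run: six turns per speaker
            (15, 15, "A", 1, ["A"]),
            (60, 20, "B", 3, ["B", "A", "B"]),
        ],
    )
    def test_examples(self, run, turn, first, n_turns, speakers):
        sched = sd.generate_turn_schedule(run, turn, first_speaker=first)
        assert len(sched.turns) == n_turns
        if speakers:
            assert [t.speaker for t in sched.turns] == speakers
        if n_turns == 12:
            assert len(sched.turns_of("A")) == 6
            assert len(sched.turns_of("B")) == 6

    def test_non_multiple_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            sd.generate_turn_schedule(100, 15)

    @given(n=st.integers(1, 40), turn=st.integers(5, 30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_tiling_and_alternation(self, n, turn):
        sched = sd.generate_turn_schedule(n * turn, turn)
        total = sum(t.duration for t in sched.turns)
        assert total == pytest.approx(sched.run_duration)
        speakers = [t.speaker for t in sched.turns]
        assert all(a != b for a, b in zip(speakers, speakers[1:]))
        # each subject speaks for half the turns (within one)
        assert abs(speakers.count("A") - speakers.count("B")) <= 1


class TestHemodynamics:
    def test_noise_free_channel_is_boxcar_convolution(self, schedule, small_geometry):
        truth = sd.HemoGroundTruth(beta_talk=2.0, beta_listen=-1.0, global_gain=0.0,
                                   noise_sd=0.0, seed=3)
        sess = sd.generate_hemodynamics(schedule, truth, small_geometry)
        from dyadflow.glm import convolve_hrf

        n = sess.n_samples
        talk = convolve_hrf(schedule.speaker_boxcar("A", n, 0.1), 0.1)
        listen = convolve_hrf(1 - schedule.speaker_boxcar("A", n, 0.1), 0.1)
        expected = 2.0 * talk - 1.0 * listen
        np.testing.assert_allclose(sess.subjects["A"].hbo[0], expected, atol=1e-12)
        # deOxyHb mirror is negative-going
        np.testing.assert_allclose(sess.subjects["A"].hbr[0], -expected, atol=1e-12)

    def test_total_hemoglobin_is_sum(self, schedule, small_geometry):
        truth = sd.HemoGroundTruth(global_gain=0.4, noise_sd=0.2, seed=5)
        sess = sd.generate_hemodynamics(schedule, truth, small_geometry)
        for rec in sess.subjects.values():
            np.testing.assert_allclose(rec.hbt, rec.hbo + rec.hbr, atol=1e-12)

    def test_determinism(self, schedule, small_geometry):
        truth = sd.HemoGroundTruth(global_gain=0.3, noise_sd=0.3, seed=11)
        a = sd.generate_hemodynamics(schedule, truth, small_geometry)
        b = sd.generate_hemodynamics(schedule, truth, small_geometry)
        np.testing.assert_array_equal(a.subjects["A"].hbo, b.subjects["A"].hbo)
        np.testing.assert_array_equal(a.subjects["B"].hbr, b.subjects["B"].hbr)

    def test_leading_pc_tracks_global_component(self, schedule):
        truth = sd.HemoGroundTruth(beta_talk=0.0, beta_listen=0.0, global_gain=1.0,
                                   noise_sd=0.2, seed=7)
        sess = sd.generate_hemodynamics(schedule, truth, default_geometry())
        X = sess.subjects["A"].hbo
        Xc = X - X.mean(axis=1, keepdims=True)
        _, _, Vt = np.linalg.svd(Xc.T, full_matrices=False)
        pc1 = Xc.T @ Vt[0]
        r = np.corrcoef(pc1, sess.global_component["A"])[0, 1]
        assert abs(r) > 0.9

    def test_unknown_coupling_roi_rejected(self, schedule, small_geometry):
        truth = sd.HemoGroundTruth(
            coupling=(sd.Coupling("AG", "FEF", 12.8, 0.5, "agree"),), seed=0
        )
        with pytest.raises(ValueError, match="FEF"):
            sd.generate_hemodynamics(schedule, truth, small_geometry)


class TestSpeech:
    def test_syllable_count_matches_rate(self, schedule):
        truth = sd.SpeechGroundTruth(syllable_rate=4.0, seed=2)
        audio = sd.generate_turn_audio(schedule.turns[0], truth, sample_rate=8000)
        assert audio.true_syllable_count == 60  # 4/s x 15 s

    def test_zero_range_gives_constant_f0(self, schedule):
        truth = sd.SpeechGroundTruth(f0_median=220.0, f0_range=0.0, seed=2)
        audio = sd.generate_turn_audio(schedule.turns[0], truth, sample_rate=8000)
        np.testing.assert_allclose(audio.true_f0, 220.0)

    def test_male_f0_one_octave_down(self, schedule):
        truth = sd.SpeechGroundTruth(f0_median=220.0, f0_range=0.0, seed=2)
        audio = sd.generate_turn_audio(
            schedule.turns[0], truth, sample_rate=8000, speaker_sex="M"
        )
        np.testing.assert_allclose(audio.true_f0, 110.0)

    def test_excessive_rate_rejected(self, schedule):
        truth = sd.SpeechGroundTruth(syllable_rate=6.0, seed=0)
        with pytest.raises(ValueError, match="syllable rate"):
            sd.generate_turn_audio(schedule.turns[0], truth, sample_rate=8000)

    def test_disagree_parameters_elevated(self):
        ag = sd.CONDITION_SPEECH_DEFAULTS["agree"]
        dg = sd.CONDITION_SPEECH_DEFAULTS["disagree"]
        assert dg.syllable_rate > ag.syllable_rate
        assert dg.f0_median > ag.f0_median
        assert dg.f0_range > ag.f0_range
        assert dg.amplitude > ag.amplitude

    def test_generate_speech_covers_all_turns(self, schedule):
        audio = sd.generate_speech(
            schedule, sd.SpeechGroundTruth(seed=1), sample_rate=8000
        )
        assert sorted(audio) == [t.index for t in schedule.turns]
        assert all(audio[t.index].speaker == t.speaker for t in schedule.turns)


class TestShufflePairs:
    def _cohort(self, n, seed=0):
        return sd.simulate_cohort(n_dyads=n, conditions=("agree",), seed=seed,
                                  run_duration=60, turn_duration=15,
                                  couplings=(), noise_sd=0.1)

    def test_two_dyads_unique_derangement(self):
        sessions = self._cohort(2)
        pseudo = sd.shuffle_pairs(sessions, seed=0)
        pairs = {tuple(p.subjects) for p in pseudo}
        assert pairs == {("d00s1", "d01s2"), ("d01s1", "d00s2")}

    def test_no_true_partners(self):
        sessions = self._cohort(7)
        pseudo = sd.shuffle_pairs(sessions, seed=3)
        for p in pseudo:
            s1, s2 = p.subject_ids
            assert s1[:3] != s2[:3]  # different source dyads

    def test_determinism(self):
        sessions = self._cohort(6)
        a = [p.dyad_id for p in sd.shuffle_pairs(sessions, seed=9)]
        b = [p.dyad_id for p in sd.shuffle_pairs(sessions, seed=9)]
        assert a == b

    def test_single_dyad_rejected(self):
        sessions = self._cohort(1)
        with pytest.raises(ValueError, match="derangement"):
            sd.shuffle_pairs(sessions, seed=0)
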