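"""Synthetic dyadic sessions with known ground truth.

Emulates the structured-debate protocol: two participants across a table,
alternating 15 s speaker/listener turns over 180 s runs (12 turns, six per
speaker), under an "agree" or "disagree" condition.  For every dyad the
generator produces

* paired multi-channel hemodynamic time series (HbO/HbR/HbT) built from
  turn-block responses convolved with a canonical HRF, a single global
  systemic component shared across all channels of one subject, optional
  cross-brain coupled slow oscillations at chosen periods in chosen ROI
  pairs, and Gaussian noise;
* per-turn speech audio: sawtooth-carrier syllable bursts whose syllable
  rate, F0 median/range and amplitude depend on condition (all elevated under
  disagreement), with the true syllable count and F0 recorded;
* the turn schedule and full ground truth, so every downstream stage has a
  defined correct answer.

Everything is driven by explicit seeds: identical seeds give bit-identical
sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .glm import HrfParams, convolve_hrf
from .preprocess import ChannelGeometry, default_geometry

__all__ = [
    "Turn",
    "TurnSchedule",
    "generate_turn_schedule",
    "Coupling",
    "HemoGroundTruth",
    "SpeechGroundTruth",
    "CONDITION_SPEECH_DEFAULTS",
    "SubjectRecording",
    "DyadSession",
    "generate_hemodynamics",
    "TurnAudio",
    "generate_turn_audio",
    "generate_speech",
    "shuffle_pairs",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# Turn schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Turn:
    index: int
    speaker: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class TurnSchedule:
    """Alternating speaker/listener intervals exactly tiling a run."""

    run_duration: float
    turn_duration: float
    turns: tuple[Turn, ...]

    def __post_init__(self) -> None:
        if not self.turns:
            raise ValueError("schedule has no turns")
        prev_end = 0.0
        prev_speaker = None
        for turn in self.turns:
            if abs(turn.start - prev_end) > 1e-9:
                raise ValueError("turns must be contiguous and non-overlapping")
            if turn.speaker == prev_speaker:
                raise ValueError("turns must alternate speakers")
            prev_end = turn.end
            prev_speaker = turn.speaker
        if abs(prev_end - self.run_duration) > 1e-9:
            raise ValueError("turns must tile the full run duration")

    @property
    def subjects(self) -> tuple[str, str]:
        first = self.turns[0].speaker
        second = next(t.speaker for t in self.turns if t.speaker != first)
        return (first, second)

    def turns_of(self, subject: str) -> tuple[Turn, ...]:
        return tuple(t for t in self.turns if t.speaker == subject)

    def speaker_boxcar(self, subject: str, n_samples: int, sampling_interval: float) -> np.ndarray:
        t = np.arange(n_samples) * sampling_interval
        box = np.zeros(n_samples)
        for turn in self.turns_of(subject):
            box[(t >= turn.start) & (t < turn.end)] = 1.0
        return box

    def relabel(self, mapping: dict[str, str]) -> "TurnSchedule":
        return TurnSchedule(
            self.run_duration,
            self.turn_duration,
            tuple(replace(t, speaker=mapping[t.speaker]) for t in self.turns),
        )


def generate_turn_schedule(
    run_duration: float,
    turn_duration: float,
    first_speaker: str = "A",
    second_speaker: str | None = None,
) -> TurnSchedule:
    """Alternating schedule: roles switch every ``turn_duration`` seconds.

    ``run_duration`` must be a positive integer multiple of ``turn_duration``
    (the protocol's 180 s run with 15 s turns yields 12 turns, six per
    speaker).
    """
    if turn_duration <= 0 or run_duration <= 0:
        raise ValueError("durations must be positive")
    if second_speaker is None:
        second_speaker = "A" if first_speaker == "B" else "B"
    if second_speaker == first_speaker:
        raise ValueError("the two speakers must be distinct")
    n = run_duration / turn_duration
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"run duration {run_duration} s is not an integer multiple of the "
            f"turn duration {turn_duration} s"
        )
    n = int(round(n))
    speakers = [first_speaker, second_speaker]
    turns = tuple(
        Turn(i, speakers[i % 2], i * turn_duration, (i + 1) * turn_duration)
        for i in range(n)
    )
    return TurnSchedule(float(run_duration), float(turn_duration), turns)


# ---------------------------------------------------------------------------
# Hemodynamic ground truth and generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Coupling:
    """A cross-brain coupled oscillation: subject 1's ``roi_a`` and subject
    2's ``roi_b`` share one sinusoid of the given period under ``condition``,
    with amplitude ``strength`` (kappa in [0, 1])."""

    roi_a: str
    roi_b: str
    period: float
    strength: float
    condition: str  # "agree" | "disagree"

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("coupling strength must lie in [0, 1]")
        if not 2.5 <= self.period <= 40.0:
            raise ValueError("coupling period must lie in the analyzable 2.5-40 s band")


@dataclass(frozen=True)
class HemoGroundTruth:
    beta_talk: float = 1.0
    beta_listen: float = 0.4
    global_gain: float = 0.0
    coupling: tuple[Coupling, ...] = ()
    noise_sd: float = 0.1
    seed: int = 0
    hbr_ratio: float = 1.0  # |HbR| response relative to HbO, negative-going
    #: depth of the shared slow amplitude modulation of coupled oscillations;
    #: amplitude-only coherence measures detect coupling through this shared
    #: waxing and waning (a constant-amplitude sinusoid carries no envelope
    #: information)
    coupling_am_depth: float = 0.6
    #: spectral exponent of per-channel Gaussian noise (PSD ~ 1/f^alpha);
    #: 1.0 emulates the pink physiological noise of real recordings, 0 is white
    noise_exponent: float = 1.0


@dataclass
class SubjectRecording:
    subject_id: str
    hbo: np.ndarray  # (n_channels, n_samples)
    hbr: np.ndarray
    hbt: np.ndarray

    def chromophore(self, name: str) -> np.ndarray:
        return {"hbo": self.hbo, "hbr": self.hbr, "hbt": self.hbt}[name]


@dataclass
class DyadSession:
    dyad_id: str
    condition: str
    schedule: TurnSchedule
    sampling_interval: float
    geometry: ChannelGeometry
    subjects: dict[str, SubjectRecording]
    ground_truth: HemoGroundTruth | None = None
    global_component: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def subject_ids(self) -> tuple[str, str]:
        return self.schedule.subjects

    @property
    def n_samples(self) -> int:
        first = next(iter(self.subjects.values()))
        return first.hbo.shape[1]


def _smooth_noise(rng: np.random.Generator, n: int, sampling_interval: float,
                  cutoff_hz: float = 0.1) -> np.ndarray:
    """Unit-variance low-pass Gaussian noise (slow systemic fluctuation)."""
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, sampling_interval)
    spec = np.fft.rfft(white) * np.exp(-((freqs / cutoff_hz) ** 2))
    g = np.fft.irfft(spec, n)
    sd = g.std()
    return g / sd if sd > 0 else g


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int],
                sampling_interval: float, exponent: float) -> np.ndarray:
    """Unit-variance Gaussian noise with PSD ~ 1/f**exponent per row."""
    n_ch, n = shape
    white = rng.standard_normal((n_ch, n))
    if exponent == 0:
        return white
    freqs = np.fft.rfftfreq(n, sampling_interval)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(np.fft.rfft(white, axis=1) * shaping, n, axis=1)
    return x / x.std(axis=1, keepdims=True)


def generate_hemodynamics(
    schedule: TurnSchedule,
    truth: HemoGroundTruth,
    geometry: ChannelGeometry | None = None,
    sampling_interval: float = 0.1,
    condition: str = "agree",
    dyad_id: str = "dyad0",
    hrf_params: HrfParams | None = None,
) -> DyadSession:
    """Generate a paired hemodynamic session from explicit ground truth.

    Each HbO channel of subject ``s`` is
    ``beta_talk * (talk_boxcar_s (*) h) + beta_listen * (listen_boxcar_s (*) h)
    + global_gain * g_s(t) + kappa * shared_oscillation`` (coupled ROIs only)
    ``+ noise``;  HbR is the negative-going mirror of the neural response
    (scaled by ``hbr_ratio``) plus its own share of the non-neural terms, and
    HbT = HbO + HbR exactly.
    """
    geometry = geometry or default_geometry()
    for c in truth.coupling:
        for roi in (c.roi_a, c.roi_b):
            if roi not in geometry.rois:
                raise ValueError(f"coupling ROI {roi!r} absent from geometry")
    rng = np.random.default_rng(truth.seed)
    n = int(round(schedule.run_duration / sampling_interval))
    t = np.arange(n) * sampling_interval
    n_ch = geometry.n_channels

    subjects: dict[str, SubjectRecording] = {}
    globals_: dict[str, np.ndarray] = {}
    # One shared oscillation realization per coupling, identical across both
    # subjects: a sinusoid at the coupling period whose amplitude waxes and
    # wanes on a slow shared envelope.
    osc = {}
    for c in truth.coupling:
        phase = rng.uniform(0, 2 * np.pi)
        carrier = np.sin(2 * np.pi * t / c.period + phase)
        env = 1.0 + truth.coupling_am_depth * np.clip(
            _smooth_noise(rng, n, sampling_interval, cutoff_hz=0.03), -1.0, 1.0
        )
        osc[c] = carrier * env

    for pos, sid in enumerate(schedule.subjects):
        talk = convolve_hrf(schedule.speaker_boxcar(sid, n, sampling_interval),
                            sampling_interval, hrf_params)
        listen_box = 1.0 - schedule.speaker_boxcar(sid, n, sampling_interval)
        listen = convolve_hrf(listen_box, sampling_interval, hrf_params)
        neural = truth.beta_talk * talk + truth.beta_listen * listen
        g = _smooth_noise(rng, n, sampling_interval)
        globals_[sid] = g

        hbo = np.tile(neural, (n_ch, 1))
        hbr = np.tile(-truth.hbr_ratio * neural, (n_ch, 1))
        if truth.global_gain:
            hbo += truth.global_gain * g
            hbr += truth.global_gain * g
        for c in truth.coupling:
            if c.condition != condition:
                continue
            roi = c.roi_a if pos == 0 else c.roi_b
            idx = geometry.roi_indices(roi)
            hbo[idx] += c.strength * osc[c]
            hbr[idx] += c.strength * osc[c]
        if truth.noise_sd:
            hbo += truth.noise_sd * _pink_noise(rng, (n_ch, n), sampling_interval,
                                               truth.noise_exponent)
            hbr += truth.noise_sd * _pink_noise(rng, (n_ch, n), sampling_interval,
                                               truth.noise_exponent)
        subjects[sid] = SubjectRecording(sid, hbo=hbo, hbr=hbr, hbt=hbo + hbr)

    return DyadSession(
        dyad_id=dyad_id,
        condition=condition,
        schedule=schedule,
        sampling_interval=sampling_interval,
        geometry=geometry,
        subjects=subjects,
        ground_truth=truth,
        global_component=globals_,
    )


# ---------------------------------------------------------------------------
# Speech ground truth and generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeechGroundTruth:
    """Per-condition prosodic parameters for synthetic turn audio.

    F0 parameters are female-reference values; male speakers produce an
    octave lower (the analysis doubles male F0 back for comparison).
    ``last3_*`` factors model the within-debate decline: the last three turns
    of a speaker are slower and quieter than the first three.
    """

    syllable_rate: float = 3.5  # syllables / s
    f0_median: float = 200.0  # Hz (female reference)
    f0_range: float = 40.0  # Hz
    amplitude: float = 0.10  # linear gain
    last3_rate_factor: float = 0.90
    last3_amplitude_factor: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.syllable_rate, self.f0_median, self.amplitude) <= 0 or self.f0_range < 0:
            raise ValueError("rates, frequencies and amplitude must be positive")


#: Condition-specific defaults: every prosodic parameter elevated under
#: disagreement (faster, higher, wider, louder).
CONDITION_SPEECH_DEFAULTS: dict[str, SpeechGroundTruth] = {
    "agree": SpeechGroundTruth(syllable_rate=3.5, f0_median=200.0, f0_range=40.0,
                               amplitude=0.10),
    "disagree": SpeechGroundTruth(syllable_rate=4.0, f0_median=214.0, f0_range=54.0,
                                  amplitude=0.13),
}

_SYLLABLE_ENV_S = 0.120  # raised-cosine syllable envelope length
_MIN_DIP_S = 0.060  # minimum inter-syllable silence


@dataclass
class TurnAudio:
    turn_index: int
    speaker: str
    samples: np.ndarray
    sample_rate: int
    true_syllable_count: int
    true_f0: np.ndarray  # per-syllable F0 actually synthesized (Hz)
    duration: float


def generate_turn_audio(
    turn: Turn,
    truth: SpeechGroundTruth,
    sample_rate: int = 44100,
    rng: np.random.Generator | None = None,
    speaker_sex: str = "F",
    rate_factor: float = 1.0,
    amplitude_factor: float = 1.0,
) -> TurnAudio:
    """Synthesize one speaker turn as a train of voiced syllable bursts.

    Each syllable is a sawtooth carrier at a fixed per-syllable F0 (drawn
    uniformly over ``f0_median +- f0_range/2``), amplitude-modulated by a
    120 ms raised-cosine envelope; bursts are separated by at least 60 ms of
    silence so an RMS-based syllable counter has a defined correct answer.
    """
    if sample_rate < 8000:
        raise ValueError("sample_rate must be at least 8000 Hz")
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    dur = turn.duration
    rate = truth.syllable_rate * rate_factor
    count = int(round(rate * dur))
    interval = dur / count if count else dur
    if _SYLLABLE_ENV_S > dur:
        raise ValueError("syllable duration exceeds turn duration")
    if count and interval < _SYLLABLE_ENV_S + _MIN_DIP_S:
        raise ValueError(
            f"syllable rate {rate:g}/s leaves less than "
            f"{_MIN_DIP_S * 1000:.0f} ms between {_SYLLABLE_ENV_S * 1000:.0f} ms bursts"
        )
    n = int(round(dur * sample_rate))
    samples = np.zeros(n)
    env_n = int(_SYLLABLE_ENV_S * sample_rate)
    env = 0.5 * (1 - np.cos(2 * np.pi * np.arange(env_n) / (env_n - 1)))
    sex_factor = 0.5 if speaker_sex.upper().startswith("M") else 1.0
    f0s = truth.f0_median + truth.f0_range * (rng.random(count) - 0.5)
    amp = truth.amplitude * amplitude_factor
    tt = np.arange(env_n) / sample_rate
    for i in range(count):
        onset = i * interval + (interval - _SYLLABLE_ENV_S) / 2
        start = int(round(onset * sample_rate))
        f0 = f0s[i] * sex_factor
        # sawtooth carrier: 2*frac(f0*t) - 1
        carrier = 2 * np.mod(f0 * tt, 1.0) - 1.0
        seg = amp * env * carrier
        end = min(start + env_n, n)
        samples[start:end] += seg[: end - start]
    return TurnAudio(
        turn_index=turn.index,
        speaker=turn.speaker,
        samples=samples,
        sample_rate=sample_rate,
        true_syllable_count=count,
        true_f0=f0s * sex_factor,
        duration=dur,
    )


def generate_speech(
    schedule: TurnSchedule,
    truth: dict[str, SpeechGroundTruth] | SpeechGroundTruth,
    sample_rate: int = 44100,
    speaker_sex: dict[str, str] | None = None,
    seed: int | None = None,
    fatigue: bool = True,
) -> dict[int, TurnAudio]:
    """Per-turn audio for every speaker turn of a debate.

    ``truth`` may be one ground truth for both speakers or a per-subject
    mapping.  Non-turn intervals are silent by construction (audio exists per
    turn only).  With ``fatigue`` the last three turns of each speaker use the
    ``last3_*`` factors.
    """
    speaker_sex = speaker_sex or {}
    first = truth if isinstance(truth, SpeechGroundTruth) else next(iter(truth.values()))
    rng = np.random.default_rng(first.seed if seed is None else seed)
    out: dict[int, TurnAudio] = {}
    by_speaker: dict[str, list[Turn]] = {}
    for t in schedule.turns:
        by_speaker.setdefault(t.speaker, []).append(t)
    for t in schedule.turns:
        gt = truth if isinstance(truth, SpeechGroundTruth) else truth[t.speaker]
        own = by_speaker[t.speaker]
        is_last3 = fatigue and len(own) >= 6 and own.index(t) >= len(own) - 3
        out[t.index] = generate_turn_audio(
            t,
            gt,
            sample_rate=sample_rate,
            rng=rng,
            speaker_sex=speaker_sex.get(t.speaker, "F"),
            rate_factor=gt.last3_rate_factor if is_last3 else 1.0,
            amplitude_factor=gt.last3_amplitude_factor if is_last3 else 1.0,
        )
    return out


# ---------------------------------------------------------------------------
# Shuffled (pseudo) dyads
# ---------------------------------------------------------------------------

def shuffle_pairs(sessions: list[DyadSession], seed: int = 0) -> list[DyadSession]:
    """Re-pair subjects across dyads of the same condition (pseudo-dyads).

    Within each condition, subject 1 of each dyad is paired with subject 2 of
    a *different* dyad via a uniformly drawn cyclic derangement (Sattolo's
    algorithm), so no pseudo-pair contains true partners.  Seed-reproducible.
    """
    rng = np.random.default_rng(seed)
    by_condition: dict[str, list[DyadSession]] = {}
    for s in sessions:
        by_condition.setdefault(s.condition, []).append(s)
    out: list[DyadSession] = []
    for condition in sorted(by_condition):
        group = by_condition[condition]
        m = len(group)
        if m < 2:
            raise ValueError(
                f"condition {condition!r} has only {m} dyad(s); no derangement exists"
            )
        perm = np.arange(m)
        for i in range(m - 1, 0, -1):  # Sattolo: cyclic, hence fixed-point free
            j = int(rng.integers(0, i))
            perm[i], perm[j] = perm[j], perm[i]
        for i, donor in enumerate(group):
            partner_session = group[perm[i]]
            s1_id = donor.subject_ids[0]
            s2_id = partner_session.subject_ids[1]
            donor_s2 = donor.subject_ids[1]
            schedule = donor.schedule.relabel({s1_id: s1_id, donor_s2: s2_id})
            subjects = {
                s1_id: donor.subjects[s1_id],
                s2_id: partner_session.subjects[s2_id],
            }
            out.append(
                DyadSession(
                    dyad_id=f"pseudo:{donor.dyad_id}+{partner_session.dyad_id}",
                    condition=condition,
                    schedule=schedule,
                    sampling_interval=donor.sampling_interval,
                    geometry=donor.geometry,
                    subjects=subjects,
                    ground_truth=None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Default cross-brain couplings: the angular-supramarginal and
#: occipitotemporal-superior-temporal pairs oscillate together at 12.8 s,
#: strongly under agreement and weakly under disagreement.
DEFAULT_COUPLINGS: tuple[Coupling, ...] = (
    Coupling("AG", "SMG", 12.8, 0.7, "agree"),
    Coupling("OTC", "STG", 12.8, 0.6, "agree"),
    Coupling("AG", "SMG", 12.8, 0.15, "disagree"),
    Coupling("OTC", "STG", 12.8, 0.15, "disagree"),
)


def simulate_cohort(
    n_dyads: int = 19,
    conditions: tuple[str, ...] = ("agree", "disagree"),
    seed: int = 0,
    sampling_interval: float = 0.1,
    run_duration: float = 180.0,
    turn_duration: float = 15.0,
    geometry: ChannelGeometry | None = None,
    couplings: tuple[Coupling, ...] = DEFAULT_COUPLINGS,
    beta_talk: dict[str, float] | None = None,
    beta_listen: float = 0.4,
    global_gain: float = 0.3,
    noise_sd: float = 0.3,
) -> list[DyadSession]:
    """One hemodynamic session per dyad and condition, study-scale defaults
    (19 dyads, 180 s runs of 15 s turns, coupling stronger under agreement,
    talking response larger under disagreement)."""
    geometry = geometry or default_geometry()
    beta_talk = beta_talk or {"agree": 1.0, "disagree": 1.3}
    sessions = []
    root = np.random.default_rng(seed)
    for d in range(n_dyads):
        s1, s2 = f"d{d:02d}s1", f"d{d:02d}s2"
        schedule = generate_turn_schedule(run_duration, turn_duration, s1, s2)
        for condition in conditions:
            truth = HemoGroundTruth(
                beta_talk=beta_talk[condition],
                beta_listen=beta_listen,
                global_gain=global_gain,
                coupling=couplings,
                noise_sd=noise_sd,
                seed=int(root.integers(0, 2**31 - 1)),
            )
            sessions.append(
                generate_hemodynamics(
                    schedule,
                    truth,
                    geometry,
                    sampling_interval,
                    condition=condition,
                    dyad_id=f"d{d:02d}",
                )
            )
    return sessions
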