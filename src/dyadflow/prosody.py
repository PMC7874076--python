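"""Turn-level acoustic features and keyword scoring.

Four measures are computed for every speaker turn:

* SYLR -- syllable rate: RMS-envelope syllable-nucleus count (Mermelstein-style
  peak picking with a dip threshold) divided by turn duration;
* MF0  -- median fundamental frequency over the turn, with male speakers'
  values doubled so sexes are comparable;
* RF0  -- F0 range after Tukey-fence outlier removal (values outside
  Q1 - 1.5 IQR .. Q3 + 1.5 IQR discarded);
* ASE  -- area under the speech envelope (50 ms RMS of x100-decimated audio)
  normalized by turn duration; also emitted at 10 Hz as the GLM co-regressor.

Transcript keyword scoring counts agreement cues ("yes", "I agree",
"absolutely", ...) versus disagreement cues ("no", "I disagree", "but", ...)
per debate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "Envelope",
    "speech_envelope",
    "ase",
    "ase_series_10hz",
    "F0Track",
    "estimate_f0",
    "mf0",
    "rf0",
    "count_syllables",
    "sylr",
    "AGREE_CUES",
    "DISAGREE_CUES",
    "KeywordScore",
    "keyword_score",
    "turn_measures",
]


# ---------------------------------------------------------------------------
# Speech envelope and acoustic energy
# ---------------------------------------------------------------------------

@dataclass
class Envelope:
    """Smoothed RMS amplitude envelope on a decimated grid."""

    values: np.ndarray
    rate: float  # Hz of the decimated grid
    turn_id: int | None = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.rate


def speech_envelope(
    audio: np.ndarray,
    sample_rate: float,
    window: float = 0.05,
    decimation: int = 100,
    turn_id: int | None = None,
) -> Envelope:
    """50 ms sliding RMS amplitude on a x100-decimated grid.

    The RMS is computed on the full-band waveform and the resulting envelope
    is decimated, rather than decimating the audio first: a decimator's
    anti-alias filter would cut into the voice band itself (the fundamental
    sits near or above the decimated Nyquist), making the energy measure
    depend on speaker F0 instead of loudness.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.size == 0:
        raise ValueError("empty turn audio")
    win = max(1, int(round(window * sample_rate)))
    kernel = np.ones(win) / win
    ms = np.convolve(audio**2, kernel, mode="same")
    rms = np.sqrt(ms[::decimation])
    return Envelope(values=rms, rate=sample_rate / decimation, turn_id=turn_id)


def ase(envelope: Envelope, turn_duration: float) -> float:
    """Area under the speech envelope normalized by turn duration
    (acoustic-energy rate; a constant envelope of value c gives ASE = c)."""
    if turn_duration <= 0:
        raise ValueError("turn duration must be positive")
    area = np.trapezoid(envelope.values, dx=1.0 / envelope.rate)
    return float(area / turn_duration)


def ase_series_10hz(envelope: Envelope) -> np.ndarray:
    """Mean envelope over consecutive 100 ms windows (the 10 Hz co-regressor
    samples for this turn)."""
    per = int(round(envelope.rate / 10.0))
    if per < 1:
        raise ValueError("envelope grid coarser than 10 Hz")
    n = len(envelope.values) // per
    return envelope.values[: n * per].reshape(n, per).mean(axis=1)


# ---------------------------------------------------------------------------
# Fundamental frequency
# ---------------------------------------------------------------------------

@dataclass
class F0Track:
    """Per-frame F0 with voicing decisions."""

    times: np.ndarray
    f0: np.ndarray  # Hz; meaningful only where voiced
    voiced: np.ndarray  # bool
    speaker_sex: str = "F"

    @property
    def voiced_f0(self) -> np.ndarray:
        return self.f0[self.voiced]


def estimate_f0(
    audio: np.ndarray,
    sample_rate: float,
    fmin: float = 75.0,
    fmax: float = 500.0,
    frame: float = 0.04,
    hop: float = 0.01,
    voicing_threshold: float = 0.45,
    speaker_sex: str = "F",
) -> F0Track:
    """Autocorrelation pitch tracker: 40 ms frames every 10 ms.

    A frame is voiced when the normalized autocorrelation peak in the
    ``fmin``-``fmax`` lag range exceeds the voicing threshold and the frame
    has non-negligible energy.  Peak lag is refined by parabolic
    interpolation.
    """
    if sample_rate < 2 * fmax:
        raise ValueError("sample rate must be at least twice the F0 search maximum")
    audio = np.asarray(audio, dtype=float)
    fn = int(round(frame * sample_rate))
    hn = int(round(hop * sample_rate))
    if len(audio) < fn:
        return F0Track(np.empty(0), np.empty(0), np.empty(0, bool), speaker_sex)
    starts = np.arange(0, len(audio) - fn + 1, hn)
    frames = np.lib.stride_tricks.sliding_window_view(audio, fn)[starts]
    frames = frames - frames.mean(axis=1, keepdims=True)
    # autocorrelation via FFT, batched over frames
    nfft = int(2 ** np.ceil(np.log2(2 * fn)))
    spec = np.fft.rfft(frames, nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, :fn]
    lag_min = int(np.floor(sample_rate / fmax))
    lag_max = min(int(np.ceil(sample_rate / fmin)), fn - 2)
    energy = ac[:, 0]
    rms = np.sqrt(np.maximum(energy, 0) / fn)
    silence = rms < max(1e-6, 0.02 * (rms.max() if rms.size else 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(energy[:, None] > 0, ac / np.maximum(energy[:, None], 1e-30), 0.0)
    band = norm[:, lag_min : lag_max + 1]
    peak_rel = np.argmax(band, axis=1)
    peak = peak_rel + lag_min
    peak_val = band[np.arange(len(band)), peak_rel]
    # parabolic refinement around the integer peak lag
    li = np.clip(peak, 1, fn - 2)
    y0 = norm[np.arange(len(norm)), li - 1]
    y1 = norm[np.arange(len(norm)), li]
    y2 = norm[np.arange(len(norm)), li + 1]
    denom = y0 - 2 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    shift = np.clip(shift, -0.5, 0.5)
    lag = li + shift
    f0 = sample_rate / lag
    voiced = (peak_val > voicing_threshold) & ~silence & (f0 >= fmin) & (f0 <= fmax)
    times = starts / sample_rate + frame / 2
    return F0Track(times=times, f0=f0, voiced=voiced, speaker_sex=speaker_sex)


def _sex_scaled(track: F0Track) -> np.ndarray:
    vals = track.voiced_f0
    if track.speaker_sex.upper().startswith("M"):
        vals = vals * 2.0
    return vals


def mf0(track: F0Track) -> float:
    """Median F0 over voiced frames (Hz); male values doubled."""
    vals = _sex_scaled(track)
    if vals.size == 0:
        return float("nan")
    return float(np.median(vals))


def rf0(track: F0Track) -> float:
    """F0 range (max - min, Hz) after discarding Tukey-fence outliers
    (outside Q1 - 1.5 IQR .. Q3 + 1.5 IQR); sex doubling applied first."""
    vals = _sex_scaled(track)
    if vals.size < 2:
        return 0.0
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    keep = vals[(vals >= q1 - 1.5 * iqr) & (vals <= q3 + 1.5 * iqr)]
    if keep.size < 2:
        return 0.0
    return float(keep.max() - keep.min())


# ---------------------------------------------------------------------------
# Syllables
# ---------------------------------------------------------------------------

def count_syllables(
    envelope: Envelope,
    dip_db: float = 2.0,
    min_spacing: float = 0.100,
    floor_db: float = -60.0,
) -> int:
    """RMS-based syllable nucleus count.

    Local envelope peaks (in dB) count as syllable nuclei when they stand at
    least ``dip_db`` above the intervening minima (peak prominence) and are
    separated by ``min_spacing`` seconds; near-silent peaks below ``floor_db``
    relative to the envelope maximum are ignored.
    """
    env = envelope.values
    if env.size == 0 or env.max() <= 0:
        return 0
    db = 20 * np.log10(np.maximum(env, env.max() * 10 ** (floor_db / 20)))
    distance = max(1, int(round(min_spacing * envelope.rate)))
    peaks, _ = sps.find_peaks(
        db, prominence=dip_db, distance=distance, height=db.max() - abs(floor_db) / 2
    )
    return int(len(peaks))


def sylr(count: int, duration: float) -> float:
    """Syllables per second."""
    if duration <= 0:
        raise ValueError("turn duration must be positive")
    return count / duration


# ---------------------------------------------------------------------------
# Keyword scoring
# ---------------------------------------------------------------------------

AGREE_CUES: tuple[str, ...] = (
    "yes", "i agree", "absolutely", "that's true", "sounds great",
    "exactly", "definitely", "good point", "me too",
)
DISAGREE_CUES: tuple[str, ...] = (
    "no", "i disagree", "you are wrong", "but", "that does not answer the question",
    "however", "not really", "i don't think so",
)


@dataclass
class KeywordScore:
    debate_id: str
    agree_count: int
    disagree_count: int

    @property
    def agree_fraction(self) -> float:
        total = self.agree_count + self.disagree_count
        return self.agree_count / total if total else float("nan")


def keyword_score(
    transcript: str,
    debate_id: str = "",
    agree_cues: tuple[str, ...] = AGREE_CUES,
    disagree_cues: tuple[str, ...] = DISAGREE_CUES,
) -> KeywordScore:
    """Case-insensitive phrase counts of agreement vs. disagreement cues."""
    if not agree_cues or not disagree_cues:
        raise ValueError("cue lexicons must be non-empty")
    text = transcript.lower()

    def count(cues: tuple[str, ...]) -> int:
        total = 0
        for cue in cues:
            pattern = r"\b" + re.escape(cue.lower()) + r"\b"
            total += len(re.findall(pattern, text))
        return total

    return KeywordScore(debate_id, count(agree_cues), count(disagree_cues))


# ---------------------------------------------------------------------------
# Turn-measure table
# ---------------------------------------------------------------------------

def _turn_bin(position: int, n_turns_of_speaker: int) -> str:
    if position < 3:
        return "FIRST3"
    if position >= n_turns_of_speaker - 3:
        return "LAST3"
    return "MID"


def turn_measures(
    turn_audio: dict[int, "object"],
    schedule,
    condition: str,
    dyad_id: str = "",
    debate_id: str = "",
    speaker_sex: dict[str, str] | None = None,
    sample_rate: float | None = None,
) -> pd.DataFrame:
    """SYLR/MF0/RF0/ASE for every speaker turn of one debate.

    ``turn_audio`` maps turn index to an object with ``samples``,
    ``sample_rate``, ``speaker`` and ``duration`` attributes (e.g.
    :class:`dyadflow.synthdyad.TurnAudio`), or to a bare sample array when
    ``sample_rate`` is given.
    """
    speaker_sex = speaker_sex or {}
    positions: dict[str, int] = {}
    counts: dict[str, int] = {}
    for t in schedule.turns:
        counts[t.speaker] = counts.get(t.speaker, 0) + 1
    rows = []
    for t in schedule.turns:
        audio = turn_audio.get(t.index)
        if audio is None:
            continue
        if hasattr(audio, "samples"):
            samples = audio.samples
            sr = audio.sample_rate
        else:
            samples = np.asarray(audio)
            if sample_rate is None:
                raise ValueError("sample_rate required for bare arrays")
            sr = sample_rate
        pos = positions.get(t.speaker, 0)
        positions[t.speaker] = pos + 1
        sex = speaker_sex.get(t.speaker, "F")
        env = speech_envelope(samples, sr, turn_id=t.index)
        track = estimate_f0(samples, sr, speaker_sex=sex)
        n_syll = count_syllables(env)
        rows.append(
            {
                "dyad": dyad_id,
                "debate": debate_id,
                "speaker": t.speaker,
                "turn": t.index,
                "bin": _turn_bin(pos, counts[t.speaker]),
                "condition": condition,
                "SYLR": sylr(n_syll, t.duration),
                "MF0": mf0(track),
                "RF0": rf0(track),
                "ASE": ase(env, t.duration),
            }
        )
    return pd.DataFrame(rows)
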