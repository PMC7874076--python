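"""Cross-brain wavelet coherence between ROI signals of paired subjects.

Each subject's channels are averaged within 15 anatomical regions of
interest; each ROI series is decomposed with a continuous wavelet transform
(complex-Gaussian kernel) over periods of 2.5-40 s (0.4-0.025 Hz).  Only the
coefficient amplitude is used: cross-brain coherence at a period is the
Pearson correlation over time of the two partners' amplitude envelopes,
excluding a cone of influence of sqrt(2) x period at each end of the record.

A wavelet needs three cycles, and the shortest behaviorally meaningful cycle
is the 30 s turn pair (15 s talking + 15 s listening), so condition
comparisons are restricted to periods of 10-20 s, split into three equal
bins; a condition difference counts as significant only when at least two
consecutive bins pass.  A shuffled-pair (pseudo-dyad) control re-runs the
identical pipeline on non-partners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import stats

from .glm import make_design
from .preprocess import remove_global_median, remove_global_pca, wavelet_detrend
from .synthdyad import DyadSession, shuffle_pairs

__all__ = [
    "default_periods",
    "resolvable_period_bound",
    "cwt",
    "coi_mask",
    "roi_signal",
    "residualize_task",
    "cross_brain_coherence",
    "CoherenceSpectrum",
    "dyad_coherence",
    "CohortCoherence",
    "BinComparison",
    "compare_conditions",
    "shuffled_control",
]

WAVELET = "cgau2"  # complex Gaussian (Mexican-hat-shaped) kernel

#: scale-to-period conversion factor for 'cgau2': the frequency at which the
#: amplitude response of the discretized kernel peaks, located numerically by
#: scanning scales against known sinusoids (pywt's central_frequency reports
#: the coarser FFT-bin peak, 0.4, which misaligns the period grid by ~10%)
_CGAU2_AMP_CENTER_FREQ = 0.4443
MIN_CYCLES = 3
PERIOD_BAND = (2.5, 40.0)  # seconds <-> 0.4-0.025 Hz
COMPARISON_BINS = ((10.0, 10 + 10 / 3), (10 + 10 / 3, 10 + 20 / 3), (10 + 20 / 3, 20.0))


def default_periods(n: int = 32) -> np.ndarray:
    """Log-spaced period grid spanning the analyzed 2.5-40 s band."""
    return np.geomspace(PERIOD_BAND[0], PERIOD_BAND[1], n)


def resolvable_period_bound(min_cycle: float = 10.0, n_cycles: int = MIN_CYCLES) -> float:
    """Coarsest resolvable period: a wavelet needs ``n_cycles`` cycles and the
    experimental cycle (talk + listen) sets the 10 s minimum, giving 30 s."""
    return n_cycles * min_cycle


def cwt(
    ts: np.ndarray,
    periods: np.ndarray,
    sampling_interval: float,
    wavelet: str = WAVELET,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous wavelet transform at the requested periods.

    Periods too long for the record (fewer than ``MIN_CYCLES`` cycles) are
    dropped with a warning.

    Returns
    -------
    (coefficients, kept_periods) -- complex array (n_periods, n_samples).
    """
    ts = np.asarray(ts, dtype=float)
    periods = np.asarray(periods, dtype=float)
    n = ts.shape[-1]
    max_period = n * sampling_interval / MIN_CYCLES
    keep = periods <= max_period
    if not keep.all():
        warnings.warn(
            f"dropping {np.sum(~keep)} period(s) longer than {max_period:.1f} s "
            f"({MIN_CYCLES} cycles do not fit the record)",
            stacklevel=2,
        )
    periods = periods[keep]
    if periods.size == 0:
        raise ValueError("no requested period fits the record")
    if wavelet == WAVELET:
        fc = _CGAU2_AMP_CENTER_FREQ
    else:
        fc = pywt.central_frequency(wavelet)
    scales = fc * periods / sampling_interval
    coeffs, _ = pywt.cwt(ts, scales, wavelet, sampling_period=sampling_interval)
    return coeffs, periods


def coi_mask(n_samples: int, period: float, sampling_interval: float,
             factor: float = np.sqrt(2.0)) -> np.ndarray:
    """Boolean mask of samples *outside* the cone of influence (True = valid);
    ``factor * period`` is excluded at each end."""
    k = int(np.ceil(factor * period / sampling_interval))
    mask = np.ones(n_samples, dtype=bool)
    k = min(k, n_samples // 2)
    mask[:k] = False
    mask[n_samples - k:] = False
    return mask


def roi_signal(
    session: DyadSession,
    subject: str,
    roi: str,
    chromophore: str = "hbr",
    dead_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mean time series over the live channels of one ROI."""
    idx = session.geometry.roi_indices(roi)
    if dead_mask is not None:
        idx = idx[~dead_mask[idx]]
    if idx.size == 0:
        raise ValueError(f"ROI {roi!r}: no live channels")
    data = session.subjects[subject].chromophore(chromophore)
    return data[idx].mean(axis=0)


def residualize_task(
    x: np.ndarray, schedule, subject: str, sampling_interval: float
) -> np.ndarray:
    """Regress the HRF-convolved talk/listen design out of a series.

    The coherence analysis targets coupling beyond the shared block design, so
    the task-evoked component is removed first (the residual signal is what is
    decomposed), as in psychophysiological-interaction analyses.  Accepts a
    1-D series or a (n_channels, n_samples) matrix.
    """
    x = np.asarray(x, dtype=float)
    design = make_design(schedule, subject, x.shape[-1], sampling_interval)
    X = design.matrix
    beta, *_ = np.linalg.lstsq(X, np.atleast_2d(x).T, rcond=None)
    resid = np.atleast_2d(x) - (X @ beta).T
    return resid[0] if x.ndim == 1 else resid


@dataclass
class CoherenceSpectrum:
    """Per-period cross-brain coherence for one dyad, condition and ROI pair."""

    dyad_id: str
    condition: str
    roi_pair: tuple[str, str]
    periods: np.ndarray
    coherence: np.ndarray  # Pearson r per period, NaN where undefined

    def band_mean(self, lo: float, hi: float) -> float:
        sel = (self.periods >= lo) & (self.periods < hi)
        vals = self.coherence[sel]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else np.nan


def _amplitude_coherence(
    amp_a: np.ndarray, amp_b: np.ndarray, periods: np.ndarray, sampling_interval: float
) -> np.ndarray:
    n = amp_a.shape[-1]
    out = np.full(len(periods), np.nan)
    for i, period in enumerate(periods):
        valid = coi_mask(n, period, sampling_interval)
        a = amp_a[i, valid]
        b = amp_b[i, valid]
        if a.std() == 0 or b.std() == 0:
            continue
        out[i] = np.corrcoef(a, b)[0, 1]
    return out


def cross_brain_coherence(
    a: np.ndarray,
    b: np.ndarray,
    periods: np.ndarray,
    sampling_interval: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Coherence between two same-grid series: per period, the correlation of
    wavelet-amplitude envelopes outside the cone of influence.

    Returns (coherence, kept_periods); undefined (zero-variance) periods are
    NaN.
    """
    if a.shape != b.shape:
        raise ValueError("series must share length and grid")
    ca, kept = cwt(a, periods, sampling_interval)
    cb, _ = cwt(b, periods, sampling_interval)
    return _amplitude_coherence(np.abs(ca), np.abs(cb), kept, sampling_interval), kept


def dyad_coherence(
    session: DyadSession,
    roi_pair: tuple[str, str],
    periods: np.ndarray | None = None,
    chromophore: str = "hbr",
    preprocess: bool = False,
) -> CoherenceSpectrum:
    """Coherence spectrum for one dyad and ROI pair, symmetrized over subject
    order (mean of roi_a<->roi_b in both orientations for cross-ROI pairs)."""
    periods = default_periods() if periods is None else np.asarray(periods, float)
    s1, s2 = session.subject_ids
    dt = session.sampling_interval

    def prep(subject: str, roi: str) -> np.ndarray:
        x = roi_signal(session, subject, roi, chromophore)
        if preprocess:
            # task removal first: detrending distorts the block-periodic task
            # component enough that OLS could no longer cancel it exactly
            x = residualize_task(x, session.schedule, subject, dt)
            x = wavelet_detrend(x, dt)
        return x

    ra, rb = roi_pair
    coh1, kept = cross_brain_coherence(prep(s1, ra), prep(s2, rb), periods, dt)
    if ra == rb:
        coh = coh1
    else:
        coh2, _ = cross_brain_coherence(prep(s1, rb), prep(s2, ra), periods, dt)
        coh = np.nanmean(np.vstack([coh1, coh2]), axis=0)
    return CoherenceSpectrum(session.dyad_id, session.condition, roi_pair, kept, coh)


class CohortCoherence:
    """Coherence over a cohort with cached per-subject wavelet amplitudes.

    Computing the CWT once per (session, subject, ROI) makes whole-cohort
    screens and repeated shuffled-pair controls cheap: re-pairing subjects
    only re-correlates cached amplitude envelopes.
    """

    def __init__(
        self,
        sessions: list[DyadSession],
        rois: list[str] | None = None,
        periods: np.ndarray | None = None,
        chromophore: str = "hbr",
        detrend: bool = True,
        remove_task: bool = True,
        remove_global: str | None = "median",
    ) -> None:
        """``remove_global``: ``"median"`` (robust nuisance regression,
        default), ``"pca"`` (leading-component spatial filter) or ``None``."""
        self.sessions = sessions
        self.periods = default_periods() if periods is None else np.asarray(periods, float)
        self.chromophore = chromophore
        first = sessions[0]
        self.sampling_interval = first.sampling_interval
        self.rois = list(rois) if rois is not None else list(first.geometry.rois)
        self._amps: dict[tuple[str, str, str], np.ndarray] = {}
        self._kept: np.ndarray | None = None
        for s in sessions:
            for pos, sid in enumerate(s.subject_ids):
                data = s.subjects[sid].chromophore(chromophore)
                # order matters: the block design is removed per channel first
                # (the DWT detrend would distort it enough to defeat exact OLS
                # removal), then the shared global component
                if remove_task:
                    data = residualize_task(data, s.schedule, sid, self.sampling_interval)
                if remove_global == "median":
                    data, _ = remove_global_median(data)
                elif remove_global == "pca":
                    data, _ = remove_global_pca(data)
                elif remove_global:
                    raise ValueError(f"unknown global-removal mode {remove_global!r}")
                for roi in self.rois:
                    idx = s.geometry.roi_indices(roi)
                    x = data[idx].mean(axis=0)
                    if detrend:
                        x = wavelet_detrend(x, self.sampling_interval)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        coeffs, kept = cwt(x, self.periods, self.sampling_interval)
                    self._kept = kept
                    self._amps[(s.condition, f"{s.dyad_id}:{pos}", roi)] = np.abs(coeffs)
        self.kept_periods: np.ndarray = self._kept if self._kept is not None else self.periods

    def pair_spectrum(
        self, condition: str, dyad_id: str, roi_pair: tuple[str, str],
        partner_dyad_id: str | None = None,
    ) -> CoherenceSpectrum:
        """Spectrum for one (possibly pseudo) dyad: subject 1 of ``dyad_id``
        against subject 2 of ``partner_dyad_id`` (defaults to the true
        partner)."""
        partner = partner_dyad_id or dyad_id
        ra, rb = roi_pair
        dt = self.sampling_interval
        a1 = self._amps[(condition, f"{dyad_id}:0", ra)]
        b2 = self._amps[(condition, f"{partner}:1", rb)]
        coh = _amplitude_coherence(a1, b2, self.kept_periods, dt)
        if ra != rb:
            a2 = self._amps[(condition, f"{dyad_id}:0", rb)]
            b1 = self._amps[(condition, f"{partner}:1", ra)]
            coh = np.nanmean(
                np.vstack([coh, _amplitude_coherence(a2, b1, self.kept_periods, dt)]),
                axis=0,
            )
        label = dyad_id if partner == dyad_id else f"pseudo:{dyad_id}+{partner}"
        return CoherenceSpectrum(label, condition, roi_pair, self.kept_periods, coh)

    def condition_spectra(
        self, roi_pair: tuple[str, str], pairing: dict[str, str] | None = None
    ) -> dict[str, list[CoherenceSpectrum]]:
        """Spectra per condition for every dyad (optionally re-paired)."""
        out: dict[str, list[CoherenceSpectrum]] = {}
        dyads: dict[str, list[str]] = {}
        for s in self.sessions:
            dyads.setdefault(s.condition, [])
            if s.dyad_id not in dyads[s.condition]:
                dyads[s.condition].append(s.dyad_id)
        for condition, ids in dyads.items():
            out[condition] = [
                self.pair_spectrum(
                    condition, d, roi_pair, (pairing or {}).get((condition, d))
                )
                for d in ids
            ]
        return out


@dataclass
class BinComparison:
    """Condition comparison over the three 10-20 s period bins."""

    roi_pair: tuple[str, str]
    bins: tuple[tuple[float, float], ...]
    mean_diff: np.ndarray  # agree - disagree per bin
    t: np.ndarray
    p: np.ndarray
    significant_bins: np.ndarray  # bool per bin
    decision: bool  # >= 2 consecutive significant bins
    paired: bool
    n: tuple[int, int]


def _consecutive_rule(flags: np.ndarray, run: int = 2) -> bool:
    count = 0
    for f in flags:
        count = count + 1 if f else 0
        if count >= run:
            return True
    return False


def compare_conditions(
    agree: list[CoherenceSpectrum],
    disagree: list[CoherenceSpectrum],
    alpha: float = 0.05,
    paired: bool | None = None,
    bins: tuple[tuple[float, float], ...] = COMPARISON_BINS,
) -> BinComparison:
    """Per-bin t-tests of mean coherence (agree vs. disagree across dyads);
    overall decision requires at least two consecutive significant bins.

    Dyads experiencing both conditions are compared with a paired test
    (matched by dyad id) when possible.
    """
    if len(agree) < 2 or len(disagree) < 2:
        raise ValueError("need at least 2 dyads per condition")
    roi_pair = agree[0].roi_pair
    a_vals = np.array([[s.band_mean(lo, hi) for lo, hi in bins] for s in agree])
    d_vals = np.array([[s.band_mean(lo, hi) for lo, hi in bins] for s in disagree])
    if paired is None:
        a_ids = [s.dyad_id for s in agree]
        d_ids = [s.dyad_id for s in disagree]
        paired = len(a_ids) == len(d_ids) and set(a_ids) == set(d_ids)
    if paired:
        order = {s.dyad_id: i for i, s in enumerate(disagree)}
        d_vals = d_vals[[order[s.dyad_id] for s in agree]]
        res = stats.ttest_rel(a_vals, d_vals, axis=0, nan_policy="omit")
    else:
        # Welch: condition variances need not match (e.g. coupling present in
        # one condition only inflates its coherence spread)
        res = stats.ttest_ind(a_vals, d_vals, axis=0, nan_policy="omit",
                              equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # zero-variance differences (e.g. literally identical spectra): no evidence
    degenerate = ~np.isfinite(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    sig = p < alpha
    return BinComparison(
        roi_pair=roi_pair,
        bins=bins,
        mean_diff=np.nanmean(a_vals, axis=0) - np.nanmean(d_vals, axis=0),
        t=t,
        p=p,
        significant_bins=sig,
        decision=_consecutive_rule(sig),
        paired=bool(paired),
        n=(len(agree), len(disagree)),
    )


def shuffled_control(
    sessions: list[DyadSession] | CohortCoherence,
    roi_pairs: list[tuple[str, str]],
    seed: int = 0,
    alpha: float = 0.05,
    **cohort_kwargs,
) -> dict[tuple[str, str], BinComparison]:
    """Run the identical condition comparison on pseudo-dyads (non-partners
    re-paired within condition).

    Accepts either raw sessions or a pre-built :class:`CohortCoherence` (whose
    cached amplitudes make repeated shuffles cheap).
    """
    if isinstance(sessions, CohortCoherence):
        cohort = sessions
        raw = cohort.sessions
    else:
        cohort = CohortCoherence(sessions, **cohort_kwargs)
        raw = sessions
    pseudo = shuffle_pairs(raw, seed=seed)
    pairing: dict[tuple[str, str], str] = {}
    for ps in pseudo:
        donor, partner = ps.dyad_id.removeprefix("pseudo:").split("+")
        pairing[(ps.condition, donor)] = partner
    out = {}
    for rp in roi_pairs:
        spectra = cohort.condition_spectra(rp, pairing=pairing)
        out[rp] = compare_conditions(
            spectra["agree"], spectra["disagree"], alpha=alpha, paired=False
        )
    return out
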