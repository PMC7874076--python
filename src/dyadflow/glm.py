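"""Channel-level general linear model of talking vs. listening.

Each channel's time series is modeled as a linear combination of the talk and
listen boxcars convolved with a canonical double-gamma hemodynamic response
function (HRF), an acoustic-energy co-regressor (area under the speech
envelope, sampled at 10 Hz and likewise HRF-convolved), and a constant.  The
contrast of interest is [talk - listen]; channel-wise p values are corrected
with the Benjamini-Hochberg false discovery rate procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "HrfParams",
    "hrf",
    "hrf_kernel",
    "convolve_hrf",
    "DesignMatrix",
    "make_design",
    "ase_regressor",
    "GlmFit",
    "fit_glm",
    "fdr_bh",
    "condition_contrast",
]


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma HRF parameters (seconds), canonical defaults: response
    peaking near 6 s with an undershoot near 16 s at one sixth amplitude."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length: float = 32.0

    def __post_init__(self) -> None:
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("dispersions must be positive")
        if self.length <= 0:
            raise ValueError("kernel length must be positive")


def hrf(t: np.ndarray | float, params: HrfParams | None = None) -> np.ndarray:
    """Evaluate the double-gamma HRF at times ``t`` (s), unit peak.

    ``hrf(0) == 0`` and the kernel decays to (near) zero by ~30 s.
    """
    params = params or HrfParams()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    peak = stats.gamma.pdf(
        t, params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion
    )
    under = stats.gamma.pdf(
        t,
        params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    h = peak - params.undershoot_ratio * under
    # normalize to unit peak on a fine reference grid
    ref = np.arange(0, params.length, 0.01)
    refp = stats.gamma.pdf(
        ref, params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion
    ) - params.undershoot_ratio * stats.gamma.pdf(
        ref,
        params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    return h / refp.max()


def hrf_kernel(sampling_interval: float, params: HrfParams | None = None) -> np.ndarray:
    """HRF sampled on a grid of spacing ``sampling_interval`` up to ``length``."""
    params = params or HrfParams()
    t = np.arange(0, params.length, sampling_interval)
    return hrf(t, params)


def convolve_hrf(
    x: np.ndarray, sampling_interval: float, params: HrfParams | None = None
) -> np.ndarray:
    """Causal convolution with the HRF, scaled by dt so the result is
    invariant to the sampling grid (a sustained unit boxcar plateaus at the
    kernel integral)."""
    k = hrf_kernel(sampling_interval, params)
    return np.convolve(x, k)[: len(x)] * sampling_interval


_convolve_hrf = convolve_hrf


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_samples, n_columns)
    names: list[str]
    sampling_interval: float
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("column count does not match names")
        zero = [n for n, col in zip(self.names, self.matrix.T) if not np.any(col)]
        if zero:
            raise ValueError(f"all-zero design columns: {zero}")

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


def make_design(
    schedule,
    subject,
    n_samples: int,
    sampling_interval: float,
    ase: np.ndarray | None = None,
    hrf_params: HrfParams | None = None,
    condition: str | None = None,
) -> DesignMatrix:
    """Build the first-level design: talk/listen boxcars (from the turn
    schedule, convolved with the HRF), optional ASE co-regressor, constant."""
    t = np.arange(n_samples) * sampling_interval
    talk = np.zeros(n_samples)
    listen = np.zeros(n_samples)
    for turn in schedule.turns:
        sel = (t >= turn.start) & (t < turn.end)
        if turn.speaker == subject:
            talk[sel] = 1.0
        else:
            listen[sel] = 1.0
    cols = [
        _convolve_hrf(talk, sampling_interval, hrf_params),
        _convolve_hrf(listen, sampling_interval, hrf_params),
    ]
    names = ["talk", "listen"]
    if ase is not None:
        ase = np.asarray(ase, dtype=float)
        if len(ase) != n_samples:
            raise ValueError(
                f"ASE regressor length {len(ase)} does not match session grid {n_samples}"
            )
        cols.append(ase)
        names.append("ase")
    cols.append(np.ones(n_samples))
    names.append("const")
    return DesignMatrix(np.column_stack(cols), names, sampling_interval, condition)


def ase_regressor(
    energy_10hz: np.ndarray,
    n_samples: int,
    sampling_interval: float,
    hrf_params: HrfParams | None = None,
) -> np.ndarray:
    """HRF-convolved acoustic-energy co-regressor on the session grid.

    ``energy_10hz`` is the 100 ms-window speech energy series for the whole
    run (both speakers' turns concatenated in run time) at 10 Hz.  It is
    convolved with the HRF at 10 Hz and resampled to the session grid.
    """
    energy_10hz = np.asarray(energy_10hz, dtype=float)
    dt10 = 0.1
    run_duration = n_samples * sampling_interval
    expected = int(round(run_duration / dt10))
    if abs(len(energy_10hz) - expected) > 1:
        raise ValueError(
            f"10 Hz energy series has {len(energy_10hz)} samples; session of "
            f"{run_duration:g} s expects ~{expected} (offset "
            f"{(len(energy_10hz) - expected) * dt10:+.1f} s)"
        )
    conv = _convolve_hrf(energy_10hz, dt10, hrf_params)
    t10 = np.arange(len(conv)) * dt10
    t = np.arange(n_samples) * sampling_interval
    return np.interp(t, t10, conv)


@dataclass
class GlmFit:
    """Per-channel OLS results for one subject/session."""

    names: list[str]
    betas: np.ndarray  # (n_channels, n_columns)
    contrast: np.ndarray  # (n_channels,)
    t: np.ndarray
    p: np.ndarray
    df: int
    resid_var: np.ndarray
    fdr_significant: np.ndarray | None = None
    residuals: np.ndarray | None = None


def fit_glm(
    data: np.ndarray,
    design: DesignMatrix,
    contrast: dict[str, float] | None = None,
    keep_residuals: bool = False,
) -> GlmFit:
    """Ordinary least squares fit of each channel against the design.

    Parameters
    ----------
    data : ndarray, (n_channels, n_samples) or (n_samples,)
    contrast : mapping column name -> weight; default ``{"talk": 1, "listen": -1}``.
    """
    X = design.matrix
    Y = np.atleast_2d(np.asarray(data, dtype=float))
    if Y.shape[1] != X.shape[0]:
        raise ValueError("data length does not match design")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by checking rank drop when removed
        collinear = [
            design.names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"design is rank deficient; collinear columns: {collinear}")
    contrast = contrast or {"talk": 1.0, "listen": -1.0}
    c = np.zeros(X.shape[1])
    for name, w in contrast.items():
        c[design.names.index(name)] = w

    pinv = np.linalg.pinv(X)
    betas = Y @ pinv.T  # (n_channels, n_cols)
    resid = Y - betas @ X.T
    df = X.shape[0] - rank
    resid_var = np.sum(resid**2, axis=1) / df
    xtx_inv = pinv @ pinv.T
    c_var = c @ xtx_inv @ c
    est = betas @ c
    se = np.sqrt(resid_var * c_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, est / se, 0.0)
    pval = 2 * stats.t.sf(np.abs(tval), df)
    return GlmFit(
        names=list(design.names),
        betas=betas,
        contrast=est,
        t=tval,
        p=pval,
        df=df,
        resid_var=resid_var,
        residuals=resid if keep_residuals else None,
    )


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at rate ``q``."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


@dataclass
class ConditionContrast:
    """Second-level paired comparison of first-level contrasts per channel."""

    t: np.ndarray
    p: np.ndarray
    df: int
    mean_diff: np.ndarray
    fdr_significant: np.ndarray


def condition_contrast(
    contrasts_a: np.ndarray,
    contrasts_b: np.ndarray,
    q: float = 0.05,
) -> ConditionContrast:
    """Paired t-test per channel of first-level contrast estimates between two
    conditions (a - b), FDR-corrected over channels.

    Parameters
    ----------
    contrasts_a, contrasts_b : ndarray, (n_subjects, n_channels), matched rows.
    """
    A = np.asarray(contrasts_a, dtype=float)
    B = np.asarray(contrasts_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"unmatched channel sets: {A.shape} vs {B.shape}")
    d = A - B
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    df = n - 1
    pval = 2 * stats.t.sf(np.abs(tval), df)
    return ConditionContrast(
        t=tval, p=pval, df=df, mean_diff=mean, fdr_significant=fdr_bh(pval, q)
    )
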