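"""Optical-to-hemoglobin conversion and channel-level cleaning.

Continuous-wave fNIRS instruments record changes in light absorbance at a
small number of wavelengths.  The modified Beer-Lambert law converts these to
concentration changes of oxy- and deoxyhemoglobin (HbO, HbR); their sum is
total hemoglobin (HbT).  Before any model fitting, channels with no usable
signal are flagged, slow baseline drift is removed with a discrete wavelet
decomposition, and a spatial principal-component filter subtracts the global
systemic component (blood pressure, respiration) that is shared across all
channels of one subject and would otherwise masquerade as neural activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "ROI_CATALOG",
    "ROI_FULL_NAMES",
    "Channel",
    "ChannelGeometry",
    "default_geometry",
    "OpticalModel",
    "beer_lambert",
    "detect_dead_channels",
    "wavelet_detrend",
    "remove_global_pca",
    "remove_global_median",
]


#: The 15 bilateral regions of interest used for channel grouping, keyed by a
#: short label.  Values give (description, Brodmann area).
ROI_FULL_NAMES: dict[str, tuple[str, str]] = {
    "AG": ("angular gyrus", "BA39"),
    "DLPFC9": ("dorsolateral prefrontal cortex", "BA9"),
    "DLPFC46": ("dorsolateral prefrontal cortex", "BA46"),
    "ParsT": ("pars triangularis", "BA45"),
    "SMG": ("supramarginal gyrus", "BA40"),
    "OTC": ("occipitotemporal cortex", "BA37"),
    "MTG": ("middle temporal gyrus", "BA21"),
    "STG": ("superior temporal gyrus", "BA22"),
    "SSC": ("somatosensory cortex", "BA1-2-3"),
    "SSA": ("somatosensory association cortex", "BA7"),
    "PMC": ("pre-motor and supplementary motor cortex", "BA6"),
    "SubC": ("subcentral area", "BA43"),
    "IFG": ("inferior frontal gyrus", "BA47"),
    "V3": ("extrastriate visual cortex V3", "BA19"),
    "FEF": ("frontal eye fields", "BA8"),
}

ROI_CATALOG: tuple[str, ...] = tuple(ROI_FULL_NAMES)


@dataclass(frozen=True)
class Channel:
    channel_id: str
    hemisphere: str  # "L" or "R"
    roi: str


@dataclass(frozen=True)
class ChannelGeometry:
    """Mapping from measurement channels to anatomical regions of interest."""

    channels: tuple[Channel, ...]

    def __post_init__(self) -> None:
        for ch in self.channels:
            if ch.roi not in ROI_CATALOG:
                raise ValueError(
                    f"channel {ch.channel_id!r} maps to unknown ROI {ch.roi!r}; "
                    f"valid ROIs: {', '.join(ROI_CATALOG)}"
                )
            if ch.hemisphere not in ("L", "R"):
                raise ValueError(f"hemisphere must be 'L' or 'R', got {ch.hemisphere!r}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def rois(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for ch in self.channels:
            seen.setdefault(ch.roi, None)
        return tuple(seen)

    def roi_indices(self, roi: str) -> np.ndarray:
        if roi not in ROI_CATALOG:
            raise KeyError(f"unknown ROI {roi!r}")
        idx = np.array([i for i, ch in enumerate(self.channels) if ch.roi == roi], dtype=int)
        return idx


def default_geometry() -> ChannelGeometry:
    """42-channel montage: 2-3 channels for each of the 15 ROIs.

    The first 12 ROIs get three channels, the remainder two, alternating
    hemispheres, for 42 channels total.
    """
    channels = []
    k = 0
    for i, roi in enumerate(ROI_CATALOG):
        n = 3 if i < 12 else 2
        for j in range(n):
            k += 1
            channels.append(Channel(f"ch{k:02d}", "L" if j % 2 == 0 else "R", roi))
    return ChannelGeometry(tuple(channels))


# ---------------------------------------------------------------------------
# Modified Beer-Lambert conversion
# ---------------------------------------------------------------------------

#: Extinction coefficients [mM^-1 cm^-1] for (HbO, HbR) at the instrument's
#: three wavelengths.  Literature values (Matcher/Cope compilations); the
#: middle wavelength is close to the isosbestic point where both chromophores
#: absorb equally.
_DEFAULT_EXTINCTION = np.array(
    [
        [0.735, 1.102],  # 780 nm
        [0.860, 0.820],  # 805 nm
        [1.070, 0.780],  # 830 nm
    ]
)


@dataclass(frozen=True)
class OpticalModel:
    wavelengths: tuple[float, ...] = (780.0, 805.0, 830.0)
    extinction_matrix: np.ndarray = field(default_factory=lambda: _DEFAULT_EXTINCTION.copy())
    pathlength_factor: float = 6.0

    def __post_init__(self) -> None:
        eps = np.asarray(self.extinction_matrix, dtype=float)
        if eps.shape != (len(self.wavelengths), 2):
            raise ValueError(
                f"extinction matrix must be ({len(self.wavelengths)}, 2), got {eps.shape}"
            )
        if np.linalg.matrix_rank(eps) < 2:
            raise ValueError("extinction matrix is rank deficient; cannot separate HbO/HbR")
        if self.pathlength_factor <= 0:
            raise ValueError("pathlength factor must be positive")


def beer_lambert(
    delta_absorbance: np.ndarray, model: OpticalModel | None = None
) -> dict[str, np.ndarray]:
    """Convert absorbance changes to chromophore concentration changes.

    Solves ``dA = eps * L * dc`` per sample by least squares, where ``dA`` is
    the absorbance change at the three wavelengths, ``eps`` the extinction
    matrix and ``L`` the differential pathlength.

    Parameters
    ----------
    delta_absorbance : ndarray, shape (..., n_wavelengths)
        Absorbance change, trailing axis over wavelengths.
    model : OpticalModel, optional

    Returns
    -------
    dict with keys ``"hbo"``, ``"hbr"``, ``"hbt"``; each ndarray of shape
    ``delta_absorbance.shape[:-1]``.  HbT is the exact sum HbO + HbR.
    """
    model = model or OpticalModel()
    da = np.asarray(delta_absorbance, dtype=float)
    nwl = len(model.wavelengths)
    if da.shape[-1] != nwl:
        raise ValueError(f"expected trailing axis of length {nwl}, got {da.shape[-1]}")
    A = model.extinction_matrix * model.pathlength_factor
    flat = da.reshape(-1, nwl).T  # (nwl, n)
    dc, *_ = np.linalg.lstsq(A, flat, rcond=None)  # (2, n)
    hbo = dc[0].reshape(da.shape[:-1])
    hbr = dc[1].reshape(da.shape[:-1])
    return {"hbo": hbo, "hbr": hbr, "hbt": hbo + hbr}


def forward_absorbance(
    hbo: np.ndarray, hbr: np.ndarray, model: OpticalModel | None = None
) -> np.ndarray:
    """Forward model: concentration changes to absorbance changes (for tests
    and synthetic raw data)."""
    model = model or OpticalModel()
    dc = np.stack([np.asarray(hbo, float), np.asarray(hbr, float)], axis=-1)
    A = model.extinction_matrix * model.pathlength_factor
    return dc @ A.T


# ---------------------------------------------------------------------------
# Channel quality control
# ---------------------------------------------------------------------------

def detect_dead_channels(raw: np.ndarray, factor: float = 10.0) -> np.ndarray:
    """Flag channels whose RMS magnitude exceeds ``factor`` times the mean RMS
    of the *other* channels of the same subject.

    Saturated or unconnected optodes show up as extreme-magnitude channels.
    The candidate channel is excluded from the reference average so a single
    extreme channel cannot mask itself.

    Parameters
    ----------
    raw : ndarray, shape (n_channels, n_samples)

    Returns
    -------
    ndarray of bool, shape (n_channels,) -- True marks a dead channel.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] < 2:
        raise ValueError("need a (n_channels >= 2, n_samples) matrix")
    rms = np.sqrt(np.mean(raw**2, axis=1))
    total = rms.sum()
    n = len(rms)
    others_mean = (total - rms) / (n - 1)
    flagged = rms > factor * others_mean
    if flagged.all():
        raise ValueError("all channels flagged as dead; subject unusable")
    return flagged


def wavelet_detrend(
    ts: np.ndarray,
    sampling_interval: float,
    cutoff_period: float = 128.0,
    wavelet: str = "sym8",
) -> np.ndarray:
    """Remove baseline drift slower than ``cutoff_period`` seconds.

    The series is decomposed with a discrete wavelet transform; the coarse
    approximation (periods above the cutoff) is subtracted and the result is
    mean-centered.  Series shorter than one cutoff period are mean-centered
    only, with a warning.

    Works on 1-D series or (n_channels, n_samples) matrices (last axis time).
    """
    ts = np.asarray(ts, dtype=float)
    n = ts.shape[-1]
    if not np.all(np.isfinite(ts)):
        raise ValueError("input contains non-finite values")
    if n * sampling_interval < cutoff_period:
        warnings.warn(
            "series shorter than one cutoff period; mean-centering only",
            stacklevel=2,
        )
        return ts - ts.mean(axis=-1, keepdims=True)
    # Approximation at level L spans periods > 2**(L+1) * dt; choose the level
    # whose band edge is nearest the requested cutoff.
    level = int(round(np.log2(cutoff_period / sampling_interval))) - 1
    level = max(1, min(level, pywt.dwt_max_level(n, wavelet)))
    coeffs = pywt.wavedec(ts, wavelet, level=level, axis=-1)
    coeffs[0] = np.zeros_like(coeffs[0])
    out = pywt.waverec(coeffs, wavelet, axis=-1)[..., :n]
    return out - out.mean(axis=-1, keepdims=True)


def remove_global_pca(
    data: np.ndarray,
    var_threshold: float = 0.30,
    sign_fraction: float = 0.80,
    max_iter: int = 10,
) -> tuple[np.ndarray, dict]:
    """Subtract globally shared principal components from a channel matrix.

    Components are computed across channels (channels as variables, samples as
    observations).  A component is treated as the global systemic signal when
    it explains more than ``var_threshold`` of the total variance *and* at
    least ``sign_fraction`` of its channel loadings share one sign -- i.e. it
    moves (nearly) all channels up and down together.  Qualifying leading
    components are removed and the criterion re-evaluated on the residual, so
    the filter is idempotent.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)

    Returns
    -------
    (filtered, report) -- filtered matrix (channel-mean removed) and a dict
    with ``n_removed`` and ``variance_removed`` (fraction of total).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 channels")
    X = X - X.mean(axis=1, keepdims=True)
    total_var = np.sum(X**2)
    n_removed = 0
    removed_var = 0.0
    if total_var == 0:
        return X, {"n_removed": 0, "variance_removed": 0.0}
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(X.T, full_matrices=False)  # rows=time, cols=channels
        var = s**2
        tot = var.sum()
        if tot <= total_var * 1e-15:
            break
        frac = var[0] / tot
        loadings = Vt[0]
        dominant_sign = np.mean(np.sign(loadings) == np.sign(loadings[np.argmax(np.abs(loadings))]))
        if frac > var_threshold and dominant_sign >= sign_fraction:
            X = X - np.outer(U[:, 0] * s[0], Vt[0]).T
            n_removed += 1
            removed_var += var[0] / total_var
        else:
            break
    return X, {"n_removed": n_removed, "variance_removed": float(removed_var)}


def remove_global_median(data: np.ndarray) -> tuple[np.ndarray, dict]:
    """Regress a robust (cross-channel median) global estimate out of every
    channel.

    The principal-component filter estimates the global time course from all
    channels jointly, so a strong oscillation confined to a few channels
    contaminates the estimate and its subtraction smears that oscillation
    (with flipped sign) into every other channel.  The cross-channel median
    is insensitive to signals present in a small minority of channels, which
    matters for coherence analyses that look for exactly such localized
    activity.

    Returns (filtered, report); report holds ``variance_removed``.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 channels")
    X = X - X.mean(axis=1, keepdims=True)
    total = np.sum(X**2)
    if total == 0:
        return X, {"variance_removed": 0.0}
    g = np.median(X, axis=0)
    norm = g @ g
    if norm == 0:
        return X, {"variance_removed": 0.0}
    gn = g / np.sqrt(norm)
    filtered = X - np.outer(X @ gn, gn)
    return filtered, {"variance_removed": float(1 - np.sum(filtered**2) / total)}
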