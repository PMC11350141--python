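"""Raw recordings to analysis-ready chromophore series.

Two branches share the optical-density and modified Beer-Lambert (MBLL)
steps but differ in their filtering, and are never mixed:

* NVC branch  — quality screen -> OD -> motion handling -> MBLL -> DCT
  high-pass (0.009 Hz) -> AR prewhitening (applied jointly with the GLM
  design in :mod:`cogvasc.glm`).
* FC branch   — OD -> 5th-order Butterworth band-pass (0.0045-0.4 Hz) ->
  MBLL -> correlation-based signal improvement (CBSI) -> total hemoglobin.

Concentration changes are relative (ΔHbO/ΔHbR, μM scale); the absolute
baseline is unobservable with continuous-wave instruments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sig
from scipy.fft import dct, idct
from scipy.ndimage import median_filter

from .io import FnirsRecording
from .montage import Montage

__all__ = [
    "ChromophoreSeries",
    "QualityReport",
    "EXTINCTION_UM_CM",
    "intensities_to_od",
    "assess_quality",
    "correct_motion",
    "mbll",
    "mbll_forward",
    "dct_highpass",
    "prewhiten",
    "bandpass_fc",
    "cbsi",
    "total_hemoglobin",
    "nvc_preprocess",
    "fc_preprocess",
]

# Molar extinction coefficients from the standard compiled hemoglobin
# spectra, converted to cm^-1 per μM.  Keys are wavelengths in nm; values
# are (HbO, HbR).
EXTINCTION_UM_CM: dict[float, tuple[float, float]] = {
    760.0: (1486.5865e-6, 3843.707e-6),
    850.0: (2526.3910e-6, 1798.643e-6),
}

#: Differential pathlength factor, per wavelength (dimensionless).
DEFAULT_DPF: dict[float, float] = {760.0: 6.0, 850.0: 6.0}

#: Scalp-coupling score below which a channel is considered poor.
DEFAULT_COUPLING_THRESHOLD = 0.75


@dataclass
class ChromophoreSeries:
    """Relative chromophore concentration changes, channel x time (μM)."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs_hz: float
    hbt: np.ndarray | None = None
    branch: str = ""
    filters_applied: tuple[str, ...] = ()
    channel_labels: tuple[str, ...] = ()
    dct_cutoff_hz: float | None = None  # set by the NVC branch; the GLM
    # design must be filtered identically to avoid attenuation bias

    def __post_init__(self) -> None:
        self.hbo = np.atleast_2d(np.asarray(self.hbo, dtype=float))
        self.hbr = np.atleast_2d(np.asarray(self.hbr, dtype=float))
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr must share shape")
        if self.hbt is not None and not np.allclose(self.hbt, self.hbo + self.hbr):
            raise ValueError("hbt must equal hbo + hbr")

    def with_step(self, name: str, **updates) -> "ChromophoreSeries":
        out = ChromophoreSeries(
            hbo=updates.get("hbo", self.hbo),
            hbr=updates.get("hbr", self.hbr),
            fs_hz=self.fs_hz,
            hbt=updates.get("hbt", self.hbt),
            branch=self.branch,
            filters_applied=self.filters_applied + (name,),
            channel_labels=self.channel_labels,
            dct_cutoff_hz=self.dct_cutoff_hz,
        )
        return out


@dataclass
class QualityReport:
    coupling_score: np.ndarray  # per channel, in [-1, 1]
    poor: np.ndarray  # per channel bool
    threshold: float
    excluded: bool = False
    reason: str = ""


def intensities_to_od(recording: FnirsRecording) -> np.ndarray:
    """ΔOD = -log10(I / mean(I)) per channel and wavelength."""
    I = recording.intensities
    finite = np.isfinite(I)
    if np.any(I[finite] <= 0):
        raise ValueError("intensities must be strictly positive")
    mean = np.nanmean(I, axis=-1, keepdims=True)
    return -np.log10(I / mean)


def assess_quality(
    recording: FnirsRecording,
    threshold: float = DEFAULT_COUPLING_THRESHOLD,
    cardiac_band_hz: tuple[float, float] = (0.5, 2.5),
) -> QualityReport:
    """Scalp-coupling screen.

    The coupling score is the Pearson correlation between the two
    wavelengths' cardiac-band signals: a pulsatile component visible at
    both wavelengths indicates optode-scalp contact.  A subject is
    excluded when more than 80% of montage channels are poor or when any
    LDLPFC channel is poor.
    """
    if recording.n_time / recording.fs_hz < 30.0:
        raise ValueError("need at least 30 s of data for quality assessment")
    nyq = recording.fs_hz / 2.0
    lo = cardiac_band_hz[0]
    hi = min(cardiac_band_hz[1], 0.95 * nyq)
    sos = sig.butter(3, [lo, hi], btype="band", fs=recording.fs_hz, output="sos")
    I = np.nan_to_num(recording.intensities)
    filt = sig.sosfiltfilt(sos, I, axis=-1)
    a, b = filt[:, 0, :], filt[:, 1, :]
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    denom = np.sqrt((a**2).sum(-1) * (b**2).sum(-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(denom > 0, (a * b).sum(-1) / denom, 0.0)
    poor = (score < threshold) | ~recording.quality_mask
    report = QualityReport(coupling_score=score, poor=poor, threshold=threshold)
    frac_poor = poor.mean()
    ldl = recording.montage.ldlpfc_indices()
    if frac_poor > 0.8:
        report.excluded = True
        report.reason = f"{frac_poor:.0%} of channels poor (> 80%)"
    elif poor[ldl].any():
        bad = [recording.montage.labels[i] for i in ldl if poor[i]]
        report.excluded = True
        report.reason = f"poor LDLPFC channel(s): {', '.join(bad)}"
    return report


def _correct_trace(x: np.ndarray, fs: float, z_thr: float, step_thr: float):
    n = x.size
    y = x.copy()
    mask = np.zeros(n, dtype=bool)
    # baseline steps first; medians on either side resist spikes, so a
    # transient spike is not mistaken for a step
    d = np.diff(y)
    dmad = np.median(np.abs(d - np.median(d)))
    dsig = 1.4826 * dmad if dmad > 0 else d.std()
    if dsig > 0:
        k = max(int(round(2.0 * fs)), 4)
        for j in np.flatnonzero(np.abs(d) > step_thr * dsig):
            pre = np.median(y[max(0, j - k + 1):j + 1])
            post = np.median(y[j + 1:j + 1 + k])
            jump = post - pre
            # a genuine step persists at roughly the jump height
            if np.abs(jump) > 0.5 * np.abs(d[j]):
                y[j + 1:] -= jump
                mask[j + 1] = True
    # spikes: deviations from a rolling-median baseline
    win = max(int(round(4.0 * fs)) | 1, 5)
    base = median_filter(y, size=win, mode="nearest")
    resid = y - base
    mad = np.median(np.abs(resid - np.median(resid)))
    sigma = 1.4826 * mad if mad > 0 else resid.std()
    if sigma > 0:
        spikes = np.abs(resid) > z_thr * sigma
        # dilate by one sample to cover spike shoulders
        spikes = spikes | np.r_[spikes[1:], False] | np.r_[False, spikes[:-1]]
        y[spikes] = base[spikes]
        mask |= spikes
    return y, mask


def correct_motion(
    series: np.ndarray, fs_hz: float, z_thr: float = 5.0, step_thr: float = 6.0
) -> tuple[np.ndarray, np.ndarray]:
    """Spike + step motion correction on the last (time) axis.

    Spikes are samples deviating from a rolling-median baseline by more
    than ``z_thr`` robust SDs; they are replaced by interpolation across
    the flanking clean samples.  Sustained baseline steps are re-leveled.
    Returns (corrected, artifact mask).
    """
    arr = np.asarray(series, dtype=float)
    flat = arr.reshape(-1, arr.shape[-1])
    out = np.empty_like(flat)
    masks = np.zeros(flat.shape, dtype=bool)
    for i, tr in enumerate(flat):
        out[i], masks[i] = _correct_trace(tr, fs_hz, z_thr, step_thr)
    return out.reshape(arr.shape), masks.reshape(arr.shape)


def _extinction_matrix(
    wavelengths: tuple[float, float],
    extinction_table: dict[float, tuple[float, float]],
) -> np.ndarray:
    try:
        rows = [extinction_table[wl] for wl in wavelengths]
    except KeyError as e:  # pragma: no cover - config error path
        raise KeyError(f"no extinction coefficients for {e.args[0]} nm") from e
    E = np.asarray(rows, dtype=float)
    if abs(np.linalg.det(E)) < 1e-12:
        raise ValueError("extinction matrix is singular")
    return E


def mbll(
    od: np.ndarray,
    montage: Montage,
    wavelengths_nm: tuple[float, float] = (760.0, 850.0),
    dpf: dict[float, float] | None = None,
    extinction_table: dict[float, tuple[float, float]] | None = None,
    fs_hz: float = 3.9,
) -> ChromophoreSeries:
    """Modified Beer-Lambert inversion: ΔOD -> (ΔHbO, ΔHbR) in μM.

    Solves, per channel, ΔOD(λ) = [ε_HbO(λ)ΔHbO + ε_HbR(λ)ΔHbR] · d · DPF(λ).
    """
    dpf = dpf or DEFAULT_DPF
    E = _extinction_matrix(wavelengths_nm, extinction_table or EXTINCTION_UM_CM)
    od = np.asarray(od, dtype=float)
    d = np.asarray(montage.separation_cm)[:, None, None]
    L = np.asarray([dpf[wl] for wl in wavelengths_nm])[None, :, None]
    scaled = od / (d * L)  # (ch, 2, time)
    Einv = np.linalg.inv(E)
    conc = np.einsum("kw,cwt->ckt", Einv, scaled)
    return ChromophoreSeries(
        hbo=conc[:, 0], hbr=conc[:, 1], fs_hz=fs_hz,
        filters_applied=("mbll",), channel_labels=tuple(montage.labels),
    )


def mbll_forward(
    hbo: np.ndarray,
    hbr: np.ndarray,
    montage: Montage,
    wavelengths_nm: tuple[float, float] = (760.0, 850.0),
    dpf: dict[float, float] | None = None,
    extinction_table: dict[float, tuple[float, float]] | None = None,
) -> np.ndarray:
    """Forward model: chromophore changes (μM) -> ΔOD, the exact inverse of
    :func:`mbll`.  Used by the simulator."""
    dpf = dpf or DEFAULT_DPF
    E = _extinction_matrix(wavelengths_nm, extinction_table or EXTINCTION_UM_CM)
    conc = np.stack([np.atleast_2d(hbo), np.atleast_2d(hbr)], axis=1)  # (ch,2,t)
    od = np.einsum("wk,ckt->cwt", E, conc)
    d = np.asarray(montage.separation_cm)[:, None, None]
    L = np.asarray([dpf[wl] for wl in wavelengths_nm])[None, :, None]
    return od * d * L


def dct_highpass(
    series: np.ndarray, fs_hz: float, cutoff_hz: float = 0.009
) -> np.ndarray:
    """Project out discrete-cosine basis vectors below ``cutoff_hz``.

    DCT-II basis vector k has frequency k·fs/(2N); all components with
    frequency strictly below the cutoff (including the constant) are
    removed.
    """
    arr = np.asarray(series, dtype=float)
    n = arr.shape[-1]
    if cutoff_hz >= fs_hz / 2:
        raise ValueError("cutoff must be below Nyquist")
    coeff = dct(arr, type=2, norm="ortho", axis=-1)
    freqs = np.arange(n) * fs_hz / (2.0 * n)
    coeff[..., freqs < cutoff_hz] = 0.0
    return idct(coeff, type=2, norm="ortho", axis=-1)


def _fit_ar(resid: np.ndarray, order_max: int) -> np.ndarray:
    """AIC-selected Yule-Walker AR fit via one Levinson-Durbin pass."""
    x = resid - resid.mean()
    n = x.size
    # biased autocovariances r_0..r_pmax (the Yule-Walker convention)
    r = np.array([x[: n - k] @ x[k:] for k in range(order_max + 1)]) / n
    if r[0] <= 0:
        return np.array([])
    best_aic = n * np.log(r[0])  # p = 0
    best_phi = np.array([])
    phi = np.zeros(order_max)
    v = r[0]
    for p in range(1, order_max + 1):
        k = (r[p] - phi[: p - 1] @ r[p - 1 : 0 : -1]) / v
        phi[: p - 1] = phi[: p - 1] - k * phi[: p - 1][::-1]
        phi[p - 1] = k
        v *= 1.0 - k**2
        if v <= 0:
            break
        aic = n * np.log(v) + 2.0 * p
        if aic < best_aic:
            best_aic, best_phi = aic, phi[:p].copy()
    if best_phi.size:
        roots = np.roots(np.r_[1.0, -best_phi])
        if np.any(np.abs(roots) >= 1.0):
            warnings.warn("AR fit nonstationary; falling back to AR(1)")
            rho1 = min(max(float(r[1] / r[0]), -0.98), 0.98)
            best_phi = np.array([rho1])
    return best_phi


def prewhiten(
    series: np.ndarray,
    design_matrix: np.ndarray,
    order_max: int = 4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """AR(p) prewhitening of a single time series and its design matrix.

    Fits AR(p), p <= ``order_max`` selected by AIC, to the OLS residuals,
    then applies the whitening filter (1 - φ1 B - ... - φp B^p) to both
    the series and every design column.  Returns (whitened series,
    whitened design, AR coefficients).
    """
    y = np.asarray(series, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(design_matrix, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("series and design must share the time axis")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    phi = _fit_ar(resid, order_max)
    if phi.size == 0:
        return y, X, phi
    b = np.r_[1.0, -phi]
    yw = sig.lfilter(b, [1.0], y)
    Xw = sig.lfilter(b, [1.0], X, axis=0)
    return yw, Xw, phi


def bandpass_fc(
    series: np.ndarray,
    fs_hz: float,
    low_hz: float = 0.0045,
    high_hz: float = 0.4,
    order: int = 5,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (FC branch), last axis = time.

    Applied circularly in the frequency domain with the forward-backward
    gain |H(f)|^2.  A recursive forward-backward pass leaves transients
    near the record edges that are long compared to the low corner's
    period (~1/0.0045 Hz); they make the filter response depend on
    position in the record, which biases windowed correlations and their
    surrogate nulls.  The circular implementation responds identically
    at every sample.
    """
    if not 0 < low_hz < high_hz:
        raise ValueError("require 0 < low < high")
    if fs_hz <= 2 * high_hz:
        raise ValueError("sampling rate must exceed twice the upper band edge")
    arr = np.asarray(series, dtype=float)
    n = arr.shape[-1]
    b, a = sig.butter(order, [low_hz, high_hz], btype="band", fs=fs_hz)
    freqs = np.fft.rfftfreq(n, 1.0 / fs_hz)
    _, H = sig.freqz(b, a, worN=2.0 * np.pi * freqs / fs_hz)
    gain = np.abs(H) ** 2
    return np.fft.irfft(np.fft.rfft(arr, axis=-1) * gain, n=n, axis=-1)


def cbsi(hbo: np.ndarray, hbr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Correlation-based signal improvement.

    Per channel, with α = SD(HbO)/SD(HbR):
    HbO' = (HbO - α·HbR)/2 and HbR' = -HbO'/α, which enforces
    corr(HbO', HbR') = -1 and cancels common-mode (same-sign) motion.
    Channels with zero-variance HbR pass through unchanged and are
    flagged.
    """
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float))
    hbr = np.atleast_2d(np.asarray(hbr, dtype=float))
    sd_o = hbo.std(axis=-1)
    sd_r = hbr.std(axis=-1)
    flagged = sd_r == 0
    alpha = np.where(flagged, 1.0, sd_o / np.where(flagged, 1.0, sd_r))
    hbo_c = (hbo - alpha[:, None] * hbr) / 2.0
    hbr_c = -hbo_c / alpha[:, None]
    hbo_c[flagged] = hbo[flagged]
    hbr_c[flagged] = hbr[flagged]
    return hbo_c, hbr_c, flagged


def total_hemoglobin(series: ChromophoreSeries) -> ChromophoreSeries:
    """Attach HbT = HbO + HbR."""
    return series.with_step("hbt", hbt=series.hbo + series.hbr)


# ---------------------------------------------------------------------------
# branch drivers
# ---------------------------------------------------------------------------

def nvc_preprocess(
    recording: FnirsRecording,
    motion_correction: bool = True,
    dct_cutoff_hz: float = 0.009,
    dpf: dict[float, float] | None = None,
) -> ChromophoreSeries:
    """NVC branch: OD -> motion handling -> MBLL -> DCT high-pass.

    Prewhitening is applied later, jointly with the GLM design.
    """
    od = intensities_to_od(recording)
    steps = ["od"]
    if motion_correction:
        od, _ = correct_motion(od, recording.fs_hz)
        steps.append("motion")
    series = mbll(
        od, recording.montage, recording.wavelengths_nm, dpf=dpf,
        fs_hz=recording.fs_hz,
    )
    hbo = dct_highpass(series.hbo, recording.fs_hz, dct_cutoff_hz)
    hbr = dct_highpass(series.hbr, recording.fs_hz, dct_cutoff_hz)
    return ChromophoreSeries(
        hbo=hbo, hbr=hbr, fs_hz=recording.fs_hz, branch="nvc",
        filters_applied=tuple(steps) + ("mbll", "dct_highpass"),
        channel_labels=tuple(recording.montage.labels),
        dct_cutoff_hz=dct_cutoff_hz,
    )


def fc_preprocess(
    recording: FnirsRecording,
    low_hz: float = 0.0045,
    high_hz: float = 0.4,
    dpf: dict[float, float] | None = None,
) -> ChromophoreSeries:
    """FC branch: OD -> Butterworth band-pass -> MBLL -> CBSI -> HbT."""
    od = intensities_to_od(recording)
    od = bandpass_fc(od, recording.fs_hz, low_hz, high_hz)
    series = mbll(
        od, recording.montage, recording.wavelengths_nm, dpf=dpf,
        fs_hz=recording.fs_hz,
    )
    hbo_c, hbr_c, _ = cbsi(series.hbo, series.hbr)
    out = ChromophoreSeries(
        hbo=hbo_c, hbr=hbr_c, fs_hz=recording.fs_hz, branch="fc",
        filters_applied=("od", "bandpass", "mbll", "cbsi"),
        channel_labels=tuple(recording.montage.labels),
    )
    return total_hemoglobin(out)
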