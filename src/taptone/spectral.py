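"""Per-bin periodograms and periodic/aperiodic spectral decomposition.

Two periodogram routes are provided:

* a continuous wavelet transform with an analytic generalized Morse wavelet
  (gamma = 3, time-bandwidth P^2 = 120, 30 voices per octave, L1
  normalization) whose squared magnitudes are averaged within each 1-minute
  bin, and
* Welch's method (4 s Hann windows, 50% overlap) applied to each bin.

Both are expressed as one-sided power spectral densities (uV^2/Hz) so that
white noise integrates to its variance and the two routes agree on long
stationary signals.

Each per-bin spectrum is then decomposed into an aperiodic power law
``log10 P = offset - exponent * log10 f`` plus Gaussian peaks (in log-power
over linear frequency), in the style of the specparam/FOOOF model.  The
"flattened" spectrum — log power minus the aperiodic fit — is the surface
on which band power and the level-1 regressions operate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import curve_fit

from .synthgen import EEGRecording

__all__ = [
    "TFPower", "BinnedSpectra", "SpectrumModel", "SpecParamSettings",
    "morse_filter", "cwt_power", "bin_periodogram", "binned_cwt_spectra",
    "welch_power", "binned_welch_spectra",
    "fit_aperiodic", "fit_aperiodic_batch", "parameterize_spectrum",
    "corrected_band_power", "flatten_spectra_batch",
]


# ---------------------------------------------------------------------------
# generalized Morse wavelet CWT
# ---------------------------------------------------------------------------


def _morse_psi(omega: np.ndarray, beta: float, gamma: float) -> np.ndarray:
    """Frequency response of the analytic Morse wavelet, peak value 2."""
    wp = (beta / gamma) ** (1.0 / gamma)
    out = np.zeros_like(omega)
    pos = omega > 0
    w = omega[pos]
    ln = beta * np.log(w / wp) + (wp**gamma - w**gamma)
    out[pos] = 2.0 * np.exp(np.clip(ln, -700, 50))
    return out


def _log_freq_grid(f_min: float, f_max: float, voices: int) -> np.ndarray:
    n = int(np.floor(voices * np.log2(f_max / f_min))) + 1
    return f_max * 2.0 ** (-np.arange(n)[::-1] / voices)


def _mother_efold_width(beta: float, gamma: float, n: int = 8192) -> float:
    """e-folding half-width (in samples at scale 1) of the mother envelope."""
    omega = 2 * np.pi * np.fft.fftfreq(n)
    psi = np.fft.ifft(_morse_psi(omega, beta, gamma))
    env = np.abs(psi)
    peak = env.max()
    half = env[:n // 2]
    below = np.flatnonzero(half < peak / np.e)
    return float(below[0]) if below.size else float(n // 2)


@dataclass(frozen=True)
class TFPower:
    """Time-frequency power |W|^2 with its grid and edge (COI) metadata."""

    power: np.ndarray            # (channels, freqs, times), uV^2 (not density)
    freqs: np.ndarray            # ascending, log-spaced
    sfreq: float
    coi_s: np.ndarray            # per-frequency cone-of-influence width, seconds
    density_factor: np.ndarray   # per-frequency factor converting mean power to PSD

    def coi_mask(self) -> np.ndarray:
        """(freqs, times) boolean mask; True where edge effects contaminate."""
        n = self.power.shape[-1]
        t = np.arange(n) / self.sfreq
        dist = np.minimum(t, t[::-1])
        return dist[None, :] < self.coi_s[:, None]


def morse_filter(n: int, sfreq: float, freq: float, *, gamma: float = 3.0,
                 time_bandwidth: float = 120.0) -> np.ndarray:
    """FFT-domain Morse filter tuned so the response peaks at ``freq`` Hz."""
    beta = time_bandwidth / gamma
    wp = (beta / gamma) ** (1.0 / gamma)
    scale = wp / (2 * np.pi * freq / sfreq)
    omega = 2 * np.pi * np.fft.fftfreq(n)
    return _morse_psi(scale * omega, beta, gamma)


def cwt_power(eeg: EEGRecording, f_range: tuple[float, float] = (0.1, 40.0),
              voices_per_octave: int = 30,
              time_bandwidth: float = 120.0, gamma: float = 3.0) -> TFPower:
    """Analytic Morse-wavelet scalogram of the recording.

    L1 normalization: a unit-amplitude sinusoid yields |W| ~ 1 at its ridge.
    ``density_factor`` rescales the time-averaged |W|^2 at each frequency to
    a one-sided PSD, so white noise integrates to its variance.

    Holds the full (channels, freqs, times) array in memory; for long
    recordings use :func:`binned_cwt_spectra`, which streams per scale.
    """
    f_min, f_max = f_range
    nyq = eeg.sfreq / 2.0
    if not (0 < f_min < f_max < nyq):
        raise ValueError("f_range must lie within (0, Nyquist)")
    freqs = _log_freq_grid(f_min, f_max, voices_per_octave)
    n = eeg.n_samples
    beta = time_bandwidth / gamma
    X = np.fft.fft(eeg.data, axis=1)
    power = np.empty((eeg.n_channels, freqs.size, n))
    dens = np.empty(freqs.size)
    for i, f in enumerate(freqs):
        psi = morse_filter(n, eeg.sfreq, f, gamma=gamma,
                           time_bandwidth=time_bandwidth)
        W = np.fft.ifft(X * psi[None, :], axis=1)
        power[:, i, :] = np.abs(W) ** 2
        q = (psi**2).sum() / n
        dens[i] = 2.0 / (eeg.sfreq * q)
    w0 = _mother_efold_width(beta, gamma)
    wp = (beta / gamma) ** (1.0 / gamma)
    scales = wp / (2 * np.pi * freqs / eeg.sfreq)
    coi_s = scales * w0 / eeg.sfreq
    return TFPower(power=power, freqs=freqs, sfreq=eeg.sfreq,
                   coi_s=coi_s, density_factor=dens)


@dataclass(frozen=True)
class BinnedSpectra:
    """Per-bin power spectral densities: (bins, channels, freqs) in uV^2/Hz."""

    power: np.ndarray
    freqs: np.ndarray
    bin_indices: np.ndarray
    method: str                   # "cwt" | "welch"


def bin_periodogram(tf: TFPower, bins: pd.DataFrame, *,
                    start_offset_s: float = 0.0,
                    mode: str = "mean_sq") -> BinnedSpectra:
    """Average the scalogram over each 1-minute bin to a per-bin PSD.

    ``mode="mean_sq"`` (default) averages squared magnitudes over time;
    ``mode="sq_mean"`` squares the time-averaged magnitude instead — the two
    readings of "squared mean magnitudes".  Samples inside the recording-edge
    cone of influence are excluded from the averages.
    """
    if mode not in ("mean_sq", "sq_mean"):
        raise ValueError("mode must be 'mean_sq' or 'sq_mean'")
    n = tf.power.shape[-1]
    coi = tf.coi_mask()
    t0_ms = bins["start_ms"].to_numpy()
    t1_ms = bins["end_ms"].to_numpy()
    rel0 = (t0_ms - t0_ms[0]) / 1000.0 + start_offset_s
    rel1 = (t1_ms - t0_ms[0]) / 1000.0 + start_offset_s
    i0 = np.round(rel0 * tf.sfreq).astype(int)
    i1 = np.round(rel1 * tf.sfreq).astype(int)
    if i0.min() < 0 or i1.max() > n:
        raise ValueError("bins extend outside the time support of the transform")
    out = np.empty((len(bins), tf.power.shape[0], tf.freqs.size))
    for b, (a, z) in enumerate(zip(i0, i1)):
        valid = ~coi[:, a:z]                      # (freqs, time)
        cnt = np.maximum(valid.sum(axis=1), 1)
        seg = tf.power[:, :, a:z]
        if mode == "mean_sq":
            s = (seg * valid[None]).sum(axis=2) / cnt[None, :]
        else:
            m = (np.sqrt(seg) * valid[None]).sum(axis=2) / cnt[None, :]
            s = m**2
        out[b] = s * tf.density_factor[None, :]
    return BinnedSpectra(power=out, freqs=tf.freqs,
                         bin_indices=bins["bin_index"].to_numpy(), method="cwt")


def binned_cwt_spectra(eeg: EEGRecording, bins: pd.DataFrame,
                       f_range: tuple[float, float] = (0.1, 40.0),
                       voices_per_octave: int = 30,
                       time_bandwidth: float = 120.0, gamma: float = 3.0,
                       mode: str = "mean_sq") -> BinnedSpectra:
    """Memory-light CWT periodogram: one scale at a time, reduced per bin."""
    f_min, f_max = f_range
    nyq = eeg.sfreq / 2.0
    if not (0 < f_min < f_max < nyq):
        raise ValueError("f_range must lie within (0, Nyquist)")
    freqs = _log_freq_grid(f_min, f_max, voices_per_octave)
    n = eeg.n_samples
    beta = time_bandwidth / gamma
    wp = (beta / gamma) ** (1.0 / gamma)
    w0 = _mother_efold_width(beta, gamma)

    t0 = bins["start_ms"].to_numpy()
    rel0 = (t0 - t0[0]) / 1000.0
    rel1 = (bins["end_ms"].to_numpy() - t0[0]) / 1000.0
    i0 = np.round(rel0 * eeg.sfreq).astype(int)
    i1 = np.round(rel1 * eeg.sfreq).astype(int)
    if i0.min() < 0 or i1.max() > n:
        raise ValueError("bins extend outside the recording")

    X = np.fft.fft(eeg.data, axis=1)
    t = np.arange(n) / eeg.sfreq
    edge_dist = np.minimum(t, t[::-1])
    out = np.empty((len(bins), eeg.n_channels, freqs.size))
    for i, f in enumerate(freqs):
        psi = morse_filter(n, eeg.sfreq, f, gamma=gamma,
                           time_bandwidth=time_bandwidth)
        W = np.fft.ifft(X * psi[None, :], axis=1)
        if mode == "mean_sq":
            P = np.abs(W) ** 2
        else:
            P = np.abs(W)
        scale = wp / (2 * np.pi * f / eeg.sfreq)
        coi_s = scale * w0 / eeg.sfreq
        valid = edge_dist >= coi_s
        dens = 2.0 / (eeg.sfreq * (psi**2).sum() / n)
        for b, (a, z) in enumerate(zip(i0, i1)):
            v = valid[a:z]
            cnt = max(int(v.sum()), 1)
            m = (P[:, a:z] * v[None, :]).sum(axis=1) / cnt
            out[b, :, i] = (m**2 if mode == "sq_mean" else m) * dens
    return BinnedSpectra(power=out, freqs=freqs,
                         bin_indices=bins["bin_index"].to_numpy(), method="cwt")


# ---------------------------------------------------------------------------
# Welch route
# ---------------------------------------------------------------------------


def welch_power(data: np.ndarray, sfreq: float, window_s: float = 4.0,
                overlap_frac: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Hann-window Welch PSD (density) of a segment, channels along axis 0."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    nper = int(round(window_s * sfreq))
    if data.shape[-1] < nper:
        raise ValueError("segment shorter than one Welch window")
    freqs, psd = signal.welch(data, fs=sfreq, window="hann", nperseg=nper,
                              noverlap=int(nper * overlap_frac), axis=-1,
                              detrend="constant")
    return freqs, psd


def binned_welch_spectra(eeg: EEGRecording, bins: pd.DataFrame,
                         window_s: float = 4.0, overlap_frac: float = 0.5,
                         f_range: tuple[float, float] | None = None) -> BinnedSpectra:
    """Welch PSD computed separately within each 1-minute bin."""
    t0 = bins["start_ms"].to_numpy()
    rel0 = (t0 - t0[0]) / 1000.0
    rel1 = (bins["end_ms"].to_numpy() - t0[0]) / 1000.0
    i0 = np.round(rel0 * eeg.sfreq).astype(int)
    i1 = np.round(rel1 * eeg.sfreq).astype(int)
    if i0.min() < 0 or i1.max() > eeg.n_samples:
        raise ValueError("bins extend outside the recording")
    spectra = []
    freqs = None
    for a, z in zip(i0, i1):
        freqs, psd = welch_power(eeg.data[:, a:z], eeg.sfreq,
                                 window_s, overlap_frac)
        spectra.append(psd)
    power = np.stack(spectra)
    if f_range is not None:
        keep = (freqs >= f_range[0]) & (freqs <= f_range[1])
        freqs, power = freqs[keep], power[..., keep]
    return BinnedSpectra(power=power, freqs=freqs,
                         bin_indices=bins["bin_index"].to_numpy(), method="welch")


# ---------------------------------------------------------------------------
# aperiodic / periodic decomposition
# ---------------------------------------------------------------------------


def fit_aperiodic(freqs: np.ndarray, power: np.ndarray,
                  mode: str = "fixed") -> tuple[float, float]:
    """Robust knee-free aperiodic fit: log10 P = offset - exponent * log10 f.

    Two passes: ordinary log-log least squares, then a refit excluding the
    top-quartile positive residuals (putative peak regions).
    """
    if mode != "fixed":
        raise ValueError("only the fixed (knee-free) mode is implemented")
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    if freqs.size < 3:
        raise ValueError("need at least 3 frequencies")
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    if np.any(power <= 0):
        raise ValueError("power must be positive (log undefined)")
    off, exp_ = fit_aperiodic_batch(freqs, power[None, :])
    return float(off[0]), float(exp_[0])


def fit_aperiodic_batch(freqs: np.ndarray,
                        power: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized robust aperiodic fit over the leading axes of ``power``.

    ``power`` has shape (..., n_freqs); returns (offset, exponent) with the
    leading shape.
    """
    freqs = np.asarray(freqs, dtype=float)
    y = np.log10(np.asarray(power, dtype=float))
    lead = y.shape[:-1]
    y = y.reshape(-1, freqs.size)
    x = np.log10(freqs)

    def _wls(w):
        s0 = w.sum(axis=1)
        s1 = (w * x).sum(axis=1)
        s2 = (w * x**2).sum(axis=1)
        b0 = (w * y).sum(axis=1)
        b1 = (w * x * y).sum(axis=1)
        det = s0 * s2 - s1**2
        det = np.where(det == 0, 1.0, det)
        a = (s2 * b0 - s1 * b1) / det       # intercept = offset
        b = (s0 * b1 - s1 * b0) / det       # slope = -exponent
        return a, b

    w = np.ones_like(y)
    a, b = _wls(w)
    resid = y - (a[:, None] + b[:, None] * x[None, :])
    q75 = np.quantile(resid, 0.75, axis=1, keepdims=True)
    keep = resid <= np.maximum(q75, 0.0)
    # never drop below 3 points
    few = keep.sum(axis=1) < 3
    keep[few] = True
    a, b = _wls(keep.astype(float))
    return a.reshape(lead), (-b).reshape(lead)


@dataclass(frozen=True)
class SpecParamSettings:
    """Tunables of the spectral parameterization (specparam-style defaults)."""

    max_n_peaks: int = 6
    peak_width_limits_hz: tuple[float, float] = (1.0, 12.0)
    min_peak_height: float = 0.05        # log10 power units
    peak_threshold_sd: float = 2.0       # relative threshold, residual SDs
    fit_range_hz: tuple[float, float] = (1.0, 40.0)


@dataclass(frozen=True)
class SpectrumModel:
    """One channel/bin spectrum decomposed into aperiodic + Gaussian peaks."""

    offset: float                 # log10(uV^2/Hz) intercept at 1 Hz
    exponent: float               # 1/f slope magnitude
    peaks: tuple[tuple[float, float, float], ...]  # (center Hz, height, bandwidth=2*sigma)
    freqs: np.ndarray = field(repr=False)
    flattened: np.ndarray = field(repr=False)      # log10 P - aperiodic fit
    fit_error: float = np.nan     # mean absolute residual of the full model

    def aperiodic(self, freqs: np.ndarray | None = None) -> np.ndarray:
        f = self.freqs if freqs is None else np.asarray(freqs)
        return self.offset - self.exponent * np.log10(f)


def _gauss_sum(f, *params):
    out = np.zeros_like(f)
    for i in range(0, len(params), 3):
        c, h, s = params[i:i + 3]
        out += h * np.exp(-0.5 * ((f - c) / s) ** 2)
    return out


def parameterize_spectrum(freqs: np.ndarray, power: np.ndarray,
                          settings: SpecParamSettings | None = None) -> SpectrumModel:
    """Iterative periodic/aperiodic decomposition of one power spectrum.

    Robust aperiodic fit; then repeatedly locate the largest flattened
    residual above threshold, fit a Gaussian there and subtract; jointly
    refit all Gaussians; finally refit the aperiodic component on the
    peak-subtracted spectrum.
    """
    st = settings or SpecParamSettings()
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    keep = (freqs >= st.fit_range_hz[0]) & (freqs <= st.fit_range_hz[1])
    f = freqs[keep]
    if f.size < 3:
        raise ValueError("fit range contains fewer than 3 frequencies")
    logp = np.log10(power[keep])

    off, exp_ = fit_aperiodic(f, power[keep])
    flat = logp - (off - exp_ * np.log10(f))

    sig_lo = st.peak_width_limits_hz[0] / 2.0
    sig_hi = st.peak_width_limits_hz[1] / 2.0
    guesses: list[tuple[float, float, float]] = []
    resid = flat.copy()
    for _ in range(st.max_n_peaks):
        i = int(np.argmax(resid))
        h = resid[i]
        thresh = max(st.min_peak_height, st.peak_threshold_sd * resid.std())
        if h < thresh:
            break
        # half-height extent as the width guess
        half = h / 2.0
        li = i
        while li > 0 and resid[li] > half:
            li -= 1
        ri = i
        while ri < resid.size - 1 and resid[ri] > half:
            ri += 1
        fwhm = max(f[ri] - f[li], 1e-6)
        sig = float(np.clip(fwhm / 2.355, sig_lo, sig_hi))
        guesses.append((float(f[i]), float(h), sig))
        resid = resid - h * np.exp(-0.5 * ((f - f[i]) / sig) ** 2)

    peaks: list[tuple[float, float, float]] = []
    if guesses:
        p0, lo_b, hi_b = [], [], []
        for c, h, s in guesses:
            p0 += [c, h, s]
            lo_b += [f[0], 0.0, sig_lo * 0.5]
            hi_b += [f[-1], max(2 * h, 1.0), sig_hi * 2.0]
        try:
            popt, _ = curve_fit(_gauss_sum, f, flat, p0=p0,
                                bounds=(lo_b, hi_b), maxfev=3000)
            fitted = [tuple(popt[i:i + 3]) for i in range(0, len(popt), 3)]
        except RuntimeError:
            warnings.warn("joint Gaussian refit did not converge; keeping guesses")
            fitted = guesses
        for c, h, s in fitted:
            if h >= st.min_peak_height and st.fit_range_hz[0] <= c <= st.fit_range_hz[1]:
                peaks.append((float(c), float(h), float(2 * s)))

    peak_model = _gauss_sum(f, *[v for c, h, bw in peaks for v in (c, h, bw / 2)])
    # final aperiodic refit on the peak-subtracted spectrum (plain lstsq)
    x = np.log10(f)
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, logp - peak_model, rcond=None)
    off_f, exp_f = float(coef[0]), float(-coef[1])
    flattened = logp - (off_f - exp_f * x)
    model = (off_f - exp_f * x) + peak_model
    return SpectrumModel(offset=off_f, exponent=exp_f, peaks=tuple(peaks),
                         freqs=f, flattened=flattened,
                         fit_error=float(np.mean(np.abs(logp - model))))


def corrected_band_power(model: SpectrumModel,
                         band: tuple[float, float] = (4.0, 8.0)) -> float:
    """Mean flattened (aperiodic-corrected) log10 power within ``band``."""
    lo, hi = band
    if hi <= lo:
        raise ValueError("empty band")
    sel = (model.freqs >= lo) & (model.freqs <= hi)
    if not sel.any():
        raise ValueError("band contains no grid frequencies")
    return float(model.flattened[sel].mean())


def flatten_spectra_batch(spectra: BinnedSpectra,
                          fit_range_hz: tuple[float, float] = (1.0, 40.0)):
    """Flatten all (bin, channel) spectra with the batched robust aperiodic fit.

    Returns ``(freqs_sel, flattened, offsets, exponents)`` where flattened is
    (bins, channels, n_sel) log10 power above the aperiodic fit and
    offsets/exponents are (bins, channels).
    """
    keep = (spectra.freqs >= fit_range_hz[0]) & (spectra.freqs <= fit_range_hz[1])
    f = spectra.freqs[keep]
    P = spectra.power[..., keep]
    off, exp_ = fit_aperiodic_batch(f, P)
    ap = off[..., None] - exp_[..., None] * np.log10(f)
    return f, np.log10(P) - ap, off, exp_
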