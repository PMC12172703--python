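"""Filtering, epoching, baselining, and per-bin trimmed-mean evoked potentials.

The auditory-ERP path mirrors the usual mobile-EEG pipeline: a Hamming-window
linear-phase FIR band-pass (0.1-45 Hz by default), common-average reference,
epochs from -200 to +500 ms around each tone, per-epoch baseline removal over
(-200, 0) ms, then a 20% trimmed mean across the trials accumulated in each
1-minute bin.  Epochs whose window crosses a bin boundary or the recording
edge are excluded, and bins with fewer than ``min_trials`` (10) surviving
epochs are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .masstats import trimmed_mean
from .synthgen import EEGRecording, ToneEvents

__all__ = ["Epochs", "BinnedERP", "fir_bandpass", "average_reference",
           "extract_epochs", "bin_erp", "design_fir"]


@dataclass(frozen=True)
class Epochs:
    """Tone-locked epochs: (trials, channels, time) in microvolts."""

    data: np.ndarray
    times_s: np.ndarray          # relative to tone onset; [-0.2, 0.5), half-open
    bin_labels: np.ndarray       # bin index per trial
    edge_flags: np.ndarray       # True where the epoch crossed a bin/recording edge

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class BinnedERP:
    """Per-bin trimmed-mean ERPs: (bins, channels, time)."""

    data: np.ndarray
    bin_indices: np.ndarray      # which bins survived the min-trial filter
    trial_counts: np.ndarray     # retained trials per surviving bin
    times_s: np.ndarray


def design_fir(lo: float, hi: float, sfreq: float,
               transition_hz: float | None = None) -> np.ndarray:
    """Hamming-window linear-phase band-pass FIR taps.

    The transition width defaults to ``max(lo, 0.5)`` Hz at the low edge,
    which keeps the filter length manageable for a 0.1 Hz high-pass while
    still attenuating DC by >40 dB.
    """
    nyq = sfreq / 2.0
    if not (0 <= lo < hi < nyq):
        raise ValueError("require 0 <= lo < hi < Nyquist")
    if transition_hz is None:
        transition_hz = max(lo, 0.5)
    # Hamming window: ~3.3 normalized-width main lobe
    numtaps = int(np.ceil(3.3 * sfreq / transition_hz))
    numtaps |= 1  # odd length -> type-I linear phase
    if lo == 0:
        return signal.firwin(numtaps, hi, window="hamming", fs=sfreq)
    return signal.firwin(numtaps, [lo, hi], window="hamming",
                         pass_zero=False, fs=sfreq)


def fir_bandpass(eeg: EEGRecording, lo: float, hi: float,
                 transition_hz: float | None = None) -> EEGRecording:
    """Zero-phase band-pass via a symmetric FIR with group-delay compensation.

    The filter is linear phase, so a single FFT-based pass followed by a
    shift of (numtaps-1)/2 samples yields an exactly zero-phase response.
    Edges are handled by reflect-padding one filter length.
    """
    taps = design_fir(lo, hi, eeg.sfreq, transition_hz)
    half = (taps.size - 1) // 2
    n = eeg.n_samples
    pad = min(taps.size, n - 1)
    x = np.pad(eeg.data, ((0, 0), (pad, pad)), mode="reflect")
    y = signal.fftconvolve(x, taps[None, :], mode="same", axes=1)
    return eeg.copy_with(y[:, pad:pad + n])


def average_reference(eeg: EEGRecording) -> EEGRecording:
    """Re-reference to the common average; the channel mean becomes ~0 everywhere."""
    if eeg.n_channels < 2:
        raise ValueError("average reference requires >= 2 channels")
    return eeg.copy_with(eeg.data - eeg.data.mean(axis=0, keepdims=True))


def extract_epochs(eeg: EEGRecording, tones: ToneEvents, bins: pd.DataFrame,
                   window_s: tuple[float, float] = (-0.2, 0.5),
                   baseline_s: tuple[float, float] = (-0.2, 0.0)) -> Epochs:
    """Cut tone-locked epochs, assign them to bins, and baseline-correct.

    The window is half-open ``[window_s[0], window_s[1])`` at the recording's
    sampling rate.  An epoch is edge-flagged (and later excluded) if its
    window extends beyond the recording or beyond the bin containing its
    tone onset; tones falling outside any complete bin are edge-flagged too.
    """
    sfreq = eeg.sfreq
    n_pre = int(round(-window_s[0] * sfreq))
    n_post = int(round(window_s[1] * sfreq))
    n_len = n_pre + n_post
    times = (np.arange(n_len) - n_pre) / sfreq

    t0 = eeg.start_time_ms
    starts = (bins["start_ms"].to_numpy() - t0) / 1000.0
    ends = (bins["end_ms"].to_numpy() - t0) / 1000.0
    bin_idx_arr = bins["bin_index"].to_numpy()

    data, labels, flags = [], [], []
    for onset in tones.onsets_s:
        i_on = int(round(onset * sfreq))
        i0, i1 = i_on - n_pre, i_on + n_post
        in_bin = (starts <= onset) & (onset < ends)
        if not in_bin.any():
            label, edge = -1, True
        else:
            j = int(np.flatnonzero(in_bin)[0])
            label = int(bin_idx_arr[j])
            w_lo = onset + window_s[0]
            w_hi = onset + window_s[1]
            edge = (w_lo < starts[j]) or (w_hi > ends[j])
        if i0 < 0 or i1 > eeg.n_samples:
            edge = True
            ep = np.zeros((eeg.n_channels, n_len))
        else:
            ep = eeg.data[:, i0:i1].copy()
        data.append(ep)
        labels.append(label)
        flags.append(edge)

    if not data:
        warnings.warn("no epochs extracted")
        return Epochs(np.zeros((0, eeg.n_channels, n_len)), times,
                      np.zeros(0, dtype=int), np.zeros(0, dtype=bool))

    arr = np.stack(data)
    b0 = int(round((baseline_s[0] - window_s[0]) * sfreq))
    b1 = int(round((baseline_s[1] - window_s[0]) * sfreq))
    arr -= arr[:, :, b0:b1].mean(axis=2, keepdims=True)
    return Epochs(arr, times, np.asarray(labels), np.asarray(flags))


def bin_erp(epochs: Epochs, min_trials: int = 10, trim: float = 0.2) -> BinnedERP:
    """Per-bin 20% trimmed-mean ERP; bins with < ``min_trials`` clean epochs drop out."""
    keep = ~epochs.edge_flags
    labels = epochs.bin_labels[keep]
    data = epochs.data[keep]
    out, idxs, counts = [], [], []
    for b in np.unique(labels):
        sel = data[labels == b]
        if sel.shape[0] < min_trials:
            continue
        out.append(trimmed_mean(sel, trim=trim, axis=0))
        idxs.append(int(b))
        counts.append(sel.shape[0])
    if not out:
        warnings.warn("no bins reached the minimum trial count")
        shp = (0,) + epochs.data.shape[1:]
        return BinnedERP(np.zeros(shp), np.zeros(0, dtype=int),
                         np.zeros(0, dtype=int), epochs.times_s)
    return BinnedERP(np.stack(out), np.asarray(idxs), np.asarray(counts),
                     epochs.times_s)
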