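"""Read/write session files, align clocks, and build the per-minute regressor table.

File formats
------------
* touch log: CSV with a ``timestamp_ms`` column (UTC milliseconds)
* tone events: TSV with an ``onset_s`` column (seconds from recording start)
* EEG: HDF5 container (data, sfreq, start time, montage) with an optional
  JSON sidecar of the generating parameters; EDF reading is available via
  :func:`read_edf` when mne is installed
* bin table: TSV export of :func:`bin_session`'s output
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthgen import EEGRecording, Montage, ToneEvents, TouchLog

__all__ = [
    "ParseError",
    "read_touch_log", "write_touch_log",
    "read_tone_events", "write_tone_events",
    "align_clocks", "bin_session",
    "write_bin_table", "read_bin_table",
    "write_eeg", "read_eeg", "read_edf",
]

#: paper-motivated bound on the smartphone-vs-EEG clock mismatch (ms)
CLOCK_MISMATCH_BOUND_MS = 4000


class ParseError(ValueError):
    """A session file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"{message} (line {line})")


def _read_numeric_column(path, column: str, sep: str) -> np.ndarray:
    df = pd.read_csv(path, sep=sep)
    if df.empty and column not in df.columns:
        warnings.warn(f"{path}: empty file, returning empty series")
        return np.empty(0)
    if column not in df.columns:
        raise ParseError(f"{path}: missing required column {column!r}")
    vals = pd.to_numeric(df[column], errors="coerce")
    bad = np.flatnonzero(vals.isna().to_numpy())
    if bad.size:
        # +2: 1-based line numbering plus the header line
        raise ParseError(f"{path}: non-numeric value {df[column].iloc[bad[0]]!r}",
                         line=int(bad[0]) + 2)
    return vals.to_numpy()


def read_touch_log(path) -> TouchLog:
    """Read a ``timestamp_ms`` CSV; output is sorted even if the file is not."""
    vals = _read_numeric_column(path, "timestamp_ms", sep=",")
    return TouchLog(np.sort(vals).astype(np.int64))


def write_touch_log(log: TouchLog, path) -> None:
    pd.DataFrame({"timestamp_ms": log.timestamps_ms}).to_csv(path, index=False)


def read_tone_events(path) -> ToneEvents:
    vals = _read_numeric_column(path, "onset_s", sep="\t")
    return ToneEvents(np.sort(vals))


def write_tone_events(tones: ToneEvents, path) -> None:
    pd.DataFrame({"onset_s": tones.onsets_s}).to_csv(path, sep="\t", index=False)


def align_clocks(events, offset_ms: float):
    """Shift behavioral timestamps onto the EEG clock by a constant offset.

    The measured smartphone-vs-PC mismatch is bounded by ~4 s; a larger
    offset is applied but flagged with a warning.  ``align_clocks(x, o)``
    followed by ``align_clocks(x, -o)`` is the identity.
    """
    if not np.isfinite(offset_ms):
        raise ValueError("offset_ms must be finite")
    if abs(offset_ms) > CLOCK_MISMATCH_BOUND_MS:
        warnings.warn(f"clock offset {offset_ms} ms exceeds the expected "
                      f"<{CLOCK_MISMATCH_BOUND_MS} ms bound")
    if isinstance(events, TouchLog):
        return TouchLog(events.timestamps_ms + int(round(offset_ms)))
    if isinstance(events, ToneEvents):
        return ToneEvents(events.onsets_s + offset_ms / 1000.0)
    return np.asarray(events) + offset_ms


def bin_session(touches: TouchLog, t0_ms: int, duration_s: float,
                bin_width_s: float = 60.0) -> pd.DataFrame:
    """Count touches in half-open 1-min bins anchored at the EEG start.

    Returns a DataFrame with columns ``bin_index``, ``start_ms``, ``end_ms``,
    ``touch_count``, ``usage`` (= sqrt(count), the momentary-usage regressor)
    and ``elapsed`` (= bin index, the time regressor).  A trailing partial
    bin is dropped; touches outside the span are ignored (count reported via
    a warning).
    """
    if duration_s <= 0 or bin_width_s <= 0:
        raise ValueError("duration_s and bin_width_s must be positive")
    n_bins = int(duration_s // bin_width_s)
    bw_ms = bin_width_s * 1000.0
    counts = np.zeros(n_bins, dtype=np.int64)
    rel = touches.timestamps_ms.astype(np.float64) - t0_ms
    idx = np.floor(rel / bw_ms).astype(int)
    ok = (idx >= 0) & (idx < n_bins)
    n_out = int((~ok).sum())
    if n_out:
        warnings.warn(f"{n_out} touches outside the session span were ignored")
    np.add.at(counts, idx[ok], 1)
    starts = t0_ms + np.arange(n_bins, dtype=np.int64) * int(round(bw_ms))
    return pd.DataFrame({
        "bin_index": np.arange(n_bins),
        "start_ms": starts,
        "end_ms": starts + int(round(bw_ms)),
        "touch_count": counts,
        "usage": np.sqrt(counts.astype(float)),
        "elapsed": np.arange(n_bins, dtype=float),
    })


def write_bin_table(bins: pd.DataFrame, path) -> None:
    bins.to_csv(path, sep="\t", index=False)


def read_bin_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# EEG container
# ---------------------------------------------------------------------------


def write_eeg(rec: EEGRecording, path, params_json: dict | None = None) -> None:
    """Write the recording to an HDF5 container (+ optional JSON sidecar)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip", compression_opts=1)
        f.attrs["sfreq"] = rec.sfreq
        f.attrs["start_time_ms"] = rec.start_time_ms
        g = f.create_group("montage")
        g.create_dataset("labels", data=np.array(rec.montage.labels, dtype="S16"))
        g.create_dataset("positions", data=rec.montage.positions)
        g.create_dataset("adjacency", data=rec.montage.adjacency.astype(np.uint8))
    if params_json is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(params_json, indent=2, default=float))


def read_eeg(path) -> EEGRecording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        sfreq = float(f.attrs["sfreq"])
        start = int(f.attrs["start_time_ms"])
        labels = tuple(s.decode() for s in f["montage/labels"][()])
        positions = f["montage/positions"][()]
        adjacency = f["montage/adjacency"][()].astype(bool)
    return EEGRecording(data=data, sfreq=sfreq, start_time_ms=start,
                        montage=Montage(labels, positions, adjacency))


def read_edf(path, montage: Montage | None = None,
             start_time_ms: int = 0) -> EEGRecording:
    """Read an EDF recording via mne (optional dependency).

    Channel positions/adjacency are not stored in EDF; supply a montage or a
    ring layout for the channel count is generated.
    """
    try:
        import mne
    except ImportError as e:  # pragma: no cover - optional path
        raise ImportError("EDF reading requires the optional 'mne' dependency") from e
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    if montage is None:
        from .synthgen import make_montage
        montage = make_montage(data.shape[0])
    return EEGRecording(data=data, sfreq=float(raw.info["sfreq"]),
                        start_time_ms=start_time_ms, montage=montage)
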