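"""Synthetic sessions: touch logs, tone schedules, and multichannel EEG with planted effects.

The generator emulates a ~1.5 h mobile-EEG session in which a participant
spontaneously uses a smartphone while task-irrelevant auditory tones are
played every 1-3 s.  The EEG it produces is built, per 1-minute bin, from

* a 1/f-shaped aperiodic background whose log10 power spectral density is
  ``offset_k - exponent_k * log10(f)``, with per-bin offset and exponent
  drifting linearly in the usage regressor ``u_k = sqrt(touches in bin k)``
  and in elapsed time,
* a theta-band (Gaussian-shaped, ~6 Hz) oscillation whose total log10 power
  is linear in ``u_k``,
* an auditory evoked-potential template (Gaussian components at ~50, ~100,
  ~160 and ~280 ms) added at every tone onset, with the ~100 ms component's
  amplitude linear in ``u_k`` and in the bin index.

All planted quantities are returned in a :class:`GroundTruth` so downstream
estimators can be scored against a known answer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "SessionParams",
    "TouchLog",
    "ToneEvents",
    "Montage",
    "EEGRecording",
    "GroundTruth",
    "gen_touch_series",
    "gen_tone_schedule",
    "make_montage",
    "gen_eeg",
    "erp_template",
]


class InvalidParameterError(ValueError):
    """Raised when generator parameters are outside their valid domain."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionParams:
    """Parameters of one synthetic recording session.

    Amplitude-like quantities are in microvolts; power offsets are in
    log10(uV^2/Hz); the usage regressor is dimensionless (sqrt touches/bin).
    """

    duration_s: float = 5400.0
    sfreq: float = 250.0
    n_channels: int = 16
    bin_width_s: float = 60.0
    isi_range: tuple[float, float] = (1.0, 3.0)
    seed: int = 0

    # --- touch process (two-state renewal: exponential dwell times) ---
    mean_active_s: float = 40.0       # mean dwell in the touching state
    mean_idle_s: float = 30.0         # mean dwell in the idle state
    itv_shape: float = 2.0            # Gamma shape of inter-touch intervals
    itv_scale: float = 0.35           # Gamma scale (s); truncated to itv_range
    itv_range: tuple[float, float] = (0.1, 5.0)

    # --- planted effects (level-1 regression ground truth) ---
    beta_theta_usage: float = 0.03    # dlog10(theta power) per unit usage
    beta_n100_usage: float = -0.4     # uV per unit usage on the ~100 ms component
    beta_n100_time: float = 0.02      # uV per bin index
    beta_exp_usage: float = -0.02     # exponent units per unit usage
    beta_exp_time: float = 0.002      # exponent units per bin index
    beta_off_usage: float = -0.02     # log10 power per unit usage
    beta_off_time: float = 0.002      # log10 power per bin index

    # --- base signal content ---
    exponent0: float = 1.0
    offset0: float = 0.5              # log10(uV^2/Hz) at 1 Hz
    theta_center_hz: float = 6.0
    theta_sigma_hz: float = 1.0
    theta_log_power0: float = 0.7     # log10 of total theta variance (uV^2)
    erp_latencies_s: tuple[float, ...] = (0.05, 0.10, 0.16, 0.28)
    erp_amplitudes_uv: tuple[float, ...] = (1.0, -3.0, 2.0, -1.5)
    erp_widths_s: tuple[float, ...] = (0.010, 0.015, 0.020, 0.040)
    noise_sd: float = 0.5             # white sensor noise, uV

    # --- plumbing ---
    crossfade_s: float = 1.0          # raised-cosine cross-fade across bin edges
    aperiodic_f_floor: float = 0.3    # clamp 1/f divergence below this frequency
    lead_in_s: float = 1.0            # silence before the first tone

    def validate(self) -> None:
        if not self.duration_s > 0:
            raise InvalidParameterError("duration_s must be positive")
        if not (0 < self.bin_width_s <= self.duration_s):
            raise InvalidParameterError("bin_width_s must be in (0, duration_s]")
        lo, hi = self.isi_range
        if lo < 0 or lo > hi:
            raise InvalidParameterError("isi_range must satisfy 0 <= min <= max")
        if self.sfreq <= 2 * max(45.0, self.theta_center_hz + 4 * self.theta_sigma_hz):
            raise InvalidParameterError("sfreq must exceed twice the highest synthesized frequency")
        if self.n_channels < 1:
            raise InvalidParameterError("n_channels must be >= 1")
        if not all(np.isfinite([self.beta_theta_usage, self.beta_n100_usage,
                                self.beta_n100_time, self.beta_exp_usage,
                                self.beta_exp_time, self.beta_off_usage,
                                self.beta_off_time])):
            raise InvalidParameterError("effect magnitudes must be finite")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sfreq))

    @property
    def n_bins(self) -> int:
        """Number of complete bins covering the session."""
        return int(self.duration_s // self.bin_width_s)

    def with_(self, **kwargs) -> "SessionParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TouchLog:
    """Touchscreen interaction timestamps in UTC milliseconds, ascending."""

    timestamps_ms: np.ndarray

    def __post_init__(self):
        ts = np.asarray(self.timestamps_ms, dtype=np.int64)
        object.__setattr__(self, "timestamps_ms", ts)
        if ts.size and np.any(np.diff(ts) < 0):
            raise ValueError("touch timestamps must be nondecreasing")

    def __len__(self) -> int:
        return int(self.timestamps_ms.size)


@dataclass(frozen=True)
class ToneEvents:
    """Tone onset times in seconds from recording start, ascending."""

    onsets_s: np.ndarray

    def __post_init__(self):
        on = np.asarray(self.onsets_s, dtype=float)
        object.__setattr__(self, "onsets_s", on)
        if on.size and np.any(np.diff(on) < 0):
            raise ValueError("tone onsets must be nondecreasing")

    def __len__(self) -> int:
        return int(self.onsets_s.size)


@dataclass(frozen=True)
class Montage:
    """Channel labels, 2-D unit-disc positions, and a symmetric adjacency."""

    labels: tuple[str, ...]
    positions: np.ndarray          # (n, 2)
    adjacency: np.ndarray          # (n, n) bool, symmetric, zero diagonal

    @property
    def n_channels(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class EEGRecording:
    """Multichannel EEG: (channels, samples) in microvolts."""

    data: np.ndarray
    sfreq: float
    start_time_ms: int
    montage: Montage

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        return EEGRecording(data=data, sfreq=self.sfreq,
                            start_time_ms=self.start_time_ms, montage=self.montage)


@dataclass(frozen=True)
class GroundTruth:
    """Everything that was planted, for scoring recovery downstream.

    ``beta_maps`` holds the per-channel planted regression slopes:

    - ``"erp_usage"``, ``"erp_time"``: (channels, epoch samples) — the
      slope of the evoked potential at each post-onset time point.
    - ``"erp_usage_car"``, ``"erp_time_car"``: same after projecting through
      the common-average-reference operator (what a CAR'd analysis sees).
    - ``"theta_usage"``: (channels,) — dlog10 theta power per unit usage.
    - ``"exp_usage"``, ``"exp_time"``, ``"off_usage"``, ``"off_time"``:
      (channels,) slopes of the aperiodic exponent / offset.
    """

    usage: np.ndarray                 # (n_bins,) u_k = sqrt(count)
    touch_counts: np.ndarray          # (n_bins,)
    exponent_k: np.ndarray            # (n_bins,)
    offset_k: np.ndarray              # (n_bins,)
    theta_log_power_k: np.ndarray     # (n_bins,) planted total theta variance, log10
    erp_topography: np.ndarray        # (channels,) weight of the evoked template
    theta_topography: np.ndarray      # (channels,) weight of the theta oscillation
    beta_maps: dict = field(default_factory=dict)
    epoch_times_s: np.ndarray | None = None  # time axis of the erp beta maps
    erp_base_template: np.ndarray | None = None  # (channels, epoch samples), u=0, k=0


# ---------------------------------------------------------------------------
# touch process
# ---------------------------------------------------------------------------


def gen_touch_series(params: SessionParams, *, start_time_ms: int = 0) -> TouchLog:
    """Simulate a bursty touch sequence as a two-state (active/idle) renewal process.

    Dwell times in each state are exponential; during active bouts,
    inter-touch intervals are Gamma(shape, scale) truncated to
    ``params.itv_range`` (0.1-5 s by default).  Deterministic given
    ``params.seed``.
    """
    params.validate()
    if params.mean_active_s <= 0:
        return TouchLog(np.empty(0, dtype=np.int64))
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 101]))
    lo, hi = params.itv_range
    # inverse-CDF sampling of the truncated Gamma
    gdist = stats.gamma(params.itv_shape, scale=params.itv_scale)
    c_lo, c_hi = gdist.cdf(lo), gdist.cdf(hi)

    t = 0.0
    active = rng.random() < params.mean_active_s / (params.mean_active_s + params.mean_idle_s)
    times: list[float] = []
    while t < params.duration_s:
        dwell = rng.exponential(params.mean_active_s if active else params.mean_idle_s)
        t_end = min(t + dwell, params.duration_s)
        if active:
            tt = t + gdist.ppf(c_lo + (c_hi - c_lo) * rng.random())
            while tt < t_end:
                times.append(tt)
                tt += gdist.ppf(c_lo + (c_hi - c_lo) * rng.random())
        t = t_end
        active = not active
    ts_ms = start_time_ms + np.round(np.asarray(times) * 1000.0).astype(np.int64)
    return TouchLog(ts_ms)


# ---------------------------------------------------------------------------
# tone schedule
# ---------------------------------------------------------------------------

EPOCH_PRE_S = 0.2
EPOCH_POST_S = 0.5


def gen_tone_schedule(params: SessionParams) -> ToneEvents:
    """Tone onsets with uniform ISI in ``params.isi_range`` (1-3 s default).

    Onsets start after a short lead-in and stop early enough that the last
    epoch window (-200..+500 ms) fits inside the recording.
    """
    params.validate()
    if params.duration_s < params.lead_in_s + EPOCH_PRE_S + EPOCH_POST_S:
        warnings.warn("recording shorter than one epoch window: empty tone schedule")
        return ToneEvents(np.empty(0))
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 202]))
    lo, hi = params.isi_range
    last_allowed = params.duration_s - EPOCH_POST_S
    # draw in blocks for speed; mean ISI (lo+hi)/2
    n_guess = int(np.ceil((last_allowed - params.lead_in_s) / max((lo + hi) / 2, 1e-9))) + 16
    onsets = [max(params.lead_in_s, EPOCH_PRE_S)]
    while onsets[-1] <= last_allowed:
        for isi in rng.uniform(lo, hi, size=n_guess):
            onsets.append(onsets[-1] + isi)
            if onsets[-1] > last_allowed:
                break
        else:
            continue
        break
    out = np.asarray(onsets)
    return ToneEvents(out[out <= last_allowed])


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------


def make_montage(n_channels: int) -> Montage:
    """Lay channels on concentric rings of the unit disc.

    Adjacency links pairs closer than 1.5x the median nearest-neighbour
    distance; for n >= 2 the resulting graph is connected.
    """
    if n_channels < 1:
        raise InvalidParameterError("n_channels must be >= 1")
    pos = [(0.0, 0.0)]
    ring = 0
    while len(pos) < n_channels:
        ring += 1
        capacity = 6 * ring
        n_here = min(capacity, n_channels - len(pos))
        # radius grows with ring index; rescaled to the unit disc below
        for j in range(n_here):
            ang = 2 * np.pi * j / n_here + (np.pi / capacity) * (ring % 2)
            pos.append((ring * np.cos(ang), ring * np.sin(ang)))
    positions = np.asarray(pos[:n_channels], dtype=float)
    rmax = np.abs(positions).max()
    if rmax > 0:
        positions = positions / (rmax / 0.95)

    labels = tuple(f"E{i:02d}" for i in range(n_channels))
    if n_channels == 1:
        return Montage(labels, positions, np.zeros((1, 1), dtype=bool))

    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    thresh = 1.5 * np.median(nn)
    adj = d <= thresh
    np.fill_diagonal(adj, False)
    adj = adj | adj.T
    # guarantee connectivity: link each isolated component to its nearest neighbour
    adj = _ensure_connected(adj, d)
    return Montage(labels, positions, adj)


def _ensure_connected(adj: np.ndarray, d: np.ndarray) -> np.ndarray:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    adj = adj.copy()
    while True:
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        if n_comp <= 1:
            return adj
        # bridge component 0 to the nearest node outside it
        in0 = labels == 0
        sub = d[np.ix_(in0, ~in0)]
        i, j = np.unravel_index(np.argmin(sub), sub.shape)
        gi = np.flatnonzero(in0)[i]
        gj = np.flatnonzero(~in0)[j]
        adj[gi, gj] = adj[gj, gi] = True


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------


def erp_template(params: SessionParams, times_s: np.ndarray,
                 usage: float = 0.0, bin_index: int = 0) -> np.ndarray:
    """Evoked-potential template evaluated at ``times_s`` (s, relative to onset).

    The second component (~100 ms) has amplitude
    ``A0 + beta_n100_usage * usage + beta_n100_time * bin_index``.
    """
    amps = list(params.erp_amplitudes_uv)
    amps[1] = amps[1] + params.beta_n100_usage * usage + params.beta_n100_time * bin_index
    out = np.zeros_like(times_s, dtype=float)
    for a, mu, sig in zip(amps, params.erp_latencies_s, params.erp_widths_s):
        out += a * np.exp(-0.5 * ((times_s - mu) / sig) ** 2)
    return out


def _component_shape(times_s: np.ndarray, mu: float, sig: float) -> np.ndarray:
    return np.exp(-0.5 * ((times_s - mu) / sig) ** 2)


def _erp_topography(montage: Montage) -> np.ndarray:
    """Smooth central topography with compact support (zero beyond radius 0.6)."""
    d = np.linalg.norm(montage.positions, axis=1)
    w = np.exp(-d**2 / (2 * 0.3**2))
    w[d > 0.6] = 0.0
    return w


def _theta_topography(montage: Montage) -> np.ndarray:
    """Binary central mask: channels within radius 0.6 of the vertex."""
    d = np.linalg.norm(montage.positions, axis=1)
    return (d <= 0.6).astype(float)


def _shaped_noise(rng: np.random.Generator, n: int, sfreq: float,
                  log_offset: float, exponent: float, f_floor: float) -> np.ndarray:
    """White noise spectrally shaped to one-sided PSD 10^offset * f^-exponent."""
    w = rng.standard_normal(n)
    W = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, 1.0 / sfreq)
    fc = np.maximum(f, f_floor)
    psd = 10.0 ** log_offset * fc ** (-exponent)
    h = np.sqrt(psd * sfreq / 2.0)
    h[0] = 0.0
    return np.fft.irfft(W * h, n)


def _theta_segment(rng: np.random.Generator, n: int, sfreq: float,
                   center: float, sigma: float) -> np.ndarray:
    """Unit-variance narrowband (Gaussian spectral shape) noise segment."""
    w = rng.standard_normal(n)
    W = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, 1.0 / sfreq)
    g = np.exp(-0.5 * ((f - center) / sigma) ** 2)
    x = np.fft.irfft(W * g, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_eeg(params: SessionParams, touches: TouchLog, tones: ToneEvents,
            montage: Montage | None = None,
            *, start_time_ms: int = 0) -> tuple[EEGRecording, GroundTruth]:
    """Synthesize the multichannel recording and its ground truth.

    Per bin k the aperiodic background has exponent
    ``exponent0 + beta_exp_usage*u_k + beta_exp_time*k`` and offset
    ``offset0 + beta_off_usage*u_k + beta_off_time*k``; the theta component
    has total log10 power ``theta_log_power0 + beta_theta_usage*u_k`` (its
    within-bin variance is normalized exactly, so the linearity holds by
    construction on the interior samples of each bin); the evoked template
    is added at every tone onset with the ~100 ms amplitude linear in u_k
    and k.  Bins are cross-faded over ``crossfade_s`` to avoid boundary
    discontinuities.
    """
    params.validate()
    if montage is None:
        montage = make_montage(params.n_channels)
    if montage.n_channels != params.n_channels:
        raise InvalidParameterError("montage size does not match n_channels")
    if len(tones) and (tones.onsets_s.min() < 0 or tones.onsets_s.max() > params.duration_s):
        raise InvalidParameterError("tones outside the recording span")

    sfreq = params.sfreq
    n_total = params.n_samples
    bin_samp = int(round(params.bin_width_s * sfreq))
    n_bins = params.n_bins
    guard = int(round(params.crossfade_s * sfreq / 2))

    # --- per-bin regressors and planted trajectories ---
    rel_ms = touches.timestamps_ms - start_time_ms
    counts = np.zeros(n_bins, dtype=np.int64)
    bw_ms = params.bin_width_s * 1000.0
    if len(touches):
        idx = np.floor(rel_ms / bw_ms).astype(int)
        ok = (idx >= 0) & (idx < n_bins)
        np.add.at(counts, idx[ok], 1)
    usage = np.sqrt(counts.astype(float))
    k = np.arange(n_bins, dtype=float)
    exponent_k = params.exponent0 + params.beta_exp_usage * usage + params.beta_exp_time * k
    offset_k = params.offset0 + params.beta_off_usage * usage + params.beta_off_time * k
    theta_logp_k = params.theta_log_power0 + params.beta_theta_usage * usage
    if np.any(~np.isfinite(exponent_k)) or np.any(~np.isfinite(offset_k)) \
            or np.any(theta_logp_k > 12):
        raise InvalidParameterError("effect magnitudes produce non-finite signals")

    w_erp = _erp_topography(montage)
    v_theta = _theta_topography(montage)

    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 303]))

    data = np.zeros((params.n_channels, n_total))

    # raised-cosine cross-fade window across a 2*guard overlap
    if guard > 0:
        ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, 2 * guard)))
    # bin sample spans; the tail beyond the last full bin reuses the last bin's params
    edges = [(kk * bin_samp, (kk + 1) * bin_samp if kk < n_bins - 1 else n_total)
             for kk in range(n_bins)]

    have_background = np.isfinite(params.offset0) and params.offset0 > -20
    have_theta = params.theta_log_power0 > -20 and np.any(v_theta > 0)

    for c in range(params.n_channels):
        chan = np.zeros(n_total)
        for kk, (s0, s1) in enumerate(edges):
            seg_len = (s1 - s0) + 2 * guard
            a0 = max(s0 - guard, 0)
            a1 = min(s1 + guard, n_total)
            seg = np.zeros(seg_len)
            if have_background:
                seg += _shaped_noise(rng, seg_len, sfreq, offset_k[kk],
                                     exponent_k[kk], params.aperiodic_f_floor)
            if have_theta and v_theta[c] > 0:
                th = _theta_segment(rng, seg_len, sfreq,
                                    params.theta_center_hz, params.theta_sigma_hz)
                # normalize the *interior* (non-crossfaded) variance exactly;
                # the interior excludes the guard on each side of the bin
                interior = th[2 * guard:seg_len - 2 * guard] if guard > 0 else th
                sd = interior.std()
                if sd > 0:
                    th = th / sd
                seg += v_theta[c] * (10.0 ** (theta_logp_k[kk] / 2.0)) * th
            # cross-fade into the output
            win = np.ones(seg_len)
            if guard > 0:
                if s0 > 0:
                    win[:2 * guard] = ramp
                if s1 < n_total:
                    win[-2 * guard:] = ramp[::-1]
            off0 = a0 - (s0 - guard)
            chan[a0:a1] += (seg * win)[off0:off0 + (a1 - a0)]
        if params.noise_sd > 0:
            chan += params.noise_sd * rng.standard_normal(n_total)
        data[c] = chan

    # --- evoked responses ---
    if len(tones) and np.any(w_erp > 0):
        t_axis = np.arange(int(round(0.5 * sfreq)) + 1) / sfreq  # template support 0..0.5 s
        for onset in tones.onsets_s:
            kk = min(int(onset // params.bin_width_s), n_bins - 1)
            i0 = int(round(onset * sfreq))
            # evoked activity is locked to the sample grid so that epoch
            # extraction (which rounds onsets the same way) aligns exactly
            tt = (np.arange(i0, min(i0 + t_axis.size, n_total)) - i0) / sfreq
            tpl = erp_template(params, tt, usage=usage[kk], bin_index=kk)
            data[:, i0:i0 + tt.size] += w_erp[:, None] * tpl[None, :]

    if not np.all(np.isfinite(data)):
        raise InvalidParameterError("generated signal is non-finite")

    # --- ground truth beta maps on the epoch time axis ---
    n_pre = int(round(EPOCH_PRE_S * sfreq))
    n_post = int(round(EPOCH_POST_S * sfreq))
    ep_times = (np.arange(n_pre + n_post) - n_pre) / sfreq
    g100 = _component_shape(ep_times, params.erp_latencies_s[1], params.erp_widths_s[1])
    beta_erp_usage = params.beta_n100_usage * w_erp[:, None] * g100[None, :]
    beta_erp_time = params.beta_n100_time * w_erp[:, None] * g100[None, :]
    C = params.n_channels
    L = np.eye(C) - np.full((C, C), 1.0 / C)  # common-average-reference operator
    base_tpl = w_erp[:, None] * erp_template(params, ep_times)[None, :]
    gt = GroundTruth(
        usage=usage,
        touch_counts=counts,
        exponent_k=exponent_k,
        offset_k=offset_k,
        theta_log_power_k=theta_logp_k,
        erp_topography=w_erp,
        theta_topography=v_theta,
        beta_maps={
            "erp_usage": beta_erp_usage,
            "erp_time": beta_erp_time,
            "erp_usage_car": L @ beta_erp_usage,
            "erp_time_car": L @ beta_erp_time,
            "theta_usage": params.beta_theta_usage * (v_theta > 0).astype(float),
            "exp_usage": np.full(C, params.beta_exp_usage),
            "exp_time": np.full(C, params.beta_exp_time),
            "off_usage": np.full(C, params.beta_off_usage),
            "off_time": np.full(C, params.beta_off_time),
        },
        epoch_times_s=ep_times,
        erp_base_template=base_tpl,
    )
    rec = EEGRecording(data=data, sfreq=sfreq, start_time_ms=start_time_ms,
                       montage=montage)
    return rec, gt
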