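"""Filtering, normalization, onset detection, epoching and windowing.

EEG and sEMG channels live side by side in a :class:`Recording`; every
operation here respects the per-channel modality tag, so a single call
filters the EEG rows with the EEG band and leaves sEMG rows untouched
(and vice versa).  All filters are applied forward-backward (zero
phase): the corticomuscular lag studied downstream is a few tens of
milliseconds, and causal filtering would add a modality-dependent group
delay of the same order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .exceptions import (
    BoundaryError,
    ConfigurationError,
    DegenerateInputError,
    OnsetNotFoundError,
    ShapeError,
)

logger = logging.getLogger(__name__)

EEG = "EEG"
SEMG = "sEMG"

#: band edges (Hz) used for each modality's Butterworth band-pass
EEG_BAND = (0.5, 64.0)
SEMG_BAND = (20.0, 200.0)
NOTCH_FREQ = 50.0
NOTCH_Q = 30.0
FILTER_ORDER = 4


@dataclass
class Recording:
    """Multichannel signal matrix with per-channel modality tags.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal amplitudes (microvolt scale assumed, unit not enforced).
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    modality : list of str
        ``"EEG"`` or ``"sEMG"`` per channel.
    """

    data: np.ndarray
    fs: float
    channel_names: list = field(default_factory=list)
    modality: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ShapeError("data must be a 2-D (channels x samples) array")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        n = self.data.shape[0]
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(n)]
        if len(self.channel_names) != n:
            raise ShapeError("one channel name per row required")
        if len(self.modality) != n:
            raise ShapeError("one modality tag per row required")
        for m in self.modality:
            if m not in (EEG, SEMG):
                raise ConfigurationError(f"unknown modality tag {m!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_indices(self, modality: str) -> np.ndarray:
        return np.array([i for i, m in enumerate(self.modality) if m == modality],
                        dtype=int)

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs,
                         list(self.channel_names), list(self.modality))


@dataclass
class EpochSet:
    """Labeled trials segmented around movement onset.

    ``epochs`` has shape (n_epochs, n_channels, T) with T = 4 * fs and
    the onset at ``t0_index`` = 2 * fs (i.e. -2 .. +2 s around onset).
    """

    epochs: np.ndarray
    labels: np.ndarray
    t0_index: int
    fs: float
    channel_names: list = field(default_factory=list)
    modality: list = field(default_factory=list)

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.epochs.ndim != 3:
            raise ShapeError("epochs must be (n_epochs, channels, samples)")
        if len(self.labels) != self.epochs.shape[0]:
            raise ShapeError("one label per epoch required")

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def channel_indices(self, modality: str) -> np.ndarray:
        return np.array([i for i, m in enumerate(self.modality) if m == modality],
                        dtype=int)


@dataclass
class WindowConfig:
    """Sliding-window geometry and lag compensation.

    Parameters
    ----------
    L : int
        Window length in samples at the native rate.
    step : int, optional
        Hop between consecutive window starts; defaults to ``L // 2``
        (half-overlapping windows).
    delta_t_ms : float
        Compensation lag between EEG and sEMG in milliseconds.  The
        per-rate sample count comes from :meth:`lag_samples`.
    """

    L: int
    step: int = 0
    delta_t_ms: float = 35.0

    def __post_init__(self):
        if self.step == 0:
            self.step = max(1, self.L // 2)
        if self.L <= 0 or not (0 < self.step <= self.L):
            raise ConfigurationError("need 0 < step <= L and L > 0")
        if self.delta_t_ms < 0:
            raise ConfigurationError("delta_t_ms must be >= 0")

    def lag_samples(self, fs: float) -> int:
        """Compensation lag in samples (round half up)."""
        return int(np.floor(self.delta_t_ms * fs / 1000.0 + 0.5))


# ---------------------------------------------------------------------------
# filtering


def _bandpass_sos(band, fs):
    lo, hi = band
    if fs <= 2 * hi:
        raise ConfigurationError(
            f"sampling rate {fs} Hz too low for band edge {hi} Hz")
    return signal.butter(FILTER_ORDER, [lo, hi], btype="bandpass",
                         fs=fs, output="sos")


def _notch_ba(fs):
    return signal.iirnotch(NOTCH_FREQ, NOTCH_Q, fs=fs)


def _filter_channels(rec: Recording, modality: str, band) -> Recording:
    out = rec.copy()
    idx = rec.channel_indices(modality)
    if idx.size == 0:
        return out
    sos = _bandpass_sos(band, rec.fs)
    b, a = _notch_ba(rec.fs)
    x = out.data[idx]
    x = x - x.mean(axis=1, keepdims=True)  # baseline calibration
    x = signal.sosfiltfilt(sos, x, axis=1)
    x = signal.filtfilt(b, a, x, axis=1)
    out.data[idx] = x
    return out


def filter_eeg(rec: Recording) -> Recording:
    """Band-pass 0.5-64 Hz + 50 Hz notch, zero phase, EEG channels only."""
    return _filter_channels(rec, EEG, EEG_BAND)


def filter_semg(rec: Recording) -> Recording:
    """Band-pass 20-200 Hz + 50 Hz notch, zero phase, sEMG channels only."""
    return _filter_channels(rec, SEMG, SEMG_BAND)


def filter_recording(rec: Recording) -> Recording:
    """Apply both modality filter chains."""
    return filter_semg(filter_eeg(rec))


# ---------------------------------------------------------------------------
# normalization


def normalize(x: np.ndarray) -> np.ndarray:
    """Min-max scale a sequence to [-1, +1].

    Computes ``2 * (x - min) / (max - min) - 1`` so that the minimum
    maps to -1 and the maximum to +1 exactly.  Raises
    :class:`DegenerateInputError` for constant input, where the range is
    zero and the mapping undefined.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("need at least 2 samples to normalize")
    mn, mx = x.min(), x.max()
    if mx == mn:
        raise DegenerateInputError("constant input cannot be min-max scaled")
    return 2.0 * (x - mn) / (mx - mn) - 1.0


# ---------------------------------------------------------------------------
# onset detection


def moving_rms(x: np.ndarray, width: int) -> np.ndarray:
    """Causal moving RMS with the given window width in samples."""
    x = np.asarray(x, dtype=float)
    sq = np.concatenate([np.zeros(1), np.cumsum(x * x)])
    n = len(x)
    out = np.empty(n)
    for_start = np.maximum(0, np.arange(n) - width + 1)
    counts = np.arange(n) + 1 - for_start
    out = (sq[np.arange(n) + 1] - sq[for_start]) / counts
    return np.sqrt(out)


def detect_onset(semg: np.ndarray, fs: float, *,
                 baseline_s: float = 1.0,
                 rms_window_s: float = 0.05,
                 hold_s: float = 0.025,
                 n_sd: float = 3.0) -> int:
    """First index where the 50 ms moving RMS of an sEMG trace exceeds
    the baseline mean + ``n_sd`` baseline SDs for at least ``hold_s``.

    The first ``baseline_s`` seconds are treated as rest and define the
    threshold.  Raises :class:`OnsetNotFoundError` when no sustained
    crossing exists and :class:`ConfigurationError` when the trace is
    too short to contain a baseline.
    """
    semg = np.asarray(semg, dtype=float)
    nb = int(round(baseline_s * fs))
    if semg.size <= nb:
        raise ConfigurationError(
            "signal shorter than the required baseline period")
    w = max(1, int(round(rms_window_s * fs)))
    hold = max(1, int(round(hold_s * fs)))
    env = moving_rms(semg, w)
    base = env[:nb]
    thr = base.mean() + n_sd * base.std()
    above = env >= thr
    # first run of >= hold consecutive True values after the baseline
    run = 0
    for i in range(nb, len(above)):
        run = run + 1 if above[i] else 0
        if run >= hold:
            return i - hold + 1
    raise OnsetNotFoundError("no sustained threshold crossing found")


# ---------------------------------------------------------------------------
# epoching and windowing


def epoch_recording(rec: Recording, onsets, labels=None,
                    pre_s: float = 2.0, post_s: float = 2.0) -> EpochSet:
    """Cut fixed-length epochs around each onset sample index.

    Each epoch spans ``[onset - pre_s * fs, onset + post_s * fs)``;
    onsets too close to either edge are skipped with a warning log.
    """
    fs = rec.fs
    pre = int(round(pre_s * fs))
    post = int(round(post_s * fs))
    T = pre + post
    eps, labs = [], []
    n_skipped = 0
    if labels is None:
        labels = [0] * len(onsets)
    for onset, lab in zip(onsets, labels):
        start = int(onset) - pre
        stop = int(onset) + post
        if start < 0 or stop > rec.n_samples:
            n_skipped += 1
            continue
        eps.append(rec.data[:, start:stop])
        labs.append(lab)
    if n_skipped:
        logger.warning("skipped %d onset(s) too close to the recording edge",
                       n_skipped)
    epochs = (np.stack(eps) if eps
              else np.empty((0, rec.n_channels, T)))
    return EpochSet(epochs, np.asarray(labs, dtype=int), pre, fs,
                    list(rec.channel_names), list(rec.modality))


def sliding_windows(epoch: np.ndarray, wc: WindowConfig) -> list:
    """All length-L windows of a (channels x T) matrix at the hop `wc.step`.

    Window count is ``floor((T - L) / step) + 1``; raises
    :class:`BoundaryError` when the epoch is shorter than one window.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    T = epoch.shape[1]
    if wc.L > T:
        raise BoundaryError(f"window length {wc.L} exceeds epoch length {T}")
    starts = range(0, T - wc.L + 1, wc.step)
    return [epoch[:, s:s + wc.L] for s in starts]
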