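"""Lag-compensated EEG/sEMG window alignment and dataset construction.

The cortical drive leads the muscle response by the conduction delay
dT, so a fusion window must not pair EEG and sEMG samples with the
same index.  Two alignment conventions cover the two use cases:

* **offline** (:func:`align_offline`): EEG time t is the benchmark, the
  sEMG span starts dT later — ``EEG [t, t+L)``, ``sEMG [t+lag, t+lag+L)``;
* **online** (:func:`align_online`): the freshest sEMG sample is the
  benchmark because future sEMG is not yet in the acquisition buffer —
  ``sEMG`` takes the last L buffer samples and ``EEG`` the L samples
  ending ``lag`` before the buffer end.

Both express the same relative shift and agree sample-for-sample on
identical absolute spans.  Each modality row is min-max normalized to
[-1, 1] within its own window after alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import BoundaryError, ConfigurationError
from .features import eeg_features, fuse_features, semg_features
from .preprocess import EEG, SEMG, EpochSet, WindowConfig, normalize

logger = logging.getLogger(__name__)


@dataclass
class FusionWindow:
    """Normalized, lag-aligned EEG+sEMG matrix of one window.

    Rows are the EEG channels (montage order) followed by the sEMG
    channels (muscle order); ``eeg_span`` and ``semg_span`` record the
    absolute half-open sample intervals the rows came from.
    """

    matrix: np.ndarray
    eeg_span: tuple
    semg_span: tuple
    label: int = None
    channel_names: list = field(default_factory=list)


def _normalize_rows(block: np.ndarray) -> np.ndarray:
    out = np.empty_like(block, dtype=float)
    for i, row in enumerate(block):
        if row.max() == row.min():
            out[i] = 0.0   # silent channel: flat at mid-scale
        else:
            out[i] = normalize(row)
    return out


def _split_indices(modality):
    eeg_idx = [i for i, m in enumerate(modality) if m == EEG]
    semg_idx = [i for i, m in enumerate(modality) if m == SEMG]
    if not eeg_idx or not semg_idx:
        raise ConfigurationError("need both EEG and sEMG channels to fuse")
    return eeg_idx, semg_idx


def align_offline(epoch: np.ndarray, t: int, wc: WindowConfig, fs: float,
                  modality=None, label=None,
                  normalize_rows: bool = True) -> FusionWindow:
    """Offline alignment: EEG at [t, t+L), sEMG delayed by the lag.

    ``epoch`` is a (channels x T) matrix and ``modality`` tags each
    row.  With ``normalize_rows`` each extracted row is min-max scaled
    within its window; pass ``False`` when the epoch was already
    normalized at a wider scope (see :func:`build_dataset`).
    """
    epoch = np.asarray(epoch, dtype=float)
    C, T = epoch.shape
    if modality is None:
        raise ConfigurationError("modality tags are required")
    lag = wc.lag_samples(fs)
    if t < 0 or t + wc.L + lag > T:
        raise BoundaryError(
            f"window [{t}, {t + wc.L}) + lag {lag} exceeds epoch length {T}")
    eeg_idx, semg_idx = _split_indices(modality)
    eeg = epoch[eeg_idx, t:t + wc.L]
    semg = epoch[semg_idx, t + lag:t + lag + wc.L]
    if normalize_rows:
        eeg, semg = _normalize_rows(eeg), _normalize_rows(semg)
    matrix = np.vstack([eeg, semg])
    return FusionWindow(matrix, (t, t + wc.L), (t + lag, t + lag + wc.L),
                        label=label)


def align_online(buffer: np.ndarray, wc: WindowConfig, fs: float,
                 modality=None, label=None,
                 normalize_rows: bool = True) -> FusionWindow:
    """Online alignment: sEMG takes the freshest L samples of the buffer,
    EEG the L samples ending ``lag`` before the buffer end."""
    buffer = np.asarray(buffer, dtype=float)
    C, T = buffer.shape
    if modality is None:
        raise ConfigurationError("modality tags are required")
    lag = wc.lag_samples(fs)
    if T < wc.L + lag:
        raise BoundaryError(
            f"buffer length {T} shorter than L + lag = {wc.L + lag}")
    eeg_idx, semg_idx = _split_indices(modality)
    semg = buffer[semg_idx, T - wc.L:T]
    eeg = buffer[eeg_idx, T - wc.L - lag:T - lag]
    if normalize_rows:
        eeg, semg = _normalize_rows(eeg), _normalize_rows(semg)
    matrix = np.vstack([eeg, semg])
    return FusionWindow(matrix, (T - wc.L - lag, T - lag), (T - wc.L, T),
                        label=label)


@dataclass
class FusionDataset:
    """Windowed, labeled dataset ready for the decoder.

    ``X`` is (n, channels, L) for data fusion or (n, n_features) for
    feature fusion; ``groups`` maps each window back to its source
    epoch so cross-validation can keep an epoch's windows together.
    """

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    mode: str
    fs: float
    window: WindowConfig
    n_dropped: int = 0

    def __len__(self):
        return self.X.shape[0]


def _feature_vector(win: FusionWindow, n_eeg: int, fs: float) -> np.ndarray:
    eeg_rows = win.matrix[:n_eeg]
    semg_rows = win.matrix[n_eeg:]
    ef = [eeg_features(r, fs, adapt_level=True) for r in eeg_rows]
    sf = [semg_features(r, fs) for r in semg_rows]
    return fuse_features(ef, sf)


def build_dataset(epochs: EpochSet, wc: WindowConfig, mode: str = "data",
                  compensate: bool = True) -> FusionDataset:
    """Slide lag-compensated windows over every epoch.

    ``mode="data"`` emits the normalized FusionWindow matrices;
    ``mode="feature"`` emits cascaded feature vectors computed on the
    aligned spans.  ``compensate=False`` forces dT = 0 (both spans
    identical), which is the uncompensated baseline.  Window starts
    whose compensated sEMG span would leave the epoch are dropped and
    counted in ``n_dropped``.

    Normalization is per modality, per epoch: each epoch's EEG block
    and sEMG block are min-max scaled to [-1, 1] as wholes before
    windowing, so the relative amplitudes of the channels within a
    modality — which carry the activation pattern — survive in every
    window.
    """
    if mode not in ("data", "feature"):
        raise ConfigurationError("mode must be 'data' or 'feature'")
    wc_eff = wc if compensate else WindowConfig(wc.L, wc.step, 0.0)
    lag = wc_eff.lag_samples(epochs.fs)
    T = epochs.n_samples
    eeg_idx, semg_idx = _split_indices(epochs.modality)
    n_eeg = len(eeg_idx)
    X, y, groups = [], [], []
    n_dropped = 0
    for gi in range(len(epochs)):
        epoch = epochs.epochs[gi].copy()
        for idx in (eeg_idx, semg_idx):
            block = epoch[idx]
            if block.max() > block.min():
                epoch[idx] = (2.0 * (block - block.min())
                              / (block.max() - block.min()) - 1.0)
        label = int(epochs.labels[gi])
        for t in range(0, T - wc_eff.L + 1, wc_eff.step):
            if t + wc_eff.L + lag > T:
                n_dropped += 1
                continue
            win = align_offline(epoch, t, wc_eff, epochs.fs,
                                modality=epochs.modality, label=label,
                                normalize_rows=False)
            if mode == "data":
                X.append(win.matrix)
            else:
                X.append(_feature_vector(win, n_eeg, epochs.fs))
            y.append(label)
            groups.append(gi)
    if n_dropped:
        logger.info("dropped %d window(s) whose compensated span left the epoch",
                    n_dropped)
    return FusionDataset(np.asarray(X, dtype=float), np.asarray(y, dtype=int),
                         np.asarray(groups, dtype=int), mode, epochs.fs,
                         wc_eff, n_dropped)
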