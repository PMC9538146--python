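"""End-to-end offline pipeline and simulated-online replay.

The offline pipeline chains simulate/load -> filter -> (optional)
TE-based lag estimation -> lag-compensated dataset construction ->
k-fold CNN-LSTM evaluation, logging the resolved configuration and the
dropped-window count of every stage.  The online replay slides an
acquisition buffer over a continuous recording and emits one label per
step using the online (buffer-end) alignment convention.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from . import io
from .coupling import SymbolizerConfig, te_profile
from .exceptions import ConfigurationError
from .fusion import align_online, build_dataset
from .model import DecoderResults, ModelSpec, MovementDecoder
from .preprocess import (EEG, SEMG, EpochSet, Recording, WindowConfig,
                         filter_recording)
from .sim import SimConfig, simulate_movement_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One declarative document holding every stage's tunables."""

    sim: SimConfig = field(default_factory=SimConfig)
    trials_per_class: int = 10
    input_path: str = None            # NPZ EpochSet; None -> simulate
    window: WindowConfig = field(default_factory=lambda: WindowConfig(200))
    mode: str = "data"
    compensate: bool = True
    estimate_lag: bool = False        # replace window.delta_t_ms by TE argmax
    symbolizer: SymbolizerConfig = field(default_factory=SymbolizerConfig)
    u_max: int = 50
    model: ModelSpec = None
    k_folds: int = 5
    seed: int = 0

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in doc and isinstance(doc["sim"], dict):
            doc["sim"] = SimConfig(**doc["sim"])
        if "window" in doc and isinstance(doc["window"], dict):
            doc["window"] = WindowConfig(**doc["window"])
        if "symbolizer" in doc and isinstance(doc["symbolizer"], dict):
            doc["symbolizer"] = SymbolizerConfig(**doc["symbolizer"])
        if "model" in doc and isinstance(doc["model"], dict):
            doc["model"] = ModelSpec(**doc["model"])
        return cls(**doc)


def filter_epochs(epochs: EpochSet) -> EpochSet:
    """Run both modality filter chains over every epoch."""
    out = epochs.epochs.copy()
    for i in range(len(epochs)):
        rec = Recording(epochs.epochs[i], epochs.fs,
                        list(epochs.channel_names), list(epochs.modality))
        out[i] = filter_recording(rec).data
    return EpochSet(out, epochs.labels, epochs.t0_index, epochs.fs,
                    list(epochs.channel_names), list(epochs.modality))


_filter_epochs = filter_epochs


def estimate_lag_ms(epochs: EpochSet, cfg: PipelineConfig,
                    eeg_channel: int = None, semg_channel: int = None) -> float:
    """Trial-averaged symbolic-TE lag estimate in ms."""
    eeg_idx = epochs.channel_indices(EEG)
    semg_idx = epochs.channel_indices(SEMG)
    ei = eeg_idx[0] if eeg_channel is None else eeg_channel
    si = semg_idx[0] if semg_channel is None else semg_channel
    prof = te_profile(epochs.epochs[:, ei, :], epochs.epochs[:, si, :],
                      cfg.symbolizer, cfg.u_max, epochs.fs)
    logger.info("TE lag estimate: %s", prof.summary())
    return prof.argmax_ms


def run_offline_pipeline(cfg: PipelineConfig):
    """Full offline chain; returns (CrossValidationResults, info dict)."""
    logger.info("resolved config: %s", cfg)
    if cfg.input_path is not None:
        epochs = io.load_epochs(cfg.input_path)
    else:
        epochs = simulate_movement_dataset(cfg.sim, cfg.trials_per_class)
    epochs = filter_epochs(epochs)
    window = cfg.window
    info = {"n_epochs": len(epochs)}
    if cfg.estimate_lag:
        window = WindowConfig(window.L, window.step,
                              estimate_lag_ms(epochs, cfg))
        info["estimated_delta_t_ms"] = window.delta_t_ms
    ds = build_dataset(epochs, window, mode=cfg.mode,
                       compensate=cfg.compensate)
    info["n_windows"] = len(ds)
    info["n_dropped"] = ds.n_dropped
    spec = cfg.model or ModelSpec(n_classes=len(np.unique(ds.y)))
    report = MovementDecoder.from_dataset(ds, spec).fit_kfold(
        k=cfg.k_folds, seed=cfg.seed)
    logger.info("evaluation: %s", report.summary())
    return report, info


def run_online_sim(results: DecoderResults, stream: Recording,
                   wc: WindowConfig, step: int = None):
    """Replay a continuous recording through the online alignment.

    Slides a buffer over ``stream`` with hop ``step`` (default
    ``wc.step``), applies buffer-end alignment at every position and
    returns (timestamps_s, labels); positions whose buffer is still
    shorter than L + lag are skipped.
    """
    step = step or wc.step
    lag = wc.lag_samples(stream.fs)
    need = wc.L + lag
    filtered = filter_recording(stream)
    eeg_idx = filtered.channel_indices(EEG)
    semg_idx = filtered.channel_indices(SEMG)
    context = int(round(4 * stream.fs))   # normalization context, samples
    times, labels = [], []
    for end in range(need, stream.n_samples + 1, step):
        buf = filtered.data[:, max(0, end - context):end].copy()
        # per-modality min-max over the buffer, matching the offline
        # per-epoch normalization scope
        for idx in (eeg_idx, semg_idx):
            block = buf[idx]
            if block.max() > block.min():
                buf[idx] = (2.0 * (block - block.min())
                            / (block.max() - block.min()) - 1.0)
        win = align_online(buf, wc, stream.fs,
                           modality=stream.modality, normalize_rows=False)
        pred = results.predict(win.matrix[None, :, :])
        times.append(end / stream.fs)
        labels.append(int(pred[0]))
    return np.asarray(times), np.asarray(labels, dtype=int)
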