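"""NPZ / CSV / EDF round-tripping for recordings, epochs and datasets."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .fusion import FusionDataset
from .preprocess import EpochSet, Recording, WindowConfig


def save_recording(path, rec: Recording) -> None:
    np.savez(path, data=rec.data, fs=rec.fs,
             channel_names=np.array(rec.channel_names),
             modality=np.array(rec.modality))


def load_recording(path) -> Recording:
    with np.load(path, allow_pickle=False) as z:
        return Recording(z["data"], float(z["fs"]),
                         [str(s) for s in z["channel_names"]],
                         [str(s) for s in z["modality"]])


def save_epochs(path, ep: EpochSet) -> None:
    np.savez(path, epochs=ep.epochs, labels=ep.labels,
             t0_index=ep.t0_index, fs=ep.fs,
             channel_names=np.array(ep.channel_names),
             modality=np.array(ep.modality))


def load_epochs(path) -> EpochSet:
    with np.load(path, allow_pickle=False) as z:
        return EpochSet(z["epochs"], z["labels"], int(z["t0_index"]),
                        float(z["fs"]),
                        [str(s) for s in z["channel_names"]],
                        [str(s) for s in z["modality"]])


def epochs_to_csv(path, ep: EpochSet) -> None:
    """Long-format CSV: trial, channel, sample_index, value, label."""
    n, c, t = ep.epochs.shape
    trial = np.repeat(np.arange(n), c * t)
    chan = np.tile(np.repeat(np.arange(c), t), n)
    samp = np.tile(np.arange(t), n * c)
    df = pd.DataFrame({
        "trial": trial,
        "channel": np.asarray(ep.channel_names)[chan],
        "sample_index": samp,
        "value": ep.epochs.ravel(),
        "label": np.asarray(ep.labels)[trial],
    })
    df.to_csv(path, index=False)


def epochs_from_csv(path, fs: float, t0_index: int,
                    modality_map: dict) -> EpochSet:
    """Inverse of :func:`epochs_to_csv`; ``modality_map`` assigns each
    channel name its modality tag."""
    df = pd.read_csv(path)
    channels = list(dict.fromkeys(df["channel"]))
    trials = sorted(df["trial"].unique())
    t = df["sample_index"].max() + 1
    epochs = np.empty((len(trials), len(channels), t))
    labels = np.empty(len(trials), dtype=int)
    piv = df.set_index(["trial", "channel", "sample_index"])["value"].sort_index()
    for i, tr in enumerate(trials):
        labels[i] = df.loc[df["trial"] == tr, "label"].iloc[0]
        for j, ch in enumerate(channels):
            epochs[i, j] = piv.loc[(tr, ch)].to_numpy()
    modality = [modality_map[ch] for ch in channels]
    return EpochSet(epochs, labels, t0_index, fs, channels, modality)


def save_dataset(path, ds: FusionDataset) -> None:
    np.savez(path, X=ds.X, y=ds.y, groups=ds.groups,
             mode=ds.mode, fs=ds.fs, L=ds.window.L, step=ds.window.step,
             delta_t_ms=ds.window.delta_t_ms, n_dropped=ds.n_dropped)


def load_dataset(path) -> FusionDataset:
    with np.load(path, allow_pickle=False) as z:
        wc = WindowConfig(int(z["L"]), int(z["step"]), float(z["delta_t_ms"]))
        return FusionDataset(z["X"], z["y"], z["groups"], str(z["mode"]),
                             float(z["fs"]), wc, int(z["n_dropped"]))


def read_edf(path, modality_map: dict) -> Recording:
    """Read an EDF file into a :class:`Recording`.

    ``modality_map`` maps channel labels to ``"EEG"``/``"sEMG"``;
    unmapped channels are dropped.  Requires the optional ``mne``
    dependency.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ConfigurationError(
            "EDF import requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    keep = [ch for ch in raw.ch_names if ch in modality_map]
    if not keep:
        raise ConfigurationError("no EDF channel matches the modality map")
    raw.pick(keep)
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(data, float(raw.info["sfreq"]), keep,
                     [modality_map[ch] for ch in keep])


def report_to_json(path, report, extra: dict = None) -> None:
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
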