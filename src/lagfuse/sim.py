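"""Synthetic coupled EEG/sEMG generator with a known conduction delay.

Real corticomuscular recordings carry a directed, lagged coupling: the
cortical drive measurable in the EEG precedes the muscle activity
measurable in the sEMG by the nerve-conduction plus neuromuscular-
junction time.  The generator reproduces exactly that structure with a
configurable ground-truth lag so every downstream stage (lag
estimation, compensated alignment, decoding) can be validated without
recorded data:

* a latent *driver* — band-limited (0.5-64 Hz) Gaussian noise —
  stands in for the cortical drive and appears (noisily) in the EEG
  channels;
* the sEMG channels are wide-band (20-200 Hz) Gaussian carriers whose
  amplitude envelope is the rectified, delayed driver
  ``max(1 + g * driver(t - lag), 0)``;
* 50 Hz line interference and additive measurement noise are applied
  to all channels; the coupling SNR is stated in dB on the
  envelope-modulation component versus the additive noise power.

For movement datasets, each class activates a distinct subset of EEG
and sEMG channels and modulates the activation envelope at a
class-specific frequency; the sEMG activation starts exactly ``lag``
samples after the EEG drive changes, with the detected-onset convention
placing the sEMG onset at the trial midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import ConfigurationError
from .preprocess import EEG, SEMG, EpochSet, Recording

#: fixed seed for the class -> channel-pattern assignment; patterns are a
#: property of the task definition, not of an individual simulated run.
_PATTERN_SEED = 986233

#: modulation depth of the driver on the sEMG envelope
_MOD_DEPTH = 1.0

#: amplitude of the preparatory (pre-onset) cortical activity relative to
#: the movement drive
_PREP_AMP = 1.0

#: tonic floor of the activation envelope during movement; the rhythmic
#: class-frequency modulation rides on top of it
_TONIC = 0.35


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults mirror the acquisition setup the package targets: 1,024 Hz
    sampling, 9 EEG + 4 sEMG channels, 4 s trials (-2 .. +2 s around
    onset), 8 movement classes, and an EEG->sEMG conduction delay of
    35 samples (~34 ms).
    """

    fs: float = 1024.0
    n_eeg: int = 9
    n_semg: int = 4
    lag: int = 35
    snr_db: float = 5.0
    line_amp: float = 0.05
    n_classes: int = 8
    trial_len_s: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if self.lag < 0:
            raise ConfigurationError("lag must be >= 0")
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if self.n_eeg < 1 or self.n_semg < 1:
            raise ConfigurationError("need at least one channel per modality")
        n = self.trial_len_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("trial_len_s * fs must be an integer")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_len_s * self.fs))


def _bandlimited_noise(rng, n, band, fs):
    lo, hi = band
    x = signal.sosfiltfilt(
        signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos"),
        rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _line(n, fs, amp, phase):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * 50.0 * t + phase)


def _channel_names(cfg: SimConfig):
    eeg = ["FC1", "FC2", "FC5", "FC6", "Cz", "C3", "C4", "CP1", "CP2"]
    semg = ["VM", "BF", "LG", "TA"]  # vastus med., biceps fem., lat. gastroc., tib. ant.
    names = [eeg[i] if i < len(eeg) else f"EEG{i}" for i in range(cfg.n_eeg)]
    names += [semg[i] if i < len(semg) else f"sEMG{i}" for i in range(cfg.n_semg)]
    return names


def class_patterns(cfg: SimConfig):
    """Per-class binary activation masks and envelope frequencies.

    Masks are pairwise distinct, contain at least one active channel per
    modality, and are a deterministic function of the channel counts and
    class count alone (independent of ``cfg.seed``).
    """
    if cfg.n_classes > 2 ** cfg.n_semg - 1 or cfg.n_classes > 2 ** cfg.n_eeg - 1:
        raise ConfigurationError(
            "not enough distinct non-empty channel masks for the class count")
    rng = np.random.default_rng(_PATTERN_SEED)
    masks = []
    seen_e, seen_s = set(), set()
    while len(masks) < cfg.n_classes:
        e = rng.integers(0, 2, size=cfg.n_eeg)
        s = rng.integers(0, 2, size=cfg.n_semg)
        # masks pairwise distinct within each modality so either modality
        # alone identifies the class
        if e.sum() == 0 or s.sum() == 0:
            continue
        if tuple(e) in seen_e or tuple(s) in seen_s:
            continue
        seen_e.add(tuple(e))
        seen_s.add(tuple(s))
        masks.append((e.astype(float), s.astype(float)))
    freqs = 2.0 + 0.75 * np.arange(cfg.n_classes)  # Hz, distinct per class
    return masks, freqs


def _noise_std(signal_rms: float, snr_db: float) -> float:
    return signal_rms * 10.0 ** (-snr_db / 20.0)


def simulate_coupled_pair(cfg: SimConfig) -> Recording:
    """One continuous recording with stationary lagged coupling.

    Every EEG channel carries the latent driver plus independent noise;
    every sEMG channel is an independent 20-200 Hz carrier modulated by
    the driver delayed by exactly ``cfg.lag`` samples.  Reproducible:
    identical configs give bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    lag = cfg.lag
    z = _bandlimited_noise(rng, n + lag, (0.5, 64.0), cfg.fs)
    # x(t) sees z at t + lag; y(t) sees z at t  =>  y lags x by `lag`
    z_eeg = z[lag:lag + n]
    z_semg = z[:n]
    env = np.maximum(1.0 + _MOD_DEPTH * z_semg, 0.0)

    data = np.empty((cfg.n_eeg + cfg.n_semg, n))
    nstd_eeg = _noise_std(z_eeg.std(), cfg.snr_db)
    for j in range(cfg.n_eeg):
        noise = _bandlimited_noise(rng, n, (0.5, 64.0), cfg.fs) * nstd_eeg
        data[j] = z_eeg + noise + _line(n, cfg.fs, cfg.line_amp,
                                        rng.uniform(0, 2 * np.pi))
    for k in range(cfg.n_semg):
        carrier = _bandlimited_noise(rng, n, (20.0, 200.0), cfg.fs)
        clean = carrier * env
        mod = clean - carrier  # coupling-borne component
        nstd = _noise_std(mod.std(), cfg.snr_db)
        noise = rng.standard_normal(n) * nstd
        data[cfg.n_eeg + k] = clean + noise + _line(n, cfg.fs, cfg.line_amp,
                                                    rng.uniform(0, 2 * np.pi))
    modality = [EEG] * cfg.n_eeg + [SEMG] * cfg.n_semg
    return Recording(data, cfg.fs, _channel_names(cfg), modality)


def _simulate_trial(cfg: SimConfig, label: int, rng,
                    masks, freqs) -> np.ndarray:
    n = cfg.n_samples
    lag = cfg.lag
    t0 = n // 2                       # sEMG onset at trial midpoint
    eeg_on = t0 - lag                 # EEG drive changes `lag` samples earlier
    e_mask, s_mask = masks[label]
    f_c = freqs[label]

    z = _bandlimited_noise(rng, n + lag, (0.5, 64.0), cfg.fs)

    # activation envelope, indexed in *driver time*: 0 at rest; once the
    # drive turns on, tonic activity plus a raised-cosine oscillation at
    # the class frequency (sustained movement keeps the muscle tonically
    # active, rhythmically modulated)
    tt = np.arange(n + lag, dtype=float)
    tau = (tt - (eeg_on + lag)) / cfg.fs   # driver-time onset aligns w/ eeg_on
    osc = 0.5 * (1 - np.cos(2 * np.pi * f_c * tau))
    act = np.where(tau >= 0, _TONIC + (1 - _TONIC) * osc, 0.0)

    drive = z * act                  # modulated cortical drive (driver time)
    drive_eeg = drive[lag:lag + n]   # EEG sees it immediately -> onset eeg_on
    drive_semg = drive[:n]           # sEMG sees it `lag` samples later -> t0

    # preparatory cortical activity: class-masked, class-frequency
    # oscillation ramping up over the 1.5 s before the drive onset
    # (readiness activity precedes the muscular response by seconds);
    # it stays cortical — nothing of it reaches the muscle channels
    prep_len = min(eeg_on, int(round(1.5 * cfg.fs)))
    prep_start = eeg_on - prep_len
    rise = min(prep_len, int(round(0.5 * cfg.fs)))
    t_loc = np.arange(n, dtype=float)
    ramp = np.clip((t_loc - prep_start) / max(rise, 1), 0.0, 1.0)
    ramp[t_loc >= eeg_on] = 1.0
    tau_p = (t_loc - prep_start) / cfg.fs
    osc_p = np.where(
        tau_p >= 0,
        _TONIC + (1 - _TONIC) * 0.5 * (1 - np.cos(2 * np.pi * f_c * tau_p)),
        0.0)
    z_prep = _bandlimited_noise(rng, n, (0.5, 64.0), cfg.fs)
    prep = _PREP_AMP * ramp * osc_p * z_prep

    data = np.empty((cfg.n_eeg + cfg.n_semg, n))
    ref_rms = np.sqrt(np.mean(drive_eeg[eeg_on:] ** 2)) or 1.0
    nstd_eeg = _noise_std(ref_rms, cfg.snr_db)
    for j in range(cfg.n_eeg):
        noise = _bandlimited_noise(rng, n, (0.5, 64.0), cfg.fs) * nstd_eeg
        data[j] = e_mask[j] * (drive_eeg + prep) + noise + _line(
            n, cfg.fs, cfg.line_amp, rng.uniform(0, 2 * np.pi))

    env = act[:n] * np.maximum(1.0 + _MOD_DEPTH * z[:n], 0.0)
    for k in range(cfg.n_semg):
        carrier = _bandlimited_noise(rng, n, (20.0, 200.0), cfg.fs)
        clean = s_mask[k] * carrier * env
        mod_rms = np.sqrt(np.mean((carrier * env)[t0:] ** 2)) or 1.0
        nstd = _noise_std(mod_rms, cfg.snr_db)
        data[cfg.n_eeg + k] = clean + rng.standard_normal(n) * nstd + _line(
            n, cfg.fs, cfg.line_amp, rng.uniform(0, 2 * np.pi))
    return data


def simulate_movement_dataset(cfg: SimConfig,
                              trials_per_class: int) -> EpochSet:
    """Class-balanced labeled epochs with lag-structured activation.

    Each class has a fixed, distinct channel-activation pattern and
    envelope frequency (:func:`class_patterns`); the sEMG activation
    onset sits at the trial midpoint, exactly ``cfg.lag`` samples after
    the EEG drive onset.
    """
    if trials_per_class < 1:
        raise ConfigurationError("trials_per_class must be >= 1")
    masks, freqs = class_patterns(cfg)
    rng = np.random.default_rng(cfg.seed)
    epochs, labels = [], []
    for c in range(cfg.n_classes):
        for _ in range(trials_per_class):
            epochs.append(_simulate_trial(cfg, c, rng, masks, freqs))
            labels.append(c)
    modality = [EEG] * cfg.n_eeg + [SEMG] * cfg.n_semg
    return EpochSet(np.stack(epochs), np.asarray(labels, dtype=int),
                    cfg.n_samples // 2, cfg.fs,
                    _channel_names(cfg), modality)
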