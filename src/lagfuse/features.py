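"""EEG wavelet-packet features, sEMG time/frequency features, and the
cascaded feature-fusion vector.

EEG channels are decimated to 128 Hz and decomposed with a full
wavelet-packet tree (Daubechies-4, 5 layers by default), whose
frequency-ordered leaves tile 0-64 Hz in 2 Hz strips.  Leaves are
aggregated into the classic delta (0-4 Hz), theta (4-8 Hz), alpha
(8-12 Hz) and beta (12-32 Hz) bands by leaf center frequency, and each
band contributes its coefficient variance and relative energy.  (The
nominal 13-30 Hz beta band cannot be hit exactly on a dyadic 2 Hz grid;
the 12-32 Hz aggregate is the closest dyadic cover.)

sEMG channels contribute six per-channel statistics: variance (VAR),
slope-sign changes (SSC), zero crossings (ZC), root mean square (RMS),
mean power frequency (MPF) and the leading Fourier cepstrum
coefficients (FCC).

The fusion vector cascades the per-channel EEG blocks then the
per-channel sEMG blocks in fixed channel order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import fft as sfft
from scipy import signal

from .exceptions import ConfigurationError, DegenerateInputError, ShapeError

#: named EEG bands (Hz) on the dyadic leaf grid
EEG_BANDS = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 32.0),
}

EEG_WPT_FS = 128.0
DEFAULT_WAVELET = "db4"
DEFAULT_LAYERS = 5
N_FCC = 4
SSC_EPS = 0.01


# ---------------------------------------------------------------------------
# wavelet packet transform


@dataclass
class WptTree:
    """Full wavelet-packet tree with frequency-ordered leaves.

    ``leaves[i]`` holds the coefficient sequence of the i-th leaf in
    *frequency* order (not the natural Paley order of the recursion),
    so leaf ``i`` covers the band ``[i, i+1) * fs / 2^(J+1)`` Hz.
    """

    leaves: list
    layers: int
    wavelet: str
    fs: float

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def leaf_band(self, i: int) -> tuple:
        width = self.fs / 2.0 / self.n_leaves
        return (i * width, (i + 1) * width)

    def leaf_energies(self) -> np.ndarray:
        return np.array([float(np.sum(c * c)) for c in self.leaves])

    def reconstruct(self) -> np.ndarray:
        n = len(self.leaves[0]) * 2 ** self.layers
        wp = pywt.WaveletPacket(data=np.zeros(n), wavelet=self.wavelet,
                                mode="periodization", maxlevel=self.layers)
        for node, coeffs in zip(wp.get_level(self.layers, order="freq"),
                                self.leaves):
            wp[node.path] = coeffs
        return np.asarray(wp.reconstruct(update=False))


def wpt_decompose(x, J: int = DEFAULT_LAYERS,
                  wavelet: str = DEFAULT_WAVELET,
                  fs: float = EEG_WPT_FS) -> WptTree:
    """Full binary wavelet-packet decomposition to layer ``J``.

    Zero-padding boundary mode keeps the transform orthogonal so leaf
    energies sum to the signal energy.  Requires ``len(x) >= 2**J``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ShapeError("input must be 1-D")
    if x.size < 2 ** J:
        raise ConfigurationError(
            f"need at least 2^{J} = {2 ** J} samples, got {x.size}")
    wp = pywt.WaveletPacket(data=x, wavelet=wavelet, mode="periodization",
                            maxlevel=J)
    leaves = [np.asarray(node.data, dtype=float)
              for node in wp.get_level(J, order="freq")]
    return WptTree(leaves, J, wavelet, fs)


# ---------------------------------------------------------------------------
# EEG features


@dataclass
class EegFeature:
    """Per-band WPT statistics of one EEG channel."""

    band_variances: dict
    band_energies: dict          # relative: E_band / E_tot
    leaf_energies: np.ndarray = field(repr=False, default=None)
    bands: tuple = tuple(EEG_BANDS)

    def as_vector(self) -> np.ndarray:
        return np.array([self.band_variances[b] for b in self.bands]
                        + [self.band_energies[b] for b in self.bands])

    @property
    def relative_leaf_energies(self) -> np.ndarray:
        tot = self.leaf_energies.sum()
        return self.leaf_energies / tot


def _decimate_to(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Integer-factor decimation; assumes the caller already band-limited
    the input below the target Nyquist (the 0.5-64 Hz EEG band-pass)."""
    factor = fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ConfigurationError(
            f"fs {fs} is not an integer multiple of {target_fs}")
    return x[::int(round(factor))]


def eeg_features(x, fs: float, J: int = DEFAULT_LAYERS,
                 wavelet: str = DEFAULT_WAVELET,
                 adapt_level: bool = False) -> EegFeature:
    """Band variances and relative band energies of one EEG channel.

    The channel is decimated to 128 Hz, decomposed with a ``J``-layer
    WPT, and the frequency-ordered leaves are pooled into the named
    bands by leaf center frequency.  With ``adapt_level=True`` the layer
    count is reduced to what the (short) window supports instead of
    raising; band resolution degrades accordingly.
    """
    x = np.asarray(x, dtype=float)
    if fs < EEG_WPT_FS:
        raise ConfigurationError("fs must be >= 128 Hz")
    xd = _decimate_to(x, fs, EEG_WPT_FS) if fs > EEG_WPT_FS else x
    if not np.any(xd):
        raise DegenerateInputError("all-zero input has no defined energies")
    if adapt_level:
        J = min(J, max(1, int(np.floor(np.log2(xd.size)))))
    tree = wpt_decompose(xd, J=J, wavelet=wavelet, fs=EEG_WPT_FS)
    energies = tree.leaf_energies()
    e_tot = energies.sum()
    variances, rel = {}, {}
    for name, (lo, hi) in EEG_BANDS.items():
        idx = [i for i in range(tree.n_leaves)
               if lo <= np.mean(tree.leaf_band(i)) < hi]
        if idx:
            cat = np.concatenate([tree.leaves[i] for i in idx])
            variances[name] = float(np.mean(np.abs(cat) ** 2))
            rel[name] = float(energies[idx].sum() / e_tot)
        else:
            variances[name] = 0.0
            rel[name] = 0.0
    return EegFeature(variances, rel, leaf_energies=energies)


# ---------------------------------------------------------------------------
# sEMG features


def _check_semg(x, min_len=3) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < min_len:
        raise DegenerateInputError(f"need a 1-D sequence of length >= {min_len}")
    return x


def semg_var(x) -> float:
    """Sample variance with the 1/(N-1) convention."""
    x = _check_semg(x, 2)
    return float(np.var(x, ddof=1))


def semg_ssc(x, eps: float = SSC_EPS) -> int:
    """Count of slope-sign changes exceeding the threshold ``eps``.

    An interior sample k counts when ``(x_k - x_{k-1}) * (x_k - x_{k+1})``
    is >= eps (both neighbors on the same side, by at least the
    threshold product)."""
    x = _check_semg(x)
    if eps < 0:
        raise ConfigurationError("eps must be >= 0")
    d1 = x[1:-1] - x[:-2]
    d2 = x[1:-1] - x[2:]
    return int(np.count_nonzero(d1 * d2 >= eps))


def semg_zc(x) -> int:
    """Count of strict sign changes between consecutive samples."""
    x = _check_semg(x, 2)
    return int(np.count_nonzero(x[:-1] * x[1:] < 0))


def semg_rms(x) -> float:
    x = _check_semg(x, 1)
    return float(np.sqrt(np.mean(x * x)))


def semg_mpf(x, fs: float, f0: float = 200.0) -> float:
    """Power-weighted mean frequency over [0, f0] Hz.

    Spectral estimate: averaged periodogram (Welch) with segments no
    longer than the input."""
    x = _check_semg(x, 8)
    nper = min(256, x.size)
    f, p = signal.welch(x, fs=fs, nperseg=nper)
    m = f <= f0
    denom = np.trapezoid(p[m], f[m])
    if denom <= 0:
        raise DegenerateInputError("input has no power below f0")
    return float(np.trapezoid(f[m] * p[m], f[m]) / denom)


def semg_fcc(x, n_fcc: int = N_FCC) -> np.ndarray:
    """First ``n_fcc`` Fourier cepstrum coefficients.

    Cosine-transform (DCT-II) coefficients of the natural-log magnitude
    spectrum, with a small floor inside the log to keep zero bins
    finite."""
    x = _check_semg(x)
    X = np.fft.fft(x)
    Y = np.log(np.abs(X) + 1e-12)
    c = sfft.dct(Y, type=2, norm=None)
    return c[:n_fcc].astype(float)


@dataclass
class SemgFeature:
    """The six per-channel sEMG statistics."""

    var: float
    ssc: int
    zc: int
    rms: float
    mpf: float
    fcc: np.ndarray

    def as_vector(self) -> np.ndarray:
        return np.concatenate([[self.var, self.ssc, self.zc, self.rms,
                                self.mpf], np.asarray(self.fcc, dtype=float)])


def semg_features(x, fs: float, eps: float = SSC_EPS,
                  f0: float = 200.0, n_fcc: int = N_FCC) -> SemgFeature:
    """All six sEMG statistics of one channel window."""
    x = _check_semg(x, 8)
    return SemgFeature(
        var=semg_var(x), ssc=semg_ssc(x, eps), zc=semg_zc(x),
        rms=semg_rms(x), mpf=semg_mpf(x, fs, f0), fcc=semg_fcc(x, n_fcc))


# ---------------------------------------------------------------------------
# cascade


def fuse_features(eeg_feats, semg_feats) -> np.ndarray:
    """Cascade per-channel EEG blocks then per-channel sEMG blocks.

    Output length = M * len(EEG block) + K * len(sEMG block); channel
    order is preserved, so permuting the inputs permutes the blocks.
    """
    eeg_feats = list(eeg_feats)
    semg_feats = list(semg_feats)
    if not eeg_feats or not semg_feats:
        raise ShapeError("need at least one channel block per modality")
    eeg_vecs = [f.as_vector() if hasattr(f, "as_vector") else np.asarray(f, float)
                for f in eeg_feats]
    semg_vecs = [f.as_vector() if hasattr(f, "as_vector") else np.asarray(f, float)
                 for f in semg_feats]
    for vecs in (eeg_vecs, semg_vecs):
        if len({v.shape for v in vecs}) > 1:
            raise ShapeError("per-channel feature blocks must agree in length")
    return np.concatenate(eeg_vecs + semg_vecs)


def feature_names(n_eeg: int, n_semg: int, n_fcc: int = N_FCC) -> list:
    """Column names matching :func:`fuse_features` ordering."""
    names = []
    for ch in range(n_eeg):
        names += [f"eeg_{ch}_{band}_{stat}"
                  for stat in ("var", "energy") for band in EEG_BANDS]
    for ch in range(n_semg):
        names += [f"semg_{ch}_{feat}" for feat in ("var", "ssc", "zc", "rms", "mpf")]
        names += [f"semg_{ch}_fcc{i}" for i in range(n_fcc)]
    return names
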