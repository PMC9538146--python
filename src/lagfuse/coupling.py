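"""Corticomuscular lag estimation.

Two independent routes to the EEG->sEMG response-time difference:

1. a physiological bound from conduction distance, motor-nerve
   conduction velocity and the neuromuscular-junction conversion time
   (:func:`physio_delta_t`), and
2. a data-driven estimate from symbolic transfer entropy: both signals
   are amplitude-quantized into ``Ps + 1`` uniform bins, the plug-in
   transfer entropy TE(x -> y) is evaluated over a range of time steps
   ``u``, and the lag is read off as the ``u`` that maximizes the
   (trial-averaged) profile (:func:`te_profile`).

Transfer entropy here is the conditional mutual information
``I(y_{i+u}; x_i | y_i)`` estimated by joint relative frequencies over
all valid triplets, in bits.  It is model-free and directed, which is
why it is preferred over coherence for this asymmetric coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DegenerateInputError, ShapeError

__all__ = [
    "SymbolizerConfig", "SymbolSequence", "TEProfile", "PhysioParams",
    "DeltaTEstimate", "symbolize", "transfer_entropy", "te_profile",
    "physio_delta_t",
]


@dataclass
class SymbolizerConfig:
    """Uniform amplitude quantizer with ``Ps + 1`` bins.

    The bin width is ``delta = (max - min) / (Ps + 1)``; larger ``Ps``
    means a finer partition.  Default Ps = 30.
    """

    Ps: int = 30

    def __post_init__(self):
        if self.Ps < 2:
            raise ConfigurationError("Ps must be >= 2")


@dataclass
class SymbolSequence:
    symbols: np.ndarray
    alphabet_size: int
    source_len: int

    def __post_init__(self):
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.ndim != 1:
            raise ShapeError("symbols must be 1-D")
        if len(self.symbols) != self.source_len:
            raise ShapeError("symbol sequence must match source length")
        if self.symbols.size and (self.symbols.min() < 0
                                  or self.symbols.max() >= self.alphabet_size):
            raise ShapeError("symbol codes out of range")

    def __len__(self):
        return self.source_len


def symbolize(x, cfg: SymbolizerConfig = SymbolizerConfig()) -> SymbolSequence:
    """Quantize ``x`` into ``Ps + 1`` uniform amplitude bins.

    Codes are categorical labels 0..Ps (bin index from the minimum);
    the sample equal to the maximum falls in the last bin.  Any affine
    relabeling of the codes leaves every entropy downstream unchanged,
    so the labels carry no sign convention.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DegenerateInputError("need a 1-D sequence of length >= 2")
    mn, mx = x.min(), x.max()
    if mx == mn:
        raise DegenerateInputError("constant sequence cannot be symbolized")
    delta = (mx - mn) / (cfg.Ps + 1)
    codes = np.minimum(np.floor((x - mn) / delta).astype(np.int64), cfg.Ps)
    return SymbolSequence(codes, cfg.Ps + 1, len(x))


def _empirical_te(sx: np.ndarray, sy: np.ndarray, u: int, A: int) -> float:
    """Plug-in TE over triplets (y_{i+u}, y_i, x_i), base-2."""
    yp = sy[u:]
    y0 = sy[:-u]
    x0 = sx[:-u]
    n = yp.size
    code = (yp * A + y0) * A + x0
    states, counts = np.unique(code, return_counts=True)
    p = counts / n
    ypc = states // (A * A)
    y0c = (states // A) % A
    x0c = states % A

    def marginal(sub):
        _, inv = np.unique(sub, return_inverse=True)
        tot = np.bincount(inv, weights=counts)
        return tot[inv] / n

    p_y = marginal(y0c)
    p_yy = marginal(ypc * A + y0c)
    p_yx = marginal(y0c * A + x0c)
    return float(np.sum(p * np.log2(p * p_y / (p_yy * p_yx))))


def transfer_entropy(sx: SymbolSequence, sy: SymbolSequence, u: int) -> float:
    """Plug-in transfer entropy TE(x -> y) at time step ``u``, in bits.

    All probabilities are joint relative frequencies over the same
    triplet sample, which makes the estimate a conditional mutual
    information and hence non-negative up to rounding.  Zero-count
    states contribute nothing (0 * log 0 = 0 by construction).
    """
    if len(sx) != len(sy):
        raise ShapeError("sequences must have equal length")
    if not (1 <= u < len(sy)):
        raise ValueError(f"u must satisfy 1 <= u < N, got {u}")
    A = max(sx.alphabet_size, sy.alphabet_size)
    return _empirical_te(sx.symbols, sy.symbols, u, A)


@dataclass
class TEProfile:
    """Transfer entropy as a function of the time step ``u``.

    ``argmax_u`` is the profile's peak location in samples;
    ``argmax_ms`` its conversion via the sampling rate.
    """

    u_values: np.ndarray
    te_values: np.ndarray
    fs: float
    n_trials: int = 1

    def __post_init__(self):
        self.u_values = np.asarray(self.u_values, dtype=int)
        self.te_values = np.asarray(self.te_values, dtype=float)
        if self.u_values.shape != self.te_values.shape:
            raise ShapeError("u_values and te_values must align")

    @property
    def argmax_u(self) -> int:
        return int(self.u_values[int(np.argmax(self.te_values))])

    @property
    def argmax_ms(self) -> float:
        return 1000.0 * self.argmax_u / self.fs

    @staticmethod
    def average(profiles) -> "TEProfile":
        """Element-wise mean of several profiles on the same u grid."""
        profiles = list(profiles)
        u0 = profiles[0].u_values
        for p in profiles[1:]:
            if not np.array_equal(p.u_values, u0) or p.fs != profiles[0].fs:
                raise ShapeError("profiles must share the u grid and fs")
        te = np.mean([p.te_values for p in profiles], axis=0)
        return TEProfile(u0.copy(), te, profiles[0].fs,
                         n_trials=sum(p.n_trials for p in profiles))

    def summary(self) -> str:
        return (f"TE profile over u = {self.u_values[0]}..{self.u_values[-1]} "
                f"({self.n_trials} trial(s), fs = {self.fs:g} Hz)\n"
                f"  peak TE = {self.te_values.max():.4f} bits at "
                f"u = {self.argmax_u} samples = {self.argmax_ms:.2f} ms")

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.u_values, self.te_values)
        ax.plot([self.argmax_u], [self.te_values.max()], "ko")
        ax.set_xlabel("time step u (samples)")
        ax.set_ylabel("transfer entropy (bits)")
        return ax


def te_profile(x, y, cfg: SymbolizerConfig = SymbolizerConfig(),
               u_max: int = 50, fs: float = 1024.0) -> TEProfile:
    """Symbolic-TE profile from x to y for u = 1 .. u_max.

    ``x`` and ``y`` may be single sequences or (trials x N) stacks; with
    stacks each trial is symbolized and profiled on its own and the
    profiles are averaged element-wise, so no triplet ever straddles a
    trial boundary.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ShapeError("x and y must have the same shape")
    if u_max >= x.shape[1] // 2:
        raise ValueError("u_max must be below N/2")
    u_values = np.arange(1, u_max + 1)
    profiles = []
    for xi, yi in zip(x, y):
        sx, sy = symbolize(xi, cfg), symbolize(yi, cfg)
        te = [transfer_entropy(sx, sy, int(u)) for u in u_values]
        profiles.append(TEProfile(u_values, te, fs))
    return TEProfile.average(profiles) if len(profiles) > 1 else profiles[0]


# ---------------------------------------------------------------------------
# physiological estimate


def _as_range(v) -> tuple:
    try:
        lo, hi = v
    except TypeError:
        lo = hi = float(v)
    if lo > hi:
        raise ConfigurationError("range bounds must be ordered")
    return float(lo), float(hi)


@dataclass
class PhysioParams:
    """Parameters of the conduction-delay decomposition.

    The EEG->sEMG response-time difference decomposes as
    ``dT = -t1 + t2 + t3 + t4`` with the cortical surface potential as
    the time reference: t1 the cortex-to-scalp volume conduction, t2 the
    motor-nerve conduction time ``D_n / v``, t3 the neuromuscular-
    junction conversion, and t4 the muscle-to-skin volume conduction.
    t1 and t4 are microsecond-scale and default to zero.

    Defaults: conduction distance 1.4-1.5 m (scalp to tibialis
    anterior), velocity 60 m/s, junction delay 0.5-1.0 ms.
    """

    d_n: tuple = (1.4, 1.5)      # m, may be scalar or (lo, hi)
    v: float = 60.0              # m/s
    t3_ms: tuple = (0.5, 1.0)    # ms, may be scalar or (lo, hi)
    t1_ms: float = 0.0
    t4_ms: float = 0.0

    def __post_init__(self):
        self.d_n = _as_range(self.d_n)
        self.t3_ms = _as_range(self.t3_ms)
        if self.d_n[0] <= 0:
            raise ConfigurationError("conduction distance must be positive")
        if self.v <= 0:
            raise ConfigurationError("conduction velocity must be positive")


@dataclass
class DeltaTEstimate:
    """Physiological bounds on the response-time difference, in ms."""

    t2_ms: tuple
    delta_t_ms: tuple
    params: PhysioParams = field(repr=False, default=None)

    def summary(self) -> str:
        return (f"nerve conduction t2 = {self.t2_ms[0]:.2f}..{self.t2_ms[1]:.2f} ms; "
                f"response-time difference dT = "
                f"{self.delta_t_ms[0]:.2f}..{self.delta_t_ms[1]:.2f} ms "
                f"(rounds to {round(self.delta_t_ms[0])}~{round(self.delta_t_ms[1])} ms)")


def physio_delta_t(p: PhysioParams) -> DeltaTEstimate:
    """Evaluate ``dT = -t1 + t2 + t3 + t4`` over the parameter ranges.

    ``t2 = 1000 * D_n / v`` in ms; the bounds combine the extremes of
    the distance and junction-delay ranges.
    """
    t2 = (1000.0 * p.d_n[0] / p.v, 1000.0 * p.d_n[1] / p.v)
    lo = -p.t1_ms + t2[0] + p.t3_ms[0] + p.t4_ms
    hi = -p.t1_ms + t2[1] + p.t3_ms[1] + p.t4_ms
    return DeltaTEstimate(t2_ms=t2, delta_t_ms=(lo, hi), params=p)
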