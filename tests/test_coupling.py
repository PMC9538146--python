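"""Symbolization, transfer entropy, lag profiling, physiological bound."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lagfuse as lf
from lagfuse.coupling import (PhysioParams, SymbolizerConfig, SymbolSequence,
                              TEProfile, physio_delta_t, symbolize,
                              te_profile, transfer_entropy)
from lagfuse.exceptions import DegenerateInputError, ShapeError


def naive_te(sx, sy, u, base=2.0):
    """Independent oracle: literal triple-loop plug-in estimate."""
    trips = list(zip(sy[u:], sy[:-u], sx[:-u]))
    n = len(trips)
    te = 0.0
    for state in set(trips):
        yp, y0, x0 = state
        p = trips.count(state) / n
        py = sum(1 for t in trips if t[1] == y0) / n
        pyy = sum(1 for t in trips if t[0] == yp and t[1] == y0) / n
        pyx = sum(1 for t in trips if t[1] == y0 and t[2] == x0) / n
        te += p * np.log2(p * py / (pyy * pyx))
    return te


# ---------------------------------------------------------------------------
# symbolization


def test_symbolize_one_value_per_bin():
    s = symbolize([0.0, 1.0, 2.0, 3.0], SymbolizerConfig(Ps=3))
    assert s.alphabet_size == 4
    assert np.array_equal(s.symbols, [0, 1, 2, 3])


def test_symbolize_monotone_input_gives_monotone_codes():
    x = np.sort(np.random.default_rng(0).standard_normal(500))
    s = symbolize(x)
    assert np.all(np.diff(s.symbols) >= 0)


def test_symbolize_matches_bruteforce_binning():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(2000)
    cfg = SymbolizerConfig(Ps=30)
    s = symbolize(x, cfg)
    assert s.symbols.min() >= 0 and s.symbols.max() <= 30
    delta = (x.max() - x.min()) / 31
    edges = x.min() + delta * np.arange(1, 31)
    oracle = np.searchsorted(edges, x, side="right")
    assert np.array_equal(s.symbols, oracle)
    assert np.array_equal(np.bincount(s.symbols, minlength=31),
                          np.bincount(oracle, minlength=31))


def test_symbolize_rejects_degenerate():
    with pytest.raises(DegenerateInputError):
        symbolize(np.ones(100))
    with pytest.raises(DegenerateInputError):
        symbolize([1.0])


# ---------------------------------------------------------------------------
# transfer entropy


def seq(arr, a):
    arr = np.asarray(arr)
    return SymbolSequence(arr, a, len(arr))


def test_te_zero_for_constant_target():
    rng = np.random.default_rng(0)
    sx = seq(rng.integers(0, 4, 300), 4)
    sy = seq(np.zeros(300, dtype=int), 4)
    assert transfer_entropy(sx, sy, 3) == 0.0


def test_te_small_for_independent_sequences():
    rng = np.random.default_rng(2)
    sx = seq(rng.integers(0, 2, 100_000), 2)
    sy = seq(rng.integers(0, 2, 100_000), 2)
    assert 0 <= transfer_entropy(sx, sy, 1) < 0.01


def test_te_hand_enumerated_pair():
    """Frozen value from an exhaustive enumeration of all (y_{i+u}, y_i,
    x_i) triplet counts of a 12-sample binary pair."""
    sx = seq([0, 1, 1, 0, 1, 0, 0, 1, 1, 0, 1, 1], 2)
    sy = seq([1, 0, 1, 1, 0, 0, 1, 0, 1, 1, 0, 1], 2)
    val = transfer_entropy(sx, sy, 1)
    assert val == pytest.approx(0.534027543720656, abs=1e-12)
    assert val == pytest.approx(naive_te(list(sx.symbols), list(sy.symbols), 1),
                                abs=1e-12)


@settings(deadline=None, max_examples=30)
@given(st.integers(0, 10_000), st.integers(2, 6), st.integers(1, 5),
       st.integers(20, 120))
def test_te_matches_naive_oracle(seed, a, u, n):
    rng = np.random.default_rng(seed)
    sx = rng.integers(0, a, n)
    sy = rng.integers(0, a, n)
    fast = transfer_entropy(seq(sx, a), seq(sy, a), u)
    assert fast == pytest.approx(naive_te(list(sx), list(sy), u), abs=1e-10)
    assert fast >= -1e-12


def test_te_invariant_under_relabeling():
    rng = np.random.default_rng(7)
    a = 6
    sx = rng.integers(0, a, 800)
    sy = rng.integers(0, a, 800)
    base = transfer_entropy(seq(sx, a), seq(sy, a), 2)
    for _ in range(5):
        px, py = rng.permutation(a), rng.permutation(a)
        val = transfer_entropy(seq(px[sx], a), seq(py[sy], a), 2)
        assert val == pytest.approx(base, abs=1e-12)


def test_te_preconditions():
    s = seq(np.zeros(10, dtype=int), 2)
    with pytest.raises(ShapeError):
        transfer_entropy(s, seq(np.zeros(9, dtype=int), 2), 1)
    with pytest.raises(ValueError):
        transfer_entropy(s, s, 0)
    with pytest.raises(ValueError):
        transfer_entropy(s, s, 10)


# ---------------------------------------------------------------------------
# profiles


def test_profile_peaks_at_imposed_lag():
    """y is a noisy function of x delayed by 35 samples."""
    rng = np.random.default_rng(0)
    lag = 35
    n = 4096
    x = np.convolve(rng.standard_normal(n + lag), np.ones(8) / 8, "same")
    y = x[:n] + 0.3 * rng.standard_normal(n)
    prof = te_profile(x[lag:lag + n], y, u_max=50, fs=1024.0)
    assert 32 <= prof.argmax_u <= 38
    assert prof.argmax_ms == pytest.approx(1000.0 * prof.argmax_u / 1024.0)


def test_profile_below_shuffle_null_when_independent():
    rng = np.random.default_rng(3)
    n = 2000
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    cfg = SymbolizerConfig(Ps=5)
    prof = te_profile(x, y, cfg, u_max=10, fs=1024.0)
    nulls = []
    for _ in range(100):
        nulls.append(te_profile(rng.permutation(x), y, cfg,
                                u_max=10, fs=1024.0).te_values)
    p95 = np.percentile(np.asarray(nulls), 95)
    # independent TE values carry only plug-in bias, which the shuffle
    # null reproduces
    assert np.all(prof.te_values <= p95 * 1.5)


def test_profile_average_idempotent():
    rng = np.random.default_rng(4)
    prof = te_profile(rng.standard_normal(1000), rng.standard_normal(1000),
                      u_max=10, fs=1024.0)
    avg = TEProfile.average([prof, prof])
    assert np.allclose(avg.te_values, prof.te_values)
    assert avg.argmax_u == prof.argmax_u


def test_profile_trials_average_and_summary():
    rng = np.random.default_rng(5)
    x = rng.standard_normal((3, 1000))
    y = rng.standard_normal((3, 1000))
    prof = te_profile(x, y, u_max=5, fs=1024.0)
    assert prof.n_trials == 3
    assert "ms" in prof.summary()


# ---------------------------------------------------------------------------
# physiological estimate


def test_physio_nerve_conduction_time():
    est = physio_delta_t(PhysioParams(d_n=1.5, v=60.0, t3_ms=(0.5, 1.0)))
    assert est.t2_ms[1] == pytest.approx(25.0)


def test_physio_bounds_round_to_expected_range():
    est = physio_delta_t(PhysioParams())   # 1.4-1.5 m, 60 m/s, 0.5-1 ms
    assert round(est.delta_t_ms[0]) == 24
    assert round(est.delta_t_ms[1]) == 26


def test_physio_limits_and_validation():
    est = physio_delta_t(PhysioParams(d_n=1.5, v=1e12, t3_ms=0.0))
    assert est.delta_t_ms[0] == pytest.approx(0.0, abs=1e-6)
    assert est.delta_t_ms[1] == pytest.approx(0.0, abs=1e-6)
    with pytest.raises(Exception):
        PhysioParams(v=-1.0)
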