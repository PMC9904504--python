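"""MODWT correctness: filter identities, oracle equivalence, inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from specais.modwt import (
    MODWT,
    WaveletDecomposition,
    cascade_filter,
    max_level,
    modwt_filters,
    modwt_forward,
    modwt_inverse,
    scale_to_band,
    synthesize_scale,
)


def brute_force_modwt(x, filter_name, level):
    """Literal per-scale circular convolution with the full cascade
    filters and explicit mod-N indexing — the independent oracle for the
    pyramid implementation."""
    n = len(x)
    details = []
    g, _ = modwt_filters(filter_name)
    for j in range(1, level + 1):
        hj = cascade_filter(filter_name, j)
        w = np.zeros(n)
        for t in range(n):
            for l, c in enumerate(hj):
                w[t] += c * x[(t - l) % n]
        details.append(w)
    # scaling filter cascade: convolve upsampled g's
    a = np.array([1.0])
    for i in range(1, level + 1):
        up = np.zeros((len(g) - 1) * 2 ** (i - 1) + 1)
        up[:: 2 ** (i - 1)] = g
        a = np.convolve(a, up)
    v = np.zeros(n)
    for t in range(n):
        for l, c in enumerate(a):
            v[t] += c * x[(t - l) % n]
    return details, v


@pytest.mark.parametrize("filter_name", ["d2", "la8"])
def test_pyramid_matches_brute_force_oracle(filter_name, rng):
    x = rng.normal(size=32)
    level = 3
    dec = modwt_forward(x, filter_name, level)
    details, scaling = brute_force_modwt(x, filter_name, level)
    for j in range(level):
        np.testing.assert_allclose(dec.details[j], details[j], atol=1e-10)
    np.testing.assert_allclose(dec.scaling, scaling, atol=1e-10)


def test_haar_level1_matches_hand_convolution():
    # Eq-style direct circular convolution for the Haar pair on [1,2,3,4]
    x = np.array([1.0, 2.0, 3.0, 4.0])
    g, h = modwt_filters("d2")
    expected_w = np.array([h[0] * x[t] + h[1] * x[(t - 1) % 4] for t in range(4)])
    expected_v = np.array([g[0] * x[t] + g[1] * x[(t - 1) % 4] for t in range(4)])
    dec = modwt_forward(x, "d2", 1)
    np.testing.assert_allclose(dec.details[0], expected_w, atol=1e-12)
    np.testing.assert_allclose(dec.scaling, expected_v, atol=1e-12)


@pytest.mark.parametrize("filter_name", ["d2", "la8", "la16"])
def test_constant_signal_passes_to_scaling_only(filter_name):
    x = np.full(64, 3.25)
    dec = modwt_forward(x, filter_name, 4)
    for w in dec.details:
        np.testing.assert_allclose(w, 0.0, atol=1e-10)
    np.testing.assert_allclose(dec.scaling, 3.25, atol=1e-10)
    np.testing.assert_allclose(modwt_inverse(dec), x, atol=1e-10)


@pytest.mark.parametrize("filter_name", ["d2", "la8", "la16"])
@pytest.mark.parametrize("level", [1, 3, 5])
def test_round_trip_identity(filter_name, level, rng):
    x = rng.normal(size=512)
    dec = modwt_forward(x, filter_name, level)
    np.testing.assert_allclose(modwt_inverse(dec), x, atol=1e-10)


def test_energy_conservation(rng):
    x = rng.normal(size=1000)
    dec = modwt_forward(x, "la8", 6)
    assert abs(dec.energy() - np.sum(x**2)) / np.sum(x**2) < 1e-8


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    n=st.integers(min_value=16, max_value=200),
    level=st.integers(min_value=1, max_value=4),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_roundtrip_and_energy_property(n, level, seed):
    x = np.random.default_rng(seed).normal(size=n)
    dec = modwt_forward(x, "la8", level)
    assert all(w.shape[-1] == n for w in dec.details)
    np.testing.assert_allclose(modwt_inverse(dec), x, atol=1e-9)
    assert abs(dec.energy() - np.sum(x**2)) <= 1e-8 * np.sum(x**2)


def test_level_bounds_and_filter_validation():
    x = np.arange(16.0)
    with pytest.raises(ValueError, match="floor"):
        modwt_forward(x, "la8", 5)  # floor(log2(16)) = 4
    with pytest.raises(ValueError, match="unknown wavelet"):
        modwt_forward(x, "coif5", 2)
    assert max_level(16) == 4


def test_filter_sums():
    for name in ("d2", "la8", "la16"):
        g, h = modwt_filters(name)
        assert abs(g.sum() - 1.0) < 1e-10  # scaling filter sums to 1
        assert abs(h.sum()) < 1e-10  # wavelet filter sums to 0
        # MODWT filter energy is 1/2
        assert abs(np.sum(g**2) - 0.5) < 1e-10
        assert abs(np.sum(h**2) - 0.5) < 1e-10


def test_cascade_filter_length():
    # L_j = (2^j - 1)(L - 1) + 1
    for j in (1, 2, 3):
        assert len(cascade_filter("la8", j)) == (2**j - 1) * 7 + 1


@pytest.mark.parametrize(
    "j, fs, expected",
    [
        (1, 120.0, (30.0, 60.0)),
        (5, 500.0, (7.8125, 15.625)),
        (3, 1000.0, (62.5, 125.0)),
        (9, 1000.0, (0.9765625, 1.953125)),
    ],
)
def test_scale_to_band_values(j, fs, expected):
    assert scale_to_band(j, fs) == expected


def test_band_edges_halve():
    for j in range(1, 8):
        assert scale_to_band(j + 1, 256.0)[1] == scale_to_band(j, 256.0)[0]


def test_scale_to_band_rejects_bad_args():
    with pytest.raises(ValueError):
        scale_to_band(0, 120.0)
    with pytest.raises(ValueError):
        scale_to_band(2, -1.0)


def test_band_selective_modification(rng):
    """Replacing one scale's coefficients by a permutation changes the
    PSD only inside (and near) that band."""
    from scipy.signal import welch

    x = rng.normal(size=2**13)
    fs = 128.0
    j = 3  # 8-16 Hz
    dec = modwt_forward(x, "la8", 5)
    details = list(dec.details)
    details[j - 1] = details[j - 1][rng.permutation(len(x))]
    y = modwt_inverse(
        WaveletDecomposition(details=details, scaling=dec.scaling, filter="la8")
    )
    f, px = welch(x, fs=fs, nperseg=1024)
    f, py = welch(y, fs=fs, nperseg=1024)
    lo, hi = scale_to_band(j, fs)
    outside = (f < lo / 2) | (f > hi * 2)
    ratio = py[outside].sum() / px[outside].sum()
    assert abs(ratio - 1.0) < 0.10


def test_synthesis_operator_matches_single_scale_inverse(rng):
    x = rng.normal(size=256)
    dec = modwt_forward(x, "la8", 4)
    w = dec.details[1]
    single = WaveletDecomposition(
        details=[np.zeros(256), w, np.zeros(256), np.zeros(256)],
        scaling=np.zeros(256),
        filter="la8",
    )
    np.testing.assert_allclose(
        synthesize_scale(w, 2, "la8"), modwt_inverse(single), atol=1e-10
    )


def test_transformer_class_roundtrip(rng):
    X = rng.normal(size=(3, 128))
    t = MODWT(level=4).fit(X)
    C = t.transform(X)
    assert C.shape == (3, 5, 128)
    np.testing.assert_allclose(t.inverse_transform(C), X, atol=1e-10)
    assert t.get_params() == {"wavelet": "la8", "level": 4}
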