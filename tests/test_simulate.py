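"""Validation-signal generators: closed-form and behavioural checks."""

import numpy as np
import pytest
from scipy.signal import welch

from specais.simulate import (
    ARFIMAParams,
    RoesslerParams,
    band_power,
    frac_integrate,
    gen_arfima,
    gen_burst_trio,
    gen_roessler,
    gen_two_sinusoids,
    gen_white_noise,
)


def psd_peak(data, fs, nperseg=512):
    f, p = welch(data, fs=fs, nperseg=nperseg, axis=-1)
    return f[np.argmax(p.mean(axis=0))]


def test_white_noise_is_uncorrelated_and_reproducible():
    ens = gen_white_noise(n_trials=2, n_samples=20_000, seed=1)
    x = ens.data[0] - ens.data[0].mean()
    r1 = x[:-1] @ x[1:] / (x @ x)
    assert abs(r1) < 3 / np.sqrt(20_000)
    again = gen_white_noise(n_trials=2, n_samples=20_000, seed=1)
    np.testing.assert_array_equal(ens.data, again.data)


def test_two_sinusoids_psd_peaks():
    ens = gen_two_sinusoids(seed=2)
    f, p = welch(ens.data, fs=120.0, nperseg=512, axis=-1)
    pm = p.mean(axis=0)
    peaks = f[np.argsort(pm)[-4:]]
    assert any(abs(pk - 50) < 1 for pk in peaks)
    assert any(abs(pk - 12) < 1 for pk in peaks)


def test_two_sinusoids_equal_tones_single_peak():
    ens = gen_two_sinusoids(20.0, 20.0, seed=3)
    f, p = welch(ens.data, fs=120.0, nperseg=512, axis=-1)
    pm = p.mean(axis=0)
    # all power concentrated near 20 Hz
    assert abs(f[np.argmax(pm)] - 20) < 1
    assert pm[np.abs(f - 20) > 3].max() < 0.01 * pm.max()


def test_two_sinusoids_rejects_aliased_tone():
    with pytest.raises(ValueError, match="Nyquist"):
        gen_two_sinusoids(f_a=70.0, fs=120.0)


def test_frac_integrate_matches_binomial_oracle(rng):
    # truncated binomial-series oracle, exact for the first 50 samples
    d = 0.3
    u = rng.normal(size=512)
    out = frac_integrate(u, d)[0]
    coeffs = [1.0]
    for k in range(1, 50):
        coeffs.append(coeffs[-1] * (k - 1 + d) / k)
    direct = np.array(
        [sum(coeffs[k] * u[t - k] for k in range(min(t + 1, 50))) for t in range(50)]
    )
    np.testing.assert_allclose(out[:50], direct, atol=1e-8)


def test_arfima_d0_equals_ar2_recursion_oracle():
    """With d=0 the generator must reproduce a literal AR(2) recursion
    driven by the identical innovation stream (to rounding: the linear
    filter evaluates the same recursion in a different operation order)."""
    params = ARFIMAParams(p=0.9, d=0.0, f1=30.0, fs=120.0, n_trials=1,
                          n_samples=500, burn_in=100, seed=9)
    ens = gen_arfima(params)
    u = np.random.default_rng(9).standard_normal((1, 600))[0]
    x = np.zeros(600)
    for t in range(600):
        x[t] = u[t]
        if t >= 1:
            x[t] += params.a1 * x[t - 1]
        if t >= 2:
            x[t] += params.a2 * x[t - 2]
    np.testing.assert_allclose(ens.data[0], x[100:], rtol=0, atol=1e-12)


def test_arfima_acf_matches_yule_walker():
    # AR(2) closed-form ACF recursion rho_k = A1 rho_{k-1} + A2 rho_{k-2}
    params = ARFIMAParams(p=0.98, d=0.0, f1=50.0, fs=120.0, n_trials=50,
                          n_samples=4000, seed=10)
    ens = gen_arfima(params)
    a1, a2 = params.a1, params.a2
    rho = [1.0, a1 / (1 - a2)]
    for _ in range(2, 11):
        rho.append(a1 * rho[-1] + a2 * rho[-2])
    x = ens.data - ens.data.mean(axis=1, keepdims=True)
    denom = np.sum(x * x)
    for k in range(1, 11):
        sample = np.sum(x[:, :-k] * x[:, k:]) / denom
        assert abs(sample - rho[k]) < 0.05


def test_arfima_paper_parameters_peak_in_gamma_band():
    ens = gen_arfima(ARFIMAParams(n_trials=20, seed=11))
    assert 30 <= psd_peak(ens.data, 120.0) <= 60


def test_arfima_degenerate_is_white_noise():
    params = ARFIMAParams(p=0.0, d=0.0, n_trials=1, n_samples=1000, seed=12)
    ens = gen_arfima(params)
    ref = np.random.default_rng(12).standard_normal((1, 1000 + params.burn_in))
    np.testing.assert_array_equal(ens.data[0], ref[0, params.burn_in:])


def test_arfima_parameter_validation():
    with pytest.raises(ValueError):
        ARFIMAParams(d=0.6)
    with pytest.raises(ValueError):
        ARFIMAParams(p=1.1)


def test_roessler_peak_near_8hz():
    ens = gen_roessler(RoesslerParams(n_trials=3, seed=13))
    assert abs(psd_peak(ens.data, 500.0, nperseg=1024) - 8.0) < 2.0


def test_roessler_decoupled_x1_ignores_second_oscillator():
    a = gen_roessler(RoesslerParams(eps=0.0, w2=0.9, noise_sd=0.0, n_trials=1,
                                    trial_len=1.0, burn_in=100, seed=14))
    b = gen_roessler(RoesslerParams(eps=0.0, w2=1.3, noise_sd=0.0, n_trials=1,
                                    trial_len=1.0, burn_in=100, seed=14))
    np.testing.assert_array_equal(a.data, b.data)
    c = gen_roessler(RoesslerParams(eps=0.07, w2=1.3, noise_sd=0.0, n_trials=1,
                                    trial_len=1.0, burn_in=100, seed=14))
    assert not np.array_equal(a.data, c.data)


def test_roessler_trajectory_bounded():
    ens = gen_roessler(RoesslerParams(n_trials=1, trial_len=8.0, seed=15))
    assert np.max(np.abs(ens.data)) < 100


def test_burst_trio_band_power_matched():
    trio = gen_burst_trio(n_signals=30, seed=16)
    powers = [band_power(e.data, e.fs, (8.0, 15.0)) for e in trio]
    for p in powers:
        assert abs(p / powers[2] - 1.0) < 0.05
    assert [e.label for e in trio] == ["random_bursts", "single_burst", "sinusoid"]


def test_burst_trio_zero_bursts_is_flat_noise():
    trio = gen_burst_trio(n_signals=10, burst_count_range=(0, 1), seed=17)
    x = trio[0].data
    # no oscillatory excess: in-band power density matches neighbours
    inside = band_power(x, 120.0, (8.0, 15.0))
    outside = band_power(x, 120.0, (20.0, 27.0))
    assert abs(inside / outside - 1.0) < 0.15


def test_generators_record_provenance():
    ens = gen_arfima(ARFIMAParams(n_trials=1, n_samples=100, seed=1))
    assert ens.meta["generator"] == "arfima"
    assert ens.fs == 120.0
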