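"""Synthetic validation signals.

Every generator returns a :class:`~specais.io.TrialEnsemble` and is
seeded and bit-reproducible.  The set covers the canonical ground-truth
cases for a frequency-resolved storage test:

* white noise — no storage at any scale (null calibration);
* a two-sinusoid mixture (50 Hz + 12 Hz at fs = 120 Hz) — storage in two
  disjoint bands with a silent band in between (specificity);
* an ARFIMA process — an AR(2) resonance at 50 Hz driven through a
  fractional integrator (long memory), a linear process with storage
  concentrated in one band;
* a delay-coupled pair of Roessler oscillators, observed through one
  variable only — a nonlinear chaotic rhythm near 8 Hz;
* a burst/single-burst/sinusoid trio with matched narrow-band power —
  signals whose spectral power is equal but whose predictability (and
  hence storage) differs greatly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, lfilter, welch

from .io import TrialEnsemble

__all__ = [
    "ARFIMAParams",
    "RoesslerParams",
    "gen_white_noise",
    "gen_ar1",
    "gen_two_sinusoids",
    "gen_arfima",
    "gen_roessler",
    "gen_burst_trio",
    "band_power",
    "frac_integrate",
]


def gen_white_noise(
    n_trials: int = 100, n_samples: int = 1200, fs: float = 120.0, seed: int = 0
) -> TrialEnsemble:
    """I.i.d. standard normal samples — the storage-free null process."""
    if n_trials < 1 or n_samples < 2:
        raise ValueError("need positive dimensions")
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_trials, n_samples))
    ens = TrialEnsemble(data, fs, label="white_noise")
    ens.meta.update(generator="white_noise", seed=seed)
    return ens


def gen_ar1(
    phi: float,
    n_trials: int = 1,
    n_samples: int = 100_000,
    fs: float = 120.0,
    seed: int = 0,
    burn_in: int = 1000,
) -> TrialEnsemble:
    """Stationary AR(1) ``x_t = phi x_{t-1} + e_t`` with unit innovations.

    Its exact storage is ``-0.5 ln(1 - phi**2)`` nats, a convenient
    analytic target for estimator validation.
    """
    if not -1 < phi < 1:
        raise ValueError("|phi| must be < 1 for stationarity")
    rng = np.random.default_rng(seed)
    e = rng.standard_normal((n_trials, n_samples + burn_in))
    x = lfilter([1.0], [1.0, -phi], e, axis=-1)[:, burn_in:]
    ens = TrialEnsemble(x, fs, label=f"ar1_{phi}")
    ens.meta.update(generator="ar1", phi=phi, seed=seed)
    return ens


def gen_two_sinusoids(
    f_a: float = 50.0,
    f_b: float = 12.0,
    fs: float = 120.0,
    duration_s: float = 10.0,
    n_trials: int = 50,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> TrialEnsemble:
    """Sum of two unit-amplitude sinusoids with random phase per trial.

    A small Gaussian noise floor (default SD 0.1) keeps the signal
    full-rank for continuous information estimators.
    """
    for f in (f_a, f_b):
        if f >= fs / 2:
            raise ValueError(f"frequency {f} Hz at or above Nyquist ({fs / 2} Hz)")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    ph = rng.uniform(0, 2 * np.pi, size=(n_trials, 2))
    data = (
        np.sin(2 * np.pi * f_a * t + ph[:, :1])
        + np.sin(2 * np.pi * f_b * t + ph[:, 1:])
        + noise_sd * rng.standard_normal((n_trials, n))
    )
    ens = TrialEnsemble(data, fs, label="two_sinusoids")
    ens.meta.update(generator="two_sinusoids", f_a=f_a, f_b=f_b, seed=seed)
    return ens


def frac_integrate(u: np.ndarray, d: float) -> np.ndarray:
    """Apply the inverse fractional-differencing filter ``(1-L)**-d``.

    Fast fractional differencing: the binomial-series coefficients
    ``b_0 = 1, b_k = b_{k-1} (k - 1 + d) / k`` are convolved with the
    input by FFT, O(N log N) instead of the O(N^2) direct recursion.
    """
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if d == 0:
        return u.copy()
    n = u.shape[-1]
    k = np.arange(1, n)
    b = np.concatenate([[1.0], np.cumprod((k - 1 + d) / k)])
    return fftconvolve(u, b[None, :], mode="full", axes=-1)[:, :n]


@dataclass
class ARFIMAParams:
    """ARFIMA(2, d, 0) with an AR resonance at ``f1`` Hz.

    The AR coefficients are ``A1 = 2 p cos(2 pi f1 / fs)`` and
    ``A2 = -p**2`` (conjugate poles of modulus ``p`` at the resonance
    frequency); the driving noise is fractionally integrated with order
    ``d`` (long memory for ``0 < d < 0.5``).
    """

    p: float = 0.98
    f1: float = 50.0
    d: float = 0.3
    n_trials: int = 100
    n_samples: int = 1200
    fs: float = 120.0
    burn_in: int = 2000
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p < 1:
            raise ValueError("AR pole modulus p must satisfy 0 <= p < 1")
        if not abs(self.d) < 0.5:
            raise ValueError("|d| must be < 0.5 for stationarity")
        if not 0 <= self.f1 <= self.fs / 2:
            raise ValueError("f1 must lie in [0, fs/2]")

    @property
    def a1(self) -> float:
        return 2 * self.p * np.cos(2 * np.pi * self.f1 / self.fs)

    @property
    def a2(self) -> float:
        return -self.p**2


def gen_arfima(params: ARFIMAParams | None = None, **kw) -> TrialEnsemble:
    """Simulate the ARFIMA process ``A(L) (1-L)**d X = U``.

    Gaussian unit-variance innovations are fractionally integrated by
    fast fractional differencing, then passed through the AR(2)
    recursion; a burn-in segment is discarded.
    """
    params = params or ARFIMAParams(**kw)
    rng = np.random.default_rng(params.seed)
    total = params.n_samples + params.burn_in
    u = rng.standard_normal((params.n_trials, total))
    x = frac_integrate(u, params.d)
    x = lfilter([1.0], [1.0, -params.a1, -params.a2], x, axis=-1)
    data = x[:, params.burn_in :]
    ens = TrialEnsemble(data, params.fs, label="arfima")
    ens.meta.update(
        generator="arfima", p=params.p, d=params.d, f1=params.f1, seed=params.seed
    )
    return ens


@dataclass
class RoesslerParams:
    """Delay-coupled Roessler pair; only ``x1`` is observed.

    ``w1, w2`` set the natural frequencies, ``eps`` the (unidirectional)
    coupling of the second oscillator into the first, ``tau`` the
    coupling delay in integration steps.  ``dt`` is the integration step
    in model-time units; with one output sample per step, the model
    rhythm of ``w1 = 0.8`` lands near 8 Hz at fs = 500 Hz (the printed
    oscillation frequency used to calibrate the time scaling).
    """

    w1: float = 0.8
    w2: float = 0.9
    eps: float = 0.07
    tau: int = 2
    noise_sd: float = 0.1
    fs: float = 500.0
    n_trials: int = 25
    trial_len: float = 4.0
    dt: float = 0.1257
    burn_in: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.eps < 0 or self.tau < 0:
            raise ValueError("eps and tau must be non-negative")


def _roessler_deriv(s, w1, w2, c):
    x1, y1, z1, x2, y2, z2 = s
    return np.array(
        [
            -w1 * y1 - z1 + c,
            w1 * x1 + 0.15 * y1,
            0.2 + z1 * (x1 - 10.0),
            -w2 * y2 - z2,
            w2 * x2 + 0.15 * y2,
            0.2 + z2 * (x2 - 10.0),
        ]
    )


def gen_roessler(params: RoesslerParams | None = None, **kw) -> TrialEnsemble:
    """Integrate the 6-D delay-coupled system (fixed-step RK4).

    The delayed coupling term ``eps * x2(t - tau)`` is held constant
    over each step (step buffer).  Gaussian observation noise with SD
    ``noise_sd`` times the signal SD is added to the observed ``x1``.
    """
    params = params or RoesslerParams(**kw)
    rng = np.random.default_rng(params.seed)
    n = int(round(params.trial_len * params.fs))
    steps = n + params.burn_in
    data = np.empty((params.n_trials, n))
    dt = params.dt
    for tr in range(params.n_trials):
        s = rng.uniform(-1, 1, size=6) + np.array([0.5, 0.5, 0.1, 0.5, 0.5, 0.1])
        x2_buf = [s[3]] * (params.tau + 1)
        x1 = np.empty(steps)
        for i in range(steps):
            c = params.eps * x2_buf[0]
            k1 = _roessler_deriv(s, params.w1, params.w2, c)
            k2 = _roessler_deriv(s + 0.5 * dt * k1, params.w1, params.w2, c)
            k3 = _roessler_deriv(s + 0.5 * dt * k2, params.w1, params.w2, c)
            k4 = _roessler_deriv(s + dt * k3, params.w1, params.w2, c)
            s = s + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            if np.max(np.abs(s)) > 1e6:
                raise FloatingPointError(f"trajectory diverged at step {i}")
            x2_buf.append(s[3])
            x2_buf.pop(0)
            x1[i] = s[0]
        x1 = x1[params.burn_in :]
        data[tr] = x1 + params.noise_sd * np.std(x1) * rng.standard_normal(n)
    ens = TrialEnsemble(data, params.fs, label="roessler_x1")
    ens.meta.update(generator="roessler", w1=params.w1, eps=params.eps, seed=params.seed)
    return ens


def band_power(data: np.ndarray, fs: float, band: tuple) -> float:
    """Mean Welch power in ``band`` (Hz), averaged over trials."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    nper = min(data.shape[-1], 512)
    f, p = welch(data, fs=fs, nperseg=nper, axis=-1)
    sel = (f >= band[0]) & (f <= band[1])
    return float(np.mean(p[:, sel]))


def _burst(t: np.ndarray, f0: float, t0: float, phase: float, n_cycles: int = 3) -> np.ndarray:
    """Hann-windowed wave packet of ``n_cycles`` cycles centred at ``t0``."""
    width = n_cycles / f0
    w = np.zeros_like(t)
    m = np.abs(t - t0) <= width / 2
    w[m] = 0.5 * (1 + np.cos(2 * np.pi * (t[m] - t0) / width))
    return w * np.sin(2 * np.pi * f0 * t + phase)


def gen_burst_trio(
    fs: float = 120.0,
    duration_s: float = 10.0,
    n_signals: int = 100,
    target_band: tuple = (8.0, 15.0),
    burst_freq: float = 10.0,
    burst_count_range: tuple = (6, 13),
    seed: int = 0,
):
    """Three ensembles with matched narrow-band power but different dynamics.

    1. randomly spaced oscillatory bursts (around ``burst_freq`` Hz,
       random phases) on Gaussian noise;
    2. a single burst placed randomly near the end of a noise series;
    3. a sinusoid (per-signal frequency drawn uniformly inside
       ``target_band``) plus Gaussian noise.

    All three are amplitude-scaled so their mean power inside
    ``target_band`` matches (the sinusoid ensemble is the reference).
    """
    if not 0 < target_band[0] < target_band[1] < fs / 2:
        raise ValueError("target_band must lie inside (0, fs/2)")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    bursts = rng.standard_normal((n_signals, n))
    for i in range(n_signals):
        for _ in range(rng.integers(*burst_count_range)):
            t0 = rng.uniform(0.2, duration_s - 0.2)
            bursts[i] += 3.0 * _burst(t, burst_freq, t0, rng.uniform(0, 2 * np.pi))

    single = rng.standard_normal((n_signals, n))
    for i in range(n_signals):
        t0 = rng.uniform(0.8 * duration_s, duration_s - 0.2)
        single[i] += 3.0 * _burst(t, burst_freq, t0, rng.uniform(0, 2 * np.pi))

    freqs = rng.uniform(target_band[0], target_band[1], size=n_signals)
    sine = np.sin(
        2 * np.pi * freqs[:, None] * t[None, :] + rng.uniform(0, 2 * np.pi, (n_signals, 1))
    ) + 0.5 * rng.standard_normal((n_signals, n))

    ref = band_power(sine, fs, target_band)
    bursts *= np.sqrt(ref / band_power(bursts, fs, target_band))
    single *= np.sqrt(ref / band_power(single, fs, target_band))

    out = []
    for name, arr in (("random_bursts", bursts), ("single_burst", single), ("sinusoid", sine)):
        ens = TrialEnsemble(arr, fs, label=name)
        ens.meta.update(generator="burst_trio", kind=name, seed=seed)
        out.append(ens)
    return tuple(out)
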