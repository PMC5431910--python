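"""Fluctuation-dissipation susceptibility spectra and Debye fits.

The complex susceptibility tensor follows from the equilibrium
magnetization correlation functions C_kl(t) = <M_k(t) M_l(0)> via the
classical fluctuation-dissipation theorem,

    alpha_kl(omega) = C_kl(0)/(N k_B T)
                      + (i omega)/(N k_B T) int_0^inf C_kl(t) e^{+i omega t} dt.

The e^{+i omega t} convention makes Im alpha_kk >= 0 for decaying
correlations, i.e. dissipation is positive; an exponential C(t) = C0
exp(-t/tau) gives exactly the Debye spectrum

    alpha''(omega) = (C0/N k_B T) * omega tau / (1 + (omega tau)^2),

which peaks at omega = 1/tau with half the static amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .constants import K_B
from .dynamics import MagnetizationTrace
from .params import SimulationParams, coupling_energy, predicted_relaxation_time

_COMP = {"x": 0, "y": 1, "z": 2, "n": 0, "p": 1}


class FitFailureError(RuntimeError):
    """Debye fit could not locate an interior absorption maximum."""


# ---------------------------------------------------------------------------

@dataclass
class CorrelationFunction:
    """Tensor-valued time correlation of the magnetization fluctuations."""

    lags: np.ndarray            # (L,), s
    C: np.ndarray               # (L, 3, 3), (A m^2)^2

    def diagonal(self, k: int | str) -> np.ndarray:
        k = _COMP.get(k, k)
        return self.C[:, k, k]


def autocorrelation(trace: MagnetizationTrace, max_lag: float | None = None,
                    segments: int = 1) -> CorrelationFunction:
    """Time-averaged correlation tensor estimator via FFT (Wiener-Khinchin).

    The mean of each component is removed (fluctuation correlation), the
    estimator is unbiased (each lag divided by its number of contributing
    products), Welch-style averaging over ``segments`` equal trace segments
    is optional, and the tensor is symmetrized in (k, l), which is exact in
    equilibrium by time reversal.

    max_lag must not exceed a fifth of the trace duration -- beyond that the
    time average carries too few independent products to be meaningful.
    """
    n = trace.n_samples
    dt = trace.dt_sample
    if n < 2:
        raise ValueError("trace too short for autocorrelation (need >= 2 samples)")
    if max_lag is None:
        max_lag = trace.duration / 10.0
    seg_len = n // segments
    n_lags = int(max_lag / dt) + 1
    if n_lags > seg_len // 5 + 1:
        raise ValueError(
            f"max_lag {max_lag:g} s exceeds a fifth of the (segment) trace "
            f"duration {seg_len * dt:g} s")
    m = trace.M - trace.M.mean(axis=0)
    nfft = int(2 ** np.ceil(np.log2(2 * seg_len)))
    acc = np.zeros((n_lags, 3, 3))
    counts = np.arange(seg_len, seg_len - n_lags, -1, dtype=float)
    for s in range(segments):
        seg = m[s * seg_len:(s + 1) * seg_len]
        seg = seg - seg.mean(axis=0)
        F = np.fft.rfft(seg, n=nfft, axis=0)
        for k in range(3):
            for l in range(3):
                # sum_t M_k(t+lag) M_l(t)
                cc = np.fft.irfft(F[:, k] * np.conj(F[:, l]), n=nfft)[:n_lags]
                acc[:, k, l] += cc / counts
    acc /= segments
    acc = 0.5 * (acc + np.transpose(acc, (0, 2, 1)))
    return CorrelationFunction(np.arange(n_lags) * dt, acc)


def autocorrelation_direct(trace: MagnetizationTrace,
                           max_lag: float) -> CorrelationFunction:
    """O(n^2) direct lag-sum estimator; the oracle the FFT path must match."""
    n = trace.n_samples
    dt = trace.dt_sample
    n_lags = int(max_lag / dt) + 1
    m = trace.M - trace.M.mean(axis=0)
    C = np.empty((n_lags, 3, 3))
    for lag in range(n_lags):
        a, b = m[lag:], m[:n - lag]
        C[lag] = (a.T @ b) / (n - lag)
    return CorrelationFunction(np.arange(n_lags) * dt,
                               0.5 * (C + np.transpose(C, (0, 2, 1))))


# ---------------------------------------------------------------------------

@dataclass
class SusceptibilitySpectrum:
    """Complex per-particle susceptibility tensor alpha_kl(omega)."""

    angular_frequencies: np.ndarray     # (W,), rad/s
    alpha: np.ndarray                   # (W, 3, 3), complex, 1/T units of M/B
    n_particles: int
    temperature: float

    def imag(self, k: int | str) -> np.ndarray:
        k = _COMP.get(k, k)
        return self.alpha[:, k, k].imag

    def real(self, k: int | str) -> np.ndarray:
        k = _COMP.get(k, k)
        return self.alpha[:, k, k].real


def _filon_weights(omega, delta, n):
    """Quadrature weights of the one-sided Fourier integral for a
    piecewise-linear integrand on a uniform grid.

    Exact for linearly interpolated C(t) at every frequency (the plain
    trapezoid rule degrades once omega*delta is no longer small).  Returns
    a (len(omega), n) complex array to be multiplied elementwise with
    exp(i omega t_k) and the samples.
    """
    theta = np.asarray(omega) * delta
    a = np.empty(theta.shape, dtype=complex)
    b = np.empty(theta.shape, dtype=complex)
    small = np.abs(theta) < 1e-3
    ts = theta[small]
    a[small] = delta * (0.5 + 1j * ts / 6.0 - ts ** 2 / 24.0)
    b[small] = delta * (0.5 + 1j * ts / 3.0 - ts ** 2 / 8.0)
    tl = theta[~small]
    eith = np.exp(1j * tl)
    b[~small] = delta * (eith / (1j * tl) + (eith - 1.0) / tl ** 2)
    a[~small] = delta * (eith - 1.0) / (1j * tl) - b[~small]
    wgt = np.empty((theta.size, n), dtype=complex)
    b_shift = b * np.exp(-1j * theta)
    wgt[:, 0] = a
    wgt[:, 1:-1] = (a + b_shift)[:, None]
    wgt[:, -1] = b_shift
    return wgt


def _fit_exponential_tail(lags, c):
    """Least-squares exponential A e^{-t/tau} on the window where the
    diagonal correlation has decayed to between 50% and 5% of C(0)."""
    c0 = c[0]
    mask = (c > 0.05 * c0) & (c < 0.5 * c0) & (lags > 0)
    if mask.sum() < 4:
        return None
    t, y = lags[mask], np.log(c[mask])
    slope, intercept = np.polyfit(t, y, 1)
    if slope >= 0:
        return None
    return np.exp(intercept), -1.0 / slope


def susceptibility(corr: CorrelationFunction, temperature: float,
                   n_particles: int,
                   angular_frequencies: np.ndarray | None = None,
                   n_omega: int = 200,
                   tail_correction: bool = True) -> SusceptibilitySpectrum:
    """Evaluate the FDT transform on a log-spaced frequency grid.

    The one-sided Fourier integral is computed by trapezoidal quadrature on
    the measured lags; for diagonal components an analytic exponential-tail
    continuation (fitted on the decayed part of C_kk) removes the truncation
    bias at low frequency.  Warns when C_kk has not decayed below 5% of
    C_kk(0) within the available lags.
    """
    lags = corr.lags
    beta = 1.0 / (n_particles * K_B * temperature)

    diag_mean = np.trace(corr.C, axis1=1, axis2=2) / 3.0
    if diag_mean[-1] > 0.05 * diag_mean[0]:
        warnings.warn(
            "correlation has not decayed below 5% of C(0) within max_lag; "
            "low-frequency susceptibility may be biased", stacklevel=2)

    if angular_frequencies is None:
        # integral correlation time of the mean diagonal sets the grid span;
        # the top is capped well below the sampling Nyquist frequency, where
        # the trapezoid transform of the discrete lags is still accurate
        tau_est = max(np.trapezoid(np.clip(diag_mean, 0, None), lags)
                      / diag_mean[0], lags[1])
        w_max = min(1e3 / tau_est, 0.5 * np.pi / (lags[1] - lags[0]))
        angular_frequencies = np.logspace(np.log10(1e-2 / tau_est),
                                          np.log10(w_max), n_omega)
    w = np.asarray(angular_frequencies, dtype=float)

    alpha = np.empty((w.size, 3, 3), dtype=complex)
    tails = {}
    for k in range(3):
        fit = _fit_exponential_tail(lags, corr.C[:, k, k]) if tail_correction \
            else None
        tails[k] = fit
    t_max = lags[-1]
    delta = lags[1] - lags[0]
    for block in range(0, w.size, 32):
        wb = w[block:block + 32, None]
        phase = np.exp(1j * wb * lags[None, :]) * _filon_weights(wb[:, 0],
                                                                 delta,
                                                                 lags.size)
        for k in range(3):
            for l in range(k, 3):
                integral = phase @ corr.C[:, k, l]
                if k == l and tails[k] is not None:
                    amp, tau_f = tails[k]
                    s = 1.0 / tau_f - 1j * wb[:, 0]
                    integral = integral + amp * np.exp(-s * t_max) / s
                a = beta * corr.C[0, k, l] + 1j * wb[:, 0] * beta * integral
                alpha[block:block + 32, k, l] = a
                alpha[block:block + 32, l, k] = a
    return SusceptibilitySpectrum(w, alpha, n_particles, temperature)


# ---------------------------------------------------------------------------

@dataclass
class DebyeFit:
    """Single-relaxation-time fit of an absorption spectrum component."""

    amplitude: float        # static susceptibility alpha(0)
    tau: float              # relaxation time, s
    component: str
    residual: float         # rms residual / peak value
    fit_window: tuple[float, float]

    @property
    def peak_frequency(self) -> float:
        """Angular frequency of maximum absorption, 1/tau."""
        return 1.0 / self.tau

    @property
    def peak_value(self) -> float:
        """alpha'' at omega = 1/tau, amplitude/2."""
        return 0.5 * self.amplitude


def debye_imag(omega, amplitude, tau):
    """Debye absorption alpha''(omega) = amplitude * x/(1+x^2), x = omega tau."""
    x = omega * tau
    return amplitude * x / (1.0 + x * x)


def fit_debye(spectrum: SusceptibilitySpectrum,
              component: int | str = 0) -> DebyeFit:
    """Weighted least squares of the Debye law on alpha''_kk(omega).

    Points enter with uniform weight on the (log-spaced) grid.  Requires at
    least 10 points and an interior absorption maximum.
    """
    name = component if isinstance(component, str) else "xyz"[component]
    w = spectrum.angular_frequencies
    y = spectrum.imag(component)
    if w.size < 10:
        raise FitFailureError("need >= 10 frequency points spanning the peak")
    ipk = int(np.argmax(y))
    if ipk == 0 or ipk == w.size - 1 or y[ipk] <= 0:
        raise FitFailureError(
            f"no interior absorption maximum for component {name!r}")
    p0 = (2.0 * y[ipk], 1.0 / w[ipk])
    popt, _ = curve_fit(debye_imag, w, y, p0=p0, maxfev=10_000)
    amplitude, tau = float(popt[0]), float(abs(popt[1]))
    resid = y - debye_imag(w, amplitude, tau)
    return DebyeFit(amplitude=amplitude, tau=tau, component=name,
                    residual=float(np.sqrt(np.mean(resid ** 2)) / y[ipk]),
                    fit_window=(float(w[0]), float(w[-1])))


# ---------------------------------------------------------------------------

def relaxation_prediction(rho: float, params: SimulationParams,
                          prefactor: float = 1.0) -> float:
    """Additive-rate relaxation time 1/tau = 1/tau_B + a U(rho)/zeta, s.

    rho is the surface density in m^-2; U(rho) the nearest-neighbor dipolar
    energy scale mu0 mu^2 rho^{3/2}/4pi.  rho = 0 returns tau_B.
    """
    return predicted_relaxation_time(params, rho, prefactor)


def fit_rate_prefactor(rhos, taus, params: SimulationParams) -> float:
    """Least-squares (in log rate) single prefactor a of the additive rate
    law against measured relaxation times."""
    rhos = np.asarray(rhos, dtype=float)
    taus = np.asarray(taus, dtype=float)
    u_over_zeta = np.array([coupling_energy(r, params.moment) / params.friction
                            for r in rhos])
    rate_b = 1.0 / params.brownian_time
    from scipy.optimize import minimize_scalar
    def cost(log_a):
        model = rate_b + np.exp(log_a) * u_over_zeta
        return np.sum((np.log(model) - np.log(1.0 / taus)) ** 2)
    res = minimize_scalar(cost, bounds=(-5, 5), method="bounded")
    return float(np.exp(res.x))


def power_spectrum(spectrum: SusceptibilitySpectrum,
                   component: int | str = 0) -> np.ndarray:
    """Dissipated power density P(omega) = omega * alpha''(omega).

    For a Debye component this rises monotonically and saturates at
    amplitude/tau; it is the per-particle heating rate per unit B^2 of a
    weak ac drive at omega.
    """
    return spectrum.angular_frequencies * spectrum.imag(component)


def kramers_kronig_real(omega: np.ndarray, alpha_imag: np.ndarray) -> np.ndarray:
    """Reconstruct Re alpha from Im alpha by the Kramers-Kronig relation

        Re alpha(w) = (2/pi) P int_0^inf x alpha''(x) / (x^2 - w^2) dx,

    evaluated by principal-value trapezoid quadrature on the given grid
    (the two grid points nearest each singularity are paired and skipped).
    Used as an internal consistency check of the FDT transform.
    """
    omega = np.asarray(omega, dtype=float)
    re = np.empty_like(omega)
    x = omega
    f = x * alpha_imag
    for i, w in enumerate(omega):
        keep = np.abs(np.log(x / w)) > 0.03   # excise the singular point
        g = f[keep] / (x[keep] ** 2 - w ** 2)
        re[i] = (2.0 / np.pi) * np.trapezoid(g, x[keep])
    return re
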