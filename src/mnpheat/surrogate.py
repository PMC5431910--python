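"""Surrogate magnetization traces with exactly exponential correlations.

A stationary Gaussian AR(1) process

    x_{k+1} = c x_k + sqrt(C0 (1 - c^2)) xi_k,     c = exp(-dt/tau),

has autocorrelation C0 exp(-t/tau) on the sample grid exactly, so the
surrogate gives the downstream FDT pipeline (autocorrelation ->
susceptibility -> Debye fit) a closed-form oracle without running any
dynamics.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter, lfiltic

from .dynamics import MagnetizationTrace


def make_surrogate_trace(amplitude: float, tau: float, n_samples: int,
                         dt: float, seed: int, n_particles: int = 1,
                         moment_magnitude: float = 1.0) -> MagnetizationTrace:
    """Three independent AR(1) components with variance ``amplitude`` =
    C_kk(0) in (A m^2)^2 and correlation time ``tau``.

    The trace is bit-reproducible for a given seed (counter-based Philox).
    """
    if amplitude <= 0 or tau <= 0 or dt <= 0 or n_samples < 1:
        raise ValueError("amplitude, tau, dt must be > 0 and n_samples >= 1")
    rng = np.random.Generator(np.random.Philox(seed))
    c = np.exp(-dt / tau)
    innov = np.sqrt(amplitude * (1.0 - c * c))
    m = np.empty((n_samples, 3))
    m[0] = np.sqrt(amplitude) * rng.standard_normal(3)
    noise = innov * rng.standard_normal((n_samples - 1, 3))
    for comp in range(3):
        zi = lfiltic([1.0], [1.0, -c], [m[0, comp]])
        m[1:, comp], _ = lfilter([1.0], [1.0, -c], noise[:, comp], zi=zi)
    times = np.arange(1, n_samples + 1) * dt
    return MagnetizationTrace(times, m, n_particles, moment_magnitude)
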