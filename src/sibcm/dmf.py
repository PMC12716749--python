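"""Stochastic dynamic mean-field model driven by the co-activity pattern.

Each region i carries one synaptic gating variable S_i in [0, 1]:

    dS_i = [ -S_i/tau_s + r (1 - S_i) H(z_i) ] dt + sigma dW_i
    z_i  = omega * J * S_i + G * J * sum_j W_ij S_j + I0
    H(z) = (a z - b) / (1 - exp(-d (a z - b)))

with the co-activity pattern W (max-abs-normalized, zero diagonal, signed
entries retained) as the coupling matrix, recurrent strength omega, global
coupling G, background input I0 (nA) and noise amplitude sigma.  Integration
is Euler-Maruyama at a fine step (default 1 ms), gating clamped to [0, 1]
after each step.  All randomness comes from one numpy Generator seeded
explicitly, so trajectories are bitwise reproducible.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit

from .coactivity import CoactivityPattern


class StabilityError(ValueError):
    """Integration step too coarse for the synaptic time constant."""


class DivergenceError(RuntimeError):
    """Non-finite state encountered during integration."""


@dataclasses.dataclass(frozen=True)
class DMFParameters:
    """Constants and the four fitted parameters of the mean-field model.

    The four free parameters are ``omega`` (recurrent strength), ``coupling_G``
    (global coupling), ``I0`` (background input, nA) and ``sigma`` (noise
    amplitude).  The transfer-function constants a, b, d and the synaptic
    constants J, tau_s, r follow the reduced mean-field literature.
    """

    omega: float = 0.9
    coupling_G: float = 4.0
    I0: float = 0.28
    sigma: float = 0.005
    J: float = 0.2609          # nA, synaptic coupling
    tau_s: float = 0.1         # s, synaptic time constant
    r_kinetic: float = 0.641   # kinetic coefficient
    a: float = 270.0           # n/C
    b: float = 108.0           # Hz
    d: float = 0.154           # s

    def __post_init__(self) -> None:
        if self.omega < 0 or self.coupling_G < 0 or self.sigma < 0:
            raise ValueError("omega, coupling_G, sigma must be nonnegative")
        for name in ("J", "tau_s", "r_kinetic", "a", "b", "d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **kw) -> "DMFParameters":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass(frozen=True)
class NeuralTrajectory:
    """Synaptic gating S over time: (T', M) with T' = round(duration/dt)."""

    gating: np.ndarray
    dt_seconds: float
    seed: int


def transfer_rate(z, params: DMFParameters | None = None):
    """Population firing rate H(z) in Hz.

    The removable singularity at a*z = b evaluates to the limit 1/d; near it
    the first-order expansion 1/d + x/2 (x = a*z - b) is used, which keeps the
    function smooth and nonnegative for all inputs.
    """
    params = params or DMFParameters()
    z = np.asarray(z, dtype=float)
    x = params.a * z - params.b
    near = np.abs(x) < 1e-8
    safe = np.where(near, 1.0, x)
    h = np.where(near, 1.0 / params.d + x / 2.0,
                 safe / (1.0 - np.exp(-params.d * safe)))
    return h if h.ndim else float(h)


@njit(cache=True)
def _dmf_euler(w, omega, g, i0, sigma, j, tau_s, r, a, b, d, dt, s0, noise):  # pragma: no cover
    n_steps, m = noise.shape
    out = np.empty((n_steps, m))
    s = s0.copy()
    for t in range(n_steps):
        z = omega * j * s + g * j * (w @ s) + i0
        for i in range(m):
            x = a * z[i] - b
            if abs(x) < 1e-8:
                h = 1.0 / d + x / 2.0
            else:
                h = x / (1.0 - np.exp(-d * x))
            si = s[i] + (-s[i] / tau_s + r * (1.0 - s[i]) * h) * dt \
                + sigma * noise[t, i]
            if si < 0.0:
                si = 0.0
            elif si > 1.0:
                si = 1.0
            s[i] = si
        out[t] = s
    return out


def simulate_dmf(
    pattern: CoactivityPattern,
    params: DMFParameters,
    duration_seconds: float,
    dt_seconds: float = 0.001,
    seed: int = 0,
) -> NeuralTrajectory:
    """Euler-Maruyama integration of the gating dynamics.

    The coupling matrix is the pattern normalized by its spectral radius
    (zeta(W) = W / rho(W)), which makes the fitted global coupling G comparable
    across subjects and across pattern estimates of different weight scale.
    Noise increments are ``sigma * sqrt(dt) * N(0,1)``; the initial state is
    S_i(0) = 0.1 + 0.01 * U(0,1) drawn from the run seed.  Deterministic for
    fixed (seed, dt, duration).
    """
    w = np.asarray(pattern.weights, dtype=float)
    m = w.shape[0]
    if m < 2:
        raise ValueError("pattern must couple at least 2 regions")
    # zeta(W): spectral-radius normalization pins the network gain G*J*lam_max,
    # so G means the same thing whatever the estimated pattern's weight scale
    rho = np.max(np.abs(np.linalg.eigvalsh(0.5 * (w + w.T))))
    if rho > 0:
        w = w / rho
    if dt_seconds > params.tau_s / 10.0:
        raise StabilityError(
            f"dt={dt_seconds} too coarse; need dt <= tau_s/10 = {params.tau_s / 10}"
        )
    n_steps = int(round(duration_seconds / dt_seconds))
    if n_steps < 1:
        raise ValueError("duration shorter than one step")
    rng = np.random.default_rng(seed)
    s0 = 0.1 + 0.01 * rng.uniform(size=m)
    noise = np.sqrt(dt_seconds) * rng.standard_normal(size=(n_steps, m))
    gating = _dmf_euler(
        w, params.omega, params.coupling_G, params.I0, params.sigma,
        params.J, params.tau_s, params.r_kinetic,
        params.a, params.b, params.d, dt_seconds, s0, noise,
    )
    if not np.all(np.isfinite(gating)):
        step = int(np.argwhere(~np.isfinite(gating))[0][0])
        raise DivergenceError(f"non-finite gating at step {step}")
    return NeuralTrajectory(gating=gating, dt_seconds=dt_seconds, seed=seed)


def gating_fixed_point(params: DMFParameters, tol: float = 1e-12) -> float:
    """Uncoupled (G=0) deterministic fixed point of the gating equation.

    Solves -S/tau_s + r (1 - S) H(omega*J*S + I0) = 0 by bisection on [0, 1].
    """
    def rhs(s: float) -> float:
        h = transfer_rate(params.omega * params.J * s + params.I0, params)
        return -s / params.tau_s + params.r_kinetic * (1.0 - s) * h

    lo, hi = 0.0, 1.0
    flo = rhs(lo)
    if flo < 0:
        return 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if rhs(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
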