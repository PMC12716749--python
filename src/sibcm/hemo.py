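"""Balloon-Windkessel hemodynamic model: synaptic gating to BOLD.

Per region, synaptic activity S drives a vasodilatory signal Z, inflow f,
blood volume v and deoxyhemoglobin content q:

    dZ/dt = S - kappa Z - gamma (f - 1)
    df/dt = Z
    tau dv/dt = f - v^(1/alpha)
    tau dq/dt = f [1 - (1 - rho)^(1/f)] / rho - q v^(1/alpha - 1)

    BOLD = V0 [ k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v) ]

Integrated with the same Euler step as the neural model from the resting
state (Z=0, f=v=q=1), a burn-in discarded, then decimated to the acquisition
TR by plain subsampling (every round(tr_out/dt)-th point; no anti-alias
filter, which keeps the output bit-reproducible and matches common practice
for these forward models).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit

from .data_io import ParcellatedTimeSeries
from .dmf import DivergenceError, NeuralTrajectory


@dataclasses.dataclass(frozen=True)
class HemodynamicParameters:
    """Balloon-Windkessel constants (standard literature values)."""

    kappa: float = 0.65    # 1/s, signal decay
    gamma_h: float = 0.41  # 1/s, flow-dependent elimination
    tau_h: float = 0.98    # s, mean transit time
    alpha: float = 0.32    # Grubb exponent
    rho: float = 0.34      # resting oxygen extraction fraction
    V0: float = 0.02       # resting venous volume fraction
    k1: float | None = None  # defaults to 7*rho
    k2: float = 2.0
    k3: float | None = None  # defaults to 2*rho - 0.2

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.gamma_h <= 0 or self.tau_h <= 0 or self.V0 <= 0:
            raise ValueError("kappa, gamma_h, tau_h, V0 must be positive")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if not (0 < self.rho < 1):
            raise ValueError("rho must lie in (0, 1)")
        if self.k1 is None:
            object.__setattr__(self, "k1", 7.0 * self.rho)
        if self.k3 is None:
            object.__setattr__(self, "k3", 2.0 * self.rho - 0.2)


@njit(cache=True)
def _balloon_euler(gating, dt, kappa, gamma, tau, alpha, rho, v0, k1, k2, k3):  # pragma: no cover
    n, m = gating.shape
    z = np.zeros(m)
    f = np.ones(m)
    v = np.ones(m)
    q = np.ones(m)
    bold = np.empty((n, m))
    inv_alpha = 1.0 / alpha
    for t in range(n):
        for i in range(m):
            s = gating[t, i]
            dz = s - kappa * z[i] - gamma * (f[i] - 1.0)
            df = z[i]
            dv = (f[i] - v[i] ** inv_alpha) / tau
            dq = (f[i] * (1.0 - (1.0 - rho) ** (1.0 / f[i])) / rho
                  - q[i] * v[i] ** (inv_alpha - 1.0)) / tau
            z[i] += dt * dz
            f[i] += dt * df
            v[i] += dt * dv
            q[i] += dt * dq
            if f[i] <= 0.0 or v[i] <= 0.0 or q[i] <= 0.0:
                return bold, t
            bold[t, i] = v0 * (k1 * (1.0 - q[i]) + k2 * (1.0 - q[i] / v[i])
                               + k3 * (1.0 - v[i]))
    return bold, -1


def balloon_bold(
    traj: NeuralTrajectory,
    hparams: HemodynamicParameters | None = None,
    tr_out_seconds: float = 0.72,
    burn_in_seconds: float = 60.0,
    region_ids=None,
    subject_id: str = "",
    session_id: str = "",
) -> ParcellatedTimeSeries:
    """Transform a gating trajectory into TR-sampled BOLD.

    The output has floor((duration - burn_in)/tr_out) samples; the first
    retained sample sits one TR after the end of the burn-in.
    """
    hparams = hparams or HemodynamicParameters()
    gating = np.asarray(traj.gating, dtype=float)
    dt = traj.dt_seconds
    duration = gating.shape[0] * dt
    if duration <= burn_in_seconds + tr_out_seconds:
        raise ValueError(
            f"duration {duration}s must exceed burn-in {burn_in_seconds}s + one TR"
        )
    bold, bad_step = _balloon_euler(
        gating, dt, hparams.kappa, hparams.gamma_h, hparams.tau_h,
        hparams.alpha, hparams.rho, hparams.V0,
        hparams.k1, hparams.k2, hparams.k3,
    )
    if bad_step >= 0:
        raise DivergenceError(
            f"hemodynamic state became non-positive at step {bad_step}"
        )
    stride = int(round(tr_out_seconds / dt))
    burn = int(round(burn_in_seconds / dt))
    n_out = int(np.floor((duration - burn_in_seconds) / tr_out_seconds))
    idx = burn + stride * (np.arange(n_out) + 1) - 1
    idx = idx[idx < bold.shape[0]]
    m = gating.shape[1]
    if region_ids is None:
        region_ids = [f"R{i:03d}" for i in range(m)]
    return ParcellatedTimeSeries(
        values=bold[idx], tr_seconds=tr_out_seconds, region_ids=region_ids,
        subject_id=subject_id, session_id=session_id,
    )


def balloon_steady_state(s_bar: float, hparams: HemodynamicParameters | None = None):
    """Algebraic steady state of the Balloon system for constant input s_bar.

    Returns (z, f, v, q, bold): z = 0, f = 1 + s_bar/gamma, v = f^alpha, and q
    from the q-stationarity equation.  Serves as an independent check on the
    integrated trajectory.
    """
    hp = hparams or HemodynamicParameters()
    f = 1.0 + s_bar / hp.gamma_h
    v = f ** hp.alpha
    q = f * (1.0 - (1.0 - hp.rho) ** (1.0 / f)) / hp.rho / (v ** (1.0 / hp.alpha - 1.0))
    bold = hp.V0 * (hp.k1 * (1.0 - q) + hp.k2 * (1.0 - q / v) + hp.k3 * (1.0 - v))
    return 0.0, f, v, q, bold
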