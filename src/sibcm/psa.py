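"""Phase-space association (PSA): the fitting target and cost.

Each region's signal is delay-embedded into 3-D phase space,

    PS_i = [x_i(t), x_i(t+tau), x_i(t+2tau)],  t = 1..T-2tau,

with a common delay tau chosen to precede the first local minimum of the
autocorrelation function.  For a region pair the PSA index is an SSIM-form
similarity of the two trajectories,

    PSA_ij = (2 mu_i mu_j + c1)(2 sigma_ij + c2)
             / ((mu_i^2 + mu_j^2 + c1)(sigma_i^2 + sigma_j^2 + c2)),

where means, variances and the cross-covariance are pooled over all
3(T-2tau) scalar entries of the embeddings.  Two variants are provided: the
``literal`` form above (symmetric), and a ``directional`` form whose
cross-covariance pairs PS_i(t) with PS_j(t+tau), which breaks the i/j
symmetry on lead-lag structured signals.  The scalar cost PSAC is the
Pearson correlation between the off-diagonal entries of an empirical and a
simulated PSA matrix.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .data_io import ParcellatedTimeSeries


class DegenerateSignalError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class PhaseTrajectory:
    """3-D delay embedding of one region's signal: (T - 2*tau, 3)."""

    points: np.ndarray
    tau_delay: int


@dataclasses.dataclass(frozen=True)
class PSAMatrix:
    values: np.ndarray
    tau_delay: int
    c1: float
    c2: float
    variant: str  # "literal" | "directional"


def select_delay(series: np.ndarray, max_lag: int = 20) -> int:
    """Embedding delay preceding the first local minimum of the ACF.

    Returns max(1, l* - 1) where l* is the first lag at which the sample
    autocorrelation has a local minimum; if no local minimum occurs within
    ``max_lag``, returns ``max_lag`` with a warning.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size <= 3 * max_lag:
        raise ValueError(f"series length {x.size} too short for max_lag {max_lag}")
    if np.ptp(x) == 0:
        raise DegenerateSignalError("constant series has no autocorrelation structure")
    xc = x - x.mean()
    denom = float(xc @ xc)
    acf = np.empty(max_lag + 2)
    acf[0] = 1.0
    for lag in range(1, max_lag + 2):
        acf[lag] = float(xc[:-lag] @ xc[lag:]) / denom
    for lag in range(1, max_lag + 1):
        if acf[lag] < acf[lag - 1] and acf[lag] < acf[lag + 1]:
            return max(1, lag - 1)
    warnings.warn(
        f"no ACF local minimum within {max_lag} lags; using tau={max_lag}",
        stacklevel=2,
    )
    return max_lag


def embed_trajectory(series: np.ndarray, tau: int) -> PhaseTrajectory:
    """Rows (x(t), x(t+tau), x(t+2tau)) for t = 1..T-2tau."""
    x = np.asarray(series, dtype=float).ravel()
    t = x.size
    if tau < 1:
        raise ValueError("tau must be a positive integer")
    n = t - 2 * tau
    if n < 3:
        raise ValueError(f"series length {t} too short for tau={tau} (need T >= 2*tau+3)")
    pts = np.column_stack([x[:n], x[tau : tau + n], x[2 * tau : 2 * tau + n]])
    return PhaseTrajectory(points=pts, tau_delay=tau)


def default_stability_constants(values: np.ndarray) -> tuple[float, float]:
    """SSIM-convention constants c1=(0.01 R)^2, c2=(0.03 R)^2 for range R."""
    r = float(np.ptp(values))
    if r == 0:
        r = 1.0
    return (0.01 * r) ** 2, (0.03 * r) ** 2


def psa_matrix(
    ts: ParcellatedTimeSeries,
    tau: int,
    c1: float | None = None,
    c2: float | None = None,
    variant: str = "literal",
) -> PSAMatrix:
    """PSA matrix over all region pairs of a series."""
    if variant not in ("literal", "directional"):
        raise ValueError(f"unknown variant {variant!r}")
    x = ts.values
    if c1 is None or c2 is None:
        d1, d2 = default_stability_constants(x)
        c1 = d1 if c1 is None else c1
        c2 = d2 if c2 is None else c2
    if c1 <= 0 or c2 <= 0:
        raise ValueError("stability constants c1, c2 must be positive")
    m = ts.n_regions
    emb = np.stack([embed_trajectory(x[:, i], tau).points for i in range(m)])
    flat = emb.reshape(m, -1)                      # (M, 3*(T-2tau))
    mu = flat.mean(axis=1)
    centered = flat - mu[:, None]
    var = (centered ** 2).mean(axis=1)
    if variant == "literal":
        cov = (centered @ centered.T) / flat.shape[1]
    else:
        ce = emb - mu[:, None, None]
        lead = ce[:, :-tau, :].reshape(m, -1)      # PS_i(t)
        lag = ce[:, tau:, :].reshape(m, -1)        # PS_j(t+tau)
        cov = (lead @ lag.T) / lead.shape[1]
    lum = (2.0 * np.outer(mu, mu) + c1) / (np.add.outer(mu ** 2, mu ** 2) + c1)
    struct = (2.0 * cov + c2) / (np.add.outer(var, var) + c2)
    vals = lum * struct
    np.fill_diagonal(vals, 1.0)
    return PSAMatrix(values=vals, tau_delay=tau, c1=float(c1), c2=float(c2),
                     variant=variant)


def subject_delay(ts: ParcellatedTimeSeries, max_lag: int = 20) -> int:
    """One global embedding delay: the median of per-region delays."""
    taus = [select_delay(ts.values[:, i], max_lag) for i in range(ts.n_regions)]
    return int(np.median(taus))


def psac(psa_emp: PSAMatrix, psa_sim: PSAMatrix) -> float:
    """Pearson correlation of off-diagonal PSA entries (the GA fitness).

    Uses the upper triangle for the literal variant (symmetric matrices) and
    all off-diagonal entries for the directional variant.
    """
    a, b = psa_emp.values, psa_sim.values
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if psa_emp.variant != psa_sim.variant:
        raise ValueError("cannot compare PSA matrices of different variants")
    m = a.shape[0]
    if psa_emp.variant == "literal":
        idx = np.triu_indices(m, k=1)
    else:
        idx = np.where(~np.eye(m, dtype=bool))
    return float(np.corrcoef(a[idx], b[idx])[0, 1])
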