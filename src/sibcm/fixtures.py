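"""Synthetic ground-truth generators.

These emulate the statistical structure the pipeline assumes — a shared
low-rank connectivity component with per-window sparse outliers, modular
coupling patterns, and model-generated BOLD subjects — so every stage can be
tested with known truth and no external dataset.  All generators are pure
functions of their arguments including the seed.  They do not attempt to
emulate scanner noise, motion artifacts, or the empirical spectral content
of real acquisitions.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .coactivity import CoactivityPattern, SegmentStack
from .data_io import ParcellatedTimeSeries
from .dmf import DMFParameters, simulate_dmf
from .hemo import HemodynamicParameters, balloon_bold


@dataclasses.dataclass(frozen=True)
class PlantedGroundTruth:
    """What a generator planted, for recovery scoring."""

    true_low_rank: np.ndarray | None = None
    true_sparse_support: tuple | None = None   # per window, upper-tri indices
    true_params: DMFParameters | None = None
    true_pattern: CoactivityPattern | None = None
    seed: int = 0


def make_planted_stack(
    m: int = 20,
    n: int = 12,
    rank: int = 2,
    sparse_fraction: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[SegmentStack, PlantedGroundTruth]:
    """Shared low-rank component + per-window sparse outliers.

    The shared component is a symmetric rank-``rank`` matrix scaled to peak
    magnitude 0.35; each window adds symmetric large-magnitude outliers
    (uniform 0.45-0.6, either sign — clearly separable from the shared
    component) at ``sparse_fraction`` of the off-diagonal edges (support
    disjoint from the diagonal), plus optional Gaussian perturbation.  Matrices are symmetrized,
    the diagonal is set to 1 and entries are clipped to [-1, 1]; magnitudes
    are chosen so clipping never bites and the truth stays exact.
    """
    if not (0 <= sparse_fraction <= 0.3):
        raise ValueError("sparse_fraction must lie in [0, 0.3]")
    if rank >= m:
        raise ValueError("rank must be smaller than the number of regions")
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(m, rank))
    shared = u @ u.T
    shared *= 0.35 / np.abs(shared).max()
    shared = 0.5 * (shared + shared.T)

    iu = np.triu_indices(m, k=1)
    n_edges = iu[0].size
    k = int(round(sparse_fraction * n_edges))
    mats = np.empty((n, m, m))
    supports = []
    for w in range(n):
        s = np.zeros((m, m))
        pick = rng.choice(n_edges, size=k, replace=False)
        vals = rng.uniform(0.45, 0.6, size=k) * rng.choice([-1.0, 1.0], size=k)
        s[iu[0][pick], iu[1][pick]] = vals
        s = s + s.T
        supports.append(tuple(sorted(int(p) for p in pick)))
        mat = shared + s
        if noise_sd > 0:
            e = rng.normal(scale=noise_sd, size=(m, m))
            mat = mat + 0.5 * (e + e.T)
        np.fill_diagonal(mat, 1.0)
        mats[w] = np.clip(mat, -1.0, 1.0)
    stack = SegmentStack(matrices=mats, window_length=30, step=10)
    truth = PlantedGroundTruth(
        true_low_rank=shared, true_sparse_support=tuple(supports), seed=seed
    )
    return stack, truth


def fractional_gaussian_noise(n: int, hurst: float, seed: int = 0) -> np.ndarray:
    """Exact fractional Gaussian noise by circulant embedding (Davies-Harte).

    Unit-variance increments of fractional Brownian motion with the given
    Hurst exponent; hurst=0.5 gives white noise.  Used as a known-exponent
    signal for the DFA estimator.
    """
    if not (0 < hurst < 1):
        raise ValueError("hurst must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    k = np.arange(n)
    gamma = 0.5 * (np.abs(k - 1) ** (2 * hurst) - 2 * k ** (2 * hurst)
                   + (k + 1) ** (2 * hurst))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.fft(row).real
    eig = np.maximum(eig, 0.0)  # clip tiny negatives from rounding
    m = row.size
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.fft(np.sqrt(eig / (2.0 * m)) * z)
    return x[:n].real * np.sqrt(2.0)


def make_modular_pattern(
    m: int = 20,
    n_modules: int = 4,
    within_weight: float = 0.8,
    between_weight: float = -0.15,
    seed: int = 0,
    jitter: float = 0.05,
) -> CoactivityPattern:
    """Block-modular coupling pattern, symmetric, zero diagonal, peak 1."""
    if n_modules > m or n_modules < 1:
        raise ValueError("need 1 <= n_modules <= m")
    rng = np.random.default_rng(seed)
    labels = np.arange(m) % n_modules
    w = np.where(np.equal.outer(labels, labels), within_weight, between_weight)
    e = rng.normal(scale=jitter, size=(m, m))
    w = w + 0.5 * (e + e.T)
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    w /= np.abs(w).max()
    return CoactivityPattern(
        weights=w, normalization="max-abs-one",
        provenance={"generator": "make_modular_pattern", "seed": seed,
                    "n_modules": n_modules},
    )


def make_synthetic_subject(
    pattern: CoactivityPattern,
    params: DMFParameters,
    duration_seconds: float = 300.0,
    tr_out_seconds: float = 0.72,
    seed: int = 0,
    dt_seconds: float = 0.001,
    burn_in_seconds: float = 60.0,
    hparams: HemodynamicParameters | None = None,
    subject_id: str = "synthetic",
) -> tuple[ParcellatedTimeSeries, PlantedGroundTruth]:
    """Self-simulated BOLD subject with recorded generating truth.

    ``duration_seconds`` covers the post-burn-in window, so the output has
    floor(duration/tr_out) samples.
    """
    traj = simulate_dmf(
        pattern, params, duration_seconds + burn_in_seconds,
        dt_seconds=dt_seconds, seed=seed,
    )
    bold = balloon_bold(
        traj, hparams, tr_out_seconds=tr_out_seconds,
        burn_in_seconds=burn_in_seconds, subject_id=subject_id,
        session_id=f"seed{seed}",
    )
    truth = PlantedGroundTruth(true_params=params, true_pattern=pattern, seed=seed)
    return bold, truth
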