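"""Stable spatiotemporal co-activity pattern inference.

The observed BOLD series is cut into overlapping windows and a per-window
connectivity matrix (pairwise Pearson correlation) is computed.  The upper
triangles of the N window matrices are stacked as columns of one
edge-by-window matrix X (M(M-1)/2 x N), which is decomposed into a low-rank
component shared across windows plus sparse per-window outliers,

    min  ||L||_*  +  lambda1 ||S||_1  +  lambda2 ||B vec(L)||_1
    s.t. L + S = X,

where B is the first-order difference operator across consecutive windows,
so the last term is a fused (total-variation) penalty pulling each edge's
low-rank profile toward a constant across windows.  Penalizing the rank of
the stacked matrix — few shared edge-patterns explain all windows — is what
pools the windows' information; a per-window rank penalty would decouple
into N independent problems.  The enforced unit diagonal of each correlation
matrix never enters the decomposition (only off-diagonal edges are stacked).
The solver is a two-block ADMM: singular-value soft-thresholding of the
stacked matrix, elementwise soft-thresholding of S, and an exact 1-D
total-variation prox per edge across the window index (Condat's direct
algorithm) on an auxiliary copy Z = L.

The co-activity pattern W_L is the across-window mean of the low-rank
components, symmetrized, zero-diagonal, optionally scaled to unit maximum
absolute weight so the global coupling G is comparable across subjects.
"""

from __future__ import annotations

import dataclasses
import numpy as np
from numba import njit

from .data_io import ParcellatedTimeSeries


class DegenerateWindowError(ValueError):
    """A region is constant within a window, so its correlation is undefined."""


class OptionError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class SegmentStack:
    """N windowed connectivity matrices, each M x M symmetric, unit diagonal."""

    matrices: np.ndarray  # (N, M, M)
    window_length: int
    step: int

    @property
    def n_segments(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_regions(self) -> int:
        return self.matrices.shape[1]


@dataclasses.dataclass(frozen=True)
class FusedRpcaOptions:
    """Tuning knobs of the fused low-rank + sparse decomposition.

    ``lambda1`` weights per-window sparsity; the default 1/sqrt(N) reflects
    that the window axis is the random-sign dimension of the stacked
    edge-by-window matrix: the recovery condition requires lambda1 to exceed
    max_e |u_e| / sqrt(N) for the normalized shared edge profile u, and both
    sides shrink at the same 1/sqrt(N) rate.  ``lambda2`` weights the
    across-window fusion penalty; default 0.1 * lambda1.  ``admm_penalty`` is
    the ADMM step parameter rho.
    """

    lambda1: float | None = None
    lambda2: float | None = None
    max_iterations: int = 1500
    tolerance: float = 1e-6
    admm_penalty: float = 1.0

    def resolve(self, m: int, n: int) -> tuple[float, float]:
        lam1 = self.lambda1 if self.lambda1 is not None else 1.0 / np.sqrt(n)
        lam2 = self.lambda2 if self.lambda2 is not None else 0.1 * lam1
        if lam1 <= 0:
            raise OptionError(f"lambda1 must be positive, got {lam1}")
        if lam2 < 0:
            raise OptionError(f"lambda2 must be nonnegative, got {lam2}")
        if self.tolerance <= 0 or self.max_iterations < 1 or self.admm_penalty <= 0:
            raise OptionError("tolerance, max_iterations, admm_penalty must be positive")
        return lam1, lam2


@dataclasses.dataclass(frozen=True)
class DecompositionResult:
    low_rank: np.ndarray       # (N, M, M)
    sparse: np.ndarray         # (N, M, M)
    iterations_used: int
    final_residual: float
    converged: bool
    objective_history: np.ndarray


@dataclasses.dataclass(frozen=True)
class CoactivityPattern:
    """The stable symmetric coupling matrix W_L (zero diagonal)."""

    weights: np.ndarray
    normalization: str = "max-abs-one"
    provenance: dict = dataclasses.field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def segment_connectivity(
    ts: ParcellatedTimeSeries, window_length: int, step: int
) -> SegmentStack:
    """Per-window pairwise Pearson correlation matrices.

    Window n covers samples [n*step, n*step + window_length); the number of
    windows is N = floor((T - window_length)/step) + 1.  The diagonal is set
    to exactly 1.
    """
    x = ts.values
    t, m = x.shape
    if window_length > t:
        raise ValueError(f"window_length {window_length} exceeds T={t}")
    if window_length < 3:
        raise ValueError("window_length must be at least 3")
    if step < 1:
        raise ValueError("step must be positive")
    n = (t - window_length) // step + 1
    out = np.empty((n, m, m))
    for k in range(n):
        seg = x[k * step : k * step + window_length]
        sd = seg.std(axis=0)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            raise DegenerateWindowError(
                f"region {ts.region_ids[flat[0]]!r} constant in window {k}"
            )
        c = np.corrcoef(seg, rowvar=False)
        np.fill_diagonal(c, 1.0)
        out[k] = c
    return SegmentStack(matrices=out, window_length=window_length, step=step)


@njit(cache=True)
def _tv1d(y, lam, x):  # pragma: no cover - exercised via tv_prox
    """Direct single-sweep algorithm for the 1-D total-variation prox.

    Solves min_x 0.5*||x - y||^2 + lam * sum_k |x_{k+1} - x_k| exactly by
    forward segment fusion (Condat's direct method).
    """
    n = y.shape[0]
    if n == 0:
        return
    if n == 1 or lam <= 0.0:
        x[:] = y
        return
    k = 0
    k0 = 0
    kminus = 0
    kplus = 0
    umin = lam
    umax = -lam
    vmin = y[0] - lam
    vmax = y[0] + lam
    while True:
        while k == n - 1:
            if umin < 0.0:
                while True:
                    x[k0] = vmin
                    k0 += 1
                    if k0 > kminus:
                        break
                kminus = k = k0
                vmin = y[k0]
                umin = lam
                umax = vmin + lam - vmax
            elif umax > 0.0:
                while True:
                    x[k0] = vmax
                    k0 += 1
                    if k0 > kplus:
                        break
                kplus = k = k0
                vmax = y[k0]
                umax = -lam
                umin = vmax - lam - vmin
            else:
                vmin += umin / (k - k0 + 1)
                while True:
                    x[k0] = vmin
                    k0 += 1
                    if k0 > k:
                        break
                return
        umin += y[k + 1] - vmin
        if umin < -lam:
            while True:
                x[k0] = vmin
                k0 += 1
                if k0 > kminus:
                    break
            kplus = kminus = k = k0
            vmin = y[k0]
            vmax = vmin + 2.0 * lam
            umin = lam
            umax = -lam
        else:
            umax += y[k + 1] - vmax
            if umax > lam:
                while True:
                    x[k0] = vmax
                    k0 += 1
                    if k0 > kplus:
                        break
                kplus = kminus = k = k0
                vmax = y[k0]
                vmin = vmax - 2.0 * lam
                umin = lam
                umax = -lam
            else:
                k += 1
                if umin >= lam:
                    kminus = k
                    vmin += (umin - lam) / (kminus - k0 + 1)
                    umin = lam
                if umax <= -lam:
                    kplus = k
                    vmax += (umax + lam) / (kplus - k0 + 1)
                    umax = -lam


@njit(cache=True)
def _tv_prox_columns(y, lam):  # pragma: no cover
    """Apply the 1-D TV prox to every column of a (N, P) array."""
    n, p = y.shape
    out = np.empty_like(y)
    buf = np.empty(n)
    for j in range(p):
        _tv1d(np.ascontiguousarray(y[:, j]), lam, buf)
        out[:, j] = buf
    return out


def tv_prox(y: np.ndarray, lam: float) -> np.ndarray:
    """Exact prox of ``lam * TV`` along axis 0 of a 2-D array."""
    y = np.ascontiguousarray(np.atleast_2d(np.asarray(y, dtype=float).T).T)
    return _tv_prox_columns(y, float(lam))


def _svt(a: np.ndarray, thresh: float) -> np.ndarray:
    """Singular-value soft-thresholding (nuclear-norm prox)."""
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    s = np.maximum(s - thresh, 0.0)
    return (u * s) @ vt


def _soft(a: np.ndarray, thresh: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - thresh, 0.0)


def _objective(low: np.ndarray, sigma: np.ndarray, lam1: float, lam2: float,
               iu: tuple[np.ndarray, np.ndarray]) -> float:
    """Objective with S eliminated by the constraint S = Sigma - L."""
    nuc = sum(np.linalg.svd(m, compute_uv=False).sum() for m in low)
    l1 = np.abs(sigma - low).sum()
    edges = low[:, iu[0], iu[1]]
    fuse = np.abs(np.diff(edges, axis=0)).sum()
    return nuc + lam1 * l1 + lam2 * fuse


def fused_rpca(stack: SegmentStack, opts: FusedRpcaOptions | None = None) -> DecompositionResult:
    """Fused low-rank + sparse decomposition of a window-connectivity stack.

    Operates on the stacked edge-by-window matrix (see module docstring); the
    returned per-window components are the re-symmetrized columns, with the
    unit diagonal assigned to the low-rank side so that L_n + S_n = Sigma(n)
    holds exactly and S's support is purely off-diagonal.

    Deterministic for fixed inputs and options.  Non-convergence within
    ``max_iterations`` is reported through ``converged=False`` rather than an
    exception; diagnostics (iterations, final relative residual, objective
    history) are always returned.
    """
    opts = opts or FusedRpcaOptions()
    sigma = np.asarray(stack.matrices, dtype=float)
    n, m, _ = sigma.shape
    if n < 2:
        raise ValueError(f"need at least 2 windows, got {n}")
    lam1, lam2 = opts.resolve(m, n)
    rho = opts.admm_penalty

    iu = np.triu_indices(m, k=1)
    x = sigma[:, iu[0], iu[1]].T          # (E, N): one column per window

    low = np.zeros_like(x)
    spr = np.zeros_like(x)
    z = np.zeros_like(x)
    u_dual = np.zeros_like(x)             # scaled dual for L + S = X
    v_dual = np.zeros_like(x)             # scaled dual for L - Z = 0

    norm_x = np.linalg.norm(x)

    def objective(lmat):
        nuc = np.linalg.svd(lmat, compute_uv=False).sum()
        return (nuc + lam1 * np.abs(x - lmat).sum()
                + lam2 * np.abs(np.diff(lmat, axis=1)).sum())

    obj_hist = [objective(low)]
    rel = np.inf
    converged = False
    it = 0
    for it in range(1, opts.max_iterations + 1):
        # L-update: nuclear prox at the average of the two pulls
        low = _svt(0.5 * ((x - spr - u_dual) + (z - v_dual)), 0.5 / rho)
        # S-update (soft threshold) and Z-update (fusion prox), separable
        spr_old = spr
        z_old = z
        spr = _soft(x - low - u_dual, lam1 / rho)
        z = tv_prox((low + v_dual).T, lam2 / rho).T   # TV along windows per edge
        # dual ascent
        r1 = low + spr - x
        r2 = low - z
        u_dual = u_dual + r1
        v_dual = v_dual + r2
        prim = np.sqrt(np.linalg.norm(r1) ** 2 + np.linalg.norm(r2) ** 2)
        dual = rho * np.sqrt(np.linalg.norm(spr - spr_old) ** 2
                             + np.linalg.norm(z - z_old) ** 2)
        rel = max(prim, dual) / max(norm_x, 1e-12)
        obj_hist.append(objective(low))
        if rel <= opts.tolerance:
            converged = True
            break

    low_mats = np.zeros_like(sigma)
    low_mats[:, iu[0], iu[1]] = low.T
    low_mats[:, iu[1], iu[0]] = low.T
    didx = np.arange(m)
    low_mats[:, didx, didx] = sigma[:, didx, didx]  # carries the (unit) diagonal
    return DecompositionResult(
        low_rank=low_mats, sparse=sigma - low_mats, iterations_used=it,
        final_residual=float(rel), converged=converged,
        objective_history=np.asarray(obj_hist),
    )


def build_pattern(
    decomp: DecompositionResult,
    normalization: str = "max-abs-one",
    provenance: dict | None = None,
) -> CoactivityPattern:
    """Average the low-rank components into the stable pattern W_L.

    The mean is symmetrized as (A + A')/2, the diagonal zeroed (self-coupling
    is carried by the recurrent strength omega in the dynamic model), and the
    result optionally scaled so the maximum absolute off-diagonal weight is 1.
    """
    if normalization not in ("none", "max-abs-one"):
        raise ValueError(f"unknown normalization {normalization!r}")
    a = decomp.low_rank.mean(axis=0)
    w = 0.5 * (a + a.T)
    np.fill_diagonal(w, 0.0)
    if normalization == "max-abs-one":
        peak = np.abs(w).max()
        if peak > 0:
            w = w / peak
    return CoactivityPattern(
        weights=w, normalization=normalization, provenance=provenance or {}
    )


def extract_pattern(
    ts: ParcellatedTimeSeries,
    window_length: int = 30,
    step: int = 10,
    opts: FusedRpcaOptions | None = None,
    normalization: str = "max-abs-one",
) -> tuple[CoactivityPattern, DecompositionResult]:
    """Convenience: series -> windowed stack -> decomposition -> pattern.

    A single-window stack has nothing to decompose: the pattern is that
    window's connectivity itself (symmetrized, zero diagonal, normalized).
    """
    stack = segment_connectivity(ts, window_length, step)
    if stack.n_segments == 1:
        decomp = DecompositionResult(
            low_rank=stack.matrices.copy(), sparse=np.zeros_like(stack.matrices),
            iterations_used=0, final_residual=0.0, converged=True,
            objective_history=np.zeros(1),
        )
    else:
        decomp = fused_rpca(stack, opts)
    prov = {
        "window_length": window_length, "step": step,
        "n_segments": stack.n_segments,
        "converged": bool(decomp.converged),
        "final_residual": decomp.final_residual,
    }
    pattern = build_pattern(decomp, normalization, provenance=prov)
    return pattern, decomp


def pattern_correlation(a: CoactivityPattern, b: CoactivityPattern) -> float:
    """Pearson correlation of upper-triangle weights of two patterns."""
    iu = np.triu_indices(a.n_regions, k=1)
    return float(np.corrcoef(a.weights[iu], b.weights[iu])[0, 1])
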