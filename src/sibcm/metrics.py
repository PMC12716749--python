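"""Evaluation metrics for empirical vs simulated BOLD.

Covers static FC similarity (edge- and node-level), dynamic FC (sliding
window FC, sigma-dFC, FCD and its KS distance), signal descriptors (Welch
spectra with cosine distance, DFA Hurst exponent), phase dynamics (Kuramoto
synchrony and metastability, per-window integration/segregation, ISOR),
binary graph topology at a proportional threshold, within/between-RSN block
FC, and the intraclass correlation coefficient for test-retest stability.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .coactivity import segment_connectivity
from .data_io import DegenerateRegionError, ParcellatedTimeSeries, ParcellationMap

RSN_ORDER = ("VIS", "SMN", "DAN", "VAN", "LIM", "FPN", "DMN")


class NyquistError(ValueError):
    """Requested band is not representable at the sampling interval."""


@dataclasses.dataclass(frozen=True)
class WindowFCStack:
    matrices: np.ndarray  # (N_w, M, M)
    window_length: int
    step: int


@dataclasses.dataclass(frozen=True)
class PhaseDynamicsSummary:
    synchrony: float
    metastability: float
    integration: float
    segregation: float
    isor: float
    window_integration: np.ndarray


@dataclasses.dataclass(frozen=True)
class GraphMetrics:
    global_efficiency: float
    local_efficiency: float
    path_length: float
    clustering: float
    participation: float
    modularity: float
    connected: bool


def static_fc(ts: ParcellatedTimeSeries) -> np.ndarray:
    """Full-series pairwise Pearson correlation, unit diagonal."""
    sd = ts.values.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise DegenerateRegionError(f"constant region {ts.region_ids[flat[0]]!r}")
    fc = np.corrcoef(ts.values, rowvar=False)
    np.fill_diagonal(fc, 1.0)
    return fc


def _fisher_z(fc: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(fc, -1 + 1e-7, 1 - 1e-7))


def fc_similarity(fc_a: np.ndarray, fc_b: np.ndarray) -> tuple[float, float]:
    """(edge_r, node_r) between two FC matrices.

    edge_r correlates Fisher-z-transformed upper triangles; node_r correlates
    per-region mean off-diagonal FC strengths.
    """
    if fc_a.shape != fc_b.shape:
        raise ValueError(f"shape mismatch: {fc_a.shape} vs {fc_b.shape}")
    m = fc_a.shape[0]
    iu = np.triu_indices(m, k=1)
    edge_r = float(np.corrcoef(_fisher_z(fc_a[iu]), _fisher_z(fc_b[iu]))[0, 1])
    off = ~np.eye(m, dtype=bool)
    node_a = (fc_a * off).sum(axis=1) / (m - 1)
    node_b = (fc_b * off).sum(axis=1) / (m - 1)
    node_r = float(np.corrcoef(node_a, node_b)[0, 1])
    return edge_r, node_r


def dynamic_fc(
    ts: ParcellatedTimeSeries, window_length: int = 30, step: int = 10
) -> tuple[WindowFCStack, np.ndarray, np.ndarray]:
    """(window FC stack, sigma-dFC, FCD).

    sigma-dFC is the across-window standard deviation of each edge; FCD entry
    (p, q) is the Pearson correlation between the upper-triangle vectors of
    window FCs p and q.
    """
    stack = segment_connectivity(ts, window_length, step)
    mats = stack.matrices
    sigma_dfc = mats.std(axis=0)
    np.fill_diagonal(sigma_dfc, 0.0)
    m = mats.shape[1]
    iu = np.triu_indices(m, k=1)
    vecs = mats[:, iu[0], iu[1]]
    if vecs.shape[0] == 1:
        fcd = np.ones((1, 1))
    else:
        fcd = np.corrcoef(vecs)
        np.fill_diagonal(fcd, 1.0)
    return (
        WindowFCStack(matrices=mats, window_length=window_length, step=step),
        sigma_dfc,
        fcd,
    )


def dfc_similarity(sigma_dfc_a: np.ndarray, sigma_dfc_b: np.ndarray) -> float:
    """Correlation of vectorized sigma-dFC matrices (dynamic-FC similarity)."""
    iu = np.triu_indices(sigma_dfc_a.shape[0], k=1)
    return float(np.corrcoef(sigma_dfc_a[iu], sigma_dfc_b[iu])[0, 1])


def fcd_ks(fcd_a: np.ndarray, fcd_b: np.ndarray) -> float:
    """Two-sample KS statistic between the FCD upper-triangle distributions."""
    if fcd_a.shape[0] < 2 or fcd_b.shape[0] < 2:
        raise ValueError("need at least 2 windows in each FCD matrix")
    a = fcd_a[np.triu_indices(fcd_a.shape[0], k=1)]
    b = fcd_b[np.triu_indices(fcd_b.shape[0], k=1)]
    return float(spstats.ks_2samp(a, b, method="asymp").statistic)


def power_spectrum(ts: ParcellatedTimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Welch periodogram per region (Hann, 50% overlap, nperseg<=256)."""
    t = ts.n_timepoints
    if t < 8:
        raise ValueError("need at least 8 samples for a spectrum")
    nperseg = min(t, 256)
    freqs, pxx = sps.welch(
        ts.values, fs=1.0 / ts.tr_seconds, window="hann",
        nperseg=nperseg, noverlap=nperseg // 2, axis=0,
    )
    return freqs, pxx.T  # (M, F)


def spectral_cosine_distance(spectra_a: np.ndarray, spectra_b: np.ndarray) -> float:
    """1 - cosine similarity of the region-mean spectrum vectors."""
    a = np.asarray(spectra_a).mean(axis=0)
    b = np.asarray(spectra_b).mean(axis=0)
    if a.shape != b.shape:
        raise ValueError("spectra have different frequency grids")
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        raise ValueError("zero spectrum")
    return float(1.0 - (a @ b) / denom)


def _dfa_single(x: np.ndarray, box_sizes: np.ndarray) -> float:
    profile = np.cumsum(x - x.mean())
    fluct = np.empty(box_sizes.size)
    for k, n in enumerate(box_sizes):
        n_boxes = profile.size // n
        segs = profile[: n_boxes * n].reshape(n_boxes, n)
        tt = np.arange(n)
        # least-squares linear detrend per box
        coef = np.polynomial.polynomial.polyfit(tt, segs.T, 1)
        resid = segs - (coef[0][:, None] + coef[1][:, None] * tt)
        fluct[k] = np.sqrt(np.mean(resid ** 2))
    slope = np.polyfit(np.log(box_sizes), np.log(fluct), 1)[0]
    return float(slope)


def hurst_exponent(ts: ParcellatedTimeSeries) -> np.ndarray:
    """Per-region DFA scaling exponent (box sizes 4 .. T/4, log-spaced)."""
    t = ts.n_timepoints
    if t < 100:
        raise ValueError("need at least 100 samples for DFA")
    sd = ts.values.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise DegenerateRegionError(f"constant region {ts.region_ids[flat[0]]!r}")
    box_sizes = np.unique(
        np.floor(np.logspace(np.log10(4), np.log10(t // 4), 12)).astype(int)
    )
    return np.array([_dfa_single(ts.values[:, i], box_sizes)
                     for i in range(ts.n_regions)])


def bandpass(ts: ParcellatedTimeSeries, band: tuple[float, float]) -> ParcellatedTimeSeries:
    """Zero-phase 2nd-order Butterworth band-pass."""
    nyq = 0.5 / ts.tr_seconds
    low, high = band
    if not (0 < low < high < nyq):
        raise NyquistError(
            f"band {band} infeasible at TR={ts.tr_seconds}s (Nyquist {nyq:.3f} Hz)"
        )
    sos = sps.butter(2, [low / nyq, high / nyq], btype="bandpass", output="sos")
    return ts.with_values(sps.sosfiltfilt(sos, ts.values, axis=0))


def kuramoto_order(ts: ParcellatedTimeSeries, band: tuple[float, float] = (0.01, 0.1)) -> np.ndarray:
    """Instantaneous Kuramoto order parameter R(t) from Hilbert phases."""
    filtered = bandpass(ts, band)
    phases = np.angle(sps.hilbert(filtered.values, axis=0))
    return np.abs(np.exp(1j * phases).mean(axis=1))


def weighted_global_efficiency(w: np.ndarray) -> float:
    """Global efficiency of a weighted graph (distance = 1/weight)."""
    m = w.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(m))
    for i in range(m):
        for j in range(i + 1, m):
            if w[i, j] > 0:
                g.add_edge(i, j, distance=1.0 / w[i, j])
    total, count = 0.0, 0
    for src, dists in nx.all_pairs_dijkstra_path_length(g, weight="distance"):
        for dst, dval in dists.items():
            if dst != src and dval > 0:
                total += 1.0 / dval
                count += 1
    pairs = m * (m - 1)
    return total / pairs if pairs else 0.0


def _partition_sets(labels) -> list[set]:
    groups: dict[str, set] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(idx)
    return list(groups.values())


def _positive_graph(w: np.ndarray) -> nx.Graph:
    m = w.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(m))
    for i in range(m):
        for j in range(i + 1, m):
            if w[i, j] > 0:
                g.add_edge(i, j, weight=w[i, j])
    return g


def phase_dynamics(
    ts: ParcellatedTimeSeries,
    band: tuple[float, float] = (0.01, 0.1),
    window_length: int = 30,
    step: int = 10,
    parcmap: ParcellationMap | None = None,
    reference_integration: np.ndarray | None = None,
) -> PhaseDynamicsSummary:
    """Synchrony, metastability, integration, segregation and ISOR.

    Synchrony/metastability are the time-mean and time-std of the Kuramoto
    order parameter of band-passed Hilbert phases.  Integration is the
    weighted global efficiency of each window's absolute FC; segregation the
    Newman modularity of each window's positive FC under the RSN partition
    (communities found by greedy modularity maximization when no partition is
    supplied); both are averaged over windows.  ISOR is the fraction of
    windows whose integration exceeds the median integration of the reference
    (the series itself when no reference is given).
    """
    r = kuramoto_order(ts, band)
    stack = segment_connectivity(ts, window_length, step).matrices
    labels = parcmap.labels_for(ts.region_ids) if parcmap is not None else None
    integ = np.empty(stack.shape[0])
    segr = np.empty(stack.shape[0])
    for k, fc in enumerate(stack):
        a = np.abs(fc.copy())
        np.fill_diagonal(a, 0.0)
        integ[k] = weighted_global_efficiency(a)
        pos = np.where(fc > 0, fc, 0.0)
        np.fill_diagonal(pos, 0.0)
        g = _positive_graph(pos)
        if g.number_of_edges() == 0:
            segr[k] = 0.0
            continue
        if labels is not None:
            comms = _partition_sets(labels)
        else:
            comms = list(nx.community.greedy_modularity_communities(g, weight="weight"))
        segr[k] = nx.community.modularity(g, comms, weight="weight")
    ref = integ if reference_integration is None else np.asarray(reference_integration)
    isor = float(np.mean(integ > np.median(ref)))
    return PhaseDynamicsSummary(
        synchrony=float(r.mean()),
        metastability=float(r.std()),
        integration=float(integ.mean()),
        segregation=float(segr.mean()),
        isor=isor,
        window_integration=integ,
    )


def proportional_threshold(fc: np.ndarray, density: float) -> np.ndarray:
    """Binarize |FC| keeping the top ``density`` fraction of edges."""
    if not (0 < density <= 1):
        raise ValueError("density must lie in (0, 1]")
    m = fc.shape[0]
    iu = np.triu_indices(m, k=1)
    strengths = np.abs(fc[iu])
    k = int(round(density * strengths.size))
    adj = np.zeros((m, m), dtype=bool)
    if k > 0:
        order = np.argsort(strengths)[::-1][:k]
        order = order[strengths[order] > 0]  # a zero entry is no connection
        adj[iu[0][order], iu[1][order]] = True
        adj |= adj.T
    return adj


def participation_coefficient(g: nx.Graph, labels) -> np.ndarray:
    """PC_i = 1 - sum_m (k_im / k_i)^2 over modules m (0 for isolated nodes)."""
    modules = sorted(set(labels))
    pc = np.zeros(g.number_of_nodes())
    for i in g.nodes:
        k_i = g.degree(i)
        if k_i == 0:
            continue
        acc = 0.0
        for mod in modules:
            k_im = sum(1 for nb in g.neighbors(i) if labels[nb] == mod)
            acc += (k_im / k_i) ** 2
        pc[i] = 1.0 - acc
    return pc


def graph_metrics(
    fc: np.ndarray,
    density: float = 0.15,
    parcmap: ParcellationMap | None = None,
    region_ids=None,
) -> GraphMetrics:
    """The six binary-graph measures at a proportional threshold.

    On a disconnected graph the characteristic path length averages only
    finite distances and global efficiency (harmonic mean) naturally skips
    infinite ones; the ``connected`` flag records the situation.
    """
    if not np.allclose(fc, fc.T):
        raise ValueError("FC matrix must be symmetric")
    m = fc.shape[0]
    adj = proportional_threshold(fc, density)
    g = nx.from_numpy_array(adj.astype(int))
    connected = nx.is_connected(g) if m > 0 else True
    eglob = nx.global_efficiency(g)
    eloc = nx.local_efficiency(g)
    total, count = 0.0, 0
    for src, dists in nx.all_pairs_shortest_path_length(g):
        for dst, dval in dists.items():
            if dst != src:
                total += dval
                count += 1
    path_length = total / count if count else float("inf")
    cc = nx.average_clustering(g)
    if parcmap is not None and region_ids is not None:
        labels = parcmap.labels_for(region_ids)
    else:
        comms = list(nx.community.greedy_modularity_communities(g))
        labels = [0] * m
        for ci, com in enumerate(comms):
            for node in com:
                labels[node] = ci
    pc = participation_coefficient(g, labels)
    q = nx.community.modularity(g, _partition_sets(labels))
    return GraphMetrics(
        global_efficiency=float(eglob), local_efficiency=float(eloc),
        path_length=float(path_length), clustering=float(cc),
        participation=float(pc.mean()), modularity=float(q),
        connected=bool(connected),
    )


def network_block_fc(
    fc: np.ndarray, parcmap: ParcellationMap, region_ids
) -> np.ndarray:
    """7x7 RSN block means of an FC matrix (order VIS..DMN).

    Diagonal blocks average within-RSN off-diagonal FC; off-diagonal blocks
    average all region pairs across the two RSNs.  An RSN with fewer than 2
    regions has an undefined within value (NaN); absent RSNs give NaN rows.
    """
    labels = np.array(parcmap.labels_for(region_ids))
    k = len(RSN_ORDER)
    out = np.full((k, k), np.nan)
    for a in range(k):
        mask_a = labels == RSN_ORDER[a]
        if not mask_a.any():
            continue
        for b in range(a, k):
            mask_b = labels == RSN_ORDER[b]
            if not mask_b.any():
                continue
            block = fc[np.ix_(mask_a, mask_b)]
            if a == b:
                if mask_a.sum() < 2:
                    continue
                off = ~np.eye(mask_a.sum(), dtype=bool)
                out[a, a] = block[off].mean()
            else:
                out[a, b] = out[b, a] = block.mean()
    return out


def icc(measurements: np.ndarray) -> float:
    """Consistency ICC from a subjects x sessions table.

    Two-way mean squares: MSR between subjects, MSE the residual after
    removing subject and session effects; ICC = (MSR - MSE)/(MSR + (k-1) MSE).
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 sessions")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing entries in the measurement table")
    n, k = x.shape
    grand = x.mean()
    ssr = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ssc = n * np.sum((x.mean(axis=0) - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse
    if denom == 0:
        raise ValueError("ICC undefined: zero total variance")
    return float((msr - mse) / denom)
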