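"""Density-thresholded weighted graphs and their summary metrics.

A connectivity matrix is turned into a weighted graph by proportional
thresholding: the fraction ``density`` of strongest channel pairs keeps its
weights, everything else is zeroed (negative debiased dwPLI values are
clipped to 0 first — they are noise artifacts with no weight interpretation).
On each graph we compute:

* modularity Q of the best Louvain partition (Newman weighted form),
* mean Onnela weighted clustering coefficient,
* the standard deviation over nodes of the participation coefficient,
* modular span: the weight-weighted mean electrode distance covered by a
  module, averaged over modules, in head-radius units.

All metrics are averaged over connection densities 90% down to 10% in 10%
steps. Community detection uses Louvain with seeded restarts from shuffled
node orders, keeping the highest-Q partition, so results are deterministic
given the seed.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import igraph as _ig
import numpy as np

from .connectivity import ConnectivityMatrix, band_connectivity, median_connectivity
from .eeg_io import Montage
from .preprocess import EpochedRecording
from .spectral import BANDS, compute_psd, mean_relative_power, relative_band_power

__all__ = [
    "ThresholdedGraph",
    "Partition",
    "GraphMetrics",
    "threshold_by_density",
    "detect_communities",
    "modularity",
    "participation_coefficients",
    "clustering_coefficients",
    "modular_span",
    "density_averaged_metrics",
    "extract_features",
    "FEATURE_KEYS",
    "DEFAULT_DENSITIES",
]

DEFAULT_DENSITIES = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)

FEATURE_KEYS = [
    "alpha_rel_power",
    "alpha_median_dwpli",
    "alpha_modular_span",
    "alpha_participation_sd",
    "delta_rel_power",
    "delta_median_dwpli",
    "delta_clustering_mean",
    "delta_modularity",
]


@dataclass
class ThresholdedGraph:
    """Symmetric non-negative weight matrix after density thresholding."""

    weights: np.ndarray
    density: float
    node_labels: list[str]
    montage_ref: str | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("thresholded graph weights must be non-negative")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class Partition:
    """Node-to-module assignment with its modularity score."""

    assignment: np.ndarray  # module id per node, contiguous from 0
    q: float

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max()) + 1 if self.assignment.size else 0

    def members(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == module)


@dataclass
class GraphMetrics:
    """Per-density and density-averaged graph features for one band."""

    per_density: dict[float, dict[str, float]]
    averaged: dict[str, float]


def threshold_by_density(cm: ConnectivityMatrix, density: float) -> ThresholdedGraph:
    """Keep the ``round(density * n(n-1)/2)`` strongest pairs with their weights.

    Ties are broken by lexicographic pair order (stable), negatives clipped
    to zero before ranking.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n = cm.n_channels
    n_pairs = n * (n - 1) // 2
    k = int(round(density * n_pairs))
    if k == 0:
        raise ValueError(f"density {density} retains zero edges for {n} nodes")
    ii, jj = np.triu_indices(n, k=1)
    vals = np.clip(cm.values[ii, jj], 0.0, None)
    # stable sort on descending weight; lexicographic (i, j) order breaks ties
    order = np.argsort(-vals, kind="stable")[:k]
    weights = np.zeros((n, n))
    weights[ii[order], jj[order]] = vals[order]
    weights = weights + weights.T
    return ThresholdedGraph(
        weights=weights, density=density,
        node_labels=list(cm.channel_labels),
    )


def _edge_arrays(g: ThresholdedGraph):
    ii, jj = np.triu_indices(g.n_nodes, k=1)
    pos = g.weights[ii, jj] > 0
    return ii[pos], jj[pos], g.weights[ii, jj][pos]


def detect_communities(
    g: ThresholdedGraph, seed: int, n_runs: int = 100
) -> Partition:
    """Best-Q Louvain partition over ``n_runs`` seeded restarts.

    Each restart shuffles the node order (Louvain's greedy sweeps are
    order-dependent); candidate partitions are re-scored with
    :func:`modularity` and the highest-Q one returned. Deterministic given
    ``seed``.
    """
    ii, jj, w = _edge_arrays(g)
    if ii.size == 0:
        raise ValueError("community detection requires at least one edge")
    n = g.n_nodes
    rng = np.random.default_rng(seed)
    state = _pyrandom.getstate()
    best_q, best_memb = -np.inf, None
    try:
        for _ in range(n_runs):
            perm = rng.permutation(n)
            _pyrandom.seed(int(rng.integers(0, 2**31 - 1)))
            inv = np.empty(n, dtype=int)
            inv[perm] = np.arange(n)
            graph = _ig.Graph(
                n=n, edges=list(zip(inv[ii].tolist(), inv[jj].tolist()))
            )
            comm = graph.community_multilevel(weights=w.tolist())
            memb = np.empty(n, dtype=int)
            memb[perm] = comm.membership  # back to canonical node order
            q = _modularity_from_membership(g.weights, memb)
            if q > best_q:
                best_q, best_memb = q, memb
    finally:
        _pyrandom.setstate(state)
    return Partition(assignment=_relabel_contiguous(best_memb), q=float(best_q))


def _relabel_contiguous(memb: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty_like(memb)
    for i, m in enumerate(memb):
        out[i] = mapping.setdefault(int(m), len(mapping))
    return out


def _modularity_from_membership(W: np.ndarray, memb: np.ndarray) -> float:
    two_m = W.sum()
    if two_m == 0:
        return 0.0
    s = W.sum(axis=1)
    q = 0.0
    for m in np.unique(memb):
        idx = memb == m
        e_c = W[np.ix_(idx, idx)].sum() / two_m
        a_c = s[idx].sum() / two_m
        q += e_c - a_c**2
    return float(q)


def modularity(g: ThresholdedGraph, p: Partition) -> float:
    """Newman weighted modularity Q = (1/2m) sum_ij [w_ij - s_i s_j / 2m] d(c_i, c_j)."""
    return _modularity_from_membership(g.weights, p.assignment)


def participation_coefficients(
    g: ThresholdedGraph, p: Partition
) -> tuple[np.ndarray, float]:
    """P_i = 1 - sum_m (kappa_im / kappa_i)^2 per node, plus the population SD.

    ``kappa_im`` is node i's strength into module m, ``kappa_i`` its total
    strength; isolated nodes get P_i = 0.
    """
    if p.assignment.shape[0] != g.n_nodes:
        raise ValueError("partition does not cover all nodes")
    strength = g.weights.sum(axis=1)
    frac_sq = np.zeros(g.n_nodes)
    safe = np.where(strength == 0, 1.0, strength)
    for m in np.unique(p.assignment):
        kappa_im = g.weights[:, p.assignment == m].sum(axis=1)
        frac_sq += (kappa_im / safe) ** 2
    pc = np.where(strength == 0, 0.0, 1.0 - frac_sq)
    return pc, float(pc.std(ddof=0))


def clustering_coefficients(g: ThresholdedGraph) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering per node, plus the mean over nodes.

    C_i = (1/(k_i(k_i-1))) sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3) with weights
    normalized by the largest weight; nodes with degree < 2 get 0.
    """
    W = g.weights
    wmax = W.max()
    if wmax == 0:
        zeros = np.zeros(g.n_nodes)
        return zeros, 0.0
    cube = np.cbrt(W / wmax)
    triangles = np.diagonal(cube @ cube @ cube)
    k = (W > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1), 0.0)
    return c, float(c.mean())


def modular_span(g: ThresholdedGraph, p: Partition, m: Montage) -> float:
    """Mean, over modules, of the weight-weighted intra-module electrode distance.

    Distances are Euclidean between unit-head-radius electrode positions, so
    the result is in head-radius units. Modules without an internal edge are
    skipped; 0 if no module has one.
    """
    coords = m.positions(g.node_labels)
    diffs = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diffs**2).sum(axis=2))
    spans = []
    for mod in np.unique(p.assignment):
        idx = np.flatnonzero(p.assignment == mod)
        sub_w = np.triu(g.weights[np.ix_(idx, idx)], k=1)
        total_w = sub_w.sum()
        if total_w > 0:
            sub_d = dist[np.ix_(idx, idx)][np.triu_indices(idx.size, k=1)]
            spans.append(
                (sub_w[np.triu_indices(idx.size, k=1)] * sub_d).sum() / total_w
            )
    return float(np.mean(spans)) if spans else 0.0


METRIC_NAMES = ("modularity", "clustering_mean", "participation_sd", "modular_span")


def density_averaged_metrics(
    cm: ConnectivityMatrix,
    m: Montage,
    densities: tuple[float, ...] = DEFAULT_DENSITIES,
    seed: int = 0,
    n_runs: int = 100,
) -> GraphMetrics:
    """The four graph features per density and their arithmetic mean."""
    rng = np.random.default_rng(seed)
    per_density: dict[float, dict[str, float]] = {}
    for density in densities:
        dseed = int(rng.integers(0, 2**31 - 1))
        g = threshold_by_density(cm, density)
        part = detect_communities(g, seed=dseed, n_runs=n_runs)
        _, part_sd = participation_coefficients(g, part)
        _, clust_mean = clustering_coefficients(g)
        per_density[density] = {
            "modularity": modularity(g, part),
            "clustering_mean": clust_mean,
            "participation_sd": part_sd,
            "modular_span": modular_span(g, part, m),
        }
    averaged = {
        name: float(np.mean([per_density[d][name] for d in densities]))
        for name in METRIC_NAMES
    }
    return GraphMetrics(per_density=per_density, averaged=averaged)


def extract_features(
    ep: EpochedRecording,
    m: Montage,
    seed: int = 0,
    densities: tuple[float, ...] = DEFAULT_DENSITIES,
    n_runs: int = 100,
    bands: dict | None = None,
) -> dict[str, float]:
    """The eight scalar EEG features of one preprocessed recording.

    Channels are put in canonical (sorted-label) order first so the features
    are invariant to the input channel ordering.
    """
    order = np.argsort(np.asarray(ep.channel_labels, dtype=object))
    canonical = EpochedRecording(
        epochs=ep.epochs[:, order, :],
        sampling_rate=ep.sampling_rate,
        channel_labels=[ep.channel_labels[i] for i in order],
        montage_ref=ep.montage_ref,
        rejection_log=dict(ep.rejection_log),
    )
    bands = bands or BANDS
    spec = compute_psd(canonical)
    rng = np.random.default_rng(seed)
    band_seeds = {b: int(rng.integers(0, 2**31 - 1)) for b in ("alpha", "delta")}

    features: dict[str, float] = {}
    graph: dict[str, GraphMetrics] = {}
    for band_name in ("alpha", "delta"):
        band = bands[band_name]
        features[f"{band_name}_rel_power"] = mean_relative_power(
            relative_band_power(spec, band)
        )
        cm = band_connectivity(canonical, band)
        features[f"{band_name}_median_dwpli"] = median_connectivity(cm)
        graph[band_name] = density_averaged_metrics(
            cm, m, densities=densities, seed=band_seeds[band_name], n_runs=n_runs
        )
    features["alpha_modular_span"] = graph["alpha"].averaged["modular_span"]
    features["alpha_participation_sd"] = graph["alpha"].averaged["participation_sd"]
    features["delta_clustering_mean"] = graph["delta"].averaged["clustering_mean"]
    features["delta_modularity"] = graph["delta"].averaged["modularity"]
    return {k: features[k] for k in FEATURE_KEYS}
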