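"""Spatial readouts: cross-pair correlation, components, and replicate curves.

The cross-pair correlation function (cross-PCF) g(r) measures whether
target-type cells (CD8+ T cells) are enriched (g > 1) or depleted (g < 1)
in annular bins at distance r from center-type cells (cancer). The
estimator is

    g_k = (1 / N_C) * sum_i n_i(k) / (lambda_T * a_k)

with n_i(k) the targets in bin k around center i, a_k the annulus area,
and lambda_T = N_T / domain_area the global target density. No boundary
edge correction is applied: near the domain edge part of an annulus lies
outside the window, which biases g downward at large r. Quantitative reads
should therefore stay on bins short relative to the distance of the point
mass from the boundary ("interior bins").

Cancer clustering is summarized by connected components of the
cancer-cell-induced subgraph of the contact neighbor graph, reported as the
cumulative fraction of cancer cells in components of size <= s.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .model import Snapshot, Trajectory

DEFAULT_BIN_EDGES = np.arange(0.0, 201.0, 10.0)


@dataclass
class CrossPCF:
    """Binned enrichment g(r) of targets around centers."""

    bin_edges: np.ndarray  # (K+1,)
    g: np.ndarray  # (K,)
    center_type: str
    target_type: str
    n_centers: int
    n_targets: int
    domain_area: float
    empty: np.ndarray = field(default=None)  # (K,) True where the bin saw no pair

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges[0] < 0 or np.any(np.diff(edges) <= 0):
            raise ValidationError("bin_edges must be strictly increasing and >= 0")
        if self.empty is None:
            self.empty = np.zeros(len(self.g), dtype=bool)


def cross_pcf_points(
    centers_xy: np.ndarray,
    targets_xy: np.ndarray,
    bin_edges: np.ndarray,
    domain_area: float,
    center_type: str = "center",
    target_type: str = "target",
) -> CrossPCF:
    """Cross-PCF between two explicit point sets (both in µm)."""
    centers_xy = np.asarray(centers_xy, dtype=float).reshape(-1, 2)
    targets_xy = np.asarray(targets_xy, dtype=float).reshape(-1, 2)
    edges = np.asarray(bin_edges, dtype=float)
    if len(centers_xy) == 0:
        raise ValidationError("cross-PCF needs at least one center cell")
    if domain_area <= 0:
        raise ValidationError("domain_area must be > 0")
    k_bins = len(edges) - 1
    if len(targets_xy) == 0:
        return CrossPCF(
            edges,
            np.zeros(k_bins),
            center_type,
            target_type,
            len(centers_xy),
            0,
            domain_area,
            empty=np.ones(k_bins, dtype=bool),
        )
    ct = cKDTree(centers_xy)
    tt = cKDTree(targets_xy)
    dm = ct.sparse_distance_matrix(
        tt, max_distance=float(edges[-1]), output_type="ndarray"
    )
    d = dm["v"]
    d = d[(d >= edges[0]) & (d < edges[-1])]  # right-open bins [lo, hi)
    counts, _ = np.histogram(d, bins=edges)
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    lam = len(targets_xy) / domain_area
    g = counts / (len(centers_xy) * lam * areas)
    return CrossPCF(
        edges,
        g,
        center_type,
        target_type,
        len(centers_xy),
        len(targets_xy),
        domain_area,
        empty=counts == 0,
    )


def cross_pcf(
    snapshot: Snapshot,
    center_type: str,
    target_type: str,
    bin_edges: np.ndarray = DEFAULT_BIN_EDGES,
    domain_area: Optional[float] = None,
) -> CrossPCF:
    """Cross-PCF between two cell types of one snapshot.

    ``domain_area`` defaults to the area of the snapshot's simulation domain.
    """
    if domain_area is None:
        domain_area = snapshot.domain.area
    centers = snapshot.xy[snapshot.types == center_type]
    targets = snapshot.xy[snapshot.types == target_type]
    return cross_pcf_points(
        centers, targets, bin_edges, domain_area, center_type, target_type
    )


@dataclass
class CrossPCFSeries:
    """Cross-PCF of every saved snapshot; one heatmap row per time point."""

    times: np.ndarray  # (T,)
    bin_edges: np.ndarray  # (K+1,)
    G: np.ndarray  # (T, K); NaN rows where the snapshot had no centers
    center_type: str
    target_type: str

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.G).all(axis=1)


def cross_pcf_timeseries(
    trajectory: Trajectory,
    center_type: str,
    target_type: str,
    bin_edges: np.ndarray = DEFAULT_BIN_EDGES,
) -> CrossPCFSeries:
    """Row-per-snapshot cross-PCF matrix; center-free snapshots are masked."""
    edges = np.asarray(bin_edges, dtype=float)
    times = []
    rows = []
    for snap in trajectory.snapshots:
        times.append(snap.time)
        if (snap.types == center_type).sum() == 0:
            rows.append(np.full(len(edges) - 1, np.nan))
            continue
        rows.append(cross_pcf(snap, center_type, target_type, edges).g)
    return CrossPCFSeries(
        np.asarray(times), edges, np.vstack(rows), center_type, target_type
    )


def neighbor_graph(snapshot: Snapshot, contact_scale: float = 1.25) -> nx.Graph:
    """Contact graph over all agents of a snapshot.

    Nodes are agent ids; an edge joins i and j exactly when their center
    distance is <= contact_scale * (r_i + r_j).
    """
    if contact_scale < 1:
        raise ValidationError("contact_scale must be >= 1")
    graph = nx.Graph()
    graph.add_nodes_from(snapshot.ids.tolist())
    n = len(snapshot.ids)
    if n < 2:
        return graph
    tree = cKDTree(snapshot.xy)
    pairs = tree.query_pairs(
        contact_scale * 2.0 * snapshot.radii.max(), output_type="ndarray"
    )
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        dv = snapshot.xy[j] - snapshot.xy[i]
        d = np.hypot(dv[:, 0], dv[:, 1])
        ok = d <= contact_scale * (snapshot.radii[i] + snapshot.radii[j])
        graph.add_edges_from(
            zip(snapshot.ids[i[ok]].tolist(), snapshot.ids[j[ok]].tolist())
        )
    return graph


def cancer_components(
    graph: nx.Graph, snapshot: Snapshot, cancer_type: str = "cancer"
) -> list[int]:
    """Cancer-cell counts of the components of the cancer-induced subgraph.

    Returned sizes are sorted descending; an all-cell-graph alternative is
    deliberately not used — only cancer-cancer contacts join a component.
    """
    cancer_ids = snapshot.ids[snapshot.types == cancer_type]
    sub = graph.subgraph(cancer_ids.tolist())
    return sorted((len(c) for c in nx.connected_components(sub)), reverse=True)


@dataclass
class ComponentCDF:
    """Cumulative fraction of cancer cells by component size."""

    sizes: np.ndarray  # sorted unique component sizes
    F: np.ndarray  # cumulative cell fraction at each size
    empty: bool = False

    def at(self, grid: np.ndarray) -> np.ndarray:
        """Right-continuous step evaluation of F on an arbitrary size grid."""
        if self.empty:
            return np.zeros(len(grid))
        pos = np.searchsorted(self.sizes, grid, side="right") - 1
        out = np.where(pos >= 0, self.F[np.clip(pos, 0, None)], 0.0)
        return out


def component_cdf(sizes: Sequence[int]) -> ComponentCDF:
    """CDF of cancer-cell mass over component sizes, weighted by cell count.

    F(s) = (cells in components of size <= s) / (all cancer cells).
    """
    sizes = np.asarray(list(sizes), dtype=int)
    if len(sizes) == 0:
        return ComponentCDF(np.array([], dtype=int), np.array([]), empty=True)
    if (sizes < 1).any():
        raise ValidationError("component sizes must be >= 1")
    uniq, counts = np.unique(sizes, return_counts=True)
    mass = uniq * counts
    F = np.cumsum(mass) / mass.sum()
    return ComponentCDF(uniq, F)


def fraction_in_components_larger_than(sizes: Sequence[int], threshold: int) -> float:
    """Fraction of cancer cells sitting in components of size > threshold."""
    sizes = np.asarray(list(sizes), dtype=int)
    if sizes.sum() == 0:
        return 0.0
    return float(sizes[sizes > threshold].sum() / sizes.sum())


def aggregate_replicates(
    curves: Sequence[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and sample SD (ddof=1) of aligned replicate series.

    A single replicate reports SD = 0 everywhere.
    """
    if len(curves) == 0:
        raise ValidationError("need at least one replicate curve")
    arrs = [np.asarray(c, dtype=float) for c in curves]
    length = len(arrs[0])
    for k, a in enumerate(arrs):
        if len(a) != length:
            raise ValidationError(
                f"replicate {k} has length {len(a)}, expected {length}"
            )
    stacked = np.vstack(arrs)
    mean = stacked.mean(axis=0)
    sd = (
        stacked.std(axis=0, ddof=1) if len(arrs) > 1 else np.zeros(length)
    )
    return mean, sd


@dataclass
class ComponentCDFEnsemble:
    """Replicate component CDFs on the union size grid, with mean and SD."""

    sizes: np.ndarray
    F_per_replicate: np.ndarray  # (R, S)
    F_mean: np.ndarray
    F_sd: np.ndarray


def aggregate_component_cdfs(
    cdfs: Sequence[ComponentCDF],
) -> ComponentCDFEnsemble:
    """Align replicate CDFs on the union of sizes (step interpolation) and average."""
    if len(cdfs) == 0:
        raise ValidationError("need at least one replicate CDF")
    union = np.unique(np.concatenate([c.sizes for c in cdfs if not c.empty]))
    if len(union) == 0:
        union = np.array([0], dtype=int)
    per_rep = np.vstack([c.at(union) for c in cdfs])
    mean, sd = aggregate_replicates(list(per_rep))
    return ComponentCDFEnsemble(union, per_rep, mean, sd)
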