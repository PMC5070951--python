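"""Graph-level analyses of coupling networks.

Cross-frequency edges are directed from a low-frequency to a
high-frequency parcel.  Networks significant at several 1:m ratios are
pooled into summary graphs; because source-space signal mixing smears a
single true interaction into a cloud of nearby edges, pooled edges are
bundled into *hyperedges* using an edge-edge affinity defined by
pairwise parcel cross-talk, and hyperedges attributable to a single
ratio are discarded (the pooled representation should reflect sharing
across ratios).  System-level structure is summarized as 7x7 connection
densities between functional systems tested against edge-count-
preserving randomized graphs, and hub structure as correlations of
vertex degrees between networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .parcels import ParcelMeta

logger = logging.getLogger(__name__)

__all__ = [
    "Hyperedge",
    "SummaryGraph",
    "SystemMatrix",
    "pool_ratios",
    "single_ratio_attribution",
    "edge_adjacency",
    "cluster_hyperedges",
    "select_central_edges",
    "system_density",
    "degree_correlation",
    "cross_frequency_degree_similarity",
]


@dataclass
class Hyperedge:
    """A bundle of edges likely reflecting one smeared interaction."""

    member_edges: list[tuple[int, int, int]]  # (parcel_low, parcel_high, ratio)
    single_ratio_p: float = float("nan")

    @property
    def size(self) -> int:
        return len(self.member_edges)


@dataclass
class SummaryGraph:
    """Ratio-pooled edge list with low/high-frequency vertex degrees.

    ``edges`` has columns parcel_low, parcel_high, weight (number of
    ratios sharing the edge) and ratios (tuple).  LF degree of a parcel
    counts edges where it is the low-frequency endpoint; HF analogous.
    """

    edges: pd.DataFrame
    n_parcels: int
    meta: dict = field(default_factory=dict)

    def lf_degree(self) -> np.ndarray:
        deg = np.zeros(self.n_parcels, dtype=int)
        for p, cnt in self.edges["parcel_low"].value_counts().items():
            deg[int(p)] = cnt
        return deg

    def hf_degree(self) -> np.ndarray:
        deg = np.zeros(self.n_parcels, dtype=int)
        for p, cnt in self.edges["parcel_high"].value_counts().items():
            deg[int(p)] = cnt
        return deg


@dataclass
class SystemMatrix:
    """Directed system-by-system connection densities with random nulls."""

    K: np.ndarray
    null_threshold: np.ndarray
    n_randomizations: int
    edge_counts: np.ndarray

    @property
    def significant(self) -> np.ndarray:
        return self.K > self.null_threshold


def pool_ratios(
    edge_sets: dict[int, list[tuple[int, int]]],
    n_parcels: int,
) -> SummaryGraph:
    """Union of per-ratio significant edge sets with ratio provenance.

    ``edge_sets`` maps each ratio m to its significant (low, high) edge
    list on a common parcellation.  The pooled weight of an edge is the
    number of ratios sharing it.
    """
    rows: dict[tuple[int, int], list[int]] = {}
    for m in sorted(edge_sets):
        for (p, q) in edge_sets[m]:
            rows.setdefault((int(p), int(q)), []).append(int(m))
    if rows:
        data = [
            {"parcel_low": p, "parcel_high": q, "weight": len(ms), "ratios": tuple(ms)}
            for (p, q), ms in sorted(rows.items())
        ]
        edges = pd.DataFrame(data)
    else:
        edges = pd.DataFrame(columns=["parcel_low", "parcel_high", "weight", "ratios"])
    return SummaryGraph(edges=edges, n_parcels=n_parcels)


def single_ratio_attribution(
    member_ratios: list[int],
    pooled_ratios: list[int],
    n_permutations: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Permutation p-value for single-ratio dominance within a hyperedge.

    The statistic is the count of the most frequent ratio among the
    hyperedge's members; the null redistributes the pooled graph's ratio
    labels at random across all pooled edges and re-draws the member
    labels.  Small p means the bundle is attributable to one ratio.
    Single-member bundles return p = 1 (no dominance evidence).
    """
    k = len(member_ratios)
    if k <= 1:
        return 1.0
    observed = max(np.bincount(np.asarray(member_ratios)).max(), 1)
    labels = np.asarray(pooled_ratios)
    if labels.size < k:
        raise ValueError("pooled ratio pool smaller than the hyperedge")
    rng = np.random.default_rng(rng)
    count = 0
    for _ in range(n_permutations):
        draw = labels[rng.choice(labels.size, size=k, replace=False)]
        if np.bincount(draw).max() >= observed:
            count += 1
    return (count + 1) / (n_permutations + 1)


def edge_adjacency(
    edges: pd.DataFrame,
    meta: ParcelMeta,
) -> np.ndarray:
    """Edge-edge affinity: product of endpoint pairwise cross-talk.

    affinity(e1, e2) = crosstalk(low1, low2) * crosstalk(high1, high2),
    orientation-respecting, with unit self-affinity (the cross-talk
    matrix has a unit diagonal).  High affinity marks edge pairs likely
    to reflect the same underlying interaction smeared by mixing.
    """
    ct = meta.crosstalk_matrix
    if ct is None:
        raise ValueError("parcel metadata lacks a cross-talk matrix")
    lo = edges["parcel_low"].to_numpy(dtype=int)
    hi = edges["parcel_high"].to_numpy(dtype=int)
    if lo.size and (lo.max() >= ct.shape[0] or hi.max() >= ct.shape[0]):
        raise ValueError("edge endpoint outside cross-talk matrix")
    aff = ct[np.ix_(lo, lo)] * ct[np.ix_(hi, hi)]
    np.fill_diagonal(aff, 1.0)
    return aff


def cluster_hyperedges(
    edges: pd.DataFrame,
    affinity: np.ndarray,
    min_size: int = 4,
    centrality_floor: float = 0.5,
    distance_cut: float = 0.5,
    lf_degree: np.ndarray | None = None,
    hf_degree: np.ndarray | None = None,
) -> list[Hyperedge]:
    """Bundle edges into hyperedges by average-linkage clustering.

    Edges are clustered on distance 1 - affinity with an average-linkage
    dendrogram cut at ``distance_cut``; bundles smaller than ``min_size``
    are dropped, and within each bundle the edges whose end-vertex
    degree centrality falls below the ``centrality_floor`` quantile of
    the bundle are discarded.  Output order is deterministic and
    invariant to the input edge order (clusters sorted by smallest
    member index after sorting edges canonically).
    """
    n = len(edges)
    if n == 0:
        return []
    aff = np.asarray(affinity, dtype=float)
    if aff.shape != (n, n):
        raise ValueError("affinity must be n_edges x n_edges")
    if not np.allclose(aff, aff.T, atol=1e-12):
        raise ValueError("affinity must be symmetric")
    dist = 1.0 - np.clip(aff, 0.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    if n == 1:
        labels = np.array([1])
    else:
        labels = fcluster(average(squareform(dist, checks=False)), t=distance_cut,
                          criterion="distance")
    n_parcels = int(max(edges["parcel_low"].max(), edges["parcel_high"].max())) + 1
    if lf_degree is None or hf_degree is None:
        g = SummaryGraph(edges=edges, n_parcels=n_parcels)
        lf_degree, hf_degree = g.lf_degree(), g.hf_degree()
    centrality = (
        np.asarray(lf_degree)[edges["parcel_low"].to_numpy(dtype=int)]
        + np.asarray(hf_degree)[edges["parcel_high"].to_numpy(dtype=int)]
    ).astype(float)

    ratios = (
        edges["ratio"].to_numpy(dtype=int)
        if "ratio" in edges.columns
        else np.ones(n, dtype=int)
    )
    out: list[Hyperedge] = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < min_size:
            continue
        floor = np.quantile(centrality[idx], centrality_floor)
        keep = idx[centrality[idx] >= floor]
        members = sorted(
            (int(edges["parcel_low"].iat[i]), int(edges["parcel_high"].iat[i]), int(ratios[i]))
            for i in keep
        )
        out.append(Hyperedge(member_edges=members))
    out.sort(key=lambda h: h.member_edges[0])
    return out


def select_central_edges(
    graph: SummaryGraph,
    n_edges: int,
    end: str = "LF",
) -> SummaryGraph:
    """Keep the n most central edges by one end's vertex degree.

    Edges are ranked by the degree of their low-frequency (``end='LF'``)
    or high-frequency (``end='HF'``) endpoint vertex; ties are broken by
    pooled weight, then lexicographic parcel indices, so the selection
    is deterministic.
    """
    if end not in {"LF", "HF"}:
        raise ValueError("end must be 'LF' or 'HF'")
    edges = graph.edges
    if n_edges >= len(edges):
        if n_edges > len(edges):
            logger.info("requested %d edges but graph has %d; returning all",
                        n_edges, len(edges))
        return SummaryGraph(edges=edges.copy(), n_parcels=graph.n_parcels,
                            meta={**graph.meta, "selected": end})
    deg = graph.lf_degree() if end == "LF" else graph.hf_degree()
    key_parcel = "parcel_low" if end == "LF" else "parcel_high"
    df = edges.assign(_deg=deg[edges[key_parcel].to_numpy(dtype=int)])
    df = df.sort_values(
        by=["_deg", "weight", "parcel_low", "parcel_high"],
        ascending=[False, False, True, True],
        kind="stable",
    ).head(n_edges)
    return SummaryGraph(
        edges=df.drop(columns="_deg").reset_index(drop=True),
        n_parcels=graph.n_parcels,
        meta={**graph.meta, "selected": end},
    )


def _system_K(
    lo_sys: np.ndarray,
    hi_sys: np.ndarray,
    parcels_per_system: np.ndarray,
    n_systems: int,
) -> np.ndarray:
    counts = np.zeros((n_systems, n_systems))
    np.add.at(counts, (lo_sys, hi_sys), 1)
    possible = np.outer(parcels_per_system, parcels_per_system).astype(float)
    np.fill_diagonal(possible, parcels_per_system * (parcels_per_system - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(possible > 0, counts / np.where(possible > 0, possible, 1.0), 0.0)


def system_density(
    graph: SummaryGraph,
    meta: ParcelMeta,
    n_rand: int = 5000,
    percentile: float = 95.0,
    rng: np.random.Generator | int | None = None,
) -> SystemMatrix:
    """Connection density per directed (LF system -> HF system) pair.

    The observed coarse graph is compared against ``n_rand`` randomized
    graphs with the same number of edges placed uniformly among all
    possible directed parcel pairs; a cell is significant when its
    density exceeds the stated percentile of the randomized densities.
    """
    systems = meta.coarse_to_system
    n_sys = meta.n_systems
    parcels_per_system = np.bincount(systems, minlength=n_sys)
    if np.any(parcels_per_system == 0):
        raise ValueError("every system must contain at least one parcel")
    n_parcels = len(systems)
    lo = graph.edges["parcel_low"].to_numpy(dtype=int)
    hi = graph.edges["parcel_high"].to_numpy(dtype=int)
    K_obs = _system_K(systems[lo], systems[hi], parcels_per_system, n_sys)
    counts = np.zeros((n_sys, n_sys), dtype=int)
    np.add.at(counts, (systems[lo], systems[hi]), 1)

    n_edges = len(lo)
    rng = np.random.default_rng(rng)
    # all possible directed ordered pairs p != q
    pairs = np.array([(p, q) for p in range(n_parcels) for q in range(n_parcels) if p != q])
    surr = np.empty((n_rand, n_sys, n_sys))
    for i in range(n_rand):
        pick = rng.choice(len(pairs), size=n_edges, replace=False)
        rp = pairs[pick]
        surr[i] = _system_K(systems[rp[:, 0]], systems[rp[:, 1]], parcels_per_system, n_sys)
    thr = np.percentile(surr, percentile, axis=0)
    return SystemMatrix(K=K_obs, null_threshold=thr, n_randomizations=n_rand,
                        edge_counts=counts)


def degree_correlation(
    cfs_graph: SummaryGraph,
    ps_degree_low: np.ndarray,
    ps_degree_high: np.ndarray,
) -> dict:
    """Correlate CFS hub degrees with within-frequency network degrees.

    Pearson correlation across parcels of the CFS graph's LF degrees
    with the 1:1 network degrees at f_low, and of its HF degrees with
    the 1:1 degrees at f_high.  Degenerate (constant) degree vectors are
    reported as NaN.  Benjamini-Hochberg correction across a batch of
    such tests is applied by :func:`bh_adjust` at the call site.
    """
    from scipy.stats import pearsonr

    out = {}
    for name, a, b in (
        ("LF", cfs_graph.lf_degree(), np.asarray(ps_degree_low)),
        ("HF", cfs_graph.hf_degree(), np.asarray(ps_degree_high)),
    ):
        if a.shape != b.shape:
            raise ValueError("degree vectors must share the parcellation")
        if np.std(a) == 0 or np.std(b) == 0:
            out[name] = {"r": float("nan"), "p": float("nan")}
        else:
            r, p = pearsonr(a, b)
            out[name] = {"r": float(r), "p": float(p)}
    return out


def bh_adjust(p_values: list[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg adjusted p-values and rejection mask."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    ok = np.isfinite(p)
    adj = np.full(p.shape, np.nan)
    rej = np.zeros(p.shape, dtype=bool)
    if ok.any():
        rej[ok], adj[ok], *_ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
    return adj, rej


def cross_frequency_degree_similarity(degrees: np.ndarray) -> np.ndarray:
    """Frequency x frequency Pearson similarity of vertex-degree profiles.

    ``degrees`` is (n_frequencies, n_parcels) of 1:1 network vertex
    degrees; the result is symmetric with a unit diagonal.  Rows with
    constant degree yield NaN off-diagonals.
    """
    d = np.asarray(degrees, dtype=float)
    if d.ndim != 2:
        raise ValueError("degrees must be (n_frequencies, n_parcels)")
    sd = d.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(d)
    r = np.asarray(r)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    return r
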