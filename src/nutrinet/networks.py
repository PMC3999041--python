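"""Co-occurrence networks of features and sliding-window topology trends.

Edges link feature pairs whose ReBoot-validated Spearman correlation is
significant at the chosen alpha; the node set is the set of edge
endpoints. Graph summary statistics follow the Cytoscape NetworkAnalyzer
definitions (centralization, heterogeneity, characteristic path length
averaged over connected ordered pairs). The sliding-window analysis
orders samples by cumulative nutritional index, builds one network per
overlapping window and correlates each graph property with the window's
mean index, tracing how community interdependence shifts along the
nutrition gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import norm

from .association import (
    RebootParams,
    _null_stats_vs_target,
    _pearson_rows,
    _rank_rows,
)
from .profiles import FeatureTable

__all__ = [
    "CooccurrenceNetwork",
    "GraphProperties",
    "WindowRecord",
    "WindowSeries",
    "build_network",
    "graph_properties",
    "sliding_windows",
    "compute_window_series",
    "window_trend",
]

PROPERTY_NAMES = (
    "avg_num_neighbors",
    "characteristic_path_length",
    "clustering_coefficient",
    "centralization",
    "density",
    "heterogeneity",
    "n_nodes",
    "n_edges",
)


@dataclass
class GraphProperties:
    """NetworkAnalyzer-style summary of an undirected graph."""

    avg_num_neighbors: float
    characteristic_path_length: float
    clustering_coefficient: float
    centralization: float
    density: float
    heterogeneity: float
    n_nodes: int
    n_edges: int
    n_shortest_paths: int = 0  # connected ordered pairs

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in PROPERTY_NAMES} | {
            "n_shortest_paths": self.n_shortest_paths
        }


@dataclass
class CooccurrenceNetwork:
    """Undirected signed co-occurrence graph plus the full pair statistics.

    ``pair_stats`` records (rho, z, p) for *every* unordered feature pair
    tested, so edge sets at any stricter alpha can be read off without
    recomputation.
    """

    graph: nx.Graph
    alpha: float
    context: str = "whole-cohort"
    pair_stats: pd.DataFrame = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"feature_a": a, "feature_b": b, **attrs}
            for a, b, attrs in sorted(self.graph.edges(data=True))
        ]
        cols = ["feature_a", "feature_b", "rho", "reboot_z", "p_value", "sign"]
        return pd.DataFrame(rows, columns=cols)

    def write_edge_tsv(self, path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def graph_properties(network) -> GraphProperties:
    """Summary statistics of a co-occurrence network (or bare nx.Graph).

    - avg_num_neighbors: mean degree (2E/N)
    - characteristic_path_length: mean shortest-path length over connected
      ordered pairs; disconnected pairs are excluded, not infinite
    - clustering_coefficient: mean local clustering over nodes of degree >= 2
      (NaN when no such node exists)
    - density: 2E / (N(N-1))
    - centralization: (N/(N-2)) * (max_degree/(N-1) - density), undefined
      (NaN) for N < 3
    - heterogeneity: population sd of the degree distribution / mean degree
    """
    G = network.graph if isinstance(network, CooccurrenceNetwork) else network
    N = G.number_of_nodes()
    E = G.number_of_edges()
    if N == 0:
        return GraphProperties(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 0, 0, 0)

    degrees = np.array([d for _, d in G.degree()], dtype=float)
    avg_nn = 2.0 * E / N
    density = 2.0 * E / (N * (N - 1)) if N > 1 else np.nan

    total_len = 0
    n_pairs = 0
    for node, lengths in nx.all_pairs_shortest_path_length(G):
        for other, dist in lengths.items():
            if other != node:
                total_len += dist
                n_pairs += 1
    cpl = total_len / n_pairs if n_pairs else np.nan

    local = nx.clustering(G)
    eligible = [local[v] for v in G if G.degree(v) >= 2]
    clustering = float(np.mean(eligible)) if eligible else np.nan

    if N >= 3:
        centralization = (N / (N - 2.0)) * (degrees.max() / (N - 1.0) - density)
    else:
        centralization = np.nan

    mean_deg = degrees.mean()
    heterogeneity = float(degrees.std(ddof=0) / mean_deg) if mean_deg > 0 else np.nan

    return GraphProperties(
        avg_num_neighbors=float(avg_nn),
        characteristic_path_length=float(cpl) if n_pairs else np.nan,
        clustering_coefficient=clustering,
        centralization=float(centralization) if N >= 3 else np.nan,
        density=float(density),
        heterogeneity=heterogeneity,
        n_nodes=N,
        n_edges=E,
        n_shortest_paths=n_pairs,
    )


def _bootstrap_mean_matrix(X: np.ndarray, boot_idx: np.ndarray) -> np.ndarray:
    """Mean bootstrap Spearman correlation matrix over resampled sample sets.

    Ranks are computed once on the observed samples and the rank pairs are
    resampled (no re-ranking), matching the bootstrap convention used for
    single associations.
    """
    F = X.shape[0]
    base_ranks = _rank_rows(X)
    acc = np.zeros((F, F))
    cnt = np.zeros((F, F))
    for idx in boot_idx:
        ranks = base_ranks[:, idx]
        centered = ranks - ranks.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        ok = norms > 0
        unit = np.zeros_like(centered)
        unit[ok] = centered[ok] / norms[ok, None]
        C = unit @ unit.T
        valid = np.outer(ok, ok)
        acc[valid] += C[valid]
        cnt += valid
    with np.errstate(invalid="ignore", divide="ignore"):
        return acc / cnt


def build_network(
    composition: FeatureTable,
    subset=None,
    alpha: float = 0.05,
    params: RebootParams | None = None,
    context: str = "whole-cohort",
) -> CooccurrenceNetwork:
    """Build a co-occurrence network over a sample subset.

    For every unordered feature pair the Spearman correlation is computed
    on the subset and its significance judged by ReBoot (the pair's
    alphabetically first feature is the permuted profile, so edges are
    canonical and reproducible). Pairs with p < alpha become edges; the
    node set is the edge endpoints. Constant features are dropped with a
    warning. Deterministic for a fixed ``params.seed`` and independent of
    alpha, so lowering alpha can only remove edges.
    """
    params = params or RebootParams()
    table = composition if subset is None else composition.subset_samples(subset)
    n = table.n_samples
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")

    order = sorted(table.feature_ids)
    X_full = table.data.loc[order].to_numpy(float)
    variable = np.ptp(X_full, axis=1) > 0
    if not variable.all():
        dropped = [f for f, v in zip(order, variable) if not v]
        warnings.warn(f"dropping constant features from network: {dropped}", stacklevel=2)
    features = [f for f, v in zip(order, variable) if v]
    X = X_full[variable]
    F = len(features)

    empty_cols = ["feature_a", "feature_b", "rho", "reboot_z", "p_value", "sign"]
    if F < 2:
        warnings.warn("fewer than 2 variable features; empty network", stacklevel=2)
        return CooccurrenceNetwork(nx.Graph(), alpha, context, pd.DataFrame(columns=empty_cols))

    root = np.random.SeedSequence([params.seed, 0x6E6574])
    boot_ss, *null_ss = root.spawn(F + 1)

    # observed Spearman matrix
    ranks = _rank_rows(X)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    unit = centered / np.sqrt((centered**2).sum(axis=1))[:, None]
    rho_obs = np.clip(unit @ unit.T, -1.0, 1.0)

    boot_rng = np.random.default_rng(boot_ss)
    boot_idx = boot_rng.integers(0, n, size=(params.n_bootstraps, n))
    mean_boot = _bootstrap_mean_matrix(X, boot_idx)

    rows = []
    G = nx.Graph()
    for i in range(F):
        if i == F - 1:
            break
        rng = np.random.default_rng(null_ss[i])
        perms = np.argsort(rng.random((params.n_permutations, n)), axis=1)
        # permute feature i, renormalize, correlate with every later feature
        a = X[i]
        col_sums = X.sum(axis=0)
        a_perm = a[perms]
        new_sums = (col_sums - a)[None, :] + a_perm
        with np.errstate(invalid="ignore", divide="ignore"):
            factor = np.where(new_sums > 0, col_sums / new_sums, 0.0)
        a_ranks = _rank_rows(a_perm * factor)  # (P, n)
        others = X[i + 1:][None, :, :] * factor[:, None, :]  # (P, F-i-1, n)
        other_ranks = _rank_rows(others)
        rho_null = _pearson_rows(a_ranks[:, None, :], other_ranks)  # (P, F-i-1)
        mean_null = np.nanmean(rho_null, axis=0)
        sd_null = np.nanstd(rho_null, axis=0, ddof=1)
        for off, j in enumerate(range(i + 1, F)):
            if not np.isfinite(sd_null[off]) or sd_null[off] == 0:
                warnings.warn(
                    f"degenerate ReBoot null for pair ({features[i]}, {features[j]})",
                    stacklevel=2,
                )
                continue
            z = (mean_boot[i, j] - mean_null[off]) / sd_null[off]
            p = float(2.0 * norm.sf(abs(z)))
            rho = float(rho_obs[i, j])
            sign = "+" if rho >= 0 else "-"
            rows.append(
                {
                    "feature_a": features[i],
                    "feature_b": features[j],
                    "rho": rho,
                    "reboot_z": float(z),
                    "p_value": p,
                    "sign": sign,
                }
            )
            if p < alpha:
                G.add_edge(
                    features[i], features[j],
                    rho=rho, reboot_z=float(z), p_value=p, sign=sign,
                )
    pair_stats = pd.DataFrame(rows, columns=empty_cols)
    return CooccurrenceNetwork(G, alpha, context, pair_stats)


def sliding_windows(
    metadata: pd.DataFrame, window_size: int = 7, step: int = 1
) -> list[list[str]]:
    """Overlapping sample windows along the nutrition gradient.

    Samples are sorted by ascending cumulative index (ties by sample id);
    windows are consecutive runs of ``window_size`` samples advancing by
    ``step``, giving floor((n - window_size)/step) + 1 windows.
    """
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be positive")
    n = len(metadata)
    if window_size > n:
        raise ValueError(f"window_size {window_size} exceeds sample count {n}")
    ordered = metadata.sort_values(["cumulative_index", "sample_id"])
    ids = list(ordered["sample_id"])
    n_windows = (n - window_size) // step + 1
    return [ids[k * step : k * step + window_size] for k in range(n_windows)]


@dataclass
class WindowRecord:
    sample_ids: list[str]
    mean_index: float
    properties: GraphProperties


@dataclass
class WindowSeries:
    """Graph properties of co-occurrence networks along ordered windows."""

    records: list[WindowRecord]
    window_size: int
    step: int
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, rec in enumerate(self.records):
            rows.append(
                {
                    "window": k + 1,
                    "mean_index": rec.mean_index,
                    "samples": ",".join(rec.sample_ids),
                    **rec.properties.to_dict(),
                }
            )
        return pd.DataFrame(rows)


def compute_window_series(
    composition: FeatureTable,
    metadata: pd.DataFrame,
    window_size: int = 7,
    step: int = 1,
    alpha: float = 0.05,
    params: RebootParams | None = None,
) -> WindowSeries:
    """One co-occurrence network per sliding window, with its graph properties."""
    params = params or RebootParams()
    index = metadata.set_index("sample_id")["cumulative_index"]
    records = []
    for k, window in enumerate(sliding_windows(metadata, window_size, step)):
        win_params = RebootParams(
            params.n_permutations, params.n_bootstraps,
            seed=params.seed, z_threshold=params.z_threshold,
        )
        net = build_network(
            composition, subset=window, alpha=alpha,
            params=win_params, context=f"window-{k + 1}",
        )
        records.append(
            WindowRecord(
                sample_ids=window,
                mean_index=float(index.loc[window].mean()),
                properties=graph_properties(net),
            )
        )
    return WindowSeries(records, window_size, step, alpha)


def window_trend(series: WindowSeries) -> dict[str, tuple[float, float]]:
    """Spearman trend of each graph property against the windows' mean index.

    Windows where a property is undefined are dropped pairwise; a property
    needs at least 4 defined windows, otherwise (NaN, NaN) is reported.
    Constant properties are likewise reported as (NaN, NaN).
    """
    frame = series.to_frame()
    x = frame["mean_index"].to_numpy(float)
    trends: dict[str, tuple[float, float]] = {}
    for prop in PROPERTY_NAMES:
        y = frame[prop].to_numpy(float)
        ok = np.isfinite(y) & np.isfinite(x)
        if ok.sum() < 4:
            warnings.warn(f"fewer than 4 defined windows for {prop}; trend skipped",
                          stacklevel=2)
            trends[prop] = (float("nan"), float("nan"))
            continue
        if np.ptp(y[ok]) == 0 or np.ptp(x[ok]) == 0:
            trends[prop] = (float("nan"), float("nan"))
            continue
        rho, p = stats.spearmanr(x[ok], y[ok])
        trends[prop] = (float(rho), float(p))
    return trends
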