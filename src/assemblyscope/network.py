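"""Spearman co-occurrence networks and their topology along the gradient.

Edges require |r| > 0.5 and p < 0.05 (both strict); nodes are the taxa
with at least one passing edge, matching how per-panel node counts are
usually reported from Gephi.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_core import CommunityTable

R_THRESHOLD = 0.5
P_THRESHOLD = 0.05


def spearman_matrix(
    table: CommunityTable, use_relative: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tie-corrected Spearman r and two-sided p for every taxon pair.

    Correlations are computed across samples, on relative abundances by
    default (``use_relative=False`` uses raw counts). Taxa constant
    across samples yield undefined correlations (NaN) and a warning.
    """
    if table.n_samples < 5:
        raise ValueError("need at least 5 samples for correlations")
    data = table.relative_abundance() if use_relative else table.counts.astype(float)
    constant = np.ptp(data, axis=0) == 0
    if constant.any():
        names = [t for t, c in zip(table.taxon_ids, constant) if c]
        warnings.warn(
            f"{len(names)} taxa constant across samples; correlations undefined",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = stats.spearmanr(data, axis=0)
    if np.ndim(r) == 0:  # spearmanr collapses the 2-taxon case to scalars
        r = np.array([[1.0, float(r)], [float(r), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    p[constant, :] = np.nan
    p[:, constant] = np.nan
    np.fill_diagonal(r, 1.0)
    ids = table.taxon_ids
    return (
        pd.DataFrame(r, index=ids, columns=ids),
        pd.DataFrame(p, index=ids, columns=ids),
    )


def build_network(
    table: CommunityTable,
    r_threshold: float = R_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    use_relative: bool = True,
    group_label: str | None = None,
) -> nx.Graph:
    """Undirected network whose edges satisfy |r| > r_threshold AND
    p < p_threshold (both strict). Isolated taxa are excluded.
    """
    r, p = spearman_matrix(table, use_relative=use_relative)
    rv, pv = r.to_numpy(), p.to_numpy()
    n = len(r.index)
    net = nx.Graph(group=group_label, r_threshold=r_threshold, p_threshold=p_threshold)
    iu, ju = np.triu_indices(n, 1)
    ok = (
        np.isfinite(rv[iu, ju])
        & (np.abs(rv[iu, ju]) > r_threshold)
        & (pv[iu, ju] < p_threshold)
    )
    for a, b in zip(iu[ok], ju[ok]):
        net.add_edge(
            r.index[a],
            r.index[b],
            r=float(rv[a, b]),
            p=float(pv[a, b]),
            sign=1 if rv[a, b] > 0 else -1,
        )
    return net


@dataclasses.dataclass
class TopologyStats:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    neg_pos_ratio: float | None  # None when n_positive == 0
    mean_degree: float
    modularity: float | None  # None on an empty edge set
    group: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def topology(net: nx.Graph, seed: int = 0) -> TopologyStats:
    """Exact edge/node counts plus Louvain modularity (fixed seed)."""
    signs = [d["sign"] for _, _, d in net.edges(data=True)]
    n_pos = sum(1 for s in signs if s > 0)
    n_neg = len(signs) - n_pos
    n_nodes = net.number_of_nodes()
    if net.number_of_edges() > 0:
        communities = nx.community.louvain_communities(net, seed=seed, resolution=1.0)
        modularity = float(nx.community.modularity(net, communities))
    else:
        modularity = None
    return TopologyStats(
        n_nodes=n_nodes,
        n_edges=net.number_of_edges(),
        n_positive=n_pos,
        n_negative=n_neg,
        neg_pos_ratio=(n_neg / n_pos) if n_pos > 0 else None,
        mean_degree=(2 * net.number_of_edges() / n_nodes) if n_nodes else 0.0,
        modularity=modularity,
        group=net.graph.get("group"),
    )


def networks_by_group(
    table: CommunityTable,
    by: Sequence[str] = ("altitude", "season"),
    min_prevalence: float = 0.10,
    seed: int = 0,
    **kwargs,
) -> dict:
    """Build one prevalence-filtered network per metadata group."""
    from .io_core import filter_prevalence

    out = {}
    for key, samples in table.groups(by).items():
        sub = table.subset_samples(samples)
        sub = filter_prevalence(sub, min_prevalence)
        label = "_".join(str(k) for k in key)
        out[key] = build_network(sub, group_label=label, **kwargs)
    return out


def topology_vs_gradient(
    stats_list: Sequence[TopologyStats], altitudes: Sequence[float]
) -> pd.DataFrame:
    """Spearman rho and p of each topology metric against altitude.

    Constant metrics are flagged with NaN rho/p and ``defined=False``.
    """
    if len(stats_list) != len(altitudes):
        raise ValueError("stats and altitudes differ in length")
    if len(stats_list) < 4:
        raise ValueError("need at least 4 groups")
    metrics = ["n_nodes", "n_edges", "n_positive", "n_negative",
               "neg_pos_ratio", "mean_degree", "modularity"]
    alt = np.asarray(altitudes, dtype=float)
    rows = []
    for metric in metrics:
        vals = np.array(
            [np.nan if getattr(s, metric) is None else float(getattr(s, metric))
             for s in stats_list]
        )
        ok = np.isfinite(vals)
        if ok.sum() < 4 or np.ptp(vals[ok]) == 0 or np.ptp(alt[ok]) == 0:
            rows.append({"metric": metric, "rho": np.nan, "p_value": np.nan,
                         "defined": False})
            continue
        rho, p = stats.spearmanr(alt[ok], vals[ok])
        if ok.sum() <= 8:
            p = _exact_spearman_p(alt[ok], vals[ok], float(rho))
        rows.append({"metric": metric, "rho": float(rho), "p_value": float(p),
                     "defined": True})
    return pd.DataFrame(rows).set_index("metric")


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (small n only).

    The t approximation degenerates at |rho| = 1 for the handful of
    gradient groups typically available, so enumerate all permutations.
    """
    from itertools import permutations

    n = len(x)
    hits = total = 0
    y = np.asarray(y, dtype=float)
    for perm in permutations(range(n)):
        r, _ = stats.spearmanr(x, y[list(perm)])
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            hits += 1
    return hits / total


def write_edge_list(net: nx.Graph, path) -> None:
    rows = [
        {"source": a, "target": b, "r": d["r"], "p": d["p"], "sign": d["sign"]}
        for a, b, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "r", "p", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, str(path))
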