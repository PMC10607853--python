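"""Synthetic communities under known assembly regimes.

These generators are test scaffolding: they produce trees, metacommunity
abundance profiles and sample tables whose assembly regime is known, so
the downstream null models, process partitioning and neutral-model fit
can be validated against ground truth. The neutral generator draws each
local community from a Dirichlet with concentration ``N*m*p_i`` and then
multinomially samples ``N`` reads; the marginal per-taxon relative
abundance is then Beta(N*m*p_i, N*m*(1-p_i)), the stationary
distribution assumed by the neutral-model fit in :mod:`.neutral`.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd
import skbio

from .io_core import CommunityTable, PhyloTree

DEFAULT_ALTITUDES = (3118.0, 3363.0, 3550.0, 3945.0, 4343.0, 4761.0)

REGIMES = (
    "neutral_drift",
    "homogeneous_selection",
    "variable_selection",
    "dispersal_limitation",
    "mixed",
)


@dataclasses.dataclass
class MetacommunityProfile:
    """Metacommunity relative abundances p_i (sum to 1)."""

    taxon_ids: list[str]
    p: np.ndarray
    distribution: str = "lognormal"
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if (self.p <= 0).any():
            raise ValueError("metacommunity abundances must be positive")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("metacommunity abundances must sum to 1")
        self.p = self.p / self.p.sum()


@dataclasses.dataclass
class AssemblyScenario:
    """Design of a simulated study (regime + sampling parameters)."""

    regime: str = "neutral_drift"
    m: float = 0.1
    reads_per_sample: int = 2000
    n_taxa: int = 300
    selection_strength: float = 0.0
    brownian_rate: float = 1.0
    sigma_lognormal: float = 2.0
    altitudes: Sequence[float] = DEFAULT_ALTITUDES
    seasons: Sequence[str] = ("warm", "cold")
    samples_per_group: int = 10
    m_by_season: dict | None = None
    retained_fraction: float = 0.4  # taxa kept per group under dispersal limitation
    pool_fraction: float = 1 / 6  # clade-pool size under selection regimes
    selection_turnover: float = 0.15  # Dirichlet mass per pool taxon under selection
    seed: int = 20230

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if not (0 < self.m <= 1):
            raise ValueError("m must be in (0, 1]")
        if self.regime in ("homogeneous_selection", "variable_selection", "mixed"):
            if self.selection_strength <= 0:
                raise ValueError(f"{self.regime} requires selection_strength > 0")


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> PhyloTree:
    """Yule (pure-birth) ultrametric rooted tree with tips ASV_0001..."""
    if n_tips < 4:
        raise ValueError("n_tips must be >= 4")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)

    # Each active lineage splits at rate birth_rate; track node birth times.
    root = skbio.TreeNode()
    root.time = 0.0
    active = []
    for _ in range(2):
        child = skbio.TreeNode()
        child.time = 0.0
        root.append(child)
        active.append(child)
    now = 0.0
    while len(active) < n_tips:
        now += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(rng.integers(len(active)))
        node.time = now
        for _ in range(2):
            child = skbio.TreeNode()
            child.time = now
            node.append(child)
            active.append(child)
    now += rng.exponential(1.0 / (birth_rate * len(active)))

    width = max(4, len(str(n_tips)))
    order = rng.permutation(len(active))
    for label_i, node_i in enumerate(order):
        active[node_i].name = f"ASV_{label_i + 1:0{width}d}"
        active[node_i].time = now
    for node in root.traverse(include_self=False):
        node.length = node.time - node.parent.time
    for node in root.traverse():
        del node.time
    return PhyloTree(root)


def simulate_metacommunity(
    n_taxa: int,
    sigma_lognormal: float = 2.0,
    seed: int = 0,
    taxon_ids: Sequence[str] | None = None,
) -> MetacommunityProfile:
    """Lognormal(0, sigma^2) abundances, normalized to sum to 1."""
    if n_taxa < 4:
        raise ValueError("n_taxa must be >= 4")
    if sigma_lognormal <= 0:
        raise ValueError("sigma_lognormal must be positive")
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=sigma_lognormal, size=n_taxa)
    if taxon_ids is None:
        width = max(4, len(str(n_taxa)))
        taxon_ids = [f"ASV_{i + 1:0{width}d}" for i in range(n_taxa)]
    return MetacommunityProfile(
        list(taxon_ids),
        raw / raw.sum(),
        "lognormal",
        {"sigma": sigma_lognormal},
    )


def _dirichlet_multinomial_rows(
    p: np.ndarray, m: float, n_reads: int, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw local communities: Dirichlet(N*m*p) composition, N reads each."""
    alpha = n_reads * m * p
    rows = np.empty((n_samples, p.size), dtype=np.int64)
    for i in range(n_samples):
        # gamma draws avoid rng.dirichlet's failure mode for tiny alphas
        g = rng.gamma(shape=alpha)
        tot = g.sum()
        q = g / tot if tot > 0 else p
        rows[i] = rng.multinomial(n_reads, q)
    return rows


def simulate_neutral_samples(
    meta: MetacommunityProfile,
    m: float,
    n_reads: int,
    n_samples: int,
    seed: int,
    sample_ids: Sequence[str] | None = None,
    metadata: pd.DataFrame | None = None,
) -> CommunityTable:
    """Neutral dispersal-drift communities (Dirichlet-multinomial)."""
    if not (0 < m <= 1):
        raise ValueError("m must be in (0, 1]")
    if n_reads < 100:
        raise ValueError("n_reads must be >= 100")
    if n_samples < 5:
        raise ValueError("n_samples must be >= 5")
    rng = np.random.default_rng(seed)
    counts = _dirichlet_multinomial_rows(meta.p, m, n_reads, n_samples, rng)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    return CommunityTable(counts, sample_ids, meta.taxon_ids, metadata)


def brownian_traits(tree: PhyloTree, rate: float, seed: int) -> pd.Series:
    """One trait value per tip from Brownian motion along the tree."""
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree.tree): 0.0}
    out = {}
    for node in tree.tree.preorder(include_self=False):
        step = rng.normal(0.0, np.sqrt(rate * (node.length or 0.0)))
        values[id(node)] = values[id(node.parent)] + step
        if node.is_tip():
            out[node.name] = values[id(node)]
    return pd.Series(out)


def simulate_selected_samples(
    meta: MetacommunityProfile,
    tree: PhyloTree,
    selection_strength: float,
    optima: Sequence[float],
    n_reads: int,
    seed: int,
    traits: pd.Series | None = None,
    brownian_rate: float = 1.0,
    sample_ids: Sequence[str] | None = None,
    metadata: pd.DataFrame | None = None,
) -> CommunityTable:
    """Environmental-filtering communities.

    Taxon i receives sampling weight ``p_i * exp(-s * (trait_i - E)^2)``
    for the sample's environmental optimum E; reads are multinomial. With
    s = 0 this reduces to a plain multinomial from the metacommunity.
    """
    if selection_strength < 0:
        raise ValueError("selection_strength must be >= 0")
    rng = np.random.default_rng(seed)
    if traits is None:
        traits = brownian_traits(tree, brownian_rate, rng.integers(2**63))
    trait = traits.loc[meta.taxon_ids].to_numpy()
    optima = np.asarray(optima, dtype=float)
    counts = np.empty((optima.size, meta.p.size), dtype=np.int64)
    for i, e in enumerate(optima):
        w = meta.p * np.exp(-selection_strength * (trait - e) ** 2)
        tot = w.sum()
        if tot <= 0:
            raise ValueError("selection weights vanished; lower selection_strength")
        counts[i] = rng.multinomial(n_reads, w / tot)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(optima.size)]
    return CommunityTable(counts, sample_ids, meta.taxon_ids, metadata)


def _smallest_clade(tree: PhyloTree, min_size: int) -> list[str]:
    """Tip names of the smallest clade containing at least *min_size* tips."""
    best: list[str] | None = None
    for node in tree.tree.postorder(include_self=False):
        tips = [t.name for t in node.tips()]
        if len(tips) >= min_size and (best is None or len(tips) < len(best)):
            best = tips
    if best is None:
        best = [t.name for t in tree.tree.tips()]
    return best


def _ladder_window(tree: PhyloTree, rank: int, n_ranks: int, size: int) -> list[str]:
    """A contiguous window of *size* tips in traversal order.

    Traversal order keeps clade members adjacent, so windows at different
    ranks occupy different regions of the tree; used to give each
    altitude group its own selected pool under variable selection.
    """
    order = [t.name for t in tree.tree.postorder(include_self=False) if t.is_tip()]
    n = len(order)
    size = min(size, n)
    start = round(rank * (n - size) / max(1, n_ranks - 1))
    return order[start:start + size]


@dataclasses.dataclass
class SimulatedStudy:
    table: CommunityTable
    tree: PhyloTree
    metacommunity: MetacommunityProfile
    truth: dict


def simulate_study(scenario: AssemblyScenario) -> SimulatedStudy:
    """Emulate the full gradient design: altitudes x seasons x replicates.

    Every (altitude, season) group receives ``samples_per_group`` samples
    drawn under the scenario's regime from one shared metacommunity.
    """
    rng = np.random.default_rng(scenario.seed)
    tree = simulate_tree(scenario.n_taxa, seed=rng.integers(2**63))
    meta = simulate_metacommunity(
        scenario.n_taxa,
        scenario.sigma_lognormal,
        seed=rng.integers(2**63),
        taxon_ids=[t.name for t in sorted(tree.tree.tips(), key=lambda n: n.name)],
    )
    altitudes = list(scenario.altitudes)
    n_groups = len(altitudes)

    # Selection pools: phylogenetically confined subsets of the
    # metacommunity. Homogeneous selection filters every sample into one
    # shared clade; variable selection slides the pool along the tree
    # with altitude rank. Within a pool, weights are flattened by
    # selection strength (strong selection -> near-even packing) and the
    # drift stage uses a low Dirichlet concentration so replicate
    # communities turn over within the pool — the turnover is what the
    # phylogenetic nulls measure.
    pool_size = max(8, round(scenario.pool_fraction * scenario.n_taxa))
    shared_pool = _smallest_clade(tree, pool_size)
    gamma = 1.0 / (1.0 + scenario.selection_strength)

    blocks, ids, meta_rows = [], [], []
    truth_groups = {}
    for season in scenario.seasons:
        m_season = scenario.m
        if scenario.m_by_season and season in scenario.m_by_season:
            m_season = scenario.m_by_season[season]
        for g, altitude in enumerate(altitudes):
            regime = scenario.regime
            if regime == "mixed":
                # half the gradient assembles neutrally, half under selection
                regime = "neutral_drift" if g < n_groups // 2 else "variable_selection"
            group_seed = rng.integers(2**63)
            n = scenario.samples_per_group
            if regime == "neutral_drift":
                block = _dirichlet_multinomial_rows(
                    meta.p, m_season, scenario.reads_per_sample, n,
                    np.random.default_rng(group_seed),
                )
            elif regime == "dispersal_limitation":
                grng = np.random.default_rng(group_seed)
                k = max(4, int(round(scenario.retained_fraction * scenario.n_taxa)))
                kept = grng.choice(scenario.n_taxa, size=k, replace=False)
                p_group = np.zeros_like(meta.p)
                p_group[kept] = meta.p[kept]
                p_group /= p_group.sum()
                block = _dirichlet_multinomial_rows(
                    p_group, min(m_season, 0.05), scenario.reads_per_sample, n, grng,
                )
            elif regime in ("homogeneous_selection", "variable_selection"):
                if regime == "homogeneous_selection":
                    pool = shared_pool
                else:
                    pool = _ladder_window(tree, g, n_groups, pool_size)
                grng = np.random.default_rng(group_seed)
                in_pool = np.isin(meta.taxon_ids, pool)
                w = np.where(in_pool, meta.p**gamma, 0.0)
                w /= w.sum()
                m_sel = scenario.selection_turnover * in_pool.sum() / scenario.reads_per_sample
                block = _dirichlet_multinomial_rows(
                    w, min(1.0, m_sel), scenario.reads_per_sample, n, grng,
                )
            else:  # pragma: no cover
                raise ValueError(f"unhandled regime {regime}")

            label = f"A{int(altitude)}_{season}"
            truth_groups[label] = {"regime": regime, "m": m_season}
            for r in range(n):
                ids.append(f"{label}_{r + 1:02d}")
                meta_rows.append((altitude, season, label))
            blocks.append(block)

    counts = np.vstack(blocks)
    metadata = pd.DataFrame(
        meta_rows, columns=["altitude", "season", "site"],
        index=pd.Index(ids, name="sample_id"),
    )
    table = CommunityTable(counts, ids, meta.taxon_ids, metadata)
    truth = {
        "regime": scenario.regime,
        "m": scenario.m,
        "reads_per_sample": scenario.reads_per_sample,
        "selection_strength": scenario.selection_strength,
        "seed": scenario.seed,
        "groups": truth_groups,
    }
    return SimulatedStudy(table, tree, meta, truth)


def write_study(study: SimulatedStudy, out_dir) -> None:
    from pathlib import Path

    from . import io_core

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_core.write_count_table(study.table, out / "counts.tsv")
    io_core.write_metadata(study.table.metadata, out / "metadata.tsv")
    study.tree.write(out / "tree.nwk")
    with open(out / "truth.json", "w") as fh:
        json.dump(study.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
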