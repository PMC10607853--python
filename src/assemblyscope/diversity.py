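"""Alpha/beta diversity, ordination, PERMANOVA and gradient regressions."""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .io_core import CommunityTable, PhyloTree


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities with zero diagonal."""

    data: np.ndarray
    sample_ids: list[str]
    metric: str

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.sample_ids)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match sample ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.data < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)

    def subset(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return DistanceMatrix(self.data[np.ix_(idx, idx)], list(keep), self.metric)


@dataclasses.dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues only


@dataclasses.dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


# --------------------------------------------------------------------------
# Alpha diversity
# --------------------------------------------------------------------------

def shannon(counts) -> float:
    """Shannon entropy H = -sum p ln p (natural log)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty sample")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def gini_simpson(counts) -> float:
    """Gini-Simpson index 1 - sum p^2."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty sample")
    p = counts / total
    return float(1.0 - (p**2).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1))."""
    counts = np.asarray(counts)
    if counts.sum() <= 0:
        raise ValueError("empty sample")
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def alpha_diversity(table: CommunityTable) -> pd.DataFrame:
    """Per-sample observed richness, Shannon, Chao1 and Gini-Simpson."""
    rows = []
    for i, sid in enumerate(table.sample_ids):
        c = table.counts[i]
        rows.append(
            {
                "sample_id": sid,
                "observed_richness": int((c > 0).sum()),
                "shannon": shannon(c),
                "chao1": chao1(c),
                "gini_simpson": gini_simpson(c),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


# --------------------------------------------------------------------------
# Beta diversity
# --------------------------------------------------------------------------

def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on counts as given (no renormalization)."""
    sums = table.sample_sums
    if (sums == 0).sum() >= 2:
        raise ValueError("Bray-Curtis undefined for a pair of all-zero samples")
    condensed = pdist(table.counts.astype(float), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), list(table.sample_ids), "bray_curtis")


def _branch_table(tree: PhyloTree, taxon_ids: Sequence[str]):
    """Per-branch (length, tip-membership row over taxon_ids) arrays."""
    order = {t: i for i, t in enumerate(taxon_ids)}
    missing = [t for t in taxon_ids if t not in {x.name for x in tree.tree.tips()}]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing[:5]}")
    lengths = []
    members = []
    for node in tree.tree.postorder(include_self=False):
        row = np.zeros(len(taxon_ids), dtype=bool)
        hit = False
        for tip in node.tips(include_self=True):
            j = order.get(tip.name)
            if j is not None:
                row[j] = True
                hit = True
        if hit and node.length:
            lengths.append(node.length)
            members.append(row)
    return np.asarray(lengths, dtype=float), np.asarray(members)


def weighted_unifrac(
    table: CommunityTable, tree: PhyloTree, normalized: bool = True
) -> DistanceMatrix:
    """Weighted UniFrac: sum over branches of l_b * |A_b - B_b| where A_b,
    B_b are the fractions of each sample's reads descending from branch b.
    The normalized variant divides by sum l_b * (A_b + B_b), bounding the
    distance in [0, 1].
    """
    lengths, members = _branch_table(tree, table.taxon_ids)
    rel = table.relative_abundance()
    frac = rel @ members.T  # samples x branches
    num = squareform(pdist(frac, metric="cityblock", w=lengths))
    if not normalized:
        return DistanceMatrix(num, list(table.sample_ids), "weighted_unifrac")
    load = frac @ lengths  # sum_b l_b * A_b per sample
    denom = load[:, None] + load[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(out, list(table.sample_ids), "weighted_unifrac")


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis by Gower double-centering.

    Negative eigenvalues are reported but excluded from the
    proportion-explained denominator; coordinates span positive axes only.
    """
    n = len(dm.sample_ids)
    if n < 3:
        raise ValueError("PCoA requires at least 3 samples")
    d2 = dm.data**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ d2 @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0]) if eigvals.size else 0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    pos_sum = eigvals[pos].sum()
    proportion = eigvals[pos] / pos_sum if pos_sum > 0 else np.zeros(0)
    return OrdinationResult(
        pd.DataFrame(coords, index=dm.sample_ids, columns=axes),
        eigvals,
        proportion,
    )


# --------------------------------------------------------------------------
# Group statistics
# --------------------------------------------------------------------------

def _group_indices(sample_ids: Sequence[str], groups) -> dict:
    """groups: mapping sample_id -> label, or sequence aligned to ids."""
    if isinstance(groups, dict):
        labels = [groups[s] for s in sample_ids]
    else:
        labels = list(groups)
        if len(labels) != len(sample_ids):
            raise ValueError("groups length does not match samples")
    out: dict = {}
    for i, lab in enumerate(labels):
        out.setdefault(lab, []).append(i)
    return out


def permanova(
    dm: DistanceMatrix, groups, n_permutations: int = 999, seed: int = 0
) -> dict:
    """One-way PERMANOVA on a distance matrix.

    Returns pseudo-F, R^2 = SS_between / SS_total, and a permutation
    p-value with the observed statistic counted in numerator and
    denominator: p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    idx = _group_indices(dm.sample_ids, groups)
    if len(idx) < 2:
        raise ValueError("PERMANOVA requires at least 2 groups")
    sizes = {k: len(v) for k, v in idx.items()}
    small = [k for k, s in sizes.items() if s < 2]
    if small:
        raise ValueError(f"groups with a single sample: {small}")

    d2 = dm.data**2
    n = len(dm.sample_ids)
    k = len(idx)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    labels = np.empty(n, dtype=int)
    for g, (_, members) in enumerate(sorted(idx.items(), key=lambda kv: str(kv[0]))):
        labels[members] = g

    def stat(lab: np.ndarray) -> tuple[float, float]:
        ss_within = 0.0
        for g in range(k):
            members = np.flatnonzero(lab == g)
            sub = d2[np.ix_(members, members)]
            ss_within += sub[np.triu_indices(members.size, 1)].sum() / members.size
        ss_between = ss_total - ss_within
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
        return f, ss_between / ss_total

    f_obs, r2 = stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        f_perm, _ = stat(rng.permutation(labels))
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return {"pseudo_F": f_obs, "R2": r2, "p_value": p, "n_permutations": n_permutations}


def within_group_similarity(dm: DistanceMatrix, groups) -> dict:
    """Per group, 1 - dissimilarity for every within-group sample pair."""
    idx = _group_indices(dm.sample_ids, groups)
    out = {}
    for label, members in idx.items():
        if len(members) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
        sims = [
            1.0 - dm.data[a, b]
            for i, a in enumerate(members)
            for b in members[i + 1:]
        ]
        out[label] = np.asarray(sims)
    return out


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )


def distance_decay(dm: DistanceMatrix, altitudes) -> RegressionResult:
    """OLS of pairwise similarity (1 - d) on pairwise |altitude difference|."""
    if isinstance(altitudes, dict):
        alt = np.array([altitudes[s] for s in dm.sample_ids], dtype=float)
    else:
        alt = np.asarray(altitudes, dtype=float)
    if np.ptp(alt) == 0:
        raise ValueError("all altitudes are equal")
    iu = np.triu_indices(len(dm.sample_ids), 1)
    dx = np.abs(alt[:, None] - alt[None, :])[iu]
    sim = 1.0 - dm.data[iu]
    return _ols(dx, sim)


def gradient_regression(y_per_sample, altitudes) -> RegressionResult:
    """OLS of a per-sample quantity on altitude with a t-test on the slope."""
    y = np.asarray(y_per_sample, dtype=float)
    x = np.asarray(altitudes, dtype=float)
    if y.size != x.size:
        raise ValueError("y and altitudes differ in length")
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    return _ols(x, y)


def aggregate_taxonomy(
    table: CommunityTable,
    taxonomy: pd.DataFrame,
    rank: str,
    top_k: int = 5,
) -> pd.DataFrame:
    """Per-sample relative abundance of the top_k groups at *rank*.

    Taxa absent from the taxonomy pool into "unclassified"; remaining
    groups beyond top_k (ranked by mean relative abundance) pool into
    "others". Rows sum to 1.
    """
    if rank not in taxonomy.columns:
        raise ValueError(f"unknown rank {rank!r}")
    lineages = [
        str(taxonomy[rank].get(t, "unclassified")) if t in taxonomy.index else "unclassified"
        for t in table.taxon_ids
    ]
    rel = pd.DataFrame(
        table.relative_abundance(), index=table.sample_ids, columns=table.taxon_ids
    )
    grouped = rel.T.groupby(pd.Index(lineages, name=rank)).sum().T
    top = grouped.mean(axis=0).sort_values(ascending=False).index[:top_k]
    out = grouped[list(top)].copy()
    others = grouped.drop(columns=list(top)).sum(axis=1)
    out["others"] = others
    return out


def kruskal_wallis_by_group(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) with chi-square p on k-1 df.

    Identical values across all groups give H = 0, p = 1 by convention.
    """
    values = np.asarray(values, dtype=float)
    idx = _group_indices(range(len(values)), groups)
    if len(idx) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [values[np.asarray(members)] for members in idx.values()]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    if sum(a.size for a in arrays) < 5:
        raise ValueError("need at least 5 observations in total")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)
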