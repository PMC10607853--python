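"""Phylogenetic/taxonomic null models and ecological-process partitioning.

Implements MNTD and its standardized effect size, betaMNTD/betaNTI with a
tip-label-shuffling null, the Bray-Curtis Raup-Crick null, and the
five-way process classification combining betaNTI with RC_bray:

* betaNTI > +2          -> variable selection
* betaNTI < -2          -> homogeneous selection
* otherwise RC > +0.95  -> dispersal limitation
* otherwise RC < -0.95  -> homogenizing dispersal
* otherwise             -> ecological drift

All randomization is driven by an explicit seed. The label-shuffling null
permutes taxon identities over the pool of taxa present in the analyzed
table (one permutation per null draw, shared by all samples in the draw).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .diversity import RegressionResult, gradient_regression
from .io_core import CommunityTable, PhyloTree

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


@dataclasses.dataclass
class NullDistribution:
    """Observed value against a randomized ensemble."""

    observed: float
    null_mean: float
    null_sd: float
    n_null: int

    @property
    def ses(self) -> float:
        """(observed - null mean) / null SD; NaN when the null is degenerate."""
        if self.null_sd > 0:
            return (self.observed - self.null_mean) / self.null_sd
        return float("nan")


# --------------------------------------------------------------------------
# MNTD / SES.MNTD
# --------------------------------------------------------------------------

def _patristic(table: CommunityTable, tree: PhyloTree) -> np.ndarray:
    return tree.patristic_matrix(table.taxon_ids)


def _mntd_from_dist(counts: np.ndarray, dist: np.ndarray, weighted: bool) -> float:
    present = np.flatnonzero(counts > 0)
    if present.size < 2:
        raise ValueError("MNTD needs at least 2 taxa present")
    sub = dist[np.ix_(present, present)].copy()
    np.fill_diagonal(sub, np.inf)
    nearest = sub.min(axis=1)
    if weighted:
        w = counts[present] / counts[present].sum()
        return float((w * nearest).sum())
    return float(nearest.mean())


def mntd(
    sample_counts,
    tree: PhyloTree,
    taxon_ids,
    abundance_weighted: bool = True,
) -> float:
    """Mean nearest-taxon distance of one community.

    For each present taxon the shortest patristic distance to any other
    present taxon is found; these are averaged, abundance-weighted if
    requested.
    """
    counts = np.asarray(sample_counts, dtype=float)
    dist = tree.patristic_matrix(list(taxon_ids))
    return _mntd_from_dist(counts, dist, abundance_weighted)


def ses_mntd(
    table: CommunityTable,
    tree: PhyloTree,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
) -> pd.DataFrame:
    """SES.MNTD per sample under the taxa-label-shuffling null.

    Negative SES = phylogenetic clustering, positive = overdispersion.
    Samples whose null SD is zero (e.g. a sample containing the entire
    taxon pool) get SES = NaN.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    dist = _patristic(table, tree)
    n_taxa = table.n_taxa
    rng = np.random.default_rng(seed)

    observed = np.array(
        [_mntd_from_dist(table.counts[i].astype(float), dist, abundance_weighted)
         for i in range(table.n_samples)]
    )
    nulls = np.empty((n_null, table.n_samples))
    for k in range(n_null):
        perm = rng.permutation(n_taxa)
        dperm = dist[np.ix_(perm, perm)]
        for i in range(table.n_samples):
            nulls[k, i] = _mntd_from_dist(
                table.counts[i].astype(float), dperm, abundance_weighted
            )
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ses = np.where(sd > 0, (observed - mean) / sd, np.nan)
    return pd.DataFrame(
        {
            "mntd_observed": observed,
            "null_mean": mean,
            "null_sd": sd,
            "ses_mntd": ses,
        },
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


# --------------------------------------------------------------------------
# betaMNTD / betaNTI
# --------------------------------------------------------------------------

def _beta_mntd_matrix(
    weights: np.ndarray, presence: np.ndarray, dist: np.ndarray
) -> np.ndarray:
    """All-pairs betaMNTD.

    weights: samples x taxa (relative abundances, or presence/richness
    for the unweighted variant). presence: boolean samples x taxa.
    For each sample b, ``nearest[b, i]`` is the patristic distance from
    taxon i to its nearest taxon present in b; the directed term a->b is
    sum_i weights[a, i] * nearest[b, i], and the matrix is the symmetrized
    average of the two directions.
    """
    n_samples = presence.shape[0]
    nearest = np.empty((n_samples, dist.shape[0]))
    for b in range(n_samples):
        cols = np.flatnonzero(presence[b])
        nearest[b] = dist[:, cols].min(axis=1)
    directed = weights @ nearest.T  # [a, b] = mean nearest distance a -> b
    return 0.5 * (directed + directed.T)


def _weights(table: CommunityTable, abundance_weighted: bool) -> tuple[np.ndarray, np.ndarray]:
    presence = table.counts > 0
    if (presence.sum(axis=1) == 0).any():
        raise ValueError("betaMNTD undefined for empty samples")
    if abundance_weighted:
        weights = table.relative_abundance()
    else:
        weights = presence / presence.sum(axis=1, keepdims=True)
    return weights, presence


def beta_mntd(
    table: CommunityTable,
    tree: PhyloTree,
    abundance_weighted: bool = True,
) -> pd.DataFrame:
    """Pairwise betaMNTD matrix (symmetrized, abundance-weighted by default)."""
    dist = _patristic(table, tree)
    weights, presence = _weights(table, abundance_weighted)
    mat = _beta_mntd_matrix(weights, presence, dist)
    np.fill_diagonal(mat, 0.0)
    return pd.DataFrame(mat, index=table.sample_ids, columns=table.sample_ids)


def beta_nti(
    table: CommunityTable,
    tree: PhyloTree,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
) -> pd.DataFrame:
    """Pairwise betaNTI: (observed betaMNTD - null mean) / null SD.

    The null shuffles taxon labels (one permutation per draw, applied to
    the patristic matrix) and recomputes betaMNTD for all pairs. Diagonal
    entries are NaN; so are pairs with a degenerate null SD.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    dist = _patristic(table, tree)
    weights, presence = _weights(table, abundance_weighted)
    observed = _beta_mntd_matrix(weights, presence, dist)

    rng = np.random.default_rng(seed)
    running_sum = np.zeros_like(observed)
    running_sq = np.zeros_like(observed)
    for _ in range(n_null):
        perm = rng.permutation(table.n_taxa)
        dperm = dist[np.ix_(perm, perm)]
        null = _beta_mntd_matrix(weights, presence, dperm)
        running_sum += null
        running_sq += null**2
    mean = running_sum / n_null
    var = (running_sq - n_null * mean**2) / (n_null - 1)
    sd = np.sqrt(np.clip(var, 0.0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        bnti = np.where(sd > 0, (observed - mean) / sd, np.nan)
    np.fill_diagonal(bnti, np.nan)
    return pd.DataFrame(bnti, index=table.sample_ids, columns=table.sample_ids)


# --------------------------------------------------------------------------
# Raup-Crick (Bray-Curtis) null
# --------------------------------------------------------------------------

def raup_crick_bray(
    table: CommunityTable, n_null: int = 999, seed: int = 0
) -> pd.DataFrame:
    """Pairwise RC_bray in [-1, 1].

    Null communities preserve each sample's observed richness and total
    abundance: taxa are drawn without replacement with probability
    proportional to their occurrence frequency across samples, seeded
    with one individual each, and the remaining reads are allocated
    multinomially proportional to regional relative abundance. Per pair,
    RC = (#{BC_null < BC_obs} + 0.5 * #{BC_null = BC_obs}) / n_null,
    rescaled to 2*RC - 1.
    """
    from scipy.spatial.distance import pdist, squareform

    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    counts = table.counts
    richness = (counts > 0).sum(axis=1)
    if (richness == 0).any():
        raise ValueError("RC_bray undefined for empty samples")
    totals = counts.sum(axis=1)
    n_samples, n_taxa = counts.shape

    occurrence = (counts > 0).sum(axis=0).astype(float)
    occ_p = occurrence / occurrence.sum()
    regional = counts.sum(axis=0).astype(float)

    obs_bc = squareform(pdist(counts.astype(float), metric="braycurtis"))

    rng = np.random.default_rng(seed)
    less = np.zeros((n_samples, n_samples))
    equal = np.zeros((n_samples, n_samples))
    null_counts = np.empty((n_samples, n_taxa))
    for _ in range(n_null):
        for s in range(n_samples):
            k = int(richness[s])
            chosen = rng.choice(n_taxa, size=k, replace=False, p=occ_p)
            row = np.zeros(n_taxa)
            row[chosen] = 1.0
            remaining = int(totals[s]) - k
            if remaining > 0:
                w = regional[chosen]
                tot = w.sum()
                probs = w / tot if tot > 0 else np.full(k, 1.0 / k)
                row[chosen] += rng.multinomial(remaining, probs)
            null_counts[s] = row
        null_bc = squareform(pdist(null_counts, metric="braycurtis"))
        less += null_bc < obs_bc - 1e-12
        equal += np.abs(null_bc - obs_bc) <= 1e-12
    rc = (less + 0.5 * equal) / n_null
    out = 2.0 * rc - 1.0
    np.fill_diagonal(out, np.nan)
    return pd.DataFrame(out, index=table.sample_ids, columns=table.sample_ids)


# --------------------------------------------------------------------------
# Process classification and partitioning
# --------------------------------------------------------------------------

def classify_pair(beta_nti_value: float, rc_value: float) -> str:
    """Assign one of the five assembly processes to a sample pair.

    The betaNTI rule takes precedence; thresholds are strict, so boundary
    values (exactly +-2, exactly +-0.95) fall through to the next rule.
    """
    if not (np.isfinite(beta_nti_value) and np.isfinite(rc_value)):
        raise ValueError("classify_pair requires finite betaNTI and RC values")
    if beta_nti_value > BNTI_THRESHOLD:
        return "variable_selection"
    if beta_nti_value < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc_value > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc_value < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "drift"


def classify_pairs(
    bnti: pd.DataFrame, rc: pd.DataFrame
) -> pd.DataFrame:
    """Long-format per-pair table: betaNTI, RC and assigned process."""
    if list(bnti.index) != list(rc.index):
        raise ValueError("betaNTI and RC matrices are not aligned")
    ids = list(bnti.index)
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            bn, rv = bnti.loc[a, b], rc.loc[a, b]
            process = (
                classify_pair(bn, rv)
                if np.isfinite(bn) and np.isfinite(rv)
                else "unclassified"
            )
            rows.append({"sample_a": a, "sample_b": b, "beta_nti": bn,
                         "rc_bray": rv, "process": process})
    return pd.DataFrame(rows)


def partition_processes(pairs: pd.DataFrame, groups) -> pd.DataFrame:
    """Per-group fractions of the five processes over within-group pairs.

    *groups* maps sample id -> group label. Pairs spanning two groups and
    unclassified pairs are excluded; fractions sum to 1 per group.
    """
    sizes: dict = {}
    for label in groups.values() if isinstance(groups, dict) else groups:
        sizes[label] = sizes.get(label, 0) + 1
    small = [g for g, n in sizes.items() if n < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    rows = {}
    for _, rec in pairs.iterrows():
        ga, gb = groups[rec["sample_a"]], groups[rec["sample_b"]]
        if ga != gb or rec["process"] == "unclassified":
            continue
        rows.setdefault(ga, []).append(rec["process"])
    if not rows:
        raise ValueError("no within-group classified pairs")
    out = []
    for label, procs in sorted(rows.items(), key=lambda kv: str(kv[0])):
        if len(procs) < 1:
            raise ValueError(f"group {label!r} has no within-group pairs")
        counts = {p: procs.count(p) / len(procs) for p in PROCESSES}
        counts["group"] = label
        counts["n_pairs"] = len(procs)
        out.append(counts)
    return pd.DataFrame(out).set_index("group")


def ses_vs_gradient(ses_values, altitudes) -> RegressionResult:
    """OLS of per-sample SES.MNTD on altitude (NaN SES rows dropped)."""
    ses_values = np.asarray(ses_values, dtype=float)
    altitudes = np.asarray(altitudes, dtype=float)
    ok = np.isfinite(ses_values)
    return gradient_regression(ses_values[ok], altitudes[ok])


def bnti_vs_gradient(bnti: pd.DataFrame, groups, altitudes: dict) -> RegressionResult:
    """OLS of within-group mean betaNTI on group altitude."""
    ids = list(bnti.index)
    sums: dict = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if groups[a] != groups[b]:
                continue
            v = bnti.loc[a, b]
            if np.isfinite(v):
                tot, n = sums.get(groups[a], (0.0, 0))
                sums[groups[a]] = (tot + v, n + 1)
    labels = sorted(sums, key=str)
    means = [sums[g][0] / sums[g][1] for g in labels]
    alts = [altitudes[g] for g in labels]
    return gradient_regression(means, alts)
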