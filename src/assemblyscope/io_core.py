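"""Data model, file I/O, normalization, and prevalence filtering.

Count tables are stored samples-by-taxa. Supported on-disk formats are
plain TSV (taxa as rows or columns, orientation auto-detected against
sample metadata) and BIOM 2.1 (HDF5, read/written with h5py).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import skbio

SEASONS = ("warm", "cold")

METADATA_COLUMNS = ("altitude", "season", "site")


class CommunityTableError(ValueError):
    """Raised on malformed count tables or metadata."""


@dataclasses.dataclass
class CommunityTable:
    """Samples x taxa integer count matrix with per-sample metadata.

    Parameters
    ----------
    counts : ndarray of shape (n_samples, n_taxa)
        Non-negative integer counts.
    sample_ids, taxon_ids : sequences of unique strings.
    metadata : DataFrame indexed by sample id with columns
        ``altitude`` (positive number), ``season`` (warm|cold), ``site``.
    """

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    metadata: pd.DataFrame

    def __init__(
        self,
        counts,
        sample_ids: Sequence[str],
        taxon_ids: Sequence[str],
        metadata: pd.DataFrame | None = None,
        *,
        allow_empty_samples: bool = False,
    ):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise CommunityTableError("counts must be a 2-D matrix")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            as_int = counts.astype(np.int64)
            if not np.allclose(counts, as_int):
                raise CommunityTableError("counts must be integers")
            counts = as_int
        counts = counts.astype(np.int64, copy=True)
        if counts.size and counts.min() < 0:
            raise CommunityTableError("counts must be non-negative")

        sample_ids = [str(s) for s in sample_ids]
        taxon_ids = [str(t) for t in taxon_ids]
        if counts.shape != (len(sample_ids), len(taxon_ids)):
            raise CommunityTableError(
                f"shape {counts.shape} does not match "
                f"{len(sample_ids)} samples x {len(taxon_ids)} taxa"
            )
        if len(set(sample_ids)) != len(sample_ids):
            raise CommunityTableError("duplicate sample ids")
        if len(set(taxon_ids)) != len(taxon_ids):
            raise CommunityTableError("duplicate taxon ids")
        if not allow_empty_samples and counts.size and (counts.sum(axis=1) == 0).any():
            empty = [s for s, tot in zip(sample_ids, counts.sum(axis=1)) if tot == 0]
            raise CommunityTableError(f"all-zero sample rows: {empty}")

        if metadata is None:
            metadata = default_metadata(sample_ids)
        metadata = _validate_metadata(metadata, sample_ids)

        self.counts = counts
        self.sample_ids = sample_ids
        self.taxon_ids = taxon_ids
        self.metadata = metadata

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative abundances; all-zero samples map to zeros."""
        sums = self.sample_sums.astype(float)
        safe = np.where(sums > 0, sums, 1.0)
        return self.counts / safe[:, None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    def groups(self, by: Sequence[str] = ("altitude", "season")) -> dict:
        """Map group key (tuple of metadata values) -> list of sample ids."""
        meta = self.metadata.loc[self.sample_ids]
        out: dict = {}
        for sid, row in meta.iterrows():
            key = tuple(row[c] for c in by)
            out.setdefault(key, []).append(sid)
        return out

    def subset_samples(self, keep: Iterable[str]) -> "CommunityTable":
        keep = list(keep)
        idx = [self.sample_ids.index(s) for s in keep]
        return CommunityTable(
            self.counts[idx],
            keep,
            self.taxon_ids,
            self.metadata.loc[keep],
            allow_empty_samples=True,
        )

    def subset_taxa(self, keep: Iterable[str]) -> "CommunityTable":
        keep = list(keep)
        idx = [self.taxon_ids.index(t) for t in keep]
        return CommunityTable(
            self.counts[:, idx],
            self.sample_ids,
            keep,
            self.metadata,
            allow_empty_samples=True,
        )


def default_metadata(sample_ids: Sequence[str]) -> pd.DataFrame:
    """Placeholder metadata for tables generated without a study design."""
    return pd.DataFrame(
        {
            "altitude": 1.0,
            "season": "warm",
            "site": "unspecified",
        },
        index=pd.Index([str(s) for s in sample_ids], name="sample_id"),
    )


def _validate_metadata(metadata: pd.DataFrame, sample_ids: Sequence[str]) -> pd.DataFrame:
    missing_cols = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing_cols:
        raise CommunityTableError(f"metadata missing columns: {missing_cols}")
    metadata = metadata.copy()
    metadata.index = metadata.index.astype(str)
    missing = [s for s in sample_ids if s not in metadata.index]
    if missing:
        raise CommunityTableError(f"metadata does not cover samples: {missing[:5]}")
    metadata = metadata.loc[list(sample_ids)]
    metadata["altitude"] = pd.to_numeric(metadata["altitude"])
    if (metadata["altitude"] <= 0).any():
        raise CommunityTableError("altitude must be positive")
    bad = set(metadata["season"]) - set(SEASONS)
    if bad:
        raise CommunityTableError(f"season must be one of {SEASONS}, got {bad}")
    return metadata


@dataclasses.dataclass
class PhyloTree:
    """Rooted tree with branch lengths, backed by an skbio TreeNode."""

    tree: skbio.TreeNode

    def __post_init__(self):
        for node in self.tree.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                raise ValueError("negative branch length")

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def patristic_matrix(self, taxon_ids: Sequence[str]) -> np.ndarray:
        """Pairwise tip-to-tip path-length matrix aligned to *taxon_ids*."""
        names = set(self.tip_names)
        missing = [t for t in taxon_ids if t not in names]
        if missing:
            raise ValueError(f"taxa missing from tree: {missing[:5]}")
        dm = self.tree.tip_tip_distances()
        pos = {name: i for i, name in enumerate(dm.ids)}
        idx = np.array([pos[t] for t in taxon_ids])
        return dm.data[np.ix_(idx, idx)]

    def write(self, path) -> None:
        self.tree.write(str(path), format="newick")


def read_tree(path) -> PhyloTree:
    return PhyloTree(skbio.TreeNode.read(str(path), format="newick"))


# --------------------------------------------------------------------------
# Count table I/O
# --------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, altitude, season, site)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise CommunityTableError("metadata must have a sample_id column")
    meta = meta.set_index("sample_id")
    return meta


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_count_table(
    path,
    metadata: pd.DataFrame | None = None,
    format: str = "auto",
) -> CommunityTable:
    """Read a count table from TSV or BIOM 2.1.

    Orientation of a TSV (samples as rows vs columns) is auto-detected by
    matching ids against *metadata*; with no metadata rows are assumed to
    be samples.
    """
    path = Path(path)
    if format == "auto":
        format = "biom" if path.suffix == ".biom" else "tsv"
    if format == "tsv":
        frame = _read_tsv_frame(path)
    elif format == "biom":
        frame = _read_biom_frame(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    if metadata is not None:
        meta_ids = set(metadata.index.astype(str))
        row_hits = sum(str(i) in meta_ids for i in frame.index)
        col_hits = sum(str(c) in meta_ids for c in frame.columns)
        if row_hits == 0 and col_hits == 0:
            raise CommunityTableError("no id overlap between table and metadata")
        if col_hits > row_hits:
            frame = frame.T
    return CommunityTable(
        frame.to_numpy(),
        list(frame.index.astype(str)),
        list(frame.columns.astype(str)),
        metadata,
    )


def _read_tsv_frame(path: Path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise CommunityTableError("no data rows") from None
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise CommunityTableError("no data rows")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise CommunityTableError("non-numeric cells in count table")
    if np.isnan(values.astype(float)).any():
        raise CommunityTableError("missing values in count table")
    return frame


def write_count_table(table: CommunityTable, path, format: str = "auto") -> None:
    path = Path(path)
    if format == "auto":
        format = "biom" if path.suffix == ".biom" else "tsv"
    if format == "tsv":
        frame = table.to_frame()
        frame.index.name = "sample_id"
        frame.to_csv(path, sep="\t")
    elif format == "biom":
        _write_biom(table, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_biom_frame(path: Path) -> pd.DataFrame:
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as fh:
        obs_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in fh["observation/ids"][:]]
        samp_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in fh["sample/ids"][:]]
        grp = fh["observation/matrix"]
        mat = sparse.csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(obs_ids), len(samp_ids)),
        )
    # BIOM stores observations (taxa) as rows; our convention is samples-as-rows.
    dense = np.asarray(mat.todense()).T
    return pd.DataFrame(dense, index=samp_ids, columns=obs_ids)


def _write_biom(table: CommunityTable, path: Path) -> None:
    import datetime

    import h5py
    from scipy import sparse

    obs = sparse.csr_matrix(table.counts.T)  # taxa x samples
    samp = sparse.csr_matrix(table.counts)  # samples x taxa
    with h5py.File(path, "w") as fh:
        fh.attrs["id"] = "No Table ID"
        fh.attrs["type"] = "OTU table"
        fh.attrs["format-url"] = "http://biom-format.org"
        fh.attrs["format-version"] = (2, 1)
        fh.attrs["generated-by"] = "assemblyscope"
        fh.attrs["creation-date"] = datetime.datetime.now().isoformat()
        fh.attrs["shape"] = (table.n_taxa, table.n_samples)
        fh.attrs["nnz"] = int(obs.nnz)
        fh.create_dataset("observation/ids", data=[t.encode() for t in table.taxon_ids])
        fh.create_dataset("sample/ids", data=[s.encode() for s in table.sample_ids])
        for name, m in (("observation", obs), ("sample", samp)):
            fh.create_dataset(f"{name}/matrix/data", data=m.data.astype(float))
            fh.create_dataset(f"{name}/matrix/indices", data=m.indices)
            fh.create_dataset(f"{name}/matrix/indptr", data=m.indptr)
        fh.create_group("observation/metadata")
        fh.create_group("sample/metadata")
        fh.create_group("observation/group-metadata")
        fh.create_group("sample/group-metadata")


# --------------------------------------------------------------------------
# Taxonomy
# --------------------------------------------------------------------------

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


def read_taxonomy(path, ranks: Sequence[str] = RANKS) -> pd.DataFrame:
    """Read taxon -> lineage TSV; missing ranks become "unclassified"."""
    tax = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    tax.index = tax.index.astype(str)
    for rank in ranks:
        if rank not in tax.columns:
            tax[rank] = "unclassified"
    tax = tax[list(ranks)].fillna("unclassified")
    tax = tax.replace("", "unclassified")
    return tax


# --------------------------------------------------------------------------
# Normalization and filtering
# --------------------------------------------------------------------------

def rarefy(
    table: CommunityTable,
    depth: int,
    seed: int,
    drop_shallow: bool = False,
) -> CommunityTable:
    """Subsample every sample to *depth* reads without replacement.

    Samples with fewer than *depth* reads raise unless ``drop_shallow``,
    in which case they are removed. One hypergeometric draw per sample;
    reproducible under *seed*.
    """
    depth = int(depth)
    if depth <= 0:
        raise ValueError("depth must be positive")
    sums = table.sample_sums
    shallow = [s for s, tot in zip(table.sample_ids, sums) if tot < depth]
    if shallow:
        if not drop_shallow:
            raise ValueError(
                f"depth {depth} exceeds sample sums for {shallow[:5]}; "
                "pass drop_shallow=True to remove them"
            )
        table = table.subset_samples([s for s in table.sample_ids if s not in set(shallow)])
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        out[i] = rng.multivariate_hypergeometric(table.counts[i], depth)
    return CommunityTable(out, table.sample_ids, table.taxon_ids, table.metadata)


def goods_coverage(sample_counts) -> float:
    """Good's coverage 1 - F1/N (F1 = singletons, N = sample sum)."""
    counts = np.asarray(sample_counts)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty sample")
    singletons = int((counts == 1).sum())
    return 1.0 - singletons / total


def filter_prevalence(table: CommunityTable, min_fraction: float) -> CommunityTable:
    """Keep taxa present (count > 0) in strictly more than *min_fraction*
    of samples. The sample set is unchanged; samples may become all-zero.
    """
    if not (0 <= min_fraction < 1):
        raise ValueError("min_fraction must be in [0, 1)")
    occurrence = (table.counts > 0).sum(axis=0)
    keep = occurrence > min_fraction * table.n_samples
    taxa = [t for t, k in zip(table.taxon_ids, keep) if k]
    return CommunityTable(
        table.counts[:, keep],
        table.sample_ids,
        taxa,
        table.metadata,
        allow_empty_samples=True,
    )
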