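"""Reading, writing and filtering of count matrices and gene annotation tables.

All tabular formats are plain TSV/CSV. Output files may carry ``#``-prefixed
metadata comment lines before the header; every reader here skips/parses them.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "GeneLengthTable",
    "LibrarySizeTable",
    "GeneSet",
    "normalize_symbol",
    "read_count_matrix",
    "filter_all_zero_genes",
    "read_gene_lengths",
    "read_library_sizes",
    "read_gene_sets",
    "read_normalized_matrix",
    "read_selection",
    "write_table",
]


def normalize_symbol(symbol: str) -> str:
    """Canonical form used for gene-set matching: strip whitespace, uppercase.

    No alias or cross-database ID resolution is attempted.
    """
    return str(symbol).strip().upper()


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise ValueError(f"duplicate {what} ID {dup!r}")


@dataclass
class CountMatrix:
    """Nonnegative integer gene-by-sample matrix.

    ``counts`` is a DataFrame with gene IDs as index and sample IDs as columns.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "sample")
        if self.counts.shape[1] < 1:
            raise ValueError("count matrix needs at least one sample")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class GeneLengthTable:
    """Per-gene length in bases (strictly positive)."""

    lengths: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.lengths.index, "gene")
        if (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0][0]
            raise ValueError(f"non-positive length for gene {bad!r}")
        self.lengths = self.lengths.astype(np.int64)


@dataclass
class LibrarySizeTable:
    """Per-sample total aligned reads (strictly positive)."""

    sizes: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.sizes.index, "sample")
        if (self.sizes <= 0).any():
            bad = self.sizes.index[self.sizes <= 0][0]
            raise ValueError(f"non-positive library size for sample {bad!r}")
        self.sizes = self.sizes.astype(np.int64)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (symbols already normalized)."""

    name: str
    members: frozenset = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in self.members


_SEPS = {"tsv": "\t", "csv": ","}


def read_count_matrix(path, dialect: str = "tsv") -> CountMatrix:
    """Read a gene-by-sample integer count matrix.

    First column holds gene IDs, the header row sample IDs. Cells must be
    nonnegative integers; violations are reported with their location.
    """
    sep = _SEPS[dialect]
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    df.index = df.index.astype(str).rename(None)
    df.columns.name = None
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    out = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            gene = df.index[bad][0]
            raise ValueError(
                f"non-integer count {df[col][bad].iloc[0]!r} at gene {gene!r}, "
                f"sample {col!r} in {path}"
            )
        neg = vals < 0
        if neg.any():
            gene = df.index[neg][0]
            raise ValueError(
                f"negative count at gene {gene!r}, sample {col!r} in {path}"
            )
        out[col] = vals.astype(np.int64)
    return CountMatrix(pd.DataFrame(out, index=df.index))


def filter_all_zero_genes(m: CountMatrix) -> CountMatrix:
    """Drop genes whose count is zero in every sample; keep original order.

    Column sums are unchanged by construction. Raises if nothing survives.
    """
    keep = (m.counts != 0).any(axis=1)
    if not keep.any():
        raise ValueError("all genes have zero counts in every sample")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_all_zero_genes: removed %d all-zero genes", dropped)
    return CountMatrix(m.counts.loc[keep])


def _read_two_column(path, what: str) -> pd.Series:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{what}: expected 2 tab-separated columns, got {line!r}")
            rows.append(parts)
    if rows and not rows[0][1].strip().lstrip("+-").isdigit():
        rows = rows[1:]  # optional header row
    if not rows:
        raise ValueError(f"{what}: no data rows in {path}")
    ids = [r[0] for r in rows]
    vals = [int(r[1]) for r in rows]
    return pd.Series(vals, index=pd.Index(ids), dtype=np.int64)


def read_gene_lengths(path) -> GeneLengthTable:
    """Read a two-column TSV of gene ID and length in bases."""
    return GeneLengthTable(_read_two_column(path, "gene lengths"))


def read_library_sizes(path) -> LibrarySizeTable:
    """Read a two-column TSV of sample ID and total aligned reads."""
    return LibrarySizeTable(_read_two_column(path, "library sizes"))


def read_gene_sets(path, format: str = "plain") -> list[GeneSet]:
    """Read external gene lists.

    ``plain``: one symbol per line, set named after the file stem.
    ``gmt``: standard GMT (name, description, members), one set per line.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    if format == "plain":
        members = set()
        with open(path) as fh:
            for line in fh:
                sym = line.strip()
                if sym and not sym.startswith("#"):
                    members.add(normalize_symbol(sym))
        if not members:
            raise ValueError(f"gene set file {path} is empty after parsing")
        sets.append(GeneSet(path.stem, frozenset(members)))
    elif format == "gmt":
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed GMT line in {path}: {line!r}")
                name, _desc, *genes = parts
                members = frozenset(normalize_symbol(g) for g in genes if g.strip())
                if not members:
                    raise ValueError(f"GMT set {name!r} in {path} has no members")
                sets.append(GeneSet(name, members))
        if not sets:
            raise ValueError(f"GMT file {path} contains no sets")
    else:
        raise ValueError(f"unknown gene set format {format!r}")
    return sets


def _read_comment_metadata(path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta


def read_normalized_matrix(path):
    """Read back a normalized matrix written by :func:`write_table`."""
    from .normalize import NormalizedMatrix

    meta = _read_comment_metadata(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str).rename(None)
    df.columns.name = None
    return NormalizedMatrix(df.astype(float), meta.get("method", "unknown"))


def read_selection(path):
    """Read back an HKG selection written by :func:`write_table`."""
    from .hkg_select import HKGSelection

    meta = _read_comment_metadata(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    df["gene"] = df["gene"].astype(str)
    cvs = pd.Series(df["cv"].to_numpy(), index=df["gene"].to_numpy())
    return HKGSelection(
        method=meta.get("method", "unknown"),
        percentile=float(meta.get("percentile", "nan")),
        genes=list(df["gene"]),
        cvs=cvs,
    )


def _float_repr(v) -> str:
    # shortest round-trip representation, independent of numpy scalar types
    return repr(float(v))


def _write_frame(df: pd.DataFrame, path, comments: list[str], index_label=None) -> None:
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index_label=index_label, float_format=_float_repr)


def write_table(obj, path) -> None:
    """Write any tabular pipeline result as TSV (with ``#`` metadata lines).

    Floats are written with full round-trip precision.
    """
    from .evaluate import BiasVarianceReport, CVSummary, OverlapTable
    from .hkg_select import ConsensusSet, CVTable, HKGSelection, RatioBinTable
    from .normalize import NormalizedMatrix, ScalingFactorSet

    if isinstance(obj, CountMatrix):
        _write_frame(obj.counts, path, [], index_label="gene_id")
    elif isinstance(obj, NormalizedMatrix):
        _write_frame(obj.values, path, [f"method = {obj.method}"], index_label="gene_id")
    elif isinstance(obj, ScalingFactorSet):
        df = obj.factors.rename("factor").to_frame()
        _write_frame(df, path, [f"method = {obj.method}"], index_label="sample_id")
    elif isinstance(obj, GeneLengthTable):
        _write_frame(obj.lengths.rename("length_bp").to_frame(), path, [], index_label="gene_id")
    elif isinstance(obj, LibrarySizeTable):
        _write_frame(obj.sizes.rename("library_size").to_frame(), path, [], index_label="sample_id")
    elif isinstance(obj, CVTable):
        _write_frame(
            obj.table, path,
            [f"method = {obj.method}", f"zero_mean_genes_excluded = {obj.n_zero_mean_excluded}"],
            index_label="gene",
        )
    elif isinstance(obj, HKGSelection):
        df = pd.DataFrame(
            {"gene": obj.genes, "cv": obj.cvs.to_numpy(), "rank": np.arange(1, obj.size + 1)}
        )
        with open(path, "w") as fh:
            fh.write(f"# method = {obj.method}\n")
            fh.write(f"# percentile = {obj.percentile!r}\n")
            fh.write(f"# size = {obj.size}\n")
            df.to_csv(fh, sep="\t", index=False, float_format=_float_repr)
    elif isinstance(obj, ConsensusSet):
        _write_frame(obj.cv_by_method, path, [f"size = {len(obj)}"], index_label="gene")
    elif isinstance(obj, RatioBinTable):
        _write_frame(obj.table, path, [], index_label="bin")
    elif isinstance(obj, BiasVarianceReport):
        comments = [
            f"method = {obj.method}",
            f"n_samples = {obj.n_samples}",
            f"genes_skipped_for_zeros = {obj.n_skipped}",
            f"mean_bias = {obj.mean_bias!r}",
            f"mean_variance = {obj.mean_variance!r}",
        ]
        _write_frame(obj.per_gene, path, comments, index_label="gene")
    elif isinstance(obj, CVSummary):
        df = pd.DataFrame(
            [[obj.minimum, obj.q1, obj.median, obj.q3, obj.maximum]],
            columns=["min", "q1", "median", "q3", "max"],
        )
        with open(path, "w") as fh:
            df.to_csv(fh, sep="\t", index=False, float_format=_float_repr)
    elif isinstance(obj, OverlapTable):
        _write_frame(obj.formatted(), path, [f"percentage_basis = {obj.basis}"])
    elif isinstance(obj, pd.DataFrame):
        _write_frame(obj, path, [])
    else:
        raise TypeError(f"write_table: unsupported object type {type(obj).__name__}")
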