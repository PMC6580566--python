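"""Scoring of normalization methods and validation of HKG selections.

Bias and variance of a normalization are computed per gene from the log2
deviations of its normalized counts around the gene's mean:

    bias_i     = sqrt( (1/n) * sum_j log2(K_ij / Kbar_i)^2 )
    variance_i = (1/(n-1)) * sum_j ( log2(K_ij / Kbar_i) - mbar_i )^2

with Kbar_i the gene's arithmetic mean across samples and mbar_i the mean of
its log2-ratios.  Both are invariant to rescaling a gene by a constant.
A method's score is the arithmetic mean of the per-gene values over a stable
gene set (typically the method's own HKG selection).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .countio import GeneSet, normalize_symbol
from .hkg_select import CVTable, HKGSelection, _as_values
from .normalize import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class BiasVarianceReport:
    """Per-gene and method-level bias/variance of one normalization."""

    method: str
    per_gene: pd.DataFrame  # index gene; columns bias, variance
    mean_bias: float
    mean_variance: float
    n_samples: int
    n_skipped: int  # genes dropped because they contain a zero value


@dataclass
class CVSummary:
    """Five-number summary of a CV distribution (boxplot statistics)."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float

    def __post_init__(self) -> None:
        vals = (self.minimum, self.q1, self.median, self.q3, self.maximum)
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError(f"summary not ordered: {vals}")


@dataclass
class OverlapTable:
    """Overlap counts and percentages of HKG selections vs external lists."""

    counts: pd.DataFrame  # rows external lists, columns methods
    percents: pd.DataFrame
    list_sizes: pd.Series
    basis: str  # "list_size" or "hkg_size"

    def formatted(self) -> pd.DataFrame:
        """Cells rendered as ``count (pct)`` with two-decimal percentages."""
        out = self.counts.astype(str) + " (" + self.percents.round(2).astype(str) + ")"
        out.insert(0, "list_size", self.list_sizes)
        out.index.name = "gene_list"
        return out


def bias_variance(
    nm: NormalizedMatrix,
    genes: Optional[GeneSet | Iterable[str]] = None,
    pseudocount: float = 0.0,
) -> BiasVarianceReport:
    """Evaluate the bias/variance formulas over a gene set.

    Genes containing any zero normalized value are skipped (the log is
    undefined) and counted, unless a positive ``pseudocount`` is added to
    every value first.
    """
    values, method = _as_values(nm)
    n = values.shape[1]
    if n < 2:
        raise ValueError("bias/variance need at least 2 samples")
    if genes is not None:
        wanted = list(genes.members) if isinstance(genes, GeneSet) else list(genes)
        lookup = {normalize_symbol(g): g for g in values.index}
        rows = []
        for g in wanted:
            key = normalize_symbol(g)
            if key not in lookup:
                raise ValueError(f"gene {g!r} not present in the normalized matrix")
            rows.append(lookup[key])
        values = values.loc[sorted(set(rows), key=rows.index)]
    arr = values.to_numpy(dtype=float) + pseudocount
    ok = (arr > 0).all(axis=1)
    n_skipped = int((~ok).sum())
    if not ok.any():
        raise ValueError("every gene contains a zero value; nothing to evaluate")
    if n_skipped:
        logger.info("bias_variance: skipped %d genes containing zeros", n_skipped)
    sub = arr[ok]
    logr = np.log2(sub / sub.mean(axis=1, keepdims=True))
    bias = np.sqrt(np.mean(logr**2, axis=1))
    variance = logr.var(axis=1, ddof=1)
    per_gene = pd.DataFrame(
        {"bias": bias, "variance": variance}, index=values.index[ok]
    )
    return BiasVarianceReport(
        method=method,
        per_gene=per_gene,
        mean_bias=float(bias.mean()),
        mean_variance=float(variance.mean()),
        n_samples=n,
        n_skipped=n_skipped,
    )


def cv_summary(cvt: CVTable, genes: Optional[GeneSet | Iterable[str]] = None) -> CVSummary:
    """Boxplot five-number summary of a CV table, optionally on a subset.

    Quartiles use linear interpolation between order statistics.
    """
    cvs = cvt.cvs
    if genes is not None:
        members = genes.members if isinstance(genes, GeneSet) else set(genes)
        members = {normalize_symbol(g) for g in members}
        keep = [g for g in cvs.index if normalize_symbol(g) in members]
        cvs = cvs.loc[keep]
    if len(cvs) == 0:
        raise ValueError("no genes left after restriction")
    mn, q1, med, q3, mx = np.percentile(cvs.to_numpy(), [0, 25, 50, 75, 100])
    return CVSummary(float(mn), float(q1), float(med), float(q3), float(mx))


def overlap_report(
    selections: list[HKGSelection],
    lists: list[GeneSet],
    basis: str = "list_size",
) -> OverlapTable:
    """Count genes shared between each HKG selection and each external list.

    Percentages are 100 * overlap / |external list| when ``basis`` is
    ``"list_size"`` (the convention used when the lists are
    disease-associated DE gene sets or published HKG compendia), or
    100 * overlap / |selection| when ``basis`` is ``"hkg_size"``.
    Symbols are matched case-insensitively after whitespace stripping.
    """
    if not selections or not lists:
        raise ValueError("need at least one selection and one gene list")
    if basis not in ("list_size", "hkg_size"):
        raise ValueError(f"unknown percentage basis {basis!r}")
    counts = {}
    percents = {}
    for sel in selections:
        sel_set = sel.gene_set.members
        col_counts = []
        col_pcts = []
        for gl in lists:
            ov = len(sel_set & gl.members)
            denom = len(gl.members) if basis == "list_size" else sel.size
            col_counts.append(ov)
            col_pcts.append(100.0 * ov / denom)
        counts[sel.method] = col_counts
        percents[sel.method] = col_pcts
    names = [gl.name for gl in lists]
    return OverlapTable(
        counts=pd.DataFrame(counts, index=names),
        percents=pd.DataFrame(percents, index=names),
        list_sizes=pd.Series([len(gl) for gl in lists], index=names),
        basis=basis,
    )


def cv_boxplot(cv_tables: dict[str, CVTable], path, genes=None) -> None:
    """Optional boxplot of CV distributions per method (PNG/PDF via matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels, data = [], []
    for method, cvt in cv_tables.items():
        cvs = cvt.cvs
        if genes is not None:
            members = genes.members if isinstance(genes, GeneSet) else set(genes)
            members = {normalize_symbol(g) for g in members}
            cvs = cvs.loc[[g for g in cvs.index if normalize_symbol(g) in members]]
        labels.append(method)
        data.append(cvs.to_numpy())
    fig, ax = plt.subplots(figsize=(1.2 * len(labels) + 2, 4))
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("coefficient of variation")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
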