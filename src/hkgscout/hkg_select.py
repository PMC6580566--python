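"""Coefficient-of-variation ranking and housekeeping-gene selection.

A housekeeping gene (HKG) is operationally a gene whose normalized
expression varies least across samples: its coefficient of variation
(CV = sd/mean) falls below a low percentile — the 2nd by default — of the
CV distribution over all expressed genes.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .countio import CountMatrix, GeneSet
from .normalize import NormalizedMatrix

logger = logging.getLogger(__name__)

#: Fixed expression-ratio bin edges (fractions of the set-wide maximum).
RATIO_BIN_EDGES = (0.0, 0.01, 0.05, 0.20, 0.40, 0.60, 0.80, 1.0)
RATIO_BIN_LABELS = (
    "0-0.01",
    "0.01-0.05",
    "0.05-0.20",
    "0.20-0.40",
    "0.40-0.60",
    "0.60-0.80",
    "0.80-1.0",
)


@dataclass
class CVTable:
    """Per-gene mean, sample SD (n-1 denominator) and CV for one method.

    Genes with zero mean are excluded (their CV is undefined); the count of
    exclusions is retained.
    """

    table: pd.DataFrame  # index gene; columns mean, sd, cv
    method: str
    n_zero_mean_excluded: int = 0

    def __len__(self) -> int:
        return len(self.table)

    @property
    def cvs(self) -> pd.Series:
        return self.table["cv"]


@dataclass
class HKGSelection:
    """Genes below a CV percentile, ascending by CV (ties by gene ID)."""

    method: str
    percentile: float
    genes: list[str]
    cvs: pd.Series

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def gene_set(self) -> GeneSet:
        return GeneSet(self.method, frozenset(str(g).strip().upper() for g in self.genes))


@dataclass
class RatioBinTable:
    """Expression ratios of a selection, binned with Table-style fixed edges."""

    ratios: pd.Series
    table: pd.DataFrame  # index bin label; columns count, percent
    denominator: str


@dataclass
class ConsensusSet:
    """Genes common to every per-method selection, with their per-method CVs."""

    gene_set: GeneSet
    cv_by_method: pd.DataFrame  # genes x method labels

    @property
    def members(self) -> frozenset:
        return self.gene_set.members

    def __len__(self) -> int:
        return len(self.gene_set)


def _as_values(nm) -> tuple[pd.DataFrame, str]:
    if isinstance(nm, NormalizedMatrix):
        return nm.values, nm.method
    if isinstance(nm, CountMatrix):
        return nm.counts.astype(float), "raw"
    raise TypeError("expected a NormalizedMatrix or CountMatrix")


def gene_cv(nm: NormalizedMatrix) -> CVTable:
    """Per-gene CV = sample SD / arithmetic mean across samples.

    SD uses the n-1 denominator. Genes whose mean is zero are dropped from
    the table (counted, and logged).
    """
    values, method = _as_values(nm)
    if values.shape[1] < 2:
        raise ValueError("CV needs at least 2 samples")
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    keep = mean > 0
    excluded = int((~keep).sum())
    if excluded:
        logger.info("gene_cv: excluded %d genes with zero mean", excluded)
    table = pd.DataFrame({"mean": mean[keep], "sd": sd[keep]})
    table["cv"] = table["sd"] / table["mean"]
    return CVTable(table, method, excluded)


def select_hkg(cvt: CVTable, percentile: float = 2.0) -> HKGSelection:
    """Pick the floor(percentile/100 * N) genes with lowest CV.

    Ties in CV are broken lexicographically by gene ID, so the selection is
    deterministic. 47,613 ranked genes at the 2nd percentile yield 952.
    """
    if not 0 < percentile <= 100:
        raise ValueError(f"percentile must lie in (0, 100], got {percentile}")
    n = len(cvt)
    if n == 0:
        raise ValueError("empty CV table")
    size = math.floor(percentile / 100.0 * n)
    if size < 1:
        raise ValueError(
            f"percentile {percentile} of {n} genes selects 0 genes; use a larger percentile"
        )
    ranked = (
        cvt.table.reset_index()
        .rename(columns={cvt.table.index.name or "index": "gene"})
        .assign(gene=lambda d: d["gene"].astype(str))
        .sort_values(["cv", "gene"], kind="mergesort")
        .head(size)
    )
    cvs = pd.Series(ranked["cv"].to_numpy(), index=ranked["gene"].to_numpy())
    return HKGSelection(cvt.method, float(percentile), list(ranked["gene"]), cvs)


def expression_ratios(
    nm: NormalizedMatrix,
    sel: HKGSelection,
    denominator: str = "set_max",
) -> RatioBinTable:
    """Per-gene mean expression as a fraction of the maximum value.

    ``denominator="set_max"`` divides by the largest normalized value
    attained by any selected gene in any sample; ``"global_max"`` divides by
    the largest value in the whole matrix. Ratios are binned into the fixed
    intervals (0-0.01, ..., 0.80-1.0], closed on the right, with the first
    bin including 0.
    """
    values, _ = _as_values(nm)
    missing = [g for g in sel.genes if g not in values.index]
    if missing:
        raise ValueError(f"selection genes absent from matrix: {missing[:5]}")
    sub = values.loc[sel.genes]
    if denominator == "set_max":
        denom = float(sub.to_numpy().max())
    elif denominator == "global_max":
        denom = float(values.to_numpy().max())
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom <= 0:
        raise ValueError("maximum normalized value is zero; cannot form ratios")
    ratios = sub.mean(axis=1) / denom
    binned = pd.cut(
        ratios,
        bins=list(RATIO_BIN_EDGES),
        labels=list(RATIO_BIN_LABELS),
        include_lowest=True,
        right=True,
    )
    counts = binned.value_counts().reindex(list(RATIO_BIN_LABELS)).fillna(0).astype(int)
    table = pd.DataFrame(
        {"count": counts, "percent": 100.0 * counts / len(ratios)}
    )
    table.index.name = "bin"
    return RatioBinTable(ratios, table, denominator)


def consensus(selections: list[HKGSelection]) -> ConsensusSet:
    """Intersect per-method selections into one universal HKG set.

    An empty intersection is reported with a warning, not an error.
    """
    if len(selections) < 2:
        raise ValueError("consensus needs at least 2 selections")
    common = set(selections[0].genes)
    for sel in selections[1:]:
        common &= set(sel.genes)
    if not common:
        logger.warning("consensus: selections share no gene")
    genes = sorted(common)
    cv_by_method = pd.DataFrame(
        {sel.method: sel.cvs.reindex(genes) for sel in selections}, index=genes
    )
    cv_by_method.index.name = "gene"
    members = frozenset(str(g).strip().upper() for g in genes)
    return ConsensusSet(GeneSet("consensus", members), cv_by_method)
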