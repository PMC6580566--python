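"""Nine RNA-seq count normalization schemes.

Six are per-sample scaling-factor methods — total counts (TC), library size,
upper quartile (UQ), median, trimmed mean of M-values (TMM) and the
median-of-ratios size factors popularised by DESeq — where each sample's
counts are divided by a single positive factor.  The remaining three reshape
values per gene or per distribution: quantile normalization, RPKM and TPM.

Conventions
-----------
* Percentiles use linear interpolation between order statistics (numpy's
  default, the "type 7" rule) and are taken over *all* counts of the
  already-filtered matrix, zeros included.
* UQ/median/TC/library-size factors are each sample's statistic divided by
  the arithmetic mean of that statistic over samples, so factors average
  to one.  TMM factors are rescaled to geometric mean one; median-of-ratios
  factors are left as computed (they are naturally centred).  Downstream
  coefficient-of-variation ranking is invariant to any single global
  rescaling of a factor set, so these centring conventions cannot change
  which genes are selected.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .countio import CountMatrix, GeneLengthTable, LibrarySizeTable

logger = logging.getLogger(__name__)

#: Canonical labels of the nine methods.
METHODS = (
    "library_size",
    "total_count",
    "upper_quartile",
    "median",
    "quantile",
    "rpkm",
    "tpm",
    "tmm",
    "deseq",
)

#: Methods realised as per-sample scaling factors.
FACTOR_METHODS = (
    "total_count",
    "library_size",
    "upper_quartile",
    "median",
    "tmm",
    "deseq",
)

_ALIASES = {
    "tc": "total_count",
    "uq": "upper_quartile",
    "lib_size": "library_size",
    "libsize": "library_size",
}


def canonical_method(method: str) -> str:
    m = method.strip().lower()
    m = _ALIASES.get(m, m)
    if m not in METHODS:
        raise ValueError(f"unknown normalization method {method!r}; choose from {METHODS}")
    return m


@dataclass
class TMMParams:
    """Tuning knobs of the TMM procedure.

    logratio_trim
        Fraction trimmed from each tail of the M (log2 ratio) values, 0.30.
    abs_expr_trim
        Fraction trimmed from each tail of the A (mean log2 abundance)
        values, 0.05.
    weighted
        Use inverse asymptotic (binomial) variance weights for the mean.
    reference_sample
        Sample ID to use as the reference; by default the sample whose
        upper-quartile-to-total fraction is closest to the mean fraction.
    """

    logratio_trim: float = 0.30
    abs_expr_trim: float = 0.05
    weighted: bool = True
    reference_sample: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("logratio_trim", "abs_expr_trim"):
            v = getattr(self, name)
            if not 0 <= v < 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5), got {v}")


@dataclass
class ScalingFactorSet:
    """One positive scale factor per sample, tagged with its method."""

    method: str
    factors: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any() or not np.isfinite(self.factors).all():
            raise ValueError(f"{self.method}: scaling factors must be positive and finite")


@dataclass
class NormalizedMatrix:
    """Real-valued gene-by-sample matrix tagged with its normalization method."""

    values: pd.DataFrame
    method: str

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValueError("normalized values must be finite and nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _resolve_lib_sizes(m: CountMatrix, lib_sizes: Optional[LibrarySizeTable]) -> pd.Series:
    """External aligned-read totals when supplied, else in-matrix column sums."""
    if lib_sizes is None:
        return m.counts.sum(axis=0).astype(float)
    missing = [s for s in m.sample_ids if s not in lib_sizes.sizes.index]
    if missing:
        raise ValueError(f"library size table missing samples: {missing}")
    return lib_sizes.sizes.reindex(m.sample_ids).astype(float)


def _tmm_factors(m: CountMatrix, params: TMMParams) -> pd.Series:
    """Weighted trimmed mean of M-values, two-pass edgeR-style procedure.

    For each non-reference sample j, over genes positive in both j and the
    reference r:

        M_g = log2((K_gj/N_j) / (K_gr/N_r))
        A_g = 1/2 * log2((K_gj/N_j) * (K_gr/N_r))

    The upper and lower ``logratio_trim`` of M and ``abs_expr_trim`` of A are
    discarded, and f_j = 2**(sum w_g M_g / sum w_g) with inverse
    asymptotic-variance weights

        w_g = ((N_j - K_gj)/(N_j K_gj) + (N_r - K_gr)/(N_r K_gr))**-1.

    The returned per-sample factors are f_j * N_j rescaled to geometric
    mean 1.
    """
    counts = m.counts.to_numpy(dtype=float)
    samples = m.sample_ids
    n = len(samples)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("tmm: every sample needs a positive total count")
    # Reference: P75-to-total fraction closest to the mean fraction.
    f75 = np.percentile(counts, 75, axis=0) / lib
    if params.reference_sample is not None:
        if params.reference_sample not in samples:
            raise ValueError(f"tmm reference sample {params.reference_sample!r} not in matrix")
        ref = samples.index(params.reference_sample)
    else:
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
    f = np.ones(n)
    for j in range(n):
        if j == ref:
            continue
        pos = (counts[:, j] > 0) & (counts[:, ref] > 0)
        if not pos.any():
            raise ValueError(
                f"tmm: sample {samples[j]!r} shares no positively expressed gene "
                f"with reference {samples[ref]!r}"
            )
        kj, kr = counts[pos, j], counts[pos, ref]
        pj, pr = kj / lib[j], kr / lib[ref]
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        ng = M.size
        lo_m = np.floor(ng * params.logratio_trim) + 1
        hi_m = ng + 1 - lo_m
        lo_a = np.floor(ng * params.abs_expr_trim) + 1
        hi_a = ng + 1 - lo_a
        rank_m = pd.Series(M).rank(method="average").to_numpy()
        rank_a = pd.Series(A).rank(method="average").to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            f[j] = 1.0
            continue
        if params.weighted:
            w = 1.0 / ((lib[j] - kj) / (lib[j] * kj) + (lib[ref] - kr) / (lib[ref] * kr))
        else:
            w = np.ones(ng)
        f[j] = 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    s = f * lib
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=samples)


def _deseq_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Restricted to genes with strictly positive counts in every sample,
    s_j = median_i( K_ij / geometric-mean_i ).
    """
    counts = m.counts.to_numpy(dtype=float)
    allpos = (counts > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("deseq: no gene has strictly positive counts in all samples")
    sub = counts[allpos]
    log_geo = np.mean(np.log(sub), axis=1)
    ratios = sub / np.exp(log_geo)[:, None]
    return pd.Series(np.median(ratios, axis=0), index=m.sample_ids)


def scaling_factors(
    m: CountMatrix,
    method: str,
    lib_sizes: Optional[LibrarySizeTable] = None,
    tmm_params: Optional[TMMParams] = None,
) -> ScalingFactorSet:
    """Per-sample scale factors for one of the six factor-based methods.

    ``m`` should already have all-zero genes removed. ``lib_sizes`` is only
    consulted by the library-size method (column sums otherwise).
    """
    method = canonical_method(method)
    counts = m.counts.to_numpy(dtype=float)
    if method == "total_count":
        stat = counts.sum(axis=0)
    elif method == "library_size":
        stat = _resolve_lib_sizes(m, lib_sizes).to_numpy()
    elif method == "upper_quartile":
        stat = np.percentile(counts, 75, axis=0)
        if (stat <= 0).any():
            bad = m.sample_ids[int(np.argmax(stat <= 0))]
            raise ValueError(
                f"upper_quartile: 75th percentile is zero for sample {bad!r}; "
                "pre-filter low-count genes"
            )
    elif method == "median":
        stat = np.percentile(counts, 50, axis=0)
        if (stat <= 0).any():
            bad = m.sample_ids[int(np.argmax(stat <= 0))]
            raise ValueError(
                f"median: 50th percentile is zero for sample {bad!r}; "
                "pre-filter low-count genes"
            )
    elif method == "tmm":
        return ScalingFactorSet("tmm", _tmm_factors(m, tmm_params or TMMParams()))
    elif method == "deseq":
        return ScalingFactorSet("deseq", _deseq_factors(m))
    else:
        raise ValueError(f"{method!r} is not a scaling-factor method")
    factors = pd.Series(stat / stat.mean(), index=m.sample_ids)
    return ScalingFactorSet(method, factors)


def apply_scaling(m: CountMatrix, f: ScalingFactorSet) -> NormalizedMatrix:
    """Divide each sample's counts by its scale factor."""
    missing = [s for s in m.sample_ids if s not in f.factors.index]
    if missing:
        raise ValueError(f"scaling factors missing samples: {missing}")
    values = m.counts.astype(float).div(f.factors.reindex(m.sample_ids), axis=1)
    return NormalizedMatrix(values, f.method)


def quantile_normalize(m: CountMatrix) -> NormalizedMatrix:
    """Force every sample onto a common reference distribution.

    The reference is the per-rank mean of the sorted columns; each value is
    replaced by the reference value at its within-column rank.  Ties within
    a column all receive the mean of the reference values over the tied
    ranks, matching the behaviour of limma's ``normalizeQuantiles``.
    """
    if m.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    arr = m.counts.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # average reference values over tied ranks
        ties = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = ties.to_numpy()
    values = pd.DataFrame(out, index=m.counts.index, columns=m.counts.columns)
    return NormalizedMatrix(values, "quantile")


def _lengths_kb(m: CountMatrix, lengths: GeneLengthTable, drop_missing: bool) -> tuple[CountMatrix, pd.Series]:
    missing = [g for g in m.gene_ids if g not in lengths.lengths.index]
    if missing:
        if not drop_missing:
            shown = ", ".join(map(repr, missing[:10]))
            more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
            raise ValueError(f"genes missing from length table: {shown}{more}")
        logger.warning("dropping %d genes with no annotated length", len(missing))
        m = CountMatrix(m.counts.drop(index=missing))
    return m, lengths.lengths.reindex(m.gene_ids).astype(float) / 1000.0


def rpkm(
    m: CountMatrix,
    lengths: GeneLengthTable,
    lib_sizes: Optional[LibrarySizeTable] = None,
    drop_missing: bool = False,
) -> NormalizedMatrix:
    """Reads per kilobase per million mapped reads.

    Depth first (counts over reads-in-millions), then gene length in kb:
    value_ij = K_ij / (N_j / 1e6) / (L_i / 1000).
    """
    m, kb = _lengths_kb(m, lengths, drop_missing)
    depth = _resolve_lib_sizes(m, lib_sizes) / 1e6
    values = m.counts.astype(float).div(depth, axis=1).div(kb, axis=0)
    return NormalizedMatrix(values, "rpkm")


def tpm(
    m: CountMatrix,
    lengths: GeneLengthTable,
    drop_missing: bool = False,
) -> NormalizedMatrix:
    """Transcripts per million: length correction *before* depth correction.

    rate_ij = K_ij / (L_i / 1000); value_ij = rate_ij / sum_i(rate_ij) * 1e6.
    Every column of the result sums to one million.
    """
    m, kb = _lengths_kb(m, lengths, drop_missing)
    rate = m.counts.astype(float).div(kb, axis=0)
    colsum = rate.sum(axis=0)
    if (colsum <= 0).any():
        bad = colsum.index[colsum <= 0][0]
        raise ValueError(f"tpm: sample {bad!r} has no nonzero counts")
    values = rate.div(colsum, axis=1) * 1e6
    return NormalizedMatrix(values, "tpm")


def normalize(
    m: CountMatrix,
    method: str,
    lengths: Optional[GeneLengthTable] = None,
    lib_sizes: Optional[LibrarySizeTable] = None,
    tmm_params: Optional[TMMParams] = None,
) -> NormalizedMatrix:
    """Dispatch to one of the nine normalization methods by label."""
    method = canonical_method(method)
    if method in FACTOR_METHODS:
        return apply_scaling(m, scaling_factors(m, method, lib_sizes, tmm_params))
    if method == "quantile":
        return quantile_normalize(m)
    if method in ("rpkm", "tpm"):
        if lengths is None:
            raise ValueError(f"method {method!r} requires a gene-length table")
        if method == "rpkm":
            return rpkm(m, lengths, lib_sizes)
        return tpm(m, lengths)
    raise AssertionError(f"unhandled method {method}")  # pragma: no cover
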