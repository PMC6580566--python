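import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hkgscout as h
from hkgscout.normalize import FACTOR_METHODS, canonical_method

from conftest import make_counts


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def naive_tmm(counts: np.ndarray, trim_m=0.30, trim_a=0.05) -> np.ndarray:
    """Explicit sort-trim-weight loop; deliberately different code path."""
    counts = counts.astype(float)
    n_samples = counts.shape[1]
    lib = counts.sum(axis=0)
    frac75 = [np.percentile(counts[:, j], 75) / lib[j] for j in range(n_samples)]
    ref = min(range(n_samples), key=lambda j: abs(frac75[j] - np.mean(frac75)))
    factors = []
    for j in range(n_samples):
        if j == ref:
            factors.append(1.0)
            continue
        rows = [
            (math.log2((counts[g, j] / lib[j]) / (counts[g, ref] / lib[ref])),
             0.5 * math.log2((counts[g, j] / lib[j]) * (counts[g, ref] / lib[ref])),
             1.0 / ((lib[j] - counts[g, j]) / (lib[j] * counts[g, j])
                    + (lib[ref] - counts[g, ref]) / (lib[ref] * counts[g, ref])))
            for g in range(counts.shape[0])
            if counts[g, j] > 0 and counts[g, ref] > 0
        ]
        ng = len(rows)

        def kept(values, trim):
            lo = math.floor(ng * trim) + 1
            hi = ng + 1 - lo
            order = sorted(range(ng), key=lambda i: values[i])
            rank = [0.0] * ng
            i = 0
            while i < ng:  # average ranks over ties
                k = i
                while k + 1 < ng and values[order[k + 1]] == values[order[i]]:
                    k += 1
                avg = (i + k) / 2 + 1
                for t in range(i, k + 1):
                    rank[order[t]] = avg
                i = k + 1
            return [lo <= rank[i] <= hi for i in range(ng)]

        keep_m = kept([r[0] for r in rows], trim_m)
        keep_a = kept([r[1] for r in rows], trim_a)
        num = sum(r[2] * r[0] for r, km, ka in zip(rows, keep_m, keep_a) if km and ka)
        den = sum(r[2] for r, km, ka in zip(rows, keep_m, keep_a) if km and ka)
        factors.append(2.0 ** (num / den) if den else 1.0)
    s = np.array(factors) * lib
    return s / np.exp(np.mean(np.log(s)))


def naive_median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """Brute-force size factors, gene by gene."""
    keep = [g for g in range(counts.shape[0]) if all(counts[g] > 0)]
    out = []
    for j in range(counts.shape[1]):
        ratios = []
        for g in keep:
            geo = math.prod(float(c) for c in counts[g]) ** (1.0 / counts.shape[1])
            ratios.append(counts[g, j] / geo)
        out.append(float(np.median(ratios)))
    return np.array(out)


# ---------------------------------------------------------------------------
# factor methods
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("method", FACTOR_METHODS)
def test_identical_columns_give_unit_factors(method):
    m = make_counts(np.tile([[3], [7], [11], [2]], (1, 4)))
    f = h.scaling_factors(m, method)
    np.testing.assert_allclose(f.factors.to_numpy(), 1.0, atol=1e-12)


def test_deseq_worked_example(tiny_counts):
    f = h.scaling_factors(tiny_counts, "deseq")
    np.testing.assert_allclose(
        f.factors.to_numpy(), [1 / math.sqrt(2), math.sqrt(2)], rtol=1e-12
    )


def test_deseq_brute_force_oracle(random_positive_counts):
    for m in random_positive_counts:
        got = h.scaling_factors(m, "deseq").factors.to_numpy()
        want = naive_median_of_ratios(m.counts.to_numpy())
        np.testing.assert_allclose(got, want, rtol=1e-10)


def test_deseq_matches_pydeseq2():
    """Independent cross-check against the reference median-of-ratios code."""
    from pydeseq2.preprocessing import deseq2_norm

    rng = np.random.default_rng(7)
    m = make_counts(rng.negative_binomial(5, 0.02, size=(200, 6)))
    m = h.filter_all_zero_genes(m)
    mine = h.scaling_factors(m, "deseq").factors.to_numpy()
    _, theirs = deseq2_norm(m.counts.T)
    np.testing.assert_allclose(mine, np.asarray(theirs).ravel(), rtol=1e-4)


def test_upper_quartile_worked_example():
    m = make_counts(np.array([[1, 2], [2, 4], [3, 6], [4, 8]]))
    f = h.scaling_factors(m, "upper_quartile")
    # P75 = (3.25, 6.5) under linear interpolation, mean 4.875
    np.testing.assert_allclose(f.factors.to_numpy(), [2 / 3, 4 / 3], rtol=1e-12)


def test_deseq_requires_an_everywhere_positive_gene():
    m = make_counts([[0, 5], [5, 0]])
    with pytest.raises(ValueError, match="deseq"):
        h.scaling_factors(m, "deseq")


def test_median_with_zero_median_instructs_prefiltering():
    m = make_counts([[0, 0], [0, 0], [0, 0], [9, 9]])
    with pytest.raises(ValueError, match="pre-filter"):
        h.scaling_factors(m, "median")


def test_tmm_disjoint_support_is_an_error():
    m = make_counts([[10, 0], [20, 0], [0, 7], [0, 9]])
    with pytest.raises(ValueError, match="tmm"):
        h.scaling_factors(m, "tmm")


def test_tmm_naive_oracle_agreement():
    rng = np.random.default_rng(42)
    for _ in range(8):
        ng = int(rng.integers(50, 501))
        ns = int(rng.integers(3, 13))
        arr = rng.negative_binomial(2, rng.uniform(0.005, 0.05), size=(ng, ns))
        arr[arr.sum(axis=1) == 0, 0] = 1
        m = make_counts(arr)
        got = h.scaling_factors(m, "tmm").factors.to_numpy()
        want = naive_tmm(arr)
        np.testing.assert_allclose(got, want, rtol=1e-10)


def test_tmm_matches_edger():
    """Cross-check against edgeR's calcNormFactors on one seeded matrix."""
    rng = np.random.default_rng(7)
    m = h.filter_all_zero_genes(make_counts(rng.negative_binomial(5, 0.02, size=(200, 6))))
    mine = h.scaling_factors(m, "tmm").factors
    script = (
        "suppressMessages(library(edgeR));"
        "x <- as.matrix(read.delim('counts.tsv', row.names=1, comment.char='#'));"
        "s <- calcNormFactors(x, method='TMM') * colSums(x);"
        "cat(sprintf('%.15g', s / exp(mean(log(s)))), sep='\\n')"
    )
    import tempfile, os

    with tempfile.TemporaryDirectory() as td:
        h.write_table(m, os.path.join(td, "counts.tsv"))
        res = subprocess.run(
            ["Rscript", "-e", script], cwd=td, capture_output=True, text=True, check=True
        )
    theirs = np.array([float(x) for x in res.stdout.split()])
    np.testing.assert_allclose(mine.to_numpy(), theirs, rtol=1e-8)


@given(
    base=st.lists(st.integers(1, 200), min_size=4, max_size=40),
    scales=st.lists(st.integers(1, 9), min_size=2, max_size=6),
)
def test_scale_recovery_property(base, scales):
    """Columns proportional to one base column: every factor method recovers
    the proportionality constants, and scaling equalizes all columns."""
    arr = np.outer(np.array(base), np.array(scales))
    m = make_counts(arr)
    lib = h.LibrarySizeTable(pd.Series(arr.sum(axis=0), index=m.sample_ids))
    for method in FACTOR_METHODS:
        f = h.scaling_factors(m, method, lib_sizes=lib)
        ratio = f.factors.to_numpy() / np.array(scales)
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)
        nm = h.apply_scaling(m, f)
        cols = nm.values.to_numpy()
        np.testing.assert_allclose(cols, cols[:, [0]] * np.ones((1, len(scales))), rtol=1e-9)


def test_apply_scaling_basics(tiny_counts):
    f = h.ScalingFactorSet("total_count", pd.Series([2.0, 1.0], index=["s0", "s1"]))
    nm = h.apply_scaling(tiny_counts, f)
    np.testing.assert_allclose(nm.values["s0"].to_numpy(), [1.0, 2.0, 4.0])
    np.testing.assert_allclose(nm.values["s1"].to_numpy(), [4.0, 8.0, 16.0])
    with pytest.raises(ValueError, match="missing"):
        h.apply_scaling(tiny_counts, h.ScalingFactorSet("total_count", pd.Series([1.0], index=["s0"])))


# ---------------------------------------------------------------------------
# quantile
# ---------------------------------------------------------------------------

class TestQuantile:
    def test_two_column_worked_example(self):
        m = make_counts([[1, 2], [3, 4]])
        out = h.quantile_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out, [[1.5, 1.5], [3.5, 3.5]])

    def test_tie_rule(self):
        m = make_counts([[5, 2], [5, 4]])
        out = h.quantile_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out[:, 0], [4.0, 4.0])
        np.testing.assert_allclose(out[:, 1], [3.5, 4.5])

    def test_identical_columns_are_a_fixed_point(self):
        m = make_counts(np.tile([[4], [1], [9]], (1, 3)))
        out = h.quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.counts.to_numpy())

    def test_columns_share_one_multiset_and_mean(self, random_positive_counts):
        for m in random_positive_counts[:5]:
            vals = h.quantile_normalize(m).values.to_numpy()
            ref = np.sort(vals[:, 0])
            means = vals.mean(axis=0)
            for j in range(vals.shape[1]):
                # ties may redistribute within a column but never off the
                # common reference grid of rank means
                np.testing.assert_allclose(np.sort(vals[:, j]).sum(), ref.sum(), rtol=1e-12)
                np.testing.assert_allclose(means[j], means[0], rtol=1e-12)
            distinct = m.counts.nunique(axis=0).min() == m.shape[0]
            if distinct:
                for j in range(1, vals.shape[1]):
                    np.testing.assert_allclose(np.sort(vals[:, j]), ref, rtol=1e-12)


# ---------------------------------------------------------------------------
# rpkm / tpm
# ---------------------------------------------------------------------------

@pytest.fixture
def lengths2():
    return h.GeneLengthTable(pd.Series({"g0": 2000, "g1": 1000}))


class TestRPKM:
    def test_direct_formula(self, lengths2):
        m = make_counts([[10], [0]])
        lib = h.LibrarySizeTable(pd.Series({"s0": 1_000_000}))
        out = h.rpkm(m, lengths2, lib_sizes=lib).values.to_numpy().ravel()
        np.testing.assert_allclose(out, [5.0, 0.0])

    def test_doubling_depth_halves_column(self, lengths2):
        m = make_counts([[10, 10], [4, 4]])
        lib = h.LibrarySizeTable(pd.Series({"s0": 10**6, "s1": 2 * 10**6}))
        out = h.rpkm(m, lengths2, lib_sizes=lib).values
        np.testing.assert_allclose(out["s0"].to_numpy(), 2 * out["s1"].to_numpy())

    def test_missing_length_lists_genes(self):
        m = make_counts([[1, 2], [3, 4]])
        short = h.GeneLengthTable(pd.Series({"g0": 500}))
        with pytest.raises(ValueError, match="g1"):
            h.rpkm(m, short)
        out = h.rpkm(m, short, drop_missing=True)
        assert out.gene_ids == ["g0"]


class TestTPM:
    def test_worked_example(self, lengths2):
        m = make_counts([[10], [30]])
        out = h.tpm(m, lengths2).values.to_numpy().ravel()
        np.testing.assert_allclose(out, [1e6 * 5 / 35, 1e6 * 30 / 35])

    def test_columns_sum_to_one_million(self, random_positive_counts):
        for m in random_positive_counts[:5]:
            lens = h.GeneLengthTable(pd.Series(np.arange(1, m.shape[0] + 1) * 100, index=m.gene_ids))
            sums = h.tpm(m, lens).values.sum(axis=0).to_numpy()
            np.testing.assert_allclose(sums, 1e6, rtol=1e-9)

    def test_uniform_counts_and_lengths_give_uniform_values(self):
        m = make_counts(np.full((5, 3), 7))
        lens = h.GeneLengthTable(pd.Series(np.full(5, 900), index=m.gene_ids))
        out = h.tpm(m, lens).values.to_numpy()
        np.testing.assert_allclose(out, 1e6 / 5)

    def test_all_zero_column_is_an_error(self, lengths2):
        m = make_counts([[1, 0], [1, 0]])
        with pytest.raises(ValueError, match="tpm"):
            h.tpm(m, lengths2)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def test_dispatch_tc_equals_factor_route(tiny_counts):
    via_dispatch = h.normalize(tiny_counts, "tc")
    via_factors = h.apply_scaling(tiny_counts, h.scaling_factors(tiny_counts, "total_count"))
    np.testing.assert_allclose(
        via_dispatch.values.to_numpy(), via_factors.values.to_numpy()
    )
    assert via_dispatch.method == "total_count"


def test_dispatch_requires_lengths_for_length_methods(tiny_counts):
    for method in ("rpkm", "tpm"):
        with pytest.raises(ValueError, match=method):
            h.normalize(tiny_counts, method)


def test_unknown_method_rejected(tiny_counts):
    with pytest.raises(ValueError, match="unknown"):
        h.normalize(tiny_counts, "housekeeping")


def test_all_nine_methods_share_shape(default_simulation):
    _, m, lengths, lib_sizes, _ = default_simulation
    small = h.CountMatrix(m.counts.iloc[:300])
    for method in h.METHODS:
        nm = h.normalize(small, method, lengths=lengths, lib_sizes=lib_sizes)
        assert nm.values.shape == small.shape
        assert nm.method == canonical_method(method)


def test_gene_row_permutation_equivariance():
    rng = np.random.default_rng(5)
    arr = rng.integers(1, 300, size=(40, 4))
    m = make_counts(arr)
    perm = rng.permutation(40)
    mp = h.CountMatrix(m.counts.iloc[perm])
    lens = h.GeneLengthTable(pd.Series(rng.integers(200, 3000, 40), index=m.gene_ids))
    for method in ("tmm", "deseq", "quantile", "tpm", "upper_quartile"):
        a = h.normalize(m, method, lengths=lens).values.iloc[perm]
        b = h.normalize(mp, method, lengths=lens).values
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-12)
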