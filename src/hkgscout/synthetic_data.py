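"""Negative-binomial count simulator with planted housekeeping genes.

The generator emulates the structure of a bulk RNA-seq study of biopsy
tissue collected under several clinical conditions: a handful of condition
groups with a few samples each, a long-tailed distribution of baseline
expression, heterogeneous sequencing depths, and three gene classes —

* planted housekeeping genes (HKG): identical mean in every group and a
  much lower dispersion than the background, the two constancy properties
  the HKG concept implies;
* differentially expressed (DE) genes: perturbed by a log2 fold change in
  exactly one disease group;
* background genes: constant mean, ordinary biological dispersion.

Counts are drawn as K_ij ~ NB(mean = mu_i * 2^fc_{i,g(j)} * l_j,
dispersion = phi_i), where l_j is the sample's library-depth factor and the
NB variance is mean + phi * mean^2.  Full ground truth is recorded so that
selection pipelines can be scored for recovery.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .countio import CountMatrix, GeneLengthTable, GeneSet, LibrarySizeTable
from .hkg_select import HKGSelection

#: Condition groups mirroring a transplant-biopsy study design: stable
#: function plus five disease categories, five biopsies each.
DEFAULT_GROUPS = ("STA", "ATI", "TCMR", "IFTA", "BKVN", "ISN")


@dataclass
class SimulationConfig:
    """Knobs of the generative model (defaults = the emulated study design).

    n_genes
        Number of simulated transcripts (default 10,000; the emulated assay
        measures ~47,600 expressed transcripts, scaled down for speed).
    group_labels / samples_per_group
        Condition groups and replicates per group (6 x 5 = 30 samples).
    fraction_hkg / fraction_de
        Fractions of genes planted as HKG (0.04) and as DE (0.06).
    hkg_dispersion / base_dispersion
        NB dispersion phi for planted HKG (0.005) and all other genes (0.2).
    de_log2fc_mean / de_log2fc_sd
        |log2 fold change| of DE genes ~ Normal(2, 0.5), sign random.
    libfactor_sigma
        Library-depth factors l_j ~ logNormal(0, 0.3).
    length_log_mean / length_sigma / min_length
        Gene lengths ~ logNormal(log 1500, 0.6) bp, floored at 100.
    mean_log_mean / mean_sigma
        Baseline means mu_i ~ logNormal(log 50, 1.5).
    """

    n_genes: int = 10_000
    group_labels: tuple[str, ...] = DEFAULT_GROUPS
    samples_per_group: int = 5
    fraction_hkg: float = 0.04
    fraction_de: float = 0.06
    hkg_dispersion: float = 0.005
    base_dispersion: float = 0.2
    de_log2fc_mean: float = 2.0
    de_log2fc_sd: float = 0.5
    libfactor_sigma: float = 0.3
    length_log_mean: float = math.log(1500.0)
    length_sigma: float = 0.6
    min_length: int = 100
    mean_log_mean: float = math.log(50.0)
    mean_sigma: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.samples_per_group < 1 or len(self.group_labels) < 1:
            raise ValueError("need at least one group with at least one sample")
        if len(set(self.group_labels)) != len(self.group_labels):
            raise ValueError("group labels must be unique")
        for name in ("fraction_hkg", "fraction_de"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.fraction_hkg + self.fraction_de > 1.0:
            raise ValueError("fraction_hkg + fraction_de must not exceed 1")
        if self.hkg_dispersion <= 0 or self.base_dispersion <= 0:
            raise ValueError("dispersions must be positive")
        if self.hkg_dispersion >= self.base_dispersion:
            raise ValueError("hkg_dispersion must be below base_dispersion")

    @property
    def n_samples(self) -> int:
        return len(self.group_labels) * self.samples_per_group


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    hkg_genes: frozenset
    de_genes: frozenset
    de_log2fc: pd.DataFrame  # DE genes x group labels (0 where unaffected)
    library_factors: pd.Series  # per sample
    baseline_means: pd.Series  # per gene
    gene_lengths: pd.Series  # per gene, bp
    dispersions: pd.Series  # per gene
    seed: int

    @property
    def hkg_gene_set(self) -> GeneSet:
        return GeneSet("true_hkg", frozenset(g.upper() for g in self.hkg_genes))

    @property
    def de_gene_set(self) -> GeneSet:
        return GeneSet("true_de", frozenset(g.upper() for g in self.de_genes))


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, GeneLengthTable, LibrarySizeTable, SimulationTruth]:
    """Draw one dataset (counts, lengths, library sizes) plus its truth.

    The same config and seed always reproduce byte-identical outputs: all
    randomness flows from a single seeded generator in a fixed draw order.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    sample_ids = [
        f"{grp}_{k + 1}" for grp in cfg.group_labels for k in range(cfg.samples_per_group)
    ]
    groups = [grp for grp in cfg.group_labels for _ in range(cfg.samples_per_group)]

    mu = rng.lognormal(cfg.mean_log_mean, cfg.mean_sigma, size=n)
    lengths = np.maximum(
        rng.lognormal(cfg.length_log_mean, cfg.length_sigma, size=n), cfg.min_length
    ).astype(np.int64)
    libfac = rng.lognormal(0.0, cfg.libfactor_sigma, size=cfg.n_samples)

    n_hkg = int(round(cfg.fraction_hkg * n))
    n_de = int(round(cfg.fraction_de * n))
    perm = rng.permutation(n)
    hkg_idx = perm[:n_hkg]
    de_idx = perm[n_hkg : n_hkg + n_de]

    phi = np.full(n, cfg.base_dispersion)
    phi[hkg_idx] = cfg.hkg_dispersion

    # DE genes are disease-specific: each is perturbed in exactly one
    # non-reference group (the first group plays the stable/control role).
    n_groups = len(cfg.group_labels)
    fc = np.zeros((n, n_groups))
    if n_de:
        disease_choices = rng.integers(1, n_groups, size=n_de) if n_groups > 1 else np.zeros(n_de, dtype=int)
        mags = rng.normal(cfg.de_log2fc_mean, cfg.de_log2fc_sd, size=n_de)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        fc[de_idx, disease_choices] = np.abs(mags) * signs

    group_index = np.array([cfg.group_labels.index(g) for g in groups])
    mean_ij = mu[:, None] * (2.0 ** fc[:, group_index]) * libfac[None, :]
    size = 1.0 / phi
    p = size[:, None] / (size[:, None] + mean_ij)
    counts = rng.negative_binomial(size[:, None], p)

    colsum = counts.sum(axis=0)
    # aligned-read totals exceed in-matrix totals (reads mapping outside
    # the quantified transcript set)
    lib_sizes = np.round(colsum * rng.uniform(1.05, 1.15, size=cfg.n_samples)).astype(np.int64)
    lib_sizes = np.maximum(lib_sizes, 1)

    counts_df = pd.DataFrame(counts.astype(np.int64), index=gene_ids, columns=sample_ids)
    de_gene_ids = [gene_ids[i] for i in de_idx]
    truth = SimulationTruth(
        hkg_genes=frozenset(gene_ids[i] for i in hkg_idx),
        de_genes=frozenset(de_gene_ids),
        de_log2fc=pd.DataFrame(
            fc[de_idx], index=de_gene_ids, columns=list(cfg.group_labels)
        ),
        library_factors=pd.Series(libfac, index=sample_ids),
        baseline_means=pd.Series(mu, index=gene_ids),
        gene_lengths=pd.Series(lengths, index=gene_ids),
        dispersions=pd.Series(phi, index=gene_ids),
        seed=cfg.seed,
    )
    return (
        CountMatrix(counts_df),
        GeneLengthTable(pd.Series(lengths, index=gene_ids)),
        LibrarySizeTable(pd.Series(lib_sizes, index=sample_ids)),
        truth,
    )


def recovery_score(truth: SimulationTruth, sel: HKGSelection) -> tuple[float, float]:
    """Score a selection against the planted truth.

    Returns (precision, de_contamination): the fraction of selected genes
    that are planted HKG, and the fraction that are planted DE genes.
    """
    if sel.size == 0:
        raise ValueError("empty selection")
    simulated = set(truth.baseline_means.index)
    unknown = [g for g in sel.genes if g not in simulated]
    if unknown:
        raise ValueError(f"selection contains non-simulated genes: {unknown[:5]}")
    chosen = set(sel.genes)
    precision = len(chosen & truth.hkg_genes) / sel.size
    contamination = len(chosen & truth.de_genes) / sel.size
    return precision, contamination
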