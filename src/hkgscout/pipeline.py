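"""End-to-end orchestration: counts -> normalize (xN) -> CV -> select ->
consensus -> bias/variance -> expression-ratio bins -> overlap report.

`run_all` is the library-level driver behind the ``hkgscout run-all``
subcommand; it returns every intermediate object and writes each as TSV
plus a JSON manifest describing the run.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .countio import (
    CountMatrix,
    GeneLengthTable,
    GeneSet,
    LibrarySizeTable,
    filter_all_zero_genes,
    read_count_matrix,
    read_gene_lengths,
    read_gene_sets,
    read_library_sizes,
    write_table,
)
from .evaluate import bias_variance, cv_summary, overlap_report
from .hkg_select import consensus, expression_ratios, gene_cv, select_hkg
from .normalize import METHODS, TMMParams, canonical_method, normalize
from .synthetic_data import SimulationConfig, recovery_score, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (TOML-loadable)."""

    counts_path: Optional[str] = None
    lengths_path: Optional[str] = None
    lib_sizes_path: Optional[str] = None
    gene_list_paths: tuple[str, ...] = ()
    gene_list_format: str = "plain"
    methods: tuple[str, ...] = METHODS
    percentile: float = 2.0
    overlap_basis: str = "list_size"
    outdir: str = "hkgscout_out"
    seed: int = 0
    simulate: Optional[SimulationConfig] = None
    tmm: TMMParams = field(default_factory=TMMParams)

    def validate(self) -> None:
        if not self.methods:
            raise ValueError("method list is empty")
        self.methods = tuple(canonical_method(m) for m in self.methods)
        if not 0 < self.percentile <= 100:
            raise ValueError(f"percentile must lie in (0, 100], got {self.percentile}")
        if self.counts_path is None and self.simulate is None:
            raise ValueError("either counts_path or a simulation config is required")


@dataclass
class RunResult:
    """In-memory products of `run_all` (everything is also written as TSV)."""

    filtered: CountMatrix
    normalized: dict
    cv_tables: dict
    selections: dict
    consensus: object
    bias_variance: dict
    cv_summaries: dict
    ratio_bins: dict
    overlap: object
    recovery: dict
    manifest: dict


def load_run_config(path) -> RunConfig:
    """Load a RunConfig (and optional [simulate] table) from TOML."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    sim = raw.pop("simulate", None)
    tmm = raw.pop("tmm", None)
    cfg = RunConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
    if sim is not None:
        if "group_labels" in sim:
            sim["group_labels"] = tuple(sim["group_labels"])
        cfg.simulate = SimulationConfig(**sim)
    if tmm is not None:
        cfg.tmm = TMMParams(**tmm)
    return cfg


def _config_hash(cfg: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    blob = json.dumps(cfg, default=default, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_all(cfg: RunConfig) -> RunResult:
    """Execute every pipeline stage and write all outputs under cfg.outdir."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "hkgscout_version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "methods": list(cfg.methods),
        "percentile": cfg.percentile,
        "outputs": [],
    }

    def emit(obj, name: str):
        path = outdir / name
        write_table(obj, path)
        manifest["outputs"].append(name)
        return path

    t0 = time.perf_counter()
    truth = None
    lengths = None
    lib_sizes = None
    if cfg.simulate is not None:
        sim_cfg = cfg.simulate
        sim_cfg.seed = cfg.seed
        counts, lengths, lib_sizes, truth = simulate_dataset(sim_cfg)
        emit(counts, "counts.tsv")
        emit(lengths, "lengths.tsv")
        emit(lib_sizes, "libsizes.tsv")
        truth_df = truth.de_log2fc.copy()
        emit(truth_df, "truth_de_log2fc.tsv")
    else:
        counts = read_count_matrix(cfg.counts_path)
        if cfg.lengths_path:
            lengths = read_gene_lengths(cfg.lengths_path)
        if cfg.lib_sizes_path:
            lib_sizes = read_library_sizes(cfg.lib_sizes_path)
    logger.info("stage load/simulate done in %.2fs", time.perf_counter() - t0)

    filtered = filter_all_zero_genes(counts)
    emit(filtered, "counts_filtered.tsv")

    normalized, cv_tables, selections = {}, {}, {}
    bv, summaries, bins = {}, {}, {}
    for method in cfg.methods:
        t = time.perf_counter()
        if method in ("rpkm", "tpm") and lengths is None:
            raise ValueError(f"method {method!r} requires a gene-length table")
        nm = normalize(filtered, method, lengths=lengths, lib_sizes=lib_sizes, tmm_params=cfg.tmm)
        cvt = gene_cv(nm)
        sel = select_hkg(cvt, cfg.percentile)
        normalized[method], cv_tables[method], selections[method] = nm, cvt, sel
        emit(nm, f"normalized_{method}.tsv")
        emit(cvt, f"cv_{method}.tsv")
        emit(sel, f"hkg_{method}.tsv")
        bv[method] = bias_variance(nm, sel.genes)
        emit(bv[method], f"bias_variance_{method}.tsv")
        summaries[method] = cv_summary(cvt, sel.genes)
        emit(summaries[method], f"cv_summary_{method}.tsv")
        bins[method] = expression_ratios(nm, sel)
        emit(bins[method], f"expression_ratios_{method}.tsv")
        logger.info("stage %s done in %.2fs", method, time.perf_counter() - t)

    cons = None
    if len(selections) >= 2:
        cons = consensus(list(selections.values()))
        emit(cons, "consensus.tsv")

    overlap = None
    if cfg.gene_list_paths:
        lists: list[GeneSet] = []
        for p in cfg.gene_list_paths:
            lists.extend(read_gene_sets(p, cfg.gene_list_format))
        overlap = overlap_report(list(selections.values()), lists, cfg.overlap_basis)
        emit(overlap, "overlap.tsv")

    recovery = {}
    if truth is not None:
        for method, sel in selections.items():
            precision, contamination = recovery_score(truth, sel)
            recovery[method] = {"precision": precision, "de_contamination": contamination}
        with open(outdir / "recovery.json", "w") as fh:
            json.dump(recovery, fh, indent=2, sort_keys=True)
        manifest["outputs"].append("recovery.json")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return RunResult(
        filtered=filtered,
        normalized=normalized,
        cv_tables=cv_tables,
        selections=selections,
        consensus=cons,
        bias_variance=bv,
        cv_summaries=summaries,
        ratio_bins=bins,
        overlap=overlap,
        recovery=recovery,
        manifest=manifest,
    )
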