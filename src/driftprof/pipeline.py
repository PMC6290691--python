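"""Orchestration: configuration, logging, and the end-to-end divergence report.

One flat key=value config file (YAML syntax, namespaced keys such as
``sim.seed`` or ``cnv.overlap_fraction``) drives every stage; all
randomness flows from the single ``seed``.  The report is written both as
JSON (machine-readable, diffable) and TSV.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cnvseg, enrich, kinship, simgenome, vardata, varcompare

log = logging.getLogger("driftprof")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _fraction(lo, hi):
    def check(v):
        if not lo <= v <= hi:
            raise ValueError(f"value {v} outside [{lo}, {hi}]")
        return v
    return check


# key -> (namespace dataclass field, type, optional domain check)
CONFIG_SCHEMA = {
    "seed": ("run", int, None),
    "sim.n_ancestor_variants": ("sim", int, None),
    "sim.known_fraction": ("sim", float, _fraction(0, 1)),
    "sim.n_shared_rare": ("sim", int, None),
    "sim.n_private_a": ("sim", int, None),
    "sim.n_private_b": ("sim", int, None),
    "sim.n_private_coding": ("sim", int, None),
    "sim.n_db_decoys": ("sim", int, None),
    "sim.indel_fraction": ("sim", float, _fraction(0, 1)),
    "sim.depth_mean": ("sim", float, None),
    "sim.gc_bias_amplitude": ("sim", float, None),
    "sim.platform_error_rate": ("sim", float, _fraction(0, 1)),
    "sim.n_genes": ("sim", int, None),
    "sim.ref_panel_size": ("sim", int, None),
    "kinship.min_sites": ("kinship", int, None),
    "cnv.bin_size": ("cnv", int, None),
    "cnv.gain_threshold": ("cnv", float, None),
    "cnv.loss_threshold": ("cnv", float, None),
    "cnv.min_cnv_length": ("cnv", int, None),
    "cnv.overlap_fraction": ("cnv", float, _fraction(0, 1)),
    "cnv.reciprocal": ("cnv", bool, None),
    "cnv.bridge_gap": ("cnv", int, None),
    "cnv.merge_gap": ("cnv", int, None),
    "cnv.min_seg_z": ("cnv", float, None),
    "cascade.min_depth": ("cascade", int, None),
    "cascade.min_quality": ("cascade", float, None),
    "cascade.allele_balance_low": ("cascade", float, _fraction(0, 1)),
    "cascade.allele_balance_high": ("cascade", float, _fraction(0, 1)),
    "enrich.max_rows": ("enrich", int, None),
}


@dataclass
class PipelineConfig:
    seed: int = 0
    sim: simgenome.DriftConfig = None
    cnv: cnvseg.SegmentationConfig = None
    cascade: varcompare.ConcordanceConfig = None
    kinship_min_sites: int = 1000
    enrich_max_rows: int = 10


def validate_config(source) -> PipelineConfig:
    """Parse and validate a flat key=value config (path, YAML text or dict).

    Unknown keys are rejected by name; domain violations raise ValueError.
    """
    if source is None:
        flat = {}
    elif isinstance(source, dict):
        flat = dict(source)
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        flat = yaml.safe_load(text) or {}
        if not isinstance(flat, dict):
            raise ValueError("config must be flat key: value pairs")
    namespaces: dict[str, dict] = {"run": {}, "sim": {}, "kinship": {},
                                   "cnv": {}, "cascade": {}, "enrich": {}}
    for key, value in flat.items():
        if key not in CONFIG_SCHEMA:
            raise ValueError(f"unknown config key {key!r}")
        ns, typ, check = CONFIG_SCHEMA[key]
        if typ in (int, float) and isinstance(value, bool):
            raise ValueError(f"config key {key!r}: expected {typ.__name__}")
        try:
            value = typ(value)
        except (TypeError, ValueError):
            raise ValueError(
                f"config key {key!r}: expected {typ.__name__}, got {value!r}")
        if check:
            try:
                check(value)
            except ValueError as exc:
                raise ValueError(f"config key {key!r}: {exc}") from exc
        namespaces[ns][key.split(".", 1)[-1]] = value

    seed = namespaces["run"].get("seed", 0)
    sim = simgenome.DriftConfig(seed=seed, **namespaces["sim"]).validate()
    cascade_kw = dict(namespaces["cascade"])
    lo = cascade_kw.pop("allele_balance_low", None)
    hi = cascade_kw.pop("allele_balance_high", None)
    cascade = varcompare.ConcordanceConfig(**cascade_kw)
    if lo is not None or hi is not None:
        window = (lo if lo is not None else cascade.allele_balance_window[0],
                  hi if hi is not None else cascade.allele_balance_window[1])
        cascade = dataclasses.replace(cascade, allele_balance_window=window)
    cascade.validate()
    cnv = cnvseg.SegmentationConfig(**namespaces["cnv"]).validate()
    cfg = PipelineConfig(
        seed=seed, sim=sim, cnv=cnv, cascade=cascade,
        kinship_min_sites=namespaces["kinship"].get("min_sites", 1000),
        enrich_max_rows=namespaces["enrich"].get("max_rows", 10))
    log.info("resolved config: %s", flat)
    return cfg


# ---------------------------------------------------------------------------
# end-to-end run
# ---------------------------------------------------------------------------

def _genes_hit_by_calls(calls, gene_models):
    genes = set()
    for call in calls:
        for g in gene_models:
            if g.chrom == call.chrom and call.start < g.end and call.end > g.start:
                genes.add(g.gene_id)
    return genes


def run_all(config: PipelineConfig | None = None, outdir="driftprof_run",
            seed: int | None = None) -> dict:
    """Simulate a paired cohort and run every analysis stage on it.

    Writes report.json / report.tsv plus all intermediate artifacts into
    ``outdir`` and returns the report as a dict.  Bit-identical for a fixed
    seed (timestamps live in a single provenance field).
    """
    config = config or validate_config(None)
    if seed is not None:
        config.seed = seed
        config.sim = dataclasses.replace(config.sim, seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("stage simulate: seed=%d", config.sim.seed)
    cohort = simgenome.simulate_all(config.sim, outdir)
    log.info("stage simulate: %d + %d variant calls, %d panel sites",
             len(cohort.variants_a), len(cohort.variants_b), len(cohort.popdb))

    # --- genetic identity -------------------------------------------------
    matrix = kinship.build_genotype_matrix(
        [r for r in cohort.variants_a if r.genotype in {"het", "hom_alt"}],
        [r for r in cohort.variants_b if r.genotype in {"het", "hom_alt"}],
        cohort.popdb)
    identity = kinship.estimate_ibd(matrix, min_sites=config.kinship_min_sites)
    log.info("stage identity: %d sites used, pi_hat=%.4f",
             identity.n_sites_used, identity.pi_hat)

    # --- coverage + CNV ---------------------------------------------------
    coverage, cnv_calls = {}, {}
    for sample in ("a", "b"):
        cov, ref_cov = simgenome.simulate_coverage(
            cohort.reference, config.sim.cnvs_for(sample), config.sim, sample)
        stats = cnvseg.coverage_stats(cov)
        corrected = cnvseg.gc_correct_and_normalize(cov, ref_cov, config.cnv)
        calls = cnvseg.segment_and_call(corrected, config.cnv)
        coverage[sample] = stats
        cnv_calls[sample] = calls
        log.info("stage cnv-call[%s]: mean %.1fx, %d calls",
                 sample, stats.mean_coverage, len(calls))

    retained_a, removed_a = cnvseg.filter_common(
        cnv_calls["a"], cohort.common_cnv_db, config.cnv)
    retained_b, removed_b = cnvseg.filter_common(
        cnv_calls["b"], cohort.common_cnv_db, config.cnv)
    shared_cnv, a_only, b_only = cnvseg.compare_interval_sets(
        retained_a, retained_b, config.cnv)
    for name, calls in (("cnv_shared", [p[0] for p in shared_cnv]),
                        ("cnv_a_only", a_only), ("cnv_b_only", b_only),
                        ("cnv_common_removed", removed_a + removed_b)):
        vardata.write_bed(calls, outdir / f"{name}.bed")
    log.info("stage cnv-compare: %d shared, %d a_only, %d b_only, %d common",
             len(shared_cnv), len(a_only), len(b_only),
             len(removed_a) + len(removed_b))

    # --- SNV/indel cascade ------------------------------------------------
    cascade = varcompare.run_cascade(
        cohort.variants_a, cohort.variants_b, [cohort.popdb],
        cohort.gene_models, cohort.reference, config.cascade)
    cascade.counts_frame().to_csv(outdir / "cascade_report.tsv", sep="\t",
                                  index=False)
    for sample, genes in (("a", cascade.genes_specific_a),
                          ("b", cascade.genes_specific_b)):
        (outdir / f"specific_genes_{sample}.txt").write_text(
            "\n".join(genes) + ("\n" if genes else ""))
    log.info("stage cascade: terminal specific a=%d b=%d shared=%d",
             len(cascade.specific_a), len(cascade.specific_b),
             len(cascade.shared))

    # --- enrichment -------------------------------------------------------
    enrichment = {}
    gene_lists = {
        "a": set(cascade.genes_specific_a) | _genes_hit_by_calls(
            a_only, cohort.gene_models),
        "b": set(cascade.genes_specific_b) | _genes_hit_by_calls(
            b_only, cohort.gene_models),
    }
    for sample, genes in gene_lists.items():
        if not genes & cohort.pathways.universe:
            log.info("stage enrich[%s]: no genes in universe, skipped", sample)
            enrichment[sample] = []
            continue
        rows = enrich.ora(genes, cohort.pathways)
        enrichment[sample] = [r.to_dict() for r in rows[:config.enrich_max_rows]]
        log.info("stage enrich[%s]: top pathway %s (p=%.3g)", sample,
                 rows[0].pathway_id, rows[0].p_value)

    report = {
        "identity": identity.to_dict() | {"n_sites_dropped": matrix.n_dropped},
        "coverage": {s: dataclasses.asdict(coverage[s]) for s in coverage},
        "cnv": {
            "n_calls": {s: len(cnv_calls[s]) for s in cnv_calls},
            "n_shared": len(shared_cnv), "n_a_only": len(a_only),
            "n_b_only": len(b_only),
            "n_common_removed": {"a": len(removed_a), "b": len(removed_b)},
            "tracks": {name: f"{name}.bed" for name in
                       ("cnv_shared", "cnv_a_only", "cnv_b_only",
                        "cnv_common_removed")},
        },
        "cascade": {
            "stages": [s.to_dict() for s in cascade.stages],
            "class_label": cascade.class_label,
            "genes_specific_a": cascade.genes_specific_a,
            "genes_specific_b": cascade.genes_specific_b,
        },
        "enrichment": enrichment,
        "provenance": {
            "tool": "driftprof", "version": __version__, "seed": config.seed,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
    }
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    flat_rows = [("identity.pi_hat", identity.pi_hat),
                 ("identity.n_sites_used", identity.n_sites_used)]
    flat_rows += [(f"coverage.{s}.mean", coverage[s].mean_coverage)
                  for s in coverage]
    flat_rows += [(f"cnv.{k}", v) for k, v in (
        ("n_shared", len(shared_cnv)), ("n_a_only", len(a_only)),
        ("n_b_only", len(b_only)))]
    last = cascade.stages[-1]
    flat_rows += [("cascade.terminal_specific_a", last.n_specific_a),
                  ("cascade.terminal_specific_b", last.n_specific_b),
                  ("cascade.terminal_shared", last.n_shared)]
    pd.DataFrame(flat_rows, columns=["metric", "value"]).to_csv(
        outdir / "report.tsv", sep="\t", index=False)
    return report
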