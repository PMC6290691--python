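"""Synthetic paired-genome generator with full ground truth.

Emulates the statistical structure of a WGS comparison of two clonally
related cell subpopulations: a shared ancestor variant spectrum in which the
vast majority of variants are catalogued in population databases, a small
set of rare variants (partly shared, partly private), a handful of private
protein-changing variants, planted CNVs (shared, private and
population-common), and ~30x binned coverage with a GC-dependent bias.

Scale is ~10 Mb / 1e5 ancestor variants: the class *ratios* of the real
comparison (millions of known variants, tens of thousands rare, tens
protein-changing) are preserved, not the absolute counts.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import vardata
from .vardata import (CoverageProfile, GeneModel, IntervalCall, VariantRecord,
                      affected_span, normalize_variant)

SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA"}
)

OWNERSHIPS = ("ancestor_known", "ancestor_novel", "shared_rare",
              "private_a", "private_b")

PROTEIN_AFFECTING = frozenset(
    {"missense", "nonsense", "splice", "frameshift", "inframe_indel"})

SEVERITY_ORDER = ("noncoding", "synonymous", "inframe_indel", "missense",
                  "splice", "nonsense", "frameshift")
_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}


@dataclass(frozen=True)
class PlantedCNV:
    chrom: str
    start: int
    end: int
    ploidy: float
    ownership: str  # shared | common | private_a | private_b

    def as_call(self, source: str = "truth") -> IntervalCall:
        call_type = "cnv_gain" if self.ploidy > 2 else "cnv_loss"
        return IntervalCall(self.chrom, self.start, self.end, call_type,
                            self.ploidy, source)


def default_cnv_plants() -> tuple[PlantedCNV, ...]:
    """Realistic mix of planted CNVs, aligned to 1-kb bins.

    Includes one 4-kb shared deletion modelled on the small intragenic
    deletions seen in real drifted subpopulation pairs.
    """
    return (
        PlantedCNV("chr1", 1_000_000, 1_050_000, 3.0, "private_a"),
        PlantedCNV("chr1", 2_000_000, 2_040_000, 1.0, "shared"),
        PlantedCNV("chr1", 3_500_000, 3_530_000, 1.0, "common"),
        PlantedCNV("chr2", 1_200_000, 1_260_000, 3.0, "shared"),
        PlantedCNV("chr2", 2_500_000, 2_504_000, 1.0, "shared"),
        PlantedCNV("chr2", 3_000_000, 3_030_000, 3.0, "common"),
        PlantedCNV("chr2", 4_000_000, 4_050_000, 1.0, "private_b"),
    )


@dataclass
class DriftConfig:
    """All knobs of the paired-genome simulation (one seed drives everything)."""

    seed: int = 0
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000})
    n_ancestor_variants: int = 100_000
    known_fraction: float = 0.99
    n_shared_rare: int = 40
    n_private_a: int = 250
    n_private_b: int = 250
    n_private_coding: int = 3
    n_db_decoys: int = 500
    indel_fraction: float = 0.1
    cnv_plant_list: tuple = field(default_factory=default_cnv_plants)
    depth_mean: float = 30.0
    read_length: int = 100
    gc_bias_amplitude: float = 0.3
    platform_error_rate: float = 1e-3
    n_genes: int = 24
    ref_panel_size: int = 20
    bin_size: int = 1000

    def validate(self) -> "DriftConfig":
        counts = [self.n_ancestor_variants, self.n_shared_rare, self.n_private_a,
                  self.n_private_b, self.n_private_coding, self.n_db_decoys]
        if any(c < 0 for c in counts):
            raise ValueError("negative count in DriftConfig")
        for frac in (self.known_fraction, self.indel_fraction,
                     self.platform_error_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fraction outside [0,1] in DriftConfig")
        if self.n_private_coding > min(self.n_private_a, self.n_private_b) and (
                self.n_private_a or self.n_private_b):
            raise ValueError("n_private_coding exceeds private variant count")
        for cnv in self.cnv_plant_list:
            if cnv.chrom not in self.chrom_lengths:
                raise ValueError(f"planted CNV on unknown chromosome {cnv.chrom}")
            if not 0 <= cnv.start < cnv.end <= self.chrom_lengths[cnv.chrom]:
                raise ValueError("planted CNV outside chromosome bounds")
            if cnv.ownership not in {"shared", "common", "private_a", "private_b"}:
                raise ValueError(f"bad CNV ownership {cnv.ownership!r}")
        return self

    def cnvs_for(self, sample: str) -> list[PlantedCNV]:
        """Planted CNVs carried by descendant 'a' or 'b'."""
        own = {"shared", "common", f"private_{sample}"}
        return [c for c in self.cnv_plant_list if c.ownership in own]


@dataclass
class SimulatedCohort:
    """In-memory output of the generator, with full ground truth."""

    reference: dict
    gene_models: list
    variants_a: list
    variants_b: list
    popdb: dict              # (chrom,pos,ref,alt) -> allele frequency
    common_cnv_db: list      # IntervalCall entries for the common-CNV database
    truth_variants: pd.DataFrame
    truth_cnvs: pd.DataFrame
    pathways: vardata.PathwayDB
    config: DriftConfig


# ---------------------------------------------------------------------------
# reference + gene models
# ---------------------------------------------------------------------------

def _random_sequence(length: int, gc_target_per_bin: np.ndarray,
                     bin_size: int, rng: np.random.Generator) -> bytearray:
    p_gc = np.repeat(gc_target_per_bin, bin_size)[:length]
    is_gc = rng.random(length) < p_gc
    second = rng.random(length) < 0.5
    out = np.where(is_gc, np.where(second, ord("G"), ord("C")),
                   np.where(second, ord("A"), ord("T"))).astype(np.uint8)
    return bytearray(out.tobytes())


def _make_gene(gene_id: str, chrom: str, start: int, strand: str,
               rng: np.random.Generator) -> tuple[GeneModel, str]:
    """A 3-exon gene whose concatenated CDS is a clean ORF (ATG ... stop)."""
    n_aa = int(rng.integers(120, 300))
    cds_len = (n_aa + 2) * 3
    cut1 = int(rng.integers(60, cds_len - 120))
    cut2 = int(rng.integers(cut1 + 60, cds_len - 60))
    sizes = [cut1, cut2 - cut1, cds_len - cut2]
    introns = [int(rng.integers(500, 2000)) for _ in range(2)]
    exons, pos = [], start
    for i, size in enumerate(sizes):
        exons.append((pos, pos + size))
        pos += size + (introns[i] if i < 2 else 0)
    codon_idx = rng.integers(0, len(SENSE_CODONS), size=n_aa)
    cds = "ATG" + "".join(SENSE_CODONS[i] for i in codon_idx) + "TAA"
    model = GeneModel(gene_id, chrom, strand, tuple(exons),
                      exons[0][0], exons[-1][1])
    return model, cds


def simulate_reference(config: DriftConfig):
    """Random reference with sinusoidal+noise GC landscape and >= 20 gene models.

    The GC waveform (amplitude 0.15 around 0.42, period 700 kb) guarantees a
    per-kb GC range of at least 0.2 within each chromosome, so the downstream
    GC correction has a real signal to remove.  Gene CDS regions are
    overwritten with clean ORFs so that consequence classes are well defined.
    """
    config.validate()
    ss = np.random.SeedSequence([config.seed, 11])
    rng_seq, rng_gene = [np.random.default_rng(s) for s in ss.spawn(2)]
    reference: dict[str, str] = {}
    gene_models: list[GeneModel] = []
    chroms = list(config.chrom_lengths)
    genes_per_chrom = -(-config.n_genes // len(chroms))
    gene_no = 0
    for ci, (chrom, length) in enumerate(config.chrom_lengths.items()):
        nbins = -(-length // config.bin_size)
        x = np.arange(nbins) * config.bin_size
        phase = ci * 1.7
        gc = (0.42 + 0.15 * np.sin(2 * np.pi * x / 700_000.0 + phase)
              + rng_seq.normal(0.0, 0.02, size=nbins))
        gc = np.clip(gc, 0.25, 0.65)
        seq = _random_sequence(length, gc, config.bin_size, rng_seq)
        # place genes on an even grid with jitter, alternating strands
        n_here = min(genes_per_chrom, config.n_genes - gene_no)
        if n_here > 0 and length < 20_000:
            raise ValueError(f"{chrom} too short to hold a gene model")
        grid = length // max(n_here, 1)
        for gi in range(n_here):
            start = gi * grid + 50_000 + int(rng_gene.integers(0, 20_000))
            strand = "+" if gene_no % 2 == 0 else "-"
            model, cds = _make_gene(f"g{gene_no + 1:03d}", chrom, start,
                                    strand, rng_gene)
            if model.end > length:
                raise ValueError(f"gene {model.gene_id} falls off {chrom}")
            genomic = cds if strand == "+" else str(Seq(cds).reverse_complement())
            offset = 0
            for s, e in model.exons:
                seq[s:e] = genomic[offset:offset + (e - s)].encode()
                offset += e - s
            gene_models.append(model)
            gene_no += 1
        reference[chrom] = seq.decode()
    return reference, gene_models


# ---------------------------------------------------------------------------
# whole-CDS rebuild consequence oracle
# ---------------------------------------------------------------------------

def _transcript_cds(gene: GeneModel, seq: str) -> str:
    s = "".join(seq[a:b] for a, b in gene.cds_exons)
    return s if gene.strand == "+" else str(Seq(s).reverse_complement())


def classify_by_cds_rebuild(variant: VariantRecord, gene_models: Sequence[GeneModel],
                            reference: Mapping[str, str]) -> str:
    """Consequence class by rebuilding and translating the whole mutant CDS.

    Independent of the codon-local annotator: the mutant chromosome sequence
    is spliced, reverse-complemented where needed, translated in full, and
    the two protein strings compared.  Used to verify planted coding
    variants and as the test oracle for the annotator.
    """
    span = affected_span(variant)
    best = "noncoding"
    for gene in gene_models:
        if gene.chrom != variant.chrom:
            continue
        if span[1] <= gene.start or span[0] >= gene.end:
            continue
        cand = "noncoding"
        hits_splice = any(span[0] < we and span[1] > ws
                          for ws, we in gene.splice_windows())
        in_cds = any(span[0] < e and span[1] > s for s, e in gene.cds_exons)
        if in_cds:
            if variant.variant_class == "indel":
                delta = abs(len(variant.ref) - len(variant.alt))
                cand = "frameshift" if delta % 3 else "inframe_indel"
            else:
                seq = reference[variant.chrom]
                pos0 = variant.pos - 1
                mutant = seq[:pos0] + variant.alt + seq[pos0 + len(variant.ref):]
                ref_prot = str(Seq(_transcript_cds(gene, seq)).translate())
                mut_prot = str(Seq(_transcript_cds(gene, mutant)).translate())
                if mut_prot == ref_prot:
                    cand = "synonymous"
                else:
                    gained_stop = any(m == "*" and r != "*"
                                      for r, m in zip(ref_prot, mut_prot))
                    cand = "nonsense" if gained_stop else "missense"
        if hits_splice and _SEVERITY_RANK["splice"] > _SEVERITY_RANK[cand]:
            cand = "splice"
        if _SEVERITY_RANK[cand] > _SEVERITY_RANK[best]:
            best = cand
    return best


# ---------------------------------------------------------------------------
# variant placement
# ---------------------------------------------------------------------------

_SLOT = 80  # one variant per 80-bp slot keeps planted events from colliding


def _coding_windows(gene_models: Sequence[GeneModel]) -> dict[str, list]:
    wins: dict[str, list] = {}
    for g in gene_models:
        spans = list(g.cds_exons) + list(g.splice_windows())
        wins.setdefault(g.chrom, []).extend(
            (max(0, s - 12), e + 12) for s, e in spans)
    return wins


def _slot_layout(config: DriftConfig, gene_models):
    """Global slot table: (chrom, slot_start) with a coding-touching flag."""
    coding = _coding_windows(gene_models)
    chroms, starts, is_coding = [], [], []
    for chrom, length in config.chrom_lengths.items():
        n = (length - 2 * _SLOT) // _SLOT
        slot_starts = _SLOT + np.arange(n) * _SLOT
        mask = np.zeros(n, dtype=bool)
        for s, e in coding.get(chrom, []):
            lo = max(0, (s - _SLOT - _SLOT) // _SLOT)
            hi = min(n, e // _SLOT + 1)
            mask[lo:hi] = True
        chroms.extend([chrom] * n)
        starts.append(slot_starts)
        is_coding.append(mask)
    return (np.array(chroms), np.concatenate(starts), np.concatenate(is_coding))


def _draw_variant(chrom: str, slot_start: int, reference, rng,
                  indel_fraction: float) -> tuple[int, str, str]:
    seq = reference[chrom]
    pos = int(slot_start + rng.integers(5, 50))  # 1-based; leaves shift room
    ref_base = seq[pos - 1]
    if rng.random() >= indel_fraction:  # SNV
        alt = "ACGT"[int(rng.integers(0, 4))]
        while alt == ref_base:
            alt = "ACGT"[int(rng.integers(0, 4))]
        return pos, ref_base, alt
    size = int(rng.integers(1, 11))
    if rng.random() < 0.5:  # deletion
        return pos, seq[pos - 1: pos + size], ref_base
    ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=size))
    return pos, ref_base, ref_base + ins


def _qc_fields(genotype: str, config: DriftConfig, rng) -> dict:
    depth = max(1, int(rng.poisson(config.depth_mean)))
    if genotype == "het":
        balance = float(np.clip(rng.normal(0.5, 0.05), 0.05, 0.95))
    else:
        balance = float(np.clip(rng.normal(0.98, 0.01), 0.5, 1.0))
    quality = round(float(rng.uniform(40, 80)), 1)
    return {"depth": depth, "allele_balance": balance, "quality": quality}


def _plant_coding_variant(gene: GeneModel, reference, used_pos, rng
                          ) -> tuple[int, str, str, str]:
    """An SNV inside the gene's CDS whose rebuilt protein differs."""
    seq = reference[gene.chrom]
    cds_positions = [p for s, e in gene.cds_exons for p in range(s, e)]
    for _ in range(200):
        pos0 = cds_positions[int(rng.integers(0, len(cds_positions)))]
        if (gene.chrom, pos0 + 1) in used_pos:
            continue
        ref_base = seq[pos0]
        for alt in rng.permutation([b for b in "ACGT" if b != ref_base]):
            cand = VariantRecord(gene.chrom, pos0 + 1, ref_base, str(alt), "het")
            cons = classify_by_cds_rebuild(cand, [gene], reference)
            if cons in {"missense", "nonsense"}:
                return pos0 + 1, ref_base, str(alt), cons
    raise RuntimeError(
        f"could not place an amino-acid-changing variant in {gene.gene_id}")


def apply_platform_noise(variants: Sequence[VariantRecord], rate: float,
                         rng: np.random.Generator) -> list[VariantRecord]:
    """Symmetric site dropout / genotype corruption, one platform's worth."""
    if rate == 0:
        return list(variants)
    out = []
    for rec in variants:
        u = rng.random()
        if u < rate / 2:
            continue  # dropped call
        if u < rate:
            flipped = "hom_alt" if rec.genotype == "het" else "het"
            balance = 0.95 if flipped == "hom_alt" else 0.5
            rec = dataclasses.replace(rec, genotype=flipped,
                                      allele_balance=balance)
        out.append(rec)
    return out


def derive_subpopulations(reference: Mapping[str, str],
                          gene_models: Sequence[GeneModel],
                          config: DriftConfig) -> SimulatedCohort:
    """Drift two descendants from a common ancestor and build all databases."""
    config.validate()
    ss = np.random.SeedSequence([config.seed, 23])
    rng_place, rng_qc, rng_noise_a, rng_noise_b, rng_path = [
        np.random.default_rng(s) for s in ss.spawn(5)]

    chroms_arr, starts_arr, coding_mask = _slot_layout(config, gene_models)
    # ancestor/decoy/shared variants may fall anywhere (their consequence is
    # recorded by the oracle); the non-coding private fillers must avoid gene
    # territory so exactly n_private_coding privates per descendant are coding
    n_priv_noncoding = (max(0, config.n_private_a - config.n_private_coding)
                        + max(0, config.n_private_b - config.n_private_coding))
    n_anywhere = (config.n_ancestor_variants + config.n_db_decoys
                  + config.n_shared_rare)
    noncoding_idx = np.flatnonzero(~coding_mask)
    if len(noncoding_idx) < n_priv_noncoding or \
            len(chroms_arr) < n_priv_noncoding + n_anywhere:
        raise ValueError("genome too small for the requested variant counts")
    priv_picked = rng_place.choice(noncoding_idx, size=n_priv_noncoding,
                                   replace=False)
    remaining = np.setdiff1d(np.arange(len(chroms_arr)), priv_picked)
    any_picked = rng_place.choice(remaining, size=n_anywhere, replace=False)
    picked = np.concatenate([any_picked, priv_picked])

    cursor = 0

    def take(n: int) -> list[tuple[str, int]]:
        nonlocal cursor
        sel = picked[cursor:cursor + n]
        cursor += n
        return [(str(chroms_arr[i]), int(starts_arr[i])) for i in sel]

    used_pos: set[tuple[str, int]] = set()
    truth_rows = []
    variants_a: list[VariantRecord] = []
    variants_b: list[VariantRecord] = []
    popdb: dict[tuple, float] = {}

    def make_record(chrom, slot, label, genotype=None) -> VariantRecord:
        pos, ref, alt = _draw_variant(chrom, slot, reference, rng_place,
                                      config.indel_fraction)
        gt = genotype or ("het" if rng_place.random() < 0.6 else "hom_alt")
        rec = VariantRecord(chrom, pos, ref, alt, gt, sample_label=label,
                            **_qc_fields(gt, config, rng_qc))
        rec = normalize_variant(rec, reference)
        used_pos.add((rec.chrom, rec.pos))
        return rec

    # --- ancestor spectrum: mostly known in the population DB -------------
    n_known = int(round(config.n_ancestor_variants * config.known_fraction))
    for i, (chrom, slot) in enumerate(take(config.n_ancestor_variants)):
        rec = make_record(chrom, slot, "ancestor")
        ownership = "ancestor_known" if i < n_known else "ancestor_novel"
        if ownership == "ancestor_known":
            popdb[rec.key] = float(rng_place.uniform(0.05, 0.95))
        variants_a.append(dataclasses.replace(rec, sample_label="a"))
        variants_b.append(dataclasses.replace(rec, sample_label="b"))
        truth_rows.append(rec.key + (ownership,))

    # --- decoy DB entries: known in the population, absent from both SPs --
    for chrom, slot in take(config.n_db_decoys):
        rec = make_record(chrom, slot, "decoy")
        popdb[rec.key] = float(rng_place.uniform(0.05, 0.95))
        truth_rows.append(rec.key + ("db_decoy",))

    # --- rare variants shared by both descendants -------------------------
    for chrom, slot in take(config.n_shared_rare):
        rec = make_record(chrom, slot, "shared", genotype="het")
        variants_a.append(dataclasses.replace(rec, sample_label="a"))
        variants_b.append(dataclasses.replace(rec, sample_label="b"))
        truth_rows.append(rec.key + ("shared_rare",))

    # --- private variants, including planted protein-changing ones --------
    gene_pool = list(rng_place.permutation(np.arange(len(gene_models))))
    for sample, n_private, target in (
            ("a", config.n_private_a, variants_a),
            ("b", config.n_private_b, variants_b)):
        n_coding = config.n_private_coding if n_private else 0
        for chrom, slot in take(n_private - n_coding):
            rec = make_record(chrom, slot, sample, genotype="het")
            target.append(rec)
            truth_rows.append(rec.key + (f"private_{sample}",))
        for _ in range(n_coding):
            gene = gene_models[gene_pool.pop()]
            pos, ref, alt, _cons = _plant_coding_variant(
                gene, reference, used_pos, rng_place)
            rec = VariantRecord(gene.chrom, pos, ref, alt, "het",
                                sample_label=sample,
                                **_qc_fields("het", config, rng_qc))
            used_pos.add((rec.chrom, rec.pos))
            target.append(rec)
            truth_rows.append(rec.key + (f"private_{sample}",))

    truth = pd.DataFrame(truth_rows,
                         columns=["chrom", "pos", "ref", "alt", "ownership"])
    if truth.duplicated(["chrom", "pos", "ref", "alt"]).any():
        raise RuntimeError("variant key collision in generator")

    # consequence ground truth via the whole-CDS rebuild oracle; variants
    # that cannot touch a gene are noncoding by construction
    coding = _coding_windows(gene_models)
    consequences = []
    for chrom, pos, ref, alt, _own in truth.itertuples(index=False):
        span = (pos - 1, pos - 1 + len(ref) + 1)
        near_gene = any(span[0] < e and span[1] > s
                        for s, e in coding.get(chrom, []))
        if not near_gene:
            consequences.append("noncoding")
            continue
        probe = VariantRecord(chrom, pos, ref, alt, "het")
        consequences.append(
            classify_by_cds_rebuild(probe, gene_models, reference))
    truth["consequence"] = consequences

    # --- platform noise, applied last -------------------------------------
    variants_a = apply_platform_noise(variants_a, config.platform_error_rate,
                                      rng_noise_a)
    variants_b = apply_platform_noise(variants_b, config.platform_error_rate,
                                      rng_noise_b)
    variants_a.sort(key=VariantRecord.sort_key)
    variants_b.sort(key=VariantRecord.sort_key)

    # --- CNV truth and common-CNV database --------------------------------
    cnv_rows = [(c.chrom, c.start, c.end, c.ploidy, c.ownership)
                for c in config.cnv_plant_list]
    truth_cnvs = pd.DataFrame(
        cnv_rows, columns=["chrom", "start", "end", "ploidy", "ownership"])
    common_db = [c.as_call("common_db") for c in config.cnv_plant_list
                 if c.ownership == "common"]
    # decoy database intervals where neither descendant carries a CNV
    for chrom, start in (("chr1", 4_200_000), ("chr2", 200_000)):
        if chrom in config.chrom_lengths and start + 20_000 <= config.chrom_lengths[chrom]:
            common_db.append(IntervalCall(chrom, start, start + 20_000,
                                          "cnv_loss", 1.0, "common_db_decoy"))

    # --- pathway gene sets over the simulated gene universe ---------------
    gene_ids = [g.gene_id for g in gene_models]
    shuffled = list(rng_path.permutation(gene_ids))
    n_paths = max(1, len(gene_ids) // 4)
    sets = {f"PW{i + 1:02d}": frozenset(shuffled[i::n_paths])
            for i in range(n_paths)}
    pathways = vardata.PathwayDB(sets=sets, universe=frozenset(gene_ids))

    return SimulatedCohort(
        reference=dict(reference), gene_models=list(gene_models),
        variants_a=variants_a, variants_b=variants_b, popdb=popdb,
        common_cnv_db=common_db, truth_variants=truth, truth_cnvs=truth_cnvs,
        pathways=pathways, config=config)


# ---------------------------------------------------------------------------
# coverage simulation
# ---------------------------------------------------------------------------

def simulate_coverage(reference: Mapping[str, str], cnvs: Sequence[PlantedCNV],
                      config: DriftConfig, sample_label: str,
                      ) -> tuple[CoverageProfile, CoverageProfile]:
    """Binned read depth for one sample plus its matched reference profile.

    Counts are drawn at the read level: the number of reads in a bin is
    Poisson(depth_mean * bin/read_length * ploidy/2 * gcbias(gc)) and
    raw_depth is the implied mean per-base coverage, so E[raw_depth] =
    depth_mean * ploidy/2 * gcbias with the bin-count noise of real binned
    WGS (~bin/read_length reads per bin, not a single Poisson(depth) draw).
    gcbias = 1 + amplitude * (gc - genome_mean_gc) / genome_mean_gc.  The
    reference coverage profile emulates a population panel: the mean of
    ``ref_panel_size`` independent diploid draws under the same bias.
    """
    config.validate()
    ss = np.random.SeedSequence(
        [config.seed, 37, sum(ord(c) for c in sample_label)])
    rng_s, rng_r = [np.random.default_rng(s) for s in ss.spawn(2)]
    frames = []
    for chrom, length in config.chrom_lengths.items():
        nbins = -(-length // config.bin_size)
        starts = np.arange(nbins) * config.bin_size
        ends = np.minimum(starts + config.bin_size, length)
        frames.append(pd.DataFrame(
            {"chrom": chrom, "bin_start": starts, "bin_end": ends}))
    bins = pd.concat(frames, ignore_index=True)

    profile = CoverageProfile(bins.assign(raw_depth=0.0), config.bin_size)
    vardata.attach_gc(profile, reference)
    gc = profile.bins["gc_fraction"].to_numpy()
    mean_gc = float(np.nanmean(gc))
    gcbias = 1.0 + config.gc_bias_amplitude * (gc - mean_gc) / mean_gc
    gcbias = np.maximum(gcbias, 0.0)

    ploidy = np.full(len(profile.bins), 2.0)
    starts = profile.bins["bin_start"].to_numpy()
    ends = profile.bins["bin_end"].to_numpy()
    chrom_col = profile.bins["chrom"].to_numpy()
    for cnv in cnvs:
        ov = (np.minimum(ends, cnv.end) - np.maximum(starts, cnv.start)).clip(min=0)
        frac = np.where(chrom_col == cnv.chrom, ov / (ends - starts), 0.0)
        ploidy += (cnv.ploidy - 2.0) * frac

    reads_per_bin = (ends - starts) / config.read_length
    lam = config.depth_mean * (ploidy / 2.0) * gcbias * reads_per_bin
    sample_bins = profile.bins.copy()
    sample_bins["raw_depth"] = rng_s.poisson(lam) / reads_per_bin
    lam_ref = config.depth_mean * gcbias * reads_per_bin
    k = max(1, config.ref_panel_size)
    ref_bins = profile.bins.copy()
    ref_bins["raw_depth"] = rng_r.poisson(lam_ref * k) / (k * reads_per_bin)
    return (CoverageProfile(sample_bins, config.bin_size),
            CoverageProfile(ref_bins, config.bin_size))


# ---------------------------------------------------------------------------
# top-level: write everything to a directory
# ---------------------------------------------------------------------------

def simulate_all(config: DriftConfig, outdir) -> SimulatedCohort:
    """Run the full generator and write the standard file set into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference, gene_models = simulate_reference(config)
    cohort = derive_subpopulations(reference, gene_models, config)

    vardata.write_fasta(reference, outdir / "reference.fa")
    vardata.write_gene_models(gene_models, outdir / "genes.bed12")
    vardata.write_vcf(
        [r for r in cohort.variants_a if r.genotype in {"het", "hom_alt"}],
        outdir / "a.vcf", sample_name="a", contigs=config.chrom_lengths)
    vardata.write_vcf(
        [r for r in cohort.variants_b if r.genotype in {"het", "hom_alt"}],
        outdir / "b.vcf", sample_name="b", contigs=config.chrom_lengths)
    vardata.write_sites_vcf(cohort.popdb, outdir / "popdb.vcf",
                            contigs=config.chrom_lengths)
    vardata.write_bed(cohort.common_cnv_db, outdir / "common_cnv.bed")
    for sample in ("a", "b"):
        cov, ref_cov = simulate_coverage(reference, config.cnvs_for(sample),
                                         config, sample)
        vardata.write_bedgraph(cov, outdir / f"{sample}.cov.bedgraph")
        vardata.write_bedgraph(ref_cov, outdir / f"{sample}.ref.bedgraph")
    vardata.write_gmt(cohort.pathways, outdir / "pathways.gmt")

    truth_v = cohort.truth_variants.assign(kind="variant")
    truth_c = cohort.truth_cnvs.assign(kind="cnv")
    truth = pd.concat([truth_v, truth_c], ignore_index=True)
    cols = ["kind", "chrom", "pos", "ref", "alt", "ownership", "consequence",
            "start", "end", "ploidy"]
    for c in cols:
        if c not in truth.columns:
            truth[c] = np.nan
    truth[cols].to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return cohort
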