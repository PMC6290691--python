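"""The SNV/indel reduction cascade.

Millions of raw calls per genome are reduced to a handful of candidate
variants in four moves: (1) per-record quality concordance filtering
(depth, site quality, het allele balance) to suppress platform-specific
artifacts; (2) subtraction of variants catalogued in population databases
("somatic" here means *absent from all consulted databases*, following the
cell-line usage, not the tumor-normal one — the report labels the class
``not_in_databases`` with ``somatic`` as an alias); (3) allele-exact
partition into shared and subpopulation-specific sets; (4) protein
consequence annotation, keeping only amino-acid / splice-affecting classes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from . import vardata
from .vardata import GeneModel, VariantRecord, affected_span

SEVERITY_ORDER = ("noncoding", "synonymous", "inframe_indel", "missense",
                  "splice", "nonsense", "frameshift")
_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

PROTEIN_AFFECTING = frozenset(
    {"missense", "nonsense", "splice", "frameshift", "inframe_indel"})


@dataclass
class ConcordanceConfig:
    """Cross-platform concordance filter thresholds (conventional 30x-WGS values)."""

    min_depth: int = 10
    allele_balance_window: tuple[float, float] = (0.2, 0.8)
    min_quality: float = 30.0
    require_normalized: bool = True

    def validate(self) -> "ConcordanceConfig":
        lo, hi = self.allele_balance_window
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("allele_balance_window must satisfy 0 <= lo < hi <= 1")
        if self.min_depth < 0:
            raise ValueError("negative min_depth")
        return self


@dataclass
class StageCount:
    stage_name: str
    n_a: int
    n_b: int
    n_shared: int | None = None
    n_specific_a: int | None = None
    n_specific_b: int | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class FilterCascadeReport:
    """Counts surviving each cascade stage plus terminal variant/gene lists."""

    stages: list
    specific_a: list          # protein-affecting records private to A
    specific_b: list
    shared: list              # protein-affecting records present in both
    genes_specific_a: list
    genes_specific_b: list
    class_label: str = "not_in_databases"   # alias: "somatic"

    def counts_frame(self):
        import pandas as pd
        return pd.DataFrame([s.to_dict() for s in self.stages])


# ---------------------------------------------------------------------------
# stage 2: concordance filter
# ---------------------------------------------------------------------------

def concordance_filter(varset: Sequence[VariantRecord],
                       config: ConcordanceConfig | None = None):
    """Keep records passing depth/quality/het-allele-balance rules.

    Returns (kept, dropped) with each dropped record paired with the first
    failing rule name: "depth", "quality" or "allele_balance".
    """
    config = (config or ConcordanceConfig()).validate()
    lo, hi = config.allele_balance_window
    kept, dropped = [], []
    for rec in varset:
        if rec.depth is None or rec.depth < config.min_depth:
            dropped.append((rec, "depth"))
        elif rec.quality is None or rec.quality < config.min_quality:
            dropped.append((rec, "quality"))
        elif (rec.genotype == "het" and rec.allele_balance is not None
              and not lo <= rec.allele_balance <= hi):
            dropped.append((rec, "allele_balance"))
        else:
            kept.append(rec)
    return kept, dropped


# ---------------------------------------------------------------------------
# stage 3: database subtraction
# ---------------------------------------------------------------------------

def subtract_known(varset: Sequence[VariantRecord],
                   known_dbs: Sequence[Iterable[tuple]]):
    """Partition into (somatic, known) by allele-exact database lookup.

    A variant is known iff some database holds the identical
    (chrom, pos, ref, alt); a different alt allele at a known site stays
    somatic.  Both sides must be normalized identically beforehand.
    """
    keysets = [db if isinstance(db, (set, frozenset, dict)) else set(db)
               for db in known_dbs]
    somatic, known = [], []
    for rec in varset:
        (known if any(rec.key in db for db in keysets) else somatic).append(rec)
    return somatic, known


# ---------------------------------------------------------------------------
# stage 4: shared/private partition
# ---------------------------------------------------------------------------

def partition_shared_private(somatic_a: Sequence[VariantRecord],
                             somatic_b: Sequence[VariantRecord]):
    """Allele-exact set logic: (shared pairs, specific_a, specific_b)."""
    by_key_b = {r.key: r for r in somatic_b}
    keys_a = {r.key for r in somatic_a}
    shared = [(r, by_key_b[r.key]) for r in somatic_a if r.key in by_key_b]
    specific_a = [r for r in somatic_a if r.key not in by_key_b]
    specific_b = [r for r in somatic_b if r.key not in keys_a]
    return shared, specific_a, specific_b


# ---------------------------------------------------------------------------
# consequence annotation (codon-local)
# ---------------------------------------------------------------------------

def _cds_genomic_positions(gene: GeneModel) -> list[int]:
    """Genomic positions of the CDS in transcript (5'->3') order."""
    positions = [p for s, e in gene.cds_exons for p in range(s, e)]
    return positions if gene.strand == "+" else positions[::-1]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _annotate_snv_in_cds(pos0: int, alt_base: str, gene: GeneModel,
                         seq: str) -> str:
    """Classify one substituted base by translating only its codon."""
    tx_positions = _cds_genomic_positions(gene)
    tx_index = tx_positions.index(pos0)
    codon_start = tx_index - tx_index % 3
    codon_pos = tx_positions[codon_start:codon_start + 3]

    def base_at(p: int, substituted: bool) -> str:
        b = alt_base if (substituted and p == pos0) else seq[p]
        return b if gene.strand == "+" else b.translate(_COMPLEMENT)

    ref_codon = "".join(base_at(p, False) for p in codon_pos)
    alt_codon = "".join(base_at(p, True) for p in codon_pos)
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == ref_aa:
        return "synonymous"
    if alt_aa == "*":
        return "nonsense"
    return "missense"


def annotate_consequence(variant: VariantRecord,
                         gene_models: Sequence[GeneModel],
                         reference: Mapping[str, str]) -> str:
    """Consequence class of one normalized variant against a gene model set.

    Splice = any affected base within 2 bp of an exon-intron boundary on the
    intron side.  Coding SNVs translate the affected codon only; indels in
    CDS are frameshift/inframe by length; block substitutions are treated as
    SNV sets of their constituent positions.  Across multiple transcripts
    the most severe class wins (frameshift > nonsense > splice > missense >
    inframe_indel > synonymous > noncoding).
    """
    seq = reference[variant.chrom]
    if variant.pos - 1 + len(variant.ref) > len(seq):
        raise ValueError(f"variant at {variant.chrom}:{variant.pos} "
                         "outside reference bounds")
    span = affected_span(variant)
    best = "noncoding"
    for gene in gene_models:
        if gene.chrom != variant.chrom or span[1] <= gene.start or span[0] >= gene.end:
            continue
        cand = "noncoding"
        in_cds = any(span[0] < e and span[1] > s for s, e in gene.cds_exons)
        if in_cds:
            if variant.variant_class == "indel":
                delta = abs(len(variant.ref) - len(variant.alt))
                cand = "frameshift" if delta % 3 else "inframe_indel"
            else:
                pos0 = variant.pos - 1
                cds_positions = set(_cds_genomic_positions(gene))
                for offset, (rb, ab) in enumerate(zip(variant.ref, variant.alt)):
                    if rb == ab or (pos0 + offset) not in cds_positions:
                        continue
                    c = _annotate_snv_in_cds(pos0 + offset, ab, gene, seq)
                    if _RANK[c] > _RANK[cand]:
                        cand = c
        if any(span[0] < we and span[1] > ws for ws, we in gene.splice_windows()):
            if _RANK["splice"] > _RANK[cand]:
                cand = "splice"
        if _RANK[cand] > _RANK[best]:
            best = cand
    return best


# ---------------------------------------------------------------------------
# the full cascade
# ---------------------------------------------------------------------------

def _load(varset, reference, label) -> list[VariantRecord]:
    if isinstance(varset, (str, bytes)) or hasattr(varset, "__fspath__"):
        varset = vardata.read_vcf(varset, sample_label=label)
    records = [r for r in varset if r.genotype in {"het", "hom_alt"}]
    normalized = [vardata.normalize_variant(r, reference) for r in records]
    seen, unique = set(), []
    for r in sorted(normalized, key=VariantRecord.sort_key):
        if r.key not in seen:
            seen.add(r.key)
            unique.append(r)
    return unique


def run_cascade(varset_a, varset_b, known_dbs, gene_models, reference,
                concordance: ConcordanceConfig | None = None
                ) -> FilterCascadeReport:
    """Run all cascade stages and report per-stage counts and gene lists.

    ``varset_a`` / ``varset_b`` may be VCF paths or VariantRecord sequences;
    ``known_dbs`` is a list of key sets / dicts (e.g. from
    :func:`vardata.read_vcf_sites`).
    """
    a = _load(varset_a, reference, "a")
    b = _load(varset_b, reference, "b")
    stages = [StageCount("read_normalize", len(a), len(b))]

    a, _ = concordance_filter(a, concordance)
    b, _ = concordance_filter(b, concordance)
    stages.append(StageCount("concordance_filter", len(a), len(b)))

    somatic_a, _ = subtract_known(a, known_dbs)
    somatic_b, _ = subtract_known(b, known_dbs)
    stages.append(StageCount("not_in_databases", len(somatic_a), len(somatic_b)))

    shared, spec_a, spec_b = partition_shared_private(somatic_a, somatic_b)
    stages.append(StageCount("shared_private_partition",
                             len(somatic_a), len(somatic_b),
                             n_shared=len(shared), n_specific_a=len(spec_a),
                             n_specific_b=len(spec_b)))

    def protein_affecting(records):
        out = []
        for rec in records:
            cons = annotate_consequence(rec, gene_models, reference)
            if cons in PROTEIN_AFFECTING:
                out.append((rec, cons))
        return out

    term_a = protein_affecting(spec_a)
    term_b = protein_affecting(spec_b)
    term_shared = protein_affecting([ra for ra, _rb in shared])
    stages.append(StageCount("protein_affecting",
                             len(term_a), len(term_b),
                             n_shared=len(term_shared),
                             n_specific_a=len(term_a),
                             n_specific_b=len(term_b)))

    def gene_list(terminal):
        genes = set()
        for rec, _cons in terminal:
            span = affected_span(rec)
            for g in gene_models:
                if g.chrom == rec.chrom and span[0] < g.end and span[1] > g.start:
                    genes.add(g.gene_id)
        return sorted(genes)

    return FilterCascadeReport(
        stages=stages,
        specific_a=term_a, specific_b=term_b, shared=term_shared,
        genes_specific_a=gene_list(term_a), genes_specific_b=gene_list(term_b))
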