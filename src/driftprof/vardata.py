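"""Domain types and readers/writers for the standard formats the pipeline touches.

Coordinate conventions: every interval type (CNV/SV calls, gene models,
coverage bins) is 0-based half-open.  :class:`VariantRecord.pos` is the
1-based position of the first reference base, i.e. the VCF convention; the
consequence annotator converts once at its boundary.
"""
from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

BASES = frozenset("ACGT")
GENOTYPES = frozenset({"hom_ref", "het", "hom_alt", "missing"})
VARIANT_CLASSES = frozenset({"snv", "indel", "block_substitution"})
CNV_TYPES = frozenset({"cnv_gain", "cnv_loss"})
SV_TYPES = frozenset({"deletion", "duplication", "inversion"})
CALL_TYPES = CNV_TYPES | SV_TYPES

MAX_INDEL_ALLELE = 51  # anchor base + 50 bp inserted/deleted run
MIN_CNV_LENGTH = 1000  # strictly-greater rule
MIN_SV_LENGTH = 1000
MAX_SV_LENGTH = 3_000_000


class FormatError(ValueError):
    """Malformed input file; readers reject rather than repair."""


# ---------------------------------------------------------------------------
# chromosome naming
# ---------------------------------------------------------------------------

def canonical_chrom(name: str, style: str = "chr") -> str:
    """Normalize chromosome name dialects ('chr1' vs '1') to one style."""
    base = name[3:] if name.lower().startswith("chr") else name
    if style == "chr":
        return "chr" + base
    if style == "plain":
        return base
    raise ValueError(f"unknown chromosome style {style!r}")


def chrom_sort_key(name: str):
    base = name[3:] if name.lower().startswith("chr") else name
    return (0, int(base)) if base.isdigit() else (1, base)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One normalized small-variant call (SNV/indel/block substitution)."""

    chrom: str
    pos: int  # 1-based position of the first reference base
    ref: str
    alt: str
    genotype: str
    depth: int | None = None
    allele_balance: float | None = None
    quality: float | None = None
    sample_label: str = ""

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele at {self.chrom}:{self.pos}")
        if set(self.ref) - BASES or set(self.alt) - BASES:
            raise ValueError(
                f"non-ACGT allele {self.ref}>{self.alt} at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"bad genotype {self.genotype!r}")
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")
        if self.depth is not None and self.depth < 0:
            raise ValueError("negative depth")
        if self.allele_balance is not None and not 0.0 <= self.allele_balance <= 1.0:
            raise ValueError("allele_balance outside [0,1]")
        if (len(self.ref) != len(self.alt)
                and max(len(self.ref), len(self.alt)) > MAX_INDEL_ALLELE):
            raise ValueError(
                f"indel longer than 50 bp at {self.chrom}:{self.pos}")

    @property
    def variant_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "snv"
        if len(self.ref) == len(self.alt):
            return "block_substitution"
        return "indel"

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Allele-exact identity used throughout the comparison cascade."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def dosage(self) -> float:
        return {"hom_ref": 0, "het": 1, "hom_alt": 2, "missing": float("nan")}[self.genotype]

    def sort_key(self):
        return (chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)


@dataclass(frozen=True, slots=True)
class IntervalCall:
    """A CNV or SV call as a 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    call_type: str
    ploidy: float = 2.0
    source_label: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"end <= start for {self.chrom}:{self.start}-{self.end}")
        if self.call_type not in CALL_TYPES:
            raise ValueError(f"unknown call_type {self.call_type!r}")
        if self.ploidy < 0:
            raise ValueError("negative ploidy")
        n = len(self)
        if self.call_type == "cnv_gain" and self.ploidy <= 2:
            raise ValueError("cnv_gain requires ploidy > 2")
        if self.call_type == "cnv_loss" and self.ploidy >= 2:
            raise ValueError("cnv_loss requires ploidy < 2")
        if self.call_type in CNV_TYPES and n <= MIN_CNV_LENGTH:
            raise ValueError(f"CNV call length {n} not > {MIN_CNV_LENGTH}")
        if self.call_type in SV_TYPES and not MIN_SV_LENGTH <= n <= MAX_SV_LENGTH:
            raise ValueError(f"SV call length {n} outside [1 kb, 3 Mb]")

    def __len__(self) -> int:
        return self.end - self.start

    def sort_key(self):
        return (chrom_sort_key(self.chrom), self.start, self.end, self.call_type)


@dataclass(frozen=True)
class GeneModel:
    """Minimal transcript model: exon chain plus CDS bounds (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")
        ex = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", ex)
        if not ex:
            raise ValueError(f"{self.gene_id}: no exons")
        for s, e in ex:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon {s}-{e}")
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
        if not (ex[0][0] <= self.cds_start < self.cds_end <= ex[-1][1]):
            raise ValueError(f"{self.gene_id}: CDS outside exon span")
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_exons(self) -> tuple[tuple[int, int], ...]:
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 < e2:
                out.append((s2, e2))
        return tuple(out)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_exons)

    def splice_windows(self) -> tuple[tuple[int, int], ...]:
        """2-bp intronic windows flanking every internal exon boundary."""
        wins = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            wins.append((e1, min(e1 + 2, s2)))
            wins.append((max(s2 - 2, e1), s2))
        return tuple(wins)


@dataclass
class CoverageProfile:
    """Per-bin read depth with GC fraction, before/after correction.

    ``bins`` columns: chrom, bin_start, bin_end, raw_depth, gc_fraction and,
    after GC correction + normalization, corrected_ratio (NaN = masked).
    """

    bins: pd.DataFrame
    bin_size: int = 1000

    def __post_init__(self):
        df = self.bins
        required = {"chrom", "bin_start", "bin_end", "raw_depth"}
        if missing := required - set(df.columns):
            raise ValueError(f"coverage profile missing columns {sorted(missing)}")
        if "gc_fraction" not in df.columns:
            df["gc_fraction"] = np.nan
        df = df.sort_values(
            ["chrom", "bin_start"],
            key=lambda c: c.map(chrom_sort_key) if c.name == "chrom" else c,
        ).reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            starts, ends = sub["bin_start"].to_numpy(), sub["bin_end"].to_numpy()
            if (ends <= starts).any():
                raise FormatError(f"{chrom}: bin end <= start")
            if (starts[1:] < ends[:-1]).any():
                raise FormatError(f"{chrom}: overlapping bins")
            if (starts % self.bin_size).any():
                raise FormatError(f"{chrom}: bin_start not a multiple of bin_size")
            widths = ends - starts
            if (widths[:-1] != self.bin_size).any() or widths[-1] > self.bin_size:
                raise FormatError(f"{chrom}: non-uniform bin width")
        self.bins = df

    @property
    def has_corrected(self) -> bool:
        return "corrected_ratio" in self.bins.columns

    def same_binning(self, other: "CoverageProfile") -> bool:
        a, b = self.bins, other.bins
        return (self.bin_size == other.bin_size and len(a) == len(b)
                and (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
                and (a["bin_start"].to_numpy() == b["bin_start"].to_numpy()).all())


@dataclass(frozen=True)
class PathwayDB:
    """Named gene sets plus the annotatable gene universe."""

    sets: Mapping[str, frozenset]
    universe: frozenset

    def __post_init__(self):
        object.__setattr__(
            self, "sets", {k: frozenset(v) for k, v in self.sets.items()})
        object.__setattr__(self, "universe", frozenset(self.universe))
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"pathway {name!r} is empty")
            if genes - self.universe:
                raise ValueError(f"pathway {name!r} has genes outside the universe")


# ---------------------------------------------------------------------------
# variant normalization
# ---------------------------------------------------------------------------

def normalize_variant(record: VariantRecord, reference: Mapping[str, str]) -> VariantRecord:
    """Left-align and trim a variant against the reference (vt-style).

    Idempotent; indels come out anchored on one shared leading base.
    """
    try:
        seq = reference[record.chrom]
    except KeyError:
        raise ValueError(f"chromosome {record.chrom!r} not in reference") from None
    pos, ref, alt = record.pos, record.ref, record.alt
    observed = seq[pos - 1: pos - 1 + len(ref)].upper()
    if observed != ref:
        raise ValueError(
            f"reference mismatch at {record.chrom}:{pos}: "
            f"expected {ref!r}, reference has {observed!r}")
    while True:
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if (len(ref) == 1 or len(alt) == 1) and pos == 1:
                break  # anchored at the contig start; cannot shift further
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                pos -= 1
                b = seq[pos - 1].upper()
                ref, alt = b + ref, b + alt
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (pos, ref, alt) == (record.pos, record.ref, record.alt):
        return record
    return replace(record, pos=pos, ref=ref, alt=alt)


def affected_span(record: VariantRecord) -> tuple[int, int]:
    """0-based half-open genomic span whose bases the variant touches.

    Substitutions cover their reference bases; anchored deletions cover the
    deleted run (excluding the anchor); insertions cover the two bases
    flanking the insertion point.
    """
    pos0 = record.pos - 1
    lr, la = len(record.ref), len(record.alt)
    if lr == la:
        return (pos0, pos0 + lr)
    if lr > la:  # deletion
        return (pos0 + 1, pos0 + lr)
    return (pos0, pos0 + 2)  # insertion junction


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _genotype_from_dosage(dosage: int | None) -> str:
    if dosage is None:
        return "missing"
    return {0: "hom_ref", 1: "het", 2: "hom_alt"}[dosage]


def read_vcf(path, sample_label: str = "", chrom_style: str = "chr") -> list[VariantRecord]:
    """Read a VCF into biallelic :class:`VariantRecord`s, splitting multi-allelics.

    Records come back sorted by (chrom, pos, ref, alt).  Not yet normalized
    against a reference; use :func:`normalize_variant` for that.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    if not samples:
        raise FormatError(f"{path}: no sample column with GT field")
    sample = sample_label if sample_label in samples else samples[0]
    if len(samples) > 1 and sample_label not in samples:
        raise FormatError(
            f"{path}: multi-sample VCF, sample {sample_label!r} not found")
    records: list[VariantRecord] = []
    for lineno, rec in enumerate(vf, start=1):
        call = rec.samples[sample]
        gt = call.get("GT")
        if gt is None or len(gt) == 0:
            raise FormatError(
                f"{path} record {lineno} ({rec.chrom}:{rec.pos}): no GT field")
        dp = call.get("DP")
        ad = call.get("AD")
        alts = rec.alts or ()
        for ai, alt in enumerate(alts, start=1):
            if alt is None or set(str(alt)) - BASES:
                raise FormatError(
                    f"{path} record {lineno} ({rec.chrom}:{rec.pos}): "
                    f"unsupported ALT allele {alt!r}")
            dosage = None if None in gt else sum(1 for a in gt if a == ai)
            balance = None
            if ad is not None and None not in ad and sum(ad) > 0:
                balance = ad[ai] / sum(ad)
            try:
                records.append(VariantRecord(
                    chrom=canonical_chrom(rec.chrom, chrom_style),
                    pos=rec.pos,
                    ref=str(rec.ref),
                    alt=str(alt),
                    genotype=_genotype_from_dosage(dosage),
                    depth=int(dp) if dp is not None else None,
                    allele_balance=balance,
                    quality=float(rec.qual) if rec.qual is not None else None,
                    sample_label=sample_label or sample,
                ))
            except ValueError as exc:
                raise FormatError(f"{path} record {lineno}: {exc}") from exc
    records.sort(key=VariantRecord.sort_key)
    return records


def read_vcf_sites(path, chrom_style: str = "chr") -> dict[tuple, float | None]:
    """Read site-allele keys (and AF, when present) from a site-only VCF.

    Used for population "known variant" databases and allele-frequency panels.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    sites: dict[tuple, float | None] = {}
    for rec in vf:
        afs = rec.info.get("AF")
        if afs is not None and not isinstance(afs, (tuple, list)):
            afs = (afs,)
        for ai, alt in enumerate(rec.alts or ()):
            key = (canonical_chrom(rec.chrom, chrom_style), rec.pos,
                   str(rec.ref), str(alt))
            sites[key] = float(afs[ai]) if afs is not None else None
    return sites


VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
]

_GT_STRING = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}


def write_vcf(records: Sequence[VariantRecord], path, sample_name: str = "SAMPLE",
              contigs: Mapping[str, int] | None = None) -> None:
    """Write biallelic records as a single-sample VCF 4.2 text file."""
    lines = list(VCF_HEADER_LINES)
    for chrom, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_name)
    for rec in sorted(records, key=VariantRecord.sort_key):
        dp = rec.depth if rec.depth is not None else 0
        ab = rec.allele_balance
        if ab is None:
            ab = {"hom_ref": 0.0, "het": 0.5, "hom_alt": 1.0, "missing": 0.0}[rec.genotype]
        ad_alt = int(round(dp * ab))
        qual = f"{rec.quality:.1f}" if rec.quality is not None else "."
        lines.append("\t".join([
            rec.chrom, str(rec.pos), ".", rec.ref, rec.alt, qual, "PASS", ".",
            "GT:DP:AD", f"{_GT_STRING[rec.genotype]}:{dp}:{dp - ad_alt},{ad_alt}",
        ]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_sites_vcf(sites: Mapping[tuple, float | None], path,
                    contigs: Mapping[str, int] | None = None) -> None:
    """Write a site-only VCF (no genotypes) with AF in INFO, e.g. a panel DB."""
    lines = list(VCF_HEADER_LINES[:2])
    for chrom, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for (chrom, pos, ref, alt), af in sorted(
            sites.items(), key=lambda kv: (chrom_sort_key(kv[0][0]),) + kv[0][1:]):
        info = f"AF={af:.4f}" if af is not None else "."
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

_BED_ALIAS = {"gain": "cnv_gain", "loss": "cnv_loss"}
_DEFAULT_PLOIDY = {"cnv_gain": 3.0, "cnv_loss": 1.0, "deletion": 1.0,
                   "duplication": 3.0, "inversion": 2.0}


def read_bed(path, chrom_style: str = "chr") -> list[IntervalCall]:
    """Read interval calls from BED4+ (name = call type, col 5 = ploidy)."""
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 BED columns")
            chrom, start, end, name = fields[:4]
            try:
                start, end = int(start), int(end)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            call_type = _BED_ALIAS.get(name, name)
            if call_type not in CALL_TYPES:
                raise FormatError(f"{path}:{lineno}: unknown call type {name!r}")
            ploidy = _DEFAULT_PLOIDY[call_type]
            if len(fields) >= 5 and fields[4] not in {".", ""}:
                ploidy = float(fields[4])
            source = fields[5] if len(fields) >= 6 else ""
            try:
                calls.append(IntervalCall(canonical_chrom(chrom, chrom_style),
                                          start, end, call_type, ploidy, source))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    calls.sort(key=IntervalCall.sort_key)
    return calls


def write_bed(calls: Iterable[IntervalCall], path) -> None:
    with open(path, "w") as fh:
        for c in sorted(calls, key=IntervalCall.sort_key):
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.call_type}\t"
                     f"{c.ploidy:g}\t{c.source_label}\n")


def read_bedgraph(path, bin_size: int = 1000,
                  reference: Mapping[str, str] | None = None,
                  chrom_style: str = "chr") -> CoverageProfile:
    """Read a bedGraph coverage track, re-binned to ``bin_size`` by bp-weighted mean."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                rows.append((canonical_chrom(fields[0], chrom_style),
                             int(fields[1]), int(fields[2]), float(fields[3])))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed record") from None
            if rows[-1][2] <= rows[-1][1]:
                raise FormatError(f"{path}:{lineno}: end <= start")
    if not rows:
        raise FormatError(f"{path}: empty bedGraph")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    out = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise FormatError(f"{path}: overlapping intervals on {chrom}")
        chrom_end = int(ends[-1])
        nbins = -(-chrom_end // bin_size)
        depth_sum = np.zeros(nbins)
        bp_sum = np.zeros(nbins)
        for s, e, v in zip(starts, ends, sub["value"].to_numpy()):
            b0, b1 = s // bin_size, (e - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo, hi = max(s, b * bin_size), min(e, (b + 1) * bin_size)
                depth_sum[b] += v * (hi - lo)
                bp_sum[b] += hi - lo
        with np.errstate(invalid="ignore"):
            mean_depth = np.where(bp_sum > 0, depth_sum / np.maximum(bp_sum, 1), 0.0)
        bin_starts = np.arange(nbins) * bin_size
        bin_ends = np.minimum(bin_starts + bin_size, chrom_end)
        out.append(pd.DataFrame({
            "chrom": chrom, "bin_start": bin_starts, "bin_end": bin_ends,
            "raw_depth": mean_depth,
        }))
    profile = CoverageProfile(pd.concat(out, ignore_index=True), bin_size=bin_size)
    if reference is not None:
        attach_gc(profile, reference)
    return profile


def write_bedgraph(profile: CoverageProfile, path, column: str = "raw_depth") -> None:
    with open(path, "w") as fh:
        for row in profile.bins.itertuples(index=False):
            value = getattr(row, column)
            fh.write(f"{row.chrom}\t{row.bin_start}\t{row.bin_end}\t{value:.6g}\n")


def attach_gc(profile: CoverageProfile, reference: Mapping[str, str]) -> CoverageProfile:
    """Fill gc_fraction per bin from the reference sequence, in place."""
    gcs = []
    for row in profile.bins.itertuples(index=False):
        seq = reference[row.chrom][row.bin_start:row.bin_end].upper()
        acgt = sum(seq.count(b) for b in "ACGT")
        gcs.append((seq.count("G") + seq.count("C")) / acgt if acgt else np.nan)
    profile.bins["gc_fraction"] = gcs
    return profile


# ---------------------------------------------------------------------------
# BED12 gene models
# ---------------------------------------------------------------------------

def read_gene_models(path, chrom_style: str = "chr") -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED12 columns")
            try:
                chrom, start = canonical_chrom(f[0], chrom_style), int(f[1])
                name, strand = f[3], f[5]
                thick_start, thick_end = int(f[6]), int(f[7])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed BED12 record") from None
            if len(sizes) != len(offsets) or len(sizes) != int(f[9]):
                raise FormatError(f"{path}:{lineno}: block count mismatch")
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            try:
                genes.append(GeneModel(name, chrom, strand, exons,
                                       thick_start, thick_end))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    genes.sort(key=lambda g: (chrom_sort_key(g.chrom), g.start))
    return genes


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (chrom_sort_key(g.chrom), g.start)):
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, _ in g.exons)
            fh.write("\t".join(map(str, [
                g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                g.cds_start, g.cds_end, "0,0,0", len(g.exons), sizes, offsets,
            ])) + "\n")


# ---------------------------------------------------------------------------
# GMT pathway sets
# ---------------------------------------------------------------------------

def read_gmt(path, universe: Iterable[str] | None = None) -> PathwayDB:
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT needs name, description and >= 1 gene")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: pathway {name!r} has no genes")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate pathway {name!r}")
            sets[name] = frozenset(genes)
    if universe is None:
        universe = frozenset().union(*sets.values()) if sets else frozenset()
    return PathwayDB(sets=sets, universe=frozenset(universe))


def write_gmt(db: PathwayDB, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(db.sets):
            fh.write("\t".join([name, "na"] + sorted(db.sets[name])) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Load an (indexed) FASTA into an in-memory chrom -> sequence mapping."""
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
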