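"""Format readers/writers, domain-type invariants and variant normalization."""
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from driftprof import vardata
from driftprof.vardata import (CoverageProfile, FormatError, GeneModel,
                               IntervalCall, VariantRecord, normalize_variant)

VCF_HEADER = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
    ##contig=<ID=chr1,length=100000>
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
    """)


def write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestVariantRecord:
    def test_variant_classes(self):
        assert VariantRecord("chr1", 5, "A", "G", "het").variant_class == "snv"
        assert VariantRecord("chr1", 5, "AT", "A", "het").variant_class == "indel"
        assert VariantRecord("chr1", 5, "AT", "GC", "het").variant_class \
            == "block_substitution"

    @pytest.mark.parametrize("ref,alt", [
        ("A", "A"), ("", "G"), ("N", "G"), ("A", "a"),
        ("A" * 52, "A"),  # indel run > 50 bp
    ])
    def test_invalid_alleles_rejected(self, ref, alt):
        with pytest.raises(ValueError):
            VariantRecord("chr1", 5, ref, alt, "het")


class TestReadVcf:
    def test_basic_field_mapping(self, tmp_path):
        path = write(tmp_path, "a.vcf", VCF_HEADER +
                     "chr1\t100\t.\tA\tG\t50\tPASS\t.\tGT:DP\t0/1:30\n")
        (rec,) = vardata.read_vcf(path)
        assert (rec.chrom, rec.pos, rec.ref, rec.alt) == ("chr1", 100, "A", "G")
        assert rec.genotype == "het" and rec.depth == 30
        assert rec.quality == 50 and rec.variant_class == "snv"

    def test_multiallelic_split(self, tmp_path):
        path = write(tmp_path, "a.vcf", VCF_HEADER +
                     "chr1\t100\t.\tA\tG,T\t50\tPASS\t.\tGT\t1/2\n")
        recs = vardata.read_vcf(path)
        assert [(r.alt, r.genotype) for r in recs] == [("G", "het"), ("T", "het")]
        assert all(r.pos == 100 for r in recs)

    def test_indel_class_and_sorting(self, tmp_path):
        path = write(tmp_path, "a.vcf", VCF_HEADER +
                     "chr1\t200\t.\tAT\tA\t50\tPASS\t.\tGT\t0/1\n"
                     "chr1\t100\t.\tC\tG\t50\tPASS\t.\tGT\t1/1\n")
        recs = vardata.read_vcf(path)
        assert [r.pos for r in recs] == [100, 200]
        assert recs[1].variant_class == "indel"
        assert recs[0].genotype == "hom_alt"

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            vardata.read_vcf("/nonexistent.vcf")

    def test_symbolic_alt_rejected_with_position(self, tmp_path):
        path = write(tmp_path, "a.vcf", VCF_HEADER +
                     "chr1\t100\t.\tA\t<DEL>\t50\tPASS\t.\tGT\t0/1\n")
        with pytest.raises(FormatError, match="record 1"):
            vardata.read_vcf(path)

    def test_roundtrip_through_writer(self, tmp_path):
        recs = [VariantRecord("chr1", 100, "A", "G", "het", depth=30,
                              allele_balance=0.5, quality=55.0),
                VariantRecord("chr1", 250, "CTT", "C", "hom_alt", depth=28,
                              allele_balance=1.0, quality=60.0)]
        path = tmp_path / "rt.vcf"
        vardata.write_vcf(recs, path, contigs={"chr1": 100000})
        back = vardata.read_vcf(path)
        assert [r.key for r in back] == [r.key for r in recs]
        assert [r.genotype for r in back] == ["het", "hom_alt"]


# ---------------------------------------------------------------------------
# normalization against a brute-force leftmost-representation oracle
# ---------------------------------------------------------------------------

def apply_variant(seq, pos, ref, alt):
    assert seq[pos - 1:pos - 1 + len(ref)] == ref
    return seq[:pos - 1] + alt + seq[pos - 1 + len(ref):]


def brute_force_leftmost(seq, pos, ref, alt):
    """Smallest-position minimal representation, by exhaustive search.

    Enumerates every (p, r, a) that produces the same mutated sequence,
    keeps the minimal ones (no shared leading base beyond the anchor, no
    shared trailing base), and returns the leftmost.
    """
    mutated = apply_variant(seq, pos, ref, alt)
    delta = len(mutated) - len(seq)
    hits = []
    for p in range(1, len(seq) + 1):
        for lr in range(1, min(10, len(seq) - p + 2)):
            la = lr + delta
            if la < 1:
                continue
            r, a = seq[p - 1:p - 1 + lr], mutated[p - 1:p - 1 + la]
            if len(r) < lr or r == a:
                continue
            if apply_variant(seq, p, r, a) != mutated:
                continue
            minimal = not (len(r) > 1 and len(a) > 1
                           and (r[0] == a[0] or r[-1] == a[-1]))
            if len(r) != len(a):  # indels keep exactly one anchor base
                minimal = (min(len(r), len(a)) == 1 and r[0] == a[0]
                           and r[-1] != a[-1])
            if minimal:
                hits.append((p, r, a))
    return min(hits)


class TestNormalize:
    def test_homopolymer_deletion_shifts_left(self):
        # deletion of one A inside the run starting after C at position 4
        seq = "GGGCAAAT"
        rec = VariantRecord("chr1", 6, "AA", "A", "het")
        norm = normalize_variant(rec, {"chr1": seq})
        assert (norm.pos, norm.ref, norm.alt) == (4, "CA", "C")
        # equivalence: applying either representation mutates identically
        assert apply_variant(seq, 6, "AA", "A") == apply_variant(seq, 4, "CA", "C")

    def test_snv_is_fixed_point(self):
        rec = VariantRecord("chr1", 3, "G", "T", "het")
        assert normalize_variant(rec, {"chr1": "AAGAA"}) is rec

    def test_reference_mismatch_names_position(self):
        rec = VariantRecord("chr1", 3, "T", "A", "het")
        with pytest.raises(ValueError, match="chr1:3"):
            normalize_variant(rec, {"chr1": "AAGAA"})

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_idempotent_and_equivalent(self, data):
        seq = data.draw(st.text(alphabet="ACGT", min_size=20, max_size=40))
        pos = data.draw(st.integers(2, len(seq) - 8))
        kind = data.draw(st.sampled_from(["del", "ins", "snv"]))
        if kind == "del":
            dlen = data.draw(st.integers(1, 4))
            ref, alt = seq[pos - 1:pos + dlen], seq[pos - 1]
        elif kind == "ins":
            ins = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=4))
            ref, alt = seq[pos - 1], seq[pos - 1] + ins
        else:
            ref = seq[pos - 1]
            alt = data.draw(st.sampled_from([b for b in "ACGT" if b != ref]))
        rec = VariantRecord("c", pos, ref, alt, "het")
        norm = normalize_variant(rec, {"c": seq})
        again = normalize_variant(norm, {"c": seq})
        assert norm.key == again.key
        assert norm.pos <= rec.pos
        assert apply_variant(seq, rec.pos, rec.ref, rec.alt) \
            == apply_variant(seq, norm.pos, norm.ref, norm.alt)
        if norm.pos > 1:  # at the contig edge the anchor convention degenerates
            expect = brute_force_leftmost(seq, rec.pos, rec.ref, rec.alt)
            assert (norm.pos, norm.ref, norm.alt) == expect


# ---------------------------------------------------------------------------
# BED / bedGraph / GMT / BED12
# ---------------------------------------------------------------------------

class TestBed:
    def test_read_maps_call_types(self, tmp_path):
        path = write(tmp_path, "c.bed", "chr1\t0\t2000\tloss\n")
        (call,) = vardata.read_bed(path)
        assert (call.start, call.end, call.call_type) == (0, 2000, "cnv_loss")

    def test_roundtrip_byte_identical(self, tmp_path):
        calls = [IntervalCall("chr1", 0, 2000, "cnv_loss", 1.0, "x"),
                 IntervalCall("chr2", 100, 5100, "cnv_gain", 3.25, "y"),
                 IntervalCall("chr2", 9000, 99000, "inversion", 2.0, "z")]
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        vardata.write_bed(calls, p1)
        vardata.write_bed(vardata.read_bed(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_rejects_end_before_start(self, tmp_path):
        path = write(tmp_path, "c.bed", "chr1\t2000\t1000\tloss\n")
        with pytest.raises(FormatError, match=":1"):
            vardata.read_bed(path)


class TestBedgraph:
    def test_rebins_with_weighted_mean(self, tmp_path):
        path = write(tmp_path, "c.bedgraph",
                     "chr1\t0\t500\t10\nchr1\t500\t1000\t30\nchr1\t1000\t2000\t20\n")
        prof = vardata.read_bedgraph(path, bin_size=1000)
        assert prof.bins["raw_depth"].tolist() == [20.0, 20.0]

    def test_rejects_overlapping_intervals(self, tmp_path):
        path = write(tmp_path, "c.bedgraph",
                     "chr1\t0\t1000\t10\nchr1\t500\t1500\t30\n")
        with pytest.raises(FormatError, match="overlap"):
            vardata.read_bedgraph(path, bin_size=1000)

    def test_writer_reader_cycle(self, tmp_path, small_genome):
        import pandas as pd
        bins = pd.DataFrame({"chrom": ["chr1"] * 3, "bin_start": [0, 1000, 2000],
                             "bin_end": [1000, 2000, 3000],
                             "raw_depth": [12.0, 30.5, 0.0]})
        prof = CoverageProfile(bins, 1000)
        path = tmp_path / "x.bedgraph"
        vardata.write_bedgraph(prof, path)
        back = vardata.read_bedgraph(path, 1000)
        assert np.allclose(back.bins["raw_depth"], prof.bins["raw_depth"])


class TestGmt:
    def test_parses_sets(self, tmp_path):
        path = write(tmp_path, "p.gmt", "P1\tdesc\tG1\tG2\tG3\nP2\tdesc\tG3\tG4\n")
        db = vardata.read_gmt(path)
        assert db.sets["P1"] == {"G1", "G2", "G3"}
        assert db.universe == {"G1", "G2", "G3", "G4"}

    def test_pathway_outside_universe_rejected(self, tmp_path):
        path = write(tmp_path, "p.gmt", "P1\tdesc\tG1\tG2\n")
        with pytest.raises(ValueError, match="universe"):
            vardata.read_gmt(path, universe={"G1"})


class TestGeneModels:
    def test_roundtrip(self, tmp_path, small_genome):
        _cfg, _ref, genes = small_genome
        path = tmp_path / "g.bed12"
        vardata.write_gene_models(genes, path)
        back = vardata.read_gene_models(path)
        assert [(g.gene_id, g.exons, g.cds_start, g.cds_end) for g in back] \
            == [(g.gene_id, g.exons, g.cds_start, g.cds_end) for g in genes]

    def test_cds_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            GeneModel("g", "chr1", "+", ((0, 10),), 0, 10)

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GeneModel("g", "chr1", "+", ((0, 10), (5, 20)), 0, 9)


class TestCoverageProfileInvariants:
    def test_overlapping_bins_rejected(self):
        import pandas as pd
        bins = pd.DataFrame({"chrom": ["chr1", "chr1"], "bin_start": [0, 0],
                             "bin_end": [1000, 1000], "raw_depth": [1.0, 2.0]})
        with pytest.raises(FormatError):
            CoverageProfile(bins, 1000)

    def test_misaligned_bin_start_rejected(self):
        import pandas as pd
        bins = pd.DataFrame({"chrom": ["chr1"], "bin_start": [500],
                             "bin_end": [1500], "raw_depth": [1.0]})
        with pytest.raises(FormatError):
            CoverageProfile(bins, 1000)
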