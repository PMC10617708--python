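"""Filter cascade, masking, parental subtraction and effect annotation."""

import numpy as np
import pytest

from conftest import (
    cascade_oracle_surviving,
    clean_annotations,
    make_record,
    random_variant_table,
)
from evohotspot.variants import (
    GeneModel,
    SampleCall,
    VariantRecord,
    VariantTable,
    annotate_effects,
    apply_cohort_filters,
    apply_hard_site_filters,
    audit_frame,
    mask_sample_calls,
    parse_variant_table,
    run_filter_cascade,
)


def table_of(*records, samples=None):
    samples = samples or sorted({s for r in records for s in r.calls})
    return VariantTable(records=list(records), samples=samples)


def call(sample, gt=1, dp=20, ad=None):
    ad = ad if ad is not None else ((dp, 0) if gt == 0 else (0, dp))
    return SampleCall(sample, gt, dp, ad)


class TestHardFilters:
    def test_single_failing_annotation_named(self):
        rec = make_record(qual=100.0, **{**clean_annotations(), "QD": 1.9})
        out = apply_hard_site_filters(table_of(rec))
        assert out.records[0].filter_status == ("QD",)

    def test_indel_uses_relaxed_fs_bound(self):
        rec = make_record(
            ref="A", alt="ATT", qual=100.0, QD=20.0, FS=150.0, ReadPosRankSum=0.0
        )
        out = apply_hard_site_filters(table_of(rec))
        assert out.records[0].passes

    def test_exact_threshold_values_pass(self):
        rec = make_record(
            qual=30.0,
            QD=2.0,
            MQ=40.0,
            FS=60.0,
            SOR=4.0,
            MQRankSum=-12.5,
            ReadPosRankSum=-8.0,
        )
        out = apply_hard_site_filters(table_of(rec))
        assert out.records[0].passes

    def test_missing_annotation_fails_closed(self):
        annotations = clean_annotations()
        del annotations["MQ"]
        rec = make_record(qual=100.0, **annotations)
        audit = []
        out = apply_hard_site_filters(table_of(rec), audit=audit)
        assert out.records[0].filter_status == ("MQ",)
        log = audit_frame(audit)
        assert (log["action"] == "fail-closed (missing)").any()

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        table = random_variant_table(rng)
        once = apply_hard_site_filters(table)
        twice = apply_hard_site_filters(once)
        assert [r.filter_status for r in once] == [r.filter_status for r in twice]


class TestSampleMasking:
    @pytest.mark.parametrize(
        "dp, ad, expect_masked",
        [
            (3, (0, 3), True),  # read depth below 4
            (20, (10, 10), True),  # second allele AD 10 > 4 and ratio 1.0
            (10, (9, 1), False),  # second AD 1 <= 4, ratio 0.111 <= 0.2
            (24, (20, 4), False),  # boundary: second AD 4, ratio 0.2 exactly
            (10, (0, 0), True),  # AD all zero despite dp > 0
        ],
    )
    def test_mask_rules(self, dp, ad, expect_masked):
        rec = make_record(calls={"s1": SampleCall("s1", 1, dp, ad)})
        out = mask_sample_calls(table_of(rec, samples=["s1"]))
        assert out.records[0].calls["s1"].masked is expect_masked

    def test_masking_idempotent(self):
        rng = np.random.default_rng(6)
        table = random_variant_table(rng)
        once = mask_sample_calls(table)
        twice = mask_sample_calls(once)
        for r1, r2 in zip(once, twice):
            assert [c.masked for c in r1.calls.values()] == [
                c.masked for c in r2.calls.values()
            ]


class TestCohortFilters:
    def make(self, calls, qual=100.0, **extra):
        return make_record(qual=qual, calls=calls, **{**clean_annotations(), **extra})

    def test_low_mean_depth_removed(self):
        calls = {f"s{i}": call(f"s{i}", gt=i == 0, dp=10 if i else 9) for i in range(10)}
        calls["s0"] = call("s0", gt=1, dp=9)  # mean depth 9.9
        rec = self.make(calls)
        out = apply_cohort_filters(table_of(rec), parental_sample_ids=[])
        assert len(out) == 0

    def test_high_total_depth_removed(self):
        rec = self.make({"s1": call("s1")}, DP=20001.0)
        assert len(apply_cohort_filters(table_of(rec), [])) == 0

    def test_fixed_allele_frequency_removed(self):
        calls = {f"s{i}": call(f"s{i}", gt=1, dp=30) for i in range(50)}
        rec = self.make(calls)
        assert len(apply_cohort_filters(table_of(rec), [])) == 0

    def test_parental_only_variant_removed(self):
        calls = {"parent": call("parent", gt=1), "s1": call("s1", gt=0)}
        rec = self.make(calls)
        audit = []
        out = apply_cohort_filters(table_of(rec), ["parent"], audit=audit)
        assert len(out) == 0
        reasons = set(audit_frame(audit)["rule"])
        assert "frequency" in reasons  # AC over non-parental samples is 0

    def test_parental_shared_variant_removed(self):
        calls = {
            "parent": call("parent", gt=1),
            "s1": call("s1", gt=1),
            "s2": call("s2", gt=0),
        }
        rec = self.make(calls)
        audit = []
        out = apply_cohort_filters(table_of(rec), ["parent"], audit=audit)
        assert len(out) == 0
        assert "parental" in set(audit_frame(audit)["rule"])

    def test_af_recomputed_over_unmasked_nonparental(self):
        calls = {
            "parent": call("parent", gt=0),
            "s1": call("s1", gt=1),
            "s2": call("s2", gt=0),
            "s3": SampleCall("s3", 1, 2, (0, 2)),  # will be masked (dp < 4)
        }
        rec = self.make(calls)
        masked = mask_sample_calls(table_of(rec))
        out = apply_cohort_filters(masked, ["parent"])
        assert len(out) == 1
        assert out.records[0].annotations["AF"] == pytest.approx(0.5)
        assert out.records[0].annotations["AC"] == 1

    def test_mask_then_filter_equals_composed(self):
        rng = np.random.default_rng(17)
        table = random_variant_table(rng)
        staged = apply_cohort_filters(mask_sample_calls(table), ["parent"])

        def composed(t):
            return apply_cohort_filters(mask_sample_calls(t), ["parent"])

        assert {r.key for r in staged} == {r.key for r in composed(table)}


class TestCascadeOracle:
    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(40):
            table = random_variant_table(rng)
            ours = {r.key for r in run_filter_cascade(table, ["parent"])}
            expected = cascade_oracle_surviving(table, ["parent"])
            assert ours == expected


HOTSPOT_CDS = (
    "ATG" "CGT" "TGG" "AAA" "GGC" "TAT" "CTG" "GAA" "TAA"
)  # M R W K G Y L E *


@pytest.fixture(scope="module")
def toy_reference():
    # plus-strand gene at [10, 37); minus-strand copy at [50, 77)
    from Bio.Seq import Seq

    seq = ["A"] * 100
    seq[10:37] = list(HOTSPOT_CDS)
    seq[50:77] = list(str(Seq(HOTSPOT_CDS).reverse_complement()))
    reference = {"chr1": "".join(seq)}
    plus = GeneModel("genP", "chr1", "+", ((10, 37),), promoter_window_bp=5)
    minus = GeneModel("genM", "chr1", "-", ((50, 77),), promoter_window_bp=5)
    return reference, plus, minus


class TestEffectAnnotation:
    def annotate(self, toy_reference, records):
        reference, plus, minus = toy_reference
        return annotate_effects(
            table_of(*records, samples=["s1"]), [plus, minus], reference
        )

    def test_start_codon_snp_is_start_lost(self, toy_reference):
        rec = make_record(pos=11, ref="A", alt="G", calls={"s1": call("s1")})
        out = self.annotate(toy_reference, [rec])
        eff = out.records[0].effect
        assert (eff.effect_class, eff.protein_change) == ("start_lost", "M1V")

    def test_tryptophan_to_stop(self, toy_reference):
        # TGG codon 3 at positions 16-18; G->A at the third base gives TGA
        rec = make_record(pos=19, ref="A", alt="G")  # placeholder replaced below
        rec = make_record(pos=18, ref="G", alt="A", calls={"s1": call("s1")})
        out = self.annotate(toy_reference, [rec])
        eff = out.records[0].effect
        assert (eff.effect_class, eff.protein_change) == ("stop_gained", "W3*")

    def test_synonymous_third_position(self, toy_reference):
        # CGT (R2) -> CGA stays arginine: position 15 is the codon's 3rd base
        rec = make_record(pos=16, ref="T", alt="A", calls={"s1": call("s1")})
        out = self.annotate(toy_reference, [rec])
        assert out.records[0].effect.effect_class == "synonymous"

    def test_two_bp_deletion_is_frameshift(self, toy_reference):
        rec = make_record(pos=20, ref="AAA", alt="A", calls={"s1": call("s1")})
        out = self.annotate(toy_reference, [rec])
        assert out.records[0].effect.effect_class == "frameshift"

    def test_inframe_deletion(self, toy_reference):
        rec = make_record(pos=20, ref="AAAG", alt="A", calls={"s1": call("s1")})
        out = self.annotate(toy_reference, [rec])
        assert out.records[0].effect.effect_class == "inframe_indel"

    def test_promoter_and_intergenic(self, toy_reference):
        up = make_record(pos=8, ref="A", alt="C", calls={"s1": call("s1")})
        away = make_record(pos=95, ref="A", alt="C", calls={"s1": call("s1")})
        out = self.annotate(toy_reference, [up, away])
        assert out.records[0].effect.effect_class == "upstream"
        assert out.records[1].effect.effect_class == "intergenic"

    def test_minus_strand_matches_plus_strand_changes(self, toy_reference):
        reference, plus, minus = toy_reference
        # same codon-1 A->G start-lost change, expressed on the minus strand:
        # genomic base 77 (1-based) is the complementary T of the start's A
        rec = make_record(pos=77, ref="T", alt="C", calls={"s1": call("s1")})
        out = self.annotate(toy_reference, [rec])
        eff = out.records[0].effect
        assert (eff.gene_id, eff.effect_class, eff.protein_change) == (
            "genM",
            "start_lost",
            "M1V",
        )

    def test_cds_snp_classes_partition(self, toy_reference, genome, truth):
        """Every CDS SNP falls in exactly one of the four coding classes."""
        from evohotspot import simdata

        profile = simdata.DEFAULT_CALLER_PROFILES["tolerant"]
        table = simdata.emit_caller_calls(truth, profile, "A")
        g = simdata.generate_genome(truth.config)
        out = annotate_effects(table, g.genes, g.sequences)
        coding = {"synonymous", "missense", "stop_gained", "start_lost"}
        for rec in out:
            if rec.effect is None or rec.variant_type != "snp":
                continue
            in_cds = any(
                gm.contains_cds(rec.pos - 1)
                for gm in g.genes
                if gm.chrom == rec.chrom
            )
            assert (rec.effect.effect_class in coding) == in_cds

    def test_reference_mismatch_logged_not_fatal(self, toy_reference):
        bad = make_record(pos=11, ref="C", alt="G", calls={"s1": call("s1")})
        good = make_record(pos=18, ref="G", alt="A", calls={"s1": call("s1")})
        audit = []
        out = self.annotate(toy_reference, [bad])  # smoke: no raise
        reference, plus, minus = toy_reference
        out = annotate_effects(
            table_of(bad, good, samples=["s1"]), [plus, minus], reference, audit=audit
        )
        assert out.records[0].effect is None
        assert out.records[1].effect.effect_class == "stop_gained"
        assert "ref-mismatch" in set(audit_frame(audit)["rule"])


class TestParseRoundTrip:
    def test_vcf_round_trip(self, tmp_path):
        from evohotspot.io import write_vcf

        rec1 = make_record(
            chrom="chr1", pos=10, ref="A", alt="T", qual=55.0,
            calls={"s1": call("s1", gt=1, dp=20, ad=(0, 20)),
                   "s2": call("s2", gt=0, dp=18, ad=(18, 0))},
            **clean_annotations(),
        )
        rec2 = make_record(
            chrom="chr1", pos=40, ref="G", alt="GAA", qual=70.0,
            calls={"s1": call("s1", gt=0, dp=25, ad=(25, 0)),
                   "s2": call("s2", gt=1, dp=22, ad=(1, 21))},
            **clean_annotations(),
        )
        path = tmp_path / "two.vcf"
        write_vcf(table_of(rec1, rec2, samples=["s1", "s2"]), path, {"chr1": 100})
        table = parse_variant_table(path)
        assert len(table) == 2
        assert table.samples == ["s1", "s2"]
        back = table.records[0]
        assert back.key == ("chr1", 10, "A", "T")
        assert back.qual == pytest.approx(55.0)
        assert back.annotations["QD"] == pytest.approx(20.0)
        assert back.calls["s1"].gt == 1
        assert back.calls["s1"].ad == (0, 20)
        assert table.records[1].variant_type == "indel"

    def test_multiallelic_split(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=100>\n'
            '##INFO=<ID=QD,Number=1,Type=Float,Description="qd">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "chr1\t7\t.\tA\tC,T\t90\t.\tQD=25\tGT:DP:AD\t1:30:2,27,1\t2:28:0,1,27\n"
        )
        path = tmp_path / "multi.vcf"
        path.write_text(text)
        table = parse_variant_table(path)
        assert [r.alt for r in table.records] == ["C", "T"]
        first, second = table.records
        # allele-specific genotypes after the split
        assert (first.calls["s1"].gt, first.calls["s2"].gt) == (1, 0)
        assert (second.calls["s1"].gt, second.calls["s2"].gt) == (0, 1)
        # the full AD vector is preserved for second-allele masking logic
        assert first.calls["s1"].ad == (2, 27, 1)

    def test_missing_info_keys_tolerated(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=100>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t7\t.\tA\tC\t90\t.\t.\tGT\t1\n"
        )
        path = tmp_path / "sparse.vcf"
        path.write_text(text)
        table = parse_variant_table(path)
        rec = table.records[0]
        assert "MQ" not in rec.annotations
        # downstream, the missing MQ fails the hard filter fail-closed
        out = apply_hard_site_filters(table)
        assert "MQ" in out.records[0].filter_status

    def test_unknown_contig_warns(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chrX,length=100>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chrX\t7\t.\tA\tC\t90\t.\t.\tGT\t1\n"
        )
        path = tmp_path / "odd.vcf"
        path.write_text(text)
        with pytest.warns(UserWarning, match="not in reference"):
            table = parse_variant_table(path, reference={"chr1": "A" * 100})
        assert len(table) == 1
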