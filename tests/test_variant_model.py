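"""Variant domain types, filter cascade, QC, and file round trips."""

import dataclasses

import numpy as np
import pytest

from correaevo.simulate import SimConfig, simulate_filter_variants, simulate_patient
from correaevo.variant_model import (
    DataIntegrityError,
    FilterConfig,
    LesionSample,
    SchemaError,
    VariantCall,
    apply_filter_cascade,
    qc_sample,
    read_variants,
    write_variants_tsv,
    write_variants_vcf,
)


def make_call(**overrides) -> VariantCall:
    base = dict(chrom="chr1", pos=1000, ref="C", alt="T", gene="TP53",
                effect="missense", depth=100, alt_reads=10, vaf=0.10,
                mean_base_quality=30.0, alt_fwd=5, alt_rev=5)
    base.update(overrides)
    return VariantCall(**base)


class TestVariantCallInvariants:
    def test_alt_reads_cannot_exceed_depth(self):
        with pytest.raises(DataIntegrityError):
            make_call(alt_reads=200, alt_fwd=100, alt_rev=100)

    def test_strand_counts_must_sum_to_alt_reads(self):
        with pytest.raises(DataIntegrityError):
            make_call(alt_fwd=9, alt_rev=2)

    def test_vaf_must_match_read_counts(self):
        with pytest.raises(DataIntegrityError):
            make_call(vaf=0.5)

    def test_duplicate_keys_rejected_within_sample(self):
        v = make_call()
        with pytest.raises(DataIntegrityError):
            LesionSample(patient_id="P01", stage="EGC", variants=[v, v])


class TestFilterCascade:
    @pytest.mark.parametrize("overrides,reason", [
        (dict(depth=19, alt_reads=10, vaf=10 / 19, alt_fwd=5, alt_rev=5),
         "min_depth"),
        (dict(alt_fwd=10, alt_rev=0), "both_strands"),
        (dict(vaf=0.01, alt_reads=1, alt_fwd=1, alt_rev=0), "min_vaf"),
        (dict(mean_base_quality=14.9), "min_base_quality"),
        (dict(alt_reads=4, vaf=0.04, alt_fwd=2, alt_rev=2), "min_alt_reads"),
        (dict(alt_reads=50, vaf=0.5, alt_fwd=46, alt_rev=4), "strand_bias"),
        (dict(pop_af_exac_eas=0.02), "population_frequency"),
        (dict(blacklist=True), "blacklist"),
    ])
    def test_first_failing_rule_reported(self, overrides, reason):
        kept, rejected = apply_filter_cascade([make_call(**overrides)])
        assert kept == []
        assert rejected[0][1] == reason

    def test_clean_variant_kept(self):
        kept, rejected = apply_filter_cascade([make_call()])
        assert len(kept) == 1 and rejected == []

    def test_missing_population_af_passes(self):
        kept, _ = apply_filter_cascade([make_call(pop_af_1kg=None)])
        assert len(kept) == 1

    def test_depth_zero_with_alt_reads_is_integrity_error(self):
        v = dataclasses.replace(make_call(), depth=100)
        object.__setattr__(v, "depth", 0)  # bypass constructor check
        with pytest.raises(DataIntegrityError):
            apply_filter_cascade([v])

    def test_partition_and_idempotence(self):
        variants = simulate_filter_variants(500, rng=7)
        kept, rejected = apply_filter_cascade(variants)
        assert len(kept) + len(rejected) == len(variants)
        assert set(v.key for v in kept) | set(v.key for v, _ in rejected) \
            == set(v.key for v in variants)
        kept2, rejected2 = apply_filter_cascade(kept)
        assert kept2 == kept and rejected2 == []

    def test_kept_set_matches_rule_by_rule_oracle(self):
        """Cascade equals an independent conjunction of per-rule predicates."""
        variants = simulate_filter_variants(2000, rng=11)
        cfg = FilterConfig()
        kept, _ = apply_filter_cascade(variants, cfg)

        def passes_all(v):
            checks = [
                v.vaf >= cfg.min_vaf,
                v.depth >= cfg.min_depth,
                v.mean_base_quality >= cfg.min_base_quality,
                v.alt_reads >= cfg.min_alt_reads,
                v.alt_fwd > 0 and v.alt_rev > 0,
                min(v.alt_fwd, v.alt_rev) / v.alt_reads >= cfg.min_minor_strand_fraction
                if v.alt_reads else False,
                all(af is None or af <= cfg.max_pop_af for af in
                    (v.pop_af_1kg, v.pop_af_exac_all, v.pop_af_exac_eas)),
                not v.blacklist,
            ]
            return all(checks)

        oracle_kept = {v.key for v in variants if passes_all(v)}
        assert {v.key for v in kept} == oracle_kept

    @pytest.mark.parametrize("field,tighter", [
        ("min_depth", 40), ("min_base_quality", 25.0), ("min_alt_reads", 10),
        ("min_vaf", 0.05), ("min_minor_strand_fraction", 0.3),
        ("max_pop_af", 0.001),
    ])
    def test_tightening_thresholds_is_monotone(self, field, tighter):
        variants = simulate_filter_variants(800, rng=3)
        kept_default, _ = apply_filter_cascade(variants, FilterConfig())
        kept_tight, _ = apply_filter_cascade(
            variants, FilterConfig(**{field: tighter}))
        assert {v.key for v in kept_tight} <= {v.key for v in kept_default}


class TestQC:
    @pytest.mark.parametrize("role,pre,post,oscore,failed", [
        ("lesion", 250, 70, 40, set()),
        ("lesion", 250, 55, 40, {"post_dedup_depth"}),
        ("lesion", 180, 70, 40, {"pre_dedup_depth"}),
        ("normal", 120, 35, 34, {"oscore"}),
        ("normal", 120, 35, 40, set()),
        ("normal", 90, 20, 30, {"pre_dedup_depth", "post_dedup_depth",
                                "oscore"}),
    ])
    def test_depth_and_damage_thresholds(self, role, pre, post, oscore, failed):
        sample = LesionSample(patient_id="P01",
                              stage="EGC" if role == "lesion" else "NM",
                              depth_pre_dedup=pre, depth_post_dedup=post,
                              oscore=oscore)
        verdict = qc_sample(sample, role)
        assert verdict.failed_checks == frozenset(failed)
        assert verdict.passed == (not failed)

    def test_unknown_role_rejected(self):
        sample = LesionSample(patient_id="P01", stage="EGC")
        with pytest.raises(ValueError, match="role"):
            qc_sample(sample, "tumour")


class TestIO:
    def test_round_trips_are_exact(self, tmp_path, rng):
        patient, _ = simulate_patient(SimConfig(seed=9), "linear", rng)
        variants = patient.samples["EGC"].variants
        vcf = tmp_path / "egc.vcf"
        tsv = tmp_path / "egc.tsv"
        write_variants_vcf(variants, vcf)
        write_variants_tsv(variants, tsv)
        by_key = sorted(variants, key=lambda v: v.key)
        assert sorted(read_variants(vcf, "vcf"), key=lambda v: v.key) == by_key
        assert read_variants(tsv, "tsv") == list(variants)

    def test_vcf_field_mapping(self, tmp_path):
        vcf = tmp_path / "one.vcf"
        write_variants_vcf([make_call(depth=100, alt_reads=5, vaf=0.05,
                                      alt_fwd=3, alt_rev=2)], vcf)
        (v,) = read_variants(vcf, "vcf")
        assert (v.depth, v.alt_reads, v.vaf) == (100, 5, 0.05)
        assert v.pos == 1000  # 1-based preserved

    def test_empty_vcf_gives_empty_list(self, tmp_path):
        vcf = tmp_path / "empty.vcf"
        write_variants_vcf([], vcf)
        assert read_variants(vcf, "vcf") == []

    def test_multiallelic_records_are_decomposed(self, tmp_path):
        vcf = tmp_path / "multi.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000000>\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS\n"
            "chr1\t500\t.\tA\tC,G\t.\t.\t.\tDP:AD\t100:88,7,5\n")
        calls = read_variants(vcf, "vcf")
        assert [(c.alt, c.alt_reads) for c in calls] == [("C", 7), ("G", 5)]

    def test_missing_tsv_column_is_schema_error(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("chrom\tpos\nchr1\t5\n")
        with pytest.raises(SchemaError, match="missing mandatory columns"):
            read_variants(bad, "tsv")
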