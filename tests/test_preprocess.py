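from collections import Counter

import pytest

from oracles import brute_classify
from uvbsrna.io import Feature
from uvbsrna.preprocess import (
    FastqParseError,
    classify_tags,
    clean_reads,
    length_distribution,
    merge_tag_counts,
    qc_report,
)
from uvbsrna.synthetic import DEFAULT_ADAPTER

AD = DEFAULT_ADAPTER
Q40 = "I"


def _read(insert, rid="r0", qual_char=Q40, read_len=50, adapter=AD):
    seq = (insert + adapter + "CGTATGCCGTCTTCTGCTTG" * 3)[:read_len]
    return rid, seq, qual_char * len(seq)


class TestCleanReads:
    def test_canonical_clean_read_is_retained(self):
        tags, qc = clean_reads([_read("ACGTACGTACGTACGTACGTAC")], AD)
        assert tags == Counter({"ACGTACGTACGTACGTACGTAC": 1})
        assert qc.clean == 1 and qc.raw == 1

    def test_sixteen_nt_insert_removed_too_short(self):
        tags, qc = clean_reads([_read("ACGTACGTACGTACGT")], AD)
        assert not tags and qc.categories == Counter({"too_short": 1})

    def test_polya_insert_removed(self):
        tags, qc = clean_reads([_read("A" * 18 + "CG")], AD)  # 90% A
        assert qc.categories == Counter({"poly_a": 1})

    def test_polya_run_rule(self):
        insert = "CG" + "A" * 10 + "CGCGTACG"  # 50% A but a 10-A run
        tags, qc = clean_reads([_read(insert)], AD)
        assert qc.categories == Counter({"poly_a": 1})

    def test_adapter_only_is_insert_null(self):
        tags, qc = clean_reads([_read("")], AD)
        assert qc.categories == Counter({"insert_null": 1})

    def test_missing_adapter_removed(self):
        rid, seq, qual = "r0", "GTCGTCGTCGTCGTCGTCGTCGTCGTCGTCGTCGTCGTCGTCGTCGTCGT", None
        tags, qc = clean_reads([(rid, seq, Q40 * len(seq))], AD)
        assert qc.categories == Counter({"removed_adapter": 1})

    def test_n_containing_has_top_precedence(self):
        rid, seq, qual = _read("ACGTNCGTACGTACGTACGTAC")
        tags, qc = clean_reads([(rid, seq, "&" * len(seq))], AD)  # also low-qual
        assert qc.categories == Counter({"n_containing": 1})

    def test_low_quality_removed(self):
        rid, seq, _ = _read("ACGTACGTACGTACGTACGTAC")
        qual = "&" * 10 + Q40 * (len(seq) - 10)  # 20% below Q20
        tags, qc = clean_reads([(rid, seq, qual)], AD)
        assert qc.categories == Counter({"low_quality": 1})

    def test_truncated_adapter_suffix_recovered(self):
        insert = "ACGTACGTACGTACGTACGTACGTACGTAC"  # 30 nt; adapter truncated
        rid, seq, qual = _read(insert)
        assert len(seq) == 50
        tags, qc = clean_reads([(rid, seq, qual)], AD)
        assert tags == Counter({insert: 1})

    def test_malformed_record_raises_with_index(self):
        with pytest.raises(FastqParseError, match="#1"):
            clean_reads([_read("ACGTACGTACGTACGTACGTAC"), ("r1", "ACGT", "II")], AD)

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            clean_reads([], "")

    def test_idempotent_on_clean_tags(self):
        reads = [_read("ACGTACGTACGTACGTACGTAC", f"r{i}") for i in range(5)]
        tags1, _ = clean_reads(reads, AD)
        again = [
            _read(seq, f"s{i}") for i, seq in enumerate(tags1.elements())
        ]
        tags2, qc2 = clean_reads(again, AD)
        assert tags1 == tags2
        assert qc2.clean == qc2.raw

    def test_reconciliation_on_simulated_libraries(self, cleaned):
        _, qc_rows = cleaned
        for lib, qc in qc_rows.items():
            assert qc.reconciles(), lib
            assert qc.raw == 12_000

    def test_simulated_contaminants_classified_exactly(self, small_sim, cleaned):
        _, _, _, truth = small_sim
        _, qc_rows = cleaned
        remap = {"no_adapter": "removed_adapter"}
        for lib, qc in qc_rows.items():
            planted = truth.origin_counts[lib]
            for cat in (
                "insert_null",
                "poly_a",
                "too_short",
                "too_long",
                "low_quality",
                "n_containing",
                "no_adapter",
            ):
                want = planted.get(f"contaminant:{cat}", 0)
                assert qc.categories.get(remap.get(cat, cat), 0) == want, (lib, cat)

    def test_qc_report_percentages(self, cleaned):
        _, qc_rows = cleaned
        df = qc_report(list(qc_rows.values()))
        pct_cols = [c for c in df.columns if c.endswith("_pct") or c == "clean_pct"]
        assert ((df[pct_cols].sum(axis=1) - 100).abs() < 0.01).all()


class TestLengthDistribution:
    def test_single_length_input(self):
        tags = {"ACGTACGTACGTACGTACGTA": {"lib": 5}}  # one 21-mer
        dist = length_distribution(tags)
        assert dist.loc[21, "lib_reads"] == 1.0
        assert dist["lib_reads"].sum() == pytest.approx(1.0)
        assert (dist.drop(index=21) == 0).all().all()

    def test_weighted_vs_unique_fractions(self):
        tags = {
            "ACGTACGTACGTACGTACGTA": {"lib": 3},  # 21 nt, count 3
            "ACGTACGTACGTACGTACGTACGT": {"lib": 1},  # 24 nt, count 1
        }
        dist = length_distribution(tags)
        assert dist.loc[21, "lib_reads"] == pytest.approx(0.75)
        assert dist.loc[24, "lib_reads"] == pytest.approx(0.25)
        assert dist.loc[21, "lib_tags"] == pytest.approx(0.5)
        assert dist.loc[24, "lib_tags"] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self, cleaned):
        tags, _ = cleaned
        dist = length_distribution(tags)
        assert (abs(dist.sum(axis=0) - 1.0) < 1e-9).all()

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            length_distribution({})

    def test_simulated_length_modes(self, cleaned):
        tags, _ = cleaned
        dist = length_distribution(tags)
        reads = dist[[c for c in dist.columns if c.endswith("_reads")]].mean(axis=1)
        uniq = dist[[c for c in dist.columns if c.endswith("_tags")]].mean(axis=1)
        assert reads.idxmax() == 21
        assert uniq.idxmax() == 21
        assert uniq.drop(index=21).idxmax() == 24


class TestClassifyTags:
    GENOME = {"c1": "T" * 60 + "ACGTACGTACGTACGTACGTAC" + "T" * 60}
    TAG = "ACGTACGTACGTACGTACGTAC"

    def test_tag_inside_rrna_interval(self):
        feats = [Feature("c1", 50, 100, "+", "rRNA", "r1")]
        bd = classify_tags({self.TAG: {"lib": 2}}, self.GENOME, feats)
        assert bd.tag_class[self.TAG] == "rRNA"
        assert bd.reads.loc["rRNA", "lib"] == 2

    def test_precedence_ncrna_over_repeat_over_exon(self):
        feats = [
            Feature("c1", 50, 100, "+", "exon", "e1"),
            Feature("c1", 55, 90, "+", "repeat_region", "rep1"),
            Feature("c1", 58, 70, "+", "snoRNA", "s1"),
        ]
        bd = classify_tags({self.TAG: {"lib": 1}}, self.GENOME, feats)
        assert bd.tag_class[self.TAG] == "snoRNA"

    def test_unmapped_tag_is_unannotated(self):
        bd = classify_tags({"G" * 22: {"lib": 1}}, self.GENOME, [])
        assert bd.tag_class["G" * 22] == "unannotated"

    def test_unknown_chromosome_raises(self):
        with pytest.raises(ValueError, match="unknown chromosome"):
            classify_tags(
                {self.TAG: {"lib": 1}},
                self.GENOME,
                [Feature("nope", 0, 10, "+", "rRNA", "x")],
            )

    def test_counts_reconcile_to_clean_totals(self, cleaned):
        tags, qc_rows = cleaned
        # restrict to a cheap subset: classification must partition all reads
        from uvbsrna.synthetic import ReferenceParams, generate_reference

        ref = generate_reference(ReferenceParams(), seed=101)
        bd = classify_tags(tags, ref.genome, ref.features)
        for lib, qc in qc_rows.items():
            assert bd.reads[lib].sum() == qc.clean

    def test_agrees_with_exhaustive_interval_oracle(self, small_ref, cleaned, rng):
        tags, _ = cleaned
        bd = classify_tags(tags, small_ref.genome, small_ref.features)
        sample = rng.choice(sorted(tags), size=60, replace=False)
        for tag in sample:
            assert bd.tag_class[tag] == brute_classify(
                tag, small_ref.genome, small_ref.features
            ), tag


def test_merge_tag_counts_roundtrip():
    per_lib = {"a": Counter({"ACGT": 2}), "b": Counter({"ACGT": 1, "GGGG": 4})}
    merged = merge_tag_counts(per_lib)
    assert merged == {"ACGT": {"a": 2, "b": 1}, "GGGG": {"b": 4}}
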