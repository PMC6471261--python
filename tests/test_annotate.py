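import numpy as np
import pytest

from mejamir.annotate import (
    HairpinCandidate, ReferenceSet, classify_tags, match_known, screen_novel,
)
from mejamir.preprocess import CleanTag

MATURE = "TGACGATCGATCCGATCGTAC"  # 21 nt


def _refs(**over):
    base = dict(
        mature_mirnas={"MIR169-x1": MATURE},
        mature_families={"MIR169-x1": "MIR169"},
        other_ncrna={"rRNA1": "G" * 30 + MATURE + "C" * 30},
        transcriptome={"Unigene1": "ACGT" * 30},
    )
    base.update(over)
    return ReferenceSet(**base)


def _revcomp(s):
    return s[::-1].translate(str.maketrans("ACGT", "TGCA"))


class TestMatchKnown:
    def test_exact_match(self):
        refs = _refs()
        mid, family, mm = match_known(MATURE, refs)
        assert (mid, family, mm) == ("MIR169-x1", "MIR169", 0)

    def test_two_mismatches_tolerated_three_rejected(self):
        refs = _refs()
        two = "CC" + MATURE[2:]
        assert match_known(two, refs)[2] == 2
        three = "CCC" + MATURE[3:]
        assert match_known(three, refs) is None

    def test_end_offset_within_two(self):
        refs = _refs()
        shifted = MATURE[2:] + "GG"  # starts +2, ends +2 with extra bases
        assert match_known(shifted, refs) is not None
        assert match_known(MATURE[3:] + "GGA", refs) is None

    def test_tie_goes_to_alphabetically_first(self):
        refs = _refs(
            mature_mirnas={"MIR2-b": MATURE, "MIR1-a": MATURE},
            mature_families={"MIR2-b": "MIR2", "MIR1-a": "MIR1"})
        assert match_known(MATURE, refs)[0] == "MIR1-a"


class TestScreenNovel:
    def test_planted_inverted_repeat_accepted(self):
        rng = np.random.default_rng(0)
        tag = "".join("ACGT"[i] for i in rng.integers(0, 4, 22))
        flank1 = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        flank2 = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        contig = flank1 + tag + "ATTTGCAA" + _revcomp(tag) + flank2
        start = len(flank1)
        result = screen_novel(tag, "c1", contig, start)
        assert isinstance(result, HairpinCandidate)
        assert result.paired_bases >= 14
        assert result.arm == "5p"
        assert _revcomp(tag) in result.star_seq or result.star_seq in _revcomp(tag) \
            or len(result.star_seq) >= 14

    def test_tag_straddling_loop_rejected(self):
        rng = np.random.default_rng(1)
        arm = "".join("ACGT"[i] for i in rng.integers(0, 4, 22))
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        contig = flank + arm + "ATTTGCAA" + _revcomp(arm) + flank
        # tag spans the loop: last 10 of the arm + loop + first 4 of star
        start = len(flank) + 12
        tag = contig[start: start + 22]
        result = screen_novel(tag, "c1", contig, start)
        assert result in ("arm-rule", "no-hairpin", "bulge-rule")

    def test_contig_too_short(self):
        assert screen_novel("ACGT" * 5, "c1", "ACGT" * 7, 4) == "no-window"


class TestClassification:
    def test_ncrna_precedence_over_mirna(self):
        """A tag equal to both an rRNA subsequence and a mature reference
        is classified other_ncrna — removal order comes first."""
        refs = _refs()
        tags = [CleanTag(MATURE, {"A": 1})]
        anns, _ = classify_tags(tags, refs)
        assert anns[0].category == "other_ncrna"

    def test_known_mirna_with_family(self):
        refs = _refs(other_ncrna={"rRNA1": "G" * 60})
        anns, _ = classify_tags([CleanTag(MATURE, {"A": 1})], refs)
        assert anns[0].category == "known_mirna"
        assert anns[0].family == "MIR169"
        assert anns[0].mirna_id == "MIR169-x1"

    def test_unannotated_fallthrough(self):
        refs = _refs(other_ncrna={"rRNA1": "G" * 60})
        anns, _ = classify_tags([CleanTag("TTGACCGGTACCGGTTAACC", {"A": 1})], refs)
        assert anns[0].category == "unannotated"

    def test_repeat_exclusion(self):
        tag = "TGCATGCCATGGCAATTGGC"
        refs = _refs(other_ncrna={"rRNA1": "G" * 60},
                     transcriptome={"U1": ("ACGT" * 10 + tag) * 12})
        anns, _ = classify_tags([CleanTag(tag, {"A": 1})], refs)
        assert anns[0].category == "repeat"

    def test_partition_on_synthetic_bundle(self, small_run):
        """Every unique tag receives exactly one category."""
        import pandas as pd
        out, truth, _ = small_run
        ann = pd.read_csv(out / "annotations.tsv", sep="\t")
        assert ann["tag"].is_unique
        assert ann["category"].notna().all()
        counts = ann["category"].value_counts()
        assert counts.sum() == len(ann)

    def test_planted_truth_recovery(self, small_metrics):
        """>= 95% of planted known miRNAs labelled known_mirna; no planted
        ncRNA fragment ever is."""
        assert small_metrics["known_recall"] >= 0.95
        assert small_metrics["ncrna_false_known"] == 0


def test_reference_set_validation():
    with pytest.raises(Exception):
        ReferenceSet({}, {}, {}, {"c": "ACGT"})
    with pytest.raises(Exception):
        ReferenceSet({"m": "ACGT"}, {}, {}, {"c": "ACGT"})  # mature too short
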