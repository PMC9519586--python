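"""Tier decision table, isoform demotion, and cumulative set semantics."""

import itertools

import pytest

from dsdscreen.ingest import AnnotatedVariant, TranscriptConsequence
from dsdscreen.panel import ClassLabel, TierLabel
from dsdscreen.reference import reported_tier_counts
from dsdscreen.tiers import (
    TierAssignment,
    assign_tier,
    demote_minor_isoform_lof,
    tier_count_matrix,
    tier_sets,
)


def _variant(intervar, clinvar="absent", hgmd="absent", aaf=0.001, **kw):
    ac = int(round(aaf * 100000))
    return AnnotatedVariant(
        "chr1", 100, "A", "G", gene="G1", an=100000, ac=ac,
        intervar=ClassLabel(intervar), clinvar=clinvar, hgmd=hgmd, **kw,
    )


def oracle_tier(intervar, clinvar, hgmd, below_threshold):
    """Independent, literal transcription of the set definitions:
    Set 1 = most conservative pathogenic variants, class P/LP corroborated by
    ClinVar P/LP; Set 2 = all class P and LP variants; Set 3 = Set 2 plus the
    ClinVar P/LP variants among class VUS; Set 4 = Set 3 plus the HGMD
    disease-causing variants among class VUS; VUS rescue requires the
    frequency filter.
    """
    if intervar in ("P", "LP"):
        return "SET1" if clinvar in ("P", "LP") else "SET2"
    if intervar == "VUS" and below_threshold:
        if clinvar in ("P", "LP"):
            return "SET3"
        if hgmd == "DM":
            return "SET4"
    return "NONE"


class TestAssignTier:
    @pytest.mark.parametrize(
        "intervar,clinvar,hgmd,aaf,want",
        [
            ("P", "LP", "absent", 0.001, TierLabel.SET1),
            ("VUS", "P", "absent", 0.05, TierLabel.NONE),  # 0.05 >= 0.03
            ("VUS", "absent", "DM", 0.002, TierLabel.SET4),
            ("LP", "absent", "absent", 0.01, TierLabel.SET2),
            ("VUS", "conflicting", "DM", 0.002, TierLabel.SET4),  # conflicting is not P/LP
            ("VUS", "absent", "other", 0.002, TierLabel.NONE),  # only literal DM rescues
            ("LB", "P", "DM", 0.001, TierLabel.NONE),
            ("B", "P", "DM", 0.001, TierLabel.NONE),
        ],
    )
    def test_examples(self, intervar, clinvar, hgmd, aaf, want):
        a = assign_tier(_variant(intervar, clinvar, hgmd, aaf))
        assert a.tier is want

    @pytest.mark.parametrize("threshold", [0.03, 0.001, 0.5])
    def test_exhaustive_truth_table(self, threshold):
        """All 80 label combinations agree with the independent oracle, for
        any frequency threshold."""
        for intervar, clinvar, hgmd, below in itertools.product(
            ["P", "LP", "VUS", "LB", "B"],
            ["P", "LP", "VUS", "absent"],
            ["DM", "absent"],
            [True, False],
        ):
            aaf = threshold / 2 if below else min(threshold * 1.5, 0.9)
            got = assign_tier(_variant(intervar, clinvar, hgmd, aaf), maf_threshold=threshold)
            assert got.tier.value == oracle_tier(intervar, clinvar, hgmd, below), (
                intervar, clinvar, hgmd, below,
            )

    def test_set1_reasons(self):
        a = assign_tier(_variant("P", "LP"))
        assert {"INTERVAR_PLP", "CLINVAR_PLP"} <= a.reasons

    def test_maf_fail_never_in_set3_set4(self):
        for intervar, clinvar, hgmd in (("VUS", "P", "absent"), ("VUS", "absent", "DM")):
            a = assign_tier(_variant(intervar, clinvar, hgmd, aaf=0.001))
            assert a.tier in (TierLabel.SET3, TierLabel.SET4)
            assert "MAF_FAIL" not in a.reasons

    def test_undefined_aaf_for_vus_is_error(self):
        v = AnnotatedVariant("chr1", 1, "A", "G", an=0, ac=0, intervar=ClassLabel.VUS, clinvar="P")
        with pytest.raises(ValueError, match="undefined aaf"):
            assign_tier(v)


def _trap(major_cons="intronic", minor_cons="stop_gain", w=(10.0, 1.0), intervar="LP",
          criteria=frozenset({"PVS1", "PM2"}), override=None):
    return _variant(
        intervar,
        acmg_criteria=criteria,
        class_without_pvs1=override,
        consequences=(
            TranscriptConsequence("TX_major", major_cons, w[0]),
            TranscriptConsequence("TX_minor", minor_cons, w[1]),
        ),
    )


class TestDemotion:
    def test_minor_isoform_lof_demoted(self):
        v = demote_minor_isoform_lof(_trap())
        assert v.ambiguous_lof and v.pvs1_removed
        assert "PVS1" not in v.acmg_criteria
        assert v.intervar is ClassLabel.VUS
        a = assign_tier(v)
        assert a.ambiguous and {"MINOR_ISOFORM_LOF", "PVS1_REMOVED"} <= a.reasons

    def test_intergenic_major_also_demotes(self):
        v = demote_minor_isoform_lof(_trap(major_cons="intergenic", minor_cons="splice"))
        assert v.ambiguous_lof and v.intervar is ClassLabel.VUS

    def test_lof_on_major_unchanged(self):
        v = _trap(major_cons="stop_gain", minor_cons="intronic")
        assert demote_minor_isoform_lof(v) == v

    def test_missense_everywhere_unchanged(self):
        v = _trap(major_cons="missense", minor_cons="missense")
        assert demote_minor_isoform_lof(v) == v

    def test_weight_tie_blocks_demotion(self):
        v = _trap(w=(10.0, 10.0))
        assert demote_minor_isoform_lof(v) == v

    def test_explicit_reclassification_override(self):
        v = demote_minor_isoform_lof(_trap(override=ClassLabel.LB))
        assert v.intervar is ClassLabel.LB and v.ambiguous_lof

    def test_no_consequences_is_error(self):
        with pytest.raises(ValueError, match="no transcript consequences"):
            demote_minor_isoform_lof(_variant("LP"))

    def test_never_raises_severity_never_adds_criteria(self):
        for v in (_trap(), _trap(major_cons="stop_gain"), _trap(intervar="VUS"),
                  _trap(criteria=frozenset({"PM2"}))):
            out = demote_minor_isoform_lof(v)
            assert out.intervar.severity <= v.intervar.severity
            assert out.acmg_criteria <= v.acmg_criteria


def _assignment(gene, tier, ambiguous=False, pos=1):
    return TierAssignment(("chr1", pos, "A", "G"), gene, TierLabel(tier), ambiguous=ambiguous)


class TestTierSets:
    def test_single_set1_in_all_cumulative_sets(self):
        sets = tier_sets([_assignment("G1", "SET1")])
        assert [len(sets[t]) for t in sets] == [1, 1, 1, 1]

    def test_cumulative_union_counts(self):
        assignments = [
            _assignment("G1", "SET1", pos=1),
            _assignment("G1", "SET2", pos=2),
            _assignment("G2", "SET4", pos=3),
        ]
        sets = tier_sets(assignments)
        assert [len(sets[t]) for t in sets] == [1, 2, 2, 3]

    def test_nesting_invariant(self):
        assignments = [
            _assignment("G1", t, pos=i)
            for i, t in enumerate(["SET1", "SET2", "SET2", "SET3", "SET4", "NONE"])
        ]
        sets = tier_sets(assignments)
        keys = {t: {a.key for a in members} for t, members in sets.items()}
        assert keys[TierLabel.SET1] <= keys[TierLabel.SET2] <= keys[TierLabel.SET3] <= keys[TierLabel.SET4]

    def test_reported_margins_reproduced(self):
        """A fixture engineered to the reported per-gene first-tier counts
        yields the published cumulative set sizes."""
        counts = reported_tier_counts()
        assignments = []
        pos = 0
        for gene, row in counts.iterrows():
            firsts = (
                [("SET1", row.set1), ("SET2", row.set2 - row.set1),
                 ("SET3", row.set3 - row.set2), ("SET4", row.set4 - row.set3)]
            )
            for tier, n in firsts:
                for _ in range(int(n)):
                    pos += 1
                    assignments.append(_assignment(gene, tier, pos=pos))
        sets = tier_sets(assignments)
        assert [len(sets[t]) for t in sets] == [14, 42, 57, 91]
        matrix = tier_count_matrix(assignments, genes=list(counts.index))
        assert matrix["set1"].tolist() == counts["set1"].tolist()
        assert matrix["set4"].tolist() == counts["set4"].tolist()
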