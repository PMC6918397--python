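import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cannamark.calling import VariantCall
from cannamark.proteins import (
    annotate_consequences,
    apply_variants,
    classify_impact,
    codon_of,
    translate,
)
from cannamark.simulate import DELETION_SPAN, PanelConfig, make_references


@pytest.fixture(scope="module")
def refs():
    return make_references(PanelConfig(seed=1))


def _fiber_thcas_variants(panel):
    ref_a = panel.references[0]
    rows = panel.truth.loci
    rows = rows[(rows.gene == "THCAS") & (rows.kind == "snp")]
    return [
        VariantCall("THCAS", int(r.position), "snp", ref_a.cds[r.position - 1], r.fiber_allele)
        for r in rows.itertuples()
    ]


def _drug_cbdas_snps(panel):
    ref_b = panel.references[1]
    rows = panel.truth.loci
    rows = rows[(rows.gene == "CBDAS") & (rows.kind == "snp")]
    return [
        VariantCall("CBDAS", int(r.position), "snp", ref_b.cds[r.position - 1], r.drug_allele)
        for r in rows.itertuples()
    ]


class TestTranslate:
    def test_short_orf(self):
        rec = translate("ATGAAATAA")
        assert rec.aa_sequence == "MK"
        assert rec.stop_codon_index == 3 and not rec.truncated

    def test_full_length_synthase_protein_lengths(self, refs):
        ref_a, ref_b = refs
        assert len(translate(ref_a.cds).aa_sequence) == 545
        assert len(translate(ref_b.cds).aa_sequence) == 544

    def test_premature_stop_truncates_at_codon_195(self, refs):
        _, ref_b = refs
        # the planted drug-type A->T change at position 583 creates a stop
        mutant = ref_b.cds[:582] + "T" + ref_b.cds[583:]
        rec = translate(mutant)
        assert rec.stop_codon_index == 195 and rec.truncated
        assert len(rec.aa_sequence) == 194

    def test_no_stop_flagged(self):
        rec = translate("ATGAAAAAA")
        assert not rec.has_stop and rec.aa_sequence == "MKK"

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            translate("ATGARATAA")


class TestCodonOf:
    @pytest.mark.parametrize(
        "position,codon",
        [(583, 195), (153, 51), (269, 90), (494, 165), (749, 250), (763, 255),
         (1, 1), (3, 1), (4, 2)],
    )
    def test_printed_position_residue_pairs(self, position, codon):
        assert codon_of(position) == codon

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            codon_of(0)


class TestApplyVariants:
    def test_no_variants_returns_reference(self, refs):
        ref_a, _ = refs
        assert apply_variants(ref_a, []) == ref_a.cds

    def test_four_bp_deletion_shortens_and_frameshifts(self, refs):
        _, ref_b = refs
        lo, hi = DELETION_SPAN
        v = VariantCall("CBDAS", lo, "deletion", ref_b.cds[lo - 1 : hi], "")
        mutant = apply_variants(ref_b, [v])
        assert len(mutant) == len(ref_b.cds) - 4
        _, summary = annotate_consequences(ref_b, [v])
        assert summary["frameshift"]

    def test_snp_changes_single_base(self, refs):
        ref_a, _ = refs
        pos = 10
        alt = "A" if ref_a.cds[pos - 1] != "A" else "C"
        mutant = apply_variants(
            ref_a, [VariantCall("THCAS", pos, "snp", ref_a.cds[pos - 1], alt)]
        )
        diffs = [i for i, (a, b) in enumerate(zip(ref_a.cds, mutant)) if a != b]
        assert diffs == [pos - 1]

    def test_het_variant_rejected(self, refs):
        ref_a, _ = refs
        v = VariantCall("THCAS", 10, "snp", ref_a.cds[9], "R", "het")
        with pytest.raises(ValueError, match="eterozygous"):
            apply_variants(ref_a, [v])

    def test_overlapping_variants_rejected(self, refs):
        _, ref_b = refs
        lo, hi = DELETION_SPAN
        vs = [
            VariantCall("CBDAS", lo, "deletion", ref_b.cds[lo - 1 : hi], ""),
            VariantCall("CBDAS", lo + 1, "snp", ref_b.cds[lo], "A" if ref_b.cds[lo] != "A" else "C"),
        ]
        with pytest.raises(ValueError, match="verlapping"):
            apply_variants(ref_b, vs)


class TestAnnotate:
    def test_thcas_mutant_reproduces_design_arithmetic(self, default_panel):
        ref_a = default_panel.references[0]
        variants = _fiber_thcas_variants(default_panel)
        annotations, summary = annotate_consequences(ref_a, variants)
        assert summary["n_snps"] == 25
        assert summary["n_nonsyn"] == 19
        assert summary["n_syn"] == 6
        assert summary["n_aa_changes"] == 18
        assert round(summary["ratio"], 1) == 3.2
        impacts = {a.codon_index: a.impact for a in annotations}
        for codon in (90, 165, 250, 255):
            assert impacts[codon] == "high"

    def test_shared_codon_counting(self, default_panel):
        ref_a = default_panel.references[0]
        variants = _fiber_thcas_variants(default_panel)
        annotations, _ = annotate_consequences(ref_a, variants)
        by_codon = {a.codon_index: a for a in annotations}
        # positions 136/137 share codon 46 and jointly change the amino acid
        assert by_codon[46].contributing_variants == [136, 137]
        assert not by_codon[46].synonymous
        # positions 862/864 share codon 288 and are jointly synonymous
        assert by_codon[288].contributing_variants == [862, 864]
        assert by_codon[288].synonymous

    def test_cbdas_mutant_truncated_at_195(self, default_panel):
        ref_b = default_panel.references[1]
        _, summary = annotate_consequences(ref_b, _drug_cbdas_snps(default_panel))
        assert summary["truncated"]
        assert summary["mutant_stop_codon_index"] == 195

    def test_synonymous_third_position_is_low_impact(self, refs):
        ref_a, _ = refs
        # planted position 300 is a synonymous third-position change
        v = VariantCall("THCAS", 300, "snp", ref_a.cds[299], "A")
        annotations, summary = annotate_consequences(ref_a, [v])
        assert annotations[0].synonymous and annotations[0].impact == "low"
        assert summary["n_syn"] == 1 and summary["n_nonsyn"] == 0

    @pytest.mark.parametrize(
        "ref_aa,alt_aa,impact",
        [
            ("I", "D", "high"),   # hydrophobic -> charged
            ("K", "L", "high"),   # charged -> hydrophobic
            ("I", "S", "moderate"),  # hydrophobic -> polar
            ("P", "A", "moderate"),  # ring/rigid -> fluid
            ("D", "E", "low"),    # charged -> charged
            ("Q", "*", "high"),   # nonsense
        ],
    )
    def test_side_chain_rules(self, ref_aa, alt_aa, impact):
        assert classify_impact(ref_aa, alt_aa) == impact


class TestInvariants:
    def test_translate_after_empty_apply_is_identity(self, refs):
        for ref in refs:
            assert (
                translate(apply_variants(ref, []), ref.name).aa_sequence
                == translate(ref.cds, ref.name).aa_sequence
            )

    @settings(derandomize=True, max_examples=60)
    @given(st.data())
    def test_single_snp_synonymy_iff_identical_proteins(self, data):
        ref_a, _ = make_references(PanelConfig(seed=1))
        pos = data.draw(st.integers(min_value=4, max_value=len(ref_a.cds) - 3))
        ref_base = ref_a.cds[pos - 1]
        alt = data.draw(st.sampled_from([b for b in "ACGT" if b != ref_base]))
        mutant_codon_start = 3 * ((pos - 1) // 3)
        mutant = ref_a.cds[: pos - 1] + alt + ref_a.cds[pos:]
        if mutant[mutant_codon_start : mutant_codon_start + 3] in ("TAA", "TAG", "TGA"):
            return  # nonsense change: protein comparison is about truncation
        v = VariantCall("THCAS", pos, "snp", ref_base, alt)
        annotations, _ = annotate_consequences(ref_a, [v])
        same_protein = (
            translate(mutant).aa_sequence == translate(ref_a.cds).aa_sequence
        )
        assert annotations[0].synonymous == same_protein

    @pytest.mark.parametrize("length,expect_shift", [(1, True), (2, True), (3, False), (4, True), (6, False)])
    def test_frameshift_iff_length_not_multiple_of_three(self, refs, length, expect_shift):
        _, ref_b = refs
        start = 300
        v = VariantCall(
            "CBDAS", start, "deletion", ref_b.cds[start - 1 : start - 1 + length], ""
        )
        _, summary = annotate_consequences(ref_b, [v])
        assert summary["frameshift"] == expect_shift
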