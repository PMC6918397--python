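"""Protein-level consequences of CDS variants.

Translates reference and mutant coding sequences with the standard genetic
code, classifies SNPs as synonymous / non-synonymous, grades amino-acid
substitutions by the chemical nature of the side chains involved, and
detects frameshifts and premature stop codons with truncated-protein
reporting.

Impact grading: hydrophobic <-> charged substitutions are high impact;
hydrophobic <-> polar, and ring/rigid <-> fluid, are moderate; anything
else (including synonymous changes) is low. Substitutions creating or
removing a stop codon are graded high. The residue classes are standard
side-chain groupings and can be overridden per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .calling import ReferenceGene, VariantCall, apply_calls

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
FORWARD_TABLE = dict(_STANDARD.forward_table)
STOP_CODONS = set(_STANDARD.stop_codons)

HYDROPHOBIC = frozenset("AVLIMFWC")
POLAR = frozenset("STNQYG")
CHARGED = frozenset("DEKRH")
RING = frozenset("FWYHP")  # rigid / ring side chains; "fluid" = complement

#: Literature deleteriousness annotations for the two synthases (PROVEAN
#: calls recorded as annotations; not recomputed here).
LITERATURE_DELETERIOUS = {
    "THCAS": (165,),
    "CBDAS": (136, 182),
}


@dataclass
class ProteinRecord:
    gene: str
    aa_sequence: str
    stop_codon_index: int | None  # 1-based codon index of the terminating stop
    truncated: bool
    has_stop: bool = True


@dataclass
class ImpactAnnotation:
    codon_index: int
    ref_aa: str
    alt_aa: str
    synonymous: bool
    impact: str  # "high" | "moderate" | "low"
    contributing_variants: list[int] = field(default_factory=list)


def codon_of(position: int) -> int:
    """Map a 1-based CDS nucleotide position to its 1-based codon index."""
    if position < 1:
        raise ValueError("CDS positions are 1-based")
    return (position + 2) // 3


def _translate_codon(codon: str) -> str:
    if codon in STOP_CODONS:
        return "*"
    return FORWARD_TABLE[codon]


def translate(cds: str, gene: str = "", ref_stop_index: int | None = None) -> ProteinRecord:
    """Translate a CDS, halting at the first in-frame stop.

    ``stop_codon_index`` records the 1-based index of the terminating stop
    codon; a truncated protein is one whose stop precedes ``ref_stop_index``
    (by default the last complete codon of the input, i.e. the position a
    full-length CDS terminates at). If no stop is found the sequence is
    translated to its end and flagged via ``has_stop=False``. Ambiguity
    codes must be resolved upstream.
    """
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    bad = set(cds) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in CDS: {sorted(bad)}")
    n_codons = len(cds) // 3
    if ref_stop_index is None:
        ref_stop_index = n_codons
    aa = []
    stop_index: int | None = None
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        res = _translate_codon(codon)
        if res == "*":
            stop_index = i + 1
            break
        aa.append(res)
    if stop_index is None:
        return ProteinRecord(gene, "".join(aa), None, truncated=False, has_stop=False)
    return ProteinRecord(
        gene, "".join(aa), stop_index, truncated=stop_index < ref_stop_index
    )


def apply_variants(ref: ReferenceGene, variants: list[VariantCall]) -> str:
    """Apply homozygous variants of one gene to its reference CDS.

    Substitutions and indels are applied right-to-left by position so earlier
    coordinates stay valid. Heterozygous or overlapping variants are errors
    (resolve upstream)."""
    for v in variants:
        if v.gene != ref.name:
            raise ValueError(f"variant on {v.gene!r} applied to {ref.name!r}")
        if v.zygosity != "hom":
            raise ValueError(
                f"heterozygous variant at {v.gene}:{v.position} cannot be applied"
            )
        if v.kind == "snp" and v.alt_allele not in "ACGT":
            raise ValueError(f"ambiguous alt allele {v.alt_allele!r} at {v.position}")
        end = v.position + max(len(v.ref_allele), 1) - 1
        if end > len(ref.cds):
            raise ValueError(f"variant at {v.gene}:{v.position} beyond CDS end")
    spans = sorted(
        (v.position, v.position + max(len(v.ref_allele), 1) - 1, v.kind) for v in variants
    )
    for (s1, e1, k1), (s2, e2, k2) in zip(spans, spans[1:]):
        # an insertion at position p sits between p and p+1, so it may share
        # p with a SNP span; true overlaps are errors
        if s2 <= e1 and not (k1 == "insertion" or k2 == "insertion"):
            raise ValueError(f"overlapping variants at positions {s1}-{e1} and {s2}-{e2}")
    return apply_calls(ref.cds, variants, gene=ref.name)


def classify_impact(
    ref_aa: str,
    alt_aa: str,
    hydrophobic=HYDROPHOBIC,
    polar=POLAR,
    charged=CHARGED,
    ring=RING,
) -> str:
    """Grade a substitution by side-chain chemistry (high/moderate/low)."""
    if ref_aa == alt_aa:
        return "low"
    if "*" in (ref_aa, alt_aa):
        return "high"  # nonsense / stop-loss
    both = {ref_aa, alt_aa}
    if (ref_aa in hydrophobic and alt_aa in charged) or (
        ref_aa in charged and alt_aa in hydrophobic
    ):
        return "high"
    if (ref_aa in hydrophobic and alt_aa in polar) or (
        ref_aa in polar and alt_aa in hydrophobic
    ):
        return "moderate"
    if (ref_aa in ring) != (alt_aa in ring):
        return "moderate"
    return "low"


def annotate_consequences(ref: ReferenceGene, variants: list[VariantCall]):
    """Annotate per-codon consequences and summarize a mutant gene.

    SNPs sharing a codon are applied jointly; every SNP in a codon whose
    amino acid changes counts as non-synonymous (two SNPs in one changed
    codon contribute two non-synonymous mutations but one amino-acid
    change). Indels contribute frameshift / in-frame events, not to the
    synonymous accounting. Returns ``(annotations, summary)`` where summary
    holds n_nonsyn, n_syn, ratio, n_aa_changes, frameshift and truncation
    information for the full mutant.
    """
    snps = [v for v in variants if v.kind == "snp"]
    indels = [v for v in variants if v.kind != "snp"]
    for v in variants:
        if v.position > len(ref.cds):
            raise ValueError(f"variant at {v.position} beyond CDS of {ref.name}")

    by_codon: dict[int, list[VariantCall]] = {}
    for v in snps:
        by_codon.setdefault(codon_of(v.position), []).append(v)

    annotations: list[ImpactAnnotation] = []
    n_nonsyn = n_syn = n_aa_changes = 0
    for ci in sorted(by_codon):
        group = by_codon[ci]
        start = 3 * (ci - 1)
        ref_codon = ref.cds[start : start + 3]
        mut = list(ref_codon)
        for v in group:
            if v.zygosity != "hom":
                raise ValueError(
                    f"heterozygous SNP at {v.gene}:{v.position}; resolve upstream"
                )
            mut[(v.position - 1) % 3] = v.alt_allele
        ref_aa = _translate_codon(ref_codon)
        alt_aa = _translate_codon("".join(mut))
        syn = ref_aa == alt_aa
        if syn:
            n_syn += len(group)
        else:
            n_nonsyn += len(group)
            n_aa_changes += 1
        annotations.append(
            ImpactAnnotation(
                codon_index=ci,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                synonymous=syn,
                impact=classify_impact(ref_aa, alt_aa),
                contributing_variants=[v.position for v in group],
            )
        )

    frameshift = any(
        len(v.ref_allele or v.alt_allele) % 3 != 0 for v in indels
    )
    mutant_cds = apply_variants(ref, variants)
    ref_protein = translate(ref.cds, ref.name)
    mutant = translate(
        mutant_cds, ref.name, ref_stop_index=ref_protein.stop_codon_index
    )
    ratio = (n_nonsyn / n_syn) if n_syn else math.inf
    summary = {
        "gene": ref.name,
        "n_snps": len(snps),
        "n_nonsyn": n_nonsyn,
        "n_syn": n_syn,
        "ratio": ratio,
        "n_aa_changes": n_aa_changes,
        "frameshift": frameshift,
        "truncated": mutant.truncated,
        "mutant_stop_codon_index": mutant.stop_codon_index,
        "reference_stop_codon_index": ref_protein.stop_codon_index,
        "literature_deleterious_residues": list(
            LITERATURE_DELETERIOUS.get(ref.name, ())
        ),
    }
    return annotations, summary
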