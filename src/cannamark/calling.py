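"""Variant discovery against a coding-sequence reference.

Each per-sample gene sequence is globally aligned to the reference CDS
(affine gap penalties), differences are emitted as SNP / deletion /
insertion calls in 1-based reference CDS coordinates, and calls across
samples are assembled into a samples x loci categorical genotype matrix.

Coordinate conventions
----------------------
* SNP: ``position`` is the reference base that differs; the alt may be an
  IUPAC ambiguity code, in which case zygosity is ``het``.
* deletion: ``position`` is the first deleted reference base; ``ref_allele``
  holds the deleted bases and ``alt_allele`` is empty.
* insertion: ``position`` is the reference base AFTER WHICH the bases in
  ``alt_allele`` are inserted (``ref_allele`` empty).

Indels are left-normalized, as in standard variant representation, so
coordinates are deterministic inside repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .sequences import AMBIGUOUS_CODES, IUPAC_TO_BASES, SequenceRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}

# default alignment scoring: favors one contiguous gap over scattered
# mismatches (a length-4 deletion costs 5 + 4*2 = 13 < 4 mismatches + context)
DEFAULT_MATCH = 2.0
DEFAULT_MISMATCH = -3.0
DEFAULT_GAP_OPEN = -5.0
DEFAULT_GAP_EXTEND = -2.0


@dataclass(frozen=True)
class ReferenceGene:
    """A named CDS used as the 1-based coordinate system for calls."""

    name: str
    cds: str
    source_label: str = ""

    def __post_init__(self):
        if set(self.cds) - set("ACGT"):
            raise ValueError(f"reference {self.name}: CDS must be plain A/C/G/T")
        if len(self.cds) % 3 != 0:
            raise ValueError(f"reference {self.name}: length not divisible by 3")
        if not self.cds.startswith("ATG"):
            raise ValueError(f"reference {self.name}: CDS must start with ATG")
        codons = [self.cds[i : i + 3] for i in range(0, len(self.cds), 3)]
        stops = [i for i, c in enumerate(codons) if c in STOP_CODONS]
        if stops != [len(codons) - 1]:
            raise ValueError(
                f"reference {self.name}: expected exactly one in-frame stop, at the end"
            )

    def __len__(self) -> int:
        return len(self.cds)


@dataclass(frozen=True)
class VariantCall:
    gene: str
    position: int  # 1-based reference CDS coordinate
    kind: str  # "snp" | "deletion" | "insertion"
    ref_allele: str
    alt_allele: str
    zygosity: str = "hom"  # "hom" | "het"

    def __post_init__(self):
        if self.kind == "snp":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("SNP alleles must be single characters")
            if self.ref_allele == self.alt_allele:
                raise ValueError("SNP ref and alt alleles must differ")
        elif self.kind == "deletion":
            if self.alt_allele or not self.ref_allele:
                raise ValueError("deletion must have empty alt and non-empty ref")
        elif self.kind == "insertion":
            if self.ref_allele or not self.alt_allele:
                raise ValueError("insertion must have empty ref and non-empty alt")
        else:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.position < 0 or (self.kind != "insertion" and self.position < 1):
            raise ValueError("variant position out of range")
        if self.zygosity not in ("hom", "het"):
            raise ValueError("zygosity must be 'hom' or 'het'")

    @property
    def locus_key(self) -> str:
        return f"{self.gene}:{self.position}:{self.kind}"


def locus_key(gene: str, position: int, kind: str) -> str:
    return f"{gene}:{position}:{kind}"


@dataclass
class GenotypeMatrix:
    """Samples x loci categorical genotypes plus binary class labels.

    ``cells`` holds allele symbols: a base or IUPAC code at SNP loci and
    ``"del"``/``"ins"``/``"ref"`` at indel loci; ``"ref"`` wherever a sample
    has no call. ``loci`` is indexed by the same keys as the columns of
    ``cells`` and carries (gene, position, kind).
    """

    cells: pd.DataFrame
    labels: pd.Series  # index = sample ids, values in {"drug", "fiber"}
    loci: pd.DataFrame  # index = locus keys; columns gene, position, kind

    def __post_init__(self):
        if not self.cells.columns.equals(self.loci.index):
            raise ValueError("cells columns and loci index disagree")
        if not self.cells.index.equals(self.labels.index):
            raise ValueError("cells index and labels index disagree")
        bad = set(self.labels.unique()) - {"drug", "fiber"}
        if bad:
            raise ValueError(f"labels must be 'drug'/'fiber'; got {bad}")

    @property
    def samples(self) -> list[str]:
        return list(self.cells.index)

    def subset_loci(self, keys) -> "GenotypeMatrix":
        keys = list(keys)
        return GenotypeMatrix(self.cells[keys], self.labels, self.loci.loc[keys])

    def subset_samples(self, ids) -> "GenotypeMatrix":
        ids = list(ids)
        return GenotypeMatrix(self.cells.loc[ids], self.labels.loc[ids], self.loci)


def _aligner(match, mismatch, gap_open, gap_extend) -> Align.PairwiseAligner:
    alphabet = "".join(sorted(IUPAC_TO_BASES))
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            overlap = IUPAC_TO_BASES[a] & IUPAC_TO_BASES[b]
            mat[a, b] = match if overlap else mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    # biopython's open_gap_score is the score of the first gap position, so a
    # length-L gap totals gap_open + L * gap_extend under this setting
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def align_global(
    sample: SequenceRecord,
    ref: ReferenceGene,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
):
    """Optimal global alignment of a sample sequence to the reference CDS.

    IUPAC codes in the sample score as matches against any base they contain.
    Returns a ``Bio.Align.Alignment`` (reference is the target, sample the
    query); the first optimal alignment under biopython's canonical traceback
    order is taken, so the result is deterministic.
    """
    if not sample.bases or not ref.cds:
        raise ValueError("cannot align empty sequences")
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    return next(iter(aligner.align(ref.cds, sample.bases.replace("-", ""))))


def _left_normalize_deletion(ref: str, pos: int, deleted: str) -> tuple[int, str]:
    # shift a deletion left while the base preceding it equals its last base
    while pos > 1 and ref[pos - 2] == deleted[-1]:
        deleted = ref[pos - 2] + deleted[:-1]
        pos -= 1
    return pos, deleted


def _left_normalize_insertion(ref: str, pos: int, inserted: str) -> tuple[int, str]:
    # insertion after pos; shift left while ref[pos] equals the last inserted base
    while pos > 0 and ref[pos - 1] == inserted[-1]:
        inserted = ref[pos - 1] + inserted[:-1]
        pos -= 1
    return pos, inserted


def call_variants(alignment, ref: ReferenceGene) -> list[VariantCall]:
    """Emit SNP and indel calls from a global alignment to the reference.

    Adjacent gap columns are merged into a single indel; indels are
    left-normalized; an IUPAC ambiguity code at a SNP yields ``het`` zygosity.
    """
    ref_aln = str(alignment[0])
    sam_aln = str(alignment[1])
    if ref_aln.replace("-", "") != ref.cds:
        raise ValueError("alignment does not cover the full reference CDS")
    calls: list[VariantCall] = []
    ref_pos = 0  # last consumed 1-based reference position
    i = 0
    n = len(ref_aln)
    while i < n:
        r, s = ref_aln[i], sam_aln[i]
        if r != "-" and s != "-":
            ref_pos += 1
            if r != s:
                zyg = "het" if s in AMBIGUOUS_CODES else "hom"
                calls.append(
                    VariantCall(ref.name, ref_pos, "snp", r, s, zyg)
                )
            i += 1
        elif s == "-":  # deletion run in sample
            start = ref_pos + 1
            deleted = []
            while i < n and sam_aln[i] == "-":
                deleted.append(ref_aln[i])
                ref_pos += 1
                i += 1
            pos, dseq = _left_normalize_deletion(ref.cds, start, "".join(deleted))
            calls.append(VariantCall(ref.name, pos, "deletion", dseq, ""))
        else:  # insertion run in sample (gap in reference)
            inserted = []
            while i < n and ref_aln[i] == "-":
                inserted.append(sam_aln[i])
                i += 1
            pos, iseq = _left_normalize_insertion(ref.cds, ref_pos, "".join(inserted))
            calls.append(VariantCall(ref.name, pos, "insertion", "", iseq))
    calls.sort(key=lambda c: (c.position, c.kind))
    return calls


def apply_calls(ref_cds: str, calls, gene: str | None = None) -> str:
    """Apply calls (right-to-left) to a reference CDS string.

    Heterozygous SNPs are written as their IUPAC code, so applying the calls
    emitted by :func:`call_variants` reconstructs the aligned sample sequence
    exactly. Used by the simulator and by round-trip checks.
    """
    seq = list(ref_cds)
    ordered = sorted(calls, key=lambda c: (-c.position, c.kind))
    for c in ordered:
        if gene is not None and c.gene != gene:
            raise ValueError(f"call on gene {c.gene!r} applied to {gene!r}")
        if c.kind == "snp":
            if seq[c.position - 1] != c.ref_allele:
                raise ValueError(
                    f"ref allele mismatch at {c.gene}:{c.position}: "
                    f"expected {c.ref_allele!r}, found {seq[c.position - 1]!r}"
                )
            seq[c.position - 1] = c.alt_allele
        elif c.kind == "deletion":
            span = "".join(seq[c.position - 1 : c.position - 1 + len(c.ref_allele)])
            if span != c.ref_allele:
                raise ValueError(
                    f"deleted bases at {c.gene}:{c.position} do not match reference"
                )
            del seq[c.position - 1 : c.position - 1 + len(c.ref_allele)]
        else:  # insertion after position
            seq[c.position : c.position] = list(c.alt_allele)
    return "".join(seq)


def build_matrix(
    calls_by_sample,
    labels: dict | pd.Series,
    loci: list[tuple[str, int, str]] | None = None,
) -> GenotypeMatrix:
    """Assemble per-sample calls into a samples x loci genotype matrix.

    ``calls_by_sample`` is an iterable of ``(sample_id, [VariantCall])``
    pairs (or a mapping). Cells default to ``"ref"`` where a sample has no
    call; indel loci are encoded presence/absence (``"del"``/``"ins"`` vs
    ``"ref"``). ``loci`` optionally restricts/reorders the columns.
    """
    if hasattr(calls_by_sample, "items"):
        pairs = list(calls_by_sample.items())
    else:
        pairs = list(calls_by_sample)
    sample_ids = [s for s, _ in pairs]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = {s for s in sample_ids if sample_ids.count(s) > 1}
        raise ValueError(f"duplicate sample ids: {sorted(dupes)}")

    if loci is None:
        seen: dict[tuple[str, int, str], None] = {}
        for _, calls in pairs:
            for c in calls:
                seen[(c.gene, c.position, c.kind)] = None
        loci = sorted(seen)
    keys = [locus_key(*t) for t in loci]
    loci_df = pd.DataFrame(loci, columns=["gene", "position", "kind"], index=keys)

    cells = pd.DataFrame("ref", index=sample_ids, columns=keys, dtype=object)
    for sample_id, calls in pairs:
        for c in calls:
            key = c.locus_key
            if key not in cells.columns:
                continue  # outside the requested locus restriction
            if c.kind == "snp":
                cells.at[sample_id, key] = c.alt_allele
            elif c.kind == "deletion":
                cells.at[sample_id, key] = "del"
            else:
                cells.at[sample_id, key] = "ins"

    labels = pd.Series(labels).reindex(sample_ids)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])
        raise ValueError(f"samples without class labels: {missing}")
    return GenotypeMatrix(cells=cells, labels=labels, loci=loci_df)


def write_variant_table(calls_by_sample, path):
    """Write calls as a TSV with columns sample, gene, pos, kind, ref, alt, zygosity."""
    rows = []
    items = calls_by_sample.items() if hasattr(calls_by_sample, "items") else calls_by_sample
    for sample_id, calls in items:
        for c in calls:
            rows.append(
                (sample_id, c.gene, c.position, c.kind, c.ref_allele, c.alt_allele, c.zygosity)
            )
    df = pd.DataFrame(
        rows, columns=["sample", "gene", "pos", "kind", "ref", "alt", "zygosity"]
    )
    df.to_csv(path, sep="\t", index=False)
    return path
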