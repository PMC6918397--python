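"""FASTA input/output and Sanger-style consensus merging.

Sanger genotyping of a diploid yields a single trace per strand; a
heterozygous site shows two overlapping peaks and is conventionally recorded
as the IUPAC ambiguity code of the observed base pair (e.g. ``R`` for A/G).
This module reads and writes such sequences and merges co-aligned
forward/reverse reads into one per-sample consensus.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

#: The 15 standard IUPAC nucleotide codes mapped to their base sets.
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}

#: Ambiguity codes denoting more than one base (heterozygous or uncertain).
AMBIGUOUS_CODES = frozenset(c for c, s in IUPAC_TO_BASES.items() if len(s) > 1)

VALID_CHARS = frozenset(IUPAC_TO_BASES) | {"-"}


class FastaParseError(ValueError):
    """Raised when a FASTA record contains an illegal character or header."""


@dataclass
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,-, IUPAC codes}.

    ``gene`` is parsed from ids of the form ``sample|gene`` (the convention
    used for per-sample gene sequences) and is empty otherwise.
    """

    id: str
    bases: str
    gene: str = field(default="")

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaParseError("sequence record has an empty id")
        if not self.bases:
            raise FastaParseError(f"record {self.id!r} has an empty sequence")
        for i, ch in enumerate(self.bases):
            if ch not in VALID_CHARS:
                raise FastaParseError(
                    f"record {self.id!r}: illegal character {ch!r} at position {i + 1}"
                )
        if not self.gene and "|" in self.id:
            self.gene = self.id.split("|", 1)[1]

    @property
    def sample(self) -> str:
        return self.id.split("|", 1)[0]


def _normalize(raw: str) -> str:
    return raw.upper().replace("U", "T")


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Sequences are uppercased and RNA ``U`` is normalized to ``T``. Duplicate
    ids and characters outside the IUPAC-plus-gap alphabet raise
    :class:`FastaParseError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, bases=_normalize(str(rec.seq))))
    if not records:
        raise FastaParseError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path, width: int = 70):
    """Write records as wrapped FASTA; returns the path written."""
    bio = [
        _BioRecord(Seq(r.bases), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)
    return path


def merge_reads(reads: list[SequenceRecord], min_agreement: float = 1.0) -> SequenceRecord:
    """Merge co-aligned reads of one sample into a consensus sequence.

    Per column: if a single base reaches ``min_agreement`` among the non-gap
    symbols it is emitted; otherwise the IUPAC code of the union of observed
    base sets is emitted. All-gap columns are removed. Reads must be
    pre-aligned to equal length (gaps allowed) and on the same strand;
    reverse-complementing reverse reads is the caller's responsibility.
    """
    if not reads:
        raise ValueError("merge_reads requires at least one read")
    if not 0.0 < min_agreement <= 1.0:
        raise ValueError("min_agreement must be in (0, 1]")
    length = len(reads[0].bases)
    for r in reads:
        if len(r.bases) != length:
            raise ValueError(
                f"reads are not co-aligned: {reads[0].id!r} has length {length}, "
                f"{r.id!r} has length {len(r.bases)}"
            )
    out: list[str] = []
    for col in zip(*(r.bases for r in reads)):
        symbols = [c for c in col if c != "-"]
        if not symbols:
            continue  # all-gap column: drop
        counts = Counter(symbols)
        # deterministic tie-break: highest count, then alphabetical
        best, n_best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(IUPAC_TO_BASES[best]) == 1 and n_best / len(symbols) >= min_agreement:
            out.append(best)
        else:
            union = frozenset().union(*(IUPAC_TO_BASES[c] for c in symbols))
            out.append(BASES_TO_IUPAC[union])
    if not out:
        warnings.warn("consensus is empty (all columns were gaps)")
        raise ValueError("consensus of all-gap reads is empty")
    return SequenceRecord(id=reads[0].id, bases="".join(out), gene=reads[0].gene)
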