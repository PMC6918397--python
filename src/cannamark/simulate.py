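"""Synthetic marker panels for the two cannabinoid synthase genes.

Generates a pair of reference coding sequences standing in for the
drug-type THCAS and fiber-type CBDAS references, a panel of drug-type and
fiber-type plants and seeds carrying planted discriminating variants, the
corresponding per-sample FASTA sequences and metadata, a ground-truth
marker table, and a per-variety chemotype (THC/CBD) table.

The generator's defaults encode the study conditions the downstream
analysis assumes:

* 47 drug-type + 50 fiber-type plants (11 and 10 varieties) plus
  20 + 50 seeds — 167 samples in total;
* 25 homozygous discriminating SNPs in the THCAS-like gene and 8 in the
  CBDAS-like gene, at the published CDS positions;
* a 4-bp deletion (CGTA, positions 153-156) plus a 3-bp insertion (AAC
  after position 755) in the CBDAS-like gene of drug-type samples;
* occasional heterozygous sites (IUPAC codes) in drug samples and
  per-sample background variation at non-marker sites;
* drug-type THC between 2.08% and 11.80% of dry weight, fiber-type THC
  at most 0.31%.

The planted THCAS alleles follow a fixed codon design so that the mutant
gene carrying all 25 SNPs shows 19 non-synonymous and 6 synonymous
mutations producing 18 amino-acid changes (two SNPs share codon 46, which
changes; two share codon 288, which does not), with high-impact
substitutions at codons 90, 165, 250 and 255. The CBDAS design plants an
A→T change at position 583 creating a premature stop at codon 195, and
Arg/His and Gly/Ala changes at codons 136 and 182.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .calling import (
    GenotypeMatrix,
    ReferenceGene,
    VariantCall,
    apply_calls,
    build_matrix,
)
from .proteins import STOP_CODONS, _translate_codon
from .sequences import BASES_TO_IUPAC, SequenceRecord

GENE_A = "THCAS"  # reference is drug-type; fiber samples carry the alt alleles
GENE_B = "CBDAS"  # reference is fiber-type; drug samples carry the alt alleles

#: Published discriminating SNP positions (1-based CDS coordinates).
THCAS_MARKER_POSITIONS: tuple[int, ...] = (
    136, 137, 154, 221, 269, 287, 300, 355, 383, 385, 409, 412, 418,
    424, 494, 505, 612, 678, 699, 744, 749, 763, 862, 864, 869,
)
CBDAS_MARKER_POSITIONS: tuple[int, ...] = (407, 545, 583, 588, 613, 637, 688, 704)

# codons forced in the reference so the planted alleles realize the intended
# synonymous/non-synonymous and side-chain-impact design (see module docstring)
_FORCED_CODONS_A = {
    46: "GCT",   # +136T,+137A jointly -> TAT (Ala->Tyr): 2 nonsyn, 1 aa change
    90: "ATA",   # 269 T->A -> AAA: Ile->Lys, hydrophobic->charged (high)
    100: "GCT",  # 300 third position, 4-fold: synonymous
    165: "ATA",  # 494 -> Ile->Lys (high)
    204: "GCT",  # 612 synonymous
    226: "GCT",  # 678 synonymous
    233: "GCT",  # 699 synonymous
    248: "ATA",  # 744 third position A->G -> ATG: Ile->Met (non-synonymous)
    250: "ATA",  # 749 -> Ile->Lys (high)
    255: "CGT",  # 763 C->T -> TGT: Arg->Cys, charged->hydrophobic (high)
    288: "CTG",  # +862T,+864A jointly -> TTA: Leu->Leu, 2 synonymous SNPs
}
_FIXED_ALTS_A = {
    136: "T", 137: "A", 269: "A", 300: "A", 494: "A", 612: "A", 678: "A",
    699: "A", 744: "G", 749: "A", 763: "T", 862: "T", 864: "A",
}
_FORCED_CODONS_B = {
    51: "CTC",   # Leu51; position 153 is its third base "C"
    52: "GTA",   # Val52 = positions 154-156, so 153-156 spell CGTA
    136: "CGC",  # 407 G->A -> CAC: Arg136His
    182: "GGA",  # 545 G->C -> GCA: Gly182Ala
    195: "AAA",  # 583 A->T -> TAA: premature stop at codon 195
    196: "ATA",  # 588 is its third base; A->G -> ATG keeps the change non-synonymous
    252: "TGG",  # keeps the AAC insertion after 755 left-normalization-stable
}
_FIXED_ALTS_B = {407: "A", 545: "C", 583: "T"}

DELETION_SPAN = (153, 156)
DELETED_BASES = "CGTA"
INSERTION_POSITION = 755
INSERTED_BASES = "AAC"

_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

DRUG_THC_RANGE = (2.08, 11.80)  # % dry weight, drug-type plants
FIBER_THC_MAX = 0.31            # % dry weight, fiber-type bound


class ConfigurationError(ValueError):
    """Raised for an invalid :class:`PanelConfig`."""


@dataclass(frozen=True)
class PanelConfig:
    seed: int = 0
    n_drug_plants: int = 47
    n_fiber_plants: int = 50
    n_drug_seeds: int = 20
    n_fiber_seeds: int = 50
    n_drug_varieties: int = 11
    n_fiber_varieties: int = 10
    gene_lengths: tuple[int, int] = (1638, 1635)  # THCAS-like, CBDAS-like
    n_disc_snps_geneA: int = 25
    n_disc_snps_geneB: int = 8
    het_rate: float = 0.002
    background_mutation_rate: float = 0.0005
    deletion_span: tuple[int, int] = DELETION_SPAN
    insertion: tuple[int, str] = (INSERTION_POSITION, INSERTED_BASES)
    indel_discordance_rate: float = 0.0
    het_rate_planted: float = 0.0  # off by default: markers are homozygous

    def __post_init__(self):
        counts = (
            self.n_drug_plants, self.n_fiber_plants,
            self.n_drug_seeds, self.n_fiber_seeds,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("sample counts must be non-negative")
        if self.n_drug_varieties < 1 or self.n_fiber_varieties < 1:
            raise ConfigurationError("need at least one variety per class")
        for length in self.gene_lengths:
            if length % 3 != 0:
                raise ConfigurationError(
                    f"gene length {length} is not divisible by 3"
                )
        for rate in (
            self.het_rate, self.background_mutation_rate,
            self.indel_discordance_rate, self.het_rate_planted,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"rate {rate} outside [0, 1]")
        if self.deletion_span[1] - self.deletion_span[0] + 1 != 4:
            raise ConfigurationError("deletion span must cover 4 positions")
        posA = self.geneA_positions
        posB = self.geneB_positions
        for positions, length, gene in (
            (posA, self.gene_lengths[0], GENE_A),
            (posB, self.gene_lengths[1], GENE_B),
        ):
            if len(set(positions)) != len(positions):
                raise ConfigurationError(f"{gene}: duplicate marker positions")
            if any(p < 4 or p > length - 3 for p in positions):
                raise ConfigurationError(
                    f"{gene}: marker positions must lie inside the CDS "
                    "(outside start and stop codons)"
                )

    @property
    def geneA_positions(self) -> tuple[int, ...]:
        return _marker_positions(
            THCAS_MARKER_POSITIONS, self.n_disc_snps_geneA, self.gene_lengths[0]
        )

    @property
    def geneB_positions(self) -> tuple[int, ...]:
        return _marker_positions(
            CBDAS_MARKER_POSITIONS, self.n_disc_snps_geneB, self.gene_lengths[1]
        )


def _marker_positions(published: tuple[int, ...], n: int, length: int) -> tuple[int, ...]:
    """First ``n`` published positions, extended with evenly spaced extras."""
    if n <= len(published):
        return published[:n]
    extra = []
    p = 901  # beyond every published position
    used = set(published)
    while len(extra) < n - len(published) and p <= length - 3:
        if p not in used:
            extra.append(p)
            used.add(p)
        p += 7
    if len(published) + len(extra) < n:
        raise ConfigurationError("cannot place that many marker positions")
    return published + tuple(extra)


@dataclass
class TruthTable:
    """Ground truth for a simulated panel.

    ``loci`` records each planted marker (gene, position, kind, drug and
    fiber alleles, planted flag). ``sample_variants`` holds every variant
    each emitted sequence carries relative to the references, including
    background and heterozygous variation. ``indel_carriage`` flags per
    sample whether the CBDAS-like deletion and insertion are present.
    """

    loci: pd.DataFrame
    sample_variants: dict[str, list[VariantCall]]
    indel_carriage: pd.DataFrame

    def planted_snp_keys(self, gene: str | None = None) -> list[str]:
        df = self.loci[(self.loci["kind"] == "snp") & self.loci["planted"]]
        if gene is not None:
            df = df[df["gene"] == gene]
        return [f"{g}:{p}:snp" for g, p in zip(df["gene"], df["position"])]


@dataclass
class SimulatedPanel:
    config: PanelConfig
    references: tuple[ReferenceGene, ReferenceGene]
    records: list[SequenceRecord]  # one per sample per gene, id "sample|gene"
    metadata: pd.DataFrame  # sample_id, variety, class, tissue
    matrix: GenotypeMatrix
    truth: TruthTable


def _random_cds(rng: np.random.Generator, length: int, forced: dict[int, str]) -> str:
    n_codons = length // 3
    codons = list(rng.choice(_SENSE_CODONS, size=n_codons))
    codons[0] = "ATG"
    codons[-1] = "TAA"
    for ci, codon in forced.items():
        if 1 < ci < n_codons:
            codons[ci - 1] = codon
    return "".join(codons)


def _nonsyn_alt(cds: str, position: int) -> str:
    """First alt base (ACGT order) giving a non-synonymous, non-stop codon."""
    ci = (position + 2) // 3
    start = 3 * (ci - 1)
    ref_codon = cds[start : start + 3]
    offset = (position - 1) % 3
    ref_aa = _translate_codon(ref_codon)
    for base in "ACGT":
        if base == ref_codon[offset]:
            continue
        mut = ref_codon[:offset] + base + ref_codon[offset + 1 :]
        if mut in STOP_CODONS:
            continue
        if _translate_codon(mut) != ref_aa:
            return base
    raise ConfigurationError(
        f"no non-synonymous substitution available at position {position}"
    )


def make_references(config: PanelConfig) -> tuple[ReferenceGene, ReferenceGene]:
    """Generate the drug-type THCAS-like and fiber-type CBDAS-like references.

    Deterministic for a given seed: both CDSs start with ATG, end with a
    single stop codon and contain none internally. Codons touched by the
    planted marker design are fixed so the design is realizable.
    """
    rng = np.random.default_rng(config.seed)
    cds_a = _random_cds(rng, config.gene_lengths[0], _FORCED_CODONS_A)
    cds_b = _random_cds(rng, config.gene_lengths[1], _FORCED_CODONS_B)
    ref_a = ReferenceGene(GENE_A, cds_a, source_label="synthetic drug-type reference")
    ref_b = ReferenceGene(GENE_B, cds_b, source_label="synthetic fiber-type reference")
    return ref_a, ref_b


def _planted_alts(cds: str, positions, fixed: dict[int, str]) -> dict[int, str]:
    alts = {}
    for p in positions:
        alts[p] = fixed.get(p) or _nonsyn_alt(cds, p)
        if alts[p] == cds[p - 1]:
            raise ConfigurationError(f"planted alt equals reference base at {p}")
    return alts


def _variety_assignment(n_samples: int, n_varieties: int, prefix: str) -> list[str]:
    return [f"{prefix}-{i % n_varieties + 1:02d}" for i in range(n_samples)]


def _het_code(ref_base: str, other: str) -> str:
    return BASES_TO_IUPAC[frozenset((ref_base, other))]


def simulate_panel(config: PanelConfig | None = None) -> SimulatedPanel:
    """Simulate the full genotyped panel with ground truth.

    Every drug sample carries the drug alleles at all planted loci and
    (unless discordant) both CBDAS-like indels; fiber samples carry the
    fiber alleles and neither indel. Heterozygous sites are encoded as
    IUPAC codes. The emitted sequences, genotype matrix and truth table are
    mutually consistent by construction.
    """
    config = config or PanelConfig()
    ref_a, ref_b = make_references(config)
    rng = np.random.default_rng([config.seed, 1])

    alts_a = _planted_alts(ref_a.cds, config.geneA_positions, _FIXED_ALTS_A)
    alts_b = _planted_alts(ref_b.cds, config.geneB_positions, _FIXED_ALTS_B)

    del_start, del_end = config.deletion_span
    ins_pos, ins_seq = config.insertion
    deleted_ref = ref_b.cds[del_start - 1 : del_end]

    # loci truth records: gene A ref is drug-type, gene B ref is fiber-type
    loci_rows = []
    for p in config.geneA_positions:
        loci_rows.append((GENE_A, p, "snp", ref_a.cds[p - 1], alts_a[p], True))
    for p in config.geneB_positions:
        loci_rows.append((GENE_B, p, "snp", alts_b[p], ref_b.cds[p - 1], True))
    loci_rows.append((GENE_B, del_start, "deletion", "del", "ref", True))
    loci_rows.append((GENE_B, ins_pos, "insertion", "ins", "ref", True))
    loci = pd.DataFrame(
        loci_rows,
        columns=["gene", "position", "kind", "drug_allele", "fiber_allele", "planted"],
    )

    # positions background/het variation must not touch
    protected = {
        GENE_A: set(config.geneA_positions) | {1, 2, 3}
        | set(range(config.gene_lengths[0] - 2, config.gene_lengths[0] + 1)),
        GENE_B: set(config.geneB_positions) | {1, 2, 3}
        | set(range(config.gene_lengths[1] - 2, config.gene_lengths[1] + 1))
        | set(range(del_start - 1, del_end + 2))
        | {ins_pos, ins_pos + 1},
    }

    meta_rows = []
    counter = {"drug": 0, "fiber": 0}
    groups = [
        ("drug", "leaf", config.n_drug_plants),
        ("fiber", "leaf", config.n_fiber_plants),
        ("drug", "seed", config.n_drug_seeds),
        ("fiber", "seed", config.n_fiber_seeds),
    ]
    for klass, tissue, n in groups:
        n_var = config.n_drug_varieties if klass == "drug" else config.n_fiber_varieties
        prefix = "Drug" if klass == "drug" else "Fiber"
        varieties = _variety_assignment(n, n_var, prefix)
        for v in varieties:
            counter[klass] += 1
            sid = f"{'D' if klass == 'drug' else 'F'}{counter[klass]:03d}"
            meta_rows.append((sid, v, klass, tissue))
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "variety", "class", "tissue"]
    )

    refs = {GENE_A: ref_a, GENE_B: ref_b}
    records: list[SequenceRecord] = []
    sample_variants: dict[str, list[VariantCall]] = {}
    indel_rows = []
    for sid, _, klass, _ in metadata.itertuples(index=False):
        calls: list[VariantCall] = []
        # planted SNP alleles for the non-reference class of each gene
        if klass == "fiber":
            for p in config.geneA_positions:
                calls.append(VariantCall(GENE_A, p, "snp", ref_a.cds[p - 1], alts_a[p]))
        else:
            for p in config.geneB_positions:
                calls.append(VariantCall(GENE_B, p, "snp", ref_b.cds[p - 1], alts_b[p]))
        # indels: drug samples carry both unless discordant
        has_del = has_ins = False
        if klass == "drug":
            has_del = has_ins = True
            if rng.random() < config.indel_discordance_rate:
                if rng.random() < 0.5:
                    has_ins = False
                else:
                    has_del = False
            if has_del:
                calls.append(VariantCall(GENE_B, del_start, "deletion", deleted_ref, ""))
            if has_ins:
                calls.append(VariantCall(GENE_B, ins_pos, "insertion", "", ins_seq))
        indel_rows.append((sid, has_del, has_ins))

        # heterozygous sites at planted loci (off by default)
        if klass == "drug" and config.het_rate_planted > 0:
            for i, c in enumerate(list(calls)):
                if c.kind == "snp" and rng.random() < config.het_rate_planted:
                    code = _het_code(c.ref_allele, c.alt_allele)
                    calls[i] = replace(c, alt_allele=code, zygosity="het")

        taken = {(c.gene, c.position) for c in calls}
        for gene, ref in refs.items():
            length = len(ref.cds)
            # private homozygous background variation, any sample
            if config.background_mutation_rate > 0:
                hits = np.flatnonzero(
                    rng.random(length) < config.background_mutation_rate
                ) + 1
                for p in hits:
                    p = int(p)
                    if p in protected[gene] or (gene, p) in taken:
                        continue
                    ref_base = ref.cds[p - 1]
                    alt = "ACGT".replace(ref_base, "")[rng.integers(3)]
                    calls.append(VariantCall(gene, p, "snp", ref_base, alt))
                    taken.add((gene, p))
            # heterozygous non-marker sites in drug samples
            if klass == "drug" and config.het_rate > 0:
                hits = np.flatnonzero(rng.random(length) < config.het_rate) + 1
                for p in hits:
                    p = int(p)
                    if p in protected[gene] or (gene, p) in taken:
                        continue
                    ref_base = ref.cds[p - 1]
                    other = "ACGT".replace(ref_base, "")[rng.integers(3)]
                    calls.append(
                        VariantCall(
                            gene, p, "snp", ref_base, _het_code(ref_base, other), "het"
                        )
                    )
                    taken.add((gene, p))

        sample_variants[sid] = sorted(calls, key=lambda c: (c.gene, c.position, c.kind))
        for gene, ref in refs.items():
            bases = apply_calls(
                ref.cds, [c for c in calls if c.gene == gene], gene=gene
            )
            records.append(SequenceRecord(id=f"{sid}|{gene}", bases=bases, gene=gene))

    truth = TruthTable(
        loci=loci,
        sample_variants=sample_variants,
        indel_carriage=pd.DataFrame(
            indel_rows, columns=["sample_id", "deletion", "insertion"]
        ).set_index("sample_id"),
    )
    labels = metadata.set_index("sample_id")["class"]
    matrix = build_matrix(sample_variants, labels)
    return SimulatedPanel(
        config=config,
        references=(ref_a, ref_b),
        records=records,
        metadata=metadata,
        matrix=matrix,
        truth=truth,
    )


def simulate_chemotable(config: PanelConfig | None = None) -> pd.DataFrame:
    """Simulate a per-variety chemotype table (% of inflorescence dry weight).

    Drug varieties draw mean THC uniformly within the observed drug-type
    range and a THC/CBD ratio well above the drug/fiber boundary; fiber
    varieties draw THC below the fiber-type bound with ratios in the
    published fiber band (0.05-0.18), occasionally a cannabinoid-null
    variety. Standard deviations are drawn as fractions of the means.
    """
    config = config or PanelConfig()
    rng = np.random.default_rng([config.seed, 2])
    n_per = {}
    for klass, n_samples, n_var, prefix in (
        ("drug", config.n_drug_plants, config.n_drug_varieties, "Drug"),
        ("fiber", config.n_fiber_plants, config.n_fiber_varieties, "Fiber"),
    ):
        for v in _variety_assignment(n_samples, n_var, prefix):
            n_per[v] = n_per.get(v, 0) + 1
    rows = []
    for variety, n_plants in n_per.items():
        if variety.startswith("Drug"):
            thc = rng.uniform(*DRUG_THC_RANGE)
            ratio = rng.uniform(3.0, 52.0)
            cbd = thc / ratio
            klass = "drug"
        else:
            thc = rng.uniform(0.0, FIBER_THC_MAX)
            if thc < 0.01:
                thc, cbd = 0.0, 0.0  # cannabinoid-null hemp variety
            else:
                cbd = thc / rng.uniform(0.05, 0.18)
            klass = "fiber"
        sd_thc = thc * rng.uniform(0.05, 0.5)
        sd_cbd = cbd * rng.uniform(0.05, 0.5)
        rows.append(
            (variety, n_plants, round(cbd, 2), round(sd_cbd, 2),
             round(thc, 2), round(sd_thc, 2), klass)
        )
    return pd.DataFrame(
        rows, columns=["variety", "n_plants", "CBD", "SD_CBD", "THC", "SD_THC", "class"]
    )


def write_panel(panel: SimulatedPanel, outdir) -> dict[str, str]:
    """Write references, sample FASTA, metadata, genotype matrix and truth."""
    import os

    from .calling import write_variant_table
    from .sequences import write_fasta

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    ref_a, ref_b = panel.references
    paths["references"] = str(
        write_fasta(
            [SequenceRecord(ref_a.name, ref_a.cds), SequenceRecord(ref_b.name, ref_b.cds)],
            os.path.join(outdir, "references.fasta"),
        )
    )
    paths["samples"] = str(
        write_fasta(panel.records, os.path.join(outdir, "samples.fasta"))
    )
    meta_path = os.path.join(outdir, "metadata.csv")
    panel.metadata.to_csv(meta_path, index=False)
    paths["metadata"] = meta_path
    matrix_path = os.path.join(outdir, "genotypes.csv")
    panel.matrix.cells.to_csv(matrix_path)
    paths["genotypes"] = matrix_path
    truth_path = os.path.join(outdir, "truth_loci.tsv")
    panel.truth.loci.to_csv(truth_path, sep="\t", index=False)
    paths["truth_loci"] = truth_path
    paths["truth_variants"] = str(
        write_variant_table(
            panel.truth.sample_variants, os.path.join(outdir, "truth_variants.tsv")
        )
    )
    return paths
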