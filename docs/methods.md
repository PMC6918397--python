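# Methods

This note documents the statistical procedures, the synthetic-data design,
the numerical choices and the known limitations of `cannamark`. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

*Cannabis sativa* splits into drug-type (high-THC) and fiber-type
(low-THC) classes. The chemotype is governed by the two competing
synthases THCAS and CBDAS, which act on the shared precursor
cannabigerolic acid: loss-of-function variation in CBDAS leaves the
precursor to THCAS (drug chemotype) and vice versa. Sanger consensus
sequences of the two coding regions therefore carry markers that predict
the class in plants and in seeds, before any cannabinoid has accumulated.
The package discovers such markers, quantifies their discriminating power,
and predicts their protein-level consequences.

## Variant calling

Per-sample gene sequences are aligned to a reference CDS with a global
pairwise aligner under affine gap penalties. Coordinates are 1-based on
the reference CDS (deletions reported at their first deleted base,
insertions anchored after the reference base they follow), and indels are
left-normalized so coordinates are deterministic in repeats.

Scoring defaults: match +2, mismatch −3, gap open −5, gap extend −2, a
length-L gap costing `open + L·extend`. These favor one contiguous 4-bp
deletion (−13) over scattered mismatches (−12 for four, but at the cost of
losing eight match points), so the characteristic CBDAS deletion is
recovered as a single event. IUPAC ambiguity codes in the sample score as
matches against any base they contain; an ambiguity code at a SNP yields a
heterozygous call. Ties between equal-scoring alignments are resolved by
the aligner's canonical traceback, so output is deterministic.

The genotype matrix is categorical: a base or IUPAC code per SNP locus,
presence/absence (`del`/`ins` vs `ref`) per indel locus, `ref` where a
sample has no call.

## Locus association: Firth + Benjamini–Hochberg

Each polymorphic locus is tested as a categorical predictor of the binary
class with Firth's penalized-likelihood logistic regression, which
maximizes `l(beta) + 0.5·log det I(beta)` (the Jeffreys-prior penalty).
Ordinary maximum likelihood diverges under complete separation — the
situation every perfect marker creates — while the Firth estimate stays
finite on any 2×K table, including tables with empty cells.

- Coding: indicator contrasts against the fiber-class consensus (modal)
  allele; a K-category locus gets a joint (K−1)-df test. Heterozygous
  IUPAC symbols are distinct categories, because Sanger genotypes are
  unphased.
- p-values: profile penalized likelihood-ratio test. The null value
  maximizes the penalized likelihood over the intercept with the locus
  coefficients held at zero **while keeping the full design's penalty**,
  so the two penalized likelihoods are comparable. (Penalizing the reduced
  model with its own, smaller information matrix makes the test markedly
  anticonservative; with the profile construction the null p-values are
  uniform to Monte-Carlo accuracy, which the acceptance suite verifies via
  the empirical FDR of the scan.)
- Newton iteration with the Firth-adjusted score and step-halving;
  convergence at score norm < 1e-8, at most 50 iterations, error with the
  iteration trace otherwise. Monomorphic loci are recorded as untestable
  and excluded from the multiplicity adjustment.
- Multiplicity: Benjamini–Hochberg step-up at q = 0.05 (default), applied
  jointly across both genes — the stricter reading of "adjusted for
  multiplicity" when two genes are scanned together.

## Discriminant scoring

For each significant SNP locus the *consensus profile* records the modal
allele of each class; ties are broken by a fixed allele ordering
(A<C<G<T<IUPAC codes<del/ins) with a warning. A sample earns +1 at a locus
where it matches the drug consensus, −1 for the fiber consensus, 0
otherwise — in particular, a heterozygous code matching neither consensus
earns 0. Indel loci contribute 1 when the variant is present and 0
otherwise, with the sign carried by the weight; the published fixed-weight
pair (+1.1 deletion, −1 insertion) therefore takes values exactly
{−1, 0, 0.1, 1.1}, and `score > 0` classifies a sample as drug-type.

AUC is the Mann–Whitney probability that a random drug-class score exceeds
a random fiber-class score, ties counting ½ (computed from rank sums, and
cross-checked in the tests against exhaustive pair enumeration).

Weight optimization uses deterministic greedy forward selection: at each
step the (locus, weight) pair with the largest AUC gain is added, weights
drawn from the fixed grid [−2, 2] in steps of 0.1, followed by one
coordinate-descent pass over all weights with zero admitted. Because the
refinement pass can always zero the newly added locus, the achieved AUC is
non-decreasing in k. The "most weights non-negative" constraint is
operationalized as at most ⌊(k−1)/2⌋ negative weights, with the special
case k = 2 allowing one negative weight so the indel pair (+1.1, −1) is
admissible. Every score used in practice (single-locus weights, the indel
pair) is exactly representable on the grid. The original optimizer behind
the published weights is not specified to this level of detail; this
deterministic scheme is the package's own design choice.

Threshold performance (sensitivity = fraction of drug samples strictly
above the threshold; specificity = fraction of fiber samples at or below
it) is reported with stratified percentile-bootstrap 95% CIs (B = 2000 by
default, seed mandatory). A metric constant across resamples yields the
degenerate CI equal to the point estimate.

## Population structure and chemotypes

- **Gower distance**: with all-categorical loci the Gower coefficient
  reduces to the mismatch fraction over loci where both samples are
  observed; pairs with no comparable loci are an error. On such data it
  satisfies the metric axioms (property-tested).
- **Classical MDS** (Torgerson): double-center −½·D², eigendecompose,
  order axes by eigenvalue, scale eigenvectors by √λ. Sign convention:
  the largest-magnitude loading on each axis is made positive. Fewer
  positive eigenvalues than requested dimensions → zero-padding with a
  warning. The implementation is cross-checked against scikit-bio's
  principal coordinate analysis in the tests.
- **Entropy summaries**: per-locus Shannon entropy of allele frequencies
  (natural log by default, base configurable), averaged over loci
  ("mean entropy"). Within-group values repeat the computation inside each
  group. "Between-group variation" has no standard definition in this
  context; it is defined here as the mean per-locus entropy of the
  group-consensus (modal) alleles, which is 0 when all groups share the
  same consensus and grows with consensus disagreement.
- **Chemotypes**: ratio = mean THC / mean CBD per variety, with the
  zero-CBD convention 0/0 → 0 and x/0 → ∞. Groups are closed below:
  1: ratio ≤ 0.05, 2: ≤ 0.2, 3: ≤ 10, 4: > 10 (reading "up to 0.05" /
  "more than 10" as inclusive lower bounds). Ratio-of-variety-means is
  used throughout; for a few published varieties the printed ratio is
  consistent only with per-plant averaging, so tests assert only rows
  where both conventions agree. A bundled reference table
  (`cannamark/data/chemotype_reference.csv`) carries the published
  per-variety means for 10 fiber and 11 drug cultivars.

## Protein consequences

Translation uses the standard genetic code, halting at the first in-frame
stop. The reported "amino acids" figure for a truncated protein is the
**stop codon index** (stop at codon 195 → "195 amino acids"), matching the
conventional arithmetic for the CBDAS premature stop at CDS position 583;
a strict residues-before-stop count would give 194. This is a labelling
convention, not biology, and the residue sequence itself has length
`stop_codon_index − 1`.

SNPs sharing a codon are applied jointly; every SNP in a codon whose amino
acid changes counts as non-synonymous, so two SNPs in one changed codon
contribute two non-synonymous mutations but one amino-acid change (and two
SNPs in a codon whose joint change is silent are both synonymous). Indels
set the frameshift flag iff their length is not divisible by 3.

Substitution impact is graded by side-chain chemistry: hydrophobic ↔
charged is high impact; hydrophobic ↔ polar and ring/rigid ↔ fluid are
moderate; everything else (including synonymous changes) is low; nonsense
changes are high. The residue classes (hydrophobic AVLIMFWC, polar STNQYG,
charged DEKRH, ring/rigid FWYHP) are standard groupings, configurable per
call, since the grading rule names the categories but no canonical set.
PROVEAN-style deleteriousness is **not** recomputed; literature
deleterious residues (THCAS 165; CBDAS 136 and 182) are carried as
annotations only.

## Synthetic-data design

The generator emulates the study conditions the analysis assumes; its
defaults are fixed and are not tuning knobs.

- **Panel**: 47 drug + 50 fiber plants (11 and 10 varieties, round-robin)
  plus 20 drug + 50 fiber seeds — 167 samples.
- **References**: random sense codons (seeded), ATG start, single terminal
  stop; 1638 nt (THCAS-like, a 545-residue protein) and 1635 nt
  (CBDAS-like, 544 residues). The THCAS-like reference plays the drug-type
  reference role and the CBDAS-like one the fiber-type role, so fiber
  samples carry the THCAS alternates and drug samples the CBDAS
  alternates.
- **Markers**: the 25 + 8 published CDS positions. Codons containing
  design-relevant positions are pinned so the planted alleles realize the
  published consequence arithmetic: the 25-SNP THCAS mutant shows 19
  non-synonymous / 6 synonymous mutations and 18 amino-acid changes
  (positions 136+137 share codon 46, which changes; 862+864 share codon
  288 as a jointly synonymous Leu→Leu pair; third-position sites 300, 612,
  678 and 699 are synonymous; 744 is a non-synonymous third-position
  change), with hydrophobic↔charged substitutions at codons 90, 165, 250
  and 255. The CBDAS design plants A→T at 583 (premature stop, codon 195),
  Arg/His at codon 136 and Gly/Ala at 182, the 4-bp CGTA deletion at
  153–156 (removing Leu51/Val52 and shifting the frame) and the AAC
  insertion after 755. The actual base identities at the remaining sites
  are not published; they are chosen deterministically (first
  non-synonymous, non-stop substitution in base order) and recorded in the
  truth table.
- **Noise**: heterozygous IUPAC sites in drug samples at non-marker
  positions (rate 0.002/site — a handful per sample, matching the
  observation that some markers were heterozygous in drug accessions and
  motivating the homozygous-marker focus), and private homozygous
  background substitutions in all samples (rate 0.0005/site), both kept
  away from marker positions, the indel neighborhood and the start/stop
  codons so ground truth stays exact. An `indel_discordance_rate` option
  makes a drug sample carry only one of the two indels, and
  `het_rate_planted` allows heterozygosity at marker loci to exercise the
  0-point scoring rule; both default to 0.
- **Chemotypes**: per-variety mean THC uniform on [2.08, 11.80]% for drug
  varieties and on [0, 0.31]% for fiber varieties (the observed class
  ranges); fiber THC/CBD ratios drawn in the published fiber band
  [0.05, 0.18] with occasional cannabinoid-null varieties; drug ratios in
  [3, 52]; SDs drawn as 5–50% of the means. Ranges, not distributions, are
  published, so uniform draws within them are the package's choice.

What the generator does **not** emulate: within-variety haplotype sharing
(background variation is private per sample), linkage between loci,
sequencing error and chromatogram artifacts, genuine fiber samples with
drug-like indel patterns (which in real data lowered the indel-score
specificity below 1), and any demographic structure. Passing tests
therefore demonstrate the correctness of the algorithms under the planted
model, not the real-data error rates of the assay.

## Problem sizes and determinism

The test suite runs the full 167-sample panel for the scan/scoring checks
and a 16-sample noise-free panel for the alignment round trip. The
empirical-FDR check uses 200 null replicates of 200 binary loci at
n = 97 (47/50), the scan's deployment size; the per-replicate false
discovery proportion of an all-null panel is 1 whenever anything is
flagged, so its mean estimates the FDR and is compared to q plus twice the
Monte-Carlo standard error. All simulations, bootstraps and optimizers
take explicit seeds; the pipeline report is byte-identical across reruns
with the same configuration (JSON with sorted keys, timings only in the
log).

## Known limitations

- Real-data figures that depend on the deposited study sequences (the
  47/40 discovered-SNP counts, the published entropy values, the 99.87%
  indel AUC and 95.56% specificity) require those accessions and are not
  reproduced by the synthetic panel; the package accepts real reference
  and sample FASTA through the same paths.
- The weight optimizer is a deterministic greedy/grid scheme, not a global
  optimizer; with strongly correlated loci it returns one of several
  equally good specs (deterministically).
- `merge_reads` assumes co-aligned, same-strand reads;
  reverse-complementing and aligning reads is the caller's duty.
- The truncation figure follows the stop-codon-index convention discussed
  above.
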