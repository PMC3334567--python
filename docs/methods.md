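# Methods

## The measurement model

`rmaecall` detects random monoallelic expression (RMAE) of autosomal genes
from SNP genotyping arrays hybridized with two kinds of material from the same
F1-hybrid cell line: genomic DNA (gDNA), and double-stranded cDNA synthesized
from nuclear RNA (a "transcriptome genotype"). At a SNP that is truly
heterozygous, the gDNA hybridization reads AB; the cDNA hybridization reads AB
when both alleles are transcribed, and drifts to a homozygous call (AA or BB)
when transcription is essentially monoallelic. The unit observation is
therefore the pair (gDNA call, cDNA consensus call) per SNP per line.

RMAE is a cell-lineage property: a polyclonal population averages over
lineages and looks biallelic, so the assay requires clonal cell lines (every
cell shares one allelic-choice configuration) plus one non-clonal line of the
same genotype as a control. The supported analysis-set design is one gDNA
array and two replicate cDNA arrays per line, at least two clonal lines, and
exactly one non-clonal line; the readers enforce this cardinality.

Alleles are abstract array channels A/B. A per-SNP map assigns each channel to
the maternal or paternal haplotype of the cross; "maternal/paternal" labels
distinguish the two alleles and do not imply an imprinting mechanism.

## Filter cascade

A SNP×clone observation becomes an allelic state only after four filters:

1. **Confidence.** Every call carries a confidence score, lower = better
   (array-genotyping convention); calls above `confidence_threshold`
   (default 0.05, config-exposed — chosen as a stringent default since no
   canonical value exists for this score) are treated as NoCall.
2. **Replicate agreement.** The two cDNA replicates must produce identical
   passing calls; a lone passing call is not trusted, and two confident calls
   that disagree yield NoCall with provenance `filtered`.
3. **Both-allele detectability.** Somewhere in the analysis set's cDNA arrays,
   allele A and allele B must each appear in a passing call (an AB call
   evidences both). This guards against probes that can only ever report one
   channel from cDNA.
4. **Non-clonal control.** The non-clonal line's cDNA consensus must be AB or
   NoCall. A homozygous pooled call means the imbalance is uniform across
   cells — imprinting, strong cis-acting skew, or an annotation/LOH artifact —
   and the SNP is masked in every clone.

Surviving observations map to states: gDNA AB + cDNA homozygous →
mono-maternal or mono-paternal (via the allele→parent map); gDNA AB + cDNA AB
→ biallelic; anything else → uninformative. Intergenic SNPs are excluded from
gene-level analysis; X-linked SNPs are retained and distinguished by
chromosome label.

A monotonicity caveat: each individual filter only removes information as the
threshold tightens, but the cascade as a whole is not strictly monotone —
tightening the threshold can degrade a homozygous non-clonal consensus to
NoCall, which the non-clonal rule admits, re-enabling SNPs the looser
threshold had vetoed. The property tests therefore assert monotonicity
conditional on unchanged non-clonal admissibility.

## G-score and gene classes

Within a gene and clone, let m+ be the count of informative SNPs monoallelic
in the majority direction, m− the count in the opposite direction, and b the
biallelic count. The clone score is

    0                          if m+ = 0
    m+                         if m− = b = 0 (perfect agreement)
    m+ · m+ / (m+ + m− + b)    otherwise
    m+ / (m+ + m− + b)         if m+ = m− (direction tie; at most 1/2)

and the gene's G-score is the **maximum** clone score. The design constraints
this satisfies: a single monoallelic SNP gives exactly 1; a gene whose single
SNP is monoallelic in several clones stays exactly at 1 (hence max, not sum);
multiple concordant SNPs exceed 1; any disagreement drives the score into
(0, 1); the tie rule keeps equivocal evidence strictly below 1 (the quadratic
form would cross 1 at m+ = m− ≥ 2). The scoring is isolated behind
`clone_score` so an alternative weighting can be swapped in.

Classes: G > 1 → RMAE class I; G = 1 → class II; 0 < G < 1 → class III
(inconclusive, excluded from downstream sets); G = 0 with ≥ 2 informative
clones → biallelic (BAE); otherwise unassessed. "Assessed" genes are class I,
class II and BAE. Cohort summaries report class percentages over assessed
genes, the mean number of assessed SNPs per assessed gene, and the fraction
of multi-SNP gene×clone observations in perfect internal agreement.

## Downstream statistics

* **Neighbor coordination.** Within each clone and chromosome, monoallelic
  genes of the RMAE set are ordered by start coordinate; each adjacent pair
  (optionally restricted to a bp window; start-to-start distance, a
  config-exposed convention) agrees when both express the same parental
  allele. Pooled agree/disagree counts are tested against 50:50 with a 1-df
  chi-square without continuity correction — with correction the test no
  longer reproduces its own closed form 2(Δ/2)²/mean on the printed examples.
* **Ortholog overlap.** For one-to-one orthologs assessed in both species,
  the shared-RMAE count k is tested against Hypergeometric(N, K, n) with an
  upper-tail P(X ≥ k); the expectation is K·n/N. SciPy's survival function is
  used, and a direct `math.comb` enumeration serves as an independent oracle
  in tests for every population size up to 30.
* **Skewed allelic choice.** Among RMAE genes with exactly n ∈ {2, 3, 4}
  directional monoallelic clones (genes containing a direction-tied clone are
  excluded — no direction is assignable), the unidirectional count is compared
  with the null fraction 0.5^(n−1) by a one-sided exact binomial test. A
  two-parameter mixture — a fraction f of genes choose a preferred allele with
  probability p, the rest fairly — gives q(n; f, p) = (1−f)·0.5^(n−1) +
  f·(pⁿ + (1−p)ⁿ); the grid search (default f ∈ {0, 0.1, …, 1},
  p ∈ {0.5, 0.55, …, 1}) minimizes the sum of squared differences between
  observed and expected unidirectional counts over n. The SSD surface has a
  near-degenerate ridge — e.g. (f = 0.8, p = 0.85) and (f = 0.4, p ≈ 1) fit
  almost identically — so at a few thousand genes the argmin identifies the
  ridge, not a point; point recovery of both parameters requires on the order
  of 10⁵ genes (verified: exact argmin recovery on noiseless expected counts,
  and one-grid-step recovery at 100,000 simulated genes).
* **X-inactivation concordance.** Per clone, the fraction of X-linked
  monoallelic SNPs sharing the majority direction, and the inferred active
  parental X; a positive control, since X-inactivation enforces chromosome-
  wide coordination. Clones with no informative X-linked SNP are omitted.
* **Imprinting screen.** Runs on the pre-filter state table (non-clonal rule
  and detectability filter lifted, non-clonal line included — both filters
  hide imprinting by design): candidates are genes monoallelic in one
  parental direction in every informative sample, with no biallelic
  observation. When samples span reciprocal crosses, each cross carries its
  own allele→parent map, so strain-driven (cis) imbalance flips parental
  direction between crosses and is rejected, while true parent-of-origin
  expression is retained; single-cross candidates carry a flag because the
  two mechanisms are indistinguishable there.
* **Tissue-scale imbalance.** With a fraction β of cells biallelic and the
  rest monoallelic for one allele at a fixed per-allele expression level, the
  aggregate allelic ratio is 1 : β (2:1 at β = 0.5, ∞ at β = 0) — skewed RMAE
  masquerades as classical allelic imbalance in bulk tissue.

## Synthetic data generator

The generator draws an analysis set in the supported design. Defaults
represent the lymphoblast study scale: 7 clonal lines, 1,000 autosomal and 30
X-linked genes across 5 autosomes plus chrX, SNPs per gene from the mixture
{1: 0.65, 2: 0.21, 3: 0.10, 4: 0.04} (mode 1, mean 1.53), regime fractions
{BAE 0.80, balanced RMAE 0.06, skewed RMAE 0.09, imprinted 0.02, cis-skewed
0.03}, per-clone monoallelic probability 0.35 at RMAE genes, skew model
(f, p) = (0.8, 0.85), symmetric miscall rate 0.02 and NoCall rate 0.05 per
replicate (no measured rates exist for this noise; these are plausible array
magnitudes). All SNPs of a gene share the clone's state (stable mitotic
inheritance); X-linked genes are fully coordinated per female clone. The
non-clonal line is a simulated pool of 1,000 cells whose consensus reads AB
when each allele is expressed in ≥ 10% of cells, else the majority homozygous
call. Gene positions are uniform per chromosome with an optional SNP-desert
block emulating crosses of shared descent. Every dataset carries a truth
table (regime per gene, state per gene×clone, active X per clone).

What the generator does **not** emulate: probe-level intensity noise and its
correlation structure, PCR and hybridization bias, loss of heterozygosity,
expression-level variation (calls are derived from discrete states), linkage
between neighboring genes' choices, and non-uniform SNP ascertainment.
Passing end-to-end tests therefore demonstrates the correctness of the
calling logic under the stated noise model, not performance on raw array
data.

## Numerical and design choices

* Confidence semantics are `confidence ≤ threshold`, lower = better.
* Replicate discordance yields a SNP-level NoCall rather than excluding the
  sample, keeping the clone assessable at its other SNPs.
* gDNA heterozygosity comes from each line's own gDNA array; the parental
  strain map is used only for direction labels.
* Gene×clone consensus state is the direction of the monoallelic majority;
  an exact direction tie is reported uninformative.
* Chi-square and binomial tests take SciPy's implementations; the
  hypergeometric tail is SciPy's `sf` cross-checked against enumeration.
* Coordinates are 0-based half-open (BED convention) in all files.
* Outputs are deterministic: stable sort keys everywhere, seeds recorded in
  `#` provenance headers.

## Problem sizes

Default test and verification sizes: 1,000-gene, 7-clone simulations for
end-to-end recovery; 2,000-gene × 20-seed and 100,000-gene runs for the skew
grid; exhaustive hypergeometric checks to N = 30; 1,000-gene independent-
choice null for neighbor coordination. These sizes were chosen so the full
suite completes in well under a minute while keeping binomial sampling error
far below the tested effect sizes.

## Known limitations

* The G-score weighting is one concrete member of the family of
  agreement-weighted scores satisfying the class constraints; the per-clone
  scorer is the single place to change it.
* The skew model grid reports a ridge at realistic gene counts (see above);
  treat the argmin as a model-family statement, not a point estimate.
* Class III (inconclusive) genes are excluded from all downstream sets, so
  cohort percentages depend on the confidence threshold through the
  class III rate.
* The imprinting screen cannot separate imprinting from cis-skew without
  reciprocal crosses in the analysis sets.
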