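# Methods

This note documents the models behind each analysis, the parameters that
matter, what the synthetic-data generators do and do not emulate, and the
numerical and design choices made where more than one reasonable option
existed.

## Coordinate conventions

All intervals are 0-based half-open internally; GFF3 and VCF convert at the
file boundary, BED passes through. Synteny works in *gene-rank space*: the
position of a gene is its 0-based order along its chromosome (ties at equal
start broken by gene id). Genotypes are stored as reference-allele counts
(0/1/2, −1 missing), so a homozygous-reference call is 2.

## Synteny and the rearrangement clock

Similarity hits (12-column blast tabular; query, target, bitscore) are
pruned per (query gene, target genome) to the top-`n` bitscores — `n = 2`
for paralog analyses (a WGD genome needs two hits to capture ortholog plus
homeolog), `n = 1` for pan-genome construction. Ties at the cutoff keep the
lexicographically smaller target id, making every downstream step
deterministic. Orthogroups are connected components of the retained-hit
graph; this replaces MCL-style clustering with a deterministic,
oracle-testable rule and is a deliberate simplification — it can merge
families linked by a single spurious retained hit, which the synteny
constraint later removes.

Collinear blocks are maximal monotone chains of anchors in rank space:
consecutive anchors must move strictly forward on the query axis,
monotonically (either direction) on the target axis, and jump at most
`max_gap` ranks on both axes (paralog runs: 50; pan-genome runs: 20).
Chains shorter than `min_size` (10) are dropped. Extraction is greedy by
chain length with ties broken by the smaller starting query rank; each
anchor joins at most one block. Before chaining, anchors are
density-refined with DBSCAN (Euclidean metric in rank space, radius 50,
min hits 10); noise anchors are discarded. Border points follow
scikit-learn's assignment (first core cluster by scan order).

Within one genome, hits restricted to pairs sharing an orthogroup and
mapped per unordered off-diagonal chromosome pair give the homeolog block
count. A perfectly conserved post-WGD karyotype shows one block per
homeolog pair, so only blocks in excess of the base chromosome number
witness rearrangements:

    interval (Myr) = wgd_age / (n_blocks − n_chroms)

reported to one decimal, with a sentinel when the block count equals the
chromosome number. Whether the correction is applied per comparison or in
aggregate is ambiguous in general; aggregate subtraction is used because it
is the reading consistent with one block per homeolog pair.

## Pan-genome construction and PAV

Hits outside every collinear block are removed (small translocations below
the minimum block size are therefore invisible by construction), and
self-genome off-diagonal (homeologous) hits are masked from orthologous
pairing; same-chromosome self hits survive as tandem-array candidates.
Orthogroups are re-clustered on the surviving network.

Placement against the reference gene order is hierarchical:

* single-copy in the reference → that gene's rank;
* multi-copy → the condensed-array representative with the highest summed
  within-genome bitscore, ties by physical centrality (distance to the
  orthogroup's median rank), then gene length, then gene id;
* reference-absent → the mean of each other genome's representative
  projected into reference rank space by linear interpolation between the
  anchors of its enclosing collinear block (nearest block when no block
  strictly contains the rank);
* no projectable member → an explicit "unplaced" bucket.

Tandem condensation reuses the chaining gap (20 ranks) as its adjacency
threshold rather than introducing a separate parameter.

Absence classification aligns the orthogroup CDS against the syntenic
region (local alignment, match 2 / mismatch −3 / gap open −5 / extend −2):
coverage = 100 × matched positions / CDS length, identity over aligned
columns, with category boundaries: *very similar* requires coverage > 99
and identity ≥ 95; *diverged* requires coverage ≥ 75 and identity ≥ 75;
otherwise *absent*. The published category ranges overlap at their
endpoints; these inequalities are the resolution adopted here, and the
identity formula is implemented as matches/(matches+mismatches) — the
inverted form sometimes quoted for this statistic is treated as a
typographical error. Categories are monotone: raising identity or coverage
never demotes a locus.

Private-gene enrichment in an interval uses the exact hypergeometric
two-sided test (tail summation of tables at most as probable as the
observed one — `scipy.stats.fisher_exact`) on the 2×2 table (interval vs
rest) × (private-to-focal vs not), reporting the sample odds ratio
(ad/bc, zero when the interval has no private genes).

Haplotype projection places each alternative-haplotype contig at the
midpoint of its members' primary pan positions and classifies each entry
as *both* (with percent identity = 100 × identical /(aligned + internal
gaps), terminal gaps excluded), *primary-only with alt contig* (a placed
contig spans the locus but no ortholog was annotated — high-confidence
PAV), *primary-only without alt contig* (likely a homozygous, collapsed
region), or *alt-only*.

## Ka/Ks

Codon alignments are protein-guided (BLOSUM62 global alignment,
open −11 / extend −1, back-translated); trailing partial codons are
trimmed with a warning, terminal stops dropped, internal stops are errors.
NG86 counts fractional synonymous sites per codon position (mutations to
stop codons count as non-synonymous sites but are never used as
substitution targets), averages site totals over both sequences, and
averages substitution counts over all minimal mutational pathways with
equal weights, excluding pathways through stop codons (falling back to all
pathways if every one is blocked). Both proportions receive the
Jukes–Cantor correction; p ≥ 3/4 sets the `saturated` flag with an
undefined rate. Pairwise NG86 (not maximum likelihood) matches the
codon-based pairwise statistics conventional for within-species divergence
this low; multi-sequence orthogroups reduce to all pairs.

The divergence landscape replaces each gene's Ks by its mid-rank empirical
quantile (midrank − 0.5)/n within (genome, chromosome) — tie-robust and
bounded — and averages quantiles in 100-gene windows sliding by one gene.
Chromosomes shorter than the window emit nothing.

## Local-ancestry HMM

States are unordered pairs of per-haplotype source ancestries (10 states
for 4 sources), assuming haplotype exchangeability. Emissions assume the
two alleles are independent Bernoulli draws at the source's reference
allele frequency, each misread with probability `e` (default 1e-3), so the
effective frequency is f(1−e) + (1−f)e. Source frequencies are estimated
with a pseudocount of 0.5 per allele to keep emissions strictly positive.
Transitions collapse the multi-pulse admixture model used in the original
analysis (pulses at 2–5 generations, ne 1000; the full command line is
preserved in `pansyn.config.DEFAULTS` as documentation) into a
one-parameter kernel: over d morgans each haplotype switches with
probability 1 − exp(−switch_rate·d) into an ancestry drawn from the prior
proportions. This one-parameter model is identifiable at desk scale and
exactly testable against path enumeration; it sacrifices timing inference,
which is out of scope. Global ancestry proportions (the natural prior) are
non-negative least squares of the sample allele-frequency vector on the
source frequencies, normalized; indistinguishable sources return the
uniform vector with a warning.

Decoding takes the posterior argmax per marker (ties → larger prior, then
lower state index), then culls runs iteratively: for L = 2…500, any
maximal run shorter than L is absorbed into the flanking run with more
markers (ties and edges go left where possible) until stable. The
recurrence is one consistent reading of an under-specified published
procedure; it is deterministic and idempotent. High-confidence
introgressions are, per donor, the interval intersection of
donor-containing blocks across the focal genotype and all its relatives.

Variant pruning before inference: biallelic, no missing calls, minor
allele count ≥ 3, then greedy left-to-right LD pruning that drops a site
when its r² with any retained site in the trailing 100-SNP window exceeds
0.999 (the earlier site always wins — the direction is fixed here for
determinism).

## Pseudo-testcross QTL mapping

Markers are filtered on minor allele frequency (< 0.05 dropped),
heterozygous call frequency (> 0.8), missing rate (> 0.1), allele count
(> 2) and the extreme 1% tails of mean read depth. Informative markers
(heterozygous in the focal parent, homozygous in the other) are phased per
chromosome by a greedy seed-and-extend on signed genotype agreement: the
first marker seeds phase 1 and each marker joins the side that matches the
sign of its correlation with the running consensus; parental ("GBS-like")
tables then name each phase by the grandparent that contributed the
alternate allele. Binning keeps one marker per (phase, 25-kb bin), chosen
by agreement with the per-progeny majority call over 10 observed flanking
markers each side; ties keep the lower coordinate.

Map estimation inverts the observed adjacent-marker discordance p under a
symmetric per-call error model, r = (p − 2e(1−e))/(1−2e)², the closed-form
fixed point of the corresponding EM — with e = 0.0165, capping r at 0.4999
before the Kosambi transform d = 25 ln((1+2r)/(1−2r)). Pairs with no
jointly called progeny are flagged unlinked.

The scan inserts pseudomarkers on a 0.1 cM grid (coarser grids are used in
the test suite) and computes genotype probabilities by a per-chromosome
hidden Markov reconstruction over the two haplotype states: transitions
use the Kosambi-inverse recombination fraction of each gap and emissions
the symmetric error model. A two-point (flanking-markers-only)
interpolation was evaluated first and rejected: it cannot correct isolated
genotyping errors at the tested position, which displaces peaks and makes
credible intervals anti-conservative; the forward–backward version
restores nominal interval coverage. The mixed model is a single
variance component: kinship is the centered genotype cross-product of all
other chromosomes (LOCO), heritability is fit once per kinship by a
restricted-likelihood grid search (step 0.01), and each position is tested
by generalized least squares in the eigenrotated space,
LOD = (n/2) log₁₀(RSS₀/RSS₁). This is deliberately simpler than a full
REML mixed-model scan but exact for the one-component model on a grid.
Phenotypes are analyzed untransformed; significance comes from seeded
permutations of the phenotype (default 10,000; heritability refit per
permutation), thresholded at the 95th percentile of the genome-wide
maximum LOD. The 95% Bayes credible interval is the smallest contiguous
peak-containing interval holding ≥ 95% of the normalized 10^LOD mass
(leftmost on ties), projected to bp by linear interpolation between
markers. Candidate genes inside the interval rank high when alt-only,
PAV-between-haplotypes, or divergent between haplotypes (< 98% peptide
identity); primary-only genes without an assembled alternative contig rank
low as likely homozygous regions. Domain tags (e.g. LRR/immune Pfam or
PANTHER identifiers) attach as metadata from a user-supplied table.

## Synthetic data: what it does and does not emulate

All generators are deterministic given their seed and return truth objects
sufficient to score recovery without re-simulation.

* **Pan-genome scenario.** An ancestral karyotype of `n_chroms`
  chromosomes × `genes_per_chrom` loci is duplicated under WGD into
  homeolog pairs (`chrNa`/`chrNb`). Rearrangements are one-way
  terminal-segment events on the "b" copies (translocation to an unused
  pair, or in-place terminal inversion), each adding exactly one
  off-diagonal block; events use fresh chromosome pairs so planted counts
  are exactly recoverable. All genomes share the rearranged karyotype
  (orthologous order is conserved); per genome, orthogroups are lost at
  `pav_rate`, tandem duplicates inserted at `tandem_rate`, private genes
  at `private_rate`. Sequences evolve by uniform per-site substitution
  (ortholog divergence 0.01/site, homeolog 0.10/site, no codon-usage
  bias), and bitscores are a decreasing function of sequence divergence,
  so ortholog hits strictly outscore homeolog hits. Not emulated: gene
  order divergence between genomes, segmental duplications, annotation
  errors, alignment-score noise — so passing recovery tests shows the
  machinery is correct, not that it is robust to noisy annotations.
* **CDS pairs.** Substitution counts are fixed at the rounded expected
  values implied by the target rates and placed at positions sampled by
  synonymous/non-synonymous opportunity, never creating stops; the
  recovered rates therefore carry only estimator-side noise.
* **Admixture panel.** Source frequencies drift from shared ancestral
  frequencies under Balding–Nichols with parameter F; F = 0 makes sources
  identical (the non-identifiable control) and F ≥ 1 plants a
  deterministic fixed-difference design (even markers separate every
  donor from the background, odd markers identify the donor round-robin),
  which resolves ancestry boundaries to one inter-marker spacing. Source
  panels are 20 diploids per population; test genomes and relatives are
  homozygous background outside the planted donor blocks and homozygous
  donor inside, with per-allele genotyping error (1e-3). Not emulated:
  admixture LD decay over generations, phasing error, reference bias.
* **F1 cross.** 143 progeny by default; crossovers are Poisson (one per
  morgan) without interference — the Kosambi function is tested as a
  transform of recombination fractions, not as an interference model.
  Markers carry 1.65% genotyping error matching the map `error.prob`
  default, and the planted additive QTL's effect is sized from the
  requested variance fraction. Not emulated: segregation distortion,
  missing-data structure, epistasis.

## Problem sizes and test design

The test suite runs every oracle comparison at small, exhaustively
checkable sizes (≤ 40 anchors for chaining, ≤ 12-marker/3-state chains for
forward–backward, 50-codon pairs for NG86, margins ≤ 60 for the exact
test) and the recovery checks at the study's design sizes where they are
cheap (143 progeny, 2,000-marker panels, 2,000-codon pairs) with scan
grids of 1 cM and 1,000 permutations — sizes chosen so the full suite
runs in a few minutes on one core while keeping every statistical claim at
its stated tolerance. Default analysis parameters (0.1 cM step, 10,000
permutations) are the published configuration and remain the package
defaults.

## Known limitations

Connected-component orthology is greedier than MCL; the synteny constraint
compensates only where blocks exist. The rank-interpolated placement of
reference-absent orthogroups degrades near block edges. The HMM's
one-parameter transition kernel cannot date admixture. The mixed-model
scan fits a single variance component on a grid and tests one QTL at a
time; multiple-QTL models and epistasis are out of scope. BAM/CRAM input,
assembly manipulation and annotation pipelines are deliberately excluded:
annotations, hits and genotypes enter as GFF3/FASTA/tabular/VCF text.
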