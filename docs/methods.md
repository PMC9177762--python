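# Methods

This note documents the models and procedures magforge implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Annotation bundles

All stages consume a directory of UTF-8 TSV files plus a Newick tree. Gene
coordinates are 1-based and inclusive on both ends (GFF3 convention);
floats are written with 6 significant digits and rows in a fixed sort
order, so writing the same bundle twice is byte-identical and
`load(write(b))` equals `b` up to that precision. Set-valued fields (KO
ids, gene symbols, rRNA inventory) are comma-joined in sorted order.
Validation enforces referential integrity (every annotated gene exists,
every genome in the abundance table has metadata), coordinate sanity,
KO-identifier shape (`K` + 5 digits), CAZy family/class consistency, the
fiber nesting ADL ≤ ADF ≤ NDF, and tree coverage of all abundance taxa.
Missing Newick branch lengths default to 1.0 (with a warning) so weighted
UniFrac is always defined.

## Genome quality

**N50** is the smallest contig length L such that contigs ≥ L sum to at
least half the assembly.

**Quality tiers.** A genome *fails* below 75% completeness or above 10%
contamination; passing that gate alone is *medium*; ≥ 90% completeness,
≤ 5% contamination and ≥ 18 tRNAs is *near_high*; a full 5S/16S/23S rRNA
complement upgrades to *high*. The `reasons` list records every threshold
missed, so tier assignments are auditable.

**ANI/AF estimator.** A deliberately simplified fragment-mapping analogue
of the FastANI approach: the smaller genome is cut into non-overlapping
2000 bp windows; each window is placed on the subject by 16-mer seeds
sampled every 40 bp voting on diagonals (≥ 2 votes required); identity is
scored gap-free at the best diagonal, falling back to a banded
match-count alignment (band ± 16, 0.5 penalty per gap column) when the
gap-free identity drops below 0.75, i.e. when indels shifted the frame.
ANI is the mean identity of mapped windows (%); AF is the mapped fraction
of the smaller genome, maximized over subject orientation (forward or
reverse complement). Accuracy is asserted against an exact
Needleman–Wunsch per-fragment oracle (Biopython `PairwiseAligner`): within
0.7 percentage points across substitution rates 0–10% on 100 kb pairs.
The estimator is not bit-compatible with FastANI and is not meant to be.

**Dereplication.** Single-linkage clustering over edges with ANI ≥
threshold AND AF ≥ 0.65, in two stages (99% "strain", then 90% "species"
on the strain representatives). The representative maximizes
`completeness − 5 × contamination`, with ties broken by larger genome and
then lexicographic id — a common dereplication convention, stated
explicitly because the upstream tools leave it unspecified. Absent ANI
records count as below threshold. Results are invariant to input order up
to these tie rules.

## Metabolic capability inference

The rule engine evaluates three evidence layers per genome:

- **Sugars** (8): one diagnostic KO each — glucose-6P K01810, fructose
  K00847, galactose K00849, arabinose K01804, fucose K01818, xylose
  K01805, mannose K01809, rhamnose K01813.
- **Fermentation**: boolean rules in disjunctive normal form over gene
  symbols. Butyrate is interpreted as (*ptb* ∧ *buk*) ∨ *but*: the
  phosphotransbutyrylase/butyrate-kinase pair and the CoA-transferase are
  alternative terminal routes, so requiring all three would be too strict.
  Methanogenesis uses *mcrA* as its marker — methyl-CoM reductase is the
  universal diagnostic gene, chosen here as a documented default. An
  optional formate rule (*pflB*/*pflD*) ships disabled.
- **Pathways**: completeness fraction = found/required markers; present
  iff fraction ≥ 0.75. The shipped marker lists (10 glycolysis, 7 PPP,
  8 TCA KOs) are explicit stand-ins, fully configurable via YAML and
  serialized with results for provenance. They are deliberately disjoint
  from the sugar diagnostic KOs (phosphoglucomutase stands in for
  glucose-6-phosphate isomerase in the glycolysis list) so sugar and
  pathway calls stay independently testable.
- **Polymers** (6): present iff ≥ 1 family from the polymer's configured
  CAZy set, with subfamily-aware prefix matching (GH13_9 satisfies GH13;
  GH130 does not).

**Trophic levels.** `degrader` requires a structural polymer (starch alone
does not qualify); level I = degrader, II = non-degrading sugar utilizer,
III_only = SCFA producer or methanogen with neither, `dependent` =
none — the pattern of reduced-genome lineages such as Patescibacteria.
Calls are monotone under gene-set growth: adding genes can only switch
capabilities on.

## CAZyme profiling

Hits are kept iff e-value ≤ 1e−15 AND query coverage ≥ 35%; within a
protein, hits overlapping a better hit (lower e-value; ties → longer
domain) by more than 50% of the shorter are dropped. Filtering is
idempotent. Because it is ambiguous whether class percentages should count
domains or CAZyme-bearing genes, summaries report both, labelled.
Densities are `count / Mb` per genome; group densities are unweighted
means over member genomes. The appended fraction for a directed family
pair (a → b) is (# proteins containing both) / (total domain count of a).
Scaffoldin candidates carry ≥ 2 cohesin domains in tandem. A gene counts
as secretory if flagged in either Gram mode (the conservative union,
since predictions are run in both modes upstream). Differential features
use TPM (length-normalized rates scaled to 1e6 per sample) with a
Mann–Whitney U test (Kruskal–Wallis for > 2 groups) and Bonferroni
control at α = 0.01 — a rank test stands in for a negative-binomial
package fit and is recorded in the output's `test` column.

## PUL calling

SusC/SusD recognition uses annotation labels carried by the bundle (gene
symbols or the KOs K21573/K21572); HMM detection is upstream. Pairing is
greedy left-to-right: a susC and susD on the same contig and strand with
at most `max_intervening` (default 1) genes between; each gene joins one
pair. Each pair is grown outward while the next gene is sus or
CAZyme-bearing, tolerating up to `max_gap` (default 2) consecutive
unannotated genes; touching loci merge. The defaults approximate common
PUL-predictor behaviour and are exposed as CLI flags. "Vicinity" for the
CAZyme-free flag is the extended locus itself. Family enrichment uses a
2×2 Fisher exact test (in-PUL vs genome-wide background domain counts)
with Benjamini–Hochberg correction; a family absent from the background
gets the capped fold sentinel 1e6.

## Community statistics

All implemented directly (scikit-bio serves only as a cross-check in
tests):

- **Bray–Curtis**: 1 − 2Σmin(x,y)/Σ(x+y).
- **Weighted UniFrac** (normalized, bounded [0,1]):
  Σ_b l_b|A_b−B_b| / Σ_b l_b(A_b+B_b) over all non-root branches, with
  A_b the clade sum of relative abundances. The normalized variant was
  chosen so distances are comparable across sample pairs. Unweighted
  UniFrac is unique/total branch length over branches with any descendant
  present.
- **PCoA**: eigendecomposition of the Gower-centered squared-distance
  matrix; negative eigenvalues are reported but excluded from variance
  fractions; no Lingoes correction.
- **PERMANOVA**: pseudo-F from the among/within partition of squared
  distances; p = (1 + #{F_perm ≥ F_obs})/(n_perm + 1) under free label
  permutation. Permutations are unrestricted: the paired-animal structure
  of a real incubation design is not modeled. Note that a permutation can
  reproduce the observed partition (or its label swap) and then ties with
  F_obs, so the attainable minimum p is occasionally 2/(n_perm+1).
- **PERMDISP**: distances to own-group centroids in positive-eigenvalue
  PCoA space; ANOVA F on those distances, p by permuting which samples
  carry which residual distance (the vegan `permutest` scheme).
- **RDA**: response centered, constraints standardized; multivariate least
  squares, then SVD of the fitted values; variance explained = constrained
  SS / total SS per axis. Constraints with condition number > 1e8 are
  rejected as collinear.
- **Correlation screen**: Pearson r per (taxon, fiber variable);
  significant iff |r| > 0.38 AND p < 0.01 (two-sided).
- **ANCOM**: W_i counts taxa j for which a rank test on
  log((x_i+1)/(x_j+1)) across groups rejects at α = 0.05; detected iff
  W ≥ 0.7(m−1). The rank-based per-ratio test and pseudocount 1 are
  documented defaults (the exact upstream variant is unstated);
  `detected_bonferroni` repeats the call at per-ratio α/m as a stricter
  reporting layer.
- **Heatmap ordering**: average linkage on 1 − Spearman ρ (range [0,2];
  the value 2 for perfect anticorrelation is retained, not clipped).
  Constant rows get unit distance to all others, with a warning. Rows are
  pre-sorted by label so agglomeration tie-breaks are deterministic.

## Synthetic communities

The generator states one world and the tests measure it; none of its
parameters were adjusted against test outcomes.

- **Design defaults** mirror the emulated incubation study: 11 substrate
  codes (WS, CS, RS, CR, KS, DP, SG, SC, AP, SS, SB), time points
  24/48/72/96 h, 2 replicates (two animals), completeness drawn from
  [75, 100]%, contamination from [0, 8]%. Designs outside completeness
  [50, 100] or contamination [0, 25] are rejected.
- **Genomes**: ~16–25 contigs with log-normal length spread, 400 genes by
  default (1000 where a test needs tight binomial expectations). Marker
  genes realizing each planted capability are placed first; background
  KOs (K9xxxx) and CAZyme families are drawn only from pools that can
  never satisfy a rule, so recovery at completeness 100 is exact by
  construction — a green test establishes the inference path, not
  annotation realism.
- **PULs** are planted on Bacteroidota genomes as susC/susD pairs plus
  optional CAZyme genes (gaps ≤ 1), with a 4-gene unannotated margin so
  planted locus boundaries are unambiguous at the default caller
  parameters. Roughly half the loci carry no CAZyme, exercising the
  CAZyme-free flag.
- **Degradation**: uniform random gene dropout to the target completeness
  (a CheckM-style proxy — real incompleteness is spatially clustered,
  this is not); contamination realized by duplicating retained genes onto
  a separate contig. Truth records intended and retained gene sets.
- **Abundance**: log x = baseline + group effect + c·z(NDF) + N(0, 0.5),
  exponentiated and truncated below a 0.01 detection floor (zeros
  exercise ANCOM's pseudocount handling). Planted differential taxa get
  log(fold) in their target substrate; chemistry-tracking taxa get
  c = ±1, which realizes |Pearson r| ≥ 0.5 with NDF in expectation.
- **Chemistry**: per-substrate starting NDF ∈ [45, 75]% DM with ADF and
  ADL nested fractions, all three decaying by a shared per-substrate
  exponential rate — preserving ADL ≤ ADF ≤ NDF and monotonicity exactly.
- **Not emulated**: nucleotide-level sequence realism (the ANI tests use
  a separate substitution-mutation sequence generator), animal random
  effects, spatial gene clustering of dropout, and real phylogenetic
  signal (the tree is a random binary tree with exponential branch
  lengths).

## Known limitations

- The ANI estimator's banded fallback approximates alignment identity
  with a match-count DP; heavy indel load (not exercised by the stated
  world) would degrade accuracy gracefully but untested.
- KEGG module-graph completeness (requiring the KEGG database) is out of
  scope; pathway presence is marker-fraction based.
- PERMANOVA/ANCOM p-values are permutation-based and seed-reproducible;
  they are not strata-aware.
- The quality tiering consumes completeness/contamination as inputs; it
  does not re-estimate them from markers.
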