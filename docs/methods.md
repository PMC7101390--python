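# Methods

`ctlineage` implements joint genetic + epigenetic clonal tracking of
metastatic cancer across multi-region tissue samples and circulating
tumour DNA (ctDNA).  This note records the models, the defaults and the
numerical choices, in the order the pipeline runs.

## Methylation-clock haplotypes

A methylation clock is a CpG island whose methylation state drifts with
cell division through *epimutations* — methyltransferase errors that
occur orders of magnitude more often than DNA point mutations.  Each
sequenced bisulfite molecule yields a binary haplotype over the locus's
CpGs (1 = methylated), and because cancer cells divide asexually, these
neutral barcodes hitchhike with their clone and encode clonal ancestry.

The filter cascade (`clock_haplotypes`):

1. **Site coverage** — a CpG is analysed only when its total calls
   (methylated + unmethylated) reach `min_site_calls` (default 1000;
   targeted assays routinely reach thousands of molecules).  Dropping a
   site shortens the effective haplotype; all downstream fractions use
   the retained-site count, never the locus's nominal CpG number.
2. **Completeness** — reads missing a call at any retained site are
   removed, so haplotypes are fully observed vectors.
3. **Informativeness** — reads need at least one methylated CpG
   (fully unmethylated molecules are overwhelmingly contributed by
   admixed normal cells, which have low turnover at these loci) and at
   most 80% methylation (a clock at saturation no longer records
   divisions).  The 80% boundary is treated as *kept* (fraction <= 0.8
   survives); the comparator is exposed (`meth_comparator="lt"`) because
   the strict reading is also defensible.
4. **Rarity** (genealogy building only) — haplotypes at 1% abundance or
   less are removed; the denominator is the post-informativeness-filter
   read total.  A haplotype at exactly 1.0% is removed.

Bottom-strand calls (cytosine at CpG position + 1) are collapsed onto
the forward-strand coordinate (1-based); a read whose two strands
disagree at a CpG is dropped with a warning.

`flag_hypermethylation` reports the fraction of complete reads above 80%
methylation and flags the clock when that fraction exceeds 0.5.  The
0.5 read-fraction cut is this package's heuristic for "saturated, do not
use"; the raw fraction is always returned so callers can apply their
own rule.

## Haplotype-population similarity and genealogies

Per sample, 100 haplotypes are drawn with replacement (probabilities
proportional to counts); a synthetic population of 100 fully
unmethylated haplotypes is added as the ancestral reference.  The
distance between two populations is the **iterative minimal Hamming
pairing**: compute all pairwise Hamming distances, repeatedly record the
globally shortest remaining pair and remove it, and sum the recorded
distances.  Matching the closest molecules first cancels the shared
(ancestral) component of two populations, leaving the private drift.

Two details the procedure itself does not fix:

* **Tie-breaking.** The choice among equally short pairs *can* change
  the final sum (greedy matching is not exchange-stable), so a fixed
  rule is required for determinism.  The two populations are put in a
  canonical order (sorted haplotype lists) and the lexicographically
  smallest index pair wins; this also makes the distance exactly
  symmetric.
* **Resampling unit.** Each sample is resampled once and that resample
  is reused across all pairwise comparisons (internally consistent
  matrix); per-pair resampling is available via `resample_per="pair"`.
  The seed is recorded in the matrix metadata.

Trees are built with classical Saitou–Nei neighbour joining
(scikit-bio); negative branch lengths are clamped to zero (deficit
logged) and the tree is rooted on the unmethylated reference's pendant
edge.

## Parsimony sample trees from binarised CCFs

Mutations are binarised at CCF >= 0.2 (inclusive) and a
maximum-parsimony tree over the samples is sought.  Up to 9 leaves the
minimum over all unrooted binary topologies is found exactly by
branch-and-bound over stepwise leaf insertion (the Fitch score of a
partial tree can only grow, so partial scores bound completions); with
more leaves, NNI hill-climbing from a neighbour-joining start plus 24
seeded random restarts is used.  Fitch counting is Hartigan's
generalisation, which handles multifurcations and reduces to Fitch on
binary nodes.

Edge lengths follow the **ACCTRAN** (accelerated transformation)
criterion: states are assigned top-down from the bottom-up parsimony
state sets, keeping the parent's state whenever admissible.  Restricting
to the bottom-up sets is what accelerates changes — the delayed
(parallel-gains) reconstructions require states outside those sets — and
the assignment provably spends exactly the Fitch score, so edge lengths
sum to the tree score (an identity asserted in the tests).  At a fully
ambiguous root the ancestral state 0 (unmethylated / germline) is
preferred, deterministically.

## Seeding classification

Cluster ancestry is a partial order, supplied explicitly (from a clone
tree) or derived by CCF pigeonholing: A is an ancestor of B when A is
present wherever B is and with at least B's mean CCF.  A metastasis is
**polyclonally seeded** only when it contains (mean CCF >= 0.2) at least
two clusters that are mutually unrelated in that order; nested clusters
are one lineage sampled at two times and never count.  Cluster/tree
compatibility is clade membership of the presence set in the rooted
sample tree.

## Variant filtering and CCF

Call-level rules: depth strictly > 10 in the matched normal and in at
least one tumour sample that also shows >= 3 variant reads; normal
genotype 0/0 with some tumour genotype different; highest tumour VAF at
least 10x the normal VAF; optional caller-flag whitelist (consumed as
given, e.g. PASS, alleleBias, Q20, QD, SC, HapScore).  "Greater than 10"
is read strictly.

Region-level rules ahead of subclonal reconstruction: clonal diploid
copy state; mean mappability exactly 1 in the ±25 bp window; no overlap
with simple repeats / low-complexity regions; CCF >= 0.2 in two or more
samples (shared subclonal mutations inform the metastatic cascade;
private subclones do not).  The four rules commute — a tested property.

CCF is computed as

    CCF = VAF · (p·CNt + 2(1 − p)) / (p·m)

with purity `p`, local total copy number `CNt` and multiplicity `m`
fixed at 1 to avoid overcalling subclonality (the conservative choice
even in genome-doubled/LOH genomes).  Values are reported uncapped with
a capped-at-1 view.  The cluster-count cap for subclonal deconvolution
is `2n − 1` for `n` tumour samples — the number of non-private edges in
a clone tree with twice as many clones as samples.

## ctDNA deconvolution

The ctDNA feature vector `y` (per-mutation CCFs, or haplotype
frequencies filtered for >= 1 methylated site and < 80% methylation) is
modelled through the origin as a non-negative mixture `y ≈ Xβ` of
tissue-sample profiles.  Selection is forward-then-backward:

1. forward: add the column whose NNLS refit maximises adjusted R²
   (`1 − (1 − R²)(n − 1)/(n − k − 1)`, R² against the mean of `y`);
   stop at the first non-improving addition (no look-ahead).  The empty
   model's adjusted R² is computed the same way with fitted values 0.
2. backward: p-values come from an ordinary least-squares refit on the
   selected support (non-negativity makes exact inference awkward; the
   OLS-refit t-test is the documented, swappable convention).  While any
   p > 0.05, the largest-p column is dropped and the model refitted.
   Final coefficients are the NNLS solution on the surviving support.

Features constant across all tissues (e.g. truncal mutations) are
dropped before fitting — they carry no information about *which* lesion
sheds.  Per-organ contributions are sums of the selected samples'
coefficients, with normalised shares alongside.

## Allelic imbalance (mirrored BAF)

Het SNPs are taken from the matched normal (allele fraction in
[0.4, 0.6], depth >= 25).  LRR is `log2(depth ratio)` minus its global
median.  Per chromosome arm, the *mirrored* BAFs (folded to
`max(b, 1−b)`) are segmented by exact penalised least-squares
changepoint dynamic programming; the default penalty is the BIC-style
`γ = 2·σ̂²·log n` with a difference-based robust σ̂, exposed as a flag.

Each segment is tested against the balanced expectation `N(0.5, σ)`
with a one-sample Kolmogorov–Smirnov test (p < 0.05 → imbalanced;
degenerate or < 10-SNP segments are "untestable").  The fixed σ comes
from an initial per-segment fit of the symmetric mixture
`w·N(0.5+d, σ) + (1−w)·N(0.5−d, σ)` with all parameters free (EM),
taking the median σ across segments; σ is shared genome-wide.  For
imbalanced segments the major-allele BAF `0.5 + d̂` is the maximum-
likelihood point on a grid over `d ∈ [0, 0.5]` (step 0.001) and
`w ∈ [0.1, 0.9]` (step 0.01) — the grid ranges are this package's
defaults; the original description specifies only "grid search".
The mixture is fitted on *unfolded* BAFs: folding would collapse the
two symmetric bands the model describes.

## Synthetic clonal evolution

The generator provides ground truth for every stage.

* **Clone tree** — random (or fixed) rooted topology; per-branch
  division counts (default drawn from 50–500); SNVs assigned per branch
  under infinite sites, so clone SNV sets are nested along ancestry.
* **Epimutation drift** — each CpG flips per division (0→1 at
  `mu_gain`, 1→0 at `mu_loss`; defaults 0.002/0.002).  End states after
  `t` divisions are drawn from the two-state Markov chain closed form
  `π + (s − π)(1 − g − l)^t`, `π = g/(g+l)`, identical in distribution
  to stepping and far cheaper.  Every clone — including the root — is
  founded by a **single cell** (a tumour is clonal from one transformed
  cell; metastatic clones bottleneck at seeding): the founder drifts
  through the branch's divisions and the clone then expands into
  `cells_per_clone` (default 50) independent lineages over
  `expansion_divisions` (default 5) further divisions, which sets the
  within-clone epiallele diversity.  Fifty distinct lineages at a
  sequencing depth of 1000 keep true epialleles comfortably above the
  1% rarity filter.
* **Samples** — multinomial reads over the clone-fraction-weighted cell
  mixture; normal contamination is fully unmethylated molecules
  (removed by the >= 1-methylated filter, matching why that filter
  exists).  SNV records draw alt counts binomially from the
  CCF-implied allele fraction (diploid, m = 1); noise-free mode emits
  exact expectations for round-trip tests.  ctDNA is
  `Σ wᵢ · tissueᵢ` with binomial (CCF mode) or multinomial (haplotype
  mode) read noise.

### Default study conditions

Two frozen study designs drive the recovery experiments (and the
acceptance script):

* **Drift study** (`simulate_drift_study`): four extant clones related
  as ((c3,c4),(c5,c6)) through two unsampled ancestral lineages; 16
  CpGs; gain rate 0.02/CpG/division with loss 0.002 (CpG-island clocks
  drift hypermethylated; near-symmetric rates saturate multi-branch
  paths — pairwise distances then violate the four-point condition and
  no distance method can recover the topology); divisions: root 10,
  ancestral branches 15, leaf branches 5, expansion 3 (long shared
  history in the primary, recent brief metastatic expansions); 50
  cells/clone; purity 0.95; depth 1000.  Recovery is judged on the
  induced quartet over the four clones — the unmethylated reference is
  the rooting device, not part of the genealogy.  Under these
  conditions neighbour joining on the greedy-pairing matrix recovers
  the genealogy in ~97% of replicates; what this does *not* show is
  performance under the shallower or noisier drift regimes where the
  16-CpG barcode is information-limited.
* **Deconvolution study** (`simulate_deconvolution_study`): five
  lesions seeded independently from the primary (star clone tree), so
  each carries private mutations — a lesion whose only markers are
  truncal is structurally unidentifiable after the zero-variance drop,
  whatever the regression.  240 SNVs (40/branch; the 40 truncal ones
  are removed as zero-variance, leaving 200 informative features);
  tissue design matrix recomputed from binomially noised tissue VAFs
  through `compute_ccf`; ctDNA mixed at weights (0.6, 0.3, 0.1, 0, 0)
  with depth-1000 noise.  Mean per-component recovery error is
  ~0.004, absent lesions are pruned in ~100% of replicates, and the
  SNV-CCF and methylation-haplotype routes agree on the top lesion in
  ~100%.

## Known limitations

* The simulator models neutral drift and neutral mixtures: no
  selection, no spatial structure, no fragmentomics, and PCR/bisulfite
  conversion errors are not modelled — filters are exercised on clean
  calls.
* With 16 CpGs the epigenetic barcode is information-limited: realised
  drift on a short internal branch can be zero or erased by parallel
  gains, which bounds genealogy recovery away from 100% regardless of
  sequencing depth.
* Post-selection inference in the deconvolution (OLS-refit p-values
  after NNLS forward selection) is a convention, not exact inference;
  coefficients should be read as point estimates.
* The KS balance test assumes the fixed genome-wide σ transfers across
  segments; strongly depth-heterogeneous genomes would need per-arm σ.
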