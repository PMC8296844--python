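# Methods

`plastevo` re-implements, as a tested library, a comparative analysis of
plastid protein-coding genes across a set of related taxa: which genes are
pseudogenized or lost in which species, how fast each gene evolves, where
selection acts at the site and branch level, and whether selected sites
concentrate in particular functional gene groups.  This note records the
models, the tunable parameters, and the design decisions taken where the
analysis was genuinely open.

## Pseudogene lesion calling

Each (gene, taxon) coding sequence is aligned against an intact reference
ORF of the same gene (the longest cleanly translating copy, since a
terminally truncated copy still translates) and walked in the reference
reading frame.  The first of these events is recorded as the lesion:

* **frameshift** — the cumulative net indel length modulo 3 becomes nonzero
  and persists for at least `F = 10` reference codons.  A compensating indel
  restoring the frame within fewer than `F` codons is treated as evidence of
  a functional gene (a compensated frameshift), not a lesion.
* **premature stop** — an in-frame stop strictly before the terminal codon.
  A stop inside the final 5% of codons is tolerated with a logged warning.
* **truncation** — an alignment deletion running to the query 5' or 3' end
  and covering at least `T = 5%` of the reference.  A missing start region
  is reported as a truncation with first lesion codon 1.  An entirely
  missing sequence is the `absent` status (reported as truncation from
  codon 1, preserved fraction 0).

`intact_fraction = (first_lesion_codon - 1) / n_codons` drives the status
heatmap categories: `pseudo_severe` (< 0.25), `pseudo_moderate`
(0.25–0.75), `pseudo_mild` (> 0.75), plus `intact` and `absent`.  The
`F`, `T` and shading thresholds are declared package defaults — the kind of
cut-offs every such analysis needs but rarely states.

The scan alignment is glocal (reference end-overhangs free) with stiff gap
costs (match 2, mismatch −3, gap open −20, extend −4): free end-gaps keep a
genuine terminal deletion contiguous instead of letting the optimizer
scatter the query's last few bases into the gap, and the stiff internal gap
costs suppress spurious compensated indel pairs in divergent regions.  When
the end-overhangs are too short to be truncations the walk is redone on a
fully global alignment, so a small indel near an end is still localized to
its true codon.

## Codon-aware alignment

The built-in aligner exists so the pipeline and its tests need no external
binary; aligned FASTA from any other tool is accepted downstream.  Clean
ORFs are aligned progressively at the amino-acid level (guide order from
3-mer distances, profile Needleman–Wunsch with BLOSUM62, linear gap −10 per
column) and back-translated so every amino-acid gap is a 3-nt gap.
Untranslatable records — pseudogene candidates — are threaded onto the
frame anchor by global nucleotide alignment with affine gaps (2/−3/−5/−2),
which is what allows non-triplet, frameshift-revealing gaps.  Degapping any
output row reproduces the input exactly.  All dynamic programs use a fixed
tie-break (substitution preferred over gap-in-query over gap-in-ref), so
outputs are byte-reproducible.

## Masking, concatenation, windows

Rows called non-intact are replaced by all-gap rows of the same length;
columns left gap-only (insertions private to masked rows) are dropped so
each gene block keeps a codon-multiple width.  Genes are concatenated with
an explicit partition map.  Window tracks (default 100 bp, non-overlapping,
alignment coordinates) report pooled GC (gaps and N excluded from numerator
and denominator), gap fraction, and the per-column Fitch parsimony
substitution count on the fixed input topology.  Pooling GC across taxa
(rather than averaging per-taxon values) is a declared choice.

## Branch lengths and per-gene rates

Reference branch lengths are estimated once on the masked concatenate under
JC69 by coordinate-wise Brent passes (stop when the log-likelihood improves
by less than 1e-4); the topology is never re-estimated.  JC69 is
deliberately minimal: branch lengths only calibrate relative rates, and a
richer substitution model would add parameters without changing the rank
structure the rate track reports.  Each gene's **rate scaler** is then the
maximum-likelihood single multiplier of all reference branch lengths for
that gene's columns (bounded Brent on [1e-4, 50], tolerance 1e-6); the
relative rate normalizes scalers to mean 1 over genes.  An all-gap gene has
no defined rate (null); a gene driven to the lower bound is flagged
`no_signal`.  Fitch steps per ungapped column are emitted alongside as a
model-free cross-check track.

## Selection analysis

**Gene-wide Kn/Ks** is Nei–Gojobori (1986): per-codon fractional
synonymous/nonsynonymous site counts with mutations to stop codons
discarded from the per-position thirds; pathway averaging with equal
weights over stop-free orderings for codons differing at >1 position;
Jukes–Cantor correction of the proportions; averaged over all unordered
pairs of non-empty rows.  Pairs with Ks = 0 or saturated proportions
(p ≥ 3/4) are excluded from the average with a logged count; the ratio is
null when no pair remains.

**Method A (counting test).**  Ancestral codons per site by 61-state Fitch
parsimony (missing codons carry the full state universe; ties resolved
toward the minimal nonsynonymous change from the parent, then
lexicographically; the root takes the lexicographically smallest set
member).  Per-branch changes are classified syn/nonsyn with pathway
averaging and summed into per-site counts (s, n).  The neutral expectation
uses the site's NG86 opportunity fraction f = N/(N+S); `p_pos` is the upper
binomial tail of n out of s+n at success probability f (continuous
extension via the regularized incomplete beta, since pathway averaging
yields fractional counts).  A site is flagged at `p_pos ≤ 0.05` with at
least one reconstructed change.

**Method B (empirical-Bayes grid).**  A 20×20 grid of synonymous and
nonsynonymous rates (α, β) on [0, 5].  Per-site likelihoods come from
Felsenstein pruning under an MG94-style codon model with uniform codon
frequencies, the branch lengths fixed from the concatenate fit, and a
gene-level κ counted from reconstructed changes (κ = 2·ts/tv, clipped to
[0.5, 20]).  The generator is normalized so α = β = 1 corresponds to three
expected substitutions per codon per unit branch length.  Grid weights are
fitted by EM on the summed per-site log marginal likelihoods (the objective
is asserted non-decreasing every iteration); the per-site posterior mass on
β > α is the evidence for positive selection, flagged at ≥ 0.9.

**Consensus** sites are those flagged by both methods — the same
"confirmed by several methods" reliability rule the analysis is built
around.  The counting test is deliberately conservative (parsimony
undercounts multiple hits, the tie-break prefers synonymous
interpretations, and f ignores the transition bias), with an empirical
type-I rate far below its nominal 0.05; the EB grid carries most of the
power, and the intersection inherits the conservatism.  This is a known
property of the design, not a defect: the consensus list is meant to be
high-precision.

**Branch screening** aggregates the reconstructed per-branch syn/nonsyn
counts over sites, normalizes by the gene's total S/N site opportunities,
and reports branches with Kn/Ks > 1 carrying at least 3 substitutions.  It
is explicitly a screen, not a likelihood-ratio test.

**Ontology enrichment** pools consensus-selected vs non-selected site
counts per functional group (seven groups: ATP synthesis,
cytochrome/electron transport, *ndh* genes, photosynthesis, translation,
transcription, other), runs all pairwise two-sided Fisher exact tests with
Holm–Bonferroni step-down adjustment as one family, and emits each-vs-rest
tests as a second, separately adjusted family.  Pairwise-with-Holm is the
primary contract; the r×2 "overall" reading of a multi-sample Fisher test
is intentionally not implemented.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:
40–80 plastid genes (named from the canonical 78-gene angiosperm plastome
complement, round-robin across the seven ontologies; the trans-spliced
rps12 is excluded throughout) across 10–50 taxa evolved on one shared tree
(supplied Newick or a pure-birth tree rescaled to a configurable total
length, default 2 expected substitutions per site) under an MG94-style
codon model: per-site ω drawn from configurable classes (default 75% ω=0.3,
20% ω=1, 5% ω=5), per-gene rate multipliers scaling all branch lengths,
κ = 2, uniform codon frequencies.  Branch transitions are exact CTMC draws
via the matrix exponential of the 61×61 generator; stop codons are excluded
from the state space, so intact sequences always translate.  Lesions —
premature stop (codon substituted by TAA), frameshift (1–2 bp deletion),
truncation (deletion to the 3' end at a codon boundary), whole-gene
deletion — are injected after simulation on chosen (gene, taxon) cells and
recorded in `truth.json`.  Random streams are keyed by (seed, gene index),
so adding genes never perturbs earlier genes, and a fixed seed reproduces
the output byte-for-byte.

What the generator does **not** emulate: indel evolution along the tree
(intact rows are equal-length, so multiple alignment of undamaged genes is
nearly trivial), rate variation beyond the ω classes and gene multipliers,
base-composition heterogeneity, inverted-repeat structure, and annotation
errors.  Green tests therefore certify the statistical machinery and the
lesion logic, not robustness to hard real-world alignment problems.

## Numerical choices and problem sizes

Pruning partials are rescaled per node to avoid underflow; EM stops when
the objective improves by < 1e-6 or after 500 iterations; Brent tolerances
are 1e-7 (branch lengths) and 1e-6 (rate scalers).  The bundled statistical
checks run at deliberately desk-scale sizes — 20 taxa, 300-codon genes,
200 replicates for sampling intervals, 30 planted lesions — chosen so the
full suite completes in a few minutes on one core while keeping every
comparison statistically meaningful.

## Known limitations

* The counting test's binomial null is conservative under κ > 1; its
  per-site power at ω = 5 (20 taxa, tree length 2) is ~0.15–0.2, so the
  consensus list is short and high-precision rather than exhaustive.
* NG86 Kn/Ks is biased toward 1 at high divergence (pathway saturation);
  the replicate checks compare against its own sampling distribution, not
  against the generating ω.
* The scanner trusts its reference choice; if every copy of a gene is
  damaged, no scan is possible and the gene errors out rather than
  guessing.
* Trans-spliced genes (rps12) and mixed-strand joins are not extracted.
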