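# Methods

## Scope and data model

`hetsel` analyses an aligned set of allele sequences of one
allorecognition gene.  The natural *het-c* alleles of *Podospora
anserina* carry no indel variation, so sequences are required to be
equal-length, gap-free and strictly ACGT; IUPAC ambiguity codes are
rejected rather than expanded, because the intended input is clean
Sanger consensus and a silent expansion would corrupt the site counts.
All coordinates are 1-based inclusive; protein positions are numbered
from the initiator methionine, matching the residue numbering used in
the *het-c* literature (118, 133, 153).  Exon/intron structure is
supplied explicitly (YAML intervals) — the package does not do de novo
ORF finding, and the reference intron coordinates must come from the
GenBank record or user configuration.

## Polymorphism accounting

A site is polymorphic when its column holds ≥ 2 nucleotides; columns
with more than two states still count once (site-based accounting).  The
silent/replacement label of an exonic site is decided by
*background-restricted single-site swaps*: the site is silent iff, for
every codon actually observed at its codon position, exchanging the
site's observed states never changes the encoded amino acid (a change to
a stop counts as a change).  This attribution is per nucleotide site, so
a codon can contribute one silent and one replacement site without
double-counting at either level.  The alternative codon-level
attribution can be recovered from the emitted table (`codon_index` is
reported per site), but the per-site rule is the default because it is
the only rule under which "41 ORF sites, 6 of them silent" is a
well-defined partition of sites.

## Phylogeny

Distances: p-distance, JC69 (−3/4 ln(1 − 4p/3)) and Kimura 2-parameter
(from transition and transversion proportions; default, as a reasonable
model for closely related alleles — the original analysis does not state
its correction, so the choice is configurable and tree-based acceptance
is qualitative).  Neighbor joining follows Saitou–Nei: join the pair
minimizing Q(i,j) = (n−2)d(i,j) − R_i − R_j, standard branch-length
formulas, ties broken on the lowest (row, column) index pair for
reproducibility, negative branch lengths clamped to zero with an
aggregate warning.  On additive matrices the algorithm is exact, which
the suite verifies against random trees and against scikit-bio's
independent implementation.  Bootstrap supports resample alignment
columns with replacement (seeded); the support of an internal edge is
the percentage of replicate trees containing the same unrooted
bipartition, with bipartitions canonicalized by their smaller side.
Because index tie-breaking is order-dependent, supports are only
order-invariant on tie-free data; the near-star *het-c* alignment has
genuine Q-ties, which is why figure-style reporting suppresses weak
supports (the `min_support` option, e.g. 95).

## Codon substitution model

The engine works on the 61 sense codons of the standard code.  The
generator sets q_ij = 0 when codons differ at more than one position and
otherwise q_ij ∝ π_j, times κ for a transition and ω for an
amino-acid-changing exchange.  Equilibrium frequencies π default to F3×4
(position-specific nucleotide frequencies), with F1×4 and F61 (observed,
add-one pseudocount) as options; the original software's frequency model
is unstated, so this is a documented package choice.  The generator is
scaled so one unit of branch length is one expected substitution per
codon site *at the mixture level* (class generators share the
mixture-averaged rate), making branch lengths comparable across models.

Likelihoods use Felsenstein pruning over all 61 states with per-site
rescaling against underflow; transition matrices come from an
eigendecomposition of the π-symmetrized generator, verified against
`scipy.linalg.expm` and against exhaustive enumeration over internal
states on small trees (|ΔlnL| < 1e−8).

Site-class mixtures: M0, M1 {ω₀ ≤ 1, 1}, M2 {ω₀ ≤ 1, 1, ω₂ ≥ 1}, M3
(three free classes), M7 (Beta(p, q) discretized into K = 10
equal-probability categories represented by their within-bin means) and
M8 (M7 plus a spike at ω_s ≥ 1).  Free parameters are optimized by
L-BFGS-B on transformed coordinates (log for κ, ω and Beta shapes;
stick-breaking logits for proportions; bounded raw branch lengths), with
convergence on the likelihood at ~1e−10 relative tolerance and, for
mixture models, three seeded random restarts by default.  Branch lengths
are re-estimated together with the model parameters by default; the
model-series helper optimizes them once under M0 and holds them fixed
for the rest of the series, a standard practical compromise whose effect
on ΔlnL is marginal at this data size and which the caller can disable.

Nested pairs (M1, M2) and (M7, M8) are compared by 2ΔlnL against χ² with
2 df, without boundary correction — the historical convention for these
tests.  The null hypothesis pins parameters to the boundary of the
alternative, so the test is conservative; the suite's calibration run
(100 seeded null replicates at 8 taxa × 120 codons) observes a rejection
rate below nominal but within the 95% binomial interval of 5%.

Positively selected sites use naive empirical Bayes: P(k|x_h) ∝ p_k
L_h(ω_k) at the MLEs, a site being flagged at a level when the total
posterior of ω > 1 classes reaches it.  NEB (rather than BEB) matches
the era of the analysis; NEB is known to be overconfident when
parameters are poorly estimated, which is why the simulation tests check
*precision against the known labels*, not calibration of the posterior.

## Specificity analysis

Phenotypic classes are equivalence classes of identical reaction rows,
ordered and labelled by first-seen allele.  Implication rules A ⟹ B are
mined over all ordered tester pairs with non-vacuous support, reported
strict when exception-free.  The minimal discriminating set asks for the
smallest set of variable residue positions such that any two alleles in
*different* classes differ inside the set; same-class alleles may differ
freely (alleles ten residues apart can share a specificity, so
within-class homogeneity must not be required — demanding it would make
the documented 7-position answer infeasible).  The search is exact:
between-class pairs differing at a single position force that position;
remaining pairs are covered by breadth-first search over cardinality,
returning the lexicographically smallest optimum (or all optima on
request).  Determinant analysis reports every allele pair one residue
apart, labelled causal when the pair's classes differ.

## Population statistics

Class frequencies coarsen allele frequencies through the partition.  The
reactivity–frequency association is a Spearman rank correlation between
reaction-matrix row sums and sample frequencies, by default including
matrix alleles absent from the sample at frequency 0 (their absence is
part of the signal); it is reported as undefined when either variable is
constant.  Plasmid–genotype association uses Fisher's exact test for
2×2 tables and a seeded Monte Carlo conditional exact test (both margins
fixed, table probability via log-binomials, +1-corrected p) for r×2
tables — the samples are small enough that an asymptotic χ² would be
untrustworthy.

## Synthetic data

The generators produce every input the pipeline reads, with ground truth
retained.  Codon alignments evolve site by site along a tree (user
newick or a seeded Yule tree rescaled to a target root-to-tip height in
substitutions/codon): class label from the mixture, root codon from π,
branch transitions from the class's matrices, using the same scaling as
the fitting engine.  Incompatibility matrices satisfy declared
implication rules strictly, guarantee at least one reaction per allele,
and honor mutual-exclusivity pairs except in designated exception
alleles (emulating the one natural exception); unsatisfiable constraints
raise.  Population samples are multinomial.  One global seed fans out to
named substreams (CRC32 of the generator name as spawn key), so adding a
generator never perturbs existing draws.

The default "het-c-like" regime is 11 taxa and ~208 codons with a
conserved majority and a positively selected minority (M2 with ω =
{0.1, 1, 3}, p = {0.6, 0.25, 0.15}), mirroring the scale of the real
allele set; recovery tests that need more information use 16 taxa × 500
codons.  What the simulations do *not* emulate: recombination, indels
(the real data has none), selection on the partner WD-repeat loci,
sequencing error, and any within-population genealogical structure —
passing tests demonstrate the estimators' correctness under the model,
not robustness to model violation.

## Packaged fixtures

Two fixtures are transcriptions of documented facts: the 11×5
incompatibility matrix (derivable uniquely from the published class
memberships, hierarchy rules and reaction counts, and confirmed by
reproducing every published population percentage) and the Wageningen
count table (minimal integer reconstruction of the published percentages
at n = 110; exact counts were never published, so analyses of this table
are property-level, not digit-level).  The residue table and nucleotide
alignment are *synthetic stand-ins*: the real sequences are deposited in
GenBank and not redistributed here, so `datasets.py` constructs a
214-codon gene (three exons, two introns) that carries, by construction,
the documented variation — 26 variable residues in the documented
clusters, the single-residue determinant pairs at 118 and 133, the
ten-residue distance between het-c4 and het-c10, the unique 7-position
discriminating set, 50 polymorphic sites (9 in one intron, 41 in the
ORF, 6 silent of which 4 in het-c7).  Tests against these fixtures
validate the pipeline's bookkeeping and search algorithms exactly, and
the selection engine qualitatively (excess replacement variation yields
M0 dN/dS > 1 and a significant M1–M2 test); they do not reproduce the
published likelihood values, which depend on the true sequences.

## Numerical choices and degenerate inputs

Transition-probability entries are clipped at 0 after
eigen-reconstruction; per-site partial maxima are floored at 1e−300
before taking logs; JC69/K2P raise (naming the offending pair) when a
distance is undefined; NJ input matrices must be symmetric, finite and
hollow; bootstrap replicates whose resampled distances are undefined
count as not supporting any split.  `fit_model` reports non-convergence
in the result (and warns) rather than failing silently; a negative LRT
statistic beyond 1e−4 raises, as it can only mean an optimization
failure.  Beta category means use the regularized incomplete beta
function and are clipped to [0, 1].

## Known limitations

Branch and branch-site models, BEB posteriors, model variants M4–M6 and
M9–M13, and nucleotide model selection are out of scope.  The χ²
reference for the LRTs is conservative at the boundary.  NEB posteriors
inherit MLE uncertainty.  The exact search for discriminating sets is
exponential in the worst case (fine at C(26, 7) scale; pathological
inputs with no forced positions and many classes could be slow).  The
package analyses haploid allele samples and does not model population
structure.
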