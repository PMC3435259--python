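# Methods

## Problem and data model

Some transcripts carry several closely spaced modification sites whose
states are read out together on each sequenced molecule — the canonical
example being the five A-to-I editing sites (A, B, E, C, D) of the
serotonin 2C receptor mRNA.  Each read is a binary vector over the S sites
(1 = edited), and an individual's data reduce without loss to a histogram
of length 2^S: the count of reads showing each pattern.  The first listed
site is the most-significant bit of the pattern index, so with the default
site order (A, B, E, C, D) the pattern `11001` (A, B and D edited) has
index 25.  This MSB-first convention is internal bookkeeping only; no
result depends on it.

The scientific question is which sites depend on which: the joint
distribution of the S binary states, and a parsimonious factorisation of
it.

## Exhaustive model space

Every factorisation of the joint distribution corresponds to a labeled DAG
over the sites.  DAGs are enumerated exhaustively (29,281 at S=5) by
deciding each ordered pair in row-major adjacency-bit order with
transitive-closure pruning, which visits only acyclic graphs and yields a
deterministic lexicographic order; the count is cross-checked against the
standard inclusion–exclusion recursion for labeled DAGs.  DAGs encoding the
same conditional-independence model are merged into Markov equivalence
classes via the (skeleton, v-structures) signature — 8,782 classes at S=5.
Each class is visualised as a CPDAG (pDAG) computed by member census: an
edge is drawn directed only if every member orients it identically.  At
this scale the census is exact and simpler than rule-based compelled-edge
algorithms.

Class identifiers are the smallest member's enumeration rank.  They are
deterministic and reproducible across runs of this package, but they are a
package convention: integer model ids from other implementations (e.g.
ids derived from different DAG ranking schemes) will not match.

Enumeration is capped at S = 6 (3,781,503 DAGs); larger site sets are
refused, because every stage downstream is exponential in S.  The method
is intended for the small, densely read site clusters where it shines.

## Scoring

A model's sufficient statistics are the family counts N(x_i, pa_i)
obtained by marginalising the pattern histogram onto each node and its
parents.  Maximum-likelihood CPT entries are count ratios; configurations
never observed are reported as undefined rather than imputed, and
contribute nothing to the likelihood (0·ln 0 = 0).  Scores:

* log-likelihood  lnL = Σ_i Σ_pa Σ_x N(x,pa) ln θ̂(x|pa)
* BIC = −2 lnL + K ln N  and  AIC = −2 lnL + 2K, minimised, with
  K = Σ_i 2^{|Pa_i|}
* Bayesian score: log marginal likelihood under Dirichlet priors
  equivalent to one pseudo-measurement per possible pattern,
  α(x,pa) = 2^{S−1−|Pa_i|}, α(pa) = 2^{S−|Pa_i|}, maximised.  This
  uniform pseudo-sample keeps the score identical across the members of an
  equivalence class, and with no data the score is exactly 0 for every
  model.

All computation is in log space (log-gamma, no factorials).  Because a
score depends on a DAG only through its parent sets, the per-dataset score
of every one of the S·2^(S−1) distinct (node, parent-set) families is
precomputed once; scoring all 8,782 classes is then a vectorised
gather-sum, which is what makes per-individual sequences over a hundred
individuals take well under a second.  The log-likelihood omits no
data-dependent constant, but as in any model-selection setting only score
differences and rankings are meaningful.  Exact score ties between classes
are broken by the smaller class id and logged.

## Model selection outputs

Classes are grouped by pDAG edge count e = 0..S(S−1)/2 and the best class
M_e found within each group.  Edge importance is summarised by

* rank: the smallest e with the edge in M_e, and
* support: the fraction of M_rank..M_Emax containing it,

with edge identity always the unordered pair.  Repeating the fit per
individual yields, at each e, a tally of best classes; the
"equally supported" set is the prefix of the descending tally up to the
first model whose support falls significantly below the top model's in a
Bonferroni-corrected series of one-sided two-sample proportion z-tests
(pooled variance, divisor = number of comparisons performed).  The paper
trail behind this choice: the test family is described only as "proportion
tests" at level 0.05, so one-sided/pooled is this package's documented
choice; supporter counts are treated as marginal binomials, ignoring that
they come from the same individuals and sum to n.  The same test compares
the e-th most-supported edge against later edges to flag "additional"
edges whose support is not significantly lower than the basic set's
weakest member.  Per-edge appearance proportions carry the binomial
proportion variance p̂(1−p̂)/n (the count variance n·p̂(1−p̂) is also
exposed).

## Descriptive statistics

* φ-coefficient per site pair and individual (Pearson correlation of two
  binary columns, from the 2×2 marginal table); undefined when a margin is
  zero, in which case the individual is excluded from aggregation with a
  warning.  Across individuals, z = mean/(sd/√m) with a two-sided normal
  p-value — the standard-error form, one of two readings of the published
  procedure and the one adopted here — and Benjamini–Hochberg FDR across
  the S(S−1)/2 pairs.
* Jaccard (1 − n11/(n11+n10+n01)) and Dice (1 − 2n11/(2n11+n10+n01))
  distances between sites, single-linkage clustering on the pooled cohort,
  and a per-cluster confidence: the fraction of individuals whose own
  dendrogram contains an internal node with the identical site set (set
  identity, not height, since no height tolerance is defined for this
  notion in the literature it follows).
* Two-group comparison: the likelihood-ratio G statistic over the 2^S
  pattern categories with pooled expectations, and a subject-label
  randomisation null — subjects, not reads, are reassigned with group
  sizes fixed, and pooled group counts recomputed each repetition.  The
  p-value counts random statistics ≥ the observed one, a conservative
  convention; a (r+1)/(reps+1) estimator is available.  The permutation
  loop is vectorised in chunks, so the default 10^6 repetitions run in
  seconds to minutes on one core.

## Simulator

Synthetic cohorts are drawn from a ground-truth network: per individual
the CPTs are optionally jittered with independent logit-normal noise
(default sd 0, i.e. individuals as exchangeable replicates — the
between-individual model is deliberately the simplest one consistent with
treating individuals as replicates) and the reads drawn in one multinomial
pass from the exact implied 2^S distribution, which is equivalent to
ancestral sampling per read.  Jittered probabilities are clamped to
(1e−6, 1−1e−6) with a warning.  The generator has no read-level error
model (sequencing error, PCR bias) and no within-individual overdispersion,
so passing tests demonstrate correctness of the inference machinery under
the assumed sampling model, not robustness to artefacts of real library
preparation.

Presets fix the study conditions: `human-like` (101 individuals,
dependencies anchored at site A with D attached through B: A→B, B→D, A→C,
A→E, echoing the human edge-rank order), `rat-like` (19 individuals, hub
at B: B→A, B→D, B→C, B→E), and `null` (independent sites at plausible
editing levels: A, B high; E, C low; D intermediate).  Conditional
probabilities were chosen once so that the intended dependence ordering
holds clearly (e.g. rat-like: 0.90/0.08 for A|B down to 0.70/0.25 for
E|B).  Read depth defaults to 10^4 per individual — a desk-scale choice;
deep-sequencing studies of this receptor run to several 10^5 reads per
specimen, and full-scale depths are available by argument.

## Numerical and design choices

* Ties everywhere are broken deterministically (smaller class id,
  lexicographic site pair) and logged at INFO/WARNING level.
* Individuals with zero reads are kept at load time but rejected or
  skipped (with a warning) by every analysis stage.
* Pattern distance degeneracy (no read edited at either site of a pair)
  yields distance 1 with a warning.
* φ aggregation with sd = 0 is flagged degenerate: p = 0 if the common
  value is nonzero, else 1.
* The test suite uses small problem sizes chosen to keep the full run in
  minutes on one core: exhaustive cross-checks at n ≤ 4, full 5-site
  checks where vectorisation makes them cheap (score equivalence over all
  29,281 DAGs), 20-replicate recovery studies at 50×10^4 reads, and
  200/500-replicate calibration studies at reduced repetition counts.

## Known limitations

* Exponential in S by design; not a structure-search method for large
  site sets.
* Proportion tests ignore the dependence between supporter counts; the
  resulting p-values are approximate (the published analyses this follows
  make the same approximation).
* Only the one-pseudo-measurement-per-pattern Dirichlet prior is provided
  (with a configurable multiplier); no K2 or general BDeu priors.
* No χ² alternative to the G statistic and no bootstrap clustering
  confidence — only the per-individual support described above.
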