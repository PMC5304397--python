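# Methods

This note records the models implemented in `dupdyn`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would otherwise have to
reverse-engineer.

## Gene-family clustering

Families are Markov Cluster (MCL) partitions of a protein similarity graph.
Hits are kept when E-value < 10⁻⁵ (strict) and the alignment covers at
least 50% of the *longer* sequence of the pair; edges are weighted
min(200, −log₁₀ E) (E = 0 capped at 200), reciprocal hits merged by the
larger weight. The flow matrix starts from the weighted adjacency with
self-loops set per node to its maximum incident edge weight — with unit
loops on heavily weighted cliques the doubly-stochastic iteration collapses
to the identity and shatters genuine families, so the max-loop convention
is load-bearing, not cosmetic. Iteration alternates expansion (matrix
square) and inflation (elementwise power 2.1, column renormalisation);
entries below 10⁻⁵ are pruned per column as a stand-in for the mcl
binary's pruning schemes (exact parity with that binary is not claimed).
Clusters are attractor supports, overlapping systems merged so the output
is a strict partition; ties and orderings resolve lexicographically, making
the clustering a pure function of the graph.

Lineage-specific accumulation rates divide the number of group-specific
genes (or families — both counts are exposed) by stem + crown age of the
group in relative divergence time; crown age is 0 for single species. Group
ages are computed on a rooted timetree and verified in tests against an
independent root-distance computation.

## Pairwise dN/dS (NG86)

The estimator is Nei–Gojobori (1986) codon counting rather than the
codon-frequency-corrected YN00: every downstream decision (dS > 2
saturation cut, dS-threshold age classes) is threshold-relative, so the
simpler estimator shifts absolute values slightly but not the analysis
structure; externally computed dN/dS tables
can be substituted anywhere estimates are consumed. Sites: per codon
position, the fraction of single-nucleotide changes to other *sense*
codons that are synonymous (changes to stops excluded from the
denominator), so S + N = 3 × codons exactly. Counts: averaged over all
orderings of the single-nucleotide steps between a codon pair, skipping
pathways through stop codons; in the rare case every pathway is blocked,
the differences are split evenly and a warning is logged. Proportions are
Jukes–Cantor corrected (d = −¾ ln(1 − 4p/3)); 4p/3 ≥ 1 sets a `saturated`
flag (d = ∞) and such pairs are excluded wherever dS ≤ 2 is required.
ω is undefined when dS = 0.

Protein pairs are aligned globally (Needleman–Wunsch, BLOSUM62, gap open
11 / extend 1 — standard protein-search defaults) via Biopython's
PairwiseAligner; a brute-force enumeration over all alignment paths backs
this in tests. Codon alignments are threaded through the protein
alignment; columns with gaps, ambiguous nucleotides or stops never enter
the counting. Age classification is dS > threshold ⇒ "old"
(pre-speciation), ties "young"; the threshold is the arithmetic mean dS of
1:1 orthologs surviving the saturation filter.

## Paralog chain and loss rates

"Nearest paralog" is read per protein: each gene keeps its
highest-bitscore non-self within-genome hit passing the ≥ 150 aa / ≥ 30%
identity filters (bitscore ties to the smaller subject id), and the union
is deduplicated on unordered pairs — so a pair (A,B) can coexist with
(B,C) when best-hit relations are asymmetric. The strict ω filter removes
pairs with dN < 0.01 OR dS < 0.01 OR < 50 synonymous sites; the protocol
wording this rule follows is ambiguous between OR and AND of the site
condition, so the AND variant is available behind a flag.

A family counts as *ancestrally duplicated* in genome X when it contains a
within-X pair with threshold < dS ≤ 2; it has *lost* duplicates in the
sister genome Y when ≤ 1 of its members belong to Y. Loss rate =
lost/ancestral per direction; the function also returns the 2×2 table for
the chi-square comparison. This family-level operationalisation is the
package's reference definition; it reproduces the published table
arithmetic exactly (tests pin 224/382 → 59% and 69/285 → 24%).

## Birth–death family-size model

Family size evolves as a linear birth–death process with equal per-copy
gain and loss rate λ (per relative-time unit). With α = λt/(1+λt):

P(c | s, t) = Σ_{j=0}^{min(s,c)} C(s,j) C(s+c−j−1, s−1) α^{s+c−2j} (1−2α)^j

with state 0 absorbing. Rows are validated against the matrix exponential
of the truncated generator to 1e-8. Likelihoods use Felsenstein-style
pruning over sizes 0..S_max (S_max = max observed + 10 by default), with
per-node rescaling of partial likelihoods; the root prior is uniform on
1..root_max (root_max = max observed), conditioning on presence to match
the Fitch root-presence pre-filter (ties at the root resolve to "present",
which retains borderline families — the conservative direction for a
filter). Families whose copy-number range exceeds 200 are dropped before
fitting, as extreme families otherwise dominate (and can destroy) the
likelihood.

λ is fitted per branch class (branches keyed by their descendant leaf
sets; unassigned branches share a background class) by L-BFGS-B on log λ
in [10⁻⁶, 10], from a fixed ladder of starting values (0.001, 0.01, 0.1)
plus optional seeded random starts — deterministic given the seed. Nested
models are compared by 2ΔlogL against χ² with df = Δ(number of λ classes).
Ancestral sizes come from a max-product (Viterbi-style) pass over the same
state space; "expansion" means positive child − parent change. Per-family
expansion p-values are deliberately not implemented; cross-lineage
expansion claims use the exact two-sided binomial test at p = ½, and
per-taxon counts are normalised by the terminal branch length (relative
divergence time since the taxon's first ancestor).

## Expression filter chain

Counts are normalised by median-of-ratios size factors. The 40% quantile
filter ranks genes by mean normalised count over *all* samples (the
protocol leaves the statistic unstated; per-condition means are a
configuration switch) with lexicographic tie-breaks. The two-condition
test is deliberately *not* a DESeq reimplementation: it is a Wald test on
the log difference of normalised condition means with a **common-scale
method-of-moments NB dispersion** — each gene contributes
(pooled within-condition variance − mean)/mean², and the common dispersion
is the median over genes. Sharing one dispersion removes the 4-df noise of
per-gene variance estimates that otherwise wrecks both calibration and
power at 3 + 3 replicates; the statistic is referred to a t distribution
with n₁+n₂−2 df, whose heavier tails absorb the residual small-sample skew
of NB means (null simulations in the tests hold the < 5% tail near or
below nominal, and planted-DE simulations recover ≥ 80–90% of
well-expressed effects at empirical FDR ≤ 0.15). Externally computed
(p, log2FC) tables plug directly into the BH step and the final call.
BH is the literal step-up rule; DE requires q ≤ 0.10 AND linear fold
change ≥ 1.5 (|log2FC| ≥ log₂ 1.5 — applied on normalised means with a 0.5
pseudocount). qPCR quantification is 2^−(Ct_target − Ct_reference).

## Enrichment statistics

The 2×2 chi-square is Pearson's N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)], df = 1,
*without* continuity correction by default — required to reproduce the
published statistics (78.55, 295.03, 88.31, 195.62); Yates is a flag. The
DE-enrichment harness builds DE-versus-*rest* tables (a = |DE ∩ cat|,
b = |DE \ cat|, c = |cat \ DE|, d = the remainder); the overlapping
variant (whole genome as the second row) is available for sensitivity
analysis but does not reproduce the published 195.62. Mann–Whitney U uses
the exact permutation distribution when the smaller sample has ≤ 8
observations (and the enumeration is affordable), otherwise the normal
approximation with tie correction and 0.5 continuity.

## Synthetic data: what it emulates, what it does not

Family sizes: exact Gillespie simulation of the linear birth–death process
per branch (chosen over time-discretisation so the formula cross-check in
the tests is unbiased); root sizes 1 + Poisson, conditioned ≥ 1.
Sequences: root CDS uniform over sense codons; substitution proposals
arrive per nucleotide site at a tunable intensity, synonymous proposals
always fix, nonsynonymous fix with probability ω, stops never — so
realised dS grows ≈ intensity × path length and realised dN/dS tracks ω.
Gene genealogies record every duplication and speciation split, making
"duplicated before/after speciation" exact truth. Hits come from the
package's own aligner behind an edlib edit-distance prescreen
(pairs under ~25% approximate identity are skipped; random unrelated
proteins never reach reportable E-values, verified empirically) with a
Karlin–Altschul-shaped E-value surrogate E = m·n·2^(−bits),
bits = 0.385·score + 4.6. Count matrices are NB with per-sample size
factors, planted ±log2FC shifts, and DE membership odds multiplied for
designated categories.

The default two-genome world (200 families, stem and post-speciation spans
1.0 each, stem duplication 0.8/copy, tip duplication 0.15, per-copy loss
0.9 vs 0.45 — a 2× planted asymmetry — 180 codons, substitution intensity
0.12, ω = 0.2) gives a mean ortholog dS ≈ 0.25, emulating the published
aphid anchor of 0.26, and enough ancestral duplicates (~30–60 per
direction) that the 50-world end-to-end check measures pipeline
correctness rather than binomial sampling noise; the ensemble was sized
for that statistical power at design time. Worlds of this size run the
full chain in a few seconds each; the published genomes are two orders of
magnitude larger, and nothing here emulates assembly artefacts, isoforms,
codon-usage bias, indel evolution, horizontal transfer or expression
batch structure — so green tests certify the algorithms and their
statistical behaviour under the stated models, not robustness to those
real-data complications.

## Numerical and interface decisions

- Coordinates are 1-based inclusive everywhere; species default to a
  `SPECIES|gene` id prefix with an explicit mapping as override.
- A terminal stop codon is allowed and trimmed; internal stops are hard
  errors; codons containing N are excluded columns.
- Newick trees are parsed as rooted (`default-rooted`); unrooted trees and
  negative branch lengths are rejected. The naïve parse otherwise
  collapses the root bifurcation and corrupts stem lengths — a real bug
  caught by the age-oracle test.
- All randomness flows through `numpy.random.default_rng(seed)`; the same
  seed gives byte-identical synthetic outputs.
- MCL non-convergence after `max_iter` returns the current partition with
  a warning flag rather than raising.
- Problem sizes in the test suite (world counts, replicate numbers, state
  truncations) are the package's chosen validation conditions and are
  stated in the tests themselves.

## Known limitations

- NG86, not YN00: absolute dS/dN shift slightly against the published
  values; only printed-count arithmetic is reproduced exactly.
- The MCL pruning approximation can differ from the mcl binary's scheme 6
  on large dense graphs.
- The NB test is a calibrated stand-in, not DESeq; dispersion is common
  across genes, so genuinely high-dispersion genes are anticonservative.
- Tandem calling uses the ≤ 1 intervening-gene convention, not MCScanX's
  full collinearity machinery.
- The birth–death model fixes gain = loss (λ = μ) and has no
  among-family rate variation or assembly-error model.
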