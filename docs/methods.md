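# Methods

## Codon substitution model

Evolution of each codon column is modeled as a reversible continuous-time
Markov chain on the 61 sense codons of the standard genetic code (stop
codons are excluded from the state space and rejected on input). The
instantaneous rate from codon *i* to codon *j* is

    q_ij = π_j · κ^[transition] · ω^[nonsynonymous]

for pairs differing at exactly one nucleotide, and 0 otherwise. κ is the
transition/transversion rate ratio, ω the nonsynonymous/synonymous rate
ratio, and π the codon frequencies. Within a site-class mixture all class
generators share one scale factor, chosen so the expected substitution rate
averaged over classes is one; branch lengths are therefore expected
substitutions per codon averaged over the site distribution, and classes
with larger ω evolve proportionally faster. P(t) = exp(Qt) is computed by
symmetrizing the generator with √π and eigendecomposition; tiny negative
entries from round-off are clipped and rows renormalized.

Codon frequencies default to F3x4 (products of position-specific nucleotide
frequencies over the 61 sense codons, with Laplace smoothing of the
nucleotide counts and a relative floor of 1e-4 so every sense codon remains
reachable); `equal`, `F1x4`, and `F61` are available.

### Site-class families

* **M0** — one ω for all columns.
* **M1a** — ω₀ < 1 with proportion p₀, ω₁ = 1 fixed.
* **M2a** — M1a plus a free positive class (p₂, ω₂ > 1).
* **M3** — K discrete classes (K = 3 by default), free proportions and ω's.
* **M7** — Beta(p, q) on (0, 1), discretized into 10 equal-probability
  categories; each category's ω is the conditional mean of the beta over its
  decile (incomplete-beta differences), which preserves the beta mean
  exactly.
* **M8** — the M7 categories scaled by p₀ plus an eleventh class
  (1 − p₀, ω₁₀ ≥ 1).
* **Fixed-sites A/B** — model A is M0; model B gives the designated key
  partition its own ω with κ and branch lengths shared (partition rates are
  composition-weighted into the common scale). The default likelihood-ratio
  test uses df = 1 (one extra ω), configurable to 2.

### Likelihood, optimization, NEB

Column likelihoods use Felsenstein pruning over site patterns (duplicate
columns are compressed and weighted); gaps and ambiguous codons are missing
data (all-ones partial vectors), so an all-gap column contributes likelihood
one. Per-pattern rescaling guards against underflow.

Maximization is bounded L-BFGS-B on transformed parameters: log κ, log
branch lengths, logits for proportions (stick-breaking for three or more
classes), logit ω₀ (constrained below 1), log (ω − 1) for positive classes
(the M8 positive ω is bounded below at 1), log p, log q for the beta.
Convergence tolerance is 1e-8 relative; fits restart from jittered starting
points (seeded and recorded; 3 restarts by default). When a nested pair is
fitted, the alternative is additionally started from the null's MLE embedded
in the larger family, and a deficit beyond 1e-4 log-units triggers one
tighter-tolerance restart — lnL(alt) ≥ lnL(null) then holds up to optimizer
noise, and the LRT statistic floors at zero. Branch lengths are re-estimated
under every model by default; `branch_mode="fixed"` keeps the input tree's
lengths, and the pipeline's `fixed-at-m0` setting estimates them once under
M0 and reuses them (the configuration used by the heavier simulation studies
in the test suite, where it cuts fit dimension sharply at negligible cost to
the test statistics).

Naive empirical Bayes: at the MLEs, P(class k | column) ∝ p_k · L(column |
k); P(ω > 1) sums the posterior over classes with ω > 1; the per-column NEB
ω is the posterior mean. Columns with P(ω > 1) above 0.95 are called
"Positive" in the per-site report.

Likelihood ratio tests compare 2Δ = 2(lnL_alt − lnL_null) with the χ² upper
tail: Test 1 (M2a vs M1a, df 2), Test 2 (M8 vs M7, df 2), Test 3 (B vs A,
df 1 by default), Test 4 (M3 vs M0, df 4). The alternative is "tenable" when
p < α (default 0.05). Because the null often sits on the boundary of the
alternative's parameter space, the naive χ² reference makes Tests 1–2
conservative; the test suite asserts the empirical null rejection rate stays
at or below 8% at nominal 5%.

## Pairwise rates and subgroup admission

Nei–Gojobori counting: each codon position contributes one site, split
between synonymous and nonsynonymous according to its three
single-nucleotide alternatives. Mutations creating stop codons count as
nonsynonymous by default (so s + n = 3 exactly per codon); the variant that
excludes stop mutations from the alternatives is available, since published
implementations differ. Differences between codons that differ at k > 1
positions are averaged over all k! orderings of the single changes,
excluding orderings that pass through a stop codon (every sense-codon pair
retains at least one stop-free ordering, verified exhaustively in the test
suite). Site totals are averaged over the two sequences, columns with a gap
in either sequence are deleted pairwise, and proportions are corrected with
Jukes–Cantor d = −(3/4)·ln(1 − 4p/3), undefined (flagged saturated) when
p ≥ 3/4.

A subgroup is admitted when the maximum pairwise dN is below 1. While the
condition fails and more than three members remain, the member with the
largest mean dN to the others is removed (ties broken by label order); an
irreducible subgroup is flagged "N" and excluded from the diversity
regressions. Subgroups whose maximum dS reaches 3 (or with a saturated
synonymous proportion) are retained but flagged "S". A `criterion="mean"`
switch tests the mean-over-pairs dN instead of the maximum.

## Phylogeny

Protein distances are either Kimura-corrected, d = −ln(1 − p − p²/5), or
JTT-ML: the per-pair divergence time maximizing Σ ln π_x P_xy(t) under the
published JTT rate table (bundled as package data), with pairwise deletion
of gapped columns. Trees come from Saitou–Nei neighbor joining; negative
branch-length estimates are clamped to zero with the deficit shifted to the
sister branch, preserving the joined pair's path length. On additive
matrices the generating topology and branch lengths are recovered exactly
(tested against an independent implementation). Bootstrap support is by
column resampling with majority-rule consensus (support = bipartition
frequency); the replicate count is configurable (default 100 — the source
analyses do not state one) and the seed is an explicit required argument.

## Selection profiles

The per-subgroup ω profile is the per-column NEB ω from M7, or from M8 when
Test 2 rejects (the beta-plus-positive model is the right profile source
once its extra class is supported). ⟨ω_key⟩ averages the ten key columns. The null is 200 cohorts of
ten columns drawn uniformly without replacement within a cohort (with
replacement across cohorts) from all 7TM columns — key columns included by
default, with an exclusion switch. Reported per subgroup: the cohort grand
mean and SD, the z-offset (⟨ω_key⟩ − mean)/SD, a |z| > 2 flag, the ratio of
⟨ω_key⟩ to the grand mean, and the ω > 0.1 threshold flag marking subgroups
predicted not to bind a small molecule. Cross-subgroup comparisons use the
Kruskal–Wallis rank test over ligand categories and ordinary least squares
for the trend reports (the ratio regressions on log₁₀ scale), with
positively selected subgroups excluded by default and the exclusion list
recorded.

## Diversity

Shannon entropy per column in bits, gaps excluded from the frequencies by
default (a gaps-as-21st-symbol switch exists); the theoretical ceiling for
20 equiprobable residues is log₂20 ≈ 4.32 bits. The Karlin–Brocchieri
similarity of a column is the mean over unordered sequence pairs of
m(x,y)/√(m(x,x)·m(y,y)) with m the BLOSUM80 scores (taken from Biopython's
substitution-matrix collection). D_key is the mean pairwise JTT-ML distance
over the concatenated ten-key-column mini-alignment (a per-column averaging
mode exists; the mini-alignment reading is the default since the source
procedure is ambiguous); identical key residues give D_key = 0 and a flagged
infinite −log₁₀D_key. Diversity–selection regressions are OLS of each
measure on log₁₀⟨ω_key⟩ over admitted ("N"-free) subgroups, repeated
restricted to ⟨ω_key⟩ < 0.1.

## Synthetic data

The generator emulates the data shape of real subgroup analyses: subgroups of 3–10
paralogs, 190 aligned codon columns of concatenated 7TM fragments, ten key
columns at the bundled map's alignment indices (68, 71, 72, 114, 117, 121, 124,
168, 171, 175 ↔ BW 3.29 … 7.39). Columns draw a site class, a root codon is
drawn from π, and states evolve along the tree under the shared-scale class
generators; everything is a pure function of (config, seed) and fixture
bundles are byte-identical under a repeated seed.

Fixture regimes (root-to-tip heights in expected substitutions/codon):

* **strong-negative** (h = 1.0) — background (0.75, ω 0.03), (0.20, 0.25),
  (0.05, 1.0); key columns forced to ω = 0.02. Emulates the most conserved
  small-molecule receptor subgroups; the divergence is needed because NEB
  estimates for conserved columns in 4-taxon alignments cannot fall much
  below ~0.1 on shorter trees.
* **mixed** (h = 0.5) — (0.50, 0.1), (0.35, 0.5), (0.15, 1.0); nothing
  forced.
* **positive-at-key** (h = 1.0) — background (0.55, 0.1), (0.30, 0.5),
  (0.15, 4.0) with the three signature columns (key 68 and non-key 49, 53)
  forced to ω = 6 and the other nine key columns pinned to ω = 0.3. This
  emulates an MRGX-like pain-receptor subgroup in which positive selection
  is pervasive across the 7TMs while exactly one key position is positively
  selected; with only three positive columns in 190, the site-model LRTs
  have little power at four taxa, so the pervasive-class structure is the
  realistic emulation target.

Four-taxon fixtures use a fixed symmetric quartet (tip branches 0.7h,
internal 0.3h): random coalescent shapes occasionally produce near-star
trees carrying almost no phylogenetic signal, which adds across-seed
variance unrelated to the properties under test. Larger fixtures use random
coalescent-shaped trees rescaled to the regime height. Every emitted bundle
is verified against the admission bounds (max dN < 1, max dS < 3) and
redrawn from a shifted stream if a draw violates them.

What the generator does **not** emulate: real GPCR residue composition
(codon frequencies are uniform by default), indels (fixtures are gapless;
the likelihood engine nevertheless treats gaps as missing data), among-site
rate variation beyond the ω classes, and recombination. Passing tests
therefore demonstrate correctness of the machinery and statistical behavior
under the model, not robustness to model violation in real alignments.

## Numerical and design choices

* 1-based MSA codon-column coordinates in all I/O.
* Ambiguous CDS nucleotides become missing codons; duplicate FASTA labels
  are hard errors; a trailing stop codon on a CDS is tolerated, internal
  stops are not.
* The ligand-category rules are applied in order: all-orphan → orphan; more
  than two orphans, or non-orphan members spanning more than one chemical
  class (or any class outside small/lipid/peptide) → divergent; otherwise
  the unanimous class. The packaged tables annotate each member's ligand
  chemistry; the overlapping subgroup 13b is excluded from category counts.
* Simulation studies in the tests use single-restart fits with branch
  lengths fixed at M0 estimates, and the following problem sizes: parameter
  recovery at 8 taxa × 500 codons × 20 replicates per ω; detection at 20
  fixture seeds; null calibration at 100 replicates of 4 taxa × 190 codons.
* The bootstrap replicate count, M3 class count (3), frequency scheme
  (F3x4), fixed-sites df (1), and α = 0.05 are documented conventions where
  the source analyses are silent, and all are configurable.

## Known limitations

* NEB posteriors ignore MLE uncertainty; with 3–5 sequences the per-column
  P(ω > 1) is noisy, and single-column identification can fail even for a
  true ω = 6 column (a Bayes-empirical-Bayes treatment is out of scope).
* The χ² reference for boundary LRTs is conservative; no mixture-χ²
  correction is applied.
* JTT-ML distances use the standard JTT table but do not reproduce any
  particular legacy program's discretization bit-for-bit; downstream use is topology
  and rough distances.
* No branch models, branch-site models, or ML-based pairwise dN/dS.
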