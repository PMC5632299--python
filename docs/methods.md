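# Methods

`flightsel` implements a comparative molecular-evolution analysis of
flight gain and loss: codon-model likelihood tests for episodic positive
selection on focal branches, pooled-branch dN/dS comparisons for relaxed
selection, replicated-lineage candidate calling, and functional
over-representation statistics. Everything runs end to end on synthetic
codon alignments the package generates itself, so every stage is
testable without external sequence data.

## Codon substitution model

The engine is a Goldman–Yang (GY94) codon model over the sense codons of
the active genetic code (61 states for the standard nuclear table, 62
for the invertebrate mitochondrial table; both available per gene set).
The instantaneous rate from codon *i* to *j* is zero unless the codons
differ at exactly one nucleotide position, and otherwise proportional to
the target codon frequency π*ⱼ*, multiplied by κ for transitions and by
ω = dN/dS for nonsynonymous changes. The chain is time-reversible
(π*ᵢ*q*ᵢⱼ* = π*ⱼ*q*ⱼᵢ*), so transition probabilities P(t) = exp(Qt) are
computed by eigendecomposition of the symmetrised generator
diag(√π) Q diag(1/√π), with scipy's scaling-and-squaring `expm` as a
fallback for ill-conditioned inputs.

Codon frequencies default to F3x4 (products of position-specific
nucleotide frequencies estimated from the alignment, renormalised over
sense codons, with a one-count pseudocount); equal and F1x4 are
selectable.

**Rate scaling.** A single-ω matrix is scaled to one expected
substitution per codon per unit branch length. For site-class mixtures
(the branch-site models) the classes are put on a common time scale:
per branch category, effective time for class *c* is
t·μ(ω*c*)/Σ*c'* p*c'* μ(ω*c'*), where μ(ω) is the mean rate of the
unnormalised generator (linear in ω). Branch length then means expected
substitutions averaged over site classes, and sites in a class with
ω > 1 genuinely substitute faster — without this, episodic selection
would only change the synonymous/nonsynonymous composition of changes,
not their number, and most of the test's power would vanish. The
simulator uses exactly the same scaling, closing the
generative/inferential loop.

## Likelihood and fitting

Likelihoods use Felsenstein pruning over codon states, vectorised across
distinct site patterns, with per-node rescaling against underflow. Any
codon containing a gap, N, or IUPAC ambiguity letter is treated as fully
missing data (partial-likelihood vector of ones); this is a documented
choice, not a reproduction of any particular codeml gap setting.
Site-class mixtures are the probability-weighted sum of per-class site
likelihoods, where each class assigns its own ω per branch class.

Because quasi-Newton fitting evaluates the likelihood under one-
parameter perturbations, the engine caches P matrices by (κ, ω, t) and
node partials by a subtree signature of the (ω, t) pairs below the node;
site classes that differ only on the foreground branch then recompute
only the rootward path.

Maximisation is bounded L-BFGS-B on transformed parameters: log κ
(bounds 0.01–100), log ω (10⁻⁴–999), site-class proportions through a
logistic stick-breaking pair (p0+p1 and p0/(p0+p1)), and
ω₂ = 1 + eˣ so the branch-site alternative respects ω₂ ≥ 1 (the null
fixes ω₂ = 1). Multi-start (default 3 starts, seeded jitter around
heuristic initial values) makes fits deterministic given a seed.
Nested fits are started from the null optimum so the nesting inequality
lnL₀ ≤ lnL₁ holds to optimizer tolerance; the LRT statistic is clamped
at zero.

**Branch lengths.** Input branch lengths are taken as given; before a
nested comparison a single tree-wide scale factor is fitted under the
single-ω model and the scaled lengths are then fixed for both nested
fits. Full per-branch re-estimation exists behind
`branch_lengths="full"` but is not the default: at desk scale the extra
30+ dimensions slow each fit by an order of magnitude and mostly add
noise that cancels in the LRT, since the null and alternative share the
same lengths either way.

## Selection tests

*Branch-site test* (`branch_site_test`): model A (four site classes;
a fraction p₂ of sites allowed ω₂ ≥ 1 on the foreground branches)
against A1 (ω₂ = 1). 2Δℓ is referred to χ²₁ with df = 1. The 50:50
boundary mixture is available behind `null="mixture"`; χ²₁ is the
default because it is conservative at the boundary, which the null
simulations confirm (rejection rates below nominal α). A
positive-selection call requires significance *and* fitted ω₂ > 1 with
p₂ > 0.

*Branch-rates test* (`branch_rates_test`): a 3-rate branch model
(background / flightless / flying, one ω each) against the 2-rate model
pooling flightless+flying; df = 1. The direction field records which
focal class has the higher fitted ω; the relaxed-selection call
requires significance, ω_flightless > ω_flying, and both focal ω's in
(0, 1) — i.e. weakened purifying selection, not positive selection.

*Multiple testing*: Benjamini–Hochberg step-up within one family per
(gene set × test × focal lineage), family-wise α = 0.05 by default.
The adjustment delegates to statsmodels and is cross-checked against a
hand-rolled step-up implementation in the tests.

## Comparative design

`unique_focal_candidates` keeps genes significant on a focal branch but
on neither of two control branches (upstream/downstream of the trait
origin). `tally_candidates` counts significant detections per gene
across flightless panels, subtracts the counts across flying panels
(floored at zero per gene), and keeps genes with net count ≥ 3 by
default; genes absent from a panel's tested universe contribute no
count there, and a per-gene panels-tested denominator is reported.
`direction_sign_test` is the exact two-sided binomial test at p = ½,
doubling the smaller tail and capping at 1 — the convention under which
a 12-of-14 split gives p = 0.013. (An 11-of-13 split gives 0.0225
under this and every other standard exact convention we enumerated.)

## Enrichment statistics

For a category with K members among N background genes and O observed
among n candidates: expected count E = (K/N)·n and fold enrichment
FE = O/E, where E enters the division at full precision — display
values are rounded half-away-from-zero to one decimal afterwards
(two decimals below 0.05). Rounding E before dividing is wrong: with
(K, N, n, O) = (21, 1229, 21, 3) it yields 7.5 instead of the correct
8.4; a regression test pins this.

One-tailed p-values: Fisher's exact over-representation is the
hypergeometric upper tail P(X ≥ O) (inclusive of the observed table;
under-representation is P(X ≤ O)); the EASE-penalised variant reduces
the observed-in-category cell by one with margins unchanged,
p = P(X ≥ O−1), so a singleton hit scores 1 and EASE ≥ Fisher always.
Published DAVID p-values are treated as approximate cross-checks only —
DAVID's exact margin adjustment is described inconsistently in the
literature, and our convention reproduces the printed values to within
about a factor of two but not exactly. The binomial variant is
P(X ≥ O) with X ~ Bin(n, K/N); it reproduces the printed
process-category p-values exactly at their printed precision.
Grouped-term tests (e.g. wing-related or mitochondrion/ATP/OXPHOS
unions) are ordinary Fisher calls on user-defined category unions.
No additional FDR layer is applied to enrichment p-values: the
gene-level tests feeding the candidate lists are already corrected.

## Synthetic data

The generator emulates the statistical structure of a multi-lineage
flight-loss study: 11 flightless lineages (3 female-only) against 9
flying lineages by default, each on its own random-join sub-tree of
14–19 taxa with one focal stem branch, plus a combined rates tree with
flightless and flying clades (default 4 each, 3 taxa per clade) over
background taxa for the pooled-branch comparison. Branch lengths are
drawn uniformly from 0.02–0.2 expected substitutions per codon —
shallow, transcriptome-scale divergences. Defaults κ = 2 and background
ω = 0.05 describe typical purifying selection on conserved
single-copy orthologs; mitochondrial-like scenarios use flying/
flightless ω of 0.02/0.03. Simulation draws the root codon from π and
samples each branch transition from the same P(t) the likelihood uses
(site-wise transition sampling, not event-level Gillespie simulation);
a branch-site class is drawn once per site and applies across the whole
tree. Annotation tables assign category members uniformly, except that
planted categories over-sample candidate genes by a configurable factor.

What the generator does *not* emulate: indels and alignment error,
codon-usage heterogeneity across genes, among-site rate variation
beyond the branch-site classes, and selection regimes that shift along
a branch. Passing tests therefore demonstrate that the inference
machinery is correct and calibrated under its own model class, not that
real transcriptome alignments satisfy that model.

## Problem sizes and calibration checks

Desk-scale sizes used by the test suite and the acceptance script:
oracle equivalence on ≤4-leaf, ≤3-site instances against explicit
internal-state enumeration; ω-ordering recovery on 8-taxon trees with
1000-codon genes (ω_flightless = 0.08 vs ω_flying = 0.02); null
calibration on 300-codon genes; the end-to-end scenario plants 5
relaxed genes (ω 0.1 vs 0.02) among 45 no-difference genes at 300
codons on a 32-taxon rates tree. Under these conditions the ordering is
recovered in ≥95% of replicates, null LRT rejection stays below nominal
α (χ²₁ at a boundary is conservative), and the BH-significant set
recovers the planted genes with an exact-Fisher recovery p ≪ 0.05.

## Known limitations

- No Bayes empirical Bayes site identification: detection is
  gene-level, as in the analyses this package reproduces.
- No NEXUS input, no alignment estimation or masking.
- Branch-site power on a single short focal branch is intrinsically
  low at a few hundred codons; the per-panel demonstrations reflect
  this honestly.
- The EASE convention is one of several in circulation; its p-values
  should not be compared across tools at face value.
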