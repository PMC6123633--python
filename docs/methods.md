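# Methods

`symscreen` implements a lineage-specific positive-selection screen for
comparative genomics of dinoflagellates (and structurally similar settings):
given protein families clustered across a set of genomes, it identifies
families in which the stem lineage of a focal clade — here the coral
endosymbiont genus *Symbiodinium* against other dinoflagellates with
*Perkinsus marinus* as outgroup — shows an excess of nonsynonymous
substitution. Around that core test it provides the auxiliary statistics such
a screen needs: family filtering, tree-congruence paralog removal, pairwise
dN/dS for duplicated gene pairs, hypergeometric term enrichment, and
Dollo-parsimony gain/loss of gene families.

## The branch-site model and its likelihood

The substitution process is a GY94-type codon model on the 61 sense codons:
the instantaneous rate from codon *i* to *j* is zero unless the codons differ
at exactly one position and *j* is a sense codon, and otherwise

q_ij = π_j · κ^[transition] · ω^[nonsynonymous],

with κ the transition/transversion rate ratio, π the equilibrium codon
frequencies and ω = dN/dS the selection intensity. The model is
time-reversible, so the generator has a real spectrum under the π-symmetric
similarity transform; transition matrices P(t) = exp(Qt) are computed by a
single symmetric eigendecomposition per generator, which makes repeated
exponentials over many branch lengths cheap.

The branch-site mixture (model A) assigns each codon site to one of four
classes:

| class | weight            | background ω | foreground ω |
|-------|-------------------|--------------|--------------|
| 0     | p0                | ω0 ∈ (0,1)   | ω0           |
| 1     | p1                | 1            | 1            |
| 2a    | (1−p0−p1)·p0/(p0+p1) | ω0        | ω2           |
| 2b    | (1−p0−p1)·p1/(p0+p1) | 1         | ω2           |

"Foreground" branches are marked on the tree (`#1` label suffix in Newick);
the default foreground is the stem branch of the focal clade, with an option
to extend the marks to every branch inside the clade. The null model fixes
ω2 = 1; the alternative frees ω2 ∈ [1, 999]. The test statistic is
2(ℓ_alt − ℓ_null), referred to χ²(1); because ω2 = 1 lies on the boundary of
the alternative this reference is conservative, and the 50:50 {0, χ²(1)}
boundary mixture is available as an option.

Branch lengths are measured in expected substitutions per codon under the
background class mixture: one shared scale factor, computed from the class
weights and the background ωs, divides the raw generators. This keeps branch
lengths comparable across classes and between the null and alternative fits.

Likelihoods are computed by Felsenstein pruning over site-pattern-compressed
alignments. Two structural optimisations matter: (i) the two background
classes are pruned as independent single-class passes with contiguous
matrices, and (ii) classes 2a/2b share every partial likelihood from
subtrees that contain no foreground branch, so only the path from the marked
branches to the root is recomputed with the ω2 matrices. A gap or ambiguous
codon at a tip contributes an all-ones partial vector. Partial likelihoods
are rescaled by their maximum at each internal node with the log-scale
carried separately, so deep trees cannot underflow.

## Model fitting

Fitting is maximum likelihood with L-BFGS-B over transformed parameters:
log κ, stick-breaking logits for (p0, p1), a logit for ω0 and
log(ω2 − 1 + ε) for ω2, so all constraints are built into the
parametrisation. Gradients are numerical; convergence uses a relative
function tolerance of 1e-8.

The protocol is two-step, as is standard for branch-site screens: M0 (single
ω, free branch lengths) is fitted first, and the branch-site null and
alternative are fitted with branch lengths fixed at the M0 estimates. For M0
the package offers per-branch optimisation (`branch_mode="free"`, the
default for standalone fits) or a single scale multiplier on the input
tree's relative branch lengths (`branch_mode="scale"`). The screen pipeline
uses `scale`, on the reasoning that family trees arriving from upstream ML
inference already carry informative relative lengths and the selection test
is driven by the ω parameters, not by per-branch length refinements. The
pipeline also holds κ fixed at the M0 estimate in both branch-site models
(`fix_kappa`); since the same value is used in null and alternative, the
models remain nested and the LRT remains valid, at a large saving in
function evaluations.

ω2 sits on a boundary at 1 where the likelihood surface often has a local
optimum that traps ascent methods. Rather than relying on random restarts
alone, the alternative fit first profiles the likelihood over ω2 at fixed
remaining parameters (evaluations that reuse the cached background pruning
pass and are nearly free), starts from the best profiled value, and then
refines jointly. Additional random restarts (deterministic in the seed) are
available through `n_starts`; every fit is a pure function of its inputs and
seed, so reruns are bit-identical.

## Pairwise dN/dS (NG86)

For duplicated gene pairs inside syntenic collinear blocks the package uses
the Nei–Gojobori (1986) counting estimator: per-codon synonymous and
nonsynonymous site counts (changes to stop codons excluded, each position
contributing one site split by the synonymous fraction of its remaining
changes, so S + N = 3 per codon), averaged over the two sequences; observed
differences at multi-hit codons averaged over all equally weighted minimal
mutational pathways, excluding pathways through stops (falling back to all
pathways when every one is blocked); and the Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3). A proportion ≥ 3/4 in either class flags the pair
saturated; ω is reported only when dS > 0 and unsaturated, and excluded
pairs are counted rather than silently dropped. A counting estimator was
chosen over an ML pairwise method because it is assumption-light, fast over
tens of thousands of pairs, and exactly checkable against an independent
literal implementation.

## Family filtering and the paralog filter

Families are filtered in the order: composition (≥ 4 proteins including at
least one from the focal genus; the count is over proteins, not taxa),
column trimming (a column is dropped when its gap fraction exceeds 0.5 —
gap characters are `-` and `.`, ambiguity codes count as residues), and
alignment size (≥ 60 retained columns over ≥ 4 rows). The trimmer is a
deliberately simple, deterministic stand-in for heuristic alignment-cleaning
tools: its behaviour is fully specified and testable, which matters more
here than reproducing any particular heuristic.

Families with at most one sequence per taxon are single-copy (orthologous)
and proceed directly. Multi-copy families pass only if their gene tree is
consistent with pure co-orthology: (i) all focal-genus sequences form an
exclusive monophyletic clade (in the unrooted sense — one side of some
branch), and (ii) the tree collapsed to genus level is topologically
identical (Robinson–Foulds distance 0, unrooted) to the reference species
tree collapsed to genus level and pruned to the genera present in the
family. Collapse requires every genus with ≥ 2 tips to be exclusively
monophyletic; a monophyletic genus occupies one side of a branch, so
pruning to one representative tip per genus preserves the genus-level
topology exactly, which is how the collapse is implemented. "Congruent at
genus level" is interpreted as this collapse-and-compare; branch support
values are ignored (the criterion is purely topological), and a polytomy
that lacks a reference bipartition counts as a difference.

## FDR control and enrichment

The screen's family-level p-values are adjusted with Storey q-values:
π0 is estimated as #{p > λ}/(m(1−λ)) on the grid λ = 0.05, 0.10, …, 0.95,
smoothed with a natural cubic spline and read off at the largest λ, clamped
to (1/m, 1]; q-values are π0 times the BH-adjusted values with a
cumulative-minimum enforcement. Degenerate grids fall back to π0 = 1 (plain
BH) with a warning. Benjamini–Hochberg is available as an alternative and is
the method used for term enrichment, where terms (not genes) are the
multiple-testing units and the test is the hypergeometric upper tail
P(X ≥ k). Families or terms are called significant at adjusted p (or q)
≤ 0.05. Ties in p order stably by unit id, so output order is reproducible.

## Presence/absence screening and Dollo gain/loss

A panel gene is called present in a taxon when at least one similarity hit
reaches E ≤ 1e-5 (boundary inclusive). Gene-family histories are
reconstructed under Dollo parsimony: each family present anywhere is gained
exactly once, on the branch above the MRCA of its present tips (the root if
the MRCA is the root), and losses are the minimal set — one per maximal
all-absent clade inside the origin subtree. The reconstruction requires a
rooted tree; in the screen's setting the tree is rooted with the outgroup
basal, and the gene-panel analysis is run on the focal subtree plus its
immediate outgroup.

## The synthetic-data generator

The generator produces every input the pipeline consumes, with planted
truth, under conditions that emulate the motivating study:

- **Species tree** — 15 taxa: a 4-lineage focal clade (*Symbiodinium*) on a
  marked stem, *Polarella glacialis* and nine other dinoflagellate lineages,
  and *Perkinsus marinus* attached at the root as outgroup. The topology is
  Yule (uniform splits); branch lengths are exponential draws rescaled so
  the mean is exactly 0.2 substitutions per codon — a divergence depth at
  which the lineages are clearly separated but far from saturated.
- **Codon alignments** — 300 codons per family, evolved site by site: class
  from the mixture weights, root codon from π, and each branch transition
  sampled from the exact matrix exponential. Defaults: κ = 2, p0 = 0.45,
  p1 = 0.35 (so 20% of sites fall in the foreground-selectable classes),
  ω0 = 0.2, ω2 = 8 for selected families. π comes from an F3×4-style
  construction over a seed composition with G+C = 0.56, matching the coding
  G+C of the genomes that motivated the design.
- **Planted structure** — an exact 30% of families evolve under the
  alternative; 20% of the *unselected* families are contaminated with a
  planted paralog: a duplicated sequence grafted either next to an
  unrelated non-focal taxon (breaking genus monophyly) or inside the focal
  clade (breaking focal exclusivity); a further fraction receives a benign
  within-taxon duplicate (a co-ortholog that must survive the filter).
  Keeping selection and paralogy disjoint makes sensitivity well-defined:
  a selected family planted as a paralog would be excluded by design and
  could never be detected.
- **Dollo matrices** — one gain on a uniformly chosen branch per family;
  each branch below the origin loses the family with probability
  P(Poisson(rate × length) ≥ 1).

Everything is a pure function of (config, seed). What the generator does
*not* emulate: indels and alignment uncertainty (alignments are gap-free
except where grafting adds sequences), rate variation beyond the four-class
mixture, base-composition heterogeneity across lineages, gene-tree
discordance from incomplete lineage sorting, and assembly or annotation
error. Tests passing on this generator therefore demonstrate correctness of
the inference machinery under the model's own assumptions, not robustness
to real-data violations of them.

Because the simulator reuses the same generator matrices as the likelihood,
simulator-vs-likelihood agreement alone would be circular; the tests that
validate the simulator (stationarity of tip frequencies under long
branches, class-weight recovery, distributional equality of the ω2 = 1
alternative and the null) deliberately avoid the pruning code, and the
likelihood itself is validated against exhaustive internal-state
enumeration with matrix exponentials cross-checked against an independent
Padé implementation.

## Numerical and design choices

- Codon frequencies: F3×4 by default (position-specific nucleotide
  frequencies from the alignment), with F1×4 and equal-frequency options;
  frequencies are floored at 1e-6 and renormalised so the similarity
  transform is always defined.
- Transition matrices are clipped at 0 to remove eigendecomposition
  round-off; rows then sum to 1 within 1e-10 across t ∈ [0, 50].
- Negative LRT statistics (optimiser noise under the null) are clamped to 0.
- Unconverged fits are propagated as flagged results, never exceptions; the
  pipeline records such families as `fit_failed` and continues.
- Problem sizes in the validation suite are scaled to desk hardware: the
  likelihood oracle sweeps ≤ 4-tip trees × ≤ 3 codons; LRT calibration uses
  100 null replicates at 6 taxa × 200 codons and power 50 replicates at 300
  codons; M0 recovery 20 replicates at 8 taxa × 500 codons; the end-to-end
  screen 200 families at the full 15-taxon, 300-codon setting; the
  acceptance script reports the same quantities at moderately smaller
  replicate counts.

## Known limitations

- No Bayes-empirical-Bayes identification of selected sites; the screen
  reports family-level evidence only.
- Pairwise dN/dS requires equal-length in-frame CDS (pairs from the
  simulator satisfy this; real pairs need upstream codon alignment, which
  is outside this package's scope).
- The q-value spline estimator of π0 is noisy below ~50 tests; for short
  p-value lists BH is the safer choice (`fdr_method="bh"`).
- The congruence filter is strict: any genus-level rearrangement discards
  the family, trading sensitivity for a paralog-free test set — the
  appropriate trade-off for a selection screen, where paralogy inflates
  false positives.
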