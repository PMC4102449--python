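# Methods

## The problem

Arbuscular mycorrhizal (AM) symbiosis is an ancient association between
land plants and glomeromycete fungi. Several plant lineages
(Brassicaceae among them) have lost the ability to host AM fungi, and
the genes of the symbiotic toolkit tend to disappear with the trait.
`symbiodrop` implements the comparative-phylogenomic machinery for
detecting such convergent gene loss: a screen for genes missing from a
focal (non-host) species set against a resampled background null, a
logistic detection-probability model that turns transcriptome
non-detection into calibrated absence calls, a stepwise refinement
cascade against additional non-host datasets, a randomization-based
enrichment test, and maximum-likelihood ancestral reconstruction of
the host/non-host trait. A synthetic-data generator reproduces the
statistical structure of such a study so every stage is testable
without genome downloads.

## Ortholog groups

Gene family trees (tips = genes, annotated with species) are
partitioned into ortholog groups: the maximal *species-unique* clades,
i.e. clades whose tip species are all distinct while the parent
clade's are not. These clades partition the tips, and each OG has zero
to one gene per species, which makes an OG × species presence matrix
well defined. Within a family, the OG with most members is flagged
primary; exact ties break to the deeper node, then to the
lexicographically smallest member gene id — an arbitrary but
deterministic rule. Unrooted inputs are treated as rooted as written;
extraction is root-sensitive and no automatic rerooting is attempted.

## The apparent-loss screen

For a presence matrix with ternary states (present / absent /
unknown), a row shows **apparent loss** for a species set F when it is
absent in *every* member of F and present in at least `n_min` species
outside F. Genome incompleteness alone produces such patterns, so the
focal count is compared with the distribution of the same statistic
over random species sets of size |F| — exhaustively when C(S, k) ≤
10⁵, otherwise by seeded Monte-Carlo sampling (default 10⁴ subsets,
drawn from the full panel; an option excludes the focal species). A
focal count more than two SD above the background mean (a one-sided
rule: only excess loss is interesting) flags the candidate set as
signal rather than incompleteness. Required-clade filters (e.g.
"present in at least one distant host lineage") are applied *after*
the z computation, as an additional requirement, so the z score always
refers to the pre-filter count.

Unknown cells are conservative everywhere: unknown never counts as
absent inside F nor as present outside it, so missing data cannot
manufacture loss signal — it can only cost power.

## Detection-probability model

The probability of observing gene *i* in species *j*'s transcriptome,
given the gene is present, is

    p_ij = logistic(α_i + β_j),

with a gene (expression-level) effect α_i and a species
(transcriptome-coverage) effect β_j on the log-odds scale. The model
is fitted by maximum likelihood on the cells where presence is assumed
a priori — conserved genes in every species, symbiosis-specific genes
in host species — using Newton/IRLS with step-halving, which makes the
log-likelihood provably non-decreasing per iteration; convergence at
ΔlogL < 10⁻⁸ or 100 iterations. Since α_i + β_j is invariant to the
shift (α+c, β−c), identifiability is fixed by zeroing the first fitted
species' β; all probabilities are shift-invariant.

Separation is handled in two distinct ways:

* a gene **never** detected in its training cells is *degenerate*: it
  carries no information about its own detectability, its predictions
  are forced to 0 and flagged "presence cannot be rejected" (so its
  absence can never be supported);
* a gene or species **always** detected (or a species never detected)
  is *separated*: its maximum-likelihood effect is infinite. These
  levels are flagged but kept in the joint fit, where Newton leaves
  them at a large finite iterate whose predicted probabilities
  saturate at 1 (or 0). They are excluded from parameter-recovery
  comparisons because no finite estimate exists to recover. We do not
  pin such effects to a fixed constant inside the fit: in fully
  separated instances the likelihood supremum requires *pairs*
  (α_i + β_j) to diverge jointly, and clipping one coordinate breaks
  the other's fit.

For a gene undetected across a species set, the combined probability
of having been detected at least once, if present in all of them, is
P_i = 1 − Π_j (1 − p_ij). Absence is called supported when P_i ≥ θ;
θ defaults to 0.95 and is always an explicit parameter. A per-cell
view (p_ij ≥ θ) is reported alongside.

**Hold-out validation.** A species with both a genome and a
transcriptome lets the procedure be audited: genes present in the
genome but undetected in the transcriptome are all truly present, so
every supported absence call on them is a false call. The reported
rate divides supported calls by *evaluated* genes (the convention of
the study design this mirrors; among the calls themselves, all are
false by construction — both numbers are recoverable from the result).

## Enrichment test

A candidate list of size L is compared with m (default 10) random
lists of the same size drawn without replacement from a caller-supplied
universe. The 2×2 table [[s, L−s], [r, mL−r]] (candidate vs pooled
random × in-reference vs not) is tested with Pearson's χ², df 1, no
continuity correction; a per-list (unpooled) mode exists because the
pooling convention is not uniquely determined by the procedure's
description. The exact hypergeometric upper tail P(X ≥ s) serves as an
independent check; the two agree in direction, and the χ² procedure is
calibrated (type-I error 0.05 ± 0.02 at nominal 0.05 in the null
simulation of the test suite: U = 5000, K = 150, L = 300, 2000
datasets). Percent overlap is reported as 100·s/L rounded half-up to
one decimal.

## Ancestral reconstruction

The binary host/non-host trait evolves under a two-state
continuous-time Markov model with rates q01, q10, equal-rates by
default (all-rates-different available), root prior equal by default
(stationary optional). Likelihood uses the pruning recursion with the
closed-form 2-state transition matrix P(t) = π + e^{−(q01+q10)t}(I−π);
rates are maximized by bounded deterministic search on the log scale
(Brent for ER, L-BFGS-B for ARD; rate bounds 10⁻⁸–100 per unit branch
length). Trees without branch lengths get unit lengths. Marginal state
probabilities come from an inside–outside pass and equal the re-rooted
pruning computation at every node. Transition branches are edges whose
endpoint maximum-a-posteriori states differ; exact posterior ties
resolve toward the parent's state (root ties to host) to avoid
spurious transition pairs. The Fitch parsimony minimum is reported as
a cross-check. When all tips share one state the rate MLE sits at the
0 boundary; this is returned directly with a warning.

## Synthetic studies

The generator emulates the design of a ~30-species study in which one
clade lost the trait once:

* **Tree**: Yule (pure-birth) topology, unit branch lengths. The loss
  clade is guaranteed by growing the backbone on n−k+1 lineages and
  expanding one uniformly chosen tip into a k-tip Yule subtree, so a
  stem branch for the non-host clade always exists. Tree shape is not
  the object of study.
* **Gene classes**: `conserved` genes present everywhere (default 10);
  `symbiosis-specific` genes present in all hosts, absent in the whole
  loss clade (default 20, the approximate size of the characterized
  symbiotic toolkit); `background` families (default 300) present at
  the root and lost irreversibly (Dollo-like, no regain) at 0.05 per
  branch — enough lineage-specific loss to give the screen a
  non-trivial background.
* **Data sources**: loss-clade species always carry genomes (they are
  the screen's focal set); about 30% of host species are
  transcriptome-only. Every species carries a transcriptome column.
* **Genome incompleteness**: genome cells are blanked to *unknown* at
  rate 0.02 — masking hides information, it does not assert absence.
  Transcriptome-only presence columns hold present where detected and
  unknown otherwise, because non-detection in a transcriptome is never
  evidence of absence.
* **Detection layer**: Bernoulli with α_i ~ N(1, 1.5²), β_j ~ N(0, 1²)
  log-odds, giving conserved-gene detection rates around 70–90%,
  resembling deep transcriptomes; false positives default to 0 (the
  detection model has no false-detection term) and exist only for
  robustness experiments. All randomness flows through a single
  seeded PCG64 generator: identical configs give bit-identical
  studies.

What the generator does **not** emulate: sequence-level homology
search (presence calls are the input boundary), expression magnitude
or tissue effects, gene regain, correlated incompleteness between
neighboring genes, and more than one trait-loss event per study.
Passing tests therefore show that the statistical machinery behaves as
designed under its own assumptions, not that those assumptions hold in
any particular real dataset.

## Problem sizes and tolerances in the test suite

The suite checks the detection fit against an independent GLM
maximizer at 10⁻³ on small (≤5×5) non-separated instances; OG
extraction against exhaustive clade enumeration on 1000 random trees
of ≤12 tips; pruning likelihoods against full enumeration at 10⁻¹⁰ on
≤8-tip trees; background nulls against hand enumeration and 3-SE
Monte-Carlo bands; single-loss transition recovery over 200 simulated
scenarios (panels of 10–16 species, clades of 3–5); parameter recovery
on a 200-gene × 30-species study (r ≥ 0.9 for both effect vectors);
and the hold-out false-call rate over 100 seeded studies of 150 genes
× 15 species against the closed-form rate implied by the true
Bernoulli probabilities (3 SE plus 0.03 plug-in slack, since the
empirical rule thresholds fitted rather than true probabilities).
These sizes were chosen as the smallest at which each property is
statistically sharp.

## Known limitations

* The screen's background null treats random species sets as
  exchangeable with the focal set; phylogenetic autocorrelation of
  incompleteness is not modeled.
* The detection model assumes independence of detections across cells
  given the effects; shared-tissue or batch structure would violate
  it.
* The enrichment χ² relies on large expected counts; for small
  universes the hypergeometric oracle is the safer statistic.
* Marginal ancestral reconstruction reports per-node marginals, not
  joint histories; stochastic character mapping is out of scope.
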