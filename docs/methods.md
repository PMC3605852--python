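# Methods

`divsel` analyzes population-divergent positive selection at a single
multi-allele locus sampled from two populations — the setting of gamete-
recognition genes such as sea star bindin, where 40 diploid individuals per
population are clone-sequenced, alleles are phased by cloning, and the locus
carries repetitive domains with extensive length variation. This note
records the models, the numerical choices, and what the synthetic data do
and do not emulate.

## Allele QC (`alleles_qc`)

Each individual contributes 6–10 aligned clone reads assigned to one or two
alleles. The consensus is the per-column majority over the clones of an
allele; ties are broken by lexicographic base order (A<C<G<T<-) so the
operation is deterministic (a tie is logged; at 6–10x depth ties are rare).
The sequencing error rate is the fraction of clone bases disagreeing with
their allele consensus, over columns where both carry an unambiguous base;
single-clone alleles are excluded (their consensus is the clone itself, so
they carry no information about error). Singleton recoding replaces any
base carried by exactly one allele in a column with the column's majority
base — the rationale is that when the singleton frequency matches the
independently estimated error rate, singletons are most parsimoniously read
as errors. Gaps and Ns are never singletons and never created or destroyed;
the operation is idempotent. `N` is missing data everywhere. Coordinates
are 1-based inclusive alignment columns; codon indices are alignment-column
triplets of the coding span. The recombination breakpoint that splits the
alignment into independently analyzed partitions is a config value, not
inferred.

## Population structure (`popgen_structure`)

Pairwise distances are Kimura two-parameter with the alignment gap as a
fifth character state. K2P itself does not define a fifth state, so: a
base-vs-gap mismatch enters the transversion class (a gap is maximally
unlike both transition partners), gap-vs-gap counts as identity, and
columns with N in either sequence are dropped (pairwise deletion). When the
K2P logarithm argument is non-positive the raw mismatch proportion is
returned and flagged as saturated.

Phi_ST is the two-level distance AMOVA fixation index: sums of squares from
squared pairwise distances (total scaled by 1/N, within-group by 1/n_g),
variance components from the expected mean squares with unequal group
sizes, Phi_ST = sigma_a / (sigma_a + sigma_w). Negative estimates are
reported as computed. The permutation test shuffles allele (gene-copy)
labels between populations with sizes preserved and uses the add-one rule
p = (1 + #{Phi_perm >= Phi_obs}) / (n_perm + 1); the seed is mandatory.
Default n_perm is 10,000.

Phi'_ST = Phi_ST / Phi_ST_max, where Phi_ST_max is Phi_ST recomputed after
replacing every between-population distance with D_max. Two choices of
D_max: (i) the maximum observed distance in the matrix; (ii) the distance
of two sequences differing at every site of the fragment. The K2P formula
diverges at full saturation, so for (ii) the default cap is the mismatch
proportion (D_max = 1.0 substitutions/site, finite and stable); the largest
finite K2P value at double precision (~4.85) is available as an
alternative. Under either cap D_max does not depend on the fragment length
itself, because the distances are per site.

## Branch-site selection test (`codon_selection`)

The core model is the branch-site mixture ("modified model A") over the 61
sense codons of the standard nuclear code. Site classes: class 0 (weight
p0, omega0 <= 1 everywhere), class 1 (p1, omega1 = 1 everywhere), classes
2a/2b (weight p2 split in ratio p0:p1; omega0 or 1 on background branches,
omega2 >= 1 on foreground branches). Foreground branches are defined by the
sampling population: terminal branches to alleles from the focal population
plus internal branches whose descendant tips all come from it. The LRT
compares the alternative (omega2 free) against the null (omega2 = 1), with
2*delta-lnL referred to chi-square with 1 df; because the null allows
foreground-neutral sites, the test is conservative.

The generator is Goldman–Yang: q_ij nonzero only for single-nucleotide
codon changes, proportional to pi_j, times kappa for transitions and omega
for nonsynonymous changes. All class matrices share one normalization — the
stationary rate of the omega = 1 matrix with the same kappa and frequencies
— so classes with different omega keep their relative substitution rates
(an omega2 > 1 class genuinely evolves faster), and branch lengths are
expected substitutions per codon for a neutral site; any constant factor is
absorbed by the jointly optimized branch-length scale. Per-class
self-normalization, which leaves only the synonymous/nonsynonymous
composition as signal, is available as an option but severely weakens both
the LRT and site identification. Codon frequencies default to F3x4
estimated from the ungapped coding data (positional frequencies floored at
1e-6 and renormalized).

Likelihoods use Felsenstein pruning over the 61 states with per-node
rescaling against underflow; site patterns are compressed. P(t) comes from
the spectral decomposition of the reversible generator (symmetrized by
sqrt(pi)), one eigendecomposition per distinct omega. A codon containing a
gap or N at a tip is fully missing at that tip (all-ones partial), the
likelihood-level analogue of pairwise deletion; this keeps indel-adjacent
codons informative for the alleles that carry them. A stop codon at an
ungapped tip is an input error, reported with its codon site.

Fitting maximizes over (kappa, p0, p1, omega0[, omega2][, scale]). The
class proportions are profiled out exactly: the four class weights factor
as an outer product of (p0+p1, p2) and (p0, p1)/(p0+p1), so for fixed rate
parameters the proportions satisfy closed-form EM updates (two fixed
starts, tolerance 1e-8 lnL, so the profiled objective is smooth and
deterministic). The outer search is L-BFGS-B on log/logit-transformed
parameters (omega0 in [1e-6, 1], omega2 in [1, 999], kappa in [0.1, 50])
from >= 3 dispersed starts; the alternative model is warm-started from the
null solution and floored at the null lnL (the null sits inside the
alternative's parameter space at omega2 = 1), so 2*delta-lnL is never
negative. A fit is flagged converged when
the two best restarts (including an optional jittered confirmation restart
from the best optimum) agree within 0.01 lnL. Branch lengths are taken
from the input tree and jointly rescaled by one ML factor by default;
fixing them is a config choice, used in the simulation studies below where
the true lengths are known.

Site identification is Bayes empirical Bayes: the posterior probability
that a codon belongs to class 2a or 2b, averaged over a grid prior with
(p0, p1) uniform on the simplex (10x10 midpoint grid), omega0 on 10
midpoints of (0,1), omega2 on 10 midpoints of (1,11); kappa, scale and
frequencies stay at their MLEs. Sites with posterior > 0.95 are flagged. A
naive empirical Bayes mode (everything at the MLEs) is the fallback.
Robustness to gene-tree uncertainty re-runs the null/alt pair and BEB over
a set of candidate trees and reports the fraction significant and per-site
flag frequencies. Rooted trees are used for labeling; an outgroup used
only for rooting can be pruned before fitting.

## Repeat architecture (`repeat_architecture`)

Repeat copies are extracted from configured per-copy spans (alignment
coordinates); an all-gap span is an absent copy. Copy distances reuse the
K2P-gap model for consistency (p-distance optional). Neighbor joining is
the standard Saitou–Nei agglomeration with deterministic tie-breaking by
taxon label and negative branch lengths clamped to zero with the deficit
moved to the sister branch (the pair still spans d_ij); on additive
matrices it recovers the generating tree exactly.

The gene-conversion screen flags (a) whole-copy events — a copy whose
nearest paralog consensus is a different paralog at identity >=
min_identity while the same copy index in most other alleles is nearest its
own paralog (this guards against degenerate paralogs that are simply
similar everywhere); and (b) phase-shifted events — a window of at least
min_window columns crossing a copy boundary that is identical (>=
min_identity) to the window offset by one or two whole copies. Only
positive offsets are reported, because a match at +k from boundary b is the
same event as a match at -k from boundary b+k. Copy-number covariation
between two domains classifies alleles as varying from the modal copy
number and tests the 2x2 table with a Yates-corrected chi-square, df = 1.

Yates correction here floors each |O-E| - 0.5 term at zero (the correction
can only shrink, never overshoot); the classical unclamped form is an
option. For tables with |O-E| < 0.5 in every cell, the clamped statistic is
exactly 0 while the classical form can report a small positive value — the
clamped form is the default because overshooting the expectation is an
artifact, and it agrees with scipy's continuity correction.

## Indel analysis (`indel_analysis`)

An indel type is a maximal run of consecutive gap columns with a distinct
(start, end) signature carried by at least one allele: sharing across
alleles does not multiply types, and runs sharing a start but differing in
end are distinct types. Insertions and deletions are not polarized. A type
is assigned to the region class containing its start column; a run the
region map does not cover is tagged unassigned with a warning. The density
test compares observed type counts in coding vs intron sequence with
expectations proportional to region lengths, using the clamped Yates
chi-square (df = 1). For the study-scale worked example (22 types over
2850 coding bp, 2 over 1285 intron bp) the statistic is 4.78.

## Synthetic data (`synthetic_data`)

The generator emulates the two-population design end to end and is the
basis of every recovery test. Genealogies come from msprime's structured
coalescent: two populations (default 20 diploids each; the focal population
with the larger Ne, 30,000 vs 5,000, mirroring the sixfold diversity
contrast), splitting 50,000 generations ago (~200 kyr at ~4 yr/generation)
with low symmetric migration (1e-5/generation). Branch lengths are
generations times a per-codon substitution rate, or are rescaled to a
target total tree length when one is set; the default dataset target is
3 substitutions/codon. Codon sites are drawn from the four model classes
and evolved with the same generators the inference uses, so no stop codons
are emitted and round-trip parameter recovery is well defined.

Structural variation overlays the coding alignment: a collagen-like domain
(4 copies x 36 nt) and a tandem-repeat domain (9 copies x 96 nt); per-
allele copy counts drawn per population (focal: collagen 1-4 with mode 3,
tandem 5-9 with mode 8; other population nearly fixed), realized as gap
runs over the trailing deleted copy spans, i.e. indels aligned to copy
boundaries; a few small codon-multiple indels in the nonrepetitive tail,
concentrated in the focal population; and a neutral HKY intron (branch
lengths /3, per-nucleotide) with rare planted deletion types. Gene
conversion can be planted: whole-copy events overwrite a copy with the
donor paralog's consensus (computed with the same majority rule as the
detector, so identity is exactly 1), and phase-shifted events copy a
boundary-spanning window one copy downstream. Clone reads are 6-10 per
individual split between its alleles with iid per-base errors at 0.00128
(the published clone-error estimate). Every generator draws from the
config seed; identical seeds give byte-identical FASTA.

What the generator does not emulate: recombination within the analyzed
partition (the analysis assumes a recombination-free partition),
selection-driven allele-frequency dynamics (selection enters only through
per-site omega on foreground branches, not through the genealogy),
mid-copy repeat indels, alignment error, or an intron embedded inside the
coding region (the synthetic intron is appended after the coding span; the
region map carries the layout, so downstream code is agnostic).
Passing recovery tests therefore show the estimators are correct under the
assumed model, not that the model captures every feature of real data.

## Simulation study sizes

Chosen to make each check informative on a single CPU; all seeds are fixed.

* LRT null calibration: 200 replicates, 20 tips x 200 codons, omega2 = 1;
  rejection at alpha = 0.05 must stay below 6% (the branch-site null is
  conservative by construction).
* Power and site recovery: 20 replicates, 40 tips x 300 codons, omega2 = 4,
  p2 ~ 0.1; expected: >= 80% significant LRTs, omega2 MLE in [2, 8], BEB
  median sensitivity >= 60% with on average <= 1 false positive.
* Both use genealogies rescaled to a total tree length of 8 expected
  substitutions/codon, within the range customary in branch-site power
  studies; at shallower depths (e.g. total length 3) the LRT retains full
  power but site-level posteriors are honestly borderline and BEB
  sensitivity drops to ~25% — a statement about information content, not
  about the estimator.
* Fits in these studies use fixed (true) branch lengths, 3 starts, and no
  confirmation restart; the defaults (joint rescaling, confirmation) are
  for real data where truth is unknown.

## Known limitations

* The branch-site machinery assumes the gene tree; the multi-tree
  robustness summary quantifies, but does not remove, that dependence.
* BEB averages over a grid prior at the MLEs of kappa and scale; full
  uncertainty in those is not propagated.
* The AMOVA is two-level, two-population only.
* The conversion screen requires equal-width copy spans within a domain
  and detects only events that leave near-identity to a non-homologous
  paralog; old or partial conversions below the identity threshold are
  invisible.
* K2P distances treat every gap column as one difference, so a long
  deletion contributes its full length; this matches the "gap as
  difference" convention the structure statistics assume, and is one
  reason coding-length variation inflates between-population distance.
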