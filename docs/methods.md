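# Methods

## The ordered independent spacer-loss (OISL) model

A CRISPR array is an ordered sequence of spacer identities, leader (5′) end
first. The model assumes (i) each spacer is deleted independently at rate 1
(time is therefore measured in expected deletions per spacer), (ii) new
spacers are inserted only at the leader end, at rate ρ relative to the
per-spacer deletion rate, and (iii) the two haplotypes of a pair sit at the
same distance *t* from their most recent common ancestor (a single
divergence-time parameter per pair). Under (i) a spacer survives one branch
with probability p = e^(−t), so an ancestral spacer is:

* retained in both lineages ("shared") with probability p²,
* retained in exactly one ("internal-unique") with probability p(1−p) per
  lineage,
* lost in both — and thereby *unobservable* — with probability (1−p)².

### Pairwise alignment

Because insertion happens only at the leader and deletion never reorders
spacers, the spacers common to two arrays must appear in the same relative
order; the aligner partitions each array into shared, internal-unique
(unique, at or trailer-ward of the leader-most shared spacer) and
leader-unique (unique, leader-ward of all shared spacers — candidate
post-divergence insertions) classes, and raises a collinearity error on
order-discordant input rather than guessing (such pairs are outside the
model). When two arrays share nothing the leader/internal boundary is
undefined; all unique spacers are counted internal, and the pair's distance
is capped (below).

### Likelihood and estimation

Spacers deleted in both lineages leave no trace, so each observed
ancestral-class spacer is conditioned on observability,
P(observable) = 1 − (1−p)² = p(2−p):

    log L = n_s·log[p/(2−p)] + (n_a + n_b)·log[(1−p)/(2−p)]
            + log Pois(k_a; λ) + log Pois(k_b; λ),   λ = ρ(1−p)

where n_s counts shared, n_a/n_b internal-unique and k_a/k_b leader-unique
spacers; the number of post-divergence insertions still surviving at a tip
is Poisson with mean ρ(1−p) by exponential thinning. The conditioning
matters: the unnormalized product of class probabilities p² and p(1−p) over
observed spacers looks natural but yields an inconsistent estimator — its
maximizer converges to p̂ = 1/(2−p) rather than p, shrinking every
divergence time (at simulated truth t = 0.3 it recovers ≈ 0.23). With the
normalizer the MLE is consistent, and when k_a = k_b = 0 it is closed form:

    p̂ = 2·n_s / (2·n_s + n_a + n_b),   t̂ = −log p̂,   ρ̂ = 0.

With leader-unique spacers present, ρ is profiled (λ̂ = mean leader count,
clipped at ρ_max) and t is maximized numerically by a coarse grid plus
bounded Brent refinement (tolerance 10⁻⁸ on t). The search domain is
bounded: t ∈ [0, t_max] with t_max = 10 (p ≈ 4.5·10⁻⁵ — beyond this the
surface is flat for any realistic array) and ρ ∈ [0, ρ_max] with
ρ_max = 50. The ρ bound is required, not cosmetic: for a pair differing
*only* by leader insertions the unconstrained supremum is at t → 0,
ρ → ∞ and is never attained. ρ is estimated per pair; a shared ρ across
all pairs would be a natural alternative but couples all pairwise
estimates.

The reported pairwise distance is 2·t̂ (tip to tip through the ancestor).
Pairs with no shared spacers get distance 2·t_max instead of an error, so
downstream matrices stay total; the minimum-spanning-network builder can
treat that cap as "absent edge".

## Rooted neighbour joining with branch clamping

Standard NJ agglomeration on the 2·t̂ distance matrix, modified so that no
branch is ever negative: when a joined pair's branch estimate is negative
it is set to zero and the deficit added to the sister branch, preserving
that pair's tip-to-tip distance; if the pair distance itself is negative
(possible between internal nodes of a non-metric input) both branches
collapse to zero. Q-criterion ties are broken by smallest pair distance,
then lexicographic clade labels — the distance preference keeps clock-like
inputs balanced (pure lexicographic tie-breaking can join a non-cherry when
all Q values tie, which is exactly the ultrametric case). The final edge is
rooted at the depth-balancing point (equal mean tip depth on both sides),
which reduces to the equal split for two taxa and makes tips equidistant
from the root on ultrametric input; patristic distances are invariant to
where on that edge the root sits. Downstream population-structure analyses
use the tree's patristic distances.

## Hierarchical AMOVA

Each read is one individual (one bacterial cell; PCR amplification bias is
knowingly ignored). For nested strata (region ⊃ habitat ⊃ site ⊃ host ⊃
section ⊃ replicate) the sums of squares are the classic distance form
SS(group) = Σ_{i<j∈group} d²ᵢⱼ / n_group. Variance components solve the
expected-sum-of-squares equations of the nested random-effects model, with
coefficients computed directly from group sizes via
E[d²ᵢⱼ] = 2σ²_w + 2Σ_k σ²_k·[i, j differ at level k]; on two levels this
reproduces the textbook n_c coefficient, and it handles unbalanced designs
at any depth. Negative components are reported as-is, never truncated.
Φ at level k is σ²_k over the sum of components at k and finer; Φ_total is
the among-groups fraction of total variance.

Significance is by permutation (seed mandatory): to test level k, whole
level-(k+1) units are permuted among level-k groups within their
level-(k−1) parents; individuals are permuted when k is the innermost
grouping. One consequence worth knowing: with few sub-units the achievable
p-values are coarse (six habitat blocks in three regions admit only 90
distinct assignments, so p ≤ 0.01 is unreachable no matter how many
permutations are drawn). Power analyses here therefore size designs by the
number of *units below the tested level*, not by reads.

Squared distances behave as Euclidean ones only if the matrix is
Euclidean-embeddable; phylogenetic distance matrices frequently are not, so
the AMOVA entry point expects a Lingoes-corrected matrix: if the smallest
eigenvalue of the Gower-centred −d²/2 is −c < 0, the constant 2c is added
to all off-diagonal squared distances — the smallest additive correction
achieving embeddability; an already-Euclidean matrix passes through
unchanged.

Pairwise F_ST between populations is the among fraction of a two-level
variance partition, on 0/1 haplotype identity ("haplotype-frequency" mode,
the classic F_ST for gene markers) or on supplied distances (Φ_ST, used
for CRISPR patristic distances); p-values permute individuals between the
two populations. Mantel correlations between population-pair matrices are
one-sided (greater), with all n! permutations enumerated for ≤ 6
populations; non-significant entries (own permutation p > 0.05) are either
zeroed — negative differentiation values are clamped to 0 in this mode
only — or excluded pairwise, with an error if fewer than three usable
pairs remain.

## Haplotype calling from CCS-like reads

Edit thresholds are Levenshtein distances (substitutions + indels), because
long-read consensus errors are indel-rich; the default budget of 5 edits
corresponds to ~85 % identity on a typical 35 nt spacer and is applied to
primers and spacers alike. Occurrences are found with edlib, iteratively
(best hit, mask, repeat), so overlaps resolve greedily by ascending edit
distance, then leftmost position. Reads are orientation-normalized by their
primer hits before classification. Exactly one QC category per read, by
precedence: MISSING_PRIMER (either primer absent), TOO_SHORT (insert
< 33 nt after primer trimming — about one spacer), MIXED_ORIENTATION
(spacer hits on both strands), MISORDERED (duplicate spacer hit, or order
inconsistent with the catalog's ancestral spacer order when one is known),
IRREGULAR_SPACING (an inter-hit gap differing from the repeat length by
more than ±5 nt — slack for indel errors — or an insert with no catalog
hit at all: a putative un-catalogued spacer), then PASS. Irregular gaps
are extracted together with their bordering repeats so spacer discovery can
be re-run on them; re-discovered candidates whose best catalog match falls
just below the identity threshold (within 0.15) are degraded copies of
known spacers and are discarded rather than admitted as new.

Spacer discovery clusters inter-repeat segments (20–60 nt between
approximate repeat occurrences) greedily at 85 % identity and represents
each cluster by its most frequent member sequence — at the depths used
(≥ 50×) the error-free sequence is always the mode; ties break
lexicographically. Catalogs refuse spacer pairs closer than 6 edits, which
would be uncallable as distinct under the fuzzy threshold.

## Synthetic data generator

The generator emulates the statistical structure of a regional survey of an
uncultured host-associated bacterium typed at one CRISPR locus:

* **Arrays:** a random coalescent genealogy (msprime, haploid samples,
  branch lengths rescaled by `time_scale`, default 0.15 deletions per
  spacer per coalescent unit) with the OISL process run along branches from
  a 60-spacer ancestor (defaults; 123 tips mirroring the scale of a real
  survey). With ρ = 0 — the default, matching a locus whose diversity is
  deletion-generated — every tip is an ordered subsequence of the
  ancestral array, the nested-deletion architecture seen in such data. A
  lineage that loses its last spacer triggers a re-simulation (up to 10
  attempts) and then a hard error.
* **Populations:** nested design of 3 regions × 2 habitats × 2 sites × 3
  hosts (defaults), with per-host haplotype profiles built top-down: each
  stratum mixes a fresh Dirichlet(0.3) draw into its parent profile with
  the stratum's differentiation weight (defaults region 0.9, habitat 0.05,
  site 0.05, host 0.3 — strong regional and weak habitat structure).
  Regions can be restricted to disjoint haplotype pools for maximal
  regional differentiation, including a single-haplotype region as the
  degenerate case. Reads are multinomial draws of `depth` (default 200)
  per host/section/replicate.
* **Reads:** `primerF + repeat + (spacer + repeat)* + primerR` with i.i.d.
  per-base errors (default 0.5 % substitutions + 0.5 % indels, CCS-like),
  random strand, constant Q40 qualities, and configurable broken-read
  fractions: primer dropout (removes a primer and part of its flank) and
  truncation (insert shrunk below the usable minimum) to exercise the QC
  classes.

What the generator does *not* emulate: position- and homopolymer-dependent
error profiles, PCR chimeras, quality-score variation, host-genome
contamination, spacer duplication, and amplification bias across
haplotypes. Tests passing on these simulations therefore demonstrate the
correctness of the algorithms under the stated model, not robustness to
every artefact of real libraries.

All randomness flows from one mandatory seed; identical configurations are
byte-for-byte reproducible, and every CLI artifact records its parameters
and seed in `manifest.json`.

## Verification problem sizes

The test suite and `scripts/acceptance.py` verify, at these sizes:
likelihood optimizer vs an exhaustively refined 2-D grid (resolution 10⁻⁴,
agreement in t̂ to 10⁻³; 1 000 alignments in the suite, 400 in the
script); spacer-fate class probabilities by Monte Carlo (10⁵ trials);
divergence recovery (500 pairs, 200-spacer ancestor, truth t = 0.3, mean
within 3 SE); NJ reconstruction of additive 4–8 taxon matrices to 10⁻⁹ and
branch non-negativity on 1 000 random matrices; MST weight vs exhaustive
spanning-tree enumeration (n ≤ 7) and Mantel vs full permutation
enumeration (n ≤ 5); AMOVA components vs hand-solved algebra, Φ vs
pairwise F_ST, permutation-p uniformity under the null
(200 datasets, 99 permutations, KS at α = 0.01); caller round trips at
zero error (exact) and at 0.5 % + 0.5 % error, depth 200 (exact set,
frequencies within 5 points); and the structure experiment (50 replicates,
3 regions × 4 habitats × 2 hosts, 20 reads per host, 199 permutations —
four habitats per region so that whole-unit permutation can reach
p ≤ 0.01, see the granularity note above).

## Known limitations

* Divergence is pairwise only; no joint multi-taxon likelihood on the tree.
* ρ per pair is weakly identified when leader-unique counts are small; the
  deletion-only data the pipeline targets has ρ̂ = 0 throughout.
* Order-discordant array pairs (e.g. from recombination or independent
  acquisition) fail loudly instead of being modelled.
* The permutation scheme's p-value granularity depends on the number of
  sub-units below the tested level (see above).
* F_ST p-values are not corrected for multiple comparisons across
  population pairs; apply a correction downstream if many pairs are
  screened.
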