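# Models and methods

`mscintro` implements a desk-scale pipeline for species-tree and
introgression inference in small clades (the motivating system is the
*Heliconius* melpomene–silvaniform group): multilocus dataset
extraction from genotype calls, coalescent simulation, Bayesian
blockwise inference under the multispecies coalescent (MSC) with and
without pulse introgression (MSC-I), triplet isolation-with-migration
(IM) maximum likelihood, and marginal-likelihood model comparison.

## The models

**MSC.** Gene genealogies evolve within a rooted species tree.  Each
population (an edge of the tree, including the infinite root
population) has a mutation-scaled size θ = 4Nμ; within a population, k
lineages coalesce at total rate k(k−1)/θ (2/θ per pair).  All times
(τ, node ages) are expected substitutions per site; no internal
generation or year units are used.  Loci are completely linked within
and freely recombining between.

**MSC-I.** Introgression is a pulse: a *pair* of hybridization nodes,
one on each of two contemporaneous branches, sharing a single event
time.  Tracing a lineage backwards, at the hybridization node on its
branch it follows the donor branch (the segment *above* the partner
node) with probability φ and its own ancestral branch with probability
1−φ.  Both directions of a pair share the event time; this convention
is forced by the published parameter counts of the two reference
models (40 = 12φ + 13τ + 15θ for the eight-species six-pair model;
25 for the one-pair backbone model).  Under the `linked` theta model
the populations above and below a hybridization node share one θ, so
n_θ = #tips + #divergence nodes.

**MSC-M.** Continuous gene flow at rate M_ij = N_j·m_ij expected
migrants per generation (forward, i→j).  On the substitutions-per-site
time scale a lineage in population j jumps backwards to population i
at rate 4·M_ij/θ_j.  MSC-M is supported in the simulator and in the
three-species triplet likelihood; MSC-M MCMC with migration-history
augmentation for larger systems is out of scope.

**Mutation.** The equal-rates (JC69) model throughout:
P(no change over t) = 1/4 + (3/4)e^(−4t/3), uniform base frequencies.
Unphased diploid individuals are encoded as one sequence with IUPAC
ambiguity codes at heterozygous sites; the likelihood treats ambiguity
codes as partial likelihood 1 over the compatible bases.  This
approximates rather than replicates full diploid phase integration —
a deliberate simplification, adequate for the low heterozygosity
(≲1%) regime the pipeline targets.

## Priors

Root age τ₀ ~ Gamma(7, 200) (mean 0.035); given τ₀, non-root
divergence times are flat over the order-constrained polytope
("uniform-Dirichlet"), normalized in closed form as
m!/(τ₀^m · ∏ subtree sizes); θ ~ Gamma(4, 200) (mean 0.02);
φ ~ U(0, 1); migration rates M ~ Gamma(2, 10) (mean 0.2).  Each
introgression-pair time is uniform over its feasible interval given
the divergence times.

## The MCMC sampler

The state is (τ, θ, φ, per-locus gene trees).  The sequence likelihood
(pruning, compiled kernel) depends only on the gene trees; the
coalescent density couples gene trees to the species model and is
computed by sweeping each gene tree through the population structure,
yielding per-population sufficient statistics (coalescence counts,
waiting sums) and per-hybridization crossing counts.  Moves:

- sliding-window updates of each divergence/introgression time,
  reflected at the feasible bounds (pair times move jointly);
- multiplier updates of each θ using the cached sufficient statistics
  (O(1) per proposal);
- per-locus gene-tree node-age windows and subtree-prune-regraft moves
  whose attachment candidates are the branches existing at the proposed
  age (Hastings ratio = candidate-count ratio);
- hybrid-path indicator flips, and a joint *path-switch* move that
  flips one crossing indicator while re-grafting the lineage's parent
  at a proposed age above the pulse time (a bare flip is almost always
  infeasible because the lineage's existing coalescence sits in a
  population the other path never visits; keeping the proposed age
  above the event time preserves the crossing and hence
  reversibility);
- a *direction-swap* move that jointly flips the indicator of a
  crossing lineage and the partner-hybrid indicator of the lineage it
  first coalesces with, leaving the tree unchanged.  A lineage that
  introgressed and then coalesced with a partner is typically
  indistinguishable from that partner having introgressed the other
  way; without this move the chain cannot hop between the two
  explanations and direction attribution freezes near its
  initialization (Hastings ratio from the flip-set multiplicities);
- every 10th iteration, a whole-model scaling move multiplying all
  times and θ by a common factor (Jacobian included).

**Collapsed φ.** The introgression probabilities are integrated out of
the chain's target analytically: with U(0,1) priors, the product of
φ^d(1−φ)^a factors over loci marginalizes to the Beta function
B(D+1, A+1) of the *total* donor/ancestral crossing counts per
hybridization node, which enters every acceptance ratio that changes
those counts.  φ itself is drawn from its exact Beta(D+1, A+1)
conditional at each sampling step, purely so the recorded samples form
the φ posterior.  Collapsing removes a severe mutual-reinforcement
pathology (a sampled φ near the current crossing fraction suppresses
indicator transitions, which freezes φ); with φ fixed the sampler's
donor-crossing fraction matches φ exactly, and with φ collapsed the
posterior covers simulated truths at nominal rates.

**Persistent indicators.** A path indicator exists for *every*
(lineage, hybridization node) key whether or not the lineage currently
crosses that node; inactive indicators carry probability 1/2 each.
Marginalizing the inactive ones recovers the target posterior exactly,
the state dimension never changes, and age/SPR moves remain reversible
with a simple 2^(Δ active crossings) factor in the acceptance ratio.

**Topology search (≤ 5 taxa).** The chain state includes a *ranked
history* (a labelled topology plus the rank order of its internal
nodes); node ages and internal-node θs are indexed by rank and shared
across topologies.  Every 10th iteration the topology is redrawn by an
exact Gibbs step over all enumerated ranked histories (18 for 4 taxa,
180 for 5), conditional on the current gene trees; the weight of each
candidate is its gene-tree density product times the
topology-dependent normalizer of the flat age prior (1/∏ subtree
sizes).  Age updates are additionally constrained to preserve the rank
order, so the (topology, ages) point always corresponds to exactly one
ranked state.  This replaces reversible in-chain SPR on the species
tree; it is exact for the taxon counts used here and mixes well
because near-star gene trees let the chain traverse topologies.
Chains start from a UPGMA tree on mean pairwise distances and from
species-compatible gene trees; starting points do not affect the
target distribution.

**Blockwise inference.** Each block of loci is analysed by n
independent runs (the study protocol used 10; desk-scale default 2);
a run is discarded when the total-variation distance between its
topology posterior and the coordinate-wise median posterior exceeds
0.1 (inclusive boundary; the threshold is a repository choice — the
study states no numeric criterion); kept runs are merged with equal
weight into the block posterior and its MAP tree.

**Proposal tuning.** Step sizes adapt during burn-in toward 30%
acceptance and are frozen afterwards.

## Marginal likelihood and Bayes factors

Thermodynamic integration over power posteriors π_β ∝ prior ×
likelihood^β at Gauss–Legendre β points on (0,1) (default 32; the
coalescent gene-tree density belongs to the prior and is not
tempered).  Chains are warm-started from small to large β.  The log
Bayes factor is the difference of log marginal likelihoods; noisy
Bayes-factor series along a genome can be smoothed with local
quadratic polynomials (tricube weights, span 0.4 of the points).

## Triplet isolation-with-migration likelihood

For ((S1,S2),S3) with gene flow only between S1 and S2: model M0
(no flow; 6 parameters τ1, τ0, θ1, θ2, θ4, θ5 — no θ3 because at most
one S3 sequence per locus) and M2 (plus M12, M21; 8 parameters).
Per locus, three phased sequences in configuration 123, 113 or 223
(sampled with probabilities 0.5/0.25/0.25, renormalized over feasible
types).  Site patterns collapse under JC69 base symmetry to five
classes (xxx, xxy, xyx, yxx, xyz) with closed-form probabilities given
the two coalescent ages.  Before τ1 the two ingroup lineages follow a
three-state occupancy chain (both-in-1, split, both-in-2) with
backward migration rates 4M_ij/θ_j and coalescence as absorption,
solved by eigendecomposition (scaling-and-squaring fallback when the
eigenbasis is ill-conditioned).  Ages are integrated by Gauss–Legendre
quadrature: directly on the finite phases, and after the exponential
change of variables w = e^(−rate·(t−t₀)) on the unbounded root phase,
under which the genealogy density becomes exactly uniform.  The
resulting weighted "genealogy atoms" (two ages + first-coalescing
pair) are shared across configurations — only their weights differ —
so the per-locus log-likelihood is one loci×atoms matrix operation
(logsumexp of counts·log p + log w; the multinomial coefficient, a
constant, is dropped).

Fitting uses L-BFGS-B from dispersed random starts in (log τ0,
τ1/τ0, log θ, log M) with box bounds; restarts whose τ0/θ estimates
hit a bound (or M its upper bound) are flagged extreme and excluded
from the argmax — the τ1→τ0 boundary (star tree) and M→0 (no flow)
are legitimate estimates and are not flagged.  M2 can be warm-started
from the M0 optimum, the standard strategy for nested models.  M0 vs
M2 is compared by LRT against χ²(2) at the 1% level (the regularity
caveat at the M = 0 boundary makes this conservative).  Δτ = τ0 − τ1
below 1% of τ0 (configurable) raises the star-tree flag that
diagnoses a misassigned branching order.

## Synthetic data generator

`sim_block_dataset` emulates the study's data shape: blocks of 100–200
short loci (default lengths drawn uniformly on a configurable range,
100–1000 bp), 1–4 haploid sequences or unphased diploid individuals
per species, parameter magnitudes in the estimated ranges (τ ~
0.002–0.035, θ ~ 0.002–0.02 — defaults, not published values).  Each
locus draws its own generator from (master seed, locus index), so
datasets are bit-identical regardless of generation order.  The truth
record (network, parameters, per-locus gene trees) supports recovery
tests.  The generator does *not* emulate alignment error, indel
structure, base-composition bias, selection, within-locus
recombination or rate variation; passing tests demonstrate correctness
of the inference machinery under its assumed model, not robustness to
real-data violations of it.

## Dataset extraction

Two genotyping pipelines mirror the study.  *Per-individual*: all-sites
VCF; site QUAL ≥ 20; genotype GQ ≥ 20 and max(meanDP/2, d) ≤ DP ≤
2·meanDP with d ∈ {12, 20} (halved on the Z chromosome in females,
the heterogametic sex); sites within 5 bp of indels masked; loci with
>50% missing data (computed before column removal — the protocol is
ambiguous on the order; this reading is flagged for sensitivity
checks) or ≤10 surviving sites discarded; every column containing
missing data removed.  *Joint*: constant sites from the reference
unless masked by depth < 20 ('-') or non-SNP/low-quality variation
('N'); SNPs kept only with QD ≥ 2 and MQ ≥ 40; sequences >50% missing
dropped; all-missing columns dropped; loci with fewer than two
sequences rejected.  meanDP is the sample-averaged depth.  Loci: a
coding locus coincides with a CDS (≥100 bp); noncoding loci are carved
from the complement of CDS and repeats (100–1000 bp); loci within a
class are ≥2 kb apart, selected greedily left-to-right (deterministic),
except in designated relaxed regions (e.g. an inversion interior)
where only non-overlap is enforced.  Coordinates are 0-based half-open
internally; GFF3 and VCF are converted on read; all loci are reported
on the forward strand.

## Numerical choices and sizes

- Pruning uses per-node rescaling; all densities are computed in log
  space.  The compiled kernels are mirrored by pure-Python reference
  implementations and tested equal to 1e-10.
- Gauss–Legendre order: 16 per time dimension by default in the
  triplet likelihood (8 in the large null-calibration study; 32 in
  oracle comparisons).  Quadrature order changes the fitted optimum by
  far less than Monte-Carlo spread (checked 16 vs 32).
- Tie-breaking: MAP trees by canonical rooted Newick (sorted child
  subtrees), lexicographic on ties; coalescences at exactly a species
  event time are processed before the event (measure-zero under the
  continuous model).
- Desk-scale study sizes used by the test suite: blocks of 30–100 loci
  of 100–500 sites, chains of 400–3000 iterations (200k for no-data
  prior recovery), 20-replicate coverage/recovery studies, 200-dataset
  LRT null calibration at 250 loci × 100 sites.  The original analyses
  used 200-locus blocks and 10 runs of 1–2 × 10⁶ iterations.

## Known limitations

- Topology search is exhaustive-enumeration based and limited to 5
  taxa; larger searches would need reversible species-tree moves.
- The MSC-I density requires explicit path indicators; the number of
  enumerable paths grows with stacked hybridization nodes, which is
  fine for the pulse counts used here.
- Introgression *direction* can be exactly unidentifiable per locus:
  when a pulse connects an internal stem and a contemporaneous branch
  whose upper population windows coincide, the forward-donor and
  reverse-donor explanations of a young cross-clade coalescence have
  identical densities, and only the joint posterior over both phi
  values is informed.  Direction estimates are meaningful when the
  two crossing windows differ (as for the tip-branch pulses of the
  bundled models).
- The triplet likelihood assumes at most one sequence from S3 and
  exactly the 3-sequence configurations of the sampling scheme.
- IUPAC-coded diploid sequences are approximated as single ambiguous
  sequences (no phase integration); with ~0.5% heterozygosity the
  effect on τ/θ estimates is small but not zero.
- The joint-mode depth mask needs per-site DP records; with a
  variants-only VCF, constant sites cannot be depth-masked.
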