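# mscintro

Species-tree and introgression inference under the multispecies
coalescent (MSC), at desk scale, for small clades with pervasive gene
flow — the motivating system is the *Heliconius* melpomene–silvaniform
group, where different genomic regions support different species trees
and the task is to separate incomplete lineage sorting from
introgression.

The package covers the full analysis path:

- **`mscintro.loci`** — multilocus dataset extraction from genotype
  calls: plan short, well-spaced coding/noncoding loci from annotation,
  filter genotypes (QUAL/GQ ≥ 20, depth window max(meanDP/2, d) ≤ DP ≤
  2·meanDP, 5-bp indel masks), and build IUPAC-coded unphased-diploid
  alignments under either of two genotyping pipelines.
- **`mscintro.network`** — species trees plus *pulse* introgression
  (MSC-I): pairs of hybridization nodes sharing one event time, with a
  directed introgression probability φ each way; extended-Newick
  read/write; free-parameter counting under the linked-theta
  convention.
- **`mscintro.simulate`** — coalescent simulation of gene trees under
  MSC / MSC-I / MSC-M (continuous migration) and JC69 alignments, with
  blockwise datasets and truth records for recovery tests.
- **`mscintro.likelihood` / `mscintro.mcmc`** — pruning likelihoods,
  coalescent gene-tree densities, priors, and a Metropolis–Hastings
  sampler for blockwise species-tree posteriors (exhaustive
  ranked-history jumps for ≤ 5 taxa) and fixed-network MSC-I parameter
  estimation (τ, θ, φ); marginal likelihoods by thermodynamic
  integration and loess-smoothed Bayes factors.
- **`mscintro.triplet`** — maximum-likelihood isolation-with-migration
  for triplets ((S1,S2),S3): M0 (no flow, 6 parameters) vs M2
  (bidirectional flow, 8 parameters), likelihood-ratio test at the 1%
  level against χ²(2), and the Δτ = τ0 − τ1 star-tree diagnostic.
- **`mscintro.summaries` / CLI** — MAP-tree tabulation with clade
  lumping, absolute-time calibration, coding/noncoding divergence
  slope, heterozygosity.

All times are in expected substitutions per site (τ); population sizes
are θ = 4Nμ; the mutation model is JC69 throughout.  See
`docs/methods.md` for the models, priors, sampler moves and numerical
choices.

## Worked example

Simulate one 100-locus block under a 4-species tree, infer the
blockwise species-tree posterior, and date the root:

```python
import numpy as np
from mscintro import (
    ParamSet, tree_from_newick, sim_block_dataset,
    infer_block_species_tree, ChainSettings, calibrate_age_ma,
)
from mscintro.likelihood import PriorSpec

net = tree_from_newick("(((A,B)n1,C)n2,D)r;")
params = ParamSet(
    tau={"n1": 0.01, "n2": 0.03, "r": 0.05},
    theta={k: 0.01 for k in ["A", "B", "C", "D", "n1", "n2", "r"]},
)
alns, trees, index = sim_block_dataset(
    net, params, n_blocks=1, loci_per_block=100, sites_per_locus=500,
    samples={s: 1 for s in "ABCD"}, rng_seed=11,
)
post = infer_block_species_tree(
    alns, PriorSpec(),
    ChainSettings(n_iterations=600, burn_in=200, sample_every=2,
                  n_runs=2, seed=5),
)
print(post.map_tree, round(post.map_prob, 3))
print(round(calibrate_age_ma(0.020, 2.9e-9, 4), 1), "Ma")
```

prints

```
(((A,B),C),D); 1.0
1.7 Ma
```

— the MAP tree recovers the generating topology with posterior
probability 1.0 under this strong-signal simulation, and a root age of
τ = 0.020 substitutions/site translates to 1.7 Ma under a neutral
mutation rate of 2.9 × 10⁻⁹ per site per generation and four
generations per year.

The same steps are available from the shell:

```bash
mscintro simulate --config sim.yaml --seed 11 --out data/
mscintro infer-blocks --loci-dir data/ --out blocks.tsv
mscintro triplet-im --loci-dir data/ --s1 A --s2 B --outgroup D --out trip.tsv
mscintro summarize --blocks blocks.tsv --out summary.tsv
```

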