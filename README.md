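# grndup

Simulation toolkit for studying the **early phenotypic effects of gene
duplication in gene regulatory networks (GRNs)**. It is aimed at
researchers in evolutionary systems biology who want to ask, within a
well-controlled discrete dynamical model: which networks tolerate the
duplication of a regulator gene without changing their expression
phenotype, how duplication reshapes a network's robustness to further
mutations, and which alternative phenotypes stay reachable by mutation
after the duplication.

## Model

A network has `N_r` transcription-factor genes and `N_s` structural
genes whose activity defines the phenotype. Interactions live in a real
matrix **M** (`N_r + N_s` rows × `N_r` columns, structural genes never
regulate). Activity states `s_i ∈ {+1, −1}` update synchronously:

```
s_i(t+1) = σ( Σ_{j=1..N_r} m_ij · s_j(t) )
```

with `σ(x) = 1` for `x > 0`, `−1` for `x < 0`, and *hold the previous
state* at `x = 0`. Every trajectory from the predefined initial
condition `s⁰` settles into an attractor (fixed point or κ-cycle); the
**phenotype** is the repeating sequence of structural-gene patterns in
the attractor, compared up to cyclic rotation. Robustness to a
perturbation class K is the fraction of class-K perturbations that leave
the phenotype unchanged (`R_μ` single-interaction mutations, `R_D`
single-gene duplications, `R_a` additions of an unrelated regulator);
`S_K` is the mean Hamming-based similarity of the perturbed phenotypes
to the original.

Networks producing one shared phenotype *A* are sampled uniformly by a
Metropolis-style Monte Carlo walk on the neutral set (accept a random
mutation only if the phenotype stays *A* and the interaction count stays
in `[C−2, C+2]`; record a network every `20(N_r+N_s)N_r` steps). The
defaults — `N_r = 12`, `N_s = 6`, `C = 54` — follow connectivities
observed in developmental GRNs.

## Worked example

```python
import numpy as np
from grndup import (ModelConfig, make_founder, mc_walk_sample,
                    assay_mutational, assay_duplication, assay_addition)

cfg = ModelConfig()                      # 12 regulators, 6 structural genes, C=54
rng = np.random.default_rng(7)
founder, a = make_founder(cfg, rng)      # phenotype A: a stable expression pattern
print("phenotype A:", a.pattern)

sample = mc_walk_sample(founder, a, 20, cfg, rng)   # 20 networks, 4320 steps apart
g = sample.networks[0]
mu  = assay_mutational(g, a, rng)        # 432 independent single mutants
dup = assay_duplication(g, a)            # all 12 single-gene duplications
add = assay_addition(g, a, rng)          # 12 random unrelated-gene additions
print(f"R_mu={mu.robustness:.3f}  S_mu={mu.mean_similarity:.3f}")
print(f"R_D ={dup.robustness:.3f}  S_D ={dup.mean_similarity:.3f}")
print(f"R_a ={add.robustness:.3f}  S_a ={add.mean_similarity:.3f}")
```

prints

```
phenotype A: ((1, 1, 1, 1, -1, 1),)
R_mu=0.799  S_mu=0.942
R_D =0.667  S_D =0.917
R_a =0.333  S_a =0.790
```

Read: this particular network keeps phenotype *A* under 80% of random
single-interaction mutations, under 8 of its 12 possible gene
duplications, but under only a third of unrelated-gene insertions — and
even the perturbations that do change the phenotype leave most
structural genes in their original state (similarities well above the
0.5 chance level). Ensemble means over a uniform sample sharpen these
into the study's headline numbers: `R_μ ≈ 0.81`, `S_μ ≈ 0.94`,
`R_D ≈ 0.60`, `R_a ≈ 0.43`, with duplication-resistant networks (~59%)
gaining further mutational robustness after duplication.

The full study — paired pre/post gene-gain comparisons, accessible
phenotype profiling with recurrent/lost/newcomer classification,
stratified deletion/addition assays with a type-II two-way ANOVA, and a
statistics table — runs through `grndup.pipeline.run_study`, or from the
shell:

```
grn-dup sample --n 1000 --seed 1 --out samples/
grn-dup run --config study.yaml
```

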