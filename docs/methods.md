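# Methods

## Model

A gene regulatory network (GRN) holds `n_reg` transcription-factor
(regulator) genes and `n_struct` structural genes. Regulatory
interactions live in a real matrix **M** with `n_reg + n_struct` rows and
`n_reg` columns; entry `m[i, j]` is the effect of regulator `j` on gene
`i` (structural genes regulate nothing, so they contribute rows but no
columns). Gene activity is a ±1 vector updated synchronously:

    s_i(t+1) = sign( Σ_j m[i, j] · s_j(t) ),

where a gene whose summed input is exactly zero keeps its previous
state. The zero branch is compared to `0.0` exactly: with continuous
weights an exact zero essentially only arises from empty regulation
(e.g. after deleting a gene's last incoming interaction), which is
precisely the case the hold rule is meant for.

The state space is finite, so every trajectory from the network's
predefined initial condition `s⁰` enters an attractor — a fixed point or
a limit cycle of period κ — after a transient of τ steps. The
*phenotype* is the repeating sequence of structural-gene patterns along
the attractor, reduced to its minimal period and rotated to the
lexicographically smallest cyclic rotation. Rotation invariance is
deliberate: the phase at which a trajectory enters its cycle depends on
the transient, and cross-network phenotype identity (needed to count
distinct phenotypes) must not depend on phase.

Default dimensions are `n_reg = 12`, `n_struct = 6`, and
`C = (n_reg + n_struct) · n_reg / 4 = 54` interactions, a connectivity
comparable to empirically characterized developmental GRNs. The
attractor search is capped at 100 000 updates — a pure safety net, as
observed trajectories at this size are a few dozen steps at most.

## Phenotype similarity

Similarity between phenotypes is 1 minus the normalized Hamming distance
over structural genes. For two fixed points that is the fraction of
structural genes in the same state; for a fixed point versus a cycle,
the fixed point is compared with every cycle row and the distances
averaged. The case of two limit cycles is not fixed by the definitions
above; we unroll both patterns to the least common multiple of their
periods and use the cyclic offset of one pattern that maximizes the mean
positionwise similarity. This rule reduces exactly to the
fixed-point-versus-cycle average when either period is 1, is symmetric,
and guarantees S(p, p) = 1 (an all-pairs row average would not). It is
an extension, and measurably rare: most sampled phenotypes and their
mutant derivatives involve at least one fixed point.

## Perturbation operators

*Mutation* picks one matrix entry uniformly at random. A zero entry
gains an interaction with a standard-normal weight (redrawn in the
measure-zero event of 0.0); a nonzero entry is deleted or has its weight
redrawn — sign preserved — with equal probability. A robustness assay
uses `2 (n_reg + n_struct) n_reg` independent single mutants (432 at
default size), each applied to a fresh copy of the network. After a gene
gain the formula is evaluated at the enlarged dimensions (494).

*Duplication* of regulator `i` inserts a copy of column `i` and row `i`
at position `n_reg + 1` (between regulators and structural genes, so
structural genes always occupy the last rows); the new diagonal entry
copies `m[i, i]`, and the duplicate starts with the same activity as its
template. Because the copies receive identical inputs and start equal,
they remain identical forever; the duplicated network restricted to the
original genes behaves exactly like the original with column `i`
doubled. That equivalence is the module's main test oracle.

*Addition* attaches a regulator unrelated to existing genes with `k`
random interactions, each independently incoming or outgoing with
probability 1/2, endpoints uniform (self-loops allowed), standard-normal
weights, occupied positions redrawn. By default `k` is the average
total degree — incoming plus outgoing interactions — of the network's
regulator genes, rounded with halves up (8 at default size, where
regulators average 7.5 interactions). This makes the newcomer
comparable to a typical duplicated gene, so the duplication and
addition controls probe the same connectivity scale; an alternative
mode passes `k` explicitly to match one designated gene's degree, and
the two behave very similarly. The newcomer's initial activity is drawn
uniformly from {+1, −1} (nothing in the model constrains it).

## Uniform sampling of the neutral set

Networks producing a given phenotype *A* from a shared `s⁰` form a huge
set connected under single-interaction mutations. A Metropolis-style
walk samples it: each step proposes one random mutation and accepts it
only if the mutant still produces *A* and keeps its interaction count in
`[C − 2, C + 2]`; otherwise the walk stays put. The proposal is
symmetric and the acceptance an indicator, so the stationary
distribution is uniform over the reachable neutral set. Every proposal
— accepted or rejected — counts as one mutational step, and a network
is recorded every `20 (n_reg + n_struct) n_reg` steps (4320 at default
size); sign-agreement between consecutive samples is indistinguishable
from agreement between distant ones. No burn-in beyond the first
recording interval is applied. The connectivity check runs before the
(much more expensive) phenotype check; the order cannot change the
accepted chain. Exact uniformity cannot be verified over continuous
weights, so a surrogate test runs the same walk on a tiny instance with
weights restricted to {+1, −1}, where the neutral set is enumerable, and
checks the sampling distribution over the founder's connected component
with a chi-squared test at α = 0.01.

The founder is a random genotype with exactly `C` standard-normal
interactions and a random ±1 initial condition, redrawn until its
dynamics settle into a fixed point; *A* is the stable structural pattern
it produces. Designing *A* to be stable matters: ensemble robustness
depends strongly on the target's period (walk samples for a period-6
target average R_μ ≈ 0.55, versus ≈ 0.80 for a stable target), and a
stable expression pattern is the canonical phenotype notion for this
model family. Networks *on* the walk may still realize *A* through
cycling regulators, since only the structural pattern is constrained.
`s⁰` is drawn once per study and shared by the entire ensemble.

## What the generator emulates — and what it does not

The sampler is the study's data generator: it emulates an unbiased draw
from the set of regulatory circuits that develop one fixed expression
pattern, the backdrop against which duplication is assessed. It does not
emulate real regulatory networks' degree heterogeneity, signed-motif
enrichment, or multicellular dynamics (one initial condition, one
phenotype per network), and no selection acts during sampling. Passing
tests therefore show that the *model's* ensemble statistics are
reproduced, not that any particular biological network behaves this way.

## Assays and statistics

Per network: R_K is the fraction of class-K perturbations (μ mutation,
D duplication, a addition) that leave the phenotype equal to the
reference, and S_K the mean similarity of perturbed phenotypes to it
(preserving perturbations contribute similarity 1, hence S_K ≥ R_K).
Mutation assays draw the formula count of independent mutants;
duplication is exhaustive over the `n_reg` regulators; addition draws
`n_reg` independent newcomers. Access profiles collect the distinct
non-reference phenotypes among the same number of independent mutants,
with per-phenotype mutation counts; profiles before and after a gene
gain split phenotypes into recurrent / lost / newcomer classes.

Statistics follow conventional implementations: Spearman with mid-ranks,
Wilcoxon signed-rank dropping zero differences, two-sided Mann-Whitney U,
and a type-II two-way ANOVA (statsmodels) of per-mutant similarity on
regulator class × target class, with the classical η² = SS_term /
SS_total (not partial η²) as effect size; η² is defined as 0 when the
response is constant. The three structural-trait comparisons of the
duplicated gene (shortest path to a structural gene, in-degree,
out-degree, all measured on the pre-duplication genotype where they are
unambiguous) are Bonferroni-corrected with m = 3. Stratified-assay
similarities are recorded per mutant, not per network, which is what the
two-way design requires. α = 0.01 throughout.

## Problem sizes and determinism

The full study pipeline (`run_study`) chains founder → walk → paired
ensembles → assays → statistics. All randomness derives from one master
seed through spawned generator streams; reruns are byte-identical. The
bundled acceptance script samples 250 networks (the headline numbers in
the source study used 1000) and caps the stratified deletion/addition
assay at 50 duplicate-carrying networks; at these sizes a run takes
roughly seven minutes on one core. Ensemble means are tight at this
scale (standard errors ≈ 0.002 on R_μ, ≈ 1.6 percentage points on the
resistant fractions); founder-to-founder variation adds a comparable
spread, since each study conditions on one target phenotype.

## Known limitations

- The count of distinct mutation-accessible phenotypes runs ~25% above
  the source study's reported mean (≈ 23–26 vs 18.33), and the recurrent
  share among duplication-resistant networks correspondingly lower
  (≈ 51–56% vs 61.7%), consistently across founders and connectivity
  choices. The access-profile *structure* matches (post-duplication
  counts drop in resistant networks; recurrent phenotypes have roughly
  twice the pre-gain mutational access of lost ones), and every
  robustness, similarity and correlation statistic reproduces; the
  level difference traces to how rare, often long-period, mutant
  phenotypes are individuated, which the published description does not
  pin down further. Alternative identity notions (row-set, row-multiset)
  and alternative post-gain mutation counts were tested and change the
  counts by ≤ 10%.
- Cycle-versus-cycle similarity is a documented extension (see above).
- Dynamics are deterministic and synchronous; no noise, no sigmoidal
  response, no multiple initial conditions, no evolutionary dynamics.
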