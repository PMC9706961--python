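"""Per-network measurements of robustness, similarity and phenotypic
access.

Robustness to a perturbation class K (single-interaction mutation,
single-gene duplication, or unrelated-gene addition) is the fraction of
class-K perturbations that leave the phenotype unchanged; similarity
after K is the mean Hamming-based similarity between the reference
phenotype and the perturbed phenotypes.  The access profile records
which distinct non-reference phenotypes single mutations can uncover and
with how many distinct mutations each is reached; comparing profiles
before and after a gene gain classifies phenotypes as recurrent, lost or
newcomer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np

from .core import (
    GRNGenotype,
    Phenotype,
    pattern_from_matrix,
    phenotype_similarity,
)
from .perturb import (
    MutationRecord,
    add_random_gene,
    apply_mutation,
    draw_mutation,
    default_mutant_count,
    duplicate_gene,
    revert_mutation,
)

__all__ = [
    "PerturbationSummary",
    "AccessProfile",
    "AccessClassification",
    "StratifiedSimilarityRecord",
    "DuplicateStructuralProps",
    "assay_mutational",
    "assay_duplication",
    "assay_addition",
    "access_profile",
    "classify_access",
    "duplicate_structural_props",
    "stratified_mutation_assay",
]


@dataclass
class PerturbationSummary:
    """Robustness R_K and mean similarity S_K for one network under one
    perturbation class."""

    perturbation_class: str  # "mutation" | "duplication" | "addition"
    robustness: float
    mean_similarity: float
    n_perturbations: int
    records: list[MutationRecord] | None = None


@dataclass
class AccessProfile:
    """Distinct non-reference phenotypes reachable by single mutations,
    with the number of distinct mutations producing each."""

    reference: Phenotype
    phenotype_counts: dict[Phenotype, int]
    n_mutations_tried: int
    n_preserving: int

    @property
    def n_accessible(self) -> int:
        return len(self.phenotype_counts)


@dataclass
class AccessClassification:
    """Set comparison of accessible phenotypes before vs. after a gene
    gain.  ``before_counts`` keeps the pre-gain mutation count of every
    recurrent and lost phenotype (newcomers have none by definition)."""

    recurrent: frozenset[Phenotype]
    lost: frozenset[Phenotype]
    newcomer: frozenset[Phenotype]
    before_counts: dict[Phenotype, int] = field(default_factory=dict)


@dataclass(frozen=True)
class StratifiedSimilarityRecord:
    """One deletion or addition mutant of a duplicate-carrying network,
    labeled by the classes of the genes flanking the mutated interaction."""

    mutation_kind: str  # "delete" | "add"
    regulator_class: str  # "duplicate" | "non-duplicate"
    target_class: str  # "duplicate" | "non-duplicate" | "structural"
    similarity: float


class DuplicateStructuralProps(NamedTuple):
    path_length: float  # math.inf when no structural gene is reachable
    in_degree: int
    out_degree: int


def _similarity_to(ref: Phenotype, pattern: tuple) -> float:
    if pattern == ref.pattern:
        return 1.0
    return phenotype_similarity(ref, Phenotype(pattern=pattern))


def assay_mutational(
    g: GRNGenotype,
    ref: Phenotype,
    rng: np.random.Generator,
    n: int | None = None,
) -> PerturbationSummary:
    """R_mu and S_mu from ``n`` independent single mutants (default
    2 (n_reg+n_struct) n_reg), each applied to a fresh copy of ``g``.

    The drawn mutation records are kept on the summary so an independent
    pass can replay them and reproduce the numbers exactly.
    """
    if n is None:
        n = default_mutant_count(g)
    scratch = g.matrix.copy()
    nr, ns, s0 = g.n_reg, g.n_struct, g.initial_state
    robust = 0
    sims = np.empty(n)
    records = []
    for m in range(n):
        rec = draw_mutation(scratch, rng)
        apply_mutation(scratch, rec)
        pattern = pattern_from_matrix(scratch, nr, ns, s0)
        revert_mutation(scratch, rec)
        records.append(rec)
        if pattern == ref.pattern:
            robust += 1
            sims[m] = 1.0
        else:
            sims[m] = _similarity_to(ref, pattern)
    return PerturbationSummary(
        perturbation_class="mutation",
        robustness=robust / n,
        mean_similarity=float(sims.mean()),
        n_perturbations=n,
        records=records,
    )


def assay_duplication(g: GRNGenotype, ref: Phenotype) -> PerturbationSummary:
    """R_D and S_D from the n_reg exhaustive single-gene duplications of
    ``g``, one regulator at a time.  Deterministic."""
    nr = g.n_reg
    robust = 0
    sims = np.empty(nr)
    for i in range(nr):
        d = duplicate_gene(g, i)
        pattern = pattern_from_matrix(d.matrix, d.n_reg, d.n_struct, d.initial_state)
        if pattern == ref.pattern:
            robust += 1
            sims[i] = 1.0
        else:
            sims[i] = _similarity_to(ref, pattern)
    return PerturbationSummary(
        perturbation_class="duplication",
        robustness=robust / nr,
        mean_similarity=float(sims.mean()),
        n_perturbations=nr,
    )


def assay_addition(
    g: GRNGenotype, ref: Phenotype, rng: np.random.Generator
) -> PerturbationSummary:
    """R_a and S_a from n_reg independent additions of a random unrelated
    regulator gene (network-average interaction count), each from ``g``."""
    nr = g.n_reg
    robust = 0
    sims = np.empty(nr)
    for i in range(nr):
        d = add_random_gene(g, rng)
        pattern = pattern_from_matrix(d.matrix, d.n_reg, d.n_struct, d.initial_state)
        if pattern == ref.pattern:
            robust += 1
            sims[i] = 1.0
        else:
            sims[i] = _similarity_to(ref, pattern)
    return PerturbationSummary(
        perturbation_class="addition",
        robustness=robust / nr,
        mean_similarity=float(sims.mean()),
        n_perturbations=nr,
    )


def access_profile(
    g: GRNGenotype,
    ref: Phenotype,
    rng: np.random.Generator,
    n: int | None = None,
) -> AccessProfile:
    """Profile the distinct non-reference phenotypes that ``n``
    independent single mutations (default 2 n_reg (n_reg+n_struct))
    uncover, with per-phenotype mutation counts."""
    if n is None:
        n = default_mutant_count(g)
    scratch = g.matrix.copy()
    nr, ns, s0 = g.n_reg, g.n_struct, g.initial_state
    counts: dict[Phenotype, int] = {}
    preserving = 0
    for _ in range(n):
        rec = draw_mutation(scratch, rng)
        apply_mutation(scratch, rec)
        pattern = pattern_from_matrix(scratch, nr, ns, s0)
        revert_mutation(scratch, rec)
        if pattern == ref.pattern:
            preserving += 1
        else:
            p = Phenotype(pattern=pattern)
            counts[p] = counts.get(p, 0) + 1
    return AccessProfile(
        reference=ref,
        phenotype_counts=counts,
        n_mutations_tried=n,
        n_preserving=preserving,
    )


def classify_access(
    before: AccessProfile, after: AccessProfile
) -> AccessClassification:
    """Split accessible phenotypes into recurrent (before and after a gene
    gain), lost (before only) and newcomer (after only)."""
    if before.reference.pattern != after.reference.pattern:
        raise ValueError("profiles have different reference phenotypes")
    b, a = set(before.phenotype_counts), set(after.phenotype_counts)
    recurrent, lost, newcomer = b & a, b - a, a - b
    return AccessClassification(
        recurrent=frozenset(recurrent),
        lost=frozenset(lost),
        newcomer=frozenset(newcomer),
        before_counts={p: before.phenotype_counts[p] for p in recurrent | lost},
    )


def duplicate_structural_props(g: GRNGenotype, i: int) -> DuplicateStructuralProps:
    """Structural traits of regulator ``i`` on the pre-duplication network:
    incoming interaction count (nonzeros in row i), outgoing count
    (nonzeros in column i over all genes), and the directed shortest-path
    length from ``i`` to the nearest structural gene (``inf`` if none is
    reachable)."""
    if not (0 <= i < g.n_reg):
        raise ValueError(f"gene {i} is not a regulator")
    in_degree = int(np.count_nonzero(g.matrix[i, :]))
    out_degree = int(np.count_nonzero(g.matrix[:, i]))
    graph = nx.DiGraph()
    graph.add_nodes_from(range(g.n_genes))
    targets, regulators = np.nonzero(g.matrix)
    graph.add_edges_from(zip(regulators, targets))
    lengths = nx.single_source_shortest_path_length(graph, i)
    path = min(
        (lengths[t] for t in range(g.n_reg, g.n_genes) if t in lengths),
        default=math.inf,
    )
    if path == 0:  # i itself can never be structural; defensive
        path = math.inf
    return DuplicateStructuralProps(float(path), in_degree, out_degree)


def stratified_mutation_assay(
    g: GRNGenotype,
    ref: Phenotype,
    rng: np.random.Generator,
    n_add_per_slot: int = 10,
) -> list[StratifiedSimilarityRecord]:
    """Deletion and addition mutants of a duplicate-carrying network,
    stratified by the classes of the mutated interaction's endpoints.

    Deletes every existing interaction one at a time, and tries
    ``n_add_per_slot`` positive plus ``n_add_per_slot`` negative
    standard-normal weights for every missing interaction, one at a time.
    Each record carries the mutant's phenotype similarity to ``ref`` and
    the regulator/target class labels (a gene is "duplicate" when it is
    either member of the labeled pair).
    """
    if g.duplicate_pair is None:
        raise ValueError("genotype carries no labeled duplicate pair")
    pair = set(g.duplicate_pair)

    def reg_class(j: int) -> str:
        return "duplicate" if j in pair else "non-duplicate"

    def tgt_class(i: int) -> str:
        if i in pair:
            return "duplicate"
        return "non-duplicate" if i < g.n_reg else "structural"

    scratch = g.matrix.copy()
    nr, ns, s0 = g.n_reg, g.n_struct, g.initial_state
    records = []

    def try_weight(i: int, j: int, kind: str, w: float) -> None:
        old = scratch[i, j]
        scratch[i, j] = w
        pattern = pattern_from_matrix(scratch, nr, ns, s0)
        scratch[i, j] = old
        records.append(
            StratifiedSimilarityRecord(
                mutation_kind=kind,
                regulator_class=reg_class(j),
                target_class=tgt_class(i),
                similarity=_similarity_to(ref, pattern),
            )
        )

    n_rows, n_cols = scratch.shape
    for i in range(n_rows):
        for j in range(n_cols):
            if scratch[i, j] != 0.0:
                try_weight(i, j, "delete", 0.0)
            else:
                for sign in (1.0, -1.0):
                    for _ in range(n_add_per_slot):
                        w = 0.0
                        while w == 0.0:
                            w = rng.standard_normal()
                        try_weight(i, j, "add", sign * abs(w))
    return records
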