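"""Perturbation operators: interaction mutation, gene duplication, and
addition of an unrelated regulator gene.

All operators are non-destructive: they return a new genotype and leave
the input untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import GRNGenotype

__all__ = [
    "MutationRecord",
    "mutate_random",
    "enumerate_single_mutants",
    "duplicate_gene",
    "add_random_gene",
    "default_mutant_count",
    "write_mutation_records",
]


@dataclass(frozen=True)
class MutationRecord:
    """One single-interaction mutation: addition of a missing interaction,
    deletion of an existing one, or modification of its weight (sign
    preserved)."""

    kind: str  # "add" | "delete" | "modify"
    target_index: int
    regulator_index: int
    old_weight: float
    new_weight: float


def _std_normal_nonzero(rng: np.random.Generator) -> float:
    """Standard-normal draw, redrawn in the (measure-zero) event of 0.0 —
    an added or modified interaction must be nonzero."""
    while True:
        w = rng.standard_normal()
        if w != 0.0:
            return float(w)


def draw_mutation(matrix: np.ndarray, rng: np.random.Generator) -> MutationRecord:
    """Draw a random mutation of ``matrix`` without applying it.

    A matrix entry is picked uniformly over all rows x columns.  A zero
    entry is turned into a new interaction with a standard-normal weight;
    a nonzero entry is deleted or modified with equal probability, and
    modification redraws the weight from the standard normal with the
    original sign forced.
    """
    n_rows, n_cols = matrix.shape
    flat = int(rng.integers(n_rows * n_cols))
    i, j = flat // n_cols, flat % n_cols
    old = float(matrix[i, j])
    if old == 0.0:
        return MutationRecord("add", i, j, 0.0, _std_normal_nonzero(rng))
    if rng.random() < 0.5:
        return MutationRecord("delete", i, j, old, 0.0)
    new = abs(_std_normal_nonzero(rng)) * (1.0 if old > 0 else -1.0)
    return MutationRecord("modify", i, j, old, new)


def apply_mutation(matrix: np.ndarray, rec: MutationRecord) -> None:
    """Apply ``rec`` to ``matrix`` in place."""
    matrix[rec.target_index, rec.regulator_index] = rec.new_weight


def revert_mutation(matrix: np.ndarray, rec: MutationRecord) -> None:
    """Undo ``rec`` on ``matrix`` in place."""
    matrix[rec.target_index, rec.regulator_index] = rec.old_weight


def mutate_random(
    g: GRNGenotype, rng: np.random.Generator
) -> tuple[GRNGenotype, MutationRecord]:
    """Return a copy of ``g`` carrying one random single-interaction
    mutation, together with the record of what changed."""
    rec = draw_mutation(g.matrix, rng)
    g2 = g.copy()
    apply_mutation(g2.matrix, rec)
    return g2, rec


def default_mutant_count(g: GRNGenotype) -> int:
    """Number of independent single mutants assayed per network:
    2 (n_reg + n_struct) n_reg, evaluated at the genotype's current
    dimensions (432 for the default 12+6 networks)."""
    return 2 * g.n_genes * g.n_reg


def enumerate_single_mutants(
    g: GRNGenotype, n: int | None = None, rng: np.random.Generator | None = None
) -> list[tuple[GRNGenotype, MutationRecord]]:
    """``n`` independent single mutants of ``g`` (non-cumulative: each
    starts from ``g``).  Defaults to ``default_mutant_count(g)``."""
    if rng is None:
        raise ValueError("an rng is required")
    if n is None:
        n = default_mutant_count(g)
    if n < 1:
        raise ValueError("n must be >= 1")
    return [mutate_random(g, rng) for _ in range(n)]


def duplicate_gene(g: GRNGenotype, i: int) -> GRNGenotype:
    """Duplicate regulator gene ``i``.

    The matrix grows by one column and one row, inserted at position
    ``n_reg`` (after the regulators, before the structural rows) and
    identical to column/row ``i``; the new diagonal entry copies
    ``m[i, i]``.  The duplicate starts with the same activity state as the
    original gene.  Both pair members are recorded in ``duplicate_pair``.
    """
    if not (0 <= i < g.n_reg):
        raise ValueError(f"gene {i} is not a regulator (n_reg={g.n_reg})")
    nr = g.n_reg
    m1 = np.insert(g.matrix, nr, g.matrix[:, i], axis=1)
    m2 = np.insert(m1, nr, m1[i, :], axis=0)  # m2[nr, nr] = m[i, i]
    s0 = np.insert(g.initial_state, nr, g.initial_state[i])
    return GRNGenotype(
        matrix=m2,
        n_reg=nr + 1,
        n_struct=g.n_struct,
        initial_state=s0,
        duplicate_pair=(i, nr),
    )


def add_random_gene(
    g: GRNGenotype,
    rng: np.random.Generator,
    k: int | None = None,
) -> GRNGenotype:
    """Attach a new regulator gene, unrelated to existing genes, with
    exactly ``k`` random interactions.

    ``k`` defaults to the average number of interactions — incoming plus
    outgoing — of the network's regulator genes, rounded with halves up
    (8 for a default-size network with 54 interactions, whose regulators
    average 7.5); this makes the default newcomer comparable to a typical
    duplicated gene, so the two gene-gain controls probe the same
    connectivity.  Pass ``k`` explicitly to match a particular gene's
    degree instead.  Each interaction is
    independently incoming (a regulator, possibly the new gene itself,
    regulating the newcomer) or outgoing (the newcomer regulating any
    gene, itself included) with probability 1/2; occupied positions are
    redrawn.  Weights are standard normal; the newcomer's initial activity
    is drawn uniformly from {+1, -1}.
    """
    if k is None:
        incoming = int(np.count_nonzero(g.matrix[: g.n_reg, :]))
        k = int(np.floor((incoming + g.n_connections) / g.n_reg + 0.5))
    nr, n = g.n_reg, g.n_genes
    max_slots = (nr + 1) + (n + 1) - 1  # new row + new column share the self-loop
    if k < 0 or k > max_slots:
        raise ValueError(f"k={k} outside the {max_slots} available new-gene slots")
    m1 = np.insert(g.matrix, nr, 0.0, axis=1)
    m2 = np.insert(m1, nr, 0.0, axis=0)
    placed = 0
    while placed < k:
        if rng.random() < 0.5:  # incoming: some regulator acts on the new gene
            slot = (nr, int(rng.integers(nr + 1)))
        else:  # outgoing: the new gene acts on some gene
            slot = (int(rng.integers(n + 1)), nr)
        if m2[slot] != 0.0:
            continue
        m2[slot] = _std_normal_nonzero(rng)
        placed += 1
    s_new = 1 if rng.random() < 0.5 else -1
    s0 = np.insert(g.initial_state, nr, s_new)
    return GRNGenotype(
        matrix=m2,
        n_reg=nr + 1,
        n_struct=g.n_struct,
        initial_state=s0,
        duplicate_pair=g.duplicate_pair,
    )


def write_mutation_records(
    records: Sequence[MutationRecord], path: str | Path
) -> None:
    """Audit/replay stream: one TSV row per mutation."""
    lines = ["kind\ttarget\tregulator\told_weight\tnew_weight"]
    for r in records:
        lines.append(
            f"{r.kind}\t{r.target_index}\t{r.regulator_index}\t{r.old_weight!r}\t{r.new_weight!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
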