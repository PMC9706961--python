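"""Discrete threshold dynamics of gene regulatory networks.

The model is a two-tier variant of Wagner's GRN model.  A network holds
``n_reg`` transcription-factor (regulator) genes followed by ``n_struct``
structural genes.  Regulatory interactions live in a real matrix ``M`` of
``n_reg + n_struct`` rows and ``n_reg`` columns: entry ``m[i, j]`` is the
effect of regulator ``j`` on gene ``i`` (positive = activation, negative =
inhibition).  Structural genes never regulate, so the matrix has no columns
for them.

Gene activity is a vector of +1/-1 states.  From a predefined initial
condition the network is updated synchronously,

    s_i(t+1) = sign( sum_j m[i, j] * s_j(t) ),

with the convention that a gene whose total regulatory input is exactly
zero keeps its previous state.  Because the state space is finite the
trajectory always falls into an attractor: a fixed point or a limit cycle.
The *phenotype* is the repeating sequence of structural-gene activity
patterns along the attractor, reduced to its minimal period and compared
up to cyclic rotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from math import lcm
from pathlib import Path
import numpy as np

__all__ = [
    "ModelConfig",
    "GRNGenotype",
    "Attractor",
    "Phenotype",
    "update_state",
    "find_attractor",
    "phenotype_of",
    "phenotypes_equal",
    "phenotype_similarity",
    "genotype_to_json",
    "genotype_from_json",
    "write_edge_list",
]


@dataclass(frozen=True)
class ModelConfig:
    """Model dimensions and global knobs for one study.

    Defaults are the study conditions: 12 regulator genes, 6 structural
    genes and a target of C = (n_reg + n_struct) * n_reg / 4 = 54
    interactions, held within ``[C - connection_tolerance,
    C + connection_tolerance]`` during network sampling.
    """

    n_reg: int = 12
    n_struct: int = 6
    target_connections: int | None = None
    connection_tolerance: int = 2
    max_update_steps: int = 100_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_reg < 1:
            raise ValueError("n_reg must be >= 1")
        if self.n_struct < 0:
            raise ValueError("n_struct must be >= 0")
        if self.target_connections is None:
            object.__setattr__(
                self, "target_connections", (self.n_reg + self.n_struct) * self.n_reg // 4
            )
        if self.target_connections > (self.n_reg + self.n_struct) * self.n_reg:
            raise ValueError("target_connections exceeds matrix size")

    @property
    def n_genes(self) -> int:
        return self.n_reg + self.n_struct


@dataclass
class GRNGenotype:
    """An interaction matrix plus gene-role bookkeeping.

    ``matrix`` has ``n_reg + n_struct`` rows and ``n_reg`` columns; genes
    are indexed with regulators first (0..n_reg-1) and structural genes
    last.  ``initial_state`` is the predefined +1/-1 start condition shared
    by all dynamics of this genotype.  ``duplicate_pair`` marks the two
    regulator indices of a duplicate pair when the genotype was produced by
    a single-gene duplication.
    """

    matrix: np.ndarray
    n_reg: int
    n_struct: int
    initial_state: np.ndarray
    duplicate_pair: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.initial_state = np.asarray(self.initial_state, dtype=np.int8)
        if self.matrix.shape != (self.n_reg + self.n_struct, self.n_reg):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"({self.n_reg + self.n_struct}, {self.n_reg})"
            )
        if self.initial_state.shape != (self.n_reg + self.n_struct,):
            raise ValueError("initial_state length must equal n_reg + n_struct")
        if not np.all(np.abs(self.initial_state) == 1):
            raise ValueError("initial_state entries must be +1 or -1")

    @property
    def n_genes(self) -> int:
        return self.n_reg + self.n_struct

    @property
    def n_connections(self) -> int:
        return int(np.count_nonzero(self.matrix))

    @property
    def roles(self) -> list[str]:
        return ["regulator"] * self.n_reg + ["structural"] * self.n_struct

    def copy(self) -> "GRNGenotype":
        return replace(self, matrix=self.matrix.copy(), initial_state=self.initial_state.copy())


@dataclass
class Attractor:
    """The repeating state sequence a trajectory settles into.

    ``cycle`` is a (period, n_genes) array of +1/-1 states; applying one
    update to row k yields row (k+1) mod period.  ``transient_length`` is
    the number of updates from the initial condition to the first cycle
    state.
    """

    cycle: np.ndarray
    period: int
    transient_length: int


@dataclass(frozen=True)
class Phenotype:
    """Canonical repeating sequence of structural-gene activity patterns.

    ``pattern`` is a tuple of rows (each a tuple of +1/-1 ints of length
    n_struct), reduced to minimal period and rotated to the
    lexicographically smallest cyclic rotation so that equal structural
    dynamics compare equal regardless of attractor phase.  Hashable, so
    phenotypes can key dictionaries when counting distinct variants.
    """

    pattern: tuple[tuple[int, ...], ...]
    canonical: bool = True

    @property
    def period(self) -> int:
        return len(self.pattern)

    @property
    def n_struct(self) -> int:
        return len(self.pattern[0]) if self.pattern else 0

    def as_array(self) -> np.ndarray:
        return np.array(self.pattern, dtype=np.int8).reshape(self.period, self.n_struct)


def update_state(g: GRNGenotype, s: np.ndarray) -> np.ndarray:
    """Apply one synchronous update to activity state ``s``.

    Each gene takes the sign of its summed regulatory input; a gene with
    input exactly zero holds its previous state.
    """
    s = np.asarray(s)
    if s.shape != (g.n_genes,):
        raise ValueError(f"state length {s.shape} does not match {g.n_genes} genes")
    field_ = g.matrix @ s[: g.n_reg].astype(np.float64)
    return np.where(field_ > 0, 1, np.where(field_ < 0, -1, s)).astype(np.int8)


def find_attractor(g: GRNGenotype, max_steps: int = 100_000) -> Attractor:
    """Iterate the dynamics from the genotype's initial condition until a
    state recurs; return the cycle, its period and the transient length.

    Deterministic: the same genotype always yields the same attractor.
    Raises ``RuntimeError`` if no recurrence appears within ``max_steps``
    (unreachable for any finite network unless the cap is set below the
    trajectory length).
    """
    m = g.matrix
    nr = g.n_reg
    s = g.initial_state.astype(np.float64)
    seen: dict[bytes, int] = {s.tobytes(): 0}
    traj: list[np.ndarray] = [s]
    for t in range(1, max_steps + 1):
        f = m @ s[:nr]
        s = np.where(f > 0.0, 1.0, np.where(f < 0.0, -1.0, s))
        key = s.tobytes()
        tau = seen.get(key)
        if tau is not None:
            cycle = np.array(traj[tau:], dtype=np.int8)
            return Attractor(cycle=cycle, period=t - tau, transient_length=tau)
        seen[key] = t
        traj.append(s)
    raise RuntimeError(f"no attractor found within {max_steps} update steps")


def _canonical_pattern(rows: np.ndarray) -> tuple[tuple[int, ...], ...]:
    """Reduce rows of a cycle projection to minimal period and smallest
    lexicographic rotation."""
    kappa = rows.shape[0]
    # minimal period: smallest divisor d of kappa with rows == tile(rows[:d])
    d = kappa
    for cand in range(1, kappa):
        if kappa % cand == 0 and np.array_equal(
            rows, np.tile(rows[:cand], (kappa // cand, 1))
        ):
            d = cand
            break
    reduced = [tuple(int(x) for x in row) for row in rows[:d]]
    rotations = [tuple(reduced[k:] + reduced[:k]) for k in range(d)]
    return min(rotations)


def phenotype_of(a: Attractor, n_struct: int) -> Phenotype:
    """Project an attractor onto its structural genes and canonicalize.

    Consecutive repeats collapse through minimal-period reduction, so two
    networks with different attractors but identical structural dynamics
    map to equal phenotypes.
    """
    if n_struct == 0:
        return Phenotype(pattern=((),))
    rows = a.cycle[:, -n_struct:]
    return Phenotype(pattern=_canonical_pattern(rows))


def phenotypes_equal(p: Phenotype, q: Phenotype) -> bool:
    """True iff the canonical patterns are identical."""
    return p.pattern == q.pattern


def phenotype_similarity(p: Phenotype, q: Phenotype) -> float:
    """Similarity = 1 - normalized Hamming distance between phenotypes.

    For two fixed points this is the fraction of structural genes with the
    same state.  When one phenotype cycles, the fixed point is compared
    against every cycle row and the distances averaged.  When both cycle,
    the patterns are unrolled to the least common multiple of their periods
    and the cyclic offset of ``q`` that maximizes the mean positionwise
    similarity is used; this reduces to the fixed-point-versus-cycle rule
    whenever either period is 1 and guarantees S(p, p) = 1.
    """
    ns = p.n_struct
    if ns != q.n_struct:
        raise ValueError("phenotypes have different numbers of structural genes")
    if ns == 0:
        return 1.0
    if p.pattern == q.pattern:
        return 1.0
    pa, qa = p.as_array(), q.as_array()
    n = lcm(p.period, q.period)
    pu = np.tile(pa, (n // p.period, 1))
    qu = np.tile(qa, (n // q.period, 1))
    best = 0.0
    for off in range(q.period):
        sim = float(np.mean(pu == np.roll(qu, -off, axis=0)))
        if sim > best:
            best = sim
    return best


def pattern_from_matrix(
    matrix: np.ndarray,
    n_reg: int,
    n_struct: int,
    initial_state: np.ndarray,
    max_steps: int = 100_000,
) -> tuple[tuple[int, ...], ...]:
    """Canonical phenotype pattern straight from a matrix and initial
    condition, skipping genotype construction.

    Fast path for the network sampler and the perturbation assays, which
    evaluate millions of candidate matrices; equivalent to
    ``phenotype_of(find_attractor(g), n_struct).pattern``.
    """
    s = initial_state.astype(np.float64)
    seen: dict[bytes, int] = {s.tobytes(): 0}
    traj: list[np.ndarray] = [s]
    for t in range(1, max_steps + 1):
        f = matrix @ s[:n_reg]
        s = np.where(f > 0.0, 1.0, np.where(f < 0.0, -1.0, s))
        key = s.tobytes()
        tau = seen.get(key)
        if tau is not None:
            if n_struct == 0:
                return ((),)
            rows = np.array(traj[tau:], dtype=np.int8)[:, -n_struct:]
            return _canonical_pattern(rows)
        seen[key] = t
        traj.append(s)
    raise RuntimeError(f"no attractor found within {max_steps} update steps")


# ---------------------------------------------------------------------------
# serialization

def genotype_to_json(g: GRNGenotype) -> dict:
    return {
        "n_reg": g.n_reg,
        "n_struct": g.n_struct,
        "matrix": g.matrix.tolist(),
        "roles": g.roles,
        "duplicate_pair": list(g.duplicate_pair) if g.duplicate_pair else None,
        "initial_state": g.initial_state.tolist(),
    }


def genotype_from_json(d: dict) -> GRNGenotype:
    pair = d.get("duplicate_pair")
    return GRNGenotype(
        matrix=np.array(d["matrix"], dtype=np.float64),
        n_reg=d["n_reg"],
        n_struct=d["n_struct"],
        initial_state=np.array(d["initial_state"], dtype=np.int8),
        duplicate_pair=tuple(pair) if pair else None,
    )


def write_edge_list(g: GRNGenotype, path: str | Path) -> None:
    """Write nonzero interactions as a TSV edge list with 0-based indices:
    regulator_index, target_index, weight."""
    lines = ["regulator_index\ttarget_index\tweight"]
    targets, regulators = np.nonzero(g.matrix)
    for i, j in zip(targets, regulators):
        lines.append(f"{j}\t{i}\t{float(g.matrix[i, j])!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def save_genotype(g: GRNGenotype, path: str | Path) -> None:
    Path(path).write_text(json.dumps(genotype_to_json(g)))


def load_genotype(path: str | Path) -> GRNGenotype:
    return genotype_from_json(json.loads(Path(path).read_text()))
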