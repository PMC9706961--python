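"""Shared fixtures: tiny hand-checkable genotypes, random genotype
factories, and a reduced-size sampled ensemble for ensemble-level
property tests."""

from __future__ import annotations

import numpy as np
import pytest

from grndup.core import GRNGenotype, ModelConfig
from grndup.sampler import make_founder, mc_walk_sample


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def tiny_genotype():
    """n_reg=1, n_struct=1; regulator self-activates, inhibits the
    structural gene.  Fixed point (+1, -1) from s0=(+1, +1)."""
    return GRNGenotype(
        matrix=np.array([[1.0], [-2.0]]),
        n_reg=1,
        n_struct=1,
        initial_state=np.array([1, 1], dtype=np.int8),
    )


def random_genotype(
    rng: np.random.Generator,
    n_reg: int = 4,
    n_struct: int = 3,
    n_connections: int | None = None,
) -> GRNGenotype:
    """Random dense-ish genotype for property tests."""
    n = n_reg + n_struct
    if n_connections is None:
        n_connections = max(1, n * n_reg // 2)
    matrix = np.zeros((n, n_reg))
    pos = rng.choice(n * n_reg, size=n_connections, replace=False)
    for flat in pos:
        w = 0.0
        while w == 0.0:
            w = rng.standard_normal()
        matrix[flat // n_reg, flat % n_reg] = w
    s0 = (rng.integers(0, 2, size=n) * 2 - 1).astype(np.int8)
    return GRNGenotype(matrix=matrix, n_reg=n_reg, n_struct=n_struct, initial_state=s0)


# reduced model for ensemble-level property tests: same structure, smaller
# dimensions so the walk stays fast (interval = 20*10*6 = 1200 steps)
REDUCED = ModelConfig(n_reg=6, n_struct=4)


@pytest.fixture(scope="session")
def reduced_ensemble():
    """A 60-network uniform sample at reduced size, with its target
    phenotype; shared across ensemble-property tests."""
    rng = np.random.default_rng(42)
    founder, a = make_founder(REDUCED, rng)
    sample = mc_walk_sample(founder, a, 60, REDUCED, rng)
    return sample, a


# ---------------------------------------------------------------------------
# uniformity surrogate: an enumerable toy neutral set with unit weights

import functools
import itertools

from grndup.core import Phenotype, pattern_from_matrix
from grndup.perturb import MutationRecord


def discrete_proposal(matrix: np.ndarray, rng: np.random.Generator) -> MutationRecord:
    """Symmetric walk proposal on matrices with weights in {-1, 0, +1}: a
    zero entry gains +/-1 with equal probability; a nonzero entry is
    deleted with probability 1/2 and otherwise kept (sign-preserving
    'modify' is the identity on unit weights)."""
    n_rows, n_cols = matrix.shape
    flat = int(rng.integers(n_rows * n_cols))
    i, j = flat // n_cols, flat % n_cols
    old = float(matrix[i, j])
    if old == 0.0:
        return MutationRecord("add", i, j, 0.0, 1.0 if rng.random() < 0.5 else -1.0)
    if rng.random() < 0.5:
        return MutationRecord("delete", i, j, old, 0.0)
    return MutationRecord("modify", i, j, old, old)


@functools.lru_cache(maxsize=1)
def toy_walk_uniformity(seed: int = 123, samples_per_state: int = 40):
    """Run the Monte Carlo walk on a tiny discrete instance (n_reg=2,
    n_struct=1, unit weights, 2-4 connections) where the neutral set is
    enumerable; return (chi-squared p-value over the founder's connected
    component, component size, sampled counts)."""
    from scipy import stats as sps

    from grndup.core import GRNGenotype
    from grndup.sampler import mc_walk_sample

    cfg = ModelConfig(n_reg=2, n_struct=1, target_connections=3, connection_tolerance=1)
    s0 = np.array([1, -1, 1], dtype=np.int8)
    founder_matrix = np.array([[1.0, 0.0], [0.0, -1.0], [1.0, 0.0]])
    founder = GRNGenotype(matrix=founder_matrix, n_reg=2, n_struct=1, initial_state=s0)
    a = Phenotype(pattern=pattern_from_matrix(founder_matrix, 2, 1, s0))

    members = set()
    for values in itertools.product((-1.0, 0.0, 1.0), repeat=6):
        m = np.array(values).reshape(3, 2)
        if not (2 <= np.count_nonzero(m) <= 4):
            continue
        if pattern_from_matrix(m, 2, 1, s0) == a.pattern:
            members.add(m.astype(np.int8).tobytes())

    start = founder_matrix.astype(np.int8).tobytes()
    comp, frontier = {start}, [start]
    while frontier:  # component under single entry moves 0 <-> +/-1
        cur = np.frombuffer(frontier.pop(), dtype=np.int8).reshape(3, 2)
        for i in range(3):
            for j in range(2):
                for v in (1, -1) if cur[i, j] == 0 else (0,):
                    nxt = cur.copy()
                    nxt[i, j] = v
                    key = nxt.tobytes()
                    if key in members and key not in comp:
                        comp.add(key)
                        frontier.append(key)

    rng = np.random.default_rng(seed)
    sample = mc_walk_sample(
        founder, a, samples_per_state * len(comp), cfg, rng,
        propose=discrete_proposal, interval=29,
    )
    counts = dict.fromkeys(comp, 0)
    for g in sample.networks:
        counts[g.matrix.astype(np.int8).tobytes()] += 1
    pvalue = float(sps.chisquare(list(counts.values())).pvalue)
    return pvalue, len(comp), counts
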