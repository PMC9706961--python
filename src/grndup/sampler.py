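"""Uniform sampling of networks on a neutral set.

The set of genotypes that produce a given phenotype *A* from a shared
initial condition is huge and connected under single-interaction
mutations.  A Metropolis-style Monte Carlo walk traverses it: every step
proposes one random mutation and accepts it only if the mutant still
produces *A* and keeps its interaction count inside a narrow window
around the target connectivity C; otherwise the walk stays put.  Because
the proposal is symmetric and acceptance is an indicator, the stationary
distribution is uniform over the (connected component of the) neutral
set.  Networks are recorded every 20 (n_reg + n_struct) n_reg steps —
4320 steps at the default size — so consecutive samples are decorrelated.

This module is the study's data generator: it builds the founder network
that defines phenotype *A*, draws the sample X_i, and derives the paired
ensembles X_D (one random gene duplicated per network) and X_a (one
random unrelated regulator added per network).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .core import (
    GRNGenotype,
    ModelConfig,
    Phenotype,
    find_attractor,
    genotype_from_json,
    genotype_to_json,
    pattern_from_matrix,
    phenotype_of,
)
from .perturb import (
    MutationRecord,
    add_random_gene,
    apply_mutation,
    draw_mutation,
    duplicate_gene,
    revert_mutation,
)

__all__ = [
    "NetworkSample",
    "make_founder",
    "mc_walk_sample",
    "build_paired_ensembles",
    "sampling_interval",
    "sample_to_json",
    "sample_from_json",
]

ProposalFn = Callable[[np.ndarray, np.random.Generator], MutationRecord]


@dataclass
class NetworkSample:
    """An ordered ensemble of genotypes sharing one target phenotype.

    ``kind`` distinguishes the initial sample ("initial") from its paired
    derivatives ("duplication" / "addition"); for those, ``gain_indices``
    records, per network, which regulator was duplicated (X_D) or is
    otherwise ``-1`` (X_a, where the newcomer has no template gene).
    """

    networks: list[GRNGenotype]
    target_phenotype: Phenotype
    initial_condition: np.ndarray
    config: ModelConfig
    walk_stats: dict = field(default_factory=dict)
    kind: str = "initial"
    gain_indices: list[int] | None = None

    def __len__(self) -> int:
        return len(self.networks)


def sampling_interval(cfg: ModelConfig) -> int:
    """Mutational steps between recorded networks: 20 (n_reg+n_struct) n_reg."""
    return 20 * cfg.n_genes * cfg.n_reg


def make_founder(
    cfg: ModelConfig, rng: np.random.Generator
) -> tuple[GRNGenotype, Phenotype]:
    """Build the walk's starting network and the phenotype *A* it defines.

    The founder has exactly ``target_connections`` interactions at
    uniformly random positions with standard-normal weights and a random
    +1/-1 initial condition, redrawn until its dynamics settle into a
    fixed point: *A* is designed to be a stable gene-expression pattern,
    the canonical phenotype notion for this model family (networks *on*
    the walk may still realize *A* through cycling regulators, since only
    the structural pattern is constrained).  The founder satisfies the
    walk's acceptance condition by construction.
    """
    n, nr = cfg.n_genes, cfg.n_reg
    while True:
        matrix = np.zeros((n, nr))
        positions = rng.choice(n * nr, size=cfg.target_connections, replace=False)
        for flat in positions:
            w = 0.0
            while w == 0.0:
                w = rng.standard_normal()
            matrix[flat // nr, flat % nr] = w
        s0 = (rng.integers(0, 2, size=n) * 2 - 1).astype(np.int8)
        g = GRNGenotype(
            matrix=matrix, n_reg=nr, n_struct=cfg.n_struct, initial_state=s0
        )
        attractor = find_attractor(g, cfg.max_update_steps)
        if attractor.period == 1:
            return g, phenotype_of(attractor, cfg.n_struct)


def mc_walk_sample(
    founder: GRNGenotype,
    a: Phenotype,
    n: int,
    cfg: ModelConfig,
    rng: np.random.Generator,
    propose: ProposalFn = draw_mutation,
    interval: int | None = None,
) -> NetworkSample:
    """Collect ``n`` networks producing phenotype ``a`` by a Monte Carlo
    walk started at ``founder`` (the founder itself is never included).

    Every proposal — accepted or rejected — counts as one mutational
    step; a proposal is rejected if it pushes the interaction count out
    of ``[C - tol, C + tol]`` or changes the phenotype.  ``propose`` can
    be swapped (e.g. for discrete-weight toy instances) as long as it
    stays symmetric.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if interval is None:
        interval = sampling_interval(cfg)
    nr, ns = founder.n_reg, founder.n_struct
    s0 = founder.initial_state.copy()
    matrix = founder.matrix.copy()
    nnz = int(np.count_nonzero(matrix))
    lo = cfg.target_connections - cfg.connection_tolerance
    hi = cfg.target_connections + cfg.connection_tolerance
    target = a.pattern
    delta = {"add": 1, "delete": -1, "modify": 0}
    accepted = rejected_conn = rejected_phen = 0
    networks: list[GRNGenotype] = []
    steps = 0
    while len(networks) < n:
        rec = propose(matrix, rng)
        steps += 1
        new_nnz = nnz + delta[rec.kind]
        if new_nnz < lo or new_nnz > hi:
            rejected_conn += 1
        else:
            apply_mutation(matrix, rec)
            if pattern_from_matrix(matrix, nr, ns, s0, cfg.max_update_steps) == target:
                nnz = new_nnz
                accepted += 1
            else:
                revert_mutation(matrix, rec)
                rejected_phen += 1
        if steps % interval == 0:
            networks.append(
                GRNGenotype(
                    matrix=matrix.copy(),
                    n_reg=nr,
                    n_struct=ns,
                    initial_state=s0.copy(),
                )
            )
    stats = {
        "steps": steps,
        "accepted": accepted,
        "rejected_connectivity": rejected_conn,
        "rejected_phenotype": rejected_phen,
        "interval": interval,
    }
    return NetworkSample(
        networks=networks,
        target_phenotype=a,
        initial_condition=s0,
        config=cfg,
        walk_stats=stats,
    )


def build_paired_ensembles(
    xi: NetworkSample, rng: np.random.Generator
) -> tuple[NetworkSample, NetworkSample]:
    """Derive X_D and X_a from X_i, index-aligned for paired comparisons.

    X_D duplicates one uniformly chosen regulator per network; X_a adds
    one random unrelated regulator with the network-average number of
    interactions.
    """
    if not xi.networks:
        raise ValueError("X_i is empty")
    dup_networks, dup_indices, add_networks = [], [], []
    for g in xi.networks:
        i = int(rng.integers(g.n_reg))
        dup_networks.append(duplicate_gene(g, i))
        dup_indices.append(i)
        add_networks.append(add_random_gene(g, rng))
    xd = NetworkSample(
        networks=dup_networks,
        target_phenotype=xi.target_phenotype,
        initial_condition=xi.initial_condition,
        config=xi.config,
        kind="duplication",
        gain_indices=dup_indices,
    )
    xa = NetworkSample(
        networks=add_networks,
        target_phenotype=xi.target_phenotype,
        initial_condition=xi.initial_condition,
        config=xi.config,
        kind="addition",
        gain_indices=[-1] * len(add_networks),
    )
    return xd, xa


def sample_to_json(sample: NetworkSample) -> dict:
    return {
        "kind": sample.kind,
        "config": {
            "n_reg": sample.config.n_reg,
            "n_struct": sample.config.n_struct,
            "target_connections": sample.config.target_connections,
            "connection_tolerance": sample.config.connection_tolerance,
            "max_update_steps": sample.config.max_update_steps,
            "seed": sample.config.seed,
        },
        "target_phenotype": [list(row) for row in sample.target_phenotype.pattern],
        "initial_condition": sample.initial_condition.tolist(),
        "walk_stats": sample.walk_stats,
        "gain_indices": sample.gain_indices,
        "networks": [genotype_to_json(g) for g in sample.networks],
    }


def sample_from_json(d: dict) -> NetworkSample:
    cfg = ModelConfig(**d["config"])
    return NetworkSample(
        networks=[genotype_from_json(g) for g in d["networks"]],
        target_phenotype=Phenotype(
            pattern=tuple(tuple(int(x) for x in row) for row in d["target_phenotype"])
        ),
        initial_condition=np.array(d["initial_condition"], dtype=np.int8),
        config=cfg,
        walk_stats=d.get("walk_stats", {}),
        kind=d.get("kind", "initial"),
        gain_indices=d.get("gain_indices"),
    )


def save_sample(sample: NetworkSample, path: str | Path) -> None:
    Path(path).write_text(json.dumps(sample_to_json(sample)))


def load_sample(path: str | Path) -> NetworkSample:
    return sample_from_json(json.loads(Path(path).read_text()))
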