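"""Robustness/similarity assays, access profiling and stratified
mutation records."""

import math

import numpy as np
import pytest

from grndup.assays import (
    access_profile,
    assay_addition,
    assay_duplication,
    assay_mutational,
    classify_access,
    duplicate_structural_props,
    stratified_mutation_assay,
    AccessProfile,
)
from grndup.core import (
    GRNGenotype,
    Phenotype,
    find_attractor,
    pattern_from_matrix,
    phenotype_of,
)
from grndup.perturb import apply_mutation, duplicate_gene

from conftest import random_genotype


def ref_of(g: GRNGenotype) -> Phenotype:
    return phenotype_of(find_attractor(g), g.n_struct)


class TestMutationalAssay:
    def test_counts_and_bounds(self, rng):
        g = random_genotype(rng, n_reg=12, n_struct=6, n_connections=54)
        summary = assay_mutational(g, ref_of(g), rng)
        assert summary.n_perturbations == 432
        assert 0.0 <= summary.robustness <= 1.0
        assert 0.0 <= summary.mean_similarity <= 1.0

    def test_replay_oracle(self, rng):
        """R_mu recomputed by re-applying each stored mutation record and
        re-running the dynamics matches the assay's value exactly."""
        g = random_genotype(rng)
        ref = ref_of(g)
        summary = assay_mutational(g, ref, rng, n=200)
        robust = 0
        for rec in summary.records:
            m = g.matrix.copy()
            apply_mutation(m, rec)
            if pattern_from_matrix(m, g.n_reg, g.n_struct, g.initial_state) == ref.pattern:
                robust += 1
        assert robust / 200 == pytest.approx(summary.robustness)

    def test_fully_robust_genotype(self, rng):
        # no interactions: every possible mutation is an addition into a
        # single-regulator network whose structural gene has no input;
        # with n_struct=0 the phenotype is the trivial empty pattern
        g = GRNGenotype(
            matrix=np.zeros((1, 1)),
            n_reg=1,
            n_struct=0,
            initial_state=np.array([1], dtype=np.int8),
        )
        summary = assay_mutational(g, ref_of(g), rng, n=20)
        assert summary.robustness == 1.0 and summary.mean_similarity == 1.0

    def test_seed_reproducibility(self, rng):
        g = random_genotype(rng)
        ref = ref_of(g)
        s1 = assay_mutational(g, ref, np.random.default_rng(5), n=100)
        s2 = assay_mutational(g, ref, np.random.default_rng(5), n=100)
        assert s1.robustness == s2.robustness
        assert s1.mean_similarity == s2.mean_similarity


class TestDuplicationAssay:
    def test_exhaustive_over_regulators(self, rng):
        g = random_genotype(rng, n_reg=12, n_struct=6, n_connections=54)
        summary = assay_duplication(g, ref_of(g))
        assert summary.n_perturbations == 12
        assert summary.robustness * 12 == int(round(summary.robustness * 12))

    def test_zero_column_duplicate_is_silent(self, rng):
        g = random_genotype(rng, n_reg=3, n_struct=2)
        g.matrix[:, 1] = 0.0  # gene 1 regulates nothing
        ref = ref_of(g)
        d = duplicate_gene(g, 1)
        assert (
            pattern_from_matrix(d.matrix, d.n_reg, d.n_struct, d.initial_state)
            == ref.pattern
        )

    def test_deterministic(self, rng):
        g = random_genotype(rng)
        ref = ref_of(g)
        s1, s2 = assay_duplication(g, ref), assay_duplication(g, ref)
        assert (s1.robustness, s1.mean_similarity) == (s2.robustness, s2.mean_similarity)


class TestAdditionAssay:
    def test_counts_and_reproducibility(self, rng):
        g = random_genotype(rng, n_reg=12, n_struct=6, n_connections=54)
        ref = ref_of(g)
        s1 = assay_addition(g, ref, np.random.default_rng(3))
        s2 = assay_addition(g, ref, np.random.default_rng(3))
        assert s1.n_perturbations == 12
        assert s1.robustness == s2.robustness

    def test_summary_invariant_s_ge_r(self, rng):
        """Preserving perturbations contribute similarity 1, so S_K >= R_K
        for every class."""
        for seed in range(10):
            g = random_genotype(np.random.default_rng(seed))
            ref = ref_of(g)
            r = np.random.default_rng(seed)
            for summary in (
                assay_mutational(g, ref, r, n=60),
                assay_duplication(g, ref),
                assay_addition(g, ref, r),
            ):
                assert summary.mean_similarity >= summary.robustness - 1e-12
                if summary.robustness == 1.0:
                    assert summary.mean_similarity == 1.0


class TestAccessProfile:
    def test_partition_of_mutations(self, rng):
        g = random_genotype(rng)
        ref = ref_of(g)
        prof = access_profile(g, ref, rng, n=150)
        assert ref not in prof.phenotype_counts
        assert sum(prof.phenotype_counts.values()) + prof.n_preserving == 150
        assert prof.n_accessible == len(prof.phenotype_counts)

    def test_classification_set_algebra(self, rng):
        g = random_genotype(rng)
        ref = ref_of(g)
        before = access_profile(g, ref, rng, n=200)
        after = access_profile(g, ref, rng, n=200)
        cls = classify_access(before, after)
        assert cls.recurrent | cls.lost == set(before.phenotype_counts)
        assert cls.recurrent | cls.newcomer == set(after.phenotype_counts)
        assert not (cls.recurrent & cls.lost)
        assert not (cls.recurrent & cls.newcomer)
        assert not (cls.lost & cls.newcomer)
        assert set(cls.before_counts) == cls.recurrent | cls.lost

    def test_identical_profiles_all_recurrent(self, rng):
        g = random_genotype(rng)
        ref = ref_of(g)
        prof = access_profile(g, ref, rng, n=100)
        cls = classify_access(prof, prof)
        assert cls.recurrent == set(prof.phenotype_counts)
        assert not cls.lost and not cls.newcomer

    def test_mismatched_reference_raises(self, rng):
        p1 = AccessProfile(Phenotype(pattern=((1,),)), {}, 10, 10)
        p2 = AccessProfile(Phenotype(pattern=((-1,),)), {}, 10, 10)
        with pytest.raises(ValueError):
            classify_access(p1, p2)


class TestDuplicateStructuralProps:
    def build(self, matrix, n_reg, n_struct):
        n = n_reg + n_struct
        return GRNGenotype(
            matrix=np.asarray(matrix, dtype=float),
            n_reg=n_reg,
            n_struct=n_struct,
            initial_state=np.ones(n, dtype=np.int8),
        )

    def test_direct_regulation_path_one(self):
        # gene 0 -> structural gene 2
        g = self.build([[0, 0], [0, 0], [1, 0]], 2, 1)
        props = duplicate_structural_props(g, 0)
        assert props == (1.0, 0, 1)

    def test_isolated_gene_unreachable(self):
        g = self.build([[0, 0], [0, 0], [0, 1]], 2, 1)
        props = duplicate_structural_props(g, 0)
        assert props.in_degree == 0 and props.out_degree == 0
        assert math.isinf(props.path_length)

    def test_two_step_chain(self):
        # 0 -> 1 -> structural 2, no direct edge from 0
        g = self.build([[0, 0], [1, 0], [0, 1]], 2, 1)
        props = duplicate_structural_props(g, 0)
        assert props.path_length == 2.0
        assert props.out_degree == 1 and props.in_degree == 0

    def test_degrees_count_row_and_column(self, rng):
        g = random_genotype(rng, n_reg=5, n_struct=3)
        for i in range(5):
            props = duplicate_structural_props(g, i)
            assert props.in_degree == np.count_nonzero(g.matrix[i, :])
            assert props.out_degree == np.count_nonzero(g.matrix[:, i])

    def test_structural_index_raises(self, rng):
        g = random_genotype(rng, n_reg=2, n_struct=2)
        with pytest.raises(ValueError):
            duplicate_structural_props(g, 3)


class TestStratifiedAssay:
    def test_requires_duplicate_pair(self, rng):
        g = random_genotype(rng)
        with pytest.raises(ValueError):
            stratified_mutation_assay(g, ref_of(g), rng)

    def test_record_counts(self, rng):
        g = duplicate_gene(random_genotype(rng, n_reg=3, n_struct=2), 1)
        ref = ref_of(g)
        records = stratified_mutation_assay(g, ref, rng, n_add_per_slot=2)
        nnz = g.n_connections
        zeros = g.matrix.size - nnz
        deletions = [r for r in records if r.mutation_kind == "delete"]
        additions = [r for r in records if r.mutation_kind == "add"]
        assert len(deletions) == nnz
        assert len(additions) == 4 * zeros  # 2 positive + 2 negative per slot
        assert all(0.0 <= r.similarity <= 1.0 for r in records)

    def test_class_labels(self, rng):
        g = duplicate_gene(random_genotype(rng, n_reg=3, n_struct=2), 0)
        assert g.duplicate_pair == (0, 3)
        records = stratified_mutation_assay(g, ref_of(g), rng, n_add_per_slot=1)
        assert {r.regulator_class for r in records} == {"duplicate", "non-duplicate"}
        assert {r.target_class for r in records} == {
            "duplicate",
            "non-duplicate",
            "structural",
        }

    def test_twin_deletion_equivalence_oracle(self):
        """Deleting one copy's outgoing interaction leaves a network whose
        phenotype equals that of the pre-duplication network with column i
        doubled except at that target, where the original weight remains."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g = random_genotype(rng, n_reg=4, n_struct=3)
            i = int(rng.integers(4))
            # exclude t == i: deleting the twin->original edge makes the
            # copies diverge, so the reduced-network equivalence need not hold
            targets = [t for t in np.nonzero(g.matrix[:, i])[0] if t != i]
            if not targets:
                continue
            t = int(targets[0])
            d = duplicate_gene(g, i)
            copy_col = g.n_reg  # the twin sits at index n_reg
            t_dup = t if t < g.n_reg else t + 1  # structural rows shifted by 1
            mutant = d.matrix.copy()
            mutant[t_dup, copy_col] = 0.0
            equivalent = g.matrix.copy()
            equivalent[:, i] *= 2
            equivalent[t, i] = g.matrix[t, i]
            assert pattern_from_matrix(
                mutant, d.n_reg, d.n_struct, d.initial_state
            ) == pattern_from_matrix(equivalent, g.n_reg, g.n_struct, g.initial_state)
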