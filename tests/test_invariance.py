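"""Invariance transforms and the hierarchical gauge-fixing pipeline."""

import numpy as np
import pytest

from slicerank.core import (
    SLICE_TYPES,
    RankTuple,
    UsageError,
    masked_mse,
    partial_reconstruct,
    reconstruct,
    relative_error,
)
from slicerank.fitting import FitConfig
from slicerank.invariance import (
    BetweenConfig,
    BetweenTransferParams,
    WithinTransform,
    apply_between_transform,
    apply_transfer_params,
    apply_within_transform,
    canonicalize_within,
    hierarchical_optimize,
    optimize_between,
    partial_energy,
)

from conftest import random_model

DIMS = (12, 10, 8)


class TestWithinTransform:
    def test_identity_leaves_model_unchanged(self, rng):
        m = random_model(rng, DIMS, (2, 0, 0))
        out = apply_within_transform(m, WithinTransform("neuron", np.eye(2)))
        for a, b in zip(m.components, out.components):
            assert np.allclose(a.loading, b.loading) and np.allclose(a.slice, b.slice)

    def test_permutation_preserves_reconstruction(self, rng):
        m = random_model(rng, DIMS, (0, 3, 0))
        P = np.eye(3)[[2, 0, 1]]
        out = apply_within_transform(m, WithinTransform("time", P))
        assert relative_error(reconstruct(m), reconstruct(out)) < 1e-12

    def test_random_invertible_preserves_partial(self, rng):
        m = random_model(rng, DIMS, (2, 0, 0))
        F = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        out = apply_within_transform(m, WithinTransform("neuron", F))
        assert relative_error(
            partial_reconstruct(m, "neuron"), partial_reconstruct(out, "neuron")
        ) < 1e-10
        # but the individual components do change
        assert not np.allclose(m.components[0].loading, out.components[0].loading)

    def test_singular_matrix_rejected(self, rng):
        m = random_model(rng, DIMS, (2, 0, 0))
        with pytest.raises(UsageError):
            apply_within_transform(m, WithinTransform("neuron", np.ones((2, 2))))


class TestBetweenTransform:
    def test_zero_transfer_is_identity(self, rng):
        m = random_model(rng, DIMS, (1, 1, 0))
        out = apply_between_transform(m, ("neuron", "time"), np.zeros(DIMS[2]))
        for a, b in zip(m.components, out.components):
            assert np.allclose(a.slice, b.slice)

    @pytest.mark.parametrize(
        "pair,rank,vec_len",
        [
            (("neuron", "time"), (1, 1, 0), 8),
            (("neuron", "trial"), (1, 0, 1), 10),
            (("time", "trial"), (0, 1, 1), 12),
        ],
        ids=["nt", "nk", "tk"],
    )
    def test_reconstruction_invariant_partials_change(self, rng, pair, rank, vec_len):
        m = random_model(rng, DIMS, rank)
        rec = reconstruct(m)
        out = apply_between_transform(m, pair, rng.normal(size=vec_len))
        assert relative_error(rec, reconstruct(out)) < 1e-10
        for st in pair:
            assert relative_error(
                partial_reconstruct(m, st), partial_reconstruct(out, st)
            ) > 1e-3

    def test_transfer_then_negation_restores(self, rng):
        m = random_model(rng, DIMS, (1, 1, 0))
        z = rng.normal(size=DIMS[2])
        back = apply_between_transform(
            apply_between_transform(m, ("neuron", "time"), z), ("neuron", "time"), -z
        )
        for a, b in zip(m.components, back.components):
            assert np.allclose(a.slice, b.slice, atol=1e-12)

    def test_empty_type_rejected(self, rng):
        m = random_model(rng, DIMS, (1, 0, 0))
        with pytest.raises(UsageError):
            apply_between_transform(m, ("neuron", "time"), np.zeros(DIMS[2]))

    def test_commutes_with_within_transform(self, rng):
        """Both orders preserve the reconstruction exactly."""
        m = random_model(rng, DIMS, (2, 1, 0))
        rec = reconstruct(m)
        F = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        z = rng.normal(size=DIMS[2])
        a = apply_between_transform(
            apply_within_transform(m, WithinTransform("neuron", F)),
            ("neuron", "time"), z,
        )
        b = apply_within_transform(
            apply_between_transform(m, ("neuron", "time"), z),
            WithinTransform("neuron", F),
        )
        assert relative_error(rec, reconstruct(a)) < 1e-10
        assert relative_error(rec, reconstruct(b)) < 1e-10


class TestOptimizeBetween:
    def test_single_type_unchanged(self, rng):
        m = random_model(rng, DIMS, (2, 0, 0))
        out = optimize_between(m)
        for a, b in zip(m.components, out.model.components):
            assert np.allclose(a.slice, b.slice)

    def test_reconstruction_preserved_and_l2_decreases(self, rng):
        m = random_model(rng, DIMS, (1, 1, 1))
        l2_before = partial_energy(m)
        out = optimize_between(m)
        assert out.l2 <= l2_before + 1e-9
        assert relative_error(reconstruct(m), reconstruct(out.model)) < 1e-6

    def test_planted_transfer_recovery(self, rng):
        """Optimizing a contaminated model lands on the same partial
        reconstructions as optimizing the clean model it came from."""
        clean = random_model(rng, DIMS, (1, 1, 0))
        contaminated = apply_between_transform(
            clean, ("neuron", "time"), 3.0 * rng.normal(size=DIMS[2])
        )
        o_clean = optimize_between(clean)
        o_cont = optimize_between(contaminated)
        for st in ("neuron", "time"):
            assert relative_error(
                partial_reconstruct(o_clean.model, st),
                partial_reconstruct(o_cont.model, st),
            ) < 1e-3

    def test_idempotence(self, rng):
        m = random_model(rng, DIMS, (1, 1, 1))
        once = optimize_between(m)
        twice = optimize_between(once.model)
        assert abs(twice.l2 - once.l2) < 1e-8 * max(1.0, once.l2)


class TestCanonicalize:
    def test_partials_preserved(self, rng):
        m = random_model(rng, DIMS, (2, 1, 1))
        out = canonicalize_within(m)
        for st in SLICE_TYPES:
            assert relative_error(
                partial_reconstruct(m, st), partial_reconstruct(out, st)
            ) < 1e-10

    def test_orthonormal_loadings_and_ordering(self, rng):
        m = random_model(rng, DIMS, (3, 0, 0))
        out = canonicalize_within(m)
        L = out.loadings("neuron")
        assert np.allclose(L.T @ L, np.eye(3), atol=1e-10)
        variances = [np.sum(c.slice**2) for c in out.components_of("neuron")]
        assert all(a >= b - 1e-12 for a, b in zip(variances, variances[1:]))

    def test_rotation_then_canonicalize_equality(self, rng):
        m = random_model(rng, DIMS, (2, 0, 0))
        F = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        rotated = apply_within_transform(m, WithinTransform("neuron", F))
        c1 = canonicalize_within(m)
        c2 = canonicalize_within(rotated)
        for a, b in zip(c1.components, c2.components):
            assert np.allclose(a.loading, b.loading, atol=1e-8)
            assert np.allclose(a.slice, b.slice, atol=1e-8)

    def test_idempotent_up_to_sign(self, rng):
        m = random_model(rng, DIMS, (2, 1, 0))
        once = canonicalize_within(m)
        twice = canonicalize_within(once)
        for a, b in zip(once.components, twice.components):
            assert np.allclose(a.loading, b.loading, atol=1e-10)

    def test_sign_convention(self, rng):
        m = random_model(rng, DIMS, (2, 1, 1))
        out = canonicalize_within(m)
        for c in out.components:
            assert c.loading[np.argmax(np.abs(c.loading))] > 0


class TestHierarchicalPipeline:
    def test_stage_protections_and_loss_preservation(self, rng):
        truth = random_model(rng, (15, 12, 10), (1, 1, 1))
        x = reconstruct(truth)
        opt = hierarchical_optimize(x, (1, 1, 1), FitConfig(seed=0), n_seeds=2)
        assert abs(masked_mse(x, reconstruct(opt.model)) - opt.l1) <= 1e-6 * max(1, opt.l1)

    def test_neuron_only_tensor_matches_pca(self, rng):
        """With purely neuron-slicing structure the pipeline must return
        the PCA components of the neuron unfolding up to sign."""
        truth = random_model(rng, (12, 9, 7), (2, 0, 0))
        x = reconstruct(truth)
        opt = hierarchical_optimize(x, (2, 0, 0), FitConfig(seed=1), n_seeds=2)
        U, S, Vt = np.linalg.svd(x.reshape(12, 63), full_matrices=False)
        for r, c in enumerate(opt.model.components_of("neuron")):
            cos = abs(np.dot(c.loading, U[:, r]))
            assert cos > 1 - 1e-4

    def test_nonnegative_skips_gauge_stages(self, rng):
        truth = random_model(rng, (8, 7, 6), (1, 1, 0), nonnegative=True)
        x = reconstruct(truth)
        opt = hierarchical_optimize(
            x, (1, 1, 0), FitConfig(seed=2, nonnegative=True,
                                    n_blocks=2, iters_per_block=40),
            n_seeds=1,
        )
        assert "skipped" in str(opt.provenance["stage2"])
        assert opt.model.nonnegative
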