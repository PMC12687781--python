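"""Flow-matching core: decomposition, paths, velocities, losses, integration."""

import numpy as np
import pytest

from cfmdock.flow import (
    DecomposedState,
    PriorSpec,
    cfm_loss,
    conditional_velocity,
    decompose,
    denoiser_to_velocity,
    draw_provenance,
    euler_step,
    integrate,
    integrate_batch,
    interpolate,
    make_time_grid,
    recompose,
    sample_prior,
)
from cfmdock.geometry import RigidTransform, sample_uniform_rotation, so3_log


@pytest.fixture(scope="module")
def prior(flex_library):
    return PriorSpec(flex_library=flex_library, flex_sampling_probs=(1.0, 0.0, 0.0))


@pytest.fixture(scope="module")
def x1(bound_complex):
    return decompose(bound_complex, bound_complex)


@pytest.fixture(scope="module")
def x0(bound_complex, prior):
    return sample_prior(bound_complex, prior, np.random.default_rng(1))


class TestDecomposition:
    def test_round_trip_identity(self, bound_complex, x1):
        back = recompose(x1, bound_complex)
        for a, b in zip(back.chains, bound_complex.chains):
            assert np.abs(a.coords - b.coords).max() < 1e-6

    def test_reference_decomposition(self, bound_complex, x1):
        assert np.allclose(x1.c, bound_complex.ligand.ca.mean(axis=0), atol=1e-9)
        for a, b in zip(x1.internal, bound_complex.chains):
            assert np.abs(a - b.coords).max() < 1e-9

    def test_planted_rigid_ligand_move(self, bound_complex, x1):
        rng = np.random.default_rng(2)
        Q = sample_uniform_rotation(rng)
        v = rng.normal(size=3) * 8
        moved = bound_complex.copy()
        moved.chains[1] = moved.chains[1].transformed(RigidTransform(Q, v))
        st = decompose(moved, bound_complex)
        # internal coordinates remove the rigid motion entirely
        assert np.abs(st.internal[1] - x1.internal[1]).max() < 1e-6
        # and the pose change is exactly the planted rotation
        assert np.allclose(st.R @ x1.R.T, Q, atol=1e-9)
        back = recompose(st, bound_complex)
        assert np.abs(back.ligand.coords - moved.ligand.coords).max() < 1e-6

    def test_role_mismatch_rejected(self, bound_complex):
        other = bound_complex.copy()
        other.receptor_index, other.ligand_index = 1, 0
        with pytest.raises(ValueError):
            decompose(other, bound_complex)


class TestPrior:
    def test_translation_moments(self, bound_complex, flex_library):
        prior = PriorSpec(
            sigma_tr=15.0, flex_library=flex_library, flex_sampling_probs=(1.0, 0, 0)
        )
        rng = np.random.default_rng(3)
        center = bound_complex.receptor.ca.mean(axis=0)
        draws = np.array(
            [sample_prior(bound_complex, prior, rng).c - center for _ in range(10_000)]
        )
        assert np.abs(draws.std(axis=0) / 15.0 - 1.0).max() < 0.03
        assert np.abs(draws.mean(axis=0)).max() < 3 * 15.0 / np.sqrt(10_000) * 3

    def test_holo_only_probs_reproduce_holo(self, bound_complex, prior, x1):
        st = sample_prior(bound_complex, prior, np.random.default_rng(4))
        assert st.provenance == ("holo", "holo")
        for a, b in zip(st.internal, x1.internal):
            assert np.abs(a - b).max() < 1e-6

    def test_seed_determinism(self, bound_complex, prior):
        a = sample_prior(bound_complex, prior, np.random.default_rng(5))
        b = sample_prior(bound_complex, prior, np.random.default_rng(5))
        assert np.array_equal(a.c, b.c) and np.array_equal(a.R, b.R)

    def test_missing_class_falls_back_to_holo(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="cfmdock.flow"):
            tag = draw_provenance((0.0, 1.0, 0.0), {"holo": ["x"]}, np.random.default_rng(0))
        assert tag == "holo"
        assert any("falling back" in r.message for r in caplog.records)

    def test_rotation_is_haar_spread(self, bound_complex, prior):
        rng = np.random.default_rng(6)
        traces = [
            np.trace(sample_prior(bound_complex, prior, rng).R) for _ in range(2000)
        ]
        assert abs(np.mean(traces)) < 0.1  # E[tr R] = 0 under Haar


class TestPathAndVelocity:
    def test_endpoints(self, x0, x1):
        for t, ref in ((0.0, x0), (1.0, x1)):
            xt = interpolate(x0, x1, t)
            assert np.abs(xt.c - ref.c).max() < 1e-9
            assert np.abs(xt.R - ref.R).max() < 1e-9
            for a, b in zip(xt.internal, ref.internal):
                assert np.abs(a - b).max() < 1e-9

    def test_linear_midpoint(self, x0, x1):
        a = x0.copy()
        b = x1.copy()
        a.c = np.zeros(3)
        b.c = np.array([10.0, 0.0, 0.0])
        assert np.allclose(interpolate(a, b, 0.5).c, [5.0, 0.0, 0.0])

    def test_translation_velocity_constant_along_path(self, x0, x1):
        for t in (0.1, 0.5, 0.9):
            v = conditional_velocity(interpolate(x0, x1, t), x1, t)
            assert np.allclose(v.dc, x1.c - x0.c, atol=1e-8)

    def test_finite_difference_matches_velocity(self, x0, x1):
        t, h = 0.4, 1e-5
        xt = interpolate(x0, x1, t)
        xth = interpolate(x0, x1, t + h)
        v = conditional_velocity(xt, x1, t)
        fd_c = (xth.c - xt.c) / h
        assert np.abs(fd_c - v.dc).max() < 1e-4
        fd_rot = so3_log(xt.R.T @ xth.R) / h
        assert np.abs(fd_rot - v.omega).max() < 1e-4
        for a, b, d in zip(xt.internal, xth.internal, v.dinternal):
            assert np.abs((b - a) / h - d).max() < 1e-4

    def test_velocity_zero_at_target(self, x1):
        v = conditional_velocity(x1, x1, 0.5)
        assert np.abs(v.dc).max() < 1e-9 and np.abs(v.omega).max() < 1e-9

    def test_velocity_grows_near_t1(self, x0, x1):
        v_a = conditional_velocity(x0, x1, 0.0)
        v_b = conditional_velocity(x0, x1, 0.5)
        assert np.linalg.norm(v_b.dc) == pytest.approx(2 * np.linalg.norm(v_a.dc), rel=1e-9)
        with pytest.raises(ValueError):
            conditional_velocity(x0, x1, 1.0)

    def test_denoiser_velocity_substitution(self, x0, x1):
        xt = interpolate(x0, x1, 0.3)
        v_cond = conditional_velocity(xt, x1, 0.3)
        v_den = denoiser_to_velocity(x1, xt, 0.3)
        assert np.allclose(v_cond.dc, v_den.dc) and np.allclose(v_cond.omega, v_den.omega)
        v_zero = denoiser_to_velocity(xt, xt, 0.3)
        assert np.abs(v_zero.dc).max() < 1e-9

    def test_scaling_at_half_time(self, x0, x1):
        xt = interpolate(x0, x1, 0.5)
        v = denoiser_to_velocity(x1, xt, 0.5)
        assert np.allclose(v.dc, 2.0 * (x1.c - xt.c), atol=1e-9)

    def test_euler_equals_reinterpolation(self, x0, x1):
        # the two inference code paths must agree to 1e-9
        for t, tn in ((0.0, 0.1), (0.3, 0.4), (0.8, 0.9)):
            xt = interpolate(x0, x1, t)
            a = interpolate(xt, x1, (tn - t) / (1.0 - t))
            b = euler_step(xt, denoiser_to_velocity(x1, xt, t), tn - t)
            assert np.abs(a.c - b.c).max() < 1e-9
            assert np.abs(a.R - b.R).max() < 1e-9
            for p, q in zip(a.internal, b.internal):
                assert np.abs(p - q).max() < 1e-9


class TestCfmLoss:
    def test_zero_at_target(self, bound_complex):
        coords = np.concatenate([c.coords for c in bound_complex.chains])
        rec_len = len(bound_complex.receptor)
        assert cfm_loss(coords, coords, rec_len, 0.5, "weighted_mse") == 0.0
        assert cfm_loss(coords, coords, rec_len, 0.5, "fape_like") < 1e-9

    def test_weighted_mse_weight(self, bound_complex):
        coords = np.concatenate([c.coords for c in bound_complex.chains])
        shifted = coords + 1.0  # unit error in every coordinate
        rec_len = len(bound_complex.receptor)
        # unit squared error per coordinate, weight (1-t)^-2 = 4
        assert cfm_loss(shifted, coords, rec_len, 0.5, "weighted_mse") == pytest.approx(4.0)

    def test_fape_invariant_to_joint_rigid_transform(self, bound_complex):
        rng = np.random.default_rng(7)
        coords = np.concatenate([c.coords for c in bound_complex.chains])
        noisy = coords + rng.normal(0, 1.0, coords.shape)
        rec_len = len(bound_complex.receptor)
        base = cfm_loss(noisy, coords, rec_len, 0.2, "fape_like")
        T = RigidTransform(sample_uniform_rotation(rng), rng.normal(size=3) * 10)
        moved = noisy @ T.rotation.T + T.translation
        assert cfm_loss(moved, coords, rec_len, 0.2, "fape_like") == pytest.approx(
            base, abs=1e-6
        )

    def test_singular_t_rejected(self, bound_complex):
        coords = np.concatenate([c.coords for c in bound_complex.chains])
        with pytest.raises(ValueError):
            cfm_loss(coords, coords, len(bound_complex.receptor), 1.0, "weighted_mse")


class TestTimeGrid:
    def test_ten_steps(self):
        grid = make_time_grid(10)
        assert np.allclose(grid, np.arange(10) / 10)

    def test_single_step(self):
        assert np.array_equal(make_time_grid(1), [0.0])

    def test_strictly_increasing_below_one(self):
        grid = make_time_grid(7)
        assert np.all(np.diff(grid) > 0) and grid.max() < 1.0

    def test_zero_steps_rejected(self):
        with pytest.raises(ValueError):
            make_time_grid(0)


class TestIntegration:
    def test_oracle_denoiser_exact_for_any_k(self, bound_complex, prior, x1):
        for K in (1, 3, 10):
            _, final = integrate(
                lambda s, t: x1,
                bound_complex,
                prior,
                make_time_grid(K),
                np.random.default_rng(8),
            )
            rmsd = np.sqrt(np.mean(np.sum((final.ligand.ca - bound_complex.ligand.ca) ** 2, axis=1)))
            assert rmsd < 1e-6

    def test_identity_denoiser_is_fixed_point(self, bound_complex, prior):
        traj, final = integrate(
            lambda s, t: s,
            bound_complex,
            prior,
            make_time_grid(5),
            np.random.default_rng(9),
        )
        start = recompose(traj[0], bound_complex)
        assert np.abs(final.ligand.coords - start.ligand.coords).max() < 1e-9

    def test_trajectory_records_every_step(self, bound_complex, prior, x1):
        traj, _ = integrate(
            lambda s, t: x1, bound_complex, prior, make_time_grid(10), np.random.default_rng(10)
        )
        assert len(traj) == 11  # prior + one state per grid point
        assert traj[0].t == 0.0 and traj[-1].t == 1.0

    def test_nan_denoiser_aborts_with_step_index(self, bound_complex, prior, x1):
        def bad(s, t):
            out = x1.copy()
            out.c = np.array([np.nan, 0.0, 0.0])
            return out

        with pytest.raises(FloatingPointError, match="step 0"):
            integrate(bad, bound_complex, prior, make_time_grid(4), np.random.default_rng(11))

    def test_equivariance_under_reference_transform(self, bound_complex, flex_library, x1):
        rng = np.random.default_rng(12)
        Q = sample_uniform_rotation(rng)
        T = RigidTransform(Q, rng.normal(size=3) * 5)
        moved = bound_complex.transformed(T)
        moved_lib = {
            role: {tag: [c.transformed(T) for c in confs] for tag, confs in lib.items()}
            for role, lib in flex_library.items()
        }
        prior_a = PriorSpec(flex_library=flex_library, flex_sampling_probs=(1, 0, 0))
        prior_b = PriorSpec(flex_library=moved_lib, flex_sampling_probs=(1, 0, 0))
        x1_b = decompose(moved, moved)
        _, f_a = integrate(
            lambda s, t: x1, bound_complex, prior_a, make_time_grid(5), np.random.default_rng(13)
        )
        _, f_b = integrate(
            lambda s, t: x1_b, moved, prior_b, make_time_grid(5), np.random.default_rng(13)
        )
        for ca, cb in zip(f_a.transformed(T).chains, f_b.chains):
            assert np.abs(ca.coords - cb.coords).max() < 1e-8

    def test_oracle_collapse_over_seeds(self, bound_complex, prior, x1):
        # with the oracle denoiser the output distribution collapses to x1
        grid = make_time_grid(10)
        for seed in range(50):
            _, final = integrate(
                lambda s, t: x1, bound_complex, prior, grid, np.random.default_rng(seed)
            )
            rmsd = np.sqrt(np.mean(np.sum((final.ligand.ca - bound_complex.ligand.ca) ** 2, axis=1)))
            assert rmsd < 1e-6

    def test_batch_matches_sequential(self, bound_complex, prior, x1):
        grid = make_time_grid(4)

        def batched(states, t):
            return [x1 for _ in states]

        _, finals = integrate_batch(
            batched, bound_complex, prior, grid, np.random.default_rng(14), n_samples=3
        )
        assert len(finals) == 3
        for f in finals:
            assert np.abs(f.ligand.ca - bound_complex.ligand.ca).max() < 1e-6

    def test_bad_grid_rejected(self, bound_complex, prior):
        for grid in ([0.0, 0.0, 0.5], [0.1, 0.5], [0.0, 1.0]):
            with pytest.raises(ValueError):
                integrate_batch(
                    lambda s, t: s,
                    bound_complex,
                    prior,
                    np.array(grid),
                    np.random.default_rng(0),
                    1,
                )
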