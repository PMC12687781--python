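"""Docking-module network: shapes, conditioning, identity init, equivariance."""

import numpy as np
import pytest

from cfmdock import nn
from cfmdock.denoiser import (
    AdaLN,
    ConfidenceReadout,
    DenoiserConfig,
    DockingModel,
    PairDenoiser,
    adaln_modulate,
    gram_schmidt_rotation,
    load_checkpoint,
    save_checkpoint,
)
from cfmdock.features import assemble_features
from cfmdock.geometry import (
    RigidTransform,
    backbone_frames,
    is_rotation_matrix,
    sample_uniform_rotation,
)
from cfmdock.nn import Tensor


@pytest.fixture(scope="module")
def tiny_cfg():
    return DenoiserConfig(channels=16, n_blocks=2, n_heads=2, embedder_blocks=1, seed=0)


@pytest.fixture(scope="module")
def tiny_model(tiny_cfg):
    return DockingModel(tiny_cfg)


def _random_features(cfg, B=1, L=12, seed=0):
    rng = np.random.default_rng(seed)
    nf = rng.normal(size=(B, L, L, cfg.noisy_in_channels)).astype(np.float32)
    cf = rng.normal(size=(B, L, L, cfg.cond_in_channels)).astype(np.float32)
    return nf, cf


class TestEmbeddersAndDenoiser:
    def test_output_shapes(self, tiny_model, tiny_cfg):
        for L in (8, 12):
            nf, cf = _random_features(tiny_cfg, L=L)
            pair = tiny_model.forward_pair(nf, cf)
            assert pair.shape == (1, L, L, tiny_cfg.channels)

    def test_deterministic(self, tiny_model, tiny_cfg):
        nf, cf = _random_features(tiny_cfg, seed=1)
        a = tiny_model.forward_pair(nf, cf).data
        b = tiny_model.forward_pair(nf, cf).data
        assert np.array_equal(a, b)

    def test_default_block_count(self):
        cfg = DenoiserConfig()
        assert cfg.n_blocks == 4
        assert cfg.embedder_blocks == 2
        assert len(PairDenoiser(cfg, np.random.default_rng(0)).blocks) == 4

    def test_time_conditioning_changes_embedding(self, tiny_model, tiny_cfg):
        _, cf = _random_features(tiny_cfg, seed=2)
        cf2 = cf.copy()
        cf2[..., -8:] += 0.5  # perturb time-embedding channels only
        a = tiny_model.conditioning_embedder(Tensor(cf)).data
        b = tiny_model.conditioning_embedder(Tensor(cf2)).data
        assert not np.allclose(a, b)

    def test_conditioning_reaches_denoiser_once_modulation_is_nonzero(self, tiny_cfg):
        model = DockingModel(tiny_cfg)
        rng = np.random.default_rng(42)
        for block in model.pair_denoiser.blocks:
            for ada in (block.ada_att_start, block.ada_att_end, block.ada_trans):
                ada.lin_scale.weight.data = rng.normal(
                    0, 0.2, ada.lin_scale.weight.data.shape
                ).astype(np.float32)
        nf, cf = _random_features(tiny_cfg, seed=2)
        cf2 = cf.copy()
        cf2[..., -8:] += 0.5
        assert not np.allclose(
            model.forward_pair(nf, cf).data, model.forward_pair(nf, cf2).data
        )

    def test_zero_features_finite(self, tiny_model, tiny_cfg):
        L = 10
        nf = np.zeros((1, L, L, tiny_cfg.noisy_in_channels), np.float32)
        cf = np.zeros((1, L, L, tiny_cfg.cond_in_channels), np.float32)
        assert np.all(np.isfinite(tiny_model.forward_pair(nf, cf).data))

    def test_residue_permutation_equivariance(self, tiny_cfg):
        # with no positional channels, permuting residues permutes rows/cols
        model = DockingModel(tiny_cfg)
        L = 9
        rng = np.random.default_rng(3)
        nf, cf = _random_features(tiny_cfg, L=L, seed=4)
        perm = rng.permutation(L)
        out = model.forward_pair(nf, cf).data[0]
        out_p = model.forward_pair(
            nf[:, perm][:, :, perm], cf[:, perm][:, :, perm]
        ).data[0]
        assert np.allclose(out_p, out[perm][:, perm], atol=1e-4)

    def test_gradient_reaches_every_parameter(self, tiny_cfg):
        model = DockingModel(
            DenoiserConfig(
                channels=16,
                n_blocks=1,
                n_heads=2,
                embedder_blocks=1,
                readout_mode="rigid_deform",
                seed=5,
            )
        )
        # move readout heads off their zero init so their inputs get gradients
        rng = np.random.default_rng(0)
        for _, p in model.named_parameters():
            if not np.any(p.data):
                p.data = rng.normal(0, 0.05, p.data.shape).astype(np.float32)
        L, Lr = 10, 5
        nf, cf = _random_features(model.cfg, L=L, seed=6)
        F = np.tile(np.eye(3, dtype=np.float32), (1, L - Lr, 1, 1))
        body_ca = rng.normal(size=(1, L - Lr, 3))
        lig_ca = body_ca + rng.normal(size=3)
        uv = rng.normal(size=(1, L - Lr, Lr, 3))
        pair = model.forward_pair(nf, cf)
        out = model.pose_readout(pair, Lr, F, lig_ca, body_ca, uv)
        conf = model.confidence_readout(pair, Lr)
        loss = (
            (out["c_hat"] * out["c_hat"]).sum()
            + (out["R_hat"] * Tensor(np.ones((1, 3, 3), np.float32))).sum()
            + (out["deform"] * out["deform"]).sum()
            + conf.sum()
        )
        model.zero_grad()
        loss.backward()
        dead = [
            name
            for name, p in model.named_parameters()
            if p.grad is None or not np.any(p.grad)
        ]
        assert dead == []


class TestAdaLN:
    def test_identity_modulation_reduces_to_layernorm(self):
        rng = np.random.default_rng(7)
        x = Tensor(rng.normal(2.0, 3.0, size=(1, 4, 4, 8)).astype(np.float32))
        zero = Tensor(np.zeros((1, 4, 4, 8), np.float32))
        y = adaln_modulate(x, zero, zero).data
        assert np.allclose(y.mean(axis=-1), 0.0, atol=1e-5)
        assert np.allclose(y.std(axis=-1), 1.0, atol=1e-2)

    def test_gate_zero_gives_residual_passthrough(self):
        rng = np.random.default_rng(8)
        ada = AdaLN(8, rng)
        ada.lin_gate.bias.data = np.full(8, -30.0, dtype=np.float32)
        cond = Tensor(rng.normal(size=(1, 3, 3, 8)).astype(np.float32))
        x = Tensor(rng.normal(size=(1, 3, 3, 8)).astype(np.float32))
        update = ada.gate(cond) * Tensor(rng.normal(size=(1, 3, 3, 8)).astype(np.float32))
        assert np.abs((x + update).data - x.data).max() < 1e-5

    def test_finite_across_seeds(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ada = AdaLN(8, rng)
            x = Tensor(rng.normal(size=(1, 4, 4, 8)).astype(np.float32))
            cond = Tensor(rng.normal(size=(1, 4, 4, 8)).astype(np.float32))
            out = ada.gate(cond) * ada.modulate(x, cond)
            assert np.all(np.isfinite(out.data))


class TestGramSchmidt:
    def test_valid_rotations_from_random_vectors(self):
        rng = np.random.default_rng(9)
        u1 = Tensor(rng.normal(size=(20, 3)).astype(np.float32))
        u2 = Tensor(rng.normal(size=(20, 3)).astype(np.float32))
        R = gram_schmidt_rotation(u1, u2).data
        for r in R:
            assert is_rotation_matrix(r, tol=1e-4)

    def test_recovers_rotation_from_its_columns(self):
        rng = np.random.default_rng(10)
        Q = sample_uniform_rotation(rng)
        R = gram_schmidt_rotation(
            Tensor(Q[:, 0].astype(np.float32)), Tensor(Q[:, 1].astype(np.float32))
        ).data
        assert np.allclose(R, Q, atol=1e-6)


class TestReadouts:
    @staticmethod
    def _readout_inputs(conf):
        from cfmdock.flow import _body_coords, decompose
        from cfmdock.residues import ATOM_INDEX

        lig = conf.ligand
        F = backbone_frames(lig.n, lig.ca, lig.c).rotations[None]
        state = decompose(conf, conf)
        body = _body_coords(state.internal[conf.ligand_index], conf.ligand)
        noisy, _ = assemble_features(conf, t=0.0)
        Lr = len(conf.receptor)
        d = np.linalg.norm(conf.receptor.ca[None] - lig.ca[:, None], axis=-1)
        uv = (noisy.unit_vectors[Lr:, :Lr, :] * d[:, :, None])[None]
        return (F, lig.ca[None], body[:, ATOM_INDEX["CA"], :][None], uv), state

    def test_identity_initialization(self, bound_complex):
        model = DockingModel(DenoiserConfig(channels=16, n_blocks=1, n_heads=2, embedder_blocks=1))
        noisy, cond = assemble_features(bound_complex, t=0.4)
        (F, lig_ca, body_ca, uv), state = self._readout_inputs(bound_complex)
        pair = model.forward_pair(noisy.concat()[None], cond.concat()[None])
        out = model.pose_readout(pair, len(bound_complex.receptor), F, lig_ca, body_ca, uv)
        assert np.allclose(out["c_hat"].data[0], state.c, atol=1e-5)
        assert np.allclose(out["R_hat"].data[0], state.R, atol=1e-5)

    def test_rotation_output_valid_for_random_weights(self, bound_complex):
        model = DockingModel(DenoiserConfig(channels=16, n_blocks=1, n_heads=2, embedder_blocks=1, seed=3))
        rng = np.random.default_rng(12)
        for p in model.pose_readout.parameters():
            p.data = rng.normal(0, 0.5, p.data.shape).astype(np.float32)
        noisy, cond = assemble_features(bound_complex, t=0.2)
        (F, lig_ca, body_ca, uv), _ = self._readout_inputs(bound_complex)
        pair = model.forward_pair(noisy.concat()[None], cond.concat()[None])
        out = model.pose_readout(pair, len(bound_complex.receptor), F, lig_ca, body_ca, uv)
        assert is_rotation_matrix(out["R_hat"].data[0], tol=1e-4)

    def test_pose_equivariance(self, bound_complex):
        # rigid transform of the input complex -> identically transformed pose
        model = DockingModel(DenoiserConfig(channels=16, n_blocks=1, n_heads=2, embedder_blocks=1, seed=4))
        rng = np.random.default_rng(13)
        for p in model.pose_readout.parameters():
            p.data = rng.normal(0, 0.3, p.data.shape).astype(np.float32)
        Q = sample_uniform_rotation(rng)
        v = rng.normal(size=3) * 10
        T = RigidTransform(Q, v)
        moved = bound_complex.transformed(T)

        def predict(conf, body_ca):
            noisy, cond = assemble_features(conf, t=0.3)
            lig = conf.ligand
            Lr = len(conf.receptor)
            d = np.linalg.norm(conf.receptor.ca[None] - lig.ca[:, None], axis=-1)
            uv = (noisy.unit_vectors[Lr:, :Lr, :] * d[:, :, None])[None]
            F = backbone_frames(lig.n, lig.ca, lig.c).rotations[None]
            pair = model.forward_pair(noisy.concat()[None], cond.concat()[None])
            return model.pose_readout(pair, Lr, F, lig.ca[None], body_ca, uv)

        (_, _, body_ca, _), _ = self._readout_inputs(bound_complex)
        out_a = predict(bound_complex, body_ca)
        # the body conformation is invariant, so the same body_ca applies
        out_b = predict(moved, body_ca)
        assert np.allclose(out_b["c_hat"].data[0], Q @ out_a["c_hat"].data[0] + v, atol=1e-3)
        assert np.allclose(out_b["R_hat"].data[0], Q @ out_a["R_hat"].data[0], atol=1e-3)

    def test_confidence_in_unit_interval(self, tiny_cfg, bound_complex):
        rng = np.random.default_rng(15)
        conf_head = ConfidenceReadout(tiny_cfg, rng)
        for p in conf_head.parameters():
            p.data = rng.normal(0, 1.0, p.data.shape).astype(np.float32)
        for seed in range(10):
            pair = Tensor(
                np.random.default_rng(seed).normal(size=(2, 12, 12, 16)).astype(np.float32)
            )
            out = conf_head(pair, 6).data
            assert out.shape == (2,)
            assert np.all((out >= 0) & (out <= 1))

    def test_deform_mode_bounded(self, bound_complex):
        cfg = DenoiserConfig(
            channels=16, n_blocks=1, n_heads=2, embedder_blocks=1,
            readout_mode="rigid_deform", max_deform=3.0, seed=6,
        )
        model = DockingModel(cfg)
        rng = np.random.default_rng(16)
        for p in model.pose_readout.parameters():
            p.data = rng.normal(0, 2.0, p.data.shape).astype(np.float32)
        noisy, cond = assemble_features(bound_complex, t=0.1)
        (F, lig_ca, body_ca, uv), _ = self._readout_inputs(bound_complex)
        pair = model.forward_pair(noisy.concat()[None], cond.concat()[None])
        out = model.pose_readout(pair, len(bound_complex.receptor), F, lig_ca, body_ca, uv)
        norms = np.linalg.norm(out["deform"].data[0], axis=-1)
        assert np.all(norms <= 3.0 * np.sqrt(3) + 1e-5)


class TestCheckpoint:
    def test_round_trip(self, tiny_model, tiny_cfg, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_model, path, extra={"stage": "test"})
        loaded, extra = load_checkpoint(path)
        assert extra["stage"] == "test"
        nf, cf = _random_features(tiny_cfg, seed=17)
        assert np.array_equal(
            tiny_model.forward_pair(nf, cf).data, loaded.forward_pair(nf, cf).data
        )
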