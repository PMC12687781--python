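"""The docking-module network at toy scale.

Mirrors the architecture of the docking module that replaces the template
stack in an AlphaFold-style model: a *structure embedder* and a
*conditioning embedder* (linear embedding + a two-block pair stack each),
followed by a *pair denoiser* of four AdaLN-conditioned blocks combining
triangle multiplicative updates, triangle attention and pair transitions.

Because the surrounding folding trunk is out of scope, the denoised pair
representation is closed back to coordinates by a light-weight
:class:`PoseReadout` (translation + two-vector Gram-Schmidt rotation update
expressed in per-residue local frames, hence rigid-equivariant) and ranked
by a :class:`ConfidenceReadout` trained to regress the DockQ of the model's
own predictions — the stand-in for ipTM in the sample-and-rank scheme.

All stacks operate on a leading sample axis: pair tensors are
``(B, L, L, C)``.  Sample-and-rank inference batches its prior draws into a
single forward pass, which is what makes 20-sample docking tractable on one
CPU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import LayerNorm, Linear, Module, Parameter, Tensor, concat, einsum, layer_norm_op, softmax

__all__ = [
    "DenoiserConfig",
    "PairStackBlock",
    "DenoiserBlock",
    "StructureEmbedder",
    "ConditioningEmbedder",
    "PairDenoiser",
    "PoseReadout",
    "ConfidenceReadout",
    "DockingModel",
    "adaln_modulate",
    "gram_schmidt_rotation",
    "save_checkpoint",
    "load_checkpoint",
]

#: Levi-Civita symbol used for differentiable cross products
_EPS_LC = np.zeros((3, 3, 3), dtype=np.float32)
for _i, _j, _k, _s in [(0, 1, 2, 1), (1, 2, 0, 1), (2, 0, 1, 1), (0, 2, 1, -1), (2, 1, 0, -1), (1, 0, 2, -1)]:
    _EPS_LC[_i, _j, _k] = _s


@dataclass(frozen=True)
class DenoiserConfig:
    """Hyperparameters of the docking module.

    ``channels`` is the pair-representation width, ``n_blocks`` the depth of
    the conditioned pair denoiser (four by default), ``embedder_blocks`` the
    depth of the two embedder pair stacks.  ``readout_mode`` selects whether
    internal coordinates are copied through ("rigid") or additionally moved
    by a bounded learned per-residue deformation ("rigid_deform").
    """

    channels: int = 32
    n_blocks: int = 4
    n_heads: int = 4
    embedder_blocks: int = 2
    transition_factor: int = 4
    readout_mode: str = "rigid"  # or "rigid_deform"
    confidence_head: bool = True
    max_deform: float = 3.0  # Angstrom bound on per-residue deformation
    translation_scale: float = 10.0  # Angstrom scale of the translation head
    noisy_in_channels: int = 85
    cond_in_channels: int = 101
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.channels % self.n_heads != 0:
            raise ValueError("channels must be divisible by n_heads")
        if self.readout_mode not in ("rigid", "rigid_deform"):
            raise ValueError(f"unknown readout mode {self.readout_mode!r}")


def _cross_batch(a: Tensor, b: Tensor) -> Tensor:
    """Row-wise cross product of (B, 3) tensors."""
    eps = Tensor(_EPS_LC)
    return einsum("sik,sk->si", einsum("ijk,sj->sik", eps, a), b)


def _normalize_rows(v: Tensor) -> Tensor:
    return v * ((v * v).sum(axis=-1, keepdims=True) + 1e-12).pow(-0.5)


def gram_schmidt_rotation(u1: Tensor, u2: Tensor) -> Tensor:
    """Orthonormalize two (B, 3) vector batches into (B, 3, 3) rotations.

    Columns are (e1, e2, e1 x e2); feeding the first two columns of a
    rotation matrix returns that matrix, which is what makes the
    zero-initialized readout an exact identity.
    """
    single = u1.ndim == 1
    if single:
        u1 = u1.reshape(1, 3)
        u2 = u2.reshape(1, 3)
    e1 = _normalize_rows(u1)
    w = u2 - e1 * (e1 * u2).sum(axis=-1, keepdims=True)
    e2 = _normalize_rows(w)
    e3 = _cross_batch(e1, e2)
    B = e1.shape[0]
    R = concat([e1.reshape(B, 3, 1), e2.reshape(B, 3, 1), e3.reshape(B, 3, 1)], axis=2)
    return R.reshape(3, 3) if single else R


# ---------------------------------------------------------------------------
# triangle operations
# ---------------------------------------------------------------------------


class TriangleMultiplicative(Module):
    """Triangle multiplicative update, outgoing or incoming edges."""

    def __init__(self, c: int, direction: str, rng: np.random.Generator):
        if direction not in ("out", "in"):
            raise ValueError("direction must be 'out' or 'in'")
        self.direction = direction
        self.ln_in = LayerNorm(c)
        self.lin_a = Linear(c, c, rng=rng)
        self.lin_ag = Linear(c, c, rng=rng)
        self.lin_b = Linear(c, c, rng=rng)
        self.lin_bg = Linear(c, c, rng=rng)
        self.ln_out = LayerNorm(c)
        self.lin_g = Linear(c, c, rng=rng)
        self.lin_o = Linear(c, c, rng=rng)

    def __call__(self, z: Tensor) -> Tensor:
        zl = self.ln_in(z)
        a = self.lin_ag(zl).sigmoid() * self.lin_a(zl)
        b = self.lin_bg(zl).sigmoid() * self.lin_b(zl)
        if self.direction == "out":
            g = einsum("sikc,sjkc->sijc", a, b)
        else:
            g = einsum("skic,skjc->sijc", a, b)
        return self.lin_g(zl).sigmoid() * self.lin_o(self.ln_out(g))


class TriangleAttention(Module):
    """Triangle self-attention around the starting or ending node."""

    def __init__(self, c: int, n_heads: int, node: str, rng: np.random.Generator):
        if node not in ("start", "end"):
            raise ValueError("node must be 'start' or 'end'")
        self.node = node
        self.h = n_heads
        self.d = c // n_heads
        self.ln = LayerNorm(c)
        self.lin_q = Linear(c, c, bias=False, rng=rng)
        self.lin_k = Linear(c, c, bias=False, rng=rng)
        self.lin_v = Linear(c, c, bias=False, rng=rng)
        self.lin_bias = Linear(c, n_heads, bias=False, rng=rng)
        self.lin_g = Linear(c, c, rng=rng)
        self.lin_o = Linear(c, c, rng=rng)

    def __call__(self, z: Tensor) -> Tensor:
        if self.node == "end":
            z = z.transpose(0, 2, 1, 3)
        B, L = z.shape[0], z.shape[1]
        zl = self.ln(z)
        h, d = self.h, self.d
        q = self.lin_q(zl).reshape(B, L, L, h, d)
        k = self.lin_k(zl).reshape(B, L, L, h, d)
        v = self.lin_v(zl).reshape(B, L, L, h, d)
        logits = einsum("sijhd,sikhd->shijk", q, k) * (1.0 / np.sqrt(d))
        bias = self.lin_bias(zl).transpose(0, 3, 1, 2).reshape(B, h, 1, L, L)
        att = softmax(logits + bias, axis=-1)
        o = einsum("shijk,sikhd->sijhd", att, v)
        o = o * self.lin_g(zl).sigmoid().reshape(B, L, L, h, d)
        out = self.lin_o(o.reshape(B, L, L, h * d))
        if self.node == "end":
            out = out.transpose(0, 2, 1, 3)
        return out


class Transition(Module):
    """Two-layer pointwise MLP with expansion."""

    def __init__(self, c: int, factor: int, rng: np.random.Generator):
        self.ln = LayerNorm(c)
        self.lin1 = Linear(c, factor * c, rng=rng)
        self.lin2 = Linear(factor * c, c, rng=rng)

    def __call__(self, z: Tensor) -> Tensor:
        return self.lin2(self.lin1(self.ln(z)).relu())


# ---------------------------------------------------------------------------
# AdaLN conditioning
# ---------------------------------------------------------------------------


def adaln_modulate(x: Tensor, scale: Tensor, shift: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer-normalize ``x`` (no affine) and modulate: ``ln(x)*(1+scale)+shift``."""
    y = layer_norm_op(x, eps=eps)
    return y * (1.0 + scale) + shift


class AdaLN(Module):
    """Conditioned layer norm: scale/shift and residual gate from the conditioning.

    Scale and shift linears are zero-initialized so the layer starts as a
    plain (unconditioned) layer norm; the gate starts near 1 so signal flows.
    """

    def __init__(self, c: int, rng: np.random.Generator, gate_bias: float = 2.0):
        self.ln_cond = LayerNorm(c)
        self.lin_scale = Linear(c, c, init="zero", rng=rng)
        self.lin_shift = Linear(c, c, init="zero", rng=rng)
        self.lin_gate = Linear(c, c, init="zero", rng=rng, bias_init=gate_bias)

    def modulate(self, x: Tensor, cond: Tensor) -> Tensor:
        cl = self.ln_cond(cond)
        return adaln_modulate(x, self.lin_scale(cl), self.lin_shift(cl))

    def gate(self, cond: Tensor) -> Tensor:
        return self.lin_gate(self.ln_cond(cond)).sigmoid()


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------


class PairStackBlock(Module):
    """Unconditioned pair-stack block (used by the embedders)."""

    def __init__(self, cfg: DenoiserConfig, rng: np.random.Generator):
        c = cfg.channels
        self.tri_out = TriangleMultiplicative(c, "out", rng)
        self.tri_in = TriangleMultiplicative(c, "in", rng)
        self.att_start = TriangleAttention(c, cfg.n_heads, "start", rng)
        self.att_end = TriangleAttention(c, cfg.n_heads, "end", rng)
        self.transition = Transition(c, cfg.transition_factor, rng)

    def __call__(self, z: Tensor) -> Tensor:
        z = z + self.tri_out(z)
        z = z + self.tri_in(z)
        z = z + self.att_start(z)
        z = z + self.att_end(z)
        z = z + self.transition(z)
        return z


class DenoiserBlock(Module):
    """Conditioned pair-denoiser block.

    Triangle multiplicative updates run unconditioned; the triangle
    attention and pair transition steps are AdaLN-modulated before and
    residual-gated after, with all modulation predicted from the pair
    conditioning.
    """

    def __init__(self, cfg: DenoiserConfig, rng: np.random.Generator):
        c = cfg.channels
        self.tri_out = TriangleMultiplicative(c, "out", rng)
        self.tri_in = TriangleMultiplicative(c, "in", rng)
        self.ada_att_start = AdaLN(c, rng)
        self.att_start = TriangleAttention(c, cfg.n_heads, "start", rng)
        self.ada_att_end = AdaLN(c, rng)
        self.att_end = TriangleAttention(c, cfg.n_heads, "end", rng)
        self.ada_trans = AdaLN(c, rng)
        self.transition = Transition(c, cfg.transition_factor, rng)

    def __call__(self, z: Tensor, cond: Tensor) -> Tensor:
        z = z + self.tri_out(z)
        z = z + self.tri_in(z)
        z = z + self.ada_att_start.gate(cond) * self.att_start(self.ada_att_start.modulate(z, cond))
        z = z + self.ada_att_end.gate(cond) * self.att_end(self.ada_att_end.modulate(z, cond))
        z = z + self.ada_trans.gate(cond) * self.transition(self.ada_trans.modulate(z, cond))
        return z


class StructureEmbedder(Module):
    """Linear embedding of the concatenated pair features + pair stack."""

    def __init__(self, cfg: DenoiserConfig, in_channels: int, rng: np.random.Generator):
        self.proj = Linear(in_channels, cfg.channels, rng=rng)
        self.blocks = [PairStackBlock(cfg, rng) for _ in range(cfg.embedder_blocks)]

    def __call__(self, features: Tensor) -> Tensor:
        z = self.proj(features)
        for i, block in enumerate(self.blocks):
            z = block(z)
            if not np.all(np.isfinite(z.data)):
                raise FloatingPointError(f"non-finite pair representation after embedder block {i}")
        return z


class ConditioningEmbedder(StructureEmbedder):
    """Same stack as the structure embedder, fed features + time embedding."""


class PairDenoiser(Module):
    """The conditioned denoising stack (default: four blocks)."""

    def __init__(self, cfg: DenoiserConfig, rng: np.random.Generator):
        self.blocks = [DenoiserBlock(cfg, rng) for _ in range(cfg.n_blocks)]

    def __call__(self, noisy: Tensor, cond: Tensor) -> Tensor:
        z = noisy
        for i, block in enumerate(self.blocks):
            z = block(z, cond)
            if not np.all(np.isfinite(z.data)):
                raise FloatingPointError(f"non-finite pair representation after denoiser block {i}")
        return z


# ---------------------------------------------------------------------------
# readouts
# ---------------------------------------------------------------------------


class PoseReadout(Module):
    """Close the pair representation back to a rigid pose prediction.

    For each ligand residue i, the inter-chain row (i, j in receptor) is
    pooled and mapped to a displacement in residue i's local backbone frame
    — "where should I move" — giving a predicted CA cloud.  The translation
    update is the cloud centroid; the rotation update fits the ligand body
    conformation onto the cloud by an (un-orthonormalized) least-squares
    frame, polished with the two-vector Gram-Schmidt parametrization.

    Local-frame displacements make the whole readout rigid-equivariant, and
    the zero-initialized head leaves the cloud at the input pose, so an
    untrained network predicts x_hat1 = x_t exactly.
    """

    def __init__(self, cfg: DenoiserConfig, rng: np.random.Generator):
        c = cfg.channels
        self.ln = LayerNorm(c)
        self.lin_tr = Linear(c, 3, init="zero", rng=rng)
        self.lin_point = Linear(c, 1, init="zero", rng=rng)
        self.tr_scale = cfg.translation_scale
        self.mode = cfg.readout_mode
        self.max_deform = cfg.max_deform
        if self.mode == "rigid_deform":
            self.lin_deform = Linear(c, 3, init="zero", rng=rng)

    def __call__(
        self,
        pair: Tensor,
        receptor_len: int,
        ligand_frames: np.ndarray,
        ligand_ca: np.ndarray,
        body_ca: np.ndarray,
        local_displacements: np.ndarray,
    ) -> dict:
        """Pose prediction from a (B, L, L, C) pair representation.

        ``ligand_frames`` is (B, L_lig, 3, 3) current-pose backbone frames,
        ``ligand_ca`` (B, L_lig, 3) the current ligand CA positions,
        ``body_ca`` (B, L_lig, 3) the CA positions of the ligand's body-
        frame (internal) conformation and ``local_displacements`` (B, L_lig,
        L_rec, 3) the CA displacement vectors toward each receptor residue,
        expressed in the ligand residues' local frames.  Returns Tensors
        ``c_hat`` (B, 3), ``R_hat`` (B, 3, 3) and, in deform mode,
        ``deform`` (B, L_lig, 3) global per-residue displacements.
        """
        L = pair.shape[1]
        lig = self.ln(pair[:, receptor_len:L, 0:receptor_len, :])  # (B, Ll, Lr, C)
        pooled = lig.mean(axis=2)  # (B, Ll, C)
        F = Tensor(np.ascontiguousarray(ligand_frames, dtype=np.float32))

        # per-residue displacement from two heads: a free local-frame vector
        # scaled to Angstrom range, plus per-pair scalar coefficients on the
        # raw displacement vectors toward the receptor residues.  The second
        # head makes "move residue i to an affine combination of receptor
        # positions" — the natural form of a docking target — linear in the
        # coefficients, so the readout does not have to synthesize
        # distance-identity products before it can start learning
        disp = Tensor(np.ascontiguousarray(local_displacements, dtype=np.float32))
        coef = self.lin_point(lig)  # (B, Ll, Lr, 1)
        pointed = (coef * disp).mean(axis=2)  # (B, Ll, 3)
        v_local = self.lin_tr(pooled) * self.tr_scale + pointed
        cloud = Tensor(np.asarray(ligand_ca, dtype=np.float32)) + einsum(
            "siab,sib->sia", F, v_local
        )
        c_hat = cloud.mean(axis=1)  # (B, 3)

        # least-squares frame fit of the body conformation onto the cloud:
        # with A the centered body CAs and V = A (A^T A)^-1, the matrix
        # sum_i (cloud_i - c_hat) V_i^T equals the rotation exactly whenever
        # cloud = R A + c, and Gram-Schmidt re-orthonormalizes otherwise
        A = np.asarray(body_ca, dtype=np.float64)
        A = A - A.mean(axis=1, keepdims=True)
        V = np.einsum("sia,sab->sib", A, np.linalg.inv(np.einsum("sia,sib->sab", A, A)))
        M = einsum("sia,sib->sab", cloud - c_hat.reshape(-1, 1, 3), Tensor(V.astype(np.float32)))
        R_hat = gram_schmidt_rotation(M[:, :, 0], M[:, :, 1])

        out = {"c_hat": c_hat, "R_hat": R_hat, "cloud": cloud, "deform": None}
        if self.mode == "rigid_deform":
            d_local = (self.lin_deform(pooled)).tanh() * self.max_deform
            out["deform"] = einsum("siab,sib->sia", F, d_local)
        return out


class ConfidenceReadout(Module):
    """Pooled inter-chain channels -> sigmoid scalar per sample."""

    def __init__(self, cfg: DenoiserConfig, rng: np.random.Generator):
        c = cfg.channels
        self.ln = LayerNorm(c)
        self.lin1 = Linear(c, c, rng=rng)
        self.lin2 = Linear(c, 1, init="zero", rng=rng)

    def __call__(self, pair: Tensor, receptor_len: int) -> Tensor:
        L = pair.shape[1]
        upper = self.ln(pair[:, 0:receptor_len, receptor_len:L, :]).mean(axis=(1, 2))
        lower = self.ln(pair[:, receptor_len:L, 0:receptor_len, :]).mean(axis=(1, 2))
        h = (self.lin1(upper + lower)).relu()
        return self.lin2(h).sigmoid().reshape((pair.shape[0],))


# ---------------------------------------------------------------------------
# full model + checkpointing
# ---------------------------------------------------------------------------


class DockingModel(Module):
    """Structure/conditioning embedders + pair denoiser + readouts."""

    def __init__(self, cfg: DenoiserConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.structure_embedder = StructureEmbedder(cfg, cfg.noisy_in_channels, rng)
        self.conditioning_embedder = ConditioningEmbedder(cfg, cfg.cond_in_channels, rng)
        self.pair_denoiser = PairDenoiser(cfg, rng)
        self.pose_readout = PoseReadout(cfg, rng)
        self.confidence_readout = ConfidenceReadout(cfg, rng) if cfg.confidence_head else None

    def forward_pair(self, noisy_features: np.ndarray, cond_features: np.ndarray) -> Tensor:
        """(B, L, L, C_in) feature stacks -> (B, L, L, C) denoised pair rep."""
        if noisy_features.ndim != 4 or cond_features.ndim != 4:
            raise ValueError("forward_pair expects batched (B, L, L, C) features")
        noisy = self.structure_embedder(Tensor(noisy_features))
        cond = self.conditioning_embedder(Tensor(cond_features))
        return self.pair_denoiser(noisy, cond)

    def parameter_groups(self) -> dict[str, list[Parameter]]:
        """Named parameter groups used for per-stage trainable scopes."""
        groups = {
            "embedders": self.structure_embedder.parameters()
            + self.conditioning_embedder.parameters(),
            "denoiser": self.pair_denoiser.parameters(),
            "pose_readout": self.pose_readout.parameters(),
        }
        if self.confidence_readout is not None:
            groups["confidence"] = self.confidence_readout.parameters()
        return groups


def save_checkpoint(model: DockingModel, path: str | Path, extra: dict | None = None) -> None:
    """Weights + config (+ provenance extras) in a single .npz file."""
    path = Path(path)
    meta = {"config": asdict(model.cfg), "extra": extra or {}}
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[DockingModel, dict]:
    data = np.load(Path(path), allow_pickle=False)
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg = DenoiserConfig(**meta["config"])
    model = DockingModel(cfg)
    model.load_state_dict(
        {k[len("param/"):]: v for k, v in data.items() if k.startswith("param/")}
    )
    return model, meta.get("extra", {})
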