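"""Staged conditional-flow-matching training.

Training follows the three-stage schedule: stage one uses holo monomer
inputs only and trains the docking module; the later stages mix holo, apo
and predicted monomer conformers with probabilities 20%/40%/40% and widen
the trainable scope (full fine-tuning, including the confidence head, in
stage three).  Each step samples t uniformly below 1, draws a prior state
(monomer provenance by the stage probabilities), forms x_t on the
conditional OT path, predicts x_hat1 and minimizes the structure loss
(FAPE-like by default, or the 1/(1-t)^2-weighted MSE), plus a confidence
regression loss against the DockQ of the model's own prediction when the
confidence head is in scope.

Everything is deterministic given (seed, config, manifest) in
single-threaded numpy.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .denoiser import DenoiserConfig, DockingModel, save_checkpoint
from .evaluation import dockq
from .features import assemble_features
from .flow import (
    DecomposedState,
    PriorSpec,
    _body_coords,
    decompose,
    interpolate,
    recompose,
    sample_prior,
)
from .geometry import backbone_frames
from .nn import Adam, Tensor, einsum
from .residues import ATOM_INDEX
from .structio import ChainStructure, ComplexConformation, read_chain_pdb, read_pdb
from .toygen import load_manifest

logger = logging.getLogger(__name__)

#: training-time ceiling on t (avoids the (1-t)^-2 blow-up)
T_CEILING = 0.99

__all__ = [
    "StageConfig",
    "TrainConfig",
    "ComplexRecord",
    "load_dataset",
    "training_step",
    "run_stages",
]


@dataclass(frozen=True)
class StageConfig:
    """One training stage: length, trainable scope, monomer sampling."""

    steps: int
    trainable: tuple[str, ...]
    flex_sampling_probs: tuple[float, float, float]
    name: str = "stage"

    def __post_init__(self) -> None:
        if self.steps <= 0:
            raise ValueError("stage steps must be positive")
        if abs(sum(self.flex_sampling_probs) - 1.0) > 1e-9:
            raise ValueError("stage sampling probabilities must sum to 1")


def default_stages(
    steps: tuple[int, int, int] = (300, 300, 200)
) -> tuple[StageConfig, ...]:
    """The three-stage schedule: holo-only docking module, mixed-provenance
    fine-tuning, then full-parameter fine-tuning (confidence head included)."""
    docking = ("embedders", "denoiser", "pose_readout")
    return (
        StageConfig(steps[0], docking, (1.0, 0.0, 0.0), name="stage1_holo"),
        StageConfig(steps[1], docking, (0.2, 0.4, 0.4), name="stage2_mixed"),
        StageConfig(
            steps[2],
            docking + ("confidence",),
            (0.2, 0.4, 0.4),
            name="stage3_full",
        ),
    )


@dataclass
class TrainConfig:
    """Training hyperparameters; stage list defaults to the three-stage schedule."""

    stages: tuple[StageConfig, ...] = field(default_factory=default_stages)
    batch_size: int = 1
    draws_per_record: int = 1
    learning_rate: float = 1e-3
    seed: int = 0
    loss_mode: str = "fape_like"
    sigma_tr: float = 15.0
    confidence_loss_weight: float = 1.0
    confidence_lr_scale: float = 4.0  # the small sigmoid head trains on a
    # weak scalar signal and needs a faster rate than the pair stack
    use_seq_embed: bool = True

    def __post_init__(self) -> None:
        if self.loss_mode not in ("fape_like", "weighted_mse"):
            raise ValueError(f"unknown loss mode {self.loss_mode!r}")
        if self.batch_size < 1 or self.draws_per_record < 1:
            raise ValueError("batch_size and draws_per_record must be >= 1")


@dataclass
class ComplexRecord:
    """One training complex: the bound structure plus its conformer library."""

    record_id: str
    bound: ComplexConformation
    flex_library: dict  # role -> provenance tag -> list[ChainStructure]


def load_dataset(manifest_path: str | Path) -> list[ComplexRecord]:
    """Read every complex of a toy-dataset manifest into memory."""
    records = []
    for rec in load_manifest(manifest_path):
        bound = read_pdb(rec["bound"])
        library: dict = {}
        for role in ("receptor", "ligand"):
            entry = rec["chains"][role]
            library[role] = {
                tag: [read_chain_pdb(entry[tag])] for tag in ("holo", "apo", "predicted")
            }
        records.append(ComplexRecord(rec["id"], bound, library))
    if not records:
        raise ValueError(f"empty manifest {manifest_path}")
    return records


# ---------------------------------------------------------------------------
# differentiable structure loss
# ---------------------------------------------------------------------------


def _local_interchain_points(coords: np.ndarray, receptor_len: int) -> np.ndarray:
    """(L, L, 3) other-chain CA positions in each residue's backbone frame (numpy)."""
    n_idx, ca_idx, c_idx = ATOM_INDEX["N"], ATOM_INDEX["CA"], ATOM_INDEX["C"]
    frames = backbone_frames(coords[:, n_idx], coords[:, ca_idx], coords[:, c_idx])
    ca = coords[:, ca_idx]
    diff = ca[None, :, :] - ca[:, None, :]
    return np.einsum("iab,ija->ijb", frames.rotations, diff)


def pose_loss(
    c_hat: Tensor,
    R_hat: Tensor,
    deform: Tensor | None,
    cloud: Tensor | None,
    xt: DecomposedState,
    x1_coords: np.ndarray,
    reference: ComplexConformation,
    t: float,
    mode: str,
    clamp: float = 10.0,
) -> Tensor:
    """Differentiable structure loss of a predicted pose against x1.

    The predicted complex keeps the receptor and the ligand internal
    conformation of ``xt`` (plus the optional bounded deformation) and
    repositions the ligand by (R_hat, c_hat).  ``x1_coords`` is the (L,5,3)
    coordinate block of the bound complex in the anchored frame.
    """
    rec_len = len(reference.receptor)
    lig_ref = reference.ligand
    body = _body_coords(xt.internal[reference.ligand_index], lig_ref)  # (Ll, 5, 3)
    Ll = body.shape[0]
    body_t = Tensor(body.reshape(-1, 3).astype(np.float32))
    pred_lig = einsum("nk,ak->na", body_t, R_hat) + c_hat  # (Ll*5, 3)
    if deform is not None:
        pred_lig = (pred_lig.reshape(Ll, 5, 3) + deform.reshape(Ll, 1, 3)).reshape(Ll * 5, 3)
    rec_coords = xt.internal[reference.receptor_index]  # constant

    if mode == "weighted_mse":
        true_lig = x1_coords[rec_len:].reshape(-1, 3).astype(np.float32)
        true_rec = x1_coords[:rec_len].reshape(-1, 3)
        diff = pred_lig - Tensor(true_lig)
        sq_lig = (diff * diff).sum()
        sq_rec = float(((rec_coords.reshape(-1, 3) - true_rec) ** 2).sum())
        n_total = x1_coords.size
        return (sq_lig + sq_rec) * (1.0 / n_total / (1.0 - t) ** 2)

    if mode != "fape_like":
        raise ValueError(f"unknown loss mode {mode!r}")

    # --- FAPE-like, in Tensor ops ---------------------------------------
    n_idx, ca_idx, c_idx = ATOM_INDEX["N"], ATOM_INDEX["CA"], ATOM_INDEX["C"]
    pred_lig_res = pred_lig.reshape(Ll, 5, 3)
    pred_lig_ca = pred_lig_res[:, ca_idx, :]  # (Ll, 3) Tensor

    rec_frames = backbone_frames(
        rec_coords[:, n_idx], rec_coords[:, ca_idx], rec_coords[:, c_idx]
    )
    body_frames = backbone_frames(body[:, n_idx], body[:, ca_idx], body[:, c_idx])

    # receptor frames (constant) looking at predicted ligand CAs
    Fr = Tensor(rec_frames.rotations.astype(np.float32))  # (Lr, 3, 3)
    diff_r = pred_lig_ca.reshape(1, Ll, 3) - Tensor(
        rec_frames.origins[:, None, :].astype(np.float32)
    )
    local_r = einsum("iab,ija->ijb", Fr, diff_r)  # (Lr, Ll, 3)

    # ligand frames (rotate with R_hat) looking at constant receptor CAs
    Fl = einsum("ak,ikb->iab", R_hat, Tensor(body_frames.rotations.astype(np.float32)))
    rec_ca = Tensor(rec_coords[:, ca_idx, :].astype(np.float32))
    diff_l = rec_ca.reshape(1, rec_len, 3) - pred_lig_ca.reshape(Ll, 1, 3)
    local_l = einsum("iab,ija->ijb", Fl, diff_l)  # (Ll, Lr, 3)

    true_local = _local_interchain_points(x1_coords, rec_len)
    true_r = Tensor(true_local[:rec_len, rec_len:, :].astype(np.float32))
    true_l = Tensor(true_local[rec_len:, :rec_len, :].astype(np.float32))

    def clamped_mean(pred: Tensor, true: Tensor) -> Tensor:
        d = pred - true
        err = ((d * d).sum(axis=-1) + 1e-8).pow(0.5)
        return err.clip_max(clamp).mean()

    fape = (clamped_mean(local_r, true_r) + clamped_mean(local_l, true_l)) * 0.5

    # auxiliary unclamped coordinate term on the predicted per-residue CA
    # cloud (the raw readout output, before the rigid fit): the clamp
    # starves gradients when the pose is far off (every local error
    # saturates), while this term keeps pulling each residue toward its
    # bound position from any distance — and it trains translation and
    # rotation at equal gradient scale, which a loss routed through the
    # fitted pose does not
    true_lig_ca = Tensor(x1_coords[rec_len:, ca_idx, :].astype(np.float32))
    target = cloud if cloud is not None else pred_lig_ca
    d_ca = target - true_lig_ca
    aux = (d_ca * d_ca).sum(axis=-1).mean() * (1.0 / clamp)
    return fape + aux


# ---------------------------------------------------------------------------
# training step and stage loop
# ---------------------------------------------------------------------------


def training_step(
    model: DockingModel,
    record: ComplexRecord,
    cfg: TrainConfig,
    stage: StageConfig,
    rng: np.random.Generator,
    train_confidence: bool | None = None,
    n_draws: int = 1,
) -> tuple[float, dict]:
    """One CFM step on one complex; computes the loss and backpropagates.

    ``n_draws`` independent (t, x0) draws of the same complex are stacked
    into one batched forward/backward pass — cheaper per sample than
    separate steps.  Returns (mean loss value, diagnostics of the last
    draw, with provenance pooled over draws).  The optimizer update is the
    caller's job, so gradient accumulation over records works naturally.
    """
    bound = record.bound
    reference = bound
    x1 = decompose(bound, reference)
    x1_coords = np.concatenate([c.coords for c in recompose(x1, reference).chains])
    rec_len = len(reference.receptor)

    prior = PriorSpec(
        sigma_tr=cfg.sigma_tr,
        flex_library=record.flex_library,
        flex_sampling_probs=stage.flex_sampling_probs,
    )

    draws = []
    for _ in range(n_draws):
        t = float(rng.uniform(0.0, T_CEILING))
        x0 = sample_prior(reference, prior, rng)
        draws.append((t, x0, interpolate(x0, x1, t)))

    nf_l, cf_l, F_l, ca_l, body_l, uv_l = [], [], [], [], [], []
    for t, _, xt in draws:
        conf_xt = recompose(xt, reference)
        noisy, cond = assemble_features(conf_xt, t, use_seq_embed=cfg.use_seq_embed)
        nf_l.append(noisy.concat())
        cf_l.append(cond.concat())
        lig = conf_xt.ligand
        F_l.append(backbone_frames(lig.n, lig.ca, lig.c).rotations.astype(np.float32))
        ca_l.append(lig.ca)
        body_l.append(_body_coords(xt.internal[reference.ligand_index], reference.ligand))
        d = np.linalg.norm(conf_xt.receptor.ca[None, :, :] - lig.ca[:, None, :], axis=-1)
        uv_l.append(noisy.unit_vectors[rec_len:, :rec_len, :] * d[:, :, None])

    bodies = np.stack(body_l)
    pair = model.forward_pair(np.stack(nf_l), np.stack(cf_l))
    out = model.pose_readout(
        pair,
        rec_len,
        np.stack(F_l),
        np.stack(ca_l),
        bodies[:, :, ATOM_INDEX["CA"], :],
        np.stack(uv_l),
    )

    loss = None
    for i, (t, x0, xt) in enumerate(draws):
        c_hat = out["c_hat"][i]
        R_hat = out["R_hat"][i]
        deform = None if out["deform"] is None else out["deform"][i]
        cloud = out["cloud"][i]
        term = pose_loss(
            c_hat, R_hat, deform, cloud, xt, x1_coords, reference, t, cfg.loss_mode
        )
        loss = term if loss is None else loss + term
    loss = loss * (1.0 / n_draws)

    t, x0, xt = draws[-1]
    diagnostics = {
        "t": t,
        "provenance": tuple(tag for _, d0, _ in draws for tag in d0.provenance),
        "structure_loss": float(loss.data),
    }

    if train_confidence is None:
        train_confidence = "confidence" in stage.trainable
    if train_confidence and model.confidence_readout is not None:
        conf = model.confidence_readout(pair, rec_len)
        conf_loss = None
        targets = []
        for i, (_, _, xt_i) in enumerate(draws):
            pred_state = DecomposedState(
                c=out["c_hat"].data[i].astype(float),
                R=_nearest_rotation(out["R_hat"].data[i].astype(float)),
                internal=[a.copy() for a in xt_i.internal],
                t=1.0,
            )
            target = dockq(recompose(pred_state, reference), bound).dockq
            targets.append(target)
            d_conf = conf[i] - target
            term = d_conf * d_conf
            conf_loss = term if conf_loss is None else conf_loss + term
        conf_loss = conf_loss * (1.0 / n_draws)
        loss = loss + cfg.confidence_loss_weight * conf_loss
        diagnostics["confidence_target"] = targets[-1]
        diagnostics["confidence_loss"] = float(conf_loss.data)

    if not np.isfinite(loss.data):
        raise FloatingPointError(
            f"non-finite loss on record {record.record_id} (t={t:.3f})"
        )
    loss.backward()
    return float(loss.data), diagnostics


def _nearest_rotation(R: np.ndarray) -> np.ndarray:
    U, _, Vt = np.linalg.svd(R)
    D = np.diag([1.0, 1.0, float(np.sign(np.linalg.det(U @ Vt)))])
    return U @ D @ Vt


def run_stages(
    manifest_path: str | Path,
    cfg: TrainConfig,
    out_dir: str | Path,
    model: DockingModel | None = None,
    denoiser_cfg: DenoiserConfig | None = None,
) -> dict:
    """Run the staged training schedule over a toy-dataset manifest.

    Writes one checkpoint per stage plus a JSON-lines loss log and returns
    a summary dict (checkpoint paths, per-stage loss curves, provenance
    draw counts).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset = load_dataset(manifest_path)
    if model is None:
        model = DockingModel(denoiser_cfg or DenoiserConfig(seed=cfg.seed))

    groups = model.parameter_groups()
    unknown = {
        name for stage in cfg.stages for name in stage.trainable if name not in groups
    }
    if unknown:
        raise ValueError(f"unknown trainable scopes: {sorted(unknown)}")

    log_path = out_dir / "loss_log.jsonl"
    summary: dict = {"checkpoints": [], "stages": [], "log": str(log_path)}
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xC0FFEE)))

    with open(log_path, "w") as log:
        for stage_idx, stage in enumerate(cfg.stages):
            base = [
                p
                for name in stage.trainable
                if name != "confidence"
                for p in groups[name]
            ]
            optimizers = [Adam(base, lr=cfg.learning_rate)]
            if "confidence" in stage.trainable:
                optimizers.append(
                    Adam(
                        groups["confidence"],
                        lr=cfg.learning_rate * cfg.confidence_lr_scale,
                    )
                )
            losses = []
            prov_counts = {tag: 0 for tag in ("holo", "apo", "predicted")}
            for step in range(stage.steps):
                for optimizer in optimizers:
                    optimizer.zero_grad()
                batch_loss = 0.0
                for _ in range(cfg.batch_size):
                    record = dataset[int(rng.integers(len(dataset)))]
                    value, diag = training_step(
                        model, record, cfg, stage, rng, n_draws=cfg.draws_per_record
                    )
                    batch_loss += value
                    for tag in diag["provenance"]:
                        prov_counts[tag] += 1
                for optimizer in optimizers:
                    optimizer.step()
                batch_loss /= cfg.batch_size
                losses.append(batch_loss)
                log.write(
                    json.dumps(
                        {
                            "stage": stage.name,
                            "step": step,
                            "loss": batch_loss,
                            "t": diag["t"],
                            "provenance": list(diag["provenance"]),
                        }
                    )
                    + "\n"
                )
            ckpt = out_dir / f"checkpoint_{stage_idx + 1}_{stage.name}.npz"
            save_checkpoint(
                model,
                ckpt,
                extra={
                    "stage": stage.name,
                    "seed": cfg.seed,
                    "train_config": _config_dict(cfg),
                },
            )
            summary["checkpoints"].append(str(ckpt))
            summary["stages"].append(
                {
                    "name": stage.name,
                    "losses": losses,
                    "provenance_counts": prov_counts,
                }
            )
            logger.info(
                "stage %s done: mean loss %.4f -> %.4f",
                stage.name,
                float(np.mean(losses[: max(1, len(losses) // 4)])),
                float(np.mean(losses[-max(1, len(losses) // 4):])),
            )
    return summary


def _config_dict(cfg: TrainConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["stages"] = [dataclasses.asdict(s) for s in cfg.stages]
    return d
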