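"""Sample-and-rank inference: the model as a flow denoiser.

:class:`ModelDenoiser` adapts a trained :class:`~cfmdock.denoiser.DockingModel`
to the batched denoiser interface of :func:`cfmdock.flow.integrate_batch`:
recompose the current states, featurize them, run one batched forward pass
and read the predicted poses back out.  :func:`sample_and_rank` draws many
prior samples, integrates them jointly over the time grid and ranks the
final structures by the confidence head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .denoiser import DockingModel
from .features import assemble_features
from .flow import (
    DecomposedState,
    PriorSpec,
    _body_coords,
    decompose,
    integrate_batch,
    make_time_grid,
    recompose,
)
from .geometry import backbone_frames
from .residues import ATOM_INDEX
from .structio import ComplexConformation

__all__ = ["ModelDenoiser", "RankedSample", "sample_and_rank"]


@dataclass
class RankedSample:
    conformation: ComplexConformation
    confidence: float
    sample_index: int


class ModelDenoiser:
    """Batched (states, t) -> x_hat1 callable backed by a DockingModel.

    Keeps the pair representation of its most recent forward pass so the
    confidence head can score the final integration step.
    """

    def __init__(
        self,
        model: DockingModel,
        reference: ComplexConformation,
        use_seq_embed: bool = True,
    ):
        if reference.receptor_index != 0 or reference.ligand_index != 1:
            raise ValueError("model inference expects receptor first, ligand second")
        self.model = model
        self.reference = reference
        self.receptor_len = len(reference.receptor)
        self.use_seq_embed = use_seq_embed
        self.last_pair = None

    def __call__(self, states: list[DecomposedState], t: float) -> list[DecomposedState]:
        confs = [recompose(s, self.reference) for s in states]
        noisy_list, cond_list, frame_list, ca_list, body_list, uv_list = [], [], [], [], [], []
        lig_idx = self.reference.ligand_index
        Lr = self.receptor_len
        for conf, state in zip(confs, states):
            noisy, cond = assemble_features(conf, t, use_seq_embed=self.use_seq_embed)
            noisy_list.append(noisy.concat())
            cond_list.append(cond.concat())
            lig = conf.ligand
            rec_ca = conf.receptor.ca
            d = np.linalg.norm(rec_ca[None, :, :] - lig.ca[:, None, :], axis=-1)
            uv_list.append(noisy.unit_vectors[Lr:, :Lr, :] * d[:, :, None])
            frame_list.append(
                backbone_frames(lig.n, lig.ca, lig.c).rotations.astype(np.float32)
            )
            ca_list.append(lig.ca)
            body = _body_coords(state.internal[lig_idx], self.reference.ligand)
            body_list.append(body[:, ATOM_INDEX["CA"], :])
        nf = np.stack(noisy_list)
        cf = np.stack(cond_list)
        F = np.stack(frame_list)
        lig_ca = np.stack(ca_list)
        body_ca = np.stack(body_list)
        uv = np.stack(uv_list)

        with nn.no_grad():
            pair = self.model.forward_pair(nf, cf)
            out = self.model.pose_readout(pair, Lr, F, lig_ca, body_ca, uv)
        self.last_pair = pair

        predictions = []
        for i, s in enumerate(states):
            x_hat = DecomposedState(
                c=out["c_hat"].data[i].astype(float),
                R=_project_rotation(out["R_hat"].data[i].astype(float)),
                internal=[a.copy() for a in s.internal],
                t=1.0,
                provenance=s.provenance,
            )
            if out["deform"] is not None:
                x_hat = _apply_deformation(
                    x_hat, out["deform"].data[i].astype(float), self.reference
                )
            predictions.append(x_hat)
        return predictions

    def confidences(self) -> np.ndarray:
        """Confidence of each sample in the most recent forward pass."""
        if self.model.confidence_readout is None:
            raise ValueError("model has no confidence head")
        if self.last_pair is None:
            raise ValueError("no forward pass has been run yet")
        with nn.no_grad():
            conf = self.model.confidence_readout(self.last_pair, self.receptor_len)
        return conf.data.astype(float)


def _project_rotation(R: np.ndarray) -> np.ndarray:
    """Re-project a float32 rotation onto SO(3) (polish numerical drift)."""
    U, _, Vt = np.linalg.svd(R)
    D = np.diag([1.0, 1.0, float(np.sign(np.linalg.det(U @ Vt)))])
    return U @ D @ Vt


def _apply_deformation(
    state: DecomposedState, deform: np.ndarray, reference: ComplexConformation
) -> DecomposedState:
    """Apply a per-residue global-frame displacement to the ligand and re-decompose."""
    conf = recompose(state, reference)
    lig = conf.ligand
    lig.coords = lig.coords + deform[:, None, :]
    new = decompose(conf, reference)
    new.t = state.t
    new.provenance = state.provenance
    return new


def sample_and_rank(
    model: DockingModel,
    reference: ComplexConformation,
    prior: PriorSpec,
    n_samples: int = 20,
    steps: int = 10,
    rng: np.random.Generator | None = None,
    use_seq_embed: bool = True,
) -> list[RankedSample]:
    """Draw ``n_samples`` prior samples, integrate over ``steps`` time steps
    and return the final structures sorted by confidence (descending,
    ties broken by sample index)."""
    rng = rng or np.random.default_rng(0)
    denoiser = ModelDenoiser(model, reference, use_seq_embed=use_seq_embed)
    grid = make_time_grid(steps)
    _, finals = integrate_batch(denoiser, reference, prior, grid, rng, n_samples)
    if model.confidence_readout is not None:
        confs = denoiser.confidences()
    else:
        confs = np.zeros(len(finals))
    ranked = [
        RankedSample(conformation=conf, confidence=float(c), sample_index=i)
        for i, (conf, c) in enumerate(zip(finals, confs))
    ]
    ranked.sort(key=lambda r: (-r.confidence, r.sample_index))
    return ranked
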