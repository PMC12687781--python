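"""Conditional flow matching over rigid-body pose and internal flexibility.

The state of a two-chain complex is decomposed, after a global RMSD
alignment anchored on the receptor, into

* ``c`` — the ligand center (CA centroid) in the receptor-anchored frame,
* ``R`` — the ligand orientation mapping its body-fixed conformation into
  the anchored frame, and
* per-chain *internal* coordinates obtained by aligning each chain
  individually onto its counterpart in the reference.

Conditional probability paths are the optimal-transport choices: linear in
``c`` and the internal coordinates, the SO(3) geodesic in ``R``; the
corresponding conditional velocity is ``(x1 - xt)/(1 - t)``.  The prior is
a wide Gaussian for translation, Haar-uniform for rotation, and a library
of unbound conformers (holo / apo-like / predicted-like) for internal
flexibility.

Equivariance convention: the prior's translation noise and rotation draw
are expressed in a frame attached to the receptor (a backbone frame of its
middle residue) and the ligand body frame is derived from the ligand's own
backbone, so rigidly moving the reference transforms every sampled
trajectory — and the final complex — identically.

Inference follows the denoise-and-reinterpolate scheme: at each grid time
the network predicts the fully denoised state x_hat1 and the state is
interpolated toward it by the fraction ``(t_next - t)/(1 - t)``; this is
algebraically identical to an Euler step with the reparametrized velocity
``(x_hat1 - x_t)/(1 - t)`` and the last grid point jumps directly to the
prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    backbone_frames,
    geodesic_rotation,
    kabsch_align,
    sample_uniform_rotation,
    so3_exp,
    so3_log,
)
from .residues import ATOM_INDEX
from .structio import ChainStructure, ComplexConformation

logger = logging.getLogger(__name__)

#: times are kept below 1 - EPS_T to avoid the 1/(1-t) singularity
EPS_T = 1e-6

#: FAPE-style loss clamp in Angstrom
FAPE_CLAMP = 10.0

PROVENANCE_ORDER = ("holo", "apo", "predicted")

__all__ = [
    "PriorSpec",
    "DecomposedState",
    "Velocity",
    "decompose",
    "recompose",
    "sample_prior",
    "draw_provenance",
    "interpolate",
    "conditional_velocity",
    "denoiser_to_velocity",
    "euler_step",
    "cfm_loss",
    "make_time_grid",
    "integrate",
    "integrate_batch",
]


@dataclass
class PriorSpec:
    """Prior distribution p0 = p0_rigid x p0_flex.

    ``sigma_tr`` is the std (Angstrom, per coordinate) of the Gaussian
    translation prior, centered on the receptor centroid.  ``flex_library``
    maps chain role ("receptor"/"ligand") to provenance-tagged lists of
    unbound conformers; ``flex_sampling_probs`` are the draw probabilities
    for (holo, apo, predicted), defaulting to the mixed-stage 20/40/40%.
    """

    sigma_tr: float = 15.0
    flex_library: dict = field(default_factory=dict)
    flex_sampling_probs: tuple[float, float, float] = (0.2, 0.4, 0.4)

    def __post_init__(self) -> None:
        if self.sigma_tr <= 0:
            raise ValueError("sigma_tr must be positive")
        if abs(sum(self.flex_sampling_probs) - 1.0) > 1e-9 or min(self.flex_sampling_probs) < 0:
            raise ValueError("flex_sampling_probs must be a probability vector")


@dataclass
class DecomposedState:
    """Receptor-anchored decomposition of a conformation.

    ``internal`` holds one (L, 5, 3) coordinate array per chain (in chain
    order), each individually aligned onto its counterpart in the
    reference.  ``provenance`` records which conformer class produced each
    chain's internal coordinates (diagnostic only).
    """

    c: np.ndarray  # (3,)
    R: np.ndarray  # (3, 3)
    internal: list[np.ndarray]
    t: float
    provenance: tuple[str, ...] = ()

    def copy(self) -> "DecomposedState":
        return DecomposedState(
            self.c.copy(), self.R.copy(), [x.copy() for x in self.internal], self.t, self.provenance
        )


@dataclass
class Velocity:
    """Tangent vector of the decomposed state."""

    dc: np.ndarray  # (3,)
    omega: np.ndarray  # (3,) body-frame rotation tangent
    dinternal: list[np.ndarray]


# ---------------------------------------------------------------------------
# anchoring helpers
# ---------------------------------------------------------------------------


def _anchor_frame(chain: ChainStructure) -> np.ndarray:
    """An equivariant orthonormal frame attached to a chain.

    Uses the backbone frame of the middle residue (first valid one from
    there); rotating the chain rotates this frame identically.
    """
    frames = backbone_frames(
        chain.n, chain.ca, chain.c, atom_valid=chain.atom_mask[:, [0, 1, 2]].all(axis=1)
    )
    order = np.argsort(np.abs(np.arange(len(chain)) - len(chain) // 2))
    for i in order:
        if frames.valid[i]:
            return frames.rotations[i]
    raise ValueError(f"chain {chain.chain_id} has no valid backbone frame")


def _body_coords(internal: np.ndarray, chain_template: ChainStructure) -> np.ndarray:
    """Ligand internal coordinates expressed in their own body frame.

    The body frame is the middle-residue backbone frame of the conformation
    itself, so the result is invariant under rigid motion of ``internal``.
    """
    tmp = ChainStructure(
        chain_template.chain_id,
        chain_template.sequence,
        internal,
        chain_template.atom_mask,
    )
    B = _anchor_frame(tmp)
    cen = internal[:, ATOM_INDEX["CA"], :].mean(axis=0)
    return (internal - cen) @ B  # == B.T applied to row vectors


def _align_chain(mobile: np.ndarray, mask: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Kabsch-align one chain's (L, 5, 3) coordinates onto a reference chain (CA atoms)."""
    transform, _ = kabsch_align(mobile[:, ATOM_INDEX["CA"], :], reference[:, ATOM_INDEX["CA"], :])
    return transform.apply(mobile)


def decompose(x: ComplexConformation, reference: ComplexConformation) -> DecomposedState:
    """Decompose ``x`` into (c, R, internal) in the frame of ``reference``.

    ``x`` is first Kabsch-aligned onto the reference receptor CA atoms; the
    ligand pose is then read off relative to the ligand's own body frame.
    """
    _check_topology(x, reference)
    rec_t, _ = kabsch_align(x.receptor.ca, reference.receptor.ca)
    anchored = x.transformed(rec_t)

    lig = anchored.ligand
    c = lig.ca.mean(axis=0)

    internal = []
    for chain, ref_chain in zip(anchored.chains, reference.chains):
        internal.append(_align_chain(chain.coords, chain.atom_mask, ref_chain.coords))

    lig_internal = internal[x.ligand_index]
    body = _body_coords(lig_internal, reference.ligand)
    rot_t, _ = kabsch_align(body[:, ATOM_INDEX["CA"], :], lig.ca - c)
    return DecomposedState(c=c, R=rot_t.rotation, internal=internal, t=1.0)


def recompose(state: DecomposedState, reference: ComplexConformation) -> ComplexConformation:
    """Rebuild a conformation from a decomposed state in the reference frame."""
    chains = []
    for k, ref_chain in enumerate(reference.chains):
        coords = state.internal[k]
        if k == reference.ligand_index:
            body = _body_coords(coords, ref_chain)
            coords = body @ state.R.T + state.c
        chains.append(
            ChainStructure(
                ref_chain.chain_id,
                ref_chain.sequence,
                coords,
                ref_chain.atom_mask.copy(),
                interface_mask=None
                if ref_chain.interface_mask is None
                else ref_chain.interface_mask.copy(),
            )
        )
    return ComplexConformation(
        chains,
        reference.receptor_index,
        reference.ligand_index,
        provenance="sampled",
    )


def _check_topology(a: ComplexConformation, b: ComplexConformation) -> None:
    if (
        a.receptor_index != b.receptor_index
        or a.ligand_index != b.ligand_index
        or [len(c) for c in a.chains] != [len(c) for c in b.chains]
    ):
        raise ValueError("conformations do not share chain lengths and roles")


# ---------------------------------------------------------------------------
# prior
# ---------------------------------------------------------------------------


def draw_provenance(
    probs: tuple[float, float, float],
    available: dict,
    rng: np.random.Generator,
) -> str:
    """Draw a provenance class (holo/apo/predicted) by the given probabilities.

    Falls back to holo (with a warning) when the drawn class has no
    conformer available.
    """
    u = rng.random()
    edges = np.cumsum(probs)
    tag = PROVENANCE_ORDER[int(np.searchsorted(edges, u, side="right"))]
    if not available.get(tag):
        if tag != "holo":
            logger.warning("no %s conformer available; falling back to holo", tag)
        tag = "holo"
    return tag


def sample_prior(
    x1: ComplexConformation,
    prior: PriorSpec,
    rng: np.random.Generator,
) -> DecomposedState:
    """Draw x0: Gaussian translation, Haar rotation, library conformers.

    The translation noise and the rotation draw are expressed in the
    receptor's anchor frame so the prior is exactly equivariant (same seed,
    rigidly moved reference -> rigidly moved draw).
    """
    W = _anchor_frame(x1.receptor)

    internal = []
    provenance = []
    roles = {x1.receptor_index: "receptor", x1.ligand_index: "ligand"}
    for k, ref_chain in enumerate(x1.chains):
        library = prior.flex_library.get(roles[k], {})
        tag = draw_provenance(prior.flex_sampling_probs, library, rng)
        options = library.get(tag) or []
        if options:
            pick = options[int(rng.integers(len(options)))]
            coords = _align_chain(pick.coords, pick.atom_mask, ref_chain.coords)
        else:
            coords = ref_chain.coords.copy()
        internal.append(coords)
        provenance.append(tag)

    c0 = x1.receptor.ca.mean(axis=0) + W @ (prior.sigma_tr * rng.standard_normal(3))
    R0 = W @ sample_uniform_rotation(rng)
    return DecomposedState(
        c=c0, R=R0, internal=internal, t=0.0, provenance=tuple(provenance)
    )


# ---------------------------------------------------------------------------
# paths and velocities
# ---------------------------------------------------------------------------


def interpolate(x0: DecomposedState, x1: DecomposedState, t: float) -> DecomposedState:
    """Point at ``t`` on the conditional OT path from x0 (t=0) to x1 (t=1)."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    if len(x0.internal) != len(x1.internal):
        raise ValueError("states do not share chain topology")
    c_t = (1.0 - t) * x0.c + t * x1.c
    R_t = geodesic_rotation(x0.R, x1.R, t)
    internal_t = [(1.0 - t) * a + t * b for a, b in zip(x0.internal, x1.internal)]
    return DecomposedState(c=c_t, R=R_t, internal=internal_t, t=t, provenance=x0.provenance)


def conditional_velocity(xt: DecomposedState, x1: DecomposedState, t: float) -> Velocity:
    """u_t(x_t | x_1) = (x_1 - x_t)/(1 - t); geodesic tangent for rotation."""
    if t >= 1.0 - EPS_T:
        raise ValueError("conditional velocity is singular at t >= 1")
    scale = 1.0 / (1.0 - t)
    dc = scale * (x1.c - xt.c)
    omega = scale * so3_log(xt.R.T @ x1.R)
    dinternal = [scale * (b - a) for a, b in zip(xt.internal, x1.internal)]
    return Velocity(dc=dc, omega=omega, dinternal=dinternal)


def denoiser_to_velocity(x1_hat: DecomposedState, xt: DecomposedState, t: float) -> Velocity:
    """Reparametrized velocity: the conditional formula with x_hat1 as target."""
    return conditional_velocity(xt, x1_hat, t)


def euler_step(xt: DecomposedState, v: Velocity, dt: float) -> DecomposedState:
    """x_{t+dt} from an explicit Euler step along the velocity field."""
    c = xt.c + dt * v.dc
    R = xt.R @ so3_exp(dt * v.omega)
    internal = [a + dt * d for a, d in zip(xt.internal, v.dinternal)]
    return DecomposedState(c=c, R=R, internal=internal, t=xt.t + dt, provenance=xt.provenance)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def _fape_like(
    pred: np.ndarray,
    true: np.ndarray,
    receptor_len: int,
    clamp: float = FAPE_CLAMP,
) -> float:
    """Clamped frame-aligned point error on the other chain's CA atoms.

    Frames are built from each residue's N/CA/C in both structures; for
    every frame the CA atoms of the *other* chain are expressed in local
    coordinates and compared.  Invariant to global rigid motion of either
    input.
    """
    n_idx, ca_idx, c_idx = ATOM_INDEX["N"], ATOM_INDEX["CA"], ATOM_INDEX["C"]
    L = pred.shape[0]

    def local_points(coords: np.ndarray) -> np.ndarray:
        frames = backbone_frames(coords[:, n_idx], coords[:, ca_idx], coords[:, c_idx])
        ca = coords[:, ca_idx]
        diff = ca[None, :, :] - frames.origins[:, None, :]
        return np.einsum("iab,ija->ijb", frames.rotations, diff)

    lp = local_points(pred)
    lt = local_points(true)
    other = np.zeros((L, L), dtype=bool)
    other[:receptor_len, receptor_len:] = True
    other[receptor_len:, :receptor_len] = True
    err = np.linalg.norm(lp - lt, axis=-1)
    return float(np.minimum(err[other], clamp).mean())


def cfm_loss(
    x1_hat: np.ndarray,
    x1: np.ndarray,
    receptor_len: int,
    t: float,
    mode: str = "weighted_mse",
) -> float:
    """Training loss between predicted and true coordinates.

    ``weighted_mse`` is the mean squared coordinate error scaled by
    ``1/(1-t)^2`` (the conditional-flow-matching weight after the
    denoiser reparametrization); ``fape_like`` is the clamped local-frame
    inter-chain CA error, unweighted by t.
    """
    x1_hat = np.asarray(x1_hat, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    if x1_hat.shape != x1.shape:
        raise ValueError("coordinate shapes do not match")
    if t >= 1.0 - EPS_T:
        raise ValueError("loss weight is singular at t >= 1")
    if mode == "weighted_mse":
        return float(np.mean((x1_hat - x1) ** 2) / (1.0 - t) ** 2)
    if mode == "fape_like":
        return _fape_like(x1_hat, x1, receptor_len)
    raise ValueError(f"unknown loss mode {mode!r}")


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def make_time_grid(K: int) -> np.ndarray:
    """Uniform grid {k/K : k = 0..K-1}; t=1 is reached by the final direct jump."""
    if K < 1:
        raise ValueError("K must be >= 1")
    return np.arange(K) / K


def _check_state_finite(x: DecomposedState, step: int) -> None:
    if not (
        np.all(np.isfinite(x.c))
        and np.all(np.isfinite(x.R))
        and all(np.all(np.isfinite(a)) for a in x.internal)
    ):
        raise FloatingPointError(f"denoiser produced non-finite state at step {step}")


def integrate_batch(
    denoiser,
    reference: ComplexConformation,
    prior: PriorSpec,
    grid: np.ndarray,
    rng: np.random.Generator,
    n_samples: int,
) -> tuple[list[list[DecomposedState]], list[ComplexConformation]]:
    """Denoise-and-reinterpolate integration of a batch of prior draws.

    ``denoiser`` maps (list of states, t) -> list of predicted x_hat1
    states.  Returns per-sample trajectories (including the final state)
    and the recomposed final conformations.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a strictly increasing 1-D array")
    if grid[0] != 0.0 or grid[-1] >= 1.0 - EPS_T:
        raise ValueError("grid must start at 0 and stay below 1")

    states = [sample_prior(reference, prior, rng) for _ in range(n_samples)]
    trajectories = [[s.copy()] for s in states]
    for k, t_k in enumerate(grid):
        predictions = denoiser(states, float(t_k))
        for x_hat in predictions:
            _check_state_finite(x_hat, k)
        if k + 1 < len(grid):
            s_frac = (grid[k + 1] - t_k) / (1.0 - t_k)
            states = [
                interpolate(x, x_hat, s_frac) for x, x_hat in zip(states, predictions)
            ]
            for x in states:
                x.t = float(grid[k + 1])
        else:
            states = [x_hat.copy() for x_hat in predictions]
            for x in states:
                x.t = 1.0
        for traj, x in zip(trajectories, states):
            traj.append(x.copy())
    finals = [recompose(x, reference) for x in states]
    return trajectories, finals


def integrate(
    denoiser,
    x1_ref_topology: ComplexConformation,
    prior: PriorSpec,
    grid: np.ndarray,
    rng: np.random.Generator,
) -> tuple[list[DecomposedState], ComplexConformation]:
    """Single-sample integration; ``denoiser`` maps (state, t) -> x_hat1."""

    def batched(states, t):
        return [denoiser(s, t) for s in states]

    trajectories, finals = integrate_batch(
        batched, x1_ref_topology, prior, grid, rng, n_samples=1
    )
    return trajectories[0], finals[0]
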