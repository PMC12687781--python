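"""Synthetic toy-complex generator.

Produces learnable bound two-chain complexes plus unbound conformers that
emulate the holo/apo/predicted provenance classes of real docking inputs:

* :func:`generate_chain` builds a self-avoiding smoothed random-walk CA
  trace with ideal-geometry N/C/O/CB atoms and plants a contiguous
  *interface patch* whose residue composition is biased toward a small set
  of "sticky" amino acids — the docking signal a model can learn from
  sequence alone.
* :func:`generate_bound_complex` rigidly poses the ligand so the two patches
  face each other with a minimum number of CB-CB contacts and no clashes.
* :func:`perturb_unbound` applies smoothed correlated backbone noise plus a
  hinge rotation, mimicking apo (small) and predicted (larger) deviations
  from the bound conformation.
* :func:`build_dataset` writes bound + monomer PDB files and a JSON-lines
  manifest; the whole dataset is a pure function of its seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import RigidTransform, so3_exp
from .residues import ATOM_INDEX, ONE_LETTER
from .structio import (
    ChainStructure,
    ComplexConformation,
    write_chain_pdb,
    write_pdb,
)

logger = logging.getLogger(__name__)

#: virtual CA-CA bond length (Angstrom)
BOND_LENGTH = 3.8

#: amino acids over-represented in interface patches (the learnable signal)
PATCH_RESIDUES = "WYRFH"
#: probability that a patch residue is drawn from PATCH_RESIDUES
PATCH_BIAS = 0.85

#: CB-CB distance defining a generator-side contact (distinct from the
#: 5 A any-atom evaluation contact so the generator cannot leak the metric)
GEN_CONTACT_CUTOFF = 8.0

__all__ = [
    "ToyComplexSpec",
    "FlexPerturbSpec",
    "generate_chain",
    "generate_bound_complex",
    "perturb_unbound",
    "build_dataset",
]


@dataclass(frozen=True)
class ToyComplexSpec:
    """Recipe for one bound toy complex."""

    receptor_length: int = 20
    ligand_length: int = 18
    interface_patch_size: int = 6
    contact_target: int = 6
    clash_floor: float = 2.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.receptor_length, self.ligand_length) < 8:
            raise ValueError("chain lengths must be at least 8 residues")
        if self.interface_patch_size > min(self.receptor_length, self.ligand_length):
            raise ValueError("interface patch cannot exceed the shorter chain")
        if self.clash_floor <= 0:
            raise ValueError("clash_floor must be positive")


@dataclass(frozen=True)
class FlexPerturbSpec:
    """Recipe for an unbound conformer derived from a bound chain.

    ``apo_like`` uses small backbone noise and hinge angles, emulating a
    resolved unbound conformation; ``predicted_like`` uses larger ones,
    emulating a model-predicted monomer.
    """

    mode: str = "apo_like"
    backbone_noise_sigma: float | None = None
    hinge_angle_sigma: float | None = None
    smoothing_window: int = 5
    seed: int = 0

    _DEFAULTS = {
        "apo_like": (0.4, 0.02),
        "predicted_like": (0.9, 0.12),
    }

    def __post_init__(self) -> None:
        if self.mode not in self._DEFAULTS:
            raise ValueError(f"unknown perturbation mode {self.mode!r}")
        sig, hinge = self._DEFAULTS[self.mode]
        if self.backbone_noise_sigma is None:
            object.__setattr__(self, "backbone_noise_sigma", sig)
        if self.hinge_angle_sigma is None:
            object.__setattr__(self, "hinge_angle_sigma", hinge)
        if self.backbone_noise_sigma < 0 or self.hinge_angle_sigma < 0:
            raise ValueError("perturbation sigmas must be non-negative")


# ---------------------------------------------------------------------------
# chain generation
# ---------------------------------------------------------------------------


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _ca_walk(length: int, rng: np.random.Generator, max_tries: int = 200) -> np.ndarray:
    """Persistent self-avoiding random walk with 3.8 A steps."""
    for _ in range(max_tries):
        pos = np.zeros((length, 3))
        d = _random_unit(rng)
        ok = True
        for i in range(1, length):
            d = d * 0.75 + 0.45 * _random_unit(rng)
            d /= np.linalg.norm(d)
            pos[i] = pos[i - 1] + BOND_LENGTH * d
            if i >= 2:
                if np.min(np.linalg.norm(pos[: i - 1] - pos[i], axis=1)) <= 3.0:
                    ok = False
                    break
        if ok:
            return pos
    raise RuntimeError(f"self-avoiding walk failed after {max_tries} attempts")


def _backbone_from_ca(ca: np.ndarray) -> np.ndarray:
    """Place ideal-geometry N, C, O, CB atoms from the local CA frame.

    Returns (L, 5, 3) in the package atom order.  The frame at residue i is
    built from the walk direction and the direction to the previous residue,
    so the placement is equivariant under rigid motion of the CA trace.
    """
    L = len(ca)
    coords = np.zeros((L, 5, 3))
    coords[:, ATOM_INDEX["CA"]] = ca
    for i in range(L):
        # interior residues: frame from the i-1 -> i+1 span; ends use the
        # single available bond
        if i == 0:
            fwd = ca[1] - ca[0]
        elif i == L - 1:
            fwd = ca[-1] - ca[-2]
        else:
            fwd = ca[i + 1] - ca[i - 1]
        a = fwd / np.linalg.norm(fwd)
        ref = ca[i - 1] - ca[i] if i > 0 else ca[i] - ca[i + 1]
        b = ref - (ref @ a) * a
        nb = np.linalg.norm(b)
        if nb < 1e-8:  # collinear fallback: any vector orthogonal to a
            tmp = np.array([1.0, 0.0, 0.0])
            if abs(a[0]) > 0.9:
                tmp = np.array([0.0, 1.0, 0.0])
            b = tmp - (tmp @ a) * a
            nb = np.linalg.norm(b)
        b /= nb
        c_ax = np.cross(a, b)
        n_pos = ca[i] + 1.46 * (-0.81 * a + 0.59 * b)
        c_pos = ca[i] + 1.52 * (0.81 * a + 0.59 * b)
        o_dir = 0.55 * a - 0.45 * b - 0.70 * c_ax
        o_pos = c_pos + 1.23 * o_dir / np.linalg.norm(o_dir)
        # virtual CB from the N/CA/C triad (standard tetrahedral construction)
        vb = ca[i] - n_pos
        vc = c_pos - ca[i]
        va = np.cross(vb, vc)
        cb_pos = ca[i] - 0.58273431 * va + 0.56802827 * vb - 0.54067466 * vc
        coords[i, ATOM_INDEX["N"]] = n_pos
        coords[i, ATOM_INDEX["C"]] = c_pos
        coords[i, ATOM_INDEX["O"]] = o_pos
        coords[i, ATOM_INDEX["CB"]] = cb_pos
    return coords


def _draw_sequence(
    length: int, patch: np.ndarray, rng: np.random.Generator
) -> str:
    seq = []
    for i in range(length):
        if patch[i] and rng.random() < PATCH_BIAS:
            seq.append(PATCH_RESIDUES[rng.integers(len(PATCH_RESIDUES))])
        else:
            seq.append(ONE_LETTER[rng.integers(len(ONE_LETTER))])
    return "".join(seq)


def generate_chain(
    length: int,
    rng: np.random.Generator,
    chain_id: str = "A",
    interface_patch_size: int = 6,
) -> ChainStructure:
    """Generate one toy chain with a planted interface patch.

    The patch is a contiguous residue window whose composition is biased
    toward :data:`PATCH_RESIDUES`; its location is drawn uniformly among
    interior windows and recorded in ``interface_mask``.
    """
    if length < 8:
        raise ValueError("length must be at least 8")
    ca = _ca_walk(length, rng)
    coords = _backbone_from_ca(ca)
    patch = np.zeros(length, dtype=bool)
    start = int(rng.integers(1, length - interface_patch_size))
    patch[start : start + interface_patch_size] = True
    seq = _draw_sequence(length, patch, rng)
    mask = np.ones((length, 5), dtype=bool)
    mask[:, ATOM_INDEX["CB"]] = [aa != "G" for aa in seq]
    return ChainStructure(
        chain_id=chain_id,
        sequence=seq,
        coords=coords,
        atom_mask=mask,
        interface_mask=patch,
    )


# ---------------------------------------------------------------------------
# bound-complex construction
# ---------------------------------------------------------------------------


def _patch_geometry(chain: ChainStructure) -> tuple[np.ndarray, np.ndarray]:
    """Patch CB centroid and outward normal (centroid -> patch direction)."""
    cb = chain.coords[:, ATOM_INDEX["CB"]]
    cb = np.where(chain.atom_mask[:, ATOM_INDEX["CB"], None], cb, chain.ca)
    patch_centroid = cb[chain.interface_mask].mean(axis=0)
    body_centroid = chain.ca.mean(axis=0)
    normal = patch_centroid - body_centroid
    nn = np.linalg.norm(normal)
    if nn < 1e-6:  # patch centered on the centroid; pick a stable fallback
        normal = np.array([1.0, 0.0, 0.0])
        nn = 1.0
    return patch_centroid, normal / nn


def _rotation_aligning(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector u to unit vector v."""
    cross = np.cross(u, v)
    s = np.linalg.norm(cross)
    c = float(u @ v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # u = -v: rotate by pi about any axis orthogonal to u
        tmp = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            tmp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, tmp)
        axis /= np.linalg.norm(axis)
        return so3_exp(np.pi * axis)
    axis = cross / s
    angle = np.arctan2(s, c)
    return so3_exp(angle * axis)


def _effective_cb(chain: ChainStructure) -> np.ndarray:
    """CB coordinates with CA substituted where CB is absent (glycine)."""
    return np.where(
        chain.atom_mask[:, ATOM_INDEX["CB"], None],
        chain.coords[:, ATOM_INDEX["CB"]],
        chain.ca,
    )


def _interchain_metrics(
    receptor: ChainStructure, ligand: ChainStructure
) -> tuple[float, int]:
    """(min any-atom distance, number of CB-CB contacts < GEN_CONTACT_CUTOFF)."""
    ra = receptor.present_atoms()
    la = ligand.present_atoms()
    d_atoms = np.linalg.norm(ra[:, None, :] - la[None, :, :], axis=-1)
    d_cb = np.linalg.norm(
        _effective_cb(receptor)[:, None, :] - _effective_cb(ligand)[None, :, :], axis=-1
    )
    return float(d_atoms.min()), int((d_cb < GEN_CONTACT_CUTOFF).sum())


def generate_bound_complex(spec: ToyComplexSpec) -> ComplexConformation:
    """Build a bound complex whose interface patches face each other.

    The ligand orientation is searched over spin angles about the approach
    axis (with small random tilts) and the separation found by an outward
    line search until clash-free; among clash-free poses the one with the
    most CB-CB contacts wins, ties broken by search order, so the result is
    a deterministic function of the seed.
    """
    rng = np.random.default_rng(spec.seed)
    receptor = generate_chain(
        spec.receptor_length, rng, chain_id="A", interface_patch_size=spec.interface_patch_size
    )
    ligand0 = generate_chain(
        spec.ligand_length, rng, chain_id="B", interface_patch_size=spec.interface_patch_size
    )

    rec_pc, rec_n = _patch_geometry(receptor)
    lig_pc, lig_n = _patch_geometry(ligand0)

    rec_atoms = receptor.present_atoms()
    lig_atoms0 = ligand0.present_atoms() - lig_pc
    cb_r = _effective_cb(receptor)
    cb_l0 = _effective_cb(ligand0) - lig_pc

    best: tuple[int, float, RigidTransform] | None = None
    spins = np.linspace(0.0, 2 * np.pi, 24, endpoint=False)
    seps = np.arange(0.5, 12.0, 0.25)
    for trial in range(16):
        # approach direction: receptor patch normal with a growing random tilt
        tilt = 0.0 if trial == 0 else 0.25 + 0.35 * (trial / 15.0)
        approach = rec_n + tilt * _random_unit(rng)
        approach /= np.linalg.norm(approach)
        R_face = _rotation_aligning(lig_n, -approach)
        for spin in spins:
            R = so3_exp(spin * approach) @ R_face
            lig_rot = lig_atoms0 @ R.T
            cb_rot = cb_l0 @ R.T
            # along the ray target(sep) = rec_pc + sep*approach the squared
            # pair distances are quadratic in sep, so the whole line search
            # is a vectorized min/count over precomputed coefficients
            u = (rec_atoms[:, None, :] - (lig_rot + rec_pc)[None, :, :]).reshape(-1, 3)
            A = np.einsum("pi,pi->p", u, u)
            B = u @ approach
            d2min = (A[None, :] - 2.0 * seps[:, None] * B[None, :]).min(axis=1) + seps**2
            ok = np.flatnonzero(d2min >= spec.clash_floor**2)
            if ok.size == 0:
                continue
            k = ok[0]  # first clash-free separation along this ray
            sep = float(seps[k])
            u_cb = (cb_r[:, None, :] - (cb_rot + rec_pc)[None, :, :]).reshape(-1, 3)
            A_cb = np.einsum("pi,pi->p", u_cb, u_cb)
            B_cb = u_cb @ approach
            d2_cb = A_cb - 2.0 * sep * B_cb + sep**2
            ncontacts = int((d2_cb < GEN_CONTACT_CUTOFF**2).sum())
            if ncontacts >= spec.contact_target:
                key = (ncontacts, -sep)
                if best is None or key > (best[0], best[1]):
                    target = rec_pc + sep * approach
                    transform = RigidTransform(R, target - R @ lig_pc)
                    best = (ncontacts, -sep, transform)
        if best is not None and trial >= 1:
            break
    if best is None:
        raise RuntimeError(
            f"no clash-free pose with >= {spec.contact_target} contacts found "
            f"(seed {spec.seed})"
        )
    return ComplexConformation(
        chains=[receptor, ligand0.transformed(best[2])],
        receptor_index=0,
        ligand_index=1,
        provenance="holo",
    )


# ---------------------------------------------------------------------------
# unbound perturbation
# ---------------------------------------------------------------------------


def _smooth_noise(
    L: int, sigma: float, window: int, rng: np.random.Generator
) -> np.ndarray:
    """Correlated per-residue Gaussian displacements with per-coordinate std sigma."""
    if sigma == 0:
        return np.zeros((L, 3))
    raw = rng.standard_normal((L + window - 1, 3))
    kernel = np.ones(window) / window
    sm = np.stack([np.convolve(raw[:, k], kernel, mode="valid") for k in range(3)], axis=1)
    sm *= sigma * np.sqrt(window)  # undo the variance shrink of the moving average
    return sm


def perturb_unbound(chain: ChainStructure, spec: FlexPerturbSpec) -> ChainStructure:
    """Derive an unbound conformer: smooth noise + one hinge, re-idealized.

    With both sigmas zero the chain is returned bitwise identical.  The
    perturbed CA trace is re-idealized (bonds rescaled to 3.8 A, backbone
    atoms re-placed from local frames) so all ChainStructure invariants hold.
    """
    if spec.backbone_noise_sigma == 0 and spec.hinge_angle_sigma == 0:
        return chain.copy()
    rng = np.random.default_rng(spec.seed)
    L = len(chain)
    ca = chain.ca.copy()

    # one hinge rotation about an interior residue
    if spec.hinge_angle_sigma > 0 and L >= 5:
        h = int(rng.integers(2, L - 2))
        axis = _random_unit(rng)
        angle = rng.normal(0.0, spec.hinge_angle_sigma)
        R = so3_exp(angle * axis)
        ca[h:] = (ca[h:] - ca[h]) @ R.T + ca[h]

    ca = ca + _smooth_noise(L, spec.backbone_noise_sigma, spec.smoothing_window, rng)

    # re-idealize bond lengths by walking along the perturbed trace
    ideal = np.empty_like(ca)
    ideal[0] = ca[0]
    for i in range(1, L):
        step = ca[i] - ca[i - 1]
        ideal[i] = ideal[i - 1] + BOND_LENGTH * step / np.linalg.norm(step)
    coords = _backbone_from_ca(ideal)
    out = chain.copy()
    out.coords = coords
    # re-placed CB: keep the glycine absences of the source chain
    return ChainStructure(
        chain_id=chain.chain_id,
        sequence=chain.sequence,
        coords=coords,
        atom_mask=chain.atom_mask.copy(),
        interface_mask=None if chain.interface_mask is None else chain.interface_mask.copy(),
    )


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------


def build_dataset(
    n_complexes: int,
    out_dir: str | Path,
    seed: int = 0,
    length_range: tuple[int, int] = (16, 24),
    interface_patch_size: int = 6,
    contact_target: int = 6,
    clash_floor: float = 2.8,
) -> Path:
    """Generate ``n_complexes`` toy complexes with unbound conformers.

    For each complex a directory with the bound PDB plus per-chain holo,
    apo-like and predicted-like monomer PDBs is written; one JSON record per
    complex goes to ``manifest.jsonl``.  The dataset is a pure function of
    ``seed``.  Individual failures are skipped and logged; more than 10%
    failures raise.
    """
    if n_complexes < 1:
        raise ValueError("n_complexes must be positive")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.jsonl"
    seed_stream = np.random.default_rng(np.random.SeedSequence(seed))
    next_seed = lambda: int(seed_stream.integers(2**31))  # noqa: E731
    records = []
    failures = 0
    idx = 0
    while len(records) < n_complexes:
        cseed = next_seed()
        rng = np.random.default_rng(cseed)
        lo, hi = length_range
        spec = ToyComplexSpec(
            receptor_length=int(rng.integers(lo, hi + 1)),
            ligand_length=int(rng.integers(lo, hi + 1)),
            interface_patch_size=interface_patch_size,
            contact_target=contact_target,
            clash_floor=clash_floor,
            seed=cseed,
        )
        try:
            bound = generate_bound_complex(spec)
        except RuntimeError as exc:
            failures += 1
            logger.warning("complex generation failed (%s); skipping", exc)
            if failures > max(1, n_complexes // 10):
                raise RuntimeError(f"more than 10% of complex generations failed ({failures})")
            continue
        cdir = out_dir / f"complex_{idx:04d}"
        cdir.mkdir(exist_ok=True)
        write_pdb(bound, cdir / "bound.pdb")
        record: dict = {
            "id": f"complex_{idx:04d}",
            "seed": int(cseed),
            "bound": str(cdir / "bound.pdb"),
            "spec": dataclasses.asdict(spec),
            "chains": {},
        }
        for role, chain in (("receptor", bound.receptor), ("ligand", bound.ligand)):
            entry = {}
            holo = chain.copy()
            holo_path = cdir / f"{role}_holo.pdb"
            write_chain_pdb(holo, holo_path)
            entry["holo"] = str(holo_path)
            for mode, tag in (("apo_like", "apo"), ("predicted_like", "predicted")):
                pspec = FlexPerturbSpec(mode=mode, seed=next_seed())
                conf = perturb_unbound(chain, pspec)
                p = cdir / f"{role}_{tag}.pdb"
                write_chain_pdb(conf, p)
                entry[tag] = str(p)
            entry["interface"] = np.flatnonzero(chain.interface_mask).tolist()
            record["chains"][role] = entry
        records.append(record)
        idx += 1
    with open(manifest_path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")
    return manifest_path


def load_manifest(manifest_path: str | Path) -> list[dict]:
    """Read a JSON-lines dataset manifest."""
    with open(manifest_path) as fh:
        return [json.loads(line) for line in fh if line.strip()]
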