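"""Toy protein structure data model and PDB reading/writing.

The package works on backbone-plus-CB ("all-atom-lite") structures: each
residue carries up to five atoms (N, CA, C, O, CB) with a per-atom presence
mask.  A :class:`ComplexConformation` is an ordered set of chains with one
receptor and one ligand role — the state ``x_t`` that the flow transports.

PDB files are read and written through gemmi with fixed-column ATOM records,
TER separators, occupancy 1.00 and the B-factor column available for
per-residue scalar annotation.  Alternate locations, insertion codes and
multi-model files are rejected rather than silently merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from .geometry import RigidTransform
from .residues import (
    ATOM_INDEX,
    ATOM_NAMES,
    ELEMENT_OF_ATOM,
    N_ATOMS,
    ONE_TO_THREE,
    THREE_TO_ONE,
)

logger = logging.getLogger(__name__)

#: CA-CA virtual bond sanity window in Angstrom
CA_CA_MIN = 2.0
CA_CA_MAX = 5.0

PROVENANCE_TAGS = ("holo", "apo", "predicted", "noisy", "sampled")

__all__ = [
    "ChainStructure",
    "ComplexConformation",
    "StructureError",
    "read_pdb",
    "write_pdb",
    "read_chain_pdb",
    "write_chain_pdb",
]


class StructureError(ValueError):
    """Raised for malformed structures or files that violate the data model."""


@dataclass
class ChainStructure:
    """One polymer chain: sequence plus per-residue backbone/CB coordinates.

    ``coords`` is (L, 5, 3) in Angstrom, atom order (N, CA, C, O, CB);
    ``atom_mask`` is (L, 5) boolean (CB may be absent, the glycine analog).
    ``bfactors`` holds an optional per-residue scalar written to/read from
    the PDB B-factor column; ``interface_mask`` is the toy generator's
    interface-flag channel and is never written to coordinates files.
    """

    chain_id: str
    sequence: str
    coords: np.ndarray
    atom_mask: np.ndarray
    bfactors: np.ndarray | None = None
    interface_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.atom_mask = np.asarray(self.atom_mask, dtype=bool)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        L = len(self.sequence)
        if len(self.chain_id) != 1:
            raise StructureError(f"chain_id must be a single character, got {self.chain_id!r}")
        if self.coords.shape != (L, N_ATOMS, 3):
            raise StructureError(
                f"chain {self.chain_id}: coords shape {self.coords.shape} does not "
                f"match sequence length {L}"
            )
        if self.atom_mask.shape != (L, N_ATOMS):
            raise StructureError(f"chain {self.chain_id}: atom_mask shape mismatch")
        ca_idx = ATOM_INDEX["CA"]
        if not self.atom_mask[:, ca_idx].all():
            missing = int(np.flatnonzero(~self.atom_mask[:, ca_idx])[0])
            raise StructureError(f"chain {self.chain_id}: residue {missing + 1} has no CA atom")
        if not np.all(np.isfinite(self.coords[self.atom_mask])):
            raise StructureError(f"chain {self.chain_id}: non-finite coordinates")
        ca = self.ca
        if L > 1:
            d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
            bad = np.flatnonzero((d < CA_CA_MIN) | (d > CA_CA_MAX))
            if bad.size:
                raise StructureError(
                    f"chain {self.chain_id}: CA-CA distance {d[bad[0]]:.2f} A between "
                    f"residues {bad[0] + 1} and {bad[0] + 2} outside [{CA_CA_MIN}, {CA_CA_MAX}]"
                )
        if self.bfactors is not None and len(self.bfactors) != L:
            raise StructureError(f"chain {self.chain_id}: bfactors length mismatch")
        if self.interface_mask is not None and len(self.interface_mask) != L:
            raise StructureError(f"chain {self.chain_id}: interface_mask length mismatch")

    # -- views ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ca(self) -> np.ndarray:
        """(L, 3) CA coordinates."""
        return self.coords[:, ATOM_INDEX["CA"], :]

    @property
    def n(self) -> np.ndarray:
        return self.coords[:, ATOM_INDEX["N"], :]

    @property
    def c(self) -> np.ndarray:
        return self.coords[:, ATOM_INDEX["C"], :]

    def present_atoms(self) -> np.ndarray:
        """(n_present, 3) coordinates of all masked-present atoms."""
        return self.coords[self.atom_mask]

    def transformed(self, transform: RigidTransform) -> "ChainStructure":
        """Return a copy with all atoms moved by ``transform``."""
        return replace(self, coords=transform.apply(self.coords))

    def copy(self) -> "ChainStructure":
        return replace(
            self,
            coords=self.coords.copy(),
            atom_mask=self.atom_mask.copy(),
            bfactors=None if self.bfactors is None else np.array(self.bfactors),
            interface_mask=None
            if self.interface_mask is None
            else np.array(self.interface_mask),
        )


@dataclass
class ComplexConformation:
    """A multi-chain structure with receptor/ligand role labels."""

    chains: list[ChainStructure]
    receptor_index: int = 0
    ligand_index: int = 1
    provenance: str = "holo"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.chains)
        if n < 2:
            raise StructureError("a complex needs at least two chains")
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != n:
            raise StructureError(f"duplicate chain ids in complex: {ids}")
        for idx in (self.receptor_index, self.ligand_index):
            if not 0 <= idx < n:
                raise StructureError(f"role index {idx} out of range for {n} chains")
        if self.receptor_index == self.ligand_index:
            raise StructureError("receptor and ligand roles must be distinct chains")
        if self.provenance not in PROVENANCE_TAGS:
            raise StructureError(f"unknown provenance tag {self.provenance!r}")

    @property
    def receptor(self) -> ChainStructure:
        return self.chains[self.receptor_index]

    @property
    def ligand(self) -> ChainStructure:
        return self.chains[self.ligand_index]

    def __len__(self) -> int:
        return sum(len(c) for c in self.chains)

    def copy(self) -> "ComplexConformation":
        return ComplexConformation(
            [c.copy() for c in self.chains],
            self.receptor_index,
            self.ligand_index,
            self.provenance,
        )

    def transformed(self, transform: RigidTransform) -> "ComplexConformation":
        return ComplexConformation(
            [c.transformed(transform) for c in self.chains],
            self.receptor_index,
            self.ligand_index,
            self.provenance,
        )

    def with_provenance(self, tag: str) -> "ComplexConformation":
        return ComplexConformation(
            self.chains, self.receptor_index, self.ligand_index, tag
        )


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------


def _chain_from_gemmi(chain: gemmi.Chain, ignored: list[int]) -> ChainStructure | None:
    """Convert one gemmi chain; returns None for chains without ATOM residues."""
    seq: list[str] = []
    coords: list[np.ndarray] = []
    mask: list[np.ndarray] = []
    bfac: list[float] = []
    for res in chain:
        if res.het_flag != "A":  # HETATM records are not part of the toy model
            ignored[0] += len(res)
            continue
        if res.seqid.icode not in (" ", "\x00", ""):
            raise StructureError(
                f"chain {chain.name} residue {res.seqid.num}: insertion codes are not supported"
            )
        if res.name not in THREE_TO_ONE:
            raise StructureError(
                f"chain {chain.name} residue {res.seqid.num}: unknown residue name {res.name!r}"
            )
        res_xyz = np.zeros((N_ATOMS, 3))
        res_mask = np.zeros(N_ATOMS, dtype=bool)
        res_b = 0.0
        for atom in res:
            if atom.altloc not in ("\x00", "", " "):
                raise StructureError(
                    f"chain {chain.name} residue {res.seqid.num}: alternate locations "
                    "are not supported"
                )
            if atom.name not in ATOM_INDEX:
                ignored[0] += 1
                continue
            k = ATOM_INDEX[atom.name]
            res_xyz[k] = (atom.pos.x, atom.pos.y, atom.pos.z)
            res_mask[k] = True
            if atom.name == "CA":
                res_b = atom.b_iso
        if not res_mask[ATOM_INDEX["CA"]]:
            raise StructureError(
                f"chain {chain.name} residue {res.seqid.num} ({res.name}) is missing its CA atom"
            )
        seq.append(THREE_TO_ONE[res.name])
        coords.append(res_xyz)
        mask.append(res_mask)
        bfac.append(res_b)
    if not seq:
        return None
    return ChainStructure(
        chain_id=chain.name,
        sequence="".join(seq),
        coords=np.stack(coords),
        atom_mask=np.stack(mask),
        bfactors=np.array(bfac),
    )


def _read_chains(path: str | Path) -> list[ChainStructure]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    if len(st) != 1:
        raise StructureError(f"{path}: multi-model files are not supported ({len(st)} models)")
    ignored = [0]
    chains: list[ChainStructure] = []
    for gchain in st[0]:
        parsed = _chain_from_gemmi(gchain, ignored)
        if parsed is None:
            logger.warning("%s: chain %s has no ATOM residues; skipped", path, gchain.name)
            continue
        chains.append(parsed)
    if ignored[0]:
        logger.info("%s: ignored %d atoms outside the N/CA/C/O/CB set", path, ignored[0])
    return chains


def read_pdb(path: str | Path) -> ComplexConformation:
    """Read a two-chain complex from a PDB file.

    Only N/CA/C/O/CB atoms of ATOM records are retained (others are counted
    and logged); the first chain in file order becomes the receptor and the
    second the ligand.
    """
    chains = _read_chains(path)
    if len(chains) < 2:
        raise StructureError(
            f"{path}: cannot assign receptor/ligand roles to {len(chains)} chain(s); "
            "a complex needs exactly two"
        )
    if len(chains) > 2:
        raise StructureError(f"{path}: more than two chains; only bi-protein complexes are supported")
    return ComplexConformation(chains=chains, receptor_index=0, ligand_index=1)


def read_chain_pdb(path: str | Path) -> ChainStructure:
    """Read a single-chain monomer PDB file."""
    chains = _read_chains(path)
    if len(chains) != 1:
        raise StructureError(f"{path}: expected a single-chain monomer file, found {len(chains)}")
    return chains[0]


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------


def _check_finite(chain: ChainStructure) -> None:
    present = chain.coords[chain.atom_mask]
    if present.size and not np.all(np.isfinite(present)):
        raise StructureError(f"chain {chain.chain_id}: NaN/inf coordinate; refusing to write")


def _gemmi_structure(chains: list[ChainStructure]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "cfmdock"
    model = gemmi.Model("1")
    for chain in chains:
        gchain = gemmi.Chain(chain.chain_id)
        for i, aa in enumerate(chain.sequence):
            res = gemmi.Residue()
            res.name = ONE_TO_THREE[aa]
            res.seqid = gemmi.SeqId(i + 1, " ")
            res.het_flag = "A"
            b = 0.0 if chain.bfactors is None else float(chain.bfactors[i])
            for name in ATOM_NAMES:
                k = ATOM_INDEX[name]
                if not chain.atom_mask[i, k]:
                    continue
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(ELEMENT_OF_ATOM[name])
                atom.pos = gemmi.Position(*chain.coords[i, k])
                atom.occ = 1.0
                atom.b_iso = b
                res.add_atom(atom)
            gchain.add_residue(res)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()  # marks chains as polymers so TER records are emitted
    return st


def write_pdb(conformation: ComplexConformation, path: str | Path) -> None:
    """Write a complex as fixed-column PDB ATOM records, chains ending in TER."""
    for chain in conformation.chains:
        _check_finite(chain)
    st = _gemmi_structure(conformation.chains)
    st.write_pdb(str(path))


def write_chain_pdb(chain: ChainStructure, path: str | Path) -> None:
    """Write a single-chain monomer PDB file."""
    _check_finite(chain)
    st = _gemmi_structure([chain])
    st.write_pdb(str(path))
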