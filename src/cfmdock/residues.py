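"""Residue alphabet and backbone-atom conventions shared across the package."""

from __future__ import annotations

#: atom slots carried per residue, in storage order
ATOM_NAMES: tuple[str, ...] = ("N", "CA", "C", "O", "CB")
ATOM_INDEX: dict[str, int] = {name: i for i, name in enumerate(ATOM_NAMES)}
N_ATOMS = len(ATOM_NAMES)

#: backbone atoms used for RMSD-style metrics
BACKBONE_ATOMS: tuple[str, ...] = ("N", "CA", "C", "O")

#: the 20 standard amino acids, alphabetical by one-letter code
ONE_LETTER: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ONE_LETTER)}
N_AA = len(ONE_LETTER)

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

ELEMENT_OF_ATOM: dict[str, str] = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
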