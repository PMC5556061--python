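"""Heavy-atom residue topologies and chemical classifications.

Bond graphs cover the 20 standard amino acids (heavy atoms only).
They drive 1-2/1-3/1-4 classification in the energetics module and
donor/acceptor/apolar-carbon logic in interface contact detection.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

BACKBONE_BONDS: Tuple[Tuple[str, str], ...] = (("N", "CA"), ("CA", "C"), ("C", "O"))

SIDECHAIN_BONDS: Dict[str, Tuple[Tuple[str, str], ...]] = {
    "GLY": (),
    "ALA": (("CA", "CB"),),
    "SER": (("CA", "CB"), ("CB", "OG")),
    "CYS": (("CA", "CB"), ("CB", "SG")),
    "THR": (("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")),
    "VAL": (("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")),
    "LEU": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")),
    "ILE": (("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")),
    "MET": (("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")),
    "PRO": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")),
    "PHE": (
        ("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
        ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
    ),
    "TYR": (
        ("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
        ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
        ("CZ", "OH"),
    ),
    "TRP": (
        ("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
        ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
        ("CE2", "CZ2"), ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2"),
    ),
    "ASP": (("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")),
    "ASN": (("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")),
    "GLU": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")),
    "GLN": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")),
    "LYS": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")),
    "ARG": (
        ("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
        ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2"),
    ),
    "HIS": (
        ("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
        ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2"),
    ),
}

STANDARD_RESIDUES: FrozenSet[str] = frozenset(SIDECHAIN_BONDS)

FORMAL_CHARGE: Dict[str, int] = {name: 0 for name in STANDARD_RESIDUES}
FORMAL_CHARGE.update({"ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1})

# H-bond capable heavy atoms (heavy-atom level; explicit H refines geometry)
_DONORS_SIDECHAIN: Dict[str, Tuple[str, ...]] = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",), "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"), "TRP": ("NE1",),
}
_ACCEPTORS_SIDECHAIN: Dict[str, Tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",), "GLN": ("OE1",),
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}

CATIONIC_ATOMS: Dict[str, Tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}
ANIONIC_ATOMS: Dict[str, Tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


def residue_bonds(resname: str, with_oxt: bool = False) -> List[Tuple[str, str]]:
    """Intra-residue heavy-atom bonds (backbone + side chain)."""
    if resname not in SIDECHAIN_BONDS:
        raise KeyError(f"unknown residue {resname!r}")
    bonds = list(BACKBONE_BONDS) + list(SIDECHAIN_BONDS[resname])
    if with_oxt:
        bonds.append(("C", "OXT"))
    return bonds


def residue_atoms(resname: str, with_oxt: bool = False) -> List[str]:
    """Canonical heavy-atom names in deterministic order."""
    seen: List[str] = []
    for a, b in residue_bonds(resname, with_oxt=with_oxt):
        for name in (a, b):
            if name not in seen:
                seen.append(name)
    return seen


def is_donor(resname: str, atom_name: str) -> bool:
    if atom_name == "N":
        return resname != "PRO"  # proline backbone N carries no H
    return atom_name in _DONORS_SIDECHAIN.get(resname, ())


def is_acceptor(resname: str, atom_name: str) -> bool:
    if atom_name in ("O", "OXT"):
        return True
    return atom_name in _ACCEPTORS_SIDECHAIN.get(resname, ())


def is_cationic(resname: str, atom_name: str) -> bool:
    return atom_name in CATIONIC_ATOMS.get(resname, ())


def is_anionic(resname: str, atom_name: str) -> bool:
    if atom_name == "OXT":
        return True
    return atom_name in ANIONIC_ATOMS.get(resname, ())


def _neighbor_map(resname: str) -> Dict[str, Set[str]]:
    nbrs: Dict[str, Set[str]] = {}
    for a, b in residue_bonds(resname, with_oxt=True):
        nbrs.setdefault(a, set()).add(b)
        nbrs.setdefault(b, set()).add(a)
    return nbrs


_APOLAR_CACHE: Dict[str, FrozenSet[str]] = {}


def apolar_carbons(resname: str) -> FrozenSet[str]:
    """Carbons with no N/O/S bonded neighbor (within the residue).

    Backbone CA (bonded to N) and carbonyl C are excluded, so apolar
    contacts are effectively side-chain hydrophobic contacts.
    """
    if resname not in _APOLAR_CACHE:
        nbrs = _neighbor_map(resname)
        apolar = set()
        for atom, neigh in nbrs.items():
            if not atom.startswith("C"):
                continue
            if any(n[0] in "NOS" for n in neigh):
                continue
            apolar.add(atom)
        _APOLAR_CACHE[resname] = frozenset(apolar)
    return _APOLAR_CACHE[resname]


def element_of(atom_name: str) -> str:
    """Element guess from a PDB atom name (heavy atoms + hydrogens)."""
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name")
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    return "H" if name[0] == "H" else name[0]
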