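"""Editable molecular-mechanics parameter table (heavy-atom level).

This is a functional-form parameter set, not a force-field reproduction:
charges follow a simple polar-group scheme that sums exactly to each
residue's formal charge, Lennard-Jones and generalized-Born values are
element-class based.  The table serialises to TSV so users can swap in
their own parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

from sh3kit import topology


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class AtomParams:
    charge: float          # e
    lj_radius: float       # Rmin/2, Angstrom
    lj_epsilon: float      # kcal/mol
    gb_radius: float       # intrinsic Born radius, Angstrom
    gb_screen: float       # HCT descreening scale


# element-class LJ (Rmin/2, eps), GB radii and HCT screening factors
_ELEMENT_DEFAULTS: Dict[str, Tuple[float, float, float, float]] = {
    "C": (1.908, 0.086, 1.70, 0.72),
    "N": (1.824, 0.170, 1.55, 0.79),
    "O": (1.661, 0.210, 1.50, 0.85),
    "S": (2.000, 0.250, 1.80, 0.96),
    "H": (0.600, 0.0157, 1.20, 0.85),
}

# backbone partial charges (sum to zero)
_BACKBONE_CHARGES = {"N": -0.15, "CA": 0.10, "C": 0.55, "O": -0.50}

# side-chain polar-group charges; unlisted side-chain atoms are 0.
# Each residue's total (backbone + side chain) equals its formal charge.
_SIDECHAIN_CHARGES: Dict[str, Dict[str, float]] = {
    "SER": {"CB": 0.40, "OG": -0.40},
    "THR": {"CB": 0.40, "OG1": -0.40},
    "CYS": {"CB": 0.10, "SG": -0.10},
    "TYR": {"CZ": 0.40, "OH": -0.40},
    "TRP": {"CE2": 0.20, "NE1": -0.20},
    "ASP": {"CG": 0.10, "OD1": -0.55, "OD2": -0.55},
    "GLU": {"CD": 0.10, "OE1": -0.55, "OE2": -0.55},
    "ASN": {"CG": 0.10, "OD1": -0.50, "ND2": 0.40},
    "GLN": {"CD": 0.10, "OE1": -0.50, "NE2": 0.40},
    "LYS": {"NZ": 1.00},
    "ARG": {"CZ": 0.40, "NE": 0.00, "NH1": 0.30, "NH2": 0.30},
    "HIS": {"ND1": -0.20, "NE2": 0.20},
}


@dataclass
class ParameterTable:
    """Atom parameters keyed by (residue name, atom name) plus bond graph."""

    entries: Dict[Tuple[str, str], AtomParams]

    def lookup(self, res_name: str, atom_name: str) -> AtomParams:
        key = (res_name, atom_name)
        if key in self.entries:
            return self.entries[key]
        if topology.element_of(atom_name) == "H" and (res_name, "H*") in self.entries:
            return self.entries[(res_name, "H*")]
        raise ParameterError(
            f"no parameters for atom {atom_name!r} of residue {res_name!r}"
        )

    def residue_charge(self, res_name: str) -> float:
        return sum(
            p.charge for (rn, an), p in self.entries.items()
            if rn == res_name and an != "OXT" and topology.element_of(an) != "H"
        )

    def to_tsv(self, path) -> None:
        lines = ["res_name\tatom_name\tcharge\tlj_radius\tlj_epsilon\t"
                 "gb_radius\tgb_screen"]
        for (rn, an), p in sorted(self.entries.items()):
            lines.append(
                f"{rn}\t{an}\t{p.charge:.4f}\t{p.lj_radius:.4f}\t"
                f"{p.lj_epsilon:.4f}\t{p.gb_radius:.4f}\t{p.gb_screen:.4f}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "ParameterTable":
        lines = Path(path).read_text().strip().splitlines()
        entries = {}
        for line in lines[1:]:
            rn, an, q, rad, eps, gbr, scr = line.split("\t")
            entries[(rn, an)] = AtomParams(
                charge=float(q), lj_radius=float(rad), lj_epsilon=float(eps),
                gb_radius=float(gbr), gb_screen=float(scr),
            )
        return cls(entries=entries)


def default_parameter_table() -> ParameterTable:
    """Built-in table covering the 20 standard residues (heavy atoms + H)."""
    entries: Dict[Tuple[str, str], AtomParams] = {}
    for res in sorted(topology.STANDARD_RESIDUES):
        sc = _SIDECHAIN_CHARGES.get(res, {})
        for atom in topology.residue_atoms(res, with_oxt=True):
            elem = topology.element_of(atom)
            lj_r, lj_e, gb_r, screen = _ELEMENT_DEFAULTS[elem]
            if atom in _BACKBONE_CHARGES:
                charge = _BACKBONE_CHARGES[atom]
            elif atom == "OXT":
                charge = -1.0  # deprotonated C-terminus marker
            else:
                charge = sc.get(atom, 0.0)
            entries[(res, atom)] = AtomParams(
                charge=charge, lj_radius=lj_r, lj_epsilon=lj_e,
                gb_radius=gb_r, gb_screen=screen,
            )
        # generic hydrogen entry so protonated inputs still parameterise
        lj_r, lj_e, gb_r, screen = _ELEMENT_DEFAULTS["H"]
        entries[(res, "H*")] = AtomParams(
            charge=0.0, lj_radius=lj_r, lj_epsilon=lj_e,
            gb_radius=gb_r, gb_screen=screen,
        )
    return ParameterTable(entries=entries)
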