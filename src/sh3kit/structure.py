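"""Ensemble interface analysis: contacts, occupancies, pockets, RMSD, CSP.

Multi-MODEL PDB files are read through biotite; each MODEL block becomes
one model of a :class:`StructureEnsemble`.  Contact detection is purely
geometric (configurable cutoffs) and deliberately conservative about
unknown residue names: their atoms are excluded with a warning rather
than guessed at.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from sh3kit import topology

logger = logging.getLogger(__name__)


class StructureError(ValueError):
    pass


class EnsembleFormatError(StructureError):
    pass


# ---------------------------------------------------------------------------
# selections


@dataclass(frozen=True)
class Selection:
    """Atom subset addressed by chain and/or residue-number range."""

    chain: Optional[str] = None
    res_start: Optional[int] = None
    res_end: Optional[int] = None

    def mask(self, atoms: struc.AtomArray) -> np.ndarray:
        m = np.ones(atoms.array_length(), dtype=bool)
        if self.chain is not None:
            m &= atoms.chain_id == self.chain
        if self.res_start is not None:
            m &= atoms.res_id >= self.res_start
        if self.res_end is not None:
            m &= atoms.res_id <= self.res_end
        return m


@dataclass
class StructureEnsemble:
    """Ordered models of one complex with ligand/linker bookkeeping."""

    stack: struc.AtomArrayStack
    source: str = ""
    peptide_selection: Optional[Selection] = None
    linker_selection: Optional[Selection] = None

    @property
    def n_models(self) -> int:
        return self.stack.stack_depth()

    def model(self, index: int) -> struc.AtomArray:
        return self.stack[index]

    def __iter__(self):
        for i in range(self.n_models):
            yield self.stack[i]


def load_ensemble(
    path,
    peptide_selection: Optional[Selection] = None,
    linker_selection: Optional[Selection] = None,
) -> StructureEnsemble:
    """Parse a (multi-MODEL) PDB file into an ensemble."""
    try:
        pdb = PDBFile.read(str(path))
        n = pdb.get_model_count()
    except Exception as exc:
        raise EnsembleFormatError(f"cannot parse PDB {path}: {exc}") from exc
    if n < 1:
        raise EnsembleFormatError(f"{path} contains no MODEL/ATOM records")
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:
        try:
            counts = [
                pdb.get_structure(model=i).array_length()
                for i in range(1, n + 1)
            ]
        except Exception:
            raise EnsembleFormatError(
                f"{path}: malformed coordinate records ({exc})"
            ) from exc
        bad = [i + 1 for i, c in enumerate(counts) if c != counts[0]]
        raise EnsembleFormatError(
            f"{path}: inconsistent atom inventory across models "
            f"(model(s) {bad} differ from model 1)"
        ) from exc
    return StructureEnsemble(
        stack=stack,
        source=str(path),
        peptide_selection=peptide_selection,
        linker_selection=linker_selection,
    )


def strip_linker(
    ensemble: StructureEnsemble,
    residue_range: Optional[Tuple[int, int]] = None,
    chain: Optional[str] = None,
) -> StructureEnsemble:
    """Remove a residue range (e.g. a chimera linker) from every model."""
    if residue_range is None:
        sel = ensemble.linker_selection
    else:
        sel = Selection(chain=chain, res_start=residue_range[0],
                        res_end=residue_range[1])
    if sel is None:
        return ensemble
    template = ensemble.stack[0]
    drop = sel.mask(template)
    if not drop.any():
        return ensemble
    keep = ~drop
    if not keep.any():
        raise StructureError("stripping the range would remove every atom")
    new_stack = ensemble.stack[..., keep]
    new = StructureEnsemble(
        stack=new_stack,
        source=ensemble.source,
        peptide_selection=ensemble.peptide_selection,
        linker_selection=None,
    )
    if new.peptide_selection is not None:
        if not new.peptide_selection.mask(new_stack[0]).any():
            raise StructureError("ligand selection is empty after stripping")
    return new


# ---------------------------------------------------------------------------
# contacts


@dataclass(frozen=True)
class ContactCriteria:
    hbond_da_max: float = 3.5
    hbond_angle_min: float = 120.0  # applied only with explicit hydrogens
    salt_no_max: float = 4.0
    nonpolar_cc_max: float = 4.5

    def __post_init__(self) -> None:
        for name in ("hbond_da_max", "salt_no_max", "nonpolar_cc_max"):
            if getattr(self, name) <= 0:
                raise StructureError(f"{name} must be positive")

    @property
    def max_cutoff(self) -> float:
        return max(self.hbond_da_max, self.salt_no_max, self.nonpolar_cc_max)


AtomKey = Tuple[str, int, str, str]  # chain, res_id, res_name, atom_name


@dataclass(frozen=True)
class ContactRecord:
    kind: str  # hbond | salt_bridge | nonpolar
    partner_a: AtomKey  # receptor side
    partner_b: AtomKey  # ligand side
    distance: float
    model_index: int = 0

    def residue_pair(self) -> Tuple[str, Tuple[str, int, str], Tuple[str, int, str]]:
        return (
            self.kind,
            (self.partner_a[0], self.partner_a[1], self.partner_a[2]),
            (self.partner_b[0], self.partner_b[1], self.partner_b[2]),
        )


def _atom_key(atoms: struc.AtomArray, i: int) -> AtomKey:
    return (
        str(atoms.chain_id[i]),
        int(atoms.res_id[i]),
        str(atoms.res_name[i]),
        str(atoms.atom_name[i]),
    )


def _hydrogen_positions(atoms: struc.AtomArray) -> Dict[int, List[np.ndarray]]:
    """Map heavy-atom index -> positions of hydrogens bonded to it.

    A hydrogen is attached to the nearest heavy atom of the same residue
    within 1.3 A.
    """
    names = atoms.atom_name
    is_h = np.array([topology.element_of(n) == "H" for n in names])
    attached: Dict[int, List[np.ndarray]] = {}
    if not is_h.any():
        return attached
    heavy_idx = np.where(~is_h)[0]
    tree = cKDTree(atoms.coord[heavy_idx])
    for hi in np.where(is_h)[0]:
        dist, j = tree.query(atoms.coord[hi], k=1)
        heavy = heavy_idx[j]
        if dist <= 1.3 and atoms.res_id[heavy] == atoms.res_id[hi] \
                and atoms.chain_id[heavy] == atoms.chain_id[hi]:
            attached.setdefault(int(heavy), []).append(atoms.coord[hi])
    return attached


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_contacts(
    model: struc.AtomArray,
    criteria: Optional[ContactCriteria] = None,
    ligand: Optional[Selection] = None,
    model_index: int = 0,
) -> List[ContactRecord]:
    """Geometric interface contacts between receptor and ligand sides.

    hbond: donor/acceptor N,O pair within ``hbond_da_max`` (D-H...A angle
    additionally required when explicit hydrogens exist on the donor).
    salt_bridge: Lys/Arg/His N+ to Asp/Glu/C-terminal O- within
    ``salt_no_max``.  nonpolar: apolar carbon pair within
    ``nonpolar_cc_max``.
    """
    criteria = criteria or ContactCriteria()
    if ligand is None:
        raise StructureError("a ligand selection is required to partition atoms")
    lig_mask = ligand.mask(model)
    if not lig_mask.any() or lig_mask.all():
        raise StructureError("ligand selection must split atoms into two sides")

    known = np.isin(model.res_name, list(topology.STANDARD_RESIDUES))
    unknown = set(model.res_name[~known])
    if unknown:
        logger.warning("excluding atoms of unknown residues: %s", sorted(unknown))

    names = model.atom_name
    not_h = np.array([topology.element_of(n) != "H" for n in names])
    usable = known & not_h
    rec_idx = np.where(usable & ~lig_mask)[0]
    lig_idx = np.where(usable & lig_mask)[0]
    if len(rec_idx) == 0 or len(lig_idx) == 0:
        return []

    hydrogens = _hydrogen_positions(model)

    tree = cKDTree(model.coord[lig_idx])
    pairs = tree.query_ball_point(model.coord[rec_idx], criteria.max_cutoff)

    contacts: List[ContactRecord] = []
    for ri, neighbors in zip(rec_idx, pairs):
        rn, ra = str(model.res_name[ri]), str(model.atom_name[ri])
        for lj in (lig_idx[k] for k in neighbors):
            ln, la = str(model.res_name[lj]), str(model.atom_name[lj])
            d = float(np.linalg.norm(model.coord[ri] - model.coord[lj]))
            key_a, key_b = _atom_key(model, ri), _atom_key(model, int(lj))

            if d <= criteria.salt_no_max and (
                (topology.is_cationic(rn, ra) and topology.is_anionic(ln, la))
                or (topology.is_anionic(rn, ra) and topology.is_cationic(ln, la))
            ):
                contacts.append(ContactRecord("salt_bridge", key_a, key_b, d,
                                              model_index))

            if d <= criteria.hbond_da_max:
                for di, ai, dn_, da_ in (
                    (ri, lj, rn, ra),
                    (lj, ri, ln, la),
                ):
                    dres = str(model.res_name[di])
                    datom = str(model.atom_name[di])
                    ares = str(model.res_name[ai])
                    aatom = str(model.atom_name[ai])
                    if not (topology.is_donor(dres, datom)
                            and topology.is_acceptor(ares, aatom)):
                        continue
                    h_pos = hydrogens.get(int(di), [])
                    if h_pos:
                        ok = any(
                            _angle_deg(model.coord[di], h, model.coord[ai])
                            >= criteria.hbond_angle_min
                            for h in h_pos
                        )
                        if not ok:
                            continue
                    contacts.append(ContactRecord("hbond", key_a, key_b, d,
                                                  model_index))
                    break

            if d <= criteria.nonpolar_cc_max \
                    and ra in topology.apolar_carbons(rn) \
                    and la in topology.apolar_carbons(ln):
                contacts.append(ContactRecord("nonpolar", key_a, key_b, d,
                                              model_index))
    return contacts


# ---------------------------------------------------------------------------
# occupancy

BANDS = (
    ("conserved", 0.90, 1.01),
    ("moderate", 0.50, 0.90),
    ("transient", 0.20, 0.50),
    ("weak", -0.01, 0.20),
)


def occupancy_band(fraction: float) -> str:
    """conserved > 0.90 >= moderate > 0.50 >= transient > 0.20 >= weak."""
    for label, lo, hi in BANDS:
        if lo < fraction <= hi:
            return label
    return "weak"


@dataclass
class OccupancyTable:
    rows: Dict[Tuple, float]
    n_models: int

    def band(self, key) -> str:
        return occupancy_band(self.rows[key])

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for (kind, res_a, res_b), occ in sorted(self.rows.items()):
            records.append(
                {
                    "kind": kind,
                    "receptor_chain": res_a[0],
                    "receptor_resid": res_a[1],
                    "receptor_resname": res_a[2],
                    "ligand_chain": res_b[0],
                    "ligand_resid": res_b[1],
                    "ligand_resname": res_b[2],
                    "occupancy": occ,
                    "band": occupancy_band(occ),
                }
            )
        return pd.DataFrame(
            records,
            columns=[
                "kind", "receptor_chain", "receptor_resid", "receptor_resname",
                "ligand_chain", "ligand_resid", "ligand_resname",
                "occupancy", "band",
            ],
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def ensemble_occupancy(
    ensemble: StructureEnsemble,
    criteria: Optional[ContactCriteria] = None,
    ligand: Optional[Selection] = None,
) -> OccupancyTable:
    """Fraction of models containing each residue-pair interaction."""
    ligand = ligand or ensemble.peptide_selection
    counts: Dict[Tuple, int] = {}
    n = ensemble.n_models
    for i, model in enumerate(ensemble):
        present: Set[Tuple] = set()
        for c in detect_contacts(model, criteria, ligand, model_index=i):
            present.add(c.residue_pair())
        for key in present:
            counts[key] = counts.get(key, 0) + 1
    return OccupancyTable(
        rows={k: v / n for k, v in counts.items()}, n_models=n
    )


# ---------------------------------------------------------------------------
# pockets

#: Receptor residues delimiting the four ligand-binding pockets
#: (zero/upstream, first xP, second xP, specificity), by residue number.
DEFAULT_POCKET_MAP: Dict[int, str] = {
    25: "pocket0", 26: "pocket0",
    12: "pocket1", 59: "pocket1", 58: "pocket1", 56: "pocket1",
    14: "pocket2", 17: "pocket2", 43: "pocket2",
    20: "pocket3", 21: "pocket3", 18: "pocket3",
}


def classify_pockets(
    contacts: Sequence[ContactRecord],
    pocket_map: Optional[Mapping[int, str]] = None,
    ligand_positions: Optional[Mapping[int, str]] = None,
) -> Dict[str, Set[str]]:
    """Map each contacted ligand position to the pocket(s) it touches.

    ``pocket_map`` keys are receptor residue numbers; receptor residues
    absent from the map label the contact "outside".  ``ligand_positions``
    optionally renames ligand residue numbers to motif position labels.
    """
    pocket_map = DEFAULT_POCKET_MAP if pocket_map is None else pocket_map
    out: Dict[str, Set[str]] = {}
    for c in contacts:
        lig_resid = c.partner_b[1]
        label = (
            ligand_positions.get(lig_resid, str(lig_resid))
            if ligand_positions
            else str(lig_resid)
        )
        pocket = pocket_map.get(c.partner_a[1], "outside")
        out.setdefault(label, set()).add(pocket)
    return out


# ---------------------------------------------------------------------------
# RMSD

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def _backbone_coords(
    atoms: struc.AtomArray, residue_range: Optional[Tuple[int, int]]
) -> np.ndarray:
    mask = np.isin(atoms.atom_name, BACKBONE_ATOMS)
    if residue_range is not None:
        lo, hi = residue_range
        mask &= (atoms.res_id >= lo) & (atoms.res_id <= hi)
        present = set(atoms.res_id[mask].tolist())
        missing = [r for r in range(lo, hi + 1) if r not in present]
        if missing:
            raise StructureError(
                f"residues missing backbone atoms in range {lo}-{hi}: {missing}"
            )
    if not mask.any():
        raise StructureError("no backbone atoms selected")
    sub = atoms[mask]
    order = np.lexsort(
        (np.array([BACKBONE_ATOMS.index(a) for a in sub.atom_name]),
         sub.res_id, sub.chain_id)
    )
    return sub.coord[order].astype(np.float64)


def backbone_rmsd(
    a: struc.AtomArray,
    b: struc.AtomArray,
    residue_range: Optional[Tuple[int, int]] = None,
    superimpose: bool = True,
) -> float:
    """Backbone (N, CA, C, O) RMSD after optimal rigid superposition."""
    xa = _backbone_coords(a, residue_range)
    xb = _backbone_coords(b, residue_range)
    if xa.shape != xb.shape:
        raise StructureError(
            f"backbone atom counts differ: {xa.shape[0]} vs {xb.shape[0]}"
        )
    if superimpose:
        xb = _kabsch_fit(xb, xa)
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def _kabsch_fit(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rigid superposition of ``mobile`` onto ``target``."""
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    h = mc.T @ tc
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return mc @ rot + target.mean(axis=0)


# ---------------------------------------------------------------------------
# chemical shift perturbations


@dataclass
class ShiftTable:
    """Combined and normalised amide CSPs between two states."""

    residues: np.ndarray
    csp: np.ndarray
    relative_csp: np.ndarray
    all_zero: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.residues,
                "csp": self.csp,
                "relative_csp": self.relative_csp,
            }
        )


def relative_csp(
    shifts_free: pd.DataFrame,
    shifts_bound: pd.DataFrame,
    alpha: float = 0.2,
) -> ShiftTable:
    """Combined CSP sqrt(dH^2 + (alpha*dN)^2), scaled by its own stdev.

    Input frames need columns ``residue``, ``H_ppm``, ``N_ppm``.
    """
    merged = shifts_free.merge(
        shifts_bound, on="residue", suffixes=("_free", "_bound")
    )
    if len(merged) < 3:
        raise StructureError(
            f"only {len(merged)} overlapping residues; need at least 3"
        )
    dh = merged["H_ppm_bound"].to_numpy() - merged["H_ppm_free"].to_numpy()
    dn = merged["N_ppm_bound"].to_numpy() - merged["N_ppm_free"].to_numpy()
    csp = np.sqrt(dh**2 + (alpha * dn) ** 2)
    sd = float(np.std(csp, ddof=1))
    if sd == 0.0:
        return ShiftTable(
            residues=merged["residue"].to_numpy(),
            csp=csp,
            relative_csp=np.zeros_like(csp),
            all_zero=True,
        )
    return ShiftTable(
        residues=merged["residue"].to_numpy(),
        csp=csp,
        relative_csp=csp / sd,
    )


def read_shift_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"residue", "H_ppm", "N_ppm"}
    if not required <= set(df.columns):
        raise StructureError(f"{path} must have columns {sorted(required)}")
    return df
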