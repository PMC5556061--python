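"""Per-residue interaction-energy decomposition (single-trajectory style).

The interaction energy of a receptor-ligand partition is
E(complex) - E(receptor) - E(ligand) over four components:
Coulomb electrostatics, 12-6 van der Waals, generalized-Born polar
solvation (HCT effective radii with Debye-Hueckel salt screening) and a
solvent-accessible-surface-area nonpolar term.  Cross-partition pair
terms are attributed half to each partner's residue, so the per-residue
contributions sum exactly to the total.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

import biotite.structure as struc

from sh3kit import topology
from sh3kit.params import ParameterTable, default_parameter_table
from sh3kit.structure import Selection

logger = logging.getLogger(__name__)

COULOMB = 332.0636  # kcal*A/(mol*e^2)
GB_OFFSET = 0.09    # A, intrinsic-radius offset in HCT
KAPPA_COEFF = 0.3293  # kappa = 0.3293*sqrt(I[M]) 1/A, water at 298 K
BORN_RADIUS_CLAMP = 30.0


class EnergeticsError(ValueError):
    pass


@dataclass(frozen=True)
class EnergeticsConfig:
    interior_dielectric: float = 1.0
    solvent_dielectric: float = 78.5
    ionic_strength: float = 0.150      # mol/L
    surften: float = 0.0072            # kcal/(mol*A^2)
    surfoff: float = 0.0               # kcal/mol
    gb_variant: str = "HCT"
    probe_radius: float = 1.4
    sphere_points: int = 960
    scale_elec_14: float = 1.0 / 1.2
    scale_vdw_14: float = 0.5

    def __post_init__(self) -> None:
        if self.interior_dielectric <= 0 or self.solvent_dielectric <= 0:
            raise EnergeticsError("dielectrics must be positive")
        if self.ionic_strength < 0:
            raise EnergeticsError("ionic strength must be non-negative")
        if self.gb_variant != "HCT":
            raise EnergeticsError(f"unsupported GB variant {self.gb_variant!r}")

    @property
    def kappa(self) -> float:
        return KAPPA_COEFF * math.sqrt(self.ionic_strength)


@dataclass
class ParameterizedStructure:
    """An AtomArray with charges, LJ/GB parameters and exclusion sets."""

    atoms: struc.AtomArray
    charge: np.ndarray
    lj_radius: np.ndarray
    lj_epsilon: np.ndarray
    gb_radius: np.ndarray
    gb_screen: np.ndarray
    residue_index: np.ndarray          # per-atom index into ``residues``
    residues: List[Tuple[str, int, str]]  # (chain, res_id, res_name)
    excluded: set                      # 1-2/1-3 pairs (i, j), i < j
    scaled_14: set                     # 1-4 pairs (i, j), i < j

    @property
    def n_atoms(self) -> int:
        return len(self.charge)

    @property
    def coord(self) -> np.ndarray:
        cached = self.__dict__.get("_coord64")
        if cached is None or cached.shape[0] != self.atoms.array_length():
            cached = self.atoms.coord.astype(np.float64)
            self.__dict__["_coord64"] = cached
        return cached

    def subset(self, mask: np.ndarray) -> "ParameterizedStructure":
        idx = np.where(mask)[0]
        remap = {int(old): new for new, old in enumerate(idx)}
        res_seen: Dict[Tuple, int] = {}
        res_list: List[Tuple[str, int, str]] = []
        res_index = np.empty(len(idx), dtype=int)
        for new, old in enumerate(idx):
            key = self.residues[self.residue_index[old]]
            if key not in res_seen:
                res_seen[key] = len(res_list)
                res_list.append(key)
            res_index[new] = res_seen[key]

        def keep(pairs):
            return {
                (remap[i], remap[j])
                for i, j in pairs
                if i in remap and j in remap
            }

        return ParameterizedStructure(
            atoms=self.atoms[mask],
            charge=self.charge[idx],
            lj_radius=self.lj_radius[idx],
            lj_epsilon=self.lj_epsilon[idx],
            gb_radius=self.gb_radius[idx],
            gb_screen=self.gb_screen[idx],
            residue_index=res_index,
            residues=res_list,
            excluded=keep(self.excluded),
            scaled_14=keep(self.scaled_14),
        )


def _bond_list(atoms: struc.AtomArray) -> List[Tuple[int, int]]:
    """Heavy-atom bonds from residue topologies plus peptide bonds."""
    index: Dict[Tuple[str, int, str], int] = {}
    for i in range(atoms.array_length()):
        index[(str(atoms.chain_id[i]), int(atoms.res_id[i]),
               str(atoms.atom_name[i]))] = i
    residues = []
    seen = set()
    for i in range(atoms.array_length()):
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]))
        if key not in seen:
            seen.add(key)
            residues.append((key, str(atoms.res_name[i])))
    bonds: List[Tuple[int, int]] = []
    for (chain, res_id), res_name in residues:
        if res_name not in topology.STANDARD_RESIDUES:
            raise EnergeticsError(f"unknown residue {res_name!r} {chain}{res_id}")
        for a, b in topology.residue_bonds(res_name, with_oxt=True):
            ia = index.get((chain, res_id, a))
            ib = index.get((chain, res_id, b))
            if ia is not None and ib is not None:
                bonds.append((min(ia, ib), max(ia, ib)))
        ic = index.get((chain, res_id, "C"))
        in_next = index.get((chain, res_id + 1, "N"))
        if ic is not None and in_next is not None:
            bonds.append((min(ic, in_next), max(ic, in_next)))
    return bonds


def assign_params(
    model: struc.AtomArray, table: Optional[ParameterTable] = None
) -> ParameterizedStructure:
    """Attach charges/LJ/GB parameters and build exclusion lists."""
    table = table or default_parameter_table()
    n = model.array_length()
    charge = np.empty(n)
    lj_r = np.empty(n)
    lj_e = np.empty(n)
    gb_r = np.empty(n)
    screen = np.empty(n)
    residues: List[Tuple[str, int, str]] = []
    res_seen: Dict[Tuple, int] = {}
    res_index = np.empty(n, dtype=int)
    for i in range(n):
        rn = str(model.res_name[i])
        an = str(model.atom_name[i])
        p = table.lookup(rn, an)
        charge[i], lj_r[i], lj_e[i] = p.charge, p.lj_radius, p.lj_epsilon
        gb_r[i], screen[i] = p.gb_radius, p.gb_screen
        key = (str(model.chain_id[i]), int(model.res_id[i]), rn)
        if key not in res_seen:
            res_seen[key] = len(residues)
            residues.append(key)
        res_index[i] = res_seen[key]

    bonds = _bond_list(model)
    nbrs: Dict[int, set] = {}
    for a, b in bonds:
        nbrs.setdefault(a, set()).add(b)
        nbrs.setdefault(b, set()).add(a)

    excluded = set(bonds)
    for neigh in nbrs.values():
        for a in neigh:
            for b in neigh:
                if a < b:
                    excluded.add((a, b))  # 1-3
    scaled_14 = set()
    for a, b in bonds:
        for x in nbrs.get(a, ()):
            for y in nbrs.get(b, ()):
                if x in (b, y) or y == a:
                    continue
                scaled_14.add((min(x, y), max(x, y)))
    scaled_14 -= excluded

    return ParameterizedStructure(
        atoms=model, charge=charge, lj_radius=lj_r, lj_epsilon=lj_e,
        gb_radius=gb_r, gb_screen=screen,
        residue_index=res_index, residues=residues,
        excluded=excluded, scaled_14=scaled_14,
    )


# ---------------------------------------------------------------------------
# molecular-mechanics pair terms


def mm_pair_energy(
    struct: ParameterizedStructure,
    i: int,
    j: int,
    config: Optional[EnergeticsConfig] = None,
) -> Tuple[float, float]:
    """(electrostatic, van der Waals) energy of one atom pair, kcal/mol."""
    config = config or EnergeticsConfig()
    pair = (min(i, j), max(i, j))
    if pair in struct.excluded:
        raise EnergeticsError(f"pair {pair} is 1-2/1-3 excluded")
    r = float(np.linalg.norm(struct.coord[i] - struct.coord[j]))
    if r == 0.0:
        raise EnergeticsError(f"zero distance between atoms {i} and {j}")
    elec = COULOMB * struct.charge[i] * struct.charge[j] / (
        config.interior_dielectric * r
    )
    rmin = struct.lj_radius[i] + struct.lj_radius[j]
    eps = math.sqrt(struct.lj_epsilon[i] * struct.lj_epsilon[j])
    ratio6 = (rmin / r) ** 6
    vdw = eps * (ratio6 * ratio6 - 2.0 * ratio6)
    if pair in struct.scaled_14:
        elec *= config.scale_elec_14
        vdw *= config.scale_vdw_14
    return elec, vdw


def _mm_cross_matrices(
    struct: ParameterizedStructure,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    config: EnergeticsConfig,
) -> Tuple[np.ndarray, np.ndarray]:
    """Dense (len(a), len(b)) elec and vdw matrices with 1-2/1-3 zeroed."""
    r = cdist(struct.coord[idx_a], struct.coord[idx_b])
    if np.any(r == 0):
        raise EnergeticsError("coincident atoms across the partition")
    elec = COULOMB * np.outer(struct.charge[idx_a], struct.charge[idx_b]) / (
        config.interior_dielectric * r
    )
    rmin = struct.lj_radius[idx_a][:, None] + struct.lj_radius[idx_b][None, :]
    eps = np.sqrt(
        np.outer(struct.lj_epsilon[idx_a], struct.lj_epsilon[idx_b])
    )
    ratio6 = (rmin / r) ** 6
    vdw = eps * (ratio6 * ratio6 - 2.0 * ratio6)

    pos_a = {int(v): k for k, v in enumerate(idx_a)}
    pos_b = {int(v): k for k, v in enumerate(idx_b)}
    for pairs, elec_f, vdw_f in (
        (struct.excluded, 0.0, 0.0),
        (struct.scaled_14, config.scale_elec_14, config.scale_vdw_14),
    ):
        for i, j in pairs:
            for a, b in ((i, j), (j, i)):
                if a in pos_a and b in pos_b:
                    elec[pos_a[a], pos_b[b]] *= elec_f
                    vdw[pos_a[a], pos_b[b]] *= vdw_f
    return elec, vdw


def interface_mm_energy(
    struct: ParameterizedStructure,
    ligand_mask: np.ndarray,
    config: Optional[EnergeticsConfig] = None,
) -> Tuple[float, float]:
    """Total cross-partition (elec, vdw) energies, kcal/mol."""
    config = config or EnergeticsConfig()
    idx_a = np.where(~ligand_mask)[0]
    idx_b = np.where(ligand_mask)[0]
    elec, vdw = _mm_cross_matrices(struct, idx_a, idx_b, config)
    return float(elec.sum()), float(vdw.sum())


# ---------------------------------------------------------------------------
# generalized Born (HCT)


def effective_born_radii(
    struct: ParameterizedStructure, config: Optional[EnergeticsConfig] = None
) -> np.ndarray:
    """HCT pairwise-descreening effective radii (vectorised over pairs)."""
    config = config or EnergeticsConfig()
    rho = struct.gb_radius - GB_OFFSET
    if np.any(rho <= 0):
        raise EnergeticsError("intrinsic GB radius at or below the HCT offset")
    r = cdist(struct.coord, struct.coord)
    srho = struct.gb_screen * rho
    with np.errstate(divide="ignore", invalid="ignore"):
        lij = np.maximum(rho[:, None], np.abs(r - srho[None, :]))
        uij = r + srho[None, :]
        term = 0.5 * (
            1.0 / lij
            - 1.0 / uij
            + 0.25 * r * (1.0 / uij**2 - 1.0 / lij**2)
            + 0.5 / r * np.log(lij / uij)
            + 0.25 * srho[None, :] ** 2 / r * (1.0 / lij**2 - 1.0 / uij**2)
        )
    np.fill_diagonal(term, 0.0)
    term[uij <= rho[:, None]] = 0.0  # neighbour buried inside atom i
    inv = 1.0 / rho - term.sum(axis=1)
    bad = inv <= 0
    if bad.any():
        logger.warning(
            "clamped %d nonpositive effective Born radii", int(bad.sum())
        )
    radii = np.where(bad, BORN_RADIUS_CLAMP, 1.0 / np.where(bad, 1.0, inv))
    return radii


def _gb_energy_matrix(
    struct: ParameterizedStructure,
    config: EnergeticsConfig,
    born_radii: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Symmetric matrix whose total over i<=j is the GB energy.

    Diagonal holds self terms; off-diagonal entries each hold half the
    pair energy so that ``matrix.sum()`` is the total.
    """
    radii = born_radii if born_radii is not None else \
        effective_born_radii(struct, config)
    q = struct.charge
    r2 = cdist(struct.coord, struct.coord) ** 2
    rr = np.outer(radii, radii)
    f = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
    tau = COULOMB * (
        1.0 / config.interior_dielectric
        - np.exp(-config.kappa * f) / config.solvent_dielectric
    )
    energy = -tau * np.outer(q, q) / f
    return 0.5 * energy  # halves double-counted off-diagonal; self term = -q^2/2R


def gb_pair_terms(
    struct: ParameterizedStructure,
    config: Optional[EnergeticsConfig] = None,
    born_radii: Optional[np.ndarray] = None,
) -> Dict[Tuple[int, int], float]:
    """Decomposed GB polar solvation: self (i, i) and cross (i, j), i < j.

    E_ij = -tau(f_ij) q_i q_j / f_ij with
    f_ij = sqrt(r^2 + R_i R_j exp(-r^2/(4 R_i R_j))) and
    tau(f) = 332.0636 (1/eps_in - exp(-kappa f)/eps_solv); the self term
    (f = R_i) carries the 1/2 of the double sum.
    """
    config = config or EnergeticsConfig()
    m = _gb_energy_matrix(struct, config, born_radii)
    terms: Dict[Tuple[int, int], float] = {}
    n = struct.n_atoms
    for i in range(n):
        terms[(i, i)] = float(m[i, i])
        for j in range(i + 1, n):
            terms[(i, j)] = float(m[i, j] + m[j, i])
    return terms


def gb_polar(
    struct: ParameterizedStructure, config: Optional[EnergeticsConfig] = None
) -> float:
    """Total GB polar solvation energy, kcal/mol."""
    config = config or EnergeticsConfig()
    return float(_gb_energy_matrix(struct, config).sum())


# ---------------------------------------------------------------------------
# nonpolar SASA term


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def shrake_rupley_sasa(
    coord: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    sphere_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2) by sphere sampling."""
    from scipy.spatial import cKDTree

    n = len(coord)
    points = _sphere_points(sphere_points)
    expanded = radii + probe_radius
    # zero-radius atoms have no surface and occlude nothing
    real = np.asarray(radii) > 0.0
    areas = np.zeros(n)
    if not real.any():
        return areas
    real_idx = np.where(real)[0]
    tree = cKDTree(coord[real_idx])
    max_r = float(expanded[real_idx].max())
    for i in real_idx:
        ri = expanded[i]
        neighbors = [
            real_idx[j]
            for j in tree.query_ball_point(coord[i], ri + max_r)
            if real_idx[j] != i
        ]
        test = coord[i] + ri * points
        accessible = np.ones(sphere_points, dtype=bool)
        for j in neighbors:
            accessible &= (
                np.sum((test - coord[j]) ** 2, axis=1) > expanded[j] ** 2
            )
        areas[i] = 4.0 * math.pi * ri**2 * accessible.mean()
    return areas


def sasa_nonpolar(
    struct: ParameterizedStructure, config: Optional[EnergeticsConfig] = None
) -> Tuple[float, np.ndarray]:
    """(energy kcal/mol, per-atom SASA) with E = surften * SASA + surfoff."""
    config = config or EnergeticsConfig()
    areas = shrake_rupley_sasa(
        struct.coord, struct.lj_radius,
        probe_radius=config.probe_radius,
        sphere_points=config.sphere_points,
    )
    return config.surften * float(areas.sum()) + config.surfoff, areas


# ---------------------------------------------------------------------------
# per-residue decomposition


@dataclass
class EnergyDecomposition:
    """Per-residue binding-energy contributions, kcal/mol."""

    table: pd.DataFrame  # rows: chain, res_id, res_name, elec, vdw, gb,
    #                      sasa, total (+ *_sem columns for ensembles)
    total: float
    total_sem: float = 0.0
    n_models: int = 1

    def residue_total(self, chain: str, res_id: int) -> float:
        row = self.table[
            (self.table.chain == chain) & (self.table.res_id == res_id)
        ]
        if row.empty:
            raise KeyError(f"no residue {chain}{res_id}")
        return float(row["total"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def per_residue_decomposition(
    model: struc.AtomArray,
    ligand: Selection,
    config: Optional[EnergeticsConfig] = None,
    table: Optional[ParameterTable] = None,
) -> EnergyDecomposition:
    """Single-model interaction-energy decomposition.

    Components: cross-partition Coulomb + van der Waals (1-4 scaled terms
    folded in), change in GB polar solvation and change in the SASA
    nonpolar term upon complexation.  Pair terms split half/half between
    the two residues involved, so residue totals sum to the interaction
    energy exactly.
    """
    config = config or EnergeticsConfig()
    pstruct = assign_params(model, table)
    lig_mask = ligand.mask(model)
    if not lig_mask.any():
        raise EnergeticsError("empty ligand selection")
    if lig_mask.all():
        raise EnergeticsError("ligand selection covers every atom")
    rec_mask = ~lig_mask

    n_res = len(pstruct.residues)
    ridx = pstruct.residue_index
    idx_a = np.where(rec_mask)[0]
    idx_b = np.where(lig_mask)[0]

    # gas-phase cross terms (intra-partition contributions cancel exactly)
    elec_m, vdw_m = _mm_cross_matrices(pstruct, idx_a, idx_b, config)
    elec_r = np.zeros(n_res)
    vdw_r = np.zeros(n_res)
    half_a_e = 0.5 * elec_m.sum(axis=1)
    half_b_e = 0.5 * elec_m.sum(axis=0)
    half_a_v = 0.5 * vdw_m.sum(axis=1)
    half_b_v = 0.5 * vdw_m.sum(axis=0)
    np.add.at(elec_r, ridx[idx_a], half_a_e)
    np.add.at(elec_r, ridx[idx_b], half_b_e)
    np.add.at(vdw_r, ridx[idx_a], half_a_v)
    np.add.at(vdw_r, ridx[idx_b], half_b_v)

    # GB: complex minus separated monomers, half/half per atom pair
    def gb_residue_vector(ps: ParameterizedStructure, res_map: np.ndarray):
        m = _gb_energy_matrix(ps, config)
        per_atom = 0.5 * (m.sum(axis=1) + m.sum(axis=0))
        vec = np.zeros(n_res)
        np.add.at(vec, res_map, per_atom)
        return vec

    gb_r = gb_residue_vector(pstruct, ridx)
    rec = pstruct.subset(rec_mask)
    lig = pstruct.subset(lig_mask)
    gb_r -= gb_residue_vector(rec, ridx[idx_a])
    gb_r -= gb_residue_vector(lig, ridx[idx_b])

    # SASA: per-atom change upon complexation
    _, areas_cplx = sasa_nonpolar(pstruct, config)
    _, areas_rec = sasa_nonpolar(rec, config)
    _, areas_lig = sasa_nonpolar(lig, config)
    d_area = areas_cplx.copy()
    d_area[idx_a] -= areas_rec
    d_area[idx_b] -= areas_lig
    sasa_r = np.zeros(n_res)
    np.add.at(sasa_r, ridx, config.surften * d_area)

    totals = elec_r + vdw_r + gb_r + sasa_r
    rows = pd.DataFrame(
        {
            "chain": [r[0] for r in pstruct.residues],
            "res_id": [r[1] for r in pstruct.residues],
            "res_name": [r[2] for r in pstruct.residues],
            "elec": elec_r,
            "vdw": vdw_r,
            "gb": gb_r,
            "sasa": sasa_r,
            "total": totals,
        }
    )
    return EnergyDecomposition(table=rows, total=float(totals.sum()))


def ensemble_mmgbsa(
    ensemble,
    ligand: Selection,
    config: Optional[EnergeticsConfig] = None,
    table: Optional[ParameterTable] = None,
) -> EnergyDecomposition:
    """Per-model decomposition with arithmetic mean and SEM per residue."""
    models = list(ensemble)
    if len(models) < 2:
        raise EnergeticsError("need at least 2 models for an ensemble SEM")
    decomps = [
        per_residue_decomposition(m, ligand, config, table) for m in models
    ]
    ref = decomps[0].table[["chain", "res_id", "res_name"]]
    for d in decomps[1:]:
        if not d.table[["chain", "res_id", "res_name"]].equals(ref):
            raise EnergeticsError("heterogeneous residue inventory across models")
    comps = ["elec", "vdw", "gb", "sasa", "total"]
    stacked = np.stack([d.table[comps].to_numpy() for d in decomps])
    mean = stacked.mean(axis=0)
    sem = stacked.std(axis=0, ddof=1) / math.sqrt(len(decomps))
    out = ref.copy()
    for k, comp in enumerate(comps):
        out[comp] = mean[:, k]
        out[comp + "_sem"] = sem[:, k]
    totals = np.array([d.total for d in decomps])
    return EnergyDecomposition(
        table=out,
        total=float(totals.mean()),
        total_sem=float(totals.std(ddof=1) / math.sqrt(len(decomps))),
        n_models=len(decomps),
    )
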