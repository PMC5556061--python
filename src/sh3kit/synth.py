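"""Seeded synthetic-data generators with machine-readable truth tables.

Every generator is deterministic under (seed, parameters, GENERATOR_VERSION)
and emits a TruthTable describing exactly what was planted, so downstream
stages can be tested without any external data.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from sh3kit import topology
from sh3kit.binding import (
    BindingParams,
    DoseResponse,
    FourPLParams,
    Titration,
    TitrationSchedule,
    simulate_displacement,
    simulate_itc,
)
from sh3kit.motif import (
    AMINO_ACIDS,
    CORE_LENGTH,
    MotifPattern,
    Peptide,
    PositionFrequencyMatrix,
    locate_core,
)

GENERATOR_VERSION = "1.0"

#: SwissProt-like amino-acid composition (fractions), configurable.
BACKGROUND_COMPOSITION: Dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}


class SynthError(ValueError):
    pass


@dataclass
class TruthTable:
    """What a generator planted, serialisable next to its artifacts."""

    kind: str
    seed: Optional[int]
    generator_version: str
    payload: Dict

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "kind": self.kind,
                    "seed": self.seed,
                    "generator_version": self.generator_version,
                    "payload": self.payload,
                },
                indent=2,
                default=_jsonable,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        data = json.loads(Path(path).read_text())
        return cls(
            kind=data["kind"],
            seed=data["seed"],
            generator_version=data["generator_version"],
            payload=data["payload"],
        )


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _background_sampler(rng: np.random.Generator,
                        composition: Optional[Mapping[str, float]] = None):
    comp = dict(composition or BACKGROUND_COMPOSITION)
    letters = sorted(comp)
    probs = np.array([comp[a] for a in letters], dtype=float)
    probs /= probs.sum()

    def draw(n: int) -> str:
        return "".join(rng.choice(letters, size=n, p=probs))

    return draw


def _sample_core(rng: np.random.Generator,
                 source: Union[MotifPattern, PositionFrequencyMatrix]) -> str:
    if isinstance(source, PositionFrequencyMatrix):
        core = []
        for col in source.probs:
            letters = sorted(col)
            probs = np.array([col[a] for a in letters])
            probs /= probs.sum()
            core.append(str(rng.choice(letters, p=probs)))
        return "".join(core)
    core = []
    for allowed in source.allowed:
        choices = sorted(allowed) if allowed is not None else list(AMINO_ACIDS)
        core.append(str(rng.choice(choices)))
    return "".join(core)


# ---------------------------------------------------------------------------
# peptide libraries


def gen_peptide_library(
    source: Union[MotifPattern, PositionFrequencyMatrix, None] = None,
    n: int = 14,
    seed: int = 0,
    peptide_length: int = 12,
    pattern: Optional[MotifPattern] = None,
) -> Tuple[List[Peptide], TruthTable]:
    """n peptides, each with exactly one motif core at a random offset."""
    if n < 1:
        raise SynthError("n must be >= 1")
    pattern = pattern or (
        source if isinstance(source, MotifPattern) else MotifPattern.default()
    )
    source = source or pattern
    rng = np.random.default_rng(seed)
    draw = _background_sampler(rng)
    peptides: List[Peptide] = []
    truth_rows = []
    for i in range(n):
        for _attempt in range(200):
            offset = int(rng.integers(0, peptide_length - CORE_LENGTH + 1))
            core = _sample_core(rng, source)
            seq = draw(offset) + core + draw(peptide_length - CORE_LENGTH - offset)
            pep = Peptide(id=f"lib{i + 1}", sequence=seq)
            if locate_core(pep, pattern) == [offset]:
                break
        else:
            raise SynthError("could not sample a single-core peptide")
        peptides.append(pep)
        truth_rows.append({"id": pep.id, "offset": offset, "core": core})
    truth = TruthTable(
        kind="peptide_library", seed=seed,
        generator_version=GENERATOR_VERSION,
        payload={"n": n, "peptide_length": peptide_length,
                 "peptides": truth_rows},
    )
    return peptides, truth


def write_peptides_fasta(peptides: Sequence[Peptide], path) -> None:
    lines = []
    for pep in peptides:
        lines.append(f">{pep.id}")
        lines.append(pep.sequence)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# proteomes


def gen_proteome(
    n_records: int,
    length_range: Tuple[int, int] = (200, 600),
    n_plants: int = 0,
    plant_positions: Optional[Sequence[Tuple[int, int]]] = None,
    seed: int = 0,
    pattern: Optional[MotifPattern] = None,
    reject_accidental: bool = True,
    composition: Optional[Mapping[str, float]] = None,
) -> Tuple[List[Tuple[str, str]], TruthTable]:
    """Synthetic proteome with planted motif windows and exact truth.

    Returns ([(record_id, sequence), ...], truth).  Plants are either
    ``n_plants`` windows at random feasible positions or explicit
    ``plant_positions`` [(record_index, 0-based offset), ...].
    """
    pattern = pattern or MotifPattern.default()
    rng = np.random.default_rng(seed)
    draw = _background_sampler(rng, composition)
    lengths = [
        int(rng.integers(length_range[0], length_range[1] + 1))
        for _ in range(n_records)
    ]

    if plant_positions is None:
        plant_positions = []
        for _ in range(n_plants):
            rec = int(rng.integers(0, n_records))
            if lengths[rec] < CORE_LENGTH:
                raise SynthError(f"record {rec} too short to plant into")
            plant_positions.append(
                (rec, int(rng.integers(0, lengths[rec] - CORE_LENGTH + 1)))
            )
    by_record: Dict[int, List[int]] = {}
    for rec, off in plant_positions:
        if rec >= n_records or off < 0 or off + CORE_LENGTH > lengths[rec]:
            raise SynthError(f"infeasible plant at record {rec} offset {off}")
        for other in by_record.get(rec, []):
            if abs(other - off) < CORE_LENGTH:
                raise SynthError("overlapping plants requested")
        by_record.setdefault(rec, []).append(off)

    records: List[Tuple[str, str]] = []
    truth_rows = []
    non_k = [a for a in AMINO_ACIDS if a != "K"]
    for rec_idx in range(n_records):
        seq = list(draw(lengths[rec_idx]))
        for off in by_record.get(rec_idx, []):
            core = _sample_core(rng, pattern)
            seq[off : off + CORE_LENGTH] = list(core)
            truth_rows.append(
                {"record_id": f"syn{rec_idx + 1}", "start": off + 1,
                 "window": core}
            )
        if reject_accidental:
            planted = set(by_record.get(rec_idx, []))
            for _round in range(100):
                text = "".join(seq)
                accidental = [
                    o for o in locate_core(Peptide("tmp", text), pattern)
                    if o not in planted
                ]
                if not accidental:
                    break
                for o in accidental:
                    # breaking the obligatory +2 lysine kills the window
                    seq[o + 3] = str(rng.choice(non_k))
            else:
                raise SynthError("accidental-core rejection did not converge")
        records.append((f"syn{rec_idx + 1}", "".join(seq)))

    truth = TruthTable(
        kind="proteome", seed=seed, generator_version=GENERATOR_VERSION,
        payload={
            "n_records": n_records,
            "reject_accidental": reject_accidental,
            "plants": truth_rows,
        },
    )
    return records, truth


def write_proteome_fasta(records: Sequence[Tuple[str, str]], path,
                         width: int = 60) -> None:
    lines = []
    for rec_id, seq in records:
        lines.append(f">{rec_id}")
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width])
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# toy complex template and jittered ensembles

LIGAND_SEQUENCE = ("PRO", "PRO", "PRO", "LYS", "PRO", "PRO", "ARG", "LEU")
RECEPTOR_SEQUENCE = ("GLY", "GLY", "GLY", "GLU", "GLU", "TRP", "SER", "ARG",
                     "GLY")
_CA_SPACING = 3.8
_RECEPTOR_Y = 13.0


def _indole_ring() -> Dict[str, np.ndarray]:
    """Planar fused pentagon/hexagon with ~1.4 A sides (local 2D coords)."""
    side = 1.41
    # pentagon CG-CD1-NE1-CE2-CD2, centre below CG
    r5 = side / (2.0 * math.sin(math.pi / 5.0))
    pent_names = ["CG", "CD1", "NE1", "CE2", "CD2"]
    pent = {}
    for k, name in enumerate(pent_names):
        ang = math.pi / 2.0 - 2.0 * math.pi * k / 5.0
        pent[name] = np.array([r5 * math.cos(ang), r5 * math.sin(ang) - r5])
    # hexagon fused on the CD2-CE2 edge, extending away from the pentagon
    a = pent["CD2"]
    b = pent["CE2"]
    edge_mid = 0.5 * (a + b)
    edge_dir = (b - a) / np.linalg.norm(b - a)
    normal = np.array([edge_dir[1], -edge_dir[0]])
    pent_centre = np.mean([pent[n] for n in pent_names], axis=0)
    if np.dot(normal, edge_mid - pent_centre) < 0:
        normal = -normal
    r6 = side  # hexagon circumradius equals its side
    hex_centre = edge_mid + normal * math.sqrt(r6**2 - (side / 2.0) ** 2)
    hex_names = ["CD2", "CE3", "CZ3", "CH2", "CZ2", "CE2"]
    start_ang = math.atan2(a[1] - hex_centre[1], a[0] - hex_centre[0])
    sweep = math.atan2(b[1] - hex_centre[1], b[0] - hex_centre[0]) - start_ang
    sweep = (sweep + 2 * math.pi) % (2 * math.pi)
    step = -2.0 * math.pi / 6.0 if sweep > math.pi else 2.0 * math.pi / 6.0
    ring = dict(pent)
    for k, name in enumerate(hex_names):
        ang = start_ang + step * k
        ring[name] = hex_centre + r6 * np.array([math.cos(ang), math.sin(ang)])
    return ring


def _sidechain_generic(resname: str, ca: np.ndarray,
                       direction: np.ndarray) -> Dict[str, np.ndarray]:
    """BFS placement of side-chain atoms along ``direction`` from CA."""
    bonds = topology.SIDECHAIN_BONDS[resname]
    children: Dict[str, List[str]] = {}
    for a, b in bonds:
        if b == "N":  # proline ring closure
            continue
        children.setdefault(a, []).append(b)
    coords: Dict[str, np.ndarray] = {}
    perp = np.array([0.0, 0.0, 1.0])
    zig = np.array([0.35, 0.0, 0.0])

    def place(name: str, parent_pos: np.ndarray, depth: int, branch: int):
        offset = direction * 1.45
        if branch > 0:
            offset = direction * 1.05 + perp * (0.95 * (1 if branch % 2 else -1))
        pos = parent_pos + offset + zig * ((-1) ** depth) * 0.5
        coords[name] = pos
        for k, child in enumerate(children.get(name, [])):
            place(child, pos, depth + 1, k if len(children[name]) > 1 else 0)

    if "CB" in children.get("CA", []) or ("CA", "CB") in bonds:
        cb = ca + direction * 1.52
        coords["CB"] = cb
        for k, child in enumerate(children.get("CB", [])):
            place(child, cb, 1, k if len(children.get("CB", [])) > 1 else 0)
    return coords


def _backbone_atoms(ca: np.ndarray) -> Dict[str, np.ndarray]:
    return {
        "N": ca + np.array([-1.30, 0.0, 0.60]),
        "CA": ca,
        "C": ca + np.array([1.30, 0.0, 0.60]),
        "O": ca + np.array([1.30, 0.0, 1.83]),
    }


def _chain_between(names: Sequence[str], start: np.ndarray,
                   end: np.ndarray) -> Dict[str, np.ndarray]:
    """Place atoms evenly between two anchor positions (exclusive)."""
    coords = {}
    n = len(names) + 1
    for k, name in enumerate(names, start=1):
        coords[name] = start + (end - start) * (k / n)
    return coords


def template_complex() -> struc.AtomArray:
    """Hand-built toy receptor-ligand complex with planted interactions.

    Chain A: 9-residue strand presenting Glu, Trp, Ser and Arg side
    chains toward the ligand.  Chain B: PPPKPPRL-like 8-mer.  Planted:
    a Lys(NZ, B4)-Glu(OE1, A4) salt bridge, Ser(OG, A7)-Arg(NH1, B7) and
    Arg(NH1, A8)-Leu(O, B8) hydrogen bonds, and Trp(A6) ring carbons
    packed against Pro(B6).
    """
    atoms: List[Tuple[str, int, str, str, np.ndarray]] = []
    down = np.array([0.0, -1.0, 0.0])
    up = np.array([0.0, 1.0, 0.0])

    # --- ligand chain B along x at y ~ 0, side chains pointing up
    lig_coords: Dict[Tuple[int, str], np.ndarray] = {}
    for i, resname in enumerate(LIGAND_SEQUENCE):
        res_id = i + 1
        ca = np.array([_CA_SPACING * i, 0.0, 0.0])
        pos = _backbone_atoms(ca)
        pos.update(_sidechain_generic(resname, ca, up))
        for name, xyz in pos.items():
            atoms.append(("B", res_id, resname, name, xyz))
            lig_coords[(res_id, name)] = xyz

    # --- receptor chain A, special side chains targeted at ligand atoms
    special: Dict[int, Dict[str, np.ndarray]] = {}

    # A4/A5 Glu pair flanking the ligand Lys NZ with bidentate carboxylates
    nz = lig_coords[(4, "NZ")]
    zhat = np.array([0.0, 0.0, 1.0])

    def glu_sidechain(sign: float) -> Dict[str, np.ndarray]:
        u = np.array([0.8 * sign, 1.0, 0.0])
        u /= np.linalg.norm(u)
        cd = nz + u * 3.3
        return {
            "CD": cd,
            "OE1": cd - u * 0.63 + zhat * 1.08,
            "OE2": cd - u * 0.63 - zhat * 1.08,
            "CG": cd + u * 1.5,
            "CB": cd + u * 3.0,
            "CA": cd + u * 4.5,
        }

    special[4] = glu_sidechain(-1.0)
    special[5] = glu_sidechain(1.0)

    # A6 Trp: indole plane vertical, lowest ring atoms ~3.95 A above Pro B6 CG
    pro_cg = lig_coords[(6, "CG")]
    ring2d = _indole_ring()
    ring = {n: np.array([p[0], p[1], 0.0]) for n, p in ring2d.items()}
    lowest = min(p[1] for p in ring.values())
    shift = np.array([pro_cg[0], pro_cg[1] + 3.95 - lowest, pro_cg[2]])
    ring = {n: p + shift for n, p in ring.items()}
    cb6 = ring["CG"] + np.array([0.35, 1.45, 0.0])
    ca6 = cb6 + np.array([-0.35, 1.50, 0.0])
    special[6] = {"CA": ca6, "CB": cb6, **ring}

    # A7 Ser: OG 3.2 A above the ligand Arg NH1
    nh1_b = lig_coords[(7, "NH1")]
    og = nh1_b + up * 3.2
    cb7 = og + np.array([0.30, 1.40, 0.0])
    ca7 = cb7 + np.array([-0.30, 1.50, 0.0])
    special[7] = {"CA": ca7, "CB": cb7, "OG": og}

    # A8 Arg: NH1 3.2 A from the ligand Leu backbone O, approached from +x
    leu_o = lig_coords[(8, "O")]
    nh1_a = leu_o + np.array([2.26, 2.26, 0.0])
    cz = nh1_a + np.array([0.40, 1.20, 0.0])
    nh2 = cz + np.array([1.20, 0.35, 0.0])
    ne = cz + np.array([-0.50, 1.20, 0.0])
    cd8 = ne + np.array([0.40, 1.35, 0.0])
    cg8 = cd8 + np.array([-0.40, 1.35, 0.0])
    cb8 = cg8 + np.array([0.40, 1.35, 0.0])
    ca8 = cb8 + np.array([-0.30, 1.40, 0.0])
    special[8] = {"CA": ca8, "CB": cb8, "CG": cg8, "CD": cd8, "NE": ne,
                  "CZ": cz, "NH1": nh1_a, "NH2": nh2}

    for i, resname in enumerate(RECEPTOR_SEQUENCE):
        res_id = i + 1
        if res_id in special:
            pos = dict(special[res_id])
            ca = pos["CA"]
            backbone = _backbone_atoms(ca)
            backbone["O"] = ca + np.array([1.30, 0.0, -1.83])  # point away
            backbone["C"] = ca + np.array([1.30, 0.0, -0.60])
            backbone["N"] = ca + np.array([-1.30, 0.0, -0.60])
            pos.update(backbone)
        else:
            ca = np.array([_CA_SPACING * i, _RECEPTOR_Y, 0.0])
            pos = _backbone_atoms(ca)
            pos["O"] = ca + np.array([1.30, 0.0, -1.83])
            pos["C"] = ca + np.array([1.30, 0.0, -0.60])
            pos["N"] = ca + np.array([-1.30, 0.0, -0.60])
        for name in topology.residue_atoms(resname):
            if name in pos:
                atoms.append(("A", res_id, resname, name, pos[name]))

    # ring of neutral Ala "pocket wall" residues partially burying the
    # lysine site (non-consecutive ids: no artificial peptide bonds)
    centre = nz + np.array([0.0, 1.0, 0.0])
    for w in range(6):
        ang = 2.0 * math.pi * w / 6.0
        cb = centre + np.array([4.0 * math.cos(ang), 0.0, 4.0 * math.sin(ang)])
        ca = cb + np.array([0.0, 1.5, 0.0])
        pos = {
            "CB": cb, "CA": ca,
            "N": ca + np.array([-1.30, 0.0, -0.60]),
            "C": ca + np.array([1.30, 0.0, -0.60]),
            "O": ca + np.array([1.30, 0.0, -1.83]),
        }
        res_id = 11 + 2 * w
        for name in topology.residue_atoms("ALA"):
            atoms.append(("A", res_id, "ALA", name, pos[name]))

    array = struc.AtomArray(len(atoms))
    for k, (chain, res_id, resname, name, xyz) in enumerate(atoms):
        array.chain_id[k] = chain
        array.res_id[k] = res_id
        array.res_name[k] = resname
        array.atom_name[k] = name
        array.element[k] = topology.element_of(name)
        array.coord[k] = xyz
        array.hetero[k] = False
    return array


#: Interactions planted in the template, as (kind, receptor atom, ligand atom).
PLANTED_CONTACTS = (
    ("salt_bridge", ("A", 4, "GLU", "OE1"), ("B", 4, "LYS", "NZ")),
    ("salt_bridge", ("A", 5, "GLU", "OE1"), ("B", 4, "LYS", "NZ")),
    ("hbond", ("A", 7, "SER", "OG"), ("B", 7, "ARG", "NH1")),
    ("hbond", ("A", 8, "ARG", "NH1"), ("B", 8, "LEU", "O")),
    ("nonpolar", ("A", 6, "TRP", None), ("B", 6, "PRO", None)),
)


def _naive_contact_scan(model: struc.AtomArray, ligand_chain: str = "B",
                        hbond_max: float = 3.5, salt_max: float = 4.0,
                        nonpolar_max: float = 4.5) -> List[Tuple]:
    """Independent all-pairs contact oracle over every atom pair."""
    out = []
    n = model.array_length()
    for i in range(n):
        if str(model.chain_id[i]) == ligand_chain:
            continue
        rn, ra = str(model.res_name[i]), str(model.atom_name[i])
        for j in range(n):
            if str(model.chain_id[j]) != ligand_chain:
                continue
            ln, la = str(model.res_name[j]), str(model.atom_name[j])
            d = float(np.linalg.norm(model.coord[i] - model.coord[j]))
            key_a = (str(model.chain_id[i]), int(model.res_id[i]), rn, ra)
            key_b = (str(model.chain_id[j]), int(model.res_id[j]), ln, la)
            if d <= salt_max and (
                (topology.is_cationic(rn, ra) and topology.is_anionic(ln, la))
                or (topology.is_anionic(rn, ra) and topology.is_cationic(ln, la))
            ):
                out.append(("salt_bridge", key_a, key_b, d))
            if d <= hbond_max and (
                (topology.is_donor(rn, ra) and topology.is_acceptor(ln, la))
                or (topology.is_donor(ln, la) and topology.is_acceptor(rn, ra))
            ):
                out.append(("hbond", key_a, key_b, d))
            if (d <= nonpolar_max
                    and ra in topology.apolar_carbons(rn)
                    and la in topology.apolar_carbons(ln)):
                out.append(("nonpolar", key_a, key_b, d))
    return out


def expected_contact_occupancy(distance: float, cutoff: float,
                               jitter_sd: float) -> float:
    """P(jittered distance <= cutoff) for i.i.d. Gaussian coordinate jitter."""
    if jitter_sd == 0:
        return 1.0 if distance <= cutoff else 0.0
    from scipy.stats import ncx2

    s2 = 2.0 * jitter_sd**2
    return float(ncx2.cdf(cutoff**2 / s2, 3, distance**2 / s2))


def gen_complex_ensemble(
    template: Optional[struc.AtomArray] = None,
    n_models: int = 40,
    jitter_sd: float = 0.3,
    seed: int = 0,
    out_path=None,
) -> Tuple[struc.AtomArrayStack, TruthTable]:
    """Jittered copies of the template with a contact truth table."""
    if jitter_sd < 0:
        raise SynthError("jitter_sd must be non-negative")
    template = template if template is not None else template_complex()
    rng = np.random.default_rng(seed)
    stack = struc.stack([template] * n_models)
    noise = rng.normal(0.0, jitter_sd, size=stack.coord.shape) \
        if jitter_sd > 0 else np.zeros(stack.coord.shape)
    stack.coord = stack.coord + noise

    cutoffs = {"hbond": 3.5, "salt_bridge": 4.0, "nonpolar": 4.5}
    baseline = _naive_contact_scan(template)
    contact_rows = []
    for kind, key_a, key_b, dist in baseline:
        contact_rows.append(
            {
                "kind": kind,
                "receptor": list(key_a),
                "ligand": list(key_b),
                "distance": dist,
                "expected_occupancy": expected_contact_occupancy(
                    dist, cutoffs[kind], jitter_sd
                ),
            }
        )
    truth = TruthTable(
        kind="complex_ensemble", seed=seed,
        generator_version=GENERATOR_VERSION,
        payload={
            "n_models": n_models,
            "jitter_sd": jitter_sd,
            "ligand_chain": "B",
            "planted": [
                {"kind": k, "receptor": list(a), "ligand": list(b)}
                for k, a, b in (
                    (p[0], p[1], p[2]) for p in PLANTED_CONTACTS
                )
            ],
            "template_contacts": contact_rows,
        },
    )
    if out_path is not None:
        write_ensemble_pdb(stack, out_path)
    return stack, truth


def write_ensemble_pdb(stack: struc.AtomArrayStack, path) -> None:
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# titrations and displacement curves


def gen_titrations(
    truth: BindingParams,
    replicates: int = 3,
    noise_sd: float = 0.1,
    seed: int = 0,
    schedule: Optional[TitrationSchedule] = None,
    out_dir=None,
    label: str = "itc",
) -> Tuple[List[Titration], TruthTable]:
    """Replicate titrations with independent seeds and a truth table."""
    schedule = schedule or TitrationSchedule()
    titrations = [
        simulate_itc(truth, schedule, noise_sd=noise_sd, seed=seed + i)
        for i in range(replicates)
    ]
    table = TruthTable(
        kind="titrations", seed=seed, generator_version=GENERATOR_VERSION,
        payload={
            "kd": truth.kd, "dh": truth.dh, "n": truth.n,
            "noise_sd": noise_sd, "replicates": replicates,
            "schedule": asdict(schedule),
        },
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, t in enumerate(titrations, start=1):
            t.to_tsv(out_dir / f"{label}_rep{i}.tsv")
        table.to_json(out_dir / f"{label}_truth.json")
    return titrations, table


def gen_displacement_curves(
    truth: FourPLParams,
    doses: np.ndarray,
    replicates: int = 3,
    noise_sd: Optional[float] = None,
    seed: int = 0,
    out_dir=None,
    label: str = "elisa",
) -> Tuple[List[DoseResponse], TruthTable]:
    """Replicate 4PL displacement curves (noise defaults to 2% of top)."""
    if noise_sd is None:
        noise_sd = 0.02 * truth.top
    curves = [
        simulate_displacement(truth, doses, noise_sd=noise_sd, seed=seed + i)
        for i in range(replicates)
    ]
    table = TruthTable(
        kind="displacement_curves", seed=seed,
        generator_version=GENERATOR_VERSION,
        payload={
            "ec50": truth.ec50, "top": truth.top, "bottom": truth.bottom,
            "hill": truth.hill, "noise_sd": noise_sd,
            "replicates": replicates, "doses": list(map(float, doses)),
        },
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, c in enumerate(curves, start=1):
            c.to_tsv(out_dir / f"{label}_rep{i}.tsv")
        table.to_json(out_dir / f"{label}_truth.json")
    return curves, table
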