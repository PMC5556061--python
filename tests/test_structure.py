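import numpy as np
import pandas as pd
import pytest

import biotite.structure as struc

from sh3kit import topology
from sh3kit.structure import (
    ContactCriteria,
    EnsembleFormatError,
    Selection,
    StructureEnsemble,
    StructureError,
    backbone_rmsd,
    classify_pockets,
    detect_contacts,
    ensemble_occupancy,
    load_ensemble,
    occupancy_band,
    relative_csp,
    strip_linker,
)
from sh3kit.synth import gen_complex_ensemble, template_complex, write_ensemble_pdb


def make_atoms(rows):
    """rows: (chain, res_id, res_name, atom_name, xyz)"""
    arr = struc.AtomArray(len(rows))
    for k, (chain, res_id, res_name, atom_name, xyz) in enumerate(rows):
        arr.chain_id[k] = chain
        arr.res_id[k] = res_id
        arr.res_name[k] = res_name
        arr.atom_name[k] = atom_name
        arr.element[k] = topology.element_of(atom_name)
        arr.coord[k] = xyz
    return arr


def oracle_contacts(model, ligand_chain, criteria):
    """Test-local all-pairs brute-force contact detection."""
    out = set()
    n = model.array_length()
    for i in range(n):
        if str(model.chain_id[i]) == ligand_chain:
            continue
        rn, ra = str(model.res_name[i]), str(model.atom_name[i])
        if rn not in topology.STANDARD_RESIDUES:
            continue
        for j in range(n):
            if str(model.chain_id[j]) != ligand_chain:
                continue
            ln, la = str(model.res_name[j]), str(model.atom_name[j])
            if ln not in topology.STANDARD_RESIDUES:
                continue
            d = float(np.linalg.norm(model.coord[i] - model.coord[j]))
            ka = (str(model.chain_id[i]), int(model.res_id[i]), rn, ra)
            kb = (str(model.chain_id[j]), int(model.res_id[j]), ln, la)
            if d <= criteria.salt_no_max and (
                (topology.is_cationic(rn, ra) and topology.is_anionic(ln, la))
                or (topology.is_anionic(rn, ra)
                    and topology.is_cationic(ln, la))
            ):
                out.add(("salt_bridge", ka, kb))
            if d <= criteria.hbond_da_max and (
                (topology.is_donor(rn, ra) and topology.is_acceptor(ln, la))
                or (topology.is_donor(ln, la) and topology.is_acceptor(rn, ra))
            ):
                out.add(("hbond", ka, kb))
            if (d <= criteria.nonpolar_cc_max
                    and ra in topology.apolar_carbons(rn)
                    and la in topology.apolar_carbons(ln)):
                out.add(("nonpolar", ka, kb))
    return out


def salt_pair(distance):
    return make_atoms([
        ("A", 1, "GLU", "OE1", (0.0, 0.0, 0.0)),
        ("B", 1, "LYS", "NZ", (distance, 0.0, 0.0)),
    ])


class TestLoadEnsemble:
    def test_forty_model_fixture(self, tmp_path):
        stack, _ = gen_complex_ensemble(n_models=40, jitter_sd=0.1, seed=1)
        path = tmp_path / "ens.pdb"
        write_ensemble_pdb(stack, path)
        ens = load_ensemble(path)
        assert ens.n_models == 40

    def test_single_model(self, tmp_path, template):
        path = tmp_path / "one.pdb"
        write_ensemble_pdb(struc.stack([template]), path)
        assert load_ensemble(path).n_models == 1

    def test_truncated_file(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text("MODEL     1\nATOM  garbage\n")
        with pytest.raises(EnsembleFormatError):
            load_ensemble(path)

    def test_inconsistent_models_named(self, tmp_path, template):
        path = tmp_path / "ens.pdb"
        write_ensemble_pdb(struc.stack([template] * 3), path)
        lines = path.read_text().splitlines()
        # drop one ATOM line from the second MODEL block
        starts = [i for i, l in enumerate(lines) if l.startswith("MODEL")]
        del lines[starts[1] + 5]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(EnsembleFormatError, match="model"):
            load_ensemble(path)


class TestStripLinker:
    def test_linker_removed_everywhere(self, template):
        ens = StructureEnsemble(
            stack=struc.stack([template] * 4),
            peptide_selection=Selection(chain="B"),
        )
        stripped = strip_linker(ens, (4, 5), chain="A")
        for model in stripped:
            mask = (model.chain_id == "A") & np.isin(model.res_id, [4, 5])
            assert not mask.any()

    def test_empty_range_is_identity(self, template):
        ens = StructureEnsemble(stack=struc.stack([template]))
        assert strip_linker(ens) is ens

    def test_total_removal_rejected(self, template):
        ens = StructureEnsemble(stack=struc.stack([template]))
        with pytest.raises(StructureError):
            strip_linker(ens, (1, 999))

    def test_no_contacts_from_stripped_residues(self, template):
        ens = StructureEnsemble(
            stack=struc.stack([template]),
            peptide_selection=Selection(chain="B"),
        )
        stripped = strip_linker(ens, (4, 4), chain="A")
        contacts = detect_contacts(
            stripped.model(0), ligand=Selection(chain="B")
        )
        assert not any(
            c.partner_a[0] == "A" and c.partner_a[1] == 4 for c in contacts
        )


class TestDetectContacts:
    def test_close_salt_bridge_and_hbond(self):
        contacts = detect_contacts(
            salt_pair(2.9), ligand=Selection(chain="B")
        )
        kinds = {c.kind for c in contacts}
        assert kinds == {"salt_bridge", "hbond"}

    def test_distant_pair_no_contacts(self):
        assert detect_contacts(salt_pair(6.0),
                               ligand=Selection(chain="B")) == []

    def test_template_equals_oracle(self, template):
        criteria = ContactCriteria()
        got = {
            (c.kind, c.partner_a, c.partner_b)
            for c in detect_contacts(template, criteria,
                                     Selection(chain="B"))
        }
        assert got == oracle_contacts(template, "B", criteria)

    def test_jittered_models_equal_oracle(self, small_ensemble):
        stack, _ = small_ensemble
        criteria = ContactCriteria()
        for i in range(3):
            model = stack[i]
            got = {
                (c.kind, c.partner_a, c.partner_b)
                for c in detect_contacts(model, criteria,
                                         Selection(chain="B"))
            }
            assert got == oracle_contacts(model, "B", criteria)

    def test_unknown_residue_excluded_not_fatal(self):
        atoms = make_atoms([
            ("A", 1, "XYZ", "OE1", (0.0, 0.0, 0.0)),
            ("A", 2, "GLU", "OE1", (0.0, 3.0, 0.0)),
            ("B", 1, "LYS", "NZ", (2.9, 0.0, 0.0)),
        ])
        contacts = detect_contacts(atoms, ligand=Selection(chain="B"))
        assert all(c.partner_a[2] != "XYZ" for c in contacts)

    def test_requires_partition(self, template):
        with pytest.raises(StructureError):
            detect_contacts(template, ligand=Selection(chain="Z"))

    def test_monotone_under_cutoff_shrink(self, template):
        loose = ContactCriteria()
        tight = ContactCriteria(hbond_da_max=3.0, salt_no_max=3.2,
                                nonpolar_cc_max=4.0)
        n_loose = len(detect_contacts(template, loose, Selection(chain="B")))
        n_tight = len(detect_contacts(template, tight, Selection(chain="B")))
        assert n_tight <= n_loose


class TestOccupancy:
    def _ensemble_with_partial_contact(self, present_in, n_models=10):
        """Salt bridge present only in the first ``present_in`` models."""
        models = []
        for i in range(n_models):
            d = 2.9 if i < present_in else 8.0
            models.append(salt_pair(d))
        # pad to equal inventories (they already are)
        return StructureEnsemble(stack=struc.stack(models),
                                 peptide_selection=Selection(chain="B"))

    @pytest.mark.parametrize("present,expected_band", [
        (9, "moderate"), (10, "conserved"), (3, "transient"), (2, "weak"),
    ])
    def test_exact_counts_and_bands(self, present, expected_band):
        ens = self._ensemble_with_partial_contact(present)
        table = ensemble_occupancy(ens)
        key = ("salt_bridge", ("A", 1, "GLU"), ("B", 1, "LYS"))
        assert table.rows[key] == pytest.approx(present / 10)
        assert table.band(key) == expected_band

    def test_band_edges(self):
        assert occupancy_band(0.91) == "conserved"
        assert occupancy_band(0.90) == "moderate"
        assert occupancy_band(0.51) == "moderate"
        assert occupancy_band(0.50) == "transient"
        assert occupancy_band(0.21) == "transient"
        assert occupancy_band(0.20) == "weak"

    def test_occupancies_in_unit_interval(self, small_ensemble):
        stack, _ = small_ensemble
        ens = StructureEnsemble(stack=stack,
                                peptide_selection=Selection(chain="B"))
        table = ensemble_occupancy(ens)
        assert all(0 < v <= 1 for v in table.rows.values())

    def test_monotone_under_cutoff_shrink(self, small_ensemble):
        stack, _ = small_ensemble
        ens = StructureEnsemble(stack=stack,
                                peptide_selection=Selection(chain="B"))
        loose = ensemble_occupancy(ens, ContactCriteria())
        tight = ensemble_occupancy(
            ens, ContactCriteria(hbond_da_max=3.2, salt_no_max=3.5,
                                 nonpolar_cc_max=4.0))
        for key, occ in tight.rows.items():
            assert occ <= loose.rows.get(key, 0.0) + 1e-12

    def test_zero_jitter_planted_occupancy_one(self):
        stack, truth = gen_complex_ensemble(n_models=5, jitter_sd=0.0, seed=0)
        ens = StructureEnsemble(stack=stack,
                                peptide_selection=Selection(chain="B"))
        table = ensemble_occupancy(ens)
        for row in truth.payload["template_contacts"]:
            key = (row["kind"],
                   tuple(row["receptor"][:3]), tuple(row["ligand"][:3]))
            key = (key[0], (key[1][0], int(key[1][1]), key[1][2]),
                   (key[2][0], int(key[2][1]), key[2][2]))
            assert table.rows[key] == pytest.approx(1.0)


class TestPockets:
    def test_pocket_assignment(self, template):
        contacts = detect_contacts(template, ligand=Selection(chain="B"))
        pocket_map = {4: "pocket2", 5: "pocket2", 6: "pocket1"}
        positions = {4: "+2", 6: "+3"}
        out = classify_pockets(contacts, pocket_map, positions)
        assert "pocket2" in out["+2"]
        assert "pocket1" in out["+3"]

    def test_no_contacts_empty(self):
        assert classify_pockets([], {1: "pocket1"}) == {}

    def test_unmapped_receptor_is_outside(self, template):
        contacts = detect_contacts(template, ligand=Selection(chain="B"))
        out = classify_pockets(contacts, pocket_map={})
        assert all(v == {"outside"} for v in out.values())


class TestBackboneRmsd:
    def test_identity_zero(self, template):
        assert backbone_rmsd(template, template) == pytest.approx(0.0, abs=1e-6)

    def test_rigid_motion_invariance(self, template, rng):
        moved = template.copy()
        # random rotation + translation
        q = rng.normal(size=(3, 3))
        u, _, vt = np.linalg.svd(q)
        rot = u @ vt
        if np.linalg.det(rot) < 0:
            rot[:, 0] *= -1
        moved.coord = template.coord @ rot.T + np.array([5.0, -3.0, 2.0])
        assert backbone_rmsd(template, moved) == pytest.approx(0.0, abs=1e-6)

    def test_unit_shift_without_superposition(self, template):
        moved = template.copy()
        moved.coord = template.coord + np.array([1.0, 0.0, 0.0])
        assert backbone_rmsd(template, moved,
                             superimpose=False) == pytest.approx(1.0)

    def test_symmetry(self, template, rng):
        moved = template.copy()
        moved.coord = template.coord + rng.normal(0, 0.4,
                                                  size=template.coord.shape)
        assert backbone_rmsd(template, moved) == pytest.approx(
            backbone_rmsd(moved, template), abs=1e-6)

    def test_missing_residues_listed(self, template):
        with pytest.raises(StructureError, match="999"):
            backbone_rmsd(template, template, residue_range=(1, 999))


class TestRelativeCsp:
    def _table(self, residues, h, n):
        return pd.DataFrame({"residue": residues, "H_ppm": h, "N_ppm": n})

    def test_identical_tables_flagged_zero(self):
        t = self._table([1, 2, 3], [8.0, 8.1, 8.2], [118.0, 119.0, 120.0])
        out = relative_csp(t, t.copy())
        assert out.all_zero
        assert np.allclose(out.relative_csp, 0.0)

    def test_hand_arithmetic(self):
        free = self._table([1, 2, 3], [8.0, 8.0, 8.0], [120.0, 120.0, 120.0])
        bound = self._table([1, 2, 3], [8.1, 8.0, 8.0],
                            [120.5, 120.0, 120.0])
        out = relative_csp(free, bound, alpha=0.2)
        assert out.csp[0] == pytest.approx(np.sqrt(0.01 + 0.01))
        assert out.csp[1] == pytest.approx(0.0)

    def test_unit_standard_deviation(self, rng):
        residues = list(range(1, 21))
        free = self._table(residues, rng.normal(8, 0.1, 20),
                           rng.normal(119, 2, 20))
        bound = self._table(residues, rng.normal(8, 0.1, 20),
                            rng.normal(119, 2, 20))
        out = relative_csp(free, bound)
        assert np.std(out.relative_csp, ddof=1) == pytest.approx(1.0)

    def test_too_few_overlapping(self):
        free = self._table([1, 2], [8.0, 8.1], [118.0, 119.0])
        bound = self._table([2, 3], [8.0, 8.1], [118.0, 119.0])
        with pytest.raises(StructureError):
            relative_csp(free, bound)
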