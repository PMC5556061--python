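import math

import numpy as np
import pytest

import biotite.structure as struc

from sh3kit import topology
from sh3kit.energetics import (
    COULOMB,
    GB_OFFSET,
    EnergeticsConfig,
    EnergeticsError,
    ParameterizedStructure,
    assign_params,
    effective_born_radii,
    ensemble_mmgbsa,
    gb_pair_terms,
    gb_polar,
    interface_mm_energy,
    mm_pair_energy,
    per_residue_decomposition,
    sasa_nonpolar,
    shrake_rupley_sasa,
)
from sh3kit.params import ParameterError, default_parameter_table
from sh3kit.structure import Selection
from sh3kit.synth import gen_complex_ensemble, template_complex
from tests.test_structure import make_atoms


def bare_structure(charges, coords, gb_radii=None, lj_radii=None,
                   lj_eps=None, screens=None):
    """Hand-built ParameterizedStructure with no bonds/exclusions."""
    n = len(charges)
    rows = [("A", i + 1, "GLY", "CA", coords[i]) for i in range(n)]
    atoms = make_atoms(rows)
    return ParameterizedStructure(
        atoms=atoms,
        charge=np.asarray(charges, dtype=float),
        lj_radius=np.asarray(lj_radii if lj_radii is not None
                             else [1.908] * n, dtype=float),
        lj_epsilon=np.asarray(lj_eps if lj_eps is not None
                              else [0.086] * n, dtype=float),
        gb_radius=np.asarray(gb_radii if gb_radii is not None
                             else [1.7] * n, dtype=float),
        gb_screen=np.asarray(screens if screens is not None
                             else [0.72] * n, dtype=float),
        residue_index=np.arange(n),
        residues=[("A", i + 1, "GLY") for i in range(n)],
        excluded=set(),
        scaled_14=set(),
    )


def gly_dipeptide():
    rows = []
    for res_id, x in ((1, 0.0), (2, 3.8)):
        rows += [
            ("A", res_id, "GLY", "N", (x - 1.3, 0.0, 0.6)),
            ("A", res_id, "GLY", "CA", (x, 0.0, 0.0)),
            ("A", res_id, "GLY", "C", (x + 1.3, 0.0, 0.6)),
            ("A", res_id, "GLY", "O", (x + 1.3, 0.0, 1.83)),
        ]
    return make_atoms(rows)


class TestAssignParams:
    def test_gly_dipeptide_neutral(self):
        p = assign_params(gly_dipeptide())
        assert p.charge.sum() == pytest.approx(0.0, abs=1e-3)

    @pytest.mark.parametrize("res,expected", sorted(
        topology.FORMAL_CHARGE.items()))
    def test_formal_charges(self, res, expected):
        table = default_parameter_table()
        assert table.residue_charge(res) == pytest.approx(expected, abs=1e-3)

    def test_unknown_residue_rejected(self):
        atoms = make_atoms([("A", 1, "XYZ", "CA", (0, 0, 0))])
        with pytest.raises((EnergeticsError, ParameterError)):
            assign_params(atoms)

    def test_exclusions_built(self):
        p = assign_params(gly_dipeptide())
        names = {(int(p.atoms.res_id[i]), str(p.atoms.atom_name[i])): i
                 for i in range(p.n_atoms)}
        n1, ca1, c1 = names[(1, "N")], names[(1, "CA")], names[(1, "C")]
        n2 = names[(2, "N")]
        assert (min(n1, ca1), max(n1, ca1)) in p.excluded      # 1-2
        assert (min(n1, c1), max(n1, c1)) in p.excluded        # 1-3
        assert (min(n1, n2), max(n1, n2)) in p.scaled_14       # 1-4


class TestMmPairEnergy:
    def test_unit_charges_at_reference_distance(self):
        s = bare_structure([1.0, -1.0], [(0, 0, 0), (3.320636, 0, 0)])
        elec, _ = mm_pair_energy(s, 0, 1)
        assert elec == pytest.approx(-100.0, abs=0.01)

    def test_zero_charge_pair(self):
        s = bare_structure([0.0, 0.0], [(0, 0, 0), (3.0, 0, 0)])
        elec, _ = mm_pair_energy(s, 0, 1)
        assert elec == 0.0

    def test_lj_minimum(self):
        s = bare_structure([0.0, 0.0], [(0, 0, 0), (2 * 1.908, 0, 0)],
                           lj_radii=[1.908, 1.908], lj_eps=[0.086, 0.086])
        _, vdw = mm_pair_energy(s, 0, 1)
        assert vdw == pytest.approx(-0.086, rel=1e-9)

    def test_zero_distance_rejected(self):
        s = bare_structure([1.0, 1.0], [(0, 0, 0), (0, 0, 0)])
        with pytest.raises(EnergeticsError):
            mm_pair_energy(s, 0, 1)

    def test_excluded_pair_rejected(self):
        s = bare_structure([1.0, 1.0], [(0, 0, 0), (1.5, 0, 0)])
        s.excluded.add((0, 1))
        with pytest.raises(EnergeticsError):
            mm_pair_energy(s, 0, 1)

    def test_pair_sum_oracle_on_template(self, template, ligand_selection):
        pstruct = assign_params(template)
        mask = ligand_selection.mask(template)
        config = EnergeticsConfig()
        elec_total, vdw_total = interface_mm_energy(pstruct, mask, config)
        # brute-force double loop over all cross pairs
        brute_e = brute_v = 0.0
        for i in np.where(~mask)[0]:
            for j in np.where(mask)[0]:
                pair = (min(int(i), int(j)), max(int(i), int(j)))
                if pair in pstruct.excluded:
                    continue
                e, v = mm_pair_energy(pstruct, int(i), int(j), config)
                brute_e += e
                brute_v += v
        assert elec_total == pytest.approx(brute_e, abs=1e-6)
        assert vdw_total == pytest.approx(brute_v, abs=1e-6)


class TestGbPolar:
    def test_born_limit_single_ion(self):
        a = 2.0
        config = EnergeticsConfig(ionic_strength=0.0)
        s = bare_structure([1.5], [(0, 0, 0)], gb_radii=[a + GB_OFFSET])
        expected = -0.5 * COULOMB * 1.5**2 * (1 - 1 / 78.5) / a
        assert gb_polar(s, config) == pytest.approx(expected, rel=1e-9)

    def test_distant_ions_additive(self):
        config = EnergeticsConfig(ionic_strength=0.0)
        far = bare_structure([1.0, -1.0], [(0, 0, 0), (1.0e8, 0, 0)])
        lone1 = bare_structure([1.0], [(0, 0, 0)])
        lone2 = bare_structure([-1.0], [(0, 0, 0)])
        total = gb_polar(far, config)
        assert total == pytest.approx(
            gb_polar(lone1, config) + gb_polar(lone2, config), abs=1e-5)

    def test_salt_screening_weakens_interaction(self):
        # screened net pair electrostatics (Coulomb + GB cross term) must
        # not exceed the unscreened one in magnitude
        s = bare_structure([1.0, -1.0], [(0, 0, 0), (4.0, 0, 0)])

        def net(config):
            elec = COULOMB * (1.0 * -1.0) / 4.0
            return elec + gb_pair_terms(s, config)[(0, 1)]

        screened = net(EnergeticsConfig(ionic_strength=0.15))
        unscreened = net(EnergeticsConfig(ionic_strength=0.0))
        assert abs(screened) <= abs(unscreened)

    def test_pair_terms_sum_to_total(self, template):
        pstruct = assign_params(template)
        config = EnergeticsConfig()
        terms = gb_pair_terms(pstruct, config)
        assert sum(terms.values()) == pytest.approx(
            gb_polar(pstruct, config), abs=1e-8)

    def test_effective_radii_at_least_intrinsic_for_lone_atom(self):
        s = bare_structure([0.0], [(0, 0, 0)], gb_radii=[1.7])
        radii = effective_born_radii(s)
        assert radii[0] == pytest.approx(1.7 - GB_OFFSET)


class TestSasa:
    def test_isolated_sphere_area(self):
        s = bare_structure([0.0], [(0, 0, 0)], lj_radii=[1.9])
        config = EnergeticsConfig(sphere_points=960)
        energy, areas = sasa_nonpolar(s, config)
        expected = 4 * math.pi * (1.9 + 1.4) ** 2
        assert areas[0] == pytest.approx(expected, rel=0.01)
        assert energy == pytest.approx(0.0072 * expected, rel=0.01)

    def test_buried_atom_zero(self):
        areas = shrake_rupley_sasa(
            np.array([[0.0, 0, 0], [0.0, 0, 0.1]]),
            np.array([1.0, 5.0]),
        )
        assert areas[0] == 0.0

    def test_point_density_convergence(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 3.0, 0]])
        radii = np.array([1.9, 1.7, 1.5])
        a1 = shrake_rupley_sasa(coords, radii, sphere_points=960).sum()
        a2 = shrake_rupley_sasa(coords, radii, sphere_points=1920).sum()
        assert abs(a1 - a2) / a2 < 0.01

    def test_zero_radius_atoms_vanish(self):
        areas = shrake_rupley_sasa(
            np.array([[0.0, 0, 0], [2.0, 0, 0]]),
            np.array([0.0, 1.9]),
        )
        assert areas[0] == 0.0
        assert areas[1] == pytest.approx(4 * math.pi * 3.3**2, rel=0.01)


class TestDecomposition:
    def test_zeroed_ligand_all_terms_zero(self, template, ligand_selection):
        table = default_parameter_table()
        entries = {
            key: type(p)(charge=0.0, lj_radius=0.0, lj_epsilon=0.0,
                         gb_radius=p.gb_radius, gb_screen=p.gb_screen)
            for key, p in table.entries.items()
        }
        zero_table = type(table)(entries=entries)
        config = EnergeticsConfig(sphere_points=120)
        dec = per_residue_decomposition(template, ligand_selection, config,
                                        zero_table)
        assert dec.total == pytest.approx(0.0, abs=1e-9)
        for comp in ("elec", "vdw", "gb", "sasa"):
            assert np.allclose(dec.table[comp], 0.0, atol=1e-9)

    def test_conservation_every_component(self, template, ligand_selection):
        config = EnergeticsConfig(sphere_points=240)
        dec = per_residue_decomposition(template, ligand_selection, config)
        assert dec.table["total"].sum() == pytest.approx(dec.total, abs=1e-6)
        recomposed = (dec.table["elec"] + dec.table["vdw"]
                      + dec.table["gb"] + dec.table["sasa"])
        assert np.allclose(recomposed, dec.table["total"], atol=1e-9)

    def test_charged_lysine_beats_neutralised_copy(self, template,
                                                   ligand_selection):
        config = EnergeticsConfig(sphere_points=240)
        charged = per_residue_decomposition(template, ligand_selection,
                                            config)
        table = default_parameter_table()
        entries = dict(table.entries)
        for (rn, an), p in table.entries.items():
            if rn == "LYS":
                entries[(rn, an)] = type(p)(
                    charge=0.0, lj_radius=p.lj_radius,
                    lj_epsilon=p.lj_epsilon, gb_radius=p.gb_radius,
                    gb_screen=p.gb_screen,
                )
        neutral = per_residue_decomposition(
            template, ligand_selection, config, type(table)(entries=entries))
        assert charged.residue_total("B", 4) < neutral.residue_total("B", 4)

    def test_central_lysine_top_attractive(self, template, ligand_selection):
        config = EnergeticsConfig(sphere_points=240)
        dec = per_residue_decomposition(template, ligand_selection, config)
        ligand_rows = dec.table[dec.table.chain == "B"]
        best = ligand_rows.loc[ligand_rows["total"].idxmin()]
        assert best.res_name == "LYS"
        assert best.total < 0

    def test_empty_ligand_rejected(self, template):
        with pytest.raises(EnergeticsError):
            per_residue_decomposition(template, Selection(chain="Z"))


class TestEnsemble:
    def test_identical_models_zero_sem(self, template, ligand_selection):
        stack = struc.stack([template] * 3)
        config = EnergeticsConfig(sphere_points=120)
        dec = ensemble_mmgbsa(stack, ligand_selection, config)
        assert dec.total_sem == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(dec.table["total_sem"], 0.0, atol=1e-12)

    def test_mean_and_sem_formula(self, ligand_selection):
        stack, _ = gen_complex_ensemble(n_models=2, jitter_sd=0.05, seed=3)
        config = EnergeticsConfig(sphere_points=120)
        dec = ensemble_mmgbsa(stack, ligand_selection, config)
        singles = [
            per_residue_decomposition(stack[i], ligand_selection, config)
            for i in range(2)
        ]
        totals = np.array([s.total for s in singles])
        assert dec.total == pytest.approx(totals.mean(), abs=1e-9)
        assert dec.total_sem == pytest.approx(
            totals.std(ddof=1) / math.sqrt(2), abs=1e-9)

    def test_two_value_hand_arithmetic(self):
        # mean/sem contract on totals -10 and -12
        totals = np.array([-10.0, -12.0])
        assert totals.mean() == -11.0
        assert totals.std(ddof=1) / math.sqrt(2) == pytest.approx(1.0)

    def test_small_jitter_stays_near_single_model(self, template,
                                                  ligand_selection):
        stack, _ = gen_complex_ensemble(n_models=4, jitter_sd=0.02, seed=9)
        config = EnergeticsConfig(sphere_points=120)
        dec = ensemble_mmgbsa(stack, ligand_selection, config)
        single = per_residue_decomposition(template, ligand_selection, config)
        assert abs(dec.total - single.total) < 5.0

    def test_single_model_rejected(self, template, ligand_selection):
        with pytest.raises(EnergeticsError):
            ensemble_mmgbsa(struc.stack([template]), ligand_selection)
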