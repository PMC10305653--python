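"""MM kernels, GB radii and energies, SASA, SIE/MM-GBSA composition, decomposition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from bindscape import energetics as en
from bindscape import datasets as ds
from bindscape.constants import COULOMB_CONSTANT, GB_RADIUS_OFFSET
from bindscape.io_model import Atom, Topology, ConfigError, SpecError, build_smt
from bindscape.synthetic import EnsembleSpec, simulate_ensemble

from tests.conftest import two_atom_topology, random_mixed_topology


class TestCoulomb:
    def test_closed_form_pair(self):
        top = two_atom_topology(a={"charge": 1.0}, b={"charge": -1.0})
        frame = np.array([[0.0, 0, 0], [3.320636, 0, 0]])
        e = en.coulomb_pair_energy(top, frame, [0], [1], dielectric=1.0)
        assert abs(e + 100.0) < 1e-9

    def test_zero_charge_contributes_nothing(self):
        top = two_atom_topology(a={"charge": 0.0}, b={"charge": -1.0})
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert en.coulomb_pair_energy(top, frame, [0], [1]) == 0.0

    def test_matches_double_loop_oracle(self):
        top = random_mixed_topology(12, 8, seed=1)
        rng = np.random.default_rng(2)
        frame = rng.normal(scale=6.0, size=(20, 3))
        got = en.coulomb_pair_energy(top, frame, top.receptor_atoms, top.ligand_atoms)
        expected = 0.0
        for i in top.receptor_atoms:
            for j in top.ligand_atoms:
                r = np.linalg.norm(frame[i] - frame[j])
                expected += COULOMB_CONSTANT * top.charges[i] * top.charges[j] / r
        assert abs(got - expected) < 1e-10

    def test_overlapping_atoms_raise(self):
        top = two_atom_topology(a={"charge": 1.0}, b={"charge": 1.0})
        frame = np.zeros((2, 3))
        with pytest.raises(SpecError):
            en.coulomb_pair_energy(top, frame, [0], [1])


class TestLennardJones:
    def test_minimum_is_minus_epsilon(self):
        top = two_atom_topology(
            a={"lj_rmin_half": 1.9082, "lj_epsilon": 0.1094},
            b={"lj_rmin_half": 1.9082, "lj_epsilon": 0.1094},
        )
        frame = np.array([[0.0, 0, 0], [3.8164, 0, 0]])
        assert abs(en.lj_pair_energy(top, frame, [0], [1]) + 0.1094) < 1e-12

    def test_vanishes_at_long_range(self):
        top = two_atom_topology()
        frame = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        assert abs(en.lj_pair_energy(top, frame, [0], [1])) < 1e-6

    def test_matches_double_loop_oracle(self):
        top = random_mixed_topology(10, 10, seed=3)
        rng = np.random.default_rng(4)
        frame = rng.normal(scale=7.0, size=(20, 3))
        got = en.lj_pair_energy(top, frame, top.receptor_atoms, top.ligand_atoms)
        expected = 0.0
        for i in top.receptor_atoms:
            for j in top.ligand_atoms:
                r = np.linalg.norm(frame[i] - frame[j])
                rmin = top.lj_rmin_half[i] + top.lj_rmin_half[j]
                eps = math.sqrt(top.lj_epsilon[i] * top.lj_epsilon[j])
                expected += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
        assert abs(got - expected) < 1e-10


class TestBornRadii:
    def test_isolated_atom_recovers_reduced_radius(self):
        top = two_atom_topology(a={"born_radius": 1.6})
        frame = np.array([[0.0, 0, 0], [500.0, 0, 0]])
        for backend in ("HCT", "OBC_I", "OBC_II", "numerical_R6"):
            r = en.effective_born_radii(top, frame, backend=backend, atom_subset=[0])
            assert abs(r[0] - (1.6 - GB_RADIUS_OFFSET)) < 2e-2, backend

    def test_two_sphere_hct_matches_quadrature_oracle(self):
        """The descreening integral agrees with direct volume quadrature (<3%)."""
        rho_i, rho_j, screen_j, dist = 1.41, 1.61, 0.85, 4.0
        top = Topology(
            [
                Atom(index=0, name="A", element="C", residue_index=0, residue_name="R",
                     segment="receptor", region="sidechain",
                     born_radius=rho_i + GB_RADIUS_OFFSET, screen=0.8),
                Atom(index=1, name="B", element="C", residue_index=0, residue_name="L",
                     segment="ligand", region="ligand",
                     born_radius=rho_j + GB_RADIUS_OFFSET, screen=screen_j),
            ]
        )
        frame = np.array([[0.0, 0, 0], [dist, 0, 0]])
        r_eff = en.effective_born_radii(top, frame, backend="HCT")[0]

        # Oracle: I = (1/4pi) * integral over neighbor's scaled sphere of 1/s^4.
        s_j = screen_j * rho_j
        h = 0.02
        ax = np.arange(dist - s_j, dist + s_j + h, h)
        yz = np.arange(-s_j, s_j + h, h)
        X, Y, Z = np.meshgrid(ax, yz, yz, indexing="ij")
        inside = (X - dist) ** 2 + Y**2 + Z**2 <= s_j**2
        s2 = X**2 + Y**2 + Z**2
        integral = h**3 / (4 * math.pi) * np.sum(1.0 / s2[inside] ** 2)
        r_oracle = 1.0 / (1.0 / rho_i - integral)
        assert abs(r_eff - r_oracle) / r_oracle < 0.03

    def test_burying_increases_effective_radius(self):
        atoms = [
            Atom(index=0, name="X", element="C", residue_index=0, residue_name="R",
                 segment="receptor", region="sidechain", born_radius=1.7)
        ]
        # Icosahedral-ish shell of 12 neighbors.
        shell = []
        rng = np.random.default_rng(0)
        for k in range(12):
            v = rng.normal(size=3)
            shell.append(3.5 * v / np.linalg.norm(v))
        for k in range(12):
            atoms.append(
                Atom(index=k + 1, name=f"N{k}", element="C", residue_index=1,
                     residue_name="R", segment="receptor", region="sidechain",
                     born_radius=1.7)
            )
        top = Topology(atoms)
        frame = np.vstack([[0.0, 0, 0], shell])
        for backend in ("HCT", "OBC_I", "OBC_II", "numerical_R6"):
            isolated = en.effective_born_radii(top, frame, backend=backend, atom_subset=[0])[0]
            buried = en.effective_born_radii(top, frame, backend=backend)[0]
            assert buried > isolated, backend

    def test_unknown_backend_rejected(self):
        top = two_atom_topology()
        with pytest.raises(ConfigError):
            en.effective_born_radii(top, np.zeros((2, 3)), backend="PB")


class TestGBEnergy:
    def test_born_ion_closed_form(self):
        """q = 1 e at R_eff = 2 A in eps 78.5 water gives -81.96 kcal/mol."""
        top = Topology(
            [Atom(index=0, name="I", element="C", residue_index=0, residue_name="ION",
                  segment="ligand", region="ligand", charge=1.0, born_radius=2.0)]
        )
        e = en.gb_polar_energy(top, np.zeros((1, 3)), np.array([2.0]), 1.0, 78.5)
        expected = -(COULOMB_CONSTANT / 2) * (1 - 1 / 78.5) / 2.0
        assert abs(e - expected) < 1e-9
        assert abs(e + 81.96) < 5e-3

    def test_self_term_fgb_limit(self):
        """At r = 0 the effective interaction distance reduces to R_i."""
        q, r_eff = 0.7, 1.8
        top = Topology(
            [Atom(index=0, name="I", element="C", residue_index=0, residue_name="ION",
                  segment="ligand", region="ligand", charge=q, born_radius=r_eff)]
        )
        e = en.gb_polar_energy(top, np.zeros((1, 3)), np.array([r_eff]), 1.0, 78.5)
        expected = -(COULOMB_CONSTANT / 2) * (1 - 1 / 78.5) * q * q / r_eff
        assert abs(e - expected) < 1e-12

    def test_asymptotic_screened_coulomb(self):
        """Widely separated charges: cross term -> -k (1 - 1/eps) q1 q2 / r."""
        q1, q2, r = 0.9, -0.6, 50.0
        atoms = [
            Atom(index=0, name="A", element="C", residue_index=0, residue_name="R",
                 segment="receptor", region="sidechain", charge=q1, born_radius=1.5),
            Atom(index=1, name="B", element="C", residue_index=0, residue_name="L",
                 segment="ligand", region="ligand", charge=q2, born_radius=1.5),
        ]
        top = Topology(atoms)
        frame = np.array([[0.0, 0, 0], [r, 0, 0]])
        radii = np.array([1.5, 1.5])
        total = en.gb_polar_energy(top, frame, radii, 1.0, 78.5)
        self_terms = sum(
            -(COULOMB_CONSTANT / 2) * (1 - 1 / 78.5) * q * q / 1.5 for q in (q1, q2)
        )
        cross = total - self_terms
        expected_cross = -COULOMB_CONSTANT * (1 - 1 / 78.5) * q1 * q2 / r
        assert abs(cross - expected_cross) / abs(expected_cross) < 0.01

    def test_binding_energy_invariant_under_rigid_motion(self, toy_complex):
        _, topology, reference = toy_complex
        e0 = en.gb_binding_polar(topology, reference, backend="OBC_I")
        rot = Rotation.from_euler("zyx", [12, 220, -75], degrees=True).as_matrix()
        moved = reference @ rot.T + np.array([11.0, -3.0, 8.0])
        e1 = en.gb_binding_polar(topology, moved, backend="OBC_I")
        assert abs(e0 - e1) < 1e-8


class TestSASA:
    def test_lone_sphere_area(self):
        top = two_atom_topology(a={"born_radius": 1.6})
        frame = np.array([[0.0, 0, 0], [200.0, 0, 0]])
        area = en.sasa(top, frame, probe=1.4, n_points=960, atom_subset=[0])
        assert abs(area[0] - 4 * math.pi * 3.0**2) / (4 * math.pi * 9) < 0.01

    def test_fully_buried_atom_zero(self):
        atoms = [
            Atom(index=0, name="X", element="C", residue_index=0, residue_name="R",
                 segment="receptor", region="sidechain", born_radius=1.0)
        ]
        # Enclose in a tight shell of large spheres.
        k = 1
        for dx in (-1.2, 0, 1.2):
            for dy in (-1.2, 0, 1.2):
                for dz in (-1.2, 0, 1.2):
                    if dx == dy == dz == 0:
                        continue
                    atoms.append(
                        Atom(index=k, name=f"S{k}", element="C", residue_index=1,
                             residue_name="R", segment="receptor", region="sidechain",
                             born_radius=2.5)
                    )
                    k += 1
        top = Topology(atoms)
        coords = [[0.0, 0, 0]]
        for dx in (-1.2, 0, 1.2):
            for dy in (-1.2, 0, 1.2):
                for dz in (-1.2, 0, 1.2):
                    if dx == dy == dz == 0:
                        continue
                    coords.append([dx, dy, dz])
        area = en.sasa(top, np.array(coords), probe=1.4, n_points=240)
        assert area[0] == 0.0

    def test_distant_spheres_additive(self):
        top = two_atom_topology(a={"born_radius": 1.5}, b={"born_radius": 1.9})
        frame = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        both = en.sasa(top, frame, probe=1.4, n_points=480)
        alone_a = en.sasa(top, frame, probe=1.4, n_points=480, atom_subset=[0])
        alone_b = en.sasa(top, frame, probe=1.4, n_points=480, atom_subset=[1])
        assert abs(both.sum() - (alone_a[0] + alone_b[1])) < 1e-9

    def test_too_few_points_rejected(self):
        top = two_atom_topology()
        with pytest.raises(ConfigError):
            en.sasa(top, np.zeros((2, 3)), n_points=10)


class TestSIEComposition:
    @pytest.mark.parametrize(
        "inhibitor,expected",
        [("60W", -8.82), ("954", -7.30), ("60X", -7.39)],
    )
    def test_published_component_tables(self, inhibitor, expected):
        comp = ds.sie_reference_components(inhibitor)
        assert abs(en.sie_score(comp) - expected) < 0.005

    def test_all_zero_components_give_constant(self):
        comp = en.SIEComponents(0.0, 0.0, 0.0, 0.0)
        assert en.sie_score(comp) == pytest.approx(-2.89)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        ec=st.floats(-100, 100),
        evdw=st.floats(-100, 100),
        gr=st.floats(-100, 100),
        msa=st.floats(-100, 100),
        scale=st.floats(0.1, 5.0),
    )
    def test_linearity_in_components(self, ec, evdw, gr, msa, scale):
        """Scaling any single component scales its contribution exactly."""
        params = en.SIEParameters()
        base = en.sie_score(en.SIEComponents(ec, evdw, gr, msa), params)
        scaled = en.sie_score(en.SIEComponents(ec, evdw, gr, msa * scale), params)
        assert scaled - base == pytest.approx(params.alpha * msa * (scale - 1), abs=1e-9)


class TestSIETrajectory:
    @staticmethod
    @pytest.fixture(scope="class")
    def sie_inputs(toy_complex):
        _, topology, reference = toy_complex
        spec = EnsembleSpec(n_residues=20, n_replicas=1, frames_per_replica=12, seed=31)
        frames = build_smt(simulate_ensemble(topology, reference, spec))
        return topology, frames

    def test_score_equals_composition_of_averages(self, sie_inputs):
        topology, frames = sie_inputs
        comp, score = en.sie_from_trajectory(topology, frames, n_snapshots=6, sasa_points=120)
        assert score == pytest.approx(en.sie_score(comp), abs=1e-12)

    def test_doubling_gamma_doubles_surface_term(self, sie_inputs):
        topology, frames = sie_inputs
        p1 = en.SIEParameters()
        p2 = en.SIEParameters(gamma_msa=2 * p1.gamma_msa)
        c1, _ = en.sie_from_trajectory(topology, frames, p1, n_snapshots=4, sasa_points=120)
        c2, _ = en.sie_from_trajectory(topology, frames, p2, n_snapshots=4, sasa_points=120)
        assert c2.gamma_msa_term == pytest.approx(2 * c1.gamma_msa_term, rel=1e-9)

    def test_reaction_field_penalizes_charged_ligand_binding(self, sie_inputs):
        """Desolvating charge on binding makes the GB reaction term positive."""
        topology, frames = sie_inputs
        comp, _ = en.sie_from_trajectory(topology, frames, n_snapshots=4, sasa_points=120)
        assert comp.g_reaction > 0


class TestGBSAComposition:
    def test_published_igb2_composition(self):
        comp = ds.gbsa_reference_components("60W", "GB2")
        assert comp.g_bind == pytest.approx(-19.16, abs=0.005)
        assert comp.g_pol == pytest.approx(17.90, abs=0.005)
        assert comp.enthalpy == pytest.approx(-41.68, abs=0.005)
        assert ds.gbsa_reference_components("954", "GB2").g_hydro == pytest.approx(
            -46.28, abs=0.005
        )

    def test_published_igb5_enthalpy(self):
        assert ds.gbsa_reference_components("60W", "GB5").enthalpy == pytest.approx(
            -83.85, abs=0.005
        )

    def test_derived_identities_hold_exactly(self):
        for inhibitor in ds.INHIBITORS:
            for model in ("GB1", "GB2", "GB5", "GB66"):
                c = ds.gbsa_reference_components(inhibitor, model)
                assert c.g_pol == pytest.approx(c.d_ele + c.d_gb, abs=1e-9)
                assert c.g_hydro == pytest.approx(c.d_vdw + c.d_surf, abs=1e-9)
                assert c.enthalpy == pytest.approx(c.g_pol + c.g_hydro, abs=1e-9)
                assert c.g_bind == pytest.approx(c.enthalpy + c.minus_t_ds, abs=1e-9)

    def test_neutral_lj_only_system_has_zero_polar_terms(self):
        top = random_mixed_topology(8, 4, seed=7)
        for atom in top.atoms:
            atom.charge = 0.0
        top = Topology(top.atoms)
        rng = np.random.default_rng(8)
        frame = rng.normal(scale=6.0, size=(12, 3))
        comp = en.gbsa_binding(top, frame, gb_model="GB2", sasa_points=60)
        assert comp.d_ele == 0.0
        assert comp.d_gb == pytest.approx(0.0, abs=1e-12)
        assert comp.d_vdw != 0.0

    def test_unknown_model_rejected(self, toy_complex):
        _, topology, reference = toy_complex
        with pytest.raises(ConfigError):
            en.gbsa_binding(topology, reference, gb_model="GB99")

    def test_sem_decreases_with_snapshot_count(self, toy_complex):
        _, topology, reference = toy_complex
        spec = EnsembleSpec(n_residues=20, n_replicas=1, frames_per_replica=64, seed=41)
        frames = build_smt(simulate_ensemble(topology, reference, spec))
        small = en.gbsa_binding(topology, frames, n_snapshots=8, sasa_points=60)
        large = en.gbsa_binding(topology, frames, n_snapshots=56, sasa_points=60)
        # Roughly n^{-1/2}: a 7x sample should shrink the SEM noticeably.
        assert large.stderr["dEvdW"] < small.stderr["dEvdW"]


class TestCompareSystems:
    def _published(self, model="GB2"):
        return {lig: ds.gbsa_reference_components(lig, model) for lig in ds.INHIBITORS}

    def test_published_pairwise_deltas(self):
        """60W vs 954 differences match the published comparison figures."""
        table = en.compare_systems(self._published(), reference="954")
        row = table.loc["60W"]
        assert row["dEele"] == pytest.approx(-7.98, abs=0.005)
        assert row["dGgb"] == pytest.approx(11.42, abs=0.005)
        assert row["dGhydro"] == pytest.approx(-13.30, abs=0.005)
        assert row["dH"] == pytest.approx(-9.86, abs=0.005)
        assert row["dGbind"] == pytest.approx(-5.94, abs=0.005)
        row_x = table.loc["60X"]
        assert row_x["dEele"] == pytest.approx(-5.63, abs=0.005)
        assert row_x["dGbind"] == pytest.approx(-1.29, abs=0.005)

    def test_self_difference_zero(self):
        systems = self._published()
        table = en.compare_systems(
            {"a": systems["60W"], "b": systems["60W"]}, reference="a"
        )
        assert np.allclose(table.loc["b"].to_numpy(dtype=float), 0.0)

    def test_antisymmetric_under_reference_swap(self):
        systems = self._published()
        fwd = en.compare_systems(systems, reference="954").loc["60W"]
        rev = en.compare_systems(systems, reference="60W").loc["954"]
        assert np.allclose(fwd.to_numpy(dtype=float), -rev.to_numpy(dtype=float))

    def test_mixed_gb_models_rejected(self):
        with pytest.raises(ConfigError):
            en.compare_systems(
                {
                    "a": ds.gbsa_reference_components("60W", "GB2"),
                    "b": ds.gbsa_reference_components("954", "GB5"),
                },
                reference="a",
            )


class TestResidueDecomposition:
    @staticmethod
    @pytest.fixture(scope="class")
    def decomposition(toy_complex):
        _, topology, reference = toy_complex
        spec = EnsembleSpec(n_residues=20, n_replicas=1, frames_per_replica=4, seed=51)
        frames = build_smt(simulate_ensemble(topology, reference, spec))
        table = en.residue_decomposition(topology, frames, "GB2", sasa_points=120)
        comp = en.gbsa_binding(topology, frames, "GB2", sasa_points=120)
        return table, comp

    def test_total_equals_sidechain_plus_backbone(self, decomposition):
        table, _ = decomposition
        for stem in ("vdW", "ele", "gb", "surf"):
            assert np.allclose(
                table[f"T{stem}"], table[f"S{stem}"] + table[f"B{stem}"], atol=1e-12
            )

    def test_conservation_of_cross_terms(self, decomposition):
        """Residue sums reproduce the complex totals (pairwise attributable)."""
        table, comp = decomposition
        receptor_rows = table[table["residue_name"] != "LIG"]
        assert receptor_rows["TvdW"].sum() == pytest.approx(comp.d_vdw, abs=1e-6)
        assert receptor_rows["Tele"].sum() == pytest.approx(comp.d_ele, abs=1e-6)
        assert table["Tgb"].sum() == pytest.approx(comp.d_gb, abs=1e-6)
        assert table["Tsurf"].sum() == pytest.approx(comp.d_surf, abs=1e-6)

    def test_per_residue_total_is_sum_of_terms(self, decomposition):
        table, _ = decomposition
        assert np.allclose(
            table["dG"],
            table["TvdW"] + table["Tele"] + table["Tgb"] + table["Tsurf"],
            atol=1e-12,
        )

    def test_single_residue_receptor_degenerate_case(self):
        top = random_mixed_topology(4, 3, seed=9)
        for atom in top.atoms:
            if atom.segment == "receptor":
                atom.residue_index = 0
        top = Topology(top.atoms)
        rng = np.random.default_rng(10)
        frame = rng.normal(scale=5.0, size=(7, 3))
        table = en.residue_decomposition(top, frame, "GB2", sasa_points=60)
        comp = en.gbsa_binding(top, frame, "GB2", sasa_points=60)
        row = table[table["residue_name"] != "LIG"].iloc[0]
        assert row["TvdW"] == pytest.approx(comp.d_vdw, abs=1e-9)
        assert row["Tele"] == pytest.approx(comp.d_ele, abs=1e-9)


class TestExperimentalAffinity:
    def test_one_nanomolar(self):
        assert round(en.delta_g_from_ki(1e-9), 1) == -12.3

    def test_forty_five_nanomolar(self):
        assert round(en.delta_g_from_ki(45e-9), 1) == -10.0

    def test_one_molar_is_zero(self):
        assert en.delta_g_from_ki(1.0) == 0.0

    def test_inconsistent_report_flagged(self):
        _, consistent = en.experimental_affinity(48e-9, reported_delta_g=-11.4)
        assert not consistent
        _, consistent = en.experimental_affinity(1e-9, reported_delta_g=-12.3)
        assert consistent

    def test_nonpositive_ki_rejected(self):
        with pytest.raises(ValueError):
            en.delta_g_from_ki(0.0)
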