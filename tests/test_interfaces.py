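"""Contacts, salt bridges, SASA and interface energetics."""

import math

import numpy as np
import pytest

import fibrilkit as fk
from fibrilkit.interfaces import VDW_RADII, _sphere_points
from fibrilkit.model import Atom, Chain, MolecularModel, Residue
from fibrilkit.synth import FibrilSpec, build_fibril


def _cloud_model(rng, n=120, box=25.0, two_chains=True):
    chains = []
    n_chain = 2 if two_chains else 1
    per = n // n_chain
    for c in range(n_chain):
        residues = []
        for r in range(per):
            pos = rng.uniform(0, box, 3)
            residues.append(Residue("ALA", r + 1, [Atom("CA", "C", pos)]))
        chains.append(Chain(f"C{c}", residues))
    return MolecularModel(chains)


class TestContacts:
    def test_boundary_inclusion(self):
        m = MolecularModel(
            [
                Chain("A", [Residue("ALA", 1, [Atom("CA", "C", (0, 0, 0))])]),
                Chain("B", [Residue("ALA", 1, [Atom("CA", "C", (4.9, 0, 0))])]),
            ]
        )
        assert len(fk.find_contacts(m, {"A"}, {"B"}, cutoff=5.0)) == 1
        assert len(fk.find_contacts(m, {"A"}, {"B"}, cutoff=4.8)) == 0

    def test_zero_cutoff_empty(self, plain_fibril):
        fibril, _ = plain_fibril
        assert fk.find_contacts(fibril, {"A0"}, {"B0"}, cutoff=0.0) == []

    def test_overlapping_groups_rejected(self, plain_fibril):
        fibril, _ = plain_fibril
        with pytest.raises(ValueError):
            fk.find_contacts(fibril, {"A0"}, {"A0", "B0"})

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = _cloud_model(rng)
        cutoff = rng.uniform(2.0, 8.0)
        found = {
            (c.a, c.b) for c in fk.find_contacts(m, {"C0"}, {"C1"}, cutoff=cutoff)
        }
        # O(n^2) oracle
        brute = set()
        for ra in m.chain("C0").residues:
            for rb in m.chain("C1").residues:
                d = np.linalg.norm(ra.atoms[0].position - rb.atoms[0].position)
                if d <= cutoff:
                    brute.add(
                        (
                            ("C0", ra.seq_id, "CA"),
                            ("C1", rb.seq_id, "CA"),
                        )
                    )
        assert found == brute


class TestNeighborCount:
    def test_end_chain_of_two_layer_stack(self):
        spec = FibrilSpec(n_layers=2, sym=fk.HelicalSymmetry(4.8, -1.15, 1),
                          strand_length=6, arch="none", radius=10.0)
        fibril, _ = build_fibril(spec)
        nc = fk.neighbor_count(fibril, "A0")
        assert nc.total == 1
        assert not nc.converged

    def test_symmetry_of_neighborhood(self, murine_fibril):
        fibril, _ = murine_fibril
        nc = fk.neighbor_count(fibril, "A4")
        for partner in nc.partners:
            assert "A4" in fk.neighbor_count(fibril, partner).partners

    def test_interior_chain_converged_flag(self, murine_fibril):
        fibril, _ = murine_fibril
        assert fk.neighbor_count(fibril, "A4").converged
        assert not fk.neighbor_count(fibril, "A0").converged


class TestSaltBridges:
    def test_constructed_pair_detected_bidentate(self):
        # Asp carboxylate facing an Arg guanidinium, both N-O pairs ~3 A
        asp = Residue(
            "ASP", 1,
            [
                Atom("CB", "C", (0.0, 0.0, 0.0)),
                Atom("CG", "C", (1.5, 0.0, 0.0)),
                Atom("OD1", "O", (2.2, 1.05, 0.0)),
                Atom("OD2", "O", (2.2, -1.05, 0.0)),
            ],
        )
        arg = Residue(
            "ARG", 1,
            [
                Atom("CZ", "C", (5.2, 0.0, 0.0)),
                Atom("NH1", "N", (4.5, 1.05, 0.0)),
                Atom("NH2", "N", (4.5, -1.05, 0.0)),
                Atom("NE", "N", (6.5, 0.0, 0.0)),
            ],
        )
        m = MolecularModel([Chain("A", [asp]), Chain("B", [arg])])
        bridges = fk.salt_bridges(m, include_termini=False)
        assert len(bridges) == 1
        sb = bridges[0]
        assert sb.bidentate
        assert sb.min_distance == pytest.approx(2.3, abs=0.01)

    def test_reciprocal_cross_stack_bridges_in_stand_in(self, murine_fibril):
        fibril, _ = murine_fibril
        cross = [
            s for s in fk.salt_bridges(fibril)
            if fibril.stack_of()[s.acid.chain_id] != fibril.stack_of()[s.base.chain_id]
        ]
        assert cross, "expected cross-stack salt bridges"
        assert all(s.acid.residue_name == "ASP" and s.base.residue_name == "ARG"
                   for s in cross)
        assert any(s.bidentate for s in cross)
        # reciprocity under the pseudo-2-fold: bridges run in both directions
        a_to_b = {(s.acid.chain_id, s.base.chain_id) for s in cross}
        assert any(a.startswith("A") for a, _ in a_to_b)
        assert any(a.startswith("B") for a, _ in a_to_b)


class TestSasa:
    def test_isolated_atom_closed_form(self):
        m = MolecularModel(
            [Chain("A", [Residue("ALA", 1, [Atom("CA", "C", (0, 0, 0))])])]
        )
        area = fk.sasa(m)
        expected = 4 * math.pi * (VDW_RADII["C"] + 1.4) ** 2
        assert area[0] == pytest.approx(expected, rel=0.01)

    def test_two_overlapping_spheres_bury_area(self):
        m = MolecularModel(
            [
                Chain("A", [Residue("ALA", 1, [Atom("CA", "C", (0, 0, 0))])]),
                Chain("B", [Residue("ALA", 1, [Atom("CA", "C", (2.0, 0, 0))])]),
            ]
        )
        total = fk.sasa(m).sum()
        single = 4 * math.pi * (VDW_RADII["C"] + 1.4) ** 2
        assert total < 2 * single

    def test_disjoint_union_additive(self, rng):
        m = _cloud_model(rng, n=40, box=12.0)
        # separate the chains far apart: union SASA = sum of parts
        far = m.copy()
        for a in far.chain("C1").atoms():
            a.position = a.position + np.array([200.0, 0, 0])
        whole = fk.sasa(far).sum()
        parts = fk.sasa(far, chain_ids={"C0"}).sum() + fk.sasa(far, chain_ids={"C1"}).sum()
        assert whole == pytest.approx(parts, rel=1e-9)

    def test_quadrature_convergence(self, rng):
        m = _cloud_model(rng, n=60, box=10.0)
        coarse = fk.sasa(m, n_points=960).sum()
        fine = fk.sasa(m, n_points=4000).sum()
        assert coarse == pytest.approx(fine, rel=0.005)

    def test_sphere_points_unit_norm(self):
        pts = _sphere_points(500)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)

    def test_matches_independent_implementation(self, rng, tmp_path):
        """Cross-check against biotite's Shrake-Rupley on a random cloud."""
        biotite_structure = pytest.importorskip("biotite.structure")
        m = _cloud_model(rng, n=50, box=12.0)
        ours = fk.sasa(m, probe=1.4, n_points=4000).sum()
        import biotite.structure as struc

        arr = struc.AtomArray(50)
        arr.coord = m.coords().astype(np.float32)
        arr.atom_name = np.array(["CA"] * 50)
        arr.res_name = np.array(["ALA"] * 50)
        arr.res_id = np.arange(1, 51)
        arr.chain_id = np.array(["A"] * 50)
        arr.element = np.array(["C"] * 50)
        theirs = struc.sasa(
            arr, probe_radius=1.4, point_number=1000,
            vdw_radii=np.full(50, VDW_RADII["C"]),
        ).sum()
        assert ours == pytest.approx(theirs, rel=0.02)


class TestInterfaceEnergy:
    def _slab(self, chain_id, x0, n=16):
        residues = []
        for i in range(n):
            y, z = divmod(i, 4)
            residues.append(
                Residue("ALA", i + 1, [Atom("CB", "C", (x0, 3.0 * y, 3.0 * z))])
            )
        return Chain(chain_id, residues)

    def test_no_contact_means_no_interface(self):
        m = MolecularModel([self._slab("A", 0.0), self._slab("B", 60.0)])
        e = fk.interface_energy(m, {"A"}, {"B"})
        assert e.no_interface
        assert e.buried_area == 0.0
        assert e.delta_g_diss == pytest.approx(-e.t_delta_s)

    def test_buried_area_grows_when_closer(self):
        areas = []
        for gap in (5.5, 5.0):
            m = MolecularModel([self._slab("A", 0.0), self._slab("B", gap)])
            areas.append(fk.interface_energy(m, {"A"}, {"B"}).buried_area)
        assert areas[1] > areas[0] > 0

    def test_hydrophobic_interface_is_favorable(self):
        m = MolecularModel([self._slab("A", 0.0), self._slab("B", 4.5)])
        e = fk.interface_energy(m, {"A"}, {"B"})
        assert e.delta_g_int < 0  # carbon burial gains solvation energy


class TestLayerCurve:
    def test_zero_contact_fibril_flat_at_entropy_cost(self):
        sub = MolecularModel(
            [Chain("A", [Residue("ALA", 1, [Atom("CB", "C", (30.0, 0, 0))])])]
        )
        curve = fk.layer_stability_curve(
            sub, fk.HelicalSymmetry(4.8, -1.15, 2), range(1, 5), n_points=480
        )
        assert curve.crossing is None
        assert all(dg == pytest.approx(-12.0) for _, dg in curve.points)

    def test_monotone_non_decreasing(self, rng):
        spec = FibrilSpec(n_layers=1, sym=fk.HelicalSymmetry(4.8, -1.15, 2),
                          strand_length=6, arch="none", radius=6.0)
        sub = build_fibril(spec)[0]
        sub_model = MolecularModel([sub.chain("A0").copy()])
        curve = fk.layer_stability_curve(
            sub_model, spec.sym, range(1, 7), n_points=240
        )
        dgs = [dg for _, dg in curve.points]
        assert all(b >= a - 1e-6 for a, b in zip(dgs, dgs[1:]))

    def test_requires_two_start_symmetry(self):
        sub = MolecularModel(
            [Chain("A", [Residue("ALA", 1, [Atom("CB", "C", (5.0, 0, 0))])])]
        )
        with pytest.raises(ValueError):
            fk.layer_stability_curve(sub, fk.HelicalSymmetry(4.8, -1.15, 1), range(1, 3))
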