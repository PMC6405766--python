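"""Helical parameter generation/estimation and morphological measures."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import fibrilkit as fk
from fibrilkit.errors import InsufficientSubunitsError, NonHelicalModelError
from fibrilkit.geometry import Z_AXIS, mirror_model
from fibrilkit.model import Atom, Chain, MolecularModel, Residue
from fibrilkit.synth import FibrilSpec, build_fibril


def _point_subunit(radius=10.0):
    res = Residue("ALA", 1, [Atom("CA", "C", (radius, 0.0, 0.0))])
    return MolecularModel([Chain("A", [res])])


class TestCrossover:
    @pytest.mark.parametrize(
        "rise,twist,expected",
        [
            (4.8, -1.15, 75.13),
            (4.7, 1.54, 54.94),
            (4.8, 1.15, 75.13),  # sign-invariant
        ],
    )
    def test_closed_form(self, rise, twist, expected):
        d = fk.crossover_distance(fk.HelicalSymmetry(rise, twist, 2))
        assert d.distance_nm == pytest.approx(expected, abs=0.005)

    def test_half_turn_per_layer(self):
        d = fk.crossover_distance(fk.HelicalSymmetry(4.8, 180.0, 1))
        assert d.distance_nm == pytest.approx(0.48)

    def test_untwisted_is_flagged_not_raised(self):
        d = fk.crossover_distance(fk.HelicalSymmetry(4.8, 0.0, 1))
        assert d.untwisted
        assert math.isinf(d.distance_nm)

    def test_linear_in_rise(self):
        a = fk.crossover_distance(fk.HelicalSymmetry(2.4, 1.15, 1)).distance_nm
        b = fk.crossover_distance(fk.HelicalSymmetry(4.8, 1.15, 1)).distance_nm
        assert b == pytest.approx(2 * a)


class TestAxisFit:
    def test_z_built_fibril(self, plain_fibril):
        fibril, truth = plain_fibril
        axis = fk.fit_fibril_axis(fibril)
        assert abs(axis.direction @ truth.axis.direction) > 1 - 1e-6

    def test_equivariance_under_rotation(self, plain_fibril):
        fibril, _ = plain_fibril
        R = Rotation.from_euler("xyz", [40.0, -25.0, 110.0], degrees=True).as_matrix()
        axis = fk.fit_fibril_axis(fibril.transformed(R, np.array([3.0, -8.0, 2.0])))
        assert abs(axis.direction @ (R @ np.array([0, 0, 1.0]))) > 1 - 1e-6

    def test_noisy_axis_within_half_degree(self):
        spec = FibrilSpec(
            n_layers=20, sym=fk.HelicalSymmetry(4.8, -1.15, 2),
            strand_length=8, arch="none", radius=12.0, noise_sd=0.2, seed=11,
        )
        fibril, truth = build_fibril(spec)
        axis = fk.fit_fibril_axis(fibril)
        angle = math.degrees(math.acos(min(1.0, abs(axis.direction @ truth.axis.direction))))
        assert angle < 0.5

    def test_too_few_chains(self):
        with pytest.raises(InsufficientSubunitsError):
            fk.fit_fibril_axis(_point_subunit())


class TestApplySymmetry:
    def test_single_layer_is_identity(self):
        sub = _point_subunit()
        out = fk.apply_helical_symmetry(sub, fk.HelicalSymmetry(4.8, -1.15, 1), 1)
        assert np.allclose(out.coords(), sub.coords())

    def test_accumulated_twist_near_half_turn(self):
        # 157 subunit steps of -1.15 deg accumulate to -180.55 deg
        out = fk.apply_helical_symmetry(
            _point_subunit(radius=10.0), fk.HelicalSymmetry(4.8, -1.15, 1), 158
        )
        p = out.chain("A157").coords()[0]
        azimuth = math.degrees(math.atan2(p[1], p[0]))
        assert azimuth == pytest.approx(-180.55 + 360.0, abs=1e-6)
        assert p[2] == pytest.approx(157 * 4.8)

    def test_two_start_axial_offset_is_half_rise(self):
        out = fk.apply_helical_symmetry(
            _point_subunit(), fk.HelicalSymmetry(4.8, -1.15, 2), 3
        )
        za = out.chain("A0").coords()[0][2]
        zb = out.chain("B0").coords()[0][2]
        assert zb - za == pytest.approx(2.4)
        assert len(out.chains) == 6  # starts * n_layers

    def test_chain_ids_deterministic(self):
        out = fk.apply_helical_symmetry(
            _point_subunit(), fk.HelicalSymmetry(4.8, -1.15, 2), 2
        )
        assert out.chain_ids == ["A0", "A1", "B0", "B1"]


class TestEstimate:
    def test_exact_inverse_noiseless(self, plain_fibril):
        fibril, truth = plain_fibril
        est = fk.estimate_helical_parameters(fibril)
        assert est.rise == pytest.approx(truth.sym.rise, abs=1e-6)
        assert est.twist == pytest.approx(truth.sym.twist, abs=1e-6)
        assert est.starts == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovery_under_noise(self, seed):
        spec = FibrilSpec(
            n_layers=8, sym=fk.HelicalSymmetry(4.7, 1.54, 2), strand_length=9,
            arch="none", phi=-119.0, psi=117.0, radius=12.0,
            noise_sd=0.1, seed=seed,
        )
        fibril, _ = build_fibril(spec)
        est = fk.estimate_helical_parameters(fibril)
        assert est.rise == pytest.approx(4.7, abs=0.02)
        assert est.twist == pytest.approx(1.54, abs=0.05)

    def test_mirror_flips_twist_sign_only(self, plain_fibril):
        fibril, truth = plain_fibril
        est = fk.estimate_helical_parameters(mirror_model(fibril))
        assert est.twist == pytest.approx(-truth.sym.twist, abs=1e-6)
        assert est.rise == pytest.approx(truth.sym.rise, abs=1e-6)

    @pytest.mark.parametrize(
        "rise,twist,starts", [(4.8, -1.15, 2), (4.7, 1.54, 2), (5.0, -3.0, 1), (4.75, 0.4, 2)]
    )
    def test_round_trip_over_parameter_grid(self, rise, twist, starts):
        spec = FibrilSpec(
            n_layers=4, sym=fk.HelicalSymmetry(rise, twist, starts),
            strand_length=6, arch="none", radius=11.0,
        )
        fibril, _ = build_fibril(spec)
        est = fk.estimate_helical_parameters(fibril)
        assert est.rise == pytest.approx(rise, abs=1e-6)
        assert est.twist == pytest.approx(twist, abs=1e-6)

    def test_non_identical_chains_raise(self, plain_fibril):
        fibril, _ = plain_fibril
        broken = fibril.copy()
        del broken.chains[0].residues[0]
        with pytest.raises(NonHelicalModelError):
            fk.estimate_helical_parameters(broken)


class TestMorphology:
    def test_cylinder_width(self):
        rng = np.random.default_rng(5)
        chains = []
        for c in range(4):
            residues = []
            for r in range(40):
                theta = rng.uniform(0, 2 * math.pi)
                pos = (40 * math.cos(theta), 40 * math.sin(theta), c * 5.0 + r * 0.1)
                residues.append(Residue("ALA", r + 1, [Atom("CA", "C", pos)]))
            chains.append(Chain(f"C{c}", residues))
        model = MolecularModel(chains)
        width = fk.fibril_width(model, Z_AXIS)
        assert width == pytest.approx(8.0, rel=0.02)

    def test_width_robust_to_outlier(self):
        rng = np.random.default_rng(6)
        chains = []
        for c in range(3):
            residues = [
                Residue(
                    "ALA", r + 1,
                    [Atom("CA", "C", (40 * math.cos(t), 40 * math.sin(t), c * 5 + r * 0.1))],
                )
                for r, t in enumerate(rng.uniform(0, 2 * math.pi, 60))
            ]
            chains.append(Chain(f"C{c}", residues))
        model = MolecularModel(chains)
        base = fk.fibril_width(model, Z_AXIS)
        model.chains[0].residues[0].atoms.append(Atom("CB", "C", (100.0, 0.0, 0.0)))
        spiked = fk.fibril_width(model, Z_AXIS)
        assert spiked == pytest.approx(base, rel=0.02)

    def test_strand_spacing_matches_rise(self, plain_fibril):
        fibril, truth = plain_fibril
        assert fk.strand_spacing(fibril) == pytest.approx(truth.sym.rise, abs=1e-6)

    def test_axial_height_change_flat_and_modulated(self):
        flat_spec = FibrilSpec(n_layers=1, sym=fk.HelicalSymmetry(4.8, -1.15, 1),
                               strand_length=10, arch="none", radius=10.0)
        flat, _ = build_fibril(flat_spec)
        chain = flat.chains[0]
        h = fk.axial_height_change(chain, Z_AXIS, 1, 10, atom_name="CA")
        assert h < 1.5  # flat strand perpendicular to the axis

        mod, _ = build_fibril(
            FibrilSpec(n_layers=1, sym=fk.HelicalSymmetry(4.8, -1.15, 1),
                       strand_length=10, arch="none", radius=10.0,
                       height_modulation=13.0)
        )
        h = fk.axial_height_change(mod.chains[0], Z_AXIS, 1, 10, atom_name="C")
        assert h == pytest.approx(13.0, abs=0.5)

    def test_missing_atom_raises(self, plain_fibril):
        fibril, _ = plain_fibril
        with pytest.raises(fk.FibrilkitError):
            fk.axial_height_change(fibril.chains[0], Z_AXIS, 1, 9, atom_name="XX")

    def test_axial_quantities_rigid_motion_invariant(self, plain_fibril):
        fibril, _ = plain_fibril
        R = Rotation.from_euler("zyx", [15.0, 75.0, -30.0], degrees=True).as_matrix()
        moved = fibril.transformed(R, np.array([-4.0, 9.0, 1.0]))
        est0 = fk.estimate_helical_parameters(fibril)
        est1 = fk.estimate_helical_parameters(moved)
        assert est1.rise == pytest.approx(est0.rise, abs=1e-6)
        assert est1.twist == pytest.approx(est0.twist, abs=1e-6)
        assert fk.strand_spacing(moved) == pytest.approx(
            fk.strand_spacing(fibril), abs=1e-6
        )
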