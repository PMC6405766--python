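"""Dihedrals, strand assignment and the phi+psi twist-handedness statistic."""

import numpy as np
import pytest

import fibrilkit as fk
from fibrilkit.errors import EmptyStatisticError
from fibrilkit.geometry import mirror_model
from fibrilkit.secondary import dihedral_angle
from fibrilkit.synth import FibrilSpec, build_fibril, build_subunit


def test_dihedral_angle_reference_values():
    p = [np.zeros(3), np.array([1.0, 0, 0]), np.array([1.0, 1, 0])]
    cis = dihedral_angle(*p, np.array([0.0, 1, 0]))
    trans = dihedral_angle(*p, np.array([2.0, 1, 0]))
    up = dihedral_angle(*p, np.array([1.0, 1, 1]))
    assert cis == pytest.approx(0.0, abs=1e-12)
    assert abs(trans) == pytest.approx(180.0)
    # sign convention cross-checked against biotite.structure.dihedral
    assert up == pytest.approx(90.0)


@pytest.mark.parametrize(
    "phi,psi",
    [(-57.0, -47.0), (-119.0, 113.0), (-124.0, 132.0)],
)
def test_builder_dihedrals_recovered(phi, psi):
    sub = build_subunit(
        FibrilSpec(strand_length=8, arch="none", phi=phi, psi=psi)
    )
    recs = fk.compute_dihedrals(sub)
    interior = [r for r in recs if r.phi is not None and r.psi is not None]
    assert interior, "interior residues expected"
    for r in interior:
        assert r.phi == pytest.approx(phi, abs=1e-3)
        assert r.psi == pytest.approx(psi, abs=1e-3)


def test_termini_have_undefined_dihedrals(plain_fibril):
    fibril, _ = plain_fibril
    recs = [r for r in fk.compute_dihedrals(fibril) if r.chain_id == "A0"]
    assert recs[0].phi is None
    assert recs[-1].psi is None


class TestStrandAssignment:
    def test_fibril_core_residues_are_strands(self, plain_fibril):
        fibril, _ = plain_fibril
        asg = fk.assign_strands(fibril)
        # interior residues of interior chains must all be labeled strand
        for r in range(4, 9):
            assert asg.is_strand("A2", r)
            assert asg.is_strand("B2", r)

    def test_isolated_chain_has_no_strands(self):
        sub = build_subunit(FibrilSpec(strand_length=8, arch="none"))
        asg = fk.assign_strands(sub)
        assert len(asg.strand_residues) == 0

    def test_connector_residues_not_strands(self, murine_fibril):
        fibril, _ = murine_fibril
        asg = fk.assign_strands(fibril)
        for seq in (11, 12, 13):  # connector glycines
            assert not asg.is_strand("A4", seq)

    def test_manual_ranges_verbatim(self, plain_fibril):
        fibril, _ = plain_fibril
        ranges = {"A0": [(2, 4)], "B1": [(7, 9)]}
        asg = fk.assign_strands(fibril, method="manual", manual_ranges=ranges)
        assert asg.strand_residues == {
            ("A0", 2), ("A0", 3), ("A0", 4), ("B1", 7), ("B1", 8), ("B1", 9),
        }

    def test_labels_cover_all_residues(self, plain_fibril):
        fibril, _ = plain_fibril
        asg = fk.assign_strands(fibril)
        n_residues = sum(len(c.residues) for c in fibril.chains)
        assert len(asg.labels) == n_residues


class TestTwistStatistic:
    def test_on_diagonal_is_indeterminate(self, plain_fibril):
        fibril, _ = plain_fibril
        sym_spec = FibrilSpec(
            n_layers=4, sym=fk.HelicalSymmetry(4.8, -1.15, 2), strand_length=9,
            arch="none", phi=-120.0, psi=120.0, radius=12.0,
        )
        fib, _ = build_fibril(sym_spec)
        tw = fk.twist_statistic(fk.compute_dihedrals(fib), fk.assign_strands(fib))
        assert tw.mean_phi_plus_psi == pytest.approx(0.0, abs=0.3)
        assert tw.handedness == "indeterminate"

    def test_left_handed_sheet_positive_sum(self, plain_fibril):
        fibril, truth = plain_fibril
        tw = fk.twist_statistic(fk.compute_dihedrals(fibril), fk.assign_strands(fibril))
        assert tw.mean_phi_plus_psi == pytest.approx(truth.phi_psi_sum, abs=0.01)
        assert tw.handedness == "left"
        assert set(tw.per_chain) <= set(fibril.chain_ids)

    def test_mirror_negates_statistic_and_flips_handedness(self, plain_fibril):
        fibril, _ = plain_fibril
        tw = fk.twist_statistic(fk.compute_dihedrals(fibril), fk.assign_strands(fibril))
        m = mirror_model(fibril)
        tw_m = fk.twist_statistic(fk.compute_dihedrals(m), fk.assign_strands(m))
        assert tw_m.mean_phi_plus_psi == pytest.approx(-tw.mean_phi_plus_psi, abs=1e-6)
        assert {tw.handedness, tw_m.handedness} == {"left", "right"}

    def test_invariant_under_chain_reordering_and_rigid_motion(self, plain_fibril):
        from scipy.spatial.transform import Rotation

        fibril, _ = plain_fibril
        tw = fk.twist_statistic(fk.compute_dihedrals(fibril), fk.assign_strands(fibril))
        shuffled = fibril.copy()
        shuffled.chains = shuffled.chains[::-1]
        R = Rotation.from_euler("xyz", [12.0, 55.0, -80.0], degrees=True).as_matrix()
        moved = shuffled.transformed(R, np.array([1.0, 2.0, 3.0]))
        tw2 = fk.twist_statistic(fk.compute_dihedrals(moved), fk.assign_strands(moved))
        assert tw2.mean_phi_plus_psi == pytest.approx(tw.mean_phi_plus_psi, abs=1e-6)

    def test_empty_statistic_raises(self):
        sub = build_subunit(FibrilSpec(strand_length=8, arch="none"))
        dihedrals = fk.compute_dihedrals(sub)
        asg = fk.assign_strands(sub)  # no inter-chain bonds -> no strands
        with pytest.raises(EmptyStatisticError):
            fk.twist_statistic(dihedrals, asg)
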