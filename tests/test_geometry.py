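"""Geometry core: torsions, pseudorotation, extraction, measurement."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sugarcdl.geometry import (
    GeometryError,
    compute_pseudorotation,
    extract_fragments,
    measure_fragment,
    measure_torsion,
    pseudorotation_torsions,
)
from sugarcdl.synthetic import build_dinucleotide, build_nucleotide, to_gemmi_structure


# ---------------------------------------------------------------------------
# measure_torsion
# ---------------------------------------------------------------------------

A = np.array([0.0, 1.0, 0.0])
B = np.array([0.0, 0.0, 0.0])
C = np.array([1.0, 0.0, 0.0])


def test_torsion_planar_cis_is_zero():
    d = np.array([1.0, 1.0, 0.0])
    assert measure_torsion(A, B, C, d) == pytest.approx(0.0, abs=1e-12)


def test_torsion_planar_trans_is_180():
    d = np.array([1.0, -1.0, 0.0])
    assert measure_torsion(A, B, C, d) == pytest.approx(180.0, abs=1e-12)


def test_torsion_mirror_image_flips_sign():
    d = np.array([1.0, 0.5, 0.8])
    t = measure_torsion(A, B, C, d)
    mirror = [p * np.array([1.0, 1.0, -1.0]) for p in (A, B, C, d)]
    assert measure_torsion(*mirror) == pytest.approx(-t, abs=1e-12)


def test_torsion_invariant_under_atom_order_reversal():
    d = np.array([1.0, 0.4, -0.9])
    assert measure_torsion(d, C, B, A) == pytest.approx(
        measure_torsion(A, B, C, d), abs=1e-12)


def test_torsion_degenerate_raises():
    with pytest.raises(GeometryError):
        measure_torsion(A, B, B, C)  # coincident central atoms
    with pytest.raises(GeometryError):
        measure_torsion(2 * C, B, C, A)  # a collinear with b-c


# ---------------------------------------------------------------------------
# pseudorotation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("P,tau", [(18.0, 38.0), (162.0, 35.0)])
def test_pseudorotation_exact_round_trip(P, tau):
    pk = compute_pseudorotation(pseudorotation_torsions(P, tau))
    assert pk.P == pytest.approx(P, abs=1e-6)
    assert pk.tau_m == pytest.approx(tau, abs=1e-6)


@given(P=st.floats(0.0, 359.999), tau=st.floats(20.0, 50.0))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_pseudorotation_round_trip_property(P, tau):
    pk = compute_pseudorotation(pseudorotation_torsions(P, tau))
    dP = (pk.P - P + 180.0) % 360.0 - 180.0
    assert abs(dP) < 1e-6
    assert pk.tau_m == pytest.approx(tau, abs=1e-6)


def _brute_force_pucker(nu):
    """Independent oracle: scan P on a fine grid, tau analytic per P."""
    nu = np.asarray(nu, float)
    phases = np.radians(144.0 * (np.arange(5) - 2))
    best = None
    for P in np.arange(0.0, 360.0, 0.02):
        c = np.cos(np.radians(P) + phases)
        tau = float(nu @ c / (c @ c))
        if tau < 0:  # amplitude is non-negative by definition
            continue
        sse = float(np.sum((nu - tau * c) ** 2))
        if best is None or sse < best[0]:
            best = (sse, P, tau)
    return best[1], best[2]


def test_pseudorotation_noisy_recovery_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    nu = np.asarray(pseudorotation_torsions(90.0, 40.0)) + rng.normal(0, 0.5, 5)
    pk = compute_pseudorotation(nu)
    P_o, tau_o = _brute_force_pucker(nu)
    assert pk.P == pytest.approx(90.0, abs=1.5)
    assert pk.tau_m == pytest.approx(40.0, abs=1.5)
    assert pk.P == pytest.approx(P_o, abs=0.02)
    assert pk.tau_m == pytest.approx(tau_o, abs=0.01)


def test_flat_ring_reports_zero_amplitude_by_convention():
    pk = compute_pseudorotation([0.0] * 5)
    assert pk.tau_m == 0.0
    assert pk.P == 0.0
    assert pk.flat


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def test_single_adenosine_extracts_one_purine_ribose_fragment():
    st_ = to_gemmi_structure(build_nucleotide(), "ribose", "purine")
    frags = extract_fragments(st_)
    assert len(frags) == 1
    f = frags[0]
    assert f.base_type == "purine" and f.sugar_type == "ribose"
    assert f.terminal_o3 and f.terminal_o5


def test_dinucleotide_terminal_flags():
    residues = build_dinucleotide(sugar_type="deoxyribose", base_type="pyrimidine")
    st_ = to_gemmi_structure(residues, "deoxyribose", "pyrimidine")
    frags = {f.resnum: f for f in extract_fragments(st_)}
    assert frags[1].terminal_o5 and not frags[1].terminal_o3
    assert frags[2].terminal_o3 and not frags[2].terminal_o5


def test_residue_missing_atom_is_skipped_with_warning(caplog):
    coords = build_nucleotide()
    coords.pop("C5'")
    st_ = to_gemmi_structure(coords, "ribose", "purine")
    with caplog.at_level(logging.WARNING, logger="sugarcdl.geometry"):
        frags = extract_fragments(st_)
    assert frags == []
    assert any("C5'" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("sugar,base", [("ribose", "purine"),
                                        ("deoxyribose", "pyrimidine")])
def test_fixture_round_trip_chi_gamma_and_imposed_bond(sugar, base):
    st_ = to_gemmi_structure(
        build_nucleotide(sugar_type=sugar, base_type=base,
                         chi=-120.0, gamma=60.0, ring_bond=1.52),
        sugar, base)
    (frag,) = extract_fragments(st_)
    geom = measure_fragment(frag)
    assert geom.torsions.chi == pytest.approx(-120.0, abs=1e-6)
    assert geom.torsions.gamma == pytest.approx(60.0, abs=1e-6)
    assert geom.bonds["C1'-C2'"] == pytest.approx(1.52, abs=1e-9)


def test_chi_uses_n9_c4_path_for_purine_and_n1_c2_for_pyrimidine():
    pur = to_gemmi_structure(build_nucleotide(base_type="purine", chi=75.0),
                             "ribose", "purine")
    pyr = to_gemmi_structure(
        build_nucleotide(base_type="pyrimidine", chi=75.0), "ribose", "pyrimidine")
    for st_, n_name in ((pur, "N9"), (pyr, "N1")):
        (frag,) = extract_fragments(st_)
        assert frag.glyco_n == n_name
        assert measure_fragment(frag).torsions.chi == pytest.approx(75.0, abs=1e-6)


def test_all_measurements_rigid_body_invariant():
    from scipy.spatial.transform import Rotation

    st_ = to_gemmi_structure(build_nucleotide(P=160.0, tau_m=36.0), "ribose", "purine")
    (frag,) = extract_fragments(st_)
    g0 = measure_fragment(frag)

    rot = Rotation.random(random_state=3).as_matrix()
    shift = np.array([12.3, -4.5, 7.7])
    from dataclasses import replace
    moved = replace(frag, atoms={
        nm: replace(a, position=rot @ a.position + shift)
        for nm, a in frag.atoms.items()})
    g1 = measure_fragment(moved)
    for k in g0.bonds:
        assert g1.bonds[k] == pytest.approx(g0.bonds[k], abs=1e-9)
    for k in g0.angles:
        assert g1.angles[k] == pytest.approx(g0.angles[k], abs=1e-9)
    assert g1.torsions.chi == pytest.approx(g0.torsions.chi, abs=1e-9)
    assert g1.pucker.P == pytest.approx(g0.pucker.P, abs=1e-9)
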