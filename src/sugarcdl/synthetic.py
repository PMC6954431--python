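"""Synthetic data: CSD-style fragment-geometry tables and 3D test fixtures.

Two kinds of synthetic objects live here.

``generate_synthetic_table`` emulates a curated small-molecule fragment
table: one row per sugar-base fragment with conformational variables drawn
from realistic nucleoside distributions, per-parameter values drawn from a
restraint dictionary (group mean or functional value plus Gaussian noise at
the dictionary sigma), structure-level quality metadata (R-factor,
sigma(C-C), disorder flag) and optional planted gross outliers.  Its
defaults reproduce the study conditions of the source analysis: 130
ribose-purine, 51 deoxyribose-purine, 84 ribose-pyrimidine and 167
deoxyribose-pyrimidine fragments.

``build_nucleotide`` / ``build_dinucleotide`` construct idealized 3D
nucleotide coordinates at requested (P, tau_m, chi, gamma) for geometry
round-trip tests; chi and gamma are exact by construction, the ring pucker
is calibrated iteratively to the requested (P, tau_m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

from .classify import ConformationContext
from .dictionary import RestraintDictionary, applicable_parameters
from .geometry import (
    NU_TORSION_ATOMS,
    compute_pseudorotation,
    measure_torsion,
)

__all__ = [
    "DEFAULT_CLASS_SIZES",
    "CHI_ANGLE_TRUE_CURVES",
    "evaluate_true_chi_curve",
    "generate_synthetic_table",
    "build_nucleotide",
    "build_dinucleotide",
    "to_gemmi_structure",
]

#: fragment counts per sugar-base class under the study conditions
DEFAULT_CLASS_SIZES = {
    ("ribose", "purine"): 130,
    ("deoxyribose", "purine"): 51,
    ("ribose", "pyrimidine"): 84,
    ("deoxyribose", "pyrimidine"): 167,
}

# ---------------------------------------------------------------------------
# Analytic truth curves for the chi-dependent glycosidic-link angles.
# f(chi) = c + a1*cos(2*chi + p1) + a2*cos(chi + p2)   (degrees)
# The two-harmonic form is 360-periodic but not sinusoidal, with extremes
# near chi = +/-90 and a syn/anti asymmetry carried by the second harmonic.
# These curves are the generating truth used to build the packaged
# tabulated grids; peak-to-peak swings stay at or below ~5 degrees.
# ---------------------------------------------------------------------------
CHI_ANGLE_TRUE_CURVES: dict[tuple[str, str], tuple[float, ...]] = {
    ("N-C1'-C2'", "purine"): (113.6, 1.6, 0.0, 1.0, -90.0),
    ("N-C1'-C2'", "pyrimidine"): (112.9, 1.3, 0.0, 0.9, -90.0),
    ("N-C1'-O4'", "purine"): (108.2, 1.1, 180.0, 0.9, 90.0),
    ("N-C1'-O4'", "pyrimidine"): (108.4, 0.9, 180.0, 0.8, 90.0),
    ("C1'-N-C2/C4", "purine"): (126.4, 1.4, 0.0, 1.0, -90.0),
    ("C1'-N-C2/C4", "pyrimidine"): (117.8, 1.5, 0.0, 1.1, -90.0),
    ("C1'-N-C6/C8", "purine"): (127.0, 1.4, 180.0, 1.1, 90.0),
    ("C1'-N-C6/C8", "pyrimidine"): (121.2, 1.5, 180.0, 1.2, 90.0),
}

#: observation noise (deg) used when building the packaged grid curves
CHI_ANGLE_TRUE_SIGMA = {
    "N-C1'-C2'": 1.2,
    "N-C1'-O4'": 1.0,
    "C1'-N-C2/C4": 1.3,
    "C1'-N-C6/C8": 1.3,
}


def evaluate_true_chi_curve(parameter: str, base_type: str, chi) -> np.ndarray:
    """Noise-free value of a glycosidic-angle truth curve at chi (degrees)."""
    c, a1, p1, a2, p2 = CHI_ANGLE_TRUE_CURVES[(parameter, base_type)]
    chi = np.asarray(chi, dtype=float)
    return (c
            + a1 * np.cos(np.radians(2.0 * chi + p1))
            + a2 * np.cos(np.radians(chi + p2)))


# ---------------------------------------------------------------------------
# Conformer sampling
# ---------------------------------------------------------------------------

def _sample_context(rng: np.random.Generator, sugar: str, base: str,
                    gamma_other_fraction: float) -> ConformationContext:
    # pucker mixture: ribose favours C3'-endo, deoxyribose C2'-endo
    p_c3 = 0.55 if sugar == "ribose" else 0.35
    p_c2 = 0.90 - p_c3  # Other gets the remaining 10%
    u = rng.random()
    if u < p_c3:
        P = rng.uniform(1.0, 35.0)
    elif u < p_c3 + p_c2:
        P = rng.uniform(145.0, 189.0)
    else:
        P = rng.uniform(40.0, 140.0)
    # amplitude spread: uniform over the fitted range; intermediate puckers
    # show the broadest amplitudes
    tau_m = rng.uniform(22.0, 48.0) if 40.0 <= P <= 140.0 else rng.uniform(28.0, 48.0)
    # chi: 85% anti; magnitude uniform over the rotamer range, sign mostly -
    anti = rng.random() < 0.85
    mag = rng.uniform(91.0, 180.0) if anti else rng.uniform(0.0, 90.0)
    chi = -mag if rng.random() < 0.65 else mag
    # gamma rotamer mixture with a small unassigned tail
    if rng.random() < gamma_other_fraction:
        gamma = rng.uniform(100.0, 140.0)  # outside all three windows
    else:
        center = rng.choice([60.0, 180.0, -60.0], p=[0.65, 0.21, 0.14])
        off = float(np.clip(rng.normal(0.0, 10.0), -28.0, 28.0))
        gamma = center + off
        if gamma > 180.0:
            gamma -= 360.0
    return ConformationContext.from_values(sugar, base, P=P, tau_m=tau_m,
                                           chi=chi, gamma=gamma)


def generate_synthetic_table(
    dictionary: RestraintDictionary | None = None,
    class_sizes: dict | None = None,
    outlier_fraction: float = 0.02,
    poor_quality_fraction: float = 0.05,
    gamma_other_fraction: float = 0.03,
    seed: int = 0,
    return_truth: bool = False,
):
    """Reproducible CSD-style fragment table drawn from a dictionary.

    Returns a :class:`pandas.DataFrame` with one row per fragment:
    structure/quality metadata, the conformational variables, and one
    column per measured bond/angle.  With ``return_truth=True`` also
    returns a parallel DataFrame of the noise-free generating values
    (NaN where a parameter does not apply).
    """
    if dictionary is None:
        dictionary = RestraintDictionary.load("this-work")
    if class_sizes is None:
        class_sizes = DEFAULT_CLASS_SIZES
    rng = np.random.default_rng(seed)

    rows: list[dict] = []
    truth_rows: list[dict] = []
    i = 0
    for (sugar, base), n in class_sizes.items():
        for _ in range(int(n)):
            ctx = _sample_context(rng, sugar, base, gamma_other_fraction)
            poor = rng.random() < poor_quality_fraction
            if poor and rng.random() < 0.5:
                r_factor, sig_cc = rng.uniform(8.6, 10.0), rng.uniform(0.003, 0.0095)
            elif poor:
                r_factor, sig_cc = rng.uniform(4.5, 8.4), rng.uniform(0.0105, 0.013)
            else:
                r_factor, sig_cc = rng.uniform(4.5, 8.4), rng.uniform(0.003, 0.0095)
            row = {
                "structure_id": f"SYN{i:04d}",
                "R_factor": r_factor,
                "sigma_CC": sig_cc,
                "disordered": bool(rng.random() < 0.10),
                "sugar_type": sugar,
                "base_type": base,
                "P": ctx.P,
                "tau_m": ctx.tau_m,
                "chi": ctx.chi,
                "gamma": ctx.gamma,
                "terminal_o3": False,
                "terminal_o5": False,
            }
            truth = dict(row)
            for param in applicable_parameters(ctx):
                if (param, base) in CHI_ANGLE_TRUE_CURVES:
                    # glycosidic-link angles: the population follows the
                    # analytic truth curve with observation noise (the
                    # dictionary's tabulated sigma additionally carries the
                    # curve-estimation uncertainty and would double-count)
                    ideal = float(evaluate_true_chi_curve(param, base, ctx.chi))
                    sigma = CHI_ANGLE_TRUE_SIGMA[param]
                else:
                    ideal, sigma = dictionary.lookup_evaluate(param, ctx)
                row[param] = ideal + rng.normal(0.0, sigma)
                truth[param] = ideal
            rows.append(row)
            truth_rows.append(truth)
            i += 1

    table = pd.DataFrame(rows)
    truth_df = pd.DataFrame(truth_rows)

    # plant gross outliers: a random parameter shifted by 8-12 sigma
    meta = {"structure_id", "R_factor", "sigma_CC", "disordered", "sugar_type",
            "base_type", "P", "tau_m", "chi", "gamma", "terminal_o3", "terminal_o5"}
    param_cols = [c for c in table.columns if c not in meta]
    n_out = int(round(outlier_fraction * len(table)))
    if n_out:
        idx = rng.choice(len(table), size=n_out, replace=False)
        for j in idx:
            avail = [c for c in param_cols if pd.notna(table.iloc[j][c])]
            col = avail[rng.integers(len(avail))]
            ctx_sigma = table[col].std()
            sign = 1.0 if rng.random() < 0.5 else -1.0
            table.loc[table.index[j], col] += sign * rng.uniform(8.0, 12.0) * ctx_sigma
    if return_truth:
        return table, truth_df
    return table


# ---------------------------------------------------------------------------
# 3D fixture builders
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: new atom bonded to c with given internal coordinates.

    The returned point d satisfies |d-c| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (degrees).
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang, tor = math.radians(angle), math.radians(torsion)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


_RING_ORDER = ("C1'", "C2'", "C3'", "C4'", "O4'")


def _ring_coords(amplitude: float, phase: float, scale: float) -> dict[str, np.ndarray]:
    """Puckered pentagon: planar ring with cosine out-of-plane displacements."""
    coords = {}
    r = scale / (2.0 * math.sin(math.pi / 5.0))
    for k, name in enumerate(_RING_ORDER):
        th = 2.0 * math.pi * k / 5.0
        z = amplitude * math.cos(phase + 4.0 * math.pi * k / 5.0)
        coords[name] = np.array([r * math.cos(th), r * math.sin(th), z])
    return coords


def _measure_ring_pucker(coords: dict[str, np.ndarray]):
    nu = tuple(measure_torsion(*(coords[nm] for nm in path))
               for path in NU_TORSION_ATOMS)
    return compute_pseudorotation(nu)


def _calibrated_ring(P: float, tau_m: float, ring_bond: float) -> dict[str, np.ndarray]:
    """Iterate (amplitude, phase) of the z-displacement pattern until the
    measured pseudorotation matches the request to ~1e-9 degrees."""
    amp = 0.45 * math.radians(max(tau_m, 1e-3)) * ring_bond / math.radians(38.0) * 0.38
    amp = max(amp, 0.05)
    phase = 0.0
    # determine phase->P slope with a finite difference once
    c0 = _ring_coords(amp, phase, ring_bond)
    p0 = _measure_ring_pucker(c0)
    c1 = _ring_coords(amp, phase + 0.05, ring_bond)
    p1 = _measure_ring_pucker(c1)
    dP = ((p1.P - p0.P + 180.0) % 360.0) - 180.0
    sign = 1.0 if dP >= 0 else -1.0  # phase -> P slope is +/-1 rad/rad
    coords = c0
    for _ in range(200):
        pk = _measure_ring_pucker(coords)
        err_p = ((P - pk.P + 180.0) % 360.0) - 180.0
        err_t = tau_m - pk.tau_m
        if abs(err_p) < 1e-10 and abs(err_t) < 1e-10:
            break
        phase += sign * math.radians(err_p)
        amp *= tau_m / max(pk.tau_m, 1e-9)
        coords = _ring_coords(amp, phase, ring_bond)
    # uniform rescale (torsion-invariant) so |C1'-C2'| equals ring_bond
    scale = ring_bond / float(np.linalg.norm(coords["C1'"] - coords["C2'"]))
    return {nm: xyz * scale for nm, xyz in coords.items()}


def build_nucleotide(
    sugar_type: str = "ribose",
    base_type: str = "purine",
    P: float = 18.0,
    tau_m: float = 38.0,
    chi: float = -120.0,
    gamma: float = 60.0,
    terminal_o3: bool = True,
    terminal_o5: bool = True,
    ring_bond: float = 1.52,
) -> dict[str, np.ndarray]:
    """Idealized nucleotide coordinates at the requested conformation.

    chi and gamma are exact by construction; (P, tau_m) are matched by the
    calibrated ring.  All ring bonds share ``ring_bond``.  Phosphorus atoms
    are added 1.6 A from O3'/O5' when the corresponding terminal flag is
    False, so that terminal detection behaves as on real structures.
    """
    coords = _calibrated_ring(P, tau_m, ring_bond)
    c1, c2, c3, c4, o4 = (coords[nm] for nm in _RING_ORDER)

    n_name = "N9" if base_type == "purine" else "N1"
    # glycosidic nitrogen on the face opposite the ring-oxygen lone pairs
    coords[n_name] = place_atom(c2, o4, c1, 1.47, 108.5, -119.0)
    near, far = (("C4", "C8") if base_type == "purine" else ("C2", "C6"))
    ang_near = 126.5 if base_type == "purine" else 118.0
    ang_far = 127.5 if base_type == "purine" else 121.0
    coords[near] = place_atom(o4, c1, coords[n_name], 1.37, ang_near, chi)
    chi_far = chi - 180.0
    if chi_far <= -180.0:
        chi_far += 360.0
    coords[far] = place_atom(o4, c1, coords[n_name], 1.37, ang_far, chi_far)

    if sugar_type == "ribose":
        coords["O2'"] = place_atom(c4, c3, c2, 1.412, 113.0, -155.0)
    coords["O3'"] = place_atom(o4, c4, c3, 1.42, 110.5, -95.0)

    t_o4 = measure_torsion(c2, c3, c4, o4)
    t_c5 = t_o4 + 120.0
    if t_c5 > 180.0:
        t_c5 -= 360.0
    coords["C5'"] = place_atom(c2, c3, c4, 1.51, 115.5, t_c5)
    if np.linalg.norm(coords["C5'"] - o4) < 2.0:  # wrong face: flip
        t_c5 = t_o4 - 120.0
        if t_c5 <= -180.0:
            t_c5 += 360.0
        coords["C5'"] = place_atom(c2, c3, c4, 1.51, 115.5, t_c5)
    coords["O5'"] = place_atom(c3, c4, coords["C5'"], 1.425, 110.6, gamma)

    if not terminal_o3:
        coords["P"] = place_atom(c4, c3, coords["O3'"], 1.607, 119.0, -60.0)
    if not terminal_o5:
        coords["P5"] = place_atom(c4, coords["C5'"], coords["O5'"], 1.593, 120.0, -150.0)
    return coords


def build_dinucleotide(**kwargs) -> list[tuple[str, dict[str, np.ndarray]]]:
    """Two linked nucleotides: residue 1 has a free 5'-OH, residue 2's
    5'-phosphorus sits 1.6 A from residue 1's O3' (the phosphodiester
    bridge), and residue 2's O3' is free."""
    res1 = build_nucleotide(terminal_o3=True, terminal_o5=True, **kwargs)
    res2 = build_nucleotide(terminal_o3=True, terminal_o5=False, **kwargs)
    bridge = res1["O3'"] + 1.6 * _unit(res1["O3'"] - res1["C3'"])
    shift = bridge - res2["P5"]
    res2 = {nm: xyz + shift for nm, xyz in res2.items()}
    return [("1", res1), ("2", res2)]


_RESNAME = {
    ("ribose", "purine"): "A",
    ("ribose", "pyrimidine"): "C",
    ("deoxyribose", "purine"): "DA",
    ("deoxyribose", "pyrimidine"): "DC",
}


def to_gemmi_structure(
    residues,
    sugar_type: str = "ribose",
    base_type: str = "purine",
    chain: str = "A",
    altloc: str = "",
    occupancy: float = 1.0,
    name: str = "synthetic",
) -> gemmi.Structure:
    """Pack builder output into a gemmi Structure (first model, one chain).

    ``residues`` is a coordinate dict for a single residue, or a list of
    (residue_number_string, coords) pairs as from :func:`build_dinucleotide`.
    The bridging phosphorus placeholder ``P5`` is renamed to ``P``.
    """
    if isinstance(residues, dict):
        residues = [("1", residues)]
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain)
    for num, coords in residues:
        res = gemmi.Residue()
        res.name = _RESNAME[(sugar_type, base_type)]
        res.seqid = gemmi.SeqId(int(num), " ")
        res.het_flag = "A"
        for atom_name, xyz in coords.items():
            at = gemmi.Atom()
            at.name = "P" if atom_name == "P5" else atom_name
            at.element = gemmi.Element(at.name[0])
            at.pos = gemmi.Position(*xyz)
            at.occ = occupancy
            if altloc:
                at.altloc = altloc
            res.add_atom(at)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st
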