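"""Restraint emitters for the three refinement-program dialects.

Distance and angle targets are written as REFMAC external-restraint
keyword lines, PHENIX ``geometry_restraints.edits`` blocks, or SHELXL
DFIX/DANG instructions.  SHELXL has no native angle restraint, so an angle
theta between bonds b1 and b2 becomes a DANG 1-3 distance
``d13 = sqrt(b1^2 + b2^2 - 2 b1 b2 cos theta)`` with the sigma propagated
to first order from the bond and angle sigmas.

Output is deterministic: records are sorted by chain, residue, altloc,
kind and atom names, and every invocation regenerates the restraints from
scratch (conformational group assignments change as a model is rebuilt,
so restraints should be refreshed before each refinement cycle).

Printed precision is fixed: 3 decimals for distances (A), 2 for angles
(degrees) and their sigmas.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .dictionary import GeneratedRestraint

logger = logging.getLogger(__name__)

__all__ = [
    "RestraintRecord",
    "records_from_generated",
    "write_refmac",
    "write_phenix",
    "write_shelxl",
    "MissingBondError",
]


class MissingBondError(KeyError):
    """An angle record's flanking bond target is unavailable (SHELXL)."""


@dataclass(frozen=True)
class AtomSelector:
    chain: str
    resnum: int
    icode: str
    altloc: str
    name: str


@dataclass(frozen=True)
class RestraintRecord:
    """One distance or angle restraint with resolved atom selectors."""

    kind: str  # "distance" | "angle"
    atoms: tuple[AtomSelector, ...]
    ideal: float
    sigma: float
    parameter: str = ""

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        expected = 2 if self.kind == "distance" else 3
        if self.kind not in ("distance", "angle") or len(self.atoms) != expected:
            raise ValueError(f"bad record: kind={self.kind}, {len(self.atoms)} atoms")


def records_from_generated(generated) -> list[RestraintRecord]:
    """Convert dictionary output into writer records (one per restraint)."""
    records = []
    for g in generated:
        f = g.fragment
        sel = tuple(
            AtomSelector(chain=f.chain, resnum=f.resnum, icode=f.icode,
                         altloc=f.altloc, name=nm)
            for nm in g.atom_names
        )
        records.append(RestraintRecord(
            kind="distance" if g.kind == "bond" else "angle",
            atoms=sel, ideal=g.ideal, sigma=g.sigma, parameter=g.parameter,
        ))
    return records


def _sorted(records) -> list[RestraintRecord]:
    return sorted(records, key=lambda r: (
        r.atoms[0].chain, r.atoms[0].resnum, r.atoms[0].icode,
        r.atoms[0].altloc, r.kind, r.parameter,
        tuple(a.name for a in r.atoms)))


def _fmt(value: float, kind: str) -> str:
    return f"{value:.3f}" if kind == "distance" else f"{value:.2f}"


# --------------------------------------------------------------------------
# REFMAC
# --------------------------------------------------------------------------

def _refmac_atom(a: AtomSelector, ordinal: str) -> str:
    parts = [f"{ordinal} chain {a.chain} resi {a.resnum}"]
    if a.icode:
        parts.append(f"ins {a.icode}")
    parts.append(f"atom {a.name}")
    if a.altloc:
        parts.append(f"alte {a.altloc}")
    return " ".join(parts)


def write_refmac(records) -> str:
    """External-restraint keyword file (one ``exte`` line per record)."""
    lines = ["# sugarcdl conformation-dependent sugar restraints (REFMAC external)"]
    for r in _sorted(records):
        ordinals = ("first", "second", "next")
        sel = " ".join(_refmac_atom(a, o) for a, o in zip(r.atoms, ordinals))
        key = "dist" if r.kind == "distance" else "angle"
        lines.append(
            f"exte {key} {sel} value {_fmt(r.ideal, r.kind)} "
            f"sigma {_fmt(r.sigma, r.kind)}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# PHENIX
# --------------------------------------------------------------------------

def _phenix_sel(a: AtomSelector) -> str:
    sel = f"chain {a.chain} and resseq {a.resnum} and name {a.name}"
    if a.icode:
        sel += f" and icode {a.icode}"
    if a.altloc:
        sel += f" and altid {a.altloc}"
    return sel


def write_phenix(records) -> str:
    """``refinement.geometry_restraints.edits`` parameter file."""
    body = []
    for r in _sorted(records):
        if r.kind == "distance":
            body.append("    bond {")
            body.append("      action = *add")
            for i, a in enumerate(r.atoms, 1):
                body.append(f"      atom_selection_{i} = {_phenix_sel(a)}")
            body.append(f"      distance_ideal = {_fmt(r.ideal, r.kind)}")
            body.append(f"      sigma = {_fmt(r.sigma, r.kind)}")
            body.append("    }")
        else:
            body.append("    angle {")
            body.append("      action = *add")
            for i, a in enumerate(r.atoms, 1):
                body.append(f"      atom_selection_{i} = {_phenix_sel(a)}")
            body.append(f"      angle_ideal = {_fmt(r.ideal, r.kind)}")
            body.append(f"      sigma = {_fmt(r.sigma, r.kind)}")
            body.append("    }")
    lines = ["refinement {", "  geometry_restraints.edits {"]
    lines += body
    lines += ["  }", "}"]
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# SHELXL
# --------------------------------------------------------------------------

def angle_to_13_distance(b1: float, b2: float, theta_deg: float,
                         sigma_b1: float, sigma_b2: float,
                         sigma_theta_deg: float) -> tuple[float, float]:
    """Law-of-cosines 1-3 distance and first-order propagated sigma.

    d13 = sqrt(b1^2 + b2^2 - 2 b1 b2 cos theta);
    sigma13^2 = (dd/db1 s1)^2 + (dd/db2 s2)^2 + (dd/dtheta s_theta)^2 with
    dd/dtheta = b1 b2 sin(theta) / d13 (theta in radians).
    """
    th = math.radians(theta_deg)
    d13 = math.sqrt(b1 * b1 + b2 * b2 - 2.0 * b1 * b2 * math.cos(th))
    dd_b1 = (b1 - b2 * math.cos(th)) / d13
    dd_b2 = (b2 - b1 * math.cos(th)) / d13
    dd_th = b1 * b2 * math.sin(th) / d13
    var = ((dd_b1 * sigma_b1) ** 2 + (dd_b2 * sigma_b2) ** 2
           + (dd_th * math.radians(sigma_theta_deg)) ** 2)
    return d13, math.sqrt(var)


def _shelxl_atom(a: AtomSelector) -> str:
    # SHELXL names atoms NAME_resnum; altloc conformers carry part suffixes
    # in real files, here encoded in the residue field of the name.
    return f"{a.name}_{a.resnum}"


def write_shelxl(records, on_missing_bond: str = "error") -> str:
    """DFIX (distances) and DANG (angle-derived 1-3 distances) lines.

    Every angle needs both flanking bond targets from the same record set;
    a missing one raises :class:`MissingBondError` naming the bond, or
    skips the angle with a log entry when ``on_missing_bond="skip"``.
    """
    recs = _sorted(records)
    # index bond targets by (fragment identity, unordered atom pair)
    bond_index: dict = {}
    for r in recs:
        if r.kind == "distance":
            a1, a2 = r.atoms
            key = (a1.chain, a1.resnum, a1.icode, a1.altloc,
                   frozenset((a1.name, a2.name)))
            bond_index[key] = r
    lines = ["REM sugarcdl conformation-dependent sugar restraints (SHELXL)"]
    for r in recs:
        if r.kind == "distance":
            a1, a2 = r.atoms
            lines.append(f"DFIX {r.ideal:.3f} {r.sigma:.3f} "
                         f"{_shelxl_atom(a1)} {_shelxl_atom(a2)}")
            continue
        a1, a2, a3 = r.atoms
        frag = (a1.chain, a1.resnum, a1.icode, a1.altloc)
        sides = []
        for outer in (a1, a3):
            key = frag + (frozenset((a2.name, outer.name)),)
            b = bond_index.get(key)
            if b is None:
                msg = (f"angle {r.parameter}: flanking bond "
                       f"{a2.name}-{outer.name} has no restraint target")
                if on_missing_bond == "skip":
                    logger.warning("%s; skipped", msg)
                    sides = None
                    break
                raise MissingBondError(msg)
            sides.append(b)
        if sides is None:
            continue
        d13, s13 = angle_to_13_distance(
            sides[0].ideal, sides[1].ideal, r.ideal,
            sides[0].sigma, sides[1].sigma, r.sigma)
        lines.append(f"DANG {d13:.3f} {s13:.3f} "
                     f"{_shelxl_atom(a1)} {_shelxl_atom(a3)}")
    return "\n".join(lines) + "\n"
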