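"""Coordinate-level geometry of nucleic-acid sugar (furanose) fragments.

This module parses PDB/mmCIF coordinates (via gemmi), extracts one
(deoxy)ribose fragment per nucleotide per alternative conformation, and
measures every bond length, bond angle and torsion angle that the
conformation-dependent restraint dictionary knows about, including the
pseudorotation description (P, tau_m) of the furanose ring pucker.

Atom nomenclature follows the standard PDB convention with primes
(C1', C2', ..., O4'); the glycosidic nitrogen is N9 for purines and N1 for
pyrimidines.  All distances are in angstroms and all angles in degrees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomSite",
    "SugarFragment",
    "TorsionSet",
    "PuckerParams",
    "FragmentGeometry",
    "GeometryError",
    "measure_torsion",
    "measure_angle",
    "measure_distance",
    "compute_pseudorotation",
    "pseudorotation_torsions",
    "extract_fragments",
    "measure_fragment",
    "read_structure",
    "BOND_ATOMS",
    "ANGLE_ATOMS",
    "NU_TORSION_ATOMS",
    "PURINE_RESIDUES",
    "PYRIMIDINE_RESIDUES",
]


class GeometryError(ValueError):
    """Raised for degenerate geometry (e.g. an undefined torsion)."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomSite:
    """One atom with its label, element, position (A), altloc and occupancy."""

    name: str
    element: str
    position: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


#: residue names recognised as purine / pyrimidine nucleotides
PURINE_RESIDUES = frozenset({"A", "G", "I", "DA", "DG", "DI"})
PYRIMIDINE_RESIDUES = frozenset({"C", "U", "DT", "DC", "DU", "T"})
KNOWN_RESIDUES = PURINE_RESIDUES | PYRIMIDINE_RESIDUES

_SUGAR_CORE = ("C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O3'", "O5'")
#: base atoms needed for chi and the three glycosidic-link angles
_BASE_ATOMS = {"purine": ("N9", "C4", "C8"), "pyrimidine": ("N1", "C2", "C6")}


@dataclass
class SugarFragment:
    """One (deoxy)ribose with its glycosidic attachment and chain context.

    ``atoms`` maps atom names to :class:`AtomSite`; it always contains the
    eight sugar core atoms, ``O2'`` when ``sugar_type == "ribose"``, and the
    glycosidic nitrogen with its two base neighbours.
    """

    chain: str
    resnum: int
    icode: str
    resname: str
    altloc: str
    atoms: Mapping[str, AtomSite]
    sugar_type: str  # "ribose" | "deoxyribose"
    base_type: str  # "purine" | "pyrimidine"
    terminal_o3: bool = False
    terminal_o5: bool = False

    def __post_init__(self) -> None:
        if self.sugar_type not in ("ribose", "deoxyribose"):
            raise ValueError(f"bad sugar_type {self.sugar_type!r}")
        if self.base_type not in ("purine", "pyrimidine"):
            raise ValueError(f"bad base_type {self.base_type!r}")
        has_o2 = "O2'" in self.atoms
        if has_o2 != (self.sugar_type == "ribose"):
            raise ValueError("O2' present iff sugar_type is ribose")
        n_name = self.glyco_n
        if n_name not in self.atoms:
            raise ValueError(f"missing glycosidic nitrogen {n_name}")

    @property
    def glyco_n(self) -> str:
        """Name of the glycosidic nitrogen (N9 purine, N1 pyrimidine)."""
        return "N9" if self.base_type == "purine" else "N1"

    @property
    def label(self) -> str:
        alt = f".{self.altloc}" if self.altloc else ""
        return f"{self.chain}/{self.resname}{self.resnum}{self.icode.strip()}{alt}"

    def pos(self, name: str) -> np.ndarray:
        return self.atoms[name].position


@dataclass(frozen=True)
class TorsionSet:
    """chi, gamma and the five endocyclic ring torsions nu0..nu4 (degrees)."""

    chi: float
    gamma: float
    nu: tuple[float, float, float, float, float]


@dataclass(frozen=True)
class PuckerParams:
    """Pseudorotation phase P in [0, 360) and amplitude tau_m >= 0, degrees."""

    P: float
    tau_m: float
    flat: bool = False  # True when the ring is planar and P is conventional


@dataclass
class FragmentGeometry:
    """Everything measured on one fragment: torsions, pucker, bonds, angles."""

    torsions: TorsionSet
    pucker: PuckerParams
    bonds: dict[str, float] = field(default_factory=dict)
    angles: dict[str, float] = field(default_factory=dict)


# --------------------------------------------------------------------------
# Elementary measurements
# --------------------------------------------------------------------------

def measure_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def measure_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Bond angle a-b-c in degrees."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise GeometryError("coincident atoms in angle measurement")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def measure_torsion(a, b, c, d) -> float:
    """Signed dihedral angle a-b-c-d in (-180, 180], IUPAC sign convention.

    Looking down b->c, the torsion is positive when d rotates clockwise
    from a.  Raises :class:`GeometryError` when b-c is degenerate or either
    terminal atom is collinear with the central bond.
    """
    a, b, c, d = (np.asarray(p, float) for p in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n2 = np.linalg.norm(b2)
    if n2 < 1e-12:
        raise GeometryError("central atoms coincide: torsion undefined")
    n1v = np.cross(b1, b2)
    n2v = np.cross(b2, b3)
    if np.linalg.norm(n1v) < 1e-10 or np.linalg.norm(n2v) < 1e-10:
        raise GeometryError("collinear atoms: torsion undefined")
    x = np.dot(n1v, n2v)
    y = np.dot(np.cross(n1v, n2v), b2) / n2
    ang = math.degrees(math.atan2(y, x))
    # wrap to (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return ang


# --------------------------------------------------------------------------
# Pseudorotation
# --------------------------------------------------------------------------

#: endocyclic torsion atom paths, in the order nu0..nu4
NU_TORSION_ATOMS: tuple[tuple[str, str, str, str], ...] = (
    ("C4'", "O4'", "C1'", "C2'"),  # nu0
    ("O4'", "C1'", "C2'", "C3'"),  # nu1
    ("C1'", "C2'", "C3'", "C4'"),  # nu2
    ("C2'", "C3'", "C4'", "O4'"),  # nu3
    ("C3'", "C4'", "O4'", "C1'"),  # nu4
)

_NU_PHASES = np.radians(144.0 * (np.arange(5) - 2))  # 144 deg * (j - 2)


def pseudorotation_torsions(P: float, tau_m: float) -> tuple[float, ...]:
    """Ideal endocyclic torsions nu_j = tau_m * cos(P + 144 deg * (j - 2))."""
    return tuple(float(tau_m * math.cos(math.radians(P) + ph)) for ph in _NU_PHASES)


def compute_pseudorotation(nu: Sequence[float]) -> PuckerParams:
    """Fit (P, tau_m) to five ring torsions by least squares.

    The model is nu_j = tau_m * cos(P + 144 deg * (j - 2)), linearised as
    nu_j = A cos(theta_j) - B sin(theta_j) with A = tau_m cos P and
    B = tau_m sin P; solving over all five torsions is robust to
    ring-closure noise.  A perfectly flat ring yields tau_m = 0 with P = 0
    by convention and ``flat=True``.
    """
    nu = np.asarray(nu, dtype=float)
    if nu.shape != (5,) or not np.all(np.isfinite(nu)):
        raise ValueError("need five finite ring torsions")
    design = np.column_stack([np.cos(_NU_PHASES), -np.sin(_NU_PHASES)])
    (A, B), *_ = np.linalg.lstsq(design, nu, rcond=None)
    tau_m = float(math.hypot(A, B))
    if tau_m < 1e-9:
        logger.debug("flat ring: tau_m = 0, P set to 0 by convention")
        return PuckerParams(P=0.0, tau_m=0.0, flat=True)
    P = math.degrees(math.atan2(B, A)) % 360.0
    return PuckerParams(P=P, tau_m=tau_m)


# --------------------------------------------------------------------------
# Dictionary parameter definitions (atom paths)
# --------------------------------------------------------------------------
# Parameter names are canonical: the glycosidic nitrogen is written "N" and
# base carbons "C2/C4" (the atom adjacent to N towards the six/five ring
# fusion) and "C6/C8"; measure_fragment resolves them per base type.

BOND_ATOMS: dict[str, tuple[str, str]] = {
    "C1'-C2'": ("C1'", "C2'"),
    "C2'-C3'": ("C2'", "C3'"),
    "C3'-C4'": ("C3'", "C4'"),
    "C4'-O4'": ("C4'", "O4'"),
    "O4'-C1'": ("O4'", "C1'"),
    "C2'-O2'": ("C2'", "O2'"),
    "C4'-C5'": ("C4'", "C5'"),
    "C3'-O3'": ("C3'", "O3'"),
    "C5'-O5'": ("C5'", "O5'"),
    "C1'-N": ("C1'", "N"),
}

ANGLE_ATOMS: dict[str, tuple[str, str, str]] = {
    # endocyclic
    "C1'-C2'-C3'": ("C1'", "C2'", "C3'"),
    "C2'-C3'-C4'": ("C2'", "C3'", "C4'"),
    "C3'-C4'-O4'": ("C3'", "C4'", "O4'"),
    "C4'-O4'-C1'": ("C4'", "O4'", "C1'"),
    "O4'-C1'-C2'": ("O4'", "C1'", "C2'"),
    # hydroxyl / ester branches
    "C1'-C2'-O2'": ("C1'", "C2'", "O2'"),
    "C3'-C2'-O2'": ("C3'", "C2'", "O2'"),
    "C2'-C3'-O3'": ("C2'", "C3'", "O3'"),
    "C4'-C3'-O3'": ("C4'", "C3'", "O3'"),
    # C5' side chain
    "C3'-C4'-C5'": ("C3'", "C4'", "C5'"),
    "C5'-C4'-O4'": ("C5'", "C4'", "O4'"),
    "C4'-C5'-O5'": ("C4'", "C5'", "O5'"),
    # glycosidic link
    "N-C1'-C2'": ("N", "C1'", "C2'"),
    "N-C1'-O4'": ("N", "C1'", "O4'"),
    "C1'-N-C2/C4": ("C1'", "N", "C2/C4"),
    "C1'-N-C6/C8": ("C1'", "N", "C6/C8"),
}

#: parameters that exist only for ribose
RIBOSE_ONLY_PARAMS = frozenset({"C2'-O2'", "C1'-C2'-O2'", "C3'-C2'-O2'"})


def resolve_atom(name: str, frag: SugarFragment) -> str:
    """Map a canonical parameter atom name to the fragment's actual atom."""
    if name == "N":
        return frag.glyco_n
    if name == "C2/C4":
        return "C4" if frag.base_type == "purine" else "C2"
    if name == "C6/C8":
        return "C8" if frag.base_type == "purine" else "C6"
    return name


# --------------------------------------------------------------------------
# Extraction from coordinate files
# --------------------------------------------------------------------------

def read_structure(path) -> gemmi.Structure:
    """Read a PDB or mmCIF file; only the first model is ever used."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def _phosphorus_positions(model: gemmi.Model) -> np.ndarray:
    pos = [
        np.array([at.pos.x, at.pos.y, at.pos.z])
        for chain in model
        for res in chain
        for at in res
        if at.element.name == "P"
    ]
    return np.array(pos) if pos else np.empty((0, 3))


def _near_phosphorus(point: np.ndarray, p_pos: np.ndarray, cutoff: float = 1.8) -> bool:
    if len(p_pos) == 0:
        return False
    return bool(np.min(np.linalg.norm(p_pos - point, axis=1)) < cutoff)


def _altloc_of(at: gemmi.Atom) -> str:
    # gemmi encodes "no altloc" as the NUL character
    return at.altloc if at.altloc not in ("", "\x00") else ""


def _collect_altloc(res: gemmi.Residue, name: str, alt: str) -> gemmi.Atom | None:
    """Atom with matching altloc, preferring the exact conformer over blank."""
    blank = None
    for at in res:
        if at.name != name:
            continue
        if _altloc_of(at) == alt and alt != "":
            return at
        if _altloc_of(at) == "":
            blank = at
    return blank


def extract_fragments(structure, include_partial_occupancy: bool = True) -> list[SugarFragment]:
    """Extract one :class:`SugarFragment` per nucleotide per altloc.

    ``structure`` is a :class:`gemmi.Structure` or a path to a PDB/mmCIF
    file.  Incomplete sugars and unknown residue names are skipped with a
    logged reason.  Terminal flags are set by the absence of a phosphorus
    atom within 1.8 A of O3'/O5'.  Hydrogens are ignored.
    """
    if not isinstance(structure, gemmi.Structure):
        structure = read_structure(structure)
    if len(structure) == 0:
        return []
    model = structure[0]
    p_positions = _phosphorus_positions(model)
    fragments: list[SugarFragment] = []
    n_skipped = 0
    for chain in model:
        for res in chain:
            rname = res.name.strip()
            if rname not in KNOWN_RESIDUES:
                if any(at.name == "C1'" for at in res):
                    logger.warning("skipping unknown residue %s %s%s", rname,
                                   chain.name, res.seqid.num)
                    n_skipped += 1
                continue
            base_type = "purine" if rname in PURINE_RESIDUES else "pyrimidine"
            sugar_type = "ribose" if any(a.name == "O2'" for a in res) else "deoxyribose"
            needed = list(_SUGAR_CORE) + list(_BASE_ATOMS[base_type])
            if sugar_type == "ribose":
                needed.append("O2'")
            altlocs = sorted({_altloc_of(at) for at in res} - {""}) or [""]
            for alt in altlocs:
                sites: dict[str, AtomSite] = {}
                missing = None
                for name in needed:
                    at = _collect_altloc(res, name, alt)
                    if at is None:
                        missing = name
                        break
                    sites[name] = AtomSite(
                        name=name,
                        element=at.element.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        altloc=_altloc_of(at),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                    )
                if missing is not None:
                    logger.warning("skipping %s %s%s%s: missing atom %s",
                                   rname, chain.name, res.seqid.num,
                                   f" alt {alt}" if alt else "", missing)
                    n_skipped += 1
                    continue
                frag = SugarFragment(
                    chain=chain.name,
                    resnum=res.seqid.num,
                    icode=res.seqid.icode.strip() or "",
                    resname=rname,
                    altloc=alt,
                    atoms=sites,
                    sugar_type=sugar_type,
                    base_type=base_type,
                    terminal_o3=not _near_phosphorus(sites["O3'"].position, p_positions),
                    terminal_o5=not _near_phosphorus(sites["O5'"].position, p_positions),
                )
                fragments.append(frag)
    logger.info("extracted %d sugar fragment(s), skipped %d", len(fragments), n_skipped)
    return fragments


# --------------------------------------------------------------------------
# Per-fragment measurement
# --------------------------------------------------------------------------

def measure_fragment(frag: SugarFragment) -> FragmentGeometry:
    """Measure chi, gamma, nu0..nu4, (P, tau_m) and every dictionary
    bond/angle applicable to the fragment.

    chi is the O4'-C1'-N1-C2 torsion for pyrimidines and O4'-C1'-N9-C4 for
    purines; gamma is O5'-C5'-C4'-C3'.
    """
    def p(name: str) -> np.ndarray:
        return frag.pos(resolve_atom(name, frag))

    chi = measure_torsion(p("O4'"), p("C1'"), p("N"), p("C2/C4"))
    gamma = measure_torsion(p("O5'"), p("C5'"), p("C4'"), p("C3'"))
    nu = tuple(
        measure_torsion(*(p(nm) for nm in path)) for path in NU_TORSION_ATOMS
    )
    pucker = compute_pseudorotation(nu)

    bonds: dict[str, float] = {}
    for pname, (a, b) in BOND_ATOMS.items():
        if pname in RIBOSE_ONLY_PARAMS and frag.sugar_type != "ribose":
            continue
        bonds[pname] = measure_distance(p(a), p(b))
    angles: dict[str, float] = {}
    for pname, (a, b, c) in ANGLE_ATOMS.items():
        if pname in RIBOSE_ONLY_PARAMS and frag.sugar_type != "ribose":
            continue
        angles[pname] = measure_angle(p(a), p(b), p(c))

    return FragmentGeometry(
        torsions=TorsionSet(chi=chi, gamma=gamma, nu=nu),
        pucker=pucker,
        bonds=bonds,
        angles=angles,
    )
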