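"""Discrete conformational classification of sugar fragments.

The restraint dictionary is keyed by discrete labels derived from the
continuous conformational variables:

* ring pucker class from the pseudorotation phase P —
  C3'-endo for 0 <= P <= 36, C2'-endo for 144 <= P <= 190, Other elsewhere
  (the 190 upper bound is taken verbatim even though it exceeds the
  conventional 180 half-range);
* glycosidic rotamer from chi — syn for |chi| <= 90 (boundary inclusive),
  anti otherwise;
* side-chain rotamer from gamma — gauche+ (60 +/- 30), gauche- (-60 +/- 30),
  trans (180 +/- 30, the window spans the +/-180 wrap), otherwise "other".

The continuous variables (P, tau_m, chi, gamma) are carried along in the
context because several restraint targets are functions of tau_m or chi.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import FragmentGeometry, SugarFragment

__all__ = [
    "ConformationContext",
    "classify_pucker",
    "classify_chi",
    "classify_gamma",
    "C2P_ENDO",
    "C3P_ENDO",
    "OTHER_PUCKER",
]

C3P_ENDO = "C3'-endo"
C2P_ENDO = "C2'-endo"
OTHER_PUCKER = "Other"


def classify_pucker(P: float) -> str:
    """Pucker class from the pseudorotation phase P in [0, 360)."""
    if not 0.0 <= P < 360.0:
        raise ValueError(f"P = {P} outside [0, 360)")
    if 0.0 <= P <= 36.0:
        return C3P_ENDO
    if 144.0 <= P <= 190.0:
        return C2P_ENDO
    return OTHER_PUCKER


def classify_chi(chi: float) -> str:
    """syn iff |chi| <= 90 (inclusive), else anti; chi in (-180, 180]."""
    if not -180.0 < chi <= 180.0:
        raise ValueError(f"chi = {chi} outside (-180, 180]")
    return "syn" if abs(chi) <= 90.0 else "anti"


def _angular_distance(x: float, center: float) -> float:
    return abs((x - center + 180.0) % 360.0 - 180.0)


def classify_gamma(gamma: float) -> str:
    """gauche+ / gauche- / trans within +/-30 deg windows, else "other".

    The windows are disjoint; the trans window spans the 180/-180 wrap, so
    classification is invariant under gamma -> gamma - 360.
    """
    for label, center in (("gauche+", 60.0), ("gauche-", -60.0), ("trans", 180.0)):
        if _angular_distance(gamma, center) <= 30.0:
            return label
    return "other"


@dataclass(frozen=True)
class ConformationContext:
    """Discrete labels plus continuous variables keying the dictionary."""

    sugar_type: str  # "ribose" | "deoxyribose"
    base_type: str  # "purine" | "pyrimidine"
    pucker_class: str
    chi_rotamer: str
    gamma_rotamer: str
    terminal_o3: bool
    terminal_o5: bool
    P: float
    tau_m: float
    chi: float
    gamma: float

    def __post_init__(self) -> None:
        if self.pucker_class != classify_pucker(self.P % 360.0):
            raise ValueError("pucker_class inconsistent with P")
        if self.chi_rotamer != classify_chi(self.chi):
            raise ValueError("chi_rotamer inconsistent with chi")

    @classmethod
    def from_measurement(
        cls, frag: SugarFragment, geom: FragmentGeometry
    ) -> "ConformationContext":
        t = geom.torsions
        return cls(
            sugar_type=frag.sugar_type,
            base_type=frag.base_type,
            pucker_class=classify_pucker(geom.pucker.P),
            chi_rotamer=classify_chi(t.chi),
            gamma_rotamer=classify_gamma(t.gamma),
            terminal_o3=frag.terminal_o3,
            terminal_o5=frag.terminal_o5,
            P=geom.pucker.P,
            tau_m=geom.pucker.tau_m,
            chi=t.chi,
            gamma=t.gamma,
        )

    @classmethod
    def from_values(
        cls,
        sugar_type: str,
        base_type: str,
        P: float = 18.0,
        tau_m: float = 38.0,
        chi: float = -120.0,
        gamma: float = 60.0,
        terminal_o3: bool = False,
        terminal_o5: bool = False,
    ) -> "ConformationContext":
        """Convenience constructor classifying the continuous values."""
        return cls(
            sugar_type=sugar_type,
            base_type=base_type,
            pucker_class=classify_pucker(P % 360.0),
            chi_rotamer=classify_chi(chi),
            gamma_rotamer=classify_gamma(gamma),
            terminal_o3=terminal_o3,
            terminal_o5=terminal_o5,
            P=P % 360.0,
            tau_m=tau_m,
            chi=chi,
            gamma=gamma,
        )
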