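"""Conformation-dependent restraint dictionary: lookup and evaluation.

A dictionary row conditions a bond/angle target on a subset of the discrete
conformational keys (sugar type, base type, pucker class, chi rotamer,
gamma rotamer, terminal status).  Targets come in four forms:

* ``fixed`` — a plain mean with standard deviation;
* ``linear_tau`` — value = a * tau_m + b (endocyclic ring angles soften as
  the pucker amplitude grows, so all slopes are negative);
* ``periodic_chi`` — value = a * cos(2*chi + b) + c, the 180-degree-period
  cosine describing how the glycosidic C1'-N and the anomeric O4'-C1' bond
  lengths breathe with chi (extremes near chi = +/-90);
* ``grid_chi`` — a dense tabulated chi-curve with interpolation, used for
  the four glycosidic-link angles whose chi-dependence is periodic but not
  sinusoidal; the curves carry a local sigma.

Lookup is total for every valid context: a fragment whose gamma falls
outside the three named rotamer windows receives the N-weighted pooled
target over the gamma-split groups (with pooled standard deviation), and a
warning is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import ConformationContext
from .geometry import (
    ANGLE_ATOMS,
    BOND_ATOMS,
    RIBOSE_ONLY_PARAMS,
    FragmentGeometry,
    SugarFragment,
    measure_fragment,
    resolve_atom,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RestraintTarget",
    "RestraintDictionary",
    "GeneratedRestraint",
    "build_full_restraint_set",
    "applicable_parameters",
    "TAU_M_FIT_RANGE",
]

_KEYS = ("sugar", "base", "pucker", "chi", "gamma", "terminal")
#: tau_m range covered by the fitted linear relations; outside it the
#: evaluation still proceeds but is flagged as extrapolation.
TAU_M_FIT_RANGE = (20.0, 50.0)


@dataclass(frozen=True)
class RestraintTarget:
    """One bond/angle target with its functional form and sigma."""

    parameter: str
    kind: str  # "bond" | "angle"
    form: str  # "fixed" | "linear_tau" | "periodic_chi" | "grid_chi"
    conditioning: dict = field(hash=False, default_factory=dict)
    value: float | None = None
    a: float | None = None  # slope (linear) or amplitude (periodic)
    b: float | None = None  # intercept (linear) or phase, deg (periodic)
    c: float | None = None  # offset (periodic)
    sigma: float = 0.0
    n: int = 0
    provenance: str = "this-work"
    curve: tuple | None = None  # (chi_grid, mean, sigma) arrays for grid_chi

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"{self.parameter}: sigma must be positive")


@dataclass(frozen=True)
class GeneratedRestraint:
    """One evaluated restraint for one fragment, ready for a writer."""

    fragment: SugarFragment
    parameter: str
    kind: str
    atom_names: tuple[str, ...]
    ideal: float
    sigma: float


def _matches(row, ctx: ConformationContext, parameter: str) -> bool:
    checks = {
        "sugar": ctx.sugar_type,
        "base": ctx.base_type,
        "pucker": ctx.pucker_class,
        "chi": ctx.chi_rotamer,
        "gamma": ctx.gamma_rotamer,
        "terminal": _terminal_value(parameter, ctx),
    }
    return all(row[k] == "*" or row[k] == v for k, v in checks.items())


def _terminal_value(parameter: str, ctx: ConformationContext) -> str:
    if "O3'" in parameter:
        return "yes" if ctx.terminal_o3 else "no"
    if "O5'" in parameter:
        return "yes" if ctx.terminal_o5 else "no"
    return "no"


class RestraintDictionary:
    """Keyed lookup over a table of conformation-dependent targets."""

    def __init__(self, table: pd.DataFrame, provenance: str = "this-work",
                 curves: pd.DataFrame | None = None):
        table = table.copy()
        for k in _KEYS:
            table[k] = table[k].fillna("*").astype(str)
        self.table = table
        self.provenance = provenance
        # curves are keyed by an explicit curve_id when present (derived
        # dictionaries, arbitrary conditioning) or by (parameter, base)
        # (the packaged files, where only base conditions the grids)
        self._curves: dict = {}
        if curves is not None:
            key_cols = ["curve_id"] if "curve_id" in curves.columns else ["parameter", "base"]
            for key, grp in curves.groupby(key_cols):
                grp = grp.sort_values("chi")
                self._curves[key[0] if len(key) == 1 else tuple(key)] = (
                    grp["chi"].to_numpy(float),
                    grp["mean"].to_numpy(float),
                    grp["sigma"].to_numpy(float),
                )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_csv(cls, path, provenance: str = "this-work", curves_path=None):
        table = pd.read_csv(path, comment="#")
        curves = pd.read_csv(curves_path, comment="#") if curves_path else None
        return cls(table, provenance=provenance, curves=curves)

    @classmethod
    def load(cls, provenance: str = "this-work") -> "RestraintDictionary":
        """Load a packaged dictionary: ``"this-work"`` or ``"parkinson"``."""
        pkg = resources.files("sugarcdl") / "data"
        if provenance == "this-work":
            with resources.as_file(pkg / "sugar_targets_synthetic.csv") as p, \
                 resources.as_file(pkg / "chi_angle_curves_synthetic.csv") as cp:
                return cls.from_csv(p, provenance, curves_path=cp)
        if provenance == "parkinson":
            with resources.as_file(pkg / "parkinson_reference_synthetic.csv") as p:
                return cls.from_csv(p, provenance)
        raise ValueError(f"unknown dictionary provenance {provenance!r}")

    # -- lookup ------------------------------------------------------------

    @property
    def parameters(self) -> list[str]:
        return sorted(self.table["parameter"].unique())

    def _row_to_target(self, row, pooled_conditioning=None) -> RestraintTarget:
        form = row["form"]
        curve = None
        if form == "grid_chi":
            key = row["curve_id"] if "curve_id" in row.index else (
                row["parameter"], row["base"])
            if key not in self._curves:
                raise KeyError(
                    f"no tabulated chi-curve for {key}; dictionary loaded without curves")
            curve = self._curves[key]
        return RestraintTarget(
            parameter=row["parameter"],
            kind=row["kind"],
            form=form,
            conditioning=pooled_conditioning
            or {k: row[k] for k in _KEYS if row[k] != "*"},
            value=None if pd.isna(row["value"]) else float(row["value"]),
            a=None if pd.isna(row["a"]) else float(row["a"]),
            b=None if pd.isna(row["b"]) else float(row["b"]),
            c=None if pd.isna(row["c"]) else float(row["c"]),
            sigma=float(row["sigma"]),
            n=int(row["n"]),
            provenance=self.provenance,
            curve=curve,
        )

    def lookup(self, parameter: str, ctx: ConformationContext) -> RestraintTarget:
        """The unique target whose conditioning matches ``ctx``.

        For a gamma outside the named rotamer windows the gamma-split groups
        are pooled (N-weighted mean, pooled SD).  Unknown parameters raise a
        ``KeyError`` listing the supported names.
        """
        rows = self.table[self.table["parameter"] == parameter]
        if rows.empty:
            raise KeyError(
                f"unknown parameter {parameter!r}; supported: "
                + ", ".join(self.parameters))
        hits = rows[[_matches(r, ctx, parameter) for _, r in rows.iterrows()]]
        if len(hits) == 1:
            return self._row_to_target(hits.iloc[0])
        if len(hits) > 1:
            raise LookupError(
                f"ambiguous dictionary: {len(hits)} rows match {parameter} / {ctx}")
        # fallback: pool gamma-split groups for an unassigned gamma rotamer
        if ctx.gamma_rotamer == "other" and (rows["gamma"] != "*").any():
            pool = rows[[self._matches_except_gamma(r, ctx, parameter)
                         for _, r in rows.iterrows()]]
            if not pool.empty and (pool["form"] == "fixed").all():
                return self._pool(parameter, pool, ctx)
        raise LookupError(f"no dictionary entry for {parameter} in context {ctx}")

    def _matches_except_gamma(self, row, ctx, parameter) -> bool:
        checks = {
            "sugar": ctx.sugar_type,
            "base": ctx.base_type,
            "pucker": ctx.pucker_class,
            "chi": ctx.chi_rotamer,
            "terminal": _terminal_value(parameter, ctx),
        }
        return row["gamma"] != "*" and all(
            row[k] == "*" or row[k] == v for k, v in checks.items())

    def _pool(self, parameter: str, pool: pd.DataFrame,
              ctx: ConformationContext) -> RestraintTarget:
        n = pool["n"].to_numpy(float)
        mu = pool["value"].to_numpy(float)
        sd = pool["sigma"].to_numpy(float)
        w = n / n.sum()
        mean = float(np.sum(w * mu))
        # pooled variance = E[sigma^2 + mu^2] - mean^2 over the mixture
        var = float(np.sum(w * (sd**2 + mu**2)) - mean**2)
        logger.warning(
            "gamma rotamer 'other' for %s: pooled %d gamma groups", parameter, len(pool))
        return RestraintTarget(
            parameter=parameter,
            kind=pool.iloc[0]["kind"],
            form="fixed",
            conditioning={"gamma": "pooled"},
            value=mean,
            sigma=math.sqrt(max(var, 1e-12)),
            n=int(n.sum()),
            provenance=self.provenance,
        )

    # -- evaluation --------------------------------------------------------

    def evaluate(self, target: RestraintTarget,
                 ctx: ConformationContext) -> tuple[float, float]:
        """Evaluate a target at the context's own (tau_m, chi) -> (ideal, sigma)."""
        if target.form == "fixed":
            return float(target.value), target.sigma
        if target.form == "linear_tau":
            lo, hi = TAU_M_FIT_RANGE
            if not lo <= ctx.tau_m <= hi:
                logger.warning("tau_m = %.1f outside fitted range [%g, %g] for %s: "
                               "extrapolating", ctx.tau_m, lo, hi, target.parameter)
            return target.a * ctx.tau_m + target.b, target.sigma
        if target.form == "periodic_chi":
            val = target.a * math.cos(math.radians(2.0 * ctx.chi + target.b)) + target.c
            return val, target.sigma
        if target.form == "grid_chi":
            grid, mean, sig = target.curve
            chi = ((ctx.chi + 180.0) % 360.0) - 180.0
            return (float(np.interp(chi, grid, mean)),
                    float(np.interp(chi, grid, sig)))
        raise ValueError(f"unknown target form {target.form!r}")

    def lookup_evaluate(self, parameter: str,
                        ctx: ConformationContext) -> tuple[float, float]:
        return self.evaluate(self.lookup(parameter, ctx), ctx)


# --------------------------------------------------------------------------
# Full restraint set for fragments
# --------------------------------------------------------------------------

def applicable_parameters(ctx: ConformationContext) -> list[str]:
    """Dictionary parameters applicable to a fragment in this context.

    O2' parameters exist only for ribose; the C3'-O3' and C5'-O5' bond
    targets apply only to terminal hydroxyls (their phosphoester versions
    belong to the phosphodiester library, outside this dictionary).
    """
    params = list(BOND_ATOMS) + list(ANGLE_ATOMS)
    out = []
    for p in params:
        if p in RIBOSE_ONLY_PARAMS and ctx.sugar_type != "ribose":
            continue
        if p == "C3'-O3'" and not ctx.terminal_o3:
            continue
        if p == "C5'-O5'" and not ctx.terminal_o5:
            continue
        out.append(p)
    return out


def build_full_restraint_set(
    fragments: Iterable[SugarFragment],
    dictionary: RestraintDictionary | None = None,
) -> list[GeneratedRestraint]:
    """One evaluated restraint per applicable parameter per fragment.

    Fragments are measured and classified internally; parameters whose
    atoms are missing from a fragment are skipped with a log entry.
    """
    if dictionary is None:
        dictionary = RestraintDictionary.load("this-work")
    records: list[GeneratedRestraint] = []
    for frag in fragments:
        geom = measure_fragment(frag)
        ctx = ConformationContext.from_measurement(frag, geom)
        for param in applicable_parameters(ctx):
            atom_spec = BOND_ATOMS.get(param) or ANGLE_ATOMS[param]
            names = tuple(resolve_atom(nm, frag) for nm in atom_spec)
            if any(nm not in frag.atoms for nm in names):
                logger.warning("%s: missing atoms for %s, skipped", frag.label, param)
                continue
            try:
                ideal, sigma = dictionary.lookup_evaluate(param, ctx)
            except LookupError as exc:
                logger.warning("%s: %s", frag.label, exc)
                continue
            records.append(GeneratedRestraint(
                fragment=frag,
                parameter=param,
                kind="bond" if param in BOND_ATOMS else "angle",
                atom_names=names,
                ideal=ideal,
                sigma=sigma,
            ))
    return records
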