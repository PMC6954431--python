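"""Score coordinate models (or measured fragment tables) against a
restraint dictionary.

Every applicable target is evaluated at the fragment's *own* conformational
variables (P, tau_m, chi, gamma) — the functional forms are what they are
precisely so that the target follows the conformation — and compared with
the measured value.  RMSDs are reported separately over bonds (A) and
angles (degrees); the per-record absolute deviations are kept for
histogram-style comparisons of two dictionaries, and a Wilcoxon
signed-rank test decides whether one dictionary's deviations are
significantly smaller than the other's.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ConformationContext
from .derivation import META_COLUMNS
from .dictionary import (
    BOND_ATOMS,
    RestraintDictionary,
    applicable_parameters,
)
from .geometry import SugarFragment, extract_fragments, measure_fragment

logger = logging.getLogger(__name__)

__all__ = ["DeviationReport", "score_model", "score_fragments", "score_table",
           "compare_dictionaries"]


@dataclass
class DeviationReport:
    """Per-record deviations plus bond/angle RMSDs for one dictionary."""

    records: pd.DataFrame  # columns: fragment, parameter, kind, measured, ideal, abs_dev
    provenance: str = ""

    def _rmsd(self, kind: str) -> float:
        dev = self.records.loc[self.records["kind"] == kind, "abs_dev"]
        return float(np.sqrt(np.mean(dev**2))) if len(dev) else 0.0

    @property
    def rmsd_bonds(self) -> float:
        return self._rmsd("bond")

    @property
    def rmsd_angles(self) -> float:
        return self._rmsd("angle")

    @property
    def n_bonds(self) -> int:
        return int((self.records["kind"] == "bond").sum())

    @property
    def n_angles(self) -> int:
        return int((self.records["kind"] == "angle").sum())

    def to_json(self) -> str:
        return json.dumps({
            "provenance": self.provenance,
            "rmsd_bonds": self.rmsd_bonds,
            "rmsd_angles": self.rmsd_angles,
            "n_bonds": self.n_bonds,
            "n_angles": self.n_angles,
        }, indent=2)

    def deviations_table(self) -> pd.DataFrame:
        """|delta| table suitable for plotting deviation histograms."""
        return self.records[["fragment", "parameter", "kind", "abs_dev"]].copy()


def _score_one(ctx: ConformationContext, measured: dict, label: str,
               dictionary: RestraintDictionary, rows: list) -> None:
    for param in applicable_parameters(ctx):
        if param not in measured or measured[param] is None or (
                isinstance(measured[param], float) and math.isnan(measured[param])):
            continue
        try:
            ideal, _sigma = dictionary.lookup_evaluate(param, ctx)
        except LookupError as exc:
            logger.warning("%s: %s", label, exc)
            continue
        rows.append({
            "fragment": label,
            "parameter": param,
            "kind": "bond" if param in BOND_ATOMS else "angle",
            "measured": float(measured[param]),
            "ideal": float(ideal),
            "abs_dev": abs(float(measured[param]) - float(ideal)),
        })


def score_fragments(fragments, dictionary: RestraintDictionary,
                    well_ordered_only: bool = True) -> DeviationReport:
    """Score extracted fragments; the well-ordered filter keeps only
    full-occupancy, single-conformer sugars."""
    rows: list[dict] = []
    frags = list(fragments)
    if well_ordered_only:
        multi = {(f.chain, f.resnum, f.icode) for f in frags if f.altloc}
        frags = [
            f for f in frags
            if (f.chain, f.resnum, f.icode) not in multi
            and all(a.occupancy >= 0.999 for a in f.atoms.values())
        ]
    for frag in frags:
        geom = measure_fragment(frag)
        ctx = ConformationContext.from_measurement(frag, geom)
        measured = {**geom.bonds, **geom.angles}
        _score_one(ctx, measured, frag.label, dictionary, rows)
    return DeviationReport(records=pd.DataFrame(
        rows, columns=["fragment", "parameter", "kind", "measured", "ideal", "abs_dev"]),
        provenance=dictionary.provenance)


def score_model(structure, dictionary: RestraintDictionary,
                well_ordered_only: bool = True) -> DeviationReport:
    """Score a PDB/mmCIF model (path or gemmi Structure)."""
    return score_fragments(extract_fragments(structure), dictionary,
                           well_ordered_only=well_ordered_only)


def score_table(table: pd.DataFrame,
                dictionary: RestraintDictionary) -> DeviationReport:
    """Score a measured fragment table (one row per sugar) — the same
    comparison as scoring a model, but starting from tabulated geometry."""
    rows: list[dict] = []
    for _, row in table.iterrows():
        ctx = ConformationContext.from_values(
            row["sugar_type"], row["base_type"], P=row["P"], tau_m=row["tau_m"],
            chi=row["chi"], gamma=row["gamma"],
            terminal_o3=bool(row.get("terminal_o3", False)),
            terminal_o5=bool(row.get("terminal_o5", False)))
        measured = {k: row[k] for k in row.index if k not in META_COLUMNS}
        _score_one(ctx, measured, str(row.get("structure_id", "?")), dictionary, rows)
    return DeviationReport(records=pd.DataFrame(
        rows, columns=["fragment", "parameter", "kind", "measured", "ideal", "abs_dev"]),
        provenance=dictionary.provenance)


def compare_dictionaries(report_a: DeviationReport,
                         report_b: DeviationReport) -> dict:
    """Wilcoxon signed-rank test on paired |delta| values, bonds and angles
    separately.

    The reports must cover identical (fragment, parameter) sets.  All-zero
    differences are the degenerate no-difference case and are reported with
    p = 1.  The one-sided direction field says which report has the smaller
    deviations when the two-sided test is significant.
    """
    out = {}
    a = report_a.records.set_index(["fragment", "parameter"])
    b = report_b.records.set_index(["fragment", "parameter"])
    if set(a.index) != set(b.index):
        raise ValueError("reports cover different (fragment, parameter) sets")
    b = b.loc[a.index]
    for kind in ("bond", "angle"):
        sel = a["kind"] == kind
        d = (a.loc[sel, "abs_dev"] - b.loc[sel.to_numpy(), "abs_dev"]).to_numpy()
        if len(d) == 0 or np.allclose(d, 0.0):
            out[kind] = {"p_value": 1.0, "statistic": 0.0, "n": int(len(d)),
                         "better": None}
            continue
        res = stats.wilcoxon(d)
        out[kind] = {
            "p_value": float(res.pvalue),
            "statistic": float(res.statistic),
            "n": int(len(d)),
            "better": (report_a.provenance if np.median(d) < 0
                       else report_b.provenance),
        }
    return out
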