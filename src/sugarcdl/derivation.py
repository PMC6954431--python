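"""Statistical derivation of a restraint dictionary from a fragment table.

The pipeline mirrors how conformation-dependent covalent-geometry libraries
are compiled from curated small-molecule data:

1.  quality filtering — keep structures with R <= 8.5% and average C-C bond
    e.s.d. sigma(C-C) < 0.01 A (disordered structures are retained: dropping
    them shrinks samples and inflates the standard error of the mean);
2.  robust outlier rejection with the modified Z-score
    M_i = 0.6745 (x_i - median) / MAD, |M_i| > 3.5, applied per parameter
    within each sugar-base class; a flagged parameter removes the whole
    structure;
3.  subgroup discovery — pairwise two-sided Welch t-tests (alpha = 0.05,
    no equal-variance assumption) over the candidate factors (sugar type,
    base type, pucker class, chi rotamer, gamma rotamer); when more than
    one factor is significant, factor pairs are adopted only if the
    majority of sibling subgroup comparisons stay significant, otherwise
    the factor with the smallest p-value wins;
4.  functional screening — Spearman rank correlation (|rho| > 0.5,
    p < 0.05) of each group's values against tau_m (linear candidates) or
    against |chi| within chi-rotamer subgroups (periodic candidates, the
    fold removing the non-monotonicity of 180-degree-periodic curves);
    a family adopts a functional form when the majority of its groups pass;
5.  fitting — Bayesian ridge regression for tau_m-linear relations and
    Gaussian-process regression with an exp-sine-squared kernel (180- and
    360-degree period candidates, white-noise level free over 1e-7..1e7)
    for chi-periodic relations, selected by log marginal likelihood; data
    are mean-normalised before fitting and de-normalised on output.

Welch p-values are deliberately not corrected for multiple testing; the
report records how many tests were performed.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    ConstantKernel,
    ExpSineSquared,
    WhiteKernel,
)
from sklearn.linear_model import BayesianRidge

from .classify import classify_chi, classify_gamma, classify_pucker
from .dictionary import BOND_ATOMS, RestraintDictionary

logger = logging.getLogger(__name__)

__all__ = [
    "DerivationConfig",
    "CorrelationResult",
    "FittedFunctional",
    "DictionaryBuilder",
    "quality_filter",
    "modified_zscore",
    "modified_zscore_outliers",
    "remove_outlier_structures",
    "welch_test",
    "welch_split",
    "spearman_screen",
    "fit_functional",
    "build_dictionary",
    "sampling_diagnostics",
    "META_COLUMNS",
]

META_COLUMNS = (
    "structure_id", "R_factor", "sigma_CC", "disordered", "sugar_type",
    "base_type", "P", "tau_m", "chi", "gamma", "terminal_o3", "terminal_o5",
)

#: candidate discrete grouping factors -> dictionary key names
_FACTOR_KEY = {
    "sugar_type": "sugar",
    "base_type": "base",
    "_pucker": "pucker",
    "_chi_rot": "chi",
    "_gamma_rot": "gamma",
}


@dataclass
class DerivationConfig:
    """Thresholds of the derivation pipeline (all positive)."""

    alpha_t: float = 0.05        # Welch significance level
    alpha_s: float = 0.05        # Spearman significance level
    rho_min: float = 0.5         # minimum |rho| for a functional relation
    r_max: float = 8.5           # R-factor cutoff, %
    sigma_cc_max: float = 0.01   # sigma(C-C) cutoff, A (strict <)
    z_threshold: float = 3.5     # modified Z-score cutoff
    min_group: int = 5           # groups below this merge into a sibling
    min_corr_n: int = 10         # minimum n for a correlation screen
    noise_bounds: tuple = (1e-7, 1e7)
    periods: tuple = (180.0, 360.0)
    grid_step: float = 5.0       # chi grid spacing for tabulated curves
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_t", "alpha_s", "rho_min", "r_max", "sigma_cc_max",
                     "z_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    passed: bool
    n: int


@dataclass
class FittedFunctional:
    """Result of fit_functional: linear coefficients or a periodic curve."""

    kind: str                   # "linear" | "periodic"
    sigma: float
    n: int
    slope: float | None = None
    intercept: float | None = None
    period: float | None = None
    grid: np.ndarray | None = None
    mean: np.ndarray | None = None
    sigma_curve: np.ndarray | None = None
    log_marginal_likelihood: float | None = None
    fallback: bool = False

    @property
    def amplitude(self) -> float | None:
        """Half the peak-to-peak swing of a periodic curve."""
        if self.mean is None:
            return None
        return float(self.mean.max() - self.mean.min()) / 2.0


# --------------------------------------------------------------------------
# Filtering and outlier rejection
# --------------------------------------------------------------------------

def quality_filter(table: pd.DataFrame,
                   config: DerivationConfig | None = None) -> pd.DataFrame:
    """Keep rows with R <= r_max (inclusive) and sigma(C-C) < sigma_cc_max
    (strict); disordered structures are retained."""
    config = config or DerivationConfig()
    for col in ("R_factor", "sigma_CC"):
        if col not in table.columns:
            raise KeyError(f"missing quality column {col!r}")
    mask = (table["R_factor"] <= config.r_max) & (table["sigma_CC"] < config.sigma_cc_max)
    return table[mask].copy()


def modified_zscore(sample) -> np.ndarray:
    """M_i = 0.6745 (x_i - median) / median|x_j - median|.

    With a zero MAD the score is defined by its limit: exactly-median
    points score 0, any deviating point scores +/-inf.
    """
    x = np.asarray(sample, dtype=float)
    med = np.median(x)
    dev = x - med
    mad = np.median(np.abs(dev))
    if mad == 0.0:
        out = np.zeros_like(dev)
        nz = dev != 0.0
        out[nz] = np.sign(dev[nz]) * np.inf
        if nz.any():
            logger.warning("degenerate MAD = 0 with %d deviating point(s)", nz.sum())
        return out
    return 0.6745 * dev / mad


def modified_zscore_outliers(sample, z_threshold: float = 3.5) -> np.ndarray:
    """Boolean outlier flags, |M_i| > z_threshold.  Needs n >= 3."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations for the outlier test")
    return np.abs(modified_zscore(x)) > z_threshold


def remove_outlier_structures(table: pd.DataFrame,
                              config: DerivationConfig | None = None
                              ) -> tuple[pd.DataFrame, int]:
    """Structure-level rejection: a structure leaves the table when any of
    its parameters is an outlier within its sugar-base class."""
    config = config or DerivationConfig()
    param_cols = [c for c in table.columns if c not in META_COLUMNS]
    bad = pd.Series(False, index=table.index)
    for _, cls in table.groupby(["sugar_type", "base_type"]):
        for col in param_cols:
            vals = cls[col].dropna()
            if len(vals) < 3:
                continue
            flags = modified_zscore_outliers(vals.to_numpy(), config.z_threshold)
            bad.loc[vals.index[flags]] = True
    n_removed = int(bad.sum())
    if n_removed:
        logger.info("outlier rejection removed %d structure(s)", n_removed)
    return table[~bad].copy(), n_removed


# --------------------------------------------------------------------------
# Statistical tests
# --------------------------------------------------------------------------

def welch_test(a, b) -> tuple[float, float]:
    """Two-sided Welch t-test; degenerate zero-variance pairs fall back to
    the limit (p = 1 for identical constants, p = 0 otherwise)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        p = 1.0 if np.mean(a) == np.mean(b) else 0.0
        logger.warning("zero-variance Welch pair: p from degenerate limit")
        return 0.0 if p == 1.0 else math.inf, p
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def welch_split(groups: dict, alpha: float = 0.05) -> dict:
    """Pairwise Welch tests over labelled samples.

    Returns ``{"pairs": {(l1, l2): (t, p)}, "significant": bool,
    "min_p": float, "n_tests": int}`` where ``significant`` requires a
    strict majority of pairwise comparisons below ``alpha``.
    """
    labels = sorted(groups)
    pairs = {}
    for l1, l2 in itertools.combinations(labels, 2):
        pairs[(l1, l2)] = welch_test(groups[l1], groups[l2])
    pvals = [p for _, p in pairs.values()]
    n_sig = sum(p < alpha for p in pvals)
    return {
        "pairs": pairs,
        "significant": bool(pvals) and n_sig > len(pvals) / 2,
        "min_p": min(pvals) if pvals else 1.0,
        "n_tests": len(pvals),
    }


def spearman_screen(x, y, config: DerivationConfig | None = None) -> CorrelationResult:
    """Spearman screen: pass iff |rho| > rho_min and p < alpha_s.

    Ties are handled by average ranks (scipy's default).
    """
    config = config or DerivationConfig()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < config.min_corr_n:
        raise ValueError(f"need n >= {config.min_corr_n} for the Spearman screen")
    rho, p = stats.spearmanr(x, y)
    passed = bool(abs(rho) > config.rho_min and p < config.alpha_s)
    return CorrelationResult(rho=float(rho), p_value=float(p), passed=passed,
                             n=int(x.size))


# --------------------------------------------------------------------------
# Functional fitting
# --------------------------------------------------------------------------

def fit_functional(x, y, kind: str,
                   config: DerivationConfig | None = None) -> FittedFunctional:
    """Fit a tau_m-linear or chi-periodic relation.

    Inputs are mean-normalised internally and de-normalised on output.
    Periodic fits try exp-sine-squared kernels with both candidate periods
    and keep the higher log marginal likelihood; a non-convergent
    hyperparameter search falls back to the widest-noise kernel, flagged.
    """
    config = config or DerivationConfig()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ybar = y.mean()
    yc = y - ybar

    if kind == "linear":
        xbar = x.mean()
        model = BayesianRidge()
        model.fit((x - xbar).reshape(-1, 1), yc)
        slope = float(model.coef_[0])
        intercept = float(ybar + model.intercept_ - slope * xbar)
        sigma = float(1.0 / math.sqrt(model.alpha_))
        return FittedFunctional(kind="linear", slope=slope, intercept=intercept,
                                sigma=sigma, n=int(x.size))

    if kind != "periodic":
        raise ValueError(f"unknown functional kind {kind!r}")

    chi = ((x + 180.0) % 360.0) - 180.0
    grid = np.arange(-180.0, 180.0 + config.grid_step, config.grid_step)
    best = None
    for period in config.periods:
        kernel = (
            ConstantKernel(np.var(yc) + 1e-6, (1e-6, 1e6))
            * ExpSineSquared(length_scale=60.0, length_scale_bounds=(5.0, 1e4),
                             periodicity=period, periodicity_bounds="fixed")
            + WhiteKernel(noise_level=max(np.var(yc), 1e-6),
                          noise_level_bounds=config.noise_bounds)
        )
        gpr = GaussianProcessRegressor(kernel=kernel, normalize_y=False,
                                       n_restarts_optimizer=1,
                                       random_state=config.seed)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gpr.fit(chi.reshape(-1, 1), yc)
            lml = float(gpr.log_marginal_likelihood_value_)
        except Exception:
            logger.warning("GPR failed for period %g: widest-noise fallback", period)
            continue
        if best is None or lml > best[0]:
            best = (lml, period, gpr)

    if best is None:
        # non-convergent search: flat curve at the sample mean, sample SD
        sd = float(y.std(ddof=1)) if y.size > 1 else 1.0
        return FittedFunctional(kind="periodic", sigma=sd, n=int(x.size),
                                period=None, grid=grid,
                                mean=np.full_like(grid, ybar),
                                sigma_curve=np.full_like(grid, sd),
                                fallback=True)

    lml, period, gpr = best
    mean_c, std = gpr.predict(grid.reshape(-1, 1), return_std=True)
    # the predictive std at new points already contains the white-noise
    # level (the kernel's diagonal), i.e. it is the full observation sigma
    sigma_curve = std
    return FittedFunctional(
        kind="periodic",
        sigma=float(np.mean(sigma_curve)),
        n=int(x.size),
        period=float(period),
        grid=grid,
        mean=mean_c + ybar,
        sigma_curve=sigma_curve,
        log_marginal_likelihood=lml,
    )


# --------------------------------------------------------------------------
# Dictionary builder
# --------------------------------------------------------------------------

class DictionaryBuilder:
    """Derive a conformation-dependent dictionary from a fragment table.

    Fit-style estimator: ``fit(table)`` populates ``targets_`` (rows in the
    packaged dictionary schema), ``curves_`` (tabulated chi grids) and
    ``report_`` (groupings, p-values, rho values, chosen models, sample
    sizes, number of Welch tests run).
    """

    def __init__(self, config: DerivationConfig | None = None):
        self.config = config or DerivationConfig()

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _label(table: pd.DataFrame) -> pd.DataFrame:
        t = table.copy()
        t["_pucker"] = [classify_pucker(p % 360.0) for p in t["P"]]
        t["_chi_rot"] = [classify_chi(c) for c in t["chi"]]
        t["_gamma_rot"] = [classify_gamma(g) for g in t["gamma"]]
        return t

    def _factor_verdict(self, sub: pd.DataFrame, col: str, factor: str) -> dict:
        cfg = self.config
        groups = {
            lvl: g[col].to_numpy()
            for lvl, g in sub.groupby(factor)
            if len(g) >= max(cfg.min_group, 2) and lvl != "other"
        }
        if len(groups) < 2:
            return {"significant": False, "min_p": 1.0, "n_tests": 0}
        return welch_split(groups, cfg.alpha_t)

    def _combination_ok(self, sub: pd.DataFrame, col: str, f1: str, f2: str) -> bool:
        """Majority of sibling-cell Welch comparisons significant."""
        cfg = self.config
        cells = {
            key: g[col].to_numpy()
            for key, g in sub.groupby([f1, f2])
            if len(g) >= max(cfg.min_group, 2) and "other" not in key
        }
        pvals = []
        for k1, k2 in itertools.combinations(sorted(cells), 2):
            if sum(a != b for a, b in zip(k1, k2)) == 1:  # siblings
                pvals.append(welch_test(cells[k1], cells[k2])[1])
        self._n_tests += len(pvals)
        return bool(pvals) and sum(p < cfg.alpha_t for p in pvals) > len(pvals) / 2

    def _select_grouping(self, sub: pd.DataFrame, col: str) -> tuple[list, dict]:
        verdicts = {}
        for factor in _FACTOR_KEY:
            v = self._factor_verdict(sub, col, factor)
            self._n_tests += v["n_tests"]
            verdicts[factor] = v
        sig = [f for f, v in verdicts.items() if v["significant"]]
        sig.sort(key=lambda f: verdicts[f]["min_p"])
        if not sig:
            return [], verdicts
        if len(sig) == 1:
            return sig, verdicts
        f1, f2 = sig[0], sig[1]
        if self._combination_ok(sub, col, f1, f2):
            return [f1, f2], verdicts
        return [f1], verdicts

    def _chi_screen(self, group: pd.DataFrame, col: str) -> tuple[bool, list]:
        """Periodic candidate: Spearman of chi vs value within each
        chi-sign x rotamer quadrant.  Each quadrant is a monotone stretch
        of a curve with extremes near 0/+-90/180, which is exactly the
        regime rank correlation can detect; a majority of the testable
        quadrants must pass."""
        cfg = self.config
        results = []
        for _, g in group.groupby(["_chi_rot", np.sign(group["chi"])]):
            if len(g) < cfg.min_corr_n:
                continue
            results.append(spearman_screen(g["chi"], g[col], cfg))
        if not results:
            return False, results
        n_pass = sum(r.n for r in results if r.passed)
        n_all = sum(r.n for r in results)
        # majority weighted by sample size: the quadrants holding most of
        # the observations carry the decision
        return n_pass > n_all / 2, results

    def _tau_screen(self, group: pd.DataFrame, col: str):
        cfg = self.config
        if len(group) < cfg.min_corr_n:
            return False, None
        r = spearman_screen(group["tau_m"], group[col], cfg)
        return r.passed, r

    # -- main fit ----------------------------------------------------------

    def fit(self, table: pd.DataFrame) -> "DictionaryBuilder":
        cfg = self.config
        t = quality_filter(table, cfg)
        t, n_outliers = remove_outlier_structures(t, cfg)
        t = self._label(t)
        param_cols = [c for c in table.columns if c not in META_COLUMNS]

        rows: list[dict] = []
        curve_rows: list[dict] = []
        report: dict = {"n_rows_in": len(table), "n_rows_used": len(t),
                        "n_outlier_structures": n_outliers, "parameters": {}}
        self._n_tests = 0

        for col in param_cols:
            sub = t[t[col].notna()]
            grouping, verdicts = self._select_grouping(sub, col)
            preport = {
                "grouping": [_FACTOR_KEY[f] for f in grouping],
                "welch": {
                    _FACTOR_KEY[f]: {"significant": v["significant"],
                                     "min_p": v["min_p"]}
                    for f, v in verdicts.items()
                },
                "groups": [],
                "merged": [],
            }

            groups = ([(tuple(), sub)] if not grouping else
                      [(k if isinstance(k, tuple) else (k,), g)
                       for k, g in sub.groupby(grouping)])
            # merge undersized cells into the largest sibling
            groups.sort(key=lambda kg: len(kg[1]), reverse=True)
            kept: list = []
            for key, g in groups:
                if len(g) < cfg.min_group and kept:
                    kept[0] = (kept[0][0], pd.concat([kept[0][1], g]))
                    preport["merged"].append(key)
                    logger.warning("%s: group %s (n=%d) merged", col, key, len(g))
                else:
                    kept.append((key, g))

            # family-level functional decision: majority of groups,
            # weighted by group size
            chi_pass, tau_pass = [], []
            for _, g in kept:
                cp, _ = self._chi_screen(g, col)
                tp, _ = self._tau_screen(g, col)
                chi_pass.append(cp)
                tau_pass.append(tp)
            sizes = np.array([len(g) for _, g in kept], dtype=float)
            family_chi = sizes[chi_pass].sum() > sizes.sum() / 2
            family_tau = (not family_chi) and sizes[tau_pass].sum() > sizes.sum() / 2

            for (key, g), cp, tp in zip(kept, chi_pass, tau_pass):
                cond = {k: "*" for k in ("sugar", "base", "pucker", "chi", "gamma")}
                for f, lvl in zip(grouping, key):
                    cond[_FACTOR_KEY[f]] = lvl
                base_row = {
                    "parameter": col,
                    "kind": "bond" if col in BOND_ATOMS else "angle",
                    **cond,
                    "terminal": "*",
                    "value": np.nan, "a": np.nan, "b": np.nan, "c": np.nan,
                    "n": len(g),
                }
                ginfo = {"key": key, "n": len(g)}
                if family_chi and cp:
                    fit = fit_functional(g["chi"], g[col], "periodic", cfg)
                    curve_id = col + "".join(
                        f"|{k}={v}" for k, v in cond.items() if v != "*")
                    base_row.update(form="grid_chi", sigma=fit.sigma,
                                    curve_id=curve_id)
                    ginfo.update(form="grid_chi", period=fit.period,
                                 amplitude=fit.amplitude)
                    for chi_v, m_v, s_v in zip(fit.grid, fit.mean, fit.sigma_curve):
                        curve_rows.append({"curve_id": curve_id, "parameter": col,
                                           "chi": chi_v, "mean": m_v, "sigma": s_v})
                elif family_tau and tp:
                    fit = fit_functional(g["tau_m"], g[col], "linear", cfg)
                    base_row.update(form="linear_tau", a=fit.slope, b=fit.intercept,
                                    sigma=fit.sigma)
                    ginfo.update(form="linear_tau", slope=fit.slope,
                                 intercept=fit.intercept)
                else:
                    base_row.update(form="fixed", value=g[col].mean(),
                                    sigma=max(g[col].std(ddof=1), 1e-6))
                    ginfo.update(form="fixed", mean=g[col].mean())
                rows.append(base_row)
                preport["groups"].append(ginfo)
            report["parameters"][col] = preport

        report["n_welch_tests"] = self._n_tests
        self.targets_ = pd.DataFrame(rows)
        self.curves_ = pd.DataFrame(curve_rows) if curve_rows else None
        self.report_ = report
        return self

    def to_dictionary(self, provenance: str = "derived") -> RestraintDictionary:
        if not hasattr(self, "targets_"):
            raise RuntimeError("builder not fitted")
        return RestraintDictionary(self.targets_, provenance=provenance,
                                   curves=self.curves_)

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **params) -> "DictionaryBuilder":
        for k, v in params.items():
            setattr(self, k, v)
        return self


def build_dictionary(table: pd.DataFrame,
                     config: DerivationConfig | None = None) -> RestraintDictionary:
    """One-call derivation: filtered table -> RestraintDictionary."""
    return DictionaryBuilder(config).fit(table).to_dictionary()


# --------------------------------------------------------------------------
# Sampling diagnostics (report only)
# --------------------------------------------------------------------------

def sampling_diagnostics(table: pd.DataFrame, r_grid=None) -> pd.DataFrame:
    """Average SEM and STD of all parameters versus the R-factor cutoff.

    Diagnostic only — it drives no decision; it documents the SEM/STD
    trade-off that motivates the quality thresholds.
    """
    if r_grid is None:
        r_grid = np.arange(4.5, 10.01, 0.5)
    param_cols = [c for c in table.columns if c not in META_COLUMNS]
    out = []
    for r in r_grid:
        sel = table[table["R_factor"] <= r]
        sems, stds = [], []
        for col in param_cols:
            v = sel[col].dropna()
            if len(v) >= 2:
                stds.append(v.std(ddof=1))
                sems.append(v.std(ddof=1) / math.sqrt(len(v)))
        out.append({"r_max": r, "n": len(sel),
                    "mean_sem": float(np.mean(sems)) if sems else np.nan,
                    "mean_std": float(np.mean(stds)) if stds else np.nan})
    return pd.DataFrame(out)
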