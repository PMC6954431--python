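"""Derivation statistics: filters, outliers, tests, fits, generator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sugarcdl.derivation import (
    DerivationConfig,
    DictionaryBuilder,
    fit_functional,
    modified_zscore,
    modified_zscore_outliers,
    quality_filter,
    remove_outlier_structures,
    spearman_screen,
    welch_split,
    welch_test,
)
from sugarcdl.synthetic import DEFAULT_CLASS_SIZES, generate_synthetic_table


def _table(**cols):
    base = {"structure_id": ["s"], "R_factor": [5.0], "sigma_CC": [0.005],
            "disordered": [False], "sugar_type": ["ribose"],
            "base_type": ["purine"], "P": [18.0], "tau_m": [38.0],
            "chi": [-120.0], "gamma": [60.0], "terminal_o3": [False],
            "terminal_o5": [False]}
    n = max(len(v) for v in cols.values()) if cols else 1
    out = {k: v * n if len(v) == 1 else v for k, v in base.items()}
    out.update(cols)
    out["structure_id"] = [f"s{i}" for i in range(n)]
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# quality filter
# ---------------------------------------------------------------------------

def test_r_factor_cutoff_inclusive():
    t = _table(R_factor=[8.0, 8.5, 9.0])
    kept = quality_filter(t)
    assert list(kept["R_factor"]) == [8.0, 8.5]


def test_sigma_cc_cutoff_strict():
    t = _table(sigma_CC=[0.009, 0.01, 0.011])
    kept = quality_filter(t)
    assert list(kept["sigma_CC"]) == [0.009]


def test_disordered_structures_are_retained():
    t = _table(disordered=[True, False])
    assert len(quality_filter(t)) == 2


def test_empty_table_passes_through():
    t = _table().iloc[:0]
    assert len(quality_filter(t)) == 0


def test_missing_quality_column_raises():
    with pytest.raises(KeyError):
        quality_filter(_table().drop(columns=["R_factor"]))


@given(r1=st.floats(5.0, 9.0), r2=st.floats(5.0, 9.0))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_tightening_r_cutoff_never_keeps_more_rows(r1, r2):
    t = _table(R_factor=list(np.linspace(4.5, 10.0, 23)))
    lo, hi = sorted((r1, r2))
    kept_lo = quality_filter(t, DerivationConfig(r_max=lo))
    kept_hi = quality_filter(t, DerivationConfig(r_max=hi))
    assert len(kept_lo) <= len(kept_hi)


# ---------------------------------------------------------------------------
# modified Z-score
# ---------------------------------------------------------------------------

def test_hand_example_flags_exactly_the_gross_point():
    sample = [1.0, 2.0, 3.0, 4.0, 100.0]
    m = modified_zscore(sample)
    # median 3, MAD 1: M for 100 is 0.6745 * 97 = 65.4265
    assert m[-1] == pytest.approx(0.6745 * 97, abs=1e-12)
    flags = modified_zscore_outliers(sample)
    assert flags.tolist() == [False, False, False, False, True]


def test_constant_sample_has_no_outliers():
    assert not modified_zscore_outliers([5.0] * 4).any()


def test_flags_invariant_under_sign_flip():
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(0, 1, 40), [9.0, -7.5]])
    assert (modified_zscore_outliers(x) == modified_zscore_outliers(-x)).all()


def test_degenerate_mad_flags_deviators():
    flags = modified_zscore_outliers([2.0, 2.0, 2.0, 2.0, 7.0])
    assert flags.tolist() == [False, False, False, False, True]


def test_structure_level_removal():
    t = _table(**{"C1'-C2'": [1.52, 1.53, 1.52, 1.53, 1.52, 2.0]})
    kept, n = remove_outlier_structures(t)
    assert n == 1 and len(kept) == 5


# ---------------------------------------------------------------------------
# Welch
# ---------------------------------------------------------------------------

def test_identical_samples_do_not_split():
    a = np.arange(10.0)
    res = welch_split({"x": a, "y": a.copy()})
    assert res["pairs"][("x", "y")][1] == pytest.approx(1.0)
    assert not res["significant"]


def test_shifted_normals_split_and_match_independent_oracle():
    from statsmodels.stats.weightstats import ttest_ind as sm_ttest

    rng = np.random.default_rng(7)
    a = rng.normal(0.0, 1.0, 200)
    b = rng.normal(0.5, 1.0, 200)
    t, p = welch_test(a, b)
    t_o, p_o, _ = sm_ttest(a, b, usevar="unequal")
    assert p == pytest.approx(p_o, rel=1e-9)
    assert t == pytest.approx(t_o, rel=1e-9)
    assert welch_split({"a": a, "b": b})["significant"]


def test_zero_variance_pair_degenerate_limits():
    assert welch_test([1.0, 1.0], [1.0, 1.0])[1] == 1.0
    assert welch_test([1.0, 1.0], [2.0, 2.0])[1] == 0.0


# ---------------------------------------------------------------------------
# Spearman screen
# ---------------------------------------------------------------------------

def test_monotone_relation_gives_rho_one():
    x = np.linspace(0, 1, 30)
    r = spearman_screen(x, x**3 + 2)
    assert r.rho == pytest.approx(1.0) and r.passed


def test_independent_noise_fails_screen():
    rng = np.random.default_rng(11)
    r = spearman_screen(rng.normal(size=200), rng.normal(size=200))
    assert not r.passed and abs(r.rho) < 0.5


def test_weak_negative_linear_relation_passes():
    rng = np.random.default_rng(5)
    x = np.linspace(25, 45, 200)
    y = -0.2 * x + rng.normal(0, 0.3, 200)
    r = spearman_screen(x, y)
    assert r.passed and r.rho < -0.9


# ---------------------------------------------------------------------------
# functional fits
# ---------------------------------------------------------------------------

def test_linear_fit_recovers_slope():
    rng = np.random.default_rng(3)
    x = rng.uniform(25, 45, 300)
    y = -0.15 * x + 112.0 + rng.normal(0, 0.3, 300)
    fit = fit_functional(x, y, "linear")
    assert fit.slope == pytest.approx(-0.15, abs=0.02)
    assert fit.intercept == pytest.approx(112.0, abs=0.8)
    assert fit.sigma == pytest.approx(0.3, rel=0.2)


def test_periodic_fit_recovers_cosine_and_selects_180_period():
    rng = np.random.default_rng(9)
    chi = rng.uniform(-180, 180, 300)
    y = 0.012 * np.cos(np.radians(2 * chi)) + 1.46 + rng.normal(0, 0.004, 300)
    fit = fit_functional(chi, y, "periodic")
    assert fit.period == 180.0
    swing = fit.mean.max() - fit.mean.min()
    assert swing == pytest.approx(0.024, rel=0.2)


def test_constant_data_gives_near_flat_curve():
    rng = np.random.default_rng(13)
    chi = rng.uniform(-180, 180, 200)
    y = 5.0 + rng.normal(0, 0.5, 200)
    fit = fit_functional(chi, y, "periodic")
    assert fit.mean.max() - fit.mean.min() < 0.5
    assert fit.sigma == pytest.approx(0.5, rel=0.3)


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------

def test_generator_reproduces_study_class_sizes():
    t = generate_synthetic_table(seed=0)
    counts = t.groupby(["sugar_type", "base_type"]).size()
    for (sugar, base), n in DEFAULT_CLASS_SIZES.items():
        assert counts[(sugar, base)] == n


def test_generator_is_deterministic_per_seed():
    a = generate_synthetic_table(seed=4)
    b = generate_synthetic_table(seed=4)
    pd.testing.assert_frame_equal(a, b)
    c = generate_synthetic_table(seed=5)
    assert not a.equals(c)


def test_zero_outlier_fraction_flags_almost_no_values():
    from sugarcdl.derivation import META_COLUMNS

    t = generate_synthetic_table(seed=2, outlier_fraction=0.0,
                                 poor_quality_fraction=0.0)
    params = [c for c in t.columns if c not in META_COLUMNS]
    n_flags = n_values = 0
    for _, cls in t.groupby(["sugar_type", "base_type"]):
        for col in params:
            v = cls[col].dropna().to_numpy()
            if len(v) >= 3:
                n_flags += modified_zscore_outliers(v).sum()
                n_values += len(v)
    # false-positive rate of the 3.5 cutoff on clean data is ~0
    assert n_flags / n_values < 0.005
    kept, n_removed = remove_outlier_structures(t)
    assert n_removed < 0.05 * len(t)


def test_planted_outliers_shift_class_means_by_less_than_half_sem():
    """Robustness: modified-Z rejection of 5% gross outliers recovers the
    class means an oracle (that knows which rows were contaminated) would
    compute, to well under half a SEM."""
    clean = generate_synthetic_table(seed=6, outlier_fraction=0.0,
                                     poor_quality_fraction=0.0)
    dirty = generate_synthetic_table(seed=6, outlier_fraction=0.05,
                                     poor_quality_fraction=0.0)
    from sugarcdl.derivation import META_COLUMNS
    params = [c for c in clean.columns if c not in META_COLUMNS]
    # planted rows are exactly those where the seeded tables differ
    planted = (clean[params].fillna(0) - dirty[params].fillna(0)).abs().sum(axis=1) > 0
    assert 0.03 <= planted.mean() <= 0.07
    # the oracle drops exactly the contaminated rows, then both go through
    # the same rejection, so any difference is imperfect outlier handling
    oracle, _ = remove_outlier_structures(clean[~planted])
    kept_d, _ = remove_outlier_structures(dirty)
    for cls, go in oracle.groupby(["sugar_type", "base_type"]):
        gd = kept_d[(kept_d["sugar_type"] == cls[0])
                    & (kept_d["base_type"] == cls[1])]
        for p in params:
            a, b = go[p].dropna(), gd[p].dropna()
            if len(a) < 10 or len(b) < 10:
                continue
            sem = a.std() / np.sqrt(len(a))
            assert abs(a.mean() - b.mean()) < 0.5 * sem


# ---------------------------------------------------------------------------
# builder smoke behaviour
# ---------------------------------------------------------------------------

def test_builder_on_grouped_table_recovers_grouping_and_forms():
    t = generate_synthetic_table(seed=1)
    b = DictionaryBuilder(DerivationConfig(seed=1)).fit(t)
    rep = b.report_["parameters"]
    # pucker-split bond recovered with a pucker grouping
    assert rep["C3'-C4'"]["grouping"] == ["pucker"]
    # planted chi-dependence of the glycosidic bond selects the periodic form
    assert any(g.get("form") == "grid_chi" for g in rep["C1'-N"]["groups"])
    # endocyclic angles adopt the tau_m-linear form
    assert any(g.get("form") == "linear_tau"
               for g in rep["C4'-O4'-C1'"]["groups"])
    assert b.report_["n_welch_tests"] > 0


def test_builder_without_group_differences_yields_single_groups():
    rng = np.random.default_rng(12)
    n = 200
    t = _table(R_factor=[5.0] * n)
    t["sugar_type"] = rng.choice(["ribose", "deoxyribose"], n)
    t["base_type"] = rng.choice(["purine", "pyrimidine"], n)
    t["P"] = rng.uniform(0, 190, n)
    t["tau_m"] = rng.uniform(28, 48, n)
    t["chi"] = rng.uniform(-180, 180, n)
    t["gamma"] = rng.normal(60, 10, n)
    t["C1'-C2'"] = rng.normal(1.528, 0.01, n)
    b = DictionaryBuilder(DerivationConfig(seed=2)).fit(t)
    rows = b.targets_[b.targets_["parameter"] == "C1'-C2'"]
    assert len(rows) == 1
    assert rows.iloc[0]["form"] == "fixed"
    assert rows.iloc[0]["value"] == pytest.approx(1.528, abs=0.003)
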