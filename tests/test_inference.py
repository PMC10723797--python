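"""Statistical battery: gated tests, exact Wilcoxon, JZS BF, ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from forcediscrim.inference import (
    CONTRAST_PLANS,
    ConstantDataError,
    bf01_label,
    compare_conditions,
    hodges_lehmann_ci,
    jzs_bf01,
    jzs_bf01_montecarlo,
    normality_gate,
    oneway_anova,
    paired_t,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------

def test_gate_rejects_tiny_or_constant():
    with pytest.raises(ConstantDataError):
        normality_gate([1.0, 2.0])
    with pytest.raises(ConstantDataError):
        normality_gate([1.0, 1.0, 1.0, 1.0])


def test_gate_keeps_t_for_normal_data():
    rng = np.random.default_rng(1)
    picks = [normality_gate(rng.normal(0, 1, 30)) for _ in range(200)]
    # type-I of the gate is ~alpha, so the t-branch dominates
    assert picks.count("paired_t") > 0.85 * len(picks)


def test_gate_detects_skew():
    rng = np.random.default_rng(2)
    picks = [normality_gate(np.exp(rng.normal(0, 1, 30))) for _ in range(100)]
    assert picks.count("wilcoxon") > 0.8 * len(picks)


# ---------------------------------------------------------------------------
# Paired t
# ---------------------------------------------------------------------------

def test_paired_t_hand_computed():
    # differences (1, 2, 3): t = 2 / (1/sqrt(3)) = 3.4641..., df = 2
    res = paired_t([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
    assert res.statistic == pytest.approx(2.0 * np.sqrt(3.0), abs=1e-12)
    assert res.df == 2
    assert res.effect_size == pytest.approx(2.0, abs=1e-12)  # mean 2 / sd 1
    ref = stats.ttest_rel([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_paired_t_identity_gives_null_result():
    res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == 0.0 and res.p_value == 1.0
    assert res.effect_size == 0.0
    assert res.ci95 == (0.0, 0.0)


def test_paired_t_constant_nonzero_difference_errors():
    with pytest.raises(ConstantDataError):
        paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])


def test_paired_t_type_one_error_rate():
    rng = np.random.default_rng(3)
    rej = sum(
        paired_t(rng.normal(0, 1, 20), rng.normal(0, 1, 20)).p_value < 0.05
        for _ in range(2000)
    )
    assert 0.03 < rej / 2000 < 0.07


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _brute_force_wilcoxon_p(d):
    """Two-tailed exact p by literal enumeration of all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = np.array(
        [sum(r for r, s in zip(ranks, signs) if s)
         for signs in itertools.product([False, True], repeat=n)]
    )
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


def test_wilcoxon_three_points():
    res = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]))
    assert res.statistic == 6.0
    assert res.effect_size == 1.0
    assert res.p_value == pytest.approx(0.25)
    neg = wilcoxon_signed_rank(np.array([-1.0, -2.0, -3.0]))
    assert neg.statistic == 0.0 and neg.effect_size == -1.0


def test_wilcoxon_all_zero_differences_error():
    with pytest.raises(ConstantDataError):
        wilcoxon_signed_rank(np.zeros(5))


def test_wilcoxon_matches_enumeration_oracle():
    """Exact p equals full 2^n enumeration, with and without ties, n <= 12."""
    rng = np.random.default_rng(4)
    for trial in range(30):
        n = int(rng.integers(4, 13))
        d = rng.normal(0.3, 1.0, n)
        if trial % 2:
            d = np.round(d, 1)  # induce ties (and possible zeros)
            if np.all(d == 0):
                continue
        ours = wilcoxon_signed_rank(d).p_value
        assert ours == pytest.approx(_brute_force_wilcoxon_p(d), abs=1e-12)


def test_wilcoxon_matches_scipy_exact():
    rng = np.random.default_rng(5)
    for _ in range(20):
        d = rng.normal(0.2, 1.0, 15)
        ours = wilcoxon_signed_rank(d).p_value
        ref = stats.wilcoxon(d, mode="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)


def test_wilcoxon_normal_approx_tracks_exact():
    rng = np.random.default_rng(6)
    d = rng.normal(0.3, 1.0, 24)
    exact = wilcoxon_signed_rank(d, exact_max_n=25).p_value
    approx = wilcoxon_signed_rank(d, exact_max_n=10).p_value
    assert approx == pytest.approx(exact, abs=0.02)


def test_hodges_lehmann_matches_r_convention():
    """Pseudomedian and exact CI agree with R's wilcox.test conf.int."""
    import shutil
    import subprocess

    d = [0.12, -0.35, 0.47, 0.81, 0.22, -0.11, 0.55, 0.38, -0.02, 0.66,
         0.29, 0.4]
    est, (lo, hi) = hodges_lehmann_ci(np.array(d))
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not on PATH")
    rcode = (
        "d <- c(0.12, -0.35, 0.47, 0.81, 0.22, -0.11, 0.55, 0.38, -0.02, "
        "0.66, 0.29, 0.4); "
        "w <- wilcox.test(d, conf.int=TRUE, exact=TRUE); "
        "cat(sprintf('%.10f %.10f %.10f', w$estimate, w$conf.int[1], "
        "w$conf.int[2]))"
    )
    out = subprocess.run(
        ["Rscript", "-e", rcode], capture_output=True, text=True, check=True
    ).stdout.split()
    r_est, r_lo, r_hi = map(float, out)
    assert est == pytest.approx(r_est, abs=1e-9)
    assert lo == pytest.approx(r_lo, abs=1e-9)
    assert hi == pytest.approx(r_hi, abs=1e-9)


def test_hodges_lehmann_ci_coverage():
    rng = np.random.default_rng(7)
    cover = 0
    reps = 400
    for _ in range(reps):
        d = rng.normal(0.5, 1.0, 15)
        _, (lo, hi) = hodges_lehmann_ci(d)
        cover += lo <= 0.5 <= hi
    assert 0.90 < cover / reps < 0.99


# ---------------------------------------------------------------------------
# JZS Bayes factor
# ---------------------------------------------------------------------------

def test_bf01_monotone_decreasing_in_t():
    vals = [jzs_bf01(t, 30) for t in np.arange(0.0, 6.1, 0.5)]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_bf01_against_pingouin():
    import pingouin as pg

    for t, n in [(0.45, 30), (2.0, 30), (1.0, 15)]:
        ours = jzs_bf01(t, n)
        ref = 1.0 / float(pg.bayesfactor_ttest(t, n, paired=True, r=0.707))
        assert ours == pytest.approx(ref, rel=1e-6)


def test_bf01_against_monte_carlo():
    for t, n in [(0.0, 30), (1.5, 10), (3.0, 100)]:
        q = jzs_bf01(t, n)
        mc = jzs_bf01_montecarlo(t, n, n_draws=2_000_000, seed=11)
        assert mc == pytest.approx(q, rel=0.01)


def test_bf01_moderate_band_for_small_t():
    bf = jzs_bf01(0.45, 30)
    assert 3.0 < bf < 10.0
    assert bf01_label(bf) == "moderate_null"


def test_bf01_input_validation():
    with pytest.raises(ValueError):
        jzs_bf01(1.0, 1)
    with pytest.raises(ValueError):
        jzs_bf01(np.inf, 30)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def test_anova_identical_groups():
    res = oneway_anova([[1.0, 2.0, 3.0]] * 3)
    assert res.f_value == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)
    assert res.partial_eta_sq == pytest.approx(0.0)


def test_anova_closed_form():
    # groups (1,2,3),(2,3,4),(3,4,5): SSb=6, SSw=6, F=(6/2)/(6/6)=3, eta=0.5
    res = oneway_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
    assert res.f_value == pytest.approx(3.0, abs=1e-12)
    assert res.partial_eta_sq == pytest.approx(0.5, abs=1e-12)
    assert res.df_between == 2 and res.df_within == 6
    ref = stats.f_oneway([1, 2, 3], [2, 3, 4], [3, 4, 5])
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_anova_two_groups_is_t_squared():
    rng = np.random.default_rng(8)
    a, b = rng.normal(0, 1, 30), rng.normal(0.4, 1, 30)
    res = oneway_anova([a, b])
    assert res.f_value == pytest.approx(res.posthoc[0].t ** 2, abs=1e-10)
    assert res.posthoc[0].df == 58


def test_anova_bonferroni_caps_at_one():
    rng = np.random.default_rng(9)
    groups = [rng.normal(0, 1, 10) for _ in range(4)]
    res = oneway_anova(groups)
    assert len(res.posthoc) == 6
    for ph in res.posthoc:
        assert ph.p_bonferroni == pytest.approx(min(1.0, ph.p_raw * 6))
        assert 0 <= ph.p_bonferroni <= 1


def test_anova_constant_group_flags_levene():
    res = oneway_anova([[1.0, 1.0, 1.0], [2.0, 3.0, 4.0]])
    assert not res.levene_defined
    assert np.isnan(res.levene_p)
    assert np.isfinite(res.f_value)


# ---------------------------------------------------------------------------
# Planned contrasts
# ---------------------------------------------------------------------------

def _fits_frame(rng, n=20, shift=-0.2):
    rows = []
    for i in range(n):
        base = rng.normal(2.0, 0.15)
        rows += [
            {"participant_id": f"P{i}", "condition": "baseline", "pse": base,
             "jnd": rng.normal(0.4, 0.05)},
            {"participant_id": f"P{i}", "condition": "contact",
             "pse": base + shift + rng.normal(0, 0.05),
             "jnd": rng.normal(0.4, 0.05)},
            {"participant_id": f"P{i}", "condition": "no_contact",
             "pse": base + rng.normal(0, 0.05), "jnd": rng.normal(0.4, 0.05)},
        ]
    return pd.DataFrame(rows)


def test_compare_conditions_detects_shift(rng):
    fits = _fits_frame(rng)
    out = compare_conditions(fits, CONTRAST_PLANS["exp1"], measure="pse")
    by = {(c.condition_a, c.condition_b): c for c in out}
    assert by[("contact", "baseline")].result.p_value < 0.01
    assert by[("contact", "baseline")].result.estimate < 0  # attenuation
    nc = by[("no_contact", "baseline")].result
    if nc.p_value >= 0.05:
        assert nc.bf01 is not None and nc.bf01 > 0


def test_compare_conditions_unknown_condition(rng):
    fits = _fits_frame(rng)
    with pytest.raises(KeyError):
        compare_conditions(fits, [("contact", "phantom")])


def test_compare_conditions_identical_columns(rng):
    fits = _fits_frame(rng)
    dup = fits[fits["condition"] == "baseline"].copy()
    dup["condition"] = "baseline2"
    both = pd.concat([fits, dup], ignore_index=True)
    out = compare_conditions(both, [("baseline", "baseline2")])
    res = out[0].result
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_compare_conditions_drops_missing_pairs(rng):
    fits = _fits_frame(rng)
    fits = fits[~((fits["participant_id"] == "P0")
                  & (fits["condition"] == "contact"))]
    out = compare_conditions(fits, [("contact", "baseline")])
    assert out[0].n_dropped == 1
    assert out[0].result.n_pairs == 19


def test_contrast_plans_cover_spec():
    assert len(CONTRAST_PLANS["exp1"]) == 3
    assert len(CONTRAST_PLANS["exp2"]) == 7
    assert len(CONTRAST_PLANS["exp3"]) == 3


# ---------------------------------------------------------------------------
# Property: signed-rank outputs stay in their defined ranges
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    st.lists(
        st.floats(min_value=-5, max_value=5, allow_nan=False).filter(
            lambda v: v != 0
        ),
        min_size=2, max_size=20,
    )
)
def test_wilcoxon_output_ranges(diffs):
    d = np.asarray(diffs)
    res = wilcoxon_signed_rank(d)
    assert 0.0 <= res.p_value <= 1.0
    assert -1.0 <= res.effect_size <= 1.0
    assert res.ci95[0] <= res.estimate <= res.ci95[1]
    # flipping every sign leaves the two-tailed p unchanged
    flipped = wilcoxon_signed_rank(-d)
    assert flipped.p_value == pytest.approx(res.p_value, abs=1e-12)
    assert flipped.effect_size == pytest.approx(-res.effect_size, abs=1e-12)
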