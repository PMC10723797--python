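"""Group-level comparison battery for PSE/JND (and kinematic) contrasts.

Pairwise condition contrasts follow a normality-gated two-branch procedure:
Shapiro–Wilk on the paired differences decides between a paired t-test
(Cohen's d, t-based CI95 on the mean difference) and a Wilcoxon signed-rank
test (matched rank-biserial correlation, Hodges–Lehmann CI95 on the location
shift).  Non-significant contrasts additionally get a JZS Bayes factor BF01
(default Cauchy prior on standardised effect size, scale 0.707) quantifying
support for the null.  Between-experiment comparisons use a one-way ANOVA
with partial eta squared, Levene's homogeneity check, and Bonferroni-corrected
pooled-variance post hoc t-tests.

The Wilcoxon test here is exact: the null distribution of the positive-rank
sum is enumerated by dynamic programming over sign assignments (equivalent to
full 2^n enumeration, tie-aware via average ranks) whenever the number of
nonzero differences is at most ``exact_max_n``; beyond that a tie- and
continuity-corrected normal approximation is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "PairedComparisonResult",
    "ContrastResult",
    "PostHocResult",
    "AnovaResult",
    "ConstantDataError",
    "CONTRAST_PLANS",
    "normality_gate",
    "paired_t",
    "wilcoxon_signed_rank",
    "signed_rank_null_distribution",
    "hodges_lehmann_ci",
    "jzs_bf01",
    "jzs_bf01_montecarlo",
    "bf01_label",
    "oneway_anova",
    "compare_conditions",
]


class ConstantDataError(ValueError):
    """Raised when a test is requested on zero-variance (or all-zero) data."""


@dataclass
class PairedComparisonResult:
    """One paired contrast: test choice, statistic, p, effect size, CI, BF01."""

    test_used: str  # "paired_t" | "wilcoxon"
    statistic: float  # t, or W = sum of positive-difference ranks
    df: int | None
    p_value: float
    effect_size: float  # Cohen's d, or matched rank-biserial r_rb
    effect_size_name: str
    ci95: tuple[float, float]
    estimate: float  # mean difference (t) or Hodges-Lehmann pseudomedian
    n_pairs: int
    bf01: float | None = None
    bf01_label: str | None = None

    def to_dict(self) -> dict:
        return {
            "test": self.test_used,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p_value,
            "effect_size": self.effect_size,
            "effect_size_name": self.effect_size_name,
            "ci95": list(self.ci95),
            "estimate": self.estimate,
            "n_pairs": self.n_pairs,
            "bf01": self.bf01,
            "bf01_label": self.bf01_label,
            "display": {
                "statistic": round(self.statistic, 2),
                "effect_size": round(self.effect_size, 2),
                "p": round(self.p_value, 3),
                "ci95": [round(v, 2) for v in self.ci95],
            },
        }


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------

def normality_gate(differences: Sequence[float], alpha: float = 0.05) -> str:
    """Choose the paired test from Shapiro–Wilk on the differences.

    Returns ``"wilcoxon"`` when Shapiro–Wilk rejects normality at ``alpha``,
    else ``"paired_t"``.  Needs at least 3 non-identical values.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise ConstantDataError("normality gate needs n >= 3")
    if np.ptp(d) == 0:
        raise ConstantDataError("normality gate undefined for constant data")
    p = stats.shapiro(d).pvalue
    return "wilcoxon" if p < alpha else "paired_t"


# ---------------------------------------------------------------------------
# Paired t-test
# ---------------------------------------------------------------------------

def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedComparisonResult:
    """Two-tailed paired t-test with Cohen's d and a t-based CI95.

    t = mean(d) / (sd(d)/sqrt(n)), df = n-1, d = mean(d)/sd(d) with the
    differences d = x - y; the CI95 covers the mean difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    n = d.size
    if n < 2:
        raise ConstantDataError("paired t-test needs n >= 2")
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            # identical samples: the no-effect limit, reported as t = 0
            return PairedComparisonResult(
                test_used="paired_t", statistic=0.0, df=n - 1, p_value=1.0,
                effect_size=0.0, effect_size_name="cohen_d", ci95=(0.0, 0.0),
                estimate=0.0, n_pairs=n,
            )
        raise ConstantDataError("zero-variance nonzero differences")
    m = d.mean()
    se = sd / np.sqrt(n)
    t = m / se
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    return PairedComparisonResult(
        test_used="paired_t",
        statistic=float(t),
        df=df,
        p_value=float(min(1.0, p)),
        effect_size=float(m / sd),
        effect_size_name="cohen_d",
        ci95=(float(m - tcrit * se), float(m + tcrit * se)),
        estimate=float(m),
        n_pairs=n,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (exact)
# ---------------------------------------------------------------------------

def _signed_rank_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments per doubled positive-rank sum.

    Dynamic-programming convolution over the 2^n equally likely sign vectors:
    ``out[s]`` is the number of assignments whose doubled T+ equals ``s``.
    Equivalent to full enumeration, in O(n * total) time.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def signed_rank_null_distribution(n: int) -> np.ndarray:
    """Null pmf of the signed-rank statistic W for n untied differences."""
    counts = _signed_rank_counts(2 * np.arange(1, n + 1))[::2]
    return counts / counts.sum()


def _exact_two_tailed_p(doubled_ranks: np.ndarray, w_doubled: int) -> float:
    counts = _signed_rank_counts(doubled_ranks)
    total = counts.sum()
    lo = counts[: w_doubled + 1].sum() / total
    hi = counts[w_doubled:].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def hodges_lehmann_ci(
    differences: Sequence[float],
    alpha: float = 0.05,
    exact_max_n: int = 25,
) -> tuple[float, tuple[float, float]]:
    """Hodges–Lehmann pseudomedian and CI via Walsh averages.

    The point estimate is the median of the n(n+1)/2 pairwise Walsh averages
    (d_i + d_j)/2, i <= j; the interval trims the extreme Walsh averages at
    the exact (or, for large n, normal-approximated) signed-rank critical
    value, mirroring the classical distribution-free construction.
    """
    d = np.sort(np.asarray(differences, dtype=float))
    n = d.size
    walsh = np.sort(((d[:, None] + d[None, :]) / 2.0)[np.triu_indices(n)])
    m = walsh.size
    if n <= exact_max_n:
        cdf = np.cumsum(signed_rank_null_distribution(n))
        # smallest q with P(W <= q) >= alpha/2
        qu = int(np.searchsorted(cdf, alpha / 2.0))
    else:
        mean = n * (n + 1) / 4.0
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        qu = int(np.floor(mean + stats.norm.ppf(alpha / 2.0) * sd))
    qu = max(qu, 1)
    ql = n * (n + 1) // 2 - qu
    lower = walsh[qu - 1]
    upper = walsh[min(ql, m - 1)]
    return float(np.median(walsh)), (float(lower), float(upper))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    exact_max_n: int = 25,
) -> PairedComparisonResult:
    """Wilcoxon signed-rank test on paired samples (or on differences).

    Zero differences are dropped; |d| are ranked with average ranks for ties;
    the statistic W is the sum of ranks of positive differences.  The
    two-tailed p is exact (sign-assignment enumeration) for n <= exact_max_n,
    else normal with tie and continuity corrections.  Effect size is the
    matched rank-biserial correlation r_rb = (T+ - T-)/(T+ + T-); the CI95 is
    the Hodges–Lehmann interval.
    """
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        d_all = x - y
    else:
        d_all = x
    d = d_all[d_all != 0]
    n = d.size
    if n == 0:
        raise ConstantDataError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    t_minus = float(ranks[d < 0].sum())
    w = t_plus
    r_rb = (t_plus - t_minus) / (t_plus + t_minus)
    doubled = np.rint(2 * ranks).astype(int)
    if n <= exact_max_n:
        w_doubled = int(round(2 * w))
        p = _exact_two_tailed_p(doubled, w_doubled)
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        tie_corr = (tie_counts**3 - tie_counts).sum() / 48.0
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr)
        z = (w - mean - 0.5 * np.sign(w - mean)) / sd
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    est, ci = hodges_lehmann_ci(d, exact_max_n=exact_max_n)
    return PairedComparisonResult(
        test_used="wilcoxon",
        statistic=w,
        df=None,
        p_value=p,
        effect_size=float(r_rb),
        effect_size_name="rank_biserial",
        ci95=ci,
        estimate=est,
        n_pairs=int(d_all.size),
    )


# ---------------------------------------------------------------------------
# JZS Bayes factor
# ---------------------------------------------------------------------------

def _jzs_marginal(t: float, nu: int, sqrt_n: float, scale: float) -> float:
    """Marginal likelihood of t under delta ~ Cauchy(0, scale)."""

    def integrand(delta: float) -> float:
        return stats.nct.pdf(t, nu, delta * sqrt_n) * stats.cauchy.pdf(
            delta, 0.0, scale
        )

    lo, _ = integrate.quad(integrand, -np.inf, 0.0, epsabs=0.0, epsrel=1e-8,
                           limit=200)
    hi, _ = integrate.quad(integrand, 0.0, np.inf, epsabs=0.0, epsrel=1e-8,
                           limit=200)
    return lo + hi


def jzs_bf01(t: float, n: int, cauchy_scale: float = 0.707) -> float:
    """JZS Bayes factor in favour of the null for a one-sample/paired t.

    BF10 is the ratio of the marginal likelihood of the observed t under a
    Cauchy(0, scale) prior on the standardised effect size (integrated by
    adaptive quadrature) to the central-t null likelihood, with nu = n - 1
    degrees of freedom; BF01 = 1/BF10.
    """
    if n < 2:
        raise ValueError("jzs_bf01 needs n >= 2")
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    nu = n - 1
    alt = _jzs_marginal(float(t), nu, np.sqrt(n), cauchy_scale)
    null = stats.t.pdf(float(t), nu)
    return float(null / alt)


def jzs_bf01_montecarlo(
    t: float,
    n: int,
    cauchy_scale: float = 0.707,
    n_draws: int = 1_000_000,
    seed: int = 0,
    batch: int = 2_000_000,
) -> float:
    """Monte-Carlo cross-check of :func:`jzs_bf01` by joint simulation.

    An independent integration route used to validate the adaptive
    quadrature: using T = (Z + delta*sqrt(n)) / sqrt(V/nu) with V ~ chi2_nu,
    the marginal density of t under the Cauchy prior is
    E[ w * phi(w*t - delta*sqrt(n)) ] over delta ~ Cauchy(0, scale) and
    w = sqrt(V/nu), estimated by averaging normal densities over prior draws.
    """
    rng = np.random.default_rng(seed)
    nu = n - 1
    sqrt_n = np.sqrt(n)
    total = 0.0
    remaining = n_draws
    while remaining > 0:
        m = min(batch, remaining)
        delta = rng.standard_cauchy(m) * cauchy_scale
        w = np.sqrt(rng.chisquare(nu, size=m) / nu)
        z = w * t - delta * sqrt_n
        total += float(np.sum(w * np.exp(-0.5 * z * z)))
        remaining -= m
    alt = total / (n_draws * np.sqrt(2.0 * np.pi))
    return float(stats.t.pdf(t, nu) / alt)


def bf01_label(bf01: float) -> str:
    """Conventional evidence bands for BF01 (support for the null)."""
    if bf01 >= 10:
        return "strong_null"
    if bf01 >= 3:
        return "moderate_null"
    if bf01 >= 1:
        return "anecdotal_null"
    if bf01 > 1 / 3:
        return "anecdotal_alternative"
    if bf01 > 1 / 10:
        return "moderate_alternative"
    return "strong_alternative"


# ---------------------------------------------------------------------------
# One-way ANOVA with Bonferroni post hocs
# ---------------------------------------------------------------------------

@dataclass
class PostHocResult:
    pair: tuple[str, str]
    t: float
    df: int
    p_raw: float
    p_bonferroni: float
    d: float
    ci95: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "t": self.t,
            "df": self.df,
            "p_raw": self.p_raw,
            "p_bonferroni": self.p_bonferroni,
            "d": self.d,
            "ci95": list(self.ci95),
            "display": {
                "t": round(self.t, 2),
                "d": round(self.d, 2),
                "p_bonferroni": round(self.p_bonferroni, 3),
            },
        }


@dataclass
class AnovaResult:
    f_value: float
    df_between: int
    df_within: int
    p_value: float
    partial_eta_sq: float
    levene_p: float
    posthoc: list[PostHocResult] = field(default_factory=list)
    levene_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "F": self.f_value,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p": self.p_value,
            "partial_eta_sq": self.partial_eta_sq,
            "levene_p": self.levene_p,
            "levene_defined": self.levene_defined,
            "posthoc": [ph.to_dict() for ph in self.posthoc],
            "display": {
                "F": round(self.f_value, 2),
                "p": round(self.p_value, 3),
                "partial_eta_sq": round(self.partial_eta_sq, 3),
            },
        }


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float, float,
                                                      tuple[float, float]]:
    n1, n2 = a.size, b.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    sp = np.sqrt(sp2)
    diff = a.mean() - b.mean()
    se = sp * np.sqrt(1.0 / n1 + 1.0 / n2)
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    d = diff / sp
    return float(t), df, float(min(1.0, p)), float(d), (
        float(diff - tcrit * se), float(diff + tcrit * se))


def oneway_anova(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> AnovaResult:
    """Between-subjects one-way ANOVA with ηp², Levene, Bonferroni post hocs.

    Partial eta squared is SS_between / (SS_between + SS_within); Levene's
    homogeneity test uses the mean-centred variant; post hoc pairwise tests
    are pooled-variance independent t-tests with p multiplied by the number
    of pairs (capped at 1).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(gs))]
    allv = np.concatenate(gs)
    grand = allv.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b = len(gs) - 1
    df_w = allv.size - len(gs)
    if ss_within == 0:
        f = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    eta = ss_between / (ss_between + ss_within) if (ss_between + ss_within) else 0.0
    levene_defined = True
    try:
        if any(np.ptp(g) == 0 for g in gs):
            raise ValueError("constant group")
        levene_p = float(stats.levene(*gs, center="mean").pvalue)
    except Exception:
        levene_p = float("nan")
        levene_defined = False
    pairs = [(i, j) for i in range(len(gs)) for j in range(i + 1, len(gs))]
    posthoc = []
    for i, j in pairs:
        t, df, p_raw, d, ci = _pooled_t(gs[i], gs[j])
        posthoc.append(
            PostHocResult(
                pair=(str(labels[i]), str(labels[j])),
                t=t, df=df, p_raw=p_raw,
                p_bonferroni=min(1.0, p_raw * len(pairs)),
                d=d, ci95=ci,
            )
        )
    return AnovaResult(
        f_value=float(f), df_between=df_b, df_within=df_w, p_value=float(p),
        partial_eta_sq=float(eta), levene_p=levene_p, posthoc=posthoc,
        levene_defined=levene_defined,
    )


# ---------------------------------------------------------------------------
# Planned condition contrasts
# ---------------------------------------------------------------------------

#: Planned (condition_a, condition_b) contrasts per experiment preset;
#: differences are taken as a - b, so "attenuation of a vs b" shows as a
#: negative mean difference in PSE.
CONTRAST_PLANS: Mapping[str, tuple[tuple[str, str], ...]] = {
    "exp1": (
        ("contact", "baseline"),
        ("contact", "no_contact"),
        ("no_contact", "baseline"),
    ),
    "exp2": (
        ("contact", "baseline"),
        ("no_contact", "baseline"),
        ("nogo_contact", "baseline"),
        ("nogo_no_contact", "baseline"),
        ("no_contact", "nogo_no_contact"),
        ("contact", "nogo_contact"),
        ("nogo_contact", "nogo_no_contact"),
    ),
    "exp3": (
        ("contact", "baseline"),
        ("no_contact", "baseline"),
        ("contact", "no_contact"),
    ),
}


@dataclass
class ContrastResult:
    condition_a: str
    condition_b: str
    measure: str
    result: PairedComparisonResult
    n_dropped: int = 0  # participants missing one cell of the pair

    def to_dict(self) -> dict:
        return {
            "contrast": f"{self.condition_a}-{self.condition_b}",
            "measure": self.measure,
            "n_dropped": self.n_dropped,
            **self.result.to_dict(),
        }


def compare_conditions(
    fits: pd.DataFrame,
    contrasts: Sequence[tuple[str, str]],
    measure: str = "pse",
    alpha: float = 0.05,
    bf_scale: float = 0.707,
    bf_always: bool = False,
) -> list[ContrastResult]:
    """Run the planned paired contrasts on a per-fit table.

    ``fits`` is the tidy table from :func:`forcediscrim.psychometric.fit_table`
    (or an ingested PSE/JND table with columns participant_id, condition and
    the measure).  Per contrast: participants missing either cell are dropped
    (and counted), the normality gate picks the test, and BF01 is attached to
    non-significant contrasts (or to all of them when ``bf_always``).  The
    Bayes factor is always the JZS t-test BF computed on the same paired
    differences, also for Wilcoxon-gated contrasts.
    """
    wide = fits.pivot_table(
        index="participant_id", columns="condition", values=measure,
        aggfunc="first",
    )
    known = set(wide.columns)
    out: list[ContrastResult] = []
    for a, b in contrasts:
        if a not in known or b not in known:
            raise KeyError(
                f"contrast ({a!r}, {b!r}) references a condition absent from "
                f"the fit table (have: {sorted(known)})"
            )
        sub = wide[[a, b]].dropna()
        n_dropped = int(len(wide) - len(sub))
        xa = sub[a].to_numpy()
        xb = sub[b].to_numpy()
        d = xa - xb
        if np.ptp(d) == 0 and d.size and d[0] == 0:
            gate = "paired_t"  # identical columns: degenerate t = 0 path
        else:
            gate = normality_gate(d, alpha=alpha)
        if gate == "paired_t":
            res = paired_t(xa, xb)
        else:
            res = wilcoxon_signed_rank(xa, xb)
        if bf_always or res.p_value >= alpha:
            sd = d.std(ddof=1)
            if sd > 0:
                t_for_bf = d.mean() / (sd / np.sqrt(d.size))
                res.bf01 = jzs_bf01(t_for_bf, d.size, cauchy_scale=bf_scale)
                res.bf01_label = bf01_label(res.bf01)
        out.append(
            ContrastResult(
                condition_a=a, condition_b=b, measure=measure,
                result=res, n_dropped=n_dropped,
            )
        )
    return out
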