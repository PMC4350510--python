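"""Statistical procedures for the genotype-association analysis.

Covers the complete battery reported for this study design: Hardy-Weinberg
and contingency chi-square tests, one-way ANOVA from raw data or summary
statistics, the univariate mixed (split-plot) repeated-measures ANOVA with
an optional between-subjects covariate, one-sample and pooled independent
t-tests, Cohen's d, Bonferroni-corrected pairwise contrasts, Pearson
correlation, and two-sample power from the noncentral t distribution.

Genotype group codings follow the standard additive (AA / AG / GG, by risk
allele dose) and dominant (AA∪AG carriers vs GG) genetic models.

Design notes: chi-square tests use no continuity correction; t-tests are
two-sided by default while the power routine supports the one-sided case;
ANOVA degrees of freedom are always derived from the data supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

GENOTYPES = ("AA", "AG", "GG")
RISK_DOSE = {"AA": 2, "AG": 1, "GG": 0}


class StatsError(ValueError):
    """Raised for degenerate statistical inputs (zero variance, empty cells...)."""


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic_name: str  # "F", "t", "chi2", "r"
    statistic: float
    df: tuple[float, ...]
    p_value: float
    effect_size: float | None = None
    effect_size_name: str | None = None
    correction: str = "none"

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "effect_size": self.effect_size,
            "effect_size_name": self.effect_size_name,
            "correction": self.correction,
        }


@dataclass(frozen=True)
class PowerSpec:
    effect_size_d: float
    n1: int
    n2: int
    alpha: float = 0.05
    tails: str = "one-sided"  # or "two-sided"
    method: str = "noncentral-t"  # or "normal-approximation"


# ---------------------------------------------------------------------------
# genotype coding


def code_genotypes(genotypes: Sequence[str], scheme: str = "additive") -> dict[str, np.ndarray]:
    """Group membership masks under a genetic model.

    additive: {AA, AG, GG}; dominant: {AA/AG (risk-allele carriers), GG}.
    """
    g = np.asarray(genotypes)
    bad = set(np.unique(g)) - set(GENOTYPES)
    if bad:
        raise StatsError(f"unknown genotype labels: {sorted(bad)}")
    if scheme == "additive":
        return {lab: g == lab for lab in GENOTYPES}
    if scheme == "dominant":
        return {"AA/AG": (g == "AA") | (g == "AG"), "GG": g == "GG"}
    raise StatsError(f"unknown coding scheme {scheme!r}")


def risk_dose(genotypes: Sequence[str]) -> np.ndarray:
    return np.array([RISK_DOSE[g] for g in genotypes])


# ---------------------------------------------------------------------------
# chi-square tests


def hwe_chisq(n_AA: int, n_AG: int, n_GG: int) -> TestResult:
    """Pearson goodness-of-fit test against Hardy-Weinberg proportions.

    The risk-allele frequency is estimated from the counts; expected
    genotype counts are n(p², 2pq, q²); df = 1 (3 classes − 1 − 1
    estimated allele frequency).
    """
    obs = np.array([n_AA, n_AG, n_GG], dtype=float)
    if (obs < 0).any() or obs.sum() == 0:
        raise StatsError("counts must be nonnegative with positive total")
    n = obs.sum()
    p = (2 * n_AA + n_AG) / (2 * n)
    if p in (0.0, 1.0):
        raise StatsError("monomorphic sample: HWE test undefined")
    exp = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return TestResult(
        name="hwe",
        statistic_name="chi2",
        statistic=chi2,
        df=(1.0,),
        p_value=float(sps.chi2.sf(chi2, 1)),
    )


def contingency_chisq(table: Sequence[Sequence[float]], name: str = "contingency") -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise StatsError("table must have at least 2 rows and 2 columns")
    if (t < 0).any():
        raise StatsError("counts must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise StatsError("zero marginal total")
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(
        name=name, statistic_name="chi2", statistic=float(chi2), df=(float(dof),), p_value=float(p)
    )


# ---------------------------------------------------------------------------
# one-way ANOVA


def oneway_anova(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
                 name: str = "oneway") -> TestResult:
    """One-way between-subjects ANOVA with partial eta squared.

    For a single-factor design partial η² coincides with η²:
    SSB / (SSB + SSW).
    """
    values = list(groups.values()) if isinstance(groups, Mapping) else list(groups)
    arrs = [np.asarray(v, dtype=float) for v in values]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise StatsError("need >=2 groups with >=2 observations each")
    ns = np.array([len(a) for a in arrs])
    means = np.array([a.mean() for a in arrs])
    grand = np.concatenate(arrs).mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    if ssw == 0:
        raise StatsError("zero within-group variance: ANOVA degenerate")
    df1, df2 = len(arrs) - 1, int(ns.sum()) - len(arrs)
    f = (ssb / df1) / (ssw / df2)
    return TestResult(
        name=name,
        statistic_name="F",
        statistic=float(f),
        df=(float(df1), float(df2)),
        p_value=float(sps.f.sf(f, df1, df2)),
        effect_size=ssb / (ssb + ssw),
        effect_size_name="partial_eta_sq",
    )


def oneway_anova_summary(ns: Sequence[int], means: Sequence[float], sds: Sequence[float],
                         name: str = "oneway_summary") -> TestResult:
    """One-way ANOVA reconstructed from per-group n, mean and SD.

    Within sums of squares are rebuilt as Σ (n−1)s²; useful for checking
    published descriptive tables.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if len(ns) < 2 or (ns < 2).any():
        raise StatsError("need >=2 groups with n >= 2 each")
    grand = (ns * means).sum() / ns.sum()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    if ssw == 0:
        raise StatsError("zero within-group variance: ANOVA degenerate")
    df1, df2 = len(ns) - 1, ns.sum() - len(ns)
    f = (ssb / df1) / (ssw / df2)
    return TestResult(
        name=name,
        statistic_name="F",
        statistic=float(f),
        df=(float(df1), float(df2)),
        p_value=float(sps.f.sf(f, df1, df2)),
        effect_size=ssb / (ssb + ssw),
        effect_size_name="partial_eta_sq",
    )


# ---------------------------------------------------------------------------
# mixed (split-plot) repeated-measures ANOVA


def _gg_epsilon(y: np.ndarray, group_codes: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    k = y.shape[1]
    resid = y.copy()
    for g in np.unique(group_codes):
        m = group_codes == g
        resid[m] -= y[m].mean(axis=0)
    s = np.cov(resid, rowvar=False)
    sbar = s.mean()
    row = s.mean(axis=1)
    num = (k * (np.trace(s) / k - sbar)) ** 2
    den = (k - 1) * ((s**2).sum() - 2 * k * (row**2).sum() + k**2 * sbar**2)
    return float(num / den) if den > 0 else 1.0


def mixed_anova(
    values: np.ndarray | pd.DataFrame,
    groups: Sequence[str],
    covariate: Sequence[float] | None = None,
    sphericity_correction: str = "none",
) -> dict[str, TestResult]:
    """Mixed-design ANOVA: one between-subjects factor × one within factor.

    ``values`` is the complete subjects × levels score matrix (e.g.
    criterion per block); ``groups`` the between-subjects labels.  Returns
    the classical univariate decomposition — between effect tested against
    subjects-within-groups, the within (level) effect and the
    group × level interaction tested against the level × subjects error —
    each with partial η².

    With a ``covariate`` the between-subjects stratum becomes an analysis
    of covariance on subject means (covariate-adjusted group effect); the
    within-subject stratum is unchanged since a subject-constant covariate
    cancels from within-subject deviations.

    ``sphericity_correction="greenhouse-geisser"`` scales the within-stratum
    degrees of freedom by the Greenhouse-Geisser epsilon.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise StatsError("values must be a subjects x levels matrix with >=2 levels")
    if np.isnan(y).any():
        raise StatsError("missing cells are not supported (complete design required)")
    g = np.asarray(groups)
    if len(g) != y.shape[0]:
        raise StatsError("groups length must match number of subjects")
    labels, codes = np.unique(g, return_inverse=True)
    n_groups = len(labels)
    if n_groups < 2:
        raise StatsError("need at least 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise StatsError("every group needs at least 2 subjects")

    n, k = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=1)

    ss_total = float(((y - grand) ** 2).sum())
    ss_subjects = float(k * ((subj_means - grand) ** 2).sum())
    group_means = np.array([subj_means[codes == i].mean() for i in range(n_groups)])
    ss_group = float(k * (counts * (group_means - grand) ** 2).sum())
    ss_subj_err = ss_subjects - ss_group

    level_means = y.mean(axis=0)
    ss_level = float(n * ((level_means - grand) ** 2).sum())
    cell_means = np.array([y[codes == i].mean(axis=0) for i in range(n_groups)])
    ss_cells = float((counts[:, None] * (cell_means - grand) ** 2).sum())
    ss_inter = ss_cells - ss_group - ss_level
    ss_within_err = ss_total - ss_cells - ss_subj_err

    df_group = n_groups - 1
    df_subj_err = n - n_groups
    df_level = k - 1
    df_inter = df_group * df_level
    df_within_err = df_subj_err * df_level

    if ss_subj_err <= 0 or ss_within_err <= 0:
        raise StatsError("degenerate error strata (zero residual variance)")

    eps = 1.0
    if sphericity_correction in ("greenhouse-geisser", "gg"):
        eps = _gg_epsilon(y, codes)
    elif sphericity_correction != "none":
        raise StatsError(f"unknown sphericity correction {sphericity_correction!r}")

    results: dict[str, TestResult] = {}

    if covariate is None:
        f_group = (ss_group / df_group) / (ss_subj_err / df_subj_err)
        results["between"] = TestResult(
            name="between",
            statistic_name="F",
            statistic=float(f_group),
            df=(float(df_group), float(df_subj_err)),
            p_value=float(sps.f.sf(f_group, df_group, df_subj_err)),
            effect_size=ss_group / (ss_group + ss_subj_err),
            effect_size_name="partial_eta_sq",
        )
    else:
        cov = np.asarray(covariate, dtype=float)
        if len(cov) != n:
            raise StatsError("covariate length must match number of subjects")
        results["between"] = _ancova_between(subj_means, codes, n_groups, cov)

    f_level = (ss_level / df_level) / (ss_within_err / df_within_err)
    f_inter = (ss_inter / df_inter) / (ss_within_err / df_within_err)
    results["within"] = TestResult(
        name="within",
        statistic_name="F",
        statistic=float(f_level),
        df=(eps * df_level, eps * df_within_err),
        p_value=float(sps.f.sf(f_level, eps * df_level, eps * df_within_err)),
        effect_size=ss_level / (ss_level + ss_within_err),
        effect_size_name="partial_eta_sq",
    )
    results["interaction"] = TestResult(
        name="interaction",
        statistic_name="F",
        statistic=float(f_inter),
        df=(eps * df_inter, eps * df_within_err),
        p_value=float(sps.f.sf(f_inter, eps * df_inter, eps * df_within_err)),
        effect_size=ss_inter / (ss_inter + ss_within_err),
        effect_size_name="partial_eta_sq",
    )
    return results


def _ancova_between(subj_means: np.ndarray, codes: np.ndarray, n_groups: int,
                    cov: np.ndarray) -> TestResult:
    """Covariate-adjusted between-subjects effect (Type III group SS).

    Model comparison on subject means: full model with group dummies plus
    covariate versus the covariate-only reduction.
    """
    n = len(subj_means)
    dummies = np.zeros((n, n_groups - 1))
    for i in range(1, n_groups):
        dummies[codes == i, i - 1] = 1.0
    x_full = np.column_stack([np.ones(n), dummies, cov])
    x_red = np.column_stack([np.ones(n), cov])
    rss_full = _rss(x_full, subj_means)
    rss_red = _rss(x_red, subj_means)
    df_group = n_groups - 1
    df_err = n - n_groups - 1
    if df_err < 1 or rss_full <= 0:
        raise StatsError("too few subjects for covariate adjustment")
    ss_group = rss_red - rss_full
    f = (ss_group / df_group) / (rss_full / df_err)
    return TestResult(
        name="between",
        statistic_name="F",
        statistic=float(f),
        df=(float(df_group), float(df_err)),
        p_value=float(sps.f.sf(f, df_group, df_err)),
        effect_size=float(ss_group / (ss_group + rss_full)),
        effect_size_name="partial_eta_sq",
    )


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r)


# ---------------------------------------------------------------------------
# t-tests and effect sizes


def one_sample_t(values: Sequence[float], null_mean: float = 0.0,
                 name: str = "one_sample_t") -> TestResult:
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise StatsError("need n >= 2")
    if v.std(ddof=1) == 0:
        raise StatsError("zero variance: t-test degenerate")
    t, p = sps.ttest_1samp(v, null_mean)
    d = float((v.mean() - null_mean) / v.std(ddof=1))
    return TestResult(
        name=name, statistic_name="t", statistic=float(t), df=(float(len(v) - 1),),
        p_value=float(p), effect_size=d, effect_size_name="cohens_d",
    )


def independent_t(g1: Sequence[float], g2: Sequence[float],
                  name: str = "independent_t") -> TestResult:
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("need n >= 2 in each group")
    if _pooled_sd(a, b) == 0:
        raise StatsError("zero pooled variance: t-test degenerate")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(
        name=name, statistic_name="t", statistic=float(t),
        df=(float(len(a) + len(b) - 2),), p_value=float(p),
        effect_size=cohens_d(a, b), effect_size_name="cohens_d",
    )


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    n1, n2 = len(a), len(b)
    return float(
        np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2))
    )


def cohens_d(g1: Sequence[float], g2: Sequence[float]) -> float:
    """Standardized mean difference (g1 − g2) over the pooled SD."""
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    sd = _pooled_sd(a, b)
    if sd == 0:
        if a.mean() == b.mean():
            return 0.0
        raise StatsError("zero pooled variance with unequal means")
    return float((a.mean() - b.mean()) / sd)


def pairwise_corrected(groups: Mapping[str, Sequence[float]],
                       method: str = "bonferroni") -> list[TestResult]:
    """All pairwise pooled t-tests with multiplicity correction.

    Bonferroni: p multiplied by the number of comparisons, capped at 1.
    """
    if method != "bonferroni":
        raise StatsError(f"unsupported correction {method!r}")
    labels = list(groups)
    if len(labels) < 2:
        raise StatsError("need at least 2 groups")
    pairs = list(combinations(labels, 2))
    m = len(pairs)
    out = []
    for l1, l2 in pairs:
        r = independent_t(groups[l1], groups[l2], name=f"{l1}_vs_{l2}")
        out.append(
            TestResult(
                name=r.name, statistic_name=r.statistic_name, statistic=r.statistic,
                df=r.df, p_value=min(1.0, r.p_value * m),
                effect_size=r.effect_size, effect_size_name=r.effect_size_name,
                correction="bonferroni",
            )
        )
    return out


# ---------------------------------------------------------------------------
# power


def power_two_sample(spec: PowerSpec) -> float:
    """Power of the two-sample pooled t-test at standardized effect d.

    Noncentral-t method: noncentrality δ = d / sqrt(1/n1 + 1/n2); reject
    region from the central t at df = n1 + n2 − 2; power is the noncentral-t
    mass in the rejection region.  The normal approximation replaces both
    distributions with Gaussians.
    """
    if spec.n1 < 2 or spec.n2 < 2:
        raise StatsError("need n >= 2 per group")
    if spec.effect_size_d < 0:
        raise StatsError("effect size must be nonnegative")
    if not 0 < spec.alpha < 1:
        raise StatsError("alpha must be in (0, 1)")
    delta = spec.effect_size_d / np.sqrt(1 / spec.n1 + 1 / spec.n2)
    df = spec.n1 + spec.n2 - 2
    if spec.tails == "one-sided":
        if spec.method == "noncentral-t":
            tcrit = sps.t.ppf(1 - spec.alpha, df)
            return float(sps.nct.sf(tcrit, df, delta))
        if spec.method == "normal-approximation":
            zcrit = sps.norm.ppf(1 - spec.alpha)
            return float(sps.norm.sf(zcrit - delta))
    elif spec.tails == "two-sided":
        if spec.method == "noncentral-t":
            tcrit = sps.t.ppf(1 - spec.alpha / 2, df)
            return float(sps.nct.sf(tcrit, df, delta) + sps.nct.cdf(-tcrit, df, delta))
        if spec.method == "normal-approximation":
            zcrit = sps.norm.ppf(1 - spec.alpha / 2)
            return float(sps.norm.sf(zcrit - delta) + sps.norm.cdf(-zcrit - delta))
    raise StatsError(f"unknown tails/method combination ({spec.tails!r}, {spec.method!r})")


# ---------------------------------------------------------------------------
# correlation


def age_association(x: Sequence[float], y: Sequence[float],
                    name: str = "pearson") -> TestResult:
    """Pearson correlation with the exact t-distributed two-sided test."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise StatsError("need paired samples with n >= 3")
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        raise StatsError("zero variance in one variable")
    r, p = sps.pearsonr(a, b)
    return TestResult(
        name=name, statistic_name="r", statistic=float(r),
        df=(float(len(a) - 2),), p_value=float(p),
    )
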