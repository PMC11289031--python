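"""Group-comparison statistics for hazard-perception feature tables.

The battery mirrors a standard fitness-to-drive analysis: per-group summary
statistics, Welch's heteroscedastic one-way ANOVA, Tukey's honest
significant difference post-hoc test (Tukey–Kramer for unequal group
sizes), a multi-factor linear model with speed/IGD/TTC covariates and a
fitness x IGD x TTC interaction tested with sequential (Type I) sums of
squares, Shapiro–Wilk normality of the model residuals, and Pearson
correlations of TTF with each covariate.

Welch's ANOVA and the Tukey–Kramer test are computed from their defining
formulas with scipy supplying the F and studentized-range distributions;
this keeps the fractional Welch–Satterthwaite degrees of freedom and the
adjusted p-values at full numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import FLAG_TTF_IQR_OUTLIER, FLAG_TTF_OVER_MAX, FeatureRecord

__all__ = [
    "GroupSummary",
    "WelchResult",
    "TukeyRow",
    "GlmTermResult",
    "StatsReport",
    "summarize_groups",
    "welch_anova",
    "tukey_hsd",
    "ancova_glm",
    "shapiro_wilk",
    "pearson_correlation",
    "cohort_to_frame",
    "run_stats",
]

GROUP_ORDER = ["fit", "conditionally_fit", "unfit"]


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    min: float
    max: float
    mean: float
    sd: float | None  # Bessel-corrected; None when n < 2
    median: float


@dataclass(frozen=True)
class WelchResult:
    F: float
    df1: float
    df2: float  # Welch-Satterthwaite, fractional
    p: float


@dataclass(frozen=True)
class TukeyRow:
    pair: str
    diff: float
    lwr: float
    upr: float
    p_adj: float


@dataclass(frozen=True)
class GlmTermResult:
    term: str
    F: float
    p: float
    significant: bool


@dataclass
class StatsReport:
    """Full analysis output; reproducible bit-for-bit from one feature table."""

    summaries: dict[str, list[GroupSummary]] = field(default_factory=dict)
    welch: dict[str, WelchResult] = field(default_factory=dict)
    tukey: dict[str, list[TukeyRow]] = field(default_factory=dict)
    glm_terms: list[GlmTermResult] = field(default_factory=list)
    shapiro: tuple[float, float] | None = None
    pearson: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_used: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "summaries": {
                param: [s.__dict__ for s in rows] for param, rows in self.summaries.items()
            },
            "welch": {k: v.__dict__ for k, v in self.welch.items()},
            "tukey": {k: [r.__dict__ for r in rows] for k, rows in self.tukey.items()},
            "glm_terms": [t.__dict__ for t in self.glm_terms],
            "shapiro": (
                {"W": self.shapiro[0], "p": self.shapiro[1]} if self.shapiro else None
            ),
            "pearson": {k: {"r": v[0], "p": v[1]} for k, v in self.pearson.items()},
            "n_used": self.n_used,
        }


def summarize_groups(
    groups: dict[str, np.ndarray] | dict[str, list[float]]
) -> list[GroupSummary]:
    """Min / max / mean / SD (Bessel) / median per group."""
    out: list[GroupSummary] = []
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            continue
        sd = float(np.std(v, ddof=1)) if v.size >= 2 else None
        if sd is None:
            import warnings

            warnings.warn(f"group {name!r} has a single value: SD undefined", stacklevel=2)
        out.append(
            GroupSummary(
                group=name,
                n=int(v.size),
                min=float(v.min()),
                max=float(v.max()),
                mean=float(v.mean()),
                sd=sd,
                median=float(np.median(v)),
            )
        )
    return out


def welch_anova(groups: list[np.ndarray] | list[list[float]]) -> WelchResult:
    """Welch's (1951) heteroscedastic one-way ANOVA.

    With weights w_j = n_j / s_j^2 and weighted grand mean x~, the statistic
    is F = [sum w_j (xbar_j - x~)^2 / (k-1)] / [1 + 2(k-2)/(k^2-1) * L]
    where L = sum (1 - w_j/sum w)^2 / (n_j - 1); df1 = k - 1 and
    df2 = (k^2 - 1) / (3 L).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("Welch ANOVA needs at least two groups")
    for j, a in enumerate(arrays):
        if a.size < 2:
            raise ValueError(f"group {j} has fewer than two observations")
        if np.var(a, ddof=1) == 0:
            raise ValueError(f"group {j} has zero within-group variance")
    n = np.array([a.size for a in arrays], dtype=float)
    means = np.array([a.mean() for a in arrays])
    var = np.array([np.var(a, ddof=1) for a in arrays])
    w = n / var
    w_sum = w.sum()
    grand = float((w * means).sum() / w_sum)
    lam = float((((1.0 - w / w_sum) ** 2) / (n - 1.0)).sum())
    numer = float((w * (means - grand) ** 2).sum()) / (k - 1)
    denom = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * lam
    F = numer / denom
    df1 = float(k - 1)
    df2 = (k**2 - 1.0) / (3.0 * lam)
    p = float(sps.f.sf(F, df1, df2))
    return WelchResult(F=float(F), df1=df1, df2=float(df2), p=p)


def tukey_hsd(
    groups: dict[str, np.ndarray] | dict[str, list[float]],
    conf: float = 0.95,
) -> list[TukeyRow]:
    """Tukey's HSD all-pairs comparison (Tukey–Kramer for unequal n).

    For pair (i, j): diff = xbar_i - xbar_j, standard error
    se = sqrt(MSE/2 * (1/n_i + 1/n_j)), adjusted p from the
    studentized-range distribution of q_obs = |diff| / se with k groups and
    N - k error degrees of freedom, and a symmetric confidence interval
    diff +/- q_crit * se at the requested family-wise confidence level.
    """
    names = list(groups)
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    k = len(names)
    if k < 2:
        raise ValueError("Tukey HSD needs at least two groups")
    N = sum(a.size for a in arrays.values())
    df_err = N - k
    sse = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays.values())
    mse = sse / df_err
    if mse <= 0:
        raise ValueError("zero mean squared error: all observations identical")
    q_crit = float(sps.studentized_range.ppf(conf, k, df_err))
    rows: list[TukeyRow] = []
    for a_name, b_name in combinations(names, 2):
        a, b = arrays[a_name], arrays[b_name]
        diff = float(a.mean() - b.mean())
        se = np.sqrt(mse / 2.0 * (1.0 / a.size + 1.0 / b.size))
        q_obs = abs(diff) / se
        p_adj = float(np.clip(sps.studentized_range.sf(q_obs, k, df_err), 0.0, 1.0))
        half = q_crit * se
        rows.append(
            TukeyRow(
                pair=f"{a_name} vs {b_name}",
                diff=diff,
                lwr=diff - half,
                upr=diff + half,
                p_adj=p_adj,
            )
        )
    return rows


GLM_FORMULA = "ttf_ms ~ C(fitness) + speed_kmh + igd_deg + ttc_s + C(fitness):igd_deg:ttc_s"

_TERM_LABELS = {
    "C(fitness)": "fitness",
    "speed_kmh": "speed",
    "igd_deg": "igd",
    "ttc_s": "ttc",
    "C(fitness):igd_deg:ttc_s": "fitness:igd:ttc",
}


def ancova_glm(df: pd.DataFrame, alpha: float = 0.001) -> tuple[list[GlmTermResult], np.ndarray]:
    """Multi-factor linear model of TTF on fitness plus the speed/IGD/TTC
    covariates and the fitness x IGD x TTC interaction, tested with
    sequential (Type I) sums of squares in that order.

    Returns the per-term F tests and the model residuals (for the normality
    check). Covariates that are identically constant are dropped with a
    warning; complete cases only.
    """
    import warnings

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    needed = ["ttf_ms", "fitness", "speed_kmh", "igd_deg", "ttc_s"]
    data = df.dropna(subset=needed).copy()
    if len(data) < 8:
        raise ValueError("too few complete cases for the linear model")
    terms = ["C(fitness)", "speed_kmh", "igd_deg", "ttc_s", "C(fitness):igd_deg:ttc_s"]
    for cov in ("speed_kmh", "igd_deg", "ttc_s"):
        if np.var(data[cov].to_numpy(dtype=float)) == 0:
            warnings.warn(f"covariate {cov} is constant: dropped from the model", stacklevel=2)
            terms = [t for t in terms if cov not in t]
    formula = "ttf_ms ~ " + " + ".join(terms)
    model = smf.ols(formula, data=data).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design: aliased terms in " + formula)
    table = sm.stats.anova_lm(model, typ=1)
    results: list[GlmTermResult] = []
    for term, row in table.iterrows():
        if term == "Residual":
            continue
        F = float(row["F"])
        p = float(row["PR(>F)"])
        results.append(
            GlmTermResult(
                term=_TERM_LABELS.get(str(term), str(term)),
                F=F,
                p=p,
                significant=p < alpha,
            )
        )
    return results, np.asarray(model.resid)


def shapiro_wilk(residuals: np.ndarray | list[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p); n must lie in [3, 5000]."""
    r = np.asarray(residuals, dtype=float)
    if not 3 <= r.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = sps.shapiro(r)
    return float(res.statistic), float(res.pvalue)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p via the
    t-transform on n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def cohort_to_frame(cohort: list[FeatureRecord]) -> pd.DataFrame:
    """Feature records as a tidy DataFrame (one row per subject)."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in cohort],
            "fitness": [r.fitness.value if r.fitness else None for r in cohort],
            "ttf_ms": [r.ttf_ms for r in cohort],
            "speed_kmh": [r.speed_kmh for r in cohort],
            "igd_deg": [r.igd_deg for r in cohort],
            "ttc_s": [r.ttc_s for r in cohort],
            "prt_ms": [r.prt_ms for r in cohort],
            "flags": [";".join(sorted(r.flags)) for r in cohort],
        }
    )


_EXCLUDE_TTF = {FLAG_TTF_OVER_MAX, FLAG_TTF_IQR_OUTLIER}


def run_stats(
    cohort: list[FeatureRecord],
    tukey_conf: float = 0.95,
    glm_alpha: float = 0.001,
    include_outliers: bool = False,
) -> StatsReport:
    """The full statistical battery over a screened cohort.

    Records whose TTF screening flags mark them for removal are excluded
    unless ``include_outliers`` (the robustness re-run) is set. PRT analyses
    use the subjects with a usable TTF, mirroring how response times are
    only meaningful where the fixation was measured.
    """
    df = cohort_to_frame(cohort)

    def removed(flags: str) -> bool:
        return bool(_EXCLUDE_TTF & set(flags.split(";")))

    keep = df["ttf_ms"].notna() & df["fitness"].notna()
    if not include_outliers:
        keep &= ~df["flags"].map(removed)
    ttf_df = df[keep]

    report = StatsReport()
    report.n_used["ttf"] = int(len(ttf_df))

    def by_group(frame: pd.DataFrame, col: str) -> dict[str, np.ndarray]:
        out = {}
        for g in GROUP_ORDER:
            vals = frame.loc[frame["fitness"] == g, col].dropna().to_numpy(dtype=float)
            if vals.size:
                out[g] = vals
        return out

    for param in ("ttf_ms", "speed_kmh", "igd_deg", "ttc_s", "prt_ms"):
        groups = by_group(ttf_df, param)
        if groups:
            report.summaries[param] = summarize_groups(groups)

    ttf_groups = by_group(ttf_df, "ttf_ms")
    if len(ttf_groups) >= 2 and all(v.size >= 2 for v in ttf_groups.values()):
        report.welch["ttf_ms"] = welch_anova(list(ttf_groups.values()))
        report.tukey["ttf_ms"] = tukey_hsd(ttf_groups, conf=tukey_conf)

    prt_df = ttf_df[ttf_df["prt_ms"].notna()]
    report.n_used["prt"] = int(len(prt_df))
    prt_groups = by_group(prt_df, "prt_ms")
    if len(prt_groups) >= 2 and all(v.size >= 2 for v in prt_groups.values()):
        report.welch["prt_ms"] = welch_anova(list(prt_groups.values()))
        report.tukey["prt_ms"] = tukey_hsd(prt_groups, conf=tukey_conf)

    try:
        report.glm_terms, resid = ancova_glm(ttf_df, alpha=glm_alpha)
        report.shapiro = shapiro_wilk(resid)
    except ValueError:
        report.glm_terms, report.shapiro = [], None

    for cov in ("speed_kmh", "igd_deg", "ttc_s", "prt_ms"):
        sub = ttf_df.dropna(subset=["ttf_ms", cov])
        if len(sub) >= 3 and sub[cov].var() > 0:
            report.pearson[cov] = pearson_correlation(
                sub["ttf_ms"].to_numpy(), sub[cov].to_numpy()
            )
    return report
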