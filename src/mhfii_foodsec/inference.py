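"""Statistical analyses linking food insecurity (FI) to diet quality.

The analysis chain mirrors standard epidemiological practice for a
cross-sectional survey:

1. confounder screening — keep candidates associated with both the FI
   exposure and the mHFII outcome that materially shift the severe-FI
   estimate (change-in-estimate criterion) and are not redundant with one
   another;
2. one-way ANOVA of the mHFII total across the four FI categories, with
   Bonferroni-corrected pairwise contrasts against the food-secure
   reference;
3. multi-way ANOVA (main-effects linear model with categorical
   covariates) refining the same contrasts after adjustment;
4. per-food-group proportional-odds (cumulative logit) regression of the
   ordinal component score on severe FI vs food secure, adjusted for the
   selected confounders.  The exponentiated exposure coefficient is the
   odds ratio of achieving a higher (more optimal) component score.

Missing data are excluded listwise per analysis; the significance level
is 0.05 throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ContrastResult",
    "OneWayAnovaResult",
    "OrdinalEffect",
    "ScreeningResult",
    "AnalysisResult",
    "AnalysisError",
    "cramers_v",
    "screen_confounders",
    "anova_oneway",
    "anova_adjusted",
    "fit_proportional_odds",
    "ProportionalOddsModel",
    "run_full_analysis",
]

ALPHA_DEFAULT = 0.05


class AnalysisError(ValueError):
    """Raised when an analysis precondition fails (empty group, ...)."""


@dataclass
class ContrastResult:
    """Mean mHFII difference of one FI level vs the food-secure reference."""

    comparison: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted: bool
    n_group: int
    n_reference: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class OneWayAnovaResult:
    f_stat: float
    p_value: float
    group_means: dict[str, float]
    group_n: dict[str, int]
    contrasts: list[ContrastResult]

    def to_dict(self) -> dict:
        return {
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "group_means": self.group_means,
            "group_n": self.group_n,
            "contrasts": [c.to_dict() for c in self.contrasts],
        }


@dataclass
class OrdinalEffect:
    """Severe-FI vs food-secure odds ratio for one component score."""

    component: str
    odds_ratio: float
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    covariates: tuple[str, ...]
    n: int
    flagged: str | None = None  # e.g. quasi-separation note

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["covariates"] = list(self.covariates)
        return d


def _clean(*arrays) -> tuple:
    """Listwise deletion across parallel arrays/Series."""
    df = pd.DataFrame({i: pd.Series(np.asarray(a, dtype=object)) for i, a in enumerate(arrays)})
    keep = df.notna().all(axis=1)
    return tuple(df.loc[keep, i].to_numpy() for i in range(len(arrays)))


def _contrasts_from_fit(
    res, fi_col: str, reference: str, levels: Sequence[str],
    counts: Mapping[str, int], adjusted: bool, alpha: float, m: int,
) -> list[ContrastResult]:
    out = []
    tdist = stats.t(res.df_resid)
    crit = tdist.ppf(1 - (alpha / m) / 2)
    for lev in levels:
        if lev == reference:
            continue
        term = f"C({fi_col}, Treatment(reference='{reference}'))[T.{lev}]"
        est = res.params[term]
        se = res.bse[term]
        # degenerate case: (numerically) zero residual variance
        if se < 1e-9 or np.isnan(se):
            p, se = (1.0, 0.0) if abs(est) < 1e-8 else (0.0, 0.0)
            est = 0.0 if abs(est) < 1e-8 else est
        else:
            p = min(1.0, res.pvalues[term] * m)
        out.append(
            ContrastResult(
                comparison=f"{lev} vs {reference}",
                estimate=float(est),
                ci_low=float(est - crit * se),
                ci_high=float(est + crit * se),
                p_value=float(p),
                adjusted=adjusted,
                n_group=int(counts[lev]),
                n_reference=int(counts[reference]),
            )
        )
    return out


def anova_oneway(
    outcome,
    groups,
    reference: str = "food_secure",
    alpha: float = ALPHA_DEFAULT,
    bonferroni_m: int | None = None,
) -> OneWayAnovaResult:
    """One-way ANOVA with Bonferroni-corrected contrasts vs a reference.

    ``bonferroni_m`` defaults to the number of non-reference levels (the
    reported comparison family); pass 1 to disable the correction.
    """
    y, g = _clean(outcome, groups)
    y = y.astype(float)
    g = g.astype(str)
    levels = sorted(str(lev) for lev in set(g))
    if reference not in levels:
        raise AnalysisError(f"reference group {reference!r} absent")
    counts = {lev: int((g == lev).sum()) for lev in levels}
    bad = [lev for lev, n in counts.items() if n < 2]
    if bad or len(levels) < 2:
        raise AnalysisError(
            f"groups with <2 observations after listwise deletion: {bad}"
        )
    df = pd.DataFrame({"y": y, "fi": g})
    res = smf.ols(f"y ~ C(fi, Treatment(reference='{reference}'))", df).fit()
    m = bonferroni_m if bonferroni_m is not None else len(levels) - 1
    contrasts = _contrasts_from_fit(
        res, "fi", reference, levels, counts, False, alpha, m
    )
    means = {str(lev): float(y[g == lev].mean()) for lev in levels}
    fstat, fp = float(res.fvalue), float(res.f_pvalue)
    if np.isnan(fstat):  # zero variance everywhere
        fstat, fp = 0.0, 1.0
    return OneWayAnovaResult(
        f_stat=fstat,
        p_value=fp,
        group_means=means,
        group_n=counts,
        contrasts=contrasts,
    )


def anova_adjusted(
    data: pd.DataFrame,
    outcome: str,
    fi: str,
    covariates: Sequence[str],
    reference: str = "food_secure",
    alpha: float = ALPHA_DEFAULT,
    bonferroni_m: int | None = None,
) -> list[ContrastResult]:
    """Covariate-adjusted FI contrasts (main-effects linear model).

    Covariates enter as categorical main effects without FI interactions;
    the contrasts are the FI-level coefficients vs the reference.
    """
    cols = [outcome, fi, *covariates]
    df = data[cols].dropna().copy()
    df[fi] = df[fi].astype(str)
    levels = sorted(df[fi].unique())
    if reference not in levels:
        raise AnalysisError(f"reference group {reference!r} absent")
    counts = df[fi].value_counts().to_dict()
    terms = [f"C({fi}, Treatment(reference='{reference}'))"]
    terms += [f"C({c})" for c in covariates]
    formula = f"{outcome} ~ " + " + ".join(terms)
    res = smf.ols(formula, df).fit()
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        raise AnalysisError("singular design: aliased covariate levels")
    m = bonferroni_m if bonferroni_m is not None else len(levels) - 1
    return _contrasts_from_fit(
        res, fi, reference, levels, counts, True, alpha, m
    )


def cramers_v(x, y) -> float:
    """Cramér's V association between two categorical variables."""
    tab = pd.crosstab(pd.Series(x), pd.Series(y))
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return 0.0
    chi2 = stats.chi2_contingency(tab, correction=False)[0]
    n = tab.to_numpy().sum()
    k = min(tab.shape) - 1
    return float(np.sqrt(chi2 / (n * k)))


@dataclass
class ScreeningResult:
    selected: list[str]
    report: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "report": self.report.to_dict(orient="records"),
        }


def screen_confounders(
    data: pd.DataFrame,
    candidates: Sequence[str],
    fi: str = "fi",
    outcome: str = "mhfii_total",
    severe: str = "severe",
    reference: str = "food_secure",
    alpha: float = ALPHA_DEFAULT,
    change_threshold: float = 0.10,
    assoc_threshold: float = 0.6,
) -> ScreeningResult:
    """Select key confounders by a three-part criterion.

    A candidate is retained when it (i) is associated with FI
    (chi-square, p < alpha) and with the outcome (one-way ANOVA,
    p < alpha); (ii) shifts the severe-FI estimate by more than
    ``change_threshold`` (relative) when added to the unadjusted model;
    and (iii) has Cramér's V below ``assoc_threshold`` with every
    already-selected confounder (candidates entered in decreasing order
    of change-in-estimate).  Single-level candidates are skipped with a
    warning.
    """
    base_df = data[[outcome, fi]].dropna()
    base = smf.ols(
        f"{outcome} ~ C({fi}, Treatment(reference='{reference}'))", base_df
    ).fit()
    sev_term = f"C({fi}, Treatment(reference='{reference}'))[T.{severe}]"
    b0 = base.params[sev_term]

    rows = []
    for cand in candidates:
        sub = data[[outcome, fi, cand]].dropna()
        if sub[cand].nunique() < 2:
            warnings.warn(f"candidate {cand!r} has a single level; skipped")
            rows.append(
                dict(candidate=cand, p_fi=np.nan, p_outcome=np.nan,
                     rel_change=np.nan, passes=False, reason="single level")
            )
            continue
        p_fi = stats.chi2_contingency(pd.crosstab(sub[cand], sub[fi]))[1]
        groups = [g[outcome].to_numpy() for _, g in sub.groupby(cand, observed=True)]
        p_out = stats.f_oneway(*groups)[1]
        adj = smf.ols(
            f"{outcome} ~ C({fi}, Treatment(reference='{reference}'))"
            f" + C({cand})",
            sub,
        ).fit()
        rel = abs((adj.params[sev_term] - b0) / b0) if b0 != 0 else np.inf
        passes = (p_fi < alpha) and (p_out < alpha) and (rel > change_threshold)
        rows.append(
            dict(candidate=cand, p_fi=float(p_fi), p_outcome=float(p_out),
                 rel_change=float(rel), passes=bool(passes), reason="")
        )

    report = pd.DataFrame(rows)
    selected: list[str] = []
    order = report[report["passes"]].sort_values(
        "rel_change", ascending=False
    )["candidate"]
    max_assoc = {}
    for cand in order:
        assoc = max(
            (cramers_v(data[cand], data[s]) for s in selected), default=0.0
        )
        max_assoc[cand] = assoc
        if assoc < assoc_threshold:
            selected.append(cand)
        else:
            report.loc[report["candidate"] == cand, "reason"] = (
                "collinear with selected confounder"
            )
    report["max_assoc_with_selected"] = report["candidate"].map(max_assoc)
    report["selected"] = report["candidate"].isin(selected)
    return ScreeningResult(selected=selected, report=report)


def fit_proportional_odds(
    component_score,
    exposure,
    covariates: pd.DataFrame | None = None,
    component: str = "component",
    alpha: float = ALPHA_DEFAULT,
    tol: float = 1e-7,
) -> OrdinalEffect:
    """Cumulative-logit proportional-odds fit of score on binary exposure.

    ``exposure`` is 1 for severe FI, 0 for food secure.  Categorical
    covariates are dummy-encoded.  The exponentiated exposure coefficient
    is the odds ratio of a higher score; with a binary outcome the model
    reduces to logistic regression.  Wald confidence limits on the
    log-odds scale.  Quasi-separated fits are flagged and their CI
    reported as unavailable rather than fabricated.
    """
    y = pd.Series(np.asarray(component_score)).astype(float)
    x = pd.Series(np.asarray(exposure)).astype(float)
    parts = {"__exposure__": x}
    cov_names: tuple[str, ...] = ()
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        cov_names = tuple(cov.columns)
        dummies = pd.get_dummies(
            cov.astype("category"), drop_first=True, dtype=float
        )
        for c in dummies.columns:
            parts[c] = dummies[c]
    X = pd.DataFrame(parts)
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep], X.loc[keep]

    observed = sorted(y.unique())
    if len(observed) < 2:
        raise AnalysisError(
            f"{component}: outcome has a single observed level"
        )
    # dense recode of observed ordinal levels (unobserved levels dropped)
    y = y.map({v: i for i, v in enumerate(observed)}).astype(int)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = OrderedModel(y.to_numpy(), X.to_numpy(), distr="logit")
        res = model.fit(
            method="lbfgs", maxiter=1000, disp=0,
            pgtol=tol, factr=max(10.0, tol * 1e12),
        )
    beta = float(res.params[0])
    se = float(res.bse[0])
    converged = bool(res.mle_retvals.get("converged", True))
    flagged = None
    if not converged or not np.isfinite(se) or se > 10 or abs(beta) > 10:
        flagged = "quasi-separation or non-convergence"
    z = stats.norm.ppf(1 - alpha / 2)
    orr = float(np.exp(beta))
    if flagged:
        ci_low = ci_high = p = None
    else:
        ci_low = float(np.exp(beta - z * se))
        ci_high = float(np.exp(beta + z * se))
        p = float(2 * stats.norm.sf(abs(beta / se)))
    return OrdinalEffect(
        component=component,
        odds_ratio=orr,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        covariates=cov_names,
        n=int(len(y)),
        flagged=flagged,
    )


class ProportionalOddsModel(BaseEstimator):
    """sklearn-style estimator around the proportional-odds fit.

    ``fit(X, y)`` takes a DataFrame whose ``exposure_col`` is the binary
    exposure and whose remaining columns are categorical covariates, and
    an ordinal outcome ``y``.  Fitted attributes: ``odds_ratio_``,
    ``conf_int_``, ``p_value_``, ``effect_``.
    """

    def __init__(self, exposure_col: str = "exposure",
                 alpha: float = ALPHA_DEFAULT):
        self.exposure_col = exposure_col
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y) -> "ProportionalOddsModel":
        if self.exposure_col not in X.columns:
            raise AnalysisError(
                f"exposure column {self.exposure_col!r} missing"
            )
        cov = X.drop(columns=[self.exposure_col])
        eff = fit_proportional_odds(
            y, X[self.exposure_col],
            covariates=cov if cov.shape[1] else None,
            alpha=self.alpha,
        )
        self.effect_ = eff
        self.odds_ratio_ = eff.odds_ratio
        self.conf_int_ = (eff.ci_low, eff.ci_high)
        self.p_value_ = eff.p_value
        self.n_features_in_ = X.shape[1]
        return self


@dataclass
class AnalysisResult:
    """Bundle of all analysis outputs for one cohort."""

    screening: ScreeningResult | None
    oneway: OneWayAnovaResult
    adjusted_contrasts: list[ContrastResult]
    ordinal_effects: list[OrdinalEffect]
    covariates: list[str]
    n_input: int
    n_analyzed: int
    n_excluded_missing: int
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "screening": self.screening.to_dict() if self.screening else None,
            "oneway": self.oneway.to_dict(),
            "adjusted_contrasts": [c.to_dict() for c in self.adjusted_contrasts],
            "ordinal_effects": [e.to_dict() for e in self.ordinal_effects],
            "covariates": self.covariates,
            "n_input": self.n_input,
            "n_analyzed": self.n_analyzed,
            "n_excluded_missing": self.n_excluded_missing,
            "notes": self.notes,
        }

    def forest_table(self) -> pd.DataFrame:
        """Per-component OR table in forest-plot order."""
        return pd.DataFrame([e.to_dict() for e in self.ordinal_effects])


def run_full_analysis(
    cohort: pd.DataFrame,
    component_cols: Sequence[str] | None = None,
    candidate_confounders: Sequence[str] | None = None,
    fi: str = "fi",
    outcome: str = "mhfii_total",
    reference: str = "food_secure",
    severe: str = "severe",
    alpha: float = ALPHA_DEFAULT,
    screen: bool = True,
) -> AnalysisResult:
    """Full pipeline: screen -> one-way -> adjusted -> 11 ordinal models.

    ``candidate_confounders`` defaults to every recognised
    sociodemographic column present in the cohort; ``component_cols``
    defaults to the default scoring table's component names present as
    columns.  Participants with missing outcome or FI are excluded
    listwise (the per-analysis n is reported on each result).
    """
    from .mhfii import load_default_scoring_table

    if component_cols is None:
        names = load_default_scoring_table().component_names
        component_cols = [c for c in names if c in cohort.columns]
    if candidate_confounders is None:
        known = [
            "age_group", "sex", "education", "marital_status",
            "household_size", "children", "housing", "municipality",
            "employment", "income",
        ]
        candidate_confounders = [c for c in known if c in cohort.columns]

    n_input = len(cohort)
    core = cohort.dropna(subset=[outcome, fi])
    n_analyzed = len(core)

    screening = None
    if screen and candidate_confounders:
        screening = screen_confounders(
            core, candidate_confounders, fi=fi, outcome=outcome,
            severe=severe, reference=reference, alpha=alpha,
        )
        covariates = screening.selected
    else:
        covariates = list(candidate_confounders)

    oneway = anova_oneway(
        core[outcome], core[fi], reference=reference, alpha=alpha
    )
    adjusted = anova_adjusted(
        core, outcome, fi, covariates, reference=reference, alpha=alpha
    )

    two = core[core[fi].isin([severe, reference])]
    exposure = (two[fi] == severe).astype(int)
    effects = []
    for comp in component_cols:
        sub_keep = two[comp].notna()
        effects.append(
            fit_proportional_odds(
                two.loc[sub_keep, comp],
                exposure[sub_keep],
                covariates=two.loc[sub_keep, covariates] if covariates else None,
                component=comp,
                alpha=alpha,
            )
        )
    return AnalysisResult(
        screening=screening,
        oneway=oneway,
        adjusted_contrasts=adjusted,
        ordinal_effects=effects,
        covariates=list(covariates),
        n_input=n_input,
        n_analyzed=n_analyzed,
        n_excluded_missing=n_input - n_analyzed,
    )
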