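"""Case-control association testing and collinearity diagnostics.

Implements the analysis battery of a small incident-disease SNP study:

* univariate allelic test — Pearson 1-df chi-square on the 2x2 allele-count
  table with a Woolf (log-OR) 95% confidence interval;
* covariate-adjusted additive logistic regression, one SNP at a time;
* the joint multivariate model with all SNPs and covariates;
* tolerance / variance-inflation-factor collinearity checks;
* a fixed Bonferroni family threshold over the number of SNPs tested;
* baseline case/control comparisons (Welch t, chi-square for sex).

Genotypes must be oriented to the risk allele (A1) before testing; odds
ratios are then per copy of A1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .params import CLINICAL_COVARIATES


class DegenerateTableError(ValueError):
    """A 2x2 allele table contains an empty cell, so OR/CI are undefined.

    No continuity correction is applied silently; callers wanting the
    0.5-cell convention must add it themselves.
    """


class ModelFitError(RuntimeError):
    """Logistic fit failed (perfect separation, constant genotype, ...)."""


@dataclass(frozen=True)
class Allelic2x2:
    """Allele-count contingency table (2 alleles per genotyped subject)."""

    case_risk_alleles: int
    case_other_alleles: int
    control_risk_alleles: int
    control_other_alleles: int

    def __post_init__(self):
        if min(self.case_risk_alleles, self.case_other_alleles,
               self.control_risk_alleles, self.control_other_alleles) < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def case_freq(self) -> float:
        return self.case_risk_alleles / (self.case_risk_alleles + self.case_other_alleles)

    @property
    def control_freq(self) -> float:
        return self.control_risk_alleles / (self.control_risk_alleles + self.control_other_alleles)

    def as_array(self) -> np.ndarray:
        return np.array([[self.case_risk_alleles, self.case_other_alleles],
                         [self.control_risk_alleles, self.control_other_alleles]], dtype=float)


@dataclass(frozen=True)
class AssociationResult:
    """One term of one fitted model: log-odds, SE, OR with 95% CI, p."""

    snp_id: str
    model: str  # allelic | additive_adjusted | joint_multivariate
    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class VIFResult:
    variable: str
    tolerance: float
    vif: float


def _clean_genotypes(g) -> np.ndarray:
    """Validate codes, drop missing, return int genotypes."""
    arr = np.asarray(g, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size and not np.isin(arr, (0.0, 1.0, 2.0)).all():
        bad = sorted(set(arr[~np.isin(arr, (0.0, 1.0, 2.0))]))
        raise ValueError(f"invalid genotype codes {bad}; expected 0/1/2 or missing")
    return arr.astype(np.int64)


def allele_count_table(case_genotypes, control_genotypes) -> Allelic2x2:
    """Collapse additive genotypes into the 2x2 allele-count table.

    Missing genotypes (NaN) are excluded; each non-missing subject
    contributes two alleles.
    """
    case = _clean_genotypes(case_genotypes)
    ctrl = _clean_genotypes(control_genotypes)
    return Allelic2x2(
        case_risk_alleles=int(case.sum()),
        case_other_alleles=int(2 * case.size - case.sum()),
        control_risk_alleles=int(ctrl.sum()),
        control_other_alleles=int(2 * ctrl.size - ctrl.sum()),
    )


def allelic_test(table: Allelic2x2, snp_id: str = "") -> AssociationResult:
    """Univariate allelic association test on a 2x2 allele table.

    OR is the cross-product ratio; the 95% CI uses Woolf's log-OR variance
    1/a + 1/b + 1/c + 1/d; the p-value is the Pearson 1-df chi-square
    without continuity correction (the GWAS-toolkit convention).
    """
    a, b = table.case_risk_alleles, table.case_other_alleles
    c, d = table.control_risk_alleles, table.control_other_alleles
    if min(a, b, c, d) == 0:
        raise DegenerateTableError(f"zero cell in allele table ({a}, {b}, {c}, {d})")
    beta = float(np.log((a / b) / (c / d)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    chi2, p, _, _ = stats.chi2_contingency(table.as_array(), correction=False)
    return AssociationResult(
        snp_id=snp_id, model="allelic", beta=beta, se=se,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p_value=float(p),
    )


def or_from_freqs(p_case: float, p_control: float) -> float:
    """Allelic odds ratio implied by case/control risk-allele frequencies."""
    for name, p in (("p_case", p_case), ("p_control", p_control)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name}={p} must lie strictly inside (0, 1)")
    return (p_case * (1.0 - p_control)) / (p_control * (1.0 - p_case))


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    try:
        model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
        res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises several flavours here
        raise ModelFitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ModelFitError("logistic fit did not converge (possible separation)")
    return res

_Z95 = 1.959963984540054


def _term_result(res, term: str, snp_id: str, model: str) -> AssociationResult:
    beta = float(res.params[term])
    se = float(res.bse[term])
    return AssociationResult(
        snp_id=snp_id, model=model, beta=beta, se=se,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z95 * se)),
        ci_high=float(np.exp(beta + _Z95 * se)),
        p_value=float(res.pvalues[term]),
    )


def _complete_cases(cohort: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    sub = cohort[["status"] + columns]
    return sub.dropna()


def additive_logistic(cohort: pd.DataFrame, snp_id: str,
                      covariates: list[str] | None = None) -> AssociationResult:
    """Covariate-adjusted additive-model logistic regression for one SNP.

    Fits status ~ dosage + covariates on complete cases and returns the SNP
    term (Wald SE/CI/p).  ``covariates`` defaults to the seven clinical
    variables.
    """
    covs = list(CLINICAL_COVARIATES) if covariates is None else list(covariates)
    data = _complete_cases(cohort, [snp_id] + covs)
    y = data["status"].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ModelFitError("need at least one case and one control with complete data")
    if data[snp_id].nunique() < 2:
        raise ModelFitError(f"genotype at {snp_id} is constant in complete cases")
    res = _fit_logit(y, data[[snp_id] + covs])
    return _term_result(res, snp_id, snp_id, "additive_adjusted")


def joint_multivariate_model(cohort: pd.DataFrame, snp_ids: list[str],
                             covariates: list[str] | None = None,
                             ) -> tuple[list[AssociationResult], float]:
    """One logistic model with all SNPs and covariates entered jointly.

    Returns one :class:`AssociationResult` per term (covariates first, then
    SNPs, matching entry order) and the fitted constant.
    """
    covs = list(CLINICAL_COVARIATES) if covariates is None else list(covariates)
    terms = covs + list(snp_ids)
    data = _complete_cases(cohort, terms)
    y = data["status"].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ModelFitError("need at least one case and one control with complete data")
    res = _fit_logit(y, data[terms])
    model = "joint_multivariate"
    results = [_term_result(res, t, t if t in snp_ids else "", model) for t in terms]
    return results, float(res.params["const"])


def vif(cohort: pd.DataFrame, predictors: list[str]) -> list[VIFResult]:
    """Tolerance (1 - R^2) and VIF (1/tolerance) for each predictor.

    Each predictor is regressed by OLS on all the others (with intercept)
    over complete cases.  Exact linear dependence yields an infinite VIF
    rather than an exception.
    """
    data = cohort[predictors].dropna()
    if len(data) < len(predictors) + 2:
        raise ValueError("too few complete rows for collinearity diagnostics")
    out = []
    for var in predictors:
        others = [p for p in predictors if p != var]
        X = sm.add_constant(data[others], has_constant="add")
        r2 = float(sm.OLS(data[var].to_numpy(dtype=float), X).fit().rsquared)
        tol = max(0.0, 1.0 - r2)
        out.append(VIFResult(variable=var, tolerance=tol,
                             vif=(np.inf if tol < 1e-12 else 1.0 / tol)))
    return out


def bonferroni_threshold(family_alpha: float, m: int) -> float:
    """Per-test significance threshold controlling the family-wise error."""
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    if not 0.0 < family_alpha < 1.0:
        raise ValueError(f"family alpha {family_alpha} not in (0, 1)")
    return family_alpha / m


def baseline_comparison(cohort: pd.DataFrame) -> pd.DataFrame:
    """Case/control baseline table: mean +/- SD (or % female) and p-values.

    Continuous covariates use the Welch two-sample t-test; sex uses a
    Pearson chi-square on the 2x2 sex-by-status table.  Zero-variance
    variables get a missing p-value.
    """
    cases = cohort[cohort["status"] == 1]
    ctrls = cohort[cohort["status"] == 0]
    if len(cases) == 0 or len(ctrls) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    tab = pd.crosstab(cohort["sex"], cohort["status"])
    if tab.shape == (2, 2):
        _, p_sex, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    else:
        p_sex = np.nan
    rows.append({
        "variable": "sex",
        "case_summary": f"{100 * cases['sex'].mean():.0f}% female",
        "control_summary": f"{100 * ctrls['sex'].mean():.0f}% female",
        "p_value": float(p_sex) if np.isfinite(p_sex) else np.nan,
    })
    from .params import CONTINUOUS_COVARIATES
    for cov in CONTINUOUS_COVARIATES:
        x, z = cases[cov].dropna(), ctrls[cov].dropna()
        if x.std(ddof=1) == 0 and z.std(ddof=1) == 0:
            p = np.nan
        else:
            _, p = stats.ttest_ind(x, z, equal_var=False)
        rows.append({
            "variable": cov,
            "case_summary": f"{x.mean():.2f} ± {x.std(ddof=1):.2f}",
            "control_summary": f"{z.mean():.2f} ± {z.std(ddof=1):.2f}",
            "p_value": float(p) if np.isfinite(p) else np.nan,
        })
    return pd.DataFrame(rows)
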