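"""Analytic power of the case-control trend test for a genetic association.

The calculation follows the classic genetic-power-calculator recipe for a
discrete trait:

1.  From population prevalence K, a Hardy–Weinberg risk-allele frequency p,
    and genotypic odds ratios (het and hom vs. the reference genotype),
    solve the genotype penetrances f0 <= f1 <= f2 whose HWE-weighted mean
    is exactly K (1-d root finding on f0).
2.  Invert by Bayes' rule to the genotype distributions in cases,
    P(G|case) ∝ HWE(G)·f_G, and in screened (disease-free) controls,
    P(G|control) ∝ HWE(G)·(1−f_G).
3.  Evaluate the 1-df Cochran–Armitage trend statistic (scores 0, 1, 2) at
    the expected genotype counts for the design's n_cases/n_controls; that
    value is the noncentrality parameter, and power is the upper tail of
    the noncentral chi-square beyond the central critical value at alpha.

The additive ("log-additive") model uses or_hom = or_het**2, i.e.
multiplicative on the odds scale; a risk-additive alternative
(or_hom = 2·or_het − 1) is available via ``PowerSpec.from_additive``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2, ncx2

_SCORES = np.array([0.0, 1.0, 2.0])


class InfeasibleSpecError(ValueError):
    """No penetrance vector in (0,1) satisfies the prevalence constraint."""


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for a case-control genetic power computation."""

    n_cases: int
    n_controls: int
    risk_allele_freq: float
    or_het: float
    or_hom: float
    prevalence: float
    alpha: float
    screened_controls: bool = True

    def __post_init__(self):
        if not 0.0 < self.risk_allele_freq < 1.0:
            raise ValueError("risk_allele_freq must lie in (0, 1)")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.or_het <= 0 or self.or_hom <= 0:
            raise ValueError("odds ratios must be positive")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("sample sizes must be positive")

    @classmethod
    def from_additive(cls, n_cases, n_controls, risk_allele_freq, or_allele,
                      prevalence, alpha, model: str = "odds-multiplicative",
                      screened_controls: bool = True) -> "PowerSpec":
        """Spec for a per-allele effect under a named additive convention."""
        if model == "odds-multiplicative":
            or_hom = or_allele ** 2
        elif model == "risk-additive":
            or_hom = 2.0 * or_allele - 1.0
        else:
            raise ValueError(f"unknown additive model {model!r}")
        return cls(n_cases, n_controls, risk_allele_freq, or_allele, or_hom,
                   prevalence, alpha, screened_controls)


def hwe_genotype_freqs(p: float) -> np.ndarray:
    """Hardy–Weinberg genotype probabilities for risk-allele count 0, 1, 2."""
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])


def penetrances_from_ors(spec: PowerSpec) -> tuple[float, float, float]:
    """Solve (f0, f1, f2) matching the genotypic ORs and the prevalence.

    f1 and f2 are tied to f0 through odds(f_g) = OR_g · odds(f0); the HWE
    mean sum_g HWE(g)·f_g is strictly increasing in f0, so the prevalence
    constraint has a unique root in (0, 1).
    """
    g = hwe_genotype_freqs(spec.risk_allele_freq)

    def pen_vector(f0):
        odds0 = f0 / (1.0 - f0)
        f1 = spec.or_het * odds0 / (1.0 + spec.or_het * odds0)
        f2 = spec.or_hom * odds0 / (1.0 + spec.or_hom * odds0)
        return np.array([f0, f1, f2])

    def excess(f0):
        return float(g @ pen_vector(f0)) - spec.prevalence

    eps = 1e-15
    if excess(eps) > 0 or excess(1 - 1e-12) < 0:
        raise InfeasibleSpecError("no penetrance root in (0, 1) for this spec")
    f0 = brentq(excess, eps, 1 - 1e-12, xtol=1e-15)
    f = pen_vector(f0)
    return float(f[0]), float(f[1]), float(f[2])


def case_control_genotype_freqs(penetrances, risk_allele_freq: float,
                                screened_controls: bool = True,
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Genotype distributions among cases and controls by Bayes inversion."""
    f = np.asarray(penetrances, dtype=float)
    g = hwe_genotype_freqs(risk_allele_freq)
    case = g * f
    case = case / case.sum()
    if screened_controls:
        ctrl = g * (1.0 - f)
        ctrl = ctrl / ctrl.sum()
    else:
        ctrl = g.copy()
    return case, ctrl


def trend_statistic(case_counts, control_counts) -> float | np.ndarray:
    """Cochran–Armitage trend chi-square (scores 0,1,2) on 2x3 count tables.

    Accepts single tables (length-3 vectors) or stacked (n, 3) arrays for
    vectorized simulation.
    """
    r = np.atleast_2d(np.asarray(case_counts, dtype=float))
    s = np.atleast_2d(np.asarray(control_counts, dtype=float))
    N = r + s
    R = r.sum(axis=1)
    n = N.sum(axis=1)
    t1 = (_SCORES * r).sum(axis=1)
    tN = (_SCORES * N).sum(axis=1)
    num = (n * t1 - R * tN) ** 2
    den = R * (n - R) * (n * (_SCORES ** 2 * N).sum(axis=1) - tN ** 2) / n
    stat = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(stat[0]) if stat.size == 1 else stat


def trend_noncentrality(spec: PowerSpec) -> float:
    """NCP: the trend statistic evaluated at the expected genotype counts."""
    f = penetrances_from_ors(spec)
    pc, pu = case_control_genotype_freqs(f, spec.risk_allele_freq,
                                         spec.screened_controls)
    return float(trend_statistic(spec.n_cases * pc, spec.n_controls * pu))


def trend_test_power(spec: PowerSpec) -> float:
    """Power of the 1-df trend test at the spec's alpha."""
    ncp = trend_noncentrality(spec)
    crit = chi2.ppf(1.0 - spec.alpha, df=1)
    return float(1.0 - ncx2.cdf(crit, df=1, nc=ncp)) if ncp > 0 else spec.alpha


def empirical_trend_power(spec: PowerSpec, n_sims: int, seed) -> float:
    """Monte-Carlo power: simulate genotype tables and apply the trend test."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = penetrances_from_ors(spec)
    pc, pu = case_control_genotype_freqs(f, spec.risk_allele_freq,
                                         spec.screened_controls)
    cases = rng.multinomial(spec.n_cases, pc, size=n_sims)
    ctrls = rng.multinomial(spec.n_controls, pu, size=n_sims)
    stat = trend_statistic(cases, ctrls)
    crit = chi2.ppf(1.0 - spec.alpha, df=1)
    return float(np.mean(stat > crit))
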