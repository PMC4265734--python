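"""Synthetic cohort generation.

Two modes are provided:

* ``prospective`` — draw population covariates and Hardy–Weinberg genotypes,
  then sample incident disease status from the logistic incidence model.
  This is the mode for parameter-recovery experiments: the generating
  coefficients are the truth the association machinery should estimate.
* ``retrospective`` — fix the case/control split first and draw covariates
  and genotypes from the group-specific distributions, so the realized
  group summaries match the target marginals directly.

All randomness flows through :func:`numpy.random.default_rng` seeded by the
caller; identical ``(params, seed)`` give identical cohorts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .params import (
    CONTINUOUS_COVARIATES,
    COVARIATE_BOUNDS,
    CohortParams,
    ParameterError,
)

#: fixed column order of a cohort frame
COHORT_COLUMNS = ("pid", "status", "sex") + CONTINUOUS_COVARIATES


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def genotypes_hwe(n: int, freq: float, seed) -> np.ndarray:
    """Sample ``n`` additive genotypes at Hardy–Weinberg equilibrium.

    Each genotype is the sum of two independent Bernoulli(``freq``) allele
    draws, i.e. Binomial(2, freq), giving class probabilities
    (1-p)^2, 2p(1-p), p^2.
    """
    if not 0.0 <= freq <= 1.0:
        raise ParameterError(f"allele frequency {freq} outside [0, 1]")
    if n < 0:
        raise ParameterError(f"n must be >= 0, got {n}")
    rng = _as_rng(seed)
    return rng.binomial(2, freq, size=n).astype(np.int64)


def _truncated_normal(rng, mean, sd, low, high, n):
    """Normal(mean, sd) truncated to (low, high) by resampling (no point mass)."""
    out = rng.normal(mean, sd, size=n)
    lo = -np.inf if low is None else low
    hi = np.inf if high is None else high
    bad = (out <= lo) | (out >= hi)
    # With physical bounds many SDs from the mean this loop almost never runs.
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    return out


def generate_covariates(n: int, group: str, params: CohortParams, seed) -> pd.DataFrame:
    """Draw clinical covariates for ``n`` members of one disease group.

    Continuous covariates are independent truncated normals with the group's
    mean/SD; sex is Bernoulli(female_frac), coded female = 1.
    """
    if group not in ("case", "control"):
        raise ParameterError(f"unknown group {group!r}; expected 'case' or 'control'")
    rng = _as_rng(seed)
    means = getattr(params, f"covariate_means_{group}")
    sds = getattr(params, f"covariate_sds_{group}")
    female = getattr(params, f"female_frac_{group}")
    data = {"sex": (rng.random(n) < female).astype(np.int64)}
    for cov in CONTINUOUS_COVARIATES:
        low, high = COVARIATE_BOUNDS[cov]
        data[cov] = _truncated_normal(rng, means[cov], sds[cov], low, high, n)
    return pd.DataFrame(data)


def linear_predictor(frame: pd.DataFrame, params: CohortParams,
                     intercept: float | None = None) -> np.ndarray:
    """Evaluate intercept + sum_v beta_v * x_v row-wise over a cohort frame."""
    c = params.intercept if intercept is None else intercept
    eta = np.full(len(frame), float(c))
    for var, beta in params.logistic_betas.items():
        if var not in frame.columns:
            raise ParameterError(f"modelled variable {var!r} missing from frame")
        x = frame[var].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ParameterError(f"modelled variable {var!r} has missing values")
        eta += beta * x
    return eta


def case_probability(participant, params: CohortParams,
                     intercept: float | None = None):
    """Incidence probability under the logistic model.

    ``participant`` may be a mapping / :class:`pandas.Series` (one subject)
    or a :class:`pandas.DataFrame` (vectorized over rows).  Genotypes enter
    as risk-allele counts, covariates on their native units.
    """
    if isinstance(participant, pd.DataFrame):
        return expit(linear_predictor(participant, params, intercept))
    frame = pd.DataFrame([dict(participant)])
    return float(expit(linear_predictor(frame, params, intercept))[0])


def _population_sample(params: CohortParams, n: int, rng) -> pd.DataFrame:
    """Population draw for prospective mode: control-group covariate
    distributions (controls are ~97% of the cohort, the closest available
    proxy for the source population) and HWE genotypes at control frequencies."""
    frame = generate_covariates(n, "control", params, rng)
    for s in params.snp_info:
        frame[s.snp_id] = genotypes_hwe(n, s.control_freq, rng)
    return frame


def calibrate_intercept(params: CohortParams, target_incidence: float, seed,
                        n_draws: int = 200_000, tol: float = 1e-4) -> float:
    """Intercept for which mean incidence over a population sample hits target.

    The printed model constant was fitted on real data whose covariate joint
    distribution differs from the synthetic marginals, so the intercept must
    be recalibrated.  Mean probability is strictly increasing in the
    intercept, so bisection on a Monte-Carlo sample of ``n_draws`` subjects
    converges to the unique root.
    """
    if not 0.0 < target_incidence < 1.0:
        raise ParameterError(f"target incidence {target_incidence} not in (0, 1)")
    rng = _as_rng(seed)
    frame = _population_sample(params, n_draws, rng)
    eta = linear_predictor(frame, params, intercept=0.0)

    def mean_excess(c):
        return float(np.mean(expit(c + eta))) - target_incidence

    lo, hi = -60.0, 60.0
    return float(brentq(mean_excess, lo, hi, xtol=min(tol, 1e-6)))


def generate_cohort(params: CohortParams, seed, mode: str = "prospective",
                    intercept: float | None = None,
                    missing_rate: float = 0.0) -> pd.DataFrame:
    """Simulate a full cohort as a tidy DataFrame.

    Columns: pid, status (1 = incident case), sex (1 = female), the six
    continuous covariates, then one 0/1/2 genotype column per SNP
    (NaN where masked missing).
    """
    rng = _as_rng(seed)
    n = params.n_total
    if mode == "prospective":
        frame = _population_sample(params, n, rng)
        p = expit(linear_predictor(frame, params, intercept))
        frame.insert(0, "status", (rng.random(n) < p).astype(np.int64))
    elif mode == "retrospective":
        n_cases = params.n_cases
        if n_cases is None:
            if params.target_incidence is None:
                raise ParameterError("retrospective mode needs n_cases or target_incidence")
            n_cases = int(round(n * params.target_incidence))
        if not 0 < n_cases < n:
            raise ParameterError(f"n_cases={n_cases} incompatible with n_total={n}")
        parts = []
        for group, m, status in (("case", n_cases, 1), ("control", n - n_cases, 0)):
            g = generate_covariates(m, group, params, rng)
            for s in params.snp_info:
                g[s.snp_id] = genotypes_hwe(m, getattr(s, f"{group}_freq"), rng)
            g.insert(0, "status", np.full(m, status, dtype=np.int64))
            parts.append(g)
        frame = pd.concat(parts, ignore_index=True)
        frame = frame.iloc[rng.permutation(len(frame))].reset_index(drop=True)
    else:
        raise ParameterError(f"unknown mode {mode!r}")

    if missing_rate:
        if not 0.0 <= missing_rate < 1.0:
            raise ParameterError(f"missing_rate {missing_rate} not in [0, 1)")
        for s in params.snp_info:
            mask = rng.random(len(frame)) < missing_rate
            if mask.any():
                col = frame[s.snp_id].astype(float)
                col[mask] = np.nan
                frame[s.snp_id] = col

    frame.insert(0, "pid", [f"P{i:06d}" for i in range(1, len(frame) + 1)])
    ordered = list(COHORT_COLUMNS) + params.snp_ids
    return frame[ordered]
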