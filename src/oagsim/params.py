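"""Parameter containers for the synthetic incident-glaucoma cohort.

The default parameter set (``default_params``) describes a population-based
longitudinal cohort of 1986 older adults with 67 incident open-angle glaucoma
(OAG) cases, seven risk SNPs at five loci, group-specific baseline covariate
distributions, and a joint logistic incidence model.  It is shipped as a YAML
file so that alternative scenarios can be described without touching code.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

#: canonical order of the continuous clinical covariates
CONTINUOUS_COVARIATES = ("age", "iop", "vcdr", "dd", "sbp", "dbp")

#: all clinical covariates entering models (sex is binary, female = 1)
CLINICAL_COVARIATES = ("sex",) + CONTINUOUS_COVARIATES

#: lower/upper physical bounds used when truncating covariate normals
COVARIATE_BOUNDS = {
    "age": (0.0, None),
    "iop": (0.0, None),
    "vcdr": (0.0, 1.0),
    "dd": (0.0, None),
    "sbp": (0.0, None),
    "dbp": (0.0, None),
}


class ParameterError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass(frozen=True)
class SNPInfo:
    """Identity and group-specific risk-allele frequency of one SNP.

    ``risk_allele`` (A1) is the allele reported to increase OAG risk;
    genotypes everywhere in this package count copies of A1 (0/1/2).
    """

    snp_id: str
    chromosome: str
    position_bp: int
    risk_allele: str
    other_allele: str
    locus_label: str
    case_freq: float
    control_freq: float

    def __post_init__(self) -> None:
        for name in ("case_freq", "control_freq"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ParameterError(f"{self.snp_id}: {name}={f} outside [0, 1]")
        if self.risk_allele == self.other_allele:
            raise ParameterError(f"{self.snp_id}: risk and other allele identical")


@dataclass
class CohortParams:
    """Everything needed to simulate a cohort.

    Covariate means/SDs are per realized disease group; ``logistic_betas``
    holds the per-unit (per-risk-allele for SNPs) log-odds coefficients of
    the incidence model and ``intercept`` its constant.  ``target_incidence``
    is the marginal case fraction the intercept should be calibrated to in
    prospective simulation.
    """

    n_total: int
    covariate_means_case: dict[str, float]
    covariate_means_control: dict[str, float]
    covariate_sds_case: dict[str, float]
    covariate_sds_control: dict[str, float]
    female_frac_case: float
    female_frac_control: float
    snp_info: list[SNPInfo]
    logistic_betas: dict[str, float]
    intercept: float
    target_incidence: float | None = None
    n_cases: int | None = None

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ParameterError(f"n_total must be positive, got {self.n_total}")
        for group in ("case", "control"):
            sds = getattr(self, f"covariate_sds_{group}")
            means = getattr(self, f"covariate_means_{group}")
            for cov in CONTINUOUS_COVARIATES:
                if cov not in means or cov not in sds:
                    raise ParameterError(f"missing {group} mean/sd for covariate {cov!r}")
                if sds[cov] <= 0:
                    raise ParameterError(f"{group} SD for {cov!r} must be > 0, got {sds[cov]}")
        known = set(CLINICAL_COVARIATES) | {s.snp_id for s in self.snp_info}
        unknown = set(self.logistic_betas) - known
        if unknown:
            raise ParameterError(f"logistic_betas refer to unknown variables: {sorted(unknown)}")

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snp_info]

    def snp(self, snp_id: str) -> SNPInfo:
        for s in self.snp_info:
            if s.snp_id == snp_id:
                return s
        raise KeyError(snp_id)

    def replace(self, **changes) -> "CohortParams":
        return dataclasses.replace(self, **changes)


def _group_block(block: dict) -> tuple[dict, dict, float]:
    means = {c: float(block[c]["mean"]) for c in CONTINUOUS_COVARIATES}
    sds = {c: float(block[c]["sd"]) for c in CONTINUOUS_COVARIATES}
    return means, sds, float(block["female_frac"])


def params_from_dict(cfg: dict) -> CohortParams:
    """Build :class:`CohortParams` from a parsed parameter mapping."""
    case_m, case_s, case_f = _group_block(cfg["covariates"]["case"])
    ctrl_m, ctrl_s, ctrl_f = _group_block(cfg["covariates"]["control"])
    snps = [SNPInfo(**{**d, "chromosome": str(d["chromosome"])}) for d in cfg["snps"]]
    cohort = cfg["cohort"]
    return CohortParams(
        n_total=int(cohort["n_total"]),
        covariate_means_case=case_m,
        covariate_means_control=ctrl_m,
        covariate_sds_case=case_s,
        covariate_sds_control=ctrl_s,
        female_frac_case=case_f,
        female_frac_control=ctrl_f,
        snp_info=snps,
        logistic_betas={k: float(v) for k, v in cfg["model"]["betas"].items()},
        intercept=float(cfg["model"]["intercept"]),
        target_incidence=(float(cohort["target_incidence"])
                          if cohort.get("target_incidence") is not None else None),
        n_cases=int(cohort["n_cases"]) if cohort.get("n_cases") is not None else None,
    )


def load_params(path: str | Path) -> CohortParams:
    """Load cohort parameters from a YAML file."""
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh))


def default_params() -> CohortParams:
    """The shipped default scenario (1986 participants, 7 SNPs, 5 loci)."""
    text = resources.files("oagsim.data").joinpath("default_params.yaml").read_text()
    return params_from_dict(yaml.safe_load(text))
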