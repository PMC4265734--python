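# Default synthetic-cohort parameters: a population-based longitudinal study of
# incident open-angle glaucoma in older Australians (67 incident cases / 1919
# controls over 10 years of follow-up), with seven previously reported OAG risk
# SNPs and the baseline clinical covariates used for adjustment.
cohort:
  n_total: 1986
  n_cases: 67
  target_incidence: 0.033736152064452165   # 67 / 1986

covariates:
  # mean / sd by realized disease status; units: age years, iop mm Hg,
  # vcdr proportion, dd mm, sbp/dbp mm Hg
  case:
    female_frac: 0.73
    age:  {mean: 68.9,  sd: 7.9}
    iop:  {mean: 17.6,  sd: 2.8}
    vcdr: {mean: 0.53,  sd: 0.11}
    dd:   {mean: 1.52,  sd: 0.18}
    sbp:  {mean: 151.6, sd: 21.2}
    dbp:  {mean: 85.7,  sd: 9.5}
  control:
    female_frac: 0.57
    age:  {mean: 63.8,  sd: 8.3}
    iop:  {mean: 15.9,  sd: 2.6}
    vcdr: {mean: 0.42,  sd: 0.12}
    dd:   {mean: 1.51,  sd: 0.17}
    sbp:  {mean: 144.0, sd: 20.4}
    dbp:  {mean: 83.4,  sd: 9.6}

snps:
  # risk_allele (A1) / other_allele (A2); genotype = count of A1.
  # case_freq / control_freq are risk-allele frequencies by realized status.
  # Positions are hg18, 1-based.
  - {snp_id: rs4656461,  chromosome: "1",  position_bp: 163953829, risk_allele: G,
     other_allele: A, locus_label: TMCO1,     case_freq: 0.187, control_freq: 0.116}
  - {snp_id: rs4236601,  chromosome: "7",  position_bp: 115949965, risk_allele: A,
     other_allele: G, locus_label: CAV1/CAV2, case_freq: 0.313, control_freq: 0.268}
  - {snp_id: rs1521774,  chromosome: "8",  position_bp: 106048166, risk_allele: G,
     other_allele: A, locus_label: 8q22,      case_freq: 0.366, control_freq: 0.324}
  - {snp_id: rs1063192,  chromosome: "9",  position_bp: 21993367,  risk_allele: A,
     other_allele: G, locus_label: 9p21,      case_freq: 0.642, control_freq: 0.549}
  - {snp_id: rs1412829,  chromosome: "9",  position_bp: 22033926,  risk_allele: A,
     other_allele: G, locus_label: 9p21,      case_freq: 0.687, control_freq: 0.568}
  - {snp_id: rs4977756,  chromosome: "9",  position_bp: 22058652,  risk_allele: A,
     other_allele: G, locus_label: 9p21,      case_freq: 0.687, control_freq: 0.591}
  - {snp_id: rs10483727, chromosome: "14", position_bp: 60142628,  risk_allele: A,
     other_allele: G, locus_label: SIX1/SIX6, case_freq: 0.508, control_freq: 0.384}

model:
  # Maximum-likelihood log-odds coefficients of the joint incidence model
  # (per unit of the covariate as given above; per risk allele for SNPs).
  # sex is coded female = 1.
  betas:
    sex: 0.930
    age: 0.064
    iop: 0.217
    vcdr: 0.827
    dd: -1.803
    sbp: -0.005
    dbp: 0.021
    rs4656461: 0.608
    rs1412829: 0.439
    rs10483727: 0.525
  intercept: -16.221
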