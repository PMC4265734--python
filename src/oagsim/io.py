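"""Cohort readers/writers: native TSV dialect and PLINK-style ``.raw`` export.

The native dialect is one row per participant with a fixed header::

    pid  status  sex  age  iop  vcdr  dd  sbp  dbp  <snp_id>...

``status`` is ``case``/``control``, ``sex`` is ``female``/``male``, genotype
columns hold risk-allele counts 0/1/2 with ``NA`` for missing.  The
PLINK-style additive dialect (``FID IID PAT MAT SEX PHENOTYPE`` then one
``<snp_id>_<A1>`` dosage column per SNP) carries genotypes, sex and status
only; it exists for interoperability with standard GWAS tooling.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS

_FIXED = list(COHORT_COLUMNS)  # pid, status, sex, age, iop, vcdr, dd, sbp, dbp


class CohortFormatError(ValueError):
    """Malformed cohort file (header, codes, duplicates)."""


def write_cohort(cohort: pd.DataFrame, path: str | Path,
                 dialect: str = "tsv",
                 snp_alleles: dict[str, str] | None = None) -> None:
    """Write a cohort frame in the named dialect.

    ``snp_alleles`` (snp_id -> counted allele) is only used to build the
    ``<snp>_<A1>`` headers of the plink_raw dialect; it defaults to ``A``.
    """
    snp_cols = [c for c in cohort.columns if c not in _FIXED]
    if dialect == "tsv":
        out = cohort.copy()
        out["status"] = np.where(out["status"].astype(int) == 1, "case", "control")
        out["sex"] = np.where(out["sex"].astype(int) == 1, "female", "male")
        for c in snp_cols:
            out[c] = cohort[c].map(
                lambda v: "NA" if pd.isna(v) else str(int(v)))
        out.to_csv(path, sep="\t", index=False, na_rep="NA")
    elif dialect == "plink_raw":
        alleles = snp_alleles or {}
        out = pd.DataFrame({
            "FID": cohort["pid"], "IID": cohort["pid"],
            "PAT": 0, "MAT": 0,
            "SEX": np.where(cohort["sex"].astype(int) == 1, 2, 1),
            "PHENOTYPE": cohort["status"].astype(int) + 1,
        })
        for c in snp_cols:
            out[f"{c}_{alleles.get(c, 'A')}"] = cohort[c].map(
                lambda v: "NA" if pd.isna(v) else str(int(v)))
        out.to_csv(path, sep=" ", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _validate_genotypes(frame: pd.DataFrame, snp_cols: list[str],
                        raw: pd.DataFrame) -> None:
    for col in snp_cols:
        vals = frame[col]
        bad = vals.notna() & ~vals.isin([0.0, 1.0, 2.0])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortFormatError(
                f"invalid genotype {raw[col].iloc[row]!r} at row {row + 2}, "
                f"column {col!r} (expected 0/1/2 or NA)")


def read_cohort(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a cohort file back into the canonical numeric frame."""
    if dialect == "tsv":
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if list(raw.columns[: len(_FIXED)]) != _FIXED:
            raise CohortFormatError(
                f"header must begin with {_FIXED}, got {list(raw.columns[:len(_FIXED)])}")
        snp_cols = [c for c in raw.columns if c not in _FIXED]
        frame = pd.DataFrame({"pid": raw["pid"]})
        bad_status = ~raw["status"].isin(["case", "control"])
        if bad_status.any():
            raise CohortFormatError(
                f"invalid status value {raw['status'][bad_status].iloc[0]!r}")
        frame["status"] = (raw["status"] == "case").astype(np.int64)
        bad_sex = ~raw["sex"].isin(["female", "male"])
        if bad_sex.any():
            raise CohortFormatError(f"invalid sex value {raw['sex'][bad_sex].iloc[0]!r}")
        frame["sex"] = (raw["sex"] == "female").astype(np.int64)
        for c in _FIXED[3:]:
            frame[c] = pd.to_numeric(raw[c])
        for c in snp_cols:
            frame[c] = pd.to_numeric(raw[c].replace({"NA": None, "": None}),
                                     errors="coerce")
        _validate_genotypes(frame, snp_cols, raw)
    elif dialect == "plink_raw":
        raw = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
        expected = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if list(raw.columns[:6]) != expected:
            raise CohortFormatError(f"plink_raw header must begin with {expected}")
        dosage_cols = list(raw.columns[6:])
        frame = pd.DataFrame({"pid": raw["IID"]})
        frame["status"] = pd.to_numeric(raw["PHENOTYPE"]).astype(np.int64) - 1
        frame["sex"] = (pd.to_numeric(raw["SEX"]) == 2).astype(np.int64)
        for c in _FIXED[3:]:
            frame[c] = np.nan  # covariates are not carried by .raw
        for col in dosage_cols:
            snp = col.rsplit("_", 1)[0]
            vals = pd.to_numeric(raw[col].replace({"NA": None, "": None}),
                                 errors="coerce")
            rounded = vals.round()
            off = vals.notna() & ((vals - rounded).abs() > 1e-6)
            if off.any():
                row = int(np.flatnonzero(off.to_numpy())[0])
                raise CohortFormatError(
                    f"non-integer dosage {raw[col].iloc[row]!r} at row {row + 2}, "
                    f"column {col!r}")
            frame[snp] = rounded
        snp_cols = [c.rsplit("_", 1)[0] for c in dosage_cols]
        _validate_genotypes(frame, snp_cols, raw.rename(
            columns=dict(zip(dosage_cols, snp_cols))))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if frame["pid"].duplicated().any():
        dup = frame["pid"][frame["pid"].duplicated()].iloc[0]
        raise CohortFormatError(f"duplicated pid {dup!r}")
    for c in snp_cols:  # fully observed genotype columns round-trip as ints
        if not frame[c].isna().any():
            frame[c] = frame[c].astype(np.int64)
    return frame
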