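"""File formats, survey-style data cleaning and configuration.

All artifacts are plain delimited text.  Conventions: sex in {M, F}, BMI
class in {NW, OW, OB1, OB2, OB3}, diabetes in {0, 1}.  Raw survey rows may
carry weight (kg) and height (m) instead of a BMI class; BMI = weight/height^2
is classified by the standard cut-points 25/30/35/40 (lower bound inclusive).
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import PARAM_NAMES, ParameterSet
from .states import BMI_CLASSES

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ["person_id", "sex", "birth_year", "survey_year", "bmi_class", "diabetes"]

_BMI_CUTS = (25.0, 30.0, 35.0, 40.0)


def classify_bmi(bmi: float) -> str:
    """BMI category with lower-inclusive cut-points 25/30/35/40 kg/m2."""
    for cut, label in zip(_BMI_CUTS, BMI_CLASSES[:-1]):
        if bmi < cut:
            return label
    return BMI_CLASSES[-1]


@dataclass
class CleaningAudit:
    """Counts emitted by :func:`clean_records`."""

    n_input: int = 0
    n_missing_dropped: int = 0
    n_reclassified: int = 0
    n_malformed: int = 0
    n_output: int = 0

    def as_dict(self) -> dict[str, int]:
        return self.__dict__.copy()


def clean_records(raw: pd.DataFrame) -> tuple[pd.DataFrame, CleaningAudit, pd.DataFrame]:
    """Apply the survey cleaning rules to raw records.

    * rows whose BMI (class or weight+height) or diabetes indicator is
      missing are dropped and counted;
    * respondents under 40 with normal weight who declare diabetes are
      treated as type 1 / genetic cases: reclassified to non-diabetic
      normal weight and counted;
    * malformed rows (unparseable years, unknown codes) go to a rejects
      table, never silently dropped.

    Returns ``(clean, audit, rejects)``; audit counts are also logged.
    """
    audit = CleaningAudit(n_input=len(raw))
    df = raw.copy()
    rejects_mask = pd.Series(False, index=df.index)
    reasons = pd.Series("", index=df.index)

    for col in ("birth_year", "survey_year"):
        if col not in df.columns:
            raise ValueError(f"raw data lacks required column {col!r}")
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna()
        rejects_mask |= bad
        reasons[bad & (reasons == "")] = f"unparseable {col}"
        df[col] = parsed

    sex = df.get("sex", pd.Series(np.nan, index=df.index)).astype(str).str.upper()
    bad_sex = ~sex.isin(["M", "F"])
    rejects_mask |= bad_sex
    reasons[bad_sex & (reasons == "")] = "unknown sex code"
    df["sex"] = sex

    # resolve BMI class, from weight/height when necessary
    if "bmi_class" in df.columns:
        bmi_class = df["bmi_class"].astype("string").str.upper()
        bmi_class[~bmi_class.isin(BMI_CLASSES)] = pd.NA
    else:
        bmi_class = pd.Series(pd.NA, index=df.index, dtype="string")
    if {"weight", "height"} <= set(df.columns):
        w = pd.to_numeric(df["weight"], errors="coerce")
        h = pd.to_numeric(df["height"], errors="coerce")
        with np.errstate(divide="ignore", invalid="ignore"):
            bmi = w / h**2
        computable = bmi_class.isna() & bmi.notna() & (h > 0)
        bmi_class.loc[computable] = bmi[computable].map(classify_bmi)
    df["bmi_class"] = bmi_class

    dm = pd.to_numeric(df.get("diabetes", np.nan), errors="coerce")
    df["diabetes"] = dm

    missing = (df["bmi_class"].isna() | df["diabetes"].isna()) & ~rejects_mask
    audit.n_missing_dropped = int(missing.sum())
    audit.n_malformed = int(rejects_mask.sum())

    rejects = raw.loc[rejects_mask].copy()
    rejects["reject_reason"] = reasons[rejects_mask]

    clean = df.loc[~rejects_mask & ~missing].copy()
    clean["diabetes"] = clean["diabetes"].astype(int).clip(0, 1)
    clean["birth_year"] = clean["birth_year"].astype(int)
    clean["survey_year"] = clean["survey_year"].astype(int)

    age = clean["survey_year"] - clean["birth_year"]
    reclass = (clean["bmi_class"] == "NW") & (clean["diabetes"] == 1) & (age < 40)
    audit.n_reclassified = int(reclass.sum())
    clean.loc[reclass, "diabetes"] = 0

    if "person_id" not in clean.columns:
        clean["person_id"] = np.arange(len(clean))
    clean = clean[PANEL_COLUMNS].reset_index(drop=True)
    clean["bmi_class"] = clean["bmi_class"].astype(str)
    audit.n_output = len(clean)

    logger.info(
        "cleaning: %d in, %d malformed, %d missing dropped, %d under-40 NW "
        "diabetics reclassified, %d out",
        audit.n_input, audit.n_malformed, audit.n_missing_dropped,
        audit.n_reclassified, audit.n_output,
    )
    return clean, audit, rejects


# ---------------------------------------------------------------------------
# artifact readers / writers


def provenance_header(seed: int | None, config_digest: str | None = None) -> str:
    from . import __version__

    parts = [f"obediab={__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_digest is not None:
        parts.append(f"config_sha256={config_digest}")
    return "# " + " ".join(parts)


def config_digest(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_csv(df: pd.DataFrame, path: str | Path, seed: int | None = None,
              digest: str | None = None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    buf.write(provenance_header(seed, digest) + "\n")
    df.to_csv(buf, index=index)
    path.write_text(buf.getvalue())


def read_csv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=index_col)


def read_panel(path: str | Path) -> pd.DataFrame:
    df = read_csv(path)
    missing = set(PANEL_COLUMNS) - {"person_id"} - set(df.columns)
    if missing:
        raise ValueError(f"panel file {path} missing columns {sorted(missing)}")
    return df


def write_parameter_table(table: pd.DataFrame, path: str | Path,
                          seed: int | None = None, digest: str | None = None) -> None:
    """Parameter table (estimate, ci_low, ci_high per row), natural scale."""
    out = table.copy()
    out.index.name = "parameter"
    write_csv(out, path, seed=seed, digest=digest, index=True)


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    return read_csv(path, index_col="parameter")


def params_from_table(table: pd.DataFrame) -> ParameterSet:
    vec = np.log(table.loc[list(PARAM_NAMES), "estimate"].to_numpy(dtype=float))
    return ParameterSet.unpack(vec)


def params_to_table(params: ParameterSet) -> pd.DataFrame:
    est = np.exp(params.pack())
    return pd.DataFrame({"estimate": est}, index=list(PARAM_NAMES))


def read_lifetable(path: str | Path) -> pd.DataFrame:
    df = read_csv(path)
    missing = {"age", "year", "sex", "qx"} - set(df.columns)
    if missing:
        raise ValueError(f"life table {path} missing columns {sorted(missing)}")
    if ((df["qx"] < 0) | (df["qx"] > 1)).any():
        raise ValueError("life-table qx outside [0, 1]")
    return df


def read_cohort_sizes(path: str | Path) -> pd.DataFrame:
    df = read_csv(path)
    missing = {"year", "sex", "size"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort-size table {path} missing columns {sorted(missing)}")
    return df


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration {path} must be a mapping")
    return cfg
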