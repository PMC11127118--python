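"""Discharge records, inclusion filters and parameter extraction.

This module turns raw wide-format inpatient discharge tables (one row per
hospitalization, with up to ``n_dx`` diagnosis-code slots) into the
analysis-ready cohort the derivation and calibration modules consume:

* :func:`age_band` — the 18 five-year age bands of the instrument;
* :func:`extract_parameters` — resolve a record's diagnosis codes to the
  ten RAI parameter levels;
* :func:`ascertain_mortality` — the composite in-hospital mortality label
  (discharge disposition ``died`` OR a comfort-care transition code Z51.5);
* :func:`build_cohort` — inclusion filters (adults, operative procedures,
  complete cases) with a full exclusion ledger and missingness report.

Functions come in scalar (single record) and vectorized (DataFrame) forms;
the DataFrame path is the one used by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .codemap import ParameterCodeMap, lookup_parameters, normalize_code
from .errors import EmptyCohortError, InvalidCodeError, RaicdError

__all__ = [
    "AGE_BANDS",
    "BAND_MIDPOINTS",
    "FUNCTIONAL_LEVELS",
    "DEFICITS",
    "DischargeRecord",
    "ParameterVector",
    "MortalityLabel",
    "ExclusionLedger",
    "CsvDialect",
    "age_band",
    "age_band_index",
    "band_midpoint",
    "extract_parameters",
    "extract_parameters_frame",
    "ascertain_mortality",
    "ascertain_mortality_frame",
    "build_cohort",
    "read_discharge_csv",
    "write_discharge_csv",
]

#: The instrument's 18 age bands, youngest first.
AGE_BANDS = (
    "<=19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49", "50-54",
    "55-59", "60-64", "65-69", "70-74", "75-79", "80-84", "85-89", "90-94",
    "95-99", ">=100",
)

#: Representative age for each band: 18 for the open lower band, the band
#: midpoint for interior bands, 100 for the open upper band.  Used when a
#: continuous-age fit is tabulated into band points.
BAND_MIDPOINTS = (18, 22, 27, 32, 37, 42, 47, 52, 57, 62, 67, 72, 77, 82, 87, 92, 97, 100)

FUNCTIONAL_LEVELS = ("independent", "partially_dependent", "totally_dependent")

#: The five additive deficit parameters (cancer and the interaction grids
#: are handled separately).
DEFICITS = (
    "weight_loss",
    "poor_appetite",
    "kidney_failure",
    "congestive_heart_failure",
    "shortness_of_breath",
)

#: Which cancer severity tiers count as "cancer present" under each named
#: cancer-parameter definition.  The instrument's final definition is the
#: severe categorization.
CANCER_DEFINITIONS: dict[str, frozenset[str]] = {
    "severe": frozenset({"severe"}),
    "severe+moderate": frozenset({"severe", "moderate"}),
    "all": frozenset({"severe", "moderate", "mild"}),
}

_COMFORT_CARE_CODE = "Z515"


# -- age bands -------------------------------------------------------------

def age_band_index(age: int) -> int:
    """Index into :data:`AGE_BANDS` for an integer age in years."""
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    if age <= 19:
        return 0
    return min((int(age) - 20) // 5 + 1, len(AGE_BANDS) - 1)


def age_band(age: int) -> str:
    """Map an age in years to its band label (``"<=19"`` … ``">=100"``)."""
    return AGE_BANDS[age_band_index(age)]


def band_midpoint(band: str) -> int:
    return BAND_MIDPOINTS[AGE_BANDS.index(band)]


def _age_band_index_array(ages: np.ndarray) -> np.ndarray:
    ages = np.asarray(ages)
    if (ages < 0).any():
        raise ValueError("ages must be non-negative")
    idx = np.clip((ages - 20) // 5 + 1, 0, len(AGE_BANDS) - 1)
    return np.where(ages <= 19, 0, idx).astype(int)


# -- record-level types ----------------------------------------------------

@dataclass
class DischargeRecord:
    """One hospitalization, as read from a discharge table."""

    record_id: str
    age: int
    sex: Literal["male", "female", "missing"]
    dx_codes: tuple[str, ...] = ()
    disposition: Literal["routine", "transfer", "died", "other", "missing"] = "routine"
    survey_weight: float = 1.0
    cluster_id: str | None = None
    operative: bool = False
    elective: bool | None = None
    length_of_stay: float | None = None
    charges: float | None = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be non-negative, got {self.age}")
        if not self.survey_weight > 0:
            raise ValueError("survey_weight must be positive")


@dataclass(frozen=True)
class ParameterVector:
    """The extracted RAI parameter levels for one record."""

    age_band: str
    male: bool
    weight_loss: bool = False
    poor_appetite: bool = False
    kidney_failure: bool = False
    congestive_heart_failure: bool = False
    shortness_of_breath: bool = False
    cognitive_decline: bool = False
    cancer: bool = False
    cancer_tier: str | None = None
    functional_status: str = "independent"

    def __post_init__(self) -> None:
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_band!r}")
        if self.functional_status not in FUNCTIONAL_LEVELS:
            raise ValueError(f"unknown functional status {self.functional_status!r}")
        if self.cancer != (self.cancer_tier is not None):
            raise ValueError("cancer_tier must be present iff cancer is true")


@dataclass(frozen=True)
class MortalityLabel:
    died: bool
    source: Literal["disposition", "comfort_care_code", "both", "none"]

    def __post_init__(self) -> None:
        if self.died != (self.source != "none"):
            raise ValueError("died must be true iff a trigger fired")


# -- extraction ------------------------------------------------------------

def extract_parameters(
    record: DischargeRecord,
    cmap: ParameterCodeMap,
    cancer_definition: str = "severe",
) -> ParameterVector:
    """Extract the RAI parameter levels from a single record.

    Deficits are present when at least one diagnosis code matches the
    parameter's patterns.  Functional status uses the precedence
    total > partial > independent.  Cancer is present when the most severe
    matched tier falls within ``cancer_definition`` (default: the severe
    categorization, the instrument's final cancer parameter definition).
    Depends only on age, sex and the *set* of diagnosis codes.
    """
    tiers = CANCER_DEFINITIONS[cancer_definition]
    hits = lookup_parameters(record.dx_codes, cmap)
    p = hits.parameters
    if "functional_status_total" in p:
        fs = "totally_dependent"
    elif "functional_status_partial" in p:
        fs = "partially_dependent"
    else:
        fs = "independent"
    cancer = hits.cancer_tier is not None and hits.cancer_tier in tiers
    return ParameterVector(
        age_band=age_band(record.age),
        male=record.sex == "male",
        weight_loss="weight_loss" in p,
        poor_appetite="poor_appetite" in p,
        kidney_failure="kidney_failure" in p,
        congestive_heart_failure="congestive_heart_failure" in p,
        shortness_of_breath="shortness_of_breath" in p,
        cognitive_decline="cognitive_decline" in p,
        cancer=cancer,
        cancer_tier=hits.cancer_tier if cancer else None,
        functional_status=fs,
    )


def extract_parameters_frame(
    df: pd.DataFrame,
    cmap: ParameterCodeMap,
    cancer_definition: str = "severe",
) -> pd.DataFrame:
    """Vectorized parameter extraction over a standardized records frame.

    ``df`` must carry ``age``, ``sex`` and a list-valued ``dx_codes``
    column.  Returns a frame aligned on ``df.index`` with one column per
    parameter plus ``age_band``, ``cancer_tier``, ``functional_status`` and
    an ``n_unmatched_codes`` diagnostics tally.
    """
    tiers = CANCER_DEFINITIONS[cancer_definition]
    index = cmap.build_index()
    n = len(df)
    cols = {param: np.zeros(n, dtype=bool) for param in
            ("weight_loss", "poor_appetite", "kidney_failure",
             "congestive_heart_failure", "shortness_of_breath",
             "cognitive_decline")}
    fs_partial = np.zeros(n, dtype=bool)
    fs_total = np.zeros(n, dtype=bool)
    tier_arr = np.full(n, None, dtype=object)
    unmatched = np.zeros(n, dtype=int)
    for i, codes in enumerate(df["dx_codes"].to_numpy()):
        hits = lookup_parameters(codes, cmap, index=index)
        for param in hits.parameters:
            if param == "cancer":
                tier_arr[i] = hits.cancer_tier
            elif param == "functional_status_partial":
                fs_partial[i] = True
            elif param == "functional_status_total":
                fs_total[i] = True
            else:
                cols[param][i] = True
        unmatched[i] = len(hits.unmatched)
    fs = np.where(fs_total, "totally_dependent",
                  np.where(fs_partial, "partially_dependent", "independent"))
    in_def = np.array([t is not None and t in tiers for t in tier_arr])
    out = pd.DataFrame(cols, index=df.index)
    ages = df["age"].to_numpy()
    out["age_band"] = np.take(AGE_BANDS, _age_band_index_array(ages))
    # missing sex scores as the reference level (complete-case filtering
    # decides whether such records reach the derivation at all)
    out["male"] = (df["sex"] == "male").fillna(False).to_numpy(dtype=bool)
    out["cancer"] = in_def
    out["cancer_tier"] = np.where(in_def, tier_arr, None)
    out["functional_status"] = fs
    out["n_unmatched_codes"] = unmatched
    return out


# -- mortality -------------------------------------------------------------

def ascertain_mortality(
    record: DischargeRecord,
    definition: str = "composite",
) -> MortalityLabel:
    """Composite in-hospital mortality label for one record.

    ``definition="composite"`` (default): died iff the discharge disposition
    is ``died`` or a comfort-care transition code (Z51.5) is assigned.
    ``definition="disposition_only"``: the sensitivity-analysis variant that
    uses the disposition alone.
    """
    by_disp = record.disposition == "died"
    by_code = _COMFORT_CARE_CODE in record.dx_codes
    if definition == "disposition_only":
        by_code = False
    elif definition != "composite":
        raise ValueError(f"unknown mortality definition {definition!r}")
    if by_disp and by_code:
        return MortalityLabel(True, "both")
    if by_disp:
        return MortalityLabel(True, "disposition")
    if by_code:
        return MortalityLabel(True, "comfort_care_code")
    return MortalityLabel(False, "none")


def ascertain_mortality_frame(
    df: pd.DataFrame, definition: str = "composite"
) -> pd.DataFrame:
    """Vectorized mortality ascertainment; returns ``died`` and ``death_source``."""
    if definition not in ("composite", "disposition_only"):
        raise ValueError(f"unknown mortality definition {definition!r}")
    by_disp = (df["disposition"] == "died").to_numpy()
    if definition == "composite":
        by_code = np.array(
            [_COMFORT_CARE_CODE in codes for codes in df["dx_codes"].to_numpy()]
        )
    else:
        by_code = np.zeros(len(df), dtype=bool)
    source = np.where(
        by_disp & by_code, "both",
        np.where(by_disp, "disposition",
                 np.where(by_code, "comfort_care_code", "none")),
    )
    return pd.DataFrame(
        {"died": by_disp | by_code, "death_source": source}, index=df.index
    )


# -- cohort assembly -------------------------------------------------------

@dataclass
class ExclusionLedger:
    """Accounting of inclusion filtering: every input record is either
    retained or counted under exactly one exclusion reason."""

    n_input: int
    n_retained: int
    exclusions: dict[str, int] = field(default_factory=dict)
    missingness: dict[str, float] = field(default_factory=dict)

    def check(self) -> None:
        if self.n_input != self.n_retained + sum(self.exclusions.values()):
            raise RaicdError("exclusion ledger does not balance")

    def to_frame(self) -> pd.DataFrame:
        rows = [("retained", self.n_retained)] + sorted(self.exclusions.items())
        return pd.DataFrame(rows, columns=["reason", "count"])


_OPTIONAL_FIELDS = ("elective", "length_of_stay", "charges")
_REQUIRED_FIELDS = ("age", "sex", "disposition")


def build_cohort(
    records: pd.DataFrame,
    cmap: ParameterCodeMap,
    adults_only: bool = True,
    operative_only: bool = True,
    complete_case: bool = True,
    mortality_definition: str = "composite",
    cancer_definition: str = "severe",
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Apply inclusion filters and assemble the analysis-ready cohort.

    Filters, applied in order with each record counted under its first
    failing reason: age >= 18 (``adults_only``), operative procedure flag
    (``operative_only``), and completeness of the model covariates
    (``complete_case``: age, sex, disposition; the optional outcome fields
    elective / length_of_stay / charges may be missing without exclusion).

    Returns the cohort frame (parameters + mortality + passthrough fields)
    and an :class:`ExclusionLedger` with per-field missingness proportions
    measured on the *input*.

    Raises
    ------
    EmptyCohortError
        If no record survives filtering.
    """
    df = records.reset_index(drop=True)
    n_input = len(df)

    missing = {
        "age": df["age"].isna() if "age" in df else pd.Series(True, index=df.index),
        "sex": df["sex"].isna() | (df["sex"] == "missing"),
        "disposition": df["disposition"].isna() | (df["disposition"] == "missing"),
        "elective": df["elective"].isna() if "elective" in df else pd.Series(np.nan, index=df.index),
        "length_of_stay": df["length_of_stay"].isna() if "length_of_stay" in df else pd.Series(np.nan, index=df.index),
        "charges": df["charges"].isna() if "charges" in df else pd.Series(np.nan, index=df.index),
    }
    missingness = {
        fld: float(np.nan_to_num(m.astype(float)).mean()) if n_input else float("nan")
        for fld, m in missing.items()
    }

    reason = np.full(n_input, "", dtype=object)
    if adults_only:
        too_young = (~missing["age"]) & (df["age"] < 18)
        reason[too_young & (reason == "")] = "age<18"
    if operative_only:
        non_op = ~df["operative"].fillna(False).astype(bool)
        reason[non_op.to_numpy() & (reason == "")] = "non_operative"
    if complete_case:
        incomplete = missing["age"] | missing["sex"] | missing["disposition"]
        reason[incomplete.to_numpy() & (reason == "")] = "missing_covariate"

    keep = reason == ""
    exclusions: dict[str, int] = {}
    for r in ("age<18", "non_operative", "missing_covariate"):
        c = int((reason == r).sum())
        if c:
            exclusions[r] = c
    ledger = ExclusionLedger(
        n_input=n_input,
        n_retained=int(keep.sum()),
        exclusions=exclusions,
        missingness=missingness,
    )
    ledger.check()
    if not keep.any():
        raise EmptyCohortError("no records remain after inclusion filtering")

    kept = df.loc[keep].reset_index(drop=True)
    params = extract_parameters_frame(kept, cmap, cancer_definition=cancer_definition)
    mort = ascertain_mortality_frame(kept, definition=mortality_definition)
    cohort = pd.concat([kept.drop(columns=["dx_codes"]), params, mort], axis=1)
    return cohort, ledger


# -- discharge CSV dialect -------------------------------------------------

@dataclass
class CsvDialect:
    """Column layout and codings for the wide discharge CSV format.

    Unknown columns are ignored; every name and coding is configurable so
    the reader can be pointed at NIS-style extracts.
    """

    delimiter: str = ","
    record_id: str = "ID"
    age: str = "AGE"
    sex: str = "SEX"
    disposition: str = "DISP"
    weight: str = "WEIGHT"
    cluster: str = "CLUSTER"
    operative: str = "OPERATIVE"
    elective: str = "ELECTIVE"
    length_of_stay: str = "LOS"
    charges: str = "CHARGES"
    dx_prefix: str = "DX"
    n_dx: int = 40
    sex_map: Mapping[str, str] = field(
        default_factory=lambda: {
            "male": "male", "female": "female", "m": "male", "f": "female",
            "1": "male", "2": "female",
        }
    )
    disposition_map: Mapping[str, str] = field(
        default_factory=lambda: {
            "routine": "routine", "transfer": "transfer", "died": "died",
            "other": "other",
        }
    )

    def dx_columns(self) -> list[str]:
        return [f"{self.dx_prefix}{i}" for i in range(1, self.n_dx + 1)]


def _coded(series: pd.Series, mapping: Mapping[str, str]) -> pd.Series:
    s = series.astype("string").str.strip().str.lower()
    out = s.map({k.lower(): v for k, v in mapping.items()})
    return out.where(~s.isna() & (s != ""), other=pd.NA)


def read_discharge_csv(path: str | Path, dialect: CsvDialect | None = None) -> pd.DataFrame:
    """Read a wide discharge CSV into the standardized records frame.

    Output columns: ``record_id, age, sex, dx_codes (tuple of normalized
    codes), disposition, survey_weight, cluster_id, operative, elective,
    length_of_stay, charges``.  Diagnosis codes that fail normalization are
    dropped and tallied in ``df.attrs["n_invalid_codes"]``.
    """
    d = dialect or CsvDialect()
    raw = pd.read_csv(path, sep=d.delimiter, dtype=str, keep_default_na=False)
    n = len(raw)
    if n == 0:
        raise EmptyCohortError(f"discharge table {path} contains no records")

    def col(name: str) -> pd.Series:
        if name in raw.columns:
            s = raw[name].astype("string").str.strip()
            return s.where(s != "", other=pd.NA)
        return pd.Series(pd.NA, index=raw.index, dtype="string")

    n_invalid = 0
    dx_cols = [c for c in d.dx_columns() if c in raw.columns]
    dx_lists: list[tuple[str, ...]] = []
    dx_mat = raw[dx_cols].to_numpy(dtype=object) if dx_cols else np.empty((n, 0))
    for row in dx_mat:
        codes = []
        for cell in row:
            cell = (cell or "").strip()
            if not cell:
                continue
            try:
                codes.append(normalize_code(cell))
            except InvalidCodeError:
                n_invalid += 1
        dx_lists.append(tuple(codes))

    ids = col(d.record_id)
    if ids.isna().all():
        ids = pd.Series([f"r{i}" for i in range(n)], dtype="string")
    out = pd.DataFrame(
        {
            "record_id": ids,
            "age": pd.to_numeric(col(d.age), errors="coerce"),
            "sex": _coded(col(d.sex), d.sex_map),
            "dx_codes": dx_lists,
            "disposition": _coded(col(d.disposition), d.disposition_map),
            "survey_weight": pd.to_numeric(col(d.weight), errors="coerce").fillna(1.0),
            "cluster_id": col(d.cluster),
            "operative": pd.to_numeric(col(d.operative), errors="coerce").fillna(0).astype(bool),
            "elective": pd.to_numeric(col(d.elective), errors="coerce"),
            "length_of_stay": pd.to_numeric(col(d.length_of_stay), errors="coerce"),
            "charges": pd.to_numeric(col(d.charges), errors="coerce"),
        }
    )
    out.attrs["n_invalid_codes"] = n_invalid
    return out


def write_discharge_csv(
    records: pd.DataFrame, path: str | Path, dialect: CsvDialect | None = None
) -> None:
    """Write a standardized records frame in the wide discharge CSV dialect."""
    d = dialect or CsvDialect()
    n = len(records)
    max_dx = max((len(c) for c in records["dx_codes"]), default=0)
    n_dx = min(max(max_dx, 1), d.n_dx)
    out = pd.DataFrame(
        {
            d.record_id: records["record_id"].to_numpy(),
            d.age: records["age"].to_numpy(),
            d.sex: records["sex"].fillna("").to_numpy(),
            d.disposition: records["disposition"].fillna("").to_numpy(),
            d.weight: records["survey_weight"].to_numpy(),
            d.cluster: records["cluster_id"].fillna("").to_numpy() if "cluster_id" in records else "",
            d.operative: records["operative"].astype(int).to_numpy(),
            d.elective: records["elective"].to_numpy() if "elective" in records else np.nan,
            d.length_of_stay: records["length_of_stay"].to_numpy() if "length_of_stay" in records else np.nan,
            d.charges: records["charges"].to_numpy() if "charges" in records else np.nan,
        }
    )
    dx = np.full((n, n_dx), "", dtype=object)
    for i, codes in enumerate(records["dx_codes"].to_numpy()):
        for j, code in enumerate(codes[:n_dx]):
            dx[i, j] = code
    for j in range(n_dx):
        out[f"{d.dx_prefix}{j + 1}"] = dx[:, j]
    out.to_csv(path, sep=d.delimiter, index=False)
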