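"""The integerized RAI-ICD score and its frailty categorization.

The score is a sum of integer points over the instrument's terms:

``score = age_cancer[band, cancer] + male + Σ deficits + function_cognition[fs, cog]``

where the two grids carry the instrument's statistical interactions
(age × cancer, functional status × cognitive decline) as *total* cell
points.  With the packaged default table the attainable range is 0–81.
Scores stratify into four frailty categories: robust (<27), normal
(27–35), frail (36–45) and very frail (>45).

The weight table is a versioned data file so re-derived tables (see
:mod:`raicd.derivation`) can be swapped in without code changes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import AGE_BANDS, DEFICITS, FUNCTIONAL_LEVELS, ParameterVector
from .errors import WeightTableError

__all__ = [
    "CATEGORIES",
    "WeightTable",
    "CategoryThresholds",
    "ScoreResult",
    "total_score",
    "categorize",
    "categorize_array",
    "validate_weight_table",
    "score_frame",
    "load_weight_table",
    "save_weight_table",
    "default_weight_table",
]

#: Frailty categories in increasing order of mortality risk.
CATEGORIES = ("robust", "normal", "frail", "very_frail")


@dataclass
class WeightTable:
    """Integer point assignments for every instrument term.

    ``age_cancer`` maps each band to ``(without_cancer, with_cancer)``
    total points; ``function_cognition`` maps each functional level to
    ``(without, with)`` cognitive-decline total points.
    """

    age_cancer: dict[str, tuple[int, int]]
    male_points: int
    deficit_points: dict[str, int]
    function_cognition: dict[str, tuple[int, int]]
    version: str = "unversioned"

    # -- score bounds ------------------------------------------------------
    def min_score(self) -> int:
        return (
            min(min(v) for v in self.age_cancer.values())
            + min(self.male_points, 0)
            + sum(min(p, 0) for p in self.deficit_points.values())
            + min(min(v) for v in self.function_cognition.values())
        )

    def max_score(self) -> int:
        return (
            max(max(v) for v in self.age_cancer.values())
            + max(self.male_points, 0)
            + sum(max(p, 0) for p in self.deficit_points.values())
            + max(max(v) for v in self.function_cognition.values())
        )

    # -- persistence -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "age_cancer": {
                b: {"without_cancer": int(w), "with_cancer": int(c)}
                for b, (w, c) in self.age_cancer.items()
            },
            "male_points": int(self.male_points),
            "deficit_points": {k: int(v) for k, v in self.deficit_points.items()},
            "function_cognition": {
                f: {"without_cognitive_decline": int(w), "with_cognitive_decline": int(c)}
                for f, (w, c) in self.function_cognition.items()
            },
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "WeightTable":
        try:
            age_cancer = {
                b: (int(v["without_cancer"]), int(v["with_cancer"]))
                for b, v in doc["age_cancer"].items()
            }
            fc = {
                f: (int(v["without_cognitive_decline"]), int(v["with_cognitive_decline"]))
                for f, v in doc["function_cognition"].items()
            }
            return cls(
                age_cancer=age_cancer,
                male_points=int(doc["male_points"]),
                deficit_points={k: int(v) for k, v in doc["deficit_points"].items()},
                function_cognition=fc,
                version=str(doc.get("version", "unversioned")),
            )
        except (KeyError, TypeError) as exc:
            raise WeightTableError(f"malformed weight-table document: {exc}") from exc


@dataclass(frozen=True)
class CategoryThresholds:
    """Integer score boundaries of the four frailty categories.

    ``robust_below``: scores strictly below are robust.
    ``normal_upper``: last normal score; ``normal_upper + 1`` is the frailty
    threshold.  ``frail_upper``: last frail score; above is very frail.
    Defaults are the instrument's published boundaries (<27 / 27–35 /
    36–45 / >45).
    """

    robust_below: int = 27
    normal_upper: int = 35
    frail_upper: int = 45

    def __post_init__(self) -> None:
        if not (self.robust_below <= self.normal_upper + 1 <= self.frail_upper):
            raise ValueError(
                "thresholds must satisfy robust_below <= normal_upper+1 <= frail_upper"
            )


@dataclass(frozen=True)
class ScoreResult:
    score: int
    category: str
    breakdown: dict[str, int]


@dataclass
class ValidationReport:
    failures: list[str] = field(default_factory=list)
    min_score: int = 0
    max_score: int = 0

    @property
    def ok(self) -> bool:
        return not self.failures


def validate_weight_table(wt: WeightTable) -> ValidationReport:
    """Check every structural invariant of a weight table.

    Verified: all bands and functional levels present; all points
    non-negative; age points non-decreasing across bands within each cancer
    stratum; with-cancer >= without-cancer at every band; function grid
    non-decreasing in dependency within each cognition stratum and
    with-cognition >= without at every level.  Reports attainable min/max.
    """
    rep = ValidationReport()
    missing_bands = [b for b in AGE_BANDS if b not in wt.age_cancer]
    if missing_bands:
        rep.failures.append(f"missing bands: {missing_bands}")
    missing_fs = [f for f in FUNCTIONAL_LEVELS if f not in wt.function_cognition]
    if missing_fs:
        rep.failures.append(f"missing functional levels: {missing_fs}")
    missing_def = [d for d in DEFICITS if d not in wt.deficit_points]
    if missing_def:
        rep.failures.append(f"missing deficits: {missing_def}")
    if rep.failures:
        return rep

    allpts = (
        [p for v in wt.age_cancer.values() for p in v]
        + [wt.male_points]
        + list(wt.deficit_points.values())
        + [p for v in wt.function_cognition.values() for p in v]
    )
    if any(p < 0 for p in allpts):
        rep.failures.append("negative points")

    wo = [wt.age_cancer[b][0] for b in AGE_BANDS]
    wc = [wt.age_cancer[b][1] for b in AGE_BANDS]
    if any(b > a for a, b in zip(wo[1:], wo)) or any(b > a for a, b in zip(wc[1:], wc)):
        rep.failures.append("age monotonicity")
    if any(c < w for w, c in zip(wo, wc)):
        rep.failures.append("cancer monotonicity")

    fc_wo = [wt.function_cognition[f][0] for f in FUNCTIONAL_LEVELS]
    fc_wc = [wt.function_cognition[f][1] for f in FUNCTIONAL_LEVELS]
    if any(c < w for w, c in zip(fc_wo, fc_wc)):
        rep.failures.append("cognition monotonicity")
    if any(b > a for a, b in zip(fc_wo[1:], fc_wo)) or any(
        b > a for a, b in zip(fc_wc[1:], fc_wc)
    ):
        rep.failures.append("dependency monotonicity")

    rep.min_score = wt.min_score()
    rep.max_score = wt.max_score()
    return rep


def categorize(score: int, thresholds: CategoryThresholds | None = None) -> str:
    """Frailty category of an integer score."""
    th = thresholds or CategoryThresholds()
    if score < 0:
        raise ValueError(f"score must be non-negative, got {score}")
    if score < th.robust_below:
        return "robust"
    if score <= th.normal_upper:
        return "normal"
    if score <= th.frail_upper:
        return "frail"
    return "very_frail"


def categorize_array(
    scores: np.ndarray, thresholds: CategoryThresholds | None = None
) -> np.ndarray:
    th = thresholds or CategoryThresholds()
    scores = np.asarray(scores)
    if (scores < 0).any():
        raise ValueError("scores must be non-negative")
    out = np.where(
        scores < th.robust_below, "robust",
        np.where(scores <= th.normal_upper, "normal",
                 np.where(scores <= th.frail_upper, "frail", "very_frail")),
    )
    return out


def total_score(
    pv: ParameterVector,
    wt: WeightTable | None = None,
    thresholds: CategoryThresholds | None = None,
) -> ScoreResult:
    """Compute the integerized score and component breakdown for one vector.

    Raises
    ------
    WeightTableError
        If the vector's band or functional level is absent from the table.
    """
    table = wt or default_weight_table()
    if pv.age_band not in table.age_cancer:
        raise WeightTableError(f"band {pv.age_band!r} absent from weight table")
    if pv.functional_status not in table.function_cognition:
        raise WeightTableError(
            f"functional level {pv.functional_status!r} absent from weight table"
        )
    breakdown = {
        "age_cancer": table.age_cancer[pv.age_band][1 if pv.cancer else 0],
        "male": table.male_points if pv.male else 0,
        "function_cognition": table.function_cognition[pv.functional_status][
            1 if pv.cognitive_decline else 0
        ],
    }
    for d in DEFICITS:
        breakdown[d] = table.deficit_points[d] if getattr(pv, d) else 0
    score = int(sum(breakdown.values()))
    return ScoreResult(score=score, category=categorize(score, thresholds), breakdown=breakdown)


def score_frame(
    params: pd.DataFrame,
    wt: WeightTable | None = None,
    thresholds: CategoryThresholds | None = None,
) -> pd.DataFrame:
    """Vectorized scoring of an extracted-parameters frame.

    ``params`` needs the columns produced by
    :func:`raicd.cohort.extract_parameters_frame`.  Returns ``score``,
    ``category`` and per-term point columns aligned on the input index.
    """
    table = wt or default_weight_table()
    band_idx = {b: i for i, b in enumerate(AGE_BANDS)}
    wo = np.array([table.age_cancer[b][0] for b in AGE_BANDS])
    wc = np.array([table.age_cancer[b][1] for b in AGE_BANDS])
    bi = params["age_band"].map(band_idx).to_numpy()
    cancer = params["cancer"].to_numpy(dtype=bool)
    out = pd.DataFrame(index=params.index)
    out["pts_age_cancer"] = np.where(cancer, wc[bi], wo[bi])
    out["pts_male"] = np.where(params["male"].to_numpy(dtype=bool), table.male_points, 0)
    for d in DEFICITS:
        out[f"pts_{d}"] = np.where(
            params[d].to_numpy(dtype=bool), table.deficit_points[d], 0
        )
    fs_idx = {f: i for i, f in enumerate(FUNCTIONAL_LEVELS)}
    fc = np.array([table.function_cognition[f] for f in FUNCTIONAL_LEVELS])
    fi = params["functional_status"].map(fs_idx).to_numpy()
    cog = params["cognitive_decline"].to_numpy(dtype=bool).astype(int)
    out["pts_function_cognition"] = fc[fi, cog]
    out["score"] = out.sum(axis=1).astype(int)
    out["category"] = categorize_array(out["score"].to_numpy(), thresholds)
    return out


def enumerate_parameter_vectors() -> "itertools.product":
    """Iterate over the full 18 x 2 x 2 x 2^5 x 3 x 2 parameter grid.

    Cancer is enumerated as a with/without flag (tier fixed to severe when
    present; tiers do not alter the score).
    """
    for band, male, cancer, deficits, fs, cog in itertools.product(
        AGE_BANDS, (False, True), (False, True),
        itertools.product((False, True), repeat=len(DEFICITS)),
        FUNCTIONAL_LEVELS, (False, True),
    ):
        yield ParameterVector(
            age_band=band,
            male=male,
            cancer=cancer,
            cancer_tier="severe" if cancer else None,
            weight_loss=deficits[0],
            poor_appetite=deficits[1],
            kidney_failure=deficits[2],
            congestive_heart_failure=deficits[3],
            shortness_of_breath=deficits[4],
            functional_status=fs,
            cognitive_decline=cog,
        )


# -- persistence -----------------------------------------------------------

def load_weight_table(path: str | Path) -> WeightTable:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise WeightTableError(f"weight-table file {path} is not a mapping document")
    return WeightTable.from_dict(doc)


def save_weight_table(wt: WeightTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(wt.to_dict(), fh, sort_keys=False)


_DEFAULT_CACHE: WeightTable | None = None


def default_weight_table() -> WeightTable:
    """The packaged default table (the published instrument, range 0–81)."""
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        text = (
            resources.files("raicd.data")
            .joinpath("weights_default.yaml")
            .read_text(encoding="utf-8")
        )
        _DEFAULT_CACHE = WeightTable.from_dict(yaml.safe_load(text))
    return _DEFAULT_CACHE
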