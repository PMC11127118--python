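"""Synthetic NIS-like inpatient discharge data with known frailty structure.

The generator emulates the analysis population the instrument targets:
adult operative hospitalizations with up to 40 diagnosis-code slots,
survey weights, and an in-hospital mortality around 2–2.5%.  Demographics
and deficit prevalences default to the published population profile (mean
age ≈ 55, 39% male, CHF ≈ 10.7%, cancer ≈ 4.3%, …); deficit prevalence
rises with age through per-parameter logistic slopes so that age and
frailty correlate as they do in real claims data (set the slopes to zero
for fully independent deficits).

Mortality follows the instrument's own generative model: a record's true
integer score ``S`` (from a configurable weight table) enters a logistic
model ``P(death) = expit(alpha + S/c)``, with the intercept solved
numerically so the expected mortality matches the configured target.  One
mapped ICD-10-CM code is emitted per present deficit, plus distractor
codes from a fixed unmapped pool; dispositions and comfort-care (Z51.5)
coding are set consistently with the drawn deaths, exercising both arms
of the composite mortality definition.  Everything is reproducible from
the seed, and the generator returns a truth table (true parameters, true
score, true death probability) alongside the records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .codemap import ParameterCodeMap, default_code_map
from .cohort import AGE_BANDS, DEFICITS, _age_band_index_array
from .errors import CalibrationError, ConfigError
from .scoring import WeightTable, default_weight_table, score_frame

__all__ = ["SimulationConfig", "generate", "calibrate_intercept", "DISTRACTOR_POOL"]

#: Fixed pool of plausible, deliberately unmapped ICD-10-CM codes used as
#: matcher-specificity distractors (hypertension, diabetes, GERD, ...).
DISTRACTOR_POOL = (
    "I10", "E119", "E785", "K219", "M545", "F329", "N390", "J189", "A419",
    "D649", "M170", "S7200", "K358", "H2513", "G4733", "B9620", "L03115",
    "R079", "R1013", "Z87891",
)

_DEFAULT_PREVALENCES = {
    "cancer": 0.043,
    "weight_loss": 0.011,
    "poor_appetite": 0.002,
    "kidney_failure": 0.039,
    "congestive_heart_failure": 0.107,
    "shortness_of_breath": 0.020,
    "cognitive_decline": 0.028,
}

# log-odds increase per year of age for each deficit; geriatric syndromes
# (cognitive decline, dependence) climb fastest
_DEFAULT_AGE_SLOPES = {
    "cancer": 0.030,
    "weight_loss": 0.030,
    "poor_appetite": 0.050,
    "kidney_failure": 0.040,
    "congestive_heart_failure": 0.060,
    "shortness_of_breath": 0.030,
    "cognitive_decline": 0.090,
    "functional_partial": 0.070,
    "functional_total": 0.070,
}

_CATEGORY_ELECTIVE_P = {"robust": 0.50, "normal": 0.44, "frail": 0.30, "very_frail": 0.35}
_CATEGORY_LOS_MEAN = {"robust": 4.4, "normal": 6.3, "frail": 8.2, "very_frail": 8.8}
_CATEGORY_CHARGES_MEAN = {
    "robust": 89_420.0, "normal": 138_685.0, "frail": 146_336.0, "very_frail": 151_211.0,
}


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    The defaults are the emulated population's conditions; change them for
    designed experiments, not to make tests pass.
    """

    n: int = 10_000
    seed: int = 0
    # demographics
    age_mean: float = 55.0
    age_sd: float = 20.0
    age_min: int = 18
    age_max: int = 105
    male_p: float = 0.39
    # deficit prevalences (marginal targets)
    prevalences: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCES)
    )
    functional_p: tuple[float, float, float] = (0.938, 0.049, 0.013)
    #: prevalence of non-frail (moderate / mild tier) cancer coding, emitted
    #: as codes but carrying no mortality signal under the severe definition
    moderate_cancer_p: float = 0.020
    mild_cancer_p: float = 0.025
    age_slopes: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AGE_SLOPES)
    )
    # mortality model
    weight_table: WeightTable | None = None
    scale_c: float = 8.0
    target_mortality: float = 0.024
    comfort_care_fraction: float = 0.20
    both_fraction: float = 0.05
    # record structure
    dx_cap: int = 40
    distractor_mean: float = 3.0
    operative_p: float = 1.0
    missingness: dict[str, float] = field(
        default_factory=lambda: {
            "sex": 0.02, "elective": 0.03, "length_of_stay": 0.01, "charges": 0.04,
        }
    )
    weight_low: float = 4.5
    weight_high: float = 5.5
    n_clusters: int = 200

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ConfigError("n must be positive")
        probs = (
            list(self.prevalences.values())
            + list(self.functional_p)
            + [self.male_p, self.comfort_care_fraction, self.both_fraction,
               self.moderate_cancer_p, self.mild_cancer_p]
            + list(self.missingness.values())
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        if abs(sum(self.functional_p) - 1.0) > 1e-9:
            raise ConfigError("functional_p must sum to 1")
        if not (0.0 < self.target_mortality < 1.0):
            raise ConfigError("target mortality must lie in (0, 1)")
        if self.scale_c <= 0:
            raise ConfigError("scale_c must be positive")
        if self.dx_cap < 1:
            raise ConfigError("dx slot cap must be at least 1")


def calibrate_intercept(linear_predictor, target: float, tol: float = 1e-8) -> float:
    """Solve alpha with E[expit(alpha + lp)] = target by bisection/Brent.

    Raises
    ------
    CalibrationError
        If the target is on the boundary or outside the reachable range of
        the search bracket.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if not (0.0 < target < 1.0):
        raise CalibrationError(f"target mortality {target} is not in (0, 1)")

    def f(a: float) -> float:
        return float(expit(a + lp).mean() - target)

    lo, hi = -40.0, 15.0
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError(
            f"target mortality {target} unreachable given the configured effect sizes"
        )
    return float(brentq(f, lo, hi, xtol=tol))


def _age_graded_probability(
    ages: np.ndarray, marginal: float, slope: float, anchor: float = 55.0
) -> np.ndarray:
    """Per-record probability with logit slope in age, calibrated so the
    empirical mean over ``ages`` equals the marginal target."""
    if marginal <= 0.0:
        return np.zeros_like(ages, dtype=float)
    if marginal >= 1.0:
        return np.ones_like(ages, dtype=float)
    if slope == 0.0:
        return np.full(ages.shape, marginal, dtype=float)
    x = slope * (ages - anchor)

    def f(a: float) -> float:
        return float(expit(a + x).mean() - marginal)

    a = brentq(f, -40.0, 40.0, xtol=1e-10)
    return expit(a + x)


def _pick_codes(rng: np.random.Generator, pool: list[str], k: int) -> np.ndarray:
    return np.asarray(pool, dtype=object)[rng.integers(0, len(pool), size=k)]


def generate(
    config: SimulationConfig, cmap: ParameterCodeMap | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (records, truth) frames under the configured conditions.

    ``records`` is a standardized discharge frame (see
    :mod:`raicd.cohort`); ``truth`` carries the generating parameters, the
    true integer score, the true death probability and the drawn death for
    every record.  Identical config + seed gives identical output.
    """
    cmap = cmap or default_code_map()
    wt = config.weight_table or default_weight_table()
    rng = np.random.default_rng(config.seed)
    n = config.n

    # demographics ---------------------------------------------------------
    a_lo = (config.age_min - config.age_mean) / config.age_sd
    a_hi = (config.age_max - config.age_mean) / config.age_sd
    ages = np.rint(
        truncnorm.rvs(
            a_lo, a_hi, loc=config.age_mean, scale=config.age_sd,
            size=n, random_state=rng,
        )
    ).astype(int)
    ages = np.clip(ages, config.age_min, config.age_max)
    male = rng.random(n) < config.male_p

    # deficits -------------------------------------------------------------
    present: dict[str, np.ndarray] = {}
    for param, prev in config.prevalences.items():
        slope = config.age_slopes.get(param, 0.0)
        p = _age_graded_probability(ages, prev, slope)
        present[param] = rng.random(n) < p

    p_part = _age_graded_probability(
        ages, config.functional_p[1], config.age_slopes.get("functional_partial", 0.0)
    )
    p_tot = _age_graded_probability(
        ages, config.functional_p[2], config.age_slopes.get("functional_total", 0.0)
    )
    u = rng.random(n)
    functional = np.where(
        u < p_tot, "totally_dependent",
        np.where(u < p_tot + p_part, "partially_dependent", "independent"),
    )

    # non-frail cancer coding (moderate / mild tiers, no mortality signal
    # under the severe cancer definition)
    moderate_code = rng.random(n) < config.moderate_cancer_p
    mild_code = rng.random(n) < config.mild_cancer_p

    # true score and mortality --------------------------------------------
    params = pd.DataFrame(
        {
            "age_band": np.take(AGE_BANDS, _age_band_index_array(ages)),
            "male": male,
            "cancer": present["cancer"],
            "cancer_tier": np.where(present["cancer"], "severe", None),
            "functional_status": functional,
            "cognitive_decline": present["cognitive_decline"],
        }
    )
    for d in DEFICITS:
        params[d] = present[d]
    scored = score_frame(params, wt)
    score = scored["score"].to_numpy()
    category = scored["category"].to_numpy()

    lp = score / config.scale_c
    alpha = calibrate_intercept(lp, config.target_mortality)
    p_death = expit(alpha + lp)
    died = rng.random(n) < p_death

    # disposition and comfort-care coding ---------------------------------
    disposition = np.empty(n, dtype=object)
    z515 = np.zeros(n, dtype=bool)
    alive = ~died
    disposition[alive] = rng.choice(
        ["routine", "transfer", "other"], size=int(alive.sum()), p=[0.8, 0.1, 0.1]
    )
    d_idx = np.flatnonzero(died)
    u_d = rng.random(d_idx.size)
    comfort_only = u_d < config.comfort_care_fraction
    disposition[d_idx[comfort_only]] = "other"
    z515[d_idx[comfort_only]] = True
    rest = d_idx[~comfort_only]
    disposition[rest] = "died"
    z515[rest[rng.random(rest.size) < config.both_fraction]] = True

    # diagnosis-code emission ----------------------------------------------
    param_pools: dict[str, list[str]] = {
        p: [pat.pattern for pat in cmap.patterns(p)]
        for p in cmap.entries
    }
    tier_pools: dict[str, list[str]] = {t: [] for t in ("severe", "moderate", "mild")}
    for pat in cmap.patterns("cancer"):
        tier_pools[cmap.tier_of(pat.pattern)].append(pat.pattern)
    for p, arr in present.items():
        pool_name = p if p != "cancer" else None
        if pool_name is not None and arr.any() and not param_pools.get(pool_name):
            raise ConfigError(f"code map supplies no codes for parameter {p!r}")
    if present["cancer"].any() and not tier_pools["severe"]:
        raise ConfigError("code map supplies no severe-tier cancer codes")

    emitted: dict[str, np.ndarray] = {}
    for p in (
        "weight_loss", "poor_appetite", "kidney_failure",
        "congestive_heart_failure", "shortness_of_breath", "cognitive_decline",
    ):
        mask = present[p]
        codes = np.full(n, None, dtype=object)
        if mask.any():
            codes[mask] = _pick_codes(rng, param_pools[p], int(mask.sum()))
        emitted[p] = codes
    for level, pool_key in (
        ("partially_dependent", "functional_status_partial"),
        ("totally_dependent", "functional_status_total"),
    ):
        mask = functional == level
        codes = np.full(n, None, dtype=object)
        if mask.any():
            if not param_pools.get(pool_key):
                raise ConfigError(f"code map supplies no codes for {pool_key!r}")
            codes[mask] = _pick_codes(rng, param_pools[pool_key], int(mask.sum()))
        emitted[pool_key] = codes
    for tier, mask in (
        ("severe", present["cancer"]), ("moderate", moderate_code), ("mild", mild_code),
    ):
        codes = np.full(n, None, dtype=object)
        if mask.any():
            if not tier_pools[tier]:
                raise ConfigError(f"code map supplies no {tier}-tier cancer codes")
            codes[mask] = _pick_codes(rng, tier_pools[tier], int(mask.sum()))
        emitted[f"cancer_{tier}"] = codes

    n_distract = rng.poisson(config.distractor_mean, size=n)
    distractor_flat = _pick_codes(rng, list(DISTRACTOR_POOL), int(n_distract.sum()))
    emit_cols = list(emitted.values())
    dx_lists: list[tuple[str, ...]] = []
    pos = 0
    for i in range(n):
        row = [col[i] for col in emit_cols if col[i] is not None]
        if z515[i]:
            row.append("Z515")
        k = n_distract[i]
        row.extend(distractor_flat[pos: pos + k])
        pos += k
        dx_lists.append(tuple(row[: config.dx_cap]))

    # outcomes and survey structure ----------------------------------------
    elective = (rng.random(n) < np.vectorize(_CATEGORY_ELECTIVE_P.get)(category)).astype(float)
    los_mean = np.vectorize(_CATEGORY_LOS_MEAN.get)(category)
    los = np.round(rng.gamma(shape=1.5, scale=los_mean / 1.5, size=n), 1)
    ch_mean = np.vectorize(_CATEGORY_CHARGES_MEAN.get)(category)
    charges = np.round(rng.gamma(shape=2.0, scale=ch_mean / 2.0, size=n), 2)
    weights = rng.uniform(config.weight_low, config.weight_high, size=n)
    clusters = np.array([f"h{j:03d}" for j in rng.integers(0, config.n_clusters, n)])
    operative = rng.random(n) < config.operative_p

    # missingness injection -------------------------------------------------
    sex = pd.Series(np.where(male, "male", "female"), dtype="string")
    miss_flags = {}
    for fld in ("sex", "elective", "length_of_stay", "charges"):
        rate = config.missingness.get(fld, 0.0)
        miss_flags[fld] = rng.random(n) < rate
    sex[miss_flags["sex"]] = pd.NA
    elective[miss_flags["elective"]] = np.nan
    los[miss_flags["length_of_stay"]] = np.nan
    charges[miss_flags["charges"]] = np.nan
    has_missing = np.logical_or.reduce(list(miss_flags.values()))

    ids = np.array([f"r{i:07d}" for i in range(n)])
    records = pd.DataFrame(
        {
            "record_id": ids,
            "age": ages,
            "sex": sex,
            "dx_codes": dx_lists,
            "disposition": disposition,
            "survey_weight": weights,
            "cluster_id": clusters,
            "operative": operative,
            "elective": elective,
            "length_of_stay": los,
            "charges": charges,
        }
    )
    truth = pd.DataFrame(
        {
            "record_id": ids,
            "age": ages,
            "male": male,
            "functional_status": functional,
            "cognitive_decline": present["cognitive_decline"],
            "cancer": present["cancer"],
            "moderate_cancer_code": moderate_code,
            "mild_cancer_code": mild_code,
            "true_score": score,
            "true_category": category,
            "death_probability": p_death,
            "died": died,
            "has_missing": has_missing,
        }
    )
    for d in DEFICITS:
        truth[d] = present[d]
    truth.attrs["alpha"] = alpha
    truth.attrs["scale_c"] = config.scale_c
    return records, truth
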