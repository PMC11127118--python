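"""Re-derivation of the integerized weight table from a labeled cohort.

The instrument's weights come from a survey-weighted logistic regression of
in-hospital death on the ten RAI parameters with two interactions
(age × cancer and functional status × cognitive decline), a robust sandwich
variance (cluster-robust when a hospital/stratum identifier is supplied),
and an integerization step: each term's points are ``round(c·β)`` relative
to its reference level, floored at zero, with the interaction grids
assembled as total cell points.  The scale constant ``c`` defaults to the
auto rule mapping the smallest positive coefficient to one point.

Organisation follows statsmodels: build a :class:`FrailtyDerivationModel`
from a cohort frame, call :meth:`~FrailtyDerivationModel.fit`, and work
with the returned :class:`FrailtyDerivationResults` (coefficients, robust
standard errors, ``weight_table()``, ``c_statistic()``, ``summary()``).
Module-level functions (:func:`fit_mortality_model`, :func:`integerize`,
:func:`select_cancer_model`) expose the same operations functionally.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .calibration import CStatistic, c_statistic, net_benefit
from .cohort import AGE_BANDS, BAND_MIDPOINTS, DEFICITS, CANCER_DEFINITIONS
from .errors import SeparationError
from .scoring import WeightTable

__all__ = [
    "FrailtyDerivationModel",
    "FrailtyDerivationResults",
    "CancerModelSelection",
    "fit_mortality_model",
    "integerize",
    "auto_scale_constant",
    "select_cancer_model",
]

_REF_AGE = 18.0

_FS_TERMS = ("fs_partial", "fs_total")
_INTERACTION_TERMS = ("fs_partial:cognitive_decline", "fs_total:cognitive_decline")


def _design(cohort: pd.DataFrame, age_encoding: str) -> pd.DataFrame:
    """Build the named design matrix (without constant) from a cohort frame."""
    X = pd.DataFrame(index=cohort.index)
    age_c = cohort["age"].to_numpy(dtype=float) - _REF_AGE
    cancer = cohort["cancer"].to_numpy(dtype=bool).astype(float)
    if age_encoding == "continuous":
        X["age"] = age_c
    elif age_encoding == "categorical":
        bands = cohort["age_band"]
        for b in AGE_BANDS[1:]:
            X[f"band[{b}]"] = (bands == b).astype(float)
    else:
        raise ValueError(f"unknown age encoding {age_encoding!r}")
    X["cancer"] = cancer
    X["age:cancer"] = age_c * cancer
    X["male"] = cohort["male"].to_numpy(dtype=bool).astype(float)
    for d in DEFICITS:
        X[d] = cohort[d].to_numpy(dtype=bool).astype(float)
    fs = cohort["functional_status"]
    X["fs_partial"] = (fs == "partially_dependent").astype(float)
    X["fs_total"] = (fs == "totally_dependent").astype(float)
    cog = cohort["cognitive_decline"].to_numpy(dtype=bool).astype(float)
    X["cognitive_decline"] = cog
    X["fs_partial:cognitive_decline"] = X["fs_partial"] * cog
    X["fs_total:cognitive_decline"] = X["fs_total"] * cog
    return X


class FrailtyDerivationModel:
    """Survey-weighted logistic mortality model over the RAI parameters.

    Parameters
    ----------
    cohort
        Analysis-ready cohort frame (see :func:`raicd.cohort.build_cohort`)
        with complete covariates and a ``died`` column.
    age_encoding
        ``"continuous"`` (default): age in years enters linearly, and the
        age grid is later tabulated at band midpoints.  ``"categorical"``:
        one dummy per 5-year band (the age × cancer interaction stays
        continuous in both encodings).
    weight_col, cluster_col
        Column names for survey weights and the optional cluster
        identifier; clusters switch the sandwich variance to cluster-robust.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        age_encoding: str = "continuous",
        weight_col: str | None = "survey_weight",
        cluster_col: str | None = None,
    ) -> None:
        self.cohort = cohort
        self.age_encoding = age_encoding
        self.endog = cohort["died"].to_numpy(dtype=float)
        if self.endog.min() == self.endog.max():
            raise SeparationError("outcome has a single class; nothing to fit")
        w = (
            cohort[weight_col].to_numpy(dtype=float)
            if weight_col and weight_col in cohort
            else np.ones(len(cohort))
        )
        # survey weights enter as relative frequencies: normalizing to mean 1
        # leaves every estimate unchanged but keeps the effective sample size
        # (and hence the sandwich variance) on the scale of the actual n
        self.weights = w * (len(w) / w.sum())
        self.groups = (
            cohort[cluster_col].to_numpy()
            if cluster_col and cluster_col in cohort
            else None
        )
        X = _design(cohort, age_encoding)
        # guard degenerate columns: a zero-variance covariate cannot be
        # estimated and is dropped with a warning (its points become 0)
        keep = []
        self.dropped: list[str] = []
        for col in X.columns:
            if np.ptp(X[col].to_numpy()) == 0.0:
                self.dropped.append(col)
            else:
                keep.append(col)
        if self.dropped:
            warnings.warn(
                f"dropping zero-variance covariates: {self.dropped}", stacklevel=2
            )
        self.exog = sm.add_constant(X[keep], has_constant="add")

    def fit(self, cov_type: str | None = None) -> "FrailtyDerivationResults":
        """Fit by IRLS maximum likelihood with a robust sandwich variance.

        ``cov_type`` defaults to ``"cluster"`` when a cluster column was
        given, else the heteroskedasticity-robust ``"HC1"``.

        Raises
        ------
        SeparationError
            If a covariate perfectly separates the outcome (the offending
            term is named).
        """
        if cov_type is None:
            cov_type = "cluster" if self.groups is not None else "HC1"
        cov_kwds = {"groups": self.groups} if cov_type == "cluster" else None
        glm = sm.GLM(
            self.endog,
            self.exog,
            family=sm.families.Binomial(),
            freq_weights=self.weights,
        )
        try:
            with warnings.catch_warnings():
                warnings.filterwarnings("ignore", message=".*[Pp]erfect separation.*")
                warnings.filterwarnings(
                    "ignore", message=".*cov_type not fully supported.*"
                )
                res = glm.fit(cov_type=cov_type, cov_kwds=cov_kwds)
        except PerfectSeparationError as exc:
            raise SeparationError(f"perfect separation in mortality model: {exc}") from exc
        params = pd.Series(res.params, index=self.exog.columns)
        big = params.drop("const").abs()
        if big.max() > 15.0:
            raise SeparationError(
                f"term {big.idxmax()!r} appears to separate the outcome "
                f"(|beta| = {big.max():.1f})"
            )
        return FrailtyDerivationResults(self, res, cov_type)


@dataclass
class FrailtyDerivationResults:
    """Fitted mortality model: coefficients, robust SEs and integerization."""

    model: FrailtyDerivationModel
    _res: object
    cov_type: str

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._res.params, index=self.model.exog.columns)

    @property
    def bse(self) -> pd.Series:
        """Robust (sandwich) standard errors."""
        return pd.Series(self._res.bse, index=self.model.exog.columns)

    def _beta(self, name: str) -> float:
        return float(self.params.get(name, 0.0))

    # -- integerization ----------------------------------------------------
    @property
    def auto_c(self) -> float:
        return auto_scale_constant(self.params)

    def weight_table(self, c: float | None = None) -> WeightTable:
        """Integerize the coefficients into a :class:`WeightTable`.

        Each term's points are ``round(c·β)`` relative to its reference
        level (age 18, female, no deficits, independent without cognitive
        decline); interaction grids are assembled as total cell points.
        Negative assembled points are floored at 0 with a warning, keeping
        the all-non-negative table structure.
        """
        if c is None:
            c = self.auto_c
        if not c > 0:
            raise ValueError(f"scale constant c must be positive, got {c}")
        p = self.params

        def pts(x: float, label: str) -> int:
            v = int(np.rint(c * x))
            if v < 0:
                warnings.warn(
                    f"negative fitted points ({v}) for {label}; floored at 0",
                    stacklevel=3,
                )
                return 0
            return v

        b_cancer = self._beta("cancer")
        b_axc = self._beta("age:cancer")
        age_cancer: dict[str, tuple[int, int]] = {}
        for band, mid in zip(AGE_BANDS, BAND_MIDPOINTS):
            delta = mid - _REF_AGE
            if self.model.age_encoding == "continuous":
                b_age = self._beta("age") * delta
            else:
                b_age = self._beta(f"band[{band}]")
            wo = pts(b_age, f"band {band}")
            wc = pts(b_age + b_cancer + b_axc * delta, f"band {band} with cancer")
            age_cancer[band] = (wo, wc)

        b_cog = self._beta("cognitive_decline")
        fc: dict[str, tuple[int, int]] = {"independent": (0, pts(b_cog, "cognitive decline"))}
        for level, term, iterm in (
            ("partially_dependent", "fs_partial", "fs_partial:cognitive_decline"),
            ("totally_dependent", "fs_total", "fs_total:cognitive_decline"),
        ):
            b_fs = self._beta(term)
            fc[level] = (
                pts(b_fs, level),
                pts(b_fs + b_cog + self._beta(iterm), f"{level} with cognitive decline"),
            )

        return WeightTable(
            age_cancer=age_cancer,
            male_points=pts(self._beta("male"), "male"),
            deficit_points={d: pts(self._beta(d), d) for d in DEFICITS},
            function_cognition=fc,
            version=f"derived-c{c:g}",
        )

    # -- diagnostics -------------------------------------------------------
    def linear_predictor(self) -> np.ndarray:
        return np.asarray(self.model.exog.to_numpy() @ self.params.to_numpy())

    def c_statistic(self, n_boot: int = 0, seed: int = 0) -> CStatistic:
        """In-sample weighted C statistic of the fitted linear predictor."""
        return c_statistic(
            self.linear_predictor(),
            self.model.endog.astype(bool),
            self.model.weights,
            n_boot=n_boot,
            seed=seed,
        )

    def predicted_risk(self) -> np.ndarray:
        return np.asarray(self._res.predict())

    def report(self, c: float | None = None) -> dict:
        """Machine-readable derivation report."""
        c_used = self.auto_c if c is None else c
        return {
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "robust_se": {k: float(v) for k, v in self.bse.items()},
            "cov_type": self.cov_type,
            "scale_constant": float(c_used),
            "c_statistic": float(self.c_statistic().estimate),
            "dropped_covariates": list(self.model.dropped),
            "weight_table": self.weight_table(c_used).to_dict(),
        }

    def report_json(self, c: float | None = None, **kwargs) -> str:
        return json.dumps(self.report(c), indent=2, **kwargs)

    def summary(self) -> str:
        tab = pd.DataFrame({"beta": self.params, "robust_se": self.bse})
        tab["z"] = tab["beta"] / tab["robust_se"]
        cs = self.c_statistic()
        head = (
            "Frailty mortality model (weighted logistic, "
            f"{self.cov_type} sandwich variance)\n"
            f"n = {len(self.model.endog)}, weighted deaths = "
            f"{self.model.weights[self.model.endog.astype(bool)].sum():.0f}, "
            f"C statistic = {cs.estimate:.3f}\n"
        )
        return head + tab.to_string(float_format=lambda v: f"{v: .4f}")


def auto_scale_constant(params: pd.Series) -> float:
    """The auto rule for c: map the smallest positive coefficient to 1 point.

    ``c = 1/min positive beta`` over all non-intercept terms; e.g. a minimum
    positive coefficient of 0.05 gives c = 20.
    """
    betas = params.drop("const", errors="ignore")
    positive = betas[betas > 0]
    if positive.empty:
        raise ValueError("no positive coefficient to anchor the scale constant")
    return float(1.0 / positive.min())


def fit_mortality_model(
    cohort: pd.DataFrame,
    age_encoding: str = "continuous",
    weight_col: str | None = "survey_weight",
    cluster_col: str | None = None,
    cov_type: str | None = None,
) -> FrailtyDerivationResults:
    """Functional wrapper: build the model and fit it in one call."""
    return FrailtyDerivationModel(
        cohort, age_encoding=age_encoding, weight_col=weight_col,
        cluster_col=cluster_col,
    ).fit(cov_type=cov_type)


def integerize(results: FrailtyDerivationResults, c: float | None = None) -> WeightTable:
    """Integerize fitted coefficients into a weight table (see
    :meth:`FrailtyDerivationResults.weight_table`)."""
    return results.weight_table(c)


# -- cancer-definition model selection ------------------------------------

@dataclass
class CancerModelSelection:
    chosen: str
    report: pd.DataFrame
    results: dict[str, FrailtyDerivationResults] = field(repr=False, default_factory=dict)


def select_cancer_model(
    cohort: pd.DataFrame,
    variants: tuple[str, ...] = ("severe", "severe+moderate", "all"),
    threshold_probabilities: tuple[float, ...] = (0.02, 0.05, 0.10),
    age_encoding: str = "continuous",
    weight_col: str | None = "survey_weight",
) -> CancerModelSelection:
    """Fit one mortality model per cancer-definition variant and pick one.

    ``cohort`` must carry the full ``cancer_tier`` information (build it
    with ``cancer_definition="all"``); each variant redefines the cancer
    indicator as membership of its tier set.  Variants are compared on the
    C statistic, ties broken by mean decision-curve net benefit over
    ``threshold_probabilities``, then by declared order.
    """
    if len(variants) < 1:
        raise ValueError("at least one variant required")
    rows = []
    fitted: dict[str, FrailtyDerivationResults] = {}
    for variant in variants:
        tiers = CANCER_DEFINITIONS[variant]
        df = cohort.copy()
        df["cancer"] = df["cancer_tier"].map(
            lambda t: t is not None and t in tiers
        ).astype(bool)
        res = fit_mortality_model(df, age_encoding=age_encoding, weight_col=weight_col)
        fitted[variant] = res
        risk = res.predicted_risk()
        y = res.model.endog.astype(bool)
        w = res.model.weights
        nbs = {
            f"nb@{pt:g}": net_benefit(risk >= pt, y, pt, weights=w).net_benefit
            for pt in threshold_probabilities
        }
        rows.append(
            {"variant": variant, "c_statistic": res.c_statistic().estimate, **nbs}
        )
    report = pd.DataFrame(rows)
    nb_cols = [c for c in report.columns if c.startswith("nb@")]
    report["mean_net_benefit"] = report[nb_cols].mean(axis=1)
    best = report.sort_values(
        by=["c_statistic", "mean_net_benefit"], ascending=False, kind="stable"
    ).iloc[0]["variant"]
    return CancerModelSelection(chosen=str(best), report=report, results=fitted)
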