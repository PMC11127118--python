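"""Calibration of the integer score against observed mortality.

Everything downstream of a scored cohort lives here:

* :func:`projected_mortality_curve` — logistic fit of death on the integer
  score, giving the smoothed ("projected") mortality p̂(k) at each integer;
* :func:`threshold_scan` — the per-integer performance table (observed and
  cumulative proportions plus confusion-matrix statistics treating
  score >= k as the positive call);
* :func:`derive_thresholds` — the mortality-ratio stratification rules:
  frailty starts at the first integer whose projected mortality reaches
  twice the overall observed mortality, very frail at four times, and the
  robust/normal boundary at the last integer below the overall mortality;
* :func:`c_statistic` — survey-weighted concordance with bootstrap CI;
* :func:`net_benefit` / :func:`convergent_validity` /
  :func:`outcomes_by_category` — decision-curve points, Spearman rank
  agreement with external frailty scores, and the category-stratified
  outcome summary.

The :class:`ScoreCalibration` model object bundles the full workflow and
returns a :class:`ScoreCalibrationResults` with a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit, logit

from .errors import CalibrationError
from .scoring import CATEGORIES, CategoryThresholds, categorize_array

__all__ = [
    "ProjectionModel",
    "CalibrationTable",
    "DecisionCurvePoint",
    "CStatistic",
    "SpearmanResult",
    "ThresholdDerivation",
    "projected_mortality_curve",
    "threshold_scan",
    "build_calibration_table",
    "derive_thresholds",
    "c_statistic",
    "net_benefit",
    "convergent_validity",
    "outcomes_by_category",
    "ScoreCalibration",
    "ScoreCalibrationResults",
]

_Z = 1.959963984540054  # two-sided 95% normal quantile


def _as_weights(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError("weights must align with the data")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    return w


def effective_n(weights: np.ndarray) -> float:
    """Kish effective sample size (Σw)²/Σw²."""
    s = weights.sum()
    return float(s * s / np.square(weights).sum())


def weighted_proportion_ci(p: float, n_eff: float) -> tuple[float, float]:
    """Logit-transformed normal-approximation CI for a weighted proportion."""
    if not (0.0 < p < 1.0) or n_eff <= 0:
        return (float("nan"), float("nan"))
    se = 1.0 / np.sqrt(n_eff * p * (1.0 - p))
    lo, hi = logit(p) - _Z * se, logit(p) + _Z * se
    return (float(expit(lo)), float(expit(hi)))


# -- projected mortality ---------------------------------------------------

@dataclass
class ProjectionModel:
    """Logistic fit of death on the integer score: p̂(k) = expit(a + b·k)."""

    intercept: float
    slope: float
    cov: np.ndarray | None = None

    def predict(self, k) -> np.ndarray:
        return expit(self.intercept + self.slope * np.asarray(k, dtype=float))

    def predict_ci(self, k) -> tuple[np.ndarray, np.ndarray]:
        """Delta-method 95% CI on the probability scale (NaN without cov)."""
        k = np.asarray(k, dtype=float)
        eta = self.intercept + self.slope * k
        if self.cov is None:
            nan = np.full_like(eta, np.nan)
            return nan, nan
        var = (
            self.cov[0, 0]
            + 2.0 * k * self.cov[0, 1]
            + np.square(k) * self.cov[1, 1]
        )
        se = np.sqrt(var)
        return expit(eta - _Z * se), expit(eta + _Z * se)


def projected_mortality_curve(scores, deaths, weights=None) -> ProjectionModel:
    """Weighted logistic fit of death on score as a single covariate.

    Raises
    ------
    CalibrationError
        With fewer than two distinct scores or a single-class outcome.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(deaths, dtype=float)
    w = _as_weights(weights, len(s))
    if np.unique(s).size < 2:
        raise CalibrationError("projection needs at least two distinct scores")
    if y.min() == y.max():
        raise CalibrationError("projection needs both outcome classes present")
    X = sm.add_constant(s)
    # weights as relative frequencies (mean 1) so the covariance reflects
    # the actual sample size rather than the weighted population size
    w_rel = w * (len(w) / w.sum())
    fit = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w_rel).fit()
    return ProjectionModel(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        cov=np.asarray(fit.cov_params()),
    )


# -- per-integer threshold scan -------------------------------------------

def threshold_scan(scores, deaths, weights=None, max_score: int | None = None) -> pd.DataFrame:
    """Per-integer performance table over k = 0 .. max attainable score.

    For each integer k the positive call is ``score >= k``.  All counts are
    survey-weighted.  Ratios with zero denominators are reported as NaN
    (undefined), never as 0.  Columns: ``k, n_at_k, observed_mortality``
    (with logit-normal CI), ``cum_proportion`` (weighted P(score <= k)),
    the four weighted confusion cells and sensitivity, specificity, PPV,
    NPV, F1 and MCC.
    """
    s = np.asarray(scores)
    if not np.issubdtype(s.dtype, np.integer):
        s_int = np.asarray(np.rint(s), dtype=int)
        if not np.allclose(s, s_int):
            raise ValueError("scores must be integers")
        s = s_int
    if (s < 0).any():
        raise ValueError("scores must be non-negative")
    y = np.asarray(deaths, dtype=bool)
    w = _as_weights(weights, len(s))
    kmax = int(max_score) if max_score is not None else int(s.max(initial=0))
    nbins = kmax + 1
    s_cl = np.minimum(s, kmax)

    w_at = np.bincount(s_cl, weights=w, minlength=nbins)
    wd_at = np.bincount(s_cl[y], weights=w[y], minlength=nbins)
    W, D = w.sum(), w[y].sum()

    # cumulative from above: weighted mass with score >= k
    w_ge = np.cumsum(w_at[::-1])[::-1]
    wd_ge = np.cumsum(wd_at[::-1])[::-1]

    tp = wd_ge
    fp = np.maximum(w_ge - wd_ge, 0.0)
    fn = np.maximum(D - tp, 0.0)
    tn = np.maximum((W - D) - fp, 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        obs = np.where(w_at > 0, wd_at / np.where(w_at > 0, w_at, 1.0), np.nan)
        sens = np.where(D > 0, tp / D, np.nan)
        spec = np.where(W - D > 0, tn / (W - D), np.nan)
        ppv = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        npv = np.where(tn + fn > 0, tn / (tn + fn), np.nan)
        f1_den = 2 * tp + fp + fn
        f1 = np.where(f1_den > 0, 2 * tp / f1_den, np.nan)
        mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = np.where(mcc_den > 0, (tp * tn - fp * fn) / mcc_den, np.nan)

    n_eff_at = np.zeros(nbins)
    w2_at = np.bincount(s_cl, weights=np.square(w), minlength=nbins)
    nz = w2_at > 0
    n_eff_at[nz] = np.square(w_at[nz]) / w2_at[nz]
    ci = np.array(
        [weighted_proportion_ci(p, ne) if np.isfinite(p) else (np.nan, np.nan)
         for p, ne in zip(obs, n_eff_at)]
    )

    return pd.DataFrame(
        {
            "k": np.arange(nbins),
            "n_at_k": w_at,
            "observed_mortality": obs,
            "observed_ci_low": ci[:, 0],
            "observed_ci_high": ci[:, 1],
            "cum_proportion": np.cumsum(w_at) / W,
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "tn": tn,
            "sensitivity": sens,
            "specificity": spec,
            "ppv": ppv,
            "npv": npv,
            "f1": f1,
            "mcc": mcc,
        }
    )


@dataclass
class CalibrationTable:
    """The per-integer table plus the projection and overall mortality."""

    table: pd.DataFrame
    overall_mortality: float
    projection: ProjectionModel | None = None

    def to_csv(self, path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, index=False)


def build_calibration_table(
    scores, deaths, weights=None, max_score: int | None = None, project: bool = True
) -> CalibrationTable:
    """Assemble the full calibration table (scan + projected mortality)."""
    w = _as_weights(weights, len(np.asarray(scores)))
    y = np.asarray(deaths, dtype=bool)
    tab = threshold_scan(scores, deaths, weights=w, max_score=max_score)
    m_bar = float(w[y].sum() / w.sum())
    proj = None
    if project:
        proj = projected_mortality_curve(scores, deaths, weights=w)
        tab["projected_mortality"] = proj.predict(tab["k"].to_numpy())
        lo, hi = proj.predict_ci(tab["k"].to_numpy())
        tab["projected_ci_low"] = lo
        tab["projected_ci_high"] = hi
    return CalibrationTable(table=tab, overall_mortality=m_bar, projection=proj)


# -- stratification rules --------------------------------------------------

@dataclass(frozen=True)
class ThresholdDerivation:
    thresholds: CategoryThresholds
    frail_threshold: int
    very_frail_threshold: int
    robust_bound: int
    f1_at_frail: float
    mcc_at_frail: float
    basis: str = "projected"
    frail_multiple: float = 2.0
    very_frail_multiple: float = 4.0


def derive_thresholds(
    table: CalibrationTable,
    frail_multiple: float = 2.0,
    very_frail_multiple: float = 4.0,
    basis: str = "projected",
) -> ThresholdDerivation:
    """Derive the four-category thresholds by mortality-ratio rules.

    * frailty threshold: smallest integer k whose projected mortality
      reaches ``frail_multiple`` (default 2x) times the overall observed
      mortality m̄;
    * very-frail threshold: smallest k reaching ``very_frail_multiple``
      (default 4x) times m̄;
    * robust bound: largest k with projected mortality strictly below m̄
      (the robust/normal boundary is one above it).

    ``basis="observed"`` applies the same rules to the observed per-integer
    mortality instead of the smoothed curve.  The F1 and MCC values at the
    frailty threshold are reported alongside.

    Raises
    ------
    CalibrationError
        If the projection slope is not positive or a rule is unsatisfiable
        within the attainable score range.
    """
    m_bar = table.overall_mortality
    tab = table.table
    k = tab["k"].to_numpy()
    if basis == "projected":
        if table.projection is None:
            raise CalibrationError("calibration table carries no projection model")
        if not table.projection.slope > 0:
            raise CalibrationError("projected mortality is not increasing (slope <= 0)")
        p = table.projection.predict(k)
    elif basis == "observed":
        p = tab["observed_mortality"].to_numpy()
    else:
        raise ValueError(f"unknown basis {basis!r}")

    with np.errstate(invalid="ignore"):
        frail_ix = np.flatnonzero(p >= frail_multiple * m_bar)
        vf_ix = np.flatnonzero(p >= very_frail_multiple * m_bar)
        robust_ix = np.flatnonzero(p < m_bar)
    if frail_ix.size == 0 or vf_ix.size == 0 or robust_ix.size == 0:
        raise CalibrationError(
            "threshold rule unsatisfiable within the attainable score range "
            f"(m̄={m_bar:.4f}, multiples {frail_multiple}x/{very_frail_multiple}x)"
        )
    frail = int(k[frail_ix[0]])
    very_frail = int(k[vf_ix[0]])
    robust_bound = int(k[robust_ix[-1]])
    if not (robust_bound + 1 <= frail <= very_frail - 1):
        raise CalibrationError(
            f"degenerate thresholds: robust bound {robust_bound}, frail {frail}, "
            f"very frail {very_frail}"
        )
    row = tab.loc[tab["k"] == frail].iloc[0]
    return ThresholdDerivation(
        thresholds=CategoryThresholds(
            robust_below=robust_bound + 1,
            normal_upper=frail - 1,
            frail_upper=very_frail - 1,
        ),
        frail_threshold=frail,
        very_frail_threshold=very_frail,
        robust_bound=robust_bound,
        f1_at_frail=float(row["f1"]),
        mcc_at_frail=float(row["mcc"]),
        basis=basis,
        frail_multiple=frail_multiple,
        very_frail_multiple=very_frail_multiple,
    )


# -- discrimination --------------------------------------------------------

@dataclass(frozen=True)
class CStatistic:
    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int


def _concordance(scores: np.ndarray, deaths: np.ndarray, weights: np.ndarray) -> float:
    """Weighted concordance probability; tied scores count 1/2."""
    d, s_mask = deaths, ~deaths
    ds, dw = scores[d], weights[d]
    ss, sw = scores[s_mask], weights[s_mask]
    order = np.argsort(ss, kind="stable")
    ss, sw = ss[order], sw[order]
    csw = np.concatenate([[0.0], np.cumsum(sw)])
    lo = np.searchsorted(ss, ds, side="left")
    hi = np.searchsorted(ss, ds, side="right")
    below = csw[lo]
    tied = csw[hi] - csw[lo]
    num = float(np.sum(dw * (below + 0.5 * tied)))
    den = float(dw.sum() * sw.sum())
    return num / den


def c_statistic(
    scores, deaths, weights=None, n_boot: int = 200, seed: int = 0
) -> CStatistic:
    """Weighted C statistic (concordance / AUROC) with a bootstrap CI.

    The CI uses a stratified bootstrap (deaths and survivors resampled
    separately, ``n_boot`` resamples, percentile interval); pass
    ``n_boot=0`` to skip it.

    Raises
    ------
    CalibrationError
        If only one outcome class is present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(deaths, dtype=bool)
    w = _as_weights(weights, len(s))
    if y.all() or (~y).all():
        raise CalibrationError("C statistic needs both outcome classes present")
    est = _concordance(s, y, w)
    if n_boot <= 0:
        return CStatistic(est, float("nan"), float("nan"), 0)
    rng = np.random.default_rng(seed)
    di, si = np.flatnonzero(y), np.flatnonzero(~y)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        rd = di[rng.integers(0, di.size, di.size)]
        rs = si[rng.integers(0, si.size, si.size)]
        idx = np.concatenate([rd, rs])
        yy = np.zeros(idx.size, dtype=bool)
        yy[: rd.size] = True
        reps[b] = _concordance(s[idx], yy, w[idx])
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return CStatistic(est, float(lo), float(hi), n_boot)


# -- decision curve --------------------------------------------------------

@dataclass(frozen=True)
class DecisionCurvePoint:
    threshold_probability: float
    net_benefit: float


def net_benefit(calls, deaths, threshold_probability: float, weights=None) -> DecisionCurvePoint:
    """Decision-curve net benefit NB = TP/n − (FP/n)·p_t/(1−p_t)."""
    p_t = float(threshold_probability)
    if not (0.0 < p_t < 1.0):
        raise ValueError(f"threshold probability must lie in (0, 1), got {p_t}")
    c = np.asarray(calls, dtype=bool)
    y = np.asarray(deaths, dtype=bool)
    w = _as_weights(weights, len(c))
    n = w.sum()
    tp = w[c & y].sum()
    fp = w[c & ~y].sum()
    nb = tp / n - (fp / n) * p_t / (1.0 - p_t)
    return DecisionCurvePoint(p_t, float(nb))


# -- convergent validity ---------------------------------------------------

@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    ci_low: float
    ci_high: float
    n: int


def convergent_validity(score_a, score_b, n_boot: int = 200, seed: int = 0) -> SpearmanResult:
    """Spearman rank correlation (average ranks for ties) with bootstrap CI.

    A constant input vector makes the correlation undefined; the result is
    then reported as NaN rather than raising.
    """
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be paired 1-d arrays")
    n = a.size
    if n < 3:
        raise ValueError("Spearman correlation needs n >= 3 pairs")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        return SpearmanResult(float("nan"), float("nan"), float("nan"), n)
    rho = float(stats.spearmanr(a, b).statistic)
    if n_boot <= 0:
        return SpearmanResult(rho, float("nan"), float("nan"), n)
    rng = np.random.default_rng(seed)
    reps = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            r = stats.spearmanr(a[idx], b[idx]).statistic
            if np.isfinite(r):
                reps.append(r)
    if not reps:
        return SpearmanResult(rho, float("nan"), float("nan"), n)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return SpearmanResult(rho, float(lo), float(hi), n)


# -- category-stratified outcomes -----------------------------------------

def outcomes_by_category(
    cohort: pd.DataFrame,
    scores=None,
    thresholds: CategoryThresholds | None = None,
) -> pd.DataFrame:
    """Weighted outcome summary per frailty category.

    ``cohort`` must carry ``died`` and ``survey_weight`` and may carry
    ``elective``, ``length_of_stay`` and ``charges`` (missing values are
    dropped per field).  ``scores`` defaults to the cohort's ``score``
    column.  Empty categories are emitted with n = 0 and NaN statistics.
    """
    s = np.asarray(scores if scores is not None else cohort["score"])
    cats = categorize_array(s, thresholds)
    w = cohort["survey_weight"].to_numpy(dtype=float)
    died = cohort["died"].to_numpy(dtype=bool)
    W = w.sum()
    rows = []
    for cat in CATEGORIES:
        m = cats == cat
        wc = w[m]
        nw = wc.sum()
        row: dict[str, float | str] = {
            "category": cat,
            "n_weighted": nw,
            "pct": 100.0 * nw / W if W > 0 else np.nan,
        }
        if nw == 0:
            row.update(
                mortality_pct=np.nan, mortality_ci_low=np.nan,
                mortality_ci_high=np.nan, elective_pct=np.nan,
                mean_los=np.nan, se_los=np.nan,
                mean_charges=np.nan, se_charges=np.nan,
            )
            rows.append(row)
            continue
        p = wc[died[m]].sum() / nw
        lo, hi = weighted_proportion_ci(p, effective_n(wc))
        row["mortality_pct"] = 100.0 * p
        row["mortality_ci_low"] = 100.0 * lo
        row["mortality_ci_high"] = 100.0 * hi
        for col, mean_name, se_name, scale in (
            ("elective", "elective_pct", None, 100.0),
            ("length_of_stay", "mean_los", "se_los", 1.0),
            ("charges", "mean_charges", "se_charges", 1.0),
        ):
            mean, se = np.nan, np.nan
            if col in cohort:
                x = pd.to_numeric(cohort.loc[m, col], errors="coerce").to_numpy(dtype=float)
                ok = np.isfinite(x)
                if ok.any():
                    ww, xx = wc[ok], x[ok]
                    mean = float(np.sum(ww * xx) / ww.sum())
                    ne = effective_n(ww)
                    var = float(np.sum(ww * np.square(xx - mean)) / ww.sum())
                    se = float(np.sqrt(var / ne)) if ne > 1 else np.nan
            row[mean_name] = scale * mean
            if se_name is not None:
                row[se_name] = se
        rows.append(row)
    return pd.DataFrame(rows)


# -- model-object workflow -------------------------------------------------

class ScoreCalibration:
    """Calibration workflow for a scored cohort, statsmodels-style.

    Parameters
    ----------
    scores, deaths, weights
        Integer scores, death indicators and optional survey weights.
    max_score
        Upper end of the scan range (default: the table maximum observed).
    """

    def __init__(self, scores, deaths, weights=None, max_score: int | None = None):
        self.scores = np.asarray(scores)
        self.deaths = np.asarray(deaths, dtype=bool)
        self.weights = _as_weights(weights, len(self.scores))
        self.max_score = max_score

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, score_col: str = "score",
                    max_score: int | None = None) -> "ScoreCalibration":
        return cls(
            cohort[score_col].to_numpy(),
            cohort["died"].to_numpy(),
            cohort["survey_weight"].to_numpy(),
            max_score=max_score,
        )

    def fit(
        self,
        frail_multiple: float = 2.0,
        very_frail_multiple: float = 4.0,
        basis: str = "projected",
        n_boot: int = 200,
        seed: int = 0,
    ) -> "ScoreCalibrationResults":
        table = build_calibration_table(
            self.scores, self.deaths, self.weights, max_score=self.max_score
        )
        derivation = derive_thresholds(
            table, frail_multiple=frail_multiple,
            very_frail_multiple=very_frail_multiple, basis=basis,
        )
        cstat = c_statistic(
            self.scores, self.deaths, self.weights, n_boot=n_boot, seed=seed
        )
        return ScoreCalibrationResults(self, table, derivation, cstat)


@dataclass
class ScoreCalibrationResults:
    model: ScoreCalibration
    calibration: CalibrationTable
    threshold_derivation: ThresholdDerivation
    cstat: CStatistic

    @property
    def thresholds(self) -> CategoryThresholds:
        return self.threshold_derivation.thresholds

    def summary(self) -> str:
        d = self.threshold_derivation
        m = self.calibration.overall_mortality
        proj = self.calibration.projection
        lines = [
            "Score calibration summary",
            "=" * 60,
            f"overall weighted mortality  m̄ = {100 * m:.2f}%",
            (
                f"projection  p̂(k) = expit({proj.intercept:+.4f} {proj.slope:+.4f}·k)"
                if proj is not None else "projection  (none)"
            ),
            f"C statistic                 {self.cstat.estimate:.3f} "
            f"(95% CI, {self.cstat.ci_low:.3f}-{self.cstat.ci_high:.3f})",
            f"frailty threshold           {d.frail_threshold} "
            f"({d.basis} mortality >= {d.frail_multiple:g}x m̄; F1 {d.f1_at_frail:.3f}, "
            f"MCC {d.mcc_at_frail:.3f})",
            f"very-frail threshold        {d.very_frail_threshold}",
            f"robust scores               < {d.thresholds.robust_below}",
            f"categories                  robust <{d.thresholds.robust_below} | "
            f"normal {d.thresholds.robust_below}-{d.thresholds.normal_upper} | "
            f"frail {d.thresholds.normal_upper + 1}-{d.thresholds.frail_upper} | "
            f"very frail >{d.thresholds.frail_upper}",
        ]
        return "\n".join(lines)
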