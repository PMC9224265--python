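"""Cohort-level diagnostic statistics.

Implements the statistical layer used to judge biomarkers for separating
true progression (TP) from treatment-related changes (TRC):

* non-parametric (empirical) ROC analysis, AUC via the Mann-Whitney
  statistic (ties count 1/2) and its DeLong structural-components variance;
* DeLong-type two-sided comparison of two ROC curves (paired or unpaired);
* Youden-optimal cut-points with a seeded, outcome-stratified bootstrap
  percentile interval for the threshold;
* Wilson score intervals for sensitivity / specificity / accuracy;
* the Mann-Whitney-Wilcoxon rank-sum U test (exact for small untied samples);
* chi-square / Fisher tests of proportions;
* a logistic-regression combiner of TAC score, IDH status and TBR values;
* a Table-style per-stratum cohort summary.

Orientation: a biomarker may indicate TP through *higher* values (TBRs, LR
probability) or *lower* values (TTP).  Internally "lower" negates the values,
so every routine reasons in a single direction; reported thresholds are
mapped back to the original scale.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RocResult",
    "CutoffResult",
    "ProportionCI",
    "LrFit",
    "empirical_roc",
    "compare_roc",
    "youden_optimum",
    "cutoff_ci",
    "wilson_ci",
    "mwu_test",
    "proportion_test",
    "fit_logistic",
    "summarize_cohort",
]

POSITIVE_LABEL = "TP"
NEGATIVE_LABEL = "TRC"


def _binary_labels(labels) -> np.ndarray:
    """Map outcome labels to booleans (TP -> True)."""
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    out = np.zeros(arr.shape, dtype=bool)
    for i, v in enumerate(arr.ravel()):
        if v in (POSITIVE_LABEL, 1, True):
            out.ravel()[i] = True
        elif v in (NEGATIVE_LABEL, 0, False):
            out.ravel()[i] = False
        else:
            raise ValueError(f"unknown outcome label {v!r}")
    return out


def _oriented(values, labels, orientation: str):
    v = np.asarray(values, dtype=float)
    y = _binary_labels(labels)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D arrays")
    if np.any(np.isnan(v)):
        raise ValueError("values contain missing entries; exclude them first")
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    if orientation == "higher":
        return v, y
    if orientation == "lower":
        return -v, y
    raise ValueError("orientation must be 'higher' or 'lower'")


# --------------------------------------------------------------------------
# ROC / AUC / DeLong
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve with its Mann-Whitney AUC and DeLong SD."""

    auc: float
    auc_sd: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # oriented scale, one per interior ROC point
    orientation: str


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components.

    ``V10[i]`` is the fraction of negatives below positive i (ties 1/2);
    ``V01[j]`` the fraction of positives above negative j.
    """
    diff = pos[:, None] - neg[None, :]
    ge = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return ge.mean(axis=1), ge.mean(axis=0)


def _auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    var = 0.0
    if pos.size > 1:
        var += float(np.var(v10, ddof=1)) / pos.size
    if neg.size > 1:
        var += float(np.var(v01, ddof=1)) / neg.size
    return auc, var


def empirical_roc(values, labels, orientation: str = "higher") -> RocResult:
    """Empirical ROC over all distinct thresholds.

    AUC equals the normalised Mann-Whitney statistic (tied pairs count 1/2)
    and also the trapezoidal area under the returned points, which run from
    (0, 0) to (1, 1) with both coordinates non-decreasing.  ``auc_sd`` is the
    DeLong structural-components standard deviation.
    """
    v, y = _oriented(values, labels, orientation)
    pos, neg = v[y], v[~y]
    auc, var = _auc_variance(pos, neg)

    thresholds = np.unique(v)[::-1]  # descending: most conservative first
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append(float((pos >= t).mean()))
        fpr.append(float((neg >= t).mean()))
    # the final threshold (minimum value) already yields (1, 1)
    return RocResult(
        auc=auc,
        auc_sd=math.sqrt(var),
        fpr=np.asarray(fpr),
        tpr=np.asarray(tpr),
        thresholds=thresholds,
        orientation=orientation,
    )


def compare_roc(a, b, paired: bool = True) -> float:
    """Two-sided p-value for the difference of two empirical AUCs.

    ``a`` and ``b`` are ``(values, labels, orientation)`` triples (orientation
    optional, default "higher").  Paired comparisons require identical label
    vectors in identical patient order and use the DeLong covariance of the
    paired structural components; unpaired comparisons sum the two variances.
    A degenerate zero-variance, zero-difference comparison returns p = 1.
    """

    def unpack(x):
        if len(x) == 2:
            return _oriented(x[0], x[1], "higher")
        return _oriented(x[0], x[1], x[2])

    va, ya = unpack(a)
    vb, yb = unpack(b)
    if paired:
        if va.shape != vb.shape or not np.array_equal(ya, yb):
            raise ValueError("paired comparison requires shared labels and patient order")
        pos_a, neg_a = va[ya], va[~ya]
        pos_b, neg_b = vb[ya], vb[~ya]
        v10a, v01a = _placements(pos_a, neg_a)
        v10b, v01b = _placements(pos_b, neg_b)
        auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
        m, n = pos_a.size, neg_a.size
        var = 0.0
        if m > 1:
            s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
            var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        if n > 1:
            s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
            var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    else:
        auc_a, var_a = _auc_variance(va[ya], va[~ya])
        auc_b, var_b = _auc_variance(vb[yb], vb[~yb])
        var = var_a + var_b

    delta = auc_a - auc_b
    if var <= 0:
        return 1.0 if delta == 0 else 0.0
    z = delta / math.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


# --------------------------------------------------------------------------
# Youden cut-point
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ProportionCI:
    """A proportion with its Wilson 95% interval."""

    estimate: float
    ci_low: float
    ci_high: float
    successes: int
    trials: int


@dataclass(frozen=True)
class CutoffResult:
    """Youden-optimal operating point of a biomarker."""

    threshold: float  # original scale
    threshold_observed: float  # nearest observed biomarker value
    threshold_ci95: tuple[float, float] | None
    sensitivity: ProportionCI
    specificity: ProportionCI
    accuracy: ProportionCI
    youden_j: float
    orientation: str  # classification rule: "higher" => value >= threshold -> TP


def wilson_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, clipped to [0, 1]."""
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials and trials >= 1")
    lo, hi = proportion_confint(successes, trials, alpha=1 - level, method="wilson")
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


def _proportion(successes: int, trials: int) -> ProportionCI:
    lo, hi = wilson_ci(successes, trials)
    return ProportionCI(successes / trials, lo, hi, int(successes), int(trials))


def _youden_scan(v: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Best threshold on the oriented scale.

    Candidates are midpoints between consecutive sorted unique values plus
    +/- infinity; the rule ``value >= threshold`` predicts TP.  Ties in J are
    broken toward higher sensitivity, then the lower threshold — since
    sensitivity is non-increasing in the threshold, this is the lowest
    candidate attaining the maximal J.  Returns (threshold, sens, spec).
    """
    order = np.argsort(v, kind="mergesort")
    vs, ys = v[order], y[order]
    uniq, first = np.unique(vs, return_index=True)
    n1 = int(ys.sum())
    n0 = ys.size - n1
    pos_per = np.add.reduceat(ys.astype(int), first)
    neg_per = np.add.reduceat((~ys).astype(int), first)
    pos_le = np.cumsum(pos_per)  # positives with value <= uniq[i]
    neg_le = np.cumsum(neg_per)
    # candidate k = 0: -inf; k in 1..K-1: midpoint between uniq[k-1], uniq[k];
    # k = K: +inf
    K = uniq.size
    cand = np.empty(K + 1)
    cand[0] = -np.inf
    cand[1:K] = 0.5 * (uniq[:-1] + uniq[1:])
    cand[K] = np.inf
    pos_below = np.concatenate([[0], pos_le])  # positives strictly below cand[k]
    neg_below = np.concatenate([[0], neg_le])
    sens = (n1 - pos_below) / n1
    spec = neg_below / n0
    j = sens + spec - 1.0
    k = int(np.argmax(j))  # first (lowest-threshold) maximiser
    return float(cand[k]), float(sens[k]), float(spec[k])


def youden_optimum(
    values,
    labels,
    orientation: str = "higher",
    n_boot: int = 0,
    seed: int | None = None,
) -> CutoffResult:
    """Youden-optimal cut-point with Wilson intervals at the optimum.

    With ``n_boot > 0`` a stratified bootstrap percentile interval for the
    threshold is attached (see :func:`cutoff_ci`).
    """
    v, y = _oriented(values, labels, orientation)
    thr, sens, spec = _youden_scan(v, y)
    n1 = int(y.sum())
    n0 = y.size - n1
    tp = round(sens * n1)
    tn = round(spec * n0)
    pred_pos = v >= thr
    acc = int((pred_pos == y).sum())

    orig = np.asarray(values, dtype=float)
    thr_orig = thr if orientation == "higher" else -thr
    if np.isfinite(thr_orig):
        nearest = float(orig[np.argmin(np.abs(orig - thr_orig))])
    else:
        nearest = float(orig.min() if thr_orig < 0 else orig.max())

    ci = None
    if n_boot:
        ci = cutoff_ci(values, labels, orientation, n_boot=n_boot, seed=seed)
    return CutoffResult(
        threshold=float(thr_orig),
        threshold_observed=nearest,
        threshold_ci95=ci,
        sensitivity=_proportion(tp, n1),
        specificity=_proportion(tn, n0),
        accuracy=_proportion(acc, y.size),
        youden_j=sens + spec - 1.0,
        orientation=orientation,
    )


def cutoff_ci(
    values,
    labels,
    orientation: str = "higher",
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Bootstrap 95% percentile interval for the Youden-optimal threshold.

    Resampling is stratified within each outcome class, so every resample
    keeps both classes; seeded and reproducible.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    v, y = _oriented(values, labels, orientation)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    thresholds = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate(
            [
                rng.choice(pos_idx, size=pos_idx.size, replace=True),
                rng.choice(neg_idx, size=neg_idx.size, replace=True),
            ]
        )
        thresholds[b] = _youden_scan(v[take], y[take])[0]
    finite = thresholds[np.isfinite(thresholds)]
    if finite.size == 0:
        raise ValueError("all bootstrap thresholds degenerate (infinite)")
    lo, hi = np.percentile(finite, [2.5, 97.5])
    if orientation == "lower":
        lo, hi = -hi, -lo
    return float(lo), float(hi)


# --------------------------------------------------------------------------
# rank / proportion tests
# --------------------------------------------------------------------------

MwuResult = namedtuple("MwuResult", ["statistic", "pvalue", "method"])
ProportionTestResult = namedtuple("ProportionTestResult", ["statistic", "pvalue", "method"])


def mwu_test(x, y) -> MwuResult:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum U test.

    Exact null distribution when the combined sample has at most 20
    observations and no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    exact = combined.size <= 20 and np.unique(combined).size == combined.size
    if exact:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return MwuResult(float(res.statistic), float(res.pvalue), "exact")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return MwuResult(float(res.statistic), float(res.pvalue), "asymptotic")


def proportion_test(table, method: str = "chisq") -> ProportionTestResult:
    """Test of association in a 2x2 count table.

    ``chisq`` is the uncorrected Pearson chi-square; ``fisher`` the two-sided
    Fisher exact test (statistic = odds ratio).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a non-negative 2x2 count table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("degenerate margins")
    if method == "chisq":
        chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
        return ProportionTestResult(float(chi2), float(p), "chisq")
    if method == "fisher":
        oddsratio, p = sps.fisher_exact(t, alternative="two-sided")
        return ProportionTestResult(float(oddsratio), float(p), "fisher")
    raise ValueError("method must be 'chisq' or 'fisher'")


# --------------------------------------------------------------------------
# logistic regression combiner
# --------------------------------------------------------------------------

KNOWN_PREDICTORS = ("tac_score", "idh", "tbr_mean", "tbr_max")


@dataclass
class LrFit:
    """Results of the logistic-regression biomarker combiner."""

    predictors: tuple[str, ...]
    params: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    odds_ratios: dict[str, tuple[float, float, float]]  # OR, CI low, CI high
    pvalues: dict[str, float]
    predicted_prob: np.ndarray
    converged: bool
    separation_flag: bool
    nobs: int

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.params:
            lo, hi = self.conf_int[name]
            orr, olo, ohi = self.odds_ratios[name]
            rows.append(
                {
                    "term": name,
                    "coef": self.params[name],
                    "ci_low": lo,
                    "ci_high": hi,
                    "odds_ratio": orr,
                    "or_ci_low": olo,
                    "or_ci_high": ohi,
                    "pvalue": self.pvalues[name],
                }
            )
        return pd.DataFrame(rows)


def _design_matrix(cohort: pd.DataFrame, predictors: tuple[str, ...]):
    cols = {}
    for p in predictors:
        if p == "idh":
            cols["idh_mutant"] = _idh_indicator(cohort["idh"])
        elif p in KNOWN_PREDICTORS:
            cols[p] = cohort[p].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown predictor {p!r}")
    X = pd.DataFrame(cols, index=cohort.index) if cols else pd.DataFrame(index=cohort.index)
    X.insert(0, "intercept", 1.0)
    return X


def _idh_indicator(col) -> np.ndarray:
    arr = np.asarray(col)
    out = np.zeros(arr.shape, dtype=float)
    for i, v in enumerate(arr):
        if v == "mutant":
            out[i] = 1.0
        elif v != "wildtype":
            raise ValueError(f"unknown IDH value {v!r}")
    return out


def fit_logistic(
    cohort: pd.DataFrame, predictors: tuple[str, ...] = ("tac_score", "idh", "tbr_mean")
) -> LrFit:
    """Maximum-likelihood logistic regression of outcome (TP = 1) on biomarkers.

    Newton-Raphson fit (tolerance 1e-8, at most 100 iterations) with Wald
    95% intervals; odds ratios are ``exp(coefficient)``.  Complete or
    quasi-separation (diverging coefficients) is flagged and reported with
    ``converged = False``.  An empty predictor tuple fits the intercept-only
    model.  A rank-deficient (collinear) design raises.
    """
    y = _binary_labels(cohort["outcome"]).astype(float)
    if y.all() or not y.any():
        raise ValueError("outcome is constant; logistic fit undefined")
    if any(cohort[c].isna().any() for c in set(predictors) & set(cohort.columns)):
        raise ValueError("missing values in predictor columns; exclude them first")
    X = _design_matrix(cohort, tuple(predictors))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear predictor matrix")

    model = sm.Logit(y, X)
    separation = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=0)
            converged = bool(res.mle_retvals.get("converged", True))
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
            separation = True
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(method="lbfgs", maxiter=500, disp=0)
    if np.abs(res.params.to_numpy()).max() > 15:
        separation = True
        converged = False

    ci = res.conf_int(alpha=0.05)
    params = {k: float(v) for k, v in res.params.items()}
    conf = {k: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in params}
    def _exp(x: float) -> float:
        try:
            return math.exp(x)
        except OverflowError:  # separated fits can have huge Wald bounds
            return math.inf

    odds = {k: (_exp(params[k]), _exp(conf[k][0]), _exp(conf[k][1])) for k in params}
    return LrFit(
        predictors=tuple(predictors),
        params=params,
        conf_int=conf,
        odds_ratios=odds,
        pvalues={k: float(v) for k, v in res.pvalues.items()},
        predicted_prob=np.asarray(res.predict(X)),
        converged=converged,
        separation_flag=separation,
        nobs=int(y.size),
    )


# --------------------------------------------------------------------------
# cohort summary
# --------------------------------------------------------------------------

#: diagnostic variables and the direction in which they indicate TP
VARIABLE_ORIENTATIONS = {
    "tbr_max": "higher",
    "tbr_mean": "higher",
    "ttp_min": "lower",
    "lr_prob": "higher",
}


def _group_stats(x: np.ndarray) -> dict:
    return {
        "n": int(x.size),
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "range": (float(np.min(x)), float(np.max(x))),
    }


def summarize_cohort(
    cohort: pd.DataFrame,
    stratum: str = "all",
    lr_predictors: tuple[str, ...] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Per-stratum diagnostic summary of the biomarker cohort.

    For each variable (TBRmax, TBRmean, TTP and the logistic-regression
    probability): group statistics by outcome, the Youden threshold with its
    bootstrap CI, sensitivity / specificity / accuracy with Wilson intervals
    at the optimum, and the MWU p-value.  Records with missing values are
    excluded listwise per analysis with a logged count.  A stratum with a
    single outcome class has its diagnostic block omitted with a warning.

    ``stratum`` is ``all``, ``IDHm`` or ``IDHwt``.  ``lr_predictors``
    defaults to TAC score + IDH + TBRmean overall and TAC score + TBRmean
    within IDH strata.
    """
    if stratum == "all":
        sub = cohort
        default_lr = ("tac_score", "idh", "tbr_mean")
    elif stratum in ("IDHm", "IDHwt"):
        key = "mutant" if stratum == "IDHm" else "wildtype"
        sub = cohort[cohort["idh"] == key]
        default_lr = ("tac_score", "tbr_mean")
    else:
        raise ValueError("stratum must be 'all', 'IDHm' or 'IDHwt'")
    if sub.empty:
        raise ValueError(f"stratum {stratum!r} is empty")
    lr_predictors = default_lr if lr_predictors is None else tuple(lr_predictors)

    y = _binary_labels(sub["outcome"])
    n = int(len(sub))
    n_tp = int(y.sum())
    n_trc = n - n_tp
    counts = {
        "n": n,
        "TP": n_tp,
        "TRC": n_trc,
        "IDHm": int((sub["idh"] == "mutant").sum()),
        "IDHwt": int((sub["idh"] == "wildtype").sum()),
        "male": int((sub["sex"] == "male").sum()) if "sex" in sub else None,
        "female": int((sub["sex"] == "female").sum()) if "sex" in sub else None,
    }
    proportions = {
        "tp_pct": 100.0 * n_tp / n,
        "trc_pct": 100.0 * n_trc / n,
        "idhm_pct": 100.0 * counts["IDHm"] / n,
        "idhwt_pct": 100.0 * counts["IDHwt"] / n,
    }
    if counts["male"] is not None:
        proportions["male_pct"] = 100.0 * counts["male"] / n
        proportions["female_pct"] = 100.0 * counts["female"] / n

    report: dict = {
        "stratum": stratum,
        "counts": counts,
        "proportions": proportions,
        "variables": {},
        "warnings": [],
    }

    degenerate = n_tp == 0 or n_trc == 0
    if degenerate:
        msg = f"stratum {stratum}: single outcome class; diagnostic block omitted"
        logger.warning(msg)
        report["warnings"].append(msg)
        return report

    # logistic-regression probabilities on rows complete in the LR columns
    lr_cols = [c for c in lr_predictors if c != "idh"] + (
        ["idh"] if "idh" in lr_predictors else []
    )
    lr_complete = sub.dropna(subset=lr_cols) if lr_cols else sub
    lr_prob = pd.Series(np.nan, index=sub.index)
    lr_block = None
    try:
        fit = fit_logistic(lr_complete, lr_predictors)
        lr_prob.loc[lr_complete.index] = fit.predicted_prob
        lr_block = {
            "predictors": list(fit.predictors),
            "converged": fit.converged,
            "separation_flag": fit.separation_flag,
            "terms": fit.summary_frame().to_dict(orient="records"),
        }
    except ValueError as exc:
        msg = f"stratum {stratum}: logistic fit skipped ({exc})"
        logger.warning(msg)
        report["warnings"].append(msg)
    report["logistic_regression"] = lr_block

    data = sub.assign(lr_prob=lr_prob)
    for var, orientation in VARIABLE_ORIENTATIONS.items():
        if var not in data.columns:
            continue
        col = data[var]
        keep = col.notna()
        dropped = int((~keep).sum())
        if dropped:
            msg = f"stratum {stratum}, {var}: {dropped} record(s) excluded listwise"
            logger.warning(msg)
            report["warnings"].append(msg)
        vals = col[keep].to_numpy(dtype=float)
        lab = y[keep.to_numpy()]
        if lab.all() or not lab.any() or vals.size == 0:
            report["warnings"].append(
                f"stratum {stratum}, {var}: single class after exclusions; block omitted"
            )
            continue
        roc = empirical_roc(vals, lab, orientation)
        cut = youden_optimum(vals, lab, orientation, n_boot=n_boot, seed=seed)
        mwu = mwu_test(vals[lab], vals[~lab])
        report["variables"][var] = {
            "orientation": orientation,
            "by_outcome": {
                "TP": _group_stats(vals[lab]),
                "TRC": _group_stats(vals[~lab]),
            },
            "auc": roc.auc,
            "auc_sd": roc.auc_sd,
            "threshold": cut.threshold,
            "threshold_observed": cut.threshold_observed,
            "threshold_ci95": cut.threshold_ci95,
            "sensitivity": cut.sensitivity.__dict__,
            "specificity": cut.specificity.__dict__,
            "accuracy": cut.accuracy.__dict__,
            "youden_j": cut.youden_j,
            "mwu_p": mwu.pvalue,
        }
    return report
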