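"""Cohort-level evaluation: 2x2 diagnostics, ROC cut-offs, zone rates,
odds ratios and logistic regression.

All proportions are carried as exact numerator/denominator pairs; a zero
denominator makes the metric explicitly undefined rather than silently
zero.  Percentages render to one decimal, half-up.  ROC machinery uses
scikit-learn for the empirical curve and AUC, with a DeLong variance
estimator (written here; optional stratified bootstrap fallback) for the
confidence interval, and Youden's J for cut-off selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

from .exceptions import InvalidSpecificationError, UndefinedStatisticError

__all__ = [
    "ContingencyTable2x2",
    "MetricValue",
    "DiagnosticResult",
    "RocResult",
    "OddsRatioResult",
    "LogisticModelResult",
    "diagnostic_values",
    "zone_rates",
    "roc_analysis",
    "odds_ratio",
    "logistic_model",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, as clinical tables print."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricValue:
    """A proportion carried as an exact count ratio.

    `value` is numerator/denominator, or None when the denominator is
    zero (the metric is then flagged undefined with a reason instead of
    silently reporting 0).
    """

    numerator: int
    denominator: int
    reason: str = ""

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def value(self) -> float | None:
        return self.numerator / self.denominator if self.defined else None

    @property
    def percent(self) -> float | None:
        """Percentage rounded to one decimal, half-up (None if undefined)."""
        return round_half_up(100.0 * self.value) if self.defined else None

    def __str__(self) -> str:
        if not self.defined:
            return f"undefined ({self.reason or 'zero denominator'})"
        return f"{self.percent}% ({self.numerator}/{self.denominator})"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """TP/FP/FN/TN counts (positive test = slow perfusion,
    positive outcome = anastomotic complication)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidSpecificationError("2x2 counts must be non-negative")
        if self.total == 0:
            raise InvalidSpecificationError("2x2 table must have total > 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, predicted, outcome) -> "ContingencyTable2x2":
        p = np.asarray(predicted, dtype=bool)
        o = np.asarray(outcome, dtype=bool)
        if p.shape != o.shape:
            raise InvalidSpecificationError("predictions and outcomes differ in length")
        return cls(
            tp=int(np.sum(p & o)),
            fp=int(np.sum(p & ~o)),
            fn=int(np.sum(~p & o)),
            tn=int(np.sum(~p & ~o)),
        )


@dataclass(frozen=True)
class DiagnosticResult:
    """Sensitivity/specificity/PPV/NPV/accuracy with exact count ratios."""

    sensitivity: MetricValue
    specificity: MetricValue
    ppv: MetricValue
    npv: MetricValue
    accuracy: MetricValue
    table: ContingencyTable2x2

    def to_dict(self) -> dict:
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            m: MetricValue = getattr(self, name)
            out[name] = {
                "percent": m.percent,
                "numerator": m.numerator,
                "denominator": m.denominator,
                "defined": m.defined,
            }
        return out

    def summary(self) -> str:
        lines = ["Diagnostic values"]
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            lines.append(f"  {name:<12} {getattr(self, name)}")
        return "\n".join(lines)


def diagnostic_values(table: ContingencyTable2x2) -> DiagnosticResult:
    """Table of diagnostic proportions from a 2x2 contingency table.

    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), PPV = tp/(tp+fp),
    NPV = tn/(tn+fn), accuracy = (tp+tn)/total; each carried exactly and
    flagged undefined when its denominator is zero.
    """
    t = table
    return DiagnosticResult(
        sensitivity=MetricValue(t.tp, t.tp + t.fn, "no positive outcomes"),
        specificity=MetricValue(t.tn, t.tn + t.fp, "no negative outcomes"),
        ppv=MetricValue(t.tp, t.tp + t.fp, "no positive tests"),
        npv=MetricValue(t.tn, t.tn + t.fn, "no negative tests"),
        accuracy=MetricValue(t.tp + t.tn, t.total, "empty table"),
        table=t,
    )


def zone_rates(zones, outcomes) -> dict:
    """Per-zone complication fraction with exact counts.

    `zones` may hold any hashable labels (risk zones, categories, ...);
    an empty zone yields an undefined rate with count 0 shown.
    Returns a dict label -> MetricValue, ordered by first appearance
    (or by zone severity when labels are RiskZone members).
    """
    zones = list(zones)
    outcomes = np.asarray(list(outcomes), dtype=int)
    if len(zones) != outcomes.size:
        raise InvalidSpecificationError("zones and outcomes differ in length")
    labels = []
    for z in zones:
        if z not in labels:
            labels.append(z)
    try:
        labels.sort(key=lambda z: z.severity)
    except AttributeError:
        pass
    out = {}
    for label in labels:
        sel = np.array([z == label for z in zones])
        out[label] = MetricValue(
            int(outcomes[sel].sum()), int(sel.sum()), "empty zone"
        )
    return out


# ----------------------------------------------------------------------
# ROC
# ----------------------------------------------------------------------

def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from positive/negative scores.

    Uses the midrank formulation: the placement values V10 (per positive)
    and V01 (per negative) estimate P(X > Y) with tie correction; the
    variance combines their empirical variances across the two samples.
    """
    m, n = pos.size, neg.size
    allv = np.concatenate([pos, neg])
    rank_all = sps.rankdata(allv)          # midranks over pooled sample
    rank_pos = sps.rankdata(pos)
    rank_neg = sps.rankdata(neg)
    auc = (rank_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    return float(auc), float(var)


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC analysis of one perfusion factor.

    `auc` is reported in the raw "larger value => complication"
    orientation, matching how published tables print protective factors
    (slope) with AUC below 0.5; `auc_directed` is oriented by the stated
    `direction` and is >= 0.5 for an informative factor.  `chosen_cutoff`
    maximizes Youden's J on the directed scores, placed midway between
    the bracketing observed values.
    """

    auc: float
    auc_directed: float
    direction: str
    ci_low: float
    ci_high: float
    p_value: float
    chosen_cutoff: float
    youden_j: float
    curve: pd.DataFrame = field(repr=False)
    n_pos: int = 0
    n_neg: int = 0
    ci_method: str = "delong"

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise InvalidSpecificationError("auc out of [0, 1]")
        if not self.ci_low <= self.auc <= self.ci_high:
            raise InvalidSpecificationError("CI must bracket the AUC")

    @property
    def auc_flipped(self) -> float:
        return 1.0 - self.auc

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_directed": self.auc_directed,
            "auc_flipped": self.auc_flipped,
            "direction": self.direction,
            "ci": [self.ci_low, self.ci_high],
            "p_value": self.p_value,
            "cutoff": self.chosen_cutoff,
            "youden_j": self.youden_j,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def roc_analysis(
    values,
    outcomes,
    direction: str = "higher",
    ci_method: str = "delong",
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | None = None,
) -> RocResult:
    """Empirical ROC with tie-aware AUC, DeLong CI and Youden cut-off.

    Parameters
    ----------
    direction : str
        "higher" when larger values indicate complication (time factors),
        "lower" when larger values are protective (slope).
    ci_method : str
        "delong" (default) or "bootstrap" (stratified, seeded).
    """
    values = np.asarray(values, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    if values.shape != outcomes.shape:
        raise InvalidSpecificationError("values and outcomes differ in length")
    if not set(np.unique(outcomes)) <= {0, 1}:
        raise InvalidSpecificationError("outcomes must be binary 0/1")
    n_pos = int(outcomes.sum())
    n_neg = int(outcomes.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError(
            "AUC undefined: both outcome classes must be present"
        )
    if direction not in ("higher", "lower"):
        raise InvalidSpecificationError("direction must be 'higher' or 'lower'")

    scores = values if direction == "higher" else -values
    auc_dir = float(roc_auc_score(outcomes, scores))
    _, var = _delong_auc_variance(scores[outcomes == 1], scores[outcomes == 0])
    se = float(np.sqrt(var))
    z = sps.norm.ppf(1 - alpha / 2.0)
    if ci_method == "delong":
        lo_dir, hi_dir = auc_dir - z * se, auc_dir + z * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        ipos, ineg = np.nonzero(outcomes == 1)[0], np.nonzero(outcomes == 0)[0]
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.concatenate(
                [rng.choice(ipos, n_pos), rng.choice(ineg, n_neg)]
            )
            boots[b] = roc_auc_score(outcomes[idx], scores[idx])
        lo_dir, hi_dir = np.quantile(boots, [alpha / 2.0, 1 - alpha / 2.0])
    else:
        raise InvalidSpecificationError("ci_method must be 'delong' or 'bootstrap'")
    lo_dir, hi_dir = max(0.0, min(lo_dir, auc_dir)), min(1.0, max(hi_dir, auc_dir))
    p_value = float(2.0 * sps.norm.sf(abs(auc_dir - 0.5) / se)) if se > 0 else (
        0.0 if auc_dir != 0.5 else 1.0
    )

    fpr, tpr, thr = roc_curve(outcomes, scores)
    j = tpr - fpr
    best = int(np.argmax(j))
    cut_score = float(thr[best])
    uniq = np.unique(scores)
    below = uniq[uniq < cut_score]
    if below.size:  # midway between the bracketing observed values
        cut_score = 0.5 * (cut_score + float(below[-1]))
    cutoff = cut_score if direction == "higher" else -cut_score

    if direction == "higher":
        auc_raw, lo, hi = auc_dir, lo_dir, hi_dir
    else:
        auc_raw, lo, hi = 1.0 - auc_dir, 1.0 - hi_dir, 1.0 - lo_dir
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold_score": thr})
    return RocResult(
        auc=auc_raw,
        auc_directed=auc_dir,
        direction=direction,
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=p_value,
        chosen_cutoff=float(cutoff),
        youden_j=float(j[best]),
        curve=curve,
        n_pos=n_pos,
        n_neg=n_neg,
        ci_method=ci_method,
    )


# ----------------------------------------------------------------------
# odds ratios and logistic regression
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class OddsRatioResult:
    """2x2 odds ratio with a Wald log-scale confidence interval."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or: float
    se_log_or: float
    corrected: bool = False  # Haldane-Anscombe 0.5 applied to a zero cell

    def to_dict(self) -> dict:
        return {
            "odds_ratio": self.odds_ratio,
            "ci": [self.ci_low, self.ci_high],
            "corrected": self.corrected,
        }


def odds_ratio(
    table: ContingencyTable2x2, alpha: float = 0.05
) -> OddsRatioResult:
    """OR = (tp*tn)/(fp*fn) with Wald CI on the log scale.

    A single zero cell triggers the Haldane-Anscombe 0.5 correction to
    every cell (flagged); a fully empty margin (two zero cells in a row
    or column) leaves the OR undefined.
    """
    t = table
    margins = (t.tp + t.fn, t.fp + t.tn, t.tp + t.fp, t.fn + t.tn)
    if 0 in margins:
        raise UndefinedStatisticError(
            "odds ratio undefined: an entire row or column of the 2x2 "
            "table is zero"
        )
    cells = np.array([t.tp, t.fp, t.fn, t.tn], dtype=float)
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    log_or = float(np.log(a * d / (b * c)))
    se = float(np.sqrt((1.0 / cells).sum()))
    z = sps.norm.ppf(1 - alpha / 2.0)
    return OddsRatioResult(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        log_or=log_or,
        se_log_or=se,
        corrected=corrected,
    )


@dataclass(frozen=True)
class LogisticModelResult:
    """Per-covariate odds ratios from a maximum-likelihood logistic fit.

    `table` has one row per covariate: OR, Wald CI bounds, coefficient,
    SE, p-value.  `converged` / `separation` report fit diagnostics --
    with few events and strong predictors quasi-separation is likely and
    manifests as enormous ORs with very wide CIs.
    """

    table: pd.DataFrame
    converged: bool
    separation: bool
    llf: float
    n_obs: int
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "covariates": self.table.to_dict(orient="index"),
            "converged": self.converged,
            "separation": self.separation,
            "n_obs": self.n_obs,
        }


def logistic_model(
    X,
    outcomes,
    names: list[str] | None = None,
    alpha: float = 0.05,
    add_intercept: bool = True,
) -> LogisticModelResult:
    """Binary logistic regression fitted by IRLS (Newton) via statsmodels.

    Rank-deficient designs raise; perfect or quasi-separation is detected
    and reported diagnostically rather than returned as silent estimates.
    """
    import statsmodels.api as sm

    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(outcomes).size != 1:
        X = X.T
    y = np.asarray(outcomes, dtype=float)
    if X.shape[0] != y.size:
        raise InvalidSpecificationError("design and outcomes differ in length")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise InvalidSpecificationError("outcomes must be binary 0/1")
    if y.size - X.shape[1] < 2:
        raise InvalidSpecificationError(
            "need at least 2 more observations than covariates"
        )
    names = names or [f"x{i + 1}" for i in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise InvalidSpecificationError("names length does not match covariates")
    design = sm.add_constant(X, has_constant="add") if add_intercept else X
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise InvalidSpecificationError(
            "design matrix is rank deficient (duplicated or collinear covariates)"
        )

    import warnings as _warnings

    separation = False
    message = ""
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, design).fit(disp=0, method="newton", maxiter=100)
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception as exc:  # perfect separation raises in statsmodels
            separation = True
            message = f"fit failed: {exc}"
            fit = None
            converged = False
    if fit is not None:
        for w in caught:
            if "separation" in str(w.message).lower():
                separation = True
                message = str(w.message)
        # quasi-separation heuristic: implausibly large coefficients or SEs
        if np.any(np.abs(fit.params) > 15) or np.any(fit.bse > 100):
            separation = True
            message = message or "quasi-separation suspected (huge coefficients)"

    z = sps.norm.ppf(1 - alpha / 2.0)
    rows = {}
    offset = 1 if add_intercept else 0
    for i, name in enumerate(names):
        if fit is None:
            rows[name] = dict(
                odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                coef=np.nan, se=np.nan, p_value=np.nan,
            )
            continue
        b, se = float(fit.params[i + offset]), float(fit.bse[i + offset])
        rows[name] = dict(
            odds_ratio=float(np.exp(b)),
            ci_low=float(np.exp(b - z * se)),
            ci_high=float(np.exp(b + z * se)),
            coef=b,
            se=se,
            p_value=float(fit.pvalues[i + offset]),
        )
    return LogisticModelResult(
        table=pd.DataFrame.from_dict(rows, orient="index"),
        converged=converged,
        separation=separation,
        llf=float(fit.llf) if fit is not None else np.nan,
        n_obs=int(y.size),
        message=message,
    )


# ----------------------------------------------------------------------
# thin conveniences for cohort summary tables (not this package's
# contribution -- plain scipy wrappers kept for reproducing group
# comparisons on synthetic cohorts)
# ----------------------------------------------------------------------

def t_test_groups(values, outcomes) -> tuple[float, float]:
    """Two-sided independent-samples t test; returns (t, p)."""
    values = np.asarray(values, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    res = sps.ttest_ind(values[outcomes == 1], values[outcomes == 0])
    return float(res.statistic), float(res.pvalue)


def chi2_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table; returns (chi2, p)."""
    arr = np.array([[table.tp, table.fn], [table.fp, table.tn]])
    res = sps.chi2_contingency(arr, correction=False)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation; returns (rho, p)."""
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
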