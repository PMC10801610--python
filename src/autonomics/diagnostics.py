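"""Diagnostic prediction of ME/CFS from variability features.

Logistic regression with stepwise variable selection (forward by score
tests, backward by Wald tests), collinearity (VIF) and calibration
(Hosmer-Lemeshow) diagnostics, and ROC cutoff selection by both the
maximum-Youden and the sensitivity-equals-specificity conventions.

Two fixed published scoring models are shipped alongside freshly fitted
ones.  Their coefficients are printed at three decimals, so probabilities
computed from them are approximate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sst
from sklearn.metrics import roc_auc_score


@dataclass
class DiagnosticModel:
    """A logistic scoring model: named coefficients plus a constant."""

    predictors: dict            # name -> coefficient B
    constant: float
    provenance: str = "fitted"  # fitted | published_model_1 | published_model_2
    pvalues: dict = field(default_factory=dict)
    conf_int: dict = field(default_factory=dict)   # name -> (lo, hi) on B
    separation: bool = False

    def __post_init__(self) -> None:
        if self.provenance == "fitted" and not self.predictors:
            # intercept-only fits keep an empty predictor set deliberately
            pass

    @property
    def odds_ratios(self) -> dict:
        """exp(B) per predictor, with 95% CI where available."""
        out = {}
        for name, b in self.predictors.items():
            ci = self.conf_int.get(name)
            out[name] = {
                "or": math.exp(b),
                "ci": (math.exp(ci[0]), math.exp(ci[1])) if ci else None,
            }
        return out


#: Fixed published multifactorial scoring presets.  Model 1 (forward
#: stepwise): total HRV power and total respiration-variability power
#: during spontaneous breathing.  Model 2 (backward Wald): LF HRV power at
#: rest, HF HRV power at 12 breaths/min and total RV power at rest.
PUBLISHED_MODEL_1 = DiagnosticModel(
    predictors={"TP_HRV_SR": -0.001, "TP_RV_SR": 0.002},
    constant=0.504,
    provenance="published_model_1",
)
PUBLISHED_MODEL_2 = DiagnosticModel(
    predictors={"LF_HRV_SR": -0.001, "HF_HRV_BR12": -0.001, "TP_RV_SR": 0.002},
    constant=0.562,
    provenance="published_model_2",
)


def predict_probability(model: DiagnosticModel, x: dict) -> float:
    """Probability of ME/CFS under the logistic link:
    ``p = 1 / (1 + exp(-(constant + sum B_i x_i)))``.

    Every model predictor must be supplied in ``x``.
    """
    missing = [k for k in model.predictors if k not in x]
    if missing:
        raise KeyError(f"missing predictors: {missing}")
    eta = model.constant + sum(b * float(x[name])
                               for name, b in model.predictors.items())
    return 1.0 / (1.0 + math.exp(-eta))


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = sm.GLM(y, sm.add_constant(X, has_constant="add"),
                     family=sm.families.Binomial()).fit()
    separated = any(issubclass(w.category, PerfectSeparationWarning)
                    for w in caught)
    res._separated = separated or bool(np.any(~np.isfinite(res.bse)))
    return res


def fit_stepwise_logistic(
    data: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    method: str = "forward",
    enter_p: float = 0.05,
    remove_p: float = 0.10,
) -> DiagnosticModel:
    """Stepwise maximum-likelihood logistic regression.

    Forward selection adds, at each step, the candidate with the smallest
    Rao score-test p-value, stopping when none falls below ``enter_p``.
    Backward elimination starts from the full model and drops the
    predictor with the largest Wald p-value until all fall below
    ``remove_p``.  Complete separation is reported on the returned model's
    ``separation`` flag rather than failing silently.
    """
    if method not in ("forward", "backward"):
        raise ValueError("method must be 'forward' or 'backward'")
    y = data[outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(data) <= len(candidates) + 5:
        raise ValueError("too few observations for the candidate set")

    if method == "forward":
        selected: list[str] = []
        while True:
            remaining = [c for c in candidates if c not in selected]
            if not remaining:
                break
            base = _fit_logit(y, data[selected]) if selected else _fit_logit(
                y, pd.DataFrame(index=data.index))
            best, best_p = None, 1.0
            for cand in remaining:
                extra = data[[cand]].to_numpy(dtype=float)
                try:
                    _, p, _ = base.score_test(exog_extra=extra)
                except Exception:
                    continue
                p = float(np.squeeze(p))
                if p < best_p:
                    best, best_p = cand, p
            if best is None or best_p >= enter_p:
                break
            selected.append(best)
    else:
        selected = list(candidates)
        while selected:
            res = _fit_logit(y, data[selected])
            wald = res.pvalues.drop("const")
            worst = wald.idxmax()
            if wald[worst] <= remove_p:
                break
            selected.remove(worst)

    res = _fit_logit(y, data[selected] if selected else pd.DataFrame(index=data.index))
    params = res.params
    ci = res.conf_int()
    return DiagnosticModel(
        predictors={name: float(params[name]) for name in selected},
        constant=float(params["const"]),
        provenance="fitted",
        pvalues={name: float(res.pvalues[name]) for name in selected},
        conf_int={name: (float(ci.loc[name, 0]), float(ci.loc[name, 1]))
                  for name in selected},
        separation=bool(res._separated),
    )


def vif(design: pd.DataFrame) -> dict:
    """Variance inflation factors: ``VIF_j = 1 / (1 - R2_j)`` from an OLS
    regression of predictor j on the remaining predictors (with
    intercept).  Exact collinearity reports ``inf``."""
    cols = list(design.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs at least 2 predictors")
    if len(design) <= len(cols):
        raise ValueError("VIF needs more observations than predictors")
    out = {}
    for j, col in enumerate(cols):
        yj = design[col].to_numpy(dtype=float)
        Xj = sm.add_constant(design.drop(columns=[col]), has_constant="add")
        r2 = sm.OLS(yj, Xj).fit().rsquared
        out[col] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def hosmer_lemeshow(
    probabilities: np.ndarray,
    outcomes: np.ndarray,
    n_groups: int = 10,
) -> tuple[float, float]:
    """Hosmer-Lemeshow goodness-of-fit test on deciles of predicted risk.

    The chi-square sums ``(O - E)^2 / E`` over the event and non-event
    cells of each risk group, with ``df = g - 2``.  Groups that come out
    empty (heavily tied probabilities) are merged with their neighbour and
    the degrees of freedom adjusted; ``n_groups`` must exceed 2.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if n_groups <= 2:
        raise ValueError("n_groups must exceed 2 (df = g - 2 would be 0)")
    if len(p) < 2 * n_groups:
        raise ValueError("need at least 2 observations per risk group")
    order = np.argsort(p, kind="mergesort")
    p, y = p[order], y[order]
    edges = np.linspace(0, len(p), n_groups + 1).astype(int)
    obs_e, exp_e, obs_n, exp_n = [], [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            continue
        obs_e.append(float(np.sum(y[lo:hi])))
        exp_e.append(float(np.sum(p[lo:hi])))
        obs_n.append(float(hi - lo) - obs_e[-1])
        exp_n.append(float(hi - lo) - exp_e[-1])
    # merge groups whose expected counts vanish into the previous group
    i = 1
    while i < len(exp_e):
        if min(exp_e[i], exp_n[i]) < 1e-9 or min(exp_e[i - 1], exp_n[i - 1]) < 1e-9:
            for lst in (obs_e, exp_e, obs_n, exp_n):
                lst[i - 1] += lst.pop(i)
        else:
            i += 1
    g = len(exp_e)
    if g <= 2:
        raise ValueError("too few usable risk groups after merging")
    stat = sum((o - e) ** 2 / e for o, e in zip(obs_e, exp_e) if e > 0)
    stat += sum((o - e) ** 2 / e for o, e in zip(obs_n, exp_n) if e > 0)
    df = g - 2
    return float(stat), float(sst.chi2.sf(stat, df))


@dataclass
class RocSummary:
    """ROC analysis of one score against a binary label."""

    auc: float
    auc_ci: tuple[float, float]
    cutoff_youden: float
    se_youden: float
    sp_youden: float
    cutoff_balanced: float
    se_balanced: float
    sp_balanced: float
    orientation: str = "higher"  # which direction of the raw score marks a case

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")
        for v in (self.se_youden, self.sp_youden, self.se_balanced, self.sp_balanced):
            if not 0.0 <= v <= 1.0:
                raise ValueError("Se/Sp must lie in [0, 1]")


def _delong_ci(scores: np.ndarray, labels: np.ndarray, auc: float,
               level: float = 0.95) -> tuple[float, float]:
    """DeLong variance of the AUC via placement values."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    v10 = np.array([(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / n for x in pos])
    v01 = np.array([(np.sum(pos > x) + 0.5 * np.sum(pos == x)) / m for x in neg])
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = sst.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return (max(0.0, auc - half), min(1.0, auc + half))


def roc_cutoffs(scores: np.ndarray, labels: np.ndarray) -> RocSummary:
    """AUC with a DeLong 95% CI plus two cutoff conventions.

    The orientation is auto-detected so the reported AUC is at least 0.5
    (``orientation`` records whether higher or lower raw scores mark a
    case).  Candidate cutoffs are midpoints between consecutive distinct
    scores; a case is called when the oriented score is at or above the
    cutoff.  The Youden cutoff maximises Se + Sp - 1 (ties resolved toward
    higher sensitivity); the balanced cutoff minimises |Se - Sp|.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) != 2 or not set(classes) <= {0, 1}:
        raise ValueError("labels must contain both classes, coded 0/1")
    auc = float(roc_auc_score(labels, scores))
    orientation = "higher"
    oriented = scores
    sign = 1.0
    if auc < 0.5:
        orientation = "lower"
        oriented = -scores
        sign = -1.0
        auc = 1.0 - auc
    ci = _delong_ci(oriented, labels, auc)

    uniq = np.unique(oriented)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    pos = oriented[labels == 1]
    neg = oriented[labels == 0]
    best_y, best_b = None, None
    for c in candidates:
        se = float(np.mean(pos >= c))
        sp = float(np.mean(neg < c))
        youden = se + sp - 1.0
        if best_y is None or youden > best_y[0] + 1e-12 or (
                abs(youden - best_y[0]) <= 1e-12 and se > best_y[1]):
            best_y = (youden, se, sp, c)
        gap = abs(se - sp)
        if best_b is None or gap < best_b[0] - 1e-12 or (
                abs(gap - best_b[0]) <= 1e-12 and se > best_b[1]):
            best_b = (gap, se, sp, c)
    return RocSummary(
        auc=auc, auc_ci=ci,
        cutoff_youden=sign * best_y[3], se_youden=best_y[1], sp_youden=best_y[2],
        cutoff_balanced=sign * best_b[3], se_balanced=best_b[1], sp_balanced=best_b[2],
        orientation=orientation,
    )
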