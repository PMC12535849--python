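"""Cardiovascular risk score: logistic model, ROC evaluation, stratification.

The CV risk score is the linear predictor (log-odds) of a logistic
regression of an FD-phenotype outcome on the six conventional risk factors
(age, diabetes, dyslipidemia, hypertension, obesity, smoking). Subjects are
stratified into ``high``/``low`` at the empirical 75th percentile of the
score, computed once on the reference population; the score's discrimination
is summarised by a tie-corrected Mann-Whitney AUC with sensitivity and
specificity at a configurable threshold (reference default 1.92 on the
log-odds scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .errors import DataError, ModelError

__all__ = [
    "CV_PREDICTORS",
    "CVRiskModel",
    "CVRiskResults",
    "fit_cv_model",
    "cv_score_and_stratify",
    "roc_metrics",
]

CV_PREDICTORS = ("age", "diabetes", "dyslipidemia", "hypertension", "obesity", "smoking")

#: log-odds threshold at which the published score reached sens 0.77 / spec 0.70
REFERENCE_SCORE_THRESHOLD = 1.92


class CVRiskModel:
    """Logistic CV-risk model over the six conventional risk factors.

    Parameters
    ----------
    data : DataFrame with the outcome column and all predictor columns.
    outcome : name of the binary outcome used for fitting (default the
        dichotomized FD phenotype flag ``fdf_high``).
    predictors : predictor column names; default the six risk factors.
    """

    def __init__(self, data: pd.DataFrame, outcome: str = "fdf_high",
                 predictors: tuple[str, ...] = CV_PREDICTORS):
        missing = [c for c in (outcome, *predictors) if c not in data.columns]
        if missing:
            raise DataError(f"missing columns: {missing}")
        self.outcome = outcome
        self.predictors = tuple(predictors)
        frame = data[[outcome, *predictors]].astype(float)
        self.n_dropped = int(frame.isna().any(axis=1).sum())
        self.frame = frame.dropna()
        if len(self.frame) < len(predictors) + 10:
            raise DataError("too few complete-case rows to fit the CV model")

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, outcome: str = "fdf_high") -> "CVRiskModel":
        return cls(cohort, outcome=outcome)

    def fit(self) -> "CVRiskResults":
        y = self.frame[self.outcome].to_numpy()
        if np.unique(y).size < 2:
            raise ModelError("constant outcome; cannot fit the CV risk model")
        X = sm.add_constant(self.frame[list(self.predictors)], has_constant="add")
        try:
            res = sm.Logit(y, X).fit(disp=False, maxiter=200)
        except Exception as exc:  # pragma: no cover - statsmodels raises several types
            raise ModelError(
                "CV model fit failed (possible perfect separation); consider "
                f"penalization or a different outcome: {exc}"
            ) from exc
        if not np.isfinite(res.bse).all() or np.abs(res.params).max() > 30:
            raise ModelError(
                "CV model shows (quasi-)separation; consider penalization or config change"
            )
        coefficients = {"intercept": float(res.params["const"])}
        coefficients.update({p: float(res.params[p]) for p in self.predictors})
        return CVRiskResults(model=self, coefficients=coefficients, sm_results=res)


@dataclass
class CVRiskResults:
    """Fitted CV-risk score: coefficients, scoring, stratification, ROC."""

    model: CVRiskModel
    coefficients: dict[str, float]
    sm_results: object = None
    score_threshold: float = REFERENCE_SCORE_THRESHOLD
    quantile_cut: float = 0.75
    _quantile_value: float | None = field(default=None, repr=False)

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.coefficients)

    def score(self, data: pd.DataFrame) -> pd.Series:
        """Per-subject CV score = linear predictor on the log-odds scale.

        Subjects with any missing covariate get NaN (excluded from strata).
        """
        s = pd.Series(self.coefficients["intercept"], index=data.index, dtype=float)
        for p in self.model.predictors:
            s = s + self.coefficients[p] * data[p].astype(float)
        return s

    def stratify(self, data: pd.DataFrame, reference: pd.DataFrame | None = None) -> pd.Series:
        """Assign ``high``/``low`` strata at the reference 75th percentile.

        The percentile is computed once on ``reference`` (default: ``data``
        itself) and reused, so carrier subsets are cut at the population
        threshold. Stratum is ``high`` iff score > percentile (strict);
        unscorable subjects (missing covariates) come back as NaN.
        """
        scores = self.score(data)
        if self._quantile_value is None or reference is not None:
            ref_scores = self.score(reference) if reference is not None else scores
            self._quantile_value = float(np.nanquantile(ref_scores, self.quantile_cut))
        q = self._quantile_value
        valid = scores.notna()
        if valid.any() and np.nanmax(scores) <= q:
            warnings.warn("no score exceeds the percentile cut; all subjects are low-stratum")
        dropped = int((~valid).sum())
        if dropped:
            warnings.warn(f"{dropped} subjects unscorable (missing covariates); left unstratified")
        out = pd.Series(pd.NA, index=data.index, dtype="string")
        out[valid] = np.where(scores[valid] > q, "high", "low")
        return out

    def roc(self, labels, scores=None, threshold: float | None = None):
        scores = self.score(self.model.frame) if scores is None else scores
        return roc_metrics(scores, labels, self.score_threshold if threshold is None else threshold)

    def summary(self) -> str:
        lines = ["CV risk score (logistic, log-odds scale)", "-" * 42]
        res = self.sm_results
        for name, value in self.coefficients.items():
            key = "const" if name == "intercept" else name
            se = float(res.bse[key]) if res is not None else float("nan")
            lines.append(f"{name:>14s}  {value:+.4f}  (SE {se:.4f})")
        lines.append(f"{'threshold':>14s}  {self.score_threshold:.2f} (reference)")
        lines.append(f"{'quantile cut':>14s}  {self.quantile_cut:.2f}")
        lines.append(f"complete-case n = {len(self.model.frame)}, dropped = {self.model.n_dropped}")
        return "\n".join(lines)


def fit_cv_model(cohort: pd.DataFrame, outcome_spec: str = "fdf_high",
                 predictors: tuple[str, ...] = CV_PREDICTORS) -> CVRiskResults:
    """Fit the CV-risk logistic model on a cohort (spec-level convenience)."""
    return CVRiskModel(cohort, outcome=outcome_spec, predictors=predictors).fit()


def cv_score_and_stratify(results: CVRiskResults, cohort: pd.DataFrame,
                          reference: pd.DataFrame | None = None):
    """Score every subject and cut at the reference 75th percentile.

    Returns ``(scores, strata)`` Series aligned with ``cohort``.
    """
    scores = results.score(cohort)
    strata = results.stratify(cohort, reference=reference)
    return scores, strata


def roc_metrics(scores, labels, threshold: float):
    """AUC (tie-corrected Mann-Whitney) plus sensitivity/specificity at
    ``score > threshold``.

    The rank formulation AUC = (R1 - n1(n1+1)/2) / (n1 n0) with midranks
    equals the trapezoidal area under the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    keep = ~np.isnan(scores)
    scores, labels = scores[keep], labels[keep]
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ModelError("ROC requires both classes present")
    ranks = rankdata(scores)  # average ranks: tie correction
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    sensitivity = float((scores[labels == 1] > threshold).mean())
    specificity = float((scores[labels == 0] <= threshold).mean())
    return float(auc), sensitivity, specificity
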