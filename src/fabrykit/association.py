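"""Sex-matched carrier-versus-wild-type association models.

For each variant group, hemizygous males are compared with male wild-type
controls and heterozygous females with female controls (homozygous females
are excluded; controls carry no variant in any analyzed group). Binary
outcomes use maximum-likelihood logistic regression, multi-level ordinal
outcomes a proportional-odds model, and continuous traits least squares —
all adjusted for the six-covariate CV set unless a stratified design
forbids it. Intervals are reported at the 2.5/97.5 percent points of the
coefficient's sampling distribution (a standard 95% two-sided interval).
Multiple testing uses a from-scratch Benjamini-Hochberg step-up routine and
multicollinearity is screened with hand-computed variance inflation factors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import DataError, ModelError
from .phenotypes import Zygosity

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisSet",
    "AssociationResult",
    "CarrierAssociation",
    "build_analysis_set",
    "fit_logistic",
    "fit_ordinal",
    "fit_linear",
    "bh_adjust",
    "vif",
    "run_stratified",
]

ADJUSTMENT_COVARIATES = ("age", "diabetes", "dyslipidemia", "hypertension", "obesity", "smoking")


@dataclass
class AnalysisSet:
    """Cases (carriers of one group, one sex) and wild-type controls.

    ``data`` holds the stacked case/control rows with a binary ``carrier``
    column; ``excluded_homozygous`` counts homozygous females removed before
    matching.
    """

    group: str
    sex: str
    data: pd.DataFrame
    n_cases: int
    n_controls: int
    excluded_homozygous: int = 0

    @property
    def empty(self) -> bool:
        return self.n_cases == 0


@dataclass
class AssociationResult:
    """One fitted carrier-association model.

    ``effect`` is an odds ratio for logistic/ordinal fits and a slope for
    linear fits; ``ci_low``/``ci_high`` are the 2.5/97.5 percent endpoints
    on the effect's scale. ``separation`` marks fits abandoned because the
    likelihood has no finite maximum.
    """

    model_kind: str
    effect: float
    ci_low: float
    ci_high: float
    p_raw: float
    n_carriers: int
    n_controls: int
    covariates: tuple[str, ...] = ()
    p_adjusted: float | None = None
    n_dropped: int = 0
    separation: bool = False
    group: str = ""
    sex: str = ""
    stratum: str = ""
    outcome: str = ""
    group_mean_sd: tuple[float, float] | None = None
    control_mean_sd: tuple[float, float] | None = None
    notes: str = ""

    def summary(self) -> str:
        label = "OR" if self.model_kind in ("logistic", "ordinal") else "slope"
        head = f"{self.model_kind} model"
        if self.group:
            head += f" [{self.group} / {self.sex}" + (f" / {self.stratum}]" if self.stratum else "]")
        lines = [
            head,
            f"  outcome: {self.outcome or '-'}",
            f"  {label} = {self.effect:.4g}  (95% CI {self.ci_low:.4g} - {self.ci_high:.4g})",
            f"  p = {self.p_raw:.3g}" + (f", BH-adjusted p = {self.p_adjusted:.3g}" if self.p_adjusted is not None else ""),
            f"  carriers = {self.n_carriers}, controls = {self.n_controls}, dropped = {self.n_dropped}",
            f"  covariates: {', '.join(self.covariates) or 'none'}",
        ]
        if self.separation:
            lines.append("  WARNING: separation detected; interval unbounded")
        return "\n".join(lines)

    def to_row(self) -> dict:
        return {
            "group": self.group, "sex": self.sex, "stratum": self.stratum,
            "outcome": self.outcome, "model": self.model_kind,
            "effect": self.effect, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_raw": self.p_raw, "p_adjusted": self.p_adjusted,
            "n_carriers": self.n_carriers, "n_controls": self.n_controls,
            "n_dropped": self.n_dropped, "separation": self.separation,
        }


def build_analysis_set(cohort: pd.DataFrame, group: str, sex: str,
                       groups: tuple[str, ...] | None = None) -> AnalysisSet:
    """Assemble the sex-matched case/control rows for one variant group.

    Cases are hemizygous males or heterozygous females of ``group``;
    controls are same-sex subjects with zero alleles across *all* analyzed
    groups. Homozygous females are counted and excluded from both arms.
    """
    col = f"ac_{group}"
    if col not in cohort.columns:
        raise DataError(f"group {group!r} not present in cohort")
    if groups is None:
        groups = tuple(c[3:] for c in cohort.columns if c.startswith("ac_"))
    sub = cohort[cohort["sex"] == sex]
    count = sub[col].astype(int)
    homozygous = (sub["sex"] == "female") & (count == 2)
    carrier = (count == 1) & ~homozygous
    any_allele = np.zeros(len(sub), dtype=bool)
    for g in groups:
        any_allele |= (sub[f"ac_{g}"].astype(int) > 0).to_numpy()
    control = ~any_allele & ~homozygous.to_numpy()
    data = pd.concat([sub[carrier.to_numpy()], sub[control]])
    data = data.copy()
    data["carrier"] = np.concatenate(
        [np.ones(int(carrier.sum()), dtype=int), np.zeros(int(control.sum()), dtype=int)]
    )
    n_cases = int(carrier.sum())
    if n_cases == 0:
        warnings.warn(f"no {sex} carriers for group {group!r}; analysis set is empty")
    return AnalysisSet(
        group=group, sex=sex, data=data,
        n_cases=n_cases, n_controls=int(control.sum()),
        excluded_homozygous=int(homozygous.sum()),
    )


def _complete_cases(data: pd.DataFrame, columns: list[str]) -> tuple[pd.DataFrame, int]:
    frame = data[columns].apply(pd.to_numeric, errors="coerce")
    kept = frame.dropna().astype(float)
    return kept, len(frame) - len(kept)


def _wald_result(params, bse, pvalues, key: str, kind: str, exponentiate: bool,
                 meta: dict) -> AssociationResult:
    beta = float(params[key])
    se = float(bse[key])
    lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
    if exponentiate:
        effect, lo, hi = float(np.exp(beta)), float(np.exp(lo)), float(np.exp(hi))
    else:
        effect = beta
    return AssociationResult(
        model_kind=kind, effect=effect, ci_low=lo, ci_high=hi,
        p_raw=float(pvalues[key]), **meta,
    )


def _separation_result(kind: str, direction: float, meta: dict) -> AssociationResult:
    effect = float("inf") if direction >= 0 else 0.0
    return AssociationResult(
        model_kind=kind, effect=effect, ci_low=0.0, ci_high=float("inf"),
        p_raw=float("nan"), separation=True,
        notes="separation: likelihood unbounded; estimate flagged", **meta,
    )


def _meta(data: pd.DataFrame, exposure: str, covariates, n_dropped: int, **extra) -> dict:
    return dict(
        n_carriers=int((data[exposure] == 1).sum()),
        n_controls=int((data[exposure] == 0).sum()),
        covariates=tuple(covariates),
        n_dropped=n_dropped,
        **extra,
    )


def fit_logistic(data: pd.DataFrame, outcome: str, exposure: str = "carrier",
                 covariates=ADJUSTMENT_COVARIATES, **extra) -> AssociationResult:
    """ML logistic regression; effect reported as the exposure odds ratio.

    Rows with any missing variable are dropped (count reported). Perfect or
    quasi-complete separation returns a flagged result with an unbounded
    interval rather than raising.
    """
    covariates = tuple(covariates)
    frame, n_dropped = _complete_cases(data, [outcome, exposure, *covariates])
    if frame.empty:
        raise DataError("no complete-case rows to fit")
    y = frame[outcome].to_numpy()
    if np.unique(y).size < 2:
        raise ModelError(f"outcome {outcome!r} has a single observed class")
    X = sm.add_constant(frame[[exposure, *covariates]], has_constant="add")
    meta = _meta(frame, exposure, covariates, n_dropped, outcome=outcome, **extra)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=False, maxiter=200)
        beta, se = float(res.params[exposure]), float(res.bse[exposure])
        if not np.isfinite(se) or abs(beta) > 15:
            return _separation_result("logistic", beta, meta)
        return _wald_result(res.params, res.bse, res.pvalues, exposure, "logistic", True, meta)
    except (np.linalg.LinAlgError, PerfectSeparationError, ValueError):
        direction = 1.0 if y[frame[exposure] == 1].mean() >= y.mean() else -1.0
        return _separation_result("logistic", direction, meta)


def fit_ordinal(data: pd.DataFrame, outcome: str, exposure: str = "carrier",
                covariates=ADJUSTMENT_COVARIATES, **extra) -> AssociationResult:
    """Proportional-odds (ordinal logistic) fit; common exposure OR.

    With a two-level outcome this coincides with :func:`fit_logistic`.
    """
    covariates = tuple(covariates)
    frame, n_dropped = _complete_cases(data, [outcome, exposure, *covariates])
    if frame.empty:
        raise DataError("no complete-case rows to fit")
    levels = np.unique(frame[outcome])
    if levels.size < 2:
        raise ModelError(f"ordinal outcome {outcome!r} has a single observed level")
    y = pd.Categorical(frame[outcome], categories=sorted(levels), ordered=True)
    X = frame[[exposure, *covariates]]
    meta = _meta(frame, exposure, covariates, n_dropped, outcome=outcome, **extra)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=False, maxiter=500)
        beta, se = float(res.params[exposure]), float(res.bse[exposure])
        if not np.isfinite(se) or abs(beta) > 15:
            return _separation_result("ordinal", beta, meta)
        return _wald_result(res.params, res.bse, res.pvalues, exposure, "ordinal", True, meta)
    except (np.linalg.LinAlgError, ValueError):
        return _separation_result("ordinal", 1.0, meta)


def fit_linear(data: pd.DataFrame, y: str, exposure: str = "carrier",
               covariates=ADJUSTMENT_COVARIATES, statin_adjust: bool = False,
               **extra) -> AssociationResult:
    """Least-squares fit of a continuous trait; effect = exposure slope.

    ``statin_adjust=True`` adds ``statin_use`` to the covariates (lipid
    traits). Group/control mean +/- SD are attached for trait-table output.
    """
    covariates = tuple(covariates) + (("statin_use",) if statin_adjust else ())
    frame, n_dropped = _complete_cases(data, [y, exposure, *covariates])
    if frame.empty:
        raise DataError("no complete-case rows to fit")
    if float(np.var(frame[y])) == 0.0:
        raise ModelError(f"trait {y!r} has zero variance")
    X = sm.add_constant(frame[[exposure, *covariates]], has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ModelError(f"collinear design for trait {y!r}; check VIFs upstream")
    res = sm.OLS(frame[y], X).fit()
    carriers = frame.loc[frame[exposure] == 1, y]
    controls = frame.loc[frame[exposure] == 0, y]
    meta = _meta(frame, exposure, covariates, n_dropped, outcome=y, **extra)
    out = _wald_result(res.params, res.bse, res.pvalues, exposure, "linear", False, meta)
    out.group_mean_sd = (float(carriers.mean()), float(carriers.std(ddof=1)))
    out.control_mean_sd = (float(controls.mean()), float(controls.std(ddof=1)))
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, implemented from scratch.

    adj_(i) = min_{j >= i} (p_(j) * m / j), capped at 1 and mapped back to
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DataError("p_values must be one-dimensional")
    if np.isnan(p).any():
        raise DataError("p-values must not be NaN")
    if p.size and (p.min() < 0 or p.max() > 1):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    scaled = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def vif(design_matrix: pd.DataFrame, add_intercept: bool = True) -> pd.Series:
    """Variance inflation factors: VIF_k = 1 / (1 - R^2_k).

    Each predictor is regressed on the others (with an intercept by
    default); exact collinearity yields ``inf`` for the involved columns.
    """
    X = pd.DataFrame(design_matrix).astype(float)
    if X.shape[1] < 2:
        raise DataError("VIF needs at least two predictors")
    if X.shape[0] <= X.shape[1]:
        raise DataError("VIF needs more rows than predictors")
    out = {}
    cols = list(X.columns)
    arr = X.to_numpy()
    for k, name in enumerate(cols):
        yk = arr[:, k]
        others = np.delete(arr, k, axis=1)
        if add_intercept:
            others = np.column_stack([np.ones(len(yk)), others])
        beta, *_ = np.linalg.lstsq(others, yk, rcond=None)
        resid = yk - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yk - yk.mean()) ** 2).sum())
        if ss_tot == 0.0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


class CarrierAssociation:
    """Model object tying an :class:`AnalysisSet` to one outcome and fit kind.

    ``fit()`` dispatches to the logistic / proportional-odds / linear engine
    and returns an :class:`AssociationResult` stamped with the set's group
    and sex.
    """

    def __init__(self, analysis_set: AnalysisSet, outcome: str,
                 covariates=ADJUSTMENT_COVARIATES, kind: str = "logistic",
                 statin_adjust: bool = False):
        if kind not in ("logistic", "ordinal", "linear"):
            raise DataError(f"unknown model kind {kind!r}")
        self.analysis_set = analysis_set
        self.outcome = outcome
        self.covariates = tuple(covariates)
        self.kind = kind
        self.statin_adjust = statin_adjust

    def fit(self) -> AssociationResult:
        aset = self.analysis_set
        stamp = dict(group=aset.group, sex=aset.sex)
        if self.kind == "logistic":
            return fit_logistic(aset.data, self.outcome, covariates=self.covariates, **stamp)
        if self.kind == "ordinal":
            return fit_ordinal(aset.data, self.outcome, covariates=self.covariates, **stamp)
        return fit_linear(aset.data, self.outcome, covariates=self.covariates,
                          statin_adjust=self.statin_adjust, **stamp)


def run_stratified(cohort: pd.DataFrame, groups, strata: pd.Series,
                   outcome: str = "fdf_high", sexes=("male", "female")) -> list[AssociationResult]:
    """CV-stratum analyses: carriers in each stratum vs the full same-sex
    wild-type control population, with CV-unadjusted logistic models and BH
    correction across the whole result set.

    Empty group/sex/stratum cells are skipped with a log entry.
    """
    groups = tuple(groups)
    results: list[AssociationResult] = []
    cohort = cohort.copy()
    cohort["_stratum"] = strata
    for sex in sexes:
        for group in groups:
            aset = build_analysis_set(cohort, group, sex, groups=groups)
            if aset.empty:
                logger.info("skipping %s/%s: no carriers", group, sex)
                continue
            controls = aset.data[aset.data["carrier"] == 0]
            for stratum in ("high", "low"):
                cases = aset.data[(aset.data["carrier"] == 1) & (aset.data["_stratum"] == stratum)]
                if cases.empty:
                    logger.info("skipping %s/%s stratum %s: zero carriers", group, sex, stratum)
                    continue
                data = pd.concat([cases, controls])
                try:
                    res = fit_logistic(
                        data, outcome, covariates=(),
                        group=group, sex=sex, stratum=stratum,
                    )
                except (DataError, ModelError) as exc:
                    logger.info("skipping %s/%s stratum %s: %s", group, sex, stratum, exc)
                    continue
                results.append(res)
    ps = np.array([r.p_raw for r in results], dtype=float)
    if len(ps):
        adj = bh_adjust(np.where(np.isnan(ps), 1.0, ps))
        for r, a, raw in zip(results, adj, ps):
            r.p_adjusted = float(a) if np.isfinite(raw) else None
    return results
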