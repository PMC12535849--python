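"""FASTEX-derived Fabry (FDF) phenotype score.

The FDF score summarises four clinical domains of Fabry disease — pain,
renal, cardiac, cerebrovascular — each on a 0-4 point scale, and sums them
(0-16 total). The renal domain is scored from laboratory values (eGFR and
uACR bands, KDIGO-style staging); cardiac and cerebrovascular domains from
ICD-coded events weighted by severity; pain from questionnaire items, with
fully missing pain items imputed to the lowest category (0 points). The
total is dichotomized at > 4: because each domain caps at 4, a high flag
structurally requires involvement of at least two domains.

Band edges and point weights are shipped as editable defaults in
:class:`ScoringMap`; they are reconstructions consistent with the published
FASTEX domain structure, not a verbatim copy of any proprietary instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, ModelError

__all__ = [
    "ScoringMap",
    "FDFResult",
    "score_renal",
    "renal_component_points",
    "score_flag_domain",
    "score_pain",
    "total_fdf",
    "youden_cutoff",
]

DOMAINS = ("pain", "renal", "cardiac", "cerebrovascular")


def _default_egfr_bands() -> list[tuple[float, int]]:
    # (lower eGFR bound, points): score of the band starting at that bound
    return [(90.0, 0), (60.0, 1), (30.0, 2), (0.0, 4)]


def _default_uacr_bands() -> list[tuple[float, int]]:
    # (upper uACR bound, points) in mg/g
    return [(30.0, 0), (300.0, 1), (float("inf"), 4)]


@dataclass
class ScoringMap:
    """Point assignments for the four FDF domains.

    ``egfr_bands`` lists (lower-bound, points) pairs in decreasing bound
    order; an eGFR value scores the points of the first band whose lower
    bound it reaches. ``uacr_bands`` lists (upper-bound, points) pairs in
    increasing bound order; a uACR value scores the points of the first band
    it falls under (bounds inclusive). The renal domain is the max of the
    two components. Cardiac/cerebrovascular weights map a severity level
    (from the code registry) to points; pain weights map a questionnaire
    response level to points.
    """

    egfr_bands: list[tuple[float, int]] = field(default_factory=_default_egfr_bands)
    uacr_bands: list[tuple[float, int]] = field(default_factory=_default_uacr_bands)
    cardiac_weights: dict[int, int] = field(default_factory=lambda: {0: 0, 1: 2, 2: 4})
    cerebrovascular_weights: dict[int, int] = field(default_factory=lambda: {0: 0, 1: 2, 2: 4})
    pain_weights: dict[int, int] = field(default_factory=lambda: {0: 0, 1: 1, 2: 2, 3: 4})
    domain_max: int = 4
    dichotomization_threshold: float = 4.0  # flag is total > threshold

    def __post_init__(self) -> None:
        for name, weights in (
            ("cardiac_weights", self.cardiac_weights),
            ("cerebrovascular_weights", self.cerebrovascular_weights),
            ("pain_weights", self.pain_weights),
        ):
            for level, pts in weights.items():
                if not (0 <= pts <= self.domain_max):
                    raise ConfigurationError(f"{name}[{level}] = {pts} outside [0, {self.domain_max}]")
        egfr_bounds = [b for b, _ in self.egfr_bands]
        if sorted(egfr_bounds, reverse=True) != egfr_bounds or len(set(egfr_bounds)) != len(egfr_bounds):
            raise ConfigurationError("egfr_bands bounds must be strictly decreasing")
        uacr_bounds = [b for b, _ in self.uacr_bands]
        if sorted(uacr_bounds) != uacr_bounds or len(set(uacr_bounds)) != len(uacr_bounds):
            raise ConfigurationError("uacr_bands bounds must be strictly increasing")
        for _, pts in list(self.egfr_bands) + list(self.uacr_bands):
            if not (0 <= pts <= self.domain_max):
                raise ConfigurationError(f"band points {pts} outside [0, {self.domain_max}]")


def renal_component_points(egfr, uacr, scoring: ScoringMap | None = None):
    """Per-component renal points (eGFR points, uACR points).

    Accepts scalars or array-likes; missing (NaN) inputs give NaN points.
    Negative values are a data error.
    """
    scoring = scoring or ScoringMap()
    egfr = np.asarray(egfr, dtype=float)
    uacr = np.asarray(uacr, dtype=float)
    if np.any(np.atleast_1d(egfr) < 0) or np.any(np.atleast_1d(uacr) < 0):
        raise DataError("negative eGFR or uACR value")
    egfr_pts = np.full(egfr.shape, np.nan)
    for bound, pts in scoring.egfr_bands:  # decreasing bounds: first match wins
        egfr_pts = np.where(np.isnan(egfr_pts) & (egfr >= bound), pts, egfr_pts)
    uacr_pts = np.full(uacr.shape, np.nan)
    for bound, pts in scoring.uacr_bands:  # increasing bounds: first match wins
        uacr_pts = np.where(np.isnan(uacr_pts) & (uacr <= bound), pts, uacr_pts)
    egfr_pts = np.where(np.isnan(egfr), np.nan, egfr_pts)
    uacr_pts = np.where(np.isnan(uacr), np.nan, uacr_pts)
    return egfr_pts, uacr_pts


def score_renal(egfr, uacr, scoring: ScoringMap | None = None):
    """Renal domain points: max of the eGFR and uACR band components.

    A missing component makes the domain score missing (NaN): renal labs are
    never imputed, so affected subjects drop out of complete-case models.
    Scalar inputs return a scalar.
    """
    scoring = scoring or ScoringMap()
    egfr_pts, uacr_pts = renal_component_points(egfr, uacr, scoring)
    pts = np.maximum(egfr_pts, uacr_pts)  # NaN-propagating by design
    pts = np.minimum(pts, scoring.domain_max)
    if pts.ndim == 0:
        return float(pts)
    return pts


def score_flag_domain(severity, weights: dict[int, int], domain_max: int = 4):
    """Points for an ICD-flag domain from its highest observed severity.

    ``severity`` is 0 when no code matched. Scalars or arrays accepted;
    unknown severity levels are a configuration error.
    """
    sev = np.asarray(severity)
    known = np.asarray(sorted(weights))
    if not np.isin(sev, known).all():
        bad = sorted(set(np.unique(sev)) - set(known.tolist()))
        raise ConfigurationError(f"severity level(s) {bad} missing from weight map")
    lookup = np.zeros(int(known.max()) + 1, dtype=int)
    for level, pts in weights.items():
        lookup[level] = min(pts, domain_max)
    out = lookup[sev]
    if np.ndim(severity) == 0:
        return int(out)
    return out


def score_pain(pain_items, weights: dict[int, int] | None = None, domain_max: int = 4):
    """Pain domain points from ordinal questionnaire items.

    Takes the highest reported pain level across items and maps it through
    ``weights``. Subjects with every item missing receive 0 points with
    ``imputed=True`` (lowest-category imputation for missing pain data);
    partially missing answers use the observed items and are not flagged.

    For a 1-D item vector returns ``(points, imputed)``; for a DataFrame of
    per-subject rows returns ``(points Series, imputed Series)``.
    """
    weights = weights or ScoringMap().pain_weights
    if isinstance(pain_items, pd.DataFrame):
        arr = pain_items.to_numpy(dtype=float)
    else:
        arr = np.asarray(pain_items, dtype=float).reshape(1, -1)
    all_missing = np.isnan(arr).all(axis=1)
    highest = np.where(all_missing, 0.0, np.nanmax(np.where(np.isnan(arr), -np.inf, arr), axis=1))
    highest = highest.astype(int)
    lookup = np.zeros(max(weights) + 1, dtype=int)
    for level, pts in weights.items():
        lookup[level] = min(pts, domain_max)
    if highest.max(initial=0) > max(weights):
        raise ConfigurationError("pain response level outside the weight map")
    pts = lookup[highest]
    if isinstance(pain_items, pd.DataFrame):
        return (
            pd.Series(pts, index=pain_items.index),
            pd.Series(all_missing, index=pain_items.index),
        )
    return int(pts[0]), bool(all_missing[0])


@dataclass
class FDFResult:
    """Per-subject FDF score decomposition."""

    domain_scores: dict[str, int]
    total: int
    high_flag: bool
    pain_imputed: bool = False

    def __post_init__(self) -> None:
        if self.total != sum(self.domain_scores.values()):
            raise DataError("FDF total does not equal the sum of domain scores")


def total_fdf(domain_scores: dict[str, float], scoring: ScoringMap | None = None,
              pain_imputed: bool = False) -> FDFResult:
    """Combine the four domain scores into an :class:`FDFResult`.

    ``high_flag`` is ``total > dichotomization_threshold`` (default 4); with
    a per-domain cap of 4 this can only happen when at least two domains
    contribute.
    """
    scoring = scoring or ScoringMap()
    missing = set(DOMAINS) - set(domain_scores)
    if missing:
        raise DataError(f"missing domain scores: {sorted(missing)}")
    for domain, pts in domain_scores.items():
        if not (0 <= pts <= scoring.domain_max):
            raise DataError(f"{domain} score {pts} outside [0, {scoring.domain_max}]")
    total = int(sum(domain_scores.values()))
    return FDFResult(
        domain_scores={d: int(domain_scores[d]) for d in DOMAINS},
        total=total,
        high_flag=total > scoring.dichotomization_threshold,
        pain_imputed=pain_imputed,
    )


def youden_cutoff(total_scores, binary_labels) -> tuple[float, float]:
    """ROC-optimal score cutoff by the Youden index.

    Candidate thresholds are the midpoints of adjacent distinct score
    values; for each, subjects with score > threshold are called positive,
    J = sensitivity + specificity - 1 is computed, and the threshold with
    maximal J is returned (ties broken toward the lower threshold).
    """
    scores = np.asarray(total_scores, dtype=float)
    labels = np.asarray(binary_labels).astype(int)
    if scores.shape != labels.shape:
        raise DataError("scores and labels differ in length")
    classes = np.unique(labels)
    if set(classes.tolist()) != {0, 1}:
        raise ModelError("labels must contain both classes (0 and 1)")
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise ModelError("all scores identical; no threshold exists")
    thresholds = (distinct[:-1] + distinct[1:]) / 2.0
    pos, neg = scores[labels == 1], scores[labels == 0]
    sens = (pos[None, :] > thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] <= thresholds[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax takes the first (lowest) threshold on ties
    return float(thresholds[best]), float(j[best])
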