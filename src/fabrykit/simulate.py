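"""Seeded synthetic biobank cohort generator.

Emulates the structure of a large genotyped biobank for an X-linked gene:
sex-stratified allele counts at configurable carrier frequencies, ICD-10
coded cardiovascular risk factors, Fabry-disease clinical-domain events
driven by a logistic liability model, laboratory panels calibrated per sex,
and realistic missingness (notably in pain questionnaire items).

The liability model for each FD domain event is

    logit P(event) = b0_domain + b_age (age - 57) + b_rf * (#risk factors)
                     + carrier * (beta_main + beta_interaction * high_CV)

where ``high_CV`` marks subjects above the 75th percentile of the true risk
index (the age + risk-factor part of the liability). Pathogenic variant
groups default to an unconditional effect (beta_main = log 5,
beta_interaction = 0); non-pathogenic groups default to a mildly protective
main effect with a positive interaction (log 0.8 and log 2.5), so their
carriers express an FD-like phenotype only under a high CV burden. Female
carrier effects are attenuated by a single multiplicative X-inactivation
factor. These effect sizes are calibration choices: the source data report
only fitted odds ratios, not generative parameters.

Right-skewed labs (uACR, urinary creatinine, triglycerides, Lp(a)) are
log-normal with moments matched to the target mean/SD; the rest are normal
truncated to positive support. Urinary albumin is derived from uACR and
urinary creatinine (with multiplicative noise) so the three stay consistent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import log

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "GroupEffect",
    "SimConfig",
    "Cohort",
    "assign_genotypes",
    "sample_labs",
    "generate_cohort",
]

#: labs drawn log-normally (right-skewed); everything else is truncated normal
LOGNORMAL_LABS = frozenset({"uacr", "u_creatinine", "triglycerides", "lpa"})

#: default per-sex lab calibration: {lab: (mean, sd)}; control-population moments
DEFAULT_LAB_CALIBRATION: dict[str, dict[str, tuple[float, float]]] = {
    "male": {
        "bmi": (27.834, 4.21),
        "sbp": (142.706, 18.47),
        "dbp": (84.005, 10.54),
        "urea": (5.613, 1.45),
        "creatinine": (81.745, 19.10),
        "cystatin_c": (0.943, 0.18),
        "egfr": (100.58, 20.32),
        "u_creatinine": (10881.0, 6116.0),
        "uacr": (20.527, 43.21),
        "glucose": (5.189, 1.40),
        "hba1c": (36.515, 7.60),
        "urate": (354.62, 71.748),
        "cholesterol": (5.479, 1.13),
        "triglycerides": (1.98, 1.155),
        "hdl": (1.279, 0.312),
        "apob": (1.026, 0.239),
        "lpa": (43.855, 49.02),
    },
    "female": {
        "bmi": (27.075, 5.14),
        "sbp": (137.197, 20.22),
        "dbp": (80.677, 10.556),
        "urea": (5.23, 1.33),
        "creatinine": (64.373, 13.79),
        "cystatin_c": (0.878, 0.167),
        "egfr": (100.438, 20.42),
        "u_creatinine": (7186.0, 4953.0),
        "uacr": (20.993, 38.42),
        "glucose": (5.068, 1.07),
        "hba1c": (35.807, 5.97),
        "urate": (271.06, 66.27),
        "cholesterol": (5.874, 1.12),
        "triglycerides": (1.554, 0.86),
        "hdl": (1.593, 0.37),
        "apob": (1.037, 0.23),
        "lpa": (45.279, 49.37),
    },
}

LAB_COLUMNS = tuple(DEFAULT_LAB_CALIBRATION["male"]) + ("u_albumin",)
PAIN_ITEMS = ("pain_1", "pain_2", "pain_3")

#: default carrier allele frequencies by variant group (male carrier proportions)
DEFAULT_CARRIER_FREQ: dict[str, float] = {
    "ALL_C": 0.0075,
    "ALL_P": 0.00014,
    "ALL_U": 0.0005,
    "p.Asp313Tyr_C": 0.00397,
    "p.Arg118Cys_C": 0.0008,
    "p.Ser126Gly_C": 0.00078,
    "p.Ala143Thr_C": 0.00054,
    "p.Asn215Ser_P": 0.000059,
}

DEFAULT_RISKFACTOR_PREVALENCE: dict[str, float] = {
    "hypertension": 0.27,
    "diabetes": 0.06,
    "dyslipidemia": 0.15,
    "obesity": 0.08,
    "smoking": 0.11,
}

RISKFACTOR_CODE: dict[str, str] = {
    "hypertension": "I10",
    "diabetes": "E11",
    "dyslipidemia": "E780",
    "obesity": "E669",
    "smoking": "F17",
}

SIM_DOMAINS = ("cardiac", "cerebrovascular", "renal", "pain")


@dataclass
class GroupEffect:
    """Carrier effect of one variant group on the FD-domain liabilities.

    ``beta_main`` is the unconditional log-odds shift per domain,
    ``beta_interaction`` the extra shift for carriers in the high-CV
    stratum, and ``uacr_multiplier`` a multiplicative shift of uACR (full
    strength in males, attenuated through the X-inactivation exponent in
    females).
    """

    beta_main: float = 0.0
    beta_interaction: float = 0.0
    uacr_multiplier: float = 1.0


def _default_effects() -> dict[str, GroupEffect]:
    pathogenic = dict(beta_main=log(5.0), beta_interaction=0.0, uacr_multiplier=4.0)
    nonpath = dict(beta_main=log(0.8), beta_interaction=log(2.5), uacr_multiplier=1.0)
    return {
        "ALL_P": GroupEffect(**pathogenic),
        "p.Asn215Ser_P": GroupEffect(**pathogenic),
        "ALL_C": GroupEffect(**nonpath),
        "ALL_U": GroupEffect(**nonpath),
        "p.Asp313Tyr_C": GroupEffect(**nonpath),
        "p.Arg118Cys_C": GroupEffect(**nonpath),
        "p.Ser126Gly_C": GroupEffect(**nonpath),
        "p.Ala143Thr_C": GroupEffect(**nonpath),
    }


def _default_missingness() -> dict[str, float]:
    rates = {lab: 0.03 for lab in LAB_COLUMNS}
    rates.update({"sbp": 0.05, "dbp": 0.05, "uacr": 0.25, "u_creatinine": 0.25, "u_albumin": 0.25})
    rates["pain_items"] = 0.7
    return rates


def _default_domain_baseline() -> dict[str, float]:
    # intercepts chosen so control prevalences land near cardiac 4%,
    # cerebrovascular 2%, renal 2.5%, pain 5% at the default risk-factor mix
    return {"cardiac": -3.57, "cerebrovascular": -4.28, "renal": -4.05, "pain": -3.33}


@dataclass
class SimConfig:
    """Full parameterization of one synthetic cohort draw."""

    n_males: int = 50_000
    n_females: int = 50_000
    carrier_freq_by_group: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CARRIER_FREQ))
    riskfactor_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RISKFACTOR_PREVALENCE)
    )
    effect_model: dict[str, GroupEffect] = field(default_factory=_default_effects)
    xinactivation_attenuation: float = 0.5
    lab_calibration: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {s: dict(c) for s, c in DEFAULT_LAB_CALIBRATION.items()}
    )
    missingness_rates: dict[str, float] = field(default_factory=_default_missingness)
    seed: int = 0
    # liability calibration
    domain_baseline: dict[str, float] = field(default_factory=_default_domain_baseline)
    riskfactor_beta: float = log(1.8)
    age_beta: float = 0.04
    age_range: tuple[float, float] = (40.0, 70.0)
    high_cv_quantile: float = 0.75
    # lab shifts for subjects with a renal domain event
    renal_event_egfr: tuple[float, float] = (52.0, 16.0)
    renal_event_uacr: tuple[float, float] = (120.0, 150.0)

    def __post_init__(self) -> None:
        if self.n_males < 0 or self.n_females < 0:
            raise ConfigurationError("n_males/n_females must be non-negative")
        for group, freq in self.carrier_freq_by_group.items():
            if not (0.0 <= freq <= 1.0):
                raise ConfigurationError(f"carrier_freq_by_group[{group!r}] = {freq} outside [0, 1]")
        for factor, p in self.riskfactor_prevalence.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"riskfactor_prevalence[{factor!r}] = {p} outside [0, 1]")
        if not (0.0 < self.xinactivation_attenuation <= 1.0):
            raise ConfigurationError(
                f"xinactivation_attenuation = {self.xinactivation_attenuation} outside (0, 1]"
            )
        for group, eff in self.effect_model.items():
            if isinstance(eff, dict):
                self.effect_model[group] = GroupEffect(**eff)
        for sex, cal in self.lab_calibration.items():
            if sex not in ("male", "female"):
                raise ConfigurationError(f"lab_calibration key {sex!r} is not a sex")
            for lab, (mean, sd) in cal.items():
                if sd < 0:
                    raise ConfigurationError(f"lab_calibration[{sex!r}][{lab!r}] has negative SD")
                if mean <= 0:
                    raise ConfigurationError(f"lab_calibration[{sex!r}][{lab!r}] has non-positive mean")
        for fieldname, rate in self.missingness_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ConfigurationError(f"missingness_rates[{fieldname!r}] = {rate} outside [0, 1]")
        if not (0.0 < self.high_cv_quantile < 1.0):
            raise ConfigurationError("high_cv_quantile must lie in (0, 1)")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.carrier_freq_by_group)

    def effect(self, group: str) -> GroupEffect:
        return self.effect_model.get(group, GroupEffect())


@dataclass
class Cohort:
    """A generated cohort table plus the truth record of realized parameters."""

    table: pd.DataFrame
    truth: dict

    def to_files(self, table_path, truth_path=None) -> None:
        """Write the cohort as TSV with a JSON truth sidecar."""
        self.table.to_csv(table_path, sep="\t", index=False)
        if truth_path is None:
            truth_path = str(table_path) + ".truth.json"
        with open(truth_path, "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True, default=float)

    @staticmethod
    def from_files(table_path, truth_path=None) -> "Cohort":
        table = pd.read_csv(table_path, sep="\t", dtype={"icd10": "string"})
        truth: dict = {}
        if truth_path is not None:
            with open(truth_path) as fh:
                truth = json.load(fh)
        return Cohort(table=table, truth=truth)


def assign_genotypes(sex_vector, freq: float, seed=None, rng=None) -> np.ndarray:
    """Draw X-linked allele counts: one Bernoulli(freq) draw per male X,
    two independent draws per female (Hardy-Weinberg sampling)."""
    if not (0.0 <= freq <= 1.0):
        raise ConfigurationError(f"allele frequency {freq} outside [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    sex = np.asarray(sex_vector)
    n_draws = np.where(sex == "male", 1, 2)
    return rng.binomial(n_draws, freq)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    if mean <= 0:
        raise ConfigurationError("log-normal lab requires a positive mean")
    sigma2 = log(1.0 + (sd / mean) ** 2)
    mu = log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def sample_labs(subject_context: pd.DataFrame, calibration=None, seed=None, rng=None,
                config: SimConfig | None = None) -> pd.DataFrame:
    """Draw a lab panel for each subject in ``subject_context``.

    ``subject_context`` needs a ``sex`` column; optional ``renal_event``
    (bool) re-draws eGFR/uACR from the diseased calibration, and optional
    ``uacr_multiplier`` applies a per-subject multiplicative uACR shift
    (how pathogenic carriers receive their albuminuria excess). Urinary
    albumin is derived from uACR x urinary creatinine with 20% log-scale
    noise, keeping the three consistent.
    """
    config = config or SimConfig()
    calibration = calibration or config.lab_calibration
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = len(subject_context)
    sex = subject_context["sex"].to_numpy()
    out = pd.DataFrame(index=subject_context.index)
    for lab in DEFAULT_LAB_CALIBRATION["male"]:
        values = np.empty(n, dtype=float)
        for s in ("male", "female"):
            mask = sex == s
            if not mask.any():
                continue
            mean, sd = calibration[s][lab]
            if sd < 0:
                raise ConfigurationError(f"negative SD for lab {lab!r} ({s})")
            if lab in LOGNORMAL_LABS:
                mu, sigma = _lognormal_params(mean, sd)
                values[mask] = rng.lognormal(mu, sigma, mask.sum())
            else:
                values[mask] = rng.normal(mean, sd, mask.sum())
        out[lab] = np.maximum(values, 1e-3)  # positive physical support

    if "renal_event" in subject_context:
        renal = subject_context["renal_event"].to_numpy(dtype=bool)
        if renal.any():
            k = int(renal.sum())
            e_mean, e_sd = config.renal_event_egfr
            out.loc[renal, "egfr"] = np.maximum(rng.normal(e_mean, e_sd, k), 5.0)
            u_mean, u_sd = config.renal_event_uacr
            mu, sigma = _lognormal_params(u_mean, u_sd)
            out.loc[renal, "uacr"] = rng.lognormal(mu, sigma, k)
    if "uacr_multiplier" in subject_context:
        out["uacr"] = out["uacr"] * subject_context["uacr_multiplier"].to_numpy(dtype=float)

    # albumin (mg/L) = uACR (mg/g) x urinary creatinine (g/L); 113.12 g/mol
    ucreat_g_per_l = out["u_creatinine"] * 113.12e-6
    noise = rng.lognormal(0.0, 0.2, n)
    out["u_albumin"] = out["uacr"] * ucreat_g_per_l * noise
    return out


def _draw_pain_items(event: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ordinal pain responses 0-3 per item; painful subjects answer higher."""
    n = event.size
    items = np.empty((n, len(PAIN_ITEMS)), dtype=float)
    p_event = np.array([0.10, 0.20, 0.40, 0.30])
    p_quiet = np.array([0.88, 0.09, 0.03, 0.00])
    for j in range(len(PAIN_ITEMS)):
        u = rng.random(n)
        items[:, j] = np.where(
            event,
            np.searchsorted(np.cumsum(p_event), u),
            np.searchsorted(np.cumsum(p_quiet), u),
        )
    return np.clip(items, 0, 3)


def generate_cohort(config: SimConfig | None = None) -> Cohort:
    """Generate one cohort per ``config``; deterministic for a fixed seed.

    Returns a :class:`Cohort` whose truth record stores the realized
    per-group effect parameters, liability calibration, high-CV threshold,
    and carrier counts.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_males + config.n_females
    sex = np.array(["male"] * config.n_males + ["female"] * config.n_females)

    age = rng.uniform(config.age_range[0], config.age_range[1], n)

    # genotypes: one allele draw per male X, two per female
    allele: dict[str, np.ndarray] = {}
    for group in config.groups:
        allele[group] = assign_genotypes(sex, config.carrier_freq_by_group[group], rng=rng)

    # risk factors
    rf = {f: rng.random(n) < p for f, p in config.riskfactor_prevalence.items()}
    rf_count = np.sum([v for v in rf.values()], axis=0)

    # true CV risk index and high-CV stratum (top quartile by default)
    age_mid = float(np.mean(config.age_range) + 2.0)  # 57 under the default range
    cv_index = config.age_beta * (age - age_mid) + config.riskfactor_beta * rf_count
    cv_threshold = float(np.quantile(cv_index, config.high_cv_quantile))
    high_cv = cv_index > cv_threshold

    # per-subject carrier effect on each domain liability
    is_female = sex == "female"
    atten = np.where(is_female, config.xinactivation_attenuation, 1.0)
    carrier_shift = np.zeros(n)
    uacr_mult = np.ones(n)
    for group in config.groups:
        eff = config.effect(group)
        carrier = allele[group] > 0
        shift = (eff.beta_main + eff.beta_interaction * high_cv) * atten
        carrier_shift = carrier_shift + np.where(carrier, shift, 0.0)
        mult = eff.uacr_multiplier ** atten
        uacr_mult = np.maximum(uacr_mult, np.where(carrier, mult, 1.0))

    # domain events from the logistic liability
    events: dict[str, np.ndarray] = {}
    for domain in SIM_DOMAINS:
        logit = config.domain_baseline[domain] + cv_index + carrier_shift
        p = 1.0 / (1.0 + np.exp(-logit))
        events[domain] = rng.random(n) < p

    # labs (renal events shift eGFR/uACR; carriers get their uACR multiplier)
    context = pd.DataFrame(
        {"sex": sex, "renal_event": events["renal"], "uacr_multiplier": uacr_mult}
    )
    labs = sample_labs(context, config.lab_calibration, rng=rng, config=config)

    pain_items = _draw_pain_items(events["pain"], rng)

    # ICD-10 code strings: risk factors + domain events with severity mix
    codes = pd.Series([""] * n)

    def _append(mask: np.ndarray, code: str) -> None:
        codes[mask] = codes[mask] + code + ";"

    for factor, flag in rf.items():
        _append(flag, RISKFACTOR_CODE[factor])
    severe_cardiac = events["cardiac"] & (rng.random(n) < 0.35)
    _append(severe_cardiac, "I42")
    _append(events["cardiac"] & ~severe_cardiac, "I48")
    stroke = events["cerebrovascular"] & (rng.random(n) < 0.6)
    _append(stroke, "I63")
    _append(events["cerebrovascular"] & ~stroke, "G45")
    esrd = events["renal"] & (rng.random(n) < 0.2)
    _append(esrd, "N185")
    _append(events["renal"] & ~esrd, "N181")
    _append(rng.random(n) < 0.3, "Z001")  # irrelevant wellness code
    codes = codes.str.rstrip(";")

    table = pd.DataFrame({"id": [f"S{i:07d}" for i in range(n)], "sex": sex, "age": age})
    for group in config.groups:
        table[f"ac_{group}"] = allele[group]
    table["icd10"] = codes.to_numpy()
    for lab in LAB_COLUMNS:
        table[lab] = labs[lab].to_numpy()
    for j, item in enumerate(PAIN_ITEMS):
        table[item] = pain_items[:, j]
    table["statin_use"] = np.where(
        rf["dyslipidemia"], rng.random(n) < 0.5, rng.random(n) < 0.08
    ).astype(int)

    # missingness (missing-at-random per field)
    pain_rate = config.missingness_rates.get("pain_items", 0.0)
    for item in PAIN_ITEMS:
        table.loc[rng.random(n) < pain_rate, item] = np.nan
    for lab in LAB_COLUMNS:
        rate = config.missingness_rates.get(lab, 0.0)
        if rate > 0:
            table.loc[rng.random(n) < rate, lab] = np.nan

    truth = {
        "seed": config.seed,
        "n_males": config.n_males,
        "n_females": config.n_females,
        "xinactivation_attenuation": config.xinactivation_attenuation,
        "riskfactor_beta": config.riskfactor_beta,
        "age_beta": config.age_beta,
        "domain_baseline": dict(config.domain_baseline),
        "high_cv_threshold": cv_threshold,
        "high_cv_quantile": config.high_cv_quantile,
        "effects": {g: asdict(config.effect(g)) for g in config.groups},
        "carrier_counts": {
            g: {
                "male": int(((allele[g] > 0) & ~is_female).sum()),
                "female": int(((allele[g] > 0) & is_female).sum()),
            }
            for g in config.groups
        },
        "domain_prevalence": {d: float(events[d].mean()) for d in SIM_DOMAINS},
    }
    return Cohort(table=table, truth=truth)
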