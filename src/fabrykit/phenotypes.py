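"""ICD-10 phenotype mapping and genotype zygosity classification.

Subjects arrive with a set of ICD-10 diagnosis codes (hospital-record style,
e.g. UK Biobank field 41270). A :class:`CodeRegistry` translates those codes
into Fabry-disease clinical-domain flags (cardiac, cerebrovascular, renal)
with a severity level, and into the five conventional cardiovascular/renal
risk-factor flags (diabetes, dyslipidemia, hypertension, obesity, smoking)
used as model covariates.

The shipped default registry is a documented reconstruction: the exact code
lists behind the original analysis are not public, so the defaults follow
standard ICD-10 usage (cardiomyopathy I42*, heart failure I50*, conduction
and arrhythmia I44-I49, CKD N18*, stroke I60-I64, TIA G45, diabetes E10-E14,
dyslipidemia E78, hypertension I10-I15, obesity E66, smoking F17/Z72.0) and
are fully editable through the config file.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "Zygosity",
    "CodeRegistry",
    "classify_zygosity",
    "classify_zygosity_vector",
    "map_codes",
    "map_cohort_codes",
    "normalize_code",
]

#: syntactic shape of a (normalized, dot-free) ICD-10 code or prefix
_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]*$")
_PREFIX_RE = re.compile(r"^[A-Z][0-9]+[0-9A-Z]*$")

RISK_FACTORS = ("diabetes", "dyslipidemia", "hypertension", "obesity", "smoking")
ICD_DOMAINS = ("cardiac", "cerebrovascular", "renal")


class Zygosity(str, Enum):
    WILD_TYPE = "wild_type"
    HEMIZYGOUS = "hemizygous"
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"


def normalize_code(code: str) -> str:
    """Upper-case and strip dots: 'i42.1' -> 'I421'."""
    return str(code).strip().upper().replace(".", "")


def _default_domain_codes() -> dict[str, set[str]]:
    return {
        "cardiac": {"I42", "I50", "I44", "I45", "I46", "I47", "I48", "I49"},
        "cerebrovascular": {"I60", "I61", "I62", "I63", "I64", "G45"},
        "renal": {"N18"},
    }


def _default_riskfactor_codes() -> dict[str, set[str]]:
    return {
        "diabetes": {"E10", "E11", "E12", "E13", "E14"},
        "dyslipidemia": {"E78"},
        "hypertension": {"I10", "I11", "I12", "I13", "I14", "I15"},
        "obesity": {"E66"},
        "smoking": {"F17", "Z720"},
    }


def _default_severity_weights() -> dict[str, int]:
    # severity levels: 1 = moderate, 2 = severe; scoring maps level -> points
    return {
        "I42": 2, "I50": 2,
        "I44": 1, "I45": 1, "I46": 2, "I47": 1, "I48": 1, "I49": 1,
        "I60": 2, "I61": 2, "I62": 2, "I63": 2, "I64": 2, "G45": 1,
        "N18": 1, "N184": 2, "N185": 2,
    }


@dataclass
class CodeRegistry:
    """Editable ICD-10 prefix registry for FD domains and CV risk factors.

    ``domain_codes`` maps an FD clinical domain to a set of code prefixes,
    ``riskfactor_codes`` does the same for covariate risk factors, and
    ``severity_weights`` assigns each prefix a severity level (default 1)
    that the scoring layer converts into points. Matching is prefix-based on
    normalized (upper-case, dot-free) codes, so "I42" matches "I42.1"/"I421"
    but not "I4" inputs such as "I40".
    """

    domain_codes: dict[str, set[str]] = field(default_factory=_default_domain_codes)
    riskfactor_codes: dict[str, set[str]] = field(default_factory=_default_riskfactor_codes)
    severity_weights: dict[str, int] = field(default_factory=_default_severity_weights)

    def __post_init__(self) -> None:
        self.domain_codes = {d: {normalize_code(p) for p in ps} for d, ps in self.domain_codes.items()}
        self.riskfactor_codes = {f: {normalize_code(p) for p in ps} for f, ps in self.riskfactor_codes.items()}
        self.severity_weights = {normalize_code(p): int(w) for p, w in self.severity_weights.items()}
        seen: dict[str, str] = {}
        for factor, prefixes in self.riskfactor_codes.items():
            for p in prefixes:
                if not _PREFIX_RE.match(p):
                    raise ConfigurationError(f"invalid ICD-10 prefix {p!r} for risk factor {factor!r}")
                if p in seen:
                    raise ConfigurationError(
                        f"prefix {p!r} assigned to both {seen[p]!r} and {factor!r}"
                    )
                seen[p] = factor
        for domain, prefixes in self.domain_codes.items():
            for p in prefixes:
                if not _PREFIX_RE.match(p):
                    raise ConfigurationError(f"invalid ICD-10 prefix {p!r} for domain {domain!r}")

    def severity(self, prefix: str) -> int:
        return self.severity_weights.get(prefix, 1)

    def max_severity(self) -> int:
        return max(self.severity_weights.values(), default=1)


def classify_zygosity(sex: str, allele_count: int) -> Zygosity:
    """Classify a subject's zygosity from sex and X-linked allele count.

    Males carry one X, so their count is 0 (wild type) or 1 (hemizygous);
    a male count of 2 is a data error. Female counts 0/1/2 map to wild
    type / heterozygous / homozygous.
    """
    count = int(allele_count)
    if count < 0:
        raise DataError(f"negative allele count {count}")
    if sex == "male":
        if count == 0:
            return Zygosity.WILD_TYPE
        if count == 1:
            return Zygosity.HEMIZYGOUS
        raise DataError(f"male allele count {count} impossible on the X chromosome")
    if sex == "female":
        if count == 0:
            return Zygosity.WILD_TYPE
        if count == 1:
            return Zygosity.HETEROZYGOUS
        if count == 2:
            return Zygosity.HOMOZYGOUS
        raise DataError(f"female allele count {count} out of range")
    raise DataError(f"unknown sex {sex!r}")


def classify_zygosity_vector(sex: pd.Series, allele_count: pd.Series) -> pd.Series:
    """Vectorized :func:`classify_zygosity` over cohort columns."""
    count = allele_count.astype(int)
    if (count < 0).any():
        raise DataError("negative allele count in cohort")
    male = sex == "male"
    if (count[male] > 1).any():
        raise DataError("male allele count of 2 found; impossible on the X chromosome")
    if (count[~male] > 2).any():
        raise DataError("female allele count above 2")
    out = np.where(
        count == 0,
        Zygosity.WILD_TYPE.value,
        np.where(
            male,
            Zygosity.HEMIZYGOUS.value,
            np.where(count == 1, Zygosity.HETEROZYGOUS.value, Zygosity.HOMOZYGOUS.value),
        ),
    )
    return pd.Series(out, index=sex.index)


def _clean_codes(codes) -> list[str]:
    cleaned = []
    for code in codes:
        norm = normalize_code(code)
        if not norm:
            continue
        if not _CODE_RE.match(norm):
            warnings.warn(f"skipping malformed ICD-10 code {code!r}", stacklevel=3)
            continue
        cleaned.append(norm)
    return cleaned


def map_codes(codes, registry: CodeRegistry | None = None):
    """Map one subject's ICD-10 code set to domain and risk-factor flags.

    Returns ``(domain_severity, riskfactor_flags)`` where ``domain_severity``
    holds the highest severity level seen per FD domain (0 when no code
    matched) and ``riskfactor_flags`` maps each risk factor to a boolean.
    Unknown codes are ignored; malformed code strings raise a warning and
    are skipped.
    """
    registry = registry or CodeRegistry()
    cleaned = _clean_codes(codes)
    domain_severity = {d: 0 for d in registry.domain_codes}
    rf_flags = {f: False for f in registry.riskfactor_codes}
    for code in cleaned:
        for domain, prefixes in registry.domain_codes.items():
            for p in prefixes:
                if code.startswith(p):
                    domain_severity[domain] = max(domain_severity[domain], registry.severity(p))
        for factor, prefixes in registry.riskfactor_codes.items():
            if any(code.startswith(p) for p in prefixes):
                rf_flags[factor] = True
    return domain_severity, rf_flags


def map_cohort_codes(
    icd10: pd.Series, registry: CodeRegistry | None = None, sep: str = ";"
) -> pd.DataFrame:
    """Vectorized code mapping over a cohort.

    ``icd10`` is a Series of ``sep``-joined code strings (empty or NaN for
    subjects without diagnoses). Returns a DataFrame with one integer
    severity column per FD domain (``<domain>_severity``) and one boolean
    column per risk factor.
    """
    registry = registry or CodeRegistry()
    s = icd10.fillna("").astype(str).str.upper().str.replace(".", "", regex=False)
    padded = sep + s + sep
    out = pd.DataFrame(index=icd10.index)
    for domain, prefixes in registry.domain_codes.items():
        sev = np.zeros(len(s), dtype=int)
        for p in sorted(prefixes):
            hit = padded.str.contains(sep + p, regex=False).to_numpy()
            sev = np.maximum(sev, np.where(hit, registry.severity(p), 0))
        out[f"{domain}_severity"] = sev
    for factor, prefixes in registry.riskfactor_codes.items():
        flag = np.zeros(len(s), dtype=bool)
        for p in sorted(prefixes):
            flag |= padded.str.contains(sep + p, regex=False).to_numpy()
        out[factor] = flag
    return out
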