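"""Human health risk from dust-borne heavy metals: ADD -> HQ/HI, LCR/TLCR.

Exposure model
--------------
Average daily dose (ADD, mg/kg/day) for three routes and three cohorts
(young child <6 y, older child 6-18 y, adult):

    ADD_ing  = C * IgR * EF * ED * CF / (BW * AT)
    ADD_derm = C * SA * AF * ABS * EF * ED * CF / (BW * AT)
    ADD_inh  = C * IhR * EF * ED / (PEF * BW * AT)

with C the dust concentration (mg/kg), IgR the dust ingestion rate
(mg/day), EF the exposure frequency (days/year), ED the exposure duration
(years), CF = 1e-6 kg/mg, BW body weight (kg), SA exposed skin (cm^2),
AF skin adherence (mg/cm^2/day), ABS the dermal absorption fraction,
IhR the inhalation rate (m^3/day) and PEF the particulate emission factor
(m^3/kg).  The averaging time AT is 365 * ED days for non-carcinogenic
endpoints; for carcinogenic endpoints convention says 365 * 70 days
("as_stated" mode), but published per-county risk tables for this survey
are only reproducible with AT = 365 * ED ("as_tabulated" mode) — both are
exposed and neither is silently preferred.

Non-carcinogenic risk divides each route ADD by a route-specific reference
dose (HQ = ADD/RfD) and sums routes into the hazard index (HI); HI > 1
flags potential concern.  Carcinogenic risk multiplies the carcinogenic
ADD by a route slope factor (LCR = ADD * SF) and sums routes into the
total lifetime cancer risk (TLCR), classified into five tiers and checked
against the EPA acceptable range 1e-6..1e-4.  All quantities are linear
(homogeneous of degree 1) in concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_model import ConfigurationError, StudyTable, _data_path

ROUTES: tuple[str, ...] = ("ingestion", "dermal", "inhalation")
COHORTS: tuple[str, ...] = ("young_child", "older_child", "adult")

#: The seven priority metals assessed for human health risk.
PRIORITY_METALS: tuple[str, ...] = ("As", "Cd", "Cr", "Cu", "Ni", "Pb", "Zn")

#: EPA acceptable lifetime cancer risk range.
ACCEPTABLE_RISK_RANGE: tuple[float, float] = (1e-6, 1e-4)


class ParameterError(ValueError):
    """Unknown cohort/route or unusable exposure parameter."""


class TlcrClass(str, Enum):
    VERY_LOW = "very_low"
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"
    VERY_HIGH = "very_high"


@dataclass(frozen=True)
class CohortParameters:
    """Per-cohort intake/contact constants (units in module docstring)."""

    igr: float
    ed: float
    bw: float
    sa: float
    af: float


@dataclass(frozen=True)
class ExposureParameters:
    cohorts: Mapping[str, CohortParameters]
    cf: float = 1e-6
    ef_days: float = 365.0
    ihr: float = 20.0
    pef: float = 1.36e9
    lifetime_years: float = 70.0

    def cohort(self, name: str) -> CohortParameters:
        try:
            return self.cohorts[name]
        except KeyError:
            raise ParameterError(
                f"unknown cohort {name!r}; expected one of {list(self.cohorts)}"
            ) from None


@dataclass(frozen=True)
class ElementToxicity:
    """Route RfDs (mg/kg/day), slope factors ((mg/kg/day)^-1), dermal ABS."""

    rfd: Mapping[str, float | None]
    sf: Mapping[str, float | None]
    abs_frac: float | None = 0.01


class ToxicityTable:
    def __init__(self, elements: Mapping[str, ElementToxicity]) -> None:
        self.elements = dict(elements)

    def __contains__(self, element: str) -> bool:
        return element in self.elements

    def __getitem__(self, element: str) -> ElementToxicity:
        try:
            return self.elements[element]
        except KeyError:
            raise ConfigurationError(
                f"element {element!r} absent from the toxicity table"
            ) from None

    def has_slope_factor(self, element: str) -> bool:
        entry = self.elements.get(element)
        return entry is not None and any(
            entry.sf.get(route) is not None for route in ROUTES
        )


def load_exposure_parameters(path: str | Path | None = None) -> ExposureParameters:
    """Load cohort exposure constants; ``None`` loads the bundled defaults."""
    if path is None:
        path = _data_path("exposure_parameters.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cohorts = {
        name: CohortParameters(**{k: float(v) for k, v in fields.items()})
        for name, fields in raw["cohorts"].items()
    }
    params = ExposureParameters(
        cohorts=cohorts,
        cf=float(raw.get("cf", 1e-6)),
        ef_days=float(raw.get("ef_days", 365)),
        ihr=float(raw.get("ihr", 20)),
        pef=float(raw.get("pef", 1.36e9)),
        lifetime_years=float(raw.get("lifetime_years", 70)),
    )
    for name, c in cohorts.items():
        for field_name in ("igr", "ed", "bw", "sa", "af"):
            if getattr(c, field_name) <= 0:
                raise ParameterError(
                    f"cohort {name!r}: {field_name} must be > 0"
                )
    return params


def load_toxicity_table(path: str | Path | None = None) -> ToxicityTable:
    """Load the per-element RfD/slope-factor/ABS table (bundled default)."""
    if path is None:
        path = _data_path("toxicity.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    elements = {}
    for symbol, entry in raw["elements"].items():
        rfd = {r: entry.get(f"rfd_{r}") for r in ROUTES}
        sf = {r: entry.get(f"sf_{r}") for r in ROUTES}
        rfd = {r: (None if v is None else float(v)) for r, v in rfd.items()}
        sf = {r: (None if v is None else float(v)) for r, v in sf.items()}
        for route, value in rfd.items():
            if value is not None and value <= 0:
                raise ConfigurationError(
                    f"{symbol}: rfd_{route} must be > 0, got {value}"
                )
        abs_frac = entry.get("abs")
        elements[symbol] = ElementToxicity(
            rfd=rfd, sf=sf,
            abs_frac=None if abs_frac is None else float(abs_frac),
        )
    return ToxicityTable(elements)


def _averaging_time(
    p: ExposureParameters, cohort: CohortParameters, mode: str, at_mode: str
) -> float:
    if mode == "noncarc":
        return 365.0 * cohort.ed
    if mode != "carc":
        raise ParameterError(f"mode must be 'noncarc' or 'carc', got {mode!r}")
    if at_mode == "as_stated":
        return 365.0 * p.lifetime_years
    if at_mode == "as_tabulated":
        return 365.0 * cohort.ed
    raise ParameterError(
        f"at_mode must be 'as_stated' or 'as_tabulated', got {at_mode!r}"
    )


def _check_concentration(c) -> None:
    if np.any(np.asarray(c) < 0) or not np.all(np.isfinite(np.asarray(c))):
        raise ValueError(f"concentration must be finite and >= 0, got {c!r}")


def add_ingestion(
    c,
    p: ExposureParameters,
    cohort: str,
    mode: str = "noncarc",
    at_mode: str = "as_stated",
):
    """Ingestion-route average daily dose, mg/kg/day."""
    _check_concentration(c)
    k = p.cohort(cohort)
    at = _averaging_time(p, k, mode, at_mode)
    return c * k.igr * p.ef_days * k.ed * p.cf / (k.bw * at)


def add_dermal(
    c,
    p: ExposureParameters,
    cohort: str,
    abs_frac: float | None,
    mode: str = "noncarc",
    at_mode: str = "as_stated",
):
    """Dermal-contact average daily dose, mg/kg/day."""
    _check_concentration(c)
    if abs_frac is None:
        raise ConfigurationError(
            "dermal ADD requires an absorption fraction (ABS); none defined"
        )
    k = p.cohort(cohort)
    at = _averaging_time(p, k, mode, at_mode)
    return c * k.sa * k.af * abs_frac * p.ef_days * k.ed * p.cf / (k.bw * at)


def add_inhalation(
    c,
    p: ExposureParameters,
    cohort: str,
    mode: str = "noncarc",
    at_mode: str = "as_stated",
):
    """Inhalation-route average daily dose, mg/kg/day."""
    _check_concentration(c)
    k = p.cohort(cohort)
    at = _averaging_time(p, k, mode, at_mode)
    return c * p.ihr * p.ef_days * k.ed / (p.pef * k.bw * at)


def average_daily_doses(
    c,
    element: str,
    p: ExposureParameters,
    tox: ToxicityTable,
    cohort: str,
    mode: str = "noncarc",
    at_mode: str = "as_stated",
) -> dict[str, float]:
    """All three route ADDs for one element/cohort as {route: mg/kg/day}."""
    abs_frac = tox[element].abs_frac
    return {
        "ingestion": add_ingestion(c, p, cohort, mode, at_mode),
        "dermal": add_dermal(c, p, cohort, abs_frac, mode, at_mode),
        "inhalation": add_inhalation(c, p, cohort, mode, at_mode),
    }


@dataclass(frozen=True)
class HazardResult:
    element: str
    cohort: str
    hq: Mapping[str, float]  # routes with an available RfD only
    hi: float
    complete: bool  # False when a route lacked an RfD and was omitted
    concern: bool  # HI > 1
    omitted_routes: tuple[str, ...] = ()


def hazard(
    c,
    element: str,
    p: ExposureParameters,
    tox: ToxicityTable,
    cohort: str,
) -> HazardResult:
    """Route hazard quotients and the hazard index for one element.

    Routes without a reference dose are omitted (and flagged), never
    zero-filled: an HI over a subset of routes is a lower bound.
    """
    entry = tox[element]
    if all(entry.rfd.get(route) is None for route in ROUTES):
        raise ConfigurationError(f"no reference dose available for {element!r}")
    adds = average_daily_doses(c, element, p, tox, cohort, mode="noncarc")
    hq: dict[str, float] = {}
    omitted: list[str] = []
    for route in ROUTES:
        rfd = entry.rfd.get(route)
        if rfd is None:
            omitted.append(route)
        else:
            hq[route] = float(adds[route] / rfd)
    hi = float(sum(hq.values()))
    return HazardResult(
        element=element,
        cohort=cohort,
        hq=hq,
        hi=hi,
        complete=not omitted,
        concern=hi > 1.0,
        omitted_routes=tuple(omitted),
    )


def classify_tlcr(tlcr: float) -> TlcrClass:
    """Five-tier lifetime cancer risk classification.

    Bins: very_low <= 1e-6 < low <= 1e-4 < moderate < 1e-3 <= high < 1e-1
    <= very_high.  The conventional statement of the bins assigns 1e-3 to
    both 'moderate' and 'high'; it is resolved to 'high' here so the bins
    partition the non-negative reals.
    """
    if tlcr < 0 or not np.isfinite(tlcr):
        raise ValueError(f"TLCR must be finite and >= 0, got {tlcr!r}")
    if tlcr <= 1e-6:
        return TlcrClass.VERY_LOW
    if tlcr <= 1e-4:
        return TlcrClass.LOW
    if tlcr < 1e-3:
        return TlcrClass.MODERATE
    if tlcr < 1e-1:
        return TlcrClass.HIGH
    return TlcrClass.VERY_HIGH


def tlcr_from_routes(lcr_by_route: Mapping[str, float]) -> float:
    """TLCR = sum of the available route LCRs (pure summation)."""
    return float(sum(lcr_by_route.values()))


def is_acceptable(tlcr: float) -> bool:
    low, high = ACCEPTABLE_RISK_RANGE
    return low <= tlcr <= high


@dataclass(frozen=True)
class CancerRiskResult:
    element: str
    cohort: str
    lcr: Mapping[str, float]  # routes with an available slope factor only
    tlcr: float
    tlcr_class: TlcrClass
    acceptable: bool
    omitted_routes: tuple[str, ...] = ()


def cancer_risk(
    c,
    element: str,
    p: ExposureParameters,
    tox: ToxicityTable,
    cohort: str,
    at_mode: str = "as_stated",
) -> CancerRiskResult:
    """Route lifetime cancer risks and their TLCR for one element.

    Raises :class:`ConfigurationError` when the element has no slope factor
    on any route (e.g. Cu, Pb, Zn in most registries) — such elements are
    assessed for non-carcinogenic risk only.
    """
    entry = tox[element]
    if not tox.has_slope_factor(element):
        raise ConfigurationError(
            f"no cancer slope factor available for {element!r}; "
            "element is excluded from carcinogenic risk"
        )
    adds = average_daily_doses(
        c, element, p, tox, cohort, mode="carc", at_mode=at_mode
    )
    lcr: dict[str, float] = {}
    omitted: list[str] = []
    for route in ROUTES:
        sf = entry.sf.get(route)
        if sf is None:
            omitted.append(route)
        else:
            lcr[route] = float(adds[route] * sf)
    tlcr = tlcr_from_routes(lcr)
    return CancerRiskResult(
        element=element,
        cohort=cohort,
        lcr=lcr,
        tlcr=tlcr,
        tlcr_class=classify_tlcr(tlcr),
        acceptable=is_acceptable(tlcr),
        omitted_routes=tuple(omitted),
    )


def _scope_means(study_or_means, scope: str) -> pd.DataFrame:
    if isinstance(study_or_means, StudyTable):
        if scope == "study":
            return study_or_means.mean_concentrations().to_frame("study").T
        if scope == "county":
            return study_or_means.county_mean_concentrations()
        if scope == "sample":
            return study_or_means.concentration_frame()
        raise ParameterError(
            f"scope must be 'sample', 'county' or 'study', got {scope!r}"
        )
    if isinstance(study_or_means, pd.Series):
        return study_or_means.to_frame("study").T
    if isinstance(study_or_means, pd.DataFrame):
        return study_or_means
    raise TypeError(
        "risk_table expects a StudyTable, a Series of mean concentrations, "
        "or a scope x element DataFrame"
    )


def risk_table(
    study_or_means,
    elements: Sequence[str] = PRIORITY_METALS,
    cohorts: Sequence[str] = COHORTS,
    p: ExposureParameters | None = None,
    tox: ToxicityTable | None = None,
    scope: str = "study",
    at_mode: str = "as_stated",
) -> pd.DataFrame:
    """Full risk table: one row per scope x element x cohort.

    Columns: the three non-carcinogenic route ADDs, HQs and HI, the three
    carcinogenic route ADDs, LCRs, TLCR, its class and the acceptable-range
    flag.  Elements without any slope factor get hazard output only (their
    LCR columns are NaN), mirroring how published risk tables omit them.
    """
    p = p or load_exposure_parameters()
    tox = tox or load_toxicity_table()
    means = _scope_means(study_or_means, scope)
    if means.empty:
        raise ValueError("risk_table: empty scope — nothing to assess")
    missing = [e for e in elements if e not in means.columns]
    if missing:
        raise ConfigurationError(f"no concentrations for elements {missing}")

    rows = []
    for scope_label, concentrations in means.iterrows():
        for element in elements:
            c = float(concentrations[element])
            for cohort in cohorts:
                row: dict[str, object] = {
                    "scope": scope_label,
                    "element": element,
                    "cohort": cohort,
                    "concentration_mg_kg": c,
                }
                haz = hazard(c, element, p, tox, cohort)
                adds_nc = average_daily_doses(
                    c, element, p, tox, cohort, mode="noncarc"
                )
                for route in ROUTES:
                    row[f"add_{route}_noncarc"] = adds_nc[route]
                    row[f"hq_{route}"] = haz.hq.get(route, np.nan)
                row["hi"] = haz.hi
                row["hi_complete"] = haz.complete
                row["concern"] = haz.concern
                if tox.has_slope_factor(element):
                    cr = cancer_risk(c, element, p, tox, cohort, at_mode)
                    adds_c = average_daily_doses(
                        c, element, p, tox, cohort, mode="carc", at_mode=at_mode
                    )
                    for route in ROUTES:
                        row[f"add_{route}_carc"] = adds_c[route]
                        row[f"lcr_{route}"] = cr.lcr.get(route, np.nan)
                    row["tlcr"] = cr.tlcr
                    row["tlcr_class"] = cr.tlcr_class.value
                    row["acceptable"] = cr.acceptable
                else:
                    for route in ROUTES:
                        row[f"add_{route}_carc"] = np.nan
                        row[f"lcr_{route}"] = np.nan
                    row["tlcr"] = np.nan
                    row["tlcr_class"] = None
                    row["acceptable"] = None
                rows.append(row)
    return pd.DataFrame(rows)
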