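"""Shared data model and file I/O for household dust surveys.

A survey is a per-sample table: element concentrations in mg/kg dry dust,
culturable bacterial loads in cfu/g, household habitat attributes and a
sampling location.  Units are fixed by contract (mg/kg, cfu/g) — nothing is
inferred from column headers, because silent unit errors are the dominant
failure mode in risk-assessment pipelines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

try:  # Python >= 3.9
    from importlib.resources import files as _resource_files
except ImportError:  # pragma: no cover
    _resource_files = None


class SchemaError(ValueError):
    """The input file does not conform to the declared column schema."""


class ValidationError(ValueError):
    """A row violates a data invariant (e.g. negative concentration)."""


class ConfigurationError(ValueError):
    """A reference/configuration table is unusable for the requested task."""


#: Canonical habitat attributes and their allowed levels.  ``None`` marks a
#: value explicitly missing; missing values are excluded from group summaries
#: but the sample is retained everywhere else.
HABITAT_LEVELS: dict[str, tuple[str, ...]] = {
    "home_type": ("apartment", "single_family"),
    "home_age_class": ("<10y", "10-30y", ">30y"),
    "floor_type": ("carpet", "partial", "none"),
    "pets": ("no", "yes"),
    "heating": ("electric", "gas"),
}

#: Default element panel: nine heavy metals plus five macro elements.
DEFAULT_ELEMENTS: tuple[str, ...] = (
    "Al", "As", "Cd", "Cr", "Cu", "Fe", "Ni", "Pb", "Zn",
    "Na", "Mg", "K", "Ca", "Mn",
)

#: Required non-element columns of the sample CSV, in canonical order.
SAMPLE_COLUMNS: tuple[str, ...] = ("sample_id", "county", "lon", "lat")
BACTERIA_COLUMNS: tuple[str, ...] = ("tb_cfu_g", "eb_cfu_g")
HABITAT_COLUMNS: tuple[str, ...] = tuple(HABITAT_LEVELS)


@dataclass(frozen=True)
class HabitatAttributes:
    """Household survey attributes; ``None`` = explicitly missing."""

    home_type: str | None = None
    home_age_class: str | None = None
    floor_type: str | None = None
    pets: str | None = None
    heating: str | None = None

    def __post_init__(self) -> None:
        for attr, allowed in HABITAT_LEVELS.items():
            value = getattr(self, attr)
            if value is not None and value not in allowed:
                raise ValidationError(
                    f"habitat attribute {attr!r} has level {value!r}; "
                    f"allowed: {allowed}"
                )


@dataclass(frozen=True)
class DustSample:
    """One household's dust measurements.

    Parameters
    ----------
    sample_id : unique short identifier (e.g. ``"S13"``).
    county : sampling county name.
    lon, lat : decimal degrees.
    concentrations : element symbol -> concentration in mg/kg dry dust.
    total_bacteria, enteric_bacteria : culturable loads in cfu/g.
    habitat : household attributes from the survey questionnaire.
    """

    sample_id: str
    county: str
    lon: float
    lat: float
    concentrations: Mapping[str, float]
    total_bacteria: float = 0.0
    enteric_bacteria: float = 0.0
    habitat: HabitatAttributes = field(default_factory=HabitatAttributes)

    def __post_init__(self) -> None:
        for element, value in self.concentrations.items():
            if not np.isfinite(value) or value < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: concentration of {element} "
                    f"is {value!r}; must be finite and >= 0"
                )
        for name, value in (
            ("total_bacteria", self.total_bacteria),
            ("enteric_bacteria", self.enteric_bacteria),
        ):
            if not np.isfinite(value) or value < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: {name} is {value!r}; "
                    "must be finite and >= 0"
                )


class StudyTable:
    """An ordered, validated collection of :class:`DustSample`.

    Rectangular over the declared element panel: every sample reports every
    panel element.  Provides the pandas views used by the statistics,
    enrichment and risk stages.
    """

    def __init__(
        self,
        samples: Sequence[DustSample],
        elements: Sequence[str] | None = None,
        provenance: Mapping[str, object] | None = None,
    ) -> None:
        samples = list(samples)
        if elements is None:
            if not samples:
                raise ValidationError("empty study: no samples and no panel")
            elements = tuple(samples[0].concentrations)
        self.elements: tuple[str, ...] = tuple(elements)
        self.provenance: dict[str, object] = dict(provenance or {})

        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample ids: {dupes}")
        for s in samples:
            missing = [e for e in self.elements if e not in s.concentrations]
            if missing:
                raise ValidationError(
                    f"sample {s.sample_id!r} lacks panel elements {missing}"
                )
        self.samples: tuple[DustSample, ...] = tuple(samples)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_dataframe(self) -> pd.DataFrame:
        """Flat per-sample table (one row per sample, canonical columns)."""
        rows = []
        for s in self.samples:
            row: dict[str, object] = {
                "sample_id": s.sample_id,
                "county": s.county,
                "lon": s.lon,
                "lat": s.lat,
            }
            for e in self.elements:
                row[e] = s.concentrations[e]
            row["tb_cfu_g"] = s.total_bacteria
            row["eb_cfu_g"] = s.enteric_bacteria
            for attr in HABITAT_COLUMNS:
                row[attr] = getattr(s.habitat, attr)
            rows.append(row)
        return pd.DataFrame(rows)

    def concentration_frame(self) -> pd.DataFrame:
        """Samples x elements concentration matrix, indexed by sample_id."""
        data = {
            e: [s.concentrations[e] for s in self.samples] for e in self.elements
        }
        return pd.DataFrame(data, index=self.sample_ids)

    def variable_frame(self) -> pd.DataFrame:
        """Concentrations plus bacterial loads (columns TB, EB)."""
        frame = self.concentration_frame()
        frame["TB"] = [s.total_bacteria for s in self.samples]
        frame["EB"] = [s.enteric_bacteria for s in self.samples]
        return frame

    def mean_concentrations(self) -> pd.Series:
        return self.concentration_frame().mean(axis=0)

    def county_mean_concentrations(self) -> pd.DataFrame:
        """County x element table of mean concentrations."""
        frame = self.concentration_frame()
        frame["county"] = [s.county for s in self.samples]
        return frame.groupby("county", sort=True).mean()

    def group_levels(self, attribute: str) -> dict[str, list[str]]:
        """sample_ids per level of a habitat attribute or ``"county"``.

        Samples with the attribute missing are excluded (they stay in the
        study for every non-grouped analysis).
        """
        if attribute == "county":
            levels: dict[str, list[str]] = {}
            for s in self.samples:
                levels.setdefault(s.county, []).append(s.sample_id)
            return levels
        if attribute not in HABITAT_LEVELS:
            raise KeyError(
                f"unknown grouping attribute {attribute!r}; "
                f"choose from {('county', *HABITAT_LEVELS)}"
            )
        levels = {}
        for s in self.samples:
            value = getattr(s.habitat, attribute)
            if value is not None:
                levels.setdefault(value, []).append(s.sample_id)
        return levels


@dataclass(frozen=True)
class ReferencePanel:
    """Background soil concentrations and ecological screening values.

    ``background`` holds regional (Texas) soil background concentrations in
    mg/kg; ``esv`` the ecological screening values where defined.  Elements
    with a non-positive background are ineligible for enrichment factors
    (the double ratio is undefined) and requests for them raise
    :class:`ConfigurationError` rather than returning infinity.
    """

    background: Mapping[str, float]
    esv: Mapping[str, float]
    reference_element: str = "Al"

    def __post_init__(self) -> None:
        if self.reference_element not in self.background:
            raise ConfigurationError(
                f"reference element {self.reference_element!r} missing from "
                "background table"
            )
        if self.background[self.reference_element] <= 0:
            raise ConfigurationError(
                f"background of reference element {self.reference_element!r} "
                "must be > 0"
            )

    @property
    def background_reference(self) -> float:
        return float(self.background[self.reference_element])

    def ef_eligible(self, element: str) -> bool:
        return element in self.background and self.background[element] > 0

    def require_background(self, element: str) -> float:
        if not self.ef_eligible(element):
            raise ConfigurationError(
                f"element {element!r} is EF-ineligible: background is "
                f"{self.background.get(element, 'absent')!r} (must be > 0)"
            )
        return float(self.background[element])

    def require_esv(self, element: str) -> float:
        if element not in self.esv:
            raise ConfigurationError(
                f"no ecological screening value defined for {element!r}"
            )
        return float(self.esv[element])


def _data_path(name: str) -> Path:
    return Path(str(_resource_files("dustrisk").joinpath("data", name)))


def load_reference_panel(path: str | Path | None = None) -> ReferencePanel:
    """Load a reference panel from YAML; ``None`` loads the bundled default.

    The bundled default reproduces the Texas soil background and Region 4
    ecological screening values used throughout this analysis (Cd has a
    published background of 0 and is therefore EF-ineligible by design).
    """
    if path is None:
        path = _data_path("reference_panel.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "background" not in raw:
        raise ConfigurationError(f"{path}: expected a mapping with 'background'")
    return ReferencePanel(
        background={k: float(v) for k, v in raw["background"].items()},
        esv={k: float(v) for k, v in raw.get("esv", {}).items()},
        reference_element=raw.get("reference_element", "Al"),
    )


def load_study_means(path: str | Path | None = None) -> pd.Series:
    """Published study-wide mean concentrations (mg/kg; TB/EB in cfu/g)."""
    if path is None:
        path = _data_path("study_means.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return pd.Series({k: float(v) for k, v in raw["mean"].items()})


def _coerce_habitat(value: object) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if not text or text.lower() in {"na", "nan", "missing"}:
        return None
    return text


def read_samples(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    elements: Sequence[str] | None = None,
) -> StudyTable:
    """Read and validate a per-sample dust survey CSV.

    Parameters
    ----------
    path : CSV file with columns ``sample_id, county, lon, lat``, one column
        per panel element (mg/kg), ``tb_cfu_g, eb_cfu_g`` and the habitat
        columns.  Units are fixed by this contract, never inferred.
    schema : optional mapping from canonical column name to the actual
        header in the file.
    elements : element panel to require; default: every canonical element
        column present in the file.

    Rows with non-numeric concentrations are rejected and reported in
    ``provenance["diagnostics"]``; a negative concentration raises
    :class:`ValidationError` naming the sample.  Missing habitat fields are
    kept as missing, never imputed.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    if frame.empty:
        raise SchemaError(f"{path}: no data rows")

    schema = dict(schema or {})
    rename = {actual: canonical for canonical, actual in schema.items()}
    frame = frame.rename(columns=rename)

    for column in SAMPLE_COLUMNS:
        if column not in frame.columns:
            raise SchemaError(f"{path}: missing mandatory column {column!r}")

    if elements is None:
        elements = [e for e in DEFAULT_ELEMENTS if e in frame.columns]
        if not elements:
            raise SchemaError(f"{path}: no element concentration columns found")
    else:
        missing = [e for e in elements if e not in frame.columns]
        if missing:
            raise SchemaError(f"{path}: missing element columns {missing}")

    diagnostics: list[str] = []
    samples: list[DustSample] = []
    numeric_cols = list(elements) + [
        c for c in BACTERIA_COLUMNS if c in frame.columns
    ]
    for _, row in frame.iterrows():
        sample_id = str(row["sample_id"])
        values: dict[str, float] = {}
        bad = False
        for column in numeric_cols:
            try:
                value = float(row[column])
            except (TypeError, ValueError):
                diagnostics.append(
                    f"sample {sample_id!r}: non-numeric {column} value "
                    f"{row[column]!r}; row rejected"
                )
                bad = True
                break
            if np.isnan(value):
                diagnostics.append(
                    f"sample {sample_id!r}: missing {column}; row rejected"
                )
                bad = True
                break
            if value < 0:
                raise ValidationError(
                    f"sample {sample_id!r}: negative {column} value {value}"
                )
            values[column] = value
        if bad:
            continue
        habitat = HabitatAttributes(
            **{
                attr: _coerce_habitat(row[attr]) if attr in frame.columns else None
                for attr in HABITAT_COLUMNS
            }
        )
        samples.append(
            DustSample(
                sample_id=sample_id,
                county=str(row["county"]),
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                concentrations={e: values[e] for e in elements},
                total_bacteria=values.get("tb_cfu_g", 0.0),
                enteric_bacteria=values.get("eb_cfu_g", 0.0),
                habitat=habitat,
            )
        )
    if not samples:
        raise SchemaError(f"{path}: every row was rejected; see diagnostics")
    return StudyTable(
        samples,
        elements=elements,
        provenance={
            "source": str(path),
            "units": {"concentrations": "mg/kg", "bacteria": "cfu/g"},
            "diagnostics": diagnostics,
        },
    )


def write_samples(study: StudyTable, path: str | Path) -> None:
    """Write a StudyTable back to the canonical sample CSV layout."""
    frame = study.to_dataframe()
    frame.to_csv(path, index=False, float_format="%.10g")


def write_report(
    results: pd.DataFrame | Iterable[Mapping[str, object]],
    path: str | Path,
    format: str = "csv",
) -> None:
    """Write a result table to CSV or JSON with deterministic layout.

    Floats are serialized with 10 significant digits so a round-trip read
    reproduces values to well beyond 6 significant digits.  An empty result
    set is an error and no file is created.
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame(list(results))
    if results.empty:
        raise ValidationError("refusing to write an empty result set")
    path = Path(path)
    if format == "csv":
        results.to_csv(path, index=False, float_format="%.10g")
    elif format == "json":
        records = json.loads(results.to_json(orient="records", double_precision=10))
        path.write_text(json.dumps(records, indent=1, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}; use 'csv' or 'json'")
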