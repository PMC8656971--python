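"""Synthetic household dust survey generator.

Emulates a small multi-county indoor-dust survey: right-skewed element
concentrations (log-normal marginals) with a realistic inter-element
dependence structure (Gaussian copula on the log scale), categorical
household habitat attributes with multiplicative effects on selected
elements, and sample coordinates scattered over coarse county rectangles.

The default configuration reproduces the published summary statistics of a
31-residence Southeast Texas survey: study-wide arithmetic means for nine
metals, five macro elements and two bacterial loads, the printed 16x16
Pearson correlation matrix, and the county allocation 22/4/4/1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io_model import (
    ConfigurationError,
    DustSample,
    HabitatAttributes,
    StudyTable,
    load_study_means,
)

#: Variable order of the default correlation matrix.
DEFAULT_VARIABLES: tuple[str, ...] = (
    "Al", "As", "Cd", "Cr", "Cu", "Fe", "Ni", "Pb", "Zn",
    "Na", "Mg", "K", "Ca", "Mn", "TB", "EB",
)

# Published pairwise Pearson correlations among log concentrations and
# bacterial loads (lower triangle, row -> {column: r}).  Verified to be
# positive semi-definite as printed (min eigenvalue ~ 0.016).
_DEFAULT_CORRELATIONS: dict[str, dict[str, float]] = {
    "As": {"Al": 0.42},
    "Cd": {"Al": 0.36, "As": 0.54},
    "Cr": {"Al": 0.65, "As": 0.57, "Cd": 0.38},
    "Cu": {"Al": -0.16, "As": 0.33, "Cd": 0.28, "Cr": 0.08},
    "Fe": {"Al": -0.20, "As": 0.36, "Cd": 0.26, "Cr": 0.32, "Cu": 0.57},
    "Ni": {"Al": 0.09, "As": 0.41, "Cd": 0.15, "Cr": 0.27, "Cu": 0.61,
           "Fe": 0.62},
    "Pb": {"Al": 0.54, "As": 0.59, "Cd": 0.56, "Cr": 0.56, "Cu": 0.26,
           "Fe": 0.26, "Ni": 0.36},
    "Zn": {"Al": -0.06, "As": 0.38, "Cd": 0.37, "Cr": 0.25, "Cu": 0.70,
           "Fe": 0.78, "Ni": 0.67, "Pb": 0.39},
    "Na": {"Al": -0.47, "As": -0.38, "Cd": -0.27, "Cr": -0.59, "Cu": 0.07,
           "Fe": -0.23, "Ni": -0.05, "Pb": -0.50, "Zn": -0.30},
    "Mg": {"Al": 0.06, "As": 0.23, "Cd": -0.24, "Cr": 0.19, "Cu": -0.23,
           "Fe": 0.18, "Ni": -0.07, "Pb": -0.04, "Zn": -0.11, "Na": -0.31},
    "K": {"Al": -0.11, "As": 0.29, "Cd": 0.15, "Cr": 0.21, "Cu": 0.42,
          "Fe": 0.48, "Ni": 0.38, "Pb": 0.00, "Zn": 0.37, "Na": 0.31,
          "Mg": 0.04},
    "Ca": {"Al": -0.52, "As": -0.20, "Cd": -0.33, "Cr": -0.34, "Cu": -0.06,
           "Fe": 0.20, "Ni": -0.07, "Pb": -0.31, "Zn": -0.02, "Na": -0.15,
           "Mg": 0.53, "K": -0.35},
    "Mn": {"Al": -0.05, "As": 0.29, "Cd": 0.20, "Cr": 0.32, "Cu": 0.38,
           "Fe": 0.85, "Ni": 0.57, "Pb": 0.34, "Zn": 0.63, "Na": -0.38,
           "Mg": 0.29, "K": 0.31, "Ca": 0.29},
    "TB": {"Al": 0.19, "As": 0.45, "Cd": -0.08, "Cr": 0.40, "Cu": 0.40,
           "Fe": 0.38, "Ni": 0.43, "Pb": 0.42, "Zn": 0.347, "Na": -0.18,
           "Mg": 0.10, "K": 0.46, "Ca": -0.30, "Mn": 0.38},
    "EB": {"Al": 0.15, "As": 0.56, "Cd": 0.13, "Cr": 0.36, "Cu": 0.55,
           "Fe": 0.44, "Ni": 0.54, "Pb": 0.515, "Zn": 0.45, "Na": -0.06,
           "Mg": 0.03, "K": 0.56, "Ca": -0.25, "Mn": 0.42, "TB": 0.88},
}

#: Coarse bounding rectangles (lon_min, lon_max, lat_min, lat_max) for the
#: surveyed counties; deliberately not cartographic boundaries.
DEFAULT_COUNTY_BBOXES: dict[str, tuple[float, float, float, float]] = {
    "Harris": (-95.85, -95.00, 29.50, 30.15),
    "Fort Bend": (-96.10, -95.45, 29.35, 29.80),
    "Brazoria": (-95.90, -95.15, 28.90, 29.45),
    "Montgomery": (-95.80, -95.15, 30.10, 30.65),
}


def default_correlation_matrix() -> pd.DataFrame:
    names = list(DEFAULT_VARIABLES)
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for row, cols in _DEFAULT_CORRELATIONS.items():
        for col, value in cols.items():
            r.loc[row, col] = value
            r.loc[col, row] = value
    return r


@dataclass
class SimulationConfig:
    """Full description of the stochastic world the generator draws from.

    ``means`` are target *arithmetic* means on the original scale; the
    log-normal location is set to ``ln(mean) - sigma^2/2`` so the expected
    arithmetic mean equals the target.  ``habitat_effects`` maps
    attribute -> level -> element -> multiplicative factor, applied after
    the copula draw and re-centred so overall means are preserved.
    """

    n_samples: int = 31
    means: dict[str, float] = field(default_factory=dict)
    log_sd: dict[str, float] = field(default_factory=dict)
    correlation: pd.DataFrame | None = None
    habitat_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    habitat_effects: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=dict
    )
    county_weights: dict[str, float] = field(default_factory=dict)
    county_bboxes: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict
    )
    seed: int = 0
    psd_repair_tolerance: float = 0.1

    @property
    def variables(self) -> list[str]:
        return list(self.means)

    @property
    def elements(self) -> list[str]:
        return [v for v in self.means if v not in ("TB", "EB")]

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        for name, mean in self.means.items():
            if mean <= 0:
                raise ConfigurationError(f"mean of {name!r} must be > 0")
        for name in self.means:
            if self.log_sd.get(name, 0.0) < 0:
                raise ConfigurationError(f"log_sd of {name!r} must be >= 0")
        for attr, levels in self.habitat_effects.items():
            for level, factors in levels.items():
                for element, factor in factors.items():
                    if factor <= 0:
                        raise ConfigurationError(
                            f"habitat multiplier ({attr}={level}, {element}) "
                            f"must be > 0, got {factor}"
                        )
        if self.correlation is not None:
            r = self.correlation
            if list(r.index) != list(r.columns):
                raise ConfigurationError("correlation matrix index != columns")
            if not np.allclose(r.values, r.values.T, atol=1e-12):
                raise ConfigurationError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(r.values), 1.0, atol=1e-12):
                raise ConfigurationError("correlation diagonal must be 1")


def default_config(seed: int = 0) -> SimulationConfig:
    """The stated-world default: a 31-residence, four-county survey.

    Means come from the published study-wide Mean rows; the correlation
    target is the printed 16-variable matrix; habitat effect sizes follow
    the printed home-age contrasts for Pb and Cd (old housing stock carries
    legacy paint and plastics); county weights are the published 22/4/4/1.
    """
    means = load_study_means().to_dict()
    log_sd = {v: (0.8 if v in ("TB", "EB") else 0.6) for v in means}
    habitat_probs = {
        "home_type": {"apartment": 7 / 31, "single_family": 24 / 31},
        "home_age_class": {"<10y": 4 / 31, "10-30y": 17 / 31, ">30y": 10 / 31},
        "floor_type": {"carpet": 14 / 31, "partial": 12 / 31, "none": 5 / 31},
        "pets": {"no": 20 / 31, "yes": 11 / 31},
        "heating": {"electric": 16 / 31, "gas": 15 / 31},
    }
    # Multiplicative group contrasts relative to the 10-30y baseline,
    # taken from the printed home-age group means (Pb 40/25/58, Cd 1.8/1.2/3.2).
    habitat_effects = {
        "home_age_class": {
            "<10y": {"Pb": 40 / 25, "Cd": 1.8 / 1.2},
            ">30y": {"Pb": 58 / 25, "Cd": 3.2 / 1.2},
        }
    }
    return SimulationConfig(
        n_samples=31,
        means=means,
        log_sd=log_sd,
        correlation=default_correlation_matrix(),
        habitat_probs=habitat_probs,
        habitat_effects=habitat_effects,
        county_weights={"Harris": 22, "Fort Bend": 4, "Brazoria": 4,
                        "Montgomery": 1},
        county_bboxes=dict(DEFAULT_COUNTY_BBOXES),
        seed=seed,
    )


def repair_correlation(
    r: pd.DataFrame, tolerance: float = 0.1
) -> tuple[pd.DataFrame, float]:
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping.

    Returns the repaired matrix (unit diagonal restored) and the largest
    absolute entry adjustment.  A matrix whose smallest eigenvalue is below
    ``-tolerance`` is considered too broken to repair silently.
    """
    values = r.values.astype(float)
    eigenvalues, vectors = np.linalg.eigh(values)
    if eigenvalues.min() < -tolerance:
        raise ConfigurationError(
            "correlation matrix is far from positive semi-definite "
            f"(min eigenvalue {eigenvalues.min():.3f} < -{tolerance}); "
            "check the configured targets"
        )
    if eigenvalues.min() >= 0:
        return r.copy(), 0.0
    clipped = np.clip(eigenvalues, 0.0, None)
    repaired = vectors @ np.diag(clipped) @ vectors.T
    scale = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(scale, scale)
    np.fill_diagonal(repaired, 1.0)
    adjustment = float(np.abs(repaired - values).max())
    return pd.DataFrame(repaired, index=r.index, columns=r.columns), adjustment


def _allocate_counties(weights: Mapping[str, float], n: int) -> list[str]:
    """Largest-remainder allocation of n samples to counties (deterministic)."""
    names = list(weights)
    total = float(sum(weights.values()))
    quotas = {c: n * weights[c] / total for c in names}
    counts = {c: int(np.floor(quotas[c])) for c in names}
    short = n - sum(counts.values())
    by_remainder = sorted(names, key=lambda c: (counts[c] - quotas[c], c))
    for c in by_remainder[:short]:
        counts[c] += 1
    assignment: list[str] = []
    for c in names:
        assignment.extend([c] * counts[c])
    return assignment


def _correlated_normals(
    rng: np.random.Generator, n: int, r: np.ndarray
) -> np.ndarray:
    """n x k standard normals with correlation r, via a triangular factor."""
    try:
        factor = np.linalg.cholesky(r + 1e-12 * np.eye(len(r)))
    except np.linalg.LinAlgError:
        eigenvalues, vectors = np.linalg.eigh(r)
        factor = vectors @ np.diag(np.sqrt(np.clip(eigenvalues, 0.0, None)))
    z = rng.standard_normal((n, len(r)))
    return z @ factor.T


def simulate_study(config: SimulationConfig) -> StudyTable:
    """Draw a synthetic survey; identical config and seed => identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    variables = config.variables
    n = config.n_samples

    if config.correlation is not None:
        missing = [v for v in variables if v not in config.correlation.index]
        if missing:
            raise ConfigurationError(
                f"correlation matrix lacks variables {missing}"
            )
        r = config.correlation.loc[variables, variables]
        r, adjustment = repair_correlation(r, config.psd_repair_tolerance)
        z = _correlated_normals(rng, n, r.values)
    else:
        adjustment = 0.0
        z = rng.standard_normal((n, len(variables)))

    sigma = np.array([config.log_sd.get(v, 0.0) for v in variables])
    mean = np.array([config.means[v] for v in variables])
    mu = np.log(mean) - sigma**2 / 2  # arithmetic-mean parameterization
    values = np.exp(mu + sigma * z)

    # Habitat attributes: categorical draws, then multiplicative effects
    # re-centred so the configured overall means are preserved.
    habitat_draws: dict[str, np.ndarray] = {}
    for attr in sorted(config.habitat_probs):
        levels = list(config.habitat_probs[attr])
        probs = np.array([config.habitat_probs[attr][lv] for lv in levels])
        probs = probs / probs.sum()
        habitat_draws[attr] = rng.choice(levels, size=n, p=probs)

    column = {v: i for i, v in enumerate(variables)}
    for attr in sorted(config.habitat_effects):
        if attr not in habitat_draws:
            raise ConfigurationError(
                f"habitat_effects refers to {attr!r} which has no "
                "habitat_probs entry"
            )
        level_factors = config.habitat_effects[attr]
        affected = sorted({e for f in level_factors.values() for e in f})
        for element in affected:
            if element not in column:
                raise ConfigurationError(
                    f"habitat effect on unknown variable {element!r}"
                )
            factor_by_level = {
                lv: level_factors.get(lv, {}).get(element, 1.0)
                for lv in config.habitat_probs[attr]
            }
            expected = sum(
                config.habitat_probs[attr][lv] * f
                for lv, f in factor_by_level.items()
            ) / sum(config.habitat_probs[attr].values())
            per_sample = np.array(
                [factor_by_level[lv] for lv in habitat_draws[attr]]
            )
            values[:, column[element]] *= per_sample / expected

    counties = _allocate_counties(config.county_weights or {"Study": 1}, n)
    bboxes = config.county_bboxes or {"Study": (-1.0, 1.0, -1.0, 1.0)}
    lon = np.empty(n)
    lat = np.empty(n)
    for i, county in enumerate(counties):
        lon_min, lon_max, lat_min, lat_max = bboxes.get(
            county, (-1.0, 1.0, -1.0, 1.0)
        )
        lon[i] = rng.uniform(lon_min, lon_max)
        lat[i] = rng.uniform(lat_min, lat_max)

    elements = config.elements
    samples = []
    for i in range(n):
        concentrations = {e: float(values[i, column[e]]) for e in elements}
        habitat = HabitatAttributes(
            **{attr: str(habitat_draws[attr][i]) for attr in habitat_draws}
        )
        samples.append(
            DustSample(
                sample_id=f"S{i + 1}",
                county=counties[i],
                lon=float(lon[i]),
                lat=float(lat[i]),
                concentrations=concentrations,
                total_bacteria=float(values[i, column["TB"]])
                if "TB" in column else 0.0,
                enteric_bacteria=float(values[i, column["EB"]])
                if "EB" in column else 0.0,
                habitat=habitat,
            )
        )
    return StudyTable(
        samples,
        elements=elements,
        provenance={
            "generator": "dustrisk.synthetic.simulate_study",
            "seed": config.seed,
            "correlation_adjustment": adjustment,
            "units": {"concentrations": "mg/kg", "bacteria": "cfu/g"},
        },
    )


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """A copy of ``config`` with a different seed (convenience)."""
    return replace(config, seed=seed)
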