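"""Enrichment factors of dust-borne elements relative to background soil.

The enrichment factor is the double ratio

    EF = (C_i / C_ref) / (B_i / B_ref)

where ``C_i`` and ``C_ref`` are the element of interest and a conservative
reference element (Al here) in the dust sample, and ``B_i``, ``B_ref`` the
corresponding regional soil background values.  EF near 1 means crustal
composition; large EF flags anthropogenic input.  Five conventional tiers:
<2 minimal, 2-5 moderate, 5-20 significant, 20-40 very high, >40 extreme.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .io_model import ConfigurationError, ReferencePanel, StudyTable


class EnrichmentCategory(str, Enum):
    MINIMAL = "minimal"
    MODERATE = "moderate"
    SIGNIFICANT = "significant"
    VERY_HIGH = "very_high"
    EXTREMELY_HIGH = "extremely_high"


@dataclass(frozen=True)
class EnrichmentResult:
    scope: str  # sample_id or group label
    element: str
    ef_value: float
    category: EnrichmentCategory


@dataclass(frozen=True)
class BoxplotSummary:
    """Tukey five-number summary of per-sample EF values for one element."""

    element: str
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[tuple[str, float], ...]  # (sample_id, ef)


def enrichment_factor(c_i, c_ref, bg_i, bg_ref):
    """EF = (c_i/c_ref)/(bg_i/bg_ref); accepts scalars or numpy arrays.

    All four inputs must be strictly positive: a zero background makes the
    ratio undefined and a zero concentration indicates a non-detect that
    must be handled upstream, not silently mapped to EF 0.
    """
    quantities = {"c_i": c_i, "c_ref": c_ref, "bg_i": bg_i, "bg_ref": bg_ref}
    for name, value in quantities.items():
        if np.any(np.asarray(value) <= 0):
            raise ValueError(
                f"enrichment factor requires {name} > 0 (got {value!r})"
            )
    return (c_i / c_ref) / (bg_i / bg_ref)


_CATEGORY_BOUNDS = (
    (2.0, EnrichmentCategory.MINIMAL),
    (5.0, EnrichmentCategory.MODERATE),
    (20.0, EnrichmentCategory.SIGNIFICANT),
)


def categorize_ef(ef: float) -> EnrichmentCategory:
    """Map a positive EF to its tier.

    Tiers are half-open below (2 counts as moderate, 5 as significant,
    20 as very high); 40 itself is very_high since only values strictly
    greater than 40 are conventionally called extreme.
    """
    if not np.isfinite(ef) or ef <= 0:
        raise ValueError(f"EF must be a positive finite number, got {ef!r}")
    for bound, category in _CATEGORY_BOUNDS:
        if ef < bound:
            return category
    if ef <= 40.0:
        return EnrichmentCategory.VERY_HIGH
    return EnrichmentCategory.EXTREMELY_HIGH


def ef_table(
    study: StudyTable,
    panel: ReferencePanel,
    elements: Sequence[str] | None = None,
    group_by: str | None = None,
) -> list[EnrichmentResult]:
    """Per-sample (or per-group) enrichment factors for the chosen elements.

    With ``group_by`` set, EF is computed on group *mean* concentrations
    (ratio of means, not mean of per-sample ratios); per-sample EFs are the
    ones that feed boxplot summaries.
    """
    ref = panel.reference_element
    if elements is None:
        elements = [
            e for e in study.elements if e != ref and panel.ef_eligible(e)
        ]
    for element in elements:
        panel.require_background(element)  # raises for EF-ineligible (e.g. Cd)
    bg_ref = panel.background_reference

    results: list[EnrichmentResult] = []
    if group_by is None:
        for sample in study:
            if ref not in sample.concentrations:
                raise ConfigurationError(
                    f"reference element {ref!r} not measured in sample "
                    f"{sample.sample_id!r}"
                )
            c_ref = sample.concentrations[ref]
            for element in elements:
                ef = enrichment_factor(
                    sample.concentrations[element], c_ref,
                    panel.background[element], bg_ref,
                )
                results.append(
                    EnrichmentResult(
                        sample.sample_id, element, float(ef), categorize_ef(ef)
                    )
                )
        return results

    levels = study.group_levels(group_by)
    frame = study.concentration_frame()
    for level in sorted(levels):
        means = frame.loc[levels[level]].mean(axis=0)
        for element in elements:
            ef = enrichment_factor(
                means[element], means[ref], panel.background[element], bg_ref
            )
            results.append(
                EnrichmentResult(str(level), element, float(ef),
                                 categorize_ef(ef))
            )
    return results


def study_mean_ef(
    means, panel: ReferencePanel, elements: Sequence[str]
) -> dict[str, float]:
    """EF of study-wide mean concentrations (single summary number/element)."""
    ref = panel.reference_element
    return {
        element: float(
            enrichment_factor(
                means[element], means[ref],
                panel.require_background(element), panel.background_reference,
            )
        )
        for element in elements
    }


def boxplot_summary(
    efs: Iterable[tuple[str, float]] | dict[str, float], element: str
) -> BoxplotSummary:
    """Tukey boxplot statistics for one element's per-sample EF values.

    Quartiles use linear interpolation between order statistics; whiskers
    reach the most extreme values within 1.5 x IQR of the quartile box;
    anything beyond is an outlier (reported with its sample id).
    """
    pairs = list(efs.items()) if isinstance(efs, dict) else list(efs)
    if len(pairs) < 5:
        raise ValueError(
            f"boxplot summary needs >= 5 values, got {len(pairs)}"
        )
    values = np.array([v for _, v in pairs], dtype=float)
    q1, median, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    low_fence, high_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= low_fence) & (values <= high_fence)]
    whisker_low = float(inside.min())
    whisker_high = float(inside.max())
    outliers = tuple(
        (sid, float(v)) for sid, v in pairs if v < low_fence or v > high_fence
    )
    return BoxplotSummary(
        element=element,
        q1=float(q1),
        median=float(median),
        q3=float(q3),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        outliers=outliers,
    )
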