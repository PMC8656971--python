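"""Spatial screening: IDW interpolation, ESV exceedance, hotspot ranking.

Replaces interactive GIS mapping with a deterministic engine: inverse
distance weighted (IDW) surfaces of any per-sample quantity on a regular
lon/lat grid, counts of samples exceeding an ecological screening value
(strict '>'), and top-k hotspot listings with a pinned tie-break.  The
study extent is a metropolitan region, so planar (equirectangular degree)
distances are used throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_model import ConfigurationError, ReferencePanel, StudyTable

#: A grid node closer than this (degrees) to a sample is an exact hit.
EXACT_HIT_EPS = 1e-9


@dataclass
class SurfaceGrid:
    """An interpolated surface on a regular grid.

    ``values[iy, ix]`` is the quantity at ``(lons[ix], lats[iy])``.  By IDW
    construction every node lies within [min, max] of the input values.
    """

    bbox: tuple[float, float, float, float]  # lon_min, lon_max, lat_min, lat_max
    nx: int
    ny: int
    lons: np.ndarray
    lats: np.ndarray
    values: np.ndarray
    quantity: str
    units: str


@dataclass(frozen=True)
class ExceedanceReport:
    element: str
    threshold: float
    n_exceeding: int
    n_total: int
    exceeding: tuple[tuple[str, float], ...]  # (sample_id, value), ranked desc


def idw_surface(
    lon: Sequence[float],
    lat: Sequence[float],
    values: Sequence[float],
    bbox: tuple[float, float, float, float] | None = None,
    nx: int = 100,
    ny: int = 100,
    power: float = 2.0,
    quantity: str = "value",
    units: str = "",
) -> SurfaceGrid:
    """All-points IDW: node value = sum(w_i v_i)/sum(w_i), w_i = d_i^-power.

    A node within :data:`EXACT_HIT_EPS` of a sample takes that sample's
    value exactly (interpolation honours the data).  ``bbox`` defaults to
    the data extent.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    values = np.asarray(values, dtype=float)
    if lon.size == 0:
        raise ValueError("idw_surface: empty sample set")
    if not (lon.size == lat.size == values.size):
        raise ValueError("idw_surface: lon, lat, values must be equal length")
    if power <= 0:
        raise ValueError(f"idw_surface: power must be > 0, got {power}")
    # collapse exact duplicates (same location, same value) so re-submitting
    # a sample cannot drag the surface toward it
    _, keep = np.unique(
        np.column_stack([lon, lat, values]), axis=0, return_index=True
    )
    keep.sort()
    lon, lat, values = lon[keep], lat[keep], values[keep]
    if bbox is None:
        bbox = (lon.min(), lon.max(), lat.min(), lat.max())
    lon_min, lon_max, lat_min, lat_max = bbox
    lons = np.linspace(lon_min, lon_max, nx)
    lats = np.linspace(lat_min, lat_max, ny)
    grid_lon, grid_lat = np.meshgrid(lons, lats)

    d = np.hypot(
        grid_lon[..., None] - lon[None, None, :],
        grid_lat[..., None] - lat[None, None, :],
    )
    hits = d < EXACT_HIT_EPS
    d_safe = np.where(hits, 1.0, d)
    w = d_safe ** (-power)
    surface = (w * values).sum(axis=-1) / w.sum(axis=-1)
    if hits.any():
        iy, ix, isample = np.nonzero(hits)
        # first matching sample wins on coincident duplicates
        first = {}
        for a, b, c in zip(iy, ix, isample):
            first.setdefault((a, b), c)
        for (a, b), c in first.items():
            surface[a, b] = values[c]
    return SurfaceGrid(
        bbox=bbox, nx=nx, ny=ny, lons=lons, lats=lats, values=surface,
        quantity=quantity, units=units,
    )


def study_surface(
    study: StudyTable,
    quantity: str,
    bbox: tuple[float, float, float, float] | None = None,
    nx: int = 100,
    ny: int = 100,
    power: float = 2.0,
) -> SurfaceGrid:
    """IDW surface of an element (mg/kg) or bacterial load over the study."""
    values = _sample_values(study, quantity)
    units = "cfu/g" if quantity in ("total_bacteria", "enteric_bacteria") else "mg/kg"
    return idw_surface(
        [s.lon for s in study], [s.lat for s in study], values,
        bbox=bbox, nx=nx, ny=ny, power=power, quantity=quantity, units=units,
    )


def _sample_values(study: StudyTable, quantity: str) -> list[float]:
    if quantity == "total_bacteria":
        return [s.total_bacteria for s in study]
    if quantity == "enteric_bacteria":
        return [s.enteric_bacteria for s in study]
    if quantity in study.elements:
        return [s.concentrations[quantity] for s in study]
    raise KeyError(
        f"unknown quantity {quantity!r}; expected an element of "
        f"{study.elements} or total_bacteria/enteric_bacteria"
    )


def exceedance(
    study: StudyTable,
    element: str,
    threshold: float | None = None,
    panel: ReferencePanel | None = None,
) -> ExceedanceReport:
    """Samples whose concentration is strictly above the screening value.

    ``threshold`` defaults to the panel's ecological screening value for
    the element; exceeding samples are ranked by concentration, descending
    (ties keep input order).
    """
    if threshold is None:
        if panel is None:
            raise ConfigurationError(
                f"no threshold given and no reference panel to look up an "
                f"ESV for {element!r}"
            )
        threshold = panel.require_esv(element)
    pairs = [(s.sample_id, s.concentrations[element]) for s in study]
    over = [(sid, v) for sid, v in pairs if v > threshold]
    over.sort(key=lambda item: -item[1])
    return ExceedanceReport(
        element=element,
        threshold=float(threshold),
        n_exceeding=len(over),
        n_total=len(pairs),
        exceeding=tuple(over),
    )


def hotspots(
    study: StudyTable, quantity: str, k: int
) -> list[tuple[str, float]]:
    """Top-k samples by a quantity, descending; ties keep sample order.

    ``k > n`` returns the full ranking (with no error: a screening listing
    longer than the survey is just the survey).
    """
    if k < 1:
        raise ValueError(f"hotspots: k must be >= 1, got {k}")
    values = _sample_values(study, quantity)
    pairs = list(zip(study.sample_ids, values))
    order = sorted(range(len(pairs)), key=lambda i: (-pairs[i][1], i))
    return [pairs[i] for i in order[: min(k, len(pairs))]]


def samples_to_geojson(
    study: StudyTable, path: str | Path | None = None
) -> dict:
    """Survey points as a GeoJSON FeatureCollection (optionally written)."""
    features = []
    for s in study:
        properties: dict[str, object] = {
            "sample_id": s.sample_id,
            "county": s.county,
            "tb_cfu_g": s.total_bacteria,
            "eb_cfu_g": s.enteric_bacteria,
        }
        properties.update({e: s.concentrations[e] for e in study.elements})
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [s.lon, s.lat]},
                "properties": properties,
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(collection, indent=1) + "\n")
    return collection


def surface_to_ascii_grid(grid: SurfaceGrid, path: str | Path) -> None:
    """Write a surface as an ESRI-style ASCII grid (portable plain text)."""
    lon_min, lon_max, lat_min, lat_max = grid.bbox
    cell = (lon_max - lon_min) / max(grid.nx - 1, 1)
    lines = [
        f"ncols {grid.nx}",
        f"nrows {grid.ny}",
        f"xllcorner {lon_min}",
        f"yllcorner {lat_min}",
        f"cellsize {cell:.10g}",
        "NODATA_value -9999",
    ]
    for row in grid.values[::-1]:  # north-up
        lines.append(" ".join(f"{v:.6g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")
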