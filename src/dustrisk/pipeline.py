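"""End-to-end orchestration: load/simulate -> EF -> risk -> stats -> spatial.

``run_pipeline`` is a pure function of (inputs, config, seed): the same
configuration and seed produce a byte-identical report bundle.  Each stage
writes its table in a layout that mirrors the conventional publication
tables (group means with significance letters, per-element EF boxplot
statistics, county risk tables with route LCR rows, an annotated
correlation matrix), plus exceedance/hotspot reports, GeoJSON points and
ASCII surface grids, and a run manifest recording the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .enrichment import boxplot_summary, ef_table
from .health_risk import (
    PRIORITY_METALS,
    load_exposure_parameters,
    load_toxicity_table,
    risk_table,
)
from .io_model import (
    ReferencePanel,
    StudyTable,
    load_reference_panel,
    read_samples,
    write_report,
    write_samples,
)
from .spatial import (
    exceedance,
    hotspots,
    samples_to_geojson,
    study_surface,
    surface_to_ascii_grid,
)
from .stats import correlation_matrix, group_summary_table
from .synthetic import SimulationConfig, default_config, simulate_study


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs.

    Exactly one of ``input_path`` (a sample CSV) or ``simulation``
    (a :class:`SimulationConfig`) provides the survey; ``seed`` overrides
    the simulation seed so one integer governs all randomness.
    """

    out_dir: str | Path = "dustrisk_out"
    input_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    reference_panel_path: str | Path | None = None
    toxicity_path: str | Path | None = None
    exposure_path: str | Path | None = None
    ef_elements: Sequence[str] | None = None
    risk_elements: Sequence[str] = PRIORITY_METALS
    groupings: Sequence[str] = (
        "home_type", "home_age_class", "floor_type", "pets", "heating",
    )
    surface_quantities: Sequence[str] = ("Pb", "Zn")
    grid_shape: tuple[int, int] = (50, 50)
    idw_power: float = 2.0
    at_mode: str = "as_stated"
    seed: int = 0

    def config_hash(self) -> str:
        # out_dir does not influence bundle content, so two runs of the
        # same analysis into different directories hash identically
        payload = {
            k: str(v) for k, v in sorted(self.__dict__.items())
            if k != "out_dir"
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_study(config: PipelineConfig) -> StudyTable:
    if config.input_path is not None:
        return read_samples(config.input_path)
    simulation = config.simulation or default_config()
    simulation.seed = config.seed
    return simulate_study(simulation)


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns the in-memory results keyed by stage.  Any stage failure
    removes the partially written bundle and raises :class:`PipelineError`
    naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}
    stage = "setup"
    try:
        stage = "load"
        study = _load_study(config)
        results["study"] = study
        write_samples(study, out / "samples.csv")

        stage = "reference"
        panel = load_reference_panel(config.reference_panel_path)
        tox = load_toxicity_table(config.toxicity_path)
        exposure = load_exposure_parameters(config.exposure_path)

        stage = "group_means"
        group_tables = {}
        for attribute in config.groupings:
            try:
                table = group_summary_table(study, attribute, study.elements)
            except ValueError:
                continue
            if not table.empty:
                group_tables[attribute] = table
                table.to_csv(out / f"group_means_{attribute}.csv")
        results["group_means"] = group_tables

        stage = "enrichment"
        ef_elements = config.ef_elements or [
            e
            for e in ("As", "Cr", "Cu", "Fe", "Mn", "Ni", "Pb", "Zn")
            if e in study.elements and panel.ef_eligible(e)
        ]
        efs = ef_table(study, panel, ef_elements)
        ef_frame = pd.DataFrame(
            [
                {
                    "scope": r.scope,
                    "element": r.element,
                    "ef": r.ef_value,
                    "category": r.category.value,
                }
                for r in efs
            ]
        )
        write_report(ef_frame, out / "enrichment.csv")
        box_rows = []
        for element in ef_elements:
            per_sample = [
                (r.scope, r.ef_value) for r in efs if r.element == element
            ]
            if len(per_sample) >= 5:
                box = boxplot_summary(per_sample, element)
                box_rows.append(
                    {
                        "element": element,
                        "q1": box.q1,
                        "median": box.median,
                        "q3": box.q3,
                        "whisker_low": box.whisker_low,
                        "whisker_high": box.whisker_high,
                        "n_outliers": len(box.outliers),
                        "outliers": ";".join(sid for sid, _ in box.outliers),
                    }
                )
        if box_rows:
            write_report(pd.DataFrame(box_rows), out / "ef_boxplots.csv")
        results["enrichment"] = ef_frame

        stage = "risk"
        risk_elements = [
            e for e in config.risk_elements if e in study.elements and e in tox
        ]
        skipped = [e for e in config.risk_elements if e not in risk_elements]
        risks = risk_table(
            study,
            elements=risk_elements,
            p=exposure,
            tox=tox,
            scope="county",
            at_mode=config.at_mode,
        )
        write_report(risks, out / "risk_county.csv")
        results["risk"] = risks
        results["risk_skipped_elements"] = skipped

        stage = "correlation"
        corr = correlation_matrix(study)
        corr.annotated().to_csv(out / "correlation_matrix.csv")
        results["correlation"] = corr

        stage = "spatial"
        exceedance_rows = []
        for element in sorted(panel.esv):
            if element not in study.elements:
                continue
            report = exceedance(study, element, panel=panel)
            exceedance_rows.append(
                {
                    "element": element,
                    "esv_mg_kg": report.threshold,
                    "n_exceeding": report.n_exceeding,
                    "n_total": report.n_total,
                    "exceeding_ranked": ";".join(
                        sid for sid, _ in report.exceeding
                    ),
                }
            )
        write_report(pd.DataFrame(exceedance_rows), out / "exceedance.csv")
        hotspot_rows = []
        for quantity in (*study.elements, "total_bacteria", "enteric_bacteria"):
            for rank, (sid, value) in enumerate(
                hotspots(study, quantity, k=5), start=1
            ):
                hotspot_rows.append(
                    {"quantity": quantity, "rank": rank, "sample_id": sid,
                     "value": value}
                )
        write_report(pd.DataFrame(hotspot_rows), out / "hotspots.csv")
        samples_to_geojson(study, out / "samples.geojson")
        nx, ny = config.grid_shape
        for quantity in config.surface_quantities:
            grid = study_surface(
                study, quantity, nx=nx, ny=ny, power=config.idw_power
            )
            surface_to_ascii_grid(grid, out / f"surface_{quantity}.asc")
        results["exceedance"] = pd.DataFrame(exceedance_rows)
        results["hotspots"] = pd.DataFrame(hotspot_rows)

        stage = "manifest"
        manifest = {
            "package": "dustrisk",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_samples": len(study),
            "at_mode": config.at_mode,
            "risk_skipped_elements": skipped,
            "stages": [
                "load", "reference", "group_means", "enrichment", "risk",
                "correlation", "spatial",
            ],
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )
        results["manifest"] = manifest
    except Exception as exc:
        shutil.rmtree(out, ignore_errors=True)
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results
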