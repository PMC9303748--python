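"""End-to-end orchestration: simulate -> quantify -> indices -> stats.

Each stage writes its artifacts under the run directory; the whole run is a
pure function of the configuration and master seed, so a rerun with the
same config produces byte-identical tables.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any

import pandas as pd

from .config import OUTCOME_SPECS, RunConfig
from .errors import MyocultureError
from .indices import build_analysis_table
from .io import find_field_files, read_stack
from .markers import quantify_field
from .stats import RegressionFit, fit_outcome_model
from .synthetic import (
    SceneParams,
    StudyDesign,
    calibrate_fusion,
    calibrate_marker_probs,
    generate_study,
)

log = logging.getLogger(__name__)

_DENOMINATOR_CHANNEL = {"pax7-myod": "green", "myog-myod": "red"}


def _stage(name: str):
    """Tag stage failures so an aborted run names the failing stage."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except MyocultureError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc

        return inner

    return wrap


def scene_overrides_for(config: RunConfig, mode: str, coating: str, day: int) -> dict[str, Any]:
    """Translate a mode's calibration entry into SceneParams overrides."""
    cal = config.modes.get(mode, {}).get(coating, {}).get(day, {})
    overrides: dict[str, Any] = {}
    if mode in _DENOMINATOR_CHANNEL:
        if cal:
            overrides.update(
                calibrate_marker_probs(
                    cal.get("index_pct", 0.0),
                    p_denominator=cal.get("p_denominator", 0.55),
                    denominator=_DENOMINATOR_CHANNEL[mode],
                )
            )
    elif mode == "myhc":
        base = {**config.scene, **config.mode_scene.get(mode, {})}
        n_nuclei = int(base.get("n_nuclei", SceneParams.n_nuclei))
        if cal:
            overrides.update(
                calibrate_fusion(
                    cal.get("fusion_pct", 0.0),
                    n_nuclei=n_nuclei,
                    nuclei_per_myotube=cal.get("nuclei_per_myotube", 3),
                )
            )
        overrides.setdefault("n_myotubes", 0)
        overrides["render_myhc"] = True
    return overrides


@_stage("simulate")
def simulate_stage(config: RunConfig, mode: str) -> Path:
    """Generate the synthetic study for one quantification mode."""
    out = Path(config.out_dir) / "sim" / mode
    scene = {**config.scene, **config.mode_scene.get(mode, {})}
    if "shape" in scene:
        scene["shape"] = tuple(scene["shape"])
    if "myotube_length_px" in scene:
        scene["myotube_length_px"] = tuple(scene["myotube_length_px"])
    base = SceneParams(**scene)
    design = StudyDesign(
        coatings=tuple(config.coatings),
        days=tuple(config.days),
        wells_per_condition=config.wells,
        fields_per_well=config.fields,
    )
    condition_overrides = {
        (coating, day): scene_overrides_for(config, mode, coating, day)
        for coating in config.coatings
        for day in config.days
    }
    generate_study(
        design,
        base,
        out,
        seed=config.seed,
        condition_overrides=condition_overrides,
        overwrite=config.overwrite,
    )
    log.info("simulated %d fields for mode %s under %s", design.n_fields, mode, out)
    return out

@_stage("quantify")
def quantify_stage(config: RunConfig, mode: str, image_dir: Path) -> pd.DataFrame:
    """Quantify every field of one simulated study."""
    quants = []
    for prov, paths in sorted(
        find_field_files(image_dir).items(),
        key=lambda kv: (kv[0].coating, kv[0].day, kv[0].well, kv[0].field),
    ):
        stack = read_stack(paths)
        stack.provenance = prov
        quants.append(
            quantify_field(
                stack,
                mode=mode,
                rule=config.marker_rule,
                min_area=config.min_area,
                max_area=config.max_area,
                exclude_border=config.exclude_border,
                min_myotube_area=config.min_myotube_area,
                min_contrast=config.min_contrast,
            )
        )
    rows = [
        {
            "coating": q.provenance.coating,
            "day": q.provenance.day,
            "well": q.provenance.well,
            "field": q.provenance.field,
            "n_nuclei": q.n_nuclei,
            "n_green": q.n_green,
            "n_red": q.n_red,
            "n_double": q.n_double,
            "n_myotubes": q.n_myotubes,
            "n_nuclei_in_myotubes": q.n_nuclei_in_myotubes,
        }
        for q in quants
    ]
    table = pd.DataFrame(rows)
    table.attrs["quantifications"] = quants
    return table


@_stage("indices")
def indices_stage(config: RunConfig, mode: str, field_table: pd.DataFrame) -> pd.DataFrame:
    quants = field_table.attrs["quantifications"]
    return build_analysis_table(quants, mode=mode, pooling=config.pooling)


@_stage("stats")
def stats_stage(config: RunConfig, tables: dict[str, pd.DataFrame]) -> dict[str, RegressionFit]:
    fits = {}
    for outcome, spec in OUTCOME_SPECS.items():
        mode = spec["mode"]
        if mode not in tables:
            continue
        fits[outcome] = fit_outcome_model(
            tables[mode],
            outcome,
            exclude_day1=spec["exclude_day1"],
            reference=config.reference,
        )
    return fits


def write_report(
    config: RunConfig,
    well_tables: dict[str, pd.DataFrame],
    fits: dict[str, RegressionFit],
    out_dir: Path,
) -> Path:
    """Summary report: per-condition means +/- SD and significant contrasts."""
    lines = ["# Study report", ""]
    for mode, table in well_tables.items():
        lines += [f"## Mode {mode}: per-condition summaries (mean ± SD over wells)", ""]
        outcomes = [o for o, s in OUTCOME_SPECS.items() if s["mode"] == mode]
        summary = (
            table.groupby(["coating", "day"])[outcomes].agg(["mean", "std"]).reset_index()
        )
        lines.append(summary.to_string(index=False))
        lines.append("")
    lines += ["## Coating-vs-reference contrasts", ""]
    for outcome, fit in fits.items():
        sig = fit.contrasts[fit.contrasts["significant"]]
        lines.append(
            f"### {outcome} (interaction {'included' if fit.interaction_included else 'omitted'},"
            f" days excluded: {fit.excluded_days or 'none'})"
        )
        if sig.empty:
            lines.append("no significant differences vs reference at alpha = 0.05")
        else:
            for _, row in sig.iterrows():
                lines.append(
                    f"- day {row.day}: {row.coating} vs {fit.reference}: "
                    f"{row.estimate:+.2f} (p = {row.p_value:.4g}) *"
                )
        lines.append("")
    path = out_dir / "report.md"
    path.write_text("\n".join(lines))
    return path


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns paths and in-memory results."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables_dir = out_dir / "tables"
    tables_dir.mkdir(exist_ok=True)

    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("myoculture")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    log.info("run config: %s", config)

    try:
        well_tables: dict[str, pd.DataFrame] = {}
        for mode in config.modes:
            image_dir = simulate_stage(config, mode)
            field_table = quantify_stage(config, mode, image_dir)
            field_table.to_csv(tables_dir / f"{mode}_fields.csv", index=False)
            well_table = indices_stage(config, mode, field_table)
            well_table.to_csv(tables_dir / f"{mode}_wells.csv", index=False)
            well_tables[mode] = well_table

        fits = stats_stage(config, well_tables)
        for outcome, fit in fits.items():
            fit.contrasts.to_csv(tables_dir / f"{outcome}_contrasts.csv", index=False)
        report = write_report(config, well_tables, fits, out_dir)
    finally:
        root.removeHandler(handler)
        handler.close()

    return {
        "out_dir": out_dir,
        "report": report,
        "well_tables": well_tables,
        "fits": fits,
    }
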