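"""End-to-end orchestration: ingest or simulate, summarize, dose, outcomes.

Given a :class:`~ritpipe.config.RunConfig`, these functions produce the
tabular artifacts of a full analysis run in an output directory.  Outputs
are a pure function of (config, seed): no timestamps or environment state
enter the files, so identical runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from ritpipe import __version__
from ritpipe.biodist import (
    normalize_records,
    read_biodistribution,
    summarize_curves,
    write_biodistribution,
    write_curves,
)
from ritpipe.config import RunConfig, config_digest
from ritpipe.dosimetry import (
    dose_table,
    per_animal_dose_table,
    surrogate_substitution_check,
    write_dose_table,
)
from ritpipe.errors import ValidationError
from ritpipe.nuclides import registry_from_config
from ritpipe.synthetic import simulate_biodistribution, simulate_therapy
from ritpipe.therapy import (
    body_weight_change,
    endpoint_time,
    group_series,
    normalized_volume,
    read_tumor_measurements,
    survival_curve,
    survival_curve_frame,
    write_survival_records,
    write_tumor_measurements,
)

logger = logging.getLogger("ritpipe")


def write_manifest(config: RunConfig, out_dir: Path, artifacts: list[str]) -> Path:
    manifest = {
        "config_sha256": config_digest(config),
        "seed": config.seed,
        "package_version": __version__,
        "settings": {
            "tail_mode": config.tail_mode,
            "t0_mode": config.t0_mode,
            "method": config.method,
            "per_animal": config.per_animal,
            "normalize_bw": config.normalize_bw,
            "reference_bw_g": config.reference_bw_g,
            "report_rounding_gy": config.report_rounding_gy,
            "endpoint_diameter_mm": config.endpoint_diameter_mm,
            "observation_end_d": config.observation_end_d,
            "diameter_mode": config.diameter_mode,
        },
        "artifacts": sorted(artifacts),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def run_biodist_to_dose(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Biodistribution (measured or simulated) -> curves -> dose table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = registry_from_config(config.nuclide_overrides)
    imaging = registry[config.imaging_nuclide]
    therapy = registry[config.therapy_nuclide]

    if config.biodist_input is not None:
        records = read_biodistribution(config.biodist_input)
        logger.info("read %d biodistribution records from %s", len(records), config.biodist_input)
    else:
        records = simulate_biodistribution(config.resolved_synthetic())
        logger.info("simulated %d biodistribution records", len(records))
    paths: dict[str, Path] = {}
    paths["biodist"] = out / "biodist.csv"
    write_biodistribution(records, paths["biodist"])

    if config.normalize_bw:
        records = normalize_records(records, config.reference_bw_g)
        logger.info("normalized %%ID/g to a %.1f g reference body weight", config.reference_bw_g)
    curves = summarize_curves(records)
    paths["curves"] = out / "curves.csv"
    write_curves(curves, paths["curves"])

    report = surrogate_substitution_check(imaging, therapy)
    logger.info(
        "surrogate substitution %s -> %s: half-life ratio %.4f, "
        "max decay-weight discrepancy %.3f%s",
        imaging.name,
        therapy.name,
        report.half_life_ratio,
        report.max_decay_weight_discrepancy,
        " [WARNING: ratio exceeds threshold]" if report.warn else "",
    )
    logger.info(
        "dosimetry settings: tail_mode=%s t0_mode=%s method=%s per_animal=%s",
        config.tail_mode,
        config.t0_mode,
        config.method,
        config.per_animal,
    )
    if config.per_animal:
        estimates = per_animal_dose_table(
            records,
            config.activities_bq,
            therapy,
            tail_mode=config.tail_mode,
            t0_mode=config.t0_mode,
            method=config.method,
        )
    else:
        estimates = dose_table(
            curves,
            config.activities_bq,
            therapy,
            tail_mode=config.tail_mode,
            t0_mode=config.t0_mode,
            method=config.method,
        )
    paths["doses_long"] = out / "doses_long.csv"
    paths["doses_wide"] = out / "doses_wide.csv"
    write_dose_table(
        estimates,
        paths["doses_long"],
        paths["doses_wide"],
        rounding_gy=config.report_rounding_gy,
    )
    paths["manifest"] = write_manifest(config, out, [p.name for p in paths.values()])
    return paths


def _tumor_doses_per_arm(doses_long: Path) -> list[tuple[str, float, float]]:
    frame = pd.read_csv(doses_long)
    tumor = frame[frame["organ"] == "tumor"]
    return [
        (str(r.group), float(r.activity_bq), float(r.dose_gy))
        for r in tumor.itertuples(index=False)
    ]


def run_therapy_analysis(
    config: RunConfig,
    out_dir: str | Path,
    simulated_arms: list[tuple[str, float, float]] | None = None,
) -> dict[str, Path]:
    """Caliper series (measured or simulated) -> volumes, survival, weights.

    ``simulated_arms`` is a list of (group, activity_bq, tumor_dose_gy)
    driving the simulator when no caliper input is configured.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if config.caliper_input is not None:
        measurements = read_tumor_measurements(config.caliper_input)
    else:
        sim = config.resolved_therapy_sim()
        arms = simulated_arms if simulated_arms is not None else [("untreated", 0.0, 0.0)]
        measurements = []
        for group, activity_bq, dose_gy in arms:
            label = f"{group}-{activity_bq / 1e6:g}MBq" if activity_bq else group
            for series in simulate_therapy(sim, dose_gy, n=5, group=label):
                measurements.extend(series)
        logger.info("simulated %d caliper measurements across %d arms", len(measurements), len(arms))
    paths["calipers"] = out / "calipers.csv"
    write_tumor_measurements(measurements, paths["calipers"])

    series_by_animal = group_series(measurements)

    volume_rows = [
        (m.group, m.animal_id, m.day, m.length_mm, m.width_mm, m.volume_mm3)
        for series in series_by_animal.values()
        for m in series
    ]
    paths["volumes"] = out / "volumes.csv"
    pd.DataFrame(
        volume_rows,
        columns=("group", "animal_id", "day", "length_mm", "width_mm", "volume_mm3"),
    ).to_csv(paths["volumes"], index=False)

    norm_rows = []
    for (group, animal), series in series_by_animal.items():
        try:
            ratio = normalized_volume(series, config.normalized_volume_day)
            norm_rows.append((group, animal, config.normalized_volume_day, ratio))
        except ValidationError as exc:
            logger.warning("animal %s excluded from normalized volumes: %s", animal, exc)
    paths["normalized_volumes"] = out / "normalized_volumes.csv"
    pd.DataFrame(
        norm_rows, columns=("group", "animal_id", "day", "normalized_volume")
    ).to_csv(paths["normalized_volumes"], index=False)

    survival_records = [
        endpoint_time(
            series,
            endpoint_diameter_mm=config.endpoint_diameter_mm,
            observation_end_d=config.observation_end_d,
            diameter_mode=config.diameter_mode,
        )
        for series in series_by_animal.values()
    ]
    paths["survival_records"] = out / "survival_records.csv"
    write_survival_records(survival_records, paths["survival_records"])

    curve_frames = []
    by_group: dict[str, list] = {}
    for rec in survival_records:
        by_group.setdefault(rec.group, []).append(rec)
    for group, recs in sorted(by_group.items()):
        frame = survival_curve_frame(survival_curve(recs))
        frame.insert(0, "group", group)
        curve_frames.append(frame)
    paths["survival_curves"] = out / "survival_curves.csv"
    pd.concat(curve_frames, ignore_index=True).to_csv(paths["survival_curves"], index=False)

    if config.weights_input is not None:
        weights = pd.read_csv(config.weights_input)
        rows = []
        for (group, animal), sub in weights.groupby(["group", "animal_id"], sort=True):
            series = list(zip(sub["day"].astype(float), sub["weight_g"].astype(float)))
            try:
                for day, change in body_weight_change(series):
                    rows.append((group, animal, day, change))
            except ValidationError as exc:
                logger.warning("animal %s excluded from weight changes: %s", animal, exc)
        paths["weight_changes"] = out / "weight_changes.csv"
        pd.DataFrame(
            rows, columns=("group", "animal_id", "day", "relative_change")
        ).to_csv(paths["weight_changes"], index=False)

    paths["manifest"] = write_manifest(config, out, [p.name for p in paths.values()])
    return paths


def run_full(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Biodistribution -> dose table, then therapy arms driven by tumor doses."""
    out = Path(out_dir)
    dose_paths = run_biodist_to_dose(config, out / "dosimetry")
    arms = [("untreated", 0.0, 0.0)]
    arms += _tumor_doses_per_arm(dose_paths["doses_long"])
    therapy_paths = run_therapy_analysis(config, out / "therapy", simulated_arms=arms)
    return {**{f"dose_{k}": v for k, v in dose_paths.items()},
            **{f"therapy_{k}": v for k, v in therapy_paths.items()}}
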