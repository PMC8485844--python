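"""Run configuration and the end-to-end analysis pipeline.

Ties the stages together: visits -> observation intervals -> anchor
validity -> monotone GAMM -> ED table -> rule evaluation -> group summaries
and SMD comparator, writing one artifact per stage.  Display tables are
fixed at 2 d.p.; a parallel ``results.json`` keeps full precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from ed50mcid.data_model import (
    GAD7,
    GRC_3_LEVEL,
    GRC_5_LEVEL,
    PHQ9,
    GrcMapping,
    ScaleSpec,
    anchor_validity,
    compute_changes,
    records_to_frame,
)
from ed50mcid.ed_extraction import build_ed_table
from ed50mcid.evaluation import compute_metrics, metrics_frame
from ed50mcid.monotone_gamm import SmoothSpec, fit_gamm
from ed50mcid.smd_comparator import (
    crude_and_smd,
    group_summaries,
    smd_frame,
    summaries_frame,
)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("ed50mcid")

_SCALES = {"PHQ9": PHQ9, "GAD7": GAD7}
_MAPPING_PRESETS = {"5-level": GRC_5_LEVEL, "3-level": GRC_3_LEVEL}


@dataclass
class RunConfig:
    """Everything a pipeline run needs beyond the input table."""

    scale: ScaleSpec = PHQ9
    grc_mappings: Mapping[str, GrcMapping] = dc_field(default_factory=dict)
    smooth: SmoothSpec = dc_field(default_factory=SmoothSpec)
    ed_probabilities: tuple[float, ...] = (0.25, 0.5, 0.75)
    average_mode: str = "per_observation"
    clinical_display: bool = False

    def __post_init__(self) -> None:
        probs = tuple(sorted(self.ed_probabilities))
        if probs != tuple(self.ed_probabilities):
            raise ValueError("ed_probabilities must be sorted ascending")
        if any(not 0 < p < 1 for p in probs):
            raise ValueError("ed_probabilities must be strictly inside (0, 1)")
        if 0.5 not in probs:
            raise ValueError("ed_probabilities must include 0.5 (the MCID itself)")


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration.

    Recognized keys: ``scale`` (PHQ9/GAD7), ``grc_mappings`` (study ->
    "5-level"/"3-level" preset or an explicit {label: {binary, ordinal}}
    mapping), ``smooth`` (SmoothSpec fields), ``ed_probabilities``,
    ``average_mode``, ``clinical_display``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    scale = _SCALES.get(str(raw.get("scale", "PHQ9")).upper())
    if scale is None:
        raise ValueError(f"unknown scale {raw.get('scale')!r}; choose PHQ9 or GAD7")
    mappings: dict[str, GrcMapping] = {}
    for study, m in (raw.get("grc_mappings") or {}).items():
        if isinstance(m, str):
            try:
                mappings[str(study)] = _MAPPING_PRESETS[m]
            except KeyError:
                raise ValueError(
                    f"unknown GRC mapping preset {m!r} (use '5-level' or '3-level')"
                ) from None
        else:
            mappings[str(study)] = GrcMapping(
                binary={lbl: spec["binary"] for lbl, spec in m.items()},
                ordinal={lbl: int(spec["ordinal"]) for lbl, spec in m.items()},
            )
    smooth = SmoothSpec(**(raw.get("smooth") or {}))
    return RunConfig(
        scale=scale,
        grc_mappings=mappings,
        smooth=smooth,
        ed_probabilities=tuple(raw.get("ed_probabilities", (0.25, 0.5, 0.75))),
        average_mode=str(raw.get("average_mode", "per_observation")),
        clinical_display=bool(raw.get("clinical_display", False)),
    )


def _infer_mappings(visits: pd.DataFrame, configured: Mapping[str, GrcMapping]) -> dict[str, GrcMapping]:
    """Fill in mappings for studies not in the config by matching label sets."""
    out = dict(configured)
    for study in visits["study_id"].unique():
        if str(study) in out:
            continue
        labels = {
            str(g)
            for g in visits.loc[visits["study_id"] == study, "grc"]
            if isinstance(g, str) and g.strip()
        }
        for preset in (GRC_5_LEVEL, GRC_3_LEVEL):
            if labels and labels <= set(preset.labels):
                out[str(study)] = preset
                break
        else:
            raise ValueError(
                f"study {study!r}: GRC labels {sorted(labels)} match no configured "
                "mapping and no preset; add a grc_mappings entry"
            )
    return out


def run_pipeline(
    input_csv: str | Path, config: RunConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Run every stage on an input visit table; returns artifact paths.

    Artifacts: observations.csv, anchor_validity.csv, surface.json,
    ed_table.csv, metrics.csv, group_summaries.csv, smd.csv, results.json,
    run.log.  Any stage failure propagates (the CLI maps it to a non-zero
    exit naming the stage).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    artifacts: dict[str, Path] = {}
    results: dict[str, object] = {}

    visits = pd.read_csv(input_csv, dtype={"patient_id": str, "study_id": str, "grc": str})
    mappings = _infer_mappings(visits, config.grc_mappings)

    records = compute_changes(visits, config.scale, mappings, log=log_lines)
    if not records:
        raise ValueError(f"no complete observation intervals for scale {config.scale.name}")
    obs = records_to_frame(records)
    artifacts["observations"] = out / "observations.csv"
    obs.to_csv(artifacts["observations"], index=False)

    validity = anchor_validity(records)
    artifacts["anchor_validity"] = out / "anchor_validity.csv"
    validity.round({"rho": 2}).to_csv(artifacts["anchor_validity"], index=False)
    results["anchor_validity"] = validity.to_dict(orient="records")

    logger.info("fitting monotone GAMM on %d intervals", len(records))
    surface = fit_gamm(records, config.smooth)
    artifacts["surface"] = out / "surface.json"
    artifacts["surface"].write_text(surface.to_json())
    log_lines.append(
        f"fit: converged={surface.converged} sigma_u={surface.random_intercept_sd:.3f} "
        f"lambdas=({surface.lambda_surface:.3g}, {surface.lambda_baseline:.3g})"
    )

    ed_table = build_ed_table(
        surface,
        config.scale,
        records,
        probabilities=config.ed_probabilities,
        average_mode=config.average_mode,
    )
    artifacts["ed_table"] = out / "ed_table.csv"
    ed_table.to_csv_frame(clinical_display=config.clinical_display).to_csv(
        artifacts["ed_table"], index=False
    )
    results["ed_averages"] = ed_table.averages
    if ed_table.n_excluded_baseline0:
        log_lines.append(
            f"ed_table: {ed_table.n_excluded_baseline0} records at baseline 0 "
            "excluded from the sample average"
        )

    metrics = compute_metrics(records, ed_table, log=log_lines)
    artifacts["metrics"] = out / "metrics.csv"
    metrics_frame(metrics, config.scale.name).to_csv(artifacts["metrics"], index=False)
    results["metrics"] = [
        {
            "stratum": m.stratum,
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "disagreement_percent": m.disagreement_percent,
            "n": m.n,
        }
        for m in metrics
    ]

    summaries = group_summaries(records)
    artifacts["group_summaries"] = out / "group_summaries.csv"
    summaries_frame(summaries).to_csv(artifacts["group_summaries"], index=False)

    smds = []
    by_key = {(s.study_id, s.interval_index, s.grc): s for s in summaries}
    for (study, interval, grc), better in sorted(by_key.items()):
        if "slightly better" not in grc:
            continue
        same = by_key.get((study, interval, "I feel about the same"))
        if same is None or better.n < 2 or same.n < 2:
            continue
        smds.append(
            crude_and_smd(
                better, same, stratum=f"{config.scale.name}/{study}/interval{interval}"
            )
        )
    artifacts["smd"] = out / "smd.csv"
    smd_frame(smds).to_csv(artifacts["smd"], index=False)
    results["smd"] = [
        {"stratum": r.stratum, "crude_difference": r.crude_difference, "smd": r.smd}
        for r in smds
    ]

    artifacts["results"] = out / "results.json"
    artifacts["results"].write_text(json.dumps(results, indent=2, default=float))
    artifacts["log"] = out / "run.log"
    artifacts["log"].write_text("\n".join(log_lines) + "\n")
    for line in log_lines:
        logger.info("%s", line)
    return artifacts
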