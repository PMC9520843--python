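"""End-to-end pipeline: configuration, per-field processing, aggregation.

``run_pipeline`` drives detect -> measure -> classify -> screen ->
summarize for every field, then compares the two conditions on the
summary counts, and (optionally) writes the whole bundle — masks, vesicle
tables, per-field summary, comparison JSON, config snapshot and log —
under one output directory. A rerun from the snapshot with the same seed
reproduces the outputs bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd

from . import io as eio
from .colocalization import classify_field, copositivity_column, screen_copositive
from .field import FieldOfView
from .params import (ClassificationParams, DetectionParams, ParameterError,
                     SimulationParams)
from .quantification import compare_conditions, summarize_fields
from .synthetic import GroundTruth, hss_preset, lss_preset, simulate_experiment

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to replay an analysis run.

    ``screens`` is a list of ``{"base": [markers...], "channel": name}``
    entries; each adds a nested co-positivity flag. ``simulation`` holds
    per-condition ``SimulationParams`` used when the pipeline simulates its
    own inputs. ``channel_map`` (role -> TIFF page) is only needed for
    input files without channel metadata.
    """

    detection_channel: str = "cav1"
    markers: list[str] = dc_field(default_factory=lambda: ["endoglin"])
    screens: list[dict] = dc_field(default_factory=lambda: [
        {"base": ["endoglin"], "channel": "smad1"},
    ])
    detection: DetectionParams = dc_field(default_factory=DetectionParams)
    classification: ClassificationParams = dc_field(
        default_factory=ClassificationParams)
    simulation: dict[str, SimulationParams] = dc_field(
        default_factory=lambda: {"LSS": lss_preset(), "HSS": hss_preset()})
    n_fields_per_condition: int = 5
    channel_map: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        roles = {self.detection_channel, *self.markers,
                 *(s["channel"] for s in self.screens)}
        for s in self.screens:
            roles.update(s["base"])
        for s in self.screens:
            unknown = set(s["base"]) - set(self.markers)
            if unknown:
                raise ParameterError(
                    f"screen base markers {sorted(unknown)} are not in "
                    f"markers {self.markers}")
        if self.channel_map is not None:
            missing = roles - set(self.channel_map)
            if missing:
                raise ParameterError(
                    f"channel_map lacks roles {sorted(missing)}")

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        from dataclasses import asdict
        d = {
            "detection_channel": self.detection_channel,
            "markers": list(self.markers),
            "screens": [dict(s) for s in self.screens],
            "detection": asdict(self.detection),
            "classification": _classification_to_dict(self.classification),
            "simulation": {k: v.to_dict() for k, v in self.simulation.items()},
            "n_fields_per_condition": self.n_fields_per_condition,
            "channel_map": dict(self.channel_map) if self.channel_map else None,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "detection" in d and not isinstance(d["detection"], DetectionParams):
            d["detection"] = DetectionParams(**d["detection"])
        if "classification" in d and not isinstance(
                d["classification"], ClassificationParams):
            d["classification"] = _classification_from_dict(d["classification"])
        if "simulation" in d:
            d["simulation"] = {
                k: v if isinstance(v, SimulationParams)
                else SimulationParams.from_dict(v)
                for k, v in d["simulation"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(eio.load_yaml(path))

    def to_yaml(self, path: str | Path) -> Path:
        return eio.dump_yaml(self.to_dict(), path)


def _classification_to_dict(p: ClassificationParams) -> dict:
    return {
        "enrichment_fraction": p.enrichment_fraction,
        "reference_scope": p.reference_scope,
        "measure_on": p.measure_on,
        "strict": p.strict,
        "per_marker": {k: _classification_to_dict(v)
                       for k, v in p.per_marker.items()},
    }


def _classification_from_dict(d: dict) -> ClassificationParams:
    d = dict(d)
    d["per_marker"] = {k: _classification_from_dict(v)
                       for k, v in (d.get("per_marker") or {}).items()}
    return ClassificationParams(**d)


@dataclass
class PipelineResult:
    """In-memory bundle produced by :func:`run_pipeline`."""

    tables: list[pd.DataFrame]
    summaries: pd.DataFrame
    comparisons: dict[str, dict]
    failures: dict[str, str] = dc_field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def process_field(field: FieldOfView, config: PipelineConfig):
    """Detect, classify and screen one field.

    Returns ``(mask, table)``: the labeled mask and the fully classified
    vesicle table (per-marker means, ratios, positivity and co-positivity
    flags).
    """
    from .detection import detect_vesicles

    mask, table = detect_vesicles(field, config.detection_channel,
                                  config.detection)
    table = classify_field(field, mask, table, config.markers,
                           config.classification)
    for screen in config.screens:
        table = screen_copositive(field, mask, table, screen["base"],
                                  screen["channel"], config.classification)
    logger.info("field %s (%s): %d vesicles",
                field.source or "<memory>", field.condition_label, len(table))
    return mask, table


def comparison_columns(config: PipelineConfig) -> list[str]:
    cols = ["n_vesicles"]
    cols += [f"n_pos_{m}" for m in config.markers]
    cols += ["n_" + copositivity_column(s["base"], s["channel"])
             for s in config.screens]
    return cols


def run_pipeline(
    config: PipelineConfig,
    image_paths: list[str | Path] | None = None,
    simulate: bool = False,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on real TIFFs or on simulated fields.

    With ``simulate=True`` the two condition presets in ``config.simulation``
    generate ``config.n_fields_per_condition`` fields each. With real
    inputs, unreadable files are recorded in ``result.failures`` and the run
    continues. Condition comparison requires exactly two condition labels
    with >= 2 fields each; otherwise comparisons are empty.
    """
    fields: list[FieldOfView] = []
    truths: list[GroundTruth | None] = []
    failures: dict[str, str] = {}

    if simulate:
        conditions = list(config.simulation)
        if len(conditions) != 2:
            raise ParameterError("simulation presets must name 2 conditions")
        pairs = simulate_experiment(
            config.simulation[conditions[0]], config.simulation[conditions[1]],
            config.n_fields_per_condition, config.seed)
        for fov, truth in pairs:
            fields.append(fov)
            truths.append(truth)
    else:
        for p in image_paths or []:
            try:
                fields.append(eio.read_field(p, channel_map=config.channel_map))
                truths.append(None)
            except Exception as exc:  # noqa: BLE001 - per-file error contract
                logger.error("failed to read %s: %s", p, exc)
                failures[str(p)] = str(exc)

    masks, tables = [], []
    for fov in fields:
        mask, table = process_field(fov, config)
        masks.append(mask)
        tables.append(table)
    labels = [fov.condition_label for fov in fields]
    summaries = summarize_fields(tables, labels)

    comparisons: dict[str, dict] = {}
    n_per_label = pd.Series(labels).value_counts()
    if len(n_per_label) == 2 and (n_per_label >= 2).all():
        for col in comparison_columns(config):
            if col in summaries.columns:
                result = compare_conditions(summaries, col)
                comparisons[col] = result.to_dict()

    result = PipelineResult(tables=tables, summaries=summaries,
                            comparisons=comparisons, failures=failures)
    if out_dir is not None:
        _write_bundle(result, fields, masks, truths, config, Path(out_dir))
    return result


def _write_bundle(result: PipelineResult, fields: list[FieldOfView],
                  masks: list, truths: list, config: PipelineConfig,
                  out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    for i, (fov, table) in enumerate(zip(fields, result.tables)):
        stem = f"field_{i:03d}_{fov.condition_label or 'NA'}"
        eio.write_field(fov, out / f"{stem}.tif")
        eio.write_mask(masks[i], out / f"{stem}_mask.tif")
        eio.write_table(table, out / f"{stem}_vesicles.csv")
        if truths[i] is not None:
            eio.write_ground_truth(truths[i], out / f"{stem}_truth.csv")
    eio.write_table(result.summaries, out / "summary.csv")
    (out / "comparison.json").write_text(
        json.dumps(result.comparisons, indent=2, sort_keys=True))
    if result.failures:
        (out / "failures.json").write_text(
            json.dumps(result.failures, indent=2, sort_keys=True))
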