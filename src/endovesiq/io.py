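"""Reading and writing fields, masks, tables and configuration.

Fields travel as multi-page TIFF (one page per channel; channel names,
pixel size and condition label in the shaped-TIFF JSON metadata), ground
truth and vesicle tables as CSV, simulation parameters as a JSON sidecar,
and pipeline configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .field import FieldOfView, LabeledMask
from .params import DetectionParams, SimulationParams
from .synthetic import GroundTruth


def write_field(fov: FieldOfView, path: str | Path) -> Path:
    """Write a field as a multi-page float32 TIFF with channel metadata."""
    path = Path(path)
    names = list(fov.channels)
    stack = np.stack([fov.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack", metadata={
        "channels": names,
        "pixel_size": fov.pixel_size,
        "condition_label": fov.condition_label,
    })
    return path


def read_field(
    path: str | Path,
    channel_map: dict[str, int] | None = None,
    pixel_size: float | None = None,
    condition_label: str | None = None,
) -> FieldOfView:
    """Read a multi-page TIFF as a :class:`FieldOfView`.

    Channel names come from the file's shaped metadata when present;
    otherwise ``channel_map`` (role name -> page index) is required.
    Explicit ``pixel_size`` / ``condition_label`` override the metadata.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = (tf.shaped_metadata or [{}])[0]
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"{path}: expected 2D or (C, rows, cols) TIFF, "
                         f"got shape {stack.shape}")

    if channel_map:
        channels = {name: np.asarray(stack[idx], dtype=float)
                    for name, idx in channel_map.items()}
    elif "channels" in meta:
        names = list(meta["channels"])
        if len(names) != len(stack):
            raise ValueError(f"{path}: {len(names)} channel names for "
                             f"{len(stack)} pages")
        channels = {n: np.asarray(p, dtype=float) for n, p in zip(names, stack)}
    else:
        raise ValueError(f"{path}: no channel metadata; pass a channel_map")

    return FieldOfView(
        channels=channels,
        pixel_size=float(pixel_size if pixel_size is not None
                         else meta.get("pixel_size", 1.0)),
        condition_label=(condition_label if condition_label is not None
                         else meta.get("condition_label", "")),
        source=str(path),
    )


def write_mask(mask: LabeledMask, path: str | Path) -> Path:
    """Write a labeled mask as a 16-bit TIFF."""
    path = Path(path)
    if mask.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot write 16-bit mask")
    tifffile.imwrite(path, mask.labels.astype(np.uint16),
                     photometric="minisblack", metadata={"detection_channel": mask.detection_channel})
    return path


def read_mask(path: str | Path,
              params: DetectionParams | None = None) -> LabeledMask:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        labels = tf.asarray().astype(int)
        meta = (tf.shaped_metadata or [{}])[0]
    return LabeledMask(labels=labels,
                       detection_channel=meta.get("detection_channel", ""),
                       params=params or DetectionParams())


def write_ground_truth(truth: GroundTruth, csv_path: str | Path,
                       params_path: str | Path | None = None) -> Path:
    """Ground truth as CSV (one row per vesicle) + JSON parameter sidecar."""
    csv_path = Path(csv_path)
    truth.vesicles.to_csv(csv_path, index=False)
    if params_path is not None:
        write_params_json(truth.params, params_path)
    return csv_path


def read_ground_truth(csv_path: str | Path,
                      params_path: str | Path | None = None) -> GroundTruth:
    csv_path = Path(csv_path)
    vesicles = pd.read_csv(csv_path)
    if params_path is not None:
        params = read_params_json(params_path)
        label = params.condition_label
    else:
        params = SimulationParams()
        label = ""
    return GroundTruth(vesicles=vesicles, condition_label=label, params=params)


def write_params_json(params: SimulationParams, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(params.to_dict(), indent=2, sort_keys=True))
    return path


def read_params_json(path: str | Path) -> SimulationParams:
    return SimulationParams.from_dict(json.loads(Path(path).read_text()))


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_yaml(data: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    return path
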