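"""In-memory containers for multi-channel fields of view and labeled masks."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .params import DetectionParams


@dataclass
class FieldOfView:
    """One acquired (or simulated) multi-channel 2D image.

    ``channels`` maps a channel-role name (``"cav1"``, ``"endoglin"`` ...)
    to a 2D non-negative intensity raster. All rasters must share one shape;
    channels are assumed pre-aligned, as in single-pass confocal acquisition.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = 1.0
    condition_label: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FieldOfView needs at least one channel")
        shapes = {name: np.asarray(r).shape for name, r in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel rasters differ in shape: {shapes}")
        for name, raster in self.channels.items():
            raster = np.asarray(raster)
            if raster.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")
            if np.any(raster < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
            self.channels[name] = raster
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not in field (have {sorted(self.channels)})"
            ) from None


@dataclass
class LabeledMask:
    """Connected-component vesicle labels aligned to a field.

    ``labels`` is an integer raster where 0 is background and k marks the
    pixels of vesicle k; labels are consecutive 1..n_vesicles.
    """

    labels: np.ndarray
    detection_channel: str
    params: DetectionParams

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label raster must be 2D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_vesicles(self) -> int:
        return int(self.labels.max())
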