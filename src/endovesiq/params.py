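"""Parameter containers for simulation, detection and classification.

All parameters are plain frozen dataclasses validated on construction so
that an invalid configuration fails loudly before any pixel is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


def _finite(x: float) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x)


@dataclass(frozen=True)
class SecondaryMarker:
    """One secondary fluorescence channel co-rendered with the detection marker.

    Truly positive vesicles carry an enriched Gaussian signal in this channel;
    negative vesicles receive only a small baseline bleed so that the
    enrichment classifier has a non-trivial decision to make.

    Parameters
    ----------
    name
        Channel-role name (e.g. ``"endoglin"``, ``"smad1"``).
    enrichment_factor
        Multiplicative boost applied to the vesicle's base amplitude in this
        channel for truly positive vesicles; dimensionless, > 1.
    true_positive_fraction
        Bernoulli probability that a vesicle is truly positive for this
        marker, independent across vesicles and markers.
    bleed_fraction
        Fraction of the enriched amplitude that negative vesicles still show
        (spectral bleed-through / unspecific staining).
    """

    name: str
    enrichment_factor: float = 1.5
    true_positive_fraction: float = 0.5
    bleed_fraction: float = 0.1

    def __post_init__(self) -> None:
        _require(bool(self.name), "secondary marker needs a non-empty name")
        _require(_finite(self.enrichment_factor) and self.enrichment_factor > 1.0,
                 f"enrichment_factor must be finite and > 1, got {self.enrichment_factor}")
        _require(_finite(self.true_positive_fraction)
                 and 0.0 <= self.true_positive_fraction <= 1.0,
                 f"true_positive_fraction must be in [0, 1], got {self.true_positive_fraction}")
        _require(_finite(self.bleed_fraction) and 0.0 <= self.bleed_fraction < 1.0,
                 f"bleed_fraction must be in [0, 1), got {self.bleed_fraction}")


@dataclass(frozen=True)
class SimulationParams:
    """Full description of one simulated field of view.

    Identical ``SimulationParams`` (including ``seed``) reproduce the field
    bit-identically.

    Parameters
    ----------
    field_shape
        Image shape in pixels (rows, cols).
    vesicle_density
        Expected vesicles per 1000 px²; the realised count is Poisson with
        mean ``density * rows * cols / 1000`` (minus a usually negligible
        number of placements rejected by the separation constraint).
    radius_range
        (min, max) vesicle radius in px; each vesicle draws its radius
        uniformly from this range and is rendered as an isotropic Gaussian
        blob with ``sigma = radius / 2``.
    primary_amplitude
        Mean peak intensity of a vesicle above background in the detection
        channel (arbitrary units); per-vesicle amplitudes are lognormal
        around this mean with coefficient of variation ``amplitude_cv``.
    secondary_enrichment_factor, true_positive_fraction
        Convenience scalars used to build a single-marker ``secondaries``
        tuple (channel ``"endoglin"``) when ``secondaries`` is None.
    background_level
        Mean background intensity, identical in every channel.
    background_smoothness
        Correlation length (px) of the low-frequency background field.
    background_variation
        Relative sd of the smooth background around its mean.
    gaussian_noise_sd
        Additive read-noise sd, applied after the optional Poisson step.
    poisson_noise
        Apply shot noise (Poisson resampling of the expected signal).
    amplitude_cv
        Coefficient of variation of per-vesicle peak amplitudes.
    min_separation
        Minimum centre-to-centre distance between two vesicles, expressed as
        a multiple of the sum of their radii; placements violating it are
        re-drawn (dart throwing).
    condition_label
        Free-text experimental condition (e.g. ``"LSS"``, ``"HSS"``).
    seed
        Master seed for this field.
    """

    field_shape: tuple[int, int] = (512, 512)
    vesicle_density: float = 0.8
    radius_range: tuple[float, float] = (2.0, 5.0)
    primary_amplitude: float = 220.0
    secondary_enrichment_factor: float = 1.5
    true_positive_fraction: float = 0.5
    background_level: float = 400.0
    background_smoothness: float = 40.0
    background_variation: float = 0.05
    gaussian_noise_sd: float = 5.0
    poisson_noise: bool = True
    amplitude_cv: float = 0.2
    min_separation: float = 1.0
    condition_label: str = ""
    seed: int = 0
    primary_channel: str = "cav1"
    secondaries: tuple[SecondaryMarker, ...] | None = None

    def __post_init__(self) -> None:
        rows, cols = self.field_shape
        _require(int(rows) > 0 and int(cols) > 0,
                 f"field_shape must be positive, got {self.field_shape}")
        _require(_finite(self.vesicle_density) and self.vesicle_density >= 0,
                 f"vesicle_density must be >= 0, got {self.vesicle_density}")
        rmin, rmax = self.radius_range
        _require(_finite(rmin) and _finite(rmax) and 0 < rmin <= rmax,
                 f"radius_range must satisfy 0 < min <= max, got {self.radius_range}")
        for name in ("primary_amplitude", "background_level", "background_smoothness",
                     "background_variation", "gaussian_noise_sd", "amplitude_cv",
                     "min_separation"):
            v = getattr(self, name)
            _require(_finite(v) and v >= 0, f"{name} must be finite and >= 0, got {v}")
        _require(_finite(self.true_positive_fraction)
                 and 0.0 <= self.true_positive_fraction <= 1.0,
                 "true_positive_fraction must be in [0, 1]")
        _require(self.secondary_enrichment_factor > 1.0,
                 "secondary_enrichment_factor must be > 1")
        if self.secondaries is None:
            object.__setattr__(self, "secondaries", (
                SecondaryMarker(
                    name="endoglin",
                    enrichment_factor=self.secondary_enrichment_factor,
                    true_positive_fraction=self.true_positive_fraction,
                ),
            ))
        names = [m.name for m in self.secondaries]
        _require(len(names) == len(set(names)), "duplicate secondary channel names")
        _require(self.primary_channel not in names,
                 "primary channel name collides with a secondary marker")

    @property
    def expected_count(self) -> float:
        """Poisson mean of the vesicle count: density × area / 1000."""
        rows, cols = self.field_shape
        return self.vesicle_density * rows * cols / 1000.0

    @property
    def channel_names(self) -> list[str]:
        return [self.primary_channel] + [m.name for m in self.secondaries]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationParams":
        d = dict(d)
        if d.get("secondaries") is not None:
            d["secondaries"] = tuple(
                m if isinstance(m, SecondaryMarker) else SecondaryMarker(**m)
                for m in d["secondaries"]
            )
        for key in ("field_shape", "radius_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class DetectionParams:
    """Vesicle detection settings: background subtraction, thresholding and
    particle filtering.

    ``threshold_method`` is either the name of an automatic method
    (``"otsu"``, ``"triangle"``, ``"mean_sd"``) or a fixed numeric value
    applied to the background-subtracted raster. ``mean_sd`` thresholds at
    ``mean + threshold_k * sd`` of the subtracted raster. ``smooth_sigma``
    is a Gaussian pre-filter (px) applied before background subtraction to
    suppress single-pixel shot noise; 0 disables it.

    Automatic methods are additionally floored at a robust noise estimate,
    ``median + noise_floor_k * 1.4826 * MAD`` of the subtracted raster, so
    a signal-free image yields no detections instead of a split noise
    histogram; ``noise_floor_k = 0`` disables the floor.
    """

    background_radius: float = 15.0
    smooth_sigma: float = 1.0
    noise_floor_k: float = 5.0
    threshold_method: str | float = "otsu"
    threshold_k: float = 5.0
    min_area: int = 4
    max_area: int = 400
    min_circularity: float = 0.3
    fill_holes: bool = True
    connectivity: int = 8
    split_touching: bool = False

    def __post_init__(self) -> None:
        _require(_finite(self.background_radius) and self.background_radius > 0,
                 "background_radius must be > 0")
        _require(_finite(self.smooth_sigma) and self.smooth_sigma >= 0,
                 "smooth_sigma must be >= 0")
        _require(_finite(self.noise_floor_k) and self.noise_floor_k >= 0,
                 "noise_floor_k must be >= 0")
        _require(self.min_area <= self.max_area,
                 f"min_area ({self.min_area}) must be <= max_area ({self.max_area})")
        _require(0.0 <= self.min_circularity <= 1.0,
                 "min_circularity must be in [0, 1]")
        _require(self.connectivity in (4, 8), "connectivity must be 4 or 8")
        if isinstance(self.threshold_method, str):
            _require(self.threshold_method in ("otsu", "triangle", "mean_sd"),
                     f"unknown threshold method {self.threshold_method!r}")
        else:
            _require(_finite(self.threshold_method),
                     "fixed threshold must be finite")


@dataclass(frozen=True)
class ClassificationParams:
    """The relative-enrichment positivity rule.

    A vesicle is marker-positive when its mean intensity in the marker
    channel is at least ``(1 + enrichment_fraction)`` times the reference
    intensity of the image ("at least" is inclusive unless ``strict``).

    ``reference_scope`` selects the baseline statistic:

    - ``"image_mean"`` (default): mean over all pixels of the channel raster;
    - ``"outside_mean"``: mean over pixels outside every vesicle mask;
    - ``"image_median"``: median over all pixels.

    ``measure_on`` selects the raster version on which intensities are
    measured: ``"raw"`` (default) or ``"subtracted"`` (background-subtracted).
    ``per_marker`` maps channel names to ``ClassificationParams`` overrides
    used when screening that channel.
    """

    enrichment_fraction: float = 0.15
    reference_scope: str = "image_mean"
    measure_on: str = "raw"
    strict: bool = False
    per_marker: Mapping[str, "ClassificationParams"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require(_finite(self.enrichment_fraction) and self.enrichment_fraction >= 0,
                 "enrichment_fraction must be >= 0")
        _require(self.reference_scope in ("image_mean", "outside_mean", "image_median"),
                 f"unknown reference_scope {self.reference_scope!r}")
        _require(self.measure_on in ("raw", "subtracted"),
                 f"measure_on must be 'raw' or 'subtracted', got {self.measure_on!r}")

    def for_marker(self, name: str) -> "ClassificationParams":
        """Parameters effective for channel ``name`` (override or self)."""
        override = self.per_marker.get(name)
        return override if override is not None else self
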