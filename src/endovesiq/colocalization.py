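"""Object-based colocalization scoring.

The core rule, applied per vesicle and per marker channel: translate the
detected vesicles into a mask, measure the marker's mean intensity inside
each vesicle, and call the vesicle marker-positive when that mean is at
least ``(1 + f)`` times the mean intensity of the whole image in the same
channel (default f = 0.15, i.e. "at least 15% higher"). Positives for a base
marker set can then be screened for additional markers with the same rule,
giving nested co-positivity flags (e.g. detection marker + receptor marker,
then screened for an endosomal or signaling marker).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .detection import subtract_background
from .field import FieldOfView, LabeledMask
from .params import ClassificationParams


def _reference_statistic(raster: np.ndarray, labels: np.ndarray,
                         scope: str) -> float:
    if scope == "image_mean":
        return float(raster.mean())
    if scope == "image_median":
        return float(np.median(raster))
    if scope == "outside_mean":
        outside = raster[labels == 0]
        return float(outside.mean()) if outside.size else float(raster.mean())
    raise ValueError(f"unknown reference scope {scope!r}")


def measure_channel(
    mask: LabeledMask,
    raster: np.ndarray,
    scope: str = "image_mean",
) -> tuple[np.ndarray, float]:
    """Per-vesicle arithmetic mean of ``raster`` plus the reference statistic.

    Returns an array of length ``mask.n_vesicles`` where entry ``k - 1`` is
    the mean of ``raster`` over the pixels with label ``k``, and the scalar
    reference intensity defined by ``scope`` (see
    :class:`~endovesiq.params.ClassificationParams`).
    """
    raster = np.asarray(raster, dtype=float)
    if raster.shape != mask.labels.shape:
        raise ValueError(
            f"raster shape {raster.shape} does not match mask shape "
            f"{mask.labels.shape}"
        )
    n = mask.n_vesicles
    if n == 0:
        means = np.empty(0)
    else:
        means = np.asarray(ndimage.mean(raster, labels=mask.labels,
                                        index=np.arange(1, n + 1)))
    return means, _reference_statistic(raster, mask.labels, scope)


def classify_positive(
    vesicle_means: np.ndarray,
    image_mean: float,
    params: ClassificationParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the relative-enrichment rule to per-vesicle means.

    Returns ``(flags, ratios)`` where ``ratios = vesicle_means / image_mean``
    and ``flags = ratios >= 1 + f`` ("at least f higher" is inclusive; a
    strict-inequality mode is available via ``params.strict``). Ratios are
    reported for every vesicle regardless of the flag.
    """
    if params is None:
        params = ClassificationParams()
    if not (image_mean > 0):
        raise ValueError(
            f"degenerate reference intensity {image_mean!r}: the enrichment "
            "rule needs a positive image mean"
        )
    vesicle_means = np.asarray(vesicle_means, dtype=float)
    ratios = vesicle_means / image_mean
    cutoff = 1.0 + params.enrichment_fraction
    flags = ratios > cutoff if params.strict else ratios >= cutoff
    return flags, ratios


def classify_field(
    field: FieldOfView,
    mask: LabeledMask,
    table: pd.DataFrame,
    markers: list[str],
    params: ClassificationParams | None = None,
) -> pd.DataFrame:
    """Measure and classify every marker channel against the vesicle mask.

    Appends, for each marker ``m``, columns ``mean_<m>``, ``ratio_<m>`` and
    ``pos_<m>`` to a copy of the detection table. Intensities are measured
    on the raw raster by default (``params.measure_on``); the reference is
    computed on the same raster version as the measurement.
    """
    if params is None:
        params = ClassificationParams()
    table = table.copy()
    for marker in markers:
        mp = params.for_marker(marker)
        raster = field.channel(marker)
        if mp.measure_on == "subtracted":
            raster = subtract_background(raster,
                                         mask.params.background_radius)
        means, reference = measure_channel(mask, raster, mp.reference_scope)
        flags, ratios = classify_positive(means, reference, mp)
        table[f"mean_{marker}"] = means
        table[f"ratio_{marker}"] = ratios
        table[f"pos_{marker}"] = flags
    return table


def copositivity_column(base_markers: list[str], screen_channel: str) -> str:
    """Canonical column name for a nested co-positivity flag."""
    return "copos_" + "+".join([*base_markers, screen_channel])


def screen_copositive(
    field: FieldOfView,
    mask: LabeledMask,
    table: pd.DataFrame,
    base_markers: list[str],
    screen_channel: str,
    params: ClassificationParams | None = None,
) -> pd.DataFrame:
    """Screen base-positive vesicles for an additional marker's signal.

    Only vesicles positive for *all* ``base_markers`` are evaluated against
    the screen channel, using the same enrichment rule (a per-marker
    override of ``f`` is honoured). Vesicles failing the base set get a
    ``False`` flag — never a missing value — so the co-positivity flag is
    exactly the conjunction of its component flags.
    """
    if params is None:
        params = ClassificationParams()
    if screen_channel not in field.channels:
        raise KeyError(f"screen channel {screen_channel!r} not in field "
                       f"(have {sorted(field.channels)})")
    table = table.copy()
    base = np.ones(len(table), dtype=bool)
    for m in base_markers:
        col = f"pos_{m}"
        if col not in table.columns:
            raise ValueError(f"base marker {m!r} has not been classified yet")
        base &= table[col].to_numpy(dtype=bool)

    screen_col = f"pos_{screen_channel}"
    if screen_col not in table.columns:
        table = classify_field(field, mask, table, [screen_channel], params)
    table[copositivity_column(base_markers, screen_channel)] = (
        base & table[screen_col].to_numpy(dtype=bool)
    )
    return table


@dataclass
class ProfileResult:
    """Multi-channel intensity profile along a straight segment.

    ``data`` has a ``position_px`` column (0 .. segment length, strictly
    increasing), optionally ``position_um``, and one intensity column per
    requested channel.
    """

    data: pd.DataFrame
    p0: tuple[float, float]
    p1: tuple[float, float]
    width: int

    @property
    def length_px(self) -> float:
        return float(np.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1]))


def line_profile(
    field: FieldOfView,
    channels: list[str],
    p0: tuple[float, float],
    p1: tuple[float, float],
    width: int = 1,
    n_samples: int = 100,
) -> ProfileResult:
    """Bilinear intensity profile along the segment from ``p0`` to ``p1``.

    Samples each channel at ``n_samples`` equispaced points along the
    segment (endpoints included), averaging over ``width`` parallel lines
    offset perpendicular to the segment (centred, 1-px spacing). Points are
    (row, col), 0-based; both endpoints must lie inside the image.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if width < 1:
        raise ValueError("width must be >= 1")
    rows, cols = field.shape
    for name, pt in (("p0", p0), ("p1", p1)):
        r, c = pt
        if not (0 <= r <= rows - 1 and 0 <= c <= cols - 1):
            raise ValueError(f"{name}={pt} lies outside the image {field.shape}")

    p0 = (float(p0[0]), float(p0[1]))
    p1 = (float(p1[0]), float(p1[1]))
    d = np.array([p1[0] - p0[0], p1[1] - p0[1]])
    length = float(np.hypot(*d))
    if length == 0:
        raise ValueError("p0 and p1 coincide; the profile segment is degenerate")
    t = np.linspace(0.0, 1.0, n_samples)
    base_r = p0[0] + t * d[0]
    base_c = p0[1] + t * d[1]
    normal = np.array([-d[1], d[0]]) / length
    offsets = np.arange(width, dtype=float) - (width - 1) / 2.0

    out = {"position_px": t * length}
    if field.pixel_size != 1.0:
        out["position_um"] = t * length * field.pixel_size
    for name in channels:
        raster = np.asarray(field.channel(name), dtype=float)
        acc = np.zeros(n_samples)
        for off in offsets:
            rr = base_r + off * normal[0]
            cc = base_c + off * normal[1]
            acc += ndimage.map_coordinates(raster, [rr, cc], order=1,
                                           mode="nearest")
        out[name] = acc / width
    return ProfileResult(data=pd.DataFrame(out), p0=p0, p1=p1, width=width)
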