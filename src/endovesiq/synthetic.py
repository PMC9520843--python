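"""Synthetic multi-channel fluorescence fields with vesicle ground truth.

The generator emulates the statistical structure that the downstream
object-based colocalization analysis assumes: punctate vesicles (isotropic
Gaussian blobs, sigma = radius / 2) scattered over a smooth autofluorescent
background, shot + read noise, and per-vesicle correlated secondary-marker
enrichment with a controllable true positive fraction. Two condition presets
(low vs high laminar shear stress, LSS / HSS) encode the qualitative
experimental contrast the pipeline is meant to resolve: more vesicles and a
larger marker-positive fraction under LSS than under HSS.

Everything is driven by a single integer seed; identical parameters
(including the seed) reproduce the field bit-identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .field import FieldOfView
from .params import ParameterError, SecondaryMarker, SimulationParams

_PLACEMENT_ATTEMPTS = 200


@dataclass
class GroundTruth:
    """The simulator's truth for one field, recorded before noise.

    ``vesicles`` has one row per vesicle with columns ``id``, ``row``,
    ``col`` (0-based pixel coordinates of the centre), ``radius`` (px),
    ``amp_<channel>`` (peak amplitude above background per channel) and
    ``pos_<marker>`` (true positivity per secondary marker).
    """

    vesicles: pd.DataFrame
    condition_label: str
    params: SimulationParams

    @property
    def n_vesicles(self) -> int:
        return len(self.vesicles)

    def positive_fraction(self, marker: str) -> float | None:
        """Empirical truly-positive fraction for ``marker`` (None if empty)."""
        if self.n_vesicles == 0:
            return None
        return float(self.vesicles[f"pos_{marker}"].mean())


def _lognormal_amplitudes(rng: np.random.Generator, mean: float, cv: float,
                          n: int) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if cv == 0 or mean == 0:
        return np.full(n, float(mean))
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def draw_vesicles(params: SimulationParams, rng: np.random.Generator) -> pd.DataFrame:
    """Sample vesicle positions, radii, amplitudes and true positivity.

    The count is Poisson with mean ``density * area / 1000``; centres are
    placed by dart throwing so that any two centres are at least
    ``min_separation * (r_i + r_j)`` apart (placements that cannot be
    realised within a bounded number of attempts are dropped, which is
    negligible at the densities the presets use). Centres keep a margin of
    one radius from the field edge.
    """
    rows, cols = params.field_shape
    n_target = int(rng.poisson(params.expected_count))
    rmin, rmax = params.radius_range

    radii: list[float] = []
    centres: list[tuple[float, float]] = []
    for _ in range(n_target):
        r = float(rng.uniform(rmin, rmax))
        placed = False
        for _attempt in range(_PLACEMENT_ATTEMPTS):
            cr = float(rng.uniform(min(r, rows / 2), max(rows - 1 - r, rows / 2)))
            cc = float(rng.uniform(min(r, cols / 2), max(cols - 1 - r, cols / 2)))
            if centres:
                d = np.hypot(np.array([c[0] for c in centres]) - cr,
                             np.array([c[1] for c in centres]) - cc)
                min_d = params.min_separation * (np.array(radii) + r)
                if np.any(d < min_d):
                    continue
            centres.append((cr, cc))
            radii.append(r)
            placed = True
            break
        if not placed:
            continue

    n = len(centres)
    data: dict[str, np.ndarray] = {
        "id": np.arange(n, dtype=int),
        "row": np.array([c[0] for c in centres]),
        "col": np.array([c[1] for c in centres]),
        "radius": np.array(radii),
        f"amp_{params.primary_channel}": _lognormal_amplitudes(
            rng, params.primary_amplitude, params.amplitude_cv, n),
    }
    for marker in params.secondaries:
        base = _lognormal_amplitudes(rng, params.primary_amplitude,
                                     params.amplitude_cv, n)
        positive = rng.random(n) < marker.true_positive_fraction
        amp = base * marker.enrichment_factor
        amp[~positive] *= marker.bleed_fraction
        data[f"amp_{marker.name}"] = amp
        data[f"pos_{marker.name}"] = positive
    return pd.DataFrame(data)


def _smooth_background(params: SimulationParams,
                       rng: np.random.Generator) -> np.ndarray:
    """Low-frequency Gaussian random field, exactly mean background_level."""
    rows, cols = params.field_shape
    base = np.full((rows, cols), float(params.background_level))
    if params.background_variation == 0 or params.background_smoothness == 0:
        return base
    z = rng.standard_normal((rows, cols))
    z = gaussian_filter(z, sigma=params.background_smoothness, mode="reflect")
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    return base * (1.0 + params.background_variation * z)


def _add_blob(img: np.ndarray, row: float, col: float, sigma: float,
              peak: float) -> None:
    """Add ``peak * exp(-d^2 / 2 sigma^2)`` in a ±6 sigma window (in place)."""
    rows, cols = img.shape
    half = int(np.ceil(6.0 * sigma))
    r0, r1 = max(0, int(np.floor(row)) - half), min(rows, int(np.ceil(row)) + half + 1)
    c0, c1 = max(0, int(np.floor(col)) - half), min(cols, int(np.ceil(col)) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1, dtype=float) - row
    cc = np.arange(c0, c1, dtype=float) - col
    gr = np.exp(-(rr * rr) / (2.0 * sigma * sigma))
    gc = np.exp(-(cc * cc) / (2.0 * sigma * sigma))
    img[r0:r1, c0:c1] += peak * np.outer(gr, gc)


def render_clean(params: SimulationParams, vesicles: pd.DataFrame,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Noise-free expected-intensity rasters for every channel.

    Consumes the background draws from ``rng`` (one per channel, in channel
    order) and adds each vesicle's Gaussian blob on top.
    """
    channels: dict[str, np.ndarray] = {}
    for name in params.channel_names:
        img = _smooth_background(params, rng)
        amps = vesicles[f"amp_{name}"].to_numpy()
        rows_ = vesicles["row"].to_numpy()
        cols_ = vesicles["col"].to_numpy()
        sigmas = vesicles["radius"].to_numpy() / 2.0
        for r, c, s, a in zip(rows_, cols_, sigmas, amps):
            _add_blob(img, r, c, s, a)
        channels[name] = img
    return channels


def _apply_noise(clean: np.ndarray, params: SimulationParams,
                 rng: np.random.Generator) -> np.ndarray:
    img = clean
    if params.poisson_noise:
        img = rng.poisson(np.maximum(img, 0.0)).astype(float)
    if params.gaussian_noise_sd > 0:
        img = img + rng.normal(0.0, params.gaussian_noise_sd, size=img.shape)
    return np.maximum(img, 0.0)


def simulate_field(params: SimulationParams) -> tuple[FieldOfView, GroundTruth]:
    """Render one multi-channel field of view plus its ground truth.

    The sampling order (vesicles, per-channel background, per-channel noise)
    is fixed, so a given ``SimulationParams`` — seed included — always
    produces byte-identical output.
    """
    if not isinstance(params, SimulationParams):
        raise ParameterError("params must be a SimulationParams instance")
    rng = np.random.default_rng(params.seed)
    vesicles = draw_vesicles(params, rng)
    clean = render_clean(params, vesicles, rng)
    noisy = {name: _apply_noise(img, params, rng) for name, img in clean.items()}
    fov = FieldOfView(channels=noisy, condition_label=params.condition_label,
                      source=f"simulated(seed={params.seed})")
    truth = GroundTruth(vesicles=vesicles, condition_label=params.condition_label,
                        params=params)
    return fov, truth


def subseed(master_seed: int, condition_label: str, field_index: int) -> np.random.SeedSequence:
    """Deterministic per-field seed: hash of (master seed, condition, index)."""
    return np.random.SeedSequence(
        [int(master_seed), zlib.crc32(condition_label.encode()), int(field_index)]
    )


def simulate_experiment(
    lss_params: SimulationParams,
    hss_params: SimulationParams,
    n_fields_per_condition: int,
    seed: int,
) -> list[tuple[FieldOfView, GroundTruth]]:
    """Simulate a two-condition experiment with independent fields.

    Each field gets a sub-seed derived deterministically from ``seed``, the
    condition label and the field index, so fields are independent yet the
    whole experiment replays from one integer.
    """
    if n_fields_per_condition < 1:
        raise ParameterError("n_fields_per_condition must be >= 1")
    out: list[tuple[FieldOfView, GroundTruth]] = []
    for cond_params in (lss_params, hss_params):
        label = cond_params.condition_label
        for i in range(n_fields_per_condition):
            ss = subseed(seed, label, i)
            field_seed = int(ss.generate_state(1, dtype=np.uint32)[0])
            out.append(simulate_field(replace(cond_params, seed=field_seed)))
    return out


def lss_preset(**overrides) -> SimulationParams:
    """Low-shear-stress condition: dense vesicles, high marker positivity."""
    defaults = dict(
        field_shape=(256, 256),
        vesicle_density=0.8,
        condition_label="LSS",
        secondaries=(
            SecondaryMarker("endoglin", true_positive_fraction=0.6),
            SecondaryMarker("eea1", true_positive_fraction=0.5),
            SecondaryMarker("smad1", true_positive_fraction=0.45),
        ),
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)


def hss_preset(**overrides) -> SimulationParams:
    """High-shear-stress condition: sparser vesicles, lower positivity."""
    defaults = dict(
        field_shape=(256, 256),
        vesicle_density=0.4,
        condition_label="HSS",
        secondaries=(
            SecondaryMarker("endoglin", true_positive_fraction=0.35),
            SecondaryMarker("eea1", true_positive_fraction=0.3),
            SecondaryMarker("smad1", true_positive_fraction=0.25),
        ),
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)
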