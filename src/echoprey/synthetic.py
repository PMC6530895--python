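"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates what a recreational-grade echosounder stores on a
coastal prey-field survey: 8-bit ping records over a fixed range window
in which schools of epipelagic fish appear as elliptical above-threshold
patches, the seabed as a high-intensity streak, and background noise
whose *stored* (pre-correction) level decays with range according to a
true TVG form.  Raw intensity is generated by subtracting the true TVG
gain from an "ideal" depth-independent field, so applying the correct
TVG form downstream restores depth independence — the situation the
calibration stage is designed to diagnose.

Three generators cover the pipeline's inputs:

* :func:`render_echogram` — survey/ground-truth echograms with planted
  :class:`TrueSchool` morphology conserved in a truth list;
* :func:`make_sphere_drop` — calibration-sphere lowerings with 8x1
  region annotations at stated depths;
* :func:`simulate_surveys` — predator-count survey tables drawn from a
  negative-binomial log-link model driven by true RAPP, for
  parameter-recovery testing of the count models.

All generators are deterministic under a fixed seed (default 20150522,
recorded in their outputs).  No physical acoustics is simulated: there
is no beam-pattern convolution, multiple scattering or vessel motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PingRecord, DEFAULT_META

__all__ = [
    "TrueSchool",
    "SyntheticScene",
    "TruePredatorModel",
    "render_echogram",
    "make_sphere_drop",
    "simulate_surveys",
    "default_dolphin_model",
    "default_penguin_model",
    "STUDY_REGIONS",
    "STUDY_SURVEY_ALLOCATION",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20150522

#: The six coastal survey regions (three dolphin hotspots, three
#: reference areas) and the study's survey allocation over two seasons.
STUDY_REGIONS = ("AK", "BF", "LB", "LL", "LY", "ME")
STUDY_SURVEY_ALLOCATION = {
    # region: (summer surveys, winter surveys)
    "AK": (19, 20), "BF": (10, 8), "LB": (9, 6),
    "LL": (12, 14), "LY": (7, 8), "ME": (10, 13),
}

_ORIGIN_LAT = -43.8
_ORIGIN_LON = 173.1


@dataclass
class TrueSchool:
    """A planted elliptical school with known morphology and intensity.

    The school is a filled ellipse of uniform ``core_intensity_db``
    whose boundary spans exactly ``length_m`` x ``thickness_m``;
    outside the boundary intensity falls at ``edge_falloff_db_per_m``,
    producing the soft partial-threshold edges real schools show.
    """

    center_ping: int
    center_depth_m: float
    length_m: float
    thickness_m: float
    core_intensity_db: float = -22.0
    edge_falloff_db_per_m: float = 240.0

    def __post_init__(self):
        if self.length_m <= 0 or self.thickness_m <= 0:
            raise ValueError("school dimensions must be positive")
        if not (-34.0 <= self.core_intensity_db <= -13.0):
            raise ValueError(
                "core intensity outside the observed school range "
                "[-34, -13] dB")
        if self.edge_falloff_db_per_m <= 0:
            raise ValueError("edge falloff must be positive")


@dataclass
class SyntheticScene:
    """Full specification of one synthetic echogram."""

    schools: list = field(default_factory=list)
    n_pings: int = 400
    seabed_depth_m: float | np.ndarray = 25.0
    seabed_intensity_db: float = -2.0
    noise_floor_at_1m_db: float | None = -60.0
    noise_sd_db: float = 2.0
    tvg_exponent_true: float = 10.0
    absorption_true_db_per_m: float = 0.05
    cell_along_m: float = 0.25
    cell_vertical_m: float = 0.15
    max_range_m: float = 35.0
    rng_seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.tvg_exponent_true not in (10.0, 15.0, 20.0, 40.0, 0.0):
            raise ValueError("tvg_exponent_true must be one of 0/10/15/20/40")
        if not (0.20 <= self.cell_along_m <= 0.34):
            raise ValueError("along-track cell size outside 0.20-0.34 m")
        if self.cell_vertical_m <= 0 or self.max_range_m <= 0:
            raise ValueError("cell sizes and range must be positive")
        if self.n_pings < 2:
            raise ValueError("need at least 2 pings")
        seabed = np.broadcast_to(np.asarray(self.seabed_depth_m, float),
                                 (self.n_pings,))
        for s in self.schools:
            top = s.center_depth_m - s.thickness_m / 2.0
            bot = s.center_depth_m + s.thickness_m / 2.0
            p0 = s.center_ping - s.length_m / (2 * self.cell_along_m)
            p1 = s.center_ping + s.length_m / (2 * self.cell_along_m)
            if p0 < 0 or p1 > self.n_pings - 1:
                raise ValueError("school extends beyond the transect")
            lo = max(0, int(math.floor(p0)))
            hi = min(self.n_pings - 1, int(math.ceil(p1)))
            if top <= 3.0 or bot >= float(seabed[lo:hi + 1].min()):
                raise ValueError(
                    "school must lie strictly between the 3 m near-field "
                    "line and the seabed")


def _depth_axis(scene):
    n_bins = int(round(scene.max_range_m / scene.cell_vertical_m)) + 1
    return np.arange(n_bins) * scene.max_range_m / (n_bins - 1)


def _tvg(z, xi, alpha):
    out = np.full_like(z, -np.inf, dtype=float)
    pos = z > 0
    out[pos] = xi * np.log10(z[pos]) + 2.0 * alpha * z[pos]
    return out


def render_echogram(scene: SyntheticScene, survey_id="synthetic"):
    """Render a scene to 8-bit ping records plus its verbatim truth list.

    The ideal (depth-independent) field is built in corrected dB —
    noise floor, elliptical schools, seabed streak — then the scene's
    true TVG gain is subtracted and the result quantized to 8-bit
    counts, exactly reversing what the calibration stage later applies.
    """
    rng = np.random.default_rng(scene.rng_seed)
    z = _depth_axis(scene)
    n_bins = z.size
    along = np.arange(scene.n_pings) * scene.cell_along_m
    seabed = np.broadcast_to(np.asarray(scene.seabed_depth_m, float),
                             (scene.n_pings,))

    if scene.noise_floor_at_1m_db is None:
        ideal = np.full((scene.n_pings, n_bins), -np.inf)
    else:
        ideal = (scene.noise_floor_at_1m_db
                 + rng.normal(0.0, scene.noise_sd_db,
                              size=(scene.n_pings, n_bins)))

    for s in scene.schools:
        ax = s.center_ping * scene.cell_along_m
        a = s.length_m / 2.0
        b = s.thickness_m / 2.0
        dx = (along[:, None] - ax)
        dz = (z[None, :] - s.center_depth_m)
        rho = np.sqrt(dx**2 + dz**2)
        r = np.sqrt((dx / a) ** 2 + (dz / b) ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            d_out = np.where(r > 1.0, rho * (1.0 - 1.0 / np.maximum(r, 1e-12)),
                             0.0)
        prof = s.core_intensity_db - s.edge_falloff_db_per_m * d_out
        prof = np.where(prof > s.core_intensity_db - 40.0, prof, -np.inf)
        ideal = np.maximum(ideal, prof)

    # seabed: bright streak ~3 bins thick, decaying tail below
    streak = 3 * scene.cell_vertical_m
    dz_bed = z[None, :] - seabed[:, None]
    bed = np.where(dz_bed >= 0,
                   np.where(dz_bed < streak, scene.seabed_intensity_db,
                            scene.seabed_intensity_db
                            - 15.0 * (dz_bed - streak)),
                   -np.inf)
    ideal = np.maximum(ideal, bed)

    with np.errstate(invalid="ignore"):
        raw = ideal - _tvg(z, scene.tvg_exponent_true,
                           scene.absorption_true_db_per_m)[None, :]
    raw = np.where(np.isfinite(raw), raw, -np.inf)
    counts = np.where(
        np.isfinite(raw),
        np.clip(np.round(255.0 * np.power(10.0, raw / 20.0)), 0, 255),
        0).astype(np.int64)

    mper_deg_lon = (math.pi / 180.0) * 6_371_008.8 * math.cos(
        math.radians(_ORIGIN_LAT))
    period_ms = int(round(1000.0 / DEFAULT_META["ping_rate_hz"]))
    records = []
    for p in range(scene.n_pings):
        records.append(PingRecord(
            survey_id=survey_id,
            ping_index=p,
            time_utc_ms=1_430_000_000_000 + p * period_ms,
            latitude=_ORIGIN_LAT,
            longitude=_ORIGIN_LON + p * scene.cell_along_m / mper_deg_lon,
            min_range_m=0.0,
            max_range_m=scene.max_range_m,
            samples=counts[p],
        ))
    truth = list(scene.schools)
    return records, truth


def truth_to_frame(scene: SyntheticScene):
    """Planted-school truth as a table (one row per school)."""
    rows = []
    for s in scene.schools:
        rows.append({
            "center_ping": s.center_ping,
            "center_depth_m": s.center_depth_m,
            "length_m": s.length_m,
            "thickness_m": s.thickness_m,
            "core_intensity_db": s.core_intensity_db,
        })
    df = pd.DataFrame(rows, columns=["center_ping", "center_depth_m",
                                     "length_m", "thickness_m",
                                     "core_intensity_db"])
    df.attrs["rng_seed"] = scene.rng_seed
    return df


def make_sphere_drop(depths_m, tvg_exponent_true=10.0,
                     absorption_true_db_per_m=0.05, noise_sd_db=0.5,
                     cell_vertical_m=0.15, max_range_m=35.0,
                     cell_along_m=0.25, seed=DEFAULT_SEED,
                     survey_id="sphere-drop"):
    """Simulate a calibration-sphere lowering, one ping per stated depth.

    The on-axis sphere echo at depth z has raw peak intensity
    ``K - xi*log10(z) - 2*alpha*z`` plus Gaussian noise, with the
    system constant K placed so the shallowest echo sits just below
    full scale — the strongest echo an 8-bit store can hold without
    clipping.  Returns the ping records and a ``{ping: depth}``
    annotation map locating the 8x1 extraction window per depth.
    """
    depths = np.asarray(list(depths_m), dtype=float)
    if np.any(depths <= 3.0):
        raise ValueError("sphere depths must exceed the 3 m near-field")
    if np.any(depths > 35.0):
        raise ValueError("sphere depths must be within (3, 35] m")
    rng = np.random.default_rng(seed)
    n_bins = int(round(max_range_m / cell_vertical_m)) + 1
    z = np.arange(n_bins) * max_range_m / (n_bins - 1)
    zmin = depths.min()
    k_const = (-1.0 + tvg_exponent_true * np.log10(zmin)
               + 2.0 * absorption_true_db_per_m * zmin)
    taper = np.array([-3.0, -1.0, 0.0, -1.0, -3.0])  # echo shape over 5 bins

    mper_deg_lon = (math.pi / 180.0) * 6_371_008.8 * math.cos(
        math.radians(_ORIGIN_LAT))
    period_ms = int(round(1000.0 / DEFAULT_META["ping_rate_hz"]))
    records = []
    annotations = {}
    for p, depth in enumerate(depths):
        raw = np.full(n_bins, -np.inf)
        peak = (k_const - tvg_exponent_true * np.log10(depth)
                - 2.0 * absorption_true_db_per_m * depth
                + rng.normal(0.0, noise_sd_db))
        center = int(round(depth / (max_range_m / (n_bins - 1))))
        for off, t in zip(range(-2, 3), taper):
            idx = center + off
            if 0 <= idx < n_bins:
                raw[idx] = peak + t
        counts = np.clip(np.round(255.0 * np.power(10.0, raw / 20.0)),
                         0, 255).astype(np.int64)
        records.append(PingRecord(
            survey_id=survey_id,
            ping_index=p,
            time_utc_ms=1_430_000_000_000 + p * period_ms,
            latitude=_ORIGIN_LAT,
            longitude=_ORIGIN_LON + p * cell_along_m / mper_deg_lon,
            min_range_m=0.0,
            max_range_m=max_range_m,
            samples=counts,
        ))
        annotations[p] = float(depth)
    return records, annotations


@dataclass
class TruePredatorModel:
    """Generating model for predator counts: NB log-link on true RAPP."""

    intercept: float
    smooth_effect: "callable"
    region_effects: dict
    nb_dispersion: float  # NB size parameter theta; var = mu + mu^2/theta
    driver: str = "prop_track"  # which RAPP metric drives the counts

    def __post_init__(self):
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def mean(self, rapp_value, region, distance_km):
        eta = (self.intercept + self.smooth_effect(rapp_value)
               + self.region_effects.get(region, 0.0)
               + math.log(distance_km))
        return math.exp(eta)


def default_dolphin_model(regions=STUDY_REGIONS):
    """Dolphin counts driven by Prop.Track, saturating positive effect."""
    effects = dict(zip(regions, (0.4, 0.9, -0.4, 0.5, -1.2, -0.2)))
    return TruePredatorModel(
        intercept=math.log(0.55),
        smooth_effect=lambda x: 2.8 * x / (x + 0.18),
        region_effects=effects,
        nb_dispersion=1.5,
        driver="prop_track",
    )


def default_penguin_model(regions=STUDY_REGIONS):
    """Penguin counts driven by c.SchA, effect plateauing ~700 m^2/km."""
    effects = dict(zip(regions, (1.0, -0.1, -0.1, -1.2, -2.2, -0.3)))
    return TruePredatorModel(
        intercept=math.log(0.12),
        smooth_effect=lambda a: 2.2 * math.tanh(a / 450.0),
        region_effects=effects,
        nb_dispersion=2.0,
        driver="c_scha",
    )


def _draw_rapp(rng, season):
    """Right-skewed RAPP draw; summer surveys are prey-richer.

    The two metrics share a common prey-abundance component but keep
    independent variation (tall sparse schools vs long thin layers give
    the same track coverage very different areas), so their empirical
    correlation is moderate rather than collinear.
    """
    scale = 0.055 if season == "summer" else 0.020
    shared = rng.gamma(0.75, scale)
    pt = float(min(shared + rng.gamma(0.75, scale), 0.95))
    area_component = shared + rng.gamma(0.75, scale)
    c_scha = float(min(area_component, 0.95) * 2400.0
                   * np.exp(rng.normal(0.0, 0.25)))
    return pt, c_scha


def simulate_surveys(n_surveys=136, regions=STUDY_REGIONS, models=None,
                     seed=DEFAULT_SEED, allocation=None):
    """Simulate a predator-count survey table with known generating truth.

    Each survey draws true RAPP from a right-skewed (gamma) law, sets
    the NB mean ``mu = exp(b0 + f(RAPP) + b_region + log(distance))``
    per predator model and draws the count.  With the default 136
    surveys over 6 regions the layout follows the study's allocation of
    surveys among regions and seasons.
    """
    regions = tuple(regions)
    if n_surveys < len(regions):
        raise ValueError("need at least one survey per region")
    if models is None:
        models = {"dolphin": default_dolphin_model(regions),
                  "penguin": default_penguin_model(regions)}
    for m in models.values():
        if m.nb_dispersion <= 0:
            raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)

    if allocation is None:
        if n_surveys == 136 and regions == STUDY_REGIONS:
            allocation = STUDY_SURVEY_ALLOCATION
        else:
            base = n_surveys // len(regions)
            extra = n_surveys - base * len(regions)
            allocation = {}
            for i, r in enumerate(regions):
                tot = base + (1 if i < extra else 0)
                allocation[r] = (tot - tot // 2, tot // 2)

    rows = []
    idx = 0
    for region in regions:
        n_summer, n_winter = allocation[region]
        for season, n_season in (("summer", n_summer), ("winter", n_winter)):
            for _ in range(n_season):
                distance_km = float(rng.uniform(3.0, 8.0))
                pt, c_scha = _draw_rapp(rng, season)
                row = {
                    "survey_id": f"S{idx:03d}",
                    "region": region,
                    "season": season,
                    "survey_distance_km": distance_km,
                    "prop_track": pt,
                    "c_scha_m2_per_km": c_scha,
                }
                for name, model in models.items():
                    driver = pt if model.driver == "prop_track" else c_scha
                    mu = model.mean(driver, region, distance_km)
                    theta = model.nb_dispersion
                    row[f"{name}_count"] = int(rng.negative_binomial(
                        theta, theta / (theta + mu)))
                rows.append(row)
                idx += 1
    df = pd.DataFrame(rows)
    df.attrs["rng_seed"] = seed
    return df
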