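"""Synthetic OFOS survey generator with known ground truth.

Emulates a two-region (East/West) towed-camera campaign: straight east-west
transects over along-track bathymetric features (seamounts, a flat-bottomed
canyon, abyssal hills), a platform moving at jittering speed while the camera
fires at a fixed per-dive frequency, altitude jitter that drives visual
footprint variability, Poisson taxon counts from a spatially structured
intensity (regional base rate x topographic enhancement), and small textured
seafloor images degraded by vignetting, a greenish colour cast and brightness
jitter.

Everything is deterministic given ``SurveyConfig.seed``; the ground-truth
object records the intensity surfaces, planted hotspot intervals and realized
regional mean abundances so downstream stages can be tested for parameter
recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .geo import destination_east_m
from .sampling import CameraGeometry, footprint_area

EAST = "East"
WEST = "West"

_FEATURE_KINDS = ("seamount", "canyon", "hill")

# Procedural substrate texture classes (index = ground-truth label).
TEXTURE_CLASSES = ("smooth_sediment", "bioturbated", "ripples", "foram_gravel")


class ConfigurationError(ValueError):
    """Raised when a survey configuration is internally inconsistent."""


@dataclass(frozen=True)
class Feature:
    """One along-track bathymetric feature.

    kind: 'seamount' or 'hill' (positive Gaussian bump) or 'canyon'
    (flat-bottomed notch with steep smoothed walls). centre_m/width_m are
    along-track metres; height_m is the relief amplitude (positive).
    """

    kind: str
    centre_m: float
    width_m: float
    height_m: float

    def __post_init__(self):
        if self.kind not in _FEATURE_KINDS:
            raise ConfigurationError(f"unknown feature kind {self.kind!r}")
        if self.width_m <= 0 or self.height_m <= 0:
            raise ConfigurationError("feature width and height must be positive")


@dataclass(frozen=True)
class TaxonSpec:
    """Per-taxon intensity model: regional base rates (individuals/m^2) and a
    multiplicative topographic enhancement factor applied on feature relief."""

    name: str
    intensity: dict  # region -> individuals/m^2
    topo_factor: float = 4.0

    def __post_init__(self):
        if any(v < 0 for v in self.intensity.values()):
            raise ConfigurationError("taxon intensities must be >= 0")
        if self.topo_factor <= 0:
            raise ConfigurationError("topo_factor must be > 0")


@dataclass(frozen=True)
class DiveSpec:
    dive_id: str
    region: str
    length_m: float
    acquisition_hz: float
    start_lon: float
    start_lat: float
    texture_class: int = 0
    features: tuple = ()

    def __post_init__(self):
        if self.length_m <= 0:
            raise ConfigurationError("dive length must be positive")
        if self.acquisition_hz <= 0:
            raise ConfigurationError("acquisition frequency must be positive")
        if self.region not in (EAST, WEST):
            raise ConfigurationError(f"region must be {EAST!r} or {WEST!r}")


@dataclass
class SurveyConfig:
    """Full specification of a synthetic survey."""

    dives: list
    taxa: list
    speed_mps: float = 0.8
    speed_sd: float = 0.1
    altitude_m: float = 4.0
    altitude_sd: float = 0.5
    base_depth_m: dict = field(default_factory=lambda: {EAST: -2700.0, WEST: -3400.0})
    image_size_px: tuple = (128, 128)
    seed: int = 0

    def __post_init__(self):
        if self.speed_mps <= 0 or self.altitude_m <= 0:
            raise ConfigurationError("speed and altitude must be positive")
        ids = [d.dive_id for d in self.dives]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("dive ids must be unique")

    def dive(self, dive_id: str) -> DiveSpec:
        for d in self.dives:
            if d.dive_id == dive_id:
                return d
        raise ConfigurationError(f"unknown dive {dive_id!r}")

    @property
    def region_of_dive(self) -> dict:
        return {d.dive_id: d.region for d in self.dives}

    @property
    def taxon_names(self) -> list:
        return [t.name for t in self.taxa]


@dataclass
class GroundTruth:
    """Known truth of a synthetic survey.

    intensity[dive_id] is a (grid_m, n_taxa) array of individuals/m^2 sampled
    on a 1-m along-track grid; hotspot_intervals[dive_id] lists (start_m,
    end_m) stretches where topographic enhancement exceeds half its maximum;
    regional_mean_abundance is the track-length-weighted mean of the summed
    taxon intensity per region (the quantity an unbiased abundance pipeline
    should recover).
    """

    taxa: list
    grids: dict  # dive_id -> 1-m along-track grid (metres)
    intensity: dict  # dive_id -> (len(grid), n_taxa) individuals/m^2
    hotspot_intervals: dict  # dive_id -> list of (start_m, end_m)
    regional_mean_abundance: dict  # region -> individuals/m^2
    region_of_dive: dict

    def total_intensity(self, dive_id: str) -> np.ndarray:
        return self.intensity[dive_id].sum(axis=1)


# ---------------------------------------------------------------------------
# bathymetry
# ---------------------------------------------------------------------------

def _feature_relief(feature: Feature, s: np.ndarray) -> np.ndarray:
    """Signed relief (metres) contributed by one feature at positions s."""
    if feature.kind in ("seamount", "hill"):
        sigma = feature.width_m / 4.0
        return feature.height_m * np.exp(-0.5 * ((s - feature.centre_m) / sigma) ** 2)
    # canyon: flat-bottomed notch, smoothed near-vertical walls
    wall = max(feature.width_m / 50.0, 1.0)
    left = feature.centre_m - feature.width_m / 2.0
    right = feature.centre_m + feature.width_m / 2.0
    inside = 0.25 * (1.0 + np.tanh((s - left) / wall)) * (1.0 + np.tanh((right - s) / wall))
    return -feature.height_m * inside


def generate_bathymetry(config: SurveyConfig, dive_id: str, s: np.ndarray | None = None) -> np.ndarray:
    """Depth profile (metres, negative down) along a dive track.

    ``s`` defaults to a 1-m grid over the full dive length. The profile is
    the regional base depth plus the summed relief of the dive's features;
    it is deterministic (no noise), so depth extremes are exactly the
    configured feature amplitudes.
    """
    dive = config.dive(dive_id)
    if s is None:
        s = np.arange(0.0, dive.length_m + 1.0)
    s = np.asarray(s, dtype=float)
    depth = np.full_like(s, config.base_depth_m[dive.region])
    for feat in dive.features:
        depth = depth + _feature_relief(feat, s)
    return depth


def _topographic_weight(dive: DiveSpec, s: np.ndarray) -> np.ndarray:
    """Normalised (0..1) enhancement weight from the dive's features.

    Seamounts/hills enhance on their crest; canyons enhance on their walls
    (two Gaussian lobes centred on the wall positions), matching where
    suspension feeders aggregate on steep terrain.
    """
    s = np.asarray(s, dtype=float)
    w = np.zeros_like(s)
    for feat in dive.features:
        if feat.kind in ("seamount", "hill"):
            sigma = feat.width_m / 4.0
            w = np.maximum(w, np.exp(-0.5 * ((s - feat.centre_m) / sigma) ** 2))
        else:  # canyon walls
            sigma = max(feat.width_m / 4.0, 5.0)
            for edge in (feat.centre_m - feat.width_m / 2.0, feat.centre_m + feat.width_m / 2.0):
                w = np.maximum(w, np.exp(-0.5 * ((s - edge) / sigma) ** 2))
    return w


def _intervals_above(grid: np.ndarray, weight: np.ndarray, threshold: float = 0.5) -> list:
    """Contiguous [start_m, end_m] intervals where weight >= threshold."""
    mask = weight >= threshold
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(mask.astype(int)))
    starts = [0] if mask[0] else []
    starts += [int(e) + 1 for e in edges if not mask[e]]
    ends = [int(e) for e in edges if mask[e]]
    if mask[-1]:
        ends.append(len(mask) - 1)
    return [(float(grid[a]), float(grid[b])) for a, b in zip(starts, ends)]


def build_ground_truth(config: SurveyConfig) -> GroundTruth:
    """Evaluate the configured intensity surfaces on 1-m grids."""
    grids, intensity, hotspots = {}, {}, {}
    for dive in config.dives:
        s = np.arange(0.0, dive.length_m + 1.0)
        w = _topographic_weight(dive, s)
        lam = np.empty((s.size, len(config.taxa)))
        for j, taxon in enumerate(config.taxa):
            base = taxon.intensity.get(dive.region, 0.0)
            lam[:, j] = base * (1.0 + (taxon.topo_factor - 1.0) * w)
        grids[dive.dive_id] = s
        intensity[dive.dive_id] = lam
        hotspots[dive.dive_id] = _intervals_above(s, w) if dive.features else []
    regional = {}
    for region in (EAST, WEST):
        tot, length = 0.0, 0.0
        for dive in config.dives:
            if dive.region != region:
                continue
            tot += intensity[dive.dive_id].sum(axis=1).mean() * dive.length_m
            length += dive.length_m
        if length > 0:
            regional[region] = tot / length
    return GroundTruth(
        taxa=config.taxon_names,
        grids=grids,
        intensity=intensity,
        hotspot_intervals=hotspots,
        regional_mean_abundance=regional,
        region_of_dive=config.region_of_dive,
    )


# ---------------------------------------------------------------------------
# navigation
# ---------------------------------------------------------------------------

def _dive_rng(config: SurveyConfig, dive_index: int, stream: int) -> np.random.Generator:
    # independent, reproducible stream per (dive, purpose)
    return np.random.default_rng([config.seed, dive_index, stream])


def generate_navigation(config: SurveyConfig) -> pd.DataFrame:
    """Image records for every dive.

    Timestamps tick at the fixed per-dive acquisition frequency; the platform
    advances due east by speed x dt with truncated-Gaussian speed jitter;
    altitude is mean + truncated-Gaussian jitter (floored at 0.1 m so
    footprints stay positive). Depth is read off the bathymetry profile.

    Returns a DataFrame with columns image_id, dive_id, timestamp_s,
    lon_deg, lat_deg, depth_m, altitude_m.
    """
    frames = []
    for i, dive in enumerate(config.dives):
        rng = _dive_rng(config, i, 0)
        dt = 1.0 / dive.acquisition_hz
        n_max = int(np.ceil(dive.length_m / max(config.speed_mps - 3 * config.speed_sd, 0.05) / dt)) + 2
        speeds = np.clip(rng.normal(config.speed_mps, config.speed_sd, size=n_max), 0.05, None)
        steps = speeds * dt
        along = np.concatenate([[0.0], np.cumsum(steps)])
        along = along[along <= dive.length_m]
        n = along.size
        altitude = np.clip(rng.normal(config.altitude_m, config.altitude_sd, size=n), 0.1, None)
        lon = destination_east_m(dive.start_lon, dive.start_lat, along)
        depth = generate_bathymetry(config, dive.dive_id, along)
        frames.append(
            pd.DataFrame(
                {
                    "image_id": [f"{dive.dive_id}_{k:05d}" for k in range(n)],
                    "dive_id": dive.dive_id,
                    "timestamp_s": np.arange(n) * dt,
                    "lon_deg": lon,
                    "lat_deg": dive.start_lat,
                    "depth_m": depth,
                    "altitude_m": altitude,
                    "along_track_m": along,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# detections
# ---------------------------------------------------------------------------

def generate_detections(
    records: pd.DataFrame,
    truth: GroundTruth,
    seed: int,
    geometry: CameraGeometry | None = None,
    image_size_px: tuple = (128, 128),
) -> pd.DataFrame:
    """Per-image taxon detections with Poisson counts.

    For each image and taxon, count ~ Poisson(intensity(along-track position)
    x footprint_area(altitude)); each individual gets a uniform random box
    within image bounds and a confidence in [0, 1].

    Columns: image_id, taxon, x, y, w, h, confidence.
    """
    if (records["altitude_m"] <= 0).any():
        raise ValueError("all records must have positive altitude")
    geometry = geometry or CameraGeometry()
    rng = np.random.default_rng(seed)
    H, W = image_size_px
    rows = {k: [] for k in ("image_id", "taxon", "x", "y", "w", "h", "confidence")}
    for dive_id, sub in records.groupby("dive_id", sort=False):
        grid = truth.grids[dive_id]
        lam_taxa = truth.intensity[dive_id]
        pos = np.clip(sub["along_track_m"].to_numpy(), grid[0], grid[-1])
        idx = np.searchsorted(grid, pos)
        idx = np.clip(idx, 0, len(grid) - 1)
        area = footprint_area(sub["altitude_m"].to_numpy(), geometry)
        for j, taxon in enumerate(truth.taxa):
            mean = lam_taxa[idx, j] * area
            counts = rng.poisson(mean)
            for image_id, c in zip(sub["image_id"], counts):
                if c == 0:
                    continue
                bw = rng.integers(4, max(W // 4, 5), size=c)
                bh = rng.integers(4, max(H // 4, 5), size=c)
                bx = rng.integers(0, np.maximum(W - bw, 1))
                by = rng.integers(0, np.maximum(H - bh, 1))
                rows["image_id"] += [image_id] * c
                rows["taxon"] += [taxon] * c
                rows["x"] += list(bx)
                rows["y"] += list(by)
                rows["w"] += list(bw)
                rows["h"] += list(bh)
                rows["confidence"] += list(rng.uniform(0.2, 1.0, size=c))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def _value_noise(rng, shape, cells):
    """Smooth random field in [0,1] from a coarse grid upsampled by splines."""
    coarse = rng.random((cells, cells))
    zoom = (shape[0] / cells, shape[1] / cells)
    f = ndimage.zoom(coarse, zoom, order=3, mode="reflect", grid_mode=True)
    f = f[: shape[0], : shape[1]]
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo + 1e-12)


def _texture(rng, class_id: int, shape) -> np.ndarray:
    """One grey procedural substrate texture in [0,1]."""
    name = TEXTURE_CLASSES[class_id]
    if name == "smooth_sediment":
        return 0.55 + 0.15 * _value_noise(rng, shape, 4)
    if name == "bioturbated":
        base = 0.55 + 0.1 * _value_noise(rng, shape, 6)
        blobs = _value_noise(rng, shape, 12)
        return np.where(blobs < 0.35, base * 0.45, base)
    if name == "ripples":
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        angle = rng.uniform(0, np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        wavelen = rng.uniform(10, 18)
        carrier = np.sin(2 * np.pi * (xx * np.cos(angle) + yy * np.sin(angle)) / wavelen + phase)
        return 0.5 + 0.18 * carrier + 0.08 * _value_noise(rng, shape, 8)
    if name == "foram_gravel":
        speck = rng.random(shape)
        img = np.where(speck > 0.97, 1.0, 0.35 + 0.1 * _value_noise(rng, shape, 8))
        return ndimage.uniform_filter(img, size=2)
    raise ConfigurationError(f"unknown texture class {class_id}")


_CLASS_TINT = {
    "smooth_sediment": (1.0, 0.97, 0.9),
    "bioturbated": (0.98, 0.95, 0.88),
    "ripples": (0.95, 0.97, 0.95),
    "foram_gravel": (1.0, 1.0, 0.97),
}


def vignette_mask(shape, strength: float = 0.55) -> np.ndarray:
    """Radial fall-off mask in (0,1]; 1 at centre, 1-strength at the corners."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    r2 = ((yy - cy) / cy) ** 2 + ((xx - cx) / cx) ** 2
    return 1.0 - strength * r2 / 2.0


def generate_images(
    records: pd.DataFrame,
    config: SurveyConfig,
    seed: int,
    vignette: bool = True,
    cast: bool = True,
    brightness_sd: float = 0.08,
    noise_sd: float = 0.02,
    texture_override: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """RGB image stack (n, H, W, 3) in [0,1] plus ground-truth texture labels.

    Each image is a procedural substrate texture (class fixed per dive unless
    overridden) degraded, when enabled, by a multiplicative radial vignette,
    a per-image brightness factor, a greenish colour cast and Gaussian noise.
    With all degradations disabled the output is the pure texture.
    """
    H, W = config.image_size_px
    if H < 32 or W < 32:
        raise ConfigurationError("image size must be at least 32x32")
    rng = np.random.default_rng(seed)
    class_of_dive = {d.dive_id: d.texture_class for d in config.dives}
    n = len(records)
    out = np.empty((n, H, W, 3), dtype=np.float32)
    labels = np.empty(n, dtype=int)
    mask = vignette_mask((H, W)) if vignette else None
    gains = np.array([0.85, 1.15, 1.05]) if cast else np.ones(3)
    for i, (_, rec) in enumerate(records.iterrows()):
        cls = int(texture_override[i]) if texture_override is not None else class_of_dive[rec["dive_id"]]
        grey = _texture(rng, cls, (H, W))
        tint = _CLASS_TINT[TEXTURE_CLASSES[cls]]
        img = grey[:, :, None] * np.asarray(tint)[None, None, :]
        bright = np.exp(rng.normal(0.0, brightness_sd)) if brightness_sd > 0 else 1.0
        img = img * bright
        if mask is not None:
            img = img * mask[:, :, None]
        img = img * gains[None, None, :]
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        out[i] = np.clip(img, 0.0, 1.0)
        labels[i] = cls
    return out, labels


# ---------------------------------------------------------------------------
# default study configuration
# ---------------------------------------------------------------------------

# Regional taxon composition weights (fractions of the regional total).
# East is dominated by structure-formers and trace-makers; the West's sparse
# fauna is mostly Foraminifera, Echinodermata and Arthropoda.
_EAST_WEIGHTS = {
    "Foraminifera": 0.2727, "Echinodermata": 0.1136, "Lebensspuren": 0.1818,
    "Porifera": 0.1591, "Cnidaria": 0.1136, "Mollusca": 0.0909,
    "Arthropoda": 0.0227, "Sponge-Skeleton": 0.0114, "Chordata": 0.0114,
    "Annelida": 0.0091, "Ctenophora": 0.0068, "Chaetognatha": 0.0045,
    "Other": 0.0023,
}
_WEST_WEIGHTS = {
    "Foraminifera": 0.5333, "Echinodermata": 0.2667, "Arthropoda": 0.1,
    "Lebensspuren": 0.0333, "Porifera": 0.0167, "Cnidaria": 0.0167,
    "Mollusca": 0.0067, "Sponge-Skeleton": 0.0067, "Chordata": 0.0050,
    "Annelida": 0.0050, "Ctenophora": 0.0050, "Chaetognatha": 0.0033,
    "Other": 0.0017,
}

#: Realized regional mean abundances the default survey is calibrated to
#: (individuals per square metre).
TARGET_REGIONAL_MEAN = {EAST: 0.44, WEST: 0.03}


def default_config(seed: int = 0, image_size_px: tuple = (128, 128)) -> SurveyConfig:
    """Seven-dive two-region survey mirroring a real OFOS campaign layout.

    Dives 131/144/145 form the shallower East (base depth -2700 m; canyon in
    144, seamount in 145), dives 19/32/28/78 the deeper West (-3400 m;
    seamount in 32, paired abyssal hills in 28), giving the ~700 m regional
    depth offset. Acquisition frequencies are 0.2 Hz (dive 19), 0.07 Hz
    (28, 32) and 0.1 Hz elsewhere. Track lengths are scaled to ~13.6 km total
    so the whole pipeline runs at desk scale (~1800 images, ~135 units).

    Per-taxon base intensities are calibrated so the *realized* regional mean
    abundances (topographic enhancement included) equal 0.44 (East) and 0.03
    (West) individuals/m^2, a 14.7x regional contrast.
    """
    dives = [
        DiveSpec("19", WEST, 2250.0, 0.2, -24.334, 18.001, texture_class=0),
        DiveSpec("28", WEST, 3150.0, 0.07, -22.757, 17.981, texture_class=3,
                 features=(Feature("hill", 1300.0, 600.0, 40.0), Feature("hill", 1900.0, 600.0, 40.0))),
        DiveSpec("32", WEST, 2025.0, 0.07, -23.852, 18.075, texture_class=2,
                 features=(Feature("seamount", 1000.0, 1400.0, 200.0),)),
        DiveSpec("78", WEST, 2500.0, 0.1, -22.002, 17.996, texture_class=0),
        DiveSpec("131", EAST, 1275.0, 0.1, -18.221, 18.164, texture_class=1),
        DiveSpec("144", EAST, 1550.0, 0.1, -18.353, 18.098, texture_class=1,
                 features=(Feature("canyon", 775.0, 500.0, 20.0),)),
        DiveSpec("145", EAST, 850.0, 0.1, -17.994, 18.180, texture_class=1,
                 features=(Feature("seamount", 425.0, 600.0, 200.0),)),
    ]
    taxa = [
        TaxonSpec(name, {EAST: _EAST_WEIGHTS[name], WEST: _WEST_WEIGHTS[name]})
        for name in _EAST_WEIGHTS
    ]
    config = SurveyConfig(dives=dives, taxa=taxa, image_size_px=image_size_px, seed=seed)
    # calibrate base intensities so realized regional means hit the targets
    truth = build_ground_truth(config)
    scale = {
        region: TARGET_REGIONAL_MEAN[region] / truth.regional_mean_abundance[region]
        for region in truth.regional_mean_abundance
    }
    config.taxa = [
        dataclasses.replace(
            t, intensity={region: v * scale[region] for region, v in t.intensity.items()}
        )
        for t in taxa
    ]
    return config


def hotspot_benchmark_config(seed: int = 0) -> SurveyConfig:
    """Single-dive planted-hotspot benchmark.

    One West-region dive (3.5 km, 0.1 Hz) over flat seabed except a single
    40-m abyssal hill whose enhanced interval spans ~4 sampling units —
    compact relative to the 6-neighbour LISA scale, amid ~31 background
    units. Used to measure hotspot sensitivity against the planted interval.
    """
    dive = DiveSpec(
        "bench", WEST, 3500.0, 0.1, -23.0, 18.0,
        features=(Feature("hill", 1750.0, 600.0, 40.0),),
    )
    taxa = [TaxonSpec("Megafauna", {WEST: 0.03}, topo_factor=4.0)]
    return SurveyConfig(dives=[dive], taxa=taxa, seed=seed)


def constant_intensity_config(seed: int = 0, intensity: float = 0.5,
                              altitude_sd: float = 1.0) -> SurveyConfig:
    """Flat single-dive survey with spatially constant taxon intensity.

    Altitude jitter is widened so observed area varies strongly across
    sampling units; used to demonstrate that raw counts track area while
    standardised abundances do not.
    """
    dive = DiveSpec("flat", WEST, 3000.0, 0.1, -23.0, 18.0)
    taxa = [TaxonSpec("Megafauna", {WEST: intensity}, topo_factor=1.0)]
    return SurveyConfig(dives=[dive], taxa=taxa, altitude_sd=altitude_sd, seed=seed)


# ---------------------------------------------------------------------------
# survey I/O
# ---------------------------------------------------------------------------

def generate_survey(config: SurveyConfig, with_images: bool = False):
    """Generate navigation, detections, ground truth (and optionally images)."""
    truth = build_ground_truth(config)
    records = generate_navigation(config)
    det_seed = int(np.random.default_rng([config.seed, 10_007]).integers(2**31))
    detections = generate_detections(records, truth, det_seed, image_size_px=config.image_size_px)
    if not with_images:
        return records, detections, truth
    img_seed = int(np.random.default_rng([config.seed, 20_011]).integers(2**31))
    images, labels = generate_images(records, config, img_seed)
    return records, detections, truth, images, labels


def write_survey(outdir, config: SurveyConfig, with_images: bool = False) -> dict:
    """Write a survey to disk (navigation/detections CSV, truth YAML, PNGs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = generate_survey(config, with_images=with_images)
    records, detections, truth = result[:3]
    nav = records.drop(columns=["along_track_m"])
    nav.to_csv(outdir / "navigation.csv", index=False)
    detections.to_csv(outdir / "detections.csv", index=False)
    truth_doc = {
        "region_of_dive": truth.region_of_dive,
        "regional_mean_abundance": {k: float(v) for k, v in truth.regional_mean_abundance.items()},
        "hotspot_intervals": {
            k: [[float(a), float(b)] for a, b in v] for k, v in truth.hotspot_intervals.items()
        },
        "taxa": truth.taxa,
    }
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth_doc, fh, sort_keys=False)
    paths = {
        "navigation": outdir / "navigation.csv",
        "detections": outdir / "detections.csv",
        "truth": outdir / "truth.yaml",
    }
    if with_images:
        images, labels = result[3], result[4]
        img_dir = outdir / "images"
        img_dir.mkdir(exist_ok=True)
        for i, image_id in enumerate(records["image_id"]):
            iio.imwrite(img_dir / f"{image_id}.png", (images[i] * 255).astype(np.uint8))
        pd.DataFrame({"image_id": records["image_id"], "texture_class": labels}).to_csv(
            outdir / "texture_truth.csv", index=False
        )
        paths["images"] = img_dir
    return paths
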