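"""End-to-end orchestration of the survey analysis stages.

``run`` executes enhance -> cluster -> standardise -> hotspots -> community
in order on CSV/PNG inputs, writing every artefact plus a manifest (inputs,
parameters, seed, package versions) so a rerun with the same config and seed
reproduces identical outputs. ``validate_inputs`` screens the input tables
and returns a machine-readable issue list instead of raising.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__, community, enhancement, habitats, sampling, spatial

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    navigation_csv: str
    detections_csv: str
    images_dir: str | None = None
    covariates_csv: str | None = None
    out_dir: str = "benthoscan_out"
    # stage toggles
    do_enhance: bool = True
    do_cluster: bool = True
    do_standardise: bool = True
    do_hotspots: bool = True
    do_community: bool = True
    # stage parameters (defaults follow the standard survey protocol)
    batch_size: int = 32
    k_range: tuple = (2, 20)
    unit_length_m: float = 100.0
    k_neighbours: int = 6
    n_bins: int = 8
    n_perm: int = 999
    alpha: float = 0.05
    horizontal_angle: float = 48.0
    vertical_angle: float = 33.0
    region_map: dict | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in doc:
            doc["k_range"] = tuple(doc["k_range"])
        return cls(**doc)


def validate_inputs(navigation_csv, detections_csv, images_dir=None) -> list:
    """Screen the input tables; returns a list of issue dicts (empty = clean)."""
    issues = []

    def issue(kind, **detail):
        issues.append({"kind": kind, **detail})

    try:
        nav = pd.read_csv(navigation_csv)
    except Exception as exc:  # noqa: BLE001
        return [{"kind": "navigation-unreadable", "error": str(exc)}]
    for col in sampling.NAVIGATION_COLUMNS:
        if col not in nav.columns:
            issue("navigation-missing-column", column=col)
    if issues:
        return issues
    bad_alt = nav[nav["altitude_m"] <= 0]
    for _, row in bad_alt.iterrows():
        issue("non-positive-altitude", image_id=row["image_id"], altitude_m=float(row["altitude_m"]))
    for dive_id, sub in nav.groupby("dive_id", sort=False):
        ts = sub["timestamp_s"].to_numpy()
        if len(ts) > 1 and (np.diff(ts) <= 0).any():
            k = int(np.flatnonzero(np.diff(ts) <= 0)[0]) + 1
            issue("non-monotone-timestamp", dive_id=str(dive_id), image_id=sub["image_id"].iloc[k])
    try:
        det = pd.read_csv(detections_csv)
    except Exception as exc:  # noqa: BLE001
        issue("detections-unreadable", error=str(exc))
        return issues
    for col in sampling.DETECTION_COLUMNS:
        if col not in det.columns:
            issue("detections-missing-column", column=col)
    if not issues:
        unknown = sorted(set(det["image_id"]) - set(nav["image_id"]))
        for image_id in unknown:
            issue("detection-unknown-image", image_id=image_id)
    if images_dir is not None:
        img_dir = Path(images_dir)
        if not img_dir.is_dir():
            issue("images-dir-missing", path=str(img_dir))
        else:
            missing = [i for i in nav["image_id"] if not (img_dir / f"{i}.png").exists()]
            for image_id in missing:
                issue("image-file-missing", image_id=image_id)
    return issues


def _load_images(images_dir, image_ids) -> list:
    imgs = []
    for image_id in image_ids:
        arr = iio.imread(Path(images_dir) / f"{image_id}.png")
        imgs.append(arr.astype(float) / 255.0)
    return imgs


def run(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "benthoscan",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "stages": {},
        "artefacts": {},
    }
    geometry = sampling.CameraGeometry(config.horizontal_angle, config.vertical_angle)

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    try:
        nav = pd.read_csv(config.navigation_csv)
        detections = pd.read_csv(config.detections_csv)
    except Exception as exc:
        raise RuntimeError(f"stage load: cannot read inputs: {exc}") from exc

    nav = nav.sort_values(["dive_id", "timestamp_s"], kind="stable").reset_index(drop=True)
    records = sampling.along_track_positions(nav)

    images = None
    if config.images_dir and (config.do_enhance or config.do_cluster):
        t0 = stage("load-images")
        images = _load_images(config.images_dir, records["image_id"])
        manifest["stages"]["load_images"] = {"seconds": time.perf_counter() - t0, "n": len(images)}

    if config.do_enhance and images is not None:
        t0 = stage("enhance")
        enh_config = enhancement.EnhancementConfig(batch_size=config.batch_size)
        try:
            images = enhancement.enhance_collection(records, images, enh_config)
        except Exception as exc:
            raise RuntimeError(f"stage enhance failed: {exc}") from exc
        enh_dir = out / "enhanced"
        enh_dir.mkdir(exist_ok=True)
        for image_id, img in zip(records["image_id"], images):
            iio.imwrite(enh_dir / f"{image_id}.png", (np.clip(img, 0, 1) * 255).astype(np.uint8))
        manifest["stages"]["enhance"] = {"seconds": time.perf_counter() - t0}
        manifest["artefacts"]["enhanced_images"] = str(enh_dir)

    if config.do_cluster and images is not None:
        t0 = stage("cluster")
        feats = habitats.extract_collection(records["image_id"], images)
        k, curve = habitats.select_k(feats, range(config.k_range[0], config.k_range[1] + 1), seed=config.seed)
        model = habitats.cluster(feats, k, seed=config.seed)
        proj = habitats.project_pca(feats)
        pd.DataFrame({"image_id": feats.image_ids, "cluster_id": model.labels}).to_csv(
            out / "clusters.csv", index=False)
        pd.DataFrame(curve, columns=["k", "silhouette", "wcss"]).to_csv(
            out / "cluster_selection_curve.csv", index=False)
        proj.rename_axis("image_id").to_csv(out / "feature_projection.csv")
        manifest["stages"]["cluster"] = {"seconds": time.perf_counter() - t0, "k": int(k)}
        manifest["artefacts"]["clusters"] = str(out / "clusters.csv")

    matrix = None
    if config.do_standardise or config.do_hotspots or config.do_community:
        t0 = stage("standardise")
        try:
            units, records = sampling.partition_units(records, config.unit_length_m)
            matrix = sampling.pool_and_standardise(units, records, detections, geometry,
                                                   region_map=config.region_map)
        except Exception as exc:
            raise RuntimeError(f"stage standardise failed: {exc}") from exc
        matrix.units.to_csv(out / "units.csv")
        matrix.abundance.to_csv(out / "abundance_matrix.csv")
        matrix.counts.to_csv(out / "count_matrix.csv")
        sampling.check_overlap(records, geometry).to_csv(out / "overlap_check.csv", index=False)
        sampling.decorrelation_check(matrix).to_csv(out / "decorrelation.csv", index=False)
        _write_geojson(out / "units.geojson", matrix)
        manifest["stages"]["standardise"] = {"seconds": time.perf_counter() - t0,
                                             "n_units": int(len(matrix.units))}
        manifest["artefacts"]["abundance_matrix"] = str(out / "abundance_matrix.csv")

    if config.do_hotspots and matrix is not None:
        t0 = stage("hotspots")
        try:
            lisa = spatial.lisa_per_dive(matrix, k=config.k_neighbours, n_perm=config.n_perm,
                                         seed=config.seed, alpha=config.alpha)
            bins = spatial.quantile_bins(matrix.total_abundance().to_numpy(), config.n_bins)
        except Exception as exc:
            raise RuntimeError(f"stage hotspots failed: {exc}") from exc
        lisa.to_csv(out / "lisa.csv", index=False)
        pd.DataFrame({"unit_id": matrix.unit_ids, "abundance_bin": bins}).to_csv(
            out / "abundance_bins.csv", index=False)
        manifest["stages"]["hotspots"] = {"seconds": time.perf_counter() - t0,
                                          "n_hotspots": int((lisa["class"] == "hotspot").sum()) if len(lisa) else 0}
        manifest["artefacts"]["lisa"] = str(out / "lisa.csv")

    if config.do_community and matrix is not None:
        t0 = stage("community")
        try:
            transformed = community.double_root(matrix.abundance)
            dm = community.bray_curtis(transformed)
            kept = [i for i in matrix.unit_ids if str(i) in set(dm.ids)]
            groups = matrix.units.loc[kept, "region"]
            Z, _ = community.upgma(dm)
            ano = community.anosim(dm, groups, n_perm=config.n_perm, seed=config.seed)
            simper_table = community.simper(transformed.loc[kept], groups)
            ordination = community.nmds(dm, seed=config.seed)
            cov = sampling.unit_covariates(matrix).loc[kept]
            env = community.fit_vectors(ordination.coordinates, cov,
                                        n_perm=config.n_perm, seed=config.seed)
            taxa_fits = community.fit_vectors(ordination.coordinates, transformed.loc[kept],
                                              n_perm=min(config.n_perm, 199), seed=config.seed)
        except Exception as exc:
            raise RuntimeError(f"stage community failed: {exc}") from exc
        dm.to_data_frame().to_csv(out / "bray_curtis.csv")
        simper_table.to_csv(out / "simper.csv", index=False)
        ordination.coordinates.rename_axis("unit_id").to_csv(out / "ordination.csv")
        env.to_csv(out / "env_fits.csv", index=False)
        taxa_fits.to_csv(out / "taxa_fits.csv", index=False)
        shannon_by_region = {
            region: community.shannon(matrix.abundance.loc[sub.index].sum(axis=0).to_numpy())
            for region, sub in matrix.units.groupby("region")
            if matrix.abundance.loc[sub.index].to_numpy().sum() > 0
        }
        report = {
            "anosim_r": ano.r, "anosim_p": ano.p,
            "nmds_stress": ordination.stress,
            "shannon_by_region": shannon_by_region,
            "upgma_heights_monotone": bool(np.all(np.diff(Z[:, 2]) >= -1e-12)),
        }
        with open(out / "community_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        manifest["stages"]["community"] = {"seconds": time.perf_counter() - t0, **report}
        manifest["artefacts"]["community_report"] = str(out / "community_report.json")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _write_geojson(path, matrix) -> None:
    features = []
    for unit_id, row in matrix.units.iterrows():
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point",
                             "coordinates": [row["centroid_lon"], row["centroid_lat"]]},
                "properties": {
                    "unit_id": unit_id,
                    "dive_id": row["dive_id"],
                    "region": row["region"],
                    "total_abundance": float(matrix.abundance.loc[unit_id].sum()),
                    "observed_area_m2": float(row["observed_area_m2"]),
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
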