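"""End-to-end orchestration: simulate -> preprocess -> train -> predict ->
postprocess -> evaluate, with every artifact written to disk and listed in a
checksummed manifest so a run is reproducible from config + seed."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .classifiers import (
    NetworkConfig,
    predict_pixels,
    route_zone,
    train_random_forest,
    train_recurrent,
)
from .constants import CLASSES, CLASS_CODES, SOUTH_ZONE, ZONES
from .evaluation import accuracy_metrics, area_from_map, confusion_matrix
from .postprocessing import postprocess
from .preprocessing import SequenceFeaturizer, build_feature_sequence
from .synthetic import (
    generate_coarse_mask,
    generate_label_raster,
    generate_sample_set,
    make_scenario,
)
from .types import LabelRaster

__all__ = ["PipelineConfig", "run_pipeline", "default_demo_config"]

#: Province-level administrative codes used for product filenames in demos.
DEMO_ADCODES = {"a": 230000, "b": 410000, "c": 510000, "d": 620000,
                "e": 650000, SOUTH_ZONE: 450000}


@dataclass
class PipelineConfig:
    """Resolved run configuration; round-trips losslessly through YAML."""

    zones: list[str] = field(default_factory=lambda: ["a", "b"])
    year: int = 2020
    n_per_class: int = 120
    separability: float = 1.0
    seed: int = 0
    raster_size: int = 32
    patch_size_px: int = 48
    speckle_rate: float = 0.01
    correlation_threshold: float = 0.98
    cloud_threshold: float = 0.2
    network: dict = field(default_factory=dict)
    n_trees: int = 200
    filter_radius_m: float = 10.0
    min_patch_area_m2: float = 100.0
    mask_buffer_m: float = 1000.0
    export_binary: bool = True

    def __post_init__(self) -> None:
        for z in self.zones:
            if z not in ZONES and z != SOUTH_ZONE:
                raise ValueError(f"unknown zone id {z!r} in config")

    def network_config(self, seed: int) -> NetworkConfig:
        return NetworkConfig(seed=seed, **self.network)

    def to_yaml(self, path) -> Path:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return Path(path)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def default_demo_config() -> PipelineConfig:
    """A small three-zone demonstration run (minutes on one CPU)."""
    return PipelineConfig(zones=["a", "b", "c"], n_per_class=120,
                          network={"max_epochs": 40})


def _train_zone(cfg: PipelineConfig, zone: str, samples_by_zone: dict, seed: int):
    kind = route_zone(zone)
    if kind == "recurrent_net":
        return train_recurrent(samples_by_zone[zone], cfg.network_config(seed))
    if zone == SOUTH_ZONE:
        records = samples_by_zone["b"] + samples_by_zone["c"]
    else:
        records = samples_by_zone[zone]
    return train_random_forest(records, zone, n_trees=cfg.n_trees, seed=seed)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full chain for every configured zone.

    Returns the manifest: per-zone metrics and the sha256 of every written
    artifact.  Raises with the failing stage's name; the partial manifest is
    persisted next to the outputs beforehand.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "zones": {}, "artifacts": {}}
    manifest_path = out / "manifest.json"

    def persist() -> None:
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))

    def record(path: Path) -> None:
        manifest["artifacts"][str(path.relative_to(out))] = mio.file_sha256(path)

    config.to_yaml(out / "config.yaml")
    record(out / "config.yaml")
    ss = np.random.SeedSequence(config.seed)
    zone_seeds = {
        z: int(s.generate_state(1)[0] % (2**31))
        for z, s in zip(config.zones, ss.spawn(len(config.zones)))
    }

    stage = "simulate"
    try:
        base_zones = sorted(
            set(config.zones) | ({"b", "c"} if SOUTH_ZONE in config.zones else set())
        )
        samples_by_zone = {}
        for z in base_zones:
            if z == SOUTH_ZONE:
                continue
            scen = make_scenario(
                z, config.year, config.n_per_class,
                seed=zone_seeds.get(z, config.seed),
                separability=config.separability,
            )
            samples_by_zone[z] = generate_sample_set(scen)
            zdir = out / z
            zdir.mkdir(exist_ok=True)
            recs = [r for r, _ in samples_by_zone[z]]
            record(mio.write_samples_geojson(zdir / "samples.geojson", recs))
            record(mio.write_samples_csv(zdir / "samples.csv", recs))
        persist()

        for zone in config.zones:
            zdir = out / zone
            zdir.mkdir(exist_ok=True)
            seed = zone_seeds[zone]

            stage = f"train[{zone}]"
            model = _train_zone(config, zone, samples_by_zone, seed)
            bundle = mio.save_model_bundle(zdir / "model", model)
            for f in sorted(bundle.iterdir()):
                record(f)

            stage = f"evaluate[{zone}]"
            test = model.metadata.get("test_records") or []
            report: dict = {
                "zone": zone,
                "model_kind": model.model_kind,
                "test_oa": model.metadata.get("test_oa"),
            }
            if test:
                feats = SequenceFeaturizer(flatten=False)
                X = feats.transform([s for _, s in test])
                y_true = [r.class_label for r, _ in test]
                labels, _ = predict_pixels(model, X)
                cm = confusion_matrix(y_true, labels)
                acc = accuracy_metrics(cm, verbose=True)
                report["confusion_matrix"] = cm.counts.tolist()
                report["accuracy"] = {
                    "user_accuracy": acc.user_accuracy,
                    "producer_accuracy": acc.producer_accuracy,
                    "overall_accuracy": acc.overall_accuracy,
                    "kappa": acc.kappa,
                }

            stage = f"predict[{zone}]"
            sim_zone = zone if zone != SOUTH_ZONE else "c"
            scen = make_scenario(
                sim_zone, config.year, config.n_per_class,
                seed=seed + 1, separability=config.separability,
            )
            scene = generate_label_raster(
                config.raster_size, config.raster_size,
                patch_size_px=config.patch_size_px,
                seed=seed + 2,
                speckle_rate=config.speckle_rate,
                params_per_class=scen.params_per_class,
            )
            h, w = scene.labels.data.shape
            seqs = [
                build_feature_sequence(
                    scene.pixel_series(r, c), config.cloud_threshold
                )
                for r in range(h)
                for c in range(w)
            ]
            labels, _ = predict_pixels(model, seqs)
            code_map = {c: CLASS_CODES[c] for c in CLASSES}
            pred = np.array([code_map[l] for l in labels], dtype=np.uint8)
            raw_raster = LabelRaster(
                pred.reshape(h, w),
                cell_size=scene.labels.cell_size,
                origin=scene.labels.origin,
            )

            stage = f"postprocess[{zone}]"
            coarse = generate_coarse_mask(
                scene.clean_labels,
                coarse_cell_size=scene.labels.cell_size * 16,
            )
            cleaned = postprocess(
                raw_raster, coarse,
                radius_m=config.filter_radius_m,
                min_area_m2=config.min_patch_area_m2,
                buffer_m=config.mask_buffer_m,
            )
            product = cleaned
            if config.export_binary:
                binary = (cleaned.data == CLASS_CODES["maize"]).astype(np.uint8)
                product = LabelRaster(
                    binary, cell_size=cleaned.cell_size, origin=cleaned.origin,
                    crs=cleaned.crs,
                )
            name = mio.product_filename(DEMO_ADCODES[zone], config.year)
            record(mio.write_label_raster(zdir / name, product))
            record(mio.write_label_raster(zdir / "labels_truth.tif", scene.labels))

            stage = f"area[{zone}]"
            map_cm = confusion_matrix(
                [CLASSES[0] if v == CLASS_CODES["maize"] else
                 ("non_maize_crop" if v == CLASS_CODES["non_maize_crop"]
                  else "non_cropland")
                 for v in scene.clean_labels.data.ravel()],
                [CLASSES[0] if v == CLASS_CODES["maize"] else
                 ("non_maize_crop" if v == CLASS_CODES["non_maize_crop"]
                  else "non_cropland")
                 for v in cleaned.data.ravel()],
            )
            report["map_overall_accuracy"] = accuracy_metrics(
                map_cm
            ).overall_accuracy
            report["mapped_maize_km2"] = area_from_map(cleaned)
            report["true_maize_km2"] = area_from_map(scene.clean_labels)
            (zdir / "report.json").write_text(
                json.dumps(report, indent=1, sort_keys=True)
            )
            record(zdir / "report.json")
            manifest["zones"][zone] = report
            persist()
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        persist()
        raise RuntimeError(f"pipeline failed in stage {stage}: {exc}") from exc

    persist()
    return manifest
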