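"""End-to-end driver: generate -> split -> train -> evaluate.

All randomness flows from one root seed: a numpy SeedSequence spawns one
child per stage (0: split, 1: K-means) and each child is reduced to an
int below 2^31.  The forward model itself is deterministic, so reruns
with the same config and seed reproduce every artifact bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, grid, physics, rbf

logger = logging.getLogger("kerma_rbf")

DEFAULT_CONFIG = {
    "kvp_list": list(grid.REFERENCE_VOLTAGES_KV),
    "anode_angle_deg": physics.DEFAULT_ANODE_ANGLE_DEG,
    "window_thickness_mm": physics.DEFAULT_WINDOW_THICKNESS_MM,
    "window_density_kg_m3": physics.DEFAULT_WINDOW_DENSITY_KG_M3,
    "target_density_kg_m3": physics.DEFAULT_TARGET_DENSITY_KG_M3,
    "production_depth_um": physics.DEFAULT_PRODUCTION_DEPTH_UM,
    "takeoff_floor_deg": physics.DEFAULT_TAKEOFF_FLOOR_DEG,
    "radii_mm": list(grid.REFERENCE_RADII_MM),
    "theta_max_deg": grid.REFERENCE_THETA_MAX_DEG,
    "theta_step_deg": grid.REFERENCE_THETA_STEP_DEG,
    "phi_max_deg": grid.REFERENCE_PHI_MAX_DEG,
    "phi_step_deg": grid.REFERENCE_PHI_STEP_DEG,
    "train_fraction": 0.70,
    "k": 50,
    "kmeans_iters": 100,
    "kmeans_restarts": 5,
    "sigma_factor": 2.0,
}


def load_config(path=None) -> dict:
    """Reference config, optionally overridden by a YAML/JSON file."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            cfg.update(yaml.safe_load(fh) or {})
    return cfg


def stage_seeds(root_seed: int, n: int = 2) -> list[int]:
    """Per-stage seeds spawned from the root seed (each below 2^31)."""
    children = np.random.SeedSequence(root_seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def tube_config(cfg: dict, kvp: float) -> physics.TubeConfig:
    return physics.TubeConfig(
        kvp=kvp,
        anode_angle_deg=cfg["anode_angle_deg"],
        window_thickness_mm=cfg["window_thickness_mm"],
        window_density_kg_m3=cfg["window_density_kg_m3"],
        target_density_kg_m3=cfg["target_density_kg_m3"],
        production_depth_um=cfg["production_depth_um"],
        takeoff_floor_deg=cfg["takeoff_floor_deg"],
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Config snapshot, seeds, digests and timing of one pipeline run."""

    config: dict
    root_seed: int
    seeds: dict
    digests: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    timing_s: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "config": self.config,
            "root_seed": self.root_seed,
            "seeds": self.seeds,
            "digests": self.digests,
            "metrics": self.metrics,
            "timing_s": self.timing_s,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def run_reference_pipeline(
    config_path=None,
    seed: int = 0,
    outdir="run",
) -> RunManifest:
    """Reproduce the full protocol and write every artifact to ``outdir``.

    Artifacts: data.csv (the kerma dataset), split.json (train/test
    indices), model.json (the fitted network), report.json (MRE/RMSE for
    both splits), diagnostics_{train,test}.csv, manifest.json.
    """
    cfg = load_config(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    split_seed, kmeans_seed = stage_seeds(seed)
    manifest = RunManifest(config=cfg, root_seed=seed,
                           seeds={"split": split_seed, "kmeans": kmeans_seed})

    t0 = time.perf_counter()
    detector_grid = grid.build_detector_grid(
        cfg["radii_mm"], cfg["theta_max_deg"], cfg["theta_step_deg"],
        cfg["phi_max_deg"], cfg["phi_step_deg"],
    )
    dataset = grid.build_dataset(
        detector_grid, cfg["kvp_list"], tube_config(cfg, cfg["kvp_list"][0])
    )
    dataset.provenance["root_seed"] = seed
    manifest.timing_s["generate"] = round(time.perf_counter() - t0, 3)
    logger.info("generate: %d positions x %d voltages = %d samples",
                len(detector_grid), len(cfg["kvp_list"]), len(dataset))
    if np.any(dataset.y <= 0):
        raise RuntimeError("generate stage: non-positive kerma in dataset")
    dataset.to_csv(outdir / "data.csv")

    t0 = time.perf_counter()
    train_ds, test_ds = grid.split_dataset(dataset, cfg["train_fraction"], split_seed)
    with open(outdir / "split.json", "w") as fh:
        json.dump({
            "seed": split_seed,
            "train_fraction": cfg["train_fraction"],
            "n_train": len(train_ds),
            "n_test": len(test_ds),
            "train_indices": train_ds.index.tolist(),
            "test_indices": test_ds.index.tolist(),
        }, fh)
    manifest.timing_s["split"] = round(time.perf_counter() - t0, 3)
    logger.info("split: %d train / %d test", len(train_ds), len(test_ds))

    t0 = time.perf_counter()
    tcfg = rbf.TrainingConfig(
        k=cfg["k"], kmeans_iters=cfg["kmeans_iters"],
        kmeans_restarts=cfg["kmeans_restarts"],
        sigma_factor=cfg["sigma_factor"], seed=kmeans_seed,
    )
    model = rbf.train(train_ds, tcfg)
    model.to_json(outdir / "model.json")
    manifest.timing_s["train"] = round(time.perf_counter() - t0, 3)
    logger.info("train: k=%d, sigma=%.4f", model.k, float(np.mean(model.sigma)))

    t0 = time.perf_counter()
    rep_train, rep_test = evaluation.evaluate(model, train_ds, test_ds)
    with open(outdir / "report.json", "w") as fh:
        json.dump({"train": rep_train.to_dict(), "test": rep_test.to_dict()},
                  fh, indent=2)
    evaluation.diagnostics_frame(model, train_ds).to_csv(
        outdir / "diagnostics_train.csv", index=False)
    evaluation.diagnostics_frame(model, test_ds).to_csv(
        outdir / "diagnostics_test.csv", index=False)
    manifest.timing_s["evaluate"] = round(time.perf_counter() - t0, 3)
    logger.info("evaluate: train MRE %.4f%% RMSE %.4g | test MRE %.4f%% RMSE %.4g",
                rep_train.mre_percent, rep_train.rmse,
                rep_test.mre_percent, rep_test.rmse)

    manifest.metrics = {
        "n_positions": len(detector_grid),
        "n_samples": len(dataset),
        "n_feature_rows": dataset.features.shape[0],
        "n_train": len(train_ds),
        "n_test": len(test_ds),
        "train_mre_percent": rep_train.mre_percent,
        "train_rmse": rep_train.rmse,
        "test_mre_percent": rep_test.mre_percent,
        "test_rmse": rep_test.rmse,
    }
    for name in ("data.csv", "split.json", "model.json", "report.json",
                 "diagnostics_train.csv", "diagnostics_test.csv"):
        manifest.digests[name] = _sha256(outdir / name)
    manifest.to_json(outdir / "manifest.json")
    return manifest


def kerma_map(
    source,
    r_mm: float,
    kvp: float,
    theta_step_deg: float = 2.0,
    phi_step_deg: float = 15.0,
    cfg: dict | None = None,
):
    """2-D kerma map over (theta, phi) at fixed radius and voltage.

    ``source`` is either a fitted :class:`~kerma_rbf.rbf.RBFModel` or the
    string ``"forward"`` to query the physics model directly.  Returns a
    DataFrame with theta as rows and phi as columns.
    """
    import pandas as pd

    cfg = cfg or dict(DEFAULT_CONFIG)
    if r_mm <= 0:
        raise ValueError("r must be positive")
    thetas = np.arange(0.0, cfg["theta_max_deg"] + 1e-9, theta_step_deg)
    phis = np.arange(0.0, 360.0 + 1e-9, phi_step_deg)
    values = np.empty((len(thetas), len(phis)))
    if source == "forward":
        tables = physics.load_attenuation_tables()
        tube = tube_config(cfg, kvp)
        for i, t in enumerate(thetas):
            for j, p in enumerate(phis):
                values[i, j] = physics.air_kerma_at_point(
                    tube, grid.DetectorPoint(r_mm, t, p), tables)
    else:
        if not (physics.KVP_MIN <= kvp <= physics.KVP_MAX):
            raise physics.ConfigError(f"kvp {kvp} out of range")
        tt, pp = np.meshgrid(thetas, phis, indexing="ij")
        X = np.column_stack([
            np.full(tt.size, r_mm), tt.ravel(), pp.ravel(),
            np.full(tt.size, kvp),
        ])
        values = rbf.predict(source, X).reshape(len(thetas), len(phis))
    return pd.DataFrame(values, index=thetas, columns=phis)


def anode_cathode_means(kmap) -> tuple[float, float]:
    """Mean kerma on the anode side (|phi| < 90 deg) vs the cathode side."""
    phis = kmap.columns.to_numpy(dtype=float)
    anode = (phis < 90) | (phis > 270)
    cathode = (phis > 90) & (phis < 270)
    return float(kmap.loc[:, anode].to_numpy().mean()), \
        float(kmap.loc[:, cathode].to_numpy().mean())


__all__ = [
    "DEFAULT_CONFIG",
    "RunManifest",
    "anode_cathode_means",
    "kerma_map",
    "load_config",
    "run_reference_pipeline",
    "stage_seeds",
    "tube_config",
]
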