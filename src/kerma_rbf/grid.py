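"""Detector placement grid and dataset assembly.

The reference protocol samples air kerma on a spherical grid around the
focal spot: radii 25/50/75/100/125 mm, off-axis angles 0-20 deg in 2 deg
steps, azimuths 0-360 deg in 15 deg steps (both azimuth endpoints kept
as listed grid points even though they coincide physically), at tube
voltages 40/60/80/100/120/140 kV.  That yields 5 x 11 x 25 = 1375
positions and 8250 (position, voltage) samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .physics import TubeConfig, air_kerma_at_point, load_attenuation_tables

REFERENCE_RADII_MM = (25.0, 50.0, 75.0, 100.0, 125.0)
REFERENCE_THETA_MAX_DEG = 20.0
REFERENCE_THETA_STEP_DEG = 2.0
REFERENCE_PHI_MAX_DEG = 360.0
REFERENCE_PHI_STEP_DEG = 15.0
REFERENCE_VOLTAGES_KV = (40.0, 60.0, 80.0, 100.0, 120.0, 140.0)

FEATURE_COLUMNS = ["r_mm", "theta_deg", "phi_deg", "kvp"]


class DetectorPoint(NamedTuple):
    """Spherical-coordinate sample location within the beam cone."""

    r_mm: float
    theta_deg: float
    phi_deg: float


def _inclusive_range(maximum: float, step: float, name: str) -> np.ndarray:
    if step <= 0:
        raise ValueError(f"{name} step must be positive")
    n = maximum / step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"{name} step {step} does not divide range {maximum} evenly")
    return np.linspace(0.0, maximum, int(round(n)) + 1)


def build_detector_grid(
    radii_mm: Sequence[float] = REFERENCE_RADII_MM,
    theta_max_deg: float = REFERENCE_THETA_MAX_DEG,
    theta_step_deg: float = REFERENCE_THETA_STEP_DEG,
    phi_max_deg: float = REFERENCE_PHI_MAX_DEG,
    phi_step_deg: float = REFERENCE_PHI_STEP_DEG,
) -> list[DetectorPoint]:
    """Full Cartesian product of radii x off-axis angles x azimuths.

    Endpoints are inclusive on both angular axes; for the reference
    parameters this gives 1375 points.  Steps that do not divide their
    range evenly raise ValueError.
    """
    thetas = _inclusive_range(theta_max_deg, theta_step_deg, "theta") \
        if theta_max_deg > 0 else np.array([0.0])
    phis = _inclusive_range(phi_max_deg, phi_step_deg, "phi") \
        if phi_max_deg > 0 else np.array([0.0])
    return [
        DetectorPoint(float(r), float(t), float(p))
        for r in radii_mm
        for t in thetas
        for p in phis
    ]


@dataclass
class KermaDataset:
    """Feature matrix (4 rows: r, theta, phi, kVp) with kerma targets.

    Stored internally as a tidy DataFrame with one sample per row; the
    ``features`` property exposes the 4 x N orientation.  ``index`` keeps
    each sample's position in the parent dataset so train/test splits
    remain traceable.
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    index: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_COLUMNS + ["kerma"] if c not in self.table]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        if self.index is None:
            self.index = np.arange(len(self.table))
        self.index = np.asarray(self.index)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def features(self) -> np.ndarray:
        """4 x N feature matrix (rows: r_mm, theta_deg, phi_deg, kvp)."""
        return self.table[FEATURE_COLUMNS].to_numpy().T

    @property
    def X(self) -> np.ndarray:
        """N x 4 feature matrix (samples as rows)."""
        return self.table[FEATURE_COLUMNS].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.table["kerma"].to_numpy()

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write the samples as CSV plus a JSON sidecar with provenance."""
        self.table.to_csv(path, index=False, float_format="%.10g")
        if sidecar:
            side = str(path) + ".meta.json"
            with open(side, "w") as fh:
                json.dump(self.provenance, fh, indent=2, sort_keys=True)

    @classmethod
    def from_csv(cls, path) -> "KermaDataset":
        table = pd.read_csv(path)
        provenance: dict = {}
        try:
            with open(str(path) + ".meta.json") as fh:
                provenance = json.load(fh)
        except FileNotFoundError:
            pass
        return cls(table=table, provenance=provenance)


def build_dataset(
    grid: Sequence[DetectorPoint],
    voltages_kv: Sequence[float] = REFERENCE_VOLTAGES_KV,
    config: TubeConfig | None = None,
    tables=None,
) -> KermaDataset:
    """Evaluate the forward model at every (voltage, point) combination.

    Column order is deterministic: voltage-major, then grid order.  The
    reference grid and voltages give 8250 samples.  ``config`` supplies
    everything but the voltage, which is overridden per block.
    """
    if tables is None:
        tables = load_attenuation_tables()
    if config is None:
        config = TubeConfig(kvp=voltages_kv[0])
    rows = []
    for kvp in voltages_kv:
        cfg = TubeConfig(
            kvp=float(kvp),
            anode_angle_deg=config.anode_angle_deg,
            window_thickness_mm=config.window_thickness_mm,
            window_density_kg_m3=config.window_density_kg_m3,
            target_density_kg_m3=config.target_density_kg_m3,
            production_depth_um=config.production_depth_um,
            takeoff_floor_deg=config.takeoff_floor_deg,
            n_energy_bins=config.n_energy_bins,
        )
        for point in grid:
            try:
                kerma = air_kerma_at_point(cfg, point, tables)
            except Exception as exc:
                raise RuntimeError(
                    f"forward model failed at r={point.r_mm} mm, "
                    f"theta={point.theta_deg}, phi={point.phi_deg}, "
                    f"kvp={kvp}: {exc}"
                ) from exc
            rows.append((point.r_mm, point.theta_deg, point.phi_deg, kvp, kerma))
    table = pd.DataFrame(rows, columns=FEATURE_COLUMNS + ["kerma"])
    provenance = {
        "generator": "kerma_rbf analytic forward model",
        "n_positions": len(grid),
        "voltages_kv": [float(v) for v in voltages_kv],
        "tube_config": {
            "anode_angle_deg": config.anode_angle_deg,
            "window_thickness_mm": config.window_thickness_mm,
            "window_density_kg_m3": config.window_density_kg_m3,
            "target_density_kg_m3": config.target_density_kg_m3,
            "production_depth_um": config.production_depth_um,
            "takeoff_floor_deg": config.takeoff_floor_deg,
        },
    }
    return KermaDataset(table=table, provenance=provenance)


def reference_dataset(config: TubeConfig | None = None, tables=None) -> KermaDataset:
    """The full 1375-position x 6-voltage dataset (8250 samples)."""
    return build_dataset(build_detector_grid(), REFERENCE_VOLTAGES_KV, config, tables)


def split_dataset(
    dataset: KermaDataset,
    train_fraction: float = 0.70,
    seed: int = 0,
) -> tuple[KermaDataset, KermaDataset]:
    """Uniform random train/test partition without replacement.

    Train size is round-half-away-from-zero of N * fraction (exactly 5775
    of 8250 at fraction 0.70).  Partitions are disjoint, exhaustive and
    reproducible under the seed.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n = len(dataset)
    n_train = int(np.floor(n * train_fraction + 0.5))
    if n_train == 0 or n_train == n:
        raise ValueError("split leaves an empty partition")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])

    def _subset(idx: np.ndarray, tag: str) -> KermaDataset:
        prov = dict(dataset.provenance)
        prov.update({"split": tag, "split_seed": seed,
                     "train_fraction": train_fraction})
        return KermaDataset(
            table=dataset.table.iloc[idx].reset_index(drop=True),
            provenance=prov,
            index=dataset.index[idx],
        )

    return _subset(train_idx, "train"), _subset(test_idx, "test")


__all__ = [
    "DetectorPoint",
    "FEATURE_COLUMNS",
    "KermaDataset",
    "REFERENCE_RADII_MM",
    "REFERENCE_VOLTAGES_KV",
    "build_dataset",
    "build_detector_grid",
    "reference_dataset",
    "split_dataset",
]
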