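"""Analytic forward model of a diagnostic X-ray tube.

The chain is: Kramers bremsstrahlung spectrum at the tungsten target
-> self-attenuation along the exit path through the inclined anode
(the heel effect) -> filtration by the beryllium exit window ->
inverse-square propagation to a detector point -> conversion of photon
fluence to air kerma with mass energy-absorption coefficients of air.

Air kerma is reported in relative units per source electron; there is
no absolute calibration.  Air attenuation between the window and the
detector is neglected, which makes the inverse-square law exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

# Tungsten atomic number, the Z of the Kramers yield Z*(kVp - E)/E.
TUNGSTEN_Z = 74

# Reference tube defaults: 20 deg anode, 1 mm Be window (1850 kg/m^3),
# tungsten target (19290 kg/m^3).
DEFAULT_ANODE_ANGLE_DEG = 20.0
DEFAULT_WINDOW_THICKNESS_MM = 1.0
DEFAULT_WINDOW_DENSITY_KG_M3 = 1850.0
DEFAULT_TARGET_DENSITY_KG_M3 = 19290.0
DEFAULT_PRODUCTION_DEPTH_UM = 3.0
# Rays emerging at takeoff angles below this are shadowed by anode surface
# roughness and the finite focal spot, neither of which the point-source
# model resolves; the exit path is evaluated at this floor instead.
DEFAULT_TAKEOFF_FLOOR_DEG = 2.0

KVP_MIN = 20.0
KVP_MAX = 140.0
SPECTRUM_E_MIN_KEV = 10.0


class ConfigError(ValueError):
    """Invalid tube or training configuration."""


class EnergyRangeError(ValueError):
    """Energy outside the span of an attenuation table (no extrapolation)."""


class GeometryError(ValueError):
    """Degenerate beam geometry (ray grazing or inside the anode plane)."""


class OutsideBeamError(ValueError):
    """Detector point outside the conical field of view."""


# ---------------------------------------------------------------------------
# Attenuation tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttenuationTable:
    """Mass attenuation (or energy-absorption) coefficients for one material.

    Parameters
    ----------
    material : str
        Material identifier, e.g. ``"tungsten"``.
    energies : ndarray
        Tabulated photon energies in keV, strictly increasing.
    mu_over_rho : ndarray
        Coefficients in cm^2/g, all positive.
    kind : str
        ``"attenuation"`` (mu/rho) or ``"energy-absorption"`` (mu_en/rho).
    """

    material: str
    energies: np.ndarray
    mu_over_rho: np.ndarray
    kind: str = "attenuation"

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        mu = np.asarray(self.mu_over_rho, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "mu_over_rho", mu)
        if e.ndim != 1 or e.size < 2 or mu.shape != e.shape:
            raise ConfigError("table needs matching 1-D energy/coefficient arrays")
        if not np.all(np.diff(e) > 0):
            raise ConfigError(f"energies of {self.material!r} not strictly increasing")
        if not np.all(mu > 0):
            raise ConfigError(f"non-positive coefficient in {self.material!r} table")
        if self.kind not in ("attenuation", "energy-absorption"):
            raise ConfigError(f"unknown table kind {self.kind!r}")

    @property
    def e_min(self) -> float:
        return float(self.energies[0])

    @property
    def e_max(self) -> float:
        return float(self.energies[-1])


def load_attenuation_tables(path=None) -> dict[str, AttenuationTable]:
    """Load the bundled coefficient tables (or a CSV with the same columns).

    Returns a dict keyed by material name: tungsten and beryllium mu/rho,
    air mu_en/rho, spanning 10-150 keV.
    """
    if path is None:
        ref = resources.files("kerma_rbf.data").joinpath("attenuation.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    tables: dict[str, AttenuationTable] = {}
    for (material, kind), sub in df.groupby(["material", "kind"], sort=False):
        sub = sub.sort_values("energy_keV")
        tables[material] = AttenuationTable(
            material=material,
            energies=sub["energy_keV"].to_numpy(),
            mu_over_rho=sub["mu_over_rho_cm2_g"].to_numpy(),
            kind=kind,
        )
    return tables


def interpolate_mu(table: AttenuationTable, energy) -> np.ndarray | float:
    """Log-log linear interpolation of a coefficient table.

    Exact at the table knots.  Energies outside the tabulated span raise
    :class:`EnergyRangeError`; attenuation coefficients fall off so steeply
    that extrapolation would be silently wrong.
    """
    e = np.asarray(energy, dtype=float)
    if np.any(e < table.e_min) or np.any(e > table.e_max):
        raise EnergyRangeError(
            f"energy outside {table.material} table span "
            f"[{table.e_min}, {table.e_max}] keV"
        )
    out = np.exp(
        np.interp(np.log(e), np.log(table.energies), np.log(table.mu_over_rho))
    )
    return float(out) if np.isscalar(energy) else out


# ---------------------------------------------------------------------------
# Tube configuration and spectrum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TubeConfig:
    """Geometry and operating point of the modelled tube.

    ``production_depth_um`` is the effective depth below the anode surface
    at which bremsstrahlung photons are produced; it sets the strength of
    the heel effect through the exit path length.  ``takeoff_floor_deg``
    caps how grazing that exit path may become (0 disables the floor, in
    which case rays at or below the anode plane are an error).
    """

    kvp: float
    anode_angle_deg: float = DEFAULT_ANODE_ANGLE_DEG
    window_thickness_mm: float = DEFAULT_WINDOW_THICKNESS_MM
    window_density_kg_m3: float = DEFAULT_WINDOW_DENSITY_KG_M3
    target_density_kg_m3: float = DEFAULT_TARGET_DENSITY_KG_M3
    production_depth_um: float = DEFAULT_PRODUCTION_DEPTH_UM
    takeoff_floor_deg: float = DEFAULT_TAKEOFF_FLOOR_DEG
    n_energy_bins: int | None = None

    def __post_init__(self) -> None:
        if not (KVP_MIN <= self.kvp <= KVP_MAX):
            raise ConfigError(f"kvp {self.kvp} outside [{KVP_MIN}, {KVP_MAX}] kV")
        if self.anode_angle_deg <= 0:
            raise ConfigError("anode angle must be positive")
        if self.window_thickness_mm < 0:
            raise ConfigError("window thickness must be >= 0")
        if self.production_depth_um <= 0:
            raise ConfigError("production depth must be positive")
        if self.takeoff_floor_deg < 0:
            raise ConfigError("takeoff floor must be >= 0")
        if self.n_energy_bins is not None and self.n_energy_bins < 2:
            raise ConfigError("need at least 2 energy bins")

    def energy_bins(self) -> np.ndarray:
        """Bin centers in keV: 1-keV spacing from 10 keV to kVp inclusive."""
        if self.n_energy_bins is None:
            n = int(round(self.kvp - SPECTRUM_E_MIN_KEV)) + 1
        else:
            n = self.n_energy_bins
        return np.linspace(SPECTRUM_E_MIN_KEV, self.kvp, n)


@dataclass(frozen=True)
class EnergySpectrum:
    """Binned photon fluence vs energy (relative, per source electron)."""

    bin_centers: np.ndarray
    fluence: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.bin_centers, dtype=float)
        f = np.asarray(self.fluence, dtype=float)
        object.__setattr__(self, "bin_centers", e)
        object.__setattr__(self, "fluence", f)
        if e.shape != f.shape or e.ndim != 1:
            raise ConfigError("bin_centers and fluence must be matching 1-D arrays")
        if np.any(f < 0):
            raise ConfigError("negative fluence")

    def mean_energy(self) -> float:
        """Fluence-weighted mean photon energy in keV."""
        total = self.fluence.sum()
        if total == 0:
            raise ValueError("empty spectrum has no mean energy")
        return float((self.bin_centers * self.fluence).sum() / total)


def bremsstrahlung_spectrum(config: TubeConfig) -> EnergySpectrum:
    """Unfiltered Kramers-form spectrum: fluence(E) = Z (kVp - E)/E, E < kVp."""
    if config.kvp < SPECTRUM_E_MIN_KEV:
        raise ConfigError("kvp below the lowest tabulated energy")
    e = config.energy_bins()
    fluence = np.where(e < config.kvp, TUNGSTEN_Z * (config.kvp - e) / e, 0.0)
    return EnergySpectrum(bin_centers=e, fluence=fluence)


# ---------------------------------------------------------------------------
# Geometry: heel effect
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeamDirection:
    """Direction within the beam cone.

    theta_deg is the off-axis angle (0 = central axis, up to the anode
    angle).  phi_deg is the azimuth, with phi = 0 pointing toward the
    anode (target) side, where the heel effect is strongest.
    """

    theta_deg: float
    phi_deg: float

    def __post_init__(self) -> None:
        if self.theta_deg < 0:
            raise OutsideBeamError("theta must be >= 0")
        if not (0.0 <= self.phi_deg <= 360.0):
            raise ConfigError("phi must lie in [0, 360] degrees")


def takeoff_angle_deg(direction: BeamDirection, config: TubeConfig) -> float:
    """Angle between the exiting ray and the anode surface, before flooring."""
    phi = np.deg2rad(direction.phi_deg)
    return config.anode_angle_deg - direction.theta_deg * np.cos(phi)


def heel_path_length(direction: BeamDirection, config: TubeConfig) -> float:
    """Exit path length through the target, in micrometres.

    L = production_depth / sin(alpha) with takeoff angle
    alpha = anode_angle - theta cos(phi): rays tilted toward the anode
    side see a longer path, hence the heel-effect asymmetry.  alpha is
    floored at ``config.takeoff_floor_deg``; with the floor disabled,
    alpha <= 0 raises :class:`GeometryError`.
    """
    alpha = takeoff_angle_deg(direction, config)
    if alpha <= 0 and config.takeoff_floor_deg <= 0:
        raise GeometryError(
            f"ray at theta={direction.theta_deg}, phi={direction.phi_deg} "
            "grazes or enters the anode plane"
        )
    alpha = max(alpha, config.takeoff_floor_deg)
    return config.production_depth_um / np.sin(np.deg2rad(alpha))


# ---------------------------------------------------------------------------
# Filtration and kerma
# ---------------------------------------------------------------------------

def filter_spectrum(
    spectrum: EnergySpectrum,
    table: AttenuationTable,
    density_kg_m3: float,
    path_mm: float,
) -> EnergySpectrum:
    """Beer-Lambert attenuation of every bin through one material layer.

    fluence'(E) = fluence(E) exp(-(mu/rho)(E) rho path).  Density is given
    in kg/m^3 and the path in mm; both are converted to CGS to match the
    cm^2/g coefficients.
    """
    if density_kg_m3 < 0 or path_mm < 0:
        raise ValueError("density and path must be non-negative")
    if path_mm == 0 or density_kg_m3 == 0:
        return spectrum
    mu = interpolate_mu(table, spectrum.bin_centers)
    rho_g_cm3 = density_kg_m3 / 1000.0
    path_cm = path_mm / 10.0
    return EnergySpectrum(
        bin_centers=spectrum.bin_centers,
        fluence=spectrum.fluence * np.exp(-mu * rho_g_cm3 * path_cm),
    )


def emitted_spectrum(
    config: TubeConfig,
    direction: BeamDirection,
    tables: dict[str, AttenuationTable],
) -> EnergySpectrum:
    """Spectrum leaving the tube in one direction: Kramers form after
    anode self-attenuation (heel) and beryllium window filtration."""
    spec = bremsstrahlung_spectrum(config)
    heel_um = heel_path_length(direction, config)
    spec = filter_spectrum(
        spec, tables["tungsten"], config.target_density_kg_m3, heel_um / 1000.0
    )
    spec = filter_spectrum(
        spec, tables["beryllium"], config.window_density_kg_m3,
        config.window_thickness_mm,
    )
    return spec


def kerma_from_spectrum(
    spectrum: EnergySpectrum,
    air_table: AttenuationTable,
    r_mm: float,
) -> float:
    """Fluence-to-kerma sum: K = (1/r^2) sum_E fluence(E) E (mu_en/rho)_air(E)."""
    if r_mm == 0:
        raise ZeroDivisionError("detector at the source (r = 0)")
    if r_mm < 0:
        raise ValueError("r must be positive")
    mu_en = interpolate_mu(air_table, spectrum.bin_centers)
    return float((spectrum.fluence * spectrum.bin_centers * mu_en).sum() / r_mm**2)


def air_kerma_at_point(
    config: TubeConfig,
    point,
    tables: dict[str, AttenuationTable],
) -> float:
    """Air kerma at a detector point (relative units per source electron).

    K = (1/r^2) sum_E fluence(E) E (mu_en/rho)_air(E), with the fluence
    heel- and window-filtered for the point's direction.  ``point`` needs
    attributes r_mm, theta_deg, phi_deg.
    """
    r = float(point.r_mm)
    if r == 0:
        raise ZeroDivisionError("detector at the source (r = 0)")
    if r < 0:
        raise ValueError("r must be positive")
    if point.theta_deg > config.anode_angle_deg:
        raise OutsideBeamError(
            f"theta={point.theta_deg} outside the {config.anode_angle_deg} deg cone"
        )
    direction = BeamDirection(theta_deg=point.theta_deg, phi_deg=point.phi_deg)
    spec = emitted_spectrum(config, direction, tables)
    return kerma_from_spectrum(spec, tables["air"], r)


__all__ = [
    "AttenuationTable",
    "BeamDirection",
    "ConfigError",
    "EnergyRangeError",
    "EnergySpectrum",
    "GeometryError",
    "OutsideBeamError",
    "TubeConfig",
    "air_kerma_at_point",
    "bremsstrahlung_spectrum",
    "emitted_spectrum",
    "filter_spectrum",
    "heel_path_length",
    "interpolate_mu",
    "kerma_from_spectrum",
    "load_attenuation_tables",
    "takeoff_angle_deg",
]
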