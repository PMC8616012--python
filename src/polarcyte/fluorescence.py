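"""Physical model of the chlorophyll-fluorescence channel.

The chain from cell physiology to recorded voltage:

1.  Volumetric fluorescence yield (μmol photons · m⁻³ · s⁻¹):

        F' = PAR · [chl a] · a̅* · Qa*(λ_em) · φ_F

    with PAR the photosynthetically active radiation intensity
    [μmol/(m²·s)], [chl a] the chlorophyll-a concentration (mg·m⁻³), a̅* the
    chlorophyll-specific absorption coefficient (m²·mg⁻¹), Qa* the
    dimensionless reabsorption factor at the emission wavelength, and φ_F the
    emitted quantum-efficiency factor.

2.  Geometric collection: an isotropic emitter seen through a collection
    solid angle Ω delivers the fraction Ω/4π of its output to the detector
    (0.014 sr → 0.11%).

3.  Photodetection: collected power (nW) × radiant sensitivity (V/nW) gives
    the recorded voltage; any extra DAQ gain is an explicit parameter.

The module also provides the single-occupancy bound (expected particles in
the scattering volume, with the Poisson probability of a coincidence) and a
photodamage exposure check against the photosystem-II inhibition threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants

__all__ = [
    "FluorescenceParams",
    "CollectionGeometry",
    "fluorescence_yield",
    "collection_fraction",
    "detector_voltage",
    "photon_flux_to_watts",
    "occupancy",
    "interception_factor",
    "exposure_check",
    "physics_chain",
]

FOUR_PI = 4.0 * np.pi


@dataclass(frozen=True)
class FluorescenceParams:
    """Factors of the volumetric fluorescence-yield product (units above)."""

    par: float          # μmol/(m²·s)
    chla: float         # mg·m⁻³
    a_star: float       # m²·mg⁻¹
    qa_star: float      # dimensionless, ≤ 1
    phi_f: float        # dimensionless, ≤ 1

    def __post_init__(self) -> None:
        for name in ("par", "chla", "a_star", "qa_star", "phi_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.qa_star > 1 or self.phi_f > 1:
            raise ValueError("qa_star and phi_f are fractions and must be <= 1")


@dataclass(frozen=True)
class CollectionGeometry:
    """Collection solid angle, detector sensitivity and probed volume."""

    solid_angle: float = 0.014          # sr
    detector_sensitivity: float = 5.0   # V/nW
    scattering_volume: float = 0.01     # μL

    def __post_init__(self) -> None:
        if not (0.0 < self.solid_angle <= FOUR_PI):
            raise ValueError(f"solid angle must be in (0, 4π], got {self.solid_angle}")
        if self.detector_sensitivity <= 0:
            raise ValueError("detector sensitivity must be > 0")
        if self.scattering_volume <= 0:
            raise ValueError("scattering volume must be > 0")


def fluorescence_yield(p: FluorescenceParams) -> float:
    """Volumetric fluorescence yield F' [μmol/(m³·s)]: the five-factor product."""
    return p.par * p.chla * p.a_star * p.qa_star * p.phi_f


def collection_fraction(solid_angle: float) -> float:
    """Fraction of isotropic emission intercepted by a solid angle: Ω / 4π."""
    if not (0.0 < solid_angle <= FOUR_PI):
        raise ValueError(f"solid angle must be in (0, 4π] sr, got {solid_angle}")
    return solid_angle / FOUR_PI


def photon_flux_to_watts(umol_photons_per_s: float, wavelength_nm: float) -> float:
    """Convert a photon flux (μmol photons/s) to radiant power (W).

    One mole of photons at wavelength λ carries N_A·h·c/λ joules.  Isolating
    this conversion keeps the yield product unit-agnostic and lets the
    μmol→W bookkeeping be tested on its own.
    """
    if umol_photons_per_s < 0:
        raise ValueError("photon flux must be >= 0")
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be > 0")
    energy_per_mol = constants.N_A * constants.h * constants.c / (wavelength_nm * 1e-9)
    return umol_photons_per_s * 1e-6 * energy_per_mol


def detector_voltage(power_nw: float, sensitivity_v_per_nw: float = 5.0,
                     daq_gain: float = 1.0) -> float:
    """Recorded voltage for a collected power: power × sensitivity × DAQ gain.

    ``daq_gain`` covers any amplification between photodetector and recorded
    sample; it defaults to 1 and is deliberately explicit because it is a
    per-instrument property, not a physical constant.
    """
    if power_nw < 0:
        raise ValueError("optical power must be >= 0")
    return power_nw * sensitivity_v_per_nw * daq_gain


def occupancy(concentration_per_ml: float, volume_ul: float) -> tuple[float, float]:
    """Expected particle count in the scattering volume, and P(≥2).

    At concentrations ≤ 10⁵ particles/mL and a ≤0.01 μL probed volume the
    expectation is ≤ 1, so each transit pulse is attributable to a single
    particle.  The coincidence probability assumes Poisson-distributed
    occupancy: P(≥2) = 1 − e^{−λ}(1 + λ).
    """
    if concentration_per_ml <= 0 or volume_ul <= 0:
        raise ValueError("concentration and volume must both be > 0")
    lam = concentration_per_ml * volume_ul * 1e-3   # μL → mL
    p_coincidence = float(1.0 - np.exp(-lam) * (1.0 + lam))
    return lam, p_coincidence


def interception_factor(cell_diameter_um: float, spot_diameter_um: float) -> float:
    """Fraction of the focal-spot power intercepted by a cell: the ratio of
    cross-sectional areas, capped at 1."""
    if cell_diameter_um <= 0 or spot_diameter_um <= 0:
        raise ValueError("diameters must be > 0")
    return min(1.0, (cell_diameter_um / spot_diameter_um) ** 2)


def exposure_check(power_mw: float, dwell_ms: float,
                   damage_threshold_uj: float = 816.43,
                   interception: float = 1.0) -> tuple[float, bool]:
    """Energy deposited on a transiting cell, and whether it is photosafe.

    energy [μJ] = power [mW] × dwell [ms] × interception, where interception
    (≤ 1) is the geometric fraction of the focal spot the cell actually
    covers (see :func:`interception_factor`).  ``safe`` is True when the
    energy stays below the growth-inhibition threshold (default 816.43 μJ).
    """
    if power_mw < 0 or dwell_ms < 0 or damage_threshold_uj < 0:
        raise ValueError("power, dwell and threshold must be >= 0")
    if not (0.0 <= interception <= 1.0):
        raise ValueError("interception factor must be in [0, 1]")
    energy_uj = power_mw * dwell_ms * interception
    return energy_uj, energy_uj < damage_threshold_uj


def physics_chain(p: FluorescenceParams, geom: CollectionGeometry,
                  emission_wavelength_nm: float = 685.0,
                  daq_gain: float = 1.0) -> dict:
    """Full yield → collected power → voltage chain for one probed volume.

    The yield is volumetric, so the emitting photon flux is
    F' × scattering volume; the default emission wavelength is the in-vivo
    chlorophyll-a fluorescence peak (~685 nm).
    """
    f_prime = fluorescence_yield(p)                       # μmol/(m³·s)
    volume_m3 = geom.scattering_volume * 1e-9             # μL → m³
    flux_umol_s = f_prime * volume_m3                     # μmol photons/s
    total_power_w = photon_flux_to_watts(flux_umol_s, emission_wavelength_nm)
    frac = collection_fraction(geom.solid_angle)
    collected_nw = total_power_w * 1e9 * frac
    voltage = detector_voltage(collected_nw, geom.detector_sensitivity, daq_gain)
    return {
        "yield_umol_m3_s": f_prime,
        "emitted_flux_umol_s": flux_umol_s,
        "total_power_nw": total_power_w * 1e9,
        "collection_fraction": frac,
        "collected_power_nw": collected_nw,
        "voltage_v": voltage,
    }
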