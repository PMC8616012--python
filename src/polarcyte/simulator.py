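"""Synthetic single-particle experiments: particle populations with
class-specific polarization and fluorescence signatures, sparse Poisson
transits, and noisy five-channel voltage traces.

Scattering model
----------------
Per-particle scattering Mueller matrices are drawn from a *parametric*
physical family — the product of a linear diattenuator, a linear retarder and
an isotropic depolarizer, each with small per-particle jitter around
class-mean parameters.  The family is a stand-in for real 120°-backscatter
Mueller matrices: no per-class matrices are published for the particles the
instrument targets, so every preset parameter here is a constructed synthetic
value, chosen only to reproduce the *qualitative* structure of the
experiments (which classes overlap in polarization, which are separated by
fluorescence).  A Mie/T-matrix scattering layer is out of scope.

Transit model
-------------
Arrivals follow a Poisson process (the sparse-suspension, single-occupancy
regime); each transit contributes a Gaussian temporal profile whose amplitude
is lognormal per class (transit through a Gaussian focal volume at a random
impact parameter).  Overlapping arrivals are rendered additively and counted
as coincidences.  The default transit time is 0.1 ms and the default sampling
rate 200 kHz puts ≥20 samples across a transit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .polarization import linear_retarder
from .psa import AnalyzerLayout, InstrumentMatrix, theoretical_instrument_matrix
from .pulses import SCATTER_CHANNELS, TRACE_CHANNELS, TraceSet

__all__ = [
    "ParticleClass",
    "ExperimentDesign",
    "Particle",
    "scattering_mueller",
    "sample_particles",
    "render_traces",
    "simulate_features",
    "make_benchmark_suite",
    "Benchmark",
    "PRESETS",
]


def _rotated_diattenuator(d: float, theta_deg: float) -> np.ndarray:
    """Normalized partial linear diattenuator (M00 = 1, diattenuation d)."""
    t = np.deg2rad(theta_deg)
    c, s = np.cos(2 * t), np.sin(2 * t)
    r = np.sqrt(max(0.0, 1.0 - d * d))
    m0 = np.array([
        [1.0, d, 0.0, 0.0],
        [d, 1.0, 0.0, 0.0],
        [0.0, 0.0, r, 0.0],
        [0.0, 0.0, 0.0, r],
    ])
    rot = np.array([
        [1, 0, 0, 0],
        [0, c, -s, 0],
        [0, s, c, 0],
        [0, 0, 0, 1],
    ], dtype=float)
    return rot @ m0 @ rot.T


def scattering_mueller(diattenuation: float, diatten_axis_deg: float,
                       retardance_deg: float, retard_axis_deg: float,
                       depolarization: float) -> np.ndarray:
    """One matrix of the parametric scattering family.

    ``depolarization`` is the fraction of polarization *retained* (1 = none
    lost).  The product depolarizer · retarder · diattenuator of physical
    factors is itself physical: it maps the physical Stokes cone into itself
    and has M00 = 1.
    """
    if not (0.0 <= diattenuation <= 1.0):
        raise ValueError("diattenuation must be in [0, 1]")
    if not (0.0 <= depolarization <= 1.0):
        raise ValueError("depolarization retention must be in [0, 1]")
    depol = np.diag([1.0, depolarization, depolarization, depolarization])
    ret = linear_retarder(retardance_deg, retard_axis_deg)
    diat = _rotated_diattenuator(diattenuation, diatten_axis_deg)
    return depol @ ret @ diat


@dataclass(frozen=True)
class ParticleClass:
    """One particle population: scattering-family parameters (mean ± jitter),
    a fluorescence-to-scattering ratio distribution, and a pulse-amplitude
    scale.

    ``f_mean = 0`` declares a non-fluorescent class: every particle's Fm/I
    ratio is exactly zero.  Otherwise ratios are lognormal with the given
    mean and SD (ratios are positive and right-skewed in practice).
    """

    name: str
    diattenuation: float = 0.3
    diatten_axis_deg: float = 0.0
    retardance_deg: float = 30.0
    retard_axis_deg: float = 20.0
    depolarization: float = 0.9
    jitter: float = 0.05            # relative SD applied to each parameter
    f_mean: float = 0.0             # mean of the Fm/I ratio (0 = dark class)
    f_sd: float = 0.0
    amplitude_median: float = 1.0   # lognormal amplitude: median (V-equivalent)
    amplitude_sigma: float = 0.35   # lognormal shape (SD of log amplitude)

    def sample_mueller(self, rng: np.random.Generator) -> np.ndarray:
        j = self.jitter
        d = np.clip(self.diattenuation * (1 + rng.normal(0, j)), 0.0, 1.0)
        p = np.clip(self.depolarization * (1 + rng.normal(0, j)), 0.0, 1.0)
        delta = self.retardance_deg * (1 + rng.normal(0, j))
        ax_d = self.diatten_axis_deg + rng.normal(0, 2.0)
        ax_r = self.retard_axis_deg + rng.normal(0, 2.0)
        return scattering_mueller(d, ax_d, delta, ax_r, p)

    def sample_f_ratio(self, rng: np.random.Generator) -> float:
        if self.f_mean <= 0.0:
            return 0.0
        # lognormal parametrized by arithmetic mean/SD
        var = self.f_sd**2
        mu = np.log(self.f_mean**2 / np.sqrt(var + self.f_mean**2))
        sigma = np.sqrt(np.log(1.0 + var / self.f_mean**2))
        return float(rng.lognormal(mu, sigma))

    def sample_amplitude(self, rng: np.random.Generator) -> float:
        return float(rng.lognormal(np.log(self.amplitude_median), self.amplitude_sigma))


@dataclass
class ExperimentDesign:
    """One synthetic run: which populations, how often they transit, and how
    the instrument records them.

    The defaults encode the operating regime of the instrument: 45° linearly
    polarized illumination, 0.1 ms transits, and arrival rates consistent
    with sub-single-occupancy concentrations.  ``seed`` is mandatory — every
    generated dataset must be exactly reproducible.
    """

    classes: list
    seed: int
    proportions: list | None = None
    arrival_rate: float = 20.0          # events/s
    duration: float = 1.0               # s
    incident_stokes: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 1.0, 0.0]))
    noise_sd: float = 0.002             # V per channel sample
    baseline_v: float = 0.05            # detector dark/stray-light offset, V
    transit_time: float = 1e-4          # s
    sampling_rate: float = 200_000.0    # Hz

    def __post_init__(self) -> None:
        if self.proportions is None:
            self.proportions = [1.0 / len(self.classes)] * len(self.classes)
        if len(self.proportions) != len(self.classes):
            raise ValueError("one mixing proportion per class required")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("mixing proportions must sum to 1")
        if self.arrival_rate < 0:
            raise ValueError("arrival rate must be >= 0")
        if self.transit_time * self.sampling_rate < 4:
            raise ValueError("transit must span at least 4 samples")


@dataclass(frozen=True)
class Particle:
    """Ground truth for one transit."""

    label: str
    arrival_time: float     # s
    sout: np.ndarray        # scattered Stokes vector for unit amplitude
    f_ratio: float          # Fm/I
    amplitude: float        # transit-position intensity factor


def sample_particles(design: ExperimentDesign,
                     rng: np.random.Generator | None = None) -> list[Particle]:
    """Draw a Poisson-process particle stream with per-particle signatures."""
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    n = rng.poisson(design.arrival_rate * design.duration)
    times = np.sort(rng.uniform(0.0, design.duration, size=n))
    idx = rng.choice(len(design.classes), size=n, p=design.proportions)
    particles = []
    for t, i in zip(times, idx):
        cls = design.classes[i]
        m = cls.sample_mueller(rng)
        sout = m @ design.incident_stokes
        particles.append(Particle(
            label=cls.name, arrival_time=float(t), sout=sout,
            f_ratio=cls.sample_f_ratio(rng),
            amplitude=cls.sample_amplitude(rng)))
    return particles


def render_traces(particles: list[Particle], design: ExperimentDesign,
                  instrument: InstrumentMatrix | None = None,
                  rng: np.random.Generator | None = None
                  ) -> tuple[TraceSet, int]:
    """Render a particle stream into five noisy voltage traces.

    Each transit is a Gaussian temporal profile (SD = transit_time/4, so
    ±2 SD spans one transit time); channel amplitudes are the instrument
    forward model applied to the particle's scaled Stokes vector, and the
    fluorescence channel carries ratio × I × profile.  Overlaps (arrival gaps
    shorter than one transit time) are rendered additively and counted.

    Returns (traces, n_overlaps).
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed + 1)
    instrument = instrument or theoretical_instrument_matrix(AnalyzerLayout())
    n_samples = int(round(design.duration * design.sampling_rate))
    traces = {c: np.full(n_samples, design.baseline_v) for c in TRACE_CHANNELS}

    sigma = design.transit_time * design.sampling_rate / 4.0
    half = int(np.ceil(4.0 * sigma))
    offsets = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)

    for p in particles:
        center = int(round(p.arrival_time * design.sampling_rate))
        lo, hi = center - half, center + half + 1
        klo, khi = max(0, -lo), len(offsets) - max(0, hi - n_samples)
        lo, hi = max(0, lo), min(n_samples, hi)
        if lo >= hi:
            continue
        prof = kernel[klo:khi]
        volts = instrument.forward(p.amplitude * p.sout)
        for c, v in zip(SCATTER_CHANNELS, volts):
            traces[c][lo:hi] += v * prof
        traces["FL"][lo:hi] += p.f_ratio * p.amplitude * p.sout[0] * prof

    if design.noise_sd > 0:
        for c in TRACE_CHANNELS:
            traces[c] += rng.normal(0.0, design.noise_sd, size=n_samples)

    arrivals = np.array([p.arrival_time for p in particles])
    n_overlaps = int(np.sum(np.diff(np.sort(arrivals)) < design.transit_time)) if len(arrivals) > 1 else 0
    return TraceSet(sampling_rate=design.sampling_rate, channels=traces), n_overlaps


def simulate_features(design: ExperimentDesign, n_per_class: int,
                      instrument: InstrumentMatrix | None = None,
                      measurement_noise_sd: float = 0.005,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Labeled per-particle feature table, bypassing the trace renderer.

    Simulates, per particle, the four calibrated-channel integrals plus a
    fluorescence integral with additive Gaussian measurement noise, then runs
    the standard inversion (S = A⁻¹·IPSA, q/u/v/DOP, F = Fm/I).  This is the
    fast path for classification benchmarks; the trace renderer exercises the
    full detection pipeline separately.
    """
    from .calibration import stokes_from_voltages
    from .polarization import polarization_components

    rng = rng if rng is not None else np.random.default_rng(design.seed)
    instrument = instrument or theoretical_instrument_matrix(AnalyzerLayout())
    rows = []
    for cls in design.classes:
        for _ in range(n_per_class):
            m = cls.sample_mueller(rng)
            sout = m @ design.incident_stokes
            amp = cls.sample_amplitude(rng)
            ipsa = instrument.forward(amp * sout) + rng.normal(0, measurement_noise_sd, 4)
            fm = cls.sample_f_ratio(rng) * amp * sout[0] + rng.normal(0, measurement_noise_sd)
            s = stokes_from_voltages(instrument, ipsa)
            if s.I <= 0:
                continue
            feats = polarization_components(s)
            rows.append({"I": s.I, "q": feats.q, "u": feats.u, "v": feats.v,
                         "dop": feats.dop, "F": fm / s.I,
                         "physical": feats.physical, "label": cls.name})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Benchmark presets.  All parameter values are constructed synthetic choices
# (no per-class Mueller matrices or fluorescence ratios are published for
# these particles); they reproduce only the qualitative design of the three
# experiments: which classes overlap in polarization and which are separated
# by fluorescence.
# ---------------------------------------------------------------------------

_PS10 = ParticleClass("PS10", diattenuation=0.55, diatten_axis_deg=0.0,
                      retardance_deg=25.0, retard_axis_deg=15.0,
                      depolarization=0.92, jitter=0.04)
_PS10_FAMILY = [
    _PS10,
    ParticleClass("PS10-100", diattenuation=0.40, diatten_axis_deg=0.0,
                  retardance_deg=50.0, retard_axis_deg=15.0,
                  depolarization=0.60, jitter=0.05),
    ParticleClass("SiO2", diattenuation=0.22, diatten_axis_deg=12.0,
                  retardance_deg=95.0, retard_axis_deg=35.0,
                  depolarization=0.85, jitter=0.05),
    # fluorescent twin: identical optics to PS10, separated only by F
    replace(_PS10, name="PS10-F", f_mean=0.60, f_sd=0.20),
]

_PG_OPTICS = dict(diattenuation=0.38, diatten_axis_deg=20.0,
                  retardance_deg=65.0, retard_axis_deg=25.0,
                  depolarization=0.60, jitter=0.08)
_ALGAE4 = [
    # fusiform diatom analogue: strong linear signature, weakest fluorescence
    ParticleClass("P.T.", diattenuation=0.60, diatten_axis_deg=5.0,
                  retardance_deg=18.0, retard_axis_deg=10.0,
                  depolarization=0.90, jitter=0.06, f_mean=0.15, f_sd=0.05),
    ParticleClass("D.S.", diattenuation=0.18, diatten_axis_deg=40.0,
                  retardance_deg=110.0, retard_axis_deg=45.0,
                  depolarization=0.75, jitter=0.06, f_mean=0.45, f_sd=0.15),
    # the two spherical bloom-formers share one optical family (polarization
    # overlap) and differ in fluorescence; the first has the highest mean F
    # and the widest spread
    ParticleClass("P.G.", f_mean=1.30, f_sd=0.55, **_PG_OPTICS),
    ParticleClass("M.A.", f_mean=0.50, f_sd=0.18, **_PG_OPTICS),
]

_SUBMICRON = [
    ParticleClass("PS0.5", diattenuation=0.50, diatten_axis_deg=0.0,
                  retardance_deg=12.0, retard_axis_deg=10.0,
                  depolarization=0.95, jitter=0.05,
                  amplitude_median=0.15, amplitude_sigma=0.30),
    ParticleClass("S-805", diattenuation=0.30, diatten_axis_deg=15.0,
                  retardance_deg=55.0, retard_axis_deg=25.0,
                  depolarization=0.80, jitter=0.07, f_mean=0.50, f_sd=0.15,
                  amplitude_median=0.25, amplitude_sigma=0.35),
    ParticleClass("S-WH7803", diattenuation=0.35, diatten_axis_deg=35.0,
                  retardance_deg=85.0, retard_axis_deg=40.0,
                  depolarization=0.70, jitter=0.07, f_mean=0.95, f_sd=0.25,
                  amplitude_median=0.25, amplitude_sigma=0.35),
]

PRESETS = {
    "ps10-family": _PS10_FAMILY,
    "algae4": _ALGAE4,
    "submicron": _SUBMICRON,
}


@dataclass
class Benchmark:
    """One reproducible labeled dataset plus its generating parameters."""

    name: str
    design: ExperimentDesign
    features: pd.DataFrame | None = None
    traces: TraceSet | None = None
    truth: pd.DataFrame | None = None
    params: pd.DataFrame | None = None


def make_benchmark_suite(preset: str, seed: int, n_per_class: int = 500,
                         mode: str = "features") -> Benchmark:
    """Build one of the named benchmark datasets.

    mode="features": labeled feature table (fast classification benchmark).
    mode="traces":   rendered TraceSet plus per-particle ground truth (full
    detection-pipeline benchmark).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    classes = PRESETS[preset]
    design = ExperimentDesign(classes=classes, seed=seed)
    params = pd.DataFrame([vars(c) for c in classes])
    if mode == "features":
        df = simulate_features(design, n_per_class=n_per_class)
        return Benchmark(name=preset, design=design, features=df, params=params)
    if mode == "traces":
        rng = np.random.default_rng(seed)
        particles = sample_particles(design, rng)
        traces, n_overlaps = render_traces(particles, design, rng=rng)
        truth = pd.DataFrame([
            {"label": p.label, "arrival_time": p.arrival_time,
             "amplitude": p.amplitude, "f_ratio": p.f_ratio,
             "I": p.sout[0], "Q": p.sout[1], "U": p.sout[2], "V": p.sout[3]}
            for p in particles
        ])
        truth.attrs["n_overlaps"] = n_overlaps
        return Benchmark(name=preset, design=design, traces=traces,
                         truth=truth, params=params)
    raise ValueError(f"mode must be 'features' or 'traces', got {mode!r}")
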