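"""Forward model of the four-channel division-of-amplitude polarization-state
analyzer (PSA).

The analyzer splits the collected beam into four parts with two 30:70
non-polarizing beam splitters and one 50:50 splitter, and analyzes each part
with its own element chain:

======== =================================== ==========================
channel  elements (propagation order)        ideal first-row response
======== =================================== ==========================
``L``    135° quarter-wave plate, 90° pol.   ∝ [1, 0, 0, −1]  (LCP)
``0``    0° polarizer                        ∝ [1, +1, 0, 0]
``90``   90° polarizer                       ∝ [1, −1, 0, 0]
``135``  45° polarizer                       ∝ [1, 0, +1, 0]
======== =================================== ==========================

The four photodetector voltages are collected as IPSA = [IL, I0, I90, I135]ᵀ
and are linear in the incident Stokes vector: IPSA = A · S, where A is the
4×4 instrument matrix.  Row k of A is gain_k · split_k · pre_split · (first
row of the Mueller product of channel k's elements).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .polarization import linear_polarizer, quarter_wave_plate, _as_stokes_array

__all__ = ["CHANNELS", "AnalyzerLayout", "InstrumentMatrix",
           "theoretical_instrument_matrix", "simulate_channel_voltages"]

CHANNELS = ("L", "0", "90", "135")

# Splitter tree: 30:70 → (30% | 70%), then 30:70 on the 70% arm
# (→ 21% | 49%), then 50:50 on the 49% arm (→ 24.5% | 24.5%).
# This arrangement yields the most nearly equal four-way split the three
# listed splitters allow.  Which fraction feeds which channel only affects
# conditioning (the calibrated inversion absorbs it), so the assignment is
# configurable.
DEFAULT_SPLITS = {"L": 0.30, "0": 0.21, "90": 0.245, "135": 0.245}

_DEFAULT_ELEMENTS = {
    "L": (("qwp", 135.0), ("polarizer", 90.0)),
    "0": (("polarizer", 0.0),),
    "90": (("polarizer", 90.0),),
    "135": (("polarizer", 45.0),),
}


def _element_matrix(kind: str, angle_deg: float) -> np.ndarray:
    if kind == "polarizer":
        return linear_polarizer(angle_deg)
    if kind == "qwp":
        return quarter_wave_plate(angle_deg)
    raise ValueError(f"unknown optical element kind {kind!r}")


@dataclass
class AnalyzerLayout:
    """Configuration of the division-of-amplitude analyzer.

    Parameters
    ----------
    split_fractions:
        Per-channel intensity fraction delivered by the splitter tree.
    gains:
        Per-detector volts-per-intensity-unit factors (default 1).
    pre_split:
        Fraction of the collected light that reaches the PSA after the
        upstream 50:50 splitter that feeds the fluorescence arm.  Default 1.0:
        in a calibrated instrument this constant is absorbed into the fitted
        instrument matrix, so the forward model keeps it explicit but neutral.
    channel_elements:
        Ordered ``(kind, angle_deg)`` element chains per channel, in
        propagation order.
    """

    split_fractions: dict = field(default_factory=lambda: dict(DEFAULT_SPLITS))
    gains: dict = field(default_factory=lambda: {c: 1.0 for c in CHANNELS})
    pre_split: float = 1.0
    channel_elements: dict = field(default_factory=lambda: dict(_DEFAULT_ELEMENTS))

    def __post_init__(self) -> None:
        for d, what in ((self.split_fractions, "split_fractions"),
                        (self.gains, "gains"),
                        (self.channel_elements, "channel_elements")):
            if set(d) != set(CHANNELS):
                raise ValueError(
                    f"{what} must define exactly the four channels {CHANNELS}, got {sorted(d)}")
        for c, f in self.split_fractions.items():
            if not (0.0 < f <= 1.0):
                raise ValueError(f"split fraction for channel {c!r} must be in (0, 1], got {f}")
        if not (0.0 < self.pre_split <= 1.0):
            raise ValueError(f"pre_split must be in (0, 1], got {self.pre_split}")

    @classmethod
    def equal_splits(cls, **kwargs) -> "AnalyzerLayout":
        """Idealized layout with four equal 25% splits (useful for tests)."""
        return cls(split_fractions={c: 0.25 for c in CHANNELS}, **kwargs)


@dataclass(frozen=True)
class InstrumentMatrix:
    """4×4 linear map from a Stokes vector to the four channel voltages."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"instrument matrix must be 4×4, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("instrument matrix has non-finite entries")
        object.__setattr__(self, "matrix", m)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def forward(self, s) -> np.ndarray:
        """Noiseless channel voltages A·S."""
        return self.matrix @ _as_stokes_array(s)


def theoretical_instrument_matrix(layout: AnalyzerLayout | None = None) -> InstrumentMatrix:
    """Instrument matrix implied by the ideal-element analyzer layout.

    Row k is the first row of the Mueller product of channel k's element
    chain (last element leftmost), scaled by that channel's splitter fraction,
    detector gain, and the PSA pre-split factor.
    """
    layout = layout or AnalyzerLayout()
    rows = []
    for c in CHANNELS:
        m = np.eye(4)
        for kind, angle in layout.channel_elements[c]:
            m = _element_matrix(kind, angle) @ m
        scale = layout.gains[c] * layout.split_fractions[c] * layout.pre_split
        rows.append(scale * m[0])
    return InstrumentMatrix(np.vstack(rows))


def simulate_channel_voltages(a: InstrumentMatrix, s, noise_sd: float = 0.0,
                              rng: np.random.Generator | None = None) -> np.ndarray:
    """Detector voltages for one Stokes state: A·S plus per-channel Gaussian noise.

    ``noise_sd = 0`` returns the exact noiseless product.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    v = a.forward(s)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng()
        v = v + rng.normal(0.0, noise_sd, size=4)
    return v
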