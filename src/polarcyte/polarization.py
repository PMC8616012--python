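"""Stokes vectors, Mueller matrices of ideal elements, and polarization features.

Conventions
-----------
* A Stokes vector is ``[I, Q, U, V]`` where ``I`` is total intensity and
  ``Q``, ``U``, ``V`` are the residual intensities of horizontal (0°) linear,
  45° linear, and right-handed circular polarization, all in the same
  (detector-voltage-equivalent) units.
* ``V > 0`` means right-handed circular polarization.
* Element orientation angles are measured counter-clockwise from horizontal,
  given in **degrees** at every public interface (radians are used only
  internally).
* The linear-retarder matrix follows the convention in which a quarter-wave
  plate with horizontal fast axis maps 45° linear light ``[1, 0, 1, 0]`` to
  *left*-handed circular light ``[1, 0, 0, -1]``.  All circular-channel
  arithmetic in the analyzer model derives from this single choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Stokes",
    "PolarizationFeatures",
    "linear_polarizer",
    "linear_retarder",
    "quarter_wave_plate",
    "half_wave_plate",
    "apply_element",
    "apply_chain",
    "polarization_components",
    "PHYSICALITY_TOL",
]

#: Relative tolerance for the physicality test Q² + U² + V² ≤ I².
PHYSICALITY_TOL = 1e-9


@dataclass(frozen=True)
class Stokes:
    """Polarization state of a light beam.

    Inverting noisy detector voltages can legitimately produce vectors outside
    the physical cone (DOP > 1).  Such vectors are *retained* — never clipped —
    and :meth:`is_physical` reports the violation so that downstream code can
    flag the record instead of silently distorting statistics.
    """

    I: float
    Q: float
    U: float
    V: float

    def as_array(self) -> np.ndarray:
        return np.array([self.I, self.Q, self.U, self.V], dtype=float)

    @classmethod
    def from_array(cls, a) -> "Stokes":
        a = np.asarray(a, dtype=float)
        if a.shape != (4,):
            raise ValueError(f"Stokes vector must have shape (4,), got {a.shape}")
        return cls(*a)

    def is_physical(self, tol: float = PHYSICALITY_TOL) -> bool:
        """True when I ≥ 0 and Q² + U² + V² ≤ I² within tolerance."""
        if self.I < -tol:
            return False
        pol2 = self.Q**2 + self.U**2 + self.V**2
        return pol2 <= self.I**2 * (1.0 + tol) + tol

    @property
    def dop(self) -> float:
        """Degree of polarization √(q² + u² + v²); requires I > 0."""
        return polarization_components(self).dop


@dataclass(frozen=True)
class PolarizationFeatures:
    """Dimensionless polarization components q = Q/I, u = U/I, v = V/I and
    their quadrature sum dop = √(q² + u² + v²).

    ``physical`` is False when dop exceeds 1 beyond tolerance (a noisy
    inversion outside the physical cone); the values themselves are kept.
    """

    q: float
    u: float
    v: float
    dop: float
    physical: bool = True


def _rotator(theta_rad: float) -> np.ndarray:
    """Mueller rotation matrix for a frame rotation by theta (radians)."""
    c, s = np.cos(2.0 * theta_rad), np.sin(2.0 * theta_rad)
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, c, s, 0.0],
            [0.0, -s, c, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def linear_polarizer(theta_deg: float) -> np.ndarray:
    """Mueller matrix of an ideal linear polarizer.

    Parameters
    ----------
    theta_deg:
        Transmission-axis angle from horizontal, degrees.

    Returns
    -------
    4×4 array with ``M[0, 0] = 1/2`` (an ideal polarizer passes half of
    unpolarized light).  Exactly idempotent: ``M @ M == M``.
    """
    if not np.isfinite(theta_deg):
        raise ValueError("polarizer angle must be finite")
    t = np.deg2rad(theta_deg)
    c, s = np.cos(2.0 * t), np.sin(2.0 * t)
    return 0.5 * np.array(
        [
            [1.0, c, s, 0.0],
            [c, c * c, c * s, 0.0],
            [s, c * s, s * s, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )


def linear_retarder(retardance_deg: float, theta_deg: float) -> np.ndarray:
    """Mueller matrix of an ideal (lossless) linear retarder.

    ``retardance_deg = 90`` gives a quarter-wave plate, ``180`` a half-wave
    plate; ``theta_deg`` is the fast-axis angle from horizontal.  The element
    is lossless: ``M[0, 0] = 1`` and both intensity and DOP are preserved.
    """
    if not (np.isfinite(retardance_deg) and np.isfinite(theta_deg)):
        raise ValueError("retardance and angle must be finite")
    d = np.deg2rad(retardance_deg)
    cd, sd = np.cos(d), np.sin(d)
    m0 = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, cd, sd],
            [0.0, 0.0, -sd, cd],
        ]
    )
    t = np.deg2rad(theta_deg)
    return _rotator(-t) @ m0 @ _rotator(t)


def quarter_wave_plate(theta_deg: float) -> np.ndarray:
    return linear_retarder(90.0, theta_deg)


def half_wave_plate(theta_deg: float) -> np.ndarray:
    return linear_retarder(180.0, theta_deg)


def _as_stokes_array(s) -> np.ndarray:
    if isinstance(s, Stokes):
        return s.as_array()
    a = np.asarray(s, dtype=float)
    if a.shape != (4,):
        raise ValueError(f"expected a 4-component Stokes vector, got shape {a.shape}")
    return a


def apply_element(m: np.ndarray, s) -> np.ndarray:
    """Apply one Mueller matrix to a Stokes vector (matrix–vector product)."""
    m = np.asarray(m, dtype=float)
    if m.shape != (4, 4):
        raise ValueError(f"Mueller matrix must be 4×4, got {m.shape}")
    return m @ _as_stokes_array(s)


def apply_chain(elements, s) -> np.ndarray:
    """Apply a sequence of elements in propagation order.

    ``elements[0]`` is encountered first by the beam; the composite matrix is
    therefore the product with the *last* element leftmost.
    """
    out = _as_stokes_array(s)
    for m in elements:
        out = apply_element(m, out)
    return out


def polarization_components(s, tol: float = 1e-6) -> PolarizationFeatures:
    """Normalized polarization components and degree of polarization.

    q = Q/I, u = U/I, v = V/I and dop = √(q² + u² + v²).  The features are
    scale-invariant: k·S gives the same result for any k > 0.

    Raises
    ------
    ValueError
        If I ≤ 0 — the components are undefined and a silent NaN would poison
        downstream statistics; the offending vector is named in the message.
    """
    a = _as_stokes_array(s)
    i, qq, uu, vv = a
    if i <= 0:
        raise ValueError(f"polarization components undefined for I <= 0 (got S={a.tolist()})")
    q, u, v = qq / i, uu / i, vv / i
    dop = float(np.sqrt(q * q + u * u + v * v))
    return PolarizationFeatures(q=float(q), u=float(u), v=float(v), dop=dop,
                                physical=dop <= 1.0 + tol)
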