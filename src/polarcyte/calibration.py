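"""Instrument-matrix calibration and Stokes-vector recovery.

The analyzer is linear: IPSA = A · S.  Calibration probes the instrument with
a set of known incident Stokes states S_i (measured in advance with a
reference polarimeter) while recording the four channel voltages I_i, then
solves the stacked equations for A in the least-squares sense.  Measurement
then inverts the calibrated matrix: S = A⁻¹ · IPSA.

Reconstruction errors in q, u, v are reported as percentages of full scale,
where full scale is 2 (each component ranges over [−1, 1]).  Both worst-case
and RMS statistics are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .polarization import Stokes, _as_stokes_array, polarization_components
from .psa import InstrumentMatrix, simulate_channel_voltages

__all__ = [
    "CalibrationSet",
    "canonical_probes",
    "make_calibration_set",
    "calibrate_psa",
    "stokes_from_voltages",
    "calibration_error_report",
    "QUV_FULL_SCALE",
]

#: Denominator used when expressing q/u/v errors as percentages: the full
#: range of each component, max − min = 1 − (−1) = 2.
QUV_FULL_SCALE = 2.0


def canonical_probes() -> list[tuple[str, Stokes]]:
    """The six canonical fully polarized probe states.

    Horizontal, vertical, ±45° linear, and the two circular handednesses —
    a standard, well-conditioned polarimeter calibration set.
    """
    return [
        ("H", Stokes(1, 1, 0, 0)),
        ("V", Stokes(1, -1, 0, 0)),
        ("P45", Stokes(1, 0, 1, 0)),
        ("M45", Stokes(1, 0, -1, 0)),
        ("RCP", Stokes(1, 0, 0, 1)),
        ("LCP", Stokes(1, 0, 0, -1)),
    ]


@dataclass
class CalibrationSet:
    """Paired (known Stokes state, measured 4-channel voltages) records."""

    stokes: np.ndarray        # (n, 4)
    voltages: np.ndarray      # (n, 4)
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.stokes = np.atleast_2d(np.asarray(self.stokes, dtype=float))
        self.voltages = np.atleast_2d(np.asarray(self.voltages, dtype=float))
        if self.stokes.shape[1] != 4 or self.voltages.shape[1] != 4:
            raise ValueError("stokes and voltages must both have 4 columns")
        if self.stokes.shape[0] != self.voltages.shape[0]:
            raise ValueError("stokes and voltages must pair up row for row")
        if not self.labels:
            self.labels = [f"probe{i}" for i in range(len(self.stokes))]

    def __len__(self) -> int:
        return self.stokes.shape[0]

    def validate(self, rank_tol: float = 1e-9) -> None:
        """Check the ≥4-probe and rank-4 preconditions for calibration."""
        if len(self) < 4:
            raise ValueError(
                f"calibration needs at least 4 probe states, got {len(self)}")
        u, sv, vt = np.linalg.svd(self.stokes, full_matrices=False)
        if sv[-1] <= rank_tol * sv[0]:
            # name the Stokes direction the probe set fails to span
            null_dir = vt[-1]
            raise ValueError(
                "probe Stokes vectors are rank-deficient; unconstrained "
                f"Stokes direction ≈ {np.round(null_dir, 6).tolist()}")


def make_calibration_set(a_true: InstrumentMatrix,
                         probes: list[tuple[str, Stokes]] | None = None,
                         noise_sd: float = 0.0,
                         repeats: int = 1,
                         rng: np.random.Generator | None = None) -> CalibrationSet:
    """Simulate a calibration record: probe the instrument ``a_true`` with the
    given states (default: the six canonical probes), ``repeats`` times each,
    with optional additive Gaussian voltage noise."""
    probes = probes if probes is not None else canonical_probes()
    rng = rng if rng is not None else np.random.default_rng()
    ss, vs, labels = [], [], []
    for _ in range(repeats):
        for label, s in probes:
            ss.append(_as_stokes_array(s))
            vs.append(simulate_channel_voltages(a_true, s, noise_sd=noise_sd, rng=rng))
            labels.append(label)
    return CalibrationSet(np.array(ss), np.array(vs), labels)


def calibrate_psa(cal: CalibrationSet) -> tuple[InstrumentMatrix, dict]:
    """Least-squares estimate of the instrument matrix from probe records.

    Solves min_A Σᵢ ‖A·Sᵢ − Iᵢ‖² (exact when the system is exactly
    determined).

    Returns
    -------
    (InstrumentMatrix, diagnostics) where diagnostics carries the residual
    Frobenius norm and the condition number of the probe Stokes matrix.
    """
    cal.validate()
    # stokes (n,4) @ A.T = voltages (n,4)  →  lstsq per column of A.T
    at, res, rank, sv = np.linalg.lstsq(cal.stokes, cal.voltages, rcond=None)
    a = InstrumentMatrix(at.T)
    residual = float(np.linalg.norm(cal.stokes @ at - cal.voltages))
    diagnostics = {
        "residual_norm": residual,
        "probe_condition_number": float(sv[0] / sv[-1]),
        "n_probes": len(cal),
    }
    return a, diagnostics


def stokes_from_voltages(a: InstrumentMatrix, ipsa,
                         cond_cap: float = 1e8) -> Stokes:
    """Recover the scattered Stokes vector: S = A⁻¹ · IPSA.

    The result is returned unclipped; call :meth:`Stokes.is_physical` to flag
    vectors that noise has pushed outside the physical cone (DOP > 1).

    Raises
    ------
    ValueError
        If the instrument matrix is singular or its condition number exceeds
        ``cond_cap`` (an unusable analyzer).
    """
    cond = a.condition_number
    if not np.isfinite(cond) or cond > cond_cap:
        raise ValueError(
            f"instrument matrix is too ill-conditioned to invert "
            f"(condition number {cond:.3g} > cap {cond_cap:.3g})")
    ipsa = np.asarray(ipsa, dtype=float)
    if ipsa.shape != (4,):
        raise ValueError(f"IPSA must be a 4-vector, got shape {ipsa.shape}")
    return Stokes.from_array(np.linalg.solve(a.matrix, ipsa))


def calibration_error_report(a_true: InstrumentMatrix,
                             a_fit: InstrumentMatrix,
                             holdout: list[Stokes] | None = None,
                             noise_sd: float = 0.0,
                             repeats: int = 1,
                             rng: np.random.Generator | None = None) -> dict:
    """Worst-case and RMS q/u/v reconstruction error over held-out states.

    Voltages for each held-out state are simulated with the true matrix (plus
    optional noise) and reconstructed with the fitted one.  Errors are
    expressed as percentages of the full scale 2 (the [−1, 1] range of each
    component).
    """
    if holdout is None:
        holdout = [s for _, s in canonical_probes()]
    holdout = list(holdout)
    if not holdout:
        raise ValueError("holdout set must be nonempty")
    rng = rng if rng is not None else np.random.default_rng()
    errs = {"q": [], "u": [], "v": []}
    for _ in range(repeats):
        for s in holdout:
            truth = polarization_components(s)
            v = simulate_channel_voltages(a_true, s, noise_sd=noise_sd, rng=rng)
            rec = polarization_components(stokes_from_voltages(a_fit, v))
            errs["q"].append(rec.q - truth.q)
            errs["u"].append(rec.u - truth.u)
            errs["v"].append(rec.v - truth.v)
    report = {}
    for comp, e in errs.items():
        e = np.asarray(e)
        report[f"max_{comp}_percent"] = float(np.max(np.abs(e)) / QUV_FULL_SCALE * 100.0)
        report[f"rms_{comp}_percent"] = float(np.sqrt(np.mean(e**2)) / QUV_FULL_SCALE * 100.0)
    report["max_percent"] = max(report[f"max_{c}_percent"] for c in "quv")
    report["n_holdout"] = len(holdout) * repeats
    return report
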