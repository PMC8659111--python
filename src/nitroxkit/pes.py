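"""One-dimensional potential along the NO out-of-plane inversion motion.

The nitroxide nitrogen inverts between two mirror-image pyramidal minima
across a low planar barrier.  The potential along this large-amplitude
motion is represented either as a tabulated relaxed scan
(:class:`ScanCurve`) or as the two-parameter symmetric quartic double well

    V(theta) = B * ((theta / theta_eq)**2 - 1)**2

with barrier ``B`` (cm^-1) at theta = 0 and minima at theta = +/- theta_eq
(deg).  A multiplicative barrier correction rescales a curve so that its
planar barrier matches a value from a higher level of theory while leaving
the positions and energies of the minima untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import curve_fit

from .errors import InputError, NotADoubleWellError

__all__ = [
    "ScanCurve",
    "QuarticDoubleWell",
    "QuarticFit",
    "fit_quartic",
    "interpolate",
    "apply_ts_correction",
]


@dataclass(frozen=True)
class ScanCurve:
    """A tabulated 1D potential scan: coordinate in degrees (strictly
    increasing), relative energy in cm^-1 (re-zeroed to the minimum on
    construction)."""

    coord: np.ndarray
    energy: np.ndarray

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        energy = np.asarray(self.energy, dtype=float)
        if coord.ndim != 1 or coord.shape != energy.shape:
            raise InputError("coord and energy must be 1D arrays of equal length")
        if coord.size < 5:
            raise InputError("a scan needs at least 5 points")
        if not np.all(np.diff(coord) > 0):
            raise InputError("scan coordinate must be strictly increasing")
        if not (np.all(np.isfinite(coord)) and np.all(np.isfinite(energy))):
            raise InputError("scan values must be finite")
        object.__setattr__(self, "coord", coord)
        object.__setattr__(self, "energy", energy - energy.min())

    @property
    def barrier(self) -> float:
        """Interior maximum relative to the global minimum (cm^-1)."""
        return float(self.energy[1:-1].max())

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScanCurve":
        """Read ``theta_deg,energy_cm1`` CSV; '#' comment lines allowed."""
        df = pd.read_csv(path, comment="#")
        missing = {"theta_deg", "energy_cm1"} - set(df.columns)
        if missing:
            raise InputError(f"scan CSV missing columns: {sorted(missing)}")
        return cls(df["theta_deg"].to_numpy(), df["energy_cm1"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"theta_deg": self.coord, "energy_cm1": self.energy}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class QuarticDoubleWell:
    """Symmetric quartic double well V(theta) = B ((theta/theta_eq)^2 - 1)^2."""

    B: float
    theta_eq: float

    def __post_init__(self) -> None:
        if not (self.B > 0 and np.isfinite(self.B)):
            raise InputError("barrier B must be positive and finite")
        if not (self.theta_eq > 0 and np.isfinite(self.theta_eq)):
            raise InputError("theta_eq must be positive and finite")

    def __call__(self, theta: "float | np.ndarray") -> "float | np.ndarray":
        return self.evaluate(theta)

    def evaluate(self, theta: "float | np.ndarray") -> "float | np.ndarray":
        theta = np.asarray(theta, dtype=float)
        v = self.B * ((theta / self.theta_eq) ** 2 - 1.0) ** 2
        return float(v) if v.ndim == 0 else v


@dataclass(frozen=True)
class QuarticFit:
    """Least-squares quartic double-well fit with standard errors and RMS residual."""

    model: QuarticDoubleWell
    B_stderr: float
    theta_eq_stderr: float
    rms: float

    @property
    def B(self) -> float:
        return self.model.B

    @property
    def theta_eq(self) -> float:
        return self.model.theta_eq


def _check_double_well(coord: np.ndarray, energy: np.ndarray) -> None:
    # a double well has (at least) two separated local minima
    interior = energy[1:-1]
    left = energy[:-2]
    right = energy[2:]
    minima = np.where((interior <= left) & (interior <= right))[0] + 1
    # collapse plateaus of equal energy into single minima
    distinct = [minima[0]] if minima.size else []
    for i in minima[1:]:
        if i - distinct[-1] > 1 or energy[i] != energy[distinct[-1]]:
            distinct.append(i)
    if len(distinct) < 2:
        raise NotADoubleWellError("scan has no interior barrier between two wells")
    between = energy[distinct[0] : distinct[-1] + 1]
    if between.max() <= max(energy[distinct[0]], energy[distinct[-1]]):
        raise NotADoubleWellError("no interior maximum between the two wells")


def fit_quartic(scan: ScanCurve, symmetric: bool = False) -> QuarticFit:
    """Fit the two-parameter quartic double well to a scan.

    With ``symmetric=True`` a one-sided scan (theta >= 0) is mirrored before
    fitting; otherwise the scan must span both wells, and a scan without an
    interior maximum raises :class:`NotADoubleWellError`.
    """
    coord, energy = scan.coord, scan.energy
    if symmetric and coord.min() >= 0.0:
        mask = coord > 0
        coord = np.concatenate([-coord[mask][::-1], coord])
        energy = np.concatenate([energy[mask][::-1], energy])
    _check_double_well(coord, energy)

    b0 = max(float(energy[1:-1].max()), 1.0)
    t0 = max(abs(float(coord[np.argmin(energy)])), 1e-3)

    # free offset c absorbs the re-zeroing of tabulated scans, whose sampled
    # minimum need not coincide with the true well bottom
    def model(x, B, te, c):
        return B * ((x / te) ** 2 - 1.0) ** 2 + c

    popt, pcov = curve_fit(
        model, coord, energy, p0=(b0, t0, 0.0),
        bounds=([1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=10000,
    )
    resid = energy - model(coord, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    perr = np.sqrt(np.diag(pcov))
    return QuarticFit(
        model=QuarticDoubleWell(B=float(popt[0]), theta_eq=float(popt[1])),
        B_stderr=float(perr[0]),
        theta_eq_stderr=float(perr[1]),
        rms=rms,
    )


def interpolate(scan: ScanCurve) -> Callable[[np.ndarray], np.ndarray]:
    """Cubic-spline interpolant of a scan (C2 continuous through all nodes,
    not-a-knot end conditions — natural ends would force zero curvature where
    a double well is stiffest).  Evaluation outside the scan range raises
    :class:`InputError`."""
    if np.any(np.diff(scan.coord) == 0):
        raise InputError("duplicate scan coordinates")
    spline = CubicSpline(scan.coord, scan.energy, bc_type="not-a-knot")
    lo, hi = float(scan.coord[0]), float(scan.coord[-1])

    def potential(theta):
        theta = np.asarray(theta, dtype=float)
        if np.any(theta < lo) or np.any(theta > hi):
            raise InputError(
                f"evaluation outside the scan range [{lo}, {hi}] deg"
            )
        v = spline(theta)
        return float(v) if v.ndim == 0 else v

    return potential


def apply_ts_correction(curve, target_barrier: float):
    """Rescale a potential so its planar barrier equals ``target_barrier``.

    The whole curve is multiplied by ``target_barrier / barrier``: the minima
    stay at zero energy and at the same coordinate, only the well depth ratio
    to the barrier is preserved.  Works on both :class:`QuarticDoubleWell`
    (returns a new model with B replaced) and :class:`ScanCurve`.
    """
    if not (target_barrier > 0 and np.isfinite(target_barrier)):
        raise InputError("target barrier must be positive and finite")
    if isinstance(curve, QuarticDoubleWell):
        return replace(curve, B=float(target_barrier))
    if isinstance(curve, ScanCurve):
        current = curve.barrier
        if current <= 0:
            raise NotADoubleWellError("scan has no positive interior barrier")
        return ScanCurve(curve.coord, curve.energy * (target_barrier / current))
    raise InputError(f"unsupported curve type: {type(curve).__name__}")
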