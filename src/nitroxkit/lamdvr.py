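"""Sinc-DVR solver for the 1D inversion motion and thermal property averaging.

The vibrational Schrodinger equation along the out-of-plane angle theta is
solved on a uniform grid with the Colbert-Miller sinc discrete variable
representation for an unbounded coordinate: the potential is diagonal at
the grid points and the kinetic-energy matrix is known in closed form,

    T_ii  = f * pi^2 / (3 dx^2)
    T_ij  = f * 2 (-1)^(i-j) / (dx^2 (i-j)^2),     f = hbar^2 / (2 I)

with the angle in radians and the effective inertia I in amu*Angstrom^2
(f = 16.8576292 / I cm^-1).  The effective inertia of the inversion path is
system-specific and must be supplied by the caller.  Eigenstates are then
Boltzmann-populated at temperature T and used to average coordinate-
dependent properties such as aN(theta) or |theta| itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import eigh

from .constants import HBAR2_OVER_2_CM1_AMU_A2, KB_CM1_PER_K
from .errors import ConvergenceError, InputError
from .pes import QuarticDoubleWell, ScanCurve, interpolate

__all__ = [
    "DVRGridSpec",
    "DVRSolution",
    "ThermalEnsemble",
    "solve",
    "populations",
    "thermal_average",
    "vibrational_correction",
]

#: Fraction of the grid's potential range below which eigenvalues enter the
#: Boltzmann partition function; levels close to the grid ceiling are basis
#: artifacts and are excluded.
PARTITION_CEILING_FRACTION = 0.9

_MAX_REFINEMENTS = 8


@dataclass(frozen=True)
class DVRGridSpec:
    """Uniform DVR grid: number of points, coordinate range in degrees, and
    whether to refine automatically until the low eigenvalues are converged."""

    npoints: int = 201
    range: tuple[float, float] = (-90.0, 90.0)
    auto_extend: bool = False

    def __post_init__(self) -> None:
        if self.npoints < 32:
            raise InputError("DVR grid needs at least 32 points")
        if not self.range[0] < self.range[1]:
            raise InputError("grid range must satisfy theta_min < theta_max")


@dataclass(frozen=True)
class DVRSolution:
    """Eigenpairs of the 1D Hamiltonian on the DVR grid.

    ``eigenvalues`` are in cm^-1 relative to the potential minimum on the
    grid, ascending.  ``eigenvectors[:, i]`` is the i-th state's amplitude at
    the grid points; the vectors are orthonormal under the (unit-weight) DVR
    quadrature, so ``eigenvectors[:, i]**2`` is a normalized probability
    distribution over grid points.
    """

    grid: np.ndarray  # degrees
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    potential: np.ndarray  # cm^-1 on the grid, min = 0
    inertia: float  # amu * Angstrom^2


@dataclass(frozen=True)
class ThermalEnsemble:
    """Boltzmann populations at ``temperature`` (full-length vector, zeros for
    levels excluded from the partition function) and the indices retained
    above the reporting threshold."""

    temperature: float
    populations: np.ndarray
    retained: tuple[int, ...]
    threshold: float


def _as_potential(potential) -> Callable:
    if isinstance(potential, ScanCurve):
        return interpolate(potential)
    if isinstance(potential, QuarticDoubleWell):
        return potential.evaluate
    if callable(potential):
        return potential
    raise InputError("potential must be callable, a ScanCurve or a QuarticDoubleWell")


def _solve_once(vfun: Callable, inertia: float, npoints: int,
                lo: float, hi: float) -> DVRSolution:
    grid_deg = np.linspace(lo, hi, npoints)
    v = np.asarray(vfun(grid_deg), dtype=float)
    if not np.all(np.isfinite(v)):
        raise InputError("potential is not finite on the grid")
    # potentials are normalized upstream (scans re-zeroed on construction, the
    # quartic model has min 0); re-zeroing to the sampled minimum here would
    # make eigenvalues oscillate with the grid phase around the well bottom

    dx = np.radians(grid_deg[1] - grid_deg[0])
    f = HBAR2_OVER_2_CM1_AMU_A2 / inertia
    i = np.arange(npoints)
    diff = i[:, None] - i[None, :]
    with np.errstate(divide="ignore"):
        t = f * 2.0 * ((-1.0) ** diff) / (dx**2 * diff.astype(float) ** 2)
    np.fill_diagonal(t, f * np.pi**2 / (3.0 * dx**2))
    h = t + np.diag(v)
    evals, evecs = eigh(h)
    return DVRSolution(
        grid=grid_deg, eigenvalues=evals, eigenvectors=evecs,
        potential=v, inertia=float(inertia),
    )


def solve(potential, inertia: float, gridspec: DVRGridSpec = DVRGridSpec()) -> DVRSolution:
    """Diagonalize the sinc-DVR Hamiltonian for a 1D potential.

    ``potential`` maps degrees to cm^-1 and may be a callable, a
    :class:`ScanCurve` (spline-interpolated; the grid is clipped to the scan
    range) or a :class:`QuarticDoubleWell`.  With ``gridspec.auto_extend`` the
    number of grid points is doubled until the lowest ten eigenvalues move by
    less than 0.01 cm^-1 between refinements.
    """
    if not (inertia > 0 and np.isfinite(inertia)):
        raise InputError("inertia must be positive (amu*Angstrom^2)")
    vfun = _as_potential(potential)
    lo, hi = gridspec.range
    if isinstance(potential, ScanCurve):
        lo = max(lo, float(potential.coord[0]))
        hi = min(hi, float(potential.coord[-1]))
        if not lo < hi:
            raise InputError("grid range does not overlap the scan range")

    sol = _solve_once(vfun, inertia, gridspec.npoints, lo, hi)
    if not gridspec.auto_extend:
        return sol
    nlow = min(10, gridspec.npoints)
    npoints = gridspec.npoints
    for _ in range(_MAX_REFINEMENTS):
        npoints = 2 * npoints - 1
        new = _solve_once(vfun, inertia, npoints, lo, hi)
        if np.max(np.abs(new.eigenvalues[:nlow] - sol.eigenvalues[:nlow])) < 0.01:
            return new
        sol = new
    raise ConvergenceError(
        f"lowest {nlow} eigenvalues not converged after {_MAX_REFINEMENTS} refinements"
    )


def populations(sol: DVRSolution, T: float, threshold: float = 0.005) -> ThermalEnsemble:
    """Boltzmann populations p_i ~ exp(-(E_i - E_0)/kB T) at temperature T.

    The partition function runs over the computed levels lying below 90% of
    the grid's potential range (levels near the grid ceiling are excluded).
    ``retained`` lists the indices with population at or above ``threshold``
    (default 0.5%).
    """
    if not (T > 0 and np.isfinite(T)):
        raise InputError("temperature must be positive")
    if not 0 <= threshold < 1:
        raise InputError("threshold must be a fraction in [0, 1)")
    e = sol.eigenvalues
    ceiling = PARTITION_CEILING_FRACTION * float(sol.potential.max())
    include = e <= max(ceiling, e[0])  # always keep the ground state
    w = np.zeros_like(e)
    w[include] = np.exp(-(e[include] - e[0]) / (KB_CM1_PER_K * T))
    p = w / w.sum()
    retained = tuple(int(i) for i in np.where(p >= threshold)[0])
    return ThermalEnsemble(
        temperature=float(T), populations=p, retained=retained, threshold=float(threshold)
    )


def thermal_average(sol: DVRSolution, ens: ThermalEnsemble,
                    prop: "Callable | Sequence[float]") -> float:
    """Thermal expectation <P> = sum_i p_i sum_k |psi_i(theta_k)|^2 P(theta_k).

    ``prop`` is a callable of the coordinate in degrees, or an array of
    values already evaluated on the grid.
    """
    pk = np.asarray(prop(sol.grid) if callable(prop) else prop, dtype=float)
    if pk.shape != sol.grid.shape:
        raise InputError("property values must match the grid")
    per_level = (sol.eigenvectors**2).T @ pk
    return float(np.dot(ens.populations, per_level))


def vibrational_correction(sol: DVRSolution, ens: ThermalEnsemble,
                           prop: Callable, theta_eq: float) -> float:
    """Vibrational-averaging shift <P>_T - P(theta_eq) of a property.

    Negative when delocalization over the inversion path lowers the property
    relative to its bottom-of-the-well value (the usual case for aN in a
    pyramidal nitroxide).
    """
    return thermal_average(sol, ens, prop) - float(prop(theta_eq))
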