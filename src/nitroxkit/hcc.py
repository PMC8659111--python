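"""Nitrogen hyperfine coupling: the cos^2(theta) model and composite corrections.

The isotropic 14N hyperfine coupling aN of a nitroxide is controlled by the
pyramidalization of the nitrogen: bending the N-O bond out of the CNC plane
mixes nitrogen s character into the pi SOMO.  As a function of the
out-of-plane angle theta the coupling computed at a given level of theory
follows

    aN(theta) = a * cos^2(theta) + b            (MHz)

to high accuracy.  Because DFT errors on aN are dominated by the
spin-polarization term, which scales the same way, the *difference* between
a high-level (coupled-cluster, "CC") and a low-level ("B2" double-hybrid)
model evaluated on the dimethylnitroxide template transfers to any
nitroxide with the same theta.  Two composite strategies follow:

* Delta_theta — evaluate the CC-minus-B2 difference of the fitted cos^2
  curves at the target molecule's theta; no extra CC computation needed.
* Delta_TM — difference of aN computed for the template molecule at the
  target geometry with the high- and low-level methods (both numbers are
  user input here).

The final composite coupling is the low-level equilibrium value plus the
vibrational-averaging correction, one of the two high-level corrections,
and optionally a bulk-solvent shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import SPIN_DENSITY_TO_GAUSS, SPIN_DENSITY_TO_MHZ
from .errors import InputError

__all__ = [
    "CosSqModel",
    "CosSqFit",
    "CompositeAnRecord",
    "CC_MODEL",
    "B2_MODEL",
    "B3_MODEL",
    "an_of_theta",
    "fit_cos_squared",
    "delta_theta",
    "delta_tm",
    "composite_an",
    "spin_density_to_an",
    "round_half_away",
]


@dataclass(frozen=True)
class CosSqModel:
    """Parameters of aN(theta) = a cos^2(theta) + b, in MHz, with a method label."""

    a: float
    b: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise InputError("model parameters must be finite")


#: cos^2 parameters fitted on the dimethylnitroxide template with the
#: EPR(III) basis at three levels of theory (CCSD(T); B2PLYP/maug-cc-pVTZ;
#: B3LYP/SNSD).
CC_MODEL = CosSqModel(a=-71.65, b=102.35, label="CC")
B2_MODEL = CosSqModel(a=-78.78, b=108.53, label="B2")
B3_MODEL = CosSqModel(a=-78.53, b=103.47, label="B3")


@dataclass(frozen=True)
class CosSqFit:
    """OLS fit of the cos^2 model with parameter standard errors and RMS residual."""

    model: CosSqModel
    a_stderr: float
    b_stderr: float
    rms: float

    @property
    def a(self) -> float:
        return self.model.a

    @property
    def b(self) -> float:
        return self.model.b


@dataclass(frozen=True)
class CompositeAnRecord:
    """One molecule's ledger of aN contributions (all MHz; theta in degrees).

    ``aN_base`` is the low-level (B2) equilibrium coupling; ``delta_vib`` the
    300 K vibrational-averaging correction; exactly one of ``delta_TM`` /
    ``delta_theta`` enters the composite; ``delta_solv`` is an optional bulk
    solvent shift.  ``delta_CNC`` (deg) is metadata: the CNC-angle mismatch
    between the molecule and the template at the same theta.
    """

    molecule: str
    rNO: float
    theta: float
    aN_base: float
    delta_vib: float
    delta_TM: float | None = None
    delta_theta: float | None = None
    delta_solv: float | None = None
    delta_CNC: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 90.0:
            raise InputError("theta must lie in [0, 90] degrees")


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero, the convention of printed tables."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def an_of_theta(model: CosSqModel, theta: "float | np.ndarray") -> "float | np.ndarray":
    """Evaluate aN(theta) = a cos^2(theta) + b (theta in degrees; even in theta)."""
    c2 = np.cos(np.radians(theta)) ** 2
    out = model.a * c2 + model.b
    return float(out) if np.ndim(out) == 0 else out


def fit_cos_squared(samples: Sequence[tuple[float, float]], label: str = "fit") -> CosSqFit:
    """Closed-form OLS of aN against cos^2(theta).

    ``samples`` is a sequence of (theta_deg, aN_MHz) pairs; at least two
    distinct cos^2(theta) values are required, otherwise the regression is
    rank-deficient.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise InputError("need at least 2 (theta, aN) samples")
    x = np.cos(np.radians(arr[:, 0])) ** 2
    y = arr[:, 1]
    if np.ptp(x) < 1e-12:
        raise InputError("all cos^2(theta) values identical: slope unidentifiable")

    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    a = float(np.sum((x - xbar) * (y - ybar)) / sxx)
    b = float(ybar - a * xbar)
    resid = y - (a * x + b)
    rms = float(np.sqrt(np.mean(resid**2)))
    if n > 2:
        s2 = float(np.sum(resid**2) / (n - 2))
        a_se = math.sqrt(s2 / sxx)
        b_se = math.sqrt(s2 * (1.0 / n + xbar**2 / sxx))
    else:
        a_se = b_se = 0.0
    return CosSqFit(CosSqModel(a=a, b=b, label=label), a_stderr=a_se, b_stderr=b_se, rms=rms)


def delta_theta(theta: float, high: CosSqModel = CC_MODEL,
                low: CosSqModel = B2_MODEL) -> float:
    """High-minus-low cos^2-model correction at the target's theta (MHz).

    With the packaged CC and B2 parameter sets this is
    7.13 cos^2(theta) - 6.18.
    """
    c2 = math.cos(math.radians(theta)) ** 2
    return (high.a - low.a) * c2 + (high.b - low.b)


def delta_tm(aN_high_template: float, aN_low_template: float) -> float:
    """Template-molecule correction: high-level minus low-level aN of the
    template evaluated at the target geometry (both values supplied)."""
    return float(aN_high_template) - float(aN_low_template)


def composite_an(record: CompositeAnRecord, scheme: str = "theta") -> float:
    """Assemble the composite coupling for one molecule.

    ``scheme`` selects which high-level correction enters: ``"theta"`` uses
    ``record.delta_theta``, ``"tm"`` uses ``record.delta_TM``.  The result is
    aN_base + delta_vib + correction (+ delta_solv if set); rounding is left
    to the presentation layer.
    """
    if scheme == "theta":
        corr = record.delta_theta
    elif scheme == "tm":
        corr = record.delta_TM
    else:
        raise InputError(f"unknown scheme {scheme!r}: use 'theta' or 'tm'")
    if corr is None:
        raise InputError(f"record {record.molecule!r} lacks the delta for scheme {scheme!r}")
    total = record.aN_base + record.delta_vib + corr
    if record.delta_solv is not None:
        total += record.delta_solv
    return float(total)


def spin_density_to_an(rho: float, unit: str = "MHz") -> float:
    """Convert electron spin density at the 14N nucleus to a hyperfine
    coupling: rho * 323.13 for MHz, rho * 115.3 for Gauss."""
    if unit == "MHz":
        return float(rho) * SPIN_DENSITY_TO_MHZ
    if unit in ("G", "Gauss", "gauss"):
        return float(rho) * SPIN_DENSITY_TO_GAUSS
    raise InputError(f"unknown unit {unit!r}: use 'MHz' or 'Gauss'")
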