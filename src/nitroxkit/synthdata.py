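"""Synthetic inputs with known ground truth, plus the packaged data tables.

Every stage of the pipeline consumes outputs of electronic-structure
programs that this package deliberately does not run.  The generators here
build inputs whose true descriptor values, potential parameters or
selection memberships are known exactly by construction, so estimators and
descriptors can be validated without any external data:

* quartic double-well scans with optional iid Gaussian noise,
* aN(theta) samples drawn from a cos^2 model plus noise,
* cubic mode-coupling sets with a prescribed number of above-threshold
  ratios,
* nitroxide-core geometries placed so the five core descriptors equal the
  requested values exactly,
* 5/6-membered rings displaced along a single pure puckering mode.

Noise is iid Gaussian throughout: the real inputs are deterministic
quantum-chemistry numbers, so noise serves only to exercise the fitting
machinery.  The packaged fixtures transcribe the two printed data tables
(NO-stretch frequencies; the hyperfine ledger) for molecules a-p.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import InputError
from .geometry import AtomSet, NitroxideCore
from .hcc import CompositeAnRecord, CosSqModel
from .pes import QuarticDoubleWell, ScanCurve
from .vibfreq import FrequencyRecord, ModeCoupling

__all__ = [
    "NoiseSpec",
    "gen_scan",
    "gen_an_samples",
    "gen_mode_couplings",
    "gen_core_geometry",
    "gen_ring",
    "load_fixture",
    "load_fixture_frame",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise level (in the target quantity's unit) and RNG seed."""

    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise InputError("noise sd must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_scan(B: float, theta_eq: float, npts: int = 21,
             noise: NoiseSpec = NoiseSpec()) -> ScanCurve:
    """Sample a quartic double well on a symmetric grid over
    [-1.6 theta_eq, 1.6 theta_eq] with optional Gaussian noise (cm^-1)."""
    if npts < 5:
        raise InputError("need at least 5 scan points")
    well = QuarticDoubleWell(B=B, theta_eq=theta_eq)
    theta = np.linspace(-1.6 * theta_eq, 1.6 * theta_eq, npts)
    energy = well.evaluate(theta)
    if noise.sd > 0:
        energy = energy + noise.rng().normal(0.0, noise.sd, size=npts)
    return ScanCurve(theta, energy)


def gen_an_samples(model: CosSqModel, thetas, noise: NoiseSpec = NoiseSpec()):
    """(theta, aN) pairs from aN = a cos^2(theta) + b plus Gaussian noise (MHz)."""
    thetas = np.asarray(thetas, dtype=float)
    an = model.a * np.cos(np.radians(thetas)) ** 2 + model.b
    if noise.sd > 0:
        an = an + noise.rng().normal(0.0, noise.sd, size=thetas.size)
    return list(zip(thetas.tolist(), an.tolist()))


def gen_mode_couplings(n: int, n_above: int, threshold: float = 0.03,
                       seed: int = 0) -> list[ModeCoupling]:
    """Coupling set with exactly ``n_above`` ratios |K_iij|/omega_i at or
    above ``threshold``.

    Ratios keep a margin of at least 10% of the threshold on either side of
    it, so the membership is unambiguous under small numerical error.
    """
    if not 0 <= n_above <= n:
        raise InputError("need 0 <= n_above <= n")
    if threshold <= 0:
        raise InputError("threshold must be positive")
    rng = np.random.default_rng(seed)
    ratios = np.concatenate([
        rng.uniform(1.1 * threshold, 3.0 * threshold, size=n_above),
        rng.uniform(0.05 * threshold, 0.9 * threshold, size=n - n_above),
    ])
    rng.shuffle(ratios)
    omegas = rng.uniform(200.0, 1700.0, size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    return [
        ModeCoupling(mode=i + 1, omega_i=float(w), K_iij=float(s * r * w))
        for i, (w, r, s) in enumerate(zip(omegas, ratios, signs))
    ]


def gen_core_geometry(theta: float, rNO: float = 1.280, rC1N: float = 1.455,
                      rC2N: float = 1.455, aC1NC2: float = 118.7,
                      ) -> tuple[AtomSet, NitroxideCore]:
    """Construct a four-atom C1/C2/N/O geometry with exactly the requested
    descriptors.

    N sits at the origin with C1 and C2 in the z = 0 plane, symmetric about
    the +x axis at the prescribed valence angle and bond lengths; O is placed
    in the xz plane opposite the CNC bisector so the N->O bond makes exactly
    ``theta`` degrees with the C1-N-C2 plane.
    """
    if not 0.0 <= theta <= 89.0:
        raise InputError("theta must lie in [0, 89] degrees")
    for name, v in (("rNO", rNO), ("rC1N", rC1N), ("rC2N", rC2N)):
        if not v > 0:
            raise InputError(f"{name} must be positive")
    if not 0.0 < aC1NC2 < 180.0:
        raise InputError("aC1NC2 must lie in (0, 180) degrees")
    half = np.radians(aC1NC2 / 2.0)
    th = np.radians(theta)
    coords = np.array([
        [rC1N * np.cos(half), rC1N * np.sin(half), 0.0],   # C1
        [rC2N * np.cos(half), -rC2N * np.sin(half), 0.0],  # C2
        [0.0, 0.0, 0.0],                                   # N
        [-rNO * np.cos(th), 0.0, rNO * np.sin(th)],        # O
    ])
    atoms = AtomSet(("C", "C", "N", "O"), coords)
    return atoms, NitroxideCore(iC1=0, iC2=1, iN=2, iO=3)


_RING_BOND = 1.54  # Angstrom, generic C-C distance for constructed rings


def gen_ring(n: int, mode: str = "planar", amplitude: float = 0.0) -> AtomSet:
    """Regular n-ring (n = 5 or 6) displaced along one pure puckering mode.

    ``mode``: ``"planar"`` (any supported n), ``"chair"`` (n = 6, alternating
    +/- amplitude/sqrt(6) displacements — the pure alternation mode) or
    ``"twist"`` (n = 5, pure m = 2 Fourier mode at phase 90 deg).  The total
    puckering amplitude Q equals ``amplitude`` exactly by construction.
    """
    if n not in (5, 6):
        raise InputError("ring size must be 5 or 6")
    if amplitude < 0:
        raise InputError("amplitude must be non-negative")
    j = np.arange(n)
    if mode == "planar":
        z = np.zeros(n)
    elif mode == "chair" and n == 6:
        z = amplitude / np.sqrt(6.0) * (-1.0) ** j
    elif mode == "twist" and n == 5:
        phi = np.radians(90.0)
        z = np.sqrt(2.0 / 5.0) * amplitude * np.cos(phi + 4.0 * np.pi * j / 5.0)
    else:
        raise InputError(f"unsupported ring mode {mode!r} for n = {n}")
    radius = _RING_BOND / (2.0 * np.sin(np.pi / n))
    coords = np.column_stack([
        radius * np.cos(2.0 * np.pi * j / n),
        radius * np.sin(2.0 * np.pi * j / n),
        z,
    ])
    return AtomSet(("C",) * n, coords)


# ---------------------------------------------------------------------------
# Packaged fixtures


def load_fixture_frame(name: str) -> pd.DataFrame:
    """Raw fixture table as a DataFrame (columns as printed, plus metadata)."""
    if name not in ("table4", "table6"):
        raise InputError(f"unknown fixture {name!r}: use 'table4' or 'table6'")
    path = resources.files("nitroxkit.data").joinpath(f"{name}.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, comment="#")


def load_fixture(name: str):
    """Packaged data tables as domain records.

    ``"table4"`` -> list of :class:`FrequencyRecord` (15 molecules);
    ``"table6"`` -> list of :class:`CompositeAnRecord` (15 molecules, with
    the tabulated Delta_vib / Delta_TM / Delta_theta contributions).
    """
    df = load_fixture_frame(name)
    if name == "table4":
        return [
            FrequencyRecord(
                molecule=str(r.molecule),
                nu_exp=None if pd.isna(r.nu_exp) else float(r.nu_exp),
                medium="" if pd.isna(r.medium) else str(r.medium),
                omega_B3=float(r.omega_B3),
                nu_B3=float(r.nu_B3),
                omega_B2=float(r.omega_B2),
                family=str(r.family),
            )
            for r in df.itertuples(index=False)
        ]
    return [
        CompositeAnRecord(
            molecule=str(r.molecule),
            rNO=float(r.rNO),
            theta=float(r.theta),
            aN_base=float(r.aN),
            delta_vib=float(r.dvib),
            delta_TM=float(r.dTM),
            delta_theta=float(r.dtheta),
            delta_CNC=float(r.dCNC),
        )
        for r in df.itertuples(index=False)
    ]
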