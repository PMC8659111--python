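"""Geometric descriptors of the nitroxide C1C2NO core and ring puckering.

The pyramidalization of the nitroxide nitrogen is the structural handle on
its spectroscopy: the out-of-plane angle theta (between the N-O bond and
the C1-N-C2 plane) drives the nitrogen hyperfine coupling, while the ring
shape of cyclic nitroxides is summarized by Cremer-Pople puckering
coordinates.  This module computes those descriptors from Cartesian
coordinates; the user supplies the core and ring atom indices explicitly,
so no bond perception or cheminformatics is involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateGeometryError, InputError, UnsupportedRingError

__all__ = [
    "AtomSet",
    "NitroxideCore",
    "GeometryDescriptors",
    "PuckeringCoordinates",
    "read_xyz",
    "write_xyz",
    "compute_descriptors",
    "out_of_plane_theta",
    "cremer_pople",
]

_COLLINEAR_TOL = 1e-8


@dataclass(frozen=True)
class AtomSet:
    """A molecular geometry: element symbols plus Cartesian coordinates in Angstrom."""

    elements: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InputError("coords must be an (n, 3) array")
        if len(self.elements) != coords.shape[0]:
            raise InputError("elements and coords must have the same length")
        if not np.all(np.isfinite(coords)):
            raise InputError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.elements)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomSet":
        """Return a copy with coordinates mapped through ``x -> R x + t``."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        return AtomSet(self.elements, self.coords @ rotation.T + translation)


@dataclass(frozen=True)
class NitroxideCore:
    """0-based indices of the C1, C2, N and O atoms of the nitroxide moiety."""

    iC1: int
    iC2: int
    iN: int
    iO: int

    def __post_init__(self) -> None:
        idx = (self.iC1, self.iC2, self.iN, self.iO)
        if len(set(idx)) != 4:
            raise InputError("core indices must be four distinct atoms")
        if any(i < 0 for i in idx):
            raise InputError("core indices must be non-negative")

    def validate(self, atoms: AtomSet) -> None:
        idx = (self.iC1, self.iC2, self.iN, self.iO)
        if max(idx) >= len(atoms):
            raise InputError(
                f"core index {max(idx)} out of range for {len(atoms)} atoms"
            )
        rno = float(np.linalg.norm(atoms.coords[self.iO] - atoms.coords[self.iN]))
        if rno >= 1.6:
            warnings.warn(
                f"N-O distance {rno:.3f} A exceeds 1.6 A; check the core indices",
                stacklevel=3,
            )


@dataclass(frozen=True)
class GeometryDescriptors:
    """Bond lengths (A), valence angles (deg), the C1-C2-N-O improper dihedral
    reported as |tau| in (0, 180], and the unsigned out-of-plane angle theta in
    [0, 90]."""

    rNO: float
    rC1N: float
    rC2N: float
    aC1NC2: float
    aC1NO: float
    aC2NO: float
    dC1C2NO: float
    theta: float

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in (
            "rNO", "rC1N", "rC2N", "aC1NC2", "aC1NO", "aC2NO", "dC1C2NO", "theta")}


@dataclass(frozen=True)
class PuckeringCoordinates:
    """Cremer-Pople puckering: total amplitude Q (A), per-mode amplitudes qm (A)
    and phase angles phim (deg, empty phase slot for the alternation mode of an
    even ring), for a ring of n atoms."""

    Q: float
    qm: tuple[float, ...]
    phim: tuple[float, ...]
    n: int
    z: tuple[float, ...] = field(default=(), repr=False)

    def as_dict(self) -> dict:
        return {
            "Q": float(self.Q),
            "qm": [float(q) for q in self.qm],
            "phim": [float(p) for p in self.phim],
            "n": self.n,
        }


# ---------------------------------------------------------------------------
# XYZ input/output


def read_xyz(path: str | Path) -> AtomSet:
    """Read a standard XYZ file (count line, comment line, then ``El x y z``)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise InputError(f"empty XYZ file: {path}")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise InputError(f"malformed XYZ count line in {path}") from exc
    body = lines[2 : 2 + natoms]
    if len(body) < natoms:
        raise InputError(f"XYZ file {path} declares {natoms} atoms, found {len(body)}")
    elements, coords = [], []
    for line in body:
        parts = line.split()
        if len(parts) < 4:
            raise InputError(f"malformed XYZ atom line: {line!r}")
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return AtomSet(tuple(elements), np.array(coords))


def write_xyz(atoms: AtomSet, path: str | Path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(atoms)}\n{comment}\n")
        for el, (x, y, z) in zip(atoms.elements, atoms.coords):
            fh.write(f"{el} {x:18.10f} {y:18.10f} {z:18.10f}\n")


# ---------------------------------------------------------------------------
# Core descriptors


def _angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors, degrees, robust near 0 and 180."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("zero-length bond vector")
    cross = np.linalg.norm(np.cross(u, v))
    return float(np.degrees(np.arctan2(cross, float(np.dot(u, v)))))


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 (deg) via the atan2 convention."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n == 0.0 or np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise DegenerateGeometryError("torsion undefined for collinear atoms")
    y = float(np.dot(np.cross(n1, n2), b2 / b2n))
    x = float(np.dot(n1, n2))
    return float(np.degrees(np.arctan2(y, x)))


def out_of_plane_theta(atoms: AtomSet, core: NitroxideCore) -> float:
    """Unsigned angle (deg, in [0, 90]) between the N->O bond and the C1-N-C2 plane.

    Computed as 90 deg minus the angle between N->O and the plane normal;
    raises :class:`DegenerateGeometryError` when C1, N, C2 are collinear.
    """
    core.validate(atoms)
    x = atoms.coords
    vC1 = x[core.iC1] - x[core.iN]
    vC2 = x[core.iC2] - x[core.iN]
    vO = x[core.iO] - x[core.iN]
    normal = np.cross(vC1, vC2)
    nn = np.linalg.norm(normal)
    if nn < _COLLINEAR_TOL * np.linalg.norm(vC1) * np.linalg.norm(vC2):
        raise DegenerateGeometryError("C1, N, C2 are collinear: CNC plane undefined")
    theta = 90.0 - _angle(vO, normal)
    return abs(float(theta))


def compute_descriptors(atoms: AtomSet, core: NitroxideCore) -> GeometryDescriptors:
    """All core descriptors: bond lengths, valence angles, |C1C2NO| torsion, theta."""
    core.validate(atoms)
    x = atoms.coords
    N, O, C1, C2 = x[core.iN], x[core.iO], x[core.iC1], x[core.iC2]
    theta = out_of_plane_theta(atoms, core)
    dihedral = abs(_dihedral(C1, C2, N, O))
    if dihedral == 0.0:
        dihedral = 180.0  # planar cis-degenerate case mapped into (0, 180]
    return GeometryDescriptors(
        rNO=float(np.linalg.norm(O - N)),
        rC1N=float(np.linalg.norm(C1 - N)),
        rC2N=float(np.linalg.norm(C2 - N)),
        aC1NC2=_angle(C1 - N, C2 - N),
        aC1NO=_angle(C1 - N, O - N),
        aC2NO=_angle(C2 - N, O - N),
        dC1C2NO=dihedral,
        theta=theta,
    )


# ---------------------------------------------------------------------------
# Cremer-Pople ring puckering


def cremer_pople(atoms: AtomSet, ring: "list[int] | tuple[int, ...]") -> PuckeringCoordinates:
    """Cremer-Pople puckering coordinates of an ordered 5- or 6-membered ring.

    The mean plane follows the original 1975 prescription: the origin is the
    geometric center of the ring and the plane normal is R' x R'' with
    R' = sum_j r_j sin(2 pi j / n) and R'' = sum_j r_j cos(2 pi j / n).
    Displacements z_j along the normal then satisfy sum z_j = 0 and their
    discrete Fourier amplitudes give (qm, phim); Q = sqrt(sum z_j^2).
    """
    n = len(ring)
    if n not in (5, 6):
        raise UnsupportedRingError(f"ring size {n} unsupported; need 5 or 6")
    if len(set(ring)) != n:
        raise InputError("ring indices must be distinct")
    if max(ring) >= len(atoms) or min(ring) < 0:
        raise InputError("ring index out of range")

    r = atoms.coords[list(ring)].astype(float)
    r = r - r.mean(axis=0)
    j = np.arange(n)
    rp = (r * np.sin(2 * np.pi * j / n)[:, None]).sum(axis=0)
    rpp = (r * np.cos(2 * np.pi * j / n)[:, None]).sum(axis=0)
    normal = np.cross(rp, rpp)
    nn = np.linalg.norm(normal)
    if nn < _COLLINEAR_TOL:
        raise DegenerateGeometryError("degenerate ring: mean plane undefined")
    normal /= nn
    z = r @ normal

    qm: list[float] = []
    phim: list[float] = []
    for m in range(2, (n - 1) // 2 + 1):
        c = np.sqrt(2.0 / n) * float(np.dot(z, np.cos(2 * np.pi * m * j / n)))
        s = -np.sqrt(2.0 / n) * float(np.dot(z, np.sin(2 * np.pi * m * j / n)))
        q = float(np.hypot(c, s))
        phi = float(np.degrees(np.arctan2(s, c))) % 360.0 if q > 0 else 0.0
        qm.append(q)
        phim.append(phi)
    if n % 2 == 0:
        # alternation (chair-like) mode of an even ring: amplitude only
        qm.append(abs(float(np.dot(z, (-1.0) ** j)) / np.sqrt(n)))
    Q = float(np.sqrt(np.sum(z**2)))
    return PuckeringCoordinates(
        Q=Q, qm=tuple(qm), phim=tuple(phim), n=n, z=tuple(float(v) for v in z)
    )
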