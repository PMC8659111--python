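"""Hybrid anharmonic NO-stretch frequencies and reduced-dimensionality mode selection.

Harmonic frequencies overestimate the NO stretch; full anharmonic (VPT2)
treatments at the better level of theory are often too expensive.  The
hybrid scheme combines a high-level harmonic frequency with a low-level
anharmonic shift,

    nu_H = omega_B2 + (nu_B3 - omega_B3),

where B2/B3 label the double-hybrid and hybrid DFT inputs.  Two cheaper
alternatives are supported: empirical scaling of the harmonic value
(factors 0.976 for B3, 0.980 for B2) and a constant 30 cm^-1 anharmonic
shift, which works because the B3 anharmonic corrections of nitroxides
cluster in a narrow 28-34 cm^-1 band.  For reduced-dimensionality
anharmonic runs, the modes that matter are those strongly coupled to the
NO stretch, pre-selected by the ratio of the two-mode cubic force constant
K_iij to the coupled mode's harmonic frequency omega_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .constants import CONSTANT_ANHARMONIC_SHIFT, HARMONIC_SCALING
from .errors import InputError

__all__ = [
    "FrequencyRecord",
    "ModeCoupling",
    "ModeSelection",
    "ErrorSummary",
    "FAMILIES",
    "hybrid_frequency",
    "scaled_harmonic",
    "constant_correction",
    "error_stats",
    "select_modes",
    "read_frequency_csv",
    "read_coupling_csv",
    "PREDICTORS",
]

#: Structural family of each molecule label: acyclic (a-f), six-membered
#: ring (g-i), saturated five-membered ring (j, k), unsaturated or
#: aromatic-containing five-membered ring (l-p).
FAMILIES = {
    **{m: "acyclic" for m in "abcdef"},
    **{m: "six-ring" for m in "ghi"},
    **{m: "five-ring-sat" for m in "jk"},
    **{m: "five-ring-unsat" for m in "lmnop"},
}

_FAMILY_TAGS = ("acyclic", "six-ring", "five-ring-sat", "five-ring-unsat")


@dataclass(frozen=True)
class FrequencyRecord:
    """NO-stretch frequency data for one molecule (all cm^-1).

    ``nu_exp`` is the experimental band position (None when unassigned) and
    ``medium`` the recording medium (gas, KBr, Nujol, or a solvent); the
    medium is metadata only, no solvent correction is applied.
    """

    molecule: str
    omega_B3: float
    nu_B3: float
    omega_B2: float
    nu_exp: float | None = None
    medium: str = ""
    family: str = ""

    def __post_init__(self) -> None:
        for name in ("omega_B3", "nu_B3", "omega_B2"):
            v = getattr(self, name)
            if v is None or not (v > 0 and math.isfinite(v)):
                raise InputError(f"{name} must be a positive frequency (cm^-1)")
        if self.nu_exp is not None and not self.nu_exp > 0:
            raise InputError("nu_exp must be positive when present")
        if self.family and self.family not in _FAMILY_TAGS:
            raise InputError(f"unknown family tag {self.family!r}")

    @property
    def anharmonic_shift_B3(self) -> float:
        """Delta_B3 = omega_B3 - nu_B3, the low-level anharmonic correction."""
        return self.omega_B3 - self.nu_B3


@dataclass(frozen=True)
class ModeCoupling:
    """Cubic coupling of one normal mode to the NO stretch: the two-mode
    constant K_iij (cm^-1) and the coupled mode's harmonic frequency."""

    mode: int
    omega_i: float
    K_iij: float

    def __post_init__(self) -> None:
        if not self.omega_i > 0:
            raise InputError("omega_i must be positive")

    @property
    def ratio(self) -> float:
        return abs(self.K_iij) / self.omega_i


@dataclass(frozen=True)
class ModeSelection:
    """Modes retained for a reduced-dimensionality anharmonic run: the NO
    stretch itself plus the couplings at or above the threshold, in order of
    decreasing |K_iij|/omega_i."""

    selected: tuple[ModeCoupling, ...]
    threshold: float
    no_mode: str = "NO"

    @property
    def modes(self) -> tuple:
        """Mode labels, NO stretch first."""
        return (self.no_mode, *(c.mode for c in self.selected))

    @property
    def n_selected(self) -> int:
        """Number of coupled modes retained (excluding the NO stretch)."""
        return len(self.selected)


def hybrid_frequency(rec: FrequencyRecord) -> float:
    """nu_H = omega_B2 + (nu_B3 - omega_B3), unrounded."""
    return rec.omega_B2 + (rec.nu_B3 - rec.omega_B3)


def scaled_harmonic(omega: float, level: str, factor: float | None = None) -> float:
    """Empirically scaled harmonic frequency; default factors 0.976 (B3), 0.980 (B2)."""
    if not omega > 0:
        raise InputError("omega must be positive")
    if factor is None:
        try:
            factor = HARMONIC_SCALING[level]
        except KeyError:
            raise InputError(f"unknown level {level!r}: use 'B3' or 'B2'") from None
    return omega * factor


def constant_correction(omega_B2: float, c: float = CONSTANT_ANHARMONIC_SHIFT) -> float:
    """Constant-shift estimate omega_B2 - c of the anharmonic NO stretch."""
    if not omega_B2 > 0:
        raise InputError("omega_B2 must be positive")
    return omega_B2 - c


#: Predictor tags accepted by :func:`error_stats`.
PREDICTORS = ("scaled_B3", "anharm_B3", "scaled_B2", "harm_B2", "hybrid",
              "constant", "experiment")


def _predict(rec: FrequencyRecord, predictor: str) -> float:
    if predictor == "scaled_B3":
        return scaled_harmonic(rec.omega_B3, "B3")
    if predictor == "anharm_B3":
        return rec.nu_B3
    if predictor == "scaled_B2":
        return scaled_harmonic(rec.omega_B2, "B2")
    if predictor == "harm_B2":
        return rec.omega_B2
    if predictor == "hybrid":
        return hybrid_frequency(rec)
    if predictor == "constant":
        return constant_correction(rec.omega_B2)
    if predictor == "experiment":
        if rec.nu_exp is None:
            raise InputError(f"record {rec.molecule!r} has no experimental value")
        return rec.nu_exp
    raise InputError(f"unknown predictor {predictor!r}; choose from {PREDICTORS}")


@dataclass(frozen=True)
class ErrorSummary:
    """Signed mean, mean absolute and maximum absolute error (cm^-1) of a
    predictor against experiment, overall and per structural family."""

    predictor: str
    n: int
    mean_signed: float
    mae: float
    max_abs: float
    per_family: dict
    per_molecule: dict

    def as_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "n": self.n,
            "mean_signed": self.mean_signed,
            "mae": self.mae,
            "max_abs": self.max_abs,
            "per_family": self.per_family,
            "per_molecule": self.per_molecule,
        }


def _summarize(errors: list[float]) -> dict:
    return {
        "n": len(errors),
        "mean_signed": sum(errors) / len(errors),
        "mae": sum(abs(e) for e in errors) / len(errors),
        "max_abs": max(abs(e) for e in errors),
    }


def error_stats(records: Iterable[FrequencyRecord], predictor: str = "hybrid") -> ErrorSummary:
    """Prediction errors (predicted minus experimental) over the records with
    an experimental frequency, overall and broken down by family."""
    per_molecule: dict[str, float] = {}
    per_family_errors: dict[str, list[float]] = {}
    for rec in records:
        if rec.nu_exp is None:
            continue
        err = _predict(rec, predictor) - rec.nu_exp
        per_molecule[rec.molecule] = err
        fam = rec.family or FAMILIES.get(rec.molecule, "")
        if fam:
            per_family_errors.setdefault(fam, []).append(err)
    if not per_molecule:
        raise InputError("no records carry an experimental frequency")
    overall = _summarize(list(per_molecule.values()))
    return ErrorSummary(
        predictor=predictor,
        n=overall["n"],
        mean_signed=overall["mean_signed"],
        mae=overall["mae"],
        max_abs=overall["max_abs"],
        per_family={f: _summarize(v) for f, v in per_family_errors.items()},
        per_molecule=per_molecule,
    )


def select_modes(couplings: Sequence[ModeCoupling], threshold: float = 0.03,
                 no_mode: str = "NO") -> ModeSelection:
    """Retain the modes with |K_iij|/omega_i >= threshold, strongest first.

    The NO-stretch mode itself is always part of the selection; an empty
    coupling list therefore yields the NO mode alone.
    """
    if threshold < 0:
        raise InputError("threshold must be non-negative")
    chosen = sorted(
        (c for c in couplings if c.ratio >= threshold),
        key=lambda c: c.ratio, reverse=True,
    )
    return ModeSelection(selected=tuple(chosen), threshold=float(threshold),
                         no_mode=no_mode)


# ---------------------------------------------------------------------------
# CSV dialects


def read_frequency_csv(path: str | Path) -> list[FrequencyRecord]:
    """Read ``molecule,nu_exp,medium,omega_B3,nu_B3,omega_B2,family`` CSV
    (blank nu_exp for unassigned bands)."""
    df = pd.read_csv(path, comment="#")
    required = {"molecule", "omega_B3", "nu_B3", "omega_B2"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"frequency CSV missing columns: {sorted(missing)}")
    def _opt_str(value) -> str:
        if value is None or (isinstance(value, float) and pd.isna(value)):
            return ""
        return str(value)

    records = []
    for row in df.itertuples(index=False):
        nu_exp = getattr(row, "nu_exp", None)
        records.append(FrequencyRecord(
            molecule=str(row.molecule),
            nu_exp=None if nu_exp is None or pd.isna(nu_exp) else float(nu_exp),
            medium=_opt_str(getattr(row, "medium", "")),
            omega_B3=float(row.omega_B3),
            nu_B3=float(row.nu_B3),
            omega_B2=float(row.omega_B2),
            family=_opt_str(getattr(row, "family", "")),
        ))
    return records


def read_coupling_csv(path: str | Path) -> list[ModeCoupling]:
    """Read ``mode,omega_i,K_iij`` CSV."""
    df = pd.read_csv(path, comment="#")
    missing = {"mode", "omega_i", "K_iij"} - set(df.columns)
    if missing:
        raise InputError(f"coupling CSV missing columns: {sorted(missing)}")
    return [ModeCoupling(mode=int(r.mode), omega_i=float(r.omega_i), K_iij=float(r.K_iij))
            for r in df.itertuples(index=False)]
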