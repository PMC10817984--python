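"""BOD biodegradability from closed-bottle oxygen-uptake series.

The extent of mineralisation of a polymer sample in seawater is expressed
as the measured biochemical oxygen demand, blank-corrected, over the
theoretical oxygen demand (ThOD) of the sample:

    biodegradability(%) = (BOD_s - BOD_b) / ThOD * 100
    ThOD(mg)            = w / M * (4x + y - 2z) / 4 * 32

for a monomer unit CxHyOz of molar mass M (g/mol) and sample weight w (mg).
The stoichiometric factor (4x + y - 2z)/4 counts the moles of O2 needed to
oxidise one monomer completely to CO2 and H2O. Nitrogen is deliberately
outside the model: the assay medium contains allylthiourea, a nitrification
inhibitor, so reduced nitrogen does not draw oxygen.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataWarning, InvalidInputError, UnsupportedElementError
from .residues import ATOMIC_WEIGHT

__all__ = [
    "MonomerFormula",
    "BODSeries",
    "BiodegradabilityCurve",
    "parse_monomer_formula",
    "molar_mass",
    "monomer_from_string",
    "average_formula",
    "thod",
    "bod_biodegradability",
    "biodegradability_curve",
]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MonomerFormula:
    """Monomer-unit stoichiometry CxHyOz with molar mass M (g/mol).

    Counts are floats so mole-fraction-weighted copolymer averages are
    representable. ``M`` is user-supplied (hydrate and copolymer conventions
    stay with the user); :func:`molar_mass` computes it from standard atomic
    weights when convenient.
    """

    x: float
    y: float
    z: float
    m_g_mol: float
    label: str = ""

    def __post_init__(self):
        if self.x < 1:
            raise InvalidInputError("monomer must contain at least one carbon (x >= 1)")
        if self.y < 0 or self.z < 0:
            raise InvalidInputError("H and O counts must be >= 0")
        if not self.m_g_mol > 0:
            raise InvalidInputError("molar mass must be > 0")
        if not self.oxygen_demand_factor > 0:
            raise InvalidInputError(
                "oxygen-demand factor 4x + y - 2z must be > 0; this substance "
                "cannot consume O2 under the ThOD model"
            )

    @property
    def oxygen_demand_factor(self) -> float:
        """Moles of electron-equivalents: 4x + y - 2z (4 per mole O2)."""
        return 4.0 * self.x + self.y - 2.0 * self.z


def parse_monomer_formula(text: str) -> tuple[int, int, int]:
    """Parse a C/H/O formula string like ``"C4H6O2"`` into (x, y, z).

    Missing elements count as 0; an omitted subscript means 1. Any element
    other than C, H, O raises :class:`UnsupportedElementError`.
    """
    if not text or not text.strip():
        raise InvalidInputError("empty formula string")
    text = text.strip()
    counts = {"C": 0, "H": 0, "O": 0}
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise InvalidInputError(f"cannot parse formula {text!r} at position {pos}")
        element, digits = match.groups()
        if element not in counts:
            raise UnsupportedElementError(element)
        counts[element] += int(digits) if digits else 1
        pos = match.end()
    if pos != len(text):
        raise InvalidInputError(f"cannot parse formula {text!r} at position {pos}")
    return counts["C"], counts["H"], counts["O"]


def molar_mass(x: float, y: float, z: float) -> float:
    """Molar mass of CxHyOz from conventional atomic weights (+-0.01 g/mol)."""
    return x * ATOMIC_WEIGHT["C"] + y * ATOMIC_WEIGHT["H"] + z * ATOMIC_WEIGHT["O"]


def monomer_from_string(text: str, m_g_mol: float | None = None, label: str = "") -> MonomerFormula:
    """Build a :class:`MonomerFormula` from a formula string.

    If ``m_g_mol`` is omitted it is computed from standard atomic weights.
    """
    x, y, z = parse_monomer_formula(text)
    m = m_g_mol if m_g_mol is not None else molar_mass(x, y, z)
    return MonomerFormula(x, y, z, m, label=label or text)


def average_formula(
    components: Sequence[tuple[MonomerFormula, float]], label: str = ""
) -> MonomerFormula:
    """Mole-fraction-weighted average formula for a random copolymer.

    ``components`` is a sequence of (formula, mole_fraction); fractions must
    sum to 1 within 1e-6.
    """
    if not components:
        raise InvalidInputError("need at least one component")
    fracs = np.array([f for _, f in components], dtype=float)
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-6:
        raise InvalidInputError("mole fractions must be >= 0 and sum to 1")
    x = sum(f.x * w for f, w in components)
    y = sum(f.y * w for f, w in components)
    z = sum(f.z * w for f, w in components)
    m = sum(f.m_g_mol * w for f, w in components)
    return MonomerFormula(x, y, z, m, label=label)


def thod(w_mg: float, formula: MonomerFormula) -> float:
    """Theoretical oxygen demand, mg O2: w/M * (4x + y - 2z)/4 * 32."""
    if not w_mg > 0:
        raise InvalidInputError("sample weight must be > 0")
    return w_mg / formula.m_g_mol * formula.oxygen_demand_factor / 4.0 * 32.0


def bod_biodegradability(bod_s_mg: float, bod_b_mg: float, thod_mg: float) -> float:
    """Blank-corrected oxygen uptake as a percentage of ThOD.

    Negative values (blank exceeding sample) are returned with a warning;
    values above 100% can occur transiently (priming) and are not clamped.
    """
    if not thod_mg > 0:
        raise InvalidInputError("ThOD must be > 0")
    pct = (bod_s_mg - bod_b_mg) / thod_mg * 100.0
    if pct < 0:
        warnings.warn(
            "blank BOD exceeds sample BOD; negative biodegradability returned",
            DataWarning,
            stacklevel=2,
        )
    return pct


@dataclass
class BODSeries:
    """Cumulative O2-uptake series for one bottle plus its blank."""

    sample_id: str
    w_mg: float
    formula: MonomerFormula
    readings: list[tuple[float, float]] = field(default_factory=list)
    blank_readings: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        if not self.w_mg > 0:
            raise InvalidInputError("sample weight must be > 0")
        vals = [v for _, v in self.readings]
        if any(b < a - 0.5 for a, b in zip(vals, vals[1:])):
            warnings.warn(
                f"{self.sample_id}: cumulative BOD decreases beyond instrument noise",
                DataWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class BiodegradabilityCurve:
    """Pointwise biodegradability curve with plateau summary."""

    days: np.ndarray
    percent: np.ndarray
    plateau_percent: float
    t90_days: float | None  # first day reaching 90% of the plateau


def biodegradability_curve(series: BODSeries) -> BiodegradabilityCurve:
    """Blank-align and convert a BOD series to a biodegradability curve.

    Blank readings are linearly interpolated onto the sample day grid; days
    outside the blank grid are truncated (extrapolation refused) with a
    warning. The plateau is the mean of the last three points and t90 the
    first day at which the curve reaches 90% of it.
    """
    if not series.readings:
        raise InvalidInputError("need at least one sample reading")
    if not series.blank_readings:
        raise InvalidInputError("need blank readings for correction")
    s_days = np.array([d for d, _ in series.readings], dtype=float)
    s_vals = np.array([v for _, v in series.readings], dtype=float)
    b_days = np.array([d for d, _ in series.blank_readings], dtype=float)
    b_vals = np.array([v for _, v in series.blank_readings], dtype=float)
    keep = (s_days >= b_days.min()) & (s_days <= b_days.max())
    if not keep.all():
        warnings.warn(
            "sample days outside the blank grid truncated (no extrapolation)",
            DataWarning,
            stacklevel=2,
        )
    if not keep.any():
        raise InvalidInputError("blank grid does not cover any sample day")
    s_days, s_vals = s_days[keep], s_vals[keep]
    blank_on_sample = np.interp(s_days, b_days, b_vals)
    total = thod(series.w_mg, series.formula)
    pct = (s_vals - blank_on_sample) / total * 100.0
    tail = pct[-3:] if pct.size >= 3 else pct
    plateau = float(tail.mean())
    t90 = None
    if plateau > 0:
        reached = np.nonzero(pct >= 0.9 * plateau)[0]
        if reached.size:
            t90 = float(s_days[reached[0]])
    return BiodegradabilityCurve(days=s_days, percent=pct, plateau_percent=plateau, t90_days=t90)
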