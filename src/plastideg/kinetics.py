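"""Surface-erosion kinetics of plastic specimens in seawater.

Biodegradable polyesters exposed on the seafloor lose mass from the surface
at a roughly constant (zero-order) rate, so the natural summary statistic is
the weight loss normalised to initial surface area and exposure time,

    V = dW * 1e6 / A / t            [ug / cm^2 / day]

with dW in grams, A the initial surface area in cm^2 and t in days. From V
the residual weight of a thin article (a shopping bag) declines linearly,

    residual(%) = 100 - V * S * t * 1e-6 / m * 100,

and its complete-degradation lifetime is t* = m * 1e6 / (V * S), where S is
the article's surface area (cm^2) and m its mass (g).

Note on units: V carries an explicit g -> ug conversion (factor 1e6) so that
typical field rates land in the 1-200 ug/cm^2/day range; the residual-weight
and lifetime formulas invert that conversion (factor 1e-6) so the three
operations compose exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import DataWarning, InvalidInputError

__all__ = [
    "SpecimenGeometry",
    "SpecimenRecord",
    "DegradationRate",
    "BagSpec",
    "ThicknessTrend",
    "ErosionConsistency",
    "weight_loss_percent",
    "initial_surface_area",
    "biodegradation_rate",
    "aggregate_rates",
    "residual_weight_percent",
    "estimated_lifetime",
    "thickness_loss_rate",
    "erosion_consistency",
    "NON_DEGRADING",
]

#: Sentinel lifetime for a non-degrading material (V <= 0).
NON_DEGRADING: float = math.inf

_FORMS = ("film", "injection_molded", "bag")


@dataclass(frozen=True)
class SpecimenGeometry:
    """Rectangular specimen geometry.

    Lengths and widths in cm, thickness in um. ``n_panels`` is 1 for a flat
    specimen and 2 for a bag (two welded rectangles).
    """

    form: str
    length_cm: float
    width_cm: float
    thickness_um: float
    n_panels: int = 1

    def __post_init__(self):
        if self.form not in _FORMS:
            raise InvalidInputError(f"unknown form {self.form!r}; expected one of {_FORMS}")
        for name in ("length_cm", "width_cm", "thickness_um"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be > 0")
        if self.n_panels < 1:
            raise InvalidInputError("n_panels must be >= 1")
        # Thin-sheet assumption behind face-only areas; flagged, not enforced.
        if self.thickness_um / 1e4 > 0.2 * min(self.length_cm, self.width_cm):
            warnings.warn(
                "thickness is not small relative to the panel dimensions; "
                "the thin-sheet (face-only) area convention may be inappropriate",
                DataWarning,
                stacklevel=2,
            )

    @property
    def face_area_cm2(self) -> float:
        """Both faces of every panel."""
        return self.n_panels * 2.0 * self.length_cm * self.width_cm


@dataclass
class SpecimenRecord:
    """One deployed specimen: identity, masses, geometry, thickness series."""

    id: str
    polymer: str
    site: str
    deployment_days: float
    w_initial_g: float
    w_final_g: float
    geometry: SpecimenGeometry
    thickness_series: list[tuple[float, float]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.w_initial_g > 0:
            raise InvalidInputError("w_initial_g must be > 0")
        if self.w_final_g < 0:
            raise InvalidInputError("w_final_g must be >= 0")
        if not self.deployment_days > 0:
            raise InvalidInputError("deployment_days must be > 0")
        thicknesses = [d for _, d in self.thickness_series]
        if any(b > a * 1.05 for a, b in zip(thicknesses, thicknesses[1:])):
            warnings.warn(
                f"specimen {self.id}: thickness series increases beyond "
                "plausible measurement noise",
                DataWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class DegradationRate:
    """Replicate statistics of the area-normalised rate, ug/cm^2/day."""

    v_mean: float
    v_sd: float
    v_min: float
    v_max: float
    n_replicates: int

    def __post_init__(self):
        if self.n_replicates < 1:
            raise InvalidInputError("n_replicates must be >= 1")
        if not (self.v_min <= self.v_mean <= self.v_max):
            raise InvalidInputError("require v_min <= v_mean <= v_max")

    def select(self, bound: str) -> float:
        """Rate for a lifetime bound: 'fastest' (v_max), 'slowest' (v_min), 'mean'."""
        try:
            return {"fastest": self.v_max, "slowest": self.v_min, "mean": self.v_mean}[bound]
        except KeyError:
            raise InvalidInputError(
                f"unknown bound {bound!r}; expected fastest/slowest/mean"
            ) from None


@dataclass(frozen=True)
class BagSpec:
    """A thin-film article treated as two welded rectangular panels.

    Defaults describe a typical lightweight shopping bag: two 18 x 42 cm
    panels of 15 um film weighing 3 g in total.
    """

    panel_length_cm: float = 42.0
    panel_width_cm: float = 18.0
    n_panels: int = 2
    mass_g: float = 3.0
    film_thickness_um: float = 15.0

    def __post_init__(self):
        if not self.mass_g > 0:
            raise InvalidInputError("mass_g must be > 0")
        for name in ("panel_length_cm", "panel_width_cm", "film_thickness_um"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be > 0")

    @property
    def surface_area_cm2(self) -> float:
        """Both faces of each panel (edges negligible for 15 um film)."""
        return self.n_panels * 2.0 * self.panel_length_cm * self.panel_width_cm


def weight_loss_percent(w_initial_g: float, w_final_g: float) -> float:
    """Gravimetric weight loss, (Wi - Wf)/Wi * 100.

    A negative result (net mass gain, usually residual biofouling or
    mineral deposit) is returned with a warning rather than truncated.
    """
    if not w_initial_g > 0:
        raise InvalidInputError("w_initial_g must be > 0")
    if w_final_g < 0:
        raise InvalidInputError("w_final_g must be >= 0")
    loss = (w_initial_g - w_final_g) / w_initial_g * 100.0
    if loss < 0:
        warnings.warn(
            "final weight exceeds initial weight (fouling residue?); "
            "negative weight loss returned",
            DataWarning,
            stacklevel=2,
        )
    return loss


def initial_surface_area(
    geometry: SpecimenGeometry, include_edges: bool | None = None
) -> float:
    """Initial surface area, cm^2.

    Default convention counts both faces of every panel and ignores edges,
    which is appropriate for thin films and bags. For injection-moulded bars
    (0.4 cm thick) the edge faces are not negligible, so ``include_edges``
    defaults to True for ``form == "injection_molded"``; it is a guess that
    all six faces were exposed, and can be overridden explicitly.
    """
    if include_edges is None:
        include_edges = geometry.form == "injection_molded"
    area = geometry.face_area_cm2
    if include_edges:
        t_cm = geometry.thickness_um / 1e4
        perimeter = 2.0 * (geometry.length_cm + geometry.width_cm)
        area += geometry.n_panels * perimeter * t_cm
    return area


def biodegradation_rate(delta_w_g: float, a_initial_cm2: float, t_days: float) -> float:
    """Area-normalised biodegradation rate V = dW * 1e6 / A / t, ug/cm^2/day."""
    if delta_w_g < 0:
        raise InvalidInputError(
            "delta_w_g must be >= 0; handle mass gain upstream (weight_loss_percent)"
        )
    if not a_initial_cm2 > 0:
        raise InvalidInputError("a_initial_cm2 must be > 0")
    if not t_days > 0:
        raise InvalidInputError("t_days must be > 0")
    return delta_w_g * 1e6 / a_initial_cm2 / t_days


def aggregate_rates(rates: Sequence[float]) -> DegradationRate:
    """Replicate mean, sample SD (ddof=1; 0 when n=1), min, max and n."""
    arr = np.asarray(list(rates), dtype=float)
    if arr.size == 0:
        raise InvalidInputError("need at least one rate")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("rates must be finite")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return DegradationRate(
        v_mean=float(arr.mean()),
        v_sd=sd,
        v_min=float(arr.min()),
        v_max=float(arr.max()),
        n_replicates=int(arr.size),
    )


def residual_weight_percent(
    v: float, s_cm2: float, t_days: float, mass_g: float = 3.0, *, clamp: bool = True
) -> float:
    """Residual weight of an article of mass ``mass_g`` after ``t_days``.

    Linear in time: 100 - V*S*t*1e-6/m * 100. Clamped at 0 by default
    (the linear model goes negative once the article is fully degraded);
    pass ``clamp=False`` for the raw linear value.
    """
    if not (v > 0 and s_cm2 > 0 and mass_g > 0):
        raise InvalidInputError("v, s_cm2 and mass_g must be > 0")
    if t_days < 0:
        raise InvalidInputError("t_days must be >= 0")
    raw = 100.0 - v * s_cm2 * t_days * 1e-6 / mass_g * 100.0
    return max(0.0, raw) if clamp else raw


def estimated_lifetime(
    rate: DegradationRate | float, bag: BagSpec | None = None, bound: str = "slowest"
) -> float:
    """Days until complete degradation of ``bag`` at the selected rate.

    ``bound`` picks the replicate rate used: 'slowest' (conservative,
    default), 'fastest', or 'mean'. A non-positive rate yields the
    ``NON_DEGRADING`` sentinel (infinite lifetime), not an exception.
    The raw value is returned; rounding to whole days is presentation only.
    """
    bag = bag if bag is not None else BagSpec()
    v = rate.select(bound) if isinstance(rate, DegradationRate) else float(rate)
    if v <= 0:
        return NON_DEGRADING
    return bag.mass_g * 1e6 / (v * bag.surface_area_cm2)


@dataclass(frozen=True)
class ThicknessTrend:
    """OLS fit of thickness against time: loss rate (um/day) and intercept (um)."""

    loss_rate_um_per_day: float
    intercept_um: float
    r_squared: float

    def predicted_decrease_um(self, horizon_days: float) -> float:
        return self.loss_rate_um_per_day * horizon_days


def thickness_loss_rate(series: Sequence[tuple[float, float]]) -> ThicknessTrend:
    """Ordinary least-squares thinning rate from (day, thickness_um) pairs.

    The slope is reported as a positive loss rate (thinning); at least two
    distinct time points are required.
    """
    pts = list(series)
    if len(pts) < 2:
        raise InvalidInputError("need at least two thickness measurements")
    days = np.asarray([d for d, _ in pts], dtype=float)
    thick = np.asarray([t for _, t in pts], dtype=float)
    if np.ptp(days) == 0:
        raise InvalidInputError("thickness measurements need at least two distinct days")
    fit = stats.linregress(days, thick)
    r2 = float(fit.rvalue**2) if np.ptp(thick) > 0 else 1.0
    return ThicknessTrend(
        loss_rate_um_per_day=-float(fit.slope),
        intercept_um=float(fit.intercept),
        r_squared=r2,
    )


class ErosionConsistency(NamedTuple):
    """Ratio of fractional weight-loss rate to fractional thickness-loss rate."""

    ratio: float
    flag: str | None


def erosion_consistency(record: SpecimenRecord, density_g_cm3: float) -> ErosionConsistency:
    """Compare mass-loss and thinning rates of one specimen.

    For pure face-normal erosion of a uniform sheet, the fractional rate of
    weight loss equals the fractional rate of thickness loss, so the ratio
    is ~1. Ratios well above 1 indicate extra mass loss not accounted for by
    thinning (through-holes, edge attack); ratios below 1 suggest the faces
    thinned without commensurate mass loss (swelling, fouling residue).

    ``density_g_cm3`` is accepted for interface symmetry with mass-balance
    checks; the dimensionless ratio itself does not depend on it.
    """
    if not density_g_cm3 > 0:
        raise InvalidInputError("density must be > 0")
    trend = thickness_loss_rate(record.thickness_series)
    d0 = trend.intercept_um if trend.intercept_um > 0 else record.thickness_series[0][1]
    frac_weight = (
        (record.w_initial_g - record.w_final_g)
        / record.w_initial_g
        / record.deployment_days
    )
    frac_thick = trend.loss_rate_um_per_day / d0
    if abs(frac_thick) < 1e-15:
        if abs(frac_weight) < 1e-15:
            return ErosionConsistency(1.0, "no-degradation")
        return ErosionConsistency(math.inf, "no-thinning")
    return ErosionConsistency(frac_weight / frac_thick, None)
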