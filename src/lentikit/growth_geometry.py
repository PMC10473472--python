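"""Fruit surface-area geometry and sigmoidal growth modelling.

Surface area is computed from fruit length and two orthogonal equatorial
diameters assuming sphericity: the fruit is treated as a sphere of the
geometric-mean diameter, A = pi * ((L * d1 * d2)^(1/3))^2.  This is the
standard horticultural operationalisation for near-spheroid fruit and
tracks measured peel areas closely.

The developmental surface-area time course is fitted with a 3-parameter
logistic A(t) = a_max / (1 + exp(-k (t - t_mid))); the growth rate is the
closed-form first derivative, which peaks at a_max * k / 4 at t = t_mid.
A Gompertz alternative (peak a_max * k / e at t_mid) is available via the
``family`` switch since "sigmoidal" does not pin the family down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .synthetic_data import logistic_area

FAMILIES = ("logistic", "gompertz")


@dataclass(frozen=True)
class FruitMeasurement:
    """One fruit at one developmental time point."""

    dafb: float
    mass_g: float
    length_mm: float
    diameter1_mm: float
    diameter2_mm: float

    def __post_init__(self) -> None:
        if self.dafb < 0:
            raise ValueError("dafb must be >= 0")
        for name in ("mass_g", "length_mm", "diameter1_mm", "diameter2_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class GrowthFit:
    """Fitted sigmoid with its closed-form peak growth rate."""

    a_max_cm2: float
    k_per_d: float
    t_mid_dafb: float
    residual_sd_cm2: float
    peak_rate_cm2_per_d: float
    t_peak_dafb: float
    family: str = "logistic"


def surface_area(m: FruitMeasurement) -> float:
    """Fruit surface area (cm^2) from length and two diameters (mm).

    Sphere of the geometric-mean diameter:
    A = pi * ((L * d1 * d2)^(1/3))^2, converted from mm^2 to cm^2.
    """
    return surface_area_from_dimensions(
        m.length_mm, m.diameter1_mm, m.diameter2_mm
    )


def surface_area_from_dimensions(
    length_mm: float, diameter1_mm: float, diameter2_mm: float
) -> float:
    """Surface area (cm^2) from the three linear dimensions in mm."""
    for v in (length_mm, diameter1_mm, diameter2_mm):
        if not v > 0:
            raise ValueError("all fruit dimensions must be positive")
    d_geom = (length_mm * diameter1_mm * diameter2_mm) ** (1.0 / 3.0)
    return math.pi * d_geom**2 / 100.0  # mm^2 -> cm^2


def _gompertz(t: np.ndarray, a_max: float, k: float, t_mid: float) -> np.ndarray:
    return a_max * np.exp(-np.exp(-k * (t - t_mid)))


_MODEL: dict[str, Callable[..., np.ndarray]] = {
    "logistic": logistic_area,
    "gompertz": _gompertz,
}


def _as_arrays(series: Iterable) -> tuple[np.ndarray, np.ndarray]:
    pairs = np.asarray([(float(t), float(a)) for t, a in series], dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("series must be (time, area) pairs")
    order = np.argsort(pairs[:, 0], kind="stable")
    return pairs[order, 0], pairs[order, 1]


def fit_growth(series: Iterable, family: str = "logistic") -> GrowthFit:
    """Least-squares sigmoid fit of a surface-area time series.

    Initialisation is deterministic and data-driven: a_max starts at 1.05x
    the largest observed area, t_mid at the time the series first crosses
    half of that, and k at 4 * max slope / a_max.  Non-convergence raises
    a RuntimeError naming the failed fit.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    t, y = _as_arrays(series)
    if t.size < 4:
        raise ValueError("need at least 4 points to fit a sigmoid")

    a0 = 1.05 * float(y.max())
    # average replicate measurements per time for the init heuristics
    ut, inv = np.unique(t, return_inverse=True)
    uy = np.bincount(inv, weights=y) / np.bincount(inv)
    above = np.nonzero(uy >= a0 / 2.0)[0]
    t_mid0 = float(ut[above[0]]) if above.size else float(ut[-1])
    if ut.size > 1:
        slopes = np.diff(uy) / np.diff(ut)
        k0 = 4.0 * max(float(slopes.max()), 1e-6) / a0
    else:
        k0 = 0.05
    k0 = float(np.clip(k0, 1e-4, 5.0))

    model = _MODEL[family]
    span = float(ut[-1] - ut[0]) if ut.size > 1 else 1.0
    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=(a0, k0, t_mid0),
            bounds=(
                (1e-9, 1e-9, ut[0] - 5 * span),
                (np.inf, 10.0, ut[-1] + 5 * span),
            ),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"{family} growth fit did not converge: {err}") from err

    a_max, k, t_mid = (float(v) for v in popt)
    resid = y - model(t, a_max, k, t_mid)
    dof = max(t.size - 3, 1)
    residual_sd = float(np.sqrt((resid**2).sum() / dof))
    peak = a_max * k / 4.0 if family == "logistic" else a_max * k / math.e
    return GrowthFit(
        a_max_cm2=a_max,
        k_per_d=k,
        t_mid_dafb=t_mid,
        residual_sd_cm2=residual_sd,
        peak_rate_cm2_per_d=peak,
        t_peak_dafb=t_mid,
        family=family,
    )


def growth_rate_curve(
    fit: GrowthFit, times: Sequence[float]
) -> list[tuple[float, float]]:
    """Analytic growth rate (cm^2 d^-1) at each requested time.

    Logistic: a_max k e^{-k(t-t_mid)} / (1 + e^{-k(t-t_mid)})^2, symmetric
    about t_mid where it attains a_max k / 4.
    """
    t = np.asarray(list(times), dtype=float)
    z = np.exp(-fit.k_per_d * (t - fit.t_mid_dafb))
    if fit.family == "logistic":
        rate = fit.a_max_cm2 * fit.k_per_d * z / (1.0 + z) ** 2
    elif fit.family == "gompertz":
        rate = fit.a_max_cm2 * fit.k_per_d * z * np.exp(-z)
    else:  # pragma: no cover - guarded in fit_growth
        raise ValueError(f"unknown family {fit.family!r}")
    return [(float(ti), float(ri)) for ti, ri in zip(t, rate)]


def lenticels_per_fruit(
    frequency_per_mm2: float, surface_area_cm2: float
) -> float:
    """Whole-fruit lenticel count: areal frequency x fruit surface area."""
    if frequency_per_mm2 < 0 or surface_area_cm2 < 0:
        raise ValueError("inputs must be non-negative")
    return frequency_per_mm2 * surface_area_cm2 * 100.0  # cm^2 -> mm^2
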