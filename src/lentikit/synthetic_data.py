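"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the measurement structure of a lenticel/russeting
study on 'Apple' mango: calibrated bright-field/fluorescence micrographs
of the fruit surface, sigmoidal whole-fruit surface-area growth, punched
skin-disc areas for strain-relaxation analysis, and per-fruit russeted
surface fractions.  Defaults encode the study conditions for mature
'Apple' mango (lenticel frequency 0.05 mm^-2, mean core area 0.50 mm^2)
so that a default run exercises realistic magnitudes.

Every generator is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image_morphometry import CalibratedImage
from .strain_relaxation import (
    LenticelStrainSample,
    StrainSample,
    punch_area_mm2,
)

# rendered intensities (fraction of dynamic range)
_BG_BRIGHT = 0.85
_CORE_LEVEL = 0.45
_PORE_LEVEL = 0.10
_BG_FLUOR = 0.02
_HALO_LEVEL = 0.85
_HALO_EDGE_SIGMA_PX = 1.5


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic fruit-surface scene.

    Core areas are lognormal (positive, right-skewed, CV-parameterised).
    Pore area is a lognormal fraction of its core; ``pore_ratio_cv``
    controls the scatter of that fraction and thereby the pore-vs-core
    correlation strength (the default reproduces the strong positive
    correlation, r^2 ~ 0.79, observed on mature fruit when the core CV is
    0.5).  A ``halo_fraction`` of the lenticels receive a fluorescent halo
    (moisture-induced tracer infiltration) of ``halo_area_multiple`` times
    their core area.
    """

    field_width_mm: float = 10.0
    field_height_mm: float = 10.0
    scale_um_per_px: float = 10.0
    lenticel_frequency_per_mm2: float = 0.05
    core_area_mean_mm2: float = 0.50
    core_area_cv: float = 0.5
    pore_to_core_ratio: float = 0.30
    pore_ratio_cv: float = 0.23
    halo_fraction: float = 0.5
    halo_area_multiple: float = 3.0
    background_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.field_width_mm > 0 and self.field_height_mm > 0):
            raise ValueError("field dimensions must be positive")
        if not self.scale_um_per_px > 0:
            raise ValueError("scale_um_per_px must be positive")
        if self.lenticel_frequency_per_mm2 < 0:
            raise ValueError("lenticel_frequency_per_mm2 must be >= 0")
        if not (self.core_area_mean_mm2 > 0 and self.core_area_cv >= 0):
            raise ValueError("core-area distribution parameters invalid")
        if not 0 < self.pore_to_core_ratio < 1:
            raise ValueError("pore_to_core_ratio must lie in (0, 1)")
        if self.pore_ratio_cv < 0:
            raise ValueError("pore_ratio_cv must be >= 0")
        if not 0 <= self.halo_fraction <= 1:
            raise ValueError("halo_fraction must lie in [0, 1]")
        if self.halo_area_multiple < 0:
            raise ValueError("halo_area_multiple must be >= 0")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")

    @property
    def field_area_mm2(self) -> float:
        return self.field_width_mm * self.field_height_mm


@dataclass(frozen=True)
class PlantedLenticel:
    """Ground truth for one planted lenticel."""

    lenticel_id: int
    x_mm: float
    y_mm: float
    core_area_mm2: float
    pore_area_mm2: float
    halo_area_mm2: float | None
    aspect: float
    theta_rad: float


@dataclass(frozen=True)
class GroundTruth:
    """What was planted in a scene."""

    lenticels: tuple[PlantedLenticel, ...]
    field_area_mm2: float

    @property
    def count(self) -> int:
        return len(self.lenticels)

    @property
    def frequency_per_mm2(self) -> float:
        return self.count / self.field_area_mm2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "lenticel_id": l.lenticel_id,
                    "x_mm": l.x_mm,
                    "y_mm": l.y_mm,
                    "core_area_mm2": l.core_area_mm2,
                    "pore_area_mm2": l.pore_area_mm2,
                    "halo_area_mm2": (
                        l.halo_area_mm2 if l.halo_area_mm2 is not None else np.nan
                    ),
                }
                for l in self.lenticels
            ],
            columns=[
                "lenticel_id",
                "x_mm",
                "y_mm",
                "core_area_mm2",
                "pore_area_mm2",
                "halo_area_mm2",
            ],
        )


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """Lognormal samples with the given arithmetic mean and CV."""
    if cv == 0:
        return np.full(n, mean)
    sigma2 = math.log(1.0 + cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), n)


def sample_lenticel_population(
    rng: np.random.Generator, n: int, spec: SceneSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (core_area, pore_area) pairs in mm^2 from the scene model."""
    spec = spec or SceneSpec()
    core = _lognormal(rng, spec.core_area_mean_mm2, spec.core_area_cv, n)
    ratio = spec.pore_to_core_ratio * _lognormal(rng, 1.0, spec.pore_ratio_cv, n)
    ratio = np.clip(ratio, 0.01, 0.90)
    return core, ratio * core


def _fill_ellipse(
    img: np.ndarray,
    cx_mm: float,
    cy_mm: float,
    a_mm: float,
    b_mm: float,
    theta: float,
    value: float,
    px_mm: float,
) -> None:
    """Paint a filled rotated ellipse (semi-axes a >= b, in mm) onto img."""
    ny, nx = img.shape
    r_mm = max(a_mm, b_mm)
    r0 = max(int((cy_mm - r_mm) / px_mm) - 1, 0)
    r1 = min(int((cy_mm + r_mm) / px_mm) + 2, ny)
    c0 = max(int((cx_mm - r_mm) / px_mm) - 1, 0)
    c1 = min(int((cx_mm + r_mm) / px_mm) + 2, nx)
    if r0 >= r1 or c0 >= c1:
        return
    yy = (np.arange(r0, r1) + 0.5) * px_mm - cy_mm
    xx = (np.arange(c0, c1) + 0.5) * px_mm - cx_mm
    X, Y = np.meshgrid(xx, yy)
    ct, st = math.cos(theta), math.sin(theta)
    xr = X * ct + Y * st
    yr = -X * st + Y * ct
    inside = (xr / a_mm) ** 2 + (yr / b_mm) ** 2 <= 1.0
    sub = img[r0:r1, c0:c1]
    sub[inside] = value


def generate_surface_scene(
    spec: SceneSpec,
) -> tuple[CalibratedImage, CalibratedImage, GroundTruth]:
    """Render one bright-field + fluorescence scene with ground truth.

    Lenticel cores are filled ellipses (random aspect 1-2, random
    orientation) dark on a bright background, each containing a darker
    concentric pore ellipse.  Halo-assigned lenticels carry a bright disk
    of the requested area in the fluorescence channel, with a smoothed
    edge whose half-maximum boundary encloses exactly the ground-truth
    halo area.  Placement is uniform rejection sampling with a non-overlap
    constraint; a field too small for the requested density raises.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.lenticel_frequency_per_mm2 * spec.field_area_mm2))
    W, H = spec.field_width_mm, spec.field_height_mm
    px_mm = spec.scale_um_per_px / 1000.0
    ny = int(round(H / px_mm))
    nx = int(round(W / px_mm))

    core, pore = sample_lenticel_population(rng, n, spec)
    has_halo = rng.random(n) < spec.halo_fraction
    halo = np.where(has_halo, spec.halo_area_multiple * core, np.nan)
    aspect = rng.uniform(1.0, 2.0, n)
    theta = rng.uniform(0.0, math.pi, n)

    # effective keep-out radius: whole lenticel (and halo) stays inside the
    # field and clear of its neighbours
    a_core = np.sqrt(core * aspect / math.pi)
    r_halo = np.where(has_halo, np.sqrt(np.nan_to_num(halo) / math.pi), 0.0)
    keep = np.maximum(a_core, r_halo)

    margin = 0.1  # mm of clearance between neighbours
    xs = np.empty(n)
    ys = np.empty(n)
    for i in range(n):
        if 2 * (keep[i] + margin) >= min(W, H):
            raise ValueError("field too crowded: lenticel larger than field")
        placed = False
        for _ in range(1000):
            x = rng.uniform(keep[i] + margin, W - keep[i] - margin)
            y = rng.uniform(keep[i] + margin, H - keep[i] - margin)
            d2 = (xs[:i] - x) ** 2 + (ys[:i] - y) ** 2
            if i == 0 or np.all(d2 > (keep[:i] + keep[i] + margin) ** 2):
                xs[i], ys[i] = x, y
                placed = True
                break
        if not placed:
            raise ValueError("field too crowded: could not place all lenticels")

    bf = np.full((ny, nx), _BG_BRIGHT)
    halo_layer = np.zeros((ny, nx))
    for i in range(n):
        a = math.sqrt(core[i] * aspect[i] / math.pi)
        b = math.sqrt(core[i] / (aspect[i] * math.pi))
        _fill_ellipse(bf, xs[i], ys[i], a, b, theta[i], _CORE_LEVEL, px_mm)
        ap = math.sqrt(pore[i] * aspect[i] / math.pi)
        bp = math.sqrt(pore[i] / (aspect[i] * math.pi))
        _fill_ellipse(bf, xs[i], ys[i], ap, bp, theta[i], _PORE_LEVEL, px_mm)
        if has_halo[i]:
            rh = math.sqrt(halo[i] / math.pi)
            _fill_ellipse(halo_layer, xs[i], ys[i], rh, rh, 0.0, 1.0, px_mm)

    fl = _BG_FLUOR + _HALO_LEVEL * gaussian_filter(
        halo_layer, sigma=_HALO_EDGE_SIGMA_PX
    )
    if spec.background_noise_sd > 0:
        bf = bf + rng.normal(0.0, spec.background_noise_sd, bf.shape)
        fl = fl + rng.normal(0.0, spec.background_noise_sd, fl.shape)
    bf = np.clip(bf, 0.0, 1.0)
    fl = np.clip(fl, 0.0, 1.0)

    truth = GroundTruth(
        lenticels=tuple(
            PlantedLenticel(
                lenticel_id=i + 1,
                x_mm=float(xs[i]),
                y_mm=float(ys[i]),
                core_area_mm2=float(core[i]),
                pore_area_mm2=float(pore[i]),
                halo_area_mm2=float(halo[i]) if has_halo[i] else None,
                aspect=float(aspect[i]),
                theta_rad=float(theta[i]),
            )
            for i in range(n)
        ),
        field_area_mm2=spec.field_area_mm2,
    )
    brightfield = CalibratedImage(bf, spec.scale_um_per_px, "brightfield")
    fluorescence = CalibratedImage(fl, spec.scale_um_per_px, "fluorescence")
    return brightfield, fluorescence, truth


def logistic_area(
    t: np.ndarray | float, a_max: float, k: float, t_mid: float
) -> np.ndarray | float:
    """Logistic surface-area model a_max / (1 + exp(-k (t - t_mid)))."""
    return a_max / (1.0 + np.exp(-k * (np.asarray(t, dtype=float) - t_mid)))


def generate_growth_series(
    a_max: float,
    k: float,
    t_mid: float,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Surface-area time series (DAFB, cm^2) on a logistic with Gaussian noise.

    With ``noise_sd = 0`` the series lies exactly on the logistic.
    """
    if not (a_max > 0 and k > 0):
        raise ValueError("a_max and k must be positive")
    times = np.asarray(list(times), dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    area = logistic_area(times, a_max, k, t_mid)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        area = area + rng.normal(0.0, noise_sd, times.size)
    return [(float(t), float(a)) for t, a in zip(times, area)]


def generate_strain_samples(
    true_eps_exc_iso: float,
    true_eps_extr: float,
    punch_diameter_mm: float = 8.0,
    cv: float = 0.0,
    n: int = 30,
    seed: int = 0,
    has_lenticels: bool = True,
) -> list[StrainSample]:
    """Back-solve skin-disc area triplets that carry the requested strains.

    The in-situ area A is the punch cross-section; A_DCM and A_CM are
    derived so that the apparent-strain equations return the true strains
    exactly, then both measured areas receive multiplicative Gaussian
    noise of coefficient of variation ``cv`` (cv = 0 gives an exact
    round-trip).
    """
    if true_eps_exc_iso <= -100 or true_eps_extr <= -100:
        raise ValueError("strains must exceed -100%")
    if n < 1:
        raise ValueError("n must be >= 1")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    a = punch_area_mm2(punch_diameter_mm)
    eps_tot = true_eps_exc_iso + true_eps_extr
    a_dcm = a / (1.0 + eps_tot / 100.0)
    a_cm = a_dcm * (1.0 + true_eps_extr / 100.0)
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        if cv > 0:
            f_cm = max(1.0 + cv * rng.standard_normal(), 0.05)
            f_dcm = max(1.0 + cv * rng.standard_normal(), 0.05)
        else:
            f_cm = f_dcm = 1.0
        samples.append(
            StrainSample(
                a_initial_mm2=a,
                a_cm_mm2=a_cm * f_cm,
                a_dcm_mm2=a_dcm * f_dcm,
                has_lenticels=has_lenticels,
                sample_id=f"{'wl' if has_lenticels else 'nl'}-{i + 1:03d}",
            )
        )
    return samples


def generate_lenticel_core_pairs(
    n: int = 24,
    slope: float = 0.74,
    noise_sd_mm2: float = 0.024,
    core_area_mean_mm2: float = 0.50,
    core_area_cv: float = 0.5,
    seed: int = 0,
) -> list[LenticelStrainSample]:
    """Isolated/dewaxed lenticel-core area pairs with a linear relation.

    The dewaxed core area is ``slope`` times the isolated core area plus
    Gaussian scatter (zero intercept); the defaults emulate the tight
    proportionality observed between dewaxed and isolated core areas on
    mature fruit, with scatter sized to the reported slope precision at
    n = 24 discs.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < slope:
        raise ValueError("slope must be positive")
    if noise_sd_mm2 < 0:
        raise ValueError("noise_sd_mm2 must be >= 0")
    rng = np.random.default_rng(seed)
    a_il = _lognormal(rng, core_area_mean_mm2, core_area_cv, n)
    a_dl = slope * a_il + rng.normal(0.0, noise_sd_mm2, n)
    a_dl = np.maximum(a_dl, 1e-3)
    return [
        LenticelStrainSample(float(x), float(y)) for x, y in zip(a_il, a_dl)
    ]


def generate_russet_population(
    mean_fraction: float, sd: float, n: int, seed: int = 0
) -> list[float]:
    """Russeted-surface fractions (%) for ``n`` fruit, clipped to [0, 100].

    Gaussian on the fraction scale with clipping at the physical bounds;
    a population mean of 0 with sd 0 gives a fully russet-free lot.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    fractions = np.clip(rng.normal(mean_fraction, sd, n), 0.0, 100.0)
    return [float(f) for f in fractions]
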