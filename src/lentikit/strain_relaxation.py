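"""Strain-relaxation calculus for excised fruit-skin discs.

When an epidermal segment (ES) is punched from a growing fruit, the skin
is under elastic strain: the disc shrinks on excision, shrinks further
when the cuticular membrane (CM) is enzymatically isolated, and shrinks
again when the cuticular waxes are extracted (dewaxed CM, DCM).  All
strains are *apparent* strains referenced to the fully relaxed (dewaxed)
area:

    eps'_exc+iso = (A - A_CM) / A_DCM * 100
    eps'_extr    = (A_CM - A_DCM) / A_DCM * 100
    eps'_tot     = eps'_exc+iso + eps'_extr  =  (A - A_DCM) / A_DCM * 100

where A is the in-situ disc area (the punch cross-section), A_CM the
isolated-cuticle area and A_DCM the dewaxed area.  Note that the first
strain is deliberately referenced to A_DCM, not A_CM — the sum then
telescopes exactly.  The same relative-area form applies to a single
lenticel core measured before and after wax extraction:

    eps'_lenticel = (A'_IL - A'_DL) / A'_DL * 100

Because dewaxed cuticle discs tend to curl at the rim, A_DCM is best
reconstructed from a square pattern of four holes punched in the disc
centre: the hole-pattern area shrinks by the same factor as the disc, so
A_DCM = A_CM * (holes_DCM / holes_CM).

Negative strains (swelling) are physically possible under measurement
noise and are returned unclamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Cross-sectional area (mm^2) of the nominal 8 mm biopsy punch.
PUNCH_DIAMETER_MM = 8.0


def punch_area_mm2(diameter_mm: float = PUNCH_DIAMETER_MM) -> float:
    """Cross-sectional area of a circular biopsy punch."""
    if not diameter_mm > 0:
        raise ValueError("punch diameter must be positive")
    return math.pi * (diameter_mm / 2.0) ** 2


@dataclass
class StrainSample:
    """Area quintet for one skin disc.

    ``a_dcm_mm2`` may be omitted when the two hole-pattern areas are given;
    it is then reconstructed with :func:`dcm_area_from_holes` (the
    preferred route, robust to rim curling).
    """

    a_initial_mm2: float
    a_cm_mm2: float
    a_dcm_mm2: float | None = None
    holes_cm_mm2: float | None = None
    holes_dcm_mm2: float | None = None
    has_lenticels: bool = True
    sample_id: str | None = None

    def __post_init__(self) -> None:
        for name in ("a_initial_mm2", "a_cm_mm2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def resolved_dcm_mm2(self) -> float:
        """A_DCM, reconstructed from the hole pattern when available."""
        if self.holes_cm_mm2 is not None and self.holes_dcm_mm2 is not None:
            return dcm_area_from_holes(
                self.a_cm_mm2, self.holes_cm_mm2, self.holes_dcm_mm2
            )
        if self.a_dcm_mm2 is None:
            raise ValueError(
                "sample provides neither a_dcm_mm2 nor a hole-pattern pair"
            )
        return self.a_dcm_mm2


@dataclass
class StrainResult:
    """The three apparent strains (%) for one disc; the total is exact."""

    eps_exc_iso_pct: float
    eps_extr_pct: float
    eps_tot_pct: float


@dataclass
class LenticelStrainSample:
    """Core area of one lenticel after isolation and after wax extraction."""

    a_core_isolated_mm2: float
    a_core_dewaxed_mm2: float
    eps_lenticel_pct: float | None = None

    def __post_init__(self) -> None:
        if not (self.a_core_isolated_mm2 > 0 and self.a_core_dewaxed_mm2 > 0):
            raise ValueError("lenticel core areas must be positive")


def dcm_area_from_holes(
    a_cm_mm2: float, holes_cm_mm2: float, holes_dcm_mm2: float
) -> float:
    """Reconstruct the dewaxed-disc area from the four-hole pattern.

    The square hole pattern relaxes by the same areal factor as the whole
    disc, so A_DCM = A_CM * (holes_DCM / holes_CM).
    """
    if not (a_cm_mm2 > 0 and holes_cm_mm2 > 0 and holes_dcm_mm2 > 0):
        raise ValueError("all areas must be positive")
    return a_cm_mm2 * (holes_dcm_mm2 / holes_cm_mm2)


def strain_exc_iso(s: StrainSample) -> float:
    """Apparent strain (%) released by excision plus cuticle isolation."""
    a_dcm = s.resolved_dcm_mm2()
    if not a_dcm > 0:
        raise ValueError("A_DCM must be positive")
    return (s.a_initial_mm2 - s.a_cm_mm2) / a_dcm * 100.0


def strain_extr(s: StrainSample) -> float:
    """Apparent strain (%) released by wax extraction."""
    a_dcm = s.resolved_dcm_mm2()
    if not a_dcm > 0:
        raise ValueError("A_DCM must be positive")
    return (s.a_cm_mm2 - a_dcm) / a_dcm * 100.0


def strain_total(eps_exc_iso_pct: float, eps_extr_pct: float) -> float:
    """Total apparent strain (%): the sum of the two components.

    Algebraically identical to (A - A_DCM)/A_DCM * 100.
    """
    return eps_exc_iso_pct + eps_extr_pct


def compute_strains(s: StrainSample) -> StrainResult:
    """All three apparent strains for one disc."""
    e1 = strain_exc_iso(s)
    e2 = strain_extr(s)
    return StrainResult(e1, e2, strain_total(e1, e2))


def strain_lenticel(l: LenticelStrainSample) -> float:
    """Apparent strain (%) released from a single lenticel core."""
    if not l.a_core_dewaxed_mm2 > 0:
        raise ValueError("dewaxed core area must be positive")
    return (
        (l.a_core_isolated_mm2 - l.a_core_dewaxed_mm2)
        / l.a_core_dewaxed_mm2
        * 100.0
    )


_GROUP_LABELS = {True: "with_lenticels", False: "without_lenticels"}


def compare_groups(samples: Iterable[StrainSample]) -> pd.DataFrame:
    """Group summary (mean +/- SE) of the three strains, with vs without lenticels.

    Returns a DataFrame indexed by ``with_lenticels`` / ``without_lenticels``
    plus a ``ratio_with_over_without`` row giving the ratio of group means
    for each strain component.
    """
    rows: dict[str, list[StrainResult]] = {v: [] for v in _GROUP_LABELS.values()}
    for s in samples:
        rows[_GROUP_LABELS[bool(s.has_lenticels)]].append(compute_strains(s))
    for name, group in rows.items():
        if len(group) < 2:
            raise ValueError(f"group {name!r} needs at least 2 samples")

    columns = ("eps_exc_iso_pct", "eps_extr_pct", "eps_tot_pct")
    table: dict[str, dict[str, float]] = {}
    for name, group in rows.items():
        rec: dict[str, float] = {"n": len(group)}
        for col in columns:
            vals = np.array([getattr(r, col) for r in group])
            rec[f"{col}_mean"] = float(vals.mean())
            rec[f"{col}_se"] = float(vals.std(ddof=1) / math.sqrt(len(vals)))
        table[name] = rec

    ratio: dict[str, float] = {"n": float("nan")}
    for col in columns:
        ratio[f"{col}_mean"] = (
            table["with_lenticels"][f"{col}_mean"]
            / table["without_lenticels"][f"{col}_mean"]
        )
        ratio[f"{col}_se"] = float("nan")
    table["ratio_with_over_without"] = ratio
    df = pd.DataFrame.from_dict(table, orient="index")
    df.index.name = "group"
    return df
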