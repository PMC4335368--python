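"""Ventricular measures from segmentation masks.

Volumes use slice summation (Simpson's method on the short-axis stack): the
cavity or myocardial area of each kept slice is multiplied by the effective
slice spacing (slice thickness plus inter-slice gap). Mass is myocardial
volume times a fixed tissue density; the left-ventricular mass (LVM) is
measured at end-diastole only, from the epicardial and endocardial contours.

The two contouring conventions are:

* ``minc`` — papillary muscles and trabeculations (P&T) count as myocardium:
  the cavity is the blood-only pool and LVM includes the P&T mass.
* ``mex``  — P&T count as blood pool: the cavity is bounded by the smooth
  compacted-myocardium contour and LVM is the compact wall only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .exceptions import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import CineStack
    from .segmentation import SegmentationResult

#: Conventional myocardial tissue density, g/ml.
MYOCARDIAL_DENSITY = 1.05

METHODS = ("minc", "mex")


@dataclass
class QuantConfig:
    myocardial_density: float = MYOCARDIAL_DENSITY  # g/ml
    bsa_formula: str = "mosteller"

    def __post_init__(self) -> None:
        if self.myocardial_density <= 0:
            raise ValidationError("myocardial_density must be > 0")
        if self.bsa_formula != "mosteller":
            raise ValidationError(f"unsupported BSA formula {self.bsa_formula!r}")


@dataclass
class VentricularMeasures:
    """One method's ventricular volumes, function and mass for one subject."""

    method: str
    lvedv: float        # ml
    lvesv: float        # ml
    lvm: float          # g
    lvm_indexed: float  # g/m^2 (NaN when no body-surface area is available)
    pnt_mass: float     # g (0 by construction for mex)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"method must be one of {METHODS}")
        if self.lvedv <= 0:
            raise ValidationError("lvedv must be positive")
        if self.lvesv < 0 or self.lvm < 0 or self.pnt_mass < 0:
            raise ValidationError("volumes and masses must be non-negative")

    @property
    def lvsv(self) -> float:
        """Stroke volume, strictly EDV - ESV (ml)."""
        return self.lvedv - self.lvesv

    @property
    def lvef(self) -> float:
        """Ejection fraction, percent."""
        return 100.0 * self.lvsv / self.lvedv

    @property
    def pnt_fraction(self) -> float:
        """P&T share of total LVM, percent."""
        return 100.0 * self.pnt_mass / self.lvm if self.lvm > 0 else 0.0

    def rounded(self) -> dict:
        """Values at the reporting precision (integers for ml, g, %)."""
        out = {
            "method": self.method,
            "lvedv": round(self.lvedv),
            "lvesv": round(self.lvesv),
            "lvsv": round(self.lvsv),
            "lvef": round(self.lvef),
            "lvm": round(self.lvm),
            "pnt_fraction": round(self.pnt_fraction),
        }
        out["lvm_indexed"] = (
            round(self.lvm_indexed) if np.isfinite(self.lvm_indexed) else float("nan")
        )
        return out


def slice_summation_volume(
    areas: Sequence[float], slice_thickness: float, slice_gap: float
) -> float:
    """Simpson slice-summation volume in ml from per-slice areas in mm^2.

    The effective per-slice extent is thickness + gap (each slice's area
    represents one centre-to-centre spacing interval).
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size and areas.min() < 0:
        raise ValidationError("slice areas must be non-negative")
    return float(areas.sum() * (slice_thickness + slice_gap) / 1000.0)


def myocardial_mass(myocardial_volume_ml: float, config: QuantConfig | None = None) -> float:
    """Myocardial mass in g from volume in ml."""
    config = config or QuantConfig()
    if myocardial_volume_ml < 0:
        raise ValidationError("myocardial volume must be non-negative")
    return myocardial_volume_ml * config.myocardial_density


def body_surface_area(height_cm: float, weight_kg: float,
                      config: QuantConfig | None = None) -> float:
    """Body surface area in m^2 (Mosteller formula)."""
    config = config or QuantConfig()
    if height_cm <= 0 or weight_kg <= 0:
        raise ValidationError("height and weight must be positive")
    return float(np.sqrt(height_cm * weight_kg / 3600.0))


def pnt_fraction(lvm_inc: float, lvm_ex: float) -> float:
    """Percent of M_inc LVM attributable to papillary muscles/trabeculations."""
    if lvm_ex <= 0:
        raise ValidationError("lvm_ex must be positive")
    if lvm_ex > lvm_inc:
        raise ValidationError("lvm_ex cannot exceed lvm_inc")
    return 100.0 * (lvm_inc - lvm_ex) / lvm_inc


def ventricular_measures(
    seg: "SegmentationResult",
    cine: "CineStack",
    method: str,
    config: QuantConfig | None = None,
    bsa: float | None = None,
) -> VentricularMeasures:
    """Compute one method's measures from a segmentation of one subject."""
    config = config or QuantConfig()
    if method not in METHODS:
        raise ValidationError(f"method must be one of {METHODS}")
    px_area = cine.pixel_spacing**2

    def volume(masks) -> float:
        areas = [float(m.sum()) * px_area for m in masks]
        return slice_summation_volume(areas, cine.slice_thickness, cine.slice_gap)

    if method == "minc":
        if seg.minc_area_ed is not None:
            edv = slice_summation_volume(seg.minc_area_ed, cine.slice_thickness, cine.slice_gap)
        else:
            edv = volume(seg.minc_cavity_ed)
        if seg.minc_area_es is not None:
            esv = slice_summation_volume(seg.minc_area_es, cine.slice_thickness, cine.slice_gap)
        else:
            esv = volume(seg.minc_cavity_es)
        cavity_ed = edv
    else:
        # sub-pixel refined areas when the segmentation provides them
        if seg.mex_area_ed is not None:
            edv = slice_summation_volume(seg.mex_area_ed, cine.slice_thickness, cine.slice_gap)
        else:
            edv = volume(seg.mex_cavity_ed)
        if seg.mex_area_es is not None:
            esv = slice_summation_volume(seg.mex_area_es, cine.slice_thickness, cine.slice_gap)
        else:
            esv = volume(seg.mex_cavity_es)
        cavity_ed = edv
    if edv <= 0:
        raise ValidationError("end-diastolic cavity volume is zero")

    epi_vol = volume(list(seg.epicardial_ed) + list(seg.epicardial_apex))
    lvm = myocardial_mass(max(epi_vol - cavity_ed, 0.0), config)
    if method == "minc":
        pnt_vol = volume(seg.pnt_ed)
        pnt_mass = myocardial_mass(pnt_vol, config)
    else:
        pnt_mass = 0.0

    lvm_indexed = lvm / bsa if bsa else float("nan")
    return VentricularMeasures(
        method=method,
        lvedv=edv,
        lvesv=esv,
        lvm=lvm,
        lvm_indexed=lvm_indexed,
        pnt_mass=min(pnt_mass, lvm),
    )
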