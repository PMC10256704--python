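"""Dynamic-threshold calcification detection on axial CT slices.

The detection model: on each slice, a central lumen sampling zone gives a
blood-pool reference (mean and SD of attenuation in Hounsfield units).
Calcification is any connected region of aortic pixels whose attenuation
exceeds the reference mean by more than five reference SDs. Anchoring the
cutoff to the lumen makes detection robust to intravenous contrast, which
raises lumen and threshold together while plaque stays near its intrinsic
attenuation.

Masks are inputs; no segmentation is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateReferenceError, InputError

LEVELS = ("L1", "L2", "L3", "L4")

#: Number of reference SDs above the lumen mean that defines calcification.
THRESHOLD_N_SD = 5.0


@dataclass(frozen=True)
class AxialSlice:
    """One axial CT cross-section in HU with pixel geometry.

    Parameters
    ----------
    hu : 2-D float array
        Attenuation in Hounsfield units.
    pixel_spacing : (row, col) in mm/pixel.
    slice_thickness : slice height in mm.
    vertebral_level : one of ``L1``..``L4``, or None for unlabeled slices.
    """

    hu: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    vertebral_level: str | None = None

    def __post_init__(self):
        if self.hu.ndim != 2:
            raise InputError("hu grid must be 2-D")
        if not np.all(np.isfinite(self.hu)):
            raise InputError("hu grid contains non-finite values")
        if min(self.pixel_spacing) <= 0 or self.slice_thickness <= 0:
            raise InputError("pixel spacing and slice thickness must be positive")
        if self.vertebral_level is not None and self.vertebral_level not in LEVELS:
            raise InputError(f"unknown vertebral level {self.vertebral_level!r}")

    @property
    def pixel_area(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1]


@dataclass(frozen=True)
class AortaMask:
    """Boolean masks for one slice: the full vessel and its lumen sampling zone."""

    lumen_zone: np.ndarray
    aorta: np.ndarray

    def __post_init__(self):
        if self.lumen_zone.shape != self.aorta.shape:
            raise InputError("lumen_zone and aorta masks differ in shape")
        if np.any(self.lumen_zone & ~self.aorta):
            raise InputError("lumen_zone must be a subset of the aorta mask")


@dataclass(frozen=True)
class LumenReference:
    """Blood-pool attenuation statistics from the lumen sampling zone."""

    mean_hu: float
    sd_hu: float
    n_pixels: int


@dataclass(frozen=True)
class Region:
    n_pixels: int
    area_mm2: float


@dataclass(frozen=True)
class CalcificationMap:
    mask: np.ndarray
    regions: tuple[Region, ...]
    threshold_hu: float

    @property
    def total_area(self) -> float:
        return float(sum(r.area_mm2 for r in self.regions))


@dataclass(frozen=True)
class SliceMetrics:
    calc_area: float
    mean_attenuation: float
    n_regions: int


@dataclass(frozen=True)
class LevelMetrics:
    level: str
    calc_area: float
    calc_volume: float
    mean_attenuation: float
    n_slices: int
    total_wall_area: float | None = None
    wall_calc_pct: float | None = None


@dataclass(frozen=True)
class ParticipantMetrics:
    levels: dict[str, LevelMetrics]
    l1l4_calc_area: float
    l1l4_calc_volume: float
    l1l4_mean_attenuation: float
    l1l4_total_wall_area: float | None
    l1l4_wall_calc_pct: float | None
    zero_calcification: bool


def compute_lumen_reference(slc: AxialSlice, mask: AortaMask) -> LumenReference:
    """Sample mean and SD (n-1 denominator) of HU over the lumen zone."""
    vals = slc.hu[mask.lumen_zone]
    if vals.size < 2:
        raise DegenerateReferenceError(
            f"lumen zone has {vals.size} pixels; need at least 2"
        )
    return LumenReference(
        mean_hu=float(vals.mean()),
        sd_hu=float(vals.std(ddof=1)),
        n_pixels=int(vals.size),
    )


def calcification_threshold(ref: LumenReference, n_sd: float = THRESHOLD_N_SD) -> float:
    """Dynamic cutoff: lumen mean plus ``n_sd`` lumen SDs."""
    return ref.mean_hu + n_sd * ref.sd_hu


def detect_calcification(
    slc: AxialSlice,
    mask: AortaMask,
    threshold: float,
    min_region_px: int = 1,
    connectivity: int = 8,
    search_domain: str = "aorta-minus-lumen",
) -> CalcificationMap:
    """Threshold + connected components within the vessel wall search domain.

    Candidate pixels are those strictly above ``threshold`` inside the search
    domain (by default the aorta minus the lumen sampling zone, so a
    contrast-bright lumen cannot self-trigger). Components are labeled under
    4- or 8-connectivity and those smaller than ``min_region_px`` discarded.
    """
    if slc.hu.shape != mask.aorta.shape:
        raise InputError("hu grid and masks differ in shape")
    if connectivity not in (4, 8):
        raise InputError("connectivity must be 4 or 8")
    if search_domain == "aorta-minus-lumen":
        domain = mask.aorta & ~mask.lumen_zone
    elif search_domain == "aorta":
        domain = mask.aorta
    else:
        raise InputError(f"unknown search domain {search_domain!r}")

    candidates = domain & (slc.hu > threshold)
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    labels, n = ndimage.label(candidates, structure=structure)

    px_area = slc.pixel_area
    keep = np.zeros_like(candidates)
    regions: list[Region] = []
    if n:
        counts = np.bincount(labels.ravel())[1:]
        for lab, cnt in enumerate(counts, start=1):
            if cnt >= min_region_px:
                keep |= labels == lab
                regions.append(Region(n_pixels=int(cnt), area_mm2=float(cnt) * px_area))
    return CalcificationMap(mask=keep, regions=tuple(regions), threshold_hu=float(threshold))


def slice_metrics(slc: AxialSlice, mask: AortaMask, calc: CalcificationMap) -> SliceMetrics:
    """Per-slice calcified area (mm^2) and mean attenuation over the full vessel."""
    return SliceMetrics(
        calc_area=calc.total_area,
        mean_attenuation=float(slc.hu[mask.aorta].mean()),
        n_regions=len(calc.regions),
    )


def aggregate_level(
    metrics: list[SliceMetrics],
    level: str,
    slice_thickness: float,
    total_wall_area: float | None = None,
    wall_calc_pct: float | None = None,
) -> LevelMetrics | None:
    """Collapse a level's slices: mean area, summed volume, mean attenuation.

    An empty slice list marks the level as missing (returns None) rather than
    raising, mirroring cohorts where scan coverage does not reach every level.
    """
    if not metrics:
        return None
    areas = np.array([m.calc_area for m in metrics])
    return LevelMetrics(
        level=level,
        calc_area=float(areas.mean()),
        calc_volume=float((areas * slice_thickness).sum()),
        mean_attenuation=float(np.mean([m.mean_attenuation for m in metrics])),
        n_slices=len(metrics),
        total_wall_area=total_wall_area,
        wall_calc_pct=wall_calc_pct,
    )


def summarize_participant(levels: dict[str, LevelMetrics]) -> ParticipantMetrics | None:
    """Average each metric over the participant's available levels (L1-L4).

    Returns None when no level is available (the participant is excluded,
    mirroring exclusion of scans without usable lower abdominal levels).
    """
    present = {k: v for k, v in levels.items() if v is not None}
    if not present:
        return None

    def _mean(attr):
        vals = [getattr(m, attr) for m in present.values()]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    return ParticipantMetrics(
        levels=present,
        l1l4_calc_area=_mean("calc_area"),
        l1l4_calc_volume=_mean("calc_volume"),
        l1l4_mean_attenuation=_mean("mean_attenuation"),
        l1l4_total_wall_area=_mean("total_wall_area"),
        l1l4_wall_calc_pct=_mean("wall_calc_pct"),
        zero_calcification=all(m.calc_area == 0 for m in present.values()),
    )
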