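"""Synthetic CT aorta phantoms with exact calcification ground truth.

A phantom slice is a background field holding a circular vessel: a lumen
disc of Gaussian-noise blood-pool attenuation, a noise-free soft-tissue
wall annulus, and zero or more calcified arcs (annulus sectors) overwritten
with a constant plaque attenuation. Rasterization is by pixel-center
membership, so the designed arc pixel set *is* the ground truth the
detector should recover, with no partial-volume ambiguity.

These phantoms stand in for clinical scans that are not distributable;
they emulate contrast phases only through the lumen mean (e.g. 40 HU
unenhanced vs 200 HU enhanced) and make no attempt at CT physics beyond
Gaussian lumen noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .calcium import LEVELS, AortaMask, AxialSlice
from .errors import GeometryError

#: Soft-tissue attenuation of the noise-free wall annulus (HU).
WALL_HU = 40.0
#: Attenuation of everything outside the vessel (HU).
BACKGROUND_HU = -50.0


@dataclass(frozen=True)
class CalcArc:
    """One calcified annulus sector on the inner wall.

    Angles in degrees, counter-clockwise from the image +x axis; the arc
    spans ``[start_angle, start_angle + arc_extent)`` and radially from the
    lumen boundary outward by ``radial_thickness`` mm.
    """

    start_angle: float
    arc_extent: float
    radial_thickness: float
    plaque_hu: float


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic slice; same spec + seed is bit-identical."""

    grid_shape: tuple[int, int] = (128, 128)
    pixel_spacing: tuple[float, float] = (0.5, 0.5)
    slice_thickness: float = 5.0
    lumen_center: tuple[float, float] = (64.0, 64.0)
    lumen_radius: float = 12.0
    wall_thickness: float = 3.0
    lumen_mean_hu: float = 200.0
    lumen_noise_sd: float = 10.0
    background_hu: float = BACKGROUND_HU
    wall_hu: float = WALL_HU
    calc_arcs: tuple[CalcArc, ...] = ()
    vertebral_level: str = "L3"
    seed: int = 0

    def __post_init__(self):
        if self.lumen_radius <= 0 or self.wall_thickness <= 0:
            raise GeometryError("lumen_radius and wall_thickness must be positive")
        if min(self.pixel_spacing) <= 0 or self.slice_thickness <= 0:
            raise GeometryError("spacing and thickness must be positive")
        if self.vertebral_level not in LEVELS:
            raise GeometryError(f"unknown vertebral level {self.vertebral_level!r}")
        thr = self.lumen_mean_hu + 5.0 * self.lumen_noise_sd
        for arc in self.calc_arcs:
            if not 0 < arc.arc_extent <= 360:
                raise GeometryError("arc_extent must lie in (0, 360]")
            if not 0 < arc.radial_thickness <= self.wall_thickness:
                raise GeometryError("radial_thickness must lie in (0, wall_thickness]")
            if arc.plaque_hu <= thr:
                raise GeometryError(
                    "plaque_hu must exceed lumen_mean_hu + 5*lumen_noise_sd "
                    "so designed plaques are detectable by construction"
                )
        # the vessel disc must fit inside the grid
        outer = self.outer_radius
        r0, c0 = self.lumen_center
        sr, sc = self.pixel_spacing
        if (
            r0 * sr < outer
            or c0 * sc < outer
            or (self.grid_shape[0] - 1 - r0) * sr < outer
            or (self.grid_shape[1] - 1 - c0) * sc < outer
        ):
            raise GeometryError("aorta disc extends beyond the pixel grid")

    @property
    def outer_radius(self) -> float:
        return self.lumen_radius + self.wall_thickness


@dataclass(frozen=True)
class PhantomTruth:
    """Designed ground truth for one slice."""

    calc_mask: np.ndarray
    calc_area: float
    calc_wall_fraction: float
    wall_outer_circumference: float


@dataclass(frozen=True)
class PhantomStudy:
    """An ordered slice stack with per-slice level labels and truths."""

    slices: tuple[AxialSlice, ...]
    masks: tuple[AortaMask, ...]
    truths: tuple[PhantomTruth, ...]
    levels: tuple[str, ...]

    def truth_volume_by_level(self) -> dict[str, float]:
        """Ground-truth calcified volume per level: sum of area x thickness."""
        out: dict[str, float] = {}
        for slc, truth, level in zip(self.slices, self.truths, self.levels):
            out[level] = out.get(level, 0.0) + truth.calc_area * slc.slice_thickness
        return out


def _polar_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Radius (mm) and angle (deg, CCW from +x) of every pixel center."""
    rr, cc = np.mgrid[0 : spec.grid_shape[0], 0 : spec.grid_shape[1]]
    sr, sc = spec.pixel_spacing
    x = (cc - spec.lumen_center[1]) * sc
    y = -(rr - spec.lumen_center[0]) * sr  # +y up so angles run CCW on screen
    r = np.hypot(x, y)
    ang = np.degrees(np.arctan2(y, x)) % 360.0
    return r, ang


def _arc_mask(spec: PhantomSpec, arc: CalcArc, r: np.ndarray, ang: np.ndarray) -> np.ndarray:
    rel = (ang - arc.start_angle) % 360.0
    radial = (r > spec.lumen_radius) & (r <= spec.lumen_radius + arc.radial_thickness)
    if arc.arc_extent >= 360.0:
        return radial
    return radial & (rel < arc.arc_extent)


def generate_phantom_slice(spec: PhantomSpec) -> tuple[AxialSlice, AortaMask, PhantomTruth]:
    """Rasterize one phantom slice and its exact ground truth.

    Pixel-center membership decides lumen / wall / plaque, so the truth mask
    and area are exact by construction; ``calc_area`` is the true pixel count
    times pixel area.
    """
    r, ang = _polar_grids(spec)
    lumen = r <= spec.lumen_radius
    wall = (r > spec.lumen_radius) & (r <= spec.outer_radius)
    aorta = lumen | wall

    hu = np.full(spec.grid_shape, spec.background_hu, dtype=float)
    hu[wall] = spec.wall_hu
    rng = np.random.default_rng(spec.seed)
    hu[lumen] = rng.normal(spec.lumen_mean_hu, spec.lumen_noise_sd, int(lumen.sum()))

    calc_mask = np.zeros(spec.grid_shape, dtype=bool)
    for arc in spec.calc_arcs:
        m = _arc_mask(spec, arc, r, ang)
        calc_mask |= m
        hu[m] = arc.plaque_hu

    px_area = spec.pixel_spacing[0] * spec.pixel_spacing[1]
    truth = PhantomTruth(
        calc_mask=calc_mask,
        calc_area=float(calc_mask.sum()) * px_area,
        calc_wall_fraction=min(1.0, sum(a.arc_extent for a in spec.calc_arcs) / 360.0),
        wall_outer_circumference=2.0 * np.pi * spec.outer_radius,
    )
    slc = AxialSlice(
        hu=hu,
        pixel_spacing=spec.pixel_spacing,
        slice_thickness=spec.slice_thickness,
        vertebral_level=spec.vertebral_level,
    )
    mask = AortaMask(lumen_zone=lumen, aorta=aorta)
    return slc, mask, truth


def random_phantom_spec(
    rng: np.random.Generator,
    level: str = "L3",
    max_arcs: int = 3,
    lumen_mean_hu: float = 200.0,
    lumen_noise_sd: float = 10.0,
    **overrides,
) -> PhantomSpec:
    """Draw a random valid phantom spec with non-overlapping calcified arcs.

    Arc extents and gaps are laid out sequentially around the circle so arcs
    never overlap, keeping the angular-fraction ground truth exact. Plaque
    attenuation is drawn well above the detection threshold implied by the
    lumen statistics.
    """
    n_arcs = int(rng.integers(0, max_arcs + 1))
    wall_thickness = float(overrides.pop("wall_thickness", 3.0))
    arcs = []
    if n_arcs:
        extents = rng.uniform(10.0, 300.0 / n_arcs, n_arcs)
        gaps = rng.uniform(2.0, 30.0, n_arcs)
        gaps *= (360.0 - extents.sum()) / gaps.sum()
        start = float(rng.uniform(0.0, 360.0))
        thr = lumen_mean_hu + 5.0 * lumen_noise_sd
        for ext, gap in zip(extents, gaps):
            arcs.append(
                CalcArc(
                    start_angle=start % 360.0,
                    arc_extent=float(ext),
                    radial_thickness=float(rng.uniform(1.0, wall_thickness)),
                    plaque_hu=float(rng.uniform(thr + 100.0, thr + 700.0)),
                )
            )
            start += ext + gap
    return PhantomSpec(
        lumen_radius=float(overrides.pop("lumen_radius", rng.uniform(9.0, 13.0))),
        wall_thickness=wall_thickness,
        lumen_mean_hu=lumen_mean_hu,
        lumen_noise_sd=lumen_noise_sd,
        calc_arcs=tuple(arcs),
        vertebral_level=level,
        seed=int(rng.integers(0, 2**31 - 1)),
        **overrides,
    )


def generate_phantom_stack(specs_per_level: dict[str, list[PhantomSpec]]) -> PhantomStudy:
    """Build a level-indexed slice stack from per-level spec lists.

    All specs must share the same grid shape; levels are emitted in L1..L4
    order, slices within a level in list order.
    """
    shapes = {s.grid_shape for specs in specs_per_level.values() for s in specs}
    if len(shapes) > 1:
        raise GeometryError(f"inconsistent grid shapes across specs: {sorted(shapes)}")

    slices, masks, truths, levels = [], [], [], []
    for level in LEVELS:
        for spec in specs_per_level.get(level, []):
            if spec.vertebral_level != level:
                spec = dataclasses.replace(spec, vertebral_level=level)
            slc, mask, truth = generate_phantom_slice(spec)
            slices.append(slc)
            masks.append(mask)
            truths.append(truth)
            levels.append(level)
    return PhantomStudy(
        slices=tuple(slices), masks=tuple(masks), truths=tuple(truths), levels=tuple(levels)
    )
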