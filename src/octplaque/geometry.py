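"""Calibrated IVOCT segmentation stacks and ray-casting primitives.

An intravascular OCT pullback is an ordered stack of cross-sectional
frames.  Each frame arrives here already segmented into integer tissue
labels (lumen, calcium, lipid, fibrous cap); this module defines the
in-memory containers for such a stack and the polar geometry on which
every plaque feature is built: rays cast from the lumen center of mass
record, per angle, the lumen boundary radius, the radial extent of the
fibrous cap, and the entry/exit radii of calcific plaque.

Conventions (fixed and documented, since only angular *extents* carry
meaning downstream):

* a pixel with array index ``(row, col)`` has its center at physical
  coordinates ``(x, y) = (col, row) * pixel_size`` (mm);
* ray angles are measured from the +x axis, increasing toward +y, in
  degrees on ``[0, 360)`` at uniform spacing;
* boundaries are located sub-pixel by linear interpolation between ray
  sample points spaced ``pixel_size / 2`` apart (for a 0/1 label
  indicator this is the midpoint between the last sample inside and the
  first outside);
* fibrous-cap thickness is measured radially along the ray, not normal
  to the cap surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_LUMEN",
    "LABEL_CALCIUM",
    "LABEL_LIPID",
    "LABEL_FIBROUS_CAP",
    "VP_FLAG_NAMES",
    "Calibration",
    "FrameSegmentation",
    "PullbackSegmentation",
    "RayProfile",
    "NoLumenError",
    "lumen_centroid",
    "cast_rays",
]

LABEL_BACKGROUND = 0
LABEL_LUMEN = 1
LABEL_CALCIUM = 2
LABEL_LIPID = 3
LABEL_FIBROUS_CAP = 4

VALID_LABELS = frozenset(
    {LABEL_BACKGROUND, LABEL_LUMEN, LABEL_CALCIUM, LABEL_LIPID, LABEL_FIBROUS_CAP}
)

#: Frame-level vulnerable-plaque flags, in canonical order.
VP_FLAG_NAMES = (
    "microchannel",
    "macrophage_infiltration",
    "cholesterol_crystal",
    "layered_plaque",
    "calcium_nodule",
)


class NoLumenError(ValueError):
    """Raised when an operation requires a lumen and the frame has none."""


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of a pullback.

    Parameters
    ----------
    pixel_size
        In-plane size of one pixel, mm (isotropic).
    frame_pitch
        Longitudinal spacing between consecutive frames, mm.  For a
        pullback acquired at constant speed this is speed / frame rate
        (e.g. 36 mm/s at 180 fps gives 0.2 mm).
    """

    pixel_size: float
    frame_pitch: float

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0 and self.frame_pitch > 0):
            raise ValueError("pixel_size and frame_pitch must be strictly positive")

    @classmethod
    def from_pullback(
        cls, pixel_size: float, pullback_speed: float, frame_rate: float
    ) -> "Calibration":
        """Derive the frame pitch from pullback speed (mm/s) and frame rate (fps)."""
        return cls(pixel_size=pixel_size, frame_pitch=pullback_speed / frame_rate)


@dataclass
class FrameSegmentation:
    """One segmented cross-sectional frame.

    ``label_mask`` is a 2D integer image over the labels
    {0: background, 1: lumen, 2: calcium, 3: lipid, 4: fibrous cap};
    labels are mutually exclusive per pixel by construction.  ``vp_flags``
    records the five manually assessed vulnerable-plaque findings for
    the frame (microchannel, macrophage infiltration, cholesterol
    crystal, layered plaque, calcium nodule).
    """

    label_mask: np.ndarray
    vp_flags: dict[str, bool] = field(
        default_factory=lambda: {name: False for name in VP_FLAG_NAMES}
    )

    def __post_init__(self) -> None:
        self.label_mask = np.asarray(self.label_mask)
        if self.label_mask.ndim != 2:
            raise ValueError("label_mask must be a 2D image")
        extra = set(np.unique(self.label_mask)) - VALID_LABELS
        if extra:
            raise ValueError(f"label_mask contains labels outside 0..4: {sorted(extra)}")
        missing = [k for k in VP_FLAG_NAMES if k not in self.vp_flags]
        if missing:
            raise ValueError(f"vp_flags missing entries: {missing}")

    def lumen_component_count(self) -> int:
        _, n = ndimage.label(self.label_mask == LABEL_LUMEN)
        return int(n)


@dataclass
class PullbackSegmentation:
    """An ordered, calibrated stack of segmented frames.

    ``lesion_span`` is the inclusive (start, stop) frame-index range of
    the lesion (the stented segment); feature aggregation runs over this
    span only.
    """

    frames: list[FrameSegmentation]
    calibration: Calibration
    lesion_span: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("pullback must contain at least one frame")
        shape = self.frames[0].label_mask.shape
        if any(f.label_mask.shape != shape for f in self.frames):
            raise ValueError("all frames must share the same dimensions")
        lo, hi = self.lesion_span
        if not (0 <= lo <= hi < len(self.frames)):
            raise ValueError(
                f"lesion_span {self.lesion_span} outside pullback of {len(self.frames)} frames"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def lesion_frames(self) -> list[FrameSegmentation]:
        lo, hi = self.lesion_span
        return self.frames[lo : hi + 1]


@dataclass
class RayProfile:
    """Per-angle radial measurements for one frame.

    All radii and thicknesses are in mm; entries are NaN where the
    tissue is absent on that ray.  Angles are degrees on [0, 360) at
    uniform spacing; ``fc_thickness`` is the total radial extent of the
    fibrous-cap label along the ray (the per-ray thickness used for the
    thickness-class stratification).
    """

    angles: np.ndarray
    lumen_radius: np.ndarray
    fc_thickness: np.ndarray
    calcium_inner_radius: np.ndarray
    calcium_outer_radius: np.ndarray
    centroid: tuple[float, float]  # (x, y) mm

    @property
    def n_rays(self) -> int:
        return len(self.angles)

    @property
    def delta_deg(self) -> float:
        return 360.0 / self.n_rays


def lumen_centroid(frame: FrameSegmentation, cal: Calibration) -> tuple[float, float]:
    """Center of mass of the lumen label, as (x, y) in mm.

    The centroid is the arithmetic mean of lumen-pixel centers scaled by
    the pixel size.  Raises :class:`NoLumenError` on a frame without a
    lumen.
    """
    rows, cols = np.nonzero(frame.label_mask == LABEL_LUMEN)
    if rows.size == 0:
        raise NoLumenError("frame has no lumen pixels")
    return (float(cols.mean() * cal.pixel_size), float(rows.mean() * cal.pixel_size))


def cast_rays(
    frame: FrameSegmentation, cal: Calibration, n_rays: int = 360
) -> RayProfile:
    """Cast ``n_rays`` uniformly spaced rays from the lumen centroid.

    For each ray the walk outward records:

    * ``lumen_radius`` — the first lumen→non-lumen boundary crossing,
      located at the midpoint of the straddling sample pair;
    * ``fc_thickness`` — the total radial extent of fibrous-cap samples;
    * ``calcium_inner_radius`` / ``calcium_outer_radius`` — first and
      last calcium sample, each pushed half a step outward/inward so the
      extent matches the label's radial footprint.

    Sampling uses nearest-neighbour label lookup at a ``pixel_size / 2``
    step.  A centroid falling outside the lumen (non-star-shaped lumen)
    triggers a warning; rays are still measured from the centroid and
    the lumen boundary is taken after the first lumen run encountered.
    """
    if n_rays < 36:
        raise ValueError("n_rays must be at least 36")
    if n_rays % 2:
        raise ValueError("n_rays must be even (diameters pair opposed rays)")

    mask = frame.label_mask
    cx, cy = lumen_centroid(frame, cal)
    px = cal.pixel_size
    step = px / 2.0

    h, w = mask.shape
    # farthest image corner bounds every possible radius
    corners_x = np.array([0.0, (w - 1) * px])
    corners_y = np.array([0.0, (h - 1) * px])
    r_max = max(
        float(np.hypot(x - cx, y - cy)) for x in corners_x for y in corners_y
    ) + px
    n_steps = int(np.ceil(r_max / step)) + 1

    t = np.arange(n_steps) * step  # (S,)
    theta = np.deg2rad(np.arange(n_rays) * (360.0 / n_rays))  # (R,)
    xs = cx + np.outer(np.cos(theta), t)  # (R, S)
    ys = cy + np.outer(np.sin(theta), t)
    rows = np.rint(ys / px)
    cols = np.rint(xs / px)
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    labels = np.zeros((n_rays, n_steps), dtype=mask.dtype)
    labels[inside] = mask[
        rows[inside].astype(np.intp), cols[inside].astype(np.intp)
    ]

    is_lumen = labels == LABEL_LUMEN
    if not is_lumen[:, 0].all():
        warnings.warn(
            "lumen centroid lies outside the lumen label (non-star-shaped lumen); "
            "rays measured from the centroid regardless",
            stacklevel=2,
        )

    lumen_radius = np.full(n_rays, np.nan)
    for i in range(n_rays):
        ray = is_lumen[i]
        hits = np.nonzero(ray)[0]
        if hits.size == 0:
            continue
        first = hits[0]
        after = np.nonzero(~ray[first:])[0]
        if after.size == 0:  # lumen runs to the image edge
            lumen_radius[i] = t[-1]
        else:
            exit_idx = first + after[0]
            lumen_radius[i] = (t[exit_idx - 1] + t[exit_idx]) / 2.0

    is_fc = labels == LABEL_FIBROUS_CAP
    fc_counts = is_fc.sum(axis=1)
    fc_thickness = np.where(fc_counts > 0, fc_counts * step, np.nan)

    is_ca = labels == LABEL_CALCIUM
    calcium_inner = np.full(n_rays, np.nan)
    calcium_outer = np.full(n_rays, np.nan)
    any_ca = is_ca.any(axis=1)
    if any_ca.any():
        first_ca = np.argmax(is_ca, axis=1)
        last_ca = n_steps - 1 - np.argmax(is_ca[:, ::-1], axis=1)
        calcium_inner[any_ca] = t[first_ca[any_ca]] - step / 2.0
        calcium_outer[any_ca] = t[last_ca[any_ca]] + step / 2.0
        # the half-step push must never drop the entry radius below the lumen boundary
        np.maximum(calcium_inner, lumen_radius, out=calcium_inner, where=any_ca)

    return RayProfile(
        angles=np.arange(n_rays) * (360.0 / n_rays),
        lumen_radius=lumen_radius,
        fc_thickness=fc_thickness,
        calcium_inner_radius=calcium_inner,
        calcium_outer_radius=calcium_outer,
        centroid=(cx, cy),
    )
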