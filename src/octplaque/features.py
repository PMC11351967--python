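"""Per-frame and per-lesion plaque features.

Computes the 31-feature description of a coronary lesion from the ray
profiles of its frames: lesion length; lumen area/diameter summaries;
calcium angle, thickness and depth extrema; fibrous-cap (FC) angle,
thickness, area, surface area and burden, the FC quantities stratified
into four thickness classes (1: ≤ 65 µm, 2: strictly between 65 and
150 µm, 3: ≥ 150 µm, T: all thicknesses); and five vulnerable-plaque
flags.

FC *surface area* is the area of the lumen surface covered by cap in
the unrolled en-face (θ, z) view: per frame the covered arc length
(lumen radius × covered angle) summed over rays of a class, then summed
over frames weighted by the frame pitch.  FC *burden* is that surface
area as a percentage of the total lumen surface area of the lesion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    LABEL_FIBROUS_CAP,
    LABEL_LUMEN,
    VP_FLAG_NAMES,
    NoLumenError,
    Calibration,
    FrameSegmentation,
    PullbackSegmentation,
    RayProfile,
    cast_rays,
)

__all__ = [
    "FC_CLASSES",
    "FEATURE_NAMES",
    "VP_FEATURE_NAMES",
    "FcClassScheme",
    "FrameFeatures",
    "LesionFeatures",
    "angular_extent",
    "frame_features",
    "aggregate_lesion",
    "feature_vector",
    "quantify_pullback",
]

FC_CLASSES = ("1", "2", "3", "T")

#: Canonical lesion feature names, in table order.  These are the CSV
#: column names used throughout the package.
FEATURE_NAMES = (
    "Lesion length (mm)",
    "Minimum lumen area (mm^2)",
    "Average lumen area (mm^2)",
    "Minimum lumen diameter (mm)",
    "Average lumen diameter (mm)",
    "Maximum calcium angle (°)",
    "Minimum calcium angle (°)",
    "Maximum calcium thickness (mm)",
    "Minimum calcium thickness (mm)",
    "Maximum calcium depth (mm)",
    "Minimum calcium depth (mm)",
    "Maximum FC angle (°)",
    "Minimum FC angle (°)",
    "Minimum FC thickness (mm)",
    "Maximum FC area-1 (mm^2)",
    "Maximum FC area-2 (mm^2)",
    "Maximum FC area-3 (mm^2)",
    "Maximum FC area-T (mm^2)",
    "FC Surface area-1 (mm^2)",
    "FC Surface area-2 (mm^2)",
    "FC Surface area-3 (mm^2)",
    "FC Surface area-T (mm^2)",
    "FC burden-1",
    "FC burden-2",
    "FC burden-3",
    "FC burden-T",
    "Microchannel",
    "Macrophage Infiltration",
    "Cholesterol Crystal",
    "Layered Plaque",
    "Calcium Nodule",
)

VP_FEATURE_NAMES = FEATURE_NAMES[26:]


@dataclass(frozen=True)
class FcClassScheme:
    """Thickness thresholds for the four FC classes.

    Class 1: thickness ≤ ``t1_max``; class 2: strictly between; class
    3: thickness ≥ ``t2_max``; class T: any thickness.  Defaults are the
    conventional 65 µm (thin-cap fibroatheroma cutoff) and 150 µm.
    Values exactly at a threshold go to the outer classes (1 and 3), per
    the inclusive inequalities.
    """

    t1_max: float = 0.065
    t2_max: float = 0.150

    def __post_init__(self) -> None:
        if not (0 < self.t1_max < self.t2_max):
            raise ValueError("need 0 < t1_max < t2_max")

    def classify(self, thickness: np.ndarray) -> np.ndarray:
        """Map thickness (mm) to class codes 1/2/3 (0 where NaN)."""
        thickness = np.asarray(thickness, dtype=float)
        out = np.zeros(thickness.shape, dtype=int)
        present = np.isfinite(thickness)
        out[present & (thickness <= self.t1_max)] = 1
        out[present & (thickness > self.t1_max) & (thickness < self.t2_max)] = 2
        out[present & (thickness >= self.t2_max)] = 3
        return out


@dataclass
class FrameFeatures:
    """Features of a single frame; NaN codes absent tissue."""

    lumen_area: float
    lumen_min_diameter: float
    lumen_mean_diameter: float
    lumen_circumference: float
    calcium_angle: float
    calcium_max_thickness: float
    calcium_min_thickness: float
    calcium_max_depth: float
    calcium_min_depth: float
    fc_angle: float
    fc_min_thickness: float
    fc_area: dict[str, float] = field(default_factory=dict)
    fc_arc_length: dict[str, float] = field(default_factory=dict)


@dataclass
class LesionFeatures:
    """The 31-feature lesion description; NaN codes absent tissue."""

    lesion_length: float
    min_lumen_area: float
    avg_lumen_area: float
    min_lumen_diameter: float
    avg_lumen_diameter: float
    max_calcium_angle: float
    min_calcium_angle: float
    max_calcium_thickness: float
    min_calcium_thickness: float
    max_calcium_depth: float
    min_calcium_depth: float
    max_fc_angle: float
    min_fc_angle: float
    min_fc_thickness: float
    max_fc_area: dict[str, float]
    fc_surface_area: dict[str, float]
    fc_burden: dict[str, float]
    vp_flags: dict[str, bool]


def angular_extent(present: np.ndarray, n_rays: int) -> float:
    """Total angular extent, in degrees, of the rays flagged present.

    Multiple disjoint arcs sum; an empty mask gives 0.  Each present ray
    contributes the angular spacing 360 / n_rays.
    """
    if n_rays < 36:
        raise ValueError("n_rays must be at least 36")
    present = np.asarray(present, dtype=bool)
    return float(present.sum() * (360.0 / n_rays))


def _nearest_finite_ray(ray_idx: np.ndarray, finite: np.ndarray) -> np.ndarray:
    """Snap ray indices to the circularly nearest ray with finite data."""
    n = finite.size
    finite_idx = np.nonzero(finite)[0]
    if finite_idx.size == 0:
        raise ValueError("no finite rays to snap to")
    d = np.abs(ray_idx[:, None] - finite_idx[None, :])
    d = np.minimum(d, n - d)  # circular distance
    return finite_idx[np.argmin(d, axis=1)]


def frame_features(
    profile: RayProfile,
    frame: FrameSegmentation,
    cal: Calibration,
    scheme: FcClassScheme | None = None,
) -> FrameFeatures:
    """Compute the per-frame features from a ray profile and its mask.

    Lumen area is the pixel count scaled by the pixel area (not a ray
    quantity).  Diameters are chords through the centroid, pairing each
    ray with its diametric opposite; the minimum and mean run over the
    pairs.  Per-ray calcium thickness is outer − inner radius and depth
    is inner radius − lumen radius (clipped at zero).  Each FC pixel is
    assigned to the thickness class of its nearest ray, which keeps the
    per-class areas an exact partition of the total.  Arc lengths and
    the lumen circumference integrate lumen radius over angle.
    """
    scheme = scheme or FcClassScheme()
    n = profile.n_rays
    d_rad = math.radians(profile.delta_deg)
    px = cal.pixel_size

    lumen_area = float((frame.label_mask == LABEL_LUMEN).sum()) * px * px
    half = n // 2
    chords = profile.lumen_radius[:half] + profile.lumen_radius[half:]
    lumen_min_d = float(np.nanmin(chords)) if np.isfinite(chords).any() else np.nan
    lumen_mean_d = float(np.nanmean(chords)) if np.isfinite(chords).any() else np.nan
    finite_r = np.isfinite(profile.lumen_radius)
    circumference = float(np.nansum(profile.lumen_radius[finite_r]) * d_rad)

    # calcium
    ca_present = np.isfinite(profile.calcium_inner_radius)
    if ca_present.any():
        thickness = (
            profile.calcium_outer_radius[ca_present]
            - profile.calcium_inner_radius[ca_present]
        )
        depth = np.clip(
            profile.calcium_inner_radius[ca_present]
            - profile.lumen_radius[ca_present],
            0.0,
            None,
        )
        ca_angle = angular_extent(ca_present, n)
        ca_max_t, ca_min_t = float(thickness.max()), float(thickness.min())
        ca_max_d, ca_min_d = float(np.nanmax(depth)), float(np.nanmin(depth))
    else:
        ca_angle = ca_max_t = ca_min_t = ca_max_d = ca_min_d = np.nan

    # fibrous cap
    fc_present = np.isfinite(profile.fc_thickness)
    fc_area = {c: 0.0 for c in FC_CLASSES}
    fc_arc = {c: 0.0 for c in FC_CLASSES}
    if fc_present.any():
        fc_angle = angular_extent(fc_present, n)
        fc_min_t = float(np.nanmin(profile.fc_thickness))
        ray_class = scheme.classify(profile.fc_thickness)

        # per-class covered arc length on the lumen surface
        for c in (1, 2, 3):
            sel = ray_class == c
            fc_arc[str(c)] = float(
                np.nansum(profile.lumen_radius[sel & finite_r]) * d_rad
            )
        fc_arc["T"] = fc_arc["1"] + fc_arc["2"] + fc_arc["3"]

        # per-class FC cross-sectional area: each FC pixel inherits the
        # class of its (circularly) nearest FC-bearing ray
        rows, cols = np.nonzero(frame.label_mask == LABEL_FIBROUS_CAP)
        if rows.size:
            cx, cy = profile.centroid
            ang = np.degrees(np.arctan2(rows * px - cy, cols * px - cx)) % 360.0
            idx = np.rint(ang / profile.delta_deg).astype(int) % n
            off_fc = ~fc_present[idx]
            if off_fc.any():
                idx[off_fc] = _nearest_finite_ray(idx[off_fc], fc_present)
            pix_class = ray_class[idx]
            for c in (1, 2, 3):
                fc_area[str(c)] = float((pix_class == c).sum()) * px * px
        fc_area["T"] = fc_area["1"] + fc_area["2"] + fc_area["3"]
    else:
        fc_angle = fc_min_t = np.nan
        fc_area = {c: np.nan for c in FC_CLASSES}
        fc_arc = {c: np.nan for c in FC_CLASSES}

    return FrameFeatures(
        lumen_area=lumen_area,
        lumen_min_diameter=lumen_min_d,
        lumen_mean_diameter=lumen_mean_d,
        lumen_circumference=circumference,
        calcium_angle=ca_angle,
        calcium_max_thickness=ca_max_t,
        calcium_min_thickness=ca_min_t,
        calcium_max_depth=ca_max_d,
        calcium_min_depth=ca_min_d,
        fc_angle=fc_angle,
        fc_min_thickness=fc_min_t,
        fc_area=fc_area,
        fc_arc_length=fc_arc,
    )


def _extremum(values: list[float], fn) -> float:
    vals = [v for v in values if np.isfinite(v)]
    return float(fn(vals)) if vals else np.nan


def aggregate_lesion(
    per_frame: list[FrameFeatures],
    cal: Calibration,
    vp_flags: list[dict[str, bool]] | None = None,
    n_lesion_frames: int | None = None,
) -> LesionFeatures:
    """Aggregate per-frame features over the lesion span.

    Lesion length is lesion-span frame count × frame pitch
    (``n_lesion_frames`` when measurable frames were skipped).
    "Max"/"min" fields take
    the max/min over frames of the corresponding per-frame max/min,
    skipping frames where the tissue is absent, so a single
    calcium-bearing frame defines both extrema.  FC surface area per
    class sums covered arc length × pitch over frames; burden divides by
    the total lumen surface area (circumference × pitch summed) and is
    reported in percent.  Vulnerable-plaque flags are any-frame
    presence.
    """
    if not per_frame:
        raise ValueError("lesion must contain at least one frame")
    pitch = cal.frame_pitch

    sa = {
        c: float(
            np.nansum([f.fc_arc_length[c] for f in per_frame if np.isfinite(f.fc_arc_length[c])])
            * pitch
        )
        for c in ("1", "2", "3")
    }
    sa["T"] = sa["1"] + sa["2"] + sa["3"]  # conservation exact by construction
    lumen_surface = float(sum(f.lumen_circumference for f in per_frame) * pitch)
    burden = {
        c: (100.0 * sa[c] / lumen_surface if lumen_surface > 0 else np.nan)
        for c in FC_CLASSES
    }

    flags = {name: False for name in VP_FLAG_NAMES}
    for fr in vp_flags or []:
        for name in VP_FLAG_NAMES:
            flags[name] = flags[name] or bool(fr.get(name, False))

    return LesionFeatures(
        lesion_length=(n_lesion_frames or len(per_frame)) * pitch,
        min_lumen_area=_extremum([f.lumen_area for f in per_frame], min),
        avg_lumen_area=float(np.mean([f.lumen_area for f in per_frame])),
        min_lumen_diameter=_extremum([f.lumen_min_diameter for f in per_frame], min),
        avg_lumen_diameter=_extremum([f.lumen_mean_diameter for f in per_frame], np.mean),
        max_calcium_angle=_extremum([f.calcium_angle for f in per_frame], max),
        min_calcium_angle=_extremum([f.calcium_angle for f in per_frame], min),
        max_calcium_thickness=_extremum([f.calcium_max_thickness for f in per_frame], max),
        min_calcium_thickness=_extremum([f.calcium_min_thickness for f in per_frame], min),
        max_calcium_depth=_extremum([f.calcium_max_depth for f in per_frame], max),
        min_calcium_depth=_extremum([f.calcium_min_depth for f in per_frame], min),
        max_fc_angle=_extremum([f.fc_angle for f in per_frame], max),
        min_fc_angle=_extremum([f.fc_angle for f in per_frame], min),
        min_fc_thickness=_extremum([f.fc_min_thickness for f in per_frame], min),
        max_fc_area={
            c: _extremum([f.fc_area[c] for f in per_frame], max) for c in FC_CLASSES
        },
        fc_surface_area=sa,
        fc_burden=burden,
        vp_flags=flags,
    )


def feature_vector(lesion: LesionFeatures) -> pd.Series:
    """Flatten a :class:`LesionFeatures` to the canonical 31-entry record.

    Ordering and naming follow :data:`FEATURE_NAMES`; NaN (absent-coded)
    values propagate as missing; vulnerable-plaque flags serialize as
    0/1.
    """
    values = [
        lesion.lesion_length,
        lesion.min_lumen_area,
        lesion.avg_lumen_area,
        lesion.min_lumen_diameter,
        lesion.avg_lumen_diameter,
        lesion.max_calcium_angle,
        lesion.min_calcium_angle,
        lesion.max_calcium_thickness,
        lesion.min_calcium_thickness,
        lesion.max_calcium_depth,
        lesion.min_calcium_depth,
        lesion.max_fc_angle,
        lesion.min_fc_angle,
        lesion.min_fc_thickness,
        *(lesion.max_fc_area[c] for c in FC_CLASSES),
        *(lesion.fc_surface_area[c] for c in FC_CLASSES),
        *(lesion.fc_burden[c] for c in FC_CLASSES),
        *(float(lesion.vp_flags[name]) for name in VP_FLAG_NAMES),
    ]
    return pd.Series(values, index=list(FEATURE_NAMES), dtype=float)


def quantify_pullback(
    pullback: PullbackSegmentation,
    n_rays: int = 360,
    scheme: FcClassScheme | None = None,
) -> tuple[LesionFeatures, list[FrameFeatures]]:
    """Run ray casting and feature extraction over the lesion span.

    Frames without a lumen label (e.g. all-background pages) contribute
    no plaque statistics and are skipped with a warning, but they still
    count toward the lesion length, which is defined by the lesion span.
    """
    cal = pullback.calibration
    lesion_frames = pullback.lesion_frames()
    per_frame: list[FrameFeatures] = []
    flags: list[dict[str, bool]] = []
    for i, frame in enumerate(lesion_frames):
        try:
            profile = cast_rays(frame, cal, n_rays=n_rays)
        except NoLumenError:
            warnings.warn(f"lesion frame {i} has no lumen; skipped for plaque stats")
            continue
        per_frame.append(frame_features(profile, frame, cal, scheme))
        flags.append(frame.vp_flags)
    lesion = aggregate_lesion(
        per_frame, cal, flags, n_lesion_frames=len(lesion_frames)
    )
    return lesion, per_frame
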