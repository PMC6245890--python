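"""Myocardial contour delineation and AHA 16-segment mapping.

A temporal maximum-intensity projection (MIP) over the dynamic frames
produces a high-contrast feature image in which the left-ventricular
blood pool is the brightest compact structure.  Contours are found by
polar edge detection: rays cast from the LV centre locate the
endocardial edge (signal drop below a fraction of blood-pool intensity)
and the epicardial edge (subsequent drop below a fraction of the
myocardial ring's median intensity).

The myocardium between the contours is partitioned into the standard
AHA segments — 6 basal, 6 mid-ventricular, 4 apical (the apical cap is
not covered by 3 short-axis slices) — counted counter-clockwise from a
reference angle at the anterior RV insertion, and each segment is
assigned to a coronary territory (LAD / RCA / LCX).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .data import DynamicSeries
from .exceptions import ConfigError, ContourValidationError, DelineationError

__all__ = [
    "SliceContour",
    "ContourSet",
    "SegmentMap",
    "TERRITORIES",
    "SEGMENT_TERRITORY",
    "ROLE_SEGMENTS",
    "temporal_mip",
    "delineate",
    "delineate_series",
    "override_contours",
    "build_segment_map",
    "segment_labels_from_radii",
    "myocardium_mask",
    "blood_pool_mask",
]

#: Coronary territory of each AHA segment (16-segment model).
TERRITORIES: dict[str, frozenset] = {
    "LAD": frozenset({1, 2, 7, 8, 13, 14}),
    "RCA": frozenset({3, 4, 9, 10, 15}),
    "LCX": frozenset({5, 6, 11, 12, 16}),
}

SEGMENT_TERRITORY: dict[int, str] = {
    seg: terr for terr, segs in TERRITORIES.items() for seg in segs
}

#: First label and sector count per slice role.
ROLE_SEGMENTS: dict[str, tuple[int, int]] = {
    "basal": (1, 6),
    "mid": (7, 6),
    "apical": (13, 4),
}


def temporal_mip(series):
    """Per-pixel maximum over frames.

    Accepts a :class:`DynamicSeries` (returns an array of shape
    ``(n_slices, rows, cols)``), a ``(frames, rows, cols)`` array
    (returns ``(rows, cols)``) or a plain 2-D image (returned as-is, so
    the projection is idempotent).
    """
    if isinstance(series, DynamicSeries):
        return series.data.max(axis=1)
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        return arr.max(axis=0)
    raise ConfigError("expected DynamicSeries, (frames, r, c) or 2-D image")


@dataclass
class SliceContour:
    """Closed endo/epicardial polygons for one slice, pixel coordinates
    ``[row, col]``, plus the LV centre they were drawn around."""

    endo: np.ndarray
    epi: np.ndarray
    center: tuple

    def __post_init__(self) -> None:
        self.endo = np.asarray(self.endo, dtype=float)
        self.epi = np.asarray(self.epi, dtype=float)
        if self.endo.ndim != 2 or self.endo.shape[1] != 2 or len(self.endo) < 3:
            raise ContourValidationError("endo polygon must be (N>=3, 2)")
        if self.epi.ndim != 2 or self.epi.shape[1] != 2 or len(self.epi) < 3:
            raise ContourValidationError("epi polygon must be (N>=3, 2)")

    def radius_profiles(self, angles_deg: np.ndarray):
        """Endo and epi radius as a function of angle (degrees, CCW with
        0 at the +col direction), by periodic linear interpolation.
        Assumes star-shaped polygons about the centre (true for all
        contours this module produces)."""
        endo = _radius_at(self.endo, self.center, angles_deg)
        epi = _radius_at(self.epi, self.center, angles_deg)
        return endo, epi

    def validate_nested(self, n_check: int = 360) -> None:
        ang = np.arange(n_check) * 360.0 / n_check
        endo, epi = self.radius_profiles(ang)
        if not np.all(np.isfinite(endo)) or not np.all(np.isfinite(epi)):
            raise ContourValidationError("non-finite contour radii")
        if np.any(endo <= 0) or np.any(epi <= endo):
            raise ContourValidationError(
                "endocardial contour must lie strictly inside the epicardial contour"
            )

    def translated(self, drow: float, dcol: float) -> "SliceContour":
        d = np.array([drow, dcol], dtype=float)
        return SliceContour(self.endo + d, self.epi + d,
                            (self.center[0] + drow, self.center[1] + dcol))


@dataclass
class ContourSet:
    """Contours for all slices of one series.

    ``provenance[sl]`` records whether a slice's contour came from the
    automatic delineation (``"auto"``) or a manual override
    (``"manual"``).
    """

    slices: dict = field(default_factory=dict)
    reference_angle: float = 90.0
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, sl: int) -> SliceContour:
        return self.slices[sl]

    def __contains__(self, sl: int) -> bool:
        return sl in self.slices

    @property
    def slice_indices(self):
        return sorted(self.slices)


def _pixel_polar(shape, center):
    rows, cols = np.indices(shape)
    dy = center[0] - rows          # y up so angles run CCW on screen
    dx = cols - center[1]
    radius = np.hypot(dx, dy)
    angle = np.degrees(np.arctan2(dy, dx)) % 360.0
    return radius, angle


def _radius_at(polygon, center, angles_deg):
    v = np.asarray(polygon, dtype=float)
    dy = center[0] - v[:, 0]
    dx = v[:, 1] - center[1]
    ang = np.degrees(np.arctan2(dy, dx)) % 360.0
    rad = np.hypot(dx, dy)
    order = np.argsort(ang)
    ang, rad = ang[order], rad[order]
    # pad one period on each side for wrap-around interpolation
    ang_ext = np.concatenate([ang - 360.0, ang, ang + 360.0])
    rad_ext = np.concatenate([rad, rad, rad])
    return np.interp(np.asarray(angles_deg, dtype=float) % 360.0, ang_ext, rad_ext)


def _smooth_periodic(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    ext = np.concatenate([values[-window:], values, values[:window]])
    sm = np.convolve(ext, kernel, mode="same")
    return sm[window:-window]


def _fill_missing_periodic(values: np.ndarray) -> np.ndarray:
    """Interpolate NaN entries of an angular profile periodically."""
    bad = ~np.isfinite(values)
    if not bad.any():
        return values
    n = values.size
    idx = np.arange(n, dtype=float)
    good = np.isfinite(values)
    ext_idx = np.concatenate([idx[good] - n, idx[good], idx[good] + n])
    ext_val = np.tile(values[good], 3)
    out = values.copy()
    out[bad] = np.interp(idx[bad], ext_idx, ext_val)
    return out


def delineate(mip: np.ndarray, *, n_rays: int = 360, endo_fraction: float = 0.6,
              epi_fraction: float = 0.4, smooth_window_deg: float = 15.0,
              max_missing_fraction: float = 0.25,
              radial_step: float = 0.25) -> SliceContour:
    """Automatic endo/epicardial delineation of one slice from its MIP.

    The LV centre is the centroid of the brightest connected component
    after Otsu thresholding.  Per ray (``n_rays`` over 360 degrees) the
    endocardial edge is the first outward drop below
    ``endo_fraction`` x blood-pool intensity and the epicardial edge the
    subsequent drop below ``epi_fraction`` x the myocardial ring's
    median intensity.  Profiles are smoothed with a periodic moving
    average over ``smooth_window_deg``.

    Raises :class:`DelineationError` if no blood pool is found or edges
    are missing on more than ``max_missing_fraction`` of rays; the
    caller may then supply manual contours.
    """
    mip = np.asarray(mip, dtype=float)
    if mip.ndim != 2:
        raise ConfigError("delineate expects a single-slice 2-D MIP")
    finite = mip[np.isfinite(mip)]
    if finite.size == 0 or np.ptp(finite) <= 0:
        raise DelineationError("blank image: no blood pool found")
    thr = threshold_otsu(mip)
    bw = mip > thr
    if not bw.any():
        raise DelineationError("no structure above Otsu threshold")
    lab = cc_label(bw)
    comps = range(1, lab.max() + 1)
    means = [mip[lab == i].mean() for i in comps]
    comp = 1 + int(np.argmax(means))
    rr, cc = np.nonzero(lab == comp)
    center = (float(rr.mean()), float(cc.mean()))

    # blood-pool intensity from a small disc at the centre
    radius_map, _ = _pixel_polar(mip.shape, center)
    pool_disc = radius_map <= 3.0
    blood_int = float(mip[pool_disc].mean())
    if blood_int <= thr:
        raise DelineationError("no bright compact blood pool at the detected centre")

    r_max = min(center[0], center[1],
                mip.shape[0] - 1 - center[0], mip.shape[1] - 1 - center[1])
    radii = np.arange(0.0, r_max, radial_step)
    angles = np.arange(n_rays) * 360.0 / n_rays
    th = np.radians(angles)
    # sample image along every ray (bilinear)
    rows = center[0] - np.outer(np.sin(th), radii)
    cols = center[1] + np.outer(np.cos(th), radii)
    prof = ndimage.map_coordinates(mip, [rows, cols], order=1, mode="nearest")

    endo_thr = endo_fraction * blood_int
    endo_r = np.full(n_rays, np.nan)
    endo_idx = np.full(n_rays, -1)
    for i in range(n_rays):
        below = np.nonzero(prof[i] < endo_thr)[0]
        if below.size:
            endo_idx[i] = below[0]
            endo_r[i] = radii[below[0]]

    # myocardial ring intensity: samples just beyond the endocardial edge
    ring_samples = []
    for i in range(n_rays):
        if endo_idx[i] >= 0:
            j0 = endo_idx[i] + int(round(0.5 / radial_step))
            j1 = endo_idx[i] + int(round(2.5 / radial_step))
            ring_samples.append(prof[i, j0:j1])
    if not ring_samples:
        raise DelineationError("endocardial edge missing on all rays")
    ring_int = float(np.median(np.concatenate(ring_samples)))
    epi_thr = epi_fraction * ring_int

    epi_r = np.full(n_rays, np.nan)
    for i in range(n_rays):
        if endo_idx[i] < 0:
            continue
        j0 = endo_idx[i] + 1
        below = np.nonzero(prof[i, j0:] < epi_thr)[0]
        if below.size:
            epi_r[i] = radii[j0 + below[0]]

    missing = (~np.isfinite(endo_r)) | (~np.isfinite(epi_r))
    if missing.mean() > max_missing_fraction:
        raise DelineationError(
            "edges missing on %.0f%% of rays" % (100 * missing.mean()))

    window = max(1, int(round(smooth_window_deg * n_rays / 360.0)))
    endo_r = _smooth_periodic(_fill_missing_periodic(endo_r), window)
    epi_r = _smooth_periodic(_fill_missing_periodic(epi_r), window)
    epi_r = np.maximum(epi_r, endo_r + radial_step)

    endo_poly = np.stack([center[0] - endo_r * np.sin(th),
                          center[1] + endo_r * np.cos(th)], axis=1)
    epi_poly = np.stack([center[0] - epi_r * np.sin(th),
                         center[1] + epi_r * np.cos(th)], axis=1)
    return SliceContour(endo_poly, epi_poly, center)


def delineate_series(series: DynamicSeries, reference_angle: float = 90.0,
                     **kwargs) -> ContourSet:
    """Delineate every slice of a series from its temporal MIP."""
    mips = temporal_mip(series)
    cs = ContourSet(reference_angle=reference_angle)
    for sl in range(series.n_slices):
        cs.slices[sl] = delineate(mips[sl], **kwargs)
        cs.provenance[sl] = "auto"
    return cs


def override_contours(auto: ContourSet, manual) -> ContourSet:
    """Replace automatic contours by manual ones where provided.

    ``manual`` is a :class:`ContourSet` or a ``{slice_index:
    SliceContour}`` mapping (e.g. parsed from a contour JSON file).
    Manual contours are validated for nesting before acceptance.
    """
    if manual is None:
        return auto
    manual_slices = manual.slices if isinstance(manual, ContourSet) else dict(manual)
    out = ContourSet(reference_angle=auto.reference_angle,
                     slices=dict(auto.slices), provenance=dict(auto.provenance))
    for sl, contour in manual_slices.items():
        contour.validate_nested()
        out.slices[sl] = contour
        out.provenance[sl] = "manual"
    return out


def segment_labels_from_radii(shape, center, endo_r_of_angle, epi_r_of_angle,
                              role: str, reference_angle: float = 90.0) -> np.ndarray:
    """Label the annulus between two radius-vs-angle profiles with AHA
    segment numbers for one slice.

    ``endo_r_of_angle`` / ``epi_r_of_angle`` are callables taking angles
    in degrees (or scalars for circular contours).  Sectors are counted
    counter-clockwise from ``reference_angle``.
    """
    if role not in ROLE_SEGMENTS:
        raise ConfigError("slice role must be one of %s" % sorted(ROLE_SEGMENTS))
    first, n_sectors = ROLE_SEGMENTS[role]
    radius, angle = _pixel_polar(shape, center)
    endo = endo_r_of_angle(angle) if callable(endo_r_of_angle) else float(endo_r_of_angle)
    epi = epi_r_of_angle(angle) if callable(epi_r_of_angle) else float(epi_r_of_angle)
    in_ring = (radius >= endo) & (radius < epi)
    sector = np.floor(((angle - reference_angle) % 360.0) / (360.0 / n_sectors))
    labels = np.zeros(shape, dtype=np.int16)
    labels[in_ring] = first + sector[in_ring].astype(np.int16)
    return labels


@dataclass
class SegmentMap:
    """Integer AHA segment label image per slice (0 = background) with
    the fixed segment -> territory lookup."""

    labels: np.ndarray
    slice_roles: tuple
    reference_angle: float = 90.0
    territory_of: dict = field(default_factory=lambda: dict(SEGMENT_TERRITORY))

    @property
    def segments(self):
        return sorted(int(s) for s in np.unique(self.labels) if s > 0)

    def mask(self, segment: int) -> np.ndarray:
        return self.labels == segment


def build_segment_map(contours: ContourSet, slice_roles=("basal", "mid", "apical"),
                      shape=None) -> SegmentMap:
    """Partition the myocardium of each slice into AHA segments.

    Requires one contoured slice per role (basal, mid, apical).  ``shape``
    is the spatial image shape; if omitted it is inferred from the
    contour extent (smallest enclosing integer box is not meaningful, so
    passing the true image shape is recommended).
    """
    idx = contours.slice_indices
    if len(idx) != len(slice_roles):
        raise ConfigError("need one slice role per contoured slice "
                          "(%d contours, %d roles)" % (len(idx), len(slice_roles)))
    for role in slice_roles:
        if role not in ROLE_SEGMENTS:
            raise ConfigError("unknown slice role %r" % role)
    if shape is None:
        vmax = max(float(np.max(contours[sl].epi)) for sl in idx)
        shape = (int(np.ceil(vmax)) + 2, int(np.ceil(vmax)) + 2)
    labels = np.zeros((len(idx),) + tuple(shape), dtype=np.int16)
    for pos, (sl, role) in enumerate(zip(idx, slice_roles)):
        contour = contours[sl]
        labels[pos] = segment_labels_from_radii(
            shape, contour.center,
            lambda a, c=contour: _radius_at(c.endo, c.center, a),
            lambda a, c=contour: _radius_at(c.epi, c.center, a),
            role, contours.reference_angle)
    return SegmentMap(labels, tuple(slice_roles), contours.reference_angle)


def myocardium_mask(contours: ContourSet, shape) -> np.ndarray:
    """Boolean (slice, row, col) mask of pixels between the contours."""
    idx = contours.slice_indices
    mask = np.zeros((len(idx),) + tuple(shape), dtype=bool)
    for pos, sl in enumerate(idx):
        c = contours[sl]
        radius, angle = _pixel_polar(shape, c.center)
        endo, epi = c.radius_profiles(angle)
        mask[pos] = (radius >= endo) & (radius < epi)
    return mask


def blood_pool_mask(contours: ContourSet, shape, margin_px: float = 1.0) -> np.ndarray:
    """Boolean (slice, row, col) mask of the LV blood pool, eroded by
    ``margin_px`` inside the endocardial contour to avoid partial-volume
    contamination."""
    idx = contours.slice_indices
    mask = np.zeros((len(idx),) + tuple(shape), dtype=bool)
    for pos, sl in enumerate(idx):
        c = contours[sl]
        radius, angle = _pixel_polar(shape, c.center)
        endo, _ = c.radius_profiles(angle)
        mask[pos] = radius < (endo - margin_px)
    return mask


def contour_set_to_dict(contours: ContourSet) -> dict:
    """JSON-serializable form of a ContourSet."""
    return {
        "reference_angle": contours.reference_angle,
        "slices": {
            str(sl): {
                "endo": contours[sl].endo.tolist(),
                "epi": contours[sl].epi.tolist(),
                "center": list(contours[sl].center),
                "provenance": contours.provenance.get(sl, "auto"),
            }
            for sl in contours.slice_indices
        },
    }


def contour_set_from_dict(payload: dict) -> ContourSet:
    cs = ContourSet(reference_angle=float(payload.get("reference_angle", 90.0)))
    for key, entry in payload["slices"].items():
        sc = SliceContour(np.asarray(entry["endo"], dtype=float),
                          np.asarray(entry["epi"], dtype=float),
                          tuple(entry["center"]))
        cs.slices[int(key)] = sc
        cs.provenance[int(key)] = entry.get("provenance", "manual")
    return cs
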