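"""File I/O: NIfTI dynamic series with JSON frame-time sidecars,
contour JSON, segment-map volumes and result tables.

A dynamic series is stored as a 4-D NIfTI with axes (x=col, y=row,
slice, frame) plus a ``<name>.json`` sidecar holding frame times and
pixel geometry; the sidecar is mandatory on read because frame timing
must never be silently defaulted.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .contours import ContourSet, SegmentMap, contour_set_from_dict, \
    contour_set_to_dict
from .data import DynamicSeries
from .exceptions import FileFormatError

__all__ = [
    "write_series", "read_series",
    "write_contours", "read_contours",
    "write_segment_map",
    "write_segment_table", "read_call_table",
    "write_json", "read_dicom_series",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_series(series: DynamicSeries, path) -> Path:
    """Write a series as NIfTI + JSON sidecar; returns the sidecar path."""
    path = Path(path)
    # (slice, frame, row, col) -> (col, row, slice, frame): x fastest
    vol = np.transpose(series.data, (3, 2, 0, 1))
    affine = np.diag([series.pixel_size_mm, series.pixel_size_mm,
                      series.slice_thickness_mm, 1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({
        "frame_times": series.frame_times.tolist(),
        "pixel_size_mm": series.pixel_size_mm,
        "slice_thickness_mm": series.slice_thickness_mm,
        "name": series.name,
    }, indent=1))
    return sidecar


def read_series(path) -> DynamicSeries:
    """Read a series written by :func:`write_series`.

    Raises :class:`FileFormatError` if the frame-time sidecar is missing
    or lacks the ``frame_times`` field.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileFormatError(
            "missing frame-time sidecar %s (field 'frame_times')" % sidecar)
    meta = json.loads(sidecar.read_text())
    if "frame_times" not in meta:
        raise FileFormatError("sidecar %s lacks field 'frame_times'" % sidecar)
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    if vol.ndim != 4:
        raise FileFormatError("%s: expected a 4-D volume" % path)
    data = np.transpose(vol, (2, 3, 1, 0))
    return DynamicSeries(data, np.asarray(meta["frame_times"], dtype=float),
                         float(meta.get("pixel_size_mm", 1.9)),
                         float(meta.get("slice_thickness_mm", 10.0)),
                         name=str(meta.get("name", "")))


def write_contours(contours: ContourSet, path) -> None:
    Path(path).write_text(json.dumps(contour_set_to_dict(contours), indent=1))


def read_contours(path) -> ContourSet:
    try:
        payload = json.loads(Path(path).read_text())
        return contour_set_from_dict(payload)
    except (KeyError, TypeError, ValueError) as exc:
        raise FileFormatError("malformed contour file %s: %s" % (path, exc))


def write_segment_map(segmap: SegmentMap, path, legend_path=None) -> None:
    """Integer label volume as NIfTI plus a CSV legend
    (segment, territory, slice_role)."""
    vol = np.transpose(segmap.labels, (2, 1, 0)).astype(np.int16)
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))
    if legend_path is not None:
        from .contours import ROLE_SEGMENTS
        rows = []
        for role in segmap.slice_roles:
            first, count = ROLE_SEGMENTS[role]
            for seg in range(first, first + count):
                rows.append({"segment": seg,
                             "territory": segmap.territory_of[seg],
                             "slice_role": role})
        pd.DataFrame(rows).to_csv(legend_path, index=False)


SEGMENT_TABLE_COLUMNS = ["segment", "territory", "mbf_stress", "mbf_rest",
                         "mpr", "ischemic", "indeterminate", "n_pixels"]


def write_segment_table(seg_table, path) -> None:
    df = seg_table.table.reset_index()[SEGMENT_TABLE_COLUMNS]
    df.to_csv(path, index=False)


def read_call_table(path) -> pd.DataFrame:
    """Reader-call CSV with columns patient_id, truth, call[, group]."""
    df = pd.read_csv(path)
    for col in ("patient_id", "truth", "call"):
        if col not in df.columns:
            raise FileFormatError("call table %s lacks column '%s'" % (path, col))
    if "group" not in df.columns:
        df["group"] = "all"
    return df


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_dicom_series(directory, frame_times=None) -> DynamicSeries:
    """Best-effort ingestion of a directory of single-frame DICOM files
    into a one-slice dynamic series, ordered by instance number.

    Frame times are taken from acquisition/trigger times when present;
    otherwise they must be supplied.  Requires ``pydicom``.
    """
    import pydicom

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise FileFormatError("no .dcm files in %s" % directory)
    dsets = [pydicom.dcmread(str(f)) for f in files]
    dsets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    frames = np.stack([d.pixel_array.astype(float) for d in dsets])
    if frame_times is None:
        times = []
        for d in dsets:
            t = getattr(d, "TriggerTime", None)
            if t is None:
                raise FileFormatError(
                    "DICOM series lacks TriggerTime; pass frame_times")
            times.append(float(t) / 1000.0)
        frame_times = np.asarray(times)
    px = 1.9
    if getattr(dsets[0], "PixelSpacing", None):
        px = float(dsets[0].PixelSpacing[0])
    return DynamicSeries(frames[None, ...], np.asarray(frame_times, float),
                         pixel_size_mm=px)
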