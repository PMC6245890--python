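"""In-memory containers for dynamic perfusion series and sampled curves."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError, NonUniformSamplingError

__all__ = ["DynamicSeries", "SampledCurve"]


@dataclass
class SampledCurve:
    """A signal sampled in time — an arterial input function or a tissue
    enhancement curve.

    Parameters
    ----------
    times : array-like
        Sample times in seconds, strictly increasing.
    values : array-like
        Signal values (arbitrary but consistent units), same length.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise InputError("times and values must be 1-D arrays of equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise InputError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        """Sampling interval in seconds; raises unless sampling is uniform."""
        self.require_uniform()
        return float(self.times[1] - self.times[0])

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.times)
        return bool(d.size == 0 or np.allclose(d, d[0], rtol=rtol, atol=0.0))

    def require_uniform(self) -> None:
        if not self.is_uniform():
            raise NonUniformSamplingError(
                "operation requires uniform temporal sampling; resample first"
            )

    def resample(self, times: np.ndarray) -> "SampledCurve":
        """Linear resampling onto a new time grid (edge values extended)."""
        times = np.asarray(times, dtype=float)
        vals = np.interp(times, self.times, self.values)
        return SampledCurve(times, vals)

    @property
    def peak(self) -> float:
        return float(np.max(self.values))

    @property
    def peak_time(self) -> float:
        return float(self.times[int(np.argmax(self.values))])


@dataclass
class DynamicSeries:
    """A dynamic (multi-frame) short-axis image stack.

    Data axes are ``(slice, frame, row, col)``.  Frame times are seconds
    from the start of the series; pixel coordinates are 0-based,
    row-major.
    """

    data: np.ndarray
    frame_times: np.ndarray
    pixel_size_mm: float = 1.9
    slice_thickness_mm: float = 10.0
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.data.ndim != 4:
            raise InputError("data must be 4-D (slice, frame, row, col)")
        if self.frame_times.shape != (self.data.shape[1],):
            raise InputError(
                "frame_times length %d does not match frame axis %d"
                % (self.frame_times.size, self.data.shape[1])
            )
        if self.frame_times.size >= 2 and not np.all(np.diff(self.frame_times) > 0):
            raise InputError("frame_times must be strictly increasing")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[2:]

    def pixel_curve(self, sl: int, row: int, col: int) -> SampledCurve:
        return SampledCurve(self.frame_times, self.data[sl, :, row, col])

    def mean_curve(self, mask: np.ndarray) -> SampledCurve:
        """Mean signal per frame over a boolean mask of shape
        (slice, row, col)."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_slices,) + self.spatial_shape:
            raise InputError("mask shape must be (slice, row, col)")
        if not mask.any():
            raise InputError("mask is empty")
        vals = self.data[:, :, :, :].transpose(1, 0, 2, 3)[:, mask].mean(axis=1)
        return SampledCurve(self.frame_times, vals)

    def copy(self) -> "DynamicSeries":
        return DynamicSeries(
            self.data.copy(),
            self.frame_times.copy(),
            self.pixel_size_mm,
            self.slice_thickness_mm,
            self.name,
            dict(self.meta),
        )
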