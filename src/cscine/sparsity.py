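"""Temporal-average sparsifying transform for cine image series.

A cine train {x_i} of a beating heart is not sparse frame by frame, but the
*changes* are: most of the field of view is static tissue. Subtracting the
temporal average image

    A = (1/N) * sum_i x_i

from every frame leaves difference images s_i = x_i - A that carry only the
dynamic content and are therefore sparse. The transform is exactly
invertible (add A back) and linear; both properties are exploited by the
compressed-sensing solver in :mod:`cscine.recon`.

All arithmetic is complex: sparsification happens before magnitude
extraction, and the l1 norm of a complex image is the sum of moduli.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CineSeries",
    "SparseCine",
    "temporal_average",
    "sparsify",
    "desparsify",
]


@dataclass
class CineSeries:
    """An ordered multi-frame complex image series for one slice.

    Parameters
    ----------
    frames
        Complex array of shape ``(n_frames, ny, nx)``. Frame 0 is
        end-diastole by convention.
    pixel_size_mm
        In-plane pixel edge length (isotropic), millimetres.
    slice_thickness_mm
        Through-plane slice thickness, millimetres.
    """

    frames: np.ndarray
    pixel_size_mm: float = 0.1
    slice_thickness_mm: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (n_frames, ny, nx), got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("series must contain at least one frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def matrix(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class SparseCine:
    """Sparse representation of a cine series: average image + differences."""

    average: np.ndarray
    diffs: np.ndarray
    pixel_size_mm: float = 0.1
    slice_thickness_mm: float = 1.0

    @property
    def n_frames(self) -> int:
        return self.diffs.shape[0]


def temporal_average(series: CineSeries) -> np.ndarray:
    """Mean image A over all frames, in complex arithmetic (no magnitude)."""
    if series.n_frames < 1:
        raise ValueError("cannot average an empty series")
    return series.frames.mean(axis=0)


def sparsify(series: CineSeries) -> SparseCine:
    """Transform a series into (average A, differences {s_i = x_i - A})."""
    avg = temporal_average(series)
    return SparseCine(
        average=avg,
        diffs=series.frames - avg[None],
        pixel_size_mm=series.pixel_size_mm,
        slice_thickness_mm=series.slice_thickness_mm,
    )


def desparsify(sparse: SparseCine) -> CineSeries:
    """Exact inverse of :func:`sparsify`: x_i = s_i + A."""
    return CineSeries(
        frames=sparse.diffs + sparse.average[None],
        pixel_size_mm=sparse.pixel_size_mm,
        slice_thickness_mm=sparse.slice_thickness_mm,
    )
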