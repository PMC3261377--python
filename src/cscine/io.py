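"""Hierarchical container I/O for multi-slice k-space data.

One HDF5 file holds the complex samples of every slice under
``slices/slice_NNN/samples`` with acquisition geometry in attributes; if an
undersampling mask is attached it is stored alongside as
``slices/slice_NNN/mask`` with the pattern metadata (R, sigma, seed,
score). Round-trips are lossless.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .recon import KSpaceCine
from .sampling import SamplingPattern

__all__ = ["save_kspace", "load_kspace"]


def save_kspace(path: str | Path, slices: list[KSpaceCine]) -> None:
    """Write one k-space dataset per slice to an HDF5 container."""
    with h5py.File(Path(path), "w") as fh:
        root = fh.create_group("slices")
        for z, ks in enumerate(slices):
            grp = root.create_group(f"slice_{z:03d}")
            grp.create_dataset("samples", data=ks.samples)
            grp.attrs["pixel_size_mm"] = ks.pixel_size_mm
            grp.attrs["slice_thickness_mm"] = ks.slice_thickness_mm
            if ks.pattern is not None:
                grp.create_dataset("mask", data=ks.pattern.mask)
                grp.attrs["R"] = ks.pattern.R
                grp.attrs["sigma"] = ks.pattern.sigma
                grp.attrs["seed"] = ks.pattern.seed
                grp.attrs["score"] = np.nan if ks.pattern.score is None else ks.pattern.score


def load_kspace(path: str | Path) -> list[KSpaceCine]:
    """Read every slice of a container written by :func:`save_kspace`."""
    out: list[KSpaceCine] = []
    with h5py.File(Path(path), "r") as fh:
        for name in sorted(fh["slices"]):
            grp = fh["slices"][name]
            pattern = None
            if "mask" in grp:
                score = float(grp.attrs["score"])
                pattern = SamplingPattern(
                    mask=grp["mask"][()],
                    R=float(grp.attrs["R"]),
                    sigma=float(grp.attrs["sigma"]),
                    seed=int(grp.attrs["seed"]),
                    score=None if np.isnan(score) else score,
                )
            out.append(
                KSpaceCine(
                    samples=grp["samples"][()],
                    pattern=pattern,
                    pixel_size_mm=float(grp.attrs["pixel_size_mm"]),
                    slice_thickness_mm=float(grp.attrs["slice_thickness_mm"]),
                )
            )
    return out
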