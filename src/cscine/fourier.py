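"""Centered, unitary 2-D Fourier transforms.

One convention package-wide: k-space is stored with the DC sample at index
(n//2, n//2) (even-size convention) and all transforms are unitary
(``norm="ortho"``), so Parseval's identity holds exactly and energy checks
need no bookkeeping. Transforms act on the last two axes; leading axes
(frames, slices) broadcast.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fft2c", "ifft2c"]

_AXES = (-2, -1)


def fft2c(x: np.ndarray) -> np.ndarray:
    """Image space -> centered k-space (unitary)."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )


def ifft2c(k: np.ndarray) -> np.ndarray:
    """Centered k-space -> image space (unitary)."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(k, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )
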