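"""Variable-density k-t undersampling pattern design.

Accelerated cine acquisitions omit phase-encode lines. A good mask for a
compressed-sensing reconstruction samples randomly (so aliasing is
incoherent), weights the k-space center (where most image energy lives),
changes from frame to frame, and still measures every phase-encode line at
least once over the cardiac cycle so a temporal-average image can be formed.

Candidates are drawn with Gaussian selection weights centered on k-space,
scored by the sidelobe-to-peak ratio of the per-frame point-spread function
(PSF) — the image-domain response of the binary mask, whose off-center lobes
measure how *coherent* the aliasing artifacts are — and the best of a pool
(200 by default, matching the scanner workflow) is kept.

Conventions: phase-encode indices are 0-based, k-space center at index
``n_pe // 2``; the center line is always sampled in every frame; the
aggregate pattern score is the maximum per-frame sidelobe-to-peak ratio
(conservative: the worst frame bounds the artifact coherence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SamplingPattern",
    "PSFProfile",
    "lines_per_frame",
    "generate_candidate",
    "psf_1d",
    "score_pattern",
    "select_pattern",
    "write_pattern_file",
    "read_pattern_file",
]


@dataclass
class SamplingPattern:
    """Binary k-t mask: which phase-encode lines each frame acquires.

    ``mask`` has shape ``(n_frames, n_pe)`` with entries 0/1. ``score`` is
    the PSF sidelobe-to-peak ratio, ``None`` until the pattern is scored.
    """

    mask: np.ndarray
    R: float
    sigma: float
    seed: int
    score: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.mask.ndim != 2:
            raise ValueError(f"mask must be 2-D (n_frames, n_pe), got {self.mask.shape}")
        if self.R < 1:
            raise ValueError(f"undersampling factor R must be >= 1, got {self.R}")

    @property
    def n_frames(self) -> int:
        return self.mask.shape[0]

    @property
    def n_pe(self) -> int:
        return self.mask.shape[1]

    @property
    def lines_per_frame(self) -> int:
        return lines_per_frame(self.n_pe, self.R)


@dataclass
class PSFProfile:
    """1-D point-spread function of a binary sampling row.

    ``profile`` is the magnitude response over the undersampled dimension
    with the mainlobe at index 0 (zero shift); ``sidelobe_to_peak`` is the
    largest off-mainlobe magnitude divided by the mainlobe magnitude.
    """

    profile: np.ndarray
    mainlobe_index: int
    sidelobe_to_peak: float


def lines_per_frame(n_pe: int, R: float) -> int:
    """Number of phase-encode lines acquired per frame at factor ``R``.

    Uses round-half-to-even, so non-integer factors (R = 2.5) are allowed:
    ``lines_per_frame(256, 2.5) == 102``. The same count applies to every
    frame of an acquisition.
    """
    if R < 1:
        raise ValueError(f"undersampling factor R must be >= 1, got {R}")
    if n_pe < 1:
        raise ValueError(f"n_pe must be >= 1, got {n_pe}")
    return int(np.round(n_pe / R))


def _gaussian_weights(n_pe: int, sigma: float) -> np.ndarray:
    center = n_pe // 2
    idx = np.arange(n_pe)
    return np.exp(-0.5 * ((idx - center) / sigma) ** 2)


def _repair_coverage(mask: np.ndarray, center: int) -> None:
    """Ensure every line is sampled >= once over the cycle, in place.

    Each never-sampled line (ascending) displaces the currently
    most-oversampled line (ties to the lowest index; the center line is
    never displaced) in the first frame that holds it, so per-frame counts
    are preserved. Deterministic scan order.
    """
    n_frames, n_pe = mask.shape
    for m in range(n_pe):
        if mask[:, m].any():
            continue
        colsum = mask.sum(axis=0, dtype=int)
        # candidate donors: sampled more than once, never the center line
        order = sorted(
            (d for d in range(n_pe) if d != m and d != center and colsum[d] > 1),
            key=lambda d: (-colsum[d], d),
        )
        done = False
        for d in order:
            for f in range(n_frames):
                if mask[f, d] and not mask[f, m]:
                    mask[f, d] = 0
                    mask[f, m] = 1
                    done = True
                    break
            if done:
                break
        if not done:  # cannot happen when n_frames * lines >= n_pe
            raise RuntimeError(f"coverage repair failed for line {m}")


def generate_candidate(
    n_pe: int,
    n_frames: int,
    R: float,
    sigma: float | None = None,
    seed: int = 0,
) -> SamplingPattern:
    """Draw one Gaussian-weighted random k-t mask with full-cycle coverage.

    Per frame, the center line plus ``lines_per_frame - 1`` further lines
    are drawn without replacement with selection probability proportional
    to a Gaussian of width ``sigma`` (default ``n_pe / 6``) centered on
    k-space. A deterministic repair pass then guarantees every line is
    measured at least once across the cycle. Deterministic per seed.
    """
    lines = lines_per_frame(n_pe, R)
    if lines < 1:
        raise ValueError(f"R={R} leaves no lines per frame for n_pe={n_pe}")
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    if n_frames * lines < n_pe:
        raise ValueError(
            f"full-cycle coverage unattainable: {n_frames} frames x {lines} "
            f"lines < {n_pe} phase-encode lines"
        )
    if sigma is None:
        sigma = n_pe / 6
    if R == 1 or lines == n_pe:
        mask = np.ones((n_frames, n_pe), dtype=np.uint8)
        return SamplingPattern(mask=mask, R=R, sigma=sigma, seed=seed)

    rng = np.random.default_rng(seed)
    center = n_pe // 2
    weights = _gaussian_weights(n_pe, sigma)
    others = np.array([i for i in range(n_pe) if i != center])
    w = weights[others]
    w = w / w.sum()

    mask = np.zeros((n_frames, n_pe), dtype=np.uint8)
    mask[:, center] = 1
    for f in range(n_frames):
        chosen = rng.choice(others, size=lines - 1, replace=False, p=w)
        mask[f, chosen] = 1
    _repair_coverage(mask, center)
    return SamplingPattern(mask=mask, R=R, sigma=sigma, seed=seed)


def psf_1d(mask_row: np.ndarray) -> PSFProfile:
    """Point-spread function of one binary sampling row.

    The PSF is the inverse DFT of the mask along the undersampled
    dimension; its magnitude is origin-independent, with the mainlobe at
    zero shift. A fully sampled row gives a discrete delta (ratio 0); a
    uniform every-other-line comb gives a single replica of mainlobe height
    (ratio 1); a single line gives a flat profile (ratio 1).
    """
    row = np.asarray(mask_row, dtype=float)
    if row.ndim != 1:
        raise ValueError("mask_row must be 1-D")
    if row.sum() < 1:
        raise ValueError("mask_row has no sampled line")
    profile = np.abs(np.fft.ifft(row))
    main = profile[0]
    side = float(profile[1:].max()) if profile.size > 1 else 0.0
    return PSFProfile(
        profile=profile,
        mainlobe_index=0,
        sidelobe_to_peak=side / main,
    )


def score_pattern(pattern: SamplingPattern) -> float:
    """Aggregate sidelobe-to-peak score: the maximum over per-frame PSFs.

    Stored on ``pattern.score``; invariant under frame reordering.
    """
    score = max(psf_1d(row).sidelobe_to_peak for row in pattern.mask)
    pattern.score = float(score)
    return pattern.score


def select_pattern(
    n_pe: int,
    n_frames: int,
    R: float,
    sigma: float | None = None,
    n_candidates: int = 200,
    seed: int = 0,
) -> SamplingPattern:
    """Best-of-pool pattern selection by minimum sidelobe-to-peak ratio.

    Generates ``n_candidates`` candidates from a seeded stream, scores each
    and returns the minimizer (ties broken by lowest candidate index).
    """
    if n_candidates < 1:
        raise ValueError(f"n_candidates must be >= 1, got {n_candidates}")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_candidates)
    best: SamplingPattern | None = None
    for s in child_seeds:
        cand = generate_candidate(n_pe, n_frames, R, sigma=sigma, seed=int(s))
        score_pattern(cand)
        if best is None or cand.score < best.score:
            best = cand
    assert best is not None
    return best


def write_pattern_file(pattern: SamplingPattern, path: str | Path) -> None:
    """Write a scanner-style pattern text file.

    Header lines (``# key value``) record n_pe, n_frames, R, sigma, seed
    and score; then one line per frame listing the sampled phase-encode
    indices, 0-based, ascending, space-separated. Round-trip through
    :func:`read_pattern_file` is lossless.
    """
    path = Path(path)
    lines = [
        f"# n_pe {pattern.n_pe}",
        f"# n_frames {pattern.n_frames}",
        f"# R {pattern.R!r}",
        f"# sigma {pattern.sigma!r}",
        f"# seed {pattern.seed}",
        f"# score {'nan' if pattern.score is None else repr(pattern.score)}",
    ]
    for row in pattern.mask:
        idx = np.flatnonzero(row)
        lines.append(" ".join(str(i) for i in idx))
    path.write_text("\n".join(lines) + "\n")


def read_pattern_file(path: str | Path) -> SamplingPattern:
    """Read a pattern text file written by :func:`write_pattern_file`.

    Malformed content raises ``ValueError`` naming the offending line
    number (1-based).
    """
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[np.ndarray] = []
    text = path.read_text().splitlines()
    for lineno, line in enumerate(text, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split(None, 1)
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: malformed header line {line!r}")
            header[parts[0]] = parts[1]
            continue
        try:
            idx = np.array([int(tok) for tok in line.split()], dtype=int)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-integer index in {line!r}") from exc
        rows.append((lineno, idx))
    for key in ("n_pe", "n_frames", "R", "sigma", "seed"):
        if key not in header:
            raise ValueError(f"line 1: missing header field {key!r}")
    n_pe = int(header["n_pe"])
    n_frames = int(header["n_frames"])
    if len(rows) != n_frames:
        raise ValueError(
            f"line {len(text)}: expected {n_frames} frame lines, found {len(rows)}"
        )
    mask = np.zeros((n_frames, n_pe), dtype=np.uint8)
    for f, (lineno, idx) in enumerate(rows):
        if idx.size and (idx.min() < 0 or idx.max() >= n_pe):
            raise ValueError(f"line {lineno}: index out of range [0, {n_pe})")
        if np.unique(idx).size != idx.size:
            raise ValueError(f"line {lineno}: duplicate phase-encode index")
        if np.any(np.diff(idx) < 0):
            raise ValueError(f"line {lineno}: indices not ascending")
        mask[f, idx] = 1
    score_str = header.get("score", "nan")
    score = None if math.isnan(float(score_str)) else float(score_str)
    return SamplingPattern(
        mask=mask,
        R=float(header["R"]),
        sigma=float(header["sigma"]),
        seed=int(header["seed"]),
        score=score,
    )
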