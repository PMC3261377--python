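"""Left-ventricular quantification and method-agreement statistics.

From per-frame label masks (0 = background, 1 = myocardium, 2 = blood
pool) the module computes the standard global functional parameters:

    EDV, ESV  end-diastolic / end-systolic blood-pool volume (uL),
              voxel count x voxel volume summed over slices at the frames
              of maximal / minimal blood-pool volume
    SV        stroke volume = EDV - ESV
    EF        ejection fraction = 100 * SV / EDV  (%)
    LVM       myocardial volume at end-diastole x density (mg),
              density default 1.05 mg/uL

Agreement between two measurement protocols is assessed with Bland-Altman
statistics (bias = mean paired difference, limits = bias +/- 2 SD) and a
percent observer-variability summary (difference over the pairwise mean).

A threshold-plus-largest-component segmenter is included so the phantom's
magnitude reconstructions can be quantified automatically; it is a
convenience for piecewise-constant phantom images, not a validated cardiac
segmenter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_multiotsu
from skimage.measure import label as cc_label

__all__ = [
    "LVMetrics",
    "AgreementStats",
    "lv_metrics",
    "segment_threshold",
    "bland_altman",
    "observer_variability",
    "protocol_comparison_table",
    "METRIC_ORDER",
]

#: fixed row order of every tabular metric output
METRIC_ORDER = ("LVM", "EDV", "ESV", "SV", "EF")


@dataclass
class LVMetrics:
    """Global left-ventricular structural and functional parameters."""

    lvm_mg: float
    edv_ul: float
    esv_ul: float
    sv_ul: float
    ef_pct: float

    @classmethod
    def from_volumes(cls, lvm_mg: float, edv_ul: float, esv_ul: float) -> "LVMetrics":
        """Derive SV and EF from the defining identities."""
        if edv_ul <= 0:
            raise ValueError(f"EDV must be positive, got {edv_ul}")
        if esv_ul < 0 or esv_ul > edv_ul:
            raise ValueError(f"ESV must lie in [0, EDV], got ESV={esv_ul}, EDV={edv_ul}")
        sv = edv_ul - esv_ul
        return cls(
            lvm_mg=lvm_mg,
            edv_ul=edv_ul,
            esv_ul=esv_ul,
            sv_ul=sv,
            ef_pct=100.0 * sv / edv_ul,
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "LVM": self.lvm_mg,
            "EDV": self.edv_ul,
            "ESV": self.esv_ul,
            "SV": self.sv_ul,
            "EF": self.ef_pct,
        }


@dataclass
class AgreementStats:
    """Bland-Altman summary of paired differences (method2 - method1)."""

    bias: float
    sd: float
    lower_limit: float
    upper_limit: float
    n: int


def _blood_volume_per_frame(labels: np.ndarray, voxel_volume_ul: float) -> np.ndarray:
    return (labels == 2).sum(axis=(0, 2, 3)) * voxel_volume_ul


def lv_metrics(
    labels: np.ndarray,
    voxel_area_mm2: float,
    slice_thickness_mm: float,
    density_mg_per_ul: float = 1.05,
    ed_frame: int | None = None,
    es_frame: int | None = None,
) -> LVMetrics:
    """LV metrics from label masks of shape (n_slices, n_frames, ny, nx).

    ED and ES frames default to the frames of maximal and minimal total
    blood-pool volume (ties to the earliest frame), the standard choice for
    a cine train and robust to reconstruction blur.
    """
    labels = np.asarray(labels)
    if labels.ndim != 4:
        raise ValueError(
            f"labels must be (n_slices, n_frames, ny, nx), got {labels.shape}"
        )
    vox = voxel_area_mm2 * slice_thickness_mm
    blood = _blood_volume_per_frame(labels, vox)
    if ed_frame is None:
        ed_frame = int(np.argmax(blood))
    if es_frame is None:
        es_frame = int(np.argmin(blood))
    edv = float(blood[ed_frame])
    esv = float(blood[es_frame])
    if edv <= 0:
        raise ValueError(f"empty blood pool at end-diastolic frame {ed_frame}")
    if esv > edv:
        raise ValueError(
            f"ESV ({esv:.3g} uL, frame {es_frame}) exceeds EDV ({edv:.3g} uL, "
            f"frame {ed_frame}); check frame selection"
        )
    lvm = float((labels[:, ed_frame] == 1).sum() * vox * density_mg_per_ul)
    return LVMetrics.from_volumes(lvm_mg=lvm, edv_ul=edv, esv_ul=esv)


def segment_threshold(magnitudes: np.ndarray) -> np.ndarray:
    """Three-class threshold segmentation of phantom magnitude images.

    Two Otsu thresholds separate background / myocardium / blood over the
    pooled intensity distribution; per slice and frame the blood pool is
    reduced to its largest connected component (stray supra-threshold noise
    pixels are relabeled as myocardium). Input shape
    (n_slices, n_frames, ny, nx); output labels of the same shape.
    """
    mag = np.asarray(magnitudes, dtype=float)
    if mag.ndim != 4:
        raise ValueError(
            f"magnitudes must be (n_slices, n_frames, ny, nx), got {mag.shape}"
        )
    t_low, t_high = threshold_multiotsu(mag.ravel(), classes=3)
    labels = np.zeros(mag.shape, dtype=np.uint8)
    labels[mag > t_low] = 1
    blood = mag > t_high
    for z in range(mag.shape[0]):
        for f in range(mag.shape[1]):
            comp = cc_label(blood[z, f])
            if comp.max() == 0:
                continue
            sizes = np.bincount(comp.ravel())
            sizes[0] = 0
            labels[z, f][comp == sizes.argmax()] = 2
    return labels


def bland_altman(pairs: np.ndarray) -> AgreementStats:
    """Bland-Altman agreement of two methods from paired measurements.

    ``pairs`` is an (n, 2) sequence of (method1, method2) values;
    differences are method2 - method1, bias their mean, sd the sample
    standard deviation (n-1 denominator), limits bias +/- 2 sd.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"pairs must have shape (n, 2), got {arr.shape}")
    n = arr.shape[0]
    if n < 2:
        raise ValueError(f"Bland-Altman needs at least 2 pairs, got {n}")
    d = arr[:, 1] - arr[:, 0]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementStats(
        bias=bias,
        sd=sd,
        lower_limit=bias - 2.0 * sd,
        upper_limit=bias + 2.0 * sd,
        n=n,
    )


def observer_variability(set_a: np.ndarray, set_b: np.ndarray) -> tuple[float, float]:
    """Percent variability between paired measurement sets: mean +/- SD.

    Per pair the percent difference is 100 * (a - b) / ((a + b) / 2);
    returns its mean and sample SD. Swapping the sets negates every
    difference. A pair with a + b = 0 has no defined percent difference and
    raises.
    """
    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("set_a and set_b must be equal-length 1-D sequences")
    mean_ab = (a + b) / 2.0
    if np.any(mean_ab == 0):
        raise ValueError("pair with zero mean: percent difference undefined")
    pct = 100.0 * (a - b) / mean_ab
    sd = float(pct.std(ddof=1)) if pct.size > 1 else 0.0
    return float(pct.mean()), sd


def protocol_comparison_table(
    metrics: dict[str, dict[str, LVMetrics]]
) -> pd.DataFrame:
    """Per-protocol mean +/- SD table of LV metrics across animals.

    ``metrics`` maps protocol -> animal -> :class:`LVMetrics`; every
    protocol must cover the same animals (a missing cell raises, listing
    the gap). Rows are fixed in the order LVM, EDV, ESV, SV, EF; columns
    are a (protocol, statistic) MultiIndex with statistic in {mean, sd}
    (sample SD, 0 for a single animal).
    """
    protocols = list(metrics)
    if not protocols:
        raise ValueError("no protocols given")
    animals = sorted(metrics[protocols[0]])
    missing = [
        f"{p}/{a}"
        for p in protocols
        for a in animals
        if a not in metrics[p]
    ] + [
        f"{protocols[0]}/{a}"
        for p in protocols[1:]
        for a in metrics[p]
        if a not in set(animals)
    ]
    if missing:
        raise ValueError(f"missing animal/protocol cells: {sorted(set(missing))}")
    cols = pd.MultiIndex.from_product([protocols, ["mean", "sd"]])
    table = pd.DataFrame(index=list(METRIC_ORDER), columns=cols, dtype=float)
    for p in protocols:
        values = pd.DataFrame([metrics[p][a].as_dict() for a in animals])
        for m in METRIC_ORDER:
            table.loc[m, (p, "mean")] = values[m].mean()
            table.loc[m, (p, "sd")] = values[m].std(ddof=1) if len(animals) > 1 else 0.0
    return table
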