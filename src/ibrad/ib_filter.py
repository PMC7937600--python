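"""Intensity-based (IB) percentile filter and Laplacian-of-Gaussian filter.

The IB filter is the harmonisation mechanism this pipeline studies: ROI
intensities are rescaled between the 1st and 99th percentile of the ROI
histogram, and pixel clusters are cut out between a lower and an upper
percentage threshold of the normalised range. Because the percentile
normalisation removes any positive affine transform of the grey scale
(gain/offset differences between scanners and field strengths), every
feature computed on a cluster is scanner-invariant by construction.

Thresholds run on a percent grid (default 0..100 by 10), giving the
55 ordered lower<upper pairs of the full threshold enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .imaging import ROIMask, ScanImage

VALID_STEPS = (10, 20, 25, 50, 100)


@dataclass(frozen=True)
class IBParams:
    """Lower/upper threshold pair in integer percent, ``lower < upper``."""

    lower_pct: int
    upper_pct: int

    def __post_init__(self) -> None:
        if not (0 <= self.lower_pct < self.upper_pct <= 100):
            raise ValueError(f"invalid IB thresholds ({self.lower_pct}, {self.upper_pct})")

    @property
    def label(self) -> str:
        return f"ib_{self.lower_pct}_{self.upper_pct}"


@dataclass(frozen=True)
class LoGParams:
    """Gaussian width of the LoG filter, in physical millimetres."""

    sigma_mm: float

    def __post_init__(self) -> None:
        if self.sigma_mm <= 0:
            raise ValueError("sigma_mm must be positive")

    @property
    def label(self) -> str:
        return f"log_{self.sigma_mm:g}mm"


@dataclass
class ClusterMask:
    """Subset of the ROI selected by one IB threshold pair. May be empty."""

    voxels: np.ndarray
    params: IBParams

    @property
    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


def ib_normalise(values: np.ndarray) -> np.ndarray:
    """Rescale ROI intensities onto [0, 1] between their P1 and P99.

    ``v' = clip((v - P1) / (P99 - P1), 0, 1)`` with percentiles taken by
    linear interpolation on the ROI histogram. Order is preserved. A
    near-constant ROI (P99 == P1) has no usable grey-level range and is
    rejected.
    """
    values = np.asarray(values, dtype=np.float64)
    if np.unique(values).size < 2:
        raise ValueError("degenerate intensity range")
    p1, p99 = np.percentile(values, [1.0, 99.0])
    if p99 - p1 <= 0:
        raise ValueError("degenerate intensity range")
    return np.clip((values - p1) / (p99 - p1), 0.0, 1.0)


def normalise_volume(img: ScanImage, roi: ROIMask) -> np.ndarray:
    """Full-grid array of IB-normalised intensities (NaN outside the ROI)."""
    out = np.full(img.voxels.shape, np.nan)
    out[roi.voxels] = ib_normalise(img.voxels[roi.voxels])
    return out


def ib_cluster(img_norm: np.ndarray, roi: ROIMask, params: IBParams) -> ClusterMask:
    """Select ROI voxels whose normalised intensity falls in the band.

    Membership is half-open, ``lower/100 <= v < upper/100``, except that the
    top band (``upper == 100``) is closed at 1.0 so adjacent bands partition
    the ROI. An empty cluster is a valid, flagged outcome.
    """
    lo = params.lower_pct / 100.0
    hi = params.upper_pct / 100.0
    with np.errstate(invalid="ignore"):
        if params.upper_pct == 100:
            sel = (img_norm >= lo) & (img_norm <= hi)
        else:
            sel = (img_norm >= lo) & (img_norm < hi)
    return ClusterMask(voxels=sel & roi.voxels, params=params)


def enumerate_ib_pairs(step_pct: int = 10) -> list[IBParams]:
    """All ordered (lower, upper) pairs on the percent grid, lexicographic.

    ``step_pct`` must divide 100 onto an integer grid; the default step of 10
    yields the 55 pairs of the full enumeration (C(11, 2)).
    """
    if step_pct not in VALID_STEPS:
        raise ValueError(f"step_pct must be one of {VALID_STEPS}, got {step_pct}")
    levels = list(range(0, 101, step_pct))
    return [IBParams(lo, hi) for i, lo in enumerate(levels) for hi in levels[i + 1 :]]


def _log_kernels(sigma: float, truncate: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Sampled Gaussian (sum 1) and its second derivative (sum exactly 0).

    A truncated second-derivative kernel does not sum to zero, which leaves a
    spurious DC response (~1e-3 of a constant image at sigma 1); the mean
    correction removes it so the filter annihilates constants exactly.
    """
    radius = max(1, int(truncate * sigma + 0.5))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(x * x) / (2.0 * sigma * sigma))
    g /= g.sum()
    d2 = (x * x / sigma**4 - 1.0 / sigma**2) * g
    d2 -= d2.mean()
    return g, d2


def export_cluster_mask(path, cluster: ClusterMask, spacing) -> None:
    """Write a cluster mask as NIfTI for visual debugging."""
    import numpy as _np

    from .imaging import write_nifti

    write_nifti(path, ScanImage(cluster.voxels.astype(_np.float64), spacing))


def log_filter(img: ScanImage, params: LoGParams) -> ScanImage:
    """Per-slice 2-D Laplacian-of-Gaussian response.

    Sigma is specified in millimetres and converted to pixels through the
    in-plane spacing, so the same physical scale is probed on every scanner
    grid. Geometry is unchanged. A sigma below half a pixel degenerates
    towards the discrete Laplacian and is flagged with a warning.
    """
    from scipy.ndimage import correlate1d

    row_mm, col_mm, _ = img.spacing
    sigma_px = (params.sigma_mm / row_mm, params.sigma_mm / col_mm)
    if min(sigma_px) < 0.5:
        warnings.warn(
            f"LoG sigma {params.sigma_mm} mm is {min(sigma_px):.2f} px on this grid; "
            "response approximates a discrete Laplacian",
            stacklevel=2,
        )
    g_r, d2_r = _log_kernels(sigma_px[0])
    g_c, d2_c = _log_kernels(sigma_px[1])
    out = np.empty_like(img.voxels, dtype=np.float64)
    for k in range(img.voxels.shape[0]):
        sl = img.voxels[k].astype(np.float64)
        rr = correlate1d(correlate1d(sl, d2_r, axis=0, mode="reflect"), g_c, axis=1, mode="reflect")
        cc = correlate1d(correlate1d(sl, g_r, axis=0, mode="reflect"), d2_c, axis=1, mode="reflect")
        out[k] = rr + cc
    return ScanImage(out, img.spacing, img.patient_id, img.cohort)
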