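"""SNR and CNR figures of merit from paired cementum/background ROIs.

SNR is the mean cementum greyscale over the background standard deviation;
CNR is the cementum/background mean difference over the pooled standard
deviation sqrt((sigma_c^2 + sigma_b^2)/2). Sample (n-1) standard deviations
are used throughout. ROI placement is user-supplied, never auto-detected.
"""

from __future__ import annotations

import dataclasses

import numpy as np

DEFAULT_ROI_SIZE = 150


@dataclasses.dataclass(frozen=True)
class QualityROI:
    """Square ROI pair: (x, y) are the top-left corners, size the edge."""

    cementum_xy: tuple[int, int]
    background_xy: tuple[int, int]
    size: int = DEFAULT_ROI_SIZE

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("ROI size must be >= 2")
        cx, cy = self.cementum_xy
        bx, by = self.background_xy
        if (abs(cx - bx) < self.size) and (abs(cy - by) < self.size):
            raise ValueError("cementum and background ROIs overlap")

    def extract(self, slice_px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h, w = slice_px.shape
        for (x, y) in (self.cementum_xy, self.background_xy):
            if not (0 <= x and x + self.size <= w and 0 <= y and y + self.size <= h):
                raise ValueError(f"ROI at ({x}, {y}) size {self.size} "
                                 f"outside slice of shape {slice_px.shape}")
        cx, cy = self.cementum_xy
        bx, by = self.background_xy
        return (slice_px[cy:cy + self.size, cx:cx + self.size],
                slice_px[by:by + self.size, bx:bx + self.size])


@dataclasses.dataclass
class QualityMetrics:
    snr_per_slice: list[float]
    cnr_per_slice: list[float]

    @property
    def n_slices(self) -> int:
        return len(self.snr_per_slice)

    @property
    def mean_snr(self) -> float:
        return float(np.mean(self.snr_per_slice))

    @property
    def mean_cnr(self) -> float:
        return float(np.mean(self.cnr_per_slice))


def snr(cementum_roi: np.ndarray, background_roi: np.ndarray) -> float:
    """Mean cementum greyscale / sample SD of the background."""
    sigma_b = float(np.std(background_roi, ddof=1))
    if sigma_b == 0:
        raise ValueError("undefined SNR: background ROI has zero variance")
    return float(np.mean(cementum_roi)) / sigma_b


def cnr(cementum_roi: np.ndarray, background_roi: np.ndarray) -> float:
    """(mean_c - mean_b) / sqrt((sigma_c^2 + sigma_b^2) / 2)."""
    var_c = float(np.var(cementum_roi, ddof=1))
    var_b = float(np.var(background_roi, ddof=1))
    if var_c + var_b == 0:
        raise ValueError("undefined CNR: both ROIs have zero variance")
    return (float(np.mean(cementum_roi)) - float(np.mean(background_roi))) \
        / np.sqrt((var_c + var_b) / 2.0)


def stack_quality(stack, rois: QualityROI,
                  slice_indices: list[int] | None = None) -> QualityMetrics:
    """Per-slice SNR/CNR plus their means over the listed slices."""
    if slice_indices is None:
        slice_indices = list(range(min(len(stack), 10)))
    if not slice_indices:
        raise ValueError("no slice indices given")
    snrs, cnrs = [], []
    for i in slice_indices:
        if not 0 <= i < len(stack):
            raise IndexError(f"slice index {i} outside stack of {len(stack)}")
        cem, bg = rois.extract(stack.slices[i])
        try:
            snrs.append(snr(cem, bg))
            cnrs.append(cnr(cem, bg))
        except ValueError as exc:
            raise ValueError(f"slice {i}: {exc}") from exc
    return QualityMetrics(snr_per_slice=snrs, cnr_per_slice=cnrs)
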