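"""Voxel-level image metrics for remyelination histology.

Two metrics, both computed on binarized channels:

* remyelination index — voxels positive for both the myelin channel (MBP) and
  the axon channel (neurofilament, NFH), divided by the axon-positive voxel
  count. Normalizing to axon voxels makes the index robust to variation in
  axonal density between animals; it lies in [0, 1].
* percent positive area — percentage of a region of interest covered by a
  positive channel mask (e.g. MBP coverage of the corpus callosum).

Binarization is strict ``value > threshold``; thresholds are either Otsu per
channel (default, reproducible without hand-picked values) or fixed numbers
in native intensity units, recorded in the result either way. No filtering is
applied by default; a 3-voxel median filter is available behind a flag to
keep the metric minimal and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "ChannelVolume",
    "ColocalizationResult",
    "remyelination_index",
    "percent_positive_area",
]


@dataclass
class ChannelVolume:
    """A single-channel intensity grid (z, y, x) with an optional label."""

    values: np.ndarray
    label: str = ""
    voxel_size: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.size == 0:
            raise ValueError(f"channel {self.label!r} is empty")
        if not np.isfinite(np.asarray(self.values, dtype=float)).all():
            raise ValueError(f"channel {self.label!r} contains non-finite values")


@dataclass
class ColocalizationResult:
    """Voxel counts for each channel mask, their intersection, and the index."""

    axon_voxels: int
    myelin_voxels: int
    overlap_voxels: int
    index: float
    myelin_threshold: float
    axon_threshold: float
    threshold_method: str


def _as_array(channel) -> np.ndarray:
    if isinstance(channel, ChannelVolume):
        return np.asarray(channel.values)
    arr = np.asarray(channel)
    if arr.size == 0:
        raise ValueError("channel is empty")
    return arr


def _binarize(arr: np.ndarray, threshold, median_filter: bool):
    if median_filter:
        arr = ndimage.median_filter(arr, size=3)
    if threshold == "otsu":
        t = float(threshold_otsu(arr))
        method = "otsu"
    else:
        t = float(threshold)
        method = "fixed"
    return arr > t, t, method


def remyelination_index(
    myelin,
    axon,
    threshold="otsu",
    axon_threshold=None,
    median_filter: bool = False,
) -> ColocalizationResult:
    """Colocalized (myelin AND axon) voxels normalized to axon voxels.

    Parameters
    ----------
    myelin, axon
        Intensity grids (``ChannelVolume`` or array) of identical shape.
    threshold
        ``"otsu"`` for a per-channel Otsu threshold, or a number applied to
        the myelin channel (then ``axon_threshold`` applies to the axon
        channel, defaulting to the same value).
    axon_threshold
        Optional separate fixed threshold for the axon channel.
    median_filter
        Apply a 3-voxel median filter before thresholding.
    """
    m = _as_array(myelin)
    a = _as_array(axon)
    if m.shape != a.shape:
        raise ValueError(f"channel shapes differ: myelin {m.shape} vs axon {a.shape}")
    m_mask, t_m, method = _binarize(m, threshold, median_filter)
    a_thr = threshold if axon_threshold is None else axon_threshold
    a_mask, t_a, _ = _binarize(a, a_thr, median_filter)
    n_axon = int(a_mask.sum())
    if n_axon == 0:
        raise ValueError("axon mask is empty after thresholding; index undefined")
    n_myelin = int(m_mask.sum())
    n_overlap = int((m_mask & a_mask).sum())
    return ColocalizationResult(
        axon_voxels=n_axon,
        myelin_voxels=n_myelin,
        overlap_voxels=n_overlap,
        index=n_overlap / n_axon,
        myelin_threshold=t_m,
        axon_threshold=t_a,
        threshold_method=method,
    )


def percent_positive_area(
    channel,
    roi,
    threshold="otsu",
    median_filter: bool = False,
) -> float:
    """Percentage of the ROI covered by the positive channel mask.

    Works identically on 2-D images and 3-D stacks; the ROI is a boolean mask
    of the same shape and must be nonempty.
    """
    arr = _as_array(channel)
    roi = np.asarray(roi).astype(bool)
    if roi.shape != arr.shape:
        raise ValueError(f"ROI shape {roi.shape} differs from channel {arr.shape}")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("ROI is empty")
    mask, _, _ = _binarize(arr, threshold, median_filter)
    return 100.0 * int((mask & roi).sum()) / n_roi
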