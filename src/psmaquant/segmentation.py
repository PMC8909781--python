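"""Threshold-based 3-D lesion segmentation inside operator-drawn VOIs.

Two thresholding strategies are provided. The absolute strategy keeps voxels
whose SUV exceeds a fixed value (3.0 by default for bone, and — lacking a
published scan-dependent formula — also for soft tissue, with a callable
plug-in point). The relative (isocontour) strategy thresholds at a fraction
of the VOI's SUVmax (45% by default); it is known to underestimate volumes of
high-uptake tumors and is provided for method comparison, not for the main
pipeline. Supra-threshold voxels are split into connected components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .errors import DegenerateDataError, GeometryMismatchError, ValidationError
from .volume_io import SUVVolume, VOIMask, check_aligned

#: 3-D connectivity -> scipy rank of the structuring element.
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}

ThresholdFn = Callable[[SUVVolume, VOIMask], float]


@dataclass
class SegmentationConfig:
    """Tunable segmentation parameters.

    ``bone_threshold`` is the absolute SUV cutoff for skeletal lesions;
    ``soft_tissue_threshold`` is either an absolute SUV or a callable
    ``f(volume, voi) -> SUV`` for scan-context-dependent formulas;
    ``isocontour_fraction`` applies only to the relative strategy;
    ``strict`` selects ``>`` (default, "above the threshold") vs ``>=``.
    """

    bone_threshold: float = 3.0
    soft_tissue_threshold: float | ThresholdFn = 3.0
    isocontour_fraction: float = 0.45
    connectivity: int = 26
    min_lesion_voxels: int = 1
    strict: bool = True

    def __post_init__(self) -> None:
        if self.bone_threshold <= 0:
            raise ValidationError("bone_threshold must be > 0")
        if not 0 < self.isocontour_fraction < 1:
            raise ValidationError("isocontour_fraction must be in (0, 1)")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValidationError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
        if self.min_lesion_voxels < 1:
            raise ValidationError("min_lesion_voxels must be >= 1")

    def threshold_for(self, volume: SUVVolume, voi: VOIMask) -> float:
        if voi.compartment == "bone":
            return float(self.bone_threshold)
        if callable(self.soft_tissue_threshold):
            return float(self.soft_tissue_threshold(volume, voi))
        return float(self.soft_tissue_threshold)


@dataclass
class LesionSegment:
    """A connected set of supra-threshold voxels inside one compartment VOI."""

    compartment: str
    voxel_indices: np.ndarray  # (n, 3) int array, lexicographically sorted
    threshold_used: float
    lesion_id: int = 0

    def __post_init__(self) -> None:
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=np.intp)
        if self.voxel_indices.ndim != 2 or self.voxel_indices.shape[1] != 3:
            raise ValidationError("voxel_indices must be an (n, 3) array")
        if len(self.voxel_indices) == 0:
            raise ValidationError("a lesion segment cannot be empty")

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)

    def as_tuples(self) -> set[tuple[int, int, int]]:
        return {tuple(int(v) for v in row) for row in self.voxel_indices}


def extract_components(binary: np.ndarray, connectivity: int = 26) -> list[np.ndarray]:
    """Partition the True voxels of a 3-D binary grid into connected components.

    Returns one ``(n, 3)`` index array per maximal component, ordered by the
    minimum linear (C-order) index of each component, rows sorted
    lexicographically — a deterministic partition.
    """
    binary = np.asarray(binary).astype(bool)
    if binary.ndim != 3:
        raise ValidationError(f"expected a 3-D binary grid, got {binary.ndim} axes")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValidationError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(binary, structure=structure)
    comps = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        # argwhere already yields lexicographic order; min linear index is idx[0]
        key = np.ravel_multi_index(idx[0], binary.shape)
        comps.append((int(key), idx))
    comps.sort(key=lambda t: t[0])
    return [idx for _, idx in comps]


def _segment_at(
    volume: SUVVolume,
    voi: VOIMask,
    threshold: float,
    config: SegmentationConfig,
) -> list[LesionSegment]:
    check_aligned(volume, voi)
    if config.strict:
        supra = (volume.grid > threshold) & voi.grid
    else:
        supra = (volume.grid >= threshold) & voi.grid
    segs = []
    for idx in extract_components(supra, config.connectivity):
        if len(idx) >= config.min_lesion_voxels:
            segs.append(LesionSegment(voi.compartment, idx, float(threshold)))
    for i, seg in enumerate(segs):
        seg.lesion_id = i
    return segs


def segment_absolute(
    volume: SUVVolume,
    voi: VOIMask,
    threshold: float,
    config: SegmentationConfig | None = None,
) -> list[LesionSegment]:
    """Segment lesions as connected components of voxels with SUV above ``threshold``.

    Returns the empty list when no voxel exceeds the threshold.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    return _segment_at(volume, voi, threshold, config or SegmentationConfig())


def segment_isocontour(
    volume: SUVVolume,
    voi: VOIMask,
    fraction: float | None = None,
    config: SegmentationConfig | None = None,
) -> list[LesionSegment]:
    """Segment at a fraction of the VOI's SUVmax (45% isocontour by default).

    The threshold is ``fraction * max(SUV inside voi)`` and is recorded on
    every returned segment. An all-zero VOI maximum is rejected because the
    threshold would degenerate to 0.
    """
    config = config or SegmentationConfig()
    if fraction is None:
        fraction = config.isocontour_fraction
    if not 0 < fraction < 1:
        raise ValidationError("isocontour fraction must be in (0, 1)")
    check_aligned(volume, voi)
    if not voi.grid.any():
        raise DegenerateDataError("VOI is empty; isocontour threshold undefined")
    voi_max = float(volume.grid[voi.grid].max())
    if voi_max <= 0:
        raise DegenerateDataError("VOI maximum SUV is 0; isocontour threshold degenerates")
    return _segment_at(volume, voi, fraction * voi_max, config)


def segment_scan(
    volume: SUVVolume,
    vois: Sequence[VOIMask],
    config: SegmentationConfig | None = None,
) -> list[LesionSegment]:
    """Segment every compartment VOI of one scan with its configured threshold.

    Bone VOIs use ``bone_threshold``; prostate/node VOIs use the soft-tissue
    strategy. Lesion ids are unique within each compartment.
    """
    config = config or SegmentationConfig()
    segments: list[LesionSegment] = []
    for voi in vois:
        segments.extend(_segment_at(volume, voi, config.threshold_for(volume, voi), config))
    return segments
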