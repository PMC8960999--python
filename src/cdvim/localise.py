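"""Connectivity-defined Vim extraction.

The Vim region is the intersection of the normalised tract reconstruction
with the thalamic mask, binarised at an adaptive threshold: a fixed fraction
(default 20%) of the maximum connectivity value *within the intersection*.
The reported centroid is the unweighted mean voxel-centre position of the
largest 26-connected component, mapped to world mm through the affine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import VolumeGrid
from .tracking import PICoMap

_CONN26 = np.ones((3, 3, 3), dtype=int)


class NoConnectivityError(ValueError):
    """The tract map is identically zero inside the thalamic mask."""


@dataclass(frozen=True)
class VimResult:
    hemisphere: str  # "L" | "R"
    roi: np.ndarray  # binary volume (post-threshold)
    roi_volume_mm3: float  # post-threshold (canonical)
    intersection_volume_mm3: float  # pre-threshold support, for reference
    centroid_world: np.ndarray  # (ML, AP, SI) mm
    max_pico_in_intersection: float


def intersect_dtcp_thalamus(dtcp: PICoMap, thalamus_mask: np.ndarray) -> PICoMap:
    """Zero the tract map outside the thalamic mask."""
    if thalamus_mask.shape != dtcp.grid.dims:
        raise ValueError("thalamus mask does not match the map grid")
    data = np.where(thalamus_mask.astype(bool), dtcp.data, 0.0)
    if not np.any(data > 0):
        raise NoConnectivityError("no connectivity inside the thalamic mask")
    return PICoMap(dtcp.grid, data, state=dtcp.state, norm_max=dtcp.norm_max)


def adaptive_threshold(intersection: PICoMap, fraction: float = 0.2) -> np.ndarray:
    """Keep voxels at or above ``fraction`` of the intersection maximum.

    The comparison is >= so the maximum voxel always survives; the rule is
    invariant to any positive rescaling of the map.  A relative guard of
    1e-12 keeps voxels sitting exactly on the cut-point on the same side of
    it regardless of the map's floating-point scale.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    peak = float(intersection.data.max())
    if peak <= 0:
        raise ValueError("intersection map has no positive voxel")
    return intersection.data >= (fraction - 1e-12) * peak


def _largest_component(
    roi: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Largest 26-connected component; size ties broken by higher mean weight."""
    labels, nlab = ndimage.label(roi, structure=_CONN26)
    if nlab == 0:
        raise ValueError("ROI is empty")
    if nlab == 1:
        return labels == 1
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, nlab + 1))
    best = sizes.max()
    tied = np.nonzero(sizes == best)[0] + 1
    if len(tied) > 1 and weights is not None:
        means = ndimage.mean(weights, labels, index=tied)
        winner = int(tied[int(np.argmax(means))])
    else:
        winner = int(tied[0])
    return labels == winner


def centroid_world(
    roi: np.ndarray, affine: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """World-space centroid of the largest 26-connected component of a ROI.

    Unweighted mean of the component's voxel-centre coordinates in voxel
    space, mapped through the affine.  ``weights`` (the intersection map) is
    only consulted to break exact size ties between components.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    comp = _largest_component(roi, weights)
    ijk = np.argwhere(comp).mean(axis=0)
    affine = np.asarray(affine, dtype=float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def localise_vim(
    dtcp: PICoMap,
    thalamus_mask: np.ndarray,
    fraction: float = 0.2,
    hemisphere: str = "L",
    *,
    weighted_centroid: bool = False,
) -> VimResult:
    """Full localisation: intersect, adaptively threshold, take the centroid.

    ``weighted_centroid`` switches to a connectivity-weighted mean over the
    largest component (off by default; the unweighted centroid is canonical).
    """
    grid: VolumeGrid = dtcp.grid
    inter = intersect_dtcp_thalamus(dtcp, thalamus_mask)
    roi = adaptive_threshold(inter, fraction)
    vv = grid.voxel_volume_mm3
    if weighted_centroid:
        comp = _largest_component(roi, inter.data)
        w = inter.data[comp]
        ijk = (np.argwhere(comp) * w[:, None]).sum(axis=0) / w.sum()
        centroid = ijk @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    else:
        centroid = centroid_world(roi, grid.affine, weights=inter.data)
    return VimResult(
        hemisphere=hemisphere,
        roi=roi,
        roi_volume_mm3=float(roi.sum()) * vv,
        intersection_volume_mm3=float((inter.data > 0).sum()) * vv,
        centroid_world=centroid,
        max_pico_in_intersection=float(inter.data.max()),
    )
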