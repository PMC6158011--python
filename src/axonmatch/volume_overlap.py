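"""Matched-fluorescence-signal fraction and labeling density.

LM planes are binarized (Otsu by default, manual threshold override),
segmented into 8-connected 2D components, and a component counts as
*matched* when any of its voxels lies within one voxel (Chebyshev, in 3D) of
a voxel hit by a matched skeleton node.  The matched signal fraction of a
plane is matched suprathreshold voxels / all suprathreshold voxels.

Labeling density is simply the suprathreshold voxel fraction per plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .io_formats import VolumeStack
from .skeletons import resample_polyline


@dataclass
class PlaneSegmentation:
    plane_index: int
    mask: np.ndarray
    labels: np.ndarray
    threshold: float
    n_components: int


def _threshold(plane: np.ndarray, method, manual_threshold):
    if manual_threshold is not None:
        return float(manual_threshold)
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    if np.ptp(plane) == 0:
        raise ValueError("constant image: automatic thresholding is "
                         "undefined, pass a manual threshold")
    return float(threshold_otsu(plane))


def segment_plane(plane: np.ndarray, threshold_method: str = "otsu",
                  manual_threshold=None,
                  plane_index: int = 0) -> PlaneSegmentation:
    """Binarize one 2D plane and label 8-connected components."""
    plane = np.asarray(plane)
    thr = _threshold(plane, threshold_method, manual_threshold)
    mask = plane > thr
    labels = cc_label(mask, connectivity=2)
    return PlaneSegmentation(plane_index=plane_index, mask=mask,
                             labels=labels, threshold=thr,
                             n_components=int(labels.max()))


def _rasterize_nodes(skeletons, voxel_size, shape, spacing_factor=0.5):
    """Boolean (planes, y, x) grid of voxels touched by skeleton nodes.

    Skeletons are resampled below the voxel pitch first so thin diagonal
    stretches do not skip voxels.
    """
    grid = np.zeros(shape, dtype=bool)
    vs = np.asarray(voxel_size, dtype=float)
    spacing = float(min(vs)) * spacing_factor
    for s in skeletons:
        dense = resample_polyline(s, spacing) if len(s.edges) else s
        ijk = np.round(dense.positions / vs).astype(int)
        ok = np.all((ijk >= 0) & (ijk < np.array(shape)[::-1]), axis=1)
        ijk = ijk[ok]
        # positions are (x, y, z) nm; stack layout is (plane=z, y, x)
        grid[ijk[:, 2], ijk[:, 1], ijk[:, 0]] = True
    return grid


@dataclass
class MatchedFractionReport:
    plane_indices: np.ndarray
    fractions: np.ndarray
    depths_nm: np.ndarray
    mean: float
    sd: float

    def to_dict(self) -> dict:
        return {"plane_indices": self.plane_indices.tolist(),
                "fractions": self.fractions.tolist(),
                "depths_nm": self.depths_nm.tolist(),
                "mean": self.mean, "sd": self.sd}


def matched_fraction(stack: VolumeStack, matched_skeletons, planes=None,
                     threshold_method: str = "otsu", manual_threshold=None,
                     chebyshev_tolerance: int = 1) -> MatchedFractionReport:
    """Fraction of suprathreshold voxels explained by matched skeletons.

    Skeleton coordinates must be in the LM frame (nm) of ``stack``.  A
    segmentation component is matched when it intersects the skeleton node
    raster dilated by ``chebyshev_tolerance`` voxels (3D Chebyshev), which
    absorbs rasterization error.
    """
    data = stack.data
    n_planes = data.shape[0]
    plane_list = list(range(n_planes)) if planes is None else list(planes)
    raster = _rasterize_nodes(matched_skeletons, stack.geometry.voxel_size,
                              data.shape)
    if chebyshev_tolerance > 0:
        raster = binary_dilation(raster, np.ones((3, 3, 3), dtype=bool),
                                 iterations=chebyshev_tolerance)
    fractions, depths = [], []
    vz = float(stack.geometry.voxel_size[2])
    for z in plane_list:
        seg = segment_plane(data[z], threshold_method, manual_threshold,
                            plane_index=z)
        total = int(seg.mask.sum())
        if total == 0:
            fractions.append(0.0)
            depths.append(z * vz)
            continue
        hit_labels = np.unique(seg.labels[raster[z] & seg.mask])
        hit_labels = hit_labels[hit_labels > 0]
        matched = int(np.isin(seg.labels, hit_labels).sum())
        fractions.append(matched / total)
        depths.append(z * vz)
    fractions = np.array(fractions)
    return MatchedFractionReport(
        plane_indices=np.array(plane_list), fractions=fractions,
        depths_nm=np.array(depths), mean=float(fractions.mean()),
        sd=float(fractions.std(ddof=1)) if len(fractions) > 1 else 0.0)


@dataclass
class LabelingDensityReport:
    plane_indices: np.ndarray
    fractions: np.ndarray
    mean: float
    sd: float

    def to_dict(self) -> dict:
        return {"plane_indices": self.plane_indices.tolist(),
                "fractions": self.fractions.tolist(),
                "mean": self.mean, "sd": self.sd}


def labeling_density(stack: VolumeStack, threshold_method: str = "otsu",
                     manual_threshold=None, planes=None) -> LabelingDensityReport:
    """Per-plane suprathreshold voxel fraction (labeled-signal density)."""
    data = stack.data
    plane_list = list(range(data.shape[0])) if planes is None else list(planes)
    fracs = []
    for z in plane_list:
        seg = segment_plane(data[z], threshold_method, manual_threshold,
                            plane_index=z)
        fracs.append(seg.mask.mean())
    fracs = np.array(fracs)
    return LabelingDensityReport(
        plane_indices=np.array(plane_list), fractions=fracs,
        mean=float(fracs.mean()),
        sd=float(fracs.std(ddof=1)) if len(fracs) > 1 else 0.0)
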