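"""Locus-coeruleus contrast-ratio extraction from neuromelanin-sensitive volumes.

The locus coeruleus (LC) appears as a small hyperintense blob on
neuromelanin-sensitive MRI; its structural integrity is summarized by the
contrast ratio against a pontine-tegmentum (PT) reference region:

    LC-CR = (LC intensity - PT intensity) / PT intensity

The measurement protocol implemented here:

1. intensities are multiplicatively normalized so the PT mean is a common
   target level across volumes (the CR is scale invariant either way);
2. per side and per axial slice, the maximum-intensity voxel inside an
   overinclusive LC search mask is located (lexicographic tie-break) and the
   signal is the mean over a five-voxel in-plane cross (center + 4 in-plane
   neighbors);
3. if the cross touches the fourth-ventricle mask, the center is shifted one
   in-plane voxel in the direction that maximally increases the distance to
   the ventricle (staying inside the search mask) and the shift is flagged;
4. the CR is measured on three slices (rostral / middle / caudal); the middle
   slice is supplied by the caller as a landmark-derived index (anatomy
   detection is out of scope), optionally as an inferior-colliculus landmark
   plus a millimetre offset (7 mm below by convention).

Downstream statistics default to the right caudal CR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LCVolume",
    "LCContrastResult",
    "normalize_reference",
    "locate_peak_and_sample",
    "lc_contrast_ratio",
    "UnsampleableSliceError",
]

SIDES = ("left", "right")
SLICE_POSITIONS = ("rostral", "middle", "caudal")


class UnsampleableSliceError(ValueError):
    """No valid cross center exists in a slice (even after the shift rule)."""


@dataclass
class LCVolume:
    """A neuromelanin-sensitive volume with LC/PT/ventricle masks.

    ``slice_axis`` indexes the rostro-caudal axis; by convention a *higher*
    slice index is more rostral (set ``rostral_positive=False`` otherwise).
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lc_search_masks: dict | None = None  # {"left": bool array, "right": ...}
    pt_mask: np.ndarray | None = None
    ventricle_mask: np.ndarray | None = None
    slice_axis: int = 2
    rostral_positive: bool = True

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3-D array")
        shape = self.intensities.shape
        if self.pt_mask is None or not np.asarray(self.pt_mask).any():
            raise ValueError("pt_mask must be a nonempty boolean array")
        self.pt_mask = np.asarray(self.pt_mask, dtype=bool)
        if self.pt_mask.shape != shape:
            raise ValueError("pt_mask shape mismatch")
        if self.lc_search_masks is None:
            raise ValueError("lc_search_masks required")
        for side in SIDES:
            m = np.asarray(self.lc_search_masks[side], dtype=bool)
            if m.shape != shape:
                raise ValueError(f"{side} search mask shape mismatch")
            if (m & self.pt_mask).any():
                raise ValueError(f"{side} search mask overlaps the PT mask")
            self.lc_search_masks[side] = m
        if self.ventricle_mask is not None:
            self.ventricle_mask = np.asarray(self.ventricle_mask, dtype=bool)
            if self.ventricle_mask.shape != shape:
                raise ValueError("ventricle_mask shape mismatch")

    @property
    def pt_mean(self) -> float:
        return float(self.intensities[self.pt_mask].mean())


@dataclass(frozen=True)
class LCContrastResult:
    """Per (side, slice-position) contrast ratios and sampling provenance."""

    cr: dict  # (side, position) -> float or nan
    peak_voxel: dict  # (side, position) -> (i, j, k) or None
    shifted: dict  # (side, position) -> bool
    pt_mean: float
    middle_slice: int

    def value(self, side: str = "right", position: str = "caudal") -> float:
        return self.cr[(side, position)]


def normalize_reference(vol: LCVolume, target_pt_level: float = 100.0) -> LCVolume:
    """Rescale intensities so the PT-mask mean equals ``target_pt_level``."""
    pt = vol.pt_mean
    if pt <= 0:
        raise ValueError("nonpositive PT mean intensity")
    return replace(vol, intensities=vol.intensities * (target_pt_level / pt))


def _in_plane_axes(slice_axis: int) -> tuple[int, int]:
    return tuple(a for a in range(3) if a != slice_axis)


def _cross_voxels(center: tuple, shape: tuple, slice_axis: int) -> list[tuple]:
    """Center plus its 4 in-plane neighbors, clipped to the volume bounds."""
    voxels = [tuple(center)]
    for ax in _in_plane_axes(slice_axis):
        for d in (-1, 1):
            v = list(center)
            v[ax] += d
            if 0 <= v[ax] < shape[ax]:
                voxels.append(tuple(v))
    return voxels


def locate_peak_and_sample(
    vol: LCVolume, side: str, slice_index: int
) -> tuple[tuple, float, bool]:
    """Peak voxel, 5-voxel cross mean, and shift flag for one side and slice.

    Ties between equal maxima break toward the lower coordinate tuple
    (lexicographic, which is numpy argmax order). If the cross intersects the
    ventricle mask, the center moves one in-plane voxel in the direction that
    maximally increases distance from the ventricle while staying inside the
    search mask; the sampled cross always excludes ventricle voxels.
    """
    mask = vol.lc_search_masks[side]
    sl = [slice(None)] * 3
    sl[vol.slice_axis] = slice_index
    plane_mask = mask[tuple(sl)]
    if not plane_mask.any():
        raise UnsampleableSliceError(f"empty {side} search mask in slice {slice_index}")
    plane = vol.intensities[tuple(sl)]
    masked = np.where(plane_mask, plane, -np.inf)
    flat = int(np.argmax(masked))  # first occurrence = lexicographic tie-break
    ij = np.unravel_index(flat, masked.shape)
    center = [0, 0, 0]
    center[vol.slice_axis] = slice_index
    for ax, coord in zip(_in_plane_axes(vol.slice_axis), ij):
        center[ax] = int(coord)
    center = tuple(center)
    shape = vol.intensities.shape

    shifted = False
    if vol.ventricle_mask is not None:
        cross = _cross_voxels(center, shape, vol.slice_axis)
        if any(vol.ventricle_mask[v] for v in cross):
            center = _shift_away_from_ventricle(vol, side, center, slice_index)
            shifted = True
    cross = _cross_voxels(center, shape, vol.slice_axis)
    if vol.ventricle_mask is not None:
        cross = [v for v in cross if not vol.ventricle_mask[v]]
    values = np.array([vol.intensities[v] for v in cross])
    return center, float(values.mean()), shifted


def _ventricle_distance(vol: LCVolume, voxel: tuple, slice_index: int) -> float:
    """In-plane Euclidean distance (voxels) from a voxel to the ventricle."""
    sl = [slice(None)] * 3
    sl[vol.slice_axis] = slice_index
    vent = np.argwhere(vol.ventricle_mask[tuple(sl)])
    if len(vent) == 0:
        return np.inf
    here = np.array([voxel[a] for a in _in_plane_axes(vol.slice_axis)])
    return float(np.sqrt(((vent - here) ** 2).sum(axis=1)).min())


def _shift_away_from_ventricle(
    vol: LCVolume, side: str, center: tuple, slice_index: int
) -> tuple:
    mask = vol.lc_search_masks[side]
    shape = vol.intensities.shape
    candidates = []
    for ax in _in_plane_axes(vol.slice_axis):
        for d in (-1, 1):
            v = list(center)
            v[ax] += d
            v = tuple(v)
            if not all(0 <= v[a] < shape[a] for a in range(3)):
                continue
            if not mask[v]:
                continue
            if vol.ventricle_mask[v]:
                continue
            candidates.append((_ventricle_distance(vol, v, slice_index), v))
    if not candidates:
        raise UnsampleableSliceError(
            f"no valid shifted center near {center} in slice {slice_index}"
        )
    # deterministic: max distance, then lexicographic voxel order
    candidates.sort(key=lambda c: (-c[0], c[1]))
    return candidates[0][1]


def lc_contrast_ratio(
    vol: LCVolume,
    middle_slice: int | None = None,
    landmark_slice: int | None = None,
    reference_slice_offset_mm: float = 7.0,
    slice_spacing: int = 1,
    pt_scope: str = "volume",
) -> LCContrastResult:
    """Contrast ratios on three slices (rostral / middle / caudal) per side.

    The middle slice is given directly (``middle_slice``) or derived from an
    inferior-colliculus landmark slice as ``reference_slice_offset_mm`` below
    it. Rostral/caudal slices sit ``slice_spacing`` slices above/below the
    middle. ``pt_scope`` selects the reference mean: ``"volume"`` (default,
    matching a unified reference across images) or ``"slice"`` for the
    slice-local PT mean. Unsampleable slices are reported as NaN, not imputed.
    """
    if middle_slice is None:
        if landmark_slice is None:
            raise ValueError("supply middle_slice or landmark_slice")
        step_mm = vol.voxel_size[vol.slice_axis]
        offset = int(round(reference_slice_offset_mm / step_mm))
        middle_slice = (
            landmark_slice - offset if vol.rostral_positive else landmark_slice + offset
        )
    direction = 1 if vol.rostral_positive else -1
    slices = {
        "rostral": middle_slice + direction * slice_spacing,
        "middle": middle_slice,
        "caudal": middle_slice - direction * slice_spacing,
    }
    n_slices = vol.intensities.shape[vol.slice_axis]
    cr, peaks, shifted = {}, {}, {}
    for side in SIDES:
        for position, idx in slices.items():
            key = (side, position)
            if not (0 <= idx < n_slices):
                logger.warning("slice %d out of bounds for %s", idx, key)
                cr[key], peaks[key], shifted[key] = float("nan"), None, False
                continue
            try:
                peak, sampled, was_shifted = locate_peak_and_sample(vol, side, idx)
            except UnsampleableSliceError as exc:
                logger.warning("unsampleable %s: %s", key, exc)
                cr[key], peaks[key], shifted[key] = float("nan"), None, False
                continue
            if pt_scope == "slice":
                sl = [slice(None)] * 3
                sl[vol.slice_axis] = idx
                pt_vals = vol.intensities[tuple(sl)][vol.pt_mask[tuple(sl)]]
                pt_mean = float(pt_vals.mean()) if pt_vals.size else vol.pt_mean
            else:
                pt_mean = vol.pt_mean
            cr[key] = (sampled - pt_mean) / pt_mean
            peaks[key] = peak
            shifted[key] = was_shifted
    return LCContrastResult(
        cr=cr,
        peak_voxel=peaks,
        shifted=shifted,
        pt_mean=vol.pt_mean,
        middle_slice=middle_slice,
    )
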