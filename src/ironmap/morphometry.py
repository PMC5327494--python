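"""Organ volumetry and left-ventricular function indices.

Volumes follow the contour-propagation convention: per-slice binary masks
are summed (voxel count x in-plane voxel area) and multiplied by the slice
thickness.  A voxel counts iff its center lies inside the contour.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure


@dataclass
class OrganSegmentation:
    """Per-slice binary masks with voxel geometry (mm)."""

    slices: np.ndarray  # (ny, nx, n_slices) bool
    voxel_area: float  # mm^2
    slice_thickness: float  # mm

    def __post_init__(self):
        self.slices = np.asarray(self.slices, dtype=bool)
        if self.slices.ndim == 2:
            self.slices = self.slices[:, :, None]
        if self.slices.ndim != 3:
            raise ValueError("slices must be (ny, nx, n_slices)")
        if self.slice_thickness <= 0 or self.voxel_area <= 0:
            raise ValueError("voxel_area and slice_thickness must be > 0")


@dataclass
class CardiacPhases:
    """End-diastolic and end-systolic LV blood-pool masks."""

    edv_mask: OrganSegmentation
    esv_mask: OrganSegmentation
    heart_rate: float  # beats/min

    def __post_init__(self):
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be > 0")


def organ_volume(seg: OrganSegmentation) -> float:
    """Volume in mm^3: sum over slices of voxel count x area x thickness."""
    n = int(seg.slices.sum())
    if n == 0:
        warnings.warn("empty segmentation; volume = 0")
    return n * seg.voxel_area * seg.slice_thickness


def spleen_volume_ratio(volume: float, body_mass: float) -> float:
    """Spleen volume normalized to body mass (mm^3/g) — the splenomegaly index."""
    if body_mass <= 0:
        raise ValueError("body_mass must be > 0")
    return volume / body_mass


def lv_indices(phases: CardiacPhases) -> dict[str, float]:
    """EDV/ESV (ul), SV = EDV - ESV (ul), EF = 100*SV/EDV (%),
    CO = SV x heart rate (ml/min)."""
    edv = organ_volume(phases.edv_mask)  # mm^3 == ul
    esv = organ_volume(phases.esv_mask)
    if edv == 0:
        raise ValueError("EDV is zero; ejection fraction undefined")
    if esv > edv:
        warnings.warn(f"ESV ({esv:.1f} ul) exceeds EDV ({edv:.1f} ul)")
    sv = edv - esv
    ef = 100.0 * sv / edv
    co = sv * phases.heart_rate / 1000.0  # ul/min -> ml/min
    return {"edv": edv, "esv": esv, "sv": sv, "ef": ef, "co": co}


def segment_brightest(image: np.ndarray, threshold_frac: float = 0.5) -> np.ndarray:
    """Threshold-plus-largest-component helper for the synthetic images only.

    Real scans were contoured manually; this exists so the pipeline can run
    end-to-end on phantom data without truth masks.
    """
    img = np.asarray(image, dtype=float)
    thr = threshold_frac * img.max()
    lab = measure.label(img > thr)
    if lab.max() == 0:
        return np.zeros_like(img, dtype=bool)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    return lab == largest
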