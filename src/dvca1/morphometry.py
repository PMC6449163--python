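"""Sholl analysis, dendritic length, and surface area on SWC trees.

Sholl intersections are counted with the chord (endpoint-straddle)
convention: concentric spheres of radius k * increment (20.6 um by default)
are centred on the soma, and a parent-child chord is counted for a shell
when its endpoint distances from the centre straddle the shell radius.
Segments tangent to a sphere without endpoint straddle are not counted —
a documented limitation shared with tracing-software counts.  Spheres are
3-D by default; ``flatten_z=True`` gives the 2-D projected-circle variant.

Dendrite means SWC type in {3, 4}; somatic and axonal compartments are
excluded from all three metrics (a segment whose parent is the soma
contributes length from the soma centroid).  Surface area uses the lateral
frustum model per segment: pi (r1 + r2) slant, slant = sqrt(L^2 + (r1-r2)^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Morphology

__all__ = [
    "ShollResult",
    "sholl_analysis",
    "total_dendritic_length",
    "dendritic_surface_area",
]


@dataclass(frozen=True)
class ShollResult:
    radii: np.ndarray  # um, arithmetic with the configured increment
    intersections: np.ndarray  # int counts


def _dendrite_arrays(m: Morphology, flatten_z: bool = False):
    """Per-dendritic-segment endpoint coordinates and radii."""
    p_xyz, c_xyz, p_r, c_r = [], [], [], []
    for parent, child in m.dendrite_segments():
        p_xyz.append([parent.x, parent.y, parent.z])
        c_xyz.append([child.x, child.y, child.z])
        p_r.append(parent.radius)
        c_r.append(child.radius)
    if not p_xyz:
        raise ValueError("morphology has no dendritic segments")
    p_xyz = np.asarray(p_xyz)
    c_xyz = np.asarray(c_xyz)
    if flatten_z:
        p_xyz = p_xyz.copy()
        c_xyz = c_xyz.copy()
        p_xyz[:, 2] = 0.0
        c_xyz[:, 2] = 0.0
    return p_xyz, c_xyz, np.asarray(p_r), np.asarray(c_r)


def sholl_analysis(
    m: Morphology,
    increment: float = 20.6,
    center=None,
    flatten_z: bool = False,
) -> ShollResult:
    """Dendritic chord crossings per concentric shell.

    Shell radii run from ``increment`` up to the greatest node distance
    from the centre (the soma by default).
    """
    if increment <= 0:
        raise ValueError("increment must be positive")
    if center is None:
        center = m.xyz(m.root_id)
    center = np.asarray(center, dtype=float)
    if flatten_z:
        center = center.copy()
        center[2] = 0.0
    p_xyz, c_xyz, _, _ = _dendrite_arrays(m, flatten_z=flatten_z)
    d_parent = np.linalg.norm(p_xyz - center, axis=1)
    d_child = np.linalg.norm(c_xyz - center, axis=1)
    lo = np.minimum(d_parent, d_child)
    hi = np.maximum(d_parent, d_child)
    max_dist = float(np.max(hi))
    n_shells = int(np.floor(max_dist / increment + 1e-9))
    radii = increment * np.arange(1, n_shells + 1)
    counts = np.array(
        [int(np.sum((lo < r) & (r <= hi))) for r in radii], dtype=int
    )
    return ShollResult(radii=radii, intersections=counts)


def total_dendritic_length(m: Morphology) -> float:
    """Sum of Euclidean parent-child chord lengths over dendrites, um."""
    p_xyz, c_xyz, _, _ = _dendrite_arrays(m)
    return float(np.sum(np.linalg.norm(c_xyz - p_xyz, axis=1)))


def dendritic_surface_area(m: Morphology) -> float:
    """Lateral frustum surface area summed over dendritic segments, um^2."""
    p_xyz, c_xyz, p_r, c_r = _dendrite_arrays(m)
    length = np.linalg.norm(c_xyz - p_xyz, axis=1)
    slant = np.sqrt(length**2 + (p_r - c_r) ** 2)
    return float(np.sum(np.pi * (p_r + c_r) * slant))
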