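"""Semi-automatic adaptive-threshold tumor delineation.

The primary lesion is delineated as the 26-connected component of voxels
above a fraction of the lesion SUVmax, grown from a user-supplied hot-spot
seed.  When the mask under-covers a reference extent (standing in for the
visual CT comparison of clinical workflows), the threshold fraction is
lowered stepwise.  Lesions below a minimum metabolic volume (default 5 ml)
are rejected from analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import PETVolume

#: 26-neighbourhood structuring element shared across the package.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationParams:
    initial_fraction: float = 0.40
    fraction_step: float = 0.05
    min_fraction: float = 0.20
    min_volume_ml: float = 5.0
    coverage_target: float = 0.90
    seed: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if not (0 < self.min_fraction <= self.initial_fraction < 1):
            raise ValueError("require 0 < min_fraction <= initial_fraction < 1")
        if self.min_volume_ml <= 0:
            raise ValueError("min_volume_ml must be positive")
        if self.fraction_step <= 0:
            raise ValueError("fraction_step must be positive")


@dataclass
class VOIMask:
    """Binary tumor segmentation aligned to a PETVolume grid."""

    mask: np.ndarray
    threshold_fraction_used: float
    manually_edited: bool = False
    coverage_warning: bool = False
    n_components: int = 1

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def volume_ml(self, volume: PETVolume) -> float:
        return self.voxel_count * volume.voxel_volume_ml


def _seed_component(above: np.ndarray, seed) -> np.ndarray:
    labels, _ = ndimage.label(above, structure=STRUCT_26)
    lab = labels[tuple(seed)]
    if lab == 0:
        raise ValueError("seed voxel falls below threshold; empty component")
    return labels == lab


def threshold_segment(volume: PETVolume, params: SegmentationParams) -> VOIMask:
    """Segment the lesion at ``fraction x SUVmax`` around the seed.

    The SUVmax defining the threshold is the maximum within the seed's own
    connected component, found by fixed-point iteration: start from the
    seed value, threshold, take the seed component, update the max, repeat
    until stable.  The iteration is monotone in the local max and therefore
    terminates; the result is deterministic.
    """
    seed = tuple(int(i) for i in params.seed)
    if len(seed) != 3 or any(i < 0 or i >= n for i, n in zip(seed, volume.shape)):
        raise ValueError(f"seed {seed} outside volume of shape {volume.shape}")
    if not volume.is_suv:
        raise ValueError("volume must be in SUV")
    vox = volume.voxels
    local_max = float(vox[seed])
    if local_max <= 0:
        raise ValueError("seed voxel has non-positive SUV")
    frac = params.initial_fraction
    for _ in range(100):
        comp = _seed_component(vox >= frac * local_max, seed)
        new_max = float(vox[comp].max())
        if new_max <= local_max:
            break
        local_max = new_max
    return VOIMask(comp, threshold_fraction_used=frac)


def adapt_threshold(
    volume: PETVolume, params: SegmentationParams, reference_extent: np.ndarray
) -> VOIMask:
    """Lower the threshold until the mask covers the reference extent.

    Starting from ``initial_fraction``, the fraction is decremented by
    ``fraction_step`` until the segmented mask covers at least
    ``coverage_target`` of ``reference_extent`` (a coarse truth or CT-derived
    extent) or the floor ``min_fraction`` is reached, in which case the last
    mask is returned with ``coverage_warning`` set.
    """
    ref = np.asarray(reference_extent, dtype=bool)
    if ref.shape != volume.shape:
        raise ValueError("reference extent shape mismatch")
    if not ref.any():
        raise ValueError("empty reference extent")
    nref = ref.sum()
    frac = params.initial_fraction
    while True:
        voi = threshold_segment(
            volume,
            SegmentationParams(
                initial_fraction=frac,
                fraction_step=params.fraction_step,
                min_fraction=min(params.min_fraction, frac),
                min_volume_ml=params.min_volume_ml,
                coverage_target=params.coverage_target,
                seed=params.seed,
            ),
        )
        coverage = (voi.mask & ref).sum() / nref
        if coverage >= params.coverage_target:
            return voi
        next_frac = frac - params.fraction_step
        if next_frac < params.min_fraction - 1e-12:
            voi.coverage_warning = True
            warnings.warn(
                f"coverage {coverage:.2f} below target {params.coverage_target} "
                f"at floor fraction {frac:.2f}",
                stacklevel=2,
            )
            return voi
        frac = next_frac


def apply_manual_edits(voi: VOIMask, add=(), remove=()) -> VOIMask:
    """Apply voxel-level manual additions/removals (e.g. myocardial spill).

    The single-component invariant is re-checked and reported via
    ``n_components`` (and a warning), not enforced.
    """
    mask = voi.mask.copy()
    for idx in list(add) + list(remove):
        idx = tuple(int(i) for i in idx)
        if any(i < 0 or i >= n for i, n in zip(idx, mask.shape)):
            raise IndexError(f"edit voxel {idx} outside grid {mask.shape}")
    for idx in add:
        mask[tuple(int(i) for i in idx)] = True
    for idx in remove:
        mask[tuple(int(i) for i in idx)] = False
    _, ncomp = ndimage.label(mask, structure=STRUCT_26)
    if ncomp > 1:
        warnings.warn(f"edited mask has {ncomp} connected components", stacklevel=2)
    return VOIMask(
        mask,
        threshold_fraction_used=voi.threshold_fraction_used,
        manually_edited=True,
        coverage_warning=voi.coverage_warning,
        n_components=int(ncomp),
    )


def gate_min_volume(voi: VOIMask, volume: PETVolume, min_volume_ml: float = 5.0) -> bool:
    """Inclusion gate: accept lesions with MTV >= ``min_volume_ml`` (inclusive)."""
    return voi.volume_ml(volume) >= min_volume_ml
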