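"""Gray-level quantisation and 3D texture matrices.

The VOI is quantised into G equal-width bins over its own SUV min–max
(relative resampling; a fixed-bounds mode exists but is not the default),
then four classic texture matrices are built in full 3D:

* GLCM — co-occurrence counts at distance 1, summed over the 13 unique 3D
  directions and symmetrized (merged-matrix strategy, not per-direction
  averaging).
* GLRLM — maximal runs of equal labels along each of the 13 directions,
  counts aggregated.
* GLSZM — 26-connected zones of equal label, by level and zone size.
* NGTDM — per-level sums of |label − neighbourhood mean| over the in-mask
  26-neighbourhood, with occupancy probabilities.

All matrices respect the mask: voxel pairs, runs, zones and neighbourhoods
never cross the VOI boundary.  Distances are in index space (no physical
correction for anisotropic voxels), consistent with leaving voxel sizes as
acquired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import STRUCT_26
from .volume import PETVolume

#: The 13 unique 3D direction vectors (one per +/- pair).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dz in (0, 1)
    for dy in ((-1, 0, 1) if dz == 1 else (0, 1))
    for dx in ((-1, 0, 1) if (dz == 1 or dy == 1) else (1,))
)
assert len(DIRECTIONS_13) == 13


@dataclass(frozen=True)
class QuantisationConfig:
    levels_list: tuple[int, ...] = (4, 8, 16, 32, 64, 128, 256)
    bounds: str = "voi_min_max"  # or "fixed"
    fixed_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if any(g < 2 for g in self.levels_list):
            raise ValueError("every gray-level count must be >= 2")
        if self.bounds not in ("voi_min_max", "fixed"):
            raise ValueError("bounds must be 'voi_min_max' or 'fixed'")
        if self.bounds == "fixed" and self.fixed_range is None:
            raise ValueError("fixed bounds require fixed_range")


@dataclass
class QuantisedVOI:
    """Integer labels 1..G inside the mask, 0 outside."""

    labels: np.ndarray
    mask: np.ndarray
    G: int
    source_min: float
    source_max: float


def quantise(
    values: np.ndarray | PETVolume,
    mask: np.ndarray,
    G: int,
    bounds: str = "voi_min_max",
    fixed_range: tuple[float, float] | None = None,
) -> QuantisedVOI:
    """Quantise in-mask values into G equal-width bins.

    ``label = ceil(G * (v - min) / (max - min))`` clamped to [1, G]; a
    constant VOI maps to a single label 1.  ``values`` may be a raw array
    (e.g. a wavelet sub-band) or a :class:`PETVolume`.
    """
    if isinstance(values, PETVolume):
        values = values.voxels
    values = np.asarray(values, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("mask shape mismatch")
    if not mask.any():
        raise ValueError("empty mask")
    if G < 2:
        raise ValueError("G must be >= 2")
    inside = values[mask]
    if bounds == "fixed":
        if fixed_range is None:
            raise ValueError("fixed bounds require fixed_range")
        lo, hi = (float(fixed_range[0]), float(fixed_range[1]))
    else:
        lo, hi = float(inside.min()), float(inside.max())
    labels = np.zeros(values.shape, dtype=np.int32)
    if hi <= lo:
        labels[mask] = 1
    else:
        lab = np.ceil(G * (values[mask] - lo) / (hi - lo))
        labels[mask] = np.clip(lab, 1, G).astype(np.int32)
    return QuantisedVOI(labels, mask, int(G), lo, hi)


# ---------------------------------------------------------------------------
# matrix builders


def _shift_views(a: np.ndarray, d: tuple[int, int, int]):
    """Return aligned views (a at p, a at p+d) for offset d."""
    sl_src, sl_dst = [], []
    for step, n in zip(d, a.shape):
        if step == 0:
            sl_src.append(slice(None))
            sl_dst.append(slice(None))
        elif step > 0:
            sl_src.append(slice(0, n - step))
            sl_dst.append(slice(step, n))
        else:
            sl_src.append(slice(-step, n))
            sl_dst.append(slice(0, n + step))
    return tuple(sl_src), tuple(sl_dst)


def compute_glcm(q: QuantisedVOI, distance: int = 1) -> np.ndarray:
    """Symmetric G x G co-occurrence counts over the 13 unique directions."""
    if distance < 1:
        raise ValueError("distance must be >= 1")
    G = q.G
    counts = np.zeros((G, G), dtype=np.int64)
    lab, msk = q.labels, q.mask
    for d in DIRECTIONS_13:
        dd = tuple(distance * c for c in d)
        src, dst = _shift_views(lab, dd)
        valid = msk[src] & msk[dst]
        a = lab[src][valid] - 1
        b = lab[dst][valid] - 1
        np.add.at(counts, (a, b), 1)
    return counts + counts.T


def compute_glrlm(q: QuantisedVOI) -> np.ndarray:
    """G x Rmax run-length counts aggregated over the 13 directions.

    Runs are maximal chains of equal labels within the mask; a gap in the
    mask breaks a run.  Implemented as a per-direction dynamic program over
    slices along the direction's leading axis.
    """
    G = q.G
    lab, msk = q.labels, q.mask
    n_in = int(msk.sum())
    max_len = max(1, max(lab.shape))
    # conservative bound: longest possible run is the grid diagonal length
    counts = np.zeros((G, max_len), dtype=np.int64)
    for d in DIRECTIONS_13:
        chain = np.zeros(lab.shape, dtype=np.int32)
        chain[msk] = 1
        src, dst = _shift_views(lab, d)
        same = np.zeros(lab.shape, dtype=bool)
        same[dst] = msk[src] & msk[dst] & (lab[src] == lab[dst])
        # iterate along the leading nonzero axis of d so predecessors are done
        axis = next(i for i, c in enumerate(d) if c != 0)
        order = range(lab.shape[axis]) if d[axis] > 0 else range(lab.shape[axis] - 1, -1, -1)
        pred = [slice(None)] * 3
        cur = [slice(None)] * 3
        for k in order:
            cur[axis] = k
            kp = k - d[axis]
            if not (0 <= kp < lab.shape[axis]):
                continue
            pred[axis] = kp
            csl, psl = tuple(cur), tuple(pred)
            upd = same[csl]
            chain[csl] = np.where(upd, _shifted_plane(chain, psl, d, axis) + 1, chain[csl])
        # run ends: in-mask voxels whose successor does not continue the run
        cont = np.zeros(lab.shape, dtype=bool)
        cont[src] = same[dst]
        ends = msk & ~cont
        lengths = chain[ends]
        levels = lab[ends] - 1
        np.add.at(counts, (levels, lengths - 1), 1)
    # trim trailing all-zero run-length columns (keep at least one)
    nz = np.nonzero(counts.any(axis=0))[0]
    rmax = int(nz[-1]) + 1 if nz.size else 1
    counts = counts[:, :rmax]
    # identity: sum over runs of count*length = n_in per direction
    assert (counts * np.arange(1, rmax + 1)).sum() == 13 * n_in
    return counts


def _shifted_plane(chain: np.ndarray, psl, d, axis):
    """chain values at p-d for the plane selected by psl along `axis`."""
    plane = chain[psl]
    sub = [slice(None)] * 3
    del sub[axis]
    # shift the remaining two axes by the in-plane components of -d
    inplane = [c for i, c in enumerate(d) if i != axis]
    out = plane
    for ax2, step in enumerate(inplane):
        if step == 0:
            continue
        shifted = np.zeros_like(out)
        if step > 0:
            idx_dst = [slice(None)] * 2
            idx_src = [slice(None)] * 2
            idx_dst[ax2] = slice(step, None)
            idx_src[ax2] = slice(0, -step)
        else:
            idx_dst = [slice(None)] * 2
            idx_src = [slice(None)] * 2
            idx_dst[ax2] = slice(0, step)
            idx_src[ax2] = slice(-step, None)
        shifted[tuple(idx_dst)] = out[tuple(idx_src)]
        out = shifted
    return out


def compute_glszm(q: QuantisedVOI) -> np.ndarray:
    """G x Smax zone counts: 26-connected components of equal label."""
    G = q.G
    lab, msk = q.labels, q.mask
    zones: list[tuple[int, int]] = []
    for level in np.unique(lab[msk]):
        comp, ncomp = ndimage.label((lab == level) & msk, structure=STRUCT_26)
        if ncomp == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        zones.extend((int(level), int(s)) for s in sizes)
    smax = max(s for _, s in zones)
    out = np.zeros((G, smax), dtype=np.int64)
    for level, s in zones:
        out[level - 1, s - 1] += 1
    return out


@dataclass
class NGTDM:
    """Per-level coarseness sums s_i, occupancy p_i, and counted voxel n."""

    s: np.ndarray  # length G
    p: np.ndarray  # length G, sums to 1 over occupied levels
    n: int


def compute_ngtdm(q: QuantisedVOI) -> NGTDM:
    """Neighbourhood gray-tone difference matrix.

    For each in-mask voxel with at least one in-mask 26-neighbour, the
    absolute difference between its label and the mean label of those
    neighbours is accumulated per level; voxels with no in-mask neighbour
    are excluded from the voxel count n.
    """
    G = q.G
    lab, msk = q.labels, q.mask
    kern = STRUCT_26.astype(np.float64).copy()
    kern[1, 1, 1] = 0.0
    nsum = ndimage.convolve(np.where(msk, lab, 0).astype(np.float64), kern, mode="constant")
    ncount = ndimage.convolve(msk.astype(np.float64), kern, mode="constant")
    counted = msk & (ncount > 0.5)
    n = int(counted.sum())
    s = np.zeros(G)
    p = np.zeros(G)
    if n == 0:
        return NGTDM(s, p, 0)
    abar = nsum[counted] / ncount[counted]
    diffs = np.abs(lab[counted] - abar)
    levels = lab[counted] - 1
    np.add.at(s, levels, diffs)
    cnt = np.bincount(levels, minlength=G).astype(np.float64)
    p = cnt / n
    return NGTDM(s, p, n)
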