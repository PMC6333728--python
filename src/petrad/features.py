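"""The 3D radiomics feature catalogue.

The default catalogue holds exactly 665 uniquely named features per gray
level, composed as:

* 9 image bands — the original SUV image plus the 8 sub-bands (LLL..HHH) of
  a one-level separable 3D discrete wavelet transform (first-order Coiflet,
  periodized boundaries) — times 72 per-band features:
  13 first-order, 22 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM;
* 14 shape features of the binary mask;
* 3 box-counting fractal features.

9 x 72 + 14 + 3 = 665.  The composition is configurable; the count
invariant on names is enforced for the default catalogue.  Feature names
carry the gray level as a suffix, e.g. ``GLSZM_SzVarianc_64gl`` and
``NGTDM_Complex_64gl`` (the two constituents of the published prognostic
feature vector), wavelet-band features as ``W_LLH_GLCM_Contrast_64gl``.

Texture features on a degenerate single-level VOI take their limiting
values where they exist (variance 0, complexity 0, correlation 1); a
feature with no defensible limit is recorded as missing with a reason,
never as a silent NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .texture import (
    NGTDM,
    QuantisationConfig,
    QuantisedVOI,
    compute_glcm,
    compute_glrlm,
    compute_glszm,
    compute_ngtdm,
    quantise,
)
from .volume import PETVolume

CATALOGUE_VERSION = "petrad-665-v1"
WAVELET_FAMILY = "coif1"
WAVELET_MODE = "periodization"
MIN_WAVELET_EXTENT = 6  # coif1 filter length

FIRST_ORDER_NAMES = (
    "Mean", "Median", "Min", "Max", "Range", "Variance", "Skewness",
    "Kurtosis", "Energy", "Entropy", "Uniformity", "RMS", "MeanAbsDev",
)
GLCM_NAMES = (
    "AutoCorr", "ClusterProm", "ClusterShade", "ClusterTend", "Contrast",
    "Correlation", "DiffAverage", "DiffEntropy", "DiffVariance",
    "Dissimilarity", "Energy", "Entropy", "InvDiff", "InvDiffMom",
    "InvDiffMomNorm", "InvDiffNorm", "IMC1", "IMC2", "InvVariance",
    "MaxProb", "SumAverage", "SumEntropy",
)
GLRLM_NAMES = (
    "ShortRunEmph", "LongRunEmph", "GLNonUnif", "GLNonUnifNorm",
    "RunLenNonUnif", "RunLenNonUnifNorm", "RunPct", "GLVariance",
    "RunLenVariance", "RunEntropy", "LowGLRunEmph", "HighGLRunEmph",
    "ShortRunLowGL", "ShortRunHighGL", "LongRunLowGL", "LongRunHighGL",
)
GLSZM_NAMES = (
    "SmZoneEmph", "LgZoneEmph", "GLNonUnif", "GLNonUnifNorm", "ZoneNonUnif",
    "ZoneNonUnifNorm", "ZonePct", "GLVariance", "SzVarianc", "ZoneEntropy",
    "LowGLZoneEmph", "HighGLZoneEmph", "SmZoneLowGL", "SmZoneHighGL",
    "LgZoneLowGL", "LgZoneHighGL",
)
NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complex", "Strength")
SHAPE_NAMES = (
    "VoxelCount", "Volume_ml", "SurfaceArea_mesh", "SurfaceArea_faces",
    "SurfaceToVolume", "Sphericity", "Compactness2", "SphericalDispro",
    "MaxDiameter3D", "MajorAxisLen", "MinorAxisLen", "LeastAxisLen",
    "Elongation", "Flatness",
)
FRACTAL_NAMES = ("BoundaryDim", "FilledDim", "BoundaryAbundance")

WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
BAND_PREFIXES = ("",) + tuple(f"W_{b}_" for b in WAVELET_BANDS)

_EPS = np.finfo(float).eps


def catalogue_names(G: int) -> list[str]:
    """The 665 default feature names for gray level ``G``, in stable order."""
    names: list[str] = []
    for prefix in BAND_PREFIXES:
        names += [f"{prefix}FO_{n}_{G}gl" for n in FIRST_ORDER_NAMES]
        names += [f"{prefix}GLCM_{n}_{G}gl" for n in GLCM_NAMES]
        names += [f"{prefix}GLRLM_{n}_{G}gl" for n in GLRLM_NAMES]
        names += [f"{prefix}GLSZM_{n}_{G}gl" for n in GLSZM_NAMES]
        names += [f"{prefix}NGTDM_{n}_{G}gl" for n in NGTDM_NAMES]
    names += [f"Shape_{n}_{G}gl" for n in SHAPE_NAMES]
    names += [f"Fractal_{n}_{G}gl" for n in FRACTAL_NAMES]
    return names


@dataclass
class FeatureSet:
    """Named feature values for one tumor at one gray level."""

    values: dict[str, float]
    gray_level: int
    missing: dict[str, str] = field(default_factory=dict)
    catalogue_version: str = CATALOGUE_VERSION

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


# ---------------------------------------------------------------------------
# first-order


def first_order_features(values: np.ndarray, mask: np.ndarray, q: QuantisedVOI) -> dict[str, float]:
    """Intensity statistics on the in-mask values.

    Entropy and uniformity are computed on the quantised histogram of ``q``
    (bits); skewness and kurtosis (Fisher excess) are 0 for a constant VOI.
    """
    v = np.asarray(values, dtype=np.float64)[np.asarray(mask, dtype=bool)]
    n = v.size
    mean = v.mean()
    var = v.var()
    if var > 0:
        sd = math.sqrt(var)
        skew = float(((v - mean) ** 3).mean() / sd**3)
        kurt = float(((v - mean) ** 4).mean() / var**2 - 3.0)
    else:
        skew = kurt = 0.0
    lab = q.labels[q.mask]
    p = np.bincount(lab)[1:].astype(np.float64)
    p = p[p > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    return {
        "Mean": float(mean),
        "Median": float(np.median(v)),
        "Min": float(v.min()),
        "Max": float(v.max()),
        "Range": float(v.max() - v.min()),
        "Variance": float(var),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float((v**2).sum()),
        "Entropy": entropy,
        "Uniformity": float((p**2).sum()),
        "RMS": float(math.sqrt((v**2).mean())),
        "MeanAbsDev": float(np.abs(v - mean).mean()),
    }


# ---------------------------------------------------------------------------
# GLCM features


def glcm_features(counts: np.ndarray) -> dict[str, float]:
    G = counts.shape[0]
    total = counts.sum()
    P = counts / total
    i = np.arange(1, G + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((px * i).sum())  # == mu_x == mu_y by symmetry
    sigma2 = float((px * (i - mu) ** 2).sum())
    sigma = math.sqrt(sigma2)

    # p_{x+y}, p_{x-y}
    ks = np.arange(2, 2 * G + 1)
    pxy_sum = np.array([P[(I + J) == k].sum() for k in ks])
    kd = np.arange(0, G)
    pxy_diff = np.array([P[np.abs(I - J) == k].sum() for k in kd])

    def ent(pv):
        pv = pv[pv > 0]
        return float(-(pv * np.log2(pv)).sum())

    HXY = ent(P.ravel())
    HX = ent(px)
    with np.errstate(divide="ignore"):
        logim = np.log2(np.outer(px, px) + _EPS)
    HXY1 = float(-(P * logim).sum())
    HXY2 = float(-(np.outer(px, px) * logim).sum())
    imc1 = (HXY - HXY1) / HX if HX > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (HXY2 - HXY))))

    da = float((kd * pxy_diff).sum())
    off = np.abs(I - J) > 0
    corr = (
        float(((I * J * P).sum() - mu * mu) / (sigma * sigma)) if sigma > 0 else 1.0
    )
    return {
        "AutoCorr": float((I * J * P).sum()),
        "ClusterProm": float((((I + J) - 2 * mu) ** 4 * P).sum()),
        "ClusterShade": float((((I + J) - 2 * mu) ** 3 * P).sum()),
        "ClusterTend": float((((I + J) - 2 * mu) ** 2 * P).sum()),
        "Contrast": float(((I - J) ** 2 * P).sum()),
        "Correlation": corr,
        "DiffAverage": da,
        "DiffEntropy": ent(pxy_diff),
        "DiffVariance": float(((kd - da) ** 2 * pxy_diff).sum()),
        "Dissimilarity": float((np.abs(I - J) * P).sum()),
        "Energy": float((P**2).sum()),
        "Entropy": HXY,
        "InvDiff": float((P / (1.0 + np.abs(I - J))).sum()),
        "InvDiffMom": float((P / (1.0 + (I - J) ** 2)).sum()),
        "InvDiffMomNorm": float((P / (1.0 + ((I - J) / G) ** 2)).sum()),
        "InvDiffNorm": float((P / (1.0 + np.abs(I - J) / G)).sum()),
        "IMC1": imc1,
        "IMC2": imc2,
        "InvVariance": float((P[off] / (I - J)[off] ** 2).sum()) if off.any() else 0.0,
        "MaxProb": float(P.max()),
        "SumAverage": float((ks * pxy_sum).sum()),
        "SumEntropy": ent(pxy_sum),
    }


# ---------------------------------------------------------------------------
# GLRLM / GLSZM features (shared size-weighted form)


def _rl_style_features(counts: np.ndarray, n_voxels: int, names: dict[str, str]) -> dict[str, float]:
    """Run-length-style statistics for a (level x size) count matrix."""
    G, S = counts.shape
    N = counts.sum()
    P = counts / N
    i = np.arange(1, G + 1)[:, None]
    s = np.arange(1, S + 1)[None, :]
    pg = P.sum(axis=1)  # by level
    ps = P.sum(axis=0)  # by size
    mu_i = float((pg * i.ravel()).sum())
    mu_s = float((ps * s.ravel()).sum())
    pn = P[P > 0]
    return {
        names["small"]: float((P / s**2).sum()),
        names["large"]: float((P * s**2).sum()),
        names["gln"]: float((counts.sum(axis=1) ** 2).sum() / N),
        names["glnn"]: float((pg**2).sum()),
        names["sn"]: float((counts.sum(axis=0) ** 2).sum() / N),
        names["snn"]: float((ps**2).sum()),
        names["pct"]: float(N / n_voxels),
        names["glv"]: float((P * (i - mu_i) ** 2).sum()),
        names["sv"]: float((P * (s - mu_s) ** 2).sum()),
        names["ent"]: float(-(pn * np.log2(pn)).sum()),
        names["lgl"]: float((P / i**2).sum()),
        names["hgl"]: float((P * i**2).sum()),
        names["sl"]: float((P / (i**2 * s**2)).sum()),
        names["sh"]: float((P * i**2 / s**2).sum()),
        names["ll"]: float((P * s**2 / i**2).sum()),
        names["lh"]: float((P * i**2 * s**2).sum()),
    }


_GLRLM_MAP = dict(
    small="ShortRunEmph", large="LongRunEmph", gln="GLNonUnif",
    glnn="GLNonUnifNorm", sn="RunLenNonUnif", snn="RunLenNonUnifNorm",
    pct="RunPct", glv="GLVariance", sv="RunLenVariance", ent="RunEntropy",
    lgl="LowGLRunEmph", hgl="HighGLRunEmph", sl="ShortRunLowGL",
    sh="ShortRunHighGL", ll="LongRunLowGL", lh="LongRunHighGL",
)
_GLSZM_MAP = dict(
    small="SmZoneEmph", large="LgZoneEmph", gln="GLNonUnif",
    glnn="GLNonUnifNorm", sn="ZoneNonUnif", snn="ZoneNonUnifNorm",
    pct="ZonePct", glv="GLVariance", sv="SzVarianc", ent="ZoneEntropy",
    lgl="LowGLZoneEmph", hgl="HighGLZoneEmph", sl="SmZoneLowGL",
    sh="SmZoneHighGL", ll="LgZoneLowGL", lh="LgZoneHighGL",
)


def glrlm_features(counts: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _rl_style_features(counts, n_voxels, _GLRLM_MAP)


def glszm_features(counts: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _rl_style_features(counts, n_voxels, _GLSZM_MAP)


def glszm_size_zone_variance(glszm: np.ndarray) -> float:
    """Variance of zone sizes, gray-level independent.

    With p(i, s) the fraction of zones of level i and size s, and
    mu = sum p(i, s) * s, returns sum p(i, s) * (s - mu)^2.
    """
    N = glszm.sum()
    if N == 0:
        raise ValueError("GLSZM has no zones")
    P = glszm / N
    s = np.arange(1, glszm.shape[1] + 1)[None, :]
    mu = float((P * s).sum())
    return float((P * (s - mu) ** 2).sum())


# ---------------------------------------------------------------------------
# NGTDM features


def ngtdm_features(m: NGTDM) -> dict[str, float]:
    occ = m.p > 0
    i = np.arange(1, m.p.size + 1, dtype=np.float64)
    p, s, n = m.p[occ], m.s[occ], m.n
    iv = i[occ]
    ngp = int(occ.sum())
    if n == 0:
        raise ValueError("NGTDM counted no voxels")
    ps = float((p * s).sum())
    coarseness = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        PI, PJ = np.meshgrid(p, p, indexing="ij")
        II, JJ = np.meshgrid(iv, iv, indexing="ij")
        contrast = float((PI * PJ * (II - JJ) ** 2).sum() / (ngp * (ngp - 1)) * (m.s.sum() / n))
        denom = float(np.abs(II * PI - JJ * PJ).sum())
        busyness = ps / denom if denom > 0 else 0.0
        strength_num = float(((PI + PJ) * (II - JJ) ** 2).sum())
        stot = float(m.s.sum())
        strength = strength_num / stot if stot > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complex": ngtdm_complexity(m),
        "Strength": strength,
    }


def ngtdm_complexity(m: NGTDM) -> float:
    """Amadasun–King complexity.

    ``sum_{i,j occupied} |i - j| / (n (p_i + p_j)) * (p_i s_i + p_j s_j)``
    over occupied level pairs; 0 for a single-level VOI.
    """
    if m.n == 0:
        raise ValueError("NGTDM counted no voxels")
    occ = np.nonzero(m.p > 0)[0]
    if occ.size <= 1:
        return 0.0
    i = occ + 1.0
    p, s = m.p[occ], m.s[occ]
    II, JJ = np.meshgrid(i, i, indexing="ij")
    PI, PJ = np.meshgrid(p, p, indexing="ij")
    SI, SJ = np.meshgrid(s, s, indexing="ij")
    return float((np.abs(II - JJ) / (m.n * (PI + PJ)) * (PI * SI + PJ * SJ)).sum())


# ---------------------------------------------------------------------------
# shape


def shape_features(mask: np.ndarray, spacing) -> dict[str, float]:
    """Morphological features of the binary mask.

    Two surface-area conventions are reported: a marching-cubes mesh area
    (used for sphericity and related ratios, converges to the true area for
    smooth shapes) and the voxel-face count area (6 mm^2 for a unit voxel).
    Maximum 3D diameter is the largest center-to-center distance between
    boundary voxels.  Principal axis lengths are ``4 sqrt(lambda)`` of the
    physical-coordinate covariance eigenvalues.
    """
    from skimage import measure

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing = tuple(float(s) for s in spacing)
    nvox = int(mask.sum())
    voxvol = spacing[0] * spacing[1] * spacing[2]
    V = nvox * voxvol  # mm^3

    padded = np.pad(mask, 1).astype(np.float64)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    area_mesh = float(measure.mesh_surface_area(verts, faces))

    # voxel-face area: exposed faces per axis
    area_faces = 0.0
    face_areas = (
        spacing[1] * spacing[2],
        spacing[0] * spacing[2],
        spacing[0] * spacing[1],
    )
    for ax, fa in enumerate(face_areas):
        p = np.pad(mask, [(1, 1) if a == ax else (0, 0) for a in range(3)])
        d = np.diff(p.astype(np.int8), axis=ax)
        area_faces += float(np.abs(d).sum()) * fa

    r_eq = (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0)
    sphericity = math.pi ** (1.0 / 3.0) * (6.0 * V) ** (2.0 / 3.0) / area_mesh
    compactness2 = 36.0 * math.pi * V**2 / area_mesh**3
    sph_dispro = area_mesh / (4.0 * math.pi * r_eq**2)

    # boundary voxels (6-connectivity erosion)
    interior = ndimage.binary_erosion(mask)
    boundary = mask & ~interior
    coords = np.argwhere(boundary).astype(np.float64) * np.asarray(spacing)
    if len(coords) > 2000:
        from scipy.spatial import ConvexHull

        hull = ConvexHull(coords)
        coords = coords[hull.vertices]
    if len(coords) == 1:
        max_diam = 0.0
    else:
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
        max_diam = float(np.sqrt(d2.max()))

    all_coords = np.argwhere(mask).astype(np.float64) * np.asarray(spacing)
    centered = all_coords - all_coords.mean(axis=0)
    cov = centered.T @ centered / nvox
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    major, minor, least = (4.0 * math.sqrt(e) for e in eig)
    if eig[0] > 0:
        elongation = math.sqrt(eig[1] / eig[0])
        flatness = math.sqrt(eig[2] / eig[0])
    else:
        elongation = flatness = 1.0  # point-like mask is isotropic
    return {
        "VoxelCount": float(nvox),
        "Volume_ml": V / 1000.0,
        "SurfaceArea_mesh": area_mesh,
        "SurfaceArea_faces": area_faces,
        "SurfaceToVolume": area_mesh / V,
        "Sphericity": sphericity,
        "Compactness2": compactness2,
        "SphericalDispro": sph_dispro,
        "MaxDiameter3D": max_diam,
        "MajorAxisLen": major,
        "MinorAxisLen": minor,
        "LeastAxisLen": least,
        "Elongation": elongation,
        "Flatness": flatness,
    }


# ---------------------------------------------------------------------------
# fractal


def _box_count(binary: np.ndarray, eps: int) -> int:
    pad = [(0, (-n) % eps) for n in binary.shape]
    b = np.pad(binary, pad)
    nx, ny, nz = (n // eps for n in b.shape)
    blocks = b.reshape(nx, eps, ny, eps, nz, eps)
    return int(blocks.any(axis=(1, 3, 5)).sum())


def fractal_dimension(mask: np.ndarray, return_details: bool = False):
    """Box-counting dimension of the mask boundary.

    The ladder is box edge lengths 1, 2, 4, ... up to half the largest grid
    dimension; the dimension is the negative slope of log N(eps) against
    log eps; the fit intercept (log N at eps = 1) is the 'abundance'.
    Fewer than 3 ladder points is an error.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    boundary = mask & ~ndimage.binary_erosion(mask)
    eps_ladder = []
    e = 1
    while e <= max(mask.shape) / 2:
        eps_ladder.append(e)
        e *= 2
    if len(eps_ladder) < 3:
        raise ValueError("grid too small for a box-counting ladder (need >= 3 points)")
    counts_b = np.array([_box_count(boundary, e) for e in eps_ladder], dtype=np.float64)
    counts_f = np.array([_box_count(mask, e) for e in eps_ladder], dtype=np.float64)
    loge = np.log(np.asarray(eps_ladder, dtype=np.float64))
    slope_b, inter_b = np.polyfit(loge, np.log(counts_b), 1)
    slope_f, _ = np.polyfit(loge, np.log(counts_f), 1)
    dims = {
        "BoundaryDim": float(-slope_b),
        "FilledDim": float(-slope_f),
        "BoundaryAbundance": float(inter_b),
    }
    if return_details:
        return dims, (eps_ladder, counts_b, counts_f)
    return dims


# ---------------------------------------------------------------------------
# wavelet


def wavelet_decompose(values: np.ndarray, mask: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """One-level 3D DWT of the VOI bounding box.

    Returns ``{band: (coefficients, band_mask)}`` for the 8 bands LLL..HHH
    ('L' = approximation, 'H' = detail, in axis order x, y, z).  The
    transform uses an orthogonal first-order Coiflet with periodized
    boundaries, so the sub-band energies sum exactly to the input energy.
    Band grids are half-size; the band mask is the max-pooled VOI mask.
    Raises ``ValueError`` when the bounding box is smaller than the filter
    length along any axis.
    """
    import pywt

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    bbox = ndimage.find_objects(mask.astype(np.int8))[0]
    sub = np.asarray(values, dtype=np.float64)[bbox]
    msub = mask[bbox]
    if min(sub.shape) < MIN_WAVELET_EXTENT:
        raise ValueError(
            f"VOI bounding box {sub.shape} smaller than wavelet filter length "
            f"{MIN_WAVELET_EXTENT}"
        )
    pad = [(0, n % 2) for n in sub.shape]
    sub = np.pad(sub, pad, mode="symmetric")
    msub = np.pad(msub, pad, mode="symmetric")
    coeffs = pywt.dwtn(sub, WAVELET_FAMILY, mode=WAVELET_MODE)
    # max-pool mask to the half-resolution band grid
    mp = msub.reshape(
        msub.shape[0] // 2, 2, msub.shape[1] // 2, 2, msub.shape[2] // 2, 2
    ).any(axis=(1, 3, 5))
    out = {}
    for key, arr in coeffs.items():
        band = key.replace("a", "L").replace("d", "H")
        out[band] = (arr, mp)
    return out


# ---------------------------------------------------------------------------
# extraction driver


def _band_features(values: np.ndarray, mask: np.ndarray, G: int) -> dict[str, float]:
    """The 72 per-band features (13 first-order + 59 texture)."""
    q = quantise(values, mask, G)
    n_vox = int(q.mask.sum())
    out = {}
    for k, v in first_order_features(values, mask, q).items():
        out[f"FO_{k}"] = v
    for k, v in glcm_features(compute_glcm(q)).items():
        out[f"GLCM_{k}"] = v
    for k, v in glrlm_features(compute_glrlm(q), n_vox).items():
        out[f"GLRLM_{k}"] = v
    for k, v in glszm_features(compute_glszm(q), n_vox).items():
        out[f"GLSZM_{k}"] = v
    for k, v in ngtdm_features(compute_ngtdm(q)).items():
        out[f"NGTDM_{k}"] = v
    return out


def extract_features(
    volume: PETVolume, mask: np.ndarray, G: int, shape_cache: dict | None = None
) -> FeatureSet:
    """Extract the full default catalogue at one gray level."""
    mask = np.asarray(mask, dtype=bool)
    names = catalogue_names(G)
    values: dict[str, float] = {}
    missing: dict[str, str] = {}

    for k, v in _band_features(volume.voxels, mask, G).items():
        values[f"{k}_{G}gl"] = v

    try:
        bands = wavelet_decompose(volume.voxels, mask)
    except ValueError as exc:
        reason = str(exc)
        for prefix in BAND_PREFIXES[1:]:
            for nm in names:
                if nm.startswith(prefix):
                    missing[nm] = reason
    else:
        for band, (coefs, bmask) in bands.items():
            for k, v in _band_features(coefs, bmask, G).items():
                values[f"W_{band}_{k}_{G}gl"] = v

    if shape_cache is None:
        shape_cache = {}
    if "shape" not in shape_cache:
        shape_cache["shape"] = shape_features(mask, volume.spacing)
        try:
            shape_cache["fractal"] = fractal_dimension(mask)
        except ValueError as exc:
            shape_cache["fractal"] = {"__error__": str(exc)}
    for k, v in shape_cache["shape"].items():
        values[f"Shape_{k}_{G}gl"] = v
    frac = shape_cache["fractal"]
    if "__error__" in frac:
        for k in FRACTAL_NAMES:
            missing[f"Fractal_{k}_{G}gl"] = frac["__error__"]
    else:
        for k, v in frac.items():
            values[f"Fractal_{k}_{G}gl"] = v

    ordered = {nm: values.get(nm, float("nan")) for nm in names}
    fs = FeatureSet(ordered, gray_level=G, missing=missing)
    assert len(fs.values) == len(names)
    return fs


def extract_all(
    volume: PETVolume, mask: np.ndarray, config: QuantisationConfig | None = None
) -> list[FeatureSet]:
    """One :class:`FeatureSet` (665 named features) per configured gray level."""
    if config is None:
        config = QuantisationConfig()
    shape_cache: dict = {}
    return [extract_features(volume, mask, G, shape_cache) for G in config.levels_list]


def feature_table(featuresets: list[FeatureSet]) -> "object":
    """Concatenate per-gray-level FeatureSets into one pandas row (Series)."""
    import pandas as pd

    merged: dict[str, float] = {}
    for fs in featuresets:
        merged.update(fs.values)
    return pd.Series(merged)
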