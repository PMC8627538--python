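"""Per-lesion radiomic feature extraction (42 features per VOI).

Families and counts follow the LIFEx-style roster: 2 shape + 9 first-order +
6 GLCM + 11 GLRLM + 3 NGLDM + 11 GLZLM = 42.  All texture matrices are
computed in 3-D on the discretized VOI: co-occurrences and runs are
accumulated over the 13 unique 3-D neighbour directions into a single matrix
(both orientations for GLCM), zones are 26-connected components per grey
level, and the neighbourhood-difference family uses the 26-neighbourhood.

Pipeline per lesion: resample to isotropic spacing (trilinear for the volume,
nearest-neighbour for the mask) → discretize in-mask SUVs to ``n_bins`` grey
levels → compute every family → assemble the roster-ordered vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .errors import (ConfigurationError, DegenerateVOIError,
                     TextureUndefinedError)

SHAPE_NAMES = ("Volume_mL", "Sphericity")
FIRST_ORDER_NAMES = ("SUV_min", "SUV_mean", "SUV_std", "SUV_max", "Skewness",
                     "Kurtosis", "Energy", "Entropy", "Uniformity")
GLCM_NAMES = ("GLCM_Homogeneity", "GLCM_Energy", "GLCM_Contrast",
              "GLCM_Correlation", "GLCM_Entropy", "GLCM_Dissimilarity")
GLRLM_NAMES = ("GLRLM_SRE", "GLRLM_LRE", "GLRLM_LGRE", "GLRLM_HGRE",
               "GLRLM_SRLGE", "GLRLM_SRHGE", "GLRLM_LRLGE", "GLRLM_LRHGE",
               "GLRLM_GLNU", "GLRLM_RLNU", "GLRLM_RP")
NGLDM_NAMES = ("NGLDM_Coarseness", "NGLDM_Contrast", "NGLDM_Busyness")
GLZLM_NAMES = ("GLZLM_SZE", "GLZLM_LZE", "GLZLM_LGZE", "GLZLM_HGZE",
               "GLZLM_SZLGE", "GLZLM_SZHGE", "GLZLM_LZLGE", "GLZLM_LZHGE",
               "GLZLM_GLNUz", "GLZLM_ZLNU", "GLZLM_ZP")

#: The default 42-feature roster, in output order.
DEFAULT_ROSTER: tuple[str, ...] = (SHAPE_NAMES + FIRST_ORDER_NAMES
                                   + GLCM_NAMES + GLRLM_NAMES + NGLDM_NAMES
                                   + GLZLM_NAMES)
assert len(DEFAULT_ROSTER) == 42

#: The 13 unique 3-D neighbour directions (lexicographically positive half
#: of the 26-neighbourhood; the other 13 are their negatives).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    d for d in ((dx, dy, dz)
                for dx in (0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1))
    if d > (0, 0, 0))
assert len(DIRECTIONS_13) == 13

_COARSENESS_CAP = 1e6  # conventional cap when the denominator vanishes


@dataclass
class ExtractionConfig:
    """Preprocessing and roster settings of the extractor.

    target_spacing_mm : isotropic voxel size after resampling (mm).
    n_bins : number of grey levels for intensity discretization.
    discretization_mode : ``"RELATIVE_MINMAX"`` (bins span the VOI's own
        min..max) or ``"ABSOLUTE_BOUNDS"`` (fixed SUV bounds, values clamped).
    absolute_bounds : (low, high) SUV, used only in absolute mode.
    feature_roster : ordered feature names to emit; None means the default 42.
    """

    target_spacing_mm: float = 2.0
    n_bins: int = 64
    discretization_mode: str = "RELATIVE_MINMAX"
    absolute_bounds: tuple[float, float] = (0.0, 25.0)
    feature_roster: Sequence[str] | None = None

    def validate(self) -> None:
        if self.n_bins < 2:
            raise ConfigurationError("n_bins must be >= 2")
        if self.target_spacing_mm <= 0:
            raise ConfigurationError("target_spacing_mm must be > 0")
        if self.discretization_mode not in ("RELATIVE_MINMAX",
                                            "ABSOLUTE_BOUNDS"):
            raise ConfigurationError(
                "discretization_mode must be RELATIVE_MINMAX or ABSOLUTE_BOUNDS")
        if (self.discretization_mode == "ABSOLUTE_BOUNDS"
                and not self.absolute_bounds[0] < self.absolute_bounds[1]):
            raise ConfigurationError("absolute_bounds must satisfy low < high")
        unknown = set(self.roster) - set(DEFAULT_ROSTER)
        if unknown:
            raise ConfigurationError(f"feature_roster has unknown names: "
                                     f"{sorted(unknown)}")

    @property
    def roster(self) -> tuple[str, ...]:
        return (DEFAULT_ROSTER if self.feature_roster is None
                else tuple(self.feature_roster))


@dataclass
class DiscretizedVOI:
    """A VOI after grey-level discretization.

    ``levels`` holds integers 1..n_bins inside the mask and 0 (the excluded
    sentinel) outside; ``raw`` keeps the original SUVs for first-order
    statistics on the continuous scale.
    """

    levels: np.ndarray
    mask: np.ndarray
    spacing_mm: float
    raw: np.ndarray
    n_bins: int

    @property
    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]

    @property
    def in_mask_raw(self) -> np.ndarray:
        return self.raw[self.mask]


@dataclass
class FeatureVector:
    """One lesion's roster-ordered radiomic profile."""

    names: tuple[str, ...]
    values: np.ndarray
    lesion_id: str | None = None
    suv_max: float = float("nan")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names),
                         name=self.lesion_id)


# ---------------------------------------------------------------------------
# preprocessing

def resample(volume: np.ndarray, mask: np.ndarray,
             spacing_mm: float | Sequence[float],
             target_spacing_mm: float,
             ) -> tuple[np.ndarray, np.ndarray, float]:
    """Resample a volume/mask pair to an isotropic grid.

    The volume is interpolated trilinearly and the mask by nearest
    neighbour; the grids share the origin at the first voxel centre.  An
    input already isotropic at the target spacing is returned unchanged.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if volume.shape != mask.shape:
        raise DegenerateVOIError("volume and mask must share a grid")
    if not mask.any():
        raise DegenerateVOIError("mask is empty")
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,))
    if np.allclose(spacing, target_spacing_mm):
        return volume, mask, float(target_spacing_mm)
    new_shape = np.maximum(
        1, np.round(np.array(volume.shape) * spacing / target_spacing_mm)
    ).astype(int)
    grids = np.meshgrid(*[np.arange(n) * target_spacing_mm / s
                          for n, s in zip(new_shape, spacing)],
                        indexing="ij")
    coords = np.stack(grids)
    out_vol = ndimage.map_coordinates(volume, coords, order=1, mode="nearest")
    out_mask = ndimage.map_coordinates(mask.astype(np.uint8), coords, order=0,
                                       mode="nearest").astype(bool)
    if not out_mask.any():
        raise DegenerateVOIError("mask is empty after resampling")
    return out_vol, out_mask, float(target_spacing_mm)


def discretize(volume: np.ndarray, mask: np.ndarray,
               config: ExtractionConfig,
               spacing_mm: float = 1.0) -> DiscretizedVOI:
    """Map in-mask SUVs to integer grey levels 1..n_bins.

    Relative mode: ``level = 1 + floor(n_bins * (x - min)/(max - min))``,
    clamped to ``n_bins`` at ``x = max``; a constant VOI maps wholly to
    level 1.  Absolute mode: same formula with the configured fixed bounds,
    out-of-range values clamped.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise DegenerateVOIError("mask is empty")
    vals = volume[mask]
    n = config.n_bins
    if config.discretization_mode == "RELATIVE_MINMAX":
        lo, hi = float(vals.min()), float(vals.max())
    else:
        lo, hi = map(float, config.absolute_bounds)
        if not lo < hi:
            raise ConfigurationError("absolute_bounds must satisfy low < high")
        vals = np.clip(vals, lo, hi)
    if hi > lo:
        lev = 1 + np.floor(n * (vals - lo) / (hi - lo)).astype(int)
        lev = np.clip(lev, 1, n)
    else:
        lev = np.ones(vals.shape, dtype=int)
    levels = np.zeros(volume.shape, dtype=int)
    levels[mask] = lev
    return DiscretizedVOI(levels=levels, mask=mask, spacing_mm=spacing_mm,
                          raw=volume, n_bins=n)


# ---------------------------------------------------------------------------
# first-order and shape

def first_order(voi: DiscretizedVOI) -> tuple[dict[str, float], bool]:
    """Nine first-order statistics.

    Intensity statistics (min/mean/std/max, standardized moments) are on the
    raw SUVs; Energy, Entropy and Uniformity are on the discretized
    grey-level histogram.  Returns ``(values, degenerate)`` where
    ``degenerate`` marks a zero-variance VOI (Skewness and Kurtosis set to 0).
    """
    x = voi.in_mask_raw
    if x.size < 2:
        raise DegenerateVOIError("need >= 2 in-mask voxels for moments")
    mean = float(x.mean())
    std = float(x.std())  # population (n) normalisation
    degenerate = std == 0.0
    if degenerate:
        skew = kurt = 0.0
    else:
        z = (x - mean) / std
        skew = float(np.mean(z ** 3))
        kurt = float(np.mean(z ** 4))  # non-excess
    counts = np.bincount(voi.in_mask_levels, minlength=voi.n_bins + 1)[1:]
    p = counts[counts > 0] / counts.sum()
    energy = float(np.sum(p ** 2))
    entropy = float(-np.sum(p * np.log2(p)))
    values = {"SUV_min": float(x.min()), "SUV_mean": mean, "SUV_std": std,
              "SUV_max": float(x.max()), "Skewness": skew, "Kurtosis": kurt,
              "Energy": energy, "Entropy": entropy, "Uniformity": energy}
    return values, degenerate


def voxel_face_area(mask: np.ndarray, spacing_mm: float) -> float:
    """Total exposed voxel-face area (mm^2) of a binary mask."""
    m = np.asarray(mask).astype(bool)
    faces = 0
    for ax in range(3):
        pad = np.pad(m, [(1, 1) if a == ax else (0, 0) for a in range(3)])
        sl_lo = tuple(slice(0, -1) if a == ax else slice(None) for a in range(3))
        sl_hi = tuple(slice(1, None) if a == ax else slice(None) for a in range(3))
        faces += int(np.sum(pad[sl_lo] != pad[sl_hi]))
    return faces * spacing_mm ** 2


def shape(mask: np.ndarray, spacing_mm: float) -> dict[str, float]:
    """Volume (mL) and Sphericity of a binary mask.

    Volume is voxel count times voxel volume.  Sphericity is
    ``pi^(1/3) * (6V)^(2/3) / A`` with ``A`` the surface area of the
    marching-cubes isosurface of the mask.  The mask is smoothed with a
    half-voxel Gaussian before meshing to reduce the facet bias of binary
    isosurfaces; masks too thin for an isosurface fall back to the exposed
    voxel-face area.
    """
    m = np.asarray(mask).astype(bool)
    n_vox = int(m.sum())
    if n_vox == 0:
        raise DegenerateVOIError("mask is empty")
    v_mm3 = n_vox * spacing_mm ** 3
    try:
        padded = ndimage.gaussian_filter(np.pad(m.astype(float), 2), 0.5)
        verts, faces_idx, _, _ = measure.marching_cubes(
            padded, level=0.5, spacing=(spacing_mm,) * 3)
        area = float(measure.mesh_surface_area(verts, faces_idx))
    except (ValueError, RuntimeError):
        area = voxel_face_area(m, spacing_mm)
    sphericity = float(np.pi ** (1 / 3) * (6 * v_mm3) ** (2 / 3) / area)
    return {"Volume_mL": v_mm3 / 1000.0, "Sphericity": sphericity}


# ---------------------------------------------------------------------------
# texture matrices

def _offset_slices(shape: tuple[int, ...], d: tuple[int, int, int]):
    """(src, dst) slice tuples such that arr[src] and arr[dst] pair voxel x
    with voxel x + d."""
    src = tuple(slice(max(0, -dk), shape[k] - max(0, dk))
                for k, dk in enumerate(d))
    dst = tuple(slice(max(0, dk), shape[k] - max(0, -dk))
                for k, dk in enumerate(d))
    return src, dst


def glcm(voi: DiscretizedVOI, distance: int = 1,
         directions: Sequence[tuple[int, int, int]] = DIRECTIONS_13,
         ) -> np.ndarray:
    """Grey-level co-occurrence matrix.

    Co-occurrences at the given Chebyshev distance are accumulated over all
    directions and both orientations into one symmetric ``n_bins x n_bins``
    matrix, normalized to sum 1 over in-mask voxel pairs.
    """
    lv, mask = voi.levels, voi.mask
    n = voi.n_bins
    counts = np.zeros((n, n), dtype=float)
    for d in directions:
        dd = tuple(distance * k for k in d)
        src, dst = _offset_slices(lv.shape, dd)
        both = mask[src] & mask[dst]
        a = lv[src][both] - 1
        b = lv[dst][both] - 1
        if a.size:
            np.add.at(counts, (a, b), 1.0)
            np.add.at(counts, (b, a), 1.0)
    total = counts.sum()
    if total == 0:
        raise TextureUndefinedError("no valid voxel pair for GLCM")
    return counts / total


def glcm_features(matrix: np.ndarray) -> dict[str, float]:
    """Six co-occurrence features from a normalized GLCM."""
    n = matrix.shape[0]
    i = np.arange(1, n + 1)[:, None]
    j = np.arange(1, n + 1)[None, :]
    p = matrix
    homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    energy = float(np.sum(p ** 2))
    contrast = float(np.sum((i - j) ** 2 * p))
    dissimilarity = float(np.sum(np.abs(i - j) * p))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    pi = p.sum(axis=1)
    mu = float(np.sum(np.arange(1, n + 1) * pi))
    var = float(np.sum((np.arange(1, n + 1) - mu) ** 2 * pi))
    if var > 0:
        correlation = float((np.sum(i * j * p) - mu * mu) / var)
    else:
        correlation = 0.0
    return {"GLCM_Homogeneity": homogeneity, "GLCM_Energy": energy,
            "GLCM_Contrast": contrast, "GLCM_Correlation": correlation,
            "GLCM_Entropy": entropy, "GLCM_Dissimilarity": dissimilarity}


def glrlm(voi: DiscretizedVOI,
          directions: Sequence[tuple[int, int, int]] = DIRECTIONS_13,
          ) -> np.ndarray:
    """Grey-level run-length matrix, runs accumulated over all directions.

    A run is a maximal straight segment of in-mask voxels sharing one grey
    level.  Entry ``[i-1, j-1]`` counts runs of level ``i`` and length ``j``.
    """
    lv, mask = voi.levels, voi.mask
    max_run = int(np.ceil(np.sqrt(np.sum(np.array(lv.shape) ** 2)))) + 1
    R = np.zeros((voi.n_bins, max_run), dtype=float)
    shape_ = lv.shape
    for d in directions:
        src, dst = _offset_slices(shape_, d)
        same_next = np.zeros(shape_, dtype=bool)
        same_next[src] = mask[src] & mask[dst] & (lv[src] == lv[dst])
        same_prev = np.zeros(shape_, dtype=bool)
        same_prev[dst] = same_next[src]
        starts = np.argwhere(mask & ~same_prev)
        if starts.size == 0:
            continue
        pos = starts.copy()
        start_levels = lv[tuple(starts.T)]
        alive = np.ones(len(pos), dtype=bool)
        length = np.ones(len(pos), dtype=int)
        dvec = np.array(d)
        while alive.any():
            cur = pos[alive]
            cont = same_next[tuple(cur.T)]
            idx_alive = np.flatnonzero(alive)
            ended = idx_alive[~cont]
            np.add.at(R, (start_levels[ended] - 1, length[ended] - 1), 1.0)
            go = idx_alive[cont]
            pos[go] += dvec
            length[go] += 1
            alive[:] = False
            alive[go] = True
    return R


def glrlm_features(voi: DiscretizedVOI,
                   directions: Sequence[tuple[int, int, int]] = DIRECTIONS_13,
                   ) -> dict[str, float]:
    """Eleven run-length features (IBSI definitions), with run percentage
    ``RP = n_runs / (n_voxels * n_directions)``."""
    R = glrlm(voi, directions)
    stats = _size_matrix_features(R)
    n_vox = int(voi.mask.sum())
    return {"GLRLM_SRE": stats["short"], "GLRLM_LRE": stats["long"],
            "GLRLM_LGRE": stats["low"], "GLRLM_HGRE": stats["high"],
            "GLRLM_SRLGE": stats["short_low"],
            "GLRLM_SRHGE": stats["short_high"],
            "GLRLM_LRLGE": stats["long_low"],
            "GLRLM_LRHGE": stats["long_high"],
            "GLRLM_GLNU": stats["gl_nonuniformity"],
            "GLRLM_RLNU": stats["size_nonuniformity"],
            "GLRLM_RP": stats["total"] / (n_vox * len(directions))}


def _size_matrix_features(M: np.ndarray) -> dict[str, float]:
    """Shared emphasis/non-uniformity statistics of a level x size count
    matrix (used by both run-length and size-zone families)."""
    total = M.sum()
    if total == 0:
        raise TextureUndefinedError("empty level/size matrix")
    p = M / total
    i = np.arange(1, M.shape[0] + 1)[:, None].astype(float)
    j = np.arange(1, M.shape[1] + 1)[None, :].astype(float)
    return {
        "short": float(np.sum(p / j ** 2)),
        "long": float(np.sum(p * j ** 2)),
        "low": float(np.sum(p / i ** 2)),
        "high": float(np.sum(p * i ** 2)),
        "short_low": float(np.sum(p / (i ** 2 * j ** 2))),
        "short_high": float(np.sum(p * i ** 2 / j ** 2)),
        "long_low": float(np.sum(p * j ** 2 / i ** 2)),
        "long_high": float(np.sum(p * i ** 2 * j ** 2)),
        "gl_nonuniformity": float(np.sum(M.sum(axis=1) ** 2) / total),
        "size_nonuniformity": float(np.sum(M.sum(axis=0) ** 2) / total),
        "total": float(total),
    }


def ngldm_features(voi: DiscretizedVOI) -> dict[str, float]:
    """Coarseness, Contrast and Busyness from the 26-neighbourhood
    grey-level difference construction.

    Per in-mask voxel with at least one in-mask neighbour, the difference
    ``|level - mean(in-mask 26-neighbour levels)|`` is accumulated per grey
    level into ``s(i)``; the three features follow the standard
    neighbourhood-difference formulas with the conventions Contrast := 0
    when a single grey level is present, Busyness := 0 on a zero
    denominator, and Coarseness capped at 1e6.
    """
    lv, mask = voi.levels, voi.mask
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    n_nb = ndimage.convolve(mask.astype(float), kernel, mode="constant")
    sum_nb = ndimage.convolve(np.where(mask, lv, 0).astype(float), kernel,
                              mode="constant")
    valid = mask & (n_nb > 0)
    if not valid.any():
        raise TextureUndefinedError("no voxel has an in-mask neighbour")
    mean_nb = sum_nb[valid] / n_nb[valid]
    levels = lv[valid]
    diffs = np.abs(levels - mean_nb)
    N = int(valid.sum())
    present = np.unique(levels)
    p = np.array([(levels == g).sum() for g in present], dtype=float) / N
    s = np.array([diffs[levels == g].sum() for g in present])
    denom = float(np.sum(p * s))
    coarseness = min(1.0 / denom, _COARSENESS_CAP) if denom > 0 else _COARSENESS_CAP
    ng = len(present)
    if ng < 2:
        contrast = 0.0
    else:
        pg = p[:, None] * p[None, :]
        dg2 = (present[:, None] - present[None, :]).astype(float) ** 2
        contrast = float(np.sum(pg * dg2) / (ng * (ng - 1)) * (s.sum() / N))
    busy_den = float(np.sum(np.abs(present[:, None] * p[:, None]
                                   - present[None, :] * p[None, :])))
    busyness = float(denom / busy_den) if busy_den > 0 else 0.0
    return {"NGLDM_Coarseness": float(coarseness),
            "NGLDM_Contrast": contrast,
            "NGLDM_Busyness": busyness}


def glzlm(voi: DiscretizedVOI) -> np.ndarray:
    """Grey-level size-zone matrix: zones are 26-connected components of
    equal grey level; entry ``[i-1, j-1]`` counts zones of level ``i`` and
    size ``j``."""
    lv, mask = voi.levels, voi.mask
    n_vox = int(mask.sum())
    Z = np.zeros((voi.n_bins, n_vox), dtype=float)
    structure = np.ones((3, 3, 3), dtype=int)
    for g in np.unique(lv[mask]):
        lab, n_comp = ndimage.label(lv == g, structure=structure)
        if n_comp == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for sz in sizes:
            Z[g - 1, sz - 1] += 1
    return Z


def glzlm_features(voi: DiscretizedVOI) -> dict[str, float]:
    """Eleven size-zone features, with zone percentage
    ``ZP = n_zones / n_in-mask_voxels``."""
    Z = glzlm(voi)
    stats = _size_matrix_features(Z)
    n_vox = int(voi.mask.sum())
    return {"GLZLM_SZE": stats["short"], "GLZLM_LZE": stats["long"],
            "GLZLM_LGZE": stats["low"], "GLZLM_HGZE": stats["high"],
            "GLZLM_SZLGE": stats["short_low"],
            "GLZLM_SZHGE": stats["short_high"],
            "GLZLM_LZLGE": stats["long_low"],
            "GLZLM_LZHGE": stats["long_high"],
            "GLZLM_GLNUz": stats["gl_nonuniformity"],
            "GLZLM_ZLNU": stats["size_nonuniformity"],
            "GLZLM_ZP": stats["total"] / n_vox}


# ---------------------------------------------------------------------------
# top level

def extract(volume: np.ndarray, mask: np.ndarray,
            spacing_mm: float | Sequence[float],
            config: ExtractionConfig | None = None,
            lesion_id: str | None = None) -> FeatureVector:
    """Run the full extraction chain on one VOI and return the
    roster-ordered feature vector."""
    config = config or ExtractionConfig()
    config.validate()
    try:
        vol, msk, sp = resample(volume, mask, spacing_mm,
                                config.target_spacing_mm)
        voi = discretize(vol, msk, config, spacing_mm=sp)
        values: dict[str, float] = {}
        values.update(shape(msk, sp))
        fo, _ = first_order(voi)
        values.update(fo)
        values.update(glcm_features(glcm(voi)))
        values.update(glrlm_features(voi))
        values.update(ngldm_features(voi))
        values.update(glzlm_features(voi))
    except Exception as exc:
        if lesion_id is not None and not isinstance(exc, ConfigurationError):
            raise type(exc)(f"lesion {lesion_id}: {exc}") from exc
        raise
    vec = np.array([values[name] for name in config.roster])
    return FeatureVector(names=config.roster, values=vec,
                         lesion_id=lesion_id,
                         suv_max=float(vol[msk].max()))


def extract_table(volumes: dict[str, tuple[np.ndarray, np.ndarray, float]],
                  lesions: pd.DataFrame,
                  config: ExtractionConfig | None = None) -> pd.DataFrame:
    """Extract features for every lesion and assemble the feature table
    (metadata columns + one column per roster feature)."""
    config = config or ExtractionConfig()
    rows = []
    for _, les in lesions.iterrows():
        lid = les["lesion_id"]
        vol, mask, spacing = volumes[lid]
        fv = extract(vol, mask, spacing, config, lesion_id=lid)
        row = {"lesion_id": lid, "patient_id": les["patient_id"],
               "site_class": les["site_class"], "suv_max": fv.suv_max}
        row.update(dict(zip(fv.names, fv.values)))
        rows.append(row)
    return pd.DataFrame(rows)
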