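"""Per-voxel feature extraction for the tissue classifier.

Four feature families are computed per in-mask voxel:

1. intensities — the four normalized channel values;
2. patch statistics — first-order texture (mean, variance, skewness,
   kurtosis, energy, entropy) over cubic patches at several radii, per
   modality, with patch windows clipped at the mask/grid border (statistics
   run over the available in-mask voxels only);
3. gradient — per modality, spacing-aware central-difference gradient
   magnitude and its patch mean;
4. symmetry — per modality and smoothing scale, the absolute intensity
   difference to the voxel mirrored across the mid-sagittal plane, after
   Gaussian smoothing at that scale;

plus location features: coordinates normalized to the brain-mask bounding
box and the physical distance to the mask centroid.

No feature value depends on intensities outside the brain mask: channels are
masked (out-of-mask voxels zeroed) before any filtering, and patch statistics
are renormalized by the in-window mask count.

Patch entropy uses a fixed 32-bin histogram over the in-mask intensity range
of the channel, so 0 <= entropy <= log2(32); the entropy of a constant patch
is 0, as are variance, skewness and kurtosis.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .volumes_io import MODALITIES, MultiModalStudy

ALL_STATS = ("mean", "variance", "skewness", "kurtosis", "energy", "entropy")
ENTROPY_BINS = 32
_EPS_SD = 1e-8


@dataclasses.dataclass
class FeatureConfig:
    patch_radii: tuple[int, ...] = (1, 2)
    stats: tuple[str, ...] = ALL_STATS
    gradient: bool = True
    symmetry_scales: tuple[float, ...] = (2.0, 4.0)  # mm
    location: bool = True

    def __post_init__(self) -> None:
        self.patch_radii = tuple(int(r) for r in self.patch_radii)
        self.stats = tuple(self.stats)
        self.symmetry_scales = tuple(float(s) for s in self.symmetry_scales)
        if any(r < 1 for r in self.patch_radii):
            raise ValueError("patch radii must be >= 1 voxel")
        unknown = set(self.stats) - set(ALL_STATS)
        if unknown:
            raise ValueError(f"unknown patch statistics {sorted(unknown)}")
        n_families = (
            1  # intensities always on
            + (1 if self.patch_radii and self.stats else 0)
            + (1 if self.gradient else 0)
            + (1 if self.symmetry_scales else 0)
            + (1 if self.location else 0)
        )
        if n_families < 1:
            raise ValueError("at least one feature family must be enabled")


@dataclasses.dataclass
class FeatureMatrix:
    """Row-per-voxel feature matrix with a name registry.

    ``registry`` maps each column name to ``(family, modality, scale)`` where
    scale is a patch radius (voxels), a smoothing scale (mm) or None.
    """

    values: np.ndarray  # (n_voxels, n_features)
    names: tuple[str, ...]
    voxel_index: np.ndarray  # (n_voxels, 3) int
    registry: dict[str, tuple[str, Optional[str], Optional[float]]]

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("duplicate feature names")
        if self.values.shape[1] != len(self.names):
            raise ValueError("column count does not match name list")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")


def feature_names(config: FeatureConfig) -> tuple[str, ...]:
    """Deterministic feature ordering; count =
    4 + 4*|radii|*|stats| + (gradient ? 8 : 0) + 4*|symmetry_scales| +
    (location ? 4 : 0)."""
    names: list[str] = [f"intensity_{m}" for m in MODALITIES]
    for m in MODALITIES:
        for r in config.patch_radii:
            for s in config.stats:
                names.append(f"patch_{s}_{m}_r{r}")
    if config.gradient:
        for m in MODALITIES:
            names.append(f"gradmag_{m}")
        for m in MODALITIES:
            names.append(f"gradmag_patchmean_{m}")
    for m in MODALITIES:
        for s in config.symmetry_scales:
            names.append(f"symmetry_{m}_s{s:g}mm")
    if config.location:
        names += ["loc_x", "loc_y", "loc_z", "loc_dist_mm"]
    return tuple(names)


def _registry(config: FeatureConfig) -> dict:
    reg = {}
    for name in feature_names(config):
        parts = name.split("_")
        if name.startswith("intensity"):
            reg[name] = ("intensity", parts[1], None)
        elif name.startswith("patch_"):
            reg[name] = ("patch", parts[2], float(parts[3][1:]))
        elif name.startswith("gradmag_patchmean"):
            reg[name] = ("gradient", parts[2], None)
        elif name.startswith("gradmag"):
            reg[name] = ("gradient", parts[1], None)
        elif name.startswith("symmetry"):
            reg[name] = ("symmetry", parts[1], float(parts[2][1:-2]))
        else:
            reg[name] = ("location", None, None)
    return reg


def estimate_midsagittal_plane(mask: np.ndarray) -> int:
    """Sagittal (fixed-x) plane index through the mask centroid, rounded."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    cx = ndimage.center_of_mass(mask)[0]
    return int(np.rint(cx))


def _box_sum(arr: np.ndarray, radius: int) -> np.ndarray:
    size = 2 * radius + 1
    return ndimage.uniform_filter(arr, size=size, mode="constant", cval=0.0) * size ** 3


def _patch_stats(
    img: np.ndarray, mask: np.ndarray, radius: int, stats: Sequence[str]
) -> dict[str, np.ndarray]:
    """Masked first-order statistics over (2r+1)^3 windows clipped to mask."""
    m = mask.astype(np.float64)
    x = img * m
    n = _box_sum(m, radius)
    n_safe = np.maximum(n, 1.0)
    mu = _box_sum(x, radius) / n_safe
    out: dict[str, np.ndarray] = {}
    need_var = {"variance", "skewness", "kurtosis"} & set(stats)
    if need_var or "energy" in stats:
        m2_raw = _box_sum(x * img, radius) / n_safe  # E[I^2]
    if need_var:
        var = np.maximum(m2_raw - mu ** 2, 0.0)
        # cancellation floor: treat numerically-constant patches as constant
        var = np.where(var < 1e-12 * (1.0 + m2_raw), 0.0, var)
        sd = np.sqrt(var)
    if "mean" in stats:
        out["mean"] = mu
    if "variance" in stats:
        out["variance"] = var
    if "skewness" in stats or "kurtosis" in stats:
        m3 = _box_sum(x * img * img, radius) / n_safe - 3 * mu * m2_raw + 2 * mu ** 3
        ok = sd > 0
        if "skewness" in stats:
            out["skewness"] = np.where(ok, m3 / np.where(ok, sd, 1.0) ** 3, 0.0)
        if "kurtosis" in stats:
            m4 = (
                _box_sum(x * img ** 3, radius) / n_safe
                - 4 * mu * (_box_sum(x * img * img, radius) / n_safe)
                + 6 * mu ** 2 * m2_raw
                - 3 * mu ** 4
            )
            # excess kurtosis; 0 for (near-)constant patches
            out["kurtosis"] = np.where(
                ok, m4 / np.where(ok, var, 1.0) ** 2 - 3.0, 0.0
            )
    if "energy" in stats:
        out["energy"] = m2_raw
    if "entropy" in stats:
        vals = img[mask]
        lo, hi = float(vals.min()), float(vals.max())
        if hi - lo < _EPS_SD:
            out["entropy"] = np.zeros_like(img)
        else:
            dig = np.clip(
                ((img - lo) / (hi - lo) * ENTROPY_BINS).astype(np.int64),
                0, ENTROPY_BINS - 1,
            )
            ent = np.zeros_like(img, dtype=np.float64)
            for b in range(ENTROPY_BINS):
                p = _box_sum(((dig == b) & mask).astype(np.float64), radius) / n_safe
                with np.errstate(divide="ignore", invalid="ignore"):
                    term = np.where(p > 0, p * np.log2(p), 0.0)
                ent -= term
            out["entropy"] = np.maximum(ent, 0.0)
    return out


def _gradient_magnitude(img: np.ndarray, spacing) -> np.ndarray:
    gx, gy, gz = np.gradient(img, *spacing)
    return np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)


def extract_features(
    study: MultiModalStudy,
    mask: np.ndarray,
    config: Optional[FeatureConfig] = None,
) -> FeatureMatrix:
    """Feature matrix for every in-mask voxel of a preprocessed study."""
    if config is None:
        config = FeatureConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if not study.aligned():
        raise ValueError("study channels are not on a common grid")
    spacing = np.asarray(study.spacing)
    # features must not see out-of-mask intensities
    imgs = {
        m: np.where(mask, study.channels[m].voxels.astype(np.float64), 0.0)
        for m in MODALITIES
    }
    names = feature_names(config)
    cols: dict[str, np.ndarray] = {}
    for m in MODALITIES:
        cols[f"intensity_{m}"] = imgs[m]
    for m in MODALITIES:
        for r in config.patch_radii:
            st = _patch_stats(imgs[m], mask, r, config.stats)
            for s in config.stats:
                cols[f"patch_{s}_{m}_r{r}"] = st[s]
    if config.gradient:
        for m in MODALITIES:
            g = _gradient_magnitude(imgs[m], spacing)
            cols[f"gradmag_{m}"] = g
            r0 = min(config.patch_radii) if config.patch_radii else 1
            gm = _box_sum(g * mask, r0) / np.maximum(
                _box_sum(mask.astype(np.float64), r0), 1.0
            )
            cols[f"gradmag_patchmean_{m}"] = gm
    if config.symmetry_scales:
        plane = estimate_midsagittal_plane(mask)
        nx = mask.shape[0]
        mirror_x = np.clip(2 * plane - np.arange(nx), 0, nx - 1)
        for m in MODALITIES:
            for s in config.symmetry_scales:
                sigma_vox = s / spacing
                sm = ndimage.gaussian_filter(imgs[m], sigma=sigma_vox)
                cols[f"symmetry_{m}_s{s:g}mm"] = np.abs(sm - sm[mirror_x, :, :])
    idx = np.argwhere(mask)
    if config.location:
        lo = idx.min(axis=0)
        hi = idx.max(axis=0)
        span = np.maximum(hi - lo, 1)
        norm = (idx - lo) / span
        centroid = np.asarray(ndimage.center_of_mass(mask))
        dist = np.linalg.norm((idx - centroid) * spacing, axis=1)
    rows = np.empty((idx.shape[0], len(names)), dtype=np.float64)
    for j, name in enumerate(names):
        if name == "loc_x":
            rows[:, j] = norm[:, 0]
        elif name == "loc_y":
            rows[:, j] = norm[:, 1]
        elif name == "loc_z":
            rows[:, j] = norm[:, 2]
        elif name == "loc_dist_mm":
            rows[:, j] = dist
        else:
            rows[:, j] = cols[name][mask]
    return FeatureMatrix(
        values=rows, names=names, voxel_index=idx, registry=_registry(config)
    )
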