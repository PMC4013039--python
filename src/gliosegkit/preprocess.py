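"""Skull stripping, rigid co-registration and intensity normalization.

The preprocessing contract: after `preprocess_study`, all four channels live
on the post-contrast T1w reference grid (the channel on which enhancement is
read), non-brain voxels are zeroed, and in-mask intensities of each channel
are z-scored (mean 0, SD 1). Registration is 6-DOF rigid, scored by
normalized cross-correlation over the overlap of the two fields of view, and
optimized by a multi-start Powell search initialized at identity and at the
translation suggested by phase correlation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation
from skimage.filters import threshold_otsu
from skimage.morphology import ball
from skimage.registration import phase_cross_correlation

from .volumes_io import MODALITIES, ImageVolume, MultiModalStudy


@dataclasses.dataclass
class RigidTransform:
    """6-DOF rigid map of physical points: p -> R (p - c) + c + t.

    ``rotation`` holds intrinsic xyz Euler angles in radians, ``translation``
    and ``center`` are in mm.
    """

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix acting on physical (mm) coordinates."""
        R = Rotation.from_euler("xyz", self.rotation).as_matrix()
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = -R @ c + c + t
        return M

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other (matrix product self @ other), as a RigidTransform
        with this transform's center."""
        M = self.matrix() @ other.matrix()
        return RigidTransform.from_matrix(M, center=self.center)

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(
            np.linalg.inv(self.matrix()), center=self.center
        )

    @staticmethod
    def from_matrix(M: np.ndarray, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        R = M[:3, :3]
        angles = Rotation.from_matrix(R).as_euler("xyz")
        c = np.asarray(center, dtype=float)
        t = M[:3, 3] + R @ c - c
        return RigidTransform(
            rotation=tuple(angles), translation=tuple(t), center=tuple(c)
        )


def strip_skull(
    study: MultiModalStudy, closing_radius: int = 2
) -> np.ndarray:
    """Brain mask from the T1w channel.

    Otsu threshold, morphological closing (ball of ``closing_radius``),
    hole filling, then the largest 26-connected component. Relies on the
    exterior being dark relative to brain tissue.
    """
    t1 = study.channels["T1w"].voxels
    if not np.any(t1 != 0):
        raise ValueError("no foreground found: T1w channel is all zero")
    thr = threshold_otsu(t1)
    fg = t1 > thr
    if not fg.any():
        raise ValueError("no foreground found above Otsu threshold")
    fg = ndimage.binary_closing(fg, structure=ball(closing_radius))
    fg = ndimage.binary_fill_holes(fg)
    lab, n = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        raise ValueError("no foreground found after morphology")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    return mask


def _resample_onto(
    moving: ImageVolume, fixed: ImageVolume, transform: RigidTransform,
    order: int = 1, cval: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample `moving` at transform(fixed-grid physical points).

    Returns (resampled values on fixed grid, validity mask of samples that
    fell inside the moving field of view).
    """
    M = transform.matrix()
    R, off = M[:3, :3], M[:3, 3]
    sp_f = np.asarray(fixed.spacing)
    sp_m = np.asarray(moving.spacing)
    # fixed index -> fixed mm -> moving mm -> moving index
    A = (R * sp_f[None, :]) / sp_m[:, None]
    b = off / sp_m
    # NaN fill marks samples outside the moving field of view
    res = ndimage.affine_transform(
        moving.voxels.astype(np.float64), A, offset=b,
        output_shape=fixed.shape, order=order, mode="constant", cval=np.nan,
    )
    valid = np.isfinite(res)
    res = np.where(valid, res, cval)
    return res, valid


def _sampled_objective_factory(moving, fixed, center, min_overlap, stride=2):
    """NCC deficit on a stride-subsampled fixed grid (cheap, deterministic)."""
    sp_f = np.asarray(fixed.spacing)
    sp_m = np.asarray(moving.spacing)
    sub_shape = tuple(int(np.ceil(s / stride)) for s in fixed.shape)
    fix_sub = fixed.voxels[::stride, ::stride, ::stride].astype(np.float64)
    mov = moving.voxels.astype(np.float64)

    def objective(params: np.ndarray) -> float:
        tf = RigidTransform(
            rotation=tuple(params[:3]), translation=tuple(params[3:6]),
            center=center,
        )
        M = tf.matrix()
        A = (M[:3, :3] * sp_f[None, :] * stride) / sp_m[:, None]
        b = M[:3, 3] / sp_m
        res = ndimage.affine_transform(
            mov, A, offset=b, output_shape=sub_shape, order=1,
            mode="constant", cval=np.nan,
        )
        valid = np.isfinite(res)
        if valid.mean() < min_overlap:
            return 1.0  # worse than any real NCC deficit
        return 1.0 - _ncc(res[valid], fix_sub[valid])

    return objective


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def register_rigid(
    moving: ImageVolume,
    fixed: ImageVolume,
    min_overlap: float = 0.05,
) -> tuple[RigidTransform, ImageVolume]:
    """Estimate the rigid transform aligning ``moving`` to ``fixed``.

    The similarity objective is normalized cross-correlation over voxels where
    the resampled moving image is inside its field of view; it is therefore
    exactly invariant to a positive affine rescaling of either image's
    intensities. The optimizer is Powell started from (a) identity and (b)
    the integer-voxel translation suggested by phase correlation (when the
    grids are commensurate); the best final objective wins.

    Returns the transform and the moving image resampled onto the fixed grid
    with linear interpolation.
    """
    if moving.voxels.size == 0 or fixed.voxels.size == 0:
        raise ValueError("cannot register empty volumes")
    center = tuple((np.asarray(fixed.shape) - 1) / 2.0 * np.asarray(fixed.spacing))
    objective = _sampled_objective_factory(moving, fixed, center, min_overlap)

    starts = [np.zeros(6)]
    if moving.shape == fixed.shape and moving.spacing == fixed.spacing:
        shift = phase_cross_correlation(
            fixed.voxels.astype(np.float64), moving.voxels.astype(np.float64),
            upsample_factor=4, normalization=None,
        )[0]
        # moving sample index = fixed index + (-shift); translation in mm
        t0 = -np.asarray(shift) * np.asarray(fixed.spacing)
        starts.append(np.concatenate([np.zeros(3), t0]))

    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="Powell",
            options={"xtol": 1e-3, "ftol": 1e-7, "maxfev": 800},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best.fun >= 1.0:
        raise RuntimeError(
            f"registration failed: no overlapping field of view "
            f"(final objective {best.fun:.3f})"
        )
    tf = RigidTransform(
        rotation=tuple(best.x[:3]), translation=tuple(best.x[3:6]), center=center,
    )
    resampled, _ = _resample_onto(moving, fixed, tf)
    out = ImageVolume(
        voxels=resampled.astype(np.float32), spacing=fixed.spacing,
        modality=moving.modality, affine=fixed.affine,
    )
    return tf, out


def normalize_intensities(
    study: MultiModalStudy, mask: np.ndarray
) -> MultiModalStudy:
    """Z-score each channel inside the brain mask; zero outside."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    channels = {}
    for m in MODALITIES:
        vox = study.channels[m].voxels.astype(np.float64)
        vals = vox[mask]
        sd = vals.std()
        if sd == 0:
            raise ValueError(f"zero variance in channel {m} inside the mask")
        out = np.zeros_like(vox)
        out[mask] = (vals - vals.mean()) / sd
        src = study.channels[m]
        channels[m] = ImageVolume(
            voxels=out.astype(np.float32), spacing=src.spacing,
            modality=m, affine=src.affine,
        )
    return MultiModalStudy(channels=channels, brain_mask=mask)


def preprocess_study(
    study: MultiModalStudy,
    register: bool = True,
    strip: bool = True,
) -> MultiModalStudy:
    """Full preprocessing: co-register to the T1wGd grid, skull strip, z-score.

    With ``register=False`` the channels must already share one grid.
    """
    fixed = study.channels["T1wGd"]
    channels = {"T1wGd": fixed}
    for m in MODALITIES:
        if m == "T1wGd":
            continue
        ch = study.channels[m]
        if register:
            _, ch = register_rigid(ch, fixed)
        elif ch.shape != fixed.shape:
            raise ValueError(
                f"channel {m} not on the reference grid and register=False"
            )
        channels[m] = ch
    aligned = MultiModalStudy(channels={m: channels[m] for m in MODALITIES})
    if strip:
        mask = strip_skull(aligned)
    else:
        mask = (
            study.brain_mask
            if study.brain_mask is not None
            else np.ones(fixed.shape, dtype=bool)
        )
    return normalize_intensities(aligned, mask)
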