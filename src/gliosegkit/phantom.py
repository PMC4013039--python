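"""Synthetic four-modality MRI phantoms with ground-truth tumor compartments.

A phantom is an ellipsoidal "brain" embedded in a dark exterior, containing a
single tumor built from nested concentric spheres: necrotic core inside an
enhancing rim, inside a non-enhancing margin, inside an edema halo. The
default intensity table encodes only the ordinal contrasts that define the
compartments radiologically — enhancement is bright on post-contrast T1w
only, necrosis and edema are hyperintense on T2w/FLAIR, the exterior is near
zero on every channel — in arbitrary units. Degradations are additive
zero-mean Gaussian noise and an optional smooth multiplicative bias field
(low-order polynomial in normalized coordinates).

Because the compartments are analytic spheres, compartment volumes have
closed forms ((4/3)*pi*r^3 and shell differences), which downstream tests use
as oracles.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional, Sequence

import numpy as np

from .volumes_io import (
    MODALITIES,
    ImageVolume,
    LabelMap,
    MultiModalStudy,
)

#: tissue rows of the intensity table (the two code-0 tissues differ in signal)
TISSUES = ("background", "brain", "necrosis", "edema", "nonenhancing", "enhancing")

#: tissue -> label code written to the ground-truth map
TISSUE_CODE = {
    "background": 0,
    "brain": 0,
    "necrosis": 1,
    "edema": 2,
    "nonenhancing": 3,
    "enhancing": 4,
}

# mean intensity per tissue x modality (T1w, T1wGd, T2w, FLAIR), arbitrary units.
# Encodes: enhancing bright on T1wGd only; necrosis dark on T1wGd, bright on
# T2w/FLAIR; edema bright on T2w/FLAIR; non-enhancing intermediate.
DEFAULT_MEANS = {
    "background": (10.0, 10.0, 10.0, 10.0),
    "brain": (100.0, 100.0, 100.0, 100.0),
    "necrosis": (55.0, 55.0, 165.0, 160.0),
    "edema": (80.0, 82.0, 150.0, 175.0),
    "nonenhancing": (70.0, 76.0, 128.0, 130.0),
    "enhancing": (90.0, 185.0, 120.0, 118.0),
}

# optional extra per-tissue variability on top of noise_sd (defaults to none,
# so that noise_sd = 0 yields exactly the class means)
DEFAULT_SDS = {t: (0.0, 0.0, 0.0, 0.0) for t in TISSUES}


@dataclasses.dataclass
class PhantomSpec:
    """Full description of one synthetic study; identical specs and seeds
    yield bit-identical phantoms."""

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_center: Optional[tuple[float, float, float]] = None  # voxels; default grid center
    brain_semiaxes: Optional[tuple[float, float, float]] = None  # voxels; default 0.42*shape
    tumor_center: Optional[tuple[float, float, float]] = None  # voxels; default brain center + small offset
    radii: tuple[float, float, float, float] = (4.0, 7.0, 9.0, 12.0)  # mm: core < rim < margin < halo
    means: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_MEANS))
    sds: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_SDS))
    noise_sd: float = 10.0
    bias_amplitude: float = 0.0
    lobes: float = 0.0  # relative radial perturbation amplitude for non-spherical tumors
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.brain_center is None:
            self.brain_center = tuple((s - 1) / 2.0 for s in self.shape)
        if self.brain_semiaxes is None:
            self.brain_semiaxes = tuple(0.42 * s for s in self.shape)
        if self.tumor_center is None:
            self.tumor_center = tuple(
                c + d for c, d in zip(self.brain_center, (3.0, -2.0, 1.0))
            )
        self.validate()

    def validate(self) -> None:
        r = self.radii
        if not (0 < r[0] < r[1] < r[2] < r[3]):
            raise ValueError(
                f"radii must be strictly increasing core < rim < margin < halo, got {r}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for t in TISSUES:
            if any(s < 0 for s in self.sds[t]):
                raise ValueError(f"negative SD for tissue {t!r}")
        # the halo sphere must fit inside the brain ellipsoid: check that the
        # tumor center, pushed outward by halo/semiaxis in normalized ellipsoid
        # coordinates, stays inside.
        c = np.asarray(self.tumor_center) - np.asarray(self.brain_center)
        c_mm = c * np.asarray(self.spacing)
        semi_mm = np.asarray(self.brain_semiaxes) * np.asarray(self.spacing)
        rho = np.linalg.norm(c_mm / semi_mm)
        if rho + self.radii[3] / float(np.min(semi_mm)) > 1.0:
            raise ValueError("tumor (halo sphere) does not fit inside the brain ellipsoid")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _coordinate_grids(shape, spacing):
    idx = np.indices(shape, dtype=np.float64)
    return [idx[a] * spacing[a] for a in range(3)]


def brain_mask_analytic(spec: PhantomSpec) -> np.ndarray:
    """The exact ellipsoid brain mask of a phantom (oracle for skull stripping)."""
    xs = _coordinate_grids(spec.shape, spec.spacing)
    semi_mm = [a * s for a, s in zip(spec.brain_semiaxes, spec.spacing)]
    c_mm = [c * s for c, s in zip(spec.brain_center, spec.spacing)]
    q = sum(((x - c) / a) ** 2 for x, c, a in zip(xs, c_mm, semi_mm))
    return q <= 1.0


def _tumor_distance_mm(spec: PhantomSpec) -> np.ndarray:
    """Physical distance (mm) from the tumor center, optionally lobed.

    With ``lobes > 0`` the effective distance is modulated by a smooth angular
    perturbation so compartment boundaries are non-spherical but still nested.
    """
    xs = _coordinate_grids(spec.shape, spec.spacing)
    c_mm = [c * s for c, s in zip(spec.tumor_center, spec.spacing)]
    d = [x - c for x, c in zip(xs, c_mm)]
    r = np.sqrt(sum(v ** 2 for v in d))
    if spec.lobes > 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(r > 0, d[0] / r, 0.0)
            uy = np.where(r > 0, d[1] / r, 0.0)
        # smooth degree-2 angular modulation, amplitude `lobes` (relative)
        mod = 1.0 + spec.lobes * (ux * uy + 0.5 * (ux ** 2 - uy ** 2))
        r = r * mod
    return r


def ground_truth_labels(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """(tissue index grid into TISSUES, label-code grid)."""
    brain = brain_mask_analytic(spec)
    r = _tumor_distance_mm(spec)
    core, rim, margin, halo = spec.radii
    tissue = np.zeros(spec.shape, dtype=np.int8)  # background
    tissue[brain] = TISSUES.index("brain")
    tissue[brain & (r <= halo)] = TISSUES.index("edema")
    tissue[brain & (r <= margin)] = TISSUES.index("nonenhancing")
    tissue[brain & (r <= rim)] = TISSUES.index("enhancing")
    tissue[brain & (r <= core)] = TISSUES.index("necrosis")
    codes = np.zeros(spec.shape, dtype=np.uint8)
    for i, t in enumerate(TISSUES):
        codes[tissue == i] = TISSUE_CODE[t]
    return tissue, codes


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative smooth field 1 + amplitude * P(u), with P a seeded
    quadratic polynomial in coordinates normalized to [-1, 1], scaled to
    max |P| = 1 over the grid."""
    if spec.bias_amplitude == 0:
        return np.ones(spec.shape)
    us = [
        np.linspace(-1.0, 1.0, n).reshape(
            [-1 if a == ax else 1 for ax in range(3)]
        )
        for a, n in enumerate(spec.shape)
    ]
    ux, uy, uz = np.broadcast_arrays(*us)
    terms = [ux, uy, uz, ux * uy, ux * uz, uy * uz, ux ** 2, uy ** 2, uz ** 2]
    coef = rng.uniform(-1.0, 1.0, size=len(terms))
    p = sum(c * t for c, t in zip(coef, terms))
    p = p / np.max(np.abs(p))
    return 1.0 + spec.bias_amplitude * p


def generate_phantom(spec: PhantomSpec) -> tuple[MultiModalStudy, LabelMap]:
    """Generate one study + ground-truth label map, reproducibly from the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tissue, codes = ground_truth_labels(spec)
    bias = _bias_field(spec, rng)

    channels = {}
    for mi, modality in enumerate(MODALITIES):
        mean_lut = np.array([spec.means[t][mi] for t in TISSUES])
        sd_lut = np.array([spec.sds[t][mi] for t in TISSUES])
        img = mean_lut[tissue]
        sd_vox = np.sqrt(sd_lut[tissue] ** 2 + spec.noise_sd ** 2)
        if np.any(sd_vox > 0):
            img = img + rng.standard_normal(spec.shape) * sd_vox
        img = img * bias
        channels[modality] = ImageVolume(
            voxels=img.astype(np.float32), spacing=spec.spacing, modality=modality
        )
    study = MultiModalStudy(channels=channels)
    labels = LabelMap(codes=codes, spacing=spec.spacing)
    return study, labels


DEFAULT_JITTER = {"radii": 1.0, "center": 2.0, "intensity": 5.0}


def generate_cohort(
    n: int,
    spec_template: Optional[PhantomSpec] = None,
    jitter: Optional[dict] = None,
    seed: int = 0,
) -> list[tuple[MultiModalStudy, LabelMap, PhantomSpec]]:
    """Sample ``n`` phantoms around a template spec.

    ``jitter`` maps field -> half-width: radii (mm, each radius independently),
    center (voxels, each axis), intensity (units, every non-background class
    mean jointly per class x modality). Draws are uniform in +/- half-width.
    Zero half-widths reproduce the template exactly. Sampled specs that would
    violate the nesting/containment invariants raise ``ValueError``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if spec_template is None:
        spec_template = PhantomSpec()
    jit = dict(DEFAULT_JITTER)
    if jitter is not None:
        jit.update(jitter)
    degenerate = all(v == 0 for v in jit.values())
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        radii = tuple(
            r + rng.uniform(-jit["radii"], jit["radii"])
            for r in spec_template.radii
        )
        center = tuple(
            c + rng.uniform(-jit["center"], jit["center"])
            for c in spec_template.tumor_center
        )
        means = {}
        for t in TISSUES:
            if t == "background":
                means[t] = spec_template.means[t]
            else:
                means[t] = tuple(
                    m + rng.uniform(-jit["intensity"], jit["intensity"])
                    for m in spec_template.means[t]
                )
        # zero-width jitter reproduces the template exactly (same noise seed)
        sub_seed = spec_template.seed if degenerate else int(rng.integers(0, 2 ** 31 - 1))
        try:
            spec = dataclasses.replace(
                spec_template,
                radii=radii,
                tumor_center=center,
                means=means,
                seed=sub_seed,
            )
        except ValueError as exc:
            raise ValueError(
                f"jitter ranges produced an invalid phantom spec (sample {i}): {exc}"
            ) from exc
        study, labels = generate_phantom(spec)
        out.append((study, labels, spec))
    return out
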