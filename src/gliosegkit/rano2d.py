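"""Automated bidimensional (WHO/RANO) tumor measurement.

For each contrast-enhancing lesion (3D 26-connected component of the
measured compartment), every axial (fixed-z) slice is scanned: d1 is the
largest Euclidean distance (mm) between in-plane voxel centers of the slice
mask, and d2 the largest such distance whose segment direction lies within a
perpendicularity tolerance (default +/- 5 degrees) of perpendicular to the
d1 segment. The reported slice is the one maximizing d1 (ties -> lowest z).
The per-lesion product d1*d2 is summed over measurable lesions to give the
sum of products of diameters (SPD, mm^2). Lesions whose maximal axial
diameter falls below a measurability threshold (default 10 mm; 0 disables)
are excluded from the SPD.

Diameters are measured between voxel centers, so a single-voxel slice has
d1 = 0.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats

from .volumes_io import LabelMap

DEFAULT_MIN_DIAMETER_MM = 10.0
DEFAULT_PERP_TOL_DEG = 5.0

#: compartments measurable in 2D: RANO reads the contrast-enhancing lesion;
#: a joint necrosis+enhancing mode is provided as well.
MEASURE_COMPARTMENTS = {
    "enhancing": (4,),
    "enhancing+necrosis": (1, 4),
}

# pairwise search switches from all mask pixels to boundary pixels above this
# count (max-distance endpoints are boundary extreme points)
_EXACT_PAIR_LIMIT = 1500


@dataclasses.dataclass
class DiameterMeasurement:
    lesion_id: int
    slice_z: int
    d1_mm: float
    d2_mm: float
    product_mm2: float
    endpoints: tuple  # ((p1a, p1b), (p2a, p2b)) in-plane mm, or None pairs
    measurable: bool = True

    def __post_init__(self) -> None:
        if not (self.d1_mm >= self.d2_mm >= 0):
            raise ValueError("diameters must satisfy d1 >= d2 >= 0")
        if not math.isclose(self.product_mm2, self.d1_mm * self.d2_mm, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("product must equal d1 * d2")


def find_lesions(
    enhancing_mask: np.ndarray,
    min_diameter_mm: float = DEFAULT_MIN_DIAMETER_MM,
    spacing=(1.0, 1.0, 1.0),
) -> list[tuple[np.ndarray, bool]]:
    """3D 26-connected components, largest first.

    Returns ``(component_mask, measurable)`` pairs; a component is measurable
    when its maximal axial in-plane diameter is >= ``min_diameter_mm``
    (``min_diameter_mm = 0`` keeps everything).
    """
    mask = np.asarray(enhancing_mask, dtype=bool)
    if not mask.any():
        return []
    lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    order = np.argsort(-sizes, kind="stable") + 1
    out = []
    for comp_id in order:
        comp = lab == comp_id
        if min_diameter_mm > 0:
            meas = measure_lesion(comp, spacing, lesion_id=-1)
            ok = meas.d1_mm >= min_diameter_mm
        else:
            ok = True
        out.append((comp, ok))
    return out


def _slice_points_mm(slice_mask: np.ndarray, spacing2) -> np.ndarray:
    pts = np.argwhere(slice_mask).astype(np.float64)
    pts[:, 0] *= spacing2[0]
    pts[:, 1] *= spacing2[1]
    return pts


def _boundary_reduce(slice_mask: np.ndarray) -> np.ndarray:
    er = ndimage.binary_erosion(slice_mask, structure=np.ones((3, 3), dtype=bool))
    return slice_mask & ~er


def max_perpendicular_diameters(
    slice_mask: np.ndarray,
    spacing2=(1.0, 1.0),
    perp_tol_deg: float = DEFAULT_PERP_TOL_DEG,
) -> tuple[float, float, tuple]:
    """(d1, d2, endpoints) for one axial slice mask by pairwise search.

    d1 is the maximum pairwise distance; among equal maxima the pair with
    lexicographically smallest point indices wins. d2 is the maximum distance
    over pairs whose direction is within ``perp_tol_deg`` of perpendicular to
    the d1 segment; 0 with ``None`` endpoints when no pair qualifies.
    """
    if np.count_nonzero(slice_mask) > _EXACT_PAIR_LIMIT:
        slice_mask = _boundary_reduce(slice_mask)
    pts = _slice_points_mm(slice_mask, spacing2)
    n = pts.shape[0]
    if n < 2:
        p = tuple(pts[0]) if n == 1 else None
        return 0.0, 0.0, ((p, p), (None, None))
    diff = pts[None, :, :] - pts[:, None, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    iu, ju = np.triu_indices(n, k=1)
    d = dist[iu, ju]
    k = int(np.argmax(d))  # first maximum in row-major upper-triangle order
    # pts from argwhere are lexicographically sorted, so the first maximal
    # (i, j) pair is the lexicographically smallest one
    d1 = float(d[k])
    i1, j1 = int(iu[k]), int(ju[k])
    u = pts[j1] - pts[i1]
    u /= np.linalg.norm(u)
    # |cos(angle to d1)| <= sin(tol)  <=>  within tol of perpendicular
    cos_lim = math.sin(math.radians(perp_tol_deg))
    proj = np.abs(diff @ u)
    with np.errstate(invalid="ignore", divide="ignore"):
        ok = (dist > 0) & (proj <= cos_lim * dist + 1e-12)
    d2_cand = np.where(ok[iu, ju], d, -1.0)
    k2 = int(np.argmax(d2_cand))
    if d2_cand[k2] <= 0:
        d2 = 0.0
        ep2 = (None, None)
    else:
        d2 = float(d2_cand[k2])
        ep2 = (tuple(pts[int(iu[k2])]), tuple(pts[int(ju[k2])]))
    return d1, d2, ((tuple(pts[i1]), tuple(pts[j1])), ep2)


def measure_lesion(
    component_mask: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    lesion_id: int = 0,
    perp_tol_deg: float = DEFAULT_PERP_TOL_DEG,
    slice_rule: str = "max-d1",
) -> DiameterMeasurement:
    """Largest perpendicular in-plane diameter pair of one lesion.

    ``slice_rule`` selects the reported axial slice: ``"max-d1"`` (default;
    ties -> lowest z) or ``"max-product"``.
    """
    mask = np.asarray(component_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty lesion component")
    if slice_rule not in ("max-d1", "max-product"):
        raise ValueError(f"unknown slice rule {slice_rule!r}")
    spacing2 = (float(spacing[0]), float(spacing[1]))
    best = None
    zs = np.nonzero(mask.any(axis=(0, 1)))[0]
    for z in zs:
        d1, d2, eps_ = max_perpendicular_diameters(
            mask[:, :, z], spacing2, perp_tol_deg
        )
        key = d1 if slice_rule == "max-d1" else d1 * d2
        if best is None or key > best[0] + 1e-12:
            best = (key, int(z), d1, d2, eps_)
    _, z, d1, d2, endpoints = best
    return DiameterMeasurement(
        lesion_id=lesion_id, slice_z=z, d1_mm=d1, d2_mm=d2,
        product_mm2=d1 * d2, endpoints=endpoints,
    )


def measure_labelmap(
    labels: LabelMap,
    compartment: str = "enhancing",
    min_diameter_mm: float = DEFAULT_MIN_DIAMETER_MM,
    perp_tol_deg: float = DEFAULT_PERP_TOL_DEG,
    slice_rule: str = "max-d1",
) -> list[DiameterMeasurement]:
    """Per-lesion measurements for the chosen compartment of a label map."""
    try:
        codes = MEASURE_COMPARTMENTS[compartment]
    except KeyError:
        raise KeyError(
            f"unknown compartment {compartment!r}; expected one of "
            f"{sorted(MEASURE_COMPARTMENTS)}"
        ) from None
    mask = np.isin(labels.codes, codes)
    out = []
    for i, (comp, ok) in enumerate(
        find_lesions(mask, min_diameter_mm, labels.spacing)
    ):
        meas = measure_lesion(
            comp, labels.spacing, lesion_id=i,
            perp_tol_deg=perp_tol_deg, slice_rule=slice_rule,
        )
        meas.measurable = ok
        out.append(meas)
    return out


def spd(measurements: Sequence[DiameterMeasurement]) -> float:
    """Sum of products of diameters over measurable lesions, mm^2."""
    return float(
        sum(m.product_mm2 for m in measurements if m.measurable)
    )


def compare_spd(
    auto: Sequence[float],
    rater1: Sequence[float],
    rater2: Sequence[float],
) -> dict:
    """Pairwise SPD agreement plus a Friedman test across the three sources.

    For each pair: mean absolute difference, its SD, and the 95% CI
    mean +/- t(0.975, n-1) * SD / sqrt(n).
    """
    a, r1, r2 = (np.asarray(v, dtype=float) for v in (auto, rater1, rater2))
    if not (len(a) == len(r1) == len(r2)):
        raise ValueError("SPD series must have equal length")
    n = len(a)
    out: dict = {"n": n, "pairs": {}}
    for name, x, y in (
        ("auto_vs_rater1", a, r1),
        ("auto_vs_rater2", a, r2),
        ("rater1_vs_rater2", r1, r2),
    ):
        d = np.abs(x - y)
        mean = float(d.mean())
        sd = float(d.std(ddof=1)) if n > 1 else 0.0
        if n > 1 and sd > 0:
            half = float(stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n))
        else:
            half = 0.0
        out["pairs"][name] = {
            "mean_abs_diff": mean, "sd": sd,
            "ci95": (mean - half, mean + half),
        }
    from .evaluate import friedman  # local import to avoid cycle

    out["friedman"] = friedman([a, r1, r2])
    return out
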