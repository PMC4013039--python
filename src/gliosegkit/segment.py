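"""Decision-forest voxel classification with CRF regularization.

The segmentation model assigns each brain voxel one of five tissue codes
(unaffected, necrosis, edema, non-enhancing tumor, enhancing tumor) in two
stages. First a decision forest, trained on per-voxel feature vectors from
manually or synthetically labeled studies, produces class posteriors
p_v(c) as the mean of tree votes. Second, the labeling is regularized as a
conditional random field with the contrast-sensitive Potts energy

    E(l) = sum_v -log(p_v(l_v) + eps)
         + lambda * sum_{(u,v) in N} exp(-||I_u - I_v||^2 / (2 sigma^2)) * [l_u != l_v]

where ||.|| is the Euclidean distance across the four normalized channels
and N a 6- or 26-neighborhood inside the brain mask. The energy is minimized
by iterated conditional modes (ICM) over a fixed raster sweep order, starting
from the per-voxel posterior argmax, with ties broken toward the lowest class
code; each sweep is guaranteed not to increase the energy, and iteration
stops at a fixpoint or after ``max_sweeps``.

`GlioblastomaSegmenter` packages preprocessing + features + forest + CRF as
a scikit-learn style estimator (fit on a cohort of studies with reference
label maps, predict on new studies).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureConfig, FeatureMatrix, extract_features
from .preprocess import preprocess_study
from .volumes_io import ALL_CLASSES, LabelMap, MultiModalStudy

EPS_LOG = 1e-9

#: compound regions derived from the label taxonomy
COMPOUND_REGIONS: dict[str, frozenset[int]] = {
    "CETV": frozenset({4}),
    "TV": frozenset({1, 3, 4}),
    "TVPLUS": frozenset({1, 2, 3, 4}),
}


@dataclasses.dataclass(frozen=True)
class CompoundRegion:
    name: str
    labels: frozenset[int]

    @staticmethod
    def get(name: str) -> "CompoundRegion":
        try:
            return CompoundRegion(name=name, labels=COMPOUND_REGIONS[name])
        except KeyError:
            raise KeyError(
                f"unknown compound region {name!r}; expected one of "
                f"{sorted(COMPOUND_REGIONS)}"
            ) from None


@dataclasses.dataclass
class CrfParams:
    lam: float = 1.0          # pairwise weight (>= 0)
    sigma: float = 1.0        # intensity-contrast scale (> 0), in z-score units
    neighborhood: int = 6     # 6 or 26
    max_sweeps: int = 10
    tol: int = 0              # stop when a sweep changes <= tol labels

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.neighborhood not in (6, 26):
            raise ValueError("neighborhood must be 6 or 26")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")


@dataclasses.dataclass
class ForestModel:
    """Fitted decision forest plus the feature-name registry it was trained on."""

    estimator: RandomForestClassifier
    feature_names: tuple[str, ...]
    classes: tuple[int, ...]
    hyperparams: dict
    seed: int
    training_accuracy: float  # out-of-bag estimate


@dataclasses.dataclass
class SegmentationResult:
    labels: LabelMap
    posteriors: np.ndarray  # (X, Y, Z, 5)
    energy: float
    energies: list[float]   # energy before ICM and after each sweep
    sweeps: int


DEFAULT_FOREST_PARAMS = dict(
    n_trees=50, max_depth=20, min_leaf=5, features_per_split="sqrt"
)


def train_forest(
    features: FeatureMatrix,
    labels: np.ndarray,
    hyperparams: Optional[dict] = None,
    seed: int = 0,
) -> ForestModel:
    """Fit the voxel-wise decision forest; deterministic given the seed."""
    labels = np.asarray(labels)
    if labels.shape[0] != features.values.shape[0]:
        raise ValueError(
            f"feature/label length mismatch: {features.values.shape[0]} rows "
            f"vs {labels.shape[0]} labels"
        )
    present = np.unique(labels)
    if present.size < 2:
        raise ValueError("training data contains a single class")
    hp = dict(DEFAULT_FOREST_PARAMS)
    if hyperparams:
        hp.update(hyperparams)
    rf = RandomForestClassifier(
        n_estimators=int(hp["n_trees"]),
        max_depth=hp["max_depth"],
        min_samples_leaf=int(hp["min_leaf"]),
        max_features=hp["features_per_split"],
        random_state=int(seed),
        oob_score=True,
        n_jobs=1,
    )
    rf.fit(features.values, labels)
    return ForestModel(
        estimator=rf,
        feature_names=tuple(features.names),
        classes=tuple(int(c) for c in rf.classes_),
        hyperparams=hp,
        seed=int(seed),
        training_accuracy=float(rf.oob_score_),
    )


def predict_posteriors(model: ForestModel, features: FeatureMatrix) -> np.ndarray:
    """Per-row class posteriors over the full 5-code taxonomy (rows sum to 1)."""
    if tuple(features.names) != model.feature_names:
        raise ValueError(
            "feature-name registry mismatch between model and feature matrix"
        )
    proba = model.estimator.predict_proba(features.values)
    out = np.zeros((proba.shape[0], len(ALL_CLASSES)), dtype=np.float64)
    for j, c in enumerate(model.classes):
        out[:, c] = proba[:, j]
    return out


def _neighbor_offsets(neighborhood: int) -> np.ndarray:
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                if neighborhood == 6 and abs(dx) + abs(dy) + abs(dz) != 1:
                    continue
                offs.append((dx, dy, dz))
    return np.array(offs, dtype=np.int64)


@njit(cache=True)
def _icm_sweep(labels, unary, intensity, mask, offsets, lam, inv2sig2):
    """One raster-order ICM sweep in place; returns the number of changes."""
    X, Y, Z, C = unary.shape
    K = offsets.shape[0]
    changed = 0
    for x in range(X):
        for y in range(Y):
            for z in range(Z):
                if not mask[x, y, z]:
                    continue
                best_c = 0
                best_e = 1e300
                for c in range(C):
                    e = unary[x, y, z, c]
                    if lam > 0.0:
                        for k in range(K):
                            nx = x + offsets[k, 0]
                            ny = y + offsets[k, 1]
                            nz = z + offsets[k, 2]
                            if (
                                nx < 0 or nx >= X or ny < 0 or ny >= Y
                                or nz < 0 or nz >= Z or not mask[nx, ny, nz]
                            ):
                                continue
                            if labels[nx, ny, nz] != c:
                                d2 = 0.0
                                for ch in range(intensity.shape[3]):
                                    d = (
                                        intensity[x, y, z, ch]
                                        - intensity[nx, ny, nz, ch]
                                    )
                                    d2 += d * d
                                e += lam * np.exp(-d2 * inv2sig2)
                    if e < best_e:  # strict: ties keep the lowest class code
                        best_e = e
                        best_c = c
                if labels[x, y, z] != best_c:
                    labels[x, y, z] = best_c
                    changed += 1
    return changed


def crf_energy(
    label_grid: np.ndarray,
    unary: np.ndarray,
    intensity: np.ndarray,
    mask: np.ndarray,
    params: CrfParams,
) -> float:
    """Total CRF energy of a labeling (each neighbor pair counted once)."""
    mask = np.asarray(mask, dtype=bool)
    xs, ys, zs = np.nonzero(mask)
    e = float(unary[xs, ys, zs, label_grid[xs, ys, zs]].sum())
    if params.lam > 0:
        inv2sig2 = 1.0 / (2.0 * params.sigma ** 2)
        offsets = _neighbor_offsets(params.neighborhood)
        # each unordered pair once: keep lexicographically positive offsets
        half = offsets[
            (offsets[:, 0] > 0)
            | ((offsets[:, 0] == 0) & (offsets[:, 1] > 0))
            | ((offsets[:, 0] == 0) & (offsets[:, 1] == 0) & (offsets[:, 2] > 0))
        ]
        X, Y, Z = mask.shape
        for dx, dy, dz in half:
            sl_a = (
                slice(max(0, -dx), min(X, X - dx)),
                slice(max(0, -dy), min(Y, Y - dy)),
                slice(max(0, -dz), min(Z, Z - dz)),
            )
            sl_b = (
                slice(max(0, dx), min(X, X + dx)),
                slice(max(0, dy), min(Y, Y + dy)),
                slice(max(0, dz), min(Z, Z + dz)),
            )
            both = mask[sl_a] & mask[sl_b]
            diff = label_grid[sl_a] != label_grid[sl_b]
            active = both & diff
            if not active.any():
                continue
            d2 = ((intensity[sl_a] - intensity[sl_b]) ** 2).sum(axis=-1)
            e += params.lam * float(np.exp(-d2[active] * inv2sig2).sum())
    return e


def crf_regularize(
    posteriors: np.ndarray,
    study: MultiModalStudy,
    mask: np.ndarray,
    params: Optional[CrfParams] = None,
) -> SegmentationResult:
    """ICM minimization of the contrast-sensitive Potts energy.

    ``posteriors`` is either an ``(n_mask_voxels, 5)`` matrix in the C-order
    of ``np.argwhere(mask)`` rows, or a full ``(X, Y, Z, 5)`` grid.
    """
    if params is None:
        params = CrfParams()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    shape = mask.shape
    if posteriors.ndim == 2:
        grid = np.zeros(shape + (posteriors.shape[1],), dtype=np.float64)
        grid[mask] = posteriors
    else:
        grid = np.asarray(posteriors, dtype=np.float64)
    n_classes = grid.shape[-1]
    unary = -np.log(grid + EPS_LOG)
    intensity = study.stack().astype(np.float64)
    # initialization: per-voxel argmax (np.argmax ties -> lowest class code)
    labels = np.zeros(shape, dtype=np.int64)
    labels[mask] = np.argmax(grid[mask], axis=1)

    offsets = _neighbor_offsets(params.neighborhood)
    inv2sig2 = 1.0 / (2.0 * params.sigma ** 2)
    energies = [crf_energy(labels, unary, intensity, mask, params)]
    sweeps = 0
    if params.lam > 0:
        for _ in range(params.max_sweeps):
            changed = _icm_sweep(
                labels, unary, intensity, mask, offsets,
                float(params.lam), float(inv2sig2),
            )
            sweeps += 1
            energies.append(crf_energy(labels, unary, intensity, mask, params))
            if changed <= params.tol:
                break
    out = np.zeros(shape, dtype=np.uint8)
    out[mask] = labels[mask].astype(np.uint8)
    return SegmentationResult(
        labels=LabelMap(codes=out, spacing=study.spacing),
        posteriors=grid if n_classes == len(ALL_CLASSES) else grid,
        energy=energies[-1],
        energies=energies,
        sweeps=sweeps,
    )


def compound_mask(labels: LabelMap, region) -> np.ndarray:
    """Binary mask of a compound region (CETV / TV / TVPLUS or a label set)."""
    if isinstance(region, str):
        region = CompoundRegion.get(region)
    return np.isin(labels.codes, list(region.labels))


def volume_ml(mask: np.ndarray, spacing) -> float:
    """Voxel count times voxel volume, in milliliters."""
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    voxel_mm3 = spacing[0] * spacing[1] * spacing[2]
    return float(np.count_nonzero(mask)) * voxel_mm3 / 1000.0


def _subsample_per_class(
    labels: np.ndarray, cap: int, rng: np.random.Generator
) -> np.ndarray:
    keep = []
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        if idx.size > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


class GlioblastomaSegmenter(BaseEstimator):
    """Multi-modal tumor segmentation pipeline as a scikit-learn estimator.

    ``fit`` takes a cohort of :class:`MultiModalStudy` objects with reference
    :class:`LabelMap` annotations, runs preprocessing (optional rigid
    co-registration, skull stripping, z-score normalization), extracts
    per-voxel features, subsamples training voxels per class, and fits the
    decision forest. ``predict`` segments a new study and returns its
    :class:`LabelMap`; ``segment_study`` additionally returns posteriors and
    the CRF energy trace.

    Parameters
    ----------
    n_trees, max_depth, min_leaf, features_per_split
        Decision-forest hyperparameters.
    crf_lambda, crf_sigma, neighborhood, max_sweeps
        CRF regularization parameters (``crf_lambda=0`` disables the CRF).
    per_class_cap
        Maximum training voxels sampled per class per subject.
    feature_config
        :class:`FeatureConfig`; None uses the defaults.
    register, strip
        Whether preprocessing runs rigid co-registration / skull stripping.
    random_state
        Seed for voxel subsampling and forest training.
    """

    def __init__(
        self,
        n_trees: int = 50,
        max_depth: int = 20,
        min_leaf: int = 5,
        features_per_split: str = "sqrt",
        crf_lambda: float = 1.0,
        crf_sigma: float = 1.0,
        neighborhood: int = 6,
        max_sweeps: int = 10,
        per_class_cap: int = 2000,
        feature_config: Optional[FeatureConfig] = None,
        register: bool = False,
        strip: bool = True,
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.features_per_split = features_per_split
        self.crf_lambda = crf_lambda
        self.crf_sigma = crf_sigma
        self.neighborhood = neighborhood
        self.max_sweeps = max_sweeps
        self.per_class_cap = per_class_cap
        self.feature_config = feature_config
        self.register = register
        self.strip = strip
        self.random_state = random_state

    def _config(self) -> FeatureConfig:
        return self.feature_config if self.feature_config is not None else FeatureConfig()

    def _prepare(self, study: MultiModalStudy) -> MultiModalStudy:
        return preprocess_study(study, register=self.register, strip=self.strip)

    def fit(
        self,
        X: Sequence[MultiModalStudy],
        y: Sequence[LabelMap],
    ) -> "GlioblastomaSegmenter":
        if len(X) != len(y):
            raise ValueError("studies and label maps must pair up")
        config = self._config()
        mats, labs = [], []
        for i, (study, ref) in enumerate(zip(X, y)):
            prep = self._prepare(study)
            mask = prep.brain_mask
            fm = extract_features(prep, mask, config)
            voxel_labels = ref.codes[mask]
            rng = np.random.default_rng((int(self.random_state) * 100003 + i) % 2 ** 31)
            keep = _subsample_per_class(voxel_labels, int(self.per_class_cap), rng)
            mats.append(fm.values[keep])
            labs.append(voxel_labels[keep])
        values = np.concatenate(mats, axis=0)
        labels = np.concatenate(labs, axis=0)
        fm_all = FeatureMatrix(
            values=values,
            names=fm.names,
            voxel_index=np.zeros((values.shape[0], 3), dtype=int),
            registry=fm.registry,
        )
        self.forest_ = train_forest(
            fm_all, labels,
            hyperparams=dict(
                n_trees=self.n_trees, max_depth=self.max_depth,
                min_leaf=self.min_leaf, features_per_split=self.features_per_split,
            ),
            seed=int(self.random_state),
        )
        self.feature_names_ = self.forest_.feature_names
        self.training_accuracy_ = self.forest_.training_accuracy
        return self

    def segment_study(self, study: MultiModalStudy) -> SegmentationResult:
        if not hasattr(self, "forest_"):
            raise RuntimeError("estimator is not fitted")
        prep = self._prepare(study)
        mask = prep.brain_mask
        fm = extract_features(prep, mask, self._config())
        post = predict_posteriors(self.forest_, fm)
        params = CrfParams(
            lam=self.crf_lambda, sigma=self.crf_sigma,
            neighborhood=self.neighborhood, max_sweeps=self.max_sweeps,
        )
        return crf_regularize(post, prep, mask, params)

    def predict(self, X) -> LabelMap | list[LabelMap]:
        if isinstance(X, MultiModalStudy):
            return self.segment_study(X).labels
        return [self.segment_study(s).labels for s in X]
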