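import itertools

import numpy as np
import pytest

import gliosegkit as gk
from gliosegkit.features import FeatureMatrix
from gliosegkit.segment import (
    COMPOUND_REGIONS,
    CrfParams,
    crf_energy,
    crf_regularize,
    predict_posteriors,
    train_forest,
)
from gliosegkit.volumes_io import MODALITIES


def _feature_matrix(values):
    values = np.asarray(values, dtype=float)
    names = tuple(f"f{i}" for i in range(values.shape[1]))
    return FeatureMatrix(
        values=values, names=names,
        voxel_index=np.zeros((values.shape[0], 3), dtype=int),
        registry={n: ("intensity", None, None) for n in names},
    )


def _gaussian_clouds(seed=0, n=1000, d=5, delta=6.0):
    rng = np.random.default_rng(seed)
    x0 = rng.normal(size=(n // 2, d))
    x1 = rng.normal(size=(n // 2, d)) + delta
    X = np.vstack([x0, x1])
    y = np.repeat([0, 1], n // 2)
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestForest:
    def test_separated_clusters_high_heldout_accuracy(self):
        X, y = _gaussian_clouds(seed=0)
        Xt, yt = X[:800], y[:800]
        Xh, yh = X[800:], y[800:]
        model = train_forest(_feature_matrix(Xt), yt, seed=1)
        post = predict_posteriors(model, _feature_matrix(Xh))
        acc = np.mean(np.argmax(post, axis=1) == yh)
        assert acc >= 0.99
        assert model.training_accuracy >= 0.99  # OOB estimate

    def test_deterministic_given_seed(self):
        X, y = _gaussian_clouds(seed=2)
        probe = _feature_matrix(X[:50])
        m1 = train_forest(_feature_matrix(X), y, seed=7)
        m2 = train_forest(_feature_matrix(X), y, seed=7)
        np.testing.assert_array_equal(
            predict_posteriors(m1, probe), predict_posteriors(m2, probe)
        )

    def test_single_class_rejected(self):
        X, _ = _gaussian_clouds()
        with pytest.raises(ValueError, match="single class"):
            train_forest(_feature_matrix(X), np.zeros(len(X), dtype=int))

    def test_length_mismatch_rejected(self):
        X, y = _gaussian_clouds()
        with pytest.raises(ValueError, match="mismatch"):
            train_forest(_feature_matrix(X), y[:-3])

    def test_posteriors_normalized_and_pure(self):
        X, y = _gaussian_clouds(seed=3)
        model = train_forest(_feature_matrix(X), y, seed=0)
        dup = np.vstack([X[:1], X[:1], X[1:10]])
        post = predict_posteriors(model, _feature_matrix(dup))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(post[0], post[1])

    def test_registry_mismatch_rejected(self):
        X, y = _gaussian_clouds(seed=4)
        model = train_forest(_feature_matrix(X), y, seed=0)
        fm = _feature_matrix(X[:5])
        fm = FeatureMatrix(
            values=fm.values, names=tuple(f"g{i}" for i in range(X.shape[1])),
            voxel_index=fm.voxel_index,
            registry={f"g{i}": ("intensity", None, None) for i in range(X.shape[1])},
        )
        with pytest.raises(ValueError, match="registry"):
            predict_posteriors(model, fm)


def _tiny_problem(seed, shape=(2, 2, 1), n_classes=2):
    rng = np.random.default_rng(seed)
    mask = np.ones(shape, dtype=bool)
    post = rng.dirichlet(np.ones(n_classes), size=int(mask.sum()))
    intensity = rng.normal(size=shape + (4,))
    study = gk.MultiModalStudy(channels={
        m: gk.ImageVolume(voxels=intensity[..., i], spacing=(1, 1, 1), modality=m)
        for i, m in enumerate(MODALITIES)
    })
    # channels are stored float32; hand the oracle the same precision
    return post, study, mask, study.stack().astype(np.float64)


def _oracle_energy(labels_flat, post, intensity, shape, params):
    """Independent brute-force energy: explicit loops over voxels and pairs."""
    import math

    idx = list(np.ndindex(shape))
    unary = 0.0
    for r, v in enumerate(idx):
        unary += -math.log(post[r][labels_flat[r]] + 1e-9)
    pair = 0.0
    for r, u in enumerate(idx):
        for s in range(r + 1, len(idx)):
            v = idx[s]
            if max(abs(u[0] - v[0]), abs(u[1] - v[1]), abs(u[2] - v[2])) != 1:
                continue
            if params.neighborhood == 6 and (
                abs(u[0] - v[0]) + abs(u[1] - v[1]) + abs(u[2] - v[2]) != 1
            ):
                continue
            if labels_flat[r] != labels_flat[s]:
                d2 = sum(
                    (intensity[u][c] - intensity[v][c]) ** 2 for c in range(4)
                )
                pair += params.lam * math.exp(-d2 / (2 * params.sigma ** 2))
    return unary + pair


class TestCrf:
    def test_lambda_zero_reduces_to_argmax(self):
        post, study, mask, _ = _tiny_problem(0, shape=(4, 4, 2), n_classes=5)
        res = crf_regularize(post, study, mask, CrfParams(lam=0.0))
        np.testing.assert_array_equal(
            res.labels.codes[mask], np.argmax(post, axis=1)
        )
        assert res.sweeps == 0

    def test_energy_monotone_nonincreasing(self, preprocessed_phantom):
        prep, labels = preprocessed_phantom
        rng = np.random.default_rng(0)
        mask = prep.brain_mask
        post = rng.dirichlet(np.ones(5) * 0.5, size=int(mask.sum()))
        res = crf_regularize(post, prep, mask, CrfParams(lam=1.0, max_sweeps=4))
        diffs = np.diff(res.energies)
        assert np.all(diffs <= 1e-9)
        # strictly decreasing until the fixpoint
        assert all(d < 0 for d in diffs[:-1])

    @pytest.mark.parametrize("neighborhood", [6, 26])
    def test_icm_between_argmax_and_global_minimum(self, neighborhood):
        """On all 2x2x1 two-class instances the ICM energy lands between the
        enumerated global minimum and the initial argmax energy."""
        params = CrfParams(lam=1.5, sigma=1.0, neighborhood=neighborhood)
        for seed in range(20):
            post, study, mask, intensity = _tiny_problem(seed)
            res = crf_regularize(post, study, mask, params)
            energies = [
                _oracle_energy(lab, post, intensity, (2, 2, 1), params)
                for lab in itertools.product(range(2), repeat=4)
            ]
            e_min = min(energies)
            e_init = _oracle_energy(
                tuple(np.argmax(post, axis=1)), post, intensity, (2, 2, 1), params
            )
            assert e_min - 1e-9 <= res.energy <= e_init + 1e-9
            # reported energies agree with the independent oracle
            final_oracle = _oracle_energy(
                tuple(res.labels.codes[mask]), post, intensity, (2, 2, 1), params
            )
            assert res.energy == pytest.approx(final_oracle, abs=1e-9)

    def test_strong_smoothing_reduces_boundary_faces(self, preprocessed_phantom):
        prep, _ = preprocessed_phantom
        rng = np.random.default_rng(1)
        mask = prep.brain_mask
        post = rng.dirichlet(np.ones(5), size=int(mask.sum()))

        def boundary_faces(codes):
            total = 0
            for ax in range(3):
                a = np.take(codes, range(codes.shape[ax] - 1), axis=ax)
                b = np.take(codes, range(1, codes.shape[ax]), axis=ax)
                ma = np.take(mask, range(mask.shape[ax] - 1), axis=ax)
                mb = np.take(mask, range(1, mask.shape[ax]), axis=ax)
                total += int(((a != b) & ma & mb).sum())
            return total

        res0 = crf_regularize(post, prep, mask, CrfParams(lam=0.0))
        res_inf = crf_regularize(
            post, prep, mask, CrfParams(lam=1000.0, sigma=10.0, max_sweeps=8)
        )
        assert boundary_faces(res_inf.labels.codes) <= boundary_faces(res0.labels.codes)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError, match="lambda"):
            CrfParams(lam=-1.0)


class TestCompoundRegions:
    def test_label_sets(self):
        assert COMPOUND_REGIONS["CETV"] == {4}
        assert COMPOUND_REGIONS["TV"] == {1, 3, 4}
        assert COMPOUND_REGIONS["TVPLUS"] == {1, 2, 3, 4}

    def test_all_edema_map(self):
        lm = gk.LabelMap(codes=np.full((4, 4, 4), 2), spacing=(1, 1, 1))
        assert gk.compound_mask(lm, "TVPLUS").all()
        assert not gk.compound_mask(lm, "TV").any()
        assert not gk.compound_mask(lm, "CETV").any()

    def test_nesting_on_random_maps(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            lm = gk.LabelMap(
                codes=rng.integers(0, 5, (8, 8, 8)), spacing=(1, 1, 1)
            )
            ce = gk.compound_mask(lm, "CETV")
            tv = gk.compound_mask(lm, "TV")
            tvp = gk.compound_mask(lm, "TVPLUS")
            assert np.all(ce <= tv) and np.all(tv <= tvp)

    def test_phantom_tv_is_core_rim_margin_union(self, clean_phantom):
        spec, _, labels = clean_phantom
        from gliosegkit.phantom import _tumor_distance_mm, brain_mask_analytic

        r = _tumor_distance_mm(spec)
        analytic_tv = brain_mask_analytic(spec) & (r <= spec.radii[2])
        np.testing.assert_array_equal(
            gk.compound_mask(labels, "TV"), analytic_tv
        )


class TestVolumeMl:
    @pytest.mark.parametrize(
        "spacing,expected", [((1, 1, 1), 1.0), ((1, 1, 3), 3.0)]
    )
    def test_unit_conversion(self, spacing, expected):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask.ravel()[:1000] = True
        assert gk.volume_ml(mask, spacing) == pytest.approx(expected)

    def test_empty_mask(self):
        assert gk.volume_ml(np.zeros((5, 5, 5), dtype=bool), (1, 1, 1)) == 0.0
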