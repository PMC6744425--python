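import numpy as np
import pytest
from scipy import stats
from sklearn.covariance import ledoit_wolf_shrinkage as sk_lw
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from ndba.lda import (
    cross_decode,
    crossval_accuracy,
    crossval_distance_matrix,
    crossval_distances,
    dataset_samples,
    fit_lda,
    kfold_split,
    leave_one_run_out,
    ledoit_wolf_shrinkage,
    signed_distance,
)
from ndba.synth import SyntheticConfig, generate_patterns


def _two_clouds(rng, n=40, p=5, sep=8.0, sd=1.0):
    X0 = rng.normal(0, sd, size=(n // 2, p))
    X1 = rng.normal(0, sd, size=(n // 2, p)) + sep / np.sqrt(p)
    X = np.vstack([X0, X1])
    y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    return X, y


def test_unregularized_direction_matches_closed_form(rng):
    """At shrinkage 0 the discriminant equals the textbook S^-1 (mu1-mu0)."""
    for _ in range(20):
        X = rng.normal(size=(10, 4))
        y = np.array([0] * 5 + [1] * 5)
        model = fit_lda(X, y, shrinkage=0.0)
        mu0, mu1 = X[:5].mean(0), X[5:].mean(0)
        pooled = (np.cov(X[:5], rowvar=False) + np.cov(X[5:], rowvar=False)) * 4 / 8
        w_ref = np.linalg.inv(pooled) @ (mu1 - mu0)
        cos = w_ref @ model.weights / (
            np.linalg.norm(w_ref) * np.linalg.norm(model.weights)
        )
        assert cos > 1 - 1e-10
        # boundary passes through the class-mean midpoint
        d_mid = signed_distance(model, (mu0 + mu1)[None, :] / 2)
        assert abs(d_mid[0]) < 1e-10


def test_separable_and_null_cases(rng):
    X, y = _two_clouds(rng)
    model = fit_lda(X, y)
    assert (model.predict(X) == y).all()
    # identical class means: held-out accuracy near chance
    Xn = rng.normal(size=(96, 20))
    yn = np.array(["a", "b"] * 48)
    folds = kfold_split(yn, n_folds=4, seed=0)
    acc, _ = crossval_accuracy(Xn, yn, folds)
    assert abs(acc - 0.5) < 0.17


def test_signed_distance_geometry(rng):
    X, y = _two_clouds(rng)
    model = fit_lda(X, y)
    pts = rng.normal(size=(5, X.shape[1]))
    d = signed_distance(model, pts)
    # orthogonal projection onto the hyperplane {x: w.x + b = 0}
    w, b = model.weights, model.bias
    proj = pts - np.outer((pts @ w + b) / (w @ w), w)
    np.testing.assert_allclose(proj @ w + b, 0, atol=1e-9)
    np.testing.assert_allclose(np.abs(d), np.linalg.norm(pts - proj, axis=1), atol=1e-9)
    # invariance to positive rescaling of (w, b)
    model.weights, model.bias = 3.7 * w, 3.7 * b
    np.testing.assert_allclose(signed_distance(model, pts), d, atol=1e-12)


def test_correct_side_sign_matches_prediction(rng):
    X, y = _two_clouds(rng, sep=2.0)
    model = fit_lda(X[:30], y[:30])
    d = signed_distance(model, X[30:], y_true=y[30:])
    correct = model.predict(X[30:]) == y[30:]
    assert ((d > 0) == correct).all()


def test_ledoit_wolf_matches_sklearn(rng):
    Xc = rng.normal(size=(30, 12))
    Xc -= Xc.mean(0)
    ours = ledoit_wolf_shrinkage(Xc)
    theirs = sk_lw(Xc, assume_centered=True)
    assert ours == pytest.approx(float(theirs), abs=1e-10)


def test_rank_deficient_fit_is_safe(rng):
    """Features >> samples (the searchlight regime) must never fail."""
    X = rng.normal(size=(20, 120))
    y = np.array(["a", "b"] * 10)
    for g in ("auto", 0.1, 1.0):
        model = fit_lda(X, y, shrinkage=g)
        assert np.all(np.isfinite(model.weights))
        assert np.linalg.norm(model.weights) > 0


def test_invalid_inputs(rng):
    X = rng.normal(size=(10, 3))
    with pytest.raises(ValueError):
        fit_lda(X, np.zeros(10))  # single class
    y = np.array([0, 1] * 5)
    with pytest.raises(ValueError):
        fit_lda(X, y, shrinkage=1.5)
    with pytest.raises(ValueError):
        fit_lda(X, y, shrinkage=-0.1)


def test_crossval_accuracy_matches_sklearn_loop(rng):
    X, y = _two_clouds(rng, n=24, p=4, sep=6.0)
    runs = np.tile(np.arange(3), 8)
    folds = leave_one_run_out(runs)
    acc, per_fold = crossval_accuracy(X, y, folds, shrinkage=0.2)
    ref = []
    for train, test in folds:
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.2)
        clf.fit(X[train], y[train])
        ref.append(float(np.mean(clf.predict(X[test]) == y[test])))
    assert per_fold == pytest.approx(ref)
    assert acc == pytest.approx(np.mean(ref))


def test_crossval_distances_recover_planted_ranks(design):
    cfg = SyntheticConfig(
        n_subjects=1, grid_shape=(8, 5, 5), region_voxels=30,
        run_noise_sd=1e-3, seed=21,
    )
    datasets, true = generate_patterns(design, cfg)
    roi = cfg.regions()["loc_like"]
    X, stim, runs = dataset_samples(datasets[0].values[:, :, roi])
    y = design.labels("animacy")[stim]
    correct_side = design.class_sign("animacy") * true["animacy"]
    # a single 5-fold pass leaves fold-boundary wobble (each fold's boundary
    # shifts with the held-out exemplars); repeated fold assignments average
    # it away, so rank recovery improves toward 1
    folds1 = kfold_split(y, runs=runs, n_folds=5, seed=0)
    folds3 = folds1 + kfold_split(y, runs=runs, seed=1) + kfold_split(y, runs=runs, seed=2)
    rho1 = stats.spearmanr(crossval_distances(X, y, stim, folds1).values, correct_side)[0]
    rho3 = stats.spearmanr(crossval_distances(X, y, stim, folds3).values, correct_side)[0]
    assert rho1 > 0.9
    assert rho3 > 0.97
    assert rho3 > rho1
    # permuted labels destroy the correlation
    perm = np.random.default_rng(0).permutation(32)
    y_perm = design.labels("animacy")[perm][stim]
    dv_perm = crossval_distances(X, y_perm, stim, kfold_split(y_perm, runs=runs, seed=0))
    assert abs(stats.spearmanr(dv_perm.values, correct_side)[0]) < 0.45


def test_distance_matrix_mean_equals_vector(rng):
    X, y = _two_clouds(rng, n=60, p=6, sep=3.0)
    stim = np.repeat(np.arange(20), 3)
    runs = np.tile(np.arange(3), 20)
    y = np.array(["a"] * 30 + ["b"] * 30)
    folds = kfold_split(y, runs=runs, n_folds=5, seed=1)
    dv = crossval_distances(X, y, stim, folds)
    stim_idx, unit_idx, matrix = crossval_distance_matrix(X, y, stim, runs, folds)
    np.testing.assert_allclose(matrix.mean(axis=1), dv.values, atol=1e-12)
    assert matrix.shape == (20, 3)


def test_fold_averaging_is_idempotent(rng):
    X = rng.normal(size=(20, 4))
    y = np.array(["a"] * 10 + ["b"] * 10)
    stim = np.arange(20)
    first = np.r_[0:5, 10:15]
    second = np.r_[5:10, 15:20]
    folds = [(first, second), (second, first)]
    one = crossval_distances(X, y, stim, folds)
    two = crossval_distances(X, y, stim, folds + folds)
    np.testing.assert_allclose(one.values, two.values, atol=1e-12)


def test_scheme_must_test_every_stimulus(rng):
    X = rng.normal(size=(20, 4))
    y = np.array(["a"] * 10 + ["b"] * 10)
    stim = np.arange(20)
    first = np.r_[0:5, 10:15]
    second = np.r_[5:10, 15:20]
    with pytest.raises(ValueError, match="never tested"):
        crossval_distances(X, y, stim, [(first, second)])


def test_cross_decode_generalization(design, rng):
    """Signal aligned across clusters generalizes; cluster-specific signal
    with opposite polarity in the training pair does not."""
    S, R, V = 32, 3, 40
    sign = design.class_sign("animacy")
    u = np.ones(V) / np.sqrt(V)
    noise = rng.normal(0, 1.0, size=(S, R, V))
    shared = 3.0 * np.outer(sign, u)[:, None, :] + noise
    X, stim, _ = dataset_samples(shared)
    acc, _ = cross_decode(X, stim, design, "animacy")
    assert acc > 0.9
    flip = np.where(np.isin(design.cluster, ["insects", "vegetables"]), -1.0, 1.0)
    specific = 3.0 * np.outer(sign * flip, u)[:, None, :] + noise
    Xs, stim, _ = dataset_samples(specific)
    acc_s, _ = cross_decode(Xs, stim, design, "animacy")
    assert acc_s < 0.65
    Xn, stim, _ = dataset_samples(noise)
    acc_n, _ = cross_decode(Xn, stim, design, "animacy")
    assert abs(acc_n - 0.5) < 0.25
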