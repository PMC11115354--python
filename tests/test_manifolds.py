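import numpy as np
import pytest

from cochmat.manifolds import (
    MFTMAConfig,
    mftma,
    prepare_manifolds,
    separability_oracle,
)
from cochmat.training import ActivationSet

CFG = MFTMAConfig(n_gaussian_samples=300, random_projection_dim=500, seed=0)


def _point_classes(P, N, rng, M=2):
    """Zero-extent manifolds: every class collapsed to a random centroid."""
    return [np.tile(rng.standard_normal(N), (M, 1)) for _ in range(P)]


def _cloud_classes(P, M, N, rng, scale=0.3, latent_dim=None, shell=False):
    out = []
    for _ in range(P):
        center = rng.standard_normal(N)
        if latent_dim is None:
            dev = rng.standard_normal((M, N))
        else:
            basis = np.linalg.qr(rng.standard_normal((N, latent_dim)))[0]
            dev = rng.standard_normal((M, latent_dim))
            if shell:
                dev = dev / np.linalg.norm(dev, axis=1, keepdims=True) * np.sqrt(latent_dim)
            dev = dev @ basis.T
        out.append(center + scale * dev)
    return out


def test_point_manifold_capacity_near_two(rng):
    res = mftma(_point_classes(50, 200, rng), CFG)
    assert res["capacity"] == pytest.approx(2.0, rel=0.10)
    assert res["D_M"] == pytest.approx(0.0, abs=1e-9)
    assert res["R_M"] == pytest.approx(0.0, abs=1e-9)


def test_latent_dimension_recovery(rng):
    """Densely sampled isotropic 5-D manifolds embedded in 100 dimensions.

    The anchor-dimension estimate converges to the latent dimension as the
    convex hull fills in; sparse hulls (few exemplars) bias it downward, so
    the recovery check uses a dense isotropic shell sample.
    """
    classes = _cloud_classes(12, 200, 100, rng, scale=1.0, latent_dim=5, shell=True)
    res = mftma(classes, CFG)
    assert res["D_M"] == pytest.approx(5.0, rel=0.20)


def test_scale_invariance(rng):
    classes = _cloud_classes(8, 10, 60, rng, scale=0.3)
    a = mftma(classes, CFG)
    b = mftma([7.3 * X for X in classes], CFG)
    assert b["capacity"] == pytest.approx(a["capacity"], rel=1e-9)
    assert b["D_M"] == pytest.approx(a["D_M"], rel=1e-9)
    assert b["R_M"] == pytest.approx(a["R_M"], rel=1e-9)


def test_exemplar_permutation_invariance(rng):
    classes = _cloud_classes(6, 12, 50, rng, scale=0.3)
    a = mftma(classes, CFG)
    permuted = [X[rng.permutation(X.shape[0])] for X in classes]
    b = mftma(permuted, CFG)
    assert b["capacity"] == pytest.approx(a["capacity"], rel=1e-6)
    assert b["D_M"] == pytest.approx(a["D_M"], rel=1e-6)


def test_inflating_manifolds_lowers_capacity(rng):
    classes = _cloud_classes(10, 10, 80, rng, scale=0.2)
    base = mftma(classes, CFG)
    inflated_cls = [X.mean(axis=0) + 3.0 * (X - X.mean(axis=0)) for X in classes]
    inflated = mftma(inflated_cls, CFG)
    assert inflated["capacity"] < base["capacity"]
    merged = base["per_class"].merge(inflated["per_class"], on="class_index", suffixes=("_b", "_i"))
    assert (merged["R_M_i"] > merged["R_M_b"]).all()


def test_capacity_upper_bound_at_zero_margin(rng):
    for classes in (_point_classes(20, 80, rng), _cloud_classes(10, 8, 60, rng, scale=0.5)):
        assert mftma(classes, CFG)["capacity"] <= 2.0 * 1.05


def test_prepare_manifolds_projection(rng):
    X = rng.standard_normal((20, 2000))
    acts = ActivationSet(activations={"L": X}, labels=["a"] * 10 + ["b"] * 10)
    prepared = prepare_manifolds(acts, MFTMAConfig(random_projection_dim=400, seed=1))
    Xa, Xb = prepared["L"]
    assert Xa.shape == (10, 400) and Xb.shape == (10, 400)
    # Johnson-Lindenstrauss: pairwise distances approximately preserved
    proj = np.concatenate([Xa, Xb])
    for i, j in [(0, 5), (2, 17), (8, 13)]:
        d0 = np.linalg.norm(X[i] - X[j])
        d1 = np.linalg.norm(proj[i] - proj[j])
        assert d1 == pytest.approx(d0, rel=0.25)
    # identical seed -> identical projection; wide enough layer passes through
    again = prepare_manifolds(acts, MFTMAConfig(random_projection_dim=400, seed=1))
    np.testing.assert_array_equal(again["L"][0], Xa)
    full = prepare_manifolds(acts, MFTMAConfig(random_projection_dim=2000, seed=1))
    np.testing.assert_array_equal(np.concatenate(full["L"]), X)


def test_prepare_manifolds_requires_two_exemplars(rng):
    acts = ActivationSet(activations={"L": rng.random((3, 10))}, labels=["a", "a", "b"])
    with pytest.raises(ValueError):
        prepare_manifolds(acts, CFG)


def test_oracle_point_capacity_matches_cover(rng):
    classes = _point_classes(60, 300, rng, M=1)
    est = separability_oracle(classes, n_repeats=30, seed=0)
    assert est == pytest.approx(2.0, rel=0.15)


def test_oracle_separates_two_distant_clouds(rng):
    classes = [100 + 0.1 * rng.standard_normal((10, 50)), -100 + 0.1 * rng.standard_normal((10, 50))]
    # at generous width the two clouds are always separable
    est = separability_oracle(classes, n_repeats=10, seed=0, n_grid=(10, 40))
    assert est <= 2 / 10 + 1e-9


def test_mftma_agrees_with_separability_oracle(rng):
    rel_errors = []
    for trial in range(3):
        classes = _cloud_classes(40, 5, 150, rng, scale=0.1 + 0.15 * trial)
        alpha = mftma(classes, CFG)["capacity"]
        est = separability_oracle(classes, n_repeats=20, seed=trial)
        rel_errors.append(abs(alpha - est) / est)
    assert max(rel_errors) <= 0.20
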