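import numpy as np
import pytest

from shgtex import averaged_features, compute_glcm, glcm_features
from conftest import make_image


def brute_force_features(p):
    """Double-loop evaluation of all five texture formulas."""
    n = p.shape[0]
    contrast = homogeneity = energy = entropy = 0.0
    mu_i = mu_j = 0.0
    for i in range(n):
        for j in range(n):
            mu_i += i * p[i, j]
            mu_j += j * p[i, j]
    var_i = var_j = cov = 0.0
    for i in range(n):
        for j in range(n):
            contrast += p[i, j] * (i - j) ** 2
            homogeneity += p[i, j] / (1 + (i - j) ** 2)
            energy += p[i, j] ** 2
            if p[i, j] > 0:
                entropy -= p[i, j] * np.log2(p[i, j])
            var_i += (i - mu_i) ** 2 * p[i, j]
            var_j += (j - mu_j) ** 2 * p[i, j]
            cov += (i - mu_i) * (j - mu_j) * p[i, j]
    corr = cov / np.sqrt(var_i * var_j)
    return contrast, homogeneity, energy, entropy, corr


def test_constant_image_single_entry_matrix():
    img = np.full((2, 2), 3, dtype=np.uint8)
    g = compute_glcm(img, 0, levels=8)
    assert g[3, 3] == 1.0
    assert g.sum() == 1.0
    with pytest.warns(RuntimeWarning, match="correlation"):
        f = glcm_features(g)
    assert f.contrast == 0.0
    assert f.homogeneity == 1.0
    assert f.energy == 1.0  # consistent uniform gray level -> maximum energy
    assert f.entropy == 0.0
    assert np.isnan(f.correlation)


def test_alternating_row_hand_enumeration():
    # three neighbor pairs, all (0,1) or (1,0) after symmetrization
    g = compute_glcm(np.array([[0, 1, 0, 1]]), 0, levels=2)
    np.testing.assert_allclose(g, [[0.0, 0.5], [0.5, 0.0]])


def test_checkerboard_closed_form():
    board = (np.indices((8, 8)).sum(axis=0) % 2).astype(np.uint8)
    g = compute_glcm(board, 0, levels=2)
    f = glcm_features(g)
    assert f.contrast == pytest.approx(1.0)
    assert f.homogeneity == pytest.approx(0.5)
    assert f.energy == pytest.approx(0.5)
    assert f.entropy == pytest.approx(1.0)
    assert f.correlation == pytest.approx(-1.0)


@pytest.mark.parametrize("seed", range(5))
def test_features_match_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    p = rng.random((16, 16))
    p = (p + p.T) / 2  # symmetric like a real GLCM
    p /= p.sum()
    f = glcm_features(p)
    c, h, e, ent, corr = brute_force_features(p)
    assert f.contrast == pytest.approx(c, abs=1e-12)
    assert f.homogeneity == pytest.approx(h, abs=1e-12)
    assert f.energy == pytest.approx(e, abs=1e-12)
    assert f.entropy == pytest.approx(ent, abs=1e-12)
    assert f.correlation == pytest.approx(corr, abs=1e-12)


def test_uniform_matrix_entropy_is_log2_of_entries():
    k = 8
    p = np.full((k, k), 1.0 / k**2)
    assert glcm_features(p).entropy == pytest.approx(np.log2(k**2))


def test_normalization_sums_to_one(random_image):
    for d in (0, 45, 90, 135):
        assert compute_glcm(random_image, d).sum() == pytest.approx(1.0, abs=1e-12)


def test_averaged_features_invariant_to_rot90_and_flips(random_image):
    base = averaged_features(random_image)
    for transform in (np.rot90, np.fliplr, np.flipud):
        t = averaged_features(make_image(transform(random_image.pixels)))
        for field in ("contrast", "homogeneity", "energy", "entropy", "correlation"):
            assert getattr(t, field) == pytest.approx(getattr(base, field), rel=1e-12)


def test_isotropic_noise_horizontal_close_to_vertical(rng):
    img = make_image(rng.integers(0, 256, size=(256, 256), dtype=np.uint8))
    fh = glcm_features(compute_glcm(img, 0))
    fv = glcm_features(compute_glcm(img, 90))
    assert fh.contrast == pytest.approx(fv.contrast, rel=0.05)
    assert fh.homogeneity == pytest.approx(fv.homogeneity, rel=0.05)


def test_blur_sequence_moves_contrast_and_homogeneity_oppositely(rng):
    from scipy.ndimage import gaussian_filter

    noise = rng.normal(128, 40, size=(128, 128))
    contrasts, homogeneities = [], []
    for sigma in (0.0, 1.0, 2.0, 4.0):
        blurred = np.clip(gaussian_filter(noise, sigma) if sigma else noise, 0, 255)
        f = averaged_features(make_image(blurred.astype(np.uint8)))
        contrasts.append(f.contrast)
        homogeneities.append(f.homogeneity)
    assert all(a > b for a, b in zip(contrasts, contrasts[1:]))
    assert all(a < b for a, b in zip(homogeneities, homogeneities[1:]))


def test_too_small_image_rejected():
    with pytest.raises(ValueError, match="too small"):
        compute_glcm(np.array([[0], [1]]), 0, levels=2)
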