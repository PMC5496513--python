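import itertools

import numpy as np
import pytest

from kelpscape import correlogram as cg
from kelpscape.errors import DegenerateInputError, EmptyBandError, InsufficientDataError


def brute_force_morans_i(values, w):
    """Independent double-loop oracle for Moran's I."""
    x = np.asarray(values, float)
    n = len(x)
    xbar = x.mean()
    w = np.asarray(w.todense()) if hasattr(w, "todense") else np.asarray(w, float)
    num = 0.0
    W = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * (x[i] - xbar) * (x[j] - xbar)
            W += w[i, j]
    return (n / W) * num / sum((xi - xbar) ** 2 for xi in x)


class TestBandWeights:
    def test_collinear_band_membership(self):
        pos = np.array([[0.0, 0], [5.0, 0], [10.0, 0]])
        w = cg.distance_band_weights(pos, 4.0, 6.0)
        assert w.sum() == 4  # pairs (0,1),(1,2) symmetric
        assert w[0, 2] == 0

    def test_empty_band_flagged(self):
        pos = np.random.default_rng(1).uniform(0, 10, size=(8, 2))
        with pytest.raises(EmptyBandError):
            cg.distance_band_weights(pos, 100.0, 200.0)

    def test_weights_symmetric(self):
        pos = np.random.default_rng(2).uniform(0, 50, size=(20, 2))
        w = cg.distance_band_weights(pos, 5.0, 20.0)
        assert (w != w.T).nnz == 0


class TestMoransI:
    def test_alternating_path_is_minus_one(self):
        # adjacent-pair weights on a path, values +1,-1,+1,-1
        w = np.zeros((4, 4))
        for i in range(3):
            w[i, i + 1] = w[i + 1, i] = 1
        assert cg.morans_i([1, -1, 1, -1], w) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 31)
            pos = rng.uniform(0, 30, size=(n, 2))
            vals = rng.random(n)
            w = cg.distance_band_weights(pos, 0.0, 15.0)
            assert cg.morans_i(vals, w) == pytest.approx(
                brute_force_morans_i(vals, w), abs=1e-12
            )

    def test_exhaustive_permutation_mean_is_expectation(self):
        # mean of I over all 5! value permutations = -1/(n-1)
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 10, size=(5, 2))
        vals = rng.random(5)
        w = cg.distance_band_weights(pos, 0.0, 8.0)
        Is = [cg.morans_i(np.asarray(perm), w) for perm in itertools.permutations(vals)]
        assert np.mean(Is) == pytest.approx(-1 / 4, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        pos = rng.uniform(0, 20, size=(15, 2))
        vals = rng.random(15)
        w = cg.distance_band_weights(pos, 0.0, 10.0)
        base = cg.morans_i(vals, w)
        assert cg.morans_i(3.7 * vals - 1.2, w) == pytest.approx(base, abs=1e-10)

    def test_zero_variance_rejected(self):
        w = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(DegenerateInputError):
            cg.morans_i([2.0, 2.0, 2.0], w)


class TestCorrelogram:
    def test_too_few_quadrats_rejected(self):
        pos = np.random.default_rng(1).uniform(0, 50, size=(10, 2))
        with pytest.raises(InsufficientDataError):
            cg.correlogram(pos, np.random.default_rng(2).random(10))

    def test_constant_cover_rejected(self, tiny_records):
        pos = np.random.default_rng(1).uniform(0, 50, size=(40, 2))
        with pytest.raises(DegenerateInputError):
            cg.correlogram(pos, np.full(40, 0.3))

    def test_x_intercept_linear_interpolation(self):
        mids = np.array([2.5, 7.5, 12.5])
        assert cg._x_intercept(mids, np.array([0.4, -0.4, -0.5])) == pytest.approx(5.0)
        assert cg._x_intercept(mids, np.array([-0.1, 0.2, 0.3])) is None
        assert cg._x_intercept(mids, np.array([0.4, 0.3, 0.2])) is None

    def test_random_site_shows_no_structure(self):
        from conftest import make_site_track

        hits = 0
        for seed in range(10):
            pos, covers, _ = make_site_track(
                seed, n=400, range_m=0.0, sill=0.0, nugget=1.0
            )
            res = cg.correlogram(pos, covers)
            hits += bool(np.all(np.abs(res.I) < 0.1))
        assert hits >= 9

    def test_patchy_site_structure_and_patch_scale(self):
        """Sites with a long-range, high-sill latent field show strong
        short-lag correlation and a patch scale of tens of meters; the exact
        zero-crossing distance at far lags is fluctuation-dominated, so only
        its scale (beyond 25 m, or positive throughout the plotted window)
        is asserted."""
        from conftest import make_site_track

        strong_first_band = 0
        patch_scale = 0
        for seed in range(10):
            pos, covers, _ = make_site_track(seed, n=735, range_m=25.0, sill=1.2, nugget=0.05)
            res = cg.correlogram(pos, covers)
            strong_first_band += res.I[0] > 0.5
            patch_scale += res.x_intercept is None or res.x_intercept > 25
        assert strong_first_band >= 7
        assert patch_scale >= 9


class TestNullEnvelope:
    @pytest.fixture(scope="class")
    def site(self):
        from conftest import make_site_track

        pos, covers, _ = make_site_track(1, n=200, range_m=10.0)
        res = cg.correlogram(pos, covers)
        return pos, covers, res

    def test_envelope_contains_permutation_expectation(self, site):
        pos, covers, res = site
        out = cg.null_envelope(pos, covers, res, n_reps=199, seed=0)
        expectation = -1 / (len(covers) - 1)
        assert np.all(out.null_low <= expectation)
        assert np.all(out.null_high >= expectation)

    def test_fixed_seed_identical_envelope(self, site):
        pos, covers, res = site
        a = cg.null_envelope(pos, covers, res, n_reps=49, seed=5)
        b = cg.null_envelope(pos, covers, res, n_reps=49, seed=5)
        np.testing.assert_array_equal(a.null_low, b.null_low)
        np.testing.assert_array_equal(a.null_high, b.null_high)

    def test_permuted_data_falls_inside_its_own_envelope(self, site):
        pos, covers, res = site
        rng = np.random.default_rng(7)
        inside = total = 0
        for _ in range(10):
            shuffled = rng.permutation(covers)
            r = cg.correlogram(pos, shuffled)
            r = cg.null_envelope(pos, shuffled, r, n_reps=99, seed=int(rng.integers(1e6)))
            inside += int(np.sum((r.I >= r.null_low) & (r.I <= r.null_high)))
            total += len(r.I)
        assert inside / total >= 0.9

    def test_uniform_mode_runs_and_brackets_zero_structure(self, site):
        pos, covers, res = site
        out = cg.null_envelope(pos, covers, res, n_reps=99, mode="uniform", seed=3)
        assert np.all(out.null_low < 0) and np.all(out.null_high > out.null_low)
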