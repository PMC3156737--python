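"""Weighted EM fitting, the component-count heuristic, and closed-form overlaps."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from fapscreen.ensemble import DistanceProfile
from fapscreen.gmmfit import (
    BoltzmannGMM,
    EmConfig,
    GaussianComponent,
    Gmm1D,
    fit_em,
    gaussian_overlap,
    gmm_correlation,
    n_components_heuristic,
    weighted_log_likelihood,
)


def _profile(samples, weights=None):
    samples = np.asarray(samples, dtype=float)
    if weights is None:
        weights = np.full(samples.size, 1.0 / samples.size)
    return DistanceProfile((0, 3), samples, np.asarray(weights, dtype=float))


class TestComponentHeuristic:
    @pytest.mark.parametrize(
        "n_rot, n_samples, expected",
        [(3, 100, 3), (5, 2, 2), (1, 1, 1), (4, 100, 4)],
    )
    def test_rule(self, n_rot, n_samples, expected):
        assert n_components_heuristic(n_rot, n_samples) == expected

    def test_cap(self):
        assert n_components_heuristic(7, 100, c_max=4) == 4


class TestFitEm:
    def test_single_component_closed_form(self):
        model = fit_em(_profile([1.0, 2.0, 3.0]), 1)
        (c,) = model.components
        assert c.weight == pytest.approx(1.0)
        assert c.mean == pytest.approx(2.0)
        assert c.variance == pytest.approx(2.0 / 3.0)

    def test_weighted_single_component_closed_form(self):
        model = fit_em(_profile([1e-9, 1.0], weights=[0.75, 0.25]), 1)
        (c,) = model.components
        assert c.mean == pytest.approx(0.25, abs=1e-6)
        assert c.variance == pytest.approx(0.1875, abs=1e-6)

    def test_two_component_recovery(self):
        rng = np.random.default_rng(7)
        n = 2000
        comp = rng.random(n) < 0.5
        x = np.where(comp, rng.normal(4.0, 0.3, n), rng.normal(9.0, 0.3, n))
        model = fit_em(_profile(x), 2, EmConfig(seed=7))
        means = sorted(c.mean for c in model.components)
        assert abs(means[0] - 4.0) < 0.1
        assert abs(means[1] - 9.0) < 0.1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_em(_profile([1.0, 2.0]), 3)

    def test_identical_samples_collapse(self):
        model = fit_em(_profile([2.5] * 10), 3, EmConfig(variance_floor=1e-4))
        assert model.n_components == 1
        assert model.components[0].mean == pytest.approx(2.5)
        assert model.components[0].variance == pytest.approx(1e-4)

    def test_weights_sum_to_one(self, rng):
        x = rng.uniform(2, 10, size=200)
        model = fit_em(_profile(x), 3, EmConfig(seed=1))
        assert sum(c.weight for c in model.components) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_weights_bitwise_equal_unweighted(self, rng):
        x = rng.uniform(2, 10, size=150)
        est_plain = BoltzmannGMM(n_components=2, random_state=3).fit(x)
        est_unif = BoltzmannGMM(n_components=2, random_state=3).fit(
            x, sample_weight=np.full(x.size, 1.0 / x.size)
        )
        assert np.array_equal(est_plain.means_, est_unif.means_)
        assert np.array_equal(est_plain.weights_, est_unif.weights_)
        assert np.array_equal(est_plain.variances_, est_unif.variances_)

    def test_objective_monotone_nondecreasing(self, rng):
        x = np.concatenate([rng.normal(4, 0.5, 100), rng.normal(8, 0.7, 100)])
        est = BoltzmannGMM(n_components=2, random_state=0, n_init=3).fit(x)
        for hist in est.objective_histories_:
            assert np.all(np.diff(hist) >= -1e-10)

    def test_matches_sklearn_on_uniform_weights(self, rng):
        # independent EM implementation as oracle for the unweighted special case
        from sklearn.mixture import GaussianMixture

        x = np.concatenate([rng.normal(4, 0.3, 500), rng.normal(9, 0.4, 500)])
        ours = fit_em(_profile(x), 2, EmConfig(seed=5, restarts=3))
        ref = GaussianMixture(2, n_init=3, random_state=5).fit(x.reshape(-1, 1))
        assert sorted(c.mean for c in ours.components) == pytest.approx(
            sorted(ref.means_.ravel()), abs=0.05
        )
        assert sorted(c.weight for c in ours.components) == pytest.approx(
            sorted(ref.weights_), abs=0.02
        )


class TestLogLikelihood:
    def test_zero_at_unit_density_peak(self):
        model = Gmm1D([GaussianComponent(1.0, 3.0, 1.0 / (2.0 * math.pi))])
        ll = weighted_log_likelihood(_profile([3.0]), model)
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_uniform_weights_reduce_to_plain_mean(self, rng):
        x = rng.uniform(1, 5, 50)
        model = fit_em(_profile(x), 1)
        ll = weighted_log_likelihood(_profile(x), model)
        plain = float(model.log_pdf(x).sum())
        assert ll == pytest.approx(plain)


def _random_component(rng):
    return GaussianComponent(1.0, rng.uniform(-5, 15), rng.uniform(0.01, 4.0))


def _random_mixture(rng):
    c = int(rng.integers(1, 4))
    w = rng.dirichlet(np.ones(c))
    return Gmm1D(
        [
            GaussianComponent(float(wi), float(rng.uniform(0, 12)), float(rng.uniform(0.02, 2.0)))
            for wi in w
        ]
    )


class TestOverlap:
    def test_equal_standard_normals(self):
        a = GaussianComponent(1.0, 0.0, 1.0)
        assert gaussian_overlap(a, a) == pytest.approx(1.0 / (2.0 * math.sqrt(math.pi)))

    def test_shifted_unit_normals(self):
        a = GaussianComponent(1.0, 0.0, 1.0)
        b = GaussianComponent(1.0, 2.0, 1.0)
        assert gaussian_overlap(a, b) == pytest.approx(math.exp(-1.0) / math.sqrt(4.0 * math.pi))

    def test_distant_means_vanish(self):
        a = GaussianComponent(1.0, 0.0, 1.0)
        b = GaussianComponent(1.0, 1e3, 1.0)
        assert gaussian_overlap(a, b) < 1e-300

    def test_quadrature_agreement(self, rng):
        def normal_pdf(x, c):
            return math.exp(-0.5 * (x - c.mean) ** 2 / c.variance) / math.sqrt(
                2.0 * math.pi * c.variance
            )

        for _ in range(25):
            a, b = _random_component(rng), _random_component(rng)
            sd = max(a.variance, b.variance) ** 0.5
            lo = min(a.mean, b.mean) - 15 * sd
            hi = max(a.mean, b.mean) + 15 * sd
            numeric, _ = quad(
                lambda x: normal_pdf(x, a) * normal_pdf(x, b),
                lo,
                hi,
                points=[a.mean, b.mean, 0.5 * (a.mean + b.mean)],
                limit=400,
            )
            assert gaussian_overlap(a, b) == pytest.approx(numeric, abs=1e-8)


class TestCorrelation:
    def test_identical_models_one(self, rng):
        for _ in range(10):
            g = _random_mixture(rng)
            h = Gmm1D(list(g.components))  # distinct object, identical parameters
            assert gmm_correlation(g, h) == pytest.approx(1.0, abs=1e-12)

    def test_unit_normals_two_apart(self):
        g = Gmm1D([GaussianComponent(1.0, 0.0, 1.0)])
        h = Gmm1D([GaussianComponent(1.0, 2.0, 1.0)])
        assert gmm_correlation(g, h) == pytest.approx(math.exp(-1.0))

    def test_separated_models_vanish(self):
        g = Gmm1D([GaussianComponent(1.0, 0.0, 0.5)])
        h = Gmm1D([GaussianComponent(1.0, 500.0, 0.5)])
        assert gmm_correlation(g, h) < 1e-12

    def test_symmetric_and_bounded(self, rng):
        for _ in range(50):
            g, h = _random_mixture(rng), _random_mixture(rng)
            c = gmm_correlation(g, h)
            assert c == gmm_correlation(h, g)  # exact, floating point included
            assert 0.0 < c <= 1.0

    def test_quadrature_agreement(self, rng):
        for _ in range(10):
            g, h = _random_mixture(rng), _random_mixture(rng)
            num, _ = quad(lambda x: g.pdf(x)[0] * h.pdf(x)[0], -40, 60, limit=300)
            gg, _ = quad(lambda x: g.pdf(x)[0] ** 2, -40, 60, limit=300)
            hh, _ = quad(lambda x: h.pdf(x)[0] ** 2, -40, 60, limit=300)
            assert gmm_correlation(g, h) == pytest.approx(num / math.sqrt(gg * hh), abs=1e-8)
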