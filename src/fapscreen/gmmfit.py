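"""1D Gaussian mixture models fitted by Boltzmann-weighted expectation maximization.

The distance profile of a flexible atom pair is modeled by a univariate
Gaussian mixture p(x) = sum_c pi_c N(x | mu_c, sigma_c^2).  Conformers are not
equally important in a canonical ensemble, so each distance sample carries a
Boltzmann probability p(E_n) and the EM objective becomes the weighted
log-likelihood

    L = N * sum_n p(E_n) * log p(x_n),

scaled by the sample count so that uniform weights reduce it exactly to the
plain maximum-likelihood objective.  The E-step (responsibilities) is
unchanged; the M-step uses weighted sufficient statistics:

    pi_k    = sum_n p(E_n) g_nk / sum_n p(E_n)
    mu_k    = sum_n p(E_n) g_nk x_n / sum_n p(E_n) g_nk
    sigma_k = sum_n p(E_n) g_nk (x_n - mu_k)^2 / sum_n p(E_n) g_nk

where g_nk is the responsibility of component k for sample n.

The number of components is not selected by an information criterion but by a
topological heuristic: it equals the number of internal rotatable bonds on the
pair's shortest path (capped by the sample count), the same count that
classified the pair as flexible in the first place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, DensityMixin

from .ensemble import DistanceProfile

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class GaussianComponent:
    """One mixture component: weight pi, mean (A), variance (A^2)."""

    weight: float
    mean: float
    variance: float


@dataclass
class Gmm1D:
    """A 1D Gaussian mixture: the generative model of one flexible pair."""

    components: List[GaussianComponent]

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise ValueError("a mixture needs at least one component")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights sum to {total}, not 1")
        if any(c.variance <= 0 for c in self.components):
            raise ValueError("component variances must be positive")
        self._arrays_cache: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray]] = None
        self._self_inner: Optional[float] = None
        self._canon_key: Optional[tuple] = None

    def canon_key(self) -> tuple:
        """Deterministic content key; used to fix evaluation order in symmetric kernels."""
        if self._canon_key is None:
            self._canon_key = tuple((c.mean, c.variance, c.weight) for c in self.components)
        return self._canon_key

    @property
    def n_components(self) -> int:
        return len(self.components)

    def arrays(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(weights, means, variances) as arrays (cached)."""
        if self._arrays_cache is None:
            self._arrays_cache = (
                np.array([c.weight for c in self.components]),
                np.array([c.mean for c in self.components]),
                np.array([c.variance for c in self.components]),
            )
        return self._arrays_cache

    def pdf(self, x) -> np.ndarray:
        w, m, v = self.arrays()
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - m[None, :]) ** 2 / v[None, :]
        comp = np.exp(-0.5 * z) / np.sqrt(2.0 * np.pi * v[None, :])
        return comp @ w

    def log_pdf(self, x) -> np.ndarray:
        w, m, v = self.arrays()
        x = np.atleast_1d(np.asarray(x, dtype=float))
        log_comp = (
            -0.5 * _LOG_2PI
            - 0.5 * np.log(v[None, :])
            - 0.5 * (x[:, None] - m[None, :]) ** 2 / v[None, :]
        )
        return logsumexp(log_comp + np.log(w[None, :]), axis=1)


@dataclass(frozen=True)
class EmConfig:
    """EM hyperparameters: iteration cap, tolerance, restarts, seed, floor."""

    max_iterations: int = 200
    tolerance: float = 1e-6
    restarts: int = 3
    seed: int = 0
    variance_floor: float = 1e-4
    c_max: Optional[int] = None

    def __post_init__(self) -> None:
        if self.max_iterations < 1 or self.tolerance <= 0 or self.restarts < 1:
            raise ValueError("max_iterations, tolerance and restarts must be positive")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")


def n_components_heuristic(
    n_internal_rotatable: int, n_samples: int, c_max: Optional[int] = None
) -> int:
    """Component count for a flexible pair's mixture.

    Equals the number of internal rotatable bonds on the shortest path — each
    rotor adds roughly one preferred distance mode — capped by the number of
    samples and an optional hard cap.  Never zero.
    """
    if n_internal_rotatable < 1 or n_samples < 1:
        raise ValueError("counts must be >= 1")
    c = min(n_internal_rotatable, n_samples)
    if c_max is not None:
        c = min(c, c_max)
    return max(1, c)


class BoltzmannGMM(DensityMixin, BaseEstimator):
    """Univariate Gaussian mixture fitted by sample-weighted EM.

    A single code path implements both the plain and the Boltzmann-weighted
    algorithm: ``fit(X)`` without weights uses 1/N per sample, which reduces
    the weighted M-step exactly (bit-for-bit) to the classic update.

    Parameters
    ----------
    n_components : requested number of Gaussian components.
    max_iter, tol : iteration cap and relative tolerance on the objective.
    n_init : number of restarts; the run with the best final objective wins.
    random_state : seed for the restart jitter.
    variance_floor : lower clamp on component variances (A^2), applied every
        M-step; prevents likelihood blow-up on near-constant profiles.

    Attributes
    ----------
    weights_, means_, variances_ : fitted mixture parameters.
    objective_ : final weighted log-likelihood of the best run.
    objective_history_ : per-iteration objective of the best run.
    objective_histories_ : per-iteration objectives of every restart.
    n_iter_, converged_ : iterations and convergence flag of the best run.
    """

    def __init__(
        self,
        n_components: int = 1,
        max_iter: int = 200,
        tol: float = 1e-6,
        n_init: int = 3,
        random_state: Optional[int] = None,
        variance_floor: float = 1e-4,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.n_init = n_init
        self.random_state = random_state
        self.variance_floor = variance_floor

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _log_components(x, means, variances):
        return (
            -0.5 * _LOG_2PI
            - 0.5 * np.log(variances[None, :])
            - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
        )

    def _objective(self, x, w, pi, means, variances):
        # N * sum_n w_n log p(x_n); w normalized to sum 1
        log_p = logsumexp(self._log_components(x, means, variances) + np.log(pi[None, :]), axis=1)
        return x.size * float(np.dot(w, log_p))

    def _init_params(self, x, w, n_components, rng, restart):
        order = np.argsort(x, kind="stable")
        xs, ws = x[order], w[order]
        cdf = np.cumsum(ws)
        cdf /= cdf[-1]
        q = (np.arange(n_components) + 0.5) / n_components
        means = xs[np.searchsorted(cdf, q, side="left").clip(0, xs.size - 1)].astype(float)
        std = math.sqrt(max(float(np.dot(w, (x - np.dot(w, x)) ** 2)), 0.0))
        if restart > 0:
            means = means + rng.normal(0.0, 0.1 * max(std, math.sqrt(self.variance_floor)),
                                       size=n_components)
        var0 = max(std**2 / n_components, self.variance_floor)
        variances = np.full(n_components, var0)
        pi = np.full(n_components, 1.0 / n_components)
        return pi, means, variances

    def _em_run(self, x, w, pi, means, variances):
        history = []
        prev = -np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            # E-step: responsibilities (unchanged by the weighting)
            log_comp = self._log_components(x, means, variances) + np.log(pi[None, :])
            log_norm = logsumexp(log_comp, axis=1, keepdims=True)
            resp = np.exp(log_comp - log_norm)
            # M-step with weighted sufficient statistics
            wn = w[:, None] * resp
            nk = wn.sum(axis=0)  # sum_n w_n g_nk; sums to 1
            keep = nk >= 1e-12
            if not np.all(keep):
                # empty-component collapse: drop and renormalize
                resp = resp[:, keep]
                wn = wn[:, keep]
                nk = nk[keep]
            pi = nk / nk.sum()
            means = (wn * x[:, None]).sum(axis=0) / nk
            variances = (wn * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
            variances = np.maximum(variances, self.variance_floor)
            obj = self._objective(x, w, pi, means, variances)
            history.append(obj)
            if np.isfinite(prev) and abs(obj - prev) <= self.tol * max(1.0, abs(obj)):
                converged = True
                break
            prev = obj
        return pi, means, variances, np.array(history), n_iter, converged

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None, sample_weight=None) -> "BoltzmannGMM":
        x = np.asarray(X, dtype=float).reshape(-1)
        if x.size < self.n_components:
            raise ValueError(
                f"{self.n_components} components requested but only {x.size} samples"
            )
        if sample_weight is None:
            sample_weight = np.full(x.size, 1.0 / x.size)
        w = np.asarray(sample_weight, dtype=float).reshape(-1)
        if w.shape != x.shape:
            raise ValueError("sample_weight must match X in length")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("sample_weight must be non-negative with positive sum")
        w = w / w.sum()  # one shared normalization: uniform weights reduce bit-for-bit

        if np.ptp(x) == 0.0:
            # degenerate: all samples identical — single component at the floor
            self.weights_ = np.array([1.0])
            self.means_ = np.array([float(x[0])])
            self.variances_ = np.array([self.variance_floor])
            self.objective_ = self._objective(x, w, self.weights_, self.means_, self.variances_)
            self.objective_history_ = np.array([self.objective_])
            self.objective_histories_ = [self.objective_history_]
            self.n_iter_, self.converged_ = 0, True
            self.degenerate_ = True
            return self

        rng = np.random.default_rng(self.random_state)
        best = None
        histories = []
        for restart in range(self.n_init):
            pi0, mu0, var0 = self._init_params(x, w, self.n_components, rng, restart)
            pi, mu, var, hist, n_iter, conv = self._em_run(x, w, pi0, mu0, var0)
            histories.append(hist)
            if best is None or hist[-1] > best[3][-1]:
                best = (pi, mu, var, hist, n_iter, conv)
        pi, mu, var, hist, n_iter, conv = best
        order = np.argsort(mu, kind="stable")
        self.weights_, self.means_, self.variances_ = pi[order], mu[order], var[order]
        self.objective_ = float(hist[-1])
        self.objective_history_ = hist
        self.objective_histories_ = histories
        self.n_iter_ = n_iter
        self.converged_ = conv
        self.degenerate_ = False
        return self

    def score_samples(self, X) -> np.ndarray:
        return self.to_mixture().log_pdf(np.asarray(X, dtype=float).reshape(-1))

    def score(self, X, y=None, sample_weight=None) -> float:
        """Mean (optionally weighted) log-likelihood per sample."""
        ll = self.score_samples(X)
        if sample_weight is None:
            return float(np.mean(ll))
        w = np.asarray(sample_weight, dtype=float)
        return float(np.dot(w / w.sum(), ll))

    def to_mixture(self) -> Gmm1D:
        return Gmm1D(
            [
                GaussianComponent(float(p), float(m), float(v))
                for p, m, v in zip(self.weights_, self.means_, self.variances_)
            ]
        )


def fit_em(profile: DistanceProfile, n_components: int, config: EmConfig = EmConfig()) -> Gmm1D:
    """Fit a mixture to one distance profile by Boltzmann-weighted EM."""
    est = BoltzmannGMM(
        n_components=n_components,
        max_iter=config.max_iterations,
        tol=config.tolerance,
        n_init=config.restarts,
        random_state=config.seed,
        variance_floor=config.variance_floor,
    )
    est.fit(profile.samples, sample_weight=profile.weights)
    return est.to_mixture()


def weighted_log_likelihood(profile: DistanceProfile, model: Gmm1D) -> float:
    """N * sum_n p(E_n) log p(x_n) — the weighted EM objective for a model."""
    ll = model.log_pdf(profile.samples)
    return profile.samples.size * float(np.dot(profile.weights, ll))


def gaussian_overlap(a: GaussianComponent, b: GaussianComponent) -> float:
    """Closed-form overlap integral of two normal densities.

    int N(x|mu_a, s_a^2) N(x|mu_b, s_b^2) dx = N(mu_a | mu_b, s_a^2 + s_b^2).
    """
    var = a.variance + b.variance
    return math.exp(-0.5 * (a.mean - b.mean) ** 2 / var) / math.sqrt(2.0 * math.pi * var)


def _cross_inner(ga: Gmm1D, gb: Gmm1D) -> float:
    # <g,h> = sum_cd pi_c pi_d N(mu_c | mu_d, var_c + var_d), vectorized
    wa, ma, va = ga.arrays()
    wb, mb, vb = gb.arrays()
    var = va[:, None] + vb[None, :]
    kernel = np.exp(-0.5 * (ma[:, None] - mb[None, :]) ** 2 / var) / np.sqrt(2.0 * np.pi * var)
    return float(wa @ kernel @ wb)


def _self_inner(g: Gmm1D) -> float:
    if g._self_inner is None:
        g._self_inner = _cross_inner(g, g)
    return g._self_inner


def gmm_correlation(g_m: Gmm1D, g_n: Gmm1D) -> float:
    """Normalized cross-correlation of two mixture densities, in (0, 1].

    <g,h> / sqrt(<g,g><h,h>) with <.,.> the L2 inner product of the densities
    (all pairwise Gaussian overlaps, in closed form).  Symmetric; equals 1 for
    identical models; strictly positive since Gaussians overlap everywhere.
    """
    if g_m is g_n:
        return 1.0
    # canonical orientation + symmetric denominator make the result exactly
    # invariant under argument swap (floating point included)
    if g_n.canon_key() < g_m.canon_key():
        g_m, g_n = g_n, g_m
    num = _cross_inner(g_m, g_n)
    denom = math.sqrt(_self_inner(g_m) * _self_inner(g_n))
    return min(num / denom, 1.0)
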