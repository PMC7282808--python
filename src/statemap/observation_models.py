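"""Likelihood families for hidden states, with parameters marginalized out.

Two conjugate-style observation models are provided:

* **Gaussian / normal-Wishart.**  Real-valued features are modelled as
  multivariate normal with unknown mean and precision, under a
  normal-Wishart prior.  The posterior predictive of a new observation is a
  generalized Student-t in closed form, and the marginal likelihood of a
  set of observations is computed as the chain of one-step predictives
  (exact, since the model is exchangeable).

* **Von Mises / normal-gamma.**  Circular features (degrees) are modelled
  as Von Mises with unknown mean direction mu and concentration kappa.
  The prior couples a wrapped normal on mu (variance 1/(kappa0*kappa))
  with a Gamma(a0, b0) on kappa.  No closed form exists, so predictive and
  marginal densities are obtained by trapezoid quadrature on a (mu, kappa)
  grid; multiple circular dimensions are treated as independent.

Default hyperparameters (vague priors): Gaussian mu0=0, kappa0=1e-3,
nu0=0.02, T0=0.02*I; circular mu0=0, kappa0=1e-3, a0=b0=0.01.

Degrees-of-freedom note: the nominal nu0=0.02 makes the empty-state
Student-t predictive improper for d > 1 (df = nu0 - d + 1 <= 0).  All NIW
computations therefore use the minimal proper correction
nu0_eff = nu0 + d - 1, which coincides with the nominal value for d = 1.

Kappa-grid note: the Gamma(0.01, 0.01) concentration prior puts most of
its mass at extremely small kappa where the Von Mises is indistinguishable
from uniform.  The quadrature grid spans kappa in [1e-3, 1e3] and the
(mu, kappa) prior is renormalized on that support, so marginal likelihoods
telescope exactly into chains of predictives and evidence ratios carry no
truncation offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, i0e, logsumexp
from scipy.stats import gamma as gamma_dist

from .observations import ObservationSet

__all__ = [
    "NIWHyper",
    "NIWPosterior",
    "niw_update",
    "gaussian_log_predictive",
    "gaussian_chain_log_predictives",
    "gaussian_log_marginal",
    "VonMisesNGHyper",
    "IntegrationGrid",
    "vonmises_log_predictive",
    "vonmises_log_marginal",
    "GaussianModel",
    "VonMisesModel",
]

_LOG_DEG_PER_RAD = math.log(math.pi / 180.0)  # per-degree <- per-radian conversion


# ---------------------------------------------------------------------------
# Gaussian family: normal-Wishart prior, Student-t predictive
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NIWHyper:
    """Normal-Wishart hyperparameters (mu0, kappa0, nu0, T0)."""

    mu0: np.ndarray
    kappa0: float = 1e-3
    nu0: float = 0.02
    T0: np.ndarray = None

    def __post_init__(self) -> None:
        mu0 = np.atleast_1d(np.asarray(self.mu0, dtype=float))
        t0 = self.T0
        if t0 is None:
            t0 = 0.02 * np.eye(mu0.size)
        t0 = np.atleast_2d(np.asarray(t0, dtype=float))
        if t0.shape != (mu0.size, mu0.size):
            raise ValueError("T0 must be D x D for a D-dimensional mu0")
        if self.kappa0 <= 0 or self.nu0 <= 0:
            raise ValueError("kappa0 and nu0 must be positive")
        if not np.allclose(t0, t0.T) or np.any(np.linalg.eigvalsh(t0) <= 0):
            raise ValueError("T0 must be symmetric positive-definite")
        object.__setattr__(self, "mu0", mu0)
        object.__setattr__(self, "T0", t0)

    @classmethod
    def default(cls, dim: int) -> "NIWHyper":
        return cls(mu0=np.zeros(dim))

    @property
    def dim(self) -> int:
        return self.mu0.size

    @property
    def nu0_eff(self) -> float:
        """Degrees-of-freedom floor: nu0 + d - 1 (= nu0 when d = 1)."""
        return self.nu0 + self.dim - 1


@dataclass(frozen=True)
class NIWPosterior:
    """Updated normal-Wishart sufficient statistics after m observations."""

    mu_m: np.ndarray
    kappa_m: float
    nu_m: float
    T_m: np.ndarray
    m: int

    @property
    def dim(self) -> int:
        return np.atleast_1d(self.mu_m).size


def niw_update(hyper: NIWHyper, obs: ObservationSet) -> NIWPosterior:
    """Conjugate update of the normal-Wishart prior with a set of observations.

    T_m = T0 + S + kappa0*m/(kappa0+m) (mu0 - ybar)(mu0 - ybar)^T with S the
    centered scatter matrix sum (y - ybar)(y - ybar)^T.  The empty set
    returns the prior unchanged.
    """
    if not obs.all_linear:
        raise ValueError("the Gaussian family requires all-linear features")
    if obs.n_features != hyper.dim:
        raise ValueError(
            f"dimension mismatch: hyper is {hyper.dim}-D, observations are {obs.n_features}-D"
        )
    m = obs.n_obs
    if m == 0:
        return NIWPosterior(hyper.mu0, hyper.kappa0, hyper.nu0_eff, hyper.T0, 0)
    y = obs.data
    ybar = y.mean(axis=0)
    centered = y - ybar
    scatter = centered.T @ centered
    mu_m = (hyper.kappa0 * hyper.mu0 + m * ybar) / (hyper.kappa0 + m)
    kappa_m = hyper.kappa0 + m
    nu_m = hyper.nu0_eff + m
    dev = (hyper.mu0 - ybar)[:, None]
    t_m = hyper.T0 + scatter + (hyper.kappa0 * m / (hyper.kappa0 + m)) * (dev @ dev.T)
    return NIWPosterior(mu_m, kappa_m, nu_m, t_m, m)


def _mvt_logpdf(y: np.ndarray, loc: np.ndarray, shape: np.ndarray, df: float) -> float:
    """Multivariate Student-t log density (matches scipy.stats.multivariate_t)."""
    d = loc.size
    chol = np.linalg.cholesky(shape)
    z = np.linalg.solve(chol, y - loc)
    maha = float(z @ z)
    log_det = 2.0 * np.log(np.diag(chol)).sum()
    return float(
        gammaln((df + d) / 2)
        - gammaln(df / 2)
        - 0.5 * d * np.log(df * np.pi)
        - 0.5 * log_det
        - 0.5 * (df + d) * np.log1p(maha / df)
    )


def gaussian_log_predictive(post: NIWPosterior, y) -> float:
    """Log posterior-predictive density at y: generalized Student-t.

    df = nu_m - d + 1, location mu_m, scale T_m (kappa_m + 1) / (kappa_m df).
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    d = post.dim
    if y.size != d:
        raise ValueError(f"y must be {d}-dimensional")
    df = post.nu_m - d + 1
    if df <= 0:
        raise ValueError("non-positive predictive degrees of freedom")
    shape = post.T_m * (post.kappa_m + 1) / (post.kappa_m * df)
    return _mvt_logpdf(y, np.atleast_1d(post.mu_m), np.atleast_2d(shape), df)


def gaussian_chain_log_predictives(hyper: NIWHyper, obs: ObservationSet) -> np.ndarray:
    """Per-step one-step-ahead log predictives log P(y_t | y_1..t-1).

    Cumulative sums give the log marginal of every prefix, which the
    trajectory protocols exploit.
    """
    out = np.empty(obs.n_obs)
    for t in range(obs.n_obs):
        post = niw_update(hyper, obs.head(t))
        out[t] = gaussian_log_predictive(post, obs.data[t])
    return out


def gaussian_log_marginal(hyper: NIWHyper, obs: ObservationSet) -> float:
    """Log marginal likelihood of an observation set under one hidden state.

    Computed as the chain of one-step predictives
    log P(y1) + log P(y2 | y1) + ...; the empty set returns 0.
    """
    return float(gaussian_chain_log_predictives(hyper, obs).sum())


# ---------------------------------------------------------------------------
# Von Mises family: normal-gamma prior, numerical marginalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VonMisesNGHyper:
    """Normal-gamma hyperparameters for the Von Mises family.

    mu | kappa ~ wrapped Normal(mu0, 1/(kappa0*kappa)); kappa ~ Gamma(a0, b0)
    (shape/rate).  mu0 in degrees.
    """

    mu0: float = 0.0
    kappa0: float = 1e-3
    a0: float = 0.01
    b0: float = 0.01

    def __post_init__(self) -> None:
        if self.kappa0 <= 0 or self.a0 <= 0 or self.b0 <= 0:
            raise ValueError("kappa0, a0 and b0 must be positive")


@dataclass(frozen=True)
class IntegrationGrid:
    """Quadrature grid over (mu, kappa): uniform mu, log-spaced kappa."""

    n_mu: int = 720
    n_kappa: int = 64
    kappa_min: float = 1e-3
    kappa_max: float = 1e3

    def __post_init__(self) -> None:
        if self.n_mu < 4 or self.n_kappa < 2:
            raise ValueError("grid resolutions too small")
        if not 0 < self.kappa_min < self.kappa_max:
            raise ValueError("require 0 < kappa_min < kappa_max")

    def doubled(self) -> "IntegrationGrid":
        return IntegrationGrid(2 * self.n_mu, 2 * self.n_kappa, self.kappa_min, self.kappa_max)


@lru_cache(maxsize=8)
def _grid_arrays(grid: IntegrationGrid):
    """mu nodes (rad), kappa nodes, and log quadrature weights."""
    mu = np.linspace(0.0, 2 * np.pi, grid.n_mu, endpoint=False)
    kappa = np.geomspace(grid.kappa_min, grid.kappa_max, grid.n_kappa)
    # periodic uniform mu grid: rectangle rule (= trapezoid on the circle)
    log_w_mu = np.full(grid.n_mu, np.log(2 * np.pi / grid.n_mu))
    # trapezoid weights on the non-uniform kappa grid
    w_k = np.zeros(grid.n_kappa)
    dk = np.diff(kappa)
    w_k[:-1] += dk / 2
    w_k[1:] += dk / 2
    return mu, kappa, log_w_mu, np.log(w_k)


def _log_wrapped_normal(theta: np.ndarray, loc: float, sigma: float) -> np.ndarray:
    """Log density of a wrapped normal on [0, 2pi); near-uniform shortcut for wide sigma."""
    if sigma > 6.0:
        return np.full_like(theta, -np.log(2 * np.pi))
    n_wraps = int(np.ceil((6 * sigma + np.pi) / (2 * np.pi)))
    j = np.arange(-n_wraps, n_wraps + 1)
    dev = theta[:, None] - loc + 2 * np.pi * j[None, :]
    log_terms = -0.5 * (dev / sigma) ** 2 - 0.5 * np.log(2 * np.pi * sigma**2)
    return logsumexp(log_terms, axis=1)


def _log_vm(delta: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    """Log Von Mises density (per radian) at angular deviation delta, broadcasting."""
    log_i0 = np.log(i0e(kappa)) + kappa
    return kappa * np.cos(delta) - np.log(2 * np.pi) - log_i0


@lru_cache(maxsize=8)
def _log_prior_grid(hyper: VonMisesNGHyper, grid: IntegrationGrid) -> tuple:
    """Normalized log prior mass on the grid: entry (i, j) integrates p(mu_i, kappa_j).

    Returned as (array, mu, kappa); normalized so logsumexp(array) == 0.
    """
    mu, kappa, log_w_mu, log_w_k = _grid_arrays(grid)
    mu0 = math.radians(hyper.mu0)
    cols = []
    for j, k in enumerate(kappa):
        sigma = 1.0 / math.sqrt(hyper.kappa0 * k)
        col = (
            _log_wrapped_normal(mu, mu0, sigma)
            + gamma_dist.logpdf(k, hyper.a0, scale=1.0 / hyper.b0)
            + log_w_mu
            + log_w_k[j]
        )
        cols.append(col)
    lp = np.stack(cols, axis=1)  # (n_mu, n_kappa)
    lp -= logsumexp(lp)
    return lp, mu, kappa


def _log_joint_grid(hyper: VonMisesNGHyper, grid: IntegrationGrid, train_deg: np.ndarray):
    """Log prior mass + summed Von Mises log likelihood of 1-D training angles."""
    lp, mu, kappa = _log_prior_grid(hyper, grid)
    lj = lp.copy()
    train_rad = np.deg2rad(np.asarray(train_deg, dtype=float))
    for y in train_rad:
        lj += _log_vm(y - mu[:, None], kappa[None, :])
    return lj, mu, kappa


def _check_circular(obs: ObservationSet) -> None:
    if not obs.all_circular:
        raise ValueError("the Von Mises family requires all-circular features")


def vonmises_log_marginal(
    hyper: VonMisesNGHyper, obs: ObservationSet, grid: IntegrationGrid = IntegrationGrid()
) -> float:
    """Log marginal likelihood of circular observations under one hidden state.

    Per-dimension quadrature of the Von Mises likelihood against the
    normal-gamma prior; dimensions multiply (independence).  Densities are
    per degree; the empty set returns 0.
    """
    _check_circular(obs)
    if obs.n_obs == 0:
        return 0.0
    total = 0.0
    for d in range(obs.n_features):
        lj, _, _ = _log_joint_grid(hyper, grid, obs.data[:, d])
        total += float(logsumexp(lj)) + obs.n_obs * _LOG_DEG_PER_RAD
    return total


def vonmises_log_predictive(
    hyper: VonMisesNGHyper,
    train: ObservationSet,
    y,
    grid: IntegrationGrid = IntegrationGrid(),
) -> float:
    """Log posterior-predictive density (per degree) of angle vector y.

    Ratio of the (train + y) joint quadrature to the train quadrature,
    evaluated per dimension on the same grid.
    """
    _check_circular(train)
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if y.size != train.n_features:
        raise ValueError(f"y must be {train.n_features}-dimensional")
    total = 0.0
    for d in range(train.n_features):
        lj, mu, kappa = _log_joint_grid(hyper, grid, train.data[:, d])
        y_rad = math.radians(y[d])
        num = lj + _log_vm(y_rad - mu[:, None], kappa[None, :])
        total += float(logsumexp(num) - logsumexp(lj)) + _LOG_DEG_PER_RAD
    return total


def _predictive_profile_1d(
    hyper: VonMisesNGHyper,
    train_deg: np.ndarray,
    grid: IntegrationGrid,
    z0_deg: float,
    n_z: int,
    step_deg: float,
) -> np.ndarray:
    """Log predictive (per degree) at the angles z0, z0 - step, ... (n_z values).

    Fast path used by offset search: when the step is an integer multiple of
    the mu-grid spacing, the Von Mises kernel only takes n_mu distinct
    angular deviations, so the profile reduces to gathers plus a matrix
    product instead of a dense (z, mu, kappa) evaluation.
    """
    lj, mu, kappa = _log_joint_grid(hyper, grid, train_deg)
    dmu_deg = 360.0 / grid.n_mu
    ratio = step_deg / dmu_deg
    r = int(round(ratio))
    if not math.isclose(ratio, r, rel_tol=0, abs_tol=1e-9):
        raise ValueError("offset step must be an integer multiple of the mu-grid spacing")
    w = np.exp(lj - logsumexp(lj))  # posterior mass on the grid, sums to 1
    z0 = math.radians(z0_deg)
    # kernel K[j_diff, k] = VM density at z0 - j_diff * dmu, for each kappa
    diffs = z0 - np.arange(grid.n_mu) * math.radians(dmu_deg)
    kern = np.exp(_log_vm(diffs[:, None], kappa[None, :]))  # (n_mu, n_kappa)
    # z_i - mu_j = z0 - (i*r + j) * dmu  ->  gather row (i*r + j) mod n_mu
    idx = (np.arange(n_z)[:, None] * r + np.arange(grid.n_mu)[None, :]) % grid.n_mu
    dens = np.zeros(n_z)
    for k in range(grid.n_kappa):
        dens += np.take(kern[:, k], idx) @ w[:, k]
    return np.log(dens) + _LOG_DEG_PER_RAD


# ---------------------------------------------------------------------------
# Uniform "likelihood family" interface consumed by the inference module
# ---------------------------------------------------------------------------


class GaussianModel:
    """Normal-Wishart Gaussian family bound to fixed hyperparameters."""

    def __init__(self, hyper: NIWHyper):
        self.hyper = hyper

    @classmethod
    def default(cls, dim: int) -> "GaussianModel":
        return cls(NIWHyper.default(dim))

    def log_marginal(self, obs: ObservationSet) -> float:
        return gaussian_log_marginal(self.hyper, obs)

    def log_predictive(self, y, train: ObservationSet) -> float:
        return gaussian_log_predictive(niw_update(self.hyper, train), y)


class VonMisesModel:
    """Von Mises circular family bound to hyperparameters and a quadrature grid."""

    def __init__(self, hyper: VonMisesNGHyper = VonMisesNGHyper(), grid: IntegrationGrid = IntegrationGrid()):
        self.hyper = hyper
        self.grid = grid

    def log_marginal(self, obs: ObservationSet) -> float:
        return vonmises_log_marginal(self.hyper, obs, self.grid)

    def log_predictive(self, y, train: ObservationSet) -> float:
        return vonmises_log_predictive(self.hyper, train, y, self.grid)
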