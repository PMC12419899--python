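"""The Bayesian Brownian bridge (BBB) generative model.

A clade's unobserved species diversity ``N_t`` evolves in log space as a
Brownian motion with per-Myr variance ``sigma2``, *bridged* between two
anchors: one species at the (unknown) origin time ``t0`` and, at the young
end, either one species at the extinction time ``te`` (extinct clades) or
the present-day richness ``n0`` at age 0 (extant clades). The fossil
record observes this trajectory through a Poisson preservation process:
the number of sampled species in each 1-Myr bin is

    x_t ~ Poisson(q(t) * N_t),      q(t) = q0 * exp(-beta * t),

so the per-lineage sampling rate ``q`` increases log-linearly toward the
present (``beta > 0``), reflecting the denser young fossil record;
``beta = 0`` recovers a constant rate. The rate is referenced at the
present (``q0`` is the rate at age 0) rather than at the clade origin:
an origin-referenced rate makes every bin's expected count depend on
``beta * t0``, which entangles the root age with the overall
preservation level and cripples the sampler's root-age mixing, while
the present-referenced form leaves root moves free of that coupling.

Time runs in Ma (age before present). The latent trajectory lives on the
global 1-Myr bin grid: bin ``k`` spans ``[k, k+1)`` Ma with midpoint
``k + 0.5``; a bin belongs to the clade's lifespan when its midpoint lies
in ``[te, t0]``. ``t0`` and ``te`` themselves are continuous. Diversity is
floored at one species (``N_t >= 1``) inside the lifespan, enforced as a
hard prior constraint.

Everything here is a pure function of arrays and scalars; no file I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "PriorConfig",
    "ModelState",
    "DomainError",
    "ShapeError",
    "lifespan_bins",
    "bin_midpoints",
    "preservation_rate",
    "bridge_log_prior",
    "observation_log_likelihood",
    "bridge_marginal_moments",
    "sample_bridge_segment",
    "log_posterior",
    "initial_state",
]

_LOG_2PI = math.log(2.0 * math.pi)


class DomainError(ValueError):
    """Parameter outside its mathematical domain."""


class ShapeError(ValueError):
    """Trajectory length inconsistent with the (t0, te) lifespan."""


@dataclass
class PriorConfig:
    """Priors and model flags for one clade analysis.

    Parameters
    ----------
    max_age:
        Upper bound (Ma) of the uniform prior on the root age ``t0``. The
        lower bound is the older edge of the oldest non-empty bin (the
        likelihood forbids younger roots anyway). Must exceed it.
    q_var:
        1 = time-increasing preservation (``beta`` sampled), 0 = constant
        rate (``beta`` pinned to 0).
    sigma2_mean, q0_mean, beta_mean:
        Means of the exponential hyperpriors on ``sigma2``, ``q0``, ``beta``.
    sigma2_min:
        Lower support bound on a *sampled* ``sigma2``. The joint density of
        (variance, trajectory) is unbounded along the collapsing direction
        where the trajectory is exactly linear and the variance shrinks to
        zero; bounding the variance keeps the sampler out of that funnel.
    fixed_sigma2, fixed_q0, fixed_beta:
        Optional point values; a fixed parameter is excluded from sampling
        and its hyperprior term drops out.
    """

    max_age: float
    q_var: int = 1
    sigma2_mean: float = 1.0
    q0_mean: float = 1.0
    beta_mean: float = 0.05
    sigma2_min: float = 1e-6
    fixed_sigma2: float | None = None
    fixed_q0: float | None = None
    fixed_beta: float | None = None

    def __post_init__(self):
        if self.max_age <= 0:
            raise DomainError("max_age must be positive")
        if self.q_var not in (0, 1):
            raise DomainError("q_var must be 0 or 1")
        if self.q_var == 0 and self.fixed_beta is None:
            self.fixed_beta = 0.0

    def sampled_parameters(self) -> list[str]:
        names = []
        if self.fixed_sigma2 is None:
            names.append("sigma2")
        if self.fixed_q0 is None:
            names.append("q0")
        if self.q_var == 1 and self.fixed_beta is None:
            names.append("beta")
        return names


@dataclass
class ModelState:
    """One point in the augmented parameter space.

    ``log_n[i]`` is the log diversity of bin ``k_lo + i`` where
    ``(k_lo, k_hi)`` is the lifespan of ``(t0, te)`` (ascending bin index,
    i.e. youngest bin first).
    """

    t0: float
    te: float
    sigma2: float
    q0: float
    beta: float
    log_n: np.ndarray

    def copy(self) -> "ModelState":
        return ModelState(self.t0, self.te, self.sigma2, self.q0, self.beta,
                          self.log_n.copy())


def lifespan_bins(t0: float, te: float) -> tuple[int, int]:
    """Indices (k_lo, k_hi) of bins whose midpoints lie in [te, t0]."""
    k_lo = max(0, int(math.ceil(te - 0.5)))
    k_hi = int(math.floor(t0 - 0.5))
    return k_lo, k_hi


def bin_midpoints(k_lo: int, k_hi: int) -> np.ndarray:
    """Midpoint ages (Ma) of bins k_lo..k_hi, ascending."""
    return np.arange(k_lo, k_hi + 1, dtype=float) + 0.5


def preservation_rate(q0: float, beta: float, t, t_ref: float):
    """Per-lineage sampling rate ``q0 * exp(beta * (t_ref - t))``.

    Strictly increasing toward the present when ``beta > 0``; equals ``q0``
    everywhere when ``beta = 0``. ``t`` may be scalar or array, ``t <= t_ref``.
    """
    if q0 <= 0:
        raise DomainError("q0 must be > 0")
    if beta < 0:
        raise DomainError("beta must be >= 0")
    if np.any(np.asarray(t) < 0):
        raise DomainError("ages must be >= 0")
    return q0 * np.exp(beta * (t_ref - np.asarray(t, dtype=float)))


def _anchor_young(extinct: bool, extant_richness: int) -> float:
    return 0.0 if extinct else math.log(extant_richness)


def _chain_times_values(log_n, t0, te, anchor_old, anchor_young):
    """Times (descending age) and values of the anchored chain old -> young."""
    k_lo, k_hi = lifespan_bins(t0, te)
    n_interior = k_hi - k_lo + 1
    if len(log_n) != max(n_interior, 0):
        raise ShapeError(
            f"trajectory length {len(log_n)} inconsistent with lifespan "
            f"bins [{k_lo}, {k_hi}] of (t0={t0}, te={te})"
        )
    mids = bin_midpoints(k_lo, k_hi)[::-1]  # descending age
    times = np.concatenate(([t0], mids, [te]))
    values = np.concatenate(([anchor_old], np.asarray(log_n, dtype=float)[::-1],
                             [anchor_young]))
    return times, values


def bridge_log_prior(
    log_n: np.ndarray,
    t0: float,
    te: float,
    sigma2: float,
    anchor_old: float = 0.0,
    anchor_young: float = 0.0,
    floor: bool = True,
) -> float:
    """Log density of the interior trajectory under the Brownian bridge.

    Computed as the product of Gaussian increment densities along the chain
    (old anchor, bin midpoints, young anchor) divided by the marginal
    density of the young anchor given the old one — i.e. the conditional
    density given both endpoints. An empty interior gives 0 (empty
    product). With ``floor`` active, any interior diversity below one
    species returns ``-inf`` (improper truncation, no renormalization).
    """
    if sigma2 <= 0:
        raise DomainError("sigma2 must be > 0")
    times, values = _chain_times_values(log_n, t0, te, anchor_old, anchor_young)
    if len(times) == 2:  # no interior bins
        return 0.0
    if floor and np.any(values[1:-1] < 0.0):
        return -math.inf
    dt = np.maximum(times[:-1] - times[1:], 1e-12)
    dy = values[1:] - values[:-1]
    var = sigma2 * dt
    log_incr = -0.5 * (_LOG_2PI + np.log(var) + dy * dy / var)
    span = max(t0 - te, 1e-12)
    dy_end = anchor_young - anchor_old
    log_marg = -0.5 * (_LOG_2PI + math.log(sigma2 * span) + dy_end * dy_end / (sigma2 * span))
    return float(log_incr.sum() - log_marg)


def observation_log_likelihood(
    counts: np.ndarray,
    log_n: np.ndarray,
    q0: float,
    beta: float,
    t0: float,
    te: float,
) -> float:
    """Poisson log likelihood of the binned counts given the trajectory.

    ``counts`` lives on the global bin grid; bins inside the lifespan
    contribute ``Poisson(x_k; q(m_k) * N_k)`` terms with the
    present-referenced rate ``q(t) = q0 * exp(-beta * t)``, and any fossil
    in a bin outside ``[te, t0]`` makes the likelihood ``-inf`` (a clade
    cannot be sampled before it originates or after it goes extinct).
    """
    counts = np.asarray(counts)
    k_lo, k_hi = lifespan_bins(t0, te)
    if np.any(counts[k_hi + 1:] > 0) or np.any(counts[:k_lo] > 0):
        return -math.inf
    if k_hi < k_lo:
        return 0.0
    x = np.zeros(k_hi - k_lo + 1)
    inside = counts[k_lo:k_hi + 1]
    x[: len(inside)] = inside
    if len(log_n) != len(x):
        raise ShapeError("trajectory and counts not aligned on the bin grid")
    mids = bin_midpoints(k_lo, k_hi)
    lam = preservation_rate(q0, beta, mids, 0.0) * np.exp(np.asarray(log_n, dtype=float))
    ll = np.where(x > 0, x * np.log(lam), 0.0) - lam - gammaln(x + 1.0)
    return float(ll.sum())


def bridge_marginal_moments(
    age_old: float, y_old: float, age_young: float, y_young: float,
    age: float, sigma2: float,
) -> tuple[float, float]:
    """Mean and variance of the bridge at ``age`` given both endpoints.

    With ``a = age_old - age`` and ``b = age - age_young`` the conditional
    is Gaussian with mean linearly interpolating the endpoints and variance
    ``sigma2 * a * b / (a + b)``.
    """
    if not (age_old >= age >= age_young):
        raise DomainError("age must lie between the anchors")
    a = age_old - age
    b = age - age_young
    span = max(a + b, 1e-12)
    mean = y_old + (y_young - y_old) * a / span
    var = sigma2 * a * b / span
    return float(mean), float(var)


def sample_bridge_segment(
    rng: np.random.Generator,
    old: tuple[float, float],
    young: tuple[float, float],
    sigma2: float,
    ages: np.ndarray,
) -> np.ndarray:
    """Exact draw of bridge values at ``ages`` given both anchors.

    ``old``/``young`` are ``(age, value)`` anchors with ``old[0] > young[0]``;
    ``ages`` are interior ages in descending order. Generated sequentially:
    each point is drawn from its Gaussian conditional given the previous
    point and the young anchor. As ``sigma2 -> 0`` the draw collapses onto
    the linear interpolation of the anchors.
    """
    if sigma2 <= 0:
        raise DomainError("sigma2 must be > 0")
    t_old, y_prev = float(old[0]), float(old[1])
    t_young, y_young = float(young[0]), float(young[1])
    if not t_old > t_young:
        raise DomainError("left anchor must be older than right anchor")
    ages = np.asarray(ages, dtype=float)
    out = np.empty(len(ages))
    t_prev = t_old
    z = rng.standard_normal(len(ages))
    for i, s in enumerate(ages):
        mean, var = bridge_marginal_moments(t_prev, y_prev, t_young, y_young, s, sigma2)
        out[i] = mean + math.sqrt(var) * z[i]
        t_prev, y_prev = s, out[i]
    return out


def _log_expon(x: float, mean: float) -> float:
    if x < 0:
        return -math.inf
    return -math.log(mean) - x / mean


def root_prior_bounds(data, prior: PriorConfig) -> tuple[float, float]:
    """Support of the uniform root-age prior: [oldest bin older edge, max_age]."""
    lower = float(data.oldest_bin + 1)
    return lower, float(prior.max_age)


def extinction_prior_upper(data) -> float:
    """Upper bound of the uniform extinction prior (youngest bin younger edge)."""
    return float(data.youngest_bin)


def log_posterior(state: ModelState, data, prior: PriorConfig) -> float:
    """Unnormalized log posterior of one augmented state.

    Sum of the bridge prior on the latent trajectory, the Poisson
    observation likelihood, the uniform root-age prior, the uniform
    extinction prior (extinct clades; extant clades pin ``te = 0``), and
    exponential hyperprior terms for whichever of ``sigma2``/``q0``/``beta``
    are sampled. Out-of-support states return ``-inf``.
    """
    lower, upper = root_prior_bounds(data, prior)
    if not (lower <= state.t0 <= upper):
        return -math.inf
    lp = -math.log(upper - lower) if upper > lower else 0.0

    if data.is_extinct:
        te_upper = extinction_prior_upper(data)
        if not (0.0 <= state.te <= te_upper):
            return -math.inf
        if te_upper > 0:
            lp += -math.log(te_upper)
    elif state.te != 0.0:
        return -math.inf

    if state.sigma2 <= 0 or state.q0 <= 0 or state.beta < 0:
        return -math.inf
    if prior.fixed_sigma2 is None:
        if state.sigma2 < prior.sigma2_min:
            return -math.inf
        lp += _log_expon(state.sigma2, prior.sigma2_mean)
    if prior.fixed_q0 is None:
        lp += _log_expon(state.q0, prior.q0_mean)
    if prior.q_var == 1 and prior.fixed_beta is None:
        lp += _log_expon(state.beta, prior.beta_mean)

    anchor_young = _anchor_young(data.is_extinct, data.extant_richness)
    lp += bridge_log_prior(state.log_n, state.t0, state.te, state.sigma2,
                           anchor_old=0.0, anchor_young=anchor_young)
    if not math.isfinite(lp):
        return -math.inf
    lp += observation_log_likelihood(data.counts, state.log_n, state.q0,
                                     state.beta, state.t0, state.te)
    return lp


def initial_state(data, prior: PriorConfig) -> ModelState:
    """Deterministic starting point for a chain.

    Root one bin-width above the oldest fossil bin edge, extinction halfway
    down its admissible range, latent trajectory on the straight line
    between the anchors (clipped to the one-species floor).
    """
    lower, upper = root_prior_bounds(data, prior)
    t0 = min(lower + 1.0, 0.5 * (lower + upper))
    te = 0.0 if not data.is_extinct else 0.5 * extinction_prior_upper(data)
    if te > 0 and abs(te - math.floor(te) - 0.5) < 1e-9:
        te -= min(0.25, te)  # keep the anchor off the bin-midpoint grid
    k_lo, k_hi = lifespan_bins(t0, te)
    mids = bin_midpoints(k_lo, k_hi)
    anchor_young = _anchor_young(data.is_extinct, data.extant_richness)
    span = max(t0 - te, 1e-12)
    log_n = anchor_young + (0.0 - anchor_young) * (mids - te) / span
    log_n = np.maximum(log_n, 0.0)
    sigma2 = prior.fixed_sigma2 if prior.fixed_sigma2 is not None else prior.sigma2_mean * 0.1
    q0 = prior.fixed_q0 if prior.fixed_q0 is not None else max(
        0.05, data.n_occurrences / max(span, 1.0))
    beta = prior.fixed_beta if prior.fixed_beta is not None else 0.005
    return ModelState(t0=t0, te=te, sigma2=float(sigma2), q0=float(q0),
                      beta=float(beta), log_n=log_n)
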