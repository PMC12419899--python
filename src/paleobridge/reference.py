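"""Brute-force reference posterior for small datasets.

Independent cross-check for the MCMC: the root and extinction ages are
integrated on an explicit (t0, te) grid, with the latent trajectory
marginalized at every grid node by plain Monte-Carlo integration over
exact Brownian-bridge draws. Common random numbers are reused across
nodes so the integration error varies smoothly along the grid and
cancels in quantile estimates.

All densities are written out self-contained here, on purpose: this
module must not share code paths with the model/sampler modules it
checks. It is only practical for desk-scale problems (a few fossil bins,
root bounded within a few tens of Myr) and with ``sigma2``, ``q0`` and
``beta`` held fixed, which keeps the marginalized space low-dimensional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = ["GridPosterior", "grid_posterior"]


@dataclass
class GridPosterior:
    """Marginal posterior of t0 (and te) on a grid, with quantile lookup."""

    t0_grid: np.ndarray
    t0_log_post: np.ndarray
    te_grid: np.ndarray
    te_log_post: np.ndarray

    @staticmethod
    def _quantile(grid: np.ndarray, log_post: np.ndarray, q: float) -> float:
        w = np.exp(log_post - log_post.max())
        cdf = np.cumsum(w)
        cdf /= cdf[-1]
        return float(np.interp(q, cdf, grid))

    def t0_quantile(self, q: float) -> float:
        return self._quantile(self.t0_grid, self.t0_log_post, q)

    def te_quantile(self, q: float) -> float:
        return self._quantile(self.te_grid, self.te_log_post, q)

    @property
    def t0_median(self) -> float:
        return self.t0_quantile(0.5)

    @property
    def te_median(self) -> float:
        return self.te_quantile(0.5)


def _node_log_marginal_likelihood(
    counts, t0, te, sigma2, q0, beta, anchor_young, z, floor
):
    """log E_bridge[likelihood] at one (t0, te) node, by Monte Carlo.

    ``z`` is an (n_paths, max_dims + 1) matrix of standard normals shared
    across nodes. Bridge draws are built by conditioning an unconditioned
    walk on its endpoint (the classic bridge construction), which is exact.
    """
    k_lo = max(0, int(math.ceil(te - 0.5)))
    k_hi = int(math.floor(t0 - 0.5))
    x = np.zeros(k_hi - k_lo + 1)
    inside = counts[k_lo:k_hi + 1]
    x[: len(inside)] = inside
    if np.any(counts[k_hi + 1:] > 0) or np.any(counts[:k_lo] > 0):
        return -math.inf
    mids = np.arange(k_hi, k_lo - 1, -1, dtype=float) + 0.5  # descending age
    d = len(mids)
    times = np.concatenate(([t0], mids, [te]))
    dt = times[:-1] - times[1:]
    # unconditioned walk from the old anchor, then bridge correction
    steps = z[:, : d + 1] * np.sqrt(sigma2 * np.maximum(dt, 1e-12))
    walk = np.cumsum(steps, axis=1)
    span = max(t0 - te, 1e-12)
    frac = (t0 - mids) / span
    y = walk[:, :d] - frac * (walk[:, d] - anchor_young)[:, None]  # old anchor at 0
    lam = q0 * np.exp(-beta * mids + y)
    x_desc = x[::-1]
    loglik = np.sum(np.where(x_desc > 0, x_desc * np.log(lam), 0.0) - lam, axis=1)
    loglik -= gammaln(x_desc + 1.0).sum()
    if floor:
        loglik = np.where(np.all(y >= 0.0, axis=1), loglik, -np.inf)
    if np.all(np.isneginf(loglik)):
        return -math.inf
    return float(logsumexp(loglik) - math.log(z.shape[0]))


def grid_posterior(
    counts,
    extinct: bool,
    max_age: float,
    sigma2: float,
    q0: float,
    beta: float = 0.0,
    extant_richness: int = 0,
    t0_step: float = 0.25,
    te_step: float = 0.5,
    n_paths: int = 4000,
    seed: int = 0,
    floor: bool = True,
) -> GridPosterior:
    """Grid quadrature of the (t0, te) posterior with MC trajectory marginals.

    ``t0`` runs from the older edge of the oldest non-empty bin to
    ``max_age``; ``te`` from 0 to the younger edge of the youngest
    non-empty bin (a single point 0 for extant clades). Uniform priors on
    both are constants and drop out. Hyperprior terms for the fixed
    ``sigma2``/``q0``/``beta`` are constants too.
    """
    counts = np.asarray(counts, dtype=float)
    nz = np.nonzero(counts)[0]
    if nz.size == 0:
        raise ValueError("counts vector has no fossils")
    lower = float(nz[-1] + 1)
    if max_age <= lower:
        raise ValueError("max_age must exceed the oldest non-empty bin edge")
    anchor_young = 0.0 if extinct else math.log(extant_richness)
    t0_grid = np.arange(lower + t0_step / 2, max_age, t0_step)
    if extinct and nz[0] > 0:
        te_grid = np.arange(te_step / 2, float(nz[0]), te_step)
    else:
        te_grid = np.array([0.0])

    rng = np.random.Generator(np.random.PCG64(seed))
    max_dims = int(math.floor(t0_grid[-1] - 0.5)) + 2
    z = rng.standard_normal((n_paths, max_dims))

    log_joint = np.empty((len(t0_grid), len(te_grid)))
    for i, t0 in enumerate(t0_grid):
        for j, te in enumerate(te_grid):
            log_joint[i, j] = _node_log_marginal_likelihood(
                counts, float(t0), float(te), sigma2, q0, beta,
                anchor_young, z, floor)
    t0_log_post = logsumexp(log_joint, axis=1)
    te_log_post = logsumexp(log_joint, axis=0)
    return GridPosterior(t0_grid, t0_log_post, te_grid, te_log_post)
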