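"""Metropolis-Hastings sampler for the Brownian-bridge model.

The sampler targets the augmented posterior over ``(t0, te, sigma2, q0,
beta, trajectory)`` with these moves:

* sliding-window updates of the root age ``t0`` (and extinction age ``te``
  for extinct clades) that jointly resample the trajectory segment between
  the moving anchor and a pivot bin from the conditional bridge prior —
  the bridge densities then cancel in the acceptance ratio, leaving the
  likelihood ratio times the ratio of the pivot's bridge-marginal
  densities (dimension changes carry unit Jacobian because new coordinates
  are proposed from their conditional prior);
* block redraws of random trajectory segments from the conditional bridge
  given their flanking values (prior cancels; accept on the likelihood);
* log-scale multiplier updates of ``sigma2``, ``q0`` and ``beta``.

Proposal scales adapt toward a 0.2-0.5 acceptance rate during burn-in
only and are frozen afterwards, preserving detailed balance for every
retained sample. Chains are independent given sub-seeds derived
deterministically from the master seed, so results are identical whether
chains run serially or concurrently.

Convergence follows the effective-sample-size rule: a run is declared
converged when every sampled parameter has ESS > 200 (Geyer
initial-positive-sequence estimator). Trace logs use the tab-separated
"Tracer" dialect (first column ``state``) for external inspection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import model
from .model import (
    ModelState,
    PriorConfig,
    bin_midpoints,
    bridge_log_prior,
    bridge_marginal_moments,
    lifespan_bins,
    sample_bridge_segment,
)

__all__ = [
    "McmcSettings",
    "Trace",
    "ParamSummary",
    "PosteriorSummary",
    "run_mcmc",
    "effective_sample_size",
    "summarize",
    "summarize_run",
    "check_convergence",
    "write_trace_log",
    "read_trace_log",
]

TRACE_PARAMS = ("posterior", "t0", "te", "sigma2", "q0", "beta")


@dataclass
class McmcSettings:
    """Chain length and bookkeeping. Defaults follow common practice for
    this model family: one million iterations sampled every thousand."""

    iterations: int = 1_000_000
    sampling_freq: int = 1_000
    burnin: float = 0.10
    seed: int = 0
    n_chains: int = 2
    n_jobs: int = 1

    def __post_init__(self):
        if self.iterations % self.sampling_freq != 0:
            raise ValueError("iterations must be divisible by sampling_freq")
        if not 0.0 <= self.burnin <= 0.5:
            raise ValueError("burnin fraction must be in [0, 0.5]")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class Trace:
    """Thinned post-burn-in samples of one chain."""

    iterations: np.ndarray
    samples: dict[str, np.ndarray]
    accept_rates: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.iterations)

    def __getitem__(self, param: str) -> np.ndarray:
        return self.samples[param]

    def as_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"state": self.iterations})
        for p in TRACE_PARAMS:
            df[p] = self.samples[p]
        return df


class _Chain:
    """Single-chain state and move kernels (internal)."""

    def __init__(self, data, prior: PriorConfig, rng: np.random.Generator,
                 prior_only: bool = False):
        self.data = data
        self.prior = prior
        self.rng = rng
        self.prior_only = prior_only
        # prior-only mode validates the kernel against the flat target:
        # the diversity floor is lifted too, so the bridge prior stays
        # normalized and the t0 marginal is exactly uniform
        self.floor = not prior_only

        self.counts = np.asarray(data.counts, dtype=np.int64)
        self.lower, self.upper = model.root_prior_bounds(data, prior)
        if self.upper <= self.lower:
            raise model.DomainError(
                f"max_age {prior.max_age} does not exceed the oldest non-empty "
                f"bin edge {self.lower} of clade {data.clade_name!r}"
            )
        self.extinct = data.is_extinct
        self.te_upper = model.extinction_prior_upper(data) if self.extinct else 0.0
        self.anchor_young = 0.0 if self.extinct else math.log(data.extant_richness)
        # counts padded to the largest possible lifespan
        k_hi_max = int(math.floor(self.upper - 0.5))
        pad = np.zeros(k_hi_max + 2, dtype=np.int64)
        pad[: len(self.counts)] = self.counts
        self.x_all = pad.astype(float)
        self.lgx_all = gammaln(self.x_all + 1.0)
        self.mids_all = np.arange(len(pad), dtype=float) + 0.5

        self.state = model.initial_state(data, prior)
        self.ll = self._loglik(self.state.t0, self.state.te, self.state.log_n,
                               self.state.q0, self.state.beta)

        weights = {"t0": 0.24, "traj": 0.32, "sigma2": 1 / 12, "q0": 1 / 12,
                   "beta": 1 / 12}
        if self.extinct and self.te_upper > 0:
            weights["te"] = 0.20
        for name in ("sigma2", "q0", "beta"):
            if name not in prior.sampled_parameters():
                weights.pop(name)
        total = sum(weights.values())
        self.move_names = list(weights)
        self.move_cum = np.cumsum([w / total for w in weights.values()])
        self.scales = {"t0": 8.0, "te": 8.0, "sigma2": 1.5, "q0": 1.5,
                       "beta": 1.5, "traj": 0.12}
        self.n_prop = {m: 0 for m in self.move_names}
        self.n_acc = {m: 0 for m in self.move_names}
        self.adapting = True

    # -- likelihood ---------------------------------------------------------
    def _loglik(self, t0, te, log_n, q0, beta) -> float:
        if self.prior_only:
            return 0.0
        k_lo, k_hi = lifespan_bins(t0, te)
        if np.any(self.counts[k_hi + 1:] > 0) or np.any(self.counts[:k_lo] > 0):
            return -math.inf
        x = self.x_all[k_lo:k_hi + 1]
        lam = q0 * np.exp(-beta * self.mids_all[k_lo:k_hi + 1] + log_n)
        ll = np.where(x > 0, x * np.log(lam), 0.0) - lam - self.lgx_all[k_lo:k_hi + 1]
        return float(ll.sum())

    @staticmethod
    def _log_normal_pdf(x, mean, var):
        var = max(var, 1e-15)  # anchors a hair off the midpoint grid
        return -0.5 * (math.log(2 * math.pi * var) + (x - mean) ** 2 / var)

    def _floor_ok(self, seg) -> bool:
        return (not self.floor) or not np.any(seg < 0.0)

    # -- moves --------------------------------------------------------------
    def move_t0(self) -> bool:
        st = self.state
        w = self.scales["t0"]
        if self.rng.random() < 0.2:
            w *= 5.0  # occasional long-range jump (mixture kernel, symmetric)
        t0p = st.t0 + self.rng.uniform(-w, w)
        if not (self.lower <= t0p <= self.upper):
            return False
        k_lo, k_hi = lifespan_bins(st.t0, st.te)
        k_hi_p = int(math.floor(t0p - 0.5))
        k_piv = min(k_hi, k_hi_p)
        if k_piv >= k_lo:
            i_piv = k_piv - k_lo
            y_piv = st.log_n[i_piv]
            m_piv = k_piv + 0.5
            if k_hi_p > k_piv:
                ages_new = np.arange(k_hi_p, k_piv, -1, dtype=float) + 0.5
                seg = sample_bridge_segment(self.rng, (t0p, 0.0), (m_piv, y_piv),
                                            st.sigma2, ages_new)
                if not self._floor_ok(seg):
                    return False
                log_n_p = np.concatenate((st.log_n[: i_piv + 1], seg[::-1]))
            else:
                log_n_p = st.log_n[: i_piv + 1].copy()
            mean_n, var_n = bridge_marginal_moments(
                t0p, 0.0, st.te, self.anchor_young, m_piv, st.sigma2)
            mean_o, var_o = bridge_marginal_moments(
                st.t0, 0.0, st.te, self.anchor_young, m_piv, st.sigma2)
            log_r = (self._log_normal_pdf(y_piv, mean_n, var_n)
                     - self._log_normal_pdf(y_piv, mean_o, var_o))
        else:  # whole interior replaced (tiny lifespans only)
            ages_new = np.arange(k_hi_p, k_lo - 1, -1, dtype=float) + 0.5
            seg = sample_bridge_segment(self.rng, (t0p, 0.0),
                                        (st.te, self.anchor_young),
                                        st.sigma2, ages_new)
            if not self._floor_ok(seg):
                return False
            log_n_p = seg[::-1]
            log_r = 0.0
        llp = self._loglik(t0p, st.te, log_n_p, st.q0, st.beta)
        if math.log(self.rng.random()) < llp - self.ll + log_r:
            st.t0 = t0p
            st.log_n = log_n_p
            self.ll = llp
            return True
        return False

    def move_te(self) -> bool:
        st = self.state
        w = self.scales["te"]
        if self.rng.random() < 0.2:
            w *= 5.0
        tep = st.te + self.rng.uniform(-w, w)
        if not (0.0 <= tep <= self.te_upper):
            return False
        k_lo, k_hi = lifespan_bins(st.t0, st.te)
        k_lo_p = max(0, int(math.ceil(tep - 0.5)))
        k_piv = max(k_lo, k_lo_p)
        i_piv = k_piv - k_lo
        y_piv = st.log_n[i_piv]
        m_piv = k_piv + 0.5
        if k_lo_p < k_piv:
            ages_new = np.arange(k_piv - 1, k_lo_p - 1, -1, dtype=float) + 0.5
            seg = sample_bridge_segment(self.rng, (m_piv, y_piv),
                                        (tep, self.anchor_young),
                                        st.sigma2, ages_new)
            if not self._floor_ok(seg):
                return False
            log_n_p = np.concatenate((seg[::-1], st.log_n[i_piv:]))
        else:
            log_n_p = st.log_n[i_piv:].copy()
        mean_n, var_n = bridge_marginal_moments(
            st.t0, 0.0, tep, self.anchor_young, m_piv, st.sigma2)
        mean_o, var_o = bridge_marginal_moments(
            st.t0, 0.0, st.te, self.anchor_young, m_piv, st.sigma2)
        log_r = (self._log_normal_pdf(y_piv, mean_n, var_n)
                 - self._log_normal_pdf(y_piv, mean_o, var_o))
        llp = self._loglik(st.t0, tep, log_n_p, st.q0, st.beta)
        if math.log(self.rng.random()) < llp - self.ll + log_r:
            st.te = tep
            st.log_n = log_n_p
            self.ll = llp
            return True
        return False

    def move_traj(self) -> bool:
        st = self.state
        d = len(st.log_n)
        if d == 0:
            return False
        i = int(self.rng.integers(0, d))
        length = int(self.rng.geometric(self.scales["traj"]))
        j = min(d - 1, i + length - 1)
        k_lo, k_hi = lifespan_bins(st.t0, st.te)
        if j == d - 1:
            old_anchor = (st.t0, 0.0)
        else:
            old_anchor = (k_lo + j + 1 + 0.5, st.log_n[j + 1])
        if i == 0:
            young_anchor = (st.te, self.anchor_young)
        else:
            young_anchor = (k_lo + i - 1 + 0.5, st.log_n[i - 1])
        ages = np.arange(k_lo + j, k_lo + i - 1, -1, dtype=float) + 0.5
        seg = sample_bridge_segment(self.rng, old_anchor, young_anchor,
                                    st.sigma2, ages)
        if not self._floor_ok(seg):
            return False
        new_slice = seg[::-1]
        if self.prior_only:
            d_ll = 0.0
        else:
            sl = slice(k_lo + i, k_lo + j + 1)
            x = self.x_all[sl]
            lam_scale = st.q0 * np.exp(-st.beta * self.mids_all[sl])
            lam_old = lam_scale * np.exp(st.log_n[i:j + 1])
            lam_new = lam_scale * np.exp(new_slice)
            d_ll = float(np.sum(x * (new_slice - st.log_n[i:j + 1])
                                - (lam_new - lam_old)))
        if math.log(self.rng.random()) < d_ll:
            st.log_n[i:j + 1] = new_slice
            self.ll += d_ll
            return True
        return False

    def _multiplier(self, name: str) -> float:
        return math.exp(self.scales[name] * (self.rng.random() - 0.5))

    def move_sigma2(self) -> bool:
        st = self.state
        m = self._multiplier("sigma2")
        s2p = st.sigma2 * m
        if s2p < self.prior.sigma2_min:
            return False
        lp_old = bridge_log_prior(st.log_n, st.t0, st.te, st.sigma2,
                                  anchor_young=self.anchor_young, floor=False)
        lp_new = bridge_log_prior(st.log_n, st.t0, st.te, s2p,
                                  anchor_young=self.anchor_young, floor=False)
        d_hyper = -(s2p - st.sigma2) / self.prior.sigma2_mean
        if math.log(self.rng.random()) < lp_new - lp_old + d_hyper + math.log(m):
            st.sigma2 = s2p
            return True
        return False

    def move_q0(self) -> bool:
        st = self.state
        m = self._multiplier("q0")
        q0p = st.q0 * m
        llp = self._loglik(st.t0, st.te, st.log_n, q0p, st.beta)
        d_hyper = -(q0p - st.q0) / self.prior.q0_mean
        if math.log(self.rng.random()) < llp - self.ll + d_hyper + math.log(m):
            st.q0 = q0p
            self.ll = llp
            return True
        return False

    def move_beta(self) -> bool:
        st = self.state
        m = self._multiplier("beta")
        bp = st.beta * m
        llp = self._loglik(st.t0, st.te, st.log_n, st.q0, bp)
        d_hyper = -(bp - st.beta) / self.prior.beta_mean
        if math.log(self.rng.random()) < llp - self.ll + d_hyper + math.log(m):
            st.beta = bp
            self.ll = llp
            return True
        return False

    # -- adaptation and bookkeeping ----------------------------------------
    _ADAPTABLE = ("t0", "te", "sigma2", "q0", "beta")

    def step(self):
        u = self.rng.random()
        name = self.move_names[int(np.searchsorted(self.move_cum, u))]
        accepted = getattr(self, f"move_{name if name != 'traj' else 'traj'}")()
        self.n_prop[name] += 1
        self.n_acc[name] += accepted
        if self.adapting and name in self._ADAPTABLE and self.n_prop[name] % 50 == 0:
            rate = self.n_acc[name] / self.n_prop[name]
            if rate < 0.2:
                self.scales[name] *= 0.8
            elif rate > 0.5:
                self.scales[name] *= 1.25
            self.n_prop[name] = 0
            self.n_acc[name] = 0

    def log_posterior(self) -> float:
        st = self.state
        lp = -math.log(self.upper - self.lower)
        if self.extinct and self.te_upper > 0:
            lp += -math.log(self.te_upper)
        pr = self.prior
        if pr.fixed_sigma2 is None:
            lp += -math.log(pr.sigma2_mean) - st.sigma2 / pr.sigma2_mean
        if pr.fixed_q0 is None:
            lp += -math.log(pr.q0_mean) - st.q0 / pr.q0_mean
        if pr.q_var == 1 and pr.fixed_beta is None:
            lp += -math.log(pr.beta_mean) - st.beta / pr.beta_mean
        lp += bridge_log_prior(st.log_n, st.t0, st.te, st.sigma2,
                               anchor_young=self.anchor_young, floor=self.floor)
        return lp + self.ll


def _run_chain(data, prior: PriorConfig, settings: McmcSettings,
               seed_seq: np.random.SeedSequence, prior_only: bool) -> Trace:
    rng = np.random.Generator(np.random.PCG64(seed_seq))
    chain = _Chain(data, prior, rng, prior_only=prior_only)
    burn = int(settings.burnin * settings.iterations)
    iters, rows = [], {p: [] for p in TRACE_PARAMS}
    for it in range(1, settings.iterations + 1):
        if chain.adapting and it > burn:
            chain.adapting = False
        chain.step()
        if it % settings.sampling_freq == 0 and it > burn:
            st = chain.state
            iters.append(it)
            rows["posterior"].append(chain.log_posterior())
            rows["t0"].append(st.t0)
            rows["te"].append(st.te)
            rows["sigma2"].append(st.sigma2)
            rows["q0"].append(st.q0)
            rows["beta"].append(st.beta)
    rates = {m: (chain.n_acc[m] / chain.n_prop[m] if chain.n_prop[m] else math.nan)
             for m in chain.move_names}
    return Trace(np.asarray(iters), {p: np.asarray(v) for p, v in rows.items()},
                 accept_rates=rates)


def run_mcmc(data, prior: PriorConfig, settings: McmcSettings,
             prior_only: bool = False) -> list[Trace]:
    """Run ``settings.n_chains`` independent chains and return their traces.

    Sub-seeds derive deterministically from ``settings.seed``; with
    ``settings.n_jobs > 1`` chains run concurrently (joblib) with identical
    results. ``prior_only=True`` targets the prior with a flat likelihood
    and no diversity floor — a validation mode for the kernel itself.
    """
    if np.asarray(data.counts).sum() == 0:
        raise ValueError("dataset has no fossil occurrences")
    seed_seqs = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    if settings.n_jobs > 1 and settings.n_chains > 1:
        from joblib import Parallel, delayed

        return Parallel(n_jobs=settings.n_jobs)(
            delayed(_run_chain)(data, prior, settings, ss, prior_only)
            for ss in seed_seqs
        )
    return [_run_chain(data, prior, settings, ss, prior_only) for ss in seed_seqs]


def effective_sample_size(series) -> float:
    """Autocorrelation-time ESS with Geyer's initial-positive-sequence rule.

    The sum of autocorrelations is truncated at the first nonpositive sum
    of adjacent lag pairs. A zero-variance series returns its length with
    a degeneracy warning. Requires at least 10 samples.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples for an ESS estimate")
    xc = x - x.mean()
    if np.allclose(xc, 0.0):
        warnings.warn("zero-variance series; ESS set to the series length")
        return float(n)
    nfft = int(2 ** math.ceil(math.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    pair_sums = rho[0:-1:2] + rho[1::2]
    tau = 0.0
    for g in pair_sums:
        if g <= 0:
            break
        tau += g
    tau = max(2.0 * tau - 1.0, 1.0 / n)
    return float(n / tau)


@dataclass
class ParamSummary:
    median: float
    ci_low: float
    ci_high: float
    ess: float


def summarize(traces: list[Trace], param: str) -> ParamSummary:
    """Pooled median and equal-tailed 95% interval; ESS summed per chain.

    Quantiles use the linear-interpolation rule. Fewer than 100 pooled
    samples raises a low-sample warning (the summary is still computed).
    """
    pooled = np.concatenate([t[param] for t in traces])
    if len(pooled) < 100:
        warnings.warn(f"only {len(pooled)} pooled samples for {param!r}; "
                      "interval estimates may be unstable")
    lo, med, hi = np.quantile(pooled, [0.025, 0.5, 0.975])
    ess = sum(effective_sample_size(t[param]) for t in traces)
    return ParamSummary(float(med), float(lo), float(hi), float(ess))


def check_convergence(ess: dict[str, float], threshold: float = 200.0):
    """Converged iff every parameter's ESS exceeds the threshold."""
    if not ess:
        raise ValueError("no ESS entries to assess")
    failing = sorted(p for p, v in ess.items() if v <= threshold)
    return (len(failing) == 0), failing


@dataclass
class PosteriorSummary:
    """Per-run posterior summary: root age, extinction age (extinct clades),
    ESS per sampled parameter and the ESS>200 convergence flag."""

    clade: str
    rank: str
    n_occurrences: int
    is_extinct: bool
    root: ParamSummary
    extinction: ParamSummary | None
    ess: dict[str, float]
    converged: bool
    failing: list[str] = field(default_factory=list)
    suborder: str | None = None
    propagated_from: str | None = None


def summarize_run(traces: list[Trace], data, prior: PriorConfig,
                  ess_threshold: float = 200.0) -> PosteriorSummary:
    root = summarize(traces, "t0")
    ext = summarize(traces, "te") if data.is_extinct else None
    params = ["t0"] + (["te"] if (data.is_extinct and data.youngest_bin > 0) else [])
    params += prior.sampled_parameters()
    ess = {}
    for p in params:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess[p] = sum(effective_sample_size(t[p]) for t in traces)
    converged, failing = check_convergence(ess, ess_threshold)
    return PosteriorSummary(
        clade=data.clade_name, rank=data.rank, n_occurrences=data.n_occurrences,
        is_extinct=data.is_extinct, root=root, extinction=ext, ess=ess,
        converged=converged, failing=failing, suborder=data.suborder,
    )


def write_trace_log(trace: Trace, sink) -> None:
    """Write a tab-separated trace log (first column ``state``)."""
    if len(trace) == 0:
        raise ValueError("refusing to write an empty trace")
    try:
        trace.as_dataframe().to_csv(sink, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"could not write trace log to {sink}: {exc}") from exc


def read_trace_log(source) -> Trace:
    df = pd.read_csv(source, sep="\t", float_precision="round_trip")
    return Trace(df["state"].to_numpy(),
                 {p: df[p].to_numpy() for p in TRACE_PARAMS})
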