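"""Synthetic fossil-record generator for benchmark and recovery tests.

Clades are simulated *forward* in time: log diversity starts at zero (one
species) at the origin ``t0`` and performs an unconditioned driftless
random walk with per-Myr variance ``sigma2`` down the 1-Myr bin grid.
A clade goes extinct the first time its diversity drops below one
species; ``extant`` simulations keep only walks surviving to the present
(rejection sampling), ``extinct`` simulations only walks dying before it.
Fossil counts are then drawn per bin from the same Poisson preservation
process the inference assumes, with the present-referenced rate
``q0 * exp(-beta * t)``.

Because the generator is a forward walk with rejection — not a bridge —
it is mechanistically independent of the inference machinery, making
parameter-recovery runs a genuine cross-check rather than a round trip
through shared code.

Default truth ranges are sized to the deep-time insect record the model
is built for: origins between 80 and 320 Ma, log-diversity variances of
0.01-0.1 per Myr, baseline preservation of 0.005-0.05 sampled species
per lineage per Myr with a mild increase toward the present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .occurrences import CladeDataset

__all__ = [
    "SimulatedClade",
    "SimulationRanges",
    "RejectionError",
    "random_walk_log_diversity",
    "simulate_trajectory",
    "simulate_fossil_counts",
    "make_benchmark_suite",
    "PRESETS",
    "write_suite",
]

#: benchmark presets: (number of extant clades, number of extinct clades)
PRESETS = {"extant10": (10, 0), "mixed5_5": (5, 5), "extinct10": (0, 10)}


class RejectionError(RuntimeError):
    """Rejection sampling failed within the configured cap."""


@dataclass
class SimulationRanges:
    """Uniform truth ranges used by the benchmark suites (overridable)."""

    t0: tuple[float, float] = (80.0, 320.0)
    sigma2: tuple[float, float] = (0.01, 0.1)
    q0: tuple[float, float] = (0.005, 0.05)
    beta: tuple[float, float] = (0.0, 0.01)
    min_occurrences: int = 3
    max_tries: int = 100_000


@dataclass
class SimulatedClade:
    """A simulated clade: the generating truth plus the observable dataset."""

    name: str
    t0: float
    te: float
    sigma2: float
    q0: float
    beta: float
    bins: np.ndarray      # bin indices of the lifespan, ascending
    log_n: np.ndarray     # latent log diversity per lifespan bin
    dataset: CladeDataset

    @property
    def is_extinct(self) -> bool:
        return self.te > 0.0

    def truth_row(self) -> dict:
        return {
            "clade": self.name, "t0": self.t0, "te": self.te,
            "sigma2": self.sigma2, "q0": self.q0, "beta": self.beta,
            "extant_richness": self.dataset.extant_richness,
            "n_occurrences": self.dataset.n_occurrences,
        }


def random_walk_log_diversity(rng: np.random.Generator, t0: float, sigma2: float):
    """One *unconditioned* log-diversity walk from the origin to the present.

    Returns ``(mids, y, y_present)``: bin midpoints in descending age, the
    walk values there (starting from 0 at ``t0``), and the value at age 0.
    No extinction censoring is applied — this is the raw driftless walk the
    conditioned simulations reject from.
    """
    k_hi = int(math.floor(t0 - 0.5))
    mids = np.arange(k_hi, -1, -1, dtype=float) + 0.5  # descending age
    dt = np.concatenate(([t0 - mids[0]], -np.diff(mids)))
    steps = rng.standard_normal(len(mids)) * np.sqrt(sigma2 * dt)
    y = np.cumsum(steps)
    y_present = y[-1] + rng.standard_normal() * math.sqrt(sigma2 * 0.5)
    return mids, y, y_present


def simulate_trajectory(
    rng: np.random.Generator,
    t0: float,
    sigma2: float,
    mode: str,
    max_tries: int = 100_000,
):
    """Forward-simulate one log-diversity walk from ``t0`` to its end.

    Returns ``(bins, log_n, te, log_n_present)`` where ``bins`` are the
    lifespan bin indices (ascending), ``log_n`` the log diversity at their
    midpoints, ``te`` the extinction age (0 for extant clades) and
    ``log_n_present`` the walk value at age 0 (extant mode only, else NaN).

    ``mode="extant"`` rejects walks that die before the present;
    ``mode="extinct"`` rejects walks that survive. With ``sigma2 = 0`` the
    walk is flat at one species and only the extant mode can succeed.
    Extinction is recorded at the older edge of the first bin whose
    diversity falls below one species, so the returned trajectory always
    satisfies ``N >= 1`` on ``[te, t0]``.
    """
    if t0 <= 0:
        raise ValueError("t0 must be positive")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if mode not in ("extant", "extinct"):
        raise ValueError(f"mode must be 'extant' or 'extinct', got {mode!r}")
    k_hi = int(math.floor(t0 - 0.5))
    for _ in range(max_tries):
        mids, y, y_present = random_walk_log_diversity(rng, t0, sigma2)
        below = np.nonzero(y < 0.0)[0]
        if below.size == 0:  # survived to the last bin midpoint
            if mode == "extinct" or y_present < 0.0:
                continue
            bins = np.arange(0, k_hi + 1)
            return bins, y[::-1].copy(), 0.0, float(y_present)
        if mode == "extant":
            continue
        crash = int(below[0])
        if crash == 0:  # died in its very first bin; no lifespan bins at all
            continue
        te = float(k_hi - crash + 1)  # older edge of the crash bin
        bins = np.arange(k_hi - crash + 1, k_hi + 1)
        return bins, y[:crash][::-1].copy(), te, math.nan
    raise RejectionError(
        f"no {mode} realization in {max_tries} tries for t0={t0}, "
        f"sigma2={sigma2}; consider different parameters"
    )


def simulate_fossil_counts(
    rng: np.random.Generator,
    bins: np.ndarray,
    log_n: np.ndarray,
    q0: float,
    beta: float,
) -> np.ndarray:
    """Draw per-bin Poisson fossil counts on the global grid.

    Counts are ``Poisson(q(t) * N_t)`` with ``q(t) = q0 * exp(-beta * t)``
    inside the lifespan and exactly zero outside; the returned vector spans
    bins ``0..max(bins)``.
    """
    if q0 < 0 or beta < 0:
        raise ValueError("q0 and beta must be >= 0")
    bins = np.asarray(bins)
    counts = np.zeros(int(bins.max()) + 1, dtype=np.int64)
    if q0 == 0:
        return counts
    mids = bins + 0.5
    lam = q0 * np.exp(-beta * mids + np.asarray(log_n, dtype=float))
    counts[bins] = rng.poisson(lam)
    return counts


def _simulate_clade(rng, name, mode, ranges: SimulationRanges) -> SimulatedClade:
    for _ in range(ranges.max_tries):
        t0 = rng.uniform(*ranges.t0)
        sigma2 = rng.uniform(*ranges.sigma2)
        q0 = rng.uniform(*ranges.q0)
        beta = rng.uniform(*ranges.beta)
        try:
            bins, log_n, te, y_present = simulate_trajectory(
                rng, t0, sigma2, mode, max_tries=1_000)
        except RejectionError:
            continue
        counts = simulate_fossil_counts(rng, bins, log_n, q0, beta)
        if counts.sum() < ranges.min_occurrences:
            continue
        richness = 0 if mode == "extinct" else max(1, round(math.exp(y_present)))
        dataset = CladeDataset(clade_name=name, rank="family",
                               extant_richness=richness, counts=counts)
        return SimulatedClade(name=name, t0=t0, te=te, sigma2=sigma2, q0=q0,
                              beta=beta, bins=bins, log_n=log_n, dataset=dataset)
    raise RejectionError(f"could not simulate a usable {mode} clade for {name}")


def make_benchmark_suite(preset: str, seed: int,
                         ranges: SimulationRanges | None = None) -> list[SimulatedClade]:
    """Generate a benchmark suite: ``extant10`` (10 extant), ``mixed5_5``
    (5 extant + 5 extinct) or ``extinct10`` (10 extinct). Deterministic in
    ``seed``."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    ranges = ranges or SimulationRanges()
    n_extant, n_extinct = PRESETS[preset]
    rng = np.random.Generator(np.random.PCG64(seed))
    suite = []
    for i in range(n_extant):
        suite.append(_simulate_clade(rng, f"sim_extant_{i + 1:02d}", "extant", ranges))
    for i in range(n_extinct):
        suite.append(_simulate_clade(rng, f"sim_extinct_{i + 1:02d}", "extinct", ranges))
    return suite


def write_suite(suite: list[SimulatedClade], outdir) -> None:
    """Write one TSV count vector per clade plus a truth-table TSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for clade in suite:
        df = pd.DataFrame({"bin": np.arange(len(clade.dataset.counts)),
                           "count": clade.dataset.counts})
        df.to_csv(outdir / f"{clade.name}_counts.tsv", sep="\t", index=False)
    truth = pd.DataFrame([c.truth_row() for c in suite])
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
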