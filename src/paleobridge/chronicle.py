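"""Full-analysis orchestration: multi-rank batch runs under several
root-age priors, prior-sensitivity testing and period-wise event tallies.

The batch runner executes one MCMC analysis per (clade, max_age) pair
from the analysis plan — families, superfamilies, infraorders, suborders,
plus one pooled order-level run — propagates monotypic higher ranks from
their single lower-rank member, and records every failure and
non-converged run instead of dropping it. Per-run seeds are derived by
hashing (master seed, clade, rank, max_age), so adding clades never
perturbs other clades' chains.

Sensitivity of root-age medians to the max-age prior is assessed with a
paired two-sided Wilcoxon signed-rank test per setting pair on the
family-level medians (with a two-sample Kolmogorov-Smirnov statistic as
a secondary report). Originations and extinctions are tallied per
geological period per suborder from the posterior medians, with ages on
a period boundary assigned to the older period.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .occurrences import (
    EmptyCladeError,
    PlanEntry,
    assemble_clade_dataset,
    build_analysis_plan,
    deduplicate_occurrences,
    read_occurrence_table,
    read_richness_table,
)
from .model import PriorConfig
from .sampler import McmcSettings, PosteriorSummary, run_mcmc, summarize_run, write_trace_log
from .timescale import GeoTimescale, load_default_timescale

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "AnalysisResult",
    "derive_seed",
    "run_analysis",
    "prior_sensitivity_test",
    "count_events_by_period",
    "write_summary_table",
    "read_summary_table",
]

DEFAULT_MAX_AGES = (325.0, 350.0, 386.0, 407.0)

SUMMARY_COLUMNS = [
    "clade", "rank", "max_age", "suborder", "n_occurrences", "extinct",
    "root_median", "root_ci_low", "root_ci_high",
    "ext_median", "ext_ci_low", "ext_ci_high",
    "ess_min", "converged", "propagated_from",
]


@dataclass
class RunConfig:
    """Inputs and settings for one batch analysis."""

    occurrences: str
    richness: str | None = None
    timescale: str | None = None
    max_ages: tuple[float, ...] = DEFAULT_MAX_AGES
    q_var: int = 1
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    outdir: str | None = None
    seed: int = 0
    order_name: str = "order-level"
    write_traces: bool = False

    def __post_init__(self):
        if not self.max_ages:
            raise ValueError("max_ages must be non-empty")


@dataclass
class AnalysisResult:
    summaries: pd.DataFrame
    failures: list[dict]
    plan: list[PlanEntry]

    @property
    def ok(self) -> bool:
        return not self.failures


def derive_seed(master_seed: int, clade: str, rank: str, max_age: float) -> int:
    """Stable per-run sub-seed below 2**31, independent of other runs."""
    key = f"{master_seed}:{clade}:{rank}:{max_age}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "little") % (2**31)


def _summary_row(s: PosteriorSummary, max_age: float) -> dict:
    return {
        "clade": s.clade, "rank": s.rank, "max_age": max_age,
        "suborder": s.suborder, "n_occurrences": s.n_occurrences,
        "extinct": s.is_extinct,
        "root_median": s.root.median, "root_ci_low": s.root.ci_low,
        "root_ci_high": s.root.ci_high,
        "ext_median": s.extinction.median if s.extinction else math.nan,
        "ext_ci_low": s.extinction.ci_low if s.extinction else math.nan,
        "ext_ci_high": s.extinction.ci_high if s.extinction else math.nan,
        "ess_min": min(s.ess.values()), "converged": s.converged,
        "propagated_from": s.propagated_from,
    }


def run_analysis(config: RunConfig, occs=None, richness=None,
                 timescale: GeoTimescale | None = None) -> AnalysisResult:
    """Run the full multi-rank, multi-prior batch.

    Tables may be passed in-memory (``occs``/``richness``) or read from the
    paths in ``config``. Returns one summary row per (clade, max_age),
    including propagation aliases and the pooled order-level run; failed
    runs are collected in ``failures``, never silently dropped.
    """
    ts = timescale or (GeoTimescale.from_csv(config.timescale)
                       if config.timescale else load_default_timescale())
    if occs is None:
        occs = read_occurrence_table(config.occurrences)
    if not occs:
        raise ValueError("empty occurrence table")
    if richness is None and config.richness:
        richness = read_richness_table(config.richness)

    occs = deduplicate_occurrences(occs, ts)
    plan = build_analysis_plan(occs)
    plan_runs = [e for e in plan if e.action == "run"]
    plan_aliases = [e for e in plan if e.action == "alias"]

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    rows: list[dict] = []
    failures: list[dict] = []
    run_index: dict[tuple[str, str, float], dict] = {}
    seeds_used: dict[str, int] = {}

    order_entry = PlanEntry(config.order_name, "order", "run")
    for entry in plan_runs + [order_entry]:
        try:
            data = assemble_clade_dataset(occs, entry.clade, entry.rank, richness)
            if entry.suborder and data.suborder is None:
                data.suborder = entry.suborder
        except EmptyCladeError as exc:
            failures.append({"clade": entry.clade, "rank": entry.rank,
                             "max_age": None, "error": str(exc)})
            continue
        for max_age in config.max_ages:
            seed = derive_seed(config.seed, entry.clade, entry.rank, max_age)
            seeds_used[f"{entry.clade}:{entry.rank}:{max_age}"] = seed
            settings = McmcSettings(
                iterations=config.mcmc.iterations,
                sampling_freq=config.mcmc.sampling_freq,
                burnin=config.mcmc.burnin, seed=seed,
                n_chains=config.mcmc.n_chains, n_jobs=config.mcmc.n_jobs)
            prior = PriorConfig(max_age=max_age, q_var=config.q_var)
            try:
                traces = run_mcmc(data, prior, settings)
                summary = summarize_run(traces, data, prior)
            except Exception as exc:  # noqa: BLE001 - recorded, not dropped
                logger.error("run failed for %s %s at max_age %s: %s",
                             entry.rank, entry.clade, max_age, exc)
                failures.append({"clade": entry.clade, "rank": entry.rank,
                                 "max_age": max_age, "error": str(exc)})
                continue
            row = _summary_row(summary, max_age)
            rows.append(row)
            run_index[(entry.clade, entry.rank, max_age)] = row
            if outdir and config.write_traces:
                for c, tr in enumerate(traces):
                    name = f"{entry.rank}_{entry.clade}_m{max_age:g}_c{c}.log"
                    write_trace_log(tr, outdir / name.replace(" ", "_"))

    for entry in plan_aliases:
        for max_age in config.max_ages:
            src = run_index.get((entry.target_clade, entry.target_rank, max_age))
            if src is None:
                failures.append({
                    "clade": entry.clade, "rank": entry.rank, "max_age": max_age,
                    "error": f"propagation source {entry.target_rank} "
                             f"{entry.target_clade!r} did not produce a summary"})
                continue
            row = dict(src)
            row.update(clade=entry.clade, rank=entry.rank,
                       suborder=entry.suborder or src["suborder"],
                       propagated_from=f"{entry.target_rank}:{entry.target_clade}")
            rows.append(row)

    rank_order = {"family": 0, "superfamily": 1, "infraorder": 2,
                  "suborder": 3, "order": 4}
    summaries = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if not summaries.empty:
        summaries = summaries.sort_values(
            ["rank", "clade", "max_age"],
            key=lambda s: s.map(rank_order) if s.name == "rank" else s,
        ).reset_index(drop=True)

    if outdir:
        write_summary_table(summaries, outdir / "summary.tsv")
        manifest = {
            "package_version": __version__,
            "master_seed": config.seed,
            "max_ages": list(config.max_ages),
            "q_var": config.q_var,
            "iterations": config.mcmc.iterations,
            "sampling_freq": config.mcmc.sampling_freq,
            "burnin": config.mcmc.burnin,
            "n_chains": config.mcmc.n_chains,
            "n_analyses": len(rows),
            "n_failures": len(failures),
            "seeds": seeds_used,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return AnalysisResult(summaries=summaries, failures=failures, plan=plan)


def prior_sensitivity_test(summaries: pd.DataFrame, rank: str = "family",
                           value: str = "root_median", min_pairs: int = 6) -> pd.DataFrame:
    """Pairwise paired tests of medians across the max-age settings.

    For every pair of settings: a two-sided Wilcoxon signed-rank test on
    the per-clade medians (paired by clade at the given rank), plus a
    Kolmogorov-Smirnov two-sample statistic as a secondary report. If all
    paired differences vanish the null is exactly retained (p = 1).
    Fewer than ``min_pairs`` complete pairs yields a power warning row
    with no p-value.
    """
    sub = summaries[summaries["rank"] == rank]
    if sub.empty:
        raise ValueError(f"no summaries at rank {rank!r}")
    wide = sub.pivot_table(index="clade", columns="max_age", values=value)
    settings = sorted(wide.columns)
    rows = []
    for i, a in enumerate(settings):
        for b in settings[i + 1:]:
            pair = wide[[a, b]].dropna()
            n = len(pair)
            row = {"setting_a": a, "setting_b": b, "n_pairs": n}
            if n < min_pairs:
                row.update(statistic=math.nan, pvalue=math.nan,
                           ks_statistic=math.nan, ks_pvalue=math.nan,
                           warning=f"only {n} pairs; too few for a test")
                rows.append(row)
                continue
            diffs = pair[a] - pair[b]
            if np.allclose(diffs, 0.0):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.wilcoxon(pair[a], pair[b], zero_method="wilcox",
                                         alternative="two-sided")
            ks_stat, ks_p = stats.ks_2samp(pair[a], pair[b])
            row.update(statistic=float(stat), pvalue=float(p),
                       ks_statistic=float(ks_stat), ks_pvalue=float(ks_p),
                       warning="")
            rows.append(row)
    return pd.DataFrame(rows)


def count_events_by_period(summaries: pd.DataFrame,
                           ts: GeoTimescale | None = None) -> pd.DataFrame:
    """Tally originations and extinctions per geological period per suborder.

    Each clade contributes one origination in the period containing its
    root-age median and, if extinct, one extinction in the period of its
    extinction-age median; boundary ages go to the older period. Returns
    the full (period x suborder x event) grid including zero counts, in
    timescale order. A median outside the timescale span raises an error
    naming the clade.
    """
    ts = ts or load_default_timescale()
    periods = ts.period_names()
    suborders = sorted({s for s in summaries.get("suborder", pd.Series(dtype=object))
                        if isinstance(s, str) and s})
    if not suborders:
        suborders = ["(unassigned)"]
    counts: dict[tuple[str, str, str], int] = {
        (p, s, e): 0 for p in periods for s in suborders
        for e in ("origination", "extinction")}

    def _assign(age: float, clade: str) -> str:
        try:
            return ts.period_at(age).name
        except Exception as exc:
            raise ValueError(
                f"median {age} Ma of clade {clade!r} lies outside the "
                f"timescale span") from exc

    for row in summaries.itertuples(index=False):
        sub = row.suborder if isinstance(row.suborder, str) and row.suborder \
            else "(unassigned)"
        if sub not in suborders:
            continue
        counts[(_assign(row.root_median, row.clade), sub, "origination")] += 1
        if getattr(row, "extinct", False) and not math.isnan(row.ext_median):
            counts[(_assign(row.ext_median, row.clade), sub, "extinction")] += 1

    out = pd.DataFrame(
        [{"period": p, "suborder": s, "event": e, "count": c}
         for (p, s, e), c in counts.items()])
    out["period"] = pd.Categorical(out["period"], categories=periods, ordered=True)
    return out.sort_values(["period", "suborder", "event"]).reset_index(drop=True)


def write_summary_table(summaries: pd.DataFrame, sink) -> None:
    """Write the per-(clade, max_age) summary TSV with stable row order."""
    if summaries.empty:
        raise ValueError("refusing to write an empty summary table")
    try:
        summaries.to_csv(sink, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"could not write summary table to {sink}: {exc}") from exc


def read_summary_table(source) -> pd.DataFrame:
    return pd.read_csv(source, sep="\t")
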