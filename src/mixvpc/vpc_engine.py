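"""Traditional and mixture-specific visual predictive checks.

A VPC compares percentiles of observed concentrations, binned over time,
against confidence bands for the same percentiles computed from many
datasets simulated under the model.  The mixture-specific variant first
allocates every individual — observed and simulated alike — to a
subpopulation (by MIXEST or by randomized IP_mix draws, after a
fixed-parameter evaluation of each simulated replicate at the final
estimates) and builds one panel per subpopulation, annotated with the
population mixture estimate (PMIX) and the allocation percentages for
original (ORIGID) and simulated (SIMID) individuals.

Computation is strictly separated from rendering: every VPC operation
returns a plain :class:`VPCResult` data product; ``render_vpc`` turns it
into a figure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allocation import allocate_run, allocation_summary, AllocationSummary
from .datamodel import Dataset, FitResult
from .mixture_inference import LikelihoodSettings, ModelSpec, evaluate
from .simulator import simulate_replicates

__all__ = [
    "VPCConfig",
    "VPCResult",
    "StratumResult",
    "BinResult",
    "bin_observations",
    "percentile_bands",
    "mixture_vpc",
    "traditional_vpc",
    "separation_histogram",
    "SeparationHistogram",
    "vpc_result_to_frame",
    "render_vpc",
    "render_separation",
]

_NOMINAL_TOL = 1e-9


@dataclass(frozen=True)
class VPCConfig:
    percentiles: tuple = (5.0, 50.0, 95.0)
    ci_level: float = 0.95
    n_replicates: int = 200
    binning: str = "nominal-times"   # 'nominal-times' | 'quantile'
    n_bins: int = 6                  # quantile mode only
    strategy: str = "none"           # 'none' | 'mixest' | 'randomized'
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.percentiles, dtype=float)
        if np.any(p <= 0) or np.any(p >= 100) or np.any(np.diff(p) <= 0):
            raise ValueError("percentiles must be strictly increasing in (0, 100)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.n_replicates < 20:
            raise ValueError("at least 20 replicates are needed for CI output")
        if self.binning not in ("nominal-times", "quantile"):
            raise ValueError(f"unknown binning mode {self.binning!r}")
        if self.strategy not in ("none", "mixest", "randomized"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


class Binning:
    """A fixed set of time bins applied identically to observed data and to
    every simulated replicate."""

    def __init__(self, mode: str, edges: np.ndarray | None, nominal: np.ndarray | None):
        self.mode = mode
        self.edges = edges
        self.nominal = nominal

    @property
    def n_bins(self) -> int:
        return len(self.nominal) if self.mode == "nominal-times" else len(self.edges) - 1

    def midpoints(self) -> np.ndarray:
        if self.mode == "nominal-times":
            return self.nominal
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def intervals(self):
        if self.mode == "nominal-times":
            return [(t, t) for t in self.nominal]
        return list(zip(self.edges[:-1], self.edges[1:]))

    def assign(self, times: np.ndarray) -> np.ndarray:
        """Bin index per time; −1 where no bin matches (nominal mode)."""
        times = np.asarray(times, dtype=float)
        if self.mode == "nominal-times":
            idx = np.searchsorted(self.nominal, times)
            out = np.full(times.shape, -1, dtype=int)
            for cand in (idx, idx - 1):
                cand_c = np.clip(cand, 0, len(self.nominal) - 1)
                hit = np.abs(times - self.nominal[cand_c]) <= _NOMINAL_TOL
                out = np.where((out < 0) & hit, cand_c, out)
            return out
        # left-closed right-open, last bin closed
        idx = np.searchsorted(self.edges, times, side="right") - 1
        idx = np.where(times == self.edges[-1], len(self.edges) - 2, idx)
        idx = np.where((times < self.edges[0]) | (times > self.edges[-1]), -1, idx)
        return idx


def make_binning(times: np.ndarray, config: VPCConfig) -> Binning:
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("binning requires at least one observation")
    if config.binning == "nominal-times":
        nominal = np.unique(np.round(times / _NOMINAL_TOL) * _NOMINAL_TOL)
        # merge values equal within tolerance
        keep = [nominal[0]]
        for t in nominal[1:]:
            if t - keep[-1] > _NOMINAL_TOL:
                keep.append(t)
        return Binning("nominal-times", None, np.asarray(keep))
    distinct = np.unique(times)
    if config.n_bins > distinct.size:
        raise ValueError(
            f"quantile binning with {config.n_bins} bins needs at least that many "
            f"distinct times (got {distinct.size})"
        )
    qs = np.linspace(0, 100, config.n_bins + 1)
    edges = np.percentile(times, qs)
    edges = np.unique(edges)
    return Binning("quantile", edges, None)


def bin_observations(times, values, config: VPCConfig, binning: Binning | None = None):
    """Group (time, value) pairs into bins; returns (Binning, list of value
    arrays per bin)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if binning is None:
        binning = make_binning(times, config)
    idx = binning.assign(times)
    per_bin = [values[idx == b] for b in range(binning.n_bins)]
    return binning, per_bin


@dataclass
class BinResult:
    interval: tuple
    midpoint: float
    n_obs: int
    obs_pct: np.ndarray          # (P,) observed percentile values
    ci_lo: np.ndarray            # (P,) lower CI bound across replicates
    ci_mid: np.ndarray
    ci_hi: np.ndarray
    outside: np.ndarray          # (P,) bool; False where CI unavailable
    ci_available: np.ndarray     # (P,) bool


@dataclass
class StratumResult:
    label: str
    bins: list
    n_obs_total: int = 0
    empty: bool = False

    @property
    def n_outside(self) -> int:
        return int(sum(b.outside.sum() for b in self.bins))

    @property
    def n_cells(self) -> int:
        return int(sum(b.ci_available.sum() for b in self.bins))


@dataclass
class VPCResult:
    kind: str                    # 'traditional' | 'mixest' | 'randomized'
    strata: list
    config: VPCConfig
    allocation: AllocationSummary | None = None
    warnings: list = field(default_factory=list)

    @property
    def n_outside(self) -> int:
        return sum(s.n_outside for s in self.strata)

    @property
    def n_cells(self) -> int:
        return sum(s.n_cells for s in self.strata)


def percentile_bands(obs_times, obs_values, sim_per_replicate, config: VPCConfig,
                     binning: Binning | None = None, label: str = "all") -> StratumResult:
    """One VPC stratum: observed percentiles per bin plus simulation CIs.

    ``sim_per_replicate`` is a list of (times, values) pairs, each binned
    with the same binning as the observed data.  A bin left empty by any
    replicate has its CI marked unavailable rather than raising.
    """
    obs_values = np.asarray(obs_values, dtype=float)
    binning, obs_bins = bin_observations(obs_times, obs_values, config, binning)
    P = len(config.percentiles)
    alpha = 100.0 * (1.0 - config.ci_level) / 2.0
    R = len(sim_per_replicate)
    sim_pct = np.full((R, binning.n_bins, P), np.nan)
    for r, (st, sv) in enumerate(sim_per_replicate):
        _, sim_bins = bin_observations(st, sv, config, binning)
        for b, vals in enumerate(sim_bins):
            if vals.size:
                sim_pct[r, b] = np.percentile(vals, config.percentiles)
    bins = []
    intervals = binning.intervals()
    mids = binning.midpoints()
    for b, vals in enumerate(obs_bins):
        if vals.size:
            obs_pct = np.percentile(vals, config.percentiles)
        else:
            obs_pct = np.full(P, np.nan)
        col = sim_pct[:, b, :]
        available = np.all(np.isfinite(col), axis=0) & np.isfinite(obs_pct)
        if R and np.any(available):
            lo = np.percentile(col, alpha, axis=0)
            mid = np.percentile(col, 50.0, axis=0)
            hi = np.percentile(col, 100.0 - alpha, axis=0)
        else:
            lo = mid = hi = np.full(P, np.nan)
        lo = np.where(available, lo, np.nan)
        mid = np.where(available, mid, np.nan)
        hi = np.where(available, hi, np.nan)
        outside = available & ((obs_pct < lo) | (obs_pct > hi))
        bins.append(BinResult(intervals[b], float(mids[b]), int(vals.size),
                              obs_pct, lo, mid, hi, outside, available))
    return StratumResult(label, bins, n_obs_total=int(sum(b.n_obs for b in bins)))


def _flatten(dataset: Dataset, subject_filter=None):
    times, values = [], []
    for s in dataset.subjects:
        if subject_filter is not None and not subject_filter(s.id):
            continue
        keep = ~s.obs_missing
        times.append(s.obs_times[keep])
        values.append(s.obs_values[keep])
    if not times:
        return np.array([]), np.array([])
    return np.concatenate(times), np.concatenate(values)


def _derive_seeds(seed: int):
    rng = np.random.default_rng(seed)
    return int(rng.integers(2**31)), int(rng.integers(2**31))


def traditional_vpc(dataset: Dataset, fit: FitResult, model: ModelSpec,
                    config: VPCConfig) -> VPCResult:
    """Classic single-panel VPC: all individuals pooled, no allocation."""
    sim_seed, _ = _derive_seeds(config.seed)
    reps = simulate_replicates(fit.params, dataset, config.n_replicates,
                               sim_seed, model.model_id, model.random_effects)
    obs_t, obs_v = _flatten(dataset)
    binning = make_binning(obs_t, config)
    sim_flat = [_flatten(rep) for rep in reps]
    stratum = percentile_bands(obs_t, obs_v, sim_flat, config, binning, label="all")
    return VPCResult("traditional", [stratum], config)


def mixture_vpc(dataset: Dataset, fit: FitResult, model: ModelSpec,
                config: VPCConfig,
                settings: LikelihoodSettings | None = None) -> VPCResult:
    """Mixture-specific VPC with one panel per allocated subpopulation.

    Pipeline: simulate replicates from the fitted parameters over the
    dataset design; evaluate the original dataset and every replicate at
    those parameters (the MAXEVAL=0 analog); allocate observed and simulated
    individuals by the chosen strategy; bin and band per subpopulation; and
    attach the PMIX/ORIGID/SIMID allocation summary.
    """
    if fit.params.n_components < 2:
        raise ValueError("mixture_vpc requires a fit with at least 2 components")
    if config.strategy not in ("mixest", "randomized"):
        raise ValueError("mixture_vpc requires strategy 'mixest' or 'randomized'")
    settings = settings or LikelihoodSettings()
    sim_seed, alloc_seed = _derive_seeds(config.seed)
    reps = simulate_replicates(fit.params, dataset, config.n_replicates,
                               sim_seed, model.model_id, model.random_effects)
    obs_records = evaluate(dataset, fit.params, model, settings)
    rep_records = [evaluate(rep, fit.params, model, settings) for rep in reps]
    assignments = allocate_run(obs_records, rep_records, config.strategy, alloc_seed)
    summary = allocation_summary(obs_records, rep_records, fit.params.pmix,
                                 config.strategy, alloc_seed, assignments=assignments)
    obs_alloc, rep_allocs = assignments

    obs_t_all, _ = _flatten(dataset)
    binning = make_binning(obs_t_all, config)
    strata, warnings = [], []
    for comp in range(1, fit.params.n_components + 1):
        obs_t, obs_v = _flatten(dataset, lambda sid: obs_alloc.assignment[sid] == comp)
        if obs_t.size == 0:
            warnings.append(f"subpopulation {comp}: no observed individuals allocated; "
                            "panel suppressed")
            strata.append(StratumResult(f"subpop {comp}", [], empty=True))
            continue
        sim_flat = [
            _flatten(rep, lambda sid, a=alloc: a.assignment[sid] == comp)
            for rep, alloc in zip(reps, rep_allocs)
        ]
        strata.append(percentile_bands(obs_t, obs_v, sim_flat, config, binning,
                                       label=f"subpop {comp}"))
    return VPCResult(config.strategy, strata, config, allocation=summary,
                     warnings=warnings)


@dataclass
class SeparationHistogram:
    counts: np.ndarray           # 20 equal bins over [0, 1] of IP_mix1
    edges: np.ndarray
    separation_index: float      # fraction of individuals with max ip >= 0.8


def separation_histogram(records: list) -> SeparationHistogram:
    """Distribution of IP_mix for subpopulation 1 — the mixture-separation
    diagnostic.  Mass near 0.5 marks individuals whose data cannot tell the
    subpopulations apart."""
    if not records:
        raise ValueError("separation_histogram requires non-empty records")
    ip1 = np.array([r.ip[0] for r in records])
    max_ip = np.array([r.ip.max() for r in records])
    counts, edges = np.histogram(ip1, bins=20, range=(0.0, 1.0))
    return SeparationHistogram(counts, edges, float(np.mean(max_ip >= 0.8)))


# ---------------------------------------------------------------------------
# serialization and rendering

def vpc_result_to_frame(result: VPCResult) -> pd.DataFrame:
    """One row per stratum × bin × percentile."""
    rows = []
    for s in result.strata:
        for b in s.bins:
            for j, p in enumerate(result.config.percentiles):
                rows.append({
                    "stratum": s.label,
                    "bin_lo": b.interval[0],
                    "bin_hi": b.interval[1],
                    "bin_mid": b.midpoint,
                    "n_obs": b.n_obs,
                    "percentile": p,
                    "observed": b.obs_pct[j],
                    "ci_lo": b.ci_lo[j],
                    "ci_mid": b.ci_mid[j],
                    "ci_hi": b.ci_hi[j],
                    "outside": bool(b.outside[j]),
                })
    return pd.DataFrame(rows)


def vpc_result_to_dict(result: VPCResult) -> dict:
    d = {
        "kind": result.kind,
        "n_outside": result.n_outside,
        "n_cells": result.n_cells,
        "warnings": list(result.warnings),
        "strata": vpc_result_to_frame(result).to_dict(orient="records"),
    }
    if result.allocation is not None:
        d["allocation"] = result.allocation.to_dict()
    return d


def _panel(ax, stratum: StratumResult, config: VPCConfig, annotation: str = ""):
    mids = [b.midpoint for b in stratum.bins]
    for j, p in enumerate(config.percentiles):
        lo = [b.ci_lo[j] for b in stratum.bins]
        hi = [b.ci_hi[j] for b in stratum.bins]
        obs = [b.obs_pct[j] for b in stratum.bins]
        ax.fill_between(mids, lo, hi, alpha=0.25,
                        color="tab:red" if p == 50 else "tab:blue", linewidth=0)
        ax.plot(mids, obs, color="tab:red" if p == 50 else "tab:blue",
                linestyle="-" if p == 50 else "--", linewidth=1.5)
    ax.set_title(stratum.label)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (mg/L)")
    if annotation:
        ax.text(0.98, 0.95, annotation, transform=ax.transAxes, ha="right",
                va="top", fontsize=8,
                bbox=dict(boxstyle="round", fc="white", alpha=0.8))


def render_vpc(result: VPCResult, path) -> None:
    """Write the VPC panel grid to an image file."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    strata = [s for s in result.strata if not s.empty]
    fig, axes = plt.subplots(1, max(len(strata), 1),
                             figsize=(5.0 * max(len(strata), 1), 4.0), squeeze=False)
    for i, s in enumerate(strata):
        note = ""
        if result.allocation is not None and s.label.startswith("subpop"):
            comp = int(s.label.split()[-1]) - 1
            a = result.allocation
            note = (f"SUBPOP {comp + 1}\n"
                    f"P$_{{mix}}$ {100 * a.pmix_hat[comp]:.1f}%\n"
                    f"ORIGID {a.origid_pct[comp]:.1f}%")
            if a.simid_pct is not None:
                note += f"\nSIMID {a.simid_pct[comp]:.1f}%"
        _panel(axes[0, i], s, result.config, note)
    fig.suptitle(f"{result.kind} VPC")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_separation(hist: SeparationHistogram, path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(0.5 * (hist.edges[:-1] + hist.edges[1:]), hist.counts,
           width=np.diff(hist.edges), color="tab:gray", edgecolor="black")
    ax.set_xlabel("IP$_{mix}$ (subpopulation 1)")
    ax.set_ylabel("individuals")
    ax.set_title(f"separation index {hist.separation_index:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
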