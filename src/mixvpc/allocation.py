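"""Subpopulation allocation strategies and the VPC allocation summary.

Two strategies partition individuals into subpopulation panels:

* ``mixest`` — deterministic assignment to the most likely subpopulation
  (argmax of IP_mix).  Like other empirical-Bayes style classifiers it
  shrinks toward the dominant subpopulation when individual data are
  uninformative.
* ``randomized`` — each individual is drawn into a subpopulation with
  probabilities equal to its IP_mix vector, which is unbiased in
  expectation and therefore avoids that shrinkage.

The allocation summary carries the numbers displayed on mixture VPC panels:
the population mixture estimate (PMIX), the percentage of original-data
individuals allocated per subpopulation (ORIGID), the replicate-averaged
percentage for simulated data (SIMID), and the allocation bias of the
dominant subpopulation in percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import IndividualMixtureRecord

__all__ = [
    "AllocationResult",
    "AllocationSummary",
    "mixest_assign",
    "randomized_assign",
    "allocate",
    "allocate_run",
    "allocation_summary",
]

STRATEGIES = ("mixest", "randomized")


@dataclass
class AllocationResult:
    assignment: dict            # id -> component (1-based)
    strategy: str
    seed: int | None = None


@dataclass
class AllocationSummary:
    pmix_hat: np.ndarray        # estimated population proportions
    origid_pct: np.ndarray      # % of original-data individuals per component
    simid_pct: np.ndarray | None  # replicate-mean % of simulated individuals
    bias_pp: float              # origid_pct(dominant) − 100·pmix_hat(dominant)
    strategy: str
    bias_vs_truth_pp: float | None = None
    simid_per_replicate: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "pmix_hat": [float(p) for p in self.pmix_hat],
            "origid_pct": [float(p) for p in self.origid_pct],
            "simid_pct": None if self.simid_pct is None else [float(p) for p in self.simid_pct],
            "bias_pp": float(self.bias_pp),
            "bias_vs_truth_pp": None if self.bias_vs_truth_pp is None else float(self.bias_vs_truth_pp),
        }


def mixest_assign(record: IndividualMixtureRecord) -> int:
    """Most-likely-subpopulation assignment (1-based); ties break to the
    lowest index."""
    return int(np.argmax(record.ip)) + 1


def randomized_assign(record: IndividualMixtureRecord, rng: np.random.Generator) -> int:
    """Draw a subpopulation with probabilities IP_mix from the given stream."""
    return int(rng.choice(len(record.ip), p=record.ip)) + 1


def allocate(records: list, strategy: str, rng: np.random.Generator | None = None,
             seed: int | None = None) -> AllocationResult:
    """Assign every record to one subpopulation by the chosen strategy."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if strategy == "mixest":
        return AllocationResult({r.id: mixest_assign(r) for r in records}, strategy)
    if rng is None:
        rng = np.random.default_rng(seed)
    K = len(records[0].ip)
    ip = np.vstack([r.ip for r in records])
    u = rng.random(len(records))
    comp = 1 + np.sum(np.cumsum(ip, axis=1)[:, :-1] <= u[:, None], axis=1)
    return AllocationResult(
        {r.id: int(c) for r, c in zip(records, comp)}, strategy, seed=seed
    )


def _pct(assignment: dict, K: int) -> np.ndarray:
    counts = np.zeros(K)
    for c in assignment.values():
        counts[c - 1] += 1
    return 100.0 * counts / counts.sum()


def allocate_run(obs_records: list, sim_records_per_replicate, strategy: str,
                 seed: int = 0):
    """Allocate observed records and every replicate for one VPC run.

    One dedicated stream per run is split into an observed substream plus
    one substream per replicate, so adding replicates never perturbs the
    observed-data allocation.  Returns ``(obs_alloc, rep_allocs)``.
    """
    if not obs_records:
        raise ValueError("allocate_run requires non-empty observed records")
    reps = sim_records_per_replicate or []
    streams = np.random.SeedSequence(seed).spawn(1 + len(reps))
    obs_alloc = allocate(obs_records, strategy,
                         rng=np.random.default_rng(streams[0]), seed=seed)
    rep_allocs = [
        allocate(recs, strategy, rng=np.random.default_rng(streams[1 + r]))
        for r, recs in enumerate(reps)
    ]
    return obs_alloc, rep_allocs


def allocation_summary(obs_records: list, sim_records_per_replicate: list,
                       pmix_hat, strategy: str, seed: int = 0,
                       pmix_true=None, assignments=None) -> AllocationSummary:
    """Allocation statistics for one VPC run.

    Observed records are allocated once; each replicate's records are
    allocated independently (see :func:`allocate_run`).  SIMID is the
    across-replicate mean percentage.  Bias is measured against the
    estimated dominant-component proportion (the PMIX displayed on the same
    panel); ``pmix_true`` additionally reports bias against known truth.
    ``assignments`` may carry a precomputed ``(obs_alloc, rep_allocs)``.
    """
    if not obs_records:
        raise ValueError("allocation_summary requires non-empty observed records")
    if sim_records_per_replicate is not None and len(sim_records_per_replicate) == 0:
        raise ValueError("empty replicate list; pass None to skip SIMID")
    pmix_hat = np.asarray(pmix_hat, dtype=float)
    K = len(pmix_hat)
    if assignments is None:
        assignments = allocate_run(obs_records, sim_records_per_replicate, strategy, seed)
    obs_alloc, rep_allocs = assignments
    origid = _pct(obs_alloc.assignment, K)

    simid = None
    sim_per_rep = None
    if rep_allocs:
        sim_per_rep = np.vstack([_pct(a.assignment, K) for a in rep_allocs])
        simid = sim_per_rep.mean(axis=0)

    dom = int(np.argmax(pmix_hat))
    bias = float(origid[dom] - 100.0 * pmix_hat[dom])
    bias_truth = None
    if pmix_true is not None:
        pmix_true = np.asarray(pmix_true, dtype=float)
        dom_t = int(np.argmax(pmix_true))
        bias_truth = float(origid[dom_t] - 100.0 * pmix_true[dom_t])
    return AllocationSummary(pmix_hat, origid, simid, bias, strategy,
                             bias_vs_truth_pp=bias_truth,
                             simid_per_replicate=sim_per_rep)
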