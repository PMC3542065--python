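"""Batch replication, outcome classification and sigma sweeps.

Each trial is classified into one of three cases by which adapted
background(s) escaped drift before fixation: only the wild type, both, or
only the mutator.  Batches aggregate case frequencies, the mutator
escape/fixation frequencies and exact binomial confidence intervals; sweeps
repeat a batch over a grid of mutational-spectrum factors sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .dynamics import Outcome, TrialResult, Winner, run_trial
from .model import ClassTable, SimulationParams

__all__ = [
    "Case",
    "OutcomeSummary",
    "FoldChange",
    "Trajectory",
    "classify_outcome",
    "run_replicates",
    "sigma_sweep",
    "fold_change",
    "record_trajectory",
    "summarize",
    "trial_seed",
    "DEFAULT_SIGMA_GRID",
]

#: Default sigma grid for sweeps: 0.5 to 2.0 in steps of 0.1, plus the two
#: anchor values 0.56 and 1.33 used for the fold-change comparison.
DEFAULT_SIGMA_GRID: tuple[float, ...] = tuple(
    sorted({round(0.5 + 0.1 * i, 2) for i in range(16)} | {0.56, 1.33})
)


class Case:
    """Fig.-style outcome cases (string constants)."""

    ONLY_WT = "ONLY_WT"
    BOTH = "BOTH"
    ONLY_MUT = "ONLY_MUT"
    UNCLASSIFIED = "UNCLASSIFIED"


_CASE_FROM_OUTCOME = {
    Outcome.WT_ONLY_ESTABLISHED: Case.ONLY_WT,
    Outcome.BOTH_ESTABLISHED: Case.BOTH,
    Outcome.MUT_ONLY_ESTABLISHED: Case.ONLY_MUT,
    Outcome.NONE_WITHIN_CAP: Case.UNCLASSIFIED,
}


def classify_outcome(tr: TrialResult) -> str:
    """Map a trial's establishment flags to its outcome case.

    Trials that never reached a decision (generation cap, extinction) fall
    in the ``UNCLASSIFIED`` bucket, reported separately from the three cases.
    """
    if tr.winner is Winner.NONE:
        return Case.UNCLASSIFIED
    return _CASE_FROM_OUTCOME[tr.outcome]


def trial_seed(master_seed: int, index: int, salt: tuple[int, ...] = ()) -> int:
    """Deterministic 31-bit per-trial seed.

    Derived through ``numpy.random.SeedSequence([master_seed, *salt, index])``
    so every trial is independently reproducible from the master seed and its
    position, stably across platforms.
    """
    ss = np.random.SeedSequence([int(master_seed), *map(int, salt), int(index)])
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


@dataclass
class OutcomeSummary:
    """Aggregate of a replicate batch at one sigma.

    Frequencies are over *classified* trials (those that reached fixation);
    unclassified trials are counted in ``n_unclassified``.  Intervals are
    95% Clopper–Pearson.
    """

    sigma: float
    n_trials: int
    n_classified: int
    n_unclassified: int
    case_counts: dict[str, int]
    case_freqs: dict[str, float]
    freq_escape_mut: float
    freq_fix_mut: float
    n_escape_mut: int
    n_fix_mut: int
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_classified > 0:
            total = sum(self.case_freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"case frequencies must sum to 1, got {total}")
        if self.freq_fix_mut > self.freq_escape_mut + 1e-12:
            raise ValueError("fixation cannot exceed establishment frequency")


def summarize(trials: list[TrialResult], sigma: float) -> OutcomeSummary:
    """Build an :class:`OutcomeSummary` from a list of trial results."""
    cases = [classify_outcome(t) for t in trials]
    n = len(trials)
    counts = {c: 0 for c in (Case.ONLY_WT, Case.BOTH, Case.ONLY_MUT)}
    n_uncl = 0
    for c in cases:
        if c == Case.UNCLASSIFIED:
            n_uncl += 1
        else:
            counts[c] += 1
    n_cls = n - n_uncl
    freqs = {c: (k / n_cls if n_cls else 0.0) for c, k in counts.items()}
    decided = [t for t in trials if t.winner is not Winner.NONE]
    n_escape = sum(1 for t in decided if t.established_mut)
    n_fix = sum(1 for t in decided if t.winner is Winner.MUTATOR)
    denom = n_cls if n_cls else 1
    ci: dict[str, tuple[float, float]] = {}
    for c, k in counts.items():
        lo, hi = proportion_confint(k, denom, alpha=0.05, method="beta")
        ci[c] = (float(lo), float(hi))
    for name, k in (("escape_mut", n_escape), ("fix_mut", n_fix)):
        lo, hi = proportion_confint(k, denom, alpha=0.05, method="beta")
        ci[name] = (float(lo), float(hi))
    return OutcomeSummary(
        sigma=sigma,
        n_trials=n,
        n_classified=n_cls,
        n_unclassified=n_uncl,
        case_counts=counts,
        case_freqs=freqs,
        freq_escape_mut=n_escape / denom,
        freq_fix_mut=n_fix / denom,
        n_escape_mut=n_escape,
        n_fix_mut=n_fix,
        ci=ci,
    )


def run_replicates(
    p: SimulationParams,
    n: int,
    master_seed: int,
    salt: tuple[int, ...] = (),
    progress: bool = False,
) -> tuple[list[TrialResult], OutcomeSummary]:
    """Run ``n`` independent serial-passage trials and aggregate them.

    Per-trial seeds come from :func:`trial_seed`, so the same
    ``(p, n, master_seed)`` always reproduces the same summary.
    """
    if n < 1:
        raise ValueError("need at least one trial")
    table = ClassTable(p)
    results: list[TrialResult] = []
    for i in range(n):
        results.append(run_trial(p, trial_seed(master_seed, i, salt), table=table))
        if progress and (i + 1) % 1000 == 0:
            print(f"  {i + 1}/{n} trials done", flush=True)
    return results, summarize(results, p.sigma)


def sigma_sweep(
    p_base: SimulationParams,
    sigma_grid=DEFAULT_SIGMA_GRID,
    n_per_point: int = 1000,
    master_seed: int = 0,
    progress: bool = False,
) -> list[OutcomeSummary]:
    """One replicate batch per sigma value with independent seed substreams.

    Grid point ``j`` salts its trial seeds with ``j``, so the substreams are
    disjoint and the whole sweep is reproducible from ``master_seed``.
    """
    grid = list(sigma_grid)
    if not grid:
        raise ValueError("sigma grid must be non-empty")
    out = []
    for j, sig in enumerate(grid):
        p = p_base.with_(sigma=float(sig))
        _, summ = run_replicates(p, n_per_point, master_seed, salt=(j,),
                                 progress=progress)
        if progress:
            print(f"sigma={sig}: fix_mut={summ.freq_fix_mut:.4f}", flush=True)
        out.append(summ)
    return out


@dataclass
class FoldChange:
    """Ratio of mutator-fixation frequencies between two summaries."""

    value: float
    ci_low: float
    ci_high: float
    defined: bool = True

    @classmethod
    def undefined(cls) -> "FoldChange":
        return cls(value=math.nan, ci_low=math.nan, ci_high=math.nan,
                   defined=False)


def fold_change(s1: OutcomeSummary, s2: OutcomeSummary) -> FoldChange:
    """Fold increase ``s2.freq_fix_mut / s1.freq_fix_mut`` with a 95% CI.

    The interval comes from the delta method on the log ratio of two
    independent binomial proportions.  When the denominator batch has zero
    fixation events the ratio is undefined and a marker object is returned
    (never an exception).
    """
    if s1.n_fix_mut == 0:
        return FoldChange.undefined()
    p1, p2 = s1.freq_fix_mut, s2.freq_fix_mut
    ratio = p2 / p1
    if s2.n_fix_mut == 0:
        return FoldChange(value=0.0, ci_low=0.0, ci_high=math.nan)
    var_log = ((1 - p1) / (s1.n_classified * p1)
               + (1 - p2) / (s2.n_classified * p2))
    half = 1.959963984540054 * math.sqrt(var_log)
    return FoldChange(
        value=ratio,
        ci_low=ratio * math.exp(-half),
        ci_high=ratio * math.exp(half),
    )


@dataclass
class Trajectory:
    """Per-cycle adapted-class frequencies of one trial.

    ``freq_adapted_wt`` aggregates the (b=1, m=0) classes over d;
    ``freq_adapted_mut`` aggregates (b=1, m=1) classes over d and origin.
    One record per completed bottleneck census.
    """

    cycles: np.ndarray
    freq_adapted_wt: np.ndarray
    freq_adapted_mut: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle": self.cycles,
            "freq_adapted_wt": self.freq_adapted_wt,
            "freq_adapted_mut": self.freq_adapted_mut,
        })


def record_trajectory(p: SimulationParams, seed: int) -> tuple[Trajectory, TrialResult]:
    """Run a single trial while logging per-cycle adapted-class frequencies."""
    table = ClassTable(p)
    cyc: list[int] = []
    fwt: list[float] = []
    fmut: list[float] = []

    def cb(state):
        cyc.append(state.cycle)
        fwt.append(state.frequency(table.mask_adapted_wt))
        fmut.append(state.frequency(table.mask_adapted_mut))

    result = run_trial(p, seed, table=table, census_callback=cb)
    traj = Trajectory(
        cycles=np.asarray(cyc, dtype=int),
        freq_adapted_wt=np.asarray(fwt),
        freq_adapted_mut=np.asarray(fmut),
    )
    return traj, result
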