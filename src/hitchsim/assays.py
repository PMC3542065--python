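"""Plate-assay statistics: growth rates from colony counts, competition
fitness, and two-sample distribution comparison.

A colony grown from a single founder cell to ``N`` viable cells has passed
``log2(N)`` generations; dividing by the incubation time gives a growth rate
in generations per hour that integrates over all growth phases.  Competitive
fitness of strain A against strain B over a common interval is the ratio of
realized Malthusian parameters, ``w = ln(A_f/A_0) / ln(B_f/B_0)``; ``w = 1``
means equal competitive ability.  Growth-rate samples from different strains
are compared with one- or two-sided two-sample Kolmogorov–Smirnov tests.

The module also ships a synthetic sample generator that draws growth rates
from a Gaussian mixture and back-transforms them to viable counts, emulating
the multimodal rate histograms that arise when distinct resistance mutations
segregate in a sample of independent colonies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ColonyMeasurement",
    "CompetitionRecord",
    "KSResult",
    "generations_from_count",
    "growth_rate",
    "lenski_fitness",
    "ks_compare",
    "synth_colony_sample",
    "read_colony_csv",
    "write_colony_csv",
    "read_competition_csv",
]

COLONY_COLUMNS = ["strain", "antibiotic", "viable_count", "incubation_hours"]
COMPETITION_COLUMNS = ["a_initial", "a_final", "b_initial", "b_final"]


@dataclass(frozen=True)
class ColonyMeasurement:
    """Viable-count measurement of one colony.

    ``viable_count`` is the estimated number of cells in the resuspended
    colony; assuming a single founder, it determines the number of
    generations elapsed during ``incubation_hours``.
    """

    strain: str
    antibiotic: str
    viable_count: float
    incubation_hours: float

    def __post_init__(self) -> None:
        if self.viable_count < 1:
            raise ValueError("viable_count must be >= 1 (single founder cell)")
        if self.incubation_hours <= 0:
            raise ValueError("incubation_hours must be positive")


@dataclass(frozen=True)
class CompetitionRecord:
    """Initial and final abundances of two competitors on a shared plate."""

    a_initial: float
    a_final: float
    b_initial: float
    b_final: float

    def __post_init__(self) -> None:
        for name in COMPETITION_COLUMNS:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def generations_from_count(N: float) -> float:
    """Number of generations from one founder cell to ``N`` cells: log2(N)."""
    if N < 1:
        raise ValueError(f"viable count must be >= 1, got {N}")
    return math.log2(N)


def growth_rate(cm: ColonyMeasurement) -> float:
    """Growth rate in generations per hour: ``log2(N) / hours``."""
    return generations_from_count(cm.viable_count) / cm.incubation_hours


def lenski_fitness(cr: CompetitionRecord) -> float:
    """Relative fitness of competitor A versus B.

    The ratio of realized Malthusian parameters over the competition
    interval: ``w = ln(A_f / A_0) / ln(B_f / B_0)``.  Undefined (raises)
    when the reference competitor B did not change in abundance.
    """
    denom = math.log(cr.b_final / cr.b_initial)
    if denom == 0.0:
        raise ZeroDivisionError(
            "relative fitness is undefined when the reference competitor "
            "did not change in abundance"
        )
    return math.log(cr.a_final / cr.a_initial) / denom


@dataclass(frozen=True)
class KSResult:
    statistic: float
    pvalue: float
    alternative: str


_SCIPY_ALTERNATIVE = {
    "two_sided": "two-sided",
    # D+ = max(ECDF1 - ECDF2): sample1 shifted toward *smaller* values.
    "one_sided_greater": "greater",
    "one_sided_less": "less",
}


def ks_compare(
    sample1: Sequence[float],
    sample2: Sequence[float],
    alternative: str = "two_sided",
    method: str = "asymp",
) -> KSResult:
    """Two-sample Kolmogorov–Smirnov test.

    Parameters
    ----------
    alternative : str
        ``"two_sided"`` uses D = sup |F1 - F2|.  ``"one_sided_greater"``
        uses the signed statistic D+ = sup (F1 - F2), i.e. tests whether
        sample1's ECDF lies above sample2's (sample1 shifted toward smaller
        values); ``"one_sided_less"`` uses D- = sup (F2 - F1).
    method : str
        ``"asymp"`` (default, standard at n around 40) or ``"exact"``.

    The statistic equals the maximum (signed, for one-sided alternatives)
    ECDF difference evaluated over the pooled sample points.
    """
    if alternative not in _SCIPY_ALTERNATIVE:
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method not in ("asymp", "exact"):
        raise ValueError(f"unknown method {method!r}")
    res = stats.ks_2samp(x, y, alternative=_SCIPY_ALTERNATIVE[alternative],
                         method=method)
    d = float(res.statistic)
    if alternative != "two_sided" and method == "asymp":
        # plain one-sided large-sample tail: exp(-2 n m D^2 / (n + m))
        n, m = x.size, y.size
        pvalue = min(1.0, math.exp(-2.0 * n * m * d * d / (n + m)))
    else:
        pvalue = float(res.pvalue)
    return KSResult(statistic=d, pvalue=pvalue, alternative=alternative)


def synth_colony_sample(
    n: int,
    mixture_spec: Iterable[tuple[float, float, float]],
    rng: np.random.Generator,
    strain: str = "synthetic",
    antibiotic: str = "none",
    incubation_hours: float = 24.0,
) -> list[ColonyMeasurement]:
    """Synthetic colony sample with Gaussian-mixture growth rates.

    ``mixture_spec`` is a list of ``(weight, mean, sd)`` components on the
    growth-rate scale (generations per hour); weights are normalized.  Rates
    are back-transformed to viable counts ``N = 2**(rate * hours)`` and
    clipped below at one cell.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = [(float(w), float(mu), float(sd)) for w, mu, sd in mixture_spec]
    if not spec:
        raise ValueError("mixture_spec must have at least one component")
    for w, _, sd in spec:
        if w <= 0:
            raise ValueError("mixture weights must be positive")
        if sd < 0:
            raise ValueError("mixture sds must be non-negative")
    weights = np.array([w for w, _, _ in spec])
    weights = weights / weights.sum()
    comp = rng.choice(len(spec), size=n, p=weights)
    rates = np.array([rng.normal(spec[c][1], spec[c][2]) for c in comp])
    counts = np.maximum(np.exp2(rates * incubation_hours), 1.0)
    return [
        ColonyMeasurement(strain=strain, antibiotic=antibiotic,
                          viable_count=float(N),
                          incubation_hours=incubation_hours)
        for N in counts
    ]


def write_colony_csv(measurements: Iterable[ColonyMeasurement],
                     path: str | Path) -> None:
    df = pd.DataFrame([
        {"strain": m.strain, "antibiotic": m.antibiotic,
         "viable_count": m.viable_count,
         "incubation_hours": m.incubation_hours}
        for m in measurements
    ], columns=COLONY_COLUMNS)
    df.to_csv(path, index=False)


def read_colony_csv(path: str | Path) -> list[ColonyMeasurement]:
    df = pd.read_csv(path)
    missing = set(COLONY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        ColonyMeasurement(strain=str(r.strain), antibiotic=str(r.antibiotic),
                          viable_count=float(r.viable_count),
                          incubation_hours=float(r.incubation_hours))
        for r in df.itertuples()
    ]


def read_competition_csv(path: str | Path) -> list[CompetitionRecord]:
    df = pd.read_csv(path)
    missing = set(COMPETITION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        CompetitionRecord(a_initial=float(r.a_initial),
                          a_final=float(r.a_final),
                          b_initial=float(r.b_initial),
                          b_final=float(r.b_final))
        for r in df.itertuples()
    ]
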