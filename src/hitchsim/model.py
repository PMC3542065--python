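"""Genotype lattice and fitness model for serial-passage mutator hitchhiking.

The population is structured into genotype classes defined by three loci:

* ``B`` — absence (``b = 0``) or presence (``b = 1``) of the single beneficial
  mutation available in the environment;
* ``D`` — the number ``d`` of accumulated deleterious mutations;
* ``M`` — absence (``m = 0``) or presence (``m = 1``) of a mutator allele that
  raises genome-wide mutation rates ``mutator_fold``-fold.

Adapted classes additionally carry a *provenance* tag recording the background
on which the beneficial mutation arose.  The mutational-spectrum factor
``sigma`` multiplies the beneficial selection coefficient only for adapted
mutators whose beneficial mutation arose on a mutator background: a mutator's
spectrum biases which beneficial alleles it can access, so the *average*
selection coefficient of its driver allele differs from the wild type's.  An
adapted wild-type cell that later acquires the mutator allele keeps its
wild-type-derived driver and is never affected by ``sigma``.

Fitness is multiplicative over loci::

    f(b, d, m, origin) = (1 + s_b * b * sigma_eff) * (1 - s_d) ** d

with ``sigma_eff = sigma`` iff the class is an adapted mutator of mutator
origin, else ``1``.  The per-generation abundance multiplier is ``R = 1 + f``
under the default convention, so an unadapted, mutation-free cell doubles
every generation and an adapted one grows 10% faster when ``s_b = 0.2``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum
from typing import Iterator

import numpy as np

__all__ = [
    "Origin",
    "GenotypeClass",
    "SimulationParams",
    "fitness_factor",
    "growth_multiplier",
    "enumerate_classes",
    "ClassTable",
]


class Origin(IntEnum):
    """Background on which a beneficial mutation arose (``NONE`` iff b = 0)."""

    NONE = 0
    WT = 1
    MUT = 2


@dataclass(frozen=True, slots=True)
class GenotypeClass:
    """One cell of the genotype lattice.

    Parameters
    ----------
    b : int
        0 (unadapted) or 1 (carries the beneficial mutation).
    d : int
        Number of accumulated deleterious mutations (0 ... d_max).
    m : int
        0 (wild-type repair) or 1 (mutator).
    origin : Origin
        Provenance of the beneficial mutation.  Must be ``NONE`` when
        ``b = 0``.  The combination (b=1, m=0, origin=MUT) is unreachable
        because the mutator locus never back-mutates, and is rejected here.
    """

    b: int
    d: int
    m: int
    origin: Origin = Origin.NONE

    def __post_init__(self) -> None:
        if self.b not in (0, 1) or self.m not in (0, 1):
            raise ValueError(f"b and m must be 0 or 1, got b={self.b}, m={self.m}")
        if self.d < 0:
            raise ValueError(f"deleterious count must be >= 0, got {self.d}")
        if self.b == 0 and self.origin != Origin.NONE:
            raise ValueError("unadapted classes must have origin=NONE")
        if self.b == 1 and self.origin == Origin.NONE:
            raise ValueError("adapted classes must record an origin")
        if self.b == 1 and self.m == 0 and self.origin == Origin.MUT:
            raise ValueError(
                "(b=1, m=0, origin=MUT) is unreachable: the mutator locus "
                "does not back-mutate"
            )

    def label(self) -> str:
        """Compact ``bdm`` label, e.g. ``'101:MUT'`` for the adapted mutator."""
        tag = "" if self.origin is Origin.NONE else f":{self.origin.name}"
        return f"{self.b}{self.d}{self.m}{tag}"


@dataclass(frozen=True, slots=True)
class SimulationParams:
    """All rates, selection coefficients, thresholds and caps of one run.

    Defaults are the model's study conditions: E. coli-range mutation rates,
    a strong beneficial mutation (10% per-generation advantage), a 2%
    per-generation cost per deleterious mutation, 100-fold mutator, growth to
    1e8 cells and serial 1e5-cell bottlenecks.

    Attributes
    ----------
    s_b : float
        Beneficial selection coefficient (enters fitness as ``1 + s_b``).
    s_d : float
        Deleterious selection coefficient per mutation (multiplicative
        ``(1 - s_d)`` per copy).
    sigma : float
        Mutational-spectrum factor multiplying ``s_b`` for mutator-origin
        adapted mutators only.
    mu_b, mu_d, mu_m, mu_l : float
        Wild-type per-individual per-generation rates of beneficial,
        deleterious, mutator-acquisition and lethal mutation.
    mutator_fold : float
        Genome-wide rate multiplier on mutator backgrounds (applies to
        beneficial, deleterious and lethal rates; mutator acquisition cannot
        recur on an m=1 background).
    n_max : float
        Growth threshold: a cycle's growth phase ends on the first generation
        whose total abundance exceeds this.
    n_bottleneck : int
        Number of individuals sampled at each passage.
    d_max : int
        Cap on the deleterious count; further deleterious mutations accumulate
        in the d_max class.
    est_threshold : float
        Census copy number at a bottleneck above which an adapted lineage is
        considered established (escaped drift).
    max_generations : int
        Hard stop for a single trial.
    growth_baseline : str
        ``"add_one"`` (default): per-generation multiplier R = 1 + f, so the
        wild type doubles.  ``"times_two"``: R = 2 f, an alternative baseline
        exposed for sensitivity analysis.
    stochastic_small_classes : float
        If > 0, classes below this abundance reproduce with Poisson offspring
        instead of deterministically (sensitivity switch; default off).
    seed : int | None
        Master RNG seed recorded alongside outputs.
    """

    s_b: float = 0.2
    s_d: float = 0.04
    sigma: float = 1.0
    mu_b: float = 1e-7
    mu_d: float = 1e-4
    mu_m: float = 5e-6
    mu_l: float = 1e-5
    mutator_fold: float = 100.0
    n_max: float = 1e8
    n_bottleneck: int = 100_000
    d_max: int = 30
    est_threshold: float = 100.0
    max_generations: int = 10_000
    growth_baseline: str = "add_one"
    stochastic_small_classes: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("mu_b", "mu_d", "mu_m", "mu_l"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {v}")
        if not 0.0 < self.s_d < 1.0:
            raise ValueError(f"s_d must lie in (0, 1), got {self.s_d}")
        if self.s_b <= 0:
            raise ValueError(f"s_b must be positive, got {self.s_b}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.mutator_fold < 1:
            raise ValueError(f"mutator_fold must be >= 1, got {self.mutator_fold}")
        if not self.n_bottleneck < self.n_max:
            raise ValueError("n_bottleneck must be smaller than n_max")
        if self.n_bottleneck < 1:
            raise ValueError("n_bottleneck must be at least 1")
        if self.d_max < 0:
            raise ValueError("d_max must be >= 0")
        if self.est_threshold < 1:
            raise ValueError("est_threshold must be >= 1")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.growth_baseline not in ("add_one", "times_two"):
            raise ValueError(
                f"growth_baseline must be 'add_one' or 'times_two', "
                f"got {self.growth_baseline!r}"
            )

    def with_(self, **kwargs) -> "SimulationParams":
        """Return a copy with the given fields replaced (and re-validated)."""
        return replace(self, **kwargs)


def fitness_factor(g: GenotypeClass, p: SimulationParams) -> float:
    """Fitness factor f of a genotype class.

    ``f = (1 + s_b * b * sigma_eff) * (1 - s_d)**d`` where ``sigma_eff`` is
    ``p.sigma`` for adapted mutators of mutator origin and ``1`` otherwise.
    """
    sigma_eff = p.sigma if (g.b == 1 and g.m == 1 and g.origin is Origin.MUT) else 1.0
    return (1.0 + p.s_b * g.b * sigma_eff) * (1.0 - p.s_d) ** g.d


def growth_multiplier(g: GenotypeClass, p: SimulationParams) -> float:
    """Per-generation abundance multiplier R.

    Under the default ``add_one`` baseline ``R = 1 + f``: the unadapted,
    mutation-free class doubles each generation and the relative fitness of
    the adapted class is ``(2 + s_b) / 2`` (1.1 for s_b = 0.2).  The
    ``times_two`` alternative uses ``R = 2 f``.
    """
    f = fitness_factor(g, p)
    if p.growth_baseline == "add_one":
        return 1.0 + f
    return 2.0 * f


def enumerate_classes(p: SimulationParams) -> list[GenotypeClass]:
    """All reachable genotype classes in a stable deterministic order.

    Per deleterious level d there are five classes: (0,d,0), (0,d,1),
    (1,d,0,WT), (1,d,1,WT) and (1,d,1,MUT).  (1,d,0,MUT) is unreachable.
    The order (d-major, then the five b/m/origin combinations) is fixed so
    that multinomial sampling is reproducible across runs and platforms.
    """
    out: list[GenotypeClass] = []
    for d in range(p.d_max + 1):
        out.append(GenotypeClass(0, d, 0))
        out.append(GenotypeClass(0, d, 1))
        out.append(GenotypeClass(1, d, 0, Origin.WT))
        out.append(GenotypeClass(1, d, 1, Origin.WT))
        out.append(GenotypeClass(1, d, 1, Origin.MUT))
    return out


class ClassTable:
    """Vectorised view of the genotype lattice for one parameter set.

    Precomputes, once per :class:`SimulationParams`:

    * per-class growth multipliers ``R``;
    * the sparse mutation-transition table (source index, destination index,
      per-individual rate), with destination ``-1`` denoting lethal removal;
    * boolean masks used by establishment tracking and fixation tests.

    The transition table implements single-step transitions only (double
    mutations within one individual-generation are ignored; their per-capita
    probability is below 1e-6 at the default rates):

    * beneficial ``(0,d,m) -> (1,d,m)`` with origin WT/MUT set by ``m``;
    * deleterious ``d -> d+1`` (classes at d_max absorb further hits);
    * mutator acquisition ``m: 0 -> 1`` preserving b, d and origin;
    * lethal removal.

    Beneficial, deleterious and lethal rates are multiplied by
    ``mutator_fold`` on m=1 backgrounds; mutator acquisition cannot recur.
    """

    def __init__(self, p: SimulationParams):
        self.params = p
        self.classes = enumerate_classes(p)
        self.index = {g: i for i, g in enumerate(self.classes)}
        n = len(self.classes)
        self.b = np.array([g.b for g in self.classes], dtype=np.int64)
        self.d = np.array([g.d for g in self.classes], dtype=np.int64)
        self.m = np.array([g.m for g in self.classes], dtype=np.int64)
        self.origin = np.array([int(g.origin) for g in self.classes], dtype=np.int64)
        self.R = np.array([growth_multiplier(g, p) for g in self.classes])

        src: list[int] = []
        dst: list[int] = []
        rate: list[float] = []
        for i, g in enumerate(self.classes):
            fold = p.mutator_fold if g.m == 1 else 1.0
            if g.b == 0:
                new_origin = Origin.MUT if g.m == 1 else Origin.WT
                src.append(i)
                dst.append(self.index[GenotypeClass(1, g.d, g.m, new_origin)])
                rate.append(p.mu_b * fold)
            if g.d < p.d_max:
                src.append(i)
                dst.append(self.index[GenotypeClass(g.b, g.d + 1, g.m, g.origin)])
                rate.append(p.mu_d * fold)
            if g.m == 0:
                src.append(i)
                dst.append(self.index[GenotypeClass(g.b, g.d, 1, g.origin)])
                rate.append(p.mu_m)
            src.append(i)
            dst.append(-1)  # lethal
            rate.append(p.mu_l * fold)
        self.trans_src = np.array(src, dtype=np.int64)
        self.trans_dst = np.array(dst, dtype=np.int64)
        self.trans_rate = np.array(rate)
        self._nonlethal = self.trans_dst >= 0

        self.mask_unadapted = self.b == 0
        self.mask_adapted_wt = (self.b == 1) & (self.m == 0)
        self.mask_adapted_mut = (self.b == 1) & (self.m == 1)
        self.mask_mut_origin = self.origin == int(Origin.MUT)
        self.mask_wt_background = self.m == 0
        self.n_classes = n

    def zeros(self) -> np.ndarray:
        return np.zeros(self.n_classes)

    def __len__(self) -> int:
        return self.n_classes

    def __iter__(self) -> Iterator[GenotypeClass]:
        return iter(self.classes)
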