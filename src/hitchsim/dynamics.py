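"""One trial of the serial-passage life cycle.

A trial starts from a single unadapted, mutation-free cell and iterates
growth–dilution cycles:

1. *Growth phase* — each generation every class reproduces deterministically
   (abundance multiplied by its growth factor), then mutations move
   Poisson-distributed numbers of individuals between classes (lethal hits
   remove them).  The phase ends on the first generation whose total
   abundance exceeds ``n_max``.
2. *Bottleneck* — a multinomial sample of exactly ``n_bottleneck``
   individuals replaces the population (the main source of drift).

At each post-bottleneck census the trial updates sticky establishment flags
(an adapted background whose census count reaches ``est_threshold`` has
escaped drift) and tests for fixation.  The trial ends when the beneficial
mutation is fixed in the wild-type or the mutator background, or when
``max_generations`` is exhausted.

Fixation test
-------------
The mutator background wins when the census contains no unadapted and no
non-mutator individuals (all sampled cells are adapted mutators); this state
is exactly attainable because neither locus back-mutates.  The wild-type
background wins when the census contains no unadapted individuals and the
mutator-*origin* adapted lineage is extinct.  A literal all-(b=1, m=0)
census is not required: recurrent mutator acquisition (rate ``mu_m``) keeps
wild-type-origin adapted mutators at a mutation–selection balance of roughly
``mu_m / load`` — tens of copies per 1e5-cell census at default rates — so a
pure non-mutator sample essentially never occurs.  Those satellites carry a
wild-type-derived driver (``sigma`` never applies to them) plus the full
mutator deleterious load, so they cannot overturn the outcome once the
mutator-origin lineage is gone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .model import ClassTable, GenotypeClass, SimulationParams

__all__ = [
    "Outcome",
    "Winner",
    "Fixation",
    "PopulationState",
    "TrialResult",
    "reproduce",
    "apply_mutations",
    "grow_to_threshold",
    "bottleneck",
    "update_establishment",
    "check_fixation",
    "run_trial",
]


class Outcome(str, Enum):
    """Which adapted backgrounds escaped drift during the trial."""

    WT_ONLY_ESTABLISHED = "WT_ONLY_ESTABLISHED"
    BOTH_ESTABLISHED = "BOTH_ESTABLISHED"
    MUT_ONLY_ESTABLISHED = "MUT_ONLY_ESTABLISHED"
    NONE_WITHIN_CAP = "NONE_WITHIN_CAP"


class Winner(str, Enum):
    WT = "WT"
    MUTATOR = "MUTATOR"
    NONE = "NONE"


class Fixation(str, Enum):
    NOT_FIXED = "NOT_FIXED"
    WT = "WT"
    MUTATOR = "MUTATOR"


@dataclass
class PopulationState:
    """Real-valued abundance per genotype class, with cycle/generation counters.

    ``counts`` is indexed by the class order of :class:`~hitchsim.model.ClassTable`.
    Operations mutate the state in place and return it; copy first if the old
    state is still needed.
    """

    table: ClassTable
    counts: np.ndarray
    generation: int = 0
    cycle: int = 0
    extinct: bool = False

    @classmethod
    def from_single_cell(cls, table: ClassTable) -> "PopulationState":
        """The trial's founding population: one wild-type (000) cell."""
        counts = table.zeros()
        counts[table.index[GenotypeClass(0, 0, 0)]] = 1.0
        return cls(table=table, counts=counts)

    @classmethod
    def from_counts(
        cls, table: ClassTable, abundances: dict[GenotypeClass, float]
    ) -> "PopulationState":
        counts = table.zeros()
        for g, n in abundances.items():
            counts[table.index[g]] = float(n)
        return cls(table=table, counts=counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def frequency(self, mask: np.ndarray) -> float:
        tot = self.total
        return float(self.counts[mask].sum() / tot) if tot > 0 else 0.0

    def copy(self) -> "PopulationState":
        return PopulationState(
            table=self.table,
            counts=self.counts.copy(),
            generation=self.generation,
            cycle=self.cycle,
            extinct=self.extinct,
        )


@dataclass
class EstablishmentFlags:
    """Sticky escaped-drift flags, updated at each bottleneck census."""

    wt: bool = False
    mut: bool = False


@dataclass
class TrialResult:
    """Per-replicate record of one serial-passage trial."""

    outcome: Outcome
    winner: Winner
    established_wt: bool
    established_mut: bool
    generations: int
    cycles: int
    seed: int
    sigma: float
    extinct: bool = False

    def __post_init__(self) -> None:
        if self.winner is Winner.WT and not self.established_wt:
            raise ValueError("a WT win implies WT establishment")
        if self.winner is Winner.MUTATOR and not self.established_mut:
            raise ValueError("a mutator win implies mutator establishment")


def reproduce(state: PopulationState, p: SimulationParams,
              rng: np.random.Generator | None = None) -> PopulationState:
    """One generation of reproduction: counts scaled by the growth multipliers.

    Reproduction is deterministic for every class; demographic stochasticity
    enters through Poisson mutation numbers and the multinomial bottleneck.
    If ``p.stochastic_small_classes`` is set (> 0), classes below that
    abundance instead draw Poisson offspring (sensitivity switch; requires
    ``rng``).
    """
    t = state.table
    expected = state.counts * t.R
    if p.stochastic_small_classes > 0:
        if rng is None:
            raise ValueError("stochastic reproduction requires an rng")
        small = (state.counts > 0) & (state.counts < p.stochastic_small_classes)
        if small.any():
            expected[small] = rng.poisson(expected[small]).astype(float)
    state.counts = expected
    state.generation += 1
    return state


def apply_mutations(state: PopulationState, p: SimulationParams,
                    rng: np.random.Generator) -> PopulationState:
    """Move Poisson-distributed mutation numbers between classes.

    For every source class and applicable mutation type the number of
    mutating individuals is Poisson with mean ``rate x abundance`` (rates
    pre-multiplied by ``mutator_fold`` on m=1 backgrounds).  All draws for a
    source class use the same pre-move abundance and are applied
    simultaneously; if their sum exceeds the class abundance they are scaled
    down proportionally (vanishingly rare at realistic rates).  Lethal hits
    are removed.  Flags extinction if the whole population is lost.
    """
    t = state.table
    n = state.counts
    lam = t.trans_rate * n[t.trans_src]
    moves = rng.poisson(lam).astype(float)
    if moves.any():
        outflow = np.zeros_like(n)
        np.add.at(outflow, t.trans_src, moves)
        over = outflow > n
        if over.any():
            scale = np.ones_like(n)
            np.divide(n, outflow, out=scale, where=over)
            moves = moves * scale[t.trans_src]
            outflow = np.minimum(outflow, n)
        n -= outflow
        nl = t._nonlethal
        np.add.at(n, t.trans_dst[nl], moves[nl])
    if n.sum() <= 0:
        state.extinct = True
    return state


def grow_to_threshold(state: PopulationState, p: SimulationParams,
                      rng: np.random.Generator) -> PopulationState:
    """Run generations until total abundance exceeds ``n_max``.

    Returns immediately if the population already exceeds the threshold.
    Stops early (without raising) when ``max_generations`` is reached or the
    population goes extinct; the caller inspects the counters.
    """
    while (state.total <= p.n_max and not state.extinct
           and state.generation < p.max_generations):
        reproduce(state, p, rng)
        apply_mutations(state, p, rng)
    return state


def bottleneck(state: PopulationState, p: SimulationParams,
               rng: np.random.Generator) -> PopulationState:
    """Multinomial sample of exactly ``n_bottleneck`` individuals."""
    tot = state.total
    if tot <= 0:
        state.extinct = True
        return state
    probs = state.counts / tot
    state.counts = rng.multinomial(int(p.n_bottleneck), probs).astype(float)
    state.cycle += 1
    return state


def update_establishment(state: PopulationState, p: SimulationParams,
                         flags: EstablishmentFlags) -> EstablishmentFlags:
    """Set sticky escaped-drift flags from a post-bottleneck census.

    The wild-type background is established when adapted non-mutator classes
    total at least ``est_threshold`` at a census; the mutator background
    when mutator-*origin* adapted classes do.  The threshold (default 100
    copies) is far above the ~1/(2s) scale at which drift still threatens a
    beneficial lineage, so flagged lineages are essentially safe.
    """
    t = state.table
    if not flags.wt:
        wt_count = state.counts[t.mask_adapted_wt].sum()
        if wt_count >= p.est_threshold:
            flags.wt = True
    if not flags.mut:
        mut_count = state.counts[t.mask_adapted_mut & t.mask_mut_origin].sum()
        if mut_count >= p.est_threshold:
            flags.mut = True
    return flags


def check_fixation(state: PopulationState) -> Fixation:
    """Classify a post-bottleneck census as WT-fixed, mutator-fixed or neither.

    See the module docstring for why the wild-type test tolerates
    wild-type-origin mutator satellites maintained by recurrent mutation.
    """
    t = state.table
    n = state.counts
    if n[t.mask_unadapted].sum() > 0:
        return Fixation.NOT_FIXED
    if n[t.mask_wt_background].sum() == 0:
        return Fixation.MUTATOR
    if n[t.mask_mut_origin].sum() == 0 and n[t.mask_adapted_wt].sum() > 0:
        return Fixation.WT
    return Fixation.NOT_FIXED


def _outcome_from_flags(flags: EstablishmentFlags, decided: bool) -> Outcome:
    if not decided:
        return Outcome.NONE_WITHIN_CAP
    if flags.wt and flags.mut:
        return Outcome.BOTH_ESTABLISHED
    if flags.wt:
        return Outcome.WT_ONLY_ESTABLISHED
    if flags.mut:
        return Outcome.MUT_ONLY_ESTABLISHED
    return Outcome.NONE_WITHIN_CAP


def run_trial(p: SimulationParams, seed: int,
              table: ClassTable | None = None,
              census_callback=None) -> TrialResult:
    """Run one serial-passage trial from a single wild-type cell.

    Parameters
    ----------
    p : SimulationParams
    seed : int
        Seed for this trial's own ``numpy`` Generator; a trial is fully
        reproducible from ``(p, seed)``.
    table : ClassTable, optional
        Precomputed class table for ``p`` (rebuilt when omitted; pass one
        when running many replicates).
    census_callback : callable, optional
        Called as ``census_callback(state)`` after every bottleneck census
        (used for trajectory recording).
    """
    if table is None:
        table = ClassTable(p)
    rng = np.random.default_rng(seed)
    state = PopulationState.from_single_cell(table)
    flags = EstablishmentFlags()
    fix = Fixation.NOT_FIXED

    while state.generation < p.max_generations and not state.extinct:
        grow_to_threshold(state, p, rng)
        if state.extinct or state.generation >= p.max_generations:
            break
        bottleneck(state, p, rng)
        if state.extinct:
            break
        update_establishment(state, p, flags)
        if census_callback is not None:
            census_callback(state)
        fix = check_fixation(state)
        if fix is not Fixation.NOT_FIXED:
            break

    # Fixation implies the winning background escaped drift, even in the
    # remote case where its census never crossed est_threshold beforehand.
    if fix is Fixation.WT:
        flags.wt = True
    elif fix is Fixation.MUTATOR:
        flags.mut = True

    winner = {Fixation.WT: Winner.WT, Fixation.MUTATOR: Winner.MUTATOR,
              Fixation.NOT_FIXED: Winner.NONE}[fix]
    return TrialResult(
        outcome=_outcome_from_flags(flags, decided=winner is not Winner.NONE),
        winner=winner,
        established_wt=flags.wt,
        established_mut=flags.mut,
        generations=state.generation,
        cycles=state.cycle,
        seed=seed,
        sigma=p.sigma,
        extinct=state.extinct,
    )
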