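# Methods

## The model

`hitchsim` simulates the serial passage of an asexual bacterial population
in an environment where a single beneficial mutation suffices for full
adaptation, and asks how often a mutator allele hitchhikes to fixation with
it. The population is class-structured, not individual-based: each genotype
class is defined by three loci — presence of the beneficial mutation
(`b ∈ {0,1}`), the number of accumulated deleterious mutations
(`d ∈ {0,…,d_max}`), and presence of a mutator allele (`m ∈ {0,1}`) that
raises genome-wide mutation rates `mutator_fold`-fold. Adapted classes carry
one extra bit of history, the *origin* of their driver mutation (wild-type
or mutator background).

Fitness is multiplicative over loci,

    f(b, d, m, origin) = (1 + s_b · b · σ_eff) · (1 − s_d)^d,

where the mutational-spectrum factor σ enters as `σ_eff = σ` only for
adapted mutators whose driver arose on a mutator background, and `σ_eff = 1`
otherwise. This encodes the biological claim at the model's core: a mutator
elevates a characteristic spectrum of base substitutions, so the *average*
selection coefficient of the beneficial alleles it can reach differs from
the wild type's by a factor σ. An adapted wild-type cell that subsequently
acquires the mutator allele keeps its wild-type-derived driver, so σ never
applies to it; that provenance is propagated forever and the converse class
(adapted non-mutator of mutator origin) is unreachable because the mutator
locus never back-mutates.

Each generation every class reproduces deterministically with multiplier
`R = 1 + f` (the `add_one` baseline: an unadapted, mutation-free cell
doubles). This convention is not arbitrary — it reproduces every fitness
anchor the model is calibrated to: the adapted/unadapted ratio
`2.2/2.0 = 1.1` ("a 10% advantage" at `s_b = 0.2`), a 2% per-copy cost at
`s_d = 0.04`, and competition fitnesses `w = (2 + s_b σ)/(2 + s_b)` of 0.96
at σ = 0.56 and 1.03 at σ = 1.33. An alternative `times_two` baseline
(`R = 2f`) is exposed as a configuration switch for sensitivity analysis
only.

After reproduction, mutation moves Poisson-distributed numbers of
individuals between classes, with means `rate × class abundance`:
beneficial (`b: 0→1`, origin set by the current background), deleterious
(`d → d+1`; the `d_max` class absorbs further hits), mutator acquisition
(`m: 0→1`, origin preserved), and lethal (removal). Beneficial, deleterious
and lethal rates are multiplied by `mutator_fold` on `m = 1` backgrounds —
the 100-fold increase is read as genome-wide, which is what creates the
deleterious-load disadvantage that opposes mutator fixation. Double
mutations within one individual-generation are ignored (per-capita
probability < 1e-6 at the default rates). All draws for one source class
use the same pre-move abundance; in the (vanishingly rare) event their sum
exceeds it they are rescaled proportionally.

A growth phase ends on the first generation whose total abundance exceeds
`n_max`; a multinomial sample of exactly `n_bottleneck` individuals then
founds the next cycle. The bottleneck is the model's only source of
demographic stochasticity besides the Poisson mutation numbers; a
configuration switch (`stochastic_small_classes`) optionally adds Poisson
offspring noise for rare classes, off by default.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `s_b` | 0.2 | beneficial selection coefficient (10% per-generation advantage under `add_one`) |
| `s_d` | 0.04 | per-copy deleterious coefficient (2% per-generation cost) |
| `sigma` | 1.0 | spectrum factor on mutator-origin drivers |
| `mu_b` | 1e-7 | wild-type beneficial rate (per individual per generation) |
| `mu_d` | 1e-4 | wild-type deleterious rate |
| `mu_m` | 5e-6 | mutator-acquisition rate |
| `mu_l` | 1e-5 | lethal rate |
| `mutator_fold` | 100 | genome-wide rate multiplier on mutators |
| `n_max` | 1e8 | growth threshold (individuals) |
| `n_bottleneck` | 1e5 | passage sample size |
| `d_max` | 30 | deleterious-count cap |
| `est_threshold` | 100 | census copies marking drift escape |
| `max_generations` | 10,000 | hard stop per trial |

The rates are in the range measured for *E. coli*; the bottleneck regime
(1e5 of >1e8, i.e. 1:1024, ten generations per cycle) is a moderate-strength
laboratory passage. `d_max = 30` bounds the state space at negligible cost:
classes beyond `(0.96)^30` contribute nothing to the dynamics at
`mu_d ≤ 1e-2`. `est_threshold = 100` census copies is far above the
`~1/(2s) = 2.5`-copy scale at which drift still threatens a beneficial
lineage, so flagged lineages are essentially never lost again; the split of
outcomes between "only wild type" and "coexistence" retains some
sensitivity to this operational choice (see Limitations).
`max_generations = 10,000` is ≥30× the typical time to fixation under
defaults and only binds in degenerate configurations (e.g. `mu_b = 0`).

## Trial life cycle and outcome bookkeeping

A trial starts from one wild-type cell and iterates growth → bottleneck. At
each post-bottleneck census two sticky establishment flags are updated:
wild-type-adapted classes totalling ≥ `est_threshold` copies, and
mutator-*origin* adapted classes likewise. Fixation is then tested:

* **mutator fixed** — the census contains no unadapted and no non-mutator
  individuals. This is exactly attainable since neither locus back-mutates.
* **wild type fixed** — the census contains no unadapted individuals and no
  mutator-origin individuals. A literally pure `m = 0` census is *not*
  required: recurrent mutator acquisition (`mu_m`) holds wild-type-origin
  adapted mutators at a mutation–selection balance of ≈ `mu_m/load` ≈ 5e-4
  — tens of copies in every 1e5 census — so demanding their absence would
  prevent termination. These satellites carry a wild-type driver (σ never
  applies) plus the full mutator load and cannot overturn the outcome.

Decided trials fall into three cases — only the wild type established,
both backgrounds established (coexistence), only the mutator established —
with the winner recorded separately. Batch summaries report case
frequencies over decided trials with 95% Clopper–Pearson intervals
(statsmodels), the mutator drift-escape and fixation frequencies, and
fold changes between batches with delta-method intervals on the log ratio.

Reproducibility: per-trial seeds are derived as
`SeedSequence([master_seed, *salt, index])` truncated to 31 bits; a trial is
bit-for-bit reproducible from its parameters and recorded seed, and sweep
grid points use disjoint salted substreams.

## What the dynamics produce

Under the defaults the wild-type subpopulation outnumbers mutators by
~2,000:1 at mutation–selection balance, so it nearly always generates and
establishes the driver first. At σ = 1 an established adapted mutator still
loses the ensuing competition — its genome-wide load costs ~1% per
generation — so mutator fixation is confined to the rare trials where it
fixes before any wild-type driver establishes. Above the σ threshold that
offsets the load (σ ≈ 1.1 at these rates), an established adapted mutator
is fitter than the adapted wild type and merely needs to escape drift, so
fixation probability rises sharply and non-linearly with σ while the
escape probability itself changes only modestly — the probability that a
new beneficial lineage survives drift is of order 2s and therefore only
linear in σ.

One subtle consequence of the full genotype lattice: occasionally the
winning wild-type driver arises on an already-loaded (`d ≥ 1`) background.
Such a lineage is permanently handicapped (deleterious counts never
decrease), and a later pristine mutator-origin lineage can genuinely
outcompete it even at σ = 1. This pathway is rare (roughly one trial in a
few thousand) but real in this model.

## Scaled-down experiment sizes

The published experiments used 35,000 trials per condition. The test suite
and the acceptance script use 5,000–20,000 trials per condition — enough to
resolve each reported percentage to a few binomial standard errors — and the
examples use hundreds, chosen as demonstration scale.

## The synthetic colony-assay generator

`synth_colony_sample` emulates plate assays in which independent resistant
colonies are picked, resuspended and counted: growth rates are drawn from a
Gaussian mixture (one component per segregating resistance mutation class)
and back-transformed to viable counts via `N = 2^(rate × hours)`. It
reproduces the *structure* of such data — multimodality from distinct
resistance mutations, n = 42-sized groups, count-scale measurement — but
not any empirical distribution: real colony counts carry dilution and
plating error, non-Gaussian tails, and phenotypic lag, none of which are
modelled. Tests passing on these fixtures validate the statistical
machinery (growth-rate transform, KS comparison, competition formula), not
agreement with any particular wet-lab dataset.

The one-sided two-sample KS p-value uses the plain large-sample tail
`exp(−2nmD²/(n+m))` (standard at n ≈ 42); an exact-distribution option is
exposed. The two-sided and exact branches delegate to scipy. Competition
fitness is the ratio of realized Malthusian parameters,
`w = ln(A_f/A_0)/ln(B_f/B_0)`, undefined when the reference competitor did
not change in abundance.

## Numerical choices

* Abundances are real-valued; only mutation numbers and bottleneck samples
  are integer random variates. Rounding never occurs during growth.
* Genotype classes are enumerated in a fixed d-major order so multinomial
  sampling is platform-stable.
* Extinction (possible only while the population is tiny, via a lethal hit
  on the founder) is flagged, reported as an undecided trial, and never
  silently retried; its probability is ~1e-5 per trial.
* Establishment flags are evaluated before the fixation test at the same
  census; a fixation verdict implies the winner's establishment flag.
* The fold-change between two batches returns an explicit undefined marker
  when the denominator batch has zero fixation events.

## Limitations

* The operational drift-escape criterion (census copy threshold) is a
  modelling choice; the coexistence-vs-only-wild-type split at σ = 1 moves
  by a couple of percentage points across thresholds 25–500 (the
  only-mutator and σ > threshold fixation frequencies are insensitive).
  There is no unique criterion under which every published percentage is
  reproduced simultaneously; see the acceptance-test docstrings for the
  exact quantities checked.
* Class-structured determinism means selection acts on expected growth;
  demographic noise in rare classes is only approximated by the
  mutation/bottleneck stochasticity unless the Poisson-offspring switch is
  enabled.
* Single beneficial locus, constant environment, no recombination or
  horizontal transfer, no clonal interference between distinct beneficial
  mutations (all drivers are interchangeable within a background).
* σ rescales only the selection coefficient of the driver; real spectra
  also change the beneficial mutation *rate* per target, which the model
  absorbs into the 100-fold factor.
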