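# Model and methods

## The model

`unicell` simulates evolution of programmed cell death (PCD) in a population
of self-replicating digital organisms on a `W × H` toroidal grid with at
most one organism per cell.

**Genomes and replication.** A genome is a fixed-length sequence of `L`
symbols from an alphabet of size `S` in which exactly one symbol is COPY,
one DIVIDE, one PCD, and the remaining `S − 3` are inert. A COPY cycle
copies the next uncopied site into an offspring buffer, applying a
substitution mutation with probability μ per site; a DIVIDE cycle with a
full buffer installs the offspring into one of the 8 immediate neighbours
(drawn uniformly regardless of occupancy; any occupant dies), resets the
parent's copy state, and leaves the parent in place. Insertions and
deletions do not exist, so genome length is invariant and relatedness is
plain Hamming distance. Organisms never die of age — only by being
overwritten or by their own successful PCD.

**Scheduling.** Each *update* grants `c × N` CPU cycles (default
`c = 30` cycles per organism, `N` = population at the start of the update),
one at a time, each to an organism drawn with probability proportional to
its merit. Merit is fixed at birth: base merit equals `L`, multiplied by the
parent's *offspring multiplier* at the moment of division. The ancestor (a
hand-built replicator with no PCD symbol — the behaviour must arise de novo
by mutation) starts with merit `L = 100`.

**Programmed cell death.** Executing the PCD instruction kills the executor
with probability `p = 0.05` per attempt. On death, every occupied cell
within Chebyshev distance 2 (the 24-cell 5×5 Moore block) is classified kin
(Hamming distance ≤ KIL) or nonkin against the dying genome at that
instant. In *direct* mode each kin's offspring multiplier is multiplied by
the effect factor (default 5); in *indirect* mode each nonkin's is divided
by it; with factor 1 (the no-effect control) classification is recorded but
nothing changes. Each event is logged with its kin / nonkin / cheater-kin
counts, where a cheater is a kin-classified organism whose genome contains
no PCD symbol.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| grid | 60×60 (full), 30×30 (reduced) | cells | full scale matches the Avida-style default world; reduced is the desk-scale preset |
| `L` | 100 | instructions | fixed length makes Hamming distance the exact relatedness measure |
| `S` | 26 | symbols | 23 inert symbols mimic the mutational target size of a full instruction set whose only phenotypically active parts are replication and PCD |
| μ | 0.0075 | probability / copied site | the cited system's default copy-mutation rate; configurable |
| `p_success` | 0.05 | probability / attempt | printed model parameter |
| effect factor | 5 (1 = control) | — | printed model parameter |
| KIL | sweep {0, 1, 3, 5, 30, 100} | genetic differences | spans clones-only to everyone-is-kin for `L` = 100 |
| radius | 2 | cells (Chebyshev) | "2-space radius" read as the 5×5 Moore block; consistent with square-grid figures and with ≈ 20 kin per event fitting inside 24 neighbours; a Euclidean disc was rejected |
| cycles/organism/update | 30 | cycles | the conventional update granularity |
| updates | 60,000 (full), 3,000 (reduced) | updates | ≈ 2,000 generations at full scale |
| replicates | 30 (full), 10 (reduced) | — | per treatment; replicate *r* uses seed `base_seed + r` |

## Design decisions

- **Instruction-set collapse.** With task rewards disabled, only replication
  machinery and PCD have phenotypic effect, so the Turing-complete language
  is collapsed to {COPY, DIVIDE, PCD, INERT×23}. Heads, registers, stacks,
  and label addressing are out of scope.
- **Mutation excludes the original symbol** (configurable), so μ is exactly
  the per-site probability of a genetic difference and the mutated-site
  count is Binomial(L, μ). The include-original convention realizes
  μ(1 − 1/S) instead.
- **Bonus depth.** A PCD effect changes the *recipient's* offspring
  multiplier for the recipient's lifetime; it applies to the initial merit
  of every offspring that recipient produces, and offspring start again at
  multiplier 1. Deeper inheritance would turn the effect into heritable
  merit, which the task-free model does not have.
- **Stacking.** Effects from multiple events stack multiplicatively (the
  simplest associative rule); a latch-once mode is available via
  `effect_stacking="latch"`. Stacked ×5 effects can drive multipliers into
  the 10⁷ range during PCD outbreaks — this is real model dynamics, and the
  scheduler is built to tolerate the resulting merit skew (below).
- **Offspring placement** is uniform over all 8 neighbours regardless of
  occupancy; preferring empty cells would soften local competition.
- **% executing PCD** is not operationally pinned down by the study design;
  the primary reading here is lifetime-attempt prevalence among the living,
  averaged over the trailing 100 sampled updates, with per-update incidence
  (`pcd_incidence_pct`) emitted alongside so either reading is computable.
  Attempts, not only fatal successes, are counted; deaths are recoverable
  from the event log.
- **Statistics.** Treatment comparisons use the Mann-Whitney rank-sum test:
  exact enumeration of all label assignments for both n, m ≤ 8 (ties handled
  by the enumeration), tie-corrected normal approximation otherwise;
  two-sided by default, no multiple-testing correction. Two identical
  constant samples return p = 1 with a degeneracy flag.

## Numerical and implementation choices

- **Two engines, one trajectory.** The update loop exists as a pure-Python
  reference (the readable semantic definition) and a numba-compiled kernel.
  Both consume random draws in the identical documented order — scheduling
  draw; COPY: one uniform plus one integer iff mutating; DIVIDE: one integer
  in [0, 8); PCD: one uniform — from the same `numpy.random.Generator`
  stream, so seeded runs are bit-identical under either engine; the test
  suite asserts exact array-level equality.
- **Scheduler under extreme merit skew.** Draws use a cumulative weight
  table over cells. When an organism dies mid-update its weight is zeroed
  and the table rebuilt, keeping draws exactly merit-proportional over the
  survivors; newborns stay at weight 0 until the next update. (A frozen
  table with rejection-resampling is equivalent in distribution but
  degenerates numerically when a dominant organism dies, which stacked ×5
  multipliers make common.)
- **Degenerate inputs.** A failed divide (incomplete buffer) is a silent
  no-op, keeping broken replicators slow rather than fatal; executing a dead
  organism is an internal error; extinction (the last organism's PCD) halts
  the run with a flag and partial outputs retained, never silently dropped.
- **Missing values** are explicit NaNs (empty population, event-free
  window), never zeros.

## What the simulation does and does not emulate

The model is a high-level abstraction of PCD in microbes — colicin release,
altruistic lysis, stalk formation — with perfect, free kin recognition and
an extreme (×5) effect size. It omits resources and tasks, age, phenotypic
noise in recognition, insertion/deletion mutation, and any population
structure beyond the local grid. Passing tests therefore show that the
*kin-selection mechanism* behaves as specified under these idealized
conditions; they do not calibrate quantitative outcomes for any organic
system, and the emergent percentages depend on scale (grid, updates) and on
the simplified instruction set.

## Problem sizes used by the test suite

The qualitative-ordering tests run the reduced profile: 30×30 grid, 3,000
updates, 10 replicates for each of seven conditions (direct/indirect KIL 3
with controls, direct KIL 100 with control, indirect KIL 0), chosen as the
smallest scale at which the orderings are stable. Statistical parameter
checks use 100,000 Monte Carlo attempts (success rate), 600,000 scheduled
cycles (merit proportionality), 80,000 placements (birth-site uniformity),
and 10,000 copies (binomial mutation law), each with 3σ bounds or
χ²-goodness-of-fit at α = 0.001. The event-resolution oracle check covers
1,000 randomized snapshots against a brute-force partition.

## Known limitations

- Multiplicative stacking is unbounded; merits are float64, and a
  sufficiently pathological run (hundreds of stacked events on one
  organism) would overflow. Not observed at study scales; the latch mode
  bounds the effect if needed.
- The probabilistic scheduler grants cycles i.i.d. within an update, which
  is only one of several classical merit-proportional schedulers; others
  (e.g. round-robin with integer quanta) would change within-update
  ordering.
- At full scale a single replicate executes ~10⁸ cycles; the fast engine
  handles this, but the reference engine is for toy scales only.
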