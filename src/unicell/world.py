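"""Toroidal world, merit-proportional scheduler, and cell-death event resolution.

The world is a ``grid_width x grid_height`` torus with at most one organism
per cell; state is stored column-oriented (one slot per cell) so the same
arrays back both the readable pure-Python *reference* engine defined here and
the numba-compiled *fast* engine in :mod:`unicell._kernel`. The two engines
consume random draws in the identical documented order from the same
``numpy.random.Generator`` stream, so a run is reproducible bit-for-bit under
either engine and the engines can be cross-checked for exact agreement.

Scheduling: each update grants ``cycles_per_organism_per_update x population``
CPU cycles one at a time, each to an organism drawn with probability
proportional to its merit (fixed for an organism's lifetime). Organisms
killed mid-update have their scheduling weight zeroed immediately — the
cumulative table is rebuilt so draws stay exactly proportional over the
survivors — and organisms born mid-update only become eligible at the next
update.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterator

import numpy as np

from .errors import ConfigurationError, SimulationStateError, UsageError
from .genome import (COPY, DIVIDE, PCD, Genome, InstructionSet, make_ancestor,
                     mutate_site)
from .organism import (COPIED_SITE, DIVIDED, NOOP, PCD_ATTEMPT_FAILED,
                       PCD_DEATH, Organism, apply_pcd_effect)

#: Fixed order of the 8 birth-neighbourhood offsets (dx, dy); index drawn
#: uniformly at division. The fast kernel uses the same table.
DX8 = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)
DY8 = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)


@dataclass(frozen=True)
class SimulationConfig:
    """Fully-resolved configuration of one run.

    Defaults are the study conditions: a 60x60 torus, length-100 genomes over
    a 26-symbol alphabet, copy mutation 0.0075 per site, a 5% cell-death
    success probability with a Chebyshev radius-2 effect neighbourhood, an
    effect factor of 5 (1 = no-effect control), and 30 cycles per organism
    per update for 60,000 updates.
    """

    grid_width: int = 60
    grid_height: int = 60
    genome_length: int = 100
    alphabet_size: int = 26
    mu: float = 0.0075
    p_success: float = 0.05
    mode: str = "direct"
    effect_factor: float = 5.0
    kil: int = 3
    radius: int = 2
    cycles_per_organism_per_update: int = 30
    updates: int = 60_000
    seed: int = 0
    sample_interval: int = 10
    endpoint_window: int = 100
    exclude_original_on_mutation: bool = True
    effect_stacking: str = "multiplicative"
    engine: str = "fast"

    def __post_init__(self) -> None:
        for key in ("grid_width", "grid_height", "genome_length", "alphabet_size",
                    "cycles_per_organism_per_update", "sample_interval",
                    "endpoint_window"):
            if int(getattr(self, key)) <= 0:
                raise ConfigurationError(f"{key} must be positive, got {getattr(self, key)}")
        if self.grid_width < 3 or self.grid_height < 3:
            raise ConfigurationError(
                "grid must be at least 3x3 for the 8-cell birth neighbourhood; "
                f"got {self.grid_width}x{self.grid_height}")
        if self.genome_length < 3:
            raise ConfigurationError(f"genome_length must be >= 3, got {self.genome_length}")
        if self.alphabet_size < 4:
            raise ConfigurationError(f"alphabet_size must be >= 4, got {self.alphabet_size}")
        if not 0.0 <= self.mu <= 1.0:
            raise ConfigurationError(f"mu must be in [0, 1], got {self.mu}")
        if not 0.0 <= self.p_success <= 1.0:
            raise ConfigurationError(f"p_success must be in [0, 1], got {self.p_success}")
        if self.mode not in ("direct", "indirect"):
            raise ConfigurationError(f"mode must be 'direct' or 'indirect', got {self.mode!r}")
        if self.effect_factor < 1.0:
            raise ConfigurationError(
                f"effect_factor must be >= 1 (1 is the control), got {self.effect_factor}")
        if not 0 <= self.kil <= self.genome_length:
            raise ConfigurationError(
                f"kil must be in [0, genome_length={self.genome_length}], got {self.kil}")
        if self.radius < 0:
            raise ConfigurationError(f"radius must be >= 0, got {self.radius}")
        if 2 * self.radius >= min(self.grid_width, self.grid_height):
            raise ConfigurationError(
                f"radius {self.radius} wraps onto itself on a "
                f"{self.grid_width}x{self.grid_height} torus")
        if self.updates < 0:
            raise ConfigurationError(f"updates must be >= 0, got {self.updates}")
        if self.effect_stacking not in ("multiplicative", "latch"):
            raise ConfigurationError(
                f"effect_stacking must be 'multiplicative' or 'latch', got {self.effect_stacking!r}")
        if self.engine not in ("fast", "reference"):
            raise ConfigurationError(f"engine must be 'fast' or 'reference', got {self.engine!r}")

    @property
    def instruction_set(self) -> InstructionSet:
        return InstructionSet(self.alphabet_size)

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PCDEvent:
    """Record of one successful programmed-cell-death event.

    ``n_kin_affected`` / ``n_nonkin_affected`` count the occupied
    neighbourhood cells classified kin / nonkin against the dying organism's
    genome (they partition the occupied neighbourhood regardless of mode;
    which side's merit is touched depends on the mode). ``n_cheater_kin``
    counts kin whose genomes contain no PCD instruction — beneficiaries that
    can never pay the cost.
    """

    update: int
    x: int
    y: int
    n_kin_affected: int
    n_nonkin_affected: int
    n_cheater_kin: int

    @property
    def location(self) -> tuple[int, int]:
        return (self.x, self.y)


class World:
    """Occupancy grid plus all per-organism state arrays and the event log."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        W, H, L = config.grid_width, config.grid_height, config.genome_length
        C = W * H
        self.genomes = np.zeros((C, L), dtype=np.int8)
        self.buffers = np.zeros((C, L), dtype=np.int8)
        self.alive = np.zeros(C, dtype=np.bool_)
        self.eligible = np.zeros(C, dtype=np.bool_)
        self.merit = np.zeros(C, dtype=np.float64)
        self.offspring_multiplier = np.ones(C, dtype=np.float64)
        self.ip = np.zeros(C, dtype=np.int64)
        self.copy_progress = np.zeros(C, dtype=np.int64)
        self.pcd_attempts = np.zeros(C, dtype=np.int64)
        self.births = np.zeros(C, dtype=np.int64)
        self.cycles_executed = np.zeros(C, dtype=np.int64)
        self.ids = np.full(C, -1, dtype=np.int64)
        self.birth_update = np.zeros(C, dtype=np.int64)
        self.effect_latched = np.zeros(C, dtype=np.bool_)
        self.attempted_this_update = np.zeros(C, dtype=np.bool_)
        self.rng = np.random.default_rng(config.seed)
        self.update = 0
        self.extinct = False
        self.events: list[PCDEvent] = []
        self.time_series: list[dict] = []
        self._pop = 0
        self._next_id = 0
        self._n_eligible = 0
        self._on_death = None  # scheduler hook set during step_update
        self._ev_buffers = None  # lazily allocated scratch for the fast engine

    # ------------------------------------------------------------------
    # occupancy helpers
    # ------------------------------------------------------------------
    @property
    def population(self) -> int:
        return self._pop

    def cell_index(self, location: tuple[int, int]) -> int:
        x, y = location
        W, H = self.config.grid_width, self.config.grid_height
        if not (0 <= x < W and 0 <= y < H):
            raise UsageError(f"location {location} outside {W}x{H} grid")
        return y * W + x

    def organism_at(self, location: tuple[int, int]) -> Organism | None:
        c = self.cell_index(location)
        return Organism(self, c) if self.alive[c] else None

    def organisms(self) -> Iterator[Organism]:
        for c in np.flatnonzero(self.alive):
            yield Organism(self, int(c))

    def _install(self, cell: int, sites: np.ndarray, merit: float,
                 multiplier: float = 1.0) -> Organism:
        """Put a fresh organism into ``cell`` (must be empty)."""
        if merit <= 0 or multiplier <= 0:
            raise UsageError("merit and offspring multiplier must be positive")
        self.genomes[cell, :] = sites
        self.buffers[cell, :] = 0
        self.merit[cell] = merit
        self.offspring_multiplier[cell] = multiplier
        self.ip[cell] = 0
        self.copy_progress[cell] = 0
        self.pcd_attempts[cell] = 0
        self.births[cell] = 0
        self.cycles_executed[cell] = 0
        self.ids[cell] = self._next_id
        self._next_id += 1
        self.birth_update[cell] = self.update
        self.effect_latched[cell] = False
        self.attempted_this_update[cell] = False
        self.alive[cell] = True
        self.eligible[cell] = False  # newborns wait until the next update
        self._pop += 1
        return Organism(self, cell)

    def _kill(self, cell: int) -> None:
        self.alive[cell] = False
        self._pop -= 1
        if self.eligible[cell]:
            self.eligible[cell] = False
            self._n_eligible -= 1
        if self._on_death is not None:
            self._on_death(cell)

    # ------------------------------------------------------------------
    # setup operations
    # ------------------------------------------------------------------
    def inject_ancestor(self, location: tuple[int, int] | None = None) -> Organism:
        """Seed an empty world with the ancestral self-replicator.

        The ancestor's merit is its genome length (L = 100 by default) and it
        carries no PCD instruction: the behaviour must arise de novo.
        """
        if self._pop > 0:
            raise UsageError("inject_ancestor requires an empty world")
        if location is None:
            location = (self.config.grid_width // 2, self.config.grid_height // 2)
        cell = self.cell_index(location)
        anc = make_ancestor(self.config)
        return self._install(cell, anc.sites, float(self.config.genome_length))

    def place(self, genome: Genome, location: tuple[int, int],
              merit: float | None = None, multiplier: float = 1.0) -> Organism:
        """Fixture builder: put an explicit genome at an explicit coordinate."""
        if len(genome) != self.config.genome_length:
            raise UsageError(
                f"genome length {len(genome)} != configured L={self.config.genome_length}")
        cell = self.cell_index(location)
        if self.alive[cell]:
            raise UsageError(f"cell {location} is already occupied")
        if merit is None:
            merit = float(self.config.genome_length)
        return self._install(cell, genome.sites, merit, multiplier)

    # ------------------------------------------------------------------
    # spatial operations
    # ------------------------------------------------------------------
    def neighborhood(self, center: tuple[int, int],
                     radius: int | None = None) -> list[tuple[int, int]]:
        """All cells within Chebyshev distance ``radius`` of ``center``,
        excluding the center, with toroidal wrapping; fixed row-major scan
        order, no duplicates. Radius 2 yields the 24-cell 5x5 Moore block.
        """
        radius = self.config.radius if radius is None else radius
        if radius < 0:
            raise ConfigurationError(f"radius must be >= 0, got {radius}")
        W, H = self.config.grid_width, self.config.grid_height
        if 2 * radius >= min(W, H) and radius > 0:
            raise ConfigurationError(
                f"radius {radius} wraps onto itself on a {W}x{H} torus")
        x0, y0 = center
        self.cell_index(center)  # bounds check
        out = []
        for dy in range(-radius, radius + 1):
            for dx in range(-radius, radius + 1):
                if dx == 0 and dy == 0:
                    continue
                out.append(((x0 + dx) % W, (y0 + dy) % H))
        return out

    def place_offspring(self, parent_loc: tuple[int, int], genome: Genome,
                        merit: float, rng: np.random.Generator | None = None) -> Organism:
        """Install an offspring in one of the parent's 8 immediate neighbours.

        The destination is drawn uniformly over all 8 cells regardless of
        occupancy; any occupant is killed (overwritten). The parent stays
        where it is.
        """
        rng = rng if rng is not None else self.rng
        pc = self.cell_index(parent_loc)
        if not self.alive[pc]:
            raise UsageError("parent is not alive at parent_loc")
        W, H = self.config.grid_width, self.config.grid_height
        d = int(rng.integers(0, 8))
        nx = (parent_loc[0] + int(DX8[d])) % W
        ny = (parent_loc[1] + int(DY8[d])) % H
        t = ny * W + nx
        if self.alive[t]:
            self._kill(t)
        return self._install(t, genome.sites, merit)

    def resolve_pcd_event(self, focal_loc: tuple[int, int]) -> PCDEvent:
        """Resolve a *successful* cell-death attempt at ``focal_loc``.

        Every occupied cell within the effect radius is classified kin or
        nonkin by Hamming distance to the dying organism's genome at the KIL
        in force. Direct mode multiplies each kin's offspring multiplier by
        the effect factor; indirect mode divides each nonkin's. With factor 1
        (control) the classification is still recorded but no merit changes.
        The focal organism is removed and its cell left empty.
        """
        cfg = self.config
        fc = self.cell_index(focal_loc)
        if not self.alive[fc]:
            raise SimulationStateError(f"no living organism at {focal_loc}")
        focal_sites = self.genomes[fc].copy()  # snapshot at the instant of death
        n_kin = n_nonkin = n_cheat = 0
        for (x, y) in self.neighborhood(focal_loc):
            t = y * cfg.grid_width + x
            if not self.alive[t]:
                continue
            hd = int(np.count_nonzero(self.genomes[t] != focal_sites))
            if hd <= cfg.kil:
                n_kin += 1
                if not np.any(self.genomes[t] == PCD):
                    n_cheat += 1
                if cfg.mode == "direct":
                    apply_pcd_effect(Organism(self, t), "direct",
                                     cfg.effect_factor, cfg.effect_stacking)
            else:
                n_nonkin += 1
                if cfg.mode == "indirect":
                    apply_pcd_effect(Organism(self, t), "indirect",
                                     cfg.effect_factor, cfg.effect_stacking)
        self._kill(fc)
        event = PCDEvent(self.update, focal_loc[0], focal_loc[1],
                         n_kin, n_nonkin, n_cheat)
        self.events.append(event)
        if self._pop == 0:
            self.extinct = True
        return event

    # ------------------------------------------------------------------
    # reference engine (semantic definition; RNG protocol mirrored by
    # unicell._kernel.run_updates)
    # ------------------------------------------------------------------
    def _execute_cycle(self, cell: int, rng: np.random.Generator | None = None) -> str:
        """One CPU cycle: read genome[ip], apply semantics, advance ip mod L.

        RNG draws, in order: COPY with copy space left and mu>0 draws one
        uniform (plus one integer iff mutating); a completing DIVIDE draws one
        integer in [0,8); PCD draws one uniform. A successful divide resets ip
        to 0 instead of advancing; a cell death leaves ip untouched.
        """
        rng = rng if rng is not None else self.rng
        cfg = self.config
        if not self.alive[cell]:
            raise SimulationStateError("executing a dead organism")
        L = cfg.genome_length
        self.cycles_executed[cell] += 1
        sym = int(self.genomes[cell, self.ip[cell]])
        outcome = NOOP
        advance = True
        if sym == COPY:
            pr = int(self.copy_progress[cell])
            if pr < L:
                self.buffers[cell, pr] = mutate_site(
                    int(self.genomes[cell, pr]), cfg.mu, rng, cfg.alphabet_size,
                    cfg.exclude_original_on_mutation)
                self.copy_progress[cell] = pr + 1
                outcome = COPIED_SITE
        elif sym == DIVIDE:
            if int(self.copy_progress[cell]) == L:
                x, y = cell % cfg.grid_width, cell // cfg.grid_width
                child_merit = float(L) * float(self.offspring_multiplier[cell])
                self.place_offspring((x, y), Genome(self.buffers[cell].copy()),
                                     child_merit, rng=rng)
                self.births[cell] += 1
                self.copy_progress[cell] = 0
                self.ip[cell] = 0
                advance = False
                outcome = DIVIDED
        elif sym == PCD:
            self.pcd_attempts[cell] += 1
            self.attempted_this_update[cell] = True
            if rng.random() < cfg.p_success:
                x, y = cell % cfg.grid_width, cell // cfg.grid_width
                self.resolve_pcd_event((x, y))
                advance = False
                outcome = PCD_DEATH
            else:
                outcome = PCD_ATTEMPT_FAILED
        # any other symbol is inert
        if advance:
            self.ip[cell] = (self.ip[cell] + 1) % L
        return outcome

    def step_update(self, rng: np.random.Generator | None = None) -> dict:
        """Run one update with the reference engine; returns instantaneous stats."""
        if self.extinct:
            raise SimulationStateError("world is extinct")
        if self._pop < 1:
            raise SimulationStateError("step_update requires population >= 1")
        rng = rng if rng is not None else self.rng
        cfg = self.config
        C = self.alive.size
        self.attempted_this_update[:] = False
        np.copyto(self.eligible, self.alive)
        self._n_eligible = int(self._pop)
        # Scheduling weights are zeroed on death (with the cumulative table
        # rebuilt) so draws stay exactly merit-proportional over survivors;
        # newborns keep weight 0 until the next update.
        w = np.where(self.alive, self.merit, 0.0)
        cum = np.cumsum(w)

        def on_death(cell: int) -> None:
            w[cell] = 0.0
            np.cumsum(w, out=cum)

        budget = cfg.cycles_per_organism_per_update * self._pop
        granted = 0
        prev_hook = self._on_death
        self._on_death = on_death
        try:
            while granted < budget:
                total = float(cum[-1])
                if self._n_eligible == 0 or total <= 0.0:
                    break
                u = rng.random()
                c = int(np.searchsorted(cum, u * total, side="right"))
                if c >= C:
                    c = C - 1
                if not self.eligible[c]:
                    continue  # float plateau edge: redraw
                self._execute_cycle(c, rng=rng)
                granted += 1
                if self.extinct:
                    return self._instant_stats()
        finally:
            self._on_death = prev_hook
        self.update += 1
        return self._instant_stats()

    # ------------------------------------------------------------------
    # driver
    # ------------------------------------------------------------------
    def run(self, updates: int | None = None,
            on_sample: Callable[[dict], None] | None = None,
            record: bool = True) -> None:
        """Advance the world, sampling metrics every ``sample_interval`` updates.

        Uses the configured engine (``fast`` = numba kernel, ``reference`` =
        pure Python); both produce identical trajectories for a given seed.
        An extinction (the last organism performing cell death) halts the run
        with ``self.extinct`` set; partial outputs are retained.
        """
        cfg = self.config
        target = self.update + (cfg.updates if updates is None else int(updates))
        if record and not self.time_series:
            self._record_sample(0)
            if on_sample is not None:
                on_sample(self.time_series[-1])
        while self.update < target and not self.extinct:
            n = min(cfg.sample_interval, target - self.update)
            n_events_before = len(self.events)
            if cfg.engine == "fast":
                self._run_chunk_fast(n)
            else:
                for _ in range(n):
                    self.step_update()
                    if self.extinct:
                        break
            if record:
                self._record_sample(len(self.events) - n_events_before)
                if on_sample is not None:
                    on_sample(self.time_series[-1])

    def _run_chunk_fast(self, n_updates: int) -> None:
        from ._kernel import run_updates
        cfg = self.config
        C = self.alive.size
        cap = cfg.cycles_per_organism_per_update * C * cfg.sample_interval + 1
        if self._ev_buffers is None or self._ev_buffers[0].size < cap:
            self._ev_buffers = tuple(np.empty(cap, dtype=np.int64) for _ in range(5))
        ev_update, ev_cell, ev_kin, ev_nonkin, ev_cheat = self._ev_buffers
        status, done, n_ev, pop, next_id = run_updates(
            self.genomes, self.buffers, self.alive, self.eligible,
            self.merit, self.offspring_multiplier, self.ip, self.copy_progress,
            self.pcd_attempts, self.births, self.cycles_executed, self.ids,
            self.birth_update, self.effect_latched, self.attempted_this_update,
            ev_update, ev_cell, ev_kin, ev_nonkin, ev_cheat,
            cfg.grid_width, cfg.grid_height, cfg.genome_length, cfg.alphabet_size,
            cfg.mu, cfg.p_success, cfg.mode == "direct", float(cfg.effect_factor),
            cfg.kil, cfg.radius, cfg.cycles_per_organism_per_update,
            cfg.exclude_original_on_mutation,
            cfg.effect_stacking == "multiplicative",
            self.update, int(n_updates), self._pop, self._next_id, self.rng)
        self._pop = int(pop)
        self._next_id = int(next_id)
        self.update += int(done)
        W = cfg.grid_width
        for i in range(int(n_ev)):
            c = int(ev_cell[i])
            self.events.append(PCDEvent(int(ev_update[i]), c % W, c // W,
                                        int(ev_kin[i]), int(ev_nonkin[i]),
                                        int(ev_cheat[i])))
        if status == 1:
            self.extinct = True

    # ------------------------------------------------------------------
    # metrics sampling and output frames
    # ------------------------------------------------------------------
    def _instant_stats(self) -> dict:
        alive = self.alive
        pop = self._pop
        if pop == 0:
            pct_att = carrier = mean_merit = incidence = float("nan")
        else:
            pct_att = 100.0 * float(np.mean(self.pcd_attempts[alive] >= 1))
            carrier = 100.0 * float(np.mean((self.genomes[alive] == PCD).any(axis=1)))
            mean_merit = float(np.mean(self.merit[alive]))
            incidence = 100.0 * float(np.mean(self.attempted_this_update[alive]))
        return {
            "update": self.update,
            "population": pop,
            "pct_attempting_pcd": pct_att,
            "carrier_pct": carrier,
            "mean_merit": mean_merit,
            "pcd_incidence_pct": incidence,
        }

    def _record_sample(self, n_new_events: int) -> dict:
        row = self._instant_stats()
        row["n_pcd_events"] = int(n_new_events)
        row["extinct"] = bool(self.extinct)
        self.time_series.append(row)
        return row

    def timeseries_df(self):
        import pandas as pd
        cols = ["update", "population", "pct_attempting_pcd", "carrier_pct",
                "mean_merit", "n_pcd_events", "pcd_incidence_pct", "extinct"]
        return pd.DataFrame(self.time_series, columns=cols)

    def events_df(self):
        import pandas as pd
        cfg = self.config
        rows = [{"update": e.update, "x": e.x, "y": e.y, "mode": cfg.mode,
                 "kil": cfg.kil, "n_kin_affected": e.n_kin_affected,
                 "n_nonkin_affected": e.n_nonkin_affected,
                 "n_cheater_kin": e.n_cheater_kin} for e in self.events]
        cols = ["update", "x", "y", "mode", "kil", "n_kin_affected",
                "n_nonkin_affected", "n_cheater_kin"]
        return pd.DataFrame(rows, columns=cols)

    def dump_df(self):
        """Population dump: one row per living organism, row-major order."""
        import pandas as pd
        iset = self.config.instruction_set
        rows = []
        for c in np.flatnonzero(self.alive):
            c = int(c)
            rows.append({
                "x": c % self.config.grid_width,
                "y": c // self.config.grid_width,
                "id": int(self.ids[c]),
                "merit": float(self.merit[c]),
                "offspring_multiplier": float(self.offspring_multiplier[c]),
                "pcd_attempts": int(self.pcd_attempts[c]),
                "genome": Genome(self.genomes[c]).to_string(iset),
            })
        cols = ["x", "y", "id", "merit", "offspring_multiplier",
                "pcd_attempts", "genome"]
        return pd.DataFrame(rows, columns=cols)
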