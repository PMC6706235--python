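"""Per-organism execution state and instruction semantics.

An :class:`Organism` is a live view into the column-oriented state arrays of a
:class:`~unicell.world.World` (one slot per grid cell), so reading or writing
an attribute touches the single authoritative copy of the simulation state.
The cycle-level semantics of COPY / DIVIDE / PCD / INERT are implemented by
the world's reference engine; the free functions here are the stable
operation surface over it.

Merit is the organism's scheduling weight ("metabolic rate"): an organism is
granted CPU cycles in proportion to merit, so a five-fold merit advantage
means executing instructions five times faster on average. Merit is fixed at
birth; what a programmed-cell-death event changes is the *offspring merit
multiplier* of the surviving neighbours, i.e. the factor applied to the base
merit of every offspring they subsequently produce.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError, SimulationStateError
from .genome import Genome

#: Cycle outcomes returned by :func:`execute_cycle`.
NOOP = "noop"
COPIED_SITE = "copied_site"
DIVIDED = "divided"
PCD_ATTEMPT_FAILED = "pcd_attempt_failed"
PCD_DEATH = "pcd_death"


class Organism:
    """View of the organism occupying one world cell.

    Attribute reads/writes go straight to the world's state arrays. The view
    stays bound to the cell: if the occupant dies and a newborn claims the
    cell, the view describes the newborn.
    """

    __slots__ = ("world", "cell")

    def __init__(self, world, cell: int):
        self.world = world
        self.cell = int(cell)

    # -- location ---------------------------------------------------------
    @property
    def x(self) -> int:
        return self.cell % self.world.config.grid_width

    @property
    def y(self) -> int:
        return self.cell // self.world.config.grid_width

    @property
    def location(self) -> tuple[int, int]:
        return (self.x, self.y)

    # -- state ------------------------------------------------------------
    @property
    def alive(self) -> bool:
        return bool(self.world.alive[self.cell])

    @property
    def genome(self) -> Genome:
        return Genome(self.world.genomes[self.cell])

    @property
    def merit(self) -> float:
        return float(self.world.merit[self.cell])

    @property
    def offspring_multiplier(self) -> float:
        return float(self.world.offspring_multiplier[self.cell])

    @offspring_multiplier.setter
    def offspring_multiplier(self, value: float) -> None:
        self.world.offspring_multiplier[self.cell] = value

    @property
    def ip(self) -> int:
        return int(self.world.ip[self.cell])

    @property
    def copy_progress(self) -> int:
        return int(self.world.copy_progress[self.cell])

    @property
    def offspring_buffer(self) -> np.ndarray:
        """The partially copied offspring genome (length == copy_progress)."""
        return self.world.buffers[self.cell, : self.copy_progress].copy()

    @property
    def pcd_attempts(self) -> int:
        return int(self.world.pcd_attempts[self.cell])

    @property
    def births(self) -> int:
        return int(self.world.births[self.cell])

    @property
    def cycles_executed(self) -> int:
        return int(self.world.cycles_executed[self.cell])

    @property
    def id(self) -> int:
        return int(self.world.ids[self.cell])

    @property
    def birth_update(self) -> int:
        return int(self.world.birth_update[self.cell])

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"Organism(id={self.id}, at=({self.x},{self.y}), "
                f"merit={self.merit:g}, mult={self.offspring_multiplier:g})")


def execute_cycle(org: Organism, world=None, rng: np.random.Generator | None = None) -> str:
    """Execute one CPU cycle of ``org``: read genome[ip], apply, advance ip.

    Returns one of ``noop`` / ``copied_site`` / ``divided`` /
    ``pcd_attempt_failed`` / ``pcd_death``. ``world`` and ``rng`` default to
    the organism's own world and its stream.
    """
    world = world if world is not None else org.world
    if not world.alive[org.cell]:
        raise SimulationStateError("executing a dead organism")
    return world._execute_cycle(org.cell, rng=rng)


def attempt_pcd(org: Organism, world=None, rng: np.random.Generator | None = None) -> str:
    """One programmed-cell-death attempt: with probability ``p_success`` the
    organism dies and the event is resolved against its neighbourhood;
    otherwise nothing changes beyond the attempt counter.

    Returns ``"death"`` or ``"survive"``.
    """
    world = world if world is not None else org.world
    if not world.alive[org.cell]:
        raise SimulationStateError("dead organism cannot attempt cell death")
    rng = rng if rng is not None else world.rng
    world.pcd_attempts[org.cell] += 1
    world.attempted_this_update[org.cell] = True
    if rng.random() < world.config.p_success:
        world.resolve_pcd_event((org.x, org.y))
        return "death"
    return "survive"


def offspring_merit(parent: Organism, config=None) -> float:
    """Merit assigned to the parent's next offspring.

    The base merit equals the genome length L (the ancestor's metabolic rate
    is the size of its genome), scaled by the parent's latent offspring
    multiplier accumulated from cell-death events it benefited or suffered
    from.
    """
    config = config if config is not None else parent.world.config
    return float(config.genome_length) * parent.offspring_multiplier


def apply_pcd_effect(org: Organism, mode: str, factor: float,
                     stacking: str = "multiplicative") -> Organism:
    """Apply one cell-death event's effect to a surviving neighbour.

    ``direct`` mode multiplies the recipient's offspring multiplier by
    ``factor`` (benefit to kin); ``indirect`` divides it (harm to nonkin).
    ``factor == 1`` is the no-effect control and leaves state untouched.
    Effects from multiple events stack multiplicatively by default; with
    ``stacking="latch"`` only the first event affecting an organism applies.
    """
    if factor <= 0:
        raise ConfigurationError(f"effect factor must be positive, got {factor}")
    if mode not in ("direct", "indirect"):
        raise ConfigurationError(f"mode must be 'direct' or 'indirect', got {mode!r}")
    if factor == 1.0:
        return org
    if stacking == "latch" and org.world.effect_latched[org.cell]:
        return org
    if mode == "direct":
        org.offspring_multiplier *= factor
    else:
        org.offspring_multiplier /= factor
    org.world.effect_latched[org.cell] = True
    return org
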