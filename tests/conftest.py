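"""Shared fixtures and deterministic hypothesis settings."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from unicell.genome import COPY, DIVIDE, PCD, Genome, InstructionSet
from unicell.world import SimulationConfig, World

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def iset() -> InstructionSet:
    return InstructionSet()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def make_world(**overrides) -> World:
    """Small toy world with mutation and cell death off unless asked for."""
    kwargs = dict(grid_width=7, grid_height=7, genome_length=100, mu=0.0,
                  updates=0, seed=5, engine="reference")
    kwargs.update(overrides)
    return World(SimulationConfig(**kwargs))


def all_inert_genome(L: int = 100, iset: InstructionSet | None = None) -> Genome:
    """A sterile genome: no COPY, no DIVIDE, no PCD."""
    iset = iset or InstructionSet()
    return Genome(np.full(L, iset.first_inert, dtype=np.int8))


def genome_with(L: int = 100, pcd_at: tuple[int, ...] = (),
                base_symbol: int | None = None) -> Genome:
    """An inert genome with PCD instructions planted at given sites."""
    iset = InstructionSet()
    base = iset.first_inert if base_symbol is None else base_symbol
    sites = np.full(L, base, dtype=np.int8)
    for i in pcd_at:
        sites[i] = PCD
    return Genome(sites)


def random_genome(rng: np.random.Generator, L: int = 100,
                  alphabet_size: int = 26) -> Genome:
    return Genome(rng.integers(0, alphabet_size, size=L).astype(np.int8))


def toroidal_chebyshev(a, b, W, H):
    dx = abs(a[0] - b[0])
    dy = abs(a[1] - b[1])
    return max(min(dx, W - dx), min(dy, H - dy))


def check_random_pcd_snapshot(seed: int) -> None:
    """Assert resolve_pcd_event counts match an independent brute-force
    partition of the 5x5 Moore block on one randomized toy world."""
    rng = np.random.default_rng(seed)
    kil = int(rng.integers(0, 7))
    mode = "direct" if rng.random() < 0.5 else "indirect"
    w = make_world(grid_width=9, grid_height=9, genome_length=20,
                   kil=kil, mode=mode)
    base = random_genome(rng, 20)
    occupied = []
    for x in range(9):
        for y in range(9):
            if (x, y) == (4, 4) or rng.random() < 0.5:
                g = base.copy()
                n_mut = int(rng.integers(0, 8))
                for i in rng.integers(0, 20, size=n_mut):
                    g.sites[i] = int(rng.integers(0, 26))
                w.place(Genome(g.sites.copy()), (x, y))
                occupied.append(((x, y), g))
    focal = dict(occupied)[(4, 4)]
    expect_kin = expect_nonkin = expect_cheat = 0
    for (loc, g) in occupied:
        if loc == (4, 4):
            continue
        if toroidal_chebyshev(loc, (4, 4), 9, 9) <= 2:
            hd = sum(1 for i in range(20) if g.sites[i] != focal.sites[i])
            if hd <= kil:
                expect_kin += 1
                if not np.any(g.sites == PCD):
                    expect_cheat += 1
            else:
                expect_nonkin += 1
    ev = w.resolve_pcd_event((4, 4))
    assert (ev.n_kin_affected, ev.n_nonkin_affected, ev.n_cheater_kin) == \
        (expect_kin, expect_nonkin, expect_cheat)


class QueuedRng:
    """Test double yielding scripted uniform/integer draws."""

    def __init__(self, uniforms=(), integers=()):
        self._u = list(uniforms)
        self._i = list(integers)

    def random(self, size=None):
        assert size is None
        return self._u.pop(0)

    def integers(self, low, high=None, size=None):
        assert size is None
        return self._i.pop(0)
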