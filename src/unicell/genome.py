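"""Fixed-length instruction genomes, copy mutation, and Hamming-distance kinship.

Each organism carries a genome of exactly ``L`` instruction symbols drawn from a
small alphabet in which exactly one symbol copies a site of the genome (COPY),
one finalizes reproduction (DIVIDE), one triggers stochastic programmed cell
death (PCD), and all remaining symbols are inert. Because genomes never change
length (substitution-only mutation), relatedness between two organisms is the
plain Hamming distance between their genomes, and an organism is *kin* to a
focal organism when that distance does not exceed the kin-inclusivity level
(KIL) in force.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import ConfigurationError, UsageError

#: Role codes. They double as the canonical symbol indices of the three
#: functional instructions: symbol 0 is always COPY, 1 DIVIDE, 2 PCD; symbols
#: 3..size-1 are inert.
COPY, DIVIDE, PCD, INERT = 0, 1, 2, 3

#: Characters for the 23 inert symbols of the default 26-symbol alphabet:
#: the lowercase alphabet minus 'c', 'd', 'p' (reserved for the functional
#: roles), extended with digits and uppercase for larger alphabets.
_INERT_CHARS = "abefghijklmnoqrstuvwxyz" + "0123456789" + \
    "ABEFGHIJKLMNOQRSTUVWXYZ"


@dataclass(frozen=True)
class InstructionSet:
    """An instruction alphabet of ``size`` distinct symbols.

    Exactly one symbol each has the COPY, DIVIDE and PCD role; the remaining
    ``size - 3`` symbols are inert. The default size of 26 (23 inert symbols)
    mimics the mutational target size of a full Avida-style instruction set in
    which only the replication machinery and the cell-death instruction have
    any phenotypic effect.
    """

    size: int = 26

    def __post_init__(self) -> None:
        if self.size < 4:
            raise ConfigurationError(
                f"alphabet_size must be >= 4 (one COPY, one DIVIDE, one PCD, "
                f"at least one inert symbol); got {self.size}"
            )
        if self.size - 3 > len(_INERT_CHARS):
            raise ConfigurationError(
                f"alphabet_size {self.size} exceeds the supported maximum of "
                f"{len(_INERT_CHARS) + 3}"
            )

    @property
    def n_inert(self) -> int:
        return self.size - 3

    @property
    def first_inert(self) -> int:
        """Symbol index of the first inert instruction."""
        return INERT

    def role(self, symbol: int) -> int:
        """Role code (COPY/DIVIDE/PCD/INERT) of a symbol index."""
        if not 0 <= symbol < self.size:
            raise UsageError(f"symbol {symbol} outside alphabet of size {self.size}")
        return symbol if symbol < 3 else INERT

    def char(self, symbol: int) -> str:
        """One-character serialization of a symbol ('c'/'d'/'p' + inert letters)."""
        if symbol == COPY:
            return "c"
        if symbol == DIVIDE:
            return "d"
        if symbol == PCD:
            return "p"
        return _INERT_CHARS[symbol - 3]

    def symbol(self, char: str) -> int:
        """Inverse of :meth:`char`."""
        if char == "c":
            return COPY
        if char == "d":
            return DIVIDE
        if char == "p":
            return PCD
        idx = _INERT_CHARS.find(char)
        if idx < 0 or idx >= self.n_inert:
            raise UsageError(f"character {char!r} is not in the alphabet")
        return idx + 3


class Genome:
    """A fixed-length sequence of instruction symbols (int8 codes).

    The symbol array is owned by the genome unless it was constructed as a
    view into world storage; callers treat genomes as immutable.
    """

    __slots__ = ("sites",)

    def __init__(self, sites: Iterable[int] | np.ndarray):
        self.sites = np.asarray(sites, dtype=np.int8)
        if self.sites.ndim != 1 or self.sites.size == 0:
            raise UsageError("a genome is a non-empty 1-D symbol sequence")

    def __len__(self) -> int:
        return int(self.sites.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return len(self) == len(other) and bool(np.array_equal(self.sites, other.sites))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Genome(L={len(self)})"

    def copy(self) -> "Genome":
        return Genome(self.sites.copy())

    def to_string(self, iset: InstructionSet | None = None) -> str:
        """Serialize to one character per site (used in population dumps)."""
        iset = iset or InstructionSet()
        return "".join(iset.char(int(s)) for s in self.sites)

    @classmethod
    def from_string(cls, s: str, iset: InstructionSet | None = None) -> "Genome":
        iset = iset or InstructionSet()
        return cls([iset.symbol(ch) for ch in s])


def make_ancestor(config) -> Genome:
    """Build the injected ancestor: a viable self-replicator with no PCD symbol.

    Layout for genome length ``L >= 11``: sites ``0..L-11`` are COPY (90 of
    them at the default L=100), the next nine sites are the first inert
    symbol, and the final site is DIVIDE. For ``3 <= L < 11`` the inert pad is
    dropped (all COPY then DIVIDE). Cell death must arise de novo by mutation,
    so the ancestor contains zero PCD symbols. ``config`` needs only the
    attributes ``genome_length`` and ``alphabet_size``.
    """
    L = int(config.genome_length)
    if L < 3:
        raise ConfigurationError(f"genome_length must be >= 3, got {L}")
    iset = InstructionSet(int(config.alphabet_size))
    sites = np.empty(L, dtype=np.int8)
    n_inert = 9 if L >= 11 else 0
    n_copy = L - 1 - n_inert
    sites[:n_copy] = COPY
    sites[n_copy:L - 1] = iset.first_inert
    sites[L - 1] = DIVIDE
    return Genome(sites)


def hamming_distance(g1: Genome, g2: Genome) -> int:
    """Number of sites at which two equal-length genomes differ."""
    if len(g1) != len(g2):
        raise UsageError(
            f"genomes must have equal length (got {len(g1)} and {len(g2)}); "
            "the model forbids variable-length genomes"
        )
    return int(np.count_nonzero(g1.sites != g2.sites))


def classify_kin(g_focal: Genome, g_other: Genome, kil: int) -> bool:
    """True iff ``g_other`` is kin to ``g_focal`` at kin-inclusivity level ``kil``.

    Kin means the Hamming distance is at most ``kil``: at KIL 0 only exact
    clones are kin, at KIL = L every genome is kin.
    """
    if kil < 0 or kil > len(g_focal):
        raise ConfigurationError(f"kil must be in [0, L], got {kil}")
    return hamming_distance(g_focal, g_other) <= kil


def count_pcd_sites(g: Genome) -> int:
    """Number of sites carrying the PCD instruction (0 for a non-carrier)."""
    return int(np.count_nonzero(g.sites == PCD))


def mutate_site(symbol: int, mu: float, rng: np.random.Generator,
                alphabet_size: int, exclude_original: bool = True) -> int:
    """Copy one site with the per-site substitution rule.

    With probability ``mu`` the copied symbol is replaced by a draw that is
    uniform over the alphabet excluding the original symbol (default), so that
    ``mu`` is exactly the per-site probability of a genetic difference; with
    ``exclude_original=False`` the draw is uniform over the whole alphabet
    (the Avida convention, under which the realized difference rate is
    ``mu * (1 - 1/size)``).

    RNG protocol (shared verbatim by the fast kernel): no draw when
    ``mu == 0``; otherwise one uniform, plus one integer draw iff it mutates.
    """
    if mu > 0.0 and rng.random() < mu:
        if exclude_original:
            r = int(rng.integers(0, alphabet_size - 1))
            return r + 1 if r >= symbol else r
        return int(rng.integers(0, alphabet_size))
    return int(symbol)


def copy_with_mutation(source: Genome, mu: float, rng: np.random.Generator,
                       iset: InstructionSet | None = None,
                       exclude_original: bool = True) -> Genome:
    """Whole-genome copy with independent per-site substitution at rate ``mu``.

    Length is always preserved (no insertions or deletions). The number of
    mutated sites is Binomial(L, mu) under the default exclude-original rule.
    """
    if not 0.0 <= mu <= 1.0:
        raise ConfigurationError(f"mu must be in [0, 1], got {mu}")
    iset = iset or InstructionSet()
    sites = source.sites.copy()
    if mu > 0.0:
        mask = rng.random(sites.size) < mu
        n = int(mask.sum())
        if n:
            if exclude_original:
                r = rng.integers(0, iset.size - 1, size=n)
                orig = sites[mask].astype(np.int64)
                sites[mask] = np.where(r >= orig, r + 1, r).astype(np.int8)
            else:
                sites[mask] = rng.integers(0, iset.size, size=n).astype(np.int8)
    return Genome(sites)
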