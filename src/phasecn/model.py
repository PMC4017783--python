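"""Genotype/haplotype data model for joint CNV/SNP data.

Each locus of an individual is observed as a pair ``(total_cn, allele1_count)``:
the integer total copy number across both chromosomes (0-4, since each
chromosome carries at most a single duplication) and the number of those
copies carrying allele 1.

Two phasing modes are supported:

* **non-internal** — each chromosome carries one symbol per locus from
  ``{-, 0, 1, 00, 01, 11}`` describing its total allele content (deletion,
  single copy, or duplicated pair).
* **internal** — within a fixed-ploidy region the individual copies are
  resolved, each copy carrying one allele from ``{-, 0, 1}``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

NON_INTERNAL = "non-internal"
INTERNAL = "internal"

#: per-chromosome symbols in non-internal mode, in canonical (sorted) order
NON_INTERNAL_SYMBOLS = ("-", "0", "00", "01", "1", "11")
INTERNAL_SYMBOLS = ("-", "0", "1")

SYMBOL_COPIES = {"-": 0, "0": 1, "1": 1, "00": 2, "01": 2, "11": 2}
SYMBOL_ONES = {"-": 0, "0": 0, "1": 1, "00": 0, "01": 1, "11": 2}

MAX_TOTAL_CN = 4
DEFAULT_MAX_BLOCK = 5


class GenotypeError(ValueError):
    """Raised for observations or files violating the data-model invariants."""


@dataclass(frozen=True)
class SiteObservation:
    """Observed (total copy number, allele-1 count) at one locus."""

    total_cn: int
    allele1_count: int

    def __post_init__(self) -> None:
        if not (0 <= self.total_cn <= MAX_TOTAL_CN):
            raise GenotypeError(
                f"total copy number {self.total_cn} outside [0, {MAX_TOTAL_CN}]"
            )
        if not (0 <= self.allele1_count <= self.total_cn):
            raise GenotypeError(
                f"allele-1 count {self.allele1_count} outside "
                f"[0, total_cn={self.total_cn}]"
            )

    def __str__(self) -> str:
        return f"{self.total_cn}:{self.allele1_count}"


@dataclass(frozen=True)
class GenotypeVector:
    """One individual's ordered observations across all loci."""

    individual_id: str
    sites: tuple[SiteObservation, ...]

    def __len__(self) -> int:
        return len(self.sites)

    def slice(self, start: int, end: int) -> "GenotypeVector":
        """Restrict to the half-open locus interval [start, end)."""
        return GenotypeVector(self.individual_id, self.sites[start:end])


@dataclass(frozen=True)
class GenotypeSet:
    """An ordered collection of individuals sharing the same loci."""

    individuals: tuple[GenotypeVector, ...]

    def __post_init__(self) -> None:
        lengths = {len(g) for g in self.individuals}
        if len(lengths) > 1:
            raise GenotypeError(f"individuals differ in locus count: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self) -> Iterator[GenotypeVector]:
        return iter(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.individuals[0]) if self.individuals else 0

    def slice(self, start: int, end: int) -> "GenotypeSet":
        return GenotypeSet(tuple(g.slice(start, end) for g in self.individuals))


def symbol_copies(symbol: str) -> int:
    return SYMBOL_COPIES[symbol]


def symbol_ones(symbol: str) -> int:
    return SYMBOL_ONES[symbol]


@dataclass(frozen=True, order=True)
class Haplotype:
    """A single chromosome (or copy) as an ordered symbol string.

    Equality and ordering are by the state sequence, so haplotype universes
    deduplicate and sort deterministically.
    """

    mode: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        alphabet = NON_INTERNAL_SYMBOLS if self.mode == NON_INTERNAL else INTERNAL_SYMBOLS
        for s in self.states:
            if s not in alphabet:
                raise GenotypeError(f"symbol {s!r} not in {self.mode} alphabet")

    def __len__(self) -> int:
        return len(self.states)

    def copies_at(self, i: int) -> int:
        return SYMBOL_COPIES[self.states[i]]

    def ones_at(self, i: int) -> int:
        return SYMBOL_ONES[self.states[i]]

    def __str__(self) -> str:
        return " ".join(self.states)


@dataclass(frozen=True, order=True)
class Assignment:
    """An unordered multiset of haplotypes for one individual.

    Stored as a sorted tuple so that two assignments differing only by
    haplotype order compare equal and hash identically.
    """

    haplotypes: tuple[Haplotype, ...]

    def __post_init__(self) -> None:
        if not self.haplotypes:
            raise GenotypeError("empty assignment")
        modes = {h.mode for h in self.haplotypes}
        lengths = {len(h) for h in self.haplotypes}
        if len(modes) > 1 or len(lengths) > 1:
            raise GenotypeError("assignment haplotypes must share mode and length")
        object.__setattr__(self, "haplotypes", tuple(sorted(self.haplotypes)))

    @property
    def mode(self) -> str:
        return self.haplotypes[0].mode

    @property
    def ploidy(self) -> int:
        return len(self.haplotypes)

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __str__(self) -> str:
        return " | ".join(str(h) for h in self.haplotypes)


@dataclass
class HaplotypeUniverse:
    """First-seen-ordered, deduplicated list of haplotypes with an index map."""

    haplotypes: list[Haplotype] = field(default_factory=list)
    index: dict[Haplotype, int] = field(default_factory=dict)

    def add(self, h: Haplotype) -> int:
        i = self.index.get(h)
        if i is None:
            if self.haplotypes and self.haplotypes[0].mode != h.mode:
                raise GenotypeError("mixed phasing modes in one universe")
            i = len(self.haplotypes)
            self.haplotypes.append(h)
            self.index[h] = i
        return i

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __getitem__(self, i: int) -> Haplotype:
        return self.haplotypes[i]

    def __contains__(self, h: Haplotype) -> bool:
        return h in self.index


def enumerate_site_states(
    obs: SiteObservation,
    mode: str = NON_INTERNAL,
    diploid_at_cn2: bool = True,
) -> set[tuple[str, ...]]:
    """All unordered per-chromosome symbol combinations matching ``obs``.

    Non-internal mode returns size-2 tuples (one symbol per chromosome);
    internal mode returns the allele multiset of size ``total_cn`` over
    {0, 1} (a single multiset, or ``('-',)`` marking a fully deleted locus).

    With ``diploid_at_cn2`` (the default), a total copy number of 2 is taken
    as two normal chromosomes, excluding the masked deletion+duplication
    combinations such as ``('-', '01')``.
    """
    cn, ones = obs.total_cn, obs.allele1_count
    if mode == INTERNAL:
        if cn == 0:
            return {("-",)}
        return {("0",) * (cn - ones) + ("1",) * ones}
    out: set[tuple[str, ...]] = set()
    for a, b in itertools.combinations_with_replacement(NON_INTERNAL_SYMBOLS, 2):
        if SYMBOL_COPIES[a] + SYMBOL_COPIES[b] != cn:
            continue
        if SYMBOL_ONES[a] + SYMBOL_ONES[b] != ones:
            continue
        if diploid_at_cn2 and cn == 2 and "-" in (a, b):
            continue
        out.add((a, b))
    return out


def _site_states_or_raise(
    obs: SiteObservation, locus: int, mode: str, diploid_at_cn2: bool
) -> set[tuple[str, ...]]:
    states = enumerate_site_states(obs, mode, diploid_at_cn2)
    if not states:
        raise GenotypeError(f"no valid phase at locus {locus} for observation {obs}")
    return states


def enumerate_assignments(
    g: GenotypeVector,
    mode: str = NON_INTERNAL,
    max_block: int = DEFAULT_MAX_BLOCK,
    diploid_at_cn2: bool = True,
) -> list[Assignment]:
    """Complete, duplicate-free list of assignments consistent with ``g``.

    The result is sorted lexicographically over state sequences so that
    particle expansion and tie-breaking are reproducible.  Blocks longer
    than ``max_block`` loci are refused (combinatorial guard).
    """
    L = len(g)
    if L == 0:
        raise GenotypeError("empty genotype block")
    if L > max_block:
        raise GenotypeError(
            f"block of {L} loci exceeds the maximum of {max_block}; "
            "use partition-ligation"
        )
    if mode == INTERNAL:
        return _enumerate_internal(g)
    per_locus: list[list[tuple[str, str]]] = []
    for i, obs in enumerate(g.sites):
        pairs = _site_states_or_raise(obs, i, mode, diploid_at_cn2)
        ordered: set[tuple[str, str]] = set()
        for a, b in pairs:
            ordered.add((a, b))
            ordered.add((b, a))
        per_locus.append(sorted(ordered))
    seen: set[Assignment] = set()
    for combo in itertools.product(*per_locus):
        h1 = Haplotype(mode, tuple(p[0] for p in combo))
        h2 = Haplotype(mode, tuple(p[1] for p in combo))
        seen.add(Assignment((h1, h2)))
    return sorted(seen)


def _enumerate_internal(g: GenotypeVector) -> list[Assignment]:
    p = region_ploidy(g, (0, len(g)))
    if p == 0:
        hap = Haplotype(INTERNAL, ("-",) * len(g))
        return [Assignment((hap,))]
    per_locus: list[list[tuple[str, ...]]] = []
    for obs in g.sites:
        ones = obs.allele1_count
        choices = [
            tuple("1" if j in ones_at else "0" for j in range(p))
            for ones_at in itertools.combinations(range(p), ones)
        ]
        per_locus.append(choices)
    seen: set[Assignment] = set()
    for combo in itertools.product(*per_locus):
        haps = tuple(
            Haplotype(INTERNAL, tuple(col[j] for col in combo)) for j in range(p)
        )
        seen.add(Assignment(haps))
    return sorted(seen)


def is_consistent(a: Assignment, g: GenotypeVector) -> bool:
    """True iff at every locus the summed copies and allele-1 counts match."""
    if len(a.haplotypes[0]) != len(g):
        raise GenotypeError(
            f"assignment covers {len(a.haplotypes[0])} loci, genotype {len(g)}"
        )
    for i, obs in enumerate(g.sites):
        copies = sum(h.copies_at(i) for h in a.haplotypes)
        ones = sum(h.ones_at(i) for h in a.haplotypes)
        if a.mode == INTERNAL:
            # internal haplotypes carry one symbol per copy; '-' marks cn 0
            if obs.total_cn == 0:
                if any(h.states[i] != "-" for h in a.haplotypes):
                    return False
                continue
        if copies != obs.total_cn or ones != obs.allele1_count:
            return False
    return True


def build_universe(assignment_lists: Iterable[Sequence[Assignment]]) -> HaplotypeUniverse:
    """First-seen-ordered union of every haplotype in the per-individual lists."""
    universe = HaplotypeUniverse()
    for assignments in assignment_lists:
        for a in assignments:
            for h in a.haplotypes:
                universe.add(h)
    return universe


def ploidy_profile(g: GenotypeVector) -> list[int]:
    """Per-locus total copy number vector."""
    return [obs.total_cn for obs in g.sites]


def region_ploidy(g: GenotypeVector, region: tuple[int, int]) -> int:
    """Common total copy number over the half-open region, or raise.

    Internal phasing requires constant ploidy; varying copy number within
    the region directs the caller to non-internal mode / partition-ligation.
    """
    start, end = region
    if not (0 <= start < end <= len(g)):
        raise GenotypeError(f"region {region} outside [0, {len(g)})")
    cns = {obs.total_cn for obs in g.sites[start:end]}
    if len(cns) != 1:
        raise GenotypeError(
            f"copy number varies within region {region} ({sorted(cns)}); "
            "internal phasing needs a fixed-ploidy region — use non-internal "
            "mode or partition-ligation"
        )
    return cns.pop()
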