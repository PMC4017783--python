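"""Partition-ligation: block-wise phasing of long marker sets.

Long locus sets are split into blocks of at most 5 loci, each block is
phased with the sequential sampler, and neighboring blocks are merged by
pairing chromosomes across the junction.  Only pairings producing the
minimum number of per-chromosome copy-number changes at the junction are
kept (both pairings when they tie, e.g. when the two chromosomes have equal
boundary copy number).  Each merged candidate carries a ligation weight —
the product of its two source solution weights — and the sampler is rerun
over the merged candidates with their weights offset by that ligation
weight.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import model, sampler
from .model import (
    Assignment,
    GenotypeSet,
    GenotypeVector,
    Haplotype,
    HaplotypeUniverse,
    INTERNAL,
    NON_INTERNAL,
)
from .sampler import BlockSolution, CandidateSet, phase_block

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Block:
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValueError(f"empty block [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def partition_loci(L: int, block_size: int = 5) -> list[Block]:
    """Tile [0, L) into consecutive blocks of ``block_size`` plus a remainder."""
    if L < 1:
        raise ValueError("need at least one locus")
    if block_size < 1:
        raise ValueError("block size must be >= 1")
    blocks = [Block(s, min(s + block_size, L)) for s in range(0, L, block_size)]
    return blocks


def junction_cn_changes(left: Assignment, right: Assignment, orientation: int) -> int:
    """Copy-number changes across the junction under a chromosome pairing.

    ``orientation`` 0 pairs left/right chromosomes in canonical order,
    1 pairs them crossed.  Counts chromosomes whose per-chromosome copy
    number at the last left locus differs from the first right locus.
    """
    if left.mode == INTERNAL or right.mode == INTERNAL:
        raise ValueError("ligation operates on non-internal (diploid) assignments")
    if len(left) != 2 or len(right) != 2:
        raise ValueError("ligation expects diploid assignments")
    l0, l1 = left.haplotypes
    r0, r1 = right.haplotypes
    if orientation == 1:
        r0, r1 = r1, r0
    last = len(l0) - 1
    changes = int(l0.copies_at(last) != r0.copies_at(0))
    changes += int(l1.copies_at(last) != r1.copies_at(0))
    return changes


def _merge(left: Assignment, right: Assignment, orientation: int) -> Assignment:
    l0, l1 = left.haplotypes
    r0, r1 = right.haplotypes
    if orientation == 1:
        r0, r1 = r1, r0
    mode = left.mode
    return Assignment(
        (
            Haplotype(mode, l0.states + r0.states),
            Haplotype(mode, l1.states + r1.states),
        )
    )


def ligate(
    left: BlockSolution,
    right: BlockSolution,
    K: int = 50,
    *,
    epsilon: float = 1.0,
    max_candidates: int = 256,
    genotypes: GenotypeSet | None = None,
    shuffle_seed: int | None = None,
) -> BlockSolution:
    """Merge two adjacent block solutions and rerun the sampler.

    For every individual and every (left assignment, right assignment) pair,
    merged candidates are generated only for chromosome pairings achieving
    the minimal junction copy-number change count for that pair (both
    pairings when they tie).  Candidates repeat-generated by several source
    pairs accumulate their ligation weights.
    """
    if left.block[1] != right.block[0]:
        raise ValueError(f"blocks {left.block} and {right.block} are not adjacent")
    if left.individual_ids != right.individual_ids:
        raise ValueError("block solutions cover different individuals")

    tiny = 1e-300  # guards log of weights that underflowed to 0
    merged_sets: list[list[tuple[Assignment, float]]] = []
    for t in range(len(left.individual_ids)):
        acc: dict[Assignment, float] = {}
        for la, wa in left.per_individual[t].items():
            for rb, wb in right.per_individual[t].items():
                lw = math.log(max(wa, tiny)) + math.log(max(wb, tiny))
                c0 = junction_cn_changes(la, rb, 0)
                c1 = junction_cn_changes(la, rb, 1)
                best = min(c0, c1)
                merged = {
                    _merge(la, rb, ori)
                    for ori, c in ((0, c0), (1, c1))
                    if c == best
                }
                for m in merged:
                    acc[m] = float(np.logaddexp(acc[m], lw)) if m in acc else lw
        items = sorted(acc.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(items) > max_candidates:
            logger.info(
                "individual %s: %d merged candidates capped to %d",
                left.individual_ids[t], len(items), max_candidates,
            )
            items = items[:max_candidates]
        # deterministic candidate enumeration order, offsets shifted for numerics
        items.sort(key=lambda kv: kv[0])
        shift = max(lw for _, lw in items)
        merged_sets.append([(a, lw - shift) for a, lw in items])

    universe = HaplotypeUniverse()
    for items in merged_sets:
        for a, _ in items:
            for h in a.haplotypes:
                universe.add(h)
    candidates = [
        CandidateSet.from_assignments(
            [a for a, _ in items], universe, [lw for _, lw in items]
        )
        for items in merged_sets
    ]

    span = (left.block[0], right.block[1])
    if genotypes is None:
        # reconstruct genotype slice from any consistent assignment
        rows = []
        for t, items in enumerate(merged_sets):
            a = items[0][0]
            sites = tuple(
                model.SiteObservation(
                    sum(h.copies_at(i) for h in a.haplotypes),
                    sum(h.ones_at(i) for h in a.haplotypes),
                )
                for i in range(span[1] - span[0])
            )
            rows.append(GenotypeVector(left.individual_ids[t], sites))
        genotypes = GenotypeSet(tuple(rows))

    return phase_block(
        genotypes,
        NON_INTERNAL,
        K,
        epsilon=epsilon,
        candidates=candidates,
        universe=universe,
        shuffle_seed=shuffle_seed,
        block=span,
    )


@dataclass
class PhasingResult:
    """Final output of hierarchical phasing."""

    solution: BlockSolution
    assignments: list[Assignment]
    frequencies: np.ndarray

    @property
    def universe(self) -> HaplotypeUniverse:
        return self.solution.universe

    def frequency_table(self) -> dict[Haplotype, float]:
        """Estimated frequency per universe haplotype (zeros dropped)."""
        return {
            h: float(f)
            for h, f in zip(self.universe.haplotypes, self.frequencies)
            if f > 0
        }


def hierarchical_phase(
    genotypes: GenotypeSet,
    mode: str = NON_INTERNAL,
    K: int = 50,
    *,
    epsilon: float = 1.0,
    block_size: int = model.DEFAULT_MAX_BLOCK,
    max_candidates: int = 256,
    ligation_order: str = "progressive",
    diploid_at_cn2: bool = True,
    shuffle_seed: int | None = None,
) -> PhasingResult:
    """Partition, phase each block, ligate, and hard-phase every individual.

    Ligation is progressive left-to-right by default (``ligation_order``
    "pairwise" merges adjacent pairs at log depth instead).  Internal mode
    does not ligate across blocks and is therefore limited to regions of at
    most ``block_size`` loci.
    """
    L = genotypes.n_loci
    if mode == INTERNAL and L > block_size:
        raise ValueError(
            "internal phasing is restricted to fixed-ploidy regions of at "
            f"most {block_size} loci; phase longer regions non-internally"
        )
    blocks = partition_loci(L, block_size)
    solutions = [
        phase_block(
            genotypes.slice(b.start, b.end),
            mode,
            K,
            epsilon=epsilon,
            max_block=block_size,
            diploid_at_cn2=diploid_at_cn2,
            shuffle_seed=shuffle_seed,
            block=(b.start, b.end),
        )
        for b in blocks
    ]
    if ligation_order not in ("progressive", "pairwise"):
        raise ValueError(f"unknown ligation order {ligation_order!r}")
    while len(solutions) > 1:
        if ligation_order == "progressive":
            merged = ligate(
                solutions[0],
                solutions[1],
                K,
                epsilon=epsilon,
                max_candidates=max_candidates,
                genotypes=genotypes.slice(solutions[0].block[0], solutions[1].block[1]),
                shuffle_seed=shuffle_seed,
            )
            solutions = [merged] + solutions[2:]
        else:
            nxt = []
            for i in range(0, len(solutions) - 1, 2):
                nxt.append(
                    ligate(
                        solutions[i],
                        solutions[i + 1],
                        K,
                        epsilon=epsilon,
                        max_candidates=max_candidates,
                        genotypes=genotypes.slice(
                            solutions[i].block[0], solutions[i + 1].block[1]
                        ),
                        shuffle_seed=shuffle_seed,
                    )
                )
            if len(solutions) % 2:
                nxt.append(solutions[-1])
            solutions = nxt

    final = solutions[0]
    hard = [final.best_assignment(t) for t in range(len(genotypes))]
    return PhasingResult(final, hard, final.frequencies())


DUPLICATED = {"00", "01", "11"}


def duplicated_runs(hap: Haplotype) -> list[tuple[int, int]]:
    """Maximal half-open runs of duplicated symbols along one chromosome."""
    runs = []
    start = None
    for i, s in enumerate(hap.states):
        if s in DUPLICATED:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(hap.states)))
    return runs


def internal_refine(
    assignments: Sequence[Assignment],
    K: int = 50,
    *,
    epsilon: float = 1.0,
    block_size: int = model.DEFAULT_MAX_BLOCK,
    max_candidates: int = 256,
) -> dict[tuple[int, int, tuple[int, int]], tuple[str, str]]:
    """Resolve the two copies inside every duplicated chromosome region.

    Each duplicated run of a chromosome poses a two-copy phasing problem:
    per locus the run carries 0, 1 or 2 copies of allele 1.  Runs sharing
    the same locus interval are pooled across chromosomes and phased
    jointly (non-internal machinery on copy-number-2 pseudo-genotypes,
    which is isomorphic to diploid SNP phasing of the copies).  Chromosomes
    carrying plain single-copy alleles across the whole interval are added
    as resolved homozygous pseudo-individuals: their segments are known
    population haplotypes and anchor the frequency statistics that the
    ambiguous copies are phased against.

    Returns ``{(individual, chromosome, (start, end)): (copy1, copy2)}``
    with copies as 0/1 strings.
    """
    groups: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for t, a in enumerate(assignments):
        for j, hap in enumerate(a.haplotypes):
            for run in duplicated_runs(hap):
                groups.setdefault(run, []).append((t, j))

    out: dict[tuple[int, int, tuple[int, int]], tuple[str, str]] = {}
    for (start, end), members in sorted(groups.items()):
        rows = []
        for t, a in enumerate(assignments):
            for j, hap in enumerate(a.haplotypes):
                seg = hap.states[start:end]
                if all(s in ("0", "1") for s in seg):
                    sites = tuple(
                        model.SiteObservation(2, 2 * int(s)) for s in seg
                    )
                    rows.append(GenotypeVector(f"anchor.{t}.{j}", sites))
        n_anchor = len(rows)  # anchors first: their counts inform the copies
        for t, j in members:
            hap = assignments[t].haplotypes[j]
            sites = tuple(
                model.SiteObservation(2, model.symbol_ones(hap.states[i]))
                for i in range(start, end)
            )
            rows.append(GenotypeVector(f"{t}.{j}", sites))
        sub = GenotypeSet(tuple(rows))
        result = hierarchical_phase(
            sub,
            NON_INTERNAL,
            K,
            epsilon=epsilon,
            block_size=block_size,
            max_candidates=max_candidates,
        )
        for (t, j), a in zip(members, result.assignments[n_anchor:]):
            c1, c2 = a.haplotypes
            out[(t, j, (start, end))] = (
                "".join(c1.states),
                "".join(c2.states),
            )
    return out
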