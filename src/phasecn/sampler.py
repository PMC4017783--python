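"""Tree-based deterministic sequential Monte Carlo phasing engine.

The sampler maintains ``K`` candidate solution streams ("particles").  Each
particle holds, for every individual processed so far, one compatible
haplotype assignment, together with the Dirichlet sufficient statistics of
its history and a log weight.  Processing the next individual expands every
particle with every assignment compatible with that individual's genotype,
weights each child by the Dirichlet-multinomial predictive probability of
the new draws, and deterministically retains the ``K`` highest-weight
children.

Weights are carried in natural-log space.  For an unordered assignment the
predictive is the ordered-draw beta-function ratio multiplied by the number
of distinct orderings of the haplotype multiset, which makes the particle
approximation a proper distribution over unordered assignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from . import model
from .dirichlet import SufficientStats, init_prior
from .model import Assignment, GenotypeSet, GenotypeVector, HaplotypeUniverse


def log_orderings(assignment: Assignment) -> float:
    """ln of the number of distinct orderings of the haplotype multiset."""
    p = len(assignment.haplotypes)
    n = math.factorial(p)
    prev = None
    run = 0
    for h in assignment.haplotypes:  # already sorted
        if h == prev:
            run += 1
        else:
            run = 1
            prev = h
        if run > 1:
            n //= run
    return math.log(n)


@dataclass
class CandidateSet:
    """Pre-indexed compatible assignments for one individual.

    ``idx[c, j]`` is the universe index of the ``j``-th haplotype of
    candidate ``c`` (candidates share ploidy).  ``log_offsets`` carries
    per-candidate initial log weights (zero normally; the ligation weight
    during a partition-ligation rerun).
    """

    assignments: list[Assignment]
    idx: np.ndarray
    log_ord: np.ndarray
    log_offsets: np.ndarray

    @classmethod
    def from_assignments(
        cls,
        assignments: Sequence[Assignment],
        universe: HaplotypeUniverse,
        log_offsets: Sequence[float] | None = None,
    ) -> "CandidateSet":
        if not assignments:
            raise ValueError("empty candidate list: inconsistent genotype upstream")
        p = len(assignments[0].haplotypes)
        idx = np.array(
            [[universe.index[h] for h in a.haplotypes] for a in assignments],
            dtype=np.int64,
        ).reshape(len(assignments), p)
        lo = np.array([log_orderings(a) for a in assignments])
        off = (
            np.zeros(len(assignments))
            if log_offsets is None
            else np.asarray(log_offsets, dtype=float)
        )
        return cls(list(assignments), idx, lo, off)

    def __len__(self) -> int:
        return len(self.assignments)


class _HistoryNode:
    """Parent-pointer history cell: (previous node, candidate index)."""

    __slots__ = ("parent", "cand")

    def __init__(self, parent: "_HistoryNode | None", cand: int):
        self.parent = parent
        self.cand = cand


@dataclass
class ParticleSystem:
    """The current set of at most K particles over one haplotype universe.

    ``counts[k]`` are the integer haplotype counts of stream ``k``'s history
    (its Dirichlet stats are ``epsilon + counts[k]``); ``log_weights`` are
    normalized; ``log_norm`` tracks the total retained unnormalized mass.
    """

    universe: HaplotypeUniverse
    K: int
    epsilon: float
    counts: np.ndarray
    log_weights: np.ndarray
    nodes: list[_HistoryNode | None]
    log_norm: float = 0.0
    n_processed: int = 0

    @classmethod
    def fresh(cls, universe: HaplotypeUniverse, K: int, epsilon: float = 1.0):
        if K < 1:
            raise ValueError("particle budget K must be >= 1")
        if len(universe) == 0:
            raise ValueError("empty haplotype universe")
        return cls(
            universe=universe,
            K=K,
            epsilon=float(epsilon),
            counts=np.zeros((1, len(universe)), dtype=np.int64),
            log_weights=np.zeros(1),
            nodes=[None],
            log_norm=0.0,
            n_processed=0,
        )

    @property
    def n_particles(self) -> int:
        return self.counts.shape[0]

    def stats(self, k: int) -> SufficientStats:
        return SufficientStats(
            self.epsilon + self.counts[k].astype(float), self.epsilon
        )

    def history(self, k: int) -> list[int]:
        """Candidate indices chosen by particle ``k``, in processing order."""
        out: list[int] = []
        node = self.nodes[k]
        while node is not None:
            out.append(node.cand)
            node = node.parent
        out.reverse()
        return out


@dataclass
class Expansion:
    """All K * K_ext weighted candidate particles for one individual."""

    system: ParticleSystem
    candidates: CandidateSet
    log_weights: np.ndarray  # shape (K, K_ext)


def expand(system: ParticleSystem, candidates: CandidateSet) -> Expansion:
    """Weight every (particle, candidate assignment) child.

    The child log weight is the parent's log weight plus the log
    Dirichlet-multinomial predictive of the candidate's haplotype draws
    against the parent's statistics (sequential form: no gamma functions
    needed for integer draws), plus the multiset-ordering term and any
    candidate offset.  Parent statistics are untouched.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate list")
    idx = candidates.idx
    p = idx.shape[1]
    eps = system.epsilon
    rho = system.counts + eps  # (K, M) float via broadcasting
    total0 = rho.sum(axis=1)  # (K,)
    w = (
        system.log_weights[:, None]
        + candidates.log_ord[None, :]
        + candidates.log_offsets[None, :]
    )
    for j in range(p):
        a = idx[:, j]
        eq = (idx[:, :j] == idx[:, j : j + 1]).sum(axis=1)  # same-hap earlier draws
        w = w + np.log(rho[:, a] + eq[None, :]) - np.log(total0 + j)[:, None]
    return Expansion(system, candidates, w)


def select(expansion: Expansion, K: int | None = None) -> ParticleSystem:
    """Deterministically retain the top-K children.

    Ties are broken by (parent index, candidate enumeration index); weights
    are re-normalized in log space and the retained unnormalized mass is
    accumulated in ``log_norm``.
    """
    system = expansion.system
    if K is None:
        K = system.K
    w = expansion.log_weights
    n_parent, n_cand = w.shape
    flat = w.ravel()
    parent_ids = np.repeat(np.arange(n_parent), n_cand)
    cand_ids = np.tile(np.arange(n_cand), n_parent)
    order = np.lexsort((cand_ids, parent_ids, -flat))
    keep = order[:K]
    sel_w = flat[keep]
    sel_parent = parent_ids[keep]
    sel_cand = cand_ids[keep]
    norm = float(logsumexp(sel_w))

    counts = system.counts[sel_parent].copy()
    rows = np.repeat(np.arange(keep.size), expansion.candidates.idx.shape[1])
    cols = expansion.candidates.idx[sel_cand].ravel()
    np.add.at(counts, (rows, cols), 1)

    nodes = [
        _HistoryNode(system.nodes[pk], int(ck))
        for pk, ck in zip(sel_parent, sel_cand)
    ]
    return ParticleSystem(
        universe=system.universe,
        K=system.K,
        epsilon=system.epsilon,
        counts=counts,
        log_weights=sel_w - norm,
        nodes=nodes,
        log_norm=system.log_norm + norm,
        n_processed=system.n_processed + 1,
    )


@dataclass
class BlockSolution:
    """Weighted per-individual assignment sets produced by phasing one block."""

    block: tuple[int, int]
    individual_ids: list[str]
    per_individual: list[dict[Assignment, float]]
    universe: HaplotypeUniverse
    system: ParticleSystem

    def best_assignment(self, t: int) -> Assignment:
        """Arg-max aggregated weight; ties to the lexicographically smallest."""
        sol = self.per_individual[t]
        return min(sol, key=lambda a: (-sol[a], a))

    def frequencies(
        self, subtract_prior: bool = True, average: bool = False
    ) -> np.ndarray:
        return estimate_frequencies(
            self.system, subtract_prior=subtract_prior, average=average
        )


def aggregate_solutions(
    system: ParticleSystem,
    candidate_sets: Sequence[CandidateSet],
    individual_ids: Sequence[str],
    processing_order: Sequence[int],
    block: tuple[int, int] = (0, 0),
) -> BlockSolution:
    """Collapse particles into per-individual assignment distributions.

    For each individual the distinct assignments across particles receive
    the summed normalized particle weights, so weights sum to 1.
    """
    weights = np.exp(system.log_weights - logsumexp(system.log_weights))
    per_individual: list[dict[Assignment, float]] = [dict() for _ in candidate_sets]
    for k in range(system.n_particles):
        hist = system.history(k)
        wk = float(weights[k])
        for step, cand_index in enumerate(hist):
            t = processing_order[step]
            a = candidate_sets[t].assignments[cand_index]
            d = per_individual[t]
            d[a] = d.get(a, 0.0) + wk
    return BlockSolution(
        block=tuple(block),
        individual_ids=list(individual_ids),
        per_individual=per_individual,
        universe=system.universe,
        system=system,
    )


def estimate_frequencies(
    system: ParticleSystem,
    subtract_prior: bool = True,
    average: bool = False,
) -> np.ndarray:
    """Haplotype frequency estimate from the particle statistics.

    Default: posterior mean of the highest-weight particle with the prior
    pseudocounts removed (pure observed-count frequencies).  ``average``
    weights all particles; ``subtract_prior=False`` keeps the pseudocounts.
    """
    if average:
        w = np.exp(system.log_weights - logsumexp(system.log_weights))
        base = system.counts.astype(float)
        if not subtract_prior:
            base = base + system.epsilon
        per = base / base.sum(axis=1, keepdims=True)
        return w @ per
    k = int(np.argmax(system.log_weights))
    base = system.counts[k].astype(float)
    if not subtract_prior:
        base = base + system.epsilon
    return base / base.sum()


def phase_block(
    genotypes: GenotypeSet,
    mode: str = model.NON_INTERNAL,
    K: int = 50,
    *,
    epsilon: float = 1.0,
    max_block: int = model.DEFAULT_MAX_BLOCK,
    diploid_at_cn2: bool = True,
    candidates: Sequence[CandidateSet] | None = None,
    universe: HaplotypeUniverse | None = None,
    processing_order: Sequence[int] | None = None,
    shuffle_seed: int | None = None,
    block: tuple[int, int] | None = None,
) -> BlockSolution:
    """Phase one block of loci by sequential expansion and selection.

    Individuals are processed in input order by default (``shuffle_seed``
    draws a random permutation instead); each step expands all particles
    with the individual's compatible assignments and keeps the top ``K``.
    Pre-built ``candidates`` (with a matching ``universe``) bypass
    enumeration — this is how the partition-ligation rerun injects merged
    candidates carrying ligation weights.
    """
    T = len(genotypes)
    if T == 0:
        raise ValueError("no individuals to phase")
    if candidates is None:
        assignment_lists = [
            model.enumerate_assignments(
                g, mode, max_block=max_block, diploid_at_cn2=diploid_at_cn2
            )
            for g in genotypes
        ]
        universe = model.build_universe(assignment_lists)
        candidates = [
            CandidateSet.from_assignments(al, universe) for al in assignment_lists
        ]
    elif universe is None:
        raise ValueError("pre-built candidates require their universe")
    if len(candidates) != T:
        raise ValueError("one candidate set per individual required")

    if processing_order is None:
        order = list(range(T))
        if shuffle_seed is not None:
            order = list(np.random.default_rng(shuffle_seed).permutation(T))
    else:
        order = list(processing_order)
        if sorted(order) != list(range(T)):
            raise ValueError("processing order must be a permutation of individuals")

    system = ParticleSystem.fresh(universe, K, epsilon)
    for t in order:
        system = select(expand(system, candidates[t]), K)

    ids = [g.individual_id for g in genotypes]
    if block is None:
        block = (0, genotypes.n_loci)
    return aggregate_solutions(system, candidates, ids, order, block)
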