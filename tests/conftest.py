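"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results from first principles
(exhaustive enumeration, sequential predictive products computed with
plain floats and dict counters) so they stay independent of the code paths
they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from phasecn.model import (
    Assignment,
    GenotypeSet,
    GenotypeVector,
    Haplotype,
    INTERNAL,
    NON_INTERNAL,
    NON_INTERNAL_SYMBOLS,
    SYMBOL_COPIES,
    SYMBOL_ONES,
    SiteObservation,
)

# ---------------------------------------------------------------- site states


def brute_site_pairs(cn: int, ones: int, diploid_at_cn2: bool = True):
    """All unordered symbol pairs with matching sums, by raw 6x6 scan."""
    out = set()
    for a in NON_INTERNAL_SYMBOLS:
        for b in NON_INTERNAL_SYMBOLS:
            if SYMBOL_COPIES[a] + SYMBOL_COPIES[b] != cn:
                continue
            if SYMBOL_ONES[a] + SYMBOL_ONES[b] != ones:
                continue
            if diploid_at_cn2 and cn == 2 and "-" in (a, b):
                continue
            out.add(tuple(sorted((a, b))))
    return out


# --------------------------------------------------------------- assignments


def brute_assignments_non_internal(g: GenotypeVector, diploid_at_cn2: bool = True):
    """Exhaustive scan over every per-locus ordered symbol pair."""
    per_locus = []
    for obs in g.sites:
        ordered = [
            (a, b)
            for a in NON_INTERNAL_SYMBOLS
            for b in NON_INTERNAL_SYMBOLS
            if SYMBOL_COPIES[a] + SYMBOL_COPIES[b] == obs.total_cn
            and SYMBOL_ONES[a] + SYMBOL_ONES[b] == obs.allele1_count
            and not (diploid_at_cn2 and obs.total_cn == 2 and "-" in (a, b))
        ]
        per_locus.append(ordered)
    seen = set()
    for combo in itertools.product(*per_locus):
        h1 = Haplotype(NON_INTERNAL, tuple(p[0] for p in combo))
        h2 = Haplotype(NON_INTERNAL, tuple(p[1] for p in combo))
        seen.add(Assignment((h1, h2)))
    return sorted(seen)


def brute_assignments_internal(g: GenotypeVector):
    """Exhaustive scan over all p-tuples of binary strings."""
    cns = {o.total_cn for o in g.sites}
    assert len(cns) == 1, "internal brute force needs fixed ploidy"
    p = cns.pop()
    L = len(g)
    if p == 0:
        return [Assignment((Haplotype(INTERNAL, ("-",) * L),))]
    strings = [tuple(s) for s in itertools.product("01", repeat=L)]
    seen = set()
    for haps in itertools.product(strings, repeat=p):
        ok = all(
            sum(int(h[i]) for h in haps) == g.sites[i].allele1_count
            for i in range(L)
        )
        if ok:
            seen.add(Assignment(tuple(Haplotype(INTERNAL, h) for h in haps)))
    return sorted(seen)


# -------------------------------------------------- exhaustive posterior oracle


def orderings(assignment: Assignment) -> int:
    from collections import Counter

    c = Counter(assignment.haplotypes)
    n = math.factorial(len(assignment.haplotypes))
    for v in c.values():
        n //= math.factorial(v)
    return n


def exact_posterior(assignment_lists, epsilon: float = 1.0):
    """Brute-force p(h_t | C) by enumerating every joint history.

    Returns (per-individual list of {Assignment: probability}, and the
    per-history weights for frequency checks).  Computed with plain dict
    counters and float products — independent of the sampler.
    """
    universe = []
    uindex = {}
    for al in assignment_lists:
        for a in al:
            for h in a.haplotypes:
                if h not in uindex:
                    uindex[h] = len(universe)
                    universe.append(h)
    M = len(universe)
    histories = []
    for combo in itertools.product(*assignment_lists):
        counts: dict[int, int] = {}
        total = 0
        logw = 0.0
        for a in combo:
            logw += math.log(orderings(a))
            for h in a.haplotypes:
                i = uindex[h]
                logw += math.log(epsilon + counts.get(i, 0))
                logw -= math.log(M * epsilon + total)
                counts[i] = counts.get(i, 0) + 1
                total += 1
        histories.append((combo, logw))
    mx = max(lw for _, lw in histories)
    Z = sum(math.exp(lw - mx) for _, lw in histories)
    marginals = [dict() for _ in assignment_lists]
    for combo, lw in histories:
        w = math.exp(lw - mx) / Z
        for t, a in enumerate(combo):
            marginals[t][a] = marginals[t].get(a, 0.0) + w
    return marginals, histories


# ------------------------------------------------------------ random genotypes


def random_genotype(rng: np.random.Generator, L: int, max_cn: int = 4):
    sites = []
    for _ in range(L):
        cn = int(rng.integers(0, max_cn + 1))
        ones = int(rng.integers(0, cn + 1))
        sites.append(SiteObservation(cn, ones))
    return GenotypeVector("r", tuple(sites))


def random_fixed_ploidy_genotype(rng: np.random.Generator, L: int, p: int):
    sites = tuple(
        SiteObservation(p, int(rng.integers(0, p + 1))) for _ in range(L)
    )
    return GenotypeVector("r", sites)


def random_genotype_set(rng: np.random.Generator, T: int, L: int, max_cn: int = 4):
    rows = []
    for t in range(T):
        g = random_genotype(rng, L, max_cn)
        rows.append(GenotypeVector(f"i{t}", g.sites))
    return GenotypeSet(tuple(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)
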