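"""Synthetic CNV/SNP dataset generator with known truth.

The construction mirrors a typical array-based study design: a phased
diploid SNP panel with linkage disequilibrium (produced by a mosaic
founder-copying model, standing in for a real reference panel), a minor
allele frequency filter, extraction of the distinct haplotypes with their
empirical frequencies, and stochastic replacement of segments of
frequency-selected haplotypes by CNV segments — at each position a CNV
region starts with a fixed probability and extends for a length drawn
uniformly on a small range, after which scanning resumes past the region.

Individuals are then drawn by frequency (random mating), and the emitted
genotypes carry per-locus (total copy number, allele-1 count) pairs.  The
post-insertion pool frequencies are the gold standard for frequency
evaluation; the per-individual chromosome pairs (including the ordered
copies inside duplicated regions) are the gold standard for phasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .model import (
    Assignment,
    GenotypeSet,
    GenotypeVector,
    Haplotype,
    NON_INTERNAL,
    SiteObservation,
)


@dataclass(frozen=True)
class SimConfig:
    L: int = 30
    T: int = 88
    maf_min: float = 0.05
    cnv_start_prob: float = 0.1
    cnv_len_min: int = 3
    cnv_len_max: int = 8
    dup_fraction: float = 0.5
    dup_content: str = "tandem"  # or "resampled" / "pool" (donor-haplotype copy)
    modify_fraction: float = 0.3
    seed: int = 0
    pool_size: int = 8
    switch_rate: float = 0.02
    raw_width: int | None = None  # pre-filter panel width; default 2L + 16

    def __post_init__(self) -> None:
        if self.L < 1 or self.T < 1:
            raise ValueError("L and T must be positive")
        if not (0.0 <= self.cnv_start_prob < 1.0):
            raise ValueError("cnv_start_prob must be in [0, 1)")
        if self.cnv_len_min > self.cnv_len_max or self.cnv_len_min < 1:
            raise ValueError("need 1 <= cnv_len_min <= cnv_len_max")
        if not (0.0 <= self.dup_fraction <= 1.0):
            raise ValueError("dup_fraction must be in [0, 1]")
        if self.dup_content not in ("tandem", "resampled", "pool"):
            raise ValueError("dup_content must be 'tandem', 'resampled' or 'pool'")
        if not (0.0 < self.modify_fraction <= 1.0):
            raise ValueError("modify_fraction must be in (0, 1]")
        if self.pool_size < 2:
            raise ValueError("founder pool must have at least 2 haplotypes")
        if not (0.0 <= self.switch_rate <= 1.0):
            raise ValueError("switch_rate must be in [0, 1]")


@dataclass(frozen=True)
class TrueChromosome:
    """One chromosome with per-locus copy tuples.

    ``copies[i]`` is ``()`` for a deletion, ``(a,)`` for a normal locus and
    ``(a, b)`` for a duplication (ordered: original copy first), with
    alleles in {0, 1}.
    """

    copies: tuple[tuple[int, ...], ...]

    def __len__(self) -> int:
        return len(self.copies)

    def to_haplotype(self) -> Haplotype:
        symbols = []
        for c in self.copies:
            if len(c) == 0:
                symbols.append("-")
            elif len(c) == 1:
                symbols.append(str(c[0]))
            else:
                symbols.append("".join(str(a) for a in sorted(c)))
        return Haplotype(NON_INTERNAL, tuple(symbols))

    def duplicated_runs(self) -> list[tuple[int, int]]:
        runs, start = [], None
        for i, c in enumerate(self.copies):
            if len(c) == 2:
                if start is None:
                    start = i
            elif start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, len(self.copies)))
        return runs


@dataclass
class HaplotypePool:
    chromosomes: list[TrueChromosome]
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.chromosomes) != self.frequencies.size:
            raise ValueError("pool chromosomes and frequencies misaligned")
        if not np.isclose(self.frequencies.sum(), 1.0):
            raise ValueError("pool frequencies must sum to 1")
        lengths = {len(c) for c in self.chromosomes}
        if len(lengths) > 1:
            raise ValueError("pool haplotypes differ in length")

    def __len__(self) -> int:
        return len(self.chromosomes)

    def haplotype_frequencies(self) -> dict[Haplotype, float]:
        """Frequencies keyed by non-internal haplotype (duplicates merged)."""
        out: dict[Haplotype, float] = {}
        for c, f in zip(self.chromosomes, self.frequencies):
            h = c.to_haplotype()
            out[h] = out.get(h, 0.0) + float(f)
        return out


@dataclass
class TruthSet:
    """Simulated individuals with their generating pool and genotypes."""

    chromosome_pairs: list[tuple[TrueChromosome, TrueChromosome]]
    genotypes: GenotypeSet
    pool: HaplotypePool
    config: SimConfig

    @property
    def assignments(self) -> list[Assignment]:
        return [
            Assignment((a.to_haplotype(), b.to_haplotype()))
            for a, b in self.chromosome_pairs
        ]

    def gold_frequencies(self) -> dict[Haplotype, float]:
        return self.pool.haplotype_frequencies()

    def duplicated_regions(self) -> dict[tuple[int, int, tuple[int, int]], tuple[str, str]]:
        """Ordered copy strings inside every duplicated chromosome run.

        Keys are ``(individual, chromosome, (start, end))``; chromosome
        index follows the sorted order of the truth assignment so it lines
        up with predictions made from assignments.
        """
        out: dict[tuple[int, int, tuple[int, int]], tuple[str, str]] = {}
        for t, pair in enumerate(self.chromosome_pairs):
            ordered = sorted(pair, key=lambda c: c.to_haplotype())
            for j, chrom in enumerate(ordered):
                for start, end in chrom.duplicated_runs():
                    c1 = "".join(str(chrom.copies[i][0]) for i in range(start, end))
                    c2 = "".join(str(chrom.copies[i][1]) for i in range(start, end))
                    out[(t, j, (start, end))] = (c1, c2)
        return out


def generate_snp_panel(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Phased diploid SNP panel (2T x width 0/1 matrix) with LD.

    Mosaic copying over a small founder pool: each emitted haplotype copies
    a founder and switches to a uniformly chosen founder with probability
    ``switch_rate`` per locus, so nearby loci stay correlated and whole
    haplotypes recur with appreciable frequency.
    """
    width = config.raw_width if config.raw_width is not None else 2 * config.L + 16
    n = 2 * config.T
    founders = rng.integers(0, 2, size=(config.pool_size, width), dtype=np.int8)
    choice = np.empty((n, width), dtype=np.int64)
    choice[:, 0] = rng.integers(0, config.pool_size, size=n)
    switches = rng.random(size=(n, width)) < config.switch_rate
    fresh = rng.integers(0, config.pool_size, size=(n, width))
    for j in range(1, width):
        choice[:, j] = np.where(switches[:, j], fresh[:, j], choice[:, j - 1])
    return founders[choice, np.arange(width)]


def maf_filter(panel: np.ndarray, maf_min: float, L: int) -> np.ndarray:
    """Drop loci with minor allele frequency below ``maf_min``; keep L loci."""
    freq = panel.mean(axis=0)
    keep = np.flatnonzero(np.minimum(freq, 1.0 - freq) >= maf_min)
    if keep.size < L:
        raise ValueError(
            f"only {keep.size} of {panel.shape[1]} loci pass the MAF filter; "
            f"need {L} — enlarge raw_width"
        )
    return panel[:, keep[:L]]


def extract_pool(panel: np.ndarray) -> HaplotypePool:
    """Distinct panel haplotypes with empirical frequencies (count / rows)."""
    rows = [tuple(int(a) for a in row) for row in panel]
    counts: dict[tuple[int, ...], int] = {}
    for r in rows:
        counts[r] = counts.get(r, 0) + 1
    chroms = [
        TrueChromosome(tuple((a,) for a in r)) for r in counts
    ]
    freqs = np.array([c / len(rows) for c in counts.values()])
    return HaplotypePool(chroms, freqs)


def _allele1_freqs(pool: HaplotypePool) -> np.ndarray:
    L = len(pool.chromosomes[0])
    f = np.zeros(L)
    for chrom, w in zip(pool.chromosomes, pool.frequencies):
        for i, c in enumerate(chrom.copies):
            if c:
                f[i] += w * (sum(c) / len(c))
    return f


def insert_cnvs(
    pool: HaplotypePool, config: SimConfig, rng: np.random.Generator
) -> HaplotypePool:
    """Replace segments of frequency-selected haplotypes with CNV segments.

    Haplotypes are chosen for modification with probability proportional to
    their frequency.  Each chosen haplotype is scanned left to right: a CNV
    region starts at a position with probability ``cnv_start_prob``, its
    length is uniform on [cnv_len_min, cnv_len_max] (truncated at the end),
    it becomes a duplication with probability ``dup_fraction`` and a
    deletion otherwise, and scanning resumes after the region.

    Duplication content: ``tandem`` doubles each allele in place;
    ``resampled`` draws the second copy per locus from the pool allele
    frequencies (no LD in the new copy); ``pool`` copies the second strand
    contiguously from a frequency-drawn donor haplotype, so the inserted
    copy is itself a population haplotype segment.
    """
    if config.cnv_start_prob == 0.0:
        return pool
    n = len(pool)
    n_mod = min(n, max(1, round(config.modify_fraction * n)))
    chosen = rng.choice(n, size=n_mod, replace=False, p=pool.frequencies)
    allele_freq = _allele1_freqs(pool)
    donors = pool.chromosomes  # pre-modification pool, used by 'pool' content
    chroms = list(pool.chromosomes)
    for k in chosen:
        copies = list(chroms[k].copies)
        L = len(copies)
        i = 0
        while i < L:
            if rng.random() < config.cnv_start_prob:
                length = int(rng.integers(config.cnv_len_min, config.cnv_len_max + 1))
                end = min(i + length, L)
                if rng.random() < config.dup_fraction:
                    donor = None
                    if config.dup_content == "pool":
                        donor = donors[
                            int(rng.choice(n, p=pool.frequencies))
                        ]
                    for j in range(i, end):
                        a = copies[j][0]
                        if config.dup_content == "tandem":
                            copies[j] = (a, a)
                        elif config.dup_content == "pool":
                            copies[j] = (a, donor.copies[j][0])
                        else:
                            b = int(rng.random() < allele_freq[j])
                            copies[j] = (a, b)
                else:
                    for j in range(i, end):
                        copies[j] = ()
                i = end
            else:
                i += 1
        chroms[k] = TrueChromosome(tuple(copies))
    # merge chromosomes that became identical
    merged: dict[TrueChromosome, float] = {}
    for c, f in zip(chroms, pool.frequencies):
        merged[c] = merged.get(c, 0.0) + float(f)
    return HaplotypePool(list(merged.keys()), np.array(list(merged.values())))


def sample_individuals(
    pool: HaplotypePool, T: int, rng: np.random.Generator
) -> tuple[list[tuple[TrueChromosome, TrueChromosome]], GenotypeSet]:
    """Draw two chromosomes per individual i.i.d. by pool frequency."""
    draws = rng.choice(len(pool), size=(T, 2), p=pool.frequencies)
    pairs = []
    rows = []
    for t in range(T):
        a = pool.chromosomes[int(draws[t, 0])]
        b = pool.chromosomes[int(draws[t, 1])]
        pairs.append((a, b))
        sites = tuple(
            SiteObservation(len(ca) + len(cb), sum(ca) + sum(cb))
            for ca, cb in zip(a.copies, b.copies)
        )
        rows.append(GenotypeVector(f"ind{t:04d}", sites))
    return pairs, GenotypeSet(tuple(rows))


def simulate(config: SimConfig) -> TruthSet:
    """Run the full generator pipeline deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    panel = generate_snp_panel(config, rng)
    panel = maf_filter(panel, config.maf_min, config.L)
    pool = extract_pool(panel)
    pool = insert_cnvs(pool, config, rng)
    pairs, genotypes = sample_individuals(pool, config.T, rng)
    return TruthSet(pairs, genotypes, pool, config)
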