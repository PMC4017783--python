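"""Accuracy measures: switch error rates and frequency distances.

Switch error is restricted to ambiguous markers (those with at least two
alternative orientation assignments — heterozygous SNPs, every odd-total-CN
site, duplicated-het sites) and counts the minimum number of orientation
switches needed to recover the true phase, out of one opportunity per
consecutive ambiguous-site pair.  A by-copy-number 2x2 table stratifies
each junction by the classes of its two sites.  Frequency estimates are
scored against the gold pool with the chi-square statistic and the l1
distance over the gold haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import model
from .model import (
    Assignment,
    GenotypeSet,
    GenotypeVector,
    Haplotype,
    NON_INTERNAL,
    enumerate_site_states,
)

CellKey = tuple[int, int]


def ambiguous_sites(
    g: GenotypeVector,
    mode: str = NON_INTERNAL,
    diploid_at_cn2: bool = True,
) -> list[int]:
    """Loci with at least two alternative orientation assignments.

    A locus is ambiguous when several state combinations are possible or
    when its single combination places different symbols on the two
    chromosomes (so that which chromosome carries which is a free choice).
    """
    out = []
    for i, obs in enumerate(g.sites):
        states = enumerate_site_states(obs, mode, diploid_at_cn2)
        if len(states) >= 2:
            out.append(i)
        elif states:
            combo = next(iter(states))
            if len(set(combo)) > 1:
                out.append(i)
    return out


def site_cn_class(obs: model.SiteObservation) -> int:
    """Per-chromosome CN class of an ambiguous site for stratification.

    Duplicated-het sites (total CN 4) involve two CN-2 chromosomes (class
    2); all other ambiguous sites involve a CN<=1 chromosome in the
    orientation choice (class 1).
    """
    return 2 if obs.total_cn == 4 else 1


@dataclass
class SwitchReport:
    switches: int = 0
    opportunities: int = 0
    mismatched_sites: int = 0
    cell_switches: dict[CellKey, int] = field(
        default_factory=lambda: {(1, 1): 0, (1, 2): 0, (2, 1): 0, (2, 2): 0}
    )
    cell_opportunities: dict[CellKey, int] = field(
        default_factory=lambda: {(1, 1): 0, (1, 2): 0, (2, 1): 0, (2, 2): 0}
    )

    @property
    def rate(self) -> float:
        return self.switches / self.opportunities if self.opportunities else 0.0

    def cell_rate(self, key: CellKey) -> float:
        n = self.cell_opportunities[key]
        return self.cell_switches[key] / n if n else 0.0

    def table(self) -> dict[CellKey, float]:
        return {k: self.cell_rate(k) for k in self.cell_opportunities}


def _check_prediction(pred: Assignment, g: GenotypeVector) -> None:
    for i, obs in enumerate(g.sites):
        copies = sum(h.copies_at(i) for h in pred.haplotypes)
        ones = sum(h.ones_at(i) for h in pred.haplotypes)
        if copies != obs.total_cn or ones != obs.allele1_count:
            raise ValueError(
                f"prediction for {g.individual_id} inconsistent with genotype "
                f"at locus {i}: observed {obs}, predicted sums {copies}:{ones}"
            )


def _orientation_track(
    truth: Assignment,
    pred: Assignment,
    g: GenotypeVector,
    diploid_at_cn2: bool,
) -> tuple[list[tuple[int, int, int]], int]:
    """(locus, required parity, CN class) at every orientation-constraining
    ambiguous site, plus the count of sites where the predicted unordered
    state pair does not match the truth's (those carry no orientation
    information and are dropped from the scan)."""
    t1, t2 = truth.haplotypes
    p1, p2 = pred.haplotypes
    track = []
    mismatches = 0
    for i in ambiguous_sites(g, NON_INTERNAL, diploid_at_cn2):
        ta, tb = t1.states[i], t2.states[i]
        pa, pb = p1.states[i], p2.states[i]
        par0 = pa == ta and pb == tb
        par1 = pa == tb and pb == ta
        if par0 and par1:
            continue  # identical symbols on both chromosomes: unconstraining
        if not par0 and not par1:
            mismatches += 1  # wrong state pair, not an orientation question
            continue
        track.append((i, 0 if par0 else 1, site_cn_class(g.sites[i])))
    return track, mismatches


def switch_error_rate(
    genotypes: GenotypeSet,
    truth: Sequence[Assignment],
    predicted: Sequence[Assignment],
    diploid_at_cn2: bool = True,
) -> SwitchReport:
    """Minimal-switch error over all individuals, with the by-CN table.

    Per individual the parity (which predicted chromosome tracks which true
    chromosome) is followed along the ambiguous sites; every parity change
    is one switch.  Opportunities are consecutive constraining-site pairs;
    individuals with fewer than two such sites contribute none.  The result
    is invariant to globally swapping an individual's two chromosomes.
    """
    if not (len(genotypes) == len(truth) == len(predicted)):
        raise ValueError("genotypes, truth and prediction must align")
    report = SwitchReport()
    for g, tr, pr in zip(genotypes, truth, predicted):
        _check_prediction(pr, g)
        track, mismatches = _orientation_track(tr, pr, g, diploid_at_cn2)
        report.mismatched_sites += mismatches
        parity = None
        prev_cls = None
        for _, par, cls in track:
            if parity is not None:
                report.opportunities += 1
                key = (prev_cls, cls)
                report.cell_opportunities[key] += 1
                if par != parity:
                    report.switches += 1
                    report.cell_switches[key] += 1
            parity = par
            prev_cls = cls
    return report


def switch_error_by_cn(
    genotypes: GenotypeSet,
    truth: Sequence[Assignment],
    predicted: Sequence[Assignment],
    diploid_at_cn2: bool = True,
) -> dict[CellKey, float]:
    """2x2 switch-error table keyed by the CN classes of junction sites."""
    return switch_error_rate(genotypes, truth, predicted, diploid_at_cn2).table()


def internal_switch_error(
    truth_regions: Mapping[tuple, tuple[str, str]],
    predicted_regions: Mapping[tuple, tuple[str, str]],
) -> SwitchReport:
    """Switch error of the two copies inside duplicated regions.

    Both mappings go from a region key to the pair of 0/1 copy strings.
    Only regions present in both are scored, exactly like a two-haplotype
    SNP phasing: constraining positions are those where both the true and
    the predicted copies are heterozygous.
    """
    report = SwitchReport()
    for key in sorted(set(truth_regions) & set(predicted_regions)):
        t1, t2 = truth_regions[key]
        p1, p2 = predicted_regions[key]
        if len(t1) != len(p1):
            raise ValueError(f"region {key}: length mismatch {len(t1)} vs {len(p1)}")
        parity = None
        for ta, tb, pa, pb in zip(t1, t2, p1, p2):
            par0 = pa == ta and pb == tb
            par1 = pa == tb and pb == ta
            if par0 == par1:
                continue
            par = 0 if par0 else 1
            if parity is not None:
                report.opportunities += 1
                report.cell_opportunities[(2, 2)] += 1
                if par != parity:
                    report.switches += 1
                    report.cell_switches[(2, 2)] += 1
            parity = par
    return report


@dataclass
class FrequencyComparison:
    """Predicted vs gold-standard haplotype frequencies, matched by identity."""

    predicted: Mapping[Haplotype, float]
    gold: Mapping[Haplotype, float]

    def __post_init__(self) -> None:
        if not self.gold:
            raise ValueError("empty gold-standard haplotype set")
        if any(gv <= 0 for gv in self.gold.values()):
            raise ValueError("gold frequencies must be positive")

    @property
    def stray_mass(self) -> float:
        """Predicted mass on haplotypes absent from the gold set."""
        return sum(f for h, f in self.predicted.items() if h not in self.gold)


def chi2_distance(cmp: FrequencyComparison) -> float:
    """``sum over gold haplotypes of (f_i - g_i)^2 / g_i``.

    Predicted mass on haplotypes outside the gold set does not enter the
    sum (it is reported separately as ``stray_mass``).
    """
    return sum(
        (cmp.predicted.get(h, 0.0) - gv) ** 2 / gv for h, gv in cmp.gold.items()
    )


def l1_distance(cmp: FrequencyComparison) -> float:
    """``sum over gold haplotypes of |f_i - g_i|``; lies in [0, 2]."""
    return sum(abs(cmp.predicted.get(h, 0.0) - gv) for h, gv in cmp.gold.items())
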