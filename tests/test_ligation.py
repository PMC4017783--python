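import math

import numpy as np
import pytest

from conftest import random_genotype_set
from phasecn.ligation import (
    Block,
    duplicated_runs,
    hierarchical_phase,
    internal_refine,
    junction_cn_changes,
    ligate,
    partition_loci,
)
from phasecn.model import (
    Assignment,
    GenotypeSet,
    GenotypeVector,
    Haplotype,
    INTERNAL,
    NON_INTERNAL,
    SiteObservation,
    is_consistent,
)
from phasecn.sampler import phase_block
from phasecn.simulate import SimConfig, simulate


def hap(*states):
    return Haplotype(NON_INTERNAL, tuple(states))


def diplotype(a, b):
    return Assignment((a, b))


class TestPartitionLoci:
    def test_exact_multiple(self):
        blocks = partition_loci(30)
        assert len(blocks) == 6
        assert all(len(b) == 5 for b in blocks)

    def test_remainder(self):
        blocks = partition_loci(12)
        assert [(b.start, b.end) for b in blocks] == [(0, 5), (5, 10), (10, 12)]

    def test_short(self):
        assert [(b.start, b.end) for b in partition_loci(4)] == [(0, 4)]

    @pytest.mark.parametrize("L", [1, 5, 7, 23, 100])
    def test_tiling(self, L):
        blocks = partition_loci(L)
        covered = []
        for b in blocks:
            covered.extend(range(b.start, b.end))
        assert covered == list(range(L))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            partition_loci(0)
        with pytest.raises(ValueError):
            Block(3, 3)


class TestJunctionCnChanges:
    def test_matched_vs_crossed(self):
        left = diplotype(hap("0"), hap("01"))  # boundary CNs 1, 2
        right = diplotype(hap("1"), hap("11"))  # boundary CNs 1, 2
        # canonical sort: left = (0, 01), right = (1, 11): CNs (1,2)/(1,2)
        assert junction_cn_changes(left, right, 0) == 0
        assert junction_cn_changes(left, right, 1) == 2

    def test_one_change_both_ways(self):
        left = diplotype(hap("00"), hap("01"))  # CNs 2, 2
        right = diplotype(hap("01"), hap("1"))  # CNs 2, 1
        assert junction_cn_changes(left, right, 0) == 1
        assert junction_cn_changes(left, right, 1) == 1

    def test_all_equal(self):
        left = diplotype(hap("00"), hap("11"))
        right = diplotype(hap("01"), hap("01"))
        assert junction_cn_changes(left, right, 0) == 0
        assert junction_cn_changes(left, right, 1) == 0

    def test_internal_rejected(self):
        a = Assignment((Haplotype(INTERNAL, ("0",)), Haplotype(INTERNAL, ("1",))))
        with pytest.raises(ValueError, match="non-internal"):
            junction_cn_changes(a, a, 0)


def _block_solution(rows, block, **kw):
    gvs = tuple(
        GenotypeVector(f"i{t}", tuple(SiteObservation(c, o) for c, o in row))
        for t, row in enumerate(rows)
    )
    gs = GenotypeSet(gvs)
    return gs, phase_block(gs, K=kw.pop("K", 32), block=block, **kw)


class TestLigate:
    def test_unambiguous_concatenation(self):
        rows = [[(2, 0), (2, 2)]]
        _, left = _block_solution([[(2, 0)]], (0, 1))
        _, right = _block_solution([[(2, 2)]], (1, 2))
        merged = ligate(left, right, K=8)
        assert merged.block == (0, 2)
        sol = merged.per_individual[0]
        assert len(sol) == 1
        ((a, w),) = sol.items()
        assert w == pytest.approx(1.0)
        assert a == diplotype(hap("0", "1"), hap("0", "1"))

    def test_het_blocks_tie_generates_both_pairings(self):
        # het SNP on each side, equal boundary CNs -> both pairings appear
        _, left = _block_solution([[(2, 1)]], (0, 1))
        _, right = _block_solution([[(2, 1)]], (1, 2))
        merged = ligate(left, right, K=16)
        assigns = set(merged.per_individual[0])
        assert diplotype(hap("0", "0"), hap("1", "1")) in assigns
        assert diplotype(hap("0", "1"), hap("1", "0")) in assigns

    def test_minimal_change_rule_filters(self):
        # left boundary CNs (1,2), right (1,2): only CN-matched pairing kept
        _, left = _block_solution([[(3, 1)]], (0, 1))
        _, right = _block_solution([[(3, 1)]], (1, 2))
        merged = ligate(left, right, K=32)
        for a in merged.per_individual[0]:
            h1, h2 = a.haplotypes
            for h in (h1, h2):
                assert h.copies_at(0) == h.copies_at(1), (
                    "a CN change crossed the junction despite a 0-change "
                    "pairing being available"
                )

    def test_non_adjacent_rejected(self):
        _, left = _block_solution([[(2, 0)]], (0, 1))
        _, right = _block_solution([[(2, 0)]], (2, 3))
        with pytest.raises(ValueError, match="adjacent"):
            ligate(left, right)

    def test_individual_mismatch_rejected(self):
        _, left = _block_solution([[(2, 0)]], (0, 1))
        _, right = _block_solution([[(2, 0)], [(2, 0)]], (1, 2))
        with pytest.raises(ValueError, match="individuals"):
            ligate(left, right)

    def test_merged_candidates_consistent(self, rng):
        gs = random_genotype_set(rng, 4, 6)
        left_gs = gs.slice(0, 3)
        right_gs = gs.slice(3, 6)
        left = phase_block(left_gs, K=16, block=(0, 3))
        right = phase_block(right_gs, K=16, block=(3, 6))
        merged = ligate(left, right, K=16, genotypes=gs)
        for t, g in enumerate(gs):
            for a in merged.per_individual[t]:
                assert is_consistent(a, g)

    def test_minimal_change_rule_brute_force(self, rng):
        """Every emitted candidate arises from a minimal-change pairing."""
        gs = random_genotype_set(rng, 3, 4)
        left = phase_block(gs.slice(0, 2), K=16, block=(0, 2))
        right = phase_block(gs.slice(2, 4), K=16, block=(2, 4))
        merged = ligate(left, right, K=64, genotypes=gs)
        for t in range(len(gs)):
            allowed = set()
            for la in left.per_individual[t]:
                for rb in right.per_individual[t]:
                    c0 = junction_cn_changes(la, rb, 0)
                    c1 = junction_cn_changes(la, rb, 1)
                    for ori, c in ((0, c0), (1, c1)):
                        if c == min(c0, c1):
                            l0, l1 = la.haplotypes
                            r0, r1 = rb.haplotypes
                            if ori == 1:
                                r0, r1 = r1, r0
                            allowed.add(
                                Assignment(
                                    (
                                        Haplotype(
                                            NON_INTERNAL, l0.states + r0.states
                                        ),
                                        Haplotype(
                                            NON_INTERNAL, l1.states + r1.states
                                        ),
                                    )
                                )
                            )
            assert set(merged.per_individual[t]) <= allowed


class TestHierarchicalPhase:
    def test_degenerate_equals_phase_block(self, rng):
        gs = random_genotype_set(rng, 4, 5)
        direct = phase_block(gs, K=20)
        hier = hierarchical_phase(gs, K=20)
        assert hier.solution.per_individual == direct.per_individual
        assert [
            hier.solution.best_assignment(t) for t in range(len(gs))
        ] == [direct.best_assignment(t) for t in range(len(gs))]

    def test_homozygous_right_block_no_effect(self, rng):
        left_gs = random_genotype_set(rng, 4, 5, max_cn=2)
        rows = []
        for g in left_gs:
            extra = tuple(SiteObservation(2, 2) for _ in range(5))
            rows.append(GenotypeVector(g.individual_id, g.sites + extra))
        full_gs = GenotypeSet(tuple(rows))
        short = hierarchical_phase(left_gs, K=24)
        full = hierarchical_phase(full_gs, K=24)
        for a_short, a_full in zip(short.assignments, full.assignments):
            trimmed = Assignment(
                tuple(
                    Haplotype(NON_INTERNAL, h.states[:5]) for h in a_full.haplotypes
                )
            )
            assert trimmed == a_short

    def test_long_dataset_consistent(self):
        truth = simulate(SimConfig(L=18, T=12, seed=9))
        result = hierarchical_phase(truth.genotypes, K=16)
        for g, a in zip(truth.genotypes, result.assignments):
            assert is_consistent(a, g)
        assert result.frequencies.sum() == pytest.approx(1.0, abs=1e-9)

    def test_deterministic(self):
        truth = simulate(SimConfig(L=13, T=10, seed=4))
        a = hierarchical_phase(truth.genotypes, K=12)
        b = hierarchical_phase(truth.genotypes, K=12)
        assert a.assignments == b.assignments
        assert np.array_equal(a.frequencies, b.frequencies)

    def test_pairwise_order_consistent(self):
        truth = simulate(SimConfig(L=14, T=8, seed=6))
        result = hierarchical_phase(
            truth.genotypes, K=12, ligation_order="pairwise"
        )
        for g, a in zip(truth.genotypes, result.assignments):
            assert is_consistent(a, g)

    def test_internal_mode_block_limit(self):
        gs = GenotypeSet(
            (
                GenotypeVector(
                    "a", tuple(SiteObservation(3, 1) for _ in range(6))
                ),
            )
        )
        with pytest.raises(ValueError, match="internal"):
            hierarchical_phase(gs, mode=INTERNAL)

    def test_internal_mode_small_region(self):
        gs = GenotypeSet(
            (
                GenotypeVector(
                    "a",
                    (
                        SiteObservation(3, 1),
                        SiteObservation(3, 2),
                        SiteObservation(3, 0),
                    ),
                ),
            )
        )
        result = hierarchical_phase(gs, mode=INTERNAL, K=8)
        (a,) = result.assignments
        assert a.ploidy == 3
        assert is_consistent(a, gs.individuals[0])


class TestInternalRefine:
    def test_duplicated_runs(self):
        h = hap("0", "00", "01", "1", "11")
        assert duplicated_runs(h) == [(1, 3), (4, 5)]

    def test_identical_copies_trivial(self):
        a = diplotype(hap("00", "00", "00"), hap("0", "1", "0"))
        out = internal_refine([a])
        ((key, (c1, c2)),) = out.items()
        assert key == (0, 0, (0, 3)) or key == (0, 1, (0, 3))
        assert c1 == c2 == "000"

    def test_het_copies_resolved(self):
        # one chromosome duplicated over 2 loci with one het copy-pair per
        # locus; two supporting chromosomes pin the common copy haplotypes
        a0 = diplotype(hap("01", "01"), hap("0", "0"))
        a1 = diplotype(hap("00", "00"), hap("1", "1"))
        a2 = diplotype(hap("11", "11"), hap("0", "0"))
        # canonical assignment order puts the duplicated chromosome second
        # for a0/a2 (single-copy "0" sorts before "01"/"11") and first for a1
        out = internal_refine([a0, a1, a2], K=8)
        c1, c2 = out[(0, 1, (0, 2))]
        assert sorted((c1, c2)) in (["00", "11"], ["01", "10"])
        assert out[(1, 0, (0, 2))] == ("00", "00")
        assert out[(2, 1, (0, 2))] == ("11", "11")

    def test_anchors_resolve_het_copies(self):
        # the single-copy chromosomes "00" repeated across individuals
        # anchor haplotype 00 so the dup copies {01, 01} -> phased as 00/11
        dup = diplotype(hap("01", "01"), hap("1", "1"))
        anchors = [diplotype(hap("0", "0"), hap("0", "0"))] * 6 + [
            diplotype(hap("1", "1"), hap("1", "1"))
        ] * 6
        out = internal_refine([dup] + anchors, K=16)
        c1, c2 = out[(0, 0, (0, 2))]
        assert sorted((c1, c2)) == ["00", "11"]

    def test_beats_random_on_pool_content(self):
        from phasecn.evaluate import SwitchReport, internal_switch_error
        from phasecn.simulate import SimConfig, simulate

        pooled = SwitchReport()
        for seed in (600, 601, 602):
            truth = simulate(
                SimConfig(
                    L=30, T=88, seed=seed, dup_content="pool",
                    pool_size=12, switch_rate=0.04,
                )
            )
            res = hierarchical_phase(truth.genotypes, K=30)
            pred = internal_refine(res.assignments, K=30)
            rep = internal_switch_error(truth.duplicated_regions(), pred)
            pooled.switches += rep.switches
            pooled.opportunities += rep.opportunities
        assert pooled.opportunities >= 50
        assert pooled.rate < 0.45  # clearly better than coin-flip phase
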