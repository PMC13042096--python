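"""Greedy haplotype-coverage selection: oracle equivalence, the excision
per-allele decision rule, determinism and the concavity invariant."""

import itertools

import numpy as np
import pytest

from dndcrispr import prioritize
from dndcrispr.models import (
    CommonVariant,
    ExcisionPair,
    HaplotypeId,
    PhasedPanel,
    TargetableAllele,
    Therapy,
)


def hap(n):
    return HaplotypeId(f"S{n}", 0)


def single(name, pos=None):
    v = CommonVariant("chr1", pos if pos is not None else ord(name[0]), name, "A", "G", 0.3)
    return Therapy(kind="single", alleles=(TargetableAllele("G", "exon_disruption", v, "alt"),))


# -- coverage operators --------------------------------------------------------


def panel_from(rows, variants=None):
    gt = np.array(rows, dtype=np.int8)  # (n_var, n_samples, 2)
    samples = [f"S{i}" for i in range(gt.shape[1])]
    variants = variants or [CommonVariant("chr1", 100 * (i + 1), f"v{i}", "A", "G", 0.3)
                            for i in range(gt.shape[0])]
    return PhasedPanel(samples, variants, gt), variants


def test_allele_coverage_targets_het_haplotypes_only():
    panel, (v,) = panel_from([[[0, 1], [1, 1], [0, 0]]])
    alt = TargetableAllele("G", "exon_disruption", v, "alt")
    ref = TargetableAllele("G", "exon_disruption", v, "ref")
    assert prioritize.allele_coverage(panel, alt) == {HaplotypeId("S0", 1)}
    assert prioritize.allele_coverage(panel, ref) == {HaplotypeId("S0", 0)}
    hom_panel, (v2,) = panel_from([[[0, 0], [1, 1]]])
    assert prioritize.allele_coverage(
        hom_panel, TargetableAllele("G", "exon_disruption", v2, "alt")) == frozenset()


def test_pair_coverage_requires_cis_double_het():
    rows = [
        [[0, 1], [0, 1], [1, 1]],   # v1
        [[0, 1], [1, 0], [0, 1]],   # v2
    ]
    panel, (v1, v2) = panel_from(rows)

    def pair(a1, a2):
        return ExcisionPair("G", TargetableAllele("G", "excision", v1, a1),
                            TargetableAllele("G", "excision", v2, a2))

    # S0 cis (alt,alt) on hap1 and (ref,ref) on hap0; S1 trans; S2 hom at v1
    assert prioritize.pair_coverage(panel, pair("alt", "alt")) == {HaplotypeId("S0", 1)}
    assert prioritize.pair_coverage(panel, pair("ref", "ref")) == {HaplotypeId("S0", 0)}
    assert prioritize.pair_coverage(panel, pair("alt", "ref")) == {HaplotypeId("S1", 1)}
    assert prioritize.pair_coverage(panel, pair("ref", "alt")) == {HaplotypeId("S1", 0)}


# -- greedy over singles -------------------------------------------------------


def test_greedy_stops_when_no_gain_and_skips_redundant():
    cov = {
        single("A"): frozenset({hap(1), hap(2), hap(3)}),
        single("B"): frozenset({hap(4), hap(5)}),
        single("C"): frozenset({hap(3), hap(4)}),
    }
    res = prioritize.greedy_select(cov, total_haplotypes=10)
    names = [t.alleles[0].variant.id for t in res.therapies]
    assert names == ["A", "B"]  # C would add nothing new
    assert res.cumulative_counts == [3, 5]
    assert res.cumulative_fractions[-1] == pytest.approx(0.5)


def test_greedy_empty_and_identical_coverage():
    assert prioritize.greedy_select({}, 10).therapies == []
    same = frozenset({hap(1), hap(2)})
    cov = {single("A", 1): same, single("B", 2): same, single("C", 3): same}
    res = prioritize.greedy_select(cov, 10)
    assert len(res.therapies) == 1  # the rest add zero marginal gain


def brute_force_best(coverage):
    """Oracle: the true maximum-coverage single pick."""
    return max(len(s) for s in coverage.values())


@pytest.mark.parametrize("seed", range(200))
def test_first_pick_matches_bruteforce_max_and_gains_nonincreasing(seed):
    rng = np.random.default_rng(seed)
    n_therapies = int(rng.integers(1, 9))
    n_haps = int(rng.integers(1, 13))
    cov = {}
    for i in range(n_therapies):
        members = frozenset(hap(j) for j in range(n_haps) if rng.random() < 0.4)
        cov[single(f"T{i}", pos=i)] = members
    res = prioritize.greedy_select(cov, total_haplotypes=2 * n_haps)
    if any(cov.values()):
        assert len(res.new_haplotypes[0]) == brute_force_best(cov)
    gains = [len(s) for s in res.new_haplotypes]
    assert all(a >= b for a, b in zip(gains, gains[1:]))
    # newly covered sets are pairwise disjoint
    for a, b in itertools.combinations(res.new_haplotypes, 2):
        assert not (a & b)


def test_greedy_selection_invariant_to_input_order():
    rng = np.random.default_rng(42)
    cov_items = []
    for i in range(6):
        members = frozenset(hap(j) for j in range(10) if rng.random() < 0.5)
        cov_items.append((single(f"T{i}", pos=i), members))
    baseline = prioritize.greedy_select(dict(cov_items), 20)
    for perm_seed in range(5):
        perm = np.random.default_rng(perm_seed).permutation(len(cov_items))
        shuffled = dict(cov_items[i] for i in perm)
        res = prioritize.greedy_select(shuffled, 20)
        assert [t.sort_key() for t in res.therapies] == [
            t.sort_key() for t in baseline.therapies]


def test_selecting_both_alleles_covers_all_het_haplotypes():
    rng = np.random.default_rng(3)
    gt = (rng.random((200, 2)) < 0.4).astype(np.int8)
    v = CommonVariant("chr1", 100, "v", "A", "G", 0.4)
    panel = PhasedPanel([f"S{i}" for i in range(200)], [v], gt[None])
    cov_ref = prioritize.allele_coverage(panel, TargetableAllele("G", "exon_disruption", v, "ref"))
    cov_alt = prioritize.allele_coverage(panel, TargetableAllele("G", "exon_disruption", v, "alt"))
    n_het = int((gt[:, 0] != gt[:, 1]).sum())
    assert not (cov_ref & cov_alt)
    assert len(cov_ref | cov_alt) == 2 * n_het


# -- excision greedy -----------------------------------------------------------


def _excision_setup(rows):
    """Panel over three variants with configurable phased genotypes."""
    panel, variants = panel_from(rows)

    def pair(i, j, a1="alt", a2="alt"):
        return ExcisionPair("G", TargetableAllele("G", "excision", variants[i], a1),
                            TargetableAllele("G", "excision", variants[j], a2))

    return panel, pair


def test_excision_first_step_is_best_full_pair_and_termination():
    # v0-v1 double het in two samples; v0-v2 in one
    rows = [
        [[0, 1], [0, 1], [0, 1]],
        [[0, 1], [0, 1], [0, 0]],
        [[0, 1], [0, 0], [0, 0]],
    ]
    panel, pair = _excision_setup(rows)
    res = prioritize.greedy_select_excision(panel, [pair(0, 1), pair(0, 2)])
    assert len(res.therapies[0].alleles) == 2
    assert len(res.new_haplotypes[0]) == 2  # S0,S1 hap1 via (alt,alt) on v0-v1


@pytest.mark.parametrize("ext_n,extension_wins", [(6, True), (4, False)])
def test_excision_per_allele_rule_extension_vs_new_pair(ext_n, extension_wins):
    """The decision rule divides a new pair's gain by its two new alleles:
    a brand-new pair gaining 10 (per-allele 5) loses to an extension gaining
    6 (per-allele 6) but beats an extension gaining only 4."""
    n = 40
    gt = np.zeros((4, n, 2), dtype=np.int8)
    # base pair (v0,v1 alt,alt): 12 cis haplotypes -> clear first pick
    gt[0, 0:12, 1] = 1
    gt[1, 0:12, 1] = 1
    # extension (v0,v2 alt,alt): ext_n fresh haplotypes, reuses allele v0-alt
    gt[0, 12:12 + ext_n, 1] = 1
    gt[2, 12:12 + ext_n, 1] = 1
    # brand-new pair (v1-ref, v3-alt in cis on hap0): 10 fresh haplotypes
    gt[1, 20:30] = (0, 1)   # het, ref on hap0 (alt hap1 never pairs: v0 hom)
    gt[3, 20:30] = (1, 0)   # het, alt on hap0
    panel, pair = _excision_setup(list(gt))
    base, ext = pair(0, 1), pair(0, 2)
    new_pair = pair(1, 3, "ref", "alt")
    assert len(prioritize.pair_coverage(panel, base)) == 12
    assert len(prioritize.pair_coverage(panel, ext)) == ext_n
    assert len(prioritize.pair_coverage(panel, new_pair)) == 10
    res = prioritize.greedy_select_excision(panel, [base, ext, new_pair])
    first = frozenset((a.variant.id, a.allele) for a in res.therapies[0].alleles)
    second = frozenset((a.variant.id, a.allele) for a in res.therapies[1].alleles)
    assert first == frozenset({("v0", "alt"), ("v1", "alt")})
    if extension_wins:
        assert second == frozenset({("v0", "alt"), ("v2", "alt")})
    else:
        assert second == frozenset({("v1", "ref"), ("v3", "alt")})
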