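"""Cohort-level endpoints: treatable individuals, top-k coverage and
mutation-agnostic vs mutation-specific patient-yield ratios.

The mutation-specific baseline assumes each of a gene's n_mut documented
dominant pathogenic mutations accounts for an equal share of patients, so
k mutation-specific therapies reach cohort_n * min(k / n_mut, 1) people.
On the haplotype axis the single-therapy baseline is 2 / n_mut percent
(one targeted mutation, referenced against individual counts with two
haplotypes each); a strict 1 / n_mut haplotype fraction is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .models import (
    ExcisionPair,
    HaplotypeId,
    PhasedPanel,
    PrioritizationResult,
    TargetableAllele,
)
from .prioritize import pair_coverage
from .variant_targets import heterozygous_individuals

TOP_K_DEFAULT = 4


@dataclass
class GeneMetrics:
    gene: str
    cohort_n: int
    permissive_count: int = 0
    permissive_fraction: float = 0.0
    strict_counts: Dict[str, int] = field(default_factory=dict)  # per strategy
    strict_union_count: int = 0
    top_k_fraction: Dict[str, float] = field(default_factory=dict)
    possible_fraction: Dict[str, float] = field(default_factory=dict)


@dataclass
class YieldRatio:
    gene: str
    n_mut: int
    k: int
    specific_people: float
    agnostic_people: Dict[str, int]  # per strategy
    ratios: Dict[str, float]
    mean_ratio: float


def treatable_individuals_permissive(
    panel: PhasedPanel,
    targets: Sequence[TargetableAllele],
    pairs: Sequence[ExcisionPair] = (),
) -> Set[str]:
    """Samples heterozygous at >= 1 targetable variant of any strategy, or
    double-heterozygous at >= 1 valid excision pair (some cis configuration
    of a double het always covers both haplotypes)."""
    out: Set[str] = set()
    seen_variants = set()
    for t in targets:
        key = (t.variant.chrom, t.variant.pos)
        if key in seen_variants:
            continue
        seen_variants.add(key)
        out |= heterozygous_individuals(panel, t.variant)
    seen_pairs = set()
    for p in pairs:
        key = (p.left.variant.pos, p.right.variant.pos)
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        out |= (heterozygous_individuals(panel, p.left.variant)
                & heterozygous_individuals(panel, p.right.variant))
    return out


def treatable_individuals_strict(
    panel: PhasedPanel,
    prioritization: PrioritizationResult,
    k: int = TOP_K_DEFAULT,
) -> Set[str]:
    """Samples whose both haplotypes are covered by the first k therapies
    of one strategy's prioritization."""
    covered = prioritization.covered_after(k)
    by_sample: Dict[str, Set[int]] = {}
    for h in covered:
        by_sample.setdefault(h.sample, set()).add(h.side)
    return {s for s, sides in by_sample.items() if sides == {0, 1}}


def strict_union(
    panel: PhasedPanel,
    prioritizations: Dict[str, PrioritizationResult],
    k: int = TOP_K_DEFAULT,
) -> Set[str]:
    """Samples strict-treatable under at least one strategy."""
    out: Set[str] = set()
    for pr in prioritizations.values():
        out |= treatable_individuals_strict(panel, pr, k)
    return out


def mutation_specific_people(cohort_n: int, n_mut: int, k: int = TOP_K_DEFAULT) -> float:
    """People reachable by k mutation-specific therapies under the
    equal-share assumption: cohort_n * min(k / n_mut, 1)."""
    if n_mut <= 0:
        raise ValueError("mutation-specific yield undefined for n_mut = 0")
    return cohort_n * min(k / n_mut, 1.0)


def mutation_specific_haplotype_fraction(n_mut: int, strict_haplotypes: bool = False) -> float:
    """Percent of haplotypes reachable by one mutation-specific therapy."""
    if n_mut <= 0:
        raise ValueError("mutation-specific yield undefined for n_mut = 0")
    return 100.0 * (1.0 if strict_haplotypes else 2.0) / n_mut


def yield_ratio(
    gene: str,
    panel: PhasedPanel,
    prioritizations: Dict[str, PrioritizationResult],
    n_mut: int,
    k: int = TOP_K_DEFAULT,
) -> YieldRatio:
    """Per-strategy and mean ratio of strict-treatable people over the
    mutation-specific baseline. Strategies with no therapies contribute a
    ratio of 0 (they still count toward the mean)."""
    specific = mutation_specific_people(len(panel.samples), n_mut, k)
    agnostic: Dict[str, int] = {}
    ratios: Dict[str, float] = {}
    for strategy, pr in prioritizations.items():
        n = len(treatable_individuals_strict(panel, pr, k))
        agnostic[strategy] = n
        ratios[strategy] = n / specific if specific > 0 else 0.0
    mean = sum(ratios.values()) / len(ratios) if ratios else 0.0
    return YieldRatio(gene, n_mut, k, specific, agnostic, ratios, mean)


def coverage_summary(
    prioritization: PrioritizationResult,
    k: int = TOP_K_DEFAULT,
    total_haplotypes: Optional[int] = None,
    all_possible: Optional[FrozenSet[HaplotypeId]] = None,
) -> Tuple[float, float]:
    """(top-k haplotype fraction, possible haplotype fraction).

    ``all_possible`` is the union of every targetable haplotype regardless
    of prioritization; when omitted, the union over all selected therapies
    is used (equal when the greedy runs to exhaustion).
    """
    total = total_haplotypes if total_haplotypes is not None else prioritization.total_haplotypes
    if total == 0:
        return 0.0, 0.0
    top = len(prioritization.covered_after(k)) / total
    possible_set = all_possible if all_possible is not None else prioritization.covered_after(None)
    return top, len(possible_set) / total
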