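"""Greedy haplotype-coverage prioritization of allele-specific therapies.

Each cohort member contributes two haplotypes, since a disease mutation
may sit on either one. A single-guide therapy covers the haplotypes that
carry its targeted allele in heterozygous individuals (the opposite
haplotype carries the other allele, so cutting discriminates). The greedy
algorithm repeatedly selects the therapy adding the most not-yet-covered
haplotypes — the classic maximum-coverage heuristic. For the excision
strategy (two guides per therapy) candidate moves are scored per *allele*:
a brand-new pair costs two alleles, extending a previously selected allele
into a new pair costs one.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .models import (
    ExcisionPair,
    HaplotypeId,
    PhasedPanel,
    PrioritizationResult,
    TargetableAllele,
    Therapy,
)


def allele_coverage(panel: PhasedPanel, target: TargetableAllele) -> FrozenSet[HaplotypeId]:
    """Haplotypes carrying the targeted allele in heterozygous samples."""
    gt = panel.genotype_matrix(target.variant)
    het = (gt[:, 0] != gt[:, 1]) & (gt[:, 0] >= 0) & (gt[:, 1] >= 0)
    code = target.allele_code
    out: Set[HaplotypeId] = set()
    for i in np.nonzero(het)[0]:
        side = 0 if gt[i, 0] == code else 1
        out.add(HaplotypeId(panel.samples[i], int(side)))
    return frozenset(out)


def pair_coverage(panel: PhasedPanel, pair: ExcisionPair) -> FrozenSet[HaplotypeId]:
    """Haplotypes carrying both targeted alleles in cis, in samples
    heterozygous at both variants."""
    gl = panel.genotype_matrix(pair.left.variant)
    gr = panel.genotype_matrix(pair.right.variant)
    het = ((gl[:, 0] != gl[:, 1]) & (gl >= 0).all(axis=1)
           & (gr[:, 0] != gr[:, 1]) & (gr >= 0).all(axis=1))
    cl, cr = pair.left.allele_code, pair.right.allele_code
    out: Set[HaplotypeId] = set()
    for i in np.nonzero(het)[0]:
        for side in (0, 1):
            if gl[i, side] == cl and gr[i, side] == cr:
                out.add(HaplotypeId(panel.samples[i], side))
    return frozenset(out)


def greedy_select(
    coverage: Dict[Therapy, FrozenSet[HaplotypeId]],
    total_haplotypes: int,
    max_steps: Optional[int] = None,
) -> PrioritizationResult:
    """Greedy maximum coverage over single-allele therapies.

    Each step picks the therapy covering the most not-yet-covered
    haplotypes; ties break on larger coverage first, then on genomic
    position and allele so the selection is deterministic regardless of
    input order. Stops when no therapy adds a haplotype.
    """
    for t in coverage:
        if t.kind != "single":
            raise ValueError("greedy_select only handles single-allele therapies")
    remaining = sorted(coverage, key=lambda t: t.sort_key())
    covered: Set[HaplotypeId] = set()
    result = PrioritizationResult(total_haplotypes=total_haplotypes)
    while remaining and (max_steps is None or len(result.therapies) < max_steps):
        best, best_new = None, frozenset()
        for t in remaining:
            new = coverage[t] - covered
            if len(new) > len(best_new):
                best, best_new = t, frozenset(new)
        if best is None or not best_new:
            break
        result.therapies.append(best)
        result.new_haplotypes.append(best_new)
        covered |= best_new
        remaining.remove(best)
    return result


def _pair_key(pair: ExcisionPair):
    return pair.sort_key()


def greedy_select_excision(
    panel: PhasedPanel,
    pairs: Sequence[ExcisionPair],
    max_steps: Optional[int] = None,
) -> PrioritizationResult:
    """Greedy selection of excision therapies with per-allele gain scoring.

    The first step always selects the best full pair. Afterwards each
    candidate pair is scored by (newly covered haplotypes) / (number of its
    alleles not yet selected); a pair reusing one selected allele therefore
    competes at twice the per-allele value of a brand-new pair with the
    same gain, and a pair whose two alleles are both already selected is a
    free reagent combination chosen whenever it gains anything. Ties break
    on larger raw gain, then genomic order.
    """
    cov: Dict[ExcisionPair, FrozenSet[HaplotypeId]] = {
        p: pair_coverage(panel, p) for p in pairs
    }
    universe = sorted(cov, key=_pair_key)
    covered: Set[HaplotypeId] = set()
    selected_alleles: Set[Tuple[str, int, str]] = set()
    chosen: Set[ExcisionPair] = set()
    result = PrioritizationResult(total_haplotypes=panel.n_haplotypes)

    def allele_key(a: TargetableAllele):
        return (a.variant.chrom, a.variant.pos, a.allele)

    while max_steps is None or len(result.therapies) < max_steps:
        best = None
        best_score: Tuple[float, int] = (0.0, 0)
        for p in universe:
            if p in chosen:
                continue
            new = cov[p] - covered
            if not new:
                continue
            n_new_alleles = sum(
                1 for a in (p.left, p.right) if allele_key(a) not in selected_alleles
            )
            if not result.therapies and n_new_alleles < 2:
                pass  # first step has no prior alleles by construction
            per_allele = len(new) / n_new_alleles if n_new_alleles else float("inf")
            score = (per_allele, len(new))
            if best is None or score > best_score:
                best, best_score = p, score
        if best is None:
            break
        new = frozenset(cov[best] - covered)
        result.therapies.append(
            Therapy(kind="excision", alleles=(best.left, best.right)))
        result.new_haplotypes.append(new)
        covered |= new
        chosen.add(best)
        selected_alleles.add(allele_key(best.left))
        selected_alleles.add(allele_key(best.right))
    return result


def prioritize_single_strategy(
    panel: PhasedPanel,
    targets: Sequence[TargetableAllele],
    max_steps: Optional[int] = None,
) -> PrioritizationResult:
    """Convenience wrapper: build therapies from targets and run the greedy."""
    coverage: Dict[Therapy, FrozenSet[HaplotypeId]] = {}
    seen = set()
    for t in targets:
        key = (t.variant.chrom, t.variant.pos, t.allele)
        if key in seen:
            continue
        seen.add(key)
        coverage[Therapy(kind="single", alleles=(t,))] = allele_coverage(panel, t)
    return greedy_select(coverage, panel.n_haplotypes, max_steps)
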