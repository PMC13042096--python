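"""Phased common-variant loading and strategy-target assignment.

Variants enter the analysis only if they are biallelic SNVs with a minor
allele frequency of at least 0.1 and fully phased genotypes; phase is
required because haplotype coverage drives therapy prioritization.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
from cyvcf2 import VCF

from .intervals import Interval, contains
from .models import (
    CommonVariant,
    ExcisionPair,
    GeneModel,
    PhasedPanel,
    StrategyWindowSet,
    TargetableAllele,
)

logger = logging.getLogger(__name__)

MAF_MIN = 0.1
SINGLE_VARIANT_STRATEGIES = ("exon_disruption", "splice_disruption", "epigenetic_silencing")


def load_common_variants(
    vcf_path: str, maf_min: float = MAF_MIN
) -> Tuple[List[CommonVariant], PhasedPanel]:
    """Read a phased VCF, keeping biallelic SNVs with MAF >= ``maf_min``.

    The alternate-allele frequency is taken from INFO/AF when present and
    otherwise recomputed from the genotypes. Multiallelic records, indels
    and sub-threshold sites are dropped (counts logged). Any unphased
    genotype raises an error naming the record.
    """
    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    variants: List[CommonVariant] = []
    rows: List[np.ndarray] = []
    n_multi = n_indel = n_lowmaf = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            n_indel += 1
            continue
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        codes = np.full((len(samples), 2), -1, dtype=np.int8)
        for i, g in enumerate(gts):
            a0, a1, phased = g[0], g[1], g[-1]
            if a0 >= 0 and a1 >= 0 and not phased:
                raise ValueError(
                    f"unphased genotype for sample {samples[i]} at "
                    f"{rec.CHROM}:{rec.POS} ({rec.ID}); phased input is required"
                )
            codes[i, 0] = a0 if a0 >= 0 else -1
            codes[i, 1] = a1 if a1 >= 0 else -1
        af = rec.INFO.get("AF")
        if af is None:
            called = codes[codes >= 0]
            af = float(called.mean()) if called.size else 0.0
        af = float(af)
        if min(af, 1.0 - af) < maf_min:
            n_lowmaf += 1
            continue
        variants.append(CommonVariant(rec.CHROM, rec.POS - 1,
                                      rec.ID or f"{rec.CHROM}:{rec.POS}", ref, alt, af))
        rows.append(codes)
    logger.info("VCF %s: kept %d common biallelic SNVs "
                "(dropped %d multiallelic, %d indel, %d below MAF %.2f)",
                vcf_path, len(variants), n_multi, n_indel, n_lowmaf, maf_min)
    gt = np.stack(rows) if rows else np.empty((0, len(samples), 2), dtype=np.int8)
    return variants, PhasedPanel(samples, variants, gt)


def assign_strategy_targets(
    variants: Sequence[CommonVariant],
    windows: Dict[str, Dict[str, StrategyWindowSet]],
) -> List[TargetableAllele]:
    """Emit ref- and alt-targeting alleles for every variant inside a
    single-variant strategy window. ``windows`` maps gene -> strategy ->
    StrategyWindowSet; excision pairing is handled separately."""
    out: List[TargetableAllele] = []
    for gene, per_strategy in sorted(windows.items()):
        for strategy in SINGLE_VARIANT_STRATEGIES:
            ws = per_strategy.get(strategy)
            if ws is None:
                continue
            for v in variants:
                if v.chrom == ws.chrom and contains(ws.intervals, v.pos):
                    out.append(TargetableAllele(gene, strategy, v, "ref"))
                    out.append(TargetableAllele(gene, strategy, v, "alt"))
    return out


def _span_contains_exon_of_every_transcript(
    gene: GeneModel, lo: int, hi: int
) -> bool:
    """Closed span [lo, hi] must fully contain >= 1 exon of each valid transcript."""
    for t in gene.require_valid():
        if not any(lo <= s and e <= hi + 1 for s, e in t.exons):
            return False
    return True


def find_excision_pairs(
    variants: Sequence[CommonVariant],
    window: StrategyWindowSet,
    gene: GeneModel,
) -> List[ExcisionPair]:
    """All candidate excision allele pairs within the search window.

    A positional pair qualifies when the closed span between the two
    variants fully contains at least one whole exon of every valid
    transcript (so every isoform loses an exon). Each positional pair
    expands to the four allele configurations; phasing later decides which
    configurations actually sit in cis on a haplotype.
    """
    in_win = sorted(
        (v for v in variants if v.chrom == window.chrom and contains(window.intervals, v.pos)),
        key=lambda v: v.pos,
    )
    pairs: List[ExcisionPair] = []
    for i, v1 in enumerate(in_win):
        for v2 in in_win[i + 1:]:
            if not _span_contains_exon_of_every_transcript(gene, v1.pos, v2.pos):
                continue
            for a1 in ("ref", "alt"):
                for a2 in ("ref", "alt"):
                    pairs.append(ExcisionPair(
                        gene.symbol,
                        TargetableAllele(gene.symbol, "excision", v1, a1),
                        TargetableAllele(gene.symbol, "excision", v2, a2),
                    ))
    return pairs


def heterozygous_individuals(panel: PhasedPanel, variant: CommonVariant) -> Set[str]:
    """Samples whose two haplotypes carry different alleles at the variant;
    samples with a missing call are excluded."""
    gt = panel.genotype_matrix(variant)
    het = (gt[:, 0] != gt[:, 1]) & (gt[:, 0] >= 0) & (gt[:, 1] >= 0)
    return {panel.samples[i] for i in np.nonzero(het)[0]}
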