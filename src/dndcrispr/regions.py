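"""Strategy-specific targetable genomic windows.

For each editing strategy, a common variant is only useful if editing at
its locus inactivates *every* retained transcript of the gene. Windows are
therefore built per transcript and intersected across the valid transcript
set ("ubiquitous regions"):

- exon disruption: coding positions where an indel-induced frameshift is
  predicted to trigger nonsense-mediated decay (NMD) in all transcripts;
- splice disruption: base-editable offsets around splice acceptor
  (4-21 bp either side) and donor (3-21 bp intronic) boundaries;
- epigenetic silencing: the +/-500 bp promoter intersection, admitted only
  when mean promoter GC content exceeds 30%;
- excision: the gene span plus 50 kb flanks, truncated at overlapping
  protein-coding neighbours.
"""

from __future__ import annotations

import logging
from typing import Callable, Dict, List, Optional, Sequence

from . import intervals as iv
from .intervals import Interval
from .models import GeneModel, RuleConfig, StrategyWindowSet, Transcript

logger = logging.getLogger(__name__)


def ubiquitous_intersection(
    transcripts: Sequence[Transcript],
    region_extractor: Callable[[Transcript], Sequence[Interval]],
) -> List[Interval]:
    """Positions present in the extracted region set of every transcript."""
    if not transcripts:
        raise ValueError("ubiquitous_intersection requires at least one transcript")
    return iv.intersect_many([region_extractor(t) for t in transcripts])


def _spliced_coordinates(transcript: Transcript) -> Dict[int, int]:
    """Map genomic exon positions to spliced mRNA offsets (transcription order)."""
    mapping: Dict[int, int] = {}
    offset = 0
    for s, e in transcript.exons_in_transcription_order():
        length = e - s
        if transcript.strand == "+":
            for i in range(length):
                mapping[s + i] = offset + i
        else:
            for i in range(length):
                mapping[e - 1 - i] = offset + i
        offset += length
    return mapping


def nmd_competent_positions(
    transcript: Transcript, rules: Optional[RuleConfig] = None
) -> List[Interval]:
    """Coding positions where a frameshift is assumed to induce NMD.

    A premature termination codon escapes decay when it falls in the final
    exon or within ``nmd_junction_margin`` spliced nt of the final
    exon-exon junction; the variant's own spliced position is used as the
    proxy for where the truncating codon lands. Each rule component can be
    switched off via ``RuleConfig``.
    """
    rules = rules or RuleConfig()
    if transcript.cds is None:
        raise ValueError(f"transcript {transcript.id} has no coding span")
    if rules.nmd_require_multi_exon and len(transcript.exons) < 2:
        return []

    cds_s, cds_e = transcript.cds
    tx_order = transcript.exons_in_transcription_order()
    last_exon = tx_order[-1]
    spliced = _spliced_coordinates(transcript)
    # Spliced offset of the final exon-exon junction = first base of last exon.
    junction = spliced[last_exon[0] if transcript.strand == "+" else last_exon[1] - 1]

    cds_start_genomic = cds_s if transcript.strand == "+" else cds_e - 1
    cds_start_spliced = spliced.get(cds_start_genomic)

    positions: List[int] = []
    for s, e in transcript.exons:
        for p in range(max(s, cds_s), min(e, cds_e)):
            if rules.nmd_exclude_last_exon and last_exon[0] <= p < last_exon[1]:
                continue
            if junction - spliced[p] <= rules.nmd_junction_margin:
                continue
            if (rules.nmd_start_margin is not None and cds_start_spliced is not None
                    and abs(spliced[p] - cds_start_spliced) < rules.nmd_start_margin):
                continue
            positions.append(p)
    return _positions_to_intervals(positions)


def _positions_to_intervals(positions: List[int]) -> List[Interval]:
    out: List[Interval] = []
    for p in sorted(positions):
        if out and p == out[-1][1]:
            out[-1] = (out[-1][0], p + 1)
        else:
            out.append((p, p + 1))
    return out


def exon_disruption_windows(gene: GeneModel, rules: Optional[RuleConfig] = None) -> StrategyWindowSet:
    """NMD-competent coding positions shared by every valid transcript."""
    rules = rules or RuleConfig()
    valid = gene.require_valid()
    coding = [t for t in valid if t.cds is not None]
    if len(coding) < len(valid):
        # a non-coding transcript can never be NMD-disrupted at any position
        return StrategyWindowSet(gene.symbol, "exon_disruption", gene.chrom, [])
    nmd = iv.intersect_many([nmd_competent_positions(t, rules) for t in coding])
    ubiq = ubiquitous_intersection(valid, lambda t: list(t.exons))
    return StrategyWindowSet(gene.symbol, "exon_disruption", gene.chrom,
                             iv.intersect(nmd, ubiq))


def _transcript_splice_windows(t: Transcript, rules: RuleConfig) -> List[Interval]:
    """Acceptor/donor editing windows of one transcript (union of windows)."""
    alo, ahi = rules.acceptor_window
    dlo, dhi = rules.donor_window
    wins: List[Interval] = []
    exons = list(t.exons)  # genomic order
    n = len(exons)
    for i, (s, e) in enumerate(exons):
        if t.strand == "+":
            has_acceptor = i > 0
            has_donor = i < n - 1
            if has_acceptor:
                # intronic side: offsets into the intron upstream of exon start
                wins.append((s - ahi, s - alo + 1))
                # exonic side: offsets into the exon (offset 1 = first exon base)
                wins.append((s + alo - 1, s + ahi))
            if has_donor:
                # intronic, downstream of the exon end (offset 1 = first intron base)
                wins.append((e + dlo - 1, e + dhi))
        else:
            has_acceptor = i < n - 1   # transcription-internal exons sit genomically left
            has_donor = i > 0
            if has_acceptor:
                wins.append((e + alo - 1, e + ahi))       # intronic side (higher coords)
                wins.append((e - ahi, e - alo + 1))       # exonic side
            if has_donor:
                wins.append((s - dhi, s - dlo + 1))       # intronic, downstream = lower coords
    return iv.normalize(wins)


def splice_windows(gene: GeneModel, rules: Optional[RuleConfig] = None) -> StrategyWindowSet:
    """Positions inside a base-editing splice window of every valid transcript."""
    rules = rules or RuleConfig()
    valid = gene.require_valid()
    per_tx = [_transcript_splice_windows(t, rules) for t in valid]
    return StrategyWindowSet(gene.symbol, "splice_disruption", gene.chrom,
                             iv.intersect_many(per_tx))


def promoter_window(
    gene: GeneModel,
    reference: Callable[[str, int, int], str],
    rules: Optional[RuleConfig] = None,
    chrom_length: Optional[int] = None,
) -> StrategyWindowSet:
    """Intersection of +/-halfwidth promoter windows, gated on mean GC > 30%.

    ``reference`` is a callable ``(chrom, start, end) -> sequence`` over
    0-based half-open coordinates. Promoter spans extending past the
    chromosome start are clipped to 0 (logged).
    """
    rules = rules or RuleConfig()
    valid = gene.require_valid()
    hw = rules.promoter_halfwidth
    spans: List[Interval] = []
    gcs: List[float] = []
    for t in valid:
        lo, hi = t.tss - hw, t.tss + hw + 1  # inclusive both ends
        if lo < 0:
            logger.info("promoter of %s/%s clipped at chromosome start", gene.symbol, t.id)
            lo = 0
        if chrom_length is not None:
            hi = min(hi, chrom_length)
        seq = reference(gene.chrom, lo, hi).upper()
        if seq:
            gcs.append(sum(1 for b in seq if b in "GC") / len(seq))
        spans.append((lo, hi))
    mean_gc = sum(gcs) / len(gcs) if gcs else 0.0
    if mean_gc <= rules.gc_min:
        return StrategyWindowSet(gene.symbol, "epigenetic_silencing", gene.chrom, [],
                                 metadata={"mean_gc": mean_gc})
    return StrategyWindowSet(gene.symbol, "epigenetic_silencing", gene.chrom,
                             iv.intersect_many([[s] for s in spans]),
                             metadata={"mean_gc": mean_gc})


def excision_window(
    gene: GeneModel,
    neighbors: Sequence[GeneModel],
    rules: Optional[RuleConfig] = None,
    chrom_length: Optional[int] = None,
) -> StrategyWindowSet:
    """Gene span plus flanks, truncated at protein-coding neighbours.

    Each flank is independently shortened to the nearest edge of any
    overlapping protein-coding neighbour gene span, so the search region
    excludes that neighbour; a neighbour overlapping the gene itself
    collapses the corresponding flank to zero length.
    """
    rules = rules or RuleConfig()
    g_s, g_e = gene.span
    w_s = g_s - rules.excision_flank
    w_e = g_e + rules.excision_flank
    for nb in neighbors:
        if nb.chrom != gene.chrom or nb.symbol == gene.symbol or not nb.is_protein_coding:
            continue
        nb_s, nb_e = nb.span
        # left flank [w_s, g_s)
        if nb_e > w_s and nb_s < g_s:
            new_ws = max(w_s, nb_e)
            if new_ws >= g_s:
                logger.info("left excision flank of %s removed by overlapping neighbour %s",
                            gene.symbol, nb.symbol)
                new_ws = g_s
            w_s = new_ws
        # right flank [g_e, w_e)
        if nb_s < w_e and nb_e > g_e:
            new_we = min(w_e, nb_s)
            if new_we <= g_e:
                logger.info("right excision flank of %s removed by overlapping neighbour %s",
                            gene.symbol, nb.symbol)
                new_we = g_e
            w_e = new_we
    w_s = max(w_s, 0)
    if chrom_length is not None:
        w_e = min(w_e, chrom_length)
    return StrategyWindowSet(gene.symbol, "excision", gene.chrom, [(w_s, w_e)])


def strategy_windows(
    gene: GeneModel,
    reference: Callable[[str, int, int], str],
    neighbors: Sequence[GeneModel] = (),
    rules: Optional[RuleConfig] = None,
    chrom_length: Optional[int] = None,
) -> Dict[str, StrategyWindowSet]:
    """All four strategy window sets for one gene."""
    rules = rules or RuleConfig()
    return {
        "exon_disruption": exon_disruption_windows(gene, rules),
        "splice_disruption": splice_windows(gene, rules),
        "epigenetic_silencing": promoter_window(gene, reference, rules, chrom_length),
        "excision": excision_window(gene, neighbors, rules, chrom_length),
    }
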