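"""Curation of dominant & dispensable (D&D) gene sets.

Group 1: genes with a Moderate-to-Definitive autosomal dominant or
semidominant disease association, no X-linked association, and no
sufficient/emerging evidence of haploinsufficiency. Group 2 additionally
requires tolerance to heterozygous loss of function (s_het < 0.1).
Transcript filtering keeps disease-relevant biotypes and removes
transcripts contributing on average < 5% of the gene's expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .models import GeneModel, Transcript

logger = logging.getLogger(__name__)

QUALIFYING_CLASSIFICATIONS = {"Definitive", "Strong", "Moderate"}
EXCLUDED_DOSAGE = {"sufficient_evidence_HI", "emerging_evidence_HI"}
ALLOWED_BIOTYPES = {
    "protein_coding",
    "nonsense_mediated_decay",
    "non_stop_decay",
    "lncRNA",
    "miRNA",
}
SHET_MAX = 0.1
EXPRESSION_SHARE_MIN = 0.05


@dataclass
class ClinicalGeneRecord:
    """One gene's mode-of-inheritance and dosage annotations."""

    gene: str
    moi_entries: List[Tuple[str, str]]  # (mode in {AD, AR, XL, SD}, classification)
    dosage: str = "missing"  # sufficient_evidence_HI / emerging_evidence_HI /
    #                          little_evidence_HI / no_evidence / missing


@dataclass
class ShetRecord:
    gene: str
    s_het: Optional[float] = None

    def __post_init__(self):
        if self.s_het is not None and self.s_het < 0:
            raise ValueError(f"negative s_het for {self.gene}")


@dataclass
class PathogenicMutationRecord:
    gene: str
    mutation_id: str
    significance: str  # pathogenic / likely_pathogenic / other
    direct_dominant_flag: bool = False
    omim_moi: List[str] = field(default_factory=list)


def select_dnd_group1(records: Iterable[ClinicalGeneRecord]) -> Set[str]:
    """Select Group 1 genes from clinical annotations.

    A gene qualifies when it has at least one AD or SD entry classified
    Moderate/Strong/Definitive, no XL entry at all, and its dosage
    annotation shows no sufficient or emerging evidence of
    haploinsufficiency. AR entries alongside AD are retained (many DN/GOF
    genes also have recessive loss-of-function presentations).
    """
    out: Set[str] = set()
    for rec in records:
        if not rec.moi_entries:
            continue
        modes = {m for m, _ in rec.moi_entries}
        if "XL" in modes:
            continue
        qualifying = any(
            m in ("AD", "SD") and c in QUALIFYING_CLASSIFICATIONS
            for m, c in rec.moi_entries
        )
        if not qualifying:
            continue
        if rec.dosage in EXCLUDED_DOSAGE:
            continue
        out.add(rec.gene)
    return out


def select_dnd_group2(
    group1: Set[str],
    shet: Iterable[ShetRecord],
    shet_max: float = SHET_MAX,
) -> Tuple[Set[str], List[str]]:
    """Subset Group 1 to genes with s_het strictly below ``shet_max``.

    Returns ``(group2, missing)`` where ``missing`` lists Group 1 genes
    without an s_het estimate; those are excluded conservatively.
    """
    values: Dict[str, Optional[float]] = {}
    for rec in shet:
        values[rec.gene] = rec.s_het
    group2: Set[str] = set()
    missing: List[str] = []
    for gene in sorted(group1):
        v = values.get(gene)
        if v is None:
            missing.append(gene)
            continue
        if v < shet_max:
            group2.add(gene)
    if missing:
        logger.info("%d Group 1 genes lack an s_het estimate and were excluded "
                    "from Group 2: %s", len(missing), ", ".join(missing))
    return group2, missing


def filter_transcripts(
    gene: GeneModel,
    expression: pd.DataFrame,
    min_share: float = EXPRESSION_SHARE_MIN,
    allowed_biotypes: Set[str] = ALLOWED_BIOTYPES,
    tissue_blocklist: Sequence[str] = (),
) -> GeneModel:
    """Populate ``valid_transcripts`` by biotype and mean expression share.

    ``expression`` is a transcript x tissue TPM matrix (transcript ids as
    index). For each kept-biotype transcript, its share of the gene's
    summed TPM is computed per tissue where the gene is expressed
    (gene TPM > 0), then averaged across those tissues; transcripts with a
    mean share below ``min_share`` are dropped. Transcripts absent from the
    matrix count as unexpressed and are dropped (logged). If the gene has
    no expressed tissue at all, in-table biotype-passing transcripts are
    kept: zero coverage carries no evidence against any one isoform.
    """
    expr = expression.drop(columns=[t for t in tissue_blocklist if t in expression.columns])
    tx_ids = [t.id for t in gene.transcripts]
    gene_expr = expr.reindex(tx_ids).fillna(0.0)
    absent = {t.id for t in gene.transcripts if t.id not in expr.index}
    for tid in sorted(absent):
        logger.info("transcript %s of %s absent from expression table; dropped",
                    tid, gene.symbol)

    by_biotype = [t for t in gene.transcripts if t.biotype in allowed_biotypes]
    gene_total = gene_expr.sum(axis=0)
    expressed = gene_total[gene_total > 0].index

    valid: List[Transcript] = []
    for t in by_biotype:
        if t.id in absent:
            continue
        if len(expressed) == 0:
            valid.append(t)
            continue
        shares = gene_expr.loc[t.id, expressed] / gene_total[expressed]
        if float(shares.mean()) >= min_share:
            valid.append(t)
    result = replace_valid(gene, valid)
    if not valid:
        logger.info("gene %s dropped: no transcript passed biotype/expression filters",
                    gene.symbol)
    return result


def replace_valid(gene: GeneModel, valid: List[Transcript]) -> GeneModel:
    return GeneModel(
        symbol=gene.symbol,
        chrom=gene.chrom,
        strand=gene.strand,
        transcripts=gene.transcripts,
        valid_transcripts=valid,
    )


def count_dominant_pathogenic(
    mutations: Iterable[PathogenicMutationRecord],
) -> Dict[str, int]:
    """Count pathogenic/likely-pathogenic mutations with dominant evidence.

    A record counts when its significance qualifies and it either carries a
    direct dominant annotation or any of its linked OMIM inheritance modes
    is autosomal dominant.
    """
    counts: Dict[str, int] = {}
    for rec in mutations:
        if rec.significance not in ("pathogenic", "likely_pathogenic"):
            continue
        if not (rec.direct_dominant_flag or "AD" in rec.omim_moi):
            continue
        counts[rec.gene] = counts.get(rec.gene, 0) + 1
    return counts
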