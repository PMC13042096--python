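"""Core domain types shared across the pipeline.

The central objects are gene models (transcripts with exon/CDS structure),
phased common variants from a population panel, and the strategy-specific
"targetable allele" records that the guide-design and prioritization stages
consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import Interval, normalize

# Editing strategies considered for allele-specific inactivation.
STRATEGIES = (
    "exon_disruption",
    "splice_disruption",
    "epigenetic_silencing",
    "excision",
)


@dataclass(frozen=True)
class Transcript:
    """A transcript with 0-based half-open exon intervals.

    ``cds`` is the genomic span of the coding region (half-open), or None
    for non-coding transcripts. The TSS is derived from the strand: the
    lowest exon start on '+', the highest exon end minus one on '-'.
    """

    id: str
    biotype: str
    exons: Tuple[Interval, ...]
    strand: str
    cds: Optional[Interval] = None

    def __post_init__(self):
        exons = tuple(sorted(self.exons))
        object.__setattr__(self, "exons", exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"transcript {self.id}: overlapping exons {((s1, e1), (s2, e2))}")
        if self.strand not in "+-":
            raise ValueError(f"transcript {self.id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        """0-based genomic position of the transcription start site."""
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1] - 1

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    def exons_in_transcription_order(self) -> List[Interval]:
        return list(self.exons) if self.strand == "+" else list(reversed(self.exons))


@dataclass
class GeneModel:
    """A gene with its transcripts; ``valid_transcripts`` is populated by
    transcript filtering (biotype + expression share)."""

    symbol: str
    chrom: str
    strand: str
    transcripts: List[Transcript]
    valid_transcripts: Optional[List[Transcript]] = None

    @property
    def span(self) -> Interval:
        s = min(t.exons[0][0] for t in self.transcripts)
        e = max(t.exons[-1][1] for t in self.transcripts)
        return (s, e)

    @property
    def is_protein_coding(self) -> bool:
        return any(t.biotype == "protein_coding" for t in self.transcripts)

    def require_valid(self) -> List[Transcript]:
        if not self.valid_transcripts:
            raise ValueError(f"gene {self.symbol}: no valid transcripts")
        return self.valid_transcripts


@dataclass(frozen=True)
class CommonVariant:
    """A biallelic SNV that passed the MAF filter."""

    chrom: str
    pos: int  # 0-based
    id: str
    ref: str
    alt: str
    af: float  # alternate-allele frequency

    @property
    def maf(self) -> float:
        return min(self.af, 1.0 - self.af)


class PhasedPanel:
    """Per-individual two-haplotype allele calls for biallelic variants.

    Genotypes are stored as an int8 array of shape (n_variants, n_samples, 2)
    with 0 = ref, 1 = alt, -1 = missing. Haplotype side 0/1 follows the VCF
    phased genotype order (left|right).
    """

    def __init__(self, samples: Sequence[str], variants: Sequence[CommonVariant],
                 genotypes: np.ndarray):
        self.samples = list(samples)
        self.variants = list(variants)
        gt = np.asarray(genotypes, dtype=np.int8)
        if gt.shape != (len(self.variants), len(self.samples), 2):
            raise ValueError(f"genotype array shape {gt.shape} does not match "
                             f"{len(self.variants)} variants x {len(self.samples)} samples x 2")
        self.genotypes = gt
        self._index: Dict[Tuple[str, int], int] = {
            (v.chrom, v.pos): i for i, v in enumerate(self.variants)
        }

    @property
    def n_haplotypes(self) -> int:
        return 2 * len(self.samples)

    def variant_index(self, variant: CommonVariant) -> int:
        try:
            return self._index[(variant.chrom, variant.pos)]
        except KeyError:
            raise KeyError(f"variant {variant.chrom}:{variant.pos} not in panel") from None

    def genotype_matrix(self, variant: CommonVariant) -> np.ndarray:
        """(n_samples, 2) allele codes for one variant."""
        return self.genotypes[self.variant_index(variant)]


@dataclass(frozen=True)
class TargetableAllele:
    """One allele of a common variant validated for one editing strategy."""

    gene: str
    strategy: str
    variant: CommonVariant
    allele: str  # "ref" or "alt"

    def __post_init__(self):
        if self.allele not in ("ref", "alt"):
            raise ValueError(f"allele must be 'ref' or 'alt', got {self.allele!r}")

    @property
    def allele_code(self) -> int:
        return 0 if self.allele == "ref" else 1

    @property
    def base(self) -> str:
        return self.variant.ref if self.allele == "ref" else self.variant.alt

    def sort_key(self):
        return (self.variant.chrom, self.variant.pos, self.allele, self.strategy)


@dataclass(frozen=True)
class ExcisionPair:
    """An in-cis candidate allele pair flanking at least one whole exon of
    every valid transcript; coverage is resolved later from phasing."""

    gene: str
    left: TargetableAllele
    right: TargetableAllele

    def __post_init__(self):
        if self.left.variant.pos >= self.right.variant.pos:
            raise ValueError("excision pair must satisfy left.pos < right.pos")

    def sort_key(self):
        return (self.left.variant.chrom, self.left.variant.pos, self.left.allele,
                self.right.variant.pos, self.right.allele)


@dataclass(frozen=True)
class HaplotypeId:
    sample: str
    side: int  # 0 or 1


@dataclass(frozen=True)
class GuideDesign:
    """A 20-nt spacer matched to one allele, anchored at an NGG-style PAM.

    ``variant_offset`` counts from the PAM-proximal spacer end (1 = the base
    adjacent to the PAM); 0 marks a variant inside the PAM itself.
    """

    strand: str
    pam_start: int  # genomic index of the PAM's strand-first base
    spacer: str
    variant_offset: int


@dataclass(frozen=True)
class Therapy:
    """One deliverable reagent: a single allele-specific guide, or a guide
    pair for the excision strategy."""

    kind: str  # "single" or "excision"
    alleles: Tuple[TargetableAllele, ...]
    guides: Tuple = ()

    def __post_init__(self):
        if self.kind == "excision" and len(self.alleles) != 2:
            raise ValueError("excision therapy needs exactly two alleles")
        if self.kind == "single" and len(self.alleles) != 1:
            raise ValueError("single therapy needs exactly one allele")

    def sort_key(self):
        return tuple(a.sort_key() for a in self.alleles)

    def describe(self) -> str:
        parts = [f"{a.variant.id}|{a.allele}" for a in self.alleles]
        return "+".join(parts)


@dataclass
class PrioritizationResult:
    """Ordered greedy therapy selection with per-step coverage accounting."""

    therapies: List[Therapy] = field(default_factory=list)
    new_haplotypes: List[frozenset] = field(default_factory=list)
    total_haplotypes: int = 0

    @property
    def cumulative_counts(self) -> List[int]:
        out, c = [], 0
        for s in self.new_haplotypes:
            c += len(s)
            out.append(c)
        return out

    @property
    def cumulative_fractions(self) -> List[float]:
        if self.total_haplotypes == 0:
            return [0.0 for _ in self.new_haplotypes]
        return [c / self.total_haplotypes for c in self.cumulative_counts]

    def covered_after(self, k: Optional[int] = None) -> frozenset:
        steps = self.new_haplotypes if k is None else self.new_haplotypes[:k]
        out: set = set()
        for s in steps:
            out |= s
        return frozenset(out)


@dataclass
class RuleConfig:
    """Numeric constants of the strategy window rules.

    Splice windows are inclusive offset ranges counted from the first base
    beyond the exon/intron boundary (offset 1). The NMD competence rule
    follows the canonical 50-nt boundary: a premature termination codon more
    than ``nmd_junction_margin`` spliced nt upstream of the final exon-exon
    junction is assumed to trigger decay; the start-proximal escape is
    available but off by default.
    """

    acceptor_window: Tuple[int, int] = (4, 21)
    donor_window: Tuple[int, int] = (3, 21)
    promoter_halfwidth: int = 500
    gc_min: float = 0.30  # strict >
    excision_flank: int = 50_000
    nmd_junction_margin: int = 50
    nmd_start_margin: Optional[int] = None
    nmd_require_multi_exon: bool = True
    nmd_exclude_last_exon: bool = True

    def __post_init__(self):
        for lo, hi in (self.acceptor_window, self.donor_window):
            if not (0 < lo <= hi):
                raise ValueError("window bounds must satisfy 0 < low <= high")


@dataclass
class PamConfig:
    """PAM/spacer geometry for guide design (SpCas9 defaults)."""

    pam_motif: str = "NGG"
    spacer_len: int = 20
    seed_len: int = 10
    allow_variant_in_pam: bool = True

    def __post_init__(self):
        if self.seed_len > self.spacer_len:
            raise ValueError("seed_len must not exceed spacer_len")


@dataclass
class StrategyWindowSet:
    """Per-gene, per-strategy targetable intervals (sorted, merged)."""

    gene: str
    strategy: str
    chrom: str
    intervals: List[Interval] = field(default_factory=list)
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        self.intervals = normalize(self.intervals)

    def __contains__(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.intervals)
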