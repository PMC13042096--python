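"""Allele-specific guide design around common variants.

A guide discriminates alleles when the variant sits in the PAM-proximal
seed region of the spacer (mismatches there abolish SpCas9 cutting) or
when one allele is required to complete the PAM motif itself. The scan
covers both strands of the reference with the targeted allele substituted
at the variant position; the emitted spacer therefore matches only the
targeted allele.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Optional, Sequence, Tuple

from .models import (
    CommonVariant,
    ExcisionPair,
    GuideDesign,
    PamConfig,
    TargetableAllele,
)

IUPAC: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _matches(motif: str, seq: str) -> bool:
    return len(seq) == len(motif) and all(b in IUPAC[m] for m, b in zip(motif, seq))


def find_guides(
    reference: Callable[[str, int, int], str],
    variant: CommonVariant,
    allele: str,
    cfg: Optional[PamConfig] = None,
) -> List[GuideDesign]:
    """Enumerate allele-specific guides for one allele of a variant.

    ``reference`` is a ``(chrom, start, end) -> sequence`` callable over
    0-based half-open coordinates and must cover the variant plus
    ``spacer_len + len(pam_motif)`` on both sides. A guide is emitted when
    the variant falls within the ``seed_len`` PAM-proximal spacer positions,
    or (if allowed) on a constrained PAM position that only the targeted
    allele satisfies. Guides touching reference N bases are rejected.
    """
    cfg = cfg or PamConfig()
    pam_len = len(cfg.pam_motif)
    reach = cfg.spacer_len + pam_len
    lo, hi = variant.pos - reach, variant.pos + reach + 1
    window = reference(variant.chrom, lo, hi).upper()
    if len(window) != hi - lo:
        raise ValueError(
            f"reference window {variant.chrom}:{lo}-{hi} unavailable for guide design")
    base = variant.ref if allele == "ref" else variant.alt
    other = variant.alt if allele == "ref" else variant.ref
    seq = window[: variant.pos - lo] + base + window[variant.pos - lo + 1:]

    out: List[GuideDesign] = []
    # plus strand: PAM occupies [q, q+pam_len), spacer [q-spacer_len, q)
    for q in range(lo, hi - pam_len + 1):
        pam_seq = seq[q - lo: q - lo + pam_len]
        if not _matches(cfg.pam_motif, pam_seq):
            continue
        offset = q - variant.pos
        in_seed = 1 <= offset <= cfg.seed_len
        in_pam = q <= variant.pos < q + pam_len
        pam_specific = False
        if in_pam and cfg.allow_variant_in_pam:
            m = cfg.pam_motif[variant.pos - q]
            pam_specific = m != "N" and base in IUPAC[m] and other not in IUPAC[m]
        if not (in_seed or pam_specific):
            continue
        spacer = seq[q - lo - cfg.spacer_len: q - lo]
        if len(spacer) != cfg.spacer_len or "N" in spacer or "N" in pam_seq:
            continue
        out.append(GuideDesign("+", q, spacer, offset if in_seed else 0))
    # minus strand: genomic triplet [m, m+pam_len) whose revcomp reads the motif;
    # spacer is genomic [m+pam_len, m+pam_len+spacer_len), reverse-complemented.
    for m in range(lo, hi - pam_len + 1):
        pam_genomic = seq[m - lo: m - lo + pam_len]
        if not _matches(cfg.pam_motif, revcomp(pam_genomic)):
            continue
        offset = variant.pos - (m + pam_len) + 1
        in_seed = 1 <= offset <= cfg.seed_len
        in_pam = m <= variant.pos < m + pam_len
        pam_specific = False
        if in_pam and cfg.allow_variant_in_pam:
            mchar = cfg.pam_motif[m + pam_len - 1 - variant.pos]
            comp_base = revcomp(base)
            comp_other = revcomp(other)
            pam_specific = (mchar != "N" and comp_base in IUPAC[mchar]
                            and comp_other not in IUPAC[mchar])
        if not (in_seed or pam_specific):
            continue
        spacer_genomic = seq[m - lo + pam_len: m - lo + pam_len + cfg.spacer_len]
        if len(spacer_genomic) != cfg.spacer_len or "N" in spacer_genomic or "N" in pam_genomic:
            continue
        out.append(GuideDesign("-", m + pam_len - 1, revcomp(spacer_genomic),
                               offset if in_seed else 0))
    out.sort(key=lambda g: (g.pam_start, g.strand))
    return out


def filter_targets_by_pam(
    targets: Sequence[TargetableAllele],
    reference: Callable[[str, int, int], str],
    cfg: Optional[PamConfig] = None,
) -> List[Tuple[TargetableAllele, List[GuideDesign]]]:
    """Keep targets with at least one valid guide design."""
    cfg = cfg or PamConfig()
    out: List[Tuple[TargetableAllele, List[GuideDesign]]] = []
    cache: Dict[Tuple[str, int, str], List[GuideDesign]] = {}
    for t in targets:
        key = (t.variant.chrom, t.variant.pos, t.allele)
        if key not in cache:
            cache[key] = find_guides(reference, t.variant, t.allele, cfg)
        if cache[key]:
            out.append((t, cache[key]))
    return out


def filter_pairs_by_pam(
    pairs: Sequence[ExcisionPair],
    reference: Callable[[str, int, int], str],
    cfg: Optional[PamConfig] = None,
) -> List[Tuple[ExcisionPair, Tuple[List[GuideDesign], List[GuideDesign]]]]:
    """Keep excision pairs where both member alleles have a valid guide."""
    cfg = cfg or PamConfig()
    cache: Dict[Tuple[str, int, str], List[GuideDesign]] = {}

    def designs(t: TargetableAllele) -> List[GuideDesign]:
        key = (t.variant.chrom, t.variant.pos, t.allele)
        if key not in cache:
            cache[key] = find_guides(reference, t.variant, t.allele, cfg)
        return cache[key]

    out = []
    for p in pairs:
        gl, gr = designs(p.left), designs(p.right)
        if gl and gr:
            out.append((p, (gl, gr)))
    return out
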