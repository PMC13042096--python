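"""Guide design: constructed examples, exhaustive brute-force oracle,
reverse-complement symmetry and allele-specificity by construction."""

import numpy as np
import pytest

from dndcrispr import guides
from dndcrispr.guides import IUPAC, revcomp
from dndcrispr.models import CommonVariant, PamConfig, TargetableAllele


def ref_from(seq, chrom="chrT"):
    def ref(c, s, e):
        assert c == chrom
        return seq[max(s, 0):e]
    return ref


def brute_force_guides(seq, variant, allele, cfg=None):
    """Oracle: try every PAM placement on both strands explicitly."""
    cfg = cfg or PamConfig()
    base = variant.ref if allele == "ref" else variant.alt
    other = variant.alt if allele == "ref" else variant.ref
    s = seq[: variant.pos] + base + seq[variant.pos + 1:]
    L = len(cfg.pam_motif)
    found = set()
    for q in range(len(s) - L + 1):
        # plus strand
        if all(b in IUPAC[m] for m, b in zip(cfg.pam_motif, s[q:q + L])):
            offset = q - variant.pos
            in_seed = 1 <= offset <= cfg.seed_len
            pam_ok = (cfg.allow_variant_in_pam and q <= variant.pos < q + L
                      and cfg.pam_motif[variant.pos - q] != "N"
                      and base in IUPAC[cfg.pam_motif[variant.pos - q]]
                      and other not in IUPAC[cfg.pam_motif[variant.pos - q]])
            spacer = s[q - cfg.spacer_len:q]
            if (in_seed or pam_ok) and q - cfg.spacer_len >= 0 and "N" not in spacer:
                found.add(("+", q, spacer))
        # minus strand
        if all(b in IUPAC[m] for m, b in zip(cfg.pam_motif, revcomp(s[q:q + L]))):
            offset = variant.pos - (q + L) + 1
            in_seed = 1 <= offset <= cfg.seed_len
            mi = q + L - 1 - variant.pos
            pam_ok = (cfg.allow_variant_in_pam and q <= variant.pos < q + L
                      and cfg.pam_motif[mi] != "N"
                      and revcomp(base) in IUPAC[cfg.pam_motif[mi]]
                      and revcomp(other) not in IUPAC[cfg.pam_motif[mi]])
            spacer = revcomp(s[q + L:q + L + cfg.spacer_len])
            if ((in_seed or pam_ok) and q + L + cfg.spacer_len <= len(s)
                    and "N" not in spacer):
                found.add(("-", q + L - 1, spacer))
    return found


def test_variant_upstream_of_agg_yields_offset6_guide():
    # 60 nt of PAM-free background (no G/C except the planted AGG)
    seq = list("AT" * 30)
    pos = 30
    seq[pos] = "A"
    seq[pos + 6:pos + 9] = list("AGG")  # 5 intervening nt -> seed offset 6
    seq = "".join(seq)
    v = CommonVariant("chrT", pos, "v", "A", "T", 0.3)
    got = guides.find_guides(ref_from(seq), v, "ref")
    assert len(got) == 1
    g = got[0]
    assert g.strand == "+" and g.variant_offset == 6 and g.pam_start == pos + 6
    assert len(g.spacer) == 20 and g.spacer[-6] == "A"
    # targeted allele substituted: alt spacer differs at exactly that base
    alt = guides.find_guides(ref_from(seq), v, "alt")[0]
    assert alt.spacer[-6] == "T"
    diff = [i for i, (a, b) in enumerate(zip(g.spacer, alt.spacer)) if a != b]
    assert diff == [14]


def test_variant_outside_seed_yields_no_guides():
    seq = list("AT" * 40)
    pos = 25
    seq[pos + 15:pos + 18] = list("AGG")  # offset 15 > seed 10
    seq = "".join(seq)
    v = CommonVariant("chrT", pos, "v", "A", "T", 0.3)
    assert guides.find_guides(ref_from(seq), v, "ref") == []
    assert guides.find_guides(ref_from(seq), v, "alt") == []


def test_no_g_or_c_sequence_yields_no_guides():
    seq = "AT" * 40
    v = CommonVariant("chrT", 40, "v", "A", "T", 0.3)
    assert guides.find_guides(ref_from(seq), v, "ref") == []


def test_variant_completing_pam_emitted_for_completing_allele_only():
    seq = list("AT" * 30)
    pos = 30
    seq[pos + 1] = "G"  # alt G at pos makes (pos, pos+1) read "GG" -> NGG at pos-1
    seq = "".join(seq)
    v = CommonVariant("chrT", pos, "v", "A", "G", 0.3)
    ref_guides = guides.find_guides(ref_from(seq), v, "ref")
    alt_guides = guides.find_guides(ref_from(seq), v, "alt")
    assert ref_guides == []
    assert [g.strand for g in alt_guides] == ["+"]
    assert alt_guides[0].variant_offset == 0  # inside the PAM
    # and the toggle removes PAM-completion designs
    off = PamConfig(allow_variant_in_pam=False)
    assert guides.find_guides(ref_from(seq), v, "alt", off) == []


@pytest.mark.parametrize("seed", range(20))
def test_exhaustive_oracle_equivalence_on_random_sequences(seed):
    rng = np.random.default_rng(seed)
    n = 120
    seq = "".join(rng.choice(list("ACGT"), size=n))
    pos = int(rng.integers(30, n - 30))
    ref_base = seq[pos]
    alt_base = rng.choice([b for b in "ACGT" if b != ref_base])
    v = CommonVariant("chrT", pos, "v", ref_base, alt_base, 0.3)
    for allele in ("ref", "alt"):
        got = {(g.strand, g.pam_start, g.spacer)
               for g in guides.find_guides(ref_from(seq), v, allele)}
        assert got == brute_force_guides(seq, v, allele)


@pytest.mark.parametrize("seed", range(5))
def test_reverse_complement_symmetry(seed):
    rng = np.random.default_rng(100 + seed)
    n = 100
    seq = "".join(rng.choice(list("ACGT"), size=n))
    pos = int(rng.integers(30, n - 30))
    v = CommonVariant("chrT", pos, "v", seq[pos],
                      [b for b in "ACGT" if b != seq[pos]][0], 0.3)
    rc_seq = revcomp(seq)
    rc_pos = n - 1 - pos
    rc_v = CommonVariant("chrT", rc_pos, "v", revcomp(v.ref), revcomp(v.alt), 0.3)
    fwd = guides.find_guides(ref_from(seq), v, "ref")
    rev = guides.find_guides(ref_from(rc_seq), rc_v, "ref")
    mirrored = {("-" if g.strand == "+" else "+", n - 1 - g.pam_start, g.spacer)
                for g in rev}
    assert {(g.strand, g.pam_start, g.spacer) for g in fwd} == mirrored


def test_filter_targets_by_pam_keeps_only_designable_targets():
    seq = list("AT" * 40)
    seq[44:46] = list("GG")  # PAM near pos 40 only
    seq = "".join(seq)
    v_ok = CommonVariant("chrT", 40, "ok", "A", "T", 0.3)
    v_bad = CommonVariant("chrT", 30, "bad", "A", "T", 0.3)  # PAM beyond its seed
    targets = [TargetableAllele("G", "exon_disruption", v, a)
               for v in (v_ok, v_bad) for a in ("ref", "alt")]
    kept = guides.filter_targets_by_pam(targets, ref_from(seq))
    assert {t.variant.id for t, _ in kept} == {"ok"}
    assert all(designs for _, designs in kept)
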