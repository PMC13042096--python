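"""Strategy windows: brute-force oracles, boundary offsets, strand symmetry."""

import pytest

from dndcrispr import intervals as iv
from dndcrispr import regions
from dndcrispr.models import GeneModel, RuleConfig, Transcript


def tx(exons, strand="+", cds=None, tid="t", biotype="protein_coding"):
    return Transcript(tid, biotype, tuple(exons), strand, cds)


def gene(transcripts, symbol="G", chrom="chr1"):
    return GeneModel(symbol, chrom, transcripts[0].strand, list(transcripts),
                     valid_transcripts=list(transcripts))


# -- ubiquitous intersection -------------------------------------------------

def test_ubiquitous_intersection_examples():
    t1 = tx([(100, 200)], tid="a")
    t2 = tx([(150, 250)], tid="b")
    assert regions.ubiquitous_intersection([t1], lambda t: list(t.exons)) == [(100, 200)]
    assert regions.ubiquitous_intersection([t1, t2], lambda t: list(t.exons)) == [(150, 200)]
    t3 = tx([(300, 400)], tid="c")
    assert regions.ubiquitous_intersection([t1, t3], lambda t: list(t.exons)) == []
    with pytest.raises(ValueError):
        regions.ubiquitous_intersection([], lambda t: list(t.exons))


# -- NMD competence -----------------------------------------------------------

def brute_nmd(transcript, margin=50):
    """Independent oracle: map every coding base to its spliced offset and
    apply the junction-distance rule literally."""
    if len(transcript.exons) < 2:
        return set()
    order = transcript.exons_in_transcription_order()
    spliced = {}
    off = 0
    for s, e in order:
        rng = range(s, e) if transcript.strand == "+" else range(e - 1, s - 1, -1)
        for p in rng:
            spliced[p] = off
            off += 1
    last = order[-1]
    junction = min(spliced[p] for p in range(last[0], last[1]))
    cs, ce = transcript.cds
    out = set()
    for p in range(cs, ce):
        if p not in spliced:
            continue
        if last[0] <= p < last[1]:
            continue
        if junction - spliced[p] > margin:
            out.add(p)
    return out


def as_set(ivs):
    return {p for s, e in ivs for p in range(s, e)}


@pytest.mark.parametrize("strand", ["+", "-"])
def test_nmd_competence_matches_brute_force(strand):
    t = tx([(0, 200), (300, 380), (500, 700)], strand=strand, cds=(20, 650))
    assert as_set(regions.nmd_competent_positions(t)) == brute_nmd(t)


def test_nmd_single_exon_transcript_is_empty():
    t = tx([(0, 500)], cds=(50, 400))
    assert regions.nmd_competent_positions(t) == []


def test_nmd_two_exon_first150_rule():
    # exon1 entirely coding, 200 nt: competent = first 150 spliced coding nt
    t = tx([(0, 200), (400, 600)], cds=(0, 550))
    assert regions.nmd_competent_positions(t) == [(0, 150)]


def test_nmd_last_exon_and_margin_toggles():
    t = tx([(0, 200), (400, 600)], cds=(0, 550))
    rules = RuleConfig(nmd_exclude_last_exon=False, nmd_junction_margin=0)
    got = as_set(regions.nmd_competent_positions(t, rules))
    # with both relaxations only strictly-upstream-of-junction coding stays
    assert got == set(range(0, 200))
    rules2 = RuleConfig(nmd_start_margin=100)
    assert as_set(regions.nmd_competent_positions(t, rules2)) == set(range(100, 150))


# -- splice windows ------------------------------------------------------------

def test_acceptor_and_donor_window_offsets_plus_strand():
    t = tx([(500, 1000 - 400), (1000, 2000)], cds=(520, 1900))
    g = gene([t])
    wins = regions.splice_windows(g).intervals
    # acceptor of the internal exon at 1000: intronic [979,997), exonic [1003,1021)
    assert (979, 997) in wins and (1003, 1021) in wins
    # donor of exon ending at 600: [602, 621)
    assert (602, 621) in wins


def test_donor_window_of_exon_ending_2000():
    t = tx([(1000, 2000), (3000, 3500)], cds=(1010, 3400))
    wins = regions.splice_windows(gene([t])).intervals
    assert (2002, 2021) in wins


def test_single_exon_transcript_blanks_gene_splice_windows():
    multi = tx([(0, 200), (400, 600)], cds=(0, 550), tid="m")
    single = tx([(0, 600)], cds=(0, 550), tid="s")
    assert regions.splice_windows(gene([multi, single])).intervals == []


def test_splice_windows_require_every_transcript():
    t1 = tx([(0, 200), (400, 600)], tid="a", cds=(0, 550))
    t2 = tx([(0, 200), (800, 900)], tid="b", cds=(0, 880))
    wins = regions.splice_windows(gene([t1, t2])).intervals
    # shared donor at 200 -> [202,221) survives; the acceptors differ -> gone
    assert (202, 221) in wins
    assert not any(s <= 390 < e or s <= 790 < e for s, e in wins)


def mirror_transcript(t, length):
    """Reverse-complement coordinate image of a transcript."""
    exons = tuple(sorted((length - e, length - s) for s, e in t.exons))
    cds = (length - t.cds[1], length - t.cds[0]) if t.cds else None
    return Transcript(t.id, t.biotype, exons, "-" if t.strand == "+" else "+", cds)


@pytest.mark.parametrize("maker,kwargs", [
    (regions.splice_windows, {}),
    (regions.exon_disruption_windows, {}),
])
def test_strand_symmetry_of_windows(maker, kwargs):
    L = 5000
    t = tx([(100, 700), (1200, 1500), (2600, 3100)], cds=(150, 3000))
    fwd = maker(gene([t]), **kwargs).intervals
    rev = maker(gene([mirror_transcript(t, L)]), **kwargs).intervals
    mirrored = sorted((L - e, L - s) for s, e in rev)
    assert mirrored == fwd


def test_every_splice_position_near_a_boundary_of_every_transcript():
    t1 = tx([(100, 700), (1200, 1500), (2600, 3100)], tid="a", cds=(150, 3000))
    t2 = tx([(100, 700), (1200, 1500), (2600, 3000)], tid="b", cds=(150, 2900))
    wins = regions.splice_windows(gene([t1, t2])).intervals
    boundaries = [b for t in (t1, t2) for s, e in t.exons for b in (s, e)]
    for s, e in wins:
        for p in range(s, e):
            assert all(min(abs(p - b) for b in boundaries) <= 21 for t in (t1, t2))


# -- exon disruption -----------------------------------------------------------

def test_exon_disruption_is_intersection_of_nmd_and_exons():
    shared = [(0, 1000), (2000, 2300), (4000, 4500)]
    t1 = tx(shared, tid="a", cds=(100, 4400))
    t2 = tx([(0, 1000), (2000, 2300), (4000, 4600)], tid="b", cds=(100, 4400))
    g = gene([t1, t2])
    wins = regions.exon_disruption_windows(g)
    expected = as_set(regions.nmd_competent_positions(t1)) & as_set(
        regions.nmd_competent_positions(t2))
    assert as_set(wins.intervals) == expected
    assert as_set(wins.intervals) <= as_set(
        regions.ubiquitous_intersection(g.valid_transcripts, lambda t: list(t.exons)))


def test_exon_disruption_empty_for_single_exon_transcripts():
    t = tx([(0, 1000)], cds=(100, 900))
    assert regions.exon_disruption_windows(gene([t])).intervals == []


def test_position_competent_in_only_one_transcript_excluded():
    t1 = tx([(0, 1000), (2000, 2300)], tid="a", cds=(0, 2200))
    # t2's junction sits earlier, so late exon-1 positions lose competence
    t2 = tx([(0, 300), (2000, 2300)], tid="b", cds=(0, 2200))
    wins = regions.exon_disruption_windows(gene([t1, t2]))
    only_t1 = as_set(regions.nmd_competent_positions(t1)) - as_set(
        regions.nmd_competent_positions(t2))
    assert only_t1 and not (as_set(wins.intervals) & only_t1)


# -- promoter windows ----------------------------------------------------------

def test_promoter_gc_gate_and_intersection():
    t1 = tx([(1000, 1500), (2000, 2500)], tid="a", cds=(1100, 2400))
    t2 = tx([(1100, 1500), (2000, 2500)], tid="b", cds=(1150, 2400))
    g = gene([t1, t2])
    ref_gc = lambda c, s, e: "G" * (e - s)
    w = regions.promoter_window(g, ref_gc)
    # TSSs 1000 and 1100 -> inclusive +/-500 windows intersect to [600, 1501)
    assert w.intervals == [(600, 1501)]
    ref_at = lambda c, s, e: "A" * (e - s)
    assert regions.promoter_window(g, ref_at).intervals == []


def test_promoter_gc_threshold_is_strict():
    t = tx([(1000, 1500), (2000, 2500)], cds=(1100, 2400))
    g = gene([t])

    def ref_fraction(frac):
        def ref(c, s, e):
            n = e - s
            k = round(frac * n)
            return "G" * k + "A" * (n - k)
        return ref

    assert regions.promoter_window(g, ref_fraction(0.28)).intervals == []
    assert regions.promoter_window(g, ref_fraction(0.30)).intervals == []  # strict >
    assert regions.promoter_window(g, ref_fraction(0.32)).intervals != []


def test_promoter_clipped_at_chromosome_start():
    t = tx([(100, 400), (600, 900)], cds=(150, 800))
    w = regions.promoter_window(gene([t]), lambda c, s, e: "G" * (e - s))
    assert w.intervals == [(0, 601)]


# -- excision windows ----------------------------------------------------------

def make_gene(span, symbol="G", strand="+", chrom="chr1", coding=True):
    t = tx([span], strand=strand, cds=(span[0] + 10, span[1] - 10) if coding else None,
           biotype="protein_coding" if coding else "lncRNA", tid=symbol + "-t")
    return GeneModel(symbol, chrom, strand, [t], valid_transcripts=[t])


def test_excision_window_no_neighbors_full_flanks():
    g = make_gene((100_000, 120_000))
    w = regions.excision_window(g, [])
    assert w.intervals == [(50_000, 170_000)]


def test_excision_flank_truncated_at_protein_coding_neighbor():
    g = make_gene((100_000, 120_000))
    nb = make_gene((30_000, 60_000), symbol="N")
    assert regions.excision_window(g, [nb]).intervals == [(60_000, 170_000)]
    # non-coding neighbours do not truncate
    nc = make_gene((30_000, 60_000), symbol="L", coding=False)
    assert regions.excision_window(g, [nc]).intervals == [(50_000, 170_000)]


def test_excision_flank_zeroed_by_overlapping_neighbor():
    g = make_gene((100_000, 120_000))
    nb = make_gene((90_000, 105_000), symbol="N")
    assert regions.excision_window(g, [nb]).intervals == [(100_000, 170_000)]


def test_excision_window_clipped_at_chromosome_bounds():
    g = make_gene((10_000, 20_000))
    w = regions.excision_window(g, [], chrom_length=40_000)
    assert w.intervals == [(0, 40_000)]
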