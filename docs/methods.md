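# Methods

## Model and assumptions

The pipeline asks, for each candidate disease gene: which common
heterozygous variants allow allele-specific inactivation of one gene copy,
for how many people, and with how few reagents?

The core assumptions are:

- **Haplosufficiency.** Candidate genes are curated so that losing one copy
  is tolerated (no sufficient/emerging haploinsufficiency evidence; for the
  stricter Group 2, s_het < 0.1). Inactivating the haplotype that carries
  the disease mutation is then therapeutic rather than harmful.
- **Random phase of disease alleles.** Disease mutations are assumed to
  occur on either haplotype with equal probability, so cohort haplotypes
  (2 per individual) are the unit of coverage: a therapy that targets a
  specific common-variant allele helps the patients whose disease mutation
  happens to lie in cis with that allele.
- **Whole-gene inactivation.** An edit only counts if it disables *every*
  retained transcript, hence all windows are intersections across the
  valid-transcript set ("ubiquitous regions").
- **Allele discrimination by seed/PAM.** A single mismatch in the 10-nt
  PAM-proximal seed, or a PAM completed by only one allele, is taken as
  sufficient for SpCas9 allele specificity. No efficiency or off-target
  scoring is attempted; the contract is positional.

## Strategy window rules

All coordinates are 0-based half-open internally; GTF/VCF are converted at
the I/O boundary.

- **Exon disruption.** A cut-site indel is modelled as a premature
  termination codon at the variant's own spliced position. NMD is assumed
  when the transcript has ≥ 2 exons, the position is not in the final exon,
  and it lies more than `nmd_junction_margin` (default 50) spliced nt
  upstream of the final exon–exon junction. Each component is independently
  switchable; a start-proximal escape margin (`nmd_start_margin`) is
  available but off by default, since the canonical last-junction rule is
  the dominant determinant and the start-proximal escape is reported with
  varying cutoffs. Gene windows are the intersection over valid transcripts,
  further intersected with the shared exon set. A gene with any non-coding
  valid transcript gets no exon-disruption window (no position frameshifts
  every isoform).
- **Splice disruption.** Offsets are counted from the first base beyond the
  exon/intron boundary (offset 1), in the transcription direction.
  Acceptors: offsets 4–21 on *both* the intronic and exonic side; donors:
  offsets 3–21 intronic only (the asymmetry follows base-editor access to
  the GT donor on the complementary strand). A position qualifies for the
  gene only if it falls in at least one splice window of every valid
  transcript.
- **Epigenetic silencing.** Per-transcript promoter = TSS ± 500 bp
  (inclusive, clipped at chromosome bounds). The gate is the *unweighted
  mean* of per-transcript promoter GC fractions, strictly > 0.30; passing
  genes contribute the intersection of per-transcript promoters.
- **Excision.** Search region = gene span ± 50 kb. Each flank is
  independently truncated to the nearest edge of any overlapping
  protein-coding neighbour (largest remaining window); a neighbour
  overlapping the gene itself collapses that flank. A variant pair
  qualifies when the closed span between the variants fully contains at
  least one whole exon of *every* valid transcript — the strict reading
  that guarantees every isoform loses an exon. All four allele
  configurations of a qualifying pair are emitted; phasing decides which
  configurations exist on actual haplotypes.

## Filters

- Variants: biallelic SNVs only, phased genotypes required, minor allele
  frequency ≥ 0.1 (inclusive). AF comes from INFO/AF, else is recomputed
  from genotypes. Missing genotypes exclude a sample at that variant only.
- Transcripts: biotypes {protein_coding, nonsense_mediated_decay,
  non_stop_decay, lncRNA, miRNA}; mean expression share ≥ 5% across tissues
  where the gene is expressed. The share denominator is the sum over all of
  the gene's transcripts present in the expression table; transcripts absent
  from the table are dropped. If a gene has no expressed tissue at all,
  in-table biotype-passing transcripts are kept (zero coverage is no
  evidence against a particular isoform). A tissue blocklist (for cultured
  cell lines and similar) is supported and empty by default.
- s_het: strictly below 0.1 for Group 2; genes without an estimate are
  excluded from Group 2 and reported in a side list, since membership could
  not be defended either way.

## Greedy prioritization

Single-guide strategies use the classic greedy maximum-coverage heuristic:
each step selects the allele covering the most not-yet-covered haplotypes
of heterozygous carriers, stopping at zero marginal gain. Ties break on
larger coverage first, then genomic position and allele, so the selection
is deterministic and input-order independent. For this variant the marginal
gains are non-increasing (the classic set-cover property, asserted on every
run in the tests).

Excision therapies need two guides, so candidate moves are scored **per
allele**: a brand-new pair costs 2 (gain halved), a pair reusing one
previously selected allele costs 1, and a pair whose two alleles are both
already selected is a free recombination of existing reagents, taken
whenever it gains coverage. The first step is always a full pair. Note a
consequence: the *raw* gain sequence need not be monotone — a cost-1
extension gaining 3 haplotypes legitimately precedes a cost-2 pair gaining
5 — so concavity is not asserted for excision runs. Alleles are reusable
across realized pairs (a gRNA is a reagent, not a consumable).

## Cohort metrics

- **Permissive treatable**: individuals heterozygous at ≥ 1 targetable
  variant (or double-heterozygous at ≥ 1 valid pair) of any strategy,
  PAM-agnostic. PAM availability gates only guide design and
  prioritization, mirroring the scoping of the PAM filter to reagent-level
  analyses.
- **Strict(k) treatable**: individuals whose both haplotypes are covered by
  the first k (default 4) therapies of one strategy's prioritization.
- **Patient-yield ratio**: strict(k) count divided by the mutation-specific
  baseline `cohort_n · min(k / n_mut, 1)` — k therapies each treating a
  1/n_mut share of patients under the equal-share assumption, capped at the
  cohort. On the haplotype axis the single-therapy baseline is
  `100 · 2 / n_mut` percent (treated individuals × 2 haplotypes referenced
  against individual counts); a strict haplotype-fraction alternative
  (`100 / n_mut`) sits behind `strict_haplotypes=True`. Strategies with no
  therapies contribute a ratio of 0 and still count toward the per-gene
  mean.

## Enrichment test

Terms are admitted when their patient frequency is ≥ 0.8, their categorical
code is Obligate/VeryFrequent, or no frequency is annotated. The null draws
`n_perm` (default 100) random sets of `set_size` (default 200) genes from
the catalog without replacement; per term, the effect is the observed minus
the null-mean percentage (percentage points; a ratio column is also
emitted), and the one-sided p-value is `(1 + #{null ≥ obs}) / (1 + n_perm)`
— minimum attainable 1/101 at the defaults. Benjamini–Hochberg correction
(statsmodels) is applied within each tested gene group. Mapping low-level
terms to organ-system categories is a plain two-column input; no ontology
traversal is performed.

## Synthetic data

The generator emulates the consumed slices of the real resources: a random
A/C/G/T reference with planted PAM motifs and variant reference bases;
Hardy–Weinberg phased genotypes (haplotypes independent Bernoulli(AF) per
site, sites independent unless a cis-block copies one site's haplotype
pattern across a block); GTF gene models with multi-isoform structure; and
clinical tables with controllable inheritance/dosage/s_het/mutation-count/
phenotype distributions. Everything is a pure function of the config
(seeded, named substreams per stage), and a JSON manifest records every
planted fact: group memberships, valid transcripts, dominant-mutation
counts, the per-gene × strategy targetability plan, expected treatable
counts, and the planted enrichment.

The default study uses 5 genes on a 1.2 Mb chromosome and 500 individuals:
one gene plants all four strategy contexts (with MAF-filter probes at
AF 0.05 and 0.96), three genes plant single-strategy contexts (one on the
minus strand to exercise strand-aware windows), and one plants an excision
pair next to an AT-rich promoter so the GC gate is exercised end to end.
Planted common variants sit at AF 0.3 (0.4 for the showcase exonic variant),
high enough that empirical frequencies stay within ±0.05 of target at
1,000 haplotypes. The phenotype catalog holds 1,000 genes and 5 terms: one
planted on 100% of the observed set vs 20% of the catalog, four background
terms at ~50% prevalence. These sizes keep the complete run in seconds
while leaving all statistical checks well-powered.

What the generator does **not** emulate — linkage disequilibrium (beyond
explicit cis-blocks), demographic structure and ancestry-stratified
frequencies, indels and multiallelic sites, sequencing/phasing error, and
realistic GC landscapes — bounds what passing tests show: correctness of
the rules, filters, arithmetic and bookkeeping on well-formed input, not
robustness to the messiness of real population resources.

## Numerical choices and degenerate inputs

- Interval arithmetic is exact integer 0-based half-open; no floating
  comparisons enter window membership.
- Frequency thresholds compare floats parsed from text directly; the VCF
  writer emits 6-decimal AF so threshold probes are placed ≥ 5σ from the
  MAF boundary rather than at it.
- Zero valid transcripts drops a gene (logged); an all-homozygous panel
  yields empty coverage and an empty prioritization; `n_mut = 0` makes the
  mutation-specific baseline undefined and raises.
- Guides touching reference N bases are rejected; a reference window that
  cannot cover spacer+PAM around a variant raises rather than silently
  truncating.

## Known limitations

- Allele specificity is positional only; no cutting-efficiency, chromatin
  or off-target models.
- Excision pair validity ignores regulatory elements other than
  protein-coding neighbour gene spans.
- The equal-share mutation-specific baseline ignores founder effects and
  mutation-frequency skew; ratios for genes with strong founder alleles
  will overstate the agnostic advantage.
- Phenotype enrichment treats terms independently; ontology structure and
  term correlation are not modelled.
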