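"""Synthetic inputs with planted, known ground truth.

The generator emulates the public resources the analysis consumes — a
reference genome (FASTA), gene models (GTF), a phased population panel
(VCF), and clinical annotation tables (gene/mode-of-inheritance/dosage,
pathogenic mutations, s_het, transcript expression, phenotype terms) —
and records a manifest of every planted fact so each downstream stage can
be checked against known truth without any downloads.

Haplotypes are drawn independently per site (Hardy-Weinberg phasing); an
optional cis-block mode copies one site's haplotype pattern across a
block of variants to create perfect in-cis structure for excision tests.
Only biallelic SNVs are simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

FASTA_LINE_WIDTH = 60


@dataclass(frozen=True)
class TranscriptSpec:
    id: str
    biotype: str
    exons: Tuple[Tuple[int, int], ...]  # absolute, 0-based half-open, sorted
    cds: Optional[Tuple[int, int]] = None
    expression_share: float = 0.0  # share of gene TPM, constant across tissues


@dataclass(frozen=True)
class GeneSpec:
    symbol: str
    chrom: str
    strand: str
    transcripts: Tuple[TranscriptSpec, ...]

    @property
    def span(self) -> Tuple[int, int]:
        s = min(t.exons[0][0] for t in self.transcripts)
        e = max(t.exons[-1][1] for t in self.transcripts)
        return (s, e)


@dataclass(frozen=True)
class VariantSpec:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    target_af: float
    id: str = ""
    # planted intent: (gene symbol, strategy) for single-variant strategies,
    # ("<gene>", "excision_left"/"excision_right") for pair members, or None.
    role: Optional[Tuple[str, str]] = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"variant at {self.chrom}:{self.pos}: ref equals alt")


@dataclass
class ClinicalSpec:
    """Row-level clinical tables plus phenotype-catalog parameters."""

    gene_rows: List[Tuple[str, str, str, str]] = field(default_factory=list)
    # (gene, moi, classification, dosage)
    shet: Dict[str, Optional[float]] = field(default_factory=dict)
    mutation_rows: List[Tuple[str, str, str, int, str]] = field(default_factory=list)
    # (gene, mutation id, significance, direct_dominant 0/1, omim_moi ";"-list)
    tissues: Tuple[str, ...] = ("adipose", "brain", "heart", "liver")
    n_catalog_genes: int = 1000
    planted_term: str = "HP:SYS001"
    planted_catalog_fraction: float = 0.20
    background_terms: Tuple[str, ...] = ("HP:SYS002", "HP:SYS003", "HP:SYS004", "HP:SYS005")
    background_catalog_fraction: float = 0.50


@dataclass
class SimulationConfig:
    seed: int = 0
    n_individuals: int = 500
    chrom_lengths: Dict[str, int] = field(default_factory=dict)
    genes: List[GeneSpec] = field(default_factory=list)
    variants: List[VariantSpec] = field(default_factory=list)
    clinical: ClinicalSpec = field(default_factory=ClinicalSpec)
    gc_content: float = 0.5
    # sequence plants: (chrom, pos, sequence) written over the background
    motif_plants: List[Tuple[str, int, str]] = field(default_factory=list)
    # regions re-drawn with a different GC content: (chrom, start, end, gc)
    gc_overrides: List[Tuple[str, int, int, float]] = field(default_factory=list)
    # blocks of variant ids whose haplotype pattern is copied from the first
    cis_blocks: List[Tuple[str, ...]] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for v in self.variants:
            if not (0 <= v.pos < self.chrom_lengths.get(v.chrom, 0)):
                raise ValueError(f"variant {v.id or v.pos} outside {v.chrom}")
        for g in self.genes:
            lo, hi = g.span
            if lo < 0 or hi > self.chrom_lengths.get(g.chrom, 0):
                raise ValueError(f"gene {g.symbol} outside {g.chrom}")


def _stream_rng(seed: int, stream_id: int) -> np.random.Generator:
    # named substream: deterministic and independent per generation stage
    return np.random.default_rng([seed, stream_id])


_STREAMS = {"reference": 11, "panel": 13, "expression": 17, "catalog": 19}


def generate_reference(cfg: SimulationConfig) -> Dict[str, str]:
    """Random A/C/G/T background with planted motifs and variant ref bases.

    Deterministic under the config seed. Conflicting plants (two plants
    demanding different bases at one position) raise a configuration error
    naming the position.
    """
    cfg.validate()
    rng = _stream_rng(cfg.seed, _STREAMS["reference"])
    chroms: Dict[str, np.ndarray] = {}
    bases = np.array(list("ACGT"))
    for name in sorted(cfg.chrom_lengths):
        n = cfg.chrom_lengths[name]
        gc = cfg.gc_content
        probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        chroms[name] = rng.choice(bases, size=n, p=probs)
    for chrom, start, end, gc in cfg.gc_overrides:
        probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        chroms[chrom][start:end] = rng.choice(bases, size=end - start, p=probs)

    plants: Dict[Tuple[str, int], str] = {}

    def plant(chrom: str, pos: int, base: str) -> None:
        key = (chrom, pos)
        if key in plants and plants[key] != base:
            raise ValueError(
                f"conflicting plants at {chrom}:{pos}: {plants[key]!r} vs {base!r}")
        plants[key] = base

    for chrom, pos, seq in cfg.motif_plants:
        for i, b in enumerate(seq):
            plant(chrom, pos + i, b)
    for v in cfg.variants:
        plant(v.chrom, v.pos, v.ref)
    for (chrom, pos), base in plants.items():
        if pos >= cfg.chrom_lengths[chrom]:
            raise ValueError(f"plant at {chrom}:{pos} outside chromosome")
        chroms[chrom][pos] = base
    return {name: "".join(arr) for name, arr in chroms.items()}


def write_fasta(reference: Dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(reference):
            fh.write(f">{name}\n")
            seq = reference[name]
            for i in range(0, len(seq), FASTA_LINE_WIDTH):
                fh.write(seq[i:i + FASTA_LINE_WIDTH] + "\n")


def generate_panel(cfg: SimulationConfig) -> Tuple[List[str], np.ndarray]:
    """Phased genotypes: (samples, int8 array (n_variants, n_samples, 2)).

    Each haplotype carries the alternate allele independently with
    probability ``target_af`` (Hardy-Weinberg). Variants in a cis block
    copy the haplotype pattern of the block's first variant.
    """
    cfg.validate()
    rng = _stream_rng(cfg.seed, _STREAMS["panel"])
    n = cfg.n_individuals
    samples = [f"S{i + 1:04d}" for i in range(n)]
    gt = np.zeros((len(cfg.variants), n, 2), dtype=np.int8)
    by_id = {v.id: i for i, v in enumerate(cfg.variants) if v.id}
    block_of: Dict[int, Tuple[int, ...]] = {}
    for block in cfg.cis_blocks:
        idxs = tuple(by_id[vid] for vid in block)
        for i in idxs[1:]:
            block_of[i] = idxs
    for i, v in enumerate(cfg.variants):
        if i in block_of:
            gt[i] = gt[block_of[i][0]]
        else:
            gt[i] = (rng.random((n, 2)) < v.target_af).astype(np.int8)
    return samples, gt


def write_vcf(cfg: SimulationConfig, samples: Sequence[str], gt: np.ndarray,
              path: Path) -> None:
    """Minimal phased VCFv4.2 with empirical INFO/AF and GT only."""
    idx = sorted(range(len(cfg.variants)), key=lambda i: (cfg.variants[i].chrom,
                                                          cfg.variants[i].pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in sorted(cfg.chrom_lengths):
            fh.write(f"##contig=<ID={name},length={cfg.chrom_lengths[name]}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i in idx:
            v = cfg.variants[i]
            af = float(gt[i].mean())
            cols = [v.chrom, str(v.pos + 1), v.id or ".", v.ref, v.alt, ".", "PASS",
                    f"AF={af:.6f}", "GT"]
            cols += [f"{a}|{b}" for a, b in gt[i]]
            fh.write("\t".join(cols) + "\n")


def write_gtf(cfg: SimulationConfig, path: Path) -> None:
    """GTF2.2 gene/transcript/exon/CDS features, 1-based inclusive."""
    with open(path, "w") as fh:
        for g in cfg.genes:
            lo, hi = g.span
            attrs = f'gene_id "{g.symbol}"; gene_name "{g.symbol}"; gene_biotype "protein_coding";'
            fh.write("\t".join([g.chrom, "sim", "gene", str(lo + 1), str(hi),
                                ".", g.strand, ".", attrs]) + "\n")
            for t in g.transcripts:
                tlo, thi = t.exons[0][0], t.exons[-1][1]
                tattrs = (f'gene_id "{g.symbol}"; transcript_id "{t.id}"; '
                          f'gene_name "{g.symbol}"; transcript_biotype "{t.biotype}";')
                fh.write("\t".join([g.chrom, "sim", "transcript", str(tlo + 1),
                                    str(thi), ".", g.strand, ".", tattrs]) + "\n")
                for s, e in t.exons:
                    fh.write("\t".join([g.chrom, "sim", "exon", str(s + 1), str(e),
                                        ".", g.strand, ".", tattrs]) + "\n")
                if t.cds is not None:
                    cs, ce = t.cds
                    for s, e in t.exons:
                        os_, oe = max(s, cs), min(e, ce)
                        if oe > os_:
                            fh.write("\t".join([g.chrom, "sim", "CDS", str(os_ + 1),
                                                str(oe), ".", g.strand, "0", tattrs]) + "\n")


def generate_expression(cfg: SimulationConfig) -> "pd.DataFrame":
    """Transcript x tissue TPM matrix realizing the configured shares.

    Gene totals vary log-normally across tissues; within a gene each
    transcript's share is held constant so the mean share across tissues
    equals its configured value exactly.
    """
    import pandas as pd

    rng = _stream_rng(cfg.seed, _STREAMS["expression"])
    tissues = list(cfg.clinical.tissues)
    rows = {}
    for g in cfg.genes:
        totals = rng.lognormal(mean=3.0, sigma=0.5, size=len(tissues))
        for t in g.transcripts:
            rows[t.id] = totals * t.expression_share
    return pd.DataFrame.from_dict(rows, orient="index", columns=tissues).sort_index()


def generate_clinical_tables(cfg: SimulationConfig, out_dir: Path) -> Dict[str, Path]:
    """Write all delimited clinical tables; returns name -> path."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    clin = pd.DataFrame(cfg.clinical.gene_rows,
                        columns=["gene", "moi", "classification", "dosage"])
    paths["clinical_genes"] = out_dir / "clinical_genes.tsv"
    clin.to_csv(paths["clinical_genes"], sep="\t", index=False)

    shet = pd.DataFrame(
        [(g, "" if v is None else v) for g, v in sorted(cfg.clinical.shet.items())],
        columns=["gene", "s_het"])
    paths["shet"] = out_dir / "shet.tsv"
    shet.to_csv(paths["shet"], sep="\t", index=False)

    mut = pd.DataFrame(cfg.clinical.mutation_rows,
                       columns=["gene", "id", "significance", "direct_dominant", "omim_moi"])
    paths["mutations"] = out_dir / "mutations.tsv"
    mut.to_csv(paths["mutations"], sep="\t", index=False)

    expr = generate_expression(cfg)
    paths["expression"] = out_dir / "expression.tsv"
    expr.to_csv(paths["expression"], sep="\t", index_label="transcript_id")

    pheno_rows, catalog = _phenotype_tables(cfg)
    paths["phenotypes"] = out_dir / "phenotype_annotations.tsv"
    pd.DataFrame(pheno_rows, columns=["gene", "term", "frequency"]).to_csv(
        paths["phenotypes"], sep="\t", index=False)
    paths["catalog"] = out_dir / "catalog_genes.txt"
    with open(paths["catalog"], "w") as fh:
        fh.write("\n".join(catalog) + "\n")
    return paths


def _group_sets(cfg: SimulationConfig) -> Tuple[List[str], List[str], List[str]]:
    """Ground-truth Group 1 / Group 2 / missing-s_het from the clinical spec,
    derived by re-stating the selection rules on the planted rows."""
    by_gene: Dict[str, List[Tuple[str, str, str]]] = {}
    dosage: Dict[str, str] = {}
    for gene, moi, cls, dos in cfg.clinical.gene_rows:
        by_gene.setdefault(gene, []).append((moi, cls, dos))
        dosage[gene] = dos
    group1 = []
    for gene, entries in sorted(by_gene.items()):
        modes = {m for m, _, _ in entries}
        if "XL" in modes:
            continue
        if not any(m in ("AD", "SD") and c in ("Moderate", "Strong", "Definitive")
                   for m, c, _ in entries):
            continue
        if dosage[gene] in ("sufficient_evidence_HI", "emerging_evidence_HI"):
            continue
        group1.append(gene)
    group2, missing = [], []
    for gene in group1:
        v = cfg.clinical.shet.get(gene)
        if v is None:
            missing.append(gene)
        elif v < 0.1:
            group2.append(gene)
    return group1, group2, missing


def _phenotype_tables(cfg: SimulationConfig) -> Tuple[List[Tuple], List[str]]:
    """Observed-set and catalog phenotype annotations with a planted term."""
    rng = _stream_rng(cfg.seed, _STREAMS["catalog"])
    spec = cfg.clinical
    group1, _, _ = _group_sets(cfg)
    catalog = [f"CAT{i + 1:04d}" for i in range(spec.n_catalog_genes)]
    rows: List[Tuple] = []
    # planted term: on every observed (Group 1) gene at admissible frequency
    for i, gene in enumerate(group1):
        freq = ["0.9", "Obligate", "VeryFrequent", ""][i % 4]
        rows.append((gene, spec.planted_term, freq))
    n_planted = int(round(spec.planted_catalog_fraction * len(catalog)))
    planted_idx = rng.choice(len(catalog), size=n_planted, replace=False)
    for i in sorted(planted_idx):
        rows.append((catalog[i], spec.planted_term, "0.85"))
    # background terms: ~half the catalog, half the observed set
    for term in spec.background_terms:
        n_bg = int(round(spec.background_catalog_fraction * len(catalog)))
        bg_idx = rng.choice(len(catalog), size=n_bg, replace=False)
        for i in sorted(bg_idx):
            rows.append((catalog[i], term, "0.95"))
        for gene in group1[: len(group1) // 2]:
            rows.append((gene, term, "0.9"))
        # sub-threshold rows exercise the admission filter downstream
        for gene in group1[len(group1) // 2:]:
            rows.append((gene, term, "0.5"))
    return rows, catalog


# ---------------------------------------------------------------------------
# ground truth manifest


def _planted_targetability(cfg: SimulationConfig) -> Dict[str, Dict[str, list]]:
    """Expected per-gene, per-strategy targetable variants and excision pairs.

    Single-variant strategies come from planted roles; excision pairs are
    re-derived from first principles: both variants inside the flank
    window and the closed span containing a whole exon of every
    expression-valid transcript.
    """
    out: Dict[str, Dict[str, list]] = {}
    common = [v for v in cfg.variants if min(v.target_af, 1 - v.target_af) >= 0.1]
    for g in cfg.genes:
        entry: Dict[str, list] = {
            "exon_disruption": [], "splice_disruption": [],
            "epigenetic_silencing": [], "excision": [],
        }
        for v in common:
            if v.role and v.role[0] == g.symbol and v.role[1] in entry:
                entry[v.role[1]].append(v.id)
        lo, hi = g.span
        win_lo, win_hi = lo - 50_000, hi + 50_000
        valid_tx = [t for t in g.transcripts
                    if t.biotype in ("protein_coding", "nonsense_mediated_decay",
                                     "non_stop_decay", "lncRNA", "miRNA")
                    and t.expression_share >= 0.05]
        in_win = sorted((v for v in common
                         if v.chrom == g.chrom and win_lo <= v.pos < win_hi),
                        key=lambda v: v.pos)
        for i, v1 in enumerate(in_win):
            for v2 in in_win[i + 1:]:
                ok = all(
                    any(v1.pos <= s and e <= v2.pos + 1 for s, e in t.exons)
                    for t in valid_tx
                )
                if ok:
                    entry["excision"].append([v1.id, v2.id])
        out[g.symbol] = entry
    return out


def _planted_treatable(cfg: SimulationConfig, gt: np.ndarray,
                       targetability: Dict[str, Dict[str, list]]) -> Dict[str, int]:
    """Expected permissive treatable-individual counts from raw genotypes."""
    by_id = {v.id: i for i, v in enumerate(cfg.variants)}
    out: Dict[str, int] = {}
    for gene, entry in targetability.items():
        treatable = np.zeros(cfg.n_individuals, dtype=bool)
        for strategy in ("exon_disruption", "splice_disruption", "epigenetic_silencing"):
            for vid in entry[strategy]:
                g = gt[by_id[vid]]
                treatable |= g[:, 0] != g[:, 1]
        for left, right in entry["excision"]:
            gl, gr = gt[by_id[left]], gt[by_id[right]]
            treatable |= (gl[:, 0] != gl[:, 1]) & (gr[:, 0] != gr[:, 1])
        out[gene] = int(treatable.sum())
    return out


@dataclass
class SyntheticBundle:
    config: SimulationConfig
    paths: Dict[str, Path]
    manifest: Dict


def generate_all(cfg: SimulationConfig, out_dir: Path) -> SyntheticBundle:
    """Write every synthetic input plus the ground-truth manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reference = generate_reference(cfg)
    paths: Dict[str, Path] = {}
    paths["fasta"] = out_dir / "reference.fa"
    write_fasta(reference, paths["fasta"])
    fai = Path(str(paths["fasta"]) + ".fai")
    if fai.exists():
        fai.unlink()  # stale index from a previous run would shadow new content

    samples, gt = generate_panel(cfg)
    paths["vcf"] = out_dir / "panel.vcf"
    write_vcf(cfg, samples, gt, paths["vcf"])
    paths["gtf"] = out_dir / "genes.gtf"
    write_gtf(cfg, paths["gtf"])
    paths.update(generate_clinical_tables(cfg, out_dir))

    group1, group2, missing = _group_sets(cfg)
    targetability = _planted_targetability(cfg)
    valid_tx = {
        g.symbol: sorted(t.id for t in g.transcripts
                         if t.biotype in ("protein_coding", "nonsense_mediated_decay",
                                          "non_stop_decay", "lncRNA", "miRNA")
                         and t.expression_share >= 0.05)
        for g in cfg.genes
    }
    dominant_counts: Dict[str, int] = {}
    for gene, _, sig, direct, moi in cfg.clinical.mutation_rows:
        if sig in ("pathogenic", "likely_pathogenic") and (
                int(direct) or "AD" in str(moi).split(";")):
            dominant_counts[gene] = dominant_counts.get(gene, 0) + 1

    manifest = {
        "seed": cfg.seed,
        "n_individuals": cfg.n_individuals,
        "chrom_lengths": cfg.chrom_lengths,
        "group1": sorted(group1),
        "group2": sorted(group2),
        "shet_missing": sorted(missing),
        "valid_transcripts": valid_tx,
        "dominant_mutation_counts": dominant_counts,
        "variants": {
            v.id: {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                   "target_af": v.target_af,
                   "expect_common": min(v.target_af, 1 - v.target_af) >= 0.1}
            for v in cfg.variants
        },
        "targetability": targetability,
        "treatable_permissive": _planted_treatable(cfg, gt, targetability),
        "enrichment": {
            "planted_term": cfg.clinical.planted_term,
            "observed_fraction": 1.0,
            "catalog_fraction": cfg.clinical.planted_catalog_fraction,
            "n_terms": 1 + len(cfg.clinical.background_terms),
        },
    }
    paths["manifest"] = out_dir / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return SyntheticBundle(cfg, paths, manifest)


# ---------------------------------------------------------------------------
# default study conditions: 5 genes x 500 individuals with one planted
# context per strategy, one low-GC promoter, and MAF-filter probes.


def _gene_spec(symbol: str, chrom: str, g: int, strand: str,
               extra_transcripts: Sequence[TranscriptSpec] = ()) -> GeneSpec:
    exons = ((g, g + 1200), (g + 3000, g + 3400), (g + 6000, g + 6500))
    cds = (g + 100, g + 6200)
    t1_share = 1.0 - 0.40 - sum(t.expression_share for t in extra_transcripts)
    main = (
        TranscriptSpec(f"{symbol}-T1", "protein_coding", exons, cds, t1_share),
        TranscriptSpec(f"{symbol}-T2", "protein_coding", exons, cds, 0.40),
    )
    return GeneSpec(symbol, chrom, strand, main + tuple(extra_transcripts))


def default_config(seed: int = 0, n_individuals: int = 500) -> SimulationConfig:
    """The default synthetic study: 5 genes on one 1.2 Mb chromosome."""
    chrom = "chr1"
    starts = {"SYNG1": 100_000, "SYNG2": 320_000, "SYNG3": 540_000,
              "SYNG4": 760_000, "SYNG5": 980_000}
    strands = {"SYNG1": "+", "SYNG2": "+", "SYNG3": "+", "SYNG4": "-", "SYNG5": "+"}

    g1 = starts["SYNG1"]
    syng1_extra = (
        # low-expression isoform with a short first exon: if retained, the
        # exonic plant would fall outside its exons
        TranscriptSpec("SYNG1-T3", "protein_coding",
                       ((g1, g1 + 600), (g1 + 3000, g1 + 3400), (g1 + 6000, g1 + 6500)),
                       (g1 + 100, g1 + 6200), 0.03),
        TranscriptSpec("SYNG1-T4", "processed_pseudogene",
                       ((g1, g1 + 1200), (g1 + 3000, g1 + 3400), (g1 + 6000, g1 + 6500)),
                       None, 0.0),
    )
    genes = [
        _gene_spec("SYNG1", chrom, starts["SYNG1"], "+", syng1_extra),
        _gene_spec("SYNG2", chrom, starts["SYNG2"], "+"),
        _gene_spec("SYNG3", chrom, starts["SYNG3"], "+"),
        _gene_spec("SYNG4", chrom, starts["SYNG4"], "-"),
        _gene_spec("SYNG5", chrom, starts["SYNG5"], "+"),
    ]

    variants: List[VariantSpec] = []
    motif_plants: List[Tuple[str, int, str]] = []

    def add_variant(vid: str, pos: int, af: float, role, ref="A", alt="G"):
        variants.append(VariantSpec(chrom, pos, ref, alt, af, vid, role))
        # NGG PAM three bases downstream on the plus strand: variant sits at
        # seed offset 3 for both alleles
        motif_plants.append((chrom, pos + 4, "GG"))

    # SYNG1: all four strategies, plus MAF-filter probes
    add_variant("var_SYNG1_exon", g1 + 800, 0.40, ("SYNG1", "exon_disruption"))
    add_variant("var_SYNG1_acceptor", g1 + 2990, 0.30, ("SYNG1", "splice_disruption"))
    add_variant("var_SYNG1_promoter", g1 - 200, 0.30, ("SYNG1", "epigenetic_silencing"))
    add_variant("var_SYNG1_exL", g1 - 40_000, 0.30, ("SYNG1", "excision_left"))
    add_variant("var_SYNG1_exR", g1 + 2000, 0.30, ("SYNG1", "excision_right"))
    add_variant("var_SYNG1_lowmaf", g1 + 850, 0.05, None)
    add_variant("var_SYNG1_highaf", g1 + 900, 0.96, None)

    g2 = starts["SYNG2"]
    add_variant("var_SYNG2_exon", g2 + 800, 0.30, ("SYNG2", "exon_disruption"))

    g3 = starts["SYNG3"]
    add_variant("var_SYNG3_promoter", g3 - 200, 0.30, ("SYNG3", "epigenetic_silencing"))
    add_variant("var_SYNG3_exL", g3 - 40_000, 0.30, ("SYNG3", "excision_left"))
    add_variant("var_SYNG3_exR", g3 + 2000, 0.30, ("SYNG3", "excision_right"))

    g4 = starts["SYNG4"]
    # minus-strand acceptor of the middle exon: intronic side lies at
    # higher genomic coordinates than the exon end
    add_variant("var_SYNG4_acceptor", g4 + 3400 + 9, 0.30, ("SYNG4", "splice_disruption"))

    g5 = starts["SYNG5"]
    add_variant("var_SYNG5_promoter", g5 - 200, 0.30, None, ref="A", alt="T")
    add_variant("var_SYNG5_exL", g5 - 40_000, 0.30, ("SYNG5", "excision_left"))
    add_variant("var_SYNG5_exR", g5 + 2000, 0.30, ("SYNG5", "excision_right"))

    clinical = ClinicalSpec(
        gene_rows=[
            ("SYNG1", "AD", "Definitive", "no_evidence"),
            ("SYNG1", "AR", "Strong", "no_evidence"),
            ("SYNG2", "AD", "Strong", "little_evidence_HI"),
            ("SYNG3", "AD", "Moderate", "missing"),
            ("SYNG4", "SD", "Definitive", "no_evidence"),
            ("SYNG5", "AD", "Definitive", "missing"),
            ("SEMI1", "SD", "Moderate", "no_evidence"),
            ("XLIN1", "AD", "Definitive", "no_evidence"),
            ("XLIN1", "XL", "Definitive", "no_evidence"),
            ("RECES1", "AR", "Strong", "no_evidence"),
            ("HAPLO1", "AD", "Definitive", "sufficient_evidence_HI"),
            ("EMERG1", "SD", "Strong", "emerging_evidence_HI"),
            ("WEAK1", "AD", "Limited", "no_evidence"),
        ],
        shet={
            "SYNG1": 0.019, "SYNG2": 0.5, "SYNG3": None, "SYNG4": 0.05,
            "SYNG5": 0.09, "SEMI1": 0.25, "XLIN1": 0.01, "RECES1": 0.02,
            "HAPLO1": 0.3, "EMERG1": 0.2, "WEAK1": 0.04,
        },
        mutation_rows=_default_mutations(),
    )

    cfg = SimulationConfig(
        seed=seed,
        n_individuals=n_individuals,
        chrom_lengths={chrom: 1_200_000},
        genes=genes,
        variants=variants,
        clinical=clinical,
        motif_plants=motif_plants,
        gc_overrides=[(chrom, g5 - 520, g5 + 510, 0.0)],  # AT-rich SYNG5 promoter
    )
    cfg.validate()
    return cfg


def _default_mutations() -> List[Tuple[str, str, str, int, str]]:
    rows: List[Tuple[str, str, str, int, str]] = []

    def bulk(gene: str, n_dominant: int, n_recessive: int = 2, n_other: int = 1):
        for i in range(n_dominant):
            # alternate between direct dominant flags and OMIM-derived modes
            if i % 2 == 0:
                rows.append((gene, f"{gene}_m{i + 1}", "pathogenic", 1, ""))
            else:
                sig = "likely_pathogenic" if i % 4 == 1 else "pathogenic"
                rows.append((gene, f"{gene}_m{i + 1}", sig, 0, "AR;AD"))
        for i in range(n_recessive):
            rows.append((gene, f"{gene}_r{i + 1}", "pathogenic", 0, "AR"))
        for i in range(n_other):
            rows.append((gene, f"{gene}_o{i + 1}", "other", 1, "AD"))

    bulk("SYNG1", 149)  # the many-mutation cardiomyopathy-like scenario
    bulk("SYNG2", 4)    # few mutations: mutation-agnostic gain is limited
    bulk("SYNG3", 8)
    bulk("SYNG4", 20)
    bulk("SYNG5", 40)
    bulk("SEMI1", 1)
    return rows
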