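"""End-to-end pipeline driver.

Stages: simulate? -> curate -> transcript filter -> strategy windows ->
common variants -> targets/pairs -> guide (PAM) filter -> greedy
prioritization -> cohort metrics -> phenotype enrichment -> BED tracks.
Every stage's tabular outputs land under ``out_dir``; the run manifest
records per-stage record counts so reruns can be compared byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import curation, enrichment, guides, io, metrics, prioritize, regions
from . import simulate as sim
from . import variant_targets as vt
from .models import (
    CommonVariant,
    ExcisionPair,
    GeneModel,
    PhasedPanel,
    PrioritizationResult,
    StrategyWindowSet,
    TargetableAllele,
    Therapy,
)

logger = logging.getLogger(__name__)

SINGLE_STRATEGIES = vt.SINGLE_VARIANT_STRATEGIES


@dataclass
class PipelineResult:
    config: io.PipelineConfig
    group1: Set[str] = field(default_factory=set)
    group2: Set[str] = field(default_factory=set)
    shet_missing: List[str] = field(default_factory=list)
    genes: Dict[str, GeneModel] = field(default_factory=dict)
    dropped_genes: List[str] = field(default_factory=list)
    windows: Dict[str, Dict[str, StrategyWindowSet]] = field(default_factory=dict)
    variants: List[CommonVariant] = field(default_factory=list)
    panel: Optional[PhasedPanel] = None
    targets: List[TargetableAllele] = field(default_factory=list)
    pairs: Dict[str, List[ExcisionPair]] = field(default_factory=dict)
    pam_targets: Dict[str, list] = field(default_factory=dict)  # gene -> [(target, guides)]
    pam_pairs: Dict[str, list] = field(default_factory=dict)    # gene -> [(pair, (gl, gr))]
    prioritizations: Dict[str, Dict[str, PrioritizationResult]] = field(default_factory=dict)
    gene_metrics: Dict[str, metrics.GeneMetrics] = field(default_factory=dict)
    yield_ratios: Dict[str, metrics.YieldRatio] = field(default_factory=dict)
    mutation_counts: Dict[str, int] = field(default_factory=dict)
    enrichment_results: List[enrichment.EnrichmentResult] = field(default_factory=list)
    synthetic_manifest: Optional[dict] = None

    def targetability_matrix(self) -> Dict[str, Dict[str, bool]]:
        """gene -> strategy -> has at least one targetable variant/pair."""
        out: Dict[str, Dict[str, bool]] = {}
        for gene in self.genes:
            row = {s: False for s in SINGLE_STRATEGIES}
            row["excision"] = bool(self.pairs.get(gene))
            out[gene] = row
        for t in self.targets:
            if t.gene in out:
                out[t.gene][t.strategy] = True
        return out


def run_pipeline(cfg: io.PipelineConfig) -> PipelineResult:
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(config=cfg)
    counts: Dict[str, int] = {}

    # -- stage 0: synthetic inputs -------------------------------------------
    if cfg.simulate is not None:
        sim_cfg = sim.default_config(
            seed=cfg.simulate.get("seed", cfg.seed),
            n_individuals=cfg.simulate.get("n_individuals", 500),
        )
        bundle = sim.generate_all(sim_cfg, out_dir / "synthetic")
        result.synthetic_manifest = bundle.manifest
        cfg = _with_synthetic_paths(cfg, bundle.paths)
        logger.info("simulate: %d genes, %d variants, %d individuals",
                    len(sim_cfg.genes), len(sim_cfg.variants), sim_cfg.n_individuals)

    reference = io.ReferenceGenome(cfg.fasta)
    gene_models = io.read_gtf(cfg.gtf)
    counts["gtf_genes"] = len(gene_models)

    # -- stage 1: curation ----------------------------------------------------
    clinical = io.read_clinical_genes(cfg.clinical_genes)
    result.group1 = curation.select_dnd_group1(clinical)
    shet = io.read_shet(cfg.shet) if cfg.shet else []
    result.group2, result.shet_missing = curation.select_dnd_group2(
        result.group1, shet, cfg.shet_max)
    mutations = io.read_mutations(cfg.mutations) if cfg.mutations else []
    result.mutation_counts = curation.count_dominant_pathogenic(mutations)
    counts["group1"], counts["group2"] = len(result.group1), len(result.group2)

    # -- stage 2: transcript filtering ----------------------------------------
    expression = io.read_expression(cfg.expression) if cfg.expression else pd.DataFrame()
    analyzed = [g for g in gene_models if g.symbol in result.group1]
    for gene in analyzed:
        filtered = curation.filter_transcripts(gene, expression, cfg.expr_share_min)
        if filtered.valid_transcripts:
            result.genes[gene.symbol] = filtered
        else:
            result.dropped_genes.append(gene.symbol)
    counts["analyzed_genes"] = len(result.genes)

    # -- stage 3: strategy windows --------------------------------------------
    for symbol, gene in sorted(result.genes.items()):
        neighbors = [g for g in gene_models if g.symbol != symbol and g.chrom == gene.chrom]
        result.windows[symbol] = regions.strategy_windows(
            gene, reference, neighbors, cfg.rules,
            chrom_length=reference.chrom_length(gene.chrom))

    # -- stage 4: common variants ---------------------------------------------
    result.variants, result.panel = vt.load_common_variants(cfg.vcf, cfg.maf_min)
    counts["common_variants"] = len(result.variants)

    # -- stage 5: strategy targets & excision pairs ---------------------------
    result.targets = vt.assign_strategy_targets(result.variants, result.windows)
    for symbol, gene in sorted(result.genes.items()):
        result.pairs[symbol] = vt.find_excision_pairs(
            result.variants, result.windows[symbol]["excision"], gene)
    counts["targets"] = len(result.targets)
    counts["excision_pairs"] = sum(len(p) for p in result.pairs.values())

    # -- stage 6: guide design / PAM filter -----------------------------------
    for symbol in sorted(result.genes):
        gene_targets = [t for t in result.targets if t.gene == symbol]
        result.pam_targets[symbol] = guides.filter_targets_by_pam(
            gene_targets, reference, cfg.pam)
        result.pam_pairs[symbol] = guides.filter_pairs_by_pam(
            result.pairs[symbol], reference, cfg.pam)
    counts["pam_targets"] = sum(len(v) for v in result.pam_targets.values())

    # -- stage 7: greedy prioritization ---------------------------------------
    for symbol in sorted(result.genes):
        per_strategy: Dict[str, PrioritizationResult] = {}
        for strategy in SINGLE_STRATEGIES:
            targets = [t for t, _ in result.pam_targets[symbol] if t.strategy == strategy]
            per_strategy[strategy] = prioritize.prioritize_single_strategy(
                result.panel, targets)
        per_strategy["excision"] = prioritize.greedy_select_excision(
            result.panel, [p for p, _ in result.pam_pairs[symbol]])
        result.prioritizations[symbol] = per_strategy

    # -- stage 8: cohort metrics ----------------------------------------------
    cohort_n = len(result.panel.samples)
    for symbol in sorted(result.genes):
        gene_targets = [t for t in result.targets if t.gene == symbol]
        permissive = metrics.treatable_individuals_permissive(
            result.panel, gene_targets, result.pairs[symbol])
        gm = metrics.GeneMetrics(symbol, cohort_n)
        gm.permissive_count = len(permissive)
        gm.permissive_fraction = len(permissive) / cohort_n if cohort_n else 0.0
        for strategy, pr in result.prioritizations[symbol].items():
            gm.strict_counts[strategy] = len(
                metrics.treatable_individuals_strict(result.panel, pr, cfg.top_k))
            top, possible = metrics.coverage_summary(pr, cfg.top_k)
            gm.top_k_fraction[strategy] = top
            gm.possible_fraction[strategy] = possible
        gm.strict_union_count = len(metrics.strict_union(
            result.panel, result.prioritizations[symbol], cfg.top_k))
        result.gene_metrics[symbol] = gm
        n_mut = result.mutation_counts.get(symbol, 0)
        if n_mut > 0:
            result.yield_ratios[symbol] = metrics.yield_ratio(
                symbol, result.panel, result.prioritizations[symbol], n_mut, cfg.top_k)

    # -- stage 9: phenotype enrichment ----------------------------------------
    if cfg.phenotypes and cfg.catalog:
        annotations = enrichment.admit_annotations(io.read_phenotypes(cfg.phenotypes))
        catalog = io.read_gene_list(cfg.catalog)
        if result.group1 and len(catalog) >= cfg.perm_set_size:
            result.enrichment_results = enrichment.permutation_enrichment(
                result.group1, catalog, annotations,
                n_perm=cfg.n_perm, set_size=cfg.perm_set_size,
                rng=np.random.default_rng([cfg.seed, 97]))
    counts["enriched_terms"] = len(result.enrichment_results)

    # -- stage 10: outputs -----------------------------------------------------
    _write_outputs(result, out_dir, counts)
    return result


def _with_synthetic_paths(cfg: io.PipelineConfig, paths: Dict[str, Path]) -> io.PipelineConfig:
    from dataclasses import replace

    return replace(
        cfg,
        simulate=None,
        fasta=str(paths["fasta"]), gtf=str(paths["gtf"]), vcf=str(paths["vcf"]),
        clinical_genes=str(paths["clinical_genes"]), shet=str(paths["shet"]),
        mutations=str(paths["mutations"]), expression=str(paths["expression"]),
        phenotypes=str(paths["phenotypes"]), catalog=str(paths["catalog"]),
    )


def _write_outputs(result: PipelineResult, out_dir: Path, counts: Dict[str, int]) -> None:
    cfg = result.config

    gene_rows = []
    for symbol in sorted(set(result.group1) | set(result.genes)):
        gm = result.gene_metrics.get(symbol)
        gene_rows.append({
            "gene": symbol,
            "group1": symbol in result.group1,
            "group2": symbol in result.group2,
            "n_valid_transcripts": len(result.genes[symbol].valid_transcripts)
            if symbol in result.genes else 0,
            "n_dominant_mutations": result.mutation_counts.get(symbol, 0),
            "permissive_treatable": gm.permissive_count if gm else 0,
            "strict_union_treatable": gm.strict_union_count if gm else 0,
        })
    io.write_table(pd.DataFrame(gene_rows), out_dir / "gene_report.tsv")

    guide_rows = []
    for symbol in sorted(result.pam_targets):
        for target, designs in result.pam_targets[symbol]:
            for g in designs:
                guide_rows.append({
                    "gene": symbol, "strategy": target.strategy,
                    "variant_id": target.variant.id, "allele": target.allele,
                    "strand": g.strand, "pam_start": g.pam_start,
                    "spacer": g.spacer, "variant_offset": g.variant_offset,
                })
    io.write_guide_table(guide_rows, out_dir / "guides.tsv")

    pri_rows = []
    for symbol in sorted(result.prioritizations):
        for strategy in sorted(result.prioritizations[symbol]):
            pr = result.prioritizations[symbol][strategy]
            fractions = pr.cumulative_fractions
            counts_cum = pr.cumulative_counts
            for step, therapy in enumerate(pr.therapies):
                pri_rows.append({
                    "gene": symbol, "strategy": strategy, "step": step + 1,
                    "therapy": therapy.describe(),
                    "new_haplotypes": len(pr.new_haplotypes[step]),
                    "cumulative": counts_cum[step],
                    "cumulative_fraction": round(fractions[step], 6),
                })
    io.write_table(pd.DataFrame(pri_rows), out_dir / "prioritization.tsv")

    if result.enrichment_results:
        io.write_table(enrichment.results_frame(result.enrichment_results),
                       out_dir / "enrichment.tsv")

    ratio_rows = [
        {"gene": yr.gene, "n_mut": yr.n_mut, "k": yr.k,
         "specific_people": round(yr.specific_people, 4),
         "mean_ratio": round(yr.mean_ratio, 6),
         **{f"ratio_{s}": round(r, 6) for s, r in sorted(yr.ratios.items())}}
        for _, yr in sorted(result.yield_ratios.items())
    ]
    io.write_table(pd.DataFrame(ratio_rows), out_dir / "yield_ratios.tsv")

    pairs_flat = [p for symbol in sorted(result.pairs) for p in result.pairs[symbol]]
    io.write_bed_tracks(result.targets, pairs_flat, out_dir / "tracks")

    io.write_run_manifest(
        {"counts": counts, "seed": cfg.seed,
         "targetability": {g: row for g, row in sorted(result.targetability_matrix().items())}},
        out_dir / "run_manifest.json")
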