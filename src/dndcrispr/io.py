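"""Standard-format readers/writers and pipeline configuration.

Genomic conventions: GTF and VCF are 1-based inclusive on disk and are
converted to 0-based half-open internally; BED output is 0-based
half-open. Clinical tables are tab-delimited with headers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import gffutils
import pandas as pd
from pyfaidx import Fasta

from .curation import ClinicalGeneRecord, PathogenicMutationRecord, ShetRecord
from .enrichment import PhenotypeAnnotation
from .models import (
    ExcisionPair,
    GeneModel,
    PamConfig,
    RuleConfig,
    TargetableAllele,
    Transcript,
)


# ---------------------------------------------------------------------------
# reference / gene models


class ReferenceGenome:
    """Thin pyfaidx wrapper exposing 0-based half-open slicing."""

    def __init__(self, path: str | Path):
        self._fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def __call__(self, chrom: str, start: int, end: int) -> str:
        start = max(start, 0)
        return str(self._fasta[chrom][start:end])

    def chrom_length(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {name: len(self._fasta[name]) for name in self._fasta.keys()}


def read_gtf(path: str | Path) -> List[GeneModel]:
    """Parse GTF2.2 gene/transcript/exon/CDS features into gene models."""
    db = gffutils.create_db(
        str(path), ":memory:",
        disable_infer_genes=True, disable_infer_transcripts=True,
        keep_order=True,
    )
    genes: List[GeneModel] = []
    for g in db.features_of_type("gene"):
        symbol = g.attributes.get("gene_name", g.attributes["gene_id"])[0]
        transcripts: List[Transcript] = []
        for t in db.children(g, featuretype="transcript"):
            tid = t.attributes["transcript_id"][0]
            biotype = (t.attributes.get("transcript_biotype")
                       or t.attributes.get("transcript_type") or ["unknown"])[0]
            exons = tuple(
                (e.start - 1, e.end)
                for e in db.children(t, featuretype="exon", order_by="start")
            )
            cds_feats = list(db.children(t, featuretype="CDS", order_by="start"))
            cds = None
            if cds_feats:
                cds = (min(c.start - 1 for c in cds_feats), max(c.end for c in cds_feats))
            transcripts.append(Transcript(tid, biotype, exons, g.strand, cds))
        genes.append(GeneModel(symbol, g.seqid, g.strand, transcripts))
    genes.sort(key=lambda g: (g.chrom, g.span[0], g.symbol))
    return genes


# ---------------------------------------------------------------------------
# clinical tables


def read_clinical_genes(path: str | Path) -> List[ClinicalGeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("missing")
    records: Dict[str, ClinicalGeneRecord] = {}
    for row in df.itertuples(index=False):
        rec = records.setdefault(
            row.gene, ClinicalGeneRecord(row.gene, [], row.dosage))
        rec.moi_entries.append((row.moi, row.classification))
        if row.dosage != "missing":
            rec.dosage = row.dosage
    return [records[g] for g in sorted(records)]


def read_shet(path: str | Path) -> List[ShetRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        v = row.s_het
        value = None if (v is None or (isinstance(v, float) and math.isnan(v))) else float(v)
        out.append(ShetRecord(str(row.gene), value))
    return out


def read_mutations(path: str | Path) -> List[PathogenicMutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"direct_dominant": int}).fillna("")
    return [
        PathogenicMutationRecord(
            gene=str(r.gene), mutation_id=str(r.id), significance=str(r.significance),
            direct_dominant_flag=bool(r.direct_dominant),
            omim_moi=[m for m in str(r.omim_moi).split(";") if m],
        )
        for r in df.itertuples(index=False)
    ]


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="transcript_id")


def read_phenotypes(path: str | Path) -> List[PhenotypeAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for r in df.itertuples(index=False):
        freq = r.frequency
        if freq is None or (isinstance(freq, float) and math.isnan(freq)) or freq == "":
            parsed = None
        else:
            try:
                parsed = float(freq)
            except ValueError:
                parsed = str(freq)
        out.append(PhenotypeAnnotation(str(r.gene), str(r.term), parsed))
    return out


def read_gene_list(path: str | Path) -> List[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# BED track export


def write_bed_tracks(
    targets: Sequence[TargetableAllele],
    pairs: Sequence[ExcisionPair],
    out_dir: str | Path,
) -> List[Path]:
    """BED6 per (gene, strategy): 1-bp records per targetable allele and one
    spanning record per excision pair; deterministic sort order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups: Dict[Tuple[str, str], List[Tuple]] = {}
    for t in targets:
        v = t.variant
        groups.setdefault((t.gene, t.strategy), []).append(
            (v.chrom, v.pos, v.pos + 1, f"{v.id}|{t.allele}|{t.strategy}"))
    for p in pairs:
        l, r = p.left.variant, p.right.variant
        name = f"{l.id}|{p.left.allele}+{r.id}|{p.right.allele}|excision"
        groups.setdefault((p.gene, "excision"), []).append(
            (l.chrom, l.pos, r.pos + 1, name))
    paths = []
    for (gene, strategy) in sorted(groups):
        path = out_dir / f"{gene}.{strategy}.bed"
        with open(path, "w") as fh:
            for chrom, start, end, name in sorted(set(groups[(gene, strategy)])):
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t.\n")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# report writers


def write_guide_table(rows: Sequence[dict], path: str | Path) -> None:
    cols = ["gene", "strategy", "variant_id", "allele", "strand",
            "pam_start", "spacer", "variant_offset"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Driver configuration: real input paths or a simulate block."""

    fasta: Optional[str] = None
    gtf: Optional[str] = None
    vcf: Optional[str] = None
    clinical_genes: Optional[str] = None
    shet: Optional[str] = None
    mutations: Optional[str] = None
    expression: Optional[str] = None
    phenotypes: Optional[str] = None
    catalog: Optional[str] = None
    simulate: Optional[dict] = None

    rules: RuleConfig = field(default_factory=RuleConfig)
    pam: PamConfig = field(default_factory=PamConfig)
    maf_min: float = 0.1
    shet_max: float = 0.1
    expr_share_min: float = 0.05
    top_k: int = 4
    n_perm: int = 100
    perm_set_size: int = 200
    seed: int = 0
    out_dir: str = "dndcrispr_out"

    def validate(self) -> None:
        real = [self.fasta, self.gtf, self.vcf, self.clinical_genes]
        if self.simulate is not None and any(real):
            raise ValueError("config must specify real input paths or a "
                             "simulate block, not both")
        if self.simulate is None and not all(real):
            raise ValueError("real mode requires fasta, gtf, vcf and "
                             "clinical_genes paths")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml
            raw = yaml.safe_load(path.read_text())
        elif path.suffix == ".toml":
            import tomllib
            raw = tomllib.loads(path.read_text())
        else:
            raise ValueError(f"unsupported config format: {path.suffix}")
        raw = raw or {}
        rules = RuleConfig(**raw.pop("rules", {}))
        pam = PamConfig(**raw.pop("pam", {}))
        cfg = cls(rules=rules, pam=pam, **raw)
        cfg.validate()
        return cfg


def write_run_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
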