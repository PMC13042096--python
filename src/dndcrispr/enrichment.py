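"""Phenotype-term enrichment of a gene set against a catalog.

The test draws random gene sets from the catalog and compares, per term,
the observed percentage of annotated genes against the permutation null:
effect size is the difference in percentage points and the p-value is a
one-sided empirical tail probability with an add-one pseudocount.
Benjamini-Hochberg correction is applied within each tested gene group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

# HPO-style categorical frequency codes. Terms qualify when they occur in
# >= 80% of patients, or carry no frequency annotation at all.
ADMITTED_CODES = {
    "Obligate": True,           # HP:0040280, 100%
    "HP:0040280": True,
    "VeryFrequent": True,       # HP:0040281, 99-80%
    "HP:0040281": True,
    "Frequent": False,          # HP:0040282, 79-30%
    "HP:0040282": False,
    "Occasional": False,        # HP:0040283, 29-5%
    "HP:0040283": False,
    "VeryRare": False,          # HP:0040284, 4-1%
    "HP:0040284": False,
    "Excluded": False,          # HP:0040285, 0%
    "HP:0040285": False,
}
FREQUENCY_MIN = 0.8


@dataclass(frozen=True)
class PhenotypeAnnotation:
    gene: str
    term: str
    frequency: Optional[object] = None  # fraction in [0,1], code string, or None


@dataclass
class EnrichmentResult:
    term: str
    observed_pct: float
    null_mean_pct: float
    effect: float       # observed - null mean, percentage points
    ratio: float        # observed / null mean (inf when null mean is 0)
    p: float
    q: float = float("nan")


def admit_annotations(
    annotations: Iterable[PhenotypeAnnotation],
) -> List[PhenotypeAnnotation]:
    """Keep annotations frequent enough to characterize the condition."""
    out: List[PhenotypeAnnotation] = []
    for a in annotations:
        f = a.frequency
        if f is None or (isinstance(f, float) and np.isnan(f)):
            out.append(a)
            continue
        if isinstance(f, str):
            if f not in ADMITTED_CODES:
                raise ValueError(f"unrecognized frequency code {f!r} on {a.gene}/{a.term}")
            if ADMITTED_CODES[f]:
                out.append(a)
            continue
        if float(f) >= FREQUENCY_MIN:
            out.append(a)
    return out


def term_percentages(
    gene_set: Set[str], annotations: Iterable[PhenotypeAnnotation]
) -> Dict[str, float]:
    """Percent of genes in the set annotated with each term."""
    if not gene_set:
        raise ValueError("term_percentages requires a non-empty gene set")
    genes_by_term: Dict[str, Set[str]] = {}
    for a in annotations:
        genes_by_term.setdefault(a.term, set()).add(a.gene)
    return {
        term: 100.0 * len(genes & gene_set) / len(gene_set)
        for term, genes in sorted(genes_by_term.items())
    }


def permutation_enrichment(
    observed_set: Set[str],
    catalog_genes: Sequence[str],
    annotations: Iterable[PhenotypeAnnotation],
    n_perm: int = 100,
    set_size: int = 200,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[EnrichmentResult]:
    """Empirical enrichment of every annotated term in the observed set.

    Draws ``n_perm`` uniform random gene sets of ``set_size`` (without
    replacement within each draw) from the catalog and computes, per term,
    the null distribution of annotation percentages. The one-sided p-value
    is (1 + #{null >= observed}) / (1 + n_perm).
    """
    catalog = sorted(set(catalog_genes))
    if len(catalog) < set_size:
        raise ValueError(f"catalog ({len(catalog)}) smaller than set_size ({set_size})")
    rng = rng if rng is not None else np.random.default_rng(seed)
    annotations = list(annotations)

    terms = sorted({a.term for a in annotations})
    term_index = {t: i for i, t in enumerate(terms)}
    gene_index = {g: i for i, g in enumerate(catalog)}
    member = np.zeros((len(terms), len(catalog)), dtype=bool)
    for a in annotations:
        gi = gene_index.get(a.gene)
        if gi is not None:
            member[term_index[a.term], gi] = True

    observed = term_percentages(observed_set, annotations)
    null = np.empty((n_perm, len(terms)))
    for i in range(n_perm):
        draw = rng.choice(len(catalog), size=set_size, replace=False)
        null[i] = 100.0 * member[:, draw].mean(axis=1)

    results: List[EnrichmentResult] = []
    for t in terms:
        obs = observed.get(t, 0.0)
        col = null[:, term_index[t]]
        null_mean = float(col.mean())
        p = (1.0 + int((col >= obs - 1e-12).sum())) / (1.0 + n_perm)
        ratio = obs / null_mean if null_mean > 0 else float("inf")
        results.append(EnrichmentResult(t, obs, null_mean, obs - null_mean, ratio, p))
    qs = bh_correct({r.term: r.p for r in results})
    for r in results:
        r.q = qs[r.term]
    return results


def bh_correct(pvalues: Dict[str, float]) -> Dict[str, float]:
    """Step-up Benjamini-Hochberg adjusted values, capped at 1."""
    if not pvalues:
        return {}
    terms = sorted(pvalues)
    p = [pvalues[t] for t in terms]
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return dict(zip(terms, q))


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "observed_pct": r.observed_pct,
                "null_mean_pct": r.null_mean_pct,
                "effect": r.effect,
                "ratio": r.ratio,
                "p": r.p,
                "q": r.q,
            }
            for r in results
        ]
    )
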