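"""Methylation x expression integration and gene-set enrichment.

MMSDK tags count *unmethylated* MluI sites, so the methylation direction
inverts the tag ratio: fewer tags in tumor (log2Ratio <= -1) means
hypermethylation, more tags (>= +1) hypomethylation.  Gene-level joins pair
each gene's most significant methylation locus with its expression record and
classify the combination (hyper-repressed, hypo-induced, ...).  A generic
right-tailed hypergeometric enrichment with BH correction covers GO/KEGG-style
gene-set collections supplied as GMT.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffstat import bh_adjust
from .digest import LocusAnnotation

__all__ = [
    "JointRecord",
    "EnrichmentResult",
    "classify_direction",
    "join_meth_expr",
    "hypergeom_enrich",
    "export_genome_track",
]

_CATEGORY = {
    ("hypermethylated", "down"): "hyper-repressed",
    ("hypermethylated", "up"): "hyper-induced",
    ("hypomethylated", "down"): "hypo-repressed",
    ("hypomethylated", "up"): "hypo-induced",
}


@dataclass(frozen=True)
class JointRecord:
    gene_id: str
    meth_log2: float
    meth_fdr: float
    meth_call: str  # hypermethylated | hypomethylated | ns
    expr_log2: float
    expr_fdr: float
    expr_call: str  # up | down | ns
    category: str  # hyper-repressed | hyper-induced | hypo-repressed | hypo-induced | ns


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_size: int
    overlap_size: int
    p_value: float
    fdr: float
    overlapping_gene_ids: frozenset


def classify_direction(tag_log2: float, threshold: float = 1.0) -> str:
    """Methylation direction from the tag log2 ratio (tags mark unmethylated
    sites, so the direction inverts the sign): <= -threshold hypermethylated,
    >= +threshold hypomethylated, else none."""
    if tag_log2 <= -threshold:
        return "hypermethylated"
    if tag_log2 >= threshold:
        return "hypomethylated"
    return "none"


def join_meth_expr(
    meth: pd.DataFrame,
    expr: pd.DataFrame,
    locus_annotations: Sequence[LocusAnnotation],
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Gene-level join of locus-level methylation calls with expression calls.

    A gene's methylation value is its most significant locus (smallest
    p-value, ties broken by larger |log2_ratio|, then lexicographic
    locus_id, which embeds the coordinate).  Only genes present in both
    layers are kept; the joint category is non-ns only when both layers pass
    FDR <= ``fdr_threshold`` and |log2| >= ``lfc_threshold``.  Loci mapping
    to no gene are dropped (tallied in the ``attrs`` of the result).
    """
    locus_to_genes = {a.locus_id: a.gene_ids for a in locus_annotations}
    m = meth.copy()
    dropped = 0
    rows = []
    for rec in m.itertuples(index=False):
        genes = locus_to_genes.get(rec.locus_id, frozenset())
        if not genes:
            dropped += 1
            continue
        for g in genes:
            rows.append(
                (
                    g,
                    rec.locus_id,
                    float(rec.log2_ratio),
                    float(rec.p_value),
                    float(rec.fdr),
                    bool(rec.significant),
                )
            )
    per_gene = pd.DataFrame(
        rows, columns=["gene_id", "locus_id", "log2_ratio", "p_value", "fdr", "significant"]
    )
    if len(per_gene):
        per_gene["_abs"] = per_gene["log2_ratio"].abs()
        per_gene = per_gene.sort_values(
            ["gene_id", "p_value", "_abs", "locus_id"],
            ascending=[True, True, False, True],
            kind="mergesort",
        )
        best = per_gene.groupby("gene_id", sort=True).head(1)
    else:
        best = per_gene
    e = expr.set_index("locus_id")
    out = []
    for rec in best.itertuples(index=False):
        if rec.gene_id not in e.index:
            continue
        ex = e.loc[rec.gene_id]
        meth_sig = bool(rec.significant)
        meth_call = classify_direction(rec.log2_ratio, lfc_threshold) if meth_sig else "ns"
        if meth_call == "none":
            meth_call = "ns"
        expr_sig = bool(ex["significant"])
        expr_call = str(ex["direction"]) if expr_sig else "ns"
        category = _CATEGORY.get((meth_call, expr_call), "ns")
        out.append(
            {
                "gene_id": rec.gene_id,
                "locus_id": rec.locus_id,
                "meth_log2": rec.log2_ratio,
                "meth_fdr": rec.fdr,
                "meth_call": meth_call,
                "expr_log2": float(ex["log2_ratio"]),
                "expr_fdr": float(ex["fdr"]),
                "expr_call": expr_call,
                "category": category,
            }
        )
    result = pd.DataFrame(
        out,
        columns=[
            "gene_id",
            "locus_id",
            "meth_log2",
            "meth_fdr",
            "meth_call",
            "expr_log2",
            "expr_fdr",
            "expr_call",
            "category",
        ],
    ).sort_values("gene_id", kind="mergesort", ignore_index=True)
    result.attrs["loci_without_gene"] = dropped
    return result


def hypergeom_enrich(
    query: Iterable[str],
    universe: Iterable[str],
    genesets: Mapping[str, Iterable[str]],
) -> list[EnrichmentResult]:
    """Right-tailed hypergeometric enrichment of a gene set collection.

    With N universe genes, K term members (after intersecting the term with
    the universe), n query genes and k overlapping:
    p = sum_{i >= k} C(K,i) C(N-K,n-i) / C(N,n); BH across all tested terms.
    Zero-overlap terms report p = 1.
    """
    query = set(query)
    universe = set(universe)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:10]}")
    N, n = len(universe), len(query)
    term_ids, pvals, meta = [], [], []
    for term_id in sorted(genesets):
        members = set(genesets[term_id]) & universe
        K = len(members)
        overlap = members & query
        k = len(overlap)
        p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, N, K, n))
        term_ids.append(term_id)
        pvals.append(min(1.0, p))
        meta.append((K, k, frozenset(overlap)))
    fdrs = bh_adjust(pvals) if pvals else []
    return [
        EnrichmentResult(
            term_id=t, term_size=K, overlap_size=k, p_value=p, fdr=float(f),
            overlapping_gene_ids=genes,
        )
        for t, p, f, (K, k, genes) in zip(term_ids, pvals, fdrs, meta)
    ]


def export_genome_track(
    records_by_layer: Mapping[str, pd.DataFrame],
    handle: IO[str],
    lfc_threshold: float = 1.0,
) -> int:
    """Write per-locus log2 ratios as a BEDGRAPH-style track, one block per
    omics layer, coordinate-sorted, with the significance threshold noted in
    each block header.  Returns the number of data lines written.

    Each layer's frame needs columns chrom, start, end, log2_ratio.
    """
    n = 0
    for layer in sorted(records_by_layer):
        df = records_by_layer[layer]
        handle.write(
            f'track type=bedGraph name="{layer}" '
            f'description="log2(tumor/normal), significance threshold |log2Ratio|={lfc_threshold:g}"\n'
        )
        if len(df) == 0:
            continue
        df = df.sort_values(["chrom", "start"], kind="mergesort")
        for rec in df.itertuples(index=False):
            handle.write(f"{rec.chrom}\t{int(rec.start)}\t{int(rec.end)}\t{rec.log2_ratio:.6g}\n")
            n += 1
    return n
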