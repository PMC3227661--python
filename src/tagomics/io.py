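"""Readers and writers for the pipeline's file formats.

FASTA/FASTQ go through Biopython, GFF3 reading through gffutils; BED6,
BEDGRAPH, GMT, TSV matrices and pair lists are simple tabular formats
written/read directly (pandas for the tables).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .digest import CGIRegion, GeneModel, LocusAnnotation, VirtualTagLibrary
from .simulate import SimTruth
from .tags import ReadSet, TagCountMatrix

__all__ = [
    "read_fasta", "write_fasta", "read_fastq", "write_fastq",
    "read_gff3_genes", "write_gff3_genes", "read_bed", "write_bed6",
    "read_gmt", "write_gmt", "read_pairs_tsv",
    "write_count_matrix", "read_count_matrix",
    "write_tag_library_fasta", "write_truth_json", "write_annotations_tsv",
]


# --- sequences -------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> tuple[list[str], list[list[int]]]:
    seqs, quals = [], []
    for rec in SeqIO.parse(str(path), "fastq"):
        seqs.append(str(rec.seq).upper())
        quals.append(rec.letter_annotations.get("phred_quality", []))
    return seqs, quals


def write_fastq(readset: ReadSet, path, quality: int = 40) -> None:
    with open(path, "w") as fh:
        i = 0
        for seq, mult in readset.reads.items():
            for _ in range(mult):
                i += 1
                fh.write(f"@{readset.sample_id}.{i}\n{seq}\n+\n{chr(quality + 33) * len(seq)}\n")


def write_tag_library_fasta(library: VirtualTagLibrary, path) -> None:
    """Tag library as FASTA, IDs = locus_id:side, longest tag form."""
    with open(path, "w") as fh:
        for e in library.entries:
            fh.write(f">{e.locus_id}:{e.side}\n{e.tag_sequence_18nt or e.tag_sequence_17nt}\n")


# --- annotations -----------------------------------------------------------

def read_gff3_genes(path) -> list[GeneModel]:
    """Gene models from GFF3 (gene + exon features, linked by ID/Parent)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique", force=True)
    genes = []
    for g in db.features_of_type("gene"):
        exons = tuple(
            sorted((e.start - 1, e.end) for e in db.children(g, featuretype="exon"))
        )
        genes.append(
            GeneModel(
                gene_id=g.id, chrom=g.seqid, start=g.start - 1, end=g.end,
                strand=g.strand if g.strand in "+-" else "+", exons=exons,
            )
        )
    return genes


def write_gff3_genes(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\ttagomics\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\ttagomics\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_bed6(intervals: Iterable[tuple], path, name_prefix: str = "iv") -> None:
    """Intervals as BED6; items are (chrom, start, end[, name[, score[, strand]]])."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals, 1):
            chrom, start, end = iv[0], iv[1], iv[2]
            name = iv[3] if len(iv) > 3 else f"{name_prefix}{i}"
            score = iv[4] if len(iv) > 4 else 0
            strand = iv[5] if len(iv) > 5 else "."
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def write_annotations_tsv(annotations: Sequence[LocusAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tregion_class\tgene_ids\n")
        for a in annotations:
            fh.write(f"{a.locus_id}\t{a.region_class}\t{','.join(sorted(a.gene_ids))}\n")


# --- gene sets and pair lists ---------------------------------------------

def read_gmt(path) -> dict[str, set]:
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) >= 3:
                sets[f[0]] = {g for g in f[2:] if g}
    return sets


def write_gmt(genesets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for term, genes in genesets.items():
            fh.write("\t".join([term, term] + sorted(genes)) + "\n")


def read_pairs_tsv(path) -> list[tuple[str, str]]:
    """miRNA -> gene pairs from a two-column TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    pairs = []
    for a, b in df.itertuples(index=False):
        if a.lower() in ("mirna_id", "mirna") and b.lower() in ("gene_id", "gene"):
            continue
        pairs.append((a, b))
    return pairs


# --- count matrices --------------------------------------------------------

def write_count_matrix(matrix: TagCountMatrix, path) -> None:
    """TSV: locus_id + one column per sample; header comments carry the
    per-sample library sizes and condition labels."""
    with open(path, "w") as fh:
        fh.write("#library_sizes\t" + "\t".join(str(int(s)) for s in matrix.library_sizes) + "\n")
        fh.write("#conditions\t" + "\t".join(matrix.conditions) + "\n")
        fh.write("locus_id\t" + "\t".join(matrix.samples) + "\n")
        for i, lid in enumerate(matrix.locus_ids):
            fh.write(lid + "\t" + "\t".join(str(int(c)) for c in matrix.counts[i]) + "\n")


def read_count_matrix(path) -> TagCountMatrix:
    with open(path) as fh:
        sizes_line = fh.readline().rstrip("\n").split("\t")
        cond_line = fh.readline().rstrip("\n").split("\t")
        if sizes_line[0] != "#library_sizes" or cond_line[0] != "#conditions":
            raise ValueError("count matrix missing #library_sizes/#conditions headers")
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[1:]
        locus_ids, rows = [], []
        for line in fh:
            f = line.rstrip("\n").split("\t")
            locus_ids.append(f[0])
            rows.append([int(v) for v in f[1:]])
    return TagCountMatrix(
        locus_ids=locus_ids,
        samples=samples,
        conditions=cond_line[1:],
        counts=np.asarray(rows, dtype=np.int64).reshape(len(locus_ids), len(samples)),
        library_sizes=np.asarray([int(v) for v in sizes_line[1:]], dtype=np.int64),
    )


def write_truth_json(truth: SimTruth, path) -> None:
    payload = {
        "spiked_locus_ids": sorted(truth.spiked_locus_ids),
        "spike_directions": {k: int(v) for k, v in sorted(truth.spike_directions.items())},
        "planted_site_positions": {
            c: [int(p) for p in v] for c, v in truth.planted_site_positions.items()
        },
        "planted_cgi_intervals": [[c, int(s), int(e)] for c, s, e in truth.planted_cgi_intervals],
        "gene_models": [
            {
                "gene_id": g.gene_id, "chrom": g.chrom, "start": g.start, "end": g.end,
                "strand": g.strand, "exons": [list(x) for x in g.exons],
            }
            for g in truth.gene_models
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
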