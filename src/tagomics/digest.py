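"""In-silico restriction digestion and virtual tag-library construction.

MMSDK (modified methylation-specific digital karyotyping) profiles the
unmethylated fraction of a genome by cutting with the methylation-sensitive
enzyme MluI (ACGCGT, blocked by CpG methylation), trimming with the frequent
cutter NlaIII (CATG), and sequencing the 17-18 nt tag released by MmeI next
to each NlaIII boundary.  DGE (digital gene expression) counts the 17 nt tag
3' of each CATG in transcripts.  This module reproduces both digestions in
silico to build the tag reference the sequenced tags are mapped against, calls
CpG islands by the classic three-criteria definition, and annotates tag loci
by genic context.

Coordinates are 0-based half-open throughout.  Cut offsets follow the
enzymes' published cut sites: A^CGCGT (offset +1) and CATG^ (offset +4).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "MLUI_MOTIF",
    "NLAIII_MOTIF",
    "GeneModel",
    "RestrictionSiteList",
    "VirtualFragment",
    "TagEntry",
    "VirtualTagLibrary",
    "CGIRegion",
    "LocusAnnotation",
    "revcomp",
    "find_sites",
    "build_mmsdk_library",
    "build_dge_library",
    "detect_cgi",
    "annotate_loci",
]

MLUI_MOTIF = "ACGCGT"
NLAIII_MOTIF = "CATG"

#: published cut offsets (bases from motif start to the cut position)
CUT_OFFSETS = {MLUI_MOTIF: 1, NLAIII_MOTIF: 4}
ENZYME_NAMES = {MLUI_MOTIF: "MluI", NLAIII_MOTIF: "NlaIII"}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with exon structure; TSS is the stranded 5' end."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid gene span [{self.start}, {self.end})")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class RestrictionSiteList:
    """All forward-strand motif occurrences per chromosome.

    For reverse-complement-palindromic motifs (both ACGCGT and CATG) the
    forward scan is the complete double-stranded site set.
    """

    enzyme: str
    motif: str
    cut_offset: int
    sites: dict[str, np.ndarray]

    def n_sites(self) -> int:
        return int(sum(len(v) for v in self.sites.values()))


@dataclass(frozen=True)
class VirtualFragment:
    """Genome interval between an MluI cut and the nearest NlaIII cut or obstacle."""

    chromosome: str
    start: int
    end: int
    anchor_site: int  # motif start coordinate of the anchoring MluI site
    boundary: int  # NlaIII cut coordinate, or the obstacle coordinate
    side: str  # "upstream" | "downstream" of the MluI cut
    has_internal_nla: bool

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty fragment [{self.start}, {self.end})")


@dataclass(frozen=True)
class TagEntry:
    tag_id: str
    locus_id: str
    chromosome: str
    start: int  # genomic span of the 18-mer (MMSDK) / 17-mer (DGE) tag region
    end: int
    tag_sequence_17nt: str
    tag_sequence_18nt: str | None
    side: str  # "upstream" | "downstream" (MMSDK) or "+" / "-" strand (DGE)
    gene_ids: frozenset[str] = frozenset()


@dataclass
class VirtualTagLibrary:
    """Virtual tag reference: MMSDK MluI-anchored tags or DGE CATG tags."""

    entries: list[TagEntry]
    kind: str  # "MMSDK" | "DGE"

    def __len__(self) -> int:
        return len(self.entries)

    def locus_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.locus_id, None)
        return list(seen)


@dataclass(frozen=True)
class CGIRegion:
    chromosome: str
    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float


@dataclass(frozen=True)
class LocusAnnotation:
    locus_id: str
    region_class: str  # CGI-promoter | non-CGI-promoter | exon | intron | intergenic
    gene_ids: frozenset[str] = frozenset()


# ---------------------------------------------------------------------------
# motif scanning


def find_sites(
    genome: Mapping[str, str],
    motif: str,
    cut_offset: int | None = None,
    enzyme: str | None = None,
) -> RestrictionSiteList:
    """Locate every forward-strand occurrence of ``motif`` (overlaps included).

    Raises ``ValueError`` for motifs containing ambiguous bases.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif contains ambiguous bases: {motif!r}")
    if cut_offset is None:
        cut_offset = CUT_OFFSETS.get(motif, 0)
    if enzyme is None:
        enzyme = ENZYME_NAMES.get(motif, motif)
    sites: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        hits = []
        i = seq.find(motif)
        while i != -1:
            hits.append(i)
            i = seq.find(motif, i + 1)
        sites[chrom] = np.asarray(hits, dtype=np.int64)
    return RestrictionSiteList(enzyme=enzyme, motif=motif, cut_offset=cut_offset, sites=sites)


# ---------------------------------------------------------------------------
# MMSDK virtual digestion


def build_mmsdk_library(
    genome: Mapping[str, str],
    mlu_sites: RestrictionSiteList,
    nla_sites: RestrictionSiteList,
    tag_lengths: tuple[int, int] = (17, 18),
) -> tuple[list[VirtualFragment], VirtualTagLibrary]:
    """Simulate the double MluI + NlaIII digestion under the all-unmethylated hypothesis.

    Every MluI cut releases two fragments: upstream to the nearest NlaIII cut
    (or obstacle: chromosome end / adjacent MluI cut) and downstream likewise.
    A fragment whose NlaIII-side boundary is an obstacle carries
    ``has_internal_nla=False`` and yields no tag; otherwise the tag is the
    17/18 bases of the fragment immediately interior to the NlaIII boundary
    (the CATG itself excluded), read from the boundary into the fragment --
    i.e. forward strand for upstream fragments and reverse complement for
    downstream fragments.  Fragments with fewer than ``max(tag_lengths)``
    bases past the CATG yield no tag.
    """
    short_len, long_len = sorted(tag_lengths)
    fragments: list[VirtualFragment] = []
    entries: list[TagEntry] = []
    for chrom in mlu_sites.sites:
        if chrom not in genome:
            raise ValueError(f"site list references unknown chromosome {chrom!r}")
        seq = genome[chrom]
        chrom_len = len(seq)
        msites = mlu_sites.sites[chrom]
        cuts = msites + mlu_sites.cut_offset
        ncuts = nla_sites.sites.get(chrom, np.empty(0, dtype=np.int64)) + nla_sites.cut_offset
        nla_len = len(nla_sites.motif)
        for idx, (site, cut) in enumerate(zip(msites, cuts)):
            locus_id = f"{chrom}:{int(site)}"
            # upstream fragment: from nearest NlaIII cut at or left of the MluI
            # cut, bounded by the previous MluI cut / chromosome start
            lo = int(cuts[idx - 1]) if idx > 0 else 0
            j = bisect.bisect_right(ncuts, cut) - 1
            ucut = int(ncuts[j]) if j >= 0 else None
            # the CATG motif must lie wholly right of the obstacle
            if ucut is not None and (ucut - nla_len < lo or ucut > cut):
                ucut = None
            cut = int(cut)
            if ucut is not None:
                if ucut < cut:
                    fragments.append(
                        VirtualFragment(chrom, ucut, cut, int(site), ucut, "upstream", True)
                    )
                    if cut - ucut >= long_len:
                        tag18 = seq[ucut : ucut + long_len]
                        entries.append(
                            TagEntry(
                                tag_id=f"{locus_id}:up",
                                locus_id=locus_id,
                                chromosome=chrom,
                                start=ucut,
                                end=ucut + long_len,
                                tag_sequence_17nt=tag18[:short_len],
                                tag_sequence_18nt=tag18,
                                side="upstream",
                            )
                        )
            elif lo < cut:
                fragments.append(
                    VirtualFragment(chrom, lo, cut, int(site), lo, "upstream", False)
                )
            # downstream fragment: to nearest NlaIII cut right of the MluI cut,
            # bounded by the next MluI cut / chromosome end
            hi = int(cuts[idx + 1]) if idx + 1 < len(cuts) else chrom_len
            j = bisect.bisect_right(ncuts, cut)
            dcut = int(ncuts[j]) if j < len(ncuts) else None
            if dcut is not None and dcut > hi:
                dcut = None
            if dcut is not None:
                fragments.append(
                    VirtualFragment(chrom, cut, dcut, int(site), dcut, "downstream", True)
                )
                tag_hi = dcut - nla_len  # CATG excluded
                if tag_hi - cut >= long_len:
                    region = seq[tag_hi - long_len : tag_hi]
                    tag18 = revcomp(region)
                    entries.append(
                        TagEntry(
                            tag_id=f"{locus_id}:down",
                            locus_id=locus_id,
                            chromosome=chrom,
                            start=tag_hi - long_len,
                            end=tag_hi,
                            tag_sequence_17nt=tag18[:short_len],
                            tag_sequence_18nt=tag18,
                            side="downstream",
                        )
                    )
            elif cut < hi:
                fragments.append(
                    VirtualFragment(chrom, cut, hi, int(site), hi, "downstream", False)
                )
    return fragments, VirtualTagLibrary(entries=entries, kind="MMSDK")


# ---------------------------------------------------------------------------
# DGE virtual tag reference


def build_dge_library(
    genome: Mapping[str, str],
    nla_sites: RestrictionSiteList,
    genes: Sequence[GeneModel] = (),
    tag_length: int = 17,
) -> VirtualTagLibrary:
    """Extract the ``tag_length``-mer flanking every CATG, in both orientations.

    Forward entry: the 17 bases immediately 3' of the motif.  Reverse entry:
    the reverse complement of the 17 bases immediately 5' of the motif (the
    same tag on the opposite strand, CATG being its own reverse complement).
    Entries overlapping exactly one gene take that gene as their locus, so
    per-locus counting aggregates DGE tags per gene.
    """
    gene_trees: dict[str, IntervalTree] = {}
    for g in genes:
        gene_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
    entries: list[TagEntry] = []
    motif_len = len(nla_sites.motif)
    for chrom, msites in nla_sites.sites.items():
        if chrom not in genome:
            raise ValueError(f"site list references unknown chromosome {chrom!r}")
        seq = genome[chrom]
        tree = gene_trees.get(chrom)
        for site in msites:
            site = int(site)
            for strand, lo, hi in (
                ("+", site + motif_len, site + motif_len + tag_length),
                ("-", site - tag_length, site),
            ):
                if lo < 0 or hi > len(seq):
                    continue
                tag = seq[lo:hi] if strand == "+" else revcomp(seq[lo:hi])
                gene_ids = (
                    frozenset(iv.data for iv in tree.overlap(lo, hi)) if tree else frozenset()
                )
                locus_id = (
                    next(iter(gene_ids)) if len(gene_ids) == 1 else f"{chrom}:{site}:{strand}"
                )
                entries.append(
                    TagEntry(
                        tag_id=f"{chrom}:{site}:{strand}",
                        locus_id=locus_id,
                        chromosome=chrom,
                        start=lo,
                        end=hi,
                        tag_sequence_17nt=tag,
                        tag_sequence_18nt=None,
                        side=strand,
                        gene_ids=gene_ids,
                    )
                )
    return VirtualTagLibrary(entries=entries, kind="DGE")


# ---------------------------------------------------------------------------
# CpG island detection


def _cgi_stats(prefix_c, prefix_g, prefix_cpg, start: int, end: int) -> tuple[float, float]:
    length = end - start
    c = int(prefix_c[end] - prefix_c[start])
    g = int(prefix_g[end] - prefix_g[start])
    # CpG dinucleotides wholly inside [start, end)
    cpg = int(prefix_cpg[max(end - 1, start)] - prefix_cpg[start])
    gc = (c + g) / length
    obs_exp = (cpg * length) / (c * g) if c > 0 and g > 0 else 0.0
    return gc, obs_exp


def detect_cgi(
    genome: Mapping[str, str],
    min_gc: float = 0.5,
    min_obs_exp: float = 0.6,
    min_len: int = 201,
    window: int = 200,
    step: int = 1,
) -> list[CGIRegion]:
    """Call CpG islands: GC >= ``min_gc``, observed/expected CpG > ``min_obs_exp``,
    length >= ``min_len`` (i.e. strictly longer than 200 bp at defaults).

    Seed-and-merge: every ``window``-bp window (stepped by ``step``) passing
    the GC and obs/exp criteria is a seed; overlapping/touching seeds are
    merged; each merged region is re-tested as a whole and trimmed one base
    at a time (from whichever end is not a C/G, else the right end) until it
    passes or falls below ``min_len``.  obs/exp CpG = (#CpG x L) / (#C x #G).
    """
    regions: list[CGIRegion] = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        n = len(seq)
        if n < window:
            continue
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_c = (arr == ord("C")).astype(np.int64)
        is_g = (arr == ord("G")).astype(np.int64)
        is_cpg = np.zeros(n, dtype=np.int64)
        if n > 1:
            is_cpg[:-1] = is_c[:-1] & is_g[1:]
        pc = np.concatenate(([0], np.cumsum(is_c)))
        pg = np.concatenate(([0], np.cumsum(is_g)))
        pcpg = np.concatenate(([0], np.cumsum(is_cpg)))
        starts = np.arange(0, n - window + 1, step)
        ends = starts + window
        c = pc[ends] - pc[starts]
        g = pg[ends] - pg[starts]
        cpg = pcpg[ends - 1] - pcpg[starts]
        gc_ok = (c + g) / window >= min_gc
        with np.errstate(divide="ignore", invalid="ignore"):
            obs_exp = np.where((c > 0) & (g > 0), cpg * window / np.maximum(c * g, 1), 0.0)
        passing = starts[gc_ok & (obs_exp > min_obs_exp)]
        if len(passing) == 0:
            continue
        # merge overlapping or touching seed windows
        merged: list[list[int]] = []
        for s in passing:
            s = int(s)
            if merged and s <= merged[-1][1]:
                merged[-1][1] = s + window
            else:
                merged.append([s, s + window])
        for start, end in merged:
            while end - start >= min_len:
                gc, oe = _cgi_stats(pc, pg, pcpg, start, end)
                if gc >= min_gc and oe > min_obs_exp:
                    regions.append(CGIRegion(chrom, start, end, gc, oe))
                    break
                if seq[start] not in "CG":
                    start += 1
                elif seq[end - 1] not in "CG":
                    end -= 1
                else:
                    end -= 1
    return regions


# ---------------------------------------------------------------------------
# locus annotation


def _locus_intervals(library: VirtualTagLibrary) -> dict[str, tuple[str, int, int]]:
    spans: dict[str, tuple[str, int, int]] = {}
    for e in library.entries:
        if e.locus_id in spans:
            chrom, lo, hi = spans[e.locus_id]
            spans[e.locus_id] = (chrom, min(lo, e.start), max(hi, e.end))
        else:
            spans[e.locus_id] = (e.chromosome, e.start, e.end)
    return spans


def annotate_loci(
    library: VirtualTagLibrary,
    genes: Sequence[GeneModel],
    cgis: Iterable[CGIRegion] = (),
    promoter_window: int = 1000,
    chromosomes: Iterable[str] | None = None,
) -> list[LocusAnnotation]:
    """Assign each tag locus one region class by precedence
    promoter > exon > intron > intergenic.

    The promoter is [TSS - promoter_window, TSS + promoter_window); a promoter
    locus overlapping any CpG island is "CGI-promoter", otherwise
    "non-CGI-promoter".  ``gene_ids`` are the genes whose assigned region
    contains the locus.  If ``chromosomes`` is given (e.g. the genome's
    chromosome names), gene models on unknown chromosomes raise.
    """
    if chromosomes is not None:
        known = set(chromosomes)
        for g in genes:
            if g.chrom not in known:
                raise ValueError(f"gene {g.gene_id!r} on unknown chromosome {g.chrom!r}")
    promoters: dict[str, IntervalTree] = {}
    exons: dict[str, IntervalTree] = {}
    bodies: dict[str, IntervalTree] = {}
    for g in genes:
        p_lo = max(0, g.tss - promoter_window)
        p_hi = g.tss + promoter_window
        promoters.setdefault(g.chrom, IntervalTree()).addi(p_lo, p_hi, g.gene_id)
        bodies.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
        for es, ee in g.exons:
            exons.setdefault(g.chrom, IntervalTree()).addi(es, ee, g.gene_id)
    cgi_trees: dict[str, IntervalTree] = {}
    for r in cgis:
        cgi_trees.setdefault(r.chromosome, IntervalTree()).addi(r.start, r.end)

    out: list[LocusAnnotation] = []
    for locus_id, (chrom, lo, hi) in _locus_intervals(library).items():
        p_hits = promoters.get(chrom, IntervalTree()).overlap(lo, hi)
        if p_hits:
            in_cgi = bool(cgi_trees.get(chrom, IntervalTree()).overlap(lo, hi))
            cls = "CGI-promoter" if in_cgi else "non-CGI-promoter"
            gene_ids = frozenset(iv.data for iv in p_hits)
        else:
            e_hits = exons.get(chrom, IntervalTree()).overlap(lo, hi)
            if e_hits:
                cls = "exon"
                gene_ids = frozenset(iv.data for iv in e_hits)
            else:
                b_hits = bodies.get(chrom, IntervalTree()).overlap(lo, hi)
                if b_hits:
                    cls = "intron"
                    gene_ids = frozenset(iv.data for iv in b_hits)
                else:
                    cls = "intergenic"
                    gene_ids = frozenset()
        out.append(LocusAnnotation(locus_id=locus_id, region_class=cls, gene_ids=gene_ids))
    return out
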