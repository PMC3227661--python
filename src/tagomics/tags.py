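"""Read cleaning, adapter clipping, tag mapping and per-locus counting.

Sequenced tags are short (17-18 nt) and the reference is a small virtual tag
library, so mapping is done with an exact + one-mismatch hash index rather
than a genome-scale aligner.  A tag is assigned to a locus only when it has a
single best hit at its minimal mismatch distance (<= 1); ties are discarded
as ambiguous.  Matching is orientation-aware: a tag or its reverse complement
hitting the same library entry counts as that entry.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .digest import VirtualTagLibrary, revcomp

__all__ = [
    "ReadSet",
    "TagCountMatrix",
    "TagIndex",
    "MapResult",
    "clip_adapter",
    "quality_filter",
    "filter_reads",
    "map_tags",
    "count_per_locus",
    "pool_by_mean",
    "filter_blacklist",
    "round_half_up",
]


@dataclass
class ReadSet:
    """A sample's reads as a multiset (sequence -> multiplicity)."""

    sample_id: str
    condition: str  # "tumor" | "normal"
    reads: Counter

    @classmethod
    def from_sequences(cls, sample_id: str, condition: str, seqs: Iterable[str]) -> "ReadSet":
        return cls(sample_id=sample_id, condition=condition, reads=Counter(seqs))

    def total(self) -> int:
        return sum(self.reads.values())


@dataclass
class TagCountMatrix:
    """Integer tag counts, loci x samples, with library sizes and conditions."""

    locus_ids: list[str]
    samples: list[str]
    conditions: list[str]
    counts: np.ndarray  # shape (n_loci, n_samples), int64
    library_sizes: np.ndarray  # shape (n_samples,), int64

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        if self.counts.shape != (len(self.locus_ids), len(self.samples)):
            raise ValueError("counts shape does not match locus/sample lists")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if (self.library_sizes < self.counts.sum(axis=0)).any():
            raise ValueError("library sizes smaller than column sums")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.locus_ids, columns=self.samples)

    def columns_for(self, condition: str) -> list[int]:
        return [i for i, c in enumerate(self.conditions) if c == condition]


def round_half_up(x) -> np.ndarray:
    """Round to nearest integer with .5 rounding up (not banker's rounding)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


# ---------------------------------------------------------------------------
# adapter clipping


def clip_adapter(
    read: str,
    adapter: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
    min_score: int = 7,
) -> str:
    """Clip a 3' adapter by dynamic-programming alignment against read suffixes.

    The adapter is aligned from its first base over every read suffix
    (gapped; unaligned trailing adapter bases are free).  If the best-scoring
    suffix start reaches ``min_score`` the read is truncated there, ties
    going to the rightmost start (the longer insert is kept).  Reads without
    adapter similarity are returned unchanged; the empty read is a no-op.
    """
    if len(adapter) < 6:
        raise ValueError("adapter must be at least 6 bases")
    n, m = len(read), len(adapter)
    if n == 0:
        return read
    if m * match >= min_score:
        # exact full adapter flush with the read end: provably optimal
        j = read.find(adapter)
        if j != -1 and n - j == m:
            return read[:j]
    if m >= n and n * match >= min_score and adapter.startswith(read):
        return ""  # the whole read is adapter
    best_score, best_start = _overlap_align(read, adapter, match, mismatch, gap)
    if best_score >= min_score:
        return read[:best_start]
    return read


def _overlap_align(
    read: str, adapter: str, match: int, mismatch: int, gap: int
) -> tuple[int, int]:
    """Overlap alignment: free leading read prefix (= free choice of suffix
    start), global over the rest of the read, free trailing adapter bases.

    Returns (best score, suffix start of the best alignment).  Score ties
    prefer the rightmost start (clip less), resolved per cell by preferring
    the larger-start predecessor (diagonal, then adapter-gap, then read-gap).
    """
    n, m = len(read), len(adapter)
    score = [0] * (n + 1)  # adapter prefix of length 0 aligned nowhere yet
    start = list(range(n + 1))
    best_score, best_start = None, None
    for i in range(1, m + 1):
        ai = adapter[i - 1]
        new_score = [i * gap] + [0] * n
        new_start = [0] + [0] * n
        for j in range(1, n + 1):
            diag = score[j - 1] + (match if ai == read[j - 1] else mismatch)
            up = score[j] + gap  # gap in read (adapter base unaligned inside)
            left = new_score[j - 1] + gap  # gap in adapter
            s = diag
            st = start[j - 1]
            if up > s or (up == s and start[j] > st):
                s, st = up, start[j]
            if left > s or (left == s and new_start[j - 1] > st):
                s, st = left, new_start[j - 1]
            new_score[j], new_start[j] = s, st
        # alignment must consume the read to its end; trailing adapter is free
        if best_score is None or new_score[n] > best_score or (
            new_score[n] == best_score and new_start[n] > best_start
        ):
            best_score, best_start = new_score[n], new_start[n]
        score, start = new_score, new_start
    return int(best_score), int(best_start)


# ---------------------------------------------------------------------------
# read filtering


def quality_filter(
    seqs: Sequence[str], quals: Sequence[Sequence[int]] | None, min_mean_q: float = 20.0
) -> list[str]:
    """Drop reads whose mean base quality is below ``min_mean_q``.

    A no-op when qualities are absent (plain tag lists / FASTA input).
    """
    if quals is None:
        return list(seqs)
    return [s for s, q in zip(seqs, quals) if len(q) == 0 or float(np.mean(q)) >= min_mean_q]


def filter_reads(
    reads: ReadSet,
    min_len: int = 0,
    drop_n: bool = True,
    drop_singletons: bool = False,
    dedupe: bool = False,
) -> ReadSet:
    """Remove erroneous tags: N-containing reads, too-short reads, and
    (mRNA mode) library-wide single-copy sequences.

    ``dedupe`` (miRNA mode) collapses identical sequences to one
    representative while retaining multiplicity as the count -- with the
    multiset representation this marks intent; downstream mapping already
    operates per unique sequence.
    """
    out: Counter = Counter()
    for seq, mult in reads.reads.items():
        if drop_n and "N" in seq:
            continue
        if len(seq) < min_len:
            continue
        if drop_singletons and mult == 1:
            continue
        out[seq] = mult
    return ReadSet(sample_id=reads.sample_id, condition=reads.condition, reads=out)


# ---------------------------------------------------------------------------
# tag mapping


class TagIndex:
    """Exact + one-mismatch (wildcard) hash index over a virtual tag library.

    Both tag lengths (17-mer prefix and 18-mer, when present) and both
    orientations of every entry are indexed; all keys resolve to entry
    indices, so a read matching an entry in either orientation yields the
    same assignment.
    """

    def __init__(self, library: VirtualTagLibrary):
        self.library = library
        self.exact: dict[str, set[int]] = {}
        self.wild: dict[str, set[int]] = {}
        self.lengths: list[int] = []
        self.entry_seqs: list[list[str]] = [[] for _ in library.entries]
        lengths = set()
        for idx, e in enumerate(library.entries):
            seqs = {e.tag_sequence_17nt, revcomp(e.tag_sequence_17nt)}
            if e.tag_sequence_18nt:
                seqs |= {e.tag_sequence_18nt, revcomp(e.tag_sequence_18nt)}
            for s in seqs:
                lengths.add(len(s))
                self.entry_seqs[idx].append(s)
                self.exact.setdefault(s, set()).add(idx)
                for pos in range(len(s)):
                    key = f"{s[:pos]}*{s[pos + 1:]}"
                    self.wild.setdefault(key, set()).add(idx)
        self.lengths = sorted(lengths, reverse=True)  # try longer form first

    def _min_distance(self, query: str, idx: int) -> int:
        best = len(query)
        for s in self.entry_seqs[idx]:
            if len(s) != len(query):
                continue
            d = sum(a != b for a, b in zip(query, s))
            best = min(best, d)
        return best

    def assign(self, read: str, max_mismatch: int = 1) -> int | str:
        """Entry index for a uniquely-mapping read, else "ambiguous"/"unmapped".

        A read is matched at the longest indexed length it covers -- so a
        17 nt read matches the 17-mer form of an entry whose 18-mer form a
        full-length read would match.  Uniqueness at the minimal mismatch
        distance decides the outcome; the distance never crosses tag forms.
        """
        for L in self.lengths:
            if len(read) < L:
                continue
            q = read[:L]
            hits = self.exact.get(q)
            if hits:
                return next(iter(hits)) if len(hits) == 1 else "ambiguous"
            if max_mismatch >= 1:
                cand: set[int] = set()
                for pos in range(L):
                    key = f"{q[:pos]}*{q[pos + 1:]}"
                    cand |= self.wild.get(key, set())
                cand = {i for i in cand if self._min_distance(q, i) == 1}
                if len(cand) == 1:
                    return next(iter(cand))
                if len(cand) > 1:
                    return "ambiguous"
            return "unmapped"
        return "unmapped"


@dataclass
class MapResult:
    """Per-sample mapping outcome: per-entry counts plus bookkeeping tallies."""

    sample_id: str
    condition: str
    entry_counts: Counter  # entry index -> mapped tag count
    mapped: int
    ambiguous: int
    unmapped: int
    library: VirtualTagLibrary

    def locus_counts(self) -> Counter:
        out: Counter = Counter()
        for idx, n in self.entry_counts.items():
            out[self.library.entries[idx].locus_id] += n
        return out


def map_tags(
    tags: ReadSet,
    library: VirtualTagLibrary,
    max_mismatch: int = 1,
    index: TagIndex | None = None,
) -> MapResult:
    """Map a sample's tags to the virtual library (exact or one mismatch,
    unique best hit only).  An empty library leaves every tag unmapped."""
    if index is None:
        index = TagIndex(library)
    entry_counts: Counter = Counter()
    mapped = ambiguous = unmapped = 0
    for seq, mult in tags.reads.items():
        res = index.assign(seq, max_mismatch=max_mismatch)
        if res == "unmapped":
            unmapped += mult
        elif res == "ambiguous":
            ambiguous += mult
        else:
            entry_counts[res] += mult
            mapped += mult
    return MapResult(
        sample_id=tags.sample_id,
        condition=tags.condition,
        entry_counts=entry_counts,
        mapped=mapped,
        ambiguous=ambiguous,
        unmapped=unmapped,
        library=library,
    )


def count_per_locus(assignments: Sequence[MapResult]) -> TagCountMatrix:
    """Aggregate mapping results into a loci x samples count matrix.

    A locus' count is the sum over its tag entries (for MMSDK the upstream
    and downstream 17/18-mer forms of one site; for DGE all tags of one
    gene); zero-count loci are retained.  Library sizes are the per-sample
    totals of mapped tags.
    """
    if not assignments:
        raise ValueError("no mapping results given")
    library = assignments[0].library
    locus_ids = library.locus_ids()
    pos = {lid: i for i, lid in enumerate(locus_ids)}
    counts = np.zeros((len(locus_ids), len(assignments)), dtype=np.int64)
    sizes = np.zeros(len(assignments), dtype=np.int64)
    for s, res in enumerate(assignments):
        for lid, n in res.locus_counts().items():
            counts[pos[lid], s] = n
        sizes[s] = res.mapped
    return TagCountMatrix(
        locus_ids=locus_ids,
        samples=[r.sample_id for r in assignments],
        conditions=[r.condition for r in assignments],
        counts=counts,
        library_sizes=sizes,
    )


def pool_by_mean(matrix: TagCountMatrix, group: str) -> tuple[np.ndarray, int]:
    """Pool a condition's replicate libraries into one virtual library.

    Per-locus pooled count = arithmetic mean across the group's samples,
    rounded half-up; pooled library size likewise.
    """
    cols = matrix.columns_for(group)
    if not cols:
        raise ValueError(f"no samples in group {group!r}")
    pooled = round_half_up(matrix.counts[:, cols].mean(axis=1))
    size = int(round_half_up(matrix.library_sizes[cols].mean()))
    return pooled, size


# ---------------------------------------------------------------------------
# annotation blacklist (small-RNA cleanup)


def filter_blacklist(
    tags: ReadSet,
    blacklist: Mapping[str, Iterable[tuple[str, int, int]]],
    locate: Mapping[str, tuple[str, int, int]],
) -> tuple[ReadSet, dict[str, int]]:
    """Remove tags whose unique genome mapping falls in any blacklist interval
    (protein-coding genes, repeats, rRNA/tRNA/sn(o)RNA, ...).

    ``locate`` maps a tag sequence to its unique genomic interval; unlocated
    tags are retained.  Returns the filtered read set and per-category removal
    tallies.  Tags hit by several categories are tallied under each.
    """
    trees: dict[str, dict[str, IntervalTree]] = {}
    for category, intervals in blacklist.items():
        per_chrom: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            per_chrom.setdefault(chrom, IntervalTree()).addi(start, end)
        trees[category] = per_chrom
    kept: Counter = Counter()
    tallies: dict[str, int] = {category: 0 for category in blacklist}
    for seq, mult in tags.reads.items():
        loc = locate.get(seq)
        hit = False
        if loc is not None:
            chrom, start, end = loc
            for category, per_chrom in trees.items():
                if chrom in per_chrom and per_chrom[chrom].overlap(start, end):
                    tallies[category] += mult
                    hit = True
        if not hit:
            kept[seq] = mult
    return ReadSet(sample_id=tags.sample_id, condition=tags.condition, reads=kept), tallies
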