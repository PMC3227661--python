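"""Synthetic genomes, tag-count matrices and reads with known ground truth.

The generator emulates the statistical structure the tag-sequencing analysis
assumes: a genome carrying planted MluI sites (each flanked within 30-500 bp
by NlaIII sites so every locus yields extractable 17-18 nt tags), planted CpG
islands satisfying the three-criteria definition, gene models, and per-locus
tag counts that are independently Poisson per sample -- matching the
distributional assumption of the differential test -- with a chosen subset of
loci spiked by a |log2| >= 1 fold change in the tumor condition.  Nine
matched tumor/normal pairs is the default design.

All randomness derives from one integer seed; per-stage substreams let each
stage be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .digest import GeneModel, MLUI_MOTIF, NLAIII_MOTIF, VirtualTagLibrary, revcomp
from .tags import ReadSet, TagCountMatrix

__all__ = ["SimConfig", "SimTruth", "simulate_genome", "simulate_counts", "simulate_reads"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic data.

    Defaults are a desk-scale rendition of the real design: 9 tumor/normal
    pairs and an expected 100 tags per MluI locus (the real libraries average
    ~214 tags over 21k loci; 100 over 5k loci preserves the per-locus counting
    regime at tractable size).
    """

    genome_length: int = 4_000_000
    n_chromosomes: int = 4
    gc_content: float = 0.41  # human-like background
    n_mlu_sites: int = 5000
    n_genes: int = 600
    n_cgis: int = 300
    n_pairs: int = 9
    library_size: int | None = None  # None: baseline_rate_mean tags per locus
    baseline_rate_mean: float = 100.0
    n_spiked: int = 100
    spike_log2fc: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for name in ("genome_length", "n_chromosomes", "n_mlu_sites", "n_genes",
                     "n_cgis", "n_pairs", "n_spiked"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        if self.n_spiked and self.spike_log2fc < 1.0:
            raise ValueError("spike_log2fc magnitude must be >= 1")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")


@dataclass
class SimTruth:
    spiked_locus_ids: set = field(default_factory=set)
    spike_directions: dict = field(default_factory=dict)  # locus_id -> +1 | -1
    planted_site_positions: dict = field(default_factory=dict)  # chrom -> [pos]
    planted_cgi_intervals: list = field(default_factory=list)  # (chrom, start, end)
    gene_models: list = field(default_factory=list)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _random_bases(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


#: fraction of background CpG dinucleotides rewritten; emulates the genome-wide
#: CpG depletion (obs/exp ~0.25) that makes CpG islands stand out
_CPG_DEPLETION = 0.75


def _scrubbed_background(
    rng: np.random.Generator, length: int, gc: float, forbidden: Sequence[str]
) -> str:
    """i.i.d. background of the requested GC, CpG-depleted; forbidden motifs
    are re-drawn."""
    arr = _random_bases(rng, length, gc)
    if length > 1:
        cpg = np.nonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))[0]
        hit = cpg[rng.random(len(cpg)) < _CPG_DEPLETION]
        arr[hit + 1] = np.where(rng.random(len(hit)) < 0.5, ord("A"), ord("T"))
    seq = arr.tobytes().decode("ascii")
    for _ in range(1000):
        dirty = False
        for motif in forbidden:
            i = seq.find(motif)
            while i != -1:
                dirty = True
                repl = _random_bases(rng, len(motif), gc).tobytes().decode("ascii")
                seq = seq[:i] + repl + seq[i + len(motif):]
                i = seq.find(motif, i)
            if dirty:
                break
        if not dirty:
            return seq
    raise RuntimeError("could not scrub background sequence")  # pragma: no cover


def _cgi_sequence(rng: np.random.Generator, length: int) -> str:
    """CpG-island-like sequence guaranteed to satisfy the three criteria."""
    p = np.array([0.15, 0.35, 0.35, 0.15])  # A, C, G, T
    for _ in range(200):
        seq = rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")
        if MLUI_MOTIF in seq:
            continue
        c, g = seq.count("C"), seq.count("G")
        cpg = seq.count("CG")
        if (c + g) / length >= 0.55 and cpg * length / max(c * g, 1) > 0.7:
            return seq
    raise RuntimeError("could not draw a CpG-island sequence")  # pragma: no cover


def _make_block(rng: np.random.Generator, gc: float) -> tuple[str, int]:
    """One planted locus: CATG ... ACGCGT ... CATG with 30-500 bp flanks.

    Returns the block sequence and the MluI motif offset within it.  Flank
    backgrounds are scrubbed of both motifs so the planted CATGs are the
    nearest NlaIII boundaries and both tags are extractable.
    """
    gap_u = int(rng.integers(30, 491))
    gap_d = int(rng.integers(30, 491))
    forbidden = (MLUI_MOTIF, NLAIII_MOTIF)
    bg_u = _scrubbed_background(rng, gap_u, gc, forbidden)
    bg_d = _scrubbed_background(rng, gap_d, gc, forbidden)
    block = NLAIII_MOTIF + bg_u + MLUI_MOTIF + bg_d + NLAIII_MOTIF
    return block, len(NLAIII_MOTIF) + gap_u


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], SimTruth]:
    """Generate a multi-chromosome genome with planted MluI loci and CpG islands.

    Background contains no accidental ACGCGT (rewritten during generation and
    at assembly junctions), so the planted coordinates are the complete MluI
    site set.  Accidental CATG outside the planted flanks is allowed.
    """
    rng = _rng(config, 0)
    truth = SimTruth()
    n_chrom = config.n_chromosomes
    chrom_lengths = [config.genome_length // n_chrom] * n_chrom
    chrom_lengths[-1] += config.genome_length - sum(chrom_lengths)

    features: list[list[tuple[str, str, int]]] = [[] for _ in range(n_chrom)]
    for i in range(config.n_mlu_sites):
        block, offset = _make_block(rng, config.gc_content)
        features[i % n_chrom].append(("mlu", block, offset))
    for i in range(config.n_cgis):
        seq = _cgi_sequence(rng, int(rng.integers(250, 601)))
        features[(i + config.n_mlu_sites) % n_chrom].append(("cgi", seq, 0))

    genome: dict[str, str] = {}
    min_gap = 10
    for c in range(n_chrom):
        name = f"chr{c + 1}"
        feats = features[c]
        rng.shuffle(feats)
        feat_total = sum(len(s) for _, s, _ in feats)
        slack = chrom_lengths[c] - feat_total - (len(feats) + 1) * min_gap
        if slack < 0:
            raise ValueError(
                f"infeasible packing: {config.n_mlu_sites} sites / {config.n_cgis} CGIs "
                f"do not fit in genome_length {config.genome_length}"
            )
        gaps = min_gap + (
            rng.multinomial(slack, np.ones(len(feats) + 1) / (len(feats) + 1))
            if feats
            else np.array([slack])
        )
        parts: list[str] = []
        pos = 0
        placed: list[tuple[int, int]] = []  # feature extents: never mutated
        truth.planted_site_positions[name] = []
        for i, (kind, seq, offset) in enumerate(feats):
            bg = _scrubbed_background(rng, int(gaps[i]), config.gc_content, (MLUI_MOTIF,))
            parts.append(bg)
            pos += len(bg)
            placed.append((pos, pos + len(seq)))
            if kind == "mlu":
                truth.planted_site_positions[name].append(pos + offset)
            else:
                truth.planted_cgi_intervals.append((name, pos, pos + len(seq)))
            parts.append(seq)
            pos += len(seq)
        parts.append(
            _scrubbed_background(rng, int(gaps[len(feats)]), config.gc_content, (MLUI_MOTIF,))
        )
        genome[name] = _scrub_junctions(
            "".join(parts), rng, set(truth.planted_site_positions[name]), placed,
        )
    truth.gene_models = _plant_genes(rng, config, genome, truth)
    return genome, truth


def _scrub_junctions(
    seq: str,
    rng: np.random.Generator,
    planted: set[int],
    protected: list[tuple[int, int]],
) -> str:
    """Rewrite ACGCGT occurrences created at assembly junctions.

    Mutates a base of the occurrence lying outside every protected interval;
    such a base always exists because planted features are internally
    scrubbed and separated by background.
    """
    protected = sorted(protected)
    arr = bytearray(seq, "ascii")
    guard = 0
    while True:
        s = arr.find(MLUI_MOTIF.encode("ascii"))
        pos = -1
        while s != -1:
            if s not in planted:
                pos = s
                break
            s = arr.find(MLUI_MOTIF.encode("ascii"), s + 1)
        if pos == -1:
            return arr.decode("ascii")
        for j in range(pos, pos + len(MLUI_MOTIF)):
            if not any(lo <= j < hi for lo, hi in protected):
                old = arr[j]
                choices = [b for b in b"ACGT" if b != old]
                arr[j] = int(rng.choice(choices))
                break
        else:  # pragma: no cover - cannot happen by construction
            raise RuntimeError("accidental motif fully inside protected intervals")
        guard += 1
        if guard > 10000:  # pragma: no cover
            raise RuntimeError("junction scrubbing did not converge")


def _plant_genes(
    rng: np.random.Generator,
    config: SimConfig,
    genome: Mapping[str, str],
    truth: SimTruth,
) -> list[GeneModel]:
    """Gene models over the assembled genome; about half of the CpG islands
    host a TSS so CGI-promoter loci exist."""
    genes: list[GeneModel] = []
    chroms = list(genome)
    cgi_slots = truth.planted_cgi_intervals[: config.n_genes // 2]
    for i in range(config.n_genes):
        if i < len(cgi_slots):
            chrom, cgi_start, _ = cgi_slots[i]
            start = cgi_start
            strand = "+"
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, max(1, len(genome[chrom]) - 12000)))
            strand = "+" if rng.random() < 0.5 else "-"
        span = int(rng.integers(2000, 10001))
        end = min(start + span, len(genome[chrom]))
        if end - start < 600:
            continue
        n_exons = int(rng.integers(2, 5))
        bounds = np.sort(rng.choice(np.arange(start + 1, end - 1), 2 * n_exons, replace=False))
        exons = tuple((int(bounds[2 * j]), int(bounds[2 * j + 1])) for j in range(n_exons))
        exons = tuple((s, e) for s, e in exons if e > s)
        genes.append(
            GeneModel(
                gene_id=f"gene{i + 1:04d}", chrom=chrom, start=start, end=end,
                strand=strand, exons=exons,
            )
        )
    return genes


def simulate_counts(
    config: SimConfig,
    library: VirtualTagLibrary,
    truth: SimTruth | None = None,
    dispersion: float | None = None,
) -> tuple[TagCountMatrix, SimTruth]:
    """Poisson per-locus tag counts for ``n_pairs`` tumor/normal pairs.

    Every locus has rate ``baseline_rate_mean`` (scaled so the expected
    library total is ``library_size`` when given); spiked loci multiply the
    tumor rate by 2^(+-spike_log2fc).  ``dispersion`` switches on
    negative-binomial (Gamma-Poisson) generation for robustness studies and
    is off by default -- the analysis assumes Poisson counts.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    if truth is None:
        truth = SimTruth()
    rng = _rng(config, 1)
    loci = library.locus_ids()
    n_loci = len(loci)
    scale = 1.0
    if config.library_size is not None:
        scale = config.library_size / (n_loci * config.baseline_rate_mean)
    base = np.full(n_loci, config.baseline_rate_mean * scale)

    n_spiked = min(config.n_spiked, n_loci)
    spiked_idx = rng.choice(n_loci, size=n_spiked, replace=False)
    directions = rng.choice([-1, 1], size=n_spiked)
    tumor_rate = base.copy()
    tumor_rate[spiked_idx] *= np.power(2.0, directions * config.spike_log2fc)

    samples, conditions, cols = [], [], []
    for p in range(1, config.n_pairs + 1):
        samples.append(f"T{p}")
        conditions.append("tumor")
        cols.append(tumor_rate)
    for p in range(1, config.n_pairs + 1):
        samples.append(f"N{p}")
        conditions.append("normal")
        cols.append(base)
    rates = np.column_stack(cols)
    if dispersion is not None and dispersion > 0:
        shape = 1.0 / dispersion
        rates = rng.gamma(shape, rates / shape)
    counts = rng.poisson(rates)
    matrix = TagCountMatrix(
        locus_ids=loci,
        samples=samples,
        conditions=conditions,
        counts=counts,
        library_sizes=counts.sum(axis=0),
    )
    truth.spiked_locus_ids = {loci[i] for i in spiked_idx}
    truth.spike_directions = {loci[i]: int(d) for i, d in zip(spiked_idx, directions)}
    return matrix, truth


def simulate_reads(
    genome: Mapping[str, str],
    library: VirtualTagLibrary,
    counts: TagCountMatrix,
    adapter: str = "",
    error_rate: float = 0.0,
    revcomp_fraction: float = 0.0,
    seed: int = 0,
) -> list[ReadSet]:
    """Emit single-end reads (tag + 3' adapter) realizing a count matrix.

    With ``error_rate`` 0 and no adapter the reads are the bare tag
    sequences, and the clipped multiset per sample equals the count matrix
    exactly.  Per-base substitution errors are applied at ``error_rate``;
    ``revcomp_fraction`` reverse-complements that fraction of reads for
    orientation stress-testing.  An adapter of 1-5 bases is rejected as
    unclippable.
    """
    if adapter and len(adapter) < 6:
        raise ValueError("adapter must be empty or at least 6 bases")
    entries_by_locus: dict[str, list] = {}
    for e in library.entries:
        entries_by_locus.setdefault(e.locus_id, []).append(e)
    for lid in counts.locus_ids:
        if lid not in entries_by_locus:
            raise ValueError(f"locus {lid!r} has no tag sequence in the library")
    rng = np.random.default_rng([seed, 2])
    readsets: list[ReadSet] = []
    for s, sample in enumerate(counts.samples):
        reads: list[str] = []
        for i, lid in enumerate(counts.locus_ids):
            c = int(counts.counts[i, s])
            if c == 0:
                continue
            entries = entries_by_locus[lid]
            if len(entries) == 1:
                split = [c]
            else:
                k = int(rng.binomial(c, 0.5))
                split = [k, c - k]
                if len(entries) > 2:  # DGE gene loci may carry many entries
                    split = rng.multinomial(c, np.ones(len(entries)) / len(entries))
            for e, n in zip(entries, split):
                tag = e.tag_sequence_18nt or e.tag_sequence_17nt
                reads.extend([tag + adapter] * int(n))
        if error_rate > 0:
            reads = [_mutate(r, error_rate, rng) for r in reads]
        if revcomp_fraction > 0:
            reads = [
                revcomp(r) if rng.random() < revcomp_fraction else r for r in reads
            ]
        readsets.append(ReadSet.from_sequences(sample, counts.conditions[s], reads))
    return readsets


def _mutate(read: str, error_rate: float, rng: np.random.Generator) -> str:
    hits = np.nonzero(rng.random(len(read)) < error_rate)[0]
    if len(hits) == 0:
        return read
    arr = bytearray(read, "ascii")
    for i in hits:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = int(rng.choice(choices))
    return bytes(arr).decode("ascii")
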