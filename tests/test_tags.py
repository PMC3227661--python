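"""Adapter clipping, read filtering, 1-mismatch mapping and counting."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from tagomics import (
    ReadSet,
    TagEntry,
    TagIndex,
    VirtualTagLibrary,
    clip_adapter,
    count_per_locus,
    filter_blacklist,
    filter_reads,
    map_tags,
    pool_by_mean,
    revcomp,
)

ADAPTER = "TCGTATGCCGTCTTCTGCTTG"
dna = st.text(alphabet="ACGT", min_size=17, max_size=18)


def _mutate(seq: str, pos: int) -> str:
    repl = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
    return seq[:pos] + repl + seq[pos + 1 :]


class TestClipAdapter:
    def test_exact_full_adapter_clipped(self):
        tag = "GATTACAGATTACAGATT"
        assert clip_adapter(tag + ADAPTER, ADAPTER) == tag

    def test_no_similarity_unchanged(self):
        read = "A" * 30
        assert clip_adapter(read, ADAPTER) == read

    def test_adapter_with_one_substitution_clipped_same_position(self):
        tag = "GATTACAGATTACAGATT"
        for pos in range(len(ADAPTER)):
            read = tag + _mutate(ADAPTER, pos)
            assert clip_adapter(read, ADAPTER) == tag, f"substitution at {pos}"

    def test_truncated_adapter_at_read_end(self):
        tag = "GATTACAGATTACAGATT"
        assert clip_adapter(tag + ADAPTER[:10], ADAPTER) == tag

    def test_whole_read_is_adapter(self):
        assert clip_adapter(ADAPTER[:15], ADAPTER) == ""

    def test_empty_read_noop(self):
        assert clip_adapter("", ADAPTER) == ""

    def test_short_adapter_rejected(self):
        with pytest.raises(ValueError):
            clip_adapter("ACGTACGT", "ACG000"[:5])

    @settings(max_examples=200, derandomize=True)
    @given(tag=dna, cut=st.integers(min_value=6, max_value=len(ADAPTER)))
    def test_idempotent(self, tag, cut):
        # genomic tags that themselves resemble the adapter are clipped on
        # sight and excluded: threshold clipping cannot be idempotent on them
        assume(clip_adapter(tag, ADAPTER) == tag)
        read = tag + ADAPTER[:cut]
        once = clip_adapter(read, ADAPTER)
        assert clip_adapter(once, ADAPTER) == once


class TestFilterReads:
    def test_n_containing_reads_dropped(self):
        rs = ReadSet.from_sequences("s", "tumor", ["ACGTN" + "A" * 13, "A" * 18])
        out = filter_reads(rs, drop_n=True)
        assert set(out.reads) == {"A" * 18}

    def test_singletons_dropped_in_mrna_mode(self):
        rs = ReadSet("s", "tumor", Counter({"C" * 18: 3, "G" * 18: 1}))
        out = filter_reads(rs, drop_singletons=True)
        assert dict(out.reads) == {"C" * 18: 3}

    def test_min_length_mirna_mode(self):
        rs = ReadSet.from_sequences("s", "tumor", ["A" * 17, "C" * 18])
        out = filter_reads(rs, min_len=18)
        assert set(out.reads) == {"C" * 18}

    def test_dedupe_retains_multiplicity_as_count(self):
        rs = ReadSet.from_sequences("s", "tumor", ["A" * 18] * 5)
        out = filter_reads(rs, dedupe=True)
        assert out.reads["A" * 18] == 5


def _library(seqs18: list[str]) -> VirtualTagLibrary:
    entries = [
        TagEntry(f"l{i}:up", f"l{i}", "c", 0, 18, s[:17], s, "upstream")
        for i, s in enumerate(seqs18)
    ]
    return VirtualTagLibrary(entries, kind="MMSDK")


class TestMapTags:
    def test_exact_unique_hit(self):
        lib = _library(["ACGTACGTACGTACGTAC", "TTTTGGGGCCCCAAAATT"])
        rs = ReadSet.from_sequences("s", "tumor", ["ACGTACGTACGTACGTAC"] * 3)
        res = map_tags(rs, lib)
        assert res.mapped == 3 and res.locus_counts() == {"l0": 3}

    def test_distance_two_unmapped(self):
        lib = _library(["A" * 18])
        rs = ReadSet.from_sequences("s", "tumor", ["A" * 16 + "CC"])
        res = map_tags(rs, lib)
        assert res.unmapped == 1 and res.mapped == 0

    def test_two_loci_same_tag_ambiguous(self):
        seq = "ACGTACGTACGTACGTAC"
        lib = VirtualTagLibrary(
            [
                TagEntry("l0:up", "l0", "c", 0, 18, seq[:17], seq, "upstream"),
                TagEntry("l1:up", "l1", "c", 50, 68, seq[:17], seq, "upstream"),
            ],
            kind="MMSDK",
        )
        res = map_tags(ReadSet.from_sequences("s", "tumor", [seq]), lib)
        assert res.ambiguous == 1 and res.mapped == 0

    def test_reverse_complement_maps_to_same_locus(self):
        seq = "ACGTTTCGGATCCGAAAT"
        lib = _library([seq])
        res = map_tags(ReadSet.from_sequences("s", "tumor", [revcomp(seq)]), lib)
        assert res.locus_counts() == {"l0": 1}

    def test_one_mismatch_rescued(self):
        seq = "ACGTTTCGGATCCGAAAT"
        lib = _library([seq])
        res = map_tags(ReadSet.from_sequences("s", "tumor", [_mutate(seq, 9)]), lib)
        assert res.locus_counts() == {"l0": 1}

    def test_empty_library_all_unmapped(self):
        lib = VirtualTagLibrary([], kind="MMSDK")
        res = map_tags(ReadSet.from_sequences("s", "tumor", ["A" * 18]), lib)
        assert res.unmapped == 1

    def test_conservation_mapped_ambiguous_unmapped(self, small_sim):
        lib = small_sim["library"]
        rng = np.random.default_rng(4)
        seqs = [e.tag_sequence_18nt for e in lib.entries]
        reads = [
            _mutate(seqs[rng.integers(len(seqs))], int(rng.integers(18)))
            for _ in range(500)
        ]
        rs = ReadSet.from_sequences("s", "tumor", reads)
        res = map_tags(rs, lib)
        assert res.mapped + res.ambiguous + res.unmapped == 500

    def test_agrees_with_bruteforce_hamming(self):
        """Random mutated tags vs an all-pairs Hamming scan oracle."""
        rng = np.random.default_rng(99)
        seqs = ["".join(rng.choice(list("ACGT"), 18)) for _ in range(60)]
        lib = _library(seqs)
        index = TagIndex(lib)

        def oracle(read):
            dists = []
            for i, e in enumerate(lib.entries):
                for form in (e.tag_sequence_18nt, revcomp(e.tag_sequence_18nt)):
                    d = sum(a != b for a, b in zip(read, form))
                    dists.append((d, i))
            best = min(d for d, _ in dists)
            hits = {i for d, i in dists if d == best}
            if best > 1:
                return "unmapped"
            return next(iter(hits)) if len(hits) == 1 else "ambiguous"

        for _ in range(300):
            base = seqs[rng.integers(len(seqs))]
            read = base
            for _ in range(rng.integers(0, 3)):  # 0-2 substitutions
                read = _mutate(read, int(rng.integers(18)))
            if rng.random() < 0.5:
                read = revcomp(read)
            assert index.assign(read) == oracle(read), read


class TestCounting:
    def test_up_and_down_tags_sum_per_locus(self):
        up, down = "ACGTACGTACGTACGTAC", "GGGGTTTTAAAACCCCGG"
        lib = VirtualTagLibrary(
            [
                TagEntry("l0:up", "l0", "c", 0, 18, up[:17], up, "upstream"),
                TagEntry("l0:down", "l0", "c", 40, 58, down[:17], down, "downstream"),
                TagEntry("l1:up", "l1", "c", 90, 108, "T" * 17, "T" * 18, "upstream"),
            ],
            kind="MMSDK",
        )
        rs = ReadSet.from_sequences("s", "tumor", [up] * 3 + [down] * 2)
        matrix = count_per_locus([map_tags(rs, lib)])
        frame = matrix.to_frame()
        assert frame.loc["l0", "s"] == 5
        assert frame.loc["l1", "s"] == 0  # zero-count locus retained
        assert matrix.library_sizes[0] == 5

    def test_pool_by_mean_examples(self):
        from tagomics import TagCountMatrix

        matrix = TagCountMatrix(
            locus_ids=["a", "b"],
            samples=["t1", "t2", "t3"],
            conditions=["tumor"] * 3,
            counts=np.array([[2, 4, 6], [0, 0, 0]]),
            library_sizes=np.array([10, 10, 10]),
        )
        pooled, size = pool_by_mean(matrix, "tumor")
        assert list(pooled) == [4, 0] and size == 10

    def test_pool_rounds_half_up(self):
        from tagomics import TagCountMatrix

        matrix = TagCountMatrix(
            locus_ids=["a"],
            samples=["t1", "t2"],
            conditions=["tumor"] * 2,
            counts=np.array([[1, 2]]),
            library_sizes=np.array([3, 4]),
        )
        pooled, size = pool_by_mean(matrix, "tumor")
        assert list(pooled) == [2]  # 1.5 rounds half-up
        assert size == 4  # 3.5 rounds half-up

    def test_pool_empty_group_fails(self):
        from tagomics import TagCountMatrix

        matrix = TagCountMatrix(["a"], ["t1"], ["tumor"], np.array([[1]]), np.array([1]))
        with pytest.raises(ValueError):
            pool_by_mean(matrix, "normal")


class TestBlacklist:
    def test_categories_tallied_and_filtered(self):
        rs = ReadSet.from_sequences("s", "tumor", ["AAAA", "CCCC", "GGGG"])
        locate = {"AAAA": ("c", 10, 14), "CCCC": ("c", 100, 104)}
        blacklist = {"rRNA": [("c", 0, 50)], "tRNA": [("c", 200, 300)]}
        kept, tallies = filter_blacklist(rs, blacklist, locate)
        assert set(kept.reads) == {"CCCC", "GGGG"}  # unlocated reads retained
        assert tallies == {"rRNA": 1, "tRNA": 0}

    def test_empty_blacklist_identity(self):
        rs = ReadSet.from_sequences("s", "tumor", ["AAAA"])
        kept, tallies = filter_blacklist(rs, {}, {})
        assert kept.reads == rs.reads and tallies == {}
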