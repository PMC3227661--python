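"""Virtual digestion, tag extraction, CpG islands and locus annotation."""

import numpy as np
import pytest
from _oracles import naive_find, naive_mmsdk

from tagomics import (
    GeneModel,
    MLUI_MOTIF,
    NLAIII_MOTIF,
    annotate_loci,
    build_dge_library,
    build_mmsdk_library,
    detect_cgi,
    find_sites,
    revcomp,
)


class TestFindSites:
    def test_tandem_motifs(self):
        sites = find_sites({"c": "ACGCGTACGCGT"}, "ACGCGT")
        assert list(sites.sites["c"]) == [0, 6]
        assert sites.enzyme == "MluI" and sites.cut_offset == 1

    def test_absent_motif(self):
        assert list(find_sites({"c": "AAAAAA"}, "ACGCGT").sites["c"]) == []

    def test_overlapping_occurrences_are_reported(self):
        # CATGCATG contains CATG at 0 and 4; ATATA contains ATA at 0 and 2
        assert list(find_sites({"c": "ATATA"}, "ATA").sites["c"]) == [0, 2]

    @pytest.mark.parametrize("motif", ["", "ACGN", "acgt"])
    def test_invalid_motif_rejected(self, motif):
        with pytest.raises(ValueError):
            find_sites({"c": "ACGT"}, motif)


class TestMMSDKLibrary:
    def _flanked_site(self, up=40, down=60):
        rng = np.random.default_rng(0)
        bg = lambda n: "".join(  # noqa: E731 - AT-only filler, no motifs possible
            rng.choice(list("AT"), n)
        )
        left, mid_u, mid_d, right = bg(50), bg(up - 4), bg(down - 4), bg(50)
        seq = left + "CATG" + mid_u + "ACGCGT" + mid_d + "CATG" + right
        return seq

    def test_single_flanked_site_two_tags(self):
        seq = self._flanked_site()
        genome = {"c": seq}
        mlu = find_sites(genome, MLUI_MOTIF)
        nla = find_sites(genome, NLAIII_MOTIF)
        fragments, lib = build_mmsdk_library(genome, mlu, nla)
        assert len(fragments) == 2 and len(lib) == 2
        assert all(f.has_internal_nla for f in fragments)
        oracle = naive_mmsdk(seq)
        got = [(f.start, f.end, f.side, f.has_internal_nla) for f in fragments]
        assert got == [t[:4] for t in oracle]
        assert [e.tag_sequence_18nt for e in lib.entries] == [t[4] for t in oracle]

    def test_no_nlaiii_anywhere_no_tags(self):
        seq = "A" * 60 + "ACGCGT" + "T" * 60
        genome = {"c": seq}
        fragments, lib = build_mmsdk_library(
            genome, find_sites(genome, MLUI_MOTIF), find_sites(genome, NLAIII_MOTIF)
        )
        assert len(fragments) == 2 and len(lib) == 0
        assert not any(f.has_internal_nla for f in fragments)

    def test_short_flank_yields_fragment_but_no_tag(self):
        # NlaIII boundary only 10 bases from the cut: fragment, no 18-mer
        seq = "T" * 50 + "CATG" + "A" * 9 + "ACGCGT" + "T" * 50
        genome = {"c": seq}
        fragments, lib = build_mmsdk_library(
            genome, find_sites(genome, MLUI_MOTIF), find_sites(genome, NLAIII_MOTIF)
        )
        up = [f for f in fragments if f.side == "upstream"]
        assert up and up[0].has_internal_nla
        assert all(e.side != "upstream" for e in lib.entries)

    def test_empty_mlu_list_empty_library(self):
        genome = {"c": "CATG" + "A" * 40 + "CATG"}
        fragments, lib = build_mmsdk_library(
            genome, find_sites(genome, MLUI_MOTIF), find_sites(genome, NLAIII_MOTIF)
        )
        assert fragments == [] and len(lib) == 0

    def test_oracle_equivalence_on_random_genomes(self):
        """find_sites + build_mmsdk_library vs the naive quadratic oracle."""
        rng = np.random.default_rng(12345)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), 20_000))
            genome = {"c": seq}
            mlu = find_sites(genome, MLUI_MOTIF)
            assert list(mlu.sites["c"]) == naive_find(seq, MLUI_MOTIF)
            nla = find_sites(genome, NLAIII_MOTIF)
            fragments, lib = build_mmsdk_library(genome, mlu, nla)
            oracle = naive_mmsdk(seq)
            assert [(f.start, f.end, f.side, f.has_internal_nla) for f in fragments] == [
                t[:4] for t in oracle
            ]
            assert [e.tag_sequence_18nt for e in lib.entries] == [
                t[4] for t in oracle if t[4] is not None
            ]

    def test_tag_conservation_invariants(self, small_sim):
        genome, lib = small_sim["genome"], small_sim["library"]
        fragments, mlu = small_sim["fragments"], small_sim["mlu"]
        assert len(fragments) == 2 * mlu.n_sites()
        assert len(lib) <= len(fragments)
        for e in lib.entries:
            stored = genome[e.chromosome][e.start : e.end]
            expect = stored if e.side == "upstream" else revcomp(stored)
            assert expect == e.tag_sequence_18nt
            assert e.tag_sequence_18nt.startswith(e.tag_sequence_17nt)
        per_locus = {}
        for e in lib.entries:
            per_locus[e.locus_id] = per_locus.get(e.locus_id, 0) + 1
        assert max(per_locus.values()) <= 2


class TestDGELibrary:
    def test_tag_next_to_transcript_catg_assigned_to_gene(self):
        tag = "GATTACAGATTACAGAT"
        seq = "T" * 30 + "CATG" + tag + "T" * 30
        genome = {"c": seq}
        gene = GeneModel("g1", "c", 25, 60)
        lib = build_dge_library(genome, find_sites(genome, NLAIII_MOTIF), [gene])
        fwd = [e for e in lib.entries if e.side == "+"]
        assert any(e.tag_sequence_17nt == tag and "g1" in e.gene_ids for e in fwd)

    def test_no_catg_empty_library(self):
        genome = {"c": "A" * 100}
        lib = build_dge_library(genome, find_sites(genome, NLAIII_MOTIF), [])
        assert len(lib) == 0

    def test_gene_assignment_and_strand_twins(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 3000))
        genome = {"c": seq}
        gene = GeneModel("g1", "c", 1000, 2000)
        nla = find_sites(genome, NLAIII_MOTIF)
        lib = build_dge_library(genome, nla, [gene])
        # brute-force enumeration of expected entries
        expected = []
        for g in naive_find(seq, "CATG"):
            if g + 4 + 17 <= len(seq):
                expected.append(("+", seq[g + 4 : g + 21]))
            if g - 17 >= 0:
                expected.append(("-", revcomp(seq[g - 17 : g])))
        assert [(e.side, e.tag_sequence_17nt) for e in lib.entries] == expected
        for e in lib.entries:
            in_gene = e.start < 2000 and e.end > 1000
            assert ("g1" in e.gene_ids) == in_gene
            assert (e.locus_id == "g1") == in_gene


class TestDetectCGI:
    def test_pure_cg_repeat_single_region(self):
        genome = {"c": "CG" * 150}
        regions = detect_cgi(genome)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (0, 300)
        assert r.gc_fraction == 1.0 and r.obs_exp_cpg == pytest.approx(2.0)

    def test_gc_without_cpg_dinucleotides_rejected(self):
        assert detect_cgi({"c": "G" * 150 + "C" * 150}) == []

    def test_at_rich_rejected(self):
        assert detect_cgi({"c": "A" * 300}) == []

    def test_emitted_regions_pass_direct_recheck(self, small_sim):
        genome = small_sim["genome"]
        for r in detect_cgi(genome):
            seq = genome[r.chromosome][r.start : r.end]
            length = len(seq)
            c, g, cpg = seq.count("C"), seq.count("G"), seq.count("CG")
            assert length > 200
            assert (c + g) / length >= 0.5
            assert cpg * length / (c * g) > 0.6

    def test_invariant_to_chromosome_order(self, small_sim):
        genome = small_sim["genome"]
        flipped = dict(reversed(list(genome.items())))
        key = lambda r: (r.chromosome, r.start, r.end)  # noqa: E731
        assert sorted(map(key, detect_cgi(genome))) == sorted(map(key, detect_cgi(flipped)))

    def test_short_chromosome_skipped(self):
        assert detect_cgi({"c": "CG" * 50}) == []  # shorter than the window


class TestAnnotateLoci:
    def test_planted_cgi_promoter_and_intergenic(self, small_sim):
        genome, truth, lib = small_sim["genome"], small_sim["truth"], small_sim["library"]
        cgis = detect_cgi(genome)
        ann = annotate_loci(lib, truth.gene_models, cgis, promoter_window=1000,
                            chromosomes=genome)
        assert len(ann) == len(lib.locus_ids())
        classes = {a.region_class for a in ann}
        assert classes <= {"CGI-promoter", "non-CGI-promoter", "exon", "intron", "intergenic"}
        for a in ann:
            if a.region_class == "intergenic":
                assert a.gene_ids == frozenset()
            else:
                assert a.gene_ids

    def test_intron_locus(self):
        from tagomics import VirtualTagLibrary, TagEntry

        entry = TagEntry("l1:up", "l1", "c", 5000, 5018, "A" * 17, "A" * 18, "upstream")
        lib = VirtualTagLibrary([entry], kind="MMSDK")
        gene = GeneModel("g1", "c", 1000, 9000, "+", exons=((1000, 1200), (8000, 9000)))
        ann = annotate_loci(lib, [gene], [], promoter_window=500)
        assert ann[0].region_class == "intron" and ann[0].gene_ids == {"g1"}

    def test_unknown_chromosome_named_in_error(self):
        from tagomics import VirtualTagLibrary

        lib = VirtualTagLibrary([], kind="MMSDK")
        gene = GeneModel("g1", "chrZZ", 0, 100)
        with pytest.raises(ValueError, match="chrZZ"):
            annotate_loci(lib, [gene], [], chromosomes=["chr1"])
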