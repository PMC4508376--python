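import numpy as np
import pytest

import guidepool as gp
from guidepool.design import SITE_LEN, SPACER_LEN, GuideCandidate
from guidepool.genome_io import TranscriptModel, reverse_complement
from guidepool.regions import SharedRegion, shared_regions


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def covering_transcript(length, strand="+"):
    return [TranscriptModel("t1", "g", strand, [(0, length)])]


def full_region(length):
    return SharedRegion("g", "c", 0, length, 1, 0)


class TestCountMismatches:
    def test_identity(self):
        s = "ATGCATGCATGCATGCATGC"
        assert gp.count_mismatches(s, s) == 0

    def test_constructed_positions(self):
        a = "ATGCATGCATGCATGCATGC"
        b = list(a)
        for i in (2, 9, 19):
            b[i] = {"A": "C", "T": "G", "G": "T", "C": "A"}[b[i]]
        assert gp.count_mismatches(a, "".join(b)) == 3

    def test_symmetry_on_random_pairs(self, rng):
        for _ in range(50):
            a, b = random_dna(rng, 20), random_dna(rng, 20)
            expected = sum(x != y for x, y in zip(a, b))
            assert gp.count_mismatches(a, b) == expected == gp.count_mismatches(b, a)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gp.count_mismatches("ACGT", "ACG")


class TestEnumerateCandidates:
    def test_single_constructed_site(self):
        seq = "G" + "T" * 19 + "AGG"  # one + strand N20-NGG window
        genome = gp.GenomeSequence({"c": seq})
        cands = gp.enumerate_candidates(
            full_region(len(seq)), genome, covering_transcript(len(seq))
        )
        assert len(cands) == 1
        (c,) = cands
        assert (c.strand, c.protospacer, c.pam) == ("+", "G" + "T" * 19, "AGG")

    def test_contig_shorter_than_site_yields_nothing(self):
        seq = "G" * 22
        genome = gp.GenomeSequence({"c": seq})
        assert gp.enumerate_candidates(
            full_region(22), genome, covering_transcript(22)
        ) == []

    def test_strand_symmetry_with_reverse_complement(self, rng):
        for _ in range(20):
            seq = random_dna(rng, 300)
            rc = reverse_complement(seq)
            fwd = gp.enumerate_candidates(
                full_region(300), gp.GenomeSequence({"c": seq}),
                covering_transcript(300),
            )
            rev = gp.enumerate_candidates(
                full_region(300), gp.GenomeSequence({"c": rc}),
                covering_transcript(300),
            )
            # candidate (start, strand) maps to (L - end, opposite strand)
            a = sorted((c.start, c.strand, c.protospacer) for c in fwd)
            b = sorted(
                (300 - c.start - SPACER_LEN, "+-"[c.strand == "+"], c.protospacer)
                for c in rev
            )
            assert a == b

    def test_windows_with_n_are_skipped(self):
        seq = "G" + "T" * 9 + "N" + "T" * 9 + "AGG"
        genome = gp.GenomeSequence({"c": seq})
        assert gp.enumerate_candidates(
            full_region(len(seq)), genome, covering_transcript(len(seq))
        ) == []


def brute_force_sites(seq):
    """Sliding 23-mer oracle for the NGG/NAG site census of one contig."""
    sites = set()
    for p in range(len(seq) - SITE_LEN + 1):
        window = seq[p : p + SITE_LEN]
        spacer, pam = window[:SPACER_LEN], window[SPACER_LEN:]
        if "N" not in spacer and pam[1:] in ("GG", "AG"):
            sites.add((p, "+", "NGG" if pam[1:] == "GG" else "NAG", spacer))
        rc = reverse_complement(window)
        spacer, pam = rc[:SPACER_LEN], rc[SPACER_LEN:]
        if "N" not in spacer and pam[1:] in ("GG", "AG"):
            sites.add((p + 3, "-", "NGG" if pam[1:] == "GG" else "NAG", spacer))
    return sites


class TestSiteIndex:
    def test_matches_sliding_window_oracle(self, rng):
        for seq in ["AAAAAAAAAAAAAAAAAAAAAAGGA"] + [
            random_dna(rng, 400) for _ in range(10)
        ]:
            index = gp.build_site_index(gp.GenomeSequence({"c": seq}))
            got = {
                (start, strand, pam, spacer)
                for (_, start, strand, pam), spacer in zip(index.meta, index.spacers)
            }
            assert got == brute_force_sites(seq)

    def test_all_a_genome_has_no_sites(self):
        index = gp.build_site_index(gp.GenomeSequence({"c": "A" * 100}))
        assert len(index) == 0

    def test_reverse_complement_swaps_strands(self, rng):
        seq = random_dna(rng, 500)
        fwd = gp.build_site_index(gp.GenomeSequence({"c": seq}))
        rev = gp.build_site_index(gp.GenomeSequence({"c": reverse_complement(seq)}))
        assert len(fwd) == len(rev)
        a = sorted(zip((m[2] for m in fwd.meta), fwd.spacers))
        b = sorted(zip(("+-"[m[2] == "+"] for m in rev.meta), rev.spacers))
        assert a == b


def candidate_at(index, sid):
    contig, start, strand, _ = index.meta[sid]
    return GuideCandidate("g", contig, start, strand, index.spacers[sid], "AGG", 0)


class TestFindOfftargets:
    def test_agrees_with_bruteforce_on_random_genomes(self, rng):
        for _ in range(10):
            seq = random_dna(rng, 8000)
            genome = gp.GenomeSequence({"c": seq})
            index = gp.build_site_index(genome)
            for sid in rng.choice(len(index), size=3, replace=False):
                cand = candidate_at(index, int(sid))
                for k in range(4):
                    assert gp.find_offtargets(cand, index, k) == \
                        gp.offtargets_bruteforce(cand, genome, k)

    def test_exact_duplicate_is_zero_mismatch_hit(self, rng):
        seq = random_dna(rng, 2000)
        genome = gp.GenomeSequence({"c": seq})
        index = gp.build_site_index(genome)
        cand = candidate_at(index, 0)
        planted = gp.plant_offtarget(genome, cand.protospacer, 0, "NGG", "c", 1500)
        hits = gp.find_offtargets(cand, gp.build_site_index(planted), 3)
        assert any(h.mismatches == 0 and h.start == 1500 for h in hits)

    def test_three_vs_four_mismatch_boundary(self, rng):
        guide = random_dna(rng, 20)
        base = random_dna(rng, 3000)
        genome = gp.GenomeSequence({"c": base})
        genome = gp.plant_offtarget(genome, guide, 0, "NGG", "c", 200, seed=1)
        cand = GuideCandidate("g", "c", 200, "+", guide, genome.fetch("c", 220, 223), 0)
        at3 = gp.plant_offtarget(genome, guide, 3, "NGG", "c", 2000, seed=2)
        hits = gp.find_offtargets(cand, gp.build_site_index(at3), 3)
        assert any(h.start == 2000 and h.mismatches == 3 for h in hits)
        assert hits == gp.offtargets_bruteforce(cand, at3, 3)
        # push the planted site to 4 mismatches: no longer reported
        spacer = list(at3.contigs["c"][2000:2020])
        i = next(i for i, (a, b) in enumerate(zip(spacer, guide)) if a == b)
        spacer[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[spacer[i]]
        seq4 = at3.contigs["c"][:2000] + "".join(spacer) + at3.contigs["c"][2020:]
        at4 = gp.GenomeSequence({"c": seq4})
        hits4 = gp.find_offtargets(cand, gp.build_site_index(at4), 3)
        assert not any(h.start == 2000 for h in hits4)
        assert hits4 == gp.offtargets_bruteforce(cand, at4, 3)

    def test_locus_missing_from_index_is_error(self, rng):
        seq = random_dna(rng, 1000)
        index = gp.build_site_index(gp.GenomeSequence({"c": seq}))
        cand = GuideCandidate("g", "other", 5, "+", "A" * 20, "AGG", 0)
        with pytest.raises(ValueError, match="absent from index"):
            gp.find_offtargets(cand, index)


class TestFilterUnique:
    def test_duplicate_protospacers_both_removed(self, rng):
        seq = random_dna(rng, 2000)
        genome = gp.GenomeSequence({"c": seq})
        index = gp.build_site_index(genome)
        cand = candidate_at(index, 0)
        dup = gp.plant_offtarget(genome, cand.protospacer, 0, "NGG", "c", 1500)
        idx2 = gp.build_site_index(dup)
        other = GuideCandidate("g", "c", 1500, "+", cand.protospacer,
                               dup.fetch("c", 1520, 1523), 0)
        assert gp.filter_unique([cand, other], idx2) == []

    def test_nag_neighbour_removes_candidate(self, rng):
        guide = random_dna(rng, 20)
        genome = gp.GenomeSequence({"c": random_dna(rng, 3000)})
        genome = gp.plant_offtarget(genome, guide, 0, "NGG", "c", 100, seed=5)
        cand = GuideCandidate("g", "c", 100, "+", guide,
                              genome.fetch("c", 120, 123), 0)
        with_nag = gp.plant_offtarget(genome, guide, 3, "NAG", "c", 2500, seed=6)
        kept = gp.filter_unique([cand], gp.build_site_index(with_nag))
        if gp.offtargets_bruteforce(cand, genome, 3):
            pytest.skip("random background already contains a near-match")
        assert kept == []

    def test_monotone_in_max_mismatches(self, rng):
        seq = random_dna(rng, 5000)
        genome = gp.GenomeSequence({"c": seq})
        index = gp.build_site_index(genome)
        cands = [candidate_at(index, int(i))
                 for i in rng.choice(len(index), size=20, replace=False)]
        previous = None
        for k in range(4):
            kept = set(gp.filter_unique(cands, index, k))
            if previous is not None:
                assert kept <= previous
            previous = kept


def make_cand(start, cds_offset, strand="+", gene="g"):
    return GuideCandidate(gene, "c", start, strand, "ACGT" * 5, "AGG", cds_offset)


class TestSelectGuides:
    def test_first_five_disjoint_by_rank(self):
        cands = [make_cand(i * 30, i) for i in range(10)]
        assert gp.select_guides(cands, 5) == cands[:5]

    def test_overlap_excludes_later_rank(self):
        a, b = make_cand(0, 0), make_cand(19, 1)  # overlap by 1 base
        assert gp.select_guides([a, b], 5) == [a]
        c = make_cand(20, 1)  # adjacent, disjoint
        assert gp.select_guides([a, c], 5) == [a, c]

    def test_tie_break_is_deterministic_under_shuffle(self, rng):
        cands = [
            make_cand(0, 7), make_cand(40, 7, "-"), make_cand(40, 7, "+"),
            make_cand(80, 7), make_cand(120, 3),
        ]
        expected = gp.select_guides(list(cands), 5)
        assert expected[0].cds_offset == 3
        assert [c.strand for c in expected if c.start == 40] == ["+"]
        for _ in range(10):
            shuffled = list(cands)
            rng.shuffle(shuffled)
            assert gp.select_guides(shuffled, 5) == expected


class TestAssembleOligo:
    def test_first_base_substituted_for_g(self):
        cand = GuideCandidate("g", "c", 0, "+", "ATGCATGCATGCATGCATGC", "AGG", 0)
        rec = gp.assemble_oligo(cand, "g_sg1", "AAAA", "TTTT")
        assert rec.expressed_spacer == "GTGCATGCATGCATGCATGC"
        assert rec.oligo == "AAAA" + rec.expressed_spacer + "TTTT"

    def test_g_start_is_fixed_point(self):
        cand = GuideCandidate("g", "c", 0, "+", "G" + "A" * 19, "AGG", 0)
        rec = gp.assemble_oligo(cand, "g_sg1")
        assert rec.expressed_spacer == cand.protospacer

    def test_oligo_length_and_adaptor_validation(self):
        cand = GuideCandidate("g", "c", 0, "+", "A" * 20, "AGG", 0)
        rec = gp.assemble_oligo(cand, "id", "ACGTACGT", "GG")
        assert len(rec.oligo) == 8 + 20 + 2
        with pytest.raises(ValueError):
            gp.assemble_oligo(cand, "id", "ACGTX", "")


class TestDesignLibrary:
    def test_five_guides_per_gene_on_permissive_genome(self, designed, loaded):
        records, bed, report = designed
        _, genes = loaded
        assert (report.per_gene["n_selected"] == 5).all()
        assert len(records) == 5 * len(genes.genes)
        assert len(bed) == len(records)

    def test_selected_guides_are_valid_and_disjoint(self, designed, loaded):
        records, _, _ = designed
        genome, _ = loaded
        per_gene = {}
        for r in records:
            c = r.candidate
            spacer = genome.fetch(c.contig, c.start, c.end, c.strand)
            pam = (genome.fetch(c.contig, c.end, c.end + 3) if c.strand == "+"
                   else genome.fetch(c.contig, c.start - 3, c.start, "-"))
            assert spacer == c.protospacer and pam[1:] == "GG"
            per_gene.setdefault(c.gene_id, []).append(c)
        for cands in per_gene.values():
            assert [c.cds_offset for c in cands] == sorted(c.cds_offset for c in cands)
            ivals = sorted((c.start, c.end) for c in cands)
            assert all(a[1] <= b[0] for a, b in zip(ivals, ivals[1:]))

    def test_duplicated_gene_gets_no_designs(self):
        syn = gp.make_genome(gp.GenomeSpec(n_genes=2, isoforms_per_gene=(1, 1), seed=3))
        seq = syn.genome.contigs["chrS"]
        s, e = syn.gene_intervals["gene001"]
        # append a copy of gene001's whole locus: all its candidates now
        # have an exact off-target elsewhere
        dup = gp.GenomeSequence({"chrS": seq + "TTTT" + seq[max(0, s - 30) : e + 30]})
        genes = _geneset_from(syn, dup)
        records, _, report = gp.design_library(dup, genes)
        assert report.per_gene.loc["gene001", "n_selected"] == 0
        assert "gene001" in report.genes_without_designs
        assert report.per_gene.loc["gene002", "n_selected"] == 5

    def test_design_is_deterministic(self, loaded):
        genome, genes = loaded
        first = gp.design_library(genome, genes)
        second = gp.design_library(genome, genes)
        assert gp.library_table(first[0]).equals(gp.library_table(second[0]))


def _geneset_from(syn, genome):
    import io, tempfile, os
    with tempfile.TemporaryDirectory() as d:
        gff = os.path.join(d, "a.gff3")
        with open(gff, "w") as fh:
            fh.write(syn.gff3)
        return gp.read_annotation(gff, genome)


class TestLibraryTable:
    def test_round_trip(self, designed, tmp_path):
        records = designed[0]
        path = tmp_path / "lib.tsv"
        gp.write_library(records, path)
        df = gp.read_library(path)
        assert len(df) == len(records)
        assert (df["expressed_spacer"].str[0] == "G").all()
        assert (df["expressed_spacer"].str[1:] == df["protospacer"].str[1:]).all()
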