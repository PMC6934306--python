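"""RNA bubble discovery: QC, graph, bubble oracle, filters, ORFs, effects."""

import numpy as np
import pytest

import heterokaryon as hk
from heterokaryon import bubbles as bub
from heterokaryon.seqmap import revcomp

# standard nuclear genetic code, written out for oracle independence
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def sliding_reads(seq, read_len=40, step=1):
    return [seq[i:i + read_len] for i in range(0, len(seq) - read_len + 1,
                                               step)]


def rand_seq(rng, n):
    return np.frombuffer(b"ACGT", np.uint8)[
        rng.integers(0, 4, n)].tobytes().decode()


def mutate(seq, pos):
    alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
    return seq[:pos] + alt + seq[pos + 1:], alt


def oracle_bubbles(graph):
    """Brute-force two-vertex-disjoint-path enumeration via networkx."""
    import networkx as nx
    G = nx.DiGraph()
    G.add_nodes_from(graph.counts)
    for u, v, _ in graph.edges():
        G.add_edge(u, v)
    k = graph.k
    found = set()
    for s in G:
        if G.out_degree(s) < 2:
            continue
        for t in G:
            if G.in_degree(t) < 2:
                continue
            paths = [p for p in nx.all_simple_paths(G, s, t, cutoff=k + 1)
                     if len(p) == k + 2]
            for i in range(len(paths)):
                for j in range(i + 1, len(paths)):
                    inner_a, inner_b = paths[i][1:-1], paths[j][1:-1]
                    if set(inner_a) & set(inner_b):
                        continue
                    sa = inner_a[0] + "".join(n[-1] for n in inner_a[1:])
                    sb = inner_b[0] + "".join(n[-1] for n in inner_b[1:])
                    diffs = [x for x in range(2 * k - 1) if sa[x] != sb[x]]
                    if diffs == [k - 1]:
                        found.add(tuple(sorted((sa, sb))))
    return found


class TestQc:
    def test_read_with_n_dropped(self):
        out = list(bub.qc_filter_reads([("ACGTN" + "A" * 60, "F" * 65)]))
        assert out == []

    def test_low_quality_tail_trimmed_then_length_filtered(self):
        read = ("A" * 100, "F" * 40 + "#" * 60)   # '#' is Q2
        assert list(bub.qc_filter_reads([read])) == []
        read2 = ("A" * 100, "F" * 60 + "#" * 40)  # trims to 60, kept
        out = list(bub.qc_filter_reads([read2]))
        assert out == [("A" * 60, "F" * 60)]

    def test_clean_read_unchanged(self):
        read = ("ACGT" * 20, "F" * 80)
        assert list(bub.qc_filter_reads([read])) == [read]


class TestGraph:
    def test_single_read_of_length_k(self):
        seq = "ACGTACGTACGTACG"  # 15-mer
        g = bub.build_graph([seq, seq], k=15)
        assert g.counts == {seq: 2}
        assert list(g.edges()) == []

    def test_two_overlapping_reads_one_edge(self):
        a, b = "ACGTACGTACGTACG", "CGTACGTACGTACGA"
        g = bub.build_graph([a, b] * 2, k=15)
        assert set(g.counts) == {a, b}
        assert list(g.edges()) == [(a, b, 2)]

    def test_solidity_threshold_removes_singletons(self):
        a = "ACGTACGTACGTACG"
        g = bub.build_graph([a], k=15, min_count=2)
        assert g.counts == {}

    def test_even_or_small_k_rejected(self):
        with pytest.raises(ValueError):
            bub.build_graph([], k=20)
        with pytest.raises(ValueError):
            bub.build_graph([], k=13)

    def test_unstranded_mode_canonicalises(self):
        seq = "ACGTTGCAACGTGCA"
        g = bub.build_graph([seq, revcomp(seq)], k=15, stranded=False)
        assert g.counts == {min(seq, revcomp(seq)): 2}


class TestBubbleFinder:
    def test_single_snp_yields_one_bubble(self):
        rng = np.random.default_rng(1)
        t1 = rand_seq(rng, 100)
        t2, alt = mutate(t1, 50)
        reads = sliding_reads(t1) + sliding_reads(t2)
        g = bub.build_graph(reads, k=15)
        found = bub.find_type0a_bubbles(g)
        assert len(found) == 1
        b = found[0]
        assert len(b.path_upper) == len(b.path_lower) == 29
        assert b.variant_offset == 14
        assert b.alleles == {t1[50], alt}

    def test_identical_sequences_yield_none(self):
        rng = np.random.default_rng(2)
        t = rand_seq(rng, 100)
        g = bub.build_graph(sliding_reads(t) * 2, k=15)
        assert bub.find_type0a_bubbles(g) == []

    def test_two_distant_snps_yield_two_bubbles(self):
        rng = np.random.default_rng(3)
        t1 = rand_seq(rng, 160)
        t2, _ = mutate(t1, 40)
        t2, _ = mutate(t2, 120)
        reads = sliding_reads(t1) + sliding_reads(t2)
        g = bub.build_graph(reads, k=15)
        assert len(bub.find_type0a_bubbles(g)) == 2

    @pytest.mark.parametrize("seed", [4, 5, 6])
    def test_equals_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        reads = []
        for _ in range(4):   # four transcripts, some with SNPs
            t1 = rand_seq(rng, 120)
            t2, _ = mutate(t1, int(rng.integers(30, 90)))
            reads += sliding_reads(t1) + sliding_reads(t2)
        g = bub.build_graph(reads, k=15)
        assert len(g.counts) <= 500
        got = {tuple(sorted((b.path_upper, b.path_lower)))
               for b in bub.find_type0a_bubbles(g)}
        assert got == oracle_bubbles(g)

    def test_path_counts_are_min_node_support(self):
        rng = np.random.default_rng(7)
        t1 = rand_seq(rng, 100)
        t2, _ = mutate(t1, 50)
        reads = sliding_reads(t1) * 3 + sliding_reads(t2)
        g = bub.build_graph(reads, k=15, min_count=1)
        b = bub.find_type0a_bubbles(g)[0]
        # every interior 15-mer of a 40-bp sliding window lies in 26 reads,
        # so the haplotype covered 3x has exactly 3x the path support
        assert sorted((b.count_upper, b.count_lower)) == [26, 78]


class TestFilters:
    def _bubble(self, up, lo, cu, cl):
        k = (len(up) + 1) // 2
        return bub.Bubble(up, lo, k - 1, up[k - 1], lo[k - 1], cu, cl)

    @pytest.fixture()
    def setting(self):
        rng = np.random.default_rng(9)
        t1 = rand_seq(rng, 120)
        t2, _ = mutate(t1, 60)
        up, lo = t1[46:75], t2[46:75]
        return {"gene1": t1}, up, lo

    def test_total_support_below_six_dropped(self, setting):
        transcriptome, up, lo = setting
        b = self._bubble(up, lo, 3, 2)
        assert bub.filter_bubbles([b], transcriptome) == []

    def test_weak_allele_dropped(self, setting):
        transcriptome, up, lo = setting
        b = self._bubble(up, lo, 5, 1)
        assert bub.filter_bubbles([b], transcriptome) == []

    def test_supported_unique_bubble_retained(self, setting):
        transcriptome, up, lo = setting
        b = self._bubble(up, lo, 4, 2)
        kept = bub.filter_bubbles([b], transcriptome)
        assert kept == [b]
        assert b.transcript_hit[0] == "gene1"
        assert b.transcript_hit[1] == 46

    def test_multi_transcript_hit_dropped(self, setting):
        transcriptome, up, lo = setting
        two = {"gene1": transcriptome["gene1"],
               "gene2": transcriptome["gene1"]}
        b = self._bubble(up, lo, 4, 2)
        assert bub.filter_bubbles([b], two) == []
        assert "multi_transcript" in b.ambiguity_flags

    def test_unmatched_bubble_dropped(self, setting):
        transcriptome, up, lo = setting
        rng = np.random.default_rng(10)
        stranger = rand_seq(rng, 29)
        b = self._bubble(stranger, stranger[:14] + "A" + stranger[15:], 4, 2)
        b = self._bubble(b.path_upper, b.path_lower, 4, 2)
        assert bub.filter_bubbles([b], transcriptome) == []


class TestMapSequence:
    def test_exact_substring_single_hit(self):
        rng = np.random.default_rng(11)
        t = rand_seq(rng, 300)
        idx = hk.SequenceIndex({"t": t})
        hits = hk.map_sequence(t[100:140], idx, min_identity=0.9)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].identity) == (100, 140,
                                                                  1.0)

    def test_duplicated_target_two_hits(self):
        rng = np.random.default_rng(12)
        core = rand_seq(rng, 80)
        genome = {"g": rand_seq(rng, 200) + core + rand_seq(rng, 200) + core}
        idx = hk.SequenceIndex(genome)
        hits = hk.map_sequence(core, idx, min_identity=0.9)
        assert len(hits) == 2

    def test_identity_threshold_excludes_divergent_hit(self):
        rng = np.random.default_rng(13)
        core = rand_seq(rng, 100)
        divergent = list(core)
        # 12% divergence in clusters, leaving seed-length exact runs
        for i in range(0, 100, 25):
            for j in range(i, i + 3):
                divergent[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[
                    divergent[j]]
        idx = hk.SequenceIndex({"t": "".join(divergent)})
        assert hk.map_sequence(core, idx, min_identity=0.90) == []
        assert len(hk.map_sequence(core, idx, min_identity=0.80)) == 1

    def test_empty_query_rejected(self):
        idx = hk.SequenceIndex({"t": "ACGTACGTACGTACGT"})
        with pytest.raises(ValueError):
            hk.map_sequence("", idx)


class TestOrf:
    def test_minimal_two_codon_orf(self):
        orf = hk.find_best_orf("ATGAAATAA")
        assert (orf.start, orf.end) == (0, 9)

    def test_no_atg_means_no_orf(self):
        assert hk.find_best_orf("CCCCCCTAACCC") is None

    def test_matches_exhaustive_scan_oracle(self):
        stops = {"TAA", "TAG", "TGA"}

        def oracle(seq):
            best = None
            for i in range(len(seq) - 2):
                if seq[i:i + 3] != "ATG":
                    continue
                for j in range(i, len(seq) - 2, 3):
                    if seq[j:j + 3] in stops:
                        cand = (i, j + 3)
                        if best is None or (cand[1] - cand[0]
                                            > best[1] - best[0]):
                            best = cand
                        break
            return best

        rng = np.random.default_rng(14)
        for _ in range(20):
            seq = rand_seq(rng, 1000)
            got = hk.find_best_orf(seq)
            expect = oracle(seq)
            if expect is None:
                assert got is None
            else:
                assert (got.start, got.end) == expect


class TestEffect:
    def _effect(self, codon, off, alt, prefix="ATGAAA", suffix="CCCTAA"):
        transcript = prefix + codon + suffix
        orf = hk.find_best_orf(transcript)
        b = bub.Bubble(codon[off], alt, 0, codon[off], alt, 5, 5,
                       transcript_hit=("t", len(prefix) + off, "+"))
        return hk.classify_effect(b, orf, transcript)

    def test_synonymous_example(self):
        assert self._effect("GCT", 2, "C") == "synonymous"    # GCT->GCC Ala

    def test_nonsynonymous_example(self):
        assert self._effect("AAA", 1, "G") == "nonsynonymous"  # Lys->Arg

    def test_outside_orf_is_noncoding(self):
        transcript = "CCCCCC" + "ATGAAATAA" + "CCCCCC"
        orf = hk.find_best_orf(transcript)
        b = bub.Bubble("C", "A", 0, "C", "A", 5, 5,
                       transcript_hit=("t", 2, "+"))
        assert hk.classify_effect(b, orf, transcript) == "noncoding"

    def test_out_of_bounds_offset_raises(self):
        with pytest.raises(ValueError):
            b = bub.Bubble("C", "A", 0, "C", "A", 5, 5,
                           transcript_hit=("t", 99, "+"))
            hk.classify_effect(b, hk.find_best_orf("ATGAAATAA"), "ATGAAATAA")

    def test_all_substitutions_match_translation_oracle(self):
        for codon in CODON_TABLE:
            for off in range(3):
                for alt in "ACGT":
                    if alt == codon[off]:
                        continue
                    mutated = codon[:off] + alt + codon[off + 1:]
                    expected = ("synonymous"
                                if CODON_TABLE[codon] == CODON_TABLE[mutated]
                                else "nonsynonymous")
                    transcript = "ATGAAA" + codon + "CCCTAA"
                    orf = (bub.Orf(0, 15, 0) if codon not in
                           ("TAA", "TAG", "TGA") else bub.Orf(0, 9, 0))
                    b = bub.Bubble(codon[off], alt, 0, codon[off], alt, 5, 5,
                                   transcript_hit=("t", 6 + off, "+"))
                    assert hk.classify_effect(b, orf, transcript) == expected


class TestGenomePlacement:
    def test_unique_gene_bubble_gets_truth_coordinate(self, het_study):
        cfg = het_study.cfg
        rna = hk.simulate_rna_reads(het_study.truth, cfg)
        truth = rna.snp_truth
        # pick a forward-strand and a reverse-strand transcribed SNP
        genes = {g.gene_id: g for g in het_study.genes}
        for strand in ("+", "-"):
            rows = truth[[genes[g].strand == strand
                          for g in truth.gene_id]]
            if rows.empty:
                continue
            row = rows.iloc[0]
            t1 = rna.transcriptome[row.gene_id]
            t2 = t1[:row.transcript_pos] + row.allele2 \
                + t1[row.transcript_pos + 1:]
            k = 15
            lo = row.transcript_pos - (k - 1)
            hi = row.transcript_pos + k
            if lo < 0 or hi > len(t1):
                continue
            up, down = t1[lo:hi], t2[lo:hi]
            b = bub.Bubble(up, down, k - 1, up[k - 1], down[k - 1], 5, 5)
            bub.bubble_genome_positions([b], het_study.genome)
            assert b.genome_hit == ("contig_1", int(row.genome_pos))
            snp = het_study.truth.snp_table
            planted = snp[snp.position == row.genome_pos].iloc[0]
            assert b.genome_alleles == {planted.allele1, planted.allele2}

    def test_duplicated_context_flagged_multi_genome(self):
        rng = np.random.default_rng(15)
        core = rand_seq(rng, 60)
        genome = {"g": rand_seq(rng, 150) + core + rand_seq(rng, 150) + core}
        up = core[10:39]
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[up[14]]
        b = bub.Bubble(up, up[:14] + alt + up[15:], 14, up[14], alt, 5, 5)
        bub.bubble_genome_positions([b], genome)
        assert "multi_genome" in b.ambiguity_flags
        assert b.genome_hit is None
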