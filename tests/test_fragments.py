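import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haplophase.fragments import (
    ReadFragmentMatrix,
    UNCOVERED,
    build_fragment_matrix,
    call_snps,
    decode_one_hot,
    filter_fragments,
    one_hot,
    read_fragments,
    read_sam_fragments,
    split_blocks,
    write_fragments,
    write_vcf,
)

from conftest import matrix_from_strings


class TestCallSnps:
    def test_balanced_column_called(self):
        calls = call_snps({100: {"A": 5, "C": 5}}, vaf_threshold=0.2)
        assert calls.positions == [100]

    def test_low_minor_vaf_not_called(self):
        calls = call_snps({100: {"A": 9, "C": 1}, 200: {"A": 5, "C": 5}}, 0.2)
        assert calls.positions == [200]

    def test_per_column_frequencies(self):
        pileup = {0: {"A": 6, "C": 4}, 1: {"G": 10}, 2: {"A": 7, "T": 3}}
        calls = call_snps(pileup, 0.2)
        assert calls.positions == [0, 2]

    def test_frequency_is_per_covered_depth(self):
        # 2 of 4 covering reads carry C: VAF 0.5 regardless of other columns
        calls = call_snps({5: {"A": 2, "C": 2}, 6: {"A": 100}}, 0.4)
        assert calls.positions == [5]

    def test_empty_pileup_raises(self):
        with pytest.raises(ValueError, match="no positions"):
            call_snps({}, 0.2)

    def test_bad_threshold_raises(self):
        with pytest.raises(ValueError):
            call_snps({0: {"A": 1, "C": 1}}, 1.5)

    def test_max_alleles_keeps_most_frequent(self):
        calls = call_snps({0: {"A": 4, "C": 3, "G": 3}}, 0.2, max_alleles=2)
        assert set(calls.alleles[0]) == {"A", "C"}


class TestBuildFragmentMatrix:
    def test_single_read(self):
        calls = call_snps({10: {"A": 1, "C": 1}, 11: {"C": 1, "G": 1}}, 0.3)
        m = build_fragment_matrix([("r0", [(10, "AC")])], calls)
        assert m.entries.tolist() == [[0, 1]]

    def test_mate_pair_gap_uncovered(self):
        pileup = {p: {"A": 1, "G": 1} for p in (0, 5, 9, 14)}
        calls = call_snps(pileup, 0.3)
        m = build_fragment_matrix([("r0", [(0, "A"), (14, "G")])], calls)
        assert m.entries.tolist() == [[0, UNCOVERED, UNCOVERED, 2]]

    def test_coordinate_arithmetic(self):
        # 3 reads at offsets 0, 2, 5 over SNPs at 1, 3, 6, 8; hand scan oracle
        pileup = {p: {"A": 1, "T": 1} for p in (1, 3, 6, 8)}
        calls = call_snps(pileup, 0.3)
        reads = [
            ("r0", [(0, "TATT")]),   # covers 1('A'),3('T')
            ("r1", [(2, "CTCGA")]),  # covers 3('T'),6('A')
            ("r2", [(5, "GATA")]),   # covers 6('A'),8('A')
        ]
        m = build_fragment_matrix(reads, calls)
        U = UNCOVERED
        assert m.entries.tolist() == [
            [0, 3, U, U],
            [U, 3, 0, U],
            [U, U, 0, 0],
        ]

    def test_positions_equal_calls(self):
        calls = call_snps({3: {"A": 1, "C": 1}, 7: {"A": 1, "C": 1}}, 0.3)
        m = build_fragment_matrix([("r0", [(3, "A")])], calls)
        assert m.snp_positions.tolist() == calls.positions

    def test_disallowed_allele_treated_uncovered(self):
        calls = call_snps({0: {"A": 5, "C": 5, "G": 1}, 1: {"A": 1, "T": 1}}, 0.2)
        m = build_fragment_matrix([("r0", [(0, "GA")])], calls)
        assert m.entries[0, 0] == UNCOVERED  # G below threshold at site 0
        assert m.entries[0, 1] == 0


class TestFilterFragments:
    def test_drops_single_snp_rows(self):
        m = matrix_from_strings(["A---", "AC--", "ACG-"])
        out = filter_fragments(m)
        assert out.read_ids == ["r1", "r2"]
        assert out.l == 4

    def test_identity_when_all_informative(self):
        m = matrix_from_strings(["AC--", "-CGT"])
        out = filter_fragments(m)
        assert np.array_equal(out.entries, m.entries)

    def test_idempotent(self):
        m = matrix_from_strings(["A---", "AC--", "ACG-"])
        once = filter_fragments(m)
        twice = filter_fragments(once)
        assert np.array_equal(once.entries, twice.entries)

    def test_survivor_count_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        entries = rng.integers(-1, 4, size=(20, 10)).astype(np.int8)
        m = ReadFragmentMatrix(entries, [f"r{i}" for i in range(20)], np.arange(10))
        expected = sum(1 for row in entries if (row >= 0).sum() >= 2)
        if expected == 0:
            pytest.skip("degenerate draw")
        assert filter_fragments(m).n == expected

    def test_all_removed_raises(self):
        m = matrix_from_strings(["A---", "-C--"])
        with pytest.raises(ValueError, match="no informative"):
            filter_fragments(m)


class TestSplitBlocks:
    def test_single_block(self, simple_matrix):
        blocks = split_blocks(simple_matrix)
        assert len(blocks) == 1
        assert blocks[0].l == 4

    def test_empty_column_splits(self):
        m = matrix_from_strings(["AC---", "AC---", "---GT", "---GT"])
        blocks = split_blocks(m)
        assert [b.l for b in blocks] == [2, 2]

    def test_unbridged_covered_columns_split(self):
        # columns all covered but no fragment spans columns 1->2
        m = matrix_from_strings(["AC--", "AC--", "--GT", "--GT"])
        assert len(split_blocks(m)) == 2

    def test_block_count_matches_graph_components(self):
        import networkx as nx

        rng = np.random.default_rng(42)
        for _ in range(20):
            n, l = 12, 8
            entries = np.full((n, l), UNCOVERED, dtype=np.int8)
            for i in range(n):
                lo = rng.integers(0, l - 1)
                hi = rng.integers(lo + 1, l + 1)
                entries[i, lo:hi] = rng.integers(0, 4)
            m = ReadFragmentMatrix(entries, [f"r{i}" for i in range(n)], np.arange(l))
            g = nx.Graph()
            covered_cols = [j for j in range(l) if (entries[:, j] >= 0).any()]
            g.add_nodes_from(covered_cols)
            for i in range(n):
                cols = np.flatnonzero(entries[i] >= 0)
                for a, b in zip(cols, cols[1:]):
                    g.add_edge(int(a), int(b))
            # interval reads never bridge an empty column, so blocks are
            # exactly the connected components of the column graph
            expected = nx.number_connected_components(g)
            assert len(split_blocks(m)) == expected

    def test_partition_of_columns(self, simple_matrix):
        blocks = split_blocks(simple_matrix)
        all_cols = np.concatenate([b.snp_positions for b in blocks])
        assert sorted(all_cols.tolist()) == all_cols.tolist()


class TestOneHot:
    def test_examples(self):
        m = matrix_from_strings(["AC"])
        x = one_hot(m)
        assert x[0, :, 0].tolist() == [1, 0, 0, 0]
        assert x[0, :, 1].tolist() == [0, 1, 0, 0]

    def test_uncovered_all_zero(self):
        m = matrix_from_strings(["A-"])
        assert one_hot(m)[0, :, 1].sum() == 0

    @settings(max_examples=25, deadline=None)
    @given(st.lists(
        st.lists(st.integers(-1, 3), min_size=4, max_size=4),
        min_size=1, max_size=6,
    ))
    def test_round_trip(self, rows):
        entries = np.array(rows, dtype=np.int8)
        m = ReadFragmentMatrix(entries, [f"r{i}" for i in range(len(rows))],
                               np.arange(4))
        back = decode_one_hot(one_hot(m))
        assert np.array_equal(back.entries, m.entries)


class TestIO:
    def test_fragment_tsv_round_trip(self, tmp_path, simple_matrix):
        path = tmp_path / "frags.tsv"
        write_fragments(simple_matrix, path)
        back = read_fragments(path)
        assert np.array_equal(back.entries, simple_matrix.entries)
        assert back.read_ids == simple_matrix.read_ids
        assert np.array_equal(back.snp_positions, simple_matrix.snp_positions)

    def test_vcf_export(self, tmp_path):
        calls = call_snps({4: {"A": 6, "C": 4}}, 0.2)
        path = tmp_path / "calls.vcf"
        write_vcf(calls, path)
        lines = [ln for ln in path.read_text().splitlines() if not ln.startswith("#")]
        chrom, pos, _, ref, alt, _, _, info = lines[0].split("\t")
        assert (pos, ref, alt) == ("5", "A", "C")  # 1-based on output
        assert info.startswith("VAF=0.4")

    def test_sam_reader_merges_mates(self, tmp_path):
        sam = tmp_path / "reads.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:coordinate\n"
            "@SQ\tSN:ref\tLN:100\n"
            "p1\t99\tref\t1\t60\t4M\t=\t11\t14\tACGT\tIIII\n"
            "p1\t147\tref\t11\t60\t4M\t=\t1\t-14\tTTTT\tIIII\n"
        )
        pileup = {p: {"A": 1, "T": 1} for p in (0, 12, 50)}
        calls = call_snps(pileup, 0.3)
        m = read_sam_fragments(sam, calls)
        assert m.n == 1  # one fragment from the mate pair
        assert m.entries.tolist() == [[0, 3, UNCOVERED]]
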