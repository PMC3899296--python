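from collections import defaultdict

import numpy as np
import pytest

from evopool import SimulationConfig, build_pool, build_pileup, collect_pair_stats, generate_reference, simulate_reads
from evopool.errors import ConfigurationError, InsufficientDataError
from evopool.sim import ComplexRead, ReadSet, insertion

from conftest import simple_readset, write_sam


def naive_recount(rs):
    """Independent per-read recount of base observations (oracle)."""
    counts = defaultdict(int)  # (pos, base, strand) -> n
    L = rs.read_length
    for contig, b in rs.blocks.items():
        for i in range(b.n):
            s1, s2 = int(b.start[i]), int(b.r2_start[i])
            for j in range(L):
                counts[(contig, s1 + j, int(b.aln1[i, j]), 0)] += 1
            for j in range(L):
                pos = s2 + j
                if pos >= s1 + L:  # mate-overlap rule: read 1 wins
                    counts[(contig, pos, int(b.aln2[i, j]), 1)] += 1
    return counts


class TestBuildPileupFast:
    def test_single_perfect_read_column_by_column(self, ref5k):
        rs = simple_readset(ref5k, [(41, 230)])
        pu = build_pileup(rs)
        for pos in range(41, 141):
            col = pu.column("ctg1", pos)
            assert col.depth == 1
            assert col.ref_count == 1
        assert pu.column("ctg1", 40).depth == 0

    def test_mate_overlap_counted_once(self, ref5k):
        rs = simple_readset(ref5k, [(101, 150)])  # mates overlap on 50 bp
        depth = build_pileup(rs).depth_array("ctg1")
        assert (depth[101:251] == 1).all()

    def test_counts_match_naive_recount(self, ref5k):
        pool = build_pool(ref5k, 3, [], seed=0)
        rs = simulate_reads(pool, SimulationConfig(depth=2.0, seed=13))
        assert rs.n_fragments >= 10
        pu = build_pileup(rs)
        oracle = naive_recount(rs)
        d = pu.data("ctg1")
        for (contig, pos, base, strand), n in oracle.items():
            assert d.counts[pos, base, strand] == n
        assert int(d.counts.sum()) == sum(oracle.values())

    def test_depth_conservation(self, ref5k):
        pool = build_pool(ref5k, 3, [], seed=0)
        rs = simulate_reads(pool, SimulationConfig(depth=8.0, seed=14))
        pu = build_pileup(rs)
        total_depth = int(pu.depth_array("ctg1").sum())
        L = rs.read_length
        b = rs.blocks["ctg1"]
        expected = 0
        for i in range(b.n):
            expected += L  # read 1
            expected += min(L, max(int(b.flen[i]) - L, 0))  # read 2 minus overlap
        assert total_depth == expected

    def test_naive_and_fast_paths_agree(self, ref5k):
        pool = build_pool(ref5k, 3, [insertion(ref5k, "ctg1", 2500, "TT", 1.0)], seed=0)
        rs = simulate_reads(pool, SimulationConfig(depth=6.0, seed=15))
        fast = build_pileup(rs)
        naive = build_pileup(rs, full_offsets=True)
        df, dn = fast.data("ctg1"), naive.data("ctg1")
        assert np.array_equal(df.counts, dn.counts)
        assert np.array_equal(df.ins, dn.ins)
        assert np.array_equal(df.dels, dn.dels)
        assert df.indels == dn.indels


class TestBuildPileupSam:
    def test_single_read_sam(self, ref5k, tmp_path):
        seq = ref5k.slice("ctg1", 501, 600)
        sam = write_sam(tmp_path / "a.sam", ref5k, [{"qname": "r1", "pos": 501, "seq": seq}])
        pu = build_pileup(sam, ref5k)
        for pos in range(501, 601):
            assert pu.column("ctg1", pos).depth == 1
            assert pu.column("ctg1", pos).ref_count == 1

    def test_unsorted_rejected(self, ref5k, tmp_path):
        import pysam

        rows = [
            {"qname": "a", "pos": 500, "seq": ref5k.slice("ctg1", 500, 599)},
            {"qname": "b", "pos": 100, "seq": ref5k.slice("ctg1", 100, 199)},
        ]
        # write intentionally unsorted
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "ctg1", "LN": 5000}]}
        path = tmp_path / "u.sam"
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for r in rows:
                a = pysam.AlignedSegment(out.header)
                a.query_name = r["qname"]
                a.reference_id = 0
                a.reference_start = r["pos"] - 1
                a.cigarstring = "100M"
                a.query_sequence = r["seq"]
                a.query_qualities = [30] * 100
                a.mapping_quality = 60
                out.write(a)
        with pytest.raises(ConfigurationError, match="sorted"):
            build_pileup(str(path), ref5k)

    def test_header_mismatch_rejected(self, ref5k, tmp_path):
        other = generate_reference(1, 777, 0.5, seed=1, prefix="ctg")
        sam = write_sam(tmp_path / "m.sam", other, [{"qname": "r", "pos": 1, "seq": other.slice("ctg1", 1, 100)}])
        with pytest.raises(ConfigurationError, match="header"):
            build_pileup(sam, ref5k)

    def test_base_quality_filter_is_monotone(self, ref5k, tmp_path):
        seq = ref5k.slice("ctg1", 1001, 1100)
        quals = [15 if i % 3 == 0 else 35 for i in range(100)]
        sam = write_sam(
            tmp_path / "q.sam", ref5k, [{"qname": "r", "pos": 1001, "seq": seq, "quals": quals}]
        )
        low = build_pileup(sam, ref5k, min_base_quality=10).data("ctg1").counts
        high = build_pileup(sam, ref5k, min_base_quality=20).data("ctg1").counts
        assert (high.astype(int) <= low.astype(int)).all()
        assert high.sum() < low.sum()

    def test_mapping_quality_filter(self, ref5k, tmp_path):
        seq = ref5k.slice("ctg1", 201, 300)
        sam = write_sam(tmp_path / "mq.sam", ref5k, [{"qname": "r", "pos": 201, "seq": seq, "mapq": 5}])
        assert build_pileup(sam, ref5k).depth_array("ctg1").sum() == 0

    def test_mate_overlap_higher_quality_wins(self, ref5k, tmp_path):
        # 150 bp fragment, 100 bp mates; read 2 carries a high-quality mismatch
        s1, s2 = 101, 151
        seq1 = ref5k.slice("ctg1", s1, s1 + 99)
        seq2 = list(ref5k.slice("ctg1", s2, s2 + 99))
        ref_at_200 = ref5k.base("ctg1", 200)
        mismatch = "A" if ref_at_200 != "A" else "C"
        seq2[200 - s2] = mismatch
        rows = [
            {"qname": "p", "pos": s1, "seq": seq1, "quals": [20] * 100,
             "flag": 0x1 | 0x2 | 0x40 | 0x20, "mate_pos": s2, "tlen": 150},
            {"qname": "p", "pos": s2, "seq": "".join(seq2), "quals": [40] * 100,
             "flag": 0x1 | 0x2 | 0x80 | 0x10, "mate_pos": s1, "tlen": -150},
        ]
        pu = build_pileup(write_sam(tmp_path / "ov.sam", ref5k, rows), ref5k)
        col = pu.column("ctg1", 200)
        assert col.depth == 1
        assert col.count(mismatch) == 1  # the Q40 base replaced the Q20 one
        assert (build_pileup(write_sam(tmp_path / "ov2.sam", ref5k, rows), ref5k)
                .depth_array("ctg1")[s1 : s2 + 100] == 1).all()

    def test_sam_roundtrip_matches_fast_path(self, ref5k, tmp_path):
        pool = build_pool(ref5k, 3, [], seed=0)
        rs = simulate_reads(pool, SimulationConfig(depth=10.0, seed=21))
        rs.write_truth_sam(tmp_path / "t.sam")
        from_sam = build_pileup(str(tmp_path / "t.sam"), ref5k)
        fast = build_pileup(rs)
        assert np.array_equal(from_sam.data("ctg1").counts, fast.data("ctg1").counts)


class TestPairStats:
    def test_concordant_input(self, ref5k):
        rs = simple_readset(ref5k, [(i * 40 + 1, 230) for i in range(30)])
        stats = collect_pair_stats(rs)
        assert stats.median_insert == 230
        assert stats.discordant_pairs == []

    def test_insert_outlier_listed_with_implied_size(self, ref5k):
        frags = [(i * 40 + 1, 230) for i in range(30)] + [(2000, 1230)]
        stats = collect_pair_stats(simple_readset(ref5k, frags))
        assert len(stats.discordant_pairs) == 1
        d = stats.discordant_pairs[0]
        assert d.implied_size == 1000
        assert d.left_pos == 2099 and d.right_pos == 3130

    def test_same_strand_pair_always_discordant(self, ref5k):
        codes = ref5k.codes("ctg1")
        cplx = [
            ComplexRead(0, 1, "ctg1", 0, 301, (("M", 100),), codes[300:400].copy()),
            ComplexRead(0, 2, "ctg1", 0, 431, (("M", 100),), codes[430:530].copy()),
        ]
        rs = ReadSet(ref5k, 100, 30, {}, cplx, 1)
        base = simple_readset(ref5k, [(i * 40 + 1, 230) for i in range(30)])
        rs.blocks = base.blocks
        rs.n_fragments = 31
        stats = collect_pair_stats(rs)
        orientations = {d.orientation for d in stats.discordant_pairs}
        assert "same" in orientations

    def test_no_pairs_raises(self, ref5k):
        rs = ReadSet(ref5k, 100, 30, {}, [], 0)
        with pytest.raises(InsufficientDataError):
            collect_pair_stats(rs)
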