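import numpy as np
import pysam
import pytest

from evopool import (
    ArtifactSpec,
    SimulationConfig,
    build_pool,
    generate_reference,
    inject_artifacts,
    simulate_reads,
)
from evopool.errors import InvalidArgument, PoolConflictError
from evopool.pileup import build_pileup
from evopool.sim import PlantedVariant, deletion, insertion, snp


class TestGenerateReference:
    def test_same_seed_is_byte_identical(self):
        a = generate_reference(2, [1000, 500], 0.4, seed=42)
        b = generate_reference(2, [1000, 500], 0.4, seed=42)
        assert a.sequence("ctg1") == b.sequence("ctg1")
        assert a.sequence("ctg2") == b.sequence("ctg2")

    def test_different_seed_differs(self):
        a = generate_reference(1, 1000, 0.5, seed=1)
        b = generate_reference(1, 1000, 0.5, seed=2)
        assert a.sequence("ctg1") != b.sequence("ctg1")

    def test_gc_one_gives_only_gc(self):
        ref = generate_reference(1, 2000, 1.0, seed=3)
        assert set(ref.sequence("ctg1")) <= {"G", "C"}

    def test_gc_fraction_concentrates(self):
        # binomial concentration: sd of GC fraction at n=1e5 is ~0.0016
        ref = generate_reference(1, 100_000, 0.5, seed=7)
        seq = ref.sequence("ctg1")
        gc = sum(c in "GC" for c in seq) / len(seq)
        assert 0.48 <= gc <= 0.52

    def test_zero_length_rejected(self):
        with pytest.raises(InvalidArgument):
            generate_reference(1, 0, 0.5, seed=0)

    def test_bad_gc_rejected(self):
        with pytest.raises(InvalidArgument):
            generate_reference(1, 100, 1.5, seed=0)


class TestBuildPool:
    def test_ten_percent_of_ten_is_one_carrier(self, ref5k):
        v = snp(ref5k, "ctg1", 100, _alt(ref5k, 100), 0.10)
        pool = build_pool(ref5k, 10, [v], seed=0)
        assert len(pool.carriers[0]) == 1
        assert pool.realized_frequencies == (0.1,)

    def test_fixation_hits_all_haplotypes(self, ref5k):
        v = snp(ref5k, "ctg1", 100, _alt(ref5k, 100), 1.0)
        pool = build_pool(ref5k, 10, [v], seed=0)
        assert pool.carriers[0] == frozenset(range(10))

    @pytest.mark.parametrize("f,n,expected", [(0.05, 20, 1), (0.25, 10, 2), (0.17, 10, 2)])
    def test_rounding_matches_exhaustive_assignment(self, ref5k, f, n, expected):
        # oracle: nearest k/n by exhaustive scan, ties toward zero
        best = min(range(n + 1), key=lambda k: (abs(f - k / n), k))
        assert best == expected
        v = snp(ref5k, "ctg1", 100, _alt(ref5k, 100), f)
        pool = build_pool(ref5k, n, [v], seed=1)
        assert len(pool.carriers[0]) == best
        assert pool.realized_frequencies[0] == pytest.approx(best / n)

    def test_frequency_above_one_rejected(self, ref5k):
        with pytest.raises(InvalidArgument):
            PlantedVariant("ctg1", 100, "snp", "A", "T", 1.5)

    def test_overlap_on_shared_haplotype_rejected(self, ref5k):
        d = deletion(ref5k, "ctg1", 200, 10, 1.0)
        s = snp(ref5k, "ctg1", 205, _alt(ref5k, 205), 1.0)
        with pytest.raises(PoolConflictError):
            build_pool(ref5k, 4, [d, s], seed=0)

    def test_ref_allele_must_match_reference(self, ref5k):
        base = ref5k.base("ctg1", 50)
        wrong = "A" if base != "A" else "C"
        with pytest.raises(InvalidArgument):
            PlantedVariant("ctg1", 50, "snp", wrong, "G", 0.5).validate(ref5k)

    def test_truth_table_records_both_frequencies(self, ref5k):
        v = snp(ref5k, "ctg1", 100, _alt(ref5k, 100), 0.17)
        t = build_pool(ref5k, 10, [v], seed=0).truth_table()
        assert t.loc[0, "true_freq"] == 0.17
        assert t.loc[0, "realized_freq"] == 0.2


def _alt(ref, pos, contig="ctg1"):
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[ref.base(contig, pos)]


class TestSimulateReads:
    def test_read_length_beyond_fragment_rejected(self):
        with pytest.raises(InvalidArgument):
            SimulationConfig(read_length=300, mean_fragment=230)

    def test_noiseless_fixed_snp_shows_alt_in_every_read(self, ref5k):
        v = snp(ref5k, "ctg1", 2500, _alt(ref5k, 2500), 1.0)
        pool = build_pool(ref5k, 5, [v], seed=0)
        reads = simulate_reads(pool, SimulationConfig(depth=60, per_base_error=0.0, seed=1))
        col = build_pileup(reads).column("ctg1", 2500)
        assert col.depth > 0
        assert col.ref_count == 0
        assert col.count(v.alt_allele) == col.depth

    def test_reads_emitted_is_twice_fragments(self, ref5k, tmp_path):
        pool = build_pool(ref5k, 5, [], seed=0)
        reads = simulate_reads(pool, SimulationConfig(depth=20, seed=2))
        reads.write_fastq(tmp_path / "r1.fq", tmp_path / "r2.fq")
        n1 = sum(1 for line in open(tmp_path / "r1.fq") if line.startswith("@sim:"))
        n2 = sum(1 for line in open(tmp_path / "r2.fq") if line.startswith("@sim:"))
        assert n1 == n2 == reads.n_fragments

    def test_depth_concentrates_on_target(self):
        ref = generate_reference(1, 30_000, 0.4, seed=9)
        pool = build_pool(ref, 10, [], seed=0)
        reads = simulate_reads(pool, SimulationConfig(depth=150, seed=3))
        depth = build_pileup(reads).depth_array("ctg1")
        interior = depth[300:-300]
        assert abs(interior.mean() - 150) / 150 < 0.05

    def test_fastq_determinism(self, ref5k, tmp_path):
        v = snp(ref5k, "ctg1", 1000, _alt(ref5k, 1000), 0.4)
        pool = build_pool(ref5k, 10, [v], seed=5)
        cfg = SimulationConfig(depth=30, seed=7)
        for tag in ("a", "b"):
            simulate_reads(pool, cfg).write_fastq(
                tmp_path / f"{tag}_1.fq", tmp_path / f"{tag}_2.fq"
            )
        assert (tmp_path / "a_1.fq").read_bytes() == (tmp_path / "b_1.fq").read_bytes()
        assert (tmp_path / "a_2.fq").read_bytes() == (tmp_path / "b_2.fq").read_bytes()

    def test_frequency_conservation_noiseless(self, ref5k):
        v = snp(ref5k, "ctg1", 2500, _alt(ref5k, 2500), 0.3)
        pool = build_pool(ref5k, 10, [v], seed=1)
        reads = simulate_reads(pool, SimulationConfig(depth=285, per_base_error=0.0, seed=4))
        col = build_pileup(reads).column("ctg1", 2500)
        frac = col.count(v.alt_allele) / col.depth
        sd = np.sqrt(0.3 * 0.7 / col.depth)
        assert abs(frac - 0.3) <= 3 * sd

    def test_truth_alignment_lists_every_read_once(self, ref5k, tmp_path):
        pool = build_pool(ref5k, 5, [], seed=0)
        reads = simulate_reads(pool, SimulationConfig(depth=15, seed=8))
        reads.write_truth_sam(tmp_path / "t.sam")
        seen = set()
        n = 0
        for rec in pysam.AlignmentFile(str(tmp_path / "t.sam")):
            key = (rec.query_name, rec.is_read1)
            assert key not in seen
            seen.add(key)
            n += 1
        assert n == reads.n_reads

    def test_deleted_span_uncovered_at_fixation(self, ref5k):
        d = deletion(ref5k, "ctg1", 2000, 200, 1.0)
        pool = build_pool(ref5k, 4, [d], seed=0)
        reads = simulate_reads(pool, SimulationConfig(depth=60, per_base_error=0.0, seed=9))
        pu = build_pileup(reads)
        depth = pu.depth_array("ctg1")
        assert depth[2050:2150].sum() == 0  # interior of the deleted span
        assert pu.data("ctg1").dels[2100] > 0

    def test_complex_cigar_matched_bases_equal_reference(self, ref5k):
        ins = insertion(ref5k, "ctg1", 1500, "ACGT", 1.0)
        pool = build_pool(ref5k, 2, [ins], seed=0)
        reads = simulate_reads(pool, SimulationConfig(depth=30, per_base_error=0.0, seed=10))
        checked = 0
        for r in reads.complex_reads[:200]:
            if not r.mapped:
                continue
            cur, j = r.ref_start, 0
            for op, n in r.cigar:
                if op in ("S", "I"):
                    j += n
                elif op == "M":
                    ref_seg = ref5k.codes("ctg1")[cur - 1 : cur - 1 + n]
                    assert np.array_equal(r.seq[j : j + n], ref_seg)
                    cur += n
                    j += n
                elif op == "D":
                    cur += n
            checked += 1
        assert checked > 10


class TestInjectArtifacts:
    def _reads(self, ref5k, seed=12):
        pool = build_pool(ref5k, 5, [], seed=0)
        return simulate_reads(pool, SimulationConfig(depth=120, per_base_error=0.0, seed=seed))

    def test_strand_cluster_is_forward_only(self, ref5k):
        reads = self._reads(ref5k)
        spec = ArtifactSpec("strand_biased_cluster", "ctg1", 2500, intensity=1.0)
        modified, truth = inject_artifacts(reads, [spec], seed=1)
        assert truth[0].realized
        assert len(truth[0].sites) >= 3
        pu = build_pileup(modified)
        for pos, alt, planted in truth[0].sites:
            col = pu.column("ctg1", pos)
            assert planted > 0
            assert col.count(alt, strand=1) == 0
            assert col.count(alt, strand=0) >= planted

    def test_read_end_only_has_no_mid_read_alt(self, ref5k):
        reads = self._reads(ref5k)
        spec = ArtifactSpec("read_end_only", "ctg1", 2500, width=10, intensity=1.0)
        modified, truth = inject_artifacts(reads, [spec], seed=2)
        pos, alt, planted = truth[0].sites[0]
        assert planted > 0
        pu = build_pileup(modified)
        offs = [
            off
            for base, _s, off in pu.data("ctg1").obs_offsets.get(pos, ())
            if base == "ACGT".index(alt)
        ]
        assert offs and max(offs) <= 10

    def test_empty_spec_is_identity(self, ref5k):
        reads = self._reads(ref5k)
        modified, truth = inject_artifacts(reads, [], seed=3)
        assert truth == []
        b0, b1 = reads.blocks["ctg1"], modified.blocks["ctg1"]
        assert np.array_equal(b0.aln1, b1.aln1)
        assert np.array_equal(b0.aln2, b1.aln2)

    def test_uncovered_artifact_warns_and_is_unrealized(self):
        ref = generate_reference(1, 2000, 0.4, seed=1)
        pool = build_pool(ref, 2, [], seed=0)
        reads = simulate_reads(pool, SimulationConfig(depth=5, seed=1))
        # empty the read set over a window by clipping coverage: use a position
        # past every fragment end on a second, uncovered contig-like region
        reads.blocks["ctg1"].start[:] = 1  # pile everything at the left edge
        reads.blocks["ctg1"].__post_init__()
        spec = ArtifactSpec("read_end_only", "ctg1", 1999, width=5)
        with pytest.warns(UserWarning, match="not covered"):
            _, truth = inject_artifacts(reads, [spec], seed=0)
        assert not truth[0].realized
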