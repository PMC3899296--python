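import numpy as np
import pysam
import pytest

from evopool._seq import encode
from evopool.pileup import Pileup, PileupColumn
from evopool.sim import ReadSet, ReferenceGenome, _SimpleBlock, generate_reference


@pytest.fixture(scope="session")
def ref5k():
    return generate_reference(1, 5000, 0.45, seed=11)


@pytest.fixture
def flat_reference():
    """All-A contig: every mismatch is unambiguous in hand-built fixtures."""
    return ReferenceGenome([("c", "A" * 400)])


def simple_readset(reference, fragments, read_length=100, quality=30, contig=None):
    """Build a ReadSet of perfect all-match fragments [(start, frag_len), ...]."""
    contig = contig or reference.contig_names[0]
    codes = reference.codes(contig)
    fragments = sorted(fragments)
    start = np.array([s for s, _ in fragments], dtype=np.int64)
    flen = np.array([f for _, f in fragments], dtype=np.int64)
    offs = np.arange(read_length, dtype=np.int64)
    aln1 = codes[(start[:, None] - 1) + offs]
    aln2 = codes[(start[:, None] + flen[:, None] - read_length - 1) + offs]
    block = _SimpleBlock(
        contig,
        np.arange(len(fragments), dtype=np.int64),
        start,
        flen,
        np.zeros(len(fragments), dtype=np.int64),
        aln1.copy(),
        aln2.copy(),
    )
    return ReadSet(reference, read_length, quality, {contig: block}, [], len(fragments))


def make_column(ref_base="A", counts=None, position=100, contig="ctg1", quality=30.0,
                quality_sums=None, offsets=None):
    """Hand-built PileupColumn; counts maps base -> (fwd, rev)."""
    bc = np.zeros((4, 2), dtype=np.uint32)
    qs = np.zeros(4, dtype=np.float64)
    for base, (f, r) in (counts or {}).items():
        b = "ACGT".index(base)
        bc[b, 0] = f
        bc[b, 1] = r
        qs[b] = (f + r) * quality
    if quality_sums:
        for base, q in quality_sums.items():
            qs["ACGT".index(base)] = q
    return PileupColumn(
        contig=contig,
        position=position,
        ref_base=ref_base,
        base_counts=bc,
        quality_sums=qs,
        read_offsets={b: np.asarray(v) for b, v in (offsets or {}).items()},
        insertion_support=0,
        deletion_support=0,
        clip_support=0,
    )


def empty_pileup(reference, read_length=100):
    return Pileup(reference, read_length, 20, 20, full_offsets=False)


def write_sam(path, reference, rows):
    """rows: dicts with qname, pos (1-based), seq, cigar, flags extras."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": reference.length(n)} for n in reference.contig_names],
    }
    rows = sorted(rows, key=lambda r: r["pos"])
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in rows:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r["qname"]
            a.reference_id = 0
            a.reference_start = r["pos"] - 1
            a.cigarstring = r.get("cigar", f"{len(r['seq'])}M")
            a.query_sequence = r["seq"]
            quals = r.get("quals", [30] * len(r["seq"]))
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in quals)
            )
            a.mapping_quality = r.get("mapq", 60)
            a.flag = r.get("flag", 0)
            a.next_reference_id = 0 if r.get("mate_pos") else -1
            a.next_reference_start = (r.get("mate_pos", 0) or 1) - 1
            a.template_length = r.get("tlen", 0)
            out.write(a)
    return str(path)
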