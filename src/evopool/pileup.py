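"""Per-site evidence columns and read-pair statistics.

``build_pileup`` accepts either an in-memory :class:`~evopool.sim.ReadSet`
(vectorised fast path) or a coordinate-sorted SAM/BAM file (pysam path).
Both paths apply the same rules:

* reads below ``min_mapping_quality`` and bases below ``min_base_quality``
  are excluded from counts;
* overlapping mate pairs contribute once per site (higher base quality wins,
  read 1 wins ties);
* deletions add support at every spanned site, insertions anchor to the
  site on their left (VCF convention);
* soft clips are recorded at the first clipped-off reference position.

Read offsets are stored as the distance to the nearer read end, so the
"middle of the read" is symmetric. The fast path records offsets for
mismatching observations only (all the downstream filters need); the SAM
path and ``full_offsets=True`` keep offsets for every observation.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from ._seq import BASES, decode
from .errors import ConfigurationError, InsufficientDataError, InvalidArgument
from .sim import ComplexRead, ReadSet

__all__ = [
    "PileupColumn",
    "Pileup",
    "PairStats",
    "DiscordantPair",
    "build_pileup",
    "collect_pair_stats",
]

_COUNT_CHUNK = 150_000


@dataclass
class PileupColumn:
    """Evidence at one reference site (1-based)."""

    contig: str
    position: int
    ref_base: str
    base_counts: np.ndarray          # (4 bases, 2 strands)
    quality_sums: np.ndarray         # (4,) summed Phred per base
    read_offsets: dict[str, np.ndarray]  # per base: distances to nearer read end
    insertion_support: int
    deletion_support: int
    clip_support: int

    @property
    def depth(self) -> int:
        return int(self.base_counts.sum())

    def count(self, base: str, strand: int | None = None) -> int:
        b = BASES.index(base)
        if strand is None:
            return int(self.base_counts[b].sum())
        return int(self.base_counts[b, strand])

    @property
    def ref_count(self) -> int:
        return self.count(self.ref_base)

    def alt_counts(self) -> dict[str, int]:
        """Counts of non-reference bases, descending."""
        out = {
            BASES[b]: int(self.base_counts[b].sum())
            for b in range(4)
            if BASES[b] != self.ref_base and self.base_counts[b].sum() > 0
        }
        return dict(sorted(out.items(), key=lambda kv: (-kv[1], kv[0])))


class _ContigData:
    def __init__(self, length: int):
        self.length = length
        # index arrays directly by 1-based position; slot 0 unused
        self.counts = np.zeros((length + 2, 4, 2), dtype=np.uint32)
        self.qual = np.zeros((length + 2, 4), dtype=np.float64)
        self.ins = np.zeros(length + 2, dtype=np.uint32)
        self.dels = np.zeros(length + 2, dtype=np.uint32)
        self.clip_left = np.zeros(length + 2, dtype=np.uint32)   # leading-S events
        self.clip_right = np.zeros(length + 2, dtype=np.uint32)  # trailing-S events
        self.obs_offsets: dict[int, list[tuple[int, int, int]]] = {}  # pos -> [(base, strand, offset)]
        self.indels: dict[int, Counter] = {}  # anchor pos -> Counter of ('I', seq) / ('D', len)

    def add_offset(self, pos: int, base: int, strand: int, offset: int) -> None:
        self.obs_offsets.setdefault(pos, []).append((base, strand, offset))


class Pileup:
    """Random-access collection of pileup columns over one or more contigs."""

    def __init__(
        self,
        reference,
        read_length: int,
        min_mapping_quality: int,
        min_base_quality: int,
        full_offsets: bool,
    ):
        self.reference = reference
        self.read_length = read_length
        self.min_mapping_quality = min_mapping_quality
        self.min_base_quality = min_base_quality
        self.full_offsets = full_offsets
        self._data: dict[str, _ContigData] = {
            name: _ContigData(reference.length(name)) for name in reference.contig_names
        }

    def data(self, contig: str) -> _ContigData:
        return self._data[contig]

    def depth_array(self, contig: str) -> np.ndarray:
        """Depth per 1-based position (index 0 unused)."""
        return self._data[contig].counts.sum(axis=(1, 2))

    def column(self, contig: str, position: int) -> PileupColumn:
        d = self._data[contig]
        if not 1 <= position <= d.length:
            raise InvalidArgument(f"position {position} outside {contig}")
        offs: dict[str, list[int]] = {}
        for base, _strand, off in d.obs_offsets.get(position, ()):
            offs.setdefault(BASES[base], []).append(off)
        return PileupColumn(
            contig=contig,
            position=position,
            ref_base=BASES[self.reference.codes(contig)[position - 1]],
            base_counts=d.counts[position].copy(),
            quality_sums=d.qual[position].copy(),
            read_offsets={b: np.array(v, dtype=np.int64) for b, v in offs.items()},
            insertion_support=int(d.ins[position]),
            deletion_support=int(d.dels[position]),
            clip_support=int(d.clip_left[position] + d.clip_right[position]),
        )

    def columns(self, contig: str) -> Iterator[PileupColumn]:
        depth = self.depth_array(contig)
        for pos in np.flatnonzero(depth[1:]) + 1:
            yield self.column(contig, int(pos))

    def candidate_snp_sites(self, contig: str, min_alt: int) -> np.ndarray:
        """1-based positions where some non-reference base has >= min_alt observations."""
        d = self._data[contig]
        totals = d.counts.sum(axis=2)  # (L+2, 4)
        ref_codes = self.reference.codes(contig)
        nonref = totals[1 : d.length + 1].copy()
        nonref[np.arange(d.length), ref_codes] = 0
        return np.flatnonzero(nonref.max(axis=1) >= min_alt) + 1

    def indel_sites(self, contig: str) -> dict[int, Counter]:
        return self._data[contig].indels

    def to_tsv(self, path: str | Path, contig: str | None = None) -> None:
        """Debug dump of covered columns."""
        contigs = [contig] if contig else list(self.reference.contig_names)
        with open(path, "w") as fh:
            fh.write("contig\tpos\tref\tdepth\tA\tC\tG\tT\tfwd\trev\tins\tdel\tclip\n")
            for c in contigs:
                for col in self.columns(c):
                    per_base = col.base_counts.sum(axis=1)
                    fh.write(
                        f"{c}\t{col.position}\t{col.ref_base}\t{col.depth}\t"
                        + "\t".join(str(int(x)) for x in per_base)
                        + f"\t{int(col.base_counts[:, 0].sum())}\t{int(col.base_counts[:, 1].sum())}"
                        + f"\t{col.insertion_support}\t{col.deletion_support}\t{col.clip_support}\n"
                    )


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_pileup(
    source,
    reference=None,
    min_mapping_quality: int = 20,
    min_base_quality: int = 20,
    full_offsets: bool = False,
) -> Pileup:
    """Aggregate alignments into per-site evidence columns.

    ``source`` may be a :class:`ReadSet` or a path to a coordinate-sorted
    SAM/BAM file (in which case ``reference`` is required).
    """
    if isinstance(source, ReadSet):
        if reference is not None and reference != source.reference:
            raise ConfigurationError("reference does not match the read set")
        if full_offsets:
            return _build_naive(source, min_mapping_quality, min_base_quality)
        return _build_fast(source, min_mapping_quality, min_base_quality)
    if reference is None:
        raise ConfigurationError("a reference is required for SAM/BAM input")
    return _build_from_sam(source, reference, min_mapping_quality, min_base_quality)


def _build_fast(rs: ReadSet, min_mapq: int, min_baseq: int) -> Pileup:
    pu = Pileup(rs.reference, rs.read_length, min_mapq, min_baseq, full_offsets=False)
    L = rs.read_length
    if rs.quality < min_baseq:
        # flat-quality reads below the cutoff contribute nothing
        return pu
    offs = np.arange(L, dtype=np.int64)
    end_dist = np.minimum(offs, L - 1 - offs)
    for contig, b in rs.blocks.items():
        d = pu.data(contig)
        ref_codes = rs.reference.codes(contig)
        nbins = (d.length + 2) * 8
        flat_counts = np.zeros(nbins, dtype=np.int64)
        r2s = b.r2_start
        count_from = np.maximum(r2s, b.start + L)  # mate-overlap dedup for R2
        for lo in range(0, b.n, _COUNT_CHUNK):
            hi = min(lo + _COUNT_CHUNK, b.n)
            idx1 = b.start[lo:hi, None] + offs
            flat = idx1.ravel() * 8 + b.aln1[lo:hi].ravel() * 2  # strand 0
            flat_counts += np.bincount(flat, minlength=nbins)
            mm = b.aln1[lo:hi] != ref_codes[idx1 - 1]
            rows, js = np.nonzero(mm)
            for r, j in zip(rows, js):
                d.add_offset(int(idx1[r, j]), int(b.aln1[lo + r, j]), 0, int(end_dist[j]))
            idx2 = r2s[lo:hi, None] + offs
            keep = idx2 >= count_from[lo:hi, None]
            flat = idx2[keep] * 8 + b.aln2[lo:hi][keep] * 2 + 1  # strand 1
            flat_counts += np.bincount(flat, minlength=nbins)
            mm = (b.aln2[lo:hi] != ref_codes[idx2 - 1]) & keep
            rows, js = np.nonzero(mm)
            for r, j in zip(rows, js):
                d.add_offset(int(idx2[r, j]), int(b.aln2[lo + r, j]), 1, int(end_dist[j]))
        d.counts += flat_counts.reshape(d.length + 2, 4, 2).astype(np.uint32)
    for r in rs.complex_reads:
        _count_complex_read(pu, rs, r)
    for contig in rs.reference.contig_names:
        d = pu.data(contig)
        d.qual += d.counts.sum(axis=2) * float(rs.quality)
    return pu


def _count_complex_read(pu: Pileup, rs: ReadSet, r: ComplexRead) -> None:
    if not r.mapped:
        return
    d = pu.data(r.contig)
    ref_codes = rs.reference.codes(r.contig)
    L = rs.read_length
    cur = r.ref_start
    j = 0
    for k, (op, n) in enumerate(r.cigar):
        if op == "S":
            if k == 0:
                d.clip_left[r.ref_start] += 1
            else:
                d.clip_right[min(cur, d.length + 1)] += 1
            j += n
        elif op == "M":
            for t in range(n):
                pos = cur + t
                if pos >= r.count_from:
                    base = int(r.seq[j + t])
                    d.counts[pos, base, r.strand] += 1
                    if base != ref_codes[pos - 1]:
                        jj = j + t
                        d.add_offset(pos, base, r.strand, min(jj, L - 1 - jj))
            cur += n
            j += n
        elif op == "I":
            anchor = cur - 1
            if anchor >= r.count_from - 1 and anchor >= 1:
                d.ins[anchor] += 1
                key = ("I", decode(r.seq[j : j + n]))
                d.indels.setdefault(anchor, Counter())[key] += 1
            j += n
        elif op == "D":
            anchor = cur - 1
            lo = max(cur, r.count_from)
            d.dels[lo : cur + n] += 1
            if anchor >= r.count_from - 1 and anchor >= 1:
                d.indels.setdefault(anchor, Counter())[("D", n)] += 1
            cur += n


def _build_naive(rs: ReadSet, min_mapq: int, min_baseq: int) -> Pileup:
    """Per-read reference loop keeping offsets for every observation (fixtures)."""
    pu = Pileup(rs.reference, rs.read_length, min_mapq, min_baseq, full_offsets=True)
    L = rs.read_length
    if rs.quality < min_baseq:
        return pu
    for contig, b in rs.blocks.items():
        d = pu.data(contig)
        for i in range(b.n):
            s1 = int(b.start[i])
            for j in range(L):
                base = int(b.aln1[i, j])
                d.counts[s1 + j, base, 0] += 1
                d.add_offset(s1 + j, base, 0, min(j, L - 1 - j))
            s2 = int(b.r2_start[i])
            for j in range(L):
                pos = s2 + j
                if pos < s1 + L:  # mate overlap: R1 already contributed
                    continue
                base = int(b.aln2[i, j])
                d.counts[pos, base, 1] += 1
                d.add_offset(pos, base, 1, min(j, L - 1 - j))
    for r in rs.complex_reads:
        _count_complex_read(pu, rs, r)
    for contig in rs.reference.contig_names:
        d = pu.data(contig)
        d.qual += d.counts.sum(axis=2) * float(rs.quality)
    return pu


def _build_from_sam(path, reference, min_mapq: int, min_baseq: int) -> Pileup:
    import pysam

    af = path if isinstance(path, pysam.AlignmentFile) else pysam.AlignmentFile(str(path))
    for sq in af.header.get("SQ", []):
        name = sq["SN"]
        if name not in reference.contig_names or sq["LN"] != reference.length(name):
            raise ConfigurationError(f"SAM header contig {name!r} does not match the reference")
    read_length = 0
    pu = Pileup(reference, 0, min_mapq, min_baseq, full_offsets=True)
    pending: dict[str, dict[int, tuple[int, int, int]]] = {}  # qname -> pos -> (base, strand, qual)
    last_pos: dict[str, int] = {}
    for rec in af:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        contig = rec.reference_name
        if rec.reference_start < last_pos.get(contig, -1):
            raise ConfigurationError("alignments must be coordinate-sorted")
        last_pos[contig] = rec.reference_start
        if rec.mapping_quality < min_mapq:
            continue
        L = rec.query_length
        read_length = max(read_length, L)
        d = pu.data(contig)
        ref_codes = reference.codes(contig)
        quals = rec.query_qualities
        seq = rec.query_sequence
        strand = 1 if rec.is_reverse else 0
        overlap_possible = (
            rec.is_proper_pair
            and rec.next_reference_id == rec.reference_id
            and abs(rec.template_length) < 2 * L + 64
        )
        mate_bases = pending.pop(rec.query_name, None) if overlap_possible else None
        my_bases: dict[int, tuple[int, int, int]] = {}
        cur = rec.reference_start + 1
        j = 0
        for k, (op, n) in enumerate(rec.cigartuples):
            if op == 4:  # S
                if k == 0:
                    d.clip_left[cur] += 1
                else:
                    d.clip_right[min(cur, d.length + 1)] += 1
                j += n
            elif op in (0, 7, 8):  # M/=/X
                for t in range(n):
                    pos = cur + t
                    q = quals[j + t] if quals is not None else 40
                    if q < min_baseq:
                        continue
                    base = "ACGT".find(seq[j + t])
                    if base < 0:
                        continue
                    off = min(j + t, L - 1 - j - t)
                    if mate_bases is not None and pos in mate_bases:
                        ob, os_, oq = mate_bases[pos]
                        if q > oq:  # replace the mate's observation
                            d.counts[pos, ob, os_] -= 1
                            d.qual[pos, ob] -= oq
                        else:
                            continue
                    d.counts[pos, base, strand] += 1
                    d.qual[pos, base] += q
                    d.add_offset(pos, base, strand, off)
                    my_bases[pos] = (base, strand, q)
                cur += n
                j += n
            elif op == 1:  # I
                anchor = cur - 1
                if anchor >= 1:
                    d.ins[anchor] += 1
                    d.indels.setdefault(anchor, Counter())[("I", seq[j : j + n])] += 1
                j += n
            elif op == 2:  # D
                d.dels[cur : cur + n] += 1
                anchor = cur - 1
                if anchor >= 1:
                    d.indels.setdefault(anchor, Counter())[("D", n)] += 1
                cur += n
            elif op == 3:  # N
                cur += n
            elif op == 5:  # H
                pass
        if overlap_possible and mate_bases is None:
            pending[rec.query_name] = my_bases
    pu.read_length = read_length or 100
    if not isinstance(path, pysam.AlignmentFile):
        af.close()
    return pu


# ---------------------------------------------------------------------------
# Pair statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscordantPair:
    contig: str
    left_pos: int        # last aligned base of the leftmost read
    right_pos: int       # first aligned base of the rightmost read
    orientation: str     # 'FR', 'RF' or 'same'
    implied_size: int    # observed insert minus the median insert (signed)


@dataclass
class PairStats:
    median_insert: float
    insert_mad: float    # scaled MAD (1.4826 x raw), a robust sd estimate
    n_pairs: int
    discordant_pairs: list[DiscordantPair] = field(default_factory=list)


_MAD_SCALE = 1.4826


def collect_pair_stats(source, reference=None, envelope_mads: float = 4.0) -> PairStats:
    """Median/MAD of insert sizes plus the list of discordant pairs.

    A pair is discordant when its orientation is anomalous or its implied
    insert lies outside ``median +/- envelope_mads * scaled MAD``. Pairs in
    which either read's alignment itself spans a deletion (a D CIGAR) are
    split-read, not pair, evidence and are excluded here.
    """
    if isinstance(source, ReadSet):
        records = _pairs_from_readset(source)
    else:
        records = _pairs_from_sam(source)
    records = [r for r in records if not r[5]]
    if not records:
        raise InsufficientDataError("no proper pairs found")
    inserts = np.array([r[4] for r in records], dtype=np.float64)
    med = float(np.median(inserts))
    mad = float(np.median(np.abs(inserts - med))) * _MAD_SCALE
    lim = envelope_mads * mad
    disc = [
        DiscordantPair(contig, left, right, orient, int(ins - med))
        for contig, left, right, orient, ins, _gapped in records
        if orient != "FR" or abs(ins - med) > lim
    ]
    return PairStats(median_insert=med, insert_mad=mad, n_pairs=len(records), discordant_pairs=disc)


def _pairs_from_readset(rs: ReadSet) -> list[tuple[str, int, int, str, int, bool]]:
    L = rs.read_length
    out: list[tuple[str, int, int, str, int, bool]] = []
    for contig, b in rs.blocks.items():
        r2s = b.r2_start
        for i in range(b.n):
            out.append((contig, int(b.start[i]) + L - 1, int(r2s[i]), "FR", int(b.flen[i]), False))
    by_frag: dict[int, dict[int, ComplexRead]] = {}
    for r in rs.complex_reads:
        by_frag.setdefault(r.frag_id, {})[r.mate] = r
    for mates in by_frag.values():
        r1, r2 = mates.get(1), mates.get(2)
        if r1 is None or r2 is None or not (r1.mapped and r2.mapped):
            continue
        if r1.contig != r2.contig:
            continue
        left, right = (r1, r2) if r1.ref_start <= r2.ref_start else (r2, r1)
        orient = "same" if r1.strand == r2.strand else ("FR" if left.strand == 0 else "RF")
        insert = right.ref_end - left.ref_start + 1
        gapped = any(op == "D" for op, _ in r1.cigar) or any(op == "D" for op, _ in r2.cigar)
        out.append((r1.contig, left.ref_end, right.ref_start, orient, insert, gapped))
    return out


def _pairs_from_sam(path) -> list[tuple[str, int, int, str, int, bool]]:
    import pysam

    af = path if isinstance(path, pysam.AlignmentFile) else pysam.AlignmentFile(str(path))
    seen: dict[str, tuple] = {}
    out: list[tuple[str, int, int, str, int, bool]] = []
    for rec in af:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or not rec.is_paired:
            continue
        gapped = any(op == 2 for op, _ in (rec.cigartuples or []))
        prev = seen.pop(rec.query_name, None)
        if prev is None:
            seen[rec.query_name] = (
                rec.reference_start + 1,
                rec.reference_end,
                rec.is_reverse,
                rec.reference_name,
                gapped,
            )
            continue
        if prev[3] != rec.reference_name:
            continue
        a = (prev[0], prev[1], prev[2])
        bt = (rec.reference_start + 1, rec.reference_end, rec.is_reverse)
        left, right = (a, bt) if a[0] <= bt[0] else (bt, a)
        if a[2] == bt[2]:
            orient = "same"
        else:
            orient = "FR" if not left[2] else "RF"
        insert = right[1] - left[0] + 1
        out.append((rec.reference_name, left[1], right[0], orient, insert, gapped or prev[4]))
    if not isinstance(path, pysam.AlignmentFile):
        af.close()
    return out
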