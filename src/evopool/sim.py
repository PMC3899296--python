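"""Synthetic pooled-population sequencing.

This module generates everything the downstream stages consume: a reference
genome, a pool of haplotypes carrying planted variants at known frequencies,
paired-end reads drawn from that pool, and injected artifact classes
(strand-biased mismatch clusters, read-end-only mismatches) that the
false-positive filters are meant to catch.

Reads from haplotypes that carry only SNPs are kept in a vectorised
"simple block" (plain 100M alignments); haplotypes carrying indels are
materialised with an explicit haplotype->reference coordinate map and their
reads get real CIGARs (soft clips, insertions, deletions).

Coordinates are 1-based and fully closed in all truth tables; indel alleles
use the VCF left-anchored convention (position = the base before the event).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES, decode, encode, revcomp_codes
from .errors import InvalidArgument, PoolConflictError

__all__ = [
    "ReferenceGenome",
    "PlantedVariant",
    "HaplotypePool",
    "SimulationConfig",
    "ArtifactSpec",
    "ArtifactTruth",
    "ReadSet",
    "generate_reference",
    "build_pool",
    "simulate_reads",
    "inject_artifacts",
    "snp",
    "insertion",
    "deletion",
    "large_insertion",
]


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

class ReferenceGenome:
    """An ordered collection of named ACGT contigs."""

    def __init__(self, contigs: Sequence[tuple[str, str]]):
        names = [c[0] for c in contigs]
        if len(set(names)) != len(names):
            raise InvalidArgument("contig ids must be unique")
        self._names: tuple[str, ...] = tuple(names)
        self._codes: dict[str, np.ndarray] = {}
        for name, seq in contigs:
            if len(seq) == 0:
                raise InvalidArgument(f"contig {name!r} has empty sequence")
            self._codes[name] = encode(seq)

    @property
    def contig_names(self) -> tuple[str, ...]:
        return self._names

    def codes(self, contig: str) -> np.ndarray:
        return self._codes[contig]

    def sequence(self, contig: str) -> str:
        return decode(self._codes[contig])

    def length(self, contig: str) -> int:
        return len(self._codes[contig])

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self._codes.values())

    def base(self, contig: str, position: int) -> str:
        """1-based single-base access."""
        return BASES[self._codes[contig][position - 1]]

    def slice(self, contig: str, start: int, end: int) -> str:
        """1-based, closed-interval subsequence."""
        return decode(self._codes[contig][start - 1 : end])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ReferenceGenome)
            and self._names == other._names
            and all(np.array_equal(self._codes[n], other._codes[n]) for n in self._names)
        )

    def __repr__(self) -> str:
        return f"ReferenceGenome({len(self._names)} contigs, {self.total_length} bp)"

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self._names:
                fh.write(f">{name}\n")
                seq = self.sequence(name)
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        from Bio import SeqIO

        return cls([(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")])


def generate_reference(
    n_contigs: int,
    lengths: int | Sequence[int],
    gc_fraction: float = 0.5,
    seed: int = 0,
    prefix: str = "ctg",
) -> ReferenceGenome:
    """Draw a random reference with the requested base composition."""
    if isinstance(lengths, (int, np.integer)):
        lengths = [int(lengths)] * n_contigs
    lengths = [int(x) for x in lengths]
    if len(lengths) != n_contigs:
        raise InvalidArgument("lengths must match n_contigs")
    if any(x <= 0 for x in lengths):
        raise InvalidArgument("contig lengths must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise InvalidArgument("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    probs = np.array([at, gc, gc, at])
    contigs = []
    for i, n in enumerate(lengths):
        codes = rng.choice(4, size=n, p=probs).astype(np.uint8)
        contigs.append((f"{prefix}{i + 1}", decode(codes)))
    return ReferenceGenome(contigs)


# ---------------------------------------------------------------------------
# Planted variants and the haplotype pool
# ---------------------------------------------------------------------------

VARIANT_KINDS = ("snp", "insertion", "deletion", "large_insertion")


@dataclass(frozen=True)
class PlantedVariant:
    """Truth record for one variant planted into the pool.

    ``position``, ``ref_allele`` and ``alt_allele`` follow VCF conventions:
    SNPs are single-base ref/alt at ``position``; indels are anchored on the
    reference base immediately left of the inserted/deleted sequence.
    """

    contig: str
    position: int
    kind: str
    ref_allele: str
    alt_allele: str
    true_frequency: float

    def __post_init__(self):
        if self.kind not in VARIANT_KINDS:
            raise InvalidArgument(f"unknown variant kind {self.kind!r}")
        if not 0.0 < self.true_frequency <= 1.0:
            raise InvalidArgument("true_frequency must lie in (0, 1]")
        if self.position < 1:
            raise InvalidArgument("position is 1-based and must be >= 1")
        if not self.ref_allele or not self.alt_allele:
            raise InvalidArgument("alleles must be non-empty")

    @property
    def is_indel(self) -> bool:
        return self.kind != "snp"

    @property
    def ref_span(self) -> tuple[int, int]:
        """Closed 1-based interval of reference bases touched by the variant."""
        return (self.position, self.position + len(self.ref_allele) - 1)

    def validate(self, reference: ReferenceGenome) -> None:
        start, end = self.ref_span
        if self.contig not in reference.contig_names:
            raise InvalidArgument(f"unknown contig {self.contig!r}")
        if end > reference.length(self.contig):
            raise InvalidArgument("variant extends past the contig end")
        observed = reference.slice(self.contig, start, end)
        if observed != self.ref_allele:
            raise InvalidArgument(
                f"ref allele {self.ref_allele!r} does not match reference "
                f"{observed!r} at {self.contig}:{self.position}"
            )


def snp(reference: ReferenceGenome, contig: str, position: int, alt: str, frequency: float) -> PlantedVariant:
    v = PlantedVariant(contig, position, "snp", reference.base(contig, position), alt.upper(), frequency)
    if v.ref_allele == v.alt_allele:
        raise InvalidArgument("SNP alt equals reference base")
    v.validate(reference)
    return v


def insertion(reference: ReferenceGenome, contig: str, position: int, inserted: str, frequency: float) -> PlantedVariant:
    anchor = reference.base(contig, position)
    v = PlantedVariant(contig, position, "insertion", anchor, anchor + inserted.upper(), frequency)
    v.validate(reference)
    return v


def large_insertion(reference: ReferenceGenome, contig: str, position: int, inserted: str, frequency: float) -> PlantedVariant:
    anchor = reference.base(contig, position)
    v = PlantedVariant(contig, position, "large_insertion", anchor, anchor + inserted.upper(), frequency)
    v.validate(reference)
    return v


def deletion(reference: ReferenceGenome, contig: str, first_deleted: int, length: int, frequency: float) -> PlantedVariant:
    """Delete ``length`` bases starting at ``first_deleted`` (1-based)."""
    if first_deleted < 2:
        raise InvalidArgument("deletion anchor requires a base to the left")
    anchor = first_deleted - 1
    ref = reference.slice(contig, anchor, anchor + length)
    v = PlantedVariant(contig, anchor, "deletion", ref, ref[0], frequency)
    v.validate(reference)
    return v


class HaplotypePool:
    """A reference plus ``n_haplotypes`` lineages carrying planted variants.

    The planted frequency is discretised onto the pool grid: each variant is
    carried by the nearest integer number of haplotypes (ties round down),
    and both the requested and realized frequency are kept in the truth
    table.
    """

    def __init__(
        self,
        reference: ReferenceGenome,
        n_haplotypes: int,
        variants: Sequence[PlantedVariant],
        carriers: Sequence[frozenset[int]],
    ):
        if n_haplotypes < 1:
            raise InvalidArgument("n_haplotypes must be positive")
        self.reference = reference
        self.n_haplotypes = int(n_haplotypes)
        self.variants: tuple[PlantedVariant, ...] = tuple(variants)
        self.carriers: tuple[frozenset[int], ...] = tuple(frozenset(c) for c in carriers)
        if len(self.variants) != len(self.carriers):
            raise InvalidArgument("one carrier set per variant required")
        self._check_overlaps()
        self._hap_cache: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}

    @property
    def realized_frequencies(self) -> tuple[float, ...]:
        return tuple(len(c) / self.n_haplotypes for c in self.carriers)

    @property
    def complex_haplotypes(self) -> frozenset[int]:
        """Haplotypes whose coordinates differ from the reference (indels)."""
        out: set[int] = set()
        for v, c in zip(self.variants, self.carriers):
            if v.is_indel:
                out |= c
        return frozenset(out)

    def variants_for_haplotype(self, hap: int, contig: str | None = None):
        for v, c in zip(self.variants, self.carriers):
            if hap in c and (contig is None or v.contig == contig):
                yield v

    def _check_overlaps(self):
        for v in self.variants:
            v.validate(self.reference)
        by_hap: dict[int, list[PlantedVariant]] = {}
        for v, c in zip(self.variants, self.carriers):
            for h in c:
                by_hap.setdefault(h, []).append(v)
        for h, vs in by_hap.items():
            for contig in {v.contig for v in vs}:
                spans = sorted(v.ref_span for v in vs if v.contig == contig)
                for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                    if s2 <= e1:
                        raise PoolConflictError(
                            f"variants overlap on haplotype {h} at {contig}:{s2}"
                        )

    def haplotype_arrays(self, hap: int, contig: str) -> tuple[np.ndarray, np.ndarray]:
        """(codes, ref_pos) for one haplotype on one contig.

        ``ref_pos`` holds the 0-based reference coordinate of each haplotype
        base, with -1 marking inserted bases.
        """
        key = (hap, contig)
        if key in self._hap_cache:
            return self._hap_cache[key]
        ref_codes = self.reference.codes(contig)
        n = len(ref_codes)
        parts_c: list[np.ndarray] = []
        parts_p: list[np.ndarray] = []
        cur = 0  # 0-based cursor into the reference
        for v in sorted(self.variants_for_haplotype(hap, contig), key=lambda v: v.position):
            pos0 = v.position - 1
            if v.kind == "snp":
                seg = ref_codes[cur : pos0 + 1].copy()
                seg[-1] = encode(v.alt_allele)[0]
                parts_c.append(seg)
                parts_p.append(np.arange(cur, pos0 + 1, dtype=np.int64))
                cur = pos0 + 1
            elif v.kind in ("insertion", "large_insertion"):
                parts_c.append(ref_codes[cur : pos0 + 1])
                parts_p.append(np.arange(cur, pos0 + 1, dtype=np.int64))
                ins = encode(v.alt_allele[1:])
                parts_c.append(ins)
                parts_p.append(np.full(len(ins), -1, dtype=np.int64))
                cur = pos0 + 1
            else:  # deletion: keep the anchor base, skip the deleted span
                parts_c.append(ref_codes[cur : pos0 + 1])
                parts_p.append(np.arange(cur, pos0 + 1, dtype=np.int64))
                cur = pos0 + len(v.ref_allele)
        parts_c.append(ref_codes[cur:n])
        parts_p.append(np.arange(cur, n, dtype=np.int64))
        codes = np.concatenate(parts_c)
        ref_pos = np.concatenate(parts_p)
        self._hap_cache[key] = (codes, ref_pos)
        return codes, ref_pos

    def haplotype_length(self, hap: int, contig: str) -> int:
        if hap not in self.complex_haplotypes:
            return self.reference.length(contig)
        return len(self.haplotype_arrays(hap, contig)[0])

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for v, rf in zip(self.variants, self.realized_frequencies):
            rows.append(
                {
                    "contig": v.contig,
                    "pos": v.position,
                    "kind": v.kind,
                    "ref": v.ref_allele,
                    "alt": v.alt_allele,
                    "true_freq": v.true_frequency,
                    "realized_freq": rf,
                }
            )
        return pd.DataFrame(rows, columns=["contig", "pos", "kind", "ref", "alt", "true_freq", "realized_freq"])

    def write_truth_table(self, path: str | Path) -> None:
        self.truth_table().to_csv(path, sep="\t", index=False)


def _round_half_down(x: float) -> int:
    return int(math.ceil(x - 0.5))


def build_pool(
    reference: ReferenceGenome,
    n_haplotypes: int,
    planted_variants: Sequence[PlantedVariant],
    seed: int = 0,
) -> HaplotypePool:
    """Assign each variant to ``round(f * n)`` pseudo-random carrier haplotypes."""
    rng = np.random.default_rng(seed)
    carriers = []
    for v in planted_variants:
        k = _round_half_down(v.true_frequency * n_haplotypes)
        chosen = rng.choice(n_haplotypes, size=k, replace=False) if k else np.empty(0, int)
        carriers.append(frozenset(int(h) for h in chosen))
    return HaplotypePool(reference, n_haplotypes, planted_variants, carriers)


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArtifactSpec:
    """One injectable artifact.

    strand_biased_cluster: G/C mismatches planted on forward-strand
    observations at several sites within ``width`` bp of ``position``.
    read_end_only: a mismatch planted only in reads where the site lies
    within ``width`` bp of a read end.
    """

    kind: str
    contig: str
    position: int
    width: int = 10
    intensity: float = 1.0
    n_sites: int = 4  # strand_biased_cluster only

    def __post_init__(self):
        if self.kind not in ("strand_biased_cluster", "read_end_only"):
            raise InvalidArgument(f"unknown artifact kind {self.kind!r}")
        if not 0.0 < self.intensity <= 1.0:
            raise InvalidArgument("intensity must lie in (0, 1]")
        if self.width < 1:
            raise InvalidArgument("width must be positive")


@dataclass(frozen=True)
class ArtifactTruth:
    spec: ArtifactSpec
    sites: tuple[tuple[int, str, int], ...]  # (position, planted alt base, n planted reads)
    realized: bool


@dataclass(frozen=True)
class SimulationConfig:
    depth: float = 285.0
    read_length: int = 100
    mean_fragment: float = 230.0
    fragment_sd: float = 20.0
    per_base_error: float = 0.001
    seed: int = 0
    artifacts: tuple[ArtifactSpec, ...] = ()

    def __post_init__(self):
        if self.depth <= 0:
            raise InvalidArgument("depth must be positive")
        if self.read_length > self.mean_fragment:
            raise InvalidArgument("read_length must not exceed mean_fragment")
        if not 0.0 <= self.per_base_error < 0.5:
            raise InvalidArgument("per_base_error must lie in [0, 0.5)")

    @property
    def quality(self) -> int:
        """Flat Phred quality consistent with the error rate (Q40 cap)."""
        if self.per_base_error <= 0:
            return 40
        return min(40, int(round(-10.0 * math.log10(self.per_base_error))))


# ---------------------------------------------------------------------------
# Read set
# ---------------------------------------------------------------------------

@dataclass
class ComplexRead:
    """A read from an indel-carrying haplotype, with an explicit CIGAR.

    ``seq`` is in aligned (reference-forward) orientation and covers the
    full read (soft-clipped and inserted bases included). ``ref_start`` is
    the 1-based reference position of the first aligned (M) base, or 0 for
    an unmapped read. ``count_from`` marks the first reference position this
    read may contribute to the pileup (mate-overlap deduplication).
    """

    frag_id: int
    mate: int  # 1 or 2
    contig: str
    strand: int  # 0 forward, 1 reverse
    ref_start: int
    cigar: tuple[tuple[str, int], ...]
    seq: np.ndarray
    count_from: int = 0

    @property
    def mapped(self) -> bool:
        return self.ref_start > 0

    @property
    def ref_end(self) -> int:
        """Last aligned reference base (1-based)."""
        if not self.mapped:
            return 0
        span = sum(n for op, n in self.cigar if op in ("M", "D"))
        return self.ref_start + span - 1


@dataclass
class _SimpleBlock:
    """Vectorised all-match fragments for one contig, sorted by R1 start."""

    contig: str
    frag_id: np.ndarray  # global fragment index
    start: np.ndarray    # 1-based R1 start == fragment start
    flen: np.ndarray
    hap: np.ndarray
    aln1: np.ndarray     # (n, L) uint8, aligned orientation
    aln2: np.ndarray
    order2: np.ndarray = field(init=False)  # argsort of R2 starts

    def __post_init__(self):
        self.order2 = np.argsort(self.r2_start, kind="stable")

    @property
    def n(self) -> int:
        return len(self.start)

    @property
    def r2_start(self) -> np.ndarray:
        L = self.aln1.shape[1]
        return self.start + self.flen - L

    def rows_covering_r1(self, pos: int) -> np.ndarray:
        L = self.aln1.shape[1]
        lo = np.searchsorted(self.start, pos - L + 1, side="left")
        hi = np.searchsorted(self.start, pos, side="right")
        return np.arange(lo, hi)

    def rows_covering_r2(self, pos: int) -> np.ndarray:
        L = self.aln1.shape[1]
        r2s = self.r2_start[self.order2]
        lo = np.searchsorted(r2s, pos - L + 1, side="left")
        hi = np.searchsorted(r2s, pos, side="right")
        return self.order2[lo:hi]


class ReadSet:
    """All simulated reads plus their error-free alignment of origin."""

    def __init__(
        self,
        reference: ReferenceGenome,
        read_length: int,
        quality: int,
        blocks: dict[str, _SimpleBlock],
        complex_reads: list[ComplexRead],
        n_fragments: int,
    ):
        self.reference = reference
        self.read_length = int(read_length)
        self.quality = int(quality)
        self.blocks = blocks
        self.complex_reads = complex_reads
        self.n_fragments = int(n_fragments)

    @property
    def n_reads(self) -> int:
        return 2 * self.n_fragments

    def copy(self) -> "ReadSet":
        blocks = {
            c: _SimpleBlock(b.contig, b.frag_id, b.start, b.flen, b.hap, b.aln1.copy(), b.aln2.copy())
            for c, b in self.blocks.items()
        }
        cplx = [replace(r, seq=r.seq.copy()) for r in self.complex_reads]
        return ReadSet(self.reference, self.read_length, self.quality, blocks, cplx, self.n_fragments)

    # -- output ------------------------------------------------------------

    def _qual_string(self) -> str:
        return chr(self.quality + 33) * self.read_length

    def write_fastq(self, path1: str | Path, path2: str | Path) -> None:
        q = self._qual_string()
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for contig in self.reference.contig_names:
                b = self.blocks.get(contig)
                if b is None:
                    continue
                for i in range(b.n):
                    name = f"sim:{b.frag_id[i]}"
                    f1.write(f"@{name}/1\n{decode(b.aln1[i])}\n+\n{q}\n")
                    f2.write(f"@{name}/2\n{decode(revcomp_codes(b.aln2[i]))}\n+\n{q}\n")
            for r in self.complex_reads:
                fh = f1 if r.mate == 1 else f2
                seq = decode(r.seq) if r.strand == 0 else decode(revcomp_codes(r.seq))
                fh.write(f"@sim:{r.frag_id}/{r.mate}\n{seq}\n+\n{q}\n")

    def write_truth_sam(self, path: str | Path) -> None:
        """Write the error-free origin of every read as coordinate-sorted SAM."""
        import pysam

        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": n, "LN": self.reference.length(n)} for n in self.reference.contig_names
            ],
        }
        L = self.read_length
        q = pysam.qualitystring_to_array(self._qual_string())
        records = []
        tid = {n: i for i, n in enumerate(self.reference.contig_names)}
        for contig in self.reference.contig_names:
            b = self.blocks.get(contig)
            if b is None:
                continue
            r2s = b.r2_start
            for i in range(b.n):
                records.append(
                    (tid[contig], int(b.start[i]), f"sim:{b.frag_id[i]}", 1, 0,
                     f"{L}M", decode(b.aln1[i]), int(r2s[i]), int(b.flen[i]))
                )
                records.append(
                    (tid[contig], int(r2s[i]), f"sim:{b.frag_id[i]}", 2, 1,
                     f"{L}M", decode(b.aln2[i]), int(b.start[i]), -int(b.flen[i]))
                )
        by_frag: dict[int, dict[int, ComplexRead]] = {}
        for r in self.complex_reads:
            by_frag.setdefault(r.frag_id, {})[r.mate] = r
        for fid, mates in by_frag.items():
            for mate, r in mates.items():
                if not r.mapped:
                    continue
                other = mates.get(3 - mate)
                mpos = other.ref_start if other is not None and other.mapped else r.ref_start
                cigar = "".join(f"{n}{op}" for op, n in r.cigar)
                tlen = 0
                if other is not None and other.mapped:
                    left = min(r.ref_start, other.ref_start)
                    right = max(r.ref_end, other.ref_end)
                    tlen = (right - left + 1) * (1 if r.ref_start <= other.ref_start else -1)
                records.append(
                    (tid[r.contig], r.ref_start, f"sim:{fid}", r.mate, r.strand,
                     cigar, decode(r.seq), mpos, tlen)
                )
        records.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for tid_, pos, name, mate, strand, cigar, seq, mpos, tlen in records:
                a = pysam.AlignedSegment(out.header)
                a.query_name = name
                a.reference_id = tid_
                a.reference_start = pos - 1
                a.cigarstring = cigar
                a.mapping_quality = 60
                flag = 0x1 | 0x2
                flag |= 0x40 if mate == 1 else 0x80
                if strand == 1:
                    flag |= 0x10
                else:
                    flag |= 0x20
                a.flag = flag
                a.query_sequence = seq
                a.query_qualities = q[: len(seq)]
                a.next_reference_id = tid_
                a.next_reference_start = mpos - 1
                a.template_length = tlen
                out.write(a)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

_ERROR_CHUNK = 200_000


def _inject_errors(aln: np.ndarray, e: float, rng: np.random.Generator) -> None:
    """Substitute bases in place at rate ``e``, uniform over the other three."""
    if e <= 0:
        return
    n = aln.shape[0]
    for lo in range(0, n, _ERROR_CHUNK):
        chunk = aln[lo : lo + _ERROR_CHUNK]
        mask = rng.random(chunk.shape) < e
        k = int(mask.sum())
        if k:
            shift = rng.integers(1, 4, size=k).astype(np.uint8)
            chunk[mask] = (chunk[mask] + shift) % 4


def _cigar_from_refpos(
    ref_pos: np.ndarray, min_anchor: int = 20, large_gap: int = 30
) -> tuple[int, tuple[tuple[str, int], ...]]:
    """Build (1-based ref_start, cigar) from a per-base reference-position map.

    Leading/trailing inserted bases become soft clips. Alignments whose
    match flank next to a *large* deletion (> ``large_gap``) is shorter than
    ``min_anchor`` are soft-clipped on that side, emulating what a local
    aligner reports near a large event; small indels keep short flanks.
    """
    L = len(ref_pos)
    ops: list[tuple[str, int]] = []
    i = 0
    # leading insertions -> soft clip
    while i < L and ref_pos[i] < 0:
        i += 1
    lead = i
    if lead:
        ops.append(("S", lead))
    if i == L:
        return 0, tuple(ops)  # fully inserted: unmapped
    start0 = int(ref_pos[i])
    prev = start0 - 1
    run = 0
    while i < L:
        if ref_pos[i] < 0:
            j = i
            while j < L and ref_pos[j] < 0:
                j += 1
            if j == L:  # trailing insertion -> soft clip
                if run:
                    ops.append(("M", run))
                    run = 0
                ops.append(("S", j - i))
                i = j
                break
            if run:
                ops.append(("M", run))
                run = 0
            ops.append(("I", j - i))
            i = j
            continue
        gap = int(ref_pos[i]) - prev - 1
        if gap > 0:
            if run:
                ops.append(("M", run))
                run = 0
            ops.append(("D", gap))
        run += 1
        prev = int(ref_pos[i])
        i += 1
    if run:
        ops.append(("M", run))

    # soft-clip short flanks around deletions
    def m_sum(seq: Iterable[tuple[str, int]]) -> int:
        return sum(n for op, n in seq if op == "M")

    changed = True
    while changed:
        changed = False
        d_idx = [k for k, (op, n) in enumerate(ops) if op == "D" and n > large_gap]
        if not d_idx:
            break
        first, last = d_idx[0], d_idx[-1]
        if m_sum(ops[:first]) < min_anchor:
            clipped = sum(n for op, n in ops[: first + 1] if op in ("M", "I", "S"))
            removed_ref = sum(n for op, n in ops[: first + 1] if op in ("M", "D"))
            ops = [("S", clipped)] + ops[first + 1 :]
            start0 += removed_ref
            changed = True
            continue
        if m_sum(ops[last + 1 :]) < min_anchor:
            clipped = sum(n for op, n in ops[last:] if op in ("M", "I", "S"))
            ops = ops[:last] + [("S", clipped)]
            changed = True
    if not any(op == "M" for op, _ in ops):
        return 0, tuple(ops)
    return start0 + 1, tuple(_merge_ops(ops))


def _merge_ops(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, n in ops:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def simulate_reads(pool: HaplotypePool, config: SimulationConfig) -> ReadSet:
    """Draw paired-end reads from the pool.

    Fragments are assigned uniformly across haplotypes, so each variant's
    expected read-level frequency equals its realized pool frequency.
    Read 1 is the forward strand of the fragment start, read 2 the reverse
    strand of the fragment end. When mates overlap, only read 1 contributes
    the overlapping bases to downstream pileups.
    """
    ref = pool.reference
    L = config.read_length
    rng = np.random.default_rng(config.seed)
    total = ref.total_length
    n_frag = int(round(config.depth * total / (2.0 * L)))
    if n_frag < 1:
        raise InvalidArgument("configuration yields zero fragments")
    names = ref.contig_names
    lens = np.array([ref.length(n) for n in names], dtype=np.int64)
    contig_of = (
        rng.choice(len(names), size=n_frag, p=lens / lens.sum())
        if len(names) > 1
        else np.zeros(n_frag, dtype=np.int64)
    )
    hap_of = rng.integers(0, pool.n_haplotypes, size=n_frag)
    flen = np.rint(rng.normal(config.mean_fragment, config.fragment_sd, size=n_frag)).astype(np.int64)
    complex_haps = pool.complex_haplotypes
    is_complex = (
        np.isin(hap_of, np.fromiter(complex_haps, dtype=np.int64))
        if complex_haps
        else np.zeros(n_frag, dtype=bool)
    )
    frag_ids = np.arange(n_frag, dtype=np.int64)

    blocks: dict[str, _SimpleBlock] = {}
    complex_reads: list[ComplexRead] = []

    for ci, contig in enumerate(names):
        clen = int(lens[ci])
        sel = (contig_of == ci) & ~is_complex
        if sel.any():
            fl = np.clip(flen[sel], L, clen)
            starts = rng.integers(1, clen - fl + 2)
            order = np.argsort(starts, kind="stable")
            fl = fl[order]
            starts = starts[order]
            fids = frag_ids[sel][order]
            haps = hap_of[sel][order]
            codes = ref.codes(contig)
            offs = np.arange(L, dtype=np.int64)
            aln1 = codes[(starts[:, None] - 1) + offs]
            aln2 = codes[(starts[:, None] + fl[:, None] - L - 1) + offs]
            block = _SimpleBlock(contig, fids, starts, fl, haps, aln1, aln2)
            _apply_snps(block, pool, contig)
            _inject_errors(block.aln1, config.per_base_error, rng)
            _inject_errors(block.aln2, config.per_base_error, rng)
            block.__post_init__()  # refresh order2 (flen unchanged, but be safe)
            blocks[contig] = block
        # complex fragments, grouped per haplotype for cache locality
        csel = (contig_of == ci) & is_complex
        if csel.any():
            for h in sorted(set(int(x) for x in hap_of[csel])):
                hsel = csel & (hap_of == h)
                hcodes, hrefpos = pool.haplotype_arrays(h, contig)
                hlen = len(hcodes)
                fl = np.clip(flen[hsel], L, hlen)
                starts = rng.integers(1, hlen - fl + 2)
                fids = frag_ids[hsel]
                for s, f, fid in zip(starts, fl, fids):
                    complex_reads.extend(
                        _complex_pair(int(fid), contig, hcodes, hrefpos, int(s), int(f), L, config, rng)
                    )

    return ReadSet(ref, L, config.quality, blocks, complex_reads, n_frag)


def _apply_snps(block: _SimpleBlock, pool: HaplotypePool, contig: str) -> None:
    L = block.aln1.shape[1]
    for v, carriers in zip(pool.variants, pool.carriers):
        if v.kind != "snp" or v.contig != contig or not carriers:
            continue
        lut = np.zeros(pool.n_haplotypes, dtype=bool)
        lut[list(carriers)] = True
        alt = encode(v.alt_allele)[0]
        rows = block.rows_covering_r1(v.position)
        rows = rows[lut[block.hap[rows]]]
        if len(rows):
            block.aln1[rows, v.position - block.start[rows]] = alt
        rows = block.rows_covering_r2(v.position)
        rows = rows[lut[block.hap[rows]]]
        if len(rows):
            block.aln2[rows, v.position - block.r2_start[rows]] = alt


def _complex_pair(
    frag_id: int,
    contig: str,
    hcodes: np.ndarray,
    hrefpos: np.ndarray,
    start: int,
    flen: int,
    L: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[ComplexRead]:
    out = []
    s0 = start - 1
    for mate, strand, lo in ((1, 0, s0), (2, 1, s0 + flen - L)):
        seq = hcodes[lo : lo + L].copy()
        if config.per_base_error > 0:
            mask = rng.random(L) < config.per_base_error
            k = int(mask.sum())
            if k:
                shift = rng.integers(1, 4, size=k).astype(np.uint8)
                seq[mask] = (seq[mask] + shift) % 4
        ref_start, cigar = _cigar_from_refpos(hrefpos[lo : lo + L])
        out.append(ComplexRead(frag_id, mate, contig, strand, ref_start, cigar, seq))
    r1, r2 = out
    if r1.mapped:
        r2.count_from = r1.ref_end + 1
    return out


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------

_CLUSTER_OFFSETS = (0, 3, 6, 9, -3, -6, -9)


def inject_artifacts(
    reads: ReadSet,
    artifact_spec: Sequence[ArtifactSpec],
    seed: int = 0,
) -> tuple[ReadSet, list[ArtifactTruth]]:
    """Plant artifact mismatches into a copy of the read set.

    Returns the modified reads and a truth record per artifact; an artifact
    whose sites are uncovered by any read is recorded as unrealized and a
    warning is emitted.
    """
    rs = reads.copy()
    rng = np.random.default_rng(seed)
    truth: list[ArtifactTruth] = []
    for spec in artifact_spec:
        ref_codes = rs.reference.codes(spec.contig)
        if spec.kind == "strand_biased_cluster":
            sites = []
            for off in _CLUSTER_OFFSETS:
                if len(sites) >= spec.n_sites:
                    break
                p = spec.position + off
                if abs(off) <= spec.width and 1 <= p <= len(ref_codes):
                    sites.append(p)
            site_records = []
            for p in sorted(sites):
                alt = 2 if ref_codes[p - 1] != 2 else 1  # G unless ref G, then C
                n = _plant_strand_biased(rs, spec.contig, p, alt, spec.intensity, rng)
                site_records.append((p, BASES[alt], n))
        else:  # read_end_only
            p = spec.position
            alt = int((ref_codes[p - 1] + 1) % 4)
            n = _plant_read_end_only(rs, spec.contig, p, alt, spec.width, spec.intensity, rng)
            site_records = [(p, BASES[alt], n)]
        realized = any(n > 0 for _, _, n in site_records)
        if not realized:
            warnings.warn(
                f"artifact at {spec.contig}:{spec.position} not covered by any read",
                stacklevel=2,
            )
        truth.append(ArtifactTruth(spec, tuple(site_records), realized))
    return rs, truth


def _plant_strand_biased(
    rs: ReadSet, contig: str, pos: int, alt: int, intensity: float, rng: np.random.Generator
) -> int:
    """Plant ``alt`` into forward-strand observations of ``pos``."""
    planted = 0
    b = rs.blocks.get(contig)
    if b is not None:
        rows = b.rows_covering_r1(pos)  # R1 observations are forward strand
        take = rows[rng.random(len(rows)) < intensity]
        b.aln1[take, pos - b.start[take]] = alt
        planted += len(take)
    for r in rs.complex_reads:
        if r.contig == contig and r.strand == 0:
            j = _read_index_at(r, pos)
            if j is not None and rng.random() < intensity:
                r.seq[j] = alt
                planted += 1
    return planted


def _plant_read_end_only(
    rs: ReadSet, contig: str, pos: int, alt: int, width: int, intensity: float, rng: np.random.Generator
) -> int:
    """Plant ``alt`` at ``pos`` only in reads where it sits within ``width`` bp of an end."""
    planted = 0
    b = rs.blocks.get(contig)
    L = rs.read_length
    if b is not None:
        for rows, aln, starts in (
            (b.rows_covering_r1(pos), b.aln1, b.start),
            (b.rows_covering_r2(pos), b.aln2, b.r2_start),
        ):
            j = pos - starts[rows]
            near_end = np.minimum(j, L - 1 - j) <= width
            take = rows[near_end]
            take = take[rng.random(len(take)) < intensity]
            aln[take, pos - starts[take]] = alt
            planted += len(take)
    for r in rs.complex_reads:
        if r.contig == contig:
            j = _read_index_at(r, pos)
            if j is not None and min(j, L - 1 - j) <= width and rng.random() < intensity:
                r.seq[j] = alt
                planted += 1
    return planted


def _read_index_at(r: ComplexRead, pos: int) -> int | None:
    """Index into ``r.seq`` of the base aligned to reference ``pos``, if any."""
    if not r.mapped:
        return None
    cur = r.ref_start
    j = 0
    for op, n in r.cigar:
        if op in ("S", "I"):
            j += n
        elif op == "M":
            if cur <= pos < cur + n:
                return j + (pos - cur)
            cur += n
            j += n
        elif op == "D":
            cur += n
    return None
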