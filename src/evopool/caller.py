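"""Likelihood-based pooled SNP calling and count-based small-indel calling.

The SNP score is a log-likelihood ratio over a discrete frequency grid
{0, 1/h, ..., 1} where ``h`` is the assumed number of haplotypes in the
pool. Each retained observation (the two most frequent alleles at the
site) is alt with probability ``f(1-e) + (1-f)e/3`` and ref with
probability ``(1-f)(1-e) + f e/3``; the score is the best grid
log-likelihood minus the no-variant (f=0) log-likelihood.

The reported allele frequency is the continuous read-level fraction; the
grid only drives detection. Small indels are scored by counting reads that
show the event against reads that do not.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, InvalidArgument
from .pileup import Pileup, PileupColumn

__all__ = ["CallerConfig", "VariantCall", "site_loglik", "call_snp", "call_indel", "call_variants"]


@dataclass(frozen=True)
class CallerConfig:
    haplotype_number: int = 10
    min_frequency: float = 0.05
    per_base_error: float = 0.001
    min_score: float = 10.0
    min_alt_reads: int = 8
    min_indel_support_reads: int = 5
    min_indel_support_fraction: float = 0.05

    def __post_init__(self):
        if self.haplotype_number < 1:
            raise InvalidArgument("haplotype_number must be positive")
        if not 0.0 < self.min_frequency <= 1.0:
            raise InvalidArgument("min_frequency must lie in (0, 1]")
        if not 0.0 < self.per_base_error < 0.5:
            raise InvalidArgument("per_base_error must lie in (0, 0.5)")
        if self.min_score < 0 or self.min_alt_reads < 0:
            raise InvalidArgument("thresholds must be non-negative")

    @property
    def frequency_grid(self) -> np.ndarray:
        h = self.haplotype_number
        return np.arange(h + 1) / h


@dataclass
class VariantCall:
    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    kind: str  # snp | insertion | deletion
    af_estimate: float
    alt_count: int
    total_count: int
    score: float
    grid_frequency: float
    filter_flags: set[str] = field(default_factory=set)
    founder_status: str = "unknown"  # novel | in_founder | unknown

    @property
    def is_pass(self) -> bool:
        return not self.filter_flags

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref_allele, self.alt_allele)


def _obs_probs(f: float, e: float) -> tuple[float, float]:
    p_alt = f * (1.0 - e) + (1.0 - f) * e / 3.0
    p_ref = (1.0 - f) * (1.0 - e) + f * e / 3.0
    return p_alt, p_ref


def site_loglik(column: PileupColumn, f: float, e: float, alt_base: str | None = None) -> float:
    """Log-likelihood of alt frequency ``f`` at one column.

    Only the two most frequent alleles at the site are retained (others are
    folded into the error term). ``alt_base`` forces which base is treated
    as the alternate; by default the most frequent non-reference base.
    """
    if not 0.0 <= f <= 1.0:
        raise InvalidArgument("f must lie in [0, 1]")
    if column.depth < 1:
        raise InsufficientDataError(f"no retained observations at {column.contig}:{column.position}")
    n_alt, n_ref = _retained_counts(column, alt_base)
    p_alt, p_ref = _obs_probs(f, e)
    # xlogy keeps 0*log(0) == 0 at the grid edges
    from scipy.special import xlogy

    return float(xlogy(n_alt, p_alt) + xlogy(n_ref, p_ref))


def _retained_counts(column: PileupColumn, alt_base: str | None) -> tuple[int, int]:
    if alt_base is None:
        alts = column.alt_counts()
        if not alts:
            return 0, column.ref_count
        alt_base = _best_alt(column, alts)
    return column.count(alt_base), column.ref_count


def _best_alt(column: PileupColumn, alts: dict[str, int]) -> str:
    """Most frequent alternate; ties -> higher summed quality, then base order."""
    from ._seq import BASES

    best = max(
        alts,
        key=lambda b: (alts[b], column.quality_sums[BASES.index(b)], -ord(b)),
    )
    return best


def _grid_score(n_alt: int, n_ref: int, config: CallerConfig) -> tuple[float, float]:
    """(score, argmax grid frequency); ties resolve to the smaller frequency."""
    from scipy.special import xlogy

    e = config.per_base_error
    grid = config.frequency_grid
    p_alt = grid * (1.0 - e) + (1.0 - grid) * e / 3.0
    p_ref = (1.0 - grid) * (1.0 - e) + grid * e / 3.0
    ll = xlogy(n_alt, p_alt) + xlogy(n_ref, p_ref)
    best = int(np.argmax(ll))
    return float(ll[best] - ll[0]), float(grid[best])


def call_snp(column: PileupColumn, config: CallerConfig) -> list[VariantCall]:
    """Emit zero or more SNP calls at a column (one per passing alternate).

    A call is emitted when the grid likelihood-ratio score reaches
    ``min_score``, the alternate has at least ``min_alt_reads``
    observations, and the best grid frequency reaches ``min_frequency``
    (the design detection floor). The reported ``af_estimate`` is the raw
    alternate read fraction.
    """
    if column.depth < 1:
        return []
    calls: list[VariantCall] = []
    for alt_base, alt_count in column.alt_counts().items():
        if alt_count < config.min_alt_reads:
            continue
        n_ref = column.ref_count
        score, grid_f = _grid_score(alt_count, n_ref, config)
        if score < config.min_score or grid_f < config.min_frequency:
            continue
        total = alt_count + n_ref
        calls.append(
            VariantCall(
                contig=column.contig,
                position=column.position,
                ref_allele=column.ref_base,
                alt_allele=alt_base,
                kind="snp",
                af_estimate=alt_count / total,
                alt_count=alt_count,
                total_count=total,
                score=score,
                grid_frequency=grid_f,
            )
        )
    calls.sort(key=lambda c: (-c.alt_count, c.alt_allele))
    return calls


def call_indel(
    pileup: Pileup,
    contig: str,
    anchor: int,
    allele,
    support: int,
    config: CallerConfig,
) -> VariantCall | None:
    """Count-based indel call at a left-anchored site.

    ``allele`` is ``('I', inserted_seq)`` or ``('D', deleted_length)``. The
    frequency estimate is reads showing the indel over reads showing plus
    reads not showing it.
    """
    kind, payload = ("insertion", allele[1]) if allele[0] == "I" else ("deletion", allele[1])
    depth = pileup.depth_array(contig)
    if kind == "deletion":
        first_deleted = anchor + 1
        non_showing = int(depth[first_deleted]) if first_deleted < len(depth) else 0
    else:
        non_showing = max(int(depth[anchor]) - support, 0)
    total = support + non_showing
    if total == 0:
        return None
    af = support / total
    if support < config.min_indel_support_reads or af < config.min_indel_support_fraction:
        return None
    anchor_base = pileup.reference.base(contig, anchor)
    if kind == "insertion":
        ref_allele = anchor_base
        alt_allele = anchor_base + payload
    else:
        ref_allele = pileup.reference.slice(contig, anchor, anchor + payload)
        alt_allele = anchor_base
    h = config.haplotype_number
    return VariantCall(
        contig=contig,
        position=anchor,
        ref_allele=ref_allele,
        alt_allele=alt_allele,
        kind=kind,
        af_estimate=af,
        alt_count=support,
        total_count=total,
        score=0.0,
        grid_frequency=round(af * h) / h,
    )


def call_variants(pileup: Pileup, config: CallerConfig | None = None) -> list[VariantCall]:
    """Scan a pileup for SNPs and small indels."""
    config = config or CallerConfig()
    calls: list[VariantCall] = []
    for contig in pileup.reference.contig_names:
        for pos in pileup.candidate_snp_sites(contig, config.min_alt_reads):
            calls.extend(call_snp(pileup.column(contig, int(pos)), config))
        for anchor, counter in sorted(pileup.indel_sites(contig).items()):
            for allele, support in sorted(counter.items(), key=lambda kv: (-kv[1], str(kv[0]))):
                call = call_indel(pileup, contig, int(anchor), allele, int(support), config)
                if call is not None:
                    calls.append(call)
    calls.sort(key=lambda c: (c.contig, c.position, c.alt_allele))
    return calls
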