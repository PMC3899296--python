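"""Automated false-positive filters and founder subtraction.

Three rules, each of which annotates (never removes) a call:

* STRAND_CTX — several strand-biased G/C mismatch sites near the call,
  the signature of a sequence-specific sequencing error;
* READ_POS — the alternate allele is (almost) never observed in the middle
  of a read, the signature of an alignment problem;
* NEAR_SV — indel/soft-clip evidence or a structural-variant breakpoint
  close to the call.

Founder subtraction marks calls already present in the founder population
instead of deleting them; reporting decides what to show.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import fisher_exact

from ._seq import BASES
from .caller import VariantCall
from .errors import InvalidArgument
from .pileup import Pileup

__all__ = [
    "FilterConfig",
    "FLAG_STRAND", "FLAG_READ_POS", "FLAG_NEAR_SV", "FLAG_NO_CONTEXT",
    "flag_strand_context",
    "flag_read_position",
    "flag_near_sv",
    "subtract_founder",
    "apply_filters",
]

FLAG_STRAND = "STRAND_CTX"
FLAG_READ_POS = "READ_POS"
FLAG_NEAR_SV = "NEAR_SV"
FLAG_NO_CONTEXT = "insufficient_context"

_GC = (BASES.index("G"), BASES.index("C"))


@dataclass(frozen=True)
class FilterConfig:
    context_window: int = 10
    min_biased_sites: int = 3
    strand_bias_alpha: float = 0.01
    end_zone: float = 0.25
    min_mid_read_fraction: float = 0.1
    sv_proximity: int = 25
    sv_support_min: int = 5
    founder_presence_threshold: float = 0.05

    def __post_init__(self):
        if self.context_window < 1 or self.sv_proximity < 1 or self.sv_support_min < 1:
            raise InvalidArgument("windows and support thresholds must be positive")
        for frac in (self.strand_bias_alpha, self.end_zone, self.min_mid_read_fraction,
                     self.founder_presence_threshold):
            if not 0.0 < frac < 1.0:
                raise InvalidArgument("fractional thresholds must lie in (0, 1)")


def strand_bias_pvalue(mm_fwd: int, mm_rev: int, depth_fwd: int, depth_rev: int) -> float:
    """Two-sided exact (hypergeometric) test of strand balance for a mismatch."""
    table = [[mm_fwd, mm_rev], [depth_fwd - mm_fwd, depth_rev - mm_rev]]
    return float(fisher_exact(table, alternative="two-sided")[1])


def _biased_gc_sites(pileup: Pileup, contig: str, lo: int, hi: int, alpha: float) -> int:
    """Count sites in [lo, hi] with a strand-biased G or C mismatch."""
    d = pileup.data(contig)
    ref_codes = pileup.reference.codes(contig)
    counts = d.counts[lo : hi + 1]  # (w, 4, 2)
    n_biased = 0
    for i in range(counts.shape[0]):
        pos = lo + i
        ref = ref_codes[pos - 1]
        depth_f = int(counts[i, :, 0].sum())
        depth_r = int(counts[i, :, 1].sum())
        for b in _GC:
            if b == ref:
                continue
            mf, mr = int(counts[i, b, 0]), int(counts[i, b, 1])
            if mf + mr == 0:
                continue
            if strand_bias_pvalue(mf, mr, depth_f, depth_r) < alpha:
                n_biased += 1
                break  # one biased mismatch makes the site count once
    return n_biased


def flag_strand_context(call: VariantCall, pileup: Pileup, config: FilterConfig) -> str | None:
    """Flag when >= min_biased_sites positions within the context window
    (call site included) carry strand-biased G/C mismatches."""
    if call.kind != "snp":
        return None
    d = pileup.data(call.contig)
    lo = max(1, call.position - config.context_window)
    hi = min(d.length, call.position + config.context_window)
    depth = pileup.depth_array(call.contig)
    covered = int((depth[lo : hi + 1] > 0).sum())
    if covered < config.min_biased_sites:
        call.filter_flags.add(FLAG_NO_CONTEXT)
        return FLAG_NO_CONTEXT
    if _biased_gc_sites(pileup, call.contig, lo, hi, config.strand_bias_alpha) >= config.min_biased_sites:
        call.filter_flags.add(FLAG_STRAND)
        return FLAG_STRAND
    return None


def flag_read_position(
    call: VariantCall, pileup: Pileup, config: FilterConfig, read_length: int | None = None
) -> str | None:
    """Flag when too few alternate observations sit in the middle of a read.

    "Middle" means at least ``end_zone * read_length`` from both read ends.
    """
    if call.kind != "snp":
        return None
    L = read_length or pileup.read_length
    if not L:
        raise InvalidArgument("read length unknown; pass read_length explicitly")
    d = pileup.data(call.contig)
    alt_code = BASES.index(call.alt_allele)
    offsets = [off for base, _s, off in d.obs_offsets.get(call.position, ()) if base == alt_code]
    if not offsets:
        return None
    mid_cut = config.end_zone * L
    n_mid = sum(1 for off in offsets if off >= mid_cut)
    if n_mid / len(offsets) < config.min_mid_read_fraction:
        call.filter_flags.add(FLAG_READ_POS)
        return FLAG_READ_POS
    return None


def flag_near_sv(
    call: VariantCall,
    pileup: Pileup,
    config: FilterConfig,
    sv_candidates: Sequence = (),
) -> str | None:
    """Flag when large-indel/clip evidence sits within sv_proximity bp (closed).

    Applies to SNP calls only — an indel call would otherwise be flagged by
    its own supporting evidence.
    """
    if call.kind != "snp":
        return None
    d = pileup.data(call.contig)
    lo = max(1, call.position - config.sv_proximity)
    hi = min(d.length, call.position + config.sv_proximity)
    support = (
        d.ins[lo : hi + 1].astype(np.int64)
        + d.dels[lo : hi + 1]
        + d.clip_left[lo : hi + 1]
        + d.clip_right[lo : hi + 1]
    )
    near = bool((support >= config.sv_support_min).any())
    if not near:
        for cand in sv_candidates:
            if getattr(cand, "contig", None) != call.contig:
                continue
            for bp in (cand.left_breakpoint, cand.right_breakpoint):
                if abs(bp - call.position) <= config.sv_proximity:
                    near = True
                    break
            if near:
                break
    if near:
        call.filter_flags.add(FLAG_NEAR_SV)
        return FLAG_NEAR_SV
    return None


def subtract_founder(
    calls: Iterable[VariantCall],
    founder_calls: Iterable[VariantCall] | None,
    config: FilterConfig | None = None,
) -> list[VariantCall]:
    """Set founder_status on every call; nothing is deleted.

    A call matches a founder call on (contig, position, alt allele); the
    founder variant counts as present when its frequency reaches
    ``founder_presence_threshold``.
    """
    calls = list(calls)
    if founder_calls is None:
        for c in calls:
            c.founder_status = "unknown"
        return calls
    config = config or FilterConfig()
    founder_af = {}
    for f in founder_calls:
        k = (f.contig, f.position, f.alt_allele)
        founder_af[k] = max(founder_af.get(k, 0.0), f.af_estimate)
    for c in calls:
        af = founder_af.get((c.contig, c.position, c.alt_allele))
        c.founder_status = (
            "in_founder" if af is not None and af >= config.founder_presence_threshold else "novel"
        )
    return calls


def apply_filters(
    calls: Iterable[VariantCall],
    pileup: Pileup,
    config: FilterConfig | None = None,
    sv_candidates: Sequence = (),
    read_length: int | None = None,
) -> list[VariantCall]:
    """Run the three false-positive rules over every call (idempotent)."""
    config = config or FilterConfig()
    calls = list(calls)
    for call in calls:
        flag_strand_context(call, pileup, config)
        flag_read_position(call, pileup, config, read_length)
        flag_near_sv(call, pileup, config, sv_candidates)
    return calls
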