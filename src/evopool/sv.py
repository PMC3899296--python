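"""Large-variant evidence from discordant pairs and soft clips.

Discordant pairs (anomalous orientation or insert size) are clustered into
breakpoint candidates; soft-clip consensus then refines the breakpoints to
base resolution — the automated stand-in for manual breakpoint inspection.

Deletion candidates report the deleted span itself: ``left_breakpoint`` is
the first deleted base and ``right_breakpoint`` the last.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from statistics import median

import numpy as np

from .pileup import PairStats, Pileup

__all__ = ["SVCandidate", "cluster_discordant", "refine_breakpoints"]


@dataclass(frozen=True)
class SVCandidate:
    contig: str
    left_breakpoint: int
    right_breakpoint: int
    kind: str  # deletion | insertion | inversion_like | unclassified
    pair_support: int
    clip_support: int
    implied_size: int
    refined: bool = False


def cluster_discordant(
    pair_stats: PairStats,
    min_pairs: int = 4,
) -> list[SVCandidate]:
    """Group discordant pairs into candidates; drop clusters below ``min_pairs``.

    Pairs join the same cluster when they share direction class and their
    left and right anchors each fall within the median insert of the
    cluster's current anchors.
    """
    window = max(int(round(pair_stats.median_insert)), 1)

    def direction(p) -> str:
        if p.orientation == "same":
            return "inversion_like"
        if p.orientation == "RF":
            return "unclassified"
        return "deletion" if p.implied_size > 0 else "insertion"

    groups: dict[tuple[str, str], list] = {}
    for p in pair_stats.discordant_pairs:
        groups.setdefault((p.contig, direction(p)), []).append(p)

    candidates: list[SVCandidate] = []
    for (contig, kind), pairs in sorted(groups.items()):
        pairs.sort(key=lambda p: (p.left_pos, p.right_pos))
        cluster: list = []
        for p in pairs:
            if cluster and (
                p.left_pos - cluster[-1].left_pos > window
                or abs(p.right_pos - median(q.right_pos for q in cluster)) > 2 * window
            ):
                cand = _make_candidate(contig, kind, cluster, min_pairs)
                if cand:
                    candidates.append(cand)
                cluster = []
            cluster.append(p)
        cand = _make_candidate(contig, kind, cluster, min_pairs)
        if cand:
            candidates.append(cand)
    candidates.sort(key=lambda c: (c.contig, c.left_breakpoint))
    return candidates


def _make_candidate(contig: str, kind: str, cluster: list, min_pairs: int) -> SVCandidate | None:
    if len(cluster) < min_pairs:
        return None
    left = max(p.left_pos for p in cluster) + 1   # first base past the leftmost reads
    right = min(p.right_pos for p in cluster) - 1
    if right < left:
        left, right = min(left, right), max(left, right)
    implied = int(abs(median(p.implied_size for p in cluster)))
    return SVCandidate(
        contig=contig,
        left_breakpoint=left,
        right_breakpoint=right,
        kind=kind,
        pair_support=len(cluster),
        clip_support=0,
        implied_size=implied,
    )


def refine_breakpoints(
    candidate: SVCandidate,
    pileup: Pileup,
    window: int | None = None,
    min_clip_reads: int = 2,
) -> SVCandidate:
    """Snap breakpoints to soft-clip consensus positions.

    The left breakpoint snaps to the modal position where read tails are
    clipped off (trailing clips); the right breakpoint to the modal leading
    clip position minus one. Ties resolve to the leftmost position; without
    ``min_clip_reads`` concordant clips a breakpoint is left unchanged.
    """
    d = pileup.data(candidate.contig)
    if window is None:
        window = max(candidate.implied_size, 200)

    def modal(arr: np.ndarray, center: int) -> tuple[int | None, int]:
        lo = max(1, center - window)
        hi = min(d.length + 1, center + window)
        seg = arr[lo : hi + 1]
        if seg.size == 0 or seg.max() < min_clip_reads:
            return None, 0
        return lo + int(np.argmax(seg)), int(seg.max())  # argmax -> leftmost tie

    left_pos, left_n = modal(d.clip_right, candidate.left_breakpoint)
    right_pos, right_n = modal(d.clip_left, candidate.right_breakpoint)
    left = left_pos if left_pos is not None else candidate.left_breakpoint
    right = right_pos - 1 if right_pos is not None else candidate.right_breakpoint
    refined = left_pos is not None or right_pos is not None
    return replace(
        candidate,
        left_breakpoint=left,
        right_breakpoint=max(right, left),
        clip_support=left_n + right_n,
        refined=refined,
    )


def find_sv_candidates(
    pair_stats: PairStats,
    pileup: Pileup,
    min_pairs: int = 4,
) -> list[SVCandidate]:
    """cluster + refine in one step."""
    return [refine_breakpoints(c, pileup) for c in cluster_discordant(pair_stats, min_pairs)]
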