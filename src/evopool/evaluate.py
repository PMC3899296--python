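"""Closed-loop evaluation against simulation truth.

Known-variant pools are scored for false positives, false negatives and
allele-frequency agreement; ``power_curve`` runs the whole
simulate -> pileup -> call -> filter chain per frequency and replicate.
Agreement is always measured against the realized (post-rounding) pool
frequency — the estimator cannot beat the discreteness of the pool.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES
from .caller import CallerConfig, VariantCall, call_variants
from .errors import InsufficientDataError
from .filters import FilterConfig, apply_filters
from .pileup import build_pileup
from .sim import (
    HaplotypePool,
    PlantedVariant,
    SimulationConfig,
    build_pool,
    generate_reference,
    simulate_reads,
    snp,
)

__all__ = [
    "MatchResult",
    "EvalReport",
    "match_calls",
    "af_agreement",
    "power_curve",
    "detection_floor",
    "false_positive_run",
    "evaluate_run",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Matching calls against truth
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    matched: list[tuple[VariantCall, dict]]  # (call, truth row)
    unmatched_calls: list[VariantCall]       # false positives
    unmatched_truth: list[dict]              # false negatives


def _truth_rows(truth) -> list[dict]:
    if isinstance(truth, pd.DataFrame):
        return truth.to_dict("records")
    rows = []
    for t in truth:
        if isinstance(t, PlantedVariant):
            rows.append(
                {"contig": t.contig, "pos": t.position, "kind": t.kind,
                 "ref": t.ref_allele, "alt": t.alt_allele,
                 "true_freq": t.true_frequency, "realized_freq": None}
            )
        else:
            rows.append(dict(t))
    return rows


def match_calls(
    calls: Sequence[VariantCall],
    truth,
    snp_tolerance: int = 0,
    indel_tolerance: int = 5,
) -> MatchResult:
    """One-to-one greedy matching, nearest position first.

    A call matches a truth record on contig and alt allele, with position
    within the kind-specific tolerance.
    """
    rows = _truth_rows(truth)
    taken = [False] * len(rows)
    pairs: list[tuple[int, int, int]] = []  # (distance, call idx, truth idx)
    for ci, c in enumerate(calls):
        tol = snp_tolerance if c.kind == "snp" else indel_tolerance
        for ti, t in enumerate(rows):
            if t["contig"] != c.contig or t["alt"] != c.alt_allele:
                continue
            dist = abs(int(t["pos"]) - c.position)
            if dist <= tol:
                pairs.append((dist, ci, ti))
    pairs.sort()
    matched_calls: set[int] = set()
    matched: list[tuple[VariantCall, dict]] = []
    for dist, ci, ti in pairs:
        if ci in matched_calls or taken[ti]:
            continue
        matched_calls.add(ci)
        taken[ti] = True
        matched.append((calls[ci], rows[ti]))
    fp = [c for i, c in enumerate(calls) if i not in matched_calls]
    fn = [t for i, t in enumerate(rows) if not taken[i]]
    return MatchResult(matched, fp, fn)


def af_agreement(match: MatchResult, tolerance: float = 0.05) -> float:
    """Fraction of matched variants whose estimate is within ``tolerance``
    of the realized truth frequency."""
    if not match.matched:
        raise InsufficientDataError("no matched variants; agreement undefined")
    errors = af_errors(match)
    return float(np.mean(np.abs(errors) <= tolerance))


def af_errors(match: MatchResult) -> np.ndarray:
    out = []
    for call, t in match.matched:
        truth_f = t.get("realized_freq")
        if truth_f is None:
            truth_f = t["true_freq"]
        out.append(call.af_estimate - float(truth_f))
    return np.array(out)


# ---------------------------------------------------------------------------
# End-to-end machinery
# ---------------------------------------------------------------------------

def run_pipeline(
    pool: HaplotypePool,
    sim_config: SimulationConfig,
    caller_config: CallerConfig | None = None,
    filter_config: FilterConfig | None = None,
    founder_calls: Iterable[VariantCall] | None = None,
) -> list[VariantCall]:
    """simulate -> pileup -> call -> filter, in memory."""
    from .filters import subtract_founder
    from .sim import inject_artifacts

    reads = simulate_reads(pool, sim_config)
    if sim_config.artifacts:
        reads, _ = inject_artifacts(reads, sim_config.artifacts, seed=sim_config.seed + 1)
    pu = build_pileup(reads)
    calls = call_variants(pu, caller_config or CallerConfig())
    calls = apply_filters(calls, pu, filter_config or FilterConfig())
    calls = subtract_founder(calls, founder_calls, filter_config or FilterConfig())
    return calls


def _alt_for(ref_base: str) -> str:
    return BASES[(BASES.index(ref_base) + 1) % 4]


def plant_snp_grid(
    reference,
    frequencies: Sequence[float],
    sites_per_frequency: int,
    margin: int = 1000,
    min_spacing: int = 200,
) -> list[PlantedVariant]:
    """Evenly spaced SNPs cycling through the requested frequencies."""
    contig = reference.contig_names[0]
    length = reference.length(contig)
    n_sites = len(frequencies) * sites_per_frequency
    span = length - 2 * margin
    step = span // n_sites
    if step < min_spacing:
        raise InsufficientDataError(
            f"reference too short for {n_sites} sites at >= {min_spacing} bp spacing"
        )
    variants = []
    for i in range(n_sites):
        pos = margin + i * step
        f = frequencies[i % len(frequencies)]
        ref_base = reference.base(contig, pos)
        variants.append(snp(reference, contig, pos, _alt_for(ref_base), f))
    return variants


def power_curve(
    frequencies: Sequence[float],
    depth: float = 285.0,
    replicates: int = 20,
    seed: int = 0,
    *,
    ref_length: int = 100_000,
    sites_per_frequency: int = 20,
    n_haplotypes: int = 100,
    gc_fraction: float = 0.35,
    per_base_error: float = 0.001,
    read_length: int = 100,
    mean_fragment: float = 230.0,
    fragment_sd: float = 20.0,
    caller_config: CallerConfig | None = None,
    filter_config: FilterConfig | None = None,
    require_pass: bool = True,
) -> pd.DataFrame:
    """Detection power per planted frequency from full pipeline replicates.

    Replicate seeds are the master seed plus fixed offsets (logged in the
    returned frame's ``attrs``), so reruns are bit-reproducible.
    """
    frequencies = sorted(frequencies)
    caller_config = caller_config or CallerConfig()
    filter_config = filter_config or FilterConfig()
    detected = {f: 0 for f in frequencies}
    trials = {f: 0 for f in frequencies}
    seeds_used = []
    for rep in range(replicates):
        ref_seed = seed + rep
        pool_seed = seed + 10_000 + rep
        sim_seed = seed + 20_000 + rep
        seeds_used.append({"replicate": rep, "ref": ref_seed, "pool": pool_seed, "sim": sim_seed})
        reference = generate_reference(1, ref_length, gc_fraction, seed=ref_seed)
        variants = plant_snp_grid(reference, frequencies, sites_per_frequency)
        pool = build_pool(reference, n_haplotypes, variants, seed=pool_seed)
        sim = SimulationConfig(
            depth=depth,
            read_length=read_length,
            mean_fragment=mean_fragment,
            fragment_sd=fragment_sd,
            per_base_error=per_base_error,
            seed=sim_seed,
        )
        calls = run_pipeline(pool, sim, caller_config, filter_config)
        index = {}
        for c in calls:
            if c.kind == "snp" and (not require_pass or c.is_pass):
                index[(c.contig, c.position, c.alt_allele)] = c
        for v, rf in zip(pool.variants, pool.realized_frequencies):
            trials[v.true_frequency] += 1
            if rf > 0 and (v.contig, v.position, v.alt_allele) in index:
                detected[v.true_frequency] += 1
    df = pd.DataFrame(
        {
            "frequency": frequencies,
            "n_trials": [trials[f] for f in frequencies],
            "detected": [detected[f] for f in frequencies],
        }
    )
    df["power"] = df["detected"] / df["n_trials"]
    df.attrs["seeds"] = seeds_used
    df.attrs["depth"] = depth
    return df


def detection_floor(power_table: pd.DataFrame, threshold: float = 0.95) -> float | None:
    """Smallest frequency whose detection power reaches ``threshold``."""
    for _, row in power_table.sort_values("frequency").iterrows():
        if row["power"] >= threshold:
            return float(row["frequency"])
    return None


def false_positive_run(
    ref_length: int = 1_000_000,
    depth: float = 285.0,
    seed: int = 0,
    caller_config: CallerConfig | None = None,
    filter_config: FilterConfig | None = None,
) -> list[VariantCall]:
    """PASS calls on a variant-free simulation (should be empty)."""
    reference = generate_reference(1, ref_length, 0.35, seed=seed)
    pool = build_pool(reference, 10, [], seed=seed)
    sim = SimulationConfig(depth=depth, seed=seed + 1)
    calls = run_pipeline(pool, sim, caller_config, filter_config)
    return [c for c in calls if c.is_pass]


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    n_true: int
    n_called: int
    true_positives: int
    false_positives: int
    false_negatives: int
    fpr_per_mb: float
    fnr: float
    af_errors: list[float] = field(default_factory=list)
    af_agreement_fraction: float | None = None
    power_by_frequency: dict[float, float] | None = None
    seeds: list[dict] | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def summary(self) -> str:
        lines = [
            f"true variants      {self.n_true}",
            f"calls (matched)    {self.n_called}",
            f"true positives     {self.true_positives}",
            f"false positives    {self.false_positives} ({self.fpr_per_mb:.3g} per Mb)",
            f"false negatives    {self.false_negatives} (FNR {self.fnr:.3f})",
        ]
        if self.af_agreement_fraction is not None:
            lines.append(f"AF agreement       {self.af_agreement_fraction:.3f}")
        return "\n".join(lines)


def evaluate_run(
    calls: Sequence[VariantCall],
    truth,
    genome_size: int,
    af_tolerance: float = 0.05,
    snp_tolerance: int = 0,
    indel_tolerance: int = 5,
    require_pass: bool = True,
) -> EvalReport:
    """Score one pipeline run against its truth table."""
    scored = [c for c in calls if not require_pass or c.is_pass]
    match = match_calls(scored, truth, snp_tolerance, indel_tolerance)
    # truth rows whose realized frequency rounded to zero are undetectable
    def _realized(t):
        rf = t.get("realized_freq")
        return t.get("true_freq") if rf is None else rf

    realized_absent = sum(1 for t in match.unmatched_truth if _realized(t) == 0)
    n_true = len(match.matched) + len(match.unmatched_truth) - realized_absent
    tp = len(match.matched)
    fp = len(match.unmatched_calls)
    fn = n_true - tp
    agreement = None
    errors: list[float] = []
    if match.matched:
        errors = [float(x) for x in af_errors(match)]
        agreement = af_agreement(match, af_tolerance)
    return EvalReport(
        n_true=n_true,
        n_called=tp + fp,
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        fpr_per_mb=fp / (genome_size / 1e6),
        fnr=fn / n_true if n_true else 0.0,
        af_errors=errors,
        af_agreement_fraction=agreement,
    )
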