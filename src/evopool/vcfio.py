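"""Standard-format export/import: VCF 4.2, TSV mirrors, BEDPE."""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .caller import VariantCall
from .sim import ReferenceGenome
from .sv import SVCandidate

__all__ = [
    "write_vcf",
    "read_vcf",
    "calls_to_tsv",
    "read_founder_tsv",
    "write_bedpe",
    "write_sv_vcf",
]

_INFO_LINES = [
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele read fraction">',
    '##INFO=<ID=SCORE,Number=1,Type=Float,Description="Grid log-likelihood ratio vs no-variant">',
    '##INFO=<ID=GRIDF,Number=1,Type=Float,Description="Best pool-grid frequency">',
    '##INFO=<ID=ALTC,Number=1,Type=Integer,Description="Alternate-supporting observations">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Retained observations at the site">',
    '##INFO=<ID=KIND,Number=1,Type=String,Description="snp, insertion or deletion">',
    '##INFO=<ID=FOUNDER,Number=1,Type=String,Description="novel, in_founder or unknown">',
]
_FILTER_LINES = [
    '##FILTER=<ID=STRAND_CTX,Description="Strand-biased G/C mismatch context">',
    '##FILTER=<ID=READ_POS,Description="Alternate allele only near read ends">',
    '##FILTER=<ID=NEAR_SV,Description="Large indel/clip signature nearby">',
    '##FILTER=<ID=insufficient_context,Description="Too little covered context to test">',
]


def write_vcf(
    calls: Sequence[VariantCall],
    reference: ReferenceGenome,
    path: str | Path,
    extra_header_lines: Iterable[str] = (),
) -> None:
    lines = ["##fileformat=VCFv4.2", "##source=evopool"]
    lines += [f"##contig=<ID={n},length={reference.length(n)}>" for n in reference.contig_names]
    lines += _INFO_LINES + _FILTER_LINES
    lines += list(extra_header_lines)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    order = {n: i for i, n in enumerate(reference.contig_names)}
    for c in sorted(calls, key=lambda c: (order[c.contig], c.position, c.alt_allele)):
        filt = "PASS" if c.is_pass else ";".join(sorted(c.filter_flags))
        info = (
            f"AF={c.af_estimate:.6g};SCORE={c.score:.6g};GRIDF={c.grid_frequency:.6g};"
            f"ALTC={c.alt_count};DP={c.total_count};KIND={c.kind};FOUNDER={c.founder_status}"
        )
        qual = f"{c.score:.2f}" if c.score > 0 else "."
        lines.append(
            f"{c.contig}\t{c.position}\t.\t{c.ref_allele}\t{c.alt_allele}\t{qual}\t{filt}\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[VariantCall]:
    """Read calls back (our own VCFs, or any VCF carrying an AF INFO field)."""
    from cyvcf2 import VCF

    calls = []
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            kind = "snp"
            if len(rec.REF) > len(alt):
                kind = "deletion"
            elif len(rec.REF) < len(alt):
                kind = "insertion"
            af = rec.INFO.get("AF")
            if isinstance(af, tuple):
                af = af[0]
            flags = set()
            if rec.FILTER:  # cyvcf2 reports None for PASS
                flags = set(rec.FILTER.split(";"))
            calls.append(
                VariantCall(
                    contig=rec.CHROM,
                    position=rec.POS,
                    ref_allele=rec.REF,
                    alt_allele=alt,
                    kind=rec.INFO.get("KIND", kind),
                    af_estimate=float(af) if af is not None else 0.0,
                    alt_count=int(rec.INFO.get("ALTC", 0)),
                    total_count=int(rec.INFO.get("DP", 0)),
                    score=float(rec.INFO.get("SCORE", 0.0)),
                    grid_frequency=float(rec.INFO.get("GRIDF", 0.0)),
                    filter_flags=flags,
                    founder_status=rec.INFO.get("FOUNDER", "unknown"),
                )
            )
    return calls


def calls_to_tsv(calls: Sequence[VariantCall], path: str | Path, consequences=None) -> None:
    """Spreadsheet mirror of the VCF (one row per call)."""
    rows = []
    cons = {id(call): q for call, q in (consequences or [])}
    for c in calls:
        q = cons.get(id(c))
        rows.append(
            {
                "contig": c.contig,
                "pos": c.position,
                "ref": c.ref_allele,
                "alt": c.alt_allele,
                "kind": c.kind,
                "allele_frequency": round(c.af_estimate, 6),
                "alt_reads": c.alt_count,
                "depth": c.total_count,
                "score": round(c.score, 3),
                "filters": "PASS" if c.is_pass else ";".join(sorted(c.filter_flags)),
                "founder_status": c.founder_status,
                "region": q.region if q else "",
                "genes": ";".join(q.gene_ids) if q else "",
                "effect": q.effect if q else "",
                "aa_change": (q.notation or "") if q else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_founder_tsv(path: str | Path) -> list[VariantCall]:
    """Founder calls from a TSV with contig/pos/ref/alt and a frequency column."""
    df = pd.read_csv(path, sep="\t")
    freq_col = next(
        (c for c in ("allele_frequency", "af", "realized_freq", "true_freq") if c in df.columns),
        None,
    )
    calls = []
    for _, row in df.iterrows():
        ref, alt = str(row["ref"]), str(row["alt"])
        kind = "snp" if len(ref) == len(alt) == 1 else ("deletion" if len(ref) > len(alt) else "insertion")
        calls.append(
            VariantCall(
                contig=str(row["contig"]),
                position=int(row["pos"]),
                ref_allele=ref,
                alt_allele=alt,
                kind=str(row.get("kind", kind)),
                af_estimate=float(row[freq_col]) if freq_col else 1.0,
                alt_count=0,
                total_count=0,
                score=0.0,
                grid_frequency=0.0,
            )
        )
    return calls


def write_bedpe(candidates: Sequence[SVCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(candidates):
            fh.write(
                f"{c.contig}\t{c.left_breakpoint - 1}\t{c.left_breakpoint}\t"
                f"{c.contig}\t{c.right_breakpoint - 1}\t{c.right_breakpoint}\t"
                f"{c.kind}_{i}\t{c.pair_support}\t+\t-\t"
                f"kind={c.kind};size={c.implied_size};clips={c.clip_support};refined={int(c.refined)}\n"
            )


def write_sv_vcf(
    candidates: Sequence[SVCandidate], reference: ReferenceGenome, path: str | Path
) -> None:
    sym = {"deletion": "<DEL>", "insertion": "<INS>", "inversion_like": "<INV>", "unclassified": "<BND>"}
    lines = ["##fileformat=VCFv4.2", "##source=evopool-sv"]
    lines += [f"##contig=<ID={n},length={reference.length(n)}>" for n in reference.contig_names]
    lines += [
        '##INFO=<ID=END,Number=1,Type=Integer,Description="Right breakpoint">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Implied size">',
        '##INFO=<ID=PAIRS,Number=1,Type=Integer,Description="Discordant pair support">',
        '##INFO=<ID=CLIPS,Number=1,Type=Integer,Description="Soft-clip support">',
        '##INFO=<ID=REFINED,Number=0,Type=Flag,Description="Breakpoints clip-refined">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for i, c in enumerate(candidates):
        ref_base = reference.base(c.contig, max(1, c.left_breakpoint - 1))
        svlen = -c.implied_size if c.kind == "deletion" else c.implied_size
        info = f"END={c.right_breakpoint};SVLEN={svlen};PAIRS={c.pair_support};CLIPS={c.clip_support}"
        if c.refined:
            info += ";REFINED"
        lines.append(
            f"{c.contig}\t{max(1, c.left_breakpoint - 1)}\tsv{i}\t{ref_base}\t"
            f"{sym.get(c.kind, '<BND>')}\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
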