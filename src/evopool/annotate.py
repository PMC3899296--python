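"""Genomic context and coding-consequence annotation for variant calls.

Gene models come from GFF3 or GenBank flat files; coding changes are
translated with the bacterial/plastid code (translation table 11). Amino
acids are numbered from the annotated start codon (position 1).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from ._seq import revcomp
from .caller import VariantCall
from .errors import AnnotationError, InvalidArgument
from .sim import ReferenceGenome

__all__ = [
    "GeneModel",
    "Consequence",
    "load_gff3",
    "load_genbank",
    "classify_region",
    "codon_effect",
    "annotate_call",
    "annotate_calls",
]

TRANSLATION_TABLE = 11


@dataclass(frozen=True)
class GeneModel:
    """A (possibly multi-interval) CDS on one contig."""

    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    cds_intervals: tuple[tuple[int, int], ...]  # 1-based, closed, ascending
    product: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise InvalidArgument("strand must be '+' or '-'")
        ivals = sorted(self.cds_intervals)
        object.__setattr__(self, "cds_intervals", tuple(ivals))
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise InvalidArgument(f"CDS intervals overlap in gene {self.gene_id}")
        if any(s > e or s < 1 for s, e in ivals):
            raise InvalidArgument(f"malformed CDS interval in gene {self.gene_id}")
        if self.cds_length % 3 != 0:
            raise InvalidArgument(f"CDS length of {self.gene_id} is not a multiple of 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        return (self.cds_intervals[0][0], self.cds_intervals[-1][1])

    @property
    def start_position(self) -> int:
        """Genomic coordinate of the annotated start codon's first base."""
        return self.span[0] if self.strand == "+" else self.span[1]

    def contains(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.cds_intervals)

    def cds_sequence(self, reference: ReferenceGenome) -> str:
        seq = "".join(reference.slice(self.contig, s, e) for s, e in self.cds_intervals)
        return revcomp(seq) if self.strand == "-" else seq

    def cds_offset(self, position: int) -> int:
        """0-based offset of a genomic position within the coding sequence."""
        off = 0
        for s, e in self.cds_intervals:
            if s <= position <= e:
                off += position - s
                return off if self.strand == "+" else self.cds_length - 1 - off
            off += e - s + 1
        raise InvalidArgument(f"position {position} is not inside the CDS of {self.gene_id}")


@dataclass(frozen=True)
class Consequence:
    region: str  # coding | promoter_proximal | intergenic
    gene_ids: tuple[str, ...] = ()
    codon_ref: str | None = None
    codon_alt: str | None = None
    aa_ref: str | None = None
    aa_pos: int | None = None
    aa_alt: str | None = None
    effect: str = "intergenic"  # synonymous | nonsynonymous | nonsense | frameshift | in_frame_indel | intergenic

    @property
    def notation(self) -> str | None:
        """Protein-level shorthand such as G457E."""
        if self.aa_ref is None:
            return None
        return f"{self.aa_ref}{self.aa_pos}{self.aa_alt}"


# ---------------------------------------------------------------------------
# Gene-model readers
# ---------------------------------------------------------------------------

def _attr_first(attrs, *keys) -> str | None:
    for key in keys:
        if key in attrs:
            val = attrs[key]
            return val[0] if isinstance(val, (list, tuple)) else val
    return None


def load_gff3(path: str | Path) -> list[GeneModel]:
    """Read CDS features from GFF3, grouped by Parent/ID/locus_tag."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    grouped: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        key = _attr_first(cds.attributes, "locus_tag", "Parent", "ID", "gene") or f"cds_{cds.start}"
        g = grouped.setdefault(
            key,
            {
                "contig": cds.seqid,
                "strand": cds.strand if cds.strand in "+-" else "+",
                "intervals": [],
                "product": _attr_first(cds.attributes, "product") or "",
            },
        )
        g["intervals"].append((cds.start, cds.end))
    return [
        GeneModel(key, g["contig"], g["strand"], tuple(g["intervals"]), g["product"])
        for key, g in grouped.items()
    ]


def load_genbank(path: str | Path) -> list[GeneModel]:
    from Bio import SeqIO

    models = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            gene_id = (
                _attr_first(feat.qualifiers, "locus_tag", "gene", "protein_id")
                or f"cds_{int(feat.location.start) + 1}"
            )
            intervals = tuple(
                (int(part.start) + 1, int(part.end)) for part in feat.location.parts
            )
            strand = "-" if feat.location.strand == -1 else "+"
            product = _attr_first(feat.qualifiers, "product") or ""
            models.append(GeneModel(gene_id, rec.id, strand, intervals, product))
    return models


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_region(
    call: VariantCall,
    gene_models: Sequence[GeneModel],
    promoter_window: int = 150,
) -> Consequence:
    """Coding / promoter-proximal / intergenic assignment.

    Promoter-proximal means within ``promoter_window`` bp upstream of a gene
    start on that gene's strand. Intergenic calls report both flanking
    genes, nearest first; at equal distance the gene whose upstream side
    faces the call is listed first.
    """
    pos = call.position
    genes = [g for g in gene_models if g.contig == call.contig]
    for g in genes:
        if g.contains(pos):
            return Consequence(region="coding", gene_ids=(g.gene_id,), effect="unassigned")
    promoters = []
    for g in genes:
        if g.strand == "+" and g.span[0] - promoter_window <= pos < g.span[0]:
            promoters.append((g.span[0] - pos, g.gene_id))
        elif g.strand == "-" and g.span[1] < pos <= g.span[1] + promoter_window:
            promoters.append((pos - g.span[1], g.gene_id))
    if promoters:
        promoters.sort()
        return Consequence(
            region="promoter_proximal",
            gene_ids=tuple(gid for _, gid in promoters),
            effect="intergenic",
        )

    def distance(g: GeneModel) -> int:
        s, e = g.span
        if pos < s:
            return s - pos
        if pos > e:
            return pos - e
        return 0

    def upstream_of(g: GeneModel) -> bool:
        return (g.strand == "+" and pos < g.span[0]) or (g.strand == "-" and pos > g.span[1])

    flanks = sorted(genes, key=lambda g: (distance(g), not upstream_of(g), g.gene_id))[:2]
    return Consequence(region="intergenic", gene_ids=tuple(g.gene_id for g in flanks))


def codon_effect(
    call: VariantCall,
    gene_model: GeneModel,
    reference: ReferenceGenome,
) -> Consequence:
    """Coding consequence of a call inside a CDS (translation table 11)."""
    if not gene_model.contains(call.position):
        raise AnnotationError(
            f"call at {call.contig}:{call.position} lies outside {gene_model.gene_id}"
        )
    if call.kind != "snp":
        shift = abs(len(call.ref_allele) - len(call.alt_allele))
        effect = "frameshift" if shift % 3 else "in_frame_indel"
        return Consequence(region="coding", gene_ids=(gene_model.gene_id,), effect=effect)

    cds = gene_model.cds_sequence(reference)
    off = gene_model.cds_offset(call.position)
    ref_base = call.ref_allele
    alt_base = call.alt_allele
    if gene_model.strand == "-":
        ref_base = revcomp(ref_base)
        alt_base = revcomp(alt_base)
    if cds[off] != ref_base:
        raise AnnotationError(
            f"CDS of {gene_model.gene_id} disagrees with the reference at "
            f"{call.contig}:{call.position} ({cds[off]} vs {ref_base})"
        )
    codon_idx = off // 3
    codon_ref = cds[codon_idx * 3 : codon_idx * 3 + 3]
    within = off % 3
    codon_alt = codon_ref[:within] + alt_base + codon_ref[within + 1 :]
    aa_ref = str(Seq(codon_ref).translate(table=TRANSLATION_TABLE))
    aa_alt = str(Seq(codon_alt).translate(table=TRANSLATION_TABLE))
    if aa_alt == aa_ref:
        effect = "synonymous"
    elif aa_alt == "*":
        effect = "nonsense"
    else:
        effect = "nonsynonymous"
    return Consequence(
        region="coding",
        gene_ids=(gene_model.gene_id,),
        codon_ref=codon_ref,
        codon_alt=codon_alt,
        aa_ref=aa_ref,
        aa_pos=codon_idx + 1,
        aa_alt=aa_alt,
        effect=effect,
    )


def annotate_call(
    call: VariantCall,
    gene_models: Sequence[GeneModel],
    reference: ReferenceGenome,
    promoter_window: int = 150,
) -> Consequence:
    region = classify_region(call, gene_models, promoter_window)
    if region.region != "coding":
        return region
    gene = next(
        g for g in gene_models if g.contig == call.contig and g.gene_id == region.gene_ids[0]
    )
    return codon_effect(call, gene, reference)


def annotate_calls(
    calls: Iterable[VariantCall],
    gene_models: Sequence[GeneModel],
    reference: ReferenceGenome,
    promoter_window: int = 150,
) -> list[tuple[VariantCall, Consequence]]:
    return [
        (c, annotate_call(c, gene_models, reference, promoter_window)) for c in calls
    ]
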