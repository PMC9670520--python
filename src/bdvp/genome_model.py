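"""Gene models and region-stratified classification of variant positions.

Every variant position is assigned to exactly one of five region classes
(coding, UTR, non-coding RNA, intronic, intergenic), which collapse into the
three strata the downstream analysis is built on: ``coding``, ``noncoding``
(introns + UTRs + ncRNA exons) and ``intergenic``.

Internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
converted at the I/O boundary.  Strand is stored but plays no role in
classification, which is purely positional.
"""

from __future__ import annotations

import enum
from bisect import bisect_right
from dataclasses import dataclass, field

import gffutils

__all__ = [
    "GenomicInterval",
    "GeneRecord",
    "RegionClass",
    "VariantAnnotation",
    "GeneModelError",
    "load_gene_model",
    "classify_position",
    "GeneIndex",
]


class GeneModelError(ValueError):
    """Raised for malformed or internally inconsistent gene models."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.contig:
            raise GeneModelError("interval contig must be non-empty")
        if not self.start < self.end:
            raise GeneModelError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneRecord:
    """One gene (or non-coding RNA) with its exon/CDS/UTR structure.

    ``cds`` is empty iff ``biotype == "ncRNA"``.  Exons must be sorted and
    non-overlapping, and every CDS/UTR interval must be contained in an exon.
    """

    gene_id: str
    biotype: str  # "protein_coding" | "ncRNA"
    span: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    utrs: list[GenomicInterval] = field(default_factory=list)

    def validate(self) -> None:
        if self.biotype not in ("protein_coding", "ncRNA"):
            raise GeneModelError(
                f"gene {self.gene_id}: unknown biotype {self.biotype!r}"
            )
        if self.biotype == "ncRNA" and self.cds:
            raise GeneModelError(f"ncRNA gene {self.gene_id} must not have CDS")
        prev_end = None
        for ex in self.exons:
            if ex.contig != self.span.contig:
                raise GeneModelError(
                    f"gene {self.gene_id}: exon on {ex.contig} but gene on "
                    f"{self.span.contig}"
                )
            if prev_end is not None and ex.start < prev_end:
                raise GeneModelError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = ex.end
        for kind, ivs in (("CDS", self.cds), ("UTR", self.utrs)):
            for iv in ivs:
                if not any(
                    ex.start <= iv.start and iv.end <= ex.end for ex in self.exons
                ):
                    raise GeneModelError(
                        f"gene {self.gene_id}: {kind} interval "
                        f"[{iv.start}, {iv.end}) not contained in any exon"
                    )


class RegionClass(enum.Enum):
    """Region class of a variant position, with its analysis stratum."""

    CODING = "CODING"
    UTR = "UTR"
    NCRNA = "NCRNA"
    INTRONIC = "INTRONIC"
    INTERGENIC = "INTERGENIC"

    @property
    def stratum(self) -> str:
        if self is RegionClass.CODING:
            return "coding"
        if self is RegionClass.INTERGENIC:
            return "intergenic"
        return "noncoding"


STRATA = ("coding", "noncoding", "intergenic")


@dataclass(frozen=True)
class VariantAnnotation:
    """Region class and mapped gene(s) for one variant key."""

    key: object  # VariantKey; kept loose to avoid a circular import
    region: RegionClass
    genes: tuple[str, ...]


def _prescan_gff3(path: str) -> None:
    """Cheap structural scan so parse errors can name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GeneModelError(
                    f"{path}: malformed GFF3 line {lineno}: expected 9 "
                    f"tab-separated columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GeneModelError(
                    f"{path}: malformed GFF3 line {lineno}: non-integer "
                    f"coordinates"
                ) from exc
            if start > end:
                raise GeneModelError(
                    f"{path}: malformed GFF3 line {lineno}: start > end"
                )


_UTR_TYPES = ("five_prime_UTR", "three_prime_UTR")


def load_gene_model(path: str) -> list[GeneRecord]:
    """Load GeneRecords from a GFF3 file.

    Recognized feature types: ``gene``, ``exon``, ``CDS``,
    ``five_prime_UTR``, ``three_prime_UTR``.  Genes are matched to their
    sub-features via the ``gene_id`` attribute.  Records are returned sorted
    by (contig, start, gene_id).
    """
    _prescan_gff3(path)
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )

    def _gid(feat) -> str:
        if "gene_id" in feat.attributes:
            return feat.attributes["gene_id"][0]
        if "ID" in feat.attributes:
            return feat.attributes["ID"][0]
        raise GeneModelError(
            f"{path}: feature {feat.featuretype} at {feat.seqid}:{feat.start} "
            "lacks a gene_id/ID attribute"
        )

    genes: dict[str, GeneRecord] = {}
    for feat in db.features_of_type("gene"):
        gid = _gid(feat)
        biotype = feat.attributes.get("biotype", ["protein_coding"])[0]
        span = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        if gid in genes:
            raise GeneModelError(f"{path}: duplicate gene_id {gid!r}")
        genes[gid] = GeneRecord(gene_id=gid, biotype=biotype, span=span)

    for ftype, attr in (("exon", "exons"), ("CDS", "cds")):
        for feat in db.features_of_type(ftype):
            gid = _gid(feat)
            if gid not in genes:
                raise GeneModelError(
                    f"{path}: {ftype} references unknown gene {gid!r}"
                )
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            getattr(genes[gid], attr).append(iv)
    for ftype in _UTR_TYPES:
        for feat in db.features_of_type(ftype):
            gid = _gid(feat)
            if gid not in genes:
                raise GeneModelError(
                    f"{path}: {ftype} references unknown gene {gid!r}"
                )
            genes[gid].utrs.append(
                GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            )

    records = []
    for rec in genes.values():
        rec.exons.sort(key=lambda iv: iv.start)
        rec.cds.sort(key=lambda iv: iv.start)
        rec.utrs.sort(key=lambda iv: iv.start)
        rec.validate()
        records.append(rec)
    records.sort(key=lambda g: (g.span.contig, g.span.start, g.gene_id))
    return records


class GeneIndex:
    """Per-contig sorted index over GeneRecords for repeated classification."""

    def __init__(self, genes: list[GeneRecord]):
        if not genes:
            raise GeneModelError(
                "gene model must contain at least one gene (nearest-gene "
                "assignment for intergenic positions is otherwise undefined)"
            )
        self.by_contig: dict[str, list[GeneRecord]] = {}
        for g in sorted(genes, key=lambda g: (g.span.contig, g.span.start, g.gene_id)):
            self.by_contig.setdefault(g.span.contig, []).append(g)
        self._starts = {
            c: [g.span.start for g in gs] for c, gs in self.by_contig.items()
        }

    def contigs(self) -> set[str]:
        return set(self.by_contig)

    def classify(self, contig: str, pos1: int) -> tuple[RegionClass, tuple[str, ...]]:
        """Classify a 1-based position; see :func:`classify_position`."""
        if pos1 < 1:
            raise GeneModelError(f"position must be >= 1, got {pos1}")
        if contig not in self.by_contig:
            raise GeneModelError(f"contig {contig!r} absent from gene model")
        pos0 = pos1 - 1
        gs = self.by_contig[contig]

        # only genes whose span can contain pos0 plus flanks matter, but gene
        # counts here are small enough that a bounded scan is simplest
        lo = bisect_right(self._starts[contig], pos0)
        overlapping = [g for g in gs[:lo] if g.span.contains(pos0)]

        hits_coding, hits_utr, hits_ncrna, hits_intron = [], [], [], []
        for g in overlapping:
            if any(iv.contains(pos0) for iv in g.cds):
                hits_coding.append(g.gene_id)
            elif any(iv.contains(pos0) for iv in g.utrs):
                hits_utr.append(g.gene_id)
            elif g.biotype == "ncRNA" and any(iv.contains(pos0) for iv in g.exons):
                hits_ncrna.append(g.gene_id)
            else:
                hits_intron.append(g.gene_id)
        for region, hits in (
            (RegionClass.CODING, hits_coding),
            (RegionClass.UTR, hits_utr),
            (RegionClass.NCRNA, hits_ncrna),
            (RegionClass.INTRONIC, hits_intron),
        ):
            if hits:
                return region, tuple(sorted(hits))

        # intergenic: nearest gene(s) by distance to span boundary; exact
        # ties return every gene at the minimum distance
        best_d, best = None, []
        for g in gs:
            if pos0 < g.span.start:
                d = g.span.start - pos0
            elif pos0 >= g.span.end:
                d = pos0 - (g.span.end - 1)
            else:  # pragma: no cover - would have been classified above
                d = 0
            if best_d is None or d < best_d:
                best_d, best = d, [g.gene_id]
            elif d == best_d:
                best.append(g.gene_id)
        return RegionClass.INTERGENIC, tuple(sorted(best))


def classify_position(
    contig: str, pos1: int, genes: list[GeneRecord]
) -> tuple[RegionClass, tuple[str, ...]]:
    """Classify a 1-based position against a list of GeneRecords.

    Precedence when multiple features overlap: CODING > UTR > NCRNA >
    INTRONIC > INTERGENIC.  Within the winning class all qualifying genes are
    returned sorted by gene_id.  A position inside a gene span but outside
    every exon is INTRONIC; a position in no gene span is INTERGENIC and is
    assigned the nearest gene(s), both on an exact distance tie.
    """
    return GeneIndex(genes).classify(contig, pos1)
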