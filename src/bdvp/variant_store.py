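"""Multi-sample VCF + sample sheet ingestion into a carrier matrix.

Variant identity is positional: two calls are the same variant iff they share
contig, (normalized) position, reference and alternative allele.  Keys are
parsimony-trimmed (shared trailing bases removed first, then shared leading
bases with the position advanced) and multi-allelic records are split into
one key per alternative allele.

Carrier semantics are dominant: a sample carries a variant iff its genotype
contains at least one copy of the alternative allele; missing genotypes
(./.) count as non-carrier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "VariantKey",
    "SampleRecord",
    "SampleSheet",
    "CarrierMatrix",
    "VariantError",
    "CohortError",
    "GROUPS",
    "ROLES",
    "normalize_variant",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_cohort",
    "write_vcf",
]

GROUPS = ("BD_CANCER", "BD_ONLY", "CONTROL")
ROLES = ("proband", "parent", "sibling")

_ALLELE_CHARS = frozenset("ACGTN")


class VariantError(ValueError):
    """Degenerate or malformed variant record."""


class CohortError(ValueError):
    """Inconsistent cohort configuration (VCF vs sample sheet, bad sheet)."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Canonical identity of a biallelic variant after normalization."""

    contig: str
    pos1: int
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.contig}:{self.pos1}:{self.ref}>{self.alt}"


def normalize_variant(contig: str, pos1: int, ref: str, alt: str) -> VariantKey:
    """Parsimony-trim an allele pair into a canonical VariantKey.

    Shared trailing bases are removed first, then shared leading bases with
    ``pos1`` advanced accordingly; at least one base is always retained in
    each allele.  Raises :class:`VariantError` if ref == alt.
    """
    ref, alt = ref.upper(), alt.upper()
    if not ref or not alt:
        raise VariantError(f"{contig}:{pos1}: empty allele")
    for allele in (ref, alt):
        if not set(allele) <= _ALLELE_CHARS:
            raise VariantError(f"{contig}:{pos1}: non-ACGTN allele {allele!r}")
    if ref == alt:
        raise VariantError(f"{contig}:{pos1}: ref equals alt ({ref})")
    # trim shared suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared prefix, advancing the position
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos1 += 1
    if ref == alt:  # pragma: no cover - unreachable given the guards above
        raise VariantError(f"{contig}:{pos1}: degenerate after trimming")
    return VariantKey(contig, pos1, ref, alt)


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    family_id: str
    group: str
    role: str


class SampleSheet:
    """Per-sample group/family metadata for a cohort."""

    def __init__(self, samples: Iterable[SampleRecord]):
        self.samples = list(samples)
        seen = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise CohortError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)
            if s.group not in GROUPS:
                raise CohortError(
                    f"sample {s.sample_id}: group must be one of {GROUPS}, "
                    f"got {s.group!r}"
                )
            if s.role not in ROLES:
                raise CohortError(
                    f"sample {s.sample_id}: role must be one of {ROLES}, "
                    f"got {s.role!r}"
                )
            if not s.family_id:
                raise CohortError(f"sample {s.sample_id}: empty family_id")
            if s.group == "CONTROL" and s.role == "proband":
                raise CohortError(
                    f"sample {s.sample_id}: CONTROL samples must be "
                    "parents or siblings"
                )
        self._index = {s.sample_id: i for i, s in enumerate(self.samples)}

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def indices(self, group: str, role: str | None = None) -> np.ndarray:
        return np.array(
            [
                i
                for i, s in enumerate(self.samples)
                if s.group == group and (role is None or s.role == role)
            ],
            dtype=int,
        )

    def record(self, sample_id: str) -> SampleRecord:
        return self.samples[self._index[sample_id]]


def read_sample_sheet(path: str) -> SampleSheet:
    """Read a TSV sample sheet with header `sample_id family_id group role`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sample_id", "family_id", "group", "role"]
        if header != expected:
            raise CohortError(
                f"{path}: expected header {expected}, got {header}"
            )
        records = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise CohortError(f"{path}: bad sample-sheet row: {line!r}")
            records.append(SampleRecord(*fields))
    return SampleSheet(records)


def write_sample_sheet(sheet: SampleSheet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tfamily_id\tgroup\trole\n")
        for s in sheet:
            fh.write(f"{s.sample_id}\t{s.family_id}\t{s.group}\t{s.role}\n")


@dataclass
class CarrierMatrix:
    """samples x variants carrier indicator (1 = carries >= 1 alt allele)."""

    variants: list[VariantKey]
    samples: list[str]
    carrier: np.ndarray  # shape (n_samples, n_variants), uint8 in {0,1}

    def __post_init__(self) -> None:
        self.carrier = np.asarray(self.carrier, dtype=np.uint8)
        if self.carrier.shape != (len(self.samples), len(self.variants)):
            raise CohortError(
                f"carrier matrix shape {self.carrier.shape} inconsistent "
                f"with {len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.variants)) != len(self.variants):
            raise CohortError("duplicate VariantKey in carrier matrix")
        if self.carrier.size and self.carrier.max() > 1:
            raise CohortError("carrier values must be in {0, 1}")
        self._vindex = {v: j for j, v in enumerate(self.variants)}

    def column(self, key: VariantKey) -> np.ndarray:
        return self.carrier[:, self._vindex[key]]

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._vindex


def read_cohort(
    vcf_path: str, sheet_path: str, pass_only: bool = False
) -> tuple[CarrierMatrix, SampleSheet]:
    """Read a multi-sample VCF and sample sheet into a CarrierMatrix.

    Multi-allelic records are split into one normalized key per alt allele.
    Identical keys arising from different records are merged by logical OR
    (with a warning).  Sample columns must match the sheet exactly (order may
    differ; the matrix rows follow the sheet order).
    """
    sheet = read_sample_sheet(sheet_path)
    vcf = VCF(vcf_path)
    vcf_samples = list(vcf.samples)
    sheet_ids = set(sheet.sample_ids)
    vcf_ids = set(vcf_samples)
    if sheet_ids != vcf_ids:
        missing_in_vcf = sorted(sheet_ids - vcf_ids)
        missing_in_sheet = sorted(vcf_ids - sheet_ids)
        raise CohortError(
            "sample mismatch between VCF and sheet; "
            f"in sheet but not VCF: {missing_in_vcf}; "
            f"in VCF but not sheet: {missing_in_sheet}"
        )
    # matrix rows follow sheet order
    row_of_vcf_col = np.array(
        [sheet.sample_ids.index(s) for s in vcf_samples], dtype=int
    )

    keys: list[VariantKey] = []
    cols: list[np.ndarray] = []
    index: dict[VariantKey, int] = {}
    n = len(vcf_samples)
    for rec in vcf:
        if pass_only and rec.FILTER is not None:
            continue
        gts = rec.genotype.array() if rec.genotypes is not None else None
        if gts is None or gts.shape[1] < 2:
            raise CohortError(
                f"{vcf_path}: record {rec.CHROM}:{rec.POS} lacks GT"
            )
        alleles = gts[:, :-1]  # last column is phasing flag
        for ai, alt in enumerate(rec.ALT, start=1):
            key = normalize_variant(rec.CHROM, rec.POS, rec.REF, alt)
            carr_vcf_order = (alleles == ai).any(axis=1).astype(np.uint8)
            col = np.zeros(n, dtype=np.uint8)
            col[row_of_vcf_col] = carr_vcf_order
            if key in index:
                logger.warning(
                    "duplicate variant key %s from separate records; "
                    "merging carriers by logical OR",
                    key,
                )
                cols[index[key]] |= col
            else:
                index[key] = len(keys)
                keys.append(key)
                cols.append(col)
    carrier = (
        np.stack(cols, axis=1) if cols else np.zeros((n, 0), dtype=np.uint8)
    )
    return CarrierMatrix(keys, sheet.sample_ids, carrier), sheet


def write_vcf(matrix: CarrierMatrix, path: str) -> None:
    """Write a CarrierMatrix as a minimal all-biallelic VCF v4.2 (GT 0/0 vs 0/1)."""
    idx = sorted(
        range(len(matrix.variants)),
        key=lambda j: (
            matrix.variants[j].contig,
            matrix.variants[j].pos1,
            matrix.variants[j].ref,
            matrix.variants[j].alt,
        ),
    )
    contigs = sorted({v.contig for v in matrix.variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j in idx:
            v = matrix.variants[j]
            gts = "\t".join(
                "0/1" if matrix.carrier[i, j] else "0/0"
                for i in range(len(matrix.samples))
            )
            fh.write(
                f"{v.contig}\t{v.pos1}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n"
            )
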