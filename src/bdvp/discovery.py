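"""Selection of case-exclusive recurrent variants ("variants of interest").

A variant is selected iff it is carried by at least ``min_cases`` affected
probands (counted at most once per family when ``require_unrelated``) and by
zero samples in both the disease-only group and the healthy family-control
group.  The filter is set-theoretic: no per-variant statistics are computed
at this stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome_model import GeneIndex, GeneModelError, GeneRecord, RegionClass, STRATA
from .variant_store import CarrierMatrix, CohortError, SampleSheet, VariantKey

__all__ = ["SelectionConfig", "SelectedVariant", "SelectionResult", "select_variants", "annotate_selection", "write_selection_tsv", "read_selection_tsv"]


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of the exclusive-recurrence filter."""

    min_cases: int = 3
    require_unrelated: bool = True

    def __post_init__(self) -> None:
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")


@dataclass(frozen=True)
class SelectedVariant:
    key: VariantKey
    case_carrier_count: int
    region: RegionClass | None = None
    genes: tuple[str, ...] = ()

    @property
    def stratum(self) -> str:
        if self.region is None:
            raise ValueError("variant not yet annotated")
        return self.region.stratum


@dataclass
class SelectionResult:
    """Variants passing the filter, optionally annotated with region/genes."""

    selected: list[SelectedVariant]
    config: SelectionConfig = field(default_factory=SelectionConfig)

    def __len__(self) -> int:
        return len(self.selected)

    @property
    def annotated(self) -> bool:
        return all(v.region is not None for v in self.selected)

    def by_stratum(self) -> dict[str, list[SelectedVariant]]:
        """Disjoint partition of the selection by region stratum."""
        out: dict[str, list[SelectedVariant]] = {s: [] for s in STRATA}
        for v in self.selected:
            out[v.stratum].append(v)
        return out

    @property
    def keys(self) -> list[VariantKey]:
        return [v.key for v in self.selected]


def select_variants(
    matrix: CarrierMatrix, sheet: SampleSheet, cfg: SelectionConfig | None = None
) -> SelectionResult:
    """Apply the exclusive-recurrence filter to a carrier matrix.

    Only probands of the case group are eligible as cases; relatives in the
    control group can never be cases regardless of genotype.  Output is
    sorted by (contig, pos, ref, alt).
    """
    cfg = cfg or SelectionConfig()
    if matrix.samples != sheet.sample_ids:
        raise CohortError("carrier matrix sample order differs from sheet")
    case_idx = sheet.indices("BD_CANCER", role="proband")
    if case_idx.size == 0:
        raise CohortError(
            "cohort has no BD_CANCER probands; the recurrence filter is undefined"
        )
    bd_idx = sheet.indices("BD_ONLY")
    ctrl_idx = sheet.indices("CONTROL")

    case_car = matrix.carrier[case_idx, :]
    if cfg.require_unrelated:
        fams = [sheet.samples[i].family_id for i in case_idx]
        uniq, fam_code = np.unique(fams, return_inverse=True)
        collapsed = np.zeros((len(uniq), case_car.shape[1]), dtype=np.uint8)
        np.maximum.at(collapsed, fam_code, case_car)
        case_counts = collapsed.sum(axis=0)
    else:
        case_counts = case_car.sum(axis=0)

    excl = np.ones(case_car.shape[1], dtype=bool)
    if bd_idx.size:
        excl &= matrix.carrier[bd_idx, :].sum(axis=0) == 0
    if ctrl_idx.size:
        excl &= matrix.carrier[ctrl_idx, :].sum(axis=0) == 0

    mask = (case_counts >= cfg.min_cases) & excl
    picked = [
        SelectedVariant(key=matrix.variants[j], case_carrier_count=int(case_counts[j]))
        for j in np.flatnonzero(mask)
    ]
    picked.sort(key=lambda v: (v.key.contig, v.key.pos1, v.key.ref, v.key.alt))
    return SelectionResult(selected=picked, config=cfg)


def annotate_selection(
    sel: SelectionResult, genes: list[GeneRecord] | GeneIndex
) -> SelectionResult:
    """Attach region class and mapped gene(s) to every selected variant.

    Raises :class:`GeneModelError` naming the contig if a selected variant
    lies on a contig absent from the gene model.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    missing = {v.key.contig for v in sel.selected} - index.contigs()
    if missing:
        raise GeneModelError(
            f"contig(s) absent from gene model: {sorted(missing)}"
        )
    annotated = []
    for v in sel.selected:
        region, gids = index.classify(v.key.contig, v.key.pos1)
        annotated.append(replace(v, region=region, genes=gids))
    return SelectionResult(selected=annotated, config=sel.config)


_TSV_HEADER = "contig\tpos\tref\talt\tcase_carriers\tregion_class\tstratum\tgene_ids"


def write_selection_tsv(sel: SelectionResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for v in sel.selected:
            region = v.region.value if v.region else "."
            stratum = v.stratum if v.region else "."
            fh.write(
                f"{v.key.contig}\t{v.key.pos1}\t{v.key.ref}\t{v.key.alt}\t"
                f"{v.case_carrier_count}\t{region}\t{stratum}\t"
                f"{','.join(v.genes) or '.'}\n"
            )


def read_selection_tsv(path: str) -> SelectionResult:
    selected = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TSV_HEADER:
            raise ValueError(f"{path}: unexpected selection TSV header")
        for line in fh:
            if not line.strip():
                continue
            contig, pos, ref, alt, nc, region, _stratum, gids = line.rstrip(
                "\n"
            ).split("\t")
            selected.append(
                SelectedVariant(
                    key=VariantKey(contig, int(pos), ref, alt),
                    case_carrier_count=int(nc),
                    region=None if region == "." else RegionClass(region),
                    genes=() if gids == "." else tuple(gids.split(",")),
                )
            )
    return SelectionResult(selected=selected)
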