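"""Synthetic discovery/validation cohorts with planted case-exclusive signal.

The simulator emulates the statistical structure the analysis assumes:

* a three-group cohort — affected probands with cancer, affected probands
  without cancer, and healthy family controls (parents/siblings) — with one
  family per proband and controls attached to proband families;
* shared background variation: each background variant has a carrier
  frequency drawn log-uniform (both rare and common background exists), and
  a family control copies its proband's carrier status with probability 0.5
  (a transmission approximation) or is an independent carrier otherwise;
* planted signal: per region stratum, variants carried by >= 3 unrelated
  cancer probands and by nobody else, concentrated in designated signal
  genes so that gene-level loads are informative;
* an independent validation cohort in which cancer probands carry a
  configurable fraction of the signal variants and non-cancer probands
  carry background only.

All outputs (GFF3, VCF, sample sheet, truth JSON) are byte-identical for a
fixed seed.  Default sizes are scaled down from the reference cohort shape
(541/767/345 discovery, 25/15 validation); ``full_scale_config`` restores
the full shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .genome_model import GeneIndex, GeneRecord, GenomicInterval, STRATA
from .variant_store import (
    CarrierMatrix,
    SampleRecord,
    SampleSheet,
    VariantKey,
    write_sample_sheet,
    write_vcf,
)

__all__ = [
    "SimConfig",
    "TruthTable",
    "SimulatedCohort",
    "full_scale_config",
    "simulate_gene_model",
    "write_gff3",
    "make_sample_sheet",
    "simulate_cohort",
    "simulate_validation",
    "expected_spurious_selections",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort generator (defaults: reference cohort shape,
    scaled down)."""

    # discovery cohort shape
    n_case: int = 60
    n_bd_only: int = 80
    n_control: int = 40
    # genome / gene model
    contig: str = "chr1"
    contig_length: int = 1_000_000
    n_genes: int = 120
    ncrna_fraction: float = 0.2
    exon_count_range: tuple[int, int] = (2, 4)
    exon_length_range: tuple[int, int] = (150, 400)
    intron_length_range: tuple[int, int] = (200, 1000)
    intergap_range: tuple[int, int] = (300, 1500)
    # background variation
    n_background: int = 2000
    background_freq_range: tuple[float, float] = (0.005, 0.2)  # log-uniform
    transmission_rate: float = 0.5
    # planted signal, per stratum
    n_signal_per_stratum: dict = field(
        default_factory=lambda: {"coding": 10, "noncoding": 10, "intergenic": 10}
    )
    n_signal_genes_per_stratum: int = 5
    signal_carrier_range: tuple[int, int] = (3, 6)
    adversarial_bd_only_carrier: bool = False
    # validation cohort
    n_val_case: int = 25
    n_val_bd_only: int = 15
    replant_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_bd_only", "n_control", "n_val_case", "n_val_bd_only", "n_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.signal_carrier_range[0] < 1:
            raise ValueError("signal carrier counts must be >= 1")
        if self.signal_carrier_range[1] > self.n_case:
            raise ValueError("signal carrier count exceeds number of cases")
        if not 0 <= self.replant_rate <= 1:
            raise ValueError("replant_rate must be in [0, 1]")
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")


def full_scale_config(seed: int = 0) -> SimConfig:
    """The full reference cohort shape: 541/767/345 discovery, 25/15 validation."""
    return SimConfig(n_case=541, n_bd_only=767, n_control=345, seed=seed)


@dataclass
class TruthTable:
    """Ground truth of one simulated discovery cohort."""

    signal: list[dict]  # key fields, stratum, gene, carrier sample_ids
    background: list[dict]  # key fields, carrier frequency

    def signal_keys(self) -> set[VariantKey]:
        return {VariantKey(**d["key"]) for d in self.signal}

    def background_keys(self) -> set[VariantKey]:
        return {VariantKey(**d["key"]) for d in self.background}

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"signal": self.signal, "background": self.background},
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "TruthTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(signal=d["signal"], background=d["background"])


@dataclass
class SimulatedCohort:
    matrix: CarrierMatrix
    sheet: SampleSheet
    genes: list[GeneRecord]
    truth: TruthTable
    config: SimConfig


# ---------------------------------------------------------------------------
# gene model


def simulate_gene_model(cfg: SimConfig, seed: int | None = None) -> list[GeneRecord]:
    """Generate non-overlapping genes with exon/CDS/UTR structure."""
    rng = np.random.default_rng(np.random.SeedSequence([seed if seed is not None else cfg.seed, 0]))
    genes: list[GeneRecord] = []
    pos = int(rng.integers(*cfg.intergap_range))
    for i in range(cfg.n_genes):
        is_ncrna = rng.random() < cfg.ncrna_fraction
        n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        exon_lens = rng.integers(
            cfg.exon_length_range[0], cfg.exon_length_range[1] + 1, size=n_exons
        )
        intron_lens = rng.integers(
            cfg.intron_length_range[0], cfg.intron_length_range[1] + 1, size=n_exons - 1
        )
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"G{i + 1:04d}"

        exons, cds, utrs = [], [], []
        cursor = pos
        for j in range(n_exons):
            ex = GenomicInterval(cfg.contig, cursor, cursor + int(exon_lens[j]), strand)
            exons.append(ex)
            cursor = ex.end + (int(intron_lens[j]) if j < n_exons - 1 else 0)
        span = GenomicInterval(cfg.contig, exons[0].start, exons[-1].end, strand)
        if span.end + cfg.intergap_range[0] > cfg.contig_length:
            raise ValueError(
                f"contig length {cfg.contig_length} too short for "
                f"{cfg.n_genes} genes (ran out at gene {i + 1})"
            )
        if not is_ncrna:
            # split the first/last exon into UTR and CDS parts
            first, last = exons[0], exons[-1]
            if n_exons == 1:
                # both UTRs carved from one exon; leave >= 30 bp of CDS
                cap = min(100, (len(first) - 30) // 2)
                if cap < 30:
                    raise ValueError(
                        "exon_length_range too short for single-exon UTR/CDS "
                        "structure (need >= 90 bp exons)"
                    )
                u5 = int(rng.integers(30, cap + 1))
                u3 = int(rng.integers(30, cap + 1))
            else:
                if min(len(first), len(last)) < 60:
                    raise ValueError(
                        "exon_length_range too short for UTR/CDS structure "
                        "(need >= 60 bp terminal exons)"
                    )
                u5 = int(rng.integers(30, min(100, len(first) - 30) + 1))
                u3 = int(rng.integers(30, min(100, len(last) - 30) + 1))
            if n_exons == 1:
                utrs = [
                    GenomicInterval(cfg.contig, first.start, first.start + u5, strand),
                    GenomicInterval(cfg.contig, last.end - u3, last.end, strand),
                ]
                cds = [GenomicInterval(cfg.contig, first.start + u5, last.end - u3, strand)]
            else:
                utrs = [
                    GenomicInterval(cfg.contig, first.start, first.start + u5, strand),
                    GenomicInterval(cfg.contig, last.end - u3, last.end, strand),
                ]
                cds = (
                    [GenomicInterval(cfg.contig, first.start + u5, first.end, strand)]
                    + [GenomicInterval(cfg.contig, e.start, e.end, strand) for e in exons[1:-1]]
                    + [GenomicInterval(cfg.contig, last.start, last.end - u3, strand)]
                )
        rec = GeneRecord(
            gene_id=gid,
            biotype="ncRNA" if is_ncrna else "protein_coding",
            span=span,
            exons=exons,
            cds=cds,
            utrs=utrs,
        )
        rec.validate()
        genes.append(rec)
        pos = span.end + int(rng.integers(*cfg.intergap_range))
    return genes


def write_gff3(genes: list[GeneRecord], path: str) -> None:
    """Write GeneRecords as GFF3 (1-based inclusive coordinates)."""

    def line(ftype, iv, attrs):
        return (
            f"{iv.contig}\tbdvp-sim\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{iv.strand}\t.\t{attrs}\n"
        )

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                line(
                    "gene",
                    g.span,
                    f"ID={g.gene_id};gene_id={g.gene_id};biotype={g.biotype}",
                )
            )
            for j, ex in enumerate(g.exons, 1):
                fh.write(
                    line("exon", ex, f"ID={g.gene_id}.e{j};Parent={g.gene_id};gene_id={g.gene_id}")
                )
            for j, iv in enumerate(g.cds, 1):
                fh.write(
                    line("CDS", iv, f"ID={g.gene_id}.c{j};Parent={g.gene_id};gene_id={g.gene_id}")
                )
            for j, iv in enumerate(g.utrs, 1):
                ftype = "five_prime_UTR" if j == 1 else "three_prime_UTR"
                fh.write(
                    line(ftype, iv, f"ID={g.gene_id}.u{j};Parent={g.gene_id};gene_id={g.gene_id}")
                )


# ---------------------------------------------------------------------------
# cohort simulation


def make_sample_sheet(cfg: SimConfig) -> SampleSheet:
    """Deterministic sample sheet for a config: one family per proband,
    controls attached round-robin to proband families, alternating
    parent/sibling roles."""
    records = []
    proband_fams = []
    for i in range(cfg.n_case):
        fam = f"FCA{i + 1:04d}"
        records.append(SampleRecord(f"CA{i + 1:04d}", fam, "BD_CANCER", "proband"))
        proband_fams.append(fam)
    for i in range(cfg.n_bd_only):
        fam = f"FBD{i + 1:04d}"
        records.append(SampleRecord(f"BD{i + 1:04d}", fam, "BD_ONLY", "proband"))
        proband_fams.append(fam)
    for i in range(cfg.n_control):
        fam = proband_fams[i % len(proband_fams)]
        role = "parent" if i % 2 == 0 else "sibling"
        records.append(SampleRecord(f"CT{i + 1:04d}", fam, "CONTROL", role))
    return SampleSheet(records)


def _signal_position_pools(
    genes: list[GeneRecord], index: GeneIndex
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """Candidate (start0, end0) interval pools per stratum per gene."""
    pools: dict[str, dict[str, list[tuple[int, int]]]] = {s: {} for s in STRATA}
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_contig.setdefault(g.span.contig, []).append(g)
    for contig_genes in by_contig.values():
        contig_genes.sort(key=lambda g: g.span.start)
        for i, g in enumerate(contig_genes):
            if g.biotype == "protein_coding" and g.cds:
                pools["coding"][g.gene_id] = [(iv.start, iv.end) for iv in g.cds]
            # noncoding: introns, UTRs, ncRNA exons
            nc: list[tuple[int, int]] = []
            if g.biotype == "ncRNA":
                nc.extend((iv.start, iv.end) for iv in g.exons)
            else:
                nc.extend((iv.start, iv.end) for iv in g.utrs)
            for a, b in zip(g.exons[:-1], g.exons[1:]):
                if a.end < b.start:
                    nc.append((a.end, b.start))
            if nc:
                pools["noncoding"][g.gene_id] = nc
            # intergenic positions strictly nearer g than the next gene
            nxt = contig_genes[i + 1] if i + 1 < len(contig_genes) else None
            gap_end = nxt.span.start if nxt else g.span.end + 500
            half = (g.span.end + gap_end - 1) // 2  # strict-nearest bound
            if half > g.span.end:
                pools["intergenic"][g.gene_id] = [(g.span.end, half)]
    return pools


def _draw_position(
    pool: list[tuple[int, int]], used: set[int], rng: np.random.Generator
) -> int:
    for _ in range(200):
        a, b = pool[int(rng.integers(len(pool)))]
        p = int(rng.integers(a, b))
        if p not in used:
            used.add(p)
            return p
    raise RuntimeError("could not place a signal variant (pool exhausted)")


def _snv(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(_BASES[ref]), str(_BASES[alt])


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate the discovery cohort: carrier matrix, sheet, genes, truth."""
    genes = simulate_gene_model(cfg)
    index = GeneIndex(genes)
    ss = np.random.SeedSequence([cfg.seed, 1])
    rng = np.random.default_rng(ss)
    sheet = make_sample_sheet(cfg)

    n_prob = cfg.n_case + cfg.n_bd_only
    case_rows = np.arange(cfg.n_case)
    ctrl_rows = np.arange(n_prob, n_prob + cfg.n_control)
    # row index of the proband each control is attached to
    ctrl_proband = np.array(
        [i % n_prob for i in range(cfg.n_control)], dtype=int
    )

    used_pos: set[int] = set()

    # --- planted signal -----------------------------------------------------
    signal_records: list[dict] = []
    pools = _signal_position_pools(genes, index)
    sig_cols: list[np.ndarray] = []
    sig_keys: list[VariantKey] = []
    n_total = len(sheet)
    for stratum in STRATA:
        n_sig = cfg.n_signal_per_stratum.get(stratum, 0)
        if n_sig == 0:
            continue
        candidates = sorted(pools[stratum])
        if len(candidates) < cfg.n_signal_genes_per_stratum:
            raise ValueError(
                f"gene model offers only {len(candidates)} genes with "
                f"{stratum} positions; requested {cfg.n_signal_genes_per_stratum}"
            )
        pick = rng.choice(
            len(candidates), size=cfg.n_signal_genes_per_stratum, replace=False
        )
        sig_genes = [candidates[int(j)] for j in pick]
        for v in range(n_sig):
            gid = sig_genes[v % len(sig_genes)]
            pos0 = _draw_position(pools[stratum][gid], used_pos, rng)
            region, hit_genes = index.classify(cfg.contig, pos0 + 1)
            assert region.stratum == stratum and gid in hit_genes, (
                f"planting bug: wanted {stratum}/{gid}, got {region}/{hit_genes}"
            )
            ref, alt = _snv(rng)
            key = VariantKey(cfg.contig, pos0 + 1, ref, alt)
            n_carriers = int(rng.integers(cfg.signal_carrier_range[0], cfg.signal_carrier_range[1] + 1))
            carriers = rng.choice(case_rows, size=n_carriers, replace=False)
            col = np.zeros(n_total, dtype=np.uint8)
            col[carriers] = 1
            if cfg.adversarial_bd_only_carrier:
                col[cfg.n_case + int(rng.integers(cfg.n_bd_only))] = 1
            sig_cols.append(col)
            sig_keys.append(key)
            signal_records.append(
                {
                    "key": {"contig": key.contig, "pos1": key.pos1, "ref": key.ref, "alt": key.alt},
                    "stratum": stratum,
                    "gene": gid,
                    "carriers": sorted(sheet.sample_ids[r] for r in carriers),
                }
            )

    # --- background ---------------------------------------------------------
    lo, hi = cfg.background_freq_range
    freqs = 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=cfg.n_background)
    taken = np.array(sorted(used_pos), dtype=np.int64) + 1
    avail = np.setdiff1d(np.arange(1, cfg.contig_length + 1, dtype=np.int64), taken)
    bg_pos1 = np.sort(rng.choice(avail, size=cfg.n_background, replace=False))
    bg_keys: list[VariantKey] = []
    bg_records: list[dict] = []
    bg_cols = np.zeros((n_total, cfg.n_background), dtype=np.uint8)
    for j in range(cfg.n_background):
        ref, alt = _snv(rng)
        key = VariantKey(cfg.contig, int(bg_pos1[j]), ref, alt)
        bg_keys.append(key)
        f = float(freqs[j])
        prob_car = (rng.random(n_prob) < f).astype(np.uint8)
        bg_cols[:n_prob, j] = prob_car
        copy = rng.random(cfg.n_control) < cfg.transmission_rate
        indep = (rng.random(cfg.n_control) < f).astype(np.uint8)
        bg_cols[ctrl_rows, j] = np.where(copy, prob_car[ctrl_proband], indep)
        bg_records.append(
            {
                "key": {"contig": key.contig, "pos1": key.pos1, "ref": key.ref, "alt": key.alt},
                "freq": f,
            }
        )

    keys = sig_keys + bg_keys
    cols = (
        np.concatenate([np.stack(sig_cols, axis=1), bg_cols], axis=1)
        if sig_cols
        else bg_cols
    )
    order = sorted(range(len(keys)), key=lambda j: (keys[j].contig, keys[j].pos1, keys[j].ref, keys[j].alt))
    matrix = CarrierMatrix(
        variants=[keys[j] for j in order],
        samples=sheet.sample_ids,
        carrier=cols[:, order],
    )
    truth = TruthTable(signal=signal_records, background=bg_records)
    return SimulatedCohort(matrix=matrix, sheet=sheet, genes=genes, truth=truth, config=cfg)


def write_cohort(sim: SimulatedCohort, outdir: str, prefix: str = "discovery") -> dict:
    """Serialize a simulated cohort (VCF, sheet TSV, GFF3, truth JSON)."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, f"{prefix}.vcf"),
        "sheet": os.path.join(outdir, f"{prefix}.samples.tsv"),
        "gff": os.path.join(outdir, "genes.gff3"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_vcf(sim.matrix, paths["vcf"])
    write_sample_sheet(sim.sheet, paths["sheet"])
    write_gff3(sim.genes, paths["gff"])
    sim.truth.to_json(paths["truth"])
    return paths


def simulate_validation(
    cfg: SimConfig, truth: TruthTable
) -> tuple[CarrierMatrix, SampleSheet]:
    """Generate the independent validation cohort from discovery ground truth.

    Cancer probands carry a per-sample random subset of the signal variants
    covering ``replant_rate`` of the signal spectrum; non-cancer probands
    carry background only.  All samples draw background carriers at the
    discovery frequencies.  Variants with no validation carrier are omitted
    (as an uncalled site would be).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    records = []
    for i in range(cfg.n_val_case):
        records.append(
            SampleRecord(f"VA{i + 1:04d}", f"FVA{i + 1:04d}", "BD_CANCER", "proband")
        )
    for i in range(cfg.n_val_bd_only):
        records.append(
            SampleRecord(f"VB{i + 1:04d}", f"FVB{i + 1:04d}", "BD_ONLY", "proband")
        )
    sheet = SampleSheet(records)
    n = len(sheet)

    sig = sorted(truth.signal_keys())
    bg = truth.background
    keys: list[VariantKey] = []
    cols: list[np.ndarray] = []

    n_replant = int(round(cfg.replant_rate * len(sig)))
    sig_cols = np.zeros((n, len(sig)), dtype=np.uint8)
    for i in range(cfg.n_val_case):
        if n_replant:
            pick = rng.choice(len(sig), size=n_replant, replace=False)
            sig_cols[i, pick] = 1
    for j, key in enumerate(sig):
        keys.append(key)
        cols.append(sig_cols[:, j])

    for d in sorted(bg, key=lambda d: (d["key"]["contig"], d["key"]["pos1"], d["key"]["ref"], d["key"]["alt"])):
        key = VariantKey(**d["key"])
        col = (rng.random(n) < d["freq"]).astype(np.uint8)
        keys.append(key)
        cols.append(col)

    keep = [j for j, c in enumerate(cols) if c.any()]
    order = sorted(keep, key=lambda j: (keys[j].contig, keys[j].pos1, keys[j].ref, keys[j].alt))
    matrix = CarrierMatrix(
        variants=[keys[j] for j in order],
        samples=sheet.sample_ids,
        carrier=np.stack([cols[j] for j in order], axis=1)
        if order
        else np.zeros((n, 0), dtype=np.uint8),
    )
    return matrix, sheet


# ---------------------------------------------------------------------------
# analytic expectation of spurious filter passes


def expected_spurious_selections(
    truth: TruthTable, sheet: SampleSheet, min_cases: int = 3,
    transmission_rate: float = 0.5,
) -> tuple[float, float]:
    """Exact expectation (and SD) of background variants passing the filter.

    Under the generative model, for a background variant with frequency f
    each proband is an independent carrier with probability f, and a control
    copies its proband's status with probability t (the transmission rate)
    or is an independent carrier otherwise.  The probability that a variant
    passes — >= ``min_cases`` cancer-proband carriers, zero carriers in the
    other two groups — is computed per variant by convolving per-proband
    carry/clean polynomials (a Poisson-binomial DP that accounts for the
    proband-control dependence).  Returns (sum of pass probabilities,
    Poisson-binomial SD).
    """
    t = transmission_rate
    # controls attached per proband row
    n_ctrl: dict[str, int] = {}
    fam_proband: dict[str, str] = {}
    for s in sheet:
        if s.role == "proband":
            fam_proband[s.family_id] = s.sample_id
            n_ctrl.setdefault(s.sample_id, 0)
    for s in sheet:
        if s.group == "CONTROL":
            n_ctrl[fam_proband[s.family_id]] += 1

    cases = [s for s in sheet if s.group == "BD_CANCER" and s.role == "proband"]
    others = [s for s in sheet if s.group == "BD_ONLY"]

    exp = 0.0
    var = 0.0
    for d in truth.background:
        f = d["freq"]
        clean_given_noncarrier = 1 - (1 - t) * f  # control clean | proband clean
        clean_given_carrier = (1 - t) * (1 - f)  # control clean | proband carries
        p_others = 1.0
        for s in others:
            p_others *= (1 - f) * clean_given_noncarrier ** n_ctrl.get(s.sample_id, 0)
        # DP over case probands: coeff[k] = P[k carriers, all case-side controls clean]
        coeff = np.zeros(len(cases) + 1)
        coeff[0] = 1.0
        for s in cases:
            c = n_ctrl.get(s.sample_id, 0)
            a = f * clean_given_carrier**c
            b = (1 - f) * clean_given_noncarrier**c
            coeff[1:] = coeff[1:] * b + coeff[:-1] * a
            coeff[0] *= b
        p_pass = float(coeff[min_cases:].sum()) * p_others
        exp += p_pass
        var += p_pass * (1 - p_pass)
    return exp, float(np.sqrt(var))
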