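"""Hypergeometric gene-set enrichment and somatic-catalogue overlap.

Offline stand-ins for web-based enrichment services and curated somatic
databases: any GMT gene-set collection can be tested against a query gene
list with a one-sided hypergeometric test (Benjamini-Hochberg adjusted), and
a selection can be screened against a user-supplied catalogue of somatic
variant keys by exact identity (same locus, same alternative allele).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from cyvcf2 import VCF
from scipy.stats import false_discovery_control, hypergeom

from .discovery import SelectionResult
from .variant_store import VariantKey, normalize_variant

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "hypergeom_enrich",
    "catalogue_overlap",
    "read_gmt",
    "read_catalogue",
]


@dataclass
class GeneSetCollection:
    """Named gene sets intersected with a gene universe."""

    sets: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            self.universe = sorted(uni)
        clipped = {}
        for name, members in self.sets.items():
            inside = sorted(set(members) & uni)
            outside = set(members) - uni
            if outside:
                logger.warning(
                    "gene set %s: dropping %d member(s) outside the universe",
                    name,
                    len(outside),
                )
            clipped[name] = inside
        self.sets = clipped


def read_gmt(path: str, universe: list[str]) -> GeneSetCollection:
    """Read a GMT file (set name, description, members per tab-separated line)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line needs >= 3 fields: {line!r}")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: duplicate gene-set name {name!r}")
            sets[name] = fields[2:]
    return GeneSetCollection(sets=sets, universe=universe)


def hypergeom_enrich(query: list[str], coll: GeneSetCollection) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``query`` in each gene set.

    For a universe of size N, a set of size K and a query of size n with
    overlap k, p = P[X >= k] for X ~ Hypergeom(N, K, n).  P-values are
    BH-adjusted across all sets; rows are sorted by p.
    """
    if not coll.universe:
        raise ValueError("empty gene universe")
    uni = set(coll.universe)
    inside = sorted(set(query) & uni)
    outside = set(query) - uni
    if outside:
        logger.warning(
            "dropping %d query gene(s) outside the universe", len(outside)
        )
    if not inside:
        raise ValueError("query is empty after intersecting with the universe")

    N, n = len(uni), len(inside)
    qset = set(inside)
    rows = []
    for name, members in coll.sets.items():
        K = len(members)
        k = len(qset & set(members))
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = false_discovery_control(df["p"].to_numpy(), method="bh")
        df = df.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
    return df


def read_catalogue(path: str) -> list[VariantKey]:
    """Read a somatic-variant catalogue from VCF or a 4-column TSV.

    TSV columns: contig, pos (1-based), ref, alt; a header line starting
    with 'contig' or '#' is skipped.  Keys are normalized with the same
    parsimony rule as the cohort VCF; records needing normalization are
    logged.
    """
    keys: list[VariantKey] = []
    if path.endswith((".vcf", ".vcf.gz")):
        for rec in VCF(path):
            for alt in rec.ALT:
                keys.append(_normalized_logged(rec.CHROM, rec.POS, rec.REF, alt))
        return keys
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("contig"):
                continue
            contig, pos, ref, alt = line.split("\t")[:4]
            keys.append(_normalized_logged(contig, int(pos), ref, alt))
    return keys


def _normalized_logged(contig, pos1, ref, alt) -> VariantKey:
    key = normalize_variant(contig, pos1, ref, alt)
    if (key.pos1, key.ref, key.alt) != (pos1, ref.upper(), alt.upper()):
        logger.info("catalogue record %s:%s %s>%s normalized to %s", contig, pos1, ref, alt, key)
    return key


def catalogue_overlap(
    sel: SelectionResult, catalogue: list[VariantKey]
) -> dict:
    """Exact-identity intersection of a selection with a somatic catalogue."""
    cat = set(catalogue)
    hits = [v.key for v in sel.selected if v.key in cat]
    return {
        "n_selected": len(sel.selected),
        "n_catalogue": len(cat),
        "n_overlap": len(hits),
        "overlap": [str(k) for k in sorted(hits)],
    }
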