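"""Gene-level mutation-load features and the two-layer reduction.

Selected variants are collapsed per region stratum into a samples x genes
count matrix: a sample's entry for gene *g* is the number of selected
variants mapped to *g* that the sample carries (the gene's "weight", i.e.
its mutation load).  Features are then reduced in two layers:

1. an impurity-based random-forest importance filter (normalized importances
   sum to 1; genes below a threshold, default 1e-5, are dropped), and
2. greedy forward feature selection maximizing cross-validated balanced
   accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .discovery import SelectionResult
from .variant_store import CarrierMatrix, SampleSheet

__all__ = [
    "FeatureMatrix",
    "ReductionReport",
    "build_feature_matrix",
    "importance_filter",
    "forward_select",
    "reduce_features",
    "reduction_summary",
    "write_feature_matrix",
    "read_feature_matrix",
]


@dataclass
class FeatureMatrix:
    """samples x genes mutation-load counts for one region stratum.

    ``labels`` is a binary vector over samples: 1 = affected proband with
    cancer, 0 = affected proband without cancer.
    """

    stratum: str
    genes: list[str]
    samples: list[str]
    load: np.ndarray  # (n_samples, n_genes) non-negative ints
    labels: np.ndarray | None = None  # (n_samples,) in {0,1}, None for unlabeled

    def __post_init__(self) -> None:
        self.load = np.asarray(self.load)
        if self.load.shape != (len(self.samples), len(self.genes)):
            raise ValueError("feature matrix shape mismatch")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.samples),):
                raise ValueError("labels length mismatch")

    @property
    def is_empty(self) -> bool:
        return len(self.genes) == 0

    def subset(self, genes: list[str]) -> "FeatureMatrix":
        idx = [self.genes.index(g) for g in genes]
        return FeatureMatrix(
            stratum=self.stratum,
            genes=list(genes),
            samples=self.samples,
            load=self.load[:, idx],
            labels=self.labels,
        )


@dataclass
class ReductionReport:
    """Audit trail of the two-layer feature reduction for one stratum."""

    stratum: str
    kept_genes: list[str]
    dropped_by_importance: list[str]
    dropped_by_ffs: list[str]
    importance: dict[str, float]
    variants_before: int = 0
    variants_after: int = 0

    @property
    def percent_reduction(self) -> float:
        if self.variants_before == 0:
            return 0.0
        return 100.0 * (1 - self.variants_after / self.variants_before)

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "kept_genes": self.kept_genes,
            "dropped_by_importance": self.dropped_by_importance,
            "dropped_by_ffs": self.dropped_by_ffs,
            "importance": self.importance,
            "variants_before": self.variants_before,
            "variants_after": self.variants_after,
            "percent_reduction": self.percent_reduction,
        }


def build_feature_matrix(
    sel: SelectionResult,
    matrix: CarrierMatrix,
    sheet: SampleSheet,
    stratum: str,
    gene_order: list[str] | None = None,
    binarize: bool = False,
    first_gene_only: bool = False,
) -> FeatureMatrix:
    """Collapse selected variants of one stratum to gene-level loads.

    Counts are computed over probands only (cases and disease-only).  A
    variant mapped to *k* genes contributes 1 to each of the *k* columns
    unless ``first_gene_only``.  With the default ``gene_order=None`` the
    columns are the stratum's genes sorted by id, with all-zero columns
    dropped; passing an explicit ``gene_order`` (e.g. the discovery order
    when featurizing a validation cohort) keeps exactly those columns,
    zero-filled when a gene has no variant.
    """
    if not sel.annotated and sel.selected:
        raise ValueError("selection must be annotated before featurization")
    case_idx = sheet.indices("BD_CANCER", role="proband")
    bd_idx = sheet.indices("BD_ONLY", role="proband")
    rows = np.concatenate([case_idx, bd_idx]) if (case_idx.size or bd_idx.size) else np.array([], dtype=int)
    samples = [sheet.samples[i].sample_id for i in rows]
    labels = np.array([1] * len(case_idx) + [0] * len(bd_idx), dtype=int)

    variants = [v for v in sel.selected if v.region is not None and v.stratum == stratum]
    gene_cols: dict[str, np.ndarray] = {}
    for v in variants:
        if v.key not in matrix:
            continue
        col = matrix.column(v.key)[rows].astype(np.int64)
        genes = v.genes[:1] if first_gene_only else v.genes
        for g in genes:
            if g in gene_cols:
                gene_cols[g] += col
            else:
                gene_cols[g] = col.copy()

    if gene_order is None:
        genes = sorted(g for g, c in gene_cols.items() if c.any())
    else:
        genes = list(gene_order)
    n = len(samples)
    load = np.zeros((n, len(genes)), dtype=np.int64)
    for j, g in enumerate(genes):
        if g in gene_cols:
            load[:, j] = gene_cols[g]
    if binarize:
        load = (load > 0).astype(np.int64)
    return FeatureMatrix(
        stratum=stratum, genes=genes, samples=samples, load=load, labels=labels
    )


def _check_two_classes(fm: FeatureMatrix) -> None:
    if fm.labels is None or len(np.unique(fm.labels)) < 2:
        raise ValueError("feature matrix must contain both classes")


def importance_filter(
    fm: FeatureMatrix,
    threshold: float = 1e-5,
    n_trees: int = 500,
    seed: int = 0,
) -> tuple[list[str], list[str], dict[str, float]]:
    """Random-forest importance filter.

    Fits an impurity-based forest on (load, labels); the normalized
    importances sum to 1 over the input gene set.  Genes with importance
    strictly below ``threshold`` are dropped.  Returns
    (kept, dropped, importance-by-gene); deterministic for a fixed seed.
    """
    _check_two_classes(fm)
    if fm.is_empty:
        return [], [], {}
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, class_weight="balanced"
    )
    forest.fit(fm.load, fm.labels)
    imp = forest.feature_importances_
    importance = {g: float(w) for g, w in zip(fm.genes, imp)}
    kept = [g for g, w in zip(fm.genes, imp) if w >= threshold]
    dropped = [g for g in fm.genes if g not in set(kept)]
    return kept, dropped, importance


def _default_scorer(seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=100, random_state=seed, class_weight="balanced"
    )


def forward_select(
    fm: FeatureMatrix,
    cv_folds: int = 5,
    seed: int = 0,
    patience: int = 1,
    estimator=None,
    max_candidates: int | None = 64,
) -> tuple[list[str], list[str]]:
    """Greedy forward feature selection on cross-validated balanced accuracy.

    Each round adds the candidate gene with the best CV score; the search
    stops after ``patience`` consecutive rounds without improvement over the
    best score so far, and the selected set is the best-scoring prefix, in
    pick order.  ``max_candidates`` bounds the candidate pool to the genes
    with the largest class-mean load difference (a cheap univariate screen)
    to keep the quadratic wrapper affordable; ``None`` disables the bound.
    Returns (selected, dropped).
    """
    _check_two_classes(fm)
    if len(fm.genes) < 2:
        raise ValueError("forward selection needs >= 2 candidate genes")
    counts = np.bincount(fm.labels)
    if cv_folds > counts.min():
        raise ValueError(
            f"cv_folds={cv_folds} exceeds the smaller class count {counts.min()}"
        )
    genes = list(fm.genes)
    if max_candidates is not None and len(genes) > max_candidates:
        diff = np.abs(
            fm.load[fm.labels == 1].mean(axis=0)
            - fm.load[fm.labels == 0].mean(axis=0)
        )
        order = np.argsort(-diff, kind="stable")[:max_candidates]
        genes = [fm.genes[j] for j in sorted(order)]

    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    est = estimator if estimator is not None else _default_scorer(seed)

    def score(cols: list[str]) -> float:
        X = fm.load[:, [fm.genes.index(g) for g in cols]]
        return float(
            cross_val_score(
                est, X, fm.labels, cv=cv, scoring="balanced_accuracy"
            ).mean()
        )

    picked: list[str] = []
    best_score = -np.inf
    best_len = 0
    stale = 0
    remaining = list(genes)
    while remaining:
        round_scores = [(score(picked + [g]), g) for g in remaining]
        s, g = max(round_scores, key=lambda t: (t[0], -remaining.index(t[1])))
        picked.append(g)
        remaining.remove(g)
        if s > best_score:
            best_score, best_len, stale = s, len(picked), 0
        else:
            stale += 1
            if stale > patience:
                break
    selected = picked[:best_len]
    dropped = [g for g in fm.genes if g not in set(selected)]
    return selected, dropped


def reduce_features(
    fm: FeatureMatrix,
    threshold: float = 1e-5,
    n_trees: int = 500,
    cv_folds: int = 5,
    patience: int = 1,
    seed: int = 0,
    estimator=None,
    max_candidates: int | None = 64,
) -> tuple[FeatureMatrix, ReductionReport]:
    """Run both reduction layers and return (reduced matrix, report)."""
    kept_imp, dropped_imp, importance = importance_filter(
        fm, threshold=threshold, n_trees=n_trees, seed=seed
    )
    if len(kept_imp) < 2:
        # nothing to wrap; keep whatever survived the importance layer
        kept, dropped_ffs = kept_imp, []
    else:
        kept, dropped_ffs = forward_select(
            fm.subset(kept_imp),
            cv_folds=cv_folds,
            seed=seed,
            patience=patience,
            estimator=estimator,
            max_candidates=max_candidates,
        )
    report = ReductionReport(
        stratum=fm.stratum,
        kept_genes=kept,
        dropped_by_importance=dropped_imp,
        dropped_by_ffs=dropped_ffs,
        importance=importance,
    )
    return fm.subset(kept), report


def write_feature_matrix(fm: FeatureMatrix, tsv_path: str, json_path: str) -> None:
    """Serialize as a samples x genes TSV plus a JSON sidecar (stratum,
    gene order, labels)."""
    import json

    with open(tsv_path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(fm.genes) + "\n")
        for i, s in enumerate(fm.samples):
            fh.write(s + "\t" + "\t".join(str(int(x)) for x in fm.load[i]) + "\n")
    sidecar = {
        "stratum": fm.stratum,
        "genes": fm.genes,
        "labels": None if fm.labels is None else {s: int(l) for s, l in zip(fm.samples, fm.labels)},
    }
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_feature_matrix(tsv_path: str, json_path: str) -> FeatureMatrix:
    import json

    with open(json_path) as fh:
        side = json.load(fh)
    samples, rows = [], []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        genes = header[1:]
        if genes != side["genes"]:
            raise ValueError("feature TSV gene order differs from sidecar")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            samples.append(fields[0])
            rows.append([int(x) for x in fields[1:]])
    labels = None
    if side["labels"] is not None:
        labels = np.array([side["labels"][s] for s in samples], dtype=int)
    load = np.array(rows, dtype=np.int64) if rows else np.zeros((0, len(genes)), dtype=np.int64)
    return FeatureMatrix(
        stratum=side["stratum"], genes=genes, samples=samples, load=load, labels=labels
    )


def reduction_summary(
    sel: SelectionResult, kept_genes: set[str] | list[str]
) -> dict:
    """Variant-level accounting of a gene-level reduction.

    A selected variant survives iff its mapped gene list intersects
    ``kept_genes``.  Returns counts before/after and the percent reduction.
    """
    kept = set(kept_genes)
    before = len(sel.selected)
    after = sum(1 for v in sel.selected if kept & set(v.genes))
    return {
        "variants_before": before,
        "variants_after": after,
        "percent_reduction": (100.0 * (1 - after / before)) if before else 0.0,
    }
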