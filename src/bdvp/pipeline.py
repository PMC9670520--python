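"""End-to-end orchestration of the prioritization pipeline.

Stages: simulate (optional) -> discover -> features -> train -> predict ->
compare-load -> enrich -> overlap.  Each stage consumes only serialized
artifacts of prior stages, and a manifest JSON records inputs, effective
parameters, per-stage seeds, outputs and their checksums.  A single global
seed is fanned out deterministically per stage (stage-name CRC mixed into
the base seed) so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import zlib
from dataclasses import dataclass, field

from . import __version__
from .classify import (
    TuningSpace,
    mutation_load_compare,
    predict_cohort,
    train_default,
    tune_and_train,
)
from .discovery import (
    SelectionConfig,
    annotate_selection,
    select_variants,
    write_selection_tsv,
)
from .enrich import catalogue_overlap, hypergeom_enrich, read_catalogue, read_gmt
from .features import (
    build_feature_matrix,
    reduce_features,
    reduction_summary,
    write_feature_matrix,
)
from .genome_model import STRATA, GeneIndex, load_gene_model
from .synthetic import SimConfig, simulate_cohort, simulate_validation, write_cohort
from .variant_store import read_cohort, write_sample_sheet, write_vcf

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "stage_seed",
    "run_all",
    "run_synthetic_experiment",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (base_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run.

    When ``simulate`` is set, input paths are generated into the output
    directory; otherwise ``vcf/sheet/gff`` (and optionally validation
    ``val_vcf/val_sheet``) must point to existing files.
    """

    outdir: str = "bdvp_out"
    seed: int = 0
    simulate: SimConfig | None = None
    vcf: str | None = None
    sheet: str | None = None
    gff: str | None = None
    val_vcf: str | None = None
    val_sheet: str | None = None
    gmt: str | None = None
    catalogue: str | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    pass_only: bool = False
    binarize: bool = False
    first_gene_only: bool = False
    importance_threshold: float = 1e-5
    n_trees: int = 500
    cv_folds: int = 5
    patience: int = 1
    max_candidates: int | None = 64
    tuning: TuningSpace = field(default_factory=TuningSpace)
    tune: bool = True

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("vcf", "sheet", "gff"):
                p = getattr(self, name)
                if p is None or not os.path.exists(p):
                    raise FileNotFoundError(
                        f"config: {name} path missing or does not exist: {p}"
                    )
        for name in ("gmt", "catalogue", "val_vcf", "val_sheet"):
            p = getattr(self, name)
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"config: {name} path does not exist: {p}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk).

    Raises :class:`PipelineError` naming the failing stage; partial outputs
    are retained.
    """
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "stages": [],
    }

    def record(stage: str, outputs: dict[str, str], extra: dict | None = None) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "seed": stage_seed(cfg.seed, stage),
                "outputs": {k: p for k, p in outputs.items()},
                "checksums": {k: _sha256(p) for k, p in outputs.items()},
                **({"summary": extra} if extra else {}),
            }
        )

    def _run(stage, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            _write_manifest(manifest, cfg.outdir)
            raise PipelineError(stage, exc) from exc

    # -- simulate ------------------------------------------------------------
    if cfg.simulate is not None:
        def _simulate():
            sim_cfg = dataclasses.replace(
                cfg.simulate, seed=stage_seed(cfg.seed, "simulate")
            )
            sim = simulate_cohort(sim_cfg)
            paths = write_cohort(sim, os.path.join(cfg.outdir, "sim"))
            val_matrix, val_sheet = simulate_validation(sim_cfg, sim.truth)
            vv = os.path.join(cfg.outdir, "sim", "validation.vcf")
            vs = os.path.join(cfg.outdir, "sim", "validation.samples.tsv")
            write_vcf(val_matrix, vv)
            write_sample_sheet(val_sheet, vs)
            paths.update({"val_vcf": vv, "val_sheet": vs})
            cfg.vcf, cfg.sheet, cfg.gff = paths["vcf"], paths["sheet"], paths["gff"]
            cfg.val_vcf, cfg.val_sheet = vv, vs
            return paths

        paths = _run("simulate", _simulate)
        record("simulate", paths)

    # -- discover ------------------------------------------------------------
    def _discover():
        matrix, sheet = read_cohort(cfg.vcf, cfg.sheet, pass_only=cfg.pass_only)
        genes = load_gene_model(cfg.gff)
        sel = annotate_selection(
            select_variants(matrix, sheet, cfg.selection), GeneIndex(genes)
        )
        path = os.path.join(cfg.outdir, "selection.tsv")
        write_selection_tsv(sel, path)
        return matrix, sheet, genes, sel, path

    matrix, sheet, genes, sel, sel_path = _run("discover", _discover)
    record(
        "discover",
        {"selection": sel_path},
        {"n_selected": len(sel), "per_stratum": {s: len(v) for s, v in sel.by_stratum().items()}},
    )

    # -- features ------------------------------------------------------------
    def _features():
        out = {}
        reduced, reports = {}, {}
        seed = stage_seed(cfg.seed, "features")
        for stratum in STRATA:
            fm = build_feature_matrix(
                sel, matrix, sheet, stratum,
                binarize=cfg.binarize, first_gene_only=cfg.first_gene_only,
            )
            if fm.is_empty:
                reduced[stratum] = fm
                continue
            red, rep = reduce_features(
                fm,
                threshold=cfg.importance_threshold,
                n_trees=cfg.n_trees,
                cv_folds=min(cfg.cv_folds, int(min((fm.labels == 0).sum(), (fm.labels == 1).sum()))),
                patience=cfg.patience,
                seed=seed,
                max_candidates=cfg.max_candidates,
            )
            summary = reduction_summary(
                sel, set(rep.kept_genes)
            )
            rep.variants_before = summary["variants_before"]
            rep.variants_after = summary["variants_after"]
            reduced[stratum], reports[stratum] = red, rep
            tsv = os.path.join(cfg.outdir, f"features_{stratum}.tsv")
            js = os.path.join(cfg.outdir, f"features_{stratum}.json")
            write_feature_matrix(red, tsv, js)
            out[f"features_{stratum}_tsv"], out[f"features_{stratum}_json"] = tsv, js
        rep_path = os.path.join(cfg.outdir, "reduction.json")
        with open(rep_path, "w") as fh:
            json.dump({s: r.to_dict() for s, r in reports.items()}, fh, indent=1, sort_keys=True)
            fh.write("\n")
        out["reduction"] = rep_path
        return reduced, reports, out

    reduced, reports, feat_out = _run("features", _features)
    record(
        "features",
        feat_out,
        {s: {"kept_genes": len(r.kept_genes)} for s, r in reports.items()},
    )

    # -- train ---------------------------------------------------------------
    def _train():
        models = {}
        seed = stage_seed(cfg.seed, "train")
        for stratum in STRATA:
            fm = reduced.get(stratum)
            if fm is None or fm.is_empty:
                models[stratum] = None
                continue
            if cfg.tune:
                space = dataclasses.replace(cfg.tuning, seed=seed)
                models[stratum] = tune_and_train(fm, space)
            else:
                models[stratum] = train_default(fm, seed=seed)
        path = os.path.join(cfg.outdir, "models.json")
        with open(path, "w") as fh:
            json.dump(
                {
                    s: None if m is None else {"params": m.params, "cv_loss": m.cv_loss, "genes": m.genes}
                    for s, m in models.items()
                },
                fh,
                indent=1,
                sort_keys=True,
                default=str,
            )
            fh.write("\n")
        return models, path

    models, models_path = _run("train", _train)
    record("train", {"models": models_path})

    # -- predict + compare-load (validation cohort when available) -----------
    report = None
    if cfg.val_vcf is not None:
        def _predict():
            val_matrix, val_sheet = read_cohort(cfg.val_vcf, cfg.val_sheet)
            fms = {}
            for stratum in STRATA:
                fm = reduced.get(stratum)
                if fm is None or fm.is_empty:
                    continue
                fms[stratum] = build_feature_matrix(
                    sel, val_matrix, val_sheet, stratum,
                    gene_order=fm.genes, binarize=cfg.binarize,
                    first_gene_only=cfg.first_gene_only,
                )
            rep = predict_cohort(models, fms)
            path = os.path.join(cfg.outdir, "predictions.json")
            with open(path, "w") as fh:
                json.dump(rep.to_json_dict(), fh, indent=1, sort_keys=True)
                fh.write("\n")
            tsv = os.path.join(cfg.outdir, "predictions.tsv")
            rep.per_sample.to_csv(tsv, sep="\t", index=False)
            comp = mutation_load_compare(sel, val_matrix, val_sheet)
            cpath = os.path.join(cfg.outdir, "load_comparison.json")
            with open(cpath, "w") as fh:
                json.dump(comp.to_json_dict(), fh, indent=1, sort_keys=True)
                fh.write("\n")
            return rep, {"predictions": path, "predictions_tsv": tsv}, comp, {"load_comparison": cpath}

        report, pred_out, comp, comp_out = _run("predict", _predict)
        record("predict", pred_out, report.summary)
        record("compare-load", comp_out, {"pvalue": comp.pvalue})

    # -- enrich --------------------------------------------------------------
    if cfg.gmt is not None:
        def _enrich():
            universe = [g.gene_id for g in genes]
            coll = read_gmt(cfg.gmt, universe)
            query = sorted({g for r in reports.values() for g in r.kept_genes})
            df = hypergeom_enrich(query, coll)
            path = os.path.join(cfg.outdir, "enrichment.tsv")
            df.to_csv(path, sep="\t", index=False)
            return df, path

        df, enr_path = _run("enrich", _enrich)
        record("enrich", {"enrichment": enr_path}, {"n_sets": int(len(df))})

    # -- overlap -------------------------------------------------------------
    if cfg.catalogue is not None:
        def _overlap():
            cat = read_catalogue(cfg.catalogue)
            rep = catalogue_overlap(sel, cat)
            path = os.path.join(cfg.outdir, "catalogue_overlap.json")
            with open(path, "w") as fh:
                json.dump(rep, fh, indent=1, sort_keys=True)
                fh.write("\n")
            return rep, path

        rep, ov_path = _run("overlap", _overlap)
        record("overlap", {"catalogue_overlap": ov_path}, {"n_overlap": rep["n_overlap"]})

    _write_manifest(manifest, cfg.outdir)
    return manifest


def run_synthetic_experiment(
    sim_cfg: SimConfig | None = None,
    *,
    tune: bool = True,
    tuning: TuningSpace | None = None,
    permute_labels: bool = False,
    importance_threshold: float = 1e-5,
    n_trees: int = 150,
    cv_folds: int = 3,
    patience: int = 1,
    ffs_estimator=None,
    max_candidates: int | None = 64,
) -> dict:
    """Run the whole analysis in memory on one synthetic cohort.

    Simulates discovery + validation cohorts, applies the
    exclusive-recurrence filter, builds and reduces per-stratum gene-load
    features, trains the stratum classifiers (Bayesian-tuned or default
    parameters), labels the validation cohort by majority vote, and
    compares validation mutation loads between groups.

    ``permute_labels`` shuffles the discovery case/control labels before
    feature reduction and training (seeded from the simulation seed) — the
    null experiment in which validation accuracy should hover around
    chance.

    Returns a dict of summary quantities: planted-signal recall, spurious
    selections with their analytic expectation and SD, per-stratum and
    combined validation accuracies, the variant-level reduction, and the
    validation load-comparison p-value.
    """
    import numpy as np

    from .synthetic import expected_spurious_selections

    sim_cfg = sim_cfg or SimConfig()
    sim = simulate_cohort(sim_cfg)
    sel = annotate_selection(
        select_variants(sim.matrix, sim.sheet), GeneIndex(sim.genes)
    )
    sig = sim.truth.signal_keys()
    selected = set(k for k in (v.key for v in sel.selected))
    recall = len(sig & selected) / len(sig) if sig else float("nan")
    spurious = len(selected - sig)
    exp_spurious, sd_spurious = expected_spurious_selections(
        sim.truth, sim.sheet, min_cases=sel.config.min_cases,
        transmission_rate=sim_cfg.transmission_rate,
    )

    val_matrix, val_sheet = simulate_validation(sim_cfg, sim.truth)
    perm_rng = np.random.default_rng(np.random.SeedSequence([sim_cfg.seed, 3]))
    perm = None

    models, fms, kept = {}, {}, set()
    reduction = None
    for stratum in STRATA:
        fm = build_feature_matrix(sel, sim.matrix, sim.sheet, stratum)
        if fm.is_empty:
            models[stratum] = None
            continue
        if permute_labels:
            if perm is None:
                perm = perm_rng.permutation(len(fm.samples))
            fm.labels = fm.labels[perm]
        folds = min(cv_folds, int(min((fm.labels == 0).sum(), (fm.labels == 1).sum())))
        red, rep = reduce_features(
            fm,
            threshold=importance_threshold,
            n_trees=n_trees,
            cv_folds=folds,
            patience=patience,
            seed=sim_cfg.seed,
            estimator=ffs_estimator,
            max_candidates=max_candidates,
        )
        kept |= set(rep.kept_genes)
        if red.is_empty:
            models[stratum] = None
            continue
        if tune:
            space = dataclasses.replace(tuning or TuningSpace(), seed=sim_cfg.seed)
            models[stratum] = tune_and_train(red, space, cv_folds=folds)
        else:
            models[stratum] = train_default(red, seed=sim_cfg.seed)
        fms[stratum] = build_feature_matrix(
            sel, val_matrix, val_sheet, stratum, gene_order=red.genes
        )
    report = predict_cohort(models, fms)
    comp = mutation_load_compare(sel, val_matrix, val_sheet)
    return {
        "n_selected": len(sel),
        "recall": recall,
        "spurious": spurious,
        "expected_spurious": exp_spurious,
        "sd_spurious": sd_spurious,
        "reduction": reduction_summary(sel, kept),
        "prediction": report.summary,
        "load_p": comp.pvalue,
        "load_medians": {g: s["median"] for g, s in comp.summaries.items()},
    }


def _write_manifest(manifest: dict, outdir: str) -> None:
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
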