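"""Per-stratum MLP classifiers, majority-vote combination, and load tests.

One multi-layer perceptron is trained per region stratum on the reduced
gene-load features of the discovery cohort, with hyperparameters chosen by
sequential model-based minimization of cross-validated log-loss.  An
independent cohort is labeled by each stratum model and the three votes are
combined by majority; with all three models present the majority is never
tied.  Class imbalance is handled by seeded balanced oversampling of the
minority class before each fit (sklearn's MLP has no class weights).

Mutation loads (per-individual counts of selected variants) are compared
between groups with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .discovery import SelectionResult
from .features import FeatureMatrix
from .genome_model import STRATA
from .tuning import Categorical, Integer, OptimizeResult, Real, smbo_minimize
from .variant_store import CarrierMatrix, SampleSheet

__all__ = [
    "TuningSpace",
    "TrainedModel",
    "PredictionReport",
    "LoadComparison",
    "tune_and_train",
    "train_default",
    "majority_vote",
    "predict_cohort",
    "mutation_load_compare",
]


@dataclass(frozen=True)
class TuningSpace:
    """Hyperparameter search space for the per-stratum MLP."""

    max_iter: tuple[int, int] = (100, 400)
    l2_alpha: tuple[float, float] = (1e-5, 1e-1)  # log scale
    activations: tuple[str, ...] = ("relu", "tanh", "logistic")
    solvers: tuple[str, ...] = ("adam", "lbfgs")
    learning_rates: tuple[str, ...] = ("constant", "adaptive")
    hidden_layers: tuple[int, int] = (1, 3)
    units: tuple[int, int] = (8, 64)
    budget: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        for rng_ in (self.max_iter, self.l2_alpha, self.hidden_layers, self.units):
            if rng_[0] > rng_[1]:
                raise ValueError(f"empty range {rng_}")
        for s in (self.activations, self.solvers, self.learning_rates):
            if not s:
                raise ValueError("empty categorical set")

    def to_dims(self) -> dict:
        return {
            "max_iter": Integer(*self.max_iter),
            "alpha": Real(*self.l2_alpha, log=True),
            "activation": Categorical(tuple(self.activations)),
            "solver": Categorical(tuple(self.solvers)),
            "learning_rate": Categorical(tuple(self.learning_rates)),
            "hidden_layers": Integer(*self.hidden_layers),
            "units": Integer(*self.units),
        }


@dataclass
class TrainedModel:
    model: MLPClassifier
    genes: list[str]
    stratum: str
    params: dict
    cv_loss: float | None = None
    history: OptimizeResult | None = None

    def predict(self, fm: FeatureMatrix) -> np.ndarray:
        if fm.genes != self.genes:
            raise ValueError(
                f"{self.stratum}: feature matrix gene order differs from the "
                "order the model was trained with"
            )
        return self.model.predict(fm.load).astype(int)


DEFAULT_PARAMS = {
    "max_iter": 200,
    "alpha": 1e-3,
    "activation": "relu",
    "solver": "adam",
    "learning_rate": "constant",
    "hidden_layers": 1,
    "units": 32,
}


def _make_mlp(params: dict, seed: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(params["units"],) * params["hidden_layers"],
        activation=params["activation"],
        solver=params["solver"],
        alpha=params["alpha"],
        learning_rate=params["learning_rate"],
        max_iter=params["max_iter"],
        random_state=seed,
    )


def _balanced_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Oversample minority class(es) to the majority count; shuffled."""
    classes, counts = np.unique(y, return_counts=True)
    nmax = counts.max()
    parts = []
    for c in classes:
        ci = np.flatnonzero(y == c)
        if len(ci) < nmax:
            ci = np.concatenate([ci, rng.choice(ci, nmax - len(ci), replace=True)])
        parts.append(ci)
    idx = np.concatenate(parts)
    rng.shuffle(idx)
    return idx


def _fit_balanced(model: MLPClassifier, X, y, seed: int) -> MLPClassifier:
    idx = _balanced_indices(np.asarray(y), np.random.default_rng(seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(np.asarray(X)[idx], np.asarray(y)[idx])
    return model


def _cv_log_loss(params: dict, fm: FeatureMatrix, seed: int, cv_folds: int) -> float:
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    losses = []
    for tr, te in cv.split(fm.load, fm.labels):
        model = _fit_balanced(
            _make_mlp(params, seed), fm.load[tr], fm.labels[tr], seed
        )
        proba = model.predict_proba(fm.load[te])
        losses.append(log_loss(fm.labels[te], proba, labels=[0, 1]))
    return float(np.mean(losses))


def tune_and_train(
    fm: FeatureMatrix, space: TuningSpace | None = None, cv_folds: int = 3
) -> TrainedModel:
    """Bayesian-optimize MLP hyperparameters and refit on all discovery data.

    Minimizes cross-validated log-loss within ``space.budget`` evaluations;
    trials with non-finite loss are recorded as failures and the search
    continues.  Deterministic for a fixed ``space.seed``.
    """
    space = space or TuningSpace()
    if fm.labels is None or len(np.unique(fm.labels)) < 2:
        raise ValueError("training features must contain both classes")
    result = smbo_minimize(
        lambda p: _cv_log_loss(p, fm, space.seed, cv_folds),
        space.to_dims(),
        budget=space.budget,
        seed=space.seed,
    )
    model = _fit_balanced(
        _make_mlp(result.best_params, space.seed), fm.load, fm.labels, space.seed
    )
    return TrainedModel(
        model=model,
        genes=list(fm.genes),
        stratum=fm.stratum,
        params=result.best_params,
        cv_loss=result.best_loss,
        history=result,
    )


def train_default(fm: FeatureMatrix, seed: int = 0) -> TrainedModel:
    """Train an MLP with the default hyperparameters (no search)."""
    model = _fit_balanced(_make_mlp(DEFAULT_PARAMS, seed), fm.load, fm.labels, seed)
    return TrainedModel(
        model=model, genes=list(fm.genes), stratum=fm.stratum, params=dict(DEFAULT_PARAMS)
    )


def majority_vote(votes: list[int | None]) -> int:
    """Majority over per-stratum votes; ties (possible only when a model
    abstained) break toward label 0."""
    cast = [v for v in votes if v is not None]
    if not cast:
        raise ValueError("no votes cast")
    ones = sum(cast)
    return 1 if ones * 2 > len(cast) else 0


@dataclass
class PredictionReport:
    per_sample: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "per_sample": self.per_sample.to_dict(orient="records"),
            "summary": self.summary,
        }


def predict_cohort(
    models: dict[str, TrainedModel | None],
    fms: dict[str, FeatureMatrix],
) -> PredictionReport:
    """Label a cohort with per-stratum models and combine by majority vote.

    ``fms`` must hold one feature matrix per stratum, built with the
    corresponding model's discovery gene order (missing genes zero-filled).
    A missing stratum model abstains; the majority then runs over the
    remaining votes with ties broken toward label 0.  Accuracies are
    reported as fractions and rounded integer percents when true labels are
    available.
    """
    strata = [s for s in STRATA if s in fms]
    if not strata:
        raise ValueError("no feature matrices supplied")
    samples = fms[strata[0]].samples
    for s in strata:
        if fms[s].samples != samples:
            raise ValueError("feature matrices disagree on sample order")

    votes: dict[str, np.ndarray | None] = {}
    for s in strata:
        model = models.get(s)
        votes[s] = model.predict(fms[s]) if model is not None else None

    rows = []
    true = fms[strata[0]].labels
    for i, sid in enumerate(samples):
        per = {s: (int(votes[s][i]) if votes[s] is not None else None) for s in strata}
        maj = majority_vote(list(per.values()))
        row = {"sample_id": sid}
        for s in STRATA:
            row[f"vote_{s}"] = per.get(s)
        row["majority_label"] = maj
        if true is not None:
            row["true_label"] = int(true[i])
        rows.append(row)
    df = pd.DataFrame(rows)

    summary: dict = {"n_samples": len(samples)}
    if true is not None:
        true = np.asarray(true)
        for s in strata:
            if votes[s] is not None:
                acc = float((votes[s] == true).mean())
                summary[f"accuracy_{s}"] = acc
                summary[f"accuracy_{s}_percent"] = round(100 * acc)
                summary[f"correct_{s}"] = int((votes[s] == true).sum())
        maj = df["majority_label"].to_numpy()
        acc = float((maj == true).mean())
        summary["accuracy_combined"] = acc
        summary["accuracy_combined_percent"] = round(100 * acc)
        summary["correct_combined"] = int((maj == true).sum())
        summary["errors_true_1_labeled_0"] = int(((maj == 0) & (true == 1)).sum())
        summary["errors_true_0_labeled_1"] = int(((maj == 1) & (true == 0)).sum())
    return PredictionReport(per_sample=df, summary=summary)


@dataclass
class LoadComparison:
    """Per-individual variant-of-interest counts compared between two groups."""

    groups: tuple[str, str]
    counts: dict[str, np.ndarray]
    summaries: dict[str, dict]
    statistic: float | None = None
    pvalue: float | None = None

    def to_json_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "counts": {g: c.tolist() for g, c in self.counts.items()},
            "summaries": self.summaries,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
        }


def _five_number(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {
        "n": int(x.size),
        "min": float(x.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(x.max()),
    }


def mutation_load_compare(
    sel: SelectionResult,
    matrix: CarrierMatrix,
    sheet: SampleSheet,
    groups: tuple[str, str] = ("BD_CANCER", "BD_ONLY"),
) -> LoadComparison:
    """Compare per-individual counts of selected variants between two groups.

    Counts are over probands.  Uses a two-sided Wilcoxon rank-sum
    (Mann-Whitney U) test: an exact permutation null when the group sizes
    are small enough to enumerate, the normal approximation with tie
    correction otherwise.  If either group has fewer than 2 individuals the
    test is skipped with a warning.
    """
    present = [v.key for v in sel.selected if v.key in matrix]
    cols = (
        np.stack([matrix.column(k) for k in present], axis=1)
        if present
        else np.zeros((len(matrix.samples), 0), dtype=np.uint8)
    )
    per_sample = cols.sum(axis=1)

    counts: dict[str, np.ndarray] = {}
    for g in groups:
        idx = sheet.indices(g, role="proband")
        if idx.size == 0:
            raise ValueError(f"group {g} has no probands")
        counts[g] = per_sample[idx].astype(int)

    summaries = {g: _five_number(c) for g, c in counts.items()}
    a, b = counts[groups[0]], counts[groups[1]]
    if min(a.size, b.size) < 2:
        warnings.warn("a group has < 2 individuals; rank-sum test skipped")
        return LoadComparison(groups=groups, counts=counts, summaries=summaries)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:  # all values identical: no evidence either way
        return LoadComparison(
            groups=groups,
            counts=counts,
            summaries=summaries,
            statistic=float(a.size * b.size / 2),
            pvalue=1.0,
        )
    # small samples: exact permutation null (valid with ties, unlike the
    # classical exact U distribution); otherwise normal approximation with
    # tie correction
    if comb(a.size + b.size, a.size) <= 20_000:
        stat, p = _exact_rank_sum(a, b)
    else:
        res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)
    return LoadComparison(
        groups=groups,
        counts=counts,
        summaries=summaries,
        statistic=stat,
        pvalue=p,
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    return float(
        (x[:, None] > y[None, :]).sum() + 0.5 * (x[:, None] == y[None, :]).sum()
    )


def _exact_rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact permutation p for the Mann-Whitney U statistic."""
    pooled = np.concatenate([a, b])
    n1, n = a.size, pooled.size
    center = n1 * (n - n1) / 2
    u_obs = _u_statistic(a, b)
    count = total = 0
    idx = np.arange(n)
    for chosen in combinations(idx, n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(chosen)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-9:
            count += 1
    return u_obs, count / total
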