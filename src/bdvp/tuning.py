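"""Sequential model-based (Bayesian) minimization over mixed search spaces.

A compact optimizer in the gp_minimize style: an initial batch of random
configurations, then a Gaussian-process surrogate (Matern kernel) fit to the
observed losses, with the next configuration chosen by maximizing expected
improvement over a pool of random candidates.  Integer and categorical
dimensions are handled by continuous relaxation + rounding, reals optionally
on a log10 scale.  Failed evaluations (non-finite loss) are recorded and
penalized with the worst finite loss observed, so the search continues.

Deterministic for a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

__all__ = ["Integer", "Real", "Categorical", "OptimizeResult", "smbo_minimize"]


@dataclass(frozen=True)
class Integer:
    low: int
    high: int  # inclusive

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.integers(self.low, self.high + 1))

    def to_unit(self, v) -> float:
        if self.high == self.low:
            return 0.0
        return (v - self.low) / (self.high - self.low)

    def from_unit(self, u: float):
        return int(round(self.low + u * (self.high - self.low)))


@dataclass(frozen=True)
class Real:
    low: float
    high: float
    log: bool = False

    def sample(self, rng: np.random.Generator) -> float:
        if self.log:
            return float(
                10 ** rng.uniform(math.log10(self.low), math.log10(self.high))
            )
        return float(rng.uniform(self.low, self.high))

    def to_unit(self, v) -> float:
        if self.log:
            lo, hi = math.log10(self.low), math.log10(self.high)
            return (math.log10(v) - lo) / (hi - lo)
        return (v - self.low) / (self.high - self.low)

    def from_unit(self, u: float):
        if self.log:
            lo, hi = math.log10(self.low), math.log10(self.high)
            return float(10 ** (lo + u * (hi - lo)))
        return float(self.low + u * (self.high - self.low))


@dataclass(frozen=True)
class Categorical:
    choices: tuple

    def sample(self, rng: np.random.Generator):
        return self.choices[int(rng.integers(len(self.choices)))]

    def to_unit(self, v) -> float:
        if len(self.choices) == 1:
            return 0.0
        return self.choices.index(v) / (len(self.choices) - 1)

    def from_unit(self, u: float):
        i = int(round(u * (len(self.choices) - 1)))
        return self.choices[min(max(i, 0), len(self.choices) - 1)]


@dataclass
class OptimizeResult:
    best_params: dict
    best_loss: float
    trials: list[dict] = field(default_factory=list)  # params, loss, failed


def smbo_minimize(
    objective: Callable[[dict], float],
    space: dict[str, Integer | Real | Categorical],
    budget: int,
    seed: int = 0,
    n_initial: int | None = None,
    n_candidates: int = 256,
) -> OptimizeResult:
    """Minimize ``objective`` over ``space`` within ``budget`` evaluations."""
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(space)
    dims = [space[k] for k in names]
    n_initial = n_initial if n_initial is not None else min(budget, max(4, budget // 3))

    X_unit: list[list[float]] = []
    losses: list[float] = []
    trials: list[dict] = []

    def evaluate(params: dict) -> None:
        try:
            loss = float(objective(params))
        except Exception:
            loss = float("nan")
        failed = not np.isfinite(loss)
        trials.append({"params": params, "loss": loss, "failed": failed})
        X_unit.append([d.to_unit(params[k]) for k, d in zip(names, dims)])
        losses.append(loss)

    for _ in range(min(n_initial, budget)):
        evaluate({k: d.sample(rng) for k, d in zip(names, dims)})

    while len(trials) < budget:
        y = np.array(losses, dtype=float)
        finite = np.isfinite(y)
        if finite.any():
            y = np.where(finite, y, y[finite].max() + 1.0)
        else:
            evaluate({k: d.sample(rng) for k, d in zip(names, dims)})
            continue
        mu, sd = y.mean(), y.std()
        yn = (y - mu) / (sd if sd > 0 else 1.0)
        kernel = ConstantKernel(1.0) * Matern(
            length_scale=np.full(len(dims), 0.25), nu=2.5
        ) + WhiteKernel(noise_level=1e-6, noise_level_bounds=(1e-8, 1e-1))
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=False, random_state=int(rng.integers(2**31))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.array(X_unit), yn)
        cand = rng.random((n_candidates, len(dims)))
        pred, std = gp.predict(cand, return_std=True)
        best = yn.min()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (best - pred) / std
            ei = (best - pred) * norm.cdf(z) + std * norm.pdf(z)
            ei[std <= 0] = 0.0
        u = cand[int(np.argmax(ei))]
        evaluate({k: d.from_unit(ui) for k, d, ui in zip(names, dims, u)})

    y = np.array(losses, dtype=float)
    finite = np.isfinite(y)
    if not finite.any():
        raise RuntimeError("every optimization trial failed")
    ibest = int(np.flatnonzero(finite)[np.argmin(y[finite])])
    return OptimizeResult(
        best_params=trials[ibest]["params"],
        best_loss=float(y[ibest]),
        trials=trials,
    )
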