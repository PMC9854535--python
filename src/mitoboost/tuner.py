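"""Hyperparameter tuning of the boosted classifier with the hummingbird algorithm.

The tuner maps a list of bounded hyperparameters onto the optimizer's
continuous search box, decodes each position (log-scale parameters are
exponentiated, integer parameters rounded half-up), and minimizes the mean
stratified k-fold cross-validated misclassification rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import ahba, gboost


@dataclass(frozen=True)
class Param:
    name: str
    low: float
    high: float
    is_integer: bool = False
    is_log_scale: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"invalid bounds for {self.name}")
        if self.is_log_scale and self.low <= 0:
            raise ValueError(f"log-scale parameter {self.name} needs positive bounds")


@dataclass(frozen=True)
class TuningSpace:
    params: tuple

    def __post_init__(self) -> None:
        if len(self.params) == 0:
            raise ValueError("tuning space needs at least one parameter")

    @property
    def d(self) -> int:
        return len(self.params)

    def search_space(self) -> ahba.SearchSpace:
        low = np.array([math.log(p.low) if p.is_log_scale else p.low for p in self.params])
        up = np.array([math.log(p.high) if p.is_log_scale else p.high for p in self.params])
        return ahba.SearchSpace(low, up)


#: standard booster knobs at desk-scale cost
DEFAULT_SPACE = TuningSpace(params=(
    Param("shrinkage", 0.01, 0.5, is_log_scale=True),
    Param("num_rounds", 10, 200, is_integer=True),
    Param("max_depth", 1, 6, is_integer=True),
    Param("lam", 0.0, 10.0),
    Param("gamma", 0.0, 5.0),
))


def decode_position(position, space: TuningSpace) -> dict:
    """Continuous optimizer position -> hyperparameter map."""
    position = np.asarray(position, dtype=float)
    box = space.search_space()
    if np.any(position < box.low - 1e-12) or np.any(position > box.up + 1e-12):
        raise ValueError("position outside the tuning bounds")
    out = {}
    for v, p in zip(position, space.params):
        if p.is_log_scale:
            v = math.exp(v)
        if p.is_integer:
            v = int(math.floor(v + 0.5))  # round half-up
            v = min(max(v, int(p.low)), int(p.high))
        else:
            v = min(max(float(v), p.low), p.high)
        out[p.name] = v
    return out


def _config_from_params(params: dict) -> gboost.BoostConfig:
    base = gboost.BoostConfig()
    fields = {k: params.get(k, getattr(base, k)) for k in
              ("num_rounds", "max_depth", "shrinkage", "lam", "gamma", "min_child_hessian")}
    return gboost.BoostConfig(**fields)


def cv_fitness(params: dict, X, y, k: int = 5, seed: int = 0) -> float:
    """Mean stratified k-fold misclassification rate of the boosted model."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    X, y = gboost.validate_table(X, y)
    config = _config_from_params(params)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    errors = []
    yi = y.astype(int)
    for tr, te in skf.split(X, yi):
        if len(np.unique(yi[tr])) < 2:
            raise ValueError("a CV fold lost one class; re-stratify with fewer folds")
        model = gboost.fit(X[tr], yi[tr], config)
        errors.append(float(np.mean(model.predict(X[te]) != yi[te])))
    return float(np.mean(errors))


@dataclass
class TuningResult:
    best_params: dict
    best_cv_error: float
    history: np.ndarray
    n_evals: int


class _CachedObjective:
    """Memoizes the CV fitness on the decoded parameter tuple.

    The fitness is a pure function of the decoded parameters, so revisiting a
    position (common once integer parameters collapse nearby positions) costs
    nothing; ``n_evals`` counts unique model evaluations.
    """

    def __init__(self, X, y, space: TuningSpace, k: int, seed: int):
        self.X, self.y, self.space, self.k, self.seed = X, y, space, k, seed
        self.cache: dict = {}
        self.n_evals = 0

    def __call__(self, position) -> float:
        params = decode_position(position, self.space)
        key = tuple(sorted(params.items()))
        if key not in self.cache:
            self.cache[key] = cv_fitness(params, self.X, self.y, self.k, self.seed)
            self.n_evals += 1
        return self.cache[key]


def tune(X, y, space: TuningSpace = DEFAULT_SPACE,
         ahba_config: ahba.AHBAConfig | None = None,
         k: int = 5, seed: int = 0) -> TuningResult:
    """AHBA search over the decoded CV objective."""
    if ahba_config is None:
        ahba_config = ahba.AHBAConfig(n=8, max_iters=20, seed=seed)
    obj = _CachedObjective(X, y, space, k, seed)
    res = ahba.optimize(obj, space.search_space(), ahba_config)
    return TuningResult(best_params=decode_position(res.x, space),
                        best_cv_error=float(res.fun), history=res.trace,
                        n_evals=obj.n_evals)


def random_search(X, y, space: TuningSpace = DEFAULT_SPACE, n_evals: int = 169,
                  k: int = 5, seed: int = 0) -> TuningResult:
    """Uniform random baseline with a matched evaluation budget."""
    obj = _CachedObjective(X, y, space, k, seed)
    res = ahba.random_search(obj, space.search_space(), n_evals, seed)
    return TuningResult(best_params=decode_position(res.x, space),
                        best_cv_error=float(res.fun), history=res.trace,
                        n_evals=obj.n_evals)
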