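"""Grey wolf optimizer: continuous search plus a binary wrapper for feature
selection and a decoder for CNN hyperparameter tuning.

The canonical formulation is used: for each wolf and each leader
(alpha, beta, delta) fresh per-dimension draws r1, r2 ~ U(0,1) give
A = 2 a r1 - a and C = 2 r2; the distance D = |C x_leader - x| yields the
candidate x_leader - A D, and the new position is the mean of the three
candidates, clamped to the box bounds.  The control scalar a decays linearly
from 2 to 0 over the iteration budget.  The three leaders are the best
solutions seen so far (elitist bookkeeping), so the best-so-far fitness
curve is monotone non-increasing under the minimization convention.

Draw order (relied on by reproducibility guarantees): wolves in index order;
for each wolf the leaders in the order alpha, beta, delta; for each leader
r1 (dim draws) then r2 (dim draws).
"""
from __future__ import annotations

import csv
import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class GWOConfig:
    """Knobs shared by the selection/tuning wrappers."""

    n_wolves: int = 8
    iterations: int = 15
    seed: int = 0
    lambda_sparsity: float = 0.01
    threshold: float = 0.5
    bounds: tuple[float, float] = (-4.0, 4.0)


@dataclass
class GWOState:
    positions: np.ndarray          # (n_wolves, dim)
    fitness: np.ndarray            # (n_wolves,)
    leader_positions: np.ndarray   # (3, dim): alpha, beta, delta
    leader_fitness: np.ndarray     # (3,)
    iteration: int
    max_iterations: int
    bounds_low: np.ndarray
    bounds_high: np.ndarray
    rng: np.random.Generator
    rng_seed: int
    a: float = 2.0
    evaluations: int = 0

    @property
    def alpha(self) -> np.ndarray:
        return self.leader_positions[0]


@dataclass
class FeatureMask:
    bits: np.ndarray  # boolean vector over feature indices

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.selected_count < 1:
            raise ValueError("empty feature masks are rejected")

    @property
    def selected_count(self) -> int:
        return int(self.bits.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


@dataclass
class OptResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # per-iteration best-so-far fitness, length T
    evaluations: int
    seed: int


def _as_bounds(bounds: Sequence, dim: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    b = np.asarray(bounds, dtype=float)
    if b.ndim == 1 and b.shape == (2,):
        if dim is None:
            raise ValueError("scalar bounds need an explicit dimension")
        b = np.tile(b, (dim, 1))
    if b.ndim != 2 or b.shape[1] != 2 or np.any(b[:, 0] > b[:, 1]):
        raise ValueError("bounds must be per-dimension (low, high) pairs with low <= high")
    return b[:, 0].copy(), b[:, 1].copy()


def _rank_leaders(positions: np.ndarray, fitness: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(fitness, kind="stable")[:3]
    return positions[order].copy(), fitness[order].copy()


def initialize_pack(objective: Callable[[np.ndarray], float], n_wolves: int,
                    bounds: Sequence, seed: int,
                    max_iterations: int = 100) -> GWOState:
    """Scatter a pack uniformly in the bounds and rank the leader triple."""
    if n_wolves < 3:
        raise ValueError("n_wolves must be >= 3 (alpha/beta/delta undefined otherwise)")
    low, high = _as_bounds(bounds)
    dim = low.size
    rng = np.random.default_rng(seed)
    positions = low + (high - low) * rng.random((n_wolves, dim))
    fitness = np.array([float(objective(p)) for p in positions])
    bad = ~np.isfinite(fitness)
    if bad.any():
        logger.warning("non-finite initial fitness for wolves %s", np.flatnonzero(bad).tolist())
        fitness[bad] = np.inf
    lp, lf = _rank_leaders(positions, fitness)
    return GWOState(positions, fitness, lp, lf, iteration=0,
                    max_iterations=max_iterations, bounds_low=low, bounds_high=high,
                    rng=rng, rng_seed=seed, a=2.0, evaluations=n_wolves)


def update_pack(state: GWOState, objective: Callable[[np.ndarray], float],
                rng: np.random.Generator | None = None) -> GWOState:
    """One GWO iteration: move every wolf toward the leader triple.

    A wolf whose new position evaluates non-finite keeps its previous
    position and fitness (logged).  Leaders are re-ranked from the union of
    the current pack and the previous leaders, then the iteration counter is
    incremented and a updated.
    """
    if rng is None:
        rng = state.rng
    n, dim = state.positions.shape
    T = state.max_iterations
    a = 2.0 * (1.0 - (state.iteration + 1) / T)
    new_positions = np.empty_like(state.positions)
    for i in range(n):
        x = state.positions[i]
        candidates = np.empty((3, dim))
        for ell in range(3):
            r1 = rng.random(dim)
            r2 = rng.random(dim)
            A = 2.0 * a * r1 - a
            C = 2.0 * r2
            leader = state.leader_positions[ell]
            D = np.abs(C * leader - x)
            candidates[ell] = leader - A * D
        new_positions[i] = candidates.mean(axis=0)
    np.clip(new_positions, state.bounds_low, state.bounds_high, out=new_positions)

    for i in range(n):
        f = float(objective(new_positions[i]))
        state.evaluations += 1
        if math.isfinite(f):
            state.positions[i] = new_positions[i]
            state.fitness[i] = f
        else:
            logger.warning("wolf %d returned non-finite fitness; position kept", i)
    pool_pos = np.vstack([state.leader_positions, state.positions])
    pool_fit = np.concatenate([state.leader_fitness, state.fitness])
    state.leader_positions, state.leader_fitness = _rank_leaders(pool_pos, pool_fit)
    state.iteration += 1
    state.a = a
    return state


def optimize(objective: Callable[[np.ndarray], float], bounds: Sequence,
             n_wolves: int = 20, T: int = 100, seed: int = 0,
             log_path: str | Path | None = None) -> OptResult:
    """Run T iterations and return the best solution over all evaluations."""
    if T < 1:
        raise ValueError("T must be >= 1")
    state = initialize_pack(objective, n_wolves, bounds, seed, max_iterations=T)
    history = np.empty(T)
    rows = []
    for t in range(T):
        update_pack(state, objective)
        history[t] = state.leader_fitness[0]
        if log_path is not None:
            rows.append([t, state.leader_fitness[0], *state.alpha.tolist()])
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["iteration", "best_fitness"]
                       + [f"alpha_{j}" for j in range(state.positions.shape[1])])
            w.writerows(rows)
    return OptResult(state.alpha.copy(), float(state.leader_fitness[0]),
                     history, state.evaluations, seed)


# ---------------------------------------------------------------------------
# Binary decoding for wrapper feature selection
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def binarize_positions(positions: np.ndarray, threshold: float = 0.5) -> list[FeatureMask]:
    """Sigmoid-threshold each wolf's position into a feature mask.

    Bit j is set iff sigmoid(position_j) > threshold (strict).  All-zero
    masks are repaired by setting the bit with the largest sigmoid value.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if not np.all(np.isfinite(positions)):
        raise ValueError("positions must be finite")
    masks = []
    for row in positions:
        s = _sigmoid(row)
        bits = s > threshold
        if not bits.any():
            bits = np.zeros_like(bits)
            bits[int(np.argmax(s))] = True
        masks.append(FeatureMask(bits))
    return masks


def select_features(evaluator: Callable[[FeatureMask], float], dim: int,
                    config: GWOConfig | None = None) -> FeatureMask:
    """Wrapper feature selection minimising validation error plus a sparsity
    penalty lambda_s * |mask| / dim.

    The search runs in continuous space with sigmoid decoding.  An evaluator
    failure on some mask penalises that wolf with the worst fitness observed
    so far (logged) rather than aborting the run.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    config = config or GWOConfig()
    if dim == 1:
        return FeatureMask(np.array([True]))

    cache: dict[tuple, float] = {}
    observed: list[float] = []

    def objective(pos: np.ndarray) -> float:
        mask = binarize_positions(pos[None, :], config.threshold)[0]
        key = tuple(mask.bits.tolist())
        if key not in cache:
            try:
                err = float(evaluator(mask))
            except Exception as exc:  # noqa: BLE001 - wolf-level containment
                worst = max(observed) if observed else 1e6
                logger.warning("evaluator failed on mask %s (%s); penalised at %g",
                               key, exc, worst)
                return worst
            cache[key] = err
            observed.append(err)
        return cache[key] + config.lambda_sparsity * mask.selected_count / dim

    result = optimize(objective, [config.bounds] * dim, n_wolves=config.n_wolves,
                      T=config.iterations, seed=config.seed)
    return binarize_positions(result.best_position[None, :], config.threshold)[0]


# ---------------------------------------------------------------------------
# Hyperparameter tuning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamRange:
    low: float
    high: float
    log: bool = False      # search in log10 space
    integer: bool = False  # round the decoded value

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("low must be <= high")
        if self.log and self.low <= 0:
            raise ValueError("log-scale ranges need a positive lower bound")

    def internal_bounds(self) -> tuple[float, float]:
        if self.log:
            return math.log10(self.low), math.log10(self.high)
        return self.low, self.high

    def decode(self, x: float) -> float | int:
        v = 10.0 ** x if self.log else x
        v = min(max(v, self.low), self.high)
        return int(round(v)) if self.integer else float(v)


def _apply_params(spec, params: Mapping[str, float]):
    """Map decoded parameter values onto a CNNSpec."""
    from .cnn import ConvLayerSpec  # local import: cnn does not import gwo

    conv = list(spec.conv_layers)
    fields = {}
    for name, value in params.items():
        if name in ("learning_rate", "dropout_rate", "hidden_units", "batch_size", "epochs"):
            fields[name] = value
        elif name == "conv1_filters":
            conv[0] = dataclasses.replace(conv[0], filters=int(value))
        elif name == "conv2_filters":
            if len(conv) < 2:
                raise ValueError("spec has no second convolution layer")
            conv[1] = dataclasses.replace(conv[1], filters=int(value))
        else:
            raise ValueError(f"unknown tunable parameter {name!r}")
    return dataclasses.replace(spec, conv_layers=tuple(conv), **fields)


def tune_hyperparameters(space: Mapping[str, ParamRange], evaluator,
                         config: GWOConfig | None = None, base_spec=None):
    """Tune CNN hyperparameters by maximising validation accuracy.

    ``space`` names per-parameter ranges (log-scale learning rate, integer
    filter counts, ...); ``evaluator`` maps a candidate CNNSpec to its
    validation accuracy.  Returns the spec with the highest accuracy
    encountered over the whole run.  Raises if every candidate fails.
    """
    from .cnn import CNNSpec

    config = config or GWOConfig()
    if base_spec is None:
        base_spec = CNNSpec()
    names = list(space.keys())
    bounds = [space[n].internal_bounds() for n in names]

    best: dict = {"spec": None, "acc": -np.inf}
    failures = [0]

    def objective(pos: np.ndarray) -> float:
        params = {n: space[n].decode(x) for n, x in zip(names, pos)}
        spec = _apply_params(base_spec, params)
        try:
            acc = float(evaluator(spec))
        except Exception as exc:  # noqa: BLE001 - candidate-level containment
            failures[0] += 1
            logger.warning("candidate %s failed: %s", params, exc)
            return np.inf
        if acc > best["acc"]:
            best["acc"], best["spec"] = acc, spec
        return -acc

    result = optimize(objective, bounds, n_wolves=config.n_wolves,
                      T=config.iterations, seed=config.seed)
    if best["spec"] is None:
        raise RuntimeError(f"all {failures[0]} tuning candidates failed")
    del result
    return best["spec"]
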