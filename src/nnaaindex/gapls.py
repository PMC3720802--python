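"""Genetic-algorithm variable selection for PLS (GA-PLS).

Chromosomes are binary masks over descriptor columns; the fitness of a mask
is the leave-one-out Q² of a PLS model on the selected columns, with the
component count chosen by minimal LOO PRESS.  Default hyperparameters:
population 200, up to 200 generations, generation gap 0.8, crossover
probability 0.5, per-bit mutation rate 0.005.  Selection is linear-rank,
crossover is uniform (single-point available), the best chromosome is always
preserved (elitism), and runs are fully reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pls import PLSModel, fit_pls, loo_press_profile, q2_score

__all__ = ["GAConfig", "GAPLSResult", "fitness", "run"]


@dataclass
class GAConfig:
    seed: int
    population_size: int = 200
    max_generations: int = 200
    generation_gap: float = 0.8
    crossover_rate: float = 0.5
    mutation_rate: float = 0.005
    a_max: int = 3
    crossover: str = "uniform"  # or "single_point"
    stagnation_limit: int = 30

    def __post_init__(self) -> None:
        if not 0.0 <= self.generation_gap <= 1.0:
            raise ValueError("generation_gap must be in (0, 1]")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must be in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.crossover not in ("uniform", "single_point"):
            raise ValueError(f"unknown crossover {self.crossover!r}")
        if self.seed is None:
            raise ValueError("GA-PLS requires an explicit seed")


@dataclass
class GAPLSResult:
    best_mask: np.ndarray
    best_fitness: float
    selected: list[int]
    n_components: int
    history: list[dict]
    final_model: PLSModel
    n_evaluations: int


class _FitnessCache:
    """Memoized mask -> (Q², A*) evaluation."""

    def __init__(self, X: np.ndarray, y: np.ndarray, a_max: int):
        self.X = np.asarray(X, float)
        self.y = np.asarray(y, float).ravel()
        self.a_max = a_max
        self.cache: dict[bytes, tuple[float, int]] = {}
        self.n_evaluations = 0

    def __call__(self, mask: np.ndarray) -> tuple[float, int]:
        key = np.packbits(mask.astype(np.uint8)).tobytes()
        hit = self.cache.get(key)
        if hit is not None:
            return hit
        self.n_evaluations += 1
        if not mask.any():
            out = (-np.inf, 0)
        else:
            Xm = self.X[:, mask]
            press, preds = loo_press_profile(
                Xm, self.y, self.a_max, warn=False
            )
            a = int(np.argmin(press))
            out = (q2_score(self.y, preds[:, a]), a + 1)
        self.cache[key] = out
        return out


def fitness(mask, X, y, a_max: int = 3) -> float:
    """LOO Q² of a PLS model on the masked columns (A by minimal LOO PRESS).

    An empty mask gets -inf so it can never win selection.
    """
    mask = np.asarray(mask, bool)
    return _FitnessCache(X, y, a_max)(mask)[0]


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.shape[0])] = True
    return mask


def _crossover(pa: np.ndarray, pb: np.ndarray, cfg: GAConfig,
               rng: np.random.Generator):
    if rng.random() >= cfg.crossover_rate:
        return pa.copy(), pb.copy()
    if cfg.crossover == "uniform":
        pick = rng.random(pa.shape[0]) < 0.5
        ca = np.where(pick, pa, pb)
        cb = np.where(pick, pb, pa)
    else:
        cut = int(rng.integers(1, pa.shape[0]))
        ca = np.concatenate([pa[:cut], pb[cut:]])
        cb = np.concatenate([pb[:cut], pa[cut:]])
    return ca, cb


def run(X, y, config: GAConfig) -> GAPLSResult:
    """Run the GA and refit the final PLS model on the selected variables."""
    from .pls import _coerce_X

    Xa, names = _coerce_X(X)
    y = np.asarray(y, float).ravel()
    n, p = Xa.shape
    if p < 2:
        raise ValueError("GA selection needs at least 2 variables")
    rng = np.random.default_rng(config.seed)
    evaluate = _FitnessCache(Xa, y, config.a_max)

    pop = [
        _repair(rng.random(p) < 0.5, rng) for _ in range(config.population_size)
    ]
    fits = np.array([evaluate(m)[0] for m in pop])

    best_i = int(np.argmax(fits))
    best_mask = pop[best_i].copy()
    best_fit = float(fits[best_i])
    history = [{"generation": 0, "best": best_fit,
                "mean": float(np.mean(fits[np.isfinite(fits)]))}]

    n_replace = int(round(config.generation_gap * config.population_size))
    stagnant = 0
    for gen in range(1, config.max_generations + 1):
        if n_replace == 0:
            break
        order = np.argsort(fits)          # ascending: worst first
        ranks = np.empty(config.population_size)
        ranks[order] = np.arange(1, config.population_size + 1)
        probs = ranks / ranks.sum()       # linear-rank selection

        children: list[np.ndarray] = []
        while len(children) < n_replace:
            ia, ib = rng.choice(config.population_size, size=2, p=probs)
            ca, cb = _crossover(pop[ia], pop[ib], config, rng)
            for c in (ca, cb):
                c = c ^ (rng.random(p) < config.mutation_rate)
                children.append(_repair(c, rng))
        children = children[:n_replace]

        n_keep = config.population_size - n_replace
        keep_idx = list(np.argsort(fits)[::-1][:max(n_keep, 1)])
        survivors = [pop[i] for i in keep_idx]
        if n_keep == 0:
            children = children[: config.population_size - 1]  # elite slot
        pop = survivors + children
        fits = np.array([evaluate(m)[0] for m in pop])

        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_mask = pop[gen_best].copy()
            stagnant = 0
        else:
            stagnant += 1
        history.append({"generation": gen, "best": best_fit,
                        "mean": float(np.mean(fits[np.isfinite(fits)]))})
        if stagnant >= config.stagnation_limit:
            break

    q2_best, a_best = evaluate(best_mask)
    selected = np.flatnonzero(best_mask)
    final = fit_pls(Xa[:, best_mask], y, a_best,
                    variable_names=[names[j] for j in selected])
    return GAPLSResult(
        best_mask=best_mask,
        best_fitness=q2_best,
        selected=[int(j) for j in selected],
        n_components=a_best,
        history=history,
        final_model=final,
        n_evaluations=evaluate.n_evaluations,
    )
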