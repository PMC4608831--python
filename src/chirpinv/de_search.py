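"""Constrained differential evolution over the TS-model parameter box.

The five searched genes are (sigma_B, g_syn, I_bias, g_h, g_T) and the
objective is the feature-invariance score FI of the simulated neuron on the
chirp-stimulus battery.  Fitness is F_fit = exp(-FI) (lower is better).
The variant implemented here departs from canonical DE/rand/1/bin in two
ways, both part of the method: the three donor parents are drawn from a
fitness-weighted distribution p_r proportional to exp(-F_fit(r)/max_j
F_fit(j)) rather than uniformly, and box constraints are enforced by
*resampling* (re-running differentiation with three freshly drawn parents
whenever a trial gene leaves its bounds) rather than clipping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluate import ModelEvaluator

__all__ = ["Individual", "DeConfig", "select_parents", "evolve", "fit_ts_model",
           "GENE_NAMES", "DEFAULT_BOUNDS"]

log = logging.getLogger(__name__)

GENE_NAMES = ("sigma_B", "g_syn", "I_bias", "g_h", "g_T")

#: Physiological search box: ON/OFF mixing weight, maximal synaptic
#: conductance (uS), bias current (nA), h- and T-type conductances (uS).
DEFAULT_BOUNDS = {
    "sigma_B": (0.0, 1.0),
    "g_syn": (0.01, 0.3),
    "I_bias": (-25.0, 5.0),
    "g_h": (0.0, 8.0),
    "g_T": (0.0, 6.0),
}


@dataclass
class Individual:
    genes: np.ndarray
    fitness: float  # exp(-FI), in (0, 1]

    @property
    def fi(self) -> float:
        return -float(np.log(self.fitness)) + 0.0  # normalise -0.0

    def as_dict(self, names=GENE_NAMES) -> dict:
        return dict(zip(names, map(float, self.genes)))


@dataclass
class DeConfig:
    K: int = 30                 # population size
    generations: int = 50
    F: float = 0.5              # differential weight
    CR: float = 0.9             # crossover probability
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    seed: int | None = None
    max_resample: int = 20
    stall_generations: int = 15  # early stop when the best FI stops improving
    target_fi: float | None = None  # optional early stop once reached

    def __post_init__(self) -> None:
        if self.K < 4:
            raise ValueError("population size K must be >= 4")
        if not 0.0 < self.CR <= 1.0:
            raise ValueError("CR must lie in (0, 1]")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"invalid bounds for {name}")

    @property
    def lo(self) -> np.ndarray:
        return np.array([self.bounds[n][0] for n in self.bounds])

    @property
    def hi(self) -> np.ndarray:
        return np.array([self.bounds[n][1] for n in self.bounds])


def select_parents(
    fitnesses: np.ndarray, rng: np.random.Generator, exclude: int | None = None
) -> tuple[int, int, int]:
    """Three distinct donor indices, fitness-weighted.

    Selection probabilities p_r are proportional to exp(-F_fit(r) / max_j
    F_fit(j)), so lower (better) fitness means strictly higher probability;
    sampling is without replacement and excludes ``exclude``.
    """
    f = np.asarray(fitnesses, dtype=float)
    if f.size < 4:
        raise ValueError("need at least 4 individuals to select 3 donors")
    w = np.exp(-f / f.max())
    if exclude is not None:
        w = w.copy()
        w[exclude] = 0.0
    p = w / w.sum()
    idx = rng.choice(f.size, size=3, replace=False, p=p)
    return int(idx[0]), int(idx[1]), int(idx[2])


def _differentiate(
    pop: np.ndarray,
    fitness: np.ndarray,
    r: int,
    cfg: DeConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Donor vector X_r1 + F (X_r2 - X_r3) with bound resampling.

    A trial leaving the box triggers a re-draw of all three parents, up to
    ``max_resample`` times, after which the vector is clamped (logged).
    """
    lo, hi = cfg.lo, cfg.hi
    for _ in range(cfg.max_resample):
        r1, r2, r3 = select_parents(fitness, rng, exclude=r)
        trial = pop[r1] + cfg.F * (pop[r2] - pop[r3])
        if np.all((trial >= lo) & (trial <= hi)):
            return trial
    log.debug("resampling budget exhausted for target %d; clamping", r)
    return np.clip(trial, lo, hi)


def evolve(objective, cfg: DeConfig) -> dict:
    """Run the search; ``objective`` maps a gene vector to an FI score.

    Returns ``{"best": Individual, "history": per-generation best fitness,
    "population": final Individuals, "n_eval": evaluations used}``.
    Replacement is elitist (a parent is only replaced by a no-worse
    mutant), so each individual's fitness is non-increasing over
    generations.
    """
    rng = np.random.default_rng(cfg.seed)
    d = len(cfg.bounds)
    lo, hi = cfg.lo, cfg.hi
    pop = rng.uniform(lo, hi, size=(cfg.K, d))
    n_eval = 0

    def fit_of(genes: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        score = objective(genes)
        if not np.isfinite(score):
            raise RuntimeError(f"objective returned non-finite FI for {genes}")
        return float(np.exp(-score))

    fitness = np.array([fit_of(pop[r]) for r in range(cfg.K)])
    history = [float(fitness.min())]
    best_fit = fitness.min()
    stall = 0
    for gen in range(cfg.generations):
        for r in range(cfg.K):
            trial = _differentiate(pop, fitness, r, cfg, rng)
            u = rng.uniform(0.0, 1.0, size=d)
            mutant = np.where(u < cfg.CR, trial, pop[r])
            f_mut = fit_of(mutant)
            if f_mut <= fitness[r]:
                pop[r] = mutant
                fitness[r] = f_mut
        gen_best = float(fitness.min())
        history.append(gen_best)
        if gen_best < best_fit - 1e-12:
            best_fit = gen_best
            stall = 0
        else:
            stall += 1
        best_fi = -np.log(best_fit)
        log.info("generation %d: best FI = %.3f", gen + 1, best_fi)
        if cfg.target_fi is not None and best_fi >= cfg.target_fi:
            break
        if stall >= cfg.stall_generations:
            break
    i_best = int(np.argmin(fitness))
    return {
        "best": Individual(genes=pop[i_best].copy(), fitness=float(fitness[i_best])),
        "history": history,
        "population": [
            Individual(genes=pop[r].copy(), fitness=float(fitness[r]))
            for r in range(cfg.K)
        ],
        "n_eval": n_eval,
    }


def fit_ts_model(
    stimuli,
    psth_pairs,
    base_params=None,
    cfg: DeConfig | None = None,
    syn_template=None,
    n_trials: int = 5,
) -> dict:
    """Search (sigma_B, g_syn, I_bias, g_h, g_T) maximising FI on the
    stimulus battery.

    Each candidate is simulated with ``n_trials`` noisy repeats per
    stimulus; the FI objective follows the full metric pipeline (per-
    stimulus CSI from smoothed PSTHs, pooled pairwise VPD).  Returns the
    best individual with its FI, per-stimulus CSI at the optimum, and the
    generation history.
    """
    from .afferent import SynapticConfig
    from .ts_model import TsModelParams

    cfg = cfg or DeConfig()
    evaluator = ModelEvaluator(
        stimuli=stimuli,
        psth_pairs=psth_pairs,
        base_params=base_params or TsModelParams(),
        syn_template=syn_template or SynapticConfig(),
        n_trials=n_trials,
    )
    seed = 0 if cfg.seed is None else int(cfg.seed)
    counter = {"k": 0}

    def objective(genes: np.ndarray) -> float:
        counter["k"] += 1
        overrides = dict(zip(cfg.bounds.keys(), map(float, genes)))
        return evaluator.evaluate_fi(overrides, seed=seed, tag=counter["k"])

    result = evolve(objective, cfg)
    best = result["best"]
    overrides = dict(zip(cfg.bounds.keys(), map(float, best.genes)))
    final = evaluator.evaluate(overrides, seed=seed, tag=0)
    result["best_metrics"] = final
    result["best_genes"] = overrides
    return result
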