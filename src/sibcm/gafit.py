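"""Genetic-algorithm inversion of the four free model parameters.

The free parameters (omega, G, I0, sigma) are fitted by maximizing PSAC, the
correlation between the empirical PSA matrix and the PSA matrix of simulated
BOLD.  To guard against overfitting the series is split in half: the first
half yields the co-activity pattern (model construction), the second half
the PSA fitting target.  Each candidate is scored by averaging the PSA
matrices of ``n_reps`` independent simulations before correlating with the
target.  The GA uses tournament selection, blend crossover, per-gene
Gaussian mutation and single-individual elitism.  All candidates are scored
with one common set of simulation seeds derived from the master seed
(common random numbers): with per-candidate seeds the selection operator
chases lucky noise draws rather than parameter quality, because near the
optimum the fitness surface is flatter than the evaluation noise.  The fit
is exactly reproducible from the master seed.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .coactivity import CoactivityPattern, FusedRpcaOptions, extract_pattern
from .data_io import ParcellatedTimeSeries, standardize
from .dmf import DMFParameters, DivergenceError, simulate_dmf
from .hemo import HemodynamicParameters, balloon_bold
from .psa import PSAMatrix, psa_matrix, psac, subject_delay

log = logging.getLogger(__name__)

PARAM_NAMES = ("omega", "coupling_G", "I0", "sigma")

DEFAULT_BOUNDS = {
    "omega": (0.5, 1.5),
    "coupling_G": (0.0, 6.0),
    "I0": (0.25, 0.45),
    "sigma": (0.001, 0.02),
}


@dataclasses.dataclass(frozen=True)
class GAConfig:
    population_size: int = 50
    generations: int = 30
    bounds: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    crossover_rate: float = 0.8
    mutation_rate: float = 0.2
    mutation_sd_fraction: float = 0.1   # of each parameter's range
    tournament_size: int = 3
    n_reps: int = 3
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            lo, hi = self.bounds[name]
            if lo > hi:
                raise ValueError(f"bound for {name} has low > high")
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Forward-simulation settings used inside the objective."""

    duration_seconds: float
    tr_out_seconds: float
    dt_seconds: float = 0.001
    burn_in_seconds: float = 60.0
    hparams: HemodynamicParameters | None = None


@dataclasses.dataclass(frozen=True)
class FittedModel:
    best_params: DMFParameters
    best_psac: float
    generation_history: list     # (generation, best, mean) triples
    pattern: CoactivityPattern
    seeds_used: tuple
    psa_target: PSAMatrix


def split_half(ts: ParcellatedTimeSeries) -> tuple[ParcellatedTimeSeries, ParcellatedTimeSeries]:
    """First floor(T/2) samples and the remainder, metadata preserved."""
    t = ts.n_timepoints
    if t < 6:
        raise ValueError(f"need at least 6 time points to split, got {t}")
    cut = t // 2
    return ts.with_values(ts.values[:cut]), ts.with_values(ts.values[cut:])


def candidate_seeds(master_seed: int, n_reps: int) -> tuple:
    """Deterministic simulation seeds shared by all candidates (< 2**31)."""
    ss = np.random.SeedSequence(entropy=int(master_seed) & 0x7FFFFFFF,
                                spawn_key=(1,))
    return tuple(int(s) % (2 ** 31) for s in ss.generate_state(n_reps))


def objective(
    params: DMFParameters,
    pattern: CoactivityPattern,
    psa_emp: PSAMatrix,
    n_reps: int,
    seeds,
    sim: SimConfig,
) -> float:
    """PSAC between the empirical PSA and the mean PSA of n_reps simulations.

    A simulation that diverges sends the fitness to -1 (logged) so the GA
    simply discards the candidate.
    """
    if len(seeds) != n_reps:
        raise ValueError("need exactly one seed per repetition")
    acc = None
    try:
        for seed in seeds:
            traj = simulate_dmf(
                pattern, params, sim.duration_seconds + sim.burn_in_seconds,
                dt_seconds=sim.dt_seconds, seed=seed,
            )
            bold = balloon_bold(
                traj, sim.hparams, tr_out_seconds=sim.tr_out_seconds,
                burn_in_seconds=sim.burn_in_seconds,
            )
            sim_psa = psa_matrix(
                standardize(bold),
                tau=psa_emp.tau_delay, c1=psa_emp.c1, c2=psa_emp.c2,
                variant=psa_emp.variant,
            )
            acc = sim_psa.values if acc is None else acc + sim_psa.values
    except (DivergenceError, ValueError) as exc:
        log.warning("simulation failed for %s: %s", params, exc)
        return -1.0
    mean_psa = PSAMatrix(
        values=acc / n_reps, tau_delay=psa_emp.tau_delay,
        c1=psa_emp.c1, c2=psa_emp.c2, variant=psa_emp.variant,
    )
    return psac(psa_emp, mean_psa)


def _clip_to_bounds(genes: np.ndarray, bounds) -> np.ndarray:
    lo = np.array([bounds[n][0] for n in PARAM_NAMES])
    hi = np.array([bounds[n][1] for n in PARAM_NAMES])
    return np.clip(genes, lo, hi)


def _to_params(genes: np.ndarray, base: DMFParameters) -> DMFParameters:
    return base.replace(**dict(zip(PARAM_NAMES, map(float, genes))))


def fit_parameters(
    ts: ParcellatedTimeSeries,
    gacfg: GAConfig | None = None,
    window_length: int = 30,
    step: int = 10,
    rpca_opts: FusedRpcaOptions | None = None,
    base_params: DMFParameters | None = None,
    sim: SimConfig | None = None,
    psa_variant: str = "literal",
    max_lag: int = 20,
) -> FittedModel:
    """Full inversion: pattern from the first half, GA fit on the second.

    When ``sim`` is omitted the simulated duration matches the fitting half
    (PSA statistics are length-sensitive) at the empirical TR.
    """
    gacfg = gacfg or GAConfig()
    base = base_params or DMFParameters()
    first, second = split_half(ts)
    pattern, _ = extract_pattern(first, window_length, step, rpca_opts)
    target_std = standardize(second)
    tau = subject_delay(target_std, max_lag=max_lag)
    psa_emp = psa_matrix(target_std, tau=tau, variant=psa_variant)
    if sim is None:
        sim = SimConfig(
            duration_seconds=second.n_timepoints * ts.tr_seconds,
            tr_out_seconds=ts.tr_seconds,
        )

    rng = np.random.default_rng(gacfg.master_seed)
    lo = np.array([gacfg.bounds[n][0] for n in PARAM_NAMES])
    hi = np.array([gacfg.bounds[n][1] for n in PARAM_NAMES])
    span = hi - lo
    pop = lo + rng.uniform(size=(gacfg.population_size, 4)) * span

    seeds = candidate_seeds(gacfg.master_seed, gacfg.n_reps)

    def evaluate(genes: np.ndarray) -> float:
        return objective(_to_params(genes, base), pattern, psa_emp,
                         gacfg.n_reps, seeds, sim)

    fits = np.array([evaluate(ind) for ind in pop])
    best_idx = int(np.argmax(fits))
    best = (pop[best_idx].copy(), float(fits[best_idx]))
    history = [(0, float(fits.max()), float(fits.mean()))]

    for gen in range(1, gacfg.generations + 1):
        new_pop = np.empty_like(pop)
        # elitism: the incumbent survives with its recorded fitness
        new_pop[0] = best[0]
        for i in range(1, gacfg.population_size):
            contenders = rng.integers(0, gacfg.population_size,
                                      size=gacfg.tournament_size)
            p1 = pop[contenders[np.argmax(fits[contenders])]]
            contenders = rng.integers(0, gacfg.population_size,
                                      size=gacfg.tournament_size)
            p2 = pop[contenders[np.argmax(fits[contenders])]]
            child = p1.copy()
            if rng.uniform() < gacfg.crossover_rate:
                u = rng.uniform(size=4)
                child = u * p1 + (1.0 - u) * p2
            mutate = rng.uniform(size=4) < gacfg.mutation_rate
            child = child + mutate * rng.normal(size=4) * \
                gacfg.mutation_sd_fraction * span
            new_pop[i] = _clip_to_bounds(child, gacfg.bounds)
        pop = new_pop
        fits[0] = best[1]
        for i in range(1, gacfg.population_size):
            fits[i] = evaluate(pop[i])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best[1]:
            best = (pop[gen_best].copy(), float(fits[gen_best]))
        history.append((gen, float(max(fits.max(), best[1])), float(fits.mean())))

    return FittedModel(
        best_params=_to_params(best[0], base),
        best_psac=best[1],
        generation_history=history,
        pattern=pattern,
        seeds_used=seeds,
        psa_target=psa_emp,
    )
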