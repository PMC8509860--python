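"""Agent-based model of lytic phage infection with heritable resistance traits.

Generation-discrete, probabilistic model contrasting two environments:

- *unstructured*: one well-mixed population with carrying capacity K;
- *structured*: the population is split over ``n`` dead-end channels of
  small capacity (a mother-machine-like array of spatial refuges), and
  infection dynamics play out independently within each channel.

Each bacterium carries two heritable traits: a receptor-expression level
``rho`` in [0.5, 1] acting as its per-attempt infection probability, and a
binary genetic-resistance flag ``gamma`` conferring full protection.
Phages are not tracked explicitly; an infected cell converts, on average,
``R_t = R * N_sus / (N_sus + N_inf)`` uninfected cells per generation, the
realised number of attempts being Poisson.  One model step is:
infect (using start-of-step counts) -> lyse all previously infected cells
-> double the uninfected cells under the capacity constraint.

Daughters inherit ``gamma`` exactly and ``rho`` with Gaussian perturbation
(sd 0.1, clipped back to [0.5, 1]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy import stats

from refuge_phage._rng import child_rng

try:  # pragma: no cover
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


__all__ = [
    "ABMConfig",
    "Population",
    "GenerationRecord",
    "ABMResult",
    "ReceptorComparison",
    "init_population",
    "effective_R",
    "draw_secondary_infections",
    "attempt_infections",
    "replicate",
    "step",
    "run",
    "survivor_receptor_comparison",
    "records_to_frame",
]

RHO_MIN, RHO_MAX = 0.5, 1.0


@dataclass(frozen=True)
class ABMConfig:
    """Model parameters.

    Defaults are the study conditions: K = 1e6 (unstructured) or
    4e4 = 2000 channels x 20 cells (structured); R = 20 secondary
    infections per infected cell at full susceptibility; 1e4 founders of
    which 200 start infected; genetic-resistance background frequency
    5/10,000; initial rho ~ N(0.7, 0.08) and inherited rho ~ N(parent,
    0.1), both clipped to [0.5, 1].
    """

    environment_kind: str = "structured"
    n_channels: int = 2000
    channel_capacity: int = 20
    carrying_capacity: int | None = None
    R: float = 20.0
    n_initial: int = 10_000
    n_initial_infected: int = 200
    resistance_background_freq: float = 5.0e-4
    rho_init_mean: float = 0.7
    rho_init_sd: float = 0.08
    rho_inherit_sd: float = 0.1
    n_generations: int = 25
    seed: int = 0
    n_replicates: int = 20
    #: how out-of-range rho draws are handled ("clip" is the only mode;
    #: recorded so output metadata states the convention)
    rho_constraint: str = "clip"

    def __post_init__(self) -> None:
        if self.environment_kind not in ("structured", "unstructured"):
            raise ValueError("environment_kind must be 'structured' or 'unstructured'")
        if self.carrying_capacity is None:
            k = (self.n_channels * self.channel_capacity
                 if self.structured else 1_000_000)
            object.__setattr__(self, "carrying_capacity", k)
        self.validate()

    @property
    def structured(self) -> bool:
        return self.environment_kind == "structured"

    def validate(self) -> None:
        if self.structured and self.n_channels * self.channel_capacity != self.carrying_capacity:
            raise ValueError(
                "structured runs require n_channels * channel_capacity == carrying_capacity"
            )
        if not (0.0 <= self.resistance_background_freq <= 1.0):
            raise ValueError("resistance_background_freq must be in [0, 1]")
        if self.n_initial_infected > self.n_initial:
            raise ValueError("n_initial_infected cannot exceed n_initial")
        if self.n_initial > self.carrying_capacity:
            raise ValueError("n_initial exceeds the carrying capacity")
        if self.R < 0 or self.rho_init_sd < 0 or self.rho_inherit_sd < 0:
            raise ValueError("R and standard deviations must be >= 0")
        if self.n_generations < 0 or self.n_replicates < 1:
            raise ValueError("n_generations >= 0 and n_replicates >= 1 required")
        if self.rho_constraint != "clip":
            raise ValueError("only the 'clip' rho constraint is implemented")


@dataclass
class Population:
    """Vectorised population state.

    rho : per-cell infection probability in [0.5, 1].
    gamma : genetic-resistance flags (resistant cells are never infected).
    infected : cells that will lyse at the next step.
    channel : channel assignment (structured runs) or None.
    """

    rho: np.ndarray
    gamma: np.ndarray
    infected: np.ndarray
    channel: np.ndarray | None = None

    def __len__(self) -> int:
        return self.rho.shape[0]

    @property
    def n_infected(self) -> int:
        return int(self.infected.sum())

    @property
    def n_uninfected(self) -> int:
        return len(self) - self.n_infected

    @property
    def n_susceptible(self) -> int:
        """Uninfected, genetically sensitive cells."""
        return int((~self.infected & ~self.gamma).sum())

    @property
    def n_resistant(self) -> int:
        return int(self.gamma.sum())

    def subset(self, mask: np.ndarray) -> "Population":
        return Population(
            rho=self.rho[mask], gamma=self.gamma[mask], infected=self.infected[mask],
            channel=None if self.channel is None else self.channel[mask],
        )


@dataclass
class GenerationRecord:
    generation: int
    n_total: int
    n_susceptible: int
    n_infected: int
    fraction_genetic_resistant: float
    mean_rho: float
    per_channel_counts: np.ndarray | None = None


def _clip_rho(x: np.ndarray) -> np.ndarray:
    return np.clip(x, RHO_MIN, RHO_MAX)


def init_population(config: ABMConfig, rng: np.random.Generator) -> Population:
    """Draw the founder population.

    gamma flags are independent Bernoulli(resistance_background_freq);
    rho ~ N(rho_init_mean, rho_init_sd) clipped to [0.5, 1].  In the
    structured environment founders are spread uniformly at random over
    the channel slots (never exceeding channel capacity).  Exactly
    ``n_initial_infected`` genetically sensitive cells start infected
    (resistant cells are excluded from the seeding draw).
    """
    n = config.n_initial
    gamma = rng.random(n) < config.resistance_background_freq
    if config.rho_init_sd == 0:
        rho = np.full(n, float(np.clip(config.rho_init_mean, RHO_MIN, RHO_MAX)))
    else:
        rho = _clip_rho(rng.normal(config.rho_init_mean, config.rho_init_sd, n))
    infected = np.zeros(n, dtype=bool)
    sensitive = np.flatnonzero(~gamma)
    if sensitive.size < config.n_initial_infected:
        raise ValueError("not enough sensitive cells to seed the requested infections")
    seed_idx = rng.choice(sensitive, size=config.n_initial_infected, replace=False)
    infected[seed_idx] = True
    channel = None
    if config.structured:
        slots = rng.choice(
            config.n_channels * config.channel_capacity, size=n, replace=False
        )
        channel = (slots // config.channel_capacity).astype(np.int64)
    return Population(rho=rho, gamma=gamma, infected=infected, channel=channel)


def effective_R(R: float, n_sus: int, n_inf: int) -> float:
    """Susceptible-fraction-discounted secondary-infection number.

    R_t = R * N_sus / (N_sus + N_inf); defined as 0 when there are no
    hosts at all.
    """
    total = n_sus + n_inf
    if total == 0:
        return 0.0
    return R * n_sus / total


def draw_secondary_infections(R_t: float, n_inf: int, rng: np.random.Generator) -> int:
    """Total infection attempts this generation: Poisson(R_t * N_inf)."""
    if R_t < 0 or n_inf < 0:
        raise ValueError("R_t and n_inf must be >= 0")
    return int(rng.poisson(R_t * n_inf))


@njit(cache=True)
def _attempts_grouped_kernel(rho, gamma, starts, counts, s_inf, u_target, u_succ,
                             out):  # pragma: no cover - numba
    """Sequential infection attempts for each pool (channel).

    Each attempt picks a target uniformly among the pool's currently
    uninfected cells; it succeeds with probability rho unless gamma is
    set.  Successes are removed from the candidate list (swap-remove);
    failures stay available.  Surplus attempts after pool exhaustion are
    discarded.
    """
    pos = 0
    for c in range(counts.shape[0]):
        n = counts[c]
        base = starts[c]
        idx = np.empty(n, np.int64)
        for k in range(n):
            idx[k] = base + k
        m = n
        for a in range(s_inf[c]):
            if m == 0:
                break
            j = int(u_target[pos + a] * m)
            if j >= m:
                j = m - 1
            tgt = idx[j]
            if gamma[tgt] == 0 and u_succ[pos + a] < rho[tgt]:
                out[tgt] = True
                m -= 1
                idx[j] = idx[m]
        pos += s_inf[c]


def _attempts_grouped(rho: np.ndarray, gamma: np.ndarray, starts: np.ndarray,
                      counts: np.ndarray, s_inf: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    total = int(s_inf.sum())
    u_target = rng.random(total)
    u_succ = rng.random(total)
    out = np.zeros(rho.shape[0], dtype=np.bool_)
    _attempts_grouped_kernel(
        rho, gamma.astype(np.uint8), starts.astype(np.int64),
        counts.astype(np.int64), s_inf.astype(np.int64), u_target, u_succ, out,
    )
    return out


def attempt_infections(rho: np.ndarray, gamma: np.ndarray, s_inf: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Run ``s_inf`` infection attempts on one pool of uninfected cells.

    Returns a boolean mask of newly infected cells.  Targets are drawn
    uniformly among cells not yet infected this step; an attempt succeeds
    with probability ``rho`` for gamma = 0 cells and never for gamma = 1.
    An empty pool yields no infections.
    """
    n = rho.shape[0]
    if n == 0 or s_inf == 0:
        return np.zeros(n, dtype=bool)
    if s_inf < 0:
        raise ValueError("s_inf must be >= 0")
    return _attempts_grouped(
        np.ascontiguousarray(rho, dtype=np.float64),
        np.ascontiguousarray(gamma, dtype=bool),
        np.array([0]), np.array([n]), np.array([s_inf]), rng,
    )


def _capped_daughters(pop: Population, config: ABMConfig,
                      rng: np.random.Generator) -> Population:
    """Daughters of the uninfected cells, thinned to respect capacity."""
    parents = np.flatnonzero(~pop.infected)
    if parents.size == 0:
        return Population(
            rho=np.empty(0), gamma=np.empty(0, bool), infected=np.empty(0, bool),
            channel=None if pop.channel is None else np.empty(0, np.int64),
        )
    if config.rho_inherit_sd == 0:
        d_rho = pop.rho[parents].copy()
    else:
        d_rho = _clip_rho(pop.rho[parents]
                          + rng.normal(0.0, config.rho_inherit_sd, parents.size))
    d_gamma = pop.gamma[parents].copy()
    if not config.structured:
        room = config.carrying_capacity - len(pop)
        if parents.size > room:
            keep = rng.choice(parents.size, size=max(room, 0), replace=False)
            keep.sort()
            d_rho, d_gamma, parents = d_rho[keep], d_gamma[keep], parents[keep]
        return Population(rho=d_rho, gamma=d_gamma,
                          infected=np.zeros(d_rho.size, bool), channel=None)
    # structured: per-channel cap; excess daughters flushed uniformly at random
    d_chan = pop.channel[parents]
    occupied = np.bincount(pop.channel, minlength=config.n_channels)
    room = np.maximum(config.channel_capacity - occupied, 0)
    order = np.lexsort((rng.random(d_chan.size), d_chan))  # random within channel
    sorted_chan = d_chan[order]
    # rank of each daughter within its channel after the random shuffle
    n_per = np.bincount(sorted_chan, minlength=config.n_channels)
    first = np.concatenate(([0], np.cumsum(n_per)[:-1]))
    rank = np.arange(sorted_chan.size) - first[sorted_chan]
    keep_sorted = order[rank < room[sorted_chan]]
    keep_sorted.sort()
    return Population(
        rho=d_rho[keep_sorted], gamma=d_gamma[keep_sorted],
        infected=np.zeros(keep_sorted.size, bool), channel=d_chan[keep_sorted],
    )


def replicate(pop: Population, config: ABMConfig,
              rng: np.random.Generator) -> Population:
    """Double the uninfected cells subject to the capacity constraint.

    Every uninfected bacterium produces one daughter (gamma copied, rho
    perturbed); daughters in excess of the capacity -- global K in the
    unstructured environment, per-channel capacity in the structured one --
    are flushed (discarded) uniformly at random.
    """
    daughters = _capped_daughters(pop, config, rng)
    return Population(
        rho=np.concatenate([pop.rho, daughters.rho]),
        gamma=np.concatenate([pop.gamma, daughters.gamma]),
        infected=np.concatenate([pop.infected, daughters.infected]),
        channel=(None if pop.channel is None
                 else np.concatenate([pop.channel, daughters.channel])),
    )


def _record(generation: int, pop: Population, config: ABMConfig) -> GenerationRecord:
    n = len(pop)
    per_channel = None
    if config.structured and pop.channel is not None:
        per_channel = np.bincount(pop.channel, minlength=config.n_channels)
    return GenerationRecord(
        generation=generation,
        n_total=n,
        n_susceptible=pop.n_susceptible,
        n_infected=pop.n_infected,
        fraction_genetic_resistant=(pop.n_resistant / n) if n else 0.0,
        mean_rho=float(pop.rho.mean()) if n else float("nan"),
        per_channel_counts=per_channel,
    )


def step(pop: Population, config: ABMConfig,
         rng: np.random.Generator) -> tuple[Population, GenerationRecord]:
    """Advance one bacterial generation.

    Fixed order: (1) draw secondary-infection attempts per mixing pool
    from start-of-step counts and infect; (2) remove (lyse) all cells that
    entered the step infected; (3) double the remaining uninfected cells
    under capacity; (4) record the new state.
    """
    was_infected = pop.infected.copy()
    unmask = ~was_infected
    un_idx = np.flatnonzero(unmask)
    if not config.structured:
        R_t = effective_R(config.R, int(un_idx.size), int(was_infected.sum()))
        s_inf = draw_secondary_infections(R_t, int(was_infected.sum()), rng)
        newly = attempt_infections(pop.rho[un_idx], pop.gamma[un_idx], s_inf, rng)
        new_idx = un_idx[newly]
    else:
        n_inf_c = np.bincount(pop.channel[was_infected], minlength=config.n_channels)
        n_un_c = np.bincount(pop.channel[unmask], minlength=config.n_channels)
        total_c = n_inf_c + n_un_c
        with np.errstate(divide="ignore", invalid="ignore"):
            R_t_c = np.where(total_c > 0, config.R * n_un_c / np.maximum(total_c, 1), 0.0)
        s_inf_c = rng.poisson(R_t_c * n_inf_c)
        # group uninfected cells by channel for the attempts kernel
        order = np.argsort(pop.channel[un_idx], kind="stable")
        grouped = un_idx[order]
        counts = np.bincount(pop.channel[grouped], minlength=config.n_channels)
        starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
        newly_g = _attempts_grouped(
            np.ascontiguousarray(pop.rho[grouped]),
            np.ascontiguousarray(pop.gamma[grouped]),
            starts, counts, s_inf_c, rng,
        )
        new_idx = grouped[newly_g]
    pop.infected[new_idx] = True
    survivors = pop.subset(~was_infected)  # lysis of previously infected cells
    next_pop = replicate(survivors, config, rng)
    return next_pop, _record(-1, next_pop, config)  # caller sets the index


@dataclass
class ABMResult:
    config: ABMConfig
    records: list  # list over replicates of list[GenerationRecord]
    final_populations: list

    def to_frame(self):
        import pandas as pd

        rows = []
        for rep, recs in enumerate(self.records):
            for r in recs:
                rows.append(
                    dict(replicate=rep, generation=r.generation, n_total=r.n_total,
                         n_susceptible=r.n_susceptible, n_infected=r.n_infected,
                         fraction_genetic_resistant=r.fraction_genetic_resistant,
                         mean_rho=r.mean_rho)
                )
        return pd.DataFrame(rows)

    def mean_frame(self):
        df = self.to_frame()
        return df.groupby("generation", as_index=False).mean().drop(columns="replicate")


def run(config: ABMConfig) -> ABMResult:
    """Run ``n_replicates`` independent simulations of ``n_generations``.

    Replicate ``i`` uses the child stream (seed, i), so results are
    deterministic for a given config and independent across replicates.
    """
    all_records = []
    finals = []
    for rep in range(config.n_replicates):
        rng = child_rng(config.seed, rep)
        pop = init_population(config, rng)
        recs = [_record(0, pop, config)]
        for gen in range(1, config.n_generations + 1):
            pop, rec = step(pop, config, rng)
            rec.generation = gen
            recs.append(rec)
        all_records.append(recs)
        finals.append(pop)
    return ABMResult(config=config, records=all_records, final_populations=finals)


@dataclass
class ReceptorComparison:
    """Receptor levels of cells a sampled infection attempt would kill vs spare."""

    rho_killed: np.ndarray
    rho_survived: np.ndarray
    statistic: float
    p_value: float
    direction: str
    note: str = ""

    @property
    def valid(self) -> bool:
        return not np.isnan(self.p_value)


def survivor_receptor_comparison(pop: Population, n_sample: int = 200,
                                 rng: np.random.Generator | None = None) -> ReceptorComparison:
    """Sample potential infections and compare receptor levels by outcome.

    ``n_sample`` uninfected cells are drawn at random; each sampled
    attempt kills its target with probability rho (never for gamma = 1).
    Returns the rho values of killed vs spared targets and a rank-based
    location-shift test (Mann-Whitney U, two-sided).
    """
    if rng is None:
        rng = np.random.default_rng()
    candidates = np.flatnonzero(~pop.infected)
    if candidates.size == 0:
        return ReceptorComparison(np.array([]), np.array([]), float("nan"),
                                  float("nan"), "undefined", note="no uninfected cells")
    n = n_sample
    if n > candidates.size:
        warnings.warn(
            f"n_sample={n_sample} exceeds the {candidates.size} uninfected cells; "
            "sampling capped", stacklevel=2,
        )
        n = candidates.size
    chosen = rng.choice(candidates, size=n, replace=False)
    killed_mask = (~pop.gamma[chosen]) & (rng.random(n) < pop.rho[chosen])
    killed = pop.rho[chosen[killed_mask]]
    survived = pop.rho[chosen[~killed_mask]]
    if killed.size == 0 or survived.size == 0:
        return ReceptorComparison(killed, survived, float("nan"), float("nan"),
                                  "undefined", note="one outcome class is empty")
    if np.ptp(np.concatenate([killed, survived])) == 0:
        return ReceptorComparison(killed, survived, float("nan"), 1.0, "none",
                                  note="all receptor levels identical")
    u, p = stats.mannwhitneyu(killed, survived, alternative="two-sided")
    direction = ("killed>survived" if killed.mean() > survived.mean()
                 else "killed<survived")
    return ReceptorComparison(killed, survived, float(u), float(p), direction)


def records_to_frame(records: list):
    """Per-generation records -> tidy DataFrame (one replicate)."""
    import pandas as pd

    return pd.DataFrame(
        dict(generation=[r.generation for r in records],
             n_total=[r.n_total for r in records],
             n_susceptible=[r.n_susceptible for r in records],
             n_infected=[r.n_infected for r in records],
             fraction_genetic_resistant=[r.fraction_genetic_resistant for r in records],
             mean_rho=[r.mean_rho for r in records])
    )
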