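"""Ground-truthed synthetic mother-machine and well-mixed datasets.

The channel generator emulates what time-lapse imaging of a mother-machine
infection assay records: hourly snapshots of per-channel occupancy, founder
cell lengths and events (division, lysis, flush), a 24-h live/dead end
label, and the founder's initial receptor-reporter fluorescence.  The
latent dynamics run in continuous time: cells divide with exponential
waiting times, phages arrive per channel as a Poisson process, an arrival
picks a random resident cell and infects it with a probability set by the
cell's fluorescence (a logistic map -- abundant receptors make infection
more likely), infected cells lyse after a fixed delay, and cells may start
filamenting with a bell-shaped time-dependent hazard, elongate, and get
swept out of the channel.  Channel capacity is enforced by flushing excess
daughters; founders themselves are lost at a small background rate.

Every latent event is recorded in a ground-truth table so analysis-stage
estimates (fate classes, arrival rate, filamentation curve) can be checked
against what actually happened.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from refuge_phage import abm
from refuge_phage._rng import child_rng

__all__ = ["SynthParams", "SynthResult", "generate_channels", "generate_wellmixed"]


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class SynthParams:
    """Generator settings (times in hours unless noted).

    The defaults are the study conditions of the structured-environment
    assay: 200 observed channels in biological triplicate, physical
    capacity 6 cells per channel, ~30 min division time in rich medium,
    phage arrivals at 1.2 per channel per hour, lysis ~25 min after
    infection, and a filamentation hazard peaking near 7 h scaled to
    0.26.  Fluorescence is log10-normal with an order-of-magnitude
    placeholder scale (the real reporter distribution is only published
    as violin plots); the fluorescence-to-infection-probability map is a
    bounded logistic in log-fluorescence.
    """

    n_channels: int = 200
    n_replicates: int = 3
    #: probability that a channel starts with 1 vs 2 founder cells
    p_initial_occupancy_one: float = 0.5
    capacity: int = 6
    division_time_h: float = 0.5
    phage_arrival_rate: float = 1.2  # per channel per hour
    lysis_delay_min: float = 25.0
    duration_h: float = 24.0
    burst_size: int = 100  # used by the well-mixed generator
    # receptor-reporter fluorescence (log10 arbitrary units) and its
    # logistic map to per-encounter infection probability
    log_fluor_mean: float = 2.0
    log_fluor_sd: float = 0.4
    infect_midpoint: float = 2.0  # log10 units
    infect_slope: float = 5.0  # per log10 unit
    infect_min: float = 0.05
    infect_max: float = 0.95
    #: probability a lysing cell's local burst attacks each channel mate
    secondary_attack_prob: float = 0.25
    #: fraction of founders in a dormant (non-growing, phage-tolerant)
    #: persister-like state
    dormant_prob: float = 0.05
    # filamentation: per-hour onset hazard q(t) = scale * exp(-(t-peak)^2/(2 w^2));
    # filamenting cells elongate and are swept out after fil_duration_h
    fil_hazard_scale: float = 0.09
    fil_peak_time_h: float = 7.0
    fil_width_h: float = 2.0
    fil_duration_h: float = 2.0
    #: background loss rate of the founder cell itself (per hour)
    founder_flush_hazard: float = 0.002
    # vegetative cell geometry, um
    base_length_um: float = 3.0
    length_jitter_um: float = 0.4
    filament_start_length_um: float = 8.0
    filament_growth_um_h: float = 2.5
    seed: int = 0
    # well-mixed (unstructured) companion run
    wm_n_initial: int = 10_000
    wm_n_initial_infected: int = 200
    wm_resistance_freq: float = 5.0e-4
    wm_carrying_capacity: int = 1_000_000
    wm_generations: int = 40

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_initial_occupancy_one <= 1.0):
            raise ValueError("p_initial_occupancy_one must be a probability")
        for name in ("phage_arrival_rate", "fil_hazard_scale", "founder_flush_hazard",
                     "division_time_h", "lysis_delay_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.infect_min <= self.infect_max <= 1.0):
            raise ValueError("infection probabilities must satisfy 0 <= min <= max <= 1")
        if self.capacity < 2 or self.n_channels < 1 or self.n_replicates < 1:
            raise ValueError("capacity >= 2 and at least one channel/replicate required")

    def infection_probability(self, log_fluor: float) -> float:
        """Monotone bounded map from log10 fluorescence to infection probability."""
        s = _expit(self.infect_slope * (log_fluor - self.infect_midpoint))
        return self.infect_min + (self.infect_max - self.infect_min) * s

    def filament_hazard(self, t_h: float) -> float:
        return self.fil_hazard_scale * math.exp(
            -((t_h - self.fil_peak_time_h) ** 2) / (2.0 * self.fil_width_h**2)
        )


@dataclass
class SynthResult:
    """Generated dataset: hourly tidy table, per-founder ground truth,
    per-event phage arrivals, and per-time latent filamenting fractions."""

    tidy: pd.DataFrame
    truth: pd.DataFrame
    arrivals: pd.DataFrame
    latent_filament: pd.DataFrame
    params: SynthParams


class _Cell:
    __slots__ = ("cid", "founder", "p_inf", "dormant", "infected_at", "fil_start",
                 "length0")

    def __init__(self, cid, founder, p_inf, length0, dormant=False):
        self.cid = cid
        self.founder = founder
        self.p_inf = p_inf
        self.dormant = dormant
        self.infected_at = None
        self.fil_start = None
        self.length0 = length0


def _simulate_channel(params: SynthParams, rng: np.random.Generator,
                      rep: int, chan: int, founder_rows: list, tidy_rows: list,
                      arrival_rows: list, fil_counts: np.ndarray) -> None:
    T = params.duration_h
    lysis_delay = params.lysis_delay_min / 60.0
    n_found = 1 if rng.random() < params.p_initial_occupancy_one else 2
    cells: list[_Cell] = []
    founders: dict[int, dict] = {}
    counter = 0
    heap: list = []
    tick = 0

    def push(t, kind, payload=None):
        nonlocal tick
        heapq.heappush(heap, (t, tick, kind, payload))
        tick += 1

    for i in range(n_found):
        logf = rng.normal(params.log_fluor_mean, params.log_fluor_sd)
        dormant = rng.random() < params.dormant_prob
        cell = _Cell(i, True, params.infection_probability(logf),
                     params.base_length_um + rng.normal(0, params.length_jitter_um),
                     dormant=dormant)
        cells.append(cell)
        founders[i] = dict(
            cell_id=i, gfp_t0=10.0**logf, log_fluor=logf, p_inf=cell.p_inf,
            dormant=dormant, n_divisions=0, lysis_time=None, flushed=False,
            filamented=False, alive=True, present=True, pending_events=[],
        )
        counter += 1
        if not dormant:
            push(rng.exponential(params.division_time_h), "division", cell)
        if params.founder_flush_hazard > 0:
            t_flush = rng.exponential(1.0 / params.founder_flush_hazard)
            if t_flush < T:
                push(t_flush, "founder_flush", cell)

    # phage arrivals: homogeneous Poisson process on [0, T]
    n_arr = rng.poisson(params.phage_arrival_rate * T)
    for t in np.sort(rng.uniform(0.0, T, n_arr)):
        push(float(t), "arrival", None)
    for h in range(1, int(T) + 1):
        push(float(h), "hour", h)
    push(0.0, "hour", 0)

    def remove_cell(cell: _Cell) -> None:
        cells.remove(cell)

    def emit_snapshot(h: int) -> None:
        occupancy = len(cells)
        present_f = {c.cid: c for c in cells if c.founder}
        for fid, rec in founders.items():
            length = np.nan
            if fid in present_f:
                c = present_f[fid]
                if c.fil_start is not None:
                    length = (params.filament_start_length_um
                              + params.filament_growth_um_h * (h - c.fil_start))
                else:
                    length = max(1.5, params.base_length_um
                                 + rng.normal(0, params.length_jitter_um))
            events = ";".join(rec["pending_events"])
            rec["pending_events"] = []
            tidy_rows.append((rep, chan, f"r{rep}c{chan}f{fid}", h,
                              length, occupancy, events if events else None,
                              None, rec["gfp_t0"]))
        # latent filamenting fraction among *present founders*, i.e. the
        # same population the analysis-stage curve can observe
        n_fil = sum(1 for c in cells if c.founder and c.fil_start is not None)
        fil_counts[h, 0] += n_fil
        fil_counts[h, 1] += len(present_f)

    while heap:
        t, _, kind, payload = heapq.heappop(heap)
        if t > T:
            break
        if kind == "hour":
            h = payload
            # filamentation onset check precedes the snapshot so an
            # elongated cell is visible from its onset hour
            if h > 0:
                q = params.filament_hazard(float(h))
                for c in list(cells):
                    if (c.fil_start is None and c.infected_at is None
                            and not c.dormant and q > 0):
                        if rng.random() < q:
                            c.fil_start = float(h)
                            if c.founder:
                                founders[c.cid]["filamented"] = True
                            push(h + params.fil_duration_h, "fil_sweep", c)
            emit_snapshot(h)
        elif kind == "arrival":
            arrival_rows.append((rep, chan, t))
            if cells:
                target = cells[int(rng.random() * len(cells))]
                if (target.infected_at is None and target.fil_start is None
                        and not target.dormant and rng.random() < target.p_inf):
                    target.infected_at = t
                    push(t + lysis_delay, "lysis", target)
        elif kind == "lysis":
            cell = payload
            if cell in cells:
                remove_cell(cell)
                if cell.founder:
                    rec = founders[cell.cid]
                    rec["lysis_time"] = t
                    rec["alive"] = False
                    rec["present"] = False
                    rec["pending_events"].append("lysis")
                # local burst: released phage attack the remaining channel
                # mates, each with probability secondary_attack_prob
                for mate in list(cells):
                    if (mate.infected_at is None and mate.fil_start is None
                            and not mate.dormant
                            and rng.random() < params.secondary_attack_prob
                            and rng.random() < mate.p_inf):
                        mate.infected_at = t
                        push(t + lysis_delay, "lysis", mate)
        elif kind == "division":
            cell = payload
            if cell not in cells or cell.infected_at is not None or cell.fil_start is not None:
                continue
            if cell.founder:
                founders[cell.cid]["n_divisions"] += 1
                founders[cell.cid]["pending_events"].append("division")
            daughter = _Cell(counter, False, cell.p_inf,
                             params.base_length_um + rng.normal(0, params.length_jitter_um))
            counter += 1
            cells.append(daughter)
            push(t + rng.exponential(params.division_time_h), "division", daughter)
            push(t + rng.exponential(params.division_time_h), "division", cell)
            if len(cells) > params.capacity:
                # excess pushed out of the open channel end; the founder at
                # the dead end is shielded (it has its own loss hazard)
                nonf = [c for c in cells if not c.founder]
                victim = nonf[int(rng.random() * len(nonf))]
                remove_cell(victim)
        elif kind == "founder_flush":
            cell = payload
            if cell in cells and cell.infected_at is None:
                remove_cell(cell)
                rec = founders[cell.cid]
                rec["flushed"] = True
                rec["present"] = False
                rec["pending_events"].append("flush")
        elif kind == "fil_sweep":
            cell = payload
            if cell in cells:
                remove_cell(cell)
                if cell.founder:
                    founders[cell.cid]["present"] = False
                    founders[cell.cid]["pending_events"].append("flush")

    for fid, rec in founders.items():
        if rec["lysis_time"] is not None:
            fate = "lysed"
            end = "dead"
        elif rec["filamented"]:
            fate = "filamented"
            end = "live" if rec["present"] else "absent"
        elif rec["flushed"] or not rec["present"]:
            fate = "flushed"
            end = "absent"
        else:
            fate = "survived_growing" if rec["n_divisions"] >= 1 else "survived_nongrowing"
            end = "live"
        if rec["filamented"] and rec["lysis_time"] is None:
            fate = "filamented"
        founder_rows.append(dict(
            replicate_id=rep, channel_id=chan, cell_id=f"r{rep}c{chan}f{fid}",
            gfp_t0=rec["gfp_t0"], log_fluor=rec["log_fluor"], p_inf=rec["p_inf"],
            dormant=rec["dormant"], n_divisions=rec["n_divisions"],
            lysis_time_h=rec["lysis_time"] if rec["lysis_time"] is not None else np.nan,
            flushed=rec["flushed"], filamented=rec["filamented"],
            fate_true=fate, end_label=end,
        ))


def generate_channels(params: SynthParams,
                      rng: np.random.Generator | None = None) -> SynthResult:
    """Generate the structured-environment dataset.

    Returns a :class:`SynthResult`; ``tidy`` follows the trajectory-
    analysis input schema exactly and ``truth`` holds one row per founder
    with the latent fate, division count, lysis time and infection
    probability.  The tidy table's end labels are filled from the latent
    24-h state (live / dead / absent), mirroring what staining reports.
    """
    base_seed = params.seed if rng is None else int(rng.integers(0, 2**31 - 1))
    founder_rows: list[dict] = []
    tidy_rows: list[tuple] = []
    arrival_rows: list[tuple] = []
    n_hours = int(params.duration_h) + 1
    fil_counts = np.zeros((n_hours, 2))
    for rep in range(params.n_replicates):
        for chan in range(params.n_channels):
            crng = child_rng(base_seed, rep, chan)
            _simulate_channel(params, crng, rep, chan, founder_rows, tidy_rows,
                              arrival_rows, fil_counts)
    tidy = pd.DataFrame(
        tidy_rows,
        columns=["replicate_id", "channel_id", "cell_id", "time_h", "length_um",
                 "occupancy", "event", "end_label", "gfp_t0"],
    )
    truth = pd.DataFrame(founder_rows)
    # paint the latent end label onto every row of the founder
    label_map = truth.set_index("cell_id")["end_label"]
    tidy["end_label"] = tidy["cell_id"].map(label_map)
    arrivals = pd.DataFrame(arrival_rows, columns=["replicate_id", "channel_id", "time_h"])
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(fil_counts[:, 1] > 0, fil_counts[:, 0] / np.maximum(fil_counts[:, 1], 1), np.nan)
    latent_filament = pd.DataFrame(dict(time_h=np.arange(n_hours, dtype=float),
                                        latent_fraction=frac,
                                        n_filamenting=fil_counts[:, 0],
                                        n_live=fil_counts[:, 1]))
    return SynthResult(tidy=tidy, truth=truth, arrivals=arrivals,
                       latent_filament=latent_filament, params=params)


def generate_wellmixed(params: SynthParams,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Well-mixed population and free-phage time series.

    Bacterial dynamics delegate to the unstructured agent-based model; a
    free-phage count is book-kept on top: each lysing cell releases
    ``burst_size`` virions (no decay, no adsorption losses).  Shows
    collapse followed by regrowth when a genetically resistant founder is
    present, extinction of the sensitive population otherwise.
    """
    seed = params.seed if rng is None else int(rng.integers(0, 2**31 - 1))
    cfg = abm.ABMConfig(
        environment_kind="unstructured",
        n_initial=params.wm_n_initial,
        n_initial_infected=params.wm_n_initial_infected,
        resistance_background_freq=params.wm_resistance_freq,
        carrying_capacity=params.wm_carrying_capacity,
        n_generations=params.wm_generations,
        n_replicates=1,
        seed=seed,
    )
    recs = abm.run(cfg).records[0]
    phage = [float(cfg.n_initial_infected)]  # proxy: initial infecting phage
    for prev, _cur in zip(recs[:-1], recs[1:]):
        phage.append(phage[-1] + params.burst_size * prev.n_infected)
    return pd.DataFrame(dict(
        generation=[r.generation for r in recs],
        n_bacteria=[r.n_total for r in recs],
        n_infected=[r.n_infected for r in recs],
        fraction_genetic_resistant=[r.fraction_genetic_resistant for r in recs],
        n_phage=phage,
    ))
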