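"""Brownian phage transport in the mother-machine unit cell.

Phages are non-interacting point particles that diffuse (isotropic Gaussian
steps, diffusivity ``D``) and are advected by the steady axial flow of the
main channel.  The domain is periodic along the flow axis; walls reflect
specularly.  A particle whose end-of-step position moves from the main
channel into a side channel logs an *entry* event; moving back logs an
*exit*.  Per-refuge arrival rates, residence times and phage-free-fraction
curves are derived from the event log.

The stepping kernel is compiled with numba when available (pure-Python
fallback otherwise, usable only for small problems).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from refuge_phage.flow import FlowField, Geometry, solve_flow

try:  # pragma: no cover - exercised implicitly
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
    "ParticleEnsemble",
    "ArrivalRate",
    "ResidenceSummary",
    "simulate_particles",
    "arrival_rate",
    "residence_time_distribution",
    "phage_free_fraction",
    "empirical_free_fraction",
]

#: entry/exit codes in the event log
ENTRY, EXIT = 0, 1


@dataclass
class ParticleEnsemble:
    """Result of a particle simulation.

    positions : final (n, 3) positions, um.
    displacements : cumulative true displacement per particle (valid as a
        free-diffusion diagnostic only while no wall was hit).
    events : structured record of side-channel entries/exits with columns
        ``particle``, ``channel``, ``time`` (s) and ``kind`` (0 entry,
        1 exit).
    """

    geometry: Geometry
    n_particles: int
    duration: float
    dt: float
    D: float
    positions: np.ndarray
    displacements: np.ndarray
    events: np.ndarray  # structured: particle, channel, time, kind
    flow_rate: float = 0.0

    @property
    def duration_h(self) -> float:
        return self.duration / 3600.0

    @property
    def entries(self) -> np.ndarray:
        return self.events[self.events["kind"] == ENTRY]

    @property
    def exits(self) -> np.ndarray:
        return self.events[self.events["kind"] == EXIT]


_EVENT_DTYPE = np.dtype(
    [("particle", np.int64), ("channel", np.int64), ("time", np.float64), ("kind", np.int8)]
)


@njit(cache=True)
def _step_kernel(pos, state, disp, L, W, H, side_hw, side_h, side_len, xc,
                 ux, hgrid, sigma, dt, n_steps, seed,
                 ev_p, ev_c, ev_t, ev_k, advect):  # pragma: no cover - numba
    np.random.seed(seed)
    n = pos.shape[0]
    ny = ux.shape[0] - 1
    nz = ux.shape[1] - 1
    n_ev = 0
    max_ev = ev_p.shape[0]
    nch = xc.shape[0]
    for step in range(n_steps):
        t = (step + 1) * dt
        for i in range(n):
            x = pos[i, 0]
            y = pos[i, 1]
            z = pos[i, 2]
            gx = sigma * np.random.standard_normal()
            gy = sigma * np.random.standard_normal()
            gz = sigma * np.random.standard_normal()
            if state[i] < 0:
                # main channel: advect + diffuse
                u = 0.0
                if advect:
                    fy = y / hgrid
                    fz = z / hgrid
                    iy = int(fy)
                    iz = int(fz)
                    if iy > ny - 1:
                        iy = ny - 1
                    if iz > nz - 1:
                        iz = nz - 1
                    ty = fy - iy
                    tz = fz - iz
                    u = (ux[iy, iz] * (1 - ty) * (1 - tz)
                         + ux[iy + 1, iz] * ty * (1 - tz)
                         + ux[iy, iz + 1] * (1 - ty) * tz
                         + ux[iy + 1, iz + 1] * ty * tz)
                dx = u * dt + gx
                xn = x + dx
                yn = y + gy
                zn = z + gz
                disp[i, 0] += dx
                disp[i, 1] += gy
                disp[i, 2] += gz
                # periodic wrap along the flow axis
                xn = xn % L
                # floor/ceiling
                if zn < 0.0:
                    zn = -zn
                elif zn > H:
                    zn = 2.0 * H - zn
                if yn > W:
                    yn = 2.0 * W - yn
                if yn < 0.0:
                    # candidate side-channel entry through the y=0 wall
                    entered = -1
                    if zn <= side_h and yn >= -side_len:
                        for c in range(nch):
                            if abs(xn - xc[c]) <= side_hw:
                                entered = c
                                break
                    if entered >= 0:
                        state[i] = entered
                        if n_ev < max_ev:
                            ev_p[n_ev] = i
                            ev_c[n_ev] = entered
                            ev_t[n_ev] = t
                            ev_k[n_ev] = 0
                        n_ev += 1
                    else:
                        yn = -yn
                pos[i, 0] = xn
                pos[i, 1] = yn
                pos[i, 2] = zn
            else:
                # inside dead-end side channel: diffusion only
                c = state[i]
                xn = x + gx
                yn = y + gy
                zn = z + gz
                disp[i, 0] += gx
                disp[i, 1] += gy
                disp[i, 2] += gz
                lo = xc[c] - side_hw
                hi = xc[c] + side_hw
                if xn < lo:
                    xn = 2.0 * lo - xn
                elif xn > hi:
                    xn = 2.0 * hi - xn
                if zn < 0.0:
                    zn = -zn
                elif zn > side_h:
                    zn = 2.0 * side_h - zn
                if yn < -side_len:
                    yn = -2.0 * side_len - yn
                if yn > 0.0:
                    # exit into the main channel
                    state[i] = -1
                    if n_ev < max_ev:
                        ev_p[n_ev] = i
                        ev_c[n_ev] = c
                        ev_t[n_ev] = t
                        ev_k[n_ev] = 1
                    n_ev += 1
                pos[i, 0] = xn
                pos[i, 1] = yn
                pos[i, 2] = zn
    return n_ev


def _initial_positions(geometry: Geometry, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform initial positions over the main-channel fluid volume."""
    pos = np.empty((n, 3))
    pos[:, 0] = rng.uniform(0.0, geometry.unit_cell_length, n)
    pos[:, 1] = rng.uniform(0.0, geometry.main_width, n)
    pos[:, 2] = rng.uniform(0.0, geometry.main_height, n)
    return pos


def simulate_particles(
    geometry: Geometry,
    flow: FlowField | None,
    n_particles: int,
    duration: float,
    dt: float = 5e-3,
    D: float = 4.0,
    rng: np.random.Generator | int | None = None,
    max_events_per_particle_hour: float = 200.0,
) -> ParticleEnsemble:
    """Simulate Brownian point particles in the unit cell.

    Parameters
    ----------
    flow : FlowField or None
        ``None`` (or a zero-rate field) disables advection.
    duration : simulated time, s.
    dt : timestep, s.  The rms diffusive step sqrt(2 D dt) should stay at
        or below the ~0.2 um positional accuracy the geometry resolves.
    D : particle diffusivity, um^2/s (4 for a ~100 nm phage-sized particle).
    rng : Generator or integer seed; drives both the initial positions and
        the in-kernel noise stream.

    Returns a :class:`ParticleEnsemble` with final positions and the
    entry/exit event log.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    rms = math.sqrt(2.0 * D * dt)
    if rms > 2.0 * geometry.side_width:
        raise ValueError(
            f"dt too coarse: rms diffusive step {rms:.3g} um exceeds the "
            f"side-channel width {geometry.side_width} um"
        )
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    n_steps = int(round(duration / dt))
    pos = _initial_positions(geometry, n_particles, rng)
    state = np.full(n_particles, -1, dtype=np.int64)
    disp = np.zeros((n_particles, 3))
    max_ev = int(n_particles * (duration / 3600.0) * max_events_per_particle_hour) + 1000
    ev_p = np.empty(max_ev, dtype=np.int64)
    ev_c = np.empty(max_ev, dtype=np.int64)
    ev_t = np.empty(max_ev, dtype=np.float64)
    ev_k = np.empty(max_ev, dtype=np.int8)

    advect = flow is not None and flow.flow_rate != 0.0
    if advect:
        ux = np.ascontiguousarray(flow.ux, dtype=np.float64)
        hgrid = float(flow.spacing)
    else:
        ux = np.zeros((2, 2))
        hgrid = max(geometry.main_width, geometry.main_height)

    kernel_seed = int(rng.integers(0, 2**31 - 1))
    n_ev = _step_kernel(
        pos, state, disp,
        float(geometry.unit_cell_length), float(geometry.main_width),
        float(geometry.main_height), float(geometry.side_width / 2.0),
        float(geometry.side_height), float(geometry.side_length),
        np.asarray(geometry.side_centers_x, dtype=np.float64),
        ux, hgrid, float(rms), float(dt), n_steps, kernel_seed,
        ev_p, ev_c, ev_t, ev_k, advect,
    )
    if n_ev > max_ev:
        raise RuntimeError(
            f"event buffer overflow ({n_ev} > {max_ev}); raise "
            "max_events_per_particle_hour"
        )
    events = np.empty(n_ev, dtype=_EVENT_DTYPE)
    events["particle"] = ev_p[:n_ev]
    events["channel"] = ev_c[:n_ev]
    events["time"] = ev_t[:n_ev]
    events["kind"] = ev_k[:n_ev]
    _check_positions(geometry, pos, state)
    return ParticleEnsemble(
        geometry=geometry, n_particles=n_particles, duration=duration, dt=dt,
        D=D, positions=pos, displacements=disp, events=events,
        flow_rate=flow.flow_rate if flow is not None else 0.0,
    )


def _check_positions(geometry: Geometry, pos: np.ndarray, state: np.ndarray) -> None:
    """Bug guard: every particle must sit inside the fluid domain."""
    g = geometry
    in_main = state < 0
    ok_main = (
        (pos[in_main, 0] >= 0) & (pos[in_main, 0] <= g.unit_cell_length)
        & (pos[in_main, 1] >= 0) & (pos[in_main, 1] <= g.main_width)
        & (pos[in_main, 2] >= 0) & (pos[in_main, 2] <= g.main_height)
    )
    if not np.all(ok_main):
        raise RuntimeError("particle escaped the main-channel fluid domain")
    side = ~in_main
    if np.any(side):
        xc = g.side_centers_x[state[side]]
        ok_side = (
            (np.abs(pos[side, 0] - xc) <= g.side_width / 2 + 1e-9)
            & (pos[side, 1] >= -g.side_length - 1e-9) & (pos[side, 1] <= 1e-6)
            & (pos[side, 2] >= -1e-9) & (pos[side, 2] <= g.side_height + 1e-9)
        )
        if not np.all(ok_side):
            raise RuntimeError("particle escaped a side-channel fluid domain")


@dataclass
class ArrivalRate:
    """Per-refuge arrival rate normalised to a bulk concentration.

    rate : particles per channel per hour at ``bulk_concentration``.
    se : Monte-Carlo standard error of ``rate`` (particle-level bootstrap
        of the entry counts).
    entries_per_particle_per_hour : raw per-simulated-particle entry rate
        summed over all side channels of the unit cell.
    expected_particles_in_cell : bulk_concentration x unit-cell fluid
        volume -- the concentration normalisation factor.
    """

    rate: float
    se: float
    entries_per_particle_per_hour: float
    bulk_concentration: float
    expected_particles_in_cell: float
    n_entries: int
    n_particles: int
    duration_h: float
    mode: str = "per_visit"


def arrival_rate(
    ensemble: ParticleEnsemble,
    bulk_concentration: float,
    mode: str = "per_visit",
) -> ArrivalRate:
    """Particles reaching each refuge per hour at a bulk concentration.

    ``mode="per_visit"`` counts every side-channel entry; ``"first_visit"``
    counts only each particle's first entry into each channel (repeat
    visits by the same particle deduplicated).

    The simulated entries-per-particle-per-hour are rescaled by the
    expected number of particles in the unit cell at the target
    concentration and divided by the number of side channels:

        rate = (entries / (n_particles * T_h)) * C * V_fluid / n_side
    """
    if bulk_concentration < 0:
        raise ValueError("bulk_concentration must be >= 0")
    if ensemble.duration <= 0:
        raise ValueError("zero simulated time")
    entries = ensemble.entries
    if mode == "per_visit":
        counts = np.bincount(entries["particle"], minlength=ensemble.n_particles)
    elif mode == "first_visit":
        pairs = set(zip(entries["particle"].tolist(), entries["channel"].tolist()))
        counts = np.zeros(ensemble.n_particles, dtype=np.int64)
        for p, _ in pairs:
            counts[p] += 1
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    g = ensemble.geometry
    t_h = ensemble.duration_h
    expected = bulk_concentration * g.fluid_volume / 1.0e12  # particles in cell
    per_particle = counts / t_h  # entries per particle-hour
    epph = float(per_particle.mean())
    scale = expected / g.n_side
    se = float(per_particle.std(ddof=1) / math.sqrt(len(counts))) if len(counts) > 1 else float("nan")
    return ArrivalRate(
        rate=epph * scale,
        se=se * scale,
        entries_per_particle_per_hour=epph,
        bulk_concentration=bulk_concentration,
        expected_particles_in_cell=expected,
        n_entries=int(counts.sum()),
        n_particles=ensemble.n_particles,
        duration_h=t_h,
        mode=mode,
    )


@dataclass
class ResidenceSummary:
    times: np.ndarray
    median: float
    q1: float
    q3: float
    n_visits: int


def residence_time_distribution(ensemble: ParticleEnsemble) -> ResidenceSummary:
    """Per-visit residence times (entry-to-exit) inside the refuges.

    Visits still open at the end of the simulation are censored and
    dropped.
    """
    ev = np.sort(ensemble.events, order="time")
    open_entry: dict[tuple[int, int], float] = {}
    times = []
    for rec in ev:
        key = (int(rec["particle"]), int(rec["channel"]))
        if rec["kind"] == ENTRY:
            open_entry[key] = float(rec["time"])
        else:
            t0 = open_entry.pop(key, None)
            if t0 is not None:
                times.append(float(rec["time"]) - t0)
    if not times:
        return ResidenceSummary(np.array([]), float("nan"), float("nan"), float("nan"), 0)
    arr = np.array(times)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return ResidenceSummary(arr, float(med), float(q1), float(q3), len(arr))


def phage_free_fraction(
    rate_per_channel_h: float,
    concentrations: np.ndarray,
    t_grid_h: np.ndarray,
    reference_concentration: float = 1.0e7,
) -> dict[float, np.ndarray]:
    """Fraction of refuges not yet reached by any phage, per concentration.

    First arrivals per refuge are a Poisson process whose rate scales
    linearly with bulk concentration from the simulated reference:
    ``lambda(C) = rate_per_channel_h * C / reference_concentration`` and
    ``fraction_free(t) = exp(-lambda(C) * t)``.
    """
    t = np.asarray(t_grid_h, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    if rate_per_channel_h <= 0:
        raise ValueError("reference rate must be > 0")
    out: dict[float, np.ndarray] = {}
    for c in np.atleast_1d(np.asarray(concentrations, dtype=float)):
        lam = rate_per_channel_h * c / reference_concentration
        out[float(c)] = np.exp(-lam * t)
    return out


def empirical_free_fraction(first_arrival_times_s: np.ndarray, t_grid_h: np.ndarray,
                            n_refuges: int | None = None) -> np.ndarray:
    """Empirical phage-free fraction from simulated first-arrival times.

    ``first_arrival_times_s`` holds one first-entry time per refuge that
    was reached; refuges never reached are accounted for via ``n_refuges``
    (defaults to the number of supplied times).
    """
    t = np.asarray(t_grid_h, dtype=float) * 3600.0
    if t.size == 0:
        raise ValueError("empty time grid")
    arr = np.asarray(first_arrival_times_s, dtype=float)
    n = n_refuges if n_refuges is not None else arr.size
    if n < 1:
        raise ValueError("need at least one refuge")
    return np.array([(n - np.sum(arr <= ti)) / n for ti in t])
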