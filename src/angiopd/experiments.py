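"""Treatment schedules, endpoint metrics, and the in-silico experiment drivers.

Clinical dosing follows 9-week cycles with 3-week continuous windows:

* S1 — anti-PD-1 and anti-VEGF together in weeks 1-3;
* S2 — anti-PD-1 in weeks 1-3, anti-VEGF in weeks 4-6 (non-overlapping);
* S3 — anti-VEGF in weeks 1-3, anti-PD-1 in weeks 4-6.

Cycles repeat until the endpoint or the horizon.  The endpoint T_crit is the
first time the tumor volume drops to 5% of its value at treatment start.
Mouse regimens dose both drugs continuously from day 0 (10- or 30-day
courses) and are read out at day 30.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np

from .geometry import RadialGrid
from .params import ParameterSet, human_parameters, mouse_parameters
from .solver import SimulationResult, SolverSettings, initial_state, simulate

__all__ = [
    "Schedule", "EfficacyMap", "schedule_s1", "schedule_s2", "schedule_s3",
    "continuous_schedule", "dosing_indicator", "time_to_reduction",
    "NOT_REACHED", "run_schedule_experiment", "efficacy_map",
    "mouse_regimens", "equilibrated_state", "control_run",
]

NOT_REACHED = float("inf")

WEEK = 7.0


@dataclass(frozen=True)
class Schedule:
    """Dosing protocol: per-cycle on-windows (days, half-open) per drug.

    ``gamma_A``/``gamma_B`` are the source rates (g/cm^3/day) of anti-PD-1
    and anti-VEGF while their indicator is on.
    """

    organism: str = "human"
    gamma_A: float = 0.0
    gamma_B: float = 0.0
    cycle_days: float = 9 * WEEK
    windows_A: tuple[tuple[float, float], ...] = ()
    windows_B: tuple[tuple[float, float], ...] = ()
    perfusion_mode: str = "blocking"
    horizon: float = 70 * WEEK
    label: str = ""

    def __post_init__(self):
        if self.gamma_A < 0 or self.gamma_B < 0:
            raise ValueError("dose rates must be non-negative")
        for w in (*self.windows_A, *self.windows_B):
            if not (0.0 <= w[0] < w[1] <= self.cycle_days):
                raise ValueError(f"window {w} outside the cycle")
        if self.perfusion_mode not in ("blocking", "enhancing"):
            raise ValueError(f"unknown perfusion mode {self.perfusion_mode!r}")

    def dosing_indicator(self, t: float) -> tuple[float, float]:
        """(I_A, I_B) in {0,1}^2 at time t (periodic, half-open windows)."""
        if t < 0:
            raise ValueError("t must be non-negative")
        tc = t % self.cycle_days
        I_A = float(any(a <= tc < b for a, b in self.windows_A))
        I_B = float(any(a <= tc < b for a, b in self.windows_B))
        return I_A, I_B

    def switch_times(self, horizon: float) -> list[float]:
        """All indicator discontinuities in (0, horizon]."""
        edges = sorted({e for w in (*self.windows_A, *self.windows_B) for e in w})
        out = []
        k = 0
        while k * self.cycle_days < horizon:
            for e in edges:
                s = k * self.cycle_days + e
                if 0.0 < s <= horizon:
                    out.append(s)
            k += 1
        return out


def dosing_indicator(schedule: Schedule, t: float) -> tuple[float, float]:
    """Module-level alias of :meth:`Schedule.dosing_indicator`."""
    return schedule.dosing_indicator(t)


def _clinical(windows_A, windows_B, gamma_B, gamma_A, organism, mode, label):
    return Schedule(organism=organism, gamma_A=gamma_A, gamma_B=gamma_B,
                    windows_A=windows_A, windows_B=windows_B,
                    perfusion_mode=mode, label=label)


def schedule_s1(gamma_B: float, gamma_A: float, organism: str = "human",
                perfusion_mode: str = "blocking") -> Schedule:
    """Both drugs simultaneously, weeks 1-3 of each 9-week cycle."""
    w = ((0.0, 3 * WEEK),)
    return _clinical(w, w, gamma_B, gamma_A, organism, perfusion_mode, "S1")


def schedule_s2(gamma_B: float, gamma_A: float, organism: str = "human",
                perfusion_mode: str = "blocking") -> Schedule:
    """Anti-PD-1 weeks 1-3, anti-VEGF weeks 4-6 (non-overlapping)."""
    return _clinical(((0.0, 3 * WEEK),), ((3 * WEEK, 6 * WEEK),),
                     gamma_B, gamma_A, organism, perfusion_mode, "S2")


def schedule_s3(gamma_B: float, gamma_A: float, organism: str = "human",
                perfusion_mode: str = "blocking") -> Schedule:
    """Anti-VEGF weeks 1-3, anti-PD-1 weeks 4-6 (non-overlapping)."""
    return _clinical(((3 * WEEK, 6 * WEEK),), ((0.0, 3 * WEEK),),
                     gamma_B, gamma_A, organism, perfusion_mode, "S3")


SCHEDULE_BUILDERS = {"s1": schedule_s1, "s2": schedule_s2, "s3": schedule_s3}


def continuous_schedule(gamma_B: float, gamma_A: float, days: float,
                        organism: str = "mouse", horizon: float = 30.0,
                        perfusion_mode: str = "blocking") -> Schedule:
    """Mouse-style regimen: each nonzero drug given continuously from day 0
    for ``days`` days, then stopped (no cycling within the horizon)."""
    cycle = max(horizon, days) + 1.0
    wA = ((0.0, days),) if gamma_A > 0 else ()
    wB = ((0.0, days),) if gamma_B > 0 else ()
    return Schedule(organism=organism, gamma_A=gamma_A, gamma_B=gamma_B,
                    cycle_days=cycle, windows_A=wA, windows_B=wB,
                    perfusion_mode=perfusion_mode, horizon=horizon,
                    label=f"continuous-{days:g}d")


def time_to_reduction(result: SimulationResult, fraction: float = 0.95) -> float:
    """First time (weeks) the tumor volume falls below (1-fraction) of its
    initial value, linearly interpolated between output stamps; ``NOT_REACHED``
    if the trajectory never crosses (a collapsed run counts as crossed at its
    final stamp)."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    v = result.volume
    if v.size == 0:
        raise ValueError("empty simulation result")
    thresh = (1.0 - fraction) * v[0]
    below = np.nonzero(v <= thresh)[0]
    if below.size == 0:
        if result.collapsed:
            return float(result.t[-1]) / WEEK
        return NOT_REACHED
    i = int(below[0])
    if i == 0:
        return 0.0
    t0, t1 = result.t[i - 1], result.t[i]
    v0, v1 = v[i - 1], v[i]
    t_cross = t0 + (v0 - thresh) / (v0 - v1) * (t1 - t0)
    return float(t_cross) / WEEK


# cache of pre-treatment quasi-steady states, keyed by the run conditions
_EQUILIBRIUM_CACHE: dict = {}


def equilibrated_state(params: ParameterSet, settings: SolverSettings,
                       max_days: float = 250.0, window: float = 10.0,
                       rtol: float = 1e-3):
    """Evolve the untreated model until the radius is quasi-steady.

    Utility for protocols that dose an established tumor rather than the
    day-0 state; note the untreated tumor settles into slow exponential rim
    growth, so "quasi-steady" is only reached within ``rtol`` per ``window``.
    Cached per parameter set and resolution; returns (state, grid).
    """
    key = (tuple(sorted((k, v) for k, v in params.as_dict().items())),
           settings.n_nodes, settings.tau, settings.tol)
    if key in _EQUILIBRIUM_CACHE:
        return _EQUILIBRIUM_CACHE[key]
    state, grid = initial_state(params, n_nodes=settings.n_nodes)
    t_done = 0.0
    while t_done < max_days:
        res = simulate(params, None, settings, horizon=window,
                       initial=(state, grid))
        state, grid = res.final_state, res.final_grid
        rel = abs(res.R[-1] - res.R[0]) / res.R[-1]
        t_done += window
        if rel < rtol:
            break
    grid = RadialGrid(grid.r.copy(), grid.u.copy(), 0.0)  # reset the clock
    _EQUILIBRIUM_CACHE[key] = (state, grid)
    return state, grid


def run_schedule_experiment(
    params: ParameterSet | None,
    schedule: Schedule,
    settings: SolverSettings | None = None,
    fraction: float = 0.95,
    pretreat_days: float = 0.0,
    escape_factor: float | None = 100.0,
) -> tuple[SimulationResult, float]:
    """Run one treatment schedule and report (trajectory, T_crit in weeks).

    ``params=None`` selects the canonical parameter set for the schedule's
    organism.  Dosing starts at day 0 from the standard initial state, for
    mouse and clinical runs alike; ``pretreat_days > 0`` optionally lets the
    untreated tumor evolve first (the endpoint is then measured against the
    volume at treatment start).  ``escape_factor`` ends a run early once the
    volume exceeds that multiple of its starting value and reports the
    endpoint as not reached (a tumor that has escaped by two orders of
    magnitude does not regress to 5% under the dose ranges considered here).
    """
    settings = settings or SolverSettings()
    if params is None:
        params = (human_parameters() if schedule.organism == "human"
                  else mouse_parameters())
    params = dc_replace(params, gamma_A=schedule.gamma_A, gamma_B=schedule.gamma_B)
    init = None
    if pretreat_days > 0.0:
        pre = simulate(dc_replace(params, gamma_A=0.0, gamma_B=0.0), None,
                       settings, horizon=pretreat_days)
        init = (pre.final_state,
                RadialGrid(pre.final_grid.r.copy(), pre.final_grid.u.copy(), 0.0))
    res = simulate(params, schedule, settings, horizon=schedule.horizon,
                   initial=init, stop_volume_fraction=0.6 * (1.0 - fraction),
                   stop_volume_factor_above=escape_factor)
    return res, time_to_reduction(res, fraction)


@dataclass
class EfficacyMap:
    """T_crit (weeks) over a (gamma_B, gamma_A) dose grid for one schedule."""

    gamma_B: np.ndarray
    gamma_A: np.ndarray
    t_crit: np.ndarray  # shape (len(gamma_A), len(gamma_B)); inf = not reached
    label: str = ""

    def __post_init__(self):
        self.gamma_B = np.asarray(self.gamma_B, dtype=float)
        self.gamma_A = np.asarray(self.gamma_A, dtype=float)
        self.t_crit = np.asarray(self.t_crit, dtype=float)
        if self.t_crit.shape != (self.gamma_A.size, self.gamma_B.size):
            raise ValueError("t_crit shape must be (n_gamma_A, n_gamma_B)")


def efficacy_map(
    params: ParameterSet | None,
    schedule_kind: str,
    gamma_B_grid: Sequence[float],
    gamma_A_grid: Sequence[float],
    settings: SolverSettings | None = None,
    organism: str = "human",
    perfusion_mode: str = "blocking",
    horizon: float | None = None,
) -> EfficacyMap:
    """One simulation per dose-grid cell (cells are independent); failures are
    recorded as NaN, unreached endpoints as inf."""
    if len(gamma_A_grid) == 0 or len(gamma_B_grid) == 0:
        raise ValueError("dose grids must be nonempty")
    builder = SCHEDULE_BUILDERS[schedule_kind]
    out = np.full((len(gamma_A_grid), len(gamma_B_grid)), np.nan)
    for i, ga in enumerate(gamma_A_grid):
        for j, gb in enumerate(gamma_B_grid):
            sched = builder(gb, ga, organism=organism,
                            perfusion_mode=perfusion_mode)
            if horizon is not None:
                sched = dc_replace(sched, horizon=horizon)
            try:
                _, tc = run_schedule_experiment(params, sched, settings)
                out[i, j] = tc
            except Exception:
                out[i, j] = np.nan
    return EfficacyMap(gamma_B=np.asarray(gamma_B_grid),
                       gamma_A=np.asarray(gamma_A_grid),
                       t_crit=out, label=schedule_kind)


# Mouse experiment dose rates (g/cm^3/day)
MOUSE_REGIMENS = {
    "fig4a": {"gamma_B": 3e-8, "gamma_A": 3e-8, "days": 10.0},
    "fig4b": {"gamma_B": 3.5e-8, "gamma_A": 0.5e-8, "days": 10.0},
    "fig5": {"gamma_B": 2e-8, "gamma_A": 0.0, "days": 30.0},
}


def control_run(params: ParameterSet | None = None,
                settings: SolverSettings | None = None,
                horizon: float = 30.0) -> SimulationResult:
    """Untreated mouse run from the standard initial state."""
    params = params or mouse_parameters()
    return simulate(params, None, settings or SolverSettings(), horizon=horizon)


def mouse_regimens(params: ParameterSet | None, regimen: str,
                   settings: SolverSettings | None = None,
                   horizon: float = 30.0) -> dict[str, SimulationResult]:
    """Run the mouse experiment arms for one regimen label.

    ``fig4a``/``fig4b``: control, anti-VEGF alone, anti-PD-1 alone, and the
    combination, dosed for 10 days from day 0.  ``fig5``: control and 30-day
    anti-VEGF monotherapy (the PD-1-per-CD8-cell readout lives in the P8/T8
    averages).  ``control``: the untreated run only.
    """
    params = params or mouse_parameters()
    settings = settings or SolverSettings()
    if regimen == "control":
        return {"control": control_run(params, settings, horizon)}
    if regimen not in MOUSE_REGIMENS:
        raise ValueError(f"unknown regimen {regimen!r}")
    spec = MOUSE_REGIMENS[regimen]
    days = spec["days"]
    arms: dict[str, Schedule] = {}
    if regimen in ("fig4a", "fig4b"):
        arms["anti-VEGF"] = continuous_schedule(spec["gamma_B"], 0.0, days,
                                                horizon=horizon)
        arms["anti-PD-1"] = continuous_schedule(0.0, spec["gamma_A"], days,
                                                horizon=horizon)
        arms["combination"] = continuous_schedule(spec["gamma_B"],
                                                  spec["gamma_A"], days,
                                                  horizon=horizon)
    else:
        arms["anti-VEGF"] = continuous_schedule(spec["gamma_B"], 0.0, days,
                                                horizon=horizon)
    out = {"control": control_run(params, settings, horizon)}
    for name, sched in arms.items():
        p = dc_replace(params, gamma_A=sched.gamma_A, gamma_B=sched.gamma_B)
        out[name] = simulate(p, sched, settings, horizon=horizon)
    return out


def pd1_per_cd8(result: SimulationResult, params: ParameterSet) -> np.ndarray:
    """Average per-cell relative PD-1 load on CD8+ T cells: <P8>/(rho_P <T8>)."""
    return result.average("P8") / (params.rho_P * result.average("T8"))
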