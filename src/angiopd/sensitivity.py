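"""Latin hypercube sampling, partial rank correlation (PRCC) sensitivity
analysis, and the synthetic scenario fixtures.

The sensitivity design perturbs ten rate/threshold constants over [1/2x, 2x]
of their baseline values and scores each draw by the untreated tumor volume at
day 30 (mouse calibration).  PRCC rank-transforms parameters and outcome,
partials out all other parameters by linear regression on the ranks, and
correlates the residuals; p-values come from the t-transform of the partial
correlation with n - k - 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy import stats
from scipy.stats import qmc

from .experiments import Schedule, continuous_schedule
from .params import ParameterSet, mouse_parameters
from .solver import SolverSettings, simulate

__all__ = [
    "SampleDesign", "PRCCResult", "default_design", "latin_hypercube",
    "prcc", "sensitivity_pipeline", "make_fixture",
    "SENSITIVITY_PARAMETERS",
]

# The ten constants of the sensitivity study; the checkpoint strength K_TQ is
# realized through its implemented composite K'_TQ.
SENSITIVITY_PARAMETERS = (
    "lam_DC", "lam_T8I12", "lam_TrG", "lam_E", "lam_GW",
    "eta_8", "K_DG", "Kp_TQ", "K_TG", "K_PB",
)


@dataclass
class SampleDesign:
    """LHS design: per-parameter uniform ranges and a sample count."""

    names: tuple[str, ...] = SENSITIVITY_PARAMETERS
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_samples: int = 500
    seed: int = 0

    @property
    def k(self) -> int:
        return len(self.names)

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        for name in self.names:
            lo, hi = self.ranges[name]
            if not (0.0 < lo < hi):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")


def default_design(params: ParameterSet | None = None, n_samples: int = 500,
                   seed: int = 0) -> SampleDesign:
    """Ranges [1/2x, 2x] around the (mouse) baseline of each parameter."""
    params = params or mouse_parameters()
    ranges = {}
    for name in SENSITIVITY_PARAMETERS:
        v = getattr(params, name)
        ranges[name] = (0.5 * v, 2.0 * v)
    return SampleDesign(ranges=ranges, n_samples=n_samples, seed=seed)


def latin_hypercube(design: SampleDesign) -> np.ndarray:
    """Stratified (n_samples, k) sample matrix: each parameter's marginal hits
    every equal-probability bin exactly once; reproducible under the seed."""
    design.validate()
    sampler = qmc.LatinHypercube(d=design.k, seed=design.seed)
    unit = sampler.random(design.n_samples)
    lo = np.array([design.ranges[n][0] for n in design.names])
    hi = np.array([design.ranges[n][1] for n in design.names])
    return qmc.scale(unit, lo, hi)


@dataclass
class PRCCResult:
    names: tuple[str, ...]
    prcc: np.ndarray
    p_value: np.ndarray
    outcome: str = "tumor volume at day 30"
    n_samples: int = 0
    seed: int = 0
    n_failed: int = 0
    manifest: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {n: (float(r), float(p))
                for n, r, p in zip(self.names, self.prcc, self.p_value)}


def prcc(samples: np.ndarray, outcomes: np.ndarray,
         names: tuple[str, ...] | None = None) -> PRCCResult:
    """Partial rank correlation of each column of ``samples`` with
    ``outcomes``, controlling for the remaining columns.

    Ties get average ranks.  A rank-degenerate (constant) column is flagged
    with NaN PRCC/p rather than raising.
    """
    X = np.asarray(samples, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n, k = X.shape
    if y.shape != (n,):
        raise ValueError("outcomes must match the sample count")
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} samples, got {n}")
    ranks = np.column_stack([stats.rankdata(X[:, j]) for j in range(k)])
    ry = stats.rankdata(y)
    const = np.array([np.ptp(ranks[:, j]) == 0 for j in range(k)])
    out_r = np.full(k, np.nan)
    out_p = np.full(k, np.nan)
    dof = n - k - 2
    for j in range(k):
        if const[j]:
            continue
        others = np.column_stack(
            [np.ones(n)] + [ranks[:, m] for m in range(k) if m != j and not const[m]])
        res_x = ranks[:, j] - others @ np.linalg.lstsq(others, ranks[:, j],
                                                       rcond=None)[0]
        res_y = ry - others @ np.linalg.lstsq(others, ry, rcond=None)[0]
        denom = np.sqrt((res_x ** 2).sum() * (res_y ** 2).sum())
        if denom == 0:
            continue
        r = float((res_x * res_y).sum() / denom)
        r = max(-1.0, min(1.0, r))
        if abs(r) >= 1.0 or dof <= 0:
            p = 0.0
        else:
            t = r * np.sqrt(dof / (1.0 - r ** 2))
            p = float(2.0 * stats.t.sf(abs(t), dof))
        out_r[j] = r
        out_p[j] = p
    names = names or tuple(f"x{j}" for j in range(k))
    return PRCCResult(names=tuple(names), prcc=out_r, p_value=out_p,
                      n_samples=n)


def _day30_volume(params: ParameterSet, settings: SolverSettings,
                  day: float) -> float:
    res = simulate(params, None, settings, horizon=day)
    return float(res.volume[-1])


def sensitivity_pipeline(
    params: ParameterSet | None = None,
    design: SampleDesign | None = None,
    settings: SolverSettings | None = None,
    day: float = 30.0,
    schedule: Schedule | None = None,
) -> PRCCResult:
    """LHS -> per-sample untreated day-30 simulation -> PRCC.

    Runs use the mouse calibration with no drugs unless a schedule is given.
    Per-sample failures are excluded and counted.  Deterministic under the
    design seed.
    """
    params = params or mouse_parameters()
    design = design or default_design(params)
    settings = settings or fast_sensitivity_settings()
    X = latin_hypercube(design)
    vols = np.empty(X.shape[0])
    ok = np.ones(X.shape[0], dtype=bool)
    for i in range(X.shape[0]):
        p_i = dc_replace(params, **{n: X[i, j]
                                    for j, n in enumerate(design.names)})
        try:
            if schedule is None:
                vols[i] = _day30_volume(p_i, settings, day)
            else:
                p_i = dc_replace(p_i, gamma_A=schedule.gamma_A,
                                 gamma_B=schedule.gamma_B)
                res = simulate(p_i, schedule, settings, horizon=day)
                vols[i] = float(res.volume[-1])
        except Exception:
            ok[i] = False
    result = prcc(X[ok], vols[ok], names=design.names)
    result.seed = design.seed
    result.n_failed = int((~ok).sum())
    result.outcome = f"tumor volume at day {day:g}"
    result.manifest = {
        "organism": params.organism,
        "treatment": "none" if schedule is None else schedule.label,
        "n_samples": int(X.shape[0]),
        "n_nodes": settings.n_nodes,
        "tau": settings.tau,
        "day": day,
        "seed": design.seed,
    }
    return result


def fast_sensitivity_settings() -> SolverSettings:
    """Scaled-down resolution used for the many short sensitivity runs."""
    return SolverSettings(n_nodes=32, tau=0.1, tol=1e-6, output_every=5.0)


def make_fixture(kind: str, seed: int = 0):
    """Self-consistent scaled-down scenarios for tests and CI.

    ``fast_mouse``/``fast_human``: coarse mesh, short horizon, canonical
    parameters.  ``stress``: mouse scenario with parameters jittered within
    +-10% (still satisfying the structural invariants).  Deterministic under
    ``seed``.  Returns (ParameterSet, Schedule, SolverSettings).
    """
    rng = np.random.default_rng(seed)
    if kind == "fast_mouse":
        params = mouse_parameters()
        schedule = continuous_schedule(0.0, 0.0, days=1.0, organism="mouse",
                                       horizon=10.0)
        settings = SolverSettings(n_nodes=50, tau=0.1, tol=1e-6,
                                  output_every=1.0)
    elif kind == "fast_human":
        from .params import human_parameters
        params = human_parameters()
        schedule = Schedule(organism="human", gamma_A=1.2e-10, gamma_B=9.5e-9,
                            windows_A=((0.0, 21.0),),
                            windows_B=((21.0, 42.0),), horizon=126.0,
                            label="S2-fixture")
        settings = SolverSettings(n_nodes=40, tau=0.1, tol=1e-6,
                                  output_every=1.0)
    elif kind == "stress":
        base = mouse_parameters()
        jitter = {}
        for name in SENSITIVITY_PARAMETERS:
            jitter[name] = getattr(base, name) * rng.uniform(0.9, 1.1)
        params = dc_replace(base, **jitter)
        params.validate()
        schedule = continuous_schedule(3e-8, 3e-8, days=5.0, organism="mouse",
                                       horizon=10.0)
        settings = SolverSettings(n_nodes=32, tau=0.05, tol=1e-6,
                                  output_every=0.5)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    manifest = {"kind": kind, "seed": seed, "horizon": schedule.horizon}
    settings.seed = seed
    params.__dict__["_fixture_manifest"] = manifest  # advisory only
    return params, schedule, settings
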