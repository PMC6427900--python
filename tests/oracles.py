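"""Shared independent oracles for the solver checks.

These are deliberately written against the model definition, not the solver
internals: a reduced ODE system for the well-mixed limit, an analytic
eigenmode of the Neumann Laplacian on a ball for the diffusion operator, and
direct mass bookkeeping for conservation.
"""

from dataclasses import replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from angiopd.geometry import node_volumes
from angiopd.kinetics import (ADVECTED, CELL_FIELDS, FIELDS, IDX, N_FIELDS,
                              StateFields, reaction_split)
from angiopd.params import mouse_parameters
from angiopd.solver import (INITIAL_VALUES, SolverSettings, initial_state,
                            simulate)


def inert_parameters(**overrides):
    """Every reaction, boundary flux and dose switched off: the PDE system
    reduces to independent pure-diffusion problems."""
    p = mouse_parameters()
    values = {}
    for name in p.as_dict():
        if name.startswith(("lam_", "d_", "eta_", "mu_", "sigma_")):
            values[name] = 0.0
    values.update(chi_G=0.0, gamma_A=0.0, gamma_B=0.0, eps_G=0.0)
    values.update(overrides)
    for k, v in values.items():
        setattr(p, k, v)
    return p


def diffusion_mass_drift(n_nodes=48, tau=0.01, horizon=0.5):
    """Max relative drift of the per-field mass integral under pure
    diffusion, together with the number of steps taken."""
    p = inert_parameters()
    settings = SolverSettings(n_nodes=n_nodes, tau=tau, output_every=horizon)
    state, grid = initial_state(p, n_nodes=n_nodes)
    prof = 1.0 + 0.8 * np.cos(np.pi * grid.r / grid.R)
    state.values *= prof
    before = state.values @ node_volumes(grid.r)
    res = simulate(p, None, settings, horizon=horizon, initial=(state, grid))
    after = res.final_state.values @ node_volumes(res.final_grid.r)
    rel = np.abs(after - before) / np.maximum(np.abs(before), 1e-300)
    return rel.max(), res.diagnostics["steps"]


def well_mixed_errors(horizon=10.0, n_nodes=32, tau=0.02):
    """Relative errors of every nonzero field average (and the radius)
    against a stiff ODE integration of the space-free reduced system."""
    p = replace(mouse_parameters(), sigma_T=0.0, sigma_E=0.0, sigma_W=0.0)
    settings = SolverSettings(n_nodes=n_nodes, tau=tau, output_every=1.0)
    res = simulate(p, None, settings, horizon=horizon)

    adv = np.array([f in ADVECTED for f in FIELDS])
    cells = [IDX[f] for f in CELL_FIELDS]

    def rhs(t, y):
        x, R = y[:N_FIELDS], y[N_FIELDS]
        state = StateFields(np.clip(x, 0.0, None)[:, None])
        f = reaction_split(state, p).rhs(state)[:, 0]
        div_u = sum(f[i] for i in cells) / p.theta
        return np.concatenate([f - adv * div_u * x, [R * div_u / 3.0]])

    y0 = np.array([INITIAL_VALUES[f] for f in FIELDS] + [0.01])
    sol = solve_ivp(rhs, (0.0, horizon), y0, method="BDF",
                    rtol=1e-9, atol=1e-16)
    ref = sol.y[:, -1]
    errs = {}
    for i, name in enumerate(FIELDS):
        if ref[i] != 0.0:
            errs[name] = abs(res.averages[name][-1] - ref[i]) / abs(ref[i])
    errs["R"] = abs(res.R[-1] - ref[-1]) / ref[-1]
    return errs


class NeumannEigenmode:
    """X(r, t) = 1 + a e^{-delta k^2 t} sin(kr)/(kr) with tan(kR) = kR."""

    def __init__(self, delta=0.1, radius=1.0, amplitude=0.5):
        self.delta = delta
        self.radius = radius
        self.amplitude = amplitude
        self.k = brentq(lambda k: np.tan(k) - k,
                        np.pi + 0.1, 1.5 * np.pi) / radius

    def exact(self, r, t):
        kr = self.k * r
        j0 = np.where(kr == 0, 1.0, np.sin(kr) / np.where(kr == 0, 1.0, kr))
        return 1.0 + self.amplitude * np.exp(-self.delta * self.k**2 * t) * j0

    def solver_error(self, n_nodes, tau, horizon=0.2):
        p = inert_parameters(delta_W=self.delta)
        settings = SolverSettings(n_nodes=n_nodes, tau=tau,
                                  output_every=horizon)
        state, grid = initial_state(p, R0=self.radius, n_nodes=n_nodes)
        state.values[:] = 0.0
        state["W"] = self.exact(grid.r, 0.0)
        state["C"] = 0.4064  # satisfies the driver's density-sum check
        res = simulate(p, None, settings, horizon=horizon,
                       initial=(state, grid))
        return np.abs(res.final_state["W"]
                      - self.exact(res.final_grid.r, horizon)).max()
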