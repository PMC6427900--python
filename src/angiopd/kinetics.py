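"""Pointwise reaction kinetics of the tumor–immune–drug network.

Each transported field has a local source/sink term; the checkpoint
(PD-1/PD-L1) and perfusion interactions enter as multiplicative factors.
Everything here is algebraic and vectorizes over radial grid nodes; the solver
supplies spatial derivatives where the PD-1 transport sources need them.

For the implicit time stepper the reactions are split as
``rhs = source - lin * X``: ``lin`` collects the non-negative coefficients of
the field's own linear sinks (death, degradation, drug depletion), which the
solver folds into the tridiagonal diagonal, while ``source`` is lagged across
Picard sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet

__all__ = [
    "FIELDS", "IDX", "N_FIELDS", "CELL_FIELDS", "ADVECTED", "StateFields",
    "cancer_growth_rate", "vegf_production_rate", "endothelial_growth_rate",
    "checkpoint_inhibition_factor", "perfusion_factor", "pd_l1_concentration",
    "ReactionSplit", "reaction_split", "reaction_terms", "pd1_transport_rhs",
]

FIELDS = ("D", "T1", "T8", "Tr", "E", "C", "I12", "I2", "Tb", "W", "G",
          "P1", "P8", "A", "B")
IDX = {name: i for i, name in enumerate(FIELDS)}
N_FIELDS = len(FIELDS)
CELL_FIELDS = ("D", "T1", "T8", "Tr", "E", "C")
# Fields carried by the cell velocity field (cells and the PD-1 loads riding
# on T cells); cytokines and drugs only diffuse.
ADVECTED = ("D", "T1", "T8", "Tr", "E", "C", "P1", "P8")


class StateFields:
    """The 15 transported fields as a (15, n_nodes) array with named access.

    Invariants: non-negative values; the six cell densities sum to theta at
    every node within solver tolerance.
    """

    __slots__ = ("values",)

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != N_FIELDS:
            raise ValueError(f"expected shape ({N_FIELDS}, n), got {values.shape}")
        self.values = values

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[IDX[name]]

    def __setitem__(self, name: str, arr) -> None:
        self.values[IDX[name]] = arr

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "StateFields":
        return StateFields(self.values.copy())

    def cell_total(self) -> np.ndarray:
        return sum(self.values[IDX[f]] for f in CELL_FIELDS)


# ---------------------------------------------------------------------------
# Individual rate laws


def cancer_growth_rate(W, params: ParameterSet):
    """Oxygen-limited cancer proliferation rate: linear up to the normal
    oxygen level W_0, capped at lam_CW beyond it (1/day)."""
    W = np.asarray(W, dtype=float)
    return params.lam_CW * np.minimum(W / params.W_0, 1.0)


def vegf_production_rate(W, params: ParameterSet):
    """Bimodal VEGF secretion rate per unit cancer density (1/day).

    Rises linearly to lam_GW at the hypoxia threshold W*, falls linearly to
    0.3 lam_GW at the normal level W_0, constant 0.3 lam_GW beyond.
    """
    W = np.asarray(W, dtype=float)
    p = params
    rising = W / p.W_star
    falling = 1.0 - 0.7 * (W - p.W_star) / (p.W_0 - p.W_star)
    shape = np.where(W <= p.W_star, rising, np.maximum(falling, 0.3))
    return p.lam_GW * shape


def endothelial_growth_rate(G, params: ParameterSet):
    """Thresholded VEGF-driven endothelial proliferation rate:
    lam_E (G - G_0)^+ (1/day)."""
    G = np.asarray(G, dtype=float)
    return params.lam_E * np.maximum(G - params.G_0, 0.0)


def checkpoint_inhibition_factor(P, L, params: ParameterSet):
    """Suppression of T-cell activation by the PD-1–PD-L1 complex:
    1/(1 + P L / K'_TQ), in (0, 1]."""
    return 1.0 / (1.0 + np.asarray(P) * np.asarray(L) / params.Kp_TQ)


def perfusion_factor(B, params: ParameterSet, mode: str = "blocking"):
    """Modulation of anti-PD-1 depletion efficiency by anti-VEGF.

    ``blocking``: 1/(1 + B/K_PB) in (0, 1] (anti-VEGF restricts perfusion);
    ``enhancing``: 1 + B/(K_B + B) in [1, 2) (anti-VEGF improves perfusion).
    """
    B = np.asarray(B, dtype=float)
    if mode == "blocking":
        return 1.0 / (1.0 + B / params.K_PB)
    if mode == "enhancing":
        return 1.0 + B / (params.K_B + B)
    raise ValueError(f"unknown perfusion mode {mode!r}")


def pd_l1_concentration(T1, T8, Tr, C, params: ParameterSet):
    """Algebraic PD-L1 field L = rho_L (T1 + T8 + eps_T Tr + eps_C C)."""
    return params.rho_L * (np.asarray(T1) + np.asarray(T8)
                           + params.eps_T * np.asarray(Tr)
                           + params.eps_C * np.asarray(C))


# ---------------------------------------------------------------------------
# Full reaction split


@dataclass
class ReactionSplit:
    """Reactions split for the implicit solver: rhs = source - lin * X.

    ``source`` and ``lin`` are (15, n) arrays. ``cell_sum`` is the summed full
    reaction of the six cell equations (the velocity-divergence source, before
    the chemotaxis flux contribution which the solver handles separately).
    """

    source: np.ndarray
    lin: np.ndarray
    cell_sum: np.ndarray

    def rhs(self, state: StateFields) -> np.ndarray:
        return self.source - self.lin * state.values


def reaction_split(
    state: StateFields,
    params: ParameterSet,
    I_A: float = 0.0,
    I_B: float = 0.0,
    *,
    perfusion_mode: str = "blocking",
    grad_T8: np.ndarray | None = None,
    grad_G: np.ndarray | None = None,
    lap_G: np.ndarray | None = None,
    u: np.ndarray | None = None,
) -> ReactionSplit:
    """Evaluate every local reaction term at the given state.

    The PD-1 cross-terms of the CD8 load require spatial samples (gradients
    and spherical Laplacian of G, gradient of T8, velocity u); when omitted
    they are treated as zero, which is exact for spatially uniform states.
    """
    p = params
    v = state.values
    if np.any(v < 0):
        raise ValueError("reaction terms are defined for non-negative states only")
    n = state.n_nodes
    D, T1, T8, Tr, E, C = (v[IDX[f]] for f in CELL_FIELDS)
    I12, I2, Tb, W, G = (v[IDX[f]] for f in ("I12", "I2", "Tb", "W", "G"))
    P1, P8, A, B = (v[IDX[f]] for f in ("P1", "P8", "A", "B"))

    source = np.zeros((N_FIELDS, n))
    lin = np.zeros((N_FIELDS, n))

    L = pd_l1_concentration(T1, T8, Tr, C, p)
    P = P1 + P8
    inh_Q = checkpoint_inhibition_factor(P, L, p)
    inh_Tr = 1.0 / (1.0 + Tr / p.K_TTr)
    inh_G = 1.0 / (1.0 + G / p.K_TG)
    f12 = I12 / (p.K_I12 + I12)
    f2 = I2 / (p.K_I2 + I2)

    source[IDX["D"]] = (p.lam_DC * p.D_0 * C / (p.K_C + C)) / (1.0 + G / p.K_DG)
    lin[IDX["D"]] = p.d_D

    act1 = (p.lam_T1I12 * p.T_10 * f12 * inh_Tr * inh_G
            + p.lam_T1I2 * T1 * f2)
    source[IDX["T1"]] = act1 * inh_Q
    lin[IDX["T1"]] = p.d_T1
    act8 = (p.lam_T8I12 * p.T_80 * f12 * inh_Tr * inh_G
            + p.lam_T8I2 * T8 * f2)
    source[IDX["T8"]] = act8 * inh_Q
    lin[IDX["T8"]] = p.d_T8

    source[IDX["Tr"]] = p.T_10 * (p.lam_TrTb * Tb / (p.K_Tb + Tb)
                                  + p.lam_TrG * G / (p.K_G + G))
    lin[IDX["Tr"]] = p.d_Tr

    source[IDX["E"]] = endothelial_growth_rate(G, p) * E * (1.0 - E / p.E_M)
    lin[IDX["E"]] = p.d_E

    source[IDX["C"]] = cancer_growth_rate(W, p) * C * (1.0 - C / p.C_M)
    lin[IDX["C"]] = p.d_C + p.eta_1 * T1 + p.eta_8 * T8

    source[IDX["I12"]] = p.lam_I12D * D
    lin[IDX["I12"]] = p.d_I12
    source[IDX["I2"]] = p.lam_I2T1 * T1
    lin[IDX["I2"]] = p.d_I2
    source[IDX["Tb"]] = p.lam_TbC * C + p.lam_TbTr * Tr
    lin[IDX["Tb"]] = p.d_Tb
    source[IDX["W"]] = p.lam_WE * E
    lin[IDX["W"]] = p.d_W
    source[IDX["G"]] = vegf_production_rate(W, p) * C
    lin[IDX["G"]] = p.d_G + p.mu_GB * B

    source[IDX["A"]] = p.gamma_A * I_A
    lin[IDX["A"]] = p.d_A + p.mu_AP * P
    source[IDX["B"]] = p.gamma_B * I_B
    lin[IDX["B"]] = p.d_B + p.mu_BG * G

    # PD-1 loads: algebraic images of the T-cell reactions plus drug depletion.
    rhs3 = source[IDX["T1"]] - p.d_T1 * T1
    rhs4 = source[IDX["T8"]] - p.d_T8 * T8
    rhs5 = source[IDX["Tr"]] - p.d_Tr * Tr
    rhs12 = source[IDX["G"]] - lin[IDX["G"]] * G
    perf = perfusion_factor(B, p, perfusion_mode)

    source[IDX["P1"]] = p.rho_P * (rhs3 + p.eps_T * rhs5)
    lin[IDX["P1"]] = p.mu_PA * A * perf

    cross = np.zeros(n)
    if grad_G is not None:
        if u is not None:
            cross = cross + p.eps_G * T8 * u * grad_G
        if grad_T8 is not None:
            cross = cross - 2.0 * p.eps_G * p.delta_T * grad_T8 * grad_G
    if lap_G is not None:
        cross = cross + p.eps_G * (p.delta_G - p.delta_T) * T8 * lap_G
    source[IDX["P8"]] = p.rho_P * ((1.0 + p.eps_G * G) * rhs4
                                   + p.eps_G * T8 * rhs12 + cross)
    lin[IDX["P8"]] = p.mu_PA * A * perf

    # Diagonal Newton stabilization of the checkpoint feedback: the PD-1
    # sources fall steeply with P through inh_Q (|d src/d P| can exceed any
    # practical 1/tau during regression), which makes plain Picard cycle.
    # Adding J*X to both source and lin leaves the fixed point unchanged but
    # renders the per-sweep update contractive.
    dinh_dP = (L / p.Kp_TQ) * inh_Q ** 2
    J1 = p.rho_P * act1 * dinh_dP
    J8 = p.rho_P * (1.0 + p.eps_G * G) * act8 * dinh_dP
    source[IDX["P1"]] += J1 * P1
    lin[IDX["P1"]] += J1
    source[IDX["P8"]] += J8 * P8
    lin[IDX["P8"]] += J8

    full = source - lin * v
    cell_sum = sum(full[IDX[f]] for f in CELL_FIELDS)
    return ReactionSplit(source=source, lin=lin, cell_sum=cell_sum)


def reaction_terms(state: StateFields, params: ParameterSet,
                   I_A: float = 0.0, I_B: float = 0.0, **spatial) -> np.ndarray:
    """Full local reaction right-hand sides, one row per field (g/cm^3/day)."""
    split = reaction_split(state, params, I_A, I_B, **spatial)
    return split.rhs(state)


def pd1_transport_rhs(
    state: StateFields,
    params: ParameterSet,
    rhs3: np.ndarray,
    rhs4: np.ndarray,
    rhs5: np.ndarray,
    rhs12: np.ndarray,
    *,
    grad_T8: np.ndarray,
    grad_G: np.ndarray,
    lap_G: np.ndarray,
    u: np.ndarray,
    perfusion_mode: str = "blocking",
) -> tuple[np.ndarray, np.ndarray]:
    """Local sources of the PD-1 transport equations.

    P1 rides on T1 + eps_T Tr; P8 rides on T8 with a VEGF-dependent load
    (1 + eps_G G), which generates cross-terms in u, grad G, lap G and
    grad T8 · grad G.  Both are depleted by anti-PD-1 at a rate modulated by
    the anti-VEGF perfusion factor.
    """
    for name, arr in (("grad_T8", grad_T8), ("grad_G", grad_G),
                      ("lap_G", lap_G), ("u", u)):
        if arr is None:
            raise ValueError(f"missing spatial samples: {name}")
    p = params
    T8 = state["T8"]
    G = state["G"]
    A = state["A"]
    B = state["B"]
    perf = perfusion_factor(B, p, perfusion_mode)
    dep1 = p.mu_PA * state["P1"] * A * perf
    dep8 = p.mu_PA * state["P8"] * A * perf
    src1 = p.rho_P * (rhs3 + p.eps_T * rhs5) - dep1
    cross = (p.eps_G * T8 * u * grad_G
             + p.eps_G * (p.delta_G - p.delta_T) * T8 * lap_G
             - 2.0 * p.eps_G * p.delta_T * grad_T8 * grad_G)
    src8 = p.rho_P * ((1.0 + p.eps_G * G) * rhs4
                      + p.eps_G * T8 * rhs12 + cross) - dep8
    return src1, src8
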