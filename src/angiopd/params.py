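"""Model constants and executable steady-state parameter derivations.

The model tracks six cell populations (dendritic cells D, CD4+ Th1 cells T1,
CD8+ T cells T8, Tregs Tr, endothelial cells E, cancer cells C), five diffusing
molecular species (IL-12, IL-2, TGF-beta, oxygen W, VEGF G), the PD-1 loads
carried by the T-cell compartments (P1, P8), and the two drugs (anti-PD-1 A,
anti-VEGF B).  All densities and concentrations are in g/cm^3, rates in 1/day
or cm^3/(g day), lengths in cm.

Most "estimated" rate constants follow from steady-state balances built on the
half-saturation closure K_X = X0 (each Michaelis constant equals the species'
steady-state level).  Those balances are implemented here as executable
derivations: :func:`derive_secondary_parameters` recomputes every derived
constant from the primary ones and reports it against the tabulated value, so
the parameter table can be audited rather than trusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields, replace
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "ParameterSet",
    "SpeciesBaselines",
    "ClosureRecord",
    "DerivationResult",
    "mouse_parameters",
    "human_parameters",
    "default_baselines",
    "derive_secondary_parameters",
    "protein_diffusion_coefficient",
    "species_variant",
    "write_params",
    "read_params",
    "write_audit_csv",
    "UNITS",
]


class MissingParameterError(KeyError):
    """A closure needs a primary constant that was not supplied."""


class DegenerateClosureError(ValueError):
    """A closure divisor is zero or negative."""


# Reference VEGF molecular data for the cube-root diffusion scaling.
VEGF_MOLECULAR_WEIGHT_KDA = 24.0
VEGF_DIFFUSIVITY = 8.64e-2  # cm^2/day
ANTI_VEGF_MOLECULAR_WEIGHT_KDA = 149.0  # bevacizumab


def protein_diffusion_coefficient(molecular_weight_kda: float) -> float:
    """Diffusion coefficient of a protein from cube-root molecular-weight
    scaling against VEGF (24 kDa, 8.64e-2 cm^2/day)."""
    if molecular_weight_kda <= 0:
        raise ValueError("molecular weight must be positive (kDa)")
    return VEGF_DIFFUSIVITY * (VEGF_MOLECULAR_WEIGHT_KDA / molecular_weight_kda) ** (1.0 / 3.0)


@dataclass(frozen=True)
class SpeciesBaselines:
    """Steady-state densities/concentrations (g/cm^3) used by the closures.

    Under the half-saturation closure each of these equals the corresponding
    Michaelis constant K_X.
    """

    D: float = 4e-4
    T1: float = 2e-3
    T8: float = 1e-3
    Tr: float = 5e-4
    E: float = 2.5e-3
    C: float = 0.4
    I12: float = 8e-10
    I2: float = 2.37e-11
    Tb: float = 2.68e-13
    W: float = 1.69e-4
    G: float = 7e-8

    def cell_total(self) -> float:
        """Total cell density: the constant of the incompressibility
        constraint D+T1+T8+Tr+E+C = theta."""
        return self.D + self.T1 + self.T8 + self.Tr + self.E + self.C


@dataclass
class ParameterSet:
    """Every constant of the model.  Defaults are the mouse values.

    Units are recorded in :data:`UNITS`; ``validate()`` checks positivity and
    the structural invariants (theta consistency, threshold ordering).
    """

    organism: str = "mouse"

    # --- diffusion (cm^2/day) ---
    delta_D: float = 8.64e-7
    delta_T: float = 8.64e-7
    delta_E: float = 8.64e-7
    delta_C: float = 8.64e-7
    delta_I12: float = 6.05e-2
    delta_I2: float = 9.58e-2
    delta_Tb: float = 8.52e-2
    delta_W: float = 0.8
    delta_G: float = 8.64e-2
    delta_A: float = 4.73e-2
    delta_B: float = 4.70e-2

    # --- boundary flux rates (1/cm) ---
    sigma_T: float = 1.0
    sigma_E: float = 1.0
    sigma_W: float = 1.0  # not tabulated; set by analogy with sigma_T

    # --- chemotaxis (cm^5/(g day)) ---
    chi_G: float = 10.0

    # --- activation / production rates ---
    lam_DC: float = 17.5        # 1/day (mouse; human 7.5)
    lam_T1I12: float = 11.65    # 1/day
    lam_T1I2: float = 0.25      # 1/day
    lam_T8I12: float = 10.38    # 1/day
    lam_T8I2: float = 0.25      # 1/day
    lam_TrTb: float = 0.415     # 1/day
    lam_TrG: float = 0.083      # 1/day
    lam_E: float = 2.77e7       # cm^3/(g day) (mouse; human 2.08e7)
    lam_CW: float = 2.24        # 1/day (mouse; human 1.76)
    lam_I12D: float = 2.21e-6   # 1/day
    lam_I2T1: float = 2.82e-8   # 1/day
    lam_TbC: float = 3.27e-10   # 1/day
    lam_TbTr: float = 5.57e-9   # 1/day
    lam_WE: float = 7e-2        # 1/day
    lam_GW: float = 2.21e-6     # 1/day

    # --- death / degradation rates (1/day) ---
    d_D: float = 0.1
    d_T1: float = 0.197
    d_T8: float = 0.18
    d_Tr: float = 0.2
    d_E: float = 0.69
    d_C: float = 0.17
    d_I12: float = 1.38
    d_I2: float = 2.376
    d_Tb: float = 499.066
    d_W: float = 1.04
    d_G: float = 12.6
    d_A: float = 0.34
    d_B: float = 0.17

    # --- killing rates (cm^3/(g day)) ---
    eta_1: float = 30.19
    eta_8: float = 60.375

    # --- blocking/depletion rates (cm^3/(g day)) ---
    mu_PA: float = 4.33e7
    mu_AP: float = 4.33e7
    mu_GB: float = 1.31e8   # depletion of VEGF by anti-VEGF
    mu_BG: float = 2.19e7   # depletion of anti-VEGF by VEGF

    # --- half-saturations (g/cm^3 unless noted) ---
    K_D: float = 4e-4
    K_T1: float = 2e-3
    K_T8: float = 1e-3
    K_Tr: float = 5e-4
    K_E: float = 2.5e-3
    K_C: float = 0.4
    K_I12: float = 8e-10
    K_I2: float = 2.37e-11
    K_Tb: float = 2.68e-13
    K_W: float = 1.69e-4
    K_G: float = 7e-8
    K_TTr: float = 5e-4
    K_DG: float = 2.8e-7    # = 4 K_G
    K_TG: float = 2.8e-7    # = 4 K_G
    Kp_TQ: float = 1.68e-18  # g^2/cm^6; composite 0.5*K_P*K_L
    K_PB: float = 1e-8      # g/cm^3 (mouse; human 1e-9)
    K_B: float = 1e-8       # perfusion-enhancement half-saturation; defaults to K_PB

    # --- sources / capacities (g/cm^3) ---
    D_0: float = 2e-5
    T_10: float = 4e-4
    T_80: float = 2e-4
    E_M: float = 5e-3
    C_M: float = 0.8
    T1_hat: float = 4e-3
    T8_hat: float = 2e-3
    E_hat: float = 5e-3

    # --- thresholds (g/cm^3) ---
    G_0: float = 3.65e-10
    W_star: float = 1.69e-4
    W_0: float = 4.65e-4
    # Normal blood oxygen level: boundary target of the oxygen flux condition.
    # Distinct from the rate-law threshold W_0; the steady-state closures use
    # W = K_W = 1.69e-4, which identifies the blood level with K_W.
    W_blood: float = 1.69e-4

    # --- mass ratios / relative expression ---
    rho_P: float = 2.49e-7
    rho_L: float = 5.22e-7
    eps_T: float = 0.8
    eps_C: float = 0.01
    eps_G: float = 1.43e6   # cm^3/g

    # --- dosing (g/(cm^3 day)); set per experiment ---
    gamma_A: float = 0.0
    gamma_B: float = 0.0

    # --- total cell density (g/cm^3) ---
    theta: float = 0.4064

    def validate(self, baselines: SpeciesBaselines | None = None) -> None:
        for f in dc_fields(self):
            if f.name == "organism":
                continue
            v = getattr(self, f.name)
            if f.name in ("gamma_A", "gamma_B"):
                if v < 0:
                    raise ValueError(f"{f.name} must be non-negative")
                continue
            if v <= 0:
                raise ValueError(f"{f.name} must be strictly positive, got {v!r}")
        if not (0.0 < self.eps_T <= 1.0 and 0.0 < self.eps_C <= 1.0):
            raise ValueError("eps_T and eps_C must lie in (0, 1]")
        if self.W_star > self.W_0:
            raise ValueError("W_star must not exceed W_0")
        if self.G_0 >= self.K_G:
            raise ValueError("G_0 must be below K_G")
        if baselines is not None:
            theta = baselines.cell_total()
            if abs(theta - self.theta) > 1e-12 + 1e-9 * theta:
                raise ValueError(
                    f"theta={self.theta} inconsistent with baseline cell sum {theta}"
                )

    def as_dict(self) -> dict[str, float | str]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


UNITS: dict[str, str] = {
    "organism": "-",
    **{k: "cm^2/day" for k in (
        "delta_D", "delta_T", "delta_E", "delta_C", "delta_I12", "delta_I2",
        "delta_Tb", "delta_W", "delta_G", "delta_A", "delta_B")},
    **{k: "1/cm" for k in ("sigma_T", "sigma_E", "sigma_W")},
    "chi_G": "cm^5/(g day)",
    **{k: "1/day" for k in (
        "lam_DC", "lam_T1I12", "lam_T1I2", "lam_T8I12", "lam_T8I2", "lam_TrTb",
        "lam_TrG", "lam_CW", "lam_I12D", "lam_I2T1", "lam_TbC", "lam_TbTr",
        "lam_WE", "lam_GW", "d_D", "d_T1", "d_T8", "d_Tr", "d_E", "d_C",
        "d_I12", "d_I2", "d_Tb", "d_W", "d_G", "d_A", "d_B")},
    "lam_E": "cm^3/(g day)",
    **{k: "cm^3/(g day)" for k in ("eta_1", "eta_8", "mu_PA", "mu_AP", "mu_GB", "mu_BG")},
    **{k: "g/cm^3" for k in (
        "K_D", "K_T1", "K_T8", "K_Tr", "K_E", "K_C", "K_I12", "K_I2", "K_Tb",
        "K_W", "K_G", "K_TTr", "K_DG", "K_TG", "K_PB", "K_B", "D_0", "T_10",
        "T_80", "E_M", "C_M", "T1_hat", "T8_hat", "E_hat", "G_0", "W_star",
        "W_0", "W_blood", "theta")},
    "Kp_TQ": "g^2/cm^6",
    "rho_P": "-",
    "rho_L": "-",
    "eps_T": "-",
    "eps_C": "-",
    "eps_G": "cm^3/g",
    "gamma_A": "g/(cm^3 day)",
    "gamma_B": "g/(cm^3 day)",
}

# Fields the clinical ("human") calibration changes relative to the mouse set.
ORGANISM_OVERRIDES: dict[str, dict[str, float]] = {
    "mouse": {"lam_DC": 17.5, "lam_E": 2.77e7, "lam_CW": 2.24, "K_PB": 1e-8},
    "human": {"lam_DC": 7.5, "lam_E": 2.08e7, "lam_CW": 1.76, "K_PB": 1e-9},
}


def mouse_parameters() -> ParameterSet:
    """Canonical mouse parameter set (tabulated values)."""
    p = ParameterSet()
    p.validate(default_baselines())
    return p


def human_parameters() -> ParameterSet:
    """Canonical clinical parameter set: slower tumor growth calibration."""
    return species_variant(mouse_parameters(), "human")


def species_variant(base: ParameterSet, organism: str) -> ParameterSet:
    """Return ``base`` with the organism-specific rates swapped in.

    Only lam_DC, lam_E, lam_CW and K_PB differ between the mouse and the
    in-silico clinical calibration; K_B follows K_PB unless it was customized.
    """
    try:
        over = ORGANISM_OVERRIDES[organism]
    except KeyError:
        raise ValueError(f"unknown organism {organism!r}; expected 'mouse' or 'human'")
    out = replace(base, organism=organism, **over)
    if base.K_B == base.K_PB:  # keep the default K_B = K_PB linkage
        out.K_B = out.K_PB
    return out


def default_baselines() -> SpeciesBaselines:
    return SpeciesBaselines()


@dataclass(frozen=True)
class ClosureRecord:
    symbol: str
    closure: str
    derived: float
    tabulated: float | None
    unit: str

    @property
    def rel_diff(self) -> float | None:
        if self.tabulated in (None, 0.0):
            return None
        return (self.derived - self.tabulated) / self.tabulated


@dataclass
class DerivationResult:
    params: ParameterSet
    records: list[ClosureRecord] = field(default_factory=list)

    def record_map(self) -> dict[str, ClosureRecord]:
        return {r.symbol: r for r in self.records}


# Primary constants every closure chain needs.
_REQUIRED_PRIMARIES = (
    "d_D", "d_T1", "d_T8", "d_Tr", "d_E", "d_C", "d_I2", "d_Tb", "d_G", "d_A",
    "d_B", "lam_T1I2", "lam_T8I2", "lam_TbTr", "lam_WE", "D_0", "T_10", "T_80",
    "E_M", "C_M", "G_0", "W_0", "rho_P", "rho_L", "eps_T", "eps_C", "K_TTr",
)


def _get(primaries, name: str) -> float:
    if isinstance(primaries, Mapping):
        if name not in primaries:
            raise MissingParameterError(name)
        return primaries[name]
    try:
        return getattr(primaries, name)
    except AttributeError:
        raise MissingParameterError(name)


def _safe_div(num: float, den: float, symbol: str) -> float:
    if den <= 0:
        raise DegenerateClosureError(f"non-positive divisor in closure for {symbol}")
    return num / den


def derive_secondary_parameters(
    baselines: SpeciesBaselines,
    primaries: ParameterSet | Mapping[str, float],
    *,
    lam_CW_ref: float = 1.6,
) -> DerivationResult:
    """Run every steady-state closure and assemble a complete ParameterSet.

    ``primaries`` supplies the reference-sourced constants; each derived
    constant is recomputed from the balances and recorded together with the
    tabulated value it should reproduce.  Tabulated values remain canonical for
    simulation (several derived rates were deliberately adjusted upward in the
    tables to compensate for modelling simplifications); the records expose the
    raw derivations for audit.

    ``lam_CW_ref`` is the unadjusted cancer growth rate entering the killing
    rate balance (the tabulated simulation values are larger).
    """
    for name in _REQUIRED_PRIMARIES:
        _get(primaries, name)  # raises MissingParameterError if absent

    b = baselines
    tab = mouse_parameters()
    rec: list[ClosureRecord] = []

    def add(symbol: str, closure: str, derived: float, tabulated: float | None, unit: str):
        rec.append(ClosureRecord(symbol, closure, derived, tabulated, unit))
        return derived

    # Half-saturation closure K_X = X0 for every species.
    K = {
        "K_D": b.D, "K_T1": b.T1, "K_T8": b.T8, "K_Tr": b.Tr, "K_E": b.E,
        "K_C": b.C, "K_I12": b.I12, "K_I2": b.I2, "K_Tb": b.Tb, "K_W": b.W,
        "K_G": b.G,
    }
    for k, v in K.items():
        add(k, "K_X = X0 (half-saturation closure)", v, getattr(tab, k), "g/cm^3")

    K_DG = add("K_DG", "K_DG = 4 K_G", 4.0 * b.G, tab.K_DG, "g/cm^3")
    K_TG = add("K_TG", "K_TG = 4 K_G", 4.0 * b.G, tab.K_TG, "g/cm^3")

    theta = add("theta", "theta = D+T1+T8+Tr+E+C at steady state",
                b.cell_total(), tab.theta, "g/cm^3")

    # PD-1/PD-L1 algebraic closure.
    rho_P = _get(primaries, "rho_P")
    rho_L = _get(primaries, "rho_L")
    eps_T = _get(primaries, "eps_T")
    eps_C = _get(primaries, "eps_C")
    eps_G = add("eps_G", "eps_G = 0.1 / K_G", _safe_div(0.1, b.G, "eps_G"),
                tab.eps_G, "cm^3/g")
    K_P1 = add("K_P1", "K_P1 = rho_P (T1 + eps_T Tr)",
               rho_P * (b.T1 + eps_T * b.Tr), 5.98e-10, "g/cm^3")
    K_P8 = add("K_P8", "K_P8 = rho_P T8 (1 + eps_G G)",
               rho_P * b.T8 * (1.0 + eps_G * b.G), 2.74e-10, "g/cm^3")
    K_L = add("K_L", "K_L = rho_L (T1 + T8 + eps_T Tr + eps_C C)",
              rho_L * (b.T1 + b.T8 + eps_T * b.Tr + eps_C * b.C), 3.86e-9, "g/cm^3")
    Kp_TQ = add("Kp_TQ", "K'_TQ = 0.5 (K_P1+K_P8) K_L",
                0.5 * (K_P1 + K_P8) * K_L, tab.Kp_TQ, "g^2/cm^6")

    # Inhibition factors at steady state (used inside the T-cell balances).
    inh_Q = 1.0 / (1.0 + (K_P1 + K_P8) * K_L / Kp_TQ)  # = 1/3 by construction
    inh_Tr = 1.0 / (1.0 + b.Tr / _get(primaries, "K_TTr"))
    inh_G = 1.0 / (1.0 + b.G / K_TG)
    f12 = b.I12 / (K["K_I12"] + b.I12)  # = 1/2
    f2 = b.I2 / (K["K_I2"] + b.I2)      # = 1/2

    # DC activation balance (raw; tables adjust upward for source depletion).
    lam_DC_raw = _safe_div(
        _get(primaries, "d_D") * b.D * (1.0 + b.G / K_DG) * (K["K_C"] + b.C) / b.C,
        _get(primaries, "D_0"), "lam_DC")
    add("lam_DC", "lam_DC = d_D D (1+G/K_DG)(K_C+C)/C / D_0 [raw, pre-adjustment]",
        lam_DC_raw, tab.lam_DC, "1/day")

    # T-cell activation balances.
    lam_T1I12 = _safe_div(
        _get(primaries, "d_T1") * b.T1 / inh_Q - _get(primaries, "lam_T1I2") * b.T1 * f2,
        _get(primaries, "T_10") * f12 * inh_Tr * inh_G, "lam_T1I12")
    add("lam_T1I12", "IL-12 activation balance of the Th1 equation",
        lam_T1I12, tab.lam_T1I12, "1/day")
    lam_T8I12 = _safe_div(
        _get(primaries, "d_T8") * b.T8 / inh_Q - _get(primaries, "lam_T8I2") * b.T8 * f2,
        _get(primaries, "T_80") * f12 * inh_Tr * inh_G, "lam_T8I12")
    add("lam_T8I12", "IL-12 activation balance of the CD8 equation",
        lam_T8I12, tab.lam_T8I12, "1/day")

    # Treg balance with lam_TrTb = 5 lam_TrG.
    lam_TrG = _safe_div(_get(primaries, "d_Tr") * b.Tr,
                        3.0 * _get(primaries, "T_10"), "lam_TrG")
    add("lam_TrG", "Treg balance with lam_TrTb = 5 lam_TrG", lam_TrG, tab.lam_TrG, "1/day")
    add("lam_TrTb", "lam_TrTb = 5 lam_TrG", 5.0 * lam_TrG, tab.lam_TrTb, "1/day")

    # Endothelial proliferation slope (raw; tables adjust upward).
    G_0 = _get(primaries, "G_0")
    lam_E_raw = _safe_div(
        _get(primaries, "d_E"),
        (1.0 - b.E / _get(primaries, "E_M")) * (b.G - G_0), "lam_E")
    add("lam_E", "lam_E = d_E / [(1-E/E_M)(K_G-G_0)] [raw, pre-adjustment]",
        lam_E_raw, tab.lam_E, "cm^3/(g day)")

    # Killing rates, with eta_8 = 2 eta_1 and the normal oxygen level W_0.
    W_0 = _get(primaries, "W_0")
    eta_8 = _safe_div(
        lam_CW_ref * (b.W / W_0) * (1.0 - b.C / _get(primaries, "C_M"))
        - _get(primaries, "d_C"),
        2.0 * b.T8, "eta_8")
    add("eta_8", "cancer steady balance, eta_8 = 2 eta_1, lam_CW_ref=1.6",
        eta_8, tab.eta_8, "cm^3/(g day)")
    add("eta_1", "eta_1 = eta_8 / 2", eta_8 / 2.0, tab.eta_1, "cm^3/(g day)")

    # Cytokine production balances.
    lam_TbC = _safe_div(
        _get(primaries, "d_Tb") * b.Tb - _get(primaries, "lam_TbTr") * b.Tr,
        b.C, "lam_TbC")
    add("lam_TbC", "TGF-beta production balance", lam_TbC, tab.lam_TbC, "1/day")
    d_W = _safe_div(_get(primaries, "lam_WE") * b.E, b.W, "d_W")
    add("d_W", "oxygen balance d_W = lam_WE E / W", d_W, tab.d_W, "1/day")
    lam_GW = _safe_div(_get(primaries, "d_G") * b.G, b.C, "lam_GW")
    add("lam_GW", "VEGF production balance lam_GW = d_G G / C", lam_GW, tab.lam_GW, "1/day")

    # Drug depletion rates.
    d_A = _get(primaries, "d_A")
    mu_AP = _safe_div(d_A, 9.0 * (K_P1 + K_P8), "mu_AP")
    add("mu_AP", "10% of anti-PD-1 consumed blocking PD-1: mu_AP = d_A/(9 P)",
        mu_AP, tab.mu_AP, "cm^3/(g day)")
    add("mu_PA", "mu_PA = mu_AP (similar molecular masses)", mu_AP, tab.mu_PA,
        "cm^3/(g day)")
    add("d_B", "anti-VEGF half-life 4 days: d_B = ln2/4", math.log(2.0) / 4.0,
        tab.d_B, "1/day")
    d_B = _get(primaries, "d_B")  # tabulated rounding enters the mu_BG arithmetic
    mu_BG = _safe_div(9.0 * d_B, b.G, "mu_BG")
    add("mu_BG", "90% of anti-VEGF consumed blocking VEGF: mu_BG = 9 d_B/G",
        mu_BG, tab.mu_BG, "cm^3/(g day)")
    add("mu_GB", "mu_GB = 6 mu_BG (mass ratio anti-VEGF:VEGF)", 6.0 * mu_BG,
        tab.mu_GB, "cm^3/(g day)")

    # Diffusion coefficient of the anti-VEGF antibody.
    add("delta_B", "cube-root molecular-weight scaling vs VEGF (149 kDa)",
        protein_diffusion_coefficient(ANTI_VEGF_MOLECULAR_WEIGHT_KDA),
        tab.delta_B, "cm^2/day")

    # Assemble the full set: tabulated values stay canonical where the tables
    # deliberately adjusted the derived value; purely derived fields take the
    # closure output.
    out = replace(tab) if not isinstance(primaries, ParameterSet) else replace(primaries)
    derived_fields = {
        "lam_T1I12": lam_T1I12, "lam_T8I12": lam_T8I12, "lam_TrG": lam_TrG,
        "lam_TrTb": 5.0 * lam_TrG, "lam_TbC": lam_TbC, "d_W": d_W,
        "lam_GW": lam_GW, "Kp_TQ": Kp_TQ, "mu_AP": mu_AP, "mu_PA": mu_AP,
        "mu_BG": mu_BG, "mu_GB": 6.0 * mu_BG, "eta_8": eta_8, "eta_1": eta_8 / 2.0,
        "K_DG": K_DG, "K_TG": K_TG, "eps_G": eps_G, "theta": theta,
        "delta_B": protein_diffusion_coefficient(ANTI_VEGF_MOLECULAR_WEIGHT_KDA),
        **{k: v for k, v in K.items()},
    }
    for name, value in derived_fields.items():
        setattr(out, name, value)
    return DerivationResult(params=out, records=rec)


# ---------------------------------------------------------------------------
# Flat key/value config I/O


def write_params(params: ParameterSet, path: str | Path) -> None:
    """Write a flat ``key = value  # unit`` text configuration."""
    lines = ["# angiopd parameter configuration"]
    for f in dc_fields(params):
        v = getattr(params, f.name)
        unit = UNITS.get(f.name, "")
        if isinstance(v, str):
            lines.append(f"{f.name} = {v}")
        else:
            lines.append(f"{f.name} = {v!r}  # {unit}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_params(path: str | Path) -> ParameterSet:
    """Read a configuration written by :func:`write_params`."""
    values: dict[str, float | str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        values[key] = val if key == "organism" else float(val)
    names = {f.name for f in dc_fields(ParameterSet)}
    unknown = set(values) - names
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return ParameterSet(**values)  # type: ignore[arg-type]


def write_audit_csv(records: Iterable[ClosureRecord], path: str | Path) -> None:
    """Derivation audit: symbol, closure, derived, tabulated, relative diff."""
    lines = ["symbol,closure,derived,tabulated,rel_diff"]
    for r in records:
        tabulated = "" if r.tabulated is None else repr(r.tabulated)
        rd = "" if r.rel_diff is None else f"{r.rel_diff:.6g}"
        closure = r.closure.replace(",", ";")
        lines.append(f"{r.symbol},{closure},{r.derived!r},{tabulated},{rd}")
    Path(path).write_text("\n".join(lines) + "\n")
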