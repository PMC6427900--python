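"""Parameter table, steady-state closures, and organism variants."""

import math
from dataclasses import fields as dc_fields, replace

import pytest

from angiopd.params import (DegenerateClosureError, MissingParameterError,
                            ParameterSet, SpeciesBaselines, UNITS,
                            default_baselines, derive_secondary_parameters,
                            human_parameters, mouse_parameters,
                            protein_diffusion_coefficient, read_params,
                            species_variant, write_audit_csv, write_params)


def _derived(baselines=None):
    baselines = baselines or default_baselines()
    return derive_secondary_parameters(baselines, mouse_parameters())


# Printed table values the closures must reproduce to 3 significant figures.
PRINTED = [
    ("lam_T1I12", 11.65),
    ("lam_T8I12", 10.38),
    ("lam_TrG", 0.083),
    ("lam_TrTb", 0.415),
    ("lam_GW", 2.21e-6),
    ("lam_TbC", 3.27e-10),
    ("d_W", 1.04),
    ("eta_8", 60.375),
    ("eta_1", 30.19),
    ("mu_AP", 4.33e7),
    ("mu_PA", 4.33e7),
    ("mu_BG", 2.19e7),
    ("mu_GB", 1.31e8),
    ("Kp_TQ", 1.68e-18),
    ("delta_B", 4.70e-2),
    ("K_P1", 5.98e-10),
    ("K_P8", 2.74e-10),
    ("K_L", 3.86e-9),
    ("theta", 0.4064),
]


@pytest.mark.parametrize("symbol,printed", PRINTED)
def test_closures_reproduce_printed_values(symbol, printed):
    rec = _derived().record_map()[symbol]
    assert rec.derived == pytest.approx(printed, rel=5e-3)


def test_half_saturation_closure_equals_baselines(baselines):
    recs = _derived(baselines).record_map()
    for name, attr in [("K_D", "D"), ("K_T1", "T1"), ("K_T8", "T8"),
                       ("K_Tr", "Tr"), ("K_E", "E"), ("K_C", "C"),
                       ("K_I12", "I12"), ("K_I2", "I2"), ("K_Tb", "Tb"),
                       ("K_W", "W"), ("K_G", "G")]:
        assert recs[name].derived == getattr(baselines, attr)


def test_adjusted_rates_flagged_not_overwritten():
    """The tables deliberately raise lam_DC, lam_E (and lam_CW); the audit
    must report the raw derivation while the returned set keeps the table."""
    res = _derived()
    recs = res.record_map()
    assert recs["lam_DC"].derived == pytest.approx(5.0, rel=1e-6)
    assert recs["lam_DC"].rel_diff == pytest.approx(5.0 / 17.5 - 1.0, rel=1e-6)
    assert recs["lam_E"].derived == pytest.approx(1.98e7, rel=5e-3)
    assert res.params.lam_DC == 17.5
    assert res.params.lam_E == 2.77e7


def test_theta_recomputed_from_baselines(baselines):
    assert baselines.cell_total() == pytest.approx(0.4064, abs=1e-12)


def test_zero_balance_closures():
    """With all death rates and the ref-sourced cross-production rates set to
    zero, every activation-rate balance degenerates to zero."""
    prim = mouse_parameters().as_dict()
    for k in list(prim):
        if k.startswith("d_") or k in ("lam_T1I2", "lam_T8I2", "lam_TbTr", "lam_WE"):
            prim[k] = 0.0
    res = derive_secondary_parameters(default_baselines(), prim)
    recs = res.record_map()
    for sym in ("lam_DC", "lam_T1I12", "lam_T8I12", "lam_TrG", "lam_TrTb",
                "lam_TbC", "lam_GW", "d_W"):
        assert recs[sym].derived == 0.0


def test_idempotent_on_complete_set():
    first = _derived()
    second = derive_secondary_parameters(default_baselines(), first.params)
    for f in dc_fields(ParameterSet):
        if f.name == "organism":
            continue
        a, b = getattr(first.params, f.name), getattr(second.params, f.name)
        assert b == pytest.approx(a, rel=1e-12)


def test_missing_primary_raises():
    prim = mouse_parameters().as_dict()
    del prim["d_T1"]
    with pytest.raises(MissingParameterError):
        derive_secondary_parameters(default_baselines(), prim)


def test_degenerate_closure_raises():
    bad = SpeciesBaselines(C=default_baselines().C)
    bad = replace(bad, C=bad.C)  # frozen dataclass; rebuild with zero Tr/T_10
    prim = mouse_parameters().as_dict()
    prim["T_10"] = 0.0
    with pytest.raises(DegenerateClosureError):
        derive_secondary_parameters(default_baselines(), prim)


@pytest.mark.parametrize("mw,expected", [
    (24.0, 8.64e-2),
    (149.0, 4.70e-2),
    (192.0, 4.32e-2),  # cube root of 8 is 2
])
def test_protein_diffusion_scaling(mw, expected):
    assert protein_diffusion_coefficient(mw) == pytest.approx(expected, rel=2e-3)


def test_protein_diffusion_rejects_nonpositive_weight():
    with pytest.raises(ValueError):
        protein_diffusion_coefficient(0.0)


class TestSpeciesVariant:
    def test_mouse_values(self, mouse_params):
        assert mouse_params.lam_DC == 17.5
        assert mouse_params.K_PB == 1e-8

    def test_human_values(self, human_params):
        assert human_params.lam_DC == 7.5
        assert human_params.lam_E == 2.08e7
        assert human_params.lam_CW == 1.76
        assert human_params.K_PB == 1e-9

    def test_round_trip_only_touches_listed_fields(self, mouse_params):
        back = species_variant(species_variant(mouse_params, "human"), "mouse")
        for f in dc_fields(ParameterSet):
            assert getattr(back, f.name) == getattr(mouse_params, f.name), f.name

    def test_other_fields_unchanged(self, mouse_params, human_params):
        touched = {"organism", "lam_DC", "lam_E", "lam_CW", "K_PB", "K_B"}
        for f in dc_fields(ParameterSet):
            if f.name in touched:
                continue
            assert getattr(human_params, f.name) == getattr(mouse_params, f.name)

    def test_unknown_organism(self, mouse_params):
        with pytest.raises(ValueError):
            species_variant(mouse_params, "zebrafish")


class TestValidation:
    def test_canonical_sets_valid(self, mouse_params, human_params, baselines):
        mouse_params.validate(baselines)
        human_params.validate(baselines)

    @pytest.mark.parametrize("field,value", [
        ("eps_T", 1.5), ("d_C", -0.1), ("K_G", 1e-10), ("W_star", 1e-3),
    ])
    def test_invalid_values_rejected(self, field, value):
        p = replace(mouse_parameters(), **{field: value})
        with pytest.raises(ValueError):
            p.validate()

    def test_units_cover_every_field(self):
        names = {f.name for f in dc_fields(ParameterSet)}
        assert names <= set(UNITS)


def test_config_round_trip(tmp_path, human_params):
    path = tmp_path / "human.params"
    write_params(human_params, path)
    back = read_params(path)
    for f in dc_fields(ParameterSet):
        assert getattr(back, f.name) == getattr(human_params, f.name)


def test_shipped_configs_match_canonical(tmp_path):
    from importlib.resources import files
    import angiopd
    for organism, canonical in [("mouse", mouse_parameters()),
                                ("human", human_parameters())]:
        cfg = files(angiopd) / "data" / f"{organism}.params"
        tmp = tmp_path / f"{organism}.params"
        tmp.write_text(cfg.read_text())
        back = read_params(tmp)
        for f in dc_fields(ParameterSet):
            assert getattr(back, f.name) == getattr(canonical, f.name)


def test_audit_csv(tmp_path):
    res = _derived()
    path = tmp_path / "audit.csv"
    write_audit_csv(res.records, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "symbol,closure,derived,tabulated,rel_diff"
    assert len(lines) == len(res.records) + 1
    assert any(line.startswith("Kp_TQ,") for line in lines)
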