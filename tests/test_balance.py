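import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cobalance import (
    BalanceError,
    BottleBalance,
    balance_report,
    carbon_recovery,
    electron_recovery,
    read_bottles_csv,
    write_recovery_tsv,
)

ROW1 = "2 mL/dose CO"
ROW2 = "5 mL/dose CO"


@pytest.mark.parametrize(
    "row, carbon, electron",
    [(ROW1, 61.9, 116.4), (ROW2, 50.7, 100.4)],
)
def test_published_bottle_rows(row, carbon, electron, table2_bottles):
    """Carbon (CO₂ excluded) and γ-electron recoveries of the two CO-fed
    bottle inventories reproduce the published percentages exactly."""
    b = table2_bottles[row]
    assert carbon_recovery(b) == carbon
    assert electron_recovery(b) == electron


def test_report_totals_for_low_dose_row(table2_bottles):
    r = balance_report(table2_bottles[ROW1])
    assert r.carbon_in == pytest.approx(647.8)    # 571.4*1 + 38.2*2
    assert r.carbon_out == pytest.approx(400.8)   # 3.2 + 28.7*2 + 170.1*2
    assert r.electrons_in == pytest.approx(1486.6)
    assert r.electrons_out == pytest.approx(1730.8)
    # percentage consistent with raw totals
    assert r.electron_recovery_pct == pytest.approx(
        100 * r.electrons_out / r.electrons_in, abs=0.05
    )


def test_empty_products_give_zero_carbon_recovery(registry, table2_bottles):
    b = BottleBalance("none", dict(table2_bottles[ROW1].substrates), {})
    assert carbon_recovery(b) == 0.0


@given(st.floats(min_value=0.01, max_value=1e5))
@settings(deadline=None, max_examples=30)
def test_hydrogen_identity_is_100_percent(registry, x):
    """Substrate H₂ fully recovered as product H₂ is 100.0 % for any x."""
    sub = {registry["H2"]: x}
    prod = {registry["CH4"]: x / 4}  # γ(CH4)=8=4·γ(H2): electron-equivalent
    b = BottleBalance("id", sub, prod)
    assert electron_recovery(b) == 100.0
    # untouched H2 counted as residual closes at 100 % too
    b2 = BottleBalance("id", sub, {}, residuals={registry["H2"]: x})
    assert electron_recovery(b2, include_residuals=True) == 100.0


@given(st.floats(min_value=1e-3, max_value=1e3))
@settings(deadline=None, max_examples=30)
def test_recoveries_invariant_under_uniform_rescaling(table2_bottles, scale):
    b = table2_bottles[ROW1]
    scaled = BottleBalance(
        b.treatment,
        {c: v * scale for c, v in b.substrates.items()},
        {c: v * scale for c, v in b.products.items()},
    )
    assert carbon_recovery(scaled) == carbon_recovery(b)
    assert electron_recovery(scaled) == electron_recovery(b)


def test_co2_excluded_by_default_but_includable(registry):
    sub = {registry["CO"]: 100.0}
    prod = {registry["CO2"]: 60.0, registry["acetate"]: 10.0}
    b = BottleBalance("x", sub, prod)
    assert carbon_recovery(b) == 20.0                      # acetate only
    assert carbon_recovery(b, include_co2=True) == 80.0    # CO2 counted


def test_zero_substrate_carbon_errors(registry):
    b = BottleBalance("x", {registry["H2"]: 5.0}, {registry["CH4"]: 1.0})
    with pytest.raises(BalanceError, match="carbon"):
        carbon_recovery(b)


def test_invalid_inventories_rejected(registry):
    with pytest.raises(BalanceError, match="negative"):
        BottleBalance("x", {registry["CO"]: -1.0}, {})
    with pytest.raises(BalanceError, match="both sides"):
        BottleBalance(
            "x", {registry["CO"]: 1.0}, {registry["CO"]: 1.0}
        )


def test_empty_bottle_report_errors(registry):
    with pytest.raises(BalanceError, match="empty"):
        balance_report(BottleBalance("x", {registry["CO"]: 1.0}, {}))


def test_csv_roundtrip_and_errors(tmp_path, registry, table2_bottles):
    p = tmp_path / "bottles.csv"
    p.write_text(
        "treatment,role,species,umol\n"
        "t,substrate,CO,100\n"
        "t,product,CH3COOH,10\n"
    )
    (b,) = read_bottles_csv(p, registry)
    assert carbon_recovery(b) == 20.0

    out = tmp_path / "recovery.tsv"
    write_recovery_tsv([balance_report(b)], out)
    assert "20.0" in out.read_text()

    p.write_text("treatment,role,species,umol\n")
    with pytest.raises(BalanceError, match="no records"):
        read_bottles_csv(p, registry)

    p.write_text("treatment,role,species,umol\nt,substrate,mystery,1\n")
    with pytest.raises(BalanceError, match="mystery"):
        read_bottles_csv(p, registry)

    p.write_text("treatment,role,species,umol\nt,meal,CO,1\n")
    with pytest.raises(BalanceError, match="role"):
        read_bottles_csv(p, registry)
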