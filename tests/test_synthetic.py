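import numpy as np
import pandas as pd
import pytest

from cobalance import (
    BalanceError,
    balance_report,
    carbon_recovery,
    electron_recovery,
    gas_volume_to_umol,
)
from cobalance.synthetic_data import SimConfig, make_table2_like, simulate_bottle

CARBONS = {"CO": 1, "CO2": 1, "H2": 0, "acetate": 2, "CH4": 1,
           "TCE": 2, "cDCE": 2, "VC": 2, "ethene": 2, "HCl": 0}
GAMMAS = {"CO": 2, "CO2": 0, "H2": 2, "acetate": 8, "CH4": 8,
          "TCE": 9, "cDCE": 10, "VC": 11, "ethene": 12, "HCl": 1}


def short_cfg(**kw):
    from cobalance import DoseSchedule

    defaults = dict(
        schedule=DoseSchedule.regular(2, 2.0, interval_days=5.0),
        duration_days=15.0,
        noise_sd=0.0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def test_same_seed_is_bit_identical():
    cfg = short_cfg(noise_sd=0.1, seed=42)
    a, b = simulate_bottle(cfg), simulate_bottle(cfg)
    pd.testing.assert_frame_equal(a.true.frame, b.true.frame)
    pd.testing.assert_frame_equal(a.noisy.frame, b.noisy.frame)
    assert a.fluxes == b.fluxes
    # a different seed perturbs only the measurement layer
    c = simulate_bottle(short_cfg(noise_sd=0.1, seed=43))
    pd.testing.assert_frame_equal(a.true.frame, c.true.frame)
    assert not a.noisy.frame.equals(c.noisy.frame)


def test_carbon_and_electrons_conserved_at_every_timepoint(clean_sim):
    """Dose-corrected total carbon and total γ-electrons over all pools are
    constant along the whole trajectory, parameter-free."""
    pf = clean_sim.pools_frame
    cfg = clean_sim.config
    tot_c = sum(pf[p] * w for p, w in CARBONS.items())
    tot_e = sum(pf[p] * w for p, w in GAMMAS.items())
    dosed = np.array(
        [
            sum(gas_volume_to_umol(d) for t, d in cfg.schedule.entries if t < st)
            for st in pf["time_d"]
        ]
    )
    assert np.abs(tot_c - dosed - tot_c.iloc[0]).max() < 1e-6
    assert np.abs(tot_e - 2 * dosed - tot_e.iloc[0]).max() < 1e-6


def test_run_to_completion_converts_all_tce_to_ethene(clean_sim):
    f = clean_sim.final_pools
    assert f["ethene"] == pytest.approx(
        clean_sim.config.initial_tce_umol, rel=1e-3
    )


def test_noise_free_electron_recovery_closes_at_100(clean_sim):
    """With residuals and CO₂ counted, the independently implemented
    recovery statistic returns 100 % on the simulator's true inventory —
    every simulated reaction conserves γ-electrons."""
    full = clean_sim.full_balance()
    er = electron_recovery(full, include_co2=True, include_residuals=True)
    assert abs(er - 100.0) <= 0.5
    cr = carbon_recovery(full, include_co2=True, include_residuals=True)
    assert abs(cr - 100.0) <= 0.5


def test_table2_like_balance_shortfall_is_the_co2_share(clean_sim):
    bal = make_table2_like(clean_sim)
    assert carbon_recovery(bal) < 100.0
    assert (
        carbon_recovery(bal, include_co2=True, include_residuals=True)
        == pytest.approx(100.0, abs=0.5)
    )


def test_methanogenesis_option_produces_methane():
    res = simulate_bottle(short_cfg(k_me=0.05))
    bal = make_table2_like(res)
    assert any(c.name == "CH4" and v > 0 for c, v in bal.products.items())
    base = simulate_bottle(short_cfg())
    assert base.final_pools["CH4"] == 0.0


def test_zero_rate_config_yields_empty_products():
    res = simulate_bottle(
        short_cfg(k_co=0.0, k_tce=0.0, k_cdce=0.0, k_vc=0.0, k_ac=0.0)
    )
    bal = make_table2_like(res)
    assert not bal.products
    with pytest.raises(BalanceError):
        balance_report(bal)


def test_h2_accumulates_only_after_vc_dominates(clean_sim):
    """H₂ stays near its dechlorination-limited floor while TCE/cDCE are
    being respired and rises >10× only once VC is the dominant
    chloroethene — the stage-specific pattern of CO-fed bottles."""
    tc = clean_sim.true
    t = tc.times
    h2 = tc.amounts("H2")
    vc = tc.amounts("VC")
    dominant = (vc > tc.amounts("TCE")) & (vc > tc.amounts("cDCE"))
    t_vc = t[np.argmax(dominant)]
    pre = h2[(t > 0) & (t < t_vc)]
    baseline = np.median(pre)
    assert baseline > 0
    acc_times = t[h2 > 10 * baseline]
    assert len(acc_times) > 0
    assert (acc_times >= t_vc).all()


def test_measurement_noise_matches_configured_sd():
    cfg = SimConfig(noise_sd=0.1, sample_every=0.25, seed=7)
    res = simulate_bottle(cfg)
    rel = []
    for s in res.true.species:
        truth = res.true.amounts(s)
        noisy = res.noisy.amounts(s)
        keep = truth > 0.5  # far from the zero-truncation boundary
        rel.extend(((noisy[keep] - truth[keep]) / truth[keep]).tolist())
    assert len(rel) >= 1000
    sd = float(np.std(rel))
    assert 0.07 <= sd <= 0.13  # noise_sd +/- 30 %


def test_config_validation():
    with pytest.raises(ValueError, match="k_co"):
        SimConfig(k_co=-1.0)
    with pytest.raises(ValueError, match="dt"):
        SimConfig(dt=0.0)
    with pytest.raises(ValueError, match="fraction"):
        SimConfig(co_to_acetate_fraction=1.5)


def test_result_files_are_consumable(tmp_path, registry):
    from cobalance import read_bottles_csv

    res = simulate_bottle(short_cfg(noise_sd=0.05))
    paths = res.write(tmp_path / "bottle")
    assert [p.name for p in paths] == [
        "bottle_noisy.csv", "bottle_true.csv", "bottle_balance.csv"
    ]
    (b,) = read_bottles_csv(paths[2], registry)
    assert carbon_recovery(b, include_co2=True, include_residuals=True) == (
        pytest.approx(100.0, abs=0.5)
    )
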