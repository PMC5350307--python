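"""Unit and property tests of the core flux equations and the Euler loop."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reedcarbon import (
    ModelParameters,
    ModelState,
    ParameterError,
    arrhenius_factor,
    carrying_capacity,
    compute_fluxes,
    dagu_to_depth,
    generate_forcing,
    mortality_and_decay_fluxes,
    photosynthesis_flux,
    react_flux,
    respiration_fluxes,
    simulate,
    step,
    transfer_flux,
)

P = ModelParameters()


@pytest.mark.parametrize(
    "theta, temp, expected",
    [
        (1.05, 20.0, 1.0),
        (1.09, 30.0, 2.367363674592119),
        (1.07, 10.0, 0.5083492921347176),
    ],
)
def test_arrhenius_factor_values(theta, temp, expected):
    assert arrhenius_factor(theta, temp) == pytest.approx(expected, rel=1e-12)


def test_arrhenius_rejects_nonpositive_theta():
    with pytest.raises(ParameterError):
        arrhenius_factor(0.0, 25.0)


@given(st.floats(min_value=1.0 + 1e-6, max_value=1.2), st.floats(-10, 40), st.floats(0.01, 5))
@settings(max_examples=50, deadline=None)
def test_arrhenius_increasing_in_temperature(theta, temp, dtemp):
    assert arrhenius_factor(theta, temp + dtemp) > arrhenius_factor(theta, temp)


@pytest.mark.parametrize(
    "depth, expected",
    [
        (0.8, 2450.0),
        (0.0, 2450.0 * 1.4 / 1.8),
        (1.6, 2450.0 * 1.4 / 1.8),
        (1.8, 2450.0 * 1.3 / 1.8),
    ],
)
def test_carrying_capacity_values(depth, expected):
    assert carrying_capacity(depth, P) == pytest.approx(expected, rel=1e-12)


def test_carrying_capacity_rejects_negative_depth():
    with pytest.raises(ValueError):
        carrying_capacity(-0.1, P)


@given(st.floats(min_value=0.0, max_value=0.8))
@settings(max_examples=100, deadline=None)
def test_carrying_capacity_symmetric_about_optimum(d):
    """CarryaC(depth_opt + d) == CarryaC(depth_opt − d), max at the optimum."""
    lo = carrying_capacity(P.depth_opt - d, P)
    hi = carrying_capacity(P.depth_opt + d, P)
    assert lo == pytest.approx(hi, rel=1e-12)
    assert lo <= carrying_capacity(P.depth_opt, P)


def test_carrying_capacity_floor_at_extreme_depth():
    # a depth far beyond the tent's zero crossing must still be >= the floor
    assert carrying_capacity(10.0, P) >= 1.0


def test_photosynthesis_zero_at_capacity():
    cc = carrying_capacity(0.5, P)
    s = ModelState(pac=cc, pbc=0.0)
    assert photosynthesis_flux(s, 25.0, 14.67, 400.0, 0.5, P) == pytest.approx(0.0, abs=1e-9)


def test_photosynthesis_co2_half_saturation():
    """At 300 ppm the CO₂ factor is exactly one half, whatever else varies."""
    s = ModelState(pac=100.0, pbc=0.0)
    full = photosynthesis_flux(s, 17.0, 9.0, 300.0, 0.6, P)
    # doubling the CO2 factor by hand: flux / 0.5 must equal flux with factor 1
    rad = 9.0 / (9.0 + 6.0)
    arr = 1.09 ** (17.0 - 20.0)
    cc = carrying_capacity(0.6, P)
    assert full == pytest.approx(0.5 * rad * arr * 100.0 * (1 - 100.0 / cc), rel=1e-12)


def test_photosynthesis_hand_value():
    s = ModelState(pac=103.0, pbc=1650.0)
    flux = photosynthesis_flux(s, 20.0, 14.67, 400.0, 0.8, P)
    assert flux == pytest.approx(40.01619755677514, rel=1e-12)


@pytest.mark.parametrize(
    "pac, temp, expected",
    [(0.0, 25.0, 0.0), (103.0, 20.0, 20.6), (100.0, 30.0, 39.34302714579133)],
)
def test_transfer_flux_values(pac, temp, expected):
    assert transfer_flux(ModelState(pac, 0.0), temp, P) == pytest.approx(expected, rel=1e-12)


def test_react_flux_values():
    assert react_flux(ModelState(0.0, 0.0), 25.0, P) == 0.0
    assert react_flux(ModelState(0.0, 1650.0), 20.0, P) == pytest.approx(1650 * P.reratio)
    assert react_flux(ModelState(0.0, 1650.0), 10.0, P) == pytest.approx(
        838.776332022284 * P.reratio, rel=1e-12
    )


def test_react_window_gate():
    gated = P.replace(react_window_end=60)
    s = ModelState(0.0, 1000.0)
    assert react_flux(s, 20.0, gated, day_index=60) > 0
    assert react_flux(s, 20.0, gated, day_index=61) == 0.0
    # no day index or no window: flux applies
    assert react_flux(s, 20.0, gated) > 0
    assert react_flux(s, 20.0, P, day_index=200) > 0


def test_respiration_values():
    assert respiration_fluxes(ModelState(0.0, 0.0), 30.0, P) == (0.0, 0.0)
    ra, rb = respiration_fluxes(ModelState(100.0, 1000.0), 20.0, P)
    assert ra == pytest.approx(100 * P.mrespiratio_pa)
    assert rb == pytest.approx(1000 * P.mrespiratio_pb)
    _, rb25 = respiration_fluxes(ModelState(0.0, 1000.0), 25.0, P)
    assert rb25 == pytest.approx(1538.6239549 * P.mrespiratio_pb, rel=1e-9)


def test_mortality_and_decay_values():
    assert mortality_and_decay_fluxes(ModelState(0.0, 0.0), 15.0, P) == (0.0, 0.0, 0.0)
    mpa, dpa, mpb = mortality_and_decay_fluxes(ModelState(100.0, 1650.0), 20.0, P)
    assert mpa == pytest.approx(0.1)
    assert dpa == pytest.approx(0.5)
    assert mpb == pytest.approx(1.65)


@given(st.floats(0.1, 2000.0), st.floats(0.1, 5000.0), st.floats(-5, 35))
@settings(max_examples=50, deadline=None)
def test_first_order_fluxes_linear_in_stock(pac, pbc, temp):
    """Doubling a stock doubles every first-order flux drawn from it."""
    s1 = ModelState(pac, pbc)
    s2 = ModelState(2 * pac, 2 * pbc)
    assert transfer_flux(s2, temp, P) == pytest.approx(2 * transfer_flux(s1, temp, P))
    assert react_flux(s2, temp, P) == pytest.approx(2 * react_flux(s1, temp, P))
    for a, b in zip(respiration_fluxes(s1, temp, P), respiration_fluxes(s2, temp, P)):
        assert b == pytest.approx(2 * a)
    for a, b in zip(
        mortality_and_decay_fluxes(s1, temp, P), mortality_and_decay_fluxes(s2, temp, P)
    ):
        assert b == pytest.approx(2 * a)


def test_step_identity_with_zero_rates():
    frozen = ModelParameters(
        transratio=0.0,
        reratio=0.0,
        mrespiratio_pa=0.0,
        mrespiratio_pb=0.0,
        mortalrate_pa=0.0,
        decayrate_pa=0.0,
        mortalrate_pb=0.0,
    )
    s0 = ModelState(200.0, 1000.0)
    s1, f = step(s0, 25.0, 0.0, 400.0, 0.8, frozen)  # zero radiation: no photosynthesis
    assert s1 == s0
    assert all(v == 0.0 for v in f)


def test_step_hand_ledger():
    """One Euler day from the initial stocks, each flux hand-summed."""
    s1, _ = step(ModelState(103.0, 1650.0), 20.0, 14.67, 400.0, 0.8, P)
    assert s1.pac == pytest.approx(129.53319755677515, rel=1e-12)
    assert s1.pbc == pytest.approx(1652.45, rel=1e-12)


@given(st.floats(1.0, 2400.0), st.floats(1.0, 5000.0), st.floats(-5, 35), st.floats(0, 1.8))
@settings(max_examples=50, deadline=None)
def test_step_mass_balance(pac, pbc, temp, depth):
    """Δ(pac+pbc) equals the boundary fluxes; transfer and react cancel."""
    s0 = ModelState(pac, pbc)
    s1, f = step(s0, temp, 14.67, 400.0, depth, P)
    boundary = f.photosynthesis - f.respir_pa - f.respir_pb - f.decay_pa - f.mortal_pa - f.mortal_pb
    assert (s1.pac + s1.pbc) - (pac + pbc) == pytest.approx(boundary, rel=1e-9, abs=1e-9)


def test_step_clamps_negative_stocks():
    greedy = P.replace(transratio=0.35, mrespiratio_pa=0.05, decayrate_pa=0.18, mortalrate_pa=0.15)
    s1, _ = step(ModelState(1.0, 0.0), 35.0, 0.0, 400.0, 0.8, greedy)
    assert s1.pac == 0.0 and s1.pbc >= 0.0


def naive_euler(params, forcing):
    """Independent oracle: the printed equations coded directly, no reuse."""
    pac, pbc = params.pac_init, params.pbc_init
    out = []
    for row in forcing.itertuples(index=False):
        T = row.air_temperature_c
        cc = params.carrya_max * (
            params.waterdepth_max - abs(row.water_depth_m - params.depth_opt) / 2
        ) / params.waterdepth_max
        cc = max(cc, 1.0)
        photo = (
            (row.co2_ppm / (row.co2_ppm + params.k_co2))
            * (row.radiation_mj_m2_d / (row.radiation_mj_m2_d + params.k_rad))
            * params.theta_photo ** (T - 20)
            * pac * (1 - pac / cc)
        )
        trans = params.transratio * pac * params.theta_transfer ** (T - 20)
        react = params.reratio * pbc * params.theta_react ** (T - 20)
        respa = params.mrespiratio_pa * pac * params.theta_respa ** (T - 20)
        respb = params.mrespiratio_pb * pbc * params.theta_respb ** (T - 20)
        mpa = params.mortalrate_pa * pac * params.theta_mortal_a ** (T - 20)
        dpa = params.decayrate_pa * pac * params.theta_decay ** (T - 20)
        mpb = params.mortalrate_pb * pbc * params.theta_mortal_b ** (T - 20)
        pac = pac + (photo + react - trans - respa - dpa - mpa)
        pbc = pbc + (trans - react - respb - mpb)
        pac, pbc = max(pac, 0.0), max(pbc, 0.0)
        out.append((pac, pbc))
    return out


def test_simulate_matches_naive_oracle(default_params, default_forcing):
    traj = simulate(default_params, default_forcing)
    oracle = naive_euler(default_params, default_forcing)
    np.testing.assert_array_equal(traj["pac_gc_m2"].to_numpy(), [a for a, _ in oracle])
    np.testing.assert_array_equal(traj["pbc_gc_m2"].to_numpy(), [b for _, b in oracle])


def test_simulate_zero_length_window(default_params, default_forcing):
    empty = default_forcing.iloc[0:0]
    assert len(simulate(default_params, empty)) == 0


def test_simulate_reports_forcing_gap(default_params, default_forcing):
    gappy = pd.concat([default_forcing.iloc[:10], default_forcing.iloc[12:]])
    with pytest.raises(ValueError, match="gap"):
        simulate(default_params, gappy)


def test_simulate_rejects_bad_dt(default_params, default_forcing):
    with pytest.raises(ValueError):
        simulate(default_params, default_forcing, dt=0.3)
    with pytest.raises(ValueError):
        step(ModelState(1.0, 1.0), 20.0, 10.0, 400.0, 0.8, default_params, dt=-1.0)


@pytest.mark.parametrize("level, depth", [(6.5, 0.0), (7.3, 0.8), (8.6, 2.1)])
def test_dagu_level_conversion(level, depth):
    assert dagu_to_depth(level) == pytest.approx(depth)


def test_dagu_below_datum_rejected():
    with pytest.raises(ValueError):
        dagu_to_depth(6.4)
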