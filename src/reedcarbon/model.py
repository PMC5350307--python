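"""Two-compartment daily carbon-stock model of a Phragmites australis stand.

State variables are the aboveground (shoot) carbon stock ``pac`` and the
belowground (rhizome/root) carbon stock ``pbc``, both in gC m⁻².  The shoot
pool grows by photosynthesis — a logistic term whose carrying capacity is a
tent-shaped function of water depth — and by early-season reactivation of
rhizome reserves; it loses carbon to translocation belowground, respiration,
mortality and standing-litter decay.  The rhizome pool gains the translocated
carbon and loses respiration, reactivation and mortality.  Every process rate
is first-order in its source stock and scaled by an Arrhenius factor
θ^(T − 20 °C).

Integration is explicit (forward) Euler with a default step of one day, the
scheme the state-update equations are written in.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd

from .params import ModelParameters, ParameterError

logger = logging.getLogger(__name__)

#: Floor applied to the carrying capacity (gC m⁻²) so the logistic factor
#: never divides by zero at extreme depths.
CARRYA_FLOOR = 1.0

#: Dagu-datum water level (m) at which the local water depth is zero.
DAGU_ZERO_DEPTH_LEVEL = 6.5

#: Simulation window: April 1 – October 31 inclusive, 214 days.
SEASON_DAYS = 214

FORCING_COLUMNS = (
    "date",
    "air_temperature_c",
    "radiation_mj_m2_d",
    "co2_ppm",
    "water_depth_m",
)


class ModelState(NamedTuple):
    """Instantaneous stocks, gC m⁻²."""

    pac: float
    pbc: float


class FluxSet(NamedTuple):
    """Instantaneous process fluxes, gC m⁻² d⁻¹."""

    photosynthesis: float
    transfer: float
    react: float
    respir_pa: float
    respir_pb: float
    mortal_pa: float
    decay_pa: float
    mortal_pb: float


def arrhenius_factor(theta: float, temperature: float) -> float:
    """Temperature correction θ^(T − 20) applied to every process rate.

    Parameters
    ----------
    theta
        Arrhenius base (dimensionless, > 0).  Values above 1 make the
        process accelerate with warming.
    temperature
        Air temperature, °C.
    """
    if theta <= 0:
        raise ParameterError("Arrhenius base theta must be positive")
    return float(theta) ** (temperature - 20.0)


def carrying_capacity(
    water_depth: float | np.ndarray, params: ModelParameters | None = None
) -> float | np.ndarray:
    """Environmental carrying capacity of the shoot stock at a water depth.

    A tent function peaking at the suitable growth depth::

        CarryaC(d) = carrya_max * (waterdepth_max - |d - depth_opt| / 2)
                     / waterdepth_max

    which equals ``carrya_max`` exactly at ``depth_opt`` and declines
    linearly and symmetrically on either side.  The result is floored at
    ``CARRYA_FLOOR`` (1 gC m⁻²) so downstream logistic terms stay finite.

    Accepts a scalar or an array of depths (m, non-negative).
    """
    params = params or ModelParameters()
    d = np.asarray(water_depth, dtype=float)
    if np.any(d < 0):
        raise ValueError("water depth must be non-negative")
    cc = (
        params.carrya_max
        * (params.waterdepth_max - np.abs(d - params.depth_opt) / 2.0)
        / params.waterdepth_max
    )
    cc = np.maximum(cc, CARRYA_FLOOR)
    return float(cc) if np.isscalar(water_depth) else cc


def co2_limitation(co2: float, params: ModelParameters | None = None) -> float:
    """Michaelis–Menten CO₂ limitation factor co2/(co2 + k_co2) ∈ (0, 1)."""
    k = (params or ModelParameters()).k_co2
    return co2 / (co2 + k)


def radiation_limitation(rad: float, params: ModelParameters | None = None) -> float:
    """Michaelis–Menten light limitation factor rad/(rad + k_rad) ∈ [0, 1)."""
    k = (params or ModelParameters()).k_rad
    return rad / (rad + k)


def photosynthesis_flux(
    state: ModelState,
    temperature: float,
    radiation: float,
    co2: float,
    water_depth: float,
    params: ModelParameters,
) -> float:
    """Gross shoot carbon gain, gC m⁻² d⁻¹.

    Product of CO₂ and light Michaelis–Menten factors, the Arrhenius
    factor, the shoot stock and the logistic brake (1 − pac/CarryaC).
    Zero at pac = 0 and at pac = CarryaC; negative only above capacity.
    """
    cc = carrying_capacity(water_depth, params)
    return (
        co2_limitation(co2, params)
        * radiation_limitation(radiation, params)
        * arrhenius_factor(params.theta_photo, temperature)
        * state.pac
        * (1.0 - state.pac / cc)
    )


def transfer_flux(state: ModelState, temperature: float, params: ModelParameters) -> float:
    """Shoot→rhizome translocation, first-order in the shoot stock."""
    return params.transratio * state.pac * arrhenius_factor(params.theta_transfer, temperature)


def react_flux(
    state: ModelState,
    temperature: float,
    params: ModelParameters,
    day_index: int | None = None,
) -> float:
    """Rhizome→shoot reactivation, first-order in the rhizome stock.

    Reactivation remobilises rhizome reserves to fuel shoot emergence.  It
    applies year-round by default; if ``params.react_window_end`` is set,
    the flux is zero once ``day_index`` passes that day (an optional
    early-season gate, off by default).
    """
    if (
        params.react_window_end is not None
        and day_index is not None
        and day_index > params.react_window_end
    ):
        return 0.0
    return params.reratio * state.pbc * arrhenius_factor(params.theta_react, temperature)


def respiration_fluxes(
    state: ModelState, temperature: float, params: ModelParameters
) -> tuple[float, float]:
    """Maintenance respiration of (shoot, rhizome), gC m⁻² d⁻¹.

    The rhizome pool uses a steeper Arrhenius base (1.09) than the shoot
    pool (1.07).
    """
    respir_pa = (
        params.mrespiratio_pa * state.pac * arrhenius_factor(params.theta_respa, temperature)
    )
    respir_pb = (
        params.mrespiratio_pb * state.pbc * arrhenius_factor(params.theta_respb, temperature)
    )
    return respir_pa, respir_pb


def mortality_and_decay_fluxes(
    state: ModelState, temperature: float, params: ModelParameters
) -> tuple[float, float, float]:
    """(shoot mortality, standing-litter decay, rhizome mortality) fluxes."""
    mortal_pa = (
        params.mortalrate_pa * state.pac * arrhenius_factor(params.theta_mortal_a, temperature)
    )
    decay_pa = (
        params.decayrate_pa * state.pac * arrhenius_factor(params.theta_decay, temperature)
    )
    mortal_pb = (
        params.mortalrate_pb * state.pbc * arrhenius_factor(params.theta_mortal_b, temperature)
    )
    return mortal_pa, decay_pa, mortal_pb


def compute_fluxes(
    state: ModelState,
    temperature: float,
    radiation: float,
    co2: float,
    water_depth: float,
    params: ModelParameters,
    day_index: int | None = None,
) -> FluxSet:
    """Evaluate all eight process fluxes at the given state and forcing."""
    respir_pa, respir_pb = respiration_fluxes(state, temperature, params)
    mortal_pa, decay_pa, mortal_pb = mortality_and_decay_fluxes(state, temperature, params)
    return FluxSet(
        photosynthesis=photosynthesis_flux(
            state, temperature, radiation, co2, water_depth, params
        ),
        transfer=transfer_flux(state, temperature, params),
        react=react_flux(state, temperature, params, day_index),
        respir_pa=respir_pa,
        respir_pb=respir_pb,
        mortal_pa=mortal_pa,
        decay_pa=decay_pa,
        mortal_pb=mortal_pb,
    )


def step(
    state: ModelState,
    temperature: float,
    radiation: float,
    co2: float,
    water_depth: float,
    params: ModelParameters,
    dt: float = 1.0,
    day_index: int | None = None,
) -> tuple[ModelState, FluxSet]:
    """One forward-Euler update of both stocks.

    Shoot balance:    +photosynthesis +react −transfer −respir_pa
                      −decay_pa −mortal_pa
    Rhizome balance:  +transfer −react −respir_pb −mortal_pb

    Translocation and reactivation are internal exchanges and cancel in
    the whole-plant balance.  Stocks are clamped at zero (with a logged
    warning) if a step would drive them negative.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    f = compute_fluxes(state, temperature, radiation, co2, water_depth, params, day_index)
    pac = state.pac + dt * (
        f.photosynthesis + f.react - f.transfer - f.respir_pa - f.decay_pa - f.mortal_pa
    )
    pbc = state.pbc + dt * (f.transfer - f.react - f.respir_pb - f.mortal_pb)
    if pac < 0 or pbc < 0:
        logger.warning(
            "stock clamped at zero (pac=%.3g, pbc=%.3g) on day %s", pac, pbc, day_index
        )
        pac = max(pac, 0.0)
        pbc = max(pbc, 0.0)
    return ModelState(pac, pbc), f


def validate_forcing(forcing: pd.DataFrame) -> pd.DataFrame:
    """Check a forcing frame for required columns and daily continuity."""
    missing = [c for c in FORCING_COLUMNS if c not in forcing.columns]
    if missing:
        raise ValueError(f"forcing is missing column(s): {', '.join(missing)}")
    dates = pd.to_datetime(forcing["date"])
    if len(dates) > 1:
        gaps = dates.diff().iloc[1:]
        bad = gaps[gaps != pd.Timedelta(days=1)]
        if not bad.empty:
            first = dates.iloc[bad.index[0] - 1].date()
            raise ValueError(f"forcing has a gap or disorder after {first}")
    if (forcing["radiation_mj_m2_d"] < 0).any():
        raise ValueError("radiation must be non-negative")
    if (forcing["co2_ppm"] <= 0).any():
        raise ValueError("CO2 concentration must be positive")
    if (forcing["water_depth_m"] < 0).any():
        raise ValueError("water depth must be non-negative")
    return forcing


def simulate(
    params: ModelParameters, forcing: pd.DataFrame, dt: float = 1.0
) -> pd.DataFrame:
    """Run the model over a daily forcing series.

    Parameters
    ----------
    params
        Model constants; the run starts from ``(pac_init, pbc_init)``.
    forcing
        Daily frame with columns ``date, air_temperature_c,
        radiation_mj_m2_d, co2_ppm, water_depth_m`` and no calendar gaps.
    dt
        Euler step in days.  Must divide one day evenly (1, 0.5, 0.25 …);
        forcing is held constant within each day.

    Returns
    -------
    pandas.DataFrame
        One row per forcing day: ``day_index``, ``date``, end-of-day
        stocks ``pac_gc_m2`` / ``pbc_gc_m2``, the carrying capacity
        ``carrya_gc_m2``, and the day-mean of each process flux (so that
        Δstock over the day equals the signed flux sum exactly).
    """
    validate_forcing(forcing)
    n_sub = round(1.0 / dt)
    if n_sub < 1 or abs(n_sub * dt - 1.0) > 1e-9:
        raise ValueError("dt must evenly divide one day")
    sub_dt = 1.0 / n_sub

    state = ModelState(params.pac_init, params.pbc_init)
    records: list[dict] = []
    for day_index, row in enumerate(forcing.itertuples(index=False)):
        flux_acc = np.zeros(len(FluxSet._fields))
        for _ in range(n_sub):
            state, f = step(
                state,
                row.air_temperature_c,
                row.radiation_mj_m2_d,
                row.co2_ppm,
                row.water_depth_m,
                params,
                dt=sub_dt,
                day_index=day_index,
            )
            flux_acc += np.asarray(f)
        mean_flux = flux_acc / n_sub
        rec = {
            "day_index": day_index,
            "date": row.date,
            "pac_gc_m2": state.pac,
            "pbc_gc_m2": state.pbc,
            "carrya_gc_m2": carrying_capacity(row.water_depth_m, params),
        }
        rec.update(dict(zip(FluxSet._fields, mean_flux)))
        records.append(rec)
    columns = [
        "day_index",
        "date",
        "pac_gc_m2",
        "pbc_gc_m2",
        "carrya_gc_m2",
        *FluxSet._fields,
    ]
    return pd.DataFrame(records, columns=columns)


def dagu_to_depth(dagu_level: float) -> float:
    """Convert a Dagu-datum water level (m) to local water depth (m).

    The Dagu datum is the 1902 Tanggu tide-gauge zero; a level of 6.5 m
    corresponds to zero local water depth, so depth = level − 6.5.
    Levels below the datum are outside the model's domain.
    """
    if dagu_level < DAGU_ZERO_DEPTH_LEVEL:
        raise ValueError(
            f"Dagu level {dagu_level} m is below the zero-depth datum "
            f"({DAGU_ZERO_DEPTH_LEVEL} m)"
        )
    return dagu_level - DAGU_ZERO_DEPTH_LEVEL


def write_trajectory_csv(trajectory: pd.DataFrame, path) -> None:
    """Write a trajectory frame to CSV with ISO-8601 dates."""
    out = trajectory.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
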