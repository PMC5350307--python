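"""Synthetic daily forcing for a temperate continental monsoon growing season.

The generator emulates the drivers the model needs over April 1 – October 31
(214 days): air temperature as an annual sinusoid peaking in mid-July plus
Gaussian noise, constant daily solar radiation and CO₂, and a water-depth
series built from a base depth plus stepwise management segments (the
water-transfer policies under study).  Real meteorology differs in having
autocorrelated weather, variable cloudiness and a CO₂ seasonal cycle; none
of those matter to the first-order process structure being exercised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import FORCING_COLUMNS, SEASON_DAYS, validate_forcing

logger = logging.getLogger(__name__)

#: Calendar year used for the simulation window (non-leap).
DEFAULT_YEAR = 2009


@dataclass(frozen=True)
class SyntheticForcingSpec:
    """Parameters of the synthetic forcing generator.

    ``t_mean``/``t_amp``/``t_peak_day`` define the annual temperature
    sinusoid T(doy) = t_mean + t_amp·cos(2π(doy − t_peak_day)/365), with
    day-of-year 1 = January 1 (so April 1 is day 91 in a non-leap year)
    and the default peak on day 196 (mid-July).  Defaults approximate the
    North China Plain: 13 °C annual mean, 15 °C amplitude, 2 °C daily
    noise, 14.67 MJ m⁻² d⁻¹ radiation, 400 ppm CO₂, 0.8 m base depth.
    """

    t_mean: float = 13.0
    t_amp: float = 15.0
    t_peak_day: int = 196
    noise_sd: float = 2.0
    rad_constant: float = 14.67
    co2_constant: float = 400.0
    base_depth: float = 0.8
    seed: int = 42
    year: int = DEFAULT_YEAR

    def __post_init__(self) -> None:
        if self.t_amp < 0:
            raise ValueError("t_amp must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.rad_constant < 0 or self.co2_constant <= 0:
            raise ValueError("radiation must be >= 0 and CO2 > 0")


@dataclass(frozen=True)
class DepthSegment:
    """A stepwise water-depth intervention over [start_day, end_day].

    Day indices are 0-based from April 1, inclusive on both ends.  Exactly
    one of ``offset_m`` (added to the base depth) or ``absolute_m``
    (replacing it) must be given.
    """

    start_day: int
    end_day: int
    offset_m: float | None = None
    absolute_m: float | None = None

    def __post_init__(self) -> None:
        if (self.offset_m is None) == (self.absolute_m is None):
            raise ValueError("give exactly one of offset_m or absolute_m")
        if not (0 <= self.start_day <= self.end_day <= SEASON_DAYS - 1):
            raise ValueError(
                f"segment days [{self.start_day}, {self.end_day}] outside "
                f"the 0..{SEASON_DAYS - 1} simulation window"
            )


@dataclass(frozen=True)
class DepthPolicy:
    """Base water depth plus non-overlapping stepwise segments."""

    base_depth: float = 0.8
    segments: tuple[DepthSegment, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.start_day)
        for a, b in zip(segs, segs[1:]):
            if b.start_day <= a.end_day:
                raise ValueError("depth-policy segments overlap")

    def depth_series(self, n_days: int = SEASON_DAYS) -> np.ndarray:
        """Daily water depths; negative results are clamped to 0 m."""
        depth = np.full(n_days, self.base_depth, dtype=float)
        for seg in self.segments:
            sl = slice(seg.start_day, seg.end_day + 1)
            if seg.absolute_m is not None:
                depth[sl] = seg.absolute_m
            else:
                depth[sl] += seg.offset_m
        if (depth < 0).any():
            logger.warning(
                "depth policy produced negative depth on %d day(s); clamped to 0",
                int((depth < 0).sum()),
            )
            depth = np.maximum(depth, 0.0)
        return depth


def season_dates(year: int = DEFAULT_YEAR) -> pd.DatetimeIndex:
    """The April 1 – October 31 simulation window as daily timestamps."""
    return pd.date_range(f"{year}-04-01", f"{year}-10-31", freq="D")


def generate_forcing(
    spec: SyntheticForcingSpec | None = None,
    policy: DepthPolicy | None = None,
) -> pd.DataFrame:
    """Build a 214-day synthetic forcing frame.

    Temperature is the annual sinusoid plus seeded Gaussian noise;
    radiation and CO₂ are constants; depth comes from ``policy`` (default:
    constant at the spec's base depth).  Deterministic for a fixed seed.
    """
    spec = spec or SyntheticForcingSpec()
    policy = policy or DepthPolicy(base_depth=spec.base_depth)
    dates = season_dates(spec.year)
    doy = dates.dayofyear.to_numpy()
    rng = np.random.default_rng(spec.seed)
    temp = (
        spec.t_mean
        + spec.t_amp * np.cos(2 * np.pi * (doy - spec.t_peak_day) / 365.0)
        + rng.normal(0.0, spec.noise_sd, len(dates))
    )
    frame = pd.DataFrame(
        {
            "date": dates,
            "air_temperature_c": temp,
            "radiation_mj_m2_d": spec.rad_constant,
            "co2_ppm": spec.co2_constant,
            "water_depth_m": policy.depth_series(len(dates)),
        }
    )
    return validate_forcing(frame)


def write_forcing_csv(forcing: pd.DataFrame, path: str | Path) -> None:
    """Write a forcing frame to CSV with ISO-8601 dates, full precision."""
    out = forcing.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_forcing_csv(path: str | Path) -> pd.DataFrame:
    """Read a forcing CSV, checking columns, dates and daily continuity."""
    frame = pd.read_csv(path)
    missing = [c for c in FORCING_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    try:
        frame["date"] = pd.to_datetime(frame["date"], format="%Y-%m-%d")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable date: {exc}") from exc
    return validate_forcing(frame[list(FORCING_COLUMNS)])
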