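"""Model parameters: rate constants, Arrhenius bases, carrying-capacity shape.

All rates are specific (per unit stock) daily rates in g g⁻¹ d⁻¹; stocks and
the carrying capacity are areal carbon densities in gC m⁻².  Each process rate
is temperature-corrected by an Arrhenius factor θ^(T − 20 °C) with a
process-specific base θ.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator


class ParameterError(ValueError):
    """Raised when a parameter value violates its constraint."""


@dataclass(frozen=True)
class ModelParameters:
    """Constants of the two-compartment reed carbon model.

    Defaults are the calibrated values for the Baiyangdian reed stands;
    ``reratio``, ``mrespiratio_pa`` and ``mrespiratio_pb`` have no published
    value and default to 0.005 g g⁻¹ d⁻¹ as a deliberate implementation
    choice (they are the primary calibration targets).

    Attributes
    ----------
    pac_init, pbc_init
        Initial aboveground / belowground carbon stock, gC m⁻².
    carrya_max
        Maximum environmental carrying capacity for the aboveground stock
        at the suitable growth depth, gC m⁻².
    depth_opt
        Suitable growth water depth (carrying-capacity maximum), m.
    waterdepth_max
        Scale depth of the tent-shaped carrying-capacity function, m.
    k_co2, k_rad
        Michaelis–Menten half-saturation constants for atmospheric CO₂
        (ppm) and daily solar radiation (MJ m⁻² d⁻¹).
    theta_*
        Dimensionless Arrhenius bases, one per process.
    t_ref
        Arrhenius reference temperature; fixed at 20 °C.
    transratio
        Shoot→rhizome translocation rate, g g⁻¹ d⁻¹.
    reratio
        Rhizome→shoot reactivation rate, g g⁻¹ d⁻¹.
    mrespiratio_pa, mrespiratio_pb
        Maintenance respiration rates of the two compartments, g g⁻¹ d⁻¹.
    mortalrate_pa, decayrate_pa, mortalrate_pb
        Shoot mortality, standing-litter decay and rhizome mortality
        rates, g g⁻¹ d⁻¹.
    react_window_end
        Optional day index (0 = April 1) after which reactivation is
        switched off; ``None`` (default) applies reactivation year-round.
    """

    pac_init: float = 103.0
    pbc_init: float = 1650.0
    carrya_max: float = 2450.0
    depth_opt: float = 0.8
    waterdepth_max: float = 1.8
    k_co2: float = 300.0
    k_rad: float = 6.0
    theta_photo: float = 1.09
    theta_respb: float = 1.09
    theta_respa: float = 1.07
    theta_transfer: float = 1.07
    theta_react: float = 1.07
    theta_mortal_a: float = 1.05
    theta_mortal_b: float = 1.05
    theta_decay: float = 1.05
    t_ref: float = 20.0
    transratio: float = 0.20
    reratio: float = 0.005
    mrespiratio_pa: float = 0.005
    mrespiratio_pb: float = 0.005
    mortalrate_pa: float = 0.001
    decayrate_pa: float = 0.005
    mortalrate_pb: float = 0.001
    react_window_end: int | None = None

    _RATE_FIELDS = (
        "transratio", "reratio", "mrespiratio_pa", "mrespiratio_pb",
        "mortalrate_pa", "decayrate_pa", "mortalrate_pb",
    )

    def __post_init__(self) -> None:
        if self.carrya_max <= 0:
            raise ParameterError("carrya_max must be positive")
        if not (0.0 <= self.depth_opt <= self.waterdepth_max):
            raise ParameterError("depth_opt must lie in [0, waterdepth_max]")
        if self.t_ref != 20.0:
            raise ParameterError("t_ref is fixed at 20 °C")
        for name in self._RATE_FIELDS:
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        for f in dataclasses.fields(self):
            if f.name.startswith("theta_") and getattr(self, f.name) <= 0:
                raise ParameterError(f"{f.name} must be positive")
        if self.k_co2 <= 0 or self.k_rad <= 0:
            raise ParameterError("half-saturation constants must be positive")
        if self.pac_init < 0 or self.pbc_init < 0:
            raise ParameterError("initial stocks must be non-negative")

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields changed (validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def items(self) -> Iterator[tuple[str, float]]:
        return iter(self.to_dict().items())


#: Calibration bounds per parameter.  Published ranges where they exist;
#: the unpublished rates (reratio, mrespiratio_*) get [0, 0.05].
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "pac_init": (100.0, 150.0),
    "pbc_init": (1500.0, 2000.0),
    "carrya_max": (1000.0, 5000.0),
    "waterdepth_max": (0.0, 2.0),
    "transratio": (0.0, 0.35),
    "decayrate_pa": (0.0, 0.18),
    "mortalrate_pa": (0.0, 0.15),
    "mortalrate_pb": (0.0, 1.0),
    "reratio": (0.0, 0.05),
    "mrespiratio_pa": (0.0, 0.05),
    "mrespiratio_pb": (0.0, 0.05),
}


def write_params(params: ModelParameters, path: str | Path) -> None:
    """Write parameters as a flat ``key = value`` configuration file."""
    lines = ["# reedcarbon model parameters"]
    for key, value in params.items():
        if value is None:
            continue
        lines.append(f"{key} = {value!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_params(path: str | Path) -> ModelParameters:
    """Read a flat key-value parameter file written by :func:`write_params`.

    Unknown keys raise :class:`ParameterError`; missing keys keep their
    defaults.
    """
    known = {f.name for f in dataclasses.fields(ModelParameters)}
    values: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParameterError(f"{path}:{lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in known:
            raise ParameterError(f"{path}:{lineno}: unknown parameter {key!r}")
        val = val.strip()
        if key == "react_window_end":
            values[key] = None if val in ("None", "") else int(val)
        else:
            values[key] = float(val)
    return ModelParameters(**values)
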