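"""Model parameters: reference values, validation, and config-file loading.

All rate and density constants are stored the way the reference table
reports them — the respiration, storage-respiration and assimilation
coefficients carry an implicit factor of pi (``C_over_pi`` etc.), and the
photosynthesis limit height enters as the product ``beta_h1``.  Properties
convert to the base-unit (kg, m, y) values used by the dynamics, in which
every stem volume is ``pi * r**2 * h``.

The lateral-meristem thickness ``t2`` and the reference maximal
meristem-sustained growth per volume ``Rmax0`` are never identifiable
separately: the dynamics depend only on the composites
``k_lat = t2 * Rmax0 / g1`` (m/y) and ``t_ratio = t2 / t1``.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
from typing import Any

__all__ = ["ModelParameters", "load_parameters"]

_PI = math.pi

#: Fields the calibration routines may free; anything else is structural.
TUNABLE_FIELDS = (
    "g1",
    "C_over_pi",
    "C2_over_pi",
    "k_lat",
    "t_ratio",
    "beta_h1",
    "h2",
    "S1",
    "Amax_over_pi",
    "Qr",
    "Cr",
    "beta",
    "Topt",
    "Ti_above",
    "Ti_below",
    "alpha2",
)


@dataclasses.dataclass(frozen=True)
class ModelParameters:
    """Physiological constants of the tree-growth model.

    Defaults are the reference values for European beech.

    Parameters
    ----------
    g1 : float
        Carbon density of the equivalent cylinder representing the tree
        (stem plus crown), kg m^-3.
    C_over_pi, C2_over_pi : float
        Respiration-and-litter coefficient and storage respiration
        coefficient, divided by pi, kg m^-3 y^-1.
    k_lat : float
        ``t2 * Rmax0 / g1``: reference maximal meristem-sustained lateral
        growth per unit area over carbon density, m y^-1.
    t_ratio : float
        ``t2 / t1``, lateral to apical meristem effective thickness ratio
        (dimensionless).  ``math.inf`` is accepted and makes the apical
        meristem volume term vanish (used by verification oracles).
    beta_h1 : float
        Product of the canopy geometry integrand ``beta`` and the limit
        height of occurrence for photosynthesis ``h1``, m.
    h2 : float
        Limit height of occurrence for meristem-sustained growth, m.
        ``math.inf`` disables the limit (verification oracles).
    S1 : float
        Critical storage ratio (stored carbon per unit structural carbon)
        below which the tree is considered in danger, dimensionless.
    Amax_over_pi : float
        Maximal assimilation of carbon per unit volume by photosynthesis,
        divided by pi, kg m^-3 y^-1.
    Qr, Cr : float
        Saturation constants of the PAR (W m^-2) and CO2 (ppm) responses.
    beta : float
        Canopy geometry integrand in the hydraulic decline of
        photosynthesis, dimensionless, in (0, 1].
    Topt, Ti_above, Ti_below : float
        Optimal temperature and the half-widths of the asymmetric
        temperature parabola for T > Topt and T <= Topt, degrees C.
    alpha2 : float
        Ratio of apical to lateral meristematic activity; sets the
        allometric exponent ``h ~ r**(2*alpha2)``.  Used when no
        red:far-red forcing is supplied.
    alpha0, alpha3 : float or None
        Ceiling and scale of the red:far-red control
        ``alpha2 = alpha0 * exp(-alpha3 * Ra)``; both must be set for a
        run driven by red:far-red forcing.
    storage_discount : str
        Reading of the storage factor in the sink-limited growth rate:
        ``"divisor"`` (default) divides the meristem output by
        ``1 + (S - S1)/(1 + S1)``; ``"multiplier"`` multiplies by it.
    """

    g1: float = 365.0
    C_over_pi: float = 73.0
    C2_over_pi: float = 73.0
    k_lat: float = 0.0201
    t_ratio: float = 1.0
    beta_h1: float = 67.5
    h2: float = 47.0
    S1: float = 0.2
    Amax_over_pi: float = 206.0
    Qr: float = 1000.0
    Cr: float = 500.0
    beta: float = 0.75
    Topt: float = 18.0
    Ti_above: float = 21.0
    Ti_below: float = 25.0
    alpha2: float = 0.34
    alpha0: float | None = None
    alpha3: float | None = None
    storage_discount: str = "divisor"

    def __post_init__(self) -> None:
        positive = {
            "g1": self.g1,
            "C_over_pi": self.C_over_pi,
            "C2_over_pi": self.C2_over_pi,
            "t_ratio": self.t_ratio,
            "beta_h1": self.beta_h1,
            "h2": self.h2,
            "Amax_over_pi": self.Amax_over_pi,
            "Qr": self.Qr,
            "Cr": self.Cr,
            "Ti_above": self.Ti_above,
            "Ti_below": self.Ti_below,
            "alpha2": self.alpha2,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"parameter {name} must be > 0, got {value!r}")
        if self.k_lat < 0:
            raise ValueError(f"parameter k_lat must be >= 0, got {self.k_lat!r}")
        if not 0 < self.beta <= 1:
            raise ValueError(f"parameter beta must lie in (0, 1], got {self.beta!r}")
        if self.S1 < 0:
            raise ValueError(f"parameter S1 must be >= 0, got {self.S1!r}")
        if self.storage_discount not in ("divisor", "multiplier"):
            raise ValueError(
                "storage_discount must be 'divisor' or 'multiplier', "
                f"got {self.storage_discount!r}"
            )
        if (self.alpha0 is None) != (self.alpha3 is None):
            raise ValueError("alpha0 and alpha3 must be supplied together")
        if self.alpha0 is not None:
            if not self.alpha0 > 0:
                raise ValueError("alpha0 must be > 0")
            if self.alpha3 < 0:
                raise ValueError("alpha3 must be >= 0")

    # -- base-unit composites -------------------------------------------------

    @property
    def C(self) -> float:
        """Respiration-and-litter coefficient, kg m^-3 y^-1 (times pi)."""
        return _PI * self.C_over_pi

    @property
    def C2(self) -> float:
        """Storage respiration coefficient, kg m^-3 y^-1 (times pi)."""
        return _PI * self.C2_over_pi

    @property
    def Amax(self) -> float:
        """Maximal volumetric assimilation, kg m^-3 y^-1 (times pi)."""
        return _PI * self.Amax_over_pi

    @property
    def h1(self) -> float:
        """Limit height of occurrence for photosynthesis, m."""
        return self.beta_h1 / self.beta

    # -- plumbing -------------------------------------------------------------

    def replace(self, **changes: Any) -> "ModelParameters":
        """Return a copy with the given fields changed."""
        return dataclasses.replace(self, **changes)

    def value_of(self, name: str) -> float:
        if name not in TUNABLE_FIELDS:
            raise KeyError(f"unknown tunable parameter {name!r}")
        return getattr(self, name)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)


def load_parameters(path: str | pathlib.Path) -> ModelParameters:
    """Read a parameter configuration from TOML, YAML, or JSON.

    Keys mirror :class:`ModelParameters` field names exactly; missing keys
    take the reference defaults, unknown keys are an error.
    """
    path = pathlib.Path(path)
    suffix = path.suffix.lower()
    if suffix == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    elif suffix in (".yaml", ".yml"):
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    elif suffix == ".json":
        with open(path) as fh:
            data = json.load(fh)
    else:
        raise ValueError(f"unsupported parameter file format: {path.name}")
    if not isinstance(data, dict):
        raise ValueError(f"parameter file {path.name} must define a mapping")
    return ModelParameters.from_dict(data)
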