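"""Domain types and instantaneous model quantities.

Everything here is algebraic — no differential equations.  The module
covers the height-radius allometry and its red:far-red control, the four
saturating/limiting factors of the photosynthesis model, whole-tree
assimilation, the meristem volume, and the meristem-sustained growth cap
(the "sink" limit).

Unit conventions: radius and height in m, temperature in degrees C, PAR in
W m^-2, CO2 mixing ratio in ppm, carbon masses in kg, time in years.
Stem-plus-crown volume is ``pi * r**2 * h`` throughout.
"""

from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .params import ModelParameters

__all__ = [
    "TreeState",
    "ForcingRow",
    "ForcingSeries",
    "Alpha2Estimate",
    "gamma_from_initial",
    "height_from_allometry",
    "alpha2_from_redfarred",
    "alpha2_from_stand_allometry",
    "estimate_alpha2",
    "temperature_factor",
    "co2_factor",
    "par_factor",
    "hydraulic_factor",
    "assimilation",
    "meristem_volume",
    "sink_cap",
    "effective_alpha2",
]

_PI = math.pi


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class TreeState:
    """Instantaneous tree state: radius ``r`` (m), height ``h`` (m), and
    storage ratio ``S`` (stored carbon per unit structural carbon)."""

    r: float
    h: float
    S: float

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"radius must be > 0, got {self.r!r}")
        if not self.h > 0:
            raise ValueError(f"height must be > 0, got {self.h!r}")
        if self.S < 0:
            raise ValueError(f"storage ratio must be >= 0, got {self.S!r}")

    def structural_mass(self, params: ModelParameters) -> float:
        """Structural carbon mass Mc = g1 * pi * r^2 * h (kg)."""
        return params.g1 * _PI * self.r**2 * self.h

    def stored_carbon(self, params: ModelParameters) -> float:
        """Total stored carbon Sc = S * g1 * pi * h * r^2 / (1 + S1) (kg)."""
        return self.S * params.g1 * _PI * self.h * self.r**2 / (1.0 + params.S1)

    def excess_storage(self, params: ModelParameters) -> float:
        """Stored carbon above the critical reserve,
        Sc0 = (S - S1) * g1 * pi * h * r^2 / (1 + S1) (kg)."""
        return (
            (self.S - params.S1)
            * params.g1
            * _PI
            * self.h
            * self.r**2
            / (1.0 + params.S1)
        )

    def total_mass(self, params: ModelParameters) -> float:
        """Mtot = Mc + Sc0 (kg): the carbon pool whose balance is audited."""
        return self.structural_mass(params) + self.excess_storage(params)

    @property
    def volume(self) -> float:
        """Stem-plus-crown cylinder volume pi * r^2 * h (m^3)."""
        return _PI * self.r**2 * self.h


class ForcingRow(NamedTuple):
    """One year of environmental forcing."""

    year: int
    T: float
    Q1: float
    Cg: float
    Ra: float | None = None


@dataclasses.dataclass(frozen=True)
class ForcingSeries:
    """Annual environmental drivers, piecewise constant over each year.

    ``year`` may be calendar year or tree age; it must be consecutive
    integers.  The value for ``year[i]`` applies on ``[year[i], year[i]+1)``.
    """

    year: np.ndarray
    T: np.ndarray
    Q1: np.ndarray
    Cg: np.ndarray
    Ra: np.ndarray | None = None

    def __post_init__(self) -> None:
        year = np.asarray(self.year, dtype=float)
        if year.size == 0:
            raise ValueError("forcing series is empty")
        if not np.allclose(year, np.round(year)):
            raise ValueError("forcing years must be integers")
        object.__setattr__(self, "year", year.astype(int))
        gaps = np.flatnonzero(np.diff(self.year) != 1)
        if gaps.size:
            missing = self.year[gaps[0]] + 1
            raise ValueError(
                f"forcing years must be consecutive; gap after year "
                f"{self.year[gaps[0]]} (missing {missing})"
            )
        for name in ("T", "Q1", "Cg"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.year.shape:
                raise ValueError(f"forcing column {name} has wrong length")
            if np.isnan(arr).any():
                row = int(np.flatnonzero(np.isnan(arr))[0])
                raise ValueError(f"missing value in column {name} at row {row}")
            object.__setattr__(self, name, arr)
        if (self.Q1 < 0).any():
            raise ValueError("PAR (Q1) must be >= 0")
        if (self.Cg <= 0).any():
            raise ValueError("CO2 mixing ratio (Cg) must be > 0")
        if self.Ra is not None:
            ra = np.asarray(self.Ra, dtype=float)
            if ra.shape != self.year.shape:
                raise ValueError("forcing column Ra has wrong length")
            if np.isnan(ra).any():
                raise ValueError("Ra must be absent entirely or present for all rows")
            if (ra < 0).any():
                raise ValueError("red:far-red ratio (Ra) must be >= 0")
            object.__setattr__(self, "Ra", ra)

    def __len__(self) -> int:
        return len(self.year)

    @property
    def t_min(self) -> float:
        return float(self.year[0])

    @property
    def t_max(self) -> float:
        """End of the covered time interval (exclusive of forcing rows)."""
        return float(self.year[-1] + 1)

    def covers(self, t0: float, t1: float) -> bool:
        return self.t_min <= t0 and t1 <= self.t_max

    def require_covers(self, t0: float, t1: float) -> None:
        if not self.covers(t0, t1):
            raise ValueError(
                f"forcing covers [{self.t_min}, {self.t_max}) but the run "
                f"needs [{t0}, {t1}]"
            )

    def row_at(self, t: float) -> ForcingRow:
        """Forcing active at time ``t`` (piecewise constant per year)."""
        idx = int(math.floor(t)) - self.year[0]
        if t == self.t_max:  # allow the closed right endpoint of a run
            idx = len(self.year) - 1
        if idx < 0 or idx >= len(self.year):
            raise ValueError(f"time {t} outside forcing span")
        ra = float(self.Ra[idx]) if self.Ra is not None else None
        return ForcingRow(
            int(self.year[idx]),
            float(self.T[idx]),
            float(self.Q1[idx]),
            float(self.Cg[idx]),
            ra,
        )

    def to_dataframe(self) -> pd.DataFrame:
        data = {"year": self.year, "T": self.T, "Q1": self.Q1, "Cg": self.Cg}
        if self.Ra is not None:
            data["Ra"] = self.Ra
        return pd.DataFrame(data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ForcingSeries":
        required = ("year", "T", "Q1", "Cg")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"forcing table is missing columns {missing}")
        ra = df["Ra"].to_numpy() if "Ra" in df.columns else None
        return cls(
            year=df["year"].to_numpy(),
            T=df["T"].to_numpy(),
            Q1=df["Q1"].to_numpy(),
            Cg=df["Cg"].to_numpy(),
            Ra=ra,
        )


class Alpha2Estimate(NamedTuple):
    """Meristem-activity ratio inferred from two stand measurements."""

    value: float
    in_range: bool  # True when the estimate lies in (0, 1)


# ---------------------------------------------------------------------------
# allometry and meristem control
# ---------------------------------------------------------------------------


def gamma_from_initial(r0: float, h0: float, alpha2: float) -> float:
    """Allometric constant gamma = h0 / r0**(2*alpha2).

    The power law ``h = gamma * r**(2*alpha2)`` holds at every time, so
    gamma can be evaluated from any single (radius, height) pair.
    """
    if not (r0 > 0 and h0 > 0 and alpha2 > 0):
        raise ValueError("r0, h0 and alpha2 must all be > 0")
    return h0 / r0 ** (2.0 * alpha2)


def height_from_allometry(r: float, gamma: float, alpha2: float) -> float:
    """Height from the allometric power law, h = gamma * r**(2*alpha2)."""
    if not (r > 0 and gamma > 0):
        raise ValueError("r and gamma must be > 0")
    return gamma * r ** (2.0 * alpha2)


def alpha2_from_redfarred(Ra: float, alpha0: float, alpha3: float) -> float:
    """Meristem-activity ratio under red:far-red control,
    ``alpha2 = alpha0 * exp(-alpha3 * Ra)``.

    A low red:far-red ratio signals shading by neighbours and shifts
    allocation toward height growth (larger alpha2); ``alpha0`` is the
    mechanical-failure ceiling and ``alpha0 * exp(-alpha3)`` the unshaded
    value.
    """
    if Ra < 0:
        raise ValueError("red:far-red ratio must be >= 0")
    if not alpha0 > 0 or alpha3 < 0:
        raise ValueError("need alpha0 > 0 and alpha3 >= 0")
    return alpha0 * math.exp(-alpha3 * Ra)


def alpha2_from_stand_allometry(
    m1: Sequence[float], m2: Sequence[float]
) -> Alpha2Estimate:
    """Invert the allometry from two (age, height, radius) measurements.

    Returns ``ln(h2/h1) / (2 ln(r2/r1))`` with a flag marking whether the
    estimate falls in the physically sensible open interval (0, 1).
    """
    h_a, r_a = float(m1[-2]), float(m1[-1])
    h_b, r_b = float(m2[-2]), float(m2[-1])
    if min(h_a, r_a, h_b, r_b) <= 0:
        raise ValueError("heights and radii must be > 0")
    if r_a == r_b:
        raise ValueError("identical radii: allometric exponent is undefined")
    value = math.log(h_b / h_a) / (2.0 * math.log(r_b / r_a))
    return Alpha2Estimate(value, 0.0 < value < 1.0)


def estimate_alpha2(height: np.ndarray, radius: np.ndarray) -> Alpha2Estimate:
    """Least-squares allometric exponent from a whole measurement series.

    Fits ``ln h = ln gamma + 2*alpha2 * ln r`` by ordinary least squares;
    more robust to observation noise than the two-point inversion.
    """
    h = np.asarray(height, dtype=float)
    r = np.asarray(radius, dtype=float)
    if h.size < 2 or (h <= 0).any() or (r <= 0).any():
        raise ValueError("need at least two positive (height, radius) pairs")
    slope = np.polyfit(np.log(r), np.log(h), 1)[0]
    value = float(slope / 2.0)
    return Alpha2Estimate(value, 0.0 < value < 1.0)


def effective_alpha2(params: ModelParameters, row: ForcingRow | None) -> float:
    """alpha2 for the current step: red:far-red driven when Ra forcing and
    (alpha0, alpha3) are both available, otherwise the per-run constant."""
    if row is not None and row.Ra is not None and params.alpha0 is not None:
        return alpha2_from_redfarred(row.Ra, params.alpha0, params.alpha3)
    return params.alpha2


# ---------------------------------------------------------------------------
# photosynthesis factors
# ---------------------------------------------------------------------------


def temperature_factor(
    T: float, Topt: float = 18.0, Ti_above: float = 21.0, Ti_below: float = 25.0
) -> float:
    """Asymmetric temperature parabola, clamped to [0, 1].

    ``1 - ((T - Topt)/Ti)**2`` with the half-width ``Ti`` chosen by side of
    the optimum; negative values (outside the thermal envelope) are
    clamped to zero so photosynthesis ceases rather than reverses.
    """
    if not (Ti_above > 0 and Ti_below > 0):
        raise ValueError("Ti half-widths must be > 0")
    ti = Ti_above if T > Topt else Ti_below
    return max(0.0, 1.0 - ((T - Topt) / ti) ** 2)


def co2_factor(Cg: float, Cr: float) -> float:
    """Saturating CO2 response ``1 - exp(-Cg/Cr)``, in [0, 1)."""
    if not Cr > 0:
        raise ValueError("Cr must be > 0")
    if Cg < 0:
        raise ValueError("Cg must be >= 0")
    return 1.0 - math.exp(-Cg / Cr)


def par_factor(Q1: float, Qr: float) -> float:
    """Saturating PAR response ``1 - exp(-Q1/Qr)``, in [0, 1)."""
    if not Qr > 0:
        raise ValueError("Qr must be > 0")
    if Q1 < 0:
        raise ValueError("Q1 must be >= 0")
    return 1.0 - math.exp(-Q1 / Qr)


def hydraulic_factor(h: float, h1: float, beta: float) -> float:
    """Water-potential decline of canopy photosynthesis with height.

    ``max(0, (h1 - beta*h) / h1)``: equals 1 for a vanishingly short tree
    and reaches 0 at ``h = h1/beta``.
    """
    if not h1 > 0:
        raise ValueError("h1 must be > 0")
    if h < 0:
        raise ValueError("h must be >= 0")
    return max(0.0, (h1 - beta * h) / h1)


# float-signature kernels used by the dynamics hot path ---------------------


def _assimilation(r: float, h: float, row: ForcingRow, params: ModelParameters) -> float:
    return (
        params.Amax
        * co2_factor(row.Cg, params.Cr)
        * par_factor(row.Q1, params.Qr)
        * temperature_factor(row.T, params.Topt, params.Ti_above, params.Ti_below)
        * hydraulic_factor(h, params.h1, params.beta)
        * r**2
        * h
    )


def _meristem_volume(r: float, h: float, t_ratio: float) -> float:
    apical = 0.0 if math.isinf(t_ratio) else _PI * r**2 / t_ratio
    return apical + 2.0 * _PI * r * h


def _sink_cap(r: float, h: float, params: ModelParameters) -> float:
    if math.isinf(params.h2):
        height_factor = 1.0
    else:
        height_factor = max(0.0, (params.h2 - h) / params.h2)
    return params.g1 * params.k_lat * height_factor * _meristem_volume(r, h, params.t_ratio)


# ---------------------------------------------------------------------------
# public whole-tree quantities
# ---------------------------------------------------------------------------


def assimilation(state: TreeState, row: ForcingRow, params: ModelParameters) -> float:
    """Whole-tree carbon assimilation A (kg/y).

    Product of the maximal volumetric rate, the four environmental/size
    factors, and the crown-scaling term ``r**2 * h``:

    ``A = Amax * fCO2(Cg) * fPAR(Q1) * fT(T) * fH(h) * r^2 * h``
    """
    return _assimilation(state.r, state.h, row, params)


def meristem_volume(r: float, h: float, t_ratio: float) -> float:
    """Meristem volume per unit lateral thickness, Vme/t2 (m^2).

    ``pi*r^2/t_ratio`` for the (aggregate) apical meristem plus
    ``2*pi*r*h`` for the vascular cambium sheath.
    """
    if not (r > 0 and h > 0):
        raise ValueError("r and h must be > 0")
    if not t_ratio > 0:
        raise ValueError("t_ratio must be > 0")
    return _meristem_volume(r, h, t_ratio)


def sink_cap(state: TreeState, params: ModelParameters) -> float:
    """Maximal meristem-sustained structural growth rate, Rmax*Vme (kg/y).

    ``g1 * k_lat * max(0, (h2 - h)/h2) * Vme/t2`` — zero at and above the
    meristem limit height h2.
    """
    return _sink_cap(state.r, state.h, params)
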