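"""Regime-switching right-hand side of the growth system.

The tree's structural growth rate is the smaller of what the carbon supply
can pay for (source limitation) and what the meristems can build (sink
limitation), with a single storage pool buffering the difference:

* sink-limited (supply exceeds the cap, or reserves above critical):
  growth runs at the meristem cap discounted by the current storage
  density, and the surplus (possibly negative) flows into storage;
* source-limited (supply at or below the cap, reserves at critical):
  growth equals net supply — which may be negative under stress — and the
  storage ratio stays frozen at its critical value.

State is (r, h, S): height is carried as an explicit state rather than
eliminated through the allometry so that a time-varying meristem-activity
ratio (red:far-red forcing) is supported; with constant alpha2 the power
law re-emerges from the integration as an exact invariant.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from typing import NamedTuple

from .core import ForcingRow, TreeState, _assimilation, _sink_cap, effective_alpha2
from .params import ModelParameters

__all__ = [
    "RegimeFlag",
    "FluxLedger",
    "classify_regime",
    "net_supply",
    "growth_rate_sink",
    "growth_rate_source",
    "storage_rate",
    "rhs",
]

_PI = math.pi

#: Tolerance on S - S1 for boundary classification.
REGIME_TOL = 1e-9


class RegimeFlag(enum.IntEnum):
    """Which process limits growth at an instant."""

    SOURCE_LIMITED = 0
    SINK_LIMITED = 1


@dataclasses.dataclass(frozen=True)
class FluxLedger:
    """Carbon fluxes (kg/y) at one evaluation of the right-hand side.

    Closure ``A - maintenance - storage_cost = growth + storage_change``
    holds at machine precision by construction.
    """

    A: float
    maintenance: float
    storage_cost: float
    growth: float
    storage_change: float
    regime: RegimeFlag

    @property
    def closure_error(self) -> float:
        return (
            self.A
            - self.maintenance
            - self.storage_cost
            - self.growth
            - self.storage_change
        )


class Derivatives(NamedTuple):
    dr: float
    dh: float
    dS: float
    ledger: FluxLedger


# ---------------------------------------------------------------------------
# float kernels (hot path)
# ---------------------------------------------------------------------------


def _costs(r: float, h: float, S: float, params: ModelParameters) -> tuple[float, float]:
    """(maintenance, storage respiration) costs, kg/y."""
    vol = r**2 * h
    return params.C * vol, params.C2 * S * vol


def _net_supply(r: float, h: float, S: float, row: ForcingRow, params: ModelParameters):
    a = _assimilation(r, h, row, params)
    maint, scost = _costs(r, h, S, params)
    return a - maint - scost, a, maint, scost


def _storage_factor(S: float, params: ModelParameters) -> float:
    return 1.0 + (S - params.S1) / (1.0 + params.S1)


def _classify(
    net: float, cap: float, S: float, params: ModelParameters, tol: float
) -> RegimeFlag:
    if net > cap or (S - params.S1) > tol:
        return RegimeFlag.SINK_LIMITED
    return RegimeFlag.SOURCE_LIMITED


def _derivatives(
    r: float,
    h: float,
    S: float,
    row: ForcingRow,
    params: ModelParameters,
    regime_mode: str = "auto",
    tol: float = REGIME_TOL,
) -> Derivatives:
    """Full right-hand side evaluation on plain floats.

    ``regime_mode``: "auto" switches regimes from the state; "sink_off"
    removes the meristem cap (pure supply-driven growth, S pinned);
    "sink_only" pins growth to the undiscounted cap (verification runs).
    """
    net, a, maint, scost = _net_supply(r, h, S, row, params)
    cap = _sink_cap(r, h, params)

    if regime_mode == "sink_off":
        regime = RegimeFlag.SOURCE_LIMITED
        growth = net
        dS = 0.0
        storage_change = 0.0
    elif regime_mode == "sink_only":
        regime = RegimeFlag.SINK_LIMITED
        growth = cap
        dS = 0.0
        storage_change = net - growth  # broken balance is intentional here
    else:
        regime = _classify(net, cap, S, params, tol)
        if regime is RegimeFlag.SINK_LIMITED:
            factor = _storage_factor(S, params)
            if params.storage_discount == "divisor":
                growth = cap / factor
            else:
                growth = cap * factor
            storage_change = net - growth
        else:
            growth = net
            storage_change = 0.0
            dS = 0.0

    alpha2 = effective_alpha2(params, row)
    mc = params.g1 * _PI * r**2 * h
    # dMc = g1*pi*(2 r h dr + r^2 dh) with dh = 2*alpha2*(h/r)*dr
    dr = growth / (2.0 * params.g1 * _PI * r * h * (1.0 + alpha2))
    dh = 2.0 * alpha2 * (h / r) * dr
    if regime_mode == "auto" and regime is RegimeFlag.SINK_LIMITED:
        # invert Sc0 = (S - S1) * Mc / (1 + S1) by the product rule
        dS = ((1.0 + params.S1) * storage_change - (S - params.S1) * growth) / mc

    ledger = FluxLedger(a, maint, scost, growth, storage_change, regime)
    return Derivatives(dr, dh, dS, ledger)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def net_supply(state: TreeState, row: ForcingRow, params: ModelParameters) -> float:
    """Assimilation minus maintenance and storage respiration (kg/y)."""
    return _net_supply(state.r, state.h, state.S, row, params)[0]


def classify_regime(
    state: TreeState,
    row: ForcingRow,
    params: ModelParameters,
    tol: float = REGIME_TOL,
) -> RegimeFlag:
    """Sink-limited when net supply exceeds the meristem cap *or* reserves
    sit above the critical ratio (growth can draw on storage); otherwise
    source-limited."""
    net = net_supply(state, row, params)
    cap = _sink_cap(state.r, state.h, params)
    return _classify(net, cap, state.S, params, tol)


def growth_rate_sink(state: TreeState, params: ModelParameters) -> float:
    """Structural growth under sink limitation (kg/y).

    The meristem output ``Rmax * Vme`` discounted by the storage density of
    the new tissue: ``cap / (1 + (S - S1)/(1 + S1))`` under the default
    divisor reading.  Equals the cap exactly at S = S1.
    """
    cap = _sink_cap(state.r, state.h, params)
    factor = _storage_factor(state.S, params)
    return cap / factor if params.storage_discount == "divisor" else cap * factor


def growth_rate_source(
    state: TreeState, row: ForcingRow, params: ModelParameters
) -> float:
    """Structural growth under source limitation: the net supply itself.

    May be negative under stress (assimilation below maintenance with
    reserves at the critical floor), in which case the tree loses mass.
    """
    return net_supply(state, row, params)


def storage_rate(
    state: TreeState, row: ForcingRow, params: ModelParameters, dMc_dt: float
) -> float:
    """Rate of change of excess stored carbon under sink limitation (kg/y):
    whatever the net supply does not spend on growth."""
    return net_supply(state, row, params) - dMc_dt


def rhs(
    state: TreeState,
    row: ForcingRow,
    params: ModelParameters,
    regime_mode: str = "auto",
    tol: float = REGIME_TOL,
) -> Derivatives:
    """Time derivatives (dr/dt, dh/dt, dS/dt) plus the flux ledger.

    Structural growth converts to a radial rate through the differential
    allometry ``dh/h = 2*alpha2*dr/r``:

    ``dr/dt = (dMc/dt) / (2 * g1 * pi * r * h * (1 + alpha2))``

    and dS/dt follows from differentiating the excess-storage definition.
    """
    if regime_mode not in ("auto", "sink_off", "sink_only"):
        raise ValueError(f"unknown regime_mode {regime_mode!r}")
    return _derivatives(state.r, state.h, state.S, row, params, regime_mode, tol)
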