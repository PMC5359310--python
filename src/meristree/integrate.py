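"""Numerical solution of the growth system over decades.

The solver is adaptive Runge-Kutta (RK45) applied year by year, because
the environmental forcing is piecewise constant over annual steps and the
right-hand side is therefore discontinuous at year boundaries.  Within a
year, event detection locates the storage ratio crossing its critical
floor from above (switch to source limitation, with S pinned exactly at
the floor afterwards) and net supply rising through the meristem cap while
at the floor (switch back to sink limitation).

A fixed-step trapezoidal integrator and a closed-form solution of the
simplified pure-sink configuration are provided as independent
cross-checks of the adaptive solver.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import ForcingRow, ForcingSeries, TreeState, gamma_from_initial
from .dynamics import REGIME_TOL, RegimeFlag, _derivatives, _net_supply, _sink_cap
from .params import ModelParameters

__all__ = [
    "Trajectory",
    "simulate",
    "trapezoid_simulate",
    "cross_check",
    "analytic_reference",
    "annual_regimes",
]

_PI = math.pi
_COLLAPSE_RADIUS = 1e-6  # m; below this the run is halted as collapsed
_EPS = 1e-10


class SimulationError(RuntimeError):
    pass


@dataclasses.dataclass
class Trajectory:
    """Time-indexed simulation output.

    ``regime[i]`` is the regime active on the interval
    ``[times[i], times[i+1])`` (the last entry repeats).  The ledger
    columns are instantaneous fluxes (kg/y) evaluated at each sample;
    ``audit`` is the net carbon flux integrated alongside the state by the
    solver, used for the mass-balance audit.
    """

    times: np.ndarray
    r: np.ndarray
    h: np.ndarray
    S: np.ndarray
    regime: np.ndarray
    A: np.ndarray
    maintenance: np.ndarray
    storage_cost: np.ndarray
    growth: np.ndarray
    storage_change: np.ndarray
    audit: np.ndarray
    params: ModelParameters
    meta: dict

    def __len__(self) -> int:
        return len(self.times)

    @property
    def volume(self) -> np.ndarray:
        """Stem volume pi * r^2 * h (m^3) at each sample."""
        return _PI * self.r**2 * self.h

    def state_at(self, index: int) -> TreeState:
        return TreeState(float(self.r[index]), float(self.h[index]), float(self.S[index]))

    def height_at(self, ages: np.ndarray) -> np.ndarray:
        """Heights at the requested ages (exact where sampled, linear
        interpolation between samples)."""
        ages = np.asarray(ages, dtype=float)
        if ages.min() < self.times[0] - _EPS or ages.max() > self.times[-1] + _EPS:
            raise ValueError("requested ages outside the simulated span")
        return np.interp(ages, self.times, self.h)

    def radius_at(self, ages: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        return np.interp(ages, self.times, self.r)

    def total_mass(self) -> np.ndarray:
        """Mtot = Mc + Sc0 (kg) at each sample."""
        p = self.params
        mc = p.g1 * _PI * self.r**2 * self.h
        return mc * (1.0 + (self.S - p.S1) / (1.0 + p.S1))

    def mass_balance_error(self) -> float:
        """Relative mismatch between the total-carbon change and the
        integrated net flux (the carbon-balance audit over the whole run)."""
        mtot = self.total_mass()
        change = mtot[-1] - mtot[0]
        integrated = self.audit[-1] - self.audit[0]
        scale = max(abs(change), abs(integrated), 1e-12 * mtot[0])
        return abs(change - integrated) / scale

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.times,
                "r": self.r,
                "h": self.h,
                "S": self.S,
                "volume": self.volume,
                "regime": [RegimeFlag(int(v)).name for v in self.regime],
                "A": self.A,
                "maintenance": self.maintenance,
                "storage_cost": self.storage_cost,
                "growth": self.growth,
                "storage_change": self.storage_change,
                "audit": self.audit,
            }
        )


def _coerce_initial(initial, params: ModelParameters) -> tuple[float, float, float]:
    if isinstance(initial, TreeState):
        return initial.r, initial.h, initial.S
    vals = tuple(float(v) for v in initial)
    if len(vals) == 2:
        return vals[0], vals[1], params.S1
    if len(vals) == 3:
        return vals
    raise ValueError("initial must be a TreeState, (r0, h0) or (r0, h0, S0)")


def _year_boundaries(t0: float, tf: float) -> np.ndarray:
    first = math.floor(t0) + 1
    last = math.ceil(tf) - 1
    inner = np.arange(first, last + 1, dtype=float)
    inner = inner[(inner > t0 + _EPS) & (inner < tf - _EPS)]
    return np.concatenate([[t0], inner, [tf]])


def simulate(
    initial,
    params: ModelParameters,
    forcing: ForcingSeries,
    t_span: Sequence[float],
    *,
    t_eval: Sequence[float] | None = None,
    regime_mode: str = "auto",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    tol: float = REGIME_TOL,
) -> Trajectory:
    """Integrate the growth system over ``t_span`` (years of tree age).

    Parameters
    ----------
    initial : TreeState or tuple
        ``(r0, h0)`` with storage starting at the critical ratio S1, or
        ``(r0, h0, S0)`` / a full :class:`TreeState`.
    t_eval : sequence of float, optional
        Ages at which to report the state.  Defaults to every integer age
        in the span.  Event times (regime switches) are always included.
    regime_mode : str
        ``"auto"`` (regime-switching model), ``"sink_off"`` (meristem cap
        removed; growth purely supply-driven with S pinned), or
        ``"sink_only"`` (growth pinned to the undiscounted cap; a
        verification configuration that deliberately ignores the carbon
        balance).

    Identical inputs give bit-identical trajectories: there is no hidden
    randomness anywhere in the solver.
    """
    if regime_mode not in ("auto", "sink_off", "sink_only"):
        raise ValueError(f"unknown regime_mode {regime_mode!r}")
    t0, tf = float(t_span[0]), float(t_span[1])
    if not tf > t0:
        raise ValueError("t_span must be increasing")
    forcing.require_covers(t0, tf)
    r0, h0, s0 = _coerce_initial(initial, params)
    if regime_mode in ("sink_off", "sink_only"):
        s0 = params.S1
    TreeState(r0, h0, s0)  # validate

    if t_eval is None:
        grid = np.arange(math.ceil(t0), math.floor(tf) + 1, dtype=float)
        t_out = np.unique(np.concatenate([[t0, tf], grid]))
    else:
        t_out = np.unique(np.asarray(t_eval, dtype=float))
        if t_out.size and (t_out[0] < t0 - _EPS or t_out[-1] > tf + _EPS):
            raise ValueError("t_eval outside t_span")
        t_out = np.unique(np.concatenate([[t0, tf], t_out]))

    y = np.array([r0, h0, s0, 0.0])
    times: list[float] = [t0]
    states: list[np.ndarray] = [y.copy()]
    regimes: list[int] = []
    events: list[tuple[str, float]] = []
    stress = False
    collapsed = False
    nfev = 0

    def make_rhs(row: ForcingRow):
        def fun(t: float, yv: np.ndarray) -> np.ndarray:
            r, h, s = yv[0], yv[1], yv[2]
            d = _derivatives(r, h, s, row, params, regime_mode, tol)
            net = d.ledger.A - d.ledger.maintenance - d.ledger.storage_cost
            return np.array([d.dr, d.dh, d.dS, net])

        return fun

    def segment_regime(row: ForcingRow, yv: np.ndarray) -> RegimeFlag:
        if regime_mode == "sink_off":
            return RegimeFlag.SOURCE_LIMITED
        if regime_mode == "sink_only":
            return RegimeFlag.SINK_LIMITED
        d = _derivatives(yv[0], yv[1], yv[2], row, params, "auto", tol)
        return d.ledger.regime

    boundaries = _year_boundaries(t0, tf)
    done = False
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        if done:
            break
        row = forcing.row_at(a)
        t = a
        guard = 0
        while t < b - 1e-12:
            guard += 1
            use_events = regime_mode == "auto" and guard <= 60
            current = segment_regime(row, y)
            ev = []
            if use_events:

                def floor_event(tt, yv):
                    return yv[2] - (params.S1 - 1e-12)

                floor_event.terminal = True
                floor_event.direction = -1
                ev.append(("storage_floor", floor_event))

                if current is RegimeFlag.SOURCE_LIMITED:

                    def onset_event(tt, yv):
                        net = _net_supply(yv[0], yv[1], yv[2], row, params)[0]
                        return net - _sink_cap(yv[0], yv[1], params)

                    onset_event.terminal = True
                    onset_event.direction = 1
                    ev.append(("sink_onset", onset_event))

            def collapse_event(tt, yv):
                return yv[0] - _COLLAPSE_RADIUS

            collapse_event.terminal = True
            collapse_event.direction = -1
            ev.append(("collapse", collapse_event))

            sol = solve_ivp(
                make_rhs(row),
                (t, b),
                y,
                method="RK45",
                rtol=rtol,
                atol=atol,
                max_step=1.0,
                dense_output=True,
                events=[f for _, f in ev],
            )
            if not sol.success:
                raise SimulationError(f"solver failed at t={t}: {sol.message}")
            nfev += sol.nfev
            t_end = float(sol.t[-1])

            if not stress and current is RegimeFlag.SOURCE_LIMITED:
                d0 = _derivatives(y[0], y[1], y[2], row, params, regime_mode, tol)
                if d0.ledger.growth < 0:
                    stress = True
                    warnings.warn(
                        "net carbon supply is negative with reserves at the "
                        "critical floor: the tree is under stress and losing mass",
                        RuntimeWarning,
                        stacklevel=2,
                    )

            # record requested output points inside (t, t_end)
            mask = (t_out > t + 1e-12) & (t_out < t_end - 1e-12)
            for tq in t_out[mask]:
                yq = sol.sol(tq)
                times.append(float(tq))
                states.append(np.asarray(yq, dtype=float))
                regimes.append(int(current))

            y = sol.y[:, -1].copy()
            fired = None
            if sol.status == 1:  # a terminal event fired
                for (name, _), t_ev in zip(ev, sol.t_events):
                    if len(t_ev):
                        fired = name
                        break

            times.append(t_end)
            states.append(y.copy())
            regimes.append(int(current))

            if fired == "collapse":
                collapsed = True
                warnings.warn(
                    f"state collapse (r <= {_COLLAPSE_RADIUS} m) at age "
                    f"{t_end:.2f}; simulation halted",
                    RuntimeWarning,
                    stacklevel=2,
                )
                events.append((fired, t_end))
                done = True
                break
            if fired == "storage_floor":
                y[2] = params.S1  # pin reserves exactly at the floor
                states[-1] = y.copy()
                events.append((fired, t_end))
            elif fired == "sink_onset":
                events.append((fired, t_end))

            if t_end <= t + 1e-12 and fired is not None:
                # no forward progress from an event at the segment start;
                # the RHS is continuous across this boundary, push through
                guard = 61
            t = t_end

    regimes.append(regimes[-1] if regimes else int(segment_regime(forcing.row_at(t0), y)))

    times_arr = np.asarray(times)
    order = np.argsort(times_arr, kind="stable")
    # drop duplicate times keeping the later record (post-event pinning)
    times_sorted = times_arr[order]
    keep = np.ones(len(times_sorted), dtype=bool)
    keep[:-1] = np.diff(times_sorted) > 1e-12
    idx = order[keep]
    # for duplicates, argsort(stable) keeps original order; keep last of a tie
    times_f = times_sorted[keep]
    Y = np.stack([states[i] for i in idx], axis=1)
    reg = np.asarray([regimes[i] for i in idx], dtype=np.int8)

    # ledger at each sample
    nA = np.empty(len(times_f))
    nM = np.empty_like(nA)
    nSc = np.empty_like(nA)
    nG = np.empty_like(nA)
    nSt = np.empty_like(nA)
    for i, tq in enumerate(times_f):
        row = forcing.row_at(min(tq, forcing.t_max))
        d = _derivatives(Y[0, i], Y[1, i], Y[2, i], row, params, regime_mode, tol)
        led = d.ledger
        nA[i], nM[i], nSc[i] = led.A, led.maintenance, led.storage_cost
        nG[i], nSt[i] = led.growth, led.storage_change

    meta = {
        "regime_mode": regime_mode,
        "rtol": rtol,
        "atol": atol,
        "nfev": nfev,
        "events": events,
        "stress": stress,
        "collapsed": collapsed,
        "t_span": (t0, tf),
        "initial": (r0, h0, s0),
    }
    return Trajectory(
        times=times_f,
        r=Y[0],
        h=Y[1],
        S=Y[2],
        regime=reg,
        A=nA,
        maintenance=nM,
        storage_cost=nSc,
        growth=nG,
        storage_change=nSt,
        audit=Y[3],
        params=params,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# cross-check integrators
# ---------------------------------------------------------------------------


def trapezoid_simulate(
    initial,
    params: ModelParameters,
    forcing: ForcingSeries,
    t_span: Sequence[float],
    *,
    step: float = 0.1,
    regime_mode: str = "auto",
) -> Trajectory:
    """Fixed-step implicit trapezoidal integration (second order).

    Independent of the adaptive solver: the implicit stage is resolved by
    fixed-point iteration.  No event handling — intended for smooth runs
    as a cross-method verification, not for production use.
    """
    t0, tf = float(t_span[0]), float(t_span[1])
    forcing.require_covers(t0, tf)
    r0, h0, s0 = _coerce_initial(initial, params)
    if regime_mode in ("sink_off", "sink_only"):
        s0 = params.S1

    def deriv(yv: np.ndarray, row: ForcingRow) -> np.ndarray:
        d = _derivatives(yv[0], yv[1], yv[2], row, params, regime_mode)
        net = d.ledger.A - d.ledger.maintenance - d.ledger.storage_cost
        return np.array([d.dr, d.dh, d.dS, net])

    y = np.array([r0, h0, s0, 0.0])
    times = [t0]
    states = [y.copy()]
    boundaries = _year_boundaries(t0, tf)
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        row = forcing.row_at(a)
        n = max(1, int(math.ceil((b - a) / step - 1e-12)))
        dt = (b - a) / n
        for k in range(n):
            f0 = deriv(y, row)
            y_next = y + dt * f0  # explicit Euler predictor
            for _ in range(50):
                y_new = y + 0.5 * dt * (f0 + deriv(y_next, row))
                if np.max(np.abs(y_new - y_next)) <= 1e-13 * max(1.0, np.max(np.abs(y_new))):
                    y_next = y_new
                    break
                y_next = y_new
            y = y_next
            if regime_mode == "auto" and y[2] < params.S1:
                y[2] = params.S1  # crude storage floor (no event machinery)
        times.append(b)
        states.append(y.copy())

    times_arr = np.asarray(times)
    Y = np.stack(states, axis=1)
    n = len(times_arr)
    reg = np.zeros(n, dtype=np.int8)
    nA = np.empty(n)
    nM = np.empty(n)
    nSc = np.empty(n)
    nG = np.empty(n)
    nSt = np.empty(n)
    for i, tq in enumerate(times_arr):
        row = forcing.row_at(min(tq, forcing.t_max))
        d = _derivatives(Y[0, i], Y[1, i], Y[2, i], row, params, regime_mode)
        reg[i] = int(d.ledger.regime)
        nA[i], nM[i], nSc[i] = d.ledger.A, d.ledger.maintenance, d.ledger.storage_cost
        nG[i], nSt[i] = d.ledger.growth, d.ledger.storage_change
    meta = {
        "regime_mode": regime_mode,
        "method": "trapezoid",
        "step": step,
        "t_span": (t0, tf),
        "initial": (r0, h0, s0),
    }
    return Trajectory(times_arr, Y[0], Y[1], Y[2], reg, nA, nM, nSc, nG, nSt, Y[3], params, meta)


def cross_check(
    initial,
    params: ModelParameters,
    forcing: ForcingSeries,
    t_span: Sequence[float],
    *,
    step: float = 0.1,
    regime_mode: str = "auto",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """Maximum relative height discrepancy between the adaptive RK45 and
    the fixed-step trapezoidal integrations over the span."""
    rk = simulate(initial, params, forcing, t_span, regime_mode=regime_mode, rtol=rtol, atol=atol)
    tz = trapezoid_simulate(initial, params, forcing, t_span, step=step, regime_mode=regime_mode)
    h_rk = rk.height_at(tz.times)
    return float(np.max(np.abs(h_rk - tz.h) / h_rk))


def analytic_reference(
    params: ModelParameters,
    initial,
    t_span: Sequence[float],
) -> Trajectory:
    """Closed-form trajectory of the simplified pure-sink configuration.

    Valid only when the apical meristem volume term is absent
    (``t_ratio = inf``), the meristem limit height is disabled
    (``h2 = inf``), and reserves sit at the critical ratio.  Then

    ``dr/dt = k_lat / (1 + alpha2)``  (constant), and
    ``h(t) = gamma * r(t)**(2*alpha2)``.
    """
    if not math.isinf(params.t_ratio):
        raise ValueError(
            "analytic reference requires t_ratio = inf (lateral-dominated meristem)"
        )
    if not math.isinf(params.h2):
        raise ValueError("analytic reference requires h2 = inf (no meristem height limit)")
    t0, tf = float(t_span[0]), float(t_span[1])
    r0, h0, s0 = _coerce_initial(initial, params)
    if abs(s0 - params.S1) > 1e-12:
        raise ValueError("analytic reference requires S0 = S1")
    gamma = gamma_from_initial(r0, h0, params.alpha2)
    grid = np.arange(math.ceil(t0), math.floor(tf) + 1, dtype=float)
    times = np.unique(np.concatenate([[t0, tf], grid]))
    slope = params.k_lat / (1.0 + params.alpha2)
    r = r0 + slope * (times - t0)
    h = gamma * r ** (2.0 * params.alpha2)
    n = len(times)
    nan = np.full(n, np.nan)
    meta = {"regime_mode": "sink_only", "method": "analytic", "t_span": (t0, tf)}
    return Trajectory(
        times,
        r,
        h,
        np.full(n, s0),
        np.full(n, int(RegimeFlag.SINK_LIMITED), dtype=np.int8),
        nan,
        nan,
        nan,
        nan,
        nan,
        nan,
        params,
        meta,
    )


def annual_regimes(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Time-majority regime for each whole year covered by a trajectory.

    Returns ``(ages, regimes)`` where ``ages[k]`` labels the year
    ``[ages[k], ages[k]+1)`` and ``regimes[k]`` is the flag occupying the
    larger share of that year.
    """
    t0, tf = traj.times[0], traj.times[-1]
    years = np.arange(math.floor(t0), math.ceil(tf), dtype=float)
    starts = traj.times[:-1]
    ends = traj.times[1:]
    flags = traj.regime[:-1].astype(int)
    out = np.empty(len(years), dtype=np.int8)
    for k, ya in enumerate(years):
        yb = ya + 1.0
        lo = np.maximum(starts, ya)
        hi = np.minimum(ends, yb)
        dur = np.clip(hi - lo, 0.0, None)
        sink_time = float(np.sum(dur[flags == int(RegimeFlag.SINK_LIMITED)]))
        total = float(np.sum(dur))
        if total <= 0:  # year outside the simulated span
            out[k] = traj.regime[-1]
        else:
            out[k] = int(sink_time > 0.5 * total)
    return years, out
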