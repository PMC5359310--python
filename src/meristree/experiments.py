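"""Scripted numerical experiments and structural consistency checks.

Everything here is deterministic: the experiments re-run the simulator
under systematically varied configurations (initial-condition error fans,
assimilation sweeps, sink switch-off, CO2 counterfactuals) and return
tidy tables.  Magnitude assertions against the published figures are out
of scope — the site forcing behind them is not available — so the
experiments expose structure (regime maps, ordering, differences) rather
than figure-derived numbers.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ForcingSeries, TreeState, gamma_from_initial, height_from_allometry
from .dynamics import RegimeFlag
from .integrate import Trajectory, annual_regimes, simulate
from .params import ModelParameters

__all__ = [
    "max_radial_increment",
    "sensitivity_fan",
    "RegimeMap",
    "regime_map",
    "sink_off_comparison",
    "co2_counterfactual",
    "transition_age",
]


def max_radial_increment(params: ModelParameters) -> float:
    """Asymptotic maximal annual radial increment, m/y.

    For a tall tree (lateral meristem term dominant), reserves at the
    critical ratio, and no water-potential limitation, the sink-limited
    radial growth rate tends to the size-independent value

    ``dr/dt = k_lat / (1 + alpha2)``.

    With the reference composite ``k_lat = 0.0201`` m/y and
    ``alpha2 = 0.34`` this is 0.0150 m/y, i.e. 1.5 cm/y.
    """
    return params.k_lat / (1.0 + params.alpha2)


def sensitivity_fan(
    initial: Sequence[float],
    params: ModelParameters,
    forcing: ForcingSeries,
    t_span: Sequence[float],
    *,
    r0_errors: np.ndarray | None = None,
    h0_errors: Sequence[float] = (0.0,),
    reestimate_allometry: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Family of trajectories under perturbed initial conditions.

    One forward run per (r0 error, h0 error) pair; the default radius
    grid spans -20% to +20% in 4% increments.  With
    ``reestimate_allometry=True`` the meristem-activity ratio is re-derived
    for each member from the perturbed pair against the unperturbed one
    (the "allometry unknown" design); otherwise every member keeps the
    reference ratio.

    Returns a tidy frame with one row per (member, age).
    """
    if r0_errors is None:
        r0_errors = np.round(np.arange(-0.20, 0.2001, 0.04), 10)
    r0, h0 = float(initial[0]), float(initial[1])
    rows = []
    for dh in h0_errors:
        for dr in np.asarray(r0_errors, dtype=float):
            r_start = r0 * (1.0 + dr)
            h_start = h0 * (1.0 + dh)
            p = params
            if reestimate_allometry and (dr != 0.0 or dh != 0.0):
                # treat the perturbed initials as if they were the only
                # allometric information available
                gamma = gamma_from_initial(r0, h0, params.alpha2)
                implied = math.log(h_start / gamma) / (2.0 * math.log(r_start))
                if 0.0 < implied < 1.0:
                    p = params.replace(alpha2=implied)
            traj = simulate(
                TreeState(r_start, h_start, p.S1),
                p,
                forcing,
                t_span,
                rtol=rtol,
                atol=atol,
            )
            grid = np.arange(math.ceil(t_span[0]), math.floor(t_span[1]) + 1)
            rows.append(
                pd.DataFrame(
                    {
                        "r0_error": dr,
                        "h0_error": dh,
                        "age": grid.astype(float),
                        "height": traj.height_at(grid),
                        "radius": traj.radius_at(grid),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


@dataclasses.dataclass
class RegimeMap:
    """Simulated height and limiting regime on an (Amax multiplier, age)
    grid; regimes are the time-majority flag within each year."""

    amax_multipliers: np.ndarray
    ages: np.ndarray
    height: np.ndarray  # shape (n_multipliers, n_ages)
    regime: np.ndarray  # same shape, RegimeFlag values

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.amax_multipliers):
            rows.append(
                pd.DataFrame(
                    {
                        "amax_multiplier": m,
                        "age": self.ages,
                        "height": self.height[i],
                        "regime": [RegimeFlag(int(v)).name for v in self.regime[i]],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _grid_run(
    params: ModelParameters,
    forcing: ForcingSeries,
    initial: Sequence[float],
    ages: np.ndarray,
    regime_mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    traj = simulate(
        TreeState(float(initial[0]), float(initial[1]), params.S1),
        params,
        forcing,
        (float(ages[0]), float(ages[-1])),
        regime_mode=regime_mode,
    )
    years, regimes = annual_regimes(traj)
    # align annual regimes onto the requested integer ages (last year's
    # flag extends to the final age)
    reg = np.empty(len(ages), dtype=np.int8)
    for k, a in enumerate(ages):
        idx = int(np.clip(math.floor(a) - years[0], 0, len(regimes) - 1))
        reg[k] = regimes[idx]
    return traj.height_at(ages), reg


def regime_map(
    params: ModelParameters,
    forcing: ForcingSeries,
    initial: Sequence[float],
    amax_multipliers: Sequence[float],
    ages: Sequence[float] | np.ndarray,
) -> RegimeMap:
    """Sweep the maximal assimilation rate and record height and the
    limiting process (source vs sink) for every year of every run.

    The multiplier scales ``Amax`` relative to the supplied configuration
    (1.0 = reference).
    """
    ages = np.asarray(ages, dtype=float)
    mults = np.asarray(amax_multipliers, dtype=float)
    heights = np.empty((len(mults), len(ages)))
    regimes = np.empty((len(mults), len(ages)), dtype=np.int8)
    for i, m in enumerate(mults):
        p = params.replace(Amax_over_pi=params.Amax_over_pi * m)
        heights[i], regimes[i] = _grid_run(p, forcing, initial, ages, "auto")
    return RegimeMap(mults, ages, heights, regimes)


def sink_off_comparison(
    params: ModelParameters,
    forcing: ForcingSeries,
    initial: Sequence[float],
    amax_multipliers: Sequence[float],
    ages: Sequence[float] | np.ndarray,
) -> tuple[np.ndarray, RegimeMap, np.ndarray]:
    """Height difference when the meristem (sink) cap is switched off.

    For each assimilation multiplier the model is run twice — with the
    regime-switching dynamics and with the cap removed (growth purely
    supply-driven, reserves pinned at the critical ratio) — and the
    pairwise height difference (sink-off minus baseline, m) is returned
    together with the baseline regime map and the sink-off heights.

    Removing a constraint cannot reduce growth, so the difference is
    non-negative everywhere and zero wherever the baseline never left the
    source-limited regime.
    """
    ages = np.asarray(ages, dtype=float)
    base = regime_map(params, forcing, initial, amax_multipliers, ages)
    off = np.empty_like(base.height)
    for i, m in enumerate(base.amax_multipliers):
        p = params.replace(Amax_over_pi=params.Amax_over_pi * m)
        off[i], _ = _grid_run(p, forcing, initial, ages, "sink_off")
    return off - base.height, base, off


def co2_counterfactual(
    params: ModelParameters,
    forcing: ForcingSeries,
    initial: Sequence[float],
    t_span: Sequence[float] | None = None,
) -> tuple[Trajectory, Trajectory, pd.DataFrame]:
    """Paired runs with and without the historical CO2 rise.

    The counterfactual arm holds CO2 at the forcing's first-year value;
    everything else is identical.  Returns both trajectories and a table
    of the per-age height difference (ramp minus constant, m).
    """
    if t_span is None:
        t_span = (forcing.t_min, forcing.t_max)
    const_forcing = ForcingSeries(
        year=forcing.year,
        T=forcing.T,
        Q1=forcing.Q1,
        Cg=np.full(len(forcing), float(forcing.Cg[0])),
        Ra=forcing.Ra,
    )
    state = TreeState(float(initial[0]), float(initial[1]), params.S1)
    ramp = simulate(state, params, forcing, t_span)
    const = simulate(state, params, const_forcing, t_span)
    grid = np.arange(math.ceil(t_span[0]), math.floor(t_span[1]) + 1, dtype=float)
    diff = pd.DataFrame(
        {
            "age": grid,
            "height_ramp": ramp.height_at(grid),
            "height_constant": const.height_at(grid),
        }
    )
    diff["difference"] = diff["height_ramp"] - diff["height_constant"]
    return ramp, const, diff


def transition_age(ages: np.ndarray, regimes: np.ndarray) -> float:
    """First age at which the annual-majority regime is sink-limited;
    ``inf`` when the run stays source-limited throughout."""
    sink = np.flatnonzero(np.asarray(regimes) == int(RegimeFlag.SINK_LIMITED))
    if sink.size == 0:
        return math.inf
    return float(np.asarray(ages)[sink[0]])
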