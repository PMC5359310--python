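"""Bounded nonlinear least-squares calibration against stand height series.

The central object is :class:`StandGrowthModel`, a scikit-learn style
regressor: ``fit(ages, heights)`` adjusts a chosen subset of the
physiological parameters inside relative box bounds (trust-region
reflective least squares), ``predict(ages)`` runs the calibrated forward
simulation.  The module-level functions (:func:`fit_parameters`,
:func:`refit_h2`, :func:`predict_stand`) are thin wrappers replicating the
partial-fit and site-transfer protocols.

Calibration minimises the height misfit only: height is the stand
variable with the smallest measurement error.  An optional joint
height-plus-volume loss is available but off by default.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .core import ForcingSeries, TreeState
from .integrate import Trajectory, simulate
from .params import TUNABLE_FIELDS, ModelParameters

__all__ = [
    "MeasurementSeries",
    "FitSpec",
    "FitResult",
    "StandGrowthModel",
    "fit_parameters",
    "refit_h2",
    "predict_stand",
    "r_squared",
    "DEFAULT_FREE",
    "WIDE_BOUND_PARAMS",
]

#: Parameters freed by the default partial-fit protocol.
DEFAULT_FREE = (
    "Amax_over_pi",
    "C_over_pi",
    "C2_over_pi",
    "k_lat",
    "h2",
    "Qr",
    "Cr",
    "S1",
    "g1",
)

#: Parameters whose estimation is coarse enough to warrant a wider box.
WIDE_BOUND_PARAMS = ("k_lat", "h2")

DEFAULT_MARGIN = 0.20
WIDE_MARGIN = 0.50


@dataclasses.dataclass(frozen=True)
class MeasurementSeries:
    """Stand-mean measurements at irregular ages.

    The first record supplies the simulation initial state (r0, h0);
    ``density`` (trees/ha) is provenance metadata only — it does not feed
    the dynamics because the meristem-activity ratio is constant per
    stand.
    """

    age: np.ndarray
    height: np.ndarray
    radius: np.ndarray | None = None
    density: np.ndarray | None = None
    stand: str = ""
    site: str = ""

    def __post_init__(self) -> None:
        age = np.asarray(self.age, dtype=float)
        height = np.asarray(self.height, dtype=float)
        if age.ndim != 1 or age.size == 0:
            raise ValueError("measurement series must be a non-empty 1-d table")
        if height.shape != age.shape:
            raise ValueError("age and height must have the same length")
        if not np.all(np.diff(age) > 0):
            bad = int(np.flatnonzero(np.diff(age) <= 0)[0]) + 1
            raise ValueError(f"ages must be strictly increasing (row {bad})")
        if (height <= 0).any():
            raise ValueError("heights must be positive")
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "height", height)
        for name in ("radius", "density"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != age.shape:
                    raise ValueError(f"{name} must match the number of ages")
                object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.age)

    @property
    def initial(self) -> tuple[float, float]:
        """(r0, h0) from the first record; radius is required for r0."""
        if self.radius is None:
            raise ValueError("measurement series has no radius column for r0")
        return float(self.radius[0]), float(self.height[0])

    def to_dataframe(self) -> pd.DataFrame:
        data: dict = {"age": self.age, "height": self.height}
        if self.radius is not None:
            data["radius"] = self.radius
        if self.density is not None:
            data["density"] = self.density
        return pd.DataFrame(data)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, stand: str = "", site: str = ""
    ) -> "MeasurementSeries":
        if "age" not in df.columns or "height" not in df.columns:
            raise ValueError("measurement table needs 'age' and 'height' columns")
        return cls(
            age=df["age"].to_numpy(),
            height=df["height"].to_numpy(),
            radius=df["radius"].to_numpy() if "radius" in df.columns else None,
            density=df["density"].to_numpy() if "density" in df.columns else None,
            stand=stand,
            site=site,
        )


@dataclasses.dataclass(frozen=True)
class FitSpec:
    """Which parameters to free and how far they may move.

    ``rel_bounds`` maps parameter names to relative half-widths; missing
    names default to 20%, except the coarsely estimated lateral-growth
    composite and the meristem limit height which default to 50%.
    """

    free: tuple[str, ...] = DEFAULT_FREE
    rel_bounds: Mapping[str, float] = dataclasses.field(default_factory=dict)
    loss: str = "height"

    def __post_init__(self) -> None:
        unknown = [n for n in self.free if n not in TUNABLE_FIELDS]
        if unknown:
            raise ValueError(f"unknown free parameters: {unknown}")
        if self.loss not in ("height", "height+volume"):
            raise ValueError(f"unknown loss {self.loss!r}")

    def margin(self, name: str) -> float:
        if name in self.rel_bounds:
            return float(self.rel_bounds[name])
        return WIDE_MARGIN if name in WIDE_BOUND_PARAMS else DEFAULT_MARGIN


@dataclasses.dataclass
class FitResult:
    params: ModelParameters
    residuals: np.ndarray
    r2: float
    success: bool
    message: str
    nfev: int
    free: tuple[str, ...]


def r_squared(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot.

    SS_tot is taken about the observation mean; requires at least two
    observations with nonzero variance.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or obs.size < 2:
        raise ValueError("need two equal-length series of at least 2 points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observations have zero variance: R^2 is undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


class StandGrowthModel(RegressorMixin, BaseEstimator):
    """Tree-growth simulator wrapped as a scikit-learn regressor.

    ``fit(X, y)`` takes measurement ages (X, shape ``(n,)`` or ``(n, 1)``)
    and stand-mean heights (y, m), and calibrates the ``free`` parameters
    by bounded trust-region-reflective least squares on the height misfit.
    ``predict(X)`` returns simulated heights at the requested ages.
    ``score`` is the usual R^2, evaluated on the measurement ages only.

    Parameters
    ----------
    params : ModelParameters or None
        Start point and box centres; reference defaults when None.
    forcing : ForcingSeries
        Environmental drivers covering the measurement span.
    r0, h0 : float or None
        Initial radius and height at the first measurement age.  ``h0``
        falls back to the first observed height during ``fit``.
    free : tuple of str
        Parameter names to calibrate; empty tuple returns the start point
        with the raw misfit.
    rel_bounds : mapping, optional
        Relative box half-widths per parameter (see :class:`FitSpec`).
    alpha2 : float or None
        Meristem-activity ratio for this stand (from its allometry);
        overrides ``params.alpha2`` when given.
    """

    def __init__(
        self,
        params: ModelParameters | None = None,
        forcing: ForcingSeries | None = None,
        r0: float | None = None,
        h0: float | None = None,
        free: tuple[str, ...] = DEFAULT_FREE,
        rel_bounds: Mapping[str, float] | None = None,
        alpha2: float | None = None,
        loss: str = "height",
        volume_obs: np.ndarray | None = None,
        rtol: float = 1e-6,
        atol: float = 1e-9,
        max_nfev: int | None = None,
    ) -> None:
        self.params = params
        self.forcing = forcing
        self.r0 = r0
        self.h0 = h0
        self.free = free
        self.rel_bounds = rel_bounds
        self.alpha2 = alpha2
        self.loss = loss
        self.volume_obs = volume_obs
        self.rtol = rtol
        self.atol = atol
        self.max_nfev = max_nfev

    # -- internals ----------------------------------------------------------

    def _base_params(self) -> ModelParameters:
        p = self.params if self.params is not None else ModelParameters()
        if self.alpha2 is not None:
            p = p.replace(alpha2=self.alpha2)
        return p

    def _spec(self) -> FitSpec:
        return FitSpec(
            free=tuple(self.free),
            rel_bounds=dict(self.rel_bounds or {}),
            loss=self.loss,
        )

    @staticmethod
    def _ages(X) -> np.ndarray:
        ages = np.asarray(X, dtype=float)
        if ages.ndim == 2 and ages.shape[1] == 1:
            ages = ages[:, 0]
        if ages.ndim != 1:
            raise ValueError("X must be a 1-d array of ages (or a column vector)")
        return ages

    def _simulate(self, p: ModelParameters, ages: np.ndarray) -> Trajectory:
        initial = TreeState(self._r0_, self._h0_, p.S1)
        return simulate(
            initial,
            p,
            self.forcing,
            (ages[0], ages[-1]) if ages[-1] > ages[0] else (ages[0], ages[0] + 1.0),
            t_eval=ages,
            rtol=self.rtol,
            atol=self.atol,
        )

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y) -> "StandGrowthModel":
        if self.forcing is None:
            raise ValueError("a ForcingSeries is required to fit")
        ages = self._ages(X)
        heights = np.asarray(y, dtype=float)
        if heights.shape != ages.shape:
            raise ValueError("X and y must have matching lengths")
        if len(ages) < 3:
            raise ValueError("need at least 3 measurements to fit")
        if not np.all(np.diff(ages) > 0):
            raise ValueError("ages must be strictly increasing")
        if self.r0 is None:
            raise ValueError("r0 (initial radius) must be supplied")
        self._r0_ = float(self.r0)
        self._h0_ = float(self.h0) if self.h0 is not None else float(heights[0])

        spec = self._spec()
        base = self._base_params()
        free = spec.free
        ref = np.array([base.value_of(n) for n in free], dtype=float)
        if np.any(ref == 0):
            raise ValueError("free parameters must have nonzero reference values")

        vol_obs = None
        if spec.loss == "height+volume":
            if self.volume_obs is None:
                raise ValueError("height+volume loss needs volume_obs")
            vol_obs = np.asarray(self.volume_obs, dtype=float)

        def build(x: np.ndarray) -> ModelParameters:
            return base.replace(**{n: float(v) for n, v in zip(free, x * ref)})

        def residuals(x: np.ndarray) -> np.ndarray:
            traj = self._simulate(build(x), ages)
            res = traj.height_at(ages) - heights
            if vol_obs is not None:
                vol = math.pi * traj.radius_at(ages) ** 2 * traj.height_at(ages)
                # scale volume misfit to height units via the mean ratio
                scale = np.mean(np.abs(heights)) / max(np.mean(np.abs(vol_obs)), 1e-12)
                res = np.concatenate([res, (vol - vol_obs) * scale])
            return res

        if len(free) == 0:
            self.params_ = base
            self.residuals_ = residuals(np.empty(0))
            self.result_ = None
            self.success_ = True
            self.message_ = "no free parameters; returning the start point"
            self.nfev_ = 1
        else:
            lower = np.array([1.0 - spec.margin(n) for n in free])
            upper = np.array([1.0 + spec.margin(n) for n in free])
            x0 = np.ones(len(free))
            result = least_squares(
                residuals,
                x0,
                bounds=(lower, upper),
                method="trf",
                diff_step=1e-6,
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=self.max_nfev,
            )
            self.params_ = build(result.x)
            self.residuals_ = result.fun[: len(ages)]
            self.result_ = result
            self.success_ = bool(result.success)
            self.message_ = result.message
            self.nfev_ = int(result.nfev)

        pred = heights + (self.residuals_ if len(self.residuals_) == len(heights) else 0.0)
        self.r2_ = r_squared(pred, heights)
        self.fit_ages_ = ages
        self.fit_heights_ = heights
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        ages = self._ages(X)
        span_ages = np.unique(np.concatenate([[self.fit_ages_[0]], ages]))
        traj = self._simulate(self.params_, span_ages)
        return traj.height_at(ages)

    def simulate_trajectory(self, t_span=None) -> Trajectory:
        """Forward run with the calibrated parameters (full trajectory)."""
        check_is_fitted(self, "params_")
        if t_span is None:
            t_span = (self.fit_ages_[0], self.fit_ages_[-1])
        initial = TreeState(self._r0_, self._h0_, self.params_.S1)
        return simulate(initial, self.params_, self.forcing, t_span, rtol=self.rtol, atol=self.atol)


# ---------------------------------------------------------------------------
# protocol wrappers
# ---------------------------------------------------------------------------


def fit_parameters(
    measurements: MeasurementSeries,
    forcing: ForcingSeries,
    spec: FitSpec | None = None,
    params0: ModelParameters | None = None,
    *,
    alpha2: float | None = None,
    rtol: float = 1e-6,
) -> FitResult:
    """Partial fit of the free parameters to one stand's height series.

    The optimiser starts from the reference values (box centres) and is
    deterministic given that start point.
    """
    spec = spec or FitSpec()
    r0, h0 = measurements.initial
    model = StandGrowthModel(
        params=params0,
        forcing=forcing,
        r0=r0,
        h0=h0,
        free=spec.free,
        rel_bounds=dict(spec.rel_bounds),
        alpha2=alpha2,
        loss=spec.loss,
        rtol=rtol,
    )
    model.fit(measurements.age, measurements.height)
    return FitResult(
        params=model.params_,
        residuals=model.residuals_,
        r2=model.r2_,
        success=model.success_,
        message=model.message_,
        nfev=model.nfev_,
        free=spec.free,
    )


def refit_h2(
    measurements: MeasurementSeries,
    forcing: ForcingSeries,
    fitted: ModelParameters,
    margin: float = 0.20,
    *,
    alpha2: float | None = None,
    rtol: float = 1e-6,
) -> ModelParameters:
    """Site-transfer adaptation: re-fit only the meristem limit height h2
    within ``margin``, keeping every other calibrated parameter frozen.

    ``margin = 0`` returns the input unchanged.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if margin == 0:
        return fitted
    spec = FitSpec(free=("h2",), rel_bounds={"h2": margin})
    result = fit_parameters(measurements, forcing, spec, fitted, alpha2=alpha2, rtol=rtol)
    return result.params


def predict_stand(
    params: ModelParameters,
    forcing: ForcingSeries,
    initial: Sequence[float],
    ages: np.ndarray,
    *,
    alpha2: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Pure forward prediction of a stand from its first measurement.

    No fitting: the supplied parameters are used as-is (optionally with
    this stand's own meristem-activity ratio).  Returns a table of
    predicted height, radius and stem volume at the requested ages.
    """
    ages = np.asarray(ages, dtype=float)
    if alpha2 is not None:
        params = params.replace(alpha2=alpha2)
    r0, h0 = float(initial[0]), float(initial[1])
    traj = simulate(
        TreeState(r0, h0, params.S1),
        params,
        forcing,
        (ages[0], ages[-1]),
        t_eval=ages,
        rtol=rtol,
        atol=atol,
    )
    h = traj.height_at(ages)
    r = traj.radius_at(ages)
    return pd.DataFrame(
        {"age": ages, "height": h, "radius": r, "volume": math.pi * r**2 * h}
    )
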