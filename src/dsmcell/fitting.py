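"""Parameter estimation and goodness of fit.

* ``rmse_s`` — the degrees-of-freedom-corrected root-mean-squared
  residual ``S = sqrt(sum((y_exp - y_sim)^2) / (M - N))`` used as the
  goodness-of-fit statistic for simulated traces and fitted curves.
* ``gof_pass`` — the 5%-of-data-range acceptance rule: a fit is
  satisfactory when ``S`` falls strictly below 5% of the spread
  (max - min) of the experimental values.
* ``fit_hill`` — bounded least-squares fit of the TRPM4 Hill activation
  curve (Ca_half, n) to steady-state activation points, with a fixed
  multi-start grid so the result is deterministic.
* ``calibrate_cell`` — deterministic bounded coordinate descent of
  selected model parameters (conductance scale factors by default)
  against whole-cell targets such as the resting membrane potential.
* ``synthetic_activation_curve`` — generator of noisy steady-state
  activation datasets (sigmoid in log-Ca with additive Gaussian noise)
  emulating digitized experimental activation points.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .errors import ConfigurationError, FitError
from .gating import hill_activation
from .trpm4 import TRPM4Params

__all__ = [
    "ActivationDataset",
    "FitReport",
    "CalibrationReport",
    "rmse_s",
    "gof_pass",
    "fit_hill",
    "calibrate_cell",
    "calibrate_model",
    "synthetic_activation_curve",
]


@dataclass(frozen=True)
class ActivationDataset:
    """Steady-state activation points: (cai in mM, activation in [0, 1])."""

    cai_mm: Tuple[float, ...]
    activation: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cai_mm) != len(self.activation):
            raise ConfigurationError("cai and activation lengths differ")
        if len(self.cai_mm) < 3:
            raise ConfigurationError(
                "activation dataset needs >= 3 points for a two-parameter fit"
            )
        if any(c <= 0.0 for c in self.cai_mm):
            raise ConfigurationError("cai values must be > 0 mM")


@dataclass
class FitReport:
    """Outcome of a fit: parameters, the S statistic and the 5% verdict."""

    parameters: Dict[str, float]
    s_statistic: float
    threshold: float
    passed: bool


@dataclass
class CalibrationReport:
    """Before/after table of a whole-cell calibration."""

    before: Dict[str, float]
    after: Dict[str, float]
    targets: Dict[str, float]
    parameters: Dict[str, float]
    converged: bool
    objective: float


def rmse_s(
    y_exp: Sequence[float], y_sim: Sequence[float], n_params: int = 0
) -> float:
    """Standard error of the regression
    ``S = sqrt(sum((y_exp - y_sim)^2) / (M - N))``.

    ``M`` is the number of points and ``N`` the number of fitted
    parameters; requires ``M > N``.
    """
    ye = np.asarray(y_exp, dtype=float)
    ys = np.asarray(y_sim, dtype=float)
    if ye.shape != ys.shape or ye.ndim != 1:
        raise ConfigurationError("series must be one-dimensional, equal length")
    m = ye.size
    if m <= n_params:
        raise ConfigurationError(
            f"degrees of freedom <= 0: M = {m}, N = {n_params}"
        )
    return float(np.sqrt(np.sum((ye - ys) ** 2) / (m - n_params)))


def gof_pass(
    s: float, data_range: float, fraction: float = 0.05
) -> Tuple[bool, float]:
    """Apply the range-fraction acceptance rule.

    The threshold is ``fraction * data_range`` (data_range = max - min of
    the experimental values) and the fit passes iff ``s`` is *strictly*
    below it.  Returns ``(passed, threshold)``.
    """
    if not (data_range > 0.0):
        raise ConfigurationError(
            f"data_range must be > 0, got {data_range!r} (degenerate data)"
        )
    threshold = fraction * data_range
    return bool(s < threshold), threshold


_HILL_START_LOG10_CAH = (-5.0, -4.0, -3.0, -2.0)
_HILL_START_N = (0.5, 1.0, 2.0, 4.0)
_HILL_BOUNDS = ((-8.0, 0.0), (0.05, 10.0))  # log10(ca_half/mM), n


def fit_hill(data: ActivationDataset) -> Tuple[TRPM4Params, FitReport]:
    """Fit (Ca_half, n) of the Hill activation curve to the dataset.

    Bounded least squares from a fixed multi-start grid; the best
    converged start wins, ties broken by grid order, so the result is
    deterministic.  The report carries the S statistic with N = 2 and
    the 5%-of-range verdict.
    """
    cai = np.asarray(data.cai_mm, dtype=float)
    act = np.asarray(data.activation, dtype=float)
    log_cai = np.log(cai)

    def residuals(theta: np.ndarray) -> np.ndarray:
        log10_cah, n = theta
        arg = np.clip(n * (log10_cah * math.log(10.0) - log_cai), -600, 600)
        return 1.0 / (1.0 + np.exp(arg)) - act

    lo = np.array([b[0] for b in _HILL_BOUNDS])
    hi = np.array([b[1] for b in _HILL_BOUNDS])
    best = None
    for l10 in _HILL_START_LOG10_CAH:
        for n0 in _HILL_START_N:
            x0 = np.clip(np.array([l10, n0]), lo, hi)
            try:
                sol = least_squares(
                    residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-14,
                    ftol=1e-14, gtol=1e-14,
                )
            except Exception:
                continue
            if sol.success and (best is None or sol.cost < best.cost - 1e-15):
                best = sol
    if best is None:
        raise FitError("Hill fit failed to converge from every start point")
    ca_half = 10.0 ** best.x[0]
    n = float(best.x[1])
    y_fit = np.array(
        [hill_activation(c, ca_half, n) for c in cai]
    )
    s = rmse_s(act, y_fit, n_params=2)
    spread = float(act.max() - act.min())
    passed, threshold = gof_pass(s, spread) if spread > 0 else (False, math.nan)
    params = TRPM4Params(ca_half_mm=ca_half, hill_n=n)
    report = FitReport(
        parameters={"ca_half_mm": ca_half, "hill_n": n},
        s_statistic=s,
        threshold=threshold,
        passed=passed,
    )
    return params, report


def synthetic_activation_curve(
    ca_half_mm: float = 4.0e-4,
    hill_n: float = 2.0,
    n_points: int = 9,
    noise_sd: float = 0.02,
    log10_min: float = -5.0,
    log10_max: float = -2.0,
    seed: int = 0,
) -> ActivationDataset:
    """Synthetic steady-state activation dataset.

    Samples ``n_points`` concentrations evenly on the log10-Ca axis,
    evaluates the Hill curve at the given (Ca_half, n) and adds i.i.d.
    Gaussian noise of ``noise_sd``, clipped to [0, 1].  Deterministic
    for a given seed.
    """
    if n_points < 3:
        raise ConfigurationError("n_points must be >= 3")
    rng = np.random.default_rng(seed)
    log10_cai = np.linspace(log10_min, log10_max, n_points)
    cai = 10.0 ** log10_cai
    act = np.array([hill_activation(c, ca_half_mm, hill_n) for c in cai])
    act = act + rng.normal(0.0, noise_sd, size=n_points)
    act = np.clip(act, 0.0, 1.0)
    return ActivationDataset(tuple(cai), tuple(act))


# ---------------------------------------------------------------------------
# whole-cell calibration


def calibrate_cell(
    evaluate: Callable[[Dict[str, float]], Dict[str, float]],
    targets: Dict[str, float],
    parameters: Dict[str, float],
    bounds: Dict[str, Tuple[float, float]],
    weights: Optional[Dict[str, float]] = None,
    scales: Optional[Dict[str, float]] = None,
    n_sweeps: int = 3,
    tol: float = 1e-8,
) -> CalibrationReport:
    """Deterministic bounded coordinate descent against whole-cell
    targets.

    Parameters
    ----------
    evaluate : callable
        Maps a parameter dict to a dict of measured quantities (e.g.
        ``{"rmp_mv": -52.3}``); it encapsulates model construction and
        simulation, keeping this routine model-agnostic.
    targets : dict
        Desired value per measured quantity.
    parameters : dict
        Starting value per tunable parameter.
    bounds : dict
        ``(lo, hi)`` box per parameter; the result never leaves it.
    weights, scales : dict, optional
        Per-target weight and normalization scale (defaults 1 and
        ``max(|target|, 1)``).

    The objective is the weighted sum of squared normalized target
    errors.  Each sweep minimizes one parameter at a time with a bounded
    deterministic scalar search.  If the targets are already met
    (objective below ``tol``) the parameters are returned unchanged.
    """
    weights = weights or {}
    scales = scales or {}
    for k in targets:
        scales.setdefault(k, max(abs(targets[k]), 1.0))
        weights.setdefault(k, 1.0)
    for name in parameters:
        if name not in bounds:
            raise ConfigurationError(f"no bounds given for parameter {name!r}")
        lo, hi = bounds[name]
        if not (lo <= parameters[name] <= hi):
            raise ConfigurationError(
                f"start value of {name!r} outside its bounds {bounds[name]}"
            )

    def objective(p: Dict[str, float]) -> Tuple[float, Dict[str, float]]:
        meas = evaluate(p)
        err = 0.0
        for k, tgt in targets.items():
            if k not in meas or not math.isfinite(meas[k]):
                err += weights[k] * 25.0  # missing/failed measurement penalty
                continue
            err += weights[k] * ((meas[k] - tgt) / scales[k]) ** 2
        return err, meas

    params = dict(parameters)
    f0, before = objective(params)
    if f0 < tol:
        return CalibrationReport(
            before=before, after=before, targets=dict(targets),
            parameters=params, converged=True, objective=f0,
        )
    f_best = f0
    for _ in range(n_sweeps):
        improved = False
        for name in sorted(params):
            lo, hi = bounds[name]

            def f1(x: float, _name: str = name) -> float:
                trial = dict(params)
                trial[_name] = x
                return objective(trial)[0]

            sol = minimize_scalar(
                f1, bounds=(lo, hi), method="bounded",
                options={"xatol": max((hi - lo) * 1e-4, 1e-12)},
            )
            if sol.fun < f_best - 1e-12:
                params[name] = float(np.clip(sol.x, lo, hi))
                f_best = float(sol.fun)
                improved = True
        if f_best < tol or not improved:
            break
    f_final, after = objective(params)
    return CalibrationReport(
        before=before,
        after=after,
        targets=dict(targets),
        parameters=params,
        converged=f_final < tol,
        objective=f_final,
    )


def calibrate_model(
    model,
    targets: Dict[str, float],
    channels: Sequence[str] = ("trpm4", "kir", "ik"),
    bound: float = 0.3,
    weights: Optional[Dict[str, float]] = None,
    n_sweeps: int = 3,
):
    """Calibrate channel conductances of a cell model against whole-cell
    targets, within a relative ``bound`` (0.3 = +/-30%) of each gmax.

    Supported target keys: ``rmp_mv`` (resting membrane potential).
    Returns ``(calibrated_model, CalibrationReport)``; the report's
    ``parameters`` are the per-channel scale factors.
    """
    from .simulator import resting_state, scale_gmax

    known = {"rmp_mv"}
    unknown = set(targets) - known
    if unknown:
        raise ConfigurationError(
            f"unsupported calibration targets {sorted(unknown)}; "
            f"supported: {sorted(known)}"
        )

    def evaluate(factors: Dict[str, float]) -> Dict[str, float]:
        m = scale_gmax(model, factors)
        out: Dict[str, float] = {}
        if "rmp_mv" in targets:
            try:
                out["rmp_mv"] = resting_state(m).v_mv
            except Exception:
                out["rmp_mv"] = math.nan
        return out

    report = calibrate_cell(
        evaluate,
        targets=targets,
        parameters={c: 1.0 for c in channels},
        bounds={c: (1.0 - bound, 1.0 + bound) for c in channels},
        weights=weights,
        n_sweeps=n_sweeps,
    )
    from .simulator import scale_gmax as _sg

    return _sg(model, report.parameters), report
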