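"""Constitutive-model fitting: Model classes, Results objects, comparison.

The interface follows the conventions of statistical modelling packages: a
model object is constructed from data (a :class:`~caber.constitutive.FilamentTrace`
plus the fluid environment), its :meth:`fit` returns a results object
carrying parameter estimates, goodness of fit, residuals and a
:meth:`summary` table, and plotting hangs off the results.

* :class:`NewtonianThinning` — ordinary least squares of ``D/D0`` against
  ``t``; the slope maps to the viscosity.
* :class:`UCMThinning` — ordinary least squares of ``ln(D/D0)`` against
  ``t``; the slope maps to the relaxation time (lambda = -1 / (3 s)).
* :class:`GiesekusThinning` — nonlinear least squares of the implicit law
  in the *time* domain (the law is explicit in t, implicit in D), with the
  initialisation heuristic that makes the regression robust: the Newtonian
  fit bounds the viscosity from above (10% of it is the starting value) and
  the UCM fit seeds the relaxation time.

R² conventions: each linear fit reports R² in the domain of its regression
(ratio for Newtonian, log-ratio for UCM); the Giesekus fit reports R² in
the diameter-ratio domain via round-trip inversion so the three models are
comparable on a thinning plot.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import least_squares

from .constitutive import (
    FilamentTrace,
    FluidEnvironment,
    GiesekusParams,
    NewtonianParams,
    UCMParams,
    X_NONINERTIAL,
    giesekus_ratio,
    giesekus_time,
    newtonian_breakup_time,
)
from .exceptions import (
    InvalidParameterError,
    MinPointsError,
    NonThinningError,
    UndefinedRSquaredError,
)

__all__ = [
    "ThinningResults",
    "NewtonianThinning",
    "UCMThinning",
    "GiesekusThinning",
    "ModelComparison",
    "BreakupEstimate",
    "RelaxationDecay",
    "DecayFitResults",
    "r_squared",
    "fit_newtonian",
    "fit_ucm",
    "fit_giesekus",
    "compare_models",
    "estimate_breakup_time",
    "fit_first_order_decay",
]

ModelParams = Union[NewtonianParams, UCMParams, GiesekusParams]


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination, ``1 - SS_res / SS_tot``.

    ``SS_tot`` is taken about the observed mean.  Raises
    :class:`UndefinedRSquaredError` when the observations have zero
    variance (R² is then meaningless).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise InvalidParameterError("observed and predicted must be equal-length 1-D")
    if obs.size < 2:
        raise MinPointsError("R^2 needs at least 2 points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedRSquaredError("observed values are all equal")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class ThinningResults:
    """Fit of one constitutive law to one trace.

    ``params`` is the parameter set of the fitted law; ``r_squared`` is
    computed in the domain recorded in ``rsq_domain``; ``residuals`` are
    per retained point in the fit domain; ``flags`` collects warnings
    (excluded points, non-convergence, ...).
    """

    model_id: str
    params: ModelParams
    r_squared: float
    residuals: np.ndarray
    n_points: int
    fit_window: Tuple[float, float]
    rsq_domain: str
    converged: bool = True
    flags: List[str] = field(default_factory=list)
    trace: Optional[FilamentTrace] = None
    env: Optional[FluidEnvironment] = None

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise MinPointsError("a thinning fit needs at least 3 points")
        if self.r_squared > 1.0 + 1e-12:
            raise InvalidParameterError("r_squared cannot exceed 1")

    def predict(self, t) -> np.ndarray:
        """Model diameter ratio D/D0 at times ``t``."""
        from .constitutive import newtonian_ratio, ucm_ratio

        t = np.asarray(t, dtype=float)
        d0 = self.trace.d0
        if self.model_id == "newtonian":
            return np.asarray(newtonian_ratio(t, self.params, self.env, d0))
        if self.model_id == "ucm":
            return np.asarray(ucm_ratio(t, self.params))
        return np.asarray(giesekus_ratio(t, self.params, self.env, d0))

    def summary(self) -> str:
        lines = [
            f"Thinning fit: {self.model_id}",
            "-" * 40,
        ]
        p = self.params
        if isinstance(p, NewtonianParams):
            lines.append(f"  viscosity eta0      {p.viscosity:12.6g} Pa s")
            lines.append(f"  correction X        {p.correction_factor:12.6g}")
        elif isinstance(p, UCMParams):
            lines.append(
                f"  relaxation lambda   {p.relaxation_time * 1e3:12.6g} ms"
            )
        else:
            lines.append(f"  viscosity eta0      {p.viscosity:12.6g} Pa s")
            lines.append(
                f"  relaxation lambda_G {p.relaxation_time * 1e3:12.6g} ms"
            )
            lines.append(f"  mobility a          {p.mobility:12.6g}")
        lines.append(f"  R^2 ({self.rsq_domain})  {self.r_squared:12.6g}")
        lines.append(f"  n points            {self.n_points:12d}")
        lines.append(
            f"  fit window          [{self.fit_window[0]:.6g}, "
            f"{self.fit_window[1]:.6g}] s"
        )
        if not self.converged:
            lines.append("  WARNING: optimiser did not converge")
        for fl in self.flags:
            lines.append(f"  note: {fl}")
        return "\n".join(lines)

    def plot(self, ax=None, log=False):
        """Data and fitted curve on a thinning plot (ratio vs time)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.trace.times
        ax.plot(t, self.trace.ratio, "o", ms=3, label="data")
        tt = np.linspace(t[0], t[-1], 200)
        ax.plot(tt, self.predict(tt), "-", label=f"{self.model_id} fit")
        if log:
            ax.set_yscale("log")
        ax.set_xlabel("time since motion stop (s)")
        ax.set_ylabel("D / D0")
        ax.legend()
        return ax

    def to_dict(self) -> Dict:
        p = self.params
        if isinstance(p, NewtonianParams):
            pd = {"viscosity_pa_s": p.viscosity, "correction_factor": p.correction_factor}
        elif isinstance(p, UCMParams):
            pd = {"relaxation_time_s": p.relaxation_time}
        else:
            pd = {
                "viscosity_pa_s": p.viscosity,
                "relaxation_time_s": p.relaxation_time,
                "mobility": p.mobility,
            }
        return {
            "model": self.model_id,
            "params": pd,
            "r_squared": self.r_squared,
            "rsq_domain": self.rsq_domain,
            "n_points": self.n_points,
            "fit_window_s": list(self.fit_window),
            "converged": self.converged,
            "flags": list(self.flags),
        }


# ---------------------------------------------------------------------------
# Model classes
# ---------------------------------------------------------------------------

class ThinningModel:
    """Base class: a thinning trace plus the fixed fluid environment.

    Surface tension is always a user input, never fitted.  The fit window
    starts at motion stop and ends at the last positive diameter; set
    ``exclude_terminal=True`` to drop the sharp terminal regime
    (t / t_F > 0.8) seen in some biopolymer solutions.
    """

    model_id: str = ""

    def __init__(
        self,
        trace: FilamentTrace,
        env: Optional[FluidEnvironment] = None,
        exclude_terminal: bool = False,
        min_diameter: float = 0.0,
    ) -> None:
        self.trace = trace
        self.env = env
        self.exclude_terminal = exclude_terminal
        self.min_diameter = min_diameter

    @classmethod
    def from_csv(cls, path, env=None, **kw) -> "ThinningModel":
        return cls(FilamentTrace.from_csv(path), env=env, **kw)

    def _window_mask(self) -> np.ndarray:
        d = self.trace.diameters
        mask = d > max(self.min_diameter, 0.0)
        if (~mask).any():
            pass  # zero/too-small diameters are excluded silently; flagged by callers
        if self.exclude_terminal and self.trace.t_f is not None:
            mask &= self.trace.times <= 0.8 * self.trace.t_f
        return mask

    def fit(self) -> ThinningResults:  # pragma: no cover - abstract
        raise NotImplementedError


def _linear_fit(
    x: np.ndarray, y: np.ndarray, require_negative_slope: bool = False
) -> Tuple[float, float, float, np.ndarray]:
    """OLS line fit returning (slope, intercept, r_squared, residuals)."""
    slope, intercept = np.polyfit(x, y, 1)
    if require_negative_slope and slope >= 0:
        raise NonThinningError("diameter does not decrease over the fit window")
    pred = intercept + slope * x
    return float(slope), float(intercept), r_squared(y, pred), y - pred


class NewtonianThinning(ThinningModel):
    """Newtonian fit: OLS of the diameter ratio against time.

    The slope ``s`` of ``D/D0`` versus ``t`` gives
    ``eta0 = -(2X - 1) alpha / (3 D0 s)``; the correction factor ``X`` and
    surface tension are fixed by the caller.
    """

    model_id = "newtonian"

    def __init__(self, trace, env, correction_factor: float = X_NONINERTIAL, **kw):
        super().__init__(trace, env=env, **kw)
        if not 0.5 < correction_factor <= 1.0:
            raise InvalidParameterError("X must satisfy 0.5 < X <= 1")
        self.correction_factor = correction_factor

    def fit(self) -> ThinningResults:
        mask = self._window_mask()
        t = self.trace.times[mask]
        ratio = self.trace.ratio[mask]
        if t.size < 3:
            raise MinPointsError("Newtonian fit needs >= 3 positive-diameter points")
        slope, _, rsq, resid = _linear_fit(t, ratio, require_negative_slope=True)
        x = self.correction_factor
        eta0 = -(2.0 * x - 1.0) * self.env.surface_tension / (
            3.0 * self.trace.d0 * slope
        )
        flags = []
        if mask.size != int(mask.sum()):
            flags.append(f"{mask.size - int(mask.sum())} points excluded from window")
        return ThinningResults(
            model_id=self.model_id,
            params=NewtonianParams(viscosity=eta0, correction_factor=x),
            r_squared=rsq,
            residuals=resid,
            n_points=int(t.size),
            fit_window=(float(t[0]), float(t[-1])),
            rsq_domain="diameter ratio",
            flags=flags,
            trace=self.trace,
            env=self.env,
        )


class UCMThinning(ThinningModel):
    """UCM fit: OLS of ``ln(D/D0)`` against time.

    The slope ``s`` gives ``lambda = -1 / (3 s)``; R² is reported in the
    log domain (the domain of the regression).  Zero diameters cannot enter
    the log and are excluded with a warning flag.
    """

    model_id = "ucm"

    def fit(self) -> ThinningResults:
        mask = self._window_mask()
        n_excluded = int(mask.size - mask.sum())
        t = self.trace.times[mask]
        ratio = self.trace.ratio[mask]
        if t.size < 3:
            raise MinPointsError("UCM fit needs >= 3 positive-diameter points")
        flags = []
        if n_excluded:
            flags.append(f"{n_excluded} zero/out-of-window points excluded")
            n_nonpos = int((self.trace.diameters <= 0).sum())
            if n_nonpos:
                warnings.warn(
                    f"UCM fit: {n_nonpos} non-positive diameters excluded",
                    stacklevel=2,
                )
        slope, _, rsq, resid = _linear_fit(
            t, np.log(ratio), require_negative_slope=True
        )
        lam = -1.0 / (3.0 * slope)
        return ThinningResults(
            model_id=self.model_id,
            params=UCMParams(relaxation_time=lam),
            r_squared=rsq,
            residuals=resid,
            n_points=int(t.size),
            fit_window=(float(t[0]), float(t[-1])),
            rsq_domain="log diameter ratio",
            flags=flags,
            trace=self.trace,
            env=self.env,
        )


#: Floor for the Giesekus viscosity search: the mobility group
#: 2*alpha*lambda*a/(eta0*D0) is singular at eta0 = 0.
GIESEKUS_ETA_FLOOR = 1e-9
GIESEKUS_D_MIN = 1e-6


def _giesekus_profile_start(
    d: np.ndarray,
    t: np.ndarray,
    alpha: float,
    d0: float,
    eta_upper: float,
    c_bounds: Tuple[float, float],
) -> Optional[np.ndarray]:
    """Profiled global search for the Giesekus time-domain fit.

    In the form ``t = k [ln(d + B0) - ln(c + B0)] + C0 (c - d)`` the model
    is linear in ``(k, C0)`` for fixed ``(B0, c)``, so those two are solved
    exactly by least squares on a grid over ``(log B0, c)`` and the best
    grid point refined by a simplex search.  The winner is mapped back to
    ``(eta, lambda, a)`` (via ``eta = C0 alpha / (2 d0)``,
    ``lambda a = B0 eta d0 / (2 alpha)``, ``lambda = (4 lambda a - k)/3``)
    and returned as a start point for the bounded solver, or ``None`` when
    no admissible parameter set exists.  This sidesteps the sloppy,
    ill-conditioned valley that defeats purely local iterations.
    """
    from scipy.optimize import minimize

    c0_max = max(2.0 * d0 * eta_upper / alpha, 1e-300)

    def solve_linear(log_b0: float, c: float):
        b0 = math.exp(log_b0)
        col1 = np.log(d + b0) - math.log(c + b0)
        col2 = c - d
        a_mat = np.column_stack([col1, col2])
        coef, *_ = np.linalg.lstsq(a_mat, t, rcond=None)
        k, c0 = coef
        c0 = min(max(c0, 0.0), c0_max)  # viscosity bound
        resid = a_mat @ np.array([k, c0]) - t
        return float(k), float(c0), float(0.5 * np.sum(resid**2))

    def profiled_cost(z):
        log_b0, c = z
        c = min(max(c, c_bounds[0]), c_bounds[1])
        return solve_linear(log_b0, c)[2]

    best = None
    c_mid = 0.5 * (c_bounds[0] + c_bounds[1])
    for log_b0 in np.linspace(math.log(1e-6), math.log(1e4), 40):
        cost = profiled_cost((log_b0, c_mid))
        if best is None or cost < best[1]:
            best = ((log_b0, c_mid), cost)
    res = minimize(
        profiled_cost, np.array(best[0]), method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-300, "maxiter": 400},
    )
    log_b0, c = res.x
    c = min(max(c, c_bounds[0]), c_bounds[1])
    k, c0, _ = solve_linear(log_b0, c)
    eta = max(c0 * alpha / (2.0 * d0), GIESEKUS_ETA_FLOOR)
    b0 = math.exp(log_b0)
    lam_a = b0 * eta * d0 / (2.0 * alpha)
    lam = (4.0 * lam_a - k) / 3.0
    if not lam > 0:
        return None
    mobility = lam_a / lam
    return np.array([eta, lam, mobility, c])


class GiesekusThinning(ThinningModel):
    """Giesekus fit: bounded nonlinear least squares in the time domain.

    The implicit law is explicit in ``t``, so residuals are
    ``t_model(D_i/D0) - t_i``.  Initialisation follows the regression
    heuristic that stabilises this notoriously initialisation-sensitive
    fit: the Newtonian-fit viscosity is an upper bound for ``eta0`` (10% of
    it is the starting value), the UCM-fit relaxation time seeds
    ``lambda_G``, and the mobility starts at 0.1 within [0, 10].  On
    non-convergence a multi-start fallback over 5 log-spaced relaxation
    times is tried; the best-found parameters are returned flagged.

    R² is reported in the diameter-ratio domain via round-trip inversion so
    it is comparable with the other models on a thinning plot.

    Because the law is implicit, the normalising diameter D0 enters the
    model nonlinearly, and D0 is itself a quantised measurement (one camera
    pixel of error rescales every ratio by ~1/D0px).  The Giesekus
    parameter surface is sloppy enough that such a small systematic slides
    the optimum far along a flat valley, so the fit profiles out a bounded
    nuisance scale ``c`` on D0 (``d0_slack`` relative half-width, default
    3%; set 0 to pin D0 at its measured value).
    """

    model_id = "giesekus"

    def __init__(
        self,
        trace,
        env,
        correction_factor: float = 1.0,
        mobility_start: float = 0.1,
        mobility_bounds: Tuple[float, float] = (0.0, 10.0),
        d0_slack: float = 0.03,
        **kw,
    ):
        super().__init__(trace, env=env, **kw)
        self.correction_factor = correction_factor
        self.mobility_start = mobility_start
        self.mobility_bounds = mobility_bounds
        if not 0 <= d0_slack < 0.5:
            raise InvalidParameterError("d0_slack must be in [0, 0.5)")
        self.d0_slack = d0_slack

    #: ratio units: a point must rise this far above the running minimum
    #: before it is treated as unphysical recoil rather than noise
    RECOIL_TOLERANCE = 0.05

    def _usable_points(self) -> Tuple[np.ndarray, np.ndarray, List[str]]:
        """Retain points with 0 < d <= 1 and no gross recoil.

        Points that rise more than ``RECOIL_TOLERANCE`` above the running
        minimum (recoil sections, measurement glitches) are down-weighted
        to zero by exclusion and flagged; plateaus and ordinary noise
        wiggle are kept.
        """
        mask = self._window_mask()
        t = self.trace.times[mask]
        d = self.trace.ratio[mask]
        flags: List[str] = []
        keep = d <= 1.0
        keep[0] = True
        running_min = np.minimum.accumulate(np.where(keep, d, np.inf))
        rising = d > running_min + self.RECOIL_TOLERANCE
        if rising.any():
            flags.append(
                f"{int(rising.sum())} non-monotone (rising) points excluded"
            )
        keep &= ~rising
        n_over = int((~(d <= 1.0)).sum())
        if n_over:
            flags.append(f"{n_over} points above D0 excluded")
        return t[keep], np.clip(d[keep], GIESEKUS_D_MIN, 1.0), flags

    def fit(self) -> ThinningResults:
        t, d, flags = self._usable_points()
        if t.size < 4:
            raise MinPointsError("Giesekus fit needs >= 4 usable points")
        newt = NewtonianThinning(
            self.trace, self.env, correction_factor=self.correction_factor,
            exclude_terminal=self.exclude_terminal,
            min_diameter=self.min_diameter,
        ).fit()
        ucm = UCMThinning(
            self.trace, env=self.env, exclude_terminal=self.exclude_terminal,
            min_diameter=self.min_diameter,
        ).fit()
        eta_upper = newt.params.viscosity
        lam_start = ucm.params.relaxation_time
        d0 = self.trace.d0
        alpha = self.env.surface_tension

        # With the nuisance scale c on D0 (true D0 = c * measured D0, true
        # ratio = d / c) the time-domain model collapses to
        #   t = k [ln(d + B0) - ln(c + B0)] - C0 (d - c),
        # with B0 = 2 alpha lam a / (eta D0_meas), C0 = 2 D0_meas eta/alpha
        # and k = lam (4a - 3); c = 1 recovers the standard form.
        def residual(theta: np.ndarray) -> np.ndarray:
            eta, lam, a, c = theta
            eta = max(eta, GIESEKUS_ETA_FLOOR)
            b0 = 2.0 * alpha * lam * a / (eta * d0)
            c0 = 2.0 * d0 * eta / alpha
            k = lam * (4.0 * a - 3.0)
            return k * (np.log(d + b0) - math.log(c + b0)) - c0 * (d - c) - t

        def jacobian(theta: np.ndarray) -> np.ndarray:
            # Analytic: the objective valley is extremely flat when the
            # mobility group is large and finite differences stall there.
            eta, lam, a, c = theta
            eta = max(eta, GIESEKUS_ETA_FLOOR)
            b0 = 2.0 * alpha * lam * a / (eta * d0)
            c0 = 2.0 * d0 * eta / alpha
            k = lam * (4.0 * a - 3.0)
            log_diff = np.log(d + b0) - math.log(c + b0)
            db_sens = 1.0 / (d + b0) - 1.0 / (c + b0)
            db0_da = (b0 / a) if a > 0 else 2.0 * alpha * lam / (eta * d0)
            dt_deta = k * db_sens * (-b0 / eta) + (c - d) * c0 / eta
            dt_dlam = (4.0 * a - 3.0) * log_diff + k * db_sens * (b0 / lam)
            dt_da = 4.0 * lam * log_diff + k * db_sens * db0_da
            dt_dc = np.full_like(d, -k / (c + b0) + c0)
            return np.column_stack([dt_deta, dt_dlam, dt_da, dt_dc])

        slack = self.d0_slack
        lo = np.array(
            [GIESEKUS_ETA_FLOOR, 1e-8, self.mobility_bounds[0], 1.0 - slack]
        )
        hi = np.array(
            [eta_upper, np.inf, self.mobility_bounds[1], 1.0 + slack]
        )
        if slack == 0:  # degenerate bounds are not allowed by the optimiser
            lo[3], hi[3] = 1.0 - 1e-12, 1.0 + 1e-12

        def solve(x0: np.ndarray):
            return least_squares(
                residual, x0, jac=jacobian, bounds=(lo, hi), method="trf",
                x_scale="jac", ftol=None, gtol=None, xtol=1e-15,
                max_nfev=5000,
            )

        x0 = np.array(
            [
                np.clip(0.1 * eta_upper, lo[0], hi[0]),
                lam_start,
                np.clip(self.mobility_start, *self.mobility_bounds),
                1.0,
            ]
        )
        sol = solve(x0)
        converged = bool(sol.success)
        # global cross-check: the profiled (linear-in-(k, C0)) search is
        # immune to the sloppy valley that can trap the local solver
        profile_x0 = _giesekus_profile_start(
            d, t, alpha, d0, eta_upper, (lo[3], hi[3])
        )
        if profile_x0 is not None:
            profile_x0 = np.clip(profile_x0, lo, hi)
            trial = solve(profile_x0)
            if trial.cost < sol.cost:
                sol = trial
                converged = bool(trial.success)
        if not converged:
            # multi-start fallback: 5 log-spaced relaxation-time seeds
            for lam_seed in np.geomspace(lam_start / 10.0, lam_start * 10.0, 5):
                trial = solve(np.array([x0[0], lam_seed, x0[2], 1.0]))
                if trial.cost < sol.cost:
                    sol = trial
                if trial.success:
                    converged = True
                    break
            if not converged:
                flags.append("optimiser did not converge; best-found parameters")
        eta, lam, a, c = sol.x
        params = GiesekusParams(
            viscosity=max(float(eta), GIESEKUS_ETA_FLOOR),
            relaxation_time=float(lam),
            mobility=float(a),
        )
        if abs(c - 1.0) > 1e-6:
            flags.append(f"D0 nuisance scale c = {c:.5f}")
        pred_ratio = c * np.asarray(
            giesekus_ratio(t, params, self.env, c * d0)
        )
        rsq = r_squared(d, pred_ratio)
        return ThinningResults(
            model_id=self.model_id,
            params=params,
            r_squared=rsq,
            residuals=sol.fun,
            n_points=int(t.size),
            fit_window=(float(t[0]), float(t[-1])),
            rsq_domain="diameter ratio",
            converged=converged,
            flags=flags,
            trace=self.trace,
            env=self.env,
        )


# ---------------------------------------------------------------------------
# Functional wrappers (thin aliases over the model classes)
# ---------------------------------------------------------------------------

def fit_newtonian(
    trace: FilamentTrace,
    env: FluidEnvironment,
    correction_factor: float = X_NONINERTIAL,
    **kw,
) -> ThinningResults:
    """Fit the Newtonian law; see :class:`NewtonianThinning`."""
    return NewtonianThinning(trace, env, correction_factor=correction_factor, **kw).fit()


def fit_ucm(trace: FilamentTrace, **kw) -> ThinningResults:
    """Fit the UCM law; see :class:`UCMThinning`."""
    return UCMThinning(trace, **kw).fit()


def fit_giesekus(
    trace: FilamentTrace, env: FluidEnvironment, **kw
) -> ThinningResults:
    """Fit the Giesekus law; see :class:`GiesekusThinning`."""
    return GiesekusThinning(trace, env, **kw).fit()


# ---------------------------------------------------------------------------
# Model comparison and derived quantities
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    """All three fits on one trace, ordered by goodness of fit.

    ``newtonian_adequate`` is set when the Newtonian R² comes within
    ``adequacy_threshold`` of the best model's — the practical signal that
    the fluid has lost its viscoelasticity.
    """

    results: List[ThinningResults]
    errors: Dict[str, str]
    newtonian_adequate: bool
    adequacy_threshold: float

    @property
    def best(self) -> Optional[ThinningResults]:
        return self.results[0] if self.results else None

    def __getitem__(self, model_id: str) -> ThinningResults:
        for r in self.results:
            if r.model_id == model_id:
                return r
        raise KeyError(model_id)

    def summary(self) -> str:
        lines = ["Model comparison (ordered by R^2)", "=" * 40]
        for r in self.results:
            lines.append(r.summary())
            lines.append("")
        for mid, msg in self.errors.items():
            lines.append(f"{mid}: no fit ({msg})")
        lines.append(f"Newtonian adequate: {self.newtonian_adequate}")
        return "\n".join(lines)

    def to_dict(self) -> Dict:
        return {
            "results": [r.to_dict() for r in self.results],
            "errors": dict(self.errors),
            "newtonian_adequate": self.newtonian_adequate,
        }


def compare_models(
    trace: FilamentTrace,
    env: FluidEnvironment,
    correction_factor: float = X_NONINERTIAL,
    adequacy_threshold: float = 0.01,
    **kw,
) -> ModelComparison:
    """Fit all three laws and rank them by reported R².

    Individual fit failures are captured per model (absent entry plus error
    message) rather than propagated.
    """
    results: List[ThinningResults] = []
    errors: Dict[str, str] = {}
    for model_id, builder in (
        ("newtonian", lambda: fit_newtonian(trace, env, correction_factor, **kw)),
        ("ucm", lambda: fit_ucm(trace, **kw)),
        ("giesekus", lambda: fit_giesekus(trace, env, correction_factor=correction_factor, **kw)),
    ):
        try:
            results.append(builder())
        except Exception as exc:  # per-model absence, not a pipeline failure
            errors[model_id] = str(exc)
    results.sort(key=lambda r: r.r_squared, reverse=True)
    adequate = False
    if results:
        best = results[0].r_squared
        for r in results:
            if r.model_id == "newtonian":
                adequate = r.r_squared >= best - adequacy_threshold
    return ModelComparison(
        results=results,
        errors=errors,
        newtonian_adequate=adequate,
        adequacy_threshold=adequacy_threshold,
    )


@dataclass(frozen=True)
class BreakupEstimate:
    """Observed and model-extrapolated filament break-up times (s)."""

    observed: Optional[float]
    extrapolated: Optional[float]


def estimate_breakup_time(
    trace: FilamentTrace,
    newtonian_result: Optional[ThinningResults] = None,
) -> BreakupEstimate:
    """Observed break-up time plus the Newtonian-law extrapolation.

    The extrapolated value applies ``t_F = 3 eta0 D0 / (alpha (2X - 1))``
    to the supplied Newtonian fit; it underestimates the observed time for
    viscoelastic fluids whose exponential tail outlives the linear decay.
    """
    extrapolated = None
    if newtonian_result is not None:
        if newtonian_result.env is None:
            raise InvalidParameterError("newtonian_result lacks its environment")
        extrapolated = newtonian_breakup_time(
            newtonian_result.params, newtonian_result.env, trace.d0
        )
    return BreakupEstimate(observed=trace.t_f, extrapolated=extrapolated)


# ---------------------------------------------------------------------------
# Storage-decay fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecayFitResults:
    """First-order decay of the relaxation time over storage days.

    ``ln(lambda) = ln(initial_relaxation_time) - decay_rate * day``.
    """

    initial_relaxation_time: float
    decay_rate: float  # per day
    r_squared: float

    def predict(self, days) -> np.ndarray:
        return self.initial_relaxation_time * np.exp(
            -self.decay_rate * np.asarray(days, dtype=float)
        )

    def summary(self) -> str:
        return (
            "First-order storage decay\n"
            f"  initial relaxation time {self.initial_relaxation_time:.6g} s\n"
            f"  decay rate              {self.decay_rate:.6g} / day\n"
            f"  R^2 (log domain)        {self.r_squared:.6g}"
        )


class RelaxationDecay:
    """Model for the loss of elasticity of a stored fluid sample.

    Fitted as a log-linear regression of relaxation time against storage
    day, i.e. first-order (exponential) decay.
    """

    def __init__(self, storage_days, relaxation_times) -> None:
        self.days = np.asarray(storage_days, dtype=float)
        self.relaxation_times = np.asarray(relaxation_times, dtype=float)
        if self.days.shape != self.relaxation_times.shape or self.days.ndim != 1:
            raise InvalidParameterError("days and relaxation times must match")
        if self.days.size < 3:
            raise MinPointsError("decay fit needs >= 3 (day, lambda) pairs")
        if np.any(self.relaxation_times <= 0):
            raise InvalidParameterError("relaxation times must be > 0")

    def fit(self) -> DecayFitResults:
        slope, intercept, rsq, _ = _linear_fit(self.days, np.log(self.relaxation_times))
        return DecayFitResults(
            initial_relaxation_time=float(np.exp(intercept)),
            decay_rate=-slope,
            r_squared=rsq,
        )


def fit_first_order_decay(storage_days, relaxation_times) -> DecayFitResults:
    """Fit first-order decay of relaxation time; see :class:`RelaxationDecay`."""
    return RelaxationDecay(storage_days, relaxation_times).fit()
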