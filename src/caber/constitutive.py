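"""Constitutive filament-thinning laws and dimensionless diagnostics.

In a capillary break-up extensional rheometry (CaBER) experiment a small
liquid bridge is held between two platens which are rapidly pulled apart.
Surface tension then drives the thinning of the filament that forms, and the
mid-filament diameter ``D(t)`` — normalised by its value ``D0`` when the
platens stop moving — carries the extensional rheology of the fluid.

Three constitutive descriptions are implemented:

* **Newtonian** — constant shear viscosity ``eta0``; the diameter ratio
  decreases linearly, ``D/D0 = 1 - (2X-1) * alpha * t / (3 * eta0 * D0)``,
  where ``alpha`` is the surface tension and ``X`` a shape-correction factor
  (1 for an ideal cylindrical filament, 0.7127 for non-inertial smooth
  filaments).
* **Upper Convected Maxwell (UCM)** — the simplest viscoelastic model with
  negligible viscosity; the ratio decays exponentially with time constant
  three times the relaxation time: ``D/D0 = exp(-t / (3 * lambda_ucm))``.
* **Giesekus** — a viscoelastic model with viscosity ``eta0``, relaxation
  time ``lambda_g`` and a polymer-interaction (mobility) parameter ``a``.
  The diameter ratio obeys an *implicit* relation which is explicit in time:

  ``(4a-3) * ln((d + B) / (1 + B)) - (2 D0 eta0 / (alpha lambda_g)) * (d - 1)
  = t / lambda_g``,   with ``d = D/D0`` and ``B = 2 alpha lambda_g a /
  (eta0 D0)``.  Forward evaluation of ``D(t)`` requires numerically
  inverting this monotone map.

All quantities are SI throughout (m, s, Pa s, N/m).  The module also
provides the dimensionless diagnostics used to confirm that capillary
thinning is the controlling mechanism: the Bond number (gravity versus
capillarity), the capillary length, the inertial (Rayleigh) and viscous
timescales, the elastocapillary number and the Hencky strain of the platen
gap.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.optimize import brentq

from .exceptions import (
    InvalidGeometryError,
    InvalidParameterError,
    SingularCorrectionError,
)

__all__ = [
    "FluidEnvironment",
    "NewtonianParams",
    "UCMParams",
    "GiesekusParams",
    "GeometrySpec",
    "FilamentTrace",
    "Timescales",
    "newtonian_ratio",
    "newtonian_breakup_time",
    "ucm_ratio",
    "giesekus_time",
    "giesekus_simplified_time",
    "giesekus_ratio",
    "giesekus_breakup_horizon",
    "bond_number",
    "capillary_length",
    "sample_volume",
    "timescales",
    "hencky_strain",
]

#: Standard gravitational acceleration, m s^-2.
G_STANDARD = 9.81

#: Default shape-correction factor for real (non-inertial, smooth) filaments.
X_NONINERTIAL = 0.7127

ArrayLike = Union[float, np.ndarray]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluidEnvironment:
    """Ambient fluid properties entering the thinning laws.

    Parameters
    ----------
    surface_tension : float
        Surface tension ``alpha`` in N/m.  Must be positive.
    density : float
        Fluid density ``rho`` in kg/m^3 (default 1000, aqueous).
    gravity : float
        Gravitational acceleration in m/s^2 (default 9.81).
    """

    surface_tension: float
    density: float = 1000.0
    gravity: float = G_STANDARD

    def __post_init__(self) -> None:
        if not self.surface_tension > 0:
            raise InvalidParameterError("surface_tension must be > 0")
        if not self.density > 0:
            raise InvalidParameterError("density must be > 0")
        if self.gravity < 0:
            raise InvalidParameterError("gravity must be >= 0")


@dataclass(frozen=True)
class NewtonianParams:
    """Newtonian fluid: viscosity and filament-shape correction factor.

    ``correction_factor`` (``X``) is 1 for an ideal cylindrical filament and
    0.7127 for non-inertial smooth filaments; the thinning law diverges at
    X = 0.5, so X must lie in (0.5, 1].
    """

    viscosity: float
    correction_factor: float = X_NONINERTIAL

    def __post_init__(self) -> None:
        if not self.viscosity > 0:
            raise InvalidParameterError("viscosity must be > 0")
        if not 0.5 < self.correction_factor <= 1.0:
            raise SingularCorrectionError(
                f"correction factor X must satisfy 0.5 < X <= 1, "
                f"got {self.correction_factor}"
            )


@dataclass(frozen=True)
class UCMParams:
    """Upper Convected Maxwell fluid: a single relaxation time (s)."""

    relaxation_time: float

    def __post_init__(self) -> None:
        if not self.relaxation_time > 0:
            raise InvalidParameterError("relaxation_time must be > 0")


@dataclass(frozen=True)
class GiesekusParams:
    """Giesekus fluid: viscosity, relaxation time and mobility parameter.

    ``mobility`` (``a``) couples polymer interactions into the stress
    evolution; ``a = 0`` with vanishing viscosity recovers the UCM model,
    while ``4a = 3`` makes the thinning law exactly linear in time.
    A zero viscosity with nonzero mobility is rejected: the mobility term
    ``2 alpha lambda a / (eta0 D0)`` is singular there.
    """

    viscosity: float
    relaxation_time: float
    mobility: float

    def __post_init__(self) -> None:
        if self.viscosity < 0:
            raise InvalidParameterError("viscosity must be >= 0")
        if not self.relaxation_time > 0:
            raise InvalidParameterError("relaxation_time must be > 0")
        if self.mobility < 0:
            raise InvalidParameterError("mobility must be >= 0")
        if self.viscosity == 0 and self.mobility > 0:
            raise InvalidParameterError(
                "viscosity = 0 with mobility > 0 makes the Giesekus "
                "mobility term singular"
            )


@dataclass(frozen=True)
class GeometrySpec:
    """Platen geometry of the stretching device.

    The platens are flat circular faces of radius ``platen_radius``
    (default 0.6 mm, i.e. 1.2 mm diameter).  ``initial_gap`` (g0) is the
    loaded-sample gap, ``final_gap`` (g_f) the stretched gap, bounded by
    ``max_separation`` (default 4 mm).
    """

    initial_gap: float
    final_gap: float
    platen_radius: float = 0.6e-3
    max_separation: float = 4.0e-3

    def __post_init__(self) -> None:
        if not self.platen_radius > 0:
            raise InvalidGeometryError("platen_radius must be > 0")
        if not 0 < self.initial_gap < self.final_gap <= self.max_separation:
            raise InvalidGeometryError(
                f"require 0 < g0 < g_f <= max_separation, got "
                f"g0={self.initial_gap}, g_f={self.final_gap}, "
                f"max={self.max_separation}"
            )

    @property
    def platen_diameter(self) -> float:
        return 2.0 * self.platen_radius


@dataclass
class FilamentTrace:
    """Mid-filament diameter versus time — the central observable.

    Times are in seconds, zeroed at the instant the platens stop moving;
    ``diameters`` are in metres with ``diameters[0] = D0 > 0``.  ``t_f`` is
    the observed break-up time (seconds from motion stop) or ``None`` if
    the filament did not rupture within the recording.
    """

    times: np.ndarray
    diameters: np.ndarray
    t_f: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.times.shape != self.diameters.shape or self.times.ndim != 1:
            raise InvalidParameterError("times and diameters must be equal-length 1-D")
        if self.times.size < 1:
            raise InvalidParameterError("trace must contain at least one sample")
        if self.times[0] != 0.0:
            raise InvalidParameterError("times must start at 0 (platen motion stop)")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if np.any(self.diameters < 0):
            raise InvalidParameterError("diameters must be non-negative")
        if not self.diameters[0] > 0:
            raise InvalidParameterError("initial diameter D0 must be > 0")
        if self.t_f is not None:
            positive = self.diameters > 0
            if positive.any():
                last_alive = self.times[positive][-1]
                if self.t_f < last_alive:
                    raise InvalidParameterError(
                        "t_f precedes the last frame with a surviving filament"
                    )

    @property
    def d0(self) -> float:
        """Initial diameter D0 (m), the diameter at motion stop."""
        return float(self.diameters[0])

    @property
    def ratio(self) -> np.ndarray:
        """Dimensionless diameter ratio D/D0."""
        return self.diameters / self.d0

    def __len__(self) -> int:
        return self.times.size

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                "diameter_m": self.diameters,
                "diameter_ratio": self.ratio,
            }
        )

    def to_csv(self, path) -> None:
        """Write the trace as CSV with columns time_s, diameter_m, diameter_ratio."""
        self.to_dataframe().to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path, t_f: Optional[float] = None) -> "FilamentTrace":
        import pandas as pd

        df = pd.read_csv(path)
        for col in ("time_s", "diameter_m"):
            if col not in df.columns:
                raise InvalidParameterError(f"trace CSV missing column {col!r}")
        return cls(df["time_s"].to_numpy(), df["diameter_m"].to_numpy(), t_f=t_f)


@dataclass(frozen=True)
class Timescales:
    """Characteristic timescales and the elastocapillary number.

    ``rayleigh`` — inertio-capillary time sqrt(rho D0^3 / 8 alpha) (s);
    ``viscous`` — visco-capillary time eta0 D0 / 2 alpha (s);
    ``elastocapillary`` — Ec = 2 lambda alpha / (eta0 D0) (dimensionless).
    Components are ``None`` when their parameters were not supplied.
    """

    rayleigh: Optional[float] = None
    viscous: Optional[float] = None
    elastocapillary: Optional[float] = None


# ---------------------------------------------------------------------------
# Thinning laws
# ---------------------------------------------------------------------------

def _check_d0(d0: float) -> None:
    if not d0 > 0:
        raise InvalidGeometryError(f"initial diameter D0 must be > 0, got {d0}")


def _check_t(t: ArrayLike) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("time must be >= 0")
    return t


def newtonian_ratio(
    t: ArrayLike, p: NewtonianParams, env: FluidEnvironment, d0: float
) -> ArrayLike:
    """Newtonian diameter ratio ``D/D0`` at time ``t``.

    ``D/D0 = 1 - (2X - 1) alpha t / (3 eta0 D0)``, clamped at 0 after the
    break-up time (the linear law would otherwise go negative; a zero ratio
    is the model's definition of rupture).

    Parameters
    ----------
    t : float or ndarray
        Time since platen motion stop, s.  Must be >= 0.
    p, env : NewtonianParams, FluidEnvironment
    d0 : float
        Initial mid-filament diameter, m.
    """
    _check_d0(d0)
    tt = _check_t(t)
    x = p.correction_factor
    ratio = 1.0 - (2.0 * x - 1.0) * env.surface_tension * tt / (3.0 * p.viscosity * d0)
    ratio = np.clip(ratio, 0.0, None)
    return float(ratio) if np.isscalar(t) or np.ndim(t) == 0 else ratio


def newtonian_breakup_time(
    p: NewtonianParams, env: FluidEnvironment, d0: float
) -> float:
    """Break-up time of a Newtonian filament: ``3 eta0 D0 / (alpha (2X-1))``.

    This is the time at which :func:`newtonian_ratio` reaches exactly zero.
    """
    _check_d0(d0)
    x = p.correction_factor
    if x <= 0.5:  # unreachable for validated params; kept for raw inputs
        raise SingularCorrectionError("X <= 0.5 gives no finite break-up time")
    return 3.0 * p.viscosity * d0 / (env.surface_tension * (2.0 * x - 1.0))


def ucm_ratio(t: ArrayLike, p: UCMParams) -> ArrayLike:
    """UCM diameter ratio ``exp(-t / (3 lambda))`` — strictly positive."""
    tt = _check_t(t)
    ratio = np.exp(-tt / (3.0 * p.relaxation_time))
    return float(ratio) if np.ndim(t) == 0 else ratio


def _giesekus_b(p: GiesekusParams, env: FluidEnvironment, d0: float) -> float:
    """Mobility group ``B = 2 alpha lambda a / (eta0 D0)`` (0 when a = 0)."""
    if p.mobility == 0.0:
        return 0.0
    return (
        2.0 * env.surface_tension * p.relaxation_time * p.mobility
        / (p.viscosity * d0)
    )


def _check_d_ratio(d_ratio: ArrayLike) -> np.ndarray:
    d = np.asarray(d_ratio, dtype=float)
    if np.any(d <= 0):
        raise InvalidParameterError("d_ratio must be > 0 (logarithm domain)")
    if np.any(d > 1):
        raise InvalidParameterError("d_ratio must be <= 1")
    return d


def giesekus_time(
    d_ratio: ArrayLike, p: GiesekusParams, env: FluidEnvironment, d0: float
) -> ArrayLike:
    """Time at which a Giesekus filament reaches diameter ratio ``d_ratio``.

    Evaluates the implicit law explicitly in time:

    ``t = lambda (4a-3) ln((d + B)/(1 + B)) - (2 D0 eta0 / alpha)(d - 1)``

    with ``B = 2 alpha lambda a / (eta0 D0)``.  Returns 0 at ``d_ratio = 1``
    and increases monotonically as ``d_ratio`` decreases (for mobility
    a <= 3/4, the physically fitted range).
    """
    _check_d0(d0)
    d = _check_d_ratio(d_ratio)
    b = _giesekus_b(p, env, d0)
    lam, a = p.relaxation_time, p.mobility
    log_term = lam * (4.0 * a - 3.0) * np.log((d + b) / (1.0 + b))
    visc_term = (2.0 * d0 * p.viscosity / env.surface_tension) * (d - 1.0)
    t = log_term - visc_term
    return float(t) if np.ndim(d_ratio) == 0 else t


def giesekus_simplified_time(
    d_ratio: ArrayLike, p: GiesekusParams, env: FluidEnvironment, d0: float
) -> ArrayLike:
    """Small-mobility-product approximation of :func:`giesekus_time`.

    When ``B = 2 alpha lambda a / (eta0 D0)`` is small compared with the
    diameter ratio, the implicit law reduces to

    ``t = (4a-3) lambda ln(d) + (2 eta0 / alpha)(D0 - D)``.

    As the relaxation time decays, the first (viscoelastic) term becomes
    negligible and viscous thinning dominates.
    """
    _check_d0(d0)
    d = _check_d_ratio(d_ratio)
    t = (
        (4.0 * p.mobility - 3.0) * p.relaxation_time * np.log(d)
        + (2.0 * p.viscosity / env.surface_tension) * (d0 - d * d0)
    )
    return float(t) if np.ndim(d_ratio) == 0 else t


def giesekus_breakup_horizon(
    p: GiesekusParams, env: FluidEnvironment, d0: float, d_min: float = 1e-6
) -> float:
    """Numeric break-up horizon: time at which ``D/D0`` reaches ``d_min``.

    Unless ``4a = 3`` the implicit law never reaches zero exactly, so a small
    floor ``d_min`` defines the usable time horizon for inversion.
    """
    return float(giesekus_time(d_min, p, env, d0))


def giesekus_ratio(
    t: ArrayLike,
    p: GiesekusParams,
    env: FluidEnvironment,
    d0: float,
    d_min: float = 1e-6,
    xtol: float = 1e-12,
    return_status: bool = False,
):
    """Giesekus diameter ratio ``D/D0`` at time ``t`` by numerical inversion.

    Bracketing root-finding (Brent) on the monotone map
    :func:`giesekus_time` over ``d in [d_min, 1]``.  Times beyond the
    numeric break-up horizon return ratio 0; when ``return_status`` is true
    a boolean mask flags those clipped evaluations.

    Round-trip consistency ``giesekus_ratio(giesekus_time(d)) == d`` holds to
    well below 1e-6 in ``d``.
    """
    _check_d0(d0)
    tt = _check_t(t)
    horizon = giesekus_breakup_horizon(p, env, d0, d_min=d_min)

    def invert_one(ti: float) -> float:
        if ti == 0.0:
            return 1.0
        if ti >= horizon:
            return 0.0
        f = lambda d: giesekus_time(d, p, env, d0) - ti
        return brentq(f, d_min, 1.0, xtol=xtol)

    flat = np.atleast_1d(tt)
    out = np.array([invert_one(ti) for ti in flat])
    clipped = flat >= horizon
    if np.ndim(t) == 0:
        out, clipped = float(out[0]), bool(clipped[0])
    if return_status:
        return out, clipped
    return out


# ---------------------------------------------------------------------------
# Dimensionless diagnostics
# ---------------------------------------------------------------------------

def bond_number(env: FluidEnvironment, length: float) -> float:
    """Bond number ``Bo = rho g L^2 / alpha``.

    The ratio of gravitational to capillary forces over length scale ``L``
    (here the initial sample diameter).  Bo << 1 means gravity-induced
    sagging of the bridge is negligible.
    """
    if length < 0:
        raise InvalidGeometryError("length scale must be >= 0")
    return env.density * env.gravity * length**2 / env.surface_tension


def capillary_length(env: FluidEnvironment) -> float:
    """Capillary length ``sqrt(alpha / (rho g))`` in metres.

    Gap sizes below this length keep the liquid bridge capillarity-dominated.
    Diverges (returns inf) for g = 0.
    """
    if env.gravity == 0:
        return math.inf
    return math.sqrt(env.surface_tension / (env.density * env.gravity))


def sample_volume(geom: GeometrySpec) -> float:
    """Loaded sample volume ``pi r^2 g0`` (m^3): a cylinder filling the
    initial gap between the platens."""
    return math.pi * geom.platen_radius**2 * geom.initial_gap


def timescales(
    env: FluidEnvironment,
    d0: float,
    viscosity: Optional[float] = None,
    relaxation_time: Optional[float] = None,
) -> Timescales:
    """Characteristic timescales of a filament-thinning test.

    rayleigh = sqrt(rho D0^3 / (8 alpha)); viscous = eta0 D0 / (2 alpha);
    Ec = 2 lambda alpha / (eta0 D0).  Components whose parameters are absent
    are returned as ``None``.  A test is capillarity-controlled when its
    duration greatly exceeds both timescales; Ec >> 1 signals that elastic
    relaxation outlives viscous thinning.
    """
    _check_d0(d0)
    rayleigh = math.sqrt(env.density * d0**3 / (8.0 * env.surface_tension))
    viscous = None
    ec = None
    if viscosity is not None:
        if not viscosity > 0:
            raise InvalidParameterError("viscosity must be > 0")
        viscous = viscosity * d0 / (2.0 * env.surface_tension)
        if relaxation_time is not None:
            if relaxation_time < 0:
                raise InvalidParameterError("relaxation_time must be >= 0")
            ec = 2.0 * relaxation_time * env.surface_tension / (viscosity * d0)
    return Timescales(rayleigh=rayleigh, viscous=viscous, elastocapillary=ec)


def hencky_strain(gap: ArrayLike, g0: float) -> ArrayLike:
    """Logarithmic (Hencky) strain ``ln(gap / g0)`` of the platen gap."""
    gap_arr = np.asarray(gap, dtype=float)
    if not g0 > 0:
        raise InvalidGeometryError("g0 must be > 0")
    if np.any(gap_arr <= 0):
        raise InvalidGeometryError("gap must be > 0")
    eps = np.log(gap_arr / g0)
    return float(eps) if np.ndim(gap) == 0 else eps
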