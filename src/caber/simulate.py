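"""Synthetic stretching experiments with exact ground truth.

Everything the imaging and fitting layers consume can be generated here:
platen-separation kinematics (fast ramp, slight overshoot, damped
oscillation), diameter–time traces following any of the three constitutive
laws, and rendered backlit image stacks with camera pixelation and noise.
Ground truth (noiseless diameters, drawn pixel widths, event frames) is
carried alongside every artefact so recovery can be asserted exactly.

The renderer draws silhouettes, not physics: the neck shape between the
platens is a smooth (sinusoidal) interpolation from the platen-contact
width down to the mid-diameter, with the neck pinned near the stationary
platen as the single moving platen stretches the bridge.  Ground truth is
defined by the drawn integer pixel widths, so imaging tests stay exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .constitutive import (
    FilamentTrace,
    FluidEnvironment,
    GeometrySpec,
    GiesekusParams,
    NewtonianParams,
    UCMParams,
    giesekus_breakup_horizon,
    giesekus_ratio,
    newtonian_breakup_time,
    newtonian_ratio,
    ucm_ratio,
)
from .exceptions import InvalidGeometryError, InvalidParameterError
from .imaging import FrameStack

__all__ = [
    "PlatenMotionParams",
    "RenderConfig",
    "GroundTruth",
    "MotionProfile",
    "simulate_motion",
    "simulate_trace",
    "render_stack",
    "simulate_experiment",
    "make_benchmark_suite",
    "BenchmarkFixture",
    "BenchmarkSuite",
]

ModelParams = Union[NewtonianParams, UCMParams, GiesekusParams]


@dataclass(frozen=True)
class PlatenMotionParams:
    """Separation kinematics of the moving platen.

    A constant-speed ramp (default 75 mm/s) from g0 to g_f, followed by a
    damped oscillation ``A exp(-tau/damping_time) sin(2 pi tau / period)``
    about g_f with amplitude ``A = overshoot_fraction * (g_f - g0)``.
    """

    separation_speed: float = 0.075
    overshoot_fraction: float = 0.05
    damping_time: float = 0.003
    oscillation_period: float = 0.004

    def __post_init__(self) -> None:
        if not self.separation_speed > 0:
            raise InvalidParameterError("separation_speed must be > 0")
        if self.overshoot_fraction < 0:
            raise InvalidParameterError("overshoot_fraction must be >= 0")
        if not self.damping_time > 0:
            raise InvalidParameterError("damping_time must be > 0")
        if not self.oscillation_period > 0:
            raise InvalidParameterError("oscillation_period must be > 0")


@dataclass(frozen=True)
class RenderConfig:
    """Camera and drawing parameters for the silhouette renderer."""

    image_shape: Tuple[int, int] = (144, 96)  # rows (axial), cols
    pixel_scale: float = 2.0e-5  # m per pixel
    background_level: float = 200.0
    foreground_level: float = 40.0
    noise_sd: float = 5.0
    platen_diameter: float = 1.2e-3
    contact_fraction: float = 0.9  # fluid contact width / platen diameter
    platen_slab_px: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.foreground_level == self.background_level:
            raise InvalidParameterError("foreground must differ from background")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if not self.pixel_scale > 0:
            raise InvalidParameterError("pixel_scale must be > 0")


@dataclass
class GroundTruth:
    """Generating truth for a synthetic experiment.

    ``gap`` and ``mid_diameter`` are metres per frame (noiseless);
    ``widths_px``/``gap_px`` are the pixel-exact drawn values when a stack
    was rendered; event frames index into the same timeline.
    """

    model_id: str
    params: ModelParams
    mid_diameter: np.ndarray
    motion_stop_frame: int = 0
    breakup_frame: Optional[int] = None
    gap: Optional[np.ndarray] = None
    d0: Optional[float] = None
    widths_px: Optional[np.ndarray] = None
    gap_px: Optional[np.ndarray] = None


@dataclass
class MotionProfile:
    """Gap series plus the analytic settling index (ground truth)."""

    gap: np.ndarray
    settle_frame: int
    ramp_end_frame: int


def simulate_motion(
    geom: GeometrySpec,
    motion: PlatenMotionParams,
    frame_times: np.ndarray,
    settle_tolerance: float = 0.02,
) -> MotionProfile:
    """Platen gap at each frame time (t = 0 is the solenoid trigger).

    Ramp: ``gap = g0 + speed * t`` until reaching g_f at
    ``t_ramp = (g_f - g0)/speed``; then a damped sine about g_f.  The
    ground-truth settling index is the first frame whose oscillation
    envelope has fallen within ``settle_tolerance * g_f``.
    """
    t = np.asarray(frame_times, dtype=float)
    if t.size == 0 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise InvalidParameterError("frame_times must increase from 0")
    g0, gf = geom.initial_gap, geom.final_gap  # GeometrySpec enforces g0 < gf
    speed = motion.separation_speed
    t_ramp = (gf - g0) / speed
    amp = motion.overshoot_fraction * (gf - g0)
    gap = np.where(t < t_ramp, g0 + speed * t, gf)
    tau = np.clip(t - t_ramp, 0.0, None)
    if amp > 0:
        osc = amp * np.exp(-tau / motion.damping_time) * np.sin(
            2.0 * math.pi * tau / motion.oscillation_period
        )
        gap = np.where(t >= t_ramp, gf + osc, gap)
    band = settle_tolerance * gf
    if amp > band:
        tau_settle = motion.damping_time * math.log(amp / band)
    else:
        tau_settle = 0.0
    t_settle = t_ramp + tau_settle
    settle_frame = int(np.searchsorted(t, t_settle, side="left"))
    settle_frame = min(settle_frame, t.size - 1)
    ramp_end_frame = int(np.searchsorted(t, t_ramp, side="left"))
    return MotionProfile(
        gap=gap, settle_frame=settle_frame, ramp_end_frame=ramp_end_frame
    )


def _law_ratio(
    model_id: str,
    params: ModelParams,
    env: Optional[FluidEnvironment],
    d0: float,
    t: np.ndarray,
) -> np.ndarray:
    if model_id == "newtonian":
        return np.asarray(newtonian_ratio(t, params, env, d0))
    if model_id == "ucm":
        return np.asarray(ucm_ratio(t, params))
    if model_id == "giesekus":
        return np.asarray(giesekus_ratio(t, params, env, d0))
    raise InvalidParameterError(f"unknown model_id {model_id!r}")


def _model_breakup_time(
    model_id: str,
    params: ModelParams,
    env: Optional[FluidEnvironment],
    d0: float,
) -> Optional[float]:
    if model_id == "newtonian":
        return newtonian_breakup_time(params, env, d0)
    if model_id == "giesekus":
        return giesekus_breakup_horizon(params, env, d0)
    return None  # UCM never reaches zero


def simulate_trace(
    model_id: str,
    params: ModelParams,
    d0: float,
    frame_rate: float,
    duration: float,
    env: Optional[FluidEnvironment] = None,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> Tuple[FilamentTrace, GroundTruth]:
    """Sample a thinning law at camera rate, optionally with diameter noise.

    The trace is truncated at the model's break-up time (where one exists
    within the recording) and ``t_f`` recorded; additive Gaussian noise
    (standard deviation ``noise_sd`` metres, seeded) is applied to the
    diameters and clipped at zero, while the returned ground truth keeps
    the noiseless values.
    """
    if not frame_rate > 0:
        raise InvalidParameterError("frame_rate must be > 0")
    if model_id in ("newtonian", "giesekus") and env is None:
        raise InvalidParameterError(f"{model_id} model requires env")
    n = int(math.floor(duration * frame_rate)) + 1
    t = np.arange(n) / frame_rate
    t_break = _model_breakup_time(model_id, params, env, d0)
    breakup_frame: Optional[int] = None
    t_f: Optional[float] = None
    if t_break is not None and t_break <= t[-1]:
        breakup_frame = int(np.searchsorted(t, t_break, side="right"))
        t_f = t_break
        t = t[:breakup_frame]
    ratio = _law_ratio(model_id, params, env, d0, t)
    diam = d0 * ratio
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = np.clip(diam + rng.normal(0.0, noise_sd, size=diam.shape), 0.0, None)
        noisy[0] = max(noisy[0], 1e-3 * d0)  # D0 must stay positive
    else:
        noisy = diam
    trace = FilamentTrace(times=t, diameters=noisy, t_f=t_f)
    truth = GroundTruth(
        model_id=model_id,
        params=params,
        mid_diameter=diam,
        motion_stop_frame=0,
        breakup_frame=breakup_frame,
        d0=d0,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _neck_widths_px(
    gap_px: int,
    d_px: float,
    contact_px: float,
    g0_px: float,
) -> np.ndarray:
    """Drawn integer widths for the rows inside the gap.

    Axial coordinate z runs from the bottom (stationary) platen face; the
    neck sits at ``z_n = min(g0_px / 2, gap_px / 2)`` — i.e. at the centre
    of the original sample, hence progressively nearer the stationary
    platen as the bridge is stretched.  Widths interpolate sinusoidally
    from the contact width at each platen down to ``d_px`` at the neck.
    """
    if gap_px <= 0:
        return np.zeros(0, dtype=int)
    z = np.arange(1, gap_px + 1, dtype=float)  # row centres inside the gap
    z_n = min(0.5 * g0_px, 0.5 * gap_px)
    z_n = max(z_n, 1.0)
    w = np.empty_like(z)
    lower = z <= z_n
    # raised cosine: zero slope at the neck and at the platen contacts, so
    # the drawn minimum equals d_px even when the neck falls between rows
    u = (z_n - z[lower]) / z_n
    w[lower] = d_px + (contact_px - d_px) * 0.5 * (1.0 - np.cos(math.pi * u))
    span = max(gap_px - z_n, 1.0)
    u2 = np.clip((z[~lower] - z_n) / span, 0.0, 1.0)
    w[~lower] = d_px + (contact_px - d_px) * 0.5 * (1.0 - np.cos(math.pi * u2))
    return np.rint(np.clip(w, 0, None)).astype(int)


def _cap_widths_px(
    gap_px: int, contact_px: float, cap_fraction: float = 0.3
) -> np.ndarray:
    """Post-rupture silhouette: two disjoint caps tapering off each platen."""
    widths = np.zeros(gap_px, dtype=int)
    if gap_px <= 0:
        return widths
    cap = max(1, int(round(cap_fraction * gap_px)))
    cap = min(cap, gap_px // 2)  # keep the caps disjoint
    if cap == 0:
        return widths
    z = np.arange(1, cap + 1, dtype=float)  # distance from the platen face
    taper = np.rint(contact_px * (1.0 - z / (cap + 1))).astype(int)
    widths[:cap] = taper  # top cap: widest at the top platen face
    widths[gap_px - cap :] = taper[::-1]  # bottom cap mirrors it
    return widths


def render_stack(
    truth: GroundTruth,
    geom: GeometrySpec,
    cfg: RenderConfig,
    frame_interval: float,
) -> Tuple[FrameStack, GroundTruth]:
    """Draw the experiment as a backlit image stack; truth gains pixel data.

    Each frame shows two platen slabs separated by the gap series and the
    filament silhouette between them (disjoint caps after rupture), plus
    seeded Gaussian pixel noise.  The returned truth carries the drawn
    per-row widths and gap in pixels, which are exact by construction.
    """
    if truth.gap is None:
        raise InvalidParameterError("truth must carry a gap series to render")
    h, w_img = cfg.image_shape
    s = cfg.pixel_scale
    platen_px = int(round(cfg.platen_diameter / s))
    if platen_px < 20:
        raise InvalidGeometryError(
            "pixel_scale must resolve the platen to >= 20 px"
        )
    if platen_px > w_img:
        raise InvalidGeometryError("platen wider than image")
    contact_px = cfg.contact_fraction * platen_px
    slab = cfg.platen_slab_px
    gap_px_series = np.rint(truth.gap / s).astype(int)
    max_gap = gap_px_series.max()
    if max_gap + 2 * slab > h:
        raise InvalidGeometryError(
            f"image height {h} too small for gap {max_gap}px + platen slabs"
        )
    g0_px = geom.initial_gap / s
    n = truth.gap.size
    rng = np.random.default_rng(cfg.seed)
    c0 = (w_img - platen_px) // 2
    centre = c0 + platen_px / 2.0
    bottom_face = h - slab  # platen slab occupies rows [bottom_face, h)
    cols = np.arange(w_img, dtype=float)
    frames = np.empty((n, h, w_img), dtype=np.uint8)
    widths_px = np.zeros((n, h), dtype=int)

    for i in range(n):
        gap_px = int(gap_px_series[i])
        img = np.full((h, w_img), cfg.background_level, dtype=float)
        top_face = bottom_face - gap_px - 1  # last row of the top platen
        # platen slabs (rods run out of frame)
        img[max(0, top_face - slab + 1) : top_face + 1, c0 : c0 + platen_px] = (
            cfg.foreground_level
        )
        img[bottom_face:, c0 : c0 + platen_px] = cfg.foreground_level
        d_m = truth.mid_diameter[i]
        broken = (
            truth.breakup_frame is not None and i >= truth.breakup_frame
        ) or d_m <= 0
        if broken:
            wpx = _cap_widths_px(gap_px, contact_px)
        else:
            d_px = min(d_m / s, contact_px)
            wpx = _neck_widths_px(gap_px, d_px, contact_px, g0_px)
        if wpx.size:
            rows = np.arange(top_face + 1, top_face + 1 + gap_px)
            # draw exactly wpx foreground columns per row, centred
            left = np.rint(centre - wpx / 2.0).astype(int)
            fluid = (cols[None, :] >= left[:, None]) & (
                cols[None, :] < (left + wpx)[:, None]
            )
            block = img[rows[0] : rows[-1] + 1]
            block[fluid] = cfg.foreground_level
            widths_px[i, rows[0] : rows[-1] + 1] = wpx
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)

    stack = FrameStack(
        frames=frames,
        frame_interval=frame_interval,
        pixel_scale=s,
        axis=0,
    )
    truth.widths_px = widths_px
    truth.gap_px = gap_px_series
    return stack, truth


def simulate_experiment(
    model_id: str,
    params: ModelParams,
    geom: GeometrySpec,
    env: Optional[FluidEnvironment] = None,
    motion: Optional[PlatenMotionParams] = None,
    cfg: Optional[RenderConfig] = None,
    frame_rate: float = 5000.0,
    duration: float = 0.2,
    breakup_threshold_px: float = 2.0,
) -> Tuple[FrameStack, GroundTruth]:
    """Full synthetic experiment: stretch, thinning law, rendered frames.

    During the stretch the mid-diameter follows volume conservation of the
    initial cylinder, ``D(g) = 2 r sqrt(g0 / g)`` (capped at the contact
    width); from the ground-truth settling frame onward it follows the
    requested thinning law with ``D0 = D(g at settle)``.  Rupture occurs at
    the frame where the drawn neck width would fall below
    ``breakup_threshold_px``; later frames show disjoint caps.
    """
    motion = motion or PlatenMotionParams()
    cfg = cfg or RenderConfig()
    n = int(math.floor(duration * frame_rate)) + 1
    t = np.arange(n) / frame_rate
    prof = simulate_motion(geom, motion, t)
    gap = prof.gap
    stop = prof.settle_frame
    contact_m = cfg.contact_fraction * cfg.platen_diameter
    d = np.minimum(
        2.0 * geom.platen_radius * np.sqrt(geom.initial_gap / gap), contact_m
    )
    d0 = float(d[stop])
    t_since_stop = t[stop:] - t[stop]
    ratio = _law_ratio(model_id, params, env, d0, t_since_stop)
    d[stop:] = d0 * ratio
    # rupture where the drawn width falls below the detection threshold
    px = np.rint(d / cfg.pixel_scale)
    below = np.flatnonzero((px < breakup_threshold_px) & (np.arange(n) > stop))
    breakup = int(below[0]) if below.size else None
    truth = GroundTruth(
        model_id=model_id,
        params=params,
        mid_diameter=d,
        motion_stop_frame=stop,
        breakup_frame=breakup,
        gap=gap,
        d0=d0,
    )
    stack, truth = render_stack(truth, geom, cfg, frame_interval=1.0 / frame_rate)
    return stack, truth


# ---------------------------------------------------------------------------
# Benchmark suite
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkFixture:
    """One named synthetic experiment: trace + rendered stack + truth."""

    name: str
    model_id: str
    params: ModelParams
    env: Optional[FluidEnvironment]
    geom: GeometrySpec
    trace: FilamentTrace
    trace_truth: GroundTruth
    stack: Optional[FrameStack] = None
    stack_truth: Optional[GroundTruth] = None


@dataclass
class BenchmarkSuite:
    """Deterministic fixture set spanning the three constitutive regimes.

    ``silicone`` — Newtonian oil (eta0 = 2.37 Pa s, alpha = 0.0159 N/m) at
    three initial diameters; ``pitcher_ucm`` — UCM fluids with relaxation
    times 2.95/20.6/29.8 ms (greenhouse pitcher-fluid regime);
    ``field_giesekus`` — a strongly elastic field-fluid regime
    (lambda_G ~ 620 ms, eta0 ~ 25 Pa s); ``storage_decay`` — relaxation
    time versus storage day series for two pitcher fluids.
    """

    silicone: List[BenchmarkFixture]
    pitcher_ucm: List[BenchmarkFixture]
    field_giesekus: List[BenchmarkFixture]
    storage_decay: Dict[str, Dict[str, np.ndarray]]

    def all_fixtures(self) -> List[BenchmarkFixture]:
        return self.silicone + self.pitcher_ucm + self.field_giesekus


#: Storage series: relaxation time (ms) of sealed pitcher-fluid samples
#: re-measured over days at room temperature.
STORAGE_DECAY_DATA = {
    "n_eymae": {
        "days": np.array([1.0, 2.0, 7.0, 9.0, 14.0, 23.0, 37.0]),
        "relaxation_time_ms": np.array([28.5, 15.8, 12.9, 11.7, 8.64, 2.21, 0.73]),
    },
    "n_maxima": {
        "days": np.array([1.0, 2.0, 6.0, 8.0, 16.0]),
        "relaxation_time_ms": np.array([19.6, 11.7, 4.25, 3.49, 1.08]),
    },
}

SILICONE_ENV = FluidEnvironment(surface_tension=0.0159, density=970.0)
SILICONE_VISCOSITY = 2.37
SILICONE_D0_M = (0.380e-3, 0.514e-3, 0.612e-3)
PITCHER_UCM_LAMBDAS_S = (2.95e-3, 20.6e-3, 29.8e-3)
AQUEOUS_ENV = FluidEnvironment(surface_tension=0.065, density=1000.0)
FIELD_GIESEKUS = GiesekusParams(viscosity=25.3, relaxation_time=0.620, mobility=0.2)


def make_benchmark_suite(
    seed: int = 0,
    render: bool = True,
    noise: bool = True,
) -> BenchmarkSuite:
    """Build the deterministic benchmark fixtures.

    ``render=False`` skips image rendering (traces and truth only);
    ``noise=False`` renders without pixel noise and generates noiseless
    traces.  Bit-for-bit reproducible for a given seed.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(16)
    child_iter = iter(children)

    def next_seed() -> int:
        return int(next(child_iter).generate_state(1)[0] % (2**31))

    geom_small = GeometrySpec(initial_gap=0.4e-3, final_gap=1.5e-3)
    silicone = []
    for d0 in SILICONE_D0_M:
        p = NewtonianParams(viscosity=SILICONE_VISCOSITY, correction_factor=1.0)
        t_break = newtonian_breakup_time(p, SILICONE_ENV, d0)
        trace, truth = simulate_trace(
            "newtonian", p, d0, frame_rate=5000.0, duration=t_break * 1.05,
            env=SILICONE_ENV, noise_sd=(0.01 * d0 if noise else 0.0),
            seed=next_seed(),
        )
        fx = BenchmarkFixture(
            name=f"silicone_d0_{d0 * 1e3:.3f}mm", model_id="newtonian",
            params=p, env=SILICONE_ENV, geom=geom_small,
            trace=trace, trace_truth=truth,
        )
        silicone.append(fx)

    pitcher = []
    for lam in PITCHER_UCM_LAMBDAS_S:
        p = UCMParams(relaxation_time=lam)
        d0 = 0.4e-3
        duration = 3.0 * lam * 3.0  # decay to about e^-3
        trace, truth = simulate_trace(
            "ucm", p, d0, frame_rate=5000.0, duration=duration,
            noise_sd=(0.01 * d0 if noise else 0.0), seed=next_seed(),
        )
        fx = BenchmarkFixture(
            name=f"pitcher_ucm_{lam * 1e3:.4g}ms", model_id="ucm",
            params=p, env=AQUEOUS_ENV, geom=geom_small,
            trace=trace, trace_truth=truth,
        )
        pitcher.append(fx)

    field = []
    d0 = 0.4e-3
    trace, truth = simulate_trace(
        "giesekus", FIELD_GIESEKUS, d0, frame_rate=500.0, duration=1.0,
        env=AQUEOUS_ENV, noise_sd=(0.01 * d0 if noise else 0.0),
        seed=next_seed(),
    )
    field.append(
        BenchmarkFixture(
            name="field_giesekus", model_id="giesekus",
            params=FIELD_GIESEKUS, env=AQUEOUS_ENV, geom=geom_small,
            trace=trace, trace_truth=truth,
        )
    )

    if render:
        geom_fig2 = GeometrySpec(initial_gap=0.7e-3, final_gap=1.9e-3)
        cfg = RenderConfig(
            noise_sd=(5.0 if noise else 0.0), seed=next_seed(),
        )
        # one rendered experiment per constitutive regime
        render_specs = [
            (silicone[0], 5000.0, 0.35),
            (pitcher[2], 5000.0, 0.30),
            (field[0], 500.0, 1.7),
        ]
        for fx, rate, dur in render_specs:
            stack, truth = simulate_experiment(
                fx.model_id, fx.params, geom_fig2, env=fx.env,
                cfg=cfg, frame_rate=rate, duration=dur,
            )
            fx.stack, fx.stack_truth = stack, truth

    storage = {
        k: {kk: vv.copy() for kk, vv in v.items()}
        for k, v in STORAGE_DECAY_DATA.items()
    }
    return BenchmarkSuite(
        silicone=silicone,
        pitcher_ucm=pitcher,
        field_giesekus=field,
        storage_decay=storage,
    )
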