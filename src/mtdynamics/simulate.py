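"""Synthetic-data generation: dynamic-instability traces, TIRF renders,
washout protocols, and culture growth curves.

Every generator takes an explicit integer seed and is bit-reproducible.
The two-state model is memoryless with constant velocities: a growing
microtubule catastrophes with hazard ``f_cat`` (min⁻¹) and a shrinking one
is rescued with hazard ``f_res``; length never falls below the stabilized
seed.  These are exactly the quantities the downstream pipeline estimates,
so every analysis stage can be validated by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .trace import GROWING, SHRINKING, LengthTrace

__all__ = [
    "DIParams",
    "ImagingParams",
    "WashoutProtocol",
    "GrowthParams",
    "GrowthCurve",
    "simulate_length_trace",
    "add_measurement_noise",
    "render_kymograph",
    "render_movie",
    "simulate_washout_trace",
    "simulate_growth_curve",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class DIParams:
    """Ground-truth dynamic-instability parameters.

    Velocities are magnitudes in μm·min⁻¹; switching frequencies are
    first-order hazards in events·min⁻¹ (catastrophe while growing, rescue
    while shrinking).  ``renucleate`` controls the seed boundary: ``True``
    holds the length at the seed and immediately resumes growth, ``False``
    terminates the trace when the seed is reached.
    """

    v_grow: float
    v_shrink: float
    f_cat: float
    f_res: float
    seed_length_um: float = 0.0
    renucleate: bool = True

    def __post_init__(self) -> None:
        for name in ("v_grow", "v_shrink", "f_cat", "f_res", "seed_length_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ImagingParams:
    """TIRF image-formation parameters for the renderer.

    Defaults follow a typical 100x/sCMOS TIRF setup: 65-nm pixels, 3-s
    frames for in vitro dynamics (1-s for washouts), and a Gaussian PSF.
    ``tip_sd_nm`` is the ground-truth taper SD of the rendered plus end
    (0 = blunt/step edge).  ``noise_model`` is one of ``none``, ``gaussian``
    (additive read noise of SD ``read_noise_sd``), or ``poisson`` (shot
    noise on the expected photon counts).
    """

    pixel_size_nm: float = 65.0
    frame_interval_s: float = 3.0
    psf_sigma_nm: float = 130.0
    tip_sd_nm: float = 0.0
    photons_per_um: float = 500.0
    background_level: float = 20.0
    noise_model: str = "none"
    read_noise_sd: float = 2.0
    crop_halfwidth_px: int = 4

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_nm and frame_interval_s must be positive")
        if self.psf_sigma_nm < 0 or self.tip_sd_nm < 0:
            raise ValueError("psf_sigma_nm and tip_sd_nm must be >= 0")
        if self.crop_halfwidth_px < 1:
            raise ValueError("crop_halfwidth_px must be >= 1")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError("noise_model must be none|gaussian|poisson")


@dataclass(frozen=True)
class WashoutProtocol:
    """Deterministic washout time course.

    Growth at the pre-washout velocity until ``t_washout_s``; slow
    depolymerization at ``v_slow`` for ``delay_s``; fast depolymerization at
    ``v_fast`` back to the seed.  The background fluorescence ramps linearly
    from ``background_pre`` to ``background_post`` over
    ``washout_duration_s``.
    """

    t_washout_s: float
    delay_s: float
    v_slow: float
    v_fast: float
    washout_duration_s: float = 5.0
    background_pre: float = 100.0
    background_post: float = 10.0

    def __post_init__(self) -> None:
        for name in ("t_washout_s", "delay_s", "washout_duration_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.v_fast >= self.v_slow >= 0):
            raise ValueError("require v_fast >= v_slow >= 0")
        if self.background_post >= self.background_pre:
            raise ValueError("background_post must be < background_pre")


@dataclass(frozen=True)
class GrowthParams:
    """Exponential culture growth: OD(t) = od0 * 2^((t - lag)/doubling)."""

    od0: float = 0.1
    doubling_time_min: float = 90.0
    lag_min: float = 0.0
    noise_sd: float = 0.0
    duration_h: float = 21.0
    interval_min: float = 5.0

    def __post_init__(self) -> None:
        if self.od0 <= 0 or self.doubling_time_min <= 0 or self.interval_min <= 0:
            raise ValueError("od0, doubling_time_min, interval_min must be positive")


@dataclass
class GrowthCurve:
    """Plate-reader OD600 time series for a single well."""

    times_min: np.ndarray
    od600: np.ndarray
    well: str = ""
    strain: str = ""
    condition: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times_min.shape != self.od600.shape:
            raise ValueError("times_min and od600 must have the same shape")
        if self.times_min.size >= 2 and not np.all(np.diff(self.times_min) > 0):
            raise ValueError("times_min must be strictly increasing")


# ---------------------------------------------------------------------------
# two-state simulator


def _segments(params: DIParams, duration_s: float, rng: np.random.Generator):
    """Piecewise-linear nodes of one dynamic-instability realization.

    Returns (node_times, node_lengths, seg_starts, seg_states, terminated_at).
    Segment i spans [seg_starts[i], seg_starts[i+1]) with constant state.
    """
    vg = params.v_grow / 60.0
    vs = params.v_shrink / 60.0
    fc = params.f_cat / 60.0
    fr = params.f_res / 60.0
    seed = params.seed_length_um

    t, L, state = 0.0, seed, GROWING
    node_t, node_L = [0.0], [seed]
    seg_starts, seg_states = [0.0], [GROWING]
    terminated_at = None

    while t < duration_s:
        if state == GROWING:
            wait = rng.exponential(1.0 / fc) if fc > 0 else math.inf
            t2 = min(t + wait, duration_s)
            L = L + vg * (t2 - t)
            node_t.append(t2)
            node_L.append(L)
            t = t2
            if t >= duration_s:
                break
            state = SHRINKING
            seg_starts.append(t)
            seg_states.append(state)
        else:
            wait = rng.exponential(1.0 / fr) if fr > 0 else math.inf
            t_seed = t + (L - seed) / vs if vs > 0 else math.inf
            t2 = min(t + wait, t_seed, duration_s)
            L = max(L - vs * (t2 - t), seed)
            node_t.append(t2)
            node_L.append(L)
            t = t2
            if t2 == t_seed and t_seed <= duration_s:
                if not params.renucleate:
                    terminated_at = t
                    break
                state = GROWING
            elif t >= duration_s:
                break
            else:
                state = GROWING
            seg_starts.append(t)
            seg_states.append(state)

    return node_t, node_L, seg_starts, seg_states, terminated_at


def simulate_length_trace(
    params: DIParams,
    duration_s: float,
    dt_s: float,
    rng_seed: int,
) -> LengthTrace:
    """Simulate one two-state dynamic-instability trace sampled at ``dt_s``.

    Growth segments have slope ``+v_grow`` and shrinkage segments
    ``-v_shrink``; waiting times between switches are exponential with the
    hazards of ``params``.  Length never falls below the seed.  Deterministic
    for a fixed ``rng_seed``.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if duration_s < dt_s:
        raise ValueError("duration_s must be at least dt_s")
    rng = np.random.default_rng(rng_seed)
    node_t, node_L, seg_starts, seg_states, terminated_at = _segments(
        params, duration_s, rng
    )

    t_end = duration_s if terminated_at is None else terminated_at
    n = int(math.floor(t_end / dt_s + 1e-9))
    times = np.arange(n + 1) * dt_s
    lengths = np.interp(times, node_t, node_L)
    starts = np.asarray(seg_starts)
    states = np.asarray(seg_states)[
        np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(starts) - 1)
    ]
    return LengthTrace(
        times_s=times,
        lengths_um=np.maximum(lengths, params.seed_length_um),
        frame_interval_s=dt_s,
        states=states,
        meta={"params": params, "rng_seed": rng_seed, "terminated_at_s": terminated_at},
    )


def add_measurement_noise(
    trace: LengthTrace, sd_um: float, rng_seed: int
) -> LengthTrace:
    """Add i.i.d. Gaussian length-measurement noise (clipped at 0 μm)."""
    if sd_um < 0:
        raise ValueError("sd_um must be >= 0")
    rng = np.random.default_rng(rng_seed)
    noisy = trace.lengths_um + rng.normal(0.0, sd_um, size=trace.lengths_um.shape)
    return LengthTrace(
        times_s=trace.times_s.copy(),
        lengths_um=np.maximum(noisy, 0.0),
        frame_interval_s=trace.frame_interval_s,
        condition=trace.condition,
        tubulin_conc_uM=trace.tubulin_conc_uM,
        states=None if trace.states is None else trace.states.copy(),
        meta={**trace.meta, "noise_sd_um": sd_um, "noise_seed": rng_seed},
    )


# ---------------------------------------------------------------------------
# TIRF rendering


def _edge_profile(x_nm, lo_nm, hi_nm, sigma_lo, sigma_hi):
    """Occupancy of [lo, hi] blurred with Gaussian edges of given SDs.

    A hard edge (sigma 0) is a unit step at the boundary; otherwise the edge
    is the Gaussian survival/CDF form.  The two-edge product is exact in the
    limit (hi - lo) >> sigma, which holds for all rendered geometries here.
    """
    if sigma_lo > 0:
        left = ndtr((x_nm - lo_nm) / sigma_lo)
    else:
        left = (x_nm >= lo_nm).astype(float)
    if sigma_hi > 0:
        right = ndtr((hi_nm - x_nm) / sigma_hi)
    else:
        right = (x_nm < hi_nm).astype(float)
    return left * right


def _apply_noise(expected, imaging: ImagingParams, rng: np.random.Generator):
    if imaging.noise_model == "none":
        return expected
    if imaging.noise_model == "poisson":
        return rng.poisson(np.maximum(expected, 0.0)).astype(float)
    # gaussian read noise
    out = expected + rng.normal(0.0, imaging.read_noise_sd, size=expected.shape)
    return np.maximum(out, 0.0)


def render_kymograph(
    trace: LengthTrace,
    imaging: ImagingParams,
    rng_seed: int = 0,
    seed_length_um: float = 0.0,
    width_px: int | None = None,
):
    """Render a kymograph (time x axial position) from a length trace.

    Each row is the axial intensity profile of a microtubule of that frame's
    length: background + amplitude x GaussianSurvival((x - tip)/sigma_eff)
    with sigma_eff = sqrt(tip_sd^2 + psf_sigma^2), so ``tip_sd_nm = 0``
    yields a PSF-limited edge and psf 0 a hard step.  The dynamic channel
    covers [seed_length, length]; the seed occupies [0, seed_length] and is
    reported as ``seed_span_px`` (it would be imaged in a separate channel).

    Returns ``(Kymograph, ground_truth: dict)``.
    """
    from .kymo import Kymograph

    if trace.frame_interval_s != imaging.frame_interval_s:
        n = int(math.floor(trace.duration_s / imaging.frame_interval_s + 1e-9))
        times = trace.times_s[0] + np.arange(n + 1) * imaging.frame_interval_s
        lengths = np.interp(times, trace.times_s, trace.lengths_um)
    else:
        times = trace.times_s
        lengths = trace.lengths_um

    px = imaging.pixel_size_nm
    sigma_eff = math.hypot(imaging.tip_sd_nm, imaging.psf_sigma_nm)
    tips_nm = lengths * 1000.0
    margin_nm = 4.0 * sigma_eff + 2.0 * px
    required_px = int(math.ceil((tips_nm.max() + margin_nm) / px))
    if width_px is None:
        width_px = required_px
    elif width_px < required_px:
        raise ValueError(
            f"trace extends beyond the field of view: need width_px >= {required_px}"
        )

    x_nm = (np.arange(width_px) + 0.5) * px
    amp = imaging.photons_per_um * px / 1000.0
    seed_nm = seed_length_um * 1000.0
    left_sigma = imaging.psf_sigma_nm

    rows = np.empty((len(tips_nm), width_px), dtype=float)
    for i, tip in enumerate(tips_nm):
        rows[i] = imaging.background_level + amp * _edge_profile(
            x_nm, seed_nm, tip, left_sigma, sigma_eff
        )
    rng = np.random.default_rng(rng_seed)
    rows = _apply_noise(rows, imaging, rng)

    seed_profile = imaging.background_level + amp * _edge_profile(
        x_nm, 0.0, max(seed_nm, px), left_sigma, left_sigma
    )
    seed_span = (0, max(int(round(seed_nm / px)), 1) if seed_nm > 0 else 0)
    kymo = Kymograph(
        intensity=rows,
        pixel_size_nm=px,
        frame_interval_s=imaging.frame_interval_s,
        seed_span_px=seed_span,
    )
    gt = {
        "times_s": times,
        "lengths_um": lengths,
        "tip_px": tips_nm / px,
        "seed_length_um": seed_length_um,
        "imaging": imaging,
        "rng_seed": rng_seed,
        "seed_profile": seed_profile,
    }
    return kymo, gt


def render_movie(
    trace: LengthTrace,
    imaging: ImagingParams,
    rng_seed: int = 0,
    seed_length_um: float = 1.0,
    shape: tuple[int, int] = (32, 160),
    origin_px: tuple[float, float] | None = None,
    angle_deg: float = 0.0,
    drift_px: np.ndarray | None = None,
):
    """Render a two-channel movie (seed channel + dynamic tubulin channel).

    The microtubule lies along a line through ``origin_px`` (row, col; the
    seed minus end) at ``angle_deg`` from the column axis.  ``drift_px`` is
    an optional per-frame (drow, dcol) stage drift applied to both channels.

    Returns ``({'seed': (T,H,W), 'dynamic': (T,H,W)}, ground_truth)``.
    """
    H, W = shape
    if origin_px is None:
        origin_px = (H / 2.0, W * 0.15)
    px = imaging.pixel_size_nm
    if trace.frame_interval_s != imaging.frame_interval_s:
        n = int(math.floor(trace.duration_s / imaging.frame_interval_s + 1e-9))
        times = trace.times_s[0] + np.arange(n + 1) * imaging.frame_interval_s
        lengths = np.interp(times, trace.times_s, trace.lengths_um)
    else:
        times = trace.times_s
        lengths = trace.lengths_um
    T = len(times)

    theta = math.radians(angle_deg)
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    sigma_eff = math.hypot(imaging.tip_sd_nm, imaging.psf_sigma_nm)
    # A zero-width line would vanish under point sampling; floor the
    # transverse width at half a pixel.
    sigma_perp = max(imaging.psf_sigma_nm, 0.5 * px)
    left_sigma = imaging.psf_sigma_nm
    amp = imaging.photons_per_um * px / 1000.0
    seed_nm = seed_length_um * 1000.0
    tips_nm = lengths * 1000.0
    max_extent = (tips_nm.max() + 4 * sigma_eff) / px
    if origin_px[1] + max_extent * abs(math.cos(theta)) > W or not (
        0 <= origin_px[0] + max_extent * math.sin(theta) <= H
    ):
        raise ValueError(
            f"trace extends beyond the field of view: need >= "
            f"{int(math.ceil(max_extent))} px along the axis from the origin"
        )

    rng = np.random.default_rng(rng_seed)
    seed_ch = np.empty((T, H, W), dtype=float)
    dyn_ch = np.empty((T, H, W), dtype=float)
    for i in range(T):
        r0, c0 = origin_px
        if drift_px is not None:
            r0 = r0 + drift_px[i][0]
            c0 = c0 + drift_px[i][1]
        s_nm = ((cc - c0) * math.cos(theta) + (rr - r0) * math.sin(theta)) * px
        p_nm = (-(cc - c0) * math.sin(theta) + (rr - r0) * math.cos(theta)) * px
        perp = np.exp(-0.5 * (p_nm / sigma_perp) ** 2)
        seed_ch[i] = imaging.background_level + amp * perp * _edge_profile(
            s_nm, 0.0, seed_nm, left_sigma, left_sigma
        )
        dyn_ch[i] = imaging.background_level + amp * perp * _edge_profile(
            s_nm, seed_nm, tips_nm[i], left_sigma, sigma_eff
        )
    seed_ch = _apply_noise(seed_ch, imaging, rng)
    dyn_ch = _apply_noise(dyn_ch, imaging, rng)
    gt = {
        "times_s": times,
        "lengths_um": lengths,
        "origin_px": origin_px,
        "angle_deg": angle_deg,
        "seed_length_um": seed_length_um,
        "imaging": imaging,
        "rng_seed": rng_seed,
        "drift_px": drift_px,
    }
    return {"seed": seed_ch, "dynamic": dyn_ch}, gt


# ---------------------------------------------------------------------------
# washout protocol


def simulate_washout_trace(
    pre: DIParams,
    protocol: WashoutProtocol,
    duration_s: float,
    dt_s: float = 1.0,
    rng_seed: int = 0,
    noise_sd_um: float = 0.0,
    background_noise_sd: float = 0.0,
):
    """Simulate one washout experiment at 1-s (default) sampling.

    The microtubule grows deterministically at ``pre.v_grow`` until the
    washout, shrinks at ``protocol.v_slow`` for ``protocol.delay_s``, then at
    ``protocol.v_fast`` back to the seed where it holds.  The background
    series ramps from ``background_pre`` to ``background_post`` over the
    washout duration.

    Returns ``(LengthTrace, background: np.ndarray, ground_truth: dict)``.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    tw = protocol.t_washout_s
    if not (0 < tw < duration_s):
        raise ValueError("t_washout_s must fall inside the trace duration")
    seed = pre.seed_length_um
    vg = pre.v_grow / 60.0
    vs = protocol.v_slow / 60.0
    vf = protocol.v_fast / 60.0

    L_w = seed + vg * tw
    L_cat = L_w - vs * protocol.delay_s
    if L_cat <= seed:
        raise ValueError(
            "slow phase would pass the seed before catastrophe; shorten delay_s"
        )
    t_cat = tw + protocol.delay_s
    t_seed = t_cat + ((L_cat - seed) / vf if vf > 0 else math.inf)

    n = int(math.floor(duration_s / dt_s + 1e-9))
    times = np.arange(n + 1) * dt_s
    lengths = np.empty_like(times)
    states = np.empty(times.shape, dtype=int)
    for i, t in enumerate(times):
        if t <= tw:
            lengths[i] = seed + vg * t
            states[i] = GROWING
        elif t <= t_cat:
            lengths[i] = L_w - vs * (t - tw)
            states[i] = SHRINKING
        elif t <= t_seed:
            lengths[i] = L_cat - vf * (t - t_cat)
            states[i] = SHRINKING
        else:
            lengths[i] = seed
            states[i] = 0
    lengths = np.maximum(lengths, seed)

    ramp_end = tw + protocol.washout_duration_s
    background = np.where(
        times < tw,
        protocol.background_pre,
        np.where(
            times >= ramp_end,
            protocol.background_post,
            protocol.background_pre
            + (protocol.background_post - protocol.background_pre)
            * (times - tw)
            / max(protocol.washout_duration_s, dt_s * 1e-9),
        ),
    ).astype(float)

    rng = np.random.default_rng(rng_seed)
    if noise_sd_um > 0:
        lengths = np.maximum(lengths + rng.normal(0, noise_sd_um, lengths.shape), 0.0)
    if background_noise_sd > 0:
        background = background + rng.normal(0, background_noise_sd, background.shape)

    trace = LengthTrace(
        times_s=times,
        lengths_um=lengths,
        frame_interval_s=dt_s,
        states=states,
        meta={"protocol": protocol, "pre": pre, "rng_seed": rng_seed},
    )
    gt = {
        "t_washout_s": tw,
        "t_term_s": ramp_end,
        "t_cat_s": t_cat,
        "t_seed_s": t_seed,
        "length_at_washout_um": L_w,
        "length_at_catastrophe_um": L_cat,
        "v_grow": pre.v_grow,
        "v_slow": protocol.v_slow,
        "v_fast": protocol.v_fast,
    }
    return trace, background, gt


# ---------------------------------------------------------------------------
# growth curves


def simulate_growth_curve(params: GrowthParams, rng_seed: int = 0) -> GrowthCurve:
    """Exponential OD600 curve with optional lag and additive noise."""
    n = int(math.floor(params.duration_h * 60.0 / params.interval_min + 1e-9))
    times = np.arange(n + 1) * params.interval_min
    od = np.where(
        times >= params.lag_min,
        params.od0 * 2.0 ** ((times - params.lag_min) / params.doubling_time_min),
        params.od0,
    )
    rng = np.random.default_rng(rng_seed)
    if params.noise_sd > 0:
        od = od + rng.normal(0.0, params.noise_sd, od.shape)
    od = np.maximum(od, 1e-4)
    return GrowthCurve(
        times_min=times,
        od600=od,
        meta={"params": params, "rng_seed": rng_seed},
    )
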