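"""Synthetic tribometer traces and live/dead micrograph pairs with ground truth.

The generator emulates a single pin-on-plate slide of a spherical probe over
a cell monolayer on a cast polymer substrate, and the two-channel
(Hoechst/propidium-iodide) fluorescence images of the resulting slide track.
Because every downstream stage of the pipeline is exercised against these
synthetic inputs, each generated artefact carries an explicit ground-truth
record (true friction coefficients, motion onset, zero-slope position,
per-nucleus fate labels).

Trace physics
-------------
The probe rides on a surface ``h(x) = tilt*x + meniscus(x)`` where the
meniscus is a scaled even quartic bowl (flat bottom, upturned edges, as a
liquid polymer cures in a dish).  The normal-force servo holds the measured
vertical channel at the setpoint, so on a local slope ``theta`` the contact
normal force is ``N = F_N / (cos(theta) - mu*sin(theta))`` and the recorded
lateral force is ``Fx = N*(mu*cos(theta) + sin(theta))``: the quasi-static
inclined-plane balance that the slope-adjustment rotation inverts exactly.
Stick-slip is modelled as a sawtooth modulation of the dynamic coefficient
with exponentially spaced (Poisson) slip events.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .friction import TribometerTrace

__all__ = [
    "TraceScenario",
    "ImageScenario",
    "TraceGroundTruth",
    "ScenarioError",
    "ExperimentRecord",
    "generate_trace",
    "generate_image_pair",
    "generate_experiment_set",
]


class ScenarioError(ValueError):
    """Raised when a scenario violates its invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ScenarioError(msg)


@dataclass(frozen=True)
class TraceScenario:
    """Physical description of one simulated slide.

    Defaults reproduce the FN-coated polystyrene + HUVEC condition of the
    study design this simulator mirrors: fitted static/dynamic coefficients
    0.511/0.303, a 1 mm/s tangential speed, a 10 s pre-movement loading
    dwell, and a 10-80 mN normal-force setpoint range.
    """

    mu_s: float = 0.511          # static friction coefficient
    mu_d: float = 0.303          # dynamic friction coefficient
    f_n: float = 10.0            # normal-force setpoint [mN]
    v_t: float = 1.0             # tangential speed [mm/s]
    tilt: float = 0.01           # surface slope [mm/mm]
    meniscus_depth: float = 0.02  # peak bowl deviation over the span [mm]
    slide_length: float = 4.0    # [mm]
    t_pre: float = 10.0          # pre-movement dwell [s]
    stickslip_amp: float = 0.1   # fractional sawtooth amplitude on mu_d
    noise_sd_f: float = 0.02     # additive force noise [mN]
    noise_sd_h: float = 5e-4     # height noise [mm]
    fx_baseline: float = 0.05    # lateral-channel offset before movement [mN]
    sampling_rate: float = 100.0  # [Hz]
    servo_tau: float = 0.5       # normal-force servo first-order lag [s]
    slip_spacing: float = 0.1    # mean distance between slip events [mm]
    static_rise_mm: float = 0.05  # travel over which the static peak builds
    static_decay_mm: float = 0.3  # travel over which it relaxes to dynamic
    seed: int = 0

    def __post_init__(self) -> None:
        vals = dataclasses.asdict(self)
        _require(all(np.isfinite(v) for v in vals.values() if isinstance(v, (int, float))),
                 "scenario contains non-finite values")
        _require(self.mu_s >= self.mu_d >= 0, "require mu_s >= mu_d >= 0")
        _require(self.f_n > 0, "normal-force setpoint must be positive")
        _require(self.v_t > 0, "tangential speed must be positive")
        _require(self.slide_length > 0, "slide length must be positive")
        _require(self.t_pre >= 0, "pre-movement dwell cannot be negative")
        _require(self.sampling_rate > 0, "sampling rate must be positive")
        _require(self.stickslip_amp >= 0 and self.noise_sd_f >= 0
                 and self.noise_sd_h >= 0, "noise amplitudes cannot be negative")


@dataclass(frozen=True)
class TraceGroundTruth:
    """What the analysis stage is supposed to recover from one trace."""

    mu_s: float
    mu_d: float
    f_n: float                     # mN
    onset_index: int
    static_peak_index: int
    dynamic_start_index: int       # first sample on the pure dynamic branch
    x_zero_slope: float | None     # mm, position where dh/dx = 0 (if interior)
    tilt: float
    meniscus_depth: float


def _height_profile(s: TraceScenario) -> tuple[Callable[[np.ndarray], np.ndarray],
                                               Callable[[np.ndarray], np.ndarray],
                                               float | None]:
    """Return h(x), dh/dx(x) and the interior zero-slope position (or None)."""
    L = s.slide_length

    def meniscus(x: np.ndarray) -> np.ndarray:
        return s.meniscus_depth * (2.0 * x / L - 1.0) ** 4

    def dmeniscus(x: np.ndarray) -> np.ndarray:
        return s.meniscus_depth * 8.0 / L * (2.0 * x / L - 1.0) ** 3

    def h(x):
        return s.tilt * x + meniscus(x)

    def dh(x):
        return s.tilt + dmeniscus(x)

    if s.meniscus_depth > 0:
        u3 = -s.tilt * L / (8.0 * s.meniscus_depth)
        u = math.copysign(abs(u3) ** (1.0 / 3.0), u3)
        x0 = L * (1.0 + u) / 2.0
        x_zero = x0 if 0.0 < x0 < L else None
    elif s.tilt == 0.0:
        x_zero = L / 2.0  # slope vanishes everywhere; report the midpoint
    else:
        x_zero = None
    return h, dh, x_zero


def _stickslip_multiplier(s: TraceScenario, x: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Sawtooth on the dynamic coefficient with Poisson-spaced slip events."""
    if s.stickslip_amp == 0.0:
        return np.ones_like(x)
    edges = [0.0]
    while edges[-1] < s.slide_length:
        edges.append(edges[-1] + rng.exponential(s.slip_spacing))
    edges_arr = np.asarray(edges)
    idx = np.clip(np.searchsorted(edges_arr, x, side="right") - 1, 0, len(edges) - 2)
    left = edges_arr[idx]
    width = edges_arr[idx + 1] - left
    frac = np.where(width > 0, (x - left) / width, 0.0)
    return 1.0 + s.stickslip_amp * (2.0 * frac - 1.0)


def _inclined_forces(mu: np.ndarray | float, theta: np.ndarray,
                     f_n_servo: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    """Measured (Fx, N) for sliding at coefficient mu on local angle theta.

    The servo holds the *measured vertical channel* at ``f_n_servo``; the
    contact normal force follows from the quasi-static balance.
    """
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    n_contact = f_n_servo / (cos_t - mu * sin_t)
    fx = n_contact * (mu * cos_t + sin_t)
    return fx, n_contact


def generate_trace(scenario: TraceScenario) -> tuple[TribometerTrace, TraceGroundTruth]:
    """Simulate one slide and return the raw trace plus its ground truth.

    The trace contains, in order: a pre-movement dwell with the lateral
    channel fluctuating about its baseline while the servo ramps the normal
    load in; a static-friction peak built over ``static_rise_mm`` of travel;
    a cosine relaxation onto the dynamic branch; and stick-slip dynamic
    sliding whose noise-free values follow the closed-form slope-coupled
    balance at every sample.
    """
    s = scenario
    rng = np.random.default_rng(s.seed)
    dt = 1.0 / s.sampling_rate
    n_pre = int(round(s.t_pre * s.sampling_rate))
    n_slide = int(round(s.slide_length / s.v_t * s.sampling_rate))
    n = n_pre + n_slide + 1
    t = np.arange(n) * dt
    x = np.where(t > s.t_pre, (t - s.t_pre) * s.v_t, 0.0)
    x = np.minimum(x, s.slide_length)

    h, dh, x_zero = _height_profile(s)
    theta = np.arctan(dh(x))

    # normal-force servo: first-order lag toward the setpoint during loading
    servo = s.f_n * (1.0 - np.exp(-t / max(s.servo_tau, 1e-9)))
    fz = -servo + rng.normal(0.0, s.noise_sd_f, n)

    mult = _stickslip_multiplier(s, x, rng)
    fx_dyn, _ = _inclined_forces(s.mu_d * mult, theta, servo)
    fx_static_peak, _ = _inclined_forces(s.mu_s, theta, servo)

    onset_index = n_pre + 1  # first sample with x > 0
    fx = np.full(n, 0.0)
    moving = x > 0
    rise_end_x = min(s.static_rise_mm, s.slide_length)
    decay_end_x = min(rise_end_x + s.static_decay_mm, s.slide_length)

    in_rise = moving & (x <= rise_end_x)
    fx[in_rise] = fx_static_peak[in_rise] * (x[in_rise] / rise_end_x)
    in_decay = moving & (x > rise_end_x) & (x < decay_end_x)
    if np.any(in_decay):
        frac = (x[in_decay] - rise_end_x) / (decay_end_x - rise_end_x)
        blend = 0.5 * (1.0 + np.cos(np.pi * frac))
        fx[in_decay] = blend * fx_static_peak[in_decay] + (1 - blend) * fx_dyn[in_decay]
    in_dyn = moving & (x >= decay_end_x)
    fx[in_dyn] = fx_dyn[in_dyn]

    fx += s.fx_baseline + rng.normal(0.0, s.noise_sd_f, n)
    h_m = h(x) + rng.normal(0.0, s.noise_sd_h, n)

    static_peak_index = int(np.flatnonzero(in_rise)[-1]) if np.any(in_rise) else onset_index
    dyn_idx = np.flatnonzero(in_dyn)
    dynamic_start_index = int(dyn_idx[0]) if dyn_idx.size else n - 1

    trace = TribometerTrace(
        t=t, x=x, h_m=h_m, fx=fx, fz=fz,
        meta={"f_n": s.f_n, "v_t": s.v_t, "scenario": dataclasses.asdict(s)},
    )
    truth = TraceGroundTruth(
        mu_s=s.mu_s, mu_d=s.mu_d, f_n=s.f_n,
        onset_index=onset_index,
        static_peak_index=static_peak_index,
        dynamic_start_index=dynamic_start_index,
        x_zero_slope=x_zero,
        tilt=s.tilt, meniscus_depth=s.meniscus_depth,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# fluorescence image pairs


@dataclass(frozen=True)
class ImageScenario:
    """Description of one simulated blue/red micrograph pair.

    Nuclei are placed by a homogeneous spatial Poisson process at
    ``density_ref`` (nuclei per mm^2; the default corresponds to a confluent
    endothelial monolayer on the sparse side).  Within the horizontal track
    band each nucleus is removed with probability ``p_remove``; retained
    track nuclei are membrane-compromised ("dead", red-positive) with
    probability ``p_dead``.  All retained nuclei render as Gaussian blobs in
    the blue (Hoechst) channel, dead ones additionally in red (PI).
    """

    density_ref: float = 400.0       # nuclei / mm^2
    track_center_y: float | None = None  # um; image centre when None
    track_width: float = 78.0        # um
    p_remove: float = 0.8
    p_dead: float = 0.5
    image_size: tuple[int, int] = (875, 1000)  # (rows, cols) px
    pixel_size: float = 2.0          # um / px
    nucleus_sigma: float = 4.0       # um
    nucleus_amp: float = 12000.0     # peak intensity, 16-bit counts
    background: float = 300.0        # counts
    noise_sd: float = 40.0           # counts
    seed: int = 0

    def __post_init__(self) -> None:
        _require(0.0 <= self.p_remove <= 1.0, "p_remove must be within [0, 1]")
        _require(0.0 <= self.p_dead <= 1.0, "p_dead must be within [0, 1]")
        _require(self.density_ref >= 0, "density cannot be negative")
        _require(self.track_width > 0, "track width must be positive")
        _require(self.pixel_size > 0, "pixel size must be positive")
        _require(self.nucleus_sigma > 0, "nucleus sigma must be positive")
        ny, nx = self.image_size
        _require(ny > 0 and nx > 0, "image size must be positive")
        cy = self.center_y
        _require(self.track_width / 2 <= cy <= ny * self.pixel_size - self.track_width / 2,
                 "track band extends outside the image")

    @property
    def center_y(self) -> float:
        """Track centre line in um (image centre by default)."""
        if self.track_center_y is not None:
            return self.track_center_y
        return self.image_size[0] * self.pixel_size / 2.0

    @property
    def field_um(self) -> tuple[float, float]:
        """(height, width) of the field of view in um."""
        return (self.image_size[0] * self.pixel_size,
                self.image_size[1] * self.pixel_size)

    @property
    def expected_fractions(self) -> dict[str, float]:
        """Expected relative densities inside the track band."""
        return {
            "rel_blue": (1.0 - self.p_remove) * (1.0 - self.p_dead),
            "rel_red": (1.0 - self.p_remove) * self.p_dead,
            "rel_removed": self.p_remove,
        }


def _render_nuclei(shape: tuple[int, int], xy_px: np.ndarray, amps: np.ndarray,
                   sigma_px: float) -> np.ndarray:
    """Sum of isotropic Gaussian blobs rendered in local windows."""
    img = np.zeros(shape, dtype=float)
    if xy_px.size == 0:
        return img
    r = max(1, int(math.ceil(4.0 * sigma_px)))
    ny, nx = shape
    for (cx, cy), amp in zip(xy_px, amps):
        ix, iy = int(round(cx)), int(round(cy))
        x0, x1 = max(ix - r, 0), min(ix + r + 1, nx)
        y0, y1 = max(iy - r, 0), min(iy + r + 1, ny)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += amp * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma_px**2)
        )
    return img


def generate_image_pair(
    scenario: ImageScenario,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Simulate a blue/red image pair of a slide track.

    Returns
    -------
    blue, red : uint16 arrays of ``scenario.image_size``.
    truth : DataFrame with one row per generated nucleus: position (um),
        ``in_track`` flag and ``fate`` in {"healthy", "dead", "removed"}.
        Removed nuclei appear in the table but in neither image.
    """
    s = scenario
    rng = np.random.default_rng(s.seed)
    height_um, width_um = s.field_um
    area_mm2 = height_um * width_um * 1e-6
    n = rng.poisson(s.density_ref * area_mm2)
    xs = rng.uniform(0.0, width_um, n)
    ys = rng.uniform(0.0, height_um, n)
    cy = s.center_y
    in_track = np.abs(ys - cy) <= s.track_width / 2.0

    fate = np.full(n, "healthy", dtype=object)
    removed = in_track & (rng.uniform(size=n) < s.p_remove)
    fate[removed] = "removed"
    dead = in_track & ~removed & (rng.uniform(size=n) < s.p_dead)
    fate[dead] = "dead"

    retained = fate != "removed"
    sigma_px = s.nucleus_sigma / s.pixel_size
    amps = s.nucleus_amp * rng.lognormal(mean=0.0, sigma=0.2, size=n)
    xy_px = np.column_stack([xs / s.pixel_size, ys / s.pixel_size])

    blue = _render_nuclei(s.image_size, xy_px[retained], amps[retained], sigma_px)
    red = _render_nuclei(s.image_size, xy_px[fate == "dead"], amps[fate == "dead"], sigma_px)

    def _finish(img: np.ndarray) -> np.ndarray:
        img = img + s.background + rng.normal(0.0, s.noise_sd, s.image_size)
        return np.clip(img, 0, 65535).astype(np.uint16)

    truth = pd.DataFrame(
        {"x_um": xs, "y_um": ys, "in_track": in_track, "fate": fate.astype(str)}
    )
    return _finish(blue), _finish(red), truth


# ---------------------------------------------------------------------------
# matched experiment sets


@dataclass(frozen=True)
class ExperimentRecord:
    """One (force, repeat) cell of a simulated study design."""

    f_n: float
    repeat: int
    trace: TribometerTrace
    trace_truth: TraceGroundTruth
    blue: np.ndarray | None
    red: np.ndarray | None
    image_truth: pd.DataFrame | None
    image_scenario: ImageScenario | None


def generate_experiment_set(
    forces: Sequence[float],
    repeats: int,
    trace_template: TraceScenario | None = None,
    image_template: ImageScenario | None = None,
    damage_by_force: dict[float, tuple[float, float]] | None = None,
    seed: int = 0,
    include_images: bool = True,
) -> list[ExperimentRecord]:
    """Generate a matched trace + image-pair collection for a study design.

    One trace (and, when ``include_images``, one image pair) is produced per
    (force, repeat) cell.  ``damage_by_force`` optionally maps each normal
    force to its (p_remove, p_dead); otherwise the image template's values
    apply at every force.  The whole set is deterministic under a fixed seed.
    """
    forces = list(forces)
    _require(len(forces) > 0, "forces must be non-empty")
    _require(all(f > 0 for f in forces), "all forces must be positive")
    _require(repeats >= 0, "repeats cannot be negative")
    trace_template = trace_template or TraceScenario()
    image_template = image_template or ImageScenario()
    rng = np.random.default_rng(seed)
    records: list[ExperimentRecord] = []
    for f_n in forces:
        for rep in range(repeats):
            tseed = int(rng.integers(0, 2**31 - 1))
            iseed = int(rng.integers(0, 2**31 - 1))
            t_scn = dataclasses.replace(trace_template, f_n=float(f_n), seed=tseed)
            trace, truth = generate_trace(t_scn)
            if include_images:
                kwargs = {"seed": iseed}
                if damage_by_force is not None:
                    p_remove, p_dead = damage_by_force[f_n]
                    kwargs.update(p_remove=p_remove, p_dead=p_dead)
                i_scn = dataclasses.replace(image_template, **kwargs)
                blue, red, itruth = generate_image_pair(i_scn)
            else:
                i_scn = None
                blue = red = itruth = None
            records.append(
                ExperimentRecord(
                    f_n=float(f_n), repeat=rep, trace=trace, trace_truth=truth,
                    blue=blue, red=red, image_truth=itruth, image_scenario=i_scn,
                )
            )
    return records
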