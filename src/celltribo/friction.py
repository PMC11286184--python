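"""Friction extraction from raw tribometer traces.

A single pin-on-plate slide recorded by a low-load tribometer yields time
series of lateral stage position, probe height and the two force channels.
Samples cast from a liquid polymer are never perfectly level: the probe
rides up a residual tilt and a meniscus-shaped bowl, so the measured lateral
force mixes true interfacial friction with a gravity/slope component.  This
module segments the slide into its phases (pre-movement, static peak,
stabilised sliding, zero-slope section), fits the height profile with a
polynomial, and rotates the measured force pair by the local surface angle
to recover slope-adjusted static and dynamic friction forces.  Friction
coefficients across slides are obtained by a through-origin fit following
Amonton's law F_F = mu * F_N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial

log = logging.getLogger(__name__)

__all__ = [
    "TribometerTrace",
    "HeightModel",
    "PhaseSegmentation",
    "FrictionResult",
    "AmontonFit",
    "TraceError",
    "MotionNotFoundError",
    "SlopeRegimeError",
    "fit_height_profile",
    "segment_phases",
    "slope_adjust",
    "fit_amontons",
    "batch_friction",
]


class TraceError(ValueError):
    """Raised when a trace violates its invariants or cannot be analysed."""


class MotionNotFoundError(TraceError):
    """Raised when no lateral motion is detected in a trace."""


class SlopeRegimeError(TraceError):
    """Raised when the fitted surface angle leaves the quasi-static regime."""


@dataclass(frozen=True)
class TribometerTrace:
    """Raw mechanical record of one slide.

    Attributes
    ----------
    t : array, s — sample times, strictly increasing.
    x : array, mm — lateral stage position.
    h_m : array, mm — measured probe height.
    fx : array, mN — lateral (friction-direction) force.
    fz : array, mN — normal force channel; negative in compression.
    meta : mapping — at least ``f_n`` (setpoint, mN) and ``v_t`` (mm/s).
    """

    t: np.ndarray
    x: np.ndarray
    h_m: np.ndarray
    fx: np.ndarray
    fz: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("t", "x", "h_m", "fx", "fz"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1:
                raise TraceError(f"{name} must be one-dimensional")
            if not np.all(np.isfinite(arr)):
                raise TraceError(f"{name} contains non-finite values")
            arrays[name] = arr
            object.__setattr__(self, name, arr)
        n = arrays["t"].size
        if any(a.size != n for a in arrays.values()):
            raise TraceError("trace channels must have equal length")
        if n < 2:
            raise TraceError("trace needs at least two samples")
        if not np.all(np.diff(arrays["t"]) > 0):
            raise TraceError("time must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    @property
    def f_n_set(self) -> float:
        """Normal-force setpoint in mN (positive)."""
        return abs(float(self.meta.get("f_n", np.median(np.abs(self.fz)))))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.t, "x_mm": self.x, "h_mm": self.h_m,
             "fx_mN": self.fx, "fz_mN": self.fz}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, meta: Mapping | None = None) -> "TribometerTrace":
        return cls(
            t=frame["time_s"].to_numpy(),
            x=frame["x_mm"].to_numpy(),
            h_m=frame["h_mm"].to_numpy(),
            fx=frame["fx_mN"].to_numpy(),
            fz=frame["fz_mN"].to_numpy(),
            meta=dict(meta or {}),
        )


@dataclass(frozen=True)
class HeightModel:
    """Polynomial approximation h_p(x) of the probe height over the slide.

    The polynomial (default degree 5) is fitted to the measured height
    against *position*, not time, over the sliding phase only; its analytic
    derivative gives the local surface slope used for the misalignment
    correction.  Evaluation outside the fitted domain is refused.
    """

    poly: Polynomial
    domain: tuple[float, float]
    residual_rms: float  # mm

    @property
    def degree(self) -> int:
        return self.poly.degree()

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficients in the unscaled x basis, low order first."""
        return self.poly.convert().coef

    def _check_domain(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, hi = self.domain
        pad = 0.01 * (hi - lo)
        if np.any(x < lo - pad) or np.any(x > hi + pad):
            raise TraceError(
                f"height model evaluated outside fit domain [{lo:.4g}, {hi:.4g}] mm"
            )
        return x

    def height(self, x: np.ndarray) -> np.ndarray:
        """h_p(x) in mm."""
        return self.poly(self._check_domain(x))

    def slope(self, x: np.ndarray) -> np.ndarray:
        """∂x h_p(x), dimensionless (mm/mm)."""
        return self.poly.deriv()(self._check_domain(x))


@dataclass(frozen=True)
class PhaseSegmentation:
    """Index windows for the stages of a single slide.

    Stages mirror the canonical anatomy of a one-directional slide: a
    pre-movement dwell, the static-friction peak just after motion onset, a
    stabilised dynamic-sliding window, and (when the meniscus provides one)
    a window where the fitted surface slope is essentially zero.
    """

    pre: slice
    onset_index: int
    static_peak_index: int | None
    static_missing: bool
    stabilization: slice
    end_index: int
    zero_slope: slice | None
    fx_baseline: float  # mN, median Fx during pre-movement (F_x,bm)
    fx_noise_sd: float  # mN, robust noise estimate from pre-movement window

    def __post_init__(self) -> None:
        if self.pre.stop != self.onset_index:
            raise TraceError("pre-movement window must end at the onset index")
        if self.static_peak_index is not None and self.static_peak_index < self.onset_index:
            raise TraceError("static peak cannot precede motion onset")
        if self.stabilization.start < self.onset_index:
            raise TraceError("stabilization window cannot precede onset")
        if self.stabilization.stop > self.end_index + 1:
            raise TraceError("stabilization window exceeds the analysed slide")


@dataclass(frozen=True)
class FrictionResult:
    """Static/dynamic friction forces for one slide, raw and slope-adjusted.

    ``f_fd_zero_slope`` is the alternative dynamic estimate taken as the mean
    baseline-subtracted raw Fx over the zero-slope window, available only
    when the meniscus provides a level section.
    """

    f_fs_raw: float | None  # mN, baseline-subtracted Fx at the static peak
    f_fd_raw: float | None  # mN, mean baseline-subtracted Fx, stabilised window
    f_fs_adj: float | None  # mN, slope-adjusted static friction force
    f_fd_adj: float | None  # mN, slope-adjusted dynamic friction force
    f_fd_zero_slope: float | None  # mN
    slope_at_peak: float | None  # mm/mm
    f_n: float          # mN, mean |Fz| over the stabilised window
    f_n_adj: float      # mN, mean slope-adjusted normal force, same window
    f_n_at_peak: float | None  # mN, slope-adjusted normal force at the peak

    def __post_init__(self) -> None:
        if self.f_n <= 0:
            raise TraceError("normal force must be positive")
        for name in ("f_fs_adj", "f_fd_adj"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise TraceError(f"{name} is not finite")

    @property
    def mu_s(self) -> float | None:
        """Static friction coefficient from the slope-adjusted pair."""
        if self.f_fs_adj is None or self.f_n_at_peak in (None, 0.0):
            return None
        return self.f_fs_adj / self.f_n_at_peak

    @property
    def mu_d(self) -> float | None:
        """Dynamic friction coefficient from the slope-adjusted pair."""
        if self.f_fd_adj is None:
            return None
        return self.f_fd_adj / self.f_n_adj

    @property
    def mu_d_raw(self) -> float | None:
        if self.f_fd_raw is None:
            return None
        return self.f_fd_raw / self.f_n


@dataclass(frozen=True)
class AmontonFit:
    """Through-origin least-squares fit F_F = mu * F_N."""

    mu: float
    residuals: np.ndarray  # mN, per-point F_F - mu*F_N
    n: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise TraceError("fitted mu is not finite")


# ---------------------------------------------------------------------------
# operations


def fit_height_profile(
    trace: TribometerTrace,
    degree: int = 5,
    segmentation: PhaseSegmentation | None = None,
) -> HeightModel:
    """Fit the measured probe height against position with a polynomial.

    Only the sliding phase is used: during pre-movement the stage does not
    move, so those samples carry no positional information.  Degree 5 is the
    default; it captures a linear tilt plus a smooth quartic meniscus bowl.
    """
    if degree < 1:
        raise TraceError("polynomial degree must be >= 1")
    if segmentation is not None:
        sl = slice(segmentation.onset_index, segmentation.end_index + 1)
    else:
        onset = _detect_onset(trace)[0]
        sl = slice(onset, len(trace))
    x = trace.x[sl]
    h = trace.h_m[sl]
    if x.size < degree + 2:
        raise TraceError(
            f"need at least degree+2={degree + 2} sliding samples, got {x.size}"
        )
    span = float(np.ptp(x))
    if span <= 0:
        raise TraceError("x is constant over the sliding phase; cannot fit h(x)")
    poly = Polynomial.fit(x, h, deg=degree)
    resid = h - poly(x)
    return HeightModel(
        poly=poly,
        domain=(float(x.min()), float(x.max())),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def _detect_onset(
    trace: TribometerTrace, motion_threshold_mm: float = 1e-3
) -> tuple[int, float]:
    """First index where the stage has moved beyond the noise, plus threshold.

    Threshold is max(3 x pre-movement x-noise SD, 1 um); the noise SD is
    estimated from the leading samples, which must form a stationary prefix.
    """
    n0 = min(20, max(5, len(trace) // 50))
    x0 = float(np.median(trace.x[:n0]))
    noise_sd = float(np.std(trace.x[:n0]))
    thr = max(3.0 * noise_sd, motion_threshold_mm)
    moved = np.flatnonzero(np.abs(trace.x - x0) > thr)
    if moved.size == 0:
        raise MotionNotFoundError("no lateral motion detected in trace")
    return int(moved[0]), thr


def segment_phases(
    trace: TribometerTrace,
    height_model: HeightModel | None = None,
    motion_threshold_mm: float = 1e-3,
    peak_window_mm: float = 0.5,
    end_fraction: float = 0.95,
    zero_slope_tol: float = 1e-3,
    noise_floor_k: float = 4.0,
) -> PhaseSegmentation:
    """Segment one slide into pre-movement / static / stabilised / zero-slope.

    Parameters follow the stage anatomy: the static peak is searched within
    ``peak_window_mm`` of travel after onset; the stabilised window starts
    once the (lightly smoothed) lateral force has settled to within 10% of
    its trailing mean and ends at ``end_fraction`` of the slide length; the
    zero-slope window is the contiguous run around the minimum of |∂x h_p|
    where the slope magnitude stays below ``zero_slope_tol`` (requires a
    height model, absent otherwise).
    """
    onset, _ = _detect_onset(trace, motion_threshold_mm)
    if onset == 0:
        raise TraceError("trace has no stationary pre-movement prefix")
    pre = slice(0, onset)
    fx_bm = float(np.median(trace.fx[pre]))
    mad = float(np.median(np.abs(trace.fx[pre] - fx_bm)))
    fx_noise_sd = 1.4826 * mad

    xs = trace.x - trace.x[onset]
    travel = np.abs(xs)
    end_index = int(np.flatnonzero(travel <= end_fraction * travel.max())[-1])

    # static peak: largest baseline excursion within a bounded window after onset
    in_window = np.flatnonzero((np.arange(len(trace)) >= onset) & (travel <= peak_window_mm))
    excursion = np.abs(trace.fx[in_window] - fx_bm)
    peak_pos = int(in_window[int(np.argmax(excursion))])
    floor = noise_floor_k * max(fx_noise_sd, 1e-12)
    static_missing = bool(excursion.max() < floor)
    static_peak_index = None if static_missing else peak_pos

    # stabilised dynamic window
    if static_missing:
        start = onset + max(1, (end_index - onset) // 20)
    else:
        tail_from = peak_pos + (end_index - peak_pos) // 2
        m_trail = float(np.mean(trace.fx[tail_from : end_index + 1]))
        # smoothing window of ~0.05 mm of travel
        dx = np.median(np.abs(np.diff(trace.x[onset : end_index + 1])))
        win = max(3, int(round(0.05 / max(dx, 1e-9))))
        kernel = np.ones(win) / win
        fx_smooth = np.convolve(trace.fx, kernel, mode="same")
        tol = max(0.1 * abs(m_trail), 3.0 * fx_noise_sd, 1e-9)
        settled = np.flatnonzero(
            (np.arange(len(trace)) > peak_pos)
            & (np.arange(len(trace)) <= end_index)
            & (np.abs(fx_smooth - m_trail) <= tol)
        )
        start = int(settled[0]) if settled.size else peak_pos + 1
    if start >= end_index:
        start = max(onset + 1, end_index - 1)
    stabilization = slice(start, end_index + 1)

    # zero-slope window
    zero_slope: slice | None = None
    if height_model is not None:
        xi = trace.x[onset : end_index + 1]
        dh = np.abs(height_model.slope(xi))
        ok = dh <= zero_slope_tol
        if ok.any():
            imin = int(np.argmin(dh))
            if ok[imin]:
                lo = imin
                while lo > 0 and ok[lo - 1]:
                    lo -= 1
                hi = imin
                while hi < ok.size - 1 and ok[hi + 1]:
                    hi += 1
                zero_slope = slice(onset + lo, onset + hi + 1)

    if static_missing:
        log.warning("no static peak above noise floor; static friction reported missing")

    return PhaseSegmentation(
        pre=pre,
        onset_index=onset,
        static_peak_index=static_peak_index,
        static_missing=static_missing,
        stabilization=stabilization,
        end_index=end_index,
        zero_slope=zero_slope,
        fx_baseline=fx_bm,
        fx_noise_sd=fx_noise_sd,
    )


def slope_adjust(
    trace: TribometerTrace,
    height_model: HeightModel,
    segmentation: PhaseSegmentation,
    include_lateral_in_normal: bool = True,
    max_angle_deg: float = 45.0,
) -> FrictionResult:
    """Remove the surface-slope contribution from the measured friction force.

    With the local surface angle theta(x) = arctan(∂x h_p(x)) the measured
    horizontal/vertical force pair is rotated into the surface frame::

        F_F,adj = Fx * cos(theta) - F_N * sin(theta)
        F_N,adj = F_N * cos(theta) + Fx * sin(theta)

    where ``F_N = |Fz|`` and the pre-movement baseline F_x,bm is subtracted
    from Fx before the rotation.  The second term of F_N,adj (the lateral
    force's contribution to the instantaneous normal load) is included by
    default; pass ``include_lateral_in_normal=False`` for the first-order
    variant.  The quasi-static balance is only meaningful for |theta| < 45
    degrees; steeper fitted slopes raise :class:`SlopeRegimeError`.
    """
    seg = segmentation
    sl = slice(seg.onset_index, seg.end_index + 1)
    theta = np.arctan(height_model.slope(trace.x[sl]))
    if np.max(np.abs(theta)) >= np.deg2rad(max_angle_deg):
        raise SlopeRegimeError(
            "fitted surface angle exceeds the quasi-static correction regime"
        )
    fxc = trace.fx[sl] - seg.fx_baseline
    fn = np.abs(trace.fz[sl])
    if np.any(fn <= 0):
        # a zero normal-load sample makes the rotation ill-defined but not fatal
        log.warning("normal-force channel touches zero within the slide")
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    f_adj = fxc * cos_t - fn * sin_t
    n_adj = fn * cos_t + (fxc * sin_t if include_lateral_in_normal else 0.0)

    def _local(i: int) -> int:
        return i - seg.onset_index

    stab = slice(_local(seg.stabilization.start), _local(seg.stabilization.stop))
    f_fd_raw = float(np.mean(fxc[stab]))
    f_fd_adj = float(np.mean(f_adj[stab]))
    f_n = float(np.mean(fn[stab]))
    f_n_adj = float(np.mean(n_adj[stab]))

    if seg.static_peak_index is not None:
        ip = _local(seg.static_peak_index)
        f_fs_raw: float | None = float(fxc[ip])
        f_fs_adj: float | None = float(f_adj[ip])
        slope_at_peak: float | None = float(np.tan(theta[ip]))
        f_n_at_peak: float | None = float(n_adj[ip])
    else:
        f_fs_raw = f_fs_adj = slope_at_peak = f_n_at_peak = None

    if seg.zero_slope is not None:
        zs = slice(_local(seg.zero_slope.start), _local(seg.zero_slope.stop))
        f_fd_zero = float(np.mean(fxc[zs]))
    else:
        f_fd_zero = None

    return FrictionResult(
        f_fs_raw=f_fs_raw,
        f_fd_raw=f_fd_raw,
        f_fs_adj=f_fs_adj,
        f_fd_adj=f_fd_adj,
        f_fd_zero_slope=f_fd_zero,
        slope_at_peak=slope_at_peak,
        f_n=f_n,
        f_n_adj=f_n_adj,
        f_n_at_peak=f_n_at_peak,
    )


def fit_amontons(points: Sequence[tuple[float, float]]) -> AmontonFit:
    """Fit F_F = mu * F_N through the origin by least squares.

    The closed-form estimator is mu = sum(F_N*F_F) / sum(F_N^2).
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.size == 0:
        raise TraceError("cannot fit Amonton's law to an empty point set")
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise TraceError("points must be (F_N, F_F) pairs")
    f_n, f_f = pts[:, 0], pts[:, 1]
    if np.any(f_n <= 0):
        raise TraceError("all normal forces must be positive")
    mu = float(np.sum(f_n * f_f) / np.sum(f_n**2))
    return AmontonFit(mu=mu, residuals=f_f - mu * f_n, n=len(pts))


def analyse_trace(
    trace: TribometerTrace,
    degree: int = 5,
    **segment_kwargs,
) -> tuple[FrictionResult, HeightModel, PhaseSegmentation]:
    """Convenience wrapper: height fit, segmentation, slope adjustment."""
    model = fit_height_profile(trace, degree=degree)
    seg = segment_phases(trace, height_model=model, **segment_kwargs)
    result = slope_adjust(trace, model, seg)
    return result, model, seg


def batch_friction(
    traces: Iterable[tuple[str, TribometerTrace]],
    degree: int = 5,
) -> tuple[pd.DataFrame, dict[str, AmontonFit], list[tuple[str, str]]]:
    """Analyse a collection of slides and fit Amonton coefficients.

    Parameters
    ----------
    traces : iterable of (label, trace)
        Labels identify slides in the output table; the normal-force
        condition is taken from each trace's metadata.

    Returns
    -------
    table : DataFrame with one row per successfully analysed slide.
    fits : dict with ``static`` and ``dynamic`` :class:`AmontonFit` entries
        (present when enough slides provided the respective force).
    failures : list of (label, reason) for slides that could not be analysed;
        they are excluded from the table but never silently dropped.
    """
    rows = []
    failures: list[tuple[str, str]] = []
    for label, trace in traces:
        try:
            res, model, seg = analyse_trace(trace, degree=degree)
        except TraceError as exc:
            log.warning("trace %s failed: %s", label, exc)
            failures.append((label, str(exc)))
            continue
        rows.append(
            {
                "label": label,
                "f_n_set_mN": trace.f_n_set,
                "f_n_mN": res.f_n,
                "f_n_adj_mN": res.f_n_adj,
                "f_n_at_peak_mN": res.f_n_at_peak,
                "f_fs_raw_mN": res.f_fs_raw,
                "f_fd_raw_mN": res.f_fd_raw,
                "f_fs_adj_mN": res.f_fs_adj,
                "f_fd_adj_mN": res.f_fd_adj,
                "f_fd_zero_slope_mN": res.f_fd_zero_slope,
                "mu_s": res.mu_s,
                "mu_d": res.mu_d,
                "slope_at_peak": res.slope_at_peak,
                "height_rms_mm": model.residual_rms,
                "static_missing": seg.static_missing,
            }
        )
    table = pd.DataFrame(rows)
    fits: dict[str, AmontonFit] = {}
    if not table.empty:
        stat = table.dropna(subset=["f_fs_adj_mN", "f_n_at_peak_mN"])
        if len(stat) >= 2:
            fits["static"] = fit_amontons(
                list(zip(stat["f_n_at_peak_mN"], stat["f_fs_adj_mN"]))
            )
        dyn = table.dropna(subset=["f_fd_adj_mN"])
        if len(dyn) >= 2:
            fits["dynamic"] = fit_amontons(
                list(zip(dyn["f_n_adj_mN"], dyn["f_fd_adj_mN"]))
            )
    return table, fits, failures


def summarize_by_condition(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean +/- SD of the adjusted friction forces."""
    if table.empty:
        return pd.DataFrame()
    grouped = table.groupby("f_n_set_mN")
    out = grouped.agg(
        n=("label", "size"),
        f_fs_adj_mean=("f_fs_adj_mN", "mean"),
        f_fs_adj_sd=("f_fs_adj_mN", "std"),
        f_fd_adj_mean=("f_fd_adj_mN", "mean"),
        f_fd_adj_sd=("f_fd_adj_mN", "std"),
        mu_d_mean=("mu_d", "mean"),
    )
    return out.reset_index()
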