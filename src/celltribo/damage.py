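"""Monolayer-damage quantification from two-channel live/dead micrographs.

After a slide, the sample is stained with Hoechst (blue: all retained
nuclei) and propidium iodide (red: nuclei of membrane-compromised cells).
Damage is expressed as nuclei densities in the slide band *relative to the
blue-nucleus density pooled over flanking reference areas*:

    rel_blue    = healthy density in band / rho_ref     ("healthy")
    rel_red     = dead density in band    / rho_ref     ("dead")
    rel_removed = 1 - rel_blue - rel_red                 ("removed")

The removed fraction is defined by the partition identity and may be
slightly negative when the band happens to be denser than the references;
it is reported as-is, never clipped.  A track-width estimate is obtained
automatically from the lateral profile of the local blue-density deficit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label, regionprops
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

log = logging.getLogger(__name__)

__all__ = [
    "NucleiSet",
    "RegionLayout",
    "DamageResult",
    "TrackWidthEstimate",
    "DetectionParams",
    "DamageError",
    "detect_nuclei",
    "classify_fates",
    "compute_damage",
    "estimate_track_width",
    "batch_damage",
]


class DamageError(ValueError):
    """Raised when the damage statistic is undefined or inputs are invalid."""


@dataclass(frozen=True)
class NucleiSet:
    """Detected (or ground-truth) nuclear centroids in physical coordinates.

    Coordinates are pixel-centre based, origin at the image's top-left
    corner, in micrometres.  ``blue``/``red`` flag channel positivity;
    ``fate`` is filled by :func:`classify_fates` ("healthy"/"dead").
    """

    xy: np.ndarray                     # (n, 2) um, columns (x, y)
    blue: np.ndarray                   # (n,) bool
    red: np.ndarray                    # (n,) bool
    score: np.ndarray | None = None    # detection score (mean intensity)
    fate: np.ndarray | None = None     # (n,) str, after classification

    def __post_init__(self) -> None:
        xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        if xy.size == 0:
            xy = np.empty((0, 2))
        object.__setattr__(self, "xy", xy)
        object.__setattr__(self, "blue", np.asarray(self.blue, dtype=bool))
        object.__setattr__(self, "red", np.asarray(self.red, dtype=bool))
        if self.xy.shape[0] != self.blue.size or self.blue.size != self.red.size:
            raise DamageError("xy, blue and red must have matching lengths")

    def __len__(self) -> int:
        return self.xy.shape[0]

    def to_frame(self) -> pd.DataFrame:
        d = {"x_um": self.xy[:, 0], "y_um": self.xy[:, 1],
             "blue": self.blue, "red": self.red}
        if self.fate is not None:
            d["fate"] = self.fate
        return pd.DataFrame(d)

    @classmethod
    def concatenate(cls, sets: Sequence["NucleiSet"]) -> "NucleiSet":
        """Pool several sets sharing one coordinate frame (e.g. repeats)."""
        if not sets:
            return cls(np.empty((0, 2)), np.empty(0, bool), np.empty(0, bool))
        fate = None
        if all(s.fate is not None for s in sets):
            fate = np.concatenate([s.fate for s in sets])
        return cls(
            xy=np.vstack([s.xy for s in sets]),
            blue=np.concatenate([s.blue for s in sets]),
            red=np.concatenate([s.red for s in sets]),
            fate=fate,
        )


def _rect_mask(xy: np.ndarray, rect: tuple[float, float, float, float]) -> np.ndarray:
    x0, x1, y0, y1 = rect
    return ((xy[:, 0] >= x0) & (xy[:, 0] < x1)
            & (xy[:, 1] >= y0) & (xy[:, 1] < y1))


@dataclass(frozen=True)
class RegionLayout:
    """Slide band plus flanking reference rectangles, all in um.

    The slide band runs along x at ``track_center_y`` with width
    ``track_width``; reference regions are rectangles (x0, x1, y0, y1).
    Regions must be disjoint from the band and lie within the image.
    """

    track_center_y: float
    track_width: float
    x_range: tuple[float, float]
    ref_regions: tuple[tuple[float, float, float, float], ...]
    image_size_um: tuple[float, float]  # (height, width)

    def __post_init__(self) -> None:
        h, w = self.image_size_um
        x0, x1 = self.x_range
        if not (0 <= x0 < x1 <= w):
            raise DamageError("track x-range outside image")
        band = self.band_rect
        if band[2] < 0 or band[3] > h:
            raise DamageError("slide band outside image")
        if not self.ref_regions:
            raise DamageError("need at least one reference region")
        for r in self.ref_regions:
            rx0, rx1, ry0, ry1 = r
            if not (0 <= rx0 < rx1 <= w and 0 <= ry0 < ry1 <= h):
                raise DamageError("reference region outside image")
            if not (ry1 <= band[2] or ry0 >= band[3]):
                raise DamageError("reference region overlaps the slide band")

    @property
    def band_rect(self) -> tuple[float, float, float, float]:
        half = self.track_width / 2.0
        return (self.x_range[0], self.x_range[1],
                self.track_center_y - half, self.track_center_y + half)

    @property
    def area_slide_mm2(self) -> float:
        x0, x1, y0, y1 = self.band_rect
        return (x1 - x0) * (y1 - y0) * 1e-6

    @property
    def area_ref_mm2(self) -> float:
        return sum((r[1] - r[0]) * (r[3] - r[2]) for r in self.ref_regions) * 1e-6

    @classmethod
    def default(
        cls,
        image_shape: tuple[int, int],
        pixel_size: float,
        track_center_y: float,
        track_width: float,
        ref_offset_factor: float = 3.0,
        ref_width: float | None = None,
    ) -> "RegionLayout":
        """Two reference bands flanking the track, same length.

        Reference bands of width ``ref_width`` (track width by default) are
        centred ``ref_offset_factor * track_width`` above and below the
        track centre line; bands that would leave the image are dropped.
        """
        h = image_shape[0] * pixel_size
        w = image_shape[1] * pixel_size
        rw = ref_width if ref_width is not None else track_width
        refs = []
        for sign in (-1.0, 1.0):
            cy = track_center_y + sign * ref_offset_factor * track_width
            y0, y1 = cy - rw / 2.0, cy + rw / 2.0
            if y0 >= 0 and y1 <= h:
                refs.append((0.0, w, y0, y1))
        if not refs:
            raise DamageError("no reference band fits inside the image")
        return cls(
            track_center_y=track_center_y,
            track_width=track_width,
            x_range=(0.0, w),
            ref_regions=tuple(refs),
            image_size_um=(h, w),
        )


@dataclass(frozen=True)
class DamageResult:
    """Relative nuclei densities for one slide area vs. its references."""

    rel_blue: float
    rel_red: float
    rel_removed: float
    n_healthy_band: int
    n_dead_band: int
    n_blue_ref: int
    rho_ref_mm2: float
    area_slide_mm2: float
    area_ref_mm2: float
    f_n: float | None = None  # mN condition label

    def __post_init__(self) -> None:
        if self.rel_blue < 0 or self.rel_red < 0:
            raise DamageError("relative densities of observed nuclei cannot be negative")
        if abs(self.rel_removed - (1.0 - self.rel_blue - self.rel_red)) > 1e-12:
            raise DamageError("partition identity violated")


@dataclass(frozen=True)
class TrackWidthEstimate:
    """FWHM-style width of the lateral damage profile."""

    width_um: float
    profile_offsets_um: np.ndarray   # bin centres, um (absolute y)
    profile: np.ndarray              # damage fraction per bin
    method: str                     # "fwhm" or "full"

    def __post_init__(self) -> None:
        if self.width_um < 0:
            raise DamageError("width cannot be negative")


@dataclass(frozen=True)
class DetectionParams:
    """Nucleus-detector tuning knobs (all physical units).

    The detector normalises intensities internally, so the resulting
    statistic is invariant to linear intensity rescaling of the input.
    """

    sigma_um: float = 4.0            # expected nucleus Gaussian radius
    background_sigma_factor: float = 10.0  # high-pass scale, x sigma
    smooth_sigma_factor: float = 0.35  # pre-peak smoothing, x sigma; light
    min_area_um2: float = 20.0       # smoothing preserves close-pair peaks
    max_area_um2: float = 2000.0
    min_distance_um: float = 4.0     # peak separation for splitting
    snr_guard: float = 3.0           # Otsu must exceed median + k*MAD


def detect_nuclei(
    image: np.ndarray,
    pixel_size: float,
    params: DetectionParams | None = None,
    channel: str = "blue",
) -> NucleiSet:
    """Detect nuclear centroids in a single-channel intensity image.

    Pipeline: Gaussian high-pass background subtraction, light smoothing,
    Otsu threshold (with a robust-noise guard so blank images yield zero
    detections), local-maxima + watershed splitting of touching blobs, and
    an area filter.  Centroids are returned in micrometres.  Two nuclei
    closer than roughly the blob size are a known resolution limit and are
    returned as a single object.
    """
    if pixel_size is None or pixel_size <= 0:
        raise DamageError("pixel size must be a positive number of um/px")
    if channel not in ("blue", "red"):
        raise DamageError("channel must be 'blue' or 'red'")
    p = params or DetectionParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise DamageError("expected a single-channel 2-D image")

    def _empty(reason: str) -> NucleiSet:
        log.warning("no nuclei detected in %s channel: %s", channel, reason)
        return NucleiSet(
            xy=np.empty((0, 2)),
            blue=np.empty(0, bool),
            red=np.empty(0, bool),
            score=np.empty(0),
        )

    if np.ptp(img) == 0:
        return _empty("image is constant")

    sigma_px = p.sigma_um / pixel_size
    bg = gaussian(img, sigma=p.background_sigma_factor * sigma_px, preserve_range=True)
    hp = img - bg
    sm = gaussian(hp, sigma=p.smooth_sigma_factor * sigma_px, preserve_range=True)

    med = float(np.median(sm))
    mad = float(np.median(np.abs(sm - med)))
    robust_sd = 1.4826 * mad
    try:
        thr = float(threshold_otsu(sm))
    except ValueError:
        return _empty("degenerate intensity histogram")
    if thr <= med + p.snr_guard * max(robust_sd, 1e-12):
        return _empty("no foreground above the noise floor")

    mask = sm > thr
    labels = sk_label(mask)
    min_dist_px = max(1, int(round(p.min_distance_um / pixel_size)))
    peaks = peak_local_max(
        sm, labels=labels, min_distance=min_dist_px, exclude_border=False
    )
    if peaks.shape[0] == 0:
        return _empty("threshold produced no peaks")
    markers = np.zeros(sm.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, peaks.shape[0] + 1)
    segmented = watershed(-sm, markers=markers, mask=mask)

    px_area = pixel_size**2
    xs, ys, scores = [], [], []
    for region in regionprops(segmented, intensity_image=sm):
        area_um2 = region.area * px_area
        if not (p.min_area_um2 <= area_um2 <= p.max_area_um2):
            continue
        cy, cx = region.centroid_weighted
        xs.append(cx * pixel_size)
        ys.append(cy * pixel_size)
        scores.append(region.intensity_mean)
    n = len(xs)
    if n == 0:
        return _empty("all candidates rejected by the area filter")
    return NucleiSet(
        xy=np.column_stack([xs, ys]),
        blue=np.full(n, channel == "blue"),
        red=np.full(n, channel == "red"),
        score=np.asarray(scores),
    )


def classify_fates(
    blue: NucleiSet, red: NucleiSet, match_radius_um: float = 7.0
) -> NucleiSet:
    """Label nuclei healthy/dead by matching red detections to blue ones.

    Mutual-nearest-neighbour matching within ``match_radius_um``: matched
    blue nuclei are dead, unmatched blue are healthy, unmatched red are
    counted once as dead (their nucleus was detected only in the PI
    channel).  Ties are broken by distance, then by index order.
    """
    n_blue, n_red = len(blue), len(red)
    fate = np.full(n_blue, "healthy", dtype=object)
    matched_red = np.zeros(n_red, dtype=bool)
    if n_blue and n_red:
        tree_b = cKDTree(blue.xy)
        tree_r = cKDTree(red.xy)
        d_rb, nn_rb = tree_b.query(red.xy, distance_upper_bound=match_radius_um)
        d_br, nn_br = tree_r.query(blue.xy, distance_upper_bound=match_radius_um)
        order = np.argsort(d_rb, kind="stable")
        for ri in order:
            bi = nn_rb[ri]
            if not np.isfinite(d_rb[ri]) or bi >= n_blue:
                continue
            if nn_br[bi] == ri and fate[bi] == "healthy":
                fate[bi] = "dead"
                matched_red[ri] = True
    extra = ~matched_red
    xy = np.vstack([blue.xy, red.xy[extra]]) if extra.any() else blue.xy.copy()
    fates = np.concatenate([fate, np.full(int(extra.sum()), "dead", dtype=object)])
    return NucleiSet(
        xy=xy,
        blue=np.concatenate([np.ones(n_blue, bool), np.zeros(int(extra.sum()), bool)]),
        red=np.concatenate([fate == "dead", np.ones(int(extra.sum()), bool)]),
        fate=fates.astype(str),
    )


def compute_damage(
    nuclei: NucleiSet, layout: RegionLayout, f_n: float | None = None
) -> DamageResult:
    """Relative healthy/dead/removed densities in the slide band.

    The reference density rho_ref pools blue-detected nuclei over all
    reference regions.  Healthy nuclei are blue-detected and not
    red-matched, so the three fractions partition unity by construction.
    """
    if nuclei.fate is None:
        raise DamageError("nuclei must be fate-labelled (run classify_fates first)")
    band = layout.band_rect
    in_band = _rect_mask(nuclei.xy, band)
    in_ref = np.zeros(len(nuclei), dtype=bool)
    for r in layout.ref_regions:
        in_ref |= _rect_mask(nuclei.xy, r)

    n_blue_ref = int(np.sum(in_ref & nuclei.blue))
    if n_blue_ref == 0:
        raise DamageError("zero blue-nucleus density in reference regions; "
                          "statistic undefined")
    rho_ref = n_blue_ref / layout.area_ref_mm2

    healthy = nuclei.fate == "healthy"
    dead = nuclei.fate == "dead"
    n_healthy_band = int(np.sum(in_band & healthy))
    n_dead_band = int(np.sum(in_band & dead))
    rel_blue = (n_healthy_band / layout.area_slide_mm2) / rho_ref
    rel_red = (n_dead_band / layout.area_slide_mm2) / rho_ref
    return DamageResult(
        rel_blue=rel_blue,
        rel_red=rel_red,
        rel_removed=1.0 - rel_blue - rel_red,
        n_healthy_band=n_healthy_band,
        n_dead_band=n_dead_band,
        n_blue_ref=n_blue_ref,
        rho_ref_mm2=rho_ref,
        area_slide_mm2=layout.area_slide_mm2,
        area_ref_mm2=layout.area_ref_mm2,
        f_n=f_n,
    )


def estimate_track_width(
    nuclei: NucleiSet,
    rho_ref_mm2: float,
    y_extent_um: tuple[float, float],
    x_extent_um: tuple[float, float],
    bin_um: float = 10.0,
    method: str = "fwhm",
    full_threshold: float = 0.1,
) -> TrackWidthEstimate:
    """Estimate the slide-track width from the lateral damage profile.

    The damage fraction per lateral bin combines killed and removed cells
    through the local healthy-density deficit,
    ``p(y) = 1 - healthy_density(y) / rho_ref``.  The width is the extent of
    the contiguous run around the profile maximum where the profile exceeds
    half its plateau value (``method="fwhm"``), or ``full_threshold`` times
    the plateau (``method="full"``).  When no plateau rises above the
    binomial noise floor the width is reported as zero with a warning.
    """
    if nuclei.fate is None:
        raise DamageError("nuclei must be fate-labelled")
    if rho_ref_mm2 <= 0:
        raise DamageError("reference density must be positive")
    if method not in ("fwhm", "full"):
        raise DamageError("method must be 'fwhm' or 'full'")
    y0, y1 = y_extent_um
    x0, x1 = x_extent_um
    edges = np.arange(y0, y1 + bin_um, bin_um)
    centers = 0.5 * (edges[:-1] + edges[1:])
    length_um = x1 - x0
    bin_area_mm2 = bin_um * length_um * 1e-6

    healthy = nuclei.fate == "healthy"
    sel = healthy & (nuclei.xy[:, 0] >= x0) & (nuclei.xy[:, 0] < x1)
    counts, _ = np.histogram(nuclei.xy[sel, 1], bins=edges)
    profile = 1.0 - counts / (rho_ref_mm2 * bin_area_mm2)

    plateau = float(profile.max(initial=0.0))
    n_expected = rho_ref_mm2 * bin_area_mm2
    noise_floor = max(0.2, 3.0 / np.sqrt(max(n_expected, 1.0)))
    if plateau <= noise_floor:
        warnings.warn("no detectable damage above the noise floor; width = 0",
                      stacklevel=2)
        return TrackWidthEstimate(0.0, centers, profile, method)

    level = 0.5 * plateau if method == "fwhm" else full_threshold * plateau
    imax = int(np.argmax(profile))
    lo = imax
    while lo > 0 and profile[lo - 1] >= level:
        lo -= 1
    hi = imax
    while hi < profile.size - 1 and profile[hi + 1] >= level:
        hi += 1
    width = (hi - lo + 1) * bin_um
    return TrackWidthEstimate(float(width), centers, profile, method)


def analyse_image_pair(
    blue_img: np.ndarray,
    red_img: np.ndarray,
    pixel_size: float,
    layout: RegionLayout,
    params: DetectionParams | None = None,
    match_radius_um: float = 7.0,
    f_n: float | None = None,
) -> tuple[DamageResult, NucleiSet]:
    """Full single-pair pipeline: detect both channels, classify, quantify."""
    blue = detect_nuclei(blue_img, pixel_size, params, channel="blue")
    red = detect_nuclei(red_img, pixel_size, params, channel="red")
    labelled = classify_fates(blue, red, match_radius_um)
    return compute_damage(labelled, layout, f_n=f_n), labelled


def batch_damage(
    pairs: Iterable[tuple[str, np.ndarray, np.ndarray, float, RegionLayout, float]],
    params: DetectionParams | None = None,
    match_radius_um: float = 7.0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str]]]:
    """Quantify damage for a collection of image pairs.

    Parameters
    ----------
    pairs : iterable of (label, blue, red, pixel_size, layout, f_n)

    Returns
    -------
    table : per-slide tidy DataFrame.
    summary : per-force mean +/- SD of the three fractions.
    failures : (label, reason) for pairs that could not be analysed.
    """
    rows = []
    failures: list[tuple[str, str]] = []
    for label, blue_img, red_img, pixel_size, layout, f_n in pairs:
        try:
            result, _ = analyse_image_pair(
                blue_img, red_img, pixel_size, layout, params, match_radius_um, f_n
            )
        except DamageError as exc:
            log.warning("image pair %s failed: %s", label, exc)
            failures.append((label, str(exc)))
            continue
        rows.append(
            {
                "label": label,
                "f_n_mN": f_n,
                "rel_blue": result.rel_blue,
                "rel_red": result.rel_red,
                "rel_removed": result.rel_removed,
                "n_healthy_band": result.n_healthy_band,
                "n_dead_band": result.n_dead_band,
                "rho_ref_mm2": result.rho_ref_mm2,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table, pd.DataFrame(), failures
    summary = (
        table.groupby("f_n_mN")
        .agg(
            n=("label", "size"),
            rel_blue_mean=("rel_blue", "mean"),
            rel_blue_sd=("rel_blue", "std"),
            rel_red_mean=("rel_red", "mean"),
            rel_red_sd=("rel_red", "std"),
            rel_removed_mean=("rel_removed", "mean"),
            rel_removed_sd=("rel_removed", "std"),
        )
        .reset_index()
    )
    return table, summary, failures
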