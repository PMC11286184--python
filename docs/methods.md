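# Methods

This note documents the models behind `celltribo`, the defaults and their
rationale, what the synthetic generators do and do not emulate, and the
numerical choices a user should know before trusting the output.

## Slope-adjusted friction extraction

### Model

A single pin-on-plate slide is treated as quasi-static motion of a sphere
over a surface `h(x)` at local angle `θ(x) = arctan(∂x h)`. The tribometer
measures horizontal and vertical forces `(Fx, Fz)` in the lab frame while a
servo holds the vertical channel at the normal-force setpoint. Rotating the
measured pair into the surface frame,

    F_F,adj(x) = Fx·cosθ − F_N·sinθ,
    F_N,adj(x) = F_N·cosθ + Fx·sinθ,     F_N = |Fz|,

recovers the interfacial friction force and the true contact normal load
exactly for a rigid, quasi-static contact: if the generator's inclined-plane
balance produced the trace, the rotation inverts it identically. The
second term of `F_N,adj` (the lateral force's contribution to the contact
normal load) is second-order in θ·µ; it is included by default and can be
switched off (`include_lateral_in_normal=False`) for the first-order
variant. The correction is refused for |θ| ≥ 45°, far outside the regime
where a quasi-static single-contact balance is meaningful.

The surface is not measured independently; it is estimated from the probe
height channel by a least-squares polynomial `h_p(x)` over the sliding
phase only (pre-movement samples carry no positional information). Degree
5 is the default: it represents a linear tilt plus a smooth quartic bowl
exactly and does not chase stick-slip-correlated height noise. The fit
uses position, not time, as abscissa, `numpy.polynomial` with its scaled
domain for conditioning, and refuses evaluation outside the fitted domain.

### Phase segmentation

- **Motion onset** — first sample where `|x − x0|` exceeds
  max(3 × pre-movement x-noise SD, 1 µm). The 1 µm floor is the stage
  resolution scale; the noise term guards noisy encoders.
- **Baseline** `F_x,bm` — median lateral force over the pre-movement
  window (median rather than mean: robust to drift and spikes). Subtracted
  before the rotation.
- **Static peak** — largest baseline excursion within 0.5 mm of travel
  after onset. A peak below 4 × the robust pre-movement force noise is
  reported missing rather than invented (e.g. frictionless or failed
  engagement).
- **Stabilised window** — from the first post-peak sample where the
  lightly smoothed force settles to within max(10% of the trailing mean,
  3 × noise SD), to 95% of the slide length (end effects excluded). The
  dynamic friction force is the mean of `F_F,adj` over this window.
- **Zero-slope window** — contiguous run around the minimum of |∂x h_p|
  where |∂x h_p| ≤ 1e−3; the meniscus of a cast substrate often provides
  such a level section. The mean raw (baseline-subtracted) force over it
  is reported alongside as an adjustment-free cross-check; on traces with
  both estimates they agree within noise. Absent for monotone surfaces.

Friction coefficients across slides come from the through-origin
least-squares fit `µ = Σ F_N·F_F / Σ F_N²` (Amonton's law), applied
separately to static points (adjusted force and normal load at the peak
sample) and dynamic points (window means).

## Damage quantification

### Detection and classification

Nuclei are detected per channel: Gaussian high-pass background removal
(background scale 10 × the nucleus radius), light smoothing, Otsu
threshold, local-maxima + watershed splitting, and an area filter
(20–2000 µm²). A robust-noise guard (threshold must exceed the median by
3 × MAD-based SD) returns an empty set on blank or saturated images
instead of segmenting noise. Because Otsu adapts per image and channel,
the downstream statistic is invariant to linear intensity rescaling.
Two nuclei closer than roughly one blob diameter (≈ 6–8 µm at the 4 µm
default radius) merge into one detection; this is a resolution limit, not
a bug, and it largely cancels in the relative-density statistic because it
affects slide band and reference areas alike. Where the band is much
sparser than the references the cancellation is partial and the removed
fraction is biased low by a few percentage points.

Red (PI) detections are matched to blue (Hoechst) detections by mutual
nearest neighbours within 7 µm (≈ one nuclear radius; configurable).
Matched blue nuclei are *dead*, unmatched blue are *healthy*, unmatched
red are counted once as dead. Healthy therefore excludes red-positive
nuclei, so the three reported fractions partition unity exactly — chosen
so that healthy/dead/removed percentages sum to ~100.

### The statistic

With ρ_ref the blue-nucleus density pooled over all reference regions
(pooling, rather than averaging per-region estimates, weights regions by
area and is stabler for small regions):

    rel_blue = ρ_healthy,band / ρ_ref
    rel_red  = ρ_dead,band / ρ_ref
    rel_removed = 1 − rel_blue − rel_red

`rel_removed` may be negative when the band happens to be denser than the
references; it is reported unclipped, as sampling transparency matters
more than cosmetic positivity. Zero reference density is an error (the
statistic is undefined), never a silent zero.

Default region layout: two reference bands of the track's width, centred
3 track-widths above and below the track centre line, same length as the
analysed track segment. All densities are nuclei/mm²; coordinates are
pixel-centre, origin top-left, converted to µm by the pixel size.

### Track width

The damage profile `p(y) = 1 − ρ_healthy(y)/ρ_ref` is computed in lateral
bins (10 µm default) over the full track length; it combines killed and
removed cells through the healthy-density deficit. The width is the extent
of the contiguous run around the profile maximum above half the plateau
(FWHM; a full-extent variant thresholds at 10% of the plateau). The
estimate is quantised to the bin width, so bins should be ≲ 1/10 of the
expected width when resolution matters. If the plateau does not rise above
the binomial noise floor `max(0.2, 3/sqrt(ρ_ref·A_bin))` the width is
reported as 0 with a warning.

## Contact mechanics and the piercing model

Hertz sphere-on-half-space: `1/E* = (1−ν₁²)/E₁ + (1−ν₂²)/E₂`,
`a = (3FR/4E*)^{1/3}`, `δ = a²/R`, `p0 = 3F/(2πa²)`, computed in SI
internally and reported in µm/kPa. Self-consistency of `p0` with
`3F/(2πa²)` is asserted on every result. The maximum pressure between
probe and *bare substrate* serves as the severity index for comparing load
regimes across substrates of very different stiffness.

The piercing model explains the near load-independence of kill-track
widths on stiff substrates. Cells are soft, water-filled, and burst once
compressed to a critical thickness `h_crit`; after piercing, the monolayer
is treated as *load-transparent*: the substrate alone carries the load and
indents by the Hertz depth δ. Cells are destroyed wherever the
rigid-geometry sphere–substrate gap `g(r) = r²/2R − δ` is below `h_crit`,
so the full width is `2·sqrt(2R(h_crit + δ))`. On a stiff substrate
δ ≪ h_crit and the width is almost constant in F, whereas the Hertz
contact radius doubles from 10 to 80 mN. A series-stiffness variant (the
monolayer as a compliant layer bearing part of the load before piercing)
was considered and not implemented; it changes the pre-piercing loading
history but not the post-piercing geometry that sets the width.

Defaults: `h_cell` = 3 µm, `h_crit` = 0.8 µm (the order implied by
back-calculating a ~78 µm track under a 1 mm probe: `h_crit ≈ (w/2)²/2R`);
both are explicit inputs. Material table: soft silicone 73.32 kPa (ν 0.5,
from the casting protocol the pipeline accompanies), polystyrene 3.3 GPa
(ν 0.35), soda-lime glass 70 GPa (ν 0.22), cell monolayer 5 kPa (ν 0.5);
Poisson ratios are handbook values, configurable.

Known limitation: with a realistic polystyrene modulus the substrate
indentation grows from ≈ 0.16 µm (10 mN) to ≈ 0.66 µm (80 mN), which is
*not* small against `h_crit` ≈ 0.76 µm; the model then predicts ≈ 24%
width growth over that load range, more than the few percent typically
measured. Treating the gap with the exact Hertz surface profile instead of
the rigid parabola does not close this gap. Either `h_crit` is effectively
larger during sliding, or the pile of burst-cell debris bears part of the
load; the model reports its honest geometric prediction. On substrates
with E* ≳ 20 GPa the predicted growth is below 10%, matching the
qualitative near-constancy argument. No adhesion (JKR/DMT),
viscoelasticity, or finite-layer corrections are included.

## Synthetic data

### Traces

The trace generator emulates: a pre-movement dwell (default 10 s, the
loading dwell before sliding) with the normal-force servo approaching the
setpoint as a first-order lag (τ = 0.5 s); a surface
`h(x) = tilt·x + depth·(2x/L − 1)⁴` — tilt from sample/stage misalignment
plus an even-quartic meniscus bowl with flat bottom and upturned edges, as
a liquid polymer cures in a dish (the quartic is a modelling choice; the
true cured surface shape is not specified anywhere, and any smooth bowl
with one interior stationary point would serve); a static peak built over
50 µm of travel and relaxed onto the dynamic branch over 300 µm (cosine
blend, so the dynamic branch is *exactly* the closed-form balance from
there on); stick–slip as a sawtooth on the dynamic coefficient with
exponentially spaced slip events (mean spacing 100 µm) — the real
phenomenon is only qualitatively sawtooth-like; and additive Gaussian
noise on forces and height. Sampling rate 100 Hz (instrument-typical;
not specified anywhere), speed 1 mm/s, slide length 4 mm, all
configurable. Default friction coefficients (0.511/0.303) and the
10–80 mN force range mirror the cells-on-polystyrene study condition the
generator is modelled on.

The generator writes the measured channels through the same quasi-static
inclined-plane balance the analysis inverts — with the servo holding the
*vertical* channel, the contact normal force is
`N = F_N/(cosθ − µ·sinθ)` and `Fx = N(µ·cosθ + sinθ)`. Passing tests
therefore shows the analysis is exact for rigid quasi-static contacts with
servo-held vertical load; it does not validate against compliance,
viscoelastic creep, or servo dynamics during sliding, which the generator
does not model.

### Images

Nuclei are placed by a homogeneous spatial Poisson process at the
reference density (default 400 /mm², a confluent endothelial monolayer on
the sparse side). Inside a horizontal track band each nucleus is removed
with probability `p_remove`; retained track nuclei are dead with
probability `p_dead`. Retained nuclei render as isotropic Gaussian blobs
(σ = 4 µm, lognormal brightness spread 20%) in blue, dead ones also in
red, over a uniform background with Gaussian noise, clipped to 16-bit.
Not emulated: uneven illumination, cytoplasmic staining, nuclear shape
variation, debris or smearing along the track, imaging aberrations, and
spatial clustering of cells. Recovery results on these images therefore
demonstrate the statistic and the detector's counting behaviour, not
robustness to real-microscope artefacts; the detector's background
removal and per-image Otsu give it a reasonable chance on real data, but
that is untested here.

## Problem sizes and determinism

Everything is seeded; fixed seeds give bit-identical traces, images and
reports. The test suite runs designs of 4 forces × 3 repeats (friction)
and a 12-cell probability grid at 400 nuclei/mm² with a 0.25 × 6 mm slide
band (damage). The acceptance script simulates the full design — 4 forces
× 3 repeats without cells and × 9 with cells for traces, 9 image pairs
per condition at 1.75 × 4 mm field of view — the repeat counts of the
study design it mirrors. Width profiles there use 5 µm bins pooled over
the 9 repeats, putting ~15 bins across a ~78 µm track with ~30 nuclei
expected per bin.
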