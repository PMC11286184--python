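# celltribo

Friction and damage analysis for *in-vitro* tribology experiments on cell
monolayers — endothelial cells cultured on soft (PDMS) or stiff
(polystyrene) substrates and slid against a spherical probe in a
low-load pin-on-plate tribometer.

Measuring friction on living monolayers with a generic tribometer faces two
obstacles this package addresses:

1. **Misalignment and meniscus effects.** Cast polymer substrates are never
   perfectly level: the probe rides up a residual tilt and a bowl-shaped
   meniscus, so the raw lateral force `Fx` mixes interfacial friction with a
   slope component — a serious bias when friction coefficients are small.
   `celltribo` fits the measured probe height `h_m` against position with a
   polynomial `h_p(x)` (degree 5 by default) and rotates the measured force
   pair by the local surface angle `θ(x) = arctan(∂x h_p)`:

   ```
   F_F,adj = Fx·cosθ − F_N·sinθ        F_N,adj = F_N·cosθ + Fx·sinθ
   ```

   yielding slope-adjusted static and dynamic friction forces, and friction
   coefficients via a through-origin Amonton fit `F_F = µ·F_N`.

2. **Quantifying monolayer damage.** After a slide the sample is stained
   with Hoechst (all retained nuclei, blue) and propidium iodide (nuclei of
   membrane-compromised cells, red). Nuclei are detected per channel,
   matched across channels, and damage is expressed as densities in the
   slide band relative to the blue-nucleus density ρ_ref pooled over
   flanking reference areas:

   ```
   rel_blue = ρ_healthy/ρ_ref    rel_red = ρ_dead/ρ_ref
   rel_removed = 1 − rel_blue − rel_red
   ```

   The removed fraction may be slightly negative by sampling and is never
   clipped. A track-width estimate comes from the FWHM of the lateral
   damage profile.

A third module provides Hertz sphere-on-half-space contact quantities
(`a = (3FR/4E*)^{1/3}`, `δ = a²/R`, `p0 = 3F/(2πa²)`) as a load-severity
index, plus a monolayer-piercing model: cells burst once compressed to a
critical thickness `h_crit`, after which the substrate carries the load and
the kill-track full width is `2·sqrt(2R(h_crit + δ))` — nearly independent
of load on stiff substrates, unlike the Hertz radius (`∝ F^{1/3}`).

Because raw instrument data are rarely at hand, a synthetic-data generator
produces tribometer traces (tilt + meniscus, servo lag, static peak,
stick–slip sliding, noise) and two-channel micrographs (Poisson-distributed
nuclei, per-fate rendering) with full ground truth, so the whole pipeline
is testable end to end.

## Worked example

```python
from celltribo import TraceScenario, generate_trace, analyse_trace

# a 10 mN slide on a tilted, meniscus-shaped surface
scenario = TraceScenario(mu_s=0.511, mu_d=0.303, f_n=10.0, tilt=0.01,
                         meniscus_depth=0.02, seed=1)
trace, truth = generate_trace(scenario)
result, height, phases = analyse_trace(trace)
print(f"static friction : raw {result.f_fs_raw:.3f} mN, adjusted {result.f_fs_adj:.3f} mN")
print(f"dynamic friction: raw {result.f_fd_raw:.3f} mN, adjusted {result.f_fd_adj:.3f} mN")
print(f"mu_s = {result.mu_s:.3f}   mu_d = {result.mu_d:.3f}   (truth 0.511 / 0.303)")
```

prints

```
static friction : raw 4.795 mN, adjusted 5.061 mN
dynamic friction: raw 3.151 mN, adjusted 3.046 mN
mu_s = 0.515   mu_d = 0.304   (truth 0.511 / 0.303)
```

The raw dynamic force (3.151 mN) is biased upward by the surface slope;
after adjustment (3.046 mN) the recovered coefficients match the generator
ground truth to a fraction of a percent.

The same analyses run from the shell:

```sh
celltribo simulate set --out runs/ --seed 1
celltribo friction --traces 'runs/*.csv' --out results/
celltribo damage --images 'runs/*_blue.tif' --out results/
celltribo contact --out results/
celltribo run --config config.yaml --out results/
```

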