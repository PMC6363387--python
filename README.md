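# recastate

Quantitative analysis of RecA spatio-temporal organization in *E. coli*:
single-molecule FRET kinetics of a RecA\*-specific probe (mCI, a
catalytically dead λ-repressor fragment that binds active RecA–ssDNA
filaments), brightfield cell segmentation, two-channel focus
colocalization with an analytic chance null, population fluorescence
kinetics, and RecA storage-structure morphometry and event-time
analysis. A synthetic-data package generates FRET trajectories,
titrations, multi-channel cell images and time-lapses with full ground
truth, so every analysis stage is testable without raw microscopy data.

## Who this is for

Groups doing live-cell single-molecule microscopy of the bacterial DNA
damage (SOS) response — or any system with (a) two-state smFRET
trajectories, (b) rod-shaped cells with diffraction-limited foci in two
channels, and (c) bright sub-cellular aggregates whose size and
appearance/dissolution kinetics matter.

## The models and statistics at the core

**smFRET kinetics.** FRET efficiency per frame is
`E = I_A' / (I_A' + I_D)` with crosstalk-corrected acceptor
`I_A' = I_A − c·I_D`. Pooled efficiencies are decomposed into bound
(≈0.20) and unbound (≈0.43) Gaussian states; the bound weight across a
probe titration is fit with the Hill equation
`f(c) = cⁿ / (cⁿ + K_Dⁿ)`. Trajectories thresholded at E = 0.3
(bound strictly below) yield bound dwell times whose survival is fit by
`S(t) = (1 − f_slow)·e^(−k_fast t) + f_slow·e^(−k_slow t)`,
the two-off-rate model of heterogeneous filament dissociation.

**Cell segmentation.** Bandpass filter (suppress structures > 2 px) →
Gaussian-derivative edge magnitude at scale 2 px, rescaled to 8-bit →
Steger-style curvilinear ridge detection (σ = 0.8, hysteresis 1.7/5)
with sub-pixel line points; chains closing on themselves become cell
outlines with shoelace areas.

**Colocalization.** Foci are local maxima above a per-cell
median + k·MAD threshold, localized by 5×5 centroid; two channels
colocalize when same-cell centroids are within 0.2 μm, restricted to
cells with at least one focus in both channels. The chance null is
`P = n_foci · N_cells · A_focus / ΣA_cells` per channel (focus footprint
0.28462 μm² = 25 px²), multiplied across channels.

**Population kinetics and storage structures.** Per-timepoint
area-weighted fluorescence `F_i = Σ A_k I_k / K_i` with spread
`σ_Fi = √(Σ(A_k I_k − Â·Î)²/(K−1))`, error `ΔF_i = σ_Fi/K_i`, fold
increase `FI_i = F_i/F_0` with additive error `ΔFI_i = ΔF_i + ΔF_0`.
Storage structures are thresholded components (4000 au preset; 1200 au
for low-expression strains) measured by maximum Feret diameter
(convex hull + calipers over pixel corners) and tracked through
time-lapses for dissolution/appearance times, summarized as bootstrap
event-time CDFs (80% resamples × 1000).

## Worked example

```python
import numpy as np
from recastate.synthetic import sample_biexponential_dwells, simulate_titration
from recastate.fret import fit_survival_biexp, analyze_titration

rng = np.random.default_rng(7)

# two-class unbinding kinetics from 5000 bound dwell times
dwells = sample_biexponential_dwells(5000, k_fast=0.23, k_slow=0.044,
                                     f_slow=0.91, rng=rng)
fit = fit_survival_biexp(dwells)
print(f"k_off_fast  {fit.k_off_fast:.3f} s^-1")
print(f"k_off_slow  {fit.k_off_slow:.4f} s^-1")
print(f"fraction_slow {fit.fraction_slow:.3f}")

# probe titration -> bound fractions -> Hill fit
concs = [0, 10, 100, 300, 1000, 3000]           # nM
data = simulate_titration(36.0, 2.4, concs, [179, 139, 77, 70, 172, 68],
                          rng=rng)
fracs, hill = analyze_titration(concs, data.fret_values)
print(f"K_D {hill.kd:.1f} nM, cooperativity {hill.hill_n:.2f}")
```

prints

```
k_off_fast  0.238 s^-1
k_off_slow  0.0435 s^-1
fraction_slow 0.916
K_D 42.4 nM, cooperativity 2.12
```

The survival fit recovers the two generating off-rates (0.23 and
0.044 s⁻¹) and the slow-population amplitude (0.91): most binding
events at saturating probe dissociate via the slow pathway. The single
titration replicate recovers the generating K_D = 36 nM and n = 2.4 to
within its sampling noise (about ±7 nM and ±0.3 at these per-point
molecule counts); medians over replicates converge on the generating
values.

Image-side entry points: `recastate.synthetic.simulate_cell_field` /
`simulate_timelapse` (ground-truth fields and stacks),
`recastate.segmentation.segment_cells`, `recastate.foci.detect_foci` /
`colocalize` / `chance_colocalization`, and `recastate.kinetics`
(population statistics, Feret morphometry, event tracking, bootstrap
CDFs). The `recastate` command line exposes the same stages
(`recastate simulate|segment|coloc|fret|kinetics --help`).

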