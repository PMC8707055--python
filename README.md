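# organoidphasor

Label-free functional-imaging analysis for stem-cell-derived organoids:
phasor-based FLIM metabolic mapping, spectral-phasor hyperspectral
segmentation, and ΔΔCt qPCR quantification — driven by a synthetic
organoid-phantom generator, so every stage of the pipeline can be verified
against known ground truth without a microscope.

## The problem

Retinal organoids (and organoids generally) are heterogeneous, and picking
good ones for experiments or transplantation is subjective. Two-photon
autofluorescence imaging offers a non-invasive readout of developmental
state: the fluorescence *lifetime* of NADH reports metabolism (free NADH,
~0.4 ns, dominates in glycolytic/proliferative tissue; enzyme-bound NADH,
~3.4 ns, in oxidative/differentiated tissue), and the emission *spectrum*
localizes retinoids such as retinol, whose accumulation marks functional
photoreceptors. This package implements the analysis side of that workflow
for users who want a tested, scriptable alternative to interactive phasor
software.

## The method

**FLIM phasor transform.** Each pixel's photon-arrival histogram
$I_k$ over one laser repetition period $T$ maps to

$$g = \frac{\sum_k I_k \cos(\omega t_k)}{\sum_k I_k},\qquad
  s = \frac{\sum_k I_k \sin(\omega t_k)}{\sum_k I_k},\qquad
  \omega = \frac{2\pi}{T}$$

with $t_k$ the bin centers. Mono-exponential decays of lifetime $\tau$ fall
on the *universal circle* at
$(g,s) = \big(1, \omega\tau\big)/\big(1+(\omega\tau)^2\big)$, and mixtures fall
on chords between their components, split by intensity. A reference
compound of known lifetime (coumarin 6, 2.5 ns) supplies the rotation and
scaling that undo the instrument's phase/modulation distortion.

**Metabolic trajectory.** Calibrated pixels are projected orthogonally onto
the chord between the free-NADH (0.4 ns) and bound-NADH (3.4 ns) circle
points. The normalized chord position is $F_1$ (fraction of free NADH,
$F_2 = 1 - F_1$), and the scalar metabolic readout of a region is the f/b
ratio $F_1/F_2$ evaluated at the region's intensity-weighted phasor center
of mass. Longitudinal summaries report per-age-bin quartiles with
1.5 × SD whiskers.

**Spectral phasor.** The same transform along the 32-channel wavelength
axis (410–690 nm) places each pixel by its spectral shape; a circular
cursor on that plane selects and recolors pixels whose spectrum matches a
fingerprint (e.g. retinol).

**ΔΔCt.** Ct values are averaged per (group, gene), normalized to a
housekeeping gene and to a day-0 control group; non-detected wells are
assigned Ct = 40; the output is the log₂ fold-expression matrix and heatmap.

## Worked example

Simulate a two-layer organoid phantom (glycolytic rim, free fraction 0.7;
oxidative core, 0.3), image it with 10⁴ Poisson photons/pixel, calibrate
against a 2.5 ns reference, and recover the metabolic map:

```python
import numpy as np
from organoidphasor import (
    make_organoid_phantom, simulate_decay_cube, make_reference_decay,
    decay_to_phasor, derive_calibration, apply_calibration,
    make_nadh_axis, project_to_axis, project_fb_ratio, outer_rim_mask,
)

phantom = make_organoid_phantom(
    height=128, width=128, outer_radius=48, rim_thickness=10,
    rim_free_fraction=0.7, core_free_fraction=0.3, seed=1,
)
cube = simulate_decay_cube(phantom, photons_per_pixel=1e4, noise="poisson", seed=1)
reference = make_reference_decay(tau_ref=2.5, n_bins=256)

cal = derive_calibration(decay_to_phasor(reference), tau_ref=2.5)
field = apply_calibration(decay_to_phasor(cube), cal)
axis = make_nadh_axis(field.omega)           # free 0.4 ns, bound 3.4 ns
mmap = project_to_axis(field, axis)

rim = outer_rim_mask(field.intensity, rim_width=10)
ratio = project_fb_ratio(field, axis, mask=rim)
print(f"median rim F1:  {np.nanmedian(mmap.f1[phantom.label_image == 1]):.3f}")
print(f"median core F1: {np.nanmedian(mmap.f1[phantom.label_image == 2]):.3f}")
print(f"outer-rim f/b NADH ratio: {ratio:.3f}")
```

Output:

```
median rim F1:  0.700
median core F1: 0.300
outer-rim f/b NADH ratio: 2.333
```

The rim's free-NADH fraction of 0.700 matches the programmed ground truth,
and the rim f/b ratio 2.333 is the programmed 0.7/0.3 — the glycolytic
signature a young, proliferative organoid surface would show.

The same workflow is available from the shell:

```bash
organoidphasor simulate out/ --seed 1
organoidphasor flim out/decay.tif out/reference.tif out/flim --age-days 60
organoidphasor hspec out/spectral.tif out/hspec --config config.yaml
organoidphasor report out/flim/fb_ratios.csv out/report
organoidphasor qpcr out/qpcr.csv out/qpcr_results
```

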