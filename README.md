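# axonmorph

3D axon and myelin morphometry for segmented serial block-face scanning
electron microscopy (SBF-SEM) volumes.

Single-section electron micrographs are the workhorse of axon/myelin
quantification, but axons are not cylinders: caliber, myelin thickness and
G-ratio vary substantially along a single fiber, and a section through a
tilted axon is an elongated ellipse. `axonmorph` is for researchers who have
segmented label stacks of myelinated axons (e.g. optic nerve imaged at
5 nm/px in-plane, 50 nm slices, 100 µm of depth) and want the longitudinal,
3D-aware measurements: per-section morphometry at fixed intervals along each
traced axon, per-axon ranges and means, myelin-decompaction scores, nodes of
Ranvier with paranodal gaps, nodal mitochondria, and the group statistics
for normal-vs-injured comparisons.

## Measurements

For each traced axon, at 5 µm intervals of arc length along its centerline,
the package measures in the acquisition plane:

- cross-sectional area *A* (µm²),
- minimum axon diameter *d* — the minimum caliper (Feret) width, which is
  invariant to the elliptical elongation caused by oblique sectioning,
- minimum myelin thickness *t* (ray casting from the axon centroid),
- fiber diameter *D* (axon + sheath, minimum caliper),
- G-ratio *g = d / D*,
- percent of the myelinated circumference occupied by decompacted myelin.

Longitudinally it derives per-axon ranges (max − min), per-axon means, a
decompaction score (sections with > 40% decompaction, per µm of measured
length), paranodal gap lengths at detected nodes, and nodal mitochondrion
counts and z-span lengths (within 10 µm of a node). The statistical layer
provides the thickness–diameter regression (*t = g·d + c*, with R²),
Levene-gated unpaired t-tests, and repeated-measures ANOVA with Tukey HSD.

Because public SBF-SEM datasets with this labelling scheme are scarce, the
package ships a phantom generator: tortuous myelinated axons with known
caliber profiles, thickness rule *t = 0.20·d + 0.13* µm, nodes,
decompaction patches and mitochondria, with exact ground-truth tables — so
the whole chain is testable end to end, including matched "normal" and
"injured" cohort presets.

## Worked example

```python
from axonmorph import (generate_phantom, preset, measure_profile,
                       metric_range, profile_mean, decompaction_score,
                       trace_axon, detect_nodes)

config = preset("injured", seed=7)          # one tortuous myelinated axon
volume, truth = generate_phantom(config)    # label stack + ground truth

profile = measure_profile(volume, axon_id=1)     # sections every 5 µm
print(f"measured length: {profile.measured_length_um:.1f} um")
print(f"mean diameter:   {profile_mean(profile, 'axon_diameter'):.2f} um")
print(f"diameter range:  {metric_range(profile, 'axon_diameter'):.2f} um")
print(f"decompaction score: {decompaction_score(profile):.3f} points/um")

cl = trace_axon(volume, 1)
for node in detect_nodes(volume, cl):
    print(f"node at {node.center_s_um:.1f} um, gap {node.gap_um:.2f} um")
```

Output:

```
measured length: 40.2 um
mean diameter:   0.82 um
diameter range:  0.41 um
decompaction score: 0.099 points/um
node at 25.0 um, gap 2.11 um
```

The axon's traced arc runs 40.2 µm through the 40 µm stack (it is tortuous,
not axial); its minimum caliper diameter averages 0.82 µm but swings by
0.41 µm along the fiber — the intra-axonal variability single sections
cannot see. Four of the nine sampled sections exceed 40% decompaction
(0.099 points/µm), and the node at 25.0 µm shows a widened 2.1 µm paranodal
gap, drawn from the injured preset's N(3.0, 0.5) µm distribution (the
normal preset centres on 1.5 µm).

A command-line interface wraps the same machinery:

```bash
axonmorph simulate --preset injured --seed 7 --out scratch/phantom/
axonmorph measure scratch/phantom/phantom.tif --config scratch/phantom/config.txt --out scratch/results/
axonmorph compare --n-axons 10 --seed 7 --out scratch/stats.csv
```

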