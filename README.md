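# meniscus3d

3D measurement of **medial meniscal extrusion (MME)** from surface models of
the knee, for musculoskeletal imaging researchers studying osteoarthritis
progression.

Medial meniscal extrusion — the meniscus displacing medially past the edge
of the tibial plateau — predicts cartilage loss, but the conventional
measurement is a caliper distance on a single coronal MRI slice, which can
miss the true maximum and depends on a plateau-edge reference that marginal
osteophytes corrupt. This package implements a fully 3D alternative:

1. **Anatomical tibial frame.** A cross-section of the tibia is taken at
   the top of the fibular notch, below the osteophyte zone, and a rectangle
   is fitted tangent to the condylar contours (posterior common tangent,
   medial/lateral tangents, anterior tangent of the medial condyle). Its
   center, translated superiorly to the bottom of the medial plateau, is
   the origin; the sides give the anteroposterior X and mediolateral Z
   axes, and Y = Z × X points superior. The frame can be transferred
   between CT- and MRI-derived models of the same bone by point-to-surface
   ICP.
2. **Reference region.** The tibia is cut 10 mm inferior to the plateau
   (parallel to the ZX plane) and at the XY plane; the resulting medial
   plateau block is sectioned at the −10 mm level and that cross-section is
   extruded 30 mm superiorly into a prism. Because the outline lives 10 mm
   below the joint line, rim osteophytes cannot move it.
3. **Extrusion metrics.** MME **volume** is the volume of the meniscus
   model outside the prism; MME **width** is the distance from the prism's
   medial edge to the meniscal medial edge along the Z axis (optionally the
   maximum over anteroposterior positions). A conventional single-slice 2D
   width is included for comparison.

The prism is a vertical extrusion, so "volume outside the prism" is
computed *exactly* by clipping each meniscal triangle against the prism
outline in 2D and integrating with the divergence theorem — no mesh boolean
engine is involved — and is cross-checked against a brute-force voxel
oracle. A synthetic knee phantom (two condylar lobes, articular dishes,
optional osteophytes and tibial spine ridge, C-shaped meniscal wedge with a
construction extrusion offset `e`) provides analytically known ground
truth, and CT-like (0.5 mm) / MRI-like (2.0 mm coronal) acquisition
emulation supports a full simulated validation study with the agreement
statistics such studies report (Shapiro–Wilk, two-sample t with Cohen's d,
consistency regression with adjusted R², intraclass correlation, noncentral
t power analysis).

## Worked example

```python
from meniscus3d import (
    MeniscusSpec, PhantomSpec, make_phantom,
    fit_tibial_frame, measure_extrusion,
)

spec = PhantomSpec(meniscus=MeniscusSpec(extrusion_mm=3.0))
tibia, meniscus, truth = make_phantom(spec)

frame = fit_tibial_frame(tibia, notch_plane_point=[0.0, spec.notch_level_y, 0.0])
result, section, plateau = measure_extrusion(tibia, meniscus, frame)

print(f"width  {result.width:.3f} mm   (construction offset {truth.width:.3f} mm)")
print(f"volume {result.volume:.1f} mm^3 (closed form {truth.volume:.1f} mm^3)")
```

prints

```
width  3.000 mm   (construction offset 3.000 mm)
volume 679.3 mm^3 (closed form 679.2 mm^3)
```

i.e. the pipeline recovers the phantom's built-in 3 mm extrusion to a few
microns and its closed-form extrusion volume to ~0.02%. The same chain is
available from the shell:

```bash
meniscus3d simulate -e 3.0 --out-dir phantom_out
meniscus3d measure phantom_out/tibia.stl phantom_out/meniscus.stl --notch-y -20
meniscus3d stats --n-subjects 10 --out-dir cohort_out   # simulated CT/MRI study
meniscus3d power -d 1.32                                 # -> required sample size: 10
```

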