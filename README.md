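# calcmorph

Three-dimensional morphometry of the calcaneus (heel bone) from CT-like
volumes: bone segmentation and surface meshing, landmark-based measurement
of nine morphological parameters, and the statistics of a
measurement-reliability study.

## Who it is for

Orthopaedic and anatomy researchers who quantify calcaneal shape in 3D —
for fracture-reduction planning, normative reference data, or method
validation — and need the whole chain to be reproducible and testable:
from an attenuation volume, through a triangulated bone surface, to
parameter tables, gender comparisons and reliability reports. Because real
CT cohorts are rarely shareable, the package ships a synthetic-data layer
(voxel phantoms with closed-form ground truth, and cohort/session
simulators driven by normative per-gender distributions) that exercises
every stage end to end.

## The measurements

Six landmarks are placed on the bone surface: **A** (highest point of the
posterior articular facet), **B** (bottom of the posterior facet where it
meets the anterior process), **C**/**D** (highest/lowest points of the
calcaneocuboid joint), **E** (most posterior point of the tuberosity),
**F** (highest point of the tuberosity's superior edge). With
G = (C + D)/2 and H the foot of the perpendicular from A onto line GE
(the *calcaneal axis*):

| symbol | definition | units |
|--------|------------|-------|
| LCA | axis length \|GE\| | mm |
| HPF | posterior-facet height \|AH\| | mm |
| LPF | posterior-facet length \|AB\| | mm |
| LAP | anterior-process length \|BC\| | mm |
| HAP | anterior-process height \|CD\| | mm |
| GA  | Gissane's angle ∠ABC | deg |
| BA  | Böhler's angle 180° − ∠CAF | deg |
| APF / AMF | posterior / middle articular facet area, flood-filled on the surface mesh inside an operator-marked boundary | cm² |

The statistical layer implements ICC(2,1) (two-way random effects,
absolute agreement, single measurement) with F-based 95% CIs, the
precision index RMS-SD = √(Σᵢ SDᵢ²/N) over repeated measurements, the
coefficient of variation CV = 100·RMS-SD/mean, Bonett's sample-size
approximation for ICC planning, height-adjusted ANCOVA gender comparison,
and demographic t-tests.

## Worked example

```python
import calcmorph as cm

v = cm.ParameterVector(LCA=80.0, HPF=31.5, LPF=28.6, LAP=21.1, HAP=30.4,
                       GA=127.7, BA=39.6, APF=14.5, AMF=6.1)
rec = cm.measure_all(cm.realize_landmarks(v))
print(rec.LCA, rec.GA, rec.BA)        # 80.0 127.7 39.6 (exact round trip)

print(cm.bonett_n(rho0=0.8, width=0.2, k=3))   # 36 subjects
print(round(cm.cv_percent(0.6, 74.2), 1))      # 0.8 (% CV of axis length)
```

Running `python examples/02_phantom_to_mesh.py` segments a 10 mm sphere
phantom voxelized at 0.5 mm and prints

```
mesh area       1250.15 mm^2  (sphere 4*pi*R^2 = 1256.64, err -0.52%)
cap facet area   122.42 mm^2  (cap 2*pi*R*h   = 125.66, err -2.58%)
```

— the extracted surface area and the flood-filled facet area agree with
the closed forms to within a few percent at CT-like resolution. The other
scripts in `examples/` cover cohort simulation with the height-adjusted
gender comparison (every parameter differs except the anterior-process
length) and a full reliability study (intra-observer ICCs ≳ 0.92,
inter-observer ICCs > 0.8, RMS-SD near the injected error magnitudes).

A thin CLI wraps the same stages:

```bash
calcmorph simulate --out-dir out --seed 1
calcmorph phantom  --out-dir out --seed 1
calcmorph segment  --out-dir out --volume out/phantom.nii.gz
calcmorph measure  --out-dir out --landmarks out/phantom_landmarks.csv
calcmorph reliability --out-dir out --sessions out/sessions.csv
calcmorph compare     --out-dir out --cohort out/cohort.csv
```

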