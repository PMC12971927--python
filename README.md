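# couinaudps

Pictorial-structures landmark inference and plane-based Couinaud liver
segmentation.

## The problem

Couinaud segments are the standard reference frame for liver surgery:
resection decisions hinge on per-segment volumes (the future liver
remnant).  The segment boundaries can be approximated by planes through
eight anatomical landmarks — the inferior/superior vena cava points
(IVCi, IVCs), gallbladder fossa (GBF), umbilical fissure (UF), left and
right portal vein branch points (LPV, RPV), and the middle and right
hepatic veins (MHV, RHV).  Placing those landmarks automatically is hard;
what a whole-body segmenter gives you reliably are *organ masks*.  This
package bridges the gap: it extracts nine easy auxiliary landmarks from
organ masks (organ tops, corners, centroids of liver, right kidney,
pancreas, portal vein, gallbladder, vena cava, heart), infers the eight
Couinaud landmarks from them with an explainable statistical model, and
partitions the liver mask into segments 2, 3, 4a, 4b, 5, 6, 7, 8 (the
caudate is not landmark-defined and is excluded).

## The model

A pictorial structure over N = 17 named landmarks.  Training data is the
4D displacement matrix of a cohort (P × N × N × 3): every pairwise 3D
displacement for every subject, in world millimetres — positions never
enter, so the model is invariant to patient placement and modality.
Each ordered pair (u, k) is reduced to a trivariate Gaussian with mean
μ<sub>u,k</sub> = E[l<sub>u</sub> − l<sub>k</sub>] and covariance
Σ<sub>u,k</sub> (sample covariance + λI, default λ = 1 mm²); missing
landmarks are simply excluded from the pair's sample.  An unknown
landmark u given known landmarks k = 1..K has the spatial probability
map

&nbsp;&nbsp;P<sub>u</sub>(v) = ∏<sub>k</sub> 𝒩(v; l<sub>k</sub> + μ<sub>u,k</sub>, Σ<sub>u,k</sub>),

whose mode is closed-form (precision-weighted average):
precision = Σ<sub>k</sub> Σ<sub>u,k</sub><sup>−1</sup>, mean =
precision<sup>−1</sup> Σ<sub>k</sub> Σ<sub>u,k</sub><sup>−1</sup>(l<sub>k</sub> + μ<sub>u,k</sub>).
The map decomposes into per-contributor heatmaps, so every prediction is
traceable to the evidence behind it.

For atypical anatomy, a *personalized* model refits on the n (default 10)
training cases most similar to the query under the displacement-pattern
distance

&nbsp;&nbsp;D = (1/K′²) Σ<sub>k₁</sub> Σ<sub>k₂</sub> | d<sub>B</sub>(k₁,k₂) − d<sub>A</sub>(k₁,k₂) |₁,

summed over the K′ landmarks present in both subjects.

No clinical data ship with the package; a synthetic-cohort generator
(two anatomical subtypes, per-landmark jitter, pose and scale variation,
missingness, and procedural organ masks consistent with the landmarks)
makes every stage testable end to end.

## Worked example

```python
import numpy as np
from couinaudps import (
    AUXILIARY_LANDMARKS, COUINAUD_LANDMARKS, PictorialStructuresModel,
    CohortConfig, generate_cohort, generate_subject_masks, assign_segments,
)

cohort = generate_cohort(CohortConfig(n_subjects=100, seed=42))
model = PictorialStructuresModel(cohort)

case = cohort[0]                                  # pretend this is a new patient
known = case.subset(list(AUXILIARY_LANDMARKS))    # only its auxiliary landmarks
results = model.fit_personalized(known, n=10)     # 10 most similar cases
predicted, provenance = results.predict(known)

for name in COUINAUD_LANDMARKS:
    err = np.linalg.norm(predicted[name] - case[name])
    print(f"{name:5s} predicted at {np.round(predicted[name], 1)}  error {err:5.2f} mm")

masks = generate_subject_masks(case, spacing=6.0)
segments = assign_segments(masks, predicted)
print({s: round(p, 1) for s, p in segments.volumes_pct.items()})
```

Output:

```
IVCi  predicted at [  3.5  27.8 -75.1]  error  6.44 mm
IVCs  predicted at [ 2.6 26.3 84.9]  error 11.68 mm
GBF   predicted at [ 49.5  89.5 -36.1]  error  5.12 mm
UF    predicted at [-29.   85.  -19.3]  error 19.20 mm
LPV   predicted at [-19.   53.7   5.9]  error  5.09 mm
RPV   predicted at [55.7 42.9  5.1]  error 19.64 mm
MHV   predicted at [32.7 65.3 62.4]  error  7.59 mm
RHV   predicted at [89.5 53.2 63.5]  error 17.76 mm
{'2': 17.1, '3': 12.5, '4a': 7.4, '4b': 35.6, '5': 6.7, '8': 4.2, '6': 14.3, '7': 2.3}
```

Each line is one Couinaud landmark predicted from the nine auxiliary
landmarks alone, with its Euclidean error against the subject's true
(generated) position — single-digit millimetres for well-constrained
landmarks, larger where this subject's jitter is unusual.  The final dict
is the segment partition of this subject's liver mask as percent of whole
liver volume, the quantity surgical planning consumes.

The same workflows are available from the shell:

```bash
couinaudps simulate --n 100 --seed 42 --out cohort/
couinaudps build-model --cohort cohort/ --out model.npz
couinaudps predict --model model.npz --landmarks aux.csv --out predicted.csv
couinaudps segment --liver masks.nii.gz --landmarks predicted.csv --out segments.nii.gz
couinaudps evaluate --cohort cohort/ --mode personalized --out eval/
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline workflow from scratch: it generates the
seeded two-subtype synthetic cohort (P = 200, 15 mm subtype separation,
5 mm landmark jitter), fits the base displacement model, runs
leave-one-out cross-validation in base and personalized (n = 10) modes,
measures how often the selected neighbours share the query's subtype,
sweeps the personalized subset size, and partitions one subject's liver
into Couinaud segments, logging all summaries to stderr and writing the
JSON results file to `--out`.
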