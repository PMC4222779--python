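# embryomorph

Landmark-based geometric morphometrics of embryonic mouse craniofacial
development: quantification of observer landmark-placement error and
ontogenetic allometry for 3D ectodermal surface landmarks at E10.5–E12.5.

## Who this is for

Developmental biologists and morphometricians working with micro-CT
surfaces of early mouse embryos, where facial prominences grow and fuse
before any bone exists and the ectodermal surface is the only thing to
landmark. Before landmark data from multiple observers or labs can be
pooled, two questions must be answered quantitatively:

1. **How repeatably can each landmark be placed?** Within one observer
   (trial to trial) and between observers — and which landmarks are so
   unreliable they should be dropped.
2. **Does the choice of landmarks change the biology?** Specifically,
   whether the ontogenetic allometry — the dependence of craniofacial
   shape on size — is robust to removing groups of landmarks.

The package ships the standard 36-landmark scheme (6 midline points and 15
bilateral pairs, ids 1–38 with 19/36 unused, grouped into Nasal,
Maxillary/Mandibular and Non-Facial subsets), the error statistics, the
Procrustes and regression machinery, and a synthetic-data generator that
emulates the full study design (10/9/10 specimens per age, 4 observers of
whom one is a novice, 2 placement trials) so every analysis is testable
end to end.

## The statistics

For a configuration of k landmarks `x_i ∈ R^3`, **centroid size** is
`CS = sqrt(Σ_i ||x_i − x̄||²)` — the standard size measure and the proxy for
developmental age.

- **Intraobserver error** per landmark: `||x^(trial 1) − x^(trial 2)||` in
  mm, pooled across left/right for bilateral pairs; the reference level is
  0.1 mm.
- **Interobserver error** per landmark and specimen: the centroid size of
  the observers' trial-mean placements, left and right sides separate.
- **Placement ANOVA** per age: the distance of each observer's trial-mean
  placement from the specimen mean is modelled as
  `distance ~ specimen + landmark + observer` with sequential sums of
  squares (order-invariant under the balanced design). The design fixes the
  degrees of freedom: Specimen 9/8/9, Landmark 35, Observer 3, Residual
  1392/1249/1392 at E10.5/E11.5/E12.5.
- **Allometry**: after generalized Procrustes superimposition (centering,
  unit-CS scaling, proper rotations only — embryo heads are chiral),
  Procrustes coordinates are regressed on CS. The slope vector β gives a
  per-specimen **regression score** `(y − ȳ)·β/||β||`, the **percent
  variance explained** `100·SS_pred/SS_tot`, and per-landmark
  **ontogenetic vectors** `β_l·ΔCS`. The subset-removal experiment repeats
  the regression without each landmark group, registered on three shared
  anchor landmarks (1, 8, 22) so vectors can be compared angle by angle.

## Worked example

```python
from embryomorph import (SimParams, simulate_dataset, intraobserver_error,
                         deviation_from_mean, placement_anova_by_age,
                         ontogenetic_regression)

dataset, truth = simulate_dataset(SimParams(seed=1))
intra = intraobserver_error(dataset)
print(intra[intra.observer != "obs4"].distance.median())   # 0.0547
print(intra[intra.observer == "obs4"].distance.median())   # 0.1408

anova = placement_anova_by_age(deviation_from_mean(dataset))
print(anova["E10.5"].df)
# {'Specimen': 9, 'Landmark': 35, 'Observer': 3, 'Residual': 1392}

_, allo = ontogenetic_regression(dataset, observers=("obs1", "obs2", "obs3"))
print(round(allo.pct_variance, 1))                         # 81.8
```

Experienced observers place landmarks with a median trial-to-trial error
of ~0.06 mm — well under the 0.1 mm reference — while the novice exceeds
it; the ANOVA table carries the design-determined degrees of freedom; and
the regression of shape on centroid size accounts for ~82% of shape
variance, close to the 80% share injected by the generator.

The `examples/` directory has one narrative script per capability
(scheme and file I/O, simulation, error statistics, ANOVA, allometry,
subset robustness, full pipeline). A complete reproducible run is also
available from the shell:

```
embryomorph run --seed 1 --out runs/
```

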