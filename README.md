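# fasym

Object-symmetry Procrustes analysis of fluctuating asymmetry in replicated
3-D landmark data, with mixed-effect modelling of per-individual asymmetry
against demographic and exposure covariates.

## The problem

Fluctuating asymmetry (FA) — random, individual-specific departures from
bilateral symmetry in a structure that is symmetric on average — is a widely
used morphological proxy for developmental instability: the more a
developing organism is stressed, the less precisely the two sides of its
body track each other. Quantifying FA in a structure with *object symmetry*
(a single structure with an internal midline, such as a cranium) requires
separating three confounded signals in digitized landmark coordinates:

* **directional asymmetry (DA)** — the left–right offset shared by the whole
  sample;
* **fluctuating asymmetry** — each individual's own departure from the
  shared asymmetry; and
* **measurement error** — digitizing noise, estimated from replicate
  landmark placements of the same specimen.

`fasym` implements the standard geometric-morphometrics workflow for this
problem and is aimed at researchers analysing replicated 3-D landmark
configurations (e.g. crania digitized twice in 3D Slicer) together with
specimen-level covariates such as sex, age at death, birth cohort, maternal
lineage and exposure history.

## The model

For a landmark scheme with *p* bilateral pairs and *u* midline points in
3-D, every configuration *X* is paired with its reflected, relabelled mirror
*X\** (one axis negated, paired rows swapped). All originals and mirrors
enter one generalized Procrustes analysis (GPA): each configuration is
centred, scaled to unit centroid size, and iteratively rotated by least
squares to the consensus, which is symmetric by construction. Each
observation then splits orthogonally into

* a symmetric component ½(*X* + *X\**) − consensus (dimension
  *d*<sub>sym</sub> = 3*p* + 2*u* − 4), and
* an asymmetric component ½(*X* − *X\**) (dimension
  *d*<sub>asym</sub> = 3*p* + *u* − 3).

A two-factor Procrustes ANOVA decomposes the squared Procrustes deviations
into individual, side (DA), individual×side (FA) and error strata with
degrees of freedom

| effect | df |
|---|---|
| individual | (*n* − 1) *d*<sub>sym</sub> |
| side (DA) | *d*<sub>asym</sub> |
| individual×side (FA) | (*n* − 1) *d*<sub>asym</sub> |
| error | (*r* − 1) *n* (*d*<sub>sym</sub> + *d*<sub>asym</sub>) |

for *n* individuals and *r* replicates. Individual and side are tested over
the FA mean square and FA over error; the FA-over-error *F* ratio measures
how far the FA signal stands above digitizing noise.

Each individual's **Procrustes FA score** is ‖ā<sub>i</sub> − DA‖ — the
Procrustes distance between its replicate-averaged asymmetric component and
the sample DA vector. These scores are modelled with random-intercept
linear mixed models, `fa_score ~ fixed effects + (1 | matriline)`, fitted by
REML with Satterthwaite denominator degrees of freedom, plus Holm-adjusted
pairwise contrasts and a simulation-based power analysis.

A synthetic-data generator produces landmark datasets with exactly this
statistical structure (symmetric individual variation, a fixed DA field,
individual FA optionally inflated in an exposure group, per-replicate
digitizing noise, arbitrary rigid motion and scaling per configuration), so
the whole pipeline is testable without access to physical specimens.

## Worked example

```python
import fasym

dataset = fasym.simulate_dataset(fasym.SimulationParams(seed=7))
results = fasym.ObjectSymmetryModel(dataset).fit()
print(results.summary())
```

```
Object-symmetry Procrustes analysis
===================================
individuals: 275   replicates: 2   landmarks: 34 (13 pairs + 8 midline)
directional asymmetry magnitude: 0.004326
Procrustes FA scores: mean 0.0148, median 0.0147, SD 0.0016

              Effect    df       SS       MS         F             p     % var
          Individual 13974 3.175323 0.000227 22.586883  0.000000e+00 91.119765
           Side (DA)    44 0.010291 0.000234 23.249327 1.806709e-177  0.295324
Individual*Side (FA) 12056 0.121287 0.000010  1.477557 5.248109e-145  3.480477
               Error 26125 0.177878 0.000007       NaN           NaN  5.104434
```

Individual variation dominates (~91% of the total sum of squares), DA is a
small but highly significant shared offset, and the FA stratum stands about
1.5× above digitizing error — the regime in which FA scores are
interpretable. The default simulated cohort inflates fetal-exposure FA by
40%; the exposed-subset mixed model recovers that:

```python
joined = dataset.metadata.merge(results.fa_scores(), on="specimen_id")
res4 = fasym.fit_lmm(joined, spec=fasym.MODEL_SUITE[3])
print(fasym.posthoc_holm(res4, "age_at_hurricane").round(5))
```

```
           contrast  estimate  std_error  z_value    raw_p  adjusted_p
0  fetal - juvenile   0.00239    0.00059  4.06687  0.00005     0.00014
1     fetal - adult   0.00288    0.00077  3.72222  0.00020     0.00039
2  juvenile - adult   0.00050    0.00049  1.01137  0.31184     0.31184
```

Individuals exposed as fetuses carry ~0.002–0.003 more FA (in Procrustes
distance units) than those exposed later in life, while the juvenile–adult
contrast is null.

The same analysis runs from the shell:

```sh
fasym run --seed 7 --out runs/demo     # full pipeline, synthetic scenario
fasym report runs/demo                 # Markdown summary of the artifacts
```

or from digitized data (`.fcsv`/`.tps` landmark files plus a metadata CSV)
via a YAML configuration with an `inputs:` block.

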