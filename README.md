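# afidreg

Millimetric registration-accuracy analysis for stereotactic neuroimaging,
built around 32 protocol-defined anatomical fiducials (AFIDs) placed as
single 3D points.

The package computes:

- **LD** — inter-rater localization distance (pairwise, unsigned axes);
- **AFLE** — rater-to-consensus localization error (consensus = mean of
  three or more independent raters);
- **AFRE** — registration error: signed displacement between a fiducial
  transformed into template space and the template consensus placement,
  plus a per-subject **global AFRE** (mean Euclidean AFRE);
- summaries (median/IQR, mean/variance, per-axis RMSE) and nonparametric
  comparisons (Wilcoxon signed-rank and rank-sum with exact small-sample
  null distributions, two-tier Bonferroni flags);
- the shared-misregistration analysis: electrode-tip centering, axiswise
  variance-explained (r²) maps of tip displacement on AFRE, per-landmark
  and stacked PCA of AFRE vectors, pairwise r² matrices in Cartesian or
  principal-component bases, and attribution of tip variance along its
  leading principal axis to the leading shared AFRE component (r² and
  millimeters explained per electrode);
- closed-form spherical VTA overlap (radius from volume, lens
  intersection, Dice after a center shift);
- a synthetic-cohort simulator with a known generative model (shared
  smooth misregistration pattern scaled by a per-subject latent score,
  smooth residual fields, rater and surgical noise) including the analytic
  expected attribution r² (`theoretical_r2`) for recovery tests.

Point transforms (4×4 affines and dense NIfTI displacement fields with
trilinear sampling) are included so fiducials and electrode tips can be
mapped from subject to template space. All coordinates are RAS+ world
millimeters internally; LPS files are converted at the boundary.

## Command line

`afidreg` exposes subcommands for each stage:

```sh
afidreg simulate --n-subjects 24 --seed 7 --out sim/     # fcsv + tips.csv + truth.json
afidreg ld rater_a.fcsv rater_b.fcsv
afidreg afle r1.fcsv r2.fcsv r3.fcsv
afidreg afre sim/sub-0001.fcsv --subject sub-0001        # vs bundled template consensus
afidreg summarize afre.csv
afidreg r2-map --afre-csv afre.csv --tips-csv sim/tips.csv
afidreg stacked-pca --afre-csv afre.csv --afids 2,3,4,14 --out-prefix pca
afidreg attribute --afre-csv afre.csv --tips-csv sim/tips.csv
afidreg vta-dice --volume-mm3 100 --shift-mm 2
afidreg run --config run.yaml                            # full pipeline + report.json
```

A minimal `run.yaml`:

```yaml
outdir: out/
seed: 7
simulate:            # or: fiducials_dir + tips_csv for real data
  n_subjects: 100
analysis_afids: [2, 3, 4, 14]
```

Exit codes: 0 success, 2 input error, 3 degenerate statistics.

Transform direction contract: a transform chain maps subject-space points
to template-space points. Whether the on-disk warp you export is the
"forward" or "inverse" file in your registration package's naming is your
responsibility — packages disagree. Fields are NIfTI `(X,Y,Z,3)` or
`(X,Y,Z,1,3)` volumes of world-millimeter RAS vectors; pass
`itk_vectors=True` (API) for LPS-convention vectors.

## Layout

| module | contents |
| --- | --- |
| `afidreg.io` | `.fcsv` read/write, protocol registry, template consensus |
| `afidreg.transforms` | affines, displacement fields, trilinear point transforms |
| `afidreg.metrics` | LD/AFLE/AFRE, summaries, RMSE, Wilcoxon tests, Bonferroni |
| `afidreg.covariance` | centering, regressions, PCA, r² maps, attribution |
| `afidreg.vta` | spherical VTA overlap closed forms |
| `afidreg.cohort` | synthetic cohorts + analytic attribution r² |
| `afidreg.pipeline` / `afidreg.cli` | config-driven runs, report, CLI |
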