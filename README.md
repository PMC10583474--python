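# frfx — functional liver-remnant volumetry from CT texture

Before a major hepatectomy, the future liver remnant (FLR) is grown by ALPPS
(rapid, days) or portal-vein embolisation (PVE; slower, weeks). Rapid
regeneration inflates the *anatomic* remnant with oedema and congestion that
add volume but no function, so CT volumetry overestimates the reserve that
actually protects against post-hepatectomy liver failure (PHLF). `frfx`
implements a texture-based pipeline that splits the anatomic remnant into
functional tissue and oedema and asks the clinical question directly: does
the **functional** remnant percentage predict severe PHLF better than the
anatomic one?

Because no patient images are available, a synthetic phantom generator stands
in for the cohort: paired pre/post CT-like volumes of an ellipsoidal liver
with a plane-bounded remnant, vessels, a tumour, and a ground-truth oedema
rim occupying a known fraction θ of the post-conditioning remnant. Everything
downstream is evaluated against that known truth.

The quantities involved, per case:

    FRLV%  = FRL  / (TLV − TV) × 100          anatomic remnant share
    FRFxV% = FRFx / (TLV − TV) × 100          functional remnant share
    iFRL%, iFRFx% = (post − pre)/pre × 100    relative growth
    BSA    = √(height·weight/3600)            Mosteller, m²
    sFLR%  = FRL / (−794.41 + 1267.28·BSA) × 100
    KGR    = ΔFRLV% / days                    kinetic growth rate

and the outcome model ties severe PHLF to the *true* functional share:
P(PHLF ≥ B) = expit(2.0 − 0.08·FRFxV%).

The pipeline: phantom simulation → 106-feature radiomic catalogue
(first-order / shape / GLCM / GLRLM / GLSZM / GLDM / NGTDM, frozen in
`src/frfx/radiomics/catalogue.json`) → information-gain selection of
first-order features → logistic classification of 1-cc remnant patches as
functional vs oedema → volumetry → ROC comparison of FRFxV%, FRLV%, sFLR and
KGR as PHLF predictors, plus the ALPPS-vs-PVE growth contrast. See
`docs/methods.md` for the full model description and conventions.

## Worked example

The analysis is organised as numbered drivers over the library:

```sh
python analysis/01_simulate_cohort.py   --seed 1   # cohort + ground truth
python analysis/02_train_classifier.py  --seed 1   # patch classifier
python analysis/03_estimate_function.py --seed 1   # FRFx per case
python analysis/04_outcomes.py                     # ROC + group contrasts
python analysis/05_replicate_studies.py --seed 1   # stability over cohorts
```

With seed 1 the chain prints:

```
simulated 24 cases -> results/01_cohort/cohort_manifest.csv
  PHLF >= B: 8 of 24
  mean oedema fraction: ALPPS 0.50, PVE 0.18
trained on 10998 functional / 1308 oedema patches
selected features (by information gain): firstorder_Mean,
  firstorder_RootMeanSquared, firstorder_Median, firstorder_10Percentile,
  firstorder_90Percentile
k-means (k=2) agreement with truth labels: 0.981
volumetry for 24 cases -> results/03_volumetry/volumetry.csv
  median |estimated - true| FRFx, as share of FRL: 0.014
  median FRFxV% 36.7 vs FRLV% 57.5
outcome tables -> results/04_outcomes
  AUC(FRFxV) = 0.632   AUC(FRLV) = 0.556
  AUC(sFLR)  = 0.507   AUC(KGR)  = 0.299
  iFRL median: ALPPS 90.6% vs PVE 54.4% (p = 0.004)
  iFRFx median: ALPPS 3.0% vs PVE 17.7% (p = 0.072)
```

Reading this: the classifier recovers the functional volume to ~1% of the
remnant; oedema-heavy ALPPS cases grow anatomically (iFRL, significant)
far more than functionally (iFRFx, not significant); and on this single
24-case cohort the functional percentage already out-ranks the anatomic one
as a PHLF predictor. Single-cohort AUCs are noisy at n = 24 — script 05
repeats the evaluation over fresh cohorts, where the medians stabilise near
AUC(FRFxV) ≈ 0.75 vs AUC(FRLV) ≈ 0.61, with sFLR and KGR near chance, while
a zero-texture-contrast null run stays at chance everywhere.

## Layout

    src/frfx/
      types.py        volumes, masks, case metadata
      phantom.py      geometry, texture, outcome model, cohort sampling
      volumetry.py    FRLV/FRFxV/iFRL/iFRFx/BSA/sFLR/KGR
      radiomics/      catalogue.json + first-order, shape, texture families
      classifier.py   IG selection, t-screen, k-means, logistic patch model
      stats.py        Mann-Whitney (exact + approximate), ROC/AUC, chi²,
                      Spearman, Shapiro-Wilk
      outcomes.py     PHLF prediction table, ALPPS-vs-PVE contrast
      studies.py      replicate-cohort studies
      pipeline.py     end-to-end runner with case-level train/test split
      io.py           NIfTI-1 read/write, artefact hashing
    analysis/         numbered drivers (see worked example)
    tests/            pytest suite incl. brute-force oracle cross-checks
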