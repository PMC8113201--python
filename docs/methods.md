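# Methods

This note documents the models, procedures and numerical choices behind
`petmr-lesionrisk`, in the spirit of the methods documentation of
packages like statsmodels or scanpy: what is computed, under which
assumptions, with which defaults, and what the synthetic validation
does and does not establish.

## The workflow

The package implements a non-invasive prostate-lesion risk workflow on
tri-modal PET/MRI ([68Ga]Ga-PSMA-11 PET, ADC, T2w):

1. **Preprocessing.** Each modality volume is resampled to an isotropic
   2 mm lattice and PET/T2w voxel values are normalized to the mean of
   a gluteus-muscle reference region (ADC is already quantitative and
   passes through). Lesion VOIs are either supplied externally or
   delineated as iso-count regions (connected component above a
   fraction of the lesion's local uptake maximum).
2. **Radiomics.** For every lesion, 442 registry features (intensity
   statistics, intensity-histogram statistics, GLCM at distances 1 and
   2, GLRLM, GLSZM, GLDZM, NGTDM per modality; morphology once) plus
   SUV_max, SUV_peak, SUV_mean and SUV_TLG form a 446-entry vector.
3. **Feature engineering.** Cohort-level redundancy reduction drops
   features with |Pearson r| > 0.75 against a retained feature; each
   cross-validation fold then keeps the top five features by squared
   point-biserial correlation with the binary lesion label (training
   rows only).
4. **Models.** A patient-grouped Monte Carlo cross-validation scheme
   (default 1000 unique folds, 5 validation patients each) drives three
   model families: the lesion low-vs-high model M_LH, and the patient
   models M_BCR (biochemical recurrence) and M_OPR (overall risk) which
   consume the triplet (PSA, enumerated clinical stage, CLH). The
   classifier is a mixed ensemble of nine random forests; label =
   majority vote, certainty score = fraction of positive member votes.
   CLH is the lesion-volume-weighted mean of the fold-specific M_LH
   scores of a patient's lesions:

       CLH = Σ_i M_LH(i) · v_i / V,  V = Σ_i v_i .

   Because lesion volume is uninformative for the lesion label (AUC
   ≈ 0.5 by construction in the generator, and verified on the whole
   dataset), volume acts as a pure weighting factor.
5. **Controls and evaluation.** Sham arms repeat each model with labels
   randomly permuted per fold; a D'Amico-style clinical-standard
   comparator (maximum filter over pre-binned PSA / biopsy Gleason /
   clinical T stage) is evaluated on the whole dataset. Metrics are
   confusion analytics and Mann–Whitney AUC pooled over all fold
   validation predictions (per-fold averaging available).

## Kriging resampling

Resampling uses kriging on the source voxel lattice: an isotropic
variogram (spherical by default, range 3 source voxels, nugget 0) over
a local 4×4×4 neighbourhood. Because both lattices are regular, the
kriging system only needs to be solved once per unique fractional
offset of a target point inside a source cell; the per-voxel work is a
64-point weighted gather, so a 32³ volume resamples in well under a
second. Ordinary kriging (constant drift) reproduces constant fields
exactly and is an exact interpolator at lattice points. A first-order
drift basis ("linear-compatible" mode) is available and reproduces
affine intensity fields exactly; plain ordinary kriging with a
spherical variogram does not (the 1D two-point analysis gives ~0.7%
mid-cell error on a ramp), which is why the affine-exactness test runs
in drift mode. Boundary extension follows the drift model: edge
replication for constant drift, odd (linear) reflection for linear
drift. A trilinear interpolator is available as a fast fallback, and
masks are always carried by nearest-neighbour resampling.

## Feature registry

The exact 442-feature composition is pinned by this package (the count
and the IBSI strong-consensus constraint are fixed; the breakdown is a
design choice, user-overridable and versioned in `registry.json`):
144 features per modality × 3 modalities + 10 morphology features.
Numerical conventions:

- Fixed-bin-number discretization, 32 bins for all modalities
  (configurable). PET is normalized before discretization, so fixed
  bin number operates on a ratio scale.
- GLCM: symmetric co-occurrence counts merged over the 13 unique 3D
  directions, Chebyshev distances 1 and 2; Ng in normalized inverse
  difference formulas is the bin count. Information correlation 1 is
  (HXY − HXY1)/HX, defined as 0 on a single grey level.
- GLDZM: zone distance is the minimum Chebyshev distance of a zone
  voxel to the mask border (array edges count as border), ≥ 1.
- NGTDM coarseness on a homogeneous region (zero denominator) is
  capped at 10^6.
- SUV_peak uses a 1 cm³ sphere (radius ≈ 6.2 mm, PERCIST-style) on the
  voxel lattice; near the volume edge the mean runs over the available
  in-sphere voxels.
- Undefined values (coefficient of variation at zero mean, GLCM
  correlation on constant regions) are imputed as 0 with a warning, so
  vectors are always finite.

Texture features are computed on the bounding box of the mask; all
families only reference in-mask voxels, so this is exact.

## Redundancy reduction and ranking

The elimination order for correlated pairs is not canonical; the
package visits features by descending variance (ties by name) and
retains a feature iff |r| ≤ 0.75 against all retained predecessors.
This makes the retained set deterministic and reproducible. The
reduction is computed once on the full lesion cohort, before
cross-validation — faithful to the workflow it implements, and noted
here as a mild information-leak caveat (it sees all lesions' features,
never their labels' relation to the held-out evaluation directly).
R² ranking for the binary label is the squared point-biserial
correlation, equivalent to univariate OLS R².

## Ensemble and imbalance correction

The nine members are random forests over a grid of {25, 50, 100} trees
× depth {4, 8, unlimited}, with alternating feature-subsampling
(`sqrt` vs all) and minimum-leaf (1 vs 2) settings; all nine are
re-seeded per fold from the master seed. With training sets of ~50–120
rows and 3–5 features, forests of this size are saturated — larger
grids change nothing but runtime. The grid is fully user-overridable.
The ensemble certainty score defaults to the fraction of positive hard
votes (a 9-step score in [0, 1]); probability averaging is a config
switch. With nine binary voters no tie is possible.

SMOTE (convex interpolation between a minority sample and one of its
k ≤ 5 nearest minority neighbours, k capped at minority size − 1) is
applied to the patient-model training sets only — never to lesion
training and never to validation data. A fold whose training minority
is a single patient trains unbalanced, since interpolation is
undefined there.

## Synthetic cohort: what it emulates

The generator reproduces the statistical skeleton of a ~52-patient
radical-prostatectomy PET/MRI cohort: 1–4 lesions per patient (~120
lesions), balanced low/high pathology patterns (Gleason ≥ 4 vs Gleason
3 / PIN / prostatitis / BPH in realistic proportions), PSA log-normal
around 7.5 ng/ml, stages dominated by T2/T3a/T3b, BCR prevalence ~25%
among ~70% known labels, OPR ~45%. Lesions are smooth ellipsoidal
uptake blobs with a Gaussian radial profile; high-risk lesions have
higher mean PET amplitude (6.5 vs 4.0 above background) and stronger
correlated texture noise (2.0 vs 0.5), and lower, more dispersed ADC
(750/450 vs 1200/250 mean/IQR) — so PET intensity/heterogeneity and
ADC spread genuinely separate the classes while lesion geometry (and
hence volume) is sampled identically for both classes. The BCR label
follows a clipped linear probability model on (high-risk volume
burden, centred log PSA, stage), and the post-operative PSA follow-up
series (8 visits) is constructed so that the two-consecutive-values
> 0.2 ng/ml rule reproduces the sampled label exactly. Label
missingness (default 31% BCR, 4% OPR) is completely at random.

Deliberately **not** modelled: prostate anatomy, scanner point-spread
functions, inter-modality misregistration (all modalities share one
grid), dual-tracer contamination, informative missingness, and
between-scanner batch effects. Consequently, passing tests demonstrate
that the pipeline recovers planted structure and that its controls
recover chance — not that the real-data effect sizes would be
reproduced.

## Validation scales and determinism

The acceptance-level checks run a 50-patient, ~110-lesion cohort on
32³ voxel grids with 200 Monte Carlo folds — large enough that pooled
sham AUCs concentrate near 0.5 (≈ ±0.03) while a full run stays in the
minutes range on a single CPU. Structural contracts (fold uniqueness,
no patient leakage, SMOTE balance, CLH convexity) are checked at the
full 1000-fold / 52-patient scale, which is cheap. One master seed
fans out through named `SeedSequence` substreams (cohort, folds,
per-fold member seeds, sham permutations, SMOTE), making every run —
including the sham arms — bit-reproducible.

## Known limitations

- The kriging neighbourhood is fixed (4³) and the variogram is not
  estimated from the data; for strongly anisotropic spacings an
  index-space isotropic variogram is an approximation.
- Redundancy reduction on the full cohort precedes cross-validation
  (see above).
- The clinical-standard comparator's binarization (high → positive by
  default) is one of two defensible mappings; both are reported.
- Morphology features are voxel-based (no surface mesh); sphericity
  and surface area carry the usual voxelization bias on small lesions.
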