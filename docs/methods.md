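# Methods

This note documents the statistical model behind `socpd`, the design of
the synthetic-cohort generator it is validated against, and the
numerical choices that matter for reproducibility.

## 1. Phenotype model

### SOC classification

Subjects are classified at each visit against a healthy-control (HC)
reference distribution:

- **body-first** if RBDSQ ≥ HC mean + 1 SD **or** SCOPA-AUT ≥ HC mean
  + 1 SD (equality counts as exceeding);
- **brain-first** otherwise;
- **unclassifiable** if either score is missing.

The threshold multiplier (default 1.0 SD) is a parameter of
`classify_soc`. An *autonomic-only* sensitivity mode ignores RBDSQ and
uses only SCOPA-AUT, modelling settings where sleep questionnaires are
unavailable.

Two comparator systems are implemented for the stability analysis:
a motor subtype (tremor-dominant vs postural-instability/gait, with an
indeterminate band for ratios between 0.9 and 1.15) and a cognitive
staging (MCI if ≥ 2 of 5 cognitive tests fall at or below HC mean −
1.5 SD; dementia if additionally MoCA < 21). Reclassification
stability is the percentage of baseline-classified subjects carrying a
*less severe* label at a later visit; unclassifiable visits are
excluded from the denominator.

### Boundary handling

Threshold comparisons are evaluated on the **score scale**
(`score ≥ mean + k·sd`, `score ≤ mean − z·sd`) rather than by dividing
through to a z-score first. Division can move an exactly-at-threshold
value to the wrong side of the cut (e.g. `(mean − 1.5·sd − mean)/sd`
evaluating to −1.4999999999999996), so subjects constructed exactly at
a boundary classify deterministically. A zero-variance reference
raises explicitly instead of propagating ±inf.

## 2. Locus-coeruleus gradient mapping

Connectopic mapping proceeds in four steps:

1. **Similarity.** Between LC voxels i and j, similarity is one minus
   the eta-squared distance of their connectivity fingerprints:
   η²(a, b) computed from the per-position means and the grand mean,
   so η² = 1 for identical (or affinely-offset-free identical)
   profiles. The similarity matrix is symmetric with unit diagonal.
2. **Gradient.** The dominant gradient is the Fiedler vector of the
   generalized eigenproblem L v = λ D v for the graph Laplacian
   L = D − W of the similarity graph (a Laplacian eigenmap). We solve
   the symmetrically-normalized standard problem with
   `scipy.linalg.eigh` and transform back; disconnected graphs are
   rejected (Fiedler value ≈ 0). The eigenvector sign is canonicalized
   so the gradient correlates positively with the rostro-caudal voxel
   order, making runs comparable.
3. **Trend surface.** A third-order polynomial in the spatial
   coordinates is fit to the gradient by ridge-regularized least
   squares (a Gaussian prior on the coefficients), giving a smooth,
   invertible spatial model of the gradient.
4. **SMS profile.** Per subject, the similarity-with-middle-section
   statistic for a section is the mean similarity between that
   section's voxels and the middle section's voxels, mapped to [0, 1].
   SMS = 1 exactly when the section's mean fingerprint equals the
   middle section's. Normalized SMS rescales each subject's profile so
   the middle section is 1. Worked example: a five-section gradient
   profile [0.1, 0.3, 0.5, 0.7, 0.9] yields SMS
   [0.6, 0.8, (1.0), 0.8, 0.6] for the non-middle sections.

Group contrasts of section-wise SMS use a percentile bootstrap over
subjects (default 2,000 resamples); the reported p is the two-sided
resampling p-value with the (+1)/(+1) correction, so its floor is
1/(B + 1).

## 3. Imaging indices

- **SBR** = striatal count / occipital count − 1, so SBR(3.0, 1.5) = 1
  by construction.
- **Hemisphere assignment** follows the contralateral rule: the
  hemisphere opposite the clinically more affected body side is the
  *more affected* hemisphere; ties are broken by the lower SBR.
- **DTI-ALPS** = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc);
  equal diffusivities give exactly 1, and (1.2, 1.0, 0.8, 0.6) gives
  11/7. The index is scale-invariant in the diffusivities.

## 4. Longitudinal and survival models

- **Trajectories.** Outcome ~ group + time + group:time (+ covariates)
  with a random intercept per subject (`statsmodels` MixedLM, REML).
  Covariates with zero variance in a cohort (e.g. disease duration in
  a prodromal cohort where everyone is pre-diagnosis) are collinear
  with the intercept; they are dropped with a warning rather than
  letting the fit go singular.
- **Survival.** Cox proportional hazards (`lifelines`), phenotype as
  the exposure, age/sex/education as covariates. The dementia endpoint
  is the first visit with MoCA strictly below 21 (event time = that
  visit's time; censoring at last visit otherwise). A cohort with no
  events yields a "not estimable" row in the pipeline rather than a
  crash.
- **Multiplicity.** Benjamini–Hochberg step-up. The rejection rule is
  evaluated multiplicatively — reject the k smallest p-values where k
  is the largest rank with p·m ≤ k·q — because forming q·k/m first can
  round 0.05·3/3 to 0.050000000000000001 and flip a boundary decision.
  Adjusted p-values use the usual cummin-from-the-top construction.
- **Mediation.** Product-of-coefficients: a from mediator ~ exposure
  (+ covariates), b and direct effect from outcome ~ exposure +
  mediator (+ covariates); indirect = a·b, proportion mediated =
  indirect/total. Inference is a percentile bootstrap over subjects.
  When indirect and direct effects have opposite signs the proportion
  is flagged as not interpretable rather than reported as if it were a
  share of the total.

## 5. Genetics

QC cascade, in order: (1) drop subjects with > 5% missing genotypes;
(2) drop SNPs with call rate < 98%; (3) drop SNPs failing exact
Hardy-Weinberg equilibrium at p < 1e-6 (mid-p-free exact test summing
conditional probabilities of tables at most as probable as the
observed one). The cascade is a fixed composition of row and column
filters, so it is idempotent and its removal counts are exact.

Association per SNP is additive-coded logistic regression of the
phenotype with age/sex covariates. Family-wise inference uses a
permutation FDR: phenotype labels are permuted (covariates kept
attached to subjects), the covariate-adjusted score statistic is
recomputed per SNP, and per-SNP permutation p-values are BH-adjusted.
The permutation p floor is 1/(n_perm + 1); with the default
n_perm = 2,500 the floor (≈ 4.0 × 10⁻⁴) stays below the BH threshold
q/m for panels up to m = 125 SNPs at q = 0.05, so a true signal is
not structurally barred from discovery. Smaller permutation counts are
accepted but can make rejection impossible for large panels.

## 6. Latent phenotyping (VAE)

The variational autoencoder is implemented directly in numpy with
hand-derived backpropagation (encoder 11 → 16 → 4 with tanh
activations, 2 Gaussian latent components, matching decoder, Adam,
learning rate 0.001, batch 40, default 1,000 epochs). Gradients are
verified against central finite differences in the test suite.
Features are z-standardized with the training set's statistics before
encoding. Latent separation between phenotypes is assessed per
component with Welch's t-test. The numpy implementation keeps the
package dependency-light and bit-reproducible across runs with the
same seed.

## 7. Synthetic-cohort generator

The generator is the package's ground truth; every estimator is tested
by recovering what was planted.

- **Structure.** An HC reference arm plus prodromal and clinical PD
  arms; each PD subject carries a latent phenotype (body-first or
  brain-first, default 50/50). Questionnaire and cognitive scores are
  drawn from phenotype- and cohort-shifted normals, clipped and
  rounded to instrument ranges. Visits are annual; baseline is never
  dropped, later visits thin with time (attrition).
- **Planted effects.** RBDSQ/SCOPA-AUT elevations in body-first (the
  classification signal, calibrated so one-SD thresholding recovers
  ≥ 90% of latent labels at realistic noise); a conversion hazard
  ratio of 2.0 for body-first prodromal subjects; per-year slope
  differences on the clinical outcomes; a rostro-caudal LC gradient
  whose caudal sections degrade in body-first and rostral in
  brain-first; hemispheric SBR asymmetry concentrated in brain-first;
  lower ALPS in body-first; five causal SNPs with shifted allele
  frequencies in body-first.
- **Realism of cognitive decline.** Clinical-cohort MoCA starts
  ≈ 1.5 points below the prodromal mean and declines at −0.4/yr
  baseline with an extra −0.4/yr in body-first, so the MoCA < 21
  dementia endpoint actually accrues events within a five-year window.
  A consequence reported honestly in the worked example: dementia is
  nearly exclusive to body-first, so its hazard ratio is large with a
  very wide confidence interval.
- **Sizes.** Default cohort sizes (263 HC / 500 prodromal / 500
  clinical) and replication counts (2,000 bootstrap, 2,500
  permutations) are the package's own choices, sized so the full
  pipeline and test suite run comfortably on a laptop while keeping
  Monte Carlo error well inside the stated tolerances.

## 8. Reproducibility

All randomness in a run descends from one master seed through
`numpy.random.SeedSequence` with per-module spawn keys; derived seeds
are reduced modulo 2³¹ so they remain valid for any 32-bit consumer.
The pipeline writes a manifest with the per-module seeds, a hash of
the configuration (excluding the output directory, so the same
analysis in two locations hashes identically), and SHA-256 checksums
of every output file. Two runs with the same seed are byte-identical;
this is asserted in the acceptance suite.

## 9. Limitations

- The generator draws from clipped/rounded normals; real instrument
  distributions are skewed and zero-inflated, so absolute score
  distributions should not be over-interpreted.
- The LC "connectivity" fixtures are low-dimensional stand-ins for
  voxel-wise fMRI fingerprints; the gradient machinery is exact, but
  the spatial realism is schematic.
- Mediation in the default pipeline is essentially null by
  construction (the generator does not route motor severity through
  ALPS), which is why the worked pipeline flags its proportion as not
  interpretable; the estimator itself is validated on a dedicated
  construct with a planted 15% proportion.
- The mixed model uses a random intercept only; random slopes would be
  natural for richer visit schedules.
- The VAE is intentionally small; it is a latent-phenotyping
  demonstration, not a tuned representation learner.
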