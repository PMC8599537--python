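# Methods

`methclock` re-creates, as tested library code, the analysis pipeline of a
small-primate epigenetic-clock study: penalized-regression age clocks on
methylation-array beta values, unbiased cross-validated evaluation,
cross-species clock transfer, per-CpG association screens with meta-analysis,
an intervention regression on DNAm age, and a sex classifier scored
out-of-bag.  Because the kind of cohort it targets is typically not publicly
deposited, the package also contains a synthetic-data generator whose stated
world mirrors the study design, so that every stage can be exercised and
checked against known truth.

## Clocks

A clock is an elastic-net linear regression of transformed age on CpG beta
values,

    F(age) ≈ b0 + Σ_j w_j · beta_j ,

with the L1/L2 mixing fraction fixed at α = 0.5 (the ridge/lasso midpoint; it
is a convention of this literature, not tuned).  The penalty strength is
selected by tenfold internal cross-validation over a descending log-spaced
path of 60 values, minimising internal-CV MSE; among exact ties the larger
penalty (sparser model) wins because the path is scanned largest-first.
Predictors are standardised internally and weights are reported back on the
original beta scale, so a stored model is a plain intercept + sparse weight
vector.  Numerical settings: coordinate-descent tolerance 1e-4, max 2,000
iterations.  The tolerance is deliberately modest — at 1e-6 a pure-noise fit
costs ~13 s instead of ~1.6 s, and leave-one-out evaluation refits the model
once per sample; all reproducibility contracts compare like with like and are
unaffected.

Age transforms (all invertible, all strictly increasing):

* **identity** — single-species clocks regress directly on years.
* **log-linear** — `F(a) = log((a+c)/(m+c))` below an adult-age knot `m`,
  `(a−m)/(m+c)` above it, continuous with matching slope; offset `c = 1 y`.
  The knot may be per-species (defaults: marmoset 2 y, human 15 y) or one
  shared scalar.  The *dual-species chronological clock* uses a single shared
  knot (default 5 y): it is the "single formula" construction — it carries no
  species parameters, which is what lets it be applied unchanged to a species
  it has never seen, and also what leaves it poorly calibrated there.
  A deliberate design point found during development: if the knot is instead
  made per-species and roughly proportional to maturity (2 y vs 15 y), the
  "chronological" transform becomes a near-reparameterisation of relative age
  and the two dual clocks are rank-equivalent on a held-out species — the
  comparison between them then measures nothing.
* **relative age** — `age / maxLifespan`, the map that places species of very
  different longevity on a common [0, 1] scale.  Defaults are the recorded
  maxima 22.8 y (marmoset) and 122.5 y (human).  Neither direction clips at
  1: an animal may outlive its species' recorded maximum and a clock may
  predict beyond it; clipping would bias the error statistics.

Evaluation is leave-one-out or species-stratified k-fold cross-validation.
The penalty is re-selected inside every outer fold; nothing from the held-out
sample touches the model that predicts it.  Accuracy is reported as the
Pearson correlation R between DNAm age and chronological age plus the median
absolute error in years, overall and per stratum.  At prediction time a model
CpG missing from the input matrix is imputed with its training mean; above
20 % missing the prediction refuses to run rather than extrapolate silently.

## EWAS

The age screen computes a per-CpG Pearson correlation r, the exact
`t = r·sqrt(n−2)/sqrt(1−r²)` reference with n−2 degrees of freedom, and a
signed normal-scale score `z = sign(r)·Φ⁻¹(1−p/2)`.  Group contrasts
(treatment vs control, female vs male) use per-CpG OLS of beta on
[intercept, group, covariates] — chronological age as covariate in both
study uses; treated animals are excluded from the sex contrast.  Putting z
on the normal scale (rather than carrying the raw t) is what makes strata
with different degrees of freedom combinable by Stouffer's rule

    Z = Σ w_i z_i / sqrt(Σ w_i²),

with weights √n_i per stratum (equal weights available).  A CpG missing a
stratum drops that stratum with weight renormalisation.  Constant probes are
flagged (p = 1, z = 0) rather than propagating NaN.

Top-CpG selection follows the field's reporting rule exactly: strict p < 0.005, then
at most 500 per direction of z ranked by |z|, ties broken by CpG identifier
so the output is independent of row order.  No genome-wide correction is
applied by default (the analyses this mirrors report raw-p thresholds); a
Bonferroni column is emitted for reference.  Genic-region summaries report
foreground/background counts per region class with hypergeometric tail
p-values — the enrichment p is the upper tail P(X ≥ k), the depletion p the
lower tail, reported separately rather than folded into one two-sided value.
Overlap between hit sets is counted upset-style (exclusive intersections
summing to the union).

## Intervention and sex analyses

The treatment test is OLS of

    DNAmAge ~ intercept + Age + Female + Rapamycin

on test-cohort animals, with DNAm age produced by a clock trained on a
disjoint training cohort; a sample-id intersection check makes leakage a hard
error, because any overlap biases the treatment term toward the training
residuals.  Female and Rapamycin are 1/0 indicators.  Age acceleration —
residuals of DNAmAge on age — is computed separately; the regression above is
the primary form, acceleration the secondary view.

The sex predictor is a 500-tree random forest (√p features per split,
unlimited depth — the standard classification defaults), scored out-of-bag:
each sample is classified by the trees that did not see it in their
bootstrap.  A caveat worth knowing: at small n, OOB majority-vote accuracy is
pessimistically biased.  Conditioning on a sample being out-of-bag depletes
its own class in that tree's bootstrap (29/59 same-class at n = 60 balanced),
and majority voting over ~180 OOB trees amplifies the per-tree deficit; with
no sex signal at all, accuracy centres near 0.42 rather than 0.50 (observed
0.28–0.60 over ten seeds).  Per-bootstrap class reweighting does not remove
the effect.  The estimator is kept in its standard form and the bias is
documented instead, since the same bias affects the field's usual tooling.

## The synthetic world

The generator emulates a conserved-CpG methylation array study at desk scale.
Defaults are the stated design, scaled down: 2,000 probes (study: 37,492);
60 marmoset-like blood samples aged 0.5–15.5 y plus 40 human-like samples
(maxLifespan 122.5 y) spanning the same relative-age range (2.7–83.3 y,
i.e. the marmoset range scaled by 122.5/22.8); 20 age CpGs with linear
trajectories in *relative* age (slope amplitude 0.4 on the beta scale, 70 %
gaining methylation with age, mirroring promoter-dominated hypermethylation);
10 weak sex-offset CpGs (amplitude 0.05 — blood from a hematopoietic chimera
carries little usable sex signal); 10 treatment CpGs whose default amplitude
is zero (a null intervention, the study's finding); all remaining probes
null.  Because age CpGs depend on age only through relative age, the shared
signal across species lives on the relative-age scale by construction.

Noise is Beta(mean·φ, (1−mean)·φ) per probe and sample with precision
φ = 100 — mean-preserving, variance mean(1−mean)/(φ+1), and it respects the
[0, 1] support of beta values, which Gaussian noise would not.  Trajectory
means are clipped to [0.01, 0.99] to keep the Beta parameters finite.  Ages
are uniform over each species' range (the study reports only mean/min/max).
Baselines are uniform with headroom for the full signal excursion, so no
age trajectory is silently flattened by clipping.

The first species is split into a training cohort (60 %, full age range) and
an older test cohort (40 %, ages 5.5–13.5 y) carrying the treated/control
arms (treated fraction 0.46) — mirroring an intervention cohort of
middle-aged animals on top of a full-lifespan training set.  Everything is
deterministic from (config, seed).

What the generator does **not** model: raw intensities and normalisation,
batch/plate effects, outliers, probe-species coverage maps, species-specific
baseline offsets, tissue heterogeneity, and nonlinear (saturating)
trajectories.  A green test therefore establishes that the statistical
machinery is correct and calibrated on data with the assumed structure — not
that the biological effect sizes of any real cohort will be reproduced.

## Known limitations

* The exact functional form of the "log-linear" transform is a convention of
  this clock literature, not uniquely determined; knot and offset are
  surfaced as parameters and serialised in model provenance.
* With purely linear shared trajectories, the relative-vs-chronological
  transfer comparison is meaningful only against the single-formula
  chronological clock (see above); real data contain additional structure
  (partial probe conservation, tissue effects) that the generator omits.
* The OOB sex-accuracy null band is affected by the estimator bias described
  above; at n = 60 roughly one seed in five falls below 0.35 with no sex
  signal present.
* LOOCV R on data with no age signal is strongly *negative* (≈ −0.5 at
  n = 30), not zero: null fits collapse toward intercept-only models, and the
  held-out prediction — the training mean excluding the sample — is exactly
  anticorrelated with the sample's own age.  This pessimistic small-sample
  artifact is generic to leave-one-out evaluation of mean-reverting
  estimators and disappears as real signal appears.
* The EWAS covariate model is homoscedastic OLS per CpG; beta-value variance
  shrinks near the boundaries, which OLS ignores (as does the reference
  screen it mirrors).
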