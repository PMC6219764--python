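# Methods

`siteshift` studies a failure mode of image classifiers trained on pooled
multi-hospital data: when disease prevalence differs sharply between
contributing sites and images carry site-identifying acquisition
artifacts, a classifier can earn most of its apparent discrimination by
recognising the *site* and applying its prevalence as a prior. Internal
test performance (new data from the training sites) then overstates what
the model knows about the disease; external test performance (a site that
contributed nothing to training) reveals it. The package builds the whole
causal chain synthetically — no patient data — so every link can be
manipulated and measured.

## The synthetic study population

`synthetic.generate_study_set` emulates archived chest radiographs from
several hospital systems at 64 x 64 grayscale resolution. Each site is a
`SiteProfile`:

* **Anatomy.** A fixed frontal silhouette (body ellipse, two darker lung
  fields, a bright mediastinal stripe) or a distinct lateral silhouette,
  plus Gaussian pixel noise (`noise_sd`, default 0.06).
* **Disease signal.** Pneumonia-positive frontal studies receive one soft
  elliptical opacity at a random position inside the lung-field mask,
  with amplitude `effect_size` (default **0.15**). At this amplitude a
  small CNN trained on confound-free data reaches a pneumonia AUC of
  roughly 0.75–0.8 — the difficulty regime of real chest-film pneumonia
  detection — so the shortcut and the genuine signal are of comparable
  value to the model.
* **Acquisition confounds.** A bright corner metal token (blended with
  `max`, so intensity 0 means no token), an edge banner of near-white
  rows with dark text-like dashes, an optional department-conditional
  intensity inversion (`1 - pixel`, the archived-inverted-scanner
  effect), and a global background offset. Tokens and banners sit outside
  the lung fields, so in the default experiment profiles the confounds do
  not share an intensity axis with the disease signal; the background
  offset (used by the audit profiles) deliberately does spread a site
  signature over every subregion.
* **Prevalence.** Per site, the number of pneumonia-positive *studies* is
  exactly `round(prevalence × n_studies)` (half-to-even) — an exact-count
  design rather than Bernoulli draws, so samplers and tests are
  deterministic. Positives are split between the sexes so each sex's
  prevalence matches the site's to within one study.
* **Disease persistence.** Positive studies cluster within patients:
  after a patient's first positive study each further study is positive
  with probability `disease_persistence` (default 0.6). This emulates
  disease episodes spanning several exams, concentrates the learnable
  signal, and is precisely why splitting must happen at patient level.
* **Patients.** Studies per patient follow a truncated geometric
  distribution (mean 3.5, maximum 10), matching the several-studies-per-
  patient regime of public chest-radiograph archives; sex and age come
  from per-site marginals. All randomness descends from one seed through
  `numpy` `SeedSequence` spawning, so a (config, profiles, seed) triple
  reproduces the study set bit for bit.
* **Reports.** Templated English sentences assert each positive finding
  with lexical variants (hernia-positive reports always contain the token
  "hernia"), explicitly negate a random subset of negative findings
  ("no …", "without …", "… has resolved"), and never assert an absent
  finding without a negation cue.

What the generator does *not* emulate: anatomical variation between
patients, reader disagreement and label noise, continuous disease
severity, realistic image texture, or more than one confound family per
site. Passing tests therefore demonstrate the *mechanism* — prevalence
shortcuts inflate internal performance — under clean conditions; they do
not quantify its size on real archives.

## Cohorts

`split_by_patient` assigns 70/10/20 train/tune/test fractions at patient
(or accession-group) granularity with largest-remainder rounding. An
optional stratified mode allocates within (site × patient-level disease)
strata so that, at desk scale, a rare-disease site still lands positives
in every split; the experiment orchestrators use it.

`engineer_prevalence_cohort` subsamples two source sites to an
`EngineeredCohortSpec`: per site, exactly `round(prevalence × n)` positive
patients (patient-level status = any positive study), split evenly
between the sexes, sampled without replacement. The five standard designs
hold overall prevalence at 5% while moving the between-site split from
9.9%/0.1% through 5%/5% to 0.1%/9.9%. Sampled patients keep their prior
split membership; when a split assignment is supplied, each stratum quota
is spread across train/tune/test proportionally to the source pool
(largest remainder, capacity-capped), so cohort splits mirror the pool's
without re-splitting anyone. Sex balancing is done within site (a flag
disables it), the stricter reading of equal-prevalence-by-sex.

## Report labeling

`labeling` lowercases, tokenizes on non-alphanumeric boundaries, and
counts unigrams and bigrams (counts, not binary presence). A Lasso
logistic regression (liblinear) is fitted with the penalty chosen by
cross-validated log-loss on a working split; held-out AUC, sensitivity
and specificity at the 0.5 threshold are recorded before refitting on the
full corpus. Negation is not modelled explicitly — bigrams such as
"no pneumonia" must carry it. Hernia uses a whole-token keyword rule
(case-insensitive "hernia"), which by construction never misses a true
positive and errs only on negated mentions.

## The classifier

`nn.SmallCAMNet` is a deliberately small from-scratch CNN: three
conv(3x3)–batchnorm–ReLU–maxpool blocks and a fourth conv–batchnorm–ReLU
layer produce a K=32-channel 8 x 8 feature grid; global average pooling,
a *linear* bottleneck (n = 15) and a linear task head (per-output sigmoid
for the nine-finding multilabel task, softmax for site/department/view
classification) follow. Batch normalization is what lets a from-scratch
net converge within the few productive epochs the aggressive schedule
allows. Keeping the two post-pool layers linear means they compose into a
single effective read-out `B = W_head W_bottleneck`, which is what makes
the activation maps exact (below). The architecture stands in for a
large pretrained network: the study's claims concern data and confounds,
not architecture.

Training is SGD with momentum 0.9, weight decay 1e-4, initial learning
rate 0.01, batch size 16, cross-entropy loss. "Improvement" is a strict
decrease of tune loss versus the best so far; after each non-improving
epoch the learning rate is divided by 10, training halts after three
consecutive non-improving epochs (with a 30-epoch safety cap), and the
best-tune-loss parameters are retained. `PlateauSchedule` implements the
policy as a standalone object so it can be property-tested on arbitrary
loss sequences. Everything is float32 NumPy (im2col convolutions over
BLAS); a NaN loss aborts with a diagnostic.

`view_filter` trains the same architecture as a binary frontal/lateral
classifier on a labeled subset (default 200/100/102 train/tune/test),
reports held-out view accuracy, and filters the remainder to
predicted-frontal images.

## Activation maps

For a g x g final feature grid X and effective class read-out (B, B0),
the subregion score of class c at cell (i, j) is
`Y[c,i,j] = Σ_k B[c,k] X[k,i,j] + B0[c]`; its spatial average equals the
model's own logit to 1e-5 (a tested identity). Cellwise softmax over
classes gives a per-subregion class probability; a cell is *decisive* at
threshold τ (default 0.95, inclusive) if its target-class probability
reaches τ. The influence heatmap is the target score minus the sum of all
competing class scores, mean-centred (so it always sums to zero); for
more than three classes this generalises the three-class difference
formula. Localization is scored with one grid cell of tolerance: after
four 3x3 convolutions and three poolings a final-grid cell's receptive
field extends well into its neighbours, so the peak response to a corner
token may sit one cell inward. Per-image probability maps are computed
first and aggregated afterwards (the alternative — averaging maps before
thresholding — would count borderline cells differently).

At desk scale the decisive-subregion *fraction* is reported but its
magnitude is not treated as a reproduction target: how many cells
individually exceed 95% certainty depends on the trained model's logit
scale, which grows with training-set size and is far larger for archive-
scale models than for these small runs.

## Evaluation statistics

* **AUC** is the Mann-Whitney estimator (ties one half) via midranks;
  its variance comes from DeLong structural components (placement values,
  sample covariance with ddof 1); the 95% CI is a normal approximation on
  the AUC scale clipped to [0, 1].
* **DeLong tests**: paired (shared cases, covariance of placements) and
  unpaired (variance additivity); two-sided normal p. Degenerate variance
  with identical rankings returns p = 1 with a warning. The paired
  variance is algebraically identical to a class-grouped leave-one-out
  jackknife of ΔAUC, which the tests exploit as an independent oracle.
* **Clopper-Pearson** intervals from beta quantiles, exact at the
  boundaries (0 at 0 successes, 1 at n of n).
* **χ² tests** of proportions without continuity correction (a flag
  restores it), df = m − 1.
* **Screening operating point**: the threshold is the
  `ceil(target × n_pos)`-th largest positive score and ties classify
  positive, so achieved sensitivity is never below the target (with 39
  positives and a 95% target: 38/39 = 0.974). All six reported rates
  carry Clopper-Pearson intervals.
* **Trivial prevalence ranker**: every case scores its site's training
  prevalence. Its AUC has a closed form for a two-valued score —
  `pos_hi·neg_lo + ½(pos_hi·neg_hi + pos_lo·neg_lo)` — used both as a
  baseline and as a test oracle.
* **Calibration**: observed outcomes are logistically regressed on the
  logit of predicted probability (slope 1 = well calibrated; the paperless
  choice here is the standard logistic-recalibration slope). Probabilities
  are clamped away from {0, 1} with a warning; constant probability
  vectors are flagged degenerate rather than fitted.

## The three studies and their problem sizes

All phenomenon-level claims are replicated over five seeds and tested
with one-sided paired t-tests at α = 0.05, because single-run CNN AUCs
are noisy at these sizes. The preset scales (module `presets`) are the
package's replication conditions on a single CPU:

1. **Site generalization** (`run_site_generalization`): three sites at
   the natural prevalence regime (34.2%, 1.2%, 1.0%), with site sizes
   proportioned like the real systems (the rare-disease site largest:
   120/600/150 patients). The jointly trained model's pooled-test AUC
   exceeds both single-site subset AUCs, and the trivial prevalence
   ranker alone scores ≈ 0.85 on the pooled test — the signature of a
   prevalence shortcut. The tiny external site in this configuration has
   too few positives for a stable external AUC; external claims are
   tested in the engineered study, whose external site is adequately
   powered.
2. **Site detection + CAM audit** (`run_site_detection`): a multiclass
   site classifier on audit profiles (tokens, banners, and global
   background offsets). With confounds on, held-out accuracy reaches
   ≥ 99%; with confounds off and equal prevalence it is statistically
   indistinguishable from the majority rate (binomial test, α = 0.01).
   A token-only two-site configuration verifies that influence heatmaps
   localize the injected token in ≥ 90% of images.
3. **Engineered relative risk** (`run_engineered_prevalence`): source
   pools of 600 patients per internal site at 10% prevalence, cohorts of
   300 patients per site (the full design uses 10,000), external site at
   the 5% overall target. Severe imbalance (9.9%/0.1%) raises internal
   AUC well above the balanced (5%/5%) cohort's, while external AUC shows
   no corresponding gain.

## Known limitations

* The CNN is orders of magnitude smaller than production architectures
  and sees orders of magnitude less data; absolute AUCs are not
  comparable to archive-scale results, only the internal/external
  orderings are.
* Patient-level disease status for cohort sampling is "any positive
  study", so engineered cohort prevalences are patient-level; study-level
  prevalence in a sampled cohort is diluted by each positive patient's
  negative studies.
* The aggressive plateau schedule occasionally freezes a small run in a
  poor state; replicate seeds and the paired tests absorb this.
* The labeler's negation handling is purely bigram-based; longer-range
  negation scopes ("no evidence of focal consolidation or pneumonia")
  would defeat it, as they would the approach it models.
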