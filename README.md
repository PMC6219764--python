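# siteshift

**When a chest-radiograph classifier is trained on data pooled from
hospitals with very different disease rates, how much of its measured
performance is medicine, and how much is it recognising the hospital?**

`siteshift` is a fully synthetic, end-to-end replication harness for that
question, aimed at researchers studying dataset shift and confounding in
medical image classifiers. It contains no patient data: a generator
produces multi-site chest-radiograph-like study sets in which both the
disease signal and the site-identifying acquisition artifacts (corner
metal tokens, text banners, inverted colour schemes, background offsets)
are injected by design, so the causal chain — *site artifacts + site
prevalence gap → shortcut learning → inflated internal but not external
performance* — can be switched on and off and measured.

## The core quantities

For a case with score *s* and binary label *y*, discrimination is the
area under the ROC curve, estimated by the Mann–Whitney statistic
(ties count ½) with DeLong structural-component variance; two models are
compared with paired or unpaired DeLong tests. Proportions carry exact
Clopper–Pearson intervals; screening metrics are reported at the
threshold guaranteeing sensitivity ≥ 0.95 (the `ceil(0.95·n₊)`-th largest
positive score). A *trivial prevalence ranker* scores every case with its
site's training prevalence; for a two-site test set its AUC has the
closed form

    AUC = p₊ᴴ(1−p₋ᴴ) + ½[p₊ᴴp₋ᴴ + (1−p₊ᴴ)(1−p₋ᴴ)]

where p₊ᴴ (p₋ᴴ) is the fraction of positives (negatives) from the
high-prevalence site — the yardstick for how far site membership alone
carries a pooled evaluation.

The classifier is a small from-scratch CNN (conv–batchnorm–ReLU–pool
blocks to an 8×8×32 feature grid, global average pooling, a linear n=15
bottleneck and a linear head) trained by SGD (lr 0.01, momentum 0.9,
weight decay 1e-4) with ×10 learning-rate decay on each tune-loss plateau
and early stopping after three stagnant epochs. Because everything after
the pooling is linear, applying the effective class read-out (B, B₀) to
each grid cell gives an exact class activation map

    Y[c,i,j] = Σₖ B[c,k]·X[k,i,j] + B₀[c]

whose spatial mean equals the model's own logit; cellwise softmax over
classes yields per-subregion class probabilities, from which decisive
subregions (probability ≥ 0.95) are counted and influence heatmaps
(target minus competing scores, mean-centred) are drawn.

## Worked example

Train models on two engineered cohorts that differ *only* in how a fixed
5% overall pneumonia prevalence is split between two hospital systems —
balanced (5%/5%) versus severely imbalanced (9.9%/0.1%) — and evaluate
each on an internal pooled test set and an external third site:

```python
from siteshift import presets
from siteshift.experiments import run_engineered_prevalence

config = presets.engineered_config(seed=0)
result = run_engineered_prevalence(
    config, seed=0, specs=presets.engineered_specs(("balanced", "a_severe"))
)
print(result["table"][["cohort", "internal_auc", "external_auc"]].round(3))
```

```
     cohort  internal_auc  external_auc
0  a_severe         0.832         0.694
1  balanced         0.660         0.965
```

The imbalanced cohort's model looks much stronger on internal pooled
testing (0.832 vs 0.660) — but the gain is the site shortcut, not better
medicine: on the external site, which the shortcut cannot reach, it has
no advantage at all. Across five replicate seeds the internal gain is
statistically significant while the external comparison is not, the
package's scaled-down analogue of the engineered-relative-risk result.
(Single-seed AUCs at this cohort size are noisy — the external columns
above differ by luck of a ~150-image test set; the replicated tests are
the claim.)

## Layout

| Module | Contents |
| --- | --- |
| `siteshift.synthetic` | site profiles, image rendering, exact-count label assignment, report templates, PNG/CSV/JSONL output |
| `siteshift.cohorts` | patient-level 70/10/20 splits, engineered-prevalence cohort sampler, the five standard designs |
| `siteshift.labeling` | 1-/2-gram bag-of-words Lasso labeler, hernia keyword rule |
| `siteshift.nn`, `siteshift.modeling` | the small CAM-compatible CNN, plateau-decay training schedule, view filter |
| `siteshift.interpret` | subregion score/probability maps, decisive counts, influence heatmaps |
| `siteshift.stats` | AUC + DeLong inference, Clopper–Pearson, χ², operating points, trivial ranker, calibration |
| `siteshift.experiments`, `siteshift.presets` | the three study orchestrators, YAML config, desk-scale presets |
| `siteshift.cli` | `siteshift generate / label / train / evaluate / cam / experiment` |

`docs/methods.md` documents the model, its assumptions, every tunable
parameter with its default and rationale, and what the synthetic design
does and does not show about real data.
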