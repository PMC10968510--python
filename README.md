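# noisematch

Synthetic, noise-calibrated DOTATATE-PET liver cohorts and a complete
lesion-detection generalizability study: train a deep detector on
low-noise reconstructions, test it on a noisier out-of-domain cohort,
and measure whether *noise-matched* training data closes the domain
gap.

## The problem

Deep lesion detectors for somatostatin-receptor PET (GEP-NET imaging)
degrade when deployed on scanners whose images are noisier than the
training data.  Modern scanners store list-mode data, so the *same*
acquisitions (and their expensive lesion annotations) can be
re-reconstructed at shorter effective scan times, raising background
noise to match an out-of-domain target — a cheap alternative to
annotating new cohorts.  This package reproduces that experimental
design end to end on synthetic phantoms whose background noise is
calibrated to specified levels, so every claim in the pipeline is
testable on a desk.

The noise metric is the background coefficient of variation of SUV in
a normal-liver ROI,

```
COV = SD(SUV_ROI) / mean(SUV_ROI),
```

with per-reconstruction targets 0.091 / 0.098 / 0.102 / 0.110 / 0.121
(low-noise cohort: Q.Clear-like plus 5/4/3/2-minute list-mode
reconstructions) and 0.198 (high-noise out-of-domain cohort).  Gold
lesions follow the modified PERCIST rule

```
threshold = 1.5 * SUVmean + 2 * SD   (normal liver background),
```

the detector is a four-residual-block encoder-decoder with two
transposed-convolution upsamplers trained with a BCE + Dice loss
(implemented in pure NumPy with hand-derived gradients), predictions
are binarized at logit 0 and filtered at 20 pixels, and scoring is
lesion-level: Hungarian matching on IoU with the IoU > 0 rule, then

```
PPV = TP/(TP+FP),  sensitivity = TP/(TP+FN),
F1  = 2*PPV*sensitivity/(PPV+sensitivity).
```

See `docs/methods.md` for the full model description and the
package's design choices.

## Worked example

```python
import numpy as np
from noisematch import (
    CohortSpec, NetworkConfig, TrainConfig,
    generate_cohort, noise_sweep,
)

set1 = generate_cohort(CohortSpec.set1_desk())   # 66 subjects x 5 profiles
set2 = generate_cohort(CohortSpec.set2_desk())   # 66 noisier subjects
res = noise_sweep(
    set1, set2,
    net_cfg=NetworkConfig(base_channels=8),
    train_cfg=TrainConfig(max_epochs=12, early_stop_patience=6),
)
print(res.table[["condition", "f1_mean", "f1_sd"]].to_string(index=False))
```

prints (5 seeded runs per condition, scored on the identical
out-of-domain test subjects):

```
              condition  f1_mean    f1_sd
            Set1-QClear 0.828662 0.015574
        Set1-VPFXS-5min 0.814545 0.008131
        Set1-VPFXS-4min 0.825129 0.015990
        Set1-VPFXS-3min 0.825237 0.009661
        Set1-VPFXS-2min 0.825237 0.009661
Set2-OSEM (upper bound) 0.791569 0.038990
```

Reading the table: each row is one training condition — a
reconstruction profile of the low-noise cohort, or the in-domain
upper bound trained on the noisy cohort itself — scored on the same
held-out noisy test subjects.  On these phantoms the conditions land
within a few F1 points of each other: with a homogeneous liver
background and lesions that are annotatable by construction, a
converged detector is largely robust across this noise ladder, so the
clinical-scale domain-shift effect is only marginally expressed at
phantom scale (`docs/methods.md` discusses exactly what the phantoms
do and do not emulate, and why).  The same `ExperimentResult` carries
per-run metrics and pairwise Welch p-values (`res.per_run`,
`res.pvalues`), and `sample_size_sweep` runs the companion experiment
(nested 25/50/75/100% training subsets).

A `noisematch` command-line tool exposes the stages individually
(`simulate`, `annotate`, `cov`, `train`, `predict`, `evaluate`,
`sweep`), each writing a JSON run manifest next to its outputs; images
and masks travel as NIfTI, tables as CSV.

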