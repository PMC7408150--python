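# gliomap

Multi-site MRI harmonization and molecular-subtype classification for
low grade gliomas (LGG), with a synthetic phantom cohort generator so
the whole pipeline runs and is tested without clinical data.

## The problem

LGGs are classified by molecular markers — 1p/19q codeletion and IDH
mutation status — that strongly affect prognosis, but determining them
requires tissue. Predicting them from preoperative MRI is attractive,
yet single-hospital cohorts are small, and naively pooling scans from
different sites fails because each scanner imposes its own intensity
distribution, resolution and noise. `gliomap` implements a pipeline
that makes multi-site data usable:

1. **Domain mapping** — an unpaired CycleGAN learns G_B: A→B and
   G_A: B→A between two scanner domains by minimizing

   L = L_GAN(G_B, D_B, A, B) + L_GAN(G_A, D_A, B, A) + λ·L_cyc(G_A, G_B)

   with least-squares adversarial terms and an L1 cycle-consistency
   penalty; source-domain slices are mapped onto the target domain and
   pooled, D = Ã ∪ B.
2. **Augmentation** — a DCGAN per (modality, class) synthesizes extra
   tumor crops from z ~ Uniform(−1,1)¹⁰⁰, trained toward the
   discriminator's 0.5 equilibrium.
3. **Tumor extraction** — a tight rectangular bounding box around the
   tumor, resampled to a fixed crop, instead of expert segmentation.
4. **Classification** — two convolutional-autoencoder streams (T1ce
   and FLAIR), pre-trained unsupervised on augmented crops, fine-tuned
   jointly through aggregation f = f1 ⊙ f2, bilinear pooling H = FᵀF,
   and a fully connected softmax head.
5. **Evaluation** — TP/FP/TN/FN metrics over several runs with fresh
   patient-separated 60/20/20 partitions, reported as mean ± σ.

Because clinical cohorts cannot ship with the package, a first-class
phantom module generates two-domain, two-modality, two-class cohorts
with ground-truth masks; the scanner shift (tone curve, bias field,
point-spread blur, noise) and the class texture are configurable. All
networks run on a small, fully tested numpy engine — no GPU or deep
learning framework required.

## Worked example

```python
import numpy as np
from gliomap import phantom, evaluation

cfg = evaluation.ExperimentConfig(seed=5)          # 64 phantom patients
cohort = phantom.generate_cohort(cfg.phantom)
mapped = evaluation.map_cohort(cfg, cohort)        # trains 2 CycleGANs

for arm in ("pooled", "mapped"):
    accs = []
    for rs in (1000, 1001, 1002):
        counts, _, _ = evaluation._single_run(
            cfg, arm, False, rs, cohort=cohort, mapped_cohort=mapped)
        accs.append(evaluation.metrics(counts)[0])
    print(arm, np.round(accs, 2), "mean %.3f" % np.mean(accs))
```

prints (about three minutes, mostly CycleGAN training):

```
pooled [0.96 0.5  0.96] mean 0.806
mapped [0.96 0.94 0.98] mean 0.958
```

Training on the raw pool A ∪ B is unstable because domain A's blur and
noise contradict the class texture learned from B; after mapping A
onto B's domain the pooled data is homogeneous and every run
classifies the held-out patients well. The same harness exposes the
with/without pre-training comparison and an augmentation-size sweep
(`evaluation.ablation`).

A command-line interface wraps the library for shell use:

```sh
gliomap phantom --out cohort/                 # synthesize a cohort
gliomap preprocess --in cohort/ --out prep/   # crops + splits.csv
gliomap map --in cohort/ --out mapped/        # CycleGAN harmonization
gliomap run-all --runs 5 --out report/        # full pipeline, 5 runs
```

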