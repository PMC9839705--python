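# paravae

Age estimation from paired tooth images with parallel variational
autoencoders, a linear latent-space age readout, and
regression-coefficient latent traversal for attribution.

Forensic odontology estimates a person's age from morphological changes
in their teeth — with advancing age the pulp cavity calcifies (appearing
brighter on a radiograph) and the cervical region near the gumline
erodes (appearing darker). `paravae` implements a fully seeded,
CPU-scale pipeline for this problem:

1. **Parallel VAE.** Two convolutional VAEs are trained jointly on paired
   images of each subject (a molar-like type A and a canine-like type B).
   Each branch's latent vector of length n = 2k is split into a *unique*
   half and a *common* half, and a coupling loss
   `L_separate = L_common / L_unique` makes the common halves converge
   across branches while the unique halves stay type-specific. The joint
   objective is
   `γ1·KL_A + γ2·KL_B + γ3·rec_A + γ4·rec_B + γ5·L_separate`,
   with five bundled weight presets (`loss1`..`loss5`). A single-VAE mode
   (one model on the pooled images) is included for comparison.
2. **Linear age readout.** `y_age = β·z + α`, fit by least squares on the
   posterior means; parallel mode uses n + k features per pair (two
   unique halves + one copy of the converged common half). Errors are
   reported per 10-year age group (10–19 … 70–79) with the **median**
   absolute error as the headline statistic.
3. **Traversal attribution.** β is the latent direction of fastest age
   change: decoding `z + s·β` renders the same subject older (s > 0) or
   younger (s < 0), and the signed pixel difference against the s = 0
   reconstruction — shown as a diverging red/blue overlay — reveals which
   image regions drive the estimate (red = brighter with age, blue =
   darker).

Because clinical radiographs cannot be redistributed, the package ships a
seeded phantom generator producing paired tooth silhouettes whose pulp
cavity brightens and cervical band darkens affinely with age, with
ground-truth region masks — so every stage, including attribution, is
testable end to end. See `docs/methods.md` for the model, parameter and
phantom details.

## Worked example

```python
import numpy as np
from paravae import (PhantomConfig, generate_dataset, LossWeights, VAEConfig,
                     train_parallel_vae, latent_agreement, extract_features,
                     fit_age_regression, predict_age, evaluate)

recs = generate_dataset(600, PhantomConfig(image_side=64, seed=11))
train, test = recs[:500], recs[500:]

model = train_parallel_vae(train, LossWeights.preset("loss2"),
                           VAEConfig(image_side=64, n_latent=32, epochs=20),
                           np.random.default_rng(7))

com, uni = latent_agreement(model, test)
print(f"common/unique ratio: {com/uni:.5f}")

reg = fit_age_regression(extract_features(model, train),
                         [r.age for r in train])
pred = predict_age(reg, extract_features(model, test))
print(evaluate(pred, [r.age for r in test]).to_string())
```

Output (about two minutes on one CPU):

```
common/unique ratio: 0.00023
  age_range    n  median_abs_error  mean_abs_error  std_abs_error
0     10-19   12          1.192247        1.959675       1.773264
1     20-29   14          2.225811        2.421137       2.107394
2     30-39   17          1.183209        1.682151       1.357218
3     40-49   17          1.052602        1.799937       1.573963
4     50-59   15          2.557521        2.918203       1.974428
5     60-69    9          3.449217        3.487252       2.401510
6     70-79   16          2.842725        2.713504       2.073853
7       All  100          1.805951        2.351819       1.906618
```

The ratio near zero shows the two branches' common latent halves have
converged to the same representation (they disagree ~4000× less than the
type-specific unique halves), and the held-out median absolute error of
≈1.8 years shows the latent features carry the phantoms' age signal — far
below the ≈17.25-year no-skill floor of always predicting the median age
on a uniform 10–79 range.

The same workflow is available from a shell:

```bash
paravae simulate --seed 11 --n-subjects 600 --out data/
paravae train    --manifest data/manifest.csv --seed 7 --out run/
paravae evaluate --checkpoint run/checkpoint.npz --regression run/regression.json \
                 --manifest data/manifest.csv --split run/split.json --out report.csv
paravae visualize --checkpoint run/checkpoint.npz --regression run/regression.json \
                  --manifest data/manifest.csv --mask --out traversal.png
```

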