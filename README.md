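# scatinception

An inception-style convolutional classifier augmented with a **spatial
convolutional attention (SCAT)** operator, together with the full
experimental pipeline needed to exercise it end to end: a seeded
synthetic brain-lesion image generator (two classes: irregular
ring-enhancing lesions with a dark necrotic center vs. round
homogeneously enhancing lesions, each with core/edema masks), region
dataset construction (core / edema / overall), augmentation, case-level
five-fold cross-validation, and accuracy / sensitivity / specificity /
ROC-AUC evaluation at both slice and case granularity.

The network and its training loop are implemented directly on NumPy
(im2col convolutions, pooling, dropout, Adam, explicit backprop) so the
package runs in plain scientific-Python environments without a deep
learning framework.

## Layout

| Module | Purpose |
| --- | --- |
| `scatinception.nn` | NumPy layer library: Conv2d, pooling, dropout, linear, Adam, cross-entropy |
| `scatinception.scat_core` | SCAT operator: 1×1 reduce → 1×1 logits → softmax → element-wise reweighting |
| `scatinception.inception_blocks` | The five inception unit variants (SCAT-A, SCAT-B, C, D, E) |
| `scatinception.network` | Full model assembly (stem → A×3, B×2, C×4, D×1, E×1 → GAP → dropout → linear) |
| `scatinception.synthetic_mri` | Seeded two-class lesion-slice generator with nested core/edema masks |
| `scatinception.preprocessing` | Region cropping, min-max normalization, rotation/translation/contrast augmentation |
| `scatinception.evaluation` | Stratified case-level k-fold splits, confusion metrics, ROC/AUC, fold aggregation |
| `scatinception.training` | Training loop, cross-validation orchestration, external-set evaluation, leakage audit |
| `scatinception.cli` | `scat-inception` command-line interface |

## CLI

Generate a synthetic cohort (3 slices per case, NIfTI + CSV manifest):

```bash
scat-inception synth --n-gbm 20 --n-met 20 --seed 1 --out cohort/
```

Run five-fold cross-validation end to end (config defaults carry the
published hyperparameters: 250 epochs, learning rate 0.01, dropout 0.5,
k=5, augmentation factor 3, unit counts 3/2/4/1/1; any of them can be
overridden from a YAML file):

```bash
scat-inception crossval --config cfg.yaml --region core --out results/
```

Outputs: `fold_metrics.csv` (per-fold slice- and case-level metrics),
`roc_scores.csv` (per-case scores for ROC curves), `results.json`
(summary plus training histories plus the fully resolved configuration
and all seeds, for replay).

## Notes

* The clinical MRI dataset behind the original study is private; the
  synthetic generator is a stand-in that preserves the two appearance
  classes and the nested region-mask structure, so headline clinical
  accuracies are out of scope by design.
* The SCAT softmax axis is configurable (`attn_axis: spatial|channel`,
  spatial by default), and the attention weights are rescaled by the
  size of the normalization axis so that uniform attention is an exact
  identity.
* SCAT can be ablated (`scat_enabled: false`) to compare against the
  plain inception backbone.
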