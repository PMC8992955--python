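# adaunet

Duplex adversarial U-Net with position self-attention for segmenting
small, low-contrast targets in 2D grayscale slices, plus everything
needed to exercise it end to end at desk scale: a seeded synthetic
phantom generator, the adversarial training loop, overlap/surface
evaluation metrics, and a 4-fold cross-validation harness that runs the
two-step model selection (backbone first, attention placement second).

The networks run on a small numpy reverse-mode autodiff engine
(`adaunet._nn`) — no GPU framework is required — and every layer's
gradients are verified against finite differences in the test suite.

## Model variants

| variant   | attention blocks | adversarial heads | outputs                   |
|-----------|------------------|-------------------|---------------------------|
| `unet`    | 0                | 0                 | full-res map              |
| `au_net`  | 0                | 1                 | full-res map              |
| `dau_net` | 0                | 2                 | full-res + half-res aux   |
| `adau_a1` | 1                | 2                 | full-res + half-res aux   |
| `adau_a2` | 2                | 2                 | full-res + half-res aux   |
| `adau_a3` | 3                | 2                 | full-res + half-res aux   |

The generator objective is `β·dice(main) + γ·log(1−D1(main)) +
ε·dice(aux) + μ·log(1−D2(aux))` with defaults `(1, 0.004, 0.1, 0.0004)`;
each discriminator is a five-layer strided conv critic with kernels
4,4,4,5,7. Attention computes an N×N row-stochastic spatial affinity map
from pairwise feature dot products and adds the reweighted features back
through a learnable δ-scaled residual (δ starts at 0, so the block
begins as the identity).

## CLI

All commands are driven by one YAML plan file (see `adaunet/cli.py`
docstring for the schema):

```bash
adaunet synth           --config plan.yaml --out data/            # phantoms + manifest
adaunet build           --variant adau_a2 --base-channels 16      # architecture summary
adaunet train           --config plan.yaml --out run/             # history.csv + model.npz
adaunet eval            --pred preds/ --truth truths/ --out report.csv
adaunet select-backbone --config plan.yaml --out sel/             # unet vs au_net vs dau_net
adaunet select-attention --config plan.yaml --out sel/            # dau_net vs adau_a1/a2/a3
adaunet report          --checkpoint run/model.npz --config plan.yaml --out rep/
```

Real data can be substituted for phantoms through the I/O layer
(`adaunet.io`): PNG image/mask pairs named `<case>_<slice>_img.png` /
`<case>_<slice>_mask.png`, or per-case NIfTI volume/label pairs. Images
are normalized to [0,1] on load; label-guided cropping to a square
window is available via `adaunet.crop_resize`.

## Notes on scale

Position attention materializes an N×N affinity matrix (N = H·W), so
full 208×208 attention costs a 43264² matrix; experiments here run
attention variants at ≤64×64. Training determinism holds bit-exactly for
a fixed seed and thread configuration.
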