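"""Alternating generator/discriminator optimization.

Each iteration draws one slice (batch size 1), runs one update of every
discriminator on (ground truth, detached prediction), then one generator
update on the composite objective. The sampling stream depends only on
``TrainConfig.seed`` so that different model variants consume identical
batches in identical order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._nn import Adam, Tensor, reshape
from .losses import (
    LossWeights,
    adversarial_gen_term,
    dice_loss,
    discriminator_loss,
    downsample_gt,
)
from .models import Discriminator, Segmentor

log = logging.getLogger(__name__)

_ORDER_STREAM = 555


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.99
    batch_size: int = 1
    iterations: int = 300
    seed: int = 0
    val_interval: int = 50

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class TrainingDiverged(RuntimeError):
    """Raised when a loss goes non-finite; carries a diagnostic snapshot."""

    def __init__(self, message, snapshot):
        super().__init__(message)
        self.snapshot = snapshot


def validation_dsc(model: Segmentor, slices, threshold=0.5) -> float:
    """Pooled dice (%) of thresholded predictions over a slice collection."""
    inter = psum = tsum = 0.0
    for s in slices:
        pred = (model.predict(s.image).main_map >= threshold)
        inter += float((pred & (s.mask > 0)).sum())
        psum += float(pred.sum())
        tsum += float(s.mask.sum())
    if psum + tsum == 0:
        return 100.0
    return 100.0 * 2.0 * inter / (psum + tsum)


def train(model: Segmentor, discriminators, data, tc: TrainConfig,
          w: LossWeights, val_slices=None, threshold=0.5) -> pd.DataFrame:
    """Run the alternating optimization; returns the loss history frame.

    History columns: iteration, L_S1, L_adv1, L_S2, L_adv2, L_D1, L_D2,
    val_DSC (NaN where a component does not apply / was not measured).
    Validation is recorded before the first update (iteration -1), every
    ``tc.val_interval`` iterations and after the last one.
    """
    if not data:
        raise ValueError("training data must be nonempty")
    heads = model.config.n_heads
    discriminators = list(discriminators)
    if len(discriminators) != heads:
        raise ValueError(
            f"variant {model.config.variant!r} needs {heads} discriminator(s), "
            f"got {len(discriminators)}"
        )
    g_opt = Adam(model.parameters(), tc.learning_rate, tc.adam_beta1, tc.adam_beta2)
    d_opts = [Adam(d.parameters(), tc.learning_rate, tc.adam_beta1, tc.adam_beta2)
              for d in discriminators]
    rng = np.random.default_rng(
        np.random.SeedSequence([tc.seed & 0xFFFFFFFF, _ORDER_STREAM])
    )

    rows = []
    if val_slices:
        rows.append({"iteration": -1, "val_DSC": validation_dsc(model, val_slices, threshold)})

    for it in range(tc.iterations):
        row = {"iteration": it}
        batch = [data[int(i)] for i in rng.integers(len(data), size=tc.batch_size)]
        for s in batch:
            x = Tensor(np.asarray(s.image, dtype=np.float32)[None])
            t1 = np.asarray(s.mask, dtype=np.float32)
            t2 = downsample_gt(s.mask).astype(np.float32)

            main, aux = model.forward_t(x)

            # discriminator updates on (real=truth, fake=detached prediction)
            targets = [t1, t2]
            fakes = [main, aux]
            for h in range(heads):
                d = discriminators[h]
                d_real = d.forward_t(Tensor(targets[h][None]))
                d_fake = d.forward_t(Tensor(fakes[h].data[None].copy()))
                ld = discriminator_loss(d_real, d_fake)
                d.zero_grad()
                ld.backward()
                d_opts[h].step()
                d.zero_grad()
                row[f"L_D{h + 1}"] = float(ld.data)

            # generator update
            ls1 = dice_loss(main, Tensor(t1))
            total = w.beta * ls1
            row["L_S1"] = float(ls1.data)
            if heads >= 1:
                adv1 = adversarial_gen_term(
                    discriminators[0].forward_t(reshape(main, (1,) + main.shape))
                )
                total = total + w.gamma * adv1
                row["L_adv1"] = float(adv1.data)
            if heads == 2:
                ls2 = dice_loss(aux, Tensor(t2))
                adv2 = adversarial_gen_term(
                    discriminators[1].forward_t(reshape(aux, (1,) + aux.shape))
                )
                total = total + w.epsilon * ls2 + w.mu * adv2
                row["L_S2"] = float(ls2.data)
                row["L_adv2"] = float(adv2.data)

            if not np.isfinite(total.data):
                raise TrainingDiverged(
                    f"non-finite generator loss at iteration {it}",
                    snapshot={"iteration": it, "case_id": s.case_id,
                              "slice_id": s.slice_id, "components": dict(row)},
                )
            model.zero_grad()
            for d in discriminators:
                d.zero_grad()
            total.backward()
            g_opt.step()
            model.zero_grad()
            for d in discriminators:
                d.zero_grad()

        if val_slices and ((it + 1) % tc.val_interval == 0 or it == tc.iterations - 1):
            row["val_DSC"] = validation_dsc(model, val_slices, threshold)
        rows.append(row)
        if it % 50 == 0:
            log.info("iter %d: %s", it, {k: v for k, v in row.items() if k != "iteration"})

    frame = pd.DataFrame(rows)
    for col in ("L_S1", "L_adv1", "L_S2", "L_adv2", "L_D1", "L_D2", "val_DSC"):
        if col not in frame.columns:
            frame[col] = np.nan
    return frame[["iteration", "L_S1", "L_adv1", "L_S2", "L_adv2",
                  "L_D1", "L_D2", "val_DSC"]]


def build_discriminators(model: Segmentor, config=None, seed: int = 0):
    """One fresh discriminator per adversarial head of ``model``."""
    from .models import DiscriminatorConfig

    config = config or DiscriminatorConfig()
    return [Discriminator(config, in_channels=1, seed=seed + 1000 * h)
            for h in range(model.config.n_heads)]
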