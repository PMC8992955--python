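"""Loss functions for the segmentor/discriminator game.

The generator minimizes a weighted sum of soft-dice terms on its (one or
two) probability maps plus non-saturating ``log(1 - D(fake))`` guidance
terms; each discriminator minimizes the usual real/fake cross-entropy.
All functions operate on autodiff Tensors and transparently accept plain
arrays (returning floats) so the same code serves training and tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Tensor, clip, log, mean, mul, sum_

DICE_SMOOTH = 1e-6  # defines the empty-mask case: dice_loss(0, 0) == 0
PROB_EPS = 1e-7     # log(0) protection for discriminator outputs


@dataclass(frozen=True)
class LossWeights:
    """Coefficients of the four-term duplex generator objective."""

    beta: float = 1.0
    gamma: float = 0.004
    epsilon: float = 0.1
    mu: float = 0.0004

    def __post_init__(self):
        if min(self.beta, self.gamma, self.epsilon, self.mu) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass(frozen=True)
class GroundTruthPair:
    """Full-resolution target and its half-resolution counterpart."""

    full: np.ndarray
    half: np.ndarray

    @classmethod
    def from_full(cls, full: np.ndarray) -> "GroundTruthPair":
        return cls(full=np.asarray(full), half=downsample_gt(full))


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _maybe_float(result: Tensor, *inputs):
    if any(isinstance(i, Tensor) for i in inputs):
        return result
    return float(result.data)


def dice_loss(pred, truth):
    """Soft dice loss 1 - (2*sum(p*t)+s) / (sum(p)+sum(t)+s)."""
    p, t = _wrap(pred), _wrap(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    inter = sum_(mul(p, t))
    denom = sum_(p) + sum_(t)
    loss = 1.0 - (2.0 * inter + DICE_SMOOTH) * _reciprocal(denom + DICE_SMOOTH)
    return _maybe_float(loss, pred, truth)


def _reciprocal(x: Tensor) -> Tensor:
    out = Tensor(1.0 / x.data, requires_grad=x.requires_grad, _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(-g / (x.data * x.data))

    out._backward = bwd
    return out


def adversarial_gen_term(d_out):
    """Non-saturating guidance ``mean(log(1 - d))``, d clamped off {0,1}."""
    d = _wrap(d_out)
    term = mean(log(1.0 - clip(d, PROB_EPS, 1.0 - PROB_EPS)))
    return _maybe_float(term, d_out)


def discriminator_loss(d_real, d_fake):
    """``-log(d_real) - log(1 - d_fake)`` batch-averaged; serves both heads."""
    r, f = _wrap(d_real), _wrap(d_fake)
    lr = mean(log(clip(r, PROB_EPS, 1.0 - PROB_EPS)))
    lf = mean(log(1.0 - clip(f, PROB_EPS, 1.0 - PROB_EPS)))
    loss = -1.0 * lr - 1.0 * lf
    return _maybe_float(loss, d_real, d_fake)


def downsample_gt(full: np.ndarray) -> np.ndarray:
    """Foreground-preserving factor-2 max-pool of a binary mask."""
    arr = np.asarray(full)
    h, w = arr.shape[-2], arr.shape[-1]
    if h % 2 or w % 2:
        raise ValueError(f"downsample_gt requires even side lengths, got {h}x{w}")
    view = arr.reshape(*arr.shape[:-2], h // 2, 2, w // 2, 2)
    return view.max(axis=(-3, -1))


def duplex_generator_loss(out, gt: GroundTruthPair, d1_fake, d2_fake, w: LossWeights):
    """Four-term generator objective; returns (total, component dict).

    Components are keyed ``L_S1`` (main dice), ``L_adv1`` (main guidance),
    ``L_S2`` (aux dice), ``L_adv2`` (aux guidance); the total is the
    ``(beta, gamma, epsilon, mu)``-weighted sum.

    ``out`` may be a SegmentorOutput or a (main, aux) pair of Tensors.
    """
    if hasattr(out, "main_map"):
        main, aux = out.main_map, out.aux_map
    else:
        main, aux = out
    if aux is None:
        raise ValueError("duplex generator loss requires an auxiliary head output")
    ls1 = dice_loss(_wrap(main), _wrap(gt.full))
    ls2 = dice_loss(_wrap(aux), _wrap(gt.half))
    ladv1 = adversarial_gen_term(_wrap(d1_fake))
    ladv2 = adversarial_gen_term(_wrap(d2_fake))
    total = w.beta * ls1 + w.gamma * ladv1 + w.epsilon * ls2 + w.mu * ladv2
    tensor_in = any(
        isinstance(v, Tensor) for v in (main, aux, d1_fake, d2_fake)
    )
    comps = {"L_S1": ls1, "L_adv1": ladv1, "L_S2": ls2, "L_adv2": ladv2}
    if tensor_in:
        return total, comps
    return float(total.data), {k: float(v.data) for k, v in comps.items()}
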