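"""Experiment orchestration: 4-fold CV and the two-step model selection.

Step one compares backbone candidates (unet, au_net, dau_net); step two
compares attention placements (dau_net, adau_a1, adau_a2, adau_a3). Every
compared variant shares the same phantom dataset, fold assignment, batch
order and budget, so comparisons differ only in architecture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .losses import LossWeights
from .metrics import EvalReport, evaluate
from .models import DiscriminatorConfig, SegmentorConfig, build_segmentor
from .phantom import N_FOLDS, PhantomConfig, generate_dataset
from .training import TrainConfig, build_discriminators, train

log = logging.getLogger(__name__)

BACKBONE_VARIANTS = ("unet", "au_net", "dau_net")
ATTENTION_VARIANTS = ("dau_net", "adau_a1", "adau_a2", "adau_a3")


@dataclass(frozen=True)
class ExperimentPlan:
    """Shared data/budget for a family of variant comparisons."""

    phantom: PhantomConfig
    train: TrainConfig
    weights: LossWeights = LossWeights()
    discriminator: DiscriminatorConfig = DiscriminatorConfig(
        channels=(16, 32, 64, 128, 1)
    )
    segmentor: SegmentorConfig = SegmentorConfig(variant="unet", base_channels=16)
    threshold: float = 0.5


@dataclass
class SelectionReport:
    reports: dict[str, EvalReport]
    winner: str
    curves: pd.DataFrame = field(default_factory=pd.DataFrame)
    histories: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_cross_validation(variant: str, plan: ExperimentPlan,
                         histories: list | None = None) -> EvalReport:
    """Train one model per held-out fold; every case scored exactly once."""
    slices, folds = generate_dataset(plan.phantom)
    per_case_frames = []
    for fold in range(N_FOLDS):
        test_cases = set(folds.test_cases(fold))
        if not test_cases:
            raise ValueError(f"fold {fold} has no test cases")
        train_slices = [s for s in slices if s.case_id not in test_cases]
        test_slices = [s for s in slices if s.case_id in test_cases]

        cfg = replace(plan.segmentor, variant=variant)
        model_seed = plan.train.seed * 100 + fold
        model = build_segmentor(cfg, seed=model_seed)
        discs = build_discriminators(model, plan.discriminator, seed=model_seed)
        fold_tc = replace(plan.train, seed=plan.train.seed * 100 + fold)
        history = train(model, discs, train_slices, fold_tc, plan.weights)
        if histories is not None:
            histories.append(history.assign(fold=fold))

        report = evaluate(
            [model.predict(s.image).main_map for s in test_slices],
            [s.mask for s in test_slices],
            threshold=plan.threshold,
            case_ids=[s.case_id for s in test_slices],
        )
        per_case_frames.append(report.per_case)
        log.info("variant=%s fold=%d mean DSC %.2f", variant, fold,
                 report.per_case["dsc"].mean())
    per_case = pd.concat(per_case_frames, ignore_index=True).sort_values(
        "case_id", ignore_index=True
    )
    from .metrics import aggregate_cases

    return EvalReport(per_case=per_case, aggregate=aggregate_cases(per_case))


def _select(variants, plan: ExperimentPlan) -> SelectionReport:
    if len(variants) < 2:
        raise ValueError("selection requires at least two variants")
    reports, histories, curves = {}, {}, []
    for variant in variants:
        hist: list = []
        reports[variant] = run_cross_validation(variant, plan, histories=hist)
        histories[variant] = pd.concat(hist, ignore_index=True)
        frame = reports[variant].per_case[["case_id", "dsc", "jaccard"]].copy()
        frame.insert(0, "variant", variant)
        curves.append(frame)
    # argmax mean DSC; ties broken by mean Jaccard, then variant order
    order = {v: i for i, v in enumerate(variants)}
    winner = max(
        reports,
        key=lambda v: (reports[v].mean_dsc, reports[v].mean_jaccard, -order[v]),
    )
    return SelectionReport(
        reports=reports,
        winner=winner,
        curves=pd.concat(curves, ignore_index=True),
        histories=histories,
    )


def select_backbone(plan: ExperimentPlan, variants=BACKBONE_VARIANTS) -> SelectionReport:
    """Step one: pick the backbone by cross-validated mean DSC."""
    return _select(tuple(variants), plan)


def select_attention(plan: ExperimentPlan, variants=ATTENTION_VARIANTS) -> SelectionReport:
    """Step two: pick the attention placement by cross-validated mean DSC."""
    return _select(tuple(variants), plan)


def run_pipeline(plan: ExperimentPlan) -> dict:
    """Both selection steps; returns reports and the final variant choice."""
    backbone = select_backbone(plan)
    attention = select_attention(plan)
    return {
        "backbone": backbone,
        "attention": attention,
        "final_variant": attention.winner,
    }


def plot_reports(reports: dict[str, EvalReport], out_dir,
                 histories: dict[str, pd.DataFrame] | None = None):
    """Per-case metric curves (and loss curves) as PNG + backing CSV."""
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    for metric in ("dsc", "jaccard"):
        fig, ax = plt.subplots(figsize=(6, 4))
        rows = []
        for variant, report in reports.items():
            col = report.per_case[metric]
            if col.dropna().empty:
                log.warning("metric %s empty for %s; omitted", metric, variant)
                continue
            ax.plot(report.per_case["case_id"], col, marker="o", label=variant)
            frame = report.per_case[["case_id", metric]].copy()
            frame.insert(0, "variant", variant)
            rows.append(frame)
        ax.set_xlabel("case")
        ax.set_ylabel(f"{metric.upper()} (%)")
        if rows:
            ax.legend()
        fig.tight_layout()
        png = out_dir / f"{metric}_per_case.png"
        fig.savefig(png, dpi=100)
        plt.close(fig)
        if rows:
            pd.concat(rows, ignore_index=True).to_csv(
                out_dir / f"{metric}_per_case.csv", index=False
            )
        written.append(png)

    if histories:
        fig, ax = plt.subplots(figsize=(6, 4))
        for variant, hist in histories.items():
            col = hist["L_S1"].dropna()
            if col.empty:
                log.warning("loss history empty for %s; omitted", variant)
                continue
            ax.plot(col.values, label=variant, alpha=0.8)
        ax.set_xlabel("step")
        ax.set_ylabel("dice loss (main head)")
        ax.legend()
        fig.tight_layout()
        png = out_dir / "training_loss.png"
        fig.savefig(png, dpi=100)
        plt.close(fig)
        pd.concat(
            [h.assign(variant=v) for v, h in histories.items()], ignore_index=True
        ).to_csv(out_dir / "training_loss.csv", index=False)
        written.append(png)
    return written
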