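"""Overlap and surface-distance metrics with per-case aggregation.

DSC and Jaccard are reported in percent; ASD and surface RMSE in
millimetres (isotropic pixel ``spacing``, default 1.0 mm). Borders are
foreground pixels 4-adjacent to background; nearest-border distances come
from an exact Euclidean distance transform. Cases pool all of their
slices: overlap counts are summed, surface distances are computed
slice-wise (2D) and pooled across the case.

Conventions (documented, asserted in tests): two empty masks have
DSC = Jaccard = 100; surface metrics are undefined for an empty mask and
reported as NaN with a warning; aggregate std is the sample (n-1) kind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity

METRIC_COLUMNS = ("dsc", "jaccard", "asd", "rmse")


def _as_binary(mask) -> np.ndarray:
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1, False, True)).all():
        raise ValueError("mask values must be binary")
    return arr.astype(bool)


def _check_shapes(a, b):
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dsc(a, b) -> float:
    """Dice similarity coefficient in percent: 100 * 2|A∩B| / (|A|+|B|)."""
    a, b = _as_binary(a), _as_binary(b)
    _check_shapes(a, b)
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 100.0
    return 100.0 * 2.0 * int((a & b).sum()) / (sa + sb)


def jaccard(a, b) -> float:
    """Jaccard index in percent: 100 * |A∩B| / |A∪B|."""
    a, b = _as_binary(a), _as_binary(b)
    _check_shapes(a, b)
    union = int((a | b).sum())
    if union == 0:
        return 100.0
    return 100.0 * int((a & b).sum()) / union


def border_pixels(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels 4-adjacent to background (2D boolean array)."""
    m = _as_binary(mask)
    eroded = ndimage.binary_erosion(m, structure=_CROSS, border_value=0)
    return m & ~eroded


def _directed_distances(src_border, dst_border, spacing):
    """Distances from each src border pixel to the nearest dst border pixel."""
    # EDT of the complement of dst gives distance-to-nearest-dst everywhere
    dist = ndimage.distance_transform_edt(~dst_border) * spacing
    return dist[src_border]


def _iter_slices(arr):
    if arr.ndim == 2:
        yield arr
    elif arr.ndim == 3:
        yield from arr
    else:
        raise ValueError("masks must be 2D or 3D (stacked slices)")


def surface_distances(a, b, spacing=1.0):
    """Pooled directed border distances (a->b, b->a) across slices.

    Slices where one mask is empty while the other is not contribute no
    distances and trigger a warning; fully empty slice pairs are skipped
    silently.
    """
    a, b = _as_binary(a), _as_binary(b)
    _check_shapes(a, b)
    d_ab, d_ba = [], []
    skipped = 0
    for sa, sb in zip(_iter_slices(a), _iter_slices(b)):
        ea, eb = not sa.any(), not sb.any()
        if ea and eb:
            continue
        if ea or eb:
            skipped += 1
            continue
        ba, bb = border_pixels(sa), border_pixels(sb)
        d_ab.append(_directed_distances(ba, bb, spacing))
        d_ba.append(_directed_distances(bb, ba, spacing))
    if skipped:
        warnings.warn(
            f"{skipped} slice(s) had exactly one empty mask; excluded from "
            "surface distances", stacklevel=2,
        )
    if not d_ab:
        return np.empty(0), np.empty(0)
    return np.concatenate(d_ab), np.concatenate(d_ba)


def asd(a, b, spacing=1.0) -> float:
    """Average symmetric surface distance: mean of the two directed means."""
    d_ab, d_ba = surface_distances(a, b, spacing)
    if d_ab.size == 0 or d_ba.size == 0:
        warnings.warn("ASD undefined for empty mask(s); reporting NaN", stacklevel=2)
        return float("nan")
    return 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))


def surface_rmse(a, b, spacing=1.0) -> float:
    """Root of the mean squared border distance, both directions pooled."""
    d_ab, d_ba = surface_distances(a, b, spacing)
    if d_ab.size == 0 or d_ba.size == 0:
        warnings.warn("surface RMSE undefined for empty mask(s); reporting NaN",
                      stacklevel=2)
        return float("nan")
    pooled = np.concatenate([d_ab, d_ba])
    return float(np.sqrt(np.mean(pooled ** 2)))


@dataclass
class EvalReport:
    """Per-case metric rows plus mean/std/min/max aggregates."""

    per_case: pd.DataFrame
    aggregate: pd.DataFrame

    def to_csv(self, path):
        rows = self.per_case.copy()
        rows.insert(0, "row", "case")
        agg = self.aggregate.reset_index().rename(columns={"index": "case_id"})
        agg.insert(0, "row", "aggregate")
        pd.concat([rows, agg], ignore_index=True).to_csv(path, index=False)

    @property
    def mean_dsc(self) -> float:
        return float(self.per_case["dsc"].mean())

    @property
    def mean_jaccard(self) -> float:
        return float(self.per_case["jaccard"].mean())


def aggregate_cases(per_case: pd.DataFrame) -> pd.DataFrame:
    agg = per_case[list(METRIC_COLUMNS)].agg(["mean", "std", "min", "max"])
    return agg.T


def evaluate(pred_maps, truths, threshold=0.5, spacing=1.0, case_ids=None) -> EvalReport:
    """Binarize predictions and score them per case.

    ``pred_maps`` and ``truths`` are aligned sequences of 2D arrays;
    ``case_ids`` groups entries into cases (default: one case per entry).
    All slices of a case are pooled before metric computation.
    """
    if len(pred_maps) != len(truths):
        raise ValueError(
            f"length mismatch: {len(pred_maps)} predictions vs {len(truths)} truths"
        )
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if case_ids is None:
        case_ids = list(range(len(pred_maps)))
    by_case: dict[int, tuple[list, list]] = {}
    for p, t, c in zip(pred_maps, truths, case_ids):
        by_case.setdefault(c, ([], []))[0].append(np.asarray(p) >= threshold)
        by_case[c][1].append(_as_binary(t))
    rows = []
    for case_id in sorted(by_case):
        preds, trs = by_case[case_id]
        p3 = np.stack([x.astype(np.uint8) for x in preds])
        t3 = np.stack([x.astype(np.uint8) for x in trs])
        rows.append(
            {
                "case_id": case_id,
                "dsc": dsc(p3, t3),
                "jaccard": jaccard(p3, t3),
                "asd": asd(p3, t3, spacing),
                "rmse": surface_rmse(p3, t3, spacing),
            }
        )
    per_case = pd.DataFrame(rows)
    return EvalReport(per_case=per_case, aggregate=aggregate_cases(per_case))
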