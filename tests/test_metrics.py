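import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from adaunet import asd, dsc, evaluate, jaccard, surface_rmse
from adaunet.metrics import border_pixels


# -- independent brute-force oracles ------------------------------------

def border_oracle(mask):
    """Foreground pixels with a 4-neighbor background (or edge counts as bg)."""
    m = np.asarray(mask).astype(bool)
    h, w = m.shape
    out = np.zeros_like(m)
    for r in range(h):
        for c in range(w):
            if not m[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not m[rr, cc]:
                    out[r, c] = True
                    break
    return out


def surface_oracle(a, b, spacing=1.0):
    """All-pairs nearest-border distances; returns (asd, rmse)."""
    pa = np.argwhere(border_oracle(a))
    pb = np.argwhere(border_oracle(b))
    d_ab = np.array([min(np.hypot(*(p - q)) for q in pb) for p in pa]) * spacing
    d_ba = np.array([min(np.hypot(*(q - p)) for p in pa) for q in pb]) * spacing
    asd_val = 0.5 * (d_ab.mean() + d_ba.mean())
    pooled = np.concatenate([d_ab, d_ba])
    return asd_val, float(np.sqrt((pooled ** 2).mean()))


def overlap_oracle(a, b):
    inter = sum(1 for x, y in zip(np.ravel(a), np.ravel(b)) if x and y)
    union = sum(1 for x, y in zip(np.ravel(a), np.ravel(b)) if x or y)
    na, nb = int(np.sum(a)), int(np.sum(b))
    return 100.0 * 2 * inter / (na + nb), 100.0 * inter / union


def random_mask(rng, size=16, p=0.2):
    m = (rng.random((size, size)) < p).astype(np.uint8)
    if not m.any():
        m[rng.integers(size), rng.integers(size)] = 1
    return m


class TestOverlap:
    def test_identical_masks(self, rng):
        m = random_mask(rng)
        assert dsc(m, m) == 100.0
        assert jaccard(m, m) == 100.0

    def test_closed_forms(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[0, :4] = 1          # |A| = 4
        b[0, 2:] = 1
        b[1, :2] = 1          # |B| = 4, |A∩B| = 2
        assert dsc(a, b) == pytest.approx(50.0)
        assert jaccard(a, b) == pytest.approx(100.0 * 2 / 6, abs=1e-9)

    def test_both_empty_convention(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        assert dsc(z, z) == 100.0
        assert jaccard(z, z) == 100.0

    def test_counting_oracle_random_pairs(self, rng):
        for _ in range(100):
            a, b = random_mask(rng), random_mask(rng)
            d_exp, j_exp = overlap_oracle(a, b)
            assert dsc(a, b) == pytest.approx(d_exp, abs=1e-9)
            assert jaccard(a, b) == pytest.approx(j_exp, abs=1e-9)

    def test_dsc_jaccard_identity(self, rng):
        for _ in range(100):
            a, b = random_mask(rng), random_mask(rng)
            d = dsc(a, b)
            assert jaccard(a, b) == pytest.approx(100.0 * d / (200.0 - d), abs=1e-6)

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            dsc(np.full((4, 4), 0.5), np.ones((4, 4)))


class TestSurfaceDistances:
    def test_identical_masks_zero(self, rng):
        m = random_mask(rng, p=0.3)
        assert asd(m, m) == 0.0
        assert surface_rmse(m, m) == 0.0

    def test_single_pixels_offset(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        b = np.zeros((8, 8), dtype=np.uint8)
        a[4, 1] = 1
        b[4, 4] = 1
        assert asd(a, b) == pytest.approx(3.0)
        assert surface_rmse(a, b) == pytest.approx(3.0)

    def test_spacing_scales_linearly(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        b = np.zeros((8, 8), dtype=np.uint8)
        a[2, 2] = 1
        b[2, 6] = 1
        assert asd(a, b, spacing=0.5) == pytest.approx(2.0)
        assert surface_rmse(a, b, spacing=2.0) == pytest.approx(8.0)

    def test_brute_force_oracle(self, rng):
        for _ in range(60):
            a, b = random_mask(rng, 12, 0.25), random_mask(rng, 12, 0.25)
            asd_exp, rmse_exp = surface_oracle(a, b)
            assert asd(a, b) == pytest.approx(asd_exp, abs=1e-6)
            assert surface_rmse(a, b) == pytest.approx(rmse_exp, abs=1e-6)

    def test_symmetry_exact(self, rng):
        for _ in range(20):
            a, b = random_mask(rng), random_mask(rng)
            assert asd(a, b) == asd(b, a)
            assert surface_rmse(a, b) == surface_rmse(b, a)

    def test_pooled_rms_at_least_pooled_mean(self, rng):
        from adaunet.metrics import surface_distances

        for _ in range(30):
            a, b = random_mask(rng), random_mask(rng)
            d_ab, d_ba = surface_distances(a, b)
            pooled = np.concatenate([d_ab, d_ba])
            assert surface_rmse(a, b) >= pooled.mean() - 1e-9

    def test_empty_mask_reports_nan_with_warning(self):
        a = np.zeros((6, 6), dtype=np.uint8)
        b = np.zeros((6, 6), dtype=np.uint8)
        b[2, 2] = 1
        with pytest.warns(UserWarning):
            assert np.isnan(asd(a, b))
        with pytest.warns(UserWarning):
            assert np.isnan(surface_rmse(a, b))

    def test_translation_invariance(self, rng):
        a = np.zeros((20, 20), dtype=np.uint8)
        b = np.zeros((20, 20), dtype=np.uint8)
        a[5:9, 5:8] = 1
        b[6:10, 6:9] = 1
        sa, sb = np.roll(a, (3, 4), (0, 1)), np.roll(b, (3, 4), (0, 1))
        assert asd(a, b) == pytest.approx(asd(sa, sb), abs=1e-12)
        assert dsc(a, b) == pytest.approx(dsc(sa, sb), abs=1e-12)

    def test_border_matches_loop_oracle(self, rng):
        for _ in range(20):
            m = random_mask(rng, 10, 0.4)
            np.testing.assert_array_equal(border_pixels(m), border_oracle(m))


@settings(max_examples=40, deadline=None)
@given(
    a=arrays(np.uint8, (8, 8), elements=st.integers(0, 1)),
    b=arrays(np.uint8, (8, 8), elements=st.integers(0, 1)),
)
def test_property_overlap_consistency(a, b):
    d, j = dsc(a, b), jaccard(a, b)
    assert 0.0 <= d <= 100.0 and 0.0 <= j <= 100.0
    assert j == pytest.approx(100.0 * d / (200.0 - d), abs=1e-6)
    assert d >= j - 1e-9  # dice dominates jaccard


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        truths = [random_mask(rng, 16, 0.2) for _ in range(4)]
        report = evaluate([t.astype(float) for t in truths], truths)
        assert report.per_case["dsc"].mean() == 100.0
        assert report.per_case["asd"].max() == 0.0

    def test_aggregate_matches_hand_average(self, rng):
        preds = [random_mask(rng, 16, 0.3).astype(float) for _ in range(5)]
        truths = [random_mask(rng, 16, 0.3) for _ in range(5)]
        report = evaluate(preds, truths)
        assert report.aggregate.loc["dsc", "mean"] == pytest.approx(
            report.per_case["dsc"].mean())
        assert report.aggregate.loc["dsc", "std"] == pytest.approx(
            report.per_case["dsc"].std(ddof=1))  # sample std convention

    def test_two_case_aggregation_convention(self):
        import pandas as pd

        from adaunet.metrics import aggregate_cases

        per_case = pd.DataFrame(
            {"case_id": [0, 1], "dsc": [80.0, 90.0], "jaccard": [70.0, 80.0],
             "asd": [1.0, 2.0], "rmse": [2.0, 3.0]})
        agg = aggregate_cases(per_case)
        assert agg.loc["dsc", "mean"] == 85.0
        assert agg.loc["dsc", "std"] == pytest.approx(np.std([80, 90], ddof=1))
        assert agg.loc["dsc", "min"] == 80.0 and agg.loc["dsc", "max"] == 90.0

    def test_case_pooling_differs_from_slicewise(self, rng):
        # two slices of one case pooled: counts are summed before the ratio
        t1, t2 = random_mask(rng, 8, 0.4), random_mask(rng, 8, 0.4)
        p1, p2 = random_mask(rng, 8, 0.4), random_mask(rng, 8, 0.4)
        report = evaluate([p1.astype(float), p2.astype(float)], [t1, t2],
                          case_ids=[7, 7])
        assert len(report.per_case) == 1
        stacked_d = dsc(np.stack([p1, p2]), np.stack([t1, t2]))
        assert report.per_case["dsc"].iloc[0] == pytest.approx(stacked_d)

    def test_threshold_binarizes(self):
        truth = np.zeros((8, 8), dtype=np.uint8)
        truth[2:5, 2:5] = 1
        pred = truth * 0.6
        assert evaluate([pred], [truth], threshold=0.5).mean_dsc == 100.0
        assert evaluate([pred], [truth], threshold=0.7).mean_dsc < 100.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            evaluate([np.zeros((4, 4))], [])

    def test_csv_round_trip(self, tmp_path, rng):
        import pandas as pd

        report = evaluate([random_mask(rng, 8).astype(float) for _ in range(3)],
                          [random_mask(rng, 8) for _ in range(3)])
        report.to_csv(tmp_path / "report.csv")
        frame = pd.read_csv(tmp_path / "report.csv")
        assert (frame["row"] == "case").sum() == 3
        assert (frame["row"] == "aggregate").sum() == 4
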