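"""Overlap metrics and agreement statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echoquant.agreement import (
    ZeroVarianceError,
    bland_altman,
    compare_methods,
    dice,
    icc_a1,
    icc_c1,
    iou,
    paired_t,
    stratified_eval,
)


def masks_with_overlap(na, nb, ninter, shape=(40, 40)):
    a = np.zeros(shape, dtype=np.uint8)
    b = np.zeros(shape, dtype=np.uint8)
    a.ravel()[:na] = 1
    b.ravel()[na - ninter:na - ninter + nb] = 1
    return a, b


class TestOverlap:
    def test_identical_masks(self):
        a, _ = masks_with_overlap(100, 100, 100)
        assert dice(a, a, 1) == 1.0
        assert iou(a, a, 1) == 1.0

    def test_disjoint_masks(self):
        a, b = masks_with_overlap(100, 100, 0)
        assert dice(a, b, 1) == 0.0
        assert iou(a, b, 1) == 0.0

    def test_worked_examples(self):
        # |A| = |B| = 100 with 96 shared pixels: DSC 0.96, IoU 0.9231 (0.92 at 2 dp)
        a, b = masks_with_overlap(100, 100, 96)
        assert dice(a, b, 1) == pytest.approx(0.96)
        assert iou(a, b, 1) == pytest.approx(96 / 104)
        assert round(iou(a, b, 1), 2) == 0.92
        # 95 shared pixels: DSC 0.95, IoU 0.9048 -> 0.90
        a, b = masks_with_overlap(100, 100, 95)
        assert dice(a, b, 1) == pytest.approx(0.95)
        assert round(iou(a, b, 1), 2) == 0.90

    def test_empty_vs_empty_scores_one(self):
        z = np.zeros((10, 10), dtype=np.uint8)
        assert dice(z, z, 1) == 1.0
        assert iou(z, z, 1) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((4, 4)), np.zeros((5, 5)), 1)

    @given(st.integers(0, 200), st.integers(0, 200), st.data())
    @settings(max_examples=50, deadline=None)
    def test_pairwise_identity_and_symmetry(self, na, nb, data):
        ninter = data.draw(st.integers(0, min(na, nb)))
        a, b = masks_with_overlap(na, nb, ninter)
        d, j = dice(a, b, 1), iou(a, b, 1)
        assert d == dice(b, a, 1) and j == iou(b, a, 1)
        assert j == pytest.approx(d / (2.0 - d), abs=1e-12)
        assert j <= d + 1e-15

    def test_mean_of_pairs_breaks_identity(self):
        # averaging DSC and IoU over cases does not preserve IoU = DSC/(2-DSC)
        pairs = [masks_with_overlap(100, 100, 100), masks_with_overlap(100, 100, 50)]
        mean_d = np.mean([dice(a, b, 1) for a, b in pairs])
        mean_j = np.mean([iou(a, b, 1) for a, b in pairs])
        assert mean_j != pytest.approx(mean_d / (2 - mean_d), abs=1e-3)


def icc_a1_bruteforce(x):
    """Independent oracle: explicit two-way ANOVA from cell deviations."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    mu = x.mean()
    ri = x.mean(axis=1)
    cj = x.mean(axis=0)
    msr = k * np.sum((ri - mu) ** 2) / (n - 1)
    msc = n * np.sum((cj - mu) ** 2) / (k - 1)
    mse = np.sum((x - ri[:, None] - cj[None, :] + mu) ** 2) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_duplicated_column_perfect_agreement(self):
        col = np.array([1.0, 2.0, 5.0, 9.0])
        icc, lo, hi = icc_a1(np.column_stack([col, col]))
        assert icc == pytest.approx(1.0)

    def test_offset_penalized_vs_consistency(self):
        rng = np.random.default_rng(0)
        col = rng.normal(50, 10, size=20)
        x = np.column_stack([col, col + 25.0])
        icc_abs, _, _ = icc_a1(x)
        assert icc_abs < icc_c1(x)

    def test_matches_bruteforce_anova(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(6, 2))
        icc, _, _ = icc_a1(x)
        assert icc == pytest.approx(icc_a1_bruteforce(x), abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        subjects = rng.normal(50, 10, size=15)
        x = subjects[:, None] + rng.normal(0, 3, size=(15, 2))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(15), 2),
            "rater": np.tile(["a", "b"], 15),
            "score": x.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score").set_index("Type")
        icc, lo, hi = icc_a1(x)
        assert icc == pytest.approx(float(ref.loc["ICC(A,1)", "ICC"]), abs=1e-9)
        ref_lo, ref_hi = ref.loc["ICC(A,1)", "CI95"]  # pingouin rounds to 2 dp
        assert lo == pytest.approx(ref_lo, abs=0.02)
        assert hi == pytest.approx(ref_hi, abs=0.02)

    def test_estimator_recovery_known_variance_components(self):
        # subject sd 10, no rater effect, error sd chosen for true ICC = 0.90
        rng = np.random.default_rng(42)
        n = 500
        err_sd = 10.0 / 3.0  # ICC = 100 / (100 + 100/9) = 0.90
        subj = rng.normal(0, 10, size=n)
        x = subj[:, None] + rng.normal(0, err_sd, size=(n, 2))
        icc, _, _ = icc_a1(x)
        assert icc == pytest.approx(0.90, abs=0.02)

    def test_zero_variance_named_error(self):
        with pytest.raises(ZeroVarianceError):
            icc_a1(np.full((5, 2), 3.0))


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([1.0, 2.0, 3.0])
        assert bland_altman(x, x) == (0.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        bias, lo, hi = bland_altman(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert bias == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * np.sqrt(2.0), abs=1e-9)
        assert lo == pytest.approx(-1.96 * np.sqrt(2.0), abs=1e-9)

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=30),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_limits_bracket_bias(self, xs, seed):
        x = np.asarray(xs)
        y = x + np.random.default_rng(seed).normal(size=x.size)
        bias, lo, hi = bland_altman(x, y)
        assert lo <= bias <= hi

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2, 3], [1, 2])


class TestCompareMethods:
    def _tables(self, n=200, noise_sd_frac=0.05, seed=11):
        rng = np.random.default_rng(seed)
        truth = pd.DataFrame({"edv": rng.uniform(90, 160, n)},
                             index=[f"P{i}" for i in range(n)])
        pred = truth + rng.normal(0, noise_sd_frac, (n, 1)) * truth
        return truth, pred

    def test_perfect_prediction(self):
        truth, _ = self._tables()
        report = compare_methods(truth, truth.copy())
        row = report.loc["edv"]
        assert row["pearson_r"] == pytest.approx(1.0)
        assert row["paired_t_p"] == 1.0 and row["paired_t_zero_variance"]
        assert row["bias"] == 0.0

    def test_unbiased_noise_small_bias(self):
        truth, pred = self._tables(n=200, noise_sd_frac=0.05)
        report = compare_methods(truth, pred)
        assert abs(report.loc["edv", "bias"]) < 0.01 * truth["edv"].mean()

    def test_anticorrelated_series(self):
        truth = pd.DataFrame({"v": [1.0, 2.0, 3.0]}, index=list("abc"))
        pred = pd.DataFrame({"v": [3.0, 2.0, 1.0]}, index=list("abc"))
        assert compare_methods(truth, pred).loc["v", "pearson_r"] == pytest.approx(-1.0)

    def test_too_few_pairs_suppressed(self):
        truth = pd.DataFrame({"v": [1.0, 2.0]}, index=list("ab"))
        with pytest.warns(UserWarning):
            report = compare_methods(truth, truth.copy())
        assert "bias" not in report.columns or np.isnan(report.loc["v"].get("bias", np.nan))

    def test_paired_t_zero_variance_rule(self):
        p, flag = paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])  # constant difference
        assert p == 1.0 and flag


class TestStratifiedEval:
    def _scores(self, values):
        rows = []
        for qual, vals in values.items():
            for v in vals:
                rows.append({"view": "A2C", "structure": "lv_cavity",
                             "quality": qual, "dsc": v})
        return pd.DataFrame(rows)

    def test_constant_scores_fill_every_cell(self):
        table = stratified_eval(self._scores({"good": [0.9, 0.9], "poor": [0.9]}))
        assert (table.loc[("A2C", "lv_cavity")] == 0.9).all()

    def test_single_stratum(self):
        table = stratified_eval(self._scores({"fair": [0.8, 0.6]}))
        assert list(table.columns) == ["fair"]
        assert table.iloc[0, 0] == pytest.approx(0.7)

    def test_grouped_means_rounded(self):
        table = stratified_eval(self._scores({"good": [0.911, 0.914], "poor": [0.7]}))
        assert table.loc[("A2C", "lv_cavity"), "good"] == 0.91
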