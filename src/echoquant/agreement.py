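"""Segmentation overlap metrics and observer/method agreement statistics.

Overlap: Dice similarity coefficient DSC = 2|A n B| / (|A| + |B|) and
Jaccard/IoU = |A n B| / |A u B|, related pairwise by IoU = DSC / (2 - DSC).
A structure absent from both masks scores 1.0 (correctly predicted absent).

Agreement: two-way random-effects absolute-agreement single-measures ICC
(ICC(A,1) / ICC(2,1)) with an F-based 95% CI, Bland-Altman bias and limits
of agreement (bias +- 1.96 * SD of differences), Pearson correlation and
the paired t test, assembled per clinical index into a comparison report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class ZeroVarianceError(ValueError):
    """Ratings carry no variance at all; ICC undefined."""


@dataclass(frozen=True)
class OverlapScores:
    dsc: float
    iou: float
    label: int


def _binary(a, b, label):
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a == label, b == label


def dice(a, b, label) -> float:
    """Dice similarity coefficient for one label; both-empty scores 1.0."""
    ab, bb = _binary(a, b, label)
    na, nb = int(ab.sum()), int(bb.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((ab & bb).sum()) / (na + nb)


def iou(a, b, label) -> float:
    """Intersection over union for one label; both-empty scores 1.0."""
    ab, bb = _binary(a, b, label)
    union = int((ab | bb).sum())
    if union == 0:
        return 1.0
    return int((ab & bb).sum()) / union


def overlap_scores(a, b, label) -> OverlapScores:
    return OverlapScores(dsc=dice(a, b, label), iou=iou(a, b, label), label=label)


# ---------------------------------------------------------------------------
# ICC


def _anova_mean_squares(x: np.ndarray):
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_a1(ratings, alpha: float = 0.05):
    """Two-way random, absolute-agreement, single-measures ICC with 95% CI.

    ``ratings`` is an n-subjects x k-raters matrix without missing cells.
    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE)); the CI
    uses the F-distribution method with Satterthwaite degrees of freedom.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an n x k matrix with n >= 2, k >= 2")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")
    n, k = x.shape
    msr, msc, mse = _anova_mean_squares(x)
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom <= 0 or np.allclose(x, x.mean()):
        raise ZeroVarianceError("ratings have zero total variance")
    icc = (msr - mse) / denom
    if mse <= 0 and msc <= mse:  # perfect agreement, CI degenerate
        return float(icc), float(icc), float(icc)
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if not np.isfinite(a):
        return float(icc), float(icc), float(icc)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        if not np.isfinite(v) or v <= 0:
            return float(icc), float("nan"), float("nan")
        f_lo = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_up = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        lower = n * (msr - f_lo * mse) / (f_lo * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f_up * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_up * msr)
    return float(icc), float(lower), float(upper)


def icc_c1(ratings) -> float:
    """Two-way consistency single-measures ICC(C,1) (no offset penalty)."""
    x = np.asarray(ratings, dtype=float)
    n, k = x.shape
    msr, _, mse = _anova_mean_squares(x)
    denom = msr + (k - 1) * mse
    if denom <= 0:
        raise ZeroVarianceError("ratings have zero total variance")
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# Bland-Altman / paired comparison


def bland_altman(x, y):
    """Bias and 95% limits of agreement: bias -+ 1.96 * SD(x - y), sample SD."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def paired_t(x, y):
    """Two-sided paired t test p value; zero-variance differences give p=1 (flagged)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    d = x - y
    if np.allclose(d, d[0]):
        return 1.0, True
    return float(stats.ttest_rel(x, y).pvalue), False


def compare_methods(truth: pd.DataFrame, predicted: pd.DataFrame,
                    indices=None) -> pd.DataFrame:
    """Per-index agreement between matched ground-truth and predicted tables.

    Both tables are indexed by patient and share index columns.  For each
    index: paired-t p, Pearson r and p, Bland-Altman bias/limits, ICC(A,1)
    with CI, and median (IQR) of both series.  Fewer than 3 matched pairs
    suppresses the statistics with a warning.
    """
    common = truth.index.intersection(predicted.index)
    cols = list(indices) if indices is not None else [
        c for c in truth.columns if c in predicted.columns
    ]
    rows = []
    for col in cols:
        t = truth.loc[common, col].astype(float)
        p = predicted.loc[common, col].astype(float)
        keep = t.notna() & p.notna()
        t, p = t[keep].to_numpy(), p[keep].to_numpy()
        row = {"index": col, "n": int(t.size)}
        row.update(_series_summary("truth", t))
        row.update(_series_summary("pred", p))
        if t.size < 3:
            warnings.warn(f"{col}: fewer than 3 matched pairs; statistics suppressed",
                          stacklevel=2)
            rows.append(row)
            continue
        bias, lo, hi = bland_altman(p, t)
        row.update({"bias": bias, "loa_lower": lo, "loa_upper": hi})
        if np.std(t) > 0 and np.std(p) > 0:
            r, rp = stats.pearsonr(t, p)
            row.update({"pearson_r": float(r), "pearson_p": float(rp)})
        tp, zero_var = paired_t(p, t)
        row.update({"paired_t_p": tp, "paired_t_zero_variance": zero_var})
        try:
            icc, ci_lo, ci_hi = icc_a1(np.column_stack([t, p]))
            row.update({"icc": icc, "icc_ci_lower": ci_lo, "icc_ci_upper": ci_hi})
        except ZeroVarianceError:
            pass
        rows.append(row)
    return pd.DataFrame(rows).set_index("index")


def _series_summary(tag: str, x: np.ndarray) -> dict:
    if x.size == 0:
        return {}
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {f"{tag}_median": float(med), f"{tag}_iqr_lower": float(q1),
            f"{tag}_iqr_upper": float(q3)}


# ---------------------------------------------------------------------------
# stratified summaries and the training-size ablation


def stratified_eval(scores: pd.DataFrame, value: str = "dsc") -> pd.DataFrame:
    """Mean overlap per (view, structure) x image-quality stratum, 2 dp.

    ``scores`` needs columns view, structure, quality and the ``value``
    column (one row per case per structure).  Strata with no cases are
    reported absent (NaN).
    """
    for col in ("view", "structure", "quality", value):
        if col not in scores.columns:
            raise ValueError(f"scores table lacks column {col!r}")
    table = scores.pivot_table(index=["view", "structure"], columns="quality",
                               values=value, aggfunc="mean")
    order = [q for q in ("poor", "fair", "good") if q in table.columns]
    return table[order].round(2)


def size_ablation(train_images, train_masks, train_patients, test_images, test_masks,
                  fractions, config, seed: int = 0) -> pd.DataFrame:
    """Overlap-vs-training-size curve with nested patient subsets.

    For each fraction f, the first ceil(f * n) patients of one seeded
    permutation form the training set (so smaller subsets are contained in
    larger ones), one model is trained at the fixed config/seed, and mean
    foreground DSC/IoU on the fixed test set is recorded.
    """
    from echoquant import schemes, segnet

    fractions = sorted(set(float(f) for f in fractions))
    if any(not (0.0 < f <= 1.0) for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    patients = np.asarray(train_patients)
    uniq = np.unique(patients)
    order = uniq[np.random.default_rng(seed).permutation(uniq.size)]
    codes = [c for c in schemes.label_scheme(config.view) if c != schemes.BACKGROUND]
    rows = []
    for f in fractions:
        n_pat = int(np.ceil(f * uniq.size))
        if n_pat == 0:
            warnings.warn(f"fraction {f} yields no patients; skipped", stacklevel=2)
            continue
        chosen = set(order[:n_pat].tolist())
        sel = np.array([p in chosen for p in patients])
        model = segnet.build_model(config)
        segnet.train(model, np.asarray(train_images)[sel], np.asarray(train_masks)[sel],
                     config=config)
        dscs, ious = [], []
        for img, truth in zip(test_images, test_masks):
            pred = segnet.predict_mask(model, img)
            dscs.extend(dice(pred, truth, c) for c in codes)
            ious.extend(iou(pred, truth, c) for c in codes)
        rows.append({"fraction": f, "n_patients": n_pat,
                     "dsc": float(np.mean(dscs)), "iou": float(np.mean(ious))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plots (Bland-Altman / correlation, the usual agreement figure pair)


def agreement_plots(truth: pd.DataFrame, predicted: pd.DataFrame, index: str, out_path):
    """Write a correlation + Bland-Altman panel for one clinical index."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    common = truth.index.intersection(predicted.index)
    t = truth.loc[common, index].astype(float).to_numpy()
    p = predicted.loc[common, index].astype(float).to_numpy()
    keep = ~(np.isnan(t) | np.isnan(p))
    t, p = t[keep], p[keep]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.scatter(t, p, s=12)
    lims = [min(t.min(), p.min()), max(t.max(), p.max())]
    ax1.plot(lims, lims, "k--", lw=1)
    ax1.set_xlabel(f"ground truth {index}")
    ax1.set_ylabel(f"predicted {index}")
    bias, lo, hi = bland_altman(p, t)
    mean = (t + p) / 2.0
    ax2.scatter(mean, p - t, s=12)
    for yv, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax2.axhline(yv, color="k", ls=style, lw=1)
    ax2.set_xlabel(f"mean of methods ({index})")
    ax2.set_ylabel("difference (pred - truth)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
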