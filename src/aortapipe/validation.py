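"""Agreement metrics for segmentation and feature validation.

Dice similarity between binary masks, and the two-way random-effects
intraclass correlation ICC(2,1) — single measure, absolute agreement — for
comparing continuous measurements between methods or observers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "ICCResult",
    "dice",
    "icc_two_way_random",
    "agreement_report",
    "validation_sample_accounting",
]


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    p: float
    n_items: int
    n_raters: int
    form: str  # "absolute" (ICC(2,1)) or "consistency" (ICC(3,1)-style)
    valid: bool = True


@dataclass
class AgreementReport:
    mean_dice: float
    sd_dice: float
    icc: ICCResult | None
    n_items: int


def dice(x: np.ndarray, y: np.ndarray, return_flag: bool = False):
    """Sørensen-Dice coefficient 2|X∩Y|/(|X|+|Y|) of two binary masks.

    Two empty masks agree perfectly on absence: the value is 1 with the
    ``both_empty`` flag set (request it with ``return_flag``) so callers
    can exclude such items.
    """
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape:
        raise ValueError("mask shapes differ")
    total = int(x.sum()) + int(y.sum())
    both_empty = total == 0
    value = 1.0 if both_empty else 2.0 * np.logical_and(x, y).sum() / total
    return (value, both_empty) if return_flag else value


def icc_two_way_random(
    ratings: np.ndarray,
    form: str = "absolute",
    alpha: float = 0.05,
) -> ICCResult:
    """ICC from the two-way random-effects ANOVA decomposition.

    ``ratings`` is an items × raters matrix (complete, ≥ 5 items, ≥ 2
    raters). The default ``absolute`` form is ICC(2,1): single measure,
    absolute agreement, the standard choice for method comparison; the
    ``consistency`` form ignores systematic rater offsets. The confidence
    interval uses the McGraw & Wong F approximation.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be an items x raters matrix")
    n, k = m.shape
    if n < 5 or k < 2:
        raise ValueError("need >= 5 items and >= 2 raters")
    if not np.isfinite(m).all():
        raise ValueError("ratings matrix must be complete")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)  # between items
    msc = ss_cols / (k - 1)  # between raters
    mse = ss_err / ((n - 1) * (k - 1))  # residual

    if ss_total == 0:
        return ICCResult(np.nan, np.nan, np.nan, np.nan, n, k, form, valid=False)

    if form == "consistency":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        f_stat = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        f_u = stats.f.ppf(1 - alpha / 2, df1, df2)
        f_l = stats.f.ppf(1 - alpha / 2, df2, df1)
        lower = (f_stat / f_u - 1) / (f_stat / f_u + k - 1)
        upper = (f_stat * f_l - 1) / (f_stat * f_l + k - 1)
        p = stats.f.sf(f_stat, df1, df2)
        return ICCResult(float(icc), float(lower), float(upper), float(p), n, k, form)

    if form != "absolute":
        raise ValueError(f"unknown ICC form {form!r}")

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    # Satterthwaite df for the rater+error composite (McGraw & Wong)
    fj = msc / mse if mse > 0 else np.inf
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    with np.errstate(all="ignore"):
        vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd if vd > 0 else np.nan
        f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
        p = stats.f.sf(msr / mse, n - 1, (n - 1) * (k - 1)) if mse > 0 else 0.0
    del a
    return ICCResult(float(icc), float(lower), float(upper), float(p), n, k, "absolute")


def agreement_report(
    mask_pairs: list[tuple[np.ndarray, np.ndarray]] | None = None,
    ratings: np.ndarray | None = None,
) -> AgreementReport:
    """Bundle per-item Dice summaries with an ICC over paired measurements."""
    dices = np.array([dice(a, b) for a, b in mask_pairs]) if mask_pairs else np.array([])
    icc = icc_two_way_random(ratings) if ratings is not None else None
    n = len(dices) if len(dices) else (icc.n_items if icc else 0)
    return AgreementReport(
        mean_dice=float(dices.mean()) if len(dices) else float("nan"),
        sd_dice=float(dices.std(ddof=1)) if len(dices) > 1 else float("nan"),
        icc=icc,
        n_items=n,
    )


def validation_sample_accounting(
    n_studies: int = 50,
    frames_per_study: int = 10,
    removed_studies: int = 6,
    removed_images: int = 1,
) -> tuple[int, int]:
    """(images, studies) remaining after whole-study and single-image removals,
    the bookkeeping used when a manually contoured validation set is pruned
    for unusable imagery."""
    images = (n_studies - removed_studies) * frames_per_study - removed_images
    studies = n_studies - removed_studies
    return images, studies
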