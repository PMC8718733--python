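"""Two-sample Mendelian randomization with a sensitivity framework.

The causal effect of an exposure on an outcome is estimated from per-variant
summary statistics: harmonization of allele orientation (palindromic
variants with MAF > 0.42 removed, the rest aligned by allele frequency),
per-variant instrument strength (R², F = R²(n−2)/(1−R²), weak below 10),
Steiger filtering against reverse causation, the inverse-variance-weighted
estimator with multiplicative random effects as the main model, MR-Egger
with its intercept test, the Rücker Q − Q′ framework to decide between
them, and weighted-median / weighted-mode robust estimators.

Significance follows a 10-outcome Bonferroni convention: p < 0.005 is
significant, p < 0.05 suggestive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HarmonizedInstrumentSet",
    "MRResult",
    "harmonize",
    "instrument_strength",
    "steiger_filter",
    "wald_ratio",
    "ivw_re",
    "mr_egger",
    "rucker_select",
    "weighted_median",
    "weighted_mode",
    "mr_report",
    "classify_significance",
    "PALINDROME_MAF_MAX",
    "F_WEAK",
    "P_SIGNIFICANT",
    "P_SUGGESTIVE",
]

PALINDROME_MAF_MAX = 0.42
F_WEAK = 10.0
P_SIGNIFICANT = 0.005  # 0.05 / 10 outcomes
P_SUGGESTIVE = 0.05

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class HarmonizedInstrumentSet:
    """Aligned exposure/outcome effect pairs with per-variant annotations.

    ``table`` has one row per shared variant with columns beta_exposure,
    se_exposure, beta_outcome, se_outcome, eaf, n_exposure, n_outcome and
    boolean flags palindromic_removed, flipped, steiger_removed, weak
    (plus r2_exposure, r2_outcome, f_stat once filled).
    """

    table: pd.DataFrame
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    notes: dict = field(default_factory=dict)

    @property
    def retained(self) -> pd.DataFrame:
        t = self.table
        keep = ~t["palindromic_removed"]
        if "steiger_removed" in t.columns:
            keep &= ~t["steiger_removed"].fillna(False).astype(bool)
        return t.loc[keep]

    @property
    def k(self) -> int:
        return int(len(self.retained))


@dataclass
class MRResult:
    method: str
    estimate: float  # log-odds (or outcome units) per exposure SD
    se: float
    ci_low: float
    ci_high: float
    p: float
    k: int
    odds_ratio: float = np.nan
    q: float = np.nan
    q_df: int = 0
    q_p: float = np.nan
    i2: float = np.nan
    intercept: float = np.nan
    intercept_se: float = np.nan
    intercept_p: float = np.nan
    q_prime: float = np.nan
    i2_gx: float = np.nan
    selected_model: str | None = None
    tier: str | None = None


def _is_palindromic(ea: str, oa: str) -> bool:
    return frozenset((ea.upper(), oa.upper())) in _PALINDROMIC


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> HarmonizedInstrumentSet:
    """Align outcome effects to the exposure's effect allele.

    Outcome rows reported on the other allele (directly or as the strand
    complement) get their beta negated and frequency mirrored. Palindromic
    (A/T, G/C) variants are removed when MAF > 0.42 — their strand cannot be
    inferred reliably — or when frequency is missing; below that, alleles
    are aligned by frequency concordance across the two studies.
    """
    exp = exposure.set_index("SNP")
    out = outcome.set_index("SNP")
    shared = exp.index.intersection(out.index)
    rows = []
    for snp in shared:
        e, o = exp.loc[snp], out.loc[snp]
        ea_e, oa_e = str(e["EA"]).upper(), str(e["OA"]).upper()
        ea_o, oa_o = str(o["EA"]).upper(), str(o["OA"]).upper()
        beta_y, eaf_y = float(o["BETA"]), float(o["EAF"]) if np.isfinite(o["EAF"]) else np.nan
        flipped = False
        removed = False
        if _is_palindromic(ea_e, oa_e):
            maf = min(e["EAF"], 1 - e["EAF"]) if np.isfinite(e["EAF"]) else np.nan
            if not np.isfinite(maf) or not np.isfinite(eaf_y) or maf > PALINDROME_MAF_MAX:
                removed = True
            else:
                # same letters on both strands: align by frequency side
                if (e["EAF"] < 0.5) != (eaf_y < 0.5):
                    beta_y, eaf_y, flipped = -beta_y, 1 - eaf_y, True
        else:
            comp = (_COMPLEMENT.get(ea_o, "?"), _COMPLEMENT.get(oa_o, "?"))
            if (ea_o, oa_o) == (ea_e, oa_e) or comp == (ea_e, oa_e):
                pass
            elif (oa_o, ea_o) == (ea_e, oa_e) or comp[::-1] == (ea_e, oa_e):
                beta_y, eaf_y, flipped = -beta_y, 1 - eaf_y, True
            else:
                removed = True  # allele letters irreconcilable
        rows.append(
            {
                "SNP": snp,
                "beta_exposure": float(e["BETA"]),
                "se_exposure": float(e["SE"]),
                "beta_outcome": beta_y,
                "se_outcome": float(o["SE"]),
                "eaf": float(e["EAF"]),
                "n_exposure": int(e["N"]),
                "n_outcome": int(o["N"]),
                "palindromic_removed": removed,
                "flipped": flipped,
            }
        )
    return HarmonizedInstrumentSet(
        table=pd.DataFrame(rows),
        exposure_name=exposure_name,
        outcome_name=outcome_name,
    )


def instrument_strength(
    iset: HarmonizedInstrumentSet,
    outcome_binary: bool = True,
) -> HarmonizedInstrumentSet:
    """Fill per-variant R², F-statistic and the weak-instrument flag.

    For a unit-variance (inverse-rank-normalized) exposure the variance a
    variant explains is R² = 2·maf·(1−maf)·β². For a binary outcome the
    log-odds effect is mapped to the latent liability scale,
    R² = v/(v + π²/3) with v = 2·maf·(1−maf)·β²; the logistic residual
    variance π²/3 makes the exposure and outcome R² comparable for Steiger
    filtering. F = R²(n−2)/(1−R²); F ≤ 10 flags a weak instrument.
    """
    t = iset.table.copy()
    if (t["n_exposure"] <= 2).any():
        raise ValueError("exposure sample size must exceed 2")
    maf = np.minimum(t["eaf"], 1 - t["eaf"])
    var_factor = 2.0 * maf * (1.0 - maf)
    t["r2_exposure"] = var_factor * t["beta_exposure"] ** 2
    v_out = var_factor * t["beta_outcome"] ** 2
    if outcome_binary:
        t["r2_outcome"] = v_out / (v_out + np.pi**2 / 3.0)
    else:
        t["r2_outcome"] = v_out
    r2 = t["r2_exposure"].clip(upper=1 - 1e-12)
    t["f_stat"] = r2 * (t["n_exposure"] - 2) / (1.0 - r2)
    t["weak"] = t["f_stat"] <= F_WEAK
    return HarmonizedInstrumentSet(t, iset.exposure_name, iset.outcome_name, dict(iset.notes))


def steiger_filter(iset: HarmonizedInstrumentSet, alpha: float = 0.05) -> HarmonizedInstrumentSet:
    """Remove variants significantly more associated with the outcome.

    A variant is dropped iff r²_outcome > r²_exposure AND the two-sided
    z-test on the Fisher-transformed correlations (with the respective
    sample sizes) is significant at ``alpha`` — the reverse-causation
    guard: such a variant more plausibly acts through the outcome.
    """
    t = iset.table.copy()
    if "r2_exposure" not in t.columns:
        raise ValueError("run instrument_strength first")
    r_exp = np.sqrt(t["r2_exposure"].clip(0, 1 - 1e-12))
    r_out = np.sqrt(t["r2_outcome"].clip(0, 1 - 1e-12))
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / np.sqrt(
        1.0 / (t["n_exposure"] - 3) + 1.0 / (t["n_outcome"] - 3)
    )
    p = 2.0 * stats.norm.sf(np.abs(z))
    t["steiger_p"] = p
    t["steiger_removed"] = (t["r2_outcome"] > t["r2_exposure"]) & (p < alpha)
    return HarmonizedInstrumentSet(t, iset.exposure_name, iset.outcome_name, dict(iset.notes))


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> tuple[float, float]:
    """Single-variant causal estimate βY/βX with first-order SE seY/|βX|."""
    if beta_x == 0:
        raise ZeroDivisionError("exposure effect is zero")
    return beta_y / beta_x, se_y / abs(beta_x)


def _ratio_table(iset: HarmonizedInstrumentSet) -> pd.DataFrame:
    t = iset.retained
    if len(t) == 0:
        raise ValueError("no retained instruments")
    return t


def ivw_re(iset: HarmonizedInstrumentSet) -> MRResult:
    """Inverse-variance-weighted estimate with multiplicative random effects.

    Zero-intercept weighted regression of βY on βX with weights 1/seY²; the
    fixed-effect SE is inflated by √(max(1, Q/(k−1))). Cochran's Q and
    I² = max(0, (Q − df)/Q) quantify heterogeneity. With one variant this
    reduces exactly to the Wald ratio.
    """
    t = _ratio_table(iset)
    bx = t["beta_exposure"].to_numpy()
    by = t["beta_outcome"].to_numpy()
    w = 1.0 / t["se_outcome"].to_numpy() ** 2
    k = len(t)
    sxx = float(np.sum(w * bx * bx))
    est = float(np.sum(w * bx * by)) / sxx
    se_fe = np.sqrt(1.0 / sxx)
    q = float(np.sum(w * (by - est * bx) ** 2))
    q_df = k - 1
    scale = np.sqrt(max(1.0, q / q_df)) if q_df > 0 else 1.0
    se = se_fe * scale
    z = est / se
    p = 2.0 * stats.norm.sf(abs(z))
    i2 = max(0.0, (q - q_df) / q) if q > 0 and q_df > 0 else 0.0
    ci = stats.norm.ppf(0.975) * se
    return MRResult(
        method="IVW-RE", estimate=est, se=se, ci_low=est - ci, ci_high=est + ci,
        p=float(p), k=k, odds_ratio=float(np.exp(est)),
        q=q, q_df=q_df, q_p=float(stats.chi2.sf(q, q_df)) if q_df > 0 else np.nan,
        i2=float(i2),
    )


def mr_egger(iset: HarmonizedInstrumentSet) -> MRResult:
    """MR-Egger: weighted regression of βY on βX with a free intercept.

    The intercept estimates the average directional pleiotropy; a non-zero
    intercept with excess IVW heterogeneity indicates the IVW estimate is
    biased. Variants are oriented so βX ≥ 0 first (the estimator is not
    invariant to allele orientation). Q′ is the Egger residual
    heterogeneity; I²GX gauges exposure-effect measurement error (values
    above 0.95 indicate low regression-dilution risk). Needs k ≥ 3.
    """
    t = _ratio_table(iset)
    if len(t) < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    sign = np.sign(t["beta_exposure"].to_numpy())
    sign[sign == 0] = 1.0
    bx = t["beta_exposure"].to_numpy() * sign
    by = t["beta_outcome"].to_numpy() * sign
    w = 1.0 / t["se_outcome"].to_numpy() ** 2
    k = len(t)
    # weighted least squares with intercept
    sw = w.sum()
    mx = np.sum(w * bx) / sw
    my = np.sum(w * by) / sw
    sxx = np.sum(w * (bx - mx) ** 2)
    slope = float(np.sum(w * (bx - mx) * (by - my)) / sxx)
    intercept = float(my - slope * mx)
    resid = by - intercept - slope * bx
    q_prime = float(np.sum(w * resid**2))
    q_df = k - 2
    scale = np.sqrt(max(1.0, q_prime / q_df)) if q_df > 0 else 1.0
    se_slope = float(np.sqrt(1.0 / sxx)) * scale
    se_int = float(np.sqrt(1.0 / sw + mx**2 / sxx)) * scale
    p_slope = 2.0 * stats.t.sf(abs(slope / se_slope), q_df)
    p_int = 2.0 * stats.t.sf(abs(intercept / se_int), q_df)
    # weak-instrument metric for Egger: precision-weighted dispersion of βX
    se_x = t["se_exposure"].to_numpy()
    q_gx = float(np.sum(((bx - np.average(bx, weights=1 / se_x**2)) / se_x) ** 2))
    i2_gx = max(0.0, (q_gx - (k - 1)) / q_gx) if q_gx > 0 else 0.0
    tcrit = stats.t.ppf(0.975, q_df)
    return MRResult(
        method="MR-Egger", estimate=slope, se=se_slope,
        ci_low=slope - tcrit * se_slope, ci_high=slope + tcrit * se_slope,
        p=float(p_slope), k=k, odds_ratio=float(np.exp(slope)),
        q_prime=q_prime, q_df=q_df,
        intercept=intercept, intercept_se=se_int, intercept_p=float(p_int),
        i2_gx=float(i2_gx),
    )


def rucker_select(ivw: MRResult, egger: MRResult) -> str:
    """Model choice in the Rücker framework.

    IVW-RE is the default; MR-Egger takes over only when the heterogeneity
    drop Q − Q′ exceeds the χ²₁ 5% critical value AND the Egger intercept
    differs from zero at p < 0.05 (evidence of unbalanced horizontal
    pleiotropy). Both fits are always reported.
    """
    q_drop = ivw.q - egger.q_prime
    crit = stats.chi2.ppf(0.95, df=1)
    if q_drop > crit and egger.intercept_p < 0.05:
        return "MR-Egger"
    return "IVW-RE"


def _wald_ratios(t: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    bx = t["beta_exposure"].to_numpy()
    by = t["beta_outcome"].to_numpy()
    se_y = t["se_outcome"].to_numpy()
    ratios = by / bx
    se_r = se_y / np.abs(bx)
    return ratios, se_r


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w  # mid-point cumulative weights
    return float(np.interp(0.5, cum, r))


def weighted_median(
    iset: HarmonizedInstrumentSet,
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Inverse-variance-weighted median of the Wald ratios.

    Consistent when variants carrying a majority of the weight are valid.
    SE by parametric bootstrap (βX, βY resampled from their reported SEs)
    with a fixed seed. Needs k ≥ 3.
    """
    t = _ratio_table(iset)
    if len(t) < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    ratios, se_r = _wald_ratios(t)
    weights = 1.0 / se_r**2
    est = _weighted_median_point(ratios, weights)
    rng = np.random.default_rng(seed)
    bx = t["beta_exposure"].to_numpy()
    by = t["beta_outcome"].to_numpy()
    sx = t["se_exposure"].to_numpy()
    sy = t["se_outcome"].to_numpy()
    boots = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs[bxs == 0] = 1e-12
        r = bys / bxs
        w = (np.abs(bxs) / sy) ** 2
        boots[b] = _weighted_median_point(r, w)
    se = float(boots.std(ddof=1))
    p = 2.0 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
    ci = stats.norm.ppf(0.975) * se
    return MRResult(
        method="weighted-median", estimate=est, se=se,
        ci_low=est - ci, ci_high=est + ci, p=float(p), k=len(t),
        odds_ratio=float(np.exp(est)),
    )


def _mode_point(ratios: np.ndarray, weights: np.ndarray, bandwidth: float) -> float:
    grid = np.linspace(ratios.min() - 3 * bandwidth, ratios.max() + 3 * bandwidth, 2048)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / bandwidth) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def weighted_mode(
    iset: HarmonizedInstrumentSet,
    bandwidth_factor: float = 1.0,
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Mode of the smoothed inverse-variance-weighted Wald-ratio density.

    Consistent when the largest weight-share of variants (a plurality) is
    valid. Normal kernel; bandwidth = factor × 0.9·min(SD, MAD/0.6745)·
    k^(−1/5) (modified Silverman). Bootstrap SE with a fixed seed; k ≥ 3.
    """
    t = _ratio_table(iset)
    if len(t) < 3:
        raise ValueError("weighted mode needs at least 3 instruments")
    ratios, se_r = _wald_ratios(t)
    weights = 1.0 / se_r**2
    weights = weights / weights.sum()

    def bandwidth_of(r: np.ndarray) -> float:
        spread = min(np.std(r, ddof=1), stats.median_abs_deviation(r, scale="normal"))
        if spread <= 0:
            spread = max(np.std(r, ddof=1), 1e-8)
        return bandwidth_factor * 0.9 * spread * len(r) ** (-1 / 5)

    est = _mode_point(ratios, weights, bandwidth_of(ratios))
    rng = np.random.default_rng(seed)
    bx = t["beta_exposure"].to_numpy()
    by = t["beta_outcome"].to_numpy()
    sx = t["se_exposure"].to_numpy()
    sy = t["se_outcome"].to_numpy()
    boots = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs[bxs == 0] = 1e-12
        r = bys / bxs
        w = (np.abs(bxs) / sy) ** 2
        boots[b] = _mode_point(r, w / w.sum(), bandwidth_of(r))
    se = float(boots.std(ddof=1))
    p = 2.0 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
    ci = stats.norm.ppf(0.975) * se
    return MRResult(
        method="weighted-mode", estimate=est, se=se,
        ci_low=est - ci, ci_high=est + ci, p=float(p), k=len(t),
        odds_ratio=float(np.exp(est)),
    )


def classify_significance(p: float, n_outcomes: int = 10) -> str:
    """Bonferroni tiering: significant below 0.05/n_outcomes, suggestive
    below 0.05, otherwise null."""
    if not np.isfinite(p):
        return "null"
    if p < 0.05 / n_outcomes:
        return "significant"
    if p < P_SUGGESTIVE:
        return "suggestive"
    return "null"


def mr_report(
    results: dict[tuple[str, str], dict[str, MRResult]],
    instrument_p_threshold: float = 5e-8,
    n_outcomes: int = 10,
) -> pd.DataFrame:
    """Decision table: one row per (exposure, outcome, method).

    The main model's significance tier uses the Bonferroni threshold
    0.05/n_outcomes; sensitivity methods use 0.05. Records the instrument
    p-value threshold used (5×10⁻⁸ default; 1×10⁻⁶ is the relaxed option
    for sparsely instrumented exposures) and the Rücker-selected model.
    """
    rows = []
    for (exposure, outcome), methods in results.items():
        selected = None
        if "IVW-RE" in methods and "MR-Egger" in methods:
            selected = rucker_select(methods["IVW-RE"], methods["MR-Egger"])
        for name, res in methods.items():
            main = name == (selected or "IVW-RE")
            tier = classify_significance(res.p, n_outcomes if main else 1)
            rows.append(
                {
                    "exposure": exposure,
                    "outcome": outcome,
                    "method": name,
                    "estimate": res.estimate,
                    "odds_ratio": res.odds_ratio,
                    "se": res.se,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                    "k": res.k,
                    "q": res.q,
                    "q_p": res.q_p,
                    "i2": res.i2,
                    "intercept": res.intercept,
                    "intercept_p": res.intercept_p,
                    "selected_model": selected,
                    "is_main": main,
                    "tier": tier,
                    "instrument_p_threshold": instrument_p_threshold,
                }
            )
    return pd.DataFrame(rows)
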