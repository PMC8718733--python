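"""Desk-scale instrument discovery from individual-level synthetic data.

Implements the association layer a large-cohort study would run with a
mixed-model engine, reduced to OLS on unrelated individuals: variant
filters (MAF ≥ 0.5%, imputation INFO ≥ 0.3), covariate-adjusted per-variant
association on inverse-rank-normalized phenotypes, greedy LD clumping
(R² < 0.005 within a 5 Mb window on variants passing p < 1e-5, with the
genome-wide subset marked at 5e-8), ±1 Mb locus definition with cross-trait
merging, and the genomic-inflation lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantAssociation",
    "Locus",
    "filter_variants",
    "associate",
    "associate_all",
    "ld_r2_matrix",
    "greedy_clump",
    "define_loci",
    "genomic_lambda",
    "P_CLUMP",
    "P_GENOME_WIDE",
    "R2_CLUMP",
    "CLUMP_WINDOW_BP",
    "LOCUS_HALF_WIDTH_BP",
]

P_CLUMP = 1e-5
P_GENOME_WIDE = 5e-8
R2_CLUMP = 0.005
CLUMP_WINDOW_BP = 5_000_000
LOCUS_HALF_WIDTH_BP = 1_000_000
MAF_MIN = 0.005
INFO_MIN = 0.3


@dataclass
class VariantAssociation:
    snp: str
    chrom: int
    pos: int
    ea: str
    oa: str
    eaf: float
    beta: float
    se: float
    p: float
    n: int
    info: float | None = None
    flags: tuple = ()


@dataclass
class Locus:
    lead_snp: str
    chrom: int
    start: int  # 0-based half-open interval
    end: int
    lead_p: float
    traits: set = field(default_factory=set)
    members: list = field(default_factory=list)


def filter_variants(records: pd.DataFrame, maf_min: float = MAF_MIN, info_min: float = INFO_MIN) -> pd.DataFrame:
    """Keep variants with MAF ≥ ``maf_min`` and (absent or passing) INFO."""
    maf = np.minimum(records["EAF"], 1.0 - records["EAF"])
    keep = maf >= maf_min
    if "INFO" in records.columns:
        info = records["INFO"]
        keep &= info.isna() | (info >= info_min)
    return records.loc[keep].reset_index(drop=True)


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> tuple[np.ndarray, int]:
    """Residuals of y on [1, covariates]; returns (residuals, model df)."""
    n = len(y)
    design = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef, design.shape[1]


def associate(
    dosage: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    variant: dict | None = None,
) -> VariantAssociation:
    """Covariate-adjusted OLS association of one variant.

    Equivalent to the dosage coefficient of OLS(phenotype ~ dosage +
    covariates) by Frisch–Waugh partialling. A dosage (near-)collinear with
    the covariates is flagged ``collinear`` with NaN statistics; a constant
    dosage is flagged ``monomorphic``.
    """
    dosage = np.asarray(dosage, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    n = len(dosage)
    p_cov = 0 if covariates is None else np.atleast_2d(np.asarray(covariates)).reshape(n, -1).shape[1]
    if n <= p_cov + 2:
        raise ValueError("need n > number of covariates + 2")
    meta = variant or {}
    eaf = float(meta.get("EAF", dosage.mean() / 2.0))
    base = dict(
        snp=str(meta.get("SNP", "?")), chrom=int(meta.get("CHR", 0)), pos=int(meta.get("BP", 0)),
        ea=str(meta.get("EA", "A")), oa=str(meta.get("OA", "G")), eaf=eaf, n=n,
        info=meta.get("INFO"),
    )
    if np.ptp(dosage) == 0:
        return VariantAssociation(beta=np.nan, se=np.nan, p=np.nan, flags=("monomorphic",), **base)
    ry, df_cov = _residualize(phenotype, covariates)
    rx, _ = _residualize(dosage, covariates)
    sxx = float(rx @ rx)
    if sxx < 1e-10 * float(dosage @ dosage):
        return VariantAssociation(beta=np.nan, se=np.nan, p=np.nan, flags=("collinear",), **base)
    beta = float(rx @ ry) / sxx
    resid = ry - beta * rx
    df = n - df_cov - 1
    sigma2 = float(resid @ resid) / df
    se = float(np.sqrt(sigma2 / sxx))
    p = float(2.0 * stats.t.sf(abs(beta / se), df)) if se > 0 else 0.0
    flags = ()
    if sxx < 0.05 * np.var(dosage) * n:  # most dosage variance absorbed by covariates
        flags = ("collinear_inflated_se",)
    return VariantAssociation(beta=beta, se=se, p=p, flags=flags, **base)


def associate_all(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    variant_map: pd.DataFrame,
) -> pd.DataFrame:
    """Per-variant OLS scan over an (n, m) dosage matrix.

    Vectorised Frisch–Waugh: phenotype and dosages are residualized on the
    covariates once; the per-variant slope, SE and t-test then follow from
    the residual cross-products with the correct full-model df.
    """
    dosages = np.asarray(dosages, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n, m = dosages.shape
    ry, df_cov = _residualize(y, covariates)
    design = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    coef, *_ = np.linalg.lstsq(design, dosages, rcond=None)
    rx = dosages - design @ coef
    sxx = np.einsum("ij,ij->j", rx, rx)
    sxy = ry @ rx
    ok = sxx > 1e-10 * np.maximum(np.einsum("ij,ij->j", dosages, dosages), 1e-30)
    beta = np.where(ok, sxy / np.where(ok, sxx, 1.0), np.nan)
    df = n - df_cov - 1
    rss = float(ry @ ry) - np.where(ok, beta * sxy, 0.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / np.where(ok, sxx, np.nan))
    with np.errstate(invalid="ignore"):
        pvals = 2.0 * stats.t.sf(np.abs(beta / se), df)
    out = variant_map.copy().reset_index(drop=True)
    out["EAF"] = dosages.mean(axis=0) / 2.0
    out["BETA"] = beta
    out["SE"] = se
    out["P"] = pvals
    out["N"] = n
    return out


def ld_r2_matrix(dosages: np.ndarray) -> np.ndarray:
    """Empirical LD as squared Pearson correlation between dosage columns."""
    d = np.asarray(dosages, dtype=float)
    sd = d.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    z = (d - d.mean(axis=0)) / safe
    r = (z.T @ z) / len(d)
    r[sd == 0, :] = 0.0
    r[:, sd == 0] = 0.0
    return r**2


def greedy_clump(
    associations: pd.DataFrame,
    r2: np.ndarray,
    p_threshold: float = P_CLUMP,
    r2_threshold: float = R2_CLUMP,
    window_bp: int = CLUMP_WINDOW_BP,
) -> pd.DataFrame:
    """Greedy LD clumping by ascending p (ties broken by position).

    Each selected lead removes every variant with r² ≥ ``r2_threshold``
    within ±``window_bp`` on the same chromosome. The returned leads carry
    a ``genome_wide`` flag (p < 5×10⁻⁸).
    """
    df = associations.reset_index(drop=True)
    candidates = df.index[df["P"] < p_threshold]
    order = sorted(candidates, key=lambda i: (df.at[i, "P"], df.at[i, "BP"]))
    removed = np.zeros(len(df), dtype=bool)
    leads = []
    for i in order:
        if removed[i]:
            continue
        leads.append(i)
        same_chr = df["CHR"].to_numpy() == df.at[i, "CHR"]
        in_window = np.abs(df["BP"].to_numpy() - df.at[i, "BP"]) <= window_bp
        linked = r2[i] >= r2_threshold
        removed |= same_chr & in_window & linked
        removed[i] = True
    out = df.loc[leads].copy()
    out["genome_wide"] = out["P"] < P_GENOME_WIDE
    return out.reset_index(drop=True)


def define_loci(leads_per_trait: dict[str, pd.DataFrame], half_width_bp: int = LOCUS_HALF_WIDTH_BP) -> list[Locus]:
    """±1 Mb interval per lead; overlapping intervals across traits merge,
    keeping the lowest-p lead and recording every member trait."""
    entries = []
    for trait, leads in leads_per_trait.items():
        for _, row in leads.iterrows():
            start = max(0, int(row["BP"]) - half_width_bp)
            end = int(row["BP"]) + half_width_bp
            entries.append((int(row["CHR"]), start, end, float(row["P"]), str(row["SNP"]), trait))
    entries.sort(key=lambda e: (e[0], e[1]))
    loci: list[Locus] = []
    for chrom, start, end, p, snp, trait in entries:
        if loci and loci[-1].chrom == chrom and start < loci[-1].end:
            cur = loci[-1]
            cur.end = max(cur.end, end)
            cur.start = min(cur.start, start)
            cur.traits.add(trait)
            cur.members.append(snp)
            if p < cur.lead_p:
                cur.lead_p, cur.lead_snp = p, snp
        else:
            loci.append(Locus(lead_snp=snp, chrom=chrom, start=start, end=end,
                              lead_p=p, traits={trait}, members=[snp]))
    return loci


def genomic_lambda(p_values) -> float:
    """Genomic inflation factor: median association χ²₁ over its null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 100:
        raise ValueError("need at least 100 p-values")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
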