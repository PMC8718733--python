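"""Participant-level aortic phenotypes.

From the QC-retained frames of a cine study the package derives the
systolic maximum (AAomax) and diastolic minimum (AAomin) cross-sectional
lumen areas, their body-surface-area indexed counterparts, the maximum and
minimum ellipse diameters, and aortic distensibility

    AAodist = (AAomax − AAomin) / (AAomin · PP)

reported in 10⁻³ mmHg⁻¹, where PP = SBP − DBP is the pulse pressure. The
extremes over retained frames define AAomax/AAomin; being a ratio,
distensibility is invariant to the area unit.

Also here: rank-based inverse normal transform used before association
testing, the age-by-sex reference (normal values) table, and pairwise trait
correlations with Fisher-z confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FrameFeatures

__all__ = [
    "ParticipantPhenotypes",
    "compute_bsa",
    "derive_aao_phenotypes",
    "inverse_normal_transform",
    "reference_table",
    "trait_correlations",
    "AGE_BINS",
]

AGE_BINS = (-np.inf, 55.0, 65.0, 75.0, np.inf)
AGE_BIN_LABELS = ("<55", "55-65", "65-75", ">75")


@dataclass
class ParticipantPhenotypes:
    aao_max_cm2: float = np.nan
    aao_min_cm2: float = np.nan
    aao_max_idx: float = np.nan  # cm²/m²
    aao_min_idx: float = np.nan
    diameter_max_mm: float = np.nan
    diameter_min_mm: float = np.nan
    distensibility: float = np.nan  # 10⁻³ mmHg⁻¹
    pp: float = np.nan  # mmHg
    bsa: float = np.nan  # m²
    missing_reasons: tuple = ()


def compute_bsa(height_cm: float, weight_kg: float, formula: str = "dubois") -> float:
    """Body surface area in m² (Du Bois default, Mosteller selectable).

    Missing or non-positive inputs yield NaN — the missing-BSA signal that
    drives the QC exclusion of the indexed area traits.
    """
    if height_cm is None or weight_kg is None:
        return float("nan")
    height_cm, weight_kg = float(height_cm), float(weight_kg)
    if not (np.isfinite(height_cm) and np.isfinite(weight_kg)) or height_cm <= 0 or weight_kg <= 0:
        return float("nan")
    if formula == "dubois":
        return 0.007184 * weight_kg**0.425 * height_cm**0.725
    if formula == "mosteller":
        return float(np.sqrt(height_cm * weight_kg / 3600.0))
    raise ValueError(f"unknown BSA formula {formula!r}")


def derive_aao_phenotypes(
    retained_features: list[FrameFeatures],
    sbp: float | None,
    dbp: float | None,
    bsa: float | None,
) -> ParticipantPhenotypes:
    """Phenotypes from QC-retained frames; unavailable traits become NaN
    with a recorded reason rather than an exception."""
    reasons: list[str] = []
    out = ParticipantPhenotypes()
    if not retained_features:
        return ParticipantPhenotypes(missing_reasons=("no_retained_frames",))

    areas = np.array([f.area_cm2 for f in retained_features])
    diams = np.array([f.diameter_mm for f in retained_features])
    out.aao_max_cm2 = float(areas.max())
    out.aao_min_cm2 = float(areas.min())
    out.diameter_max_mm = float(np.nanmax(diams)) if np.isfinite(diams).any() else np.nan
    out.diameter_min_mm = float(np.nanmin(diams)) if np.isfinite(diams).any() else np.nan

    if bsa is not None and np.isfinite(bsa) and bsa > 0:
        out.bsa = float(bsa)
        out.aao_max_idx = out.aao_max_cm2 / bsa
        out.aao_min_idx = out.aao_min_cm2 / bsa
    else:
        reasons.append("missing_bsa")

    have_bp = sbp is not None and dbp is not None and np.isfinite(sbp) and np.isfinite(dbp)
    if have_bp and (sbp - dbp) > 0:
        out.pp = float(sbp - dbp)
        if len(retained_features) >= 2:
            out.distensibility = (out.aao_max_cm2 - out.aao_min_cm2) / (out.aao_min_cm2 * out.pp) * 1e3
        else:
            reasons.append("too_few_frames_for_distensibility")
    else:
        reasons.append("missing_blood_pressure" if not have_bp else "non_positive_pulse_pressure")
    out.missing_reasons = tuple(reasons)
    return out


def inverse_normal_transform(values, offset: float | str = 0.5) -> np.ndarray:
    """Rank-based inverse normal transform Φ⁻¹((rank − c)/(n − 2c + 1)).

    ``offset=0.5`` gives the symmetric (rank − 0.5)/n transform; the string
    ``"blom"`` selects the Blom constant 3/8. Ties get average ranks and
    missing values propagate as NaN. All-equal input is rejected.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    finite = np.isfinite(x)
    v = x[finite]
    if v.size < 2:
        raise ValueError("need at least two non-missing values")
    if np.ptp(v) == 0:
        raise ValueError("all values equal; ranks are undefined beyond ties")
    c = 3.0 / 8.0 if offset == "blom" else float(offset)
    ranks = stats.rankdata(v, method="average")
    out[finite] = stats.norm.ppf((ranks - c) / (v.size - 2.0 * c + 1.0))
    return out


def reference_table(
    phenotypes: pd.DataFrame,
    age: pd.Series | None = None,
    sex: pd.Series | None = None,
    value_columns: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Normal values per phenotype, stratified by sex (plus All) and age bin.

    Returns a long table with columns phenotype, sex, age_bin, mean, sd, n;
    empty cells get NaN mean/sd and n = 0.
    """
    df = phenotypes.copy()
    if age is not None:
        df["age"] = np.asarray(age, dtype=float)
    if sex is not None:
        df["sex"] = np.asarray(sex)
    if value_columns is None:
        value_columns = tuple(
            c for c in ("aao_min_cm2", "aao_min_idx", "aao_max_cm2", "aao_max_idx",
                        "distensibility", "diameter_min_mm", "diameter_max_mm")
            if c in df.columns
        )
    df["age_bin"] = pd.cut(df["age"], bins=list(AGE_BINS), labels=AGE_BIN_LABELS, right=False)
    sex_groups = {"All": np.ones(len(df), dtype=bool)}
    if "sex" in df.columns:
        sex_groups["Men"] = (df["sex"] == 1).to_numpy()
        sex_groups["Women"] = (df["sex"] == 0).to_numpy()
    rows = []
    for col in value_columns:
        for sex_label, sel in sex_groups.items():
            sub = df.loc[sel]
            for bin_label in AGE_BIN_LABELS:
                cell = sub.loc[sub["age_bin"] == bin_label, col].dropna()
                rows.append(
                    {
                        "phenotype": col,
                        "sex": sex_label,
                        "age_bin": bin_label,
                        "mean": cell.mean() if len(cell) else np.nan,
                        "sd": cell.std(ddof=1) if len(cell) > 1 else np.nan,
                        "n": int(len(cell)),
                    }
                )
    return pd.DataFrame(rows)


def trait_correlations(phenotypes: pd.DataFrame, columns: tuple[str, ...] | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Pearson r with Fisher-z confidence intervals.

    Pairs with fewer than 3 complete observations or zero variance are
    flagged (``valid`` False) with NaN statistics.
    """
    if columns is None:
        columns = tuple(phenotypes.select_dtypes("number").columns)
    z_crit = stats.norm.ppf(1 - alpha / 2)
    rows = []
    for i, a in enumerate(columns):
        for b in columns[i + 1 :]:
            pair = phenotypes[[a, b]].dropna()
            n = len(pair)
            x, y = pair[a].to_numpy(), pair[b].to_numpy()
            if n < 3 or np.std(x) == 0 or np.std(y) == 0:
                rows.append({"trait_a": a, "trait_b": b, "r": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "p": np.nan, "n": n, "valid": False})
                continue
            r, p = stats.pearsonr(x, y)
            if abs(r) < 1.0 and n > 3:
                z = np.arctanh(r)
                half = z_crit / np.sqrt(n - 3)
                lo, hi = np.tanh(z - half), np.tanh(z + half)
            else:
                lo = hi = r
            rows.append({"trait_a": a, "trait_b": b, "r": float(r), "ci_low": float(lo),
                         "ci_high": float(hi), "p": float(p), "n": n, "valid": True})
    return pd.DataFrame(rows)
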