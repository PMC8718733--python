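"""Synthetic cine-CMR studies and GWAS/MR summary statistics with known truth.

The generator emulates the data a population-imaging aortic study consumes:

* per-participant cine loops (default 100 frames over one cardiac cycle) in
  which the ascending-aortic lumen is a bright filled ellipse whose area
  follows a smooth raised-cosine pulse from the diastolic to the systolic
  value and back;
* flow-void artefacts as zero-mean high-frequency noise added inside the
  lumen on systolic-phase frames;
* participant covariates (age, sex, height, weight, systolic/diastolic blood
  pressure) drawn from distributions matching a late-middle-aged population
  cohort;
* genotype dosage matrices with block LD structure, and exposure/outcome
  association summary statistics with a configurable causal effect and
  pleiotropy regime.

Every stream is seeded; the same (seed, participant id) pair always yields
bit-identical images.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "CohortConfig",
    "CineStudy",
    "GroundTruth",
    "MRSimConfig",
    "generate_cine_study",
    "generate_cohort",
    "generate_covariates",
    "generate_genotypes",
    "generate_mr_summary_stats",
    "SUMSTAT_COLUMNS",
]

SUMSTAT_COLUMNS = ["SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]


class ConfigurationError(ValueError):
    """Raised when a generator configuration is invalid."""


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cine cohort.

    Area ranges are in cm² and reproduce the population means of a
    large-cohort ascending aorta study (diastolic ≈ 7.2 cm², systolic
    ≈ 8.1 cm²); blood pressure is parameterised by SBP/DBP means and SDs
    with a correlation chosen so pulse pressure has SD ≈ 13.7 mmHg.
    """

    n_participants: int = 20
    n_frames: int = 100
    image_size: tuple[int, int] = (192, 192)  # (H, W) pixels
    pixel_spacing: tuple[float, float] = (0.55, 0.55)  # mm/pixel (row, col)
    area_diastole_range: tuple[float, float] = (6.2, 8.2)  # cm²
    area_systole_range: tuple[float, float] = (7.0, 9.2)  # cm²
    artefact_probability: float = 0.1  # fraction of artefact-prone participants
    artefact_frame_rate: float = 0.3  # per systolic-phase frame, within prone participants
    artefact_amplitude: float = 60.0  # half-width of uniform brightness noise
    noise_sigma: float = 2.5  # Gaussian pixel noise SD (brightness units)
    bp_distribution: dict = field(
        default_factory=lambda: {
            "sbp": (133.6, 17.8),
            "dbp": (78.9, 8.5),
            "correlation": 0.666,
        }
    )
    anthropometry_distribution: dict = field(
        default_factory=lambda: {"height": (170.0, 9.0), "weight": (76.0, 13.0)}
    )
    age_distribution: tuple[float, float] = (64.1, 7.5)
    male_fraction: float = 0.484
    area_age_slope: float = 0.04  # cm² per year, added to both extremes
    area_sex_effect: float = 1.1  # cm², male minus female, split around the mean
    lumen_level: float = 200.0
    background_level: float = 60.0
    texture_amplitude: float = 15.0
    edge_width_px: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        if any(s <= 0 for s in self.image_size):
            raise ConfigurationError("image dimensions must be positive")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ConfigurationError("pixel spacing must be positive")
        for lo, hi in (self.area_diastole_range, self.area_systole_range):
            if lo <= 0 or hi < lo:
                raise ConfigurationError("area ranges must be positive and ordered")
        if not 0 <= self.artefact_probability <= 1:
            raise ConfigurationError("artefact_probability must be in [0, 1]")


@dataclass
class CineStudy:
    """One participant's ordered cine frames plus acquisition metadata."""

    participant_id: str
    images: np.ndarray  # (n_frames, H, W) uint8 brightness
    pixel_spacing: tuple[float, float]  # mm/pixel (row, col)
    covariates: dict  # age, sex, height, weight, sbp, dbp, pp

    @property
    def n_frames(self) -> int:
        return self.images.shape[0]


@dataclass
class GroundTruth:
    """Generative truth for a synthetic cine study."""

    masks: np.ndarray  # (n_frames, H, W) bool lumen masks
    true_areas_cm2: np.ndarray  # analytic per-frame lumen area schedule
    true_aao_max_cm2: float
    true_aao_min_cm2: float
    true_distensibility: float  # 10⁻³ mmHg⁻¹
    artefact_frames: list[int]


def _participant_rng(seed: int, participant_id: str) -> np.random.Generator:
    """Derive a per-participant stream by hashing (seed, id).

    CRC32 keeps the derived entropy word below 2³²; SeedSequence mixes it
    with the global seed so streams are independent and reproducible.
    """
    tag = zlib.crc32(str(participant_id).encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def _area_pulse(n_frames: int) -> np.ndarray:
    """Raised-cosine systolic pulse occupying the first 40% of the cycle.

    Returns the fraction of the systolic-diastolic excursion per frame:
    0 at end-diastole, 1 at the systolic peak (20% into the cycle).
    """
    t = np.arange(n_frames) / n_frames
    p = np.zeros(n_frames)
    in_pulse = t < 0.4
    p[in_pulse] = 0.5 * (1.0 - np.cos(2.0 * np.pi * t[in_pulse] / 0.4))
    return p


def _draw_participant_geometry(config: CohortConfig, rng: np.random.Generator, cov: dict):
    """Diastolic/systolic areas (cm²) plus ellipse shape for one participant."""
    d_lo, d_hi = config.area_diastole_range
    s_lo, s_hi = config.area_systole_range
    a_d = rng.uniform(d_lo, d_hi)
    a_s = rng.uniform(s_lo, s_hi)
    # age and sex shift both extremes jointly (size effect, not pulsatility)
    shift = config.area_age_slope * (cov["age"] - config.age_distribution[0])
    shift += config.area_sex_effect * (cov["sex"] - config.male_fraction)
    # optional extra per-participant shift (e.g. an injected genetic score)
    shift += float(cov.get("area_offset_cm2", 0.0) or 0.0)
    a_d = max(1.0, a_d + shift)
    a_s = max(a_d, a_s + shift)
    axis_ratio = rng.uniform(0.85, 1.0)
    orientation = rng.uniform(0.0, np.pi)
    H, W = config.image_size
    centre = (
        (H - 1) / 2.0 + rng.uniform(-4.0, 4.0),
        (W - 1) / 2.0 + rng.uniform(-4.0, 4.0),
    )
    return a_d, a_s, axis_ratio, orientation, centre


def _draw_covariates(config: CohortConfig, rng: np.random.Generator) -> dict:
    bp = config.bp_distribution
    (sbp_m, sbp_s), (dbp_m, dbp_s) = bp["sbp"], bp["dbp"]
    rho = bp.get("correlation", 0.0)
    z1, z2 = rng.standard_normal(2)
    dbp = dbp_m + dbp_s * z1
    sbp = sbp_m + sbp_s * (rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * z2)
    # pulse pressure must stay physiological for the distensibility ratio
    sbp = max(sbp, dbp + 5.0)
    anth = config.anthropometry_distribution
    height = rng.normal(*anth["height"])
    weight = rng.normal(*anth["weight"])
    age = float(np.clip(rng.normal(*config.age_distribution), 40.0, 85.0))
    sex = int(rng.uniform() < config.male_fraction)  # 1 = male
    return {
        "age": age,
        "sex": sex,
        "height": max(120.0, height),
        "weight": max(35.0, weight),
        "sbp": sbp,
        "dbp": dbp,
        "pp": sbp - dbp,
    }


def _smooth_texture(shape: tuple[int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency background texture, static across the cine loop."""
    coarse = rng.standard_normal((12, 12))
    zoom = (shape[0] / 12.0, shape[1] / 12.0)
    tex = ndimage.zoom(coarse, zoom, order=3)[: shape[0], : shape[1]]
    return amplitude * tex


def _render_frame(
    canvas: np.ndarray,
    centre: tuple[float, float],
    semi_axes: tuple[float, float],
    orientation: float,
    lumen_delta: float,
    edge_width: float,
) -> np.ndarray:
    """Add an anti-aliased filled ellipse to ``canvas``; return its mask.

    The lumen-background transition is a smoothstep ramp of ``edge_width``
    pixels in approximate signed distance, keeping the second spatial
    derivative (what the noise estimator responds to) small at the wall.
    """
    a, b = semi_axes
    H, W = canvas.shape
    margin = max(a, b) + edge_width + 2.0
    r0 = max(0, int(np.floor(centre[0] - margin)))
    r1 = min(H, int(np.ceil(centre[0] + margin)) + 1)
    c0 = max(0, int(np.floor(centre[1] - margin)))
    c1 = min(W, int(np.ceil(centre[1] + margin)) + 1)
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    dy = rr - centre[0]
    dx = cc - centre[1]
    ca, sa = np.cos(orientation), np.sin(orientation)
    u = (ca * dx + sa * dy) / a
    v = (-sa * dx + ca * dy) / b
    d = np.sqrt(u * u + v * v)
    signed = (d - 1.0) * np.sqrt(a * b)  # approx. distance to wall in px
    ramp = np.clip(0.5 - signed / edge_width, 0.0, 1.0)
    coverage = ramp * ramp * (3.0 - 2.0 * ramp)
    canvas[r0:r1, c0:c1] += lumen_delta * coverage
    mask = np.zeros((H, W), dtype=bool)
    mask[r0:r1, c0:c1] = signed <= 0.0
    return mask


def generate_cine_study(
    config: CohortConfig,
    participant_id: str,
    covariates: dict | None = None,
) -> tuple[CineStudy, GroundTruth]:
    """Render one participant's cine loop plus its generative ground truth.

    Deterministic given ``(config.seed, participant_id)``. ``covariates``
    may be supplied (e.g. by :func:`generate_cohort`); otherwise they are
    drawn from the configured distributions.
    """
    rng = _participant_rng(config.seed, participant_id)
    # always advance the stream through the covariate draw so supplying
    # covariates (e.g. from generate_cohort) leaves the imagery unchanged
    drawn = _draw_covariates(config, rng)
    cov = covariates if covariates is not None else drawn
    a_d, a_s, axis_ratio, orientation, centre = _draw_participant_geometry(config, rng, cov)

    H, W = config.image_size
    sy, sx = config.pixel_spacing
    pulse = _area_pulse(config.n_frames)
    areas_cm2 = a_d + (a_s - a_d) * pulse

    texture = _smooth_texture((H, W), config.texture_amplitude, rng)
    background = config.background_level + texture
    lumen_delta = config.lumen_level - config.background_level

    images = np.empty((config.n_frames, H, W), dtype=np.uint8)
    masks = np.empty((config.n_frames, H, W), dtype=bool)
    artefact_frames: list[int] = []
    systolic_half = np.arange(config.n_frames) / config.n_frames < 0.5
    # flow-void artefacts cluster within participants: a participant is
    # artefact-prone with probability artefact_probability, and only then
    # do individual systolic-phase frames receive artefact noise
    artefact_prone = rng.uniform() < config.artefact_probability

    for i in range(config.n_frames):
        area_px = areas_cm2[i] * 100.0 / (sx * sy)  # cm² → px²
        a = np.sqrt(area_px / (np.pi * axis_ratio))
        b = axis_ratio * a
        frame = background.copy()
        mask = _render_frame(frame, centre, (a, b), orientation, lumen_delta, config.edge_width_px)
        frame += rng.normal(0.0, config.noise_sigma, size=(H, W))
        if artefact_prone and systolic_half[i] and rng.uniform() < config.artefact_frame_rate:
            frame[mask] += rng.uniform(-config.artefact_amplitude, config.artefact_amplitude, size=int(mask.sum()))
            artefact_frames.append(i)
        images[i] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
        masks[i] = mask

    pp = cov["pp"]
    distensibility = (a_s - a_d) / (a_d * pp) * 1e3  # 10⁻³ mmHg⁻¹
    truth = GroundTruth(
        masks=masks,
        true_areas_cm2=areas_cm2,
        true_aao_max_cm2=float(a_s),
        true_aao_min_cm2=float(a_d),
        true_distensibility=float(distensibility),
        artefact_frames=artefact_frames,
    )
    study = CineStudy(
        participant_id=str(participant_id),
        images=images,
        pixel_spacing=config.pixel_spacing,
        covariates=cov,
    )
    return study, truth


def generate_covariates(config: CohortConfig) -> pd.DataFrame:
    """Cohort covariate table (one row per participant), reproducible by seed."""
    if config.n_participants < 1:
        raise ConfigurationError("n_participants must be >= 1")
    rows = []
    for i in range(config.n_participants):
        pid = f"P{i:05d}"
        rng = _participant_rng(config.seed, pid)
        cov = _draw_covariates(config, rng)
        rows.append({"participant_id": pid, **cov})
    return pd.DataFrame(rows).set_index("participant_id")


def generate_cohort(config: CohortConfig):
    """Yield ``(study, truth)`` per participant plus the covariate table.

    Returns ``(iterator, covariates)`` so callers can stream studies without
    holding the whole image cohort in memory.
    """
    covariates = generate_covariates(config)

    def _iter():
        for pid, cov in covariates.iterrows():
            yield generate_cine_study(config, pid, covariates=cov.to_dict())

    return _iter(), covariates


def generate_genotypes(
    n: int,
    m: int,
    ld_block_size: int = 10,
    within_block_r: float = 0.0,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    spacing_bp: int = 200_000,
):
    """Dosage matrix in {0,1,2} with block-compound-symmetric latent LD.

    Each haplotype's allele indicator is thresholded from a latent Gaussian
    sharing a block factor with weight √r, so within-block latent
    correlation is ``within_block_r`` and between-block correlation is 0.
    Returns ``(dosages (n, m) int8, variant_map DataFrame)``.
    """
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    if not 0 <= within_block_r < 1:
        raise ConfigurationError("within_block_r must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(maf_range[0], maf_range[1], size=m)
    thresholds = stats.norm.ppf(mafs)
    n_blocks = int(np.ceil(m / ld_block_size))
    dosages = np.zeros((n, m), dtype=np.int8)
    for hap in range(2):
        block = np.repeat(rng.standard_normal((n, n_blocks)), ld_block_size, axis=1)[:, :m]
        indep = rng.standard_normal((n, m))
        latent = np.sqrt(within_block_r) * block + np.sqrt(1 - within_block_r) * indep
        dosages += (latent < thresholds).astype(np.int8)
    variant_map = pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(m)],
            "CHR": np.ones(m, dtype=int),
            "BP": (np.arange(m) + 1) * spacing_bp,
            "maf": mafs,
            "block": np.repeat(np.arange(n_blocks), ld_block_size)[:m],
        }
    )
    return dosages, variant_map


@dataclass
class MRSimConfig:
    """Generative model for two-sample MR summary statistics.

    Outcome effects follow βY = θ·βX + α + ε where α is the pleiotropy term:
    ``none`` sets α ≡ 0 (InSIDE holds by construction), ``balanced`` draws
    α ~ N(0, sd²), ``directional`` draws α ~ N(mean, sd²) and
    ``inside_violating`` makes α correlated with instrument strength.
    """

    k_instruments: int = 60
    beta_exposure_sd: float = 0.1  # per-SD effect scale of true instruments
    theta: float = 0.0  # causal effect (outcome per exposure SD)
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.02
    pleiotropy_mean: float = 0.03  # used by `directional`
    n_exposure: int = 30_000
    n_outcome: int = 100_000
    instrument_selection_z: float = 5.45  # genome-wide significance (p < 5e-8)
    maf_range: tuple[float, float] = (0.1, 0.4)
    palindromic_fraction: float = 0.2
    outcome_allele_flip_fraction: float = 0.5  # outcome rows reported on the other allele
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_instruments < 1:
            raise ConfigurationError("k_instruments must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5 or (0 < lo <= hi <= 0.5)):
            raise ConfigurationError("maf_range must lie in (0, 0.5]")
        if self.pleiotropy_mode not in {"none", "balanced", "directional", "inside_violating"}:
            raise ConfigurationError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")


def _assign_alleles(k: int, palindromic_fraction: float, rng: np.random.Generator):
    """Effect/other allele pairs; a configurable fraction A/T or G/C."""
    pal_pairs = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
    non_pal = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"), ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]
    ea, oa = [], []
    for _ in range(k):
        pool = pal_pairs if rng.uniform() < palindromic_fraction else non_pal
        pair = pool[rng.integers(len(pool))]
        ea.append(pair[0])
        oa.append(pair[1])
    return ea, oa


def generate_mr_summary_stats(config: MRSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exposure and outcome summary-statistic tables for the same variants.

    Standard errors follow the per-SD approximation 1/√(2·maf·(1−maf)·n).
    A configurable fraction of outcome rows is reported with the allele
    orientation swapped (beta negated, EAF mirrored) so harmonization has
    real work to do; palindromic variants keep concordant strand frequency.
    """
    rng = np.random.default_rng(config.seed)
    k = config.k_instruments
    maf = rng.uniform(*config.maf_range, size=k)
    se_x = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exposure)
    se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_outcome)
    # instruments are genome-wide-significant leads: condition the true
    # effect on detectability at the configured selection threshold
    beta_true = rng.normal(0.0, config.beta_exposure_sd, size=k)
    if config.instrument_selection_z > 0:
        floor = config.instrument_selection_z * se_x
        for _ in range(1000):
            redraw = np.abs(beta_true) <= floor
            if not redraw.any():
                break
            beta_true[redraw] = rng.normal(0.0, config.beta_exposure_sd, size=int(redraw.sum()))
    beta_x = beta_true + rng.normal(0.0, se_x)

    if config.pleiotropy_mode == "none":
        alpha = np.zeros(k)
    elif config.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, config.pleiotropy_sd, size=k)
    elif config.pleiotropy_mode == "directional":
        # directional relative to the exposure-increasing allele, the frame
        # in which an Egger intercept is defined
        sign = np.where(beta_true >= 0, 1.0, -1.0)
        alpha = sign * rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=k)
    else:  # inside_violating: pleiotropy tracks instrument strength
        alpha = config.pleiotropy_mean * np.abs(beta_true) / config.beta_exposure_sd
        alpha += rng.normal(0.0, config.pleiotropy_sd, size=k)
    beta_y = config.theta * beta_true + alpha + rng.normal(0.0, se_y)

    ea, oa = _assign_alleles(k, config.palindromic_fraction, rng)
    snps = [f"rs{i + 1}" for i in range(k)]
    bp = (np.arange(k) + 1) * 1_000_000
    exposure = pd.DataFrame(
        {
            "SNP": snps,
            "CHR": 1,
            "BP": bp,
            "EA": ea,
            "OA": oa,
            "EAF": maf,
            "BETA": beta_x,
            "SE": se_x,
            "P": 2.0 * stats.norm.sf(np.abs(beta_x / se_x)),
            "N": config.n_exposure,
        }
    )
    outcome = exposure.copy()
    outcome["BETA"] = beta_y
    outcome["SE"] = se_y
    outcome["P"] = 2.0 * stats.norm.sf(np.abs(beta_y / se_y))
    outcome["N"] = config.n_outcome
    flip = rng.uniform(size=k) < config.outcome_allele_flip_fraction
    outcome.loc[flip, ["EA", "OA"]] = outcome.loc[flip, ["OA", "EA"]].to_numpy()
    outcome.loc[flip, "BETA"] = -outcome.loc[flip, "BETA"]
    outcome.loc[flip, "EAF"] = 1.0 - outcome.loc[flip, "EAF"]
    return exposure, outcome
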