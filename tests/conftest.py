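import numpy as np
import pytest

from aortapipe.segment import segment_frame_baseline
from aortapipe.synth import CohortConfig, generate_cine_study, generate_covariates


@pytest.fixture(scope="session")
def dice_fixture():
    """Artefact-free cine fixture: 20 participants x 10 frames with baseline
    segmentations paired against ground-truth masks (200 frame pairs)."""
    cfg = CohortConfig(n_participants=20, n_frames=10, artefact_probability=0.0, seed=11)
    covariates = generate_covariates(cfg)
    pairs = []
    for pid, cov in covariates.iterrows():
        study, truth = generate_cine_study(cfg, pid, covariates=cov.to_dict())
        for i in range(cfg.n_frames):
            pairs.append((segment_frame_baseline(study.images[i]), truth.masks[i]))
    return pairs


@pytest.fixture(scope="session")
def clean_study():
    """One artefact-free participant at the default study conditions."""
    cfg = CohortConfig(artefact_probability=0.0, seed=1)
    study, truth = generate_cine_study(cfg, "P00000")
    return cfg, study, truth


def disk_mask(radius: int, size: int | None = None, center=None) -> np.ndarray:
    """Rasterized disk: pixels whose centre lies within ``radius``."""
    size = size or (2 * radius + 5)
    center = center or (size // 2, size // 2)
    rr, cc = np.mgrid[:size, :size]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
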