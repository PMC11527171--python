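"""Shared fixtures: small synthetic cohorts and phantoms, built at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from betapet import roi
from betapet.roi import ScanVolume
from betapet.synthetic import SynthConfig, generate_cohort


def zero_noise_config(**overrides) -> SynthConfig:
    base = dict(
        sd_subject=0.0, sd_hemisphere=0.0, sd_slice=0.0, sd_voxel=0.0,
        gain_sd={"CON": 0.0, "LS": 0.0},
    )
    base.update(overrides)
    return SynthConfig(**base)


def cohort_delta_table(cohort) -> pd.DataFrame:
    """Normalize every scan and build the pooled delta-SUV table."""
    tabs = []
    for subj in cohort.subjects:
        f1 = roi.normalize_scan(subj.scans["F1"], cohort.brain_mask)
        f3 = roi.normalize_scan(subj.scans["F3"], cohort.brain_mask)
        tabs.append(
            roi.delta_suv(
                roi.region_suv_table(f1, cohort.mask_set),
                roi.region_suv_table(f3, cohort.mask_set),
            )
        )
    return pd.concat(tabs, ignore_index=True)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Two subjects per group, all noise off: planted effects exact."""
    return generate_cohort(zero_noise_config(seed=5, n_con=2, n_ls=2))


@pytest.fixture(scope="session")
def paper_scale_cohort():
    """Default study conditions: 9 CON vs 15 LS with calibrated noise."""
    return generate_cohort(SynthConfig(seed=13))


@pytest.fixture(scope="session")
def paper_scale_delta(paper_scale_cohort):
    return cohort_delta_table(paper_scale_cohort)


@pytest.fixture(scope="session")
def paper_scale_features(paper_scale_cohort, paper_scale_delta):
    from betapet.classify import FeatureMatrix

    means = roi.subject_region_mean(paper_scale_delta)
    return FeatureMatrix.from_subject_means(means, paper_scale_cohort.labels)


def ort_phantom(
    n_subj: int = 9,
    grid: tuple[int, int, int] = (16, 16, 16),
    block_z: int = 10,
    delta: float = 0.10,
    sigma: float = 0.05,
    seed: int = 0,
):
    """Paired already-normalized volumes with a coherent F1->F3 increase
    planted in a contiguous voxel block (block_z coronal slices)."""
    rng = np.random.default_rng(seed)
    block = np.zeros(grid, dtype=bool)
    block[:, :, :block_z] = True
    scans = []
    for i in range(n_subj):
        f1 = 1.0 + rng.normal(0.0, sigma, grid)
        f3 = 1.0 + rng.normal(0.0, sigma, grid)
        f3[block] += delta
        sid = f"S{i:02d}"
        scans.append(ScanVolume(sid, "F1", f1, normalized=True))
        scans.append(ScanVolume(sid, "F3", f3, normalized=True))
    return scans, block
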