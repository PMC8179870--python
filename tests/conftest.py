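"""Shared fixtures: tiny simulated cases and brute-force metric oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist

import raterlab as rl

COARSE = (1.5, 1.5, 1.5)  # isotropic test spacing keeping grids small


@pytest.fixture(scope="session")
def small_spec() -> rl.CohortSpec:
    """Mid-size cohort conditions on a coarse grid for fast tests."""
    return rl.CohortSpec(
        n_cases=3,
        volume_range_cm3=(25.0, 80.0),
        spacing_mm=COARSE,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_case(small_spec) -> rl.SimulatedCase:
    return rl.simulate_case(small_spec, 0)


def random_mask(
    rng: np.random.Generator, shape=(16, 16, 16), p: float = 0.5
) -> np.ndarray:
    """A random connected-ish blob: thresholded smoothed noise."""
    field = ndi.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    mask = field > np.quantile(field, 1 - p)
    return mask


def make_volume(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> rl.LabelVolume:
    return rl.LabelVolume(np.asarray(mask, dtype=bool), spacing)


# ---------------------------------------------------------------------------
# Brute-force oracles (set arithmetic and all-pairs distances)
# ---------------------------------------------------------------------------


def oracle_dice(a: np.ndarray, b: np.ndarray) -> float:
    sa = set(map(tuple, np.argwhere(a)))
    sb = set(map(tuple, np.argwhere(b)))
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    struct = ndi.generate_binary_structure(mask.ndim, 1)
    boundary = mask & ~ndi.binary_erosion(mask, structure=struct, border_value=0)
    return np.argwhere(boundary).astype(float)


def oracle_surface_distances(
    a: np.ndarray, b: np.ndarray, spacing=(1.0, 1.0, 1.0)
) -> tuple[np.ndarray, np.ndarray]:
    pa = _boundary_points(a) * np.asarray(spacing)
    pb = _boundary_points(b) * np.asarray(spacing)
    d = cdist(pa, pb)
    return d.min(axis=1), d.min(axis=0)


def oracle_hausdorff(a, b, spacing=(1.0, 1.0, 1.0)) -> float:
    dab, dba = oracle_surface_distances(a, b, spacing)
    return float(max(dab.max(), dba.max()))


def oracle_average_hausdorff(a, b, spacing=(1.0, 1.0, 1.0)) -> float:
    dab, dba = oracle_surface_distances(a, b, spacing)
    return float(max(dab.mean(), dba.mean()))
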