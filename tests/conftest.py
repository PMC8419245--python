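import logging

import numpy as np
import pytest

from capmech.cohort import CohortConfig, generate_cohort
from capmech.contours import SliceContour
from capmech.materials import MaterialParams

logging.disable(logging.WARNING)


def circle(r: float, n: int = 96) -> np.ndarray:
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def make_annulus(r_in: float = 1.5, r_out: float = 2.5, n: int = 96):
    """Concentric-circle contour set (no lipid)."""
    return {
        "lumen": SliceContour("P", "S", "baseline", "IO", "lumen", circle(r_in, n)),
        "outwall": SliceContour("P", "S", "baseline", "IO", "outwall", circle(r_out, n)),
    }


@pytest.fixture(scope="session")
def annulus():
    return make_annulus()


@pytest.fixture(scope="session")
def bench_material():
    """Isotropic Mooney–Rivlin set used against the tube-inflation oracle."""
    return MaterialParams(c1=10.0, c2=2.0, D1=5.0, D2=1.5, name="iso-bench")


@pytest.fixture(scope="session")
def bench_materials(bench_material):
    return {k: bench_material for k in ("vessel", "lipid", "calcification")}


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny synthetic cohort for fast pipeline tests."""
    return generate_cohort(CohortConfig(seed=7, n_patients=3, slices_per_patient=(3, 3)))


@pytest.fixture(scope="session")
def one_slice(small_cohort):
    return small_cohort.slices[0]
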