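import numpy as np
import pytest

from rpescreen.simulate import CohortSpec, EyeGeometry, PigmentProfile, generate_cohort


@pytest.fixture(scope="session")
def default_geometry() -> EyeGeometry:
    return EyeGeometry()


@pytest.fixture(scope="session")
def sharp_profile() -> PigmentProfile:
    """Near-step recovery fronts at 60/120 degrees."""
    return PigmentProfile(
        dark_level=50, light_level=200,
        dorsal_front_deg=60, ventral_front_deg=120,
        front_sharpness_deg=0.01,
    )


def cohort_profiles(spec: CohortSpec, target="auto", bin_size: int = 1):
    """Generate a cohort and push it through normalize + quantify."""
    from rpescreen.pipeline import reduce_cohort

    return reduce_cohort(generate_cohort(spec), target=target, bin_size=bin_size)


@pytest.fixture(scope="session")
def null_cohort_profiles():
    """One 8v8 null cohort (no knockout effect) through the full reduction."""
    return cohort_profiles(CohortSpec(n_control=8, n_knockout=8, seed=1))


def ray_cast_inside(polygon: np.ndarray, row: float, col: float) -> bool:
    """Independent even-odd point-in-polygon oracle (pure-Python ray cast)."""
    n = len(polygon)
    inside = False
    for i in range(n):
        r1, c1 = polygon[i]
        r2, c2 = polygon[(i + 1) % n]
        if (r1 > row) != (r2 > row):
            c_int = c1 + (row - r1) * (c2 - c1) / (r2 - r1)
            if col < c_int:
                inside = not inside
    return inside
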