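import numpy as np
import pytest

from habitat_ppa import (MultitypePointPattern, SyntheticConfig,
                         clinical_frame, generate_cohort)
from habitat_ppa.spatial_map import MARKS

#: unit-square window used by the CSR fixtures
UNIT = (0.0, 1.0, 0.0, 1.0)


def csr_pattern(n, rng, window=UNIT, marks=MARKS, mark_probs=None):
    """Homogeneous Poisson-like pattern (binomial n) with independent marks."""
    xmin, xmax, ymin, ymax = window
    pts = np.column_stack([rng.uniform(xmin, xmax, n),
                           rng.uniform(ymin, ymax, n)])
    mk = rng.choice(marks, size=n, p=mark_probs)
    return MultitypePointPattern(points=pts, marks=mk.astype(object),
                                 window=window)


def make_pattern(points, marks, window=UNIT):
    return MultitypePointPattern(points=np.asarray(points, dtype=float),
                                 marks=np.asarray(marks, dtype=object),
                                 window=window)


@pytest.fixture(scope="session")
def small_cohort():
    """12 patients, small images, planted hazard on the Simpson index."""
    cfg = SyntheticConfig(n_patients=12, image_side=64,
                          roi_radius_range=(8, 12), seed=42,
                          hazard_coefficient=1.0)
    pairs, records = generate_cohort(cfg)
    return cfg, pairs, clinical_frame(records)


@pytest.fixture(scope="session")
def example_pair(small_cohort):
    return small_cohort[1][0]
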