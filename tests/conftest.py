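import numpy as np
import pandas as pd
import pytest

from histoprog.synthetic import (CohortConfig, counts_to_fractions,
                                 default_texture_params, generate_cohort,
                                 generate_slide)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort (n=60, k=10) shared across tests."""
    cfg = CohortConfig(n_patients=60, n_clusters=10, cohort="internal",
                       patches_per_sample=(100, 200), seed=7)
    patients, counts = generate_cohort(cfg)
    return patients, counts, counts_to_fractions(counts)


@pytest.fixture(scope="session")
def textured_patches():
    """Labelled procedural texture patches for 10 clusters.

    Returns ``(patches, labels)`` with 40 patches per cluster, rendered via
    the slide generator so they match what the pipeline sees.
    """
    k = 10
    params = default_texture_params(k, patch_px=16)
    counts = np.full(k, 40)
    img, truth = generate_slide(counts, params, seed=11)
    patches = [img[r.y0:r.y1, r.x0:r.x1] for r in truth.itertuples()]
    return patches, truth["cluster"].to_numpy()
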