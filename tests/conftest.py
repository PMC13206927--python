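from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_panel():
    """3 groups x 4 biomarkers with hand-picked means, mixed directions."""
    from ibrtox.ibr import panel_from_means

    means = pd.DataFrame(
        [[1.0, 10.0, 5.0, 0.2], [2.0, 6.0, 5.5, 0.8], [1.5, 8.0, 4.0, 0.5]],
        index=["control", "toxicant", "pretreated"],
        columns=["AIF", "ATP", "ROS", "TUNEL"],
    )
    directions = {"AIF": "up", "ATP": "down", "ROS": "up", "TUNEL": "up"}
    return panel_from_means(means, directions)


@pytest.fixture
def random_panel_factory():
    """Random small panels for oracle-equivalence checks."""
    from ibrtox.ibr import BiomarkerPanel

    def make(seed: int, n_groups: int | None = None, n_bio: int | None = None):
        rng = np.random.default_rng(seed)
        g = n_groups or int(rng.integers(2, 7))
        b = n_bio or int(rng.integers(2, 9))
        X = rng.uniform(0.1, 20.0, size=(g, b))
        biomarkers = [f"B{j}" for j in range(b)]
        dirs = {m: ("up" if rng.random() < 0.5 else "down") for m in biomarkers}
        return BiomarkerPanel(
            groups=[f"grp{i}" for i in range(g)],
            biomarkers=biomarkers,
            directions=dirs,
            X=X,
        )

    return make
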