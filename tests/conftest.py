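import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def geometry():
    from ymaze import MazeGeometry

    return MazeGeometry()


@pytest.fixture
def published_cells() -> pd.DataFrame:
    """The six survival cell summaries reported for the 2x3 experiment
    (per-jar survival %, ten jars per cell)."""
    return pd.DataFrame(
        {
            "predator": ["no", "no", "no", "yes", "yes", "yes"],
            "drug": ["none", "5htp", "amw", "none", "5htp", "amw"],
            "mean": [30.0, 32.0, 30.0, 62.0, 65.0, 35.0],
            "sd": [9.4, 6.3, 15.0, 11.4, 8.5, 7.1],
            "n": [10] * 6,
        }
    )


def random_balanced_survival(rng: np.random.Generator, n: int = 10) -> pd.DataFrame:
    """Random fully-crossed balanced 2x3 dataset of per-jar percentages."""
    rows = []
    for predator in ("no", "yes"):
        for drug in ("none", "5htp", "amw"):
            base = rng.uniform(20, 80)
            for _ in range(n):
                rows.append(
                    {
                        "predator": predator,
                        "drug": drug,
                        "percent": base + rng.normal(0, rng.uniform(3, 15)),
                    }
                )
    return pd.DataFrame(rows)
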