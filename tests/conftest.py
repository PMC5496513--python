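import numpy as np
import pandas as pd
import pytest
from scipy.special import expit


@pytest.fixture
def tiny_records() -> pd.DataFrame:
    """Three valid quadrats at one site, hand-written."""
    return pd.DataFrame(
        {
            "quadrat_id": ["q0", "q1", "q2"],
            "site_id": ["A", "A", "A"],
            "lon": [151.2500, 151.2501, 151.2502],
            "lat": [-33.8400, -33.8401, -33.8402],
            "altitude_m": [1.5, 2.0, 2.5],
            "k": [5, 0, 25],
            "m": [25, 25, 25],
            "depth_m": [4.0, 5.0, 6.0],
            "reef": [True, True, False],
            "track_order": [0, 1, 2],
        }
    )


def make_glm_records(
    seed: int,
    n: int = 300,
    beta: tuple = (-1.0, 0.004, -0.003, -0.15, 0.8),
    m: int = 25,
) -> pd.DataFrame:
    """Quadrat table with known GLM coefficients and no latent field.

    beta = (intercept, lat [y], long [x], bath [depth], reef); covariates are
    drawn i.i.d. so the Wald machinery is exactly correctly specified.
    """
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 500, n)
    y = rng.uniform(0, 500, n)
    depth = rng.uniform(1, 15, n)
    reef = rng.random(n) < 0.7
    eta = beta[0] + beta[1] * y + beta[2] * x + beta[3] * depth + beta[4] * reef
    k = rng.binomial(m, expit(eta))
    return pd.DataFrame(
        {
            "quadrat_id": [f"g{i}" for i in range(n)],
            "site_id": "G",
            "x": x,
            "y": y,
            "depth_m": depth,
            "reef": reef,
            "k": k,
            "m": m,
        }
    )


def make_site_track(
    seed: int,
    n: int = 735,
    range_m: float = 25.0,
    sill: float = 1.2,
    nugget: float = 0.1,
    alpha: float = -1.4,
    tag: str = "T",
    m: int = 25,
):
    """(positions, covers, records) for one synthetic site with a flat seabed
    (depth effect off), the workhorse input for spatial tests."""
    from kelpscape import synth
    from kelpscape._seeds import rng_for

    cfg = synth.SiteConfig(
        site_id=tag, n_quadrats=n, range_m=range_m, sill=sill, nugget=nugget, alpha=alpha
    )
    t = synth.generate_track(cfg, rng_for(seed, tag, "t"))
    x, y = t["x"].to_numpy(), t["y"].to_numpy()
    z = synth.generate_latent_field(x, y, range_m, sill, nugget, rng_for(seed, tag, "f"))
    p = synth.cover_probabilities(z, np.zeros(n), alpha, 0.0)
    k = synth.sample_counts(p, m, 0.0, rng_for(seed, tag, "c"))
    records = pd.DataFrame(
        {
            "site_id": tag,
            "track_order": np.arange(n),
            "x": x,
            "y": y,
            "k": k,
            "m": m,
        }
    )
    return np.column_stack([x, y]), k / m, records
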