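import numpy as np
import pytest

from mrdiv import HarmonizedPanel, HarmonizedVariant, SimulationConfig, simulate_study


def build_panel(beta_x, se_x, beta_y, se_y, rsids=None) -> HarmonizedPanel:
    n = len(beta_x)
    rsids = rsids or [f"rs{i + 1}" for i in range(n)]
    return HarmonizedPanel(
        exposure_label="exposure",
        outcome_label="outcome",
        variants=[
            HarmonizedVariant(
                rsid=rsids[i],
                beta_x=float(beta_x[i]),
                se_x=float(se_x[i]),
                beta_y=float(beta_y[i]),
                se_y=float(se_y[i]),
            )
            for i in range(n)
        ],
    )


@pytest.fixture
def panel_factory():
    return build_panel


@pytest.fixture
def random_panel_factory():
    """Panels with a common slope 0.4 plus weighted-residual noise."""

    def make(n: int, seed: int, slope: float = 0.4) -> HarmonizedPanel:
        rng = np.random.default_rng(seed)
        beta_x = rng.uniform(0.01, 0.05, n) * rng.choice([-1, 1], n)
        se_x = rng.uniform(0.002, 0.004, n)
        se_y = rng.uniform(0.01, 0.03, n)
        beta_y = slope * beta_x + rng.normal(0, se_y)
        return build_panel(beta_x, se_x, beta_y, se_y)

    return make


@pytest.fixture(scope="session")
def default_study():
    return simulate_study(SimulationConfig(seed=42))
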