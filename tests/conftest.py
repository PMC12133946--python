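import numpy as np
import pandas as pd
import pytest

from lumigrow import LongitudinalDataset, build_design
from lumigrow.bayes import PosteriorDraws
from lumigrow.simulate import SimulationConfig, simulate_growth


@pytest.fixture(scope="session")
def two_arm_ds():
    """Default synthetic cohort: 6 control, 4 treated, 10 timepoints."""
    return simulate_growth(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def clean_two_arm_ds():
    """Two-arm cohort without missingness (for exact structural checks)."""
    return simulate_growth(
        SimulationConfig(seed=7, n_control=5, n_treatment=5, missing_rate=0.0)
    )


def make_multi_condition_ds(n_conditions: int, seed: int = 0, n_units: int = 4,
                            missing_rate: float = 0.0) -> LongitudinalDataset:
    """Concatenate relabeled two-arm simulations into an n-condition dataset."""
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_conditions):
        cfg = SimulationConfig(
            n_control=n_units, n_treatment=0, seed=int(rng.integers(2**31)),
            missing_rate=missing_rate,
            base_slope=0.05 + 0.01 * i,
        )
        df = simulate_growth(cfg).df.copy()
        df["condition"] = f"C{i:02d}"
        df["unit_id"] = df["unit_id"] + f"_c{i:02d}"
        df["parent_id"] = df["parent_id"] + f"_c{i:02d}"
        frames.append(df)
    return LongitudinalDataset(df=pd.concat(frames, ignore_index=True), log_base=10)


def synthetic_draws(design, coef: dict, n_draws: int = 400, jitter: float = 0.0,
                    seed: int = 0) -> PosteriorDraws:
    """Fabricated posterior draws with given coefficient centers (testing aid)."""
    rng = np.random.default_rng(seed)
    cols = {"chain": np.repeat([0, 1], n_draws // 2)}
    for lab in design.labels:
        center = coef.get(lab, 0.0)
        cols[lab] = center + (jitter * rng.standard_normal(n_draws) if jitter else 0.0)
    for u in design.unit_labels:
        cols[f"b[{u}]"] = coef.get(f"b[{u}]", 0.0) + np.zeros(n_draws)
    cols["sigma"] = np.full(n_draws, coef.get("sigma", 1.0))
    cols["sigma_b"] = np.full(n_draws, coef.get("sigma_b", 1.0))
    return PosteriorDraws(table=pd.DataFrame(cols), meta={"n_chains": 2})


@pytest.fixture(scope="session")
def linear_design(clean_two_arm_ds):
    return build_design(clean_two_arm_ds)
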