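import numpy as np
import pytest

import screenkit as sk


@pytest.fixture(scope="session")
def ten_point_design() -> sk.DoseDesign:
    return sk.DoseDesign.ten_point()


@pytest.fixture(scope="session")
def noiseless_plate_set():
    """A two-cell-line plate set simulated without noise."""
    truth = sk.GroundTruthCompound(
        "cmpdA",
        {"LINE1": (-1.0, 100.0, 0.0, 1e-7), "LINE2": (-1.0, 100.0, 0.0, 1e-6)},
    )
    config = sk.SimulationConfig(noise_sigma=0.0, seed=11)
    plate_table, truth_table = sk.simulate_plate_set(
        [truth], config, sk.DoseDesign.ten_point(replicates=2)
    )
    return plate_table, truth_table


def random_truth(rng: np.random.Generator, compound_id: str = "c") -> sk.GroundTruthCompound:
    """A realistic decreasing viability curve with the midpoint inside the
    tested range."""
    return sk.GroundTruthCompound(
        compound_id,
        {
            "L": (
                -float(rng.uniform(0.5, 3.0)),
                float(rng.uniform(80.0, 100.0)),
                float(rng.uniform(0.0, 20.0)),
                float(10 ** rng.uniform(-8.5, -5.5)),
            )
        },
    )
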