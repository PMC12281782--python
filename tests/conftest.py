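import numpy as np
import pandas as pd
import pytest

from methfield.datamodel import BetaMatrix
from methfield.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort shared by read-only tests."""
    cfg = SimulationConfig(n_probes=800, n_filter_fail=12, seed=123)
    beta, samples, patients, annotation, truth = generate_cohort(cfg)
    return {
        "config": cfg,
        "beta": beta,
        "samples": samples,
        "patients": patients,
        "annotation": annotation,
        "truth": truth,
    }


@pytest.fixture()
def tiny_beta():
    """A hand-sized 4-probe x 6-sample beta matrix over 3 patients."""
    rng = np.random.default_rng(7)
    samples = pd.DataFrame(
        {
            "sample_id": ["a1", "a2", "b1", "b2", "c1", "c2"],
            "patient_id": ["A", "A", "B", "B", "C", "C"],
            "tissue_class": [
                "cancer", "normal_adjacent", "cancer", "normal_distant",
                "cancer", "normal_adjacent",
            ],
            "cancer_area_pct": [90.0, 0.0, 80.0, 0.0, 70.0, 0.0],
        }
    )
    df = pd.DataFrame(
        rng.uniform(0.2, 0.8, (4, 6)),
        index=[f"cg{i}" for i in range(4)],
        columns=samples["sample_id"],
    )
    return BetaMatrix(df), samples
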