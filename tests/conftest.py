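import numpy as np
import pytest

from joigam import CohortTable, GeneratorSpec, make_ncanda_like


@pytest.fixture
def tiny_table():
    """Hand-built 8-subject table: 2 structural + 1 diffusion metric, SES present."""
    rng = np.random.default_rng(7)
    n = 8
    return CohortTable(
        subject_ids=np.array([f"P{i}" for i in range(n)], dtype=object),
        labels=np.array([-1, -1, -1, -1, -1, 1, 1, 1]),
        age=np.array([12.0, 14.5, 16.0, 18.0, 20.0, 19.0, 20.5, 21.0]),
        metrics=rng.normal(size=(n, 3)),
        metric_names=["vol_a", "vol_b", "fa_c"],
        modality_tags=["STR", "STR", "DTI"],
        ses=np.array([12.0, 14.0, 16.0, 18.0, 15.0, 17.0, 19.0, 16.0]),
        supratentorial_volume=rng.normal(1250, 100, n),
        categoricals={
            "sex": np.array(list("MFMFMFMF"), dtype=object),
            "scanner": np.array(["GE", "GE", "S", "S", "GE", "GE", "S", "GE"], dtype=object),
        },
    )


SMALL_SPEC = GeneratorSpec(
    n_controls=160, n_cases=24, n_str=6, n_dti=8, pattern_size=2, delta=1.5
)


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced confounded cohort with known 2-metric pattern (fast tests)."""
    return make_ncanda_like(SMALL_SPEC, seed=11)
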