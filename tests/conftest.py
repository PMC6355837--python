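import numpy as np
import pandas as pd
import pytest

from methconcord import synthdata as sd


def two_tissue_config(**kwargs) -> sd.SynthConfig:
    """A minimal brain/blood design with a single cell type, so cross-tissue
    structure comes only from the shared subject effect and noise."""
    base = dict(
        n_subjects=21,
        n_probes=500,
        tissues=("brain", "blood"),
        cell_types=("cell",),
        tissue_mixture_params={"brain": {"cell": 1.0}, "blood": {"cell": 1.0}},
        variable_fraction=1.0,
        seed=11,
    )
    base.update(kwargs)
    return sd.SynthConfig(**base)


@pytest.fixture(scope="session")
def small_cohort() -> sd.CohortBundle:
    """Default four-tissue mixture-structured cohort, 21 subjects x 800 probes."""
    return sd.generate_cohort(sd.SynthConfig(n_probes=800, seed=11))


@pytest.fixture(scope="session")
def paired_cohort() -> sd.CohortBundle:
    """Two-tissue single-cell-type cohort with moderate shared subject effect."""
    return sd.generate_cohort(two_tissue_config(subject_effect_sd=0.5, noise_sd=0.5))


def make_sheet(subjects, tissues):
    rows = [
        {"sample": f"{s}_{t}", "subject": s, "tissue": t, "day_offset": 0}
        for s in subjects
        for t in tissues
    ]
    return pd.DataFrame(rows)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
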