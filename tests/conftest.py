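import numpy as np
import pandas as pd
import pytest

from convmine.io import ExpressionDataset
from convmine.pipeline import run_analysis
from convmine.simulate import StudyConfig, TfSpec, conversion_map, generate_study


def small_config(**overrides) -> StudyConfig:
    """A three-conversion, six-dataset study small enough for unit tests."""
    kwargs = dict(
        n_genes=400,
        conversions=(("alpha", 1, 3), ("beta", 3, 3), ("gamma", 2, 3), ("delta", 2, 3)),
        common_up=8,
        common_down=8,
        specific_per_conversion=5,
        tf_regulons=(
            TfSpec("MASTER1", regulon_size=30, de_fraction=0.6),
            TfSpec("MASTER2", regulon_size=30, de_fraction=0.6),
            TfSpec("MASTER3", regulon_size=30, de_fraction=0.6),
            TfSpec("MASTER4", regulon_size=30, de_fraction=0.6),
            TfSpec("DECOY1", regulon_size=30, de_fraction=0.0, effect_log2=0.0),
            TfSpec("DECOY2", regulon_size=30, de_fraction=0.0, effect_log2=0.0),
        ),
        seed=7,
    )
    kwargs.update(overrides)
    return StudyConfig(**kwargs)


@pytest.fixture(scope="session")
def small_noiseless_study():
    cfg = small_config(noise_sd_log2=0.0)
    datasets, regulon_db, term_db, truth = generate_study(cfg)
    return cfg, datasets, regulon_db, term_db, truth


@pytest.fixture(scope="session")
def small_noiseless_result(small_noiseless_study):
    cfg, datasets, regulon_db, term_db, truth = small_noiseless_study
    result = run_analysis(datasets, conversion_map(cfg), regulon_db, term_db)
    return result, truth, regulon_db


@pytest.fixture(scope="session")
def default_study_seed1():
    """The full-scale default study at seed 1 (shared across test modules)."""
    cfg = StudyConfig(seed=1)
    datasets, regulon_db, term_db, truth = generate_study(cfg)
    result = run_analysis(datasets, conversion_map(cfg), regulon_db, term_db)
    return cfg, datasets, regulon_db, term_db, truth, result


def make_dataset(values, groups, dataset_id="ds1", genes=None, samples=None):
    """Small ExpressionDataset from a plain array."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionDataset(dataset_id=dataset_id, values=df,
                             groups=dict(zip(samples, groups)))
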