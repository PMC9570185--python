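import pytest

from oxysig.preprocess import preprocess_pipeline
from oxysig.synthetic import SimulationConfig, generate_study


def preprocessed(synthetic_study):
    """Matched study with its matrix imputed, logged and standardized."""
    std, params, report = preprocess_pipeline(synthetic_study.matched_study.matrix)
    return synthetic_study.matched_study.with_matrix(std), params, report


@pytest.fixture(scope="session")
def small_signal_study():
    """30 pairs, 12 analytes, 2 strong signals: quick but non-trivial."""
    cfg = SimulationConfig(
        n_pairs=30, n_analytes=12, n_signal=2, effect_sizes=1.2, seed=42
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def small_study_prepped(small_signal_study):
    study, _, _ = preprocessed(small_signal_study)
    return study, small_signal_study.truth


@pytest.fixture(scope="session")
def discovery_scale_study():
    """One discovery-sized cohort (137 pairs, 54 analytes, 5 signals)."""
    cfg = SimulationConfig(
        n_pairs=137, n_analytes=54, n_signal=5, effect_sizes=0.8, seed=1,
        cohort="discovery",
    )
    return generate_study(cfg)
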