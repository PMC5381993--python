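import pytest

from gfcohort.pipeline import GFormulaModel
from gfcohort.synthetic import GeneratorParams, generate_cohort


@pytest.fixture(scope="session")
def small_params():
    """Default generating parameters scaled to a 1,500-worker cohort."""
    return GeneratorParams.from_config(n_workers=1500)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    baseline, history, truth = generate_cohort(small_params, seed=20250917)
    return baseline, history, truth


@pytest.fixture(scope="session")
def fitted_small(small_params, small_cohort):
    """Model suite fitted to the small cohort with the generating knots."""
    baseline, history, _ = small_cohort
    model = GFormulaModel(
        baseline,
        history,
        {"pipeline": {"knots": list(small_params.knots), "mc_size": 3000}},
    )
    return model.fit()
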