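import numpy as np
import pytest
from hypothesis import settings

from voe.simulate import GeneratorSpec, VarDef, generate_cohort

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def small_generator_spec(n: int = 600, seed: int | None = None) -> GeneratorSpec:
    """Compact mortality-like cohort: continuous exposure, age/sex baseline,
    three optional adjustments of mixed type."""
    corr = 0.3 ** np.abs(np.subtract.outer(np.arange(6), np.arange(6)))
    return GeneratorSpec(
        n=n,
        var_defs=(
            VarDef("exposure", "continuous", "exposure"),
            VarDef("age", "continuous", "baseline_adjustment", error_free=True),
            VarDef("sex", "binary", "baseline_adjustment", (0.0,), True),
            VarDef("smoking", "binary", "adjustment", (0.6,)),
            VarDef("bmi", "continuous", "adjustment"),
            VarDef("education", "ordinal", "adjustment", (-0.6, 0.5)),
        ),
        corr=corr,
        log_hazards=(0.3, 0.4, 0.15, 0.2, 0.1, -0.1),
        baseline_rate=0.1,
        censor_rate=0.15,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_generator_spec(600), seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
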