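import numpy as np
import pytest

import melonopt as m

#: Desk-scale training/search settings used throughout the suite; the
#: library defaults stay at the full published values.
FAST_SURROGATE = dict(restarts=2, max_epochs=150)
FAST_GA = dict(generations=40)


@pytest.fixture(scope="session")
def quality_matrix() -> m.DecisionMatrix:
    """The bundled 10 x 9 treatment x quality-indicator mean table."""
    return m.DecisionMatrix.from_dataset(m.builtin_fixture("quality_table4"))


@pytest.fixture(scope="session")
def grid_model():
    """Surrogate trained on a full-grid synthetic trial (fixed seed)."""
    sc = m.full_grid_scenario(seed=11)
    ds = m.generate_trial(sc)
    model, report = m.train_surrogate(
        ds, m.SurrogateConfig(seed=11, **FAST_SURROGATE)
    )
    return model


@pytest.fixture(scope="session")
def paper_like_model():
    """Surrogate trained on the 10-treatment design with observed-trial
    indicator quality (TOPSIS Ci) and scenario-filled yields."""
    ds = m.builtin_fixture("design_table2")
    ds.merge(m.builtin_fixture("phenology_table3"))
    ds.merge(m.builtin_fixture("quality_table4"))
    ds.merge(m.builtin_fixture("yields_text"))
    m.topsis_from_dataset(ds)
    m.fill_missing_yields(ds, m.paper_like_scenario())
    model, _ = m.train_surrogate(ds, m.SurrogateConfig(seed=5, **FAST_SURROGATE))
    return model
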