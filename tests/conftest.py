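import numpy as np
import pandas as pd
import pytest

from mhss import (IndicatorPanel, IndicatorSpec, generate_panel,
                  interpolate_missing, score)
from mhss.synthetic import SynthConfig, noiseless


@pytest.fixture(scope="session")
def default_run():
    """One default synthetic run shared across tests (seed fixed)."""
    return generate_panel(SynthConfig(), seed=11)


@pytest.fixture(scope="session")
def default_scores(default_run):
    panel, controls, scheme, truth = default_run
    return score(interpolate_missing(panel))


@pytest.fixture(scope="session")
def noiseless_run():
    return generate_panel(noiseless(), seed=7)


def make_small_panel(values: dict[str, list], provinces, years,
                     attributes=None) -> IndicatorPanel:
    """Small panel helper: values[indicator] in (province-major, year-minor)
    order."""
    attributes = attributes or {}
    specs = [IndicatorSpec(k, "dim1", attributes.get(k, "positive"))
             for k in values]
    index = pd.MultiIndex.from_product([provinces, years],
                                       names=["province", "year"])
    df = pd.DataFrame({k: np.asarray(v, dtype=float)
                       for k, v in values.items()}, index=index)
    return IndicatorPanel(specs, df)
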