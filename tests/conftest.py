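"""Shared fixtures: small synthetic cohorts, fitted once per session."""

import numpy as np
import pytest

from recalib.fitting import FitConfig, fit
from recalib.simulate import GeneratorConfig, generate_dataset, paper_like_group
from recalib.trials import aggregate, table_to_celldata


@pytest.fixture(scope="session")
def small_cohort():
    """Five participants, full design, paper-like generating values."""
    trials, truth = generate_dataset(
        GeneratorConfig(group=paper_like_group(), n_participants=5, seed=42)
    )
    table = aggregate(trials)
    return {"trials": trials, "truth": truth, "table": table,
            "cells": table_to_celldata(table)}


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """The small cohort fitted with two starts (reused across tests)."""
    return fit(small_cohort["cells"], FitConfig(n_starts=2, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
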