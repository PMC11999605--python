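import numpy as np
import pandas as pd
import pytest

from eicostats.datatypes import (
    CohortDataset,
    ConcentrationMatrix,
    Metabolite,
    Panel,
    SampleMeta,
)
from eicostats.simulate import EffectSpec, SimConfig


@pytest.fixture
def small_panel() -> Panel:
    return Panel(
        (
            Metabolite("LTE4", frozenset({"5-LOX"}), 0.0005),
            Metabolite("15-HETE", frozenset({"15-LOX"}), 0.01),
            Metabolite("PGE2", frozenset({"COX"}), 0.02),
            Metabolite("18-HEPE", frozenset({"CYP", "COX"}), 0.01),
            Metabolite("9-HETE", frozenset({"AUTOX"}), 0.01),
        )
    )


def make_matrix(condition, values, censored=None, subjects=None, metabolites=None):
    """Build a ConcentrationMatrix from plain arrays."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    subjects = subjects or [f"s{i + 1}" for i in range(n)]
    metabolites = metabolites or [f"m{j + 1}" for j in range(m)]
    idx = pd.Index(subjects, name="subject_id")
    cols = pd.Index(metabolites, name="metabolite")
    if censored is None:
        censored = np.zeros((n, m), dtype=bool)
    return ConcentrationMatrix(
        condition,
        pd.DataFrame(values, index=idx, columns=cols),
        pd.DataFrame(np.asarray(censored, dtype=bool), index=idx, columns=cols),
    )


@pytest.fixture
def make_concentration_matrix():
    return make_matrix


def null_config(
    panel=None,
    n_per_group=20,
    n_metabolites=10,
    seed=0,
    release_log_sd=1.0,
    lod=1e-9,
    effects=(),
):
    """A two-group (control vs moderate) configuration with no group effect
    unless ``effects`` plants one; tiny LOD means no censoring."""
    if panel is None:
        panel = Panel(
            tuple(
                Metabolite(f"m{j + 1}", frozenset({"COX"}), lod)
                for j in range(n_metabolites)
            )
        )
    ids = panel.ids
    return SimConfig(
        panel=panel,
        n_control=n_per_group,
        n_moderate=n_per_group,
        n_severe=0,
        n_severe_ocs=0,
        baseline_log_median={m: 0.0 for m in ids},
        baseline_log_sd={m: 0.5 for m in ids},
        release_log_median={m: 1.0 for m in ids},
        release_log_sd={m: release_log_sd for m in ids},
        wbc={"control": (6.0, 1.5), "moderate": (7.9, 2.6), "severe": (7.9, 2.6)},
        wbc_ref=6.0,
        effects=tuple(EffectSpec(*e) for e in effects),
        seed=seed,
    )


@pytest.fixture
def make_null_config():
    return null_config
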