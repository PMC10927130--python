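import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from rptfusion.pipeline import build_cohort_table
from rptfusion.simulate import Coupling, SimulationConfig, generate_cohort

#: couplings used by the recovery-style fixtures: two planted
#: structure-behavior relationships per group, |rho| >= 0.5
PLANTED = (
    Coupling("Left Putamen", "mean_k_inc", "CTRL", -0.5),
    Coupling("Left Thalamus", "polar_angle", "CTRL", 0.5),
    Coupling("Right Amygdala", "negative_offset", "MDD", -0.6),
    Coupling("Left Pallidum", "loss_resilience", "MDD", 0.55),
    Coupling("Right Thalamus", "loss_resilience", "CD", -0.5),
    Coupling("Left Ventral Diencephalon", "radial_dispersion", "CD", 0.6),
)


def make_responses(counts_by_category, participant_id="p1", valence="dec"):
    """Build a long-format response table from {category: [counts...]}."""
    rows = []
    for cat, counts in counts_by_category.items():
        for j, c in enumerate(counts):
            rows.append((participant_id, cat, f"pic{j + 1}", valence, int(c)))
    return pd.DataFrame(
        rows, columns=["participant_id", "category", "picture", "valence", "keypresses"]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 12/12/12 null cohort (no planted couplings), deterministic."""
    cfg = SimulationConfig(
        seed=11, n_per_group={"CTRL": 12, "MDD": 12, "CD": 12}
    )
    ds = generate_cohort(cfg)
    return ds, build_cohort_table(ds.responses, ds.participants)


@pytest.fixture(scope="session")
def coupled_cohort():
    """A study-sized cohort (40/25/46) with the planted couplings."""
    cfg = SimulationConfig(seed=7, coupling_spec=PLANTED)
    ds = generate_cohort(cfg)
    return ds, build_cohort_table(ds.responses, ds.participants)
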