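import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

from endopanel.pipeline import PipelineConfig, analyse_cohort
from endopanel.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default 47-sample cohort shared across read-only tests."""
    return simulate_cohort(seed=11)


@pytest.fixture(scope="session")
def analysed(default_cohort):
    """Fully analysed default cohort (summaries, groups, POLE, tables)."""
    cfg = PipelineConfig(seed=11)
    summaries, assignments, hyper, pole, patterns, tables, artifacts = analyse_cohort(
        default_cohort, cfg
    )
    return {
        "cohort": default_cohort,
        "cfg": cfg,
        "summaries": summaries,
        "assignments": assignments,
        "hyper": hyper,
        "pole": pole,
        "patterns": patterns,
        "tables": tables,
        "artifacts": artifacts,
    }


@pytest.fixture()
def small_config():
    """A scaled-down cohort for fast end-to-end runs."""
    return CohortConfig(
        counts={"EAC_G1": 3, "EAC_G3_POLE": 2, "artifact_heavy": 1, "USC": 3}
    )
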