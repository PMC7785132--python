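import math

import numpy as np
import pytest

from enrichsurv import (PartitionSummaries, ScoreSummary, SimulationScenario,
                        TrialDesign)

# Summary statistics of the published two-partition worked example
# (high-risk vs low/intermediate-risk leukaemia patients): per partition
# the interim estimate, the combined (naive) estimate and the post-interim
# increment, each with its variance.
TABLE1 = {
    1: {"stage1": (-0.902, 0.191), "combined": (-0.746, 0.089),
        "increment": (-0.609, 0.167)},
    2: {"stage1": (-0.419, 0.103), "combined": (-0.362, 0.053),
        "increment": (-0.301, 0.108)},
}


@pytest.fixture
def table1_summaries() -> PartitionSummaries:
    def block(name):
        return [ScoreSummary.from_estimate(*TABLE1[j][name]) for j in (1, 2)]

    return PartitionSummaries(K=2, stage1=block("stage1"),
                              combined=block("combined"),
                              increment=block("increment"))


@pytest.fixture(params=["adaptive_threshold", "independent"])
def worked_design(request) -> TrialDesign:
    return TrialDesign(K=2, prevalences=(0.2, 0.8), futility_threshold=0.0,
                       rule=request.param, alpha=0.05,
                       weights=(math.sqrt(0.75), math.sqrt(0.25)),
                       interim_event_count=60, stage2_event_count=31,
                       tilde_offset_days=1279.0)


@pytest.fixture
def small_scenario() -> SimulationScenario:
    """A fast two-partition trial for end-to-end simulator tests."""
    return SimulationScenario(
        gamma=1.0, lambda_C=math.log(2.0) / 200.0, theta=(-0.4, 0.1),
        prevalences=(0.5, 0.5), n_patients=400, accrual_days=365.0,
        interim_event_count=60, stage2_event_count=40,
        tilde_offset_days=60.0, rule="independent", b=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
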