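import numpy as np
import pytest

from nanoak.hmm_core import CurrentTrace, EmissionModel, TransitionMatrix
from nanoak.kinetic_model import (
    LigandConcentrations,
    ModelVariant,
    State,
    StateSpace,
    build_state_space,
)
from nanoak.reference import REFERENCE_RATES, default_emission_model


@pytest.fixture(scope="session")
def v3() -> ModelVariant:
    return ModelVariant("V3")


@pytest.fixture(scope="session")
def space(v3) -> StateSpace:
    return build_state_space(v3)


@pytest.fixture(scope="session")
def ref_rates():
    return REFERENCE_RATES


@pytest.fixture(scope="session")
def em() -> EmissionModel:
    return default_emission_model()


@pytest.fixture(scope="session")
def two_state():
    """Minimal 2-state HMM pieces: state space, emission model, Gamma factory."""
    sp = StateSpace(
        (
            State("open", "A", "open", "open", 0),
            State("closed", "B", "closed", "open", 1),
        )
    )
    emission = EmissionModel({"A": -199.3, "B": -221.0}, {"A": 8.0, "B": 8.0}, groups=("A", "B"))

    def gamma(p12: float, p21: float, dt: float = 0.2) -> TransitionMatrix:
        return TransitionMatrix(
            np.array([[1 - p12, p12], [p21, 1 - p21]]), dt, sp
        )

    return sp, emission, gamma


def make_trace(samples, atp=0.0, amp=0.0, adp=0.0, dt=0.2, label=""):
    return CurrentTrace(
        np.asarray(samples, dtype=float),
        dt,
        LigandConcentrations(atp_mM=atp, amp_mM=amp, adp_mM=adp),
        label,
    )


@pytest.fixture(scope="session")
def reduced_design_traces(v3):
    """Traces from the six-condition estimation design at 1000 ms per
    condition — the reduced layout used for simulate-and-refit checks."""
    from nanoak.trace_simulator import default_atp_amp_design, simulate_experiment

    design = default_atp_amp_design(n_replicates=1, duration_ms=1000.0)
    return simulate_experiment(REFERENCE_RATES, v3, design, seed=11)
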