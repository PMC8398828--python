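import numpy as np
import pytest

from ussingkit import (
    CompoundKinetics,
    CompoundSpec,
    ExperimentDesign,
    KineticParams,
    MeasurementModel,
)


@pytest.fixture
def design_no_sampling() -> ExperimentDesign:
    """Standard chamber geometry, but zero aliquots (no withdrawal events)."""
    return ExperimentDesign(donor_aliquot=0.0, acceptor_aliquot=0.0)


@pytest.fixture
def single_compound() -> list[CompoundSpec]:
    return [
        CompoundSpec(id="cpd", name="test compound", mz=417.1181, rt=2.20,
                     mw=416.38, compound_class="C_glycoside",
                     initial_donor_conc=100.0)
    ]


@pytest.fixture
def noise_free_model() -> MeasurementModel:
    return MeasurementModel(noise_cv=0.0, seed=7)


def kinetics(**per_compound: CompoundKinetics) -> KineticParams:
    return KineticParams(rates=dict(per_compound))
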