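import numpy as np
import pytest

from hbcurve import BloodGasState, ph_rbc_from_plasma


@pytest.fixture
def standard_state() -> BloodGasState:
    """Standard physiological state: PCO2 40, plasma pH 7.4, DPG 4.65 mM, 37 degC."""
    return BloodGasState(
        PO2=100.0,
        PCO2=40.0,
        pH_rbc=float(ph_rbc_from_plasma(7.4)),
        DPG=4.65e-3,
        T=37.0,
    )


def random_states(n: int, seed: int = 0) -> list[BloodGasState]:
    """Physiologically plausible random states (venous-to-arterial ranges)."""
    rng = np.random.default_rng(seed)
    return [
        BloodGasState(
            PO2=float(rng.uniform(5.0, 100.0)),
            PCO2=float(rng.uniform(20.0, 80.0)),
            pH_rbc=float(rng.uniform(6.9, 7.5)),
            DPG=float(rng.uniform(1e-3, 4.6e-3)),
            T=float(rng.uniform(35.0, 40.0)),
        )
        for _ in range(n)
    ]
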