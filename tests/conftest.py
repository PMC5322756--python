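import numpy as np
import pytest

from patchfr import AllometricConstants, compute_traits
from patchfr.synth import default_design, make_synthetic_feeding_table


@pytest.fixture(scope="session")
def constants():
    return AllometricConstants()


@pytest.fixture(scope="session")
def traits_100_1(constants):
    """Traits for the reference 100 mg predator / 1 mg prey pair."""
    return compute_traits(100.0, 1.0, constants)


@pytest.fixture(scope="session")
def synth_table():
    """A medium synthetic NB feeding table from known habitat scalings."""
    truth = {"ln_C_N0": 4.5, "a_N0": -0.1, "b_N0": 1.6, "ln_C_h": 0.25}
    table = make_synthetic_feeding_table(
        truth, default_design(reps=4), k=5.0, seed=2024, ln_fmax=1.9
    )
    return truth, table


@pytest.fixture(scope="session")
def flat_table():
    """Synthetic table with no habitat structure (single design point)."""
    design = default_design(areas=(1.0,), refuges=(0.25,),
                            exponents=tuple(range(0, 13)), reps=8)
    truth = {"ln_C_N0": 4.0, "ln_C_h": 0.3}
    table = make_synthetic_feeding_table(truth, design, k=6.0, seed=7, ln_fmax=1.9)
    return truth, table
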