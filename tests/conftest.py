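import numpy as np
import pytest

import tkaopt as tk


@pytest.fixture(scope="session")
def factors():
    return tk.DEFAULT_FACTORS


@pytest.fixture(scope="session")
def table3():
    """The packaged nine-run response table."""
    return tk.load_table3_responses()


@pytest.fixture(scope="session")
def table3_analysis(table3, factors):
    return tk.analyze(table3, factors)


@pytest.fixture(scope="session")
def l9_design(factors):
    array = tk.build_orthogonal_array(3, len(factors))
    return tk.instantiate_design(array, factors)


@pytest.fixture(scope="session")
def geometry():
    return tk.default_geometry()


@pytest.fixture(scope="session")
def symmetric_ligaments():
    """A left-right symmetric collateral pair (for mirror-symmetry checks;
    the default pair is anatomically asymmetric)."""
    return tuple(
        tk.LigamentSpec(
            side=side,
            c1_mpa=6.06,
            rest_length_mm=60.0,
            cross_section_mm2=15.0,
            lever_arm_mm=arm,
        )
        for side, arm in (("medial", 40.0), ("lateral", -40.0))
    )


@pytest.fixture(scope="session")
def liner_k():
    return tk.foundation_modulus(tk.MATERIALS["polyethylene_liner"], 9.0)
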