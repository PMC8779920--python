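import numpy as np
import pytest

from levpbpk.acat_absorption import fit_dissolution
from levpbpk.compound_physiology import (
    build_adult_physiology,
    build_child_physiology,
    load_compound_profile,
)
from levpbpk.partitioning import kp_for_physiology
from levpbpk.pbpk_disposition import assemble_model


@pytest.fixture(scope="session")
def compound():
    return load_compound_profile()


@pytest.fixture(scope="session")
def adult_phys():
    # the IV validation cohort: 64.19 kg, 23.7 y males
    return build_adult_physiology(64.19, 1.70, 23.7, "M")


@pytest.fixture(scope="session")
def adult_model(compound, adult_phys):
    return assemble_model(
        compound, adult_phys, kp_for_physiology(compound, adult_phys), "adult"
    )


@pytest.fixture(scope="session")
def child6_model(compound):
    phys = build_child_physiology(6, 22.26, 16.07)
    return assemble_model(compound, phys, kp_for_physiology(compound, phys), "child")


@pytest.fixture(scope="session")
def child4_model(compound):
    phys = build_child_physiology(4, 17.78)
    return assemble_model(compound, phys, kp_for_physiology(compound, phys), "child")


@pytest.fixture(scope="session")
def fast_dissolution():
    # the packaged instant-dissolving release summary: >85% at 2.5 min,
    # complete at 5 min
    return fit_dissolution([(2.5, 87), (5, 100), (10, 100), (15, 100), (20, 100), (30, 100)])
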