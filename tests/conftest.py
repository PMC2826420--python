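import pytest

from genecharts import (
    build_autoregulation,
    build_c1_ffl,
    build_dense_overlapping_regulon,
    build_ic1_ffl,
    build_interlocked_ffl_network,
    build_simple_regulation,
    build_single_input_module,
)

ALL_ON = {"S_X1": 1, "S_Y1": 1, "S_X2": 1, "S_Y2": 1}


@pytest.fixture
def interlocked():
    return build_interlocked_ffl_network()


@pytest.fixture
def c1_ffl():
    return build_c1_ffl()


@pytest.fixture
def ic1_ffl():
    return build_ic1_ffl()


def motif_fixtures():
    """One network per motif class (plus mode variants of simple regulation)."""
    return [
        ("simple_aa", build_simple_regulation("activator", "activator")),
        ("simple_ar", build_simple_regulation("activator", "repressor")),
        ("simple_ra", build_simple_regulation("repressor", "activator")),
        ("simple_rr", build_simple_regulation("repressor", "repressor")),
        ("autoreg_neg", build_autoregulation("negative")),
        ("autoreg_lock", build_autoregulation("positive", lock_in=True)),
        ("c1_ffl", build_c1_ffl()),
        ("ic1_ffl", build_ic1_ffl()),
        ("sim3", build_single_input_module(3)),
        ("dor", build_dense_overlapping_regulon()),
    ]
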