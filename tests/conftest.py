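import numpy as np
import pytest

from asmbs import synth

#: Small three-target geometry used by read-level tests (plus- and
#: minus-strand targets, modest CpG counts) to keep alignment fast.
TINY_GEOMETRY = (
    ("AHRR", "cgA", "sim1", 300, "+", 12),
    ("ALPPL2", "cgB", "sim2", 280, "-", 10),
    ("IER3", "cgC", "sim3", 260, "+", 8),
)


@pytest.fixture(scope="session")
def tiny_targets():
    return synth.synthetic_registry(11, geometry=TINY_GEOMETRY)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_targets):
    cfg = synth.study_conditions(tiny_targets, 11)
    cfg.n_subjects = 6
    return synth.simulate_cohort(cfg, tiny_targets)


@pytest.fixture(scope="session")
def clean_run(tiny_targets, tiny_cohort):
    """Error-free, duplicate-free, perfectly converted reads for round trips."""
    cfg = synth.ReadSimConfig(
        mean_depth=8,
        error_rate=0.0,
        conversion_efficiency=1.0,
        conversion_failure_rate=0.0,
        duplicate_rate=0.0,
        depth_multipliers={},
    )
    return synth.simulate_reads(tiny_cohort, tiny_targets, cfg, seed=5)
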