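import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from antiangio.seqio import LabeledDataset, Peptide

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def tiny_dataset():
    peps = [
        Peptide("p1", "ACDEFGHIKL"),
        Peptide("p2", "CCPPRRSSWW"),
        Peptide("p3", "AAEEIILLVV"),
        Peptide("p4", "WCPRSWCPRS"),
        Peptide("p5", "MNQTYVHGKF"),
        Peptide("p6", "LLLLAAAAEE"),
    ]
    return LabeledDataset("tiny", peps, np.array([1, 1, 0, 1, 0, 0]))
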