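import numpy as np
import pytest

from betawaves.params import preset
from betawaves.theory import find_operating_point
from betawaves.transfer import default_transfer


@pytest.fixture(scope="session")
def transfer_e():
    return default_transfer("E")


@pytest.fixture(scope="session")
def transfer_i():
    return default_transfer("I")


@pytest.fixture(scope="session")
def sn():
    return preset("SN")


@pytest.fixture(scope="session")
def sn_op(sn):
    return find_operating_point(sn)


@pytest.fixture(scope="session")
def reference_runs():
    """Scaled-down reference simulations of the SN model (8.5 s analyzed,
    coarse 0.05 ms step, full 24x24 grid), shared by the statistical
    tests.  Returns the list of SimulationRecords."""
    from betawaves.network import evolve_network
    p = preset("SN")
    return [evolve_network(p, 9_000.0, dt_ms=0.05, seed=100 + k)
            for k in range(3)]


def classify_record(rec, burn_ms=500.0):
    """Shared helper: classification + episodes of a record's proxy-LFP."""
    from betawaves.preprocess import analytic_signal
    from betawaves.waves import classify_frames, extract_episodes
    burn = int(round(burn_ms * rec.frame_rate_hz / 1000.0))
    mov = rec.measurement_movie("ie")[..., burn:]
    movie = analytic_signal(mov, rec.frame_rate_hz)
    cls = classify_frames(movie)
    return movie, cls, extract_episodes(cls)


@pytest.fixture(scope="session")
def reference_classification(reference_runs):
    return [classify_record(rec) for rec in reference_runs]
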