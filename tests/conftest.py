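import pytest

from phasefus import make_fixture


@pytest.fixture(scope="session")
def fus():
    """FUS defaults: N1=526, m1=m2=34, N2=65, beta_eps1=-2, no ATP."""
    return make_fixture("fus2022")


@pytest.fixture(scope="session")
def fus_coexistence(fus):
    """The ATP-free FUS tie-line, solved once per session."""
    from phasefus import solve_coexistence

    return solve_coexistence(fus)


@pytest.fixture(scope="session")
def loops():
    """Closed-loop scans for the two sticker-asymmetric chains (L=3)."""
    import numpy as np

    from phasefus import asymmetric_loop_metrics, make_fixture

    pa = make_fixture("asym_hiY", valence=3)   # m1=34 > m2=11
    pb = make_fixture("asym_hiR", valence=3)   # m1=11 < m2=34
    cs = np.geomspace(1e-5, 3e-2, 16)
    return asymmetric_loop_metrics(pa, pb, cs)
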