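import numpy as np
import pytest

import ermspec as es


@pytest.fixture(scope="session")
def tpdf_kernel():
    """Reference approximate power-law kernel (mu=0.5, eps=0.03125)."""
    return es.KernelSpec(variant="tpdf", mu=0.5, epsilon=0.03125)


@pytest.fixture(scope="session")
def default_erm(tpdf_kernel):
    """Reference intermediate-density realization: N=1024, d=2, L=10."""
    space = es.FunctionalSpace(d=2, L=10.0, N=1024)
    return es.make_erm(space, tpdf_kernel, es.VarianceModel(kind="unit"),
                       seed=12345)


@pytest.fixture(scope="session")
def small_erm(tpdf_kernel):
    """Small realization for cheap unit tests: N=256, d=2, L=5."""
    space = es.FunctionalSpace(d=2, L=5.0, N=256)
    return es.make_erm(space, tpdf_kernel, es.VarianceModel(kind="unit"),
                       seed=7)


@pytest.fixture(scope="session")
def mean_spectrum_rho256_d1(tpdf_kernel):
    """Averaged spectrum of 20 high-density (rho=256, d=1) realizations."""
    space = es.FunctionalSpace.from_density(d=1, N=1024, rho=256.0)
    acc = np.zeros(1024)
    n = 20
    for s in range(n):
        erm = es.make_erm(space, tpdf_kernel, seed=s)
        acc += np.sort(np.linalg.eigvalsh(erm.C))[::-1]
    return acc / n


@pytest.fixture(scope="session")
def mean_spectrum_1024(tpdf_kernel):
    """Averaged sorted spectrum of 30 reference ERM realizations."""
    space = es.FunctionalSpace(d=2, L=10.0, N=1024)
    acc = np.zeros(1024)
    n = 30
    for s in range(n):
        erm = es.make_erm(space, tpdf_kernel, seed=s)
        acc += np.sort(np.linalg.eigvalsh(erm.C))[::-1]
    return acc / n
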