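import numpy as np
import pytest

from cochleametrics.fcs import PhotonTrace


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def short_poisson_trace():
    """A small Poisson photon trace with nontrivial correlations (OU-modulated)."""
    gen = np.random.default_rng(7)
    n = 4000
    lam = np.empty(n)
    lam[0] = 10.0
    for i in range(1, n):  # AR(1) intensity so G(tau) is not flat
        lam[i] = 10.0 + 0.9 * (lam[i - 1] - 10.0) + gen.normal(0, 1.0)
    counts = gen.poisson(np.clip(lam, 0.1, None))
    return PhotonTrace(counts=counts, bin_width=1e-4)


def direct_autocorr_oracle(counts, lags):
    """O(n*k) brute-force fluctuation autocorrelation (the estimator's oracle)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.size
    mean = counts.mean()
    d = counts - mean
    out = []
    for k in lags:
        out.append(np.sum(d[: n - k] * d[k:]) / (n - k) / mean**2)
    return np.array(out)
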