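import numpy as np
import pytest

import thymoselect as ts


@pytest.fixture(scope="session")
def cohort():
    return ts.reference_cohort()


@pytest.fixture(scope="session")
def pooled_fit(cohort):
    return ts.estimate_pooled(cohort)


@pytest.fixture(scope="session")
def lineage_fit(cohort):
    return ts.estimate_lineage(cohort)


def random_pooled_rates(rng: np.random.Generator) -> ts.PooledRates:
    """A random stable, non-degenerate pooled rate vector."""
    while True:
        phi1, mu1, phi2, mu2, phi3, mu3 = rng.uniform(0.02, 1.2, size=6)
        lam3 = rng.uniform(0.0, 0.9) * (phi3 + mu3)
        r = ts.PooledRates(phi=rng.uniform(1e5, 5e7), phi1=phi1, mu1=mu1,
                           phi2=phi2, mu2=mu2, phi3=phi3, mu3=mu3, lam3=lam3)
        if _well_separated(r.decay_rates):
            return r


def random_lineage_rates(rng: np.random.Generator) -> ts.LineageRates:
    """A random stable, non-degenerate lineage rate vector."""
    while True:
        phi1, mu1, phi4, phi8, mu2 = rng.uniform(0.02, 1.2, size=5)
        xi4, mu4, xi8, mu8 = rng.uniform(0.02, 0.8, size=4)
        lam4 = rng.uniform(0.0, 0.9) * (xi4 + mu4)
        lam8 = rng.uniform(0.0, 0.9) * (xi8 + mu8)
        r = ts.LineageRates(phi=rng.uniform(1e5, 5e7), phi1=phi1, mu1=mu1,
                            phi4=phi4, phi8=phi8, mu2=mu2, xi4=xi4, mu4=mu4,
                            lam4=lam4, xi8=xi8, mu8=mu8, lam8=lam8)
        if _well_separated(r.decay_rates):
            return r


def _well_separated(decays, min_gap=0.05) -> bool:
    d = sorted(decays)
    return all(b - a >= min_gap for a, b in zip(d, d[1:]))
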