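import numpy as np
import pytest

import pestrisk as pr


@pytest.fixture(scope="session")
def pheno_spec():
    return pr.SyntheticPhenologySpec()


@pytest.fixture(scope="session")
def model(pheno_spec):
    return pr.gen_phenology_model(pheno_spec)


@pytest.fixture(scope="session")
def grid_spec():
    return pr.SyntheticGridSpec()


@pytest.fixture(scope="session")
def grid(grid_spec):
    return pr.gen_temperature_grid(grid_spec)


@pytest.fixture()
def optimal_cycle(pheno_spec):
    opt = pheno_spec.optimum
    return pr.build_diurnal_cycle(opt - 5.0, opt + 5.0, opt - 5.0)


def make_series(lam, r0=None, tc=None, surv=None):
    """365-day series from scalars or arrays (broadcast to the year)."""
    def full(v, default):
        if v is None:
            v = default
        v = np.asarray(v, dtype=float)
        return np.full(365, float(v)) if v.ndim == 0 else v

    lam = full(lam, 1.0)
    return pr.DailySeries.from_arrays(
        lam, net_repro=full(r0, None) if r0 is not None else None,
        gen_time=full(tc, None) if tc is not None else None,
        min_survival=full(surv, 1.0))
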