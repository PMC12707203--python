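import numpy as np
import pytest

from wsls_commons import QueueServerSpec, SystemSpec, GenericGoodSpec


@pytest.fixture(scope="session")
def table1_system():
    """Three-server reference system: 1000 users, rho=0.75 by default."""
    return SystemSpec(
        goods=(
            QueueServerSpec(mu=100.0, c=1, k=10, d=0.010),
            QueueServerSpec(mu=200.0, c=1, k=10, d=0.020),
            QueueServerSpec(mu=400.0, c=1, k=10, d=0.030),
        ),
        nu=1000,
        tau=0.100,
        rho=0.75,
    )


@pytest.fixture(scope="session")
def identical_system():
    goods = tuple(QueueServerSpec(mu=200.0, c=1, k=10, d=0.020) for _ in range(3))
    return SystemSpec(goods=goods, nu=600, tau=0.100, rho=0.75)


def make_generic_system(fns, nu=100, lambda_u=0.5):
    goods = tuple(GenericGoodSpec(failure_fn=f, check_grid=(0.0, 1.0, 10.0, float(nu))) for f in fns)
    return SystemSpec(goods=goods, nu=nu, tau=1.0, lambda_u=lambda_u)
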