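import numpy as np
import pytest

from voapipe.synth import PlantedState

# Population weights of the six monomer conformational states in water used
# as the reference planted mixture for clustering-recovery checks.
WATER_STATE_WEIGHTS = (0.474, 0.221, 0.100, 0.099, 0.080, 0.026)
WATER_STATE_MEANS = (
    (-157.3, 81.2),
    (-157.3, -37.2),
    (18.7, -39.0),
    (-157.6, 149.2),
    (20.9, -179.5),
    (15.7, 152.3),
)


# Von Mises concentration for the six-state fixture.  The two closest planted
# centers are only ~28 degrees apart (in the hydroxyl torsion); kappa = 200
# (circular sd ~4 degrees) separates them by ~7 sd, so the planted mixture is
# itself the cost-optimal 6-medoid clustering and recovery is well-posed.
WATER_STATE_KAPPA = 200.0


@pytest.fixture(scope="session")
def water_states():
    return [
        PlantedState(means=m, kappas=(WATER_STATE_KAPPA, WATER_STATE_KAPPA), weight=w)
        for m, w in zip(WATER_STATE_MEANS, WATER_STATE_WEIGHTS)
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
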