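import numpy as np
import pytest
from shapely.geometry import box

from fleetrum.choice import CoefficientSet, choice_probabilities
from fleetrum.features import ChoiceOccasion
from fleetrum.regions import RegionSet, default_region_set, region_set_from_polygons
from fleetrum.synthetic_fleet import SyntheticScenario, generate_dataset


@pytest.fixture(scope="session")
def rs12() -> RegionSet:
    return default_region_set()


@pytest.fixture()
def toy_rs() -> RegionSet:
    """Three rectangles sharing edges/corners: ids 1..3."""
    return region_set_from_polygons(
        [
            (1, box(-10, 0, 0, 10)),
            (2, box(0, 0, 10, 10)),
            (3, box(-10, -10, 10, 0)),
        ]
    )


@pytest.fixture(scope="session")
def compact_ds():
    """Small single-stratum synthetic dataset shared across tests."""
    sc = SyntheticScenario.compact(seed=7, n_vessels=6, n_months=10)
    return generate_dataset(sc)


@pytest.fixture(scope="session")
def compact_occasions(compact_ds):
    return compact_ds.occasions()


def sample_occasions(rng, N, R=3, K=1, J=0, beta=None, theta=None, base_alt=None):
    """Directly sampled occasions from a known conditional logit.

    X entries are iid standard normal; Z likewise; choices are draws from
    the model's probabilities.  Used as an oracle-friendly data source
    independent of the trip machinery.
    """
    base_alt = base_alt or R
    beta = np.zeros(K) if beta is None else np.asarray(beta, dtype=float)
    theta = np.zeros((J, R)) if theta is None else np.asarray(theta, dtype=float)
    x_names = tuple(f"x{k}" for k in range(K))
    z_names = tuple(f"z{j}" for j in range(J))
    occs = []
    for n in range(N):
        X = rng.normal(size=(R, K))
        Z = rng.normal(size=J)
        V = X @ beta + (Z @ theta if J else 0.0)
        p = choice_probabilities(V)
        chosen = int(rng.choice(R, p=p)) + 1
        occs.append(
            ChoiceOccasion(
                occasion_id=f"occ{n}",
                trip_id=f"t{n}",
                vessel_id="V",
                stage="switch",
                date=__import__("pandas").Timestamp("2001-06-15"),
                X=X,
                x_names=x_names,
                Z=Z,
                z_names=z_names,
                chosen=chosen,
            )
        )
    truth = CoefficientSet(
        beta=beta, theta=theta, base_alt=base_alt, x_names=x_names, z_names=z_names
    )
    return occs, truth
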