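import numpy as np
import pytest

import pnp_workbench as w


@pytest.fixture(scope="session")
def toy_compounds():
    """Curated two-class compound set (np_like vs drug_like)."""
    return w.gen_toy_compound_classes(seed=1)


@pytest.fixture(scope="session")
def cluster_plate():
    """Synthetic plate with 4 planted clusters, 40 active compounds, a=10 sigma."""
    spec = w.default_cluster_plate_spec(n_per_cluster=10, amplitude=10.0, seed=7)
    return w.gen_plate(spec)


@pytest.fixture(scope="session")
def cluster_profiles(cluster_plate):
    plate, _ = cluster_plate
    return w.zscore_profiles(plate)


@pytest.fixture(scope="session")
def top_conc_profiles(cluster_profiles):
    return [p for p in cluster_profiles if p.concentration_um == 50.0]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_profile(z, compound_id="p", conc=10.0):
    """Bare MorphProfile around a z vector (feature ids auto-named)."""
    z = np.asarray(z, dtype=float)
    return w.MorphProfile(
        compound_id=compound_id,
        concentration_um=conc,
        z=z,
        feature_ids=[f"f_{i}" for i in range(z.size)],
    )
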