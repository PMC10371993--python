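import numpy as np
import pandas as pd
import pytest

import oceanconn as oc


@pytest.fixture(scope="session")
def barrier_scenario():
    return oc.build_scenario("barrier_jet")


@pytest.fixture(scope="session")
def barrier_connectivity(barrier_scenario):
    """Exposure + connectivity matrices for the default barrier-jet world.

    Session-scoped: the tracer integration is deterministic and takes a
    few seconds, and several modules test properties of its output.
    """
    expo, conn = oc.run_connectivity(barrier_scenario)
    return expo, conn


@pytest.fixture(scope="session")
def barrier_conn_ordination(barrier_connectivity):
    _, conn = barrier_connectivity
    return oc.nmds2(oc.connectivity_to_dissimilarity(conn), seed=0)


def make_sample_table(rows):
    """Build a SampleTable from (sample_id, lon, lat, depth, abunds) tuples."""
    n_sp = len(rows[0][4])
    species = [f"sp{k + 1}" for k in range(n_sp)]
    recs = []
    for sid, lon, lat, depth, ab in rows:
        recs.append(
            {
                "sample_id": sid,
                "station_id": f"st_{sid}",
                "lon": lon,
                "lat": lat,
                "depth_m": depth,
                **dict(zip(species, map(float, ab))),
            }
        )
    return oc.SampleTable(data=pd.DataFrame(recs))


@pytest.fixture
def hand_table():
    """Nine samples at three stations, varied depths and communities."""
    rng = np.random.default_rng(11)
    rows = []
    for k in range(9):
        ab = rng.integers(0, 2000, size=5).astype(float)
        rows.append((f"s{k}", 7.0 + 0.1 * k, 57.0 + 0.05 * k, 5.0 + 5.0 * k, ab))
    return make_sample_table(rows)
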