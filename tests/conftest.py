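import numpy as np
import pytest

from defenscan import (ComponentDef, GeneRecord, HmmHit, Registry, Replicon,
                       SystemModel, calibrate_ga, generate_toy_registry)

MASTER_SEED = 20260924


@pytest.fixture(scope="session")
def kit():
    """Calibrated 4-model toy registry shared across the suite."""
    k = generate_toy_registry(4, seed=MASTER_SEED)
    return calibrate_ga(k, seed=MASTER_SEED + 1)


@pytest.fixture()
def cbass_model():
    """A CBASS-type-I-style decision rule: cyclase and effector mandatory,
    the sensing protein accessory, one disqualifying profile."""
    return SystemModel(
        model_name="CBASS-I",
        family="CBASS",
        subtype="CBASS-I",
        components=[
            ComponentDef("cyclase", "mandatory", ("CD-NTase",)),
            ComponentDef("effector", "mandatory", ("Effector_1TM", "Effector_2TM")),
            ComponentDef("sensor", "accessory", ("Sensor_STK",)),
            ComponentDef("antidefense", "forbidden", ("Acb_like",)),
        ],
        window_W=5,
        mechanism="abortive infection",
    )


@pytest.fixture()
def cbass_registry(cbass_model):
    manifest = {
        p: {"GA_bits": 10.0, "source": "toy"}
        for c in cbass_model.components for p in c.profiles
    }
    return Registry([cbass_model], manifest)


def make_replicon(n_genes: int, replicon_id: str = "R1",
                  topology: str = "linear") -> Replicon:
    genes = [
        GeneRecord(f"{replicon_id}_g{r:03d}", replicon_id, r,
                   (r - 1) * 1000 + 1, (r - 1) * 1000 + 300)
        for r in range(1, n_genes + 1)
    ]
    return Replicon(replicon_id, genes, topology)


def hit_at(replicon: Replicon, rank: int, profile: str,
           score: float = 50.0) -> HmmHit:
    return HmmHit(replicon.genes[rank - 1].gene_id, profile, score, None, True)


@pytest.fixture()
def make_replicon_fixture():
    return make_replicon


@pytest.fixture()
def rng():
    return np.random.default_rng(MASTER_SEED)
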