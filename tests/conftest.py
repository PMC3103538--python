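import logging

import numpy as np
import pytest

from multipk.fixtures import FixtureSpec, make_regime_ensembles, make_toy_peptide
from multipk.structure_io import assign_parameters, detect_sites, load_default_parameters, write_ensemble

logging.disable(logging.INFO)

GCN4_LIKE = "GSMKQLEDKVEELLSKNYHLENEVARLKKLVGE"  # 33 residues, 16 titratable sites


@pytest.fixture(scope="session")
def param_table():
    return load_default_parameters()


@pytest.fixture(scope="session")
def glu_lys_bridge():
    """Two facing chains with a Glu–Lys salt bridge at 3.0 Å."""
    spec = FixtureSpec(chains=("AEA", "AKA"), bridge=((0, 2), (1, 2), 3.0),
                       n_snapshots=2, jitter_sigma=0.15, seed=11)
    conf, table = make_toy_peptide(spec)
    return spec, conf, table


@pytest.fixture(scope="session")
def bridge_ensemble_paths(tmp_path_factory, glu_lys_bridge):
    spec, _, _ = glu_lys_bridge
    ensembles = make_regime_ensembles(spec)
    root = tmp_path_factory.mktemp("bridge")
    paths = {}
    for regime, ens in ensembles.items():
        p = root / f"{regime}.pdb"
        p.write_text(write_ensemble(ens))
        paths[regime] = str(p)
    return paths


@pytest.fixture(scope="session")
def weight_fixture_paths(tmp_path_factory):
    """Single chain with well-separated Glu and Lys; clean weight limits."""
    spec = FixtureSpec(chains=("AEAAKA",), n_snapshots=2, jitter_sigma=0.15, seed=5)
    ensembles = make_regime_ensembles(spec)
    root = tmp_path_factory.mktemp("weights")
    paths = {}
    for regime, ens in ensembles.items():
        p = root / f"{regime}.pdb"
        p.write_text(write_ensemble(ens))
        paths[regime] = str(p)
    return paths


@pytest.fixture(scope="session")
def parameterised_gcn4(param_table):
    conf, _ = make_toy_peptide(FixtureSpec(chains=(GCN4_LIKE,)))
    return assign_parameters(conf, param_table)
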