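import numpy as np
import pytest

from wormcircuit import (Connectome, NeuronClass, NeuronRecord,
                         load_published_fixtures)


@pytest.fixture(scope="session")
def fixtures():
    return load_published_fixtures()


@pytest.fixture()
def tiny_connectome():
    """Hand-built clustered connectome: 2 sensory, 2 inter, 2 motor."""
    c = Connectome(clustered=True)
    for name, cls in [("S1", "sensory"), ("S2", "sensory"),
                      ("I1", "inter"), ("I2", "inter"),
                      ("M1", "motor"), ("M2", "motor")]:
        c.add_neuron(NeuronRecord(name, NeuronClass(cls)))
    for pre, post, C, E in [("S1", "I1", 9, 0), ("S1", "I2", 4, 0),
                            ("S1", "M1", 2, 0), ("I1", "M1", 7, 0),
                            ("I1", "M2", 3, 0), ("I2", "M2", 5, 0),
                            ("S2", "I1", 1, 0)]:
        c.add_edge(pre, post, C, E)
    return c


def random_layered_connectome(rng, max_nodes=12):
    """Random clustered layered connectome for oracle-equivalence tests."""
    n_s = int(rng.integers(1, max(2, max_nodes // 3)))
    n_i = int(rng.integers(1, max(2, max_nodes // 3)))
    n_m = int(rng.integers(1, max(2, max_nodes // 3)))
    c = Connectome(clustered=True)
    names = {}
    for prefix, n, cls in [("S", n_s, NeuronClass.SENSORY),
                           ("I", n_i, NeuronClass.INTER),
                           ("M", n_m, NeuronClass.MOTOR)]:
        names[prefix] = [f"{prefix}{k}" for k in range(n)]
        for nm in names[prefix]:
            c.add_neuron(NeuronRecord(nm, cls))
    all_names = names["S"] + names["I"] + names["M"]
    for pre in all_names:
        for post in all_names:
            if pre != post and rng.random() < 0.3:
                c.add_edge(pre, post, int(rng.integers(1, 10)), 0)
    return c, names
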