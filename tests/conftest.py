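import pytest

import synergynet as sn


@pytest.fixture(scope="session")
def xor_net() -> sn.BayesNet:
    """Two fair independent inputs and a deterministic XOR output."""
    return sn.BayesNet(
        nodes=("A", "B", "Y"),
        cpts={
            "A": sn.Cpt.root(0.5),
            "B": sn.Cpt.root(0.5),
            "Y": sn.Cpt.from_sequence(("A", "B"), [0.0, 1.0, 1.0, 0.0]),
        },
    )


@pytest.fixture(scope="session")
def xor_joint(xor_net) -> sn.JointTable:
    return sn.joint_distribution(xor_net)


@pytest.fixture(scope="session")
def copies_net() -> sn.BayesNet:
    """A fair bit with two deterministic copies (fully redundant triplet)."""
    copy = sn.Cpt.from_sequence(("X",), [0.0, 1.0])
    return sn.BayesNet(
        nodes=("X", "C1", "C2"),
        cpts={"X": sn.Cpt.root(0.5), "C1": copy, "C2": copy},
    )


@pytest.fixture(scope="session")
def copies_joint(copies_net) -> sn.JointTable:
    return sn.joint_distribution(copies_net)


@pytest.fixture(scope="session")
def ref_net() -> sn.BayesNet:
    return sn.load_reference_network("optimized")


@pytest.fixture(scope="session")
def ref_net_fig1b() -> sn.BayesNet:
    return sn.load_reference_network("figure1b")


@pytest.fixture(scope="session")
def ref_joint(ref_net) -> sn.JointTable:
    return sn.joint_distribution(ref_net)


@pytest.fixture(scope="session")
def ref_sample_100k(ref_net) -> sn.DataMatrix:
    """One large shared sample from the optimized reference network."""
    return sn.generate_reference_dataset(ref_net, 100_000, seed=101)
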