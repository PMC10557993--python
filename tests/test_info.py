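"""Information measures: exact values, plug-in estimation, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import synergynet as sn
from synergynet.info import DataMatrix


def _joint3(weights) -> sn.JointTable:
    """A joint table over (A, B, C) from 8 non-negative weights."""
    w = np.asarray(weights, dtype=float).reshape(2, 2, 2)
    return sn.JointTable(variables=("A", "B", "C"), probs=w / w.sum())


joint3_strategy = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=8, max_size=8
).filter(lambda w: sum(w) > 1e-6)


def test_entropy_examples(xor_joint):
    assert float(sn.entropy(xor_joint, ["A"])) == pytest.approx(1.0)
    constant = sn.JointTable.from_mapping(("Z",), {(0,): 1.0, (1,): 0.0})
    assert float(sn.entropy(constant, ["Z"])) == pytest.approx(0.0)
    skew = sn.JointTable.from_mapping(("Z",), {(0,): 0.75, (1,): 0.25})
    assert float(sn.entropy(skew, ["Z"])) == pytest.approx(0.8112781245, abs=1e-9)


def test_entropy_unknown_label(xor_joint):
    with pytest.raises(ValueError, match="unknown"):
        sn.entropy(xor_joint, ["nope"])


def test_xor_mutual_information(xor_joint):
    assert float(sn.mutual_information(xor_joint, ["A"], ["Y"])) == pytest.approx(0.0, abs=1e-12)
    assert float(sn.mutual_information(xor_joint, ["B"], ["Y"])) == pytest.approx(0.0, abs=1e-12)
    assert float(sn.mutual_information(xor_joint, ["A", "B"], ["Y"])) == pytest.approx(1.0)


def test_mi_usage_errors(xor_joint):
    with pytest.raises(ValueError, match="overlap"):
        sn.mutual_information(xor_joint, ["A"], ["A", "Y"])
    with pytest.raises(ValueError, match="non-empty"):
        sn.mutual_information(xor_joint, [], ["Y"])


@settings(max_examples=60, derandomize=True, deadline=None)
@given(joint3_strategy)
def test_mi_symmetric_and_nonnegative(weights):
    joint = _joint3(weights)
    ab = float(sn.mutual_information(joint, ["A"], ["B"]))
    ba = float(sn.mutual_information(joint, ["B"], ["A"]))
    assert ab == pytest.approx(ba, abs=1e-12)
    assert ab >= -1e-12


def test_mi_zero_iff_independent():
    independent = sn.JointTable(
        variables=("A", "B"), probs=np.outer([0.7, 0.3], [0.4, 0.6])
    )
    assert float(sn.mutual_information(independent, ["A"], ["B"])) == pytest.approx(
        0.0, abs=1e-12
    )


def test_total_and_dual_total_correlation(xor_joint, copies_joint):
    independent = sn.JointTable(
        variables=("A", "B", "C"),
        probs=np.einsum("i,j,k->ijk", [0.5, 0.5], [0.7, 0.3], [0.9, 0.1]),
    )
    assert float(sn.total_correlation(independent, ["A", "B", "C"])) == pytest.approx(0, abs=1e-12)
    assert float(sn.dual_total_correlation(independent, ["A", "B", "C"])) == pytest.approx(
        0, abs=1e-12
    )
    assert float(sn.total_correlation(copies_joint, ["X", "C1", "C2"])) == pytest.approx(2.0)
    assert float(sn.total_correlation(xor_joint, ["A", "B", "Y"])) == pytest.approx(1.0)
    assert float(sn.dual_total_correlation(xor_joint, ["A", "B", "Y"])) == pytest.approx(2.0)


def test_o_information_landmarks(xor_joint, copies_joint):
    assert float(sn.o_information(xor_joint, ["A", "B", "Y"])) == pytest.approx(-1.0)
    assert float(sn.o_information(copies_joint, ["X", "C1", "C2"])) == pytest.approx(1.0)
    independent = sn.JointTable(
        variables=("A", "B", "C"),
        probs=np.einsum("i,j,k->ijk", [0.5, 0.5], [0.7, 0.3], [0.9, 0.1]),
    )
    assert float(sn.o_information(independent, ["A", "B", "C"])) == pytest.approx(0, abs=1e-12)
    with pytest.raises(ValueError, match="at least 3"):
        sn.o_information(xor_joint, ["A", "B"])


@settings(max_examples=60, derandomize=True, deadline=None)
@given(joint3_strategy)
def test_o_information_equals_tc_minus_dtc(weights):
    """Two independent code paths for Omega agree to numerical precision."""
    joint = _joint3(weights)
    labels = ["A", "B", "C"]
    omega = float(sn.o_information(joint, labels))
    tc = float(sn.total_correlation(joint, labels))
    dtc = float(sn.dual_total_correlation(joint, labels))
    assert omega == pytest.approx(tc - dtc, abs=1e-12)


def test_wms_synergy(xor_joint):
    assert float(sn.wms_synergy(xor_joint, ["A", "B"], "Y")) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="distinct"):
        sn.wms_synergy(xor_joint, ["A", "A"], "Y")


def test_wms_of_copy_target_is_nonpositive(copies_joint):
    # The target C1 is a copy of X: the "whole" equals the single-parent part.
    assert float(sn.wms_synergy(copies_joint, ["X", "C2"], "C1")) <= 1e-12


def test_wms_independent_target(xor_joint):
    independent = sn.JointTable(
        variables=("A", "B", "T"),
        probs=np.einsum("i,j,k->ijk", [0.5, 0.5], [0.5, 0.5], [0.6, 0.4]),
    )
    assert float(sn.wms_synergy(independent, ["A", "B"], "T")) == pytest.approx(0, abs=1e-12)


def test_plugin_matches_exact_on_xor_sample(xor_net, xor_joint):
    """Plug-in estimates at n=100,000 agree with exact values within 0.005 bits."""
    data = sn.generate_reference_dataset(xor_net, 100_000, seed=21)
    for labels in (["A"], ["Y"], ["A", "B", "Y"]):
        exact = float(sn.entropy(xor_joint, labels))
        plugin = float(sn.entropy(data, labels))
        assert plugin == pytest.approx(exact, abs=0.005)
    assert float(sn.mutual_information(data, ["A", "B"], ["Y"])) == pytest.approx(1.0, abs=0.005)
    assert float(sn.o_information(data, ["A", "B", "Y"])) == pytest.approx(-1.0, abs=0.005)


def test_entropy_estimator_labels(xor_net, xor_joint):
    data = sn.generate_reference_dataset(xor_net, 1000, seed=2)
    assert sn.entropy(xor_joint, ["A"]).estimator == "exact"
    assert sn.entropy(data, ["A"]).estimator == "plugin"


def test_miller_madow_correction_is_small_and_positive(xor_net):
    data = sn.generate_reference_dataset(xor_net, 500, seed=3)
    plain = float(sn.entropy(data, ["A", "B", "Y"]))
    corrected = float(sn.entropy(data, ["A", "B", "Y"], miller_madow=True))
    assert corrected > plain
    assert corrected - plain < 0.01


def test_missing_values_rejected_then_dropped():
    frame = pd.DataFrame({"a": [0, 1, None, 1], "b": [1, 1, 0, 0]})
    with pytest.raises(ValueError, match="missing"):
        sn.entropy(frame, ["a"])
    h = sn.entropy(frame, ["a"], missing="drop")
    assert float(h) == pytest.approx(-(1 / 3) * np.log2(1 / 3) - (2 / 3) * np.log2(2 / 3))


def test_mi_matrix_duplicated_column():
    rng = np.random.default_rng(4)
    col = (rng.random(5000) < 0.3).astype(int)
    data = DataMatrix.from_array(np.column_stack([col, col]), ["u", "v"])
    matrix = sn.mi_matrix(data)
    h = float(sn.entropy(data, ["u"]))
    assert matrix.loc["u", "v"] == pytest.approx(h, abs=1e-12)
    assert matrix.loc["u", "u"] == 0.0


def test_mi_matrix_independent_columns_near_zero():
    rng = np.random.default_rng(8)
    values = (rng.random((10_000, 5)) < 0.3).astype(int)
    data = DataMatrix.from_array(values, list("abcde"))
    matrix = sn.mi_matrix(data).to_numpy()
    off_diag = matrix[~np.eye(5, dtype=bool)]
    assert (off_diag < 0.01).all()
    assert np.allclose(matrix, matrix.T, atol=1e-12)


def test_mi_matrix_reference_sample_pairwise_blind(ref_sample_100k):
    """The designed synergy-only pairs read as approximately zero MI."""
    matrix = sn.mi_matrix(
        ref_sample_100k.frame[["S1", "S2", "S4"]]
    )
    assert matrix.loc["S1", "S4"] < 0.01
    assert matrix.loc["S2", "S4"] < 0.01


def test_datamatrix_validation():
    with pytest.raises(ValueError, match="non-binary"):
        DataMatrix.from_array([[0, 2], [1, 0]], ["a", "b"])
    with pytest.raises(ValueError, match="duplicate"):
        DataMatrix.from_frame(
            pd.DataFrame([[0, 1]], columns=["a", "a"])
        )
    with pytest.raises(ValueError, match="at least one row"):
        DataMatrix.from_frame(pd.DataFrame({"a": []}))
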