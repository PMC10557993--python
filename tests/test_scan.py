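"""Triangle filter, permutation test, BH adjustment and the scan pipeline."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import synergynet as sn
from synergynet.info import DataMatrix


def _xor_table(n: int, seed: int, eps: float = 0.0, extra: int = 0) -> DataMatrix:
    """Two fair inputs, an XOR target with flip noise, plus independent columns."""
    rng = np.random.default_rng(seed)
    a = (rng.random(n) < 0.5).astype(np.int8)
    b = (rng.random(n) < 0.5).astype(np.int8)
    c = (a ^ b).astype(np.int8)
    if eps > 0:
        flips = rng.random(n) < eps
        c = np.where(flips, 1 - c, c).astype(np.int8)
    cols = {"xa": a, "xb": b, "xc": c}
    for i in range(extra):
        cols[f"z{i}"] = (rng.random(n) < 0.3).astype(np.int8)
    return DataMatrix.from_array(np.column_stack(list(cols.values())), list(cols))


def _independent_table(n: int, m: int, seed: int) -> DataMatrix:
    rng = np.random.default_rng(seed)
    values = (rng.random((n, m)) < 0.3).astype(np.int8)
    return DataMatrix.from_array(values, [f"v{i:02d}" for i in range(m)])


def test_triangle_filter_retains_independent_and_planted_xor():
    cfg = sn.ScanConfig(seed=1)
    independent = _independent_table(5000, 3, seed=2)
    assert sn.triangle_filter(independent, cfg) == [("v00", "v01", "v02")]
    xor = _xor_table(5000, seed=3)
    assert ("xa", "xb", "xc") in sn.triangle_filter(xor, cfg)


def test_triangle_filter_excludes_duplicated_pair():
    rng = np.random.default_rng(5)
    a = (rng.random(5000) < 0.3).astype(np.int8)
    z = (rng.random(5000) < 0.3).astype(np.int8)
    data = DataMatrix.from_array(np.column_stack([a, a, z]), ["a1", "a2", "z"])
    assert sn.triangle_filter(data, sn.ScanConfig(seed=1)) == []


def test_triangle_filter_ordering_is_lexicographic():
    data = _independent_table(2000, 5, seed=7)
    cfg = sn.ScanConfig(mi_threshold=math.inf, seed=1)
    triples = sn.triangle_filter(data, cfg)
    assert triples == sorted(triples)
    assert len(triples) == math.comb(5, 3)


def test_permutation_pvalue_detects_planted_xor():
    data = _xor_table(5000, seed=11)
    cfg = sn.ScanConfig(permutations=1000, seed=12)
    result = sn.permutation_pvalue(data, ("xa", "xb", "xc"), cfg)
    assert result.omega == pytest.approx(-1.0, abs=0.05)
    assert result.p_value <= 0.01
    assert abs(result.null_mean) < 0.01


def test_permutation_pvalue_deterministic_and_order_invariant():
    data = _xor_table(2000, seed=13)
    cfg = sn.ScanConfig(permutations=199, seed=14)
    a = sn.permutation_pvalue(data, ("xa", "xb", "xc"), cfg)
    b = sn.permutation_pvalue(data, ("xc", "xa", "xb"), cfg)
    assert a.p_value == b.p_value


def test_permutation_pvalue_constant_column_degenerate():
    data = DataMatrix.from_array(
        np.column_stack(
            [
                np.ones(100, dtype=np.int8),
                (np.arange(100) % 2).astype(np.int8),
                (np.arange(100) % 3 == 0).astype(np.int8),
            ]
        ),
        ["const", "b", "c"],
    )
    with pytest.warns(UserWarning, match="degenerate"):
        result = sn.permutation_pvalue(data, ("const", "b", "c"), sn.ScanConfig(seed=1))
    assert result.p_value == 1.0 and result.degenerate


def test_permutation_pvalue_matches_o_information():
    """The bit-packed engine and the generic plug-in estimator agree exactly."""
    data = _xor_table(1500, seed=15, eps=0.2)
    cfg = sn.ScanConfig(permutations=99, seed=16)
    result = sn.permutation_pvalue(data, ("xa", "xb", "xc"), cfg)
    direct = float(sn.o_information(data, ["xa", "xb", "xc"]))
    assert result.omega == pytest.approx(direct, abs=1e-12)


def test_permutation_test_valid_under_null():
    """Under independence, rejection at alpha=0.05 happens ~5% of the time."""
    alpha, reps = 0.05, 200
    cfg_b = 199
    rejections = 0
    for rep in range(reps):
        data = _independent_table(500, 3, seed=1000 + rep)
        cfg = sn.ScanConfig(permutations=cfg_b, seed=rep)
        result = sn.permutation_pvalue(data, tuple(data.columns), cfg)
        rejections += result.p_value <= alpha
    rate = rejections / reps
    bound = 2.58 * math.sqrt(alpha * (1 - alpha) / reps)
    assert abs(rate - alpha) <= bound


def test_bh_adjust_worked_example():
    q = sn.bh_adjust([0.01, 0.04, 0.03, 0.20])
    assert np.round(q, 4).tolist() == [0.04, 0.0533, 0.0533, 0.20]


def _bh_oracle(p):
    """Brute-force step-up: q_i = min over j>=i (sorted) of p_j * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


@settings(max_examples=80, derandomize=True, deadline=None)
@given(
    st.lists(
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=30
    )
)
def test_bh_adjust_matches_oracle(p_values):
    assert np.allclose(sn.bh_adjust(p_values), _bh_oracle(p_values), atol=1e-12)


def test_bh_adjust_edge_cases():
    assert sn.bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]
    assert sn.bh_adjust([0.07]).tolist() == [0.07]
    assert (sn.bh_adjust([0.2, 0.1]) >= np.array([0.2, 0.1])).all()
    with pytest.raises(ValueError):
        sn.bh_adjust([0.5, 1.5])


def test_scan_needs_three_columns():
    data = _independent_table(100, 2, seed=20)
    with pytest.raises(ValueError, match="at least 3"):
        sn.scan(data, sn.ScanConfig(seed=1))


def test_scan_recovers_planted_triplets():
    cfg_gen = sn.SurveyGenConfig(
        n_subjects=5000, n_signs=9, n_diseases=0, n_planted_triplets=3,
        n_planted_pairs=0, flip_noise=0.05, seed=21,
    )
    data, manifest = sn.generate_survey(cfg_gen)
    results = sn.scan(data, sn.ScanConfig(permutations=500, seed=22))
    significant = {frozenset(r.labels) for r in results if r.significant}
    planted = set(manifest.triplet_label_sets())
    assert planted <= significant
    for r in results:
        if r.significant:
            assert r.omega < 0  # one-sided test direction
        assert r.q_value >= r.p_value
        assert r.p_value >= 1 / 501  # +1 smoothing floor at B = 500


def test_scan_results_sorted_and_q_order_invariant():
    data = _xor_table(2000, seed=23, eps=0.1, extra=3)
    results = sn.scan(data, sn.ScanConfig(permutations=199, seed=24))
    keys = [(r.q_value, r.omega) for r in results]
    assert keys == sorted(keys)
    # q-values do not depend on candidate order: BH is permutation-equivariant.
    p = [r.p_value for r in results]
    perm = np.random.default_rng(0).permutation(len(p))
    q_perm = sn.bh_adjust(np.asarray(p)[perm])
    assert np.allclose(np.asarray([r.q_value for r in results])[perm], q_perm, atol=1e-12)


def test_detection_power_monotone_in_sample_size():
    """Detection of a planted noisy XOR does not degrade as n grows."""
    sizes = [250, 500, 1000, 2500, 5000]
    reps = 40
    rates = []
    for size_index, n in enumerate(sizes):
        hits = 0
        for rep in range(reps):
            data = _xor_table(n, seed=3000 + 97 * size_index + rep, eps=0.05)
            cfg = sn.ScanConfig(permutations=199, seed=rep)
            result = sn.permutation_pvalue(data, ("xa", "xb", "xc"), cfg)
            hits += result.p_value <= 0.05
        rates.append(hits / reps)
    se = math.sqrt(0.25 / reps)
    for lo, hi in itertools.pairwise(rates):
        assert hi >= lo - 2 * se, rates


def test_conditional_profile_xor_pattern():
    """Single-sign conditionals sit near the marginal; both-sign conditionals jump."""
    data = _xor_table(5000, seed=31, eps=0.05)
    single = sn.conditional_profile(data, "xc", ["xa"])
    assert abs(single.table["p_target"] - single.marginal).max() < 0.05
    double = sn.conditional_profile(data, "xc", ["xa", "xb"])
    assert abs(double.table["p_target"] - double.marginal).max() > 0.4


def test_conditional_profile_constant_target():
    data = DataMatrix.from_array(
        np.column_stack([np.ones(50, dtype=np.int8), (np.arange(50) % 2)]),
        ["t", "g"],
    )
    profile = sn.conditional_profile(data, "t", ["g"])
    assert (profile.table["p_target"] == 1.0).all()


def test_conditional_profile_empty_cell_is_nan():
    g1 = np.array([0, 0, 1, 1], dtype=np.int8)
    g2 = np.array([0, 0, 1, 1], dtype=np.int8)  # (0,1) and (1,0) never occur
    t = np.array([0, 1, 1, 0], dtype=np.int8)
    data = DataMatrix.from_array(np.column_stack([t, g1, g2]), ["t", "g1", "g2"])
    profile = sn.conditional_profile(data, "t", ["g1", "g2"])
    empty = profile.table[(profile.table["g1"] != profile.table["g2"])]
    assert empty["p_target"].isna().all()
    assert (empty["n"] == 0).all()


def test_scan_config_validation():
    with pytest.raises(ValueError):
        sn.ScanConfig(permutations=50)
    with pytest.raises(ValueError):
        sn.ScanConfig(fdr_q=0.0)
    with pytest.raises(ValueError):
        sn.ScanConfig(mi_threshold=-0.1)
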