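"""The two-level signed KS connectivity score and drug classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fmcm import connectivity as conn
from conftest import library_from_rankings


def brute_force_ks(positions, n):
    """Literal maximization over j of the two running deviations."""
    pos = sorted(positions)
    t = len(pos)
    a = max(j / t - pos[j - 1] / n for j in range(1, t + 1))
    b = max(pos[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
    return a if a > b else -b


class TestKSScore:
    @pytest.mark.parametrize(
        "positions,n,expected",
        [
            ({1, 2}, 10, 0.8),
            ({9, 10}, 10, -0.9),
            ({5}, 10, -0.5),  # a == b tie resolves to -b
        ],
    )
    def test_hand_examples(self, positions, n, expected):
        assert conn.ks_score(positions, n) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            conn.ks_score([], 10)

    def test_invalid_positions_rejected(self):
        with pytest.raises(ValueError):
            conn.ks_score([0, 3], 10)
        with pytest.raises(ValueError):
            conn.ks_score([3, 3], 10)

    @given(
        n=st.integers(min_value=1, max_value=50),
        data=st.data(),
    )
    def test_equals_brute_force_oracle(self, n, data):
        t = data.draw(st.integers(min_value=1, max_value=n))
        positions = data.draw(
            st.lists(st.integers(1, n), min_size=t, max_size=t, unique=True)
        )
        assert conn.ks_score(positions, n) == pytest.approx(brute_force_ks(positions, n))

    @given(n=st.integers(min_value=2, max_value=40), data=st.data())
    def test_reversal_negates_up_to_tie(self, n, data):
        t = data.draw(st.integers(min_value=1, max_value=n))
        positions = data.draw(
            st.lists(st.integers(1, n), min_size=t, max_size=t, unique=True)
        )
        def deviations(pos):
            pos = sorted(pos)
            a = max(j / t - pos[j - 1] / n for j in range(1, t + 1))
            b = max(pos[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
            return a, b

        mirrored = [n + 1 - p for p in positions]
        s, sm = conn.ks_score(positions, n), conn.ks_score(mirrored, n)
        a1, b1 = deviations(positions)
        # mirroring swaps the two deviations up to the 1/n lattice offset
        # (e.g. {1,2} of 10 -> 0.8 but {9,10} -> -0.9)
        assert abs(abs(s) - abs(sm)) <= 1 / n + 1e-12
        if a1 - b1 > 2 / n:  # clear winner on both sides: sign must flip
            assert s > 0 > sm
        elif b1 - a1 > 2 / n:
            assert s < 0 < sm


@pytest.fixture
def toy_library():
    # 6 genes, rankings given top-first
    return library_from_rankings(
        {
            "i1": ["g1", "g2", "g3", "g4", "g5", "g6"],
            "i2": ["g6", "g5", "g4", "g3", "g2", "g1"],
            "i3": ["g3", "g1", "g5", "g2", "g6", "g4"],
            "i4": ["g2", "g4", "g6", "g1", "g3", "g5"],
            "i5": ["g5", "g6", "g1", "g2", "g3", "g4"],
        },
        {"i1": "mimic", "i2": "rev", "i3": "noise", "i4": "noise", "i5": "rev"},
    )


class TestInstanceConnectivity:
    def test_opposite_signs_subtract(self, toy_library):
        ranking = toy_library.rankings["i1"]
        up = {"g1", "g2"}   # top -> ks_up > 0
        down = {"g5", "g6"}  # bottom -> ks_down < 0
        s = conn.instance_connectivity(up, down, ranking)
        ks_up = conn.ks_score(sorted(ranking.loc[list(up)]), 6)
        ks_down = conn.ks_score(sorted(ranking.loc[list(down)]), 6)
        assert np.sign(ks_up) != np.sign(ks_down)
        assert s == pytest.approx(ks_up - ks_down)
        assert s > 0  # instance mimics the query

    def test_same_sign_gives_zero(self, toy_library):
        ranking = toy_library.rankings["i1"]
        s = conn.instance_connectivity({"g1"}, {"g2"}, ranking)  # both near top
        assert s == 0.0

    def test_single_tag_conventions(self, toy_library):
        ranking = toy_library.rankings["i1"]
        up_only = conn.instance_connectivity({"g1", "g2"}, set(), ranking)
        assert up_only == pytest.approx(conn.ks_score(sorted(ranking.loc[["g1", "g2"]]), 6))
        down_only = conn.instance_connectivity(set(), {"g1", "g2"}, ranking)
        assert down_only == pytest.approx(-up_only)

    def test_absent_tags_dropped_then_error(self, toy_library):
        ranking = toy_library.rankings["i1"]
        s = conn.instance_connectivity({"g1", "NOT_A_GENE"}, set(), ranking)
        assert s == pytest.approx(conn.ks_score([1], 6))
        with pytest.raises(ValueError):
            conn.instance_connectivity({"NOT_A_GENE"}, set(), ranking)

    def test_vectorized_matches_scalar(self, toy_library):
        up, down = {"g1", "g3"}, {"g5", "g6"}
        s = conn.score_instances(toy_library, up, down)
        for inst in toy_library.instances:
            expected = conn.instance_connectivity(up, down, toy_library.rankings[inst])
            assert s[inst] == pytest.approx(expected)


class TestDrugES:
    def test_top_positions(self):
        lib = library_from_rankings(
            {f"i{k}": ["g1", "g2", "g3"] for k in range(5)},
            {"i0": "d1", "i1": "d1", "i2": "d2", "i3": "d2", "i4": "d2"},
        )
        # craft s so that d1's instances occupy positions {1, 2}
        s = pd.Series({"i0": 5.0, "i1": 4.0, "i2": 3.0, "i3": 2.0, "i4": 1.0})
        es = conn.drug_es(lib, s)
        assert es["d1"] == pytest.approx(0.6)  # max(0.5-0.2, 1-0.4)

    def test_bottom_positions(self):
        lib = library_from_rankings(
            {f"i{k}": ["g1", "g2", "g3"] for k in range(5)},
            {"i0": "x", "i1": "x", "i2": "x", "i3": "d", "i4": "d"},
        )
        s = pd.Series({"i0": 5.0, "i1": 4.0, "i2": 3.0, "i3": 2.0, "i4": 1.0})
        assert conn.drug_es(lib, s)["d"] == pytest.approx(-0.8)

    def test_all_instances_degenerate(self):
        lib = library_from_rankings(
            {f"i{k}": ["g1", "g2"] for k in range(4)},
            {f"i{k}": "only" for k in range(4)},
        )
        s = pd.Series({f"i{k}": float(k) for k in range(4)})
        assert abs(conn.drug_es(lib, s)["only"]) == pytest.approx(1 / 4)

    def test_tie_break_is_lexicographic(self):
        order = conn.instance_order({"b": 1.0, "a": 1.0, "c": 2.0})
        assert order == ["c", "a", "b"]


class TestPermutationP:
    def test_extreme_drug_small_p(self):
        rng = np.random.default_rng(0)
        insts = {f"i{k:03d}": f"d{k % 50:02d}" for k in range(100)}
        genes = [f"g{i}" for i in range(5)]
        cols = {}
        for inst in insts:
            cols[inst] = list(rng.permutation(genes))
        lib = library_from_rankings(cols, insts)
        s = pd.Series({f"i{k:03d}": float(100 - k) for k in range(100)})
        # drug d00 owns instances i000 and i050 -> position 1 and 51
        s["i050"] = 98.5  # make both of d00's instances near the top
        p = conn.permutation_p(lib, s, "d00", n_perm=1000, seed=1)
        assert p <= 0.01

    def test_determinism(self, toy_library):
        s = pd.Series({"i1": 2.0, "i2": -1.0, "i3": 0.0, "i4": 0.5, "i5": -2.0})
        p1 = conn.permutation_p(toy_library, s, "rev", n_perm=1000, seed=9)
        p2 = conn.permutation_p(toy_library, s, "rev", n_perm=1000, seed=9)
        assert p1 == p2

    def test_cache_matches_direct(self, toy_library):
        s = pd.Series({"i1": 2.0, "i2": -1.0, "i3": 0.0, "i4": 0.5, "i5": -2.0})
        cache = conn.NullESCache(n_perm=1000, seed=9)
        p1 = conn.permutation_p(toy_library, s, "rev", cache=cache)
        p2 = conn.permutation_p(toy_library, s, "rev", n_perm=1000, seed=9)
        assert p1 == p2


class TestClassify:
    @pytest.mark.parametrize(
        "es,p,expected",
        [
            (-0.6, 0.001, conn.BENEFICIAL),
            (0.35, 0.5, conn.HARMFUL),   # no p gate on harmful
            (-0.6, 0.02, conn.NEUTRAL),  # beneficial p gate fails
            (-0.4, 0.001, conn.NEUTRAL),
            (0.2, 0.001, conn.NEUTRAL),
        ],
    )
    def test_threshold_rules(self, es, p, expected):
        assert conn.classify(es, p) == expected

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            conn.classify(0.0, 0.5, beneficial_max=0.1)
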