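import numpy as np
import pandas as pd
import pytest

import supplyscape as ss
from supplyscape.mobility import (
    LevelScheme,
    TransitionCounts,
    classify_levels,
    count_transitions,
    mle_transition_matrix,
    morans_i,
    spatial_lag,
    spatial_markov,
)


def moran_oracle(x, w):
    """Double-loop transliteration of the global Moran's I formula:
    I = sum_ij w_ij (x_i - xbar)(x_j - xbar) / (s^2 sum_ij w_ij),
    with s^2 the population variance of x."""
    n = len(x)
    xbar = np.mean(x)
    s2 = np.sum((x - xbar) ** 2) / n
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * (x[i] - xbar) * (x[j] - xbar)
            s0 += w[i, j]
    return num / (s2 * s0)


def levels_frame(level_lists, years):
    rows = []
    for u, levels in level_lists.items():
        for y, lvl in zip(years, levels):
            rows.append({"unit_id": u, "year": y, "level": lvl})
    return pd.DataFrame(rows)


class TestClassification:
    def test_610_distinct_values_split_quartile_counts(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            {"unit_id": [f"u{i}" for i in range(610)], "year": 2010,
             "ci": rng.permutation(np.linspace(0.001, 0.956, 610))}
        )
        levels, _ = classify_levels(frame)
        assert levels["level"].value_counts().sort_index().tolist() == [153, 152, 152, 153]

    def test_boundary_rule_on_four_values(self):
        frame = pd.DataFrame(
            {"unit_id": list("abcd"), "year": 2010, "ci": [1.0, 2.0, 3.0, 4.0]}
        )
        levels, scheme = classify_levels(frame)
        assert levels["level"].tolist() == [1, 2, 3, 4]
        assert scheme.q1 < scheme.q2 < scheme.q3

    def test_all_equal_values_collapse_to_level_one(self):
        frame = pd.DataFrame({"unit_id": list("abcd"), "year": 2010, "ci": [2.0] * 4})
        with pytest.warns(UserWarning, match="degenerate"):
            levels, _ = classify_levels(frame)
        assert (levels["level"] == 1).all()


class TestTransitions:
    def test_pooled_count_totals(self, index_frame):
        levels, _ = classify_levels(index_frame)
        counts = count_transitions(levels)
        assert counts.total == 61 * 9 == 549
        assert (counts.row_totals == counts.counts.sum(axis=1)).all()

    def test_self_transitions_counted_per_year_pair(self):
        frame = levels_frame({"u": [1, 1, 1]}, [2010, 2011, 2012])
        counts = count_transitions(frame)
        assert counts.counts[0, 0] == 2
        assert counts.total == 2

    def test_non_consecutive_years_rejected(self):
        frame = levels_frame({"u": [1, 1]}, [2010, 2012])
        with pytest.raises(ValueError, match="consecutive"):
            count_transitions(frame)

    def test_mle_worked_row(self):
        counts = TransitionCounts(
            counts=np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [3, 5, 10, 92]])
        )
        matrix = mle_transition_matrix(counts)
        assert np.round(matrix.probabilities[3] * 100, 2).tolist() == [
            2.73, 4.55, 9.09, 83.64,
        ]

    def test_diagonal_counts_give_identity(self):
        matrix = mle_transition_matrix(TransitionCounts(counts=np.diag([5, 4, 3, 2])))
        assert np.allclose(matrix.probabilities, np.eye(4))

    def test_empty_row_is_undefined(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0] = 1
        matrix = mle_transition_matrix(TransitionCounts(counts=counts))
        with pytest.raises(ValueError, match="undefined"):
            matrix.row(3)
        assert np.isnan(matrix.probabilities[3]).all()

    def test_defined_rows_are_stochastic(self, index_frame):
        levels, _ = classify_levels(index_frame)
        matrix = mle_transition_matrix(count_transitions(levels))
        sums = matrix.probabilities[matrix.defined_rows].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestSpatialLag:
    def _weights(self, units, w):
        return ss.SpatialWeights(
            units=units, matrix=np.asarray(w, dtype=float),
            row_standardized=True, binary_adjacency=False,
        )

    def test_mutual_neighbors_swap_values(self):
        frame = pd.DataFrame(
            {"unit_id": ["a", "b"], "year": 2010, "ci": [0.2, 0.8]}
        )
        scheme = LevelScheme(q1=0.25, q2=0.5, q3=0.75)
        w = self._weights(["a", "b"], [[0, 1], [1, 0]])
        lags = spatial_lag(frame, w, scheme)
        assert lags.set_index("unit_id")["lag"].tolist() == [0.8, 0.2]

    def test_four_ring_hand_values(self):
        # ring a-b-c-d-a, each row averages its two neighbors
        units = list("abcd")
        w = self._weights(
            units,
            np.array([[0, 0.5, 0, 0.5], [0.5, 0, 0.5, 0], [0, 0.5, 0, 0.5], [0.5, 0, 0.5, 0]]),
        )
        frame = pd.DataFrame({"unit_id": units, "year": 2010, "ci": [1.0, 2.0, 3.0, 4.0]})
        lags = spatial_lag(frame, w, LevelScheme(q1=1.5, q2=2.5, q3=3.5))
        assert lags["lag"].tolist() == [3.0, 2.0, 3.0, 2.0]


class TestSpatialMarkov:
    def test_toy_conditional_tally_and_partition(self):
        years = [2010, 2011, 2012]
        levels = levels_frame(
            {"a": [1, 2, 2], "b": [2, 2, 3], "c": [3, 4, 4], "d": [4, 4, 4]}, years
        )
        lag_levels = levels_frame(
            {"a": [1, 1, 2], "b": [1, 2, 2], "c": [2, 2, 3], "d": [3, 3, 3]}, years
        ).rename(columns={"level": "lag_level"})
        result = spatial_markov(levels, lag_levels)
        # brute-force tally: under lag I, transitions (a: 1->2, 2->2*, b: 2->2)
        # *a's 2011 lag is I only in the alternative; recompute by hand:
        # origin-year lags: a:(1,1) b:(1,2) c:(2,2) d:(3,3)
        lag1 = result.conditional["I"].counts.counts
        assert lag1[0, 1] == 1  # a 2010: level 1 -> 2 under lag I
        assert lag1[1, 1] == 2  # a 2011 and b 2010: level 2 -> 2 under lag I/I
        total = sum(result.conditional[k].counts.counts for k in "I II III IV".split())
        assert np.array_equal(total, result.unconditional.counts)

    def test_partition_identity_on_simulated_panel(self, index_frame, lattice_weights):
        levels, scheme = classify_levels(index_frame)
        lags = spatial_lag(index_frame, lattice_weights, scheme)
        result = spatial_markov(levels, lags)
        total = sum(m.counts.counts for m in result.conditional.values())
        assert np.array_equal(total, result.unconditional.counts)
        assert result.unconditional.total == 549


class TestMoran:
    def _random_instance(self, seed, n=12):
        rng = np.random.default_rng(seed)
        w = np.triu(rng.integers(0, 2, size=(n, n)), k=1).astype(float)
        w = w + w.T
        w[w.sum(axis=1) == 0, (0,)] = 1.0  # avoid isolates
        w = np.maximum(w, w.T)
        np.fill_diagonal(w, 0.0)
        x = rng.normal(size=n)
        return x, w

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, seed):
        x, w = self._random_instance(seed)
        sw = ss.SpatialWeights(units=[str(i) for i in range(len(x))], matrix=w)
        result = morans_i(x, sw)
        assert result.I == pytest.approx(moran_oracle(x, w), abs=1e-12)

    def test_null_expectation_for_61_units(self, lattice_weights):
        rng = np.random.default_rng(0)
        result = morans_i(rng.normal(size=61), lattice_weights)
        assert result.expected == pytest.approx(-1 / 60)
        assert round(result.expected, 3) == -0.017

    def test_checkerboard_is_negative(self):
        n = 4
        w = np.zeros((16, 16))
        for a in range(16):
            ra, ca = divmod(a, n)
            for b in range(16):
                rb, cb = divmod(b, n)
                if abs(ra - rb) + abs(ca - cb) == 1:
                    w[a, b] = 1.0
        x = np.array([(-1.0) ** ((i // n) + (i % n)) for i in range(16)])
        result = morans_i(x, ss.SpatialWeights(units=[str(i) for i in range(16)], matrix=w))
        assert result.I < 0

    def test_constant_vector_rejected(self, lattice_weights):
        with pytest.raises(ValueError, match="zero variance"):
            morans_i(np.ones(61), lattice_weights)

    def test_permutation_p_detects_structure(self, index_frame, lattice_weights):
        x = index_frame.loc[index_frame["year"] == 2019].sort_values("unit_id")["ci"]
        result = morans_i(
            x.to_numpy(), lattice_weights, method="permutation", rng=0, n_permutations=199
        )
        assert result.p <= 0.01
        assert result.n_permutations == 199

    def test_by_year_layout(self, index_frame, lattice_weights):
        table = ss.morans_i_by_year(index_frame, lattice_weights)
        assert len(table) == 10
        assert set(["year", "I", "E(I)", "SD(I)", "z", "p"]).issubset(table.columns)
        assert (table["I"] > 0).all()  # rho=0.6 generator
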