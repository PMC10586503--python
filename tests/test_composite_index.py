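import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import supplyscape as ss
from supplyscape.composite_index import (
    NormalizedMatrix,
    WeightVector,
    entropy_weights,
    minmax_normalize,
    topsis_scores,
)
from supplyscape.core_data import panel_from_frame
from conftest import tiny_panel_frame


def entropy_weights_oracle(x):
    """Hand transliteration of the entropy-weight formulas, loop form."""
    m, n = x.shape
    w = []
    for j in range(n):
        col = x[:, j]
        total = col.sum()
        e = 0.0
        for i in range(m):
            p = col[i] / total if total > 0 else 0.0
            if p > 0:
                e += p * np.log(p)
        e = -e / np.log(m) if total > 0 else 1.0
        w.append(1.0 - e)
    w = np.array(w)
    return w / w.sum()


class TestNormalization:
    def test_positive_and_negative_direction_columns(self, tiny_schema):
        frame = tiny_panel_frame([2, 4, 6, 6], [2, 4, 6, 6], years=(2010, 2011))
        panel = panel_from_frame(frame, tiny_schema)
        norm = minmax_normalize(panel)
        # data order is unit-major: a = (2,4,6,6) etc.
        assert np.allclose(norm.values[:, 0], [0, 0.5, 1, 1])  # benefit
        assert np.allclose(norm.values[:, 1], [1, 0.5, 0, 0])  # cost reversed

    def test_constant_column_becomes_half_with_warning(self, tiny_schema):
        frame = tiny_panel_frame([5, 5, 5, 5], [1, 2, 3, 4])
        panel = panel_from_frame(frame, tiny_schema)
        with pytest.warns(UserWarning, match="constant"):
            norm = minmax_normalize(panel)
        assert np.allclose(norm.values[:, 0], 0.5)

    def test_scale_invariance_of_index(self, tiny_schema):
        frame = tiny_panel_frame([1, 2, 3, 4], [4, 3, 2, 1])
        base, _ = ss.build_index_panel(panel_from_frame(frame, tiny_schema))
        scaled = frame.assign(a=frame["a"] * 1000.0)
        other, _ = ss.build_index_panel(panel_from_frame(scaled, tiny_schema))
        assert np.allclose(base["ci"], other["ci"])


class TestEntropyWeights:
    def test_constant_column_gets_zero_weight(self):
        x = NormalizedMatrix(values=np.array([[0.5, 0.0], [0.5, 0.5], [0.5, 1.0]]),
                             indicator_ids=["a", "b"])
        w = entropy_weights(x)
        # constant-at-0.5 column still varies nothing relative to its sum -> near 0
        assert w.weights[0] == pytest.approx(0.0, abs=1e-12)
        assert w.weights[1] == pytest.approx(1.0)

    def test_symmetric_columns_get_equal_weights(self):
        x = NormalizedMatrix(values=np.array([[0.0, 1.0], [0.5, 0.5], [1.0, 0.0]]),
                             indicator_ids=["a", "b"])
        w = entropy_weights(x)
        assert w.weights == pytest.approx([0.5, 0.5])

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_loop_oracle_and_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(size=(rng.integers(3, 12), rng.integers(2, 6)))
        w = entropy_weights(NormalizedMatrix(values=x, indicator_ids=[f"i{j}" for j in range(x.shape[1])]))
        assert np.allclose(w.weights, entropy_weights_oracle(x), atol=1e-12)
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=(10, 4))
        ids = ["a", "b", "c", "d"]
        w = entropy_weights(NormalizedMatrix(values=x, indicator_ids=ids))
        perm = [2, 0, 3, 1]
        wp = entropy_weights(NormalizedMatrix(values=x[:, perm], indicator_ids=[ids[i] for i in perm]))
        assert np.allclose(wp.weights, w.weights[perm])

    def test_all_constant_errors(self):
        x = NormalizedMatrix(values=np.full((4, 2), 0.5), indicator_ids=["a", "b"])
        with pytest.raises(ValueError, match="constant"):
            entropy_weights(x)


class TestTopsis:
    def _matrix(self, values):
        return NormalizedMatrix(values=np.asarray(values, dtype=float),
                                indicator_ids=[f"i{j}" for j in range(np.shape(values)[1])])

    def _weights(self, w):
        w = np.asarray(w, dtype=float)
        return WeightVector(weights=w, indicator_ids=[f"i{j}" for j in range(w.size)], source="fixed")

    def test_extremes_score_one_and_zero(self):
        scores = topsis_scores(self._matrix([[1, 1], [0, 0], [0.3, 0.6]]),
                               self._weights([0.5, 0.5]))
        assert scores.ci[0] == pytest.approx(1.0)
        assert scores.ci[1] == pytest.approx(0.0)

    def test_symmetric_pair_scores_half(self):
        # two observations mirrored about the column midpoints, equal weights:
        # D+ and D- swap, so both land exactly on 0.5
        scores = topsis_scores(self._matrix([[0.2, 0.8], [0.8, 0.2]]),
                               self._weights([0.5, 0.5]))
        assert scores.ci == pytest.approx([0.5, 0.5])

    def test_closeness_identity(self):
        rng = np.random.default_rng(3)
        scores = topsis_scores(self._matrix(rng.uniform(size=(20, 5))),
                               self._weights(np.full(5, 0.2)))
        assert np.allclose(scores.ci + scores.d_plus / (scores.d_plus + scores.d_minus), 1.0)

    def test_dominance_monotonicity(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(0.2, 0.8, size=(10, 4))
        dominated = base[3].copy()
        dominating = np.minimum(dominated + 0.1, 1.0)
        x = np.vstack([base, dominated, dominating])
        scores = topsis_scores(self._matrix(x), self._weights(np.full(4, 0.25)))
        assert scores.ci[-1] >= scores.ci[-2]

    def test_degenerate_observation_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            topsis_scores(self._matrix([[0.5, 0.5], [0.5, 0.5]]), self._weights([0.5, 0.5]))


class TestBuildIndexPanel:
    def test_fixture_panel_yields_610_bounded_scores(self, index_frame):
        assert len(index_frame) == 610
        assert index_frame["ci"].between(0, 1).all()

    def test_fixed_weight_mode_uses_published_weights(self, sim_panel):
        _, wvec = ss.build_index_panel(sim_panel, weight_mode="fixed")
        assert wvec.source == "fixed"
        assert np.allclose(wvec.weights, ss.table1_schema().fixed_weights)

    def test_dominating_unit_ranks_first(self, tiny_schema):
        # u2 beats u1 on the benefit indicator and on the (reversed) cost one
        frame = tiny_panel_frame([1, 1, 9, 9], [8, 8, 2, 2])
        scores, _ = ss.build_index_panel(panel_from_frame(frame, tiny_schema))
        by_unit = scores.groupby("unit_id")["ci"].mean()
        assert by_unit["u2"] > by_unit["u1"]
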