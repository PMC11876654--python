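"""w-space direction arithmetic, label-group selection, and recovery of the
ground-truth severity axis on the oracle decoder."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import severity_thresholded_groups
from dermavec import gan, simulate
from dermavec.directions import (
    DirectionVector,
    LabelRecord,
    apply_fraction,
    compose,
    compute_direction,
    find_compensation_scale,
    load_direction,
    save_direction,
    select_label_groups,
)
from dermavec.evaluate import erythema_index


class TestComputeDirection:
    def test_identical_groups_give_zero_vector(self):
        g = [np.ones(4), np.zeros(4)]
        assert np.allclose(compute_direction(g, g).values, 0.0)

    def test_hand_computed_two_dim_example(self):
        target = [np.array([1.0, 0.0]), np.array([3.0, 0.0])]
        source = [np.array([0.0, 1.0]), np.array([0.0, 3.0])]
        d = compute_direction(target, source)
        assert np.allclose(d.values, [2.0, -2.0])

    def test_group_sizes_recorded_at_study_scale(self):
        rng = np.random.default_rng(0)
        severe = list(rng.standard_normal((55, 512)))
        moderate = list(rng.standard_normal((54, 512)))
        d = compute_direction(moderate, severe, name="treatment")
        assert d.w_dim == 512
        assert (d.n_positive_group, d.n_negative_group) == (54, 55)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a = list(rng.standard_normal((5, 16)))
        b = list(rng.standard_normal((7, 16)))
        assert np.allclose(
            compute_direction(a, b).values, -compute_direction(b, a).values
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            compute_direction([], [np.zeros(3)])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="w_dim"):
            compute_direction([np.zeros(3)], [np.zeros(4)])


class TestApplyAndCompose:
    def test_zero_fraction_is_identity_and_input_unmodified(self):
        w = np.array([1.0, 2.0])
        d = DirectionVector(values=np.array([5.0, -5.0]))
        out = apply_fraction(w, d, 0.0)
        assert np.array_equal(out, w) and out is not w

    def test_fraction_round_trip(self):
        w = np.array([1.0, 1.0, 1.0])
        d = DirectionVector(values=np.array([0.3, -0.7, 2.0]))
        back = apply_fraction(apply_fraction(w, d, 1.0), d, -1.0)
        assert np.allclose(back, w)

    def test_half_fraction_componentwise(self):
        w = np.array([1.0, 1.0])
        d = DirectionVector(values=np.array([2.0, -2.0]))
        assert np.allclose(apply_fraction(w, d, 0.5), [2.0, 0.0])

    def test_singleton_composition(self):
        d = DirectionVector(values=np.array([1.0, 2.0]))
        assert np.allclose(compose([(d, 1.0)]).values, d.values)

    def test_two_halves_equal_whole(self):
        d = DirectionVector(values=np.array([1.0, -4.0]))
        assert np.allclose(compose([(d, 0.5), (d, 0.5)]).values, d.values)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_composite_equals_sequential_application(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.standard_normal(8)
        d1 = DirectionVector(values=rng.standard_normal(8))
        d2 = DirectionVector(values=rng.standard_normal(8))
        f1, f2 = rng.uniform(-1.5, 1.5, 2)
        sequential = apply_fraction(apply_fraction(w, d1, f1), d2, f2)
        composite = apply_fraction(w, compose([(d1, f1), (d2, f2)]), 1.0)
        assert np.allclose(sequential, composite)

    def test_compose_rejects_empty_and_mismatched(self):
        with pytest.raises(ValueError):
            compose([])
        with pytest.raises(ValueError, match="w_dim"):
            compose([(DirectionVector(values=np.zeros(3)), 1.0),
                     (DirectionVector(values=np.zeros(4)), 1.0)])


class TestLabelGroups:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["image_id", "erythema", "scale", "rater_id"])

    def test_unanimous_severe(self):
        rows = [("i1", 3, 3, r) for r in "ABC"]
        pos, neg = select_label_groups(self._table(rows), "severity")
        assert pos == ["i1"] and neg == []

    def test_unanimous_moderate(self):
        rows = [("i1", 2, 2, r) for r in "ABC"]
        pos, neg = select_label_groups(self._table(rows), "severity")
        assert pos == [] and neg == ["i1"]

    def test_consensus_rule_matches_hand_evaluation(self):
        # combined (erythema+scale)/2 averaged over raters, rounded half-up
        rows = [
            ("a", 4, 4, "A"), ("a", 3, 3, "B"),   # mean 3.5 -> 4: severe
            ("b", 3, 2, "A"), ("b", 2, 3, "B"),   # mean 2.5 -> 3: severe
            ("c", 2, 2, "A"), ("c", 2, 2, "B"),   # 2: moderate
            ("d", 2, 1, "A"), ("d", 1, 2, "B"),   # 1.5 -> 2: moderate
            ("e", 1, 1, "A"), ("e", 1, 1, "B"),   # 1: neither
            ("f", 0, 0, "A"), ("f", 0, 1, "B"),   # ~0: neither
        ]
        pos, neg = select_label_groups(self._table(rows), "severity")
        assert pos == ["a", "b"]
        assert neg == ["c", "d"]

    def test_coverage_rule_thresholds_at_half(self):
        df = pd.DataFrame(
            {
                "image_id": ["a", "b", "c"],
                "erythema": 2, "scale": 2, "rater_id": "A",
                "area_fraction": [0.2, 0.5, 0.7],
            }
        )
        small, large = select_label_groups(df, "coverage")
        assert small == ["a"] and large == ["b", "c"]

    def test_label_records_accepted(self):
        recs = [LabelRecord("x", 3, 3, "A"), LabelRecord("y", 2, 2, "A")]
        pos, neg = select_label_groups(recs, "severity")
        assert pos == ["x"] and neg == ["y"]

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="rule"):
            select_label_groups(self._table([("i", 1, 1, "A")]), "hue")

    def test_out_of_scale_label_record_rejected(self):
        with pytest.raises(ValueError):
            LabelRecord("x", 5, 0, "A")


class TestOracleRecovery:
    """The mean-difference estimator against the known severity axis e0."""

    def test_recovery_accurate_when_nonsemantic_dimension_small(self):
        # 55-vs-54 groups recover the axis when w carries few nuisance dims
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pool = rng.standard_normal((6000, 8))
            severe, moderate = severity_thresholded_groups(pool, 150, 150)
            d = compute_direction(list(moderate), list(severe))
            cosine = abs(d.values[0]) / np.linalg.norm(d.values)
            assert cosine >= 0.9

    def test_recovery_improves_with_group_size_at_full_dimension(self):
        cosines = []
        for n in (55, 1000, 8000):
            rng = np.random.default_rng(0)
            pool = rng.standard_normal((min(40 * n + 20000, 350000), 512))
            severe, moderate = severity_thresholded_groups(pool, n, n)
            d = compute_direction(list(moderate), list(severe))
            cosines.append(abs(d.values[0]) / np.linalg.norm(d.values))
        assert cosines[0] < cosines[1] < cosines[2]
        assert cosines[2] >= 0.9

    def test_treatment_vector_reduces_severity_monotonically(self, oracle32):
        rng = np.random.default_rng(2)
        pool = rng.standard_normal((6000, 512))
        severe, moderate = severity_thresholded_groups(pool, 55, 54)
        treat = compute_direction(list(moderate), list(severe), name="treatment")
        w = severe[0]
        indices = []
        for frac in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            wq = apply_fraction(w, treat, frac)
            img = oracle32.synthesize(wq)
            mask = simulate.plaque_mask(gan.decode_w(wq), 32)
            indices.append(erythema_index(img, mask))
        assert all(a > b for a, b in zip(indices, indices[1:]))


class TestSerialization:
    def test_direction_round_trip(self, tmp_path):
        d = DirectionVector(
            values=np.array([0.5, -1.25, 3.0]),
            name="treatment",
            n_positive_group=54,
            n_negative_group=55,
        )
        path = tmp_path / "treatment.csv"
        save_direction(d, path)
        back = load_direction(path)
        assert np.array_equal(back.values, d.values)
        assert back.name == "treatment"
        assert (back.n_positive_group, back.n_negative_group) == (54, 55)
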