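"""Scale encoding and scoring: worked examples, invariants, config round trip."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvds.scale import (
    MVDS_ITEM_IDS,
    MVDSScorer,
    PASGrade,
    RatingProfile,
    ScaleDefinition,
    ScaleItem,
    ScaleValidationError,
    load_scale_definition,
    pas_to_aspiration_level,
    score_profile,
)


def random_profile(scale, rng) -> RatingProfile:
    return RatingProfile(
        {it.item_id: int(rng.integers(0, it.n_levels)) for it in scale.items}
    )


class TestEncodedScale:
    def test_nine_items_total_100(self, scale):
        assert len(scale.items) == 9
        assert scale.max_total == 100.0
        assert sum(it.max_weight for it in scale.items) == 100.0
        assert scale.item_ids == MVDS_ITEM_IDS

    def test_aspiration_item_levels(self, scale):
        asp = scale.item("aspiration")
        assert asp.levels == ("intact", "penetration", "aspiration")
        assert asp.weights == (0.0, 8.5, 17.0)

    def test_best_levels_carry_zero_weight(self, scale):
        assert sum(it.weights[0] for it in scale.items) == 0.0


class TestScoring:
    def test_all_best_scores_zero(self, scale):
        assert score_profile(RatingProfile.all_best(scale), scale).total == 0.0

    def test_all_worst_scores_hundred(self, scale):
        assert score_profile(RatingProfile.all_worst(scale), scale).total == 100.0

    @pytest.mark.parametrize(
        ("item_id", "level", "expected"),
        [
            ("lip_closure", 1, 6.0),
            ("mastication", 1, 11.5),
            ("oral_transit_time", 1, 4.0),
            ("triggering_pharyngeal_swallow", 1, 7.0),
            ("epiglottis_inversion", 1, 13.0),
            ("valleculae_residue", 3, 9.0),
            ("pyriformis_residue", 3, 19.5),
            ("pharyngeal_wall_coating", 1, 13.0),
            ("aspiration", 1, 8.5),
            ("aspiration", 2, 17.0),
        ],
    )
    def test_single_item_worked_examples(self, scale, item_id, level, expected):
        """Each printed per-item weight is reproduced exactly by a profile
        deviating from normal on that single item."""
        prof = RatingProfile.single_item(scale, item_id, level)
        res = score_profile(prof, scale)
        assert res.total == expected
        assert res.breakdown[item_id] == expected

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(data=st.data())
    def test_additivity_bounds_monotonicity(self, scale, data):
        """Breakdown sums exactly to the total, totals stay in [0, 100], and
        worsening any single item never decreases the total."""
        levels = {
            it.item_id: data.draw(
                st.integers(0, it.n_levels - 1), label=it.item_id
            )
            for it in scale.items
        }
        prof = RatingProfile(levels)
        res = score_profile(prof, scale)
        assert res.total == sum(res.breakdown.values())  # exact, no drift
        assert 0.0 <= res.total <= 100.0
        for it in scale.items:
            if levels[it.item_id] < it.n_levels - 1:
                worse = dict(levels)
                worse[it.item_id] += 1
                assert score_profile(RatingProfile(worse), scale).total >= res.total

    def test_missing_item_names_item(self, scale):
        levels = {i: 0 for i in scale.item_ids if i != "mastication"}
        with pytest.raises(ScaleValidationError, match="mastication"):
            score_profile(RatingProfile(levels), scale)

    def test_out_of_range_level_names_item(self, scale):
        prof = RatingProfile.single_item(scale, "lip_closure", 0)
        bad = dict(prof.levels)
        bad["lip_closure"] = 5
        with pytest.raises(ScaleValidationError, match="lip_closure"):
            score_profile(RatingProfile(bad), scale)


class TestPASMapping:
    def test_enumerated_mapping(self):
        """Exactly grades 6-8 (the 'greater than 5' rule) map to the
        aspiration level; 1 is intact and 2-5 penetration; monotone."""
        levels = [pas_to_aspiration_level(PASGrade(v)) for v in range(1, 9)]
        assert levels == [0, 1, 1, 1, 1, 2, 2, 2]
        assert levels == sorted(levels)

    @pytest.mark.parametrize("bad", [0, 9, -1, 3.5, "3"])
    def test_invalid_grades_rejected(self, bad):
        with pytest.raises(ScaleValidationError):
            pas_to_aspiration_level(bad if not isinstance(bad, int) else PASGrade(bad))


class TestConfigRoundTrip:
    def test_yaml_round_trip_identical(self, scale, tmp_path):
        p = tmp_path / "scale.yaml"
        scale.to_yaml(p)
        reloaded = load_scale_definition(p)
        assert reloaded == scale
        for a, b in zip(scale.items, reloaded.items):
            assert a.weights == b.weights

    def test_weight_sum_mismatch_rejected(self, scale, tmp_path):
        d = scale.to_dict()
        d["max_total"] = 99.0
        import yaml

        p = tmp_path / "bad.yaml"
        p.write_text(yaml.safe_dump(d))
        with pytest.raises(ScaleValidationError):
            load_scale_definition(p)

    def test_malformed_config_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("items: 3\n")
        with pytest.raises(ScaleValidationError):
            load_scale_definition(p)


class TestScaleItemInvariants:
    def test_decreasing_weights_rejected(self):
        with pytest.raises(ScaleValidationError):
            ScaleItem("x", "X", ("a", "b", "c"), (0.0, 5.0, 3.0))

    def test_nonzero_first_weight_rejected(self):
        with pytest.raises(ScaleValidationError):
            ScaleItem("x", "X", ("a", "b"), (1.0, 2.0))

    def test_single_level_rejected(self):
        with pytest.raises(ScaleValidationError):
            ScaleItem("x", "X", ("a",), (0.0,))

    def test_declared_total_must_match_items(self, scale):
        with pytest.raises(ScaleValidationError):
            ScaleDefinition("broken", scale.items, max_total=95.0)


class TestMVDSScorer:
    def test_matches_row_wise_scoring(self, scale, rng):
        levels = pd.DataFrame(
            {
                it.item_id: rng.integers(0, it.n_levels, size=20)
                for it in scale.items
            }
        )
        totals = MVDSScorer().fit(levels).transform(levels)[:, 0]
        expected = [
            score_profile(RatingProfile({c: int(row[c]) for c in levels}), scale).total
            for _, row in levels.iterrows()
        ]
        assert np.array_equal(totals, expected)

    def test_breakdown_sums_to_total(self, scale, rng):
        levels = np.column_stack(
            [rng.integers(0, it.n_levels, size=10) for it in scale.items]
        )
        scorer = MVDSScorer().fit(levels)
        bd = scorer.breakdown(levels)
        assert np.allclose(bd.sum(axis=1), scorer.transform(levels)[:, 0])

    def test_sklearn_clone_and_params(self, scale):
        from sklearn.base import clone

        scorer = MVDSScorer(scale=scale)
        assert clone(scorer).get_params()["scale"] == scale
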