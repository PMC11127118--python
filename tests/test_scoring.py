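"""Weight-table scoring, categorization and table validation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raicd.cohort import AGE_BANDS, DEFICITS, FUNCTIONAL_LEVELS, ParameterVector
from raicd.errors import WeightTableError
from raicd.scoring import (
    CategoryThresholds,
    WeightTable,
    categorize,
    categorize_array,
    enumerate_parameter_vectors,
    load_weight_table,
    save_weight_table,
    score_frame,
    total_score,
    validate_weight_table,
)


def _ref_vector(**kw):
    base = dict(age_band="<=19", male=False, functional_status="independent")
    base.update(kw)
    return ParameterVector(**base)


class TestInstrumentCells:
    """Singleton parameter vectors reproduce every published table cell."""

    def test_reference_vector_scores_zero(self, wt):
        assert total_score(_ref_vector(), wt).score == 0

    @pytest.mark.parametrize("band", AGE_BANDS)
    def test_age_cells_without_and_with_cancer(self, wt, band):
        wo = total_score(_ref_vector(age_band=band), wt).score
        wc = total_score(
            _ref_vector(age_band=band, cancer=True, cancer_tier="severe"), wt
        ).score
        assert (wo, wc) == tuple(wt.age_cancer[band])

    def test_male_cell(self, wt):
        assert total_score(_ref_vector(male=True), wt).score == 3

    @pytest.mark.parametrize(
        "deficit, points",
        [
            ("weight_loss", 2), ("poor_appetite", 1), ("kidney_failure", 3),
            ("congestive_heart_failure", 3), ("shortness_of_breath", 2),
        ],
    )
    def test_deficit_cells(self, wt, deficit, points):
        assert total_score(_ref_vector(**{deficit: True}), wt).score == points

    @pytest.mark.parametrize(
        "fs, cog, points",
        [
            ("independent", False, 0), ("independent", True, 9),
            ("partially_dependent", False, 10), ("partially_dependent", True, 15),
            ("totally_dependent", False, 20), ("totally_dependent", True, 21),
        ],
    )
    def test_function_cognition_cells(self, wt, fs, cog, points):
        pv = _ref_vector(functional_status=fs, cognitive_decline=cog)
        assert total_score(pv, wt).score == points

    def test_worked_example_sums_table_cells(self, wt):
        pv = ParameterVector(
            age_band="65-69", male=True, congestive_heart_failure=True,
            kidney_failure=True, functional_status="independent",
        )
        assert total_score(pv, wt).score == 22 + 3 + 3 + 3

    def test_maximal_vector_hits_81(self, wt):
        pv = ParameterVector(
            age_band=">=100", male=True, cancer=True, cancer_tier="severe",
            weight_loss=True, poor_appetite=True, kidney_failure=True,
            congestive_heart_failure=True, shortness_of_breath=True,
            functional_status="totally_dependent", cognitive_decline=True,
        )
        assert total_score(pv, wt).score == 81


class TestEnumeration:
    def test_full_grid_range_and_breakdown(self, wt):
        scores = []
        for pv in enumerate_parameter_vectors():
            res = total_score(pv, wt)
            assert sum(res.breakdown.values()) == res.score
            scores.append(res.score)
        assert len(scores) == 18 * 2 * 2 * 2**5 * 3 * 2
        assert min(scores) == 0 and max(scores) == 81

    def test_category_counts_match_interval_oracle(self, wt):
        # independent oracle: classify by explicit interval membership
        def oracle(s):
            if 0 <= s <= 26:
                return "robust"
            if 27 <= s <= 35:
                return "normal"
            if 36 <= s <= 45:
                return "frail"
            return "very_frail"

        from collections import Counter

        ours, theirs = Counter(), Counter()
        for pv in enumerate_parameter_vectors():
            res = total_score(pv, wt)
            ours[res.category] += 1
            theirs[oracle(res.score)] += 1
        assert ours == theirs


class TestCategorize:
    @pytest.mark.parametrize(
        "score, cat",
        [
            (0, "robust"), (26, "robust"), (27, "normal"), (35, "normal"),
            (36, "frail"), (45, "frail"), (46, "very_frail"), (81, "very_frail"),
        ],
    )
    def test_published_boundaries(self, score, cat):
        assert categorize(score) == cat

    def test_array_form_agrees_with_scalar(self):
        s = np.arange(0, 82)
        assert list(categorize_array(s)) == [categorize(k) for k in s]

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            categorize(-1)

    def test_inconsistent_thresholds_rejected(self):
        with pytest.raises(ValueError):
            CategoryThresholds(robust_below=40, normal_upper=35, frail_upper=45)


_pv_strategy = st.builds(
    ParameterVector,
    age_band=st.sampled_from(AGE_BANDS),
    male=st.booleans(),
    weight_loss=st.booleans(),
    poor_appetite=st.booleans(),
    kidney_failure=st.booleans(),
    congestive_heart_failure=st.booleans(),
    shortness_of_breath=st.booleans(),
    cognitive_decline=st.booleans(),
    cancer=st.just(False),
    functional_status=st.sampled_from(FUNCTIONAL_LEVELS),
)


class TestMonotonicity:
    @settings(max_examples=80, derandomize=True)
    @given(_pv_strategy, st.sampled_from(DEFICITS + ("cognitive_decline",)))
    def test_setting_a_deficit_never_lowers_score(self, pv, deficit):
        from raicd.scoring import default_weight_table

        wt = default_weight_table()
        flipped = dataclasses.replace(pv, **{deficit: True})
        assert total_score(flipped, wt).score >= total_score(pv, wt).score

    @settings(max_examples=80, derandomize=True)
    @given(_pv_strategy)
    def test_increasing_dependency_never_lowers_score(self, pv):
        from raicd.scoring import default_weight_table

        wt = default_weight_table()
        order = ["independent", "partially_dependent", "totally_dependent"]
        i = order.index(pv.functional_status)
        if i < 2:
            higher = dataclasses.replace(pv, functional_status=order[i + 1])
            assert total_score(higher, wt).score >= total_score(pv, wt).score


class TestValidation:
    def test_default_table_passes_with_published_range(self, wt):
        rep = validate_weight_table(wt)
        assert rep.ok and rep.min_score == 0 and rep.max_score == 81

    def test_cancer_monotonicity_violation_detected(self, wt):
        bad = WeightTable(**{**wt.__dict__})
        bad.age_cancer = dict(wt.age_cancer)
        bad.age_cancer["65-69"] = (22, 21)
        rep = validate_weight_table(bad)
        assert not rep.ok and any("cancer" in f for f in rep.failures)

    def test_empty_table_reports_missing_bands(self):
        bad = WeightTable(age_cancer={}, male_points=0, deficit_points={},
                          function_cognition={})
        rep = validate_weight_table(bad)
        assert not rep.ok and any("missing bands" in f for f in rep.failures)

    def test_unknown_band_raises_configuration_error(self, wt):
        partial = WeightTable(
            age_cancer={"<=19": (0, 43)}, male_points=3,
            deficit_points=wt.deficit_points,
            function_cognition=wt.function_cognition,
        )
        with pytest.raises(WeightTableError, match="band"):
            total_score(_ref_vector(age_band="40-44"), partial)


class TestFrameScoring:
    def test_frame_matches_scalar_on_enumeration_sample(self, wt):
        pvs = [pv for i, pv in enumerate(enumerate_parameter_vectors()) if i % 97 == 0]
        df = pd.DataFrame(
            {
                "age_band": [p.age_band for p in pvs],
                "male": [p.male for p in pvs],
                "cancer": [p.cancer for p in pvs],
                "functional_status": [p.functional_status for p in pvs],
                "cognitive_decline": [p.cognitive_decline for p in pvs],
                **{d: [getattr(p, d) for p in pvs] for d in DEFICITS},
            }
        )
        out = score_frame(df, wt)
        expected = [total_score(p, wt).score for p in pvs]
        assert list(out["score"]) == expected
        pts_cols = [c for c in out.columns if c.startswith("pts_")]
        assert (out[pts_cols].sum(axis=1) == out["score"]).all()

    def test_round_trip(self, wt, tmp_path):
        path = tmp_path / "wt.yaml"
        save_weight_table(wt, path)
        back = load_weight_table(path)
        assert back.to_dict() == wt.to_dict()
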