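"""Questionnaire scoring, composites, exposure and inclusion filtering."""

import numpy as np
import pandas as pd
import pytest

from psyflex import survey_scores as ss
from psyflex.errors import DegenerateInputError, ValidationError


class TestOlife:
    def test_all_non_endorsed_scores_zero(self):
        s = ss.score_olife([0] * 43)
        assert s.olife_total == 0
        assert all(v == 0 for v in s.facets.values())

    def test_all_endorsed_scores_scale_maximum(self):
        s = ss.score_olife([1] * 43)
        assert s.olife_total == 43
        assert sorted(len(v) for v in ss.load_olife_key()["facets"].values()) == [10, 10, 11, 12]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_facets_partition_total(self, seed):
        rng = np.random.default_rng(seed)
        items = rng.integers(0, 2, 43)
        s = ss.score_olife(items)
        assert sum(s.facets.values()) == s.olife_total

    @pytest.mark.parametrize("bad", [[0] * 42, [0] * 44, [0.5] * 43, [2] * 43])
    def test_invalid_items_rejected(self, bad):
        with pytest.raises(ValidationError):
            ss.score_olife(bad)


class TestPdiPlus:
    def test_all_non_endorsed(self):
        assert ss.score_pdi_plus([0] * 26) == (0, 0)

    def test_cape_items_only(self):
        items = [0] * 21 + [1] * 5
        assert ss.score_pdi_plus(items) == (5, 0)

    def test_disturbance_is_mean_distress_over_endorsed(self):
        items = [1, 1] + [0] * 24
        distress = [4, 2] + [5] * 24  # non-endorsed distress must be ignored
        assert ss.pdi_disturbance(items, distress) == pytest.approx(3.0)
        assert np.isnan(ss.pdi_disturbance([0] * 26, distress))


class TestComposite:
    def test_two_respondent_closed_form(self):
        # z-scores of a 2-point sample are +/- 1/sqrt(2) under ddof=1;
        # averaging two identical-sign z's and re-standardising keeps them
        comp = ss.composite_schizotypy([0, 43], [0, 26])
        assert comp == pytest.approx([-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_mean_zero_sd_one(self, scored_frame):
        comp = scored_frame["schizotypy_composite"]
        assert comp.mean() == pytest.approx(0, abs=1e-10)
        assert comp.std(ddof=1) == pytest.approx(1, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_rank_order_matches_standardised_sum(self, seed):
        rng = np.random.default_rng(seed)
        olife = rng.integers(0, 44, 60)
        pdi = rng.integers(0, 27, 60)
        comp = ss.composite_schizotypy(olife, pdi)
        oracle = ss.zscore(olife) + ss.zscore(pdi)
        assert np.array_equal(np.argsort(comp), np.argsort(oracle))

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        olife = rng.integers(0, 44, 40).astype(float)
        pdi = rng.integers(0, 27, 40).astype(float)
        a = ss.composite_schizotypy(olife, pdi)
        b = ss.composite_schizotypy(3.0 * olife + 7.0, 0.5 * pdi - 2.0)
        assert np.allclose(a, b)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateInputError):
            ss.composite_schizotypy([5, 5, 5], [1, 2, 3])


class TestExposure:
    def test_user_at_sample_means_scores_zero(self):
        freq = np.array([2.0, 4.0, 6.0])
        rec = np.array([1.0, 3.0, 5.0])
        out = ss.exposure_composite(freq, rec)
        assert out[1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("bump", [0.5, 1, 2])
    def test_monotone_in_frequency(self, bump):
        freq = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rec = np.array([3.0, 1.0, 5.0, 2.0, 4.0])
        base = ss.exposure_composite(freq, rec)
        bumped = ss.exposure_composite(freq + np.array([0, bump, 0, 0, 0]), rec)
        assert bumped[1] > base[1]

    def test_never_user_gets_subsample_minimum(self):
        freq = np.array([2.0, 6.0, 0.0])
        rec = np.array([2.0, 6.0, 0.0])
        never = np.array([False, False, True])
        out = ss.exposure_composite(freq, rec, never_user=never)
        assert out[2] == pytest.approx(np.min(out[:2]))
        out2 = ss.exposure_composite(freq, rec, never_user=never, never_user_policy="exclude")
        assert np.isnan(out2[2])

    def test_missing_rating_flagged_not_standardised(self):
        freq = np.array([2.0, np.nan, 4.0, 6.0])
        rec = np.array([2.0, 3.0, 4.0, 6.0])
        out = ss.exposure_composite(freq, rec)
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2, 3]]).all()


class TestYoungHealthyFilter:
    def _records(self):
        return pd.DataFrame(
            {
                "age": [25, 36, 17, 30, np.nan, 35, 18],
                "diag_psychiatric": [0, 0, 0, 1, 0, 0, 0],
                "diag_neurological": 0,
                "diag_head_trauma": 0,
                "diag_serious_medical": 0,
            }
        )

    def test_boundaries_and_flags(self):
        kept, rep = ss.young_healthy_filter(self._records())
        assert list(kept.index) == [0, 5, 6]  # 18 and 35 inclusive; 36/17 out
        assert rep.n_input == 7 and rep.n_retained == 3
        assert rep.n_missing_age == 1 and rep.n_flag_excluded == 1

    def test_idempotent(self):
        kept, _ = ss.young_healthy_filter(self._records())
        again, rep = ss.young_healthy_filter(kept)
        pd.testing.assert_frame_equal(kept, again)
        assert rep.n_retained == rep.n_input

    def test_empty_input(self):
        kept, rep = ss.young_healthy_filter(pd.DataFrame({"age": []}))
        assert len(kept) == 0 and rep.n_retained == 0

    def test_study_scale_retention(self, scored_frame):
        """~1032 screened -> ~701 young healthy under default generator."""
        _, rep = ss.young_healthy_filter(scored_frame)
        assert rep.n_input == 1032
        assert abs(rep.n_retained - 701) < 50  # binomial spread around the target


def test_cohort_medians_near_instrument_targets(scored_frame):
    assert abs(scored_frame["olife_total"].median() - 15) <= 4
    assert abs(scored_frame["pdi_plus_total"].median() - 6) <= 3


def test_survey_xlsx_round_trip(tmp_path, survey_frame):
    """Real-data ingestion path: XLSX + codebook mapping reproduces scoring."""
    sub = survey_frame.head(50)
    renamed = sub.rename(columns={"olife_item_1": "OLIFE_01", "age": "AGE_YEARS"})
    path = tmp_path / "survey.xlsx"
    renamed.to_excel(path, index=False)
    back = ss.read_survey(path, codebook={"OLIFE_01": "olife_item_1", "AGE_YEARS": "age"})
    scored_a = ss.score_survey_table(back)
    scored_b = ss.score_survey_table(sub)
    assert np.array_equal(scored_a["olife_total"], scored_b["olife_total"])
    assert np.allclose(scored_a["schizotypy_composite"], scored_b["schizotypy_composite"])
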