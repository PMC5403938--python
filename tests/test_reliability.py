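import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphconn.reliability import (
    classify_reliability,
    icc_oneway,
    metric_reliability,
)
from morphconn.synthcohort import SynthConfig, generate_cohort
from oracles import icc_oneway_oracle


class TestICCOneway:
    def test_duplicated_sessions_icc_one(self):
        x = np.column_stack([np.arange(5.0), np.arange(5.0)])
        res = icc_oneway(x)
        assert res.icc == pytest.approx(1.0)
        assert res.p == 0.0

    def test_matches_explicit_anova_oracle(self):
        x = np.array([[1, 2], [2, 1], [3, 3], [5, 4]], dtype=float)
        res = icc_oneway(x)
        icc_expected, f_expected = icc_oneway_oracle(x)
        assert res.icc_raw == pytest.approx(icc_expected, abs=1e-12)
        assert res.fstat == pytest.approx(f_expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(20, 3))
        res = icc_oneway(x)
        icc_expected, f_expected = icc_oneway_oracle(x)
        assert res.icc_raw == pytest.approx(icc_expected, abs=1e-10)
        assert res.fstat == pytest.approx(f_expected, abs=1e-10)

    def test_variance_ratio_three_to_one_recovers_075(self):
        rng = np.random.default_rng(10)
        n = 500
        subj = rng.normal(0, np.sqrt(3), n)
        x = subj[:, None] + rng.normal(0, 1, (n, 2))
        assert icc_oneway(x).icc == pytest.approx(0.75, abs=0.05)

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            icc_oneway(np.ones((5, 2)))

    def test_missing_cell_rejected(self):
        x = np.ones((4, 2))
        x[0, 0] = np.nan
        x[1, 1] = 2.0
        with pytest.raises(ValueError, match="missing"):
            icc_oneway(x)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            icc_oneway(np.random.default_rng(0).normal(size=(2, 2)))

    def test_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        x = rng.normal(size=(15, 2)) + rng.normal(0, 2, 15)[:, None]
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 2),
                "session": np.tile([1, 2], 15),
                "value": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="subject", raters="session", ratings="value"
        )
        icc1 = ref.loc[ref["Type"].isin(["ICC1", "ICC(1,1)"]), "ICC"].iloc[0]
        assert icc_oneway(x).icc_raw == pytest.approx(icc1, abs=1e-6)

    @settings(max_examples=20, derandomize=True)
    @given(
        shift=st.floats(min_value=-100, max_value=100),
        scale=st.floats(min_value=0.01, max_value=100),
    )
    def test_affine_invariance(self, shift, scale):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(10, 2)) + rng.normal(0, 1, 10)[:, None]
        base = icc_oneway(x).icc
        moved = icc_oneway(x * scale + shift).icc
        assert moved == pytest.approx(base, abs=1e-7)


class TestClassify:
    @pytest.mark.parametrize(
        "icc,label",
        [
            (0.83, "excellent"),
            (0.76, "excellent"),
            (0.75, "good"),
            (0.6, "good"),
            (0.59, "below-good"),
            (0.0, "below-good"),
        ],
    )
    def test_thresholds(self, icc, label):
        assert classify_reliability(icc) == label

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_reliability(float("nan"))


class TestMetricReliability:
    # a coarse sparsity grid keeps the network stage cheap
    GRID = [0.20, 0.25, 0.30, 0.35, 0.40]

    def test_duplicated_sessions_give_icc_one(self, small_cohort):
        session1 = [m for m in small_cohort if m.session_id == 1]
        clones = [
            type(m)(subject_id=m.subject_id, session_id=2, data=m.data.copy())
            for m in session1
        ]
        table = metric_reliability(session1 + clones, "Cp", self.GRID)
        np.testing.assert_allclose(table["icc"], 1.0)

    def test_session_noise_tuned_to_4_to_1_gives_cp_icc_near_08(self):
        # network metrics respond to noise amplitude, so a 4:1 between:within
        # amplitude ratio targets a metric-level variance ratio of 4:1
        cohort, _ = generate_cohort(
            SynthConfig(n_subjects=40, between_sd=0.5, within_sd=0.125, seed=77)
        )
        table = metric_reliability(cohort, "Cp", self.GRID)
        assert table["icc"].mean() == pytest.approx(0.8, abs=0.07)

    def test_pure_noise_sessions_icc_near_zero(self):
        cohort, _ = generate_cohort(
            SynthConfig(n_subjects=100, between_sd=0.0, within_sd=0.5, seed=78)
        )
        table = metric_reliability(cohort, "Cp", [0.25, 0.35])
        assert abs(table["icc"].mean()) < 0.1

    def test_bc_reports_both_conventions(self, small_cohort):
        table = metric_reliability(small_cohort, "BC", [0.25])
        assert {"icc", "icc_of_mean"} <= set(table.columns)
        assert np.isfinite(table["icc"]).all()

    def test_unknown_metric_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="metric"):
            metric_reliability(small_cohort, "Q")
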