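"""Spearman screens, recurrence filtering, alteration regression, BH FDR."""

import numpy as np
import pandas as pd
import pytest

from cinscore.association import (
    bh_fdr, exclude_hypermutated, recurrence_filter, regress_alterations,
    spearman_screen,
)


@pytest.fixture()
def score_series(rng):
    idx = pd.Index([f"S{i}" for i in range(50)], name="sample_id")
    return pd.Series(rng.normal(size=50), index=idx)


def test_bh_fdr_reproduces_step_up():
    p = pd.Series([0.01, 0.02, 0.04, 0.8])
    np.testing.assert_allclose(bh_fdr(p), [0.04, 0.04, 0.04 * 4 / 3, 0.8])


def test_bh_fdr_keeps_nan():
    out = bh_fdr(pd.Series([0.01, np.nan, 0.5]))
    assert np.isnan(out[1]) and not np.isnan(out[0])


class TestSpearmanScreen:
    def test_identity_and_antitone_features(self, score_series):
        m = pd.DataFrame({"same": score_series, "neg": -score_series})
        rec = spearman_screen(score_series, m).set_index("feature")
        assert rec.loc["same", "estimate"] == pytest.approx(1.0)
        assert rec.loc["same", "p_value"] < 1e-6
        assert rec.loc["neg", "estimate"] == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self, score_series):
        x = np.abs(score_series) + 0.1
        m = pd.DataFrame({"raw": x, "logged": np.log(x), "cubed": x**3})
        rec = spearman_screen(score_series, m).set_index("feature")
        assert rec["estimate"].nunique() == 1

    def test_constant_feature_yields_missing_record(self, score_series):
        m = pd.DataFrame({"flat": np.ones(50)}, index=score_series.index)
        rec = spearman_screen(score_series, m)
        assert np.isnan(rec.loc[0, "estimate"])

    def test_pairwise_complete_missing_handling(self, score_series):
        x = score_series.copy()
        x.iloc[:10] = np.nan
        rec = spearman_screen(score_series, pd.DataFrame({"x": x}))
        assert rec.loc[0, "n"] == 40
        assert rec.loc[0, "estimate"] == pytest.approx(1.0)

    def test_per_cohort_requires_labels(self, score_series):
        with pytest.raises(ValueError):
            spearman_screen(score_series,
                            pd.DataFrame({"x": score_series}), per_cohort=True)

    def test_planted_rho_is_recovered_in_range(self, rng):
        """A rho=0.5 feature at n=200 estimates inside [0.3, 0.65] nearly
        always (sampling distribution of the rank correlation)."""
        hits = 0
        reps = 100
        for _ in range(reps):
            z = rng.normal(size=200)
            x = 0.5 * z + np.sqrt(1 - 0.25) * rng.normal(size=200)
            idx = pd.Index([f"S{i}" for i in range(200)], name="sample_id")
            rec = spearman_screen(pd.Series(z, index=idx),
                                  pd.DataFrame({"f": x}, index=idx))
            hits += 0.3 <= rec.loc[0, "estimate"] <= 0.65
        assert hits >= 95


class TestRecurrenceFilter:
    def _records(self, n_pass, n_total=22):
        rows = []
        for i in range(n_total):
            passing = i < n_pass
            rows.append(("F", f"C{i:02d}",
                         0.5 if passing else 0.1,
                         0.01 if passing else 0.5))
        return pd.DataFrame(rows, columns=["feature", "cohort", "estimate", "fdr"])

    def test_ten_of_22_cohorts_passes(self):
        calls = recurrence_filter(self._records(10))
        assert calls.loc[0, "passes_filter"]
        assert calls.loc[0, "n_cohorts_passing"] == 10

    def test_three_cohorts_fails_the_seven_rule(self):
        assert not recurrence_filter(self._records(3)).loc[0, "passes_filter"]

    def test_negative_correlations_never_pass(self):
        rec = self._records(10)
        rec["estimate"] = -rec["estimate"]
        assert recurrence_filter(rec).loc[0, "n_cohorts_passing"] == 0

    def test_null_features_controlled_by_fdr(self, rng):
        """All-null per-cohort screens let essentially nothing through."""
        idx = pd.Index([f"S{i}" for i in range(30 * 8)], name="sample_id")
        cohorts = pd.Series(np.repeat([f"C{i}" for i in range(8)], 30), index=idx)
        scores = pd.Series(rng.normal(size=len(idx)), index=idx)
        m = pd.DataFrame(rng.normal(size=(len(idx), 60)),
                         index=idx, columns=[f"N{i}" for i in range(60)])
        rec = spearman_screen(scores, m, cohorts=cohorts, per_cohort=True)
        calls = recurrence_filter(rec, rho_min=0.0, min_cohorts=7)
        assert calls["passes_filter"].sum() == 0


class TestRegressAlterations:
    def _data(self, rng, n=200, p=0.3, delta=0.0, cohorts=1):
        idx = pd.Index([f"S{i}" for i in range(n)], name="sample_id")
        alt = (rng.random(n) < p).astype(int)
        labels = pd.Series(np.repeat([f"C{i}" for i in range(cohorts)],
                                     n // cohorts), index=idx)
        y = pd.Series(rng.normal(size=n) + delta * alt, index=idx)
        return y, pd.DataFrame({"G": alt}, index=idx), labels

    def test_single_cohort_equals_group_mean_difference(self, rng):
        y, alt, labels = self._data(rng)
        rec = regress_alterations(y, alt, cohorts=labels)
        expected = y[alt["G"] == 1].mean() - y[alt["G"] == 0].mean()
        assert rec.loc[0, "estimate"] == pytest.approx(expected, abs=1e-12)

    def test_planted_effect_recovered(self, rng):
        y, alt, labels = self._data(rng, n=1000, delta=4.0, cohorts=4)
        rec = regress_alterations(y, alt, cohorts=labels)
        assert 3.0 < rec.loc[0, "estimate"] < 5.0
        assert rec.loc[0, "ci_low"] < 4.0 < rec.loc[0, "ci_high"]

    def test_small_carrier_group_not_tested(self, rng):
        y, alt, labels = self._data(rng, n=200)
        alt["G"] = 0
        alt.iloc[:19, 0] = 1  # 19 carriers: below the >=20 eligibility rule
        rec = regress_alterations(y, alt, cohorts=labels)
        assert rec.loc[0, "status"] == "too_few"
        assert np.isnan(rec.loc[0, "p_value"])

    def test_cohort_confounded_alteration_flagged(self, rng):
        y, alt, labels = self._data(rng, n=200, cohorts=2)
        alt["G"] = (labels == "C0").astype(int).to_numpy()
        rec = regress_alterations(y, alt, cohorts=labels)
        assert rec.loc[0, "status"] == "collinear"
        assert np.isnan(rec.loc[0, "fdr"])

    def test_non_binary_matrix_rejected(self, rng):
        y, alt, labels = self._data(rng)
        alt["G"] = alt["G"] * 2.5
        with pytest.raises(ValueError, match="binary"):
            regress_alterations(y, alt, cohorts=labels)

    def test_cohort_adjustment_removes_cohort_effect(self, rng):
        """A cohort-level score shift must not leak into the coefficient."""
        y, alt, labels = self._data(rng, n=400, cohorts=2)
        y = y + (labels == "C1") * 10.0
        rec = regress_alterations(y, alt, cohorts=labels)
        assert abs(rec.loc[0, "estimate"]) < 1.0


class TestExcludeHypermutated:
    def _df(self, flags):
        return pd.DataFrame({"min_flag": flags, "x": range(len(flags))})

    def test_all_flagged_gives_empty(self):
        assert exclude_hypermutated(self._df([True] * 4)).empty

    def test_no_flags_is_identity(self):
        df = self._df([False] * 4)
        pd.testing.assert_frame_equal(exclude_hypermutated(df), df)

    def test_fraction_retained(self, rng):
        flags = rng.random(200) < 0.1
        out = exclude_hypermutated(self._df(flags))
        assert len(out) == int((~flags).sum())

    def test_score_mode_requires_cutoff(self):
        df = pd.DataFrame({"MIN": [0.1, 5.0]})
        with pytest.raises(ValueError, match="cutoff"):
            exclude_hypermutated(df, min_flag=None, min_score="MIN")
        out = exclude_hypermutated(df, min_flag=None, min_score="MIN", cutoff=1.0)
        assert len(out) == 1

    def test_missing_annotation_errors(self):
        with pytest.raises(ValueError, match="no MIN"):
            exclude_hypermutated(pd.DataFrame({"x": [1]}), min_flag="absent")
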