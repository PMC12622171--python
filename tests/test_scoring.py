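"""Reference ranges, exceedance indicators, scores, classification."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mdmscreen as m
from mdmscreen.errors import ReferenceRangeError

from conftest import random_normalized


def _norm_from_values(values: pd.DataFrame, panel) -> m.NormalizedMatrix:
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    return m.NormalizedMatrix(values, mask, "zero", panel.content_hash())


@pytest.fixture()
def high_panel():
    return m.MetabolitePanel(
        [m.PanelEntry(f"m{i}", family="tryptophan") for i in range(5)]
    )


class TestReferenceRanges:
    def test_min_max_span(self, high_panel):
        panel = high_panel.subset(["m0"])
        values = pd.DataFrame(
            {"m0": [1.0, 2.0, 5.0]},
            index=pd.Index(["A", "B", "C"], name="participant_id"),
        )
        groups = pd.Series(["TD", "TD", "TD"], index=values.index)
        r = m.build_reference_ranges(_norm_from_values(values, panel), groups, panel)
        assert r.table.at["m0", "lower"] == 1.0
        assert r.table.at["m0", "upper"] == 5.0
        assert r.table.at["m0", "n_reference"] == 3

    def test_degenerate_constant_column(self, high_panel):
        panel = high_panel.subset(["m0"])
        values = pd.DataFrame(
            {"m0": [3.0, 3.0, 3.0]},
            index=pd.Index(["A", "B", "C"], name="participant_id"),
        )
        groups = pd.Series(["TD"] * 3, index=values.index)
        r = m.build_reference_ranges(_norm_from_values(values, panel), groups, panel)
        assert r.table.at["m0", "lower"] == r.table.at["m0", "upper"] == 3.0

    def test_all_missing_metabolite_is_named(self, high_panel):
        panel = high_panel.subset(["m0", "m1"])
        values = pd.DataFrame(
            {"m0": [1.0, 2.0], "m1": [np.nan, np.nan]},
            index=pd.Index(["A", "B"], name="participant_id"),
        )
        groups = pd.Series(["TD", "TD"], index=values.index)
        with pytest.raises(ReferenceRangeError, match="m1"):
            m.build_reference_ranges(_norm_from_values(values, panel), groups, panel)

    def test_json_round_trip(self, high_panel, tmp_path):
        rng = np.random.default_rng(0)
        norm = random_normalized(rng, 10, high_panel)
        groups = pd.Series(["TD"] * 10, index=norm.values.index)
        r = m.build_reference_ranges(norm, groups, high_panel)
        path = tmp_path / "ranges.json"
        r.to_json(path)
        back = m.ReferenceRangeSet.from_json(path)
        pd.testing.assert_frame_equal(
            back.table[["lower", "upper", "n_reference"]].astype(float),
            r.table[["lower", "upper", "n_reference"]].astype(float),
        )
        assert back.panel_hash == r.panel_hash


class TestIndicators:
    def test_strict_inequality_at_the_boundary(self, high_panel):
        panel = high_panel.subset(["m0"])
        values = pd.DataFrame(
            {"m0": [1.0, 5.0, 5.0, 5.05]},
            index=pd.Index(["T1", "T2", "E1", "E2"], name="participant_id"),
        )
        groups = pd.Series(["TD", "TD", "ASD", "ASD"], index=values.index)
        norm = _norm_from_values(values, panel)
        r = m.build_reference_ranges(norm, groups, panel)
        ind = m.exceedance_indicators(norm, r, panel)
        assert ind.at["E1", "m0"] == 0  # value exactly at the TD max
        assert ind.at["E2", "m0"] == 1  # one percent above

    def test_low_direction_scores_below_lower(self):
        panel = m.MetabolitePanel(
            [m.PanelEntry("dep", family="yeast_other", direction="low")]
        )
        values = pd.DataFrame(
            {"dep": [2.0, 4.0, 1.0, 3.0]},
            index=pd.Index(["T1", "T2", "E1", "E2"], name="participant_id"),
        )
        groups = pd.Series(["TD", "TD", "ASD", "ASD"], index=values.index)
        norm = _norm_from_values(values, panel)
        r = m.build_reference_ranges(norm, groups, panel)
        ind = m.exceedance_indicators(norm, r, panel)
        assert ind.at["E1", "dep"] == 1  # below the TD minimum
        assert ind.at["E2", "dep"] == 0  # inside the range

    def test_matches_double_loop_brute_force(self, high_panel):
        rng = np.random.default_rng(42)
        norm = random_normalized(rng, 20, high_panel)
        groups = pd.Series(
            ["TD"] * 10 + ["ASD"] * 10, index=norm.values.index
        )
        r = m.build_reference_ranges(norm, groups, high_panel)
        ind = m.exceedance_indicators(norm, r, high_panel)
        td = norm.values[groups == "TD"]
        for pid in norm.values.index:
            for met in norm.values.columns:
                expected = int(norm.values.at[pid, met] > td[met].max())
                assert ind.at[pid, met] == expected

    @given(data=st.data())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rank_invariance_under_increasing_transforms(self, data):
        """Strictly increasing transforms of a column leave high-direction
        indicators unchanged: scoring sees only ranks against the TD max."""
        panel = m.MetabolitePanel([m.PanelEntry("m0", family="tryptophan")])
        vals = data.draw(
            st.lists(
                st.floats(min_value=0.01, max_value=100.0),
                min_size=5, max_size=12, unique=True,
            )
        )
        values = pd.DataFrame(
            {"m0": vals},
            index=pd.Index([f"P{i}" for i in range(len(vals))],
                           name="participant_id"),
        )
        groups = pd.Series(
            ["TD"] * 3 + ["ASD"] * (len(vals) - 3), index=values.index
        )
        norm = _norm_from_values(values, panel)
        r = m.build_reference_ranges(norm, groups, panel)
        base = m.exceedance_indicators(norm, r, panel)
        for f in (np.log, np.sqrt, lambda v: 3 * v + 1):
            tnorm = _norm_from_values(f(values), panel)
            tr = m.build_reference_ranges(tnorm, groups, panel)
            tind = m.exceedance_indicators(tnorm, tr, panel)
            pd.testing.assert_frame_equal(tind, base)

    def test_monotonicity_raising_a_value_never_lowers_the_score(self, high_panel):
        rng = np.random.default_rng(1)
        norm = random_normalized(rng, 12, high_panel)
        groups = pd.Series(["TD"] * 6 + ["ASD"] * 6, index=norm.values.index)
        r = m.build_reference_ranges(norm, groups, high_panel)
        base_total = m.mdm_total_score(
            m.exceedance_indicators(norm, r, high_panel)
        )["total"]
        bumped = norm.values.copy()
        pid = bumped.index[8]  # an ASD participant
        bumped.at[pid, "m2"] = bumped["m2"].max() * 10
        bnorm = m.NormalizedMatrix(bumped, norm.lod_mask, "zero", norm.panel_hash)
        new_total = m.mdm_total_score(
            m.exceedance_indicators(bnorm, r, high_panel)
        )["total"]
        assert new_total[pid] >= base_total[pid]
        assert (new_total.drop(pid) == base_total.drop(pid)).all()


class TestScoresAndClassification:
    def test_total_is_row_sum_and_cutoff_rule(self, high_panel):
        ind = pd.DataFrame(
            [[0, 0, 0, 0, 0], [1, 1, 1, 1, 1], [0, 1, 0, 1, 0]],
            index=pd.Index(["A", "B", "C"], name="participant_id"),
            columns=high_panel.ids(),
        )
        s = m.mdm_total_score(ind, cutoff=1)
        assert list(s["total"]) == [0, 5, 2]
        assert list(s["classified_positive"]) == [False, True, True]
        s2 = m.mdm_total_score(ind, cutoff=3)
        assert list(s2["classified_positive"]) == [False, True, False]

    def test_score_conservation(self, calibrated_config):
        sc = m.generate_cohort(replace(calibrated_config, seed=2))
        norm = m.normalize_by_creatinine(sc.cohort, "zero")
        r = m.build_reference_ranges(norm, sc.cohort.groups, sc.cohort.panel)
        ind = m.exceedance_indicators(norm, r, sc.cohort.panel)
        s = m.mdm_total_score(ind)
        assert s["total"].sum() == ind.to_numpy().sum()

    def test_published_confusion_counts(self):
        rep = m.ClassificationReport.from_counts(tp=45, fp=0, tn=47, fn=5)
        assert rep.sensitivity == pytest.approx(0.90)
        assert rep.specificity == pytest.approx(1.00)

    def test_all_negative_scores(self):
        idx = pd.Index(["A", "B", "C", "D"], name="participant_id")
        scores = pd.DataFrame(
            {"total": [0, 0, 0, 0],
             "classified_positive": [False] * 4},
            index=idx,
        )
        groups = pd.Series(["ASD", "ASD", "TD", "TD"], index=idx)
        rep = m.classify_cohort(scores, groups)
        assert rep.sensitivity == 0.0
        assert rep.specificity == 1.0

    def test_undefined_ratios_are_none_not_zero(self):
        rep = m.ClassificationReport.from_counts(tp=0, fp=0, tn=3, fn=0)
        assert rep.sensitivity is None
        assert rep.ppv is None
        assert rep.to_dict(percent=True)["sensitivity"] is None

    def test_metrics_agree_with_confusion_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            idx = pd.Index([f"P{i}" for i in range(n)], name="participant_id")
            groups = pd.Series(rng.choice(["ASD", "TD"], size=n), index=idx)
            pred = rng.choice([True, False], size=n)
            scores = pd.DataFrame(
                {"total": pred.astype(int), "classified_positive": pred},
                index=idx,
            )
            rep = m.classify_cohort(scores, groups)
            truth = (groups == "ASD").to_numpy()
            tp = int((truth & pred).sum()); fn = int((truth & ~pred).sum())
            tn = int((~truth & ~pred).sum()); fp = int((~truth & pred).sum())
            assert (rep.tp, rep.fp, rep.tn, rep.fn) == (tp, fp, tn, fn)
            if tp + fn:
                assert rep.sensitivity == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert rep.specificity == pytest.approx(tn / (tn + fp))


class TestTautologyAndCalibration:
    def test_in_sample_td_scores_are_zero_and_specificity_perfect(
        self, calibrated_config
    ):
        """Ranges built from the full TD set span every TD value, so no TD
        participant can exceed them: specificity is exactly 100%."""
        for seed in (0, 1, 2):
            sc = m.generate_cohort(replace(calibrated_config, seed=seed))
            norm = m.normalize_by_creatinine(sc.cohort, "zero")
            r = m.build_reference_ranges(norm, sc.cohort.groups, sc.cohort.panel)
            ind = m.exceedance_indicators(norm, r, sc.cohort.panel)
            s = m.mdm_total_score(ind)
            td = sc.cohort.groups == "TD"
            assert (s.loc[td, "total"] == 0).all()
            rep = m.classify_cohort(s, sc.cohort.groups)
            assert rep.specificity == 1.0

    def test_fresh_sample_false_exceedance_rate(self):
        """A held-out unaffected draw beats the max of n references with
        probability 1/(n+1); checked by simulation within 3 SE."""
        panel = m.MetabolitePanel(
            [m.PanelEntry(f"x{i}", family="tryptophan") for i in range(40)]
        )
        n_ref = 12
        cfg = m.SimulationConfig(
            panel=panel, n_asd=1, n_td=n_ref, elevation_prob=0.0,
            creatinine_log_sd=0.0, seed=0,
        )
        hits = trials = 0
        for s in range(60):
            sc = m.generate_cohort(replace(cfg, seed=s))
            norm = m.normalize_by_creatinine(sc.cohort, "zero")
            r = m.build_reference_ranges(norm, sc.cohort.groups, sc.cohort.panel)
            ind = m.exceedance_indicators(norm, r, sc.cohort.panel)
            row = ind.loc[sc.cohort.groups == "ASD"]
            hits += int(row.to_numpy().sum())
            trials += row.size
        p = 1.0 / (n_ref + 1)
        se = np.sqrt(p * (1 - p) / trials)
        assert abs(hits / trials - p) < 3 * se
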