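"""Prevalence-based contaminant identification against negative controls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import meltcol as mc
from conftest import hypergeom_tail_oracle


def meta_frame(n_samples: int, n_controls: int) -> pd.DataFrame:
    rows = [
        {"compartment": "soil", "day": 1, "is_control": False}
        for _ in range(n_samples)
    ] + [
        {"compartment": "negative_control", "day": pd.NA, "is_control": True}
        for _ in range(n_controls)
    ]
    ids = [f"S{i}" for i in range(n_samples)] + [f"NC{i}" for i in range(n_controls)]
    return pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"))


class TestPresenceAbsence:
    @pytest.mark.parametrize(
        "threshold,expected",
        [
            (1, [[False, True], [True, False]]),
            (5, [[False, False], [True, False]]),
            (6, [[False, False], [False, False]]),
        ],
    )
    def test_elementwise_threshold(self, threshold, expected):
        table = mc.CountTable(np.array([[0, 1], [5, 0]]), ("a", "b"), ("s1", "s2"))
        np.testing.assert_array_equal(
            mc.presence_absence(table, threshold), np.array(expected)
        )

    def test_threshold_below_one_rejected(self):
        table = mc.CountTable(np.array([[1]]), ("a",), ("s1",))
        with pytest.raises(ValueError):
            mc.presence_absence(table, 0)


class TestPrevalenceScore:
    def test_control_only_feature_is_definitional_contaminant(self):
        presence = np.array([False] * 15 + [True] * 3)
        is_control = np.array([False] * 15 + [True] * 3)
        score, method = mc.prevalence_score(presence, is_control)
        assert score == 0.0 and method == "forced"
        assert score < 0.5  # flagged at the default threshold

    def test_absent_everywhere_is_undefined(self):
        presence = np.zeros(18, bool)
        is_control = np.array([False] * 15 + [True] * 3)
        score, method = mc.prevalence_score(presence, is_control)
        assert np.isnan(score) and method == "undefined"

    def test_equal_prevalence_scores_at_least_half(self):
        # present in every control and every sample
        presence = np.ones(18, bool)
        is_control = np.array([False] * 15 + [True] * 3)
        score, _ = mc.prevalence_score(presence, is_control)
        assert score >= 0.5
        # present in exactly half of each group
        presence = np.array([True] * 4 + [False] * 4 + [True, False])
        is_control = np.array([False] * 8 + [True, True])
        score, _ = mc.prevalence_score(presence, is_control)
        assert score >= 0.5

    def test_no_controls_is_configuration_error(self):
        with pytest.raises(ValueError, match="control"):
            mc.prevalence_score(np.array([True, False]), np.array([False, False]))

    def test_exact_branch_matches_hypergeometric_enumeration(self):
        """All 2x2 tables with group sizes <= 12: exact branch vs brute force."""
        checked = 0
        for n_controls in range(1, 13):
            for n_samples in range(1, 13 - n_controls + 1):
                for pres_ctrl in range(n_controls + 1):
                    for pres_samp in range(1, n_samples + 1):
                        presence = np.array(
                            [True] * pres_samp
                            + [False] * (n_samples - pres_samp)
                            + [True] * pres_ctrl
                            + [False] * (n_controls - pres_ctrl)
                        )
                        is_control = np.array(
                            [False] * n_samples + [True] * n_controls
                        )
                        score, method = mc.prevalence_score(presence, is_control)
                        if method != "fisher":
                            continue
                        expected = hypergeom_tail_oracle(
                            pres_ctrl,
                            pres_samp,
                            n_controls - pres_ctrl,
                            n_samples - pres_samp,
                        )
                        assert score == pytest.approx(expected, abs=1e-10)
                        checked += 1
        assert checked > 500  # the exact branch was actually exercised


class TestClassifyContaminants:
    def build_planted_table(self, rng, n_contaminants=10, n_real=40,
                            n_samples=20, n_controls=6):
        """Contaminants present in every control and ~5% of samples."""
        counts = np.zeros((n_contaminants + n_real, n_samples + n_controls), int)
        for i in range(n_contaminants):
            counts[i, n_samples:] = rng.integers(5, 50, n_controls)
            hits = rng.choice(n_samples, size=1, replace=False)
            counts[i, hits] = rng.integers(1, 5)
        for i in range(n_contaminants, n_contaminants + n_real):
            hits = rng.choice(n_samples, size=rng.integers(10, n_samples), replace=False)
            counts[i, hits] = rng.integers(1, 100, len(hits))
        fids = tuple(
            [f"contam{i}" for i in range(n_contaminants)]
            + [f"real{i}" for i in range(n_real)]
        )
        sids = tuple([f"S{i}" for i in range(n_samples)] + [f"NC{i}" for i in range(n_controls)])
        return mc.CountTable(counts, fids, sids), meta_frame(n_samples, n_controls)

    def test_planted_control_enriched_features_all_flagged(self, rng):
        table, meta = self.build_planted_table(rng)
        report = mc.classify_contaminants(table, meta, threshold=0.5)
        flagged = set(report.contaminant_ids)
        assert {f"contam{i}" for i in range(10)} <= flagged

    def test_threshold_to_zero_limit_flags_nothing(self, rng):
        table, meta = self.build_planted_table(rng)
        report = mc.classify_contaminants(table, meta, threshold=1e-12)
        assert report.contaminant_ids == ()

    def test_report_carries_prevalences_and_globals(self, rng):
        table, meta = self.build_planted_table(rng)
        report = mc.classify_contaminants(table, meta)
        assert report.n_controls == 6 and report.n_samples == 20
        pf = report.per_feature
        assert ((pf["prev_samples"] >= 0) & (pf["prev_samples"] <= 1)).all()
        assert ((pf["prev_controls"] >= 0) & (pf["prev_controls"] <= 1)).all()
        assert pf["is_contaminant"].notna().all()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_flagged_set_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 3, size=(25, 14))
        table = mc.CountTable(
            counts,
            tuple(f"f{i}" for i in range(25)),
            tuple([f"S{i}" for i in range(10)] + [f"NC{i}" for i in range(4)]),
        )
        meta = meta_frame(10, 4)
        flagged = [
            set(mc.classify_contaminants(table, meta, threshold=t).contaminant_ids)
            for t in (0.1, 0.3, 0.5, 0.7)
        ]
        for smaller, larger in zip(flagged, flagged[1:]):
            assert smaller <= larger

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_prevalences_invariant_to_sample_order_and_duplication(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 4, size=(12, 12))
        sids = [f"S{i}" for i in range(9)] + [f"NC{i}" for i in range(3)]
        table = mc.CountTable(counts, tuple(f"f{i}" for i in range(12)), tuple(sids))
        meta = meta_frame(9, 3)
        base = mc.classify_contaminants(table, meta).per_feature

        perm = rng.permutation(12)
        shuffled = mc.CountTable(
            counts[:, perm], table.feature_ids, tuple(sids[j] for j in perm)
        )
        shuf = mc.classify_contaminants(shuffled, meta).per_feature
        pd.testing.assert_series_equal(base["prev_samples"], shuf["prev_samples"])
        pd.testing.assert_series_equal(base["prev_controls"], shuf["prev_controls"])

        doubled = mc.CountTable(
            np.hstack([counts, counts]),
            table.feature_ids,
            tuple(sids + [s + "_dup" for s in sids]),
        )
        meta2 = pd.concat([meta, meta.set_axis([s + "_dup" for s in meta.index])])
        doub = mc.classify_contaminants(doubled, meta2).per_feature
        np.testing.assert_allclose(base["prev_samples"], doub["prev_samples"])
        np.testing.assert_allclose(base["prev_controls"], doub["prev_controls"])


class TestRemoveContaminants:
    def _report(self, table, flagged):
        pf = pd.DataFrame(
            {
                "prev_samples": 0.0,
                "prev_controls": 0.0,
                "score": 0.0,
                "method": "fisher",
                "is_contaminant": [f in flagged for f in table.feature_ids],
            },
            index=pd.Index(table.feature_ids, name="feature_id"),
        )
        return mc.ContaminantReport(pf, threshold=0.5, n_controls=3, n_samples=15)

    def test_no_flags_is_identity(self, rng):
        from conftest import make_table

        table = make_table(rng)
        out = mc.remove_contaminants(table, self._report(table, set()))
        assert out.feature_ids == table.feature_ids
        np.testing.assert_array_equal(out.counts, table.counts)

    def test_all_flagged_gives_empty_table_with_warning(self, rng):
        from conftest import make_table

        table = make_table(rng)
        with pytest.warns(UserWarning, match="all features"):
            out = mc.remove_contaminants(table, self._report(table, set(table.feature_ids)))
        assert out.n_features == 0

    def test_survivor_counts_unchanged(self, rng):
        rng2 = np.random.default_rng(7)
        counts = rng2.integers(0, 9, size=(100, 6))
        table = mc.CountTable(
            counts, tuple(f"f{i}" for i in range(100)), tuple(f"s{j}" for j in range(6))
        )
        flagged = {f"f{i}" for i in (3, 12, 40, 41, 66, 80, 99)}
        out = mc.remove_contaminants(table, self._report(table, flagged))
        assert out.n_features == 93
        for fid in out.feature_ids:
            i_old = table.feature_ids.index(fid)
            i_new = out.feature_ids.index(fid)
            np.testing.assert_array_equal(out.counts[i_new], table.counts[i_old])
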