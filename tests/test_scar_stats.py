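"""Scar bins, differential strain, ROC/AUC, ICC and group comparisons."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from densestrain import scar_stats as ss


class TestTransmuralityBin:
    @pytest.mark.parametrize("fraction,expected", [
        (0.006, ("none", False, False)),
        (0.01, ("none", False, False)),    # scar requires EXCEEDING 1%
        (0.30, ("26-50%", True, False)),
        (0.50, ("26-50%", True, False)),   # endpoint requires EXCEEDING 50%
        (0.60, ("51-75%", True, True)),
        (0.90, (">75%", True, True)),
    ])
    def test_bins_and_flags(self, fraction, expected):
        assert ss.transmurality_bin(fraction) == expected

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            ss.transmurality_bin(1.2)

    @given(st.floats(0.0, 1.0))
    def test_flags_consistent_with_bins(self, f):
        b, scar, endpoint = ss.transmurality_bin(f)
        assert scar == (b != "none")
        assert endpoint == (b in ("51-75%", ">75%"))


class TestDifferentialStrain:
    def test_measured_at_reference_scores_zero(self):
        assert ss.differential_strain(-19.0, -19.0) == 0.0

    def test_stated_sign_convention(self):
        # reference -19, measured -9 (hypokinetic): differential -10
        assert ss.differential_strain(-9.0, -19.0) == -10.0
        # supra-normal contraction: differential +2
        assert ss.differential_strain(-21.0, -19.0) == 2.0

    def test_alternate_convention_flips_sign(self):
        assert ss.differential_strain(-9.0, -19.0,
                                      convention="measured-minus-reference") == 10.0

    def test_missing_reference_propagates(self):
        assert np.isnan(ss.differential_strain(-9.0, np.nan))


def _auc_bruteforce(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        r = ss.roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_enumerated_four_pair_example(self):
        # positives {-8, -16}, negatives {-17, -12}: 3 of 4 pairs won
        r = ss.roc([-8, -16, -17, -12], [1, 1, 0, 0])
        assert r.auc == pytest.approx(0.75)

    def test_cutoff_at_80pct_specificity_threshold_sweep(self):
        neg = [-20, -19, -18, -17, -12]
        pos = [-9, -10, -11, -16, -13]
        r = ss.roc(pos + neg, [1] * 5 + [0] * 5, specificity=0.80)
        assert r.cutoff == -16.0
        assert r.specificity == pytest.approx(0.80)
        assert r.sensitivity == 1.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            ss.roc([1.0, 2.0], [1, 1])

    @given(st.lists(st.integers(-20, 20), min_size=2, max_size=25),
           st.integers(1, 24))
    def test_auc_equals_bruteforce_enumeration(self, values, n_pos):
        n_pos = min(n_pos, len(values) - 1)
        labels = [1] * n_pos + [0] * (len(values) - n_pos)
        r = ss.roc(values, labels)
        assert r.auc == pytest.approx(_auc_bruteforce(values, labels), abs=1e-12)

    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=20, unique=True))
    def test_orientation_duality(self, values):
        labels = [i % 2 for i in range(len(values))]
        if sum(labels) in (0, len(values)):
            return
        a = ss.roc(values, labels).auc
        b = ss.roc([-v for v in values], labels).auc
        assert a + b == pytest.approx(1.0)

    def test_strain_roc_orientation_and_natural_cutoff(self):
        # circumferential: scar is LESS negative -> raw value oriented as-is
        circ = ss.strain_roc([-8, -9, -17, -18, -16, -19], [1, 1, 0, 0, 0, 0],
                             "circumferential")
        assert circ.auc == 1.0
        assert circ.rule.startswith("strain >=")
        # radial: scar is SMALLER -> negated
        rad = ss.strain_roc([4, 5, 15, 14, 16, 13], [1, 1, 0, 0, 0, 0], "radial_sa")
        assert rad.auc == 1.0
        assert rad.rule.startswith("strain <=")

    def test_differential_roc_equals_raw_under_constant_reference(self):
        rng = np.random.default_rng(0)
        strain = np.concatenate([rng.normal(-9, 2, 40), rng.normal(-17, 2, 60)])
        labels = np.r_[np.ones(40, bool), np.zeros(60, bool)]
        diff = ss.differential_strain(strain, -17.0)  # constant reference
        raw = ss.strain_roc(strain, labels, "circumferential")
        dif = ss.strain_roc(diff, labels, "circumferential", differential=True)
        assert raw.auc == pytest.approx(dif.auc, abs=1e-12)
        # and the cut-offs map onto each other through the transform
        assert dif.cutoff_natural == pytest.approx(-17.0 - raw.cutoff_natural, abs=1e-9)


class TestIcc:
    def test_identical_columns_with_spread_give_one(self):
        r = ss.icc(np.array([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0]]))
        assert r.icc == pytest.approx(1.0)
        assert r.ci95 == (1.0, 1.0)

    def test_hand_computed_mean_squares_oracle(self):
        # X = [[10,14],[12,10],[14,12]]: MSR=2, MSC=0, MSE=6 ->
        # ICC(2,1) = (2-6)/(2 + 1*6 + 2*(0-6)/3) = -1
        r = ss.icc(np.array([[10.0, 14.0], [12.0, 10.0], [14.0, 12.0]]))
        assert r.icc == pytest.approx(-1.0, abs=1e-12)

    def test_matches_pingouin_reference_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        subj = rng.normal(0, 3, 12)
        X = np.column_stack([subj + rng.normal(0, 1, 12),
                             subj + 0.5 + rng.normal(0, 1, 12)])
        ours = ss.icc(X)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(12), 2),
            "raters": np.tile(["a", "b"], 12),
            "ratings": X.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="ratings")
        # two-way random, absolute agreement, single measures
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        row = ref[mask].iloc[0]
        assert ours.icc == pytest.approx(row["ICC"], abs=1e-10)
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        np.testing.assert_allclose(ours.ci95, row[ci_col], atol=0.006)

    def test_constant_table_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            ss.icc(np.full((4, 2), 3.0))

    def test_rows_with_missing_cells_dropped_and_counted(self):
        X = np.array([[1.0, 1.1], [2.0, np.nan], [3.0, 2.9], [4.0, 4.2]])
        r = ss.icc(X)
        assert r.n_dropped == 1 and r.n_subjects == 3

    def test_noise_monotonicity_toward_one(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 5, 40)
        iccs = []
        for sigma in (4.0, 1.0, 0.1):
            X = np.column_stack([base, base + rng.normal(0, sigma, 40)])
            iccs.append(ss.icc(X).icc)
        assert iccs[0] < iccs[1] < iccs[2]
        assert iccs[2] > 0.99


class TestGroupCompare:
    def test_identical_groups_all_adjusted_p_one(self):
        g = {"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [1.0, 2, 3, 4]}
        anova, pw = ss.group_compare(g)
        assert (pw["p_bonferroni"] == 1.0).all()

    def test_clearly_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        g = {"control": rng.normal(-17, 1, 20), "scar": rng.normal(-9, 1, 20)}
        anova, pw = ss.group_compare(g)
        assert anova["p"] < 1e-3
        assert (pw["p_bonferroni"] < 1e-3).all()

    def test_bonferroni_multiplies_by_comparison_count(self):
        rng = np.random.default_rng(7)
        g = {k: rng.normal(i * 0.8, 1, 12) for i, k in enumerate("abc")}
        _, pw = ss.group_compare(g)
        assert len(pw) == 3
        for _, row in pw.iterrows():
            assert row.p_bonferroni == pytest.approx(min(1.0, row.p_raw * 3))

    def test_undersized_groups_excluded(self):
        g = {"a": [1.0, 2, 3], "b": [4.0, 5, 6], "tiny": [1.0]}
        anova, _ = ss.group_compare(g)
        assert anova["excluded"] == ["tiny"]


class TestReference:
    def _table(self, subjects):
        rows = []
        for sid, val in subjects.items():
            for seg in (1, 2):
                rows.append({"subject_id": sid, "segment_id": seg,
                             "layer": "transmural", "direction": "circumferential",
                             "strain_pct": val + seg, "missing": False})
        return pd.DataFrame(rows)

    def test_single_control_mean_no_sd(self):
        ref = ss.build_reference(self._table({"c1": -18.0}), ["c1"])
        assert (ref["reference_mean"] == [-17.0, -16.0]).all()
        assert ref["reference_sd"].isna().all()

    def test_duplicated_control_gives_zero_sd(self):
        ref = ss.build_reference(self._table({"c1": -18.0, "c2": -18.0}),
                                 ["c1", "c2"])
        assert (ref["reference_sd"] == 0.0).all()

    def test_known_values_cross_checked_by_direct_summation(self):
        vals = {"c1": -18.0, "c2": -16.0, "c3": -20.0}
        ref = ss.build_reference(self._table(vals), list(vals))
        seg1 = ref[ref.segment_id == 1].iloc[0]
        data = np.array([v + 1 for v in vals.values()])
        assert seg1.reference_mean == pytest.approx(data.mean())
        assert seg1.reference_sd == pytest.approx(data.std(ddof=1))

    def test_no_controls_errors(self):
        with pytest.raises(ValueError):
            ss.build_reference(self._table({"c1": -18.0}), [])

    def test_scar_table_flags(self):
        fr = np.zeros(16)
        fr[2] = 0.6
        fr[5] = 0.2
        df = ss.scar_table({"s1": fr})
        assert df.endpoint.sum() == 1
        assert df.scar.sum() == 2
        assert df.loc[df.segment_id == 3, "transmurality_bin"].iloc[0] == "51-75%"
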