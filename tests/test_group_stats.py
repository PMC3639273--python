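"""Split-plot ANOVA, interhemispheric strength, Tukey tests, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from gtna.connectivity import NetworkGraph
from gtna.group_stats import (
    interhemispheric_strength,
    kinematics_correlations,
    mixed_anova,
    split_plot_anova,
    tukey_posthoc,
)
from gtna.node_atlas import interhemispheric_pairs

from test_node_atlas import make_table

# balanced 2x2 toy with integer values and clean sums of squares:
# SS_AGE=25, SS_subj=18, SS_PHASE=9, SS_inter=1, SS_error=2
FIXTURE_CELLS = {
    ("old", "AP"): [10, 12, 9, 11],
    ("old", "IP"): [8, 9, 7, 10],
    ("young", "AP"): [7, 8, 6, 9],
    ("young", "IP"): [6, 8, 5, 7],
}


def fixture_records():
    rows = []
    for (g, c), values in FIXTURE_CELLS.items():
        for s, v in enumerate(values):
            rows.append(
                {"subject": f"{g}{s}", "group": g, "condition": c, "value": v}
            )
    return pd.DataFrame(rows)


def records_from_array(y):
    rows = []
    for gi, g in enumerate(("old", "young")):
        for s in range(y.shape[1]):
            for ci, c in enumerate(("AP", "IP")):
                rows.append(
                    {
                        "subject": f"{g}{s}",
                        "group": g,
                        "condition": c,
                        "value": y[gi, s, ci],
                    }
                )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_all_identical_values_give_zero_f(self):
        y = np.full((2, 4, 2), 3.5)
        res = split_plot_anova(y)
        for effect in ("AGE", "PHASE", "AGE:PHASE"):
            assert res[effect].F == 0.0
            assert res[effect].p == 1.0

    def test_noiseless_group_effect_flags_infinite_f(self):
        y = np.zeros((2, 4, 2))
        y[0] += 2.0  # pure additive AGE shift, zero error variance
        res = split_plot_anova(y)
        assert res["AGE"].F == np.inf and res["AGE"].p == 0.0
        assert res["PHASE"].F == 0.0
        assert res["AGE:PHASE"].F == 0.0

    def test_hand_computed_fixture(self):
        """F values match the manual sums-of-squares solution.

        SS: AGE 25 (MS_subj 18/6=3 -> F 25/3), PHASE 9 (MS_err 2/6 ->
        F 27), interaction 1 -> F 3.  Cross-checked against pingouin and
        R aov at 6 decimals.
        """
        res = mixed_anova(fixture_records())
        assert res["AGE"].F == pytest.approx(25 / 3, abs=1e-10)
        assert (res["AGE"].df_num, res["AGE"].df_den) == (1, 6)
        assert res["AGE"].p == pytest.approx(0.027811, abs=1e-5)
        assert res["PHASE"].F == pytest.approx(27.0, abs=1e-10)
        assert res["PHASE"].p == pytest.approx(0.002022, abs=1e-5)
        assert res["AGE:PHASE"].F == pytest.approx(3.0, abs=1e-10)
        assert res["AGE:PHASE"].p == pytest.approx(0.133975, abs=1e-5)

    def test_matches_pingouin_on_random_data(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(size=(2, 8, 2)) + np.array([[0.5], [0.0]])[:, :, None]
        records = records_from_array(y)
        mine = mixed_anova(records)
        theirs = pg.mixed_anova(
            data=records,
            dv="value",
            within="condition",
            between="group",
            subject="subject",
        ).set_index("Source")
        assert mine["AGE"].F == pytest.approx(theirs.loc["group", "F"])
        assert mine["PHASE"].F == pytest.approx(theirs.loc["condition", "F"])
        assert mine["AGE:PHASE"].F == pytest.approx(
            theirs.loc["Interaction", "F"]
        )

    def test_age_f_equals_squared_t_on_subject_means(self, rng):
        from scipy import stats

        y = rng.normal(size=(2, 10, 2))
        res = split_plot_anova(y)
        subj_means = y.mean(axis=2)
        t, _ = stats.ttest_ind(subj_means[0], subj_means[1])
        assert res["AGE"].F == pytest.approx(t**2, rel=1e-10)

    @given(
        hnp.arrays(
            np.float64,
            (2, 5, 2),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
        )
    )
    def test_sum_of_squares_decomposition(self, y):
        res = split_plot_anova(y)
        ss = res.ss_components
        assert ss["total"] == pytest.approx(
            ss["between_subjects"]
            + ss["PHASE"]
            + ss["AGE:PHASE"]
            + ss["error_within"],
            abs=1e-8,
        )
        assert ss["between_subjects"] == pytest.approx(
            ss["AGE"] + ss["subjects_within_groups"], abs=1e-8
        )

    def test_missing_cell_names_subject(self):
        records = fixture_records().iloc[:-1]
        with pytest.raises(ValueError, match="youngs?3|missing cells"):
            mixed_anova(records)

    def test_unbalanced_groups_rejected(self):
        records = fixture_records()
        records = records[records["subject"] != "old3"]
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova(records)

    def test_type_i_error_calibration(self, rng):
        """Null type-I error of each effect is near the nominal 0.05."""
        n_reps = 2000
        hits = {"AGE": 0, "PHASE": 0, "AGE:PHASE": 0}
        for _ in range(n_reps):
            res = split_plot_anova(rng.normal(size=(2, 16, 2)))
            for effect in hits:
                hits[effect] += res[effect].p < 0.05
        for effect, count in hits.items():
            assert count / n_reps == pytest.approx(0.05, abs=0.015), effect


class TestInterhemisphericStrength:
    @staticmethod
    def graph(n, edges, weights):
        binary = np.zeros((n, n), dtype=int)
        w = np.zeros((n, n))
        for (i, j), wij in zip(edges, weights):
            binary[i, j] = binary[j, i] = 1
            w[i, j] = w[j, i] = wij
        return NetworkGraph(alpha=0.001, binary=binary, weights=w)

    def test_single_crossing_edge(self):
        table = make_table("LRLL")
        g = self.graph(4, [(0, 1)], [0.62])
        assert interhemispheric_strength(g, table) == pytest.approx(0.62)

    def test_only_within_hemisphere_edges_is_missing(self):
        table = make_table("LLRR")
        g = self.graph(4, [(0, 1), (2, 3)], [0.5, 0.4])
        assert np.isnan(interhemispheric_strength(g, table))

    def test_matches_set_intersection_oracle(self, rng):
        hemis = "".join(rng.choice(["L", "R"], size=10))
        table = make_table(hemis)
        A = (rng.random((10, 10)) < 0.4).astype(int)
        A = np.triu(A, 1) + np.triu(A, 1).T
        w = np.triu(rng.normal(size=(10, 10)) * A, 1)
        w = w + w.T
        g = NetworkGraph(alpha=0.001, binary=A, weights=w)
        crossing = [
            w[i, j]
            for i, j in interhemispheric_pairs(table)
            if A[i, j]
        ]
        got = interhemispheric_strength(g, table)
        if crossing:
            assert got == pytest.approx(np.mean(crossing))
        else:
            assert np.isnan(got)


class TestTukeyPosthoc:
    def test_identical_cell_means_give_p_one(self):
        y = np.zeros((2, 4, 2))
        y[:, :, :] = np.arange(4)[None, :, None]  # subject variance only
        out = tukey_posthoc(records_from_array(y))
        assert np.allclose(out["p_adj"], 1.0, atol=1e-9)

    def test_matches_r_emmeans_fixture(self):
        """Adjusted p values frozen from R aov + emmeans (tukey adjust)."""
        out = tukey_posthoc(fixture_records()).set_index(["cell_a", "cell_b"])
        expect = {
            ("old/AP", "old/IP"): 0.0108,
            ("old/AP", "young/AP"): 0.0491,
            ("old/AP", "young/IP"): 0.0121,
            ("old/IP", "young/AP"): 0.7028,
            ("old/IP", "young/IP"): 0.2117,
            ("young/AP", "young/IP"): 0.1670,
        }
        for cells, p in expect.items():
            assert out.loc[cells, "p_adj"] == pytest.approx(p, abs=2e-3)

    def test_extreme_cell_has_smallest_p(self, rng):
        y = rng.normal(size=(2, 6, 2)) * 0.1
        y[0, :, 0] += 5.0  # old/AP far from every other cell
        out = tukey_posthoc(records_from_array(y))
        involving = out[
            (out["cell_a"] == "old/AP") | (out["cell_b"] == "old/AP")
        ]["p_adj"]
        others = out[
            (out["cell_a"] != "old/AP") & (out["cell_b"] != "old/AP")
        ]["p_adj"]
        assert involving.max() < others.min()

    def test_null_familywise_error_controlled(self, rng):
        """Under the null, min adjusted p < 0.05 happens at roughly FWER 5%."""
        n_reps = 1000
        hits = 0
        for _ in range(n_reps):
            out = tukey_posthoc(records_from_array(rng.normal(size=(2, 8, 2))))
            hits += out["p_adj"].min() < 0.05
        assert 0.015 <= hits / n_reps <= 0.09


class TestKinematicsCorrelations:
    @staticmethod
    def frames(values, kin_errors, group="old", condition="AP", measure="degree"):
        subjects = [f"s{i}" for i in range(len(values))]
        metrics = pd.DataFrame(
            {
                "subject": subjects,
                "group": group,
                "condition": condition,
                "measure": measure,
                "value": values,
            }
        )
        kinematics = pd.DataFrame(
            {
                "subject": subjects,
                "group": group,
                "condition": condition,
                "phase_error": kin_errors,
                "phase_sd": kin_errors,
            }
        )
        return metrics, kinematics

    def test_perfect_correlation(self):
        x = np.arange(10.0)
        out = kinematics_correlations(*self.frames(x, x))
        assert np.allclose(out["R"], 1.0)
        assert (out["p"] < 1e-8).all()
        assert out["significant"].all()

    def test_zero_variance_reported_missing(self):
        out = kinematics_correlations(*self.frames(np.ones(8), np.arange(8.0)))
        assert out["R"].isna().all()
        assert (out["note"] == "zero variance").all()
        assert not out["significant"].any()

    def test_null_flag_rate_near_alpha(self, rng):
        """Independent pairs at n=16 are flagged at the nominal 1% rate."""
        n_reps = 5000
        subjects = [f"s{i}" for i in range(16)]
        metrics = pd.DataFrame(
            {
                "subject": np.tile(subjects, n_reps),
                "group": "old",
                "condition": "AP",
                "measure": np.repeat([f"m{r}" for r in range(n_reps)], 16),
                "value": rng.normal(size=16 * n_reps),
            }
        )
        kinematics = pd.DataFrame(
            {
                "subject": subjects,
                "group": "old",
                "condition": "AP",
                "phase_error": rng.normal(size=16),
                "phase_sd": rng.normal(size=16),
            }
        )
        out = kinematics_correlations(metrics, kinematics)
        rate = out["significant"].mean()
        assert rate == pytest.approx(0.01, abs=0.005)

    def test_coupled_summaries_yield_positive_correlations(self, rng):
        """With positive coupling the estimated R is positive in >=95% of cohorts."""
        from gtna.synthetic_data import default_cohort, simulate_kinematics

        hits = 0
        n_cohorts = 200
        for rep in range(n_cohorts):
            cohort = default_cohort(n_nodes=6, n_per_group=16, master_seed=rep)
            summary = rng.normal(0.0, 10.0, size=16)
            errors = [
                simulate_kinematics(
                    cohort, "old", i, "AP",
                    connectivity_summary=summary[i], coupling=0.8,
                )[0]
                for i in range(16)
            ]
            hits += np.corrcoef(summary, errors)[0, 1] > 0
        assert hits / n_cohorts >= 0.95
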