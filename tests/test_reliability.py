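"""PE regressors, ICC, split-half reliability, event-file export."""

import numpy as np
import pandas as pd
import pytest

from revlearn.models import ModelSpec, Params, simulate_subject
from revlearn.reliability import (
    build_regressors,
    icc,
    spearman_brown,
    split_half,
    write_events,
    write_modulator_files,
)
from revlearn.stats import session_metrics
from revlearn.task import TaskConfig

from conftest import make_session

DU2RA = ModelSpec.from_code("DU-2rho-1alpha")


def pe_trace_oracle(choices, outcomes, alpha):
    """Independent straight-line SU/DU traces with +/-1 outcome coding."""
    q_su, q_du = [0.0, 0.0], [0.0, 0.0]
    su, du = [], []
    for c, o in zip(choices, outcomes):
        su.append(o - q_su[c])
        du.append(o - q_du[c])
        q_su[c] += alpha * (o - q_su[c])
        du_cf = -o - q_du[1 - c]
        q_du[c] += alpha * (o - q_du[c])
        q_du[1 - c] += alpha * du_cf
    return np.array(su), np.array(du)


class TestBuildRegressors:
    def test_first_feedback_pe_is_outcome_sign(self, mid_params):
        s = make_session([0], [1])
        assert build_regressors(s, mid_params)["su_pe"].iloc[0] == pytest.approx(1.0)
        s = make_session([0], [-1])
        t = build_regressors(s, mid_params)
        assert t["su_pe"].iloc[0] == pytest.approx(-1.0)
        assert t["du_unique_pe"].iloc[0] == pytest.approx(0.0)

    def test_full_learning_rate_second_win_pe_zero(self, du_spec):
        p = Params.from_natural(du_spec, alpha=1 - 1e-12, rho_win=2.49,
                                rho_loss=-0.715)
        s = make_session([0, 0], [1, 1])
        t = build_regressors(s, p)
        assert t["su_pe"].iloc[1] == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_trace_oracle(self, mid_params, task_config):
        for seed in range(4):
            s = simulate_subject(mid_params, config=task_config, seed=seed)
            t = build_regressors(s, mid_params)
            su, du = pe_trace_oracle(s.choices, s.outcomes,
                                     mid_params.alpha_win)
            np.testing.assert_allclose(t["su_pe"], su, atol=1e-12)
            np.testing.assert_allclose(t["du_unique_pe"], du - su, atol=1e-12)

    def test_du_unique_appears_only_after_a_switch(self, mid_params):
        # while the agent never switches, the chosen option's SU and DU
        # traces coincide (the counterfactual updates accrue only on the
        # unchosen value); the first switch exposes that history
        choices = [0, 0, 0, 0, 1, 1, 0]
        feedback = [1, 1, -1, 1, -1, 1, 1]
        s = make_session(choices, feedback)
        t = build_regressors(s, mid_params)
        su, du = pe_trace_oracle(choices, feedback, mid_params.alpha_win)
        np.testing.assert_allclose(t["du_unique_pe"], du - su, atol=1e-12)
        assert np.allclose(t["du_unique_pe"].iloc[:4], 0.0)
        assert abs(t["du_unique_pe"].iloc[4]) > 0.1

    def test_bounds_and_below_chance_consistency(self, task_config):
        rng = np.random.default_rng(0)
        for seed in range(5):
            p = Params.from_natural(
                DU2RA, alpha=rng.uniform(0.05, 0.95),
                rho_win=rng.uniform(0.5, 4.0), rho_loss=-rng.uniform(0.1, 2.0),
            )
            s = simulate_subject(p, config=task_config, seed=seed)
            t = build_regressors(s, p)
            assert t["su_pe"].abs().max() <= 2.0 + 1e-12
            assert t["du_unique_pe"].abs().max() <= 2.0 + 1e-12
            np.testing.assert_array_equal(
                t["below_chance"].astype(bool), t["choice_prob"] < 0.5
            )

    def test_counterfactual_reading_changes_du_column_only(self, mid_params):
        s = make_session([0, 1, 0], [1, -1, 1])
        a = build_regressors(s, mid_params, du_pe="chosen")
        b = build_regressors(s, mid_params, du_pe="counterfactual")
        np.testing.assert_allclose(a["su_pe"], b["su_pe"])
        assert not np.allclose(a["du_unique_pe"], b["du_unique_pe"])
        with pytest.raises(ValueError):
            build_regressors(s, mid_params, du_pe="bogus")

    def test_missing_trials_produce_null_rows(self, mid_params):
        s = make_session([0, None, 1], [1, None, -1])
        t = build_regressors(s, mid_params, onset_spacing=10.0)
        assert np.isnan(t.loc[1, "su_pe"]) and np.isnan(t.loc[1, "choice_prob"])
        assert t["onset"].tolist() == [0.0, 10.0, 20.0]


class TestIcc:
    def test_identical_columns_give_one(self):
        x = np.random.default_rng(0).normal(size=(50, 1))
        m = np.hstack([x, x, x])
        assert icc(m) == pytest.approx(1.0)

    def test_independent_columns_give_near_zero(self):
        m = np.random.default_rng(1).normal(size=(1000, 3))
        assert abs(icc(m)) < 0.05

    def test_known_variance_components(self):
        # between 0.6, within 0.4 -> consistency ICC = 0.6
        rng = np.random.default_rng(2)
        n, k = 1000, 3
        m = (rng.normal(0, np.sqrt(0.6), size=(n, 1))
             + rng.normal(0, np.sqrt(0.4), size=(n, k)))
        rho = 0.6
        se = (1 - rho) * (1 + (k - 1) * rho) * np.sqrt(
            2.0 / (k * (k - 1) * (n - 1))
        )
        assert abs(icc(m) - rho) < 3 * se

    def test_agreement_penalizes_session_shifts(self):
        rng = np.random.default_rng(3)
        m = (rng.normal(0, 1, size=(500, 1))
             + rng.normal(0, 0.5, size=(500, 3)))
        shifted = m + np.array([0.0, 1.5, 3.0])
        assert icc(shifted, form="agreement") < icc(shifted, form="consistency")
        assert icc(shifted, form="consistency") == pytest.approx(icc(m), abs=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        m = rng.normal(size=(40, 3)) + rng.normal(size=(40, 1))
        df = pd.DataFrame(m).reset_index().melt(
            id_vars="index", var_name="rater", value_name="score"
        )
        table = pg.intraclass_corr(df, targets="index", raters="rater",
                                   ratings="score").set_index("Type")
        assert icc(m, "consistency") == pytest.approx(table.loc["ICC(C,1)", "ICC"])
        assert icc(m, "agreement") == pytest.approx(table.loc["ICC(A,1)", "ICC"])

    def test_degenerate_and_invalid_inputs(self):
        with pytest.warns(RuntimeWarning):
            assert icc(np.ones((10, 3))) == 0.0
        with pytest.raises(ValueError):
            icc(np.ones((10, 1)))
        m = np.ones((10, 3))
        m[0] = np.nan
        with pytest.raises(ValueError):
            icc(m)
        with pytest.raises(ValueError):
            icc(np.random.default_rng(0).normal(size=(2, 3)))


class TestSplitHalf:
    def test_spearman_brown_closed_form(self):
        assert spearman_brown(0.5) == pytest.approx(2 / 3)

    def test_constant_estimator_flagged(self, mid_params, task_config):
        sessions = [
            simulate_subject(mid_params, config=task_config, seed=i,
                             subject=f"s{i}")
            for i in range(10)
        ]
        report = split_half(sessions, lambda s: 1.0)
        assert report.r_half is None
        assert "undefined" in report.flag

    def test_estimator_failures_counted(self, mid_params, task_config):
        sessions = [
            simulate_subject(mid_params, config=task_config, seed=i,
                             subject=f"s{i}")
            for i in range(10)
        ]

        def flaky(s):
            if s.subject in ("s0", "s1"):
                raise ValueError("undefined on this half")
            return session_metrics(s).accuracy

        report = split_half(sessions, flaky)
        assert report.n_dropped == 2 and report.n_used == 8

    def test_reliability_rises_with_heterogeneity(self, task_config):
        def cohort(spread, seed):
            rng = np.random.default_rng(seed)
            out = []
            for i in range(60):
                a = float(np.clip(0.6 + rng.normal(0, 0.02), 0.01, 0.99))
                rw = float(np.clip(2.5 + rng.normal(0, spread), 0.2, 8.0))
                p = Params.from_natural(DU2RA, alpha=a, rho_win=rw,
                                        rho_loss=-0.7)
                out.append(simulate_subject(p, config=task_config,
                                            seed=1000 * seed + i,
                                            subject=f"s{i}"))
            return out

        est = lambda s: session_metrics(s).p_stay_win  # noqa: E731
        low = split_half(cohort(0.05, 1), est)
        high = split_half(cohort(2.0, 1), est)
        assert high.corrected > low.corrected


class TestEventExport:
    def test_round_trip_and_na_convention(self, mid_params, tmp_path):
        s = make_session([0, None, 1], [1, None, -1])
        table = build_regressors(s, mid_params)
        path = write_events(table, tmp_path / "events.tsv")
        text = path.read_text().splitlines()
        assert text[0] == ("onset\tduration\tchoice_prob\tbelow_chance\t"
                           "su_pe\tdu_unique_pe")
        assert "n/a" in text[2]  # the missing trial
        back = pd.read_csv(path, sep="\t", na_values="n/a")
        np.testing.assert_allclose(back["su_pe"], table["su_pe"], atol=1e-6)

    def test_modulator_files_drop_null_rows(self, mid_params, tmp_path):
        s = make_session([0, None, 1], [1, None, -1])
        table = build_regressors(s, mid_params)
        files = write_modulator_files(table, tmp_path)
        assert {f.name for f in files} == {
            "choice_prob.txt", "below_chance.txt", "su_pe.txt",
            "du_unique_pe.txt",
        }
        su = pd.read_csv(tmp_path / "su_pe.txt", sep="\t", header=None)
        assert len(su) == 2  # missing trial omitted
        assert su.shape[1] == 3
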