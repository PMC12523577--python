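"""End-to-end fitting, assignment, evaluation, serialization and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner
from sklearn.base import clone

from eaccd.cli import main as cli_main
from eaccd.cohort import EVENT_COL, TIME_COL
from eaccd.prognostic_system import (
    EACCD,
    UNASSIGNED,
    SchemaError,
    adjacent_separation_table,
    assign_group,
    evaluate_system,
    export_system,
    fit_system,
    import_system,
    system_to_json,
)
from eaccd.synthetic_data import SyntheticSpec, generate_cohort

SMALL = SyntheticSpec(combos_per_stratum=4, patients_per_combo=40, seed=5)


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(SMALL)


@pytest.fixture(scope="module")
def fitted(small_cohort):
    train, _ = small_cohort.split()
    return EACCD(
        factors=SMALL.factors, min_combo_size=25, n_groups=3, g_range=(2, 4)
    ).fit(train)


class TestFit:
    def test_fixed_group_count_respected(self, small_cohort):
        train, _ = small_cohort.split()
        m = EACCD(factors=SMALL.factors, n_groups=2, g_range=(2, 4)).fit(train)
        assert m.n_groups_ == 2
        assert set(m.group_map_.values()) == {1, 2}

    def test_every_combination_mapped_once(self, fitted):
        assert set(fitted.group_map_) == set(fitted.combinations_.labels)
        assert set(fitted.group_map_.values()) == {1, 2, 3}

    def test_training_rmst_ordering_invariant(self, fitted):
        # group 1 must have the best training survival under the ordering
        # statistic (restricted mean at the horizon)
        from eaccd.survival_stats import rmst

        means = [
            rmst(fitted.group_curves_[g], fitted.horizon)
            for g in sorted(fitted.group_curves_)
        ]
        assert means == sorted(means, reverse=True)

    def test_determinism(self, small_cohort):
        train, _ = small_cohort.split()
        js = [
            system_to_json(
                EACCD(factors=SMALL.factors, n_groups=3, g_range=(2, 4)).fit(train)
            )
            for _ in range(2)
        ]
        assert js[0] == js[1]

    def test_too_few_combinations_rejected(self, small_cohort):
        train, _ = small_cohort.split()
        sub = train[train["T"] == train["T"].iloc[0]]
        with pytest.raises(ValueError):
            EACCD(factors=SMALL.factors, min_combo_size=10_000).fit(train)
        assert len(sub) > 0

    def test_sklearn_params_roundtrip(self):
        m = EACCD(factors=("T", "G"), n_groups=4, horizon=48.0)
        m2 = clone(m)
        assert m2.get_params()["n_groups"] == 4 and m2.get_params()["horizon"] == 48.0

    def test_fit_with_separate_y(self, small_cohort):
        train, _ = small_cohort.split()
        X = train[list(SMALL.factors)]
        y = np.column_stack([train[TIME_COL], train[EVENT_COL]])
        m = EACCD(factors=SMALL.factors, n_groups=3, g_range=(2, 4)).fit(X, y)
        assert m.n_groups_ == 3


class TestAssignment:
    def test_training_labels_lookup(self, fitted):
        for label, group in list(fitted.group_map_.items())[:3]:
            cohort = next(
                c for c in fitted.combinations_.cohorts if c.label == label
            )
            assert assign_group(fitted, cohort.combination.level_map()) == group

    def test_unseen_combination_unassigned(self, fitted):
        levels = {"T": "T4", "N": "N1", "M": "M1", "P": "P3", "G": "G5"}
        assert levels_not_trained(fitted, levels)
        assert assign_group(fitted, levels) == UNASSIGNED

    def test_missing_factor_rejected(self, fitted):
        with pytest.raises(ValueError, match="'G'"):
            assign_group(fitted, {"T": "T1", "N": "N0", "M": "M0", "P": "P1"})

    def test_unknown_level_rejected(self, fitted):
        with pytest.raises(ValueError, match="T7"):
            assign_group(
                fitted, {"T": "T7", "N": "N0", "M": "M0", "P": "P1", "G": "G1"}
            )

    def test_predict_frame(self, fitted, small_cohort):
        _, val = small_cohort.split()
        groups = fitted.predict(val)
        assert len(groups) == len(val)
        assert set(groups) <= set(range(1, fitted.n_groups_ + 1)) | {UNASSIGNED}


def levels_not_trained(system, levels):
    return system.scheme_.label(levels, system.factors_) not in system.group_map_


class TestEvaluation:
    def test_training_data_reproduces_train_cindex(self, fitted, small_cohort):
        train, _ = small_cohort.split()
        report = evaluate_system(fitted, train, bootstrap=0)
        assert report.cindex.c == fitted.train_cindex_.c
        assert report.cindex.comparable == fitted.train_cindex_.comparable

    def test_unassigned_accounting(self, fitted, small_cohort):
        _, val = small_cohort.split()
        extra = val.iloc[:5].copy()
        extra.loc[:, "T"] = "T4"
        extra.loc[:, "G"] = "G5"  # combination unseen in training
        stacked = pd.concat([val, extra], ignore_index=True)
        report = evaluate_system(fitted, stacked, bootstrap=0)
        assert report.n_assigned + report.unassigned_count == len(stacked)
        assert report.unassigned_count == 5

    def test_bootstrap_ci_attached_and_deterministic(self, fitted, small_cohort):
        _, val = small_cohort.split()
        r1 = evaluate_system(fitted, val, bootstrap=60, seed=3)
        r2 = evaluate_system(fitted, val, bootstrap=60, seed=3)
        assert r1.cindex.ci_low == r2.cindex.ci_low is not None
        assert r1.cindex.ci_low <= r1.cindex.c <= r1.cindex.ci_high

    def test_adjacent_separation_on_separated_groups(self, fitted, small_cohort):
        _, val = small_cohort.split()
        report = evaluate_system(fitted, val, bootstrap=0)
        table = adjacent_separation_table(report)
        assert len(table) == fitted.n_groups_ - 1
        assert table["significant"].all()
        assert table["direction_expected"].all()

    def test_identical_groups_not_significant(self, fitted):
        # feed the same survival data for every combination: adjacent curves
        # coincide, p ~ 1
        rows = []
        for c in fitted.combinations_.cohorts:
            lv = c.combination.level_map()
            rows += [
                {**lv, TIME_COL: 10.0 * (i % 7 + 1), EVENT_COL: int(i % 2)}
                for i in range(30)
            ]
        report = evaluate_system(fitted, pd.DataFrame(rows), bootstrap=0)
        table = adjacent_separation_table(report)
        assert not table["significant"].any()

    def test_empty_validation_rejected(self, fitted, small_cohort):
        _, val = small_cohort.split()
        with pytest.raises(ValueError):
            evaluate_system(fitted, val.iloc[0:0])


class TestSerialization:
    def test_roundtrip_preserves_assignment_and_stats(self, fitted, small_cohort):
        doc = export_system(fitted)
        system = import_system(json.loads(json.dumps(doc)))
        assert system.group_map_ == fitted.group_map_
        assert system.train_cindex_.c == fitted.train_cindex_.c
        assert system.n_groups_ == fitted.n_groups_
        _, val = small_cohort.split()
        assert list(system.predict(val)) == list(fitted.predict(val))

    def test_roundtrip_evaluation_identical(self, fitted, small_cohort):
        _, val = small_cohort.split()
        system = import_system(system_to_json(fitted))
        a = evaluate_system(fitted, val, bootstrap=60, seed=1)
        b = evaluate_system(system, val, bootstrap=60, seed=1)
        assert a.cindex == b.cindex

    def test_truncated_json_rejected(self, fitted):
        text = system_to_json(fitted)
        with pytest.raises(SchemaError):
            import_system(text[: len(text) // 2])

    def test_version_mismatch_rejected(self, fitted):
        doc = export_system(fitted)
        doc["schema_version"] = 99
        with pytest.raises(SchemaError, match="version"):
            import_system(doc)


def test_five_and_seven_variable_systems_share_code_path():
    # 18 seven-factor combinations project onto 3 five-factor ones (the A/R
    # variants of each grade), so both systems are fittable from one table
    spec7 = SyntheticSpec(
        combos_per_stratum=6, patients_per_combo=30, seed=9,
        factors=("T", "N", "M", "P", "G", "A", "R"),
    )
    train, _ = generate_cohort(spec7).split()
    m5 = fit_system(train, factors=("T", "N", "M", "P", "G"), n_groups=3, g_range=(2, 3))
    m7 = fit_system(train, factors=spec7.factors, n_groups=3, g_range=(2, 4))
    assert m5.factors_ == ("T", "N", "M", "P", "G")
    assert m7.factors_ == ("T", "N", "M", "P", "G", "A", "R")
    assert all(len(lab) > 0 for lab in m7.group_map_)


class TestCli:
    def test_workflow(self, tmp_path):
        runner = CliRunner()
        spec_file = tmp_path / "spec.json"
        spec_file.write_text(json.dumps({"combos_per_stratum": 3, "patients_per_combo": 40}))
        cohort_csv = tmp_path / "cohort.csv"
        res = runner.invoke(
            cli_main,
            ["simulate", "--spec", str(spec_file), "--seed", "4",
             "--out", str(cohort_csv), "--truth", str(tmp_path / "truth.json")],
        )
        assert res.exit_code == 0, res.output

        system_json = tmp_path / "system.json"
        res = runner.invoke(
            cli_main,
            ["fit", "--input", str(cohort_csv), "--groups", "3", "--g-range", "2,4",
             "--seed", "1", "--out", str(system_json)],
        )
        assert res.exit_code == 0, res.output
        assert "groups" in res.output

        res = runner.invoke(
            cli_main,
            ["evaluate", "--system", str(system_json), "--input", str(cohort_csv),
             "--bootstrap", "60", "--out", str(tmp_path / "report.json")],
        )
        assert res.exit_code == 0, res.output
        report = json.loads((tmp_path / "report.json").read_text())
        assert 0 <= report["cindex"] <= 1 and report["ci_low"] is not None

        assigned_csv = tmp_path / "assigned.csv"
        res = runner.invoke(
            cli_main,
            ["assign", "--system", str(system_json), "--input", str(cohort_csv),
             "--out", str(assigned_csv)],
        )
        assert res.exit_code == 0, res.output
        assert "group" in pd.read_csv(assigned_csv).columns

        res = runner.invoke(
            cli_main,
            ["ajcc-stage", "--input", str(cohort_csv), "--out", str(tmp_path / "staged.csv")],
        )
        assert res.exit_code == 0, res.output
        staged = pd.read_csv(tmp_path / "staged.csv")
        assert {"substage", "principal_stage"} <= set(staged.columns)

        res = runner.invoke(
            cli_main,
            ["curve", "--system", str(system_json), "--out-prefix", str(tmp_path / "out")],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "out.nwk").exists()
        cindex_tab = pd.read_csv(tmp_path / "out_cindex.csv")
        assert list(cindex_tab.columns) == ["groups", "cindex"]
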