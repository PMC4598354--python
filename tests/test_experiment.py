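"""Experiment orchestration: conditions, aggregation, study runner."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from pydantic import ValidationError

import foamplug as fp
from foamplug.experiment import SimulationSpec, ConditionSpec


def noise_free_replicates(dr=2.0, n=4):
    series = []
    for _ in range(n):
        kin = fp.SimKinetics(20.0, dr, 100.0, noise_sigma=0.0)
        series.append(fp.simulate_series(kin, frame_interval=0.1))
    return series


class TestFoamCondition:
    def test_pem_with_wrong_lgr_rejected(self):
        with pytest.raises(ValidationError, match="fixed LGR"):
            fp.FoamCondition(method="PEM", gas="CO2_O2_35_65", lgr="1:3")

    def test_pem_with_wrong_gas_rejected(self):
        with pytest.raises(ValidationError, match="35:65"):
            fp.FoamCondition(method="PEM", gas="RA", lgr="1:7")

    def test_valid_pem_condition(self):
        c = fp.FoamCondition(method="PEM", gas="CO2_O2_35_65", lgr="1:7")
        assert c.n_replicates == 4
        assert "PEM" in c.key()

    def test_unknown_gas_rejected(self):
        with pytest.raises(ValidationError):
            fp.FoamCondition(gas="helium")


class TestPctDeviation:
    def test_constant_values_have_zero_deviation(self):
        assert fp.pct_deviation([1, 1, 1, 1]) == 0.0

    def test_two_values(self):
        assert fp.pct_deviation([1, 3]) == pytest.approx(50.0)

    def test_hand_computed_example(self):
        # mean 5, mean absolute deviation (3+1+1+3)/4 = 2 -> 40 %
        assert fp.pct_deviation([2, 4, 6, 8]) == pytest.approx(40.0)

    def test_cv_variant(self):
        vals = [2.0, 4.0, 6.0, 8.0]
        expected = np.std(vals, ddof=1) / np.mean(vals) * 100
        assert fp.pct_deviation(vals, method="cv") == pytest.approx(expected)

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(fp.InvalidParameterError):
            fp.pct_deviation([1.0])

    @given(
        st.lists(st.floats(min_value=0.1, max_value=100.0), min_size=2, max_size=10),
        st.floats(min_value=0.01, max_value=100.0),
    )
    def test_scale_invariance(self, values, c):
        base = fp.pct_deviation(values)
        scaled = fp.pct_deviation(np.asarray(values) * c)
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestRunCondition:
    def test_noise_free_dr2_gives_mean_dt_5(self):
        cond = fp.FoamCondition()
        res = fp.run_condition(cond, noise_free_replicates(dr=2.0))
        assert res.mean_dt == pytest.approx(5.0, rel=1e-9)
        assert res.pct_deviation == pytest.approx(0.0, abs=1e-9)
        assert res.n_failed == 0

    def test_halved_dr_doubles_mean_dt(self):
        cond = fp.FoamCondition()
        a = fp.run_condition(cond, noise_free_replicates(dr=2.0))
        b = fp.run_condition(cond, noise_free_replicates(dr=1.0))
        assert b.mean_dt == pytest.approx(2 * a.mean_dt, rel=1e-9)

    def test_failed_replicates_counted_not_imputed(self):
        cond = fp.FoamCondition()
        series = noise_free_replicates(dr=2.0, n=3)
        failed = fp.simulate_series(
            fp.SimKinetics(20, 2, 100, noise_sigma=0.0, plug_fails=True), 0.1
        )
        res = fp.run_condition(cond, series + [failed])
        assert res.n_failed == 1
        assert len(res.dts) == 3
        assert res.mean_dt == pytest.approx(5.0, rel=1e-9)

    def test_all_failed_raises(self):
        cond = fp.FoamCondition()
        failed = [
            fp.simulate_series(
                fp.SimKinetics(20, 2, 100, noise_sigma=0.0, plug_fails=True, seed=s),
                0.1,
            )
            for s in range(4)
        ]
        with pytest.raises(fp.AllPlugsFailed):
            fp.run_condition(cond, failed)

    def test_replicate_count_mismatch_rejected(self):
        with pytest.raises(fp.InvalidParameterError):
            fp.run_condition(fp.FoamCondition(), noise_free_replicates(n=2))


class TestComparisonTable:
    def make_result(self, dts, **cond_kwargs):
        cond = fp.FoamCondition(**cond_kwargs)
        return fp.ConditionResult(
            condition=cond,
            dts=list(dts),
            mean_dt=float(np.mean(dts)),
            pct_deviation=fp.pct_deviation(dts),
            n_failed=0,
            replicates=[None] * cond.n_replicates,
        )

    def test_normalised_column(self):
        results = [
            self.make_result([2.0, 2.0], method="DSS"),
            self.make_result([4.0, 4.0], method="Tessari"),
        ]
        df = fp.comparison_table(results, normalise=True)
        by_method = df.set_index("method")["dt_normalised"]
        assert by_method["DSS"] == pytest.approx(0.5)
        assert by_method["Tessari"] == pytest.approx(1.0)

    def test_single_condition_normalises_to_one(self):
        df = fp.comparison_table([self.make_result([3.0, 3.0])], normalise=True)
        assert df.loc[0, "dt_normalised"] == pytest.approx(1.0)

    def test_shuffle_invariance(self):
        results = [
            self.make_result([1.0, 2.0], method="DSS", gas="RA"),
            self.make_result([2.0, 3.0], method="Tessari", gas="CO2"),
            self.make_result([4.0, 5.0], method="PEM", gas="CO2_O2_35_65", lgr="1:7"),
        ]
        a = fp.comparison_table(results)
        b = fp.comparison_table(results[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_duplicate_conditions_rejected(self):
        results = [self.make_result([1.0, 2.0]), self.make_result([3.0, 4.0])]
        with pytest.raises(fp.InvalidParameterError, match="duplicate"):
            fp.comparison_table(results)


def study_config(tmp_path, noise=0.0, seed=123):
    return fp.StudyConfig(
        name="demo",
        seed=seed,
        conditions=[
            ConditionSpec(
                condition=fp.FoamCondition(method="DSS", gas="RA", lgr="1:3"),
                simulate=SimulationSpec(
                    formation_rate_mm_s=35.0,
                    degradation_rate_mm_s=4.0,
                    noise_sigma_mm=noise,
                    frame_interval_s=0.1,
                ),
            ),
            ConditionSpec(
                condition=fp.FoamCondition(
                    method="PEM", gas="CO2_O2_35_65", lgr="1:7"
                ),
                simulate=SimulationSpec(
                    formation_rate_mm_s=29.5,
                    degradation_rate_mm_s=3.42,
                    noise_sigma_mm=noise,
                    frame_interval_s=0.1,
                ),
            ),
        ],
    )


class TestRunStudy:
    def test_outputs_one_json_per_replicate_and_tables(self, tmp_path):
        config = study_config(tmp_path)
        table = fp.run_study(config, tmp_path / "out")
        reps = sorted((tmp_path / "out" / "replicates").glob("*.json"))
        assert len(reps) == 8  # 2 conditions x 4 replicates
        conds = sorted((tmp_path / "out" / "conditions").glob("*.csv"))
        assert len(conds) == 2
        assert (tmp_path / "out" / "comparison.csv").exists()
        assert (tmp_path / "out" / "run.log").exists()
        assert len(table) == 2
        # PEM (DR 3.42) has the longer DT and normalises to 1
        pem = table[table["method"] == "PEM"].iloc[0]
        assert pem["dt_normalised"] == pytest.approx(1.0)
        assert pem["mean_dt_s_cm"] == pytest.approx(10.0 / 3.42, rel=1e-6)

    def test_rerun_with_same_seed_is_byte_identical(self, tmp_path):
        config = study_config(tmp_path, noise=0.5)
        fp.run_study(config, tmp_path / "a")
        fp.run_study(config, tmp_path / "b")
        for name in ("comparison.csv", "run.log"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_yaml_config_round_trip(self, tmp_path):
        import yaml

        raw = {
            "name": "yaml-demo",
            "seed": 7,
            "conditions": [
                {
                    "condition": {"method": "DSS", "gas": "CO2", "lgr": "1:4"},
                    "simulate": {
                        "formation_rate_mm_s": 40.0,
                        "degradation_rate_mm_s": 8.0,
                        "frame_interval_s": 0.1,
                    },
                }
            ],
        }
        path = tmp_path / "study.yaml"
        path.write_text(yaml.safe_dump(raw))
        table = fp.run_study(path, tmp_path / "out")
        assert table.loc[0, "mean_dt_s_cm"] == pytest.approx(10.0 / 8.0, rel=1e-3)

    def test_invalid_config_reports_field_path(self):
        with pytest.raises(ValidationError) as exc:
            fp.StudyConfig.model_validate(
                {
                    "conditions": [
                        {
                            "condition": {"method": "PEM", "gas": "CO2_O2_35_65",
                                          "lgr": "1:3"},
                            "simulate": {
                                "formation_rate_mm_s": 30.0,
                                "degradation_rate_mm_s": 3.0,
                            },
                        }
                    ]
                }
            )
        assert "conditions" in str(exc.value)

    def test_condition_needs_exactly_one_source(self):
        with pytest.raises(ValidationError, match="exactly one"):
            ConditionSpec(condition=fp.FoamCondition())

    def test_series_paths_source(self, tmp_path):
        paths = []
        for i in range(2):
            s = fp.simulate_series(
                fp.SimKinetics(30.0, 5.0, 80.0, noise_sigma=0.0), 0.1
            )
            paths.append(str(s.to_csv(tmp_path / f"rep{i}.csv")))
        config = fp.StudyConfig(
            conditions=[
                ConditionSpec(
                    condition=fp.FoamCondition(n_replicates=2),
                    series_paths=paths,
                )
            ]
        )
        table = fp.run_study(config, tmp_path / "out")
        assert table.loc[0, "mean_dt_s_cm"] == pytest.approx(2.0, rel=1e-6)
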