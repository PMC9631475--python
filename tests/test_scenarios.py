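import pytest

from lvadloop.scenarios import (
    ScenarioSpec,
    apply_ai,
    apply_bp_control,
    apply_pulmonary_vasodilation,
    apply_speed,
    apply_uncoupling,
    table_specs,
)


class TestScenarioSpec:
    def test_name_round_trip(self):
        spec = ScenarioSpec("uncoupled", "mild_moderate", "pulm_vasodilation_plus_bp")
        assert ScenarioSpec.from_name(spec.name) == spec

    def test_invalid_combinations_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec("coupled", "severe", "pulmonary_vasodilation")
        with pytest.raises(ValueError):
            ScenarioSpec("sideways", "severe", "baseline")
        with pytest.raises(ValueError):
            ScenarioSpec.from_name("not_a_scenario")

    def test_table_has_sixteen_columns(self):
        specs = table_specs()
        assert len(specs) == 16
        assert len({s.name for s in specs}) == 16
        assert sum(s.rv_state == "coupled" for s in specs) == 6


class TestTransforms:
    def test_ai_none_restores_perfect_valve(self, seed_params):
        p = apply_ai(seed_params, "none")
        assert p.valves["aortic"].theta_min == 0.0

    def test_ai_severity_sets_angles(self, seed_params):
        p = apply_ai(seed_params, "severe", theta_min_mild=20.0, theta_min_severe=35.0)
        assert p.valves["aortic"].theta_min == 35.0
        q = apply_ai(seed_params, "mild_moderate", theta_min_mild=20.0, theta_min_severe=35.0)
        assert q.valves["aortic"].theta_min == 20.0
        # other valves stay competent
        assert all(p.valves[k].theta_min == 0.0 for k in ("mitral", "tricuspid", "pulmonic"))

    def test_same_speed_is_identity(self, seed_params):
        assert apply_speed(seed_params, seed_params.pump.speed_rpm) == seed_params

    def test_speed_changes_only_pump(self, seed_params):
        p = apply_speed(seed_params, 6400.0)
        assert p.pump.speed_rpm == 6400.0
        assert p.compartments == seed_params.compartments
        assert p.chambers == seed_params.chambers

    def test_uncoupling_is_idempotent(self, seed_params):
        p1 = apply_uncoupling(seed_params, r_factor=1.3, c_factor=0.1)
        p2 = apply_uncoupling(p1, r_factor=1.3, c_factor=0.1)
        assert p1.compartments["pa"] == p2.compartments["pa"]
        assert p1.tags["rv_state"] == "uncoupled"

    def test_uncoupling_targets_pulmonary_bed_only(self, seed_params):
        p = apply_uncoupling(seed_params, r_factor=1.3, c_factor=0.1)
        assert p.compartments["pa"].r == pytest.approx(seed_params.compartments["pa"].r * 1.3)
        assert p.compartments["pa"].c == pytest.approx(seed_params.compartments["pa"].c * 0.1)
        assert p.chambers["rv"] == seed_params.chambers["rv"]

    def test_bp_control_factor_band(self, seed_params):
        with pytest.raises(ValueError):
            apply_bp_control(seed_params, factor=0.7)
        p = apply_bp_control(seed_params, factor=0.55)
        assert p.compartments["sa"].r == pytest.approx(
            seed_params.compartments["sa"].r * 0.55
        )

    def test_vasodilation_identity_factors(self, seed_params):
        p = apply_pulmonary_vasodilation(seed_params, c_factor=1.0, r_factor=1.0)
        assert p.compartments["pa"] == seed_params.compartments["pa"]

    def test_bp_and_vasodilation_commute(self, seed_params):
        a = apply_bp_control(
            apply_pulmonary_vasodilation(seed_params), factor=0.55
        )
        b = apply_pulmonary_vasodilation(
            apply_bp_control(seed_params, factor=0.55)
        )
        assert a.compartments == b.compartments


class TestCatalogue:
    def test_build_all_scenarios(self, catalogue):
        for spec in catalogue.specs():
            p = catalogue.build(spec)
            assert p.tags["scenario"] == spec.name

    def test_build_sets_ai_and_speed(self, catalogue):
        p = catalogue.build("coupled_severe_speed_augmentation")
        assert p.pump.speed_rpm == catalogue.augmented_rpm
        assert p.valves["aortic"].theta_min == pytest.approx(catalogue.theta_min_severe)
        q = catalogue.build("coupled_none_baseline")
        assert q.valves["aortic"].theta_min == 0.0
        assert q.pump.speed_rpm == catalogue.baseline_rpm

    def test_catalogue_yaml_round_trip(self, tmp_path, catalogue):
        path = tmp_path / "cat.yaml"
        catalogue.to_yaml(path)
        from lvadloop.scenarios import ScenarioCatalogue

        back = ScenarioCatalogue.from_yaml(path)
        assert back.baseline == catalogue.baseline
        assert back.theta_min_severe == catalogue.theta_min_severe

    def test_export_configs(self, tmp_path, catalogue):
        files = catalogue.export_configs(tmp_path)
        assert len(files) == 18  # 16 table columns + 2 no-AI baselines
        from lvadloop.parameters import ParameterSet

        p = ParameterSet.from_yaml(tmp_path / "coupled_severe_baseline.yaml")
        assert p.valves["aortic"].theta_min > 0.0
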