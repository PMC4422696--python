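"""GOF/LOF compatibility rule-engine tests."""

import itertools

import pytest

from drugrepo.catalog import DrugProject, parse_stage
from drugrepo.errors import ValidationError
from drugrepo.pathogenesis import (
    PathogenesisAnnotation,
    apply_pathogenesis_filter,
    compatibility,
    drug_effect_direction,
)
from drugrepo.report import load_annotation_fixture, load_repurposing_fixture
from drugrepo.simulate import generate_annotations, generate_drug_catalog


def _ann(direction, valence, scope="direct_diabetes", target="T"):
    if scope == "none":
        return PathogenesisAnnotation(target_accession=target, link_scope="none")
    return PathogenesisAnnotation(
        target_accession=target, direction=direction, valence=valence,
        link_scope=scope,
    )


class TestDrugEffectDirection:
    @pytest.mark.parametrize(
        "mode, effect",
        [
            ("inhibitor", "lof_like"),
            ("antagonist", "lof_like"),
            ("agonist", "gof_like"),
            ("activator", "gof_like"),
            ("modulator_unknown", "unknown"),
        ],
    )
    def test_mapping(self, mode, effect):
        assert drug_effect_direction(mode) == effect

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValidationError):
            drug_effect_direction("allosteric_partial")


def hand_truth(effect, direction, valence, scope):
    """Independent verdict oracle, written as an explicit case listing."""
    if scope == "none":
        return "excluded_no_link"
    if scope == "complication_only":
        return "excluded_complication"
    if effect == "unknown":
        return "indeterminate"
    helps = {
        ("lof_like", "gof", "harmful"): True,
        ("lof_like", "lof", "beneficial"): True,
        ("lof_like", "gof", "beneficial"): False,
        ("lof_like", "lof", "harmful"): False,
        ("gof_like", "gof", "harmful"): False,
        ("gof_like", "lof", "beneficial"): False,
        ("gof_like", "gof", "beneficial"): True,
        ("gof_like", "lof", "harmful"): True,
    }[(effect, direction, valence)]
    return "therapeutic" if helps else "aggravating"


class TestCompatibility:
    def test_exhaustive_single_annotation_truth_table(self):
        """Every effect x (direction, valence, scope) combination."""
        for effect in ("lof_like", "gof_like"):
            for direction, valence in itertools.product(
                ("gof", "lof"), ("beneficial", "harmful")
            ):
                for scope in ("direct_diabetes", "complication_only"):
                    verdict = compatibility(effect, [_ann(direction, valence, scope)])
                    assert verdict.verdict == hand_truth(
                        effect, direction, valence, scope
                    ), (effect, direction, valence, scope)

    def test_lof_drug_on_beneficial_lof_target_is_therapeutic(self):
        verdict = compatibility("lof_like", [_ann("lof", "beneficial")])
        assert verdict.verdict == "therapeutic"

    def test_gof_drug_on_harmful_gof_target_aggravates(self):
        verdict = compatibility("gof_like", [_ann("gof", "harmful")])
        assert verdict.verdict == "aggravating"

    def test_two_concordant_annotations_are_both_supporting(self):
        # inhibitor target carrying both beneficial-LOF and harmful-GOF evidence
        verdict = compatibility(
            "lof_like", [_ann("lof", "beneficial"), _ann("gof", "harmful")]
        )
        assert verdict.verdict == "therapeutic"
        assert len(verdict.supporting_annotations) == 2

    def test_aggravating_evidence_vetoes_therapeutic(self):
        verdict = compatibility(
            "lof_like", [_ann("lof", "beneficial"), _ann("lof", "harmful")]
        )
        assert verdict.verdict == "aggravating"

    def test_no_evidence_is_excluded_no_link(self):
        assert compatibility("gof_like", []).verdict == "excluded_no_link"
        assert compatibility("gof_like", [_ann(None, None, "none")]).verdict \
            == "excluded_no_link"

    def test_complication_only_excluded(self):
        verdict = compatibility(
            "lof_like", [_ann("gof", "harmful", "complication_only")]
        )
        assert verdict.verdict == "excluded_complication"

    def test_unknown_effect_with_direct_evidence_is_indeterminate(self):
        verdict = compatibility("unknown", [_ann("gof", "harmful")])
        assert verdict.verdict == "indeterminate"

    def test_pure_function_order_invariance(self):
        anns = [_ann("lof", "beneficial"), _ann("gof", "harmful"),
                _ann("gof", "harmful", "complication_only")]
        assert compatibility("lof_like", anns).verdict == \
            compatibility("lof_like", anns[::-1]).verdict

    def test_mixed_targets_rejected(self):
        with pytest.raises(ValidationError):
            compatibility(
                "lof_like",
                [_ann("lof", "beneficial", target="A"),
                 _ann("lof", "beneficial", target="B")],
            )


def test_scope_none_forbids_direction_content():
    with pytest.raises(ValidationError):
        PathogenesisAnnotation(
            target_accession="T", direction="gof", valence="harmful",
            link_scope="none",
        )


def _project(target, mode, drug="d", stage="Approved"):
    return DrugProject(
        target_accession=target, target_name=target, drug_name=drug,
        indication="Pain", stage_raw=stage, stage_class=parse_stage(stage),
        action_mode=mode,
    )


class TestApplyPathogenesisFilter:
    def test_repurposing_fixture_all_rows_therapeutic(self):
        candidates = load_repurposing_fixture()
        annotations = load_annotation_fixture()
        result = apply_pathogenesis_filter(candidates, annotations)
        assert len(result["partition"]["therapeutic"]) == len(candidates)
        assert result["n_therapeutic_targets"] == 12

    def test_all_agonists_of_harmful_gof_targets_logged_aggravating(self):
        candidates = [_project("T", "agonist", drug=f"d{i}") for i in range(4)]
        annotations = [_ann("gof", "harmful")]
        result = apply_pathogenesis_filter(candidates, annotations)
        assert result["repurposing_table"].empty
        assert len(result["partition"]["aggravating"]) == 4

    def test_partition_is_exhaustive(self):
        candidates = [
            _project("T1", "inhibitor", "a"),
            _project("T2", "agonist", "b"),
            _project("T3", "modulator_unknown", "c"),
            _project("T4", "antagonist", "d"),
            _project("T5", "activator", "e"),
        ]
        annotations = [
            _ann("gof", "harmful", target="T1"),
            _ann("gof", "harmful", target="T2"),
            _ann("gof", "harmful", target="T3"),
            _ann(None, None, "none", target="T4"),
            _ann("lof", "beneficial", "complication_only", target="T5"),
        ]
        result = apply_pathogenesis_filter(candidates, annotations)
        assert sum(len(v) for v in result["partition"].values()) == len(candidates)
        verdicts = {v.pair[0]: v.verdict for v in result["verdicts"]}
        assert verdicts == {
            "T1": "therapeutic", "T2": "aggravating", "T3": "indeterminate",
            "T4": "excluded_no_link", "T5": "excluded_complication",
        }

    def test_annotation_for_unknown_target_rejected(self):
        with pytest.raises(ValidationError, match="unknown target"):
            apply_pathogenesis_filter(
                [_project("T", "inhibitor")], [_ann("gof", "harmful", target="X")]
            )

    def test_drug_level_veto_across_targets(self):
        candidates = [
            _project("GOOD", "inhibitor", drug="dual"),
            _project("BAD", "inhibitor", drug="dual"),
        ]
        annotations = [
            _ann("gof", "harmful", target="GOOD"),
            _ann("lof", "harmful", target="BAD"),
        ]
        result = apply_pathogenesis_filter(candidates, annotations)
        assert result["repurposed_drugs"] == []

    def test_generator_round_trip_planted_verdicts(self, small_config):
        table, _ = generate_drug_catalog(
            small_config, [f"P{i:05d}" for i in range(1, 40)]
        )
        candidates = [
            _project(r.target_accession, r.action_mode, drug=r.drug_name,
                     stage=r.stage)
            for r in table.itertuples(index=False)
        ]
        annotations, expected = generate_annotations(small_config, candidates)
        result = apply_pathogenesis_filter(candidates, annotations)
        got = {v.pair: v.verdict for v in result["verdicts"]}
        assert got == expected
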