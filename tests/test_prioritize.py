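import itertools

import numpy as np
import pytest

from cffvar.model import ValidationError
from cffvar.prioritize import (
    CascadeConfig,
    cadd_filter,
    conservation_vote,
    deleteriousness_vote,
    fcvpp_cascade,
    intolerance_screen,
    maf_filter,
)
from cffvar.simulate import PROFILES, gen_annotated_variants
from conftest import make_variant


class TestMafFilter:
    def test_rare_everywhere_passes(self):
        v = make_variant(maf_by_source={"thousand_genomes": 1e-4, "exac_nfe_nontcga": 5e-4, "local": 0.0})
        assert maf_filter(v) == "pass"

    def test_common_in_one_source_fails(self):
        v = make_variant(maf_by_source={"exac_nfe_nontcga": 3.96e-3})
        assert maf_filter(v) == "fail"

    def test_boundary_is_strict(self):
        assert maf_filter(make_variant(maf_by_source={"local": 0.001})) == "fail"

    def test_no_sources_not_evaluated(self):
        assert maf_filter(make_variant(maf_by_source={})) == "not_evaluated"


class TestCaddFilter:
    @pytest.mark.parametrize("score,verdict", [(24.1, "pass"), (0.11, "fail"), (10.0, "fail")])
    def test_threshold_strictly_greater(self, score, verdict):
        assert cadd_filter(make_variant(cadd_phred=score)) == verdict

    def test_missing_not_evaluated(self):
        assert cadd_filter(make_variant(cadd_phred=None)) == "not_evaluated"


class TestConservationVote:
    def test_two_votes_pass(self):
        k, n, verdict = conservation_vote(make_variant(gerp=2.1, phastcons=0.2, phylop=3.5))
        assert (k, n, verdict) == (2, 3, "pass")

    def test_all_boundaries(self):
        # GERP and PhastCons strict, PhyloP inclusive.
        k, n, verdict = conservation_vote(make_variant(gerp=2.0, phastcons=0.3, phylop=2.9))
        assert (k, verdict) == (0, "fail")
        k, _, _ = conservation_vote(make_variant(gerp=2.0, phastcons=0.3, phylop=3.0))
        assert k == 1

    def test_three_votes(self):
        k, _, verdict = conservation_vote(make_variant(gerp=5.0, phastcons=0.9, phylop=7.0))
        assert (k, verdict) == (3, "pass")

    def test_no_scores_not_evaluated(self):
        assert conservation_vote(make_variant())[2] == "not_evaluated"


def calls(n_deleterious, n_available=10):
    from cffvar.model import PREDICTOR_TOOLS

    out = {}
    for i, tool in enumerate(PREDICTOR_TOOLS):
        if i < n_deleterious:
            out[tool] = "deleterious"
        elif i < n_available:
            out[tool] = "tolerated"
        else:
            out[tool] = "missing"
    return out


class TestDeleteriousnessVote:
    @pytest.mark.parametrize(
        "k,n,verdict",
        [(7, 10, "pass"), (0, 4, "fail"), (5, 10, "fail"), (6, 10, "pass"), (3, 4, "pass"), (2, 4, "fail")],
    )
    def test_strict_majority_of_available(self, k, n, verdict):
        got_k, got_n, got = deleteriousness_vote(make_variant(predictor_calls=calls(k, n)))
        assert (got_k, got_n, got) == (k, n, verdict)

    def test_no_tool_data_not_evaluated(self):
        assert deleteriousness_vote(make_variant(predictor_calls=calls(0, 0)))[2] == "not_evaluated"


class TestIntoleranceScreen:
    def test_default_is_non_blocking(self):
        record, verdict = intolerance_screen(make_variant())
        assert record == {} and verdict == "pass"

    def test_threshold_mode_fails_low_score(self):
        config = CascadeConfig(intolerance_thresholds={"missense_z": 0.0})
        _, verdict = intolerance_screen(make_variant(intolerance_ranks={"missense_z": -1.2}), config)
        assert verdict == "fail"

    def test_verdict_unchanged_by_intolerance_data_by_default(self):
        genes = {"GENE0001"}
        with_scores = make_variant(
            maf_by_source={"local": 1e-4}, cadd_phred=20, gerp=5, phastcons=0.9, phylop=5,
            predictor_calls=calls(8), intolerance_ranks={"missense_z": -3.0},
        )
        without = make_variant(
            maf_by_source={"local": 1e-4}, cadd_phred=20, gerp=5, phastcons=0.9, phylop=5,
            predictor_calls=calls(8),
        )
        for v in (with_scores, without):
            _, survivors = fcvpp_cascade([v], genes, "non_synonymous")
            assert len(survivors) == 1


class TestCascade:
    def test_planted_single_stage_failures_recovered(self):
        mix = {"all_pass": 5, "fail_maf": 3, "fail_cadd": 3, "fail_conservation": 2, "fail_deleteriousness": 2}
        genes = [f"G{i}" for i in range(5)]
        variants, profiles = gen_annotated_variants(15, mix, seed=21, genes=genes)
        audits, survivors = fcvpp_cascade(variants, genes, "non_synonymous")
        assert len(audits) == 15  # every variant audited exactly once
        assert len(survivors) == 5
        for audit, profile in zip(audits, profiles):
            if profile == "all_pass":
                assert audit.final
            else:
                stage = profile.removeprefix("fail_")
                assert audit.stages[stage] == "fail"
                failed = [s for s, v in audit.stages.items() if v == "fail"]
                assert failed == [stage]

    def test_gene_restriction_precedes_stages(self):
        variants, _ = gen_annotated_variants(4, {"all_pass": 4}, seed=2, genes=["IN1", "IN2", "OUT1", "OUT2"])
        audits, survivors = fcvpp_cascade(variants, ["IN1", "IN2"], "non_synonymous")
        assert len(audits) == 2 and len(survivors) == 2

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValidationError):
            fcvpp_cascade([], [], "non_synonymous")

    def test_lof_exempt_from_vote_stages(self):
        lof = make_variant(consequence="stop_gain", maf_by_source={"local": 1e-4}, cadd_phred=25.0)
        audits, survivors = fcvpp_cascade([lof], {"GENE0001"}, "lof")
        assert survivors == [lof]
        assert audits[0].stages["deleteriousness"] == "not_evaluated"
        assert audits[0].stages["conservation"] == "not_evaluated"
        # and the exemption holds even in strict-missing mode
        _, strict_survivors = fcvpp_cascade([lof], {"GENE0001"}, "lof", CascadeConfig(strict_missing=True))
        assert strict_survivors == [lof]

    def test_conjunction_equals_intersection_of_stage_passes(self):
        mix = {"all_pass": 4, "fail_maf": 2, "fail_cadd": 2, "fail_conservation": 2, "fail_deleteriousness": 2}
        genes = ["G0"]
        variants, _ = gen_annotated_variants(12, mix, seed=33, genes=genes)
        _, survivors = fcvpp_cascade(variants, genes, "non_synonymous")
        stage_sets = []
        config = CascadeConfig()
        for check in (
            lambda v: maf_filter(v, config.maf_threshold) != "fail",
            lambda v: cadd_filter(v, config.cadd_threshold) != "fail",
            lambda v: conservation_vote(v, config)[2] != "fail",
            lambda v: deleteriousness_vote(v)[2] != "fail",
        ):
            stage_sets.append({v.key for v in variants if check(v)})
        expected = set.intersection(*stage_sets)
        assert {v.key for v in survivors} == expected

    def test_monotone_in_thresholds(self):
        variants, _ = gen_annotated_variants(
            30, {"all_pass": 10, "fail_cadd": 10, "fail_maf": 10}, seed=44, genes=["G0"]
        )
        sizes = []
        for cadd in (5.0, 10.0, 20.0, 30.0):
            _, survivors = fcvpp_cascade(variants, ["G0"], "non_synonymous", CascadeConfig(cadd_threshold=cadd))
            sizes.append(len(survivors))
        assert sizes == sorted(sizes, reverse=True)

    def test_strict_missing_mode_fails_unscored_variants(self):
        v = make_variant(maf_by_source={"local": 1e-4}, cadd_phred=None,
                         gerp=5.0, phastcons=0.9, phylop=5.0, predictor_calls=calls(8))
        _, lenient = fcvpp_cascade([v], {"GENE0001"}, "non_synonymous")
        _, strict = fcvpp_cascade([v], {"GENE0001"}, "non_synonymous", CascadeConfig(strict_missing=True))
        assert len(lenient) == 1 and len(strict) == 0
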