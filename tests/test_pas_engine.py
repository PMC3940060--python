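import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pathcloud import (
    MEAN_OF_OLD,
    GeneRole,
    GeneScore,
    PathwayCloud,
    PASProfile,
    RoleAnnotatedPathway,
    ScoringConfig,
    compute_btif,
    compute_disturbance,
    compute_gene_scores,
    compute_oyr,
    compute_pas,
    compute_spcd,
    score_study,
    young_reference,
)
from conftest import perturb_old


def scores_for(**kwargs):
    """Build a gene -> GeneScore map from gene=(oyr, btif) pairs."""
    return {
        gene: GeneScore(gene=gene, oyr=oyr, btif=btif,
                        deviation_sd=math.inf if btif else 0.0)
        for gene, (oyr, btif) in kwargs.items()
    }


class TestOyr:
    def test_divides_old_by_young_mean(self):
        assert compute_oyr(4.0, 2.0) == 2.0

    def test_equal_levels_give_unity(self):
        assert compute_oyr(3.7, 3.7) == 1.0

    def test_floor_keeps_ratio_positive(self):
        assert compute_oyr(0.0, 1.0, floor=1e-6) == 1e-6

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            compute_oyr(-1.0, 2.0)


class TestBtif:
    @pytest.mark.parametrize(
        "oyr, old, mean, sd, expected",
        [
            (2.0, 4.0, 2.0, 0.5, 1),   # both criteria met (4 SD out)
            (1.4, 4.0, 2.0, 0.1, 0),   # ratio within tolerance
            (2.0, 4.0, 2.0, 1.5, 0),   # only ~1.33 SD out: not simultaneous
            (1.5, 3.0, 2.0, 0.1, 0),   # boundary is strict: 3/2 is inside
        ],
    )
    def test_requires_both_criteria_simultaneously(self, oyr, old, mean, sd,
                                                   expected):
        assert compute_btif(oyr, old, mean, sd) == expected

    def test_lower_boundary_is_strict(self):
        assert compute_btif(2.0 / 3.0, 2.0, 3.0, 0.1) == 0
        assert compute_btif(0.66, 1.98, 3.0, 0.1) == 1

    def test_zero_sd_policy(self):
        # default: any deviation from a constant young cohort counts
        assert compute_btif(2.0, 4.0, 2.0, 0.0) == 1
        assert compute_btif(2.0, 4.0, 2.0, 0.0, zero_sd_policy="always_fail") == 0


class TestPas:
    def test_single_flagged_activator(self):
        pathway = RoleAnnotatedPathway("P", "p", (GeneRole("A", 1.0),))
        pas = compute_pas(pathway, scores_for(A=(10.0, 1)), log_base=10)
        assert pas == pytest.approx(1.0)

    def test_zero_when_nothing_beyond_tolerance(self):
        pathway = RoleAnnotatedPathway("P", "p", (
            GeneRole("A", 1.0), GeneRole("B", -1.0),
        ))
        pas = compute_pas(pathway, scores_for(A=(1.4, 0), B=(0.8, 0)))
        assert pas == 0.0

    def test_activator_and_repressor_cancel(self):
        pathway = RoleAnnotatedPathway("P", "p", (
            GeneRole("A", 1.0), GeneRole("B", -1.0),
        ))
        pas = compute_pas(pathway, scores_for(A=(10.0, 1), B=(10.0, 1)))
        assert pas == pytest.approx(0.0)

    def test_unmeasured_members_are_skipped(self):
        pathway = RoleAnnotatedPathway("P", "p", (
            GeneRole("A", 1.0), GeneRole("MISSING", -1.0),
        ))
        pas = compute_pas(pathway, scores_for(A=(10.0, 1)))
        assert pas == pytest.approx(1.0)

    def test_member_order_irrelevant(self):
        members = (GeneRole("A", 1.0), GeneRole("B", -0.5), GeneRole("C", 0.5))
        scores = scores_for(A=(3.0, 1), B=(0.2, 1), C=(5.0, 1))
        forward = compute_pas(
            RoleAnnotatedPathway("P", "p", members), scores)
        backward = compute_pas(
            RoleAnnotatedPathway("P", "p", members[::-1]), scores)
        assert forward == pytest.approx(backward)


class TestSpcd:
    def test_hand_example(self):
        assert compute_spcd([2.0, 3.0], [2.0]) == pytest.approx(3.0)

    def test_all_unit_levels(self):
        assert compute_spcd([1.0, 1.0], [1.0, 1.0, 1.0]) == pytest.approx(1.0)

    @given(
        activators=st.lists(st.floats(0.01, 100.0), min_size=1, max_size=8),
        repressors=st.lists(st.floats(0.01, 100.0), min_size=1, max_size=8),
    )
    def test_log_of_product_equals_sum_of_logs(self, activators, repressors):
        spcd = compute_spcd(activators, repressors)
        additive = (sum(math.log(a) for a in activators)
                    - sum(math.log(r) for r in repressors))
        assert math.log(spcd) == pytest.approx(additive, abs=1e-9)

    def test_matches_pas_with_unit_roles_and_forced_flags(self):
        # with ARR +/-1, natural log and every flag raised, PAS over OYR
        # values is exactly ln(SPCD of those OYR values)
        oyr_act, oyr_rep = [2.5, 0.3, 7.0], [1.2, 0.05]
        pathway = RoleAnnotatedPathway("P", "p", tuple(
            [GeneRole(f"A{i}", 1.0) for i in range(len(oyr_act))]
            + [GeneRole(f"R{j}", -1.0) for j in range(len(oyr_rep))]
        ))
        scores = {
            **{f"A{i}": GeneScore(f"A{i}", v, 1, math.inf)
               for i, v in enumerate(oyr_act)},
            **{f"R{j}": GeneScore(f"R{j}", v, 1, math.inf)
               for j, v in enumerate(oyr_rep)},
        }
        pas = compute_pas(pathway, scores, log_base=math.e)
        assert pas == pytest.approx(math.log(compute_spcd(oyr_act, oyr_rep)))


class TestDisturbance:
    def test_zero_profile(self):
        assert compute_disturbance([0.0, 0.0, 0.0]) == 0.0

    def test_l1_and_l2_hand_values(self):
        assert compute_disturbance([1.0, -2.0], norm="L1") == pytest.approx(3.0)
        assert compute_disturbance([3.0, 4.0], norm="L2") == pytest.approx(5.0)

    def test_unknown_norm_rejected(self):
        with pytest.raises(ValueError, match="unknown norm"):
            compute_disturbance([1.0], norm="L3")

    def test_accepts_profile_objects(self):
        profile = PASProfile("s", {"P1": 1.0, "P2": -2.0})
        assert compute_disturbance(profile, "L1") == pytest.approx(3.0)


class TestScoreStudy:
    def test_null_case_all_pas_zero(self, tiny_study, tiny_cloud):
        report = score_study(tiny_study, tiny_cloud)
        assert all(v == 0.0 for p in report.profiles for v in p.pas.values())
        assert report.mean_disturbance == 0.0

    def test_planted_activation_is_the_unique_signal(self, tiny_study,
                                                     tiny_cloud):
        # raise P1's activators 4x and drop its repressor 4x in old samples
        study = tiny_study
        for gene, factor in (("ACT1", 4.0), ("ACT2", 4.0), ("REP1", 0.25)):
            study = perturb_old(study, gene, factor)
        # young SD is 0 and old != mean, so flags are raised; expected PAS:
        # 1*log10(4) + 0.5*log10(4) + (-1)*log10(1/4) = 2.5*log10(4)
        report = score_study(study, tiny_cloud)
        assert report.mean_profile.pas["P1"] == pytest.approx(
            2.5 * math.log10(4.0))
        assert report.mean_profile.pas["P2"] == 0.0

    def test_identical_old_samples_share_the_mean_profile(self, tiny_study,
                                                          tiny_cloud):
        study = perturb_old(tiny_study, "ACT1", 3.0)
        report = score_study(study, tiny_cloud)
        first, second = report.profiles
        assert first.pas == second.pas == report.mean_profile.pas

    def test_sign_coherence_for_activators_and_repressors(self, tiny_study,
                                                          tiny_cloud):
        factors = [0.1, 0.3, 0.8, 1.0, 1.4, 1.6, 2.5, 6.0]
        act = [
            score_study(perturb_old(tiny_study, "ACT1", f), tiny_cloud)
            .mean_profile.pas["P1"]
            for f in factors
        ]
        rep = [
            score_study(perturb_old(tiny_study, "REP1", f), tiny_cloud)
            .mean_profile.pas["P1"]
            for f in factors
        ]
        assert act == sorted(act)          # raising an activator never lowers PAS
        assert rep == sorted(rep, reverse=True)

    def test_log_base_covariance(self, tiny_study, tiny_cloud):
        study = perturb_old(tiny_study, "ACT1", 5.0)
        base10 = score_study(study, tiny_cloud, ScoringConfig(log_base=10.0))
        base2 = score_study(study, tiny_cloud, ScoringConfig(log_base=2.0))
        for pid in tiny_cloud.pathway_ids:
            assert base2.mean_profile.pas[pid] == pytest.approx(
                base10.mean_profile.pas[pid] * math.log2(10.0), abs=1e-9)

    def test_unmeasured_pathway_flagged_and_skipped_counted(self, tiny_study):
        cloud = PathwayCloud(pathways=(
            RoleAnnotatedPathway("HERE", "h", (
                GeneRole("ACT1", 1.0), GeneRole("GHOST", 1.0))),
            RoleAnnotatedPathway("GONE", "g", (GeneRole("NOWHERE", 1.0),)),
        ))
        report = score_study(tiny_study, cloud)
        assert report.unmeasured_pathways == ("GONE",)
        assert report.skipped_genes == {"HERE": 1, "GONE": 1}
        assert report.mean_profile.pas["GONE"] == 0.0

    def test_empty_cloud_rejected(self, tiny_study):
        with pytest.raises(ValueError, match="nothing to score"):
            score_study(tiny_study, PathwayCloud(pathways=()))

    def test_gene_scores_match_scalar_definitions(self, tiny_study):
        study = perturb_old(tiny_study, "ACT1", 2.0)
        ref = young_reference(study)
        scores = compute_gene_scores(study.sample_values("O1"), ref)
        for i, gene in enumerate(study.genes):
            old = study.sample_values("O1")[i]
            expected_oyr = compute_oyr(old, ref.mean[i])
            assert scores[gene].oyr == pytest.approx(expected_oyr)
            assert scores[gene].btif == compute_btif(
                expected_oyr, old, ref.mean[i], ref.sd[i])
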