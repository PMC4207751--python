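"""Alignment, E-values, reciprocal validation, PSSM, iterative survey."""

import math

import numpy as np
import pytest

from acylscan.simulate import (
    FamilySpec,
    generate_decoys,
    generate_family,
    generate_survey_set,
    generate_two_step_scenario,
)
from acylscan.survey import (
    SurveyParams,
    best_hit,
    build_profile,
    iterative_survey,
    motif_evidence,
    reciprocal_validate,
    smith_waterman,
)
from _oracles import sw_oracle

PARAMS = SurveyParams()


class TestSmithWaterman:
    def test_self_alignment_sums_diagonal(self):
        result = smith_waterman("ACDEFG", "ACDEFG")
        assert result.score == 36  # 4 + 9 + 6 + 5 + 6 + 6
        assert result.identity == 1.0
        assert result.query_span == (0, 6)

    def test_all_negative_pairs_floor_at_zero(self):
        result = smith_waterman("KKKK", "PPPP")
        assert result.score == 0.0
        assert result.identity == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(10):
            a = "".join(rng.choice(aa, 30))
            b = "".join(rng.choice(aa, 40))
            assert (
                smith_waterman(a, b).score == smith_waterman(b, a).score
            )

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="standard"):
            smith_waterman("AC1", "ACD")

    def test_matches_exhaustive_enumeration_on_short_pairs(self):
        rng = np.random.default_rng(12)
        alphabet = np.array(list("ACDEG"))  # 5-letter alphabet
        for _ in range(150):
            la, lb = rng.integers(1, 9, 2)
            a = "".join(rng.choice(alphabet, la))
            b = "".join(rng.choice(alphabet, lb))
            assert smith_waterman(a, b).score == sw_oracle(a, b)


class TestBestHit:
    def test_identical_member_wins(self):
        proteome = dict(generate_decoys(20, (100, 200), seed=5))
        query = proteome["decoy_0003"]
        hit = best_hit(query, proteome)
        assert hit is not None and hit.subject_id == "decoy_0003"
        assert hit.identity == 1.0

    def test_all_decoy_proteome_returns_none(self):
        proteome = dict(generate_decoys(20, (300, 500), seed=6))
        query = "".join(
            np.random.default_rng(7).choice(
                list("ACDEFGHIKLMNPQRSTVWY"), 400
            )
        )
        assert best_hit(query, proteome) is None

    def test_tie_breaks_to_lexicographically_smaller_id(self):
        seq = "MKTLLVLAVCLAAASSTQG" * 10
        proteome = {"b_copy": seq, "a_copy": seq}
        hit = best_hit(seq, proteome)
        assert hit.subject_id == "a_copy"


class TestReciprocalValidate:
    def test_seed_itself_validates(self, profiles):
        records, _ = generate_family(
            FamilySpec(subclass="eGPAT", n=1, seed=15), profiles["eGPAT"]
        )
        seed_id, seed_seq = records[0]
        reference = dict(generate_decoys(30, (200, 400), seed=16))
        reference[seed_id] = seed_seq
        assert reciprocal_validate(seed_seq, reference, {seed_id})

    def test_decoy_copy_fails(self, profiles):
        records, _ = generate_family(
            FamilySpec(subclass="eGPAT", n=1, seed=15), profiles["eGPAT"]
        )
        seed_id, seed_seq = records[0]
        reference = dict(generate_decoys(30, (200, 400), seed=16))
        reference[seed_id] = seed_seq
        assert not reciprocal_validate(
            reference["decoy_0004"], reference, {seed_id}
        )

    def test_unknown_seed_ids_raise(self):
        with pytest.raises(ValueError, match="seed ids"):
            reciprocal_validate("ACDEF", {"x": "ACDEF"}, {"missing"})


class TestBuildProfile:
    def test_single_member_column_log_odds(self, profiles):
        prof = profiles["fGDPAT"]
        records, truth = generate_family(
            FamilySpec(subclass="fGDPAT", n=1, seed=44), prof
        )
        name, seq = records[0]
        pssm = build_profile({name: seq}, prof, pseudocount=0.5)
        row = truth.iloc[0]
        # the member's own motif-I first residue is H: with one sequence,
        # uniform background q = 1/20 and pseudocount a = 0.5 the column
        # log-odds is log2((1 + a q) / ((1 + 20 a) q))
        h_idx = "ACDEFGHIKLMNPQRSTVWY".index("H")
        expected = math.log2((1 + 0.5 * 0.05) / ((1 + 10) * 0.05))
        assert pssm.blocks[0][0, h_idx] == pytest.approx(expected)

    def test_duplicated_members_leave_profile_unchanged(self, profiles):
        prof = profiles["mitoGPAT"]
        records, _ = generate_family(
            FamilySpec(subclass="mitoGPAT", n=1, seed=45), prof
        )
        name, seq = records[0]
        one = build_profile({name: seq}, prof)
        three = build_profile(
            {f"{name}_{i}": seq for i in range(3)}, prof
        )
        for b1, b3 in zip(one.blocks, three.blocks):
            # frequencies are scale-free up to the pseudocount weight
            assert np.all(np.sign(b1) == np.sign(b3))
        assert one.score(seq) == pytest.approx(one.max_score)

    def test_member_without_chain_is_reported(self, profiles):
        prof = profiles["fGDPAT"]
        records, _ = generate_family(
            FamilySpec(subclass="fGDPAT", n=1, seed=46), prof
        )
        name, seq = records[0]
        with pytest.raises(ValueError, match="nochain"):
            build_profile({name: seq, "nochain": "A" * 200}, prof)

    def test_members_outscore_decoys(self, profiles):
        prof = profiles["DHAPAT"]
        records, _ = generate_family(
            FamilySpec(subclass="DHAPAT", n=5, seed=47), prof
        )
        pssm = build_profile(dict(records), prof)
        member_scores = [pssm.score(seq) for _, seq in records]
        decoy_scores = [
            pssm.score(seq)
            for _, seq in generate_decoys(20, (350, 650), seed=48)
        ]
        assert min(member_scores) > max(decoy_scores)


class TestMotifEvidence:
    def test_planted_member_has_informative_motifs(self, profiles):
        for sub, prof in profiles.items():
            records, _ = generate_family(
                FamilySpec(subclass=sub, n=2, seed=51), prof
            )
            for _, seq in records:
                assert motif_evidence(seq, prof) >= 2

    def test_decoys_rarely_show_informative_motifs(self, profiles):
        decoys = generate_decoys(30, (300, 600), seed=52)
        trials = [
            motif_evidence(seq, prof) > 0
            for _, seq in decoys
            for prof in profiles.values()
        ]
        # chance occurrences exist but must be rare; precision of the
        # survey comes from stacking this gate with the E-value screen
        # and reciprocal validation
        assert sum(trials) / len(trials) <= 0.02


class TestIterativeSurvey:
    def test_empty_plant_terminates_immediately(self, profiles):
        scenario = generate_survey_set(
            profiles, preset={"p1": {}, "p2": {}}, n_per_proteome=25,
            seed=60, n_reference_decoys=20,
        )
        # seeds must be supplied even when nothing is planted
        records, _ = generate_family(
            FamilySpec(subclass="eGPAT", n=1, seed=61), profiles["eGPAT"]
        )
        seeds = {"eGPAT": {"seed_eGPAT": records[0][1]}}
        reference = dict(scenario.reference)
        reference["seed_eGPAT"] = records[0][1]
        result = iterative_survey(
            scenario.proteomes, seeds, reference, profiles, PARAMS
        )
        assert result.iterations == 1
        assert result.additions.empty
        assert not result.presence.values.any()

    def test_monotone_validated_and_exact_recovery(self, profiles):
        plan = {
            "fungus": {"fGPAT-A": 1, "fGDPAT": 1},
            "animal": {"eGPAT": 1, "DHAPAT": 1},
            "empty": {},
        }
        scenario = generate_survey_set(
            profiles, preset=plan, n_per_proteome=40, seed=62,
            n_reference_decoys=40,
        )
        result = iterative_survey(
            scenario.proteomes, scenario.seeds, scenario.reference,
            profiles, PARAMS,
        )
        truth = scenario.truth_presence
        assert result.presence.loc[truth.index, truth.columns].equals(truth)
        planted = set(
            zip(scenario.truth_members.proteome, scenario.truth_members.id)
        )
        validated = {
            (pname, pid)
            for per in result.validated.values()
            for pname, ids in per.items()
            for pid in ids
        }
        assert validated == planted
        n_planted = len(planted)
        assert result.iterations <= n_planted + 1

    def test_two_step_member_found_in_second_iteration(self, profiles):
        scenario, meta = generate_two_step_scenario(profiles, seed=17)
        result = iterative_survey(
            scenario.proteomes, scenario.seeds, scenario.reference,
            profiles, PARAMS,
        )
        found_at = {
            row.protein_id: row.iteration
            for row in result.additions.itertuples()
        }
        assert found_at[meta["A"]] == 1
        assert found_at[meta["B"]] == 2
        assert len(found_at) == 2

    def test_missing_seed_in_reference_raises(self, profiles):
        with pytest.raises(ValueError, match="missing from reference"):
            iterative_survey(
                {"p": {"x": "ACDEF"}},
                {"eGPAT": {"s": "ACDEF"}},
                {"other": "ACDEF"},
                profiles,
                PARAMS,
            )
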