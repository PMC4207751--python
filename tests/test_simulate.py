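"""Synthetic-data generator: planted structure, noise model, scenarios."""

import pytest
from scipy import stats

from acylscan.scan import scan_chain
from acylscan.simulate import (
    FamilySpec,
    generate_decoys,
    generate_family,
    generate_survey_set,
)


class TestGenerateFamily:
    def test_fgpat_a_members_carry_the_invariant_motif_three(self, profiles):
        records, _ = generate_family(
            FamilySpec(subclass="fGPAT-A", n=20, seed=81),
            profiles["fGPAT-A"],
        )
        assert all("FPEGGSHD" in seq for _, seq in records)

    def test_spacings_sampled_within_profile_intervals(self, profiles):
        records, truth = generate_family(
            FamilySpec(subclass="eGPAT", n=30, seed=82), profiles["eGPAT"]
        )
        for k, (lo, hi) in enumerate(profiles["eGPAT"].dbm_ranges):
            assert truth[f"dbm_{k + 1}"].between(lo, hi).all()

    def test_same_seed_reproduces_identical_output(self, profiles):
        spec = FamilySpec(subclass="mitoGPAT", n=5, noise=0.05, seed=83)
        a, ta = generate_family(spec, profiles["mitoGPAT"])
        b, tb = generate_family(spec, profiles["mitoGPAT"])
        assert a == b
        assert ta.equals(tb)

    def test_rescan_recovers_planted_chain(self, profiles):
        for sub, prof in profiles.items():
            records, truth = generate_family(
                FamilySpec(subclass=sub, n=4, seed=84), prof
            )
            for (name, seq), (_, row) in zip(records, truth.iterrows()):
                found = scan_chain(seq, prof)
                assert found is not None, (sub, name)
                assert tuple(found.placements) == tuple(
                    (row[f"off_{lab}"], row[f"len_{lab}"])
                    for lab in ("I", "II", "III", "IV")
                )

    def test_noise_levels_apply_nested_corruption(self, profiles):
        spec_lo = FamilySpec(
            subclass="DHAPAT", n=5, noise=0.02, noise_mode="harsh", seed=85
        )
        spec_hi = FamilySpec(
            subclass="DHAPAT", n=5, noise=0.1, noise_mode="harsh", seed=85
        )
        lo, _ = generate_family(spec_lo, profiles["DHAPAT"])
        hi, _ = generate_family(spec_hi, profiles["DHAPAT"])
        base, _ = generate_family(
            FamilySpec(subclass="DHAPAT", n=5, seed=85), profiles["DHAPAT"]
        )
        for (_, s0), (_, s1), (_, s2) in zip(base, lo, hi):
            diff_lo = {i for i, (x, y) in enumerate(zip(s0, s1)) if x != y}
            diff_hi = {i for i, (x, y) in enumerate(zip(s0, s2)) if x != y}
            assert diff_lo <= diff_hi

    def test_conservative_noise_spares_hallmarks(self, profiles):
        prof = profiles["fGPAT-A"]
        records, truth = generate_family(
            FamilySpec(subclass="fGPAT-A", n=10, noise=0.3, seed=86), prof
        )
        for (_, seq), (_, row) in zip(records, truth.iterrows()):
            # motif I hallmarks: H first, D last
            off, length = int(row.off_I), int(row.len_I)
            assert seq[off] == "H" and seq[off + length - 1] == "D"

    def test_dbm_marginals_are_uniform(self, profiles):
        records, truth = generate_family(
            FamilySpec(subclass="eGPAT", n=2000, seed=87), profiles["eGPAT"]
        )
        lo, hi = profiles["eGPAT"].dbm_ranges[0]
        counts = truth["dbm_1"].value_counts()
        observed = [counts.get(v, 0) for v in range(lo, hi + 1)]
        _, p = stats.chisquare(observed)
        assert p > 0.01

    def test_undersized_length_range_rejected(self, profiles):
        with pytest.raises(ValueError, match="length range"):
            generate_family(
                FamilySpec(
                    subclass="fGPAT-A", n=1, length_range=(50, 100)
                ),
                profiles["fGPAT-A"],
            )


class TestGenerateDecoys:
    def test_uniform_composition_within_binomial_bounds(self):
        decoys = generate_decoys(250, (390, 410), seed=88)
        joined = "".join(seq for _, seq in decoys)
        n = len(joined)
        assert n >= 1e5
        p = 1 / 20
        sigma = (n * p * (1 - p)) ** 0.5
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            assert abs(joined.count(aa) - n * p) < 3.5 * sigma

    def test_reproducible_and_free_of_the_invariant_motif(self):
        a = generate_decoys(50, (200, 400), seed=89)
        b = generate_decoys(50, (200, 400), seed=89)
        assert a == b
        assert not any("FPEGGSHD" in seq for _, seq in a)


class TestGenerateSurveySet:
    def test_sack_like_preset_lacks_the_gdpat_branch(self, profiles):
        scenario = generate_survey_set(
            profiles, preset="sack_like", n_per_proteome=20, seed=90,
            n_reference_decoys=5,
        )
        truth = scenario.truth_presence
        for sub in ("mitoGPAT", "fGDPAT", "DHAPAT"):
            assert sub not in truth.index or not truth.loc[sub].any()
        assert truth.loc["fGPAT-A"].all()

    def test_single_isoform_preset_has_one_true_cell(self, profiles):
        scenario = generate_survey_set(
            profiles, preset="single_egpat", n_per_proteome=20, seed=91,
            n_reference_decoys=5,
        )
        assert scenario.truth_presence.values.sum() == 1

    def test_whole_scenario_is_seed_reproducible(self, profiles):
        a = generate_survey_set(
            profiles, preset="default", n_per_proteome=30, seed=92,
            n_reference_decoys=10,
        )
        b = generate_survey_set(
            profiles, preset="default", n_per_proteome=30, seed=92,
            n_reference_decoys=10,
        )
        assert a.proteomes == b.proteomes
        assert a.reference == b.reference
        assert a.truth_presence.equals(b.truth_presence)
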