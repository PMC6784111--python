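"""Germline scan, identity arithmetic, mismatch grouping, panel enumeration."""

import numpy as np
import pytest

from abframe.germline import (
    FrequencyProfile,
    MutationRegion,
    enumerate_variants,
    find_closest_germline,
    group_mismatches,
    percent_identity,
    positional_frequency,
)
from abframe.kabat import KabatPosition, NumberedSequence, assign_kabat_numbering

TABLE1_NAMES = ["DIQMAQ", "DIQMAQ-K", "EIVLAQ", "DIQMGQ", "DIQMAE",
                "EIVLGQ", "EIVLAE", "DIQMGE", "EIVLGE"]


def mutate(ns: NumberedSequence, changes: dict) -> NumberedSequence:
    residues = dict(ns.residues)
    for number, res in changes.items():
        residues[KabatPosition(ns.chain, number)] = res
    return NumberedSequence(ns.chain, residues, ns.source_id + "-mut")


class TestPercentIdentity:
    def test_identical_frameworks_are_100(self, parental_vl):
        assert percent_identity(parental_vl, parental_vl) == 100.0

    def test_five_framework_mismatches_give_92_86(self, parental_vl):
        other = mutate(parental_vl, {1: "E", 3: "V", 4: "L", 66: "G", 79: "E"})
        assert percent_identity(parental_vl, other) == pytest.approx(92.86, abs=0.005)

    def test_single_mismatch_is_69_of_70(self, parental_vl):
        other = mutate(parental_vl, {66: "G"})
        assert percent_identity(parental_vl, other) == pytest.approx(100 * 69 / 70)

    def test_symmetric(self, parental_vl, germline_set):
        for germ in germline_set:
            assert percent_identity(parental_vl, germ) == percent_identity(
                germ, parental_vl)

    def test_x_never_matches(self, parental_vl):
        other = mutate(parental_vl, {10: "X"})
        withx = mutate(parental_vl, {10: "X"})
        assert percent_identity(withx, other) < 100.0

    def test_disjoint_regions_error(self, parental_vl):
        fr_only = NumberedSequence("L", {
            p: r for p, r in parental_vl.residues.items() if p.number <= 23
        })
        with pytest.raises(ValueError):
            percent_identity(fr_only, parental_vl, regions=["FR2"])


class TestGermlineScan:
    def test_parental_maps_to_kv3_20_like_gene(self, germline_match):
        assert germline_match.germline_id == "KV3-20L"
        assert germline_match.framework_identity == pytest.approx(92.86, abs=0.005)
        mismatch_numbers = [p.number for p, _, _ in germline_match.mismatches]
        assert mismatch_numbers == [1, 3, 4, 66, 79]

    def test_exact_framework_match_has_no_mismatches(self, germline_set):
        query = germline_set[0]
        match = find_closest_germline(query, germline_set)
        assert match.germline_id == query.source_id
        assert match.framework_identity == 100.0
        assert match.mismatches == []

    def test_planted_closest_gene_wins(self, parental_vl, germline_set):
        # KV3-20L sits at 5 framework mismatches; every other gene is farther
        match = find_closest_germline(parental_vl, germline_set)
        others = [percent_identity(parental_vl, g) for g in germline_set
                  if g.source_id != match.germline_id]
        assert all(match.framework_identity > o for o in others)
        assert len(match.mismatches) == 5

    def test_framework_tie_broken_by_total_identity(self, parental_vl):
        tied_a = mutate(parental_vl, {66: "G"})
        tied_a.source_id = "tied-a"
        tied_b = mutate(parental_vl, {66: "G", 91: "A"})  # CDR-L3 difference
        tied_b.source_id = "tied-b"
        match = find_closest_germline(parental_vl, [tied_b, tied_a])
        assert match.germline_id == "tied-a"


@pytest.fixture(scope="module")
def profile(parental_vl):
    # 200 sequences; 122 carry G at Kabat 66, 78 carry A
    seqs = []
    for i in range(200):
        res = "G" if i < 122 else "A"
        seqs.append(mutate(parental_vl, {66: res}))
    return FrequencyProfile.from_sequences(seqs)


class TestFrequencyProfile:
    def test_planted_frequency_is_61_percent(self, profile):
        pos = KabatPosition("L", 66)
        assert positional_frequency(profile, pos, "G") == pytest.approx(61.0)

    def test_absent_residue_is_zero(self, profile):
        assert positional_frequency(profile, KabatPosition("L", 66), "W") == 0.0

    def test_frequencies_sum_to_100(self, profile):
        pos = KabatPosition("L", 66)
        total = sum(positional_frequency(profile, pos, aa)
                    for aa in "ACDEFGHIKLMNPQRSTVWY")
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_unknown_position_errors(self, profile):
        with pytest.raises(KeyError):
            positional_frequency(profile, KabatPosition("L", 106, "a"), "G")


class TestGroupMismatches:
    def test_paper_pattern_gives_three_regions(self, germline_match,
                                               parental_vl, germline_set):
        germ = next(g for g in germline_set
                    if g.source_id == germline_match.germline_id)
        regions = group_mismatches(germline_match.mismatches,
                                   query=parental_vl, germline=germ)
        assert [r.label for r in regions] == ["1-4", "66", "79"]
        assert regions[0].parental_residues == "DIQM"
        assert regions[0].germline_residues == "EIVL"

    def test_single_mismatch_is_singleton(self):
        mm = [(KabatPosition("L", 66), "A", "G")]
        regions = group_mismatches(mm)
        assert len(regions) == 1 and regions[0].label == "66"

    def test_distant_mismatches_stay_separate(self):
        mm = [(KabatPosition("L", 10), "A", "S"), (KabatPosition("L", 30), "S", "N")]
        assert [r.label for r in group_mismatches(mm)] == ["10", "30"]


class TestEnumerateVariants:
    def test_table1_panel_of_nine(self, parental_vl, mutation_regions):
        panel = enumerate_variants(parental_vl, mutation_regions,
                                   include_lysine_parental=True)
        assert panel.names() == TABLE1_NAMES
        assert [v.id for v in panel.variants] == list(range(1, 10))
        assert panel.variants[1].c_terminal_lysine

    def test_parental_combination_is_unchanged(self, parental_vl, mutation_regions):
        panel = enumerate_variants(parental_vl, mutation_regions)
        assert panel.variants[0].sequence.sequence == parental_vl.sequence

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_panel_size_is_2_to_k(self, parental_vl, k):
        # k well-separated singleton framework regions
        numbers = [5, 15, 40, 60][:k]
        regions = [
            MutationRegion(str(n), [KabatPosition("L", n)],
                           parental_vl.residues[KabatPosition("L", n)], "A")
            for n in numbers
        ]
        panel = enumerate_variants(parental_vl, regions)
        assert len(panel.variants) == 2 ** k
        assert len(set(panel.names())) == 2 ** k

    def test_more_than_12_regions_rejected(self, parental_vl):
        regions = [
            MutationRegion(str(n), [KabatPosition("L", n)], "Q", "A")
            for n in range(5, 18)
        ]
        with pytest.raises(ValueError, match="12"):
            enumerate_variants(parental_vl, regions)

    def test_germlining_never_decreases_framework_identity(
            self, parental_vl, mutation_regions, germline_set, germline_match):
        germ = next(g for g in germline_set
                    if g.source_id == germline_match.germline_id)
        panel = enumerate_variants(parental_vl, mutation_regions)
        base = percent_identity(parental_vl, germ)
        for variant in panel.variants:
            assert percent_identity(variant.sequence, germ) >= base

    def test_full_germlining_clears_mismatch_list(
            self, parental_vl, mutation_regions, germline_set):
        panel = enumerate_variants(parental_vl, mutation_regions)
        full = panel.get("EIVLGE")
        match = find_closest_germline(full.sequence, germline_set)
        assert match.framework_identity == 100.0
        assert match.mismatches == []
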