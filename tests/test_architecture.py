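"""Domain category assignment, architecture statistics, physchem panel."""

import pytest

from sublyme import (
    DomainHit,
    ProteinRecord,
    architecture_string,
    assign_segment_categories,
    default_domain_dictionary,
    domain_frequency_table,
    filter_by_confidence,
    modularity_histogram,
    physchem,
    positional_stats,
    simulate_segments_and_hits,
)
from sublyme.architecture import (
    CBD,
    EAD,
    UNKNOWN,
    ArchitectureProfile,
    DomainDictionary,
    DomainSegment,
)


def _segment(pid="p", index=1, start=1, end=150):
    return DomainSegment(pid, index, start, end)


def _hit(acc, e, start=10, end=140, pid="p"):
    return DomainHit(pid, "Pfam", acc, acc, start, end, e)


DICT = DomainDictionary(
    {"PF01510": EAD, "PF01464": EAD, "PF01471": CBD, "PF08460": CBD}
)


class TestCategoryAssignment:
    def test_strong_ead_hit_labels_segment(self):
        (seg,) = assign_segment_categories(
            [_segment()], [_hit("PF01510", 2e-30)], DICT
        )
        assert seg.category == EAD
        assert seg.best_accession == "PF01510"

    def test_hit_above_evalue_cutoff_discarded(self):
        (seg,) = assign_segment_categories([_segment()], [_hit("PF01510", 1e-2)], DICT)
        assert seg.category == UNKNOWN

    def test_cutoff_is_strict_less_than(self):
        (at,) = assign_segment_categories([_segment()], [_hit("PF01510", 1e-3)], DICT)
        (below,) = assign_segment_categories(
            [_segment()], [_hit("PF01510", 0.99e-3)], DICT
        )
        assert at.category == UNKNOWN
        assert below.category == EAD

    def test_missing_evalue_discarded(self):
        (seg,) = assign_segment_categories([_segment()], [_hit("PF01510", None)], DICT)
        assert seg.category == UNKNOWN

    def test_lowest_evalue_dictionary_hit_wins(self):
        hits = [_hit("PF01471", 1e-20), _hit("PF01510", 1e-5)]
        (seg,) = assign_segment_categories([_segment()], hits, DICT)
        assert seg.category == CBD

    def test_dictionary_absent_hit_leaves_unknown_but_recorded(self):
        (seg,) = assign_segment_categories([_segment()], [_hit("PF99999", 1e-30)], DICT)
        assert seg.category == UNKNOWN
        assert seg.best_accession == "PF99999"

    def test_hit_attributed_by_midpoint_containment(self):
        segments = [_segment(index=1, start=1, end=100), _segment(index=2, start=101, end=200)]
        # interval [90, 160] has midpoint 125 -> second segment
        hits = [_hit("PF01471", 1e-10, start=90, end=160)]
        first, second = assign_segment_categories(segments, hits, DICT)
        assert first.category == UNKNOWN
        assert second.category == CBD

    def test_orphan_hit_warns_and_is_unassigned(self):
        with pytest.warns(UserWarning, match="no segment"):
            (seg,) = assign_segment_categories(
                [_segment(start=1, end=50)], [_hit("PF01510", 1e-10, 200, 300)], DICT
            )
        assert seg.category == UNKNOWN

    def test_every_segment_gets_exactly_one_category(self):
        segments, hits, _ = simulate_segments_and_hits(seed=0)
        labelled = assign_segment_categories(segments, hits)
        assert len(labelled) == len(segments)
        assert all(s.category in (EAD, CBD, "MISC", UNKNOWN) for s in labelled)


class TestArchitectureProfiles:
    def test_ead_cbd_bimodular_string(self):
        segs = [
            DomainSegment("p", 1, 1, 100, category=EAD),
            DomainSegment("p", 2, 110, 200, category=CBD),
        ]
        prof = architecture_string(segs)
        assert prof.architecture == "EAD-CBD"
        assert prof.modularity == 2
        assert prof.has_lysin_domain and not prof.all_unknown

    def test_hexamodular_worked_example(self):
        segments, hits, expected = simulate_segments_and_hits(seed=1)
        labelled = assign_segment_categories(segments, hits)
        hexa = [s for s in labelled if s.protein_id == "hexa_1G20T"]
        prof = architecture_string(hexa)
        assert prof.modularity == 6
        counts = {c: prof.categories.count(c) for c in set(prof.categories)}
        assert counts == {EAD: 3, CBD: 1, UNKNOWN: 2}
        assert prof == expected["hexa_1G20T"]

    def test_single_unknown_segment_is_globular_all_unknown(self):
        prof = architecture_string([DomainSegment("p", 1, 1, 100)])
        assert prof.architecture == "UNKNOWN"
        assert prof.is_globular and prof.all_unknown

    def test_simulated_fixtures_match_their_ground_truth(self):
        segments, hits, expected = simulate_segments_and_hits(seed=5)
        labelled = assign_segment_categories(segments, hits)
        by_protein = {}
        for s in labelled:
            by_protein.setdefault(s.protein_id, []).append(s)
        for pid, segs in by_protein.items():
            assert architecture_string(segs) == expected[pid]


class TestModularityHistogram:
    def _profile(self, pid, cats):
        return ArchitectureProfile(pid, tuple(cats), True, False)

    def test_bins_and_total_conservation(self):
        profiles = [
            self._profile("a", [EAD]),
            self._profile("b", [EAD]),
            self._profile("c", [EAD, CBD]),
            self._profile("d", [EAD] * 6),
        ]
        bins = modularity_histogram(profiles)
        assert bins == {"1": 2, "2": 1, "3": 0, "4": 0, ">=5": 1}
        assert sum(bins.values()) == len(profiles)

    def test_empty_input_gives_zero_bins(self):
        assert sum(modularity_histogram([]).values()) == 0

    def test_hexamodular_example_lands_in_top_bin(self):
        segments, hits, _ = simulate_segments_and_hits(seed=2)
        labelled = assign_segment_categories(segments, hits)
        hexa = [s for s in labelled if s.protein_id == "hexa_1G20T"]
        bins = modularity_histogram([architecture_string(hexa)])
        assert bins[">=5"] == 1


class TestPositionalStats:
    def _profiles(self, archs):
        return [
            ArchitectureProfile(f"p{i}", tuple(a.split("-")), True, False)
            for i, a in enumerate(archs)
        ]

    def test_hand_counted_fractions(self):
        profiles = self._profiles(
            ["EAD-CBD", "EAD-UNKNOWN", "UNKNOWN-CBD", "UNKNOWN-UNKNOWN"]
        )
        stats = positional_stats(profiles)
        assert stats["ead_nterm"] == 0.5
        assert stats["cbd_cterm"] == 0.5
        assert stats["ead_cterm"] == 0.0
        assert stats["cbd_nterm"] == 0.0

    def test_uniform_ead_cbd(self):
        stats = positional_stats(self._profiles(["EAD-CBD"] * 3))
        assert stats["ead_nterm"] == 1.0 and stats["cbd_cterm"] == 1.0

    def test_non_bimodular_profiles_ignored(self):
        profiles = self._profiles(["EAD-CBD"]) + [
            ArchitectureProfile("g", (EAD,), True, False)
        ]
        assert positional_stats(profiles)["n_bimodular"] == 1

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError, match="empty stratum"):
            positional_stats([ArchitectureProfile("g", (EAD,), True, False)])


class TestDomainFrequency:
    def test_repeated_copies_each_count(self):
        segs = [
            DomainSegment("p", 1, 1, 100, category=EAD, best_accession="PF05838"),
            DomainSegment("p", 2, 110, 180, category=CBD, best_accession="PF01471"),
            DomainSegment("p", 3, 190, 260, category=CBD, best_accession="PF01471"),
        ]
        profiles = [ArchitectureProfile("p", (EAD, CBD, CBD), True, False)]
        counts = domain_frequency_table(segs, profiles)
        assert counts[("PF01471", "modular")] == 2
        assert counts[("PF05838", "modular")] == 1

    def test_globular_vs_modular_context_split(self):
        segs = [
            DomainSegment("g", 1, 1, 100, category=EAD, best_accession="PF01464"),
            DomainSegment("m", 1, 1, 100, category=EAD, best_accession="PF01464"),
            DomainSegment("m", 2, 110, 200, category=CBD, best_accession="PF01471"),
        ]
        profiles = [
            ArchitectureProfile("g", (EAD,), True, False),
            ArchitectureProfile("m", (EAD, CBD), True, False),
        ]
        counts = domain_frequency_table(segs, profiles)
        assert counts[("PF01464", "globular")] == 1
        assert counts[("PF01464", "modular")] == 1

    def test_fixture_tally_matches_brute_force(self):
        segments, hits, _ = simulate_segments_and_hits(seed=3)
        labelled = assign_segment_categories(segments, hits)
        by_protein = {}
        for s in labelled:
            by_protein.setdefault(s.protein_id, []).append(s)
        profiles = [architecture_string(v) for v in by_protein.values()]
        counts = domain_frequency_table(labelled, profiles)
        # brute force: count labelled segments directly
        expected = {}
        modularity = {p.protein_id: p.modularity for p in profiles}
        for s in labelled:
            if s.best_accession is not None:
                ctx = "globular" if modularity[s.protein_id] == 1 else "modular"
                expected[(s.best_accession, ctx)] = (
                    expected.get((s.best_accession, ctx), 0) + 1
                )
        assert counts == expected

    def test_empty_input(self):
        assert domain_frequency_table([], []) == {}


class TestConfidenceFilter:
    def test_strict_cutoff_semantics(self):
        scores = {"at": 70.0, "above": 90.0, "below": 50.0}
        assert filter_by_confidence(scores) == {"above"}

    def test_empty_mapping(self):
        assert filter_by_confidence({}) == set()


class TestPhyschem:
    def test_glycine_free_amino_acid_weight(self):
        rec = physchem(ProteinRecord("g", "G"))
        assert rec.molecular_weight == pytest.approx(75.07, abs=0.01)

    def test_gravy_endpoints_of_kyte_doolittle_scale(self):
        assert physchem(ProteinRecord("i", "I")).gravy == pytest.approx(4.5)
        assert physchem(ProteinRecord("r", "R")).gravy == pytest.approx(-4.5)

    def test_dipeptide_weight_is_residue_sum_minus_water(self):
        # G (75.07) + A (89.09) - H2O (18.02) ~ 146.14
        rec = physchem(ProteinRecord("ga", "GA"))
        assert rec.molecular_weight == pytest.approx(146.14, abs=0.02)

    def test_ambiguous_residue_rejected_with_position(self):
        with pytest.raises(ValueError, match=r"\[3\]"):
            physchem(ProteinRecord("x", "MKXL"))

    def test_gravy_within_scale_bounds(self):
        rec = physchem(ProteinRecord("p", "MKLVVAGEWRND"))
        assert -4.5 <= rec.gravy <= 4.5


def test_packaged_dictionary_covers_canonical_lysin_domains():
    d = default_domain_dictionary()
    assert d.category_of("PF01510") == EAD  # Ami2
    assert d.category_of("PF01464") == EAD  # SLT
    assert d.category_of("PF01471") == CBD  # PG1
    assert d.category_of("PF09374") == CBD  # PG3
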