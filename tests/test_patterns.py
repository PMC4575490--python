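import pandas as pd
import pytest

from titrabench.annotation import generate_annotation
from titrabench.patterns import (
    align_genes_across_platforms,
    assign_transcript_sets,
    derive_transcript_patterns,
    filter_ambiguous_probes,
    map_exons_to_patterns,
)
from titrabench.simulate import PROBE_COLUMNS, PlatformSpec, generate_platform_probes


def _probe_row(pid, chrom, start, end, gene="", cls="unique_full", platform="p"):
    return [pid, platform, chrom, start, end, gene, cls]


class TestAmbiguityFilter:
    def test_all_unique_retained(self):
        df = pd.DataFrame(
            [_probe_row(f"p{i}", "chr1", i * 100, i * 100 + 50) for i in range(5)],
            columns=PROBE_COLUMNS,
        )
        assert len(filter_ambiguous_probes(df)) == 5

    def test_multi_hit_probe_excluded(self):
        df = pd.DataFrame(
            [
                _probe_row("p1", "chr1", 0, 50, cls="multiple"),
                _probe_row("p1", "chr2", 0, 50, cls="multiple"),
                _probe_row("p2", "chr1", 100, 150),
            ],
            columns=PROBE_COLUMNS,
        )
        kept = filter_ambiguous_probes(df)
        assert set(kept["probe_id"]) == {"p2"}

    def test_mixed_toy_counts(self):
        rows = (
            [_probe_row(f"u{i}", "chr1", i * 100, i * 100 + 50) for i in range(5)]
            + [_probe_row(f"m{i}", "chr1", 0, 50, cls="multiple") for i in range(3)]
            + [_probe_row(f"q{i}", "chr1", 0, 50, cls="partial") for i in range(2)]
        )
        kept = filter_ambiguous_probes(pd.DataFrame(rows, columns=PROBE_COLUMNS))
        assert len(kept) == 5

    def test_empty_input(self):
        empty = pd.DataFrame(columns=PROBE_COLUMNS)
        assert filter_ambiguous_probes(empty).empty


class TestTranscriptAssignment:
    def test_demo_gene_region_targets_planted_set(self, demo):
        """A probe in the exon shared by four of the five isoforms maps to
        exactly those four transcripts."""
        ann, _, _ = demo
        # E2 belongs to T001, T003, T004, T005
        df = pd.DataFrame([_probe_row("x", "chr1", 2050, 2100, "DEMO1")],
                          columns=PROBE_COLUMNS)
        targets = assign_transcript_sets(df, ann)
        assert targets["x"].transcripts == frozenset(
            {"DEMO1.T001", "DEMO1.T003", "DEMO1.T004", "DEMO1.T005"}
        )

    def test_intronic_probe_dropped(self, demo):
        ann, _, _ = demo
        df = pd.DataFrame([_probe_row("x", "chr1", 1500, 1550)], columns=PROBE_COLUMNS)
        assert assign_transcript_sets(df, ann) == {}

    def test_partially_overlapping_probe_dropped(self, demo):
        """Containment, not overlap: a probe straddling an exon edge maps
        to nothing."""
        ann, _, _ = demo
        df = pd.DataFrame([_probe_row("x", "chr1", 1150, 1250)], columns=PROBE_COLUMNS)
        assert assign_transcript_sets(df, ann) == {}

    def test_common_exon_gives_full_transcript_set(self, demo):
        ann, _, _ = demo
        df = pd.DataFrame([_probe_row("x", "chr1", 1050, 1100)], columns=PROBE_COLUMNS)
        targets = assign_transcript_sets(df, ann)
        assert targets["x"].transcripts == frozenset(ann.genes["DEMO1"].transcripts)

    def test_unknown_chromosome_raises(self, demo):
        ann, _, _ = demo
        df = pd.DataFrame([_probe_row("x", "chrZ", 0, 50)], columns=PROBE_COLUMNS)
        with pytest.raises(ValueError, match="chromosome"):
            assign_transcript_sets(df, ann)


def _brute_force_patterns(maps, platforms):
    """Independent oracle: exhaustive intersection over (gene, set) pairs."""
    per_platform = []
    for p in platforms:
        seen = set()
        for target in maps[p].values():
            seen.add((target.gene_id, target.transcripts))
        per_platform.append(seen)
    return set.intersection(*per_platform)


class TestPatternDerivation:
    def test_demo_gene_yields_exactly_two_common_patterns(self, demo):
        ann, probes, expected = demo
        maps = {p: assign_transcript_sets(t, ann) for p, t in probes.items()}
        patterns = derive_transcript_patterns(maps)
        assert {p.transcript_set for p in patterns} == expected
        assert all(p.gene_id == "DEMO1" for p in patterns)
        # every platform contributes a member feature to each pattern
        for p in patterns:
            assert set(p.members) == set(probes)

    def test_disjoint_platform_sets_give_no_patterns(self, demo):
        ann, _, _ = demo
        a = pd.DataFrame([_probe_row("a", "chr1", 3050, 3100, platform="pa")],
                         columns=PROBE_COLUMNS)  # E3 -> {T002,T003}
        b = pd.DataFrame([_probe_row("b", "chr1", 5050, 5100, platform="pb")],
                         columns=PROBE_COLUMNS)  # E5 -> {T004,T005}
        maps = {
            "pa": assign_transcript_sets(a, ann),
            "pb": assign_transcript_sets(b, ann),
        }
        assert derive_transcript_patterns(maps) == []

    def test_matches_brute_force_on_random_genes(self):
        """50 random multi-isoform genes, 3 platforms: derived patterns
        equal the exhaustive (gene, transcript-set) intersection."""
        ann = generate_annotation(50, seed=13)
        maps = {}
        for i, name in enumerate(["pa", "pb", "pc"]):
            spec = PlatformSpec(name, probes_per_gene=2)
            probes = generate_platform_probes(ann, spec, seed=100 + i)
            maps[name] = assign_transcript_sets(probes, ann)
        derived = derive_transcript_patterns(maps)
        got = {(p.gene_id, p.transcript_set) for p in derived}
        assert got == _brute_force_patterns(maps, ["pa", "pb", "pc"])

    def test_adding_required_platform_never_adds_patterns(self):
        ann = generate_annotation(30, seed=17)
        maps = {}
        for i, name in enumerate(["pa", "pb", "pc", "pd"]):
            spec = PlatformSpec(name, probes_per_gene=2)
            maps[name] = assign_transcript_sets(
                generate_platform_probes(ann, spec, seed=50 + i), ann
            )
        n2 = len(derive_transcript_patterns(maps, ["pa", "pb"]))
        n3 = len(derive_transcript_patterns(maps, ["pa", "pb", "pc"]))
        n4 = len(derive_transcript_patterns(maps, ["pa", "pb", "pc", "pd"]))
        assert n2 >= n3 >= n4

    def test_member_features_are_disjoint_across_patterns(self, demo):
        ann, probes, _ = demo
        maps = {p: assign_transcript_sets(t, ann) for p, t in probes.items()}
        patterns = derive_transcript_patterns(maps)
        for platform in probes:
            seen = set()
            for p in patterns:
                feats = set(p.members[platform])
                assert not feats & seen
                seen |= feats

    def test_requires_two_platforms(self, demo):
        ann, probes, _ = demo
        maps = {"P1": assign_transcript_sets(probes["P1"], ann)}
        with pytest.raises(ValueError, match="2 platforms"):
            derive_transcript_patterns(maps)
        with pytest.raises(ValueError, match="missing"):
            derive_transcript_patterns(maps | {"P2": {}}, ["P1", "P9"])


class TestExonPatternMapping:
    def test_demo_exons_map_to_their_patterns(self, demo):
        ann, probes, _ = demo
        maps = {p: assign_transcript_sets(t, ann) for p, t in probes.items()}
        patterns = derive_transcript_patterns(maps)
        exon_map = map_exons_to_patterns(ann, patterns)
        by_set = {p.transcript_set: p.pattern_id for p in patterns}
        assert exon_map["DEMO1.E3"] == by_set[frozenset({"DEMO1.T002", "DEMO1.T003"})]
        assert exon_map["DEMO1.E5"] == by_set[frozenset({"DEMO1.T004", "DEMO1.T005"})]
        # E1/E6 carry the full transcript set, which is not a common pattern
        assert "DEMO1.E1" not in exon_map and "DEMO1.E6" not in exon_map

    def test_agrees_with_per_exon_set_comparison(self):
        ann = generate_annotation(25, seed=19)
        maps = {}
        for i, name in enumerate(["pa", "pb"]):
            spec = PlatformSpec(name, probes_per_gene=3)
            maps[name] = assign_transcript_sets(
                generate_platform_probes(ann, spec, seed=70 + i), ann
            )
        patterns = derive_transcript_patterns(maps)
        exon_map = map_exons_to_patterns(ann, patterns)
        by_key = {(p.gene_id, p.transcript_set): p.pattern_id for p in patterns}
        for exon_id, exon in ann.exons.items():
            key = (exon.gene_id, ann.transcripts_containing_exon(exon_id))
            assert exon_map.get(exon_id) == by_key.get(key)


class TestGeneAlignment:
    @pytest.mark.parametrize(
        "lists, expected",
        [
            ({"a": ["g1", "g2"], "b": ["g1", "g2"]}, {"g1", "g2"}),
            ({"a": ["g1"], "b": ["g2"]}, set()),
            ({"a": ["g1", "g2", "g3"], "b": ["g2", "g3"], "c": ["g3", "g4"]}, {"g3"}),
        ],
    )
    def test_intersection(self, lists, expected):
        assert align_genes_across_platforms(lists) == expected

    def test_random_lists_match_fold_oracle(self):
        import random

        rng = random.Random(5)
        universe = [f"g{i}" for i in range(40)]
        lists = {p: rng.sample(universe, 25) for p in "abcd"}
        oracle = set(universe)
        for v in lists.values():
            oracle &= set(v)
        assert align_genes_across_platforms(lists) == oracle
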