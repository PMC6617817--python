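import numpy as np
import pytest

from ucekit.design_compare import (
    GOOD,
    PROBLEM_BETWEEN,
    PROBLEM_WITHIN,
    UNSHARED,
    build_optimized_subset,
    classify_loci,
    cross_match,
    good_in_all_taxa,
    score_base_genomes,
)
from ucekit.seq_formats import LocusSequence, ProbeRecord


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mono(entries):
    return [LocusSequence(l, t, s) for l, t, s in entries]


@pytest.fixture
def loci_seqs(rng):
    return {f"uce-{i}": _random_seq(rng, 600) for i in range(1, 6)}


def _clean_designs(loci_seqs, taxa=("ta", "tb")):
    """Two designs carrying identical copies of every locus for every taxon."""
    designs = {}
    for d in ("A", "B"):
        entries = []
        for locus, seq in loci_seqs.items():
            for t in taxa:
                entries.append((locus, t, seq))
        designs[d] = _mono(entries)
    return designs


class TestCrossMatch:
    def test_identical_monolithics_all_single_self_matches(self, loci_seqs):
        graph = cross_match(_clean_designs(loci_seqs), identity=99)
        for (da, la, taxon, db), matched in graph.matches.items():
            assert matched == {la}

    def test_needs_two_designs(self, loci_seqs):
        with pytest.raises(ValueError):
            cross_match({"A": _mono([("uce-1", "t", "ACGT" * 100)])})

    def test_taxon_in_one_design_excluded(self, loci_seqs):
        designs = _clean_designs(loci_seqs)
        designs["A"].append(LocusSequence("uce-1", "only_in_A", "ACGT" * 100))
        graph = cross_match(designs, identity=99)
        assert graph.excluded_taxa == ["only_in_A"]
        assert not any(t == "only_in_A" for (_, _, t, _) in graph.matches)

    def test_duplicate_in_one_design_multimatches(self, loci_seqs):
        designs = _clean_designs(loci_seqs)
        # B carries a second near-identical copy of uce-1 for taxon ta
        designs["B"].append(LocusSequence("uce-99", "ta", loci_seqs["uce-1"]))
        graph = cross_match(designs, identity=99)
        assert graph.matches[("A", "uce-1", "ta", "B")] == {"uce-1", "uce-99"}

    def test_disjoint_locus_sets_no_matches(self, rng):
        designs = {
            "A": _mono([("uce-1", "t", _random_seq(rng, 500))]),
            "B": _mono([("uce-2", "t", _random_seq(rng, 500))]),
        }
        graph = cross_match(designs, identity=95)
        assert graph.matches == {}

    def test_coverage_floor_blocks_fragment_matches(self, rng):
        shared = _random_seq(rng, 200)
        designs = {
            "A": _mono([("uce-1", "t", shared + _random_seq(rng, 800))]),
            "B": _mono([("uce-2", "t", shared)]),
        }
        # fragment covers 200/1000 of A's locus but 100% of B's (the shorter)
        graph = cross_match(designs, identity=99, coverage_floor=50)
        assert graph.matches.get(("A", "uce-1", "t", "B")) == {"uce-2"}
        graph2 = cross_match(designs, identity=99, coverage_floor=150)
        assert ("A", "uce-1", "t", "B") not in graph2.matches


class TestClassifyLoci:
    def _labels(self, designs, identity=99):
        graph = cross_match(designs, identity=identity)
        return graph, classify_loci(graph)

    def test_clean_all_good(self, loci_seqs):
        _, classes = self._labels(_clean_designs(loci_seqs))
        shared = [c for c in classes if c.label != UNSHARED]
        assert shared and all(c.label == GOOD for c in classes)

    def test_lineage_specific_duplication_between(self, loci_seqs):
        designs = _clean_designs(loci_seqs)
        designs["B"].append(LocusSequence("uce-99", "ta", loci_seqs["uce-1"]))
        _, classes = self._labels(designs)
        by_label = {}
        for c in classes:
            by_label.setdefault(c.label, []).append(c)
        assert len(by_label[PROBLEM_BETWEEN]) == 1
        members = {l for (_, l, _) in by_label[PROBLEM_BETWEEN][0].members}
        assert members == {"uce-1", "uce-99"}
        assert len(by_label[GOOD]) == len(loci_seqs) - 1

    def test_split_locus_within(self, loci_seqs, rng):
        full = _random_seq(rng, 800)
        designs = {
            "A": _mono([("uce-1", t, full) for t in ("ta", "tb")]),
            "B": _mono(
                [("uce-10", t, full[:400]) for t in ("ta", "tb")]
                + [("uce-11", t, full[400:]) for t in ("ta", "tb")]
            ),
        }
        _, classes = self._labels(designs)
        labels = {c.label for c in classes}
        assert labels == {PROBLEM_WITHIN}

    def test_unshared(self, rng):
        designs = {
            "A": _mono([("uce-1", "t", _random_seq(rng, 500))]),
            "B": _mono([("uce-2", "t", _random_seq(rng, 500))]),
        }
        _, classes = self._labels(designs, identity=95)
        assert {c.label for c in classes} == {UNSHARED}

    def test_labels_partition(self, loci_seqs, rng):
        designs = _clean_designs(loci_seqs)
        designs["B"].append(LocusSequence("uce-99", "ta", loci_seqs["uce-1"]))
        designs["A"].append(LocusSequence("uce-50", "ta", _random_seq(rng, 500)))
        _, classes = self._labels(designs)
        seen = set()
        for c in classes:
            assert c.label in (GOOD, PROBLEM_WITHIN, PROBLEM_BETWEEN, UNSHARED)
            for m in c.members:
                assert m not in seen
                seen.add(m)

    def test_symmetric_in_design_order(self, loci_seqs):
        designs = _clean_designs(loci_seqs)
        designs["B"].append(LocusSequence("uce-99", "ta", loci_seqs["uce-1"]))
        _, classes_ab = self._labels(dict(designs))
        _, classes_ba = self._labels(dict(reversed(designs.items())))

        def label_map(classes):
            return {
                frozenset(l for (_, l, _) in c.members): c.label for c in classes
            }

        assert label_map(classes_ab) == label_map(classes_ba)


class TestScoreBaseGenomes:
    def test_two_identical_designs_tie(self, loci_seqs):
        graph = cross_match(_clean_designs(loci_seqs), identity=99)
        scores = score_base_genomes(classify_loci(graph), graph)
        assert scores[0].total_good == scores[1].total_good
        assert scores[0].longest_tally == scores[1].longest_tally

    def test_longer_flanks_win_length_tally(self, loci_seqs, rng):
        designs = {"A": [], "B": []}
        for locus, seq in loci_seqs.items():
            for t in ("ta", "tb"):
                designs["A"].append(LocusSequence(locus, t, seq))
                designs["B"].append(
                    LocusSequence(locus, t, _random_seq(rng, 50) + seq + _random_seq(rng, 50))
                )
        graph = cross_match(designs, identity=95)
        scores = score_base_genomes(classify_loci(graph), graph)
        best = scores[0]
        assert best.design == "B"
        assert best.longest_tally == len(loci_seqs) * 2  # every locus, every taxon
        other = scores[1]
        assert other.longest_tally == 0

    def test_good_in_all_taxa_subset(self, loci_seqs):
        designs = _clean_designs(loci_seqs)
        # uce-2 present only in taxon ta for design A and B
        for d in designs:
            designs[d] = [
                r for r in designs[d] if not (r.locus_id == "uce-2" and r.taxon == "tb")
            ]
        graph = cross_match(designs, identity=99)
        classes = classify_loci(graph)
        full = good_in_all_taxa(classes, ["ta", "tb"])
        loci = {l for c in full for (_, l, _) in c.members}
        assert "uce-2" not in loci


class TestBuildOptimizedSubset:
    def _probes(self, locus_ids, tag="opt"):
        return [
            ProbeRecord("ACGT" * 30, lid, 1, "tx", tag) for lid in locus_ids
        ]

    def test_no_legacy(self):
        final, mapping = build_optimized_subset(
            self._probes(["uce-1", "uce-2", "uce-3"]), {"uce-1", "uce-3"}
        )
        assert sorted(p.locus_id for p in final) == ["uce-1", "uce-3"]
        assert mapping == {}

    def test_disjoint_legacy_additive(self):
        final, mapping = build_optimized_subset(
            self._probes(["uce-1", "uce-2"]),
            {"uce-1", "uce-2"},
            legacy_probes=self._probes(["uce-100", "uce-101"], tag="old"),
        )
        assert len(final) == 4
        assert mapping == {}
        legacy = [p for p in final if p.design_tag.startswith("legacy")]
        assert len(legacy) == 2
        assert all("old" in p.design_tag for p in legacy)

    def test_collision_renumbered_deterministically(self):
        final, mapping = build_optimized_subset(
            self._probes(["uce-1", "uce-5"]),
            {"uce-1", "uce-5"},
            legacy_probes=self._probes(["uce-1"], tag="old"),
        )
        assert mapping == {"uce-1": "uce-6"}
        ids = sorted(p.locus_id for p in final)
        assert ids == ["uce-1", "uce-5", "uce-6"]

    def test_uncovered_good_locus_excluded(self):
        final, _ = build_optimized_subset(
            self._probes(["uce-1"]), {"uce-1", "uce-9"}
        )
        assert {p.locus_id for p in final} == {"uce-1"}
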