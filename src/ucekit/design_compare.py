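"""Cross-design locus matching, good/problematic classification, scoring,
and construction of the final optimized probe subset.

Monolithic locus files from different designs (different base genomes or
stringencies) are matched per taxon at high identity. A locus cluster is

* ``good`` when every taxon sees it as single-copy in every design pair,
* ``problematic-within`` when every matched taxon shows multi-matching
  (e.g., one region carried as two ids by one design),
* ``problematic-between`` when some taxa are single-copy but at least one
  other taxon multi-matches (lineage-specific paralogy),
* ``unshared`` when it never matches across two designs for any taxon.

"Single match" = exactly one hit at/above the identity threshold covering
at least half of the shorter sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .local_align import get_index, seed_extend_search
from .seq_formats import GenomeAssembly, LocusSequence, ProbeRecord

__all__ = [
    "MatchGraph",
    "LocusClassification",
    "BaseGenomeScore",
    "cross_match",
    "classify_loci",
    "score_base_genomes",
    "build_optimized_subset",
    "GOOD",
    "PROBLEM_WITHIN",
    "PROBLEM_BETWEEN",
    "UNSHARED",
]

GOOD = "good"
PROBLEM_WITHIN = "problematic-within"
PROBLEM_BETWEEN = "problematic-between"
UNSHARED = "unshared"


@dataclass
class MatchGraph:
    designs: list[str]
    # (designA, locusA, taxon, designB) -> set of locusB matched
    matches: dict[tuple[str, str, str, str], set[str]] = field(default_factory=dict)
    # every (design, locus, taxon) present in the monolithics
    members: set[tuple[str, str, str]] = field(default_factory=set)
    lengths: dict[tuple[str, str, str], int] = field(default_factory=dict)
    excluded_taxa: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def cross_match(
    monolithics: Mapping[str, Sequence[LocusSequence]],
    identity: float = 99.0,
    coverage_floor: float = 50.0,
    seed_length: int = 12,
) -> MatchGraph:
    """Match loci between designs, per taxon, per ordered design pair.

    A hit counts when alignment identity >= *identity* and the aligned span
    covers >= *coverage_floor* percent of the shorter of the two sequences.
    Taxa present in fewer than two designs are excluded and logged in
    ``excluded_taxa``. Reciprocality is not required (flagged in metadata).
    """
    designs = list(monolithics)
    if len(designs) < 2:
        raise ValueError("cross_match: need >= 2 designs")
    graph = MatchGraph(designs=designs)
    graph.metadata = {
        "identity": identity,
        "coverage_floor_pct_of_shorter": coverage_floor,
        "reciprocal": False,
    }
    by_design_taxon: dict[str, dict[str, dict[str, str]]] = {}
    taxa_seen: dict[str, set[str]] = {}
    for design, records in monolithics.items():
        per_taxon: dict[str, dict[str, str]] = {}
        for rec in records:
            per_taxon.setdefault(rec.taxon, {})[rec.locus_id] = rec.sequence
            graph.members.add((design, rec.locus_id, rec.taxon))
            graph.lengths[(design, rec.locus_id, rec.taxon)] = len(rec.sequence)
            taxa_seen.setdefault(rec.taxon, set()).add(design)
        by_design_taxon[design] = per_taxon

    shared_taxa = sorted(t for t, ds in taxa_seen.items() if len(ds) >= 2)
    graph.excluded_taxa = sorted(t for t, ds in taxa_seen.items() if len(ds) < 2)

    for taxon in shared_taxa:
        # one pseudo-assembly per design holding that taxon's loci as contigs
        targets = {
            design: GenomeAssembly(f"{design}:{taxon}", dict(loci))
            for design, per_taxon in by_design_taxon.items()
            if (loci := per_taxon.get(taxon))
        }
        indexes = {d: get_index(a, seed_length) for d, a in targets.items()}
        for da in targets:
            for db in targets:
                if da == db:
                    continue
                for locus_a, seq_a in by_design_taxon[da][taxon].items():
                    hits = seed_extend_search(
                        seq_a,
                        targets[db],
                        min_identity=identity,
                        min_coverage=0.0,
                        seed_length=seed_length,
                        query_id=locus_a,
                        index=indexes[db],
                    )
                    matched: set[str] = set()
                    for h in hits:
                        len_b = targets[db].length(h.contig)
                        shorter = min(len(seq_a), len_b)
                        if len(h.interval) >= coverage_floor / 100.0 * shorter:
                            matched.add(h.contig)
                    if matched:
                        graph.matches[(da, locus_a, taxon, db)] = matched
    return graph


@dataclass
class LocusClassification:
    cluster_id: int
    members: list[tuple[str, str, str]]  # (design, locus, taxon)
    label: str


def classify_loci(graph: MatchGraph) -> list[LocusClassification]:
    """Cluster loci by transitive closure of single matches and label them."""
    nodes = {(d, l) for (d, l, t) in graph.members}
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    # any match (single or multi) links loci into one cluster
    for (da, la, taxon, db), matched in graph.matches.items():
        for lb in matched:
            if (db, lb) in parent:
                union((da, la), (db, lb))

    clusters: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for n in nodes:
        clusters.setdefault(find(n), []).append(n)

    # taxon-level copy status within each cluster
    out: list[LocusClassification] = []
    for cid, (root, cluster_nodes) in enumerate(sorted(clusters.items())):
        node_set = set(cluster_nodes)
        members = sorted(
            (d, l, t) for (d, l, t) in graph.members if (d, l) in node_set
        )
        taxa = {t for (_, _, t) in members}
        matched_taxa: set[str] = set()
        multi_taxa: set[str] = set()
        for (da, la, taxon, db), matched in graph.matches.items():
            if (da, la) not in node_set:
                continue
            matched_taxa.add(taxon)
            if len(matched) >= 2:
                multi_taxa.add(taxon)
        # two distinct loci of one design for one taxon inside a cluster is
        # itself within-taxon multiplicity
        per_design_taxon: dict[tuple[str, str], int] = {}
        for d, l, t in members:
            per_design_taxon[(d, t)] = per_design_taxon.get((d, t), 0) + 1
        for (d, t), count in per_design_taxon.items():
            if count >= 2 and t in matched_taxa:
                multi_taxa.add(t)

        if not matched_taxa:
            label = UNSHARED
        elif not multi_taxa:
            label = GOOD
        elif matched_taxa - multi_taxa:
            label = PROBLEM_BETWEEN
        else:
            label = PROBLEM_WITHIN
        out.append(LocusClassification(cid, members, label))
    return out


@dataclass
class BaseGenomeScore:
    design: str
    good_per_taxon: dict[str, int]
    longest_tally: int  # taxa-slots where this design had the (tied-)longest sequence

    @property
    def total_good(self) -> int:
        return sum(self.good_per_taxon.values())


def good_in_all_taxa(
    classifications: Sequence[LocusClassification], all_taxa: Sequence[str]
) -> list[LocusClassification]:
    full = set(all_taxa)
    return [
        c
        for c in classifications
        if c.label == GOOD and {t for (_, _, t) in c.members} >= full
    ]


def score_base_genomes(
    classifications: Sequence[LocusClassification],
    graph: MatchGraph,
    all_taxa: Sequence[str] | None = None,
) -> list[BaseGenomeScore]:
    """Good-locus counts per taxon and longest-sequence tallies per design.

    The longest-sequence tally runs over clusters good in *all* taxa: for
    each taxon, every design whose sequence length is maximal (ties award
    all tied designs) gains one tally point.
    """
    taxa = (
        list(all_taxa)
        if all_taxa is not None
        else sorted({t for (_, _, t) in graph.members})
    )
    good = [c for c in classifications if c.label == GOOD]
    good_per: dict[str, dict[str, int]] = {d: {t: 0 for t in taxa} for d in graph.designs}
    for c in good:
        for d, l, t in c.members:
            if t in good_per[d]:
                good_per[d][t] += 1
    tally = {d: 0 for d in graph.designs}
    for c in good_in_all_taxa(classifications, taxa):
        for taxon in taxa:
            lengths = {
                d: graph.lengths[(d, l, t)]
                for (d, l, t) in c.members
                if t == taxon
            }
            if not lengths:
                continue
            longest = max(lengths.values())
            for d, ln in lengths.items():
                if ln == longest:
                    tally[d] += 1
    return sorted(
        (
            BaseGenomeScore(d, good_per[d], tally[d])
            for d in graph.designs
        ),
        key=lambda s: (-s.total_good, -s.longest_tally, s.design),
    )


def build_optimized_subset(
    optimized_probes: Sequence[ProbeRecord],
    good_all_taxa_loci: set[str],
    legacy_probes: Sequence[ProbeRecord] = (),
    legacy_tag: str = "legacy",
) -> tuple[list[ProbeRecord], dict[str, str]]:
    """Filter the optimized design to good-in-all-taxa loci and merge legacy.

    Keeps optimized probes whose locus is both good-in-all-taxa and covered
    by the design, then appends legacy probes. Legacy locus ids colliding
    with kept ids are renumbered deterministically past the highest kept
    number; the returned mapping records every renaming. Legacy provenance
    is preserved in the design-tag.
    """
    kept = [p for p in optimized_probes if p.locus_id in good_all_taxa_loci]
    kept_ids = {p.locus_id for p in kept}
    mapping: dict[str, str] = {}
    if legacy_probes:
        numbers = [
            int(l.rpartition("-")[2]) for l in kept_ids if l.rpartition("-")[2].isdigit()
        ]
        next_num = (max(numbers) + 1) if numbers else 1
        legacy_ids = sorted(
            {p.locus_id for p in legacy_probes},
            key=lambda l: (
                l.rpartition("-")[0],
                int(l.rpartition("-")[2]) if l.rpartition("-")[2].isdigit() else 0,
            ),
        )
        for lid in legacy_ids:
            if lid in kept_ids:
                prefix = lid.rpartition("-")[0] or "uce"
                mapping[lid] = f"{prefix}-{next_num}"
                next_num += 1
            else:
                mapping[lid] = lid
        for p in legacy_probes:
            new_id = mapping[p.locus_id]
            tag = f"{legacy_tag}:{p.design_tag}" if p.design_tag else legacy_tag
            kept.append(
                ProbeRecord(
                    sequence=p.sequence,
                    locus_id=new_id,
                    probe_index=p.probe_index,
                    source_taxon=p.source_taxon,
                    design_tag=tag,
                    extra=p.extra,
                )
            )
    return kept, {k: v for k, v in mapping.items() if k != v}
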