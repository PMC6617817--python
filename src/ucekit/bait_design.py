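"""Temporary-bait tiling, bait filtering, candidate loci, and final probes.

The design chain: putative loci on the base genome are tiled with
fixed-length temporary baits at a configurable offset (default 120-mers
every 60 bp = 2x density, plus a right-aligned terminal bait so every locus
base is covered). Baits are filtered on GC / ambiguity / masking, aligned
back to every assembly, and a locus becomes a *candidate* in a taxon iff at
least one of its baits hits uniquely there and none hits as a duplicate.
Final probes are re-tiled from each taxon's own sequence at its best-hit
interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .conservation import SharedLocusTable, masked_fraction, merge_intervals
from .local_align import (
    DEFAULT_MIN_COVERAGE,
    DEFAULT_MIN_IDENTITY,
    DEFAULT_SEED_LENGTH,
    DEFAULT_TOP_DELTA,
    AlignmentHit,
    classify_multiplicity,
    get_index,
    seed_extend_search,
)
from .seq_formats import GenomeAssembly, Interval, ProbeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TilingScheme",
    "MatchThresholds",
    "CandidateLocus",
    "CandidateLocusTable",
    "tile_starts",
    "tile_baits",
    "filter_baits",
    "candidate_loci",
    "design_final_probes",
]


@dataclass(frozen=True)
class TilingScheme:
    probe_length: int = 120
    offset: int = 60

    def __post_init__(self) -> None:
        if not (0 < self.offset <= self.probe_length):
            raise ValueError("offset must satisfy 0 < offset <= probe_length")


@dataclass(frozen=True)
class MatchThresholds:
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_coverage: float = DEFAULT_MIN_COVERAGE
    seed_length: int = DEFAULT_SEED_LENGTH
    top_delta: float = DEFAULT_TOP_DELTA


def tile_starts(length: int, scheme: TilingScheme) -> list[int]:
    """Bait start offsets: 0, offset, ... plus a right-aligned terminal start."""
    if length < scheme.probe_length:
        return []
    starts = list(range(0, length - scheme.probe_length + 1, scheme.offset))
    if starts[-1] + scheme.probe_length < length:
        starts.append(length - scheme.probe_length)
    return starts


def tile_baits(
    locus_id: str,
    interval: Interval,
    assembly: GenomeAssembly,
    scheme: TilingScheme = TilingScheme(),
    design_tag: str = "baits",
) -> list[ProbeRecord]:
    """Tile temporary baits over one locus interval of the base genome."""
    seq = assembly.slice(interval)
    starts = tile_starts(len(seq), scheme)
    if not starts:
        logger.info(
            "locus %s shorter than probe length (%d < %d): skipped",
            locus_id,
            len(seq),
            scheme.probe_length,
        )
        return []
    return [
        ProbeRecord(
            sequence=seq[s : s + scheme.probe_length],
            locus_id=locus_id,
            probe_index=i + 1,
            source_taxon=assembly.taxon,
            design_tag=design_tag,
        )
        for i, s in enumerate(starts)
    ]


def tile_putative_loci(
    table: SharedLocusTable,
    assembly: GenomeAssembly,
    scheme: TilingScheme = TilingScheme(),
    design_tag: str = "baits",
) -> list[ProbeRecord]:
    baits: list[ProbeRecord] = []
    for locus in table:
        baits.extend(tile_baits(locus.locus_id, locus.interval, assembly, scheme, design_tag))
    return baits


def filter_baits(
    baits: Sequence[ProbeRecord],
    gc_min: float = 25.0,
    gc_max: float = 70.0,
    max_ambiguous: int = 0,
    max_masked_fraction: float = 0.25,
) -> tuple[list[ProbeRecord], list[tuple[ProbeRecord, str]]]:
    """Split baits into (kept, rejected-with-first-failing-reason), order kept."""
    kept: list[ProbeRecord] = []
    rejected: list[tuple[ProbeRecord, str]] = []
    for bait in baits:
        s = bait.sequence.upper()
        n_ambig = s.count("N")
        acgt = len(s) - n_ambig
        gc = 100.0 * (s.count("G") + s.count("C")) / acgt if acgt else 0.0
        reason = None
        if n_ambig > max_ambiguous:
            reason = f"ambiguous:{n_ambig}>{max_ambiguous}"
        elif acgt == 0:
            reason = "all-ambiguous"
        elif gc < gc_min:
            reason = f"gc-low:{gc:.2f}<{gc_min}"
        elif gc > gc_max:
            reason = f"gc-high:{gc:.2f}>{gc_max}"
        elif masked_fraction(bait.sequence) > max_masked_fraction:
            reason = f"masked:{masked_fraction(bait.sequence):.2f}>{max_masked_fraction}"
        if reason is None:
            kept.append(bait)
        else:
            rejected.append((bait, reason))
    return kept, rejected


@dataclass
class CandidateLocus:
    locus_id: str
    taxa: set[str] = field(default_factory=set)  # taxa where baits matched uniquely
    best_hit: dict[str, Interval] = field(default_factory=dict)
    hit_strand: dict[str, str] = field(default_factory=dict)


@dataclass
class CandidateLocusTable:
    loci: dict[str, CandidateLocus] = field(default_factory=dict)
    collapsed: dict[str, str] = field(default_factory=dict)  # dropped id -> kept id

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci.values())


def _locus_sort_key(locus_id: str) -> tuple:
    prefix, _, num = locus_id.rpartition("-")
    return (prefix, int(num)) if num.isdigit() else (locus_id, 0)


def candidate_loci(
    baits: Sequence[ProbeRecord],
    assemblies: Mapping[str, GenomeAssembly],
    thresholds: MatchThresholds = MatchThresholds(),
    required_taxa: int = 1,
) -> CandidateLocusTable:
    """Align baits to every assembly and keep consistently-unique loci.

    A locus qualifies in a taxon iff >= 1 of its baits classifies as unique
    and none classifies as duplicate there. Loci whose baits hit overlapping
    target intervals in any taxon are collapsed onto the lower locus id.
    Returns loci qualifying in >= *required_taxa* taxa.
    """
    by_locus: dict[str, list[ProbeRecord]] = {}
    for b in baits:
        by_locus.setdefault(b.locus_id, []).append(b)

    # locus -> taxon -> (qualified, merged unique-hit span, strand)
    locus_taxa: dict[str, dict[str, tuple[Interval, str]]] = {l: {} for l in by_locus}
    # for collapse detection: taxon -> list of (locus, merged span)
    spans_per_taxon: dict[str, list[tuple[str, Interval]]] = {t: [] for t in assemblies}

    for taxon, asm in assemblies.items():
        index = get_index(asm, thresholds.seed_length)
        for locus_id, lbaits in by_locus.items():
            unique_hits: list[AlignmentHit] = []
            has_duplicate = False
            for bait in lbaits:
                hits = seed_extend_search(
                    bait.sequence,
                    asm,
                    min_identity=thresholds.min_identity,
                    min_coverage=thresholds.min_coverage,
                    seed_length=thresholds.seed_length,
                    query_id=bait.probe_id,
                    index=index,
                )
                state = classify_multiplicity(hits, thresholds.top_delta)
                if state == "duplicate":
                    has_duplicate = True
                    break
                if state == "unique":
                    unique_hits.append(hits[0])
            if has_duplicate or not unique_hits:
                continue
            merged = merge_intervals([h.interval for h in unique_hits])
            # span = merged region containing the highest-scoring hit
            best = max(unique_hits, key=lambda h: h.score)
            span = next(
                m
                for m in merged
                if m.contig == best.contig and m.overlap(best.interval) > 0
            )
            strand = best.strand
            locus_taxa[locus_id][taxon] = (span, strand)
            spans_per_taxon[taxon].append((locus_id, span))

    # Collapse loci whose spans overlap within any taxon (keep lowest id).
    parent: dict[str, str] = {l: l for l in by_locus}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra == rb:
            return
        keep, drop = sorted((ra, rb), key=_locus_sort_key)
        parent[drop] = keep

    for taxon, spans in spans_per_taxon.items():
        spans.sort(key=lambda x: (x[1].contig, x[1].start))
        for i in range(1, len(spans)):
            prev_l, prev_s = spans[i - 1]
            cur_l, cur_s = spans[i]
            if prev_l != cur_l and prev_s.overlap(cur_s) > 0:
                union(prev_l, cur_l)

    table = CandidateLocusTable()
    groups: dict[str, list[str]] = {}
    for locus_id in by_locus:
        groups.setdefault(find(locus_id), []).append(locus_id)
    for rep, members in sorted(groups.items(), key=lambda kv: _locus_sort_key(kv[0])):
        cl = CandidateLocus(rep)
        for member in sorted(members, key=_locus_sort_key):
            if member != rep:
                table.collapsed[member] = rep
            for taxon, (span, strand) in locus_taxa[member].items():
                if taxon not in cl.taxa:
                    cl.taxa.add(taxon)
                    cl.best_hit[taxon] = span
                    cl.hit_strand[taxon] = strand
        if len(cl.taxa) >= required_taxa:
            table.loci[rep] = cl
    return table


def design_final_probes(
    table: CandidateLocusTable,
    assemblies: Mapping[str, GenomeAssembly],
    scheme: TilingScheme = TilingScheme(),
    design_tag: str = "optimized",
) -> list[ProbeRecord]:
    """Per-taxon probes re-tiled from each taxon's own best-hit sequence.

    Identical sequences arising in several taxa collapse to one probe whose
    ``probes-source`` lists every contributing taxon joined with '+'.
    """
    probes: list[ProbeRecord] = []
    for locus in sorted(table, key=lambda l: _locus_sort_key(l.locus_id)):
        seen: dict[str, list[str]] = {}  # sequence -> taxa (insertion-ordered)
        order: list[str] = []
        for taxon in sorted(locus.taxa):
            iv = locus.best_hit[taxon]
            strand = locus.hit_strand.get(taxon, "+")
            seq = assemblies[taxon].slice(
                Interval(iv.contig, iv.start, iv.end, strand)
            ).upper()
            starts = tile_starts(len(seq), scheme)
            if not starts:
                logger.info(
                    "locus %s: hit interval in %s shorter than probe length; no probe",
                    locus.locus_id,
                    taxon,
                )
                continue
            for s in starts:
                tile = seq[s : s + scheme.probe_length]
                if tile not in seen:
                    seen[tile] = []
                    order.append(tile)
                if taxon not in seen[tile]:
                    seen[tile].append(taxon)
        for i, tile in enumerate(order, 1):
            probes.append(
                ProbeRecord(
                    sequence=tile,
                    locus_id=locus.locus_id,
                    probe_index=i,
                    source_taxon="+".join(seen[tile]),
                    design_tag=design_tag,
                )
            )
    return probes
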