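"""In silico capture test: match probes to assemblies and extract loci + flanks."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .local_align import (
    AlignmentHit,
    get_index,
    seed_extend_search,
)
from .bait_design import MatchThresholds
from .seq_formats import GenomeAssembly, Interval, LocusSequence, ProbeRecord

__all__ = [
    "RecoveryMatrix",
    "insilico_test",
    "completeness_filter",
    "recovery_summary",
]

RECOVERED = "recovered"
ABSENT = "absent"
DUPLICATE = "duplicate-removed"

# Pooled probe hits within this gap belong to one capture region.
_REGION_GAP = 300


@dataclass
class RecoveryMatrix:
    taxa: list[str]
    loci: list[str]
    status: dict[tuple[str, str], str] = field(default_factory=dict)  # (taxon, locus)
    length: dict[tuple[str, str], int] = field(default_factory=dict)

    def get(self, taxon: str, locus: str) -> str:
        return self.status.get((taxon, locus), ABSENT)

    def recovered_loci(self, taxon: str) -> list[str]:
        return [l for l in self.loci if self.get(taxon, l) == RECOVERED]

    def to_rows(self) -> list[dict]:
        rows = []
        for locus in self.loci:
            row: dict = {"locus": locus}
            for taxon in self.taxa:
                row[taxon] = self.get(taxon, locus)
                row[f"{taxon}_len"] = self.length.get((taxon, locus), 0)
            rows.append(row)
        return rows


def _cluster_regions(hits: Sequence[AlignmentHit]) -> list[list[AlignmentHit]]:
    """Group hits into capture regions: same contig, gap <= _REGION_GAP."""
    regions: list[list[AlignmentHit]] = []
    for h in sorted(hits, key=lambda h: (h.contig, h.interval.start)):
        if (
            regions
            and regions[-1][-1].contig == h.contig
            and h.interval.start - max(x.interval.end for x in regions[-1]) <= _REGION_GAP
        ):
            regions[-1].append(h)
        else:
            regions.append([h])
    return regions


def insilico_test(
    probes: Sequence[ProbeRecord],
    assemblies: Mapping[str, GenomeAssembly],
    thresholds: MatchThresholds = MatchThresholds(),
    flank: int = 400,
) -> tuple[RecoveryMatrix, list[LocusSequence]]:
    """Capture each locus's probes against every assembly.

    Per (locus, taxon): all probe hits are pooled and clustered into capture
    regions; >= 2 regions scoring within ``top_delta`` percent of the best
    region means potential paralogy -> ``duplicate-removed``. A single
    winning region is extracted as the union of its hit intervals +- *flank*
    (clipped at contig ends), reverse-complemented when the region's
    score-weighted strand is minus. The monolithic record list contains
    exactly the recovered cells.
    """
    if not probes:
        raise ValueError("insilico_test: empty probe set")
    by_locus: dict[str, list[ProbeRecord]] = {}
    for p in probes:
        by_locus.setdefault(p.locus_id, []).append(p)
    loci = sorted(by_locus, key=_locus_key)
    taxa = list(assemblies)
    matrix = RecoveryMatrix(taxa=taxa, loci=loci)
    monolithic: list[LocusSequence] = []

    for taxon, asm in assemblies.items():
        index = get_index(asm, thresholds.seed_length)
        for locus_id in loci:
            # identical probe sequences only need one search
            unique_seqs = {p.sequence.upper() for p in by_locus[locus_id]}
            pooled: list[AlignmentHit] = []
            for seq in sorted(unique_seqs):
                pooled.extend(
                    seed_extend_search(
                        seq,
                        asm,
                        min_identity=thresholds.min_identity,
                        min_coverage=thresholds.min_coverage,
                        seed_length=thresholds.seed_length,
                        query_id=locus_id,
                        index=index,
                    )
                )
            if not pooled:
                matrix.status[(taxon, locus_id)] = ABSENT
                continue
            regions = _cluster_regions(pooled)
            region_scores = [max(h.score for h in r) for r in regions]
            best_score = max(region_scores)
            cutoff = best_score * (1.0 - thresholds.top_delta / 100.0)
            top = [r for r, s in zip(regions, region_scores) if s >= cutoff]
            if len(top) >= 2:
                matrix.status[(taxon, locus_id)] = DUPLICATE
                continue
            region = max(regions, key=lambda r: max(h.score for h in r))
            contig = region[0].contig
            start = min(h.interval.start for h in region)
            end = max(h.interval.end for h in region)
            start = max(0, start - flank)
            end = min(asm.length(contig), end + flank)
            minus = sum(h.score for h in region if h.strand == "-")
            plus = sum(h.score for h in region if h.strand == "+")
            strand = "-" if minus > plus else "+"
            seq = asm.slice(Interval(contig, start, end, strand)).upper()
            matrix.status[(taxon, locus_id)] = RECOVERED
            matrix.length[(taxon, locus_id)] = len(seq)
            monolithic.append(LocusSequence(locus_id, taxon, seq))
    return matrix, monolithic


def _locus_key(locus_id: str) -> tuple:
    prefix, _, num = locus_id.rpartition("-")
    return (prefix, int(num)) if num.isdigit() else (locus_id, 0)


def completeness_filter(matrix: RecoveryMatrix, min_fraction: float) -> list[str]:
    """Loci recovered in >= ceil(min_fraction * T) taxa."""
    need = math.ceil(min_fraction * len(matrix.taxa))
    return [
        locus
        for locus in matrix.loci
        if sum(matrix.get(t, locus) == RECOVERED for t in matrix.taxa) >= need
    ]


def recovery_summary(matrix: RecoveryMatrix) -> dict:
    """Per-taxon recovered counts plus the union count across taxa."""
    per_taxon = {t: len(matrix.recovered_loci(t)) for t in matrix.taxa}
    union = {
        locus
        for locus in matrix.loci
        if any(matrix.get(t, locus) == RECOVERED for t in matrix.taxa)
    }
    return {"per_taxon": per_taxon, "union": len(union), "union_loci": sorted(union, key=_locus_key)}
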