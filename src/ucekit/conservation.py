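"""Interval algebra and putative-locus detection.

A *putative locus* is a merged region of the base genome overlapped by
mapped intervals from at least ``k`` non-base taxa. ``k`` is the sharing
stringency: ``k=1`` is the least stringent design, ``k=T-1`` the most.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .seq_formats import FormatError, GenomeAssembly, Interval

__all__ = [
    "StringencyK",
    "SharedLocus",
    "SharedLocusTable",
    "merge_intervals",
    "strip_masked",
    "masked_fraction",
    "putative_loci",
]


@dataclass(frozen=True)
class StringencyK:
    """Number of non-base taxa a putative locus must be shared with."""

    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"stringency k must be >= 1, got {self.k}")


@dataclass
class SharedLocus:
    locus_id: str
    interval: Interval
    support: frozenset[str]  # taxa whose mapped intervals overlap; includes base


@dataclass
class SharedLocusTable:
    base_taxon: str
    loci: dict[str, SharedLocus] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci.values())

    def intervals(self) -> list[Interval]:
        return [l.interval for l in self.loci.values()]


def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Minimal disjoint cover of the same bases, sorted by (contig, start).

    Half-open adjacency merges: [0,10) + [10,20) -> [0,20). Strand is
    dropped (merged regions are strandless, reported as '+').
    """
    merged: list[Interval] = []
    by_contig: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append(iv)
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(Interval(contig, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(Interval(contig, cur_start, cur_end))
    return merged


def masked_fraction(seq: str) -> float:
    """Fraction of soft-masked (lowercase) or N bases."""
    masked = sum(1 for b in seq if b.islower() or b in "Nn")
    return masked / len(seq) if seq else 0.0


def strip_masked(
    intervals: Sequence[Interval],
    assembly: GenomeAssembly,
    max_masked_fraction: float,
) -> list[Interval]:
    """Drop intervals whose soft-masked + N fraction exceeds the threshold."""
    kept = []
    for iv in intervals:
        if iv.contig not in assembly:
            raise FormatError(f"strip_masked: unknown contig {iv.contig!r}")
        if masked_fraction(assembly.contigs[iv.contig][iv.start : iv.end]) <= max_masked_fraction:
            kept.append(iv)
    return kept


def putative_loci(
    base: str,
    mapped: Mapping[str, Sequence[Interval]],
    k: StringencyK | int,
    min_length: int = 80,
    min_overlap: int = 1,
    base_assembly: GenomeAssembly | None = None,
    locus_prefix: str = "uce",
) -> SharedLocusTable:
    """Detect conserved regions shared by the base genome and >= k other taxa.

    *mapped* maps each non-base taxon to its read-mapping intervals on base
    contigs (assumed de-duplicated upstream). All taxa's intervals are merged
    into candidate regions; a taxon supports a region iff its intervals
    intersect it by at least *min_overlap* bp. Regions of length >=
    *min_length* with >= k supporting non-base taxa receive stable locus ids
    in (contig, start) order.
    """
    k = k.k if isinstance(k, StringencyK) else int(k)
    if k < 1:
        raise ValueError("k must be >= 1")
    if base in mapped:
        raise ValueError(f"base taxon {base!r} must not appear among mapped taxa")
    if base_assembly is not None:
        for taxon, ivs in mapped.items():
            for iv in ivs:
                if iv.contig not in base_assembly:
                    raise FormatError(
                        f"putative_loci: taxon {taxon!r} interval on unknown contig {iv.contig!r}"
                    )

    all_ivs = [iv for ivs in mapped.values() for iv in ivs]
    regions = [iv for iv in merge_intervals(all_ivs) if len(iv) >= min_length]

    # Per-taxon overlap counting via a sorted sweep over each taxon's merged set.
    support: list[set[str]] = [set() for _ in regions]
    by_contig_regions: dict[str, list[tuple[int, Interval]]] = {}
    for idx, reg in enumerate(regions):
        by_contig_regions.setdefault(reg.contig, []).append((idx, reg))
    for taxon, ivs in mapped.items():
        merged_t = merge_intervals(ivs)
        by_contig_t: dict[str, list[Interval]] = {}
        for iv in merged_t:
            by_contig_t.setdefault(iv.contig, []).append(iv)
        for contig, regs in by_contig_regions.items():
            tivs = by_contig_t.get(contig, [])
            j = 0
            for idx, reg in regs:
                while j < len(tivs) and tivs[j].end <= reg.start:
                    j += 1
                jj = j
                while jj < len(tivs) and tivs[jj].start < reg.end:
                    if reg.overlap(tivs[jj]) >= min_overlap:
                        support[idx].add(taxon)
                        break
                    jj += 1

    table = SharedLocusTable(base_taxon=base)
    counter = 0
    for idx, reg in enumerate(regions):
        if len(support[idx]) >= k:
            counter += 1
            locus_id = f"{locus_prefix}-{counter}"
            table.loci[locus_id] = SharedLocus(
                locus_id, reg, frozenset(support[idx] | {base})
            )
    return table
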