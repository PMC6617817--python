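"""Assembly contiguity/composition statistics and per-locus read depth."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .seq_formats import GenomeAssembly, Interval, LocusSequence

__all__ = ["AssemblyReport", "DepthReport", "nl_stats", "gc_percent", "locus_depth", "assembly_report"]


@dataclass
class AssemblyReport:
    taxon: str
    total_length: int
    contig_count: int
    n50: int
    l50: int
    n90: int
    l90: int
    gc_percent: float

    def as_row(self) -> dict:
        # Column order mirrors the standard assembly-stats table layout.
        return {
            "taxon": self.taxon,
            "total_length": self.total_length,
            "contigs": self.contig_count,
            "N50": self.n50,
            "L50": self.l50,
            "N90": self.n90,
            "L90": self.l90,
            "GC%": round(self.gc_percent, 2),
        }


@dataclass
class DepthReport:
    mean_depth: dict[str, float]
    covered_fraction: dict[str, float]


def nl_stats(contig_lengths: Sequence[int], fraction: float) -> tuple[int, int]:
    """N/L statistic at *fraction* (0.5 -> N50/L50, 0.9 -> N90/L90).

    N = length of the contig at which the descending cumulative length first
    reaches ``fraction * total``; L = its 1-based rank. A threshold hit
    exactly at a contig boundary reports that contig (bbmap/stats convention).
    """
    if not contig_lengths:
        raise ValueError("nl_stats: empty length list")
    if any(l <= 0 for l in contig_lengths):
        raise ValueError("nl_stats: non-positive contig length")
    lengths = sorted(contig_lengths, reverse=True)
    threshold = fraction * sum(lengths)
    cum = 0
    for rank, length in enumerate(lengths, 1):
        cum += length
        if cum >= threshold:
            return length, rank
    raise AssertionError("unreachable")  # pragma: no cover


def gc_percent(assembly: GenomeAssembly | str) -> float:
    """GC as % of unambiguous (ACGT) bases, case-insensitive."""
    if isinstance(assembly, GenomeAssembly):
        seqs: Iterable[str] = assembly.contigs.values()
    else:
        seqs = [assembly]
    gc = acgt = 0
    for seq in seqs:
        s = seq.upper()
        g, c = s.count("G"), s.count("C")
        gc += g + c
        acgt += g + c + s.count("A") + s.count("T")
    if acgt == 0:
        raise ValueError("gc_percent: no unambiguous bases")
    return 100.0 * gc / acgt


def assembly_report(assembly: GenomeAssembly) -> AssemblyReport:
    lengths = [len(s) for s in assembly.contigs.values()]
    n50, l50 = nl_stats(lengths, 0.5)
    n90, l90 = nl_stats(lengths, 0.9)
    return AssemblyReport(
        taxon=assembly.taxon,
        total_length=sum(lengths),
        contig_count=len(lengths),
        n50=n50,
        l50=l50,
        n90=n90,
        l90=l90,
        gc_percent=gc_percent(assembly),
    )


def locus_depth(
    reference_loci: Iterable[LocusSequence],
    read_intervals: Mapping[str, Sequence[Interval]],
) -> DepthReport:
    """Mean reads-per-base depth and covered fraction per locus.

    *read_intervals* maps locus-id to intervals whose ``contig`` field names
    that locus. Depth = sum of interval lengths / locus length; covered
    fraction = union length / locus length.
    """
    loci = {l.locus_id: len(l.sequence) for l in reference_loci}
    for locus_id, ivs in read_intervals.items():
        if locus_id not in loci:
            raise ValueError(f"locus_depth: unknown locus {locus_id!r}")
        for iv in ivs:
            if iv.end > loci[locus_id]:
                raise ValueError(
                    f"locus_depth: interval {iv} extends past locus {locus_id} "
                    f"(length {loci[locus_id]})"
                )
    mean_depth: dict[str, float] = {}
    covered: dict[str, float] = {}
    for locus_id, length in loci.items():
        ivs = sorted(read_intervals.get(locus_id, ()), key=lambda iv: (iv.start, iv.end))
        total = sum(len(iv) for iv in ivs)
        union = 0
        cur_start = cur_end = -1
        for iv in ivs:
            if iv.start > cur_end:
                union += max(0, cur_end - cur_start)
                cur_start, cur_end = iv.start, iv.end
            else:
                cur_end = max(cur_end, iv.end)
        union += max(0, cur_end - cur_start)
        mean_depth[locus_id] = total / length
        covered[locus_id] = union / length
    return DepthReport(mean_depth, covered)
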