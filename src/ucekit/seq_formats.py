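"""On-disk formats and the header conventions carrying locus/taxon provenance.

Coordinates are 0-based half-open everywhere in memory; SAM's 1-based
positions are converted on read. FASTA case is preserved (lowercase =
soft-masked), ``N`` is treated as ambiguity.

Final-probe header grammar::

    uce-<N>_p<K> |design:<tag>,probes-locus:uce-<N>,probes-probe:<K>,probes-source:<taxon>

Monolithic locus FASTA header grammar::

    uce-<N>_<taxon> |uce-<N>
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "GenomeAssembly",
    "Interval",
    "ProbeRecord",
    "LocusSequence",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_sam_intervals",
    "parse_probe_header",
    "format_probe_header",
    "parse_locus_header",
    "format_locus_header",
    "revcomp",
]

_VALID_BASES = set("ACGTNacgtn")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeAssembly:
    """Named contigs for one taxon. Alphabet: ACGTN plus lowercase soft-mask."""

    taxon: str
    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not seq:
                raise FormatError(f"contig {cid!r} of {self.taxon!r} is empty")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(
                    f"contig {cid!r} of {self.taxon!r} has invalid bases {sorted(bad)!r}"
                )

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def slice(self, iv: "Interval") -> str:
        """Sequence under *iv*, reverse-complemented for minus-strand intervals."""
        seq = self.contigs[iv.contig][iv.start : iv.end]
        return revcomp(seq) if iv.strand == "-" else seq

    @classmethod
    def from_fasta(cls, path: str | Path, taxon: str | None = None) -> "GenomeAssembly":
        recs = read_fasta(path)
        contigs = {h.split()[0]: s for h, s in recs}
        if len(contigs) != len(recs):
            raise FormatError(f"{path}: duplicate contig ids")
        return cls(taxon or Path(path).stem, contigs)

    def to_fasta(self, path: str | Path, wrap: int = 80) -> Path:
        return write_fasta(self.contigs.items(), path, wrap=wrap)


@dataclass(frozen=True, order=True)
class Interval:
    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise FormatError(f"invalid interval {self.contig}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


# Lenient probe-id pattern: any uce-<N>-style token, optional _p<K> tail.
_PROBE_ID_RE = re.compile(r"^(?P<locus>[A-Za-z]+-\d+)(?:_p(?P<probe>\d+))?$")
_META_RE = re.compile(r"(?P<key>[\w-]+):(?P<val>[^,|]+)")


@dataclass
class ProbeRecord:
    """One fixed-length capture probe with provenance metadata."""

    sequence: str
    locus_id: str
    probe_index: int = 1
    source_taxon: str = ""
    design_tag: str = ""
    extra: str = ""  # unparsed header tail, kept verbatim

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"probe {self.locus_id}_p{self.probe_index} has empty sequence")
        if self.probe_index < 1:
            raise FormatError("probe-index must be >= 1")

    @property
    def probe_id(self) -> str:
        return f"{self.locus_id}_p{self.probe_index}"

    def header(self) -> str:
        return format_probe_header(self)


def format_probe_header(p: ProbeRecord) -> str:
    meta = (
        f"design:{p.design_tag},probes-locus:{p.locus_id},"
        f"probes-probe:{p.probe_index},probes-source:{p.source_taxon}"
    )
    tail = f" {p.extra}" if p.extra else ""
    return f"{p.probe_id} |{meta}{tail}"


def parse_probe_header(header: str, sequence: str = "N") -> ProbeRecord:
    """Parse a phyluce-style probe header, leniently.

    Accepts any ``<tag>-<N>`` locus token in the id, with or without the
    ``_p<K>`` suffix and pipe-delimited metadata; the unparsed tail is
    retained verbatim in ``extra``.
    """
    ident, _, rest = header.partition(" ")
    m = _PROBE_ID_RE.match(ident)
    if not m:
        raise FormatError(f"cannot parse probe id from header {header!r}")
    meta = {k.lower(): v for k, v in _META_RE.findall(rest)}
    locus = meta.get("probes-locus", m.group("locus"))
    probe = int(meta.get("probes-probe", m.group("probe") or 1))
    known = {"design", "probes-locus", "probes-probe", "probes-source"}
    tail = ",".join(f"{k}:{v}" for k, v in meta.items() if k not in known)
    return ProbeRecord(
        sequence=sequence,
        locus_id=locus,
        probe_index=probe,
        source_taxon=meta.get("probes-source", ""),
        design_tag=meta.get("design", ""),
        extra=tail or (rest.strip() if not meta else ""),
    )


@dataclass
class LocusSequence:
    """One extracted locus sequence (core + flanks) for one taxon."""

    locus_id: str
    taxon: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"locus {self.locus_id} ({self.taxon}): empty sequence")

    def header(self) -> str:
        return format_locus_header(self.locus_id, self.taxon)


def format_locus_header(locus_id: str, taxon: str) -> str:
    return f"{locus_id}_{taxon} |{locus_id}"


_LOCUS_ID_RE = re.compile(r"^(?P<locus>[A-Za-z]+-\d+)_(?P<taxon>.+)$")


def parse_locus_header(header: str, sequence: str = "N") -> LocusSequence:
    ident = header.split(" ", 1)[0].split("|", 1)[0].strip()
    m = _LOCUS_ID_RE.match(ident)
    if not m:
        raise FormatError(f"cannot parse monolithic locus header {header!r}")
    return LocusSequence(m.group("locus"), m.group("taxon"), sequence)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as ordered ``(full-header, sequence)`` pairs, case preserved."""
    records: list[tuple[str, str]] = []
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise FormatError(f"{path}: malformed header on line 1 (expected '>')")
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append((rec.description, seq))
    return records


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, wrap: int = 80
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for header, seq in records:
            if not seq:
                raise FormatError(f"refusing to write empty sequence for {header!r}")
            fh.write(f">{header}\n")
            if wrap:
                for i in range(0, len(seq), wrap):
                    fh.write(seq[i : i + wrap] + "\n")
            else:
                fh.write(seq + "\n")
    return path


def read_probe_fasta(path: str | Path) -> list[ProbeRecord]:
    return [parse_probe_header(h, s) for h, s in read_fasta(path)]


def write_probe_fasta(probes: Iterable[ProbeRecord], path: str | Path) -> Path:
    return write_fasta(((p.header(), p.sequence) for p in probes), path, wrap=0)


def read_monolithic_fasta(path: str | Path) -> list[LocusSequence]:
    return [parse_locus_header(h, s) for h, s in read_fasta(path)]


def write_monolithic_fasta(loci: Iterable[LocusSequence], path: str | Path) -> Path:
    return write_fasta(((l.header(), l.sequence) for l in loci), path)


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[Interval]:
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            contig, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative coordinate {start}")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "+"
            intervals.append(Interval(contig, start, end, strand))
    return intervals


def write_bed(
    intervals: Sequence[Interval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[int] | None = None,
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.contig, str(iv.start), str(iv.end)]
            if names is not None or scores is not None:
                cols.append(names[i] if names is not None else ".")
                cols.append(str(scores[i]) if scores is not None else "0")
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")
    return path


# ---------------------------------------------------------------------------
# SAM

_SKIP_FLAGS = 0x4 | 0x100 | 0x400 | 0x800  # unmapped, secondary, duplicate, supplementary
_REF_CONSUMING = set("MDN=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def cigar_reference_span(cigar: str) -> int:
    """Reference bases consumed by a CIGAR string."""
    span = 0
    consumed = 0
    for m in _CIGAR_RE.finditer(cigar):
        consumed += m.end() - m.start()
        if m.group(2) in _REF_CONSUMING:
            span += int(m.group(1))
    if consumed != len(cigar):
        raise FormatError(f"malformed CIGAR {cigar!r}")
    return span


def read_sam_intervals(path: str | Path) -> tuple[list[Interval], dict[str, int]]:
    """Reduce mapped, non-duplicate primary SAM alignments to reference intervals.

    Returns ``(intervals, skip_counts)`` where *skip_counts* tallies records
    skipped per reason.
    """
    import pysam

    path = Path(path)
    with open(path) as fh:
        if not fh.readline().startswith("@"):
            raise FormatError(f"{path}: missing SAM header")
    intervals: list[Interval] = []
    skipped = {"unmapped": 0, "secondary": 0, "duplicate": 0, "supplementary": 0}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                skipped["unmapped"] += 1
                continue
            if rec.is_secondary:
                skipped["secondary"] += 1
                continue
            if rec.is_duplicate:
                skipped["duplicate"] += 1
                continue
            if rec.is_supplementary:
                skipped["supplementary"] += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            intervals.append(
                Interval(rec.reference_name, rec.reference_start, rec.reference_end, strand)
            )
    return intervals, skipped
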