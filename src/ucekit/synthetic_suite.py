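"""Multi-taxon synthetic genome suites with planted conserved loci.

Each suite descends from a single random ancestor. Mutation is
substitution-only by default so that locus coordinates are identical across
taxa and every assertion about planted structure is exact. Each planted
locus is a conserved core flanked on both sides by faster-evolving sequence;
background sequence diverges fastest of all. Loci absent from a taxon (and
paralog slots in taxa without the copy) are replaced by fresh random
sequence in reserved slots, so presence/absence never shifts coordinates.

The "idealized mapper" emits the true core coordinates on the base genome
for every taxon where the locus is present; :func:`corrupt_mapping` degrades
it with dropout and boundary jitter to emulate detection failure.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .seq_formats import GenomeAssembly, Interval

__all__ = [
    "SuiteConfig",
    "ParalogSpec",
    "TruthLocus",
    "TruthRegistry",
    "Suite",
    "generate_suite",
    "corrupt_mapping",
    "marker_alignments",
    "simulate_read_intervals",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ParalogSpec:
    locus_index: int
    taxon: str
    copy_divergence: float = 0.05


@dataclass
class SuiteConfig:
    taxa: Sequence[str]
    genome_length: int = 200_000
    n_loci: int = 50
    core_length: int = 300
    flank_length: int = 400
    divergence: Mapping[str, float] | float = 0.025  # substitutions/site from ancestor (core)
    flank_gradient: float = 4.0  # flank rate = core rate * gradient
    background_divergence: float = 0.30
    presence: Mapping[int, frozenset[str]] | None = None  # locus index -> taxa; default all
    paralogs: Sequence[ParalogSpec] = ()
    repeat_density: float = 0.0  # fraction of genome in tandem-repeat arrays
    repeat_unit: int = 8
    repeat_array_length: int = 240
    indel_rate: float = 0.0  # optional small-indel mode (breaks exact coordinates)
    seed: int = 0

    @property
    def base_taxon(self) -> str:
        return self.taxa[0]

    def rate_of(self, taxon: str) -> float:
        if isinstance(self.divergence, Mapping):
            return float(self.divergence[taxon])
        return float(self.divergence)

    def __post_init__(self) -> None:
        rates = [self.rate_of(t) for t in self.taxa]
        if any(not (0 <= r < 0.75) for r in rates):
            raise ValueError("divergence rates must be in [0, 0.75)")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")


@dataclass
class TruthLocus:
    locus_index: int
    span: Interval  # flank + core + flank
    core: Interval
    taxa: frozenset[str]
    paralog_spans: dict[str, Interval] = field(default_factory=dict)


@dataclass
class TruthRegistry:
    config: SuiteConfig
    loci: list[TruthLocus]
    realized_core_divergence: dict[str, float]

    def loci_in_all_taxa(self) -> list[TruthLocus]:
        full = frozenset(self.config.taxa)
        return [l for l in self.loci if l.taxa == full]


@dataclass
class Suite:
    assemblies: dict[str, GenomeAssembly]
    mapped: dict[str, list[Interval]]  # non-base taxon -> intervals on base contig
    registry: TruthRegistry

    @property
    def base_taxon(self) -> str:
        return self.registry.config.base_taxon

    def mapped_for_base(
        self, base: str, min_core_identity: float | None = None
    ) -> dict[str, list[Interval]]:
        """Mapping of every other taxon against *base*.

        Substitution-only mutation keeps coordinates shared across taxa, so
        a locus's core interval is valid on any base where it is present.
        With *min_core_identity* set, a locus is only reported for a taxon
        when its core identity to the base's core reaches the threshold —
        emulating a read mapper's divergence ceiling (real mappers cap the
        substitution rate they will align through).
        """
        out: dict[str, list[Interval]] = {}
        for taxon in self.registry.config.taxa:
            if taxon == base:
                continue
            ivs = []
            for locus in self.registry.loci:
                if taxon not in locus.taxa or base not in locus.taxa:
                    continue
                if min_core_identity is not None:
                    if self.core_identity(base, taxon, locus) < min_core_identity:
                        continue
                ivs.append(locus.core)
            out[taxon] = sorted(ivs, key=lambda iv: iv.start)
        return out

    def core_identity(self, a: str, b: str, locus: TruthLocus) -> float:
        """Hamming identity of a planted core between two taxa (fraction)."""
        sa = self.assemblies[a].slice(locus.core).upper()
        sb = self.assemblies[b].slice(locus.core).upper()
        same = sum(1 for x, y in zip(sa, sb) if x == y)
        return same / len(sa)


def _mutate(
    codes: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Substitute each position independently with prob *rate*; returns count."""
    if rate <= 0:
        return codes, 0
    mask = rng.random(len(codes)) < rate
    n = int(mask.sum())
    if n:
        shift = rng.integers(1, 4, size=n)
        codes = codes.copy()
        codes[mask] = (codes[mask] + shift) % 4
    return codes, n


def _random_codes(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int64)


def _codes_to_str(codes: np.ndarray, lowercase_mask: np.ndarray | None = None) -> str:
    out = _BASES[codes].copy()
    if lowercase_mask is not None and lowercase_mask.any():
        out[lowercase_mask] += 32
    return out.tobytes().decode()


def _place_slots(
    rng: np.random.Generator, genome_length: int, slot_lengths: Sequence[int], margin: int = 50
) -> list[int]:
    """Uniform non-overlapping slot starts via random gap allocation."""
    n = len(slot_lengths)
    if n == 0:
        return []
    order = rng.permutation(n)
    occupied = sum(slot_lengths) + margin * (n + 1)
    if occupied > genome_length:
        raise RuntimeError(
            f"cannot place {n} slots ({occupied} bp incl. margins) in "
            f"{genome_length} bp genome"
        )
    extra = genome_length - occupied
    cuts = np.sort(rng.integers(0, extra + 1, size=n))
    starts = [0] * n
    pos = margin
    prev = 0
    for idx, cut in zip(order, cuts):
        pos += int(cut) - prev
        prev = int(cut)
        starts[int(idx)] = pos
        pos += slot_lengths[int(idx)] + margin
    return starts


def generate_suite(config: SuiteConfig) -> Suite:
    """Build assemblies, idealized mapping intervals, and the truth registry."""
    rng = np.random.default_rng(config.seed)
    T = list(config.taxa)
    G = config.genome_length
    span_len = config.core_length + 2 * config.flank_length
    presence = {
        i: (
            frozenset(config.presence[i])
            if config.presence and i in config.presence
            else frozenset(T)
        )
        for i in range(config.n_loci)
    }
    for i, taxa in presence.items():
        if config.base_taxon not in taxa and taxa:
            raise ValueError(
                f"locus {i}: base taxon must be present for a recoverable locus"
            )

    n_repeats = int(config.repeat_density * G / config.repeat_array_length) if config.repeat_density else 0
    slot_lengths = (
        [span_len] * config.n_loci
        + [span_len] * len(config.paralogs)
        + [config.repeat_array_length] * n_repeats
    )
    starts = _place_slots(rng, G, slot_lengths)
    locus_starts = starts[: config.n_loci]
    paralog_starts = starts[config.n_loci : config.n_loci + len(config.paralogs)]
    repeat_starts = starts[config.n_loci + len(config.paralogs) :]

    ancestor = _random_codes(G, rng)
    contig = "chr1"

    # Per-site class map: 0 background, 1 flank, 2 core, 3 repeat
    site_class = np.zeros(G, dtype=np.int8)
    for s in locus_starts:
        site_class[s : s + span_len] = 1
        site_class[s + config.flank_length : s + config.flank_length + config.core_length] = 2
    repeat_mask = np.zeros(G, dtype=bool)
    repeat_unit_codes = _random_codes(config.repeat_unit, rng)
    for s in repeat_starts:
        reps = config.repeat_array_length // config.repeat_unit + 1
        arr = np.tile(repeat_unit_codes, reps)[: config.repeat_array_length]
        ancestor[s : s + config.repeat_array_length] = arr
        site_class[s : s + config.repeat_array_length] = 3
        repeat_mask[s : s + config.repeat_array_length] = True

    loci = [
        TruthLocus(
            locus_index=i,
            span=Interval(contig, s, s + span_len),
            core=Interval(
                contig,
                s + config.flank_length,
                s + config.flank_length + config.core_length,
            ),
            taxa=presence[i],
        )
        for i, s in enumerate(locus_starts)
    ]
    paralog_map: dict[int, list[tuple[ParalogSpec, int]]] = {}
    for spec, ps in zip(config.paralogs, paralog_starts):
        paralog_map.setdefault(spec.locus_index, []).append((spec, ps))
        loci[spec.locus_index].paralog_spans[spec.taxon] = Interval(
            contig, ps, ps + span_len
        )

    assemblies: dict[str, GenomeAssembly] = {}
    realized: dict[str, float] = {}
    core_mask = site_class == 2
    flank_mask = site_class == 1
    bg_mask = site_class == 0
    n_core = int(core_mask.sum())

    for taxon in T:
        trng = np.random.default_rng((config.seed, zlib.crc32(taxon.encode())))
        rate = config.rate_of(taxon)
        flank_rate = min(rate * config.flank_gradient, 0.74)
        genome = ancestor.copy()

        sub_mask = np.zeros(G, dtype=bool)
        r = trng.random(G)
        sub_mask |= core_mask & (r < rate)
        sub_mask |= flank_mask & (r < flank_rate)
        sub_mask |= bg_mask & (r < config.background_divergence)
        sub_mask |= (site_class == 3) & (r < rate)
        nsub = int(sub_mask.sum())
        if nsub:
            genome[sub_mask] = (genome[sub_mask] + trng.integers(1, 4, size=nsub)) % 4
        realized[taxon] = (
            int((sub_mask & core_mask).sum()) / n_core if n_core else 0.0
        )

        # Absent loci: overwrite the whole slot with fresh random sequence.
        for locus in loci:
            if taxon not in locus.taxa:
                s, e = locus.span.start, locus.span.end
                genome[s:e] = _random_codes(e - s, trng)

        # Paralog slots: the copy in the carrier taxon, random fill elsewhere.
        for locus in loci:
            for spec, ps in paralog_map.get(locus.locus_index, []):
                pe = ps + span_len
                if taxon == spec.taxon:
                    src = genome[locus.span.start : locus.span.end].copy()
                    copy, _ = _mutate(src, spec.copy_divergence, trng)
                    genome[ps:pe] = copy
                else:
                    genome[ps:pe] = _random_codes(pe - ps, trng)

        if config.indel_rate > 0:
            genome = _apply_indels(genome, config.indel_rate, trng)

        seq = _codes_to_str(
            genome, repeat_mask if len(genome) == G and repeat_mask.any() else None
        )
        assemblies[taxon] = GenomeAssembly(taxon, {contig: seq})

    mapped: dict[str, list[Interval]] = {}
    for taxon in T[1:]:
        ivs = [
            locus.core
            for locus in loci
            if taxon in locus.taxa and config.base_taxon in locus.taxa
        ]
        mapped[taxon] = sorted(ivs, key=lambda iv: iv.start)

    registry = TruthRegistry(config, loci, realized)
    return Suite(assemblies, mapped, registry)


def _apply_indels(genome: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Small (1-3 bp) indels at *rate* per site. Coordinates become approximate."""
    out: list[np.ndarray] = []
    pos = 0
    events = np.nonzero(rng.random(len(genome)) < rate)[0]
    for e in events:
        if e < pos:
            continue
        out.append(genome[pos:e])
        size = int(rng.integers(1, 4))
        if rng.random() < 0.5:
            pos = min(e + size, len(genome))  # deletion
        else:
            out.append(_random_codes(size, rng))  # insertion
            pos = e
    out.append(genome[pos:])
    return np.concatenate(out)


def corrupt_mapping(
    intervals: Sequence[Interval], dropout_rate: float, jitter: int, seed: int
) -> list[Interval]:
    """Drop each interval with *dropout_rate*; shift surviving ends by +/- jitter."""
    rng = np.random.default_rng(seed)
    out: list[Interval] = []
    for iv in intervals:
        if rng.random() < dropout_rate:
            continue
        if jitter:
            start = iv.start + int(rng.integers(-jitter, jitter + 1))
            end = iv.end + int(rng.integers(-jitter, jitter + 1))
            start = max(0, start)
            if end <= start:
                end = start + 1
            out.append(Interval(iv.contig, start, end, iv.strand))
        else:
            out.append(iv)
    return out


def marker_alignments(suite: Suite, n_markers: int = 6, seed: int = 0) -> list[dict[str, str]]:
    """Per-marker aligned sequences taken from planted cores present in all taxa.

    Substitution-only mutation means the per-taxon core sequences are already
    positionally aligned.
    """
    rng = np.random.default_rng(seed)
    candidates = suite.registry.loci_in_all_taxa()
    if not candidates:
        raise ValueError("marker_alignments: no loci present in all taxa")
    chosen = rng.choice(len(candidates), size=min(n_markers, len(candidates)), replace=False)
    markers = []
    for ci in sorted(int(c) for c in chosen):
        locus = candidates[ci]
        aln = {
            taxon: asm.slice(locus.core).upper()
            for taxon, asm in suite.assemblies.items()
        }
        markers.append(aln)
    return markers


def simulate_read_intervals(
    locus_length: int, depth: float, read_length: int, seed: int = 0
) -> list[Interval]:
    """Error-free uniform read placements over one locus, for depth tests."""
    rng = np.random.default_rng(seed)
    n_reads = int(round(depth * locus_length / read_length))
    out = []
    for _ in range(n_reads):
        start = int(rng.integers(0, max(1, locus_length - read_length + 1)))
        out.append(Interval("locus", start, min(start + read_length, locus_length)))
    return out
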