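"""Seeded local alignment for bait/probe matching, with a Smith-Waterman oracle.

The engine replaces the external mappers of the original workflow with one
internal aligner: exact seed k-mers are located through a sorted-array index
of the target, seeds are clustered by diagonal, and each cluster window is
resolved with a full local Smith-Waterman alignment. ``smith_waterman`` is
also exposed directly as the exhaustive (quadratic) oracle used in tests.

Identity is matches / aligned columns, gap columns counting as mismatches.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seq_formats import GenomeAssembly, Interval, revcomp

__all__ = [
    "AlignmentHit",
    "Scoring",
    "smith_waterman",
    "seed_extend_search",
    "classify_multiplicity",
    "KmerIndex",
]

DEFAULT_MIN_IDENTITY = 90.0
DEFAULT_MIN_COVERAGE = 80.0
DEFAULT_SEED_LENGTH = 12
DEFAULT_TOP_DELTA = 5.0

_ENC = np.full(256, 4, dtype=np.int8)
for i, b in enumerate(b"ACGT"):
    _ENC[b] = i
    _ENC[b + 32] = i  # lowercase soft-mask aligns like the plain base


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap: int = -2


@dataclass
class AlignmentHit:
    query_id: str
    contig: str
    interval: Interval
    strand: str
    identity: float  # % matching columns
    coverage: float  # % of query aligned
    score: int

    def as_tab(self) -> str:
        """BLAST outfmt-6-like row."""
        iv = self.interval
        return "\t".join(
            str(x)
            for x in (
                self.query_id,
                self.contig,
                f"{self.identity:.2f}",
                len(iv),
                iv.start,
                iv.end,
                self.strand,
                self.score,
            )
        )


# ---------------------------------------------------------------------------
# Smith-Waterman kernels (numba-jitted when available)


def _sw_matrices_py(q, t, match, mismatch, gap):
    m, n = len(q), len(t)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    P = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up, 3 left
    best = 0
    bi = bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            s = match if (qi == t[j - 1] and qi < 4) else mismatch
            diag = H[i - 1, j - 1] + s
            up = H[i - 1, j] + gap
            left = H[i, j - 1] + gap
            h = diag
            p = 1
            if up > h:
                h = up
                p = 2
            if left > h:
                h = left
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            P[i, j] = p
            if h > best:
                best = h
                bi, bj = i, j
    return H, P, best, bi, bj


def _traceback_stats_py(q, t, P, bi, bj, match, mismatch):
    i, j = bi, bj
    matches = 0
    cols = 0
    while i > 0 and j > 0 and P[i, j] != 0:
        p = P[i, j]
        cols += 1
        if p == 1:
            if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                matches += 1
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    return i, j, matches, cols


def _sw_band_scores_py(q, g, bounds, match, mismatch, gap):
    """Banded score-only DP per window -> best local score within the band.

    ``bounds`` rows are (lo, hi, bl, bh): window [lo, hi) in global target
    coordinates and the allowed diagonal range as j - i in DP coordinates
    (j - i == global_diag - lo). Cells outside the band contribute 0, so the
    result is the optimum over alignments staying within the band.
    """
    nw = bounds.shape[0]
    out = np.zeros(nw, dtype=np.int64)
    m = len(q)
    max_w = 1
    for w in range(nw):
        width = bounds[w, 3] - bounds[w, 2] + 1
        if width > max_w:
            max_w = width
    prev = np.zeros(max_w + 2, dtype=np.int32)
    cur = np.zeros(max_w + 2, dtype=np.int32)
    for w in range(nw):
        lo, hi, bl, bh = bounds[w, 0], bounds[w, 1], bounds[w, 2], bounds[w, 3]
        n = hi - lo
        width = bh - bl + 1
        best = 0
        for c in range(width + 2):
            prev[c] = 0
            cur[c] = 0
        for i in range(1, m + 1):
            jbase = i + bl
            for c in range(width):
                j = jbase + c
                if j < 1 or j > n:
                    cur[c + 1] = 0
                    continue
                s = match if (q[i - 1] == g[lo + j - 1] and q[i - 1] < 4) else mismatch
                h = prev[c + 1] + s  # diagonal keeps c
                up = prev[c + 2] + gap  # (i-1, j) is c+1
                if up > h:
                    h = up
                left = cur[c] + gap  # (i, j-1) is c-1
                if left > h:
                    h = left
                if h < 0:
                    h = 0
                cur[c + 1] = h
                if h > best:
                    best = h
            tmp = prev
            prev = cur
            cur = tmp
        out[w] = best
    return out


def _sw_windows_py(q, g, bounds, match, mismatch, gap):
    """Best local alignment of q inside each genome window; stats per window.

    Returns an (n_windows, 7) array of
    (score, window_tstart, window_tend, qstart, qend, matches, cols),
    window-relative target coordinates.
    """
    nw = bounds.shape[0]
    out = np.zeros((nw, 7), dtype=np.int64)
    m = len(q)
    max_n = 0
    for w in range(nw):
        n = bounds[w, 1] - bounds[w, 0]
        if n > max_n:
            max_n = n
    H = np.zeros((m + 1, max_n + 1), dtype=np.int32)
    P = np.zeros((m + 1, max_n + 1), dtype=np.int8)
    for w in range(nw):
        lo, hi = bounds[w, 0], bounds[w, 1]
        n = hi - lo
        best = 0
        bi = bj = 0
        for i in range(1, m + 1):
            qi = q[i - 1]
            for j in range(1, n + 1):
                s = match if (qi == g[lo + j - 1] and qi < 4) else mismatch
                diag = H[i - 1, j - 1] + s
                up = H[i - 1, j] + gap
                left = H[i, j - 1] + gap
                h = diag
                p = 1
                if up > h:
                    h = up
                    p = 2
                if left > h:
                    h = left
                    p = 3
                if h <= 0:
                    h = 0
                    p = 0
                H[i, j] = h
                P[i, j] = p
                if h > best:
                    best = h
                    bi, bj = i, j
        if best <= 0:
            continue
        i, j = bi, bj
        matches = 0
        cols = 0
        while i > 0 and j > 0 and P[i, j] != 0:
            p = P[i, j]
            cols += 1
            if p == 1:
                if q[i - 1] == g[lo + j - 1] and q[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                i -= 1
            else:
                j -= 1
        out[w, 0] = best
        out[w, 1] = j
        out[w, 2] = bj
        out[w, 3] = i
        out[w, 4] = bi
        out[w, 5] = matches
        out[w, 6] = cols
    return out


_USE_NUMBA = os.environ.get("UCEKIT_NO_NUMBA", "") != "1"
if _USE_NUMBA:
    try:
        from numba import njit

        _sw_matrices = njit(cache=True, nogil=True)(_sw_matrices_py)
        _traceback_stats = njit(cache=True, nogil=True)(_traceback_stats_py)
        _sw_windows = njit(cache=True, nogil=True)(_sw_windows_py)
        _sw_band_scores = njit(cache=True, nogil=True)(_sw_band_scores_py)
    except ImportError:  # pragma: no cover
        _USE_NUMBA = False
if not _USE_NUMBA:  # pragma: no cover
    _sw_matrices = _sw_matrices_py
    _traceback_stats = _traceback_stats_py
    _sw_windows = _sw_windows_py
    _sw_band_scores = _sw_band_scores_py


def _drift_allowance(qlen: int, min_identity: float) -> int:
    """Max net diagonal drift any hit meeting *min_identity* can have.

    Gap columns g satisfy g <= cols*(1-I) <= qlen*(1-I)/I, and net drift
    <= g. Below 50% identity the bound is useless; fall back to qlen.
    """
    i = min_identity / 100.0
    if i <= 0.5:
        return qlen
    return int(np.ceil(qlen * (1.0 - i) / i)) + 2


def _score_lower_bound(
    qlen: int, min_identity: float, min_coverage: float, scoring: Scoring
) -> int:
    """Smallest SW score any hit meeting both thresholds can have.

    With identity I and query coverage C, matches m >= I*C*qlen and
    mismatch+gap columns <= m*(1-I)/I, so
    score >= m*(match + (1-I)/I * min(mismatch, gap)). Used to prescreen
    windows with the score-only kernel before the full traceback.
    """
    i = min_identity / 100.0
    c = min_coverage / 100.0
    if i <= 0 or c <= 0:
        return 1
    m = i * c * qlen
    worst = min(scoring.mismatch, scoring.gap)
    bound = m * (scoring.match + (1.0 - i) / i * worst)
    return max(1, int(np.floor(bound)))


def smith_waterman(
    a: str, b: str, scoring: Scoring = Scoring()
) -> tuple[int, tuple[str, str], float]:
    """Optimal local alignment of *a* vs *b* under (match, mismatch, gap).

    Returns ``(score, (aligned_a, aligned_b), identity_percent)``.
    Deterministic traceback prefers diagonal > up > left; a best score <= 0
    is reported as no alignment: ``(0, ("", ""), 0.0)``. Quadratic — inputs
    are expected to be <= ~2000 bp.
    """
    q, t = encode(a), encode(b)
    H, P, best, bi, bj = _sw_matrices(
        q, t, scoring.match, scoring.mismatch, scoring.gap
    )
    if best <= 0:
        return 0, ("", ""), 0.0
    # String traceback (python; alignment length is O(len))
    i, j = bi, bj
    ra: list[str] = []
    rb: list[str] = []
    matches = 0
    while i > 0 and j > 0 and P[i, j] != 0:
        p = P[i, j]
        if p == 1:
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                matches += 1
            i -= 1
            j -= 1
        elif p == 2:
            ra.append(a[i - 1])
            rb.append("-")
            i -= 1
        else:
            ra.append("-")
            rb.append(b[j - 1])
            j -= 1
    aligned_a = "".join(reversed(ra))
    aligned_b = "".join(reversed(rb))
    identity = 100.0 * matches / len(aligned_a) if aligned_a else 0.0
    return int(best), (aligned_a, aligned_b), identity


# ---------------------------------------------------------------------------
# Seed index


class KmerIndex:
    """Sorted-array index of all seed-length k-mers of an assembly.

    Contigs are laid out in one global coordinate space; windows containing
    N or crossing a contig boundary are excluded. Lookup is a searchsorted
    over uint64 2-bit codes.
    """

    def __init__(self, assembly: GenomeAssembly, seed_length: int = DEFAULT_SEED_LENGTH):
        if seed_length < 4 or seed_length > 31:
            raise ValueError("seed_length must be in [4, 31]")
        self.assembly = assembly
        self.k = seed_length
        self._names: list[str] = []
        self._offsets: list[int] = []  # global start of each contig
        codes_parts = []
        pos_parts = []
        offset = 0
        for name, seq in assembly.contigs.items():
            self._names.append(name)
            self._offsets.append(offset)
            enc = encode(seq).astype(np.int64)
            n = len(enc)
            if n >= seed_length:
                valid = enc < 4
                code = np.zeros(n - seed_length + 1, dtype=np.uint64)
                ok = np.ones(n - seed_length + 1, dtype=bool)
                for s in range(seed_length):
                    sl = enc[s : s + n - seed_length + 1]
                    code = (code << np.uint64(2)) | sl.astype(np.uint64)
                    ok &= valid[s : s + n - seed_length + 1]
                idx = np.nonzero(ok)[0]
                codes_parts.append(code[idx])
                pos_parts.append(idx + offset)
            offset += n
        self._total = offset
        if codes_parts:
            codes = np.concatenate(codes_parts)
            positions = np.concatenate(pos_parts)
            order = np.argsort(codes, kind="stable")
            self._codes = codes[order]
            self._positions = positions[order]
        else:
            self._codes = np.empty(0, dtype=np.uint64)
            self._positions = np.empty(0, dtype=np.int64)
        self._bounds = np.array(self._offsets + [offset], dtype=np.int64)
        self._gcodes = (
            np.concatenate([encode(assembly.contigs[n]) for n in self._names])
            if self._names
            else np.empty(0, dtype=np.int8)
        )

    def contig_of(self, gpos: int) -> tuple[str, int]:
        """Map a global position to (contig, local position)."""
        ci = int(np.searchsorted(self._bounds, gpos, side="right")) - 1
        return self._names[ci], gpos - self._offsets[ci]

    def contig_span(self, gpos: int) -> tuple[int, int]:
        ci = int(np.searchsorted(self._bounds, gpos, side="right")) - 1
        return int(self._bounds[ci]), int(self._bounds[ci + 1])

    def lookup(self, query_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (query positions, global target positions) of exact seed hits."""
        lo = np.searchsorted(self._codes, query_codes, side="left")
        hi = np.searchsorted(self._codes, query_codes, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qpos = np.repeat(np.arange(len(query_codes)), counts)
        cum = np.cumsum(counts)
        flat = np.repeat(lo, counts) + (np.arange(total) - np.repeat(cum - counts, counts))
        return qpos, self._positions[flat]

    def query_codes(self, seq: str) -> np.ndarray:
        enc = encode(seq).astype(np.int64)
        n = len(enc)
        k = self.k
        if n < k:
            return np.empty(0, dtype=np.uint64)
        valid = enc < 4
        code = np.zeros(n - k + 1, dtype=np.uint64)
        ok = np.ones(n - k + 1, dtype=bool)
        for s in range(k):
            sl = enc[s : s + n - k + 1]
            code = (code << np.uint64(2)) | sl.astype(np.uint64)
            ok &= valid[s : s + n - k + 1]
        code[~ok] = np.uint64(0xFFFFFFFFFFFFFFFF)  # sentinel never in index (k<=31)
        return code


_INDEX_CACHE: dict[tuple[int, int], KmerIndex] = {}


def get_index(assembly: GenomeAssembly, seed_length: int) -> KmerIndex:
    key = (id(assembly), seed_length)
    idx = _INDEX_CACHE.get(key)
    if idx is None or idx.assembly is not assembly:
        idx = KmerIndex(assembly, seed_length)
        _INDEX_CACHE[key] = idx
    return idx


# ---------------------------------------------------------------------------
# Seed-and-extend search

_DIAG_BAND = 12  # max diagonal drift within one cluster (allows small indels)
_WINDOW_PAD = 24


def seed_extend_search(
    query: str,
    target: GenomeAssembly,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    seed_length: int = DEFAULT_SEED_LENGTH,
    scoring: Scoring = Scoring(),
    query_id: str = "query",
    index: KmerIndex | None = None,
) -> list[AlignmentHit]:
    """All local-alignment hits of *query* in *target* meeting both thresholds.

    Hits are found on both strands and sorted by score descending with a
    (contig, start) tie-break. A degenerate (all-N) query returns an empty
    list with a warning.
    """
    if len(query) < seed_length:
        raise ValueError("query shorter than seed_length")
    if set(query.upper()) <= {"N"}:
        warnings.warn(f"degenerate all-N query {query_id!r}", stacklevel=2)
        return []
    idx = index if index is not None else get_index(target, seed_length)
    qlen = len(query)
    hits: list[AlignmentHit] = []
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        qcodes = idx.query_codes(qseq)
        if len(qcodes) == 0:
            continue
        qpos, tpos = idx.lookup(qcodes)
        if len(qpos) == 0:
            continue
        qenc = encode(qseq)
        pad = _drift_allowance(qlen, min_identity)
        windows = list(_cluster_windows(qpos, tpos, qlen, idx, pad))
        bounds = np.array(windows, dtype=np.int64)
        # banded score-only prescreen: only windows that can meet both
        # thresholds get the full traceback pass
        score_bound = _score_lower_bound(qlen, min_identity, min_coverage, scoring)
        scores = _sw_band_scores(
            qenc, idx._gcodes, bounds, scoring.match, scoring.mismatch, scoring.gap
        )
        promising = np.nonzero(scores >= score_bound)[0]
        if len(promising) == 0:
            continue
        stats = _sw_windows(
            qenc,
            idx._gcodes,
            bounds[promising][:, :2],
            scoring.match,
            scoring.mismatch,
            scoring.gap,
        )
        for w, wi in enumerate(promising):
            lo_g = windows[wi][0]
            best, j0, bj, i0, bi, matches, cols = stats[w]
            if best <= 0 or cols == 0:
                continue
            identity = 100.0 * matches / cols
            coverage = 100.0 * (bi - i0) / qlen
            if identity + 1e-9 < min_identity or coverage + 1e-9 < min_coverage:
                continue
            g_start, g_end = lo_g + j0, lo_g + bj
            contig, local = idx.contig_of(int(g_start))
            hits.append(
                AlignmentHit(
                    query_id=query_id,
                    contig=contig,
                    interval=Interval(contig, local, local + int(g_end - g_start)),
                    strand=strand,
                    identity=identity,
                    coverage=coverage,
                    score=int(best),
                )
            )
    hits = _dedupe_hits(hits)
    hits.sort(key=lambda h: (-h.score, h.contig, h.interval.start, h.strand))
    return hits


def _cluster_windows(qpos, tpos, qlen, idx: KmerIndex, pad: int = _WINDOW_PAD):
    """Diagonal-clustered seed windows as (lo, hi, band_lo, band_hi).

    (lo, hi) is the target window in global coordinates, clipped to the
    seed's contig; (band_lo, band_hi) is the admitted j - i range of the DP
    (global diagonal minus lo), covering all seed diagonals +- *pad* drift.
    """
    diag = tpos - qpos
    order = np.lexsort((tpos, diag))
    diag = diag[order]
    tp = tpos[order]
    windows: list[list[int]] = []
    start = 0
    n = len(diag)
    for i in range(1, n + 1):
        if (
            i == n
            or diag[i] - diag[i - 1] > _DIAG_BAND
            or (diag[i] == diag[i - 1] and tp[i] - tp[i - 1] > qlen + pad)
        ):
            d_min = int(diag[start:i].min())
            d_max = int(diag[start:i].max())
            t_lo = d_min - pad
            t_hi = d_max + qlen + pad
            c_lo, c_hi = idx.contig_span(int(tp[start]))  # clip to seed's contig
            windows.append([max(t_lo, c_lo), min(t_hi, c_hi), d_min - pad, d_max + pad])
            start = i
    # merge overlapping same-contig windows, widening the band accordingly
    windows.sort()
    merged: list[list[int]] = []
    for lo, hi, d_lo, d_hi in windows:
        if (
            merged
            and lo <= merged[-1][1]
            and idx.contig_span(lo) == idx.contig_span(merged[-1][0])
        ):
            merged[-1][1] = max(merged[-1][1], hi)
            merged[-1][2] = min(merged[-1][2], d_lo)
            merged[-1][3] = max(merged[-1][3], d_hi)
        else:
            merged.append([lo, hi, d_lo, d_hi])
    for lo, hi, d_lo, d_hi in merged:
        if hi > lo:
            yield lo, hi, d_lo - lo, d_hi - lo


def _dedupe_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Collapse hits with overlapping target intervals on one strand; keep best."""
    hits.sort(key=lambda h: (h.contig, h.strand, h.interval.start, -h.score))
    kept: list[AlignmentHit] = []
    for h in hits:
        if (
            kept
            and kept[-1].contig == h.contig
            and kept[-1].strand == h.strand
            and kept[-1].interval.overlap(h.interval) > 0
        ):
            if h.score > kept[-1].score:
                kept[-1] = h
        else:
            kept.append(h)
    return kept


def classify_multiplicity(
    hits: Sequence[AlignmentHit], top_delta: float = DEFAULT_TOP_DELTA
) -> str:
    """Classify one query's hit list as 'unique', 'duplicate' or 'absent'.

    Duplicate: >= 2 hits whose scores are within *top_delta* percent of the
    best and whose target intervals do not overlap.
    """
    if not hits:
        return "absent"
    best = max(h.score for h in hits)
    top = [h for h in hits if h.score >= best * (1.0 - top_delta / 100.0)]
    if len(top) < 2:
        return "unique"
    for i in range(len(top)):
        for j in range(i + 1, len(top)):
            a, b = top[i], top[j]
            if a.contig != b.contig or a.interval.overlap(b.interval) == 0:
                return "duplicate"
    return "unique"
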