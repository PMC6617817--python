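"""Physical QC of probe sequences: length, GC, melting temperature, complexity.

Tm uses the salt-adjusted RNA-DNA hybrid formula (the convention of bait
check utilities for RNA capture probes)::

    Tm = 79.8 + 18.5*log10([Na+]) + 58.4*f_GC + 11.8*f_GC^2 - 820/L

with [Na+] in mol/L (default 0.9 M) and f_GC the GC fraction. The constants
are carried in :class:`QCThresholds` and echoed in every summary so any
formula mismatch is diagnosable rather than silent.

Linguistic complexity is the count of distinct substrings of every length
divided by the maximum possible for that length: sum_k min(4^k, L-k+1).
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "QCThresholds",
    "QCRecord",
    "gc_fraction",
    "melting_temperature",
    "linguistic_complexity",
    "qc_probe",
    "qc_summary",
]

# §-level GC presets: design-time command-line bounds vs reported prose bounds.
GC_PRESET_DESIGN = (25.0, 70.0)
GC_PRESET_REPORTED = (20.0, 70.0)


@dataclass(frozen=True)
class QCThresholds:
    length: int = 120
    gc_min: float = 25.0
    gc_max: float = 70.0
    tm_min: float = 80.0
    tm_max: float = 120.0
    sodium_molar: float = 0.9
    min_complexity: float = 0.0

    def __post_init__(self) -> None:
        for lo, hi in ((self.gc_min, self.gc_max), (self.tm_min, self.tm_max)):
            if lo >= hi:
                raise ValueError("threshold band min must be < max")


@dataclass
class QCRecord:
    probe_id: str
    length: int
    gc: float
    tm: float
    complexity: float
    fail_reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.fail_reasons


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("gc_fraction: no unambiguous bases")
    return (s.count("G") + s.count("C")) / acgt


def melting_temperature(seq: str, sodium_molar: float = 0.9) -> float:
    f = gc_fraction(seq)
    return 79.8 + 18.5 * math.log10(sodium_molar) + 58.4 * f + 11.8 * f * f - 820.0 / len(seq)


def linguistic_complexity(seq: str) -> float:
    s = seq.upper()
    L = len(s)
    if L == 0:
        raise ValueError("linguistic_complexity: empty sequence")
    observed = 0
    possible = 0
    for k in range(1, L + 1):
        observed += len({s[i : i + k] for i in range(L - k + 1)})
        possible += min(4**k, L - k + 1) if k <= 32 else L - k + 1
    return observed / possible


def qc_probe(sequence: str, thresholds: QCThresholds = QCThresholds(), probe_id: str = "probe") -> QCRecord:
    if not sequence:
        raise ValueError("qc_probe: empty sequence")
    fails: list[str] = []
    s = sequence.upper()
    n_count = s.count("N")
    if n_count:
        fails.append(f"ambiguous-bases:{n_count}")
    if len(s) != thresholds.length:
        fails.append(f"length:{len(s)}!={thresholds.length}")
    if n_count < len(s):
        gc = 100.0 * gc_fraction(s)
        tm = melting_temperature(s, thresholds.sodium_molar)
    else:
        gc = float("nan")
        tm = float("nan")
    lc = linguistic_complexity(s)
    if not math.isnan(gc):
        if gc < thresholds.gc_min:
            fails.append(f"gc-low:{gc:.2f}")
        elif gc > thresholds.gc_max:
            fails.append(f"gc-high:{gc:.2f}")
        if tm < thresholds.tm_min:
            fails.append(f"tm-low:{tm:.2f}")
        elif tm > thresholds.tm_max:
            fails.append(f"tm-high:{tm:.2f}")
    if lc < thresholds.min_complexity:
        fails.append(f"complexity-low:{lc:.3f}")
    return QCRecord(probe_id, len(s), gc, tm, lc, fails)


def _dist(values: Sequence[float]) -> dict:
    return {
        "min": min(values),
        "max": max(values),
        "mean": statistics.fmean(values),
        "median": statistics.median(values),
    }


def qc_summary(records: Sequence[QCRecord], thresholds: QCThresholds = QCThresholds()) -> dict:
    """Distribution report per metric plus pass rate and the Tm constants used."""
    if not records:
        raise ValueError("qc_summary: no records")
    ok = [r for r in records if not math.isnan(r.gc)]
    summary = {
        "n_probes": len(records),
        "pass_rate": sum(r.passed for r in records) / len(records),
        "length": _dist([r.length for r in records]),
        "gc_percent": _dist([r.gc for r in ok]) if ok else None,
        "tm_celsius": _dist([r.tm for r in ok]) if ok else None,
        "linguistic_complexity": _dist([r.complexity for r in records]),
        "tm_formula": {
            "form": "79.8 + 18.5*log10(Na) + 58.4*fGC + 11.8*fGC^2 - 820/L",
            "sodium_molar": thresholds.sodium_molar,
        },
    }
    return summary
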