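"""Independent brute-force oracles used by the property suites.

These deliberately avoid the package's optimised code paths: statistics are
recounted from string slices, patterns are expanded to explicit base sets,
and the reverse complement uses a literal table.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def naive_gc(window: str) -> float:
    hits = sum(1 for b in window if b in "CG")
    return hits / len(window)


def naive_oe(window: str) -> float:
    c = sum(1 for b in window if b == "C")
    g = sum(1 for b in window if b == "G")
    cpg = sum(1 for k in range(len(window) - 1) if window[k:k + 2] == "CG")
    if c * g == 0:
        return 0.0
    return cpg * len(window) / (c * g)


def _passes(window: str, min_gc: float, min_oe: float) -> bool:
    return naive_gc(window) >= min_gc and naive_oe(window) >= min_oe


def oracle_islands(s: str, window: int, min_length: int, min_gc: float,
                   min_oe: float, step: int = 1) -> List[Tuple[int, int]]:
    """Enumerate all windows, merge overlapping/abutting marked windows,
    trim each merged interval to the longest (leftmost on ties) sub-interval
    passing both thresholds as a whole, and drop short intervals."""
    n = len(s)
    if n < window:
        return []
    merged: List[List[int]] = []
    for i in range(0, n - window + 1, step):
        if _passes(s[i:i + window], min_gc, min_oe):
            if merged and i <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], i + window)
            else:
                merged.append([i, i + window])
    out: List[Tuple[int, int]] = []
    for a, b in merged:
        best = None
        for length in range(b - a, min_length - 1, -1):
            for i in range(a, b - length + 1):
                if _passes(s[i:i + length], min_gc, min_oe):
                    best = (i, i + length)
                    break
            if best:
                break
        if best is not None and best[1] - best[0] >= min_length:
            out.append(best)
    return out


def simple_revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def expand_pattern(pattern: str) -> Set[str]:
    """All concrete ACGT strings a degenerate pattern can match."""
    options = [""]
    for sym in pattern:
        options = [o + b for o in options for b in _IUPAC[sym]]
    return set(options)


def oracle_scan(subject: str, patterns: Dict[str, str],
                strands: str = "both") -> Set[Tuple[str, str, int]]:
    """All (element, strand, forward_start) matches on an ACGT subject,
    by explicit pattern expansion and substring membership."""
    hits: Set[Tuple[str, str, int]] = set()
    n = len(subject)
    rc = simple_revcomp(subject)
    for name, pattern in patterns.items():
        concrete = expand_pattern(pattern)
        m = len(pattern)
        if strands in ("+", "both"):
            for i in range(n - m + 1):
                if subject[i:i + m] in concrete:
                    hits.add((name, "+", i))
        if strands in ("-", "both"):
            for i in range(n - m + 1):
                if rc[i:i + m] in concrete:
                    hits.add((name, "-", n - i - m))
    return hits
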