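"""Sliding-window CpG-island prediction.

A window is island-like when its GC fraction and observed/expected CpG
dinucleotide ratio both clear their thresholds. Marked windows that overlap
or abut are merged; each merged interval is trimmed to the longest
sub-interval that still clears both thresholds when re-evaluated as a whole,
and intervals shorter than the minimum length are dropped. With the default
parameters (100 bp window, GC >= 0.50, obs/exp >= 0.60, minimum 100 bp,
step 1) this mirrors the classic promoter island definition used by
MethPrimer-style predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple, Union

import numpy as np

from .seqio import NucleotideSequence


@dataclass(frozen=True)
class IslandParams:
    """Parameters of the sliding-window island criteria."""

    window: int = 100
    min_length: int = 100
    min_gc: float = 0.50
    min_oe: float = 0.60
    step: int = 1

    def __post_init__(self) -> None:
        if self.window < 10:
            raise ValueError("window must be >= 10 bp")
        if not 0.0 < self.min_gc < 1.0:
            raise ValueError("min_gc must lie in (0, 1)")
        if self.min_oe <= 0:
            raise ValueError("min_oe must be positive")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass(frozen=True)
class CpgIsland:
    """A half-open island interval with its whole-interval statistics."""

    seq_id: str
    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float

    @property
    def length(self) -> int:
        return self.end - self.start


def gc_fraction(window: str) -> float:
    """(#C + #G) / length; ambiguity codes count as neither C nor G."""
    if not window:
        raise ValueError("empty window")
    w = window.upper()
    return (w.count("C") + w.count("G")) / len(w)


def obs_exp_cpg(window: str) -> float:
    """Observed/expected CpG ratio: (#CpG x length) / (#C x #G); 0 if no C or G."""
    if not window:
        raise ValueError("empty window")
    w = window.upper()
    c, g = w.count("C"), w.count("G")
    if c * g == 0:
        return 0.0
    return w.count("CG") * len(w) / (c * g)


class _PrefixStats:
    """O(1) GC and CpG statistics over arbitrary intervals via prefix sums."""

    def __init__(self, residues: str) -> None:
        arr = np.frombuffer(residues.encode(), dtype=np.uint8)
        is_c = arr == ord("C")
        is_g = arr == ord("G")
        self._c = np.concatenate(([0], np.cumsum(is_c)))
        self._g = np.concatenate(([0], np.cumsum(is_g)))
        # CpG dinucleotide starting at k
        cpg = is_c[:-1] & is_g[1:] if len(arr) > 1 else np.zeros(0, dtype=bool)
        self._cpg = np.concatenate(([0], np.cumsum(cpg)))
        self.n = len(arr)

    def counts(self, start: int, end: int) -> Tuple[int, int, int]:
        c = int(self._c[end] - self._c[start])
        g = int(self._g[end] - self._g[start])
        # dinucleotides fully inside [start, end)
        hi = min(end - 1, self.n - 1)
        cpg = int(self._cpg[hi] - self._cpg[start]) if hi > start else 0
        return c, g, cpg

    def passes(self, start: int, end: int, params: IslandParams) -> bool:
        length = end - start
        c, g, cpg = self.counts(start, end)
        if (c + g) / length < params.min_gc:
            return False
        if c * g == 0:
            return False
        return cpg * length / (c * g) >= params.min_oe

    def stats(self, start: int, end: int) -> Tuple[float, float]:
        length = end - start
        c, g, cpg = self.counts(start, end)
        gc = (c + g) / length
        oe = 0.0 if c * g == 0 else cpg * length / (c * g)
        return gc, oe


def _merge_marked(starts: List[int], window: int) -> List[Tuple[int, int]]:
    """Merge marked windows [s, s+window) that overlap or abut."""
    merged: List[Tuple[int, int]] = []
    for s in starts:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], s + window))
        else:
            merged.append((s, s + window))
    return merged


def _trim(stats: _PrefixStats, start: int, end: int,
          params: IslandParams) -> Union[Tuple[int, int], None]:
    """Longest sub-interval of [start, end) passing both thresholds as a whole.

    Ties broken leftmost. Returns None when no sub-interval of at least
    ``min_length`` passes.
    """
    if stats.passes(start, end, params):
        return (start, end)
    span = end - start
    for length in range(span - 1, params.min_length - 1, -1):
        for i in range(start, end - length + 1):
            if stats.passes(i, i + length, params):
                return (i, i + length)
    return None


def find_cpg_islands(seq: NucleotideSequence,
                     params: IslandParams = IslandParams()) -> List[CpgIsland]:
    """Predict CpG islands on one sequence.

    Returns sorted, pairwise non-overlapping islands; every reported island
    clears both thresholds when re-evaluated on its exact interval. A
    sequence shorter than the window yields an empty list with a warning.
    """
    n = len(seq)
    if n < params.window:
        warnings.warn(
            f"sequence {seq.id!r} ({n} bp) shorter than window ({params.window} bp); "
            "no islands predicted"
        )
        return []
    stats = _PrefixStats(seq.residues)
    marked = [s for s in range(0, n - params.window + 1, params.step)
              if stats.passes(s, s + params.window, params)]
    islands: List[CpgIsland] = []
    for a, b in _merge_marked(marked, params.window):
        trimmed = _trim(stats, a, b, params)
        if trimmed is None:
            continue
        i, j = trimmed
        if j - i < params.min_length:
            continue
        gc, oe = stats.stats(i, j)
        islands.append(CpgIsland(seq.id, i, j, gc, oe))
    return islands


def write_bed(islands: List[CpgIsland], path: Union[str, Path]) -> None:
    """Write islands as 0-based half-open BED with score = round(1000 x obs/exp)."""
    with Path(path).open("w") as fh:
        for k, isl in enumerate(islands, start=1):
            score = int(round(1000 * isl.obs_exp_cpg))
            fh.write(f"{isl.seq_id}\t{isl.start}\t{isl.end}\tCpG_{k}\t{score}\n")


def write_island_tsv(islands: List[CpgIsland], path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        fh.write("seq_id\tstart\tend\tlength\tgc_fraction\tobs_exp_cpg\n")
        for isl in islands:
            fh.write(f"{isl.seq_id}\t{isl.start}\t{isl.end}\t{isl.length}"
                     f"\t{isl.gc_fraction:.6f}\t{isl.obs_exp_cpg:.6f}\n")
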