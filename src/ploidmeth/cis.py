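"""Cis-regulatory element catalogue and IUPAC-degenerate motif scanning.

The packaged default catalogue holds 24 promoter elements (light-, hormone-
and stress-responsive plus one circadian element). Patterns written with
parenthesised alternations such as ``CC(G/A)CCC`` are normalised to IUPAC
degenerate symbols (``CCRCCC``). A pattern position matches a subject
position when the subject base's IUPAC set is a subset of the pattern
symbol's set, so an ambiguous subject base only matches a pattern symbol
that covers every base it could be.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Union

import yaml

from .seqio import IUPAC_SETS, NucleotideSequence, reverse_complement

CATEGORIES = ("light", "hormone", "stress", "other")

_ALTERNATION = re.compile(r"\(([ACGT](?:/[ACGT])+)\)")
_SET_TO_IUPAC = {v: k for k, v in IUPAC_SETS.items()}


class CatalogueError(ValueError):
    """Raised for malformed catalogue rows or patterns."""


def normalize_pattern(pattern: str) -> str:
    """Normalise a motif pattern to plain IUPAC symbols.

    ``CC(G/A)CCC`` becomes ``CCRCCC``. Raises :class:`CatalogueError` for an
    empty pattern or characters outside the IUPAC alphabet.
    """
    pat = pattern.strip().upper()

    def _sub(m: re.Match) -> str:
        bases = frozenset(m.group(1).split("/"))
        return _SET_TO_IUPAC[bases]

    pat = _ALTERNATION.sub(_sub, pat)
    if not pat:
        raise CatalogueError("empty pattern")
    bad = set(pat) - set(IUPAC_SETS)
    if bad:
        raise CatalogueError(f"pattern {pattern!r}: invalid symbols {sorted(bad)}")
    return pat


@dataclass(frozen=True)
class CisElement:
    name: str
    pattern: str
    category: str
    note: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", normalize_pattern(self.pattern))
        if self.category not in CATEGORIES:
            raise CatalogueError(
                f"element {self.name!r}: category {self.category!r} not in {CATEGORIES}"
            )


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence reported in forward coordinates."""

    element_name: str
    seq_id: str
    strand: str  # '+' or '-'
    start: int   # 0-based on the forward strand
    matched: str  # forward-strand subsequence of pattern length


def load_catalogue(source: Union[str, Path, None] = None) -> List[CisElement]:
    """Load a cis-element catalogue from TSV or YAML; default = packaged table.

    TSV columns: name, pattern, category, note. YAML: a list of mappings with
    the same keys. Element names must be unique.
    """
    if source is None:
        ref = resources.files("ploidmeth").joinpath("data/cis_elements.tsv")
        text = ref.read_text()
        return _parse_tsv(text)
    path = Path(source)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        rows = yaml.safe_load(text)
        elements = [CisElement(r["name"], r["pattern"], r["category"],
                               r.get("note", "")) for r in rows]
    else:
        elements = _parse_tsv(text)
    return elements


def _parse_tsv(text: str) -> List[CisElement]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    idx = {col: i for i, col in enumerate(header)}
    elements: List[CisElement] = []
    seen = set()
    for ln_no, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        try:
            name = fields[idx["name"]]
            elem = CisElement(
                name=name,
                pattern=fields[idx["pattern"]],
                category=fields[idx["category"]],
                note=fields[idx["note"]] if "note" in idx and len(fields) > idx["note"] else "",
            )
        except (CatalogueError, IndexError, KeyError) as exc:
            raise CatalogueError(f"catalogue row {ln_no}: {exc}") from exc
        if elem.name in seen:
            raise CatalogueError(f"catalogue row {ln_no}: duplicate name {elem.name!r}")
        seen.add(elem.name)
        elements.append(elem)
    return elements


def _matches_at(subject: str, pos: int, pattern: str) -> bool:
    for k, sym in enumerate(pattern):
        sub_set = IUPAC_SETS[subject[pos + k]]
        if not sub_set <= IUPAC_SETS[sym]:
            return False
    return True


def scan_motifs(seq: NucleotideSequence, catalogue: Iterable[CisElement],
                strands: str = "both") -> List[MotifHit]:
    """Scan every catalogue pattern over the sequence.

    ``strands`` is '+', '-' or 'both'. Minus-strand matches are located on
    the reverse complement and reported in forward coordinates with the
    forward-strand subsequence as ``matched``. Overlapping occurrences are
    all reported; hits are sorted by (start, element, strand).
    """
    if strands not in {"+", "-", "both"}:
        raise ValueError("strands must be '+', '-' or 'both'")
    n = len(seq)
    hits: List[MotifHit] = []
    fwd = seq.residues
    rev = reverse_complement(seq).residues if strands in {"-", "both"} else ""
    for elem in catalogue:
        m = len(elem.pattern)
        if m > n:
            continue
        if strands in {"+", "both"}:
            for i in range(n - m + 1):
                if _matches_at(fwd, i, elem.pattern):
                    hits.append(MotifHit(elem.name, seq.id, "+", i, fwd[i:i + m]))
        if strands in {"-", "both"}:
            for i in range(n - m + 1):
                if _matches_at(rev, i, elem.pattern):
                    start = n - i - m
                    hits.append(MotifHit(elem.name, seq.id, "-", start,
                                         fwd[start:start + m]))
    hits.sort(key=lambda h: (h.start, h.element_name, h.strand))
    return hits


def count_by_category(hits: Iterable[MotifHit], catalogue: Iterable[CisElement],
                      mode: str = "distinct_elements") -> Dict[str, int]:
    """Census of hits per functional category.

    ``distinct_elements`` counts element names with at least one hit (the
    convention behind "12 light-responsive elements"); ``total_hits`` counts
    occurrences. Categories with zero count are omitted.
    """
    if mode not in {"distinct_elements", "total_hits"}:
        raise ValueError("mode must be 'distinct_elements' or 'total_hits'")
    cat_of = {e.name: e.category for e in catalogue}
    counts: Dict[str, int] = {}
    if mode == "distinct_elements":
        seen = set()
        for h in hits:
            if h.element_name not in seen:
                seen.add(h.element_name)
                cat = cat_of[h.element_name]
                counts[cat] = counts.get(cat, 0) + 1
    else:
        for h in hits:
            cat = cat_of[h.element_name]
            counts[cat] = counts.get(cat, 0) + 1
    return counts


def write_hits_tsv(hits: List[MotifHit], catalogue: Iterable[CisElement],
                   path: Union[str, Path]) -> None:
    """GFF3-like TSV: seq_id, source, element, 1-based start/end, strand, matched."""
    pat_len = {e.name: len(e.pattern) for e in catalogue}
    with Path(path).open("w") as fh:
        fh.write("seq_id\tsource\telement\tstart\tend\tstrand\tmatched\n")
        for h in hits:
            end = h.start + pat_len[h.element_name]
            fh.write(f"{h.seq_id}\tploidmeth\t{h.element_name}\t{h.start + 1}"
                     f"\t{end}\t{h.strand}\t{h.matched}\n")


def write_category_counts(counts: Dict[str, int], path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        fh.write("category\tcount\n")
        for cat in CATEGORIES:
            if cat in counts:
                fh.write(f"{cat}\t{counts[cat]}\n")
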