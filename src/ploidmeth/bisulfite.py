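"""Bisulfite-clone methylation calling in CG, CHG and CHH contexts.

Sanger bisulfite-sequencing PCR (BSP) clones derive from one strand of a
known amplicon, so calling is defined on the reference top strand under an
ungapped alignment model: at every reference cytosine a clone C is read as
methylated (protected from conversion), a clone T as unmethylated
(converted), and anything else as ambiguous. Contexts follow the plant
convention: CG, CHG and CHH with H in {A, C, T}, assigned from the
reference; a cytosine whose context window is cut off by the amplicon
3' end is UNKNOWN and excluded from summaries.

Summaries are micro-averages: methylated observations over assayed
observations, pooled across clones (and, in :func:`aggregate_total`, across
islands), which makes pooling associative and conservation exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import pandas as pd

from .seqio import NucleotideSequence


class Context(str, Enum):
    CG = "CG"
    CHG = "CHG"
    CHH = "CHH"
    UNKNOWN = "UNKNOWN"


class State(str, Enum):
    METHYLATED = "methylated"
    UNMETHYLATED = "unmethylated"
    AMBIGUOUS = "ambiguous"


class MethylationError(ValueError):
    pass


@dataclass(frozen=True)
class AmpliconSpec:
    """A bisulfite amplicon: a half-open slice of the reference promoter."""

    island_id: str
    seq_id: str
    start: int
    end: int
    reference: str  # unconverted forward-strand subsequence

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference", self.reference.upper())
        if self.end <= self.start:
            raise ValueError(f"amplicon {self.island_id!r}: empty interval")
        if len(self.reference) != self.end - self.start:
            raise ValueError(
                f"amplicon {self.island_id!r}: reference length "
                f"{len(self.reference)} != interval {self.end - self.start}"
            )

    @classmethod
    def from_promoter(cls, promoter: NucleotideSequence, island_id: str,
                      start: int, end: int) -> "AmpliconSpec":
        return cls(island_id, promoter.id, start, end, promoter.residues[start:end])


@dataclass(frozen=True)
class BisulfiteClone:
    clone_id: str
    genotype: str
    island_id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())


@dataclass(frozen=True)
class AlignmentResult:
    accepted: bool
    reason: Optional[str] = None  # 'indel_or_truncation' | 'low_identity'
    mismatches: int = 0
    n_non_c: int = 0


@dataclass(frozen=True)
class CytosineCall:
    ref_position: int  # 0-based promoter coordinate
    context: Context
    state: State


@dataclass(frozen=True)
class MethylationSummary:
    """Per-genotype methylation counts for one island or the whole promoter."""

    genotype: str
    scope: str  # island_id or 'TOTAL'
    counts: Mapping[str, Tuple[int, int]]  # context -> (methylated, assayed)

    def fraction(self, context: str) -> float:
        m, a = self.counts.get(context, (0, 0))
        if a == 0:
            raise MethylationError(
                f"{self.genotype}/{self.scope}: no assayed cytosines in context {context}"
            )
        return m / a

    @property
    def total_fraction(self) -> float:
        """Pooled fraction: sum of methylated over sum of assayed (micro-average)."""
        m = sum(v[0] for v in self.counts.values())
        a = sum(v[1] for v in self.counts.values())
        if a == 0:
            raise MethylationError(f"{self.genotype}/{self.scope}: no_assayable_cytosines")
        return m / a


def bisulfite_convert(seq: str, methylated_positions: Set[int]) -> str:
    """In-silico bisulfite conversion: unprotected C -> T.

    Every position in ``methylated_positions`` must hold a C; those survive
    conversion, every other C reads as T, all other bases are unchanged.
    """
    s = seq.upper()
    for p in methylated_positions:
        if not 0 <= p < len(s) or s[p] != "C":
            raise MethylationError(f"methylated position {p} does not hold C")
        # validated above; conversion below
    out = []
    for i, b in enumerate(s):
        if b == "C" and i not in methylated_positions:
            out.append("T")
        else:
            out.append(b)
    return "".join(out)


def classify_context(reference: str, pos: int) -> Context:
    """Context of the cytosine at ``pos`` on the reference forward strand."""
    ref = reference.upper()
    if ref[pos] != "C":
        raise MethylationError(f"position {pos} holds {ref[pos]!r}, not C")
    n = len(ref)
    if pos + 1 >= n:
        return Context.UNKNOWN
    nxt = ref[pos + 1]
    if nxt == "G":
        return Context.CG
    if nxt not in "ACT":  # ambiguous base: context undecidable
        return Context.UNKNOWN
    if pos + 2 >= n:
        return Context.UNKNOWN
    nxt2 = ref[pos + 2]
    if nxt2 == "G":
        return Context.CHG
    if nxt2 not in "ACT":
        return Context.UNKNOWN
    return Context.CHH


def align_clone(clone: BisulfiteClone, spec: AmpliconSpec,
                max_mismatch_frac: float = 0.10) -> AlignmentResult:
    """Ungapped identity pairing of a clone against its amplicon reference.

    Identity is judged only at non-cytosine reference positions (cytosines
    legitimately differ after conversion). A length difference rejects with
    'indel_or_truncation'; excess mismatches reject with 'low_identity'.
    """
    if len(clone.residues) != len(spec.reference):
        return AlignmentResult(False, "indel_or_truncation")
    mismatches = 0
    n_non_c = 0
    for rb, cb in zip(spec.reference, clone.residues):
        if rb == "C":
            continue
        n_non_c += 1
        if rb != cb:
            mismatches += 1
    if n_non_c > 0 and mismatches / n_non_c > max_mismatch_frac:
        return AlignmentResult(False, "low_identity", mismatches, n_non_c)
    return AlignmentResult(True, None, mismatches, n_non_c)


def call_clone(clone: BisulfiteClone, spec: AmpliconSpec) -> List[CytosineCall]:
    """Per-cytosine methylation calls for one accepted clone.

    Clone C -> methylated, clone T -> unmethylated, anything else ->
    ambiguous; ``ref_position`` is in promoter coordinates.
    """
    calls: List[CytosineCall] = []
    for i, rb in enumerate(spec.reference):
        if rb != "C":
            continue
        cb = clone.residues[i]
        if cb == "C":
            state = State.METHYLATED
        elif cb == "T":
            state = State.UNMETHYLATED
        else:
            state = State.AMBIGUOUS
        calls.append(CytosineCall(spec.start + i, classify_context(spec.reference, i), state))
    return calls


def summarize_methylation(calls: Iterable[CytosineCall], genotype: str,
                          scope: str) -> MethylationSummary:
    """Counts and fractions per context for one genotype x scope.

    Ambiguous calls are excluded from denominators; UNKNOWN-context
    cytosines are excluded entirely. Raises when nothing is assayable.
    """
    counts: Dict[str, List[int]] = {c.value: [0, 0] for c in
                                    (Context.CG, Context.CHG, Context.CHH)}
    for call in calls:
        if call.context == Context.UNKNOWN or call.state == State.AMBIGUOUS:
            continue
        entry = counts[call.context.value]
        entry[1] += 1
        if call.state == State.METHYLATED:
            entry[0] += 1
    total_assayed = sum(v[1] for v in counts.values())
    if total_assayed == 0:
        raise MethylationError(f"{genotype}/{scope}: no_assayable_cytosines")
    return MethylationSummary(genotype, scope,
                              {k: (v[0], v[1]) for k, v in counts.items()})


def aggregate_total(per_island: Sequence[MethylationSummary]) -> MethylationSummary:
    """Micro-average island summaries of one genotype into scope TOTAL."""
    if not per_island:
        raise MethylationError("no summaries to aggregate")
    genotypes = {s.genotype for s in per_island}
    if len(genotypes) > 1:
        raise MethylationError(f"mixed genotypes in aggregate: {sorted(genotypes)}")
    counts: Dict[str, List[int]] = {c.value: [0, 0] for c in
                                    (Context.CG, Context.CHG, Context.CHH)}
    for summ in per_island:
        for ctx, (m, a) in summ.counts.items():
            counts[ctx][0] += m
            counts[ctx][1] += a
    return MethylationSummary(per_island[0].genotype, "TOTAL",
                              {k: (v[0], v[1]) for k, v in counts.items()})


def _primer_site(reference: str, primer: str, start: int) -> bool:
    # bisulfite primers are designed on the converted top strand, so a
    # primer T may sit over a reference C; other bases must match exactly
    for k, pb in enumerate(primer):
        rb = reference[start + k]
        if pb != rb and not (pb == "T" and rb == "C"):
            return False
    return True


def locate_amplicon(promoter: NucleotideSequence, island_id: str,
                    fwd_primer: str, rev_primer: str) -> AmpliconSpec:
    """Locate a BSP amplicon by its primer pair (helper; explicit
    coordinates are the canonical interface).

    Primers are matched against the unconverted top strand under the
    bisulfite rule (primer T matches reference C or T); the reverse primer
    is reverse-complemented first. Exactly one compatible placement of each
    primer is required.
    """
    from .seqio import reverse_complement
    ref = promoter.residues
    fwd = fwd_primer.upper()
    # both BSP primers amplify the converted top strand: the reverse primer
    # is the reverse complement of a converted (C->T) stretch, so after
    # reverse-complementing it the same T-over-C rule applies
    rev = reverse_complement(NucleotideSequence("r", rev_primer)).residues
    fwd_hits = [i for i in range(len(ref) - len(fwd) + 1)
                if _primer_site(ref, fwd, i)]
    rev_hits = [i for i in range(len(ref) - len(rev) + 1)
                if _primer_site(ref, rev, i)]
    if len(fwd_hits) != 1 or len(rev_hits) != 1:
        raise MethylationError(
            f"amplicon {island_id!r}: primers place ambiguously "
            f"({len(fwd_hits)} forward, {len(rev_hits)} reverse sites)"
        )
    start, end = fwd_hits[0], rev_hits[0] + len(rev)
    if end <= start:
        raise MethylationError(f"amplicon {island_id!r}: primers face outward")
    return AmpliconSpec.from_promoter(promoter, island_id, start, end)


# ---------------------------------------------------------------------------
# Bulk interfaces used by the CLI


def parse_clone_fasta(seqs: Iterable[NucleotideSequence]) -> List[BisulfiteClone]:
    """Clones from FASTA records with headers 'genotype|island|clone_id'."""
    clones = []
    for s in seqs:
        parts = s.id.split("|")
        if len(parts) != 3:
            raise MethylationError(
                f"clone header {s.id!r} is not 'genotype|island|clone_id'"
            )
        genotype, island, clone_id = parts
        clones.append(BisulfiteClone(clone_id, genotype, island, s.residues))
    return clones


def read_amplicon_bed(path: Union[str, Path],
                      promoter: NucleotideSequence) -> List[AmpliconSpec]:
    """Amplicons from a BED file (seq_id, start, end, island_id) plus reference."""
    specs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        seq_id, start, end, island_id = fields[0], int(fields[1]), int(fields[2]), fields[3]
        if seq_id != promoter.id:
            raise MethylationError(
                f"amplicon {island_id!r} references {seq_id!r}, not {promoter.id!r}"
            )
        specs.append(AmpliconSpec.from_promoter(promoter, island_id, start, end))
    return specs


def call_clone_table(clones: Sequence[BisulfiteClone],
                     specs: Sequence[AmpliconSpec],
                     max_mismatch_frac: float = 0.10,
                     ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Align and call a clone collection.

    Returns (calls, rejects): calls has columns genotype, island, clone,
    ref_position, context, state; rejects has genotype, island, clone,
    reason.
    """
    spec_of = {s.island_id: s for s in specs}
    call_rows = []
    reject_rows = []
    for clone in clones:
        spec = spec_of.get(clone.island_id)
        if spec is None:
            reject_rows.append((clone.genotype, clone.island_id, clone.clone_id,
                                "unknown_island"))
            continue
        aln = align_clone(clone, spec, max_mismatch_frac)
        if not aln.accepted:
            reject_rows.append((clone.genotype, clone.island_id, clone.clone_id,
                                aln.reason))
            continue
        for call in call_clone(clone, spec):
            call_rows.append((clone.genotype, clone.island_id, clone.clone_id,
                              call.ref_position, call.context.value, call.state.value))
    calls = pd.DataFrame(call_rows, columns=["genotype", "island", "clone",
                                             "ref_position", "context", "state"])
    rejects = pd.DataFrame(reject_rows, columns=["genotype", "island", "clone", "reason"])
    return calls, rejects


def summarize_table(calls: pd.DataFrame) -> List[MethylationSummary]:
    """Island summaries plus a TOTAL summary per genotype, from a call table."""
    summaries: List[MethylationSummary] = []
    for genotype, gdf in calls.groupby("genotype", sort=True):
        per_island = []
        for island, idf in gdf.groupby("island", sort=True):
            cy_calls = [CytosineCall(int(r.ref_position), Context(r.context), State(r.state))
                        for r in idf.itertuples()]
            per_island.append(summarize_methylation(cy_calls, str(genotype), str(island)))
        summaries.extend(per_island)
        summaries.append(aggregate_total(per_island))
    return summaries


def write_summary_tsv(summaries: Sequence[MethylationSummary],
                      path: Union[str, Path]) -> None:
    """Summaries as TSV with percentages to 2 decimals."""
    with Path(path).open("w") as fh:
        fh.write("genotype\tscope\tcontext\tmethylated\tassayed\tpercent\n")
        for s in summaries:
            for ctx in ("CG", "CHG", "CHH"):
                m, a = s.counts.get(ctx, (0, 0))
                pct = f"{100 * m / a:.2f}" if a else "NA"
                fh.write(f"{s.genotype}\t{s.scope}\t{ctx}\t{m}\t{a}\t{pct}\n")
            m = sum(v[0] for v in s.counts.values())
            a = sum(v[1] for v in s.counts.values())
            pct = f"{100 * m / a:.2f}" if a else "NA"
            fh.write(f"{s.genotype}\t{s.scope}\tALL\t{m}\t{a}\t{pct}\n")


def read_summary_tsv(path: Union[str, Path]) -> List[MethylationSummary]:
    """Rebuild summaries (counts only) from :func:`write_summary_tsv` output."""
    df = pd.read_csv(path, sep="\t")
    summaries = []
    for (genotype, scope), grp in df.groupby(["genotype", "scope"], sort=False):
        counts = {}
        for r in grp.itertuples():
            if r.context == "ALL":
                continue
            counts[r.context] = (int(r.methylated), int(r.assayed))
        summaries.append(MethylationSummary(str(genotype), str(scope), counts))
    return summaries
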