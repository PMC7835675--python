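"""Seeded generators emulating the study's inputs.

Three generators mirror the assay designs: a ~2.5 kb promoter with three
planted CpG islands (151/306/191 bp) and optional cis-element motifs; BSP
clone sets (15 clones per island per genotype) with configurable
per-context methylation rates, incomplete-conversion and sequencing-error
processes; and parent/hybrid expression trios with a known heterosis class.
Every generator is a pure function of its configuration and seed.

The promoter background is sampled at GC 0.35 with CpG-dinucleotide
suppression (no C immediately before G), the CpG-depleted composition
typical of plant genomic DNA outside islands; it guarantees that only the
planted intervals can satisfy the island criteria, so truth scoring is
unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from .bisulfite import AmpliconSpec, BisulfiteClone, Context, classify_context
from .cis import CisElement, load_catalogue
from .heterosis import CrossDesign, ParentSpec, ReplicateSet, compute_mpv
from .seqio import IUPAC_SETS, NucleotideSequence, write_fasta

Rate = Union[float, Mapping[str, float]]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class IslandSpec:
    position: int
    length: int
    target_gc: float = 0.55
    target_oe: float = 0.75


@dataclass(frozen=True)
class GenotypeSpec:
    genotype: str
    role: str  # parent_high_dose | parent_low_dose | hybrid

    def __post_init__(self) -> None:
        if self.role not in {"parent_high_dose", "parent_low_dose", "hybrid"}:
            raise ValueError(f"unknown role {self.role!r}")


def _default_islands() -> List[IslandSpec]:
    return [IslandSpec(400, 151), IslandSpec(1000, 306), IslandSpec(1800, 191)]


def _default_genotypes() -> List[GenotypeSpec]:
    return [GenotypeSpec("LQ1-4x", "parent_high_dose"),
            GenotypeSpec("GC-1", "parent_low_dose"),
            GenotypeSpec("A-3", "hybrid"),
            GenotypeSpec("A-5", "hybrid"),
            GenotypeSpec("A-6", "hybrid")]


def _default_rates() -> Dict[str, Rate]:
    # Study conditions: parental totals 21.0% / 22.5% (MPV 21.50%), hybrid
    # totals 17.56% / 18.33% / 17.84%.
    return {"LQ1-4x": 0.210, "GC-1": 0.225,
            "A-3": 0.1756, "A-5": 0.1833, "A-6": 0.1784}


def _default_expression_plan() -> Dict[str, Tuple[str, float]]:
    return {"A-3": ("AHP", 5.0), "A-5": ("AHP", 5.0), "A-6": ("AHP", 5.0)}


@dataclass
class SimulationConfig:
    """Configuration of a full simulated study."""

    seed: int = 0
    promoter_length: int = 2475
    island_specs: List[IslandSpec] = field(default_factory=_default_islands)
    motif_plan: Dict[str, int] = field(default_factory=dict)
    genotypes: List[GenotypeSpec] = field(default_factory=_default_genotypes)
    methylation_rates: Dict[str, Rate] = field(default_factory=_default_rates)
    n_clones: int = 15
    conversion_failure: float = 0.005
    seq_error: float = 0.001
    expression_plan: Dict[str, Tuple[str, float]] = field(
        default_factory=_default_expression_plan)
    n_reps: int = 3
    cv: float = 0.05
    background_gc: float = 0.35
    parent_expression_means: Tuple[float, float] = (2.0, 1.0)  # high-dose, low-dose

    def __post_init__(self) -> None:
        for p in (self.conversion_failure, self.seq_error, self.background_gc):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        spans = sorted((s.position, s.position + s.length) for s in self.island_specs)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 < b1:
                raise ValueError("island intervals must be disjoint")
        if spans and (spans[0][0] < 0 or spans[-1][1] > self.promoter_length):
            raise ValueError("island intervals must lie within the promoter")


@dataclass
class TruthBundle:
    """Ground truth needed to score recovery without re-deriving it."""

    islands: List[Tuple[int, int]] = field(default_factory=list)
    motifs: List[Dict[str, object]] = field(default_factory=list)
    methylation_rates: Dict[str, Rate] = field(default_factory=dict)
    expression_classes: Dict[str, str] = field(default_factory=dict)


def _as_rng(seed_or_rng: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# Promoter


def _sample_background(n: int, gc: float, rng: np.random.Generator) -> List[str]:
    """iid background at the given GC with CpG dinucleotides suppressed."""
    probs = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    bases = np.array(list(probs))
    p = np.array(list(probs.values()))
    out: List[str] = []
    draws = rng.choice(bases, size=2 * n + 16, p=p)
    k = 0
    while len(out) < n:
        if k >= len(draws):
            draws = rng.choice(bases, size=n, p=p)
            k = 0
        b = draws[k]
        k += 1
        if out and out[-1] == "C" and b == "G":
            continue  # resample: no CpG outside planted islands
        out.append(str(b))
    return out


def _sample_island(spec: IslandSpec, rng: np.random.Generator,
                   p_cg: float = 0.20, max_tries: int = 200) -> str:
    """CpG-enriched interval meeting the island spec's GC and obs/exp targets."""
    from .islands import gc_fraction, obs_exp_cpg
    for _ in range(max_tries):
        chars: List[str] = []
        while len(chars) < spec.length:
            if len(chars) <= spec.length - 2 and rng.random() < p_cg:
                chars.extend("CG")
            else:
                chars.append("ACGT"[rng.integers(4)])
        s = "".join(chars[:spec.length])
        if gc_fraction(s) >= spec.target_gc and obs_exp_cpg(s) >= spec.target_oe:
            return s
    raise SimulationError(
        f"island at {spec.position} ({spec.length} bp): targets gc>={spec.target_gc}, "
        f"oe>={spec.target_oe} unreachable after {max_tries} tries"
    )


def _concretize_pattern(pattern: str, rng: np.random.Generator) -> str:
    return "".join(sorted(IUPAC_SETS[sym])[rng.integers(len(IUPAC_SETS[sym]))]
                   for sym in pattern)


def simulate_promoter(config: SimulationConfig,
                      rng: Union[int, np.random.Generator, None] = None,
                      catalogue: Optional[Sequence[CisElement]] = None,
                      ) -> Tuple[NucleotideSequence, TruthBundle]:
    """Promoter with planted islands and motifs, plus its truth bundle."""
    rng = _as_rng(config.seed if rng is None else rng)
    chars = _sample_background(config.promoter_length, config.background_gc, rng)
    truth = TruthBundle()
    island_spans: List[Tuple[int, int]] = []
    for spec in config.island_specs:
        s = _sample_island(spec, rng)
        chars[spec.position:spec.position + spec.length] = list(s)
        island_spans.append((spec.position, spec.position + spec.length))
        truth.islands.append((spec.position, spec.position + spec.length))
    if config.motif_plan:
        cat = {e.name: e for e in (catalogue or load_catalogue())}
        occupied = list(island_spans)
        for name, count in sorted(config.motif_plan.items()):
            if name not in cat:
                raise SimulationError(f"motif {name!r} not in catalogue")
            m = len(cat[name].pattern)
            for _ in range(count):
                placed = False
                for _try in range(500):
                    start = int(rng.integers(0, config.promoter_length - m + 1))
                    span = (start, start + m)
                    if any(a < span[1] and span[0] < b for a, b in occupied):
                        continue
                    instance = _concretize_pattern(cat[name].pattern, rng)
                    chars[start:start + m] = list(instance)
                    occupied.append(span)
                    truth.motifs.append({"name": name, "start": start, "strand": "+"})
                    placed = True
                    break
                if not placed:
                    raise SimulationError(f"could not place motif {name!r}")
    seq = NucleotideSequence("sim_promoter", "".join(chars))
    return seq, truth


# ---------------------------------------------------------------------------
# Bisulfite clones


def _rate_for(rate: Rate, context: Context) -> float:
    if isinstance(rate, Mapping):
        # UNKNOWN-context cytosines (excluded from summaries) use the CHH rate
        key = context.value if context != Context.UNKNOWN else "CHH"
        return float(rate[key])
    return float(rate)


def simulate_clone_set(amplicon: AmpliconSpec, rate: Rate, n_clones: int = 15,
                       conversion_failure: float = 0.005, seq_error: float = 0.001,
                       rng: Union[int, np.random.Generator, None] = None,
                       genotype: str = "sim",
                       ) -> Tuple[List[BisulfiteClone], TruthBundle]:
    """Bisulfite clones of one amplicon at the given per-cytosine rates.

    Each reference cytosine is methylated independently with its context's
    probability; conversion then reads unmethylated Cs as T, except that a
    fraction ``conversion_failure`` retain C (the dominant bisulfite
    artifact); ``seq_error`` substitutes any position with a random other
    base.
    """
    rng = _as_rng(rng)
    ref = np.frombuffer(amplicon.reference.encode(), dtype="S1")
    c_pos = np.flatnonzero(ref == b"C")
    probs = np.array([_rate_for(rate, classify_context(amplicon.reference, int(i)))
                      for i in c_pos])
    template = ref.copy()
    template[c_pos] = b"T"  # fully converted baseline
    clones: List[BisulfiteClone] = []
    n = len(ref)
    alphabet = np.array([b"A", b"C", b"G", b"T"])
    for k in range(n_clones):
        arr = template.copy()
        meth = rng.random(len(c_pos)) < probs
        fail = (~meth) & (rng.random(len(c_pos)) < conversion_failure)
        arr[c_pos[meth | fail]] = b"C"
        if seq_error > 0:
            errs = np.flatnonzero(rng.random(n) < seq_error)
            for i in errs:
                choices = alphabet[alphabet != arr[i]]
                arr[i] = choices[rng.integers(len(choices))]
        clones.append(BisulfiteClone(f"clone{k + 1:02d}", genotype,
                                     amplicon.island_id,
                                     arr.tobytes().decode()))
    truth = TruthBundle(methylation_rates={genotype: rate})
    return clones, truth


# ---------------------------------------------------------------------------
# Expression trios


_PATTERNS = ("MPL", "HPL", "LPL", "AHP", "BLP")


def simulate_expression_trio(true_class: str, effect_size: float = 3.0,
                             cv: float = 0.05, n_reps: int = 3,
                             design: Optional[CrossDesign] = None,
                             rng: Union[int, np.random.Generator, None] = None,
                             parent_means: Tuple[float, float] = (2.0, 1.0),
                             trait: str = "relative_expression",
                             noise: str = "common_sd",
                             ) -> Tuple[ReplicateSet, ReplicateSet, ReplicateSet, TruthBundle]:
    """Hybrid/parent replicate sets generated under a known heterosis class.

    Parent means default to 2.0 (high-dose parent) and 1.0; the hybrid mean
    is placed at the MPV (MPL), at HP or LP (HPL/LPL), or beyond them by
    ``effect_size`` within-group standard deviations (AHP/BLP, floored at a
    small positive value). Replicates are normal on the linear scale,
    truncated at zero; the default noise model uses a common within-group
    SD of ``cv x MPV`` so that effect sizes in SD units are well defined
    (``noise="per_mean_cv"`` scales each group's SD by its own mean).
    """
    if true_class not in _PATTERNS:
        raise ValueError(f"true_class must be one of {_PATTERNS}")
    if noise not in {"common_sd", "per_mean_cv"}:
        raise ValueError("noise must be 'common_sd' or 'per_mean_cv'")
    rng = _as_rng(rng)
    design = design or CrossDesign.triploid("hybrid", "P-high", "P-low")
    mean_hi, mean_lo = parent_means
    mpv = compute_mpv(mean_hi, mean_lo, design)
    hp, lp = max(parent_means), min(parent_means)
    sigma = cv * mpv
    target = {"MPL": mpv, "HPL": hp, "LPL": lp,
              "AHP": hp + effect_size * sigma,
              "BLP": lp - effect_size * sigma}[true_class]
    floor = 1e-6
    if target <= floor:
        raise SimulationError(
            f"{true_class} placement {target:.3g} is not positive; reduce effect_size"
        )

    def draw(mean: float) -> Tuple[float, ...]:
        sd = sigma if noise == "common_sd" else cv * mean
        vals = []
        for _ in range(n_reps):
            v = rng.normal(mean, sd)
            tries = 0
            while v <= 0 and tries < 1000:
                v = rng.normal(mean, sd)
                tries += 1
            vals.append(max(v, floor))
        return tuple(vals)

    p_hi = ReplicateSet(design.parent_high_dose.genotype, trait, draw(mean_hi))
    p_lo = ReplicateSet(design.parent_low_dose.genotype, trait, draw(mean_lo))
    hyb = ReplicateSet(design.hybrid_id, trait, draw(target))
    truth = TruthBundle(expression_classes={design.hybrid_id: true_class})
    return hyb, p_hi, p_lo, truth


# ---------------------------------------------------------------------------
# Full study bundle


def simulate_study(config: SimulationConfig, outdir: Union[str, Path],
                   ) -> Dict[str, Path]:
    """Write a complete simulated study bundle consumable by the CLI.

    Emits promoter.fa, amplicons.bed, clones.fa, expression.tsv,
    design.yaml and truth.json under ``outdir``; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    rng_prom, rng_clone, rng_expr = [np.random.default_rng(s)
                                     for s in master.spawn(3)]

    promoter, truth = simulate_promoter(config, rng_prom)
    truth.methylation_rates = dict(config.methylation_rates)

    amplicons = [AmpliconSpec.from_promoter(promoter, f"CpG{i + 1}", a, b)
                 for i, (a, b) in enumerate(truth.islands)]

    clones: List[BisulfiteClone] = []
    for gspec in config.genotypes:
        rate = config.methylation_rates.get(gspec.genotype)
        if rate is None:
            raise SimulationError(f"no methylation rate for {gspec.genotype!r}")
        for amp in amplicons:
            cset, _ = simulate_clone_set(
                amp, rate, config.n_clones, config.conversion_failure,
                config.seq_error, rng_clone, genotype=gspec.genotype)
            clones.extend(cset)

    hi = next(g for g in config.genotypes if g.role == "parent_high_dose")
    lo = next(g for g in config.genotypes if g.role == "parent_low_dose")
    hybrids = [g for g in config.genotypes if g.role == "hybrid"]

    expr_rows: List[Tuple[str, str, int, float]] = []
    trait = "relative_expression"
    mean_hi, mean_lo = config.parent_expression_means
    base_design = CrossDesign("placeholder", ParentSpec(hi.genotype, 2 / 3),
                              ParentSpec(lo.genotype, 1 / 3))
    mpv = compute_mpv(mean_hi, mean_lo, base_design)
    sigma = config.cv * mpv

    def draw(mean: float) -> List[float]:
        vals = []
        for _ in range(config.n_reps):
            v = rng_expr.normal(mean, sigma)
            while v <= 0:
                v = rng_expr.normal(mean, sigma)
            vals.append(v)
        return vals

    for rep, v in enumerate(draw(mean_hi), start=1):
        expr_rows.append((hi.genotype, trait, rep, v))
    for rep, v in enumerate(draw(mean_lo), start=1):
        expr_rows.append((lo.genotype, trait, rep, v))
    hp, lp = max(mean_hi, mean_lo), min(mean_hi, mean_lo)
    for g in hybrids:
        cls, effect = config.expression_plan.get(g.genotype, ("AHP", 5.0))
        target = {"MPL": mpv, "HPL": hp, "LPL": lp,
                  "AHP": hp + effect * sigma,
                  "BLP": lp - effect * sigma}[cls]
        if target <= 0:
            raise SimulationError(f"{g.genotype}: BLP placement below zero")
        truth.expression_classes[g.genotype] = cls
        for rep, v in enumerate(draw(target), start=1):
            expr_rows.append((g.genotype, trait, rep, v))

    paths = {name: outdir / name for name in
             ("promoter.fa", "amplicons.bed", "clones.fa", "expression.tsv",
              "design.yaml", "truth.json")}
    write_fasta([promoter], paths["promoter.fa"])
    with paths["amplicons.bed"].open("w") as fh:
        for amp in amplicons:
            fh.write(f"{amp.seq_id}\t{amp.start}\t{amp.end}\t{amp.island_id}\n")
    clone_records = [NucleotideSequence(f"{c.genotype}|{c.island_id}|{c.clone_id}",
                                        c.residues) for c in clones]
    write_fasta(clone_records, paths["clones.fa"])
    with paths["expression.tsv"].open("w") as fh:
        fh.write("genotype\ttrait\treplicate\tvalue\n")
        for genotype, tr, rep, v in expr_rows:
            fh.write(f"{genotype}\t{tr}\t{rep}\t{v:.6f}\n")
    design_doc = {
        "parent_high_dose": {"id": hi.genotype, "weight": "2/3"},
        "parent_low_dose": {"id": lo.genotype, "weight": "1/3"},
        "hybrids": [g.genotype for g in hybrids],
    }
    paths["design.yaml"].write_text(yaml.safe_dump(design_doc, sort_keys=False))
    truth_doc = {
        "islands": [list(t) for t in truth.islands],
        "motifs": truth.motifs,
        "methylation_rates": {k: (dict(v) if isinstance(v, Mapping) else v)
                              for k, v in truth.methylation_rates.items()},
        "expression_classes": truth.expression_classes,
    }
    paths["truth.json"].write_text(json.dumps(truth_doc, indent=2) + "\n")
    return paths


def load_simulation_config(path: Union[str, Path]) -> SimulationConfig:
    """SimulationConfig from a YAML mapping (unknown keys rejected)."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(doc)
    if "island_specs" in kwargs:
        kwargs["island_specs"] = [IslandSpec(**d) for d in kwargs["island_specs"]]
    if "genotypes" in kwargs:
        kwargs["genotypes"] = [GenotypeSpec(**d) for d in kwargs["genotypes"]]
    if "expression_plan" in kwargs:
        kwargs["expression_plan"] = {k: (v[0], float(v[1]))
                                     for k, v in kwargs["expression_plan"].items()}
    if "parent_expression_means" in kwargs:
        kwargs["parent_expression_means"] = tuple(kwargs["parent_expression_means"])
    valid = set(SimulationConfig.__dataclass_fields__)
    unknown = set(kwargs) - valid
    if unknown:
        raise SimulationError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimulationConfig(**kwargs)
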