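"""End-to-end orchestration: islands -> scan -> methcall -> heterosis/trend.

A single YAML config drives the run; every invocation writes a manifest
with the tool version, a config hash, input digests, seeds and per-stage
row counts. Re-running with identical inputs and seeds reproduces
byte-identical TSV/BED outputs (manifests differ only in timestamps).
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Union

import yaml

from . import __version__
from .bisulfite import (call_clone_table, parse_clone_fasta, read_amplicon_bed,
                        read_summary_tsv, summarize_table, write_summary_tsv)
from .cis import count_by_category, load_catalogue, scan_motifs, write_category_counts, write_hits_tsv
from .heterosis import (classify_expression_pattern, load_cross_designs,
                        methylation_mpv_trend, read_replicates_tsv,
                        write_calls_tsv, write_trend_tsv)
from .islands import IslandParams, find_cpg_islands, write_bed, write_island_tsv
from .seqio import read_fasta
from .simulate import SimulationConfig, load_simulation_config, simulate_study


class PipelineError(RuntimeError):
    """Raised with the failing stage's name in the message."""


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config_path: Union[str, Path], outdir: Union[str, Path, None] = None,
                 ) -> Path:
    """Run every stage per the YAML config; returns the output directory."""
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text()) or {}
    out = Path(outdir or cfg.get("outdir", "ploidmeth_out"))
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "tool": "ploidmeth",
        "version": __version__,
        "config_hash": hashlib.sha256(config_path.read_bytes()).hexdigest()[:16],
        "started": datetime.now(timezone.utc).isoformat(),
        "inputs": {},
        "seeds": {},
        "rows": {},
        "warnings": [],
    }

    # --- inputs (simulated or supplied)
    stage = "inputs"
    try:
        if "simulate" in cfg:
            sim_cfg_doc = cfg["simulate"] or {}
            sim_dir = out / "fixtures"
            sim_cfg = _sim_config_from_doc(sim_cfg_doc)
            paths = simulate_study(sim_cfg, sim_dir)
            inputs = {"promoter": paths["promoter.fa"],
                      "amplicons": paths["amplicons.bed"],
                      "clones": paths["clones.fa"],
                      "expression": paths["expression.tsv"],
                      "design": paths["design.yaml"]}
            manifest["seeds"]["simulate"] = sim_cfg.seed
        else:
            inp = cfg.get("inputs", {})
            inputs = {k: Path(inp[k]) for k in
                      ("promoter", "amplicons", "clones", "expression", "design")}
        for name, p in inputs.items():
            if not Path(p).exists():
                raise PipelineError(f"stage {stage}: missing input {name}: {p}")
            manifest["inputs"][name] = _digest(Path(p))
        promoter = read_fasta(inputs["promoter"])[0]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # --- islands
    stage = "islands"
    try:
        params = IslandParams(**(cfg.get("islands") or {}))
        islands = find_cpg_islands(promoter, params)
        write_bed(islands, out / "islands.bed")
        write_island_tsv(islands, out / "islands.tsv")
        manifest["rows"]["islands"] = len(islands)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # --- scan
    stage = "scan"
    try:
        scan_cfg = cfg.get("scan") or {}
        catalogue = load_catalogue(scan_cfg.get("catalogue"))
        hits = scan_motifs(promoter, catalogue, scan_cfg.get("strands", "both"))
        write_hits_tsv(hits, catalogue, out / "hits.tsv")
        counts = count_by_category(hits, catalogue,
                                   scan_cfg.get("mode", "distinct_elements"))
        write_category_counts(counts, out / "category_counts.tsv")
        manifest["rows"]["hits"] = len(hits)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # --- methcall
    stage = "methcall"
    try:
        mc_cfg = cfg.get("methcall") or {}
        specs = read_amplicon_bed(inputs["amplicons"], promoter)
        clones = parse_clone_fasta(read_fasta(inputs["clones"]))
        calls, rejects = call_clone_table(
            clones, specs, mc_cfg.get("max_mismatch_frac", 0.10))
        calls.to_csv(out / "calls.tsv", sep="\t", index=False)
        rejects.to_csv(out / "rejects.tsv", sep="\t", index=False)
        for r in rejects.itertuples():
            manifest["warnings"].append(
                f"rejected clone {r.genotype}|{r.island}|{r.clone}: {r.reason}")
        summaries = summarize_table(calls)
        write_summary_tsv(summaries, out / "summary.tsv")
        manifest["rows"]["calls"] = len(calls)
        manifest["rows"]["rejected_clones"] = len(rejects)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # --- heterosis
    stage = "heterosis"
    try:
        het_cfg = cfg.get("heterosis") or {}
        designs = load_cross_designs(inputs["design"])
        reps = {r.genotype: r for r in read_replicates_tsv(inputs["expression"])}
        het_calls = []
        for design in designs:
            het_calls.append(classify_expression_pattern(
                reps[design.hybrid_id],
                reps[design.parent_high_dose.genotype],
                reps[design.parent_low_dose.genotype],
                design,
                alpha=het_cfg.get("alpha", 0.05),
                method=het_cfg.get("method", "pooled")))
        write_calls_tsv(het_calls, out / "heterosis.tsv")
        manifest["rows"]["heterosis_calls"] = len(het_calls)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # --- trend
    stage = "trend"
    try:
        tr_cfg = cfg.get("trend") or {}
        by_geno: Dict[str, list] = {}
        for s in summaries:
            by_geno.setdefault(s.genotype, []).append(s)
        reports = []
        for design in designs:
            if design.hybrid_id not in by_geno:
                continue
            reports.extend(methylation_mpv_trend(
                by_geno[design.hybrid_id],
                by_geno[design.parent_high_dose.genotype],
                by_geno[design.parent_low_dose.genotype],
                design, dead_band=tr_cfg.get("dead_band", 0.0)))
        write_trend_tsv(reports, out / "trend.tsv")
        manifest["rows"]["trend"] = len(reports)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def _sim_config_from_doc(doc: dict) -> SimulationConfig:
    from .simulate import GenotypeSpec, IslandSpec
    kwargs = dict(doc)
    if "island_specs" in kwargs:
        kwargs["island_specs"] = [IslandSpec(**d) for d in kwargs["island_specs"]]
    if "genotypes" in kwargs:
        kwargs["genotypes"] = [GenotypeSpec(**d) for d in kwargs["genotypes"]]
    if "expression_plan" in kwargs:
        kwargs["expression_plan"] = {k: (v[0], float(v[1]))
                                     for k, v in kwargs["expression_plan"].items()}
    return SimulationConfig(**kwargs)
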